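"""Input/output for every external format the pipeline touches.

All genomic intervals are stored 0-based half-open ``[start, end)`` on the
forward strand; GFF3's 1-based inclusive coordinates are converted at the
I/O edge and nowhere else.  Minus-strand exon lists are kept ascending by
genomic position; transcript order is derived on demand by the consumers.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import TreeNode

from .errors import InputError, InvariantError

VALID_STRANDS = {"+", "-"}


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with its identifier."""

    id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise InvariantError(f"empty sequence for record {self.id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """A transcript-level gene model anchored to genomic coordinates.

    ``exons`` and ``cds_segments`` are 0-based half-open intervals sorted
    ascending by genomic position regardless of strand.
    """

    gene_id: str
    transcript_id: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]]
    cds_segments: list[tuple[int, int]] = field(default_factory=list)
    n_isoforms: int = 1

    def __post_init__(self):
        if self.strand not in VALID_STRANDS:
            raise InputError(
                f"unknown strand {self.strand!r} for {self.transcript_id}"
            )
        if self.n_isoforms < 1:
            raise InvariantError(f"{self.gene_id}: n_isoforms must be >= 1")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        self.cds_segments = sorted((int(s), int(e)) for s, e in self.cds_segments)
        prev_end = None
        for s, e in self.exons:
            if s >= e:
                raise InvariantError(f"{self.transcript_id}: empty exon ({s},{e})")
            if prev_end is not None and s < prev_end:
                raise InvariantError(f"{self.transcript_id}: overlapping exons")
            prev_end = e
        for s, e in self.cds_segments:
            if not any(s >= xs and e <= xe for xs, xe in self.exons):
                raise InputError(
                    f"{self.transcript_id}: CDS segment ({s},{e}) outside exon span"
                )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_segments)

    def cds_segments_transcript_order(self) -> list[tuple[int, int]]:
        """CDS segments in the order the ribosome sees them."""
        if self.strand == "-":
            return list(reversed(self.cds_segments))
        return list(self.cds_segments)


def gff_to_internal(start_1based: int, end_inclusive: int) -> tuple[int, int]:
    """Convert a GFF 1-based inclusive interval to 0-based half-open."""
    return start_1based - 1, end_inclusive


def internal_to_gff(start: int, end: int) -> tuple[int, int]:
    """Inverse of :func:`gff_to_internal`."""
    return start + 1, end


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    Sequences are uppercased and terminal stop symbols ``*`` stripped from
    the ends (internal stops are preserved so they remain visible).
    Duplicate identifiers are an error; an empty file yields an empty list
    with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"FASTA file not found: {path}")
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise InputError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().strip("*")
        records.append(ProteinRecord(rec.id, seq))
    if not records:
        warnings.warn(f"FASTA file {path} contains no records")
    return records


def write_fasta(records, path, width: int = 70) -> None:
    """Write :class:`ProteinRecord` (or any id/sequence pairs) as FASTA."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seq_records, fh, "fasta")


# ---------------------------------------------------------------------------
# GFF3

def read_gff3(path) -> list[GeneModel]:
    """Read a gene/mRNA/exon/CDS GFF3 file into one GeneModel per mRNA.

    ``n_isoforms`` on every model of a gene is the number of mRNA children
    that gene has.  Coordinates are converted to the internal 0-based
    half-open convention.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"GFF3 file not found: {path}")
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
        n_iso = len(mrnas)
        for mrna in mrnas:
            exons = [
                gff_to_internal(f.start, f.end)
                for f in db.children(mrna, featuretype="exon", order_by="start")
            ]
            cds = [
                gff_to_internal(f.start, f.end)
                for f in db.children(mrna, featuretype="CDS", order_by="start")
            ]
            models.append(
                GeneModel(
                    gene_id=gene.id,
                    transcript_id=mrna.id,
                    chromosome=gene.seqid,
                    strand=mrna.strand,
                    exons=exons,
                    cds_segments=cds,
                    n_isoforms=n_iso,
                )
            )
    return models


def write_gff3(models: list[GeneModel], path) -> None:
    """Write gene models back out as GFF3 (one gene per distinct gene_id)."""
    by_gene: dict[str, list[GeneModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)
    lines = ["##gff-version 3"]
    for gene_id, group in by_gene.items():
        chrom = group[0].chromosome
        strand = group[0].strand
        g_start = min(m.start for m in group)
        g_end = max(m.end for m in group)
        s1, e1 = internal_to_gff(g_start, g_end)
        lines.append(
            f"{chrom}\tcdpkfam\tgene\t{s1}\t{e1}\t.\t{strand}\t.\tID={gene_id}"
        )
        for m in group:
            s1, e1 = internal_to_gff(m.start, m.end)
            lines.append(
                f"{chrom}\tcdpkfam\tmRNA\t{s1}\t{e1}\t.\t{strand}\t.\t"
                f"ID={m.transcript_id};Parent={gene_id}"
            )
            for i, (s, e) in enumerate(m.exons, 1):
                s1, e1 = internal_to_gff(s, e)
                lines.append(
                    f"{chrom}\tcdpkfam\texon\t{s1}\t{e1}\t.\t{strand}\t.\t"
                    f"ID={m.transcript_id}.exon{i};Parent={m.transcript_id}"
                )
            for i, (s, e) in enumerate(m.cds_segments, 1):
                s1, e1 = internal_to_gff(s, e)
                lines.append(
                    f"{chrom}\tcdpkfam\tCDS\t{s1}\t{e1}\t.\t{strand}\t0\t"
                    f"ID={m.transcript_id}.cds{i};Parent={m.transcript_id}"
                )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Newick

def _check_acyclic(tree: TreeNode) -> None:
    seen: set[int] = set()
    stack = [tree]
    while stack:
        node = stack.pop()
        if id(node) in seen:
            raise InvariantError("tree structure contains a cycle")
        seen.add(id(node))
        stack.extend(node.children)


def write_newick(tree: TreeNode) -> str:
    """Serialize a tree to a Newick string.

    Internal node names (bootstrap supports) and branch lengths survive a
    write/parse round trip.
    """
    _check_acyclic(tree)
    buf = io.StringIO()
    tree.write(buf)
    return buf.getvalue().strip()


def parse_newick(text: str) -> TreeNode:
    """Parse a Newick string into a tree."""
    return TreeNode.read(io.StringIO(text))


# ---------------------------------------------------------------------------
# Tables

def read_table(path, numeric_columns=None, dash_value=None) -> pd.DataFrame:
    """Read a TSV with a header row and row labels in the first column.

    ``numeric_columns`` (list of names, or ``"all"``) are coerced to float;
    in those columns the placeholder ``"-"`` is replaced by ``dash_value``
    (e.g. 1 for an isoform count where a dash means "no alternative
    splicing").  A non-numeric cell in a numeric column is an error naming
    the column.  Ragged rows raise an error carrying the line number.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"table not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                         on_bad_lines="error")
    except pd.errors.ParserError as exc:
        raise InputError(f"ragged TSV {path}: {exc}") from exc
    if numeric_columns is not None:
        cols = list(df.columns) if numeric_columns == "all" else numeric_columns
        for col in cols:
            series = df[col]
            if dash_value is not None:
                series = series.replace("-", str(dash_value))
            try:
                df[col] = pd.to_numeric(series)
            except (ValueError, TypeError) as exc:
                raise InputError(
                    f"non-numeric cell in column {col!r} of {path}: {exc}"
                ) from exc
    return df


def read_matrix(path) -> pd.DataFrame:
    """Read a fully numeric labelled matrix (expression values, Ct grids)."""
    return read_table(path, numeric_columns="all")


def load_family_table(path=None) -> pd.DataFrame:
    """Load the packaged reference table of the 40 maize CDPK genes.

    Columns: previous_name, accession, n_isoforms (a dash in the published
    splicing column means a single isoform), cds_length_nt, aa_length,
    mw_kda (carried verbatim, not validated), octapeptide (first eight
    residues), myristoylation (Yes/No), n_ef_hands.
    """
    if path is None:
        ref = resources.files("cdpkfam.data") / "cdpk_family_table.tsv"
        with resources.as_file(ref) as p:
            df = read_table(p)
    else:
        df = read_table(path)
    df = df.rename(columns={"alternative_splicing": "n_isoforms"})
    df["n_isoforms"] = pd.to_numeric(df["n_isoforms"].replace("-", "1")).astype(int)
    for col in ("cds_length_nt", "aa_length", "n_ef_hands"):
        df[col] = pd.to_numeric(df[col]).astype(int)
    bad = df[df["octapeptide"].str.len() != 8]
    if len(bad):
        raise InvariantError(f"octapeptides not length 8: {list(bad.index)}")
    if not df["n_ef_hands"].isin([0, 1, 2, 3, 4]).all():
        raise InvariantError("EF-hand counts outside 0..4 in family table")
    return df
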