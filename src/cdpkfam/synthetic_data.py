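"""Synthetic genomes, proteomes, gene models and expression data with
known ground truth.

The generator emulates the input structure of a genome-wide kinase-family
survey: a multi-chromosome genome carrying a planted family whose members
have the canonical domain architecture (N-terminal acylation motif for a
configured subset, Ser/Thr kinase catalytic triad, 1-4 EF-hand loops),
organised into phylogenetic groups by sequence similarity, with tandem and
segmental duplicate pairs created by per-site substitution at a target
identity, plus motif-free background genes.  Expression matrices carry
planted block structure and Ct tables are constructed so the delta-delta
Ct method recovers configured fold changes exactly in expectation.

All randomness flows from the single seed in :class:`GeneratorConfig`
through one named generator; the same config yields byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import motif_scan
from .errors import InputError
from .expression import CtTable
from .seqio import GeneModel, ProteinRecord, write_fasta, write_gff3

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# one representative codon per amino acid, for reverse translation
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}

# N-terminal octapeptides drawn from real family members: the first pool
# satisfies the myristoylation rule, the second does not.
MYR_OCTAPEPTIDES = ("MGNACSGA", "MGNACGGA", "MGQCCSKG", "MGACFSSA", "MGGRASRH")
NONMYR_OCTAPEPTIDES = ("MQPDPSGN", "MRRGGAGA", "MEDVKATY", "MGGHQLHL", "MVMAILTR")

EF_LOOP = "DKDGDGYISAAEL"
KINASE_ANCHOR_1 = "LAIK"  # VAIK-like beta-3 motif
KINASE_ANCHOR_2 = "HRD"
KINASE_ANCHOR_3 = "DFG"


@dataclass(frozen=True)
class GroupSpec:
    name: str
    n_members: int
    n_ef_hands: int = 4
    exon_range: tuple[int, int] = (2, 9)


@dataclass(frozen=True)
class DuplicationSpec:
    kind: str  # "tandem" | "segmental"
    target_identity: float = 0.9

    def __post_init__(self):
        if self.kind not in ("tandem", "segmental"):
            raise InputError(f"unknown duplication kind {self.kind!r}")
        if not 0.5 < self.target_identity <= 1.0:
            raise InputError("target_identity must be in (0.5, 1.0]")


@dataclass(frozen=True)
class ExpressionSpec:
    conditions: tuple[str, ...] = (
        "root", "stem", "leaf", "anther", "embryo", "endosperm", "seed",
        "tassel",
    )
    n_blocks: int = 4
    low_mean: float = 2.0
    high_mean: float = 8.0
    noise_sd: float = 0.25


@dataclass(frozen=True)
class CtSpec:
    reference_gene: str = "ZmActin"
    calibrator: str | None = None  # default: first condition
    n_replicates: int = 3
    noise_sd: float = 0.1
    reference_ct: float = 20.0
    target_base_ct: float = 25.0


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-scale defaults: a 10-chromosome genome bearing a 40-member
    family in four groups (17/11/9/3) with 10 segmental and 4 tandem
    duplicate pairs at ~90% identity, among motif-free background genes."""

    seed: int = 0
    n_chromosomes: int = 10
    n_background_genes: int = 60
    groups: tuple[GroupSpec, ...] = (
        GroupSpec("I", 17),
        GroupSpec("II", 11),
        GroupSpec("III", 9),
        GroupSpec("IV", 3, exon_range=(11, 12)),
    )
    duplications: tuple[DuplicationSpec, ...] = tuple(
        [DuplicationSpec("segmental", 0.9)] * 10
        + [DuplicationSpec("tandem", 0.9)] * 4
    )
    within_group_identity: float = 0.65
    between_group_identity: float = 0.40
    myristoylated_fraction: float = 17 / 40
    multi_isoform_fraction: float = 16 / 40
    expression: ExpressionSpec = ExpressionSpec()
    ct: CtSpec = CtSpec()

    @property
    def n_family_members(self) -> int:
        return sum(g.n_members for g in self.groups)


@dataclass
class GroundTruth:
    family_member_ids: list[str]
    group_labels: dict[str, str]
    duplications: list[dict]  # gene_a, gene_b, kind, target_identity
    myristoylated_ids: list[str]
    palmitoylated_ids: list[str]
    ef_hand_counts: dict[str, int]
    exon_counts: dict[str, int]
    n_isoforms: dict[str, int]

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class SyntheticGenome:
    proteins: list[ProteinRecord]
    cds: dict[str, str]  # gene id -> CDS nucleotide sequence (with stop)
    models: list[GeneModel]
    truth: GroundTruth

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.proteins, outdir / "proteins.fasta")
        write_fasta(
            [ProteinRecord(g, s) for g, s in self.cds.items()],
            outdir / "cds.fasta",
        )
        write_gff3(self.models, outdir / "genes.gff3")
        self.truth.to_json(outdir / "ground_truth.json")


# ---------------------------------------------------------------------------
# sequence-level helpers

def _pairwise_rate(identity: float) -> float:
    """Per-lineage substitution rate so that two sequences independently
    mutated from a common ancestor show the given expected pairwise
    identity (substitutions uniform over the 19 alternative residues)."""
    disc = 1.0 - (20.0 / 19.0) * (1.0 - identity)
    if disc < 0:
        raise InputError(f"pairwise identity {identity} unreachable")
    return (19.0 / 20.0) * (1.0 - math.sqrt(disc))


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _build_scaffold(
    rng: np.random.Generator, octapeptide: str, n_ef: int
) -> tuple[list[str], np.ndarray]:
    """Assemble a family-member protein and its protected-position mask.

    Layout (N to C): octapeptide, variable region, kinase domain with the
    three catalytic anchors, junction, calmodulin-like domain with n_ef
    EF-hand loops, tail.  Motif positions are protected from mutation.
    """
    parts: list[tuple[str, bool]] = [
        (octapeptide, True),
        (_random_protein(rng, 80), False),
        (KINASE_ANCHOR_1, True),
        (_random_protein(rng, 40), False),
        (KINASE_ANCHOR_2, True),
        (_random_protein(rng, 30), False),
        (KINASE_ANCHOR_3, True),
        (_random_protein(rng, 25), False),
    ]
    for _ in range(n_ef):
        parts.append((EF_LOOP, True))
        parts.append((_random_protein(rng, 16), False))
    parts.append((_random_protein(rng, 120), False))
    seq = list("".join(p for p, _ in parts))
    mask = np.concatenate(
        [np.full(len(p), prot) for p, prot in parts]
    )
    return seq, mask


def _mutate(
    rng: np.random.Generator,
    seq: list[str],
    mask: np.ndarray,
    total_rate: float,
) -> list[str]:
    """Substitute a fixed number of unprotected positions so the realized
    whole-sequence divergence equals ``total_rate`` (up to rounding): the
    planted identity is then deterministic rather than binomially noisy,
    which keeps pairwise identities tight at these sequence lengths."""
    n = len(seq)
    free = np.flatnonzero(~mask)
    n_sub = min(round(total_rate * n), len(free))
    if n_sub <= 0:
        return list(seq)
    out = list(seq)
    hits = rng.choice(free, size=n_sub, replace=False)
    for i in hits:
        choices = [a for a in AMINO_ACIDS if a != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return out


def _valid_member(seq: str, n_ef: int) -> bool:
    """Check the planted architecture survived mutation unchanged."""
    hits = motif_scan.scan_ef_hands(seq)
    if len(hits) != n_ef:
        return False
    span = motif_scan.scan_kinase_domain(seq)
    if span is None:
        return False
    return all(h.start >= span[1] for h in hits)


def _mutate_member(
    rng: np.random.Generator,
    seq: list[str],
    mask: np.ndarray,
    rate: float,
    n_ef: int,
    max_tries: int = 50,
) -> list[str]:
    for _ in range(max_tries):
        cand = _mutate(rng, seq, mask, rate)
        if _valid_member("".join(cand), n_ef):
            return cand
    raise InputError("could not mutate sequence without breaking its motifs")


def _reverse_translate(protein: str) -> str:
    return "".join(_CODON[a] for a in protein) + "TAA"


# ---------------------------------------------------------------------------
# genome generation

def _split_lengths(
    rng: np.random.Generator, total: int, n_parts: int, minimum: int = 30
) -> list[int]:
    """Split ``total`` into n_parts positive lengths, each >= minimum."""
    n_parts = max(1, min(n_parts, total // minimum))
    if n_parts == 1:
        return [total]
    base = total // n_parts
    jitter = max(1, (base - minimum) // 2)
    lengths = [base + int(rng.integers(-jitter, jitter + 1))
               for _ in range(n_parts - 1)]
    lengths = [max(minimum, v) for v in lengths]
    rest = total - sum(lengths)
    if rest < minimum:
        return [total]
    return lengths + [rest]


def generate_family_genome(config: GeneratorConfig) -> SyntheticGenome:
    """Generate proteins, CDS, gene models and ground truth for one genome."""
    rng = np.random.default_rng(config.seed)
    n_family = config.n_family_members
    if 2 * len(config.duplications) > n_family:
        raise InputError(
            "infeasible config: more duplicate slots than family members"
        )
    n_tandem = sum(1 for d in config.duplications if d.kind == "tandem")
    if n_tandem > config.n_chromosomes * max(1, n_family // 4):
        raise InputError("infeasible config: too many tandem pairs")

    q_within = _pairwise_rate(config.within_group_identity)
    q_total_between = _pairwise_rate(config.between_group_identity)
    # base-sequence divergence on top of member-level divergence
    q_base = max(0.0, 1.0 - (1.0 - q_total_between) / (1.0 - q_within))

    # member ids per group, then duplicate-pair selection (the second
    # member of each pair will be regenerated as a mutated copy of the
    # first, inheriting its N-terminus as close paralogs usually do)
    member_ids: list[str] = []
    group_labels: dict[str, str] = {}
    idx = 0
    for gspec in config.groups:
        for _ in range(gspec.n_members):
            idx += 1
            gid = f"CPK{idx:03d}"
            member_ids.append(gid)
            group_labels[gid] = gspec.name
    available = {g.name: [m for m in member_ids if group_labels[m] == g.name]
                 for g in config.groups}
    dup_records: list[dict] = []
    pair_of: dict[str, str] = {}
    copy_source: dict[str, str] = {}
    group_cycle = [g.name for g in config.groups]
    ci = 0
    for dspec in config.duplications:
        for _ in range(len(group_cycle)):
            name = group_cycle[ci % len(group_cycle)]
            ci += 1
            if len(available[name]) >= 2:
                a = available[name].pop(0)
                b = available[name].pop(0)
                break
        else:
            raise InputError("infeasible config: no group has two free members")
        a2, b2 = sorted((a, b))
        dup_records.append(
            {"gene_a": a2, "gene_b": b2, "kind": dspec.kind,
             "target_identity": dspec.target_identity}
        )
        pair_of[a] = b
        pair_of[b] = a
        copy_source[b] = a

    # octapeptide assignment: a configured fraction of members carries a
    # myristoylation-positive N-terminus; a duplicate pair shares one
    # N-terminus, so flags are assigned per pair-or-singleton unit
    n_myr = round(config.myristoylated_fraction * n_family)
    units: list[tuple[str, ...]] = [
        (a, pair_of[a]) for a in sorted(copy_source.values())
    ] + [(m,) for m in member_ids if m not in pair_of]
    unit_order = rng.permutation(len(units))
    myr_members: set[str] = set()
    for ui in unit_order:
        unit = units[ui]
        if len(myr_members) + len(unit) <= n_myr:
            myr_members |= set(unit)
        if len(myr_members) == n_myr:
            break

    ancestor, anc_mask = _build_scaffold(rng, MYR_OCTAPEPTIDES[0], 4)

    sequences: dict[str, list[str]] = {}
    masks: dict[str, np.ndarray] = {}
    group_of: dict[str, GroupSpec] = {}
    for gspec in config.groups:
        base = _mutate_member(rng, ancestor, anc_mask, q_base, 4)
        for gid in [m for m in member_ids if group_labels[m] == gspec.name]:
            pool = (MYR_OCTAPEPTIDES if gid in myr_members
                    else NONMYR_OCTAPEPTIDES)
            oct_ = pool[int(rng.integers(len(pool)))]
            for _attempt in range(50):
                seq = _mutate(rng, base, anc_mask, q_within)
                seq[:8] = list(oct_)
                mask = anc_mask.copy()
                if gspec.n_ef_hands < 4:
                    seq, mask = _drop_ef_hands(
                        rng, seq, mask, 4 - gspec.n_ef_hands
                    )
                if _valid_member("".join(seq), gspec.n_ef_hands):
                    break
            else:
                raise InputError("could not generate a valid family member")
            sequences[gid] = seq
            masks[gid] = mask
            group_of[gid] = gspec

    # duplicate copies: regenerate the second member of each pair as a
    # per-site mutated copy of the first at the pair's target identity
    for rec in dup_records:
        b = rec["gene_a"] if rec["gene_a"] in copy_source else rec["gene_b"]
        a = copy_source[b]
        sequences[b] = _mutate_member(
            rng, sequences[a], masks[a],
            1.0 - rec["target_identity"], group_of[b].n_ef_hands,
        )
        masks[b] = masks[a].copy()

    # background genes: free of both motif sets
    background_ids = [f"BGG{i:03d}" for i in range(1, config.n_background_genes + 1)]
    bg_seqs: dict[str, str] = {}
    for gid in background_ids:
        while True:
            length = int(rng.integers(200, 600))
            seq = _random_protein(rng, length)
            if (
                motif_scan.scan_kinase_domain(seq) is None
                and not motif_scan.scan_ef_hands(seq)
            ):
                bg_seqs[gid] = seq
                break

    # chromosome placement: tandem partners adjacent (<= 2 intervening
    # background genes), segmental partners on different chromosomes,
    # everything else round-robin; remaining background genes inserted
    # between blocks, never inside a tandem block
    placed: set[str] = set()
    blocks: list[list[list[str]]] = [[] for _ in range(config.n_chromosomes)]
    bg_pool = list(background_ids)
    cursor = 0

    def next_chrom() -> int:
        nonlocal cursor
        c = cursor % config.n_chromosomes
        cursor += 1
        return c

    for rec in dup_records:
        a, b = rec["gene_a"], rec["gene_b"]
        if rec["kind"] == "tandem":
            c = next_chrom()
            inner = [a]
            for _ in range(int(rng.integers(0, 3))):
                if bg_pool:
                    inner.append(bg_pool.pop(0))
            inner.append(b)
            blocks[c].append(inner)
        else:
            c1 = next_chrom()
            c2 = next_chrom()
            if c2 == c1:
                c2 = next_chrom()
            blocks[c1].append([a])
            blocks[c2].append([b])
        placed |= {a, b}
    for gid in member_ids:
        if gid not in placed:
            blocks[next_chrom()].append([gid])
    for gid in bg_pool:
        c = int(rng.integers(config.n_chromosomes))
        pos = int(rng.integers(len(blocks[c]) + 1))
        blocks[c].insert(pos, [gid])

    # gene models + coordinates
    all_prot: dict[str, str] = {g: "".join(s) for g, s in sequences.items()}
    all_prot.update(bg_seqs)
    n_multi = round(config.multi_isoform_fraction * n_family)
    multi_ids = set(
        rng.choice(member_ids, size=n_multi, replace=False)
    ) if n_multi else set()

    models: list[GeneModel] = []
    cds: dict[str, str] = {}
    exon_counts: dict[str, int] = {}
    n_isoforms: dict[str, int] = {}
    exon_n_of: dict[str, int] = {}
    for chrom_i in range(config.n_chromosomes):
        pos = int(rng.integers(1_000, 5_000))
        for block in blocks[chrom_i]:
            for gid in block:
                protein = all_prot[gid]
                cds_nt = _reverse_translate(protein)
                cds[gid] = cds_nt
                if gid in group_of:
                    lo, hi = group_of[gid].exon_range
                    partner = pair_of.get(gid)
                    n_ex = exon_n_of.get(
                        partner, int(rng.integers(lo, hi + 1))
                    ) if partner else int(rng.integers(lo, hi + 1))
                else:
                    n_ex = int(rng.integers(1, 7))
                seg_lengths = _split_lengths(rng, len(cds_nt), n_ex)
                strand = "+" if rng.random() < 0.5 else "-"
                genomic_lengths = (
                    list(reversed(seg_lengths)) if strand == "-" else seg_lengths
                )
                exons = []
                p = pos
                for k, length in enumerate(genomic_lengths):
                    exons.append((p, p + length))
                    p += length + int(rng.integers(80, 200))
                n_iso = int(rng.integers(2, 6)) if gid in multi_ids else 1
                for t in range(1, n_iso + 1):
                    models.append(
                        GeneModel(
                            gene_id=gid,
                            transcript_id=f"{gid}_T{t:02d}",
                            chromosome=f"chr{chrom_i + 1}",
                            strand=strand,
                            exons=list(exons),
                            cds_segments=list(exons),
                            n_isoforms=n_iso,
                        )
                    )
                exon_counts[gid] = len(exons)
                n_isoforms[gid] = n_iso
                exon_n_of[gid] = len(exons)
                pos = p + int(rng.integers(2_000, 8_000))

    # realized acylation ground truth from the member sequences themselves
    myr_ids, palm_ids = [], []
    for gid in member_ids:
        call = motif_scan.predict_acylation(all_prot[gid])
        if call.myristoylation:
            myr_ids.append(gid)
        if call.palmitoylation:
            palm_ids.append(gid)

    ef_counts = {
        gid: len(motif_scan.scan_ef_hands(all_prot[gid])) for gid in member_ids
    }
    order = {m.gene_id: i for i, m in enumerate(models)}
    proteins = [
        ProteinRecord(gid, all_prot[gid])
        for gid in sorted(all_prot, key=lambda g: order.get(g, 1 << 30))
    ]
    truth = GroundTruth(
        family_member_ids=list(member_ids),
        group_labels=group_labels,
        duplications=dup_records,
        myristoylated_ids=myr_ids,
        palmitoylated_ids=palm_ids,
        ef_hand_counts=ef_counts,
        exon_counts={g: exon_counts[g] for g in member_ids},
        n_isoforms={g: n_isoforms[g] for g in member_ids},
    )
    return SyntheticGenome(proteins, cds, models, truth)


def _drop_ef_hands(
    rng: np.random.Generator,
    seq: list[str],
    mask: np.ndarray,
    n_drop: int,
) -> tuple[list[str], np.ndarray]:
    """Scramble the last n_drop EF-hand loops so they no longer match."""
    s = "".join(seq)
    hits = motif_scan.scan_ef_hands(s)
    out = list(seq)
    mask = mask.copy()
    for hit in hits[len(hits) - n_drop:]:
        for _ in range(100):
            repl = _random_protein(rng, motif_scan.EF_LOOP_LENGTH)
            window = (
                "".join(out[: hit.start]) + repl
                + "".join(out[hit.start + motif_scan.EF_LOOP_LENGTH:])
            )
            if len(motif_scan.scan_ef_hands(window)) == len(
                motif_scan.scan_ef_hands("".join(out))
            ) - 1:
                out[hit.start: hit.start + motif_scan.EF_LOOP_LENGTH] = list(repl)
                mask[hit.start: hit.start + motif_scan.EF_LOOP_LENGTH] = False
                break
    return out, mask


# ---------------------------------------------------------------------------
# expression generation

def generate_expression(
    config: GeneratorConfig, gene_ids: list[str]
) -> tuple[pd.DataFrame, CtTable, dict]:
    """Block-structured expression matrix plus a matching Ct table.

    Genes are assigned to expression blocks round-robin; each block is
    high in its own subset of conditions and low elsewhere.  The Ct table
    is built so that the delta-delta Ct fold change of gene g in condition
    c (vs the calibrator condition) equals the ratio of noiseless block
    means; with zero Ct noise the recovery is exact.
    """
    if not gene_ids:
        raise InputError("gene_ids must be non-empty")
    rng = np.random.default_rng(config.seed + 1)
    spec = config.expression
    conditions = list(spec.conditions)
    n_blocks = min(spec.n_blocks, len(gene_ids))
    block_names = [chr(ord("A") + b) for b in range(n_blocks)]
    block_of = {g: block_names[i % n_blocks] for i, g in enumerate(gene_ids)}

    means = pd.DataFrame(index=gene_ids, columns=conditions, dtype=float)
    for i, g in enumerate(gene_ids):
        b = i % n_blocks
        for j, c in enumerate(conditions):
            means.loc[g, c] = (
                spec.high_mean if j % n_blocks == b else spec.low_mean
            )
    noise = rng.normal(0.0, spec.noise_sd, size=means.shape)
    matrix = (means + noise).clip(lower=0.0)

    ct_spec = config.ct
    calibrator = ct_spec.calibrator or conditions[0]
    true_folds = {
        g: {c: float(means.loc[g, c] / means.loc[g, calibrator])
            for c in conditions}
        for g in gene_ids
    }
    rows = []
    for c in conditions:
        for r in range(1, ct_spec.n_replicates + 1):
            rows.append(
                {
                    "gene": ct_spec.reference_gene,
                    "condition": c,
                    "replicate": r,
                    "ct": ct_spec.reference_ct
                    + rng.normal(0.0, ct_spec.noise_sd),
                }
            )
    for g in gene_ids:
        for c in conditions:
            true_ct = ct_spec.target_base_ct - math.log2(true_folds[g][c])
            for r in range(1, ct_spec.n_replicates + 1):
                rows.append(
                    {
                        "gene": g,
                        "condition": c,
                        "replicate": r,
                        "ct": true_ct + rng.normal(0.0, ct_spec.noise_sd),
                    }
                )
    ct_table = CtTable(
        pd.DataFrame(rows),
        reference_gene=ct_spec.reference_gene,
        calibrator=calibrator,
    )
    truth = {"blocks": block_of, "true_folds": true_folds,
             "calibrator": calibrator}
    return matrix, ct_table, truth
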