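"""Exon-intron architecture: intron phases, CDS/protein length arithmetic
and per-group structure comparison.

The intron phase after coding segment k is the cumulative CDS length
through segment k modulo 3, computed in transcript orientation (phase 0:
the intron falls between codons; 1 or 2: it splits a codon after the
first or second base).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median

import pandas as pd

from .errors import InputError
from .seqio import GeneModel


@dataclass
class GeneStructure:
    gene_id: str
    n_exons: int
    intron_phases: list[int] = field(default_factory=list)
    cds_length_nt: int = 0
    in_frame: bool = True  # False when CDS length is not divisible by 3


def derive_structure(model: GeneModel) -> GeneStructure:
    """Exon count, CDS length and intron phases for one gene model."""
    if not model.cds_segments:
        raise InputError(f"{model.transcript_id}: no CDS segments")
    segments = model.cds_segments_transcript_order()
    lengths = [e - s for s, e in segments]
    total = sum(lengths)
    phases = []
    cumulative = 0
    for length in lengths[:-1]:
        cumulative += length
        phases.append(cumulative % 3)
    return GeneStructure(
        gene_id=model.gene_id,
        n_exons=len(model.exons),
        intron_phases=phases,
        cds_length_nt=total,
        in_frame=(total % 3 == 0),
    )


def translate_cds_length(cds_length_nt: int, includes_stop: bool = True) -> int:
    """Protein length implied by a CDS length.

    With ``includes_stop`` the stop codon is subtracted: 1644 nt -> 547 aa.
    """
    if cds_length_nt % 3 != 0:
        raise InputError(f"CDS length {cds_length_nt} not divisible by 3")
    n = cds_length_nt // 3
    return n - 1 if includes_stop else n


def structure_similarity(
    groups: dict[str, str],
    structures: list[GeneStructure],
    max_range: int = 7,
) -> pd.DataFrame:
    """Per-group exon-count dispersion (min, max, median, range flag).

    Groups whose exon-count range exceeds ``max_range`` are flagged as
    structurally heterogeneous; within-group structure is expected to be
    conserved for a family with recent common origins.
    """
    by_group: dict[str, list[int]] = {}
    for s in structures:
        if s.gene_id not in groups:
            raise InputError(f"gene {s.gene_id!r} has no group label")
        by_group.setdefault(groups[s.gene_id], []).append(s.n_exons)
    rows = []
    for g in sorted(by_group):
        counts = sorted(by_group[g])
        rows.append(
            {
                "group": g,
                "n_genes": len(counts),
                "min_exons": counts[0],
                "max_exons": counts[-1],
                "median_exons": median(counts),
                "wide_range": counts[-1] - counts[0] > max_range,
            }
        )
    return pd.DataFrame(rows).set_index("group")
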