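"""Duplicated-gene detection and tandem/segmental classification.

A gene pair is a duplication event when the protein-level global alignment
covers more than 80% of the longer sequence and the aligned (gap-excluded)
region exceeds 80% identity; tightly linked passing genes are collapsed so
a tandem array counts as a single event.  An event is tandem when both
copies sit on the same chromosome with at most a small number of annotated
genes between them, otherwise segmental.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .errors import InputError, InvariantError
from .phylogeny import global_align, pairwise_stats
from .seqio import GeneModel, ProteinRecord

DEFAULT_TANDEM_MAX_INTERVENING = 5


@dataclass(frozen=True)
class DuplicationCriteria:
    """Thresholds for calling a duplication (both strict '>')."""

    min_coverage_of_longer: float = 0.80
    min_identity: float = 0.80
    linked_gene_collapse: bool = True

    def __post_init__(self):
        for v in (self.min_coverage_of_longer, self.min_identity):
            if not 0.0 < v < 1.0:
                raise InputError("duplication thresholds must be in (0, 1)")


@dataclass(frozen=True)
class DuplicationEvent:
    gene_a: str
    gene_b: str
    coverage: float
    identity: float
    kind: str  # "tandem" | "segmental"

    def __post_init__(self):
        if self.gene_a >= self.gene_b:
            raise InvariantError("event genes must be in canonical order a < b")
        if self.kind not in ("tandem", "segmental"):
            raise InvariantError(f"unknown duplication kind {self.kind!r}")


class GeneIndex:
    """Per-chromosome gene order, for counting intervening genes.

    Built from the full annotation (family plus background genes); one
    rank per distinct gene_id, ordered by start coordinate.
    """

    def __init__(self, models: list[GeneModel]):
        seen: dict[str, GeneModel] = {}
        for m in models:
            seen.setdefault(m.gene_id, m)
        self.chromosome: dict[str, str] = {}
        self.rank: dict[str, int] = {}
        by_chrom: dict[str, list[GeneModel]] = {}
        for m in seen.values():
            by_chrom.setdefault(m.chromosome, []).append(m)
        for chrom, group in by_chrom.items():
            group.sort(key=lambda m: (m.start, m.gene_id))
            for i, m in enumerate(group):
                self.chromosome[m.gene_id] = chrom
                self.rank[m.gene_id] = i

    def intervening(self, gene_a: str, gene_b: str) -> int | None:
        """Annotated genes strictly between a and b; None if on
        different chromosomes."""
        if self.chromosome.get(gene_a) != self.chromosome.get(gene_b):
            return None
        return abs(self.rank[gene_a] - self.rank[gene_b]) - 1


def classify_event(
    model_a: GeneModel,
    model_b: GeneModel,
    gene_index: GeneIndex,
    tandem_max_intervening: int = DEFAULT_TANDEM_MAX_INTERVENING,
) -> str:
    """Tandem iff same chromosome and few intervening genes, else segmental."""
    if model_a.chromosome != model_b.chromosome:
        return "segmental"
    between = gene_index.intervening(model_a.gene_id, model_b.gene_id)
    if between is None:
        return "segmental"
    return "tandem" if between <= tandem_max_intervening else "segmental"


def find_duplications(
    records: list[ProteinRecord],
    models: dict[str, GeneModel],
    criteria: DuplicationCriteria = DuplicationCriteria(),
    gene_index: GeneIndex | None = None,
    tandem_max_intervening: int = DEFAULT_TANDEM_MAX_INTERVENING,
) -> list[DuplicationEvent]:
    """Test all unordered pairs of family proteins for duplication.

    ``models`` maps each record id to its gene model; ``gene_index`` gives
    genome-wide gene order (defaults to an index over ``models`` alone).
    With ``linked_gene_collapse`` on, connected clusters of tandem-passing
    genes are collapsed to one event between the two highest-identity
    members.
    """
    for rec in records:
        if rec.id not in models:
            raise InputError(f"no gene model for record {rec.id!r}")
    if gene_index is None:
        gene_index = GeneIndex(list(models.values()))

    passing: list[DuplicationEvent] = []
    by_id = {r.id: r for r in records}
    for ra, rb in itertools.combinations(sorted(by_id), 2):
        a, b = by_id[ra], by_id[rb]
        aln = global_align(a.sequence, b.sequence)
        stats = pairwise_stats(aln, max(len(a), len(b)))
        if (
            stats.coverage > criteria.min_coverage_of_longer
            and stats.identity > criteria.min_identity
        ):
            kind = classify_event(
                models[ra], models[rb], gene_index, tandem_max_intervening
            )
            passing.append(
                DuplicationEvent(ra, rb, stats.coverage, stats.identity, kind)
            )

    if not criteria.linked_gene_collapse:
        return passing

    # collapse transitive clusters of tandem-linked genes to one event
    tandem = [e for e in passing if e.kind == "tandem"]
    segmental = [e for e in passing if e.kind == "segmental"]
    adjacency: dict[str, set[str]] = {}
    for e in tandem:
        adjacency.setdefault(e.gene_a, set()).add(e.gene_b)
        adjacency.setdefault(e.gene_b, set()).add(e.gene_a)
    seen: set[str] = set()
    collapsed: list[DuplicationEvent] = []
    for start in sorted(adjacency):
        if start in seen:
            continue
        component = set()
        stack = [start]
        while stack:
            g = stack.pop()
            if g in component:
                continue
            component.add(g)
            stack.extend(adjacency[g] - component)
        seen |= component
        in_component = [
            e for e in tandem
            if e.gene_a in component and e.gene_b in component
        ]
        best = max(in_component, key=lambda e: (e.identity, e.coverage,
                                                e.gene_a, e.gene_b))
        collapsed.append(best)
    return sorted(segmental + collapsed, key=lambda e: (e.gene_a, e.gene_b))


def chromosome_summary(
    models: list[GeneModel],
    cluster_window: int = 5_000_000,
    cluster_min: int = 3,
) -> dict[str, dict]:
    """Per-chromosome family gene counts plus a physical-clustering flag.

    A chromosome is flagged clustered when at least ``cluster_min`` genes
    start within any window of ``cluster_window`` bases.
    """
    seen: dict[str, GeneModel] = {}
    for m in models:
        seen.setdefault(m.gene_id, m)
    by_chrom: dict[str, list[int]] = {}
    for m in seen.values():
        by_chrom.setdefault(m.chromosome, []).append(m.start)
    out: dict[str, dict] = {}
    for chrom, starts in sorted(by_chrom.items()):
        starts.sort()
        clustered = False
        for i in range(len(starts) - cluster_min + 1):
            if starts[i + cluster_min - 1] - starts[i] <= cluster_window:
                clustered = True
                break
        out[chrom] = {"count": len(starts), "clustered": clustered}
    return out
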