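"""Domain-architecture annotation of candidate family members.

A calcium-dependent protein kinase (CDPK) has, N- to C-terminal: a variable
region, a Ser/Thr kinase catalytic domain, an autoinhibitory junction and a
calmodulin-like domain carrying 1-4 EF-hand Ca2+-binding loops.  Family
membership is decided purely from this architecture: a kinase-domain hit
followed by one to four EF hands.  N-terminal acylation (myristoylation at
Gly-2, palmitoylation at Cys 3-5) is predicted from the first residues.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .errors import InputError
from .seqio import ProteinRecord

# PROSITE-style N-myristoylation site anchored at the initiator Met
# (positions are 1-based with Met = 1):
#   2: G            (glycine receives the myristate after Met cleavage)
#   3: not E D R K H P F Y W
#   6: S T A G C N  (small residue packing into the NMT binding pocket)
#   7: not P
_MYR_POS3_FORBIDDEN = frozenset("EDRKHPFYW")
_MYR_POS6_ALLOWED = frozenset("STAGCN")

# EF-hand Ca2+-binding loop, 13 positions (PROSITE-style pattern):
# D-x-[DNS]-{ILVFYW}-[DENSTG]-[DNQGHRK]-{GP}-[LIVMC]-[DENQSTAGC]-x(2)-[DE]-
# [LIVMFYW]
EF_HAND_LOOP = re.compile(
    r"D.[DNS][^ILVFYW][DENSTG][DNQGHRK][^GP][LIVMC][DENQSTAGC].{2}[DE][LIVMFYW]"
)
EF_LOOP_LENGTH = 13

# Catalytic anchors of the protein kinase domain, in order:
# VAIK-like (beta-3 lysine), HRD (catalytic loop), DFG (Mg2+ binding).
_VAIK = re.compile(r"[LIVMF].[LIVMF]K")
_HRD = re.compile(r"HRD")
_DFG = re.compile(r"DFG")
# Inter-anchor spacing bounds (residues between the end of one anchor and
# the start of the next); generous limits that admit real kinase domains
# while rejecting chance co-occurrence in unrelated sequence.
ANCHOR_GAP_MIN = 10
ANCHOR_GAP_MAX = 120


@dataclass(frozen=True)
class AcylationCall:
    myristoylation: bool
    palmitoylation: bool
    matched_positions: tuple[int, ...] = ()  # Cys positions among 3..5, 1-based


@dataclass(frozen=True)
class EFHandHit:
    start: int  # 0-based position of the 13-residue loop
    loop_sequence: str


@dataclass
class DomainAnnotation:
    protein_id: str
    kinase_span: tuple[int, int] | None
    ef_hands: list[EFHandHit] = field(default_factory=list)
    acylation: AcylationCall | None = None
    is_family_member: bool = False


def predict_acylation(sequence: str) -> AcylationCall:
    """Predict N-terminal myristoylation and palmitoylation.

    Myristoylation requires (1-based, Met = 1) Gly at 2, a permissive
    residue at 3, a small residue at 6 and no Pro at 7.  Palmitoylation is
    only evaluated on the myristoylated set and requires at least one Cys
    at positions 3-5.
    """
    if len(sequence) < 7:
        raise InputError(
            f"sequence too short for acylation prediction ({len(sequence)} < 7)"
        )
    s = sequence.upper()
    myr = (
        s[1] == "G"
        and s[2] not in _MYR_POS3_FORBIDDEN
        and s[5] in _MYR_POS6_ALLOWED
        and s[6] != "P"
    )
    cys_positions = tuple(p for p in (3, 4, 5) if s[p - 1] == "C")
    palm = myr and bool(cys_positions)
    return AcylationCall(myr, palm, cys_positions if myr else ())


def scan_ef_hands(sequence: str) -> list[EFHandHit]:
    """Greedy left-to-right non-overlapping scan for EF-hand loops."""
    s = sequence.upper()
    return [
        EFHandHit(m.start(), m.group(0)) for m in EF_HAND_LOOP.finditer(s)
    ]


def scan_kinase_domain(sequence: str) -> tuple[int, int] | None:
    """Locate a Ser/Thr kinase domain via its ordered catalytic triad.

    Present iff the VAIK-like, HRD and DFG anchors occur in order with each
    inter-anchor gap between ANCHOR_GAP_MIN and ANCHOR_GAP_MAX residues.
    Returns the (start, end) span from the first anchor's start to the last
    anchor's end (0-based half-open), or None.
    """
    s = sequence.upper()
    for v in _VAIK.finditer(s):
        for h in _HRD.finditer(s, v.end()):
            gap1 = h.start() - v.end()
            if gap1 < ANCHOR_GAP_MIN:
                continue
            if gap1 > ANCHOR_GAP_MAX:
                break
            for d in _DFG.finditer(s, h.end()):
                gap2 = d.start() - h.end()
                if gap2 < ANCHOR_GAP_MIN:
                    continue
                if gap2 > ANCHOR_GAP_MAX:
                    break
                return (v.start(), d.end())
    return None


def classify_family_member(annotation: DomainAnnotation) -> bool:
    """Family membership: kinase domain N-terminal to 1-4 EF hands.

    Kinases with a kinase domain but no EF hand (CDPK-related kinase
    architecture) are excluded, as are EF-hand proteins without a kinase
    domain.
    """
    if annotation.kinase_span is None:
        return False
    n_ef = len(annotation.ef_hands)
    if not 1 <= n_ef <= 4:
        return False
    kinase_end = annotation.kinase_span[1]
    return all(hit.start >= kinase_end for hit in annotation.ef_hands)


def annotate(record: ProteinRecord) -> DomainAnnotation:
    """Full domain annotation of one protein."""
    ann = DomainAnnotation(
        protein_id=record.id,
        kinase_span=scan_kinase_domain(record.sequence),
        ef_hands=scan_ef_hands(record.sequence),
        acylation=(
            predict_acylation(record.sequence)
            if len(record.sequence) >= 7
            else AcylationCall(False, False)
        ),
    )
    ann.is_family_member = classify_family_member(ann)
    return ann


def annotate_proteome(records: list[ProteinRecord]) -> pd.DataFrame:
    """Annotate every record; one row per protein, stable input order."""
    rows = []
    for rec in records:
        ann = annotate(rec)
        ks, ke = ann.kinase_span if ann.kinase_span else (-1, -1)
        rows.append(
            {
                "protein_id": ann.protein_id,
                "kinase_start": ks,
                "kinase_end": ke,
                "n_ef_hands": len(ann.ef_hands),
                "ef_positions": ",".join(str(h.start) for h in ann.ef_hands),
                "myristoylation": ann.acylation.myristoylation,
                "palmitoylation": ann.acylation.palmitoylation,
                "is_family_member": ann.is_family_member,
            }
        )
    return pd.DataFrame(rows).set_index("protein_id")
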