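# Methods

This note documents the models and procedures implemented in `cdpkfam`,
the parameter choices that matter, what the synthetic-data generator does
and does not emulate, and the package's known limitations.

## Family identification by domain architecture

A protein is called a family member when it shows the canonical CDPK
layout: a Ser/Thr kinase catalytic domain N-terminal to one to four
EF-hand Ca²⁺-binding loops. Kinases lacking EF hands (the CDPK-related
kinase architecture) and EF-hand proteins lacking a kinase domain are
excluded.

**Kinase domain.** Detected as the ordered co-occurrence of three
catalytic anchors — a β3-lysine VAIK-like motif (`[LIVMF]-x-[LIVMF]-K`),
the catalytic-loop `HRD`, and the Mg²⁺-binding `DFG` — with each
inter-anchor gap between 10 and 120 residues. The bounds are generous
enough for real kinase domains (typical spacings are ~40 and ~30
residues) while making chance co-occurrence in unrelated sequence rare;
they gate only the screen, never a reported quantity. This motif-triad
screen replaces profile-HMM/domain-database annotation, which is out of
scope; it is a desk-scale approximation whose false-positive rate on
random sequence is checked empirically by the background-genome tests.

**EF hands.** A 13-position PROSITE-style loop pattern
(`D-x-[DNS]-{ILVFYW}-[DENSTG]-[DNQGHRK]-{GP}-[LIVMC]-[DENQSTAGC]-x(2)-[DE]-[LIVMFYW]`),
scanned greedily left to right without overlap. Greedy leftmost matching
is deterministic and mirrors the tandem arrangement of real EF hands.
Counts above four void family membership rather than being truncated.

**N-terminal acylation.** Myristoylation is called on the first seven
residues anchored at the initiator Met (1-based): Gly at 2, position 3
not in {E,D,R,K,H,P,F,Y,W}, position 6 in {S,T,A,G,C,N}, position 7 not
Pro. Glycine-2 alone over-calls: several published negative calls begin
`MG`, so the full PROSITE-style rule is used; it reproduces all 40
published per-gene calls exactly (17 positive). Palmitoylation is
evaluated only on the myristoylated set and requires ≥ 1 Cys among
positions 3–5 (15 positive). The rule is a sequence-pattern heuristic:
it knows nothing about N-myristoyltransferase substrate context beyond
these positions.

## Phylogeny

**Distances.** All-against-all global alignments (Needleman–Wunsch with
affine gaps) using BLOSUM62, gap open 10, gap extend 0.5 — standard
defaults; the first residue of a gap costs the open penalty. Identity is
computed over residue–residue columns (gap-excluded); the distance is the
p-distance d = 1 − identity. A full progressive multiple alignment is
deliberately not reimplemented; for bootstrap analysis the package
accepts an externally computed MSA in aligned FASTA. p-distance is used
rather than a Poisson or other correction; at the within-family
divergences involved the choice does not affect topology in practice.

**Neighbor joining.** Classical Saitou–Nei agglomeration: join the pair
minimising Q(i,j) = (n−2)d(i,j) − Σₖd(i,k) − Σₖd(j,k); branch lengths
from the standard formulas with negative estimates clamped to zero (the
convention of mainstream tree software); new-node distances by the
reduction formula. Ties in Q (within 1e-12) break on the
lexicographically smallest pair of subtree labels, making output
deterministic and independent of input order. The result is unrooted
(trifurcation at the root), with n−2 internal nodes for n leaves.
Correctness is established two ways: exact recovery of the generating
topology on additive matrices, and node-by-node agreement with an
independently written brute-force implementation on random matrices.

**Bootstrap.** Alignment columns are resampled with replacement per
replicate; the support of each internal bipartition of the
point-estimate tree is the percentage of replicate trees containing it,
written as an integer internal-node label. Rows are canonically ordered
by label before any computation, so supports are invariant to input
order; all resampling flows from one seed.

**Group assignment.** Queries are labelled from user-supplied reference
leaves (each group needs ≥ 2). For a query, the smallest bipartition
side containing it and at least one reference decides: if that side's
references are all one group, the query takes that label, otherwise it
is `unassigned`. Group labels are never hard-coded.

## Duplication detection

A pair of family proteins is a duplication event when (i) the alignment
covers > 80% of the longer protein (coverage = residue–residue columns /
longer length) and (ii) gap-excluded identity > 80%; both comparisons
are strict. Identity's denominator is aligned residue pairs — the
standard reading when only "identity of the aligned region" is
specified. Among passing genes that are tightly linked, transitive
clusters collapse to a single event between the two highest-identity
members, so a tandem array is counted once. Classification: *tandem*
when both genes share a chromosome with at most `tandem_max_intervening`
(default 5) annotated genes between them, else *segmental*. The
intervening-gene radius is a parameter, not a biological claim; it is
exposed on the CLI. Alignments are protein-level.

## Gene structure

Intron phase after coding segment k is the cumulative CDS length through
segment k modulo 3, computed in transcript orientation (minus-strand
models store exons in ascending genomic order and reverse them on
demand). A CDS total not divisible by 3 sets a flag rather than raising:
real annotations contain such models. Published CDS lengths are treated
as including the stop codon, so protein length = nt/3 − 1; this relation
holds for all 40 rows of the packaged table, which is the consistency
sweep the tests run. Per-group structure comparison reports min, max and
median exon counts and flags groups whose range exceeds a width
parameter (default 7).

## Expression

**ΔΔCt.** Replicate Ct values are averaged arithmetically before any
delta (the conventional reading of the method; the alternative —
medians, or averaging fold changes — is not offered). With reference
gene r, calibrator c: ΔCt(s) = Ct(t,s) − Ct(r,s), ΔΔCt = ΔCt(s) − ΔCt(c),
fold = 2^(−ΔΔCt). PCR efficiency is fixed at perfect doubling; no
efficiency correction. The calibrator must be named explicitly — there
is no default, because the natural calibrator (untreated t = 0 versus a
tissue-matched control) is experiment-specific.

**Clustering.** Agglomerative, Euclidean distance, complete linkage
(inter-cluster distance = maximum pairwise), via scipy's linkage; merge
heights are asserted non-decreasing on every construction, which
complete linkage guarantees. Cutting at k uses the lowest height that
yields k clusters. Clustering runs on unscaled values; per-gene z-scores
are available separately for display only.

## Synthetic-data generator

The generator emulates the input structure of the study system: a
10-chromosome genome bearing a 40-member family in four groups of
17/11/9/3, with 10 segmental and 4 tandem duplicate pairs at ~90%
identity, 17/40 members carrying myristoylation-positive N-termini,
16/40 with multiple annotated isoforms, group IV with 11–12 exons and
the other groups 2–9, among motif-free background genes. These defaults
are the study conditions; smaller configurations are used where a test
only needs a cheap genome.

Mechanics worth knowing:

- Family members derive from one ancestor scaffold (octapeptide,
  variable region, anchored kinase domain, junction, EF-hand loops,
  tail; ~430 aa). Group bases and members are produced by substitutions
  at non-motif positions; motif positions are protected so ground truth
  stays valid, and each candidate is re-scanned after mutation and
  redrawn if a motif was created or destroyed.
- Substitution counts are fixed at the expectation rather than sampled
  per-site, so a planted identity is realized deterministically
  (± rounding) instead of with binomial spread; per-lineage rates are
  solved from the target *pairwise* identities accounting for
  back-substitution (two lineages at per-site rate q show expected
  identity (1−q)² + q²/19).
- Default within-group identity is 0.65 — typical paralog divergence,
  and safely below the 0.8 duplication threshold so only planted pairs
  can pass it. Duplicate copies are made from one partner at the pair's
  target identity; tandem copies are placed with ≤ 2 intervening genes,
  segmental copies on another chromosome.
- Expression matrices are block-structured (per-block high/low condition
  means 8/2, Gaussian noise sd 0.25); Ct tables are built so ΔΔCt
  recovers the block-mean fold ratios exactly at zero noise (reference
  gene flat at Ct 20, targets at 25 − log₂fold, noise sd 0.1 cycles,
  triplicate).
- All randomness flows from the single config seed; identical configs
  produce byte-identical files.

What the generator does **not** emulate: real codon usage, intron
sequence content, UTRs, microarray probe behaviour, unequal family
length distributions, or alignment-ambiguous indel divergence (planted
divergence is substitution-only, so alignment coverage of planted pairs
is ~1). Passing recovery tests therefore demonstrates the pipeline's
algorithmic correctness under controlled divergence, not its robustness
to messy real annotations.

## Numerical and degenerate-input choices

- Alignment tie-breaks follow the aligner's deterministic first
  traceback; identity/coverage do not depend on which co-optimal
  alignment is chosen in the tested regimes.
- A fully gapped alignment (no residue–residue column) reports
  identity 0 with an explicit flag rather than NaN.
- NJ tie-break: smallest sorted label pair; bootstrap bipartitions are
  canonicalised as the side not containing the smallest leaf label.
- Zero-valued fold-change references yield missing folds, flagged, never
  infinities.
- GFF3 coordinates convert 1-based inclusive ↔ 0-based half-open exactly
  once, at the I/O boundary; the conversion is its own inverse and is
  property-tested.

## Limitations

- The kinase screen is a motif heuristic; diverged catalytic anchors
  (e.g. non-HRD catalytic loops) are missed by construction.
- EF-hand counting uses one loop pattern; degenerate loops that a
  profile method would score are not counted, so EF counts on real
  proteins may read low.
- The published tree topology and group memberships for the real maize
  family require the external full-length maize/rice/Arabidopsis
  sequences and are not reproduced here; the corresponding capability is
  validated by parameter recovery on planted groups (within ~80%,
  between ~40% identity, ≥ 95% correct reassignment).
- Stress-response fold changes from the study's RNA are likewise not
  reproducible; the ΔΔCt machinery is validated on constructed and
  generated Ct tables instead.
- The published molecular-weight column is carried verbatim in the
  packaged table but validated against nothing: its units are not
  internally consistent, and no computation uses it.
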