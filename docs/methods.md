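# Methods

This note documents the models and procedural choices behind `nacfam`, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the places where a design decision had to be made.

## Domain identification

Production use consumes HMMER3 per-domain tables (`--domtblout`): one
`DomainHit` per row, with 1-based inclusive envelope coordinates, and a
protein is retained when any hit has full-sequence E-value strictly below
0.01. Whether the cutoff should apply to the full-sequence or the
conditional per-domain E-value is genuinely ambiguous in this kind of
survey; the full-sequence value is the default and `per_domain=True`
switches.

The internal scanner exists so that synthetic proteomes can be screened
without external binaries. It is an *ungapped* position-specific log-odds
profile, not a profile HMM: columns with ≥ 50% gaps are dropped, each cell
scores `log2(((count + pc) / (n + 20·pc)) / background)` with pseudocount
`pc = 1` and the background taken from the training alignment itself, and a
scan reports maximal non-overlapping windows above a threshold (default
half of the profile's maximum achievable score). Window score is reported
as the bit score; the accompanying E-value is the desk-scale conversion
`n_windows · 2^-score`. Indel-free synthetic sequences make the ungapped
assumption exact; for real proteomes HMMER remains the tool of choice and
its output is parsed instead.

The NT/CT boundary follows the envelope end of the *last* qualifying domain
by default (`boundary="first"` is available): the NAM subdomains A–D define
the NT part and the remainder is the TAR, which may be empty. Subdomain
coordinates are located by exact anchor-motif match on synthetic data or
supplied as an annotation table for real data, because the literature
locates subdomains by reference alignment rather than by a stated
algorithm.

## Alignment completeness

`Ca`, `Cr`, `Cc` follow the AliStat definitions with `-` and `X` both
counted as missing. The pairwise score `Cij` uses the total alignment
length as denominator (the simplest reading of "shared completeness");
alternative AliStat variants normalise differently, so the choice is
documented here and isolated in one function. Filtering removes a sequence
when its best `Cij` against any partner is below 0.5; masking drops columns
with `Cc < 0.6`; duplicates collapse to the lexicographically smallest
identifier for determinism, with a surplus map for re-attachment.

## Subfamily classification

A query leaf is assigned label `L` when the smallest clade that contains the
query and at least one reference leaf, and whose subtending edge carries
support ≥ 70, contains references of subfamily `L` only. Supports live on
edges (bipartitions), so rerooting cannot detach them; unlabeled supports
count as 0, the conservative reading; the whole-tree "clade" never
qualifies because the root carries no bootstrap. A species-specific tree
can serve as fallback for leaves the joined tree leaves unclassified
(provenance `species-tree-fallback`); the joined tree takes precedence.

Pathogen-enriched subclades are the *maximal* clades with ≥ 5 members
(configurable; the source material is silent on a floor) and a responsive
fraction ≥ 0.6, both boundaries inclusive; reported clades never nest.

## Homoeolog grouping and nomenclature

Grouping is tree-primary with an anchor-table fallback:

1. Genes pool by ortholog anchor (anchorless genes pool by subfamily).
2. Within a pool, tandem inparalogs merge first: same chromosome and global
   pairwise protein identity ≥ 80%, by union-find over an O(n²) sweep. The
   identity scheme is fixed and documented: global alignment, match +1,
   mismatch −1, gap open −5, gap extend −0.5; identity = matching columns /
   aligned columns with terminal overhangs excluded.
3. A homoeolog group is then the **largest** supported clade (≥ 70) whose
   query leaves are exactly a set of unmerged units with pairwise-distinct
   subgenomes; widest-first matters, since smallest-first would carve a
   triad into a pair plus a singleton. A chromosome-U unit may join a group
   that already holds at least two located homoeologs, and at most one U
   unit per group.
4. Units no supported clade resolves fall back to the anchor table:
   anchored leftovers are packed greedily by chromosome position into
   subgenome-disjoint groups; anchorless leftovers stay singletons.

Names render as `TaNAC<base>-<subgenome><group>(-<paralog>)`. The base
comes from the anchor's number; when a gene is orthologous to several
anchors on one rice chromosome the first by position rank wins. Groups
sharing a base are numbered 1..k in ladderized tree order (children sorted
by clade size, ties by smallest leaf label — a pure function of topology,
chosen because "position in a tree" needs a deterministic reading).
Anchorless groups receive consecutive bases from 153 (configurable; the
value continues an existing rice catalogue of 152 names), subfamily *b*
first and then ladderized order. Paralog digits follow chromosome position
rank. Duplicate names are impossible by construction and guarded by an
internal check.

## Expression rules and statistics

Responsiveness: any condition (pathogen × genotype × timepoint) with
|log2FC| > 1 and adjusted p < 0.05, both strict. The upstream tables are
DESeq2-style, so "p" is taken as the adjusted value; a raw-p mode exists
but neither interpretation is asserted as canonical. Lifestyle categories
follow the pathogen panel map (Fg/Fp/Zt hemibiotrophs, Ps/Bg biotrophs, Xt
bacterial hemibiotroph); the universal response means ≥ 2 pathogens.

Baseline tpm uses per-organ means over five organs (grain, leaf, root,
spike, stem) with a 0.1 tpm expressed cutoff. Bin edges default to the
1st/3rd quartiles of the expressed distribution; the fixed pair (0.3, 3.7)
tpm reproduces the published desk values. Gene-wise normalisation
(divide-by-max) is a display transform only; bins always come from raw
means.

Fisher enrichment is the two-sided exact test per subfamily against the
rest of the family, reported raw and BH-adjusted (the adjustment across
subfamilies is a choice, not a quote). The family-vs-genome comparison is
a Pearson 2×2 χ² without continuity correction (flag to enable).
Kruskal–Wallis uses the tie-corrected H; the step-down homogeneous subsets
are built greedily over groups ordered by mean rank, extending a subset
while the within-subset KW test stays non-significant at 0.05 — the
SPSS procedure it mirrors is under-documented, so the greedy variant is
implemented and labeled as such. The Moses test trims `h = 1` control
values per tail by default, measures the span of the remaining control
ranks, and computes `P(span ≤ observed)` exactly from the combinatorial
distribution (counts of rank placements); ties are broken by input order,
so the exact p assumes effectively continuous data.

## The synthetic-data generator

The generator emulates the *structure* the pipeline consumes, not the
biology underneath it:

* Sequences are built by mutating a fixed 212-residue NAM-bearing template
  at free sites; the five subdomain anchor motifs (8 aa each, including the
  `WKATGTDK` DNA-recognition motif of subdomain C) and the initial Met are
  never touched. There are no indels, so "alignment" is the identity map
  and the internal ungapped scanner is exact.
* Identity targets are hit by substitution counts: group ancestors diverge
  so that cross-group identity lands near 65% (safely below the 80% merge
  rule), homoeologs within a group near 94%, and inparalog copies at the
  configured 90% against their unit base, drawn from a shared mutation pool
  so copy-to-copy identity stays ≥ ~85%.
* Families default to 8 subfamilies (*a*–*h*), 64 anchor slots (~200 genes)
  with a 0.7 triad rate, 0.15 inparalog rate, 0.2 orphan rate, a 0.1 chance
  that an anchor carries a second homoeologous group, and a 0.04 chance
  that a triad member sits on chromosome U. Planted responsiveness rates
  differ by subfamily (a 0.80, e 0.45, f 0.67 versus c 0.11, h 0.08 and
  0.25 elsewhere) so that enrichment tests have signal, mirroring the kind
  of contrast real surveys report.
* DE tables plant adjusted p = 0.001 on exactly one passing condition per
  responsive pathogen and keep every other row below both thresholds
  (|log2FC| < 1, p ≥ 0.05), because the pipeline consumes a DE table, not
  reads; there is deliberately no count-level noise model.
* CT motifs occupy three fixed slots: a subfamily signature (carried with
  probability 0.95), a responsiveness-linked motif (0.9 for responsive
  units, 0.05 otherwise) and a grain-linked motif. Carriage is decided per
  homoeolog unit so planting never erodes inparalog identity. Decoys are
  per-sequence shuffles of real family members, preserving composition.
* True names are computed from the generator's own topology with the same
  ladderized-order convention the nomenclature stage documents; grouping,
  identity computation and anchoring are recovered independently by the
  pipeline, which is what the truth-recovery tests measure.

What passing tests therefore show: the *rules* (thresholds, grouping,
naming grammar, statistics) are implemented correctly and recover a planted
structure exactly under clean supports, degrading as supports degrade.
What they do not show: robustness to indels, alignment error, incomplete
ortholog tables, annotation noise, or count-level DE uncertainty — none of
which the generator emulates.

One measured caveat: subfamily classification accuracy is exactly
monotone in support noise (losing a support can only turn a label into
`unclassified`), but naming accuracy is not — at high noise the
ortholog-table fallback re-derives many groups without the tree, creating a
recovery floor. The tests assert monotone classification and
degraded-but-floored naming accordingly.

## Problem sizes

The test suite and the acceptance script use families of ~50–210 genes
(8–64 anchor slots), 10–200 decoys, 100-replicate property checks for the
completeness identities and enrichment calibration, and exhaustive
enumeration oracles up to n = 12 for the exact tests. A full pipeline run
at the default size completes in about a second; the whole suite runs in a
few seconds.

## Known limitations

* The internal scanner is ungapped and unsuitable for indel-rich real
  proteins; it stands in for HMMER only at desk scale.
* `Cij` uses the full-alignment denominator; AliStat's exact variant
  definitions differ and real AliStat output will not match cell-for-cell.
* The step-down subset procedure is a documented greedy variant, not a
  re-implementation of SPSS's unpublished algorithm.
* The Moses exact p assumes no ties; heavily tied data should be jittered
  or bootstrapped instead.
* MEME motif *discovery* is out of scope; only its output formats are
  consumed, and the planted-motif scanner is an exact-string stand-in used
  with synthetic data.
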