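# Methods

This note documents the models, conventions and numerical choices behind
`spliceshield`, and what the synthetic validation does and does not
demonstrate.

## Interface extraction

Contacts use an all-atom distance criterion: atoms a, b on different
chains are in contact when d(a,b) ≤ r(a) + r(b) + margin, with a 0.5 Å
margin.  The van der Waals radii table ships in
`structures.VDW_RADII` (C 1.70, N 1.55, O 1.52, S 1.80, H 1.20,
P 1.80 Å); unknown elements fall back to 1.80 Å with a warning, or raise
when the fallback is disabled.  Hydrogens are used when present.  For
alternate locations the highest-occupancy conformer is kept, ties
resolved toward the earlier altloc letter.  Only `ATOM` records are
read (first model of multi-model files); the parser is strict and
reports the offending line on malformed records.  Because the radii
table and hydrogen treatment of other interface tools are not fixed by
any standard, residue-level results on real structures can shift by one
or two residues relative to other software.

Inclusion filters: both semi-interfaces ≥ 5 residues; each chain covers
≥ 30% of its protein (eliminating peptide-mediated complexes); an
optional per-chain-pair boolean for crystal-artifact screening
(biological-unit orientation agreement) is consumed as input — parsing
`REMARK 350` is deliberately out of scope.  The filters are monotone:
tightening a threshold can only turn keeps into drops.

## Isoform masks

Masks are defined purely genomically.  Residue i of the canonical
protein is *missing* in an isoform iff any base of its codon's genomic
interval is absent from the isoform's coding exons — a partial codon
cannot encode the canonical residue.  Consequences of frame shifts
downstream of an unshared region are *not* modelled at mask level (the
mask records genomic absence, not mutated identity); grossly divergent
isoforms are instead handled by the coverage filter, which restricts
analyses to isoforms retaining at least a given fraction of the
canonical sequence (grid 0–100% in steps of 10).

Genomic intervals are half-open and 0-based internally; GFF3/GTF input
(1-based inclusive) is converted on read, and protein positions are
1-based everywhere in I/O.

Reference-transcript selection prefers a candidate translating to the
identical protein; otherwise the most similar candidate is accepted if
its global alignment shows at most 5 non-contiguous difference runs
(maximal runs of gap or substitution columns).  Alignments use
Needleman–Wunsch with an identity matrix (+1/−1) and affine gaps (−5
first gap residue, −1 each further).  The scoring only ranks
candidates, so its exact values are non-critical; it is configurable in
`masks`.  Ties break to the lexicographically smallest transcript id.
NMD-flagged transcripts and transcripts translating to the reference
protein are excluded from the alternative-isoform set; distinct
transcripts sharing one alternative coding sequence are all retained,
since each represents a realized splice pattern.

## Redundancy reduction

Proteins are grouped by greedy single-linkage clustering: a pair joins
when its global alignment has ≥ 30% identity over aligned columns
covering ≥ 90% of each sequence.  Identity is matches / columns where
both sequences have a residue — the denominator convention is a package
choice, as is the coverage definition.  Each cluster gets a
center-star multiple alignment (center = member with highest summed
pairwise identity; insertions relative to the center receive private
columns).  This is intentionally simple: downstream code consumes only
column identifiers, and user-supplied alignments can override the
built-in one.

Semi-interfaces (heterodimers) or whole interfaces (homodimers) within
a protein cluster are compared by O = |shared columns| / |smaller
unit|; for homodimers the two possible side pairings are both evaluated
and the larger shared count is used, with the denominator the total
size of the smaller interface.  Complete-linkage clustering on 1 − O cut
at 0.5 guarantees within-cluster O ≥ 0.5.  Representatives are elected
by chain coverage (homodimers: product of both coverages), then best
resolution — a missing resolution sorts worse than any number — then
residue count, then a seeded random draw.

## Null models

**Single-isoform decoys.**  The stretch sequence (missing, non-missing,
…, missing) of the real mask is kept in order; every stretch size is
redrawn from Poisson(λ = real size) — zero draws are allowed, letting a
stretch vanish, because rejecting them would bias sizes upward — and the
concatenated variable region is placed uniformly over all in-bounds
starts.  A draw whose variable region is empty or longer than the
protein is rejected and redrawn (up to `max_attempts`, default 1000).
Adjacent stretches that collapse to equal status merge silently.

**All-isoforms controls.**  Isoforms of a protein are partitioned into
overlap groups (connected components under any shared missing
position).  Each group's overlapping variable region is split into
segments at every missing-stretch junction of any member; each segment
carries a per-member missing-status vector.  Segment sizes are pulsed
and each group's region re-placed as a block.  A control is accepted
when (a) pulsed missing-derived segments of *different* groups share no
protein position, and (b) with more than one group, the total pulsed
missing size is ≥ 90% of the real total (condition (a) favours
shrinkage; (b) compensates).  Constraint (a) is applied across groups
only, matching the group-pair phrasing of the model; within a group the
segment structure already preserves overlaps exactly.  On heavily
spliced proteins — total missing spans comparable to the protein
length — the acceptance region can be practically empty; generation then
raises after `max_attempts`, and orchestration skips that protein's
group controls with a logged warning.

Control sets are stored in a compact stretch representation
(`ControlSet`): removal counting over interface positions is vectorized
with interval searches and never materializes per-decoy bit strings,
which is what keeps 1000-decoy analyses and the calibration experiments
fast.  Same seed ⇒ byte-identical serialized controls.

## Stratified tests

The CMH statistic is implemented from the conditional moments
E[a] = (a+b)(a+c)/n and Var[a] = (a+b)(c+d)(a+c)(b+d)/(n²(n−1)); strata
with a zero row or column margin are skipped with a reported count
rather than erroring.  The continuity correction (−0.5 on the absolute
summed deviation) is ON by default, matching the default of R's
`mantelhaen.test`, with a flag to disable; the implementation agrees
with R to 10 decimal places for both settings.  P-values are two-sided
upper tails of χ²(df = 1); the direction of an effect is conveyed by the
reported real/control frequency pair.  Removal thresholds default to
10–100% in steps of 10, and the removal rule is inclusive (fraction ≥
t/100); homodimeric interfaces are removed when either semi-interface
crosses the threshold.

The hot-spot independence test strata are per semi-interface/isoform
pair with rows hot-spot / non-hot-spot residues and columns removed /
retained under the real mask; only semi-interfaces carrying at least
one hot-spot label participate.

Selectivity scores: spliced pairs take the fraction of their
single-isoform decoys removing the interface; never-spliced interfaces
take the fraction of all-isoforms control groups removing them.
Partition cutoff 0.5 with strict inequalities — a score exactly at the
cutoff joins neither class, and a protein joins the removed class on the
strength of any one of its spliced pairs.  Enrichment is upper-tail
hypergeometric per term with BH correction across terms; ontology-graph
propagation is intentionally not performed (a parent-closure can be
applied to the annotation map upstream).

## Synthetic data generator

The generator emulates the input corpus at desk scale: multi-exon genes
(4–10 exons of 20–60 codons, introns 50–500 nt, both strands), whole-
codon exons so skipping never shifts frame; 1–4 alternative isoforms
per gene via independent internal-exon skipping (probability 0.25) and
occasional in-frame 3'-end truncations (probability 0.10, an
alternative-donor-like event); 10% of isoforms flagged NMD; interfaces
of 5–60 residues in one or two runs with 25% clustered hot spots; toy
two-chain structures with one carbon pseudo-atom per residue, intended
contacts at 3.0 Å and every unintended inter-chain pair ≥ 8 Å apart, so
extraction recovers the prescribed interface exactly.

The splicing bias β multiplies the probability of any removal event
(exon skip or donor truncation) whose removed span overlaps the
interface: β = 1 is neutral, β < 1 protective, β > 1 targeting, and
β = 0 guarantees no isoform ever touches the interface.  The bias acts
at event level, not residue level, because real splicing removes
exon-delimited stretches.

What the generator does *not* emulate: realistic protein geometry,
splice-site sequence context, frame-shifting events, expression levels,
or interface–exon correlation (interfaces are placed uniformly,
independent of exon boundaries).  Passing tests therefore demonstrate
the correctness and calibration of the machinery, not biological
conclusions about real proteomes.

## Validation experiments and problem sizes

The self-validation suite (`spliceshield.validation`, run by
`scripts/acceptance.py` and the acceptance tests) uses these study
conditions:

- *CMH oracle*: 10⁴ random stratified tables against an independently
  coded textbook formula (agreement < 10⁻⁹), plus the worked
  single-stratum table (1,0 | 225,775): X² ≈ 3.429 uncorrected
  (p ≈ 0.064), ≈ 0.430 corrected.
- *Calibration*: β = 1, 50 genes, 200 decoys per isoform, 200
  replicates; the α = 0.05 rejection rate must lie in the 99% binomial
  band [0.010, 0.090].
- *Protection recovery*: β = 0.2, 60 independent interface/isoform
  pairs (one per gene), 1000 decoys, 100 seeded runs, thresholds
  10–50%.  The direction (real < control) and significance are
  recovered reliably at thresholds ≤ 30% (≳ 90% of runs); at 40–50%
  removal events are rare under the generator's geometry and power
  drops to ~80%, so the joint all-thresholds success rate is ~75%.
  This is a power limitation of the 60-pair design at high thresholds,
  not a defect of the test: the same machinery is calibrated under
  β = 1 and matches R exactly.
- *Decoy laws*: pulsed sizes preserve the Poisson mean to < 0.5% over
  10⁵ draws; the per-position marginal of 10⁴ single-stretch decoys
  matches the exact enumeration to < 0.01.
- *Structural round-trip*: 100 random toy complexes recovered exactly.
- *Clustering invariant*: 1000 random overlap matrices, no within-
  cluster pair below O = 0.5.
- *Case study*: a synthetic mirror of an N-terminal-removal complex
  (30-residue semi-interface, 19 residues within the spliced-out
  100-residue prefix) is recovered by `cul4a_case_study`; the same
  entry point accepts a real structure and mapping when available.

Problem sizes were chosen so the full suite runs in well under a minute
apiece while keeping Monte-Carlo error far below the asserted
tolerances.

## Known limitations

- The center-star aligner does not merge insertions across non-center
  members; interface residues falling in such insertions never match
  across those members (conservative for redundancy removal).
- The all-isoforms null is undefined (and reported as skipped) for
  proteins whose splicing is too extensive for the disjointness
  constraint.
- mmCIF input, symmetry mates, buried-surface-area computation and
  hot-spot prediction are out of scope; hot spots and biological-unit
  flags are consumed as inputs.
- Exact conditional CMH p-values and homogeneity (Breslow–Day) testing
  are not provided.
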