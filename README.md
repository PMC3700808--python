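# spliceshield

Does alternative splicing avoid cutting into protein–protein binding
sites?  `spliceshield` is a Python library for answering that question
statistically: it extracts interface residues from dimeric structures,
encodes splice isoforms as presence/absence masks over the canonical
protein, builds randomized-splicing null models, and tests whether real
splicing removes interfaces more or less often than chance with a
stratified Cochran–Mantel–Haenszel (CMH) chi-square test.

It is written for structural bioinformaticians studying how splicing
regulates protein interaction networks, and ships a synthetic-data
generator with a tunable splicing bias so every stage — and the
statistical calibration of the whole pipeline — can be validated without
any external downloads.

## The method

**Interfaces.** Two residues on different chains are in contact when any
pair of their atoms lies within r<sub>vdw</sub>(a) + r<sub>vdw</sub>(b) + 0.5 Å.  The
residues one chain contributes form a *semi-interface*, mapped to
canonical (UniProt-style) 1-based numbering through a SIFTS-style table.
Interfaces are kept when both sides contribute ≥ 5 residues and each
chain covers ≥ 30% of its protein.  Redundant observations are collapsed
by complete-linkage clustering on the overlap value
O = |shared alignment columns| / |smaller (semi-)interface|, cutting the
dendrogram at height 0.5 so every retained cluster has pairwise O ≥ 0.5.

**Masks.** Each isoform is a bit string over the canonical protein:
bit 1 where the residue's codon is (even partially) absent from the
isoform's coding exons.  Maximal runs of 1s are *missing stretches*; the
span from the first to the last missing stretch is the *variable region*.

**Null models.** Single-isoform decoys redraw every missing and
non-missing stretch size from a Poisson law with mean equal to the real
size and re-place the variable region uniformly along the protein —
preserving the number, order and expected sizes of spliced-out regions
while randomizing their location.  All-isoforms controls do the same per
*overlap group* (isoforms connected by missing-stretch overlap),
pulsing the shared segment structure so the overlap pattern between
isoforms is preserved.

**Test.** At removal threshold t, an interface is removed by an isoform
missing ≥ t% of its residues (for homodimers: of either semi-interface).
Each (semi-)interface/isoform pair contributes one 2×2 stratum — real
isoform vs its own 1000 decoys, removed vs not — and the CMH statistic

X² = (|Σₖ aₖ − Σₖ E[aₖ]| − ½)² / Σₖ Var[aₖ],  df = 1

pools evidence across strata without ever comparing a decoy to a foreign
isoform.  Selectivity scores (fraction of controls removing an
interface) partition proteins into selectively-removed and
selectively-protected classes, which can be tested for annotation
enrichment (hypergeometric + Benjamini–Hochberg FDR).

## Worked example

`examples/04_stratified_tests.py` simulates 60 genes whose splicing
avoids interface-overlapping exons (bias β = 0.2), builds 1000 pulsed
decoys per isoform and runs the single-isoform test across thresholds:

```
133 semi-interface/isoform pairs

thr   real_freq  control_freq  statistic  p_value
 10       0.153         0.363     28.439  9.67e-08
 30       0.131         0.263     12.723  3.61e-04
 50       0.073         0.178      9.902  1.65e-03
 70       0.040         0.134      7.612  5.80e-03
100       0.046         0.098      1.714  1.90e-01
```

Real splicing removes ≥ 30% of an interface in 13.1% of pairs while
randomized splicing does so in 26.3% — the interfaces are "protected" —
and the stratified test is significant at every partial-removal
threshold, losing significance only for complete excisions, where both
frequencies are small.  The other scripts in `examples/` walk through
interface extraction, mask construction, the decoy models, selectivity
scoring and the full file-based pipeline (`spliceshield run-tests` on a
bundle directory; see `spliceshield --help` for the CLI).

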