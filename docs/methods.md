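# Methods

`bspmeth` analyses bisulfite-sequencing-PCR (BSP) data for a promoter
region: it detects the CpG island, calls per-molecule methylation from
cloned amplicon reads, quantifies group-level methylation, summarises the
accompanying phenotype (eggshell color) and qPCR expression data, and
tests their association. This note records the models, the defaults and
why, the numerical choices, and what the synthetic-data generator does and
does not emulate.

## CpG island detection

An island is an interval satisfying, jointly, length ≥ `min_length`
(default 200 bp), G+C fraction ≥ `min_gc` (0.50), and observed/expected
CpG ratio ≥ `min_obs_exp` (0.60), where

    obs/exp = (#CG × L) / (#C × #G)

over the interval of length L. These are the classical
Gardiner-Garden & Frommer thresholds used by the MethPrimer family of
tools. Detection slides a `window` (100 bp) in steps of `step` (1 bp),
marks qualifying windows, unions overlapping/adjacent qualifying spans,
and re-validates each union against all three criteria; a union that
fails is trimmed base by base (preferring non-G/C terminal bases, left
end on ties) until it re-qualifies or falls below `min_length` and is
dropped. Windows with > 10 % N are skipped; N bases never count as C or
G. Other dialects exist — notably Takai & Jones-style shrinking windows
and all-substrings enumeration — and can return different bounds on the
same sequence; the windowed semantics here is also what the test-suite
brute-force oracle enumerates. Coordinates are 0-based half-open
internally and in BED output, 1-based inclusive in human-facing TSVs.
Only the forward strand is scanned: BSP amplicons are strand-resolved by
primer design.

## In-silico bisulfite conversion and alignment

Bisulfite converts unmethylated C to U (read T) and leaves 5mC as C.
`bisulfite_convert` produces the fully-methylated image (`cpg_protected`:
every C→T except C of CG) and the fully-converted image (`full`: every
C→T). Clone reads are aligned to the cpg-protected reference with a
bisulfite-aware substitution matrix: read T opposite reference C scores
as a match (the conversion image), while read C opposite reference T
stays a mismatch — the asymmetry reflects C→T chemistry on the sequenced
strand only. Scoring: match +1, mismatch −1, affine gaps costing
4 + k for a length-k gap, N scored 0 against anything.

Alignment is end-to-end over the overlap (free end gaps, affine internal
gaps). Amplicons are primer-anchored, but the supplied reference is
usually the whole ~1 kb promoter while the amplicon covers only the
island region; penalising the uncovered flanks would reject every clone,
so end gaps are free and the score floor is
`min_score_frac × min(len(read), len(reference))` (default 0.5), below
which a clone is flagged unalignable. Both orientations are tried and the
better score kept; exact ties prefer forward with a warning. For speed
the dynamic program is restricted to the window spanning the CpG sites
plus 150 bp per side. The aligner is Biopython's `PairwiseAligner`; the
test suite checks it against an independent Gotoh implementation.

## Clone QC and calling

Conversion efficiency is the fraction of non-CpG reference cytosines read
as T (read C there = escaped conversion; gaps and other bases are
uninformative). A clone passes QC iff conversion ≥ 0.95 and identity
≥ 0.90 (QUMA-style conventions; the source study reports only clean
clones). Identity is computed over aligned columns excluding reference-C
columns with read C/T, which carry methylation rather than identity
information. A clone with no informative non-CpG cytosines fails with an
explicit reason. Failing clones are excluded from every statistic and
logged, never silently dropped.

At each CpG cytosine column: read C → methylated, read T → unmethylated,
anything else (gap, A, G, N) → missing. Missing calls are excluded from
both numerator and denominator of every rate; counting them as
unmethylated was rejected because it biases rates downward.

Per-site rate: methylated/(methylated+unmethylated) at that site; a site
with no valid calls is undefined (NaN), never 0. The group-level
**integral methylation rate** is total methylated calls over total
non-missing calls across all clones and sites — equivalently the
valid-call-weighted mean of site rates. Published examples pin the
arithmetic: 94 methylated of 112 valid calls = 83.93 %; 41 of 57 =
71.93 %.

## Phenotype and expression

Each egg's color value is the mean of three colorimeter readings (obtuse,
medium, acute end); smaller = darker. Weekly summaries use the sample SD
(n−1) — the printed weekly CVs are reproduced by SD/mean under this
convention, except weeks 20/35/55 where the published CV differs in the
4th decimal, consistent with rounding of the printed SDs. Eggs flagged
abnormal are excluded before averaging.

Week effects use classical one-way ANOVA (per-egg units, week as factor);
zero total variance reports F = 0, p = 1 with a warning. The letter
display is backed by Tukey HSD at α = 0.05: p-values come from the
studentized range distribution with N−k degrees of freedom (Tukey-Kramer
SE for unequal groups), evaluated in one vectorised call — numerically
identical to `scipy.stats.tukey_hsd` (asserted in tests) but fast enough
for the replicate simulations. Letters are assigned insert-and-absorb:
two groups share a letter iff their comparison is non-significant.
Laying stages are maximal runs of consecutive weeks whose letter sets
have a running non-empty intersection; stage labels rank the stage means.

Relative expression is 2^−ΔΔCt: replicate Cts are averaged per sample,
ΔCt = mean target − mean reference, ΔΔCt subtracts the calibrator group's
mean ΔCt. Amplification-efficiency corrections (Pfaffl) are out of scope.

## Association and key sites

Correlations are Pearson on per-week aggregates (the study's 8- and
9-point series), p from the two-sided t transform with n−2 df; pairs with
a missing member are dropped and counted. Per-site tables default to
unadjusted p-values — the reporting convention of small BSP studies —
with an opt-in Benjamini-Hochberg column. A **key site** is both
significantly negatively correlated with expression at α and covered by a
predicted TF binding site (both bases of the CG inside the hit interval):
methylation there plausibly blocks factor binding.

The published study-level coefficients (−0.889 methylation-expression,
0.807 methylation-color) are not recoverable from printed values: the
methylation-color correlation recomputes to 0.846 from the printed weekly
means, so the published values presumably used unrounded per-bird data.
The package documents this and asserts only its own recomputation.

## TF motif scanning

Motifs are user-editable: IUPAC consensus with a mismatch budget, or a
PWM scored as log-odds against a uniform background with threshold
`threshold_frac` (0.85) of the maximum score. All qualifying windows are
reported; forward strand by default (promoter orientation known), both
strands opt-in. The bundled defaults are class approximations — Sp1
GC-box `GGGGCGGGGC` (≤1 mismatch), Oct-1 octamer `ATGCAAAT` (≤1), C/EBP
palindrome `TTGCGCAA` (≤1) — and make no claim to reproduce any
particular prediction server's hit list (the pairwise-similarity matrix
method of such servers is not published in reimplementable detail).

## Synthetic data generator

The generator emulates the study design: a 1 kb promoter whose 250 bp
GC-rich core (60 % GC) carries exactly 14 evenly spaced CG dinucleotides
(the only CGs in the sequence, so planted positions are exhaustively
enumerable); TF motif instances written over sites 2,3 (C/EBP), 5,6
(Sp1) and 8,9 (Oct-1, one mismatch from consensus since the octamer
contains no CG), mirroring the reported coverage pattern; 15 clones × 3
tissues per week over weeks 25–60; per-site methylation probabilities =
the published pooled site profile rescaled so weekly means track the
published ramp 0.8393→0.9133; 1 % bisulfite conversion failure and 0.2 %
substitution sequencing error (indels opt-in); half the clones emitted
reverse-complemented. Colorimeter tables reproduce the published weekly
means/SDs/sample sizes with 1.0 position noise; Ct tables plant declining
fold-changes (1.00→0.28) with 0.15 Ct noise, 3 replicates, 5 samples per
week. Construction is rejection-sampled (deterministically per seed)
until the core is detected as a single island containing all planted
sites and the default-motif scan covers exactly the planted ordinals.

Per-cell methylation is pure Bernoulli by default; a beta-binomial
per-clone mode (`beta_binomial_kappa`) mimics cell/allele mosaicism but
is off since the source design states no within-week dispersion. Each
artifact draws from its own seeded substream (reference 0, states 1,
color 2, Ct 3, clone noise 4), so bundles are byte-reproducible and each
file regenerable independently. The recorded ground truth (site and motif
positions, probability matrix, every clone's states, color means, folds)
suffices to score every estimator.

Not emulated: chromatogram noise, PCR/cloning bias, clone lineage
structure, haplotype/population structure, and the retroviral-insertion
biology itself. Passing tests therefore demonstrate correctness of the
computational chain under the stated sampling model, not robustness to
every artefact of real Sanger data.

## Validation study designs

Problem sizes were chosen as the smallest that pin down each property:

* **Exact recovery**: an error-free 8-week × 45-clone × 14-site study
  must reproduce every planted call and every weekly integral rate
  exactly.
* **Noisy recovery**: 100 seeded studies at default noise; weekly
  integral estimates within ±0.04 of the recorded clone-state truth in
  ≥95 % of seeds; per-site estimates within 3 binomial SDs of their
  planted probabilities in ≥95 % of (seed, week, site) cells. Recovery is
  scored against the recorded states (estimator error) for weekly rates
  and against the probability matrix (sampling + estimator error) for
  site rates; sites with planted probability 1 have zero binomial SD, so
  a single sequencing-error flip fails that cell — these are the bulk of
  the ~1 % failing cells.
* **Association power**: 200 replicates at the call-matrix level (the
  sequence→call chain is validated separately). Under the default ramp
  the overall methylation-expression correlation is negative and
  significant in ≥95 % of replicates. The key-site study plants a strong
  rising contrast (site probability 0.20→1.00) on sites 5 and 8 only and
  screens all 14 sites with the BH-adjusted column at α = 0.05: with
  unadjusted per-site tests, exact-set recovery is bounded near 0.90 by
  the false-flag rate of the four covered null sites alone (≈ 4 × 2.5 %),
  so the multiplicity-adjusted screen is the design under which exact
  recovery is a fair target. Effect size and screening rule were fixed by
  this power analysis at design time.
* **Oracle equivalence**: island detection against brute-force window
  enumeration on mosaics up to 2 kb; alignment scores against an
  independent Gotoh DP on ~300 bp pairs with substitutions and indels;
  motif scanning against exhaustive window checks at budgets 0–2.

## Known limitations

* Non-CpG methylation contexts (CHG/CHH) are not called; WGBS-scale read
  mapping and paired ends are out of scope.
* The island trim rule is one of several dialects; bounds near ragged
  island edges can differ from other tools by a few bases.
* The letter display assumes homoscedastic groups (Tukey); Duncan or
  pairwise-t alternatives are not implemented.
* qPCR assumes perfect doubling; efficiency-corrected models are not
  implemented.
* Published study-level correlations depending on unavailable raw data
  are documented, not asserted.
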