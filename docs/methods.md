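# Methods

This package implements the computational arms of a deep-mutational-scanning
study of CFTR variant trafficking: sort-seq scoring of per-variant plasma
membrane expression (PME), corrector-response metrics across a calnexin
(CANX) knockout and its parental cell line, AP-MS interactome filtering
statistics, and channel-kinetics extraction. Every stage has a paired
synthetic-data generator so the full chain is testable without downloads.

## Sort-seq PME scoring

**Model.** A pool of recombinant cells, each expressing one barcoded CFTR
variant, is immunostained for surface CFTR and sorted into four quartile
gates. Each gate is sequenced; a variant's read share across gates encodes
its surface-fluorescence distribution. The per-variant estimator is the
read-weighted average of the quartile mean fluorescences

    <I>_v = Σ_k <F>_k N_vk / Σ_k N_vk,   k = 1..4,

where `N_vk` is the variant's read count in quartile k after read filtering
and depth equalisation, and `<F>_k` is the mean linear-scale fluorescence of
cells in quartile k (a required input; its provenance — sort-gate statistics
or post-sort reanalysis — is not constrained). When counts concentrate in
one gate the estimator returns that gate's mean, so every raw score lies in
`[min <F>, max <F>]`.

**Processing chain and parameters.**

- *Read filter*: reads whose expected error over the 10 barcode bases
  (Σ 10^(−Q/10), Phred+33) exceeds 1.0 are dropped — the quantitative
  reading of "likely contains more than one error".
- *Barcode counting*: exact match against the variant whitelist. A
  Hamming-distance rescue is deliberately absent by default; corrupted
  barcodes that collide with another whitelist entry are counted there,
  which is the realistic failure mode of exact matching.
- *Depth equalisation*: each quartile's reads are down-sampled without
  replacement (multivariate hypergeometric) to the minimum quartile total.
  Two independent down-sampling iterations run per replicate, seeded by two
  sub-seeds spawned from the replicate seed.
- *Normalization*: scores are divided by the read-weighted mean of the
  quartile means — the pool-level mean fluorescence a cytometer would
  report for that experiment — making scores dimensionless
  "population-mean units" and removing laser/detector drift between
  experiments.
- *Variation filter*: with iteration scores I₁, I₂, the measurement is
  rejected iff |I₁−I₂| / ((I₁+I₂)/2) > 0.40 (strictly; the boundary value
  0.40 passes). I₁ = I₂ = 0 yields an unscored flag, not an error.
- *Aggregation*: reported PME is the unweighted mean of all passing
  iteration scores over replicates (2 iterations × replicates). Variants
  with no passing measurement are reported missing, never as zero.

**A note on normalization and uniform attenuation.** Because scores are
normalized by the same pool's mean, any *uniform* multiplicative attenuation
of the pool (the synthetic knockout mechanism) cancels exactly in normalized
PME. Uniform knockout effects are therefore demonstrated on raw
weighted-average intensities in the tests and analyses; in real data the
attenuation is non-uniform relative to the staining floor, which is what
makes knockout deltas visible in normalized scores.

## Synthetic sort-seq generator

Single-cell surface fluorescence is log-normal: log10 F ~ Normal(µ_v, s_v),
the usual shape of cytometry intensities. Defaults: a bimodal library
(low-expression mode Normal(2.2, 0.25), WT-like mode Normal(3.0, 0.10) in
log10 arbitrary units, 60% low — most CF variants compromise expression),
per-variant cell SD uniform in [0.15, 0.25]. Sorting gates sit at the pooled
25/50/75 percentiles and are re-drawn each replicate, as independent sorts
would be. Reads are multinomial per fraction, proportional to the fraction's
variant composition; barcodes are corrupted by uniform substitution at the
per-base error rate (no indels). Knockout multiplies linear-scale
intensities by `ko_attenuation` (default 0.26, the generative use of the
library-wide attenuation observed between knockout and parental lines);
corrector treatment multiplies per-variant intensities by configurable fold
effects. Optional FASTQ emission writes Q30 bases, with corrupted positions
at Q10, so the expected-error filter is exercisable.

What the generator does *not* model: cytometer optics, spectral spillover,
doublets, PCR amplification bias, or variant-specific knockout biology.
Passing recovery tests therefore show the estimator chain is faithful to
the stated generative model, not that it is robust to those artefacts.

## Response metrics

- ΔPME = PME(KO) − PME(parental), vehicle-treated; missing propagates.
- Response ratio = PME(drug)/PME(vehicle) within a cell line, undefined
  (with flag) when the vehicle score is below a configurable floor
  (default 0, i.e. raw division; the analyses use 1% of the WT-scale score
  because near-zero denominators make ratios meaningless; how the original
  analyses handled this case is not stated, so the floor is exposed).
- ΔResponse = KO ratio − parental ratio; negative means the corrector works
  less well without calnexin. Antisymmetric under swapping cell lines.
- Domain comparison: Mann-Whitney U between domains, variants assigned by
  the residue parsed from their id. Domains default to standard CFTR
  topology (MSD1 1–394, NBD1 395–646, R 647–845, MSD2 846–1200, NBD2
  1201–1436); all intervals are configurable, NBD2's being the only one
  fixed by convention. The test is exact by full enumeration (midrank ties)
  for pooled n ≤ 20 and a tie-corrected normal approximation with
  continuity correction above that; the named test's variant is otherwise
  unspecified, so both paths are documented and the exact path is checked
  against an independently coded permutation oracle.
- Library trend: ordinary least squares with Pearson R², complete-case with
  logged exclusion counts.

## AP-MS interactome statistics

**Normalization.** Within each TMT run, channel medians are equalised and
bait (CFTR) channels are then rescaled so the bait is equal across the
run's bait channels. Targets are fixed: mock channels scale to median 1;
bait channels scale to the run's geometric-mean bait/median ratio, so a
typical bait channel is scaled exactly like a mock channel. Fixed targets
make the map exactly idempotent and exactly invariant to per-channel
loading factors; the overall unit is arbitrary and cancels in every
downstream statistic (all are log2 ratios or within-run contrasts).

**Mock comparison.** Per protein and run, the fold change is the difference
of mean log2 abundances, bait minus run-matched mock; the consensus is the
mean over runs, and significance is a paired two-tailed t test of the
per-run bait and mock log2 means. Zero-variance differences give an
undefined p, reported as NaN and treated as non-significant. Missing values
are not imputed; proteins need at least two qualifying runs.

**Sigma and the curved filter.** The spread of the background fold-change
distribution is estimated by a nonlinear least-squares Gaussian fit to its
histogram (Freedman–Diaconis binning; initial values: tallest bin, median,
1.4826·MAD). Fitting the peak instead of taking the raw SD keeps heavy
enrichment tails from inflating the estimate (verified: 1% contamination at
+5σ inflates σ̂ by <10%). A protein passes the interactor filter iff its
fold change x exceeds x0 = 2σ̂ and −log10(p) > c/(x − x0), curvature
c = 0.8. The filter is one-sided (enrichment only), monotone in both x and
p, and never passes x ≤ x0 or undefined p. The printed form of this rule
in the source convention reads "y = p-value"; taken literally it would
select the *least* significant proteins, so the standard curved-volcano
axis −log10(p) is the default and a `literal_p=True` mode implements the
inequality as written.

**Pooling and knockout contrasts.** Per-condition pass sets are unioned
into a master interactor list with provenance. For master-list proteins the
knockout-vs-parental change is the difference of mean log2 normalized
abundances over each line's bait channels; per pathway class (translation,
folding, trafficking, proteasome, autophagy, other — an input table, not a
live database query) the deltas are tested against zero with a two-sided
one-sample t and a Wilcoxon signed-rank test, and across conditions with a
repeated-measures one-way ANOVA using the Greenhouse–Geisser epsilon
(pingouin) plus Tukey HSD post hoc comparisons (statsmodels). With two
conditions epsilon is 1 by construction and the correction is vacuous.

**Synthetic interactomes.** Background proteins carry a persistent latent
log2 offset over mock ~ Normal(0, background_sigma) — reproducible
background binding, the reason a fold-change cutoff is needed at all — plus
per-run noise (default SD 0.1); true interactors are offset by the
configured effect sizes; channels receive log-uniform(0.5, 2) loading
factors so normalization is always exercised; the bait protein is present
at high abundance in all bait channels.

## Channel kinetics

The halide-sensor ratio decays after iodide addition as
y(t) = y0 + A1·exp(−k1·t); the printed form of this equation in the source
text is typeset corruptly, but the surrounding description ("exponential
decay function", "rate constant") forces this reading. y0 is fixed during
fitting to the experimentally determined pre-quench plateau. "Global"
fitting shares k1 across the replicates of a condition with one amplitude
each (an independent per-replicate mode exists for comparison; sharing
lowers the variance of k̂1, verified over 200 simulations in testing).
Single-cell scatter is pre-aggregated into 5 s time-bin medians by default
to condition the least-squares problem; raw-point fitting is supported.
k1 ≥ 0 is enforced; rates numerically at the bound (< 1e-10/s) are snapped
to zero with a flag and an undefined half-life. Half-life is ln 2 / k1.
Noiseless fits reproduce generating parameters to 1e-6 relative error for
k1 in [1e-3, 1] /s.

ΔISC extraction: the baseline is the mean over the stability window
immediately before the event; post-event samples are marked stable when the
centred 60 s window has |slope| below 1% of the trace range per minute and
SD below 2% of the range; the longest contiguous stable run of at least
300 s (the five-minute plateau rule) supplies the plateau level, ties
broken by the larger excursion. Transient overshoots shorter than the
duration rule are thereby rejected. The measure is translation-invariant
and signed. Percent-of-WT activation is 100·ΔI_variant/ΔI_WT(forskolin).

## Reproducibility and numerics

All randomness flows from a single config seed through named sub-seeds
(SHA-256 of stage/condition/replicate labels, reduced below 2^31); no stage
touches global RNG state, and an identical config reproduces every output
file bit for bit (checksummed in the run manifest). Tolerances used
throughout: estimator exactness 1e-12 against brute force; normalization
idempotence 1e-12; noiseless fits 1e-6 relative; t_half·k1 = ln 2 at
machine precision.

## Problem sizes in the shipped analyses

The numbered analysis drivers and the acceptance script run at desk scale,
chosen as the smallest sizes at which the statistical behaviour is stable:
60–100 variants at 2×10⁵ cells and 2×10⁵ reads/fraction for scoring
recovery; 232 simulated variant pairs for the attenuation-slope check
(matching the real library's size); 5,000 background proteins for filter
calibration; 2,000 null simulations per statistical test; 5,000 cells for
quench recovery. The library itself has no size limits.

## Known limitations

- The pipeline starts from demultiplexed reads or count tables; no
  alignment, demultiplexing, or spectrum-level search is included.
- Pathway assignment is a static input table.
- The synthetic knockout is uniform across variants, so knockout deltas on
  normalized scores are only informative in real (non-uniform) data; see
  the normalization note above.
- The variation filter's 40% rule is a coefficient-of-variation-style
  criterion on two draws; with deep, equal sequencing both iterations are
  highly correlated and rejections become rare, so the filter mostly
  protects shallow or dropout-prone variants.
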