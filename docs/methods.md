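# Methods

## The measurement model

Two strains are compared: a disomic parent and a derivative monosomic for
one chromosome ("Ch5" by default). Expression is measured on single-dye
chips, one hybridization per RNA batch, three batches per strain; chips are
paired by replicate index. DNA dosage is measured on two-channel tiling
arrays (mutant and parent genomic DNA co-hybridized), three arrays of which
one is a dye swap.

The per-spot expression signal is modeled as

    s = b + L * f * eta,     b ~ N(mu_b, sigma_b) clipped at 0,
                             eta lognormal with mean 1 and CV c,

where `L` is the gene's parent-strain transcript level, `f` the
mutant/parent fold (1 on parent chips), `b` an additive non-specific
background and `eta` multiplicative spot noise. Control probes carry only
`b`; exogenous controls define the background estimate (per-chip median)
and the noise threshold (their SD, ~200 fluorescence units).

Tiling-aCGH probes observe

    log2(R) = gamma * log2(copy_mut / copy_par) + N(0, s_p),

with `gamma` in (0, 1] the dynamic-range compression factor: a single
copy (true ratio 0.5) is observed near `2^-gamma` (0.55 for the default
gamma = 0.85), which is why the SINGLE call band is 0.4–0.65 rather than
centered on 0.5. A lost locus (copy 0) hybridizes at the array background;
the generator stands in a small floor ratio (0.02) for `copy_mut = 0`, so
lost loci land near 0 instead of at `-inf` in log space.

## Statistical procedures

* **Scaling.** The published description of constant-total normalization
  leaves the algebra implicit; it is implemented as per-spot multiplication
  by `C / T_k` with `T_k` the chip total over off-monosome gene spots and
  `C` the mean of the `T_k`, the only reading under which "the total
  combined signals remain constant" holds exactly. Normalizing by *all*
  genes instead shifts every ratio by a common factor of roughly
  `1 + (1 - mean monosome fold) * monosome signal share` (~2% in the
  default world) — the "very similar" variant is available via
  `exclude_chromosome=None`.
* **Replication unit.** Spots within a chip are averaged before the paired
  t-test, so degrees of freedom come from chip pairs (n = 3), not spots:
  chips, not spots, are independent. Duplicate spotting of monosome genes
  therefore improves ratio precision but not test df.
* **Negative signals.** Background subtraction can push a dim spot
  negative; such scaled signals are replaced by 1 before ratios and logs.
  Note the consequence: a gene whose parent spot goes negative contributes
  a ratio of `mutant/1`, which can be enormous. The above-noise filter
  (mean corrected signal ≥ 200 in *both* strains) removes most such genes,
  but the mean ratio of a chromosome is not robust to the survivors —
  one reason the chromosome table reports the median alongside.
* **Chromosome p-value.** The wording "for all genes along each
  chromosome" is ambiguous between gene-level and spot-level pooling; both
  are implemented (`mode="genes"` default, `mode="spots"` variant) and
  agree on direction in every world we generate.
* **Class banding.** The published class bands live on a 0.1 grid with
  gaps (0.6→0.7, 0.8→0.9, 1.1→1.2), so they only partition the positive
  reals after rounding; ratios are rounded half-away-from-zero to one
  decimal before banding. Two bands are added beyond the published four:
  `BELOW_RANGE` (< 0.2, lost loci) and `EXCESS` (> 2.1, the four-fold
  up-regulated tail), reported separately and never silently merged.
* **Copy-call cutoffs.** The source bands are verbal ("approximately 1.0",
  "around 0.7", "0.5–0.6"); the numeric cutoffs (0.1 / 0.4 / 0.65 / 0.75 /
  0.9) are this package's documented defaults, all configurable.
* **Clustering test.** The visual claim that extreme genes scatter without
  clustering is quantified by a permutation test: statistic = mean
  nearest-neighbor distance among extreme (red/blue) genes, null =
  shuffling the extreme labels over the observed gene positions, p-value
  with the add-one estimator (never exactly 0).
* **Multiple testing.** The source analysis uses raw p-value cutoffs; no
  FDR correction is applied to any headline number. A Benjamini–Hochberg
  column (`q_value_bh`) is emitted for modern use and is clearly additional.

## The synthetic world

Defaults encode the stated design: 8 chromosomes with gene counts 1346,
966, 987, 745, 661, 507, 431, 406; Ch5 monosomic and its ORFs spotted
twice per chip; 3 chips per strain; 544 control probes (395 exogenous);
background SD 200; 50-mer tiling probes at 35 bp per-strand spacing;
3 aCGH arrays with the third dye-swapped; gamma = 0.85, probe noise 0.1
log2 units. The compensation mixture is 15/40/39/5/1% for
down2x/partial/compensated/up/excess (the published 15/40/40/6 sums to
101%; the "up" band is split to keep a true distribution), with per-class
fold ranges 0.35–0.60, 0.65–0.85, 0.90–1.10, 1.15–2.10, 2.2–4.2 drawn
uniformly. Three monosome genes retain a second copy (planted
duplications) and five have copy 0 (a lost-locus cluster analogue).

Free parameters the design does not pin down were chosen once:
transcript levels are lognormal with log-mean 8.6 and log-SD 0.6 (median
~5400 FU — a bright chip; essentially no gene sits near the 200-FU noise
floor, so the below-noise filter and the negative→1 rule are exercised by
tests that plant dim genes explicitly) and the default spot CV is 0.1
(mid-range for replicate in-situ arrays). One master seed feeds
fixed-labeled substreams per stage (genome / expression / cgh / rtpcr), so
toggling one stage never perturbs another and reruns are byte-identical.

What the generator does **not** emulate: spatial artifacts and print-tip
effects (vendor software is assumed to have corrected them), dye bias on
expression chips (single-dye design), probe thermodynamics and
cross-hybridization, GC-dependent signal (GC is planted independent of
signal, which is what makes the ANOVA calibration check meaningful), and
correlated biological variation between batches. A green recovery test
therefore establishes that the pipeline inverts its own stated measurement
model — not that it is robust to artifacts outside that model.

## Known statistical limitations

Averaging mutant/parent ratios is upward-biased by `~e^{2 sigma^2}` (about
+2% at CV 0.15) plus a Jensen term from additive background on the
denominator; the log-scale tests are unbiased, but chromosome *mean
ratios* inherit the bias, which puts the monosome mean near the top of the
0.82–0.90 band expected from the planted mixture. More consequentially,
the planted fold ranges coincide exactly with the decision bands, so with
spot CV 0.15 the per-gene ratio SE (~9%) leaks a predictable 10–15% of
genes across each class boundary. Class-proportion recovery is therefore
biased (PARTIAL reads ~0.31 against 0.40 planted) and end-to-end verdict
recovery plateaus near 0.86–0.88; recovering ≥ 95% of verdicts would
require spot CVs below ~3%, cleaner than any replicate array data. These
are properties of the measurement model, not of the implementation: at
zero noise every class, call and verdict is recovered exactly, and the
copy-number calls are exact at the default aCGH noise.

## Numerical choices

Zero-variance paired differences: p = 1 when the mean difference is also
zero, else floored at machine epsilon. Ratio histograms use left-closed
right-open bins anchored at 0. "Inside the ORF" means full probe
containment, not overlap. aCGH array averaging is arithmetic in ratio
space (log-space geometric averaging is available but non-default).
Coordinates are 0-based half-open in memory; GFF3 output is 1-based
inclusive. Strand is simulated for tiling probes but ignored in all ratio
computations.
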