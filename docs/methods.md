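# Methods

## Behavioral phenotyping

The IAP score is the per-trial mean of ordinal weights assigned to the four
thought-probe responses (+2 only pain, +1 mostly pain, −1 mostly something
else, −2 only something else), algebraically identical to
`(2·n_onlypain + n_mostlypain − 2·n_onlyelse − n_mostlyelse) / n_total` and
therefore bounded in [−2, +2]. Because the low/high grouping is defined by
the sign of the score, a score of exactly 0 belongs to neither group; we
label it `boundary`, log a warning, and exclude such subjects from
two-group contrasts (they remain in correlation analyses, which use the
continuous score). The same policy applies to ΔRT_mean = 0 in the A/P
phenotype. The alternative — silently assigning boundary subjects to one
group — would bias that group; exclusion is the conservative choice.

NI-trial filtering keeps blocks 3–6 (the first no-pain/pain block pair is
treated as practice) and reaction times in the closed interval
[200, 2500] ms: the bounds describe exclusion of trials *below* 200 ms or
*exceeding* 2500 ms, so boundary trials are retained. Missing trials are
tolerated; condition means are computed over whatever survives, and a
condition left empty raises an error naming the condition rather than
producing a silent NaN. Response accuracy is carried through the records
but plays no role in classification, which is defined on RT alone.

## Spectral pipeline

Each ROI series is z-scored (sample SD, ddof = 1) before spectral
estimation, so every subject contributes a unit-variance signal and the
band metrics measure *relative* spectral composition rather than raw
source amplitude — all downstream metrics are invariant to affine
rescaling of the input, which the tests assert.

The Welch estimate uses a 1000-sample Hamming window with 50 % overlap.
At fs = 1000 Hz such a window natively resolves 1 Hz; the 0.1 Hz analysis
grid is obtained by zero-padding each segment to an FFT length of 10000.
Zero-padding interpolates the spectrum — it adds no resolution, but it
lets the PAF argmax land on a 0.1 Hz grid. Segments are mean-detrended
only (the input is already z-scored and assumed band-pass filtered
upstream, 1–150 Hz); scaling is one-sided density, so the left-point AUC
over the whole grid approximates the (unit) variance — a Parseval check in
the tests, satisfied to well within 10 %.

Band definitions: theta [4, 8) Hz and alpha [8, 13) Hz for AUCs — half-open
at the shared 8 Hz edge so that AUC(4,8) + AUC(8,13) = AUC(4,13) exactly and
no bin is double-counted. The PAF search is inclusive, [8, 13]. Ties break
to the lowest frequency, and an argmax at the first or last in-band grid
point sets `paf_at_band_edge`: a monotone 1/f shoulder maximizes power at
the band edge without any genuine alpha peak, so edge estimates deserve
suspicion, but they are flagged and retained rather than dropped. Series
containing non-finite samples are rejected outright; artifact handling
belongs upstream of this package.

## Statistics

* **Mann–Whitney U**: the pair-count statistic (ties credited ½). The p
  value is exact by enumeration when the pooled sample is tie-free and
  n1·n2 ≤ 400, otherwise the tie-corrected normal approximation with
  continuity correction. Group sizes in the intended application (8–35 per
  group) straddle the exactness limit, hence the hybrid rule. Tests verify
  the statistic against brute-force pair counting and the identity
  U(x,y) + U(y,x) = n1·n2.
* **BH-FDR**: the standard step-up adjustment. The family is always the
  set of ROIs for *one* metric and *one* contrast (16 tests for the
  built-in atlas); families are never merged across metrics, which would
  change every adjusted value.
* **Cohen's d**: pooled-SD variant (denominator df = n1 + n2 − 2),
  reported as a magnitude, since the contrast direction is carried by the
  group means themselves.
* **Spearman**: Pearson correlation of mid-ranks with the two-sided
  t approximation.
* **Pooled t**: Student's equal-variance two-sample t in summary-statistic
  form (means, SDs, ns), so published group summaries can be checked
  directly. The pooled rather than Welch variant is used throughout for
  consistency with the worked examples the tests pin down.
* Two-sided tests everywhere.

Under the global null with independent ROIs, the BH step-up procedure's
family-wise false-discovery probability is ≤ 0.05; a 1000-replicate
simulation in the acceptance suite checks the implemented battery stays
≤ 0.06 including Monte-Carlo error.

## Synthetic cohort generator

The generator produces the minimal structure the pipeline measures — no
sensor-level physics, head models, artifacts, or beamforming.

**ROI series.** A target one-sided PSD is built on the rFFT grid:
`1/f^χ` aperiodic background (zeroed below 1 Hz, standing in for the
upstream high-pass), a Gaussian alpha bump centered at the subject's true
alpha center (`alpha_bump_width` is its SD in Hz), a flat theta elevation
on [4, 8), and a white floor of height `noise_sd²`. The amplitude spectrum
`sqrt(PSD)` gets iid uniform phases and is inverted with an inverse rFFT.
The synthesized signal's Welch PSD is then proportional to the target by
construction, which is what makes ground-truth recovery tests meaningful.
Defaults: χ = 1, alpha centers (10.0, 10.3) Hz for (low, high) groups with
0.4 Hz subject SD clipped to [8.5, 12.5], bump power 0.5 (SNR ≈ 5 against
the 1/f background at 10 Hz), theta means (0.25, 0.20), noise_sd 0.05,
5 min at 1000 Hz, 26/24 subjects per group.

**Effect-size calibration.** Subject-level true theta power is drawn
N(μ_group, σ) with σ = |μ_low − μ_high| / `theta_effect_d` (default d =
0.93, the large-effect regime the pipeline should detect in default-mode
nodes), truncated at 0. Two things attenuate the *measured* d slightly
below the configured one: z-normalization couples the theta AUC to total
power (a nonlinearity of a few percent at the default theta share), and
Welch estimation noise adds within-subject variance. At 300 s series the
estimation noise is negligible; the recovery test uses 30 s series with a
wider group separation (θ = 0.35 vs 0.20 at the same d) so that
subject-level variance still dominates, and averages the d estimate over
four ROIs because the d estimator itself has sampling SD ≈ 0.1 at 200
subjects per group. Measured recovery lands within ±0.15 of the
configured value.

**Behavioral links.** Experience-sampling responses use a
Binomial(3, latent_p) ordinal link: the count k ∈ {0..3} maps to the four
ordered categories. This is the simplest monotone link that hits both
anchors exactly (latent_p = 1 ⇒ always "only pain" ⇒ IAP +2; latent_p = 0 ⇒
IAP −2) and is symmetric at latent_p = 0.5 (mean score 0). The four
responses are treated as a single ordinal scale; sub-types of
"something else" (external distraction vs mind-wandering) are not modelled.
Latent propensities are uniform per group, (0.05, 0.45) for low-IAP and
(0.55, 0.95) for high. NI reaction times are shifted lognormal (onset
shift 150 ms, shape σ = 0.12 around a 1300 ms base) — a standard
right-skewed RT model; the pipeline itself never depends on this choice,
and σ = 0 degenerates to deterministic RTs, which the worked-example tests
use. Pain blocks shift the condition mean by the subject's true pain
shift, drawn N(−75, 50) ms for A types and N(+48, 33) ms for P types, with
A-type probability 35/47; A/P membership is drawn independently of IAP
group. An `outlier_rate` replaces trials with out-of-range RTs to exercise
the filters.

**Reproducibility.** Every subject × ROI series and each subject's
behavioral stream has its own `numpy` substream keyed by
(master seed, subject index, stream id), so any slice of a cohort can be
regenerated bit-identically without generating the rest — the end-to-end
determinism test compares output files byte for byte.

## Test problem sizes

Spectral property tests run on shortened series — 30–60 s instead of the
nominal 300 s — and the end-to-end smoke test uses 12 subjects per group;
these sizes keep the suite fast while leaving the assertions comfortably
inside their tolerances (the attenuation analysis above sets the margins).
The null-FDR calibration (1000 replicates) draws per-subject metric values
directly at the ground-truth level rather than synthesizing time series,
since it calibrates the statistical battery, not the spectral estimator.

## What the simulations do and do not show

Passing recovery tests show the pipeline correctly extracts the spectral
and behavioral structure *of the generative model*: stationary 1/f-plus-
oscillation signals with a single Gaussian alpha bump and flat theta
elevation, independent across ROIs. Real source-space MEG differs in ways
the generator deliberately omits: nonstationarity, inter-ROI correlation
and signal leakage, non-Gaussian artifacts, multi-peak alpha, and an
aperiodic slope that varies by region and subject. In particular the
band-AUC metrics conflate oscillatory power with the aperiodic background;
separating the two (spectral parameterization) is out of scope here, and
group differences in band AUC on real data can reflect either component.

## Known limitations

* PAF is the grid argmax only; no center-of-gravity or interpolated peak.
* No sex-stratified analyses are packaged, though the same operations
  apply to any grouping column.
* Exact Mann–Whitney enumeration is disabled in the presence of ties;
  heavily tied data fall back to the asymptotic approximation regardless
  of sample size.
* The FDR family is fixed to ROIs-within-(metric, contrast); other
  correction scopes require calling `bh_fdr` directly.
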