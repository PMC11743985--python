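"""Synthetic cohort generator with known ground truth.

Emulates the three data kinds the analysis consumes:

* **ROI resting-state series** — synthesized in the frequency domain: a
  target one-sided power spectrum (1/f^chi aperiodic background + Gaussian
  alpha bump at the subject's true alpha center + flat theta elevation in
  4-8 Hz + white noise floor) is given uniformly random phases and inverted
  to the time domain. The Welch pipeline downstream then sees exactly the
  spectral structure configured here.
* **Experience-sampling responses** — each trial draws one of the four
  ordered thought-probe categories through a Binomial(3, latent_p) ordinal
  link, where latent_p is the subject's probability of attending to pain.
  latent_p = 1 always yields "only pain" (IAP score +2), latent_p = 0 always
  "only something else" (score -2), and latent_p = 0.5 is symmetric.
* **NI-task reaction times** — shifted-lognormal RTs over six alternating
  blocks starting with no-pain; pain blocks shift the mean by the subject's
  true pain shift. An optional outlier rate injects out-of-range RTs
  (< 200 ms or > 2500 ms) to exercise the trial filters.

Group structure: two groups (low/high IAP) differ in true theta power and
alpha center. Subject-level true theta power is drawn around the group mean
with SD chosen so the ground-truth Cohen's d between groups equals the
configured ``theta_effect_d``. A/P membership is drawn independently of IAP
group, with pain shifts centred on the A-type and P-type means.

Reproducibility: every subject x ROI series (and each subject's behavioral
stream) has its own RNG substream derived from (master seed, subject index,
stream id), so any part of a cohort can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from painattn.atlas import ROI_NAMES
from painattn.behavior import (
    ExperienceSamplingRecord,
    NITrialRecord,
    block_condition,
)
from painattn.spectral import ROITimeSeries


class InvalidConfigError(ValueError):
    """Raised for out-of-range generator parameters."""


@dataclass(frozen=True)
class CohortConfig:
    """Generative knobs for a two-group synthetic cohort.

    ``n_subjects_per_group`` may be a single count or a (low, high) pair;
    the default 26/24 split mirrors a 50-participant cohort split at an IAP
    score of 0. ``theta_power_by_group`` and ``alpha_center_by_group`` are
    (low-IAP, high-IAP) pairs; the defaults encode the direction of the
    group effects the pipeline is meant to detect (greater theta power and
    slightly slower alpha in the low-IAP group, ground-truth theta d 0.93).
    """

    n_subjects_per_group: int | tuple[int, int] = (26, 24)
    seed: int = 0
    duration_s: float = 300.0
    fs: float = 1000.0
    aperiodic_exponent: float = 1.0
    alpha_center_by_group: tuple[float, float] = (10.0, 10.3)
    alpha_bump_power_by_group: tuple[float, float] = (0.5, 0.5)
    alpha_bump_width: float = 1.0
    alpha_center_sd: float = 0.4
    theta_power_by_group: tuple[float, float] = (0.25, 0.20)
    theta_effect_d: float = 0.93
    noise_sd: float = 0.05
    roi_list: tuple[str, ...] = ROI_NAMES
    #: fraction of subjects that are A type (faster under pain)
    p_a_type: float = 35 / 47
    rt_base_ms: float = 1300.0
    rt_sigma: float = 0.12
    #: pain-shift (mean, SD) in ms for A- and P-type subjects
    rt_shift_a: tuple[float, float] = (-75.0, 50.0)
    rt_shift_p: tuple[float, float] = (48.0, 33.0)
    #: uniform range of the latent attend-to-pain probability per group
    latent_p_range_by_group: tuple[tuple[float, float], tuple[float, float]] = (
        (0.05, 0.45),
        (0.55, 0.95),
    )
    n_es_trials: int = 20
    n_ni_blocks: int = 6
    ni_trials_per_block: int = 24
    outlier_rate: float = 0.0

    def __post_init__(self) -> None:
        n = self.group_sizes
        if min(n) < 2:
            raise InvalidConfigError("need at least 2 subjects per group")
        if self.fs <= 0 or self.duration_s <= 0:
            raise InvalidConfigError("fs and duration_s must be positive")
        if not all(8 <= c <= 13 for c in self.alpha_center_by_group):
            raise InvalidConfigError("alpha centers must lie within [8, 13] Hz")
        if self.theta_effect_d < 0:
            raise InvalidConfigError("theta_effect_d must be >= 0")
        if self.alpha_bump_width <= 0:
            raise InvalidConfigError("alpha_bump_width must be positive")
        if not 0 <= self.outlier_rate <= 1:
            raise InvalidConfigError("outlier_rate must be in [0, 1]")
        for lo, hi in self.latent_p_range_by_group:
            if not (0 <= lo <= hi <= 1):
                raise InvalidConfigError(
                    "latent_p ranges must satisfy 0 <= lo <= hi <= 1"
                )

    @property
    def group_sizes(self) -> tuple[int, int]:
        n = self.n_subjects_per_group
        return (n, n) if isinstance(n, int) else (int(n[0]), int(n[1]))

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))

    @property
    def theta_power_sd(self) -> float:
        """Subject-level SD of true theta power, set by the target effect size."""
        gap = abs(self.theta_power_by_group[0] - self.theta_power_by_group[1])
        if self.theta_effect_d > 0 and gap > 0:
            return gap / self.theta_effect_d
        return 0.1 * max(np.mean(self.theta_power_by_group), 1e-12)


#: substream ids so subject-level streams never collide
_STREAM_BEHAVIOR = 10_001
_STREAM_TRUTH = 10_002


def _subject_rng(seed: int, subject_idx: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, subject_idx, stream])


def _roi_rng(seed: int, subject_idx: int, roi_idx: int) -> np.random.Generator:
    return np.random.default_rng([seed, subject_idx, roi_idx])


def target_psd(
    freqs: np.ndarray,
    aperiodic_exponent: float,
    alpha_center: float,
    alpha_bump_power: float,
    alpha_bump_width: float,
    theta_power: float,
    noise_sd: float,
) -> np.ndarray:
    """Target one-sided PSD shape on a frequency grid (arbitrary units).

    Aperiodic 1/f^chi background above 1 Hz (inputs are modelled as already
    high-pass filtered, so power below 1 Hz is zeroed), a Gaussian alpha
    bump (``alpha_bump_width`` is its SD in Hz), a flat theta elevation on
    [4, 8), and a white floor of height noise_sd^2.
    """
    freqs = np.asarray(freqs, dtype=float)
    psd = np.full_like(freqs, noise_sd**2)
    above = freqs >= 1.0
    with np.errstate(divide="ignore"):
        psd[above] += freqs[above] ** (-aperiodic_exponent)
    psd += alpha_bump_power * np.exp(
        -0.5 * ((freqs - alpha_center) / alpha_bump_width) ** 2
    )
    psd[(freqs >= 4.0) & (freqs < 8.0)] += theta_power
    psd[freqs == 0] = 0.0
    return psd


def synthesize_series(
    psd: np.ndarray, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """Random-phase inverse-FFT synthesis of a series with the given PSD shape.

    The amplitude spectrum is sqrt(psd); phases are iid uniform on [0, 2pi).
    The absolute scale is arbitrary (the analysis z-normalizes), but relative
    band powers match the target.
    """
    psd = np.asarray(psd, dtype=float)
    amp = np.sqrt(psd)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=psd.size)
    spectrum = amp * np.exp(1j * phases)
    spectrum[0] = 0.0
    if n_samples % 2 == 0:
        spectrum[-1] = amp[-1]  # Nyquist bin must be real
    return np.fft.irfft(spectrum, n=n_samples)


@dataclass(frozen=True)
class GroundTruth:
    """Per-subject generative parameters, for parameter-recovery tests."""

    subject_id: str
    subject_idx: int
    group: str  # low | high
    ap_type: str  # A | P
    latent_p: float
    rt_shift_ms: float
    alpha_center_by_roi: dict[str, float] = field(default_factory=dict)
    theta_power_by_roi: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.latent_p <= 1:
            raise InvalidConfigError("latent_p must be in [0, 1]")
        if not np.isfinite(self.rt_shift_ms):
            raise InvalidConfigError("rt_shift_ms must be finite")


def simulate_roi_timeseries(
    config: CohortConfig,
    truth: GroundTruth,
    roi: str,
    rng: np.random.Generator | None = None,
) -> ROITimeSeries:
    """One subject x ROI series with the subject's true spectral parameters."""
    n = config.n_samples
    if n < 2:
        raise InvalidConfigError("duration_s x fs must give at least 2 samples")
    if rng is None:
        rng = _roi_rng(config.seed, truth.subject_idx, config.roi_list.index(roi))
    freqs = np.fft.rfftfreq(n, d=1.0 / config.fs)
    psd = target_psd(
        freqs,
        config.aperiodic_exponent,
        truth.alpha_center_by_roi[roi],
        config.alpha_bump_power_by_group[0 if truth.group == "low" else 1],
        config.alpha_bump_width,
        truth.theta_power_by_roi[roi],
        config.noise_sd,
    )
    samples = synthesize_series(psd, n, rng)
    return ROITimeSeries(truth.subject_id, roi, config.fs, samples)


def simulate_experience_sampling(
    latent_p: float,
    n_trials: int = 20,
    rng: np.random.Generator | int | None = None,
    subject_id: str = "sim",
) -> list[ExperienceSamplingRecord]:
    """Thought-probe responses through the Binomial(3, latent_p) ordinal link.

    The binomial count k in {0..3} maps to only_else, mostly_else,
    mostly_pain, only_pain, so the category distribution is stochastically
    increasing in latent_p and the endpoints are deterministic.
    """
    if not 0 <= latent_p <= 1:
        raise InvalidConfigError(f"latent_p {latent_p} outside [0, 1]")
    if n_trials < 1:
        raise InvalidConfigError("n_trials must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    ordered = ("only_else", "mostly_else", "mostly_pain", "only_pain")
    ks = rng.binomial(3, latent_p, size=n_trials)
    return [
        ExperienceSamplingRecord(subject_id, trial + 1, ordered[k])
        for trial, k in enumerate(ks)
    ]


def simulate_ni_trials(
    base_rt_ms: float,
    pain_shift_ms: float,
    n_blocks: int = 6,
    trials_per_block: int = 24,
    outlier_rate: float = 0.0,
    rt_sigma: float = 0.12,
    rng: np.random.Generator | int | None = None,
    subject_id: str = "sim",
) -> list[NITrialRecord]:
    """Shifted-lognormal NI reaction times over alternating blocks.

    ``rt_sigma`` is the lognormal shape parameter; 0 gives deterministic RTs
    at the condition mean. With probability ``outlier_rate`` a trial's RT is
    replaced by an out-of-range value (below 200 or above 2500 ms) so that
    downstream filters have something to remove.
    """
    if trials_per_block <= 0:
        raise InvalidConfigError("trials_per_block must be positive")
    if n_blocks < 2 or n_blocks % 2 != 0:
        raise InvalidConfigError("n_blocks must be even and >= 2")
    if not 0 <= outlier_rate <= 1:
        raise InvalidConfigError("outlier_rate must be in [0, 1]")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    shift = 150.0  # lognormal onset shift, ms
    records = []
    for block in range(1, n_blocks + 1):
        condition = block_condition(block)
        mean_rt = base_rt_ms + (pain_shift_ms if condition == "pain" else 0.0)
        # lognormal with mean (mean_rt - shift): mu = log(mean) - sigma^2/2
        body = mean_rt - shift
        if body <= 0:
            raise InvalidConfigError("base_rt_ms too small for the RT model")
        if rt_sigma > 0:
            mu = np.log(body) - rt_sigma**2 / 2
            rts = shift + rng.lognormal(mu, rt_sigma, size=trials_per_block)
        else:
            rts = np.full(trials_per_block, mean_rt)
        if outlier_rate > 0:
            is_outlier = rng.random(trials_per_block) < outlier_rate
            low = rng.uniform(50.0, 199.0, size=trials_per_block)
            high = rng.uniform(2501.0, 4000.0, size=trials_per_block)
            pick_low = rng.random(trials_per_block) < 0.5
            rts = np.where(is_outlier, np.where(pick_low, low, high), rts)
        records.extend(
            NITrialRecord(subject_id, block, condition, float(rt))
            for rt in rts
        )
    return records


def simulate_ground_truth(config: CohortConfig) -> list[GroundTruth]:
    """Draw per-subject latent parameters for both groups."""
    n_low, n_high = config.group_sizes
    truths = []
    for idx in range(n_low + n_high):
        group_i = 0 if idx < n_low else 1
        group = "low" if group_i == 0 else "high"
        rng = _subject_rng(config.seed, idx, _STREAM_TRUTH)
        latent_p = rng.uniform(*config.latent_p_range_by_group[group_i])
        ap_type = "A" if rng.random() < config.p_a_type else "P"
        shift_mean, shift_sd = (
            config.rt_shift_a if ap_type == "A" else config.rt_shift_p
        )
        rt_shift = rng.normal(shift_mean, shift_sd)
        centers = {}
        thetas = {}
        for roi in config.roi_list:
            centers[roi] = float(
                np.clip(
                    rng.normal(
                        config.alpha_center_by_group[group_i],
                        config.alpha_center_sd,
                    ),
                    8.5,
                    12.5,
                )
            )
            thetas[roi] = float(
                max(
                    rng.normal(
                        config.theta_power_by_group[group_i],
                        config.theta_power_sd,
                    ),
                    0.0,
                )
            )
        truths.append(
            GroundTruth(
                subject_id=f"sub-{idx + 1:03d}",
                subject_idx=idx,
                group=group,
                ap_type=ap_type,
                latent_p=float(latent_p),
                rt_shift_ms=float(rt_shift),
                alpha_center_by_roi=centers,
                theta_power_by_roi=thetas,
            )
        )
    return truths


@dataclass
class Cohort:
    """A fully simulated cohort: ground truth plus the three data tables."""

    config: CohortConfig
    truths: list[GroundTruth]
    es_table: pd.DataFrame  # subject_id, trial, response
    ni_table: pd.DataFrame  # subject_id, block, condition, rt_ms

    def roi_series(self, subject_id: str, roi: str) -> ROITimeSeries:
        """(Re)generate one subject x ROI series from its own substream."""
        truth = next(t for t in self.truths if t.subject_id == subject_id)
        return simulate_roi_timeseries(self.config, truth, roi)

    def iter_subject_series(self, subject_id: str):
        for roi in self.config.roi_list:
            yield self.roi_series(subject_id, roi)

    @property
    def truth_table(self) -> pd.DataFrame:
        rows = []
        for t in self.truths:
            row = {
                "subject_id": t.subject_id,
                "group": t.group,
                "ap_type": t.ap_type,
                "latent_p": t.latent_p,
                "rt_shift_ms": t.rt_shift_ms,
            }
            for roi in self.config.roi_list:
                row[f"alpha_center.{roi}"] = t.alpha_center_by_roi[roi]
                row[f"theta_power.{roi}"] = t.theta_power_by_roi[roi]
            rows.append(row)
        return pd.DataFrame(rows)


def simulate_cohort(config: CohortConfig) -> Cohort:
    """Simulate behavioral tables and ground truth for a two-group cohort.

    ROI time series are not materialized here (a full cohort at study scale
    is gigabytes); regenerate them on demand via :meth:`Cohort.roi_series`,
    which is deterministic given the config seed.
    """
    truths = simulate_ground_truth(config)
    es_rows = []
    ni_rows = []
    for t in truths:
        rng = _subject_rng(config.seed, t.subject_idx, _STREAM_BEHAVIOR)
        for rec in simulate_experience_sampling(
            t.latent_p, config.n_es_trials, rng, subject_id=t.subject_id
        ):
            es_rows.append(
                {
                    "subject_id": rec.subject_id,
                    "trial": rec.trial_index,
                    "response": rec.response,
                }
            )
        for rec in simulate_ni_trials(
            config.rt_base_ms,
            t.rt_shift_ms,
            config.n_ni_blocks,
            config.ni_trials_per_block,
            config.outlier_rate,
            config.rt_sigma,
            rng,
            subject_id=t.subject_id,
        ):
            ni_rows.append(
                {
                    "subject_id": rec.subject_id,
                    "block": rec.block_index,
                    "condition": rec.condition,
                    "rt_ms": rec.rt_ms,
                }
            )
    return Cohort(
        config=config,
        truths=truths,
        es_table=pd.DataFrame(es_rows),
        ni_table=pd.DataFrame(ni_rows),
    )
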