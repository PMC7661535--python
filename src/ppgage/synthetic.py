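"""Synthetic fingertip-PPG cohort generator with known ground truth.

Each subject gets a two-lobe pulse template whose morphology is driven by a
scalar stiffness parameter, a beat-to-beat interval sequence whose
irregularity is driven by a randomness parameter, respiratory amplitude
modulation, slow baseline drift, additive sensor noise, and jittered ~30 Hz
timestamps over ~90 s — i.e. everything the preprocessing and feature
extraction stages must cope with, but with the truth recorded.

Planted age effects: stiffness increases with age (shrinking the SDPPG
a-wave) and RR randomness increases with age (raising tpr); slopes are set
in :class:`EffectConfig` and can be zeroed for null simulations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SignalError
from .io_h4h import CovariateRecord, RawRecording

__all__ = [
    "SubjectTruth",
    "EffectConfig",
    "NULL_EFFECTS",
    "STRONG_EFFECTS",
    "SEX_TREND_EFFECTS",
    "beat_template",
    "template_peak_phase",
    "generate_recording",
    "generate_truth",
    "generate_cohort",
]


@dataclass
class SubjectTruth:
    """Ground truth for one simulated subject."""

    subject_id: str
    beat_times: np.ndarray  # systolic peak times, seconds
    rr_ms: np.ndarray  # true inter-beat intervals, ms
    stiffness: float  # in [0, 1]; larger -> blunter pulse, smaller a-wave
    rr_randomness: float  # white share of RR variation; larger -> higher tpr
    age: float
    meta: CovariateRecord
    noise_amplitude: float = 0.0
    modulation_depth: float = 0.0
    drift_amplitude: float = 0.0
    dicrotic_amp: float = 0.45  # dicrotic lobe strength (age-independent)
    dicrotic_delay: float = 0.39  # dicrotic lobe phase (age-independent)
    dicrotic_width: float = 0.145  # dicrotic lobe width (age-independent)
    rr_scale: float = 1.0  # overall RR variability scale (age-independent)
    seed: int = 0


@dataclass(frozen=True)
class EffectConfig:
    """Slopes and nuisance levels for cohort generation.

    ``stiffness_slope`` / ``randomness_slope`` scale the linear age links
    (age mapped to [0, 1] over 18–79 before scaling); ``female_age_offset``
    shifts the female age *distribution* (negative = females sampled
    younger), the planted signature recovered by the sex-stratified trend;
    ``smoking_age_link`` raises smoking probability with age.
    """

    stiffness_slope: float = 1.0
    randomness_slope: float = 1.0
    stiffness_noise: float = 0.06
    randomness_noise: float = 0.06
    female_age_offset: float = 0.0
    smoking_age_link: float = 0.0
    noise_amplitude: float = 0.01
    modulation_depth: float = 0.3
    drift_amplitude: float = 1.0


NULL_EFFECTS = EffectConfig(stiffness_slope=0.0, randomness_slope=0.0)
STRONG_EFFECTS = EffectConfig(
    stiffness_slope=1.0, randomness_slope=1.0,
    stiffness_noise=0.04, randomness_noise=0.04, smoking_age_link=0.3,
)
#: weaker feature-age slopes so regression dilution exposes the female
#: age-distribution offset in the sex-stratified trend
SEX_TREND_EFFECTS = EffectConfig(
    stiffness_slope=0.45, randomness_slope=0.45,
    stiffness_noise=0.04, randomness_noise=0.04, smoking_age_link=0.3,
    female_age_offset=-5.0,
)


def beat_template(stiffness: float, dicrotic_amp: float = 0.45,
                  dicrotic_delay: float = 0.39, dicrotic_width: float = 0.145):
    """Two-lobe pulse waveform on cycle phase [0, 1).

    The primary (systolic) lobe broadens as ``stiffness`` grows, which
    monotonically shrinks the second-derivative a-wave; the three dicrotic
    parameters model between-subject morphology variation that is
    independent of stiffness.  For any stiffness in [0, 1] and dicrotic
    parameters inside amp [0.40, 0.52] x delay [0.375, 0.405] x width
    [0.135, 0.155] the template keeps a single global maximum and exactly
    five second-derivative extrema per cycle.
    """
    if not 0.0 <= stiffness <= 1.0:
        raise SignalError("stiffness must lie in [0, 1]")
    # stiffness only widens the primary lobe, concentrating its effect in
    # the upstroke curvature (the a-wave) rather than the dicrotic shape
    mu1 = 0.22
    sigma1 = 0.055 + 0.040 * stiffness

    def template(phase: np.ndarray) -> np.ndarray:
        x = np.asarray(phase, dtype=float)
        lobe1 = np.exp(-0.5 * ((x - mu1) / sigma1) ** 2)
        lobe2 = dicrotic_amp * np.exp(
            -0.5 * ((x - dicrotic_delay) / dicrotic_width) ** 2)
        return lobe1 + lobe2

    return template


def template_peak_phase(stiffness: float, dicrotic_amp: float = 0.45,
                        dicrotic_delay: float = 0.39,
                        dicrotic_width: float = 0.145,
                        n_grid: int = 4096) -> float:
    """Phase of the template's global maximum (dense-grid argmax)."""
    grid = np.linspace(0.0, 1.0, n_grid, endpoint=False)
    tmpl = beat_template(stiffness, dicrotic_amp, dicrotic_delay,
                         dicrotic_width)
    return float(grid[np.argmax(tmpl(grid))])


def _rr_sequence(truth_seed: int, duration: float, base_rr: float,
                 randomness: float, diff_scale: float = 0.11) -> np.ndarray:
    """Beat-onset intervals (s): slow sinusoidal HRV mixed with white jitter.

    ``randomness`` sets the share of successive-difference power carried by
    the white component while the total successive-difference power stays
    roughly constant — so the turning-point ratio of the series rises with
    ``randomness`` without inflating rmssd-style dispersion in lockstep.
    """
    rng = np.random.default_rng(truth_seed)
    n_max = int(np.ceil(duration / (base_rr * 0.6))) + 4
    k = np.arange(n_max)
    theta = float(np.clip(randomness, 0.0, 1.0))
    f_slow = 0.12  # Hz
    diff_gain = 2.0 * np.sin(np.pi * f_slow * base_rr)
    amp_slow = diff_scale * base_rr * np.sqrt(1.0 - theta) / diff_gain
    amp_white = diff_scale * base_rr * np.sqrt(theta / 2.0)
    slow = amp_slow * np.sin(2 * np.pi * f_slow * k * base_rr)
    jitter = amp_white * rng.standard_normal(n_max)
    return np.clip(base_rr + slow + jitter, 0.45, 1.6)


def generate_truth(
    subject_id: str,
    age: float,
    meta: CovariateRecord,
    stiffness: float,
    rr_randomness: float,
    seed: int,
    duration: float = 90.0,
    base_rr: float | None = None,
    noise_amplitude: float = 0.0,
    modulation_depth: float = 0.0,
    drift_amplitude: float = 0.0,
    dicrotic_amp: float = 0.45,
    dicrotic_delay: float = 0.39,
    dicrotic_width: float = 0.145,
    rr_scale: float = 1.0,
) -> SubjectTruth:
    """Draw the beat sequence for one subject and package the ground truth."""
    rng = np.random.default_rng(seed)
    if base_rr is None:
        base_rr = float(rng.uniform(0.79, 0.85))
    rr = _rr_sequence(seed + 1, duration, base_rr, rr_randomness,
                      diff_scale=0.11 * rr_scale)
    onsets = np.concatenate(([0.0], np.cumsum(rr)))
    onsets = onsets[onsets < duration]
    rr_used = np.diff(onsets)
    peak_phase = template_peak_phase(stiffness, dicrotic_amp,
                                     dicrotic_delay, dicrotic_width)
    beat_times = onsets[:-1] + rr_used * peak_phase
    return SubjectTruth(
        subject_id=subject_id,
        beat_times=beat_times,
        rr_ms=np.diff(beat_times) * 1000.0,
        stiffness=float(stiffness),
        rr_randomness=float(rr_randomness),
        age=float(age),
        meta=meta,
        noise_amplitude=noise_amplitude,
        modulation_depth=modulation_depth,
        drift_amplitude=drift_amplitude,
        dicrotic_amp=float(dicrotic_amp),
        dicrotic_delay=float(dicrotic_delay),
        dicrotic_width=float(dicrotic_width),
        rr_scale=float(rr_scale),
        seed=seed,
    )


def generate_recording(truth: SubjectTruth, sf_nominal: float = 30.0,
                       jitter_s: float = 0.004) -> RawRecording:
    """Render a 7-column raw recording from a subject's ground truth.

    The pulse train is modulated by a 0.25 Hz respiratory sinusoid, summed
    with slow sinusoidal drift plus a smoothed random walk, scaled to raw
    camera-intensity units, and sampled on jittered ~30 Hz timestamps.
    """
    rng = np.random.default_rng(truth.seed + 2)
    # reconstruct onset times from systolic peak times
    peak_phase = template_peak_phase(
        truth.stiffness, truth.dicrotic_amp, truth.dicrotic_delay,
        truth.dicrotic_width)
    rr_s = np.diff(truth.beat_times)
    onset_times = truth.beat_times - np.concatenate((rr_s, rr_s[-1:])) * peak_phase
    duration = float(truth.beat_times[-1] + rr_s[-1])

    n = int(round(duration * sf_nominal))
    t = np.arange(n) / sf_nominal + rng.uniform(-jitter_s, jitter_s, size=n)
    t = np.maximum.accumulate(np.abs(t))
    t, idx = np.unique(t, return_index=True)
    n = t.size

    template = beat_template(truth.stiffness, truth.dicrotic_amp,
                             truth.dicrotic_delay, truth.dicrotic_width)
    # piecewise evaluation of the pulse train
    cycle_edges = np.concatenate((onset_times, [onset_times[-1] + rr_s[-1]]))
    which = np.clip(np.searchsorted(cycle_edges, t, side="right") - 1, 0,
                    len(onset_times) - 1)
    rr_all = np.concatenate((rr_s, rr_s[-1:]))
    phase = (t - onset_times[which]) / rr_all[which]
    pulse = template(np.clip(phase, 0.0, 1.0))

    modulation = 1.0 + truth.modulation_depth * np.sin(2 * np.pi * 0.25 * t)
    walk = np.cumsum(rng.standard_normal(n)) * 0.02
    if n > 15:
        kernel = np.ones(15) / 15.0
        walk = np.convolve(walk, kernel, mode="same")
    drift = truth.drift_amplitude * (np.sin(2 * np.pi * 0.03 * t) + walk)
    noise = truth.noise_amplitude * rng.standard_normal(n)

    red = 40000.0 + 800.0 * (pulse * modulation + drift + noise)
    green = 20000.0 + 50.0 * rng.standard_normal(n)
    blue = 10000.0 + 50.0 * rng.standard_normal(n)
    acc = 0.05 * rng.standard_normal((3, n))
    return RawRecording(
        subject_id=truth.subject_id, time=t, red=red, green=green, blue=blue,
        acc_x=acc[0], acc_y=acc[1], acc_z=acc[2], meta=truth.meta,
    )


def _age_link(age: float, slope: float, noise: float, base: float,
              rng: np.random.Generator) -> float:
    scaled = (age - 18.0) / 61.0  # 18-79 -> 0-1
    return float(np.clip(base + slope * 0.6 * (scaled - 0.5)
                         + noise * rng.standard_normal(), 0.0, 1.0))


def generate_cohort(
    n: int,
    effect_config: EffectConfig = STRONG_EFFECTS,
    seed: int = 0,
    duration: float = 90.0,
    out_dir=None,
):
    """Simulate ``n`` subjects; optionally write recordings in the CSV dialect.

    Returns ``(recordings, truths)``.  Ages are uniform over 18–79 (shifted
    by ``female_age_offset`` for females, floored at 18), covariates are
    drawn per sex, and smoking can be linked to age via
    ``smoking_age_link``.
    """
    if n < 2:
        raise SignalError("cohort needs n >= 2")
    cfg = effect_config
    rng = np.random.default_rng(seed)
    recordings, truths = [], []
    for i in range(n):
        age = float(rng.uniform(18.0, 79.0))
        sex = "female" if rng.random() < 0.5 else "male"
        if sex == "female":
            age = max(18.0, age + cfg.female_age_offset)
        stiffness = _age_link(age, cfg.stiffness_slope, cfg.stiffness_noise,
                              0.5, rng)
        randomness = _age_link(age, cfg.randomness_slope, cfg.randomness_noise,
                               0.5, rng)
        p_smoke = np.clip(0.35 + cfg.smoking_age_link * ((age - 18.0) / 61.0 - 0.5),
                          0.02, 0.98)
        smoking = "yes" if rng.random() < p_smoke else "no"
        height = float(rng.normal(178.0 if sex == "male" else 165.0, 7.0))
        weight = float(rng.normal(80.0 if sex == "male" else 68.0, 10.0))
        meta = CovariateRecord(sex=sex, age=age, weight=weight, height=height,
                               smoking=smoking)
        truth = generate_truth(
            subject_id=f"subj{i:04d}", age=age, meta=meta, stiffness=stiffness,
            rr_randomness=randomness, seed=int(rng.integers(0, 2**31)),
            duration=duration,
            noise_amplitude=cfg.noise_amplitude,
            modulation_depth=cfg.modulation_depth,
            drift_amplitude=cfg.drift_amplitude,
            dicrotic_amp=float(rng.uniform(0.40, 0.52)),
            dicrotic_delay=float(rng.uniform(0.375, 0.405)),
            dicrotic_width=float(rng.uniform(0.135, 0.155)),
            rr_scale=float(rng.uniform(0.6, 1.6)),
        )
        rec = generate_recording(truth)
        recordings.append(rec)
        truths.append(truth)
    if out_dir is not None:
        from .io_h4h import write_recording, write_truth_table

        for rec in recordings:
            write_recording(rec, f"{out_dir}/{rec.subject_id}.csv")
        write_truth_table(truths, f"{out_dir}/truth.csv")
    return recordings, truths
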