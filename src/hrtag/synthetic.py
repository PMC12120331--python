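"""Deployment-scale synthetic inputs for the heart-rate tag pipeline.

The generator emulates an ~80-day captive Atlantic bluefin tuna
deployment: a daily covariate trajectory (peripheral temperature
declining seasonally from ~27.5 to ~19 degC, its within-day variability
rising, activity drifting slightly upward, daily feed 0-20 tons with
multi-day fasting spells), a daily median heart rate drawn from the
identity-link Poisson change-point model, a 10-min logger-record stream
with a quality-index corruption process leaving ~85% of records usable,
and raw ECG / tri-axial acceleration bursts for the signal-level code.

Every generator is reproducible bit-for-bit given the config seed; each
stage uses an independent substream so stages can be re-run in
isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .model import ModelParams, ModelSpec, ThresholdSpec, evaluate_mu
from .signals import AccelBurst, ECGTrace

__all__ = [
    "DeploymentConfig",
    "GenerationError",
    "REFERENCE_PARAMS",
    "BEST_MODEL_SPEC",
    "generate_covariates",
    "generate_hr_series",
    "generate_logger_records",
    "generate_feeding_log",
    "synth_ecg",
    "synth_accel",
]


class GenerationError(ValueError):
    """Raised when a generator's inputs or outputs are inconsistent."""


#: The model structure found to explain daily median heart rate best in a
#: real 80-day captive deployment: feeding effect switching at a
#: temperature change-point, plus a linear temperature effect.
BEST_MODEL_SPEC = ModelSpec(
    covariates=("TF", "TPm"),
    threshold=ThresholdSpec(modulated="TF", governing="TPm"),
)

#: Posterior-mean parameter estimates from that deployment, used as the
#: default generating truth (bpm; slopes in bpm/ton and bpm/degC;
#: threshold in degC).  Centers are filled in from the generated
#: covariates at draw time.
REFERENCE_PARAMS = ModelParams(
    alpha=50.188,
    betas={"TPm": 2.137},
    beta_plus=0.313,
    beta_minus=1.831,
    thresh=25.462,
)


@dataclass(frozen=True)
class DeploymentConfig:
    """Knobs of the synthetic deployment (defaults = study conditions)."""

    n_days: int = 80
    records_per_day: int = 144          # 10-min cadence
    start_date: date = date(2022, 8, 1)
    temp_start_C: float = 27.5
    temp_end_C: float = 19.0
    temp_daily_noise_sd: float = 0.4    # degC, day-to-day wobble of TPm
    tpiq_start_C: float = 0.3           # within-day temp IQR, early
    tpiq_end_C: float = 1.2             # ... late (variability increases)
    acm_start_mg: float = 30.0
    acm_end_mg: float = 40.0
    acm_noise_sd: float = 3.0
    feed_max_tons: float = 20.0
    fasting_spell_prob: float = 0.06    # per-day chance a fasting spell starts
    fasting_spell_len: float = 2.5      # mean spell length, days (geometric)
    qi_bad_prob: float = 0.15           # chance a record draws QI in {2,3}
    corrupt_hr_frac: float = 0.3        # bad-QI records also given wild HR
    hr_oob_prob: float = 0.0            # independent out-of-bounds HR chance
    hr_jitter_sd: float = 6.0           # bpm, within-day spread around HRm
    dropout_prob: float = 0.0           # chance a 10-min slot is not logged
    hr_bounds: tuple[int, int] = (8, 120)
    generating_params: ModelParams = field(default_factory=lambda: REFERENCE_PARAMS)
    generating_spec: ModelSpec = field(default_factory=lambda: BEST_MODEL_SPEC)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 0:
            raise GenerationError("n_days must be >= 0")
        if self.records_per_day < 1:
            raise GenerationError("records_per_day must be >= 1")
        for p in ("fasting_spell_prob", "qi_bad_prob", "corrupt_hr_frac",
                  "hr_oob_prob", "dropout_prob"):
            v = getattr(self, p)
            if not 0.0 <= v <= 1.0:
                raise GenerationError(f"{p} must be a probability, got {v}")
        lo, hi = self.hr_bounds
        if not lo < hi:
            raise GenerationError("hr_bounds must satisfy low < high")
        if self.feed_max_tons <= 0:
            raise GenerationError("feed_max_tons must be positive")

    def dates(self) -> list[date]:
        return [self.start_date + timedelta(days=i) for i in range(self.n_days)]


def _stage_rng(config: DeploymentConfig, stage: int) -> np.random.Generator:
    # independent substream per stage so stages rerun in isolation
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stage]))


def generate_covariates(config: DeploymentConfig) -> pd.DataFrame:
    """Daily covariate trajectories: columns date, tpm, tpiq, acm, tf.

    TPm declines linearly between the configured endpoints plus seeded
    noise; TPiq and ACm trend upward with positive noise; TF follows the
    feeding schedule with fasting spells of TF = 0.
    """
    n = config.n_days
    if n == 0:
        return pd.DataFrame(columns=["date", "tpm", "tpiq", "acm", "tf"])
    rng = _stage_rng(config, 1)
    trend = np.linspace(config.temp_start_C, config.temp_end_C, n)
    tpm = trend + rng.normal(0.0, config.temp_daily_noise_sd, n)
    tpiq = np.linspace(config.tpiq_start_C, config.tpiq_end_C, n) * rng.lognormal(
        0.0, 0.25, n
    )
    acm = np.clip(
        np.linspace(config.acm_start_mg, config.acm_end_mg, n)
        + rng.normal(0.0, config.acm_noise_sd, n),
        1.0,
        None,
    )
    tf = _feed_schedule(config, rng)
    return pd.DataFrame(
        {"date": config.dates(), "tpm": tpm, "tpiq": tpiq, "acm": acm, "tf": tf}
    )


def _feed_schedule(config: DeploymentConfig, rng: np.random.Generator) -> np.ndarray:
    """Right-skewed daily feed on [0, feed_max_tons] with geometric-length
    fasting spells (TF = 0)."""
    n = config.n_days
    tf = np.round(config.feed_max_tons * rng.beta(2.0, 3.0, n), 1)
    remaining = 0
    for day in range(n):
        if remaining > 0:
            tf[day] = 0.0
            remaining -= 1
        elif rng.random() < config.fasting_spell_prob:
            remaining = rng.geometric(1.0 / config.fasting_spell_len)
            tf[day] = 0.0
            remaining -= 1
    return tf


def generate_feeding_log(covariates: pd.DataFrame) -> pd.DataFrame:
    """The daily feeding log (date, tf_tons) as the fish farm records it."""
    return pd.DataFrame(
        {"date": covariates["date"].to_numpy(), "tf_tons": covariates["tf"].to_numpy()}
    )


def generate_hr_series(
    covariates: pd.DataFrame,
    params: ModelParams | None = None,
    spec: ModelSpec | None = None,
    seed: int = 0,
    center: bool = True,
) -> pd.Series:
    """Draw the true daily median heart rate HRm_t ~ Poisson(mu_t).

    mu_t comes from :func:`hrtag.model.evaluate_mu` under the generating
    model.  With ``center=True`` (default) covariates are centered at
    their column means, matching the fitting convention, so the
    intercept is the expected heart rate at average conditions.
    """
    params = REFERENCE_PARAMS if params is None else params
    spec = BEST_MODEL_SPEC if spec is None else spec
    if center:
        from .model import COLUMN_OF

        centers = {c: float(covariates[COLUMN_OF[c]].mean()) for c in spec.covariates}
        params = params.with_centers(centers)
    mu = np.asarray(evaluate_mu(params, spec, covariates), dtype=float)
    bad = np.flatnonzero(mu <= 0)
    if bad.size:
        day = covariates["date"].iloc[bad[0]]
        raise GenerationError(
            f"non-positive expected heart rate (mu={mu[bad[0]]:.3f}) on {day}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2]))
    hrm = rng.poisson(mu)
    return pd.Series(hrm, index=covariates.index, name="hrm_true")


def _recenter(jit: np.ndarray) -> np.ndarray:
    """Shift integer jitter by the ceiling of its own median so the
    median becomes 0 or -0.5 — either way it rounds (half-up) to 0."""
    if len(jit):
        jit = jit - int(np.ceil(np.median(jit)))
    return jit


def _stratified_jitter(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    """Quantile-balanced discretized-normal integer jitter, median-true.

    Stratified normal quantiles (shuffled) share the marginal of iid
    discretized-normal noise but pin the sample median near zero, so a
    day's median heart rate stays at the true level even after a random
    subset of records is discarded by quality control.
    """
    from scipy.stats import norm

    if n == 0:
        return np.zeros(0, dtype=int)
    u = (np.arange(n) + 0.5) / n
    jit = np.round(norm.ppf(u) * sd).astype(int)
    rng.shuffle(jit)
    return _recenter(jit)


def generate_logger_records(
    covariates: pd.DataFrame,
    hr_series: pd.Series,
    config: DeploymentConfig,
) -> pd.DataFrame:
    """The 10-min logger stream: timestamp, hr_bpm, qi, temp_c, avg_ea_mg.

    Within a day, heart rate scatters around the day's true level so the
    within-day median rounds back to it; temperature scatters so its IQR
    matches the day's true TPiq; activity is lognormal around the day's
    median.  QI is 0/1 with probability 1 - qi_bad_prob, else 2/3; a
    fraction of bad-QI records (and, independently, ``hr_oob_prob`` of
    all records) get out-of-bounds heart rates.
    """
    if len(covariates) != len(hr_series):
        raise GenerationError(
            f"covariates span {len(covariates)} days but HR series spans "
            f"{len(hr_series)}"
        )
    rng = _stage_rng(config, 3)
    lo, hi = config.hr_bounds
    frames = []
    minutes = 24 * 60 / config.records_per_day
    for i, row in enumerate(covariates.itertuples(index=False)):
        n = config.records_per_day
        if config.dropout_prob > 0:
            keep_slot = rng.random(n) >= config.dropout_prob
        else:
            keep_slot = np.ones(n, dtype=bool)
        hr_true = int(hr_series.iloc[i])
        temp = row.tpm + rng.normal(0.0, max(row.tpiq, 1e-9) / 1.349, n)
        ea = row.acm * rng.lognormal(0.0, 0.4, n)

        bad_qi = rng.random(n) < config.qi_bad_prob
        qi = np.where(bad_qi, rng.integers(2, 4, n), rng.integers(0, 2, n))
        wild = bad_qi & (rng.random(n) < config.corrupt_hr_frac)
        oob = rng.random(n) < config.hr_oob_prob
        spoil = wild | oob
        # quantile-balanced jitter separately for the records QC keeps and
        # the rest, so both the raw and the post-QC daily median round
        # back to the day's true level (median of a union of multisets
        # lies between the subset medians, each pinned at 0 or -0.5)
        good = ~(bad_qi | spoil) & keep_slot
        rest = ~good & keep_slot
        jit = np.zeros(n, dtype=int)
        jit[good] = _stratified_jitter(rng, int(good.sum()), config.hr_jitter_sd)
        jit[rest] = _stratified_jitter(rng, int(rest.sum()), config.hr_jitter_sd)
        hr = np.clip(hr_true + jit, 0, None)
        k_spoil = int(spoil.sum())
        if k_spoil:
            # balanced low/high sides keep the spoiled subset median-neutral
            low_side = np.zeros(k_spoil, dtype=bool)
            low_side[: k_spoil // 2] = True
            rng.shuffle(low_side)
            hr[spoil] = np.where(
                low_side,
                rng.integers(0, lo, k_spoil),
                rng.integers(hi + 1, 2 * hi, k_spoil),
            )

        stamps = pd.Timestamp(row.date) + pd.to_timedelta(
            np.arange(n) * minutes, unit="m"
        )
        frames.append(
            pd.DataFrame(
                {
                    "timestamp": stamps[keep_slot],
                    "hr_bpm": hr[keep_slot].astype(int),
                    "qi": qi[keep_slot].astype(int),
                    "temp_c": temp[keep_slot],
                    "avg_ea_mg": ea[keep_slot],
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["timestamp", "hr_bpm", "qi", "temp_c", "avg_ea_mg"]
        )
    return pd.concat(frames, ignore_index=True)


# Gaussian-bump PQRST composite: (offset from R in s, amplitude, width in s)
_PQRST = (
    (-0.20, 0.15, 0.040),   # P
    (-0.03, -0.10, 0.012),  # Q
    (0.00, 1.00, 0.012),    # R
    (0.03, -0.15, 0.012),   # S
    (0.25, 0.30, 0.060),    # T
)


def synth_ecg(
    hr_bpm: float,
    duration_s: float = 7.5,
    sample_rate: float = 200.0,
    noise_sd: float = 0.0,
    first_peak_s: float = 0.3,
    seed: int = 0,
) -> ECGTrace:
    """A periodic PQRST-like pulse train with R-R interval 60/hr_bpm s.

    Only the R-peak timing matters downstream; the P/Q/S/T bumps give
    the waveform a realistic silhouette and exercise peak detection.
    Additive Gaussian noise is optional and seeded.
    """
    if hr_bpm <= 0 or duration_s <= 0 or sample_rate <= 0:
        raise ValueError("hr_bpm, duration_s and sample_rate must be positive")
    n = int(round(sample_rate * duration_s))
    t = np.arange(n) / sample_rate
    rr = 60.0 / hr_bpm
    x = np.zeros(n)
    beat = first_peak_s
    while beat < duration_s + rr:
        for off, amp, width in _PQRST:
            center = beat + off
            if -0.5 < center < duration_s + 0.5:
                x += amp * np.exp(-0.5 * ((t - center) / width) ** 2)
        beat += rr
    if noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 4]))
        x = x + rng.normal(0.0, noise_sd, n)
    return ECGTrace(sample_rate=sample_rate, samples=x)


def synth_accel(
    avg_ea_mg: float,
    duration_s: float = 60.0,
    sample_rate: float = 25.0,
    gravity_mg: float = 1000.0,
    tailbeat_hz: float = 1.2,
    seed: int = 0,
) -> AccelBurst:
    """A tri-axial burst (gravity included) whose external acceleration
    averages roughly ``avg_ea_mg``.

    The tail-beat oscillation is applied along the gravity axis so it
    modulates the vector norm (lateral sway orthogonal to a dominant
    gravity vector hardly changes the norm); small lateral noise keeps
    the axes realistic.
    """
    if avg_ea_mg < 0 or duration_s <= 0 or sample_rate <= 0:
        raise ValueError("invalid burst parameters")
    n = int(round(sample_rate * duration_s))
    t = np.arange(n) / sample_rate
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 5]))
    sway = avg_ea_mg * np.pi / 2.0  # |sin| has mean 2/pi
    ax = rng.normal(0.0, 0.02 * avg_ea_mg + 1e-9, n)
    ay = rng.normal(0.0, 0.02 * avg_ea_mg + 1e-9, n)
    az = gravity_mg + sway * np.sin(2 * np.pi * tailbeat_hz * t)
    return AccelBurst(sample_rate=sample_rate, ax=ax, ay=ay, az=az)
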