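"""Identity-link Poisson regression of daily median heart rate with an
optional temperature change-point.

The observation model is

    HRm_t ~ Poisson(mu_t),   mu_t = alpha + sum_i beta_i * (X_{i,t} - c_i)

where the X_i are daily covariates (total feed TF in tons, median
peripheral temperature TPm in degC, temperature interquartile range TPiq
in degC, median activity ACm in milli-g) and the c_i are fixed centering
offsets (column means when fitting, so alpha is the expected heart rate
at average conditions).  The link is the identity — mu is linear in the
covariates, not log-linear — so positivity of mu is a constraint, not a
consequence of the link.

One coefficient may switch at an estimated change-point: if a threshold
is declared for covariate M governed by covariate G, then

    beta_M(t) = beta_plus   if G_t > thresh
              = beta_minus  if G_t <= thresh

The governing covariate is compared on its natural (uncentered) scale so
the threshold is reported in natural units (e.g. degC).  Equality is
assigned to the "below" branch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "CANONICAL_COVARIATES",
    "COLUMN_OF",
    "RESPONSE_COLUMN",
    "ThresholdSpec",
    "ModelSpec",
    "ModelParams",
    "evaluate_mu",
    "log_likelihood",
    "enumerate_models",
    "params_to_vector",
    "vector_to_params",
]

#: Canonical covariate names, in the order models list them.
CANONICAL_COVARIATES = ("TF", "TPm", "TPiq", "ACm")

#: Mapping from canonical covariate name to daily-summary column.
COLUMN_OF = {"TF": "tf", "TPm": "tpm", "TPiq": "tpiq", "ACm": "acm"}

#: Daily-summary column holding the response (daily median heart rate).
RESPONSE_COLUMN = "hrm"


class ModelError(ValueError):
    """Raised for inconsistent model specifications or parameters."""


@dataclass(frozen=True)
class ThresholdSpec:
    """Declares which coefficient switches and which covariate governs it.

    ``modulated`` is the covariate whose slope takes the value beta_plus
    above the threshold and beta_minus at or below it; ``governing`` is
    the covariate whose (uncentered) value is compared to the threshold.
    """

    modulated: str
    governing: str

    def __post_init__(self) -> None:
        for name in (self.modulated, self.governing):
            if name not in CANONICAL_COVARIATES:
                raise ModelError(f"unknown covariate {name!r}")


@dataclass(frozen=True)
class ModelSpec:
    """A member of the nested model family.

    ``covariates`` is an ordered subset of :data:`CANONICAL_COVARIATES`;
    ``threshold`` is ``None`` for a plain linear model, otherwise a
    :class:`ThresholdSpec` whose modulated covariate must be listed in
    ``covariates``.  At most one threshold is allowed.
    """

    covariates: tuple[str, ...] = ()
    threshold: ThresholdSpec | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "covariates", tuple(self.covariates))
        seen = set()
        for name in self.covariates:
            if name not in CANONICAL_COVARIATES:
                raise ModelError(f"unknown covariate {name!r}")
            if name in seen:
                raise ModelError(f"duplicate covariate {name!r}")
            seen.add(name)
        if self.threshold is not None and self.threshold.modulated not in seen:
            raise ModelError(
                f"modulated covariate {self.threshold.modulated!r} "
                "is not among the model covariates"
            )

    @property
    def modulated(self) -> str | None:
        return None if self.threshold is None else self.threshold.modulated

    @property
    def governing(self) -> str | None:
        return None if self.threshold is None else self.threshold.governing

    @property
    def label(self) -> str:
        """Human-readable structure label, e.g. ``alpha + TF:thresh + TPm``."""
        parts = ["alpha"]
        for cov in self.covariates:
            parts.append(f"{cov}:thresh" if cov == self.modulated else cov)
        return " + ".join(parts)

    def parameter_names(self) -> list[str]:
        """Sampled-parameter names in canonical vector order."""
        names = ["alpha"]
        for cov in self.covariates:
            if cov == self.modulated:
                names += [f"beta_plus_{cov}", f"beta_minus_{cov}"]
            else:
                names.append(f"beta_{cov}")
        if self.threshold is not None:
            names.append("thresh")
        return names

    @property
    def n_parameters(self) -> int:
        return len(self.parameter_names())


@dataclass(frozen=True)
class ModelParams:
    """A point in parameter space for a given :class:`ModelSpec`.

    ``betas`` holds the plain (non-switched) slopes keyed by covariate
    name; ``beta_plus``/``beta_minus``/``thresh`` are present only for
    threshold models.  ``centers`` holds per-covariate centering offsets
    (natural units); missing entries mean "not centered".
    """

    alpha: float
    betas: Mapping[str, float] = field(default_factory=dict)
    beta_plus: float | None = None
    beta_minus: float | None = None
    thresh: float | None = None
    centers: Mapping[str, float] = field(default_factory=dict)

    def with_centers(self, centers: Mapping[str, float]) -> "ModelParams":
        return replace(self, centers=dict(centers))


def _as_frame(row_or_table) -> pd.DataFrame:
    if isinstance(row_or_table, pd.DataFrame):
        return row_or_table
    if isinstance(row_or_table, pd.Series):
        return row_or_table.to_frame().T
    if isinstance(row_or_table, Mapping):
        return pd.DataFrame([row_or_table])
    raise TypeError("expected a DataFrame, Series or mapping of columns")


def _column(data: pd.DataFrame, cov: str) -> np.ndarray:
    col = COLUMN_OF[cov]
    if col not in data.columns:
        raise ModelError(f"daily table lacks column {col!r} for covariate {cov}")
    return data[col].to_numpy(dtype=float)


def _check_threshold_params(params: ModelParams, spec: ModelSpec) -> None:
    if spec.threshold is not None:
        if params.beta_plus is None or params.beta_minus is None or params.thresh is None:
            raise ModelError("threshold model requires beta_plus, beta_minus and thresh")
    missing = [c for c in spec.covariates if c != spec.modulated and c not in params.betas]
    if missing:
        raise ModelError(f"missing slope(s) for covariate(s) {missing}")


def evaluate_mu(params: ModelParams, spec: ModelSpec, data) -> np.ndarray | float:
    """Expected daily heart rate mu_t (bpm) under the identity link.

    ``data`` may be a daily table (DataFrame with columns ``tf``, ``tpm``,
    ``tpiq``, ``acm`` as required by the spec) or a single row (Series or
    mapping); a scalar is returned for a single row.  The result may be
    non-positive — callers that need mu > 0 must enforce it.
    """
    _check_threshold_params(params, spec)
    frame = _as_frame(data)
    mu = np.full(len(frame), float(params.alpha))
    for cov in spec.covariates:
        x = _column(frame, cov) - float(params.centers.get(cov, 0.0))
        if cov == spec.modulated:
            g = _column(frame, spec.governing)  # natural units, never centered
            slope = np.where(g > params.thresh, params.beta_plus, params.beta_minus)
        else:
            slope = params.betas[cov]
        mu = mu + slope * x
    if not isinstance(data, pd.DataFrame):
        return float(mu[0])
    return mu


def log_likelihood(params: ModelParams, spec: ModelSpec, data: pd.DataFrame) -> float:
    """Poisson log-likelihood of the daily table under ``params``.

    Returns ``-inf`` if any mu_t <= 0.  Raises if the response column is
    not a non-negative integer series (the Poisson support).
    """
    y = data[RESPONSE_COLUMN].to_numpy(dtype=float)
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ModelError("response column 'hrm' must contain non-negative integers")
    mu = np.asarray(evaluate_mu(params, spec, data), dtype=float)
    if np.any(mu <= 0):
        return -math.inf
    return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1.0)))


# The 21 structures of the nested family, in the order they are reported:
# every subset of {TF, TPm, TPiq, ACm} with at most one thresholded term.
# "X:thresh" self-thresholds when X is a temperature variable (TPm, TPiq);
# otherwise X's coefficient switches at a threshold in TPm.
_MODEL_LABELS = (
    "alpha + TF:thresh + TPm",
    "alpha + TF:thresh + TPm + TPiq",
    "alpha + TF:thresh + TPm + TPiq + ACm",
    "alpha + TPiq:thresh + TF + TPm + ACm",
    "alpha + ACm:thresh + TF + TPm",
    "alpha + TF + TPm",
    "alpha + TF + TPm + TPiq",
    "alpha + TF + TPm + TPiq + ACm",
    "alpha + TPiq:thresh + TF + TPm",
    "alpha + TPm:thresh + TF",
    "alpha + TPm:thresh + TF + TPiq + ACm",
    "alpha + TPm:thresh + TF + TPiq",
    "alpha + ACm:thresh + TF + TPm + TPiq",
    "alpha + ACm:thresh + TF",
    "alpha + TF:thresh",
    "alpha + TF",
    "alpha + TPiq:thresh + TF",
    "alpha + TPm:thresh",
    "alpha + ACm:thresh",
    "alpha",
    "alpha + TPiq:thresh",
)


def spec_from_label(label: str) -> ModelSpec:
    """Parse a structure label like ``alpha + TF:thresh + TPm``."""
    parts = [p.strip() for p in label.split("+")]
    if not parts or parts[0] != "alpha":
        raise ModelError(f"label must start with 'alpha': {label!r}")
    covariates: list[str] = []
    threshold: ThresholdSpec | None = None
    for part in parts[1:]:
        if part.endswith(":thresh"):
            cov = part[: -len(":thresh")]
            governing = cov if cov in ("TPm", "TPiq") else "TPm"
            if threshold is not None:
                raise ModelError("at most one threshold per model")
            threshold = ThresholdSpec(modulated=cov, governing=governing)
        else:
            cov = part
        covariates.append(cov)
    return ModelSpec(covariates=tuple(covariates), threshold=threshold)


def enumerate_models() -> list[ModelSpec]:
    """The full nested model family (21 structures), in reporting order."""
    return [spec_from_label(label) for label in _MODEL_LABELS]


def params_to_vector(params: ModelParams, spec: ModelSpec) -> np.ndarray:
    """Flatten params to the canonical vector order of ``spec.parameter_names()``."""
    _check_threshold_params(params, spec)
    out = [float(params.alpha)]
    for cov in spec.covariates:
        if cov == spec.modulated:
            out += [float(params.beta_plus), float(params.beta_minus)]
        else:
            out.append(float(params.betas[cov]))
    if spec.threshold is not None:
        out.append(float(params.thresh))
    return np.asarray(out, dtype=float)


def vector_to_params(
    theta: Sequence[float],
    spec: ModelSpec,
    centers: Mapping[str, float] | None = None,
) -> ModelParams:
    """Inverse of :func:`params_to_vector`."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (spec.n_parameters,):
        raise ModelError(
            f"expected {spec.n_parameters} parameters for {spec.label!r}, "
            f"got {theta.shape}"
        )
    i = 0
    alpha = theta[i]
    i += 1
    betas: dict[str, float] = {}
    beta_plus = beta_minus = thresh = None
    for cov in spec.covariates:
        if cov == spec.modulated:
            beta_plus, beta_minus = theta[i], theta[i + 1]
            i += 2
        else:
            betas[cov] = theta[i]
            i += 1
    if spec.threshold is not None:
        thresh = theta[i]
    return ModelParams(
        alpha=float(alpha),
        betas=betas,
        beta_plus=None if beta_plus is None else float(beta_plus),
        beta_minus=None if beta_minus is None else float(beta_minus),
        thresh=None if thresh is None else float(thresh),
        centers={} if centers is None else dict(centers),
    )
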