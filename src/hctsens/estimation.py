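"""Risk-ratio estimation from subject-level hybrid-trial data.

The data model is a "subject table": one row per subject with columns

``s``  trial-inclusion indicator (1 = randomized trial, 0 = external cohort)
``a``  treatment indicator (1 = experimental arm; external subjects have a=0)
``y``  binary outcome
``w``  optional non-negative analysis weight (e.g. entropy-balancing weight
       on external controls), defaulting to 1

With a single binary predictor the log-binomial maximum-likelihood risk
ratio is the ratio of (weighted) outcome proportions, so estimation here is
closed form.  Confidence intervals are Wald intervals on the log scale; for
weighted data the variance uses Kish effective sample sizes, a sandwich-type
adjustment for unequal weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import EffectEstimate

__all__ = [
    "ArmSummary",
    "NonEstimableError",
    "read_subject_table",
    "validate_subject_table",
    "summarize_arms",
    "estimate_rr",
    "rr_from_props",
]

CONTRASTS = ("hct_effect", "trial_effect", "residual_difference")


class NonEstimableError(ValueError):
    """A requested risk ratio is not estimable (empty arm or zero events)."""


@dataclass(frozen=True)
class ArmSummary:
    """Weighted per-arm summaries of a subject table.

    ``n_*`` are weight sums (counts under unit weights), ``events_*``
    weighted event totals, ``p_*`` weighted outcome proportions and
    ``ess_*`` Kish effective sample sizes.  ``alpha_hat`` and ``eta_hat``
    are the empirical design ratios n_treated/n_IC and n_EC/n_IC.
    """

    n_treated: float
    n_internal: float
    n_external: float
    events_treated: float
    events_internal: float
    events_external: float
    p_treated: float
    p_internal: float
    p_external: float
    ess_treated: float
    ess_internal: float
    ess_external: float

    @property
    def alpha_hat(self) -> float:
        if self.n_internal == 0:
            raise NonEstimableError("internal control arm is empty")
        return self.n_treated / self.n_internal

    @property
    def eta_hat(self) -> float:
        if self.n_internal == 0:
            raise NonEstimableError("internal control arm is empty")
        return self.n_external / self.n_internal


def validate_subject_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate column presence, 0/1 coding and the design constraint that
    external subjects (s=0) are never treated.  Returns the table with a
    ``w`` column (unit weights added if absent)."""
    missing = {"s", "a", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"subject table missing columns: {sorted(missing)}")
    df = df.copy()
    for col in ("s", "a", "y"):
        vals = df[col].to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"column {col!r} must be coded 0/1")
        df[col] = vals.astype(np.int8)
    if "w" not in df.columns:
        df["w"] = 1.0
    w = df["w"].to_numpy(dtype=float)
    if not np.all(np.isfinite(w)) or np.any(w < 0):
        raise ValueError("weights must be finite and >= 0")
    df["w"] = w
    if ((df["s"] == 0) & (df["a"] == 1)).any():
        raise ValueError("external subjects (s=0) must be controls (a=0)")
    return df


def read_subject_table(path) -> pd.DataFrame:
    """Read a subject table from CSV (header required: s,a,y[,w])."""
    df = pd.read_csv(path)
    return validate_subject_table(df)


def _arm_stats(w: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    n = float(w.sum())
    events = float((w * y).sum())
    p = events / n if n > 0 else math.nan
    ss = float((w**2).sum())
    ess = n**2 / ss if ss > 0 else 0.0
    return n, events, p, ess


def summarize_arms(data: pd.DataFrame) -> ArmSummary:
    """Weighted event proportions and sizes of the three arms."""
    df = validate_subject_table(data)
    s = df["s"].to_numpy()
    a = df["a"].to_numpy()
    y = df["y"].to_numpy(dtype=float)
    w = df["w"].to_numpy(dtype=float)
    masks = {
        "treated": (s == 1) & (a == 1),
        "internal": (s == 1) & (a == 0),
        "external": (s == 0),
    }
    stats_ = {k: _arm_stats(w[m], y[m]) for k, m in masks.items()}
    return ArmSummary(
        n_treated=stats_["treated"][0],
        n_internal=stats_["internal"][0],
        n_external=stats_["external"][0],
        events_treated=stats_["treated"][1],
        events_internal=stats_["internal"][1],
        events_external=stats_["external"][1],
        p_treated=stats_["treated"][2],
        p_internal=stats_["internal"][2],
        p_external=stats_["external"][2],
        ess_treated=stats_["treated"][3],
        ess_internal=stats_["internal"][3],
        ess_external=stats_["external"][3],
    )


def rr_from_props(
    p1, ess1, p0, ess0, level: float = 0.95
):
    """Risk ratio with log-scale Wald CI from arm proportions.

    Vectorized over replicates.  ``ess`` are effective sample sizes (equal
    to n under unit weights); the log-RR variance is the delta-method form
    (1 - p1)/(ess1 * p1) + (1 - p0)/(ess0 * p0).  Entries with zero events
    in either arm come back as NaN (non-estimable).

    Returns ``(rr, lo, hi, p_value)`` arrays (or floats for scalar input).
    """
    p1a = np.asarray(p1, dtype=float)
    p0a = np.asarray(p0, dtype=float)
    e1 = np.asarray(ess1, dtype=float)
    e0 = np.asarray(ess0, dtype=float)
    scalar = p1a.ndim == 0 and p0a.ndim == 0
    z = stats.norm.ppf(0.5 + level / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rr = p1a / p0a
        var = (1.0 - p1a) / (e1 * p1a) + (1.0 - p0a) / (e0 * p0a)
        se = np.sqrt(var)
        log_rr = np.log(rr)
        lo = np.exp(log_rr - z * se)
        hi = np.exp(log_rr + z * se)
        zstat = np.where(se > 0, log_rr / se, np.inf * np.sign(log_rr))
        pval = 2.0 * stats.norm.sf(np.abs(zstat))
    bad = ~np.isfinite(rr) | (p1a <= 0) | (p0a <= 0)
    rr = np.where(bad, np.nan, rr)
    lo = np.where(bad, np.nan, lo)
    hi = np.where(bad, np.nan, hi)
    pval = np.where(bad, np.nan, pval)
    if scalar:
        return float(rr), float(lo), float(hi), float(pval)
    return rr, lo, hi, pval


_CONTRAST_ARMS = {
    # contrast -> (numerator arms, denominator arms)
    "hct_effect": ("treated", ("internal", "external")),
    "trial_effect": ("treated", ("internal",)),
    "residual_difference": ("internal", ("external",)),
}


def estimate_rr(
    data: pd.DataFrame, contrast: str = "hct_effect", level: float = 0.95
) -> EffectEstimate:
    """Estimate a risk ratio between two (possibly pooled) arms.

    ``contrast`` selects the comparison: ``hct_effect`` (treated vs pooled
    internal + external controls), ``trial_effect`` (treated vs internal
    controls) or ``residual_difference`` (internal vs external controls,
    internal in the numerator).  Weighted proportions and Kish-ESS Wald
    intervals throughout.  Raises :class:`NonEstimableError` on an empty
    arm or zero events in either side of the contrast.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"contrast must be one of {CONTRASTS}, got {contrast!r}")
    df = validate_subject_table(data)
    s = df["s"].to_numpy()
    a = df["a"].to_numpy()
    y = df["y"].to_numpy(dtype=float)
    w = df["w"].to_numpy(dtype=float)
    arm_masks = {
        "treated": (s == 1) & (a == 1),
        "internal": (s == 1) & (a == 0),
        "external": (s == 0),
    }
    num_arm, den_arms = _CONTRAST_ARMS[contrast]
    m1 = arm_masks[num_arm]
    m0 = np.zeros_like(m1)
    for arm in den_arms:
        m0 |= arm_masks[arm]
    for name, m in ((num_arm, m1), ("+".join(den_arms), m0)):
        if w[m].sum() <= 0:
            raise NonEstimableError(f"arm {name!r} is empty (zero total weight)")
    n1, ev1, p1, ess1 = _arm_stats(w[m1], y[m1])
    n0, ev0, p0, ess0 = _arm_stats(w[m0], y[m0])
    if ev1 <= 0 or ev0 <= 0:
        raise NonEstimableError(
            f"zero events in an arm of contrast {contrast!r} "
            f"(events: {ev1:g} vs {ev0:g})"
        )
    rr, lo, hi, pval = rr_from_props(p1, ess1, p0, ess0, level=level)
    return EffectEstimate(
        rr=rr, ci_lower=min(lo, rr), ci_upper=max(hi, rr),
        kind=contrast, p_value=pval, level=level,
    )
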