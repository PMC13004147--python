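"""Closed-form sensitivity metrics for hybrid controlled trials.

A hybrid controlled trial (HCT) augments the randomized internal control
arm of an RCT with external real-world controls.  Because trial inclusion
``S`` is not randomized, an unmeasured confounder ``U`` that affects both
inclusion and the outcome can bias the pooled treatment-effect estimate.
This module provides the tipping-point metrics for that problem:

* :func:`hc_value` — the minimum strength of association (on the risk-ratio
  scale) an unmeasured confounder would need with *either* trial inclusion
  or the outcome to fully explain away an observed HCT treatment effect,
  given the borrowing ratio ``eta``;
* :func:`rd_value` — the confounding strength implied by the observed
  residual difference (RD) between internal and external controls, used as
  a data-driven benchmark for the HC-value;
* :func:`bias_factor_bound` and :func:`rd_bound` — the underlying sharp
  bounds linking a hypothetical confounder (RR_SU, RR_UY) to the bias
  factor and the residual difference;
* :func:`frontier` — the boundary curve of all (RR_SU, RR_UY) pairs that
  just suffice to explain away an effect or induce an RD;
* :func:`e_value` — the classic E-value, provided for comparison only (it
  is not the recommended metric in the hybrid-control setting because the
  confounder acts on treatment only indirectly, through trial inclusion).

All ratio-valued functions fold their input through ``max(x, 1/x)`` so
callers may pass estimates on either side of 1.  Most functions accept
NumPy arrays and broadcast elementwise; scalar input yields scalar output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "DesignRatios",
    "ConfounderStrength",
    "EffectEstimate",
    "FrontierCurve",
    "DegenerateDesignError",
    "fold_ratio",
    "e_value",
    "bias_factor_bound",
    "confounding_threshold",
    "hc_value",
    "hc_value_ci",
    "rd_bound",
    "rd_value",
    "frontier",
    "approximate_rr",
]


class DegenerateDesignError(ValueError):
    """Raised when eta = 0: with no external borrowing the pooled estimate
    cannot be confounded by trial inclusion, so tipping thresholds are
    undefined."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DesignRatios:
    """Design ratios of a hybrid controlled trial.

    Parameters
    ----------
    alpha
        Allocation ratio within the trial, treated : internal-control
        (``n_treated / n_IC``).  Must be positive.
    eta
        Borrowing ratio, external-control : internal-control size
        (``n_EC / n_IC``).  Must be non-negative; ``eta = 0`` is a plain
        RCT and is allowed for bookkeeping, but tipping-point metrics
        require ``eta > 0``.
    """

    alpha: float = 1.0
    eta: float = 1.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.alpha) and self.alpha > 0):
            raise ValueError(f"alpha must be a finite positive ratio, got {self.alpha!r}")
        if not (math.isfinite(self.eta) and self.eta >= 0):
            raise ValueError(f"eta must be finite and >= 0, got {self.eta!r}")

    @classmethod
    def from_counts(cls, n_treated: float, n_internal: float, n_external: float) -> "DesignRatios":
        """Empirical ratios: alpha = n_treated/n_IC, eta = n_EC/n_IC."""
        if n_internal <= 0:
            raise ValueError("internal control arm must be non-empty")
        return cls(alpha=n_treated / n_internal, eta=n_external / n_internal)


@dataclass(frozen=True)
class ConfounderStrength:
    """Hypothetical confounder strength on the risk-ratio scale.

    ``rr_su`` is the maximal risk ratio of trial inclusion across the
    categories of the unmeasured confounder; ``rr_uy`` the maximal risk
    ratio of the outcome across categories.  Both must be >= 1 (they are
    maxima over folded category contrasts); fold raw ratios first with
    :func:`fold_ratio`.
    """

    rr_su: float
    rr_uy: float

    def __post_init__(self) -> None:
        for name, v in (("rr_su", self.rr_su), ("rr_uy", self.rr_uy)):
            if not (math.isfinite(v) and v >= 1):
                raise ValueError(
                    f"{name} must be a finite ratio >= 1 (fold raw ratios first), got {v!r}"
                )


@dataclass(frozen=True)
class EffectEstimate:
    """A risk ratio with its two-sided confidence interval.

    ``kind`` labels what the ratio contrasts: ``"hct_effect"`` (treated vs
    pooled internal+external controls), ``"trial_effect"`` (treated vs
    internal controls only) or ``"residual_difference"`` (internal vs
    external controls).  ``p_value`` and ``level`` are optional metadata
    filled in by the estimation layer.
    """

    rr: float
    ci_lower: float
    ci_upper: float
    kind: str = "hct_effect"
    p_value: float | None = None
    level: float = 0.95
    approximate: bool = False

    _KINDS = ("hct_effect", "trial_effect", "residual_difference")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"kind must be one of {self._KINDS}, got {self.kind!r}")
        if not (0 < self.ci_lower <= self.rr <= self.ci_upper):
            raise ValueError(
                "require 0 < ci_lower <= rr <= ci_upper, got "
                f"({self.ci_lower!r}, {self.rr!r}, {self.ci_upper!r})"
            )

    @property
    def significant(self) -> bool:
        """True when the CI excludes the null ratio 1 (strictly)."""
        return self.ci_lower > 1.0 or self.ci_upper < 1.0

    def ci_limit_closer_to_null(self) -> float:
        """The CI limit with the smaller folded ratio; 1.0 if the CI
        includes (or touches) 1."""
        if self.ci_lower <= 1.0 <= self.ci_upper:
            return 1.0
        lo_f, hi_f = fold_ratio(self.ci_lower), fold_ratio(self.ci_upper)
        return self.ci_lower if lo_f <= hi_f else self.ci_upper


@dataclass(frozen=True)
class FrontierCurve:
    """Boundary of a two-dimensional sensitivity region.

    ``points`` is an ``(n, 2)`` array of (rr_su, rr_uy) pairs satisfying
    the relevant bound with equality; ``threshold`` is the scalar tipping
    value attained where rr_su = rr_uy.  ``feasible`` is False when no
    finite confounder can produce the requested value (the bias-factor
    bound saturates at 1 + eta), in which case ``points`` is empty.
    """

    kind: str
    points: np.ndarray
    threshold: float
    feasible: bool = True
    value: float = field(default=math.nan)
    eta: float | None = None


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _as_array(x, name: str, *, positive: bool = True) -> tuple[np.ndarray, bool]:
    arr = np.asarray(x, dtype=float)
    scalar = arr.ndim == 0
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite, got {x!r}")
    if positive and not np.all(arr > 0):
        raise ValueError(f"{name} must be > 0, got {x!r}")
    return arr, scalar


def _ret(arr: np.ndarray, scalar: bool):
    return float(arr) if scalar else arr


def _as_strength(strength) -> tuple:
    if isinstance(strength, ConfounderStrength):
        return strength.rr_su, strength.rr_uy
    try:
        rr_su, rr_uy = strength
    except (TypeError, ValueError) as exc:
        raise TypeError(
            "strength must be a ConfounderStrength or an (rr_su, rr_uy) pair"
        ) from exc
    return rr_su, rr_uy


def _as_eta(design) -> float:
    if isinstance(design, DesignRatios):
        return design.eta
    return float(design)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def fold_ratio(x):
    """Fold a ratio onto the >= 1 scale: ``max(x, 1/x)``.

    The sensitivity formulas assume ratios >= 1; estimates below 1 are
    first inverted.  Idempotent, and symmetric under x -> 1/x.
    """
    arr, scalar = _as_array(x, "ratio")
    return _ret(np.maximum(arr, 1.0 / arr), scalar)


def e_value(rr):
    """Classic E-value of a risk ratio: ``r + sqrt(r (r - 1))`` with
    ``r = fold_ratio(rr)``.

    Included for reference only — in a hybrid controlled trial the
    confounder affects treatment only through trial inclusion, so the
    HC-value (:func:`hc_value`), not the E-value, is the appropriate
    tipping-point metric for the pooled estimate.
    """
    arr, scalar = _as_array(rr, "rr")
    r = np.maximum(arr, 1.0 / arr)
    return _ret(r + np.sqrt(r * (r - 1.0)), scalar)


def bias_factor_bound(strength, design) -> float:
    """Sharp upper bound on the bias factor induced by a confounder.

    The bias factor BF is the ratio of the HCT treatment effect to the
    (confounding-free) within-trial effect.  For a confounder with folded
    strengths (rr_su, rr_uy) and borrowing ratio eta,

        BF <= (1 + eta) * rr_su * rr_uy
              / (rr_su * rr_uy + eta * (rr_su + rr_uy) - eta).

    The bound lies in [1, 1 + eta]: it is 1 when either association is
    absent, approaches 1 + eta as both grow without limit, and is attained
    exactly when rr_su = rr_uy.
    """
    rr_su, rr_uy = _as_strength(strength)
    eta = _as_eta(design)
    su, s_scalar = _as_array(rr_su, "rr_su")
    uy, u_scalar = _as_array(rr_uy, "rr_uy")
    if np.any(su < 1) or np.any(uy < 1):
        raise ValueError("rr_su and rr_uy must be >= 1; fold raw ratios first")
    if eta < 0:
        raise ValueError(f"eta must be >= 0, got {eta!r}")
    prod = su * uy
    out = (1.0 + eta) * prod / (prod + eta * (su + uy) - eta)
    return _ret(out, s_scalar and u_scalar)


def confounding_threshold(bf, design):
    """Minimum confounder strength needed to induce a given bias factor.

    Inverts :func:`bias_factor_bound` along its diagonal: with
    ``b = fold_ratio(bf)`` the threshold is

        (eta * b + sqrt(b (b - 1) eta (eta + 1))) / (1 - b + eta),

    i.e. at least one of rr_su, rr_uy must reach this value.  Returns
    ``inf`` when ``b >= 1 + eta``: no confounder of any finite strength can
    bias the pooled estimate past the saturation point 1 + eta.
    """
    eta = _as_eta(design)
    if eta == 0:
        raise DegenerateDesignError(
            "eta = 0: without external borrowing the pooled estimate is not "
            "subject to inclusion confounding; the threshold is undefined"
        )
    if eta < 0:
        raise ValueError(f"eta must be >= 0, got {eta!r}")
    arr, scalar = _as_array(bf, "bf")
    b = np.maximum(arr, 1.0 / arr)
    with np.errstate(divide="ignore", invalid="ignore"):
        num = eta * b + np.sqrt(b * (b - 1.0) * eta * (eta + 1.0))
        out = np.where(b >= 1.0 + eta, np.inf, num / (1.0 - b + eta))
    return _ret(out, scalar)


def hc_value(est, design):
    """HC-value: the tipping threshold for the HCT treatment effect.

    The minimum strength of association (risk-ratio scale) an unmeasured
    confounder of trial inclusion would need with either inclusion or the
    outcome to explain away the observed HCT effect, were the true
    within-trial effect null.  Accepts an :class:`EffectEstimate` or a raw
    ratio; folding is applied internally.  Returns ``inf`` when the folded
    effect exceeds the saturation bound 1 + eta (flag it, don't raise: the
    result means "unexplainable by inclusion confounding at this eta").
    """
    rr = est.rr if isinstance(est, EffectEstimate) else est
    return confounding_threshold(rr, design)


def hc_value_ci(est: EffectEstimate, design):
    """HC-value of the confidence-interval limit closer to the null.

    The confounding strength needed to explain away mere *statistical
    significance* of the HCT effect.  If the CI already includes (or
    touches) 1, no confounding is needed and the value is 1.
    """
    limit = est.ci_limit_closer_to_null()
    if limit == 1.0:
        return 1.0
    return hc_value(limit, design)


def rd_bound(strength) -> float:
    """Sharp upper bound on the residual difference a confounder can induce.

        RD <= rr_su * rr_uy / (rr_su + rr_uy - 1).

    Symmetric in its arguments, 1 when either is 1, and never exceeds the
    weaker of the two associations.
    """
    rr_su, rr_uy = _as_strength(strength)
    su, s_scalar = _as_array(rr_su, "rr_su")
    uy, u_scalar = _as_array(rr_uy, "rr_uy")
    if np.any(su < 1) or np.any(uy < 1):
        raise ValueError("rr_su and rr_uy must be >= 1; fold raw ratios first")
    return _ret(su * uy / (su + uy - 1.0), s_scalar and u_scalar)


def rd_value(rd):
    """RD-value: confounding strength implied by an observed residual
    difference between internal and external controls.

    With ``r = fold_ratio(rd)`` the value is ``r + sqrt(r (r - 1))`` — the
    same closed form as the E-value, but interpreted as the minimum
    association with trial inclusion or outcome needed to *induce* the
    observed RD.  Serves as the data-driven benchmark compared against the
    HC-value in the decision rules.
    """
    arr, scalar = _as_array(rd, "rd")
    r = np.maximum(arr, 1.0 / arr)
    return _ret(r + np.sqrt(r * (r - 1.0)), scalar)


_FRONTIER_KINDS = ("explain_away_effect", "explain_away_significance", "induce_rd")


def frontier(
    kind: str,
    value: float,
    design=None,
    grid: Sequence[float] | None = None,
    n_grid: int = 200,
    span: float = 10.0,
) -> FrontierCurve:
    """Boundary curve of (rr_su, rr_uy) pairs attaining a bound exactly.

    For ``kind="explain_away_effect"`` (or ``"explain_away_significance"``,
    identical math applied to a CI limit) the curve solves the bias-factor
    bound with equality at ``b = fold_ratio(value)``; for
    ``kind="induce_rd"`` it solves the RD bound at ``r = fold_ratio(value)``.
    Both bounds are monotone in rr_uy, so the algebraic inverse is unique:

        effect:  rr_uy = b * eta * (rr_su - 1) / ((1 + eta) rr_su - b (rr_su + eta))
        rd:      rr_uy = r * (rr_su - 1) / (rr_su - r),  rr_su > r

    The default grid is ``n_grid`` log-spaced rr_su values from the scalar
    threshold (where rr_su = rr_uy) to ``span`` times it; grid points with
    no finite solution are omitted.  An infeasible request (folded effect
    >= 1 + eta) returns an empty, flagged curve rather than raising.
    """
    if kind not in _FRONTIER_KINDS:
        raise ValueError(f"kind must be one of {_FRONTIER_KINDS}, got {kind!r}")
    v = fold_ratio(value)
    if kind == "induce_rd":
        eta = None
        threshold = rd_value(value)
    else:
        if design is None:
            raise ValueError("explain-away frontiers require design ratios (eta)")
        eta = _as_eta(design)
        threshold = hc_value(value, eta)
        if not math.isfinite(threshold):
            return FrontierCurve(kind, np.empty((0, 2)), math.inf, feasible=False,
                                 value=float(value), eta=eta)

    if v == 1.0:  # null input: region degenerates to the single point (1, 1)
        return FrontierCurve(kind, np.array([[1.0, 1.0]]), 1.0, value=float(value), eta=eta)

    if grid is None:
        grid_arr = np.geomspace(threshold, span * threshold, n_grid)
    else:
        grid_arr = np.asarray(grid, dtype=float)

    pts = []
    for s in grid_arr:
        if kind == "induce_rd":
            if s <= v:
                if np.isclose(s, threshold):
                    pts.append((s, s))
                continue
            u = v * (s - 1.0) / (s - v)
        else:
            denom = (1.0 + eta) * s - v * (s + eta)
            if denom <= 0:
                if np.isclose(s, threshold):
                    pts.append((s, s))
                continue
            u = v * eta * (s - 1.0) / denom
        if u >= 1.0 - 1e-12:
            pts.append((s, max(u, 1.0)))
    points = np.asarray(pts, dtype=float).reshape(-1, 2)
    return FrontierCurve(kind, points, float(threshold), value=float(value), eta=eta)


_RR_MEASURES = ("risk_ratio", "odds_ratio", "hazard_ratio", "std_mean_diff")


def approximate_rr(effect: float, measure: str = "risk_ratio") -> float:
    """Convert a non-RR effect measure to an approximate risk ratio.

    Standard conversions used throughout E-value practice for common
    (non-rare) outcomes: OR -> sqrt(OR); HR -> (1 - 0.5**sqrt(HR)) /
    (1 - 0.5**sqrt(1/HR)); standardized mean difference d -> exp(0.91 d).
    Results fed into the sensitivity metrics should be labelled
    approximate.
    """
    if measure not in _RR_MEASURES:
        raise ValueError(f"measure must be one of {_RR_MEASURES}, got {measure!r}")
    if measure == "std_mean_diff":
        if not math.isfinite(effect):
            raise ValueError(f"effect must be finite, got {effect!r}")
        return math.exp(0.91 * effect)
    if not (math.isfinite(effect) and effect > 0):
        raise ValueError(f"{measure} must be a finite positive ratio, got {effect!r}")
    if measure == "risk_ratio":
        return float(effect)
    if measure == "odds_ratio":
        return math.sqrt(effect)
    # hazard ratio
    if effect == 1.0:
        return 1.0
    return (1.0 - 0.5 ** math.sqrt(effect)) / (1.0 - 0.5 ** math.sqrt(1.0 / effect))
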