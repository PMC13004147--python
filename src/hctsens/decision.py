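"""Decision procedures comparing HC-values against the RD-value benchmark.

The core sensitivity-analysis procedure runs five steps:

1. Gate on statistical significance of the HCT treatment effect; if the
   pooled estimate is not significant there is nothing to explain away and
   the sensitivity verdicts are "not applicable".
2. Compute the HC-value of the point estimate and of the CI limit closer
   to the null.
3. Compute the RD-value of the estimated residual difference between
   internal and external controls.
4. Reject the null for the *effect estimate* if the RD-value falls below
   the point HC-value; reject for *statistical significance* if it falls
   below the CI-limit HC-value.  Ties go to fail-to-reject.
5. Optionally trace the (RR_SU, RR_UY) frontier curves for plotting.

:func:`apply_rule` exposes the four operational rules evaluated in the
simulation study — the two sensitivity rules plus the naive pooled (HCT)
analysis and the trial-only analysis.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

from .core import (
    DesignRatios,
    EffectEstimate,
    FrontierCurve,
    fold_ratio,
    frontier,
    hc_value,
    hc_value_ci,
    rd_value,
)

__all__ = ["SensitivityReport", "run_sensitivity_analysis", "apply_rule", "RULES"]

RULES = ("effect_estimate", "statistical_significance", "hct_only", "trial_only")

VERDICTS = ("reject", "fail_to_reject", "not_applicable")


@dataclass
class SensitivityReport:
    """Auditable record of one sensitivity analysis.

    ``verdict_effect`` answers "can the observed non-exchangeability
    explain away the effect estimate?" and ``verdict_significance`` the
    same for its statistical significance.  ``narrative`` logs each step
    in order.
    """

    hct_estimate: EffectEstimate
    rd_estimate: EffectEstimate
    design: DesignRatios
    hc_point: float
    hc_ci: float
    rd_value_point: float
    verdict_effect: str
    verdict_significance: str
    trial_estimate: EffectEstimate | None = None
    rd_value_ci: float | None = None
    frontiers: list[FrontierCurve] = field(default_factory=list)
    narrative: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        def est(e: EffectEstimate | None):
            if e is None:
                return None
            d = asdict(e)
            return d

        return {
            "hct_estimate": est(self.hct_estimate),
            "trial_estimate": est(self.trial_estimate),
            "rd_estimate": est(self.rd_estimate),
            "design": {"alpha": self.design.alpha, "eta": self.design.eta},
            "hc_value_point": self.hc_point,
            "hc_value_ci": self.hc_ci,
            "rd_value_point": self.rd_value_point,
            "rd_value_ci": self.rd_value_ci,
            "verdict_effect": self.verdict_effect,
            "verdict_significance": self.verdict_significance,
            "narrative": list(self.narrative),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), default=str, **kwargs)


def _fmt(x: float, precision: int = 2) -> str:
    if math.isinf(x):
        return "Inf"
    return f"{x:.{precision}f}"


def run_sensitivity_analysis(
    hct: EffectEstimate,
    rd: EffectEstimate,
    design: DesignRatios | float,
    trial: EffectEstimate | None = None,
    compute_frontiers: bool = False,
    rd_ci_limit: str | None = None,
) -> SensitivityReport:
    """Run the five-step sensitivity analysis on summary estimates.

    Parameters
    ----------
    hct, rd
        The HCT treatment-effect estimate (treated vs pooled controls) and
        the residual-difference estimate (internal vs external controls),
        each with a two-sided CI.
    design
        Design ratios, or a bare ``eta``; ``eta`` must be positive.
    trial
        Optional trial-only estimate, carried through for reporting.
    compute_frontiers
        When True, attach the explain-away and induce-RD frontier curves.
    rd_ci_limit
        Off by default.  ``"lower"`` or ``"upper"`` additionally computes
        the RD-value of that CI limit of RD (a less/more conservative
        variant); it is reported but never changes the default verdicts.
    """
    if not isinstance(design, DesignRatios):
        design = DesignRatios(eta=float(design))
    narrative: list[str] = []

    significant = hct.significant
    narrative.append(
        f"Step 1: HCT effect {_fmt(hct.rr)} (95% CI {_fmt(hct.ci_lower)}-"
        f"{_fmt(hct.ci_upper)}) is "
        + ("statistically significant; proceeding." if significant
           else "not statistically significant; sensitivity analysis not applicable.")
    )

    hc_point = hc_value(hct, design)
    hc_ci = hc_value_ci(hct, design)
    if math.isinf(hc_point):
        narrative.append(
            f"Step 2: folded HCT effect {_fmt(fold_ratio(hct.rr))} exceeds the "
            f"bias saturation bound 1 + eta = {_fmt(1 + design.eta)}: no unmeasured "
            "confounder of trial inclusion, however strong, could produce it "
            "(HC-value = Inf)."
        )
    else:
        narrative.append(
            f"Step 2: HC-value {_fmt(hc_point)} at the point estimate, "
            f"{_fmt(hc_ci)} at the CI limit closer to the null (eta = {design.eta:g})."
        )

    rdv = rd_value(rd.rr)
    narrative.append(
        f"Step 3: residual difference {_fmt(rd.rr)} implies RD-value {_fmt(rdv)}."
    )

    rdv_ci = None
    if rd_ci_limit is not None:
        if rd_ci_limit not in ("lower", "upper"):
            raise ValueError("rd_ci_limit must be 'lower', 'upper' or None")
        lim = rd.ci_lower if rd_ci_limit == "lower" else rd.ci_upper
        rdv_ci = rd_value(lim)
        narrative.append(
            f"Step 3b (optional): RD-value of the RD CI {rd_ci_limit} limit "
            f"{_fmt(lim)} is {_fmt(rdv_ci)} (reported only; verdicts use the point RD-value)."
        )

    if not significant:
        verdict_effect = verdict_significance = "not_applicable"
        narrative.append("Step 4: skipped (step-1 gate).")
    else:
        # strict inequality: a tie means the observed non-exchangeability is
        # already strong enough, so we fail to reject
        verdict_effect = "reject" if rdv < hc_point else "fail_to_reject"
        verdict_significance = "reject" if rdv < hc_ci else "fail_to_reject"
        narrative.append(
            f"Step 4: RD-value {_fmt(rdv)} vs HC-value {_fmt(hc_point)} -> "
            f"{verdict_effect} (effect); vs CI-limit HC-value {_fmt(hc_ci)} -> "
            f"{verdict_significance} (significance)."
        )

    frontiers: list[FrontierCurve] = []
    if compute_frontiers:
        frontiers.append(frontier("explain_away_effect", hct.rr, design))
        limit = hct.ci_limit_closer_to_null()
        if limit != 1.0:
            frontiers.append(frontier("explain_away_significance", limit, design))
        frontiers.append(frontier("induce_rd", rd.rr))
        narrative.append(f"Step 5: traced {len(frontiers)} frontier curve(s).")

    return SensitivityReport(
        hct_estimate=hct,
        rd_estimate=rd,
        design=design,
        hc_point=hc_point,
        hc_ci=hc_ci,
        rd_value_point=rdv,
        verdict_effect=verdict_effect,
        verdict_significance=verdict_significance,
        trial_estimate=trial,
        rd_value_ci=rdv_ci,
        frontiers=frontiers,
        narrative=narrative,
    )


def apply_rule(
    rule: str,
    design: DesignRatios | float | None = None,
    hct: EffectEstimate | None = None,
    rd: EffectEstimate | None = None,
    trial: EffectEstimate | None = None,
) -> bool:
    """Binary reject/no-reject decision of one operational rule.

    ``effect_estimate``: HCT estimate significant and RD-value < HC-value
    of the point estimate.  ``statistical_significance``: HCT estimate
    significant and RD-value < HC-value of the CI limit closer to the null
    (never less conservative than the effect rule).  ``hct_only``: pooled
    estimate significant.  ``trial_only``: trial-only estimate significant.
    """
    if rule not in RULES:
        raise ValueError(f"rule must be one of {RULES}, got {rule!r}")
    if rule == "trial_only":
        if trial is None:
            raise ValueError("trial_only rule requires the trial-only estimate")
        return trial.significant
    if hct is None:
        raise ValueError(f"{rule} rule requires the HCT estimate")
    if rule == "hct_only":
        return hct.significant
    if rd is None or design is None:
        raise ValueError(f"{rule} rule requires the RD estimate and design ratios")
    report = run_sensitivity_analysis(hct, rd, design)
    if rule == "effect_estimate":
        return report.verdict_effect == "reject"
    return report.verdict_significance == "reject"
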