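"""Monte-Carlo study of the decision rules' operating characteristics.

The data-generating mechanism is a hybrid controlled trial with a binary
unmeasured confounder U: a trial of ``n_trial`` subjects randomized
``allocation``:1 to treatment vs internal control, augmented by an external
control arm ``eta`` times the internal-control size.  U is more prevalent
among trial participants (P(U=1|S=1) = ``p_u_trial``, and
P(U=1|S=0) = p_u_trial / rr_su), and shifts the outcome risk by a factor
``rr_uy`` — upward for trial subjects' favorable outcome when
``direction="external_poorer"``, downward when ``"external_better"``.  The
treatment multiplies risk by ``rr_ay`` with no treatment-confounder
interaction.

Each replicate yields trial-only, pooled (HCT) and residual-difference
risk-ratio estimates, the derived RD-value and HC-values, and the four
decision-rule outcomes; a scenario aggregates these over ``n_reps``
replicates into rejection rates (Type I error or power) and quantile
summaries.  Replicate ``r`` of a scenario draws from the dedicated
substream ``default_rng([seed, r])``, so scenarios are reproducible and
trivially parallelizable.

This module doubles as the package's synthetic-data generator:
:func:`generate_replicate` emits subject tables used as fixtures
throughout the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import core
from .core import DesignRatios
from .decision import RULES
from .estimation import rr_from_props

__all__ = [
    "ScenarioConfig",
    "PopulationTruths",
    "OperatingCharacteristics",
    "generate_replicate",
    "population_truths",
    "run_scenario",
    "run_grid",
    "summary_table",
]

DIRECTIONS = ("external_poorer", "external_better")

#: quantities summarized per replicate (Table-style rows)
SUMMARY_QUANTITIES = (
    "trial_rr",
    "rd",
    "hct_rr",
    "rd_value",
    "hc_value",
    "hc_value_ci",
)


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one simulation scenario.

    Defaults reproduce the reference study conditions: a 300-subject trial
    randomized 2:1, borrowing ratio eta = 5, confounder prevalence 0.5 in
    the trial, confounder-outcome risk ratio 2 with poorer external
    outcomes, baseline outcome risk 0.2, and 5000 replicates.  ``rr_su``
    in {1.5, 2, 3} encodes mild / moderate / strong confounding;
    ``rr_ay`` = 1 targets Type I error and 1.5 targets power.
    """

    n_trial: int = 300
    allocation: float = 2.0
    eta: float = 5.0
    rr_su: float = 1.5
    rr_uy: float = 2.0
    direction: str = "external_poorer"
    p_u_trial: float = 0.5
    p_y_baseline: float = 0.2
    rr_ay: float = 1.0
    n_reps: int = 5000
    seed: int = 0
    level: float = 0.95

    def __post_init__(self) -> None:
        if self.n_trial < 3:
            raise ValueError("n_trial must allow both trial arms to be non-empty")
        if not (self.allocation > 0 and math.isfinite(self.allocation)):
            raise ValueError(f"allocation must be positive, got {self.allocation!r}")
        if not (self.eta > 0 and math.isfinite(self.eta)):
            raise ValueError(f"eta must be positive, got {self.eta!r}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}, got {self.direction!r}")
        if not (self.rr_su >= 1 and self.rr_uy >= 1):
            raise ValueError("rr_su and rr_uy must be >= 1 (U more prevalent in the trial)")
        if not (0 < self.p_u_trial < 1):
            raise ValueError(f"p_u_trial must be in (0, 1), got {self.p_u_trial!r}")
        if not (0 < self.p_y_baseline < 1):
            raise ValueError(f"p_y_baseline must be in (0, 1), got {self.p_y_baseline!r}")
        if self.p_u_external > 1:
            raise ValueError("p_u_trial / rr_su must be a valid probability")
        pmax = max(
            self.outcome_prob(a, u) for a in (0, 1) for u in (0, 1)
        )
        if pmax > 1:
            raise ValueError(
                f"implied outcome probability {pmax:.3f} exceeds 1; "
                "reduce p_y_baseline, rr_uy or rr_ay"
            )
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not (0 < self.level < 1):
            raise ValueError("level must be in (0, 1)")

    # --- derived design quantities -------------------------------------

    @property
    def n_treated(self) -> int:
        return round(self.n_trial * self.allocation / (1.0 + self.allocation))

    @property
    def n_internal(self) -> int:
        return self.n_trial - self.n_treated

    @property
    def n_external(self) -> int:
        return round(self.eta * self.n_internal)

    @property
    def p_u_external(self) -> float:
        return self.p_u_trial / self.rr_su

    @property
    def design(self) -> DesignRatios:
        return DesignRatios.from_counts(self.n_treated, self.n_internal, self.n_external)

    def outcome_prob(self, a: int, u: int) -> float:
        """P(Y=1 | A=a, U=u); the confounder multiplies (poorer external)
        or divides (better external) the risk of the favorable outcome."""
        shift = self.rr_uy**u if self.direction == "external_poorer" else self.rr_uy**-u
        return self.p_y_baseline * shift * self.rr_ay**a


@dataclass(frozen=True)
class PopulationTruths:
    """Closed-form population values implied by a scenario (mixture
    arithmetic over the confounder distribution within each arm)."""

    p_treated: float
    p_internal: float
    p_external: float
    p_pooled_control: float
    trial_rr: float
    hct_rr: float
    rd: float


def population_truths(cfg: ScenarioConfig) -> PopulationTruths:
    """Exact population risk ratios for a scenario.

    Marginalizes the outcome model over the confounder within each arm:
    P(Y=1|A=a, S=1) mixes over P(U|S=1) and the external arm over
    P(U|S=0); the pooled control risk weights internal and external by
    their arm sizes.  Serves as the analytic oracle for the Monte-Carlo
    parameter-recovery checks.
    """

    def mix(a: int, p_u: float) -> float:
        return (1.0 - p_u) * cfg.outcome_prob(a, 0) + p_u * cfg.outcome_prob(a, 1)

    p_treated = mix(1, cfg.p_u_trial)
    p_internal = mix(0, cfg.p_u_trial)
    p_external = mix(0, cfg.p_u_external)
    n_ic, n_ec = cfg.n_internal, cfg.n_external
    p_pooled = (n_ic * p_internal + n_ec * p_external) / (n_ic + n_ec)
    return PopulationTruths(
        p_treated=p_treated,
        p_internal=p_internal,
        p_external=p_external,
        p_pooled_control=p_pooled,
        trial_rr=p_treated / p_internal,
        hct_rr=p_treated / p_pooled,
        rd=p_internal / p_external,
    )


def _replicate_rng(cfg: ScenarioConfig, rep: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, rep])


def _draw_subjects(cfg: ScenarioConfig, rng: np.random.Generator):
    """Draw one replicate's subject-level arrays (s, a, u, y), ordered
    treated, internal control, external control."""
    n_t, n_ic, n_ec = cfg.n_treated, cfg.n_internal, cfg.n_external
    s = np.concatenate([np.ones(n_t + n_ic, dtype=np.int8), np.zeros(n_ec, dtype=np.int8)])
    a = np.concatenate(
        [np.ones(n_t, dtype=np.int8), np.zeros(n_ic + n_ec, dtype=np.int8)]
    )
    p_u = np.where(s == 1, cfg.p_u_trial, cfg.p_u_external)
    u = (rng.random(s.shape[0]) < p_u).astype(np.int8)
    probs = np.array(
        [[cfg.outcome_prob(0, 0), cfg.outcome_prob(0, 1)],
         [cfg.outcome_prob(1, 0), cfg.outcome_prob(1, 1)]]
    )
    y = (rng.random(s.shape[0]) < probs[a, u]).astype(np.int8)
    return s, a, u, y


def generate_replicate(
    cfg: ScenarioConfig,
    rep: int = 0,
    rng: np.random.Generator | None = None,
    keep_confounder: bool = False,
) -> pd.DataFrame:
    """Generate one replicate as a subject table (columns s, a, y).

    ``rep`` selects the deterministic substream ``default_rng([seed, rep])``
    so the same (config, rep) pair always yields the identical table; pass
    an explicit ``rng`` to override.  The confounder column ``u`` is
    dropped by default — it is unmeasured by construction — but can be
    kept for didactic inspection.
    """
    if rng is None:
        rng = _replicate_rng(cfg, rep)
    s, a, u, y = _draw_subjects(cfg, rng)
    out = pd.DataFrame({"s": s, "a": a, "y": y})
    if keep_confounder:
        out["u"] = u
    return out


@dataclass
class OperatingCharacteristics:
    """Aggregated results of one simulated scenario.

    ``rejection`` maps each decision rule to its rejection proportion
    (Type I error under rr_ay = 1, power otherwise) with a binomial
    Monte-Carlo standard error; ``summaries`` holds the median and
    empirical 2.5/97.5 percentiles of each estimated quantity across the
    usable replicates.
    """

    config: ScenarioConfig
    rejection: dict[str, dict[str, float]]
    summaries: pd.DataFrame
    n_used: int
    n_dropped: int
    warnings: list[str] = field(default_factory=list)


def _scenario_arrays(cfg: ScenarioConfig) -> dict[str, np.ndarray]:
    """Simulate all replicates and return per-replicate event counts."""
    n_t, n_ic, n_ec = cfg.n_treated, cfg.n_internal, cfg.n_external
    ev = np.empty((cfg.n_reps, 3))
    for r in range(cfg.n_reps):
        rng = _replicate_rng(cfg, r)
        s, a, _, y = _draw_subjects(cfg, rng)
        treated = y[:n_t]
        internal = y[n_t : n_t + n_ic]
        external = y[n_t + n_ic :]
        ev[r] = (treated.sum(), internal.sum(), external.sum())
    return {
        "ev_treated": ev[:, 0],
        "ev_internal": ev[:, 1],
        "ev_external": ev[:, 2],
    }


def run_scenario(cfg: ScenarioConfig) -> OperatingCharacteristics:
    """Simulate one scenario and aggregate its operating characteristics.

    Per replicate: estimate the trial-only, pooled-HCT and residual-
    difference risk ratios (closed-form log-binomial with Wald intervals),
    derive the RD-value and the HC-values of the point estimate and the CI
    limit closer to the null at the scenario's eta, and apply the four
    decision rules.  Replicates with zero events in any arm are
    non-estimable; they are dropped and counted, with a loud warning if
    they exceed 1% of replicates.
    """
    counts = _scenario_arrays(cfg)
    n_t, n_ic, n_ec = cfg.n_treated, cfg.n_internal, cfg.n_external
    ev_t, ev_ic, ev_ec = (
        counts["ev_treated"],
        counts["ev_internal"],
        counts["ev_external"],
    )
    usable = (ev_t > 0) & (ev_ic > 0) & (ev_ec > 0)
    n_dropped = int((~usable).sum())
    ev_t, ev_ic, ev_ec = ev_t[usable], ev_ic[usable], ev_ec[usable]
    n_used = int(usable.sum())

    p_t, p_ic, p_ec = ev_t / n_t, ev_ic / n_ic, ev_ec / n_ec
    p_pool = (ev_ic + ev_ec) / (n_ic + n_ec)

    trial_rr, trial_lo, trial_hi, _ = rr_from_props(p_t, n_t, p_ic, n_ic, level=cfg.level)
    hct_rr, hct_lo, hct_hi, _ = rr_from_props(p_t, n_t, p_pool, n_ic + n_ec, level=cfg.level)
    rd, _, _, _ = rr_from_props(p_ic, n_ic, p_ec, n_ec, level=cfg.level)

    eta = cfg.design.eta
    rdv = core.rd_value(rd)
    hc_point = core.hc_value(hct_rr, eta)
    # CI limit closer to the null: the limit with the smaller folded ratio,
    # or 1 when the interval includes (or touches) 1
    includes_null = (hct_lo <= 1.0) & (hct_hi >= 1.0)
    closer = np.where(core.fold_ratio(hct_lo) <= core.fold_ratio(hct_hi), hct_lo, hct_hi)
    hc_ci = np.where(includes_null, 1.0, core.hc_value(closer, eta))

    hct_sig = ~includes_null
    trial_sig = (trial_lo > 1.0) | (trial_hi < 1.0)
    reject = {
        "effect_estimate": hct_sig & (rdv < hc_point),
        "statistical_significance": hct_sig & (rdv < hc_ci),
        "hct_only": hct_sig,
        "trial_only": trial_sig,
    }
    rejection = {
        rule: {
            "rate": float(r.mean()),
            "mc_se": float(np.sqrt(r.mean() * (1.0 - r.mean()) / n_used)),
        }
        for rule, r in reject.items()
    }

    values = {
        "trial_rr": trial_rr,
        "rd": rd,
        "hct_rr": hct_rr,
        "rd_value": rdv,
        "hc_value": hc_point,
        "hc_value_ci": hc_ci,
    }
    summaries = pd.DataFrame(
        {
            "median": {k: float(np.median(v)) for k, v in values.items()},
            # order statistics ("nearest") so infinite HC-values propagate
            # as inf rather than interpolating to nan
            "q2.5": {k: float(np.quantile(v, 0.025, method="nearest")) for k, v in values.items()},
            "q97.5": {k: float(np.quantile(v, 0.975, method="nearest")) for k, v in values.items()},
        }
    ).loc[list(SUMMARY_QUANTITIES)]

    warnings_: list[str] = []
    if n_dropped > 0.01 * cfg.n_reps:
        warnings_.append(
            f"{n_dropped} of {cfg.n_reps} replicates ({n_dropped / cfg.n_reps:.1%}) "
            "were non-estimable (zero-event arm) and excluded"
        )
    return OperatingCharacteristics(
        config=cfg,
        rejection=rejection,
        summaries=summaries,
        n_used=n_used,
        n_dropped=n_dropped,
        warnings=warnings_,
    )


_GRID_KEYS = ("rr_su", "eta", "direction", "rr_ay")


def run_grid(configs: list[ScenarioConfig]) -> pd.DataFrame:
    """Run several scenarios and return tidy long-format rejection rates.

    One row per (scenario, rule), keyed by rr_su, eta, direction and
    rr_ay — the layout used for rejection-rate-vs-confounding plots.
    """
    if not configs:
        raise ValueError("run_grid needs at least one scenario")
    rows = []
    for cfg in configs:
        oc = run_scenario(cfg)
        for rule in RULES:
            rows.append(
                {
                    **{k: getattr(cfg, k) for k in _GRID_KEYS},
                    "rule": rule,
                    "rejection_rate": oc.rejection[rule]["rate"],
                    "mc_se": oc.rejection[rule]["mc_se"],
                    "n_used": oc.n_used,
                    "n_dropped": oc.n_dropped,
                }
            )
    return pd.DataFrame(rows)


def summary_table(ocs: list[OperatingCharacteristics]) -> pd.DataFrame:
    """Tidy long table of median (95% quantile) summaries across scenarios,
    one row per (scenario, quantity)."""
    rows = []
    for oc in ocs:
        for quantity, row in oc.summaries.iterrows():
            rows.append(
                {
                    **{k: getattr(oc.config, k) for k in _GRID_KEYS},
                    "quantity": quantity,
                    "median": row["median"],
                    "q2.5": row["q2.5"],
                    "q97.5": row["q97.5"],
                }
            )
    return pd.DataFrame(rows)


def scenario_grid(
    rr_su=(1.5, 2.0, 3.0),
    rr_ay=(1.0, 1.5),
    eta=(5.0,),
    direction=("external_poorer",),
    base: ScenarioConfig | None = None,
    **overrides,
) -> list[ScenarioConfig]:
    """Cartesian grid of scenarios around a base configuration."""
    base = base or ScenarioConfig(**overrides)
    out = []
    for d in direction:
        for e in eta:
            for su in rr_su:
                for ay in rr_ay:
                    out.append(replace(base, rr_su=su, rr_ay=ay, eta=e, direction=d))
    return out
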