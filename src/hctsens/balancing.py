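"""Entropy balancing of external-control covariates to trial moments.

When individual patient data are available only for the external cohort,
propensity-score methods are off the table; entropy balancing needs just
summary moments of the trial arm.  Weights minimize the Kullback-Leibler
divergence from base weights subject to (i) matching target first and
second moments of the covariates and (ii) a fixed weight total — here
defaulting to the internal-control size, so the weighted external arm has
effective borrowing ratio 1.

The constrained primal is solved through its strictly convex unconstrained
dual: with constraint columns z_i and per-unit targets t, weights take the
exponential-tilting form

    w_i(lam) = total * b_i exp(z_i' lam) / sum_k b_k exp(z_k' lam)

and lam minimizes  log sum_i b_i exp(z_i' lam) - t' lam,  whose gradient is
the achieved-minus-target moment vector.  Newton iterations with
backtracking line search converge in a handful of steps on well-posed
problems; a BFGS fallback covers near-singular Hessians.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "MomentTargets",
    "BalanceResult",
    "InfeasibleTargetsError",
    "solve_entropy_weights",
    "balance_diagnostics",
    "kish_ess",
]


class InfeasibleTargetsError(ValueError):
    """Targets lie outside the convex hull of the external covariates."""


def kish_ess(w: np.ndarray) -> float:
    """Kish effective sample size (sum w)^2 / sum w^2."""
    w = np.asarray(w, dtype=float)
    ss = float((w**2).sum())
    return float(w.sum()) ** 2 / ss if ss > 0 else 0.0


@dataclass(frozen=True)
class MomentTargets:
    """Target covariate moments for balancing, as per-unit values.

    ``means`` maps covariate name -> target mean.  ``variances`` (optional
    per covariate) adds a second-moment constraint, implemented as the raw
    second moment of deviations about the *target* mean with population
    (n) convention, so the weighted SD of a balanced column equals
    sqrt(variance).  ``proportions`` maps a categorical covariate name ->
    {level: proportion}; the reference (first) level is dropped to avoid a
    redundant constraint.  ``total`` is the required weight sum (commonly
    the internal-control size).
    """

    means: dict[str, float] = field(default_factory=dict)
    variances: dict[str, float] = field(default_factory=dict)
    proportions: dict[str, dict[str, float]] = field(default_factory=dict)
    total: float = 1.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.total) and self.total > 0):
            raise ValueError(f"total must be a positive weight sum, got {self.total!r}")
        for name, v in {**self.means, **self.variances}.items():
            if not math.isfinite(v):
                raise ValueError(f"target for {name!r} must be finite, got {v!r}")
        for name, props in self.proportions.items():
            vals = np.array(list(props.values()), dtype=float)
            if np.any(vals < 0) or np.any(vals > 1):
                raise ValueError(f"proportions for {name!r} must lie in [0, 1]")
            if abs(vals.sum() - 1.0) > 1e-8:
                raise ValueError(
                    f"proportions for {name!r} must sum to 1, got {vals.sum():.6f}"
                )
        for name in self.variances:
            if name not in self.means:
                raise ValueError(f"variance target for {name!r} requires a mean target")

    @classmethod
    def from_config(cls, cfg: dict) -> "MomentTargets":
        """Build targets from a config mapping.

        Covariate blocks: ``{mean: m}`` or ``{mean: m, sd: s}`` for
        continuous covariates, ``{levels: {name: prop, ...}}`` for
        categorical ones; top-level key ``total`` sets the weight sum.
        """
        means: dict[str, float] = {}
        variances: dict[str, float] = {}
        proportions: dict[str, dict[str, float]] = {}
        total = float(cfg.get("total", 1.0))
        for name, block in cfg.items():
            if name == "total":
                continue
            if not isinstance(block, dict):
                raise ValueError(f"covariate block {name!r} must be a mapping")
            if "levels" in block:
                proportions[name] = {str(k): float(v) for k, v in block["levels"].items()}
            elif "mean" in block:
                means[name] = float(block["mean"])
                if "sd" in block:
                    variances[name] = float(block["sd"]) ** 2
                elif "variance" in block:
                    variances[name] = float(block["variance"])
            else:
                raise ValueError(
                    f"covariate block {name!r} needs 'mean' (continuous) or 'levels' (categorical)"
                )
        return cls(means=means, variances=variances, proportions=proportions, total=total)

    def build_constraints(self, data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """Constraint matrix Z (units x constraints), per-unit target
        vector t, and constraint names, from external covariate data."""
        cols: list[np.ndarray] = []
        targets: list[float] = []
        names: list[str] = []
        for name, mean in self.means.items():
            if name not in data.columns:
                raise ValueError(f"covariate {name!r} not found in external data")
            x = data[name].to_numpy(dtype=float)
            cols.append(x)
            targets.append(mean)
            names.append(f"{name}:mean")
            if name in self.variances:
                cols.append((x - mean) ** 2)
                targets.append(self.variances[name])
                names.append(f"{name}:variance")
        for name, props in self.proportions.items():
            if name not in data.columns:
                raise ValueError(f"covariate {name!r} not found in external data")
            x = data[name].astype(str).to_numpy()
            levels = list(props)
            unknown = set(np.unique(x)) - set(levels)
            if unknown:
                raise ValueError(
                    f"levels {sorted(unknown)} of {name!r} missing from targets"
                )
            for level in levels[1:]:  # drop reference level
                cols.append((x == level).astype(float))
                targets.append(props[level])
                names.append(f"{name}:{level}")
        if not cols:
            raise ValueError("no balancing constraints specified")
        return np.column_stack(cols), np.asarray(targets, dtype=float), names


@dataclass
class BalanceResult:
    """Solved entropy-balancing weights with diagnostics."""

    weights: np.ndarray
    achieved: dict[str, float]
    targets: dict[str, float]
    total: float
    converged: bool
    n_iter: int
    max_violation: float
    dropped_constraints: list[str] = field(default_factory=list)

    @property
    def weight_range(self) -> tuple[float, float]:
        return float(self.weights.min()), float(self.weights.max())

    @property
    def ess(self) -> float:
        return kish_ess(self.weights)


def _drop_redundant(Z: np.ndarray, t: np.ndarray, names: list[str], tol: float = 1e-9):
    """Keep a maximal linearly independent set of constraint columns
    (including the implicit intercept), via pivoted QR."""
    aug = np.column_stack([np.ones(Z.shape[0]), Z])
    from scipy.linalg import qr

    _, R, piv = qr(aug, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int((diag > tol * diag[0]).sum()) if diag.size else 0
    keep_aug = sorted(piv[:rank])
    keep = [j - 1 for j in keep_aug if j > 0]
    dropped = [names[j] for j in range(Z.shape[1]) if j not in keep]
    return Z[:, keep], t[keep], [names[j] for j in keep], dropped


def solve_entropy_weights(
    external_covariates: pd.DataFrame | np.ndarray,
    targets: MomentTargets,
    base_weights: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> BalanceResult:
    """Solve for entropy-balancing weights on the external cohort.

    Parameters
    ----------
    external_covariates
        Per-subject covariate values for the external controls.  A bare
        array/sequence is treated as a single covariate named ``x``.
    targets
        Moment targets (typically trial summary statistics) and the
        normalization total.
    base_weights
        Positive prior weights; uniform by default.  The solution is the
        KL projection of these onto the constraint set.
    tol
        Convergence threshold on the maximum per-unit moment violation.

    Raises
    ------
    InfeasibleTargetsError
        If a target lies outside the convex hull of the observed external
        moments (the dual diverges), naming the worst-violated constraint.
    """
    if isinstance(external_covariates, pd.DataFrame):
        data = external_covariates
    else:
        arr = np.asarray(external_covariates, dtype=float)
        if arr.ndim == 1:
            data = pd.DataFrame({"x": arr})
        else:
            data = pd.DataFrame(arr, columns=[f"x{j}" for j in range(arr.shape[1])])
    n = len(data)
    if n == 0:
        raise ValueError("external cohort is empty")
    Z, t, names = targets.build_constraints(data)
    Z, t, names, dropped = _drop_redundant(Z, t, names)

    if base_weights is None:
        b = np.full(n, 1.0 / n)
    else:
        b = np.asarray(base_weights, dtype=float)
        if b.shape != (n,) or np.any(b <= 0) or not np.all(np.isfinite(b)):
            raise ValueError("base_weights must be positive, finite, one per external subject")
        b = b / b.sum()

    # feasibility pre-check: each target must lie inside the range of its column
    for j, name in enumerate(names):
        lo, hi = Z[:, j].min(), Z[:, j].max()
        if t[j] < lo - 1e-12 or t[j] > hi + 1e-12:
            raise InfeasibleTargetsError(
                f"target for {name!r} ({t[j]:g}) is outside the observed range "
                f"[{lo:g}, {hi:g}] of the external cohort"
            )

    # center and scale constraint columns for conditioning
    scale = Z.std(axis=0)
    scale[scale == 0] = 1.0
    Zs = (Z - t) / scale  # targets become 0

    def dual(lam: np.ndarray):
        eta_lin = Zs @ lam
        m = eta_lin.max()
        log_z = m + math.log(float(b @ np.exp(eta_lin - m)))
        return log_z

    def weights_of(lam: np.ndarray) -> np.ndarray:
        eta_lin = Zs @ lam
        raw = b * np.exp(eta_lin - eta_lin.max())
        return raw / raw.sum()

    lam = np.zeros(Zs.shape[1])
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = weights_of(lam)
        grad = Zs.T @ p  # achieved-minus-target, scaled
        if np.max(np.abs(grad * scale)) < tol and np.linalg.norm(grad) < 1e-6:
            converged = True
            break
        H = (Zs * p[:, None]).T @ Zs - np.outer(grad, grad)
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(len(lam)), -grad)
        except np.linalg.LinAlgError:
            step = -grad
        f0 = dual(lam)
        g_dot_s = float(grad @ step)
        if g_dot_s >= 0:  # not a descent direction; fall back to steepest descent
            step = -grad
            g_dot_s = float(grad @ step)
        alpha = 1.0
        while alpha > 1e-12 and dual(lam + alpha * step) > f0 + 1e-4 * alpha * g_dot_s:
            alpha *= 0.5  # Armijo backtracking on the dual
        lam = lam + alpha * step
        if np.linalg.norm(lam) > 1e6:
            break

    if not converged:
        # quasi-Newton fallback for stiff or near-infeasible problems
        res = optimize.minimize(
            lambda l: dual(l) ,
            lam,
            jac=lambda l: Zs.T @ weights_of(l),
            method="BFGS",
            options={"gtol": 1e-12, "maxiter": 2000},
        )
        lam = res.x
        it += int(res.nit)

    p = weights_of(lam)
    grad = Zs.T @ p
    max_violation = float(np.max(np.abs(grad * scale)))
    converged = max_violation < max(tol, 1e-7)
    if not converged:
        j = int(np.argmax(np.abs(grad * scale)))
        raise InfeasibleTargetsError(
            f"entropy balancing failed to satisfy constraint {names[j]!r} "
            f"(violation {max_violation:.3g}); the target may be on or outside "
            "the boundary of the feasible region"
        )
    w = targets.total * p
    achieved = {name: float((w * Z[:, j]).sum() / w.sum()) for j, name in enumerate(names)}
    return BalanceResult(
        weights=w,
        achieved=achieved,
        targets=dict(zip(names, t.tolist())),
        total=targets.total,
        converged=converged,
        n_iter=it,
        max_violation=max_violation,
        dropped_constraints=dropped,
    )


def balance_diagnostics(result: BalanceResult) -> dict:
    """Diagnostics of a converged balance: weight range, coefficient of
    variation, Kish effective sample size, and the achieved-vs-target
    constraint table."""
    w = result.weights
    cv = float(w.std() / w.mean()) if w.mean() > 0 else math.nan
    table = pd.DataFrame(
        {
            "target": pd.Series(result.targets),
            "achieved": pd.Series(result.achieved),
        }
    )
    table["abs_error"] = (table["achieved"] - table["target"]).abs()
    return {
        "weight_min": result.weight_range[0],
        "weight_max": result.weight_range[1],
        "weight_cv": cv,
        "ess": result.ess,
        "sum_weights": float(w.sum()),
        "n_iter": result.n_iter,
        "max_violation": result.max_violation,
        "constraints": table,
    }
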