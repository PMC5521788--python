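"""Clonogenic survival: surviving fractions, LQ fits, iso-survival doses, RBE.

The clonogenic assay scores reproductive survival: of ``seeded`` cells plated
per well, ``colonies`` grow out after irradiation and a colony-formation
period.  The plating efficiency ``pe`` (colony yield of unirradiated
controls) normalises counts to a surviving fraction

    SF(D) = colonies / (seeded * pe)

Dose response is modelled with the linear-quadratic (LQ) model

    SF(D) = exp(-alpha*D - beta*D^2)

or its one-phase (linear-exponential) special case beta = 0, characteristic
of high-LET radiation.  alpha and beta are constrained non-negative; a fit in
which the alpha constraint binds is flagged (``alpha_at_bound``), mirroring
the "alpha < upper bound" style of reporting for curves dominated by the
quadratic term.

Two fit objectives are available:

* ``"poisson"`` (default): maximum likelihood on the colony counts,
  colonies ~ Poisson(seeded * pe * SF(D)), with ln(pe) estimated jointly
  from the control wells.  Colony counts are small where survival is low, so
  the Poisson likelihood is the calibrated choice: log-domain least squares
  is biased by the convexity of -ln at counts of order one, and zero-colony
  wells carry real information that the log domain must discard.
* ``"lsq"``: unweighted least squares on -ln SF, the classical textbook
  procedure.  Useful for comparison and as the only option when one has
  survival fractions but no underlying counts (see :func:`fit_sf_curve`).

Derived summaries: the dose at a fixed survival level (D10, D20), the
alpha/beta ratio with a delta-method standard error, and the relative
biological effectiveness RBE = D_reference / D_test at the same endpoint.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ClonogenicDataset",
    "SurvivalFit",
    "surviving_fraction",
    "fit_survival",
    "fit_sf_curve",
    "confidence_interval",
    "dose_at_survival",
    "rbe",
    "alpha_beta_ratio",
]

logger = logging.getLogger(__name__)


@dataclass
class ClonogenicDataset:
    """Colony counts vs dose, with plating efficiency from 0-dose controls.

    ``records`` needs columns ``dose_gy``, ``colonies``, ``seeded`` (an
    optional ``replicate`` column is carried through).  If
    ``plating_efficiency`` is not given it is pooled from the 0-dose rows.
    Colony counts may be non-integral (e.g. expected counts of a noise-free
    synthetic curve).
    """

    records: pd.DataFrame
    plating_efficiency: float | None = None

    def __post_init__(self) -> None:
        df = self.records
        required = {"dose_gy", "colonies", "seeded"}
        if not required.issubset(df.columns):
            raise ValueError(
                f"clonogenic records need columns {sorted(required)}, got {list(df.columns)}"
            )
        if df.empty:
            raise ValueError("clonogenic dataset is empty")
        if (df["dose_gy"] < 0).any():
            raise ValueError("doses must be non-negative")
        if (df["colonies"] < 0).any() or (df["seeded"] <= 0).any():
            raise ValueError("colony/seeded counts must be valid counts")
        if (df["colonies"] > df["seeded"]).any():
            raise ValueError("colonies cannot exceed seeded cells")
        if self.plating_efficiency is None:
            controls = df[df["dose_gy"] == 0.0]
            if controls.empty:
                raise ValueError(
                    "no 0-dose control wells and no plating efficiency supplied"
                )
            self.plating_efficiency = float(
                controls["colonies"].sum() / controls["seeded"].sum()
            )
        if not (0.0 < self.plating_efficiency <= 1.0):
            raise ValueError(
                f"plating efficiency {self.plating_efficiency} outside (0, 1]"
            )

    def surviving_fractions(self) -> pd.DataFrame:
        """Per-well surviving fractions for the irradiated (dose > 0) wells."""
        df = self.records[self.records["dose_gy"] > 0.0].copy()
        sf, se = zip(
            *(
                surviving_fraction(r.colonies, r.seeded, self.plating_efficiency)
                for r in df.itertuples()
            )
        )
        df["sf"] = sf
        df["sf_se"] = se
        return df


@dataclass(frozen=True)
class SurvivalFit:
    """Fitted survival curve.

    When ``alpha_at_bound`` is set, alpha was pinned at 0 by the
    non-negativity constraint and ``alpha_se`` is the profile ("as-if-free")
    standard error, bounding alpha from above rather than giving a symmetric
    interval.
    """

    model: str  # "lq" | "linear"
    alpha: float
    alpha_se: float
    beta: float | None
    beta_se: float | None
    covariance: np.ndarray | None = field(repr=False, default=None)
    r_squared: float = float("nan")
    alpha_at_bound: bool = False
    n_points: int = 0
    dof: int = 0
    objective: str = "poisson"
    pe_hat: float | None = None

    def sf(self, dose_gy):
        """Model surviving fraction at the given dose(s)."""
        beta = self.beta or 0.0
        d = np.asarray(dose_gy, dtype=float)
        return np.exp(-self.alpha * d - beta * d * d)


def surviving_fraction(colonies: float, seeded: float, pe: float) -> tuple[float, float]:
    """Surviving fraction and its binomial standard error.

    SF = colonies / (seeded * pe); the SE propagates the binomial sampling
    variance of the colony count: sqrt(p(1-p)/seeded)/pe with p = colonies/seeded.
    """
    if seeded <= 0:
        raise ValueError("seeded must be positive")
    if colonies < 0 or colonies > seeded:
        raise ValueError("colonies must lie in [0, seeded]")
    if not (0.0 < pe <= 1.0):
        raise ValueError(f"plating efficiency {pe} outside (0, 1]")
    p = colonies / seeded
    sf = p / pe
    se = math.sqrt(p * (1.0 - p) / seeded) / pe
    return sf, se


# ---------------------------------------------------------------------------
# fitting


def _check_design(doses: np.ndarray, model: str) -> None:
    n_distinct = np.unique(doses[doses > 0]).size
    need = 3 if model == "lq" else 2
    if n_distinct < need:
        raise ValueError(f"{model} fit needs >= {need} distinct doses, got {n_distinct}")


def _fit_poisson(data: ClonogenicDataset, model: str) -> SurvivalFit:
    df = data.records
    d = df["dose_gy"].to_numpy(dtype=float)
    c = df["colonies"].to_numpy(dtype=float)
    n = df["seeded"].to_numpy(dtype=float)
    _check_design(d, model)
    if not (c[d > 0] > 0).any():
        raise ValueError("all irradiated wells have zero colonies; survival is unresolved")
    # design: log mu = log n + t0 - alpha d (- beta d^2); t0 = ln(pe)
    cols = [np.ones_like(d), -d] + ([-d * d] if model == "lq" else [])
    X = np.column_stack(cols)
    offset = np.log(n)

    def nll(p):
        logmu = offset + X @ p
        return float(np.sum(np.exp(logmu) - c * logmu))

    p0 = np.array([np.log(data.plating_efficiency), 0.1] + ([0.01] if model == "lq" else []))
    bounds = [(None, 0.0)] + [(0.0, None)] * (X.shape[1] - 1)
    res = optimize.minimize(
        nll, p0, method="L-BFGS-B", bounds=bounds,
        options={"ftol": 1e-15, "gtol": 1e-12, "maxiter": 1000},
    )
    if not res.success and "REACHED LIMIT" not in str(res.message).upper():
        raise RuntimeError(f"Poisson survival fit failed to converge: {res.message}")
    p = res.x
    # Fisher-scoring polish for parameters strictly inside the bounds
    for _ in range(100):
        mu = np.exp(offset + X @ p)
        free = np.array([True] + [p[i] > 1e-12 for i in range(1, p.size)])
        Xf = X[:, free]
        try:
            step = np.linalg.solve(Xf.T @ (Xf * mu[:, None]), Xf.T @ (c - mu))
        except np.linalg.LinAlgError:
            raise ValueError("singular design in survival fit") from None
        p[free] += step
        p[0] = min(p[0], 0.0)
        p[1:] = np.maximum(p[1:], 0.0)
        if np.max(np.abs(step)) < 1e-13:
            break
    mu = np.exp(offset + X @ p)
    fisher = X.T @ (X * mu[:, None])
    try:
        cov_full = np.linalg.inv(fisher)
    except np.linalg.LinAlgError:
        raise ValueError("singular design in survival fit") from None
    at_bound = [False] + [bool(p[i] <= 1e-12) for i in range(1, p.size)]
    se = np.sqrt(np.diag(cov_full))
    dof = max(len(c) - X.shape[1], 1)
    alpha = float(p[1])
    beta = float(p[2]) if model == "lq" else None
    r2 = _log_domain_r2(data, alpha, beta)
    return SurvivalFit(
        model=model,
        alpha=alpha,
        alpha_se=float(se[1]),
        beta=beta,
        beta_se=float(se[2]) if model == "lq" else None,
        covariance=cov_full[1:, 1:],
        r_squared=r2,
        alpha_at_bound=at_bound[1],
        n_points=len(c),
        dof=dof,
        objective="poisson",
        pe_hat=float(np.exp(p[0])),
    )


def _lsq_loglinear(
    doses: np.ndarray, y: np.ndarray, model: str, objective_label: str
) -> SurvivalFit:
    """Constrained linear least squares of y = alpha*d (+ beta*d^2)."""
    X = doses[:, None] if model == "linear" else np.column_stack([doses, doses**2])
    res = optimize.lsq_linear(X, y, bounds=(0.0, np.inf))
    theta = res.x
    at_bound = [bool(abs(v) < 1e-12) for v in theta]
    free = [not b for b in at_bound]
    k_free = sum(free)
    dof = max(X.shape[0] - max(k_free, 1), 1)
    resid = y - X @ theta
    s2 = float(resid @ resid) / dof
    try:
        cov_all = s2 * np.linalg.inv(X.T @ X)
    except np.linalg.LinAlgError:
        raise ValueError("singular design in survival fit") from None
    cov = cov_all.copy()
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else float("nan")
    alpha = float(theta[0])
    se = np.sqrt(np.diag(cov_all))  # profile-style at bounds: as-if-free
    return SurvivalFit(
        model=model,
        alpha=alpha,
        alpha_se=float(se[0]),
        beta=float(theta[1]) if model == "lq" else None,
        beta_se=float(se[1]) if model == "lq" else None,
        covariance=cov,
        r_squared=r2,
        alpha_at_bound=at_bound[0],
        n_points=X.shape[0],
        dof=dof,
        objective=objective_label,
    )


def fit_survival(
    data: ClonogenicDataset, model: str = "lq", objective: str = "poisson"
) -> SurvivalFit:
    """Fit SF(D) = exp(-alpha D [- beta D^2]) to a clonogenic dataset.

    All replicate wells enter jointly (no per-dose averaging).  With the
    default Poisson objective zero-colony wells contribute through the
    likelihood; with ``objective="lsq"`` they have no finite log-survival and
    are excluded with a logged warning.
    """
    if model not in ("lq", "linear"):
        raise ValueError("model must be 'lq' or 'linear'")
    if objective == "poisson":
        return _fit_poisson(data, model)
    if objective != "lsq":
        raise ValueError("objective must be 'poisson' or 'lsq'")
    df = data.surviving_fractions()
    zero = df["sf"] == 0.0
    if zero.any():
        logger.warning(
            "excluding %d zero-colony well(s) from log-domain fit", int(zero.sum())
        )
        df = df[~zero]
    if df.empty:
        raise ValueError("all surviving fractions are zero; cannot fit in log domain")
    doses = df["dose_gy"].to_numpy(dtype=float)
    _check_design(doses, model)
    y = -np.log(df["sf"].to_numpy(dtype=float))
    return _lsq_loglinear(doses, y, model, "lsq")


def fit_sf_curve(
    dose_gy: np.ndarray, sf: np.ndarray, model: str = "lq"
) -> SurvivalFit:
    """Fit the survival model to (dose, surviving fraction) pairs directly.

    For published survival-curve points where the underlying colony counts
    are unavailable; unweighted least squares on -ln SF.
    """
    d = np.asarray(dose_gy, dtype=float)
    s = np.asarray(sf, dtype=float)
    if d.size != s.size or d.size == 0:
        raise ValueError("dose and SF arrays must match and be non-empty")
    if (s <= 0).any() or (s > 1).any():
        raise ValueError("surviving fractions must lie in (0, 1]")
    _check_design(d, model)
    return _lsq_loglinear(d, -np.log(s), model, "lsq")


def _log_domain_r2(data: ClonogenicDataset, alpha: float, beta: float | None) -> float:
    df = data.surviving_fractions()
    df = df[df["sf"] > 0.0]
    if df.empty:
        return float("nan")
    d = df["dose_gy"].to_numpy(dtype=float)
    y = -np.log(df["sf"].to_numpy(dtype=float))
    yhat = alpha * d + (beta or 0.0) * d * d
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return float("nan")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


def confidence_interval(
    fit: SurvivalFit, param: str, level: float = 0.95
) -> tuple[float, float]:
    """Two-sided t-based confidence interval for 'alpha' or 'beta'."""
    if param == "alpha":
        est, se = fit.alpha, fit.alpha_se
    elif param == "beta":
        if fit.beta is None:
            raise ValueError("linear fit has no beta")
        est, se = fit.beta, fit.beta_se
    else:
        raise ValueError("param must be 'alpha' or 'beta'")
    tq = stats.t.ppf(0.5 + level / 2.0, fit.dof)
    return est - tq * se, est + tq * se


# ---------------------------------------------------------------------------
# derived quantities


def dose_at_survival(fit: SurvivalFit, s_target: float) -> float:
    """Dose (Gy) at which the fitted curve reaches survival ``s_target``.

    Solves alpha*D + beta*D^2 = -ln(s_target), taking the positive root.
    """
    if not (0.0 < s_target <= 1.0):
        raise ValueError("survival target must be in (0, 1]")
    level = -math.log(s_target)
    if level == 0.0:
        return 0.0
    alpha = fit.alpha
    beta = fit.beta or 0.0
    if alpha == 0.0 and beta == 0.0:
        raise ValueError("flat survival curve (alpha = beta = 0); dose undefined")
    # cancellation-free positive root of beta D^2 + alpha D - level = 0
    return 2.0 * level / (alpha + math.sqrt(alpha * alpha + 4.0 * beta * level))


def rbe(d_reference: float, d_test: float) -> float:
    """Relative biological effectiveness: reference dose over test dose at the
    same survival endpoint (RBE > 1: test radiation more effective per Gy)."""
    if d_reference <= 0.0 or d_test <= 0.0:
        raise ValueError("doses must be positive")
    return d_reference / d_test


def alpha_beta_ratio(fit: SurvivalFit) -> tuple[float, float]:
    """alpha/beta ratio (Gy) with first-order (delta-method) standard error.

    A fit with alpha pinned at 0 returns (0, 0); beta = 0 gives an unbounded
    ratio, returned as (inf, nan).
    """
    if fit.model != "lq" or fit.beta is None:
        raise ValueError("alpha/beta ratio requires an LQ fit")
    if fit.alpha_at_bound or fit.alpha == 0.0:
        return 0.0, 0.0
    if fit.beta == 0.0:
        warnings.warn("beta = 0: alpha/beta ratio is unbounded", RuntimeWarning)
        return math.inf, math.nan
    ratio = fit.alpha / fit.beta
    var_a = fit.covariance[0, 0]
    var_b = fit.covariance[1, 1]
    cov_ab = fit.covariance[0, 1]
    if np.isnan(var_a) or np.isnan(var_b):
        return ratio, float("nan")
    var = (
        var_a / fit.beta**2
        + (fit.alpha**2 / fit.beta**4) * var_b
        - 2.0 * (fit.alpha / fit.beta**3) * cov_ab
    )
    return ratio, math.sqrt(max(var, 0.0))
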