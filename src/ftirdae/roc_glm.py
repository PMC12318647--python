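"""Covariate-adjusted binormal ROC regression (ROC-GLM).

The ROC curve of a marker is modelled on the probit scale as

    Phi^-1( ROC(t | X) ) = a + b * Phi^-1(t) + beta0 * X + beta1 * X * Phi^-1(t)

where ``t`` is the false-positive rate, ``Phi`` the standard normal CDF,
``(a, b)`` the classical binormal baseline, and each covariate X shifts the
curve's intercept (beta0) and slope (beta1).  Estimation is the standard
semiparametric placement-value construction: each case score is converted to
its placement value (the fraction of controls scoring at least as high, ties
counted one half), the binary indicators ``U_ij = 1{PV_i <= t_j}`` over an
fpr grid are regressed with a probit link, and uncertainty comes from
bootstrap resampling of cases and controls separately, with Wald tests on
the bootstrap standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
import statsmodels.api as sm

from .classification import RocCurve

__all__ = [
    "RocGlmSpec",
    "RocGlmFit",
    "placement_values",
    "fit_roc_glm",
    "bootstrap_fit",
    "wald_tests",
    "stage_contrasts",
    "predict_roc",
]


def _default_fpr_grid() -> np.ndarray:
    return np.linspace(0.05, 0.95, 19)


@dataclass
class RocGlmSpec:
    """Grid, baseline parameterization h(t) = a + b*Phi^-1(t), probit link."""

    fpr_grid: np.ndarray = field(default_factory=_default_fpr_grid)
    link: str = "probit"

    def __post_init__(self) -> None:
        grid = np.asarray(self.fpr_grid, dtype=float)
        if grid.ndim != 1 or grid.size < 2:
            raise ValueError("fpr_grid needs at least 2 points")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("fpr_grid must be strictly increasing")
        if grid[0] <= 0 or grid[-1] >= 1:
            raise ValueError("fpr_grid values must lie strictly inside (0, 1)")
        if self.link != "probit":
            raise ValueError("only the probit link is supported")
        self.fpr_grid = grid


@dataclass
class RocGlmFit:
    estimates: pd.Series  # intercept (a), probit_t (b), beta0s, beta1s
    spec: RocGlmSpec
    covariate_names: list
    converged: bool
    draws: np.ndarray | None = None  # (B, n_params) bootstrap draws
    se: pd.Series | None = None
    B: int = 0
    seed: int | None = None
    n_cases: int = 0
    n_controls: int = 0

    @property
    def a(self) -> float:
        return float(self.estimates["intercept"])

    @property
    def b(self) -> float:
        return float(self.estimates["probit_t"])


def placement_values(case_scores: np.ndarray, control_scores: np.ndarray) -> np.ndarray:
    """Survivor-function placement of each case among the controls.

    PV_i = (#controls > s_i + 0.5 * #controls == s_i) / n_controls; a case
    scoring above every control has PV 0.
    """
    cases = np.asarray(case_scores, dtype=float)
    controls = np.sort(np.asarray(control_scores, dtype=float))
    if controls.size < 2:
        raise ValueError("placement values need at least 2 controls")
    n = controls.size
    # counts via binary search on the sorted controls
    n_le = np.searchsorted(controls, cases, side="right")
    n_lt = np.searchsorted(controls, cases, side="left")
    n_gt = n - n_le
    n_eq = n_le - n_lt
    return (n_gt + 0.5 * n_eq) / n


def _expand_covariates(covariates: pd.DataFrame | None, index_len: int):
    """Numeric columns pass through; 'stage' (categorical) is dummy-coded
    with stage I as the reference level."""
    if covariates is None or covariates.shape[1] == 0:
        return np.empty((index_len, 0)), []
    cols = []
    names = []
    for name in covariates.columns:
        col = covariates[name]
        if col.dtype == object or str(col.dtype) in ("string", "category"):
            levels = [l for l in ("II", "III", "IV") if (col == l).any()] if name == "stage" \
                else sorted(set(col.dropna()))[1:]
            for level in levels:
                cols.append((col == level).to_numpy(dtype=float))
                names.append(f"{name}[{level}]")
        else:
            cols.append(col.to_numpy(dtype=float))
            names.append(name)
    x = np.column_stack(cols) if cols else np.empty((index_len, 0))
    if not np.all(np.isfinite(x)):
        raise ValueError("covariates must be observed (finite) for all cases")
    return x, names


def _design(pv: np.ndarray, x: np.ndarray, names: list, grid: np.ndarray):
    q = norm.ppf(grid)  # Phi^-1(t_j)
    n_cases = pv.size
    n_grid = grid.size
    u = (pv[:, None] <= grid[None, :]).astype(float).ravel()
    q_rep = np.tile(q, n_cases)
    blocks = [np.ones(n_cases * n_grid), q_rep]
    colnames = ["intercept", "probit_t"]
    for k, name in enumerate(names):
        xk = np.repeat(x[:, k], n_grid)
        blocks.append(xk)
        colnames.append(name)
    for k, name in enumerate(names):
        xk = np.repeat(x[:, k], n_grid)
        blocks.append(xk * q_rep)
        colnames.append(f"{name}:probit_t")
    return u, np.column_stack(blocks), colnames


def fit_roc_glm(
    scores: np.ndarray,
    labels: np.ndarray,
    covariates: pd.DataFrame | None = None,
    spec: RocGlmSpec | None = None,
) -> RocGlmFit:
    """Fit the ROC-GLM by placement-value probit regression on the fpr grid.

    ``covariates`` holds one row per *case* (aligned with the case rows of
    ``scores``/``labels``) — the ROC-GLM conditions on case covariates.
    """
    spec = spec or RocGlmSpec()
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    case_mask = labels == 1
    if case_mask.sum() == 0 or (~case_mask).sum() == 0:
        raise ValueError("both classes must be present")
    pv = placement_values(scores[case_mask], scores[~case_mask])
    if covariates is not None and len(covariates) != int(case_mask.sum()):
        raise ValueError("covariates must have one row per case")
    x, names = _expand_covariates(covariates, pv.size)
    u, design, colnames = _design(pv, x, names, spec.fpr_grid)
    model = sm.GLM(u, design, family=sm.families.Binomial(link=sm.families.links.Probit()))
    try:
        res = model.fit(maxiter=200)
        converged = bool(getattr(res, "converged", True))
        params = res.params
    except Exception as exc:  # separation / singular design
        raise RuntimeError(f"ROC-GLM fit failed: {exc}") from exc
    estimates = pd.Series(params, index=colnames)
    fit = RocGlmFit(
        estimates=estimates,
        spec=spec,
        covariate_names=names,
        converged=converged,
        n_cases=int(case_mask.sum()),
        n_controls=int((~case_mask).sum()),
    )
    return fit


def bootstrap_fit(
    scores: np.ndarray,
    labels: np.ndarray,
    covariates: pd.DataFrame | None = None,
    spec: RocGlmSpec | None = None,
    B: int = 1000,
    seed: int = 0,
    max_failed_fraction: float = 0.2,
) -> RocGlmFit:
    """ROC-GLM with bootstrap uncertainty.

    Cases and controls are resampled independently with replacement (each
    case keeps its covariates); ``se`` is the standard deviation of the
    bootstrap draws.  Errors if more than ``max_failed_fraction`` of the
    draws fail to converge.
    """
    if B < 2:
        raise ValueError("need at least 2 bootstrap draws")
    spec = spec or RocGlmSpec()
    fit = fit_roc_glm(scores, labels, covariates, spec)
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    case_idx = np.flatnonzero(labels == 1)
    ctrl_idx = np.flatnonzero(labels != 1)
    rng = np.random.default_rng(seed)
    draws = np.full((B, fit.estimates.size), np.nan)
    n_failed = 0
    for rep in range(B):
        rc = rng.choice(case_idx, size=case_idx.size, replace=True)
        rn = rng.choice(ctrl_idx, size=ctrl_idx.size, replace=True)
        idx = np.concatenate([rc, rn])
        boot_labels = np.concatenate([np.ones(rc.size, int), np.zeros(rn.size, int)])
        boot_cov = None
        if covariates is not None:
            pos = {g: i for i, g in enumerate(case_idx)}
            boot_cov = covariates.iloc[[pos[g] for g in rc]].reset_index(drop=True)
        try:
            boot = fit_roc_glm(scores[idx], boot_labels, boot_cov, spec)
            if not boot.converged:
                raise RuntimeError("non-converged")
            draws[rep] = boot.estimates.to_numpy()
        except Exception:
            n_failed += 1
    if n_failed > max_failed_fraction * B:
        raise RuntimeError(
            f"{n_failed}/{B} bootstrap refits failed to converge"
        )
    ok = ~np.isnan(draws).any(axis=1)
    se = pd.Series(draws[ok].std(axis=0, ddof=1), index=fit.estimates.index)
    fit.draws = draws[ok]
    fit.se = se
    fit.B = B
    fit.seed = seed
    return fit


def wald_tests(fit: RocGlmFit, contrasts: list) -> pd.DataFrame:
    """Wald z-tests of parameter contrasts against zero.

    Each contrast is ``(label, {param_name: weight, ...})``; the contrast's
    standard error is taken from the bootstrap draws (sd of the contrast
    across draws).  Zero-variance contrasts are flagged undefined.
    """
    if fit.draws is None or fit.se is None:
        raise ValueError("wald_tests requires a bootstrap fit (se available)")
    rows = []
    names = list(fit.estimates.index)
    for label, weights in contrasts:
        c = np.zeros(len(names))
        for pname, w in weights.items():
            c[names.index(pname)] = w
        estimate = float(c @ fit.estimates.to_numpy())
        se = float(np.std(fit.draws @ c, ddof=1))
        if se == 0:
            rows.append(
                {"contrast": label, "estimate": estimate, "se": 0.0,
                 "z": np.nan, "p": np.nan, "undefined": True}
            )
            continue
        z = estimate / se
        rows.append(
            {"contrast": label, "estimate": estimate, "se": se, "z": z,
             "p": float(2 * norm.sf(abs(z))), "undefined": False}
        )
    return pd.DataFrame(rows)


def stage_contrasts(fit: RocGlmFit, term: str = "intercept") -> list:
    """Pairwise stage contrasts (I vs II ... III vs IV) on the intercept
    (beta0) or slope (beta1) covariate effects, stage I being the reference."""
    suffix = "" if term == "intercept" else ":probit_t"
    present = [
        lvl for lvl in ("II", "III", "IV") if f"stage[{lvl}]{suffix}" in fit.estimates.index
    ]
    levels = ["I"] + present
    out = []
    for i, la in enumerate(levels):
        for lb in levels[i + 1 :]:
            weights = {}
            if la != "I":
                weights[f"stage[{la}]{suffix}"] = 1.0
            weights[f"stage[{lb}]{suffix}"] = weights.get(f"stage[{lb}]{suffix}", 0.0) - 1.0
            out.append((f"{la} vs. {lb} ({term})", weights))
    return out


def predict_roc(
    fit: RocGlmFit | None = None,
    covariate_value: dict | None = None,
    t_grid: np.ndarray | None = None,
    a: float | None = None,
    b: float | None = None,
) -> RocCurve:
    """Evaluate ROC(t | X) = Phi(a + b*Phi^-1(t) + beta0*X + beta1*X*Phi^-1(t)).

    Pass a fitted model plus covariate values, or raw ``(a, b)`` baseline
    parameters.  The AUC is the trapezoidal area over ``t_grid``.
    """
    if t_grid is None:
        t_grid = np.linspace(1e-4, 1 - 1e-4, 10_001)
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(t_grid <= 0) or np.any(t_grid >= 1):
        raise ValueError("t values must lie strictly inside (0, 1)")
    if fit is not None:
        a_val, b_val = fit.a, fit.b
        shift, slope_shift = 0.0, 0.0
        for name, value in (covariate_value or {}).items():
            shift += float(fit.estimates[name]) * value
            inter = f"{name}:probit_t"
            if inter in fit.estimates.index:
                slope_shift += float(fit.estimates[inter]) * value
    else:
        if a is None or b is None:
            raise ValueError("either fit or (a, b) must be given")
        a_val, b_val, shift, slope_shift = float(a), float(b), 0.0, 0.0
    q = norm.ppf(t_grid)
    tpr = np.clip(norm.cdf(a_val + shift + (b_val + slope_shift) * q), 0.0, 1.0)
    # close the curve at (0,0) and (1,1) for the area
    fpr_full = np.concatenate([[0.0], t_grid, [1.0]])
    tpr_full = np.concatenate([[0.0], tpr, [1.0]])
    auc = float(np.trapezoid(tpr_full, fpr_full))
    return RocCurve(fpr=t_grid, tpr=tpr, auc=auc)
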