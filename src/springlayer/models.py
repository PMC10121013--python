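"""Serial-spring compliance models.

Two model families are fitted to the per-trial feature table:

* ``physics`` — zero-intercept regression of compliance on muscle and fat
  thickness.  The coefficients are the layer inverse moduli 1/E_m and
  1/E_f (mm^2/N, numerically equal to 1/MPa), because springs in series
  add compliances: A/k = t_m/E_m + t_f/E_f.
* ``conventional`` — the same regression with a free intercept, used as a
  sensitivity check on forcing the fit through the origin.

Each family comes in two scopes: ``location_specific`` (ordinary least
squares within one site) and ``combined`` (all sites pooled, with crossed
zero-mean random intercepts for subject and location estimated by REML).

The restricted likelihood is evaluated through the low-rank structure of
V = sigma_e^2 I + sigma_s^2 Z_s Z_s' + sigma_l^2 Z_l Z_l' (Woodbury
identity on the random-effect design), so a full study fits in
milliseconds.  Variance components are optimised as log variance ratios
with a small multi-start to be robust at the zero-variance boundary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from springlayer.errors import EstimationError, UsageError
from springlayer.sites import validate_site

logger = logging.getLogger(__name__)

Family = Literal["physics", "conventional"]

_RATIO_FLOOR = 1e-8  # variance ratios below this are reported as exactly 0
_LOG_RATIO_BOUND = 25.0


@dataclass(frozen=True)
class ModelSpec:
    """Which model to fit: family, scope, and how to predict from it."""

    family: Family = "physics"
    scope: str = "combined"  # "combined" or one of the 8 site codes
    prediction_mode: Literal["fixed_only", "conditional"] = "fixed_only"

    def __post_init__(self) -> None:
        if self.family not in ("physics", "conventional"):
            raise ValueError(f"unknown model family {self.family!r}")
        if self.scope != "combined":
            validate_site(self.scope)
        if self.prediction_mode not in ("fixed_only", "conditional"):
            raise ValueError(f"unknown prediction mode {self.prediction_mode!r}")

    @property
    def include_intercept(self) -> bool:
        """Physics models are forced through the origin; conventional ones are not."""
        return self.family == "conventional"

    @property
    def is_combined(self) -> bool:
        return self.scope == "combined"


@dataclass
class SpringFit:
    """A fitted compliance model.

    ``coef``/``se``/``p``/``stars`` are keyed by term (``muscle``, ``fat``
    and, for conventional models, ``intercept``).  Thickness coefficients
    are inverse moduli in mm^2/N (equivalently 1/MPa); the intercept is in
    mm^3/N.  Combined fits additionally carry REML variance components
    (mm^6/N^2), per-level BLUPs (mm^3/N) and the restricted log-likelihood
    at the optimum.
    """

    spec: ModelSpec
    coef: dict[str, float]
    se: dict[str, float]
    p: dict[str, float]
    stars: dict[str, str]
    n_obs: int
    variance_components: dict[str, float] | None = None
    random_effects: dict[str, dict[str, float]] | None = None
    reml_value: float | None = None
    converged: bool = True
    optimizer_info: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "family": self.spec.family,
            "scope": self.spec.scope,
            "coef": self.coef,
            "se": self.se,
            "p": self.p,
            "stars": self.stars,
            "n_obs": self.n_obs,
            "variance_components": self.variance_components,
            "random_effects": self.random_effects,
            "reml_value": self.reml_value,
            "converged": self.converged,
            "optimizer_info": {
                k: v for k, v in self.optimizer_info.items() if not isinstance(v, np.ndarray)
            },
            "units_note": (
                "thickness coefficients in mm^2/N (= 1/MPa, inverse modulus); "
                "also reportable as mm^3/N per mm of thickness; intercept in mm^3/N"
            ),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SpringFit":
        return cls(
            spec=ModelSpec(family=d["family"], scope=d["scope"]),
            coef=dict(d["coef"]),
            se=dict(d["se"]),
            p=dict(d["p"]),
            stars=dict(d["stars"]),
            n_obs=int(d["n_obs"]),
            variance_components=dict(d["variance_components"])
            if d.get("variance_components")
            else None,
            random_effects={k: dict(v) for k, v in d["random_effects"].items()}
            if d.get("random_effects")
            else None,
            reml_value=d.get("reml_value"),
            converged=bool(d.get("converged", True)),
        )


def significance_stars(p: float) -> str:
    """Star label for a p-value: *** < 0.001, ** < 0.01, * < 0.05, else none."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value must be in [0, 1], got {p}")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _design(features: pd.DataFrame, include_intercept: bool) -> tuple[np.ndarray, list[str]]:
    cols = [features["t_muscle_mm"].to_numpy(float), features["t_fat_mm"].to_numpy(float)]
    names = ["muscle", "fat"]
    if include_intercept:
        cols.insert(0, np.ones(len(features)))
        names.insert(0, "intercept")
    return np.column_stack(cols), names


def fit_location_specific(features: pd.DataFrame, spec: ModelSpec) -> SpringFit:
    """Ordinary least squares for one site (through the origin for physics)."""
    if spec.is_combined:
        raise UsageError("spec.scope must be a site code for a location-specific fit")
    sub = features[features["site"] == spec.scope]
    X, names = _design(sub, spec.include_intercept)
    y = sub["compliance_mm3_per_N"].to_numpy(float)
    n, p = X.shape
    if n <= p:
        raise EstimationError(
            f"site {spec.scope}: n={n} observations cannot identify {p} "
            f"coefficients with residual degrees of freedom"
        )
    if np.linalg.matrix_rank(X) < p:
        raise EstimationError(f"site {spec.scope}: rank-deficient design matrix")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = n - p
    s2 = float(resid @ resid) / df
    cov = s2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf)
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    coef = dict(zip(names, map(float, beta)))
    return SpringFit(
        spec=spec,
        coef=coef,
        se=dict(zip(names, map(float, se))),
        p=dict(zip(names, map(float, pvals))),
        stars={k: significance_stars(v) for k, v in zip(names, pvals)},
        n_obs=n,
    )


# ---------------------------------------------------------------------------
# mixed model machinery


def _indicator(labels: Sequence) -> tuple[np.ndarray, list]:
    levels = list(dict.fromkeys(labels))  # first-appearance order
    index = {lv: j for j, lv in enumerate(levels)}
    Z = np.zeros((len(labels), len(levels)))
    Z[np.arange(len(labels)), [index[lv] for lv in labels]] = 1.0
    return Z, levels


def reml_objective(
    variance_components: Sequence[float],
    X: np.ndarray,
    Z_subject: np.ndarray,
    Z_location: np.ndarray,
    y: np.ndarray,
) -> float:
    """Restricted log-likelihood at (sigma2_subject, sigma2_location, sigma2_resid).

    Fixed effects are profiled out by generalized least squares.  Evaluated
    through the Woodbury identity on the stacked random-effect design, so
    the cost is cubic in the number of random-effect levels, not in n.
    """
    s2_s, s2_l, s2_e = (float(v) for v in variance_components)
    if s2_s < 0 or s2_l < 0 or s2_e < 0:
        raise ValueError("variance components must be >= 0")
    if s2_e == 0.0:
        raise np.linalg.LinAlgError(
            "V is singular: residual variance is 0 (infinite condition number)"
        )
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    n, p = X.shape

    blocks = []
    gammas = []
    if s2_s > 0:
        blocks.append(np.asarray(Z_subject, float))
        gammas.append(s2_s / s2_e)
    if s2_l > 0:
        blocks.append(np.asarray(Z_location, float))
        gammas.append(s2_l / s2_e)

    if blocks:
        U = np.hstack(blocks)
        d = np.concatenate(
            [np.full(b.shape[1], g) for b, g in zip(blocks, gammas)]
        )
        # W = I + U diag(d) U'; W^{-1} a = a - U C^{-1} U'a with C = diag(1/d) + U'U
        G = U.T @ U
        C = G + np.diag(1.0 / d)
        try:
            cf = np.linalg.cholesky(C)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"V is numerically singular (cond of inner capacitance matrix "
                f"~{np.linalg.cond(C):.2e})"
            ) from exc
        UtX = U.T @ X
        Uty = U.T @ y
        sol_X = np.linalg.solve(C, UtX)
        sol_y = np.linalg.solve(C, Uty)
        XtWiX = X.T @ X - UtX.T @ sol_X
        XtWiy = X.T @ y - UtX.T @ sol_y
        ytWiy = float(y @ y - Uty @ sol_y)
        # log|W| = log|C| + sum log d
        logdet_W = 2.0 * float(np.sum(np.log(np.diag(cf)))) + float(np.sum(np.log(d)))
    else:
        XtWiX = X.T @ X
        XtWiy = X.T @ y
        ytWiy = float(y @ y)
        logdet_W = 0.0

    try:
        beta = np.linalg.solve(XtWiX, XtWiy)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("X' V^{-1} X is singular") from exc
    quad = ytWiy - 2.0 * float(beta @ XtWiy) + float(beta @ XtWiX @ beta)
    quad = max(quad, 0.0)
    sign, logdet_XtWiX = np.linalg.slogdet(XtWiX)
    if sign <= 0:
        raise np.linalg.LinAlgError("X' V^{-1} X is not positive definite")
    # V = s2_e W; assemble the restricted log-likelihood on the V scale
    logdet_V = n * np.log(s2_e) + logdet_W
    logdet_XtViX = logdet_XtWiX - p * np.log(s2_e)
    return float(
        -0.5 * ((n - p) * np.log(2.0 * np.pi) + logdet_V + logdet_XtViX + quad / s2_e)
    )


class _ProfiledREML:
    """Profiled restricted likelihood over (log gamma_subject, log gamma_location).

    gamma = sigma2_component / sigma2_resid; the residual variance and the
    fixed effects are profiled out in closed form.  All data-dependent
    cross-products are precomputed once.
    """

    def __init__(self, X: np.ndarray, Z_s: np.ndarray, Z_l: np.ndarray, y: np.ndarray):
        self.X, self.y = X, y
        self.n, self.p = X.shape
        self.q_s, self.q_l = Z_s.shape[1], Z_l.shape[1]
        U = np.hstack([Z_s, Z_l])
        self.U = U
        self.G = U.T @ U
        self.UtX = U.T @ X
        self.Uty = U.T @ y
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

    def _core(self, gamma_s: float, gamma_l: float):
        d = np.concatenate(
            [np.full(self.q_s, gamma_s), np.full(self.q_l, gamma_l)]
        )
        active = d > 0
        if active.any():
            Ga = self.G[np.ix_(active, active)]
            C = Ga + np.diag(1.0 / d[active])
            cf = np.linalg.cholesky(C)
            UtXa, Utya = self.UtX[active], self.Uty[active]
            sol_X = np.linalg.solve(C, UtXa)
            sol_y = np.linalg.solve(C, Utya)
            XtWiX = self.XtX - UtXa.T @ sol_X
            XtWiy = self.Xty - UtXa.T @ sol_y
            ytWiy = self.yty - float(Utya @ sol_y)
            logdet_W = 2.0 * float(np.sum(np.log(np.diag(cf)))) + float(
                np.sum(np.log(d[active]))
            )
        else:
            XtWiX, XtWiy, ytWiy, logdet_W = self.XtX, self.Xty, self.yty, 0.0
        beta = np.linalg.solve(XtWiX, XtWiy)
        quad = ytWiy - 2.0 * float(beta @ XtWiy) + float(beta @ XtWiX @ beta)
        quad = max(quad, 1e-300)
        return beta, XtWiX, quad, logdet_W

    def loglik(self, theta: np.ndarray) -> float:
        """Profiled restricted log-likelihood at theta = log variance ratios."""
        g_s, g_l = np.exp(np.clip(theta, -_LOG_RATIO_BOUND, _LOG_RATIO_BOUND))
        _, XtWiX, quad, logdet_W = self._core(g_s, g_l)
        n, p = self.n, self.p
        s2_e = quad / (n - p)
        sign, logdet_XtWiX = np.linalg.slogdet(XtWiX)
        if sign <= 0:
            return -np.inf
        return float(
            -0.5
            * (
                (n - p) * (np.log(2.0 * np.pi) + np.log(s2_e) + 1.0)
                + logdet_W
                + logdet_XtWiX
            )
        )

    def solution(self, theta: np.ndarray):
        """Full solution (beta, cov_beta, variance components, BLUPs) at theta."""
        g_s = float(np.exp(np.clip(theta[0], -_LOG_RATIO_BOUND, _LOG_RATIO_BOUND)))
        g_l = float(np.exp(np.clip(theta[1], -_LOG_RATIO_BOUND, _LOG_RATIO_BOUND)))
        if g_s < _RATIO_FLOOR:
            g_s = 0.0
        if g_l < _RATIO_FLOOR:
            g_l = 0.0
        beta, XtWiX, quad, _ = self._core(g_s, g_l)
        s2_e = quad / (self.n - self.p)
        cov_beta = s2_e * np.linalg.inv(XtWiX)
        # BLUPs: u_hat = gamma * Z' W^{-1} (y - X beta)
        r = self.y - self.X @ beta
        Utr = self.U.T @ r
        d = np.concatenate([np.full(self.q_s, g_s), np.full(self.q_l, g_l)])
        active = d > 0
        if active.any():
            C = self.G[np.ix_(active, active)] + np.diag(1.0 / d[active])
            Wir_proj = self.U[:, active] @ np.linalg.solve(C, Utr[active])
            UtWir = self.U.T @ (r - Wir_proj)
        else:
            UtWir = Utr
        blups = d * UtWir
        u = blups[: self.q_s]
        v = blups[self.q_s:]
        return beta, cov_beta, (g_s * s2_e, g_l * s2_e, s2_e), u, v


_DEFAULT_STARTS = (
    (0.0, 0.0),       # variance ratios 1
    (np.log(1e-3), np.log(1e-3)),  # near the zero-variance boundary
    (np.log(10.0), np.log(10.0)),  # random effects dominate
)


def fit_combined(features: pd.DataFrame, spec: ModelSpec) -> SpringFit:
    """REML fit of the crossed random-intercept model over all sites.

    y = X beta + Z_subject u + Z_location v + eps, with u, v, eps
    independent zero-mean normals.  Fixed effects by GLS at the REML
    optimum; Wald (normal) p-values; BLUPs of u and v for conditional
    prediction.
    """
    if not spec.is_combined:
        raise UsageError("spec.scope must be 'combined' for a combined fit")
    X, names = _design(features, spec.include_intercept)
    y = features["compliance_mm3_per_N"].to_numpy(float)
    Z_s, subjects = _indicator(features["subject_id"].tolist())
    Z_l, locations = _indicator(features["site"].tolist())
    n, p = X.shape
    if len(subjects) < 2 or len(locations) < 2:
        raise EstimationError(
            f"combined fit needs >= 2 subjects and >= 2 sites "
            f"(got {len(subjects)} and {len(locations)})"
        )
    if np.linalg.matrix_rank(X) < p:
        raise EstimationError("rank-deficient fixed-effect design matrix")

    prof = _ProfiledREML(X, Z_s, Z_l, y)
    best = None
    trace = []
    for start in _DEFAULT_STARTS:
        res = optimize.minimize(
            lambda th: -prof.loglik(th),
            x0=np.asarray(start, float),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 600},
        )
        trace.append(
            {"start": list(start), "loglik": -float(res.fun), "success": bool(res.success)}
        )
        if best is None or -res.fun > -best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise EstimationError(f"REML optimization failed from all starts: {trace}")
    converged = any(t["success"] for t in trace)
    if not converged:
        raise EstimationError(f"REML did not converge from any start: {trace}")

    beta, cov_beta, (s2_s, s2_l, s2_e), u, v = prof.solution(best.x)
    if s2_s == 0.0 or s2_l == 0.0:
        warnings.warn(
            "a variance component was estimated at the zero boundary "
            f"(sigma2_subject={s2_s:.3g}, sigma2_location={s2_l:.3g})",
            stacklevel=2,
        )
    se = np.sqrt(np.diag(cov_beta))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.inf)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    return SpringFit(
        spec=spec,
        coef=dict(zip(names, map(float, beta))),
        se=dict(zip(names, map(float, se))),
        p=dict(zip(names, map(float, pvals))),
        stars={k: significance_stars(pv) for k, pv in zip(names, pvals)},
        n_obs=n,
        variance_components={
            "sigma2_subject": float(s2_s),
            "sigma2_location": float(s2_l),
            "sigma2_resid": float(s2_e),
        },
        random_effects={
            "subject": dict(zip(subjects, map(float, u))),
            "location": dict(zip(locations, map(float, v))),
        },
        reml_value=float(-best.fun),
        converged=converged,
        optimizer_info={"starts": trace, "theta_opt": [float(t) for t in best.x]},
    )


def fit_model(features: pd.DataFrame, spec: ModelSpec) -> SpringFit:
    """Dispatch to the location-specific or combined fitter."""
    return fit_combined(features, spec) if spec.is_combined else fit_location_specific(features, spec)


def predict_compliance(
    fit: SpringFit, rows: pd.DataFrame, mode: str | None = None
) -> np.ndarray:
    """Predicted compliance (mm^3/N) per feature row.

    ``fixed_only`` evaluates X beta; ``conditional`` (combined fits only)
    adds the subject and location BLUPs, with unseen levels contributing 0.
    """
    mode = mode or fit.spec.prediction_mode
    if mode not in ("fixed_only", "conditional"):
        raise UsageError(f"unknown prediction mode {mode!r}")
    pred = (
        fit.coef["muscle"] * rows["t_muscle_mm"].to_numpy(float)
        + fit.coef["fat"] * rows["t_fat_mm"].to_numpy(float)
        + fit.coef.get("intercept", 0.0)
    )
    if mode == "conditional":
        if not fit.spec.is_combined or fit.random_effects is None:
            raise UsageError("conditional prediction requires a combined (mixed-model) fit")
        subj = fit.random_effects["subject"]
        loc = fit.random_effects["location"]
        pred = (
            pred
            + rows["subject_id"].map(lambda s: subj.get(s, 0.0)).to_numpy(float)
            + rows["site"].map(lambda s: loc.get(s, 0.0)).to_numpy(float)
        )
    return pred


def coefficient_table(fits: Sequence[SpringFit]) -> pd.DataFrame:
    """Report-style table: one column per fit scope, 'coef stars (se)' cells."""
    cols = {}
    for fit in fits:
        label = "Combined" if fit.spec.is_combined else fit.spec.scope
        cols[label] = {
            term.capitalize(): f"{fit.coef[term]:.2f}{fit.stars[term]}({fit.se[term]:.2f})"
            for term in fit.coef
        }
    return pd.DataFrame(cols)
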