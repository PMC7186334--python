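"""Single-mediator path analysis with bias-corrected bootstrap intervals.

The model is the classic a/b/c/c' decomposition fitted by ordinary least
squares with a shared covariate set:

* ``a``  — X -> M path, from ``M ~ X + covariates``;
* ``b``, ``c'`` — from the full model ``Y ~ X + M + covariates``;
* ``c``  — total effect, from ``Y ~ X + covariates``;
* indirect effect = ``a * b``, and ``c = c' + a*b`` holds exactly.

Uncertainty of the indirect effect comes from resampling whole subject
rows with replacement ``k`` times (default 5,000) and applying the
bias-corrected (BC) percentile interval: with ``z0`` the normal quantile
of the fraction of bootstrap draws below the point estimate, the interval
endpoints are the bootstrap quantiles at ``Phi(2 z0 +/- z_{alpha/2})``.
The mediation is declared significant when the interval excludes zero.
A BCa variant (jackknife acceleration) is available behind a flag.

By default continuous variables are z-scored before fitting so the
coefficients are standardized betas; pass ``standardize=False`` to
estimate on the natural scale (e.g. to recover structural simulation
coefficients). Binary 0/1 columns are never rescaled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm


def _is_binary(v: np.ndarray) -> bool:
    return set(np.unique(v)).issubset({0.0, 1.0})


def _maybe_standardize(v: np.ndarray, on: bool) -> np.ndarray:
    if not on or _is_binary(v):
        return v
    sd = v.std(ddof=0)
    if sd == 0:
        raise ValueError("cannot standardize a constant column")
    return (v - v.mean()) / sd


@dataclass
class RegressionResult:
    """Standardized coefficient of one predictor from a multiple regression."""

    beta: float
    p_value: float
    n: int
    covariates: tuple[str, ...]

    def __repr__(self) -> str:
        return (f"RegressionResult(beta={self.beta:.4f}, "
                f"p={self.p_value:.4g}, n={self.n})")


def standardized_regression(y, x, covariates: pd.DataFrame | None = None
                            ) -> RegressionResult:
    """Standardized OLS coefficient of ``x`` predicting ``y``.

    All continuous variables (outcome, predictor, covariates) are z-scored;
    binary 0/1 covariates are left as indicators. Returns the beta for
    ``x`` with its two-sided p-value.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if covariates is None:
        covariates = pd.DataFrame(index=range(len(y)))
    covariates = pd.DataFrame(covariates)
    n = len(y)
    if n <= covariates.shape[1] + 2:
        raise ValueError("too few observations for the design")
    cols = [np.ones(n), _maybe_standardize(x, True)]
    names = ["const", "x"]
    for c in covariates.columns:
        cols.append(_maybe_standardize(covariates[c].to_numpy(float), True))
        names.append(str(c))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear design")
    fit = sm.OLS(_maybe_standardize(y, True), X).fit()
    return RegressionResult(beta=float(fit.params[1]),
                            p_value=float(fit.pvalues[1]), n=n,
                            covariates=tuple(str(c) for c in covariates.columns))


@dataclass
class MediationResults:
    a: float
    b: float
    c: float
    c_prime: float
    indirect: float
    ci_low: float
    ci_high: float
    significant: bool
    k: int
    seed: int | None
    n: int
    p_a: float
    p_b: float
    p_c: float
    p_c_prime: float
    method: str = "bc"
    degenerate: bool = False
    estimate_within_ci: bool = True

    def summary(self) -> str:
        sig = "yes" if self.significant else "no"
        return "\n".join([
            f"Mediation (n = {self.n}, {self.k} bootstrap draws, "
            f"{self.method.upper()} interval)",
            f"  a (X->M)        = {self.a: .4f}  (p = {self.p_a:.4g})",
            f"  b (M->Y | X)    = {self.b: .4f}  (p = {self.p_b:.4g})",
            f"  c (total)       = {self.c: .4f}  (p = {self.p_c:.4g})",
            f"  c' (direct)     = {self.c_prime: .4f}  "
            f"(p = {self.p_c_prime:.4g})",
            f"  indirect (a*b)  = {self.indirect: .4f}  "
            f"95% CI [{self.ci_low:.4f}, {self.ci_high:.4f}]",
            f"  CI excludes 0   : {sig}",
        ])


class MediationModel:
    """a/b/c/c' mediation of X on Y through M, adjusted for covariates."""

    def __init__(self, x, m, y, covariates: pd.DataFrame | None = None,
                 standardize: bool = True):
        x = np.asarray(x, dtype=float)
        m = np.asarray(m, dtype=float)
        y = np.asarray(y, dtype=float)
        n = len(x)
        if covariates is None:
            covariates = pd.DataFrame(index=range(n))
        covariates = pd.DataFrame(covariates).reset_index(drop=True)
        data = np.column_stack([x, m, y, covariates.to_numpy(dtype=float)
                                if covariates.shape[1] else
                                np.empty((n, 0))])
        complete = np.isfinite(data).all(axis=1)
        data = data[complete]
        if data.shape[0] <= covariates.shape[1] + 3:
            raise ValueError("too few complete cases for the mediation design")
        self.x = _maybe_standardize(data[:, 0], standardize)
        self.m = _maybe_standardize(data[:, 1], standardize)
        self.y = _maybe_standardize(data[:, 2], standardize)
        self.cov = np.column_stack(
            [_maybe_standardize(data[:, 3 + i], standardize)
             for i in range(covariates.shape[1])]
        ) if covariates.shape[1] else np.empty((data.shape[0], 0))
        self.cov_names = tuple(str(c) for c in covariates.columns)
        self.n = data.shape[0]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, x: str, m: str, y: str,
                       covariates: tuple[str, ...] = (),
                       standardize: bool = True) -> "MediationModel":
        return cls(df[x], df[m], df[y], df[list(covariates)]
                   if covariates else None, standardize=standardize)

    # -- internals ---------------------------------------------------------

    def _designs(self):
        n = self.n
        const = np.ones(n)
        Xm = np.column_stack([const, self.x, self.cov])          # M ~ X + C
        Xy = np.column_stack([const, self.x, self.m, self.cov])  # Y ~ X+M+C
        Xc = Xm                                                  # Y ~ X + C
        return Xm, Xy, Xc

    @staticmethod
    def _batched_ab(data: np.ndarray, idx: np.ndarray, p_cov: int):
        """Indirect-effect draws for bootstrap index matrix ``idx`` (k, n)."""
        boot = data[idx]                       # (k, n, 2 + 1 + p_cov) cols x,m,y,C
        k, n, _ = boot.shape
        const = np.ones((k, n, 1))
        x = boot[:, :, 0:1]
        m_col = boot[:, :, 1]
        y_col = boot[:, :, 2]
        C = boot[:, :, 3:]
        Xm = np.concatenate([const, x, C], axis=2)
        Xy = np.concatenate([const, x, boot[:, :, 1:2], C], axis=2)

        def _solve(X, y):
            AtA = np.einsum("knp,knq->kpq", X, X)
            Aty = np.einsum("knp,kn->kp", X, y)
            return np.linalg.solve(AtA, Aty[..., None])[..., 0]

        a_draw = _solve(Xm, m_col)[:, 1]
        b_draw = _solve(Xy, y_col)[:, 2]
        return a_draw * b_draw

    def fit(self, k: int = 5000, seed: int | None = None,
            ci_level: float = 0.95, method: str = "bc") -> MediationResults:
        """Point estimates plus a ``k``-draw bootstrap interval for a*b."""
        if method not in ("bc", "bca", "percentile"):
            raise ValueError("method must be 'bc', 'bca', or 'percentile'")
        Xm, Xy, Xc = self._designs()
        fit_m = sm.OLS(self.m, Xm).fit()
        fit_y = sm.OLS(self.y, Xy).fit()
        fit_c = sm.OLS(self.y, Xc).fit()
        a, p_a = float(fit_m.params[1]), float(fit_m.pvalues[1])
        c_prime, p_cp = float(fit_y.params[1]), float(fit_y.pvalues[1])
        b, p_b = float(fit_y.params[2]), float(fit_y.pvalues[2])
        c, p_c = float(fit_c.params[1]), float(fit_c.pvalues[1])
        indirect = a * b

        rng = np.random.default_rng(seed)
        data = np.column_stack([self.x, self.m, self.y, self.cov])
        idx = rng.integers(0, self.n, size=(k, self.n))
        draws = self._batched_ab(data, idx, self.cov.shape[1])

        alpha = 1.0 - ci_level
        degenerate = bool(np.ptp(draws) == 0)
        if degenerate:
            lo = hi = float(draws[0])
        else:
            z_lo, z_hi = norm.ppf(alpha / 2), norm.ppf(1 - alpha / 2)
            if method == "percentile":
                lo, hi = np.quantile(draws, [alpha / 2, 1 - alpha / 2])
            else:
                frac = np.clip(np.mean(draws < indirect),
                               1.0 / (k + 1), k / (k + 1.0))
                z0 = norm.ppf(frac)
                accel = 0.0
                if method == "bca":
                    accel = self._jackknife_acceleration()
                q_lo = norm.cdf(z0 + (z0 + z_lo) / (1 - accel * (z0 + z_lo)))
                q_hi = norm.cdf(z0 + (z0 + z_hi) / (1 - accel * (z0 + z_hi)))
                lo, hi = np.quantile(draws, [q_lo, q_hi])
        lo, hi = float(lo), float(hi)
        return MediationResults(
            a=a, b=b, c=c, c_prime=c_prime, indirect=indirect,
            ci_low=lo, ci_high=hi,
            significant=not (lo <= 0.0 <= hi),
            k=k, seed=seed, n=self.n, p_a=p_a, p_b=p_b, p_c=p_c,
            p_c_prime=p_cp, method=method, degenerate=degenerate,
            estimate_within_ci=bool(lo <= indirect <= hi))

    def _jackknife_acceleration(self) -> float:
        n = self.n
        data = np.column_stack([self.x, self.m, self.y, self.cov])
        idx = np.stack([np.delete(np.arange(n), i) for i in range(n)])
        theta = self._batched_ab(data, idx, self.cov.shape[1])
        d = theta.mean() - theta
        denom = 6.0 * (np.sum(d**2) ** 1.5)
        if denom == 0:
            return 0.0
        return float(np.sum(d**3) / denom)
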