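"""Maximum-likelihood linear mixed models for repeated-measures designs.

Implements the model family used throughout the trajectory analyses:

    y_ij = x_ij' beta + b0_i + b1_i * t_ij + e_ij

with one grouping factor (subject), a random intercept b0 ~ N(0, s0^2),
an optional independent random slope b1 ~ N(0, s1^2) on the time
covariate, and i.i.d. residuals e ~ N(0, s^2).  Estimation is by
maximum likelihood (never REML) so that log-likelihoods are comparable
across candidates that differ in their fixed-effect structure.

The likelihood is profiled over beta and s^2, leaving only the variance
ratios g0 = s0^2/s^2 and g1 = s1^2/s^2 to optimize numerically.  Because
longitudinal designs are (nearly) balanced, subjects are grouped by their
observation pattern (shared time vector), so each likelihood evaluation
costs one small Cholesky per pattern plus vectorized whitening — orders
of magnitude faster than a generic mixed-model fitter, which matters when
the model family is refit for every CpG on an array.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = ["LmmFit", "RepeatedMeasuresDesign", "fit_lmm"]

_LOG2PI = float(np.log(2.0 * np.pi))
_GAMMA_MAX = 1e4


@dataclass(frozen=True)
class LmmFit:
    """A converged (or flagged) ML fit of one mixed model."""

    loglik: float
    beta: np.ndarray
    bse: np.ndarray
    sigma2: float
    gamma_intercept: float
    gamma_slope: float
    n_obs: int
    k_fixed: int
    n_vc: int
    converged: bool
    columns: tuple[str, ...] = field(default=())

    @property
    def n_params(self) -> int:
        """Parameter count for AIC: fixed effects + residual + variance components."""
        return self.k_fixed + 1 + self.n_vc

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    def wald_pvalues(self) -> np.ndarray:
        from scipy.stats import norm

        z = self.beta / self.bse
        return 2.0 * norm.sf(np.abs(z))

    def coef(self, name: str) -> float:
        return float(self.beta[self.columns.index(name)])

    def coef_p(self, name: str) -> float:
        return float(self.wald_pvalues()[self.columns.index(name)])


class RepeatedMeasuresDesign:
    """Precomputed grouping structure shared by every feature fit.

    Parameters
    ----------
    X : (n, p) fixed-effect design including the intercept.
    groups : length-n array of subject labels.
    time : length-n numeric time covariate (random-slope carrier).
    columns : names for the columns of ``X``.
    """

    def __init__(self, X, groups, time, columns=None):
        X = np.asarray(X, dtype=float)
        time = np.asarray(time, dtype=float)
        groups = np.asarray(groups)
        n = X.shape[0]
        if groups.shape[0] != n or time.shape[0] != n:
            raise ValueError("X, groups and time must have matching length")
        if not np.isfinite(X).all() or not np.isfinite(time).all():
            raise ValueError("design contains non-finite values")
        self.n_obs = n
        self.p = X.shape[1]
        self.columns = tuple(columns) if columns is not None else tuple(
            f"x{j}" for j in range(self.p)
        )
        if len(self.columns) != self.p:
            raise ValueError("column names do not match design width")

        # stable order: sort rows by subject (keeping within-subject order)
        order = np.argsort(groups, kind="stable")
        self._order = order
        g_sorted = groups[order]
        X_sorted = X[order]
        t_sorted = time[order]

        # contiguous subject blocks
        change = np.nonzero(np.r_[True, g_sorted[1:] != g_sorted[:-1]])[0]
        starts = change
        stops = np.r_[change[1:], n]

        patterns: dict[tuple, list[int]] = {}
        for si, (a, b) in enumerate(zip(starts, stops)):
            key = tuple(np.round(t_sorted[a:b], 10))
            patterns.setdefault(key, []).append(si)
        self.n_subjects = len(starts)

        self._patterns = []
        for key, subject_idx in patterns.items():
            m = len(key)
            rows = np.concatenate(
                [np.arange(starts[si], stops[si]) for si in subject_idx]
            )
            S = len(subject_idx)
            X_pat = X_sorted[rows].reshape(S, m, self.p)
            self._patterns.append(
                {
                    "t": np.asarray(key, dtype=float),
                    "m": m,
                    "S": S,
                    "rows": rows,
                    "X": X_pat,
                    # (m, S*p) layout so whitening is a single matmul
                    "Xr": np.ascontiguousarray(
                        X_pat.transpose(1, 0, 2).reshape(m, S * self.p)
                    ),
                }
            )

    # -- likelihood machinery -------------------------------------------------

    def _profiled(self, y_stacked, g0, g1, slope):
        """Profiled ML pieces at variance ratios (g0, g1).

        Returns (loglik, XtX, Xty, beta, sigma2).
        """
        p = self.p
        XtX = np.zeros((p, p))
        Xty = np.zeros(p)
        yty = 0.0
        logdet = 0.0
        for pat, y_pat in zip(self._patterns, y_stacked):
            m, S, t = pat["m"], pat["S"], pat["t"]
            V = np.eye(m) + g0
            if slope:
                V = V + g1 * np.outer(t, t)
            L = np.linalg.cholesky(V)
            Linv = np.linalg.inv(L)
            logdet += 2.0 * S * float(np.log(np.diag(L)).sum())
            # whiten with one matmul each: columns indexed by (subject, col)
            Xw = (Linv @ pat["Xr"]).reshape(m, S, p).transpose(1, 0, 2)
            Xw2 = Xw.reshape(S * m, p)
            yw = (Linv @ y_pat.T).T  # (S, m)
            yw2 = yw.reshape(S * m)
            XtX += Xw2.T @ Xw2
            Xty += Xw2.T @ yw2
            yty += float(yw2 @ yw2)
        beta = np.linalg.solve(XtX, Xty)
        rss = max(yty - float(Xty @ beta), 1e-300)
        n = self.n_obs
        sigma2 = rss / n
        ll = -0.5 * (n * _LOG2PI + n * np.log(sigma2) + n + logdet)
        return ll, XtX, beta, sigma2

    def _stack_y(self, y_sorted):
        return [
            y_sorted[pat["rows"]].reshape(pat["S"], pat["m"])
            for pat in self._patterns
        ]

    def fit(self, y, cols=None, random_slope=False, gamma0_init=None):
        """ML fit of one model on response ``y``.

        ``cols`` selects a subset of design columns by name (default: all).
        ``gamma0_init`` seeds the random-slope search with a known
        intercept variance ratio (e.g. from the matching intercept-only
        fit), skipping the internal pre-fit.
        """
        y = np.asarray(y, dtype=float)
        if y.shape[0] != self.n_obs:
            raise ValueError("response length does not match design")
        if not np.isfinite(y).all():
            raise ValueError("response contains non-finite values")
        if float(np.ptp(y)) == 0.0:
            raise ValueError("degenerate feature: zero variance response")
        if self.n_subjects == self.n_obs:
            raise ValueError(
                "random effect inestimable: every subject has a single observation"
            )

        if cols is None:
            col_idx = None
            columns = self.columns
        else:
            col_idx = tuple(self.columns.index(c) for c in cols)
            columns = tuple(cols)

        if col_idx is None:
            design = self
        else:
            cache = self.__dict__.setdefault("_sub_cache", {})
            if col_idx not in cache:
                cache[col_idx] = _SubDesign(self, col_idx)
            design = cache[col_idx]
        y_sorted = y[self._order]
        y_stacked = design._stack_y(y_sorted)

        success = True
        if not random_slope:
            res = optimize.minimize_scalar(
                lambda g0: -design._profiled(y_stacked, g0, 0.0, False)[0],
                bounds=(0.0, _GAMMA_MAX),
                method="bounded",
                options={"xatol": 1e-7},
            )
            g0, g1 = float(res.x), 0.0
            success = bool(res.success)
            n_vc = 1
        else:
            if gamma0_init is None:
                ri = optimize.minimize_scalar(
                    lambda g0: -design._profiled(y_stacked, g0, 0.0, True)[0],
                    bounds=(0.0, _GAMMA_MAX),
                    method="bounded",
                    options={"xatol": 1e-5},
                )
                gamma0_init = float(ri.x)
            x0 = np.array([gamma0_init, 1e-3])
            nll = lambda g: -design._profiled(y_stacked, g[0], g[1], True)[0]
            bounds = [(0.0, _GAMMA_MAX), (0.0, _GAMMA_MAX)]
            res = optimize.minimize(
                nll, x0, method="L-BFGS-B", bounds=bounds,
                options={"ftol": 1e-11, "gtol": 1e-8, "maxiter": 200},
            )
            if not res.success:  # boundary-hugging cases: fall back to simplex
                res = optimize.minimize(
                    nll, x0, method="Nelder-Mead", bounds=bounds,
                    options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 200},
                )
            g0, g1 = (float(v) for v in res.x)
            success = bool(res.success)
            n_vc = 2

        ll, XtX, beta, sigma2 = design._profiled(y_stacked, g0, g1, random_slope)
        cov = sigma2 * np.linalg.inv(XtX)
        bse = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        converged = success and np.isfinite(ll)
        return LmmFit(
            loglik=float(ll),
            beta=beta,
            bse=bse,
            sigma2=float(sigma2),
            gamma_intercept=g0,
            gamma_slope=g1,
            n_obs=self.n_obs,
            k_fixed=len(columns),
            n_vc=n_vc,
            converged=converged,
            columns=columns,
        )


class _SubDesign:
    """Column-subset view of a RepeatedMeasuresDesign (shares pattern data)."""

    def __init__(self, parent: RepeatedMeasuresDesign, col_idx):
        self.n_obs = parent.n_obs
        self.p = len(col_idx)
        self._patterns = []
        for pat in parent._patterns:
            X_sub = np.ascontiguousarray(pat["X"][:, :, col_idx])
            self._patterns.append(
                {
                    "t": pat["t"],
                    "m": pat["m"],
                    "S": pat["S"],
                    "rows": pat["rows"],
                    "X": X_sub,
                    "Xr": np.ascontiguousarray(
                        X_sub.transpose(1, 0, 2).reshape(pat["m"], pat["S"] * self.p)
                    ),
                }
            )

    _profiled = RepeatedMeasuresDesign._profiled
    _stack_y = RepeatedMeasuresDesign._stack_y


def fit_lmm(y, X, groups, time, columns=None, random_slope=False) -> LmmFit:
    """One-shot convenience wrapper around :class:`RepeatedMeasuresDesign`."""
    design = RepeatedMeasuresDesign(X, groups, time, columns=columns)
    return design.fit(y, random_slope=random_slope)
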