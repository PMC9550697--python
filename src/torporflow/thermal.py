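"""Thermal-energetics curve estimation.

Implements the Scholander–Irving-style decomposition of euthermic metabolism
(a broken-stick regression whose breakpoint is the lower critical temperature
T_lc, with a BMR plateau above it and a linearly rising RMR below it), the
exponential scaling of torpid metabolic rate with ambient temperature
(V̇O2 = a * b**Ta, fitted by Gauss–Newton after a log-linear start), a
single-variance-component random-intercept model estimated by REML (one bat =
one group), the active-thermoregulation line fitted over thermoregulating
bats' low-temperature points, and the critical ambient temperature where that
line meets the TMR curve.

The breakpoint is profiled on a dense grid and polished by bounded scalar
minimization; the no-breakpoint null is tested with a Davies-type maximum
score statistic calibrated by a seeded parametric bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize_scalar

__all__ = [
    "BrokenStickFit",
    "ExponentialFit",
    "ThermoregLine",
    "RandomInterceptFit",
    "fit_broken_stick",
    "fit_exponential",
    "fit_random_intercept",
    "estimate_thermoreg_line",
    "find_critical_ta",
]


# ---------------------------------------------------------------------------
# broken-stick (segmented) regression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BrokenStickFit:
    """Two-segment continuous least-squares fit with a profiled breakpoint."""

    breakpoint: float
    left_slope: float
    left_intercept: float
    right_slope: float
    rss_segmented: float
    rss_linear: float
    f_segmented: float
    f_linear: float
    linearity_pvalue: float
    n: int
    boundary: bool = False  # breakpoint pinned at the edge of the search grid

    def predict(self, ta) -> np.ndarray:
        ta = np.asarray(ta, dtype=float)
        left = self.left_intercept + self.left_slope * ta
        right = (
            self.left_intercept
            + self.left_slope * self.breakpoint
            + self.right_slope * (ta - self.breakpoint)
        )
        return np.where(ta <= self.breakpoint, left, right)


def _segmented_rss_grid(ta, y, psis, plateau):
    """RSS of the continuous two-segment model at each candidate breakpoint.

    Vectorized over breakpoints with suffix/prefix cumulative sums; each
    breakpoint costs one small linear solve.
    """
    order = np.argsort(ta)
    x, yy = ta[order], y[order]
    n = x.size
    cx, cx2, cy, cxy = (np.concatenate(([0.0], np.cumsum(v)))
                        for v in (x, x * x, yy, x * yy))
    sy2 = float(np.sum(yy * yy))
    k = np.searchsorted(x, psis, side="right")  # points <= psi

    rss = np.empty(psis.size)
    for i, (psi, ki) in enumerate(zip(psis, k)):
        n_hi = n - ki
        sx_hi = cx[n] - cx[ki]
        sx2_hi = cx2[n] - cx2[ki]
        sy_hi = cy[n] - cy[ki]
        sxy_hi = cxy[n] - cxy[ki]
        if plateau:
            # columns: [1, min(x, psi)]
            sm = cx[ki] + psi * n_hi
            sm2 = cx2[ki] + psi * psi * n_hi
            smy = cxy[ki] + psi * sy_hi
            A = np.array([[n, sm], [sm, sm2]])
            b = np.array([cy[n], smy])
        else:
            # columns: [1, x, (x - psi)+]
            sz = sx_hi - psi * n_hi
            sz2 = sx2_hi - 2 * psi * sx_hi + psi * psi * n_hi
            sxz = sx2_hi - psi * sx_hi
            szy = sxy_hi - psi * sy_hi
            A = np.array(
                [[n, cx[n], sz], [cx[n], cx2[n], sxz], [sz, sxz, sz2]]
            )
            b = np.array([cy[n], cxy[n], szy])
        try:
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            beta = np.linalg.lstsq(A, b, rcond=None)[0]
        rss[i] = max(sy2 - beta @ b, 0.0)
    return rss


def _segmented_fit_at(ta, y, psi, plateau):
    if plateau:
        X = np.column_stack([np.ones_like(ta), np.minimum(ta, psi)])
    else:
        X = np.column_stack([np.ones_like(ta), ta, np.clip(ta - psi, 0.0, None)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    return beta, rss


def _davies_bootstrap_p(ta, y, plateau, n_boot, seed, n_score_points=20):
    """Parametric-bootstrap p-value for the no-breakpoint null.

    The statistic is the maximum absolute score t for adding a hinge term
    (x - psi)+ to the plain linear model, over a grid of interior candidate
    breakpoints (the Davies construction); its null distribution is obtained
    by simulating Gaussian data from the fitted linear model.  The add-one
    rule keeps the p-value away from zero.
    """
    n = ta.size
    Xlin = np.column_stack([np.ones_like(ta), ta])
    beta_lin, *_ = np.linalg.lstsq(Xlin, y, rcond=None)
    fitted = Xlin @ beta_lin
    resid = y - fitted
    sigma = float(np.sqrt(np.sum(resid**2) / (n - 2)))
    H = Xlin @ np.linalg.solve(Xlin.T @ Xlin, Xlin.T)
    M = np.eye(n) - H

    lo, hi = np.quantile(ta, [0.1, 0.9])
    psis = np.linspace(lo, hi, n_score_points)
    ztils = []
    for psi in psis:
        z = np.clip(ta - psi, 0.0, None)
        zt = M @ z
        nz = float(np.sqrt(np.sum(zt**2)))
        if nz > 1e-10:
            ztils.append(zt / nz)
    if not ztils or sigma == 0:
        return 1.0
    Z = np.column_stack(ztils)  # n x K, unit-norm residualized hinges

    def max_score(Y):
        R = M @ Y  # n x B residuals under the linear model
        proj = Z.T @ R  # K x B
        rss_lin = np.sum(R * R, axis=0)
        rss_seg = rss_lin - proj**2  # K x B, per-psi segmented RSS
        s2 = np.maximum(rss_seg, 1e-300) / (n - 3)
        return np.max(np.abs(proj) / np.sqrt(s2), axis=0)

    t_obs = float(max_score(y[:, None])[0])
    rng = np.random.default_rng(seed)
    Ystar = fitted[:, None] + sigma * rng.standard_normal((n, n_boot))
    t_star = max_score(Ystar)
    return float((1 + np.sum(t_star >= t_obs)) / (1 + n_boot))


def fit_broken_stick(
    ta,
    vo2,
    right_slope_zero: bool = False,
    grid_step: float = 0.01,
    n_boot: int = 999,
    seed: int = 0,
    min_points_per_side: int = 3,
) -> BrokenStickFit:
    """Continuous two-segment regression of V̇O2 on ambient temperature.

    The breakpoint minimizes the two-segment residual sum of squares over a
    dense interior grid (step ``grid_step`` deg C), then is polished by
    bounded scalar minimization around the best grid cell.  With
    ``right_slope_zero`` the upper segment is a flat plateau (the BMR
    definition); otherwise both slopes are free.  ``n_boot`` parametric
    bootstrap replicates calibrate the Davies-type test of linearity
    (``n_boot=0`` skips it, p = nan).

    Raises if fewer than ``min_points_per_side`` observations fall on either
    side of the optimum; a breakpoint pinned to the grid edge is flagged
    ``boundary=True`` (unreliable).
    """
    ta = np.asarray(ta, dtype=float)
    y = np.asarray(vo2, dtype=float)
    if ta.size != y.size or ta.size < 6:
        raise ValueError("need >= 6 paired observations")
    if np.ptp(ta) < 10.0:
        warnings.warn("Ta span below 10 deg C; breakpoint may be weakly identified",
                      stacklevel=2)
    xs = np.sort(ta)
    lo, hi = xs[1], xs[-2]
    if hi - lo <= 2 * grid_step:
        raise ValueError("interior Ta range too narrow for breakpoint search")
    psis = np.arange(lo + grid_step, hi, grid_step)
    rss = _segmented_rss_grid(ta, y, psis, right_slope_zero)
    i_best = int(np.argmin(rss))

    span = (max(psis[0], psis[i_best] - 2 * grid_step),
            min(psis[-1], psis[i_best] + 2 * grid_step))
    res = minimize_scalar(
        lambda p: _segmented_fit_at(ta, y, p, right_slope_zero)[1],
        bounds=span, method="bounded", options={"xatol": 1e-6},
    )
    psi = float(res.x)
    boundary = i_best in (0, psis.size - 1)

    n_left = int(np.sum(ta <= psi))
    n_right = int(np.sum(ta > psi))
    if min(n_left, n_right) < min_points_per_side:
        raise ValueError(
            f"only {min(n_left, n_right)} points on one side of the breakpoint"
        )

    beta, rss_seg = _segmented_fit_at(ta, y, psi, right_slope_zero)
    if right_slope_zero:
        # y = a + b*min(x, psi): left line a + b*x, plateau a + b*psi
        left_intercept, left_slope, right_slope = float(beta[0]), float(beta[1]), 0.0
    else:
        left_intercept, left_slope = float(beta[0]), float(beta[1])
        right_slope = float(beta[1] + beta[2])

    n = ta.size
    tss = float(np.sum((y - y.mean()) ** 2))
    beta_lin, rss_lin = np.linalg.lstsq(
        np.column_stack([np.ones_like(ta), ta]), y, rcond=None
    )[0], None
    rss_lin = float(
        np.sum((y - np.column_stack([np.ones_like(ta), ta]) @ beta_lin) ** 2)
    )
    rss_seg = min(rss_seg, rss_lin)  # nested models; guard against round-off
    p_seg = 2 if right_slope_zero else 3
    f_seg = ((tss - rss_seg) / p_seg) / (rss_seg / max(n - p_seg - 1, 1))
    f_lin = ((tss - rss_lin) / 1) / (rss_lin / max(n - 2, 1))
    pval = (
        _davies_bootstrap_p(ta, y, right_slope_zero, n_boot, seed)
        if n_boot > 0
        else float("nan")
    )
    return BrokenStickFit(
        breakpoint=psi,
        left_slope=left_slope,
        left_intercept=left_intercept,
        right_slope=right_slope,
        rss_segmented=float(rss_seg),
        rss_linear=rss_lin,
        f_segmented=float(f_seg),
        f_linear=float(f_lin),
        linearity_pvalue=pval,
        n=n,
        boundary=boundary,
    )


# ---------------------------------------------------------------------------
# exponential TMR curve
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExponentialFit:
    """Exponential growth curve V̇O2 = a * b**Ta."""

    coeff_a: float
    base_b: float
    r2: float
    n_points: int
    n_individuals: int = 0
    converged: bool = True

    def predict(self, ta) -> np.ndarray:
        return self.coeff_a * self.base_b ** np.asarray(ta, dtype=float)


def fit_exponential(
    ta, vo2, n_individuals: int = 0, tol: float = 1e-10, max_iter: int = 200
) -> ExponentialFit:
    """Fit V̇O2 = a * b**Ta by Gauss–Newton on the original scale.

    Initialization is ordinary least squares of log(V̇O2) on Ta (a =
    exp(intercept), b = exp(slope)); Gauss–Newton with step halving then
    minimizes the untransformed residual sum of squares to relative tolerance
    ``tol``.  R-squared is computed on the original scale.  Non-positive
    responses are an error (exclude them upstream); on divergence the
    log-linear initialization is returned flagged ``converged=False``.
    """
    x = np.asarray(ta, dtype=float)
    y = np.asarray(vo2, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need >= 4 paired observations")
    if np.any(y <= 0):
        raise ValueError(
            "non-positive V̇O2 cannot enter the exponential fit; exclude those "
            "observations first"
        )
    coef = np.polyfit(x, np.log(y), 1)
    a, b = float(np.exp(coef[1])), float(np.exp(coef[0]))

    def rss_at(a_, b_):
        return float(np.sum((y - a_ * b_**x) ** 2))

    rss = rss_at(a, b)
    converged = False
    for _ in range(max_iter):
        pred = a * b**x
        r = y - pred
        J = np.column_stack([b**x, a * x * b ** (x - 1.0)])
        try:
            step = np.linalg.lstsq(J, r, rcond=None)[0]
        except np.linalg.LinAlgError:
            break
        scale = 1.0
        improved = False
        for _ in range(30):
            a_new, b_new = a + scale * step[0], b + scale * step[1]
            if b_new > 1e-9 and a_new > 0:
                rss_new = rss_at(a_new, b_new)
                if rss_new <= rss:
                    improved = True
                    break
            scale *= 0.5
        if not improved:
            converged = True  # no downhill direction left: at a minimum
            break
        a, b = a_new, b_new
        if rss - rss_new <= tol * max(rss, 1e-300):
            rss = rss_new
            converged = True
            break
        rss = rss_new

    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else float("nan")
    return ExponentialFit(
        coeff_a=a,
        base_b=b,
        r2=max(min(r2, 1.0), 0.0) if np.isfinite(r2) else r2,
        n_points=int(x.size),
        n_individuals=n_individuals,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# random-intercept (REML) linear mixed model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RandomInterceptFit:
    """REML fit of y = X beta + u_group + e with a single intercept variance."""

    fixed_effects: tuple[tuple[str, float, float], ...]  # (name, estimate, se)
    sigma2_resid: float
    tau2_id: float
    n_obs: int
    n_groups: int

    @property
    def coefficients(self) -> dict[str, float]:
        return {name: est for name, est, _ in self.fixed_effects}


def _reml_pieces(y, X, group_slices, lam):
    """Sufficient statistics under V = I + lam * Z Z' (block diagonal)."""
    p = X.shape[1]
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    ytVy = 0.0
    logdetV = 0.0
    for sl in group_slices:
        Xg, yg = X[sl], y[sl]
        ng = Xg.shape[0]
        c = lam / (1.0 + lam * ng)
        sx = Xg.sum(axis=0)
        sy = yg.sum()
        XtVX += Xg.T @ Xg - c * np.outer(sx, sx)
        XtVy += Xg.T @ yg - c * sx * sy
        ytVy += yg @ yg - c * sy * sy
        logdetV += np.log1p(lam * ng)
    return XtVX, XtVy, ytVy, logdetV


def fit_random_intercept(
    y,
    X,
    groups,
    names: list[str] | None = None,
    lambda_fix: float | None = None,
) -> RandomInterceptFit:
    """Random-intercept linear mixed model by REML.

    ``X`` is the full fixed-effects design including the intercept column.
    The single variance ratio lambda = tau^2/sigma^2 is profiled out and
    optimized on the bounded transform u = lambda/(1+lambda); the model
    degenerates exactly to ordinary least squares at lambda = 0 (which
    ``lambda_fix=0`` forces, for testing).  Fixed-effect standard errors come
    from the GLS covariance at the optimum — no small-sample (Satterthwaite /
    Kenward–Roger) correction is applied.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    groups = np.asarray(groups)
    n, p = X.shape
    if y.size != n or groups.size != n:
        raise ValueError("y, X and groups must have matching lengths")
    uniq, codes = np.unique(groups, return_inverse=True)
    if uniq.size < 2:
        raise ValueError("all observations in one group: intercept variance "
                         "unidentifiable")
    order = np.argsort(codes, kind="stable")
    y, X, codes = y[order], X[order], codes[order]
    starts = np.searchsorted(codes, np.arange(uniq.size))
    ends = np.append(starts[1:], n)
    slices = [slice(int(s), int(e)) for s, e in zip(starts, ends)]

    def reml_crit(lam):
        XtVX, XtVy, ytVy, logdetV = _reml_pieces(y, X, slices, lam)
        try:
            beta = np.linalg.solve(XtVX, XtVy)
        except np.linalg.LinAlgError:
            return np.inf, None, None, None
        rVr = max(ytVy - 2 * beta @ XtVy + beta @ XtVX @ beta, 1e-300)
        sign, logdetX = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return np.inf, None, None, None
        crit = logdetV + logdetX + (n - p) * np.log(rVr)
        return crit, beta, rVr, XtVX

    if lambda_fix is not None:
        lam = float(lambda_fix)
    else:
        def crit_u(u):
            return reml_crit(u / (1.0 - u))[0]

        res = minimize_scalar(
            crit_u, bounds=(0.0, 1.0 - 1e-12), method="bounded",
            options={"xatol": 1e-10},
        )
        lam = float(res.x / (1.0 - res.x))
        if reml_crit(0.0)[0] <= res.fun:  # boundary check: OLS may win
            lam = 0.0

    crit, beta, rVr, XtVX = reml_crit(lam)
    if beta is None:
        raise np.linalg.LinAlgError("singular design in mixed-model fit")
    sigma2 = rVr / (n - p)
    tau2 = lam * sigma2
    cov = sigma2 * np.linalg.inv(XtVX)
    se = np.sqrt(np.diag(cov))
    if names is None:
        names = ["intercept"] + [f"x{j}" for j in range(1, p)]
    fixed = tuple((names[j], float(beta[j]), float(se[j])) for j in range(p))
    return RandomInterceptFit(
        fixed_effects=fixed,
        sigma2_resid=float(sigma2),
        tau2_id=float(tau2),
        n_obs=n,
        n_groups=int(uniq.size),
    )


# ---------------------------------------------------------------------------
# active-thermoregulation line and critical temperature
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ThermoregLine:
    """Torpid heat-production line below the critical temperature.

    ``slope`` is the positive increase of V̇O2 per deg C of cooling;
    the line as a function of Ta is ``intercept_at_0 - slope * Ta``.
    """

    slope: float
    intercept_at_0: float
    n_points: int
    n_individuals: int
    tau2_id: float = 0.0
    sigma2_resid: float = 0.0

    def predict(self, ta) -> np.ndarray:
        return self.intercept_at_0 - self.slope * np.asarray(ta, dtype=float)


def estimate_thermoreg_line(points) -> ThermoregLine:
    """Random-intercept fit of V̇O2 on Ta over thermoregulating bats' points.

    ``points`` is a DataFrame with columns ``bat_id, ta, vo2`` holding the
    qualifying low-temperature segment minima of bats flagged as actively
    thermoregulating.  At least two bats are required (otherwise the
    between-individual variance is unidentifiable).  The returned slope is
    the positive per-deg-C-of-cooling magnitude.  If thermoconformers are
    pooled in by mistake the slope attenuates toward the TMR curve's local
    slope — a warning is the caller's responsibility since conformity is not
    observable here.
    """
    if points["bat_id"].nunique() < 2:
        raise ValueError("need >= 2 thermoregulating bats")
    ta = points["ta"].to_numpy(dtype=float)
    vo2 = points["vo2"].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(ta), ta])
    fit = fit_random_intercept(
        vo2, X, points["bat_id"].to_numpy(), names=["intercept", "ta"]
    )
    slope_ta = fit.coefficients["ta"]
    return ThermoregLine(
        slope=-slope_ta,
        intercept_at_0=fit.coefficients["intercept"],
        n_points=fit.n_obs,
        n_individuals=fit.n_groups,
        tau2_id=fit.tau2_id,
        sigma2_resid=fit.sigma2_resid,
    )


def find_critical_ta(
    line: ThermoregLine,
    curve: ExponentialFit,
    bracket: tuple[float, float] = (0.0, 30.0),
    scan_step: float = 0.001,
    tangency_tol: float = 1e-9,
) -> float:
    """Temperature where the thermoregulation line meets the TMR curve.

    The difference d(T) = line(T) - curve(T) is scanned over the bracket; the
    warmest sign change is refined by root bracketing to <= 1e-6 deg C (the
    biological reading is the onset of thermoregulation as Ta falls, hence
    the warmest root).  A tangency (|d| within ``tangency_tol`` without a
    sign change) returns the touching point; otherwise a missing sign change
    is an error reporting d at both bracket ends.
    """
    lo, hi = float(bracket[0]), float(bracket[1])
    if not hi > lo:
        raise ValueError("bracket must be increasing")

    def d(t):
        return float(line.predict(t) - curve.predict(t))

    ts = np.arange(lo, hi + scan_step, scan_step)
    ts[-1] = hi
    dv = line.predict(ts) - curve.predict(ts)
    sign_change = np.flatnonzero(np.sign(dv[:-1]) * np.sign(dv[1:]) < 0)
    exact = np.flatnonzero(dv == 0.0)
    if exact.size and not sign_change.size:
        return float(ts[exact[-1]])
    if not sign_change.size:
        i_min = int(np.argmin(np.abs(dv)))
        if abs(dv[i_min]) <= tangency_tol:
            return float(ts[i_min])
        raise ValueError(
            "no intersection on the bracket: "
            f"d({lo}) = {d(lo):.6g}, d({hi}) = {d(hi):.6g}"
        )
    i = int(sign_change[-1])  # warmest root
    return float(brentq(d, ts[i], ts[i + 1], xtol=1e-9))
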