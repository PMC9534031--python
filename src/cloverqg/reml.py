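"""Restricted maximum likelihood for the random split-plot family model.

The model fitted to plot observations (family x replicate quadrant means) is

    y = mu + family + replicate + family x replicate + row(replicate)
        + column(replicate) + error

with an intercept as the only fixed effect and every other term random,
``u_t ~ N(0, sigma_t^2 I)``.  Components are estimated by maximising the
restricted log-likelihood

    l_R(sigma^2) = -1/2 [ log|V| + log|X'V^-1 X| + y'Py + (n-p) log 2*pi ]

where ``V = sum_t sigma_t^2 Z_t Z_t' + sigma_e^2 I`` and ``P`` is the usual
REML projection.  Optimisation runs an expectation-maximisation warm start
followed by Fisher-scoring (Newton-type) updates on log-variances, which keeps
every component non-negative; components that collapse below ``1e-10`` times
the phenotypic variance are pinned to exactly zero.  Standard errors come from
the inverse expected information at the optimum; a pinned component reports no
standard error.  Family BLUPs solve the mixed-model equations at the estimated
components.

Terms whose design is degenerate are dropped with a warning: a term with a
single level is inestimable, and a term with one observation per level is
confounded with the residual (the usual case for family x replicate when the
analysis unit is the plot mean — the reported residual then estimates
sigma_fR^2 + sigma_e^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .errors import ConvergenceError, SingularCovarianceError

#: grouping columns behind each named random term
TERM_COLUMNS = {
    "family": ("family",),
    "replicate": ("replicate",),
    "family_by_replicate": ("family", "replicate"),
    "row": ("replicate", "row"),
    "column": ("replicate", "column"),
}
DEFAULT_TERMS = tuple(TERM_COLUMNS)

_PIN_FRACTION = 1e-10  # of the phenotypic variance
_FLOOR_FRACTION = 1e-12


@dataclass(frozen=True)
class ModelSpec:
    """Response column plus the random terms to attempt."""

    response: str
    terms: tuple = DEFAULT_TERMS

    def __post_init__(self):
        unknown = set(self.terms) - set(TERM_COLUMNS)
        if unknown:
            raise ValueError(f"unknown random terms: {sorted(unknown)}")


@dataclass
class Component:
    estimate: float
    se: float | None
    significant: bool | None
    pinned: bool = False


@dataclass
class FitResult:
    response: str
    components: dict
    mu: float
    blups: pd.Series
    adjusted_means: pd.Series
    loglik: float
    iterations: int
    converged: bool
    dropped: tuple = ()
    n_obs: int = 0
    vcov: pd.DataFrame | None = None

    @property
    def estimates(self) -> dict:
        return {t: c.estimate for t, c in self.components.items()}


def wald_significance(estimate: float, se: float | None, alpha: float = 0.05):
    """One-sided Wald test that a variance component exceeds zero.

    Returns True/False, or None when no standard error is available (component
    pinned at the boundary), in which case significance is not assessable.
    """
    if se is None or not se > 0 or not np.isfinite(se):
        return None
    return bool(stats.norm.sf(estimate / se) <= alpha)


def _incidence(data: pd.DataFrame, cols) -> tuple[np.ndarray, list]:
    if len(cols) == 1:
        keys = data[cols[0]]
    else:
        keys = pd.Series(list(zip(*(data[c] for c in cols))), index=data.index)
    codes, uniques = pd.factorize(keys, sort=True)
    Z = np.zeros((len(data), len(uniques)))
    Z[np.arange(len(data)), codes] = 1.0
    return Z, list(uniques)


def _build(data: pd.DataFrame, spec: ModelSpec, drop_degenerate: bool = True):
    data = data.dropna(subset=[spec.response]).reset_index(drop=True)
    n = len(data)
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    y = data[spec.response].to_numpy(dtype=float)
    terms, Zs, dropped = [], {}, []
    for term in spec.terms:
        cols = TERM_COLUMNS[term]
        missing = [c for c in cols if c not in data.columns]
        if missing:
            dropped.append(term)
            warnings.warn(
                f"term {term!r} dropped: column(s) {missing} absent", stacklevel=3
            )
            continue
        Z, labels = _incidence(data, cols)
        q = Z.shape[1]
        if q < 2:
            dropped.append(term)
            if drop_degenerate:
                warnings.warn(
                    f"term {term!r} dropped: single level", stacklevel=3
                )
                continue
        if q == n:
            dropped.append(term)
            if drop_degenerate:
                warnings.warn(
                    f"term {term!r} dropped: one observation per level, "
                    "confounded with the residual",
                    stacklevel=3,
                )
                continue
        terms.append(term)
        Zs[term] = (Z, labels)
    return data, y, terms, Zs, tuple(dropped)


class _Problem:
    """Dense REML machinery for one response vector with intercept-only X."""

    def __init__(self, y: np.ndarray, G: list):
        self.y = y
        self.G = G  # covariance kernels of the non-residual terms
        self.n = len(y)

    def decompose(self, v: np.ndarray):
        n = self.n
        V = v[-1] * np.eye(n)
        for vt, Gt in zip(v[:-1], self.G):
            V += vt * Gt
        try:
            c, low = linalg.cho_factor(V, check_finite=False)
        except linalg.LinAlgError as exc:
            raise SingularCovarianceError(
                f"total covariance not positive definite at variances {v}",
                condition_number=float(np.linalg.cond(V)),
            ) from exc
        Vinv = linalg.cho_solve((c, low), np.eye(n), check_finite=False)
        logdet_v = 2.0 * np.log(np.diag(c)).sum()
        vinv1 = Vinv.sum(axis=1)
        xvx = vinv1.sum()
        if xvx <= 0:
            raise SingularCovarianceError("X'V^-1X not positive")
        P = Vinv - np.outer(vinv1, vinv1) / xvx
        Py = P @ self.y
        ll = -0.5 * (
            logdet_v
            + np.log(xvx)
            + self.y @ Py
            + (n - 1) * np.log(2.0 * np.pi)
        )
        return ll, P, Py, xvx, vinv1

    def loglik(self, v: np.ndarray) -> float:
        return self.decompose(v)[0]

    def score_info(self, v: np.ndarray):
        """Log-likelihood, gradient and expected information on the variance scale."""
        ll, P, Py, _, _ = self.decompose(v)
        kernels = self.G + [None]  # residual kernel is the identity
        PG = [P @ Gt for Gt in self.G] + [P]
        grad = np.empty(len(kernels))
        for t, Gt in enumerate(kernels):
            quad = Py @ Py if Gt is None else Py @ Gt @ Py
            grad[t] = -0.5 * (np.trace(PG[t]) - quad)
        k = len(kernels)
        info = np.empty((k, k))
        for s in range(k):
            for t in range(s, k):
                info[s, t] = info[t, s] = 0.5 * np.sum(PG[s] * PG[t].T)
        return ll, grad, info, P, Py


def fit_reml(
    data: pd.DataFrame,
    spec: ModelSpec,
    *,
    max_iter: int = 200,
    rel_tol: float = 1e-8,
    n_em: int = 15,
    drop_degenerate: bool = True,
    unconstrained: tuple = (),
) -> FitResult:
    """Fit the random model by REML and return components, BLUPs and diagnostics.

    ``data`` is a wide plot frame holding the response column plus whichever
    grouping columns the requested terms need.  Raises
    :class:`~cloverqg.errors.ConvergenceError` (carrying the log-likelihood
    trajectory) if the optimiser fails.

    Terms named in ``unconstrained`` are estimated on the raw variance scale
    and may come out negative (the total covariance must merely stay positive
    definite).  This is used for the auxiliary sum/difference responses behind
    covariance-component estimation, where truncating a near-zero component at
    the boundary would bias the recovered covariance; ordinary fits leave it
    empty, so every reported variance is non-negative.
    """
    data, y, terms, Zs, dropped = _build(data, spec, drop_degenerate)
    n = len(y)
    vary = float(np.var(y, ddof=1))

    fam_labels = None
    if "family" in Zs:
        fam_labels = Zs["family"][1]
    elif "family" in data.columns:
        fam_labels = sorted(pd.unique(data["family"].dropna()))

    if vary == 0.0:
        components = {t: Component(0.0, None, None, pinned=True) for t in terms}
        components["residual"] = Component(0.0, None, None, pinned=True)
        blups = pd.Series(0.0, index=pd.Index(fam_labels or [], name="family"))
        return FitResult(
            spec.response, components, float(y[0]), blups, blups + float(y[0]),
            loglik=np.inf, iterations=0, converged=True, dropped=dropped, n_obs=n,
        )

    G = [Zs[t][0] @ Zs[t][0].T for t in terms]
    q_levels = np.array([Zs[t][0].shape[1] for t in terms] + [n], dtype=float)
    problem = _Problem(y, G)
    floor = _FLOOR_FRACTION * vary
    uncon = np.array([t in unconstrained for t in terms] + [False])

    v = np.full(len(terms) + 1, vary / (len(terms) + 1))
    trajectory = []

    # --- EM warm start ----------------------------------------------------
    for _ in range(n_em):
        ll, P, Py, _, _ = problem.decompose(v)
        trajectory.append(ll)
        new = v.copy()
        for t, Gt in enumerate(G):
            new[t] = v[t] + v[t] ** 2 * (Py @ Gt @ Py - np.sum(P * Gt)) / q_levels[t]
        new[-1] = v[-1] + v[-1] ** 2 * (Py @ Py - np.trace(P)) / q_levels[-1]
        v = np.clip(new, floor, None)

    # --- Fisher scoring on theta (log scale, raw for unconstrained terms) --
    def to_v(theta):
        vv = np.where(uncon, theta, np.exp(np.where(uncon, 0.0, theta)))
        return np.where(uncon, vv, np.clip(vv, floor, None))

    def to_theta(vv):
        return np.where(uncon, vv, np.log(np.where(uncon, 1.0, vv)))

    ll, grad, info, P, Py = problem.score_info(v)
    trajectory.append(ll)
    converged = False
    iterations = n_em
    for _ in range(max_iter):
        iterations += 1
        theta = to_theta(v)
        jac_diag = np.where(uncon, 1.0, v)
        grad_t = grad * jac_diag
        info_t = info * np.outer(jac_diag, jac_diag)
        ridge = 1e-10 * max(info_t.diagonal().max(), 1.0)
        try:
            step = np.linalg.solve(info_t + ridge * np.eye(len(v)), grad_t)
        except np.linalg.LinAlgError:
            step = grad_t / (info_t.diagonal() + ridge)
        step = np.where(uncon, np.clip(step, -4.0 * vary, 4.0 * vary),
                        np.clip(step, -4.0, 4.0))  # guard wild early steps

        accepted = False
        for _half in range(30):
            cand = to_v(theta + step)
            try:
                cand_ll = problem.loglik(cand)
            except SingularCovarianceError:
                cand_ll = -np.inf
            if cand_ll >= ll - 1e-12 * (1.0 + abs(ll)):
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        delta = cand_ll - ll
        v = cand
        ll, grad, info, P, Py = problem.score_info(v)
        trajectory.append(ll)
        active = uncon | (v > floor * 1.01)
        jac_diag = np.where(uncon, 1.0, v)
        grad_norm = np.max(np.abs((grad * jac_diag)[active])) if active.any() else 0.0
        if abs(delta) <= rel_tol * (1.0 + abs(ll)) and grad_norm < 1e-6:
            converged = True
            break

    if not converged:
        # polish with a quasi-Newton pass before giving up
        from scipy.optimize import minimize

        def neg(theta):
            vv = to_v(theta)
            try:
                l, g, _, _, _ = problem.score_info(vv)
            except SingularCovarianceError:
                return np.inf, np.zeros_like(theta)
            return -l, -(g * np.where(uncon, 1.0, vv))

        bounds = [(-1e3 * vary, 1e3 * vary) if u else (np.log(floor), np.log(1e3 * vary))
                  for u in uncon]
        res = minimize(
            neg, to_theta(v), jac=True, method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-9},
        )
        v = to_v(res.x)
        ll, grad, info, P, Py = problem.score_info(v)
        trajectory.append(ll)
        iterations += int(res.nit)
        active = uncon | (v > floor * 1.01)
        jac_diag = np.where(uncon, 1.0, v)
        grad_norm = np.max(np.abs((grad * jac_diag)[active])) if active.any() else 0.0
        converged = bool(res.success) or grad_norm < 1e-5
        if not converged:
            raise ConvergenceError(
                f"REML did not converge after {iterations} iterations "
                f"(gradient norm {grad_norm:.3g})",
                trajectory=trajectory,
            )

    # --- pin boundary components and final quantities ---------------------
    pin = (~uncon) & (v < _PIN_FRACTION * vary)
    v_report = np.where(pin, 0.0, v)
    all_terms = terms + ["residual"]

    free = ~pin
    vcov = None
    ses = {t: None for t in all_terms}
    if free.any():
        sub = info[np.ix_(free, free)]
        try:
            cov_free = np.linalg.inv(sub)
        except np.linalg.LinAlgError:
            cov_free = np.linalg.pinv(sub)
        free_terms = [t for t, f in zip(all_terms, free) if f]
        vcov = pd.DataFrame(cov_free, index=free_terms, columns=free_terms)
        for t in free_terms:
            var = vcov.loc[t, t]
            ses[t] = float(np.sqrt(var)) if var > 0 else None

    components = {}
    for t, est, pinned in zip(all_terms, v_report, pin):
        se = ses[t]
        components[t] = Component(
            float(est), se, wald_significance(est, se), pinned=bool(pinned)
        )

    _, P, Py, xvx, vinv1 = problem.decompose(v)
    mu = float(vinv1 @ y / xvx)
    if "family" in Zs and not components["family"].pinned:
        Zf = Zs["family"][0]
        u = components["family"].estimate * (Zf.T @ Py)
        blups = pd.Series(u, index=pd.Index(Zs["family"][1], name="family"))
    else:
        blups = pd.Series(
            0.0, index=pd.Index(fam_labels or [], name="family"), dtype=float
        )
    return FitResult(
        response=spec.response,
        components=components,
        mu=mu,
        blups=blups,
        adjusted_means=mu + blups,
        loglik=float(ll),
        iterations=iterations,
        converged=converged,
        dropped=dropped,
        n_obs=n,
        vcov=vcov,
    )


def restricted_log_likelihood(
    variances, data: pd.DataFrame, spec: ModelSpec
) -> float:
    """Restricted log-likelihood of the given variances (including ``"residual"``).

    Exact including the ``-(n-p)/2 log 2 pi`` constant, so values are
    comparable across calls on the same data.  Raises
    :class:`~cloverqg.errors.SingularCovarianceError` when the implied total
    covariance is not positive definite.
    """
    data, y, terms, Zs, _ = _build(data, spec, drop_degenerate=True)
    G = [Zs[t][0] @ Zs[t][0].T for t in terms]
    v = np.array([float(variances[t]) for t in terms] + [float(variances["residual"])])
    if (v < 0).any():
        raise ValueError("variances must be non-negative")
    return float(_Problem(y, G).loglik(v))


def likelihood_ratio_test(data: pd.DataFrame, spec: ModelSpec, term: str):
    """Boundary-corrected LRT for one variance component.

    Returns ``(statistic, p_value)`` with the null p-value from the
    0.5*chi2_0 + 0.5*chi2_1 mixture appropriate for a variance tested at its
    boundary.  Exposed as an alternative to the default Wald flags.
    """
    if term not in spec.terms:
        raise ValueError(f"term {term!r} not in the model")
    full = fit_reml(data, spec)
    reduced_terms = tuple(t for t in spec.terms if t != term)
    reduced = fit_reml(data, ModelSpec(spec.response, reduced_terms))
    stat = 2.0 * (full.loglik - reduced.loglik)
    if stat <= 0:
        return float(stat), 1.0
    return float(stat), float(0.5 * stats.chi2.sf(stat, 1))
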