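"""Weighted-least-squares parameter estimation and confidence analysis.

The objective is the weighted sum of squared residuals over one or more
data curves, cost(p) = Σ_curves Σ_i w_i (data_i − model_i(p))².  Four
optimizers cover the classic algorithm families:

``simplex``
    bounded Nelder-Mead direct search (scipy), bounds by projection;
``gridsearch``
    progressively restricted search: N points per dimension on a regular
    grid, the best cell's neighbourhood becomes the next (shrunken) grid;
``sensop``
    Levenberg-Marquardt on the weighted residual vector with a
    finite-difference Jacobian, multiplicative damping (λ) adaptation and
    bound projection — the weighted nonlinear least-squares workhorse;
``simanneal``
    simulated annealing: Gaussian proposals whose scale follows a
    geometric temperature schedule, Metropolis acceptance, seeded.

Confidence ranges come from two routes.  The Jacobian route evaluates the
sensitivity matrix J at the optimum and reports covariance
s²·(JᵀWJ)⁻¹ with s² = SSR_w/(n−p), parameter SDs, Gaussian 95%% ranges
and the correlation matrix (near-singular JᵀWJ is reported with its
condition number and solved by pseudo-inverse).  The Monte-Carlo route
perturbs every data point with fresh noise draws, re-optimizes from the
baseline optimum, and reports per-parameter histograms and percentile
intervals — no symmetry or linearity assumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize as sciopt

from .analysis import get_series, solve_model, time_grid
from .plan import ComputationPlan

__all__ = ["DataBinding", "FitProblem", "FitResult", "ConfidenceReport",
           "NoiseSpec", "McEnsemble", "optimize",
           "confidence_from_jacobian", "monte_carlo"]


@dataclass
class DataBinding:
    """One data curve bound to a model variable."""

    variable: str
    abscissae: np.ndarray
    values: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self):
        self.abscissae = np.asarray(self.abscissae, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
        if self.abscissae.shape != self.values.shape:
            raise ValueError("data curve lengths differ")
        if np.any(np.diff(self.abscissae) <= 0):
            raise ValueError("data abscissae must be strictly increasing")


class FitProblem:
    """Weighted-least-squares problem over free parameters with bounds.

    ``predictor(vector) -> {variable: model values at the curve's
    abscissae}`` may be supplied directly, or built from a planned model
    via :meth:`from_model`.
    """

    def __init__(self, predictor, free: list[str], start,
                 bounds: dict | None = None,
                 curves: list[DataBinding] | None = None):
        self.predictor = predictor
        self.free = list(free)
        self.x0 = np.asarray([start[f] for f in self.free] if
                             isinstance(start, dict) else start, dtype=float)
        self.curves = curves or []
        if not self.curves:
            raise ValueError("fit problem needs at least one data curve")
        lo, hi = [], []
        for f in self.free:
            b = (bounds or {}).get(f, (-np.inf, np.inf))
            if not b[0] < b[1]:
                raise ValueError(f"bounds for {f!r}: lower must be < upper")
            lo.append(b[0])
            hi.append(b[1])
        self.lower = np.asarray(lo)
        self.upper = np.asarray(hi)
        self.n_failures = 0

    # -- model-based construction ----------------------------------------
    @classmethod
    def from_model(cls, plan: ComputationPlan, data: list[DataBinding],
                   free: list[str], start: dict | None = None,
                   bounds: dict | None = None, fixed: dict | None = None,
                   inputs=None, config=None) -> "FitProblem":
        pvals = plan.param_values()
        start = dict(start or {})
        for f in free:
            start.setdefault(f, pvals[f])

        def predictor(vec):
            overrides = dict(fixed or {})
            overrides.update({f: v for f, v in zip(free, vec)})
            sol = solve_model(plan, overrides, inputs, config)
            tm = time_grid(sol)
            out = {}
            for c in data:
                ym = np.asarray(get_series(sol, c.variable), dtype=float)
                out[c.variable] = np.interp(c.abscissae, tm, ym)
            return out

        return cls(predictor, free, start, bounds, data)

    # -- objective ---------------------------------------------------------
    def clip(self, vec: np.ndarray) -> np.ndarray:
        return np.clip(vec, self.lower, self.upper)

    def weighted_residuals(self, vec: np.ndarray) -> np.ndarray:
        """sqrt(w)·(data − model), concatenated over curves."""
        pred = self.predictor(vec)
        parts = []
        for c in self.curves:
            w = np.ones_like(c.values) if c.weights is None else c.weights
            parts.append(np.sqrt(w) * (c.values - pred[c.variable]))
        return np.concatenate(parts)

    def cost(self, vec: np.ndarray) -> float:
        try:
            r = self.weighted_residuals(vec)
        except Exception:
            self.n_failures += 1
            return np.inf
        if not np.all(np.isfinite(r)):
            self.n_failures += 1
            return np.inf
        return float(r @ r)

    @property
    def n_points(self) -> int:
        return int(sum(c.values.size for c in self.curves))


@dataclass
class ConfidenceReport:
    covariance: np.ndarray
    correlation: np.ndarray
    sd: np.ndarray
    ci95: list[tuple[float, float]]
    s2: float
    condition: float
    pseudo_inverse: bool


@dataclass
class FitResult:
    params: dict[str, float]
    vector: np.ndarray
    cost: float
    iterations: int
    evaluations: int
    converged: bool
    method: str
    history: list[float] = field(default_factory=list)
    jacobian: np.ndarray | None = None
    confidence: ConfidenceReport | None = None

    def __post_init__(self):
        if self.history and not all(
                b <= a + 1e-12 * max(1.0, abs(a))
                for a, b in zip(self.history, self.history[1:])):
            raise AssertionError("accepted-iteration cost increased")


# ---------------------------------------------------------------------------
# Optimizers
# ---------------------------------------------------------------------------

def _fd_jacobian(problem: FitProblem, vec: np.ndarray,
                 r0: np.ndarray | None = None,
                 rel_step: float = 1e-6) -> np.ndarray:
    if r0 is None:
        r0 = problem.weighted_residuals(vec)
    J = np.empty((r0.size, vec.size))
    for j in range(vec.size):
        h = rel_step * max(abs(vec[j]), 1e-8)
        vp = vec.copy()
        vp[j] = min(vec[j] + h, problem.upper[j])
        if vp[j] == vec[j]:
            vp[j] = vec[j] - h
            h = -h
        J[:, j] = (problem.weighted_residuals(vp) - r0) / (vp[j] - vec[j])
    # J is d(residual)/d(param); model sensitivity enters with opposite sign
    return J


def _optimize_sensop(problem, options, history):
    """Levenberg-Marquardt on the weighted residual vector."""
    tol = options.get("tol", 1e-10)
    max_iter = options.get("max_iter", 100)
    lam = options.get("lambda0", 1e-3)
    lam_up, lam_down = options.get("lambda_up", 4.0), options.get(
        "lambda_down", 0.5)
    x = problem.clip(problem.x0.copy())
    r = problem.weighted_residuals(x)
    cost = float(r @ r)
    history.append(cost)
    evals = 1
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        J = _fd_jacobian(problem, x, r)
        evals += x.size
        A = J.T @ J
        g = J.T @ r
        improved = False
        for _ in range(25):
            M = A + lam * np.diag(np.maximum(np.diag(A), 1e-30))
            try:
                step = np.linalg.solve(M, -g)
            except np.linalg.LinAlgError:
                lam *= lam_up
                continue
            x_try = problem.clip(x + step)
            c_try = problem.cost(x_try)
            evals += 1
            if c_try < cost:
                rel = (cost - c_try) / max(cost, 1e-300)
                x, cost = x_try, c_try
                r = problem.weighted_residuals(x)
                lam = max(lam * lam_down, 1e-12)
                history.append(cost)
                improved = True
                if rel < tol:
                    converged = True
                break
            lam *= lam_up
        if not improved:
            converged = True
        if converged:
            break
    return x, cost, it, evals, converged


def _optimize_simplex(problem, options, history):
    tol = options.get("tol", 1e-12)
    max_iter = options.get("max_iter", 2000)
    best = [np.inf]

    def f(v):
        c = problem.cost(v)
        if c < best[0]:
            best[0] = c
            history.append(c)
        return c

    bounds = sciopt.Bounds(problem.lower, problem.upper)
    res = sciopt.minimize(f, problem.clip(problem.x0), method="Nelder-Mead",
                          bounds=bounds,
                          options={"xatol": options.get("xatol", 1e-8),
                                   "fatol": tol, "maxiter": max_iter})
    return (problem.clip(res.x), float(res.fun), int(res.nit),
            int(res.nfev), bool(res.success))


def _optimize_gridsearch(problem, options, history):
    npts = int(options.get("points_per_dim", 5))
    passes = int(options.get("passes", 20))
    shrink = float(options.get("shrink", 0.5))
    lo = np.where(np.isfinite(problem.lower), problem.lower,
                  problem.x0 - np.maximum(np.abs(problem.x0), 1.0) * 2)
    hi = np.where(np.isfinite(problem.upper), problem.upper,
                  problem.x0 + np.maximum(np.abs(problem.x0), 1.0) * 2)
    center = problem.clip(problem.x0.copy())
    span = (hi - lo) / 2.0
    best_x, best_c = center.copy(), problem.cost(center)
    history.append(best_c)
    evals = 1
    for _ in range(passes):
        axes = [np.linspace(max(center[d] - span[d], problem.lower[d]),
                            min(center[d] + span[d], problem.upper[d]), npts)
                for d in range(center.size)]
        mesh = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([m.ravel() for m in mesh], axis=-1)
        for p in pts:
            c = problem.cost(p)
            evals += 1
            if c < best_c:
                best_c = c
                best_x = p.copy()
                history.append(c)
        center = best_x.copy()
        span = span * shrink
    return best_x, best_c, passes, evals, True


def _optimize_simanneal(problem, options, history, seed):
    rng = np.random.default_rng(seed if seed is not None else 0)
    max_eval = int(options.get("max_eval", 4000))
    t0 = float(options.get("t0", 1.0))
    t_final = float(options.get("t_final", 1e-4))
    x = problem.clip(problem.x0.copy())
    c = problem.cost(x)
    best_x, best_c = x.copy(), c
    history.append(best_c)
    scale0 = np.where(np.isfinite(problem.upper - problem.lower),
                      (problem.upper - problem.lower) / 4.0,
                      np.maximum(np.abs(x), 1.0))
    alpha = (t_final / t0) ** (1.0 / max(max_eval - 1, 1))
    temp = t0
    for _ in range(max_eval):
        prop = problem.clip(x + rng.normal(size=x.size) * scale0 * temp)
        cp = problem.cost(prop)
        if cp < c or rng.random() < np.exp(-(cp - c) /
                                           max(temp * (abs(c) + 1e-12),
                                               1e-300)):
            x, c = prop, cp
            if c < best_c:
                best_x, best_c = x.copy(), c
                history.append(best_c)
        temp *= alpha
    return best_x, best_c, max_eval, max_eval + 1, True


_METHODS = {"simplex": _optimize_simplex, "gridsearch": _optimize_gridsearch,
            "sensop": _optimize_sensop, "simanneal": _optimize_simanneal}


def optimize(problem: FitProblem, method: str = "sensop",
             options: dict | None = None, seed: int | None = None,
             with_confidence: bool = True) -> FitResult:
    """Minimize the weighted SSR.  The iteration history records accepted
    (non-increasing) costs; ``simanneal`` is the only stochastic method and
    is fully determined by ``seed``."""
    if method not in _METHODS:
        raise ValueError(f"unknown optimizer {method!r}")
    options = options or {}
    history: list[float] = []
    if method == "simanneal":
        x, cost, nit, nev, ok = _optimize_simanneal(problem, options,
                                                    history, seed)
    else:
        x, cost, nit, nev, ok = _METHODS[method](problem, options, history)
    result = FitResult(params=dict(zip(problem.free, x)), vector=x,
                       cost=cost, iterations=nit, evaluations=nev,
                       converged=ok, method=method, history=history)
    if with_confidence and np.isfinite(cost):
        try:
            J = _fd_jacobian(problem, x)
            result.jacobian = J
            result.confidence = confidence_from_jacobian(
                J, cost, problem.n_points)
        except Exception:
            pass
    return result


def confidence_from_jacobian(jacobian: np.ndarray, wssr: float,
                             n_points: int) -> ConfidenceReport:
    """Gaussian confidence ranges from the sensitivity matrix at the
    optimum.

    ``jacobian`` is d(weighted residual)/d(parameter) (weights already
    folded in, so JᵀJ = JᵀWJ of the unweighted sensitivities); covariance
    is s²(JᵀJ)⁻¹ with s² = weighted SSR / (n − p).
    """
    n, p = jacobian.shape
    if n_points <= p:
        raise ValueError("need more data points than free parameters")
    if not np.all(np.isfinite(jacobian)):
        raise ValueError("non-finite Jacobian")
    A = jacobian.T @ jacobian
    cond = float(np.linalg.cond(A))
    pseudo = cond > 1e12
    inv = np.linalg.pinv(A) if pseudo else np.linalg.inv(A)
    s2 = wssr / (n_points - p)
    cov = s2 * inv
    sd = np.sqrt(np.maximum(np.diag(cov), 0.0))
    denom = np.outer(sd, sd)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.where(denom > 0, cov / denom, 0.0)
    np.fill_diagonal(corr, 1.0)
    z = 1.959963984540054  # Gaussian 97.5% quantile
    ci = [(-z * s, z * s) for s in sd]
    return ConfidenceReport(covariance=cov, correlation=corr, sd=sd,
                            ci95=ci, s2=s2, condition=cond,
                            pseudo_inverse=pseudo)


# ---------------------------------------------------------------------------
# Monte-Carlo confidence distributions
# ---------------------------------------------------------------------------

@dataclass
class NoiseSpec:
    kind: str        # proportional_gaussian | additive_gaussian
    value: float     # fraction or SD

    def __post_init__(self):
        if self.kind not in ("proportional_gaussian", "additive_gaussian"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.value < 0:
            raise ValueError("noise magnitude must be >= 0")

    def perturb(self, values: np.ndarray, rng) -> np.ndarray:
        eps = rng.standard_normal(values.shape)
        if self.kind == "proportional_gaussian":
            return values * (1.0 + self.value * eps)
        return values + self.value * eps


@dataclass
class McEnsemble:
    replicates: int
    failures: int
    estimates: np.ndarray           # (successful reps, p)
    free: list[str]
    seed: int
    noise: NoiseSpec
    percentiles: dict[str, tuple[float, float]]   # 2.5 / 97.5
    histograms: dict[str, tuple[np.ndarray, np.ndarray]]  # counts, edges
    baseline: FitResult


def monte_carlo(problem: FitProblem, baseline: FitResult | None = None,
                method: str = "sensop", options: dict | None = None,
                noise: NoiseSpec = NoiseSpec("proportional_gaussian", 0.05),
                reps: int = 100, seed: int = 0,
                bins: int = 20) -> McEnsemble:
    """Perturb-and-reoptimize confidence distributions.

    Replicate r perturbs every data point with fresh draws from the noise
    model (stream ``seed + r`` — replicates are independent and the whole
    ensemble is reproducible from ``seed``) and re-optimizes starting from
    the baseline optimum.
    """
    if baseline is None:
        baseline = optimize(problem, method, options, seed=seed,
                            with_confidence=False)
    clean = [c.values.copy() for c in problem.curves]
    x0_orig = problem.x0.copy()
    estimates = []
    failures = 0
    try:
        for r in range(reps):
            rng = np.random.default_rng(seed + r)
            for c, y in zip(problem.curves, clean):
                c.values = noise.perturb(y, rng)
            problem.x0 = baseline.vector.copy()
            try:
                res = optimize(problem, method, options, seed=seed + r,
                               with_confidence=False)
                if not np.isfinite(res.cost):
                    raise RuntimeError("fit failed")
                estimates.append(res.vector)
            except Exception:
                failures += 1
    finally:
        for c, y in zip(problem.curves, clean):
            c.values = y
        problem.x0 = x0_orig
    est = np.asarray(estimates) if estimates else np.empty((0,
                                                            len(problem.free)))
    pct: dict[str, tuple[float, float]] = {}
    hist: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for j, name in enumerate(problem.free):
        if est.shape[0]:
            lo, hi = np.percentile(est[:, j], [2.5, 97.5])
            counts, edges = np.histogram(est[:, j], bins=bins)
        else:
            lo = hi = np.nan
            counts, edges = np.zeros(bins, dtype=int), np.zeros(bins + 1)
        pct[name] = (float(lo), float(hi))
        hist[name] = (counts, edges)
    return McEnsemble(replicates=reps, failures=failures, estimates=est,
                      free=list(problem.free), seed=seed, noise=noise,
                      percentiles=pct, histograms=hist, baseline=baseline)
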