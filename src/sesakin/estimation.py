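"""Multiresponse parameter estimation for the isomerization kinetics.

Both observables (sesamin and asarinin concentrations) are fitted jointly by
minimizing the determinant criterion

    S(theta) = (n + m + 1) * ln |v(theta)|,
    v_ij(theta) = sum_u [Y_iu - Yhat_iu(theta)] * [Y_ju - Yhat_ju(theta)],

where m is the number of responses (2), n the number of events per response
(all sampled points pooled across runs) and v the residual cross-product
matrix.  The determinant criterion self-weights the responses, so no
explicit residual weighting is applied.

Optimization runs over the internal vector
(ln k_ref, Ea/(R*T_ref), ln K_ref, dH_r/(R*T_ref), ln K1): logarithms keep
the positive parameters positive, and the dimensionless enthalpy group puts
all coordinates on a common O(10) scale for the simplex.  A Nelder-Mead
search is followed by a quasi-Newton (BFGS) refinement, accepted only when
it improves the objective.

Uncertainty is a first-order curvature approximation: 95% marginal
highest-posterior-density half-widths t_{0.975,df} * SE with SE from the
inverse Hessian of S/2 at the optimum and df = n*m - p.  Parameters whose
curvature is structurally negligible (no information in the design) are
flagged indeterminate and carry no interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Collection, Iterable, Sequence

import numpy as np
from scipy import optimize, stats

from .kinetic_core import (
    ArrheniusParams,
    KineticParameters,
    R_GAS,
    VantHoffParams,
)
from .simulator import KineticDataset, simulate_run

__all__ = [
    "ResidualMatrix",
    "FitResult",
    "VantHoffFit",
    "FRIENDLY_NAMES",
    "residuals",
    "response_covariance",
    "objective",
    "objective_from_residuals",
    "fit",
    "hpd_intervals",
    "parameter_correlation",
    "vant_hoff_fit",
    "parity_r2",
    "parity_by_response",
]

#: Public (reporting) parameter names, in canonical order.
FRIENDLY_NAMES = ("ln_k_ref", "ea_over_RTref", "K_ref", "dH_r", "K1")
#: Internal optimization coordinates corresponding to FRIENDLY_NAMES.
_INTERNAL_NAMES = ("ln_k_ref", "ea_over_RTref", "ln_K_ref", "dh_over_RTref",
                   "ln_K1")
_TO_INTERNAL = dict(zip(FRIENDLY_NAMES, _INTERNAL_NAMES))

#: Relative curvature below which a parameter is structurally indeterminate.
_CURVATURE_FLOOR = 1e-10
#: Relative eigenvalue below which a curvature direction counts as null.
_EIGEN_FLOOR = 1e-6
#: HPD half-width above this percentage of the estimate is also flagged.
_HPD_PERCENT_CEILING = 1e3

_RIDGE = 1e-12


def _theta_from_params(p: KineticParameters) -> np.ndarray:
    return np.array([
        p.arrhenius.ln_k_ref,
        p.arrhenius.ea_over_RTref,
        math.log(p.vant_hoff.K_ref),
        p.vant_hoff.dh_over_RTref,
        math.log(p.K1) if p.K1 > 0 else -math.inf,
    ])


def _params_from_theta(theta: np.ndarray, T_ref: float) -> KineticParameters:
    return KineticParameters(
        arrhenius=ArrheniusParams(theta[0], theta[1], T_ref),
        vant_hoff=VantHoffParams(math.exp(theta[2]),
                                 theta[3] * R_GAS * T_ref, T_ref),
        K1=math.exp(theta[4]),
    )


def _friendly_estimates(theta: np.ndarray, T_ref: float) -> dict[str, float]:
    return {
        "ln_k_ref": theta[0],
        "ea_over_RTref": theta[1],
        "K_ref": math.exp(theta[2]),
        "dH_r": theta[3] * R_GAS * T_ref,
        "K1": math.exp(theta[4]),
    }


def _internal_indices(fixed: Collection[str]) -> tuple[int, ...]:
    """Indices of free internal coordinates given friendly/internal names."""
    fixed_internal = set()
    for name in fixed:
        if name in _TO_INTERNAL:
            fixed_internal.add(_TO_INTERNAL[name])
        elif name in _INTERNAL_NAMES:
            fixed_internal.add(name)
        else:
            raise ValueError(
                f"unknown parameter {name!r}; expected one of {FRIENDLY_NAMES}")
    return tuple(i for i, n in enumerate(_INTERNAL_NAMES)
                 if n not in fixed_internal)


@dataclass
class ResidualMatrix:
    """Observed-minus-predicted residuals, one row per response.

    ``r`` has shape (m, n): row 0 sesamin, row 1 asarinin; columns are the
    pooled events (all sampled points of all runs, in dataset order).
    """

    r: np.ndarray
    n: int
    m: int

    def __post_init__(self) -> None:
        self.r = np.atleast_2d(np.asarray(self.r, dtype=float))
        if self.r.shape != (self.m, self.n):
            raise ValueError(f"residual matrix shape {self.r.shape} != "
                             f"({self.m}, {self.n})")
        if not np.all(np.isfinite(self.r)):
            raise ValueError("residuals must be finite")


def residuals(dataset: KineticDataset, params: KineticParameters,
              include_t0: bool = True) -> ResidualMatrix:
    """Residuals Y - Yhat(theta) for both responses, pooled across runs.

    Predictions come from numerical integration at each profile's own time
    grid and conditions.  t=0 points (zero residual by construction for
    noise-free data) are included as events by default.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    rows_A, rows_B = [], []
    for prof in dataset:
        sim = simulate_run(prof.conditions, params, prof.times)
        sel = slice(None) if include_t0 else slice(1, None)
        rows_A.append(prof.C_A[sel] - sim.C_A[sel])
        rows_B.append(prof.C_B[sel] - sim.C_B[sel])
    r = np.vstack([np.concatenate(rows_A), np.concatenate(rows_B)])
    return ResidualMatrix(r=r, n=r.shape[1], m=2)


def response_covariance(res: ResidualMatrix) -> np.ndarray:
    """Residual cross-product matrix v(theta), m x m, symmetric PSD."""
    return res.r @ res.r.T


def objective_from_residuals(res: ResidualMatrix) -> float:
    """Determinant criterion S = (n+m+1) * ln|v + eps*I|.

    A tiny ridge eps = 1e-12 * max(1, tr v / m) regularizes the perfect-fit
    singularity so that noise-free self-consistency fits have a finite floor.
    """
    v = response_covariance(res)
    eps = _RIDGE * max(1.0, float(np.trace(v)) / res.m)
    sign, logdet = np.linalg.slogdet(v + eps * np.eye(res.m))
    if sign <= 0:
        return math.inf
    return (res.n + res.m + 1) * logdet


def objective(dataset: KineticDataset, params: KineticParameters,
              include_t0: bool = True) -> float:
    """S(theta) for a parameter set against a dataset (lower is better)."""
    return objective_from_residuals(residuals(dataset, params, include_t0))


@dataclass
class FitResult:
    """Estimates, uncertainty and diagnostics of one determinant-criterion fit.

    ``estimates``/``hpd`` are keyed by the public parameter names; HPD
    half-widths are in the same units as the estimates (delta-method rescale
    of the internally log/dimensionless coordinates).  Indeterminate
    parameters carry NaN half-widths and zeroed correlation rows.
    """

    estimates: dict[str, float]
    free: tuple[str, ...]
    fixed: dict[str, float]
    objective: float
    hpd: dict[str, float]
    hpd_percent: dict[str, float]
    indeterminate: dict[str, bool]
    correlation: np.ndarray
    correlation_names: tuple[str, ...]
    r2: dict[str, float]
    converged: bool
    n: int
    m: int
    nfev: int
    T_ref: float
    message: str = ""

    def parameters(self) -> KineticParameters:
        """Rebuild a KineticParameters from the estimates (K2 tied to K1)."""
        e = self.estimates
        return KineticParameters(
            arrhenius=ArrheniusParams(e["ln_k_ref"], e["ea_over_RTref"],
                                      self.T_ref),
            vant_hoff=VantHoffParams(e["K_ref"], e["dH_r"], self.T_ref),
            K1=e["K1"],
        )

    def to_dict(self) -> dict:
        """JSON-serializable report (versioned schema)."""
        def clean(d):
            return {k: (None if isinstance(v, float) and not math.isfinite(v)
                        else v) for k, v in d.items()}
        return {
            "schema_version": 1,
            "estimates": clean(self.estimates),
            "free": list(self.free),
            "fixed": clean(self.fixed),
            "objective": self.objective,
            "hpd_95": clean(self.hpd),
            "hpd_percent": clean(self.hpd_percent),
            "indeterminate": self.indeterminate,
            "correlation": {
                "names": list(self.correlation_names),
                "matrix": np.asarray(self.correlation).tolist(),
            },
            "r2": clean(self.r2),
            "converged": self.converged,
            "n_events_per_response": self.n,
            "n_responses": self.m,
            "nfev": self.nfev,
            "T_ref": self.T_ref,
            "message": self.message,
        }


def _make_objective(dataset: KineticDataset, theta_full: np.ndarray,
                    free_idx: tuple[int, ...], T_ref: float,
                    include_t0: bool):
    def f(x: np.ndarray) -> float:
        theta = theta_full.copy()
        theta[list(free_idx)] = x
        try:
            params = _params_from_theta(theta, T_ref)
            return objective(dataset, params, include_t0)
        except (ValueError, OverflowError, RuntimeError):
            return math.inf
    return f


def fit(dataset: KineticDataset, init: KineticParameters,
        fixed: Collection[str] = (), include_t0: bool = True,
        polish: bool = True, maxiter: int = 5000,
        compute_uncertainty: bool = True) -> FitResult:
    """Minimize the determinant criterion over the free parameters.

    ``fixed`` names parameters frozen at their ``init`` values (public names
    such as "K1").  Deterministic given (dataset, init, fixed).  On
    non-convergence the best point found is returned with ``converged=False``
    rather than raising.
    """
    T_ref = init.arrhenius.T_ref
    if init.K1 != init.K2:
        raise ValueError("fit assumes tied adsorption constants K2 = K1")
    theta_full = _theta_from_params(init)
    free_idx = _internal_indices(fixed)
    if not free_idx:
        raise ValueError("no free parameters to fit")
    if not np.all(np.isfinite(theta_full[list(free_idx)])):
        raise ValueError("initial guess must be finite in the free parameters")
    f = _make_objective(dataset, theta_full, free_idx, T_ref, include_t0)
    x0 = theta_full[list(free_idx)]

    nm = optimize.minimize(
        f, x0, method="Nelder-Mead",
        options={"xatol": 1e-5, "fatol": 1e-7, "maxiter": maxiter,
                 "maxfev": 2 * maxiter, "adaptive": True})
    best_x, best_f = nm.x, nm.fun
    nfev = nm.nfev
    converged = bool(nm.success)
    message = nm.message

    if polish:
        try:
            qn = optimize.minimize(f, best_x, method="BFGS",
                                   options={"maxiter": 200})
            nfev += qn.nfev
            if np.isfinite(qn.fun) and qn.fun < best_f:
                best_x, best_f = qn.x, qn.fun
        except Exception:  # refinement is best-effort
            pass

    theta_hat = theta_full.copy()
    theta_hat[list(free_idx)] = best_x
    params_hat = _params_from_theta(theta_hat, T_ref)
    estimates = _friendly_estimates(theta_hat, T_ref)
    free_names = tuple(FRIENDLY_NAMES[i] for i in free_idx)
    fixed_vals = {n: estimates[n] for n in FRIENDLY_NAMES if n not in free_names}

    res = residuals(dataset, params_hat, include_t0)
    if compute_uncertainty:
        hpd, hpd_pct, flags, corr = _curvature_uncertainty(
            dataset, theta_hat, free_idx, T_ref, include_t0, res.n, res.m)
    else:
        hpd = {n: math.nan for n in free_names}
        hpd_pct = dict(hpd)
        flags = {n: False for n in free_names}
        corr = np.eye(len(free_names))

    return FitResult(
        estimates=estimates, free=free_names, fixed=fixed_vals,
        objective=best_f, hpd=hpd, hpd_percent=hpd_pct,
        indeterminate=flags, correlation=corr, correlation_names=free_names,
        r2=parity_by_response(dataset, params_hat, include_t0),
        converged=converged, n=res.n, m=res.m, nfev=nfev, T_ref=T_ref,
        message=str(message))


def _sensitivities(dataset: KineticDataset, theta_hat: np.ndarray,
                   free_idx: tuple[int, ...], T_ref: float,
                   include_t0: bool, rel_step: float = 1e-4) -> np.ndarray:
    """Prediction sensitivities G[i, :, a] = dYhat_i/dtheta_a, shape (m, n, p).

    Central differences of the simulated responses; far better conditioned
    than second differences of the log-determinant objective, so near-null
    sensitivity directions (practical non-identifiability) are resolved.
    """
    p = len(free_idx)
    cols_A, cols_B = [], []
    for a in free_idx:
        h = rel_step * max(1.0, abs(theta_hat[a]))
        rows = {}
        for s in (+1.0, -1.0):
            theta = theta_hat.copy()
            theta[a] += s * h
            params = _params_from_theta(theta, T_ref)
            A_parts, B_parts = [], []
            for prof in dataset:
                sim = simulate_run(prof.conditions, params, prof.times)
                sel = slice(None) if include_t0 else slice(1, None)
                A_parts.append(sim.C_A[sel])
                B_parts.append(sim.C_B[sel])
            rows[s] = (np.concatenate(A_parts), np.concatenate(B_parts))
        cols_A.append((rows[1.0][0] - rows[-1.0][0]) / (2.0 * h))
        cols_B.append((rows[1.0][1] - rows[-1.0][1]) / (2.0 * h))
    G_A = np.column_stack(cols_A) if p else np.empty((0, 0))
    G_B = np.column_stack(cols_B)
    return np.stack([G_A, G_B])


def _gauss_newton_curvature(G: np.ndarray, res: ResidualMatrix) -> np.ndarray:
    """Gauss-Newton Hessian of S/2: H_ab = (n+m+1) * sum_ij W_ij G_ia.G_jb,

    with W the inverse of the (ridge-stabilized) residual cross-product
    matrix.  Reduces to (n+2) * J'J / SSR in the single-response case.
    """
    v = response_covariance(res)
    eps = _RIDGE * max(1.0, float(np.trace(v)) / res.m)
    W = np.linalg.inv(v + eps * np.eye(res.m))
    p = G.shape[2]
    H = np.zeros((p, p))
    for i in range(res.m):
        for j in range(res.m):
            H += W[i, j] * (G[i].T @ G[j])
    return (res.n + res.m + 1) * H


def _delta_scale(theta_hat: np.ndarray, idx: int, T_ref: float) -> float:
    """d(friendly)/d(internal) at theta_hat, for HPD unit conversion."""
    name = _INTERNAL_NAMES[idx]
    if name == "ln_K_ref":
        return math.exp(theta_hat[idx])
    if name == "dh_over_RTref":
        return R_GAS * T_ref
    if name == "ln_K1":
        return math.exp(theta_hat[idx])
    return 1.0


def _curvature_uncertainty(dataset, theta_hat, free_idx, T_ref, include_t0,
                           n, m):
    """95% marginal HPD half-widths, indeterminate flags and correlations.

    Structural indeterminacy is detected on the Gauss-Newton curvature: (a)
    a diagonal entry negligible against the largest (no sensitivity at all,
    e.g. the activation-energy group with a single-temperature design), and
    (b) near-null eigendirections (collinear sensitivities, e.g. the
    adsorption constant absorbing into the rate constant), flagging the
    dominant parameter of each such direction, mirroring how rank-deficient
    designs are reported in practice.
    """
    G = _sensitivities(dataset, theta_hat, free_idx, T_ref, include_t0)
    res = residuals(dataset, _params_from_theta(theta_hat, T_ref), include_t0)
    H = _gauss_newton_curvature(G, res)
    p = len(free_idx)
    free_names = tuple(FRIENDLY_NAMES[i] for i in free_idx)

    diag = np.abs(np.diag(H))
    scale = diag.max() if diag.max() > 0 else 1.0
    flags = {name: bool(diag[k] <= _CURVATURE_FLOOR * scale)
             for k, name in enumerate(free_names)}

    # Near-null eigendirections on the (scaled) remaining block: flag the
    # dominant parameter of each, then re-examine.  1e-6 is set by the
    # accuracy of the finite-difference sensitivities.
    while True:
        keep = [k for k, name in enumerate(free_names) if not flags[name]]
        if not keep:
            break
        Hk = H[np.ix_(keep, keep)]
        d = np.sqrt(np.diag(Hk))
        Hs = Hk / np.outer(d, d)
        w, V = np.linalg.eigh(Hs)
        if w[0] > _EIGEN_FLOOR * w[-1]:
            break
        worst = keep[int(np.argmax(np.abs(V[:, 0])))]
        flags[free_names[worst]] = True

    # Invert the curvature on the informative subspace only.
    cov = np.full((p, p), np.nan)
    if keep:
        Hk = H[np.ix_(keep, keep)]
        try:
            ck = np.linalg.inv(Hk)
        except np.linalg.LinAlgError:
            ck = np.linalg.pinv(Hk)
        for a, ia in enumerate(keep):
            for b, ib in enumerate(keep):
                cov[ia, ib] = ck[a, b]

    df = max(n * m - p, 1)
    tq = stats.t.ppf(0.975, df)
    estimates = _friendly_estimates(theta_hat, T_ref)
    hpd, hpd_pct = {}, {}
    for k, name in enumerate(free_names):
        var = cov[k, k]
        if flags[name] or not np.isfinite(var) or var <= 0:
            flags[name] = True
            hpd[name] = math.nan
            hpd_pct[name] = math.nan
            continue
        hw_internal = tq * math.sqrt(var)
        hw = hw_internal * _delta_scale(theta_hat, free_idx[k], T_ref)
        hpd[name] = hw
        est = estimates[name]
        pct = 100.0 * hw / abs(est) if est != 0 else math.inf
        hpd_pct[name] = pct
        if pct > _HPD_PERCENT_CEILING:
            flags[name] = True
            hpd[name] = math.nan
            hpd_pct[name] = math.nan

    corr = np.eye(p)
    for a in range(p):
        for b in range(p):
            if a == b:
                continue
            na, nb = free_names[a], free_names[b]
            if flags[na] or flags[nb]:
                corr[a, b] = 0.0
            else:
                corr[a, b] = cov[a, b] / math.sqrt(cov[a, a] * cov[b, b])
    return hpd, hpd_pct, flags, corr


def hpd_intervals(dataset: KineticDataset, params_hat: KineticParameters,
                  fixed: Collection[str] = (), include_t0: bool = True,
                  ) -> tuple[dict[str, float], dict[str, bool]]:
    """95% marginal HPD half-widths (public units) and indeterminate flags."""
    theta_hat = _theta_from_params(params_hat)
    free_idx = _internal_indices(fixed)
    res = residuals(dataset, params_hat, include_t0)
    hpd, _, flags, _ = _curvature_uncertainty(
        dataset, theta_hat, free_idx, params_hat.arrhenius.T_ref,
        include_t0, res.n, res.m)
    return hpd, flags


def parameter_correlation(dataset: KineticDataset,
                          params_hat: KineticParameters,
                          fixed: Collection[str] = (),
                          include_t0: bool = True,
                          ) -> tuple[np.ndarray, tuple[str, ...]]:
    """Normalized inverse-curvature correlation matrix of the free parameters.

    Rows/columns of indeterminate parameters are zeroed off-diagonal.
    """
    theta_hat = _theta_from_params(params_hat)
    free_idx = _internal_indices(fixed)
    res = residuals(dataset, params_hat, include_t0)
    _, _, _, corr = _curvature_uncertainty(
        dataset, theta_hat, free_idx, params_hat.arrhenius.T_ref,
        include_t0, res.n, res.m)
    names = tuple(FRIENDLY_NAMES[i] for i in free_idx)
    return corr, names


@dataclass(frozen=True)
class VantHoffFit:
    """Result of the two-stage Van't Hoff regression."""

    dH_r: float      # J/mol; positive = endothermic
    K_ref: float     # equilibrium constant at T_ref (from the intercept)
    T_ref: float


def vant_hoff_fit(K_by_T: Iterable[tuple[float, float]],
                  T_ref: float) -> VantHoffFit:
    """Regress per-temperature equilibrium constants on the Van't Hoff law.

    ln K is regressed on x = (1/R)*(1/T - 1/T_ref); under the Van't Hoff law
    ln K = ln K_ref - dH_r * x, so the slope is -dH_r.  The sign convention
    makes a positive recovered dH_r endothermic (K increasing with T).
    Exact recovery when the inputs lie on the curve.
    """
    pairs = [(float(T), float(K)) for T, K in K_by_T]
    temps = {T for T, _ in pairs}
    if len(temps) < 2:
        raise ValueError(
            "Van't Hoff regression needs >= 2 distinct temperatures, "
            f"got {sorted(temps)}")
    for T, K in pairs:
        if T <= 0 or K <= 0:
            raise ValueError(f"invalid (T, K) pair ({T}, {K})")
    x = np.array([(1.0 / R_GAS) * (1.0 / T - 1.0 / T_ref) for T, _ in pairs])
    y = np.array([math.log(K) for _, K in pairs])
    slope, intercept = np.polyfit(x, y, 1)
    return VantHoffFit(dH_r=-float(slope), K_ref=float(math.exp(intercept)),
                       T_ref=T_ref)


def parity_r2(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Coefficient of determination of a parity (predicted-vs-observed) plot.

    Returns NaN when the observations are constant (R2 undefined); may be
    negative for predictions worse than the observation mean.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("observed/predicted must be equal-length, size >= 2")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        return math.nan
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def parity_by_response(dataset: KineticDataset, params: KineticParameters,
                       include_t0: bool = True) -> dict[str, float]:
    """Per-response parity R2 of a parameter set against a dataset."""
    res = residuals(dataset, params, include_t0)
    obs_A, obs_B = [], []
    for prof in dataset:
        sel = slice(None) if include_t0 else slice(1, None)
        obs_A.append(prof.C_A[sel])
        obs_B.append(prof.C_B[sel])
    obs_A = np.concatenate(obs_A)
    obs_B = np.concatenate(obs_B)
    return {
        "sesamin": parity_r2(obs_A, obs_A - res.r[0]),
        "asarinin": parity_r2(obs_B, obs_B - res.r[1]),
    }
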