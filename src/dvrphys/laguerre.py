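"""Two-input linear dynamic model estimation with a discrete Laguerre basis.

Cerebral blood flow velocity (CBFV) at rest is modelled as the output of a
linear time-invariant two-input system driven by arterial blood pressure
(ABP, the pressure-autoregulation branch) and end-tidal CO2 (ETCO2, the
vasomotor-reactivity branch).  Each first-order kernel is expanded on an
orthonormal family of discrete Laguerre functions, which compresses a
smooth, exponentially decaying impulse response of memory M samples into a
handful of coefficients, and the expansion coefficients are estimated by
(optionally ridge-regularised) least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class RankDeficientError(np.linalg.LinAlgError):
    """Raised when the regression system is rank deficient and no ridge is used."""


@dataclass(frozen=True)
class LaguerreBasis:
    """Discrete Laguerre functions b_j(m), j=0..L-1, truncated at memory M.

    The functions are generated with pole ``alpha`` (0 <= alpha < 1) by the
    standard stable recursion; they are orthonormal over m = 0..inf, with
    truncation error at lag M of order alpha**M.  The zeroth function is
    b_0(m) = sqrt(1 - alpha**2) * alpha**m.
    """

    alpha: float
    L: int
    M: int
    values: np.ndarray = field(repr=False)  # shape (L, M)

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError(f"alpha must be in [0, 1), got {self.alpha}")
        if self.L < 1:
            raise ValueError("need at least one basis function")
        if self.M < self.L:
            raise ValueError("memory M must be >= number of functions L")


def laguerre_basis(alpha: float, L: int, M: int) -> LaguerreBasis:
    """Construct the discrete Laguerre basis with pole ``alpha``.

    Uses the recursion implied by the z-domain cascade
    B_j(z) = B_{j-1}(z) * (z^-1 - alpha) / (1 - alpha z^-1):

        b_j(m) = alpha * b_j(m-1) + b_{j-1}(m-1) - alpha * b_{j-1}(m)

    which is numerically stable for all alpha in [0, 1).
    """
    if not 0.0 <= alpha < 1.0:
        raise ValueError(f"alpha must be in [0, 1), got {alpha}")
    if L < 1 or M < L:
        raise ValueError(f"require L >= 1 and M >= L, got L={L}, M={M}")
    b = np.zeros((L, M))
    b[0] = np.sqrt(1.0 - alpha**2) * alpha ** np.arange(M)
    for j in range(1, L):
        b[j, 0] = -alpha * b[j - 1, 0]
        for m in range(1, M):
            b[j, m] = alpha * b[j, m - 1] + b[j - 1, m - 1] - alpha * b[j - 1, m]
    return LaguerreBasis(alpha=alpha, L=L, M=M, values=b)


def convolve_basis(x: np.ndarray, basis: LaguerreBasis) -> np.ndarray:
    """Convolve an input series with every basis function.

    Returns an (n, L) regressor table whose column j at row n is
    sum_{m=0}^{M-1} b_j(m) * x[n-m] (x treated as zero for negative
    indices).  The first M-1 rows are burn-in: they involve samples
    before the start of the record and must be excluded from fitting.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("input series must be one-dimensional")
    n = x.size
    if n <= basis.M:
        raise ValueError(f"series length {n} must exceed basis memory M={basis.M}")
    cols = np.empty((n, basis.L))
    for j in range(basis.L):
        cols[:, j] = np.convolve(x, basis.values[j])[:n]
    return cols


@dataclass
class FitReport:
    """Diagnostics from a model fit or structure search."""

    nmse_train: float
    nmse_validation: float | None
    condition: float
    structure: dict


@dataclass
class TwoInputModel:
    """Fitted two-input Laguerre-expansion model ABP, ETCO2 -> CBFV.

    Coefficients ``a_p``/``a_c`` weight the Laguerre functions of each
    branch; the first-order kernels are recovered by ``kernel_of``.
    """

    basis_p: LaguerreBasis
    basis_c: LaguerreBasis
    a_p: np.ndarray
    a_c: np.ndarray
    intercept: float
    dt: float
    fit_nmse: float

    @property
    def memory(self) -> int:
        return max(self.basis_p.M, self.basis_c.M)

    def to_dict(self) -> dict:
        return {
            "dt": self.dt,
            "intercept": self.intercept,
            "fit_nmse": self.fit_nmse,
            "abp": {"alpha": self.basis_p.alpha, "L": self.basis_p.L,
                    "M": self.basis_p.M, "coefficients": self.a_p.tolist()},
            "etco2": {"alpha": self.basis_c.alpha, "L": self.basis_c.L,
                      "M": self.basis_c.M, "coefficients": self.a_c.tolist()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TwoInputModel":
        bp = laguerre_basis(d["abp"]["alpha"], d["abp"]["L"], d["abp"]["M"])
        bc = laguerre_basis(d["etco2"]["alpha"], d["etco2"]["L"], d["etco2"]["M"])
        return cls(basis_p=bp, basis_c=bc,
                   a_p=np.asarray(d["abp"]["coefficients"], dtype=float),
                   a_c=np.asarray(d["etco2"]["coefficients"], dtype=float),
                   intercept=float(d["intercept"]), dt=float(d["dt"]),
                   fit_nmse=float(d["fit_nmse"]))


def kernel_of(model: TwoInputModel, branch: str) -> np.ndarray:
    """First-order kernel k(m) = sum_j a_j b_j(m) of the requested branch.

    ``branch`` is "abp" (pressure) or "etco2" (CO2 / vasomotor).
    """
    if branch == "abp":
        return model.a_p @ model.basis_p.values
    if branch == "etco2":
        return model.a_c @ model.basis_c.values
    raise ValueError(f"unknown branch {branch!r}; expected 'abp' or 'etco2'")


def _design(abp, etco2, basis_p, basis_c):
    vp = convolve_basis(abp, basis_p)
    vc = convolve_basis(etco2, basis_c)
    n = vp.shape[0]
    X = np.column_stack([np.ones(n), vp, vc])
    burn = max(basis_p.M, basis_c.M) - 1
    return X, burn


def _nmse(resid: np.ndarray, y: np.ndarray) -> float:
    denom = float(np.sum(y**2))
    if denom == 0.0:
        return 0.0 if np.allclose(resid, 0) else np.inf
    return float(np.sum(resid**2) / denom)


def fit_two_input_model(series, basis_p: LaguerreBasis, basis_c: LaguerreBasis,
                        ridge: float = 0.0):
    """Least-squares fit of the two-input model on a uniform beat series.

    ``series`` is any object with demeaned ``abp``, ``etco2``, ``cbfv``
    arrays and a ``dt`` (a :class:`dvrphys.preprocess.UniformSeries`).
    The intercept is never penalised; ``ridge`` adds lam * I to the
    normal equations of the kernel coefficients.  Training NMSE is
    residual power divided by output power over the post-burn-in span.

    Returns ``(model, report)``.
    """
    abp = np.asarray(series.abp, dtype=float)
    etco2 = np.asarray(series.etco2, dtype=float)
    y_full = np.asarray(series.cbfv, dtype=float)
    if not (abp.size == etco2.size == y_full.size):
        raise ValueError("abp, etco2 and cbfv must have equal lengths")
    X_full, burn = _design(abp, etco2, basis_p, basis_c)
    X, y = X_full[burn:], y_full[burn:]
    p = X.shape[1]
    if X.shape[0] < 2 * p:
        raise ValueError(
            f"series too short: {X.shape[0]} usable samples for {p} parameters")
    beta, cond = _solve(X, y, ridge)
    resid = y - X @ beta
    nmse = _nmse(resid, y)
    model = TwoInputModel(basis_p=basis_p, basis_c=basis_c,
                          a_p=beta[1:1 + basis_p.L],
                          a_c=beta[1 + basis_p.L:],
                          intercept=float(beta[0]), dt=float(series.dt),
                          fit_nmse=nmse)
    report = FitReport(nmse_train=nmse, nmse_validation=None, condition=cond,
                       structure={"alpha_p": basis_p.alpha, "L_p": basis_p.L,
                                  "alpha_c": basis_c.alpha, "L_c": basis_c.L,
                                  "ridge": ridge})
    return model, report


def _solve(X: np.ndarray, y: np.ndarray, ridge: float):
    """Solve the (optionally ridge-penalised) normal equations.

    Raises :class:`RankDeficientError` when lam = 0 and the design is
    numerically rank deficient, advising a ridge penalty.
    """
    G = X.T @ X
    sv = np.linalg.svd(X, compute_uv=False)
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
    if ridge == 0.0:
        rank = np.linalg.matrix_rank(X, tol=sv[0] * max(X.shape) * np.finfo(float).eps)
        if rank < X.shape[1]:
            raise RankDeficientError(
                "regressor matrix is rank deficient (collinear inputs?); "
                "refit with a small ridge penalty, e.g. ridge=1e-6 * mean diag")
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        return beta, cond
    P = np.eye(X.shape[1]) * ridge
    P[0, 0] = 0.0  # intercept unpenalised
    beta = np.linalg.solve(G + P, X.T @ y)
    return beta, cond


def predict(model: TwoInputModel, abp, etco2):
    """Predicted CBFV and NMSE against an observed output, if provided.

    Prediction = intercept + k_p * abp + k_c * etco2 (discrete
    convolutions over each branch's memory).  Returns the full-length
    prediction; use ``burn = model.memory - 1`` to discard edge samples.
    """
    abp = np.asarray(abp, dtype=float)
    etco2 = np.asarray(etco2, dtype=float)
    if abp.size != etco2.size:
        raise ValueError("abp and etco2 must have equal lengths")
    if abp.size <= model.memory:
        raise ValueError("inputs must be longer than the model memory")
    kp = kernel_of(model, "abp")
    kc = kernel_of(model, "etco2")
    n = abp.size
    yhat = (model.intercept
            + np.convolve(abp, kp)[:n]
            + np.convolve(etco2, kc)[:n])
    return yhat


def prediction_nmse(model: TwoInputModel, abp, etco2, cbfv) -> float:
    """NMSE of the model prediction against an observed CBFV series."""
    cbfv = np.asarray(cbfv, dtype=float)
    yhat = predict(model, abp, etco2)
    burn = model.memory - 1
    return _nmse(cbfv[burn:] - yhat[burn:], cbfv[burn:])


def select_structure(series, alpha_grid, L_grid, ridge: float = 0.0,
                     train_frac: float = 0.7):
    """Exhaustive (alpha, L) grid search per branch on a temporal split.

    The series is split in time order (first ``train_frac`` for fitting,
    the rest for validation) to avoid leakage across the autocorrelated
    record.  The structure minimising validation NMSE wins; ties go to
    smaller total L, then smaller alpha.  Returns
    ``(model_refit_on_all_data, report)``.
    """
    alpha_grid = list(alpha_grid)
    L_grid = list(L_grid)
    if not alpha_grid or not L_grid:
        raise ValueError("alpha_grid and L_grid must be nonempty")
    n = len(series.cbfv)
    n_train = int(round(train_frac * n))
    train = _slice_series(series, 0, n_train)
    candidates = [(a_p, L_p, a_c, L_c)
                  for a_p in alpha_grid for L_p in L_grid
                  for a_c in alpha_grid for L_c in L_grid]
    best = None
    n_failed = 0
    for a_p, L_p, a_c, L_c in candidates:
        bp = laguerre_basis(a_p, L_p, max(_default_M(a_p), L_p))
        bc = laguerre_basis(a_c, L_c, max(_default_M(a_c), L_c))
        try:
            model, _ = fit_two_input_model(train, bp, bc, ridge=ridge)
        except (RankDeficientError, ValueError):
            n_failed += 1
            continue
        val_nmse = prediction_nmse(
            model,
            np.asarray(series.abp)[n_train - model.memory:],
            np.asarray(series.etco2)[n_train - model.memory:],
            np.asarray(series.cbfv)[n_train - model.memory:])
        key = (round(val_nmse, 12), L_p + L_c, a_p + a_c)
        if best is None or key < best[0]:
            best = (key, (a_p, L_p, a_c, L_c), val_nmse)
    if best is None:
        raise RankDeficientError("all candidate structures were rank deficient")
    (a_p, L_p, a_c, L_c) = best[1]
    bp = laguerre_basis(a_p, L_p, max(_default_M(a_p), L_p))
    bc = laguerre_basis(a_c, L_c, max(_default_M(a_c), L_c))
    model, rep = fit_two_input_model(series, bp, bc, ridge=ridge)
    report = FitReport(nmse_train=rep.nmse_train, nmse_validation=best[2],
                       condition=rep.condition,
                       structure={"alpha_p": a_p, "L_p": L_p,
                                  "alpha_c": a_c, "L_c": L_c, "ridge": ridge})
    return model, report


def _default_M(alpha: float, M: int = 50) -> int:
    """Memory long enough that truncation error alpha**M is negligible."""
    return M


def _slice_series(series, start: int, stop: int):
    from .preprocess import UniformSeries

    return UniformSeries(
        dt=series.dt,
        abp=np.asarray(series.abp)[start:stop],
        etco2=np.asarray(series.etco2)[start:stop],
        cbfv=np.asarray(series.cbfv)[start:stop],
        baseline_abp=series.baseline_abp,
        baseline_etco2=series.baseline_etco2,
        baseline_cbfv=series.baseline_cbfv,
    )
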