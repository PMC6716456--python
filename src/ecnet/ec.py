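"""Static and dynamic effective connectivity via Granger causality.

Static: a first-order multivariate autoregression augmented with a
zero-lag term,

    Z(t) = M0' Z(t) + M1' Z(t-1) + ... + Mp' Z(t-p) + E(t),

fitted per target column by least squares.  The zero-lag coefficients M0
(zero diagonal) absorb instantaneous cross-correlation so it cannot leak
into the lagged coefficients; Granger causality from region i to j is the
sum of the lagged coefficients, GC_ij = sum_n M(n)[i, j].

Dynamic: the same regression with time-varying coefficients, estimated by
a Kalman-filter / recursive-least-squares recursion with a forgetting
factor.  Forgetting 1 reproduces the batch fit asymptotically (the
"well-conditioned" configuration); forgetting < 1 down-weights old
evidence and tracks coefficient drift.  DGC_ij(t) sums the lagged
coefficients at each t; its variance over retained timepoints is the
edge-wise connectivity-variability measure.

Coefficient matrices are indexed [source, target] throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import ROITimeSeries, standardize_columns


@dataclass
class MVARFit:
    M0: np.ndarray                    # (k, k), zero diagonal
    M: list[np.ndarray]               # lag matrices M(1)..M(p), each (k, k)
    residuals: np.ndarray             # (T - p, k)
    order: int

    @property
    def k(self) -> int:
        return self.M0.shape[0]


@dataclass
class SECMatrix:
    gc: np.ndarray                    # (k, k), [i, j] = GC i -> j, zero diagonal


@dataclass
class DMVARFit:
    M0t: np.ndarray                   # (T, k, k) instantaneous coefficients
    Mt: np.ndarray                    # (p, T, k, k) lagged coefficients
    forgetting: float
    state_cov_init: float
    prediction_errors: np.ndarray     # (T - p, k)
    order: int


@dataclass
class DECSeries:
    dgc: np.ndarray                   # (T, k, k), [t, i, j] = DGC i -> j at t
    tr: float = 1.0


@dataclass
class ECVariance:
    vdec: np.ndarray                  # (k, k) variance of DGC over retained t
    burn_in: int


def _design(data: np.ndarray, j: int, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Regressors for target column j: other columns at t, all columns at t-1..t-p."""
    T, k = data.shape
    others = [i for i in range(k) if i != j]
    cols = [data[p:, others]]
    for n in range(1, p + 1):
        cols.append(data[p - n:T - n, :])
    return np.column_stack(cols), data[p:, j]


def _check_rank(X: np.ndarray) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, s, vt = np.linalg.svd(X, full_matrices=False)
        null = vt[rank:]
        offenders = sorted(set(np.argmax(np.abs(null), axis=1).tolist()))
        raise ValueError(f"rank-deficient predictor matrix (rank {rank} < {X.shape[1]}); "
                         f"offending columns ~ {offenders}")


def fit_mvar(ts: ROITimeSeries, p: int = 1, standardize: bool = True) -> MVARFit:
    """Least-squares fit of the zero-lag-augmented order-p MVAR."""
    if p < 1:
        raise ValueError("order p must be >= 1")
    data = ts.data
    T, k = data.shape
    if T <= 10 * k * (p + 1):
        raise ValueError(f"T={T} too short for k={k}, p={p} (need > {10 * k * (p + 1)})")
    if standardize:
        data = standardize_columns(data)
    M0 = np.zeros((k, k))
    M = [np.zeros((k, k)) for _ in range(p)]
    resid = np.empty((T - p, k))
    for j in range(k):
        X, y = _design(data, j, p)
        _check_rank(X)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        others = [i for i in range(k) if i != j]
        M0[others, j] = beta[:k - 1]
        for n in range(p):
            M[n][:, j] = beta[k - 1 + n * k: k - 1 + (n + 1) * k]
        resid[:, j] = y - X @ beta
    return MVARFit(M0=M0, M=M, residuals=resid, order=p)


def static_gc(fit: MVARFit) -> SECMatrix:
    """GC_ij = sum of lagged coefficients; zero-lag M0 excluded; zero diagonal."""
    gc = np.sum(fit.M, axis=0)
    np.fill_diagonal(gc, 0.0)
    return SECMatrix(gc=gc)


def kalman_dmvar(ts: ROITimeSeries, p: int = 1, forgetting: float = 1.0,
                 state_cov_init: float = 1.0, standardize: bool = True) -> DMVARFit:
    """Recursive (Kalman / RLS-with-forgetting) fit of the dynamic MVAR.

    Per target column, the stacked coefficient vector follows a
    random-walk state model realized through covariance inflation by
    1/forgetting at each step; coefficients start at 0 with state
    covariance ``state_cov_init * I``.  Coefficient trajectories are
    defined for t >= p (earlier timepoints hold the zero initial state);
    one-step prediction errors are returned for diagnostics.
    """
    if not (0.9 < forgetting <= 1.0):
        raise ValueError("forgetting must lie in (0.9, 1]")
    data = ts.data
    T, k = data.shape
    if standardize:
        data = standardize_columns(data)
    M0t = np.zeros((T, k, k))
    Mt = np.zeros((p, T, k, k))
    pe = np.empty((T - p, k))
    m = (k - 1) + p * k
    for j in range(k):
        X, y = _design(data, j, p)
        others = np.array([i for i in range(k) if i != j])
        beta = np.zeros(m)
        P = np.eye(m) * state_cov_init
        for t in range(T - p):
            x = X[t]
            Px = P @ x
            denom = forgetting + x @ Px
            K = Px / denom
            err = y[t] - x @ beta
            beta = beta + K * err
            P = (P - np.outer(K, Px)) / forgetting
            P = (P + P.T) / 2.0  # re-symmetrize; drift here destabilizes the recursion
            if not np.all(np.isfinite(beta)) or not np.all(np.isfinite(P)):
                raise FloatingPointError(f"state covariance blow-up at t={t + p} (target {j})")
            pe[t, j] = err
            M0t[t + p, others, j] = beta[:k - 1]
            for n in range(p):
                Mt[n, t + p, :, j] = beta[k - 1 + n * k: k - 1 + (n + 1) * k]
    return DMVARFit(M0t=M0t, Mt=Mt, forgetting=forgetting,
                    state_cov_init=state_cov_init, prediction_errors=pe, order=p)


def dynamic_gc(fit_dyn: DMVARFit, tr: float = 1.0) -> DECSeries:
    """DGC_ij(t) = sum over lags of the coefficient trajectories; zero diagonal."""
    dgc = fit_dyn.Mt.sum(axis=0)
    idx = np.arange(dgc.shape[1])
    dgc[:, idx, idx] = 0.0
    return DECSeries(dgc=dgc, tr=tr)


def default_burn_in(T: int) -> int:
    """Filter-transient prefix excluded from DEC variance."""
    return max(50, int(0.05 * T))


def dec_variance(dec: DECSeries, burn_in: int | None = None) -> ECVariance:
    """Sample variance of DGC_ij(t) over t >= burn_in."""
    T = dec.dgc.shape[0]
    if burn_in is None:
        burn_in = default_burn_in(T)
    if burn_in >= T / 2:
        raise ValueError("burn_in must be below T/2")
    v = dec.dgc[burn_in:].var(axis=0)  # population variance over retained t
    idx = np.arange(v.shape[0])
    v[idx, idx] = 0.0
    return ECVariance(vdec=v, burn_in=burn_in)
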