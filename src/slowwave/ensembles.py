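"""Cell-assembly extraction by non-negative matrix factorization (NMF).

The spike raster of the excitatory population is binned into a
non-negative firing-rate matrix D (neurons x time windows; 200 ms windows
sliding at 50 ms by default, i.e. rate vectors sampled at 20 Hz).  NMF
approximates D ~= B C with non-negative basis patterns B (columns are
co-activation patterns, the cell assemblies) and activation time courses
C.  The factorization order k is selected by Akaike's information
criterion with small-sample correction (AICc) under a Gaussian residual
model::

    AICc(k) = n ln(RSS/n) + 2K + 2K(K+1)/(n - K - 1),
    K = k (n_rows + n_cols),  n = number of matrix entries.

The factorization itself uses the classical multiplicative updates, whose
Frobenius objective is non-increasing per iteration, with a deterministic
SVD-based initialisation plus seeded random restarts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _stats

__all__ = [
    "RateMatrix",
    "NMFResult",
    "build_rate_matrix",
    "nmf",
    "select_nmf_order",
    "assembly_statistics",
    "pattern_activation_correlation",
]

_EPS = 1e-12


@dataclass
class RateMatrix:
    """Firing-rate matrix: rows = excitatory neurons, columns = windows."""

    D: np.ndarray          # (n_neurons, n_windows), Hz, >= 0
    window: float          # ms
    step: float            # ms
    t_centers: np.ndarray  # ms

    def __post_init__(self):
        if np.any(self.D < 0):
            raise ValueError("rate matrix must be non-negative")


def build_rate_matrix(
    spike_ids: np.ndarray,
    spike_times: np.ndarray,
    n_neurons: int,
    T: float,
    window: float = 200.0,
    step: float = 50.0,
    t_start: float = 0.0,
) -> RateMatrix:
    """Bin spikes of neurons 0..n_neurons-1 into sliding-window rates (Hz).

    Window b covers ``[t_start + b*step, t_start + b*step + window)``;
    ``step == window`` gives the non-overlapping variant.  ``T`` is the
    end of the raster; entries are counts divided by the window length.
    """
    span = T - t_start
    if window > span:
        raise ValueError("window longer than the raster span")
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    n_win = int(np.floor((span - window) / step)) + 1
    m = (spike_ids < n_neurons) & (spike_times >= t_start) & (spike_times < T)
    ids, ts = spike_ids[m], spike_times[m] - t_start
    D = np.zeros((n_neurons, n_win))
    # each spike falls into the run of windows whose start is within
    # (t - window, t]
    for b in range(n_win):
        lo = b * step
        sel = (ts >= lo) & (ts < lo + window)
        if sel.any():
            np.add.at(D[:, b], ids[sel], 1.0)
    D /= window / 1000.0
    t_centers = t_start + np.arange(n_win) * step + window / 2.0
    return RateMatrix(D=D, window=window, step=step, t_centers=t_centers)


def _nndsvd_init(D: np.ndarray, k: int):
    """Deterministic non-negative double-SVD initialisation (averaged
    variant: zeros are replaced by the matrix mean)."""
    U, S, Vt = np.linalg.svd(D, full_matrices=False)
    W = np.zeros((D.shape[0], k))
    H = np.zeros((k, D.shape[1]))
    W[:, 0] = np.sqrt(S[0]) * np.abs(U[:, 0])
    H[0] = np.sqrt(S[0]) * np.abs(Vt[0])
    for j in range(1, min(k, S.size)):
        u, v = U[:, j], Vt[j]
        up, un = np.maximum(u, 0), np.maximum(-u, 0)
        vp, vn = np.maximum(v, 0), np.maximum(-v, 0)
        npos = np.linalg.norm(up) * np.linalg.norm(vp)
        nneg = np.linalg.norm(un) * np.linalg.norm(vn)
        if npos >= nneg:
            scale = np.sqrt(S[j] * npos)
            W[:, j] = scale * up / (np.linalg.norm(up) + _EPS)
            H[j] = scale * vp / (np.linalg.norm(vp) + _EPS)
        else:
            scale = np.sqrt(S[j] * nneg)
            W[:, j] = scale * un / (np.linalg.norm(un) + _EPS)
            H[j] = scale * vn / (np.linalg.norm(vn) + _EPS)
    mean = D.mean()
    W[W <= 0] = mean
    H[H <= 0] = mean
    return W, H


def nmf(
    D: np.ndarray,
    k: int,
    init: str = "nndsvda",
    seed=None,
    max_iter: int = 300,
    tol: float = 1e-6,
):
    """Multiplicative-update NMF of a non-negative matrix.

    Returns ``(W, H, objective_trace)`` where the trace is the Frobenius
    RSS after every iteration (non-increasing by construction of the
    updates).
    """
    D = np.asarray(D, dtype=float)
    if np.any(D < 0):
        raise ValueError("NMF input must be non-negative")
    if not 1 <= k <= min(D.shape):
        raise ValueError("k must be in [1, min(D.shape)]")
    if init == "nndsvda":
        W, H = _nndsvd_init(D, k)
    elif init == "random":
        rng = np.random.default_rng(seed)
        scale = np.sqrt(D.mean() / max(k, 1))
        W = rng.random((D.shape[0], k)) * scale + _EPS
        H = rng.random((k, D.shape[1])) * scale + _EPS
    else:
        raise ValueError(f"unknown init {init!r}")
    trace = []
    prev = None
    for _ in range(max_iter):
        H *= (W.T @ D) / (W.T @ W @ H + _EPS)
        W *= (D @ H.T) / (W @ (H @ H.T) + _EPS)
        rss = float(np.sum((D - W @ H) ** 2))
        trace.append(rss)
        if prev is not None and prev - rss <= tol * max(prev, 1.0):
            break
        prev = rss
    return W, H, np.asarray(trace)


@dataclass
class NMFResult:
    """AICc-selected factorization D ~= B @ Cmat."""

    B: np.ndarray            # (n_neurons, k) basis patterns
    Cmat: np.ndarray         # (k, n_windows) activations
    k: int
    aicc_trace: list         # [(k, AICc), ...] over the scanned orders
    rss: float
    rss_by_k: dict
    objective_trace: np.ndarray  # per-iteration RSS of the selected fit

    def reconstruction(self) -> np.ndarray:
        return self.B @ self.Cmat


def select_nmf_order(
    D: RateMatrix | np.ndarray,
    k_range: Sequence[int] = range(1, 16),
    restarts: int = 3,
    seed=0,
    max_iter: int = 300,
) -> NMFResult:
    """Scan factorization orders and keep the AICc minimiser.

    For each k the best of (deterministic + ``restarts - 1`` random seeded)
    initialisations by RSS is kept; ties in AICc break toward the smaller
    k.  Orders with ``n - K - 1 <= 0`` are excluded with a warning.
    """
    mat = D.D if isinstance(D, RateMatrix) else np.asarray(D, dtype=float)
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    n = mat.size
    rows, cols = mat.shape
    ss = np.random.SeedSequence(seed)
    best = None
    aicc_trace = []
    rss_by_k = {}
    for k in k_range:
        if not 1 <= k < min(rows, cols):
            continue
        K = k * (rows + cols)
        if n - K - 1 <= 0:
            warnings.warn(
                f"order k={k} leaves no residual degrees of freedom "
                f"(n={n}, K={K}); excluded from the scan"
            )
            continue
        fits = [nmf(mat, k, init="nndsvda", max_iter=max_iter)]
        for child in ss.spawn(restarts - 1):
            fits.append(nmf(mat, k, init="random", seed=child, max_iter=max_iter))
        W, H, tr = min(fits, key=lambda f: f[2][-1])
        rss = float(tr[-1])
        rss_by_k[k] = rss
        aicc = n * np.log(max(rss, _EPS) / n) + 2 * K + 2 * K * (K + 1) / (n - K - 1)
        aicc_trace.append((k, float(aicc)))
        if best is None or aicc < best[0] - 1e-12:
            best = (float(aicc), k, W, H, tr, rss)
    if best is None:
        raise ValueError("no admissible order in k_range")
    _, k, W, H, tr, rss = best
    return NMFResult(B=W, Cmat=H, k=k, aicc_trace=aicc_trace, rss=rss,
                     rss_by_k=rss_by_k, objective_trace=tr)


@dataclass
class AssemblyCorrelation:
    """Correlation of NMF order with mean transient-UP duration."""

    r_order: float
    p_order: float
    r_normalized: float
    p_normalized: float
    n_conditions: int

    @property
    def defined(self) -> bool:
        return np.isfinite(self.r_order)


def assembly_statistics(
    orders: Sequence[float],
    mean_up_durations: Sequence[float],
    total_up_durations: Sequence[float] | None = None,
) -> AssemblyCorrelation:
    """Pearson correlation of NMF order vs log mean UP duration.

    ``total_up_durations`` (summed UP time per condition) normalises the
    order for the second correlation; defaults to the mean durations.
    Degenerate (constant) inputs yield NaN correlations rather than an
    error.
    """
    o = np.asarray(orders, dtype=float)
    d = np.asarray(mean_up_durations, dtype=float)
    if o.size != d.size:
        raise ValueError("orders and durations must have equal length")
    if o.size < 5:
        raise ValueError("need at least 5 conditions")
    tot = np.asarray(total_up_durations, dtype=float) if total_up_durations is not None else d
    logd = np.log(d)
    def _corr(x, y):
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return np.nan, np.nan
        r, p = _stats.pearsonr(x, y)
        return float(r), float(p)
    r1, p1 = _corr(o, logd)
    r2, p2 = _corr(o / tot, logd)
    return AssemblyCorrelation(r_order=r1, p_order=p1, r_normalized=r2,
                               p_normalized=p2, n_conditions=int(o.size))


def pattern_activation_correlation(result: NMFResult) -> float:
    """Mean pairwise Pearson correlation of the activation time courses.

    NaN for k = 1 (undefined) or when an activation row is constant.
    """
    C = result.Cmat
    k = C.shape[0]
    if k < 2:
        return np.nan
    vals = []
    for i in range(k):
        for j in range(i + 1, k):
            if np.ptp(C[i]) == 0 or np.ptp(C[j]) == 0:
                continue
            vals.append(np.corrcoef(C[i], C[j])[0, 1])
    return float(np.mean(vals)) if vals else np.nan
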