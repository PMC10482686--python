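"""Bray-Curtis dissimilarity and non-metric multidimensional scaling.

Community turnover between specimen-rarefied samples is measured with the
Bray-Curtis dissimilarity on square-root-transformed abundances,

    BC(x, y) = sum_i |x'_i - y'_i| / sum_i (x'_i + y'_i),   x'_i = sqrt(x_i),

the square root damping the influence of the few numerically dominant
morphotypes. Ordination uses Kruskal-style non-metric MDS: a k-dimensional
configuration is sought whose inter-point distances d_hat reproduce the
*rank order* of the input dissimilarities, measured by stress-1

    stress = sqrt( sum (d_hat_ij - d*_ij)^2 / sum d_hat_ij^2 ),

where d* is the least-squares monotone (isotonic) regression of d_hat on
the ranked dissimilarities, fitted by pool-adjacent-violators. Ties are
handled by Kruskal's primary approach: within a tied block the current
configuration distances set the order, so ties never inflate stress.
Stress is minimised by steepest descent with step halving (monotone
non-increasing by construction), and the best of ``n_restarts`` seeded
random starts is returned, centred and rotated to principal axes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import CommunitySample
from .zonation import ProvinceScheme, classify_province

__all__ = [
    "DissimilarityMatrix",
    "OrdinationResult",
    "abundance_matrix",
    "bray_curtis",
    "isotonic_fit",
    "nmds",
    "ordination_report",
]


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise dissimilarities in [0, 1] with a zero diagonal."""

    sample_ids: list[str]
    values: np.ndarray
    transform: str = "sqrt"

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.sample_ids):
            raise ValueError("matrix shape must match sample ids")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(self.n, 1)
        return self.values[iu]


@dataclass
class OrdinationResult:
    coordinates: np.ndarray  # n x k, centred, principal-axis rotated
    stress: float
    n_restarts: int
    converged: bool
    seed: int
    stress_history: list[float] = field(default_factory=list)


def abundance_matrix(samples: Sequence[CommunitySample]) -> pd.DataFrame:
    """Samples-by-taxa abundance matrix over the shared taxon universe."""
    taxa = sorted({t for s in samples for t in s.abundances})
    data = np.zeros((len(samples), len(taxa)))
    index = {t: j for j, t in enumerate(taxa)}
    for i, s in enumerate(samples):
        for t, v in s.abundances.items():
            data[i, index[t]] = v
    return pd.DataFrame(data, index=[s.sample_id for s in samples], columns=taxa)


def bray_curtis(
    samples: Sequence[CommunitySample] | pd.DataFrame, transform: str = "sqrt"
) -> DissimilarityMatrix:
    """Pairwise Bray-Curtis dissimilarities (optionally sqrt-transformed)."""
    if isinstance(samples, pd.DataFrame):
        X = samples.to_numpy(dtype=float)
        ids = [str(i) for i in samples.index]
    else:
        M = abundance_matrix(samples)
        X = M.to_numpy(dtype=float)
        ids = list(M.index)
    if len(ids) < 2:
        raise ValueError("need at least two samples")
    zero = X.sum(axis=1) == 0
    if zero.any():
        raise ValueError(f"all-zero abundance vector for sample {ids[int(np.flatnonzero(zero)[0])]!r}")
    if transform == "sqrt":
        X = np.sqrt(X)
    elif transform != "none":
        raise ValueError("transform must be 'sqrt' or 'none'")
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n - 1):
        num = np.abs(X[i] - X[i + 1 :]).sum(axis=1)
        den = (X[i] + X[i + 1 :]).sum(axis=1)
        D[i, i + 1 :] = num / den
    D = D + D.T
    return DissimilarityMatrix(sample_ids=ids, values=D, transform=transform)


def isotonic_fit(y: np.ndarray) -> np.ndarray:
    """Least-squares non-decreasing fit by pool-adjacent-violators.

    Merges adjacent blocks whose means violate monotonicity; the result is
    the unique minimiser of sum (y_i - f_i)^2 over non-decreasing f.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    # block means, weights and right edges, maintained as a stack
    means = np.empty(n)
    weights = np.empty(n)
    ends = np.empty(n, dtype=int)
    top = -1
    for i in range(n):
        top += 1
        means[top] = y[i]
        weights[top] = 1.0
        ends[top] = i
        while top > 0 and means[top - 1] > means[top]:
            w = weights[top - 1] + weights[top]
            means[top - 1] = (
                means[top - 1] * weights[top - 1] + means[top] * weights[top]
            ) / w
            weights[top - 1] = w
            ends[top - 1] = ends[top]
            top -= 1
    out = np.empty(n)
    start = 0
    for b in range(top + 1):
        out[start : ends[b] + 1] = means[b]
        start = ends[b] + 1
    return out


def _stress(dhat: np.ndarray, dv: np.ndarray) -> tuple[float, np.ndarray]:
    """Kruskal stress-1 of configuration distances against dissimilarities.

    Returns (stress, disparities). Primary tie approach: pairs are ordered
    by (dissimilarity, current distance) before the monotone fit.
    """
    order = np.lexsort((dhat, dv))
    disp = np.empty_like(dhat)
    disp[order] = isotonic_fit(dhat[order])
    t = float(np.sum(dhat**2))
    s = float(np.sum((dhat - disp) ** 2))
    return np.sqrt(s / t) if t > 0 else 0.0, disp


def _pdist_rows(X: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    iu = np.triu_indices(n, 1)
    diff = X[iu[0]] - X[iu[1]]
    return np.sqrt((diff**2).sum(axis=1))


def nmds(
    d: DissimilarityMatrix,
    k: int = 2,
    n_restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int = 0,
) -> OrdinationResult:
    """Non-metric MDS of a dissimilarity matrix into k dimensions.

    Runs ``n_restarts`` independent seeded random starts (seeds ``seed`` to
    ``seed + n_restarts - 1``) of steepest descent with step halving on
    stress-1 and keeps the lowest-stress configuration. Within a restart the
    stress sequence is non-increasing; iteration stops once the improvement
    drops below ``tol``.
    """
    n = d.n
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} samples, got {n}")
    iu = np.triu_indices(n, 1)
    dv = d.values[iu].astype(float)
    degenerate = np.allclose(dv, dv[0])
    if degenerate:
        warnings.warn(
            "all dissimilarities are (numerically) equal; ordination is "
            "degenerate and any configuration fits the ranks",
            stacklevel=2,
        )

    best: tuple[float, np.ndarray, list[float], bool] | None = None
    scale = float(np.mean(dv)) or 1.0
    restarts = 1 if degenerate else n_restarts
    for r in range(restarts):
        rng = np.random.default_rng(seed + r)
        X = rng.standard_normal((n, k)) * scale
        X -= X.mean(axis=0)
        dhat = _pdist_rows(X)
        stress, disp = _stress(dhat, dv)
        history = [stress]
        alpha = 0.2
        converged = False
        for _ in range(max_iter):
            grad = _stress_gradient(X, dhat, disp, stress, iu)
            gnorm = np.linalg.norm(grad)
            if gnorm == 0 or stress == 0:
                converged = True
                break
            step_dir = grad * (np.linalg.norm(X) / gnorm)
            improved = False
            a = alpha
            for _ in range(25):
                X2 = X - a * step_dir
                dhat2 = _pdist_rows(X2)
                stress2, disp2 = _stress(dhat2, dv)
                if stress2 < stress:
                    improved = True
                    break
                a *= 0.5
            if not improved:
                converged = True
                break
            gain = stress - stress2
            X, dhat, disp, stress = X2, dhat2, disp2, stress2
            X -= X.mean(axis=0)
            history.append(stress)
            alpha = min(a * 1.5, 1.0)
            if gain < tol:
                converged = True
                break
        if best is None or stress < best[0]:
            best = (stress, X, history, converged)

    stress, X, history, converged = best
    X = X - X.mean(axis=0)
    # rotate to principal axes; fix signs so the largest-|coordinate| entry
    # of each axis is positive (deterministic orientation)
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    X = X @ vt.T
    for j in range(X.shape[1]):
        i = int(np.argmax(np.abs(X[:, j])))
        if X[i, j] < 0:
            X[:, j] = -X[:, j]
    return OrdinationResult(
        coordinates=X,
        stress=float(stress),
        n_restarts=restarts,
        converged=bool(converged),
        seed=seed,
        stress_history=[float(s) for s in history],
    )


def _stress_gradient(X, dhat, disp, stress, iu) -> np.ndarray:
    """Analytic gradient of stress-1 w.r.t. the configuration, disparities fixed."""
    n = X.shape[0]
    safe = np.where(dhat > 1e-12, dhat, 1e-12)
    e = (dhat - disp) / safe  # per-pair residual weight
    W = np.zeros((n, n))
    W[iu] = e
    W = W + W.T
    rs = W.sum(axis=1, keepdims=True)
    gS = 2.0 * (rs * X - W @ X)  # d(sum (dhat-disp)^2)/dX
    gT = 2.0 * (n * X - X.sum(axis=0, keepdims=True))  # d(sum dhat^2)/dX
    t = float(np.sum(dhat**2))
    s = float(np.sum((dhat - disp) ** 2))
    if stress <= 0 or t <= 0:
        return np.zeros_like(X)
    return (gS * t - s * gT) / (2.0 * stress * t * t)


def ordination_report(
    result: OrdinationResult,
    samples: Sequence[CommunitySample],
    scheme: ProvinceScheme | None = None,
) -> pd.DataFrame:
    """Per-sample ordination payload: coordinates, site, depth, province."""
    if result.coordinates.shape[0] != len(samples):
        raise ValueError("coordinates and samples must align")
    scheme = scheme or ProvinceScheme()
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "nmds1": result.coordinates[:, 0],
            "nmds2": result.coordinates[:, 1],
            "site": [s.site for s in samples],
            "mean_depth": [s.mean_depth for s in samples],
            "province": [classify_province(s.mean_depth, scheme) for s in samples],
        }
    )
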