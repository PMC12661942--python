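"""Ordination: PCA with passive vectors, and non-metric MDS from scratch.

The nMDS minimizes Kruskal stress-1 by alternating isotonic (monotone,
pooled-adjacent-violators) regression of the configuration distances on
the input dissimilarities with Guttman-transform majorization updates,
over several random starts plus one metric (classical-scaling) start.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform


@dataclass
class OrdinationResult:
    """Station coordinates plus quality metrics and fitted vectors."""

    method: str  # 'PCA' or 'nMDS'
    coords: pd.DataFrame  # stations x axes
    quality: dict  # PCA: var_explained per axis; nMDS: stress, converged
    loadings: pd.DataFrame | None = None
    vectors: pd.DataFrame | None = field(default=None, repr=False)
    passive: pd.DataFrame | None = field(default=None, repr=False)
    clusters: pd.DataFrame | None = field(default=None, repr=False)


# ---------------------------------------------------------------- PCA


def pca(env: pd.DataFrame, scale: bool = True) -> OrdinationResult:
    """Principal component analysis of (optionally unit-scaled) columns.

    Sign convention: every axis is oriented so its largest-magnitude
    loading is positive.
    """
    if env.shape[0] < 2:
        raise ValueError("PCA needs at least 2 stations")
    x = env.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = list(env.columns[sd == 0])
            raise ValueError(f"constant columns cannot be unit-scaled: {bad}")
        x = x / sd
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # deterministic sign: largest-|loading| positive per axis
    for j in range(vt.shape[0]):
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    scores = u * s
    eigvals = s**2 / (env.shape[0] - 1)
    share = 100.0 * eigvals / eigvals.sum()
    axes = [f"PC{i + 1}" for i in range(len(s))]
    coords = pd.DataFrame(scores, index=env.index, columns=axes)
    loadings = pd.DataFrame(vt.T, index=env.columns, columns=axes)
    return OrdinationResult(
        method="PCA",
        coords=coords,
        quality={"var_explained": dict(zip(axes, share.tolist()))},
        loadings=loadings,
    )


def passive_vectors(ord_result: OrdinationResult, extra: pd.DataFrame,
                    n_axes: int = 2, scale: float = 1.0) -> pd.DataFrame:
    """Post-hoc arrows: Pearson correlation of each extra variable with
    each retained axis's scores.  Does not alter the ordination."""
    axes = ord_result.coords.columns[:n_axes]
    scores = ord_result.coords.loc[:, axes].to_numpy(dtype=float)
    rows = {}
    for name, col in extra.items():
        v = col.loc[ord_result.coords.index].to_numpy(dtype=float)
        if np.std(v) == 0:
            warnings.warn(f"[W-PASSIVE-CONST] constant passive variable {name!r}: zero arrow",
                          stacklevel=2)
            rows[name] = np.zeros(len(axes))
            continue
        rows[name] = np.array(
            [np.corrcoef(v, scores[:, j])[0, 1] for j in range(len(axes))]
        ) * scale
    return pd.DataFrame(rows, index=list(axes)).T


# ---------------------------------------------------------------- nMDS


def _disparities(d_flat: np.ndarray, order: np.ndarray, blocks: np.ndarray,
                 ties: str) -> np.ndarray:
    """Monotone regression of configuration distances on dissimilarity rank.

    ``order`` sorts pairs by input dissimilarity; ``blocks`` are tie-group
    ids along that order.  ``ties='average'`` (secondary treatment) pools
    each tie group before PAV; ``ties='break'`` (primary) lets tied pairs
    reorder freely (sorted ascending within a group).
    """
    y = d_flat[order]
    if ties == "average":
        # collapse tie groups to weighted means, PAV, then expand
        uniq, inverse, counts = np.unique(blocks, return_inverse=True, return_counts=True)
        sums = np.zeros(len(uniq))
        np.add.at(sums, inverse, y)
        means = sums / counts
        fit = isotonic_regression(means, weights=counts.astype(float)).x
        yhat = fit[inverse]
    elif ties == "break":
        idx = np.lexsort((y, blocks))
        fit = isotonic_regression(y[idx]).x
        yhat = np.empty_like(y)
        yhat[idx] = fit
    else:
        raise ValueError(f"unknown tie treatment {ties!r}")
    return yhat


def kruskal_stress(d_flat: np.ndarray, dhat_sorted: np.ndarray, order: np.ndarray) -> float:
    """Stress-1 = sqrt(sum((d - dhat)^2) / sum(d^2))."""
    d_sorted = d_flat[order]
    denom = (d_sorted**2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((d_sorted - dhat_sorted) ** 2).sum() / denom))


def _guttman_update(x: np.ndarray, dhat: np.ndarray) -> np.ndarray:
    """One majorization step toward target disparities ``dhat`` (square)."""
    n = x.shape[0]
    d = squareform(pdist(x))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(d > 0, dhat / d, 0.0)
    b = -ratio
    np.fill_diagonal(b, 0.0)
    np.fill_diagonal(b, -b.sum(axis=1))
    return b @ x / n


def _principal_rotate(x: np.ndarray) -> np.ndarray:
    x = x - x.mean(axis=0)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    rotated = x @ vt.T
    for j in range(rotated.shape[1]):
        lead = np.argmax(np.abs(rotated[:, j]))
        if rotated[lead, j] < 0:
            rotated[:, j] *= -1
    return rotated


def _classical_mds(diss: np.ndarray, k: int) -> np.ndarray:
    n = diss.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (diss**2) @ j
    vals, vecs = np.linalg.eigh(b)
    idx = np.argsort(vals)[::-1][:k]
    vals = np.clip(vals[idx], 0, None)
    return vecs[:, idx] * np.sqrt(vals)


def _nmds_single(diss_flat, order, blocks, x0, max_iter, tol, ties):
    x = x0.copy()
    d = pdist(x)
    dhat = _disparities(d, order, blocks, ties)
    stress = kruskal_stress(d, dhat, order)
    history = [stress]
    converged = False
    for _ in range(max_iter):
        dhat_sq = squareform_from_sorted(dhat, order, len(x))
        x_new = _guttman_update(x, dhat_sq)
        d_new = pdist(x_new)
        dhat_new = _disparities(d_new, order, blocks, ties)
        stress_new = kruskal_stress(d_new, dhat_new, order)
        if stress_new > stress + 1e-15:
            break  # reject non-improving step, keep last accepted config
        x, d, dhat = x_new, d_new, dhat_new
        improved = stress - stress_new
        stress = stress_new
        history.append(stress)
        if improved < tol:
            converged = True
            break
    return x, stress, converged, history


def squareform_from_sorted(dhat_sorted: np.ndarray, order: np.ndarray, n: int) -> np.ndarray:
    flat = np.empty_like(dhat_sorted)
    flat[order] = dhat_sorted
    return squareform(flat)


def nmds_stress(diss: np.ndarray, x: np.ndarray, ties: str = "average") -> float:
    """Stress-1 of an arbitrary configuration against dissimilarities."""
    flat = squareform(np.asarray(diss, dtype=float))
    order = np.argsort(flat, kind="stable")
    blocks = _tie_blocks(flat, order)
    d = pdist(np.asarray(x, dtype=float))
    dhat = _disparities(d, order, blocks, ties)
    return kruskal_stress(d, dhat, order)


def _tie_blocks(flat: np.ndarray, order: np.ndarray) -> np.ndarray:
    sorted_vals = flat[order]
    return np.concatenate([[0], np.cumsum(np.diff(sorted_vals) > 1e-12)])


def nmds(
    diss: pd.DataFrame,
    k: int = 2,
    n_starts: int = 8,
    max_iter: int = 300,
    tol: float = 1e-9,
    seed: int | None = None,
    ties: str = "average",
) -> OrdinationResult:
    """Non-metric MDS of a square symmetric dissimilarity matrix.

    Best of *n_starts* random initializations plus one classical-scaling
    start; the winning configuration is centered and rotated to its
    principal axes.
    """
    index = diss.index if isinstance(diss, pd.DataFrame) else pd.RangeIndex(len(diss))
    a = np.asarray(diss, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("dissimilarity matrix must be symmetric")
    if not np.allclose(np.diag(a), 0, atol=1e-12):
        raise ValueError("dissimilarity matrix must have a zero diagonal")
    n = a.shape[0]
    flat = squareform(a)
    order = np.argsort(flat, kind="stable")
    blocks = _tie_blocks(flat, order)

    rng = np.random.default_rng(seed)
    starts = [_classical_mds(a, k)]
    scale = max(flat.max(), 1e-6)
    starts += [rng.normal(0, scale, size=(n, k)) for _ in range(n_starts)]

    best = None
    for x0 in starts:
        x, stress, converged, history = _nmds_single(
            flat, order, blocks, np.asarray(x0, dtype=float), max_iter, tol, ties
        )
        if best is None or stress < best[1]:
            best = (x, stress, converged, history)
    x, stress, converged, history = best
    coords = pd.DataFrame(
        _principal_rotate(x), index=index, columns=[f"NMDS{i + 1}" for i in range(k)]
    )
    return OrdinationResult(
        method="nMDS",
        coords=coords,
        quality={
            "stress": stress,
            "converged": converged,
            "n_iter": len(history) - 1,
            "stress_history": history,
        },
    )


# ------------------------------------------------------- influential taxa


def influential_taxa(matrix: pd.DataFrame, ord_result: OrdinationResult,
                     k: int = 10, n_axes: int = 2) -> pd.DataFrame:
    """Top-k taxa by influence on the ordination.

    A taxon's position is the abundance-weighted average of station
    coordinates; its influence score is (taxon total) x (distance of that
    position from the origin).  Ties in score break lexicographically.
    """
    axes = ord_result.coords.columns[:n_axes]
    coords = ord_result.coords.loc[matrix.index, axes].to_numpy(dtype=float)
    w = matrix.to_numpy(dtype=float)
    totals = w.sum(axis=0)
    rows = []
    for j, taxon in enumerate(matrix.columns):
        if totals[j] == 0:
            continue
        pos = (w[:, j] @ coords) / totals[j]
        rows.append(
            {
                "taxon": taxon,
                **{ax: pos[i] for i, ax in enumerate(axes)},
                "total": totals[j],
                "influence": totals[j] * float(np.linalg.norm(pos)),
            }
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(["influence", "taxon"], ascending=[False, True], kind="stable")
    return df.head(k).reset_index(drop=True)
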