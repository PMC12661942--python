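"""Transforms, diversity indices and pairwise matrix correlations."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps


def sqrt_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Element-wise square root (skewness reduction for count-like data)."""
    vals = matrix.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("matrix has negative cells; cannot square-root transform")
    out = pd.DataFrame(np.sqrt(vals), index=matrix.index, columns=matrix.columns)
    out.attrs.update(matrix.attrs)
    return out


def shannon(values) -> float:
    """Shannon diversity H' in nats of one non-negative composition."""
    x = np.asarray(values, dtype=float)
    if (x < 0).any():
        raise ValueError("negative values in composition")
    total = x.sum()
    if total == 0:
        raise ValueError("all-zero composition: H' undefined")
    p = x[x > 0] / total
    p = p[p > 0]  # positive cells can still underflow to 0 after division
    return float(-(p * np.log(p)).sum())


def shannon_by_station(matrix: pd.DataFrame) -> pd.Series:
    out = matrix.apply(lambda row: shannon(row.to_numpy()), axis=1)
    out.name = "shannon"
    return out


def jaccard_matrix(matrix: pd.DataFrame, similarity: bool = True) -> pd.DataFrame:
    """Pairwise Jaccard similarity (or dissimilarity) between stations.

    Presence = cell > 0.  A pair of empty rows is undefined: it is set to
    NaN and a warning is emitted.
    """
    pres = (matrix.to_numpy() > 0)
    n = pres.shape[0]
    out = np.ones((n, n))
    flagged = False
    for i in range(n):
        for j in range(i + 1, n):
            union = np.logical_or(pres[i], pres[j]).sum()
            if union == 0:
                out[i, j] = out[j, i] = np.nan
                flagged = True
            else:
                inter = np.logical_and(pres[i], pres[j]).sum()
                out[i, j] = out[j, i] = inter / union
    if flagged:
        warnings.warn("[W-JACCARD-EMPTY] undefined Jaccard pair(s) (two empty rows)", stacklevel=2)
    if not similarity:
        out = 1.0 - out
        np.fill_diagonal(out, 0.0)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.index)


def bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity: sum|x-y| / sum(x+y), in [0,1]."""
    x = matrix.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("Bray-Curtis requires non-negative values")
    n = x.shape[0]
    out = np.zeros((n, n))
    flagged = False
    for i in range(n):
        for j in range(i + 1, n):
            denom = (x[i] + x[j]).sum()
            if denom == 0:
                out[i, j] = out[j, i] = np.nan
                flagged = True
            else:
                out[i, j] = out[j, i] = np.abs(x[i] - x[j]).sum() / denom
    if flagged:
        warnings.warn("[W-BC-EMPTY] undefined Bray-Curtis pair(s) (two all-zero rows)", stacklevel=2)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.index)


def lower_triangle(matrix: pd.DataFrame) -> np.ndarray:
    """Strictly-lower-triangle entries as a vector (row-major order)."""
    a = np.asarray(matrix, dtype=float)
    return a[np.tril_indices_from(a, k=-1)]


def matrix_correlation(m1: pd.DataFrame, m2: pd.DataFrame, method: str = "pearson",
                       n_perm: int = 999, seed: int | None = None) -> dict:
    """Pearson correlation between two pairwise matrices.

    The default is the plain paired-observation t test on the
    strictly-lower-triangle vectors (df = n_pairs - 2) — NOT a Mantel
    permutation.  ``method='mantel'`` switches to a Mantel permutation of
    station labels for exchangeability-correct inference.
    """
    if list(m1.index) != list(m2.index):
        raise ValueError("matrices must share the same station set and order")
    v1, v2 = lower_triangle(m1), lower_triangle(m2)
    ok = ~(np.isnan(v1) | np.isnan(v2))
    v1, v2 = v1[ok], v2[ok]
    if np.std(v1) == 0 or np.std(v2) == 0:
        warnings.warn("[W-CORR-CONST] constant distance vector: r undefined", stacklevel=2)
        return {"r": np.nan, "p": np.nan, "n_pairs": int(ok.sum()), "method": method}
    r, p = sps.pearsonr(v1, v2)
    if method == "pearson":
        return {"r": float(r), "p": float(p), "n_pairs": len(v1), "method": "pearson"}
    if method != "mantel":
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    a2 = np.asarray(m2, dtype=float)
    n = a2.shape[0]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        vp = a2[np.ix_(perm, perm)][np.tril_indices(n, k=-1)][ok]
        rp = np.corrcoef(v1, vp)[0, 1]
        if abs(rp) >= abs(r):
            count += 1
    return {
        "r": float(r),
        "p": (count + 1) / (n_perm + 1),
        "n_pairs": len(v1),
        "method": "mantel",
    }


def correlation_heatmap_table(matrices: dict, vectors: dict | None = None) -> pd.DataFrame:
    """Pairwise correlation structure across data streams.

    ``matrices`` maps stream label -> pairwise (e.g. Jaccard) matrix;
    ``vectors`` maps stream label -> per-station diversity vector.  Both
    blocks are correlated pairwise (Pearson) with significance stars.
    """
    rows = []
    labels = list(matrices)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            res = matrix_correlation(matrices[a], matrices[b])
            rows.append({"kind": "matrix", "a": a, "b": b, **res})
    if vectors:
        vlabels = list(vectors)
        for i, a in enumerate(vlabels):
            for b in vlabels[i + 1:]:
                va = np.asarray(vectors[a], dtype=float)
                vb = np.asarray(vectors[b], dtype=float)
                r, p = sps.pearsonr(va, vb)
                rows.append({"kind": "vector", "a": a, "b": b, "r": float(r),
                             "p": float(p), "n_pairs": len(va), "method": "pearson"})
    df = pd.DataFrame(rows)
    df["stars"] = df["p"].map(
        lambda p: "**" if p < 0.01 else ("*" if p < 0.05 else "")
    )
    return df
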