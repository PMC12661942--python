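"""Environmental vector fitting onto ordination scores with permutation
significance."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .ordination import OrdinationResult


def _r_squared(scores: np.ndarray, v: np.ndarray) -> tuple[float, np.ndarray]:
    beta, *_ = np.linalg.lstsq(scores, v, rcond=None)
    resid = v - scores @ beta
    ss_tot = float((v**2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot
    return r2, beta


def fit_env_vectors(
    ord_result: OrdinationResult | pd.DataFrame,
    env: pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = None,
    n_axes: int = 2,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Least-squares fit of each (centered, unit-scaled) environmental
    variable onto the first *n_axes* ordination scores.

    Returns one row per variable with the direction cosines, r2 and a
    permutation p-value using the (count+1)/(n_perm+1) estimator, plus a
    ``significant`` flag at *alpha*.
    """
    if n_perm < 99:
        warnings.warn("[W-ENVFIT-PERM] n_perm < 99 gives coarse p-values", stacklevel=2)
    coords = ord_result.coords if isinstance(ord_result, OrdinationResult) else ord_result
    axes = list(coords.columns[:n_axes])
    scores = coords.loc[:, axes].to_numpy(dtype=float)
    scores = scores - scores.mean(axis=0)
    n = scores.shape[0]
    rng = np.random.default_rng(seed)

    rows = []
    for name, col in env.items():
        v = col.loc[coords.index].to_numpy(dtype=float)
        if np.std(v) == 0:
            warnings.warn(f"[W-ENVFIT-CONST] constant variable {name!r} skipped", stacklevel=2)
            continue
        v = (v - v.mean()) / v.std(ddof=1)
        r2, beta = _r_squared(scores, v)
        norm = np.linalg.norm(beta)
        direction = beta / norm if norm > 0 else beta
        count = 0
        for _ in range(n_perm):
            r2p, _ = _r_squared(scores, v[rng.permutation(n)])
            if r2p >= r2:
                count += 1
        p = (count + 1) / (n_perm + 1)
        rows.append(
            {
                "variable": name,
                **{ax: float(direction[i]) for i, ax in enumerate(axes)},
                "r2": r2,
                "p": p,
                "significant": p < alpha,
            }
        )
    return pd.DataFrame(rows).set_index("variable")
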