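"""Endophenotype discovery: robust standardization, Ward agglomeration,
and cluster-count selection by the cubic clustering criterion (CCC).

Ward linkage is implemented via the Lance-Williams recurrence on squared
Euclidean distances. Merge heights use the within-cluster sum-of-squares
convention: merging two singletons at Euclidean distance d costs d^2 / 2
(the increase in total within-cluster SS). Ties are broken by the lowest
pair index, making the tree deterministic for a given row order.

The CCC follows Sarle's approximation: the observed R^2 of a partition is
compared against its expectation under a uniform hypercube null aligned
with the data's principal axes; large positive values indicate clustering
structure beyond the null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidInputError

MAD_SCALE = 1.4826  # makes MAD consistent for a normal distribution


@dataclass(frozen=True)
class ClusterInput:
    """Standardized matrix plus the per-column transform record."""

    X: np.ndarray
    columns: tuple[str, ...]
    centers: dict[str, float]
    scales: dict[str, float]
    ids: tuple[str, ...]
    raw: pd.DataFrame
    dropped: tuple[str, ...] = ()
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class ClusterResult:
    linkage: np.ndarray
    chosen_k: int
    ccc_by_k: dict[int, float]
    assignments: np.ndarray
    summary: pd.DataFrame


def robust_standardize(df: pd.DataFrame, id_column: str | None = None) -> ClusterInput:
    """Per-column (x - median) / (1.4826 * MAD) scaling.

    Zero-MAD columns fall back to an IQR-based scale (IQR / 1.349); columns
    with both zero are dropped with a warning. Constant-only input raises.
    """
    if id_column is not None:
        ids = tuple(df[id_column].astype(str))
        df = df.drop(columns=[id_column])
    else:
        ids = tuple(str(i) for i in df.index)
    cols, centers, scales, dropped, warnings = [], {}, {}, [], []
    data = {}
    for col in df.columns:
        x = df[col].to_numpy(dtype=float)
        if not np.all(np.isfinite(x)):
            raise InvalidInputError(f"column {col!r} contains missing/non-finite values")
        med = float(np.median(x))
        mad = float(np.median(np.abs(x - med)))
        scale = MAD_SCALE * mad
        if scale == 0:
            iqr = float(np.subtract(*np.percentile(x, [75, 25])))
            scale = iqr / 1.349
            if scale > 0:
                warnings.append(f"{col}: zero MAD, fell back to IQR scale")
        if scale == 0:
            dropped.append(col)
            warnings.append(f"{col}: constant column dropped")
            continue
        cols.append(col)
        centers[col], scales[col] = med, scale
        data[col] = (x - med) / scale
    if not cols:
        raise InvalidInputError("no usable columns after dropping constants")
    X = np.column_stack([data[c] for c in cols])
    return ClusterInput(
        X=X, columns=tuple(cols), centers=centers, scales=scales, ids=ids,
        raw=df, dropped=tuple(dropped), warnings=tuple(warnings),
    )


def ward_linkage(X: np.ndarray) -> np.ndarray:
    """Deterministic Ward agglomeration.

    Returns an (n-1, 4) array like scipy's linkage format: the two merged
    cluster ids (originals 0..n-1, new clusters n, n+1, ...), the merge
    height (increase in within-cluster SS), and the new cluster size.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if n < 2:
        raise InvalidInputError("need at least 2 observations")

    # D holds twice the merge cost (Lance-Williams on squared distances)
    sq = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    D = {(i, j): sq[i, j] for i in range(n) for j in range(i + 1, n)}
    size = {i: 1 for i in range(n)}
    active = list(range(n))
    Z = np.empty((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        best = min(
            ((D[(a, b)], a, b) for idx, a in enumerate(active)
             for b in active[idx + 1:]),
            key=lambda t: (t[0], t[1], t[2]),
        )
        d_ij, i, j = best
        Z[step] = (i, j, d_ij / 2.0, size[i] + size[j])
        new = next_id
        next_id += 1
        size[new] = size[i] + size[j]
        active = [a for a in active if a not in (i, j)]
        for k in active:
            d_ik = D[tuple(sorted((i, k)))]
            d_jk = D[tuple(sorted((j, k)))]
            nk, ni, nj = size[k], size[i], size[j]
            D[(k, new) if k < new else (new, k)] = (
                (ni + nk) * d_ik + (nj + nk) * d_jk - nk * d_ij
            ) / (ni + nj + nk)
        active.append(new)
    return Z


def cut_k(linkage: np.ndarray, k: int) -> np.ndarray:
    """Labels for a k-cluster cut, canonicalized by smallest member index."""
    n = linkage.shape[0] + 1
    if not (1 <= k <= n):
        raise InvalidInputError(f"k must be in [1, {n}], got {k}")
    parent = list(range(n + linkage.shape[0]))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for step in range(n - k):
        i, j = int(linkage[step, 0]), int(linkage[step, 1])
        new = n + step
        parent[find(i)] = new
        parent[find(j)] = new
    roots = [find(i) for i in range(n)]
    # canonical labels: cluster containing the smallest row index gets 0, etc.
    order: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, r in enumerate(roots):
        if r not in order:
            order[r] = len(order)
        labels[i] = order[r]
    return labels


def _r_squared(X: np.ndarray, labels: np.ndarray) -> float:
    Xc = X - X.mean(axis=0)
    total = float((Xc**2).sum())
    within = 0.0
    for lab in np.unique(labels):
        sub = X[labels == lab]
        within += float(((sub - sub.mean(axis=0)) ** 2).sum())
    return 1.0 - within / total


def cubic_clustering_criterion(X: np.ndarray, labels: np.ndarray) -> float:
    """Sarle's CCC for a given partition of the rows of X."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    labels = np.asarray(labels)
    q = int(np.unique(labels).size)
    if not (2 <= q <= n // 2):
        raise InvalidInputError(f"number of clusters {q} outside [2, n/2]")

    Xc = X - X.mean(axis=0)
    eig = np.linalg.eigvalsh(Xc.T @ Xc / (n - 1))[::-1]
    s = np.sqrt(np.clip(eig, 0.0, None))
    r2 = _r_squared(X, labels)
    if r2 >= 1.0:
        r2 = 1.0 - 1e-12

    vv = float(np.prod(np.where(s > 0, s, 1.0)))
    c = (vv / q) ** (1.0 / p)
    u = s / c
    k1 = int(np.sum(u >= 1.0))
    p1 = min(k1, q - 1)
    if p1 < 1:
        return float("nan")
    term1 = float(np.sum(1.0 / (n + u[:p1])))
    term2 = float(np.sum(u[p1:] ** 2 / (n + u[p1:]))) if p1 < p else 0.0
    e_r2 = 1.0 - ((term1 + term2) / float(np.sum(u**2))) * ((n - q) ** 2 / n) * (
        1.0 + 4.0 / n
    )
    if not (0 < e_r2 < 1):
        return float("nan")
    return float(
        math.log((1.0 - e_r2) / (1.0 - r2)) * (math.sqrt(n * p1 / 2.0) / ((0.001 + e_r2) ** 1.2))
    )


def choose_k_and_summarize(
    ci: ClusterInput,
    k_range: range | tuple[int, ...] = range(2, 11),
    extra: pd.DataFrame | None = None,
    female_indicator: str = "sex_indicator",
) -> ClusterResult:
    """Pick k by CCC argmax and build per-cluster summaries.

    Summaries report mean (SD) of every raw feature column, % female when a
    0/1 female indicator column is present, and the percentage of rows with
    True in any boolean columns of ``extra`` (e.g. deficient / low_TDP /
    high_TDP flags aligned with the input rows).
    """
    n = ci.X.shape[0]
    ks = [k for k in k_range if 2 <= k <= n // 2]
    if not ks:
        raise InvalidInputError(f"no usable k in {list(k_range)} for n={n}")
    Z = ward_linkage(ci.X)
    ccc_by_k: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in ks:
        labels = cut_k(Z, k)
        labels_by_k[k] = labels
        ccc_by_k[k] = cubic_clustering_criterion(ci.X, labels)
    finite = {k: v for k, v in ccc_by_k.items() if math.isfinite(v)}
    chosen_k = max(finite, key=lambda k: (finite[k], -k)) if finite else ks[0]
    labels = labels_by_k[chosen_k]

    rows = []
    for lab in range(chosen_k):
        mask = labels == lab
        row: dict = {"cluster": lab, "n": int(mask.sum())}
        for col in ci.raw.columns:
            vals = ci.raw[col].to_numpy(dtype=float)[mask]
            if col == female_indicator:
                row["pct_female"] = float(100.0 * vals.mean())
            else:
                row[f"{col}_mean"] = float(vals.mean())
                row[f"{col}_sd"] = float(vals.std(ddof=1)) if mask.sum() > 1 else math.nan
        if extra is not None:
            for col in extra.columns:
                vals = extra[col].to_numpy()
                if vals.dtype == bool or set(np.unique(vals)) <= {0, 1, True, False}:
                    row[f"pct_{col}"] = float(100.0 * np.asarray(vals, dtype=float)[mask].mean())
        rows.append(row)
    summary = pd.DataFrame(rows)
    return ClusterResult(
        linkage=Z, chosen_k=chosen_k, ccc_by_k=ccc_by_k,
        assignments=labels, summary=summary,
    )
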