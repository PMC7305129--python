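"""Cross-method community summaries.

qPCR-style ammonia-oxidizer proportions (pie fractions over comammox
*Nitrospira*, AOB and AOA, and the percent of the total community all
ammonia oxidizers represent), Bray-Curtis dissimilarities with principal
coordinate ordination, Spearman rank concordance between profiling methods,
and summed abundance of gene-bearing bins.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats

AO_COLUMNS = ("bacterial_16S", "comammox_amoA", "AOB_amoA", "AOA_16S")


def ao_proportions(table: pd.DataFrame) -> pd.DataFrame:
    """Ammonia-oxidizer proportions from a gene-copy table.

    Per sample: ``AO_total = comammox_amoA + AOB_amoA + AOA_16S``; pie
    fractions are each guild's share of ``AO_total``; ``total_AO_percent``
    is ``100 * AO_total / (bacterial_16S + AOA_16S)`` — archaea are counted
    in the denominator through their own 16S assay since bacterial 16S
    primers do not amplify them. No per-genome gene copy-number correction
    is applied. Zero ``AO_total`` leaves the pie undefined (NaN) with
    ``total_AO_percent = 0``.
    """
    missing = [c for c in AO_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"gene copy table missing columns: {missing}")
    if (table[list(AO_COLUMNS)] < 0).any().any():
        raise ValueError("gene copies must be non-negative")
    denom = table["bacterial_16S"] + table["AOA_16S"]
    if (denom <= 0).any():
        bad = table.index[denom <= 0].tolist()
        raise ValueError(f"total-community denominator is zero for samples {bad}")
    ao_total = table["comammox_amoA"] + table["AOB_amoA"] + table["AOA_16S"]
    out = pd.DataFrame(index=table.index)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["comammox_fraction"] = np.where(ao_total > 0, table["comammox_amoA"] / ao_total, np.nan)
        out["AOB_fraction"] = np.where(ao_total > 0, table["AOB_amoA"] / ao_total, np.nan)
        out["AOA_fraction"] = np.where(ao_total > 0, table["AOA_16S"] / ao_total, np.nan)
    out["total_AO_percent"] = 100.0 * ao_total / denom
    return out


def bray_curtis(abundance: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between samples (rows):
    d(x, y) = sum|x_i - y_i| / sum(x_i + y_i)."""
    values = abundance.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("abundances must be non-negative")
    if len(abundance) < 2:
        raise ValueError("at least two samples required")
    zero = abundance.index[values.sum(axis=1) == 0].tolist()
    if zero:
        raise ValueError(f"samples with all-zero abundances: {zero}")
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(values, metric="braycurtis"))
    return pd.DataFrame(d, index=abundance.index, columns=abundance.index)


def pcoa(dissimilarity: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical scaling (principal coordinate analysis).

    Double-centers the squared dissimilarities and eigendecomposes; axes are
    ordered by descending eigenvalue, coordinates are returned only for
    positive-eigenvalue axes, and the full eigenvalue spectrum (including
    any negative eigenvalues) is reported raw. Per-axis sign is fixed so the
    first nonzero coordinate on each axis is positive.
    """
    D = dissimilarity.to_numpy(dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be square and symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise ValueError("dissimilarity matrix must have a zero diagonal")
    n = D.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ (D**2) @ J
    eigvals, eigvecs = scipy.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    positive = eigvals > max(eigvals.max(), 0) * 1e-10
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    for j in range(coords.shape[1]):
        col = coords[:, j]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            coords[:, j] = -col
    axes = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=dissimilarity.index, columns=axes), eigvals


def spearman_concordance(x, y) -> tuple[float | None, float | None]:
    """Spearman's rank correlation with midranks for ties.

    Two-sided p-value by exact permutation for n <= 9, otherwise the
    t-approximation. Constant input yields ``(None, None)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = len(x)
    if n < 3:
        raise ValueError("at least three observations required")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None, None
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    rs = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 9:
        observed = abs(rs)
        count = 0
        total = 0
        rx_c = rx - rx.mean()
        denom_x = np.sqrt((rx_c**2).sum())
        for perm in permutations(ry):
            ry_p = np.asarray(perm)
            ry_c = ry_p - ry_p.mean()
            r = float(rx_c @ ry_c) / (denom_x * np.sqrt((ry_c**2).sum()))
            total += 1
            if abs(r) >= observed - 1e-12:
                count += 1
        p = count / total
    else:
        t = rs * np.sqrt((n - 2) / max(1.0 - rs**2, 1e-300))
        p = float(2 * scipy.stats.t.sf(abs(t), df=n - 2))
    return rs, p


def gene_bearing_abundance(
    matrix: pd.DataFrame,
    profiles,
    gene: str,
    bin_metadata: pd.DataFrame | None = None,
    group_by: str | None = None,
) -> pd.DataFrame:
    """Summed relative abundance, per sample, of bins carrying ``gene``
    (present = non-NaN / truthy cell of the repertoire matrix), optionally
    grouped by a bin metadata column."""
    from .recruitment import RecruitmentProfile

    if gene not in matrix.columns:
        raise ValueError(f"unknown gene {gene!r}")
    col = matrix[gene]
    if col.dtype == bool:
        bearing = set(matrix.index[col])
    else:
        bearing = set(matrix.index[~col.isna()])
    if isinstance(profiles, RecruitmentProfile):
        profiles = [profiles]
    rows = []
    for p in profiles:
        sub = p.counts[p.counts["bin_id"].isin(bearing)]
        if group_by is not None:
            if bin_metadata is None:
                raise ValueError("bin_metadata required when group_by is set")
            meta = bin_metadata.set_index("bin_id")
            joined = sub.join(meta[group_by], on="bin_id")
            grouped = joined.groupby(group_by)["relative_abundance"].sum()
            for grp, val in grouped.items():
                rows.append((p.sample, grp, val))
            if sub.empty:
                rows.append((p.sample, None, 0.0))
        else:
            rows.append((p.sample, "all", sub["relative_abundance"].sum()))
    return pd.DataFrame(rows, columns=["sample", group_by or "group", "relative_abundance"])
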