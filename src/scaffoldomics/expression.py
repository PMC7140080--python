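"""Single-cell expression statistics.

Operates on an AnnData (cells × genes, sparse integer counts in ``.X``;
mitochondrial genes flagged in ``var["mito"]``).  Implements the stated
single-cell computations: molecule-count QC trim, percent mitochondrial
RNA, median size-factor normalization, Wilcoxon rank-sum differential
expression with a natural-log fold-change pre-filter and Bonferroni
adjustment, dot-plot statistics, and population-fraction summaries.
Graph-based clustering and embedding are inputs (cell metadata), not
computed here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy.stats import mannwhitneyu

__all__ = [
    "qc_trim",
    "percent_mtrna",
    "size_factor_normalize",
    "wilcoxon_de",
    "dotplot_stats",
    "population_fraction",
    "cluster_composition",
]


def _totals(adata: AnnData) -> np.ndarray:
    X = adata.X
    if sp.issparse(X):
        return np.asarray(X.sum(axis=1)).ravel()
    return np.asarray(X).sum(axis=1)


def qc_trim(adata: AnnData, max_molecules: int = 40_000) -> AnnData:
    """Remove cells with more than ``max_molecules`` total counts.

    The inequality is strict: a cell at exactly the threshold is retained.
    """
    totals = _totals(adata)
    keep = totals <= max_molecules
    if not keep.any():
        raise ValueError("QC trim removed every cell")
    out = adata[keep].copy()
    out.obs["total_counts"] = totals[keep]
    return out


def percent_mtrna(adata: AnnData, mito_key: str = "mito") -> np.ndarray:
    """Percent of each cell's counts carried by mitochondrial genes.

    Writes ``obs["pct_mt"]`` and returns the per-cell percentages (0-100).
    """
    if mito_key not in adata.var:
        raise ValueError(f"var[{mito_key!r}] mitochondrial flags are required")
    totals = _totals(adata)
    if np.any(totals == 0):
        raise ValueError("empty cell: zero total counts")
    mito = adata.var[mito_key].to_numpy(dtype=bool)
    Xm = adata.X[:, mito]
    mito_counts = np.asarray(Xm.sum(axis=1)).ravel() if sp.issparse(Xm) else np.asarray(Xm).sum(axis=1)
    pct = 100.0 * mito_counts / totals
    adata.obs["pct_mt"] = pct
    return pct


def size_factor_normalize(adata: AnnData) -> AnnData:
    """Scale each cell by its size factor: total counts / median total.

    After normalization every cell's total equals the median raw total.
    Raw counts are preserved in ``layers["counts"]``; size factors are
    written to ``obs["size_factor"]``.
    """
    totals = _totals(adata)
    if np.any(totals == 0):
        raise ValueError("empty cell: zero total counts")
    median = float(np.median(totals))
    size_factors = totals / median
    out = adata.copy()
    out.layers["counts"] = out.X.copy()
    X = out.X
    if sp.issparse(X):
        X = X.tocsr().astype(float)
        inv = sp.diags(1.0 / size_factors)
        out.X = inv @ X
    else:
        out.X = np.asarray(X, dtype=float) / size_factors[:, None]
    out.obs["size_factor"] = size_factors
    out.obs["total_counts"] = totals
    return out


def _dense_column_means(X, mask_rows: np.ndarray) -> np.ndarray:
    sub = X[mask_rows]
    if sp.issparse(sub):
        return np.asarray(sub.mean(axis=0)).ravel()
    return np.asarray(sub).mean(axis=0)


def wilcoxon_de(
    adata: AnnData,
    group_a,
    group_b,
    lfc_threshold: float = 0.25,
    alpha: float = 0.01,
    use_adjusted: bool = True,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Wilcoxon rank-sum differential expression between two cell groups.

    ``group_a``/``group_b`` are boolean masks or integer indices over cells
    of a *normalized* matrix.  Log fold change is natural-log on group
    means of normalized values with a pseudocount:
    ``LFC = ln((mean_a + 1) / (mean_b + 1))``.  Genes are pre-filtered to
    ``|LFC| > lfc_threshold`` before testing, and the Bonferroni multiplier
    is the number of genes actually tested.  The p-value is the two-sided
    rank-sum p with tie-corrected normal approximation; when both groups
    have at most 10 cells and a gene has no ties, the exact null
    distribution is used.  A gene is flagged significant when
    ``|LFC| > lfc_threshold`` and the (adjusted, by default) p is below
    ``alpha``.
    """
    n = adata.n_obs
    mask_a = np.zeros(n, dtype=bool); mask_a[np.arange(n)[group_a]] = True
    mask_b = np.zeros(n, dtype=bool); mask_b[np.arange(n)[group_b]] = True
    if (mask_a & mask_b).any():
        raise ValueError("groups overlap")
    if mask_a.sum() < 3 or mask_b.sum() < 3:
        raise ValueError("each group needs at least 3 cells")

    X = adata.X
    mean_a = _dense_column_means(X, mask_a)
    mean_b = _dense_column_means(X, mask_b)
    lfc = np.log((mean_a + pseudocount) / (mean_b + pseudocount))

    counts = adata.layers["counts"] if "counts" in adata.layers else X
    pct_a = _dense_column_means((counts > 0), mask_a) * 100.0
    pct_b = _dense_column_means((counts > 0), mask_b) * 100.0

    tested = np.flatnonzero(np.abs(lfc) > lfc_threshold)
    m = tested.size
    Xa = X[mask_a]; Xb = X[mask_b]
    if sp.issparse(Xa):
        Xa = Xa.toarray(); Xb = Xb.toarray()
    small = mask_a.sum() <= 10 and mask_b.sum() <= 10

    pvals = np.full(adata.n_vars, np.nan)
    for j in tested:
        a = Xa[:, j]; b = Xb[:, j]
        pooled = np.concatenate([a, b])
        has_ties = np.unique(pooled).size < pooled.size
        if np.all(pooled == pooled[0]):
            pvals[j] = 1.0
            continue
        method = "exact" if (small and not has_ties) else "asymptotic"
        pvals[j] = mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue

    p_adj = np.minimum(1.0, pvals * m) if m else pvals
    df = pd.DataFrame({
        "gene": adata.var_names,
        "lfc": lfc,
        "p": pvals,
        "p_adj": p_adj,
        "mean_a": mean_a,
        "mean_b": mean_b,
        "pct_a": pct_a,
        "pct_b": pct_b,
        "tested": np.isin(np.arange(adata.n_vars), tested),
    })
    crit = df["p_adj"] if use_adjusted else df["p"]
    df["significant"] = df["tested"] & (crit < alpha)
    return df


def dotplot_stats(
    adata: AnnData, cluster_key: str, genes: list[str]
) -> tuple[pd.DataFrame, list[str]]:
    """Per-cluster mean normalized expression and percent of cells
    expressing (raw count > 0) for a gene panel.

    Unknown genes are returned in a skipped-genes list, not an error.
    """
    if cluster_key not in adata.obs:
        raise ValueError(f"obs[{cluster_key!r}] not found")
    known = [g for g in genes if g in adata.var_names]
    skipped = [g for g in genes if g not in adata.var_names]
    counts = adata.layers["counts"] if "counts" in adata.layers else adata.X
    rows = []
    clusters = adata.obs[cluster_key]
    for cl in pd.unique(clusters):
        mask = (clusters == cl).to_numpy()
        for g in known:
            j = adata.var_names.get_loc(g)
            expr = adata.X[mask, j]
            raw = counts[mask, j]
            if sp.issparse(expr):
                expr = expr.toarray().ravel()
            if sp.issparse(raw):
                raw = raw.toarray().ravel()
            rows.append({
                "cluster": cl,
                "gene": g,
                "mean_expression": float(np.mean(expr)) if expr.size else 0.0,
                "pct_expressing": float(np.mean(np.asarray(raw) > 0) * 100.0) if np.asarray(raw).size else 0.0,
            })
    return pd.DataFrame(rows, columns=["cluster", "gene", "mean_expression", "pct_expressing"]), skipped


def population_fraction(
    obs: pd.DataFrame, metric: str, threshold: float, group_by: str
) -> pd.Series:
    """Fraction of cells with ``metric < threshold`` per group."""
    if metric not in obs:
        raise ValueError(f"metric {metric!r} not present")
    out = {}
    for g, sub in obs.groupby(group_by, observed=True):
        if len(sub) == 0:
            raise ValueError(f"empty group {g!r}")
        out[g] = float((sub[metric] < threshold).mean())
    s = pd.Series(out, name=f"fraction_{metric}_lt_{threshold}")
    s.index.name = group_by
    return s


def cluster_composition(obs: pd.DataFrame, sample_key: str, cluster_key: str) -> pd.DataFrame:
    """Cells per cluster by sample group (counts cross-tabulation)."""
    return pd.crosstab(obs[cluster_key], obs[sample_key])
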