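"""Over-representation analysis and cross-network term consistency.

A study gene set is tested against an annotation collection (flat GMT gene
sets) with the upper-tail hypergeometric test; p-values are adjusted with
Benjamini-Hochberg within one run, and a term is called significant at
FDR < 0.1.  Consistency across systems-biology levels is summarized by the
number of level networks in which a term is significant; terms reaching a
minimum network count (default 3) form the consensus table.  Dense-region
enrichment applies the same test per region.  Term "families" are an
optional user-supplied mapping (curation is manual by design).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "hypergeom_ora",
    "bh_fdr",
    "consensus_terms",
    "region_enrichment",
    "gene_list_overlap",
]

ORA_COLUMNS = ["term", "k", "n", "K", "N", "p", "q", "level"]


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_ora(
    study,
    gene_sets: dict[str, set],
    universe,
    level: str | None = None,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation test per term.

    ``p = P(X >= k)`` for overlap ``k`` between the study set (size ``n``)
    and a term's genes (size ``K`` after intersection with the universe of
    size ``N``).  BH-FDR ``q`` is computed across the terms of this run.
    The study set is intersected with the universe and must remain
    non-empty.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    study = set(study) & universe
    if not study:
        raise ValueError("empty study set (after intersection with the universe)")
    N, n = len(universe), len(study)
    rows = []
    for term, genes in gene_sets.items():
        term_genes = set(genes) & universe
        K = len(term_genes)
        k = len(term_genes & study)
        p = float(hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"term": term, "k": k, "n": n, "K": K, "N": N, "p": min(p, 1.0)})
    df = pd.DataFrame(rows, columns=ORA_COLUMNS[:-2])
    df["q"] = bh_fdr(df["p"].to_numpy()) if len(df) else []
    df["level"] = level
    return df.sort_values("p", kind="stable").reset_index(drop=True)


def consensus_terms(
    per_level: dict[str, pd.DataFrame],
    q_threshold: float = 0.1,
    min_networks: int = 3,
    family_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Cross-network term consistency.

    A term is significant in a level iff ``q < q_threshold``.  The returned
    table lists every term significant somewhere, its per-level q values,
    the number of levels in which it is significant, a ``kept`` flag for
    terms reaching ``min_networks``, and an optional curated ``family``
    label.  Kept-but-isolated terms (no other kept term shares their
    family) are a manual dismissal decision; the table surfaces them via
    the family column rather than automating the dismissal.
    """
    if len(per_level) < 2:
        raise ValueError("need results from at least 2 levels")
    q_cols = {}
    for level, df in per_level.items():
        q_cols[level] = df.set_index("term")["q"]
    qmat = pd.DataFrame(q_cols)
    sig = qmat < q_threshold
    n_networks = sig.sum(axis=1)
    out = qmat.copy()
    out.columns = [f"q_{lvl}" for lvl in qmat.columns]
    out["n_networks"] = n_networks
    out["kept"] = n_networks >= min_networks
    out["family"] = [family_map.get(t) if family_map else None for t in out.index]
    out = out[n_networks > 0]
    out = out.sort_values(["n_networks"], ascending=False, kind="stable")
    out.index.name = "term"
    return out.reset_index()


def region_enrichment(
    regions,
    gene_sets: dict[str, set],
    universe,
    deg_genes=None,
) -> pd.DataFrame:
    """ORA per dense region; each term row carries the region id and, when
    a DEG list is supplied, how many of the region's in-term genes are
    differentially expressed."""
    universe = set(universe)
    deg_genes = set(deg_genes) if deg_genes is not None else set()
    frames = []
    for region in regions:
        nodes = set(region.nodes) if hasattr(region, "nodes") else set(region)
        rank = getattr(region, "rank", None)
        annotated = nodes & universe
        if not annotated:
            warnings.warn(f"region {rank or sorted(map(str, nodes))[:3]} has no annotated genes",
                          stacklevel=2)
            continue
        df = hypergeom_ora(annotated, gene_sets, universe)
        df.insert(0, "region", rank if rank is not None else -1)
        df["mapped_degs"] = [
            len(set(gene_sets[t]) & annotated & deg_genes) for t in df["term"]
        ]
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["region"] + ORA_COLUMNS + ["mapped_degs"])
    return pd.concat(frames, ignore_index=True)


def gene_list_overlap(list_a, list_b) -> tuple[int, int, int, float]:
    """Case-normalized overlap of two gene id lists:
    ``(|a|, |b|, |a ∩ b|, Jaccard)``."""
    a = {str(g).upper() for g in list_a}
    b = {str(g).upper() for g in list_b}
    inter = a & b
    union = a | b
    jac = len(inter) / len(union) if union else 0.0
    return len(a), len(b), len(inter), jac
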