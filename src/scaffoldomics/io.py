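"""Plain-text readers and writers for the pipeline's exchange formats:
GMT gene sets, TSV edge/DEG tables, and MatrixMarket count matrices with
features/barcodes/metadata sidecars (CellRanger-style layout, genes ×
cells on disk, cells × genes in memory)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData

__all__ = [
    "read_gmt", "write_gmt",
    "read_edge_table", "write_edge_table",
    "read_deg_table", "write_deg_table",
    "read_counts_mtx", "write_counts_mtx",
]


def read_gmt(path: str | Path) -> dict[str, set]:
    """Read a GMT file: term, description, member genes (tab-separated)."""
    sets: dict[str, set] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[fields[0]] = set(g for g in fields[2:] if g)
    return sets


def write_gmt(gene_sets: dict[str, set], path: str | Path,
              descriptions: dict[str, str] | None = None) -> Path:
    path = Path(path)
    lines = []
    for term, genes in gene_sets.items():
        desc = (descriptions or {}).get(term, "na")
        lines.append("\t".join([term, desc] + sorted(map(str, genes))))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_edge_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("source", "target"):
        if col not in df:
            raise ValueError(f"edge table lacks column {col!r}")
    return df


def write_edge_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_deg_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("gene", "logFC", "adj_p"):
        if col not in df:
            raise ValueError(f"DEG table lacks column {col!r}")
    return df


def write_deg_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def write_counts_mtx(adata: AnnData, out_dir: str | Path) -> Path:
    """Write counts as matrix.mtx (genes × cells) with features.tsv,
    barcodes.tsv and cell_metadata.tsv sidecars."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    X = adata.X
    mat = (X.T if sp.issparse(X) else sp.csr_matrix(np.asarray(X).T)).tocoo()
    scipy.io.mmwrite(out_dir / "matrix.mtx", mat)
    feats = pd.DataFrame({"gene": adata.var_names})
    if "mito" in adata.var:
        feats["mito"] = adata.var["mito"].to_numpy().astype(int)
    feats.to_csv(out_dir / "features.tsv", sep="\t", index=False, header=False)
    pd.Series(adata.obs_names).to_csv(out_dir / "barcodes.tsv", sep="\t",
                                      index=False, header=False)
    adata.obs.to_csv(out_dir / "cell_metadata.tsv", sep="\t")
    return out_dir


def read_counts_mtx(in_dir: str | Path) -> AnnData:
    """Read the layout written by :func:`write_counts_mtx`."""
    in_dir = Path(in_dir)
    mat = scipy.io.mmread(in_dir / "matrix.mtx").tocsr()  # genes × cells
    feats = pd.read_csv(in_dir / "features.tsv", sep="\t", header=None)
    barcodes = pd.read_csv(in_dir / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    var = pd.DataFrame(index=pd.Index(feats[0].astype(str), name="gene"))
    if feats.shape[1] > 1:
        var["mito"] = feats[1].astype(bool).to_numpy()
    meta_path = in_dir / "cell_metadata.tsv"
    obs = (pd.read_csv(meta_path, sep="\t", index_col=0) if meta_path.exists()
           else pd.DataFrame(index=barcodes))
    obs.index = obs.index.astype(str)
    adata = AnnData(X=mat.T.tocsr(), obs=obs, var=var)
    adata.obs_names = barcodes.to_numpy()
    return adata
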