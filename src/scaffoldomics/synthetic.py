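"""Ground-truthed synthetic data for the three pipeline arms.

Three generators emulate the study's data modalities without any download:

* :func:`simulate_stack` -- two-channel confocal z-stacks of a fibrin
  scaffold seeded with spherical cells, singly or in clusters, plus an
  optional dense coverslip ("glass") layer at the top of the stack whose
  per-slice summed intensity stands out from the scaffold slices.
* :func:`simulate_counts` -- negative-binomial gene × cell counts with
  per-condition mitochondrial count fractions, a small subpopulation
  overexpressing stem-marker-like genes, and an optional heavy tail of
  over-sequenced cells.
* :func:`simulate_networks` -- per-level interaction edge tables with one
  planted dense clique among the DEGs, a GMT annotation collection with one
  planted term enriched in the DEGs, and the DEG table itself.

Every generator draws from a single :class:`numpy.random.Generator` stream
seeded from its spec, so identical spec + seed gives byte-identical output.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

from .preprocessing import ImageStack

__all__ = [
    "GlassLayerSpec", "StackSpec", "StackTruth", "simulate_stack",
    "CountsSpec", "simulate_counts",
    "NetworkSpec", "simulate_networks",
    "digital_sphere_voxels",
]

DEFAULT_STEM_MARKERS = ("SOX2", "FOXM1", "CD44", "ID2", "ID3", "GPC3", "SOX4")


# ---------------------------------------------------------------------------
# Confocal stacks
# ---------------------------------------------------------------------------

def digital_sphere_voxels(radius: int) -> int:
    """Voxel count of a digital sphere: voxels with center distance <= radius."""
    r = int(radius)
    zz, yy, xx = np.mgrid[-r:r + 1, -r:r + 1, -r:r + 1]
    return int(np.count_nonzero(zz ** 2 + yy ** 2 + xx ** 2 <= r * r))


@dataclass
class GlassLayerSpec:
    """Coverslip-adherent cell layer at the top of the stack.

    Rendering is clipped to ``z_range`` (inclusive) so the layer's signal
    cannot bleed into scaffold slices.  ``intensity_scale`` keeps the glass
    voxel intensities below the scaffold's absolute maximum while the sheer
    cell density makes the summed slice intensities outlying.
    """

    z_range: tuple[int, int] = (19, 23)
    n_cells: int = 120
    intensity_scale: float = 0.6


@dataclass
class StackSpec:
    """Parameters of a synthetic two-channel scaffold stack."""

    shape_zyx: tuple[int, int, int] = (24, 96, 96)
    voxel_size_zyx: tuple[float, float, float] = (2.0, 1.0, 1.0)
    n_singletons: int = 12
    n_clusters: int = 4
    cells_per_cluster: tuple[int, int] = (3, 6)
    cell_radius_vox: int = 3
    cluster_spread_vox: float = 2.0
    glass_layer: GlassLayerSpec | None = None
    noise_sd: float = 2.0
    background: float = 10.0
    channel_gains: tuple[float, float] = (200.0, 180.0)  # (DiO, DAPI)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_singletons, self.n_clusters, self.cell_radius_vox) < 0:
            raise ValueError("counts and radius must be >= 0")
        if self.cell_radius_vox < 1:
            raise ValueError("cell_radius_vox must be >= 1")
        if self.cells_per_cluster[0] < 1 or self.cells_per_cluster[0] > self.cells_per_cluster[1]:
            raise ValueError("invalid cells_per_cluster range")
        if self.glass_layer is not None:
            lo, hi = self.glass_layer.z_range
            if not (0 <= lo <= hi < self.shape_zyx[0]):
                raise ValueError("glass z-range outside the stack")


@dataclass
class StackTruth:
    """Ground truth for a simulated stack."""

    objects: pd.DataFrame          # id, kind, cluster_id, z, y, x, intended_voxels
    glass_slices: tuple[int, int] | None   # inclusive z-range, or None

    @property
    def n_scaffold_groups(self) -> int:
        """Intended number of connected scaffold objects (each cluster is one)."""
        scaffold = self.objects[self.objects["kind"] != "glass"]
        singles = (scaffold["kind"] == "singleton").sum()
        clusters = scaffold.loc[scaffold["kind"] == "cluster", "cluster_id"].nunique()
        return int(singles + clusters)


def _render_sphere(canvas: np.ndarray, center, radius: int, value: float,
                   z_clip: tuple[int, int] | None = None) -> None:
    cz, cy, cx = center
    zdim, ydim, xdim = canvas.shape
    zlo, zhi = max(0, cz - radius), min(zdim - 1, cz + radius)
    if z_clip is not None:
        zlo, zhi = max(zlo, z_clip[0]), min(zhi, z_clip[1])
    ylo, yhi = max(0, cy - radius), min(ydim - 1, cy + radius)
    xlo, xhi = max(0, cx - radius), min(xdim - 1, cx + radius)
    if zlo > zhi or ylo > yhi or xlo > xhi:
        return
    zz, yy, xx = np.mgrid[zlo:zhi + 1, ylo:yhi + 1, xlo:xhi + 1]
    ball = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2 <= radius * radius
    region = canvas[zlo:zhi + 1, ylo:yhi + 1, xlo:xhi + 1]
    np.maximum(region, np.where(ball, value, 0.0), out=region)


def simulate_stack(spec: StackSpec) -> tuple[ImageStack, StackTruth]:
    """Render a synthetic two-channel stack and its ground truth.

    The DiO channel holds filled digital spheres (membrane dye) at singleton
    and clustered positions; the DAPI channel holds a smaller nuclear spot
    per cell.  Scaffold objects are placed with a minimum separation so
    intended groups stay disconnected, and away from the volume faces so
    none touches an edge.  Gaussian noise and a constant background are
    added and the result clipped to 8-bit.
    """
    rng = np.random.default_rng(spec.seed)
    zdim, ydim, xdim = spec.shape_zyx
    r = spec.cell_radius_vox
    gain_dio, gain_dapi = spec.channel_gains

    glass = spec.glass_layer
    z_top = (glass.z_range[0] - 1) if glass is not None else (zdim - 1)
    margin = r + 2
    z_lo, z_hi = margin, z_top - margin
    y_lo, y_hi = margin, ydim - 1 - margin
    x_lo, x_hi = margin, xdim - 1 - margin
    n_groups = spec.n_singletons + spec.n_clusters
    if n_groups > 0 and (z_hi < z_lo or y_hi < y_lo or x_hi < x_lo):
        raise ValueError("overfull stack: no room for scaffold cells")

    # group extents for separation (cluster members spread around the seed)
    cluster_reach = r + 3.0 * spec.cluster_spread_vox
    group_kinds = ["singleton"] * spec.n_singletons + ["cluster"] * spec.n_clusters
    extents = [r if k == "singleton" else cluster_reach for k in group_kinds]

    sphere_vox = digital_sphere_voxels(r)
    mean_cluster = (spec.cells_per_cluster[0] + spec.cells_per_cluster[1]) / 2
    intended_cells = spec.n_singletons + spec.n_clusters * mean_cluster
    scaffold_vox = max(1, (z_hi - z_lo + 1) * (y_hi - y_lo + 1) * (x_hi - x_lo + 1))
    if n_groups and intended_cells * sphere_vox > 0.3 * scaffold_vox:
        raise ValueError("overfull stack: requested cell volume exceeds capacity")

    centers: list[tuple[int, int, int]] = []
    for i, ext in enumerate(extents):
        for _ in range(5000):
            c = (int(rng.integers(z_lo, z_hi + 1)),
                 int(rng.integers(y_lo, y_hi + 1)),
                 int(rng.integers(x_lo, x_hi + 1)))
            ok = all(
                np.linalg.norm(np.subtract(c, other)) >= ext + extents[j] + 2
                for j, other in enumerate(centers)
            )
            if ok:
                centers.append(c)
                break
        else:
            raise ValueError("overfull stack: could not place all objects")

    dio = np.zeros(spec.shape_zyx, dtype=float)
    dapi = np.zeros(spec.shape_zyx, dtype=float)
    records = []
    obj_id = 0
    nuc_r = max(1, r // 2)

    def add_cell(center, kind, cluster_id, scale=1.0, z_clip=None):
        nonlocal obj_id
        obj_id += 1
        _render_sphere(dio, center, r, gain_dio * scale, z_clip)
        _render_sphere(dapi, center, nuc_r, gain_dapi * scale, z_clip)
        records.append({
            "id": obj_id, "kind": kind, "cluster_id": cluster_id,
            "z": center[0], "y": center[1], "x": center[2],
            "intended_voxels": sphere_vox,
        })

    cluster_id = 0
    for kind, center in zip(group_kinds, centers):
        if kind == "singleton":
            add_cell(center, "singleton", -1)
        else:
            cluster_id += 1
            size = int(rng.integers(spec.cells_per_cluster[0],
                                    spec.cells_per_cluster[1] + 1))
            add_cell(center, "cluster", cluster_id)
            for _ in range(size - 1):
                disp = rng.normal(0.0, spec.cluster_spread_vox, size=3)
                member = tuple(int(np.clip(center[a] + round(disp[a]),
                                           (z_lo, y_lo, x_lo)[a],
                                           (z_hi, y_hi, x_hi)[a]))
                               for a in range(3))
                add_cell(member, "cluster", cluster_id)

    glass_slices = None
    if glass is not None:
        glo, ghi = glass.z_range
        for _ in range(glass.n_cells):
            center = (int(rng.integers(glo, ghi + 1)),
                      int(rng.integers(0, ydim)),
                      int(rng.integers(0, xdim)))
            add_cell(center, "glass", -1, scale=glass.intensity_scale,
                     z_clip=(glo, ghi))
        glass_slices = (glo, ghi)

    channels = {}
    for name, canvas in (("DiO", dio), ("DAPI", dapi)):
        img = canvas + spec.background
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
        channels[name] = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    stack = ImageStack(channels=channels, voxel_size_zyx=spec.voxel_size_zyx)
    truth = StackTruth(
        objects=pd.DataFrame(records, columns=[
            "id", "kind", "cluster_id", "z", "y", "x", "intended_voxels"]),
        glass_slices=glass_slices,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# Single-cell counts
# ---------------------------------------------------------------------------

@dataclass
class CountsSpec:
    """Parameters of a synthetic gene × cell count matrix."""

    n_genes: int = 300
    n_cells_per_condition: dict[str, int] = field(
        default_factory=lambda: {"control": 500, "treated": 500})
    nb_mean: float = 2.0
    nb_dispersion: float = 2.0
    mito_gene_count: int = 10
    mito_fraction_by_condition: dict[str, float] = field(
        default_factory=lambda: {"control": 0.05, "treated": 0.30})
    stem_subpop: tuple[float, tuple[str, ...], float] = (0.10, DEFAULT_STEM_MARKERS, 4.0)
    max_molecules_tail: float = 0.0
    tail_threshold: int = 40_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nb_dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.mito_gene_count >= self.n_genes:
            raise ValueError("mito_gene_count must be < n_genes")
        fracs = list(self.mito_fraction_by_condition.values()) + [
            self.stem_subpop[0], self.max_molecules_tail]
        if any(not (0.0 <= f <= 1.0) for f in fracs):
            raise ValueError("fractions must lie in [0, 1]")
        if set(self.mito_fraction_by_condition) != set(self.n_cells_per_condition):
            raise ValueError("mito fractions and cell counts disagree on conditions")


def simulate_counts(spec: CountsSpec) -> tuple[AnnData, dict]:
    """Draw a negative-binomial count matrix with planted structure.

    Counts are gamma-Poisson draws with mean ``nb_mean`` per gene and
    dispersion (gamma shape) ``nb_dispersion``.  Mitochondrial gene means
    are set per cell so the expected mitochondrial count fraction equals
    the condition's target exactly.  A ``stem_subpop`` fraction of cells
    has its marker-gene means multiplied by the fold elevation.  A
    ``max_molecules_tail`` fraction of cells is over-sequenced so its
    expected total exceeds ``tail_threshold``.
    """
    rng = np.random.default_rng(spec.seed)
    stem_frac, markers, fold = spec.stem_subpop
    markers = tuple(markers)
    n_mito = spec.mito_gene_count
    n_filler = spec.n_genes - n_mito - len(markers)
    if n_filler < 0:
        raise ValueError("too many marker + mito genes for n_genes")
    genes = (list(markers)
             + [f"MT-{i + 1}" for i in range(n_mito)]
             + [f"G{i + 1:05d}" for i in range(n_filler)])
    mito_flag = np.array([g.startswith("MT-") for g in genes])

    conditions = list(spec.n_cells_per_condition)
    cond_per_cell = np.concatenate([
        np.repeat(c, spec.n_cells_per_condition[c]) for c in conditions])
    n_cells = cond_per_cell.size

    stem_n = int(round(stem_frac * n_cells))
    stem_cells = np.zeros(n_cells, dtype=bool)
    if stem_n:
        stem_cells[rng.choice(n_cells, size=stem_n, replace=False)] = True

    tail_n = int(round(spec.max_molecules_tail * n_cells))
    tail_cells = np.zeros(n_cells, dtype=bool)
    if tail_n:
        tail_cells[rng.choice(n_cells, size=tail_n, replace=False)] = True

    mu = np.full((n_cells, spec.n_genes), spec.nb_mean, dtype=float)
    marker_idx = np.arange(len(markers))
    mu[np.ix_(stem_cells, marker_idx)] *= fold

    # mitochondrial means per cell: expected mito fraction == target exactly
    nonmito_total = mu[:, ~mito_flag].sum(axis=1)
    for c in conditions:
        f = spec.mito_fraction_by_condition[c]
        in_c = cond_per_cell == c
        per_gene = (f / (1.0 - f)) * nonmito_total[in_c] / n_mito if f < 1.0 else 0.0
        mu[np.ix_(in_c, np.flatnonzero(mito_flag))] = np.atleast_1d(per_gene)[:, None]

    if tail_n:
        totals = mu.sum(axis=1)
        scale = 1.5 * spec.tail_threshold / totals[tail_cells]
        mu[tail_cells] *= scale[:, None]

    lam = rng.gamma(shape=spec.nb_dispersion, scale=mu / spec.nb_dispersion)
    counts = rng.poisson(lam)

    obs = pd.DataFrame({
        "condition": cond_per_cell,
        "stem": stem_cells,
        "tail": tail_cells,
        "cluster": np.where(stem_cells, "stem",
                            np.char.add("bulk_", cond_per_cell.astype(str))),
    }, index=[f"cell{i + 1:05d}" for i in range(n_cells)])
    var = pd.DataFrame({"mito": mito_flag}, index=genes)
    adata = AnnData(X=sp.csr_matrix(counts), obs=obs, var=var)
    truth = {
        "markers": list(markers),
        "fold": fold,
        "n_stem": stem_n,
        "n_tail": tail_n,
        "mito_fraction_by_condition": dict(spec.mito_fraction_by_condition),
    }
    return adata, truth


# ---------------------------------------------------------------------------
# Interaction networks / gene sets / DEG table
# ---------------------------------------------------------------------------

@dataclass
class NetworkSpec:
    """Parameters of the synthetic network/annotation/DEG fixtures."""

    n_genes: int = 1000
    n_deg: int = 50
    edges_per_level: dict[str, int] = field(default_factory=lambda: {
        "ppi": 600, "tf": 400, "mirna": 400, "coexpression": 800})
    planted_clique_size: int = 8
    planted_clique_level: str = "ppi"
    planted_term: tuple[str, int, float] = ("TERM_PLANTED", 20, 0.9)
    n_terms: int = 50
    term_size_range: tuple[int, int] = (10, 40)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_clique_size < 3:
            raise ValueError("planted_clique_size must be >= 3")
        if self.term_size_range[1] > self.n_genes:
            raise ValueError("term_size_range exceeds the gene universe")
        if self.planted_term[1] > self.n_genes:
            raise ValueError("planted term larger than the gene universe")
        if self.planted_clique_level not in self.edges_per_level:
            raise ValueError("planted_clique_level not among the levels")
        if self.n_deg > self.n_genes:
            raise ValueError("n_deg exceeds the gene universe")


def simulate_networks(
    spec: NetworkSpec,
) -> tuple[dict[str, pd.DataFrame], dict[str, set], pd.DataFrame, dict]:
    """Generate per-level edge tables, a GMT collection, a DEG table, and
    ground truth.

    Every level's edge table is a simple undirected edge list (no self
    loops or duplicate pairs) biased so that about half the edge endpoints
    are DEGs (first-order networks are then non-trivial).  One level
    carries a planted clique among the DEG genes, and the annotation
    collection contains one planted term drawn mostly from the DEGs plus
    uniform background terms.  Interactor ids for every level live in the
    same gene universe that the annotation collection covers, so the
    per-network ORA universe (annotation ∩ network nodes) is well defined
    at every level.
    """
    rng = np.random.default_rng(spec.seed)
    width = len(str(spec.n_genes))
    genes = np.array([f"G{i + 1:0{width}d}" for i in range(spec.n_genes)])
    deg_genes = genes[:spec.n_deg]

    # DEG table over the full measured universe; DEGs strictly below 0.05
    adj_p = np.concatenate([
        rng.uniform(0.0, 0.049, size=spec.n_deg),
        rng.uniform(0.05, 1.0, size=spec.n_genes - spec.n_deg),
    ])
    logfc = rng.normal(0.0, 1.5, size=spec.n_genes)
    logfc = np.sign(logfc) * (np.abs(logfc) + 0.3)
    deg_table = pd.DataFrame({"gene": genes, "logFC": logfc, "adj_p": adj_p})

    term_name, term_size, deg_frac = spec.planted_term
    n_from_deg = min(int(round(term_size * deg_frac)), spec.n_deg)
    term_deg = rng.choice(deg_genes, size=n_from_deg, replace=False) if n_from_deg else np.array([], dtype=genes.dtype)
    nondeg_pool = genes[spec.n_deg:]
    term_rest = rng.choice(nondeg_pool, size=term_size - n_from_deg, replace=False)
    planted_genes = set(term_deg) | set(term_rest)

    # clique members come from the planted term's DEGs, topped up from the
    # DEG list and then the term itself when those run short
    clique_pool = np.array(sorted(set(term_deg)))
    clique = rng.choice(clique_pool, size=min(spec.planted_clique_size, clique_pool.size),
                        replace=False) if clique_pool.size else np.array([], dtype=genes.dtype)
    if clique.size < spec.planted_clique_size:
        extra = [g for g in list(deg_genes) + sorted(planted_genes)
                 if g not in set(clique)]
        clique = np.concatenate([
            clique, np.array(extra[: spec.planted_clique_size - clique.size])])
    clique = sorted(map(str, clique))

    edge_tables: dict[str, pd.DataFrame] = {}
    for level, n_edges in spec.edges_per_level.items():
        seen: set[frozenset] = set()
        rows = []
        if level == spec.planted_clique_level:
            for u, v in itertools.combinations(clique, 2):
                seen.add(frozenset((u, v)))
                rows.append((u, v))
        while len(rows) < n_edges:
            bias_deg = deg_genes.size > 0 and rng.random() < 0.5
            u = str(rng.choice(deg_genes) if bias_deg else rng.choice(genes))
            v = str(rng.choice(genes))
            key = frozenset((u, v))
            if u == v or key in seen:
                continue
            seen.add(key)
            rows.append((u, v))
        edge_tables[level] = pd.DataFrame(rows, columns=["source", "target"])
        edge_tables[level]["level"] = level

    gene_sets: dict[str, set] = {term_name: planted_genes}
    lo, hi = spec.term_size_range
    for t in range(spec.n_terms - 1):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=size, replace=False)
        gene_sets[f"TERM_{t + 1:04d}"] = set(map(str, members))

    truth = {
        "deg_genes": list(map(str, deg_genes)),
        "planted_term": term_name,
        "planted_term_genes": sorted(map(str, planted_genes)),
        "clique_members": list(clique),
        "clique_level": spec.planted_clique_level,
    }
    return edge_tables, gene_sets, deg_table, truth
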