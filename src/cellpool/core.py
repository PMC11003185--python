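"""Per-sample supercell construction.

The pipeline groups phenotypically similar cells of one sample into
"supercells": PCA on the marker matrix, an exact k-nearest-neighbour graph on
the principal-component scores, walktrap community detection producing a merge
dendrogram, and a cut of that dendrogram into

    k = clamp(round_half_up(n / gamma), n_components, n)

groups, where gamma is the target cells-per-supercell ratio. The dendrogram is
retained so the compression level can be changed later (:func:`recut`) without
redoing the graph or the walktrap agglomeration.

Everything here is deterministic for a fixed input, parameter set and seed:
PCA uses a full SVD with deterministic sign convention, the kNN search is
exact, and walktrap on a fixed graph is deterministic. Ties (duplicate points,
equal-size groups) are broken by lowest cell index throughout.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import igraph as ig
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .io_transform import ExpressionTable, IntegrityError

logger = logging.getLogger("cellpool")

#: below this many cells the kNN search is brute force with a stable sort,
#: which guarantees lowest-index tie-breaking for duplicated points; above it
#: a KD-tree is used (still exact distances, tie order tree-determined)
BRUTE_FORCE_KNN_MAX = 2048

DENDROGRAM_FORMAT_VERSION = 1


class ParameterError(ValueError):
    """A pipeline parameter is out of its valid range."""


@dataclass
class CoreParams:
    """Tunable parameters of the supercell pipeline.

    gamma is the ratio of cells to supercells (compression level); 20 is a
    good default for most cytometry data. n_pcs caps the PCA dimensionality
    (reduced to the marker count when there are fewer than n_pcs markers).
    walk_steps is the random-walk length of the walktrap agglomeration.
    """

    n_pcs: int = 10
    knn_k: int = 5
    walk_steps: int = 4
    gamma: float = 20.0
    aggregation: str = "mean"
    seed: int = 0
    scale: bool = False  # unit-variance scaling before PCA (off: arcsinh scale is shared)

    def __post_init__(self) -> None:
        if self.n_pcs < 1:
            raise ParameterError(f"n_pcs must be >= 1, got {self.n_pcs}")
        if self.knn_k < 1:
            raise ParameterError(f"knn_k must be >= 1, got {self.knn_k}")
        if self.walk_steps < 1:
            raise ParameterError(f"walk_steps must be >= 1, got {self.walk_steps}")
        if self.gamma < 1:
            raise ParameterError(f"gamma must be >= 1, got {self.gamma}")
        if self.aggregation not in ("mean", "median"):
            raise ParameterError(
                f"aggregation must be 'mean' or 'median', got {self.aggregation!r}"
            )


@dataclass
class PCAScores:
    scores: np.ndarray  # (n_cells, n_components)
    explained_variance: np.ndarray  # non-increasing

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


@dataclass
class KNNGraph:
    """Union-symmetrised exact kNN graph over the cells of one sample."""

    n: int
    k: int
    edges: np.ndarray  # (m, 2) int, each row sorted, rows unique & sorted

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n, dtype=int)
        np.add.at(deg, self.edges.ravel(), 1)
        return deg


@dataclass
class MergeDendrogram:
    """Record of the walktrap agglomeration for one sample, reusable for recuts.

    Stored per connected component of the kNN graph: ``components[i]`` holds
    the member cell row indices (within the sample) and the local merge list
    in igraph convention (indices < n_i are leaves, >= n_i earlier merges).
    """

    sample_id: str
    cell_ids: list[str]
    components: list[dict]  # {"nodes": list[int], "merges": list[[int, int]]}
    params: CoreParams
    checksum: str

    @property
    def n(self) -> int:
        return len(self.cell_ids)

    @property
    def n_components(self) -> int:
        return len(self.components)

    # -- store serialisation -------------------------------------------------

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "format_version": DENDROGRAM_FORMAT_VERSION,
            "sample_id": self.sample_id,
            "n_cells": self.n,
            "params": asdict(self.params),
            "checksum": self.checksum,
            "cell_ids": self.cell_ids,
            "components": [
                {"nodes": [int(x) for x in c["nodes"]],
                 "merges": [[int(a), int(b)] for a, b in c["merges"]]}
                for c in self.components
            ],
        }
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "MergeDendrogram":
        payload = json.loads(Path(path).read_text())
        version = payload.get("format_version")
        if version != DENDROGRAM_FORMAT_VERSION:
            raise IntegrityError(
                f"dendrogram store version {version!r} not supported "
                f"(expected {DENDROGRAM_FORMAT_VERSION})"
            )
        return cls(
            sample_id=payload["sample_id"],
            cell_ids=payload["cell_ids"],
            components=payload["components"],
            params=CoreParams(**payload["params"]),
            checksum=payload["checksum"],
        )

    def verify_against(self, table_s: ExpressionTable) -> None:
        """Refuse to recut against a table that is not the one this dendrogram
        was built from."""
        actual = input_checksum(table_s)
        if actual != self.checksum:
            raise IntegrityError(
                f"dendrogram store checksum {self.checksum} does not match the "
                f"supplied table ({actual}); recut refused"
            )


@dataclass
class SupercellPartition:
    """Assignment of every cell to exactly one supercell.

    ``mapping`` columns: cell_id, sample_id, supercell_id. Supercell ids embed
    the sample id (``<sample>_SC_<j>``) so no supercell can span samples.
    """

    mapping: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"cell_id", "sample_id", "supercell_id"}
        missing = required - set(self.mapping.columns)
        if missing:
            raise IntegrityError(f"partition mapping missing columns {sorted(missing)}")
        if self.mapping["cell_id"].duplicated().any():
            raise IntegrityError("partition maps some cell more than once")
        spans = self.mapping.groupby("supercell_id")["sample_id"].nunique()
        multi = spans[spans > 1]
        if not multi.empty:
            raise IntegrityError(
                f"supercells span multiple samples: {list(multi.index)[:10]}"
            )

    @property
    def n_cells(self) -> int:
        return len(self.mapping)

    @property
    def n_supercells(self) -> int:
        return self.mapping["supercell_id"].nunique()

    def cells_of(self, supercell_id: str) -> list[str]:
        sel = self.mapping["supercell_id"] == supercell_id
        return self.mapping.loc[sel, "cell_id"].tolist()


@dataclass
class SupercellExpression:
    """One row per supercell: aggregated markers, sample id, member count."""

    data: pd.DataFrame  # supercell_id, sample_id, n_cells, <markers...>
    markers: list[str]

    def __post_init__(self) -> None:
        required = {"supercell_id", "sample_id", "n_cells", *self.markers}
        missing = required - set(self.data.columns)
        if missing:
            raise IntegrityError(f"expression missing columns {sorted(missing)}")
        if (self.data["n_cells"] < 1).any():
            raise IntegrityError("supercell with n_cells < 1")

    @property
    def n_supercells(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# Stage 1: PCA
# ---------------------------------------------------------------------------


def compute_pca(
    matrix: np.ndarray, n_pcs: int = 10, scale: bool = False, seed: int = 0
) -> PCAScores:
    """Principal-component scores of a cell x marker matrix.

    Markers are centred (and optionally scaled to unit variance). The number
    of components is ``min(n_pcs, n_markers, n_cells)`` — datasets with fewer
    markers than n_pcs simply use all markers. Full SVD, deterministic.
    """
    if n_pcs < 1:
        raise ParameterError(f"n_pcs must be >= 1, got {n_pcs}")
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1 or X.shape[1] < 1:
        raise ParameterError(f"matrix must be 2-D and non-empty, got shape {X.shape}")
    if not np.isfinite(X).all():
        raise IntegrityError("matrix contains non-finite values")
    n, p = X.shape
    d = min(n_pcs, p, n)
    if scale:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    if n == 1:
        return PCAScores(np.zeros((1, d)), np.zeros(d))
    pca = PCA(n_components=d, svd_solver="full", random_state=seed)
    scores = pca.fit_transform(X)
    return PCAScores(scores, pca.explained_variance_)


# ---------------------------------------------------------------------------
# Stage 2: exact kNN graph
# ---------------------------------------------------------------------------


def build_knn_graph(scores: PCAScores | np.ndarray, k: int) -> KNNGraph:
    """Euclidean kNN graph, symmetrised by union (edge if either end lists
    the other). Exact distances at any size; below ``BRUTE_FORCE_KNN_MAX``
    cells a stable brute-force sort additionally guarantees lowest-index
    tie-breaking for duplicated points.
    """
    X = scores.scores if isinstance(scores, PCAScores) else np.asarray(scores, float)
    n = X.shape[0]
    if n < 2:
        raise ParameterError(f"need at least 2 cells to build a kNN graph, got {n}")
    if k < 1 or k >= n:
        raise ParameterError(
            f"knn_k must satisfy 1 <= k <= n-1 (n={n}, k={k}); "
            "lower k or merge samples"
        )
    if n <= BRUTE_FORCE_KNN_MAX:
        dist = cdist(X, X)
        np.fill_diagonal(dist, np.inf)
        # stable sort: equal distances resolved by lowest cell index
        nbrs = np.argsort(dist, axis=1, kind="stable")[:, :k]
    else:
        nn = NearestNeighbors(n_neighbors=k + 1, algorithm="kd_tree").fit(X)
        _, idx = nn.kneighbors(X)
        # drop self (first column when distances are unique; guard otherwise)
        nbrs = np.empty((n, k), dtype=idx.dtype)
        for i in range(n):
            row = idx[i][idx[i] != i][:k]
            nbrs[i] = row
    src = np.repeat(np.arange(n), k)
    dst = nbrs.ravel()
    lo = np.minimum(src, dst)
    hi = np.maximum(src, dst)
    edges = np.unique(np.stack([lo, hi], axis=1), axis=0)
    edges = edges[edges[:, 0] != edges[:, 1]]
    return KNNGraph(n=n, k=k, edges=edges)


# ---------------------------------------------------------------------------
# Stage 3: walktrap dendrogram (per connected component)
# ---------------------------------------------------------------------------


def walktrap_dendrogram(
    graph: KNNGraph,
    steps: int = 4,
    sample_id: str = "",
    cell_ids: list[str] | None = None,
    params: CoreParams | None = None,
    checksum: str = "",
) -> MergeDendrogram:
    """Agglomerate cells by short-random-walk proximity.

    Walktrap runs separately on every connected component of the graph; each
    component contributes an independent merge list. A size-1 component has
    an empty merge list.
    """
    if graph.n < 1:
        raise ParameterError("graph is empty")
    if cell_ids is None:
        cell_ids = [str(i) for i in range(graph.n)]
    g = ig.Graph(n=graph.n, edges=[tuple(e) for e in graph.edges])
    membership = g.connected_components().membership
    components: list[dict] = []
    order = {}
    for node, comp in enumerate(membership):
        order.setdefault(comp, []).append(node)
    # components ordered by smallest member index for stable labelling
    for comp_id in sorted(order, key=lambda c: order[c][0]):
        nodes = order[comp_id]
        if len(nodes) == 1:
            components.append({"nodes": nodes, "merges": []})
            continue
        sub = g.induced_subgraph(nodes)  # preserves relative vertex order
        dend = sub.community_walktrap(steps=steps)
        components.append({"nodes": nodes, "merges": [list(m) for m in dend.merges]})
    if params is None:
        params = CoreParams(walk_steps=steps)
    return MergeDendrogram(
        sample_id=sample_id,
        cell_ids=list(cell_ids),
        components=components,
        params=params,
        checksum=checksum,
    )


# ---------------------------------------------------------------------------
# Stage 4: cutting the dendrogram
# ---------------------------------------------------------------------------


def _allocate_groups(sizes: list[int], k: int) -> list[int]:
    """Largest-remainder allocation of k groups across components, minimum 1
    per component, at most its size. Requires len(sizes) <= k <= sum(sizes)."""
    c = len(sizes)
    n = sum(sizes)
    quotas = [k * s / n for s in sizes]
    alloc = [min(max(1, math.floor(q)), s) for q, s in zip(quotas, sizes)]
    # distribute / retract to hit exactly k, by remainder, ties by index
    def remainders():
        return [q - a for q, a in zip(quotas, alloc)]

    while sum(alloc) < k:
        rem = remainders()
        candidates = [i for i in range(c) if alloc[i] < sizes[i]]
        i = max(candidates, key=lambda j: (rem[j], -j))
        alloc[i] += 1
    while sum(alloc) > k:
        rem = remainders()
        candidates = [i for i in range(c) if alloc[i] > 1]
        i = min(candidates, key=lambda j: (rem[j], j))
        alloc[i] -= 1
    return alloc


def _cut_component(n_i: int, merges: list, k_i: int) -> list[list[int]]:
    """Replay the first n_i - k_i merges; return groups of local node indices."""
    groups: dict[int, list[int]] = {i: [i] for i in range(n_i)}
    next_id = n_i
    for a, b in merges[: n_i - k_i]:
        groups[next_id] = groups.pop(a) + groups.pop(b)
        next_id += 1
    return list(groups.values())


def cut_to_k(dendro: MergeDendrogram, k: int) -> SupercellPartition:
    """Cut the merge dendrogram into exactly k supercells.

    k must lie in [number of graph components, number of cells]. Groups are
    allocated across disconnected components by largest remainder
    (proportional to component size, at least one each) and labelled
    ``<sample>_SC_<j>`` with j ordered by each group's smallest cell index.
    """
    n, c = dendro.n, dendro.n_components
    if not (c <= k <= n):
        raise ParameterError(
            f"k={k} outside valid range [{c}, {n}] "
            f"(graph has {c} components, {n} cells)"
        )
    sizes = [len(comp["nodes"]) for comp in dendro.components]
    alloc = _allocate_groups(sizes, k)
    groups: list[list[int]] = []
    for comp, k_i in zip(dendro.components, alloc):
        nodes = comp["nodes"]
        for local in _cut_component(len(nodes), comp["merges"], k_i):
            groups.append(sorted(nodes[j] for j in local))
    groups.sort(key=lambda grp: grp[0])
    sid = dendro.sample_id
    cell_ids = dendro.cell_ids
    rows = []
    for j, grp in enumerate(groups, start=1):
        label = f"{sid}_SC_{j}" if sid else f"SC_{j}"
        for node in grp:
            rows.append((cell_ids[node], sid, label))
    mapping = pd.DataFrame(rows, columns=["cell_id", "sample_id", "supercell_id"])
    # restore input cell order
    pos = {cid: i for i, cid in enumerate(cell_ids)}
    mapping = mapping.sort_values(
        "cell_id", key=lambda s: s.map(pos), kind="stable"
    ).reset_index(drop=True)
    return SupercellPartition(mapping)


# ---------------------------------------------------------------------------
# End-to-end per-sample run and recut
# ---------------------------------------------------------------------------


def target_supercell_count(n_cells: int, gamma: float, n_components: int) -> int:
    """k = clamp(round_half_up(n / gamma), components, n)."""
    k = math.floor(n_cells / gamma + 0.5)
    return min(max(k, n_components, 1), n_cells)


def input_checksum(table_s: ExpressionTable) -> str:
    """sha256 over cell ids and the marker matrix; binds a dendrogram store
    to the exact table it was computed from."""
    h = hashlib.sha256()
    h.update("\x00".join(map(str, table_s.data["cell_id"])).encode())
    h.update(b"\x00")
    h.update(np.ascontiguousarray(table_s.marker_matrix()).tobytes())
    return h.hexdigest()


def supercells_for_sample(
    table_s: ExpressionTable, params: CoreParams
) -> tuple[SupercellPartition, MergeDendrogram]:
    """Run the full pipeline on the cells of a single sample.

    Returns the partition at ``params.gamma`` plus the merge dendrogram for
    later recuts at other gamma values.
    """
    samples = table_s.sample_ids
    if len(samples) != 1:
        raise ParameterError(
            f"supercells_for_sample expects exactly one sample, got {samples}"
        )
    sid = samples[0]
    n = table_s.n_cells
    cell_ids = table_s.data["cell_id"].astype(str).tolist()
    checksum = input_checksum(table_s)
    if n == 1:
        dendro = MergeDendrogram(
            sample_id=sid,
            cell_ids=cell_ids,
            components=[{"nodes": [0], "merges": []}],
            params=params,
            checksum=checksum,
        )
        return cut_to_k(dendro, 1), dendro
    pcs = compute_pca(
        table_s.marker_matrix(), params.n_pcs, scale=params.scale, seed=params.seed
    )
    k_graph = min(params.knn_k, n - 1)
    graph = build_knn_graph(pcs, k_graph)
    dendro = walktrap_dendrogram(
        graph,
        steps=params.walk_steps,
        sample_id=sid,
        cell_ids=cell_ids,
        params=params,
        checksum=checksum,
    )
    c = dendro.n_components
    k = target_supercell_count(n, params.gamma, c)
    if c > math.floor(n / params.gamma + 0.5):
        logger.warning(
            "sample %s: kNN graph has %d components, exceeding the gamma "
            "target; returning %d supercells (one per component minimum)",
            sid, c, k,
        )
    return cut_to_k(dendro, k), dendro


def recut(dendro: MergeDendrogram, new_gamma: float) -> SupercellPartition:
    """Re-cut a stored dendrogram at a new gamma — identical to a fresh
    pipeline run at that gamma, without recomputing PCA, kNN or walktrap."""
    if new_gamma < 1:
        raise ParameterError(f"gamma must be >= 1, got {new_gamma}")
    k = target_supercell_count(dendro.n, new_gamma, dendro.n_components)
    return cut_to_k(dendro, k)


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------


def aggregate_expression(
    table: ExpressionTable, partition: SupercellPartition, aggregation: str = "mean"
) -> SupercellExpression:
    """Aggregate member-cell marker values (mean or median) per supercell."""
    if aggregation not in ("mean", "median"):
        raise ParameterError(
            f"aggregation must be 'mean' or 'median', got {aggregation!r}"
        )
    assigned = set(partition.mapping["cell_id"].astype(str))
    cells = table.data["cell_id"].astype(str)
    missing = [c for c in cells if c not in assigned]
    if missing:
        raise IntegrityError(
            f"cells missing from the partition: {missing[:10]}"
        )
    merged = table.data.merge(
        partition.mapping[["cell_id", "supercell_id"]], on="cell_id", how="left"
    )
    grouped = merged.groupby("supercell_id", sort=False)
    agg = grouped[table.markers].agg(aggregation)
    meta = grouped.agg(sample_id=("sample_id", "first"), n_cells=("cell_id", "size"))
    out = pd.concat([meta, agg], axis=1).reset_index()
    # deterministic row order: sample id, then numeric supercell index
    out["_j"] = out["supercell_id"].str.rsplit("_", n=1).str[-1].astype(int)
    out = (
        out.sort_values(["sample_id", "_j"], kind="stable")
        .drop(columns="_j")
        .reset_index(drop=True)
    )
    out = out[["supercell_id", "sample_id", "n_cells", *table.markers]]
    return SupercellExpression(out, table.markers)
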