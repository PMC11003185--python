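"""Downstream-analysis plumbing.

After supercells are clustered, these helpers prepare the inputs that
standard differential-expression and differential-abundance tools consume:
majority-vote annotation of supercells, per sample x cell type pseudobulk
means of cell-state markers, the "> min cells from each sample" cluster
filter, and per-sample cluster proportion tables. Proportions are computed
at the single-cell level (after expanding supercells back to cells), since
supercells hold unequal numbers of cells. The statistics themselves
(moderated t-tests, proportion models) are left to external tooling; this
module only emits their input matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core import SupercellExpression, SupercellPartition

UNASSIGNED_LABEL = "unassigned"


@dataclass
class PseudobulkMatrix:
    data: pd.DataFrame  # sample_id, cell_type, n_supercells, <markers...>
    markers: list[str]


def annotate_majority(
    partition: SupercellPartition, labels: dict[str, str] | pd.Series
) -> dict[str, str]:
    """Label each supercell with the most abundant member cell type.

    Unlabelled members are ignored; supercells with no labelled member get
    ``"unassigned"``. Ties are broken alphabetically.
    """
    labels = pd.Series(labels)
    labels = labels[labels.notna()]
    m = partition.mapping
    out: dict[str, str] = {}
    labelled = m[m["cell_id"].isin(labels.index)].copy()
    labelled["label"] = labelled["cell_id"].map(labels)
    for sc, grp in labelled.groupby("supercell_id", sort=False):
        counts = grp["label"].value_counts()
        out[sc] = sorted(counts[counts == counts.max()].index)[0]
    for sc in m["supercell_id"].unique():
        out.setdefault(sc, UNASSIGNED_LABEL)
    return out


def pseudobulk(
    expression: SupercellExpression,
    annotation: dict[str, str] | pd.Series,
    markers: list[str] | None = None,
    weight_by_cells: bool = False,
) -> PseudobulkMatrix:
    """Mean expression per (sample, cell type), averaged over supercells.

    ``markers`` selects the cell-state markers to aggregate (default: all).
    The mean is unweighted over supercells; ``weight_by_cells=True`` weights
    each supercell by its member-cell count instead.
    """
    markers = list(markers) if markers is not None else list(expression.markers)
    if not markers:
        raise ValueError("empty marker set")
    unknown = [m for m in markers if m not in expression.markers]
    if unknown:
        raise KeyError(f"unknown markers: {unknown}")
    annotation = pd.Series(annotation)
    df = expression.data.copy()
    missing = df.loc[~df["supercell_id"].isin(annotation.index), "supercell_id"]
    if not missing.empty:
        raise ValueError(f"unannotated supercells: {missing.tolist()[:10]}")
    df["cell_type"] = df["supercell_id"].map(annotation)
    rows = []
    for (sid, ctype), grp in df.groupby(["sample_id", "cell_type"], sort=True):
        if weight_by_cells:
            w = grp["n_cells"].to_numpy(dtype=float)
            means = [(grp[m].to_numpy() * w).sum() / w.sum() for m in markers]
        else:
            means = [grp[m].mean() for m in markers]
        rows.append((sid, ctype, len(grp), *means))
    data = pd.DataFrame(
        rows, columns=["sample_id", "cell_type", "n_supercells", *markers]
    )
    return PseudobulkMatrix(data=data, markers=markers)


def filter_clusters(
    cell_table: pd.DataFrame, min_per_sample: int = 3
) -> list:
    """Clusters with more than ``min_per_sample`` cells in EVERY sample.

    A cluster absent from any sample (zero cells there) is dropped: the
    strict inequality fails. Raising the threshold never adds clusters.
    """
    for col in ("cluster_id", "sample_id"):
        if col not in cell_table.columns:
            raise KeyError(f"cell table lacks required column {col!r}")
    samples = cell_table["sample_id"].unique()
    counts = (
        cell_table.groupby(["cluster_id", "sample_id"]).size().unstack(fill_value=0)
    )
    counts = counts.reindex(columns=samples, fill_value=0)
    keep = counts.gt(min_per_sample).all(axis=1)
    return sorted(counts.index[keep])


def cluster_proportions(cell_table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample cluster proportions at the single-cell level.

    Rows are samples, columns clusters, values the fraction of the sample's
    cells in each cluster; every row sums to 1. Computed on single cells
    (after supercell expansion) so unequal supercell sizes cannot distort
    the abundances.
    """
    for col in ("cluster_id", "sample_id"):
        if col not in cell_table.columns:
            raise KeyError(f"cell table lacks required column {col!r}")
    counts = (
        cell_table.groupby(["sample_id", "cluster_id"]).size().unstack(fill_value=0)
    )
    props = counts.div(counts.sum(axis=1), axis=0)
    props.index.name = "sample_id"
    return props.sort_index().sort_index(axis=1)
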