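"""Quality metrics for supercell partitions.

Purity measures within-supercell homogeneity: the proportion of the most
dominant cell type among a supercell's annotated members. ARI and NMI score
agreement between two partitions of the same cells (chance-corrected pair
counting and information-theoretic, respectively). Label-transfer accuracy is
reported per cell type and as a proportion-weighted overall score. Batch
differences per marker are quantified with a one-dimensional Earth Mover's
Distance computed on histograms with a fixed bin width (0.1 by default, on
the arcsinh scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

from .core import SupercellPartition

DEFAULT_EMD_BIN_WIDTH = 0.1


@dataclass
class PurityReport:
    per_supercell: pd.DataFrame  # supercell_id, purity, n_labelled, dominant_type
    mean_purity: float
    fraction_pure: float  # share of scored supercells at purity exactly 1
    n_labelled_cells: int
    n_unscored_supercells: int  # supercells with no labelled member


@dataclass
class LabelMapping:
    """Fine-to-consolidated label mapping; unmapped labels pass through."""

    fine_to_coarse: dict[str, str] = field(default_factory=dict)

    def apply(self, label: str) -> str:
        return self.fine_to_coarse.get(label, label)

    def coarse_to_fine(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for fine, coarse in self.fine_to_coarse.items():
            out.setdefault(coarse, []).append(fine)
        return out


@dataclass
class EMDReport:
    per_pair: pd.DataFrame  # marker, sample_1, sample_2, emd
    bin_width: float


def supercell_purity(
    partition: SupercellPartition, labels: dict[str, str] | pd.Series
) -> PurityReport:
    """Proportion of the dominant cell type within each supercell.

    Labels may be partial: unlabelled cells are ignored, and supercells with
    no labelled member are excluded from scoring (counted separately).
    """
    labels = pd.Series(labels)
    labels = labels[labels.notna()]
    if labels.empty:
        raise ValueError("no labelled cells supplied")
    m = partition.mapping
    merged = m[m["cell_id"].isin(labels.index)].copy()
    if merged.empty:
        raise ValueError("no labelled cell appears in the partition")
    merged["label"] = merged["cell_id"].map(labels)
    rows = []
    for sc, grp in merged.groupby("supercell_id", sort=False):
        counts = grp["label"].value_counts()
        dominant = sorted(counts[counts == counts.max()].index)[0]
        rows.append((sc, counts.max() / len(grp), len(grp), dominant))
    per_sc = pd.DataFrame(
        rows, columns=["supercell_id", "purity", "n_labelled", "dominant_type"]
    )
    all_sc = partition.mapping["supercell_id"].nunique()
    return PurityReport(
        per_supercell=per_sc,
        mean_purity=float(per_sc["purity"].mean()),
        fraction_pure=float((per_sc["purity"] == 1.0).mean()),
        n_labelled_cells=int(len(merged)),
        n_unscored_supercells=int(all_sc - len(per_sc)),
    )


def _align_partitions(p1, p2) -> tuple[np.ndarray, np.ndarray]:
    """Align two cell -> group mappings on their common cell universe."""
    s1, s2 = pd.Series(p1), pd.Series(p2)
    s1, s2 = s1[s1.notna()], s2[s2.notna()]
    common = s1.index.intersection(s2.index)
    if len(common) == 0:
        raise ValueError("the two partitions share no cells")
    return s1.loc[common].to_numpy(), s2.loc[common].to_numpy()


def adjusted_rand_index(p1, p2) -> float:
    """Pair-counting agreement between two partitions, corrected for chance.

    1 for identical partitions (up to relabelling), ~0 for random agreement.
    Cells present in only one partition (e.g. unannotated) are dropped.
    """
    a, b = _align_partitions(p1, p2)
    return float(adjusted_rand_score(a, b))


def normalized_mutual_information(p1, p2) -> float:
    """NMI with arithmetic-mean normalisation, in [0, 1].

    If either partition is a single cluster the score is 0 by convention
    (there is no clustering structure to agree with).
    """
    a, b = _align_partitions(p1, p2)
    if len(np.unique(a)) <= 1 or len(np.unique(b)) <= 1:
        return 0.0
    return float(normalized_mutual_info_score(a, b, average_method="arithmetic"))


@dataclass
class AccuracyReport:
    per_type: pd.DataFrame  # cell_type, n_cells, proportion, accuracy
    weighted_accuracy: float


def label_accuracy(
    pred: dict[str, str] | pd.Series,
    truth: dict[str, str] | pd.Series,
    mapping: LabelMapping | None = None,
) -> AccuracyReport:
    """Per-type accuracy and the proportion-weighted overall accuracy.

    Both label sets are consolidated through ``mapping`` (fine subsets
    amalgamated into broader categories) before comparison. Cells without a
    truth label are excluded; type proportions are taken from the truth
    labels, and the weighted accuracy is sum_t accuracy_t * proportion_t.
    """
    mapping = mapping or LabelMapping()
    pred_s, truth_s = pd.Series(pred), pd.Series(truth)
    truth_s = truth_s[truth_s.notna()]
    common = pred_s.index.intersection(truth_s.index)
    if len(common) == 0:
        raise ValueError("no cell has both a prediction and a truth label")
    p = pred_s.loc[common].map(mapping.apply)
    t = truth_s.loc[common].map(mapping.apply)
    rows = []
    n = len(common)
    for ctype, idx in t.groupby(t).groups.items():
        correct = int((p.loc[idx] == ctype).sum())
        total = len(idx)
        rows.append((ctype, total, total / n, correct / total))
    per_type = pd.DataFrame(
        rows, columns=["cell_type", "n_cells", "proportion", "accuracy"]
    ).sort_values("cell_type").reset_index(drop=True)
    weighted = float((per_type["accuracy"] * per_type["proportion"]).sum())
    return AccuracyReport(per_type=per_type, weighted_accuracy=weighted)


def earth_movers_distance(
    x1, x2, bin_width: float = DEFAULT_EMD_BIN_WIDTH
) -> float:
    """1-D EMD (Wasserstein-1) between two samples after fixed-width binning.

    Both samples are binned on a shared grid of width ``bin_width`` anchored
    at ``floor(min/bin_width) * bin_width`` of the pooled data; histograms
    are normalised to unit mass and the distance is
    ``sum over bins of |cumulative difference| * bin_width``. Zero iff the
    binned histograms coincide.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.size == 0 or x2.size == 0:
        raise ValueError("both samples must be non-empty")
    if not (np.isfinite(x1).all() and np.isfinite(x2).all()):
        raise ValueError("samples contain non-finite values")
    if bin_width <= 0:
        raise ValueError(f"bin_width must be > 0, got {bin_width}")
    # half-open bins [i*w, (i+1)*w): a value is assigned to floor(x / w),
    # with rounding at the 9th decimal so edge values land in the upper bin
    # regardless of float representation (asinh scales make exact edges rare)
    def bin_index(x: np.ndarray) -> np.ndarray:
        return np.floor(np.round(x / bin_width, 9)).astype(np.int64)

    i1, i2 = bin_index(x1), bin_index(x2)
    lo = min(i1.min(), i2.min())
    n_bins = int(max(i1.max(), i2.max()) - lo + 1)
    h1 = np.bincount(i1 - lo, minlength=n_bins)
    h2 = np.bincount(i2 - lo, minlength=n_bins)
    p = h1 / h1.sum()
    q = h2 / h2.sum()
    return float(np.abs(np.cumsum(p - q)).sum() * bin_width)


def emd_per_marker(
    expression: pd.DataFrame,
    markers: list[str],
    sample_col: str = "sample_id",
    bin_width: float = DEFAULT_EMD_BIN_WIDTH,
) -> EMDReport:
    """EMD for every marker and unordered sample pair of an expression table
    (typically the supercell expression matrix)."""
    samples = sorted(expression[sample_col].unique())
    groups = {s: expression[expression[sample_col] == s] for s in samples}
    rows = []
    for i, s1 in enumerate(samples):
        for s2 in samples[i + 1 :]:
            for m in markers:
                d = earth_movers_distance(
                    groups[s1][m].to_numpy(), groups[s2][m].to_numpy(), bin_width
                )
                rows.append((m, s1, s2, d))
    return EMDReport(
        per_pair=pd.DataFrame(rows, columns=["marker", "sample_1", "sample_2", "emd"]),
        bin_width=bin_width,
    )
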