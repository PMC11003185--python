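"""Multi-sample orchestration.

Supercells are always created within a sample — never across samples — so
each sample is an independent unit of work. Samples are processed in
descending order of cell count (longest-processing-time greedy scheduling):
workers handling small samples pick up further ones while a worker busy with
the largest sample keeps at it. Results are a pure function of the table,
the parameters and the seed; the worker count never changes the output.
"""

from __future__ import annotations

import hashlib
import logging
import shutil
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from joblib import Parallel, delayed

from .core import (
    CoreParams,
    MergeDendrogram,
    SupercellExpression,
    SupercellPartition,
    aggregate_expression,
    supercells_for_sample,
)
from .io_transform import ExpressionTable, IntegrityError, write_outputs

logger = logging.getLogger("cellpool")


@dataclass
class RunPlan:
    """Deterministic schedule: samples in descending cell-count order (ties by
    sample id ascending) and their greedy assignment to workers."""

    order: list[str]
    assignments: list[list[str]]  # one list of sample ids per worker
    loads: list[int]  # total cells assigned per worker


@dataclass
class RunResult:
    partition: SupercellPartition
    expression: SupercellExpression
    dendrograms: dict[str, MergeDendrogram]
    plan: RunPlan
    store_paths: dict[str, Path] = field(default_factory=dict)


def schedule_samples(cell_counts: dict[str, int], n_workers: int) -> RunPlan:
    """Longest-processing-time schedule over samples.

    Samples sorted by descending count (ties by id); each is assigned to the
    currently least-loaded worker (ties by worker index). Work-conserving:
    no worker stays empty while another holds more than one sample.
    """
    if not cell_counts:
        raise ValueError("no samples to schedule")
    if n_workers < 1:
        raise ValueError(f"n_workers must be >= 1, got {n_workers}")
    if any(c <= 0 for c in cell_counts.values()):
        bad = [s for s, c in cell_counts.items() if c <= 0]
        raise ValueError(f"samples with non-positive cell counts: {bad}")
    order = sorted(cell_counts, key=lambda s: (-cell_counts[s], str(s)))
    assignments: list[list[str]] = [[] for _ in range(n_workers)]
    loads = [0] * n_workers
    for sid in order:
        w = min(range(n_workers), key=lambda i: (loads[i], i))
        assignments[w].append(sid)
        loads[w] += cell_counts[sid]
    return RunPlan(order=order, assignments=assignments, loads=loads)


def derive_sample_seed(run_seed: int, sample_id: str) -> int:
    """Stable per-sample seed; adding or removing a sample from a run leaves
    every other sample's result untouched."""
    digest = hashlib.sha256(f"{run_seed}:{sample_id}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _run_one(
    table: ExpressionTable, sample_id: str, params: CoreParams
) -> tuple[str, SupercellPartition, SupercellExpression, MergeDendrogram]:
    sub = table.restrict_to_sample(sample_id)
    sparams = CoreParams(
        n_pcs=params.n_pcs,
        knn_k=params.knn_k,
        walk_steps=params.walk_steps,
        gamma=params.gamma,
        aggregation=params.aggregation,
        seed=derive_sample_seed(params.seed, sample_id),
        scale=params.scale,
    )
    part, dendro = supercells_for_sample(sub, sparams)
    expr = aggregate_expression(sub, part, params.aggregation)
    return sample_id, part, expr, dendro


def run_all_samples(
    table: ExpressionTable,
    params: CoreParams,
    n_workers: int = 1,
    out_dir: str | Path | None = None,
) -> RunResult:
    """Create supercells for every sample of the table.

    Per-sample results are identical to serial execution; ``n_workers`` only
    affects wall time. When ``out_dir`` is given, the combined cell-supercell
    map, the combined supercell expression matrix and one dendrogram store per
    sample are written there atomically (nothing is left behind on failure).
    """
    counts = table.data["sample_id"].value_counts().to_dict()
    plan = schedule_samples(counts, n_workers)
    logger.info(
        "processing %d samples (%d cells) on %d worker(s)",
        len(plan.order), table.n_cells, n_workers,
    )
    if n_workers == 1:
        results = [_run_one(table, sid, params) for sid in plan.order]
    else:
        results = Parallel(n_jobs=n_workers)(
            delayed(_run_one)(table, sid, params) for sid in plan.order
        )
    by_sample = {sid: (part, expr, dendro) for sid, part, expr, dendro in results}

    # combine deterministically: map rows in input-table cell order,
    # expression rows by (sample_id, supercell index)
    mapping = pd.concat(
        [by_sample[sid][0].mapping for sid in plan.order], ignore_index=True
    )
    pos = {cid: i for i, cid in enumerate(table.data["cell_id"].astype(str))}
    mapping = mapping.sort_values(
        "cell_id", key=lambda s: s.map(pos), kind="stable"
    ).reset_index(drop=True)
    partition = SupercellPartition(mapping)
    expr_df = pd.concat(
        [by_sample[sid][1].data for sid in sorted(by_sample)], ignore_index=True
    )
    expression = SupercellExpression(expr_df, table.markers)
    dendrograms = {sid: by_sample[sid][2] for sid in plan.order}

    store_paths: dict[str, Path] = {}
    if out_dir is not None:
        out_dir = Path(out_dir)
        # stage into a temp dir, move into place only on success
        out_dir.parent.mkdir(parents=True, exist_ok=True)
        tmp = Path(tempfile.mkdtemp(prefix=".cellpool_", dir=out_dir.parent))
        try:
            write_outputs(expression, partition, tmp)
            for sid, dendro in dendrograms.items():
                dendro.save(tmp / f"dendrogram_{sid}.json")
            out_dir.mkdir(exist_ok=True)
            for item in tmp.iterdir():
                target = out_dir / item.name
                if target.exists():
                    target.unlink()
                shutil.move(str(item), target)
            for sid in dendrograms:
                store_paths[sid] = out_dir / f"dendrogram_{sid}.json"
        finally:
            shutil.rmtree(tmp, ignore_errors=True)
    return RunResult(
        partition=partition,
        expression=expression,
        dendrograms=dendrograms,
        plan=plan,
        store_paths=store_paths,
    )


def expand_partition(
    partition: SupercellPartition, per_supercell_values: dict[str, object]
) -> dict[str, object]:
    """Propagate a per-supercell value (cluster label, annotation, statistic)
    to every member cell — the supercell-to-single-cell expansion."""
    known = set(partition.mapping["supercell_id"])
    unknown = set(per_supercell_values) - known
    if unknown:
        raise IntegrityError(
            f"unknown supercell ids: {sorted(map(str, unknown))[:10]}"
        )
    sel = partition.mapping[partition.mapping["supercell_id"].isin(per_supercell_values)]
    return {
        cell: per_supercell_values[sc]
        for cell, sc in zip(sel["cell_id"], sel["supercell_id"])
    }
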