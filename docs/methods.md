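# Methods

## The supercell model

Modern flow and mass cytometry experiments routinely measure 10⁵–10⁷ cells
per sample, which makes per-cell clustering, batch correction and
differential testing slow and memory-hungry. cellpool compresses a cytometry
dataset by grouping phenotypically similar cells of the *same sample* into
**supercells** and carrying the analysis at the supercell level; any
per-supercell result can be expanded back to single cells at no cost through
the cell–supercell map.

Per sample, the construction is:

1. **PCA** on the cell × marker matrix (markers centred; unit-variance
   scaling optional and off by default since arcsinh-transformed markers
   already share a scale). The number of components is
   `min(n_pcs, n_markers, n_cells)` with `n_pcs = 10` by default — data with
   fewer than 10 markers use all markers. Full (deterministic) SVD with the
   usual sign convention.
2. **kNN graph** on the PC scores: exact Euclidean k-nearest neighbours
   (`k = 5` by default), symmetrised by union — an edge exists if either
   endpoint lists the other. The graph is simple and unweighted.
3. **Walktrap** community detection (random-walk length 4) on the graph,
   run separately on each connected component, producing a merge dendrogram
   from singletons up to one community per component. The agglomeration is
   delegated to igraph's C implementation.
4. **Cut** the dendrogram into
   `k = clamp(round_half_up(n / γ), c, n)` groups, where `n` is the sample's
   cell count, `c` the number of graph components and γ (gamma, default 20)
   the target cells-per-supercell ratio. Round-half-up is used rather than
   floor so that e.g. 85,715 cells at γ = 20 (quota 4,285.75) give 4,286
   supercells. Across disconnected components the k groups are allocated by
   largest remainder proportional to component size, minimum one per
   component; if there are more components than the γ target allows, one
   group per component is returned with a loud warning.
5. **Aggregate** marker expression per supercell by mean (default) or
   median, recording the member-cell count.

The dendrogram (plus the parameters and a checksum of the input) is saved as
a versioned JSON store per sample, so the compression level can be changed
later (**recut**) without recomputing PCA, the graph or walktrap. A recut at
γ′ is bit-identical to a fresh run at γ′; a store whose checksum does not
match the supplied table is refused.

## Multi-sample orchestration

Supercells never span samples. Samples are processed independently in
descending cell-count order with greedy longest-processing-time assignment
to workers, which keeps workers busy without letting the largest sample
stall the rest. Results are a pure function of (table, parameters, seed):
each sample's seed is derived as `sha256(run_seed, sample_id) mod 2³¹`, so
the worker count — and adding or removing another sample — cannot change any
sample's output. Outputs are staged to a temporary directory and moved into
place only on success.

## Evaluation metrics

* **Purity** — per supercell, the proportion of its most dominant cell type
  among *annotated* members; unannotated cells are ignored and supercells
  with no annotated member are excluded (counted separately). Singletons
  score 1 by construction.
* **ARI / NMI** — chance-corrected pair-counting and information-theoretic
  agreement between two partitions of the same cells, computed on the
  common cell universe (scikit-learn backed; tests verify against
  independent pair-counting and entropy oracles). NMI uses arithmetic-mean
  normalisation; if either partition is a single cluster the score is 0 by
  convention. ARI against annotations is computed on the expanded
  partition — every cell inherits its supercell's cluster label.
* **Label-transfer accuracy** — after consolidating fine subsets into
  broader categories through an explicit label mapping, per-type accuracy
  is `correct_t / total_t` and the weighted accuracy is
  `Σ_t accuracy_t · proportion_t` with proportions taken from the truth
  labels. Cells without truth labels are excluded.
* **EMD** — one-dimensional Wasserstein-1 distance between two marker
  distributions after binning both on a shared grid of fixed width 0.1
  (arcsinh scale). Bins are half-open `[i·w, (i+1)·w)` with the index
  computed as `floor(round(x/w, 9))`, so a value sitting on a bin edge
  lands in the upper bin regardless of floating-point representation; the
  distance is `Σ_bins |cumulative difference| · w`. Zero iff the binned
  histograms coincide; two unit point masses 1.0 apart give exactly 1.0.

## Downstream plumbing

Supercells are annotated by majority vote over annotated members (ties
broken alphabetically; no annotated member → "unassigned"). Pseudobulk
matrices average cell-state markers per sample × cell type, unweighted over
supercells by default (a cell-count-weighted option exists, off by default —
the most direct reading of "mean per sample and cell type" treats
supercells as the units). Cluster abundance tables are computed at the
single-cell level after expansion, because supercells hold unequal numbers
of cells and supercell-level proportions would distort abundances. The
cluster filter for differential-abundance testing retains a cluster only if
it has strictly more than `min_per_sample` (default 3) cells in *every*
sample; absence from a sample fails the rule. The statistics themselves
(moderated t-tests, proportion models) are deliberately out of scope; the
module emits their input CSVs.

## Synthetic data

The generator draws Gaussian mixtures on the arcsinh scale (values roughly
0–4): per sample, cell-type counts come from a multinomial over the
configured proportions (or largest-remainder rounding when exact counts are
required), and marker values are Normal(type mean + batch shift, sd). Type
mean vectors follow a signature-marker block pattern: each type is elevated
by `separation · sd` (default 3 sd) on its own marker pair above a shared
baseline, guaranteeing ≥ 3 sd pairwise Euclidean separation at the default
settings. Defaults — 3 samples × 20,000 cells, 10 markers, 5 types with
proportions 0.3/0.25/0.2/0.15/0.1, sd 0.5 — emulate a small multi-sample
experiment with both abundant and modest populations; rare populations
(e.g. 0.1%) and additive per-batch marker shifts are configured explicitly.

What the generator does *not* emulate: spillover, doublets, debris,
acquisition-time drift, zero-inflation of raw counts, or non-additive batch
distortions. Passing tests on this data therefore demonstrate the
correctness and determinism of the algorithmic pipeline and the exactness
of its counting/rounding rules — not that any particular purity level will
be reached on real instruments' data, where population separation is less
clean.

## Numerical and design choices

* **k = 5 neighbours**: kept small so walktrap communities stay local; the
  value is a convention of supercell-style aggregation, exposed as a
  parameter rather than fixed.
* **Exact kNN at every size**: below 2,048 cells a brute-force search with
  a stable sort guarantees lowest-cell-index tie-breaking for duplicated
  points; above it a KD-tree gives the same exact distances (tie order
  among exactly equidistant neighbours is then tree-determined, which is
  immaterial for continuous marker data).
* **Rounding**: `round_half_up(n/γ)` (i.e. `floor(n/γ + 0.5)`), clamped to
  `[components, n]`.
* **Tie-breaks**: everywhere by lowest cell index; supercell ids are
  `<sample>_SC_<j>` with j ordered by each group's smallest member index,
  so labels are stable across runs.
* **Degenerate inputs**: a single-cell sample yields one singleton
  supercell without building a graph; γ = 1 reproduces the input exactly;
  k ≥ n on the graph raises a parameter error suggesting a smaller k.
* **Problem sizes in tests**: the suite exercises the full pipeline at up
  to 100,000 cells (and a single 85,715-cell sample for the exact-count
  check), with smaller 400–5,000-cell fixtures for properties that do not
  depend on scale; these sizes keep the whole suite comfortably
  re-runnable on a single CPU.

## Known limitations

* Walktrap cost grows super-linearly with cell count; samples approaching
  10⁶ cells take hours on one core. Since samples are independent,
  wall-clock time scales down with workers across samples but not within
  one huge sample.
* The kNN graph is unweighted; edge weighting (e.g. by distance) is a
  documented extension point, not implemented.
* FCS support is read-only, list mode, float data types, without
  compensation/spillover handling — input is assumed cleaned and
  pre-gated. Logicle/CLR transforms are out of scope (`method="none"`
  accepts pre-transformed data).
* scib-style rescaling of metrics is not promised; the metric conventions
  are exactly the ones documented above.
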