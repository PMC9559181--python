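# Methods

This note documents the model behind `migpattern`, its tunable parameters,
the numerical choices made where the design was genuinely open, what the
synthetic data generator does and does not emulate, and the package's known
limitations. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The analysis model

The object of study is a colony of cells tracked through a time-lapse
recording: one 2-D nucleus position per cell per time slice (15-min slice
interval in the reference setup, so a 24-h recording has 97 slices).
The analysis assumes

* positions are in a fixed Cartesian frame in micrometres; the origin and
  orientation are irrelevant because every comparison is made after
  translation normalization;
* tracks have no gaps — a cell is followed continuously or not at all
  (gap-free tracking is an input contract, validated on read);
* migration *pattern* means the shape-and-speed of a cell's displacement
  curve over a window, not its location: two distant cells moving the same
  way have pattern distance 0.

### Lineage unification

Dividing cells would otherwise break the "one cell, one trajectory"
premise. Every cell present in the last slice is a leaf; its trajectory is
extended backwards through its ancestors so all leaves span the full
recording, and the two daughters of a division share the mother's positions
before it. This matches the backward-tracking convention in which each
final-slice cell is followed to the first slice.

Division events are detected from geometry alone, exploiting the
separability between the largest per-step displacement (≤ ~6 μm at 15-min
intervals) and the immediate daughter separation (> 10 μm): default
`jump_threshold` 10 μm, `proximity_threshold` 6 μm, requiring
`jump > proximity`. Two table forms are handled, selected automatically
from the track spans:

* **raw** (mother track ends, daughters begin on the next slice): a pair
  of co-starting tracks ≥ 10 μm apart whose midpoint lies within 6 μm of
  an ended track's last position is a division; candidate (mother, pair)
  matches are accepted greedily by midpoint gap, each cell participating
  in at most one event per slice;
* **unified** (every track spans the whole recording): a pair of cell ids
  whose markers *coincide numerically* (< 1e-5 μm) on every slice before
  `l` and are ≥ 10 μm apart at `l` divides at `l`. Coincidence rather than
  mere proximity is required because unified daughters carry exact copies
  of the mother's positions, whereas unrelated cells can transiently pass
  within a few micrometres of each other and then separate quickly —
  proximity alone would misread such passes as divisions.

The detector is validated only against synthetic colonies with planted
divisions (precision = recall = 1 over 20 seeds in the acceptance suite);
on real data, fluorescence imagery remains the arbiter and the detector's
output should be reviewed.

### Periods, normalization, distances

The recording is cut into non-overlapping windows of `window_slices`
(default 12) consecutive slices; the trailing partial window is dropped
(97 slices → 8 periods). Within a period each trajectory is translated so
its first position is the origin. The dissimilarity of two normalized
trajectories is the slice-wise sum of Euclidean point distances — a metric,
in units of μm·slices (a plain sum, not averaged by window length;
averaging would rescale every entry equally and change nothing downstream).
The per-period N×N distance matrix is the only input to the embedding.

### Embedding

Each period is embedded independently into 2-D by UMAP (default:
`n_neighbors` 15 clipped to N−1, `min_dist` 0.1) or t-SNE (`perplexity` 10,
clipped below (N−1)/3), always with `metric="precomputed"`. Two dimensions
keep the representation consistent with visualization. Both embedders are
stochastic and order-sensitive, so the pipeline fixes a canonical cell
order (ascending cell id) and passes explicit seeds; identical inputs and
seeds reproduce embeddings bitwise. There is no alignment of embeddings
across periods.

### Clustering and selection of K

k-means (Lloyd's algorithm) runs on the embedded points with `n_init`
(default 50) seeded restarts; the restart with the lowest within-cluster
sum of squares wins. The implementation is local rather than a library
call so that the per-iteration WCSS trace is exposed (monotone descent is
asserted, not assumed) and the empty-cluster repair rule is deterministic:
an emptied center is re-seeded at the point farthest from its current
center, never robbing a cluster down to emptiness. scikit-learn serves as
an independent cross-check in the tests, not as the implementation.

Silhouettes use the three-branch definition (`1 − a/b`, `0` when `a = b`,
`b/a − 1`), with singleton-cluster points scored 0 (their within-cluster
dissimilarity is undefined; 0 is the neutral convention, and scikit-learn
agrees). K̂_p maximizes the mean silhouette coefficient over
K ∈ [`k_min`, `k_max`] (default [2, min(10, N−1)]); exact ties go to the
smaller K. By default the silhouette is computed on the embedded points;
a variant on the raw trajectory distances is selectable
(`silhouette_space: trajectory`) but is not the default.

### Window/parameter sweep

`sweep_quality` re-runs the downstream clustering for candidate observation
windows and embedding parameters and reports per-period MSC (plus first- and
last-period values), without auto-selecting. Its quality score is computed
on the **trajectory** distance matrix by default: silhouettes measured on
UMAP/t-SNE outputs saturate near 1 for almost any window, because nonlinear
embedders exaggerate whatever separation exists, whereas the raw-metric
silhouette genuinely reflects how cleanly a window isolates migration
regimes. The embedding-space score remains available
(`quality_space="embedding"`).

### Noise robustness

Observation error in manual nucleus marking is modeled as i.i.d. 2-D
Gaussian noise added to every position. The covariance is diagonal with
equal entries; by default `sigma` is the per-coordinate *standard
deviation* (`sigma_is_std: true`). The alternative literal reading that
places σ itself on the covariance diagonal (per-coordinate variance σ) is
selectable; the two differ except at σ ∈ {0, 1} and neither is silently
preferred beyond the documented default.

For each σ in the grid (default [1, 2] μm — up to roughly a quarter of a
nucleus radius, the plausible scale of manual marking error) and each of
`h` (default 20) replicates, the pipeline re-runs at a *fixed* K (default:
the maximum selected K of the noise-free run; K re-selection under noise
would inflate K and make size vectors incomparable). Clusterings are
compared through their descending cluster-size vectors normalized by N;
the difference score of a period is the mean Euclidean distance between
the noise-free and replicate vectors. Embedding and k-means seeds are
shared between the original run and all replicates, so σ = 0 reproduces
the original exactly and scores identically 0. Size vectors of different
lengths (possible only in non-default use) are zero-padded before
comparison.

Matching clusters by sorted size ignores labels entirely: two clusterings
that swap the members of two equal-size clusters score 0. This is a known
limitation of the size-spectrum view; no overlap-based relabeling is
attempted.

## The synthetic colony generator

`generate_colony` emulates the statistical structure the analysis assumes,
not cell mechanics:

* `n_founders` 28 cells placed uniformly in a 25-μm-radius disc, tracked
  for `n_slices` 97 at 15-min intervals;
* `n_groups` 4 migration groups; each cell's step is its group's constant
  drift vector plus isotropic Gaussian wander (`follower_noise_std`
  0.8 μm/coordinate), the whole step clipped to `step_cap` 6 μm. Group
  drifts point in evenly spaced directions with magnitude
  `drift_magnitude` 1.5 μm/slice, stretched ×`anisotropy` 3 along x to
  mimic fiber-aligned migration. Leader influence is thus modeled
  implicitly as shared drift, not as an interaction force;
* divisions occur at `division_rate` 0.0125 per cell per slice (≈ 28 → 90+
  leaves over 96 steps, matching the observed colony growth scale) or at
  explicitly scheduled (cell, slice) pairs; daughters appear on the next
  slice at ±`division_separation`/2 (default 12 μm, hence ≥ 10 μm apart)
  across the mother's last position, perpendicular to the group drift so
  no ordinary step cap is violated; config validation enforces
  `division_separation > 10 > step_cap`;
* a `leader_fraction` 0.2 minority carries the mesenchymal phenotype,
  spread across distinct groups and inherited by daughters; phenotype
  never influences motion, mirroring the analysis's required blindness
  to it.

`generate_separable_groups` rescales the drift magnitude to
`separation_factor × follower_noise_std`. Between-group trajectory
distances grow linearly in the drift gap over a window while within-group
distances grow only as accumulated noise, so large factors give cleanly
recoverable groups and factors near 0 give statistically indistinguishable
ones (the negative control). In the acceptance suite "well separated"
means factor 4.

What the generator does **not** emulate: cell–cell forces and volume
exclusion, chemotactic gradients, track loss or apoptosis, heterogeneous
per-cell speeds, drifts that change over time, and measurement outliers.
Passing recovery tests therefore shows that the pipeline identifies shared
drift structure under bounded noise and divisions — not that it handles
arbitrary real tracking data, where division confirmation in particular
still warrants image review.

## Problem sizes and numerical choices

* Test and acceptance simulations use colonies of 20–32 founders and 24–97
  slices; clustering-recovery runs use division-free 24-slice colonies
  (2 periods each, 20 seeds), and the robustness protocol uses h = 20
  replicates at σ ∈ {0, 1, 2} over several seeds. These sizes are chosen
  as the smallest that make the statistical claims stable across seeds.
* Every stochastic stage derives its seed from the master seed through
  `numpy.random.SeedSequence` tagged with the stage name and period or
  replicate index, so stages never share streams and runs are exactly
  reproducible.
* Distance matrices are stored dense (N is at most a few hundred);
  symmetry and a zero diagonal are enforced exactly after accumulation.
* k-means runs at most 300 Lloyd iterations with a 1e-12 relative descent
  stop; restarts initialize centers at distinct sample points.
* Degenerate inputs: a track of one slice has no step sizes (error);
  clustering all-coincident points yields silhouette 0 for every K, and
  the tie rule then selects `k_min`.

## Known limitations

* Cluster indices are arbitrary per period; there is no matching of
  clusters across periods or across noise replicates (size-sorted
  comparison only).
* The embedded-space silhouette that selects K inherits the embedder's
  distortions; the trajectory-space variant is exposed for sensitivity
  checks.
* Division detection on unified tables relies on exact pre-division
  coincidence; unified data whose pre-division copies have been perturbed
  (e.g. re-smoothed) would need the raw-table form instead.
* The trajectory distance compares equal-length, synchronized windows
  only; no time warping, rotation or scale invariance.
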