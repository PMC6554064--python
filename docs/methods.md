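# Methods

## Overview

`isotraj` infers a branching trajectory and a global pseudo-time from a
genes x cells expression matrix. The method assumes that (i) the cell
population samples a continuous differentiation process, so cells fall on
a low-dimensional branching manifold in expression space, (ii) regions of
high cell density in a 2-D embedding mark stable or well-sampled states,
and (iii) distances *along* the manifold (geodesics), not straight-line
distances, order cells correctly. Each pipeline stage is a plain function
(modules `preprocessing`, `density`, `isomap`, `trajectory`), orchestrated
by `TrajectoryModel.fit()` which returns a `TrajectoryResults` object.

## Preprocessing

Raw counts are transformed as `log2(x + 1)`; the unit pseudocount maps
zeros to zeros and preserves sparsity. Matrices already on a log scale
(flag `is_log`) are passed through, and a second transform is refused.
Gene filters: a gene must be detected (> 0) in at least `min_cells_frac`
of cells (default 0.01), and optionally lie above the
`min_variance_quantile` quantile of the surviving genes' variances
(default 0, i.e. off). Note the variance quantile is relative to the
current gene set, so re-applying a nonzero quantile keeps shrinking the
set; the expression filter alone is idempotent.

PCA treats cells as observations of the gene-centered matrix; by default
the smallest number of components reaching 90% cumulative explained
variance is kept (`var_explained=0.90`), overridable by an explicit
`n_pcs`. The 2-D t-SNE of the PC scores (perplexity 30, seed 0, 500
gradient iterations by default; all recorded in the embedding metadata)
serves density estimation, clustering and plotting only — geodesics are
computed in PCA space, where distances are meaningful beyond nearest
neighbours.

## Density peaks, valleys, and clustering

A kNN graph with default k = 50 (the cell plus its k-1 nearest t-SNE
neighbours, kd-tree backed) defines each cell's neighbourhood. Density is
a Gaussian KDE evaluated at each cell, with Scott's-rule bandwidth
`sigma * N^(-1/6)` by default (`sigma` = root-mean marginal standard
deviation). Peaks/valleys are cells strictly denser/sparser than all
their neighbours; ties disqualify both flags, and a landscape with no
strict peak at all is rejected with advice to change bandwidth or k.

Clustering cuts a Ward dendrogram (configurable linkage) over the t-SNE
coordinates at the number of peaks, then repeatedly re-cuts any cluster
containing p > 1 peaks into p parts on its own cells. Termination is
guaranteed because every re-cut acts on a strictly smaller cell subset.
Peakless clusters merge into the cluster of the peak with minimum
Euclidean distance to any of their members (ties to the lower peak
index). Final labels are 1..C with C = number of peaks, ordered by peak
cell index.

## Landmark Isomap

The geodesic graph is a symmetric m-NN graph (default m = 10) over cells
in PCA space with Euclidean edge weights. If it is disconnected, the
shortest edge between two components is added repeatedly until connected
(every join is logged): pseudo-time must exist for every cell, so
dropping cells or components is not an option. Zero-length edges between
duplicate cells are floored at 1e-12 so sparse storage retains them.

Landmarks are the union of peaks and valleys; if fewer than d_out + 1
(the minimum to anchor a d_out-dimensional embedding), the set is grown
deterministically by farthest-point (max-min) sampling. Dijkstra from
each landmark gives the n x N geodesic matrix — the only distance matrix
ever formed, linear in N. Classical MDS of the n x n landmark block
(double-center -D^2/2, top d_out eigenpairs with positive eigenvalues,
coordinates = eigenvectors scaled by sqrt(eigenvalues)) places the
landmarks; eigenvector signs are canonicalised (largest-magnitude entry
positive) so results are identical across linear-algebra backends. Every
other cell is triangulated by the landmark-MDS out-of-sample rule
`y(x) = 0.5 * L# (delta_mean - delta_x)`, where `delta_x` are squared
geodesic distances to the landmarks and `L#` is the pseudo-inverse
transpose of the landmark coordinate matrix. Landmarks embed exactly onto
their own MDS coordinates, and with all cells as landmarks the procedure
reproduces full Isomap up to a rigid motion (verified by a Procrustes
test against classical MDS of the complete geodesic matrix).

## Trajectory and pseudo-time

Cluster centers are member means in the isometric embedding. The main
trajectory is the MST of the complete Euclidean graph on centers, built
with Kruskal on edges sorted by (weight, i, j) so equal-weight ties are
deterministic. The root is either a user-chosen cluster or, with time
labels available, the cluster containing the most cells at the earliest
time point (ties to the lower index).

Each cell is projected orthogonally onto every edge, clamped to the
closed segment, and assigned to the edge with the smallest residual
(ties: edge nearer the root, then lexicographic). Its pseudo-time is the
tree-path distance from the root to the edge's near endpoint plus the
projection offset. Clamping keeps every pseudo-time within the path
distances of the edge's endpoints and gives cells beyond a terminal
vertex the leaf's time, so pseudo-time is finite and globally comparable
for all cells. Work per cell is proportional to the number of edges
(C - 1), linear in N at fixed C.

Performance evaluation uses the Spearman rank correlation (average ranks
for ties) between pseudo-time and true time labels; a constant side makes
it undefined and is reported as NA with a warning.

## Synthetic data

`simulate_branching` generates the test bed: cells uniformly placed in
time along a rooted tree of branch segments (default: a trunk over time
1-3 splitting into two terminal lineages over 3-5, 475 cells, 48 genes —
the shape of a standard two-lineage benchmark). Half the genes follow
shared sigmoid response curves of time (random baseline U(2,5), signed
amplitude 1-3, random center and width); the other half additionally
accumulate branch-specific linear divergence (slope magnitude 0.8-1.6,
opposite signs across sibling branches) after their branch point, keeping
expected expression continuous at every split. Gaussian noise (default
sd 0.1) is added on the log scale and values are clipped at zero.

What this emulates — and does not: the generator produces smooth
log-scale expression with branch-divergent programs, which exercises
every pipeline stage (density multi-modality, geodesic structure,
bifurcating MST). It does **not** model dropout, library-size variation,
or count noise, so passing tests demonstrate correct trajectory recovery
under idealised noise, not robustness to single-cell technical artifacts.

## Numerical and scaling choices

- Exact scipy hierarchical clustering for subsets up to 4000 cells; above
  that, Ward with a sparse 15-NN connectivity graph
  (scikit-learn), avoiding the O(N^2) distance matrix.
- KDE evaluated exactly up to 2000 cells; above that, kd-tree evaluation
  with relative tolerance 1e-6.
- Tolerances: MDS eigenvalues are "positive" above 1e-12 of the largest;
  landmark-block symmetry is enforced to 1e-8 and symmetrised before MDS.
- Determinism: one seed drives the simulation, t-SNE and PCA's randomized
  solver; MST and edge-assignment ties are broken lexicographically; two
  identical runs produce byte-identical output tables.
- Test problem sizes: oracle equivalences run on instances of 30-60
  points where brute-force references (Floyd-Warshall, spanning-tree
  enumeration via Prüfer sequences, full Isomap) are exact and fast; the
  end-to-end recovery check uses the default 475-cell simulation and the
  scaling check a 40,000-cell one.

## Limitations

- The trajectory is a tree over cluster centers: cycles and converging
  lineages cannot be represented, and resolution is bounded by the number
  of density peaks.
- t-SNE is stochastic and scale-free; density peaks (hence cluster count)
  can change with perplexity, bandwidth, or seed. All three are exposed
  and recorded.
- Automatic rooting needs time labels; without them the root must be
  given, and pseudo-time is only defined up to the choice of root.
- Geodesic quality depends on the m-NN graph: too small an m fragments
  the manifold (repaired joins may shortcut it), too large an m bridges
  separate branches.
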