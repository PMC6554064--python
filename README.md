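# isotraj

Reconstruction of branching cell trajectories and a **global pseudo-time**
for every cell from single-cell RNA-seq expression matrices, built for
datasets from a few hundred up to tens of thousands of cells.

Many trajectory tools either require the number of clusters up front, order
cells only within each lineage, or need the full N x N cell-cell distance
matrix and therefore stop scaling around a few thousand cells. `isotraj`
addresses all three with an unsupervised pipeline:

1. **PCA + t-SNE.** The genes x cells matrix (log2(x+1)-transformed and
   gene-filtered if raw) is reduced to the top principal components; a 2-D
   t-SNE of the PC scores is used for density analysis and visualization.
2. **Density peaks and valleys.** A kNN graph (default k = 50, kd-tree) is
   built in the t-SNE plane and a Gaussian kernel density estimate is
   evaluated at every cell. A cell strictly denser than all of its k-1
   neighbours is a *peak*; strictly sparser, a *valley*.
3. **Iterative hierarchical clustering.** A dendrogram over the t-SNE
   coordinates is cut at the number of peaks; clusters holding several
   peaks are re-cut until every cluster holds one, and peakless clusters
   merge into the cluster of their nearest peak — so the number of clusters
   is read off the density landscape, not chosen by the user.
4. **Landmark Isomap.** Using peaks and valleys as landmark points, cells
   are embedded into an isometric space that preserves geodesic (graph
   shortest-path) distances computed on an m-NN graph in PCA space.
   Only the n x N landmark geodesics are needed (n << N), so no N x N
   matrix is ever formed.
5. **MST trajectory and pseudo-time.** The minimum spanning tree of the
   cluster centers in the isometric embedding is the main trajectory.
   After rooting (explicitly, or automatically at the cluster holding most
   cells from the earliest time point), each cell c is projected onto its
   nearest tree edge e_ij = <v_i, v_j> (v_i nearer the root) and

       t_c = distance(root, v_i) + || proj. offset of c along e_ij ||

   which yields one comparable time axis for all cells across branches.

## Worked example

```python
from isotraj import TrajectoryModel, simulate_branching

ds = simulate_branching(seed=0)            # 475 cells, 48 genes, 2 lineages
model = TrajectoryModel(ds.matrix, ds.metadata(), seed=0)
results = model.fit()
print(results.summary())
```

```
Trajectory reconstruction summary
================================================
cells:                  475
genes (after filter):   48
principal components:   2
density peaks:          4
density valleys:        6
clusters:               4
root cluster:           3
tree edges:             3
branch points (deg>=3): 1
terminal lineages:      2
pseudotime range:       [0, 12.72]
Spearman vs true time:  0.9768
```

The simulated bifurcation (time 1 to 5, split at t = 3) is recovered as a
tree with a single degree-3 branch vertex and two terminal lineages, and
the inferred pseudo-time ranks cells almost exactly as their true
simulation times (Spearman 0.98). `results.cell_table()` gives the
per-cell cluster, density, flags, coordinates and pseudo-time;
`results.write_tables(outdir)` saves everything as TSV;
`results.plot_trajectory()` draws the embedding with the tree overlaid.

The same pipeline is available from the shell:

```bash
isotraj simulate --outdir sim        # writes matrix.tsv + truth.tsv
isotraj run sim/matrix.tsv --metadata sim/truth.tsv --is-log --outdir out
```

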