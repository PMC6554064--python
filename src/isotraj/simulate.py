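"""Synthetic branching expression data with known pseudo-time and branches.

Cells are placed along a rooted tree of branch segments, each covering a
time interval.  Half of the genes follow smooth branch-independent response
curves of time (sigmoidal, random direction and steepness); the other half
share the parent curve up to a branch point and then diverge linearly with
branch-specific slopes, so expected expression is continuous across every
split.  Gaussian noise is added on the log scale and values are clipped at
zero.  The default design mirrors a two-lineage differentiation experiment:
475 cells, 48 genes, continuous collection time running from 1 to 5 with a
bifurcation at the midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .containers import CellMetadata, ExpressionMatrix

__all__ = ["Branch", "SyntheticDataset", "default_bifurcation", "simulate_branching"]


@dataclass(frozen=True)
class Branch:
    """One trajectory segment: a name, its parent (None for the root), and
    the time interval it covers.  A child starts where its parent ends."""

    name: str
    parent: Optional[str]
    t_start: float
    t_end: float


def default_bifurcation() -> List[Branch]:
    """Two terminal lineages over time 1..5, splitting at t = 3."""
    return [
        Branch("trunk", None, 1.0, 3.0),
        Branch("lineage_A", "trunk", 3.0, 5.0),
        Branch("lineage_B", "trunk", 3.0, 5.0),
    ]


def _validate_topology(topology: Sequence[Branch]) -> Dict[str, Branch]:
    by_name = {}
    for b in topology:
        if b.name in by_name:
            raise ValueError(f"duplicate branch name {b.name!r}")
        if b.t_end <= b.t_start:
            raise ValueError(f"branch {b.name!r} has an empty time interval")
        by_name[b.name] = b
    roots = [b for b in topology if b.parent is None]
    if len(roots) != 1:
        raise ValueError("topology must have exactly one root branch")
    for b in topology:
        if b.parent is not None:
            if b.parent not in by_name:
                raise ValueError(f"branch {b.name!r} has unknown parent {b.parent!r}")
            if abs(b.t_start - by_name[b.parent].t_end) > 1e-9:
                raise ValueError(
                    f"branch {b.name!r} must start where its parent ends"
                )
        # walk to the root to reject cycles
        seen, cur = {b.name}, b.parent
        while cur is not None:
            if cur in seen:
                raise ValueError(f"cycle through branch {cur!r}")
            seen.add(cur)
            cur = by_name[cur].parent if cur in by_name else None
    return by_name


def _root_path(by_name: Dict[str, Branch], name: str) -> List[str]:
    path = [name]
    while by_name[path[-1]].parent is not None:
        path.append(by_name[path[-1]].parent)
    return path[::-1]


@dataclass
class GeneProgram:
    """Parameters of one gene's expected log-expression over the tree.

    Baseline is a sigmoid of time shared by all branches:
    ``base + amp / (1 + exp(-(t - center)/width))``.  A branch-specific gene
    additionally accumulates ``slope[branch] * (t - t_split)`` after the
    branch point of its assigned parent branch, which keeps the mean
    continuous at the split.
    """

    base: float
    amp: float
    center: float
    width: float
    split_parent: Optional[str] = None  # None: shared gene
    slopes: Dict[str, float] = field(default_factory=dict)

    def mean(self, by_name: Dict[str, Branch], branch: str, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        mu = self.base + self.amp / (1.0 + np.exp(-(t - self.center) / self.width))
        if self.split_parent is not None:
            path = _root_path(by_name, branch)
            if self.split_parent in path:
                k = path.index(self.split_parent)
                if k + 1 < len(path):  # past the split on some child lineage
                    child = path[k + 1]
                    t_split = by_name[self.split_parent].t_end
                    mu = mu + self.slopes.get(child, 0.0) * np.maximum(t - t_split, 0.0)
        return mu


@dataclass
class SyntheticDataset:
    """A simulated matrix plus its ground truth."""

    matrix: ExpressionMatrix
    true_time: np.ndarray
    branch: np.ndarray
    topology: List[Branch]
    seed: int
    programs: List[GeneProgram] = field(default_factory=list)

    def metadata(self) -> CellMetadata:
        return CellMetadata(
            pd.DataFrame(
                {
                    "cell_id": self.matrix.cell_ids,
                    "time_label": self.true_time,
                    "branch": self.branch,
                }
            )
        )

    def expected_expression(self, branch: str, t) -> np.ndarray:
        """Noise-free mean log-expression of every gene at (branch, t)."""
        by_name = {b.name: b for b in self.topology}
        return np.array(
            [float(p.mean(by_name, branch, np.asarray(t))) for p in self.programs]
        )

    def write(self, outdir, matrix_format: str = "tsv") -> None:
        """Write matrix, truth table and topology edge list under ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if matrix_format == "tsv":
            self.matrix.to_frame().to_csv(outdir / "matrix.tsv", sep="\t")
        elif matrix_format == "mtx":
            import scipy.io
            import scipy.sparse

            scipy.io.mmwrite(
                outdir / "matrix.mtx", scipy.sparse.coo_matrix(self.matrix.values)
            )
            pd.Series(self.matrix.gene_ids).to_csv(
                outdir / "genes.tsv", sep="\t", index=False, header=False
            )
            pd.Series(self.matrix.cell_ids).to_csv(
                outdir / "barcodes.tsv", sep="\t", index=False, header=False
            )
        else:
            raise ValueError(f"unknown matrix format {matrix_format!r}")
        self.metadata().table.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        with open(outdir / "topology.txt", "w") as fh:
            for b in self.topology:
                fh.write(
                    f"{b.parent or '-'}\t{b.name}\t{b.t_start}\t{b.t_end}\n"
                )


def simulate_branching(
    n_cells: int = 475,
    n_genes: int = 48,
    topology: Optional[Sequence[Branch]] = None,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> SyntheticDataset:
    """Simulate a branching single-cell expression dataset.

    Cells receive a root-to-leaf path uniformly at random over terminal
    lineages and a collection time uniform over that path's full time span;
    the segment containing the time is the cell's branch.  Values are on
    the log scale (``is_log`` is set), non-negative, and reproducible for a
    fixed seed.
    """
    if topology is None:
        topology = default_bifurcation()
    topology = list(topology)
    by_name = _validate_topology(topology)
    n_branches = len(topology)
    if n_genes < 2 * n_branches:
        raise ValueError(f"need n_genes >= {2 * n_branches} for {n_branches} branches")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)

    children: Dict[str, List[str]] = {b.name: [] for b in topology}
    for b in topology:
        if b.parent is not None:
            children[b.parent].append(b.name)
    leaves = sorted(name for name, ch in children.items() if not ch)
    internal = sorted(name for name, ch in children.items() if ch)

    # cell placement: a leaf (uniform), then a time uniform along its path
    leaf_pick = rng.integers(0, len(leaves), size=n_cells)
    root_name = next(b.name for b in topology if b.parent is None)
    t0 = by_name[root_name].t_start
    true_time = np.empty(n_cells)
    branch = np.empty(n_cells, dtype=object)
    for c in range(n_cells):
        leaf = leaves[leaf_pick[c]]
        path = _root_path(by_name, leaf)
        t = rng.uniform(t0, by_name[leaf].t_end)
        true_time[c] = t
        seg = path[-1]
        for name in path:
            if t <= by_name[name].t_end + 1e-12:
                seg = name
                break
        branch[c] = seg

    # gene programs: half shared, half diverging after a branch point
    n_shared = n_genes // 2
    t_lo = min(b.t_start for b in topology)
    t_hi = max(b.t_end for b in topology)
    programs: List[GeneProgram] = []
    for g in range(n_genes):
        prog = GeneProgram(
            base=float(rng.uniform(2.0, 5.0)),
            amp=float(rng.uniform(1.0, 3.0)) * float(rng.choice([-1.0, 1.0])),
            center=float(rng.uniform(t_lo, t_hi)),
            width=float(rng.uniform(0.4, 1.2)),
        )
        if g >= n_shared and internal:
            parent = internal[(g - n_shared) % len(internal)]
            kids = sorted(children[parent])
            # opposite-signed slopes so the lineages separate in expression
            signs = np.resize([1.0, -1.0], len(kids))
            mags = rng.uniform(0.8, 1.6, size=len(kids))
            prog = GeneProgram(
                base=prog.base,
                amp=prog.amp,
                center=prog.center,
                width=prog.width,
                split_parent=parent,
                slopes={k: float(s * m) for k, s, m in zip(kids, signs, mags)},
            )
        programs.append(prog)

    means = np.empty((n_genes, n_cells))
    for g, prog in enumerate(programs):
        for name in by_name:
            mask = branch == name
            if mask.any():
                means[g, mask] = prog.mean(by_name, name, true_time[mask])
    values = means + rng.normal(0.0, noise_sd, size=means.shape)
    values = np.clip(values, 0.0, None)

    width = max(4, len(str(n_genes)))
    gene_ids = np.array([f"gene_{i + 1:0{width}d}" for i in range(n_genes)])
    width = max(4, len(str(n_cells)))
    cell_ids = np.array([f"cell_{i + 1:0{width}d}" for i in range(n_cells)])
    matrix = ExpressionMatrix(values, gene_ids, cell_ids, is_log=True)
    return SyntheticDataset(
        matrix=matrix,
        true_time=true_time,
        branch=np.asarray(branch, dtype=str),
        topology=topology,
        seed=seed,
        programs=programs,
    )
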