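"""Hierarchical clustering of induction profiles, Cluster 3.0 style.

Gene-inactivation x reporter induction profiles (0-4 visual scores or fold
values) are clustered with the uncentered correlation similarity
s = sum(x_i y_i) / sqrt(sum(x_i^2) sum(y_i^2)) — cosine similarity without
mean subtraction, as Cluster 3.0 defines it — under unweighted average
linkage (UPGMA).  Results can be written as TreeView-compatible CDT/GTR
files.  Also provides the inducer vs non-inducer lifespan-extension group
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Dendrogram",
    "uncentered_correlation_distance",
    "pairwise_distances",
    "average_linkage_cluster",
    "write_cdt_gtr",
    "read_cdt_gtr",
    "compare_inducer_extension",
]


@dataclass
class Dendrogram:
    """Merge list for n leaves: n-1 (node_a, node_b, height) triples.

    Leaves are 0..n-1; the merge creating internal node ``n + k`` is
    ``merges[k]``.  Average linkage is reducible, so heights are
    non-decreasing in merge order.
    """

    n_leaves: int
    merges: list[tuple[int, int, float]]
    labels: list[str] | None = None

    @property
    def leaf_order(self) -> list[int]:
        """Leaves in display order: follow merges, lower-index subtree first."""
        if self.n_leaves == 1:
            return [0]
        children = {self.n_leaves + k: (a, b) for k, (a, b, _) in enumerate(self.merges)}
        order: list[int] = []

        def visit(node: int) -> None:
            if node < self.n_leaves:
                order.append(node)
            else:
                a, b = children[node]
                visit(a)
                visit(b)

        visit(self.n_leaves + len(self.merges) - 1)
        return order

    def cut_top(self) -> tuple[set[int], set[int]]:
        """Leaf sets of the two subtrees below the root merge."""
        a, b, _ = self.merges[-1]
        children = {self.n_leaves + k: (x, y) for k, (x, y, _) in enumerate(self.merges)}

        def leaves(node: int) -> set[int]:
            if node < self.n_leaves:
                return {node}
            x, y = children[node]
            return leaves(x) | leaves(y)

        return leaves(a), leaves(b)


def uncentered_correlation_distance(x, y) -> float:
    """1 - uncentered correlation; in [0, 2], scale-invariant for a > 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("profiles must have equal length")
    nx = np.sqrt((x * x).sum())
    ny = np.sqrt((y * y).sum())
    if nx == 0 or ny == 0:
        raise ValueError("uncentered correlation undefined for a zero profile")
    return float(1.0 - (x * y).sum() / (nx * ny))


def pairwise_distances(matrix: np.ndarray) -> np.ndarray:
    """Symmetric uncentered-correlation distance matrix over rows."""
    m = np.asarray(matrix, dtype=float)
    norms = np.sqrt((m * m).sum(axis=1))
    if (norms == 0).any():
        bad = np.flatnonzero(norms == 0)
        raise ValueError(f"zero profile at row(s) {bad.tolist()}")
    sim = (m @ m.T) / np.outer(norms, norms)
    d = 1.0 - sim
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def average_linkage_cluster(matrix, axis: str = "rows",
                            labels: list[str] | None = None) -> Dendrogram:
    """UPGMA over uncentered-correlation distances with deterministic ties.

    Inter-cluster distance is the unweighted average over all cross-pairs of
    items (maintained by the Lance-Williams size-weighted update).  Tied
    minimum distances break toward the pair whose clusters contain the lowest
    original indices; within a merge the child holding the lower original
    index comes first, matching Cluster 3.0's merge-order leaf display.
    """
    if isinstance(matrix, pd.DataFrame):
        if labels is None:
            labels = (list(matrix.index) if axis == "rows"
                      else list(matrix.columns))
        matrix = matrix.to_numpy(dtype=float)
    m = np.asarray(matrix, dtype=float)
    if axis == "columns":
        m = m.T
    elif axis != "rows":
        raise ValueError("axis must be 'rows' or 'columns'")
    n = m.shape[0]
    if n < 2:
        raise ValueError("need >= 2 items to cluster")

    dist = pairwise_distances(m)
    active: dict[int, dict] = {
        i: {"size": 1, "rep": i} for i in range(n)}  # rep = lowest original index
    d = {(i, j): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(active) > 1:
        best_key = min(
            d,
            key=lambda k: (d[k],
                           min(active[k[0]]["rep"], active[k[1]]["rep"]),
                           max(active[k[0]]["rep"], active[k[1]]["rep"])))
        i, j = best_key
        h = d[best_key]
        first, second = (i, j) if active[i]["rep"] < active[j]["rep"] else (j, i)
        merges.append((first, second, h))
        ni, nj = active[i]["size"], active[j]["size"]
        new = {"size": ni + nj, "rep": min(active[i]["rep"], active[j]["rep"])}
        del active[i], active[j]
        newd = {}
        for k in active:
            dik = d[(min(i, k), max(i, k))]
            djk = d[(min(j, k), max(j, k))]
            newd[(k, next_id)] = (ni * dik + nj * djk) / (ni + nj)
        d = {k: v for k, v in d.items()
             if i not in k and j not in k}
        d.update(newd)
        active[next_id] = new
        next_id += 1
    return Dendrogram(n_leaves=n, merges=merges, labels=labels)


def write_cdt_gtr(matrix: pd.DataFrame, dendrogram: Dendrogram,
                  prefix: str) -> tuple[str, str]:
    """Write TreeView-dialect CDT + GTR files; returns the two paths.

    The GTR lists one NODE record per merge with correlation = 1 - height;
    the CDT holds the data rows reordered to leaf order with GID
    identifiers.
    """
    if len(matrix) != dendrogram.n_leaves:
        raise ValueError("matrix rows and dendrogram leaves disagree")

    def node_name(idx: int) -> str:
        if idx < dendrogram.n_leaves:
            return f"GENE{idx}X"
        return f"NODE{idx - dendrogram.n_leaves + 1}X"

    gtr_path, cdt_path = f"{prefix}.gtr", f"{prefix}.cdt"
    with open(gtr_path, "w") as fh:
        for k, (a, b, h) in enumerate(dendrogram.merges):
            fh.write(f"NODE{k + 1}X\t{node_name(a)}\t{node_name(b)}\t{1.0 - h:.6f}\n")
    order = dendrogram.leaf_order
    with open(cdt_path, "w") as fh:
        cols = "\t".join(str(c) for c in matrix.columns)
        fh.write(f"GID\tNAME\t{cols}\n")
        for idx in order:
            row = matrix.iloc[idx]
            vals = "\t".join(f"{v:g}" for v in row.to_numpy(dtype=float))
            fh.write(f"GENE{idx}X\t{matrix.index[idx]}\t{vals}\n")
    return cdt_path, gtr_path


def read_cdt_gtr(prefix: str) -> tuple[pd.DataFrame, list[tuple[int, int, float]]]:
    """Round-trip parser for :func:`write_cdt_gtr` output."""
    cdt = pd.read_csv(f"{prefix}.cdt", sep="\t")
    cdt = cdt.set_index("NAME").drop(columns=["GID"])
    cdt.index.name = "gene"

    def parse(name: str, n_leaves: int) -> int:
        if name.startswith("GENE"):
            return int(name[4:-1])
        return n_leaves + int(name[4:-1]) - 1

    lines = [ln.split("\t") for ln in
             open(f"{prefix}.gtr").read().splitlines() if ln]
    n_leaves = len(lines) + 1
    merges = [(parse(a, n_leaves), parse(b, n_leaves), 1.0 - float(corr))
              for _, a, b, corr in lines]
    return cdt, merges


def compare_inducer_extension(inducer_extensions, non_inducer_extensions) -> dict:
    """Mean lifespan extension of reporter-inducing vs non-inducing genes.

    Two-sample (two-sided) t-test on percent-extension values; returns group
    means and the p-value.
    """
    a = np.asarray(inducer_extensions, dtype=float)
    b = np.asarray(non_inducer_extensions, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        p = 1.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
    return {"inducer_mean": float(a.mean()), "non_inducer_mean": float(b.mean()),
            "difference": float(a.mean() - b.mean()), "p_value": p}
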