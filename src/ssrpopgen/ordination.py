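"""Principal coordinates analysis and UPGMA clustering on genetic distances.

PCoA Gower-centers the squared-distance matrix (-d^2/2 double-centered
about row/column means) and eigendecomposes it; axis percentages are
formed from the positive eigenvalues only.  UPGMA agglomerates with
size-weighted average linkage; node heights are half the merge distance so
the root-to-leaf path equals d/2, and ties are broken deterministically by
the lexicographically smallest pair of cluster label sets.

The individual-level tree distance offered here is the shared-allele
distance: d(x, y) = 1 - (shared alleles / 2) averaged over co-genotyped
loci, where the shared-allele count between two genotype pairs at one
locus is 0, 1 or 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distance import DistanceMatrix
from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "PcoaResult",
    "Dendrogram",
    "TreeNode",
    "pcoa",
    "upgma",
    "shared_allele_distance",
]


# ---------------------------------------------------------------------------
# PCoA


@dataclass
class PcoaResult:
    """Coordinates, eigenvalues and explained-variation percentages."""

    coordinates: pd.DataFrame  # items x axes (Axis1, Axis2, ...)
    eigenvalues: np.ndarray  # descending, all retained (may include negatives)
    percent_variation: np.ndarray  # per positive axis, sums to 100
    cumulative_percent: np.ndarray

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]


def pcoa(dist: DistanceMatrix) -> PcoaResult:
    """Classical metric multidimensional scaling of a distance matrix.

    Axes are ordered by descending eigenvalue; only axes with positive
    eigenvalue get coordinates, and percentages are eigenvalue shares of
    the positive-eigenvalue total.
    """
    d = dist.values
    if np.isnan(d).any() or np.isinf(d).any():
        raise ValueError("distance matrix must be finite")
    n = d.shape[0]
    a = -0.5 * d**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    g = a - row - col + a.mean()
    eigval, eigvec = np.linalg.eigh((g + g.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > 1e-10 * max(abs(eigval[0]), 1.0)
    if not pos.any():
        raise ValueError("no positive eigenvalue; matrix carries no variation")
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    pct = 100.0 * eigval[pos] / eigval[pos].sum()
    return PcoaResult(
        coordinates=pd.DataFrame(
            coords,
            index=dist.labels,
            columns=[f"Axis{i + 1}" for i in range(coords.shape[1])],
        ),
        eigenvalues=eigval,
        percent_variation=pct,
        cumulative_percent=np.cumsum(pct),
    )


# ---------------------------------------------------------------------------
# UPGMA


@dataclass
class TreeNode:
    """Node of a rooted ultrametric tree; leaves have height 0."""

    height: float
    label: str | None = None
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf():
            return [self.label or ""]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class Dendrogram:
    """Rooted ultrametric tree produced by UPGMA."""

    root: TreeNode

    def leaves(self) -> list[str]:
        return self.root.leaves()

    def to_newick(self) -> str:
        """Newick string with branch lengths = parent/child height gaps."""

        def render(node: TreeNode, parent_height: float) -> str:
            bl = parent_height - node.height
            if node.is_leaf():
                return f"{node.label}:{bl:.10g}"
            inner = ",".join(render(c, node.height) for c in node.children)
            return f"({inner}):{bl:.10g}"

        inner = ",".join(render(c, self.root.height) for c in self.root.children)
        return f"({inner});"

    def cophenetic(self) -> DistanceMatrix:
        """Tree distances between leaves: twice the height of their MRCA."""
        labels = sorted(self.leaves())
        idx = {l: i for i, l in enumerate(labels)}
        n = len(labels)
        out = np.zeros((n, n))

        def walk(node: TreeNode) -> list[str]:
            if node.is_leaf():
                return [node.label or ""]
            sets = [walk(c) for c in node.children]
            for a in range(len(sets)):
                for b in range(a + 1, len(sets)):
                    for x in sets[a]:
                        for y in sets[b]:
                            out[idx[x], idx[y]] = out[idx[y], idx[x]] = 2 * node.height
            return [x for s in sets for x in s]

        walk(self.root)
        return DistanceMatrix(labels, out, kind="generic")


def upgma(dist: DistanceMatrix) -> Dendrogram:
    """Size-weighted average-linkage agglomeration (UPGMA).

    Node height is half the merge distance.  At each step the pair with
    the smallest distance merges; exact ties resolve to the
    lexicographically smallest pair of sorted leaf-label tuples, making
    the tree deterministic.
    """
    n = len(dist.labels)
    if n < 2:
        raise ValueError("UPGMA requires at least two items")
    if np.isnan(dist.values).any():
        raise ValueError("distance matrix must be complete")
    clusters: dict[int, TreeNode] = {
        i: TreeNode(height=0.0, label=lab) for i, lab in enumerate(dist.labels)
    }
    keys: dict[int, tuple[str, ...]] = {
        i: (lab,) for i, lab in enumerate(dist.labels)
    }
    sizes: dict[int, int] = {i: 1 for i in range(n)}
    d: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            d[(i, j)] = float(dist.values[i, j])
    next_id = n
    while len(clusters) > 1:
        best: tuple[float, tuple[str, ...], tuple[str, ...], int, int] | None = None
        for (i, j), val in d.items():
            ki, kj = keys[i], keys[j]
            pair = (min(ki, kj), max(ki, kj))
            cand = (val, pair[0], pair[1], i, j)
            if best is None or cand[:3] < best[:3]:
                best = cand
        assert best is not None
        val, _, _, i, j = best
        node = TreeNode(height=val / 2.0, children=[clusters[i], clusters[j]])
        ni, nj = sizes[i], sizes[j]
        new_key = tuple(sorted(keys[i] + keys[j]))
        others = [c for c in clusters if c not in (i, j)]
        for c in others:
            dic = d.pop((min(i, c), max(i, c)))
            djc = d.pop((min(j, c), max(j, c)))
            d[(min(next_id, c), max(next_id, c))] = (ni * dic + nj * djc) / (ni + nj)
        del d[(i, j)]
        del clusters[i], clusters[j], keys[i], keys[j], sizes[i], sizes[j]
        clusters[next_id] = node
        keys[next_id] = new_key
        sizes[next_id] = ni + nj
        next_id += 1
    (root,) = clusters.values()
    return Dendrogram(root=root)


# ---------------------------------------------------------------------------
# shared-allele distance


def _shared_alleles(x: np.ndarray, y: np.ndarray) -> int:
    """Allele matches (0, 1 or 2) between two genotype pairs."""
    a, b = list(x), list(y)
    shared = 0
    for allele in a:
        if allele in b:
            b.remove(allele)
            shared += 1
    return shared


def shared_allele_distance(matrix: GenotypeMatrix) -> DistanceMatrix:
    """d(x, y) = 1 - shared/2 averaged over co-genotyped loci."""
    calls = matrix.calls
    n, L, _ = calls.shape
    present = ~matrix.missing_mask()
    num = np.zeros((n, n))
    den = np.zeros((n, n), dtype=int)
    for j in range(L):
        col = calls[:, j, :]
        # shared-allele count via per-allele min of counts
        alleles = np.unique(col[col != MISSING])
        if alleles.size == 0:
            continue
        counts = np.zeros((n, alleles.size), dtype=np.int64)
        for a_idx, a in enumerate(alleles):
            counts[:, a_idx] = (col == a).sum(axis=1)
        shared = np.minimum(counts[:, None, :], counts[None, :, :]).sum(axis=2)
        both = np.outer(present[:, j], present[:, j])
        num += np.where(both, 1.0 - shared / 2.0, 0.0)
        den += both.astype(int)
    with np.errstate(invalid="ignore"):
        out = np.where(den > 0, num / np.maximum(den, 1), np.nan)
    np.fill_diagonal(out, 0.0)
    return DistanceMatrix(list(matrix.individuals), out, kind="shared-allele")
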