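"""Codominant genotypic distances, UPGMA dendrograms and F1 heterozygosity.

The pairwise distance is the squared codominant genotypic distance of Smouse
and Peakall: per biallelic locus, identical genotypes score 0, a homozygote
against a heterozygote sharing an allele scores 1, and opposite homozygotes
score 4.  With AA/AB/BB coded as allele-B dosage 0/1/2, the per-locus score
is simply the squared dosage difference.  The four-fold weight on AAxBB
configurations mirrors their value in hybrid breeding: such a cross yields a
heterozygous F1 with certainty, whereas a cross involving a heterozygote only
with probability one half.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AB, MISSING, GenotypeMatrix


def pair_distance(
    g1: np.ndarray, g2: np.ndarray, normalize: bool = False
) -> tuple[float, int]:
    """Squared genotypic distance between two call vectors.

    Loci missing in either member are dropped (pairwise deletion).  Returns
    ``(distance, n_loci_used)``; with ``normalize=True`` the distance is the
    per-locus mean instead of the sum.
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    ok = (g1 != MISSING) & (g2 != MISSING)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("no comparable loci between the pair")
    d = float(((g1[ok].astype(np.int32) - g2[ok].astype(np.int32)) ** 2).sum())
    return (d / n if normalize else d), n


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance grid with per-pair comparable-locus counts."""

    ids: list[str]
    values: np.ndarray
    n_loci: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(str(path))

    def to_phylip(self, path) -> None:
        with open(str(path), "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, sid in enumerate(self.ids):
                row = " ".join(f"{v:.6f}" for v in self.values[i])
                fh.write(f"{sid:<12s}{row}\n")


def distance_matrix(
    matrix: GenotypeMatrix,
    sample_subset: list[str] | None = None,
    normalize: bool = False,
) -> DistanceMatrix:
    """All-pairs squared genotypic distances over a genotype matrix."""
    ids = list(sample_subset) if sample_subset is not None else matrix.sample_ids
    if len(ids) < 2:
        raise ValueError("need at least 2 samples")
    n = len(ids)
    values = np.zeros((n, n), dtype=float)
    n_loci = np.zeros((n, n), dtype=int)
    rows = [matrix.row(s) for s in ids]
    for i in range(n):
        n_loci[i, i] = int((rows[i] != MISSING).sum())
        for j in range(i + 1, n):
            d, m = pair_distance(rows[i], rows[j], normalize=normalize)
            values[i, j] = values[j, i] = d
            n_loci[i, j] = n_loci[j, i] = m
    return DistanceMatrix(ids, values, n_loci)


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """Node of an ultrametric dendrogram; height is the merge distance / 2."""

    height: float
    children: tuple["TreeNode", ...] = ()
    leaf_id: str | None = None

    @property
    def leaves(self) -> list[str]:
        if self.leaf_id is not None:
            return [self.leaf_id]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves)
        return out

    def to_newick(self) -> str:
        return self._newick(parent_height=None) + ";"

    def _newick(self, parent_height: float | None) -> str:
        if self.leaf_id is not None:
            body = self.leaf_id
        else:
            body = "(" + ",".join(
                sorted(c._newick(self.height) for c in self.children)
            ) + ")"
        if parent_height is None:
            return body
        return f"{body}:{parent_height - self.height:.6g}"


@dataclass
class UltrametricTree:
    root: TreeNode

    @property
    def leaf_ids(self) -> list[str]:
        return self.root.leaves

    def to_newick(self) -> str:
        return self.root.to_newick()

    def cophenetic(self) -> DistanceMatrix:
        """Pairwise cophenetic distances (twice the lowest common merge height)."""
        ids = sorted(self.leaf_ids)
        idx = {s: i for i, s in enumerate(ids)}
        n = len(ids)
        values = np.zeros((n, n), dtype=float)

        def visit(node: TreeNode) -> list[str]:
            if node.leaf_id is not None:
                return [node.leaf_id]
            groups = [visit(c) for c in node.children]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    for x in groups[a]:
                        for y in groups[b]:
                            values[idx[x], idx[y]] = values[idx[y], idx[x]] = 2 * node.height
            return [x for g in groups for x in g]

        visit(self.root)
        return DistanceMatrix(ids, values, np.zeros((n, n), dtype=int))


def upgma(dist: DistanceMatrix) -> UltrametricTree:
    """Average-linkage (UPGMA) agglomeration of a distance matrix.

    Cluster pairs at the minimum average distance are merged at node height
    equal to half that distance; ties are broken by the lexicographically
    smallest (sorted leaf tuple) cluster pair, so the output tree and its
    Newick string are deterministic.
    """
    if not np.all(np.isfinite(dist.values)):
        raise ValueError("distance matrix contains non-finite entries")
    clusters: dict[tuple[str, ...], tuple[TreeNode, int]] = {
        (sid,): (TreeNode(height=0.0, leaf_id=sid), 1) for sid in dist.ids
    }
    idx = {s: i for i, s in enumerate(dist.ids)}

    def avg_dist(a: tuple[str, ...], b: tuple[str, ...]) -> float:
        return float(
            np.mean([dist.values[idx[x], idx[y]] for x in a for y in b])
        )

    d = {
        (a, b): avg_dist(a, b)
        for a in clusters
        for b in clusters
        if a < b
    }
    while len(clusters) > 1:
        (a, b), dmin = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        node_a, size_a = clusters.pop(a)
        node_b, size_b = clusters.pop(b)
        merged = tuple(sorted(a + b))
        node = TreeNode(height=dmin / 2.0, children=(node_a, node_b))
        d = {k: v for k, v in d.items() if a not in k and b not in k}
        for other, (_, size_o) in clusters.items():
            # UPGMA update: size-weighted average of the two old distances
            da = avg_dist(a, other)
            db = avg_dist(b, other)
            dnew = (size_a * da + size_b * db) / (size_a + size_b)
            key = (merged, other) if merged < other else (other, merged)
            d[key] = dnew
        clusters[merged] = (node, size_a + size_b)
    (root, _), = clusters.values()
    return UltrametricTree(root)


# ---------------------------------------------------------------------------
# Expected F1 heterozygosity
# ---------------------------------------------------------------------------

def expected_f1_heterozygosity(g1: np.ndarray, g2: np.ndarray) -> float:
    """Mean per-locus probability that an F1 of the two parents is heterozygous.

    Opposite homozygotes give 1, identical homozygotes 0, and any cross
    involving a heterozygous parent 1/2.  Used to prioritize crosses expected
    to maximize hybrid heterozygosity (a proxy for heterosis potential).
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    ok = (g1 != MISSING) & (g2 != MISSING)
    if not ok.any():
        raise ValueError("no comparable loci between the pair")
    a, b = g1[ok], g2[ok]
    het = np.where(
        (a == AB) | (b == AB),
        0.5,
        np.where(a != b, 1.0, 0.0),
    )
    return float(het.mean())
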