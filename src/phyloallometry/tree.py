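"""Phylogeny container and Brownian-motion covariance construction.

A :class:`Phylogeny` wraps a rooted dendropy tree with branch lengths and
provides the operations comparative allometric analyses need: taxon
alignment against a trait table, clade subsetting, and the Brownian-motion
covariance matrix whose entries are shared root-to-ancestor path lengths.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed."""


class TreeValidationError(ValueError):
    """Raised when a parsed tree violates structural requirements."""


@dataclass
class PhyloCovariance:
    """Brownian-motion trait covariance implied by a phylogeny.

    Attributes
    ----------
    taxa : list of str
        Tip labels in canonical (sorted) order; row/column order of ``C``.
    C : ndarray
        Symmetric positive semi-definite matrix. ``C[i, i]`` is the
        root-to-tip distance of taxon *i*; ``C[i, j]`` the root-to-MRCA
        shared path length.
    """

    taxa: list = field(default_factory=list)
    C: np.ndarray = None

    def __post_init__(self):
        self.C = np.asarray(self.C, dtype=float)
        n = len(self.taxa)
        if self.C.shape != (n, n):
            raise ValueError("covariance shape does not match taxa")
        if not np.allclose(self.C, self.C.T, atol=1e-12):
            raise ValueError("covariance matrix is not symmetric")
        eig = np.linalg.eigvalsh(self.C)
        if eig.min() < -1e-10 * max(np.trace(self.C), 1.0):
            raise ValueError("covariance matrix is not positive semi-definite")

    def lambda_transform(self, lam: float) -> np.ndarray:
        """Pagel's lambda transform: off-diagonals scaled by ``lam``.

        ``lam = 0`` gives a star phylogeny (diagonal retained), ``lam = 1``
        the untransformed Brownian covariance.
        """
        if not 0.0 <= lam <= 1.0:
            raise ValueError(f"lambda must lie in [0, 1], got {lam}")
        V = lam * self.C
        np.fill_diagonal(V, np.diag(self.C))
        return V

    def subset(self, taxa) -> "PhyloCovariance":
        idx = [self.taxa.index(t) for t in taxa]
        return PhyloCovariance(list(taxa), self.C[np.ix_(idx, idx)])


class Phylogeny:
    """Rooted phylogeny with branch lengths and unique tip labels."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._cov = None
        self._validate()

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick",
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several error types
            if "duplicate" in str(exc).lower():
                raise TreeValidationError(
                    f"duplicate tip labels: {exc}") from exc
            offset = getattr(exc, "column", None)
            loc = f" near character {offset}" if offset is not None else ""
            raise NewickParseError(f"malformed Newick{loc}: {exc}") from exc
        tree.is_rooted = True
        return cls(tree)

    @classmethod
    def read(cls, path) -> "Phylogeny":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    # -- validation ----------------------------------------------------

    def _validate(self) -> None:
        labels = self.tip_labels
        if any(not lbl for lbl in labels):
            raise TreeValidationError("empty tip label")
        if len(set(labels)) != len(labels):
            dups = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeValidationError(f"duplicate tip labels: {dups}")
        for edge in self._tree.preorder_edge_iter():
            if edge.length is None:
                continue
            if not np.isfinite(edge.length) or edge.length < 0:
                raise TreeValidationError(
                    f"invalid branch length {edge.length!r} above node "
                    f"{edge.head_node.taxon.label if edge.head_node.taxon else '<internal>'}"
                )

    # -- basic accessors ----------------------------------------------

    @property
    def tip_labels(self) -> list:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    def copy(self) -> "Phylogeny":
        return Phylogeny(self._tree.clone(depth=1))

    def depths(self) -> dict:
        """Root-to-tip path length per tip label."""
        out = {}
        for leaf in self._tree.leaf_node_iter():
            d, node = 0.0, leaf
            while node.parent_node is not None:
                d += node.edge.length or 0.0
                node = node.parent_node
            out[leaf.taxon.label] = d
        return out

    # -- operations ----------------------------------------------------

    def prune_to(self, taxa) -> "Phylogeny":
        """Return a copy pruned to the given tip labels."""
        keep = set(taxa)
        missing = keep - set(self.tip_labels)
        if missing:
            raise KeyError(f"taxa not in tree: {sorted(missing)}")
        tree = self._tree.clone(depth=1)
        tree.retain_taxa_with_labels(sorted(keep))
        return Phylogeny(tree)

    def subset_clade(self, tip_set) -> "Phylogeny":
        """Subtree spanned by the MRCA of ``tip_set`` (all its descendants)."""
        tips = list(tip_set)
        missing = set(tips) - set(self.tip_labels)
        if missing:
            raise KeyError(f"taxa not in tree: {sorted(missing)}")
        mrca = self._tree.mrca(taxon_labels=tips)
        clade_tips = [leaf.taxon.label for leaf in mrca.leaf_iter()]
        return self.prune_to(clade_tips)

    def bm_covariance(self) -> PhyloCovariance:
        """Shared-path-length (Brownian motion) covariance, sorted taxa.

        Cached: the tree is immutable through the public API, so the
        matrix is computed once.
        """
        if self._cov is not None:
            return self._cov
        taxa = sorted(self.tip_labels)
        pdm = self._tree.phylogenetic_distance_matrix()
        depths = self.depths()
        if max(depths.values()) <= 0:
            raise TreeValidationError("tree has zero total depth")
        taxon_by_label = {t.label: t for t in self._tree.taxon_namespace
                          if t.label in depths}
        n = len(taxa)
        C = np.zeros((n, n))
        for i, a in enumerate(taxa):
            C[i, i] = depths[a]
            for j in range(i + 1, n):
                b = taxa[j]
                # shared path = (d_a + d_b - patristic distance) / 2
                d = pdm.patristic_distance(taxon_by_label[a], taxon_by_label[b])
                C[i, j] = C[j, i] = 0.5 * (depths[a] + depths[b] - d)
        self._cov = PhyloCovariance(taxa, C)
        return self._cov

    def scale_depth(self, target: float = 1.0) -> "Phylogeny":
        """Rescale branch lengths so the maximum root-to-tip depth is ``target``."""
        depth = max(self.depths().values())
        if depth <= 0:
            raise TreeValidationError("tree has zero total depth")
        tree = self._tree.clone(depth=1)
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= target / depth
        return Phylogeny(tree)

    def __repr__(self) -> str:
        return f"Phylogeny(n_tips={self.n_tips})"


def read_newick(path) -> Phylogeny:
    """Read a single Newick tree from ``path``."""
    return Phylogeny.read(path)


def write_newick(tree: Phylogeny, path) -> None:
    tree.write(path)
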