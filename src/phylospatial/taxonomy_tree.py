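"""Ultrametric cultural hierarchies from tabular language taxonomies.

Cross-cultural datasets rarely come with a resolved phylogeny, but a
language classification (Glottolog-style nested clades) plus published clade
ages is enough to build an *assumed* hierarchy of relatedness.  Each society
is represented by its dominant language; the clade containing that language
is given a relative height ``C`` (clade age as a fraction of the root age),
and nodes inside the clade are spaced by classification level so that a node
separating languages at level ``L_s`` of a clade with maximum level ``L_c``
sits at height ``(L_c - L_s) * C / L_c``.  The root joining all clades sits
at height 1; tips sit at height 0, so the tree is ultrametric and node
heights read directly as expected dissimilarity.

Phylogenetic similarity between two societies is the shared fraction of the
root-to-tip path: ``P_ij = 1 - height(MRCA(i, j))``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "TaxonomyError",
    "InvalidCladeError",
    "TaxonEntry",
    "LanguageTaxonomy",
    "CladeSpec",
    "Hierarchy",
    "rescale_node_height",
    "build_hierarchy",
    "phylo_similarity",
]

ULTRAMETRIC_TOL = 1e-9


class TaxonomyError(ValueError):
    """Raised for inconsistent taxonomy tables (duplicate tips, bad levels)."""


class InvalidCladeError(TaxonomyError):
    """Raised for clade specifications violating their invariants."""


@dataclass(frozen=True)
class TaxonEntry:
    """One sampled society: its dominant language and classification path."""

    tip_id: str
    language_code: str
    clade_id: str
    path: tuple[str, ...]
    sample_level: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "path", tuple(self.path))
        if len(self.path) < 1:
            raise TaxonomyError(f"tip {self.tip_id!r}: empty classification path")
        if self.sample_level != len(self.path):
            raise TaxonomyError(
                f"tip {self.tip_id!r}: sample_level {self.sample_level} does not "
                f"match path length {len(self.path)}"
            )


@dataclass
class LanguageTaxonomy:
    """A set of societies placed in a language classification."""

    entries: list[TaxonEntry]

    def __post_init__(self) -> None:
        ids = [e.tip_id for e in self.entries]
        dupes = {t for t in ids if ids.count(t) > 1}
        if dupes:
            raise TaxonomyError(f"duplicate tip_id(s): {sorted(dupes)}")

    @property
    def tip_ids(self) -> list[str]:
        return [e.tip_id for e in self.entries]

    def by_clade(self) -> dict[str, list[TaxonEntry]]:
        out: dict[str, list[TaxonEntry]] = {}
        for e in self.entries:
            out.setdefault(e.clade_id, []).append(e)
        return out


@dataclass(frozen=True)
class CladeSpec:
    """A top-level language clade: relative age and classification depth.

    ``relative_height`` is the clade age as a fraction of the root age, in
    (0, 1]; ``max_level`` is the deepest classification level in the clade.
    """

    clade_id: str
    relative_height: float
    max_level: int
    n_languages: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.relative_height <= 1.0):
            raise InvalidCladeError(
                f"clade {self.clade_id!r}: relative_height must be in (0, 1], "
                f"got {self.relative_height}"
            )
        if self.max_level < 1:
            raise InvalidCladeError(
                f"clade {self.clade_id!r}: max_level must be >= 1, got {self.max_level}"
            )


def rescale_node_height(L_c: int, L_s: int, C: float) -> float:
    """Height of a within-clade node separating languages at level ``L_s``.

    The raw spacing rule ``(L_c - L_s) * C`` is in arbitrary per-clade units;
    dividing by ``L_c`` makes heights commensurable across clades, placing the
    clade ancestor (``L_s = 0``) at height ``C`` and tip-level nodes
    (``L_s = L_c``) at 0.

    Parameters
    ----------
    L_c : maximum classification level in the clade (>= 1).
    L_s : level of the node, ``0 <= L_s <= L_c``.
    C : clade height relative to the root, in (0, 1].
    """
    if C <= 0 or C > 1:
        raise InvalidCladeError(f"clade relative height must be in (0, 1], got {C}")
    if L_c < 1:
        raise InvalidCladeError(f"max_level must be >= 1, got {L_c}")
    if L_s > L_c:
        raise TaxonomyError(f"sample level {L_s} exceeds clade max level {L_c}")
    if L_s < 0:
        raise TaxonomyError(f"sample level must be >= 0, got {L_s}")
    return (L_c - L_s) * C / L_c


@dataclass
class Hierarchy:
    """An ultrametric rooted tree over societies, root at height 1, tips at 0.

    Thin wrapper around a :class:`dendropy.Tree`; branch lengths encode height
    differences so patristic distances are twice the MRCA height.
    """

    tree: dendropy.Tree
    _root_height: float = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        depths = self.tree.calc_node_root_distances(return_leaf_distances_only=True)
        if not depths:
            raise TaxonomyError("hierarchy has no tips")
        # a root edge (left by suppressing a unary chain above the first
        # split) still counts towards the root height
        root_edge = self.tree.seed_node.edge.length or 0.0
        self._root_height = float(max(depths)) + float(root_edge)
        if max(depths) - min(depths) > ULTRAMETRIC_TOL * max(1.0, self._root_height):
            raise TaxonomyError(
                "tree is not ultrametric: tip depths span "
                f"[{min(depths):.12g}, {max(depths):.12g}]"
            )

    @property
    def root_height(self) -> float:
        return self._root_height

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def node_heights(self) -> dict[dendropy.Node, float]:
        """Height above the tips for every node."""
        self.tree.calc_node_root_distances()
        tip_depth = self._root_height - (self.tree.seed_node.edge.length or 0.0)
        return {
            nd: tip_depth - nd.root_distance
            for nd in self.tree.preorder_node_iter()
        }

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    @classmethod
    def from_newick(cls, newick: str) -> "Hierarchy":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls(tree=tree)


def build_hierarchy(
    taxonomy: LanguageTaxonomy, clades: Iterable[CladeSpec]
) -> Hierarchy:
    """Assemble the ultrametric hierarchy from taxonomy rows and clade specs.

    A single root at height 1 joins all clades (no between-clade structure is
    assumed); within each clade, the node grouping languages that diverge at
    classification level ``d`` sits at height ``(L_c - d) * C / L_c``.  Tips
    whose full paths coincide (distinct societies sharing a dominant language)
    are joined by a parent at ``C / (2 * L_c)`` so the similarity matrix stays
    nonsingular.
    """
    clade_map = {c.clade_id: c for c in clades}
    by_clade = taxonomy.by_clade()
    for cid in by_clade:
        if cid not in clade_map:
            raise TaxonomyError(f"tip(s) reference unknown clade {cid!r}")

    taxa = dendropy.TaxonNamespace([e.tip_id for e in taxonomy.entries])
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node  # height 1 by construction

    def new_child(parent: dendropy.Node, parent_h: float, h: float) -> dendropy.Node:
        child = dendropy.Node()
        parent.add_child(child)
        child.edge.length = parent_h - h
        return child

    for cid, entries in sorted(by_clade.items()):
        spec = clade_map[cid]
        L_c, C = spec.max_level, spec.relative_height
        for e in entries:
            if e.sample_level > L_c:
                raise TaxonomyError(
                    f"tip {e.tip_id!r}: sample_level {e.sample_level} exceeds "
                    f"max_level {L_c} of clade {cid!r}"
                )
        if len(entries) == 1:
            warnings.warn(
                f"clade {cid!r} has a single tip; degenerate branch to root",
                stacklevel=2,
            )
        # prefix tree over classification paths; node at depth d has height
        # (L_c - d) * C / L_c, created only while the height stays positive
        clade_root = new_child(root, 1.0, C)
        nodes: dict[tuple[str, ...], dendropy.Node] = {(): clade_root}
        heights: dict[tuple[str, ...], float] = {(): C}
        for e in sorted(entries, key=lambda t: t.tip_id):
            attach_depth = min(e.sample_level, L_c - 1)
            prefix: tuple[str, ...] = ()
            for d in range(1, attach_depth + 1):
                nxt = e.path[:d]
                if nxt not in nodes:
                    h = rescale_node_height(L_c, d, C)
                    nodes[nxt] = new_child(nodes[prefix], heights[prefix], h)
                    heights[nxt] = h
                prefix = nxt
        # group same-language tips below a near-zero tie node
        groups: dict[tuple[str, ...], list[TaxonEntry]] = {}
        for e in entries:
            groups.setdefault(e.path, []).append(e)
        for path, members in sorted(groups.items()):
            L_s = members[0].sample_level
            attach = path[: min(L_s, L_c - 1)]
            parent, parent_h = nodes[attach], heights[attach]
            if len(members) > 1 and L_s == L_c:
                tie_h = C / (2.0 * L_c)
                parent = new_child(parent, parent_h, tie_h)
                parent_h = tie_h
            for e in sorted(members, key=lambda t: t.tip_id):
                leaf = new_child(parent, parent_h, 0.0)
                leaf.taxon = taxa.get_taxon(e.tip_id)

    tree.suppress_unifurcations()
    return Hierarchy(tree=tree)


def phylo_similarity(tree: Hierarchy) -> pd.DataFrame:
    """Phylogenetic similarity matrix ``P_ij = 1 - height(MRCA(i, j))``.

    With tips at height 0 and the root at 1, the patristic distance between
    two tips is twice their MRCA height, so ``P = 1 - d / (2 * root_height)``.
    Returns a symmetric unit-diagonal DataFrame over tip labels.
    """
    rh = tree.root_height
    pdm = tree.tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    P = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[i], taxa[j])
            P[i, j] = P[j, i] = 1.0 - d / (2.0 * rh)
    P = np.clip(P, 0.0, 1.0)
    return pd.DataFrame(P, index=labels, columns=labels)
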