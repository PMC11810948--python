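"""Rooted phylogenies: Newick IO, validation and the phylogenetic covariance.

Trees are held as dendropy objects; this module adds the validation the
downstream analyses rely on (unique tip labels, nonnegative branch lengths)
and the Brownian-motion covariance matrix C, where C[i, j] is the shared
root-to-tip path length of tips i and j.
"""

from __future__ import annotations

import io

import dendropy
import numpy as np

from .errors import ParseError, ValidationError


class Phylogeny:
    """A rooted, branch-length-bearing tree over species labels."""

    def __init__(self, tree: dendropy.Tree):
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            seen: set[str] = set()
            dup = next(l for l in labels if l in seen or seen.add(l))
            raise ValidationError(f"duplicate tip label {dup!r}")
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValidationError(f"negative branch length {edge.length}")
        self._tree = tree
        self.tip_labels: list[str] = labels

    # -- constructors -------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        _check_parentheses(newick)
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as exc:  # dendropy raises several parse error types
            if "Duplicate taxon" in str(exc):
                raise ValidationError(f"duplicate tip label in Newick string: {exc}") from exc
            raise ParseError(f"malformed Newick string: {exc}") from exc
        return cls(tree)

    @classmethod
    def from_file(cls, path) -> "Phylogeny":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    # -- basic properties ---------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def total_branch_length(self) -> float:
        return sum(e.length or 0.0 for e in self._tree.preorder_edge_iter())

    def tip_depths(self) -> dict[str, float]:
        """Root-to-tip path length per tip."""
        depths = {}
        for leaf in self._tree.leaf_node_iter():
            depths[leaf.taxon.label] = leaf.distance_from_root()
        return depths

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    # -- phylogenetic covariance --------------------------------------

    def vcv(self, order: list[str] | None = None) -> tuple[list[str], np.ndarray]:
        """Phylogenetic variance-covariance matrix under Brownian motion.

        Returns ``(labels, C)`` with ``C[i, j]`` the depth of the most
        recent common ancestor of tips i and j (tip depth on the
        diagonal), in the requested tip order.
        """
        labels = list(order) if order is not None else list(self.tip_labels)
        missing = set(labels) - set(self.tip_labels)
        if missing:
            raise ValidationError(f"tips not in tree: {sorted(missing)}")
        index = {lab: i for i, lab in enumerate(labels)}
        n = len(labels)
        C = np.zeros((n, n))

        # node depth = root distance; C_ij = depth of MRCA(i, j).
        root = self._tree.seed_node
        depth = {root: root.edge.length or 0.0}
        for node in self._tree.preorder_node_iter():
            if node is root:
                continue
            depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)

        leafsets: dict = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                lab = node.taxon.label
                leafsets[node] = [index[lab]] if lab in index else []
                if lab in index:
                    C[index[lab], index[lab]] = depth[node]
                    if depth[node] == 0:
                        import warnings

                        warnings.warn(f"tip {lab!r} has zero depth", stacklevel=2)
            else:
                children = [leafsets[c] for c in node.child_nodes()]
                for a in range(len(children)):
                    for b in range(a + 1, len(children)):
                        for i in children[a]:
                            for j in children[b]:
                                C[i, j] = C[j, i] = depth[node]
                leafsets[node] = [i for c in children for i in c]
        return labels, C


def _check_parentheses(newick: str) -> None:
    bal = 0
    for pos, ch in enumerate(newick):
        if ch == "(":
            bal += 1
        elif ch == ")":
            bal -= 1
            if bal < 0:
                raise ParseError(f"unbalanced parentheses at position {pos}")
    if bal != 0:
        raise ParseError(f"unbalanced parentheses: {bal} unclosed '(' at end of string")


def read_newick(path_or_string) -> Phylogeny:
    """Read a rooted Newick tree from a path or a literal string."""
    s = str(path_or_string)
    if s.lstrip().startswith("("):
        return Phylogeny.from_newick(s)
    return Phylogeny.from_file(path_or_string)


def star_tree(n_tips: int, branch_length: float = 1.0, prefix: str = "t") -> Phylogeny:
    """A star phylogeny: n tips attached directly to the root."""
    tips = ",".join(f"{prefix}{i + 1}:{branch_length}" for i in range(n_tips))
    return Phylogeny.from_newick(f"({tips});")
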