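"""Reading, validating and writing posterior samples of dated trees.

The input format is the "datedist" dialect produced by Bayesian dating
software: one rooted, ultrametric newick string per line, branch lengths in
time units (typically Ma).  Blank lines, lines of pure digits (tree-count
headers) and lines starting with ``#`` are tolerated and skipped.

A :class:`Chronogram` stores the tree as flat postorder-indexed arrays: node
``i``'s children all have indices ``< i`` and the root is the last node.
Node ages are derived from branch lengths with the *max-depth* convention —
``age(v)`` is the maximum path length from ``v`` to any descendant leaf —
which guarantees ``age(parent) >= age(child)`` even when the input text was
rounded.  Leaf ages are forced to exactly 0 after the ultrametricity check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import dendropy
import numpy as np

from .errors import ParseError, StructuralError, ValidationError

#: Default relative ultrametricity tolerance:
#: |max - min root-to-leaf distance| / root_age must not exceed this.
DEFAULT_ULTRAMETRICITY_TOL = 1e-6

_NEWICK_UNSAFE = set(" ()[]:;,'\"\t\n")


def _quote_label(label: str) -> str:
    if label and not (_NEWICK_UNSAFE & set(label)):
        return label
    return "'" + label.replace("'", "''") + "'"


class Chronogram:
    """Rooted ultrametric tree with node ages in time before present.

    Parameters
    ----------
    parent
        Integer array, ``parent[i]`` is the index of node ``i``'s parent
        (``-1`` for the root, which must be the last node).
    children
        Tuple of tuples of child indices, postorder-consistent
        (every child index is smaller than its parent's index).
    ages
        Float array of node ages (time before present); leaves are 0.
    leaf_label
        Mapping leaf index -> taxon label.
    source_line
        1-based line number of origin in the input file, if any.
    """

    __slots__ = ("parent", "children", "ages", "leaf_label", "label_to_leaf",
                 "source_line", "_cache")

    def __init__(self, parent, children, ages, leaf_label, source_line=None,
                 _cache=None):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.children = tuple(tuple(c) for c in children)
        self.ages = np.asarray(ages, dtype=float)
        self.leaf_label = dict(leaf_label)
        self.label_to_leaf = {v: k for k, v in self.leaf_label.items()}
        self.source_line = source_line
        # shared across `with_ages` copies so leaf sets are computed once
        # per topology
        self._cache = _cache if _cache is not None else {}
        if len(self.label_to_leaf) != len(self.leaf_label):
            raise StructuralError("duplicate leaf labels in tree")

    # -- basic structure ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.ages)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_label)

    @property
    def leaf_set(self) -> frozenset:
        return frozenset(self.label_to_leaf)

    def is_leaf(self, i: int) -> bool:
        return not self.children[i]

    @property
    def leafsets(self) -> list:
        """Per-node frozenset of descendant leaf labels (cached, shared)."""
        ls = self._cache.get("leafsets")
        if ls is None:
            ls = [None] * self.n_nodes
            for i in range(self.n_nodes):
                if not self.children[i]:
                    ls[i] = frozenset((self.leaf_label[i],))
                else:
                    ls[i] = frozenset().union(*(ls[c] for c in self.children[i]))
            self._cache["leafsets"] = ls
        return ls

    def with_ages(self, ages) -> "Chronogram":
        """Shallow copy sharing topology (and caches) with new node ages."""
        other = object.__new__(Chronogram)
        other.parent = self.parent
        other.children = self.children
        other.ages = np.asarray(ages, dtype=float)
        other.leaf_label = self.leaf_label
        other.label_to_leaf = self.label_to_leaf
        other.source_line = None
        other._cache = self._cache
        return other

    def shares_topology_with(self, other: "Chronogram") -> bool:
        return self.children is other.children and self.leaf_label is other.leaf_label

    # -- construction ------------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree, *,
                      tolerance: float = DEFAULT_ULTRAMETRICITY_TOL,
                      time_scale: float = 1.0,
                      source_line: int | None = None,
                      outgroup: Iterable[str] | None = None) -> "Chronogram":
        """Convert a parsed dendropy tree into a validated chronogram."""
        _ensure_bifurcating_root(tree, outgroup)
        nodes = list(tree.postorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        m = len(nodes)
        parent = np.full(m, -1, dtype=np.int64)
        children: list[list[int]] = [[] for _ in range(m)]
        blen = np.zeros(m)
        leaf_label: dict[int, str] = {}
        for i, nd in enumerate(nodes):
            el = nd.edge.length
            el = 0.0 if el is None else float(el) * time_scale
            if el < 0:
                raise ValidationError(f"negative branch length {el:g}")
            blen[i] = el
            for ch in nd.child_nodes():
                j = index[id(ch)]
                parent[j] = i
                children[i].append(j)
            if not nd.child_nodes():
                label = nd.taxon.label if nd.taxon is not None else nd.label
                if not label:
                    raise StructuralError("unlabelled leaf in tree")
                leaf_label[i] = label
        return cls._from_branch_lengths(parent, children, blen, leaf_label,
                                        tolerance=tolerance,
                                        source_line=source_line)

    @classmethod
    def _from_branch_lengths(cls, parent, children, blen, leaf_label, *,
                             tolerance, source_line=None):
        m = len(blen)
        ages = np.zeros(m)
        for i in range(m):  # postorder: children precede parents
            if children[i]:
                ages[i] = max(ages[c] + blen[c] for c in children[i])
        # ultrametricity: spread of root-to-leaf distances relative to root age
        depth = np.zeros(m)
        for i in range(m - 1, -1, -1):
            for c in children[i]:
                depth[c] = depth[i] + blen[c]
        leaf_idx = [i for i in range(m) if not children[i]]
        dists = depth[leaf_idx]
        spread = float(dists.max() - dists.min()) if len(leaf_idx) > 1 else 0.0
        root_age = float(ages[m - 1])
        if len(leaf_idx) > 1:
            if root_age <= 0:
                raise ValidationError("root age must be positive for a tree "
                                      "with >= 2 leaves")
            if spread / root_age > tolerance:
                raise ValidationError(
                    f"tree is not ultrametric: root-to-leaf distance spread "
                    f"{spread:.6g} exceeds tolerance ({tolerance:g} relative "
                    f"to root age {root_age:.6g})")
        return cls(parent, children, ages, leaf_label, source_line=source_line)

    @classmethod
    def from_newick(cls, newick: str, **kwargs) -> "Chronogram":
        """Parse a single newick string (dendropy does the parsing)."""
        try:
            tree = dendropy.Tree.get(data=newick, schema="newick",
                                     preserve_underscores=True,
                                     rooting="force-rooted")
        except Exception as exc:  # dendropy raises several exception types
            raise ParseError(f"could not parse newick: {exc}") from exc
        return cls.from_dendropy(tree, **kwargs)

    # -- queries -----------------------------------------------------------

    def mrca(self, taxa: Iterable[str]) -> int:
        """Index of the most recent common ancestor of ``taxa``.

        Walks rootward from one member leaf until the node's descendant
        leaf set covers all of ``taxa``.
        """
        from .errors import MissingTaxonError
        taxa = frozenset(taxa)
        for t in taxa:
            if t not in self.label_to_leaf:
                raise MissingTaxonError(f"taxon {t!r} not present in tree")
        ls = self.leafsets
        node = self.label_to_leaf[next(iter(taxa))]
        while not taxa <= ls[node]:
            node = int(self.parent[node])
        return node

    def branch_length(self, i: int) -> float:
        """Length of the branch above node ``i`` (0 for the root)."""
        p = int(self.parent[i])
        return 0.0 if p < 0 else float(self.ages[p] - self.ages[i])

    # -- serialization -----------------------------------------------------

    def to_newick(self, precision: int = 12) -> str:
        frag = [""] * self.n_nodes
        for i in range(self.n_nodes):
            if not self.children[i]:
                frag[i] = _quote_label(self.leaf_label[i])
            else:
                parts = []
                for c in self.children[i]:
                    bl = self.ages[i] - self.ages[c]
                    parts.append(f"{frag[c]}:{bl:.{precision}g}")
                frag[i] = "(" + ",".join(parts) + ")"
        return frag[self.root] + ";"

    def to_dendropy(self, taxon_namespace=None) -> dendropy.Tree:
        """Rebuild a dendropy tree (used for interop and as a test bridge)."""
        tree = dendropy.Tree.get(data=self.to_newick(), schema="newick",
                                 preserve_underscores=True,
                                 rooting="force-rooted",
                                 taxon_namespace=taxon_namespace)
        return tree


def _ensure_bifurcating_root(tree: dendropy.Tree,
                             outgroup: Iterable[str] | None) -> None:
    """Reject basal multifurcations unless an outgroup resolves them.

    An ultrametric tree cannot be rerooted along an edge without inventing a
    new root age, so the outgroup option instead groups the non-outgroup
    root children under a zero-length internal node at the root age.  Crown
    ages of all pre-existing clades are unchanged.
    """
    root = tree.seed_node
    kids = root.child_nodes()
    if len(kids) <= 2:
        return
    if outgroup is None:
        raise StructuralError(
            f"root has {len(kids)} children; trees must arrive rooted with a "
            f"bifurcating root (or supply an outgroup taxon set)")
    og = frozenset(outgroup)
    ingroup_kids, outgroup_kids = [], []
    for c in kids:
        leaves = frozenset(lf.taxon.label for lf in c.leaf_iter())
        if leaves <= og:
            outgroup_kids.append(c)
        elif leaves.isdisjoint(og):
            ingroup_kids.append(c)
        else:
            raise StructuralError(
                "outgroup taxa do not cleanly separate the basal polytomy")
    if not outgroup_kids or len(ingroup_kids) < 2:
        raise StructuralError(
            "outgroup does not resolve the basal polytomy into "
            "outgroup vs ingroup")
    new = dendropy.Node(edge_length=0.0)
    for c in ingroup_kids:
        root.remove_child(c)
        new.add_child(c)
    root.add_child(new)


@dataclass
class PosteriorSample:
    """Ordered collection of chronograms over a shared leaf set.

    ``provenance`` records, per input chain, the file and how many trees
    were kept/discarded as burn-in.
    """

    trees: list
    leaf_set: frozenset
    model_label: str = ""
    calibration_label: str = ""
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        if not self.trees:
            raise ValidationError("posterior sample contains no trees "
                                  "after burn-in removal")
        self.leaf_set = frozenset(self.leaf_set)
        for k, t in enumerate(self.trees):
            if t.leaf_set != self.leaf_set:
                raise StructuralError(
                    f"tree {k} leaf set differs from the sample leaf set")

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self) -> Iterator[Chronogram]:
        return iter(self.trees)

    def shares_topology(self) -> bool:
        """True when all trees share one topology object (fast paths)."""
        t0 = self.trees[0]
        return all(t.shares_topology_with(t0) for t in self.trees)

    def ages_matrix(self) -> np.ndarray:
        """(n_trees, n_nodes) age matrix; only valid for shared topology."""
        return np.stack([t.ages for t in self.trees])


def _classify_line(line: str) -> bool:
    """True if the stripped line should be skipped (header/comment/blank)."""
    s = line.strip()
    return (not s) or s.startswith("#") or s.isdigit()


def read_sample(path, burn_in_fraction: float = 0.2,
                model_label: str = "", calibration_label: str = "", *,
                tolerance: float = DEFAULT_ULTRAMETRICITY_TOL,
                time_scale: float = 1.0,
                outgroup: Iterable[str] | None = None) -> PosteriorSample:
    """Read a datedist-style tree list and discard burn-in.

    The first ``ceil(burn_in_fraction * n_trees)`` parseable trees are
    discarded (ceiling errs toward discarding); the remainder are validated
    as chronograms with order preserved.
    """
    if not (0 <= burn_in_fraction < 1):
        raise ValueError("burn_in_fraction must be in [0, 1)")
    path = Path(path)
    parsed: list[tuple[int, dendropy.Tree]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _classify_line(line):
                continue
            try:
                tree = dendropy.Tree.get(data=line, schema="newick",
                                         preserve_underscores=True,
                                         rooting="force-rooted")
            except Exception as exc:
                raise ParseError(
                    f"{path.name}, line {lineno}: unparseable newick "
                    f"({exc})") from exc
            parsed.append((lineno, tree))
    if not parsed:
        raise ParseError(f"{path.name}: no parseable trees found")
    n_discard = math.ceil(burn_in_fraction * len(parsed))
    kept = parsed[n_discard:]
    if not kept:
        raise ValidationError(
            f"{path.name}: all {len(parsed)} trees removed as burn-in")
    trees = []
    for k, (lineno, dtree) in enumerate(kept):
        try:
            trees.append(Chronogram.from_dendropy(
                dtree, tolerance=tolerance, time_scale=time_scale,
                source_line=lineno, outgroup=outgroup))
        except ValidationError as exc:
            raise ValidationError(
                f"{path.name}: tree {k} (line {lineno}): {exc}") from exc
    leaf_set = trees[0].leaf_set
    for k, t in enumerate(trees[1:], start=1):
        if t.leaf_set != leaf_set:
            raise StructuralError(
                f"{path.name}: tree {k} (line {t.source_line}) leaf set "
                f"differs from the first tree's")
    provenance = [{"file": str(path), "trees_kept": len(trees),
                   "trees_discarded": n_discard}]
    return PosteriorSample(trees=trees, leaf_set=leaf_set,
                           model_label=model_label,
                           calibration_label=calibration_label,
                           provenance=provenance)


def merge_chains(samples: Sequence[PosteriorSample]) -> PosteriorSample:
    """Pool post-burn-in trees from several MCMC chains into one sample."""
    if not samples:
        raise ValueError("no samples to merge")
    first = samples[0]
    for s in samples[1:]:
        if s.leaf_set != first.leaf_set:
            raise StructuralError("cannot merge chains with different leaf sets")
        if (s.model_label, s.calibration_label) != (first.model_label,
                                                    first.calibration_label):
            raise StructuralError("cannot merge chains with different "
                                  "model/calibration labels")
    trees = [t for s in samples for t in s.trees]
    provenance = []
    for chain_id, s in enumerate(samples):
        for rec in s.provenance:
            provenance.append({**rec, "chain": chain_id})
    return PosteriorSample(trees=trees, leaf_set=first.leaf_set,
                           model_label=first.model_label,
                           calibration_label=first.calibration_label,
                           provenance=provenance)


def compute_node_ages(tree: dendropy.Tree, *,
                      tolerance: float = DEFAULT_ULTRAMETRICITY_TOL,
                      time_scale: float = 1.0) -> Chronogram:
    """Derive validated node ages from a parsed rooted tree."""
    return Chronogram.from_dendropy(tree, tolerance=tolerance,
                                    time_scale=time_scale)


def write_sample(sample: PosteriorSample, path, precision: int = 12) -> None:
    """Write a posterior sample as a datedist-style newick list."""
    with open(path, "w") as fh:
        for t in sample.trees:
            fh.write(t.to_newick(precision=precision) + "\n")


def write_age_table(sample: PosteriorSample, clades, path) -> None:
    """Write one row per (tree index, clade) with the resolved node age."""
    import pandas as pd

    from .clades import resolve_clade_age
    rows = []
    for k, tree in enumerate(sample.trees):
        for clade in clades:
            rc = resolve_clade_age(tree, clade, tree_index=k)
            rows.append((k, clade.name, clade.group_kind, rc.age))
    df = pd.DataFrame(rows, columns=["tree_index", "clade", "group_kind",
                                     "age"])
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _node_age_table(trees: Sequence[Chronogram]) -> dict:
    """Map leaf-set -> array of that clade's age across the given trees."""
    acc: dict[frozenset, list[float]] = {}
    for t in trees:
        ls = t.leafsets
        for i in range(t.n_nodes):
            if t.children[i]:
                acc.setdefault(ls[i], []).append(float(t.ages[i]))
    return {k: np.asarray(v) for k, v in acc.items()}


def write_annotated_tree(sample: PosteriorSample, path, subset=None,
                         ci_level: float = 0.95) -> None:
    """Write the first tree's topology with per-node age annotations.

    Every internal node carries a comment block
    ``[&age_mean=...,age_ci={older,younger}]`` summarizing that clade's age
    across the whole sample; when ``subset`` is given, filtered summaries
    are appended as ``filtered_age_mean``/``filtered_age_ci``.  Branch
    lengths are those of the first tree.
    """
    base = sample.trees[0]
    lo_q, hi_q = 100 * (1 - ci_level) / 2, 100 * (1 + ci_level) / 2
    all_stats = _node_age_table(sample.trees)
    sub_stats = None
    if subset is not None:
        sub_stats = _node_age_table([sample.trees[i] for i in sorted(subset)])

    def _annot(ls_key) -> str:
        ages = all_stats[ls_key]
        lo, hi = np.percentile(ages, [lo_q, hi_q])
        parts = [f"age_mean={ages.mean():.6g}", f"age_ci={{{hi:.6g},{lo:.6g}}}"]
        if sub_stats is not None and ls_key in sub_stats:
            sa = sub_stats[ls_key]
            slo, shi = np.percentile(sa, [lo_q, hi_q])
            parts.append(f"filtered_age_mean={sa.mean():.6g}")
            parts.append(f"filtered_age_ci={{{shi:.6g},{slo:.6g}}}")
        return "[&" + ",".join(parts) + "]"

    ls = base.leafsets
    frag = [""] * base.n_nodes
    for i in range(base.n_nodes):
        if not base.children[i]:
            frag[i] = _quote_label(base.leaf_label[i])
        else:
            parts = []
            for c in base.children[i]:
                bl = base.ages[i] - base.ages[c]
                parts.append(f"{frag[c]}:{bl:.12g}")
            frag[i] = "(" + ",".join(parts) + ")" + _annot(ls[i])
    with open(path, "w") as fh:
        fh.write(frag[base.root] + ";\n")
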