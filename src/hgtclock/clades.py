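"""Named clades and their resolution to node ages.

A clade is a named taxon set with a *group kind*: ``crown`` (the MRCA of
the taxa) or ``total`` (the total group, i.e. the crown plus its stem
lineage, whose age is the age of the MRCA's parent node).  Resolution is by
MRCA, so non-monophyletic taxon sets still resolve — the ``monophyletic``
flag records whether the MRCA's descendant leaves are exactly the taxon
set, and a warning is logged when they are not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .chronogram import Chronogram, PosteriorSample
from .errors import (CladeResolutionError, UndefinedCrownError,
                     UndefinedStemError, ValidationError)

logger = logging.getLogger(__name__)

GROUP_KINDS = ("crown", "total")


@dataclass(frozen=True)
class CladeDefinition:
    """A named taxon set with crown/total group kind."""

    name: str
    taxa: frozenset
    group_kind: str = "crown"

    def __post_init__(self):
        object.__setattr__(self, "taxa", frozenset(self.taxa))
        if not self.taxa:
            raise ValueError(f"clade {self.name!r} has an empty taxon set")
        if self.group_kind not in GROUP_KINDS:
            raise ValueError(f"clade {self.name!r}: group_kind must be one "
                             f"of {GROUP_KINDS}, got {self.group_kind!r}")


@dataclass
class ResolvedClade:
    """A clade definition bound to a node (and age) in one chronogram."""

    clade: CladeDefinition
    tree_index: int
    node: int
    age: float
    monophyletic: bool


def resolve_clade_age(tree: Chronogram, clade: CladeDefinition,
                      tree_index: int = 0) -> ResolvedClade:
    """Resolve a clade to its node age in one chronogram.

    Crown age is the MRCA node's age; total-group age is the MRCA's
    parent's age (undefined when the MRCA is the root, since the stem
    branch is unobserved).  A single taxon has no crown; its total group
    age is its terminal branch's parent age.
    """
    node = tree.mrca(clade.taxa)
    mono = tree.leafsets[node] == clade.taxa
    if not mono:
        logger.warning("clade %r is not monophyletic in tree %d; "
                       "resolved via MRCA anyway", clade.name, tree_index)
    if clade.group_kind == "crown":
        if len(clade.taxa) == 1:
            raise UndefinedCrownError(
                f"clade {clade.name!r}: crown age of a single taxon is "
                f"undefined")
        age_node = node
    else:  # total
        if node == tree.root:
            raise UndefinedStemError(
                f"clade {clade.name!r}: MRCA is the root, so the stem "
                f"lineage (total group) is unobserved")
        age_node = int(tree.parent[node])
    return ResolvedClade(clade=clade, tree_index=tree_index, node=node,
                         age=float(tree.ages[age_node]), monophyletic=mono)


def monophyly_report(sample: PosteriorSample, clades) -> dict:
    """Per-clade fraction of trees in which the clade is monophyletic.

    A guard for real posteriors: the filtering workflow assumes one fixed
    topology, so any fraction below 1 is logged as a warning.
    """
    if not clades:
        raise ValueError("no clades given")
    fractions = {}
    for clade in clades:
        hits = 0
        for k, tree in enumerate(sample.trees):
            node = tree.mrca(clade.taxa)
            hits += tree.leafsets[node] == clade.taxa
        frac = hits / len(sample)
        if frac < 1.0:
            logger.warning("clade %r monophyletic in only %.1f%% of trees",
                           clade.name, 100 * frac)
        fractions[clade.name] = frac
    return fractions


# -- clade table I/O -------------------------------------------------------

def read_clade_table(path) -> list:
    """Read clade definitions from TSV (name, group_kind, taxa) or YAML.

    The TSV ``taxa`` column holds semicolon-separated leaf labels matching
    the newick labels exactly; YAML files hold a list of mappings with the
    same keys (taxa as a list or semicolon-separated string).
    """
    path = Path(path)
    records = []
    if path.suffix.lower() in (".yaml", ".yml"):
        with open(path) as fh:
            data = yaml.safe_load(fh)
        for rec in data:
            taxa = rec["taxa"]
            if isinstance(taxa, str):
                taxa = [t.strip() for t in taxa.split(";") if t.strip()]
            records.append((rec["name"], taxa,
                            rec.get("group_kind", "crown")))
    else:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        required = {"name", "group_kind", "taxa"}
        if not required <= set(df.columns):
            raise ValidationError(
                f"clade table {path.name} must have columns {sorted(required)}")
        for rec in df.itertuples(index=False):
            taxa = [t.strip() for t in rec.taxa.split(";") if t.strip()]
            records.append((rec.name, taxa, rec.group_kind))
    clades = [CladeDefinition(name=n, taxa=frozenset(t), group_kind=k)
              for n, t, k in records]
    names = [c.name for c in clades]
    if len(set(names)) != len(names):
        raise ValidationError(f"clade table {path.name}: duplicate clade names")
    return clades


def write_clade_table(clades, path) -> None:
    df = pd.DataFrame(
        [(c.name, c.group_kind, ";".join(sorted(c.taxa))) for c in clades],
        columns=["name", "group_kind", "taxa"])
    df.to_csv(path, sep="\t", index=False)
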