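"""HGT relative-age constraints and compatibility scoring.

A horizontal gene transfer from a donor clade into a recipient clade
implies the donor lineage is at least as old as the recipient, so each
curated ("index") HGT yields a relative-age assertion: a chronogram is
*compatible* with the constraint when the donor node is strictly older
than the recipient node.  Evaluating every constraint against every
posterior chronogram gives a boolean trees x constraints matrix from
which everything downstream derives:

* per-constraint compatibility percentages (the constraint *profile*),
* a model-level score (mean over constraints = fraction of true cells),
  used as an empirical model-selection criterion,
* a count of constraints supported by at least ``support_threshold`` %
  of the posterior, and
* a miscalibration flag for constraints that are (near-)incompatible
  under *every* model, which in practice points at a misplaced node
  calibration shared by the analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .chronogram import Chronogram, PosteriorSample
from .clades import CladeDefinition, resolve_clade_age
from .errors import CladeResolutionError, ValidationError

logger = logging.getLogger(__name__)

#: "supported" means compatible with at least this percentage of trees.
DEFAULT_SUPPORT_THRESHOLD = 20.0
#: a constraint below this percentage in every model flags a suspect
#: calibration.
DEFAULT_FLAG_THRESHOLD = 1.2


@dataclass(frozen=True)
class HGTConstraint:
    """Donor clade -> recipient clade relative-age assertion."""

    id: str
    donor: CladeDefinition
    recipient: CladeDefinition
    note: str = ""

    def __post_init__(self):
        if (self.donor.taxa == self.recipient.taxa
                and self.donor.group_kind == self.recipient.group_kind):
            raise ValueError(
                f"constraint {self.id!r}: donor and recipient clades are "
                f"identical")

    @property
    def pair_key(self):
        return (self.donor.taxa, self.donor.group_kind,
                self.recipient.taxa, self.recipient.group_kind)


def dedupe_constraints(constraints) -> list:
    """Collapse constraints sharing a donor/recipient clade pair.

    Multiple HGT events frequently map onto one unique donor–recipient
    pair; the matrix is built over unique pairs, with the merged ids
    preserved in ``note``.
    """
    seen: dict = {}
    order = []
    for c in constraints:
        key = c.pair_key
        if key in seen:
            seen[key].append(c.id)
        else:
            seen[key] = [c.id]
            order.append(c)
    out = []
    for c in order:
        ids = seen[c.pair_key]
        if len(ids) > 1:
            merged = "merged ids: " + ",".join(ids)
            note = f"{c.note}; {merged}" if c.note else merged
            out.append(replace(c, note=note))
        else:
            out.append(c)
    if len(out) < len(list(constraints)):
        logger.info("deduplicated %d constraints to %d unique clade pairs",
                    len(list(constraints)), len(out))
    return out


def is_compatible(tree: Chronogram, constraint: HGTConstraint) -> bool:
    """True iff the donor node is strictly older than the recipient node.

    Exact age ties count as incompatible ("older than" is strict; ties
    have measure zero in continuous posteriors).
    """
    donor_age = resolve_clade_age(tree, constraint.donor).age
    recip_age = resolve_clade_age(tree, constraint.recipient).age
    return donor_age > recip_age


@dataclass
class CompatibilityMatrix:
    """Boolean trees x constraints table; everything downstream derives
    from it."""

    values: pd.DataFrame
    model_label: str = ""
    calibration_label: str = ""

    @property
    def n_trees(self) -> int:
        return self.values.shape[0]

    @property
    def n_constraints(self) -> int:
        return self.values.shape[1]

    @property
    def constraint_ids(self) -> list:
        return list(self.values.columns)


def _age_node_index(tree: Chronogram, clade: CladeDefinition) -> int:
    """Node index whose age realizes the clade age (for fast paths)."""
    rc = resolve_clade_age(tree, clade)
    if clade.group_kind == "total":
        return int(tree.parent[rc.node])
    return rc.node


def compatibility_matrix(sample: PosteriorSample,
                         constraints) -> CompatibilityMatrix:
    """Evaluate every constraint against every chronogram.

    Constraints are first deduplicated to unique donor/recipient clade
    pairs.  When all trees share one topology object (as synthetic
    posteriors do), clades are resolved once and the matrix is computed
    on the stacked age matrix.
    """
    constraints = dedupe_constraints(constraints)
    ids = [c.id for c in constraints]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate constraint ids")
    n = len(sample)
    if constraints and sample.shares_topology():
        t0 = sample.trees[0]
        ages = sample.ages_matrix()
        cols = {}
        for c in constraints:
            try:
                di = _age_node_index(t0, c.donor)
                ri = _age_node_index(t0, c.recipient)
            except CladeResolutionError as exc:
                raise CladeResolutionError(
                    f"constraint {c.id!r}: {exc}") from exc
            cols[c.id] = ages[:, di] > ages[:, ri]
        values = pd.DataFrame(cols, index=range(n))
    else:
        data = np.zeros((n, len(constraints)), dtype=bool)
        for j, c in enumerate(constraints):
            for k, tree in enumerate(sample.trees):
                try:
                    data[k, j] = is_compatible(tree, c)
                except CladeResolutionError as exc:
                    raise CladeResolutionError(
                        f"tree {k}, constraint {c.id!r}: {exc}") from exc
        values = pd.DataFrame(data, index=range(n), columns=ids)
    return CompatibilityMatrix(values=values,
                               model_label=sample.model_label,
                               calibration_label=sample.calibration_label)


def constraint_profile(matrix: CompatibilityMatrix) -> pd.Series:
    """Percentage of compatible chronograms for each constraint."""
    if matrix.n_trees == 0:
        raise ValidationError("compatibility matrix has zero trees")
    return 100.0 * matrix.values.mean(axis=0).rename("pct_compatible")


def model_score(matrix: CompatibilityMatrix) -> float:
    """Overall compatibility percentage of a model's posterior.

    The mean over constraints of the per-constraint percentages; for a
    complete matrix this equals (to rounding) the fraction of compatible
    (tree, constraint) cells.
    """
    if matrix.n_trees == 0 or matrix.n_constraints == 0:
        raise ValidationError("compatibility matrix is empty")
    return float(constraint_profile(matrix).mean())


def supported_constraint_count(profile,
                               support_threshold: float = DEFAULT_SUPPORT_THRESHOLD
                               ) -> int:
    """Number of constraints compatible with >= ``support_threshold`` %
    of the posterior (boundary inclusive: "at least")."""
    profile = pd.Series(profile, dtype=float)
    if profile.empty:
        raise ValidationError("empty constraint profile")
    return int((profile >= support_threshold).sum())


@dataclass
class ModelReport:
    """Summary of one model's compatibility with the constraint set."""

    model_label: str
    per_constraint_pct: pd.Series
    overall_pct: float
    supported_count: int
    n_trees: int
    calibration_label: str = ""
    flagged: list = field(default_factory=list)

    @classmethod
    def from_matrix(cls, matrix: CompatibilityMatrix,
                    support_threshold: float = DEFAULT_SUPPORT_THRESHOLD
                    ) -> "ModelReport":
        profile = constraint_profile(matrix)
        return cls(model_label=matrix.model_label,
                   calibration_label=matrix.calibration_label,
                   per_constraint_pct=profile,
                   overall_pct=model_score(matrix),
                   supported_count=supported_constraint_count(
                       profile, support_threshold),
                   n_trees=matrix.n_trees)


def flag_miscalibration(reports,
                        flag_threshold: float = DEFAULT_FLAG_THRESHOLD
                        ) -> list:
    """Constraint ids with < ``flag_threshold`` % compatibility in EVERY
    report.

    Intended use: a constraint incompatible under all evolutionary models
    usually shares a misplaced node calibration; re-run after removing the
    suspect calibration and compare profiles.  The flagged ids are also
    written onto each report.
    """
    reports = list(reports)
    if not reports:
        raise ValidationError("no model reports given")
    ref_ids = list(reports[0].per_constraint_pct.index)
    for r in reports[1:]:
        if set(r.per_constraint_pct.index) != set(ref_ids):
            raise ValidationError(
                "model reports cover different constraint sets")
    flagged = [cid for cid in ref_ids
               if all(r.per_constraint_pct[cid] < flag_threshold
                      for r in reports)]
    for r in reports:
        r.flagged = list(flagged)
    return flagged


# -- constraint table I/O --------------------------------------------------

def read_constraint_table(path, clades) -> list:
    """Read HGT constraints from TSV or YAML, resolving clade names.

    Columns/keys: ``id``, ``donor_clade``, ``recipient_clade``, optional
    ``donor_kind``/``recipient_kind`` in {crown, total} (default crown for
    both sides, independently overridable), optional ``note``.  ``clades``
    is a list or dict of :class:`CladeDefinition` supplying the taxon sets.
    """
    if not isinstance(clades, dict):
        clades = {c.name: c for c in clades}
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        with open(path) as fh:
            records = yaml.safe_load(fh)
    else:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        records = df.to_dict("records")
    out = []
    for rec in records:
        def _clade(which: str) -> CladeDefinition:
            name = rec[f"{which}_clade"]
            if name not in clades:
                raise ValidationError(
                    f"constraint {rec.get('id')!r}: unknown clade {name!r}")
            kind = rec.get(f"{which}_kind")
            if kind is None or (isinstance(kind, float) and np.isnan(kind)):
                kind = "crown"
            return replace(clades[name], group_kind=kind)

        note = rec.get("note", "")
        if not isinstance(note, str):
            note = ""
        out.append(HGTConstraint(id=str(rec["id"]), donor=_clade("donor"),
                                 recipient=_clade("recipient"), note=note))
    return out


def write_constraint_table(constraints, path) -> None:
    df = pd.DataFrame(
        [(c.id, c.donor.name, c.recipient.name, c.donor.group_kind,
          c.recipient.group_kind, c.note) for c in constraints],
        columns=["id", "donor_clade", "recipient_clade", "donor_kind",
                 "recipient_kind", "note"])
    df.to_csv(path, sep="\t", index=False)
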