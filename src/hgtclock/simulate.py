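"""Synthetic chronogram posteriors with planted HGT constraints.

The generator stands in for a Bayesian dating run: it draws a fixed
pure-birth (Yule) topology with ultrametric node ages conditioned on a
known root age, jitters the internal ages multiplicatively to mimic MCMC
posterior spread, and plants donor->recipient constraints whose truth
status in the generating chronogram is recorded.  Every pipeline stage can
then be tested against known ground truth without external downloads.

Conditioned on the root age T and taxon count n, the n-2 non-root
speciation ages of a Yule(lambda) tree are i.i.d. truncated-exponential
order statistics on [0, T] (density lambda * exp(-lambda * t) truncated at
T, t measured back from the present); the topology grows by splitting a
uniformly chosen extant lineage at each successive age.

All randomness flows from one integer seed through numpy SeedSequence
spawn keys, so the topology, posterior-noise and constraint stages are
independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chronogram import Chronogram, PosteriorSample, write_sample
from .clades import CladeDefinition, write_clade_table
from .compat import HGTConstraint, write_constraint_table
from .errors import SimulationError

_STAGES = {"topology": 0, "posterior": 1, "constraints": 2}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Defaults emulate a single-model dating study on the Ma scale: a
    32-taxon crown at 3500 Ma with a typical pure-birth rate
    (~ln(16)/3500 per Ma), a 2000-tree posterior with 15% coefficient of
    variation on node ages, and 24 planted constraints, all true in the
    generating chronogram.
    """

    n_taxa: int = 32
    birth_rate: float = 8e-4
    root_age: float = 3500.0
    n_trees: int = 2000
    age_noise_cv: float = 0.15
    n_constraints: int = 24
    true_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 3:
            raise ValueError("n_taxa must be >= 3")
        if self.birth_rate <= 0 or self.root_age <= 0:
            raise ValueError("birth_rate and root_age must be positive")
        if self.n_trees < 1 or self.n_constraints < 0:
            raise ValueError("n_trees must be >= 1, n_constraints >= 0")
        if self.age_noise_cv < 0:
            raise ValueError("age_noise_cv must be non-negative")
        if not (0 <= self.true_fraction <= 1):
            raise ValueError("true_fraction must be in [0, 1]")


def _stage_rng(config: SimulationConfig, stage: str) -> np.random.Generator:
    ss = np.random.SeedSequence(config.seed, spawn_key=(_STAGES[stage],))
    return np.random.default_rng(ss)


class _N:
    __slots__ = ("age", "children")

    def __init__(self, age=None):
        self.age = age
        self.children = []


def simulate_true_chronogram(config: SimulationConfig,
                             rng: np.random.Generator | None = None
                             ) -> Chronogram:
    """Draw the generating chronogram: Yule topology, ages conditioned on
    the configured root age.  Deterministic under the config seed."""
    rng = rng if rng is not None else _stage_rng(config, "topology")
    n, lam, T = config.n_taxa, config.birth_rate, config.root_age
    u = rng.random(n - 2)
    draws = -np.log1p(-u * (1.0 - np.exp(-lam * T))) / lam
    node_ages = np.sort(draws)[::-1]  # descending; root (age T) comes first
    root = _N(T)
    root.children = [_N(), _N()]
    tips = list(root.children)
    for age in node_ages:
        j = int(rng.integers(len(tips)))
        nd = tips[j]
        nd.age = float(age)
        nd.children = [_N(), _N()]
        tips[j] = nd.children[0]
        tips.insert(j + 1, nd.children[1])
    for t in tips:
        t.age = 0.0
    return _to_chronogram(root, n)


def _to_chronogram(root: _N, n_taxa: int) -> Chronogram:
    width = len(str(n_taxa))
    order: list[_N] = []
    stack = [(root, False)]
    while stack:  # iterative postorder
        nd, done = stack.pop()
        if done or not nd.children:
            order.append(nd)
        else:
            stack.append((nd, True))
            for c in reversed(nd.children):
                stack.append((c, False))
    index = {id(nd): i for i, nd in enumerate(order)}
    m = len(order)
    parent = np.full(m, -1, dtype=np.int64)
    children = [[] for _ in range(m)]
    ages = np.zeros(m)
    leaf_label = {}
    leaf_counter = 0
    for i, nd in enumerate(order):
        ages[i] = nd.age
        for c in nd.children:
            j = index[id(c)]
            parent[j] = i
            children[i].append(j)
    # label leaves left-to-right for readable newick output
    for nd in _preorder_leaves(root):
        leaf_counter += 1
        leaf_label[index[id(nd)]] = f"T{leaf_counter:0{width}d}"
    return Chronogram(parent, children, ages, leaf_label)


def _preorder_leaves(root: _N):
    stack = [root]
    while stack:
        nd = stack.pop()
        if not nd.children:
            yield nd
        else:
            for c in reversed(nd.children):
                stack.append(c)


def simulate_posterior(true_tree: Chronogram, config: SimulationConfig,
                       model_label: str = "sim",
                       rng: np.random.Generator | None = None
                       ) -> PosteriorSample:
    """MCMC-like posterior: i.i.d. lognormal age jitter (mean 1, CV
    ``age_noise_cv``) on each internal node, with parent >= child repaired
    by propagating the max child age upward.  Leaves stay at age 0."""
    rng = rng if rng is not None else _stage_rng(config, "posterior")
    m = true_tree.n_nodes
    internal = [i for i in range(m) if true_tree.children[i]]
    ages = np.tile(true_tree.ages, (config.n_trees, 1))
    cv = config.age_noise_cv
    if cv > 0:
        s2 = np.log1p(cv * cv)
        factors = rng.lognormal(mean=-s2 / 2, sigma=np.sqrt(s2),
                                size=(config.n_trees, len(internal)))
        ages[:, internal] *= factors
        for v in internal:  # postorder: children already repaired
            kids = list(true_tree.children[v])
            ages[:, v] = np.maximum(ages[:, v], ages[:, kids].max(axis=1))
    trees = [true_tree.with_ages(ages[i]) for i in range(config.n_trees)]
    return PosteriorSample(
        trees=trees, leaf_set=true_tree.leaf_set, model_label=model_label,
        provenance=[{"file": None, "simulated": True,
                     "trees_kept": config.n_trees, "trees_discarded": 0,
                     "seed": config.seed, "age_noise_cv": cv}])


def internal_clades(tree: Chronogram, group_kind: str = "crown") -> list:
    """One crown clade per internal node, named by node index."""
    ls = tree.leafsets
    pad = len(str(tree.n_nodes))
    return [CladeDefinition(name=f"N{i:0{pad}d}", taxa=ls[i],
                            group_kind=group_kind)
            for i in range(tree.n_nodes) if tree.children[i]]


@dataclass
class PlantedConstraints:
    """Planted constraints plus their recorded ground-truth labels."""

    constraints: list
    truth: dict  # constraint id -> bool (holds in the generating tree?)


def plant_constraints(true_tree: Chronogram, config: SimulationConfig,
                      rng: np.random.Generator | None = None
                      ) -> PlantedConstraints:
    """Plant donor->recipient constraints over disjoint internal clades.

    A fraction ``true_fraction`` are oriented donor-older in the
    generating chronogram; the rest are deliberately inverted.  Ground
    truth is recorded per constraint id.
    """
    rng = rng if rng is not None else _stage_rng(config, "constraints")
    ls = true_tree.leafsets
    ages = true_tree.ages
    internal = [i for i in range(true_tree.n_nodes) if true_tree.children[i]]
    pairs = []
    for a_pos in range(len(internal)):
        for b_pos in range(a_pos + 1, len(internal)):
            a, b = internal[a_pos], internal[b_pos]
            if ls[a].isdisjoint(ls[b]) and ages[a] != ages[b]:
                pairs.append((a, b))
    if len(pairs) < config.n_constraints:
        raise SimulationError(
            f"only {len(pairs)} disjoint internal clade pairs exist; cannot "
            f"plant {config.n_constraints} constraints (increase n_taxa)")
    chosen = rng.choice(len(pairs), size=config.n_constraints, replace=False)
    n_true = int(round(config.true_fraction * config.n_constraints))
    pad = len(str(true_tree.n_nodes))
    width = len(str(max(config.n_constraints, 1)))

    def _clade(i: int) -> CladeDefinition:
        return CladeDefinition(name=f"N{i:0{pad}d}", taxa=ls[i],
                               group_kind="crown")

    constraints, truth = [], {}
    for k, pi in enumerate(chosen):
        a, b = pairs[int(pi)]
        older, younger = (a, b) if ages[a] > ages[b] else (b, a)
        holds = k < n_true
        donor, recipient = (older, younger) if holds else (younger, older)
        cid = f"HGT_{k + 1:0{width}d}"
        constraints.append(HGTConstraint(
            id=cid, donor=_clade(donor), recipient=_clade(recipient),
            note=f"planted {'true' if holds else 'inverted'}"))
        truth[cid] = holds
    return PlantedConstraints(constraints=constraints, truth=truth)


@dataclass
class SimulatedStudy:
    """Everything one synthetic dating study produces."""

    config: SimulationConfig
    truth: Chronogram
    sample: PosteriorSample
    clades: list
    constraints: PlantedConstraints


def simulate_study(config: SimulationConfig,
                   model_label: str = "sim") -> SimulatedStudy:
    """Run all three generator stages from the one config seed."""
    truth = simulate_true_chronogram(config)
    sample = simulate_posterior(truth, config, model_label=model_label)
    planted = plant_constraints(truth, config)
    return SimulatedStudy(config=config, truth=truth, sample=sample,
                          clades=internal_clades(truth),
                          constraints=planted)


def write_simulation(config: SimulationConfig, outdir) -> dict:
    """Write a full synthetic study: datedist tree file, clade table,
    constraint table and a ground-truth JSON.  Returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study = simulate_study(config)
    paths = {
        "trees": outdir / "posterior.trees",
        "clades": outdir / "clades.tsv",
        "constraints": outdir / "constraints.tsv",
        "truth": outdir / "truth.json",
    }
    write_sample(study.sample, paths["trees"])
    write_clade_table(study.clades, paths["clades"])
    write_constraint_table(study.constraints.constraints,
                           paths["constraints"])
    true_ages = {c.name: float(study.truth.ages[study.truth.mrca(c.taxa)])
                 for c in study.clades}
    with open(paths["truth"], "w") as fh:
        json.dump({"config": dataclasses.asdict(config),
                   "true_ages": true_ages,
                   "constraint_truth": study.constraints.truth},
                  fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
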