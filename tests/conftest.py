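import pytest

from hgtclock import (CladeDefinition, Chronogram, SimulationConfig,
                      simulate_study)

# Hand-computable toy: crown {A,B} at 1, crown {C,D} at 2, root at 3.
TOY = "((A:1,B:1):2,(C:2,D:2):1);"
# Same leaf set with inverted clade ages: {A,B} at 2, {C,D} at 1, root at 3.
TOY_INVERTED = "((A:2,B:2):1,(C:1,D:1):2);"


@pytest.fixture
def toy_tree():
    return Chronogram.from_newick(TOY)


@pytest.fixture
def toy_inverted():
    return Chronogram.from_newick(TOY_INVERTED)


def clade(name, taxa, kind="crown"):
    return CladeDefinition(name=name, taxa=frozenset(taxa), group_kind=kind)


@pytest.fixture(scope="session")
def small_study():
    """A modest seeded synthetic study shared by read-only tests."""
    cfg = SimulationConfig(n_taxa=12, n_trees=80, seed=7, n_constraints=8,
                           age_noise_cv=0.15, true_fraction=0.75)
    return simulate_study(cfg)


def scaled_toy(scale):
    """Toy topology scaled by an integer factor (still ultrametric)."""
    s = scale
    return f"((A:{s},B:{s}):{2 * s},(C:{2 * s},D:{2 * s}):{s});"


@pytest.fixture
def datedist_file(tmp_path):
    """Factory writing newick lines (plus optional raw lines) to a file."""

    def _write(lines, name="chain.trees"):
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write
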