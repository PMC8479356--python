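"""Chronogram parsing, validation, burn-in and round-trip behaviour."""

import math

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hgtclock import (Chronogram, ParseError, PosteriorSample,
                      SimulationConfig, StructuralError, ValidationError,
                      merge_chains, read_sample, resolve_clade_age,
                      simulate_true_chronogram, write_age_table,
                      write_annotated_tree, write_sample)
from hgtclock.chronogram import _node_age_table

from conftest import TOY, clade, scaled_toy


def _ages_by_leafset(tree):
    ls = tree.leafsets
    return {ls[i]: tree.ages[i] for i in range(tree.n_nodes)}


class TestParsing:
    def test_node_ages_match_hand_computation(self, toy_tree):
        ages = _ages_by_leafset(toy_tree)
        assert ages[frozenset("AB")] == pytest.approx(1.0)
        assert ages[frozenset("CD")] == pytest.approx(2.0)
        assert ages[frozenset("ABCD")] == pytest.approx(3.0)
        for leaf in "ABCD":
            assert ages[frozenset(leaf)] == 0.0

    def test_node_ages_agree_with_dendropy(self, toy_tree):
        dtree = dendropy.Tree.get(data=TOY, schema="newick",
                                  preserve_underscores=True,
                                  rooting="force-rooted")
        for nd in dtree.postorder_internal_node_iter():
            labels = frozenset(lf.taxon.label for lf in nd.leaf_iter())
            mine = _ages_by_leafset(toy_tree)[labels]
            assert mine == pytest.approx(nd.distance_from_tip())

    def test_single_leaf_tree_has_root_age_zero(self):
        t = Chronogram.from_newick("A;")
        assert t.n_leaves == 1
        assert t.ages[t.root] == 0.0

    def test_rounding_within_tolerance_accepted_leaves_forced_to_zero(self):
        t = Chronogram.from_newick("((A:1,B:1.0000001):2,C:3.0000001);")
        assert all(t.ages[i] == 0.0 for i in range(t.n_nodes)
                   if t.is_leaf(i))
        assert t.ages[t.root] == pytest.approx(3.0000001)

    def test_non_ultrametric_beyond_tolerance_rejected(self):
        with pytest.raises(ValidationError, match="ultrametric"):
            Chronogram.from_newick("((A:1,B:2):2,(C:2,D:2):1);")

    def test_negative_branch_length_rejected(self):
        with pytest.raises(ValidationError, match="negative"):
            Chronogram.from_newick("((A:1,B:1):-2,(C:2,D:2):1);")

    def test_time_scale_multiplies_ages(self):
        t = Chronogram.from_newick(TOY, time_scale=1000.0)
        assert t.ages[t.root] == pytest.approx(3000.0)

    def test_basal_trifurcation_rejected_without_outgroup(self):
        nwk = "((A:1,B:1):1,(C:1,D:1):1,E:2);"
        with pytest.raises(StructuralError, match="root"):
            Chronogram.from_newick(nwk)

    def test_basal_trifurcation_resolved_by_outgroup(self):
        nwk = "((A:1,B:1):1,(C:1,D:1):1,E:2);"
        t = Chronogram.from_newick(nwk, outgroup={"E"})
        assert len(t.children[t.root]) == 2
        ages = _ages_by_leafset(t)
        # crown ages of pre-existing clades are unchanged
        assert ages[frozenset("AB")] == pytest.approx(1.0)
        assert ages[frozenset("CD")] == pytest.approx(1.0)
        # the new ingroup node sits at the root age (zero-length stem)
        assert ages[frozenset("ABCD")] == pytest.approx(2.0)
        assert ages[frozenset("ABCDE")] == pytest.approx(2.0)


class TestReadSample:
    @pytest.mark.parametrize("n_trees,fraction,n_kept",
                             [(10, 0.2, 8), (7, 0.25, 5), (10, 0.0, 10),
                              (3, 0.5, 1)])
    def test_burn_in_uses_ceiling(self, datedist_file, n_trees, fraction,
                                  n_kept):
        path = datedist_file([scaled_toy(k + 1) for k in range(n_trees)])
        sample = read_sample(path, burn_in_fraction=fraction)
        assert len(sample) == n_kept
        # order preserved: first kept tree is the (n-n_kept)-th input tree
        first_scale = n_trees - n_kept + 1
        assert sample.trees[0].ages[-1] == pytest.approx(3 * first_scale)
        assert sample.provenance[0]["trees_discarded"] == n_trees - n_kept

    def test_header_blank_and_comment_lines_skipped(self, datedist_file):
        path = datedist_file(["5000", "", "# a comment", TOY, "", TOY])
        sample = read_sample(path, burn_in_fraction=0.0)
        assert len(sample) == 2
        assert sample.trees[0].source_line == 4

    def test_parse_error_names_line_number(self, datedist_file):
        path = datedist_file([TOY, TOY, "((A:1,B:1):2,(C:2"])
        with pytest.raises(ParseError, match="line 3"):
            read_sample(path, burn_in_fraction=0.0)

    def test_leaf_set_mismatch_is_structural_error(self, datedist_file):
        other = "((A:1,B:1):2,(C:2,E:2):1);"
        path = datedist_file([TOY, other])
        with pytest.raises(StructuralError, match="leaf set"):
            read_sample(path, burn_in_fraction=0.0)

    def test_non_ultrametric_tree_names_index_and_spread(self,
                                                         datedist_file):
        path = datedist_file([TOY, "((A:1,B:5):2,(C:2,D:2):1);"])
        with pytest.raises(ValidationError, match=r"tree 1 .*spread"):
            read_sample(path, burn_in_fraction=0.0)

    def test_all_trees_burned_is_an_error(self, datedist_file):
        path = datedist_file([TOY])
        with pytest.raises(ValidationError, match="burn-in"):
            read_sample(path, burn_in_fraction=0.99)

    @given(f1=st.floats(0, 0.99), f2=st.floats(0, 0.99))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_burn_in_monotonicity(self, f1, f2):
        # retained count ceil-derived: more burn-in never keeps more trees
        lo, hi = sorted([f1, f2])
        n = 9
        assert n - math.ceil(hi * n) <= n - math.ceil(lo * n)


class TestMergeChains:
    def test_concatenates_two_chains(self, datedist_file):
        p1 = datedist_file([scaled_toy(k + 1) for k in range(10)], "c1.t")
        p2 = datedist_file([scaled_toy(k + 1) for k in range(10)], "c2.t")
        s1 = read_sample(p1, 0.2, "CIR_nobd", "BE")
        s2 = read_sample(p2, 0.2, "CIR_nobd", "BE")
        merged = merge_chains([s1, s2])
        assert len(merged) == 16
        assert {rec["chain"] for rec in merged.provenance} == {0, 1}

    def test_single_chain_is_identity(self, datedist_file):
        s = read_sample(datedist_file([TOY, TOY]), 0.0)
        merged = merge_chains([s])
        assert len(merged) == len(s)
        assert merged.leaf_set == s.leaf_set

    def test_mismatched_leaf_sets_rejected(self, datedist_file):
        s1 = read_sample(datedist_file([TOY], "a.t"), 0.0)
        s2 = read_sample(
            datedist_file(["((A:1,B:1):2,(C:2,E:2):1);"], "b.t"), 0.0)
        with pytest.raises(StructuralError, match="leaf sets"):
            merge_chains([s1, s2])

    def test_mismatched_labels_rejected(self, datedist_file):
        s1 = read_sample(datedist_file([TOY], "a.t"), 0.0, "CIR")
        s2 = read_sample(datedist_file([TOY], "b.t"), 0.0, "LN")
        with pytest.raises(StructuralError, match="label"):
            merge_chains([s1, s2])


class TestRoundTrip:
    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_write_then_read_preserves_ages(self, seed):
        cfg = SimulationConfig(n_taxa=8, n_trees=1, seed=seed)
        t = simulate_true_chronogram(cfg)
        t2 = Chronogram.from_newick(t.to_newick())
        a1, a2 = _ages_by_leafset(t), _ages_by_leafset(t2)
        assert a1.keys() == a2.keys()
        for k in a1:
            assert a2[k] == pytest.approx(a1[k], rel=1e-9, abs=1e-9)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_branch_length_equals_parent_minus_child_age(self, seed):
        cfg = SimulationConfig(n_taxa=8, n_trees=1, seed=seed)
        t = simulate_true_chronogram(cfg)
        for i in range(t.n_nodes - 1):
            p = int(t.parent[i])
            assert t.branch_length(i) == pytest.approx(
                t.ages[p] - t.ages[i], abs=1e-12)

    def test_write_sample_roundtrip_through_file(self, tmp_path):
        cfg = SimulationConfig(n_taxa=6, n_trees=5, seed=3,
                               age_noise_cv=0.1, n_constraints=0)
        from hgtclock import simulate_posterior
        truth = simulate_true_chronogram(cfg)
        sample = simulate_posterior(truth, cfg)
        path = tmp_path / "out.trees"
        write_sample(sample, path)
        back = read_sample(path, burn_in_fraction=0.0)
        assert len(back) == 5
        for t_in, t_out in zip(sample.trees, back.trees):
            a1, a2 = _ages_by_leafset(t_in), _ages_by_leafset(t_out)
            for k in a1:
                assert a2[k] == pytest.approx(a1[k], rel=1e-9, abs=1e-9)


class TestAgeTable:
    def test_one_row_per_tree_and_clade(self, tmp_path, datedist_file):
        import pandas as pd
        sample = read_sample(datedist_file([TOY, TOY]), 0.0)
        clades = [clade("ab", "AB"), clade("cd", "CD"),
                  clade("ab_total", "AB", "total")]
        path = tmp_path / "ages.tsv"
        write_age_table(sample, clades, path)
        df = pd.read_csv(path, sep="\t")
        assert len(df) == 6
        expect = {("ab", 1.0), ("cd", 2.0), ("ab_total", 3.0)}
        got = {(r.clade, r.age) for r in df.itertuples()}
        assert got == expect

    def test_ages_match_resolver_exactly(self, tmp_path, datedist_file):
        import pandas as pd
        sample = read_sample(
            datedist_file([scaled_toy(k + 1) for k in range(4)]), 0.0)
        clades = [clade("ab", "AB"), clade("cd", "CD")]
        path = tmp_path / "ages.tsv"
        write_age_table(sample, clades, path)
        df = pd.read_csv(path, sep="\t")
        for row in df.itertuples():
            expected = resolve_clade_age(sample.trees[row.tree_index],
                                         clades[0] if row.clade == "ab"
                                         else clades[1]).age
            assert row.age == pytest.approx(expected, rel=1e-9)

    def test_empty_clade_list_gives_header_only(self, tmp_path,
                                                datedist_file):
        sample = read_sample(datedist_file([TOY]), 0.0)
        path = tmp_path / "ages.tsv"
        write_age_table(sample, [], path)
        lines = path.read_text().strip().splitlines()
        assert lines == ["tree_index\tclade\tgroup_kind\tage"]


class TestAnnotatedTree:
    def test_annotations_cover_means_and_ci(self, tmp_path, datedist_file):
        sample = read_sample(
            datedist_file([scaled_toy(s) for s in (1, 2, 3)]), 0.0)
        path = tmp_path / "annot.nwk"
        write_annotated_tree(sample, path, subset={1, 2})
        text = path.read_text()
        assert "age_mean=" in text and "age_ci={" in text
        assert "filtered_age_mean=" in text
        # mean crown age of {A,B} over scales 1..3 is 2; filtered (2,3) is 2.5
        assert "age_mean=2," in text.replace(" ", "")
        assert "filtered_age_mean=2.5" in text
        # the file is still valid newick for a standard parser
        dendropy.Tree.get(path=str(path), schema="newick")

    def test_node_age_table_collects_all_internal_nodes(self, toy_tree):
        table = _node_age_table([toy_tree])
        assert set(table) == {frozenset("AB"), frozenset("CD"),
                              frozenset("ABCD")}
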