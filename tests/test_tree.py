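"""Recursive localization tree: structure, level views, audits, export."""

import math

import numpy as np
import pytest

from divloc import (DomainError, TreeConfig, build_tree, level_view,
                    monotonicity_audit, ratio_report, render_ascii,
                    summarize_part, tree_from_json, tree_to_json)


def interior_breakpoints(view):
    pts = {x for part, _ in view for iv in part for x in iv}
    return sorted(p for p in pts if p > 0 and math.isfinite(p))


class TestBuildTree:
    def test_designed_null_example_is_one_ternary_split(self, null_dist):
        tree = build_tree(null_dist)
        assert tree.depth == 1
        view = level_view(tree, 1)
        assert [round(s.dou, 10) for _, s in view] == [20.0, 10.0, 5.0]
        roles = [n.role for n in tree.root.children]
        assert roles == ["P", "Z", "N"]
        reasons = [n.terminal_reason for n in tree.root.children]
        assert reasons == ["uniform", "null_set", "singleton"]

    def test_binomial_terminates_at_singletons(self, binom84):
        tree = build_tree(binom84)
        for leaf in tree.leaves:
            assert leaf.terminal_reason in ("singleton", "uniform")
            if leaf.terminal_reason == "singleton":
                assert len(leaf.part) == 1
        singles = {next(iter(n.part)) for n in tree.leaves
                   if len(n.part) == 1}
        assert singles == set(range(9))

    def test_exponential_level2_breakpoints(self, exp2):
        tree = build_tree(exp2, config=TreeConfig(max_depth=2))
        bps = interior_breakpoints(level_view(tree, 2))
        assert [round(b, 2) for b in bps] == [0.21, 0.5, 1.0]
        # frozen from an independent quadrature oracle for the truncated
        # exponential on (0, 0.5): solve p(x) = c/D
        assert bps[0] == pytest.approx(0.2090116465653369, abs=1e-9)

    def test_root_part_may_be_a_sub_part(self, binom84):
        tree = build_tree(binom84, root_part=frozenset({0, 1, 5, 6, 7, 8}))
        assert tree.root.part == frozenset({0, 1, 5, 6, 7, 8})
        assert level_view(tree, 1)[0][0] == frozenset({0, 6, 7, 8})

    def test_zero_mass_root_rejected(self, binom84):
        with pytest.raises(DomainError):
            build_tree(binom84, root_part=frozenset())

    def test_min_mass_guard_stops_branches(self, exp2):
        tree = build_tree(exp2, config=TreeConfig(max_depth=5, min_mass=0.2))
        assert any(n.terminal_reason == "min_mass" for n in tree.nodes)

    def test_determinism(self, binom84):
        t1 = build_tree(binom84)
        t2 = build_tree(binom84)
        assert tree_to_json(t1) == tree_to_json(t2)


class TestLevelView:
    def test_binomial_level2_parts(self, binom84):
        view = level_view(build_tree(binom84), 2)
        assert [sorted(p) for p, _ in view] == \
            [[0, 6, 7, 8], [1, 5], [2, 4], [3]]

    def test_carried_null_keeps_position(self):
        """A Z-node created at level 1 stays in every deeper level view at
        its ordered position while its N sibling keeps splitting."""
        from divloc import make_distribution
        # designed so that the whole-distribution threshold c/D equals the
        # middle band exactly (solved numerically and frozen): four atoms
        # 0.05 (P, uniform), six atoms z (Z), and a non-uniform N {0.16, v}
        z = 0.08876129514100234
        v = 0.10743222915398595
        probs = [0.05] * 4 + [z] * 6 + [0.16, v]
        d = make_distribution(list(range(1, 13)), probs, tol=1e-12)
        tree = build_tree(d)
        assert tree.depth == 2
        z_node = next(n for n in tree.nodes if n.role == "Z")
        assert z_node.created_level == 1
        assert z_node.terminal_reason == "null_set"
        root_dou = tree.root.summary.dou
        assert z_node.summary.dou == pytest.approx(root_dou, rel=1e-9)
        for k in (1, 2):
            view = level_view(tree, k)
            dous = [s.dou for _, s in view]
            assert all(a > b for a, b in zip(dous, dous[1:]))
            # the carried Z sits second, after P's descendants
            assert frozenset(view[1][0]) == z_node.part

    def test_dou_strictly_decreasing_at_every_level(self, binom84, exp2):
        for tree in (build_tree(binom84),
                     build_tree(exp2, config=TreeConfig(max_depth=3))):
            for k in range(1, tree.depth + 1):
                dous = [s.dou for _, s in level_view(tree, k)]
                assert all(a > b for a, b in zip(dous, dous[1:]))

    def test_out_of_range_level_rejected(self, binom84):
        tree = build_tree(binom84)
        with pytest.raises(DomainError):
            level_view(tree, 0)
        with pytest.raises(DomainError):
            level_view(tree, tree.depth + 1)


class TestStructuralInvariants:
    def test_leaves_partition_root_mass(self, binom84, exp2):
        for source, cfg in ((binom84, TreeConfig()),
                            (exp2, TreeConfig(max_depth=3))):
            tree = build_tree(source, config=cfg)
            total = sum(n.summary.mass for n in tree.leaves)
            assert total == pytest.approx(tree.root.summary.mass, abs=1e-10)

    def test_leaf_parts_are_disjoint(self, binom84):
        tree = build_tree(binom84)
        seen = set()
        for leaf in tree.leaves:
            assert not (leaf.part & seen)
            seen |= leaf.part
        assert seen == binom84.support

    def test_geometric_mean_conservation_at_every_node(self, binom84):
        tree = build_tree(binom84)
        for node in tree.nodes:
            if node.is_terminal:
                continue
            lhs = node.summary.dou ** node.summary.mass
            rhs = 1.0
            for child in node.children:
                rhs *= child.summary.dou ** child.summary.mass
            assert lhs == pytest.approx(rhs, rel=1e-10)

    def test_parent_child_dou_ordering(self, binom84, null_dist):
        for source in (binom84, null_dist):
            tree = build_tree(source)
            for node in tree.nodes:
                for child in node.children:
                    if child.role == "P":
                        assert child.summary.dou > node.summary.dou
                    elif child.role == "N":
                        assert child.summary.dou < node.summary.dou
                    else:
                        assert child.summary.dou == pytest.approx(
                            node.summary.dou, rel=1e-9)


class TestAudit:
    def test_binomial_audit_clean(self, binom84):
        tree = build_tree(binom84)
        report = monotonicity_audit(tree, binom84, n_samples=200, seed=1)
        assert report.n_checked == 200
        assert report.n_violations == 0

    def test_null_example_audit_clean(self, null_dist):
        tree = build_tree(null_dist)
        report = monotonicity_audit(tree, null_dist, n_samples=100, seed=2)
        assert report.n_violations == 0

    def test_continuous_audit_clean(self, exp2):
        tree = build_tree(exp2, config=TreeConfig(max_depth=3))
        report = monotonicity_audit(tree, exp2, n_samples=100, seed=3)
        assert report.n_checked == 100
        assert report.n_violations == 0

    def test_trivial_tree_empty_report(self):
        from divloc import make_distribution
        u = make_distribution(["a"], [1.0])
        tree = build_tree(u)
        report = monotonicity_audit(tree, u, n_samples=50, seed=0)
        assert report.n_checked == 0 and report.n_violations == 0


class TestRatioReport:
    def test_designed_level1_ratios(self, null_dist):
        r = ratio_report(build_tree(null_dist), 1)
        assert r[0, 1] == pytest.approx(2.0, rel=1e-10)
        assert r[0, 2] == pytest.approx(4.0, rel=1e-10)
        assert r[1, 2] == pytest.approx(2.0, rel=1e-10)

    def test_reciprocal_and_diagonal_structure(self, binom84):
        r = ratio_report(build_tree(binom84), 2)
        assert np.allclose(np.diag(r), 1.0)
        assert np.allclose(r * r.T, 1.0)

    def test_extreme_ratio_matches_direct_recomputation(self, binom84):
        r = ratio_report(build_tree(binom84), 2)
        expected = summarize_part(binom84, {0, 6, 7, 8}).dou \
            / summarize_part(binom84, {3}).dou
        assert r[0, -1] == pytest.approx(expected, rel=1e-12)


class TestSerialization:
    def test_json_round_trip_is_bit_identical(self, binom84, exp2):
        for source, cfg in ((binom84, TreeConfig()),
                            (exp2, TreeConfig(max_depth=2))):
            tree = build_tree(source, config=cfg)
            text = tree_to_json(tree)
            assert tree_to_json(tree_from_json(text)) == text

    def test_ascii_render_mentions_all_roles(self, null_dist):
        art = render_ascii(build_tree(null_dist))
        for token in ("root", "P {", "Z {", "N {", "dou="):
            assert token in art
        art_counts = render_ascii(build_tree(null_dist), annotate="count")
        assert "n=6" in art_counts
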