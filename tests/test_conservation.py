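"""Pair/family conservation classification, filters, pruning, identities."""

import random

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from helixkink import (
    HomologyCandidate,
    KinkClass,
    classify_family,
    classify_pair,
    correlate_sites,
    family_most_disrupted,
    family_sequence_identity,
    filter_homologous_pair,
    neighbouring_sequence_identity,
    pair_most_disrupted,
    prune_family,
    sequence_identity,
    smooth_profile,
)
from helixkink.conservation import _proline_flag, angles_by_column
from helixkink.geometry import AngleProfile
from helixkink.synth import generate_ideal_helix

from .oracles import brute_family_scan, brute_smooth, rank_spearman, window_max


class TestHomologyFilter:
    def _cand(self, **kw):
        base = dict(
            chain_length_a=100,
            chain_length_b=120,
            tm_score=0.7,
            sequence_identity=0.4,
            helix_offset_n=1,
            helix_offset_c=2,
        )
        base.update(kw)
        return HomologyCandidate(**base)

    def test_identical_chains_accepted(self):
        c = self._cand(
            chain_length_b=100, tm_score=1.0, sequence_identity=1.0,
            helix_offset_n=0, helix_offset_c=0,
        )
        assert filter_homologous_pair(c)

    @pytest.mark.parametrize(
        "kw",
        [
            {"chain_length_a": 100, "chain_length_b": 160},  # >50% longer
            {"tm_score": 0.5},  # strict inequality
            {"sequence_identity": 0.09},
            {"helix_offset_n": 5},
            {"helix_offset_c": -5},
        ],
    )
    def test_each_criterion_rejects(self, kw):
        assert filter_homologous_pair(self._cand())
        assert not filter_homologous_pair(self._cand(**kw))

    def test_boundaries_inclusive(self):
        # exactly 50% longer, exactly 10% identity, exactly 4 offset: accepted
        c = self._cand(
            chain_length_a=100, chain_length_b=150,
            sequence_identity=0.10, helix_offset_n=4, helix_offset_c=-4,
        )
        assert filter_homologous_pair(c)

    def test_symmetric_in_chain_order(self):
        a = self._cand(chain_length_a=100, chain_length_b=160)
        b = self._cand(chain_length_a=160, chain_length_b=100)
        assert filter_homologous_pair(a) == filter_homologous_pair(b)


class TestPairMostDisrupted:
    def test_identical_profiles_match_at_same_column(self):
        angles = {5: 10.0, 6: 35.0, 7: 12.0}
        col_max, t_max, col_min, t_min = pair_most_disrupted(angles, dict(angles))
        assert (col_max, t_max) == (6, 35.0)
        assert (col_min, t_min) == (6, 35.0)

    def test_gapped_window_removes_pair(self):
        a = {10: 40.0}
        b = {20: 15.0}  # nothing within ±4 of column 10
        assert pair_most_disrupted(a, b) is None

    def test_window_max_matches_brute_force(self):
        a = {10: 35.0}
        b = {7: 12.0, 13: 18.0, 20: 25.0}
        col_max, t_max, _, t_min = pair_most_disrupted(a, b)
        assert (col_max, t_max) == (10, 35.0)
        assert t_min == 18.0 == window_max(b, 10, 4)

    def test_larger_angle_may_come_from_either_helix(self):
        a = {4: 10.0}
        b = {5: 30.0}
        col_max, t_max, col_min, t_min = pair_most_disrupted(a, b)
        assert (col_max, t_max) == (5, 30.0)
        assert (col_min, t_min) == (4, 10.0)

    def test_random_windows_match_brute_force(self, rng):
        for _ in range(50):
            cols_a = rng.choice(30, size=rng.integers(1, 8), replace=False)
            cols_b = rng.choice(30, size=rng.integers(1, 8), replace=False)
            a = {int(c): float(rng.uniform(0, 60)) for c in cols_a}
            b = {int(c): float(rng.uniform(0, 60)) for c in cols_b}
            hit = pair_most_disrupted(a, b)
            t_max = max(max(a.values()), max(b.values()))
            if t_max in a.values():
                c_max = next(c for c, v in a.items() if v == t_max)
                other = b
            else:
                c_max = next(c for c, v in b.items() if v == t_max)
                other = a
            expected_min = window_max(other, c_max, 4)
            if expected_min is None:
                assert hit is None
            else:
                assert hit == (c_max, t_max, hit[2], expected_min)


class TestClassifyPair:
    @pytest.mark.parametrize(
        "t_max, t_min, eps_sum, expected",
        [
            (15.0, 3.0, 99.0, KinkClass.CONSERVED_STRAIGHT),
            (30.0, 25.0, 9.0, KinkClass.CONSERVED_KINKED),
            (30.0, 20.5, 5.0, KinkClass.NOT_CONSERVED),
            (25.0, 15.0, 12.0, KinkClass.OTHER),  # straddles 20, not significant
            (25.0, 15.0, 8.0, KinkClass.NOT_CONSERVED),
            (19.99, 19.0, 0.0, KinkClass.CONSERVED_STRAIGHT),
            (20.0, 20.0, 1.0, KinkClass.OTHER),  # exactly at threshold
        ],
    )
    def test_rule_table(self, t_max, t_min, eps_sum, expected):
        assert classify_pair(t_max, t_min, eps_sum / 2, eps_sum / 2) == expected

    @given(
        t1=st.floats(0, 180),
        t2=st.floats(0, 180),
        e1=st.floats(0, 30),
        e2=st.floats(0, 30),
    )
    def test_total_partition_and_swap_symmetry(self, t1, t2, e1, e2):
        """Every input gets exactly one of the four classes, independent of
        which helix is listed first."""
        t_max, t_min = max(t1, t2), min(t1, t2)
        cls = classify_pair(t_max, t_min, e1, e2)
        assert cls in (
            KinkClass.CONSERVED_STRAIGHT,
            KinkClass.CONSERVED_KINKED,
            KinkClass.NOT_CONSERVED,
            KinkClass.OTHER,
        )
        assert classify_pair(t_max, t_min, e2, e1) == cls

    @given(
        t_max=st.floats(0, 180),
        delta=st.floats(0, 90),
        e1=st.floats(0, 30),
        e2=st.floats(0, 30),
    )
    def test_shrinking_errors_never_creates_conserved_kinked(self, t_max, delta, e1, e2):
        """With epsilon lowered to zero a pair can only become (or stay)
        significantly different, never newly conserved-kinked."""
        t_min = max(t_max - delta, 0.0)
        before = classify_pair(t_max, t_min, e1, e2)
        after = classify_pair(t_max, t_min, 0.0, 0.0)
        if before == KinkClass.NOT_CONSERVED:
            assert after in (KinkClass.NOT_CONSERVED, KinkClass.OTHER)
        if after == KinkClass.CONSERVED_KINKED:
            # only exactly equal angles stay CK at zero error
            assert t_max == t_min

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            classify_pair(10.0, 20.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            classify_pair(30.0, 10.0, -1.0, 1.0)


class TestSmoothing:
    def test_constant_profile_unchanged(self):
        angles = {c: 12.0 for c in range(5, 15)}
        sm = smooth_profile(angles)
        assert all(sm[c] == 12.0 for c in angles)

    def test_example_window_max(self):
        angles = {0: 10.0, 1: 30.0, 2: 12.0, 3: 5.0}
        sm = smooth_profile(angles)
        assert [sm[c] for c in range(4)] == [30.0, 30.0, 30.0, 12.0]

    def test_isolated_angle_extends_one_column(self):
        sm = smooth_profile({7: 22.0})
        assert sm == {6: 22.0, 7: 22.0, 8: 22.0}

    def test_never_decreases_defined_angles(self, rng):
        for _ in range(20):
            cols = rng.choice(40, size=10, replace=False)
            angles = {int(c): float(rng.uniform(0, 60)) for c in cols}
            sm = smooth_profile(angles)
            assert all(sm[c] >= v for c, v in angles.items())

    def test_matches_brute_force_on_random_profiles(self, rng):
        for _ in range(30):
            cols = rng.choice(50, size=rng.integers(1, 12), replace=False)
            angles = {int(c): float(rng.uniform(0, 60)) for c in cols}
            assert smooth_profile(angles) == brute_smooth(angles)


class TestFamilyMostDisrupted:
    def test_identical_kinked_profiles_pick_kink_column(self):
        prof = {3: 5.0, 4: 35.0, 5: 6.0}
        assert family_most_disrupted([dict(prof) for _ in range(6)]) == 4

    def test_minimum_count_rule(self):
        """A 50-degree column seen 4 times loses to a 30-degree column seen 6
        times: under-observed sites are ineligible."""
        members = []
        for i in range(6):
            m = {10: 30.0}
            if i < 4:
                m[20] = 50.0
            members.append(m)
        assert family_most_disrupted(members) == 10

    def test_no_eligible_column_raises(self):
        with pytest.raises(ValueError):
            family_most_disrupted([{1: 10.0}] * 3)

    def test_tie_goes_to_smallest_column(self):
        members = [{2: 30.0, 8: 30.0} for _ in range(5)]
        assert family_most_disrupted(members) == 2

    def test_random_families_match_brute_scan(self, rng):
        for _ in range(30):
            members = []
            for _ in range(8):
                cols = rng.choice(15, size=rng.integers(3, 10), replace=False)
                members.append({int(c): float(rng.uniform(0, 50)) for c in cols})
            try:
                got = family_most_disrupted(members)
            except ValueError:
                got = None
            assert got == brute_family_scan(members)


class TestClassifyFamily:
    def test_tight_kinked_family(self):
        thetas = [39.0, 40.0, 41.0, 40.5, 39.5]
        cls, med, sigma, mu = classify_family(thetas, [8.0] * 5)
        assert cls == KinkClass.CONSERVED_KINKED
        assert med == 40.0 and sigma < 1.0 and mu == 8.0

    def test_wide_spread_not_conserved(self):
        thetas = [5.0, 10.0, 40.0, 45.0, 50.0]
        cls, _, sigma, mu = classify_family(thetas, [7.0] * 5)
        assert sigma == pytest.approx(np.std(thetas, ddof=1))
        assert sigma > mu
        assert cls == KinkClass.NOT_CONSERVED

    def test_straight_family(self):
        cls, *_ = classify_family([3.0, 5.0, 8.0, 4.0, 6.0], [8.0] * 5)
        assert cls == KinkClass.CONSERVED_STRAIGHT

    def test_tie_goes_to_conserved_side(self):
        # sigma == mu_eps exactly (both zero): conserved, not NotConserved
        cls, *_ = classify_family([40.0] * 5, [0.0] * 5)
        assert cls == KinkClass.CONSERVED_KINKED
        cls, *_ = classify_family([5.0] * 5, [0.0] * 5)
        assert cls == KinkClass.CONSERVED_STRAIGHT

    def test_wide_spread_all_under_threshold_is_other(self):
        thetas = [1.0, 5.0, 10.0, 15.0, 19.0]
        cls, *_ = classify_family(thetas, [1.0] * 5)
        assert cls == KinkClass.OTHER

    def test_minimum_membership(self):
        with pytest.raises(ValueError):
            classify_family([30.0] * 4, [5.0] * 4)


class TestPruneFamily:
    def test_complete_graph_fully_retained(self):
        nodes = [f"n{i}" for i in range(6)]
        edges = [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1:]]
        assert prune_family(nodes, edges) == sorted(nodes)

    def test_low_connectivity_member_removed(self):
        """One member connected to 3/5 others is pruned; the remaining
        complete five survive as a family."""
        core = [f"n{i}" for i in range(5)]
        edges = [(a, b) for i, a in enumerate(core) for b in core[i + 1:]]
        edges += [("x", "n0"), ("x", "n1"), ("x", "n2")]
        assert prune_family(core + ["x"], edges) == sorted(core)

    def test_family_below_five_discarded(self):
        nodes = ["a", "b", "c", "d"]
        edges = [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1:]]
        assert prune_family(nodes, edges) == []

    def test_iterative_removal_cascades(self):
        # chain graph: everything is low-connectivity; all pruned away
        nodes = [f"c{i}" for i in range(6)]
        edges = list(zip(nodes, nodes[1:]))
        assert prune_family(nodes, edges) == []

    def test_order_independence(self, rng):
        nodes = [f"m{i}" for i in range(10)]
        edges = [
            (a, b)
            for i, a in enumerate(nodes)
            for b in nodes[i + 1:]
            if rng.random() < 0.85
        ]
        ref = prune_family(nodes, edges)
        for seed in range(5):
            shuffled_nodes = list(nodes)
            shuffled_edges = [tuple(reversed(e)) if seed % 2 else e for e in edges]
            random.Random(seed).shuffle(shuffled_nodes)
            random.Random(seed).shuffle(shuffled_edges)
            assert prune_family(shuffled_nodes, shuffled_edges) == ref


class TestSequenceIdentity:
    def test_identical_sequences(self):
        assert sequence_identity("ACDEF", "ACDEF") == 1.0

    def test_gap_columns_ignored(self):
        assert sequence_identity("ACDEF", "ACD-F") == 1.0

    def test_column_subset(self):
        assert sequence_identity("AAAA", "AATT", columns=[0, 2]) == 0.5

    def test_all_gap_overlap_is_missing(self):
        assert sequence_identity("A--", "-AA") is None

    def test_family_mean_of_pairs(self):
        seqs = {"s1": "AAAA", "s2": "AAAA", "s3": "AACC"}
        assert family_sequence_identity(seqs) == pytest.approx(2 / 3)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            sequence_identity("AA", "AAA")


class TestNeighbouringIdentity:
    @staticmethod
    def _bundle(mutate=False):
        """Chain: a 14-residue helix plus a 6-residue segment packed at 7 Å."""
        helix = generate_ideal_helix(14)
        partner = generate_ideal_helix(6).transformed(np.eye(3), np.array([7.0, 0.0, 6.0]))
        names = ["ALA"] * 14 + ["LEU"] * 6
        if mutate:
            names[16] = "TRP"
        import helixkink.structures as hs

        ids = [str(i + 1) for i in range(20)]
        coords = np.concatenate([helix.coords, partner.coords])
        bb = hs.HelixBackbone("bundle", "A", ids, coords, names)
        return bb.to_gemmi()

    def test_identical_structure_identity_one(self):
        st = self._bundle()
        aln = "A" * 14 + "L" * 6
        val = neighbouring_sequence_identity(
            st, "A", (0, 13), aln, st, "A", (0, 13), aln
        )
        assert val == 1.0

    def test_single_mutation_counted(self):
        """One mutated contacting residue lowers identity by exactly one
        neighbour column (oracle: plain-loop contact count)."""
        st_a, st_b = self._bundle(), self._bundle(mutate=True)
        aln_a = "A" * 14 + "L" * 6
        aln_b = "A" * 14 + "L" * 2 + "W" + "L" * 3
        # brute-force neighbour set: residues 14..19 with any atom within 4 Å
        helix_atoms = np.array(
            [[a.pos.x, a.pos.y, a.pos.z] for r in list(st_a[0]["A"])[:14] for a in r]
        )
        neighbours = []
        for i, res in enumerate(list(st_a[0]["A"])[14:], start=14):
            xyz = np.array([[a.pos.x, a.pos.y, a.pos.z] for a in res])
            d = np.linalg.norm(helix_atoms[:, None] - xyz[None], axis=2)
            if (d <= 4.0).any():
                neighbours.append(i)
        assert 16 in neighbours and len(neighbours) >= 2
        expected = (len(neighbours) - 1) / len(neighbours)
        val = neighbouring_sequence_identity(
            st_a, "A", (0, 13), aln_a, st_b, "A", (0, 13), aln_b
        )
        assert val == pytest.approx(expected)

    def test_no_contacts_is_missing(self):
        helix = generate_ideal_helix(14)
        import helixkink.structures as hs

        far = generate_ideal_helix(6).transformed(np.eye(3), np.array([50.0, 0.0, 0.0]))
        ids = [str(i + 1) for i in range(20)]
        coords = np.concatenate([helix.coords, far.coords])
        st = hs.HelixBackbone("b", "A", ids, coords).to_gemmi()
        aln = "A" * 20
        assert (
            neighbouring_sequence_identity(st, "A", (0, 13), aln, st, "A", (0, 13), aln)
            is None
        )


class TestCorrelateSites:
    def test_perfectly_monotone(self):
        i = {f"m{k}": float(k) for k in range(6)}
        j = {f"m{k}": float(k**2) for k in range(6)}
        assert correlate_sites(i, j) == pytest.approx(1.0)

    def test_anti_monotone(self):
        i = {f"m{k}": float(k) for k in range(6)}
        j = {f"m{k}": float(-k) for k in range(6)}
        assert correlate_sites(i, j) == pytest.approx(-1.0)

    def test_toy_table_matches_rank_formula(self):
        x = [12.0, 30.0, 25.0, 8.0, 40.0, 25.0]
        y = [10.0, 28.0, 20.0, 15.0, 35.0, 22.0]
        i = {f"m{k}": v for k, v in enumerate(x)}
        j = {f"m{k}": v for k, v in enumerate(y)}
        assert correlate_sites(i, j) == pytest.approx(rank_spearman(x, y))

    def test_members_without_both_values_dropped(self):
        i = {f"m{k}": float(k) for k in range(7)}
        j = {f"m{k}": float(k) for k in range(2, 9)}
        assert correlate_sites(i, j) == pytest.approx(1.0)

    def test_too_few_paired_observations(self):
        i = {"a": 1.0, "b": 2.0}
        j = {"a": 1.0, "b": 2.0}
        with pytest.raises(ValueError):
            correlate_sites(i, j)


class TestProlineFlagAndColumns:
    def test_angles_mapped_through_gaps(self):
        prof = AngleProfile(
            "h", np.array([5, 6]), ["6", "7"], np.array([10.0, 20.0]),
            np.zeros(2), np.zeros(2), np.zeros(2),
        )
        aligned = "AB-CDEFGH"  # residue 5 -> column 6, residue 6 -> column 7
        assert angles_by_column(prof, aligned) == {6: 10.0, 7: 20.0}

    def test_proline_within_following_four_residues(self):
        #       0123456789
        seq = "AAAA-AAPAA"
        assert _proline_flag(seq, 3)  # residues 3..7 -> A A A P (skips gap)
        assert not _proline_flag(seq, 8)
        assert _proline_flag(seq, 7)
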