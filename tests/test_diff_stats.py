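import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from exocipn.diff_stats import (
    DIRECTION_G1,
    DIRECTION_G2,
    DIRECTION_TIED,
    Signature,
    bh_adjust,
    combine_tracks,
    direction_tally,
    mann_whitney,
    normalize,
    pca_separation,
    run_track,
    signature_directions,
)
from exocipn.quantify import QuantMatrix, TRACK_PROTEIN


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def enumeration_mw_p(a, b):
    """Exact two-sided p by enumerating every assignment of pooled ranks."""
    pooled = sorted(a) + sorted(b)
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    n_a, n_b = len(a), len(b)

    def u_stat(xs, ys):
        return sum(1 for x in xs for y in ys if x > y)

    u_obs = u_stat(a, b)
    us = []
    values = sorted(pooled)
    for idx in itertools.combinations(range(n_a + n_b), n_a):
        xs = [values[i] for i in idx]
        ys = [values[i] for i in range(n_a + n_b) if i not in set(idx)]
        us.append(u_stat(xs, ys))
    us = np.array(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(p, 1.0)


def suffix_min_bh(p):
    """Brute-force BH: q(i) = min over j >= i (sorted) of m * p(j) / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    sp = p[order]
    q_sorted = [
        min(min(m * sp[j] / (j + 1) for j in range(i, m)), 1.0)
        for i in range(m)
    ]
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def make_qm(values, groups=("group1_cipn", "group2_stable"), timepoint="T0"):
    values = pd.DataFrame(
        np.asarray(values),
        index=[f"F{i}" for i in range(len(values))],
        columns=[f"S{j}:{timepoint}" for j in range(len(values[0]))],
    )
    n = values.shape[1]
    samples = pd.DataFrame(
        {
            "sample_id": [f"S{j}" for j in range(n)],
            "timepoint": [timepoint] * n,
            "group": [groups[j % 2] if isinstance(groups, tuple) else groups[j]
                      for j in range(n)],
        },
        index=values.columns,
    )
    return QuantMatrix(TRACK_PROTEIN, values.astype(np.int64), samples)


class TestNormalize:
    def test_doubled_column_of_same_composition_becomes_identical(self):
        qm = make_qm([[1, 2], [2, 4], [3, 6]])
        norm = normalize(qm)
        np.testing.assert_allclose(
            norm.values.iloc[:, 0], norm.values.iloc[:, 1]
        )
        # hand check: both columns scale to the median total 9
        expected = np.log1p(np.array([1.5, 3.0, 4.5]))
        np.testing.assert_allclose(norm.values.iloc[:, 0], expected)

    def test_identical_columns_stay_identical(self):
        qm = make_qm([[3, 3, 3], [1, 1, 1]], groups=(
            "group1_cipn", "group1_cipn", "group2_stable"))
        norm = normalize(qm)
        assert norm.normalized
        np.testing.assert_allclose(
            norm.values.iloc[:, 0], norm.values.iloc[:, 2]
        )

    def test_all_zero_column_names_the_sample(self):
        values = pd.DataFrame(
            [[1, 0], [2, 0]], index=["A", "B"], columns=["S0:T0", "S1:T0"]
        )
        samples = pd.DataFrame(
            {
                "sample_id": ["S0", "S1"],
                "timepoint": ["T0", "T0"],
                "group": ["group1_cipn", "group2_stable"],
            },
            index=values.columns,
        )
        qm = QuantMatrix(TRACK_PROTEIN, values, samples)
        with pytest.raises(ValueError, match="S1:T0"):
            normalize(qm)


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------


class TestMannWhitney:
    def test_separated_triples(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.10)

    def test_identical_multisets_give_p_one(self):
        _, p = mann_whitney([1, 2, 3], [3, 1, 2])
        assert p == pytest.approx(1.0)

    def test_fully_degenerate_input_flagged(self):
        with pytest.warns(UserWarning, match="identical"):
            u, p = mann_whitney([2.0, 2.0], [2.0, 2.0, 2.0])
        assert p == 1.0
        assert u == 3.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    @given(
        n_a=st.integers(2, 5),
        n_b=st.integers(2, 5),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=50)
    def test_exact_mode_matches_enumeration(self, n_a, n_b, seed):
        rng = np.random.default_rng(seed)
        vals = rng.permutation(np.arange(n_a + n_b, dtype=float))
        a, b = vals[:n_a], vals[n_a:]
        _, p = mann_whitney(a, b, mode="exact")
        assert p == pytest.approx(enumeration_mw_p(list(a), list(b)), abs=1e-12)

    def test_study_scale_exact_matches_permutation_oracle(self):
        rng = np.random.default_rng(17)
        vals = rng.normal(size=17)
        a, b = vals[:8], vals[8:]
        _, p = mann_whitney(a, b, mode="auto")  # tie-free: exact at 8 vs 9
        assert p == pytest.approx(enumeration_mw_p(list(a), list(b)), abs=1e-9)


class TestBhAdjust:
    def test_single_p_is_identity(self):
        np.testing.assert_allclose(bh_adjust([0.05]), [0.05])

    def test_hand_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.005, 0.01, 0.03, 0.04]), [0.02, 0.02, 0.04, 0.04]
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @given(seed=st.integers(0, 10_000), m=st.integers(1, 60))
    @settings(max_examples=100)
    def test_matches_suffix_min_oracle(self, seed, m):
        rng = np.random.default_rng(seed)
        p = rng.random(m)
        np.testing.assert_allclose(bh_adjust(p), suffix_min_bh(p), atol=1e-12)

    def test_monotone_in_p_ordering(self):
        rng = np.random.default_rng(0)
        p = rng.random(100)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


# ---------------------------------------------------------------------------
# run_track
# ---------------------------------------------------------------------------


class TestRunTrack:
    def planted_matrix(self, seed=0):
        rng = np.random.default_rng(seed)
        n1, n2 = 8, 9
        base = rng.poisson(30, size=(30, n1 + n2))
        base[:3, n1:] *= 4  # three features elevated in group 2
        groups = ["group1_cipn"] * n1 + ["group2_stable"] * n2
        return make_qm(base.tolist(), groups=groups)

    def test_planted_features_recovered_with_direction(self):
        qm = self.planted_matrix()
        res = run_track(qm, "T0", 0.3)
        assert {"F0", "F1", "F2"} <= res.selected
        sub = res.results.set_index("feature")
        assert (
            sub.loc[["F0", "F1", "F2"], "direction"] == DIRECTION_G2
        ).all()

    def test_zero_threshold_selects_nothing(self):
        res = run_track(self.planted_matrix(), "T0", 0.0)
        assert res.selected == frozenset()

    def test_q_values_bounded_and_monotone(self):
        res = run_track(self.planted_matrix(), "T0", 0.3).results
        assert ((res["q_value"] >= res["p_value"] - 1e-12)).all()
        order = res.sort_values("p_value")
        assert (np.diff(order["q_value"]) >= -1e-12).all()

    def test_single_sample_group_rejected(self):
        groups = ["group1_cipn"] + ["group2_stable"] * 3
        qm = make_qm([[1, 2, 3, 4], [4, 3, 2, 1]], groups=groups)
        with pytest.raises(ValueError, match=">= 2 samples"):
            run_track(qm, "T0", 0.3)

    def test_missing_timepoint_rejected(self):
        with pytest.raises(ValueError, match="T12"):
            run_track(self.planted_matrix(), "T12", 0.3)


# ---------------------------------------------------------------------------
# Signatures
# ---------------------------------------------------------------------------


class TestSignature:
    def test_union_and_overlap(self):
        sig = combine_tracks({"A", "B", "C"}, {"B", "C", "D", "E"})
        assert sig.combined == {"A", "B", "C", "D", "E"}
        assert sig.overlap == {"B", "C"}

    def test_disjoint_sets(self):
        sig = combine_tracks({"A", "B", "C"}, {"D", "E", "F", "G"})
        assert len(sig.combined) == 7
        assert len(sig.overlap) == 0

    def test_subset_collapses_to_superset(self):
        sig = combine_tracks({"A"}, {"A", "B"})
        assert sig.combined == {"A", "B"}

    @given(
        a=st.sets(st.integers(0, 30), max_size=20),
        b=st.sets(st.integers(0, 30), max_size=20),
    )
    def test_inclusion_exclusion_exact(self, a, b):
        sig = combine_tracks({str(x) for x in a}, {str(x) for x in b})
        sizes = sig.sizes()
        assert sizes["combined"] == (
            sizes["protein_track"] + sizes["peptide_track"] - sizes["overlap"]
        )


class TestDirectionTally:
    def sig(self, members):
        return combine_tracks(set(members), set())

    def test_all_higher_in_group2(self):
        directions = {m: DIRECTION_G2 for m in "ABC"}
        assert direction_tally(directions, self.sig("ABC")) == (0, 3, 0)

    def test_tied_counted_separately(self):
        directions = {"A": DIRECTION_G1, "B": DIRECTION_TIED}
        assert direction_tally(directions, self.sig("AB")) == (1, 0, 1)

    def test_counts_sum_to_signature_size(self):
        directions = {"A": DIRECTION_G1, "B": DIRECTION_G2, "C": DIRECTION_G2}
        assert sum(direction_tally(directions, self.sig("ABC"))) == 3

    def test_missing_member_rejected(self):
        with pytest.raises(ValueError, match="C"):
            direction_tally({"A": DIRECTION_G1}, self.sig("AC"))

    def test_protein_track_direction_preferred(self):
        protein = pd.DataFrame(
            {"feature": ["A"], "direction": [DIRECTION_G1]}
        )
        rolled = pd.DataFrame(
            {"feature": ["A", "B"], "direction": [DIRECTION_G2, DIRECTION_G2]}
        )
        directions = signature_directions(protein, rolled)
        assert directions == {"A": DIRECTION_G1, "B": DIRECTION_G2}


# ---------------------------------------------------------------------------
# PCA separation
# ---------------------------------------------------------------------------


class TestPcaSeparation:
    def clusters(self, gap=10.0, noise=0.1, seed=0):
        rng = np.random.default_rng(seed)
        g1 = rng.normal(0, noise, size=(5, 4))
        g2 = rng.normal(gap, noise, size=(5, 4))
        values = pd.DataFrame(
            np.hstack([g1, g2]),
            index=[f"F{i}" for i in range(5)],
            columns=[f"S{j}:T0" for j in range(8)],
        )
        labels = {
            f"S{j}:T0": ("group1_cipn" if j < 4 else "group2_stable")
            for j in range(8)
        }
        return values, labels

    def test_tight_distant_clusters_have_high_index(self):
        values, labels = self.clusters()
        _, index = pca_separation(values, labels)
        assert index > 2

    def test_permuted_labels_reduce_separation(self):
        values, labels = self.clusters()
        _, clustered = pca_separation(values, labels)
        keys = list(labels)
        rng = np.random.default_rng(1)
        perm_indices = []
        for _ in range(20):
            perm = rng.permutation(list(labels.values()))
            while len(set(perm[:4])) == 1:  # skip re-drawing the true split
                perm = rng.permutation(list(labels.values()))
            _, idx = pca_separation(values, dict(zip(keys, perm)))
            perm_indices.append(idx)
        assert np.median(perm_indices) < clustered / 2

    def test_identical_samples_rejected(self):
        values = pd.DataFrame(
            np.ones((3, 4)),
            index=["F0", "F1", "F2"],
            columns=[f"S{j}:T0" for j in range(4)],
        )
        labels = {
            f"S{j}:T0": ("group1_cipn" if j < 2 else "group2_stable")
            for j in range(4)
        }
        with pytest.raises(ValueError, match="identical"):
            pca_separation(values, labels)

    def test_rank_one_data_fall_back_to_1d(self):
        base = np.array([0.0, 1.0, 2.0, 3.0])
        values = pd.DataFrame(
            np.vstack([base, 2 * base]),
            index=["F0", "F1"],
            columns=[f"S{j}:T0" for j in range(4)],
        )
        labels = {
            f"S{j}:T0": ("group1_cipn" if j < 2 else "group2_stable")
            for j in range(4)
        }
        with pytest.warns(UserWarning, match="rank"):
            scores, index = pca_separation(values, labels)
        assert (scores["pc2"] == 0).all()
        assert index > 0
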