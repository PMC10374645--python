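"""Ecotype discovery: binary matrix, gated Jaccard, clustering oracles."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from ecotyping import synthetic
from ecotyping.containers import EcotypingError, InputError
from ecotyping.ecotypes import (
    assign_ecotypes,
    build_assignment_matrix,
    cluster_states,
    discover_ecotypes,
    filter_jaccard,
    jaccard_matrix,
    overlap_significance,
)


def _bam(assignments):
    return build_assignment_matrix(
        {ct: pd.Series(v) for ct, v in assignments.items()}
    )


HAND = {
    "T1": {"p1": 0, "p2": 0, "p3": 1},
    "T2": {"p1": 1, "p2": 0, "p3": 0},
}


class TestAssignmentMatrix:
    def test_hand_written(self):
        bam = _bam(HAND)
        expect = pd.DataFrame(
            [[1, 1, 0], [0, 0, 1], [0, 1, 1], [1, 0, 0]],
            index=["T1::0", "T1::1", "T2::0", "T2::1"],
            columns=["p1", "p2", "p3"],
        )
        pd.testing.assert_frame_equal(bam.A, expect)

    def test_column_sums_count_assigned_types(self):
        bam = _bam(HAND)
        assert (bam.A.sum(axis=0) == 2).all()

    def test_row_sums_match_state_tallies(self, small_truth):
        assigns = {c: small_truth.states_of(c) for c in small_truth.cell_types}
        bam = _bam(assigns)
        for rid in bam.state_ids:
            ct, st = rid.split("::")
            expect = int((assigns[ct] == int(st)).sum())
            assert bam.A.loc[rid].sum() == expect

    def test_single_type_rejected(self):
        with pytest.raises(InputError):
            _bam({"T1": HAND["T1"]})

    def test_missing_sample_recorded(self):
        bam = _bam({"T1": {"p1": 0, "p2": 0}, "T2": {"p1": 1, "p2": 0, "p3": 0}})
        assert bam.unassigned == {"T1": ["p3"]}
        assert bam.A.loc[["T1::0"], "p3"].sum() == 0


class TestJaccard:
    def test_hand_counts(self):
        A = pd.DataFrame(
            [[1, 1, 0, 0], [1, 0, 1, 0]],
            index=["T1::0", "T2::0"],
            columns=list("abcd"),
        )
        bam = type("B", (), {})()
        bam.A = A
        bam.state_ids = list(A.index)
        J = jaccard_matrix(bam)
        assert J.loc["T1::0", "T2::0"] == pytest.approx(1 / 3)

    def test_identical_and_disjoint(self):
        A = pd.DataFrame(
            [[1, 1, 0], [1, 1, 0], [0, 0, 1]],
            index=["T1::0", "T2::0", "T2::1"],
            columns=list("abc"),
        )
        bam = type("B", (), {})()
        bam.A = A
        bam.state_ids = list(A.index)
        J = jaccard_matrix(bam)
        assert J.loc["T1::0", "T2::0"] == 1.0
        assert J.loc["T1::0", "T2::1"] == 0.0
        assert np.allclose(np.diag(J), 1.0)


def _hypergeom_oracle(N, K, n, x):
    """P(overlap >= x) by direct enumeration of the hypergeometric pmf."""
    total = comb(N, n)
    return sum(
        comb(K, i) * comb(N - K, n - i)
        for i in range(x, min(K, n) + 1)
    ) / total


class TestOverlapSignificance:
    def test_full_overlap_small_case(self):
        # 10 samples, two states of 5 each, perfectly overlapping
        t1 = {f"p{i}": (0 if i < 5 else 1) for i in range(10)}
        t2 = {f"p{i}": (0 if i < 5 else 1) for i in range(10)}
        bam = _bam({"T1": t1, "T2": t2})
        P = overlap_significance(bam)
        assert P.loc["T1::0", "T2::0"] == pytest.approx(1 / 252, abs=1e-12)

    def test_zero_overlap_p_is_one(self):
        t1 = {f"p{i}": (0 if i < 5 else 1) for i in range(10)}
        t2 = {f"p{i}": (1 if i < 5 else 0) for i in range(10)}
        bam = _bam({"T1": t1, "T2": t2})
        P = overlap_significance(bam)
        assert P.loc["T1::0", "T2::0"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 21))
        t1 = {f"p{i}": int(rng.integers(0, 2)) for i in range(n)}
        t2 = {f"p{i}": int(rng.integers(0, 3)) for i in range(n)}
        bam = _bam({"T1": t1, "T2": t2})
        P = overlap_significance(bam)
        A = bam.A
        for i in bam.state_ids:
            for k in bam.state_ids:
                if i.split("::")[0] == k.split("::")[0]:
                    continue
                ni = int(A.loc[i].sum())
                nk = int(A.loc[k].sum())
                x = int((A.loc[i] & A.loc[k]).sum())
                oracle = _hypergeom_oracle(n, nk, ni, x)
                assert P.loc[i, k] == pytest.approx(oracle, abs=1e-12)


class TestFilterJaccard:
    def _setup(self):
        ids = ["T1::0", "T1::1", "T2::0"]
        J = pd.DataFrame(
            [[1.0, 0.0, 0.4], [0.0, 1.0, 0.2], [0.4, 0.2, 1.0]],
            index=ids, columns=ids,
        )
        P = pd.DataFrame(
            [[0.0, 1.0, 1e-6], [1.0, 0.0, 0.5], [1e-6, 0.5, 0.0]],
            index=ids, columns=ids,
        )
        types = pd.Series({"T1::0": "T1", "T1::1": "T1", "T2::0": "T2"})
        return J, P, types

    def test_gate_zeroes_nonsignificant(self):
        J, P, t = self._setup()
        G = filter_jaccard(J, P, t)
        assert G.loc["T1::1", "T2::0"] == 0.0

    def test_significant_pass_through(self):
        J, P, t = self._setup()
        G = filter_jaccard(J, P, t)
        assert G.loc["T1::0", "T2::0"] == pytest.approx(0.4)

    def test_alpha_one_keeps_cross_type_values(self):
        J, P, t = self._setup()
        G = filter_jaccard(J, P, t, alpha=1.0)
        assert G.loc["T1::1", "T2::0"] == pytest.approx(0.2)

    def test_same_type_always_zeroed(self):
        J, P, t = self._setup()
        G = filter_jaccard(J, P, t, alpha=1.0)
        assert G.loc["T1::0", "T1::1"] == 0.0
        assert np.allclose(np.diag(G), 1.0)

    def test_literal_gate_inverts(self):
        J, P, t = self._setup()
        G = filter_jaccard(J, P, t, gate="literal")
        assert G.loc["T1::0", "T2::0"] == 0.0
        assert G.loc["T1::1", "T2::0"] == 1.0

    def test_gated_never_exceeds_raw(self):
        J, P, t = self._setup()
        G = filter_jaccard(J, P, t)
        off = ~np.eye(3, dtype=bool)
        assert (G.to_numpy()[off] <= J.to_numpy()[off] + 1e-12).all()


def _brute_silhouette(D, labels):
    n = len(labels)
    vals = []
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            vals.append(0.0)
            continue
        a = np.mean([D[i, j] for j in same])
        b = min(
            np.mean([D[i, j] for j in range(n) if labels[j] == lab])
            for lab in set(labels)
            if lab != labels[i]
        )
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))


class TestClusterStates:
    def test_two_perfect_blocks(self):
        ids = [f"T{i}::0" for i in range(6)]
        J = np.zeros((6, 6))
        J[:3, :3] = 1.0
        J[3:, 3:] = 1.0
        G = pd.DataFrame(J, index=ids, columns=ids)
        ecomap, sil, k = cluster_states(G)
        assert k == 2
        assert sil[2] == pytest.approx(1.0)
        assert len(set(ecomap[:3])) == 1 and len(set(ecomap[3:])) == 1

    def test_silhouette_matches_bruteforce(self):
        rng = np.random.default_rng(3)
        ids = [f"T{i}::0" for i in range(6)]
        J = rng.uniform(0, 1, (6, 6))
        J = (J + J.T) / 2
        np.fill_diagonal(J, 1.0)
        G = pd.DataFrame(J, index=ids, columns=ids)
        ecomap, sil, _ = cluster_states(G)
        from scipy.cluster.hierarchy import average, fcluster
        from scipy.spatial.distance import squareform

        D = 1 - J
        np.fill_diagonal(D, 0)
        Z = average(squareform(D, checks=False))
        for k, s in sil.items():
            lab = fcluster(Z, t=k, criterion="maxclust")
            assert s == pytest.approx(_brute_silhouette(D, lab), abs=1e-12)

    def test_too_few_states_rejected(self):
        ids = ["T1::0", "T2::0", "T3::0"]
        G = pd.DataFrame(np.eye(3), index=ids, columns=ids)
        with pytest.raises(InputError):
            cluster_states(G)


class TestAssignEcotypes:
    def test_single_ecotype_everything_one(self):
        ecomap = pd.Series(
            {"T1::0": "E1", "T2::0": "E1", "T3::0": "E1", "T1::1": "E2"}
        )
        ab = {
            t: pd.DataFrame(
                np.full((2, 4), 0.5), index=["0", "1"], columns=list("abcd")
            )
            for t in ("T1", "T2", "T3")
        }
        cleaned, abundance, dominant, dismissed = assign_ecotypes(ecomap, ab)
        assert list(abundance.columns) == ["E1"]
        assert np.allclose(abundance.to_numpy(), 1.0)
        assert ("E2", "only 1 states") in dismissed

    def test_dominant_follows_member_abundance(self):
        ecomap = pd.Series(
            {
                "T1::0": "E1", "T2::0": "E1", "T3::0": "E1",
                "T1::1": "E2", "T2::1": "E2", "T3::1": "E2",
            }
        )
        rows = {"0": [0.9, 0.1], "1": [0.1, 0.9]}
        ab = {
            t: pd.DataFrame(rows, index=["a", "b"]).T for t in ("T1", "T2", "T3")
        }
        _, abundance, dominant, _ = assign_ecotypes(ecomap, ab)
        assert dominant["a"] == "E1" and dominant["b"] == "E2"
        assert np.allclose(abundance.sum(axis=1), 1.0)

    def test_all_dismissed_raises(self):
        ecomap = pd.Series({"T1::0": "E1", "T2::0": "E2", "T3::0": "E3"})
        ab = {
            t: pd.DataFrame(
                [[1.0, 1.0]], index=["0"], columns=["a", "b"]
            )
            for t in ("T1", "T2", "T3")
        }
        with pytest.raises(EcotypingError, match="dismissed"):
            assign_ecotypes(ecomap, ab)


class TestPlantedCommunities:
    @pytest.fixture(scope="class")
    def community_truth(self):
        # one distinct state per type per community: every community is a
        # full three-state set
        return synthetic.generate_truth(
            450, ["A", "B", "C"], {"A": 3, "B": 3, "C": 3},
            n_markers_per_state=30, n_communities=3,
            community_noise_rate=0.1, n_samples=200, seed=13,
        )

    def test_planted_communities_recovered(self, community_truth):
        from sklearn.metrics import adjusted_rand_score

        truth = community_truth
        assigns = {c: truth.states_of(c) for c in truth.cell_types}
        model = discover_ecotypes(assigns)
        assert model.chosen_k == 3
        comm = [truth.sample_community[s] for s in model.dominant.index]
        assert adjusted_rand_score(comm, model.dominant.to_numpy()) >= 0.9

    def test_dominant_invariant_to_sample_order(self, community_truth):
        truth = community_truth
        assigns = {c: truth.states_of(c) for c in truth.cell_types}
        model = discover_ecotypes(assigns)
        flipped = {
            c: s.iloc[::-1] for c, s in assigns.items()
        }
        model2 = discover_ecotypes(flipped)
        common = model.dominant.index
        assert (model.dominant == model2.dominant.loc[common]).all()
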