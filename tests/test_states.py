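"""Consensus-NMF state discovery: oracles, invariants and planted recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from ecotyping import deconvolution, states, synthetic
from ecotyping.containers import InputError, PurifiedExpression


def _purified(values: np.ndarray, cell_type="T"):
    df = pd.DataFrame(
        values,
        index=[f"g{i}" for i in range(values.shape[0])],
        columns=[f"s{j}" for j in range(values.shape[1])],
    )
    levels = pd.DataFrame({cell_type: df.mean(axis=1), "other": 0.0})
    return PurifiedExpression(
        cell_type=cell_type,
        values=df,
        fitted_levels=levels,
        reliability=pd.Series(True, index=df.index),
    )


class TestNonnegTransform:
    def test_positive_negative_split_definition(self):
        # a two-sample gene standardizes to (1, -1): split is ((1,0),(0,1))
        vals = np.array([[10.0, 1.0]] * 12)
        vals += np.arange(12)[:, None]  # distinct rows, same pattern
        feats = states.nonneg_transform(_purified(vals))
        row_p = feats.values.loc["g0+"].to_numpy()
        row_n = feats.values.loc["g0-"].to_numpy()
        assert row_p == pytest.approx([1.0, 0.0])
        assert row_n == pytest.approx([0.0, 1.0])

    def test_split_reconstructs_zscore(self, rng):
        vals = rng.uniform(0, 50, size=(20, 15))
        feats = states.nonneg_transform(_purified(vals))
        half = len(feats.genes)
        z = (
            feats.values.iloc[:half].to_numpy()
            - feats.values.iloc[half:].to_numpy()
        )
        logv = np.log2(vals + 1)
        expect = (logv - logv.mean(axis=1, keepdims=True)) / logv.std(
            axis=1, keepdims=True
        )
        assert np.abs(z - expect).max() < 1e-12

    def test_constant_gene_dropped(self, rng):
        vals = rng.uniform(0, 50, size=(15, 10))
        vals[3] = 7.0
        with pytest.warns(UserWarning, match="zero-variance"):
            feats = states.nonneg_transform(_purified(vals))
        assert "g3" not in feats.genes

    def test_all_constant_rejected(self):
        with pytest.raises(InputError):
            states.nonneg_transform(_purified(np.ones((15, 6))))


class TestRunNmf:
    def test_rank_one_exact(self, rng):
        V = np.outer(rng.uniform(1, 2, 30), rng.uniform(1, 2, 10))
        fits = states.run_nmf(V, 1, n_restarts=2, seed=0)
        for W, H, trace in fits:
            assert trace[-1] / np.linalg.norm(V) < 1e-6

    def test_objective_monotone(self, rng):
        V = rng.uniform(0, 1, size=(25, 12))
        for _, _, trace in states.run_nmf(V, 3, n_restarts=4, seed=1):
            diffs = np.diff(trace)
            assert (diffs <= 1e-10 * trace[0]).all()

    def test_block_diagonal_separable(self):
        V = np.zeros((20, 10))
        V[:10, :5] = 5.0
        V[10:, 5:] = 5.0
        fits = states.run_nmf(V, 2, n_restarts=3, seed=2)
        for _, H, _ in fits:
            lab = H.argmax(axis=0)
            assert len(set(lab[:5])) == 1
            assert len(set(lab[5:])) == 1
            assert lab[0] != lab[5]

    def test_identical_under_identical_seed(self, rng):
        V = rng.uniform(0, 1, size=(20, 10))
        f1 = states.run_nmf(V, 2, n_restarts=2, seed=9)
        f2 = states.run_nmf(V, 2, n_restarts=2, seed=9)
        for (W1, H1, _), (W2, H2, _) in zip(f1, f2):
            assert np.array_equal(W1, W2) and np.array_equal(H1, H2)

    def test_rank_bound_enforced(self, rng):
        with pytest.raises(InputError):
            states.run_nmf(rng.uniform(0, 1, (5, 4)), 4, seed=0)


class TestConsensus:
    def test_identical_assignments_binary(self):
        C = states.consensus_matrix([[0, 0, 1, 1]] * 3)
        assert set(np.unique(C)) <= {0.0, 1.0}

    def test_single_restart_rejected(self):
        with pytest.raises(InputError):
            states.consensus_matrix([[0, 1]])

    def test_hand_counted_fractions(self):
        a = [[0, 0, 1], [0, 1, 1], [0, 0, 0]]
        C = states.consensus_matrix(a)
        # pair (0,1): together in restarts 1 and 3 -> 2/3
        assert C[0, 1] == pytest.approx(2 / 3)
        # pair (1,2): together in restarts 2 and 3 -> 2/3
        assert C[1, 2] == pytest.approx(2 / 3)
        # pair (0,2): together in restart 3 only -> 1/3
        assert C[0, 2] == pytest.approx(1 / 3)
        assert np.allclose(np.diag(C), 1.0)


def _brute_cophenetic(D: np.ndarray) -> float:
    """Independent average-linkage cophenetic correlation by agglomeration."""
    n = D.shape[0]
    clusters = [[i] for i in range(n)]
    coph = np.zeros((n, n))
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = d
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    iu = np.triu_indices(n, 1)
    return float(np.corrcoef(D[iu], coph[iu])[0, 1])


class TestCophenetic:
    def test_perfect_two_block_consensus(self):
        C = np.zeros((6, 6))
        C[:3, :3] = 1.0
        C[3:, 3:] = 1.0
        assert states.cophenetic_coefficient(C) == pytest.approx(1.0)

    def test_constant_consensus_convention(self):
        with pytest.warns(UserWarning, match="constant"):
            assert states.cophenetic_coefficient(np.ones((5, 5))) == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        C = rng.uniform(0, 1, size=(6, 6))
        C = (C + C.T) / 2
        np.fill_diagonal(C, 1.0)
        ours = states.cophenetic_coefficient(C)
        oracle = _brute_cophenetic(1.0 - C)
        assert ours == pytest.approx(max(0.0, min(1.0, oracle)), abs=1e-12)


class TestSelectRank:
    def test_nearest_to_target(self):
        assert states.select_rank({2: 0.99, 3: 0.96, 4: 0.80}) == 3

    def test_tie_goes_to_smaller_rank(self):
        assert states.select_rank({2: 0.93, 3: 0.97}) == 2

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            states.select_rank({})

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        hst.dictionaries(
            hst.integers(2, 20),
            hst.floats(0, 1, allow_nan=False),
            min_size=1,
            max_size=10,
        )
    )
    def test_always_attains_minimum_distance(self, coph):
        k = states.select_rank(coph)
        best = min(abs(v - 0.95) for v in coph.values())
        assert abs(coph[k] - 0.95) == pytest.approx(best)
        for other, v in coph.items():
            if abs(v - 0.95) == abs(coph[k] - 0.95):
                assert k <= other


def _discover_small(seed=7):
    truth = synthetic.generate_truth(
        450, ["A", "B", "C"], {"A": 2, "B": 3, "C": 3},
        n_markers_per_state=30, effect_size_log2=2.0, n_communities=3,
        community_noise_rate=0.1, n_samples=120, seed=seed,
    )
    bulk = synthetic.simulate_bulk(truth, noise_sd_log2=0.3, seed=seed)
    fr = deconvolution.estimate_fractions(bulk, synthetic.true_signature(truth))
    pur = deconvolution.purify_expression(bulk, fr, "B")
    model, assign = states.discover_states(
        pur, k_range=[3], n_restarts=6, seed=seed, max_genes=120
    )
    return truth, pur, model, assign


class TestMarkersAndFiltering:
    @pytest.fixture(scope="class")
    def discovered(self):
        return _discover_small()

    def test_planted_markers_recovered(self, discovered):
        truth, _, model, assign = discovered
        found = {g for lst in model.markers.values() for g, _ in lst}
        planted = {
            g for s in range(3) for g in truth.marker_map[("B", s)]
        }
        assert len(found & planted) / len(planted) > 0.6

    def test_marker_lists_disjoint(self, discovered):
        _, _, model, _ = discovered
        seen = set()
        for lst in model.markers.values():
            genes = {g for g, _ in lst}
            assert not (genes & seen)
            seen |= genes

    def test_marker_fold_changes_near_planted_effect(self, discovered):
        truth, _, model, _ = discovered
        planted = {
            g for s in range(3) for g in truth.marker_map[("B", s)]
        }
        lfcs = [
            f for lst in model.markers.values() for g, f in lst if g in planted
        ]
        assert np.median(lfcs) == pytest.approx(2.0, abs=0.6)

    def test_flat_gene_is_not_marker(self, discovered):
        _, _, model, _ = discovered
        for lst in model.markers.values():
            for _, lfc in lst:
                assert lfc >= 1.0

    def test_low_marker_state_dropped(self, discovered):
        _, pur, model, _ = discovered
        impoverished = {
            s: lst[:9] if i == 0 else lst
            for i, (s, lst) in enumerate(model.markers.items())
        }
        crippled = states.StateModel(
            cell_type=model.cell_type, rank=model.rank, W=model.W, H=model.H,
            cophenetic_by_rank=model.cophenetic_by_rank, features=model.features,
            markers=impoverished,
        )
        filtered = states.filter_states(crippled, pur, use_afi=False)
        victim = list(model.markers)[0]
        assert victim not in filtered.states
        assert any("9 markers" in r for s, r in filtered.dropped_states)

    def test_artifact_state_dropped_by_afi(self, discovered):
        _, pur, model, _ = discovered
        # plant a component that tracks held-out total signal exactly
        held = [g for g in pur.values.index if g not in set(model.features.genes)]
        total = pur.values.loc[held].sum(axis=0)
        H = model.H.copy()
        H.loc[:, :] = 1.0  # flat siblings: relative abundance mirrors the copy
        H.loc[H.index[0]] = total.to_numpy()
        fake = states.StateModel(
            cell_type=model.cell_type, rank=model.rank, W=model.W, H=H,
            cophenetic_by_rank=model.cophenetic_by_rank, features=model.features,
            markers=model.markers,
        )
        # the copy has |rho| = 1 and, being dominant, drags its flat
        # siblings into perfect anti-correlation: every state is flagged
        with pytest.raises(
            states.DegenerateStateModelError, match="tracks total signal"
        ):
            states.filter_states(fake, pur)

    def test_no_drop_renormalizes_only(self, discovered):
        _, pur, model, _ = discovered
        filtered = states.filter_states(model, pur, min_markers=1, use_afi=False)
        assert filtered.states == model.states
        assert np.allclose(filtered.H.sum(axis=0), 1.0, atol=1e-9)

    def test_assignments_match_planted(self, discovered):
        from sklearn.metrics import adjusted_rand_score

        truth, _, _, assign = discovered
        ari = adjusted_rand_score(
            truth.states_of("B").to_numpy(), assign.labels.to_numpy()
        )
        assert ari > 0.9


class TestAssign:
    def _model(self, H):
        Hdf = pd.DataFrame(
            H, index=[f"S{i+1:02d}" for i in range(H.shape[0])],
            columns=[f"s{j}" for j in range(H.shape[1])],
        )
        feats = states.NonnegFeatures(
            values=pd.DataFrame(np.zeros((0, H.shape[1])), columns=Hdf.columns),
            means=pd.Series(dtype=float),
            sds=pd.Series(dtype=float),
        )
        return states.StateModel(
            cell_type="T", rank=H.shape[0],
            W=pd.DataFrame(np.zeros((0, H.shape[0])), columns=Hdf.index),
            H=Hdf, cophenetic_by_rank={}, features=feats,
        )

    def test_argmax(self):
        a = states.assign_states(self._model(np.array([[0.7], [0.2], [0.1]])))
        assert a.labels.iloc[0] == "S01"

    def test_tie_to_lowest_index(self):
        a = states.assign_states(self._model(np.array([[0.5], [0.5]])))
        assert a.labels.iloc[0] == "S01"
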