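"""Weighted PCA, maximum-entropy fitting and landscape combinatorics.

The minima / basin / barrier operations are checked against exhaustive
brute-force oracles over all states.
"""

import heapq
import itertools

import numpy as np
import pytest

from genoscape.landscape import (
    ConvergenceError,
    EnergyLandscape,
    PairwiseMaxEnt,
    WeightedPCABinarizer,
    all_states,
    basin_map,
    build_disconnectivity,
    descend,
    empirical_distribution,
    find_local_minima,
    state_index,
    state_vector,
    summarize_nodes,
)


# --------------------------------------------------------------------------
# brute-force oracles
# --------------------------------------------------------------------------

def brute_minima(E, n):
    out = []
    for k in range(2**n):
        nbs = [k ^ (1 << i) for i in range(n)]
        if all(E[nb] > E[k] or (E[nb] == E[k] and nb > k) for nb in nbs):
            out.append(k)
    return out


def brute_descend(E, n, k):
    while True:
        nbs = [k ^ (1 << i) for i in range(n)]
        best = min(E[nb] for nb in nbs)
        if best < E[k]:
            k = next(nb for nb in nbs if E[nb] == best)
        else:
            if all(E[nb] > E[k] or (E[nb] == E[k] and nb > k) for nb in nbs):
                return k
            k = next(nb for nb in nbs if E[nb] == E[k] and nb < k)


def brute_barrier(E, n, a, b):
    """Minimax path energy by widest-path Dijkstra on the hypercube."""
    best = np.full(2**n, np.inf)
    best[a] = E[a]
    heap = [(E[a], a)]
    while heap:
        cost, k = heapq.heappop(heap)
        if cost > best[k]:
            continue
        for i in range(n):
            nb = k ^ (1 << i)
            c = max(cost, E[nb])
            if c < best[nb]:
                best[nb] = c
                heapq.heappush(heap, (c, nb))
    return best[b]


# --------------------------------------------------------------------------
# state indexing
# --------------------------------------------------------------------------

def test_state_index_bijection():
    n = 5
    S = all_states(n)
    idx = state_index(S)
    assert list(idx) == list(range(2**n))
    for k in (0, 7, 31):
        assert state_index(state_vector(k, n)) == k


def test_empirical_distribution_basics():
    states = np.array([[1, 1], [1, 1], [-1, 1], [1, -1]])
    p = empirical_distribution(states)
    assert p.sum() == pytest.approx(1.0)
    assert p[3] == pytest.approx(0.5)  # (+1,+1) = index 3
    assert p[2] == pytest.approx(0.25)


# --------------------------------------------------------------------------
# weighted PCA + binarization
# --------------------------------------------------------------------------

class TestWeightedPca:
    def test_unit_weights_match_plain_svd(self):
        rng = np.random.default_rng(0)
        X = rng.binomial(2, 0.4, size=(40, 8)).astype(float)
        enc = WeightedPCABinarizer(n_components=3).fit(X)
        Xs = (X - X.mean(0)) / X.std(0)
        U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
        ref = np.abs(Xs @ Vt[:3].T)
        assert np.allclose(np.abs(enc.scores_), ref, atol=1e-8)

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 5)) + 1.0
        X = np.clip(np.round(np.abs(X)) % 3, 0, 2)
        w = rng.uniform(0.5, 2.0, 5)
        enc = WeightedPCABinarizer(n_components=5).fit(X, weights=w)
        Xw = (X - enc.column_means_) / enc.column_sds_ * enc.weights_
        # rank may be < 5 for the discrete matrix; fit raises in that case
        recon = enc.scores_ @ enc.loadings_.T
        assert np.allclose(recon, Xw, atol=1e-8)

    def test_all_zero_weights_rejected(self):
        X = np.tile([0.0, 1.0, 2.0], (4, 1))
        with pytest.raises(ValueError, match="zero"):
            WeightedPCABinarizer(n_components=1).fit(X, weights=np.zeros(3))

    def test_loadings_orthonormal_and_variance_sorted(self):
        rng = np.random.default_rng(2)
        X = rng.binomial(2, 0.3, size=(100, 12)).astype(float)
        enc = WeightedPCABinarizer(n_components=4).fit(
            X, weights=rng.uniform(0.5, 1.5, 12)
        )
        assert np.allclose(enc.loadings_.T @ enc.loadings_, np.eye(4), atol=1e-8)
        assert (np.diff(enc.explained_variance_) <= 1e-12).all()

    def test_threshold_reuse_is_idempotent(self):
        rng = np.random.default_rng(3)
        X = rng.binomial(2, 0.4, size=(60, 10)).astype(float)
        X[rng.random(X.shape) < 0.05] = np.nan
        enc = WeightedPCABinarizer(n_components=3)
        states = enc.fit_binarize(X, weights=np.ones(10))
        again = enc.binarize(enc.transform(X))
        assert np.array_equal(states, again)

    def test_constant_scores_binarize_positive(self):
        enc = WeightedPCABinarizer(n_components=1)
        enc.thresholds_ = np.array([0.0])
        assert (enc.binarize(np.zeros((5, 1))) == 1.0).all()

    def test_n_components_beyond_rank_rejected(self):
        X = np.tile([0.0, 1.0, 2.0, 1.0], (6, 1)).T  # rank 1 after scaling
        with pytest.raises(ValueError):
            WeightedPCABinarizer(n_components=4).fit(X, weights=np.ones(6))


# --------------------------------------------------------------------------
# pairwise maximum-entropy model
# --------------------------------------------------------------------------

class TestMaxEnt:
    def test_uniform_distribution_gives_zero_parameters(self):
        m = PairwiseMaxEnt().fit_from_probabilities(np.full(8, 1 / 8))
        assert np.allclose(m.h_, 0) and np.allclose(m.J_, 0)

    def test_symmetric_two_spin_closed_form(self):
        # P(++) = P(--) = 0.4, P(+-) = P(-+) = 0.1  =>  h = 0, J = ln 2
        p = np.array([0.4, 0.1, 0.1, 0.4])
        m = PairwiseMaxEnt().fit_from_probabilities(p)
        assert np.allclose(m.h_, 0, atol=1e-4)
        assert m.J_[0, 1] == pytest.approx(np.log(2), abs=1e-4)

    def test_moment_matching_on_fitted_model(self):
        rng = np.random.default_rng(4)
        states = rng.choice([-1.0, 1.0], size=(500, 4))
        m = PairwiseMaxEnt().fit(states)
        m1, m2 = m.model_moments()
        p_emp = empirical_distribution(states)
        S = all_states(4)
        iu, ju = np.triu_indices(4, 1)
        assert np.allclose(m1, p_emp @ S, atol=2e-6)
        assert np.allclose(m2, p_emp @ (S[:, iu] * S[:, ju]), atol=2e-6)

    def test_sample_refit_recovers_parameters(self):
        rng = np.random.default_rng(5)
        n_spins = 5
        h = rng.normal(0, 0.3, n_spins)
        J = rng.normal(0, 0.2, (n_spins, n_spins))
        J = np.triu(J, 1)
        J = J + J.T
        truth = PairwiseMaxEnt().set_parameters(h, J)
        sample = truth.sample(100_000, random_state=6)
        refit = PairwiseMaxEnt().fit(sample)
        assert np.abs(refit.h_ - h).max() < 0.05
        assert np.abs(refit.J_ - J).max() < 0.05

    def test_boltzmann_normalization(self):
        rng = np.random.default_rng(7)
        m = PairwiseMaxEnt().set_parameters(
            rng.normal(size=3), np.zeros((3, 3))
        )
        assert np.exp(-m.energies_ - m.log_z_).sum() == pytest.approx(1.0, abs=1e-10)

    def test_energy_direct_substitution(self):
        J = np.array([[0.0, 0.5], [0.5, 0.0]])
        m = PairwiseMaxEnt().set_parameters(np.array([1.0, -1.0]), J)
        assert m.energy(np.array([1.0, 1.0])) == pytest.approx(-0.5)

    def test_nonconvergence_raises_with_gap(self):
        p = np.array([0.4, 0.1, 0.1, 0.4])
        with pytest.raises(ConvergenceError) as err:
            PairwiseMaxEnt(max_iter=3).fit_from_probabilities(p)
        assert err.value.moment_gap > 0


# --------------------------------------------------------------------------
# minima, basins, disconnectivity
# --------------------------------------------------------------------------

class TestLandscapeCombinatorics:
    def test_single_well_has_unique_minimum(self):
        n = 4
        E = np.array([bin(k).count("1") for k in range(2**n)], dtype=float)
        assert list(find_local_minima(E, n)) == [0]
        assert all(descend(E, n, k) == 0 for k in range(2**n))

    def test_flat_landscape_tie_rule(self):
        n = 3
        E = np.zeros(2**n)
        assert list(find_local_minima(E, n)) == [0]
        assert (basin_map(E, n) == 0).all()

    @pytest.mark.parametrize("rep", range(25))
    def test_matches_brute_force_on_random_landscapes(self, rep):
        rng = np.random.default_rng(100 + rep)
        n = 4
        E = rng.normal(size=2**n)
        if rep % 5 == 0:
            E = np.round(E, 1)  # provoke exact ties
        assert list(find_local_minima(E, n)) == brute_minima(E, n)
        basin = basin_map(E, n)
        for k in range(2**n):
            assert basin[k] == brute_descend(E, n, k)
            assert descend(E, n, k) == basin[k]
        tree = build_disconnectivity(E, n)
        for a, b in itertools.combinations(brute_minima(E, n), 2):
            assert tree.barrier(a, b) == pytest.approx(brute_barrier(E, n, a, b))

    def test_two_state_square_barrier(self):
        # E(--) = 0, E(++) = 0.5, E(+-) = E(-+) = 2: two minima, barrier 2
        E = np.array([0.0, 2.0, 2.0, 0.5])
        minima = find_local_minima(E, 2)
        assert list(minima) == [0, 3]
        tree = build_disconnectivity(E, 2)
        assert tree.barrier(0, 3) == pytest.approx(2.0)

    def test_single_minimum_tree_is_one_leaf(self):
        E = np.array([0.0, 1.0, 1.0, 2.0])
        tree = build_disconnectivity(E, 2)
        assert len(tree.minima) == 1
        with pytest.raises(ValueError, match="cannot split"):
            tree.split_two_groups(E)


class TestSplitGroups:
    def test_two_minima_each_their_own_group(self):
        E = np.array([0.0, 2.0, 2.0, 0.5])
        tree = build_disconnectivity(E, 2)
        groups = tree.split_two_groups(E)
        assert groups == {0: 1, 3: 2}

    def test_three_minima_root_cut(self):
        # barriers: b(A,B) < b(A,C) = b(B,C)  =>  groups {A,B} vs {C}
        n = 3
        E = np.full(2**n, 5.0)
        E[0b000] = 0.0   # A (global minimum)
        E[0b011] = 0.4   # B
        E[0b110] = 0.3   # C
        E[0b001] = 1.0   # low pass between A and B
        # everything else stays high (5.0): C only connects over 5.0
        tree = build_disconnectivity(E, n)
        groups = tree.split_two_groups(E)
        assert groups[0b000] == 1 and groups[0b011] == 1
        assert groups[0b110] == 2

    def test_energy_depends_only_on_state_distribution(self):
        rng = np.random.default_rng(8)
        states = rng.choice([-1.0, 1.0], size=(300, 3))
        perm = rng.permutation(300)
        a = EnergyLandscape().fit(states)
        b = EnergyLandscape().fit(states[perm])
        assert np.allclose(a.model_.h_, b.model_.h_, atol=1e-9)
        assert np.allclose(a.model_.J_, b.model_.J_, atol=1e-9)


# --------------------------------------------------------------------------
# node summaries
# --------------------------------------------------------------------------

class TestSummaries:
    def _fit(self, states, is_case):
        return EnergyLandscape().fit(states, is_case)

    def test_full_separation_colors(self):
        E = np.array([0.0, 2.0, 2.0, 0.5])
        basin = basin_map(E, 2)
        minima = find_local_minima(E, 2)
        states = np.array([[-1.0, -1.0]] * 10 + [[1.0, 1.0]] * 10)
        is_case = np.r_[np.ones(10), np.zeros(10)].astype(bool)
        summary = summarize_nodes(basin, minima, states, is_case)
        assert summary.loc[0, "freq_diff"] == pytest.approx(1.0)
        assert summary.loc[0, "color"] == "red"
        assert summary.loc[3, "freq_diff"] == pytest.approx(-1.0)
        assert summary.loc[3, "color"] == "green"

    def test_identical_distributions_gray(self):
        E = np.array([0.0, 2.0, 2.0, 0.5])
        basin = basin_map(E, 2)
        minima = find_local_minima(E, 2)
        # both classes occupy both states in equal proportion
        states = np.array([[-1.0, -1.0], [-1.0, -1.0], [1.0, 1.0], [1.0, 1.0]] * 5)
        is_case = np.tile([True, False, True, False], 5)
        summary = summarize_nodes(basin, minima, states, is_case)
        assert (summary["color"] == "gray").all()

    def test_frequencies_sum_to_one(self):
        rng = np.random.default_rng(9)
        states = rng.choice([-1.0, 1.0], size=(200, 3))
        is_case = rng.random(200) < 0.5
        scape = self._fit(states, is_case)
        assert scape.node_summary_["case_frequency"].sum() == pytest.approx(1.0)
        assert scape.node_summary_["control_frequency"].sum() == pytest.approx(1.0)


def test_landscape_serialization_round_trip(tmp_path):
    rng = np.random.default_rng(10)
    states = rng.choice([-1.0, 1.0], size=(300, 4))
    scape = EnergyLandscape().fit(states, rng.random(300) < 0.4)
    path = tmp_path / "scape.json"
    scape.to_json(path)
    back = EnergyLandscape.from_json(path)
    assert np.allclose(back.model_.h_, scape.model_.h_)
    assert np.allclose(back.model_.J_, scape.model_.J_)
    assert list(back.minima_) == list(scape.minima_)
    assert back.groups_ == scape.groups_
    assigned = back.assign(states)
    assert (assigned["basin"].to_numpy() == scape.assign(states)["basin"].to_numpy()).all()
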