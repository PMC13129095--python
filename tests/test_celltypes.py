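import numpy as np
import pandas as pd
import pytest

from predinet import (
    classification_sigma,
    classify,
    classify_pair,
    condition,
    dedicated_pe_fraction,
    make_network,
    mixed_fraction,
    pe_r_fractions,
    representation_similarity,
    segregation_index,
)
from predinet.errors import InsufficientDataError, ParameterError
from predinet.recordings import generate_probe_ensemble


class TestClassifyPair:
    def test_hand_built_definitions(self):
        sigma = 2.0
        # neuron 0: strong and similar -> R; neuron 1: strong, suppressed -> PE
        # neuron 2: subthreshold -> none; neuron 3: strong, mildly reduced -> R
        h_x = np.array([sigma, sigma, 0.1, sigma])
        h_xy = np.array([sigma, 0.0, 0.1, sigma - 0.4])
        tab = classify_pair(h_x, h_xy, sigma)
        assert list(tab["label"]) == ["R", "PE", "none", "R"]

    def test_labels_mutually_exclusive(self, rng):
        h_x = rng.standard_normal(500) * 3
        h_xy = rng.standard_normal(500) * 3
        tab = classify_pair(h_x, h_xy, 2.0)
        is_r = tab["label"] == "R"
        is_pe = tab["label"] == "PE"
        assert not np.any(is_r & is_pe)

    def test_centering_invariance_to_common_offset(self, rng):
        h_x = rng.standard_normal(300)
        h_xy = rng.standard_normal(300)
        a = classify_pair(h_x, h_xy, 1.0, center=True)
        c = classify_pair(h_x + 7.3, h_xy + 7.3, 1.0, center=True)
        assert list(a["label"]) == list(c["label"])

    def test_sigma_must_be_positive(self):
        with pytest.raises(ParameterError):
            classify_pair(np.ones(3), np.ones(3), 0.0)

    def test_dedicated_error_unit_always_pe_never_r(self):
        """A unit responding to |x - y_prediction| is PE for every pair."""
        sigma = 1.0
        # mismatch: prediction absent -> large response; match: cancelled
        h_x = np.array([5.0])
        h_xy = np.array([0.0])
        for _ in range(3):  # same tuning for any pair it is tested on
            tab = classify_pair(h_x, h_xy, sigma)
            assert tab["label"][0] == "PE"


class TestNetworkClassification:
    def test_pe_fraction_grows_with_learning(self):
        df = pe_r_fractions(N=1500, b=170.0, mus=[0.0, 0.5, 0.97], n_instances=3, seed=0)
        pe = df.sort_values("mu")["frac_PE"].to_numpy()
        assert pe[0] < 0.05
        assert np.all(np.diff(pe) > 0)

    def test_untrained_network_mixes_almost_nothing(self):
        """Before learning hardly any neuron is classified for both pairs,
        so mixed neurons are a negligible share of the population."""
        mixed_pop = {}
        for mu in (0.0, 0.97):
            net = make_network(2000, 2, mu, b=170.0, seed=1)
            sigma = classification_sigma(2000, 2, 170.0, 1)
            res = mixed_fraction(net, sigma=sigma)
            mixed_pop[mu] = res.fraction * res.n_dually_responsive / 2000
        assert mixed_pop[0.0] < 0.005
        assert mixed_pop[0.97] > 4 * mixed_pop[0.0]

    def test_mixed_fraction_joint_table_consistent(self):
        net = make_network(2000, 2, 0.97, b=20.0, seed=1)
        res = mixed_fraction(net)
        assert res.joint.shape[0] == res.n_dually_responsive
        assert res.fraction == pytest.approx(res.joint["mixed"].mean())

    def test_dedicated_fraction_matches_label_crosstab_oracle(self):
        """Exhaustive cross-tabulation over all pairs reproduces the fraction."""
        net = make_network(800, 3, 0.97, b=20.0, seed=2)
        sigma = classification_sigma(800, 3, 20.0, 2)
        frac = dedicated_pe_fraction(net, sigma=sigma, center=False)
        tab = classify(net, sigma=sigma, center=False).table
        count = 0
        for _, sub in tab.groupby("neuron"):
            labels = list(sub["label"])
            if "PE" in labels and "R" not in labels:
                count += 1
        assert frac == pytest.approx(count / 800)


class TestSegregation:
    def test_identical_probe_gives_unit_index(self):
        rec = generate_probe_ensemble([1.0], N=600, b=20.0, noise_sd=0.0, seed=0)
        res = segregation_index(rec, "expected", "probe_0")
        assert res.segregation_index == pytest.approx(1.0, abs=1e-6)
        assert res.representation_similarity == pytest.approx(1.0, abs=1e-6)

    def test_shuffled_deltas_have_null_index(self, rng):
        rec = generate_probe_ensemble([1.0], N=1500, b=20.0, noise_sd=0.0, seed=0)
        perm = rng.permutation(1500)
        probe_trials = rec.trial_stimulus == "probe_0"
        rec.values[probe_trials] = rec.values[probe_trials][:, perm, :]
        res = segregation_index(rec, "expected", "probe_0")
        # finite-sample null: |r| of order 1/sqrt(n_responsive)
        assert abs(res.segregation_index) < 4.0 / np.sqrt(res.n_neurons)

    def test_too_few_responsive_neurons_rejected(self):
        rec = generate_probe_ensemble([1.0], N=600, b=20.0, noise_sd=0.0, seed=0)
        rec.values = rec.values[:, :2, :]
        rec.neuron_class = rec.neuron_class[:2]
        with pytest.raises(InsufficientDataError):
            segregation_index(rec, "expected", "probe_0")

    def test_distinct_probes_reveal_mixing(self):
        """A novel probe breaks the perfect Delta correlation of the
        identical-probe control: the index drops measurably below 1."""
        rec = generate_probe_ensemble([1.0, 0.2], N=1500, b=20.0, seed=3)
        same = segregation_index(rec, "expected", "probe_0", seed=1)
        other = segregation_index(rec, "expected", "probe_1", seed=1)
        assert same.segregation_index > 0.99
        assert other.segregation_index < 0.97


class TestRepresentationSimilarity:
    def test_self_similarity_is_one(self, rng):
        v = rng.standard_normal(100)
        assert representation_similarity(v, v) == pytest.approx(1.0)

    def test_orthogonal_synthetic_responses_near_zero(self):
        gen = np.random.default_rng(7)
        a, c = gen.standard_normal(2000), gen.standard_normal(2000)
        assert abs(representation_similarity(a, c)) < 0.1

    def test_zero_variance_vector_rejected(self):
        with pytest.raises(ParameterError):
            representation_similarity(np.ones(10), np.arange(10.0))

    def test_similarity_increases_with_weight_overlap(self):
        rec = generate_probe_ensemble([0.1, 0.5, 0.9], N=1500, b=20.0, noise_sd=0.0, seed=5)
        sims = []
        for j in range(3):
            pas_e = rec.response_change("expected", "passive")
            pas_p = rec.response_change(f"probe_{j}", "passive")
            sims.append(representation_similarity(pas_e, pas_p))
        assert sims[0] < sims[1] < sims[2]


class TestDedicatedPeVsDimension:
    def test_dedicated_pe_fraction_decreases_with_stimulus_load(self):
        """Dedicated error neurons become rare in high-dimensional ensembles."""
        fracs = []
        for P in (2, 200):
            net = make_network(800, P, 0.97, b=20.0, seed=2)
            sigma = classification_sigma(800, P, 20.0, 2, center=True)
            fracs.append(
                dedicated_pe_fraction(net, pairs=range(min(P, 6)), sigma=sigma, center=True)
            )
        assert fracs[1] < 0.7 * fracs[0]
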