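"""Correlation statistics and the gamma/permutation/shuffle null models."""

import numpy as np
import pandas as pd
import pytest

from straindyn.dynamics import (
    CouplingConfig,
    GammaNullSpec,
    NullDistribution,
    cooccurrence_variability,
    coupling_distance_curve,
    detect_interactions,
    ecoevo_influence,
    gamma_null_correlations,
    interspecies_correlations,
    strain_coupling,
    strain_label_permutation_test,
)
from straindyn.io import ValidationError


class TestStrainCoupling:
    def test_proportional_strains_fully_coupled(self, rng):
        species = rng.gamma(4, 0.05, size=8)
        a, b = 0.3 * species, 0.7 * species  # constant f: both track the species
        c, label = strain_coupling(a, b)
        assert c == pytest.approx(1.0)
        assert label == "coupled"

    def test_antiproportional_strains_also_coupling_one(self):
        # constant species abundance, varying f: r = -1, coupling = |r| = 1
        f = np.linspace(0.2, 0.8, 8)
        c, label = strain_coupling(f * 0.5, (1 - f) * 0.5)
        assert c == pytest.approx(1.0)
        assert label == "coupled"

    def test_constant_trajectory_undefined(self):
        c, label = strain_coupling(np.full(8, 0.3), np.linspace(0, 1, 8))
        assert np.isnan(c) and label == "undefined"

    def test_independent_gamma_pairs_mostly_decoupled(self, rng):
        couplings, labels = [], []
        for _ in range(1000):
            a = rng.gamma(1.0, 0.1, size=8)
            b = rng.gamma(1.0, 0.1, size=8)
            c, label = strain_coupling(a, b)
            couplings.append(c)
            labels.append(label)
        # E|r| for independent 8-point series ~ 0.3 << 1
        assert 0.2 < np.mean(couplings) < 0.42
        assert np.mean([l == "decoupled" for l in labels]) > 0.6

    def test_spearman_variant_matches_labels(self, rng):
        species = rng.gamma(4, 0.05, size=8)
        for cfg in (CouplingConfig(), CouplingConfig(kind="spearman")):
            c, label = strain_coupling(0.3 * species, 0.7 * species, cfg)
            assert label == "coupled"


class TestInterspeciesCorrelations:
    def test_single_strain_degenerate(self, rng):
        a = rng.random(8)
        b = rng.random(8)
        sp_r, st_r, exceeds = interspecies_correlations(a, b, [a], [b])
        assert st_r == pytest.approx(sp_r)
        assert not exceeds

    def test_hidden_interaction_between_minor_strains(self, rng):
        # species uncorrelated, but the two minor strains mirror each other
        minor = rng.gamma(2, 0.02, size=8)
        major_a = rng.gamma(5, 0.05, size=8)
        major_b = rng.gamma(5, 0.05, size=8)
        a, b = major_a + minor, major_b + minor
        sp_r, st_r, exceeds = interspecies_correlations(
            a, b, [major_a, minor], [major_b, minor]
        )
        assert st_r == pytest.approx(1.0)
        assert st_r > sp_r
        assert exceeds

    def test_proportional_species(self, rng):
        a = rng.random(8)
        b = 2 * a
        sp_r, st_r, exceeds = interspecies_correlations(a, b, [a], [b])
        assert sp_r == pytest.approx(1.0)
        assert not exceeds

    def test_at_most_four_pairs(self, rng):
        a = rng.random((2, 8))
        b = rng.random((2, 8))
        sp_r, st_r, _ = interspecies_correlations(
            a.sum(0), b.sum(0), list(a), list(b)
        )
        assert 0 <= st_r <= 1


class TestGammaNull:
    def test_parameterization_beta(self):
        spec = GammaNullSpec(means=(0.1,) * 3, variances=(0.01,) * 3)
        assert np.allclose(spec.shapes, 1.0)  # exponential special case

    def test_raw_draw_moments_within_three_se(self, rng):
        spec = GammaNullSpec(means=(0.2,), variances=(0.005,))
        n = 20_000
        draws = rng.gamma(spec.shapes[0], spec.scales[0], size=n)
        se_mean = np.sqrt(0.005 / n)
        assert abs(draws.mean() - 0.2) < 3 * se_mean
        var_se = draws.var() * np.sqrt(2 / (n - 1))
        assert abs(draws.var() - 0.005) < 3 * var_se

    def test_distribution_size(self):
        spec = GammaNullSpec(means=(0.1,) * 10, variances=(0.002,) * 10, n_sims=50)
        null = gamma_null_correlations(spec, n_times=8)
        assert null.samples.size == 50 * 45

    def test_renormalized_draws_sum_to_one(self, rng):
        spec = GammaNullSpec(means=(0.3, 0.5, 0.2), variances=(0.01,) * 3)
        draws = rng.gamma(spec.shapes[:, None], spec.scales[:, None], size=(3, 8))
        rel = draws / draws.sum(axis=0)
        assert np.allclose(rel.sum(axis=0), 1.0)


class TestDetectInteractions:
    def test_perfect_correlation_is_edge(self):
        null = NullDistribution(np.linspace(0, 0.9, 999))
        net = detect_interactions({("a", "b"): 1.0}, null)
        assert len(net.edges) == 1
        assert net.edges.iloc[0]["p"] == pytest.approx(1 / 1000)

    def test_network_density_per_node(self):
        null = NullDistribution(np.linspace(0, 0.5, 200))
        strain_edges = {(f"s{i}.a", f"s{i+20}.b"): 0.99 for i in range(38)}
        strain_net = detect_interactions(
            strain_edges, null, level="strain", nodes=[f"n{i}" for i in range(24)]
        )
        species_net = detect_interactions(
            {(f"x{i}", f"y{i}"): 0.99 for i in range(10)},
            null,
            nodes=[f"m{i}" for i in range(12)],
        )
        assert strain_net.density == pytest.approx(38 / 24)
        assert species_net.density == pytest.approx(10 / 12)
        assert strain_net.density / species_net.density - 1 == pytest.approx(0.9)

    def test_false_positive_rate_matches_alpha(self, rng):
        """Null data tested against its own null: edge rate ~ alpha."""
        means = tuple(rng.uniform(0.05, 0.2, size=8))
        variances = tuple((0.3 * np.array(means)) ** 2)
        spec = GammaNullSpec(means=means, variances=variances, n_sims=400, seed=1)
        null = gamma_null_correlations(spec)
        g = np.random.default_rng(9)
        shapes, scales = spec.shapes, spec.scales
        hits = trials = 0
        for _ in range(300):
            draws = g.gamma(shapes[:, None], scales[:, None], size=(8, 8))
            rel = draws / draws.sum(axis=0)
            corr = np.corrcoef(rel)
            iu = np.triu_indices(8, k=1)
            for r in np.abs(corr[iu]):
                trials += 1
                hits += null.p_value(r) < 0.05
        rate = hits / trials
        assert abs(rate - 0.05) < 0.02

    def test_strain_level_conspecific_edges_rejected(self):
        from straindyn.dynamics import InteractionNetwork

        edges = pd.DataFrame([{"a": "sp1.s1", "b": "sp1.s2", "r": 0.9, "p": 0.01}])
        with pytest.raises(ValidationError, match="conspecific"):
            InteractionNetwork("strain", ["sp1.s1", "sp1.s2"], edges)


class TestPermutationTest:
    def toy_pairs(self, rng, n_species=3):
        return {
            f"sp{i}": (rng.gamma(3, 0.05, 8), rng.gamma(3, 0.05, 8))
            for i in range(n_species)
        }

    def test_observed_fraction_matches_brute_force(self, rng):
        import itertools

        from straindyn.dynamics import _fraction_strain_dominant, interspecies_correlations

        pairs = self.toy_pairs(rng)
        f = _fraction_strain_dominant(pairs)
        flags = []
        for a, b in itertools.combinations(sorted(pairs), 2):
            sa, sb = pairs[a], pairs[b]
            sp_r = abs(np.corrcoef(np.sum(sa, 0), np.sum(sb, 0))[0, 1])
            st_r = max(
                abs(np.corrcoef(x, y)[0, 1]) for x in sa for y in sb
            )
            flags.append(st_r > sp_r)
        assert f == pytest.approx(np.mean(flags))

    def test_permutation_preserves_marginals(self, rng):
        pairs = self.toy_pairs(rng, 4)
        out = strain_label_permutation_test(pairs, n_perm=20, seed=0)
        assert 0 <= out["F_obs"] <= 1
        assert out["null_samples"].size == 20
        assert 0 < out["p_value"] <= 1

    def test_grouped_permutation_stays_within_communities(self, rng):
        # two communities with very different scales: within-community
        # shuffling never mixes them, so the null F stays well-defined and
        # every trajectory is used exactly once per permutation
        pairs = {}
        groups = {}
        for com, scale in (("M1", 1.0), ("M2", 100.0)):
            for j in range(3):
                key = f"{com}:sp{j}"
                pairs[key] = (scale * rng.gamma(3, 0.05, 8), scale * rng.gamma(3, 0.05, 8))
                groups[key] = com
        out = strain_label_permutation_test(pairs, n_perm=30, seed=1, groups=groups)
        assert 0 <= out["F_obs"] <= 1
        assert np.isfinite(out["null_samples"]).all()

    def test_zero_permutations_is_error(self, rng):
        with pytest.raises(ValidationError):
            strain_label_permutation_test(self.toy_pairs(rng), n_perm=0)

    def test_calibration_under_label_free_data(self, rng):
        """Strains unrelated to species labels: p roughly uniform."""
        ps = []
        for i in range(40):
            g = np.random.default_rng(100 + i)
            pairs = {
                f"sp{j}": (g.gamma(2, 0.05, 8), g.gamma(2, 0.05, 8)) for j in range(4)
            }
            out = strain_label_permutation_test(pairs, n_perm=49, seed=i)
            ps.append(out["p_value"])
        ps = np.asarray(ps)
        # no excess of small p-values beyond chance
        assert (ps < 0.1).mean() < 0.25
        assert 0.25 < ps.mean() < 0.75


class TestCooccurrence:
    def test_constructed_ratio_of_two(self, rng):
        # 2 communities; each group's two members always co-occur, while
        # random relabelling pairs them across communities half the time
        membership = pd.DataFrame(
            {
                "a1": [1, 0], "a2": [1, 0],
                "b1": [0, 1], "b2": [0, 1],
                "c1": [1, 0], "c2": [1, 0],
                "d1": [0, 1], "d2": [0, 1],
            },
            index=["M1", "M2"],
        ).astype(bool)
        groups = {"A": ["a1", "a2"], "B": ["b1", "b2"], "C": ["c1", "c2"], "D": ["d1", "d2"]}
        out = cooccurrence_variability(membership, groups, n_shuffles=2000, seed=0)
        assert out["observed"] == pytest.approx(1.0)
        # null: a random partner co-occurs with probability 3/7
        assert out["normalized"] == pytest.approx(7 / 3, rel=0.1)

    def test_single_community_ratio_one(self):
        membership = pd.DataFrame({m: [1] for m in "abcd"}, index=["M1"]).astype(bool)
        groups = {"G1": ["a", "b"], "G2": ["c", "d"]}
        out = cooccurrence_variability(membership, groups, n_shuffles=100, seed=0)
        assert out["normalized"] == pytest.approx(1.0)

    def test_no_groups_is_error(self):
        membership = pd.DataFrame({"a": [1]}, index=["M1"]).astype(bool)
        with pytest.raises(ValidationError):
            cooccurrence_variability(membership, {"G": ["a"]}, 10, 0)


class TestEcoevoInfluence:
    def test_driven_species_flagged(self, rng):
        freqs = {f"sp{i}": rng.random(8) for i in range(10)}
        # species 0's abundance is a monotone function of its strain frequency
        abunds = {k: rng.gamma(3, 0.05, 8) for k in freqs}
        abunds["sp0"] = 0.1 + 0.5 * freqs["sp0"]
        out = ecoevo_influence(abunds, freqs, n_shuffles=500, seed=0)
        row = out.set_index("species").loc["sp0"]
        assert row["r"] == pytest.approx(1.0)
        assert bool(row["influential"])

    def test_constant_frequency_not_flagged(self, rng):
        freqs = {f"sp{i}": rng.random(8) for i in range(6)}
        freqs["sp0"] = np.full(8, 0.5)
        abunds = {k: rng.gamma(3, 0.05, 8) for k in freqs}
        out = ecoevo_influence(abunds, freqs, n_shuffles=200, seed=0)
        row = out.set_index("species").loc["sp0"]
        assert np.isnan(row["r"]) and not bool(row["influential"])

    def test_null_population_flags_about_five_percent(self, rng):
        flagged = []
        for i in range(30):
            g = np.random.default_rng(i)
            freqs = {f"sp{j}": g.random(8) for j in range(12)}
            abunds = {k: g.gamma(3, 0.05, 8) for k in freqs}
            out = ecoevo_influence(abunds, freqs, n_shuffles=400, seed=i)
            flagged.append(out.attrs["fraction_influential"])
        assert abs(np.mean(flagged) - 0.05) < 0.04


class TestCouplingDistanceCurve:
    def test_single_distance_single_bin(self):
        out = coupling_distance_curve([50, 50, 50], [0.2, 0.4, 0.9])
        assert len(out) == 1
        assert out.iloc[0]["mean_coupling"] == pytest.approx(0.5)

    def test_drop_across_100_snp_boundary(self, rng):
        d = np.concatenate([rng.integers(5, 100, 200), rng.integers(100, 2000, 200)])
        c = np.where(d < 100, 1.0, 0.2)
        out = coupling_distance_curve(d, c, n_bins=6)
        below = out[out["bin_high"] <= 100]["mean_coupling"]
        above = out[out["bin_low"] >= 100]["mean_coupling"]
        assert below.min() > 0.9
        assert above.max() < 0.3

    def test_monotone_inputs_monotone_bins(self):
        d = np.geomspace(1, 1000, 60)
        c = np.linspace(1.0, 0.0, 60)
        out = coupling_distance_curve(d, c, n_bins=5)
        assert (np.diff(out["mean_coupling"]) <= 1e-12).all()
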