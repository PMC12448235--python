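"""Forward simulation, clone-separation assay, and plasticity distances."""

import math

import numpy as np
import pytest

from replast import (
    Mode,
    ModelParams,
    SeparationScheme,
    agent_fitness,
    clone_experiment,
    make_clone_pair,
    mature_phenotype_distribution,
    plasticity_distances,
    policy_expected_fitness,
    simulate_agents,
)


class _Counts:
    def __init__(self, y0=0, y1=0, y0C=0, y1C=0, y0D=0, y1D=0):
        self.y0, self.y1 = y0, y1
        self.y0C, self.y1C = y0C, y1C
        self.y0D, self.y1D = y0D, y1D


class TestDistances:
    def test_opposite_specialists(self):
        """(5,0) vs (0,5) at T=5: sqrt(50) / (2*sqrt(5)) = 1.5811..."""
        o, c = _Counts(y0=5), _Counts(y1=5)
        tot, con, dec = plasticity_distances(o, c, 5)
        assert tot == pytest.approx(math.sqrt(50) / (2 * math.sqrt(5)), abs=1e-12)
        assert con == dec == 0.0

    def test_deconstruction_denominator(self):
        o, c = _Counts(y0D=1), _Counts()
        _, _, dec = plasticity_distances(o, c, 10)
        assert dec == pytest.approx(1.0 / (2 * math.sqrt(5)), abs=1e-12)

    def test_identical_agents_zero(self):
        o = _Counts(y0=2, y1=1, y0C=3, y1C=1, y0D=1)
        assert plasticity_distances(o, o, 10) == (0.0, 0.0, 0.0)

    def test_max_normalizer(self):
        o, c = _Counts(y0=10, y0C=10), _Counts(y1=10, y1C=10)
        tot, con, dec = plasticity_distances(o, c, 10, normalizer="max")
        assert tot == pytest.approx(1.0, abs=1e-12)
        assert con == pytest.approx(1.0, abs=1e-12)


class TestSimulateAgents:
    def test_deterministic_under_fixed_seed(self, solved_cache):
        pol = solved_cache(prior=0.5, reliability=0.75, t_ont=5, mode="incremental")
        a1 = simulate_agents(pol, n=20, seed=11)
        a2 = simulate_agents(pol, n=20, seed=11)
        for x, y in zip(a1, a2):
            assert x.cues == y.cues and x.actions == y.actions and x.ph == y.ph

    def test_prior_specialization_corner(self, solved_cache):
        """Prior 0.9, reliability 0.55: cues are ignored, everyone ends (0, T)."""
        pol = solved_cache(prior=0.9, reliability=0.55, t_ont=5, mode="none")
        agents = simulate_agents(pol, n=500, seed=2)
        assert all(a.ph == (0, 5) for a in agents)

    def test_bookkeeping_conservation(self, solved_cache):
        """Construct + deconstruct + wait periods account for all of ontogeny."""
        pol = solved_cache(prior=0.5, reliability=0.75, t_ont=8, mode="complete")
        for a in simulate_agents(pol, n=300, seed=5):
            assert a.y0C + a.y1C + a.y0D + a.y1D + a.waits == 8
            assert len(a.cues) == len(a.actions) == 8
            # net counts never exceed gross construction
            assert a.y0 <= a.y0C and a.y1 <= a.y1C

    def test_incremental_net_identity(self, solved_cache):
        """In the incremental regime net counts equal constructed minus deconstructed."""
        pol = solved_cache(prior=0.5, reliability=0.95, t_ont=8, mode="incremental")
        for a in simulate_agents(pol, n=300, seed=7):
            assert a.y0 == a.y0C - a.y0D
            assert a.y1 == a.y1C - a.y1D

    def test_env_override(self, solved_cache):
        pol = solved_cache(prior=0.5, reliability=0.75, t_ont=5, mode="incremental")
        agents = simulate_agents(pol, n=50, seed=1, env=0)
        assert all(a.env == 0 for a in agents)

    def test_monte_carlo_matches_exact_forward_value(self, solved_cache):
        pol = solved_cache(prior=0.7, reliability=0.75, t_ont=10, mode="complete")
        agents = simulate_agents(pol, n=4000, seed=13)
        fits = np.array([agent_fitness(a, pol.params) for a in agents])
        exact = policy_expected_fitness(pol)
        se = fits.std(ddof=1) / math.sqrt(len(fits))
        assert abs(fits.mean() - exact) < 3 * se + 1e-9


class TestCloneExperiment:
    def test_no_plasticity_corner(self, solved_cache):
        pol = solved_cache(prior=0.9, reliability=0.55, t_ont=10, mode="incremental")
        curves = clone_experiment(pol, n=400, seed=3)
        assert curves[["total", "construction", "deconstruction"]].to_numpy().max() == 0.0

    def test_histories_identical_before_separation(self, solved_cache):
        pol = solved_cache(prior=0.5, reliability=0.75, t_ont=6, mode="incremental")
        orig = simulate_agents(pol, n=5, seed=21)[0]
        pair = make_clone_pair(pol, orig, t_sep=4, seed=21)
        assert pair.clone.cues[:3] == orig.cues[:3]
        assert pair.clone.snapshots[:4] == orig.snapshots[:4]
        # from the separation point the clone's cues are complemented
        assert all(c == 1 - o for c, o in zip(pair.clone.cues[3:], orig.cues[3:]))

    def test_temporary_window_complements_then_rejoins(self, solved_cache):
        pol = solved_cache(prior=0.5, reliability=0.75, t_ont=6, mode="incremental")
        orig = simulate_agents(pol, n=3, seed=9)[0]
        pair = make_clone_pair(
            pol, orig, t_sep=2, seed=9, scheme=SeparationScheme(window=2)
        )
        oc, cc = orig.cues, pair.clone.cues
        assert cc[0] == oc[0]
        assert cc[1] == 1 - oc[1] and cc[2] == 1 - oc[2]
        assert cc[3:] == oc[3:]

    def test_scheme_validation(self):
        with pytest.raises(ValueError):
            SeparationScheme(window=0)
        with pytest.raises(ValueError):
            SeparationScheme(measure="post_window")
        with pytest.raises(ValueError):
            SeparationScheme(normalizer="median")

    def test_assay_rejects_perfect_reliability(self):
        from replast import solve

        p = ModelParams.make(prior=0.5, reliability=1.0, t_ont=3, mode=Mode.NONE)
        with pytest.raises(ValueError):
            clone_experiment(solve(p), n=10, seed=0)

    def test_flat_prior_symmetry_of_distances(self, solved_cache):
        """At prior 0.5 the model is mirror-symmetric, so relabeling the two
        cue streams leaves the mean distance statistically unchanged."""
        pol = solved_cache(prior=0.5, reliability=0.95, t_ont=6, mode="incremental")
        c1 = clone_experiment(pol, n=800, seed=4)
        c2 = clone_experiment(pol, n=800, seed=104)
        # different seeds, same distribution: means agree to MC precision
        assert np.allclose(c1["total"], c2["total"], atol=0.08)

    def test_complete_mode_total_deviates_from_construction(self, solved_cache):
        """With complete deconstruction a single deconstruct period can erase
        many specializations, decoupling total plasticity from construction."""
        pol = solved_cache(prior=0.5, reliability=0.75, t_ont=10, mode="complete")
        curves = clone_experiment(pol, n=600, seed=6)
        gap = (curves["total"] - curves["construction"]).abs().max()
        assert gap > 0.02


class TestPhenotypeDistribution:
    def test_frequencies_sum_to_one(self, solved_cache):
        pol = solved_cache(prior=0.5, reliability=0.75, t_ont=5, mode="complete")
        dist = mature_phenotype_distribution(pol, n=500, seed=8)
        assert dist.table["frequency"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_no_deconstruction_mode_never_deconstructs(self, solved_cache):
        pol = solved_cache(prior=0.5, reliability=0.75, t_ont=5, mode="none")
        dist = mature_phenotype_distribution(pol, n=500, seed=8)
        assert dist.fraction_deconstructed == 0.0
        assert (dist.table["deconstruction_periods"] == 0).all()

    def test_prior_corner_all_mass_on_full_specialization(self, solved_cache):
        pol = solved_cache(prior=0.9, reliability=0.55, t_ont=5, mode="none")
        dist = mature_phenotype_distribution(pol, n=400, seed=8)
        assert len(dist.table) == 1
        row = dist.table.iloc[0]
        assert (row["y0"], row["y1"], row["deconstruction_periods"]) == (0, 5, 0)

    def test_deconstruction_occurs_under_uncertainty(self, solved_cache):
        pol = solved_cache(prior=0.5, reliability=0.75, t_ont=10, mode="complete")
        dist = mature_phenotype_distribution(pol, n=1000, seed=8)
        assert 0.0 < dist.fraction_deconstructed < 1.0
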