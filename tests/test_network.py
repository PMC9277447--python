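"""Carbon-transition network: steady state, sampling oracle, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tcaflux import FluxParameters, TracerSpec, build_tca_network
from tcaflux.network import ConvergenceError, FluxBoundsError, POOLS

from conftest import random_admissible_fluxes


def admissible_fluxes_strategy():
    return st.builds(
        lambda f, ypc, ys, c: FluxParameters(f, ypc, c * (ypc + ys), ys),
        st.floats(0.05, 1.0),
        st.floats(0.0, 2.0),
        st.floats(0.0, 2.0),
        st.floats(0.0, 1.0),
    )


class TestConstruction:
    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="unknown model variant"):
            build_tca_network("exchange")

    def test_variants_clamp_fluxes(self):
        f = FluxParameters(0.5, 0.2, 0.1, 0.1)
        assert build_tca_network("no_cycling").clamp(f).pk == 0.0
        assert build_tca_network("no_pc").clamp(f).y_pc == 0.0
        assert build_tca_network("full").clamp(f) == f

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(fluxes=admissible_fluxes_strategy(), variant=st.sampled_from(["full", "no_cycling", "no_pc"]))
    def test_mixing_weights_sum_to_one(self, fluxes, variant, tracer):
        weights = build_tca_network(variant).mixing_weights(fluxes, tracer)
        assert set(weights) == set(POOLS)
        for pool, w in weights.items():
            assert sum(w.values()) == pytest.approx(1.0, abs=1e-12), pool
            assert all(v >= 0 for v in w.values())

    def test_invalid_fluxes_rejected_before_iteration(self, network, tracer):
        with pytest.raises(FluxBoundsError, match="f_pdh"):
            network.steady_state(FluxParameters(1.4, 0, 0, 0), tracer)
        with pytest.raises(FluxBoundsError, match="negative"):
            network.steady_state(FluxParameters(0.5, -0.2, 0, 0), tracer)
        with pytest.raises(FluxBoundsError, match="cataplerosis"):
            network.steady_state(FluxParameters(0.5, 0.1, 0.5, 0.1), tracer)

    def test_cs_reference_fixed(self):
        with pytest.raises(FluxBoundsError, match="reference"):
            FluxParameters(0.5, 0.1, 0.0, 0.1, cs=2.0).validate()


class TestSteadyState:
    def test_closed_system_fully_labeled(self, network, tracer):
        """PDH-only flux with a pure tracer drives every pool to [U-13C]."""
        res = network.steady_state(FluxParameters(1, 0, 0, 0), tracer, tolerance=1e-16)
        assert res.converged
        for pool, dist in res.distributions.items():
            assert dist.probs[-1] == pytest.approx(1.0, abs=1e-12), pool

    def test_no_tracer_stays_unlabeled(self, network, mixed_fluxes):
        res = network.steady_state(mixed_fluxes, TracerSpec(enrichment=0.0))
        for dist in res.distributions.values():
            assert dist.probs[0] == 1.0

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(fluxes=admissible_fluxes_strategy(), enrichment=st.floats(0.0, 1.0))
    def test_distributions_are_normalized(self, network, fluxes, enrichment):
        res = network.steady_state(fluxes, TracerSpec(enrichment=enrichment))
        for dist in res.distributions.values():
            assert abs(dist.probs.sum() - 1.0) <= 1e-9
            assert np.all(dist.probs >= 0)

    def test_nonconvergence_reports_residual(self, network, mixed_fluxes, tracer):
        with pytest.raises(ConvergenceError) as err:
            network.steady_state(mixed_fluxes, tracer, max_iterations=2)
        assert err.value.residual > 0
        assert err.value.iterations == 2

    def test_deterministic(self, network, mixed_fluxes, tracer):
        a = network.steady_state(mixed_fluxes, tracer)
        b = network.steady_state(mixed_fluxes, tracer)
        for pool in POOLS:
            np.testing.assert_array_equal(
                a.distributions[pool].probs, b.distributions[pool].probs
            )

    def test_fumarase_symmetry_without_carboxylase(self, network, tracer):
        """With no PC inflow, OAA comes only through the symmetric fumarate
        intermediate: C1/C4 and C2/C3 marginals must coincide."""
        res = network.steady_state(FluxParameters(0.7, 0.0, 0.0, 0.25), tracer)
        oaa = res.distributions["OAA"]
        assert oaa.marginal(1) == pytest.approx(oaa.marginal(4), abs=1e-9)
        assert oaa.marginal(2) == pytest.approx(oaa.marginal(3), abs=1e-9)

    def test_succinyl_dilution_is_monotone(self, network, tracer):
        """Raising unlabeled anaplerosis at succinyl-CoA never increases the
        labeled fraction at any glutamate carbon."""
        prev = None
        for y_s in np.linspace(0.0, 1.5, 7):
            res = network.steady_state(FluxParameters(0.6, 0.2, 0.1, y_s), tracer)
            glu = res.distributions["AKG_GLU"]
            marg = np.array([glu.marginal(i) for i in range(1, 6)])
            if prev is not None:
                assert np.all(marg <= prev + 1e-12)
            prev = marg

    def test_natural_abundance_raises_floor(self, network, mixed_fluxes):
        res = network.steady_state(mixed_fluxes, TracerSpec(natural_abundance=0.011))
        base = network.steady_state(mixed_fluxes, TracerSpec())
        glu, glu0 = res.distributions["AKG_GLU"], base.distributions["AKG_GLU"]
        for i in range(1, 6):
            assert glu.marginal(i) > glu0.marginal(i)


class TestFirstTurn:
    def test_pdh_entry_labels_c4_c5_only(self, network, tracer):
        glu = network.first_turn(FluxParameters(1, 0, 0, 0), tracer)["AKG_GLU"]
        assert [glu.marginal(i) for i in range(1, 6)] == pytest.approx([0, 0, 0, 1, 1], abs=1e-12)

    def test_carboxylase_entry_labels_c2_c3_only(self, network, tracer):
        glu = network.first_turn(FluxParameters(0, 0.5, 0, 0), tracer)["AKG_GLU"]
        marg = [glu.marginal(i) for i in range(1, 6)]
        assert marg[0] == marg[3] == marg[4] == pytest.approx(0, abs=1e-12)
        assert marg[1] > 0 and marg[2] > 0


class TestSampler:
    def test_reproducible_for_fixed_seed(self, network, mixed_fluxes, tracer):
        a = network.sample_molecules(mixed_fluxes, tracer, 500, seed=7)
        b = network.sample_molecules(mixed_fluxes, tracer, 500, seed=7)
        for pool in POOLS:
            np.testing.assert_array_equal(a[pool].probs, b[pool].probs)

    def test_closed_system_all_uniformly_labeled(self, network, tracer):
        mc = network.sample_molecules(
            FluxParameters(1, 0, 0, 0), tracer, 2000, seed=3, pools=("AKG_GLU",)
        )
        assert mc["AKG_GLU"].probs[-1] == 1.0

    def test_empirical_probs_sum_to_one(self, network, mixed_fluxes, tracer):
        mc = network.sample_molecules(mixed_fluxes, tracer, 777, seed=5)
        for dist in mc.values():
            assert dist.probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_agrees_with_fixed_point(self, network, mixed_fluxes, tracer):
        """Monte-Carlo back-tracing and the fixed-point solver are
        independent implementations of the same model."""
        p = network.steady_state(mixed_fluxes, tracer).distributions["AKG_GLU"].probs
        n = 20_000
        q = network.sample_molecules(mixed_fluxes, tracer, n, seed=1, pools=("AKG_GLU",))["AKG_GLU"].probs
        se = np.sqrt(np.maximum(p, 1.0 / n) * (1 - np.maximum(p, 1.0 / n)) / n)
        assert np.all(np.abs(q - p) <= 3 * se)

    def test_preconditions(self, network, mixed_fluxes, tracer):
        with pytest.raises(ValueError):
            network.sample_molecules(mixed_fluxes, tracer, 0, seed=1)
        with pytest.raises(ValueError):
            network.sample_molecules(mixed_fluxes, tracer, 10, max_depth=0, seed=1)
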