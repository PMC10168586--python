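"""Model construction: canonical tables, the two model variants, and the
experiment knobs (dopamine, epsilon compensation, size scaling, opto)."""

import numpy as np
import pytest

from bgbeta.builders import (
    ModelConfig,
    OptoPerturbation,
    apply_dopamine,
    apply_opto,
    build_complete_model,
    build_simplified_model,
    calibrate_auxiliary,
    complete_tables,
    population_rate,
    scale_size,
)
from bgbeta.neurons import ConfigurationError
from bgbeta.network import PoissonDrive


@pytest.fixture(scope="module")
def complete_net():
    return build_complete_model(ModelConfig(variant="complete", seed=0))


class TestCompleteModel:
    def test_total_neuron_count(self, complete_net):
        """Six populations summing to 13 872 neurons at n = 1."""
        assert complete_net.n_neurons == 13_872
        sizes = {p.name: p.size for p in complete_net.populations}
        assert sizes == {
            "D1": 6000, "D2": 6000, "FSN": 420,
            "GPTA": 264, "GPTI": 780, "STN": 408,
        }

    def test_connection_table_rows(self, tables):
        """The canonical table holds exactly 19 internal rows plus 6
        external drives, with GPi/SNr absent."""
        assert len(tables["connections"]) == 19
        assert len(tables["drives"]) == 6
        names = set(tables["sizes"])
        assert names == {"D1", "D2", "FSN", "GPTA", "GPTI", "STN"}

    def test_d2_drive_scales_with_dopamine(self, tables):
        net = build_complete_model(ModelConfig(variant="complete", D_d=1.03))
        lo, hi = net.pop_slices["D2"]
        assert np.allclose(net.ext_rate[lo:hi], 1.03 * 1.083)
        lo, hi = net.pop_slices["D1"]
        assert np.allclose(net.ext_rate[lo:hi], 1.12)

    def test_apply_dopamine_identity_and_commutation(self):
        built = build_complete_model(ModelConfig(variant="complete", D_d=1.07))
        net = build_complete_model(ModelConfig(variant="complete", D_d=1.0))
        before = net.ext_rate.copy()
        apply_dopamine(net, 1.0)
        np.testing.assert_array_equal(net.ext_rate, before)
        apply_dopamine(net, 1.07)
        np.testing.assert_allclose(net.ext_rate, built.ext_rate, rtol=1e-12)


class TestSimplifiedModel:
    def test_isolated_loops_at_zero_coupling(self):
        """epsilon = 0: no inter-loop connections; the two loops share no
        pathway and auxiliaries carry the full complement."""
        net = build_simplified_model(
            ModelConfig(variant="simplified", epsilon=0.0)
        )
        pairs = {(c.source, c.target) for c in net.connections}
        for inter in [("D2", "GPTI-A"), ("STN", "GPTI-B"),
                      ("GPTI-A", "FSN"), ("GPTI-B", "STN"),
                      ("GPTI-A", "GPTI-B")]:
            assert inter not in pairs
        assert ("D2*", "GPTI-A") in pairs
        assert ("GPTI*", "STN") in pairs

    def test_auxiliaries_silent_at_full_coupling(self):
        net = build_simplified_model(
            ModelConfig(variant="simplified", epsilon=1.0)
        )
        sources = {c.source for c in net.connections}
        assert not any(s.endswith("*") for s in sources)
        # auxiliary populations still exist but only as drive sinks
        assert {"D2*", "STN*", "GPTI*"} <= set(net.pop_slices)

    def test_half_coupling_probabilities(self):
        """epsilon = 0.5 with p1 = 0.0833 (striato-pallidal): inter-loop
        p = 0.04165 and the halved-size auxiliary doubled to 0.0833."""
        net = build_simplified_model(
            ModelConfig(variant="simplified", epsilon=0.5)
        )
        by_pair = {(c.source, c.target): c.p for c in net.connections}
        assert by_pair[("D2", "GPTI-A")] == pytest.approx(0.5 * 0.0833)
        assert by_pair[("D2*", "GPTI-A")] == pytest.approx(2 * 0.5 * 0.0833)
        assert by_pair[("D2", "GPTI-B")] == pytest.approx(0.0833)

    @pytest.mark.parametrize("eps", [0.0, 0.25, 0.5, 0.75, 1.0])
    def test_input_conservation_across_coupling(self, eps):
        """For every compensated pathway the expected in-degree
        (real + auxiliary sources) is independent of epsilon and equals
        the Complete-Model value."""
        t = complete_tables()
        p1 = {(c.source, c.target): c.p for c in t["connections"]}
        net = build_simplified_model(
            ModelConfig(variant="simplified", epsilon=eps)
        )
        sizes = {p.name: p.size for p in net.populations}
        by_pair = {(c.source, c.target): c.p for c in net.connections}

        def indeg(src, tgt):
            return by_pair.get((src, tgt), 0.0) * sizes.get(src, 0)

        # striato-pallidal input to the GPTI-A half
        assert indeg("D2", "GPTI-A") + indeg("D2*", "GPTI-A") == pytest.approx(
            p1[("D2", "GPTI")] * 6000
        )
        # subthalamic input to the GPTI-B half
        assert indeg("STN", "GPTI-B") + indeg("STN*", "GPTI-B") == pytest.approx(
            p1[("STN", "GPTI")] * 408
        )
        # pallidal input to FSN and to STN (split across halves)
        assert (
            indeg("GPTI-B", "FSN") + indeg("GPTI-A", "FSN")
            + indeg("GPTI*", "FSN")
        ) == pytest.approx(p1[("GPTI", "FSN")] * 780)
        assert (
            indeg("GPTI-A", "STN") + indeg("GPTI-B", "STN")
            + indeg("GPTI*", "STN")
        ) == pytest.approx(p1[("GPTI", "STN")] * 780)

    def test_epsilon_validation(self):
        with pytest.raises(ConfigurationError):
            ModelConfig(variant="simplified", epsilon=1.2)

    def test_d2_aux_drive_follows_dopamine(self):
        """Dopamine scales the external drive of D2 and of its surrogate
        D2* by the same factor and leaves every other drive alone."""
        ref = build_simplified_model(
            ModelConfig(variant="simplified", epsilon=0.5, D_d=1.0)
        )
        net = build_simplified_model(
            ModelConfig(variant="simplified", epsilon=0.5, D_d=1.10)
        )
        for nm in ("D2", "D2*"):
            lo, hi = net.pop_slices[nm]
            assert np.allclose(net.ext_rate[lo:hi], 1.10 * ref.ext_rate[lo:hi])
        for nm in ("STN", "FSN", "GPTI-A", "STN*"):
            lo, hi = net.pop_slices[nm]
            assert np.allclose(net.ext_rate[lo:hi], ref.ext_rate[lo:hi])


class TestSizeScaling:
    def test_identity_at_n1(self, tables):
        sizes, conns = scale_size(tables["sizes"], tables["connections"], 1)
        assert sizes == tables["sizes"]
        assert conns == tables["connections"]

    def test_expected_in_degree_preserved(self, tables):
        for n in (2, 4, 8):
            sizes, conns = scale_size(tables["sizes"], tables["connections"], n)
            for c0, c in zip(tables["connections"], conns):
                assert c.p * sizes[c.source] == pytest.approx(
                    c0.p * tables["sizes"][c0.source]
                )

    def test_realized_in_degree_and_observers_at_n2(self):
        """Built at n = 2: observer subsamples keep the n = 1 sizes and
        the realized in-degree matches the n = 1 expectation within
        binomial noise (checked on the pallido-subthalamic pathway)."""
        net = build_complete_model(ModelConfig(variant="complete", n=2, seed=0))
        assert net.n_neurons == 2 * 13_872
        assert net.observers["GPTI"].size == 780
        assert net.observers["STN"].size == 408
        ci = next(
            i for i, c in enumerate(net.connections)
            if c.source == "GPTI" and c.target == "STN"
        )
        indptr, tgt = net.conn_edges[ci]
        expected = 0.0385 * 780          # per target neuron, n-invariant
        realized = tgt.size / (2 * 408)
        sigma = np.sqrt(tgt.size) / (2 * 408)
        assert abs(realized - expected) < 4 * sigma


class TestOpto:
    def test_cortex_inhibition_arithmetic(self):
        """STN drive 0.75 x 0.5 = 0.375 kHz; exactly 20% of each striatal
        population is reduced to 0.25 x its rate."""
        net = build_complete_model(ModelConfig(
            variant="complete", D_d=1.03,
            opto=OptoPerturbation("cortex_inhibition"),
        ))
        lo, hi = net.pop_slices["STN"]
        assert np.allclose(net.ext_rate[lo:hi], 0.375)
        for nm, base in (("D1", 1.12), ("D2", 1.03 * 1.083), ("FSN", 0.944)):
            lo, hi = net.pop_slices[nm]
            r = net.ext_rate[lo:hi]
            n_motor = np.isclose(r, 0.25 * base).sum()
            assert n_motor == round(0.2 * (hi - lo))
            assert np.isclose(r, base).sum() == (hi - lo) - n_motor

    def test_gpe_inhibition_currents(self):
        """I_e(GPe-TA) = 1 - 480 = -479 pA; I_e(GPe-TI) = 12 - 120 = -108."""
        net = build_complete_model(ModelConfig(
            variant="complete", opto=OptoPerturbation("gpe_inhibition"),
        ))
        assert net.population("GPTA").params.I_e == pytest.approx(-479.0)
        assert net.population("GPTI").params.I_e == pytest.approx(-108.0)
        assert net.population("STN").params.I_e == pytest.approx(5.0)

    def test_kappa_unity_is_identity(self):
        ref = build_complete_model(ModelConfig(variant="complete", D_d=1.03))
        net = build_complete_model(ModelConfig(
            variant="complete", D_d=1.03,
            opto=OptoPerturbation("stn_modulation", kappa=1.0),
        ))
        np.testing.assert_array_equal(net.ext_rate, ref.ext_rate)

    def test_kappa_outside_range_warns(self):
        with pytest.warns(UserWarning):
            build_complete_model(ModelConfig(
                variant="complete",
                opto=OptoPerturbation("stn_modulation", kappa=2.5),
            ))

    def test_opto_commutes_with_build(self):
        built = build_complete_model(ModelConfig(
            variant="complete", D_d=1.03,
            opto=OptoPerturbation("cortex_inhibition"), seed=5,
        ))
        net = build_complete_model(ModelConfig(
            variant="complete", D_d=1.03, seed=5,
        ))
        apply_opto(OptoPerturbation("cortex_inhibition"), net)
        np.testing.assert_allclose(net.ext_rate, built.ext_rate, rtol=1e-12)


class TestAuxiliaryCalibration:
    def test_fixed_point_zero_adjustment(self, tables):
        """Target equal to the current rate returns the current I_e."""
        p = tables["params"]["GPTA"]
        d = PoissonDrive("GPTA", 0.17, 0.15, 0.05)
        r0 = population_rate(p, d, n_neurons=200, duration=1500.0, seed=2)
        ie, r = calibrate_auxiliary(
            p, d, r0, tolerance=0.5, n_neurons=200, duration=1500.0, seed=2
        )
        assert ie == p.I_e

    def test_rate_monotone_in_current(self, tables):
        p = tables["params"]["GPTA"]
        d = PoissonDrive("GPTA", 0.17, 0.15, 0.05)
        r1 = population_rate(p, d, n_neurons=200, duration=1500.0, seed=2)
        r2 = population_rate(p.with_(I_e=p.I_e + 60), d, n_neurons=200,
                             duration=1500.0, seed=2)
        assert r2 > r1

    def test_stn_surrogate_reaches_target(self, tables):
        """The subthalamic surrogate calibrates into the physiological
        window [12, 20] Hz."""
        p = tables["params"]["STN"]
        d = PoissonDrive("STN", 0.5, 0.25, 0.05)
        ie, r = calibrate_auxiliary(
            p, d, 16.0, tolerance=0.5, n_neurons=200, duration=1500.0, seed=2
        )
        assert r == pytest.approx(16.0, abs=0.5)
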