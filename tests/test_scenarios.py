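"""Virtual impairment operations on activation sets."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import emgsim as es


def make_acts():
    grid = np.linspace(0.0, 4.0, 801)
    flex = 0.5 * (1 + np.cos(np.pi * np.clip((grid / 4.0 - 0.3) / 0.25, -1, 1)))
    ext = 0.05 + 0.6 * 0.5 * (1 + np.cos(np.pi * np.clip((grid / 4.0 - 0.75) / 0.2, -1, 1)))
    return es.ActivationSet(
        grid=grid,
        activations={"BIClong": flex, "BRA": 0.8 * flex, "BRD": 0.9 * flex,
                     "TRIlong": ext},
        cycle_span=(0.0, 4.0),
    )


@pytest.fixture()
def acts():
    return make_acts()


class TestWeakness:
    def test_zero_fraction_is_identity(self, acts):
        out = es.apply_weakness(acts, 0.0)
        for m in acts.muscles():
            assert np.array_equal(out.activations[m], acts.activations[m])

    def test_scales_amplitude_without_shifting_timing(self, acts):
        out = es.apply_weakness(acts, 0.2)
        a, b = acts.activations["BIClong"], out.activations["BIClong"]
        assert b.max() == pytest.approx(0.8 * a.max())
        assert np.argmax(b) == np.argmax(a)

    def test_antagonist_untouched(self, acts):
        out = es.apply_weakness(acts, 0.6)
        assert np.max(np.abs(out.activations["TRIlong"]
                             - acts.activations["TRIlong"])) == 0.0

    def test_unknown_target_rejected(self, acts):
        with pytest.raises(es.ConfigurationError):
            es.apply_weakness(acts, 0.2, targets=("DELT",))

    @given(f=st.floats(0.0, 0.9), g=st.floats(0.0, 0.9))
    @settings(max_examples=25, deadline=None)
    def test_composition_is_multiplicative(self, f, g):
        acts = make_acts()
        ab = es.apply_weakness(es.apply_weakness(acts, f), g)
        combined = es.apply_weakness(acts, 1.0 - (1.0 - f) * (1.0 - g))
        for m in es.FLEXORS:
            assert np.allclose(ab.activations[m], combined.activations[m],
                               atol=1e-12)


class TestCoactivation:
    def test_zero_fraction_is_identity(self, acts):
        out = es.apply_coactivation(acts, 0.0)
        assert np.array_equal(out.activations["TRIlong"], acts.activations["TRIlong"])

    def test_scaling_and_clipping(self, acts):
        half = acts.copy()
        half.activations["TRIlong"] = np.full_like(half.grid, 0.5)
        out = es.apply_coactivation(half, 0.6)
        assert np.allclose(out.activations["TRIlong"], 0.8)
        high = acts.copy()
        high.activations["TRIlong"] = np.full_like(high.grid, 0.9)
        out = es.apply_coactivation(high, 0.6)
        assert np.allclose(out.activations["TRIlong"], 1.0)

    def test_flexors_byte_identical(self, acts):
        out = es.apply_coactivation(acts, 0.4)
        for m in es.FLEXORS:
            assert np.array_equal(out.activations[m], acts.activations[m])


class TestSpasticity:
    def test_neutral_parameters_are_identity(self, acts):
        out = es.apply_spasticity(acts, (0.0, 1.0), targets=("BIClong",))
        assert np.allclose(out.activations["BIClong"], acts.activations["BIClong"])

    def test_tonic_floor_on_silent_muscle(self, acts):
        silent = acts.copy()
        silent.activations["BIClong"] = np.zeros_like(silent.grid)
        out = es.apply_spasticity(silent, (0.3, 1.0), targets=("BIClong",))
        assert np.allclose(out.activations["BIClong"], 0.3)

    def test_gain_with_clipping(self, acts):
        tri = acts.copy()
        tri.activations["BIClong"] = 0.6 * acts.activations["BIClong"] / acts.activations["BIClong"].max()
        out = es.apply_spasticity(tri, (0.3, 1.5), targets=("BIClong",))
        vals = out.activations["BIClong"]
        assert vals.max() == pytest.approx(min(1.0, 0.3 + 1.5 * 0.6))
        assert vals.min() == pytest.approx(0.3)

    def test_modulation_depth_never_exceeds_clip_free(self, acts):
        b, g = 0.3, 1.5
        out = es.apply_spasticity(acts, (b, g), targets=("BIClong",))
        a = acts.activations["BIClong"]
        depth = out.activations["BIClong"].max() - out.activations["BIClong"].min()
        assert depth <= g * (a.max() - a.min()) + 1e-12

    def test_invalid_baseline_rejected(self, acts):
        with pytest.raises(es.ConfigurationError):
            es.apply_spasticity(acts, (1.0, 1.5))


class TestTremor:
    def test_zero_amplitude_is_identity(self, acts):
        out = es.apply_tremor(acts, es.ScenarioSpec(kind="tremor", tremor_amplitude=0.0))
        for m in acts.muscles():
            assert np.allclose(out.activations[m], acts.activations[m])

    def test_outside_windows_untouched(self, acts):
        spec = es.ScenarioSpec(kind="tremor", tremor_amplitude=0.6)
        out = es.apply_tremor(acts, spec)
        frac = (acts.grid - acts.cycle_span[0]) / (acts.cycle_span[1] - acts.cycle_span[0])
        outside = (frac < 0.20) | (frac > 0.85)
        for m in es.TREMOR_TARGETS:
            assert np.array_equal(out.activations[m][outside],
                                  acts.activations[m][outside])

    def test_antagonist_modulation_in_antiphase(self, acts):
        # well inside the first window, away from taper ramps and clipping
        lifted = acts.copy()
        for m in acts.muscles():
            lifted.activations[m] = 0.3 + 0.4 * acts.activations[m]
        spec = es.ScenarioSpec(kind="tremor", tremor_amplitude=0.2)
        out = es.apply_tremor(lifted, spec)
        frac = (acts.grid - acts.cycle_span[0]) / (acts.cycle_span[1] - acts.cycle_span[0])
        core = (frac > 0.30) & (frac < 0.50)
        mod_bic = out.activations["BIClong"][core] / lifted.activations["BIClong"][core] - 1
        mod_tri = out.activations["TRIlong"][core] / lifted.activations["TRIlong"][core] - 1
        nonzero = np.abs(mod_bic) > 1e-6
        assert np.all(np.sign(mod_bic[nonzero]) == -np.sign(mod_tri[nonzero]))

    def test_brachialis_spared(self, acts):
        out = es.apply_tremor(acts, es.ScenarioSpec(kind="tremor", tremor_amplitude=0.6))
        assert np.array_equal(out.activations["BRA"], acts.activations["BRA"])

    def test_cycle_mean_nearly_preserved(self, acts):
        for A in (0.2, 0.4, 0.6):
            out = es.apply_tremor(acts, es.ScenarioSpec(kind="tremor", tremor_amplitude=A))
            for m in es.TREMOR_TARGETS:
                before = acts.activations[m].mean()
                after = out.activations[m].mean()
                assert abs(after - before) < 0.05 * A

    def test_empty_windows_rejected(self, acts):
        spec = es.ScenarioSpec(kind="tremor", tremor_amplitude=0.4, tremor_windows=())
        with pytest.raises(es.ConfigurationError):
            es.apply_tremor(acts, spec)


class TestDispatchAndInvariants:
    def test_healthy_is_deep_copy(self, acts):
        out = es.build_scenario_set(acts, es.ScenarioSpec(kind="healthy"))
        for m in acts.muscles():
            assert np.array_equal(out.activations[m], acts.activations[m])
        out.activations["BIClong"][0] = 0.99
        assert acts.activations["BIClong"][0] != 0.99

    def test_dispatch_matches_direct_call(self, acts):
        spec = es.ScenarioSpec(kind="weakness", weakness_fraction=0.4)
        a = es.build_scenario_set(acts, spec)
        b = es.apply_weakness(acts, 0.4)
        for m in acts.muscles():
            assert np.array_equal(a.activations[m], b.activations[m])

    def test_repeat_application_deterministic(self, acts):
        spec = es.ScenarioSpec(kind="tremor", tremor_amplitude=0.4)
        a = es.build_scenario_set(acts, spec)
        b = es.build_scenario_set(acts, spec)
        for m in acts.muscles():
            assert np.array_equal(a.activations[m], b.activations[m])

    @given(
        kind=st.sampled_from(["weakness", "coactivation", "spasticity", "tremor"]),
        sev=st.floats(0.0, 0.95),
    )
    @settings(max_examples=40, deadline=None)
    def test_outputs_always_within_unit_interval(self, kind, sev):
        acts = make_acts()
        spec = es.ScenarioSpec(
            kind=kind,
            weakness_fraction=sev if kind == "weakness" else 0.0,
            coact_fraction=3.0 * sev if kind == "coactivation" else 0.0,
            spasticity_level="severe",
            tremor_amplitude=min(sev, 1.0) if kind == "tremor" else 0.0,
        )
        out = es.build_scenario_set(acts, spec)
        for m in out.muscles():
            assert out.activations[m].min() >= 0.0
            assert out.activations[m].max() <= 1.0 + 1e-12
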