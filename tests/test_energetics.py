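"""Aerobic/lactic volumes, energy conversion and the session partition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ergo import energetics as en
from ergo import gasex_io as gx
from ergo import synthetic_data as sd
from conftest import noiseless_effects


def exercise_series(vo2_fn, rest_vo2=0.3, rest_s=300.0, ex_s=1800.0, dt=3.0):
    t_rest = np.arange(0.0, rest_s, dt)
    t_ex = np.arange(rest_s, rest_s + ex_s + dt / 2, dt)
    vo2 = np.concatenate([np.full(t_rest.size, rest_vo2), vo2_fn(t_ex - rest_s)])
    return gx.BreathSeries(
        t=np.concatenate([t_rest, t_ex]),
        vo2=vo2,
        phase=["rest"] * t_rest.size + ["exercise"] * t_ex.size,
    )


def profile(pre, posts, ex15=None, rec15=None):
    samples = [en.LactateSample("pre", -5.0, pre)]
    if ex15 is not None:
        samples.append(en.LactateSample("ex15", 15.0, ex15))
    for label, t, c in zip(("post0", "post3", "post5", "post7"), (30, 33, 35, 37), posts):
        samples.append(en.LactateSample(label, float(t), c))
    if rec15 is not None:
        samples.append(en.LactateSample("rec15", 45.0, rec15))
    return en.LactateProfile(samples)


class TestAerobicVolume:
    def test_rectangle(self):
        s = exercise_series(lambda t: np.full(t.size, 1.0))
        assert en.aerobic_volume(s, baseline=0.3, duration=30.0) == pytest.approx(21.0, rel=1e-6)

    def test_linear_ramp_triangle_area(self):
        s = exercise_series(lambda t: 0.3 + 1.0 * t / 1800.0)
        assert en.aerobic_volume(s, baseline=0.3, duration=30.0) == pytest.approx(15.0, rel=1e-4)

    def test_below_baseline_returns_negative_with_warning(self):
        s = exercise_series(lambda t: np.full(t.size, 0.2))
        with pytest.warns(en.EnergeticsWarning):
            v = en.aerobic_volume(s, baseline=0.3, duration=30.0)
        assert v == pytest.approx(-3.0, rel=1e-6)

    def test_short_exercise_is_error(self):
        s = exercise_series(lambda t: np.full(t.size, 1.0), ex_s=600.0)
        with pytest.raises(gx.ValidationError, match="shorter"):
            en.aerobic_volume(s, baseline=0.3, duration=30.0)

    def test_integration_limited_to_declared_duration(self):
        # a longer exercise block contributes nothing beyond `duration`
        s_long = exercise_series(lambda t: np.full(t.size, 1.0), ex_s=2400.0)
        assert en.aerobic_volume(s_long, 0.3, 30.0) == pytest.approx(21.0, rel=1e-6)


class TestNetLactate:
    def test_printed_group_means(self):
        # LIE-BFR arm: peak post 2.89 over pre 1.17
        p = profile(1.17, [2.89, 2.5, 2.2, 2.0])
        assert en.net_lactate(p) == pytest.approx(1.72)

    def test_null_accumulation(self):
        p = profile(1.2, [1.2, 1.2, 1.2, 1.2])
        assert en.net_lactate(p) == 0.0

    def test_peak_selection_is_bruteforce_max(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            posts = rng.uniform(0.5, 5.0, 4)
            p = profile(1.0, posts)
            assert en.net_lactate(p) == pytest.approx(max(posts) - 1.0)

    def test_profile_requires_pre_and_post(self):
        with pytest.raises(gx.ValidationError):
            en.LactateProfile([en.LactateSample("pre", -5.0, 1.0)])
        with pytest.raises(gx.ValidationError):
            en.LactateProfile([en.LactateSample("post0", 30.0, 2.0)])


class TestLacticVolume:
    def test_unit_definition(self):
        assert en.lactic_volume(1.0, 1.0) == pytest.approx(0.003)

    def test_table_worked_example(self):
        # 1.72 mmol/L × 3 mL/kg × 82.8 kg = 427.2 mL
        assert en.lactic_volume(1.72, 82.8) == pytest.approx(0.42725, abs=5e-5)

    def test_negative_clamped_with_warning(self):
        with pytest.warns(en.EnergeticsWarning):
            assert en.lactic_volume(-0.2, 80.0) == 0.0

    def test_clamp_switchable(self):
        assert en.lactic_volume(-0.2, 80.0, clamp_negative=False) == pytest.approx(-0.048)

    def test_nonpositive_mass_is_error(self):
        with pytest.raises(ValueError):
            en.lactic_volume(1.0, 0.0)


class TestEnergyConversion:
    def test_default_constant(self):
        assert en.o2_volume_to_energy(1.0) == pytest.approx(20.92)

    def test_zero(self):
        assert en.o2_volume_to_energy(0.0) == 0.0

    def test_session_scale(self):
        assert en.o2_volume_to_energy(21.0) == pytest.approx(439.32)


@pytest.fixture(scope="module")
def session(subject):
    ser, truth = sd.simulate_breath_series(
        subject, noiseless_effects(), "LIE", seed=5, return_truth=True
    )
    prof = sd.simulate_lactate_profile(
        subject, noiseless_effects(), "LIE", seed=6,
        session_la_rise=truth.net_lactate_mmol,
    )
    return ser, prof, truth


class TestPartitionSession:

    def test_components_match_stagewise_calls(self, session, subject):
        ser, prof, _ = session
        rep = en.partition_session(ser, prof, subject.body_mass, seed=1)
        base = gx.baseline_vo2(ser)
        from ergo import kinetics as kin

        assert rep.partition.aerobic_l == pytest.approx(en.aerobic_volume(ser, base))
        fit = kin.fit_off_kinetics(ser, seed=1)
        assert rep.partition.alactic_l == pytest.approx(kin.alactic_volume(fit))
        assert rep.partition.lactic_l == pytest.approx(
            en.lactic_volume(en.net_lactate(prof), subject.body_mass)
        )

    def test_zero_noise_partition_matches_ground_truth(self, session, subject):
        ser, prof, truth = session
        p = en.partition_session(ser, prof, subject.body_mass, seed=1).partition
        assert p.aerobic_l == pytest.approx(truth.aerobic_l, rel=0.01)
        assert p.alactic_l == pytest.approx(truth.alactic_l, rel=0.01)
        assert p.lactic_l == pytest.approx(truth.lactic_l, rel=0.01)
        assert p.total_l == pytest.approx(truth.total_l, rel=0.01)

    def test_total_is_exact_sum(self, session, subject):
        ser, prof, _ = session
        p = en.partition_session(ser, prof, subject.body_mass, seed=1).partition
        assert p.total_l == p.aerobic_l + p.alactic_l + p.lactic_l
        assert p.total_kj == pytest.approx(p.total_l * p.caloric_equiv)

    def test_missing_profile_names_lactate_stage(self, session, subject):
        ser, _, _ = session
        with pytest.raises(en.StageError, match="lactate"):
            en.partition_session(ser, None, subject.body_mass)

    def test_doubling_mass_doubles_lactic_only(self, session, subject):
        ser, prof, _ = session
        p1 = en.partition_session(ser, prof, subject.body_mass, seed=1).partition
        p2 = en.partition_session(ser, prof, 2 * subject.body_mass, seed=1).partition
        assert p2.lactic_l == pytest.approx(2 * p1.lactic_l)
        assert p2.aerobic_l == pytest.approx(p1.aerobic_l)
        assert p2.alactic_l == pytest.approx(p1.alactic_l)

    def test_raising_exercise_vo2_raises_aerobic(self, session, subject):
        ser, prof, _ = session
        bumped = gx.BreathSeries(
            t=ser.t,
            vo2=np.where(ser.phase_mask("exercise"), ser.vo2 + 0.1, ser.vo2),
            phase=[p.value for p in ser.phase],
        )
        base = gx.baseline_vo2(ser)
        assert en.aerobic_volume(bumped, base) > en.aerobic_volume(ser, base)

    def test_raising_peak_lactate_raises_lactic(self, subject):
        lo = profile(1.0, [2.0, 1.8, 1.6, 1.4])
        hi = profile(1.0, [2.5, 1.8, 1.6, 1.4])
        assert en.lactic_volume(en.net_lactate(hi), subject.body_mass) > en.lactic_volume(
            en.net_lactate(lo), subject.body_mass
        )


@given(delta=st.floats(0.0, 5.0), mass=st.floats(40.0, 130.0))
@settings(deadline=None, derandomize=True)
def test_lactic_volume_is_bilinear(delta, mass):
    v = en.lactic_volume(delta, mass)
    assert v == pytest.approx(delta * 3.0 * mass / 1000.0)
    assert en.lactic_volume(delta, 2 * mass) == pytest.approx(2 * v)
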