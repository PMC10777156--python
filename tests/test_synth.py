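"""Synthetic experiment generator: design, trajectories, traces, dropout."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import peatstab as ps
from peatstab.core import DESIGN_FRACTIONS, Phase, Treatment
from peatstab.errors import ConfigurationError, InvalidArgumentError
from peatstab.synth import DEFAULT_DEEP_SLOPES, DEFAULT_MILD_SLOPES, default_schedule

from conftest import single_cell_design


class TestMixtureComposition:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(InvalidArgumentError):
            ps.MixtureComposition(0.5, 0.4)

    @given(st.floats(min_value=-1.0, max_value=2.0))
    def test_from_cuspidatum_validates_range(self, f):
        if 0.0 <= f <= 1.0:
            comp = ps.MixtureComposition.from_cuspidatum(f)
            assert comp.cuspidatum_fraction + comp.medium_fraction == pytest.approx(1.0)
        else:
            with pytest.raises(InvalidArgumentError):
                ps.MixtureComposition.from_cuspidatum(f)


class TestBuildDesign:
    @pytest.mark.parametrize("n_reps,total", [(1, 10), (4, 40)])
    def test_design_size(self, n_reps, total):
        design = ps.build_design(n_reps, seed=0)
        assert len(design) == total

    def test_full_design_balance(self):
        """Forty cores: eight per mixture, four per mixture x treatment."""
        design = ps.build_design(4, seed=7)
        per_comp: dict[float, int] = {}
        per_cell: dict[tuple[float, Treatment], int] = {}
        for rec in design:
            f = rec.composition.cuspidatum_fraction
            per_comp[f] = per_comp.get(f, 0) + 1
            per_cell[(f, rec.treatment)] = per_cell.get((f, rec.treatment), 0) + 1
        assert per_comp == {f: 8 for f in DESIGN_FRACTIONS}
        assert all(v == 4 for v in per_cell.values())
        assert len(per_cell) == 10

    @given(st.integers(min_value=1, max_value=6), st.integers(min_value=0, max_value=100))
    def test_balance_and_unique_ids_for_any_size(self, n_reps, seed):
        design = ps.build_design(n_reps, seed=seed)
        assert len({r.mesocosm_id for r in design}) == 10 * n_reps
        cells = {}
        for rec in design:
            key = (rec.composition.cuspidatum_fraction, rec.treatment)
            cells[key] = cells.get(key, 0) + 1
        assert all(v == n_reps for v in cells.values())

    def test_seeded_determinism(self):
        assert ps.build_design(4, seed=5) == ps.build_design(4, seed=5)

    def test_invalid_replicates(self):
        with pytest.raises(InvalidArgumentError):
            ps.build_design(0)


class TestSchedule:
    def test_default_calendar(self):
        mild = default_schedule(Treatment.MILD)
        deep = default_schedule(Treatment.DEEP)
        assert mild.phase_bounds[Phase.ACCLIMATION] == (0, 11)
        assert mild.phase_bounds[Phase.MILD_DRAWDOWN] == (11, 18)
        assert Phase.DEEP_DRAWDOWN not in mild.phase_bounds
        assert mild.phase_bounds[Phase.RECOVERY] == (18, 74)
        assert deep.phase_bounds[Phase.DEEP_DRAWDOWN] == (18, 32)
        assert deep.phase_bounds[Phase.RECOVERY] == (32, 88)

    def test_measurement_cadence(self):
        """Three acclimation visits; 4/week in drawdown; 2/week in recovery."""
        deep = default_schedule(Treatment.DEEP)
        assert deep.measurement_days[Phase.ACCLIMATION] == (0, 2, 10)
        assert len(deep.measurement_days[Phase.MILD_DRAWDOWN]) == 4
        assert len(deep.measurement_days[Phase.DEEP_DRAWDOWN]) == 8
        assert len(deep.measurement_days[Phase.RECOVERY]) == 16

    def test_non_contiguous_phases_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ps.PhaseSchedule(
                {Phase.ACCLIMATION: (0, 11), Phase.MILD_DRAWDOWN: (12, 19)},
                {Phase.ACCLIMATION: (0,), Phase.MILD_DRAWDOWN: (13,)},
            )


class TestGenerateNeeSeries:
    def test_noiseless_acclimation_is_flat_baseline(self, noiseless_config):
        noiseless_config.baseline_nee = {f: 1.0 for f in DESIGN_FRACTIONS}
        design = single_cell_design(1.0, Treatment.MILD, 1)
        (s,) = ps.generate_nee_series(design, None, noiseless_config)
        assert s.phase_values(Phase.ACCLIMATION) == pytest.approx([1.0, 1.0, 1.0], abs=0)

    def test_noiseless_mild_drawdown_end_value(self, noiseless_config):
        """Baseline 1.0 with slope 0.20/day for 7 days ends at 2.4."""
        noiseless_config.baseline_nee = {f: 1.0 for f in DESIGN_FRACTIONS}
        design = single_cell_design(1.0, Treatment.MILD, 1)
        (s,) = ps.generate_nee_series(design, None, noiseless_config)
        assert s.phase_values(Phase.MILD_DRAWDOWN)[-1] == pytest.approx(1.0 + 0.20 * 7, abs=1e-12)

    def test_phase_entry_continuity_deep_arm(self, noiseless_config):
        """Deep phase starts from the mild phase's noiseless end value."""
        design = single_cell_design(1.0, Treatment.DEEP, 1)
        (s,) = ps.generate_nee_series(design, None, noiseless_config)
        mild_end = noiseless_config.baseline_nee[1.0] + DEFAULT_MILD_SLOPES[1.0] * 7
        deep_days = s.phase_days(Phase.DEEP_DRAWDOWN)
        expected = mild_end + DEFAULT_DEEP_SLOPES[1.0] * (deep_days[0] - 18)
        assert s.phase_values(Phase.DEEP_DRAWDOWN)[0] == pytest.approx(expected, abs=1e-12)

    def test_noiseless_slope_recovery_is_exact(self, noiseless_config):
        """OLS on exact linear data returns the configured slope."""
        design = single_cell_design(0.5, Treatment.DEEP, 50)
        series = ps.generate_nee_series(design, None, noiseless_config)
        slopes = [ps.phase_slope(s, Phase.DEEP_DRAWDOWN)[0] for s in series]
        assert slopes == pytest.approx([DEFAULT_DEEP_SLOPES[0.5]] * 50, abs=1e-9)

    def test_missing_slope_entry_names_key(self):
        config = ps.GeneratorConfig.default()
        del config.phase_slope[(0.5, Treatment.DEEP, Phase.DEEP_DRAWDOWN)]
        design = single_cell_design(0.5, Treatment.DEEP, 2)
        with pytest.raises(ConfigurationError, match="deep_drawdown"):
            ps.generate_nee_series(design, None, config)

    def test_seeded_determinism(self):
        design = ps.build_design(2, seed=3)
        config = ps.GeneratorConfig.default(seed=9)
        a = ps.generate_nee_series(design, None, config)
        b = ps.generate_nee_series(design, None, config)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.nee, sb.nee)
            np.testing.assert_array_equal(sa.days, sb.days)

    def test_slope_scatter_grows_with_noise(self):
        """SD of fitted slopes across mesocosms is monotone in noise_sd."""
        design = single_cell_design(1.0, Treatment.MILD, 200)
        sds = []
        for noise in (0.1, 0.45, 0.9):
            config = ps.GeneratorConfig.default(seed=11, noise_sd=noise)
            series = ps.generate_nee_series(design, None, config)
            slopes = [ps.phase_slope(s, Phase.MILD_DRAWDOWN)[0] for s in series]
            sds.append(np.std(slopes))
        assert sds[0] < sds[1] < sds[2]

    def test_mild_arm_rewets_to_baseline(self, noiseless_config):
        design = single_cell_design(1.0, Treatment.MILD, 1)
        (s,) = ps.generate_nee_series(design, None, noiseless_config)
        base = noiseless_config.baseline_nee[1.0]
        rec = s.phase_values(Phase.RECOVERY)
        assert rec[0] == pytest.approx(base, abs=1e-12)  # immediate return

    def test_deep_arm_recovery_is_continuous(self, noiseless_config):
        design = single_cell_design(1.0, Treatment.DEEP, 1)
        (s,) = ps.generate_nee_series(design, None, noiseless_config)
        deep_end = (
            noiseless_config.baseline_nee[1.0]
            + DEFAULT_MILD_SLOPES[1.0] * 7
            + DEFAULT_DEEP_SLOPES[1.0] * 14
        )
        rec_days = s.phase_days(Phase.RECOVERY)
        rec_slope = noiseless_config.phase_slope[(1.0, Treatment.DEEP, Phase.RECOVERY)]
        expected = deep_end + rec_slope * (rec_days[0] - 32)
        assert s.phase_values(Phase.RECOVERY)[0] == pytest.approx(expected, abs=1e-12)


class TestConcentrationTraces:
    def test_zero_flux_gives_flat_trace(self):
        tr = ps.generate_concentration_trace(0.0, ambient_co2=420.0)
        assert np.all(tr.co2_ppm == 420.0)

    def test_uptake_decreases_concentration(self):
        tr = ps.generate_concentration_trace(1.0)
        c = dict(zip(tr.time_s, tr.co2_ppm))
        assert c[120.0] < c[30.0]

    def test_roundtrip_recovers_nee(self):
        tr = ps.generate_concentration_trace(1.0)
        assert ps.trace_to_nee(tr).nee == pytest.approx(1.0, abs=1e-9)

    def test_short_duration_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ps.generate_concentration_trace(1.0, duration_s=30)

    def test_roundtrip_over_random_conditions(self):
        """Noiseless trace -> flux inverts exactly over random physics."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            nee = rng.uniform(-3, 3)
            chamber = ps.ChamberSpec(
                chamber_diameter=rng.uniform(0.2, 0.5),
                chamber_height=rng.uniform(0.2, 0.5),
                collar_diameter=rng.uniform(0.1, 0.2),
                air_temperature=rng.uniform(278, 310),
                pressure=rng.uniform(9e4, 1.1e5),
            )
            tr = ps.generate_concentration_trace(nee, chamber=chamber)
            assert ps.trace_to_nee(tr).nee == pytest.approx(nee, abs=1e-9)


class TestApplyMissingness:
    def test_drop_one_of_forty(self):
        _, series = ps.simulate_experiment(ps.GeneratorConfig.default(seed=0))
        assert len(series) == 40
        kept = ps.apply_missingness(series, "DD_75-25_r1")
        assert len(kept) == 39
        assert all(s.mesocosm_id != "DD_75-25_r1" for s in kept)

    def test_unknown_id_raises(self):
        _, series = ps.simulate_experiment(ps.GeneratorConfig.default(seed=0))
        with pytest.raises(KeyError):
            ps.apply_missingness(series, "nope")

    def test_removal_is_local(self):
        """Only the affected cell loses a replicate."""
        _, series = ps.simulate_experiment(ps.GeneratorConfig.default(seed=0))
        kept = ps.apply_missingness(series, "DD_75-25_r1")
        counts: dict[tuple[float, Treatment], int] = {}
        for s in kept:
            key = (s.composition.cuspidatum_fraction, s.treatment)
            counts[key] = counts.get(key, 0) + 1
        assert counts[(0.75, Treatment.DEEP)] == 3
        assert all(v == 4 for k, v in counts.items() if k != (0.75, Treatment.DEEP))
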