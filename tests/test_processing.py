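"""Replicate processing: calibrator, scaling/merging, error models."""

import numpy as np
import pandas as pd
import pytest

from hepg1s.processing import (
    ErrorModel,
    compute_sem,
    estimate_constant_error,
    estimate_linear_error,
    normalize_by_calibrator,
    normalize_dataset,
    scale_and_merge,
)
from hepg1s.simulate import ExperimentProtocol, compute_observables, simulate
from hepg1s.synth import NoiseSpec, generate_timecourses


def _table(times, intensities_by_rep, calibrators=None):
    rows = []
    for r, y in intensities_by_rep.items():
        rows.append(
            pd.DataFrame(
                {
                    "observable": "x", "condition": "c", "time_h": times,
                    "replicate": r, "intensity": y,
                    "calibrator": (calibrators or {}).get(r, 1.0),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


class TestCalibrator:
    def test_unit_calibrator_is_identity(self):
        t = _table([0, 1, 2], {0: [1.0, 2.0, 3.0]})
        out = normalize_by_calibrator(t)
        assert np.allclose(out["intensity"], t["intensity"])

    def test_calibrator_two_halves_intensities(self):
        t = _table([0, 1], {0: [2.0, 4.0]}, calibrators={0: 2.0})
        out = normalize_by_calibrator(t)
        assert np.allclose(out["intensity"], [1.0, 2.0])

    def test_replicates_identical_up_to_calibrator_ratio_align(self):
        y = np.array([1.0, 2.0, 3.0])
        t = _table([0, 1, 2], {0: y, 1: 5 * y}, calibrators={0: 1.0, 1: 5.0})
        out = normalize_by_calibrator(t)
        a = out[out["replicate"] == 0]["intensity"].to_numpy()
        b = out[out["replicate"] == 1]["intensity"].to_numpy()
        assert np.allclose(a, b)

    def test_nonpositive_calibrator_rejected(self):
        t = _table([0], {0: [1.0]}, calibrators={0: 0.0})
        with pytest.raises(ValueError):
            normalize_by_calibrator(t)


class TestScaleAndMerge:
    def test_single_replicate_passes_through(self):
        times = np.linspace(0, 10, 8)
        y = np.sin(times) + 2
        ds = scale_and_merge(_table(times, {0: y}))
        assert ds.scales == (1.0,)
        assert np.allclose(ds.means, y)
        assert np.all(np.isnan(ds.sds))

    def test_factor_two_replicates_recover_scale_ratio(self):
        times = np.linspace(0, 20, 15)
        y = 1 + np.exp(-0.2 * times) * np.sin(times / 2) + times / 20
        ds = scale_and_merge(_table(times, {0: y, 1: 2 * y}))
        ratio = ds.scales[1] / ds.scales[0]
        assert ratio == pytest.approx(0.5, abs=1e-6)
        # merged curve matches the first replicate up to one global factor
        merged_over_y = ds.means / y
        assert np.std(merged_over_y) / np.mean(merged_over_y) < 1e-9

    def test_merged_shape_scale_invariant(self):
        times = np.linspace(0, 20, 12)
        y = 2 + np.cos(times / 3)
        reps = {0: y, 1: 1.7 * y, 2: 0.6 * y}
        d1 = normalize_dataset(scale_and_merge(_table(times, reps)))
        d2 = normalize_dataset(
            scale_and_merge(_table(times, {r: 10 * v for r, v in reps.items()}))
        )
        assert np.allclose(d1.means, d2.means, rtol=1e-8)

    def test_closed_loop_with_generator_scale_spread_only(self, network, truth):
        noise = NoiseSpec(relative_cv=0.0, replicate_scale_sd=0.4, seed=21)
        times = np.linspace(0, 72, 19)
        proto = ExperimentProtocol(hgf_dose=40.0)
        table = generate_timecourses(truth, network, proto, ["p21_total"], 4, noise, times)
        ds = scale_and_merge(table)
        tr = simulate(network, truth, proto, times)
        y = compute_observables(tr, network, truth)["p21_total"]
        mask = y > 0.05
        ratio = ds.means[mask] / y[mask]
        assert np.std(ratio) / np.mean(ratio) < 1e-6

    def test_all_zero_replicate_rejected(self):
        t = _table([0, 1], {0: [0.0, 0.0]})
        with pytest.raises(ValueError):
            scale_and_merge(t)


class TestErrorModels:
    def test_zero_sd_gives_zero_relative_error(self):
        em = estimate_linear_error([1.0, 2.0], [0.0, 0.0])
        assert em.relative_error == 0.0

    def test_closed_form_two_point_slope(self):
        em = estimate_linear_error([1.0, 2.0], [0.1, 0.2])
        assert em.relative_error == pytest.approx(0.1)

    def test_through_origin_regression_matches_naive_loop(self):
        rng = np.random.default_rng(0)
        m = rng.uniform(0.5, 3, 50)
        s = 0.15 * m + rng.normal(0, 0.01, 50)
        em = estimate_linear_error(m, s)
        num = sum(mi * si for mi, si in zip(m, s))
        den = sum(mi * mi for mi in m)
        assert em.relative_error == pytest.approx(num / den, rel=1e-12)

    def test_monte_carlo_recovery_of_cv(self):
        rng = np.random.default_rng(7)
        means = rng.uniform(0.5, 2.0, 200)
        reps = means[None, :] * (1 + 0.1 * rng.standard_normal((5, 200)))
        em = estimate_linear_error(reps.mean(axis=0), reps.std(axis=0, ddof=1))
        assert em.relative_error == pytest.approx(0.10, abs=0.02)

    def test_insufficient_points_rejected(self):
        with pytest.raises(ValueError):
            estimate_linear_error([1.0], [0.1])

    def test_constant_error_is_average_sd(self):
        em = estimate_constant_error([0.04, 0.08, np.nan])
        assert em.kind == "constant"
        assert em.sd == pytest.approx(0.06)


class TestSem:
    def test_linear_sem_formula(self):
        from hepg1s.processing import TimeCourseDataset

        ds = TimeCourseDataset("x", "c", np.array([0.0]), np.array([1.0]), None,
                               np.array([4]))
        out = compute_sem(ds, ErrorModel("linear", relative_error=0.2))
        assert out.sems[0] == pytest.approx(0.1)

    def test_single_replicate_sem_equals_relative_error(self):
        from hepg1s.processing import TimeCourseDataset

        ds = TimeCourseDataset("x", "c", np.array([0.0]), np.array([1.5]), None,
                               np.array([1]))
        out = compute_sem(ds, ErrorModel("linear", relative_error=0.2))
        assert out.sems[0] == pytest.approx(0.3)

    def test_constant_sem_formula(self):
        from hepg1s.processing import TimeCourseDataset

        ds = TimeCourseDataset("dna", "c", np.array([0.0]), np.array([1.0]), None,
                               np.array([9]))
        out = compute_sem(ds, ErrorModel("constant", sd=0.06))
        assert out.sems[0] == pytest.approx(0.02)


class TestNormalization:
    def _dataset(self, means, obs="x"):
        from hepg1s.processing import TimeCourseDataset

        means = np.asarray(means, float)
        return TimeCourseDataset(obs, "c", np.arange(means.size, dtype=float) * 24,
                                 means, means * 0.1, np.full(means.size, 3))

    def test_protein_unit_mean(self):
        out = normalize_dataset(self._dataset([2.0, 4.0]))
        assert np.allclose(out.means, [2 / 3, 4 / 3])
        assert np.mean(out.means) == pytest.approx(1.0)

    def test_idempotent(self):
        once = normalize_dataset(self._dataset([2.0, 4.0]))
        twice = normalize_dataset(once)
        assert np.allclose(once.means, twice.means)
        assert np.allclose(once.sems, twice.sems)

    def test_dna_anchored_at_stimulation(self):
        ds = self._dataset([0.5, 1.0], obs="dna")
        out = normalize_dataset(ds, t_stim=0.0)
        assert np.allclose(out.means, [1.0, 2.0])
        assert out.normalization == "anchored-at-stimulation"

    def test_zero_normalizer_rejected(self):
        ds = self._dataset([0.0, 0.0])
        with pytest.raises(ValueError):
            normalize_dataset(ds)
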