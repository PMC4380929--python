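"""Calibration machinery: objective, perturbation, multi-start, ensembles."""

from dataclasses import replace

import numpy as np
import pytest

from hepg1s.calibration import (
    FitResult,
    chi2,
    multistart_fit,
    parameter_spread,
    perturb_start,
    select_best,
)
from hepg1s.processing import TimeCourseDataset
from hepg1s.simulate import ExperimentProtocol, compute_observables, simulate

PROTOCOLS = {"hgf40": ExperimentProtocol(hgf_dose=40.0)}


def _noiseless_datasets(network, truth, observables, times, sem_frac=0.1):
    tr = simulate(network, truth, PROTOCOLS["hgf40"], times)
    obs = compute_observables(tr, network, truth)
    out = []
    for name in observables:
        y = obs[name]
        out.append(
            TimeCourseDataset(
                observable=name, condition="hgf40", times=times, means=y,
                sems=np.maximum(sem_frac * np.abs(y), 0.02),
                n_replicates=np.full(times.size, 3),
            )
        )
    return out


class TestChi2:
    def test_zero_at_generating_parameters(self, network, truth):
        ds = _noiseless_datasets(network, truth, ["dna"], np.linspace(8, 72, 9))
        assert chi2(truth, network, ds, PROTOCOLS) == pytest.approx(0.0, abs=1e-10)

    def test_one_sem_offset_contributes_one(self, network, truth):
        times = np.array([48.0])
        ds = _noiseless_datasets(network, truth, ["dna"], times)[0]
        shifted = replace(ds, means=ds.means + ds.sems)
        assert chi2(truth, network, [shifted], PROTOCOLS) == pytest.approx(1.0, abs=1e-6)

    def test_hand_built_three_point_sum(self, network, truth):
        times = np.array([24.0, 48.0, 72.0])
        ds = _noiseless_datasets(network, truth, ["dna"], times)[0]
        offsets = np.array([1.0, -2.0, 0.5])  # in units of SEM
        shifted = replace(ds, means=ds.means + offsets * ds.sems)
        expected = float(np.sum(offsets**2))
        assert chi2(truth, network, [shifted], PROTOCOLS) == pytest.approx(expected, rel=1e-6)

    def test_zero_sem_points_excluded_with_warning(self, network, truth):
        times = np.array([24.0, 48.0])
        ds = _noiseless_datasets(network, truth, ["dna"], times)[0]
        ds = replace(ds, sems=np.array([0.0, 0.1]), means=ds.means + np.array([5.0, 0.0]))
        with pytest.warns(UserWarning, match="SEM=0"):
            val = chi2(truth, network, [ds], PROTOCOLS)
        assert val == pytest.approx(0.0, abs=1e-8)


class _ForcedRng:
    """Stub RNG that returns a fixed normal deviate."""

    def __init__(self, value):
        self.value = value

    def standard_normal(self, size):
        return np.full(size, self.value)


class TestPerturbation:
    def test_zero_strength_is_identity(self, truth):
        out = perturb_start(truth, 0.0, np.random.default_rng(0))
        assert out.values == truth.values

    def test_printed_formula_with_unit_deviate(self, truth):
        """p = 1 disturbed at s = 1.5 with eps = 1 maps to 10^1.5."""
        base = truth.with_updates(sc_cyce_cdk2=1.0)
        out = perturb_start(base, 1.5, _ForcedRng(1.0))
        assert out.values["sc_cyce_cdk2"] == pytest.approx(10**1.5)
        assert out.values["sc_cyce_cdk2"] == pytest.approx(31.6228, abs=1e-4)

    def test_fixed_parameters_untouched(self, truth):
        out = perturb_start(truth, 1.5, np.random.default_rng(1))
        for name in set(truth.values) - set(truth.free):
            assert out.values[name] == truth.values[name]

    def test_log10_spread_matches_strength(self, truth):
        rng = np.random.default_rng(2)
        base = truth.with_updates(k_akt=1.0)
        draws = np.array(
            [np.log10(perturb_start(base, 0.8, rng).values["ks_cyce"]) for _ in range(2000)]
        )
        centered = draws - np.log10(truth.values["ks_cyce"])
        assert np.std(centered) == pytest.approx(0.8, abs=0.05)

    def test_clipped_to_bounds(self, truth):
        out = perturb_start(truth, 1.5, _ForcedRng(10.0))
        for name in out.free:
            lo, hi = out.bounds_for(name)
            assert np.log10(out.values[name]) <= hi + 1e-12


class TestMultistart:
    def test_single_start_zero_strength_converges_immediately(self, network, truth):
        ds = _noiseless_datasets(network, truth, ["dna", "pcdk2_t160"],
                                 np.linspace(8, 72, 9))
        small = replace(truth, free=("k_dna", "ks_cyce"))
        res = multistart_fit(network, small, ds, PROTOCOLS, n_starts=1, s=0.0,
                             max_iter=50, seed=0)
        assert len(res) == 1
        assert res[0].chi2 == pytest.approx(0.0, abs=1e-6)

    def test_deterministic_given_seed(self, network, truth):
        ds = _noiseless_datasets(network, truth, ["dna"], np.linspace(8, 72, 5))
        small = replace(truth, free=("k_dna",))
        r1 = multistart_fit(network, small, ds, PROTOCOLS, n_starts=3, s=0.5,
                            max_iter=20, seed=42)
        r2 = multistart_fit(network, small, ds, PROTOCOLS, n_starts=3, s=0.5,
                            max_iter=20, seed=42)
        assert [a.chi2 for a in r1] == [b.chi2 for b in r2]
        assert [a.params.values["k_dna"] for a in r1] == [
            b.params.values["k_dna"] for b in r2
        ]

    def test_default_free_mask_spans_52_dimensions(self, truth):
        assert truth.n_free == 52
        kinetic = [p for p in truth.free if not p.startswith(("sc_", "k_akt", "k_erk", "tf_basal"))]
        scaling = [p for p in truth.free if p.startswith("sc_")]
        inputs = [p for p in truth.free if p in ("k_akt", "k_erk", "tf_basal")]
        assert (len(kinetic), len(scaling), len(inputs)) == (45, 4, 3)


class TestSelection:
    def _results(self, chis):
        from hepg1s.parameters import default_parameters

        p = default_parameters()
        return [
            FitResult(params=p, chi2=c, n_iterations=1, converged=True, start_index=i)
            for i, c in enumerate(chis)
        ]

    def test_best_ten_of_twelve(self):
        res = self._results([5, 3, 8, 1, 9, 2, 7, 4, 6, 10, 11, 0])
        best = select_best(res, 10)
        assert [r.chi2 for r in best] == sorted([r.chi2 for r in res])[:10]

    def test_k_one_is_argmin(self):
        res = self._results([5.0, 1.0, 3.0])
        assert select_best(res, 1)[0].chi2 == 1.0

    def test_ties_break_by_start_index(self):
        res = self._results([2.0, 2.0, 2.0, 2.0])
        best = select_best(res, 2)
        assert [r.start_index for r in best] == [0, 1]

    def test_fewer_than_k_warns_and_returns_all(self):
        res = self._results([1.0, 2.0])
        with pytest.warns(UserWarning):
            best = select_best(res, 10)
        assert len(best) == 2


class TestSpread:
    def test_identical_members_have_zero_spread(self, truth):
        res = [
            FitResult(params=truth, chi2=0.0, n_iterations=1, converged=True, start_index=i)
            for i in range(10)
        ]
        spread = parameter_spread(res)
        for q in spread.values():
            assert q["q10"] == q["q90"] == q["median"]

    def test_hand_built_quantiles(self, truth):
        vals = [10.0**v for v in range(1, 11)]  # log10 = 1..10
        res = [
            FitResult(
                params=truth.with_updates(k_dna=v), chi2=0.0,
                n_iterations=1, converged=True, start_index=i,
            )
            for i, v in enumerate(vals)
        ]
        q = parameter_spread(res)["k_dna"]
        logs = np.arange(1.0, 11.0)
        assert q["median"] == pytest.approx(np.percentile(logs, 50))
        assert q["q25"] == pytest.approx(np.percentile(logs, 25))
        assert q["q90"] == pytest.approx(np.percentile(logs, 90))
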