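"""Multi-start calibration on synthetic data with a known ground truth.

Generates noiseless observations from the reference parameters, perturbs
four free parameters by up to several orders of magnitude (strength
s = 1.5) and runs a scaled-down multi-start trust-region fit in log10
space.  The production profile uses the same machinery with the full
52-parameter mask and ~1000 starts.
"""

from dataclasses import replace

import numpy as np

import hepg1s as h
from hepg1s.calibration import multistart_fit, parameter_spread, select_best
from hepg1s.processing import TimeCourseDataset

network = h.default_network()
truth = h.default_parameters()

FREE = ("ks_cyce", "k_dna", "kd_rb_e2f", "k_t160_dephos")
start = replace(truth, free=FREE)

protocols = {
    "hgf0": h.ExperimentProtocol(hgf_dose=0.0),
    "hgf40": h.ExperimentProtocol(hgf_dose=40.0),
}
times = np.linspace(4.0, 72.0, 13)
datasets = []
for cond, proto in protocols.items():
    traj = h.simulate(network, truth, proto, times)
    obs = h.compute_observables(traj, network, truth)
    for name in ("pcdk2_t160", "e2f1_total", "dna", "cyce_cdk2"):
        y = obs[name]
        datasets.append(
            TimeCourseDataset(
                observable=name, condition=cond, times=times, means=y,
                sems=np.maximum(0.1 * np.abs(y), 0.02),
                n_replicates=np.full(times.size, 3),
            )
        )

results = multistart_fit(
    network, start, datasets, protocols, n_starts=8, s=1.5, seed=1,
    max_iter=60, sim_rtol=1e-5, sim_atol=1e-8,
)
print("chi-square of the 8 estimation runs (sorted):")
print("  " + ", ".join(f"{r.chi2:.2e}" for r in results))

best = select_best(results, 5)
spread = parameter_spread(best)
print("\nbest-5 ensemble, log10 spread vs truth:")
for name in FREE:
    q = spread[name]
    print(f"  {name:15s} truth {np.log10(truth.values[name]):+.3f}  "
          f"median {q['median']:+.3f}  IQR [{q['q25']:+.3f}, {q['q75']:+.3f}]")
print("\n(a chi-square near 0 means the noiseless data are reproduced; "
      "narrow IQRs mark identifiable parameters)")
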