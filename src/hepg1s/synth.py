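"""Synthetic-data generation with the statistical structure of the assays.

Every downstream stage of the pipeline (processing, calibration, EC50 and
single-cell analyses) is exercised on data from this module, generated
from the reference model ("truth") rather than from wet-lab measurements:

* immunoblot-like time courses -- per-replicate multiplicative scale
  factors (gels are in arbitrary units), signal-proportional noise
  (constant relative error), and a spiked recombinant-calibrator column;
* DNA-content (Sybr-Green-like) assays -- additive constant-variance
  noise, normalized to 1 at the stimulation time;
* dose-response tables -- one readout per dose at a configured time after
  stimulation (default 48 h);
* Fucci-like two-channel single-cell tracks sampled every 15 min for up to
  60 h, with a latent per-cell phase sequence whose responder probability
  follows a four-parameter Hill curve in HGF dose.

A single integer seed drives all sub-generators through independent
spawned streams, so any table is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import ReactionNetwork
from .parameters import ParameterSet
from .simulate import ExperimentProtocol, compute_observables, simulate

__all__ = [
    "NoiseSpec",
    "HillSpec",
    "TrackGeneratorSpec",
    "generate_timecourses",
    "generate_dna_content",
    "generate_dose_response",
    "generate_tracks",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Noise structure of the population assays.

    ``relative_cv`` -- proportional (linear-error-model) noise of blot-like
    observables; ``constant_sd`` -- additive noise of DNA-content assays;
    ``replicate_scale_sd`` -- log10-SD of the per-replicate multiplicative
    scale factors (log-normal, median 1; the assays are in arbitrary units
    that differ per gel).  The default spread of 0.3 decades is a stated
    package choice, adjustable in config.
    """

    relative_cv: float = 0.1
    constant_sd: float = 0.06
    replicate_scale_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("relative_cv", "constant_sd", "replicate_scale_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(stream + 1)[stream])


@dataclass(frozen=True)
class HillSpec:
    """Four-parameter Hill curve ``base + amp * x^n / (k^n + x^n)``."""

    base: float = 0.0
    amp: float = 1.0
    k: float = 16.0
    n: float = 2.0

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.base + self.amp * x**self.n / (self.k**self.n + x**self.n)


def _condition_label(protocol: ExperimentProtocol) -> str:
    label = f"hgf{protocol.hgf_dose:g}"
    if protocol.inhibitor not in ("none", "", None):
        label += f"+{protocol.inhibitor}"
    if protocol.washout_time is not None:
        label += f"_wash{protocol.washout_time:g}"
    return label


def _replicate_scales(rng, n: int, log10_sd: float) -> np.ndarray:
    return 10.0 ** rng.normal(0.0, log10_sd, size=n)


def generate_timecourses(
    truth: ParameterSet,
    network: ReactionNetwork,
    protocol: ExperimentProtocol,
    observables: list[str],
    n_replicates: int,
    noise: NoiseSpec,
    times: np.ndarray | None = None,
) -> pd.DataFrame:
    """Immunoblot-like replicate observations of model observables.

    Each replicate r observes ``scale_r * observable(t) * (1 + cv * eps)``
    with eps standard normal and ``scale_r`` log-normal (median 1), plus a
    spiked-calibrator column carrying that replicate's own calibrator
    scale.  Columns: observable, condition, time_h, replicate, intensity,
    calibrator.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if times is None:
        times = np.arange(0.0, protocol.t_end + 1e-9, 2.0)
    rng = noise.rng(0)
    traj = simulate(network, truth, protocol, times)
    obs = compute_observables(traj, network, truth)
    unknown = set(observables) - set(obs)
    if unknown:
        raise KeyError(f"unknown observables: {sorted(unknown)}")

    condition = _condition_label(protocol)
    rows = []
    for name in observables:
        y = obs[name]
        scales = _replicate_scales(rng, n_replicates, noise.replicate_scale_sd)
        cals = _replicate_scales(rng, n_replicates, noise.replicate_scale_sd)
        for r in range(n_replicates):
            eps = rng.standard_normal(times.size)
            intensity = scales[r] * y * (1.0 + noise.relative_cv * eps)
            rows.append(
                pd.DataFrame(
                    {
                        "observable": name,
                        "condition": condition,
                        "time_h": times,
                        "replicate": r,
                        "intensity": intensity,
                        "calibrator": cals[r],
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def generate_dna_content(
    truth: ParameterSet,
    network: ReactionNetwork,
    protocols: list[ExperimentProtocol],
    noise: NoiseSpec,
    times: np.ndarray | None = None,
    n_replicates: int = 1,
) -> pd.DataFrame:
    """DNA-content assay tables with additive constant-variance noise.

    The noiseless value is the DNA state divided by its value at the
    stimulation time, so the reading at stimulation is 1 in expectation.
    """
    if "dna" not in network.observables:
        raise KeyError("network defines no 'dna' observable")
    rng = noise.rng(1)
    rows = []
    for protocol in protocols:
        t = times if times is not None else np.arange(0.0, protocol.t_end + 1e-9, 4.0)
        grid = np.union1d(t, [protocol.t_stim])
        traj = simulate(network, truth, protocol, grid)
        dna = compute_observables(traj, network, truth)["dna"]
        anchor = dna[np.searchsorted(grid, protocol.t_stim)]
        y = np.interp(t, grid, dna / anchor)
        for r in range(n_replicates):
            rows.append(
                pd.DataFrame(
                    {
                        "observable": "dna",
                        "condition": _condition_label(protocol),
                        "time_h": t,
                        "replicate": r,
                        "intensity": y + rng.normal(0.0, noise.constant_sd, t.size),
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def generate_dose_response(
    truth: ParameterSet,
    network: ReactionNetwork,
    doses: list[float],
    observables: list[str],
    n_replicates: int,
    noise: NoiseSpec,
    measurement_time_post_stim: float = 48.0,
    protocol_template: ExperimentProtocol | None = None,
) -> pd.DataFrame:
    """Single-time-point dose-response readouts of model observables.

    One reading per dose/observable/replicate at the configured time after
    stimulation (default 48 h), with the blot-like noise structure of
    :func:`generate_timecourses`.  Columns: dose_ng_ml, observable,
    replicate, intensity.
    """
    doses = np.asarray(doses, dtype=float)
    if np.any(doses < 0):
        raise ValueError("doses must be >= 0")
    base = protocol_template or ExperimentProtocol()
    t_read = base.t_stim + measurement_time_post_stim
    rng = noise.rng(2)

    readouts = {name: np.empty(doses.size) for name in observables}
    for i, dose in enumerate(doses):
        proto = ExperimentProtocol(
            hgf_dose=float(dose), t_stim=base.t_stim,
            t_end=max(base.t_end, t_read), inhibitor=base.inhibitor,
        )
        traj = simulate(network, truth, proto, np.array([t_read]))
        obs = compute_observables(traj, network, truth)
        for name in observables:
            readouts[name][i] = obs[name][0]

    rows = []
    for name in observables:
        scales = _replicate_scales(rng, n_replicates, noise.replicate_scale_sd)
        for r in range(n_replicates):
            eps = rng.standard_normal(doses.size)
            rows.append(
                pd.DataFrame(
                    {
                        "dose_ng_ml": doses,
                        "observable": name,
                        "replicate": r,
                        "intensity": scales[r] * readouts[name] * (1 + noise.relative_cv * eps),
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


# --------------------------------------------------------------------------
# Fucci-like single-cell tracks
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TrackGeneratorSpec:
    """Configuration of the two-channel single-cell track generator.

    Tracks are sampled every ``sampling_interval`` hours (default 15 min)
    for ``duration`` hours from stimulation.  Each cell is a responder with
    probability ``responder_hill(dose)``; responders traverse
    G1 -> G1/S -> S/G2/M -> early G1 with truncated-normal dwell times,
    non-responders stay in G1 with occasional abortive G1/S excursions
    that return to G1 without entering S/G2/M.  After division only one
    daughter is followed (no re-entry by default).
    """

    n_cells: int = 20
    sampling_interval: float = 0.25
    duration: float = 60.0
    dose: float = 40.0
    responder_hill: HillSpec = HillSpec(base=0.0, amp=0.92, k=16.0, n=2.0)
    #: (mean, sd) dwell times in h; G1 is the pre-transition onset time.
    g1_dwell: tuple[float, float] = (30.0, 6.0)
    g1s_dwell: tuple[float, float] = (3.0, 1.0)
    sgm_dwell: tuple[float, float] = (12.0, 2.0)
    abortive_rate: float = 0.1
    abortive_dwell: tuple[float, float] = (1.5, 0.5)
    rfp_high: float = 100.0
    rfp_low: float = 10.0
    yfp_high: float = 80.0
    yfp_low: float = 8.0
    channel_noise_sd: float = 4.0
    cells_per_field: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be > 0")
        probe = self.responder_hill(np.array([0.0, self.dose, 1e6]))
        if np.any((probe < 0) | (probe > 1)):
            raise ValueError("responder probability must stay within [0, 1]")


_PHASE_LEVELS = {
    "G1": ("rfp_high", "yfp_low"),
    "G1/S": ("rfp_high", "yfp_high"),
    "S/G2/M": ("rfp_low", "yfp_high"),
    "earlyG1": ("rfp_low", "yfp_low"),
}


def _trunc_normal(rng, mean: float, sd: float, minimum: float) -> float:
    for _ in range(100):
        v = rng.normal(mean, sd)
        if v >= minimum:
            return v
    return minimum


def generate_tracks(spec: TrackGeneratorSpec) -> pd.DataFrame:
    """Generate single-cell RFP/YFP intensity tracks.

    Returns a tidy table (cell_id, field_id, time_h, rfp, yfp).  The latent
    phase sequence is recoverable through the quadrant classification as
    long as the channel noise is small against the high/low contrast.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(4)[3])
    dt = spec.sampling_interval
    times = np.arange(0.0, spec.duration + 1e-9, dt)
    min_dwell = 4 * dt  # dwell floor so real transitions satisfy the 4+4 caller
    p_respond = float(spec.responder_hill(spec.dose))

    frames = []
    for cell in range(spec.n_cells):
        phases = np.array(["G1"] * times.size, dtype=object)
        if rng.random() < p_respond:
            g1s = _trunc_normal(rng, *spec.g1s_dwell, min_dwell)
            sgm = _trunc_normal(rng, *spec.sgm_dwell, min_dwell)
            # onset clipped so the full G1/S + S/G2/M excursion fits the track
            latest = spec.duration - (g1s + sgm)
            onset = min(_trunc_normal(rng, *spec.g1_dwell, min_dwell), max(latest, min_dwell))
            phases[(times >= onset) & (times < onset + g1s)] = "G1/S"
            phases[(times >= onset + g1s) & (times < onset + g1s + sgm)] = "S/G2/M"
            phases[times >= onset + g1s + sgm] = "earlyG1"
        elif rng.random() < spec.abortive_rate:
            onset = _trunc_normal(rng, *spec.g1_dwell, min_dwell)
            dwell = _trunc_normal(rng, *spec.abortive_dwell, dt)
            phases[(times >= onset) & (times < onset + dwell)] = "G1/S"

        rfp = np.array([getattr(spec, _PHASE_LEVELS[p][0]) for p in phases])
        yfp = np.array([getattr(spec, _PHASE_LEVELS[p][1]) for p in phases])
        if spec.channel_noise_sd > 0:
            rfp = rfp + rng.normal(0, spec.channel_noise_sd, times.size)
            yfp = yfp + rng.normal(0, spec.channel_noise_sd, times.size)
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": cell,
                    "field_id": cell // spec.cells_per_field,
                    "time_h": times,
                    "rfp": np.clip(rfp, 0, None),
                    "yfp": np.clip(yfp, 0, None),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
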