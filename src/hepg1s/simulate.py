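"""Stiff ODE simulation of the expanded network under experimental protocols.

Model time 0 is plating; growth-factor depletion runs until ``t_stim``
(default 24 h), when HGF (and any inhibitor) is applied.  An optional
washout sets HGF back to 0 (perfect, immediate receptor shut-off, emulating
c-Met inhibition after ligand removal).  Input activities are
piecewise-constant across these protocol events, and the integrator is
restarted at every event to avoid discontinuity artifacts.

Initial conditions: all protein species 0 (G1/S components are low or
undetectable directly after isolation; basal input activity then drives the
pre-stimulation rise) and DNA content 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .inputs import InputState, evaluate_inputs, inhibitor_clamps
from .network import ReactionNetwork
from .parameters import ParameterSet

__all__ = [
    "ExperimentProtocol",
    "SimulationError",
    "Trajectories",
    "simulate",
    "compute_observables",
]


class SimulationError(RuntimeError):
    """Integration failure; carries the time at which the solver stopped."""

    def __init__(self, message: str, t_fail: float | None = None):
        super().__init__(message)
        self.t_fail = t_fail


@dataclass(frozen=True)
class ExperimentProtocol:
    """Timeline of one experiment.

    ``hgf_dose`` in ng/ml applied at ``t_stim`` (h after plating);
    ``washout_time`` (absolute model time) sets HGF to 0 thereafter;
    ``inhibitor`` is a named treatment applied together with the stimulus.
    """

    hgf_dose: float = 0.0
    t_stim: float = 24.0
    t_end: float = 72.0
    washout_time: float | None = None
    inhibitor: str = "none"

    def __post_init__(self) -> None:
        if self.hgf_dose < 0:
            raise ValueError("hgf_dose must be >= 0")
        w = self.washout_time if self.washout_time is not None else self.t_end
        if not 0 <= self.t_stim <= w <= self.t_end:
            raise ValueError("require 0 <= t_stim <= washout_time <= t_end")

    def events(self) -> list[float]:
        ev = {0.0, self.t_stim, self.t_end}
        if self.washout_time is not None:
            ev.add(self.washout_time)
        return sorted(ev)

    def segment_dose(self, t_left: float) -> tuple[float, bool]:
        """(HGF dose, inhibitor active) for the segment starting at t_left."""
        if t_left < self.t_stim:
            return 0.0, False
        if self.washout_time is not None and t_left >= self.washout_time:
            return 0.0, True
        return self.hgf_dose, True


@dataclass
class Trajectories:
    """Simulated state trajectories on a time grid."""

    times: np.ndarray
    states: np.ndarray  # (n_times, n_states)
    state_names: list[str]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.states[:, self.state_names.index(name)]


class _Compiled:
    """Vectorized right-hand side for one expanded network.

    Rate of reaction j: ``keff_j * prod(x[factors_j])`` where the factor
    list concatenates reactant and modifier state indices; two virtual
    state slots hold the constant 1 (for zeroth-order reactions) and the
    ``(2 - DNA)`` capacity factor.  ``keff`` folds in the rate constant,
    the segment's input factors and the CDK4 activity flag.
    """

    def __init__(self, net: ReactionNetwork):
        names = net.state_names()
        idx = {n: i for i, n in enumerate(names)}
        self.state_names = names
        self.n = len(names)
        self.dna_idx = idx.get(net.dna_species_name)
        m = len(net.reactions)
        self.param_names = [r.rate_param for r in net.reactions]
        self.input_factors = [r.input_factors for r in net.reactions]
        self.cdk4_flags = np.array([r.cdk4_catalyzed for r in net.reactions])

        one_slot, cap_slot = self.n, self.n + 1
        factors: list[int] = []
        ptr = [0]
        stoich = np.zeros((self.n, m))
        for j, rxn in enumerate(net.reactions):
            f = [idx[s] for s in rxn.reactants] + [idx[s] for s in rxn.modifiers]
            if rxn.dna_capped:
                f.append(cap_slot)
            if not f:
                f.append(one_slot)
            factors.extend(f)
            ptr.append(len(factors))
            for s in rxn.reactants:
                stoich[idx[s], j] -= 1.0
            for s in rxn.products:
                stoich[idx[s], j] += 1.0
        self.factor_idx = np.array(factors)
        self.ptr = np.array(ptr[:-1])
        self.stoich = stoich

    def keff(self, params: ParameterSet, inp: InputState) -> np.ndarray:
        act = {
            "akt": inp.akt, "erk": inp.erk, "gsk3b": inp.gsk3b,
            "tf": inp.tf, "p53": inp.p53,
        }
        k = np.array([params.values[p] for p in self.param_names])
        for j, facs in enumerate(self.input_factors):
            for tok in facs:
                k[j] *= (1.0 - act[tok[1:]]) if tok.startswith("~") else act[tok]
        k[self.cdk4_flags] *= inp.cdk4_activity_factor
        return k

    def rhs(self, keff: np.ndarray):
        n, dna_idx = self.n, self.dna_idx
        factor_idx, ptr, stoich = self.factor_idx, self.ptr, self.stoich
        xe = np.empty(n + 2)
        xe[n] = 1.0

        def f(t: float, x: np.ndarray) -> np.ndarray:
            xe[:n] = x
            xe[n + 1] = 2.0 - x[dna_idx] if dna_idx is not None else 1.0
            rates = keff * np.multiply.reduceat(xe[factor_idx], ptr)
            return stoich @ rates

        return f


def _compiled(net: ReactionNetwork) -> _Compiled:
    comp = getattr(net, "_compiled", None)
    if comp is None:
        comp = _Compiled(net)
        net._compiled = comp
    return comp


def simulate(
    network: ReactionNetwork,
    params: ParameterSet,
    protocol: ExperimentProtocol,
    times: np.ndarray,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    method: str = "LSODA",
    retry: bool = True,
    max_rhs_evals: int | None = None,
    x0: dict[str, float] | None = None,
) -> Trajectories:
    """Integrate the network ODEs and return trajectories at ``times``.

    Uses a stiff implicit integrator (LSODA by default, switching to BDF at
    tighter tolerance on failure unless ``retry`` is disabled) with the
    integration restarted at protocol events.  ``max_rhs_evals`` caps the
    total right-hand-side evaluations (parameter estimation uses this to
    bound the cost of pathological parameter regions).  Raises
    :class:`SimulationError` (with the failure time) on failure.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or np.any(np.diff(times) < 0):
        raise ValueError("times must be a non-decreasing 1-D grid")
    if times.size and (times[0] < 0 or times[-1] > protocol.t_end + 1e-9):
        raise ValueError("times must lie within [0, t_end]")

    comp = _compiled(network)
    x = np.zeros(comp.n)
    if comp.dna_idx is not None:
        x[comp.dna_idx] = 1.0
    if x0 is not None:
        index = {n: i for i, n in enumerate(comp.state_names)}
        for name, v in x0.items():
            x[index[name]] = v

    input_params = params.input_params()
    clamps = inhibitor_clamps(protocol.inhibitor, input_params)

    out = np.empty((times.size, comp.n))
    filled = np.zeros(times.size, dtype=bool)
    if times.size and times[0] == 0.0:
        first_zero = np.searchsorted(times, 0.0, side="right")
        out[:first_zero] = x
        filled[:first_zero] = True

    budget = [max_rhs_evals if max_rhs_evals is not None else np.inf]
    events = [t for t in protocol.events() if t <= protocol.t_end]
    for t0, t1 in zip(events[:-1], events[1:]):
        if t1 <= t0:
            continue
        dose, inhibited = protocol.segment_dose(t0)
        inp = evaluate_inputs(dose, input_params, clamps if inhibited else None)
        f = _budgeted(comp.rhs(comp.keff(params, inp)), budget)
        mask = (~filled) & (times > t0) & (times <= t1 + 1e-12)
        t_eval = np.unique(times[mask])
        x = _integrate_segment(f, x, t0, t1, t_eval, out, times, mask,
                               rtol, atol, method, retry)
        filled |= mask

    states = out
    neg = states.min(initial=0.0)
    if neg < -100 * max(atol, 1e-12):
        warnings.warn(f"negative concentrations down to {neg:.3g} (solver tolerance)")
    np.clip(states, 0.0, None, out=states)
    return Trajectories(times=times, states=states, state_names=comp.state_names)


class _BudgetExceeded(RuntimeError):
    pass


def _budgeted(f, budget: list):
    """Wrap an RHS so each call draws on a shared evaluation budget."""
    if budget[0] == np.inf:
        return f

    def g(t, x):
        budget[0] -= 1
        if budget[0] <= 0:
            raise _BudgetExceeded(f"RHS evaluation budget exhausted at t={t:.3g}")
        return f(t, x)

    return g


def _integrate_segment(f, x0, t0, t1, t_eval, out, times, mask, rtol, atol, method,
                       retry=True):
    attempts = [(method, rtol, atol)]
    if retry:
        attempts.append(("BDF", rtol * 1e-2, atol * 1e-2))
    message = "integration failed"
    for attempt, (meth, r, a) in enumerate(attempts):
        try:
            with np.errstate(all="ignore"):
                sol = solve_ivp(
                    f, (t0, t1), x0, method=meth, rtol=r, atol=a,
                    t_eval=t_eval if t_eval.size else None, dense_output=False,
                )
        except (_BudgetExceeded, FloatingPointError, ValueError) as err:
            raise SimulationError(str(err), t_fail=t0) from err
        if sol.success:
            if attempt:
                warnings.warn(f"retried segment [{t0}, {t1}] at tighter tolerance with BDF")
            if t_eval.size:
                lookup = {t: i for i, t in enumerate(sol.t)}
                for i_time in np.nonzero(mask)[0]:
                    out[i_time] = sol.y[:, lookup[times[i_time]]]
                # advance from the segment end, not the last requested time
                if sol.t[-1] != t1:
                    try:
                        tail = solve_ivp(f, (sol.t[-1], t1), sol.y[:, -1],
                                         method=meth, rtol=r, atol=a)
                    except (_BudgetExceeded, FloatingPointError, ValueError) as err:
                        raise SimulationError(str(err), t_fail=float(sol.t[-1])) from err
                    if not tail.success:
                        raise SimulationError(tail.message, t_fail=float(tail.t[-1]))
                    return tail.y[:, -1]
            return sol.y[:, -1]
        message = sol.message
    raise SimulationError(message, t_fail=float(sol.t[-1]) if sol.t.size else t0)


def compute_observables(
    trajectories: Trajectories,
    network: ReactionNetwork,
    params: ParameterSet,
) -> dict[str, np.ndarray]:
    """Observable time courses: scaling parameter times the sum of matching
    species; the DNA observable is the DNA state itself (scale-free, equal
    to 1 at stimulation by construction)."""
    if not network.observables:
        raise ValueError("network has no observable map; call attach_observables")
    out: dict[str, np.ndarray] = {}
    for obs, members in network.observables.items():
        total = np.zeros(trajectories.times.size)
        for sp in members:
            total += trajectories[sp]
        scale_param = network.scaling_params.get(obs)
        if scale_param is not None:
            if scale_param not in params.values:
                raise KeyError(f"missing scaling parameter {scale_param!r}")
            total = params.values[scale_param] * total
        out[obs] = total
    return out
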