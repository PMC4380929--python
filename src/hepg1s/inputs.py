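"""Algebraic input layer: HGF dose -> bounded signaling activities.

The dynamic G1/S model is not driven by mechanistic receptor/MAPK/PI3K
kinetics.  Instead, a small algebraic layer maps the HGF dose (ng/ml) to the
activities of five input nodes -- Akt, ERK, GSK3beta, a lumped transcription
factor node TF (AP-1/Myc/p53), and p53 -- each bounded in [0, 1].  Basal
activities of Akt and ERK are nonzero because isolation/plating stress
activates both pathways even without growth factor.

Pharmacological treatments are represented as clamps that pin individual
nodes (Akt inhibitor VIII, U0126, Pifithrin-alpha) or as a model-level flag
(PD0332991, which silences CDK4 catalytic activity and is consumed by the
reaction network, not by this layer).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "InputState",
    "InputParams",
    "evaluate_inputs",
    "estimate_basal_activity",
    "inhibitor_clamps",
    "INHIBITORS",
]

INPUT_NODES = ("akt", "erk", "gsk3b", "tf", "p53")


@dataclass(frozen=True)
class InputState:
    """Activities of the five input nodes, each in [0, 1]."""

    akt: float
    erk: float
    gsk3b: float
    tf: float
    p53: float
    cdk4_activity_factor: float = 1.0  # PD0332991 flag consumed by the network

    def as_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in INPUT_NODES}


@dataclass(frozen=True)
class InputParams:
    """Parameters of the algebraic input layer.

    alpha_akt / alpha_erk are the measured basal activities (fixed from
    inhibitor-controlled immunoblots via :func:`estimate_basal_activity`);
    k_akt / k_erk are half-saturation HGF doses in ng/ml; tf_basal is the
    basal activity of the lumped transcription-factor node.  By default the
    three free parameters of the input layer are {k_akt, k_erk, tf_basal}.

    ``saturation`` selects the dose-activity form: ``"hyperbolic"`` (default,
    Michaelis-type) or ``"hill"`` with exponent ``hill_n``.
    """

    alpha_akt: float = 0.25
    alpha_erk: float = 0.15
    tf_basal: float = 0.08
    k_akt: float = 3.0
    k_erk: float = 8.0
    saturation: str = "hyperbolic"
    hill_n: float = 2.0

    def __post_init__(self) -> None:
        for name in ("alpha_akt", "alpha_erk", "tf_basal"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        for name in ("k_akt", "k_erk"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.saturation not in ("hyperbolic", "hill"):
            raise ValueError(f"unknown saturation form {self.saturation!r}")


def _saturating(hgf: float, k: float, params: InputParams) -> float:
    if params.saturation == "hyperbolic":
        return hgf / (k + hgf) if hgf > 0 else 0.0
    n = params.hill_n
    return hgf**n / (k**n + hgf**n) if hgf > 0 else 0.0


def evaluate_inputs(
    hgf: float,
    params: InputParams,
    clamps: dict[str, float] | None = None,
) -> InputState:
    """Evaluate the input node activities for a given HGF dose.

    Akt and ERK rise hyperbolically from their basal activity toward 1:
    ``akt = alpha_akt + (1 - alpha_akt) * hgf / (k_akt + hgf)`` (ERK
    analogous).  GSK3beta is inhibited by Akt (``gsk3b = 1 - akt``).  The
    lumped TF node is an AND gate of Akt and ERK realized as a product,
    lifted by its basal activity; p53 follows TF by default.

    ``clamps`` overrides individual node activities (inhibitor semantics);
    the special key ``"cdk4_activity_factor"`` is passed through to the
    dynamic model.
    """
    if hgf < 0:
        raise ValueError(f"HGF dose must be >= 0, got {hgf}")
    clamps = dict(clamps or {})
    cdk4_factor = float(clamps.pop("cdk4_activity_factor", 1.0))
    for node, value in clamps.items():
        if node not in INPUT_NODES:
            raise ValueError(f"unknown input node {node!r}")
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"clamp for {node} outside [0, 1]: {value}")

    akt = params.alpha_akt + (1 - params.alpha_akt) * _saturating(hgf, params.k_akt, params)
    if "akt" in clamps:
        akt = clamps["akt"]
    erk = params.alpha_erk + (1 - params.alpha_erk) * _saturating(hgf, params.k_erk, params)
    if "erk" in clamps:
        erk = clamps["erk"]

    gsk3b = clamps.get("gsk3b", 1.0 - akt)
    tf = clamps.get("tf", params.tf_basal + (1 - params.tf_basal) * akt * erk)
    p53 = clamps.get("p53", tf)
    return InputState(
        akt=akt, erk=erk, gsk3b=gsk3b, tf=tf, p53=p53,
        cdk4_activity_factor=cdk4_factor,
    )


def estimate_basal_activity(
    basal_signal: float, stimulated_signal: float, inhibited_signal: float
) -> float:
    """Basal pathway activity from unstimulated/stimulated/inhibited blots.

    The inhibited condition (PI3K or MEK inhibitor) defines the experimental
    background, the saturating stimulation defines full activity, and the
    basal activity is the background-corrected fraction
    ``(basal - inhibited) / (stimulated - inhibited)`` clipped to [0, 1].
    """
    if stimulated_signal <= inhibited_signal:
        raise ValueError(
            "degenerate data: stimulated signal must exceed inhibited background"
        )
    frac = (basal_signal - inhibited_signal) / (stimulated_signal - inhibited_signal)
    return min(1.0, max(0.0, frac))


#: Supported treatments and how each acts on the model.
INHIBITORS = ("none", "AktVIII", "U0126", "PifithrinA", "PD0332991")


def inhibitor_clamps(treatment: str, params: InputParams) -> dict[str, float]:
    """Translate a named inhibitor treatment into input clamps.

    * ``AktVIII`` -- Akt clamped to its basal activity.
    * ``U0126`` -- ERK (MEK inhibition) clamped to its basal activity.
    * ``PifithrinA`` -- p53 clamped to 0 (blocks p21 induction).
    * ``PD0332991`` -- not an input clamp: sets the CDK4 catalytic activity
      factor to 0, consumed by the reaction network.
    * ``none`` -- empty clamp set.
    """
    if treatment in ("none", None, ""):
        return {}
    if treatment == "AktVIII":
        return {"akt": params.alpha_akt}
    if treatment == "U0126":
        return {"erk": params.alpha_erk}
    if treatment == "PifithrinA":
        return {"p53": 0.0}
    if treatment == "PD0332991":
        return {"cdk4_activity_factor": 0.0}
    raise ValueError(f"unknown treatment {treatment!r}; supported: {INHIBITORS}")
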