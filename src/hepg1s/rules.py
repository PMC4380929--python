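"""The default hepatocyte G1/S transition rule set.

The model tracks five regulatory units plus DNA content across cytoplasm
("cyt") and nucleus ("nuc"):

* ``CD4`` -- the lumped Cyclin D1:CDK4 unit (free Cyclin D1, free CDK4 and
  Cyclin D1:CDK4:p21 are not distinguished; p21 binding does not impair CDK4
  kinase activity, and CAK phosphorylation of CDK4 is implicit).
* ``CycE`` and ``CDK2`` (site ``T160`` in {u, p}) -- Cyclin E and CDK2 bind
  in the cytoplasm; the complex is imported via p21; nuclear CAK
  phosphorylates T160 only after p21 release, because p21-bound CDK2 is
  catalytically blocked.
* ``p21`` -- assembly factor and nuclear-import mediator for both CDK
  complexes, induced by p53 and by E2F-1 (the latter requiring p53).
* ``Rb`` (sites ``S788``, ``S800``, each in {u, p}) -- sequentially
  phosphorylated, first by nuclear CDK4 complexes (S788 class) then by
  active pCDK2 T160 (S800/S804 class); hypophosphorylated Rb sequesters
  E2F-1, and full phosphorylation releases it.
* ``E2F1`` -- auto-amplifying transcription factor (Myc/TF-gated); its
  Rb-bound pool turns over at its own (slower) rate.
* DNA synthesis requires free nuclear E2F-1 AND active pCDK2 T160 and
  saturates at one genome duplication: ``dDNA/dt = k * [E2F1] * [pCDK2] *
  (2 - DNA)``.

Expansion of this rule set yields 24 dynamic species, 69 reactions and 55
distinct kinetic rate parameters (structural contract asserted in tests).
"""

from __future__ import annotations

from .network import (
    BindingRule,
    DegradationRule,
    DnaSynthesisRule,
    Molecule,
    ModificationRule,
    Pattern,
    RuleSet,
    Species,
    SynthesisRule,
    TransportRule,
    UnbindRule,
)

__all__ = ["default_rules", "OBSERVABLE_PATTERNS", "attach_observables", "toy_rules"]

CYT, NUC = "cyt", "nuc"

MOLECULES = {
    "CD4": Molecule("CD4"),
    "CycE": Molecule("CycE"),
    "CDK2": Molecule("CDK2", (("T160", ("u", "p")),)),
    "p21": Molecule("p21"),
    "Rb": Molecule("Rb", (("S788", ("u", "p")), ("S800", ("u", "p")))),
    "E2F1": Molecule("E2F1"),
}


def _mono(name: str, comp: str, **sites: str) -> Species:
    mol = MOLECULES[name]
    states = dict(mol.default_states())
    states.update(sites)
    return Species.make(comp, [(name, tuple(sorted(states.items())))])


# Frequently used patterns -------------------------------------------------

FREE_NUC_E2F1 = Pattern.of("E2F1", comp=NUC, exact=True)
ACTIVE_PCDK2 = Pattern.of("CycE", ("CDK2", {"T160": "p"}), comp=NUC, absent=("p21",))


def default_rules() -> RuleSet:
    """Build the default G1/S rule set (see module docstring)."""
    rules = []

    # -- input-driven synthesis (all to cytoplasm) -------------------------
    rules += [
        # Cyclin D1:CDK4 unit: MAPK-induced Cyclin D1 expression combined
        # with Akt-mediated GSK3b inhibition (Cyclin D1 stabilization).
        SynthesisRule("syn_cd4", _mono("CD4", CYT), "ks_cd4", ("erk", "~gsk3b")),
        SynthesisRule("syn_cyce", _mono("CycE", CYT), "ks_cyce", ("tf",)),
        SynthesisRule("syn_cdk2", _mono("CDK2", CYT), "ks_cdk2"),
        SynthesisRule("syn_p21_p53", _mono("p21", CYT), "ks_p21_p53", ("p53",)),
        # p21 induction by E2F-1 requires p53 as co-factor.
        SynthesisRule(
            "syn_p21_e2f", _mono("p21", CYT), "ks_p21_e2f", ("p53",), (FREE_NUC_E2F1,)
        ),
        SynthesisRule("syn_rb", _mono("Rb", CYT), "ks_rb"),
        SynthesisRule("syn_rb_e2f", _mono("Rb", CYT), "ks_rb_e2f", (), (FREE_NUC_E2F1,)),
        SynthesisRule("syn_e2f", _mono("E2F1", CYT), "ks_e2f", ("tf",)),
        # E2F-1 auto-transcription gated by Myc (part of the TF node).
        SynthesisRule(
            "syn_e2f_auto", _mono("E2F1", CYT), "ks_e2f_auto", ("tf",), (FREE_NUC_E2F1,)
        ),
    ]

    # -- binding -----------------------------------------------------------
    p21_mono = lambda c: Pattern.of("p21", comp=c, exact=True)  # noqa: E731
    rules += [
        BindingRule(
            "bind_cyce_cdk2",
            Pattern.of("CycE", comp=CYT, exact=True),
            Pattern.of(("CDK2", {"T160": "u"}), comp=CYT, exact=True),
            "kon_cyce_cdk2", "koff_cyce_cdk2",
        ),
        BindingRule(
            "bind_cd4_p21_cyt",
            Pattern.of("CD4", comp=CYT, absent=("p21",)),
            p21_mono(CYT), "kon_cd4_p21_cyt", "koff_cd4_p21_cyt",
        ),
        BindingRule(
            "bind_cd4_p21_nuc",
            Pattern.of("CD4", comp=NUC, absent=("p21",)),
            p21_mono(NUC), "kon_cd4_p21_nuc", "koff_cd4_p21_nuc",
        ),
        BindingRule(
            "bind_ce2_p21_cyt",
            Pattern.of("CycE", ("CDK2", {"T160": "u"}), comp=CYT, absent=("p21",)),
            p21_mono(CYT), "kon_ce2_p21_cyt", "koff_ce2_p21_cyt",
        ),
        # Nuclear p21 release from the unphosphorylated complex is driven by
        # Akt/ERK-dependent p21 phosphorylation, making T160 accessibility
        # (and hence pCDK2) require strong pathway activation.
        BindingRule(
            "bind_ce2_p21_nuc",
            Pattern.of("CycE", ("CDK2", {"T160": "u"}), comp=NUC, absent=("p21",)),
            p21_mono(NUC), "kon_ce2_p21_nuc", "koff_ce2_p21_nuc",
            koff_factors=("akt", "erk"),
        ),
        # p21 re-binding to the T160-phosphorylated complex blocks its
        # kinase activity without removing the phosphate.
        BindingRule(
            "bind_ce2p_p21_nuc",
            Pattern.of("CycE", ("CDK2", {"T160": "p"}), comp=NUC, absent=("p21",)),
            p21_mono(NUC), "kon_ce2p_p21_nuc", "koff_ce2p_p21_nuc",
        ),
    ]

    # -- nuclear transport (p21-mediated for CDK complexes) ----------------
    rules += [
        TransportRule("imp_cd4_p21", Pattern.of("CD4", "p21"), CYT, NUC, "ki_cd4_p21"),
        TransportRule("imp_ce2_p21", Pattern.of("CycE", "CDK2", "p21"), CYT, NUC, "ki_ce2_p21"),
        TransportRule("imp_p21", Pattern.of("p21", exact=True), CYT, NUC, "ki_p21"),
        TransportRule("imp_rb", Pattern.of("Rb", exact=True), CYT, NUC, "ki_rb"),
        TransportRule("imp_e2f", Pattern.of("E2F1", exact=True), CYT, NUC, "ki_e2f"),
        TransportRule("exp_p21", Pattern.of("p21", exact=True), NUC, CYT, "kx_p21"),
    ]

    # -- CDK2 T160 phosphorylation (CAK implicit, constitutively active) ---
    rules += [
        ModificationRule(
            "cak_t160",
            Pattern.of("CycE", ("CDK2", {"T160": "u"}), comp=NUC, absent=("p21",)),
            "CDK2", "T160", "u", "p", "k_cak",
        ),
        ModificationRule(
            "dephos_t160",
            Pattern.of("CycE", ("CDK2", {"T160": "p"}), comp=NUC, absent=("p21",)),
            "CDK2", "T160", "p", "u", "k_t160_dephos",
        ),
        ModificationRule(
            "dephos_t160_p21",
            Pattern.of("CycE", ("CDK2", {"T160": "p"}), "p21", comp=NUC),
            "CDK2", "T160", "p", "u", "k_t160_dephos_b",
        ),
    ]

    # -- sequential Rb phosphorylation -------------------------------------
    cd4_nuc = Pattern.of("CD4", comp=NUC)  # free and p21-bound CDK4 are equally active
    rules += [
        ModificationRule(
            "rb_s788_cdk4",
            Pattern.of(("Rb", {"S788": "u"}), comp=NUC, absent=("E2F1",)),
            "Rb", "S788", "u", "p", "k_rb_s788_cdk4",
            catalyst=cd4_nuc, cdk4_catalyzed=True,
        ),
        ModificationRule(
            "rb_s788_cdk4_e2f",
            Pattern.of(("Rb", {"S788": "u"}), "E2F1", comp=NUC),
            "Rb", "S788", "u", "p", "k_rb_s788_cdk4_e2f",
            catalyst=cd4_nuc, cdk4_catalyzed=True,
        ),
        ModificationRule(
            "rb_s800_cdk2",
            Pattern.of(("Rb", {"S788": "p", "S800": "u"}), comp=NUC, absent=("E2F1",)),
            "Rb", "S800", "u", "p", "k_rb_s800_cdk2", catalyst=ACTIVE_PCDK2,
        ),
        ModificationRule(
            "rb_s800_cdk2_e2f",
            Pattern.of(("Rb", {"S788": "p", "S800": "u"}), "E2F1", comp=NUC),
            "Rb", "S800", "u", "p", "k_rb_s800_cdk2_e2f", catalyst=ACTIVE_PCDK2,
        ),
        ModificationRule(
            "rb_dephos_s788",
            Pattern.of(("Rb", {"S788": "p", "S800": "u"}), comp=NUC, absent=("E2F1",)),
            "Rb", "S788", "p", "u", "k_rb_dephos_s788",
        ),
        ModificationRule(
            "rb_dephos_s788_e2f",
            Pattern.of(("Rb", {"S788": "p", "S800": "u"}), "E2F1", comp=NUC),
            "Rb", "S788", "p", "u", "k_rb_dephos_s788_e2f",
        ),
        ModificationRule(
            "rb_dephos_s800",
            Pattern.of(("Rb", {"S800": "p"}), comp=NUC, absent=("E2F1",)),
            "Rb", "S800", "p", "u", "k_rb_dephos_s800",
        ),
        ModificationRule(
            "rb_dephos_s800_e2f",
            Pattern.of(("Rb", {"S800": "p"}), "E2F1", comp=NUC),
            "Rb", "S800", "p", "u", "k_rb_dephos_s800_e2f",
        ),
    ]

    # -- Rb:E2F-1 sequestration and release --------------------------------
    rules += [
        BindingRule(
            "bind_rb_e2f",
            Pattern.of(("Rb", {"S788": "u", "S800": "u"}), comp=NUC, exact=True),
            Pattern.of("E2F1", comp=NUC, exact=True),
            "kon_rb_e2f", "koff_rb_e2f",
        ),
        BindingRule(
            "bind_rbp_e2f",
            Pattern.of(("Rb", {"S788": "p", "S800": "u"}), comp=NUC, exact=True),
            Pattern.of("E2F1", comp=NUC, exact=True),
            "kon_rbp_e2f", "koff_rbp_e2f",
        ),
        UnbindRule(
            "e2f_release",
            Pattern.of(("Rb", {"S800": "p"}), "E2F1", comp=NUC),
            "E2F1", "k_e2f_release",
        ),
    ]

    # -- DNA synthesis ------------------------------------------------------
    rules.append(DnaSynthesisRule("dna_syn", "k_dna", (FREE_NUC_E2F1, ACTIVE_PCDK2)))

    # -- degradation (ordered; first match wins) ---------------------------
    # Complexes degrade as a unit; Rb:E2F-1 complexes have their own (slow)
    # turnover because E2F-1 is stabilized in the bound state.
    degradation = [
        DegradationRule("deg_rb_e2f", Pattern.of("Rb", "E2F1"), "kd_rb_e2f"),
        DegradationRule("deg_ce2", Pattern.of("CycE", "CDK2"), "kd_ce2"),
        DegradationRule("deg_cd4", Pattern.of("CD4"), "kd_cd4"),
        DegradationRule("deg_cyce", Pattern.of("CycE"), "kd_cyce"),
        DegradationRule("deg_cdk2", Pattern.of("CDK2"), "kd_cdk2"),
        DegradationRule("deg_p21_nuc", Pattern.of("p21", comp=NUC), "kd_p21_nuc"),
        DegradationRule("deg_p21", Pattern.of("p21"), "kd_p21"),
        DegradationRule("deg_rb_p", Pattern.of(("Rb", {"S788": "p"})), "kd_rb_p"),
        DegradationRule("deg_rb", Pattern.of("Rb"), "kd_rb"),
        DegradationRule("deg_e2f_nuc", Pattern.of("E2F1", comp=NUC), "kd_e2f1_nuc"),
        DegradationRule("deg_e2f", Pattern.of("E2F1"), "kd_e2f1"),
    ]

    seeds = [_mono(name, CYT) for name in ("CD4", "CycE", "CDK2", "p21", "Rb", "E2F1")]
    return RuleSet(
        molecules=dict(MOLECULES), rules=rules, degradation=degradation, seeds=seeds
    )


# --------------------------------------------------------------------------
# Observables
# --------------------------------------------------------------------------

#: The nine immunoblot-style protein observables (scaled sums of species)
#: plus DNA content.  A "total" sums every species containing the molecule;
#: a phospho-observable sums every species carrying the phosphosite.
OBSERVABLE_PATTERNS: dict[str, Pattern | None] = {
    "cyce_cdk2": Pattern.of("CycE", "CDK2"),
    "cycd1_cdk4": Pattern.of("CD4"),
    "p21_cdk2": Pattern.of("p21", "CDK2"),
    "p21_total": Pattern.of("p21"),
    "e2f1_total": Pattern.of("E2F1"),
    "rb_total": Pattern.of("Rb"),
    "pcdk2_t160": Pattern.of(("CDK2", {"T160": "p"})),
    "prb_s788": Pattern.of(("Rb", {"S788": "p"})),
    "prb_s800": Pattern.of(("Rb", {"S800": "p"})),
    "dna": None,  # DNA content state, scale-free (normalized to 1 at stimulation)
}

PROTEIN_OBSERVABLES = tuple(k for k, v in OBSERVABLE_PATTERNS.items() if v is not None)


def attach_observables(network) -> None:
    """Populate the network's observable map (10 observables, 9 scaling
    parameters; the DNA observable is scale-free)."""
    obs: dict[str, list[str]] = {}
    scaling: dict[str, str] = {}
    for name, pat in OBSERVABLE_PATTERNS.items():
        if pat is None:
            obs[name] = [network.dna_species_name]
        else:
            obs[name] = [s.name for s in network.species if pat.matches(s)]
            scaling[name] = f"sc_{name}"
    network.observables = obs
    network.scaling_params = scaling


def toy_rules(kon: str = "kon", koff: str = "koff") -> RuleSet:
    """Minimal ``A + B <-> AB`` rule set used for engine-level tests."""
    mols = {"A": Molecule("A"), "B": Molecule("B")}
    a = Species.make(CYT, [("A", ())])
    b = Species.make(CYT, [("B", ())])
    rules = [
        BindingRule(
            "bind_ab",
            Pattern.of("A", comp=CYT, exact=True),
            Pattern.of("B", comp=CYT, exact=True),
            kon, koff,
        )
    ]
    return RuleSet(molecules=mols, rules=rules, seeds=[a, b])
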