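"""Rule-based construction of the G1/S reaction network.

Species are complexes of molecules (with phosphorylation sites) living in a
compartment (cytoplasm or nucleus), plus the dimensionless DNA-content state.
Rules are patterns: a binding rule, for example, applies to every pair of
species matching its reactant patterns, so one rule can expand into several
concrete reactions that share a rate constant.  :func:`generate_network`
iterates rule application from the seed species to closure and emits a
deterministic, canonically ordered reaction network.

The expansion is generic -- toy rule sets (``A + B <-> AB``) expand just as
the full G1/S rule set does; the biology lives in :mod:`hepg1s.rules`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

__all__ = [
    "Molecule",
    "Species",
    "Pattern",
    "SynthesisRule",
    "BindingRule",
    "TransportRule",
    "ModificationRule",
    "UnbindRule",
    "DegradationRule",
    "DnaSynthesisRule",
    "RuleSet",
    "Reaction",
    "ReactionNetwork",
    "ExpansionError",
    "generate_network",
]


class ExpansionError(RuntimeError):
    """Rule closure failed to terminate within the species cap."""


@dataclass(frozen=True)
class Molecule:
    """A molecular component with named modification sites.

    ``sites`` maps a site name to the tuple of its admissible states; the
    first state is the default (used when the molecule is synthesized).
    """

    name: str
    sites: tuple[tuple[str, tuple[str, ...]], ...] = ()

    def default_states(self) -> tuple[tuple[str, str], ...]:
        return tuple((s, states[0]) for s, states in self.sites)


# A molecule instance inside a species: (molecule name, ((site, state), ...))
MolInstance = tuple[str, tuple[tuple[str, str], ...]]


@dataclass(frozen=True, order=True)
class Species:
    """A complex of molecule instances in one compartment.

    The canonical name (compartment prefix, dot-joined sorted molecule names
    with site-state suffixes) makes network generation reproducible.
    """

    compartment: str
    molecules: tuple[MolInstance, ...]

    @staticmethod
    def make(compartment: str, molecules: list[MolInstance]) -> "Species":
        return Species(compartment, tuple(sorted(molecules)))

    @property
    def name(self) -> str:
        parts = []
        for mol, sites in self.molecules:
            if sites:
                suffix = ",".join(f"{s}~{v}" for s, v in sites)
                parts.append(f"{mol}({suffix})")
            else:
                parts.append(mol)
        return f"{self.compartment}:" + ".".join(parts)

    def contains(self, mol_name: str) -> bool:
        return any(m == mol_name for m, _ in self.molecules)


@dataclass(frozen=True)
class Pattern:
    """A structural condition selecting species.

    * ``compartment`` -- required compartment, or ``None`` for any.
    * ``contains`` -- molecule requirements ``(name, {site: state, ...})``;
      each required molecule must be present with the given site states
      (sites not listed are unconstrained).
    * ``absent`` -- molecule names that must not occur in the species.
    * ``exact`` -- if True the species must consist of exactly the molecules
      in ``contains`` (a monomer pattern lists one).
    """

    compartment: str | None = None
    contains: tuple[tuple[str, tuple[tuple[str, str], ...]], ...] = ()
    absent: tuple[str, ...] = ()
    exact: bool = False

    @staticmethod
    def of(
        *mols: str | tuple[str, dict[str, str]],
        comp: str | None = None,
        absent: tuple[str, ...] = (),
        exact: bool = False,
    ) -> "Pattern":
        reqs = []
        for m in mols:
            if isinstance(m, str):
                reqs.append((m, ()))
            else:
                name, conds = m
                reqs.append((name, tuple(sorted(conds.items()))))
        return Pattern(comp, tuple(reqs), tuple(absent), exact)

    def matches(self, sp: Species) -> bool:
        if self.compartment is not None and sp.compartment != self.compartment:
            return False
        if any(sp.contains(a) for a in self.absent):
            return False
        if self.exact and len(sp.molecules) != len(self.contains):
            return False
        available = list(sp.molecules)
        for req_name, req_sites in self.contains:
            req = dict(req_sites)
            for i, (mol, sites) in enumerate(available):
                if mol == req_name and all(dict(sites).get(s) == v for s, v in req.items()):
                    available.pop(i)
                    break
            else:
                return False
        return True


# --------------------------------------------------------------------------
# Rules
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SynthesisRule:
    """Zeroth-order production of a species, scaled by input activities.

    ``input_factors`` name input nodes whose activity multiplies the rate; a
    ``"~node"`` token stands for ``(1 - activity)`` (inhibitory input).
    ``modifiers`` are patterns whose matching species concentrations
    multiply the rate (e.g. transcriptional induction by free nuclear E2F-1).
    """

    rule_id: str
    product: Species
    rate_param: str
    input_factors: tuple[str, ...] = ()
    modifiers: tuple[Pattern, ...] = ()


@dataclass(frozen=True)
class BindingRule:
    """Reversible binding ``A + B <-> AB`` within one compartment.

    Expands to one forward and one reverse reaction per matching (A, B)
    pair.  ``b`` must be a monomer pattern; the product is the union of the
    two complexes.
    """

    rule_id: str
    a: Pattern
    b: Pattern
    kon_param: str
    koff_param: str
    #: input-node activity tokens multiplying the on/off rates (a ``"~node"``
    #: token stands for ``1 - activity``), e.g. signaling-dependent release
    kon_factors: tuple[str, ...] = ()
    koff_factors: tuple[str, ...] = ()


@dataclass(frozen=True)
class TransportRule:
    """First-order transport of matching species between compartments."""

    rule_id: str
    pattern: Pattern
    from_comp: str
    to_comp: str
    rate_param: str


@dataclass(frozen=True)
class ModificationRule:
    """Site-state change on a molecule within matching species.

    If ``catalyst`` is given, one reaction is emitted per
    (substrate, catalyst) species pair with rate
    ``k * [substrate] * [catalyst]``; otherwise the reaction is unary
    (implicit constitutive enzyme, e.g. CAK).  ``cdk4_catalyzed`` marks
    reactions silenced by PD0332991.
    """

    rule_id: str
    substrate: Pattern
    molecule: str
    site: str
    from_state: str
    to_state: str
    rate_param: str
    catalyst: Pattern | None = None
    cdk4_catalyzed: bool = False


@dataclass(frozen=True)
class UnbindRule:
    """Irreversible ejection of one molecule from matching complexes."""

    rule_id: str
    pattern: Pattern
    eject: str
    rate_param: str


@dataclass(frozen=True)
class DegradationRule:
    """First-order decay; an ordered list of these assigns one degradation
    reaction per protein species (first matching rule wins), so complexes
    can reuse the rate constant of a constituent."""

    rule_id: str
    pattern: Pattern
    rate_param: str


@dataclass(frozen=True)
class DnaSynthesisRule:
    """DNA-content production: ``d(DNA)/dt = k * prod(modifiers) * (2 - DNA)``.

    The ``(2 - DNA)`` factor hard-bounds the DNA state in [1, 2] (one full
    genome duplication); the modifiers realize the AND cooperation of free
    E2F-1 and active pCDK2 T160.
    """

    rule_id: str
    rate_param: str
    modifiers: tuple[Pattern, ...]


Rule = (
    SynthesisRule
    | BindingRule
    | TransportRule
    | ModificationRule
    | UnbindRule
    | DegradationRule
    | DnaSynthesisRule
)


@dataclass
class RuleSet:
    """A rule collection plus molecule declarations and seed species."""

    molecules: dict[str, Molecule]
    rules: list[Rule]
    degradation: list[DegradationRule] = field(default_factory=list)
    seeds: list[Species] = field(default_factory=list)
    dna_species_name: str = "DNA"

    def validate(self, known_params: set[str] | None = None) -> None:
        """Check that every rule references declared molecules (and, if a
        parameter universe is given, declared rate parameters)."""
        names = set(self.molecules)
        for rule in self.rules + list(self.degradation):
            for pat in _rule_patterns(rule):
                for mol, _ in pat.contains:
                    if mol not in names:
                        raise ValueError(f"rule {rule.rule_id}: unknown molecule {mol!r}")
            if known_params is not None:
                for p in _rule_params(rule):
                    if p not in known_params:
                        raise ValueError(f"rule {rule.rule_id}: unknown parameter {p!r}")


def _rule_patterns(rule: Rule) -> list[Pattern]:
    if isinstance(rule, SynthesisRule):
        return list(rule.modifiers)
    if isinstance(rule, BindingRule):
        return [rule.a, rule.b]
    if isinstance(rule, TransportRule):
        return [rule.pattern]
    if isinstance(rule, ModificationRule):
        return [rule.substrate] + ([rule.catalyst] if rule.catalyst else [])
    if isinstance(rule, (UnbindRule, DegradationRule)):
        return [rule.pattern]
    if isinstance(rule, DnaSynthesisRule):
        return list(rule.modifiers)
    return []


def _rule_params(rule: Rule) -> list[str]:
    if isinstance(rule, BindingRule):
        return [rule.kon_param, rule.koff_param]
    return [rule.rate_param]


# --------------------------------------------------------------------------
# Reactions and the expanded network
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Reaction:
    """One concrete reaction of the expanded network.

    Rate = ``k * prod([reactants]) * prod([modifier species]) *
    prod(input factors) * (2 - DNA if dna_capped)``; ``cdk4_catalyzed``
    reactions are additionally multiplied by the protocol's CDK4 activity
    factor (PD0332991 semantics).
    """

    rxn_id: str
    rule_id: str
    rate_param: str
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    modifiers: tuple[str, ...] = ()
    input_factors: tuple[str, ...] = ()
    dna_capped: bool = False
    cdk4_catalyzed: bool = False


@dataclass
class ReactionNetwork:
    """Expanded species/reaction network with its observable map."""

    species: list[Species]
    reactions: list[Reaction]
    dna_species_name: str = "DNA"
    observables: dict[str, list[str]] = field(default_factory=dict)
    scaling_params: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._has_dna = any(
            self.dna_species_name in r.reactants + r.products + r.modifiers or r.dna_capped
            for r in self.reactions
        )

    @property
    def n_dynamic_species(self) -> int:
        """Number of state variables (ODEs): protein species + DNA if used."""
        return len(self.species) + (1 if self._has_dna else 0)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def kinetic_params(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.reactions:
            seen.setdefault(r.rate_param)
        return list(seen)

    @property
    def n_kinetic_params(self) -> int:
        return len(self.kinetic_params)

    def state_names(self) -> list[str]:
        names = [s.name for s in self.species]
        if self._has_dna:
            names.append(self.dna_species_name)
        return names

    def species_index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.state_names())}


def generate_network(ruleset: RuleSet, max_species: int = 200) -> ReactionNetwork:
    """Expand a rule set to closure over its seed species.

    Applies every rule to the current species set, adding product species,
    until no new species appear (deterministic fixpoint; species and
    reactions are canonically sorted).  Raises :class:`ExpansionError` if
    the species count exceeds ``max_species``.
    """
    ruleset.validate()
    current: dict[str, Species] = {s.name: s for s in ruleset.seeds}
    for rule in ruleset.rules:
        if isinstance(rule, SynthesisRule):
            current.setdefault(rule.product.name, rule.product)

    while True:
        new: dict[str, Species] = {}
        ordered = sorted(current.values())
        for rule in ruleset.rules:
            for sp in _apply_rule_species(rule, ordered):
                if sp.name not in current:
                    new.setdefault(sp.name, sp)
        if not new:
            break
        current.update(new)
        if len(current) > max_species:
            raise ExpansionError(
                f"rule closure exceeded {max_species} species; "
                "check binding patterns for unbounded polymerization"
            )

    species = sorted(current.values())
    reactions: list[Reaction] = []
    counter = itertools.count(1)

    def rid() -> str:
        return f"r{next(counter)}"

    for rule in ruleset.rules:
        reactions.extend(_expand_rule(rule, species, rid, ruleset))
    # degradation pass: one first-order decay per protein species
    for sp in species:
        for deg in ruleset.degradation:
            if deg.pattern.matches(sp):
                reactions.append(
                    Reaction(rid(), deg.rule_id, deg.rate_param, (sp.name,), ())
                )
                break

    return ReactionNetwork(species, reactions, ruleset.dna_species_name)


def _apply_rule_species(rule: Rule, species: list[Species]) -> list[Species]:
    """Product species a rule would create from the current species set."""
    out: list[Species] = []
    if isinstance(rule, BindingRule):
        for a, b, ab in _binding_instances(rule, species):
            out.extend([a, b, ab])
    elif isinstance(rule, TransportRule):
        for sp in species:
            if sp.compartment == rule.from_comp and rule.pattern.matches(sp):
                out.append(Species.make(rule.to_comp, list(sp.molecules)))
    elif isinstance(rule, ModificationRule):
        for sp in species:
            if rule.substrate.matches(sp):
                out.append(_modify(sp, rule))
    elif isinstance(rule, UnbindRule):
        for sp in species:
            if rule.pattern.matches(sp) and len(sp.molecules) > 1:
                rest, ejected = _split(sp, rule.eject)
                out.extend([rest, ejected])
    return out


def _binding_instances(
    rule: BindingRule, species: list[Species]
) -> list[tuple[Species, Species, Species]]:
    """All (A, B, AB) triples a binding rule induces on the species set.

    Forward matching pairs up free partners; in addition, any existing
    complex that decomposes into a matching (A, B) pair (e.g. one imported
    from another compartment) contributes the same triple, so its
    dissociation channel is generated even before the free partners exist.
    """
    instances: dict[tuple[str, str, str], tuple[Species, Species, Species]] = {}
    a_matches = [s for s in species if rule.a.matches(s)]
    b_matches = [s for s in species if rule.b.matches(s)]
    for a in a_matches:
        for b in b_matches:
            if a.compartment == b.compartment:
                ab = _merge(a, b)
                instances.setdefault((a.name, b.name, ab.name), (a, b, ab))
    # reverse direction: split candidate complexes on the (monomer) b pattern
    (b_name, b_sites), = rule.b.contains if len(rule.b.contains) == 1 else ((None, ()),)
    if b_name is not None:
        for sp in species:
            if len(sp.molecules) < 2:
                continue
            for i, (mol, sites) in enumerate(sp.molecules):
                if mol != b_name or any(dict(sites).get(s) != v for s, v in b_sites):
                    continue
                rest = Species.make(
                    sp.compartment, [m for j, m in enumerate(sp.molecules) if j != i]
                )
                part = Species.make(sp.compartment, [sp.molecules[i]])
                if rule.a.matches(rest) and rule.b.matches(part):
                    instances.setdefault((rest.name, part.name, sp.name), (rest, part, sp))
    return [instances[k] for k in sorted(instances)]


def _merge(a: Species, b: Species) -> Species:
    return Species.make(a.compartment, list(a.molecules) + list(b.molecules))


def _modify(sp: Species, rule: ModificationRule) -> Species:
    mols = list(sp.molecules)
    for i, (name, sites) in enumerate(mols):
        d = dict(sites)
        if name == rule.molecule and d.get(rule.site) == rule.from_state:
            d[rule.site] = rule.to_state
            mols[i] = (name, tuple(sorted(d.items())))
            return Species.make(sp.compartment, mols)
    raise ValueError(
        f"rule {rule.rule_id}: no {rule.molecule}.{rule.site}~{rule.from_state} in {sp.name}"
    )


def _split(sp: Species, eject: str) -> tuple[Species, Species]:
    mols = list(sp.molecules)
    for i, (name, sites) in enumerate(mols):
        if name == eject:
            ejected = mols.pop(i)
            return (
                Species.make(sp.compartment, mols),
                Species.make(sp.compartment, [ejected]),
            )
    raise ValueError(f"cannot eject {eject} from {sp.name}")


def _expand_rule(rule: Rule, species: list[Species], rid, ruleset: RuleSet) -> list[Reaction]:
    out: list[Reaction] = []
    if isinstance(rule, SynthesisRule):
        mod_sets = [
            [s.name for s in species if pat.matches(s)] for pat in rule.modifiers
        ]
        for combo in itertools.product(*mod_sets) if mod_sets else [()]:
            out.append(
                Reaction(
                    rid(), rule.rule_id, rule.rate_param,
                    (), (rule.product.name,),
                    modifiers=tuple(combo), input_factors=rule.input_factors,
                )
            )
    elif isinstance(rule, BindingRule):
        for a, b, ab in _binding_instances(rule, species):
            out.append(
                Reaction(rid(), rule.rule_id, rule.kon_param, (a.name, b.name), (ab.name,),
                         input_factors=rule.kon_factors)
            )
            out.append(
                Reaction(rid(), rule.rule_id, rule.koff_param, (ab.name,), (a.name, b.name),
                         input_factors=rule.koff_factors)
            )
    elif isinstance(rule, TransportRule):
        for sp in species:
            if sp.compartment == rule.from_comp and rule.pattern.matches(sp):
                dest = Species.make(rule.to_comp, list(sp.molecules))
                out.append(
                    Reaction(rid(), rule.rule_id, rule.rate_param, (sp.name,), (dest.name,))
                )
    elif isinstance(rule, ModificationRule):
        subs = [s for s in species if rule.substrate.matches(s)]
        cats = (
            [s.name for s in species if rule.catalyst.matches(s)]
            if rule.catalyst is not None
            else [None]
        )
        for sub in subs:
            prod = _modify(sub, rule)
            for cat in cats:
                out.append(
                    Reaction(
                        rid(), rule.rule_id, rule.rate_param,
                        (sub.name,), (prod.name,),
                        modifiers=(cat,) if cat else (),
                        cdk4_catalyzed=rule.cdk4_catalyzed,
                    )
                )
    elif isinstance(rule, UnbindRule):
        for sp in species:
            if rule.pattern.matches(sp) and len(sp.molecules) > 1:
                rest, ejected = _split(sp, rule.eject)
                out.append(
                    Reaction(
                        rid(), rule.rule_id, rule.rate_param,
                        (sp.name,), (rest.name, ejected.name),
                    )
                )
    elif isinstance(rule, DnaSynthesisRule):
        mod_sets = [[s.name for s in species if pat.matches(s)] for pat in rule.modifiers]
        for combo in itertools.product(*mod_sets) if mod_sets else [()]:
            out.append(
                Reaction(
                    rid(), rule.rule_id, rule.rate_param,
                    (), (ruleset.dna_species_name,),
                    modifiers=tuple(combo), dna_capped=True,
                )
            )
    return out
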