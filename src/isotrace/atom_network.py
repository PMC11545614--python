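"""Atom-mapped central-carbon reaction network.

Metabolites carry carbon/nitrogen atom counts derived from their elemental
formula; reactions carry explicit per-atom substrate→product position maps for
C and N, so labeling outcomes of any tracer are derivable rather than
hard-coded. CO2 and NH3 are explicit sink metabolites, which makes per-element
atom conservation a checkable invariant of every reaction.

Positions are 1-based, following biochemical carbon numbering (glucose C1 is
the aldehyde carbon, pyruvate C1 the carboxyl). Reversible steps are encoded
as two directed reactions sharing an id stem (``ldh_f``/``ldh_r``); which
direction carries material is decided by source-fraction parameters at
simulation time, not by thermodynamics.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import yaml

__all__ = [
    "Metabolite",
    "AtomMap",
    "Reaction",
    "ReactionNetwork",
    "TracerSpec",
    "NetworkConfigError",
    "parse_formula",
    "formula_to_string",
    "build_canonical_network",
    "validate_network",
    "load_network",
    "dump_network",
    "to_networkx",
    "export_sif",
    "export_graphml",
]

TRACER_ELEMENTS = ("C", "N")
_ELEMENT_ORDER = ("C", "H", "N", "O", "P", "S")
_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")

MAX_CARBON = 12  # network-scale guard: this is a central-carbon model


class NetworkConfigError(ValueError):
    """Raised for invalid network configuration (unknown metabolite, bad position...)."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse 'C6H12O6' into {'C': 6, 'H': 12, 'O': 6}."""
    out: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if not m.group(0):
            continue
        if m.start() != pos:
            raise NetworkConfigError(f"cannot parse formula {formula!r}")
        pos = m.end()
        out[m.group(1)] = out.get(m.group(1), 0) + (int(m.group(2)) if m.group(2) else 1)
    if pos != len(formula) or not out:
        raise NetworkConfigError(f"cannot parse formula {formula!r}")
    return out


def formula_to_string(formula: Mapping[str, int]) -> str:
    parts = []
    for el in _ELEMENT_ORDER:
        n = formula.get(el, 0)
        if n:
            parts.append(el + (str(n) if n != 1 else ""))
    for el in sorted(set(formula) - set(_ELEMENT_ORDER)):
        if formula[el]:
            parts.append(el + str(formula[el]))
    return "".join(parts)


@dataclass(frozen=True)
class Metabolite:
    """A chemical species tracked by the network.

    ``formula`` is the elemental composition; tracer bookkeeping uses only the
    C and N counts. ``compartment`` is reserved for future use and always empty
    in the canonical network (single-compartment model).
    """

    id: str
    formula: str
    compartment: str = ""

    def __post_init__(self) -> None:
        counts = parse_formula(self.formula)
        if counts.get("C", 0) > MAX_CARBON:
            raise NetworkConfigError(
                f"{self.id}: {counts.get('C', 0)} carbons exceeds network guard ({MAX_CARBON})"
            )

    @property
    def composition(self) -> dict[str, int]:
        return parse_formula(self.formula)

    @property
    def n_carbon(self) -> int:
        return self.composition.get("C", 0)

    @property
    def n_nitrogen(self) -> int:
        return self.composition.get("N", 0)

    def n_atoms(self, element: str) -> int:
        return self.composition.get(element, 0)

    def tracer_atoms(self) -> tuple[tuple[str, int], ...]:
        """Mapped atoms in canonical order: carbons C1..Cn, then nitrogens N1..Nn."""
        atoms: list[tuple[str, int]] = []
        for el in TRACER_ELEMENTS:
            atoms.extend((el, i) for i in range(1, self.n_atoms(el) + 1))
        return tuple(atoms)


@dataclass(frozen=True)
class AtomMap:
    """Per-element atom transitions of one reaction.

    ``pairs`` entries are (substrate id, substrate position, product id,
    product position); every substrate atom of the element must appear exactly
    once on the left and every product atom exactly once on the right.
    """

    element: str
    pairs: tuple[tuple[str, int, str, int], ...]

    def __post_init__(self) -> None:
        if self.element not in TRACER_ELEMENTS:
            raise NetworkConfigError(f"unsupported mapped element {self.element!r}")
        object.__setattr__(self, "pairs", tuple(tuple(p) for p in self.pairs))


@dataclass(frozen=True)
class Reaction:
    id: str
    substrates: tuple[str, ...]
    products: tuple[str, ...]
    atom_maps: tuple[AtomMap, ...]
    reversible: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "substrates", tuple(self.substrates))
        object.__setattr__(self, "products", tuple(self.products))
        object.__setattr__(self, "atom_maps", tuple(self.atom_maps))

    def atom_map(self, element: str) -> AtomMap | None:
        for am in self.atom_maps:
            if am.element == element:
                return am
        return None

    def reversed(self, new_id: str) -> "Reaction":
        """Directed reverse of this reaction with inverted atom maps."""
        maps = tuple(
            AtomMap(am.element, tuple((p, j, s, i) for (s, i, p, j) in am.pairs))
            for am in self.atom_maps
        )
        return Reaction(new_id, self.products, self.substrates, maps, reversible=self.reversible)


@dataclass
class ReactionNetwork:
    """Directed reaction set over declared metabolites.

    ``sources`` are tracer entry points (clamped by the simulator); ``sinks``
    (CO2, NH3) absorb leaving atoms and are treated as unlabeled pools when
    they appear as substrates (e.g. the carboxylating CO2 of reductive citrate
    formation).
    """

    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    sources: tuple[str, ...] = ()
    sinks: tuple[str, ...] = ()

    def add_metabolite(self, met: Metabolite) -> None:
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise NetworkConfigError(f"duplicate reaction id {rxn.id!r}")
        self.reactions[rxn.id] = rxn

    def producers_of(self, met_id: str) -> list[Reaction]:
        return [r for r in self.reactions.values() if met_id in r.products]

    def copy(self) -> "ReactionNetwork":
        return ReactionNetwork(
            dict(self.metabolites), dict(self.reactions), self.sources, self.sinks
        )


@dataclass(frozen=True)
class TracerSpec:
    """A labeled nutrient: which positions carry heavy isotopes and how well.

    ``enrichment_fraction`` is the fraction of the source pool that is tracer
    (the rest is unlabeled); ``purity`` is the per-atom probability that a
    nominally labeled position actually carries the heavy isotope.
    """

    metabolite: str
    element_labels: Mapping[str, tuple[int, ...]]
    enrichment_fraction: float = 1.0
    purity: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.enrichment_fraction <= 1.0:
            raise NetworkConfigError("enrichment_fraction must be in [0, 1]")
        if not 0.0 <= self.purity <= 1.0:
            raise NetworkConfigError("purity must be in [0, 1]")
        object.__setattr__(
            self,
            "element_labels",
            {el: tuple(sorted(pos)) for el, pos in dict(self.element_labels).items()},
        )

    def validate_against(self, net: ReactionNetwork) -> None:
        if self.metabolite not in net.metabolites:
            raise NetworkConfigError(f"tracer metabolite {self.metabolite!r} not in network")
        met = net.metabolites[self.metabolite]
        for el, positions in self.element_labels.items():
            if el not in TRACER_ELEMENTS:
                raise NetworkConfigError(f"tracer element {el!r} not supported")
            for p in positions:
                if not 1 <= p <= met.n_atoms(el):
                    raise NetworkConfigError(
                        f"tracer position {el}{p} invalid for {met.id} "
                        f"({met.n_atoms(el)} {el} atoms)"
                    )


# Common tracers from the study design: [1,2-13C]glucose and [13C5,15N2]glutamine.
def glucose_12_13c(enrichment: float = 1.0, purity: float = 1.0) -> TracerSpec:
    return TracerSpec("glucose", {"C": (1, 2)}, enrichment, purity)


def glutamine_13c5_15n2(enrichment: float = 1.0, purity: float = 1.0) -> TracerSpec:
    return TracerSpec("glutamine", {"C": (1, 2, 3, 4, 5), "N": (1, 2)}, enrichment, purity)


# ---------------------------------------------------------------------------
# validation

def validate_network(net: ReactionNetwork) -> list[str]:
    """Check all invariants; returns a list of human-readable violations.

    Violations are data, not exceptions: an empty list means the network is
    sound. Each violation names the reaction, element and atom concerned.
    """
    violations: list[str] = []
    for rid, rxn in sorted(net.reactions.items()):
        for side, ids in (("substrate", rxn.substrates), ("product", rxn.products)):
            for mid in ids:
                if mid not in net.metabolites:
                    violations.append(f"{rid}: {side} {mid!r} not declared")
    for rid, rxn in sorted(net.reactions.items()):
        if any(m not in net.metabolites for m in rxn.substrates + rxn.products):
            continue
        for el in TRACER_ELEMENTS:
            need = any(net.metabolites[m].n_atoms(el) for m in rxn.substrates + rxn.products)
            am = rxn.atom_map(el)
            if am is None:
                if need:
                    violations.append(f"{rid}/{el}: atoms present but no atom map")
                continue
            sub_atoms = [
                (m, i)
                for m in rxn.substrates
                for i in range(1, net.metabolites[m].n_atoms(el) + 1)
            ]
            prod_atoms = [
                (m, j)
                for m in rxn.products
                for j in range(1, net.metabolites[m].n_atoms(el) + 1)
            ]
            seen_sub = [(s, i) for (s, i, _, _) in am.pairs]
            seen_prod = [(p, j) for (_, _, p, j) in am.pairs]
            for atom in sub_atoms:
                c = seen_sub.count(atom)
                if c == 0:
                    violations.append(f"{rid}/{el}: substrate atom {atom[0]} {el}{atom[1]} unmapped")
                elif c > 1:
                    violations.append(
                        f"{rid}/{el}: substrate atom {atom[0]} {el}{atom[1]} mapped {c} times"
                    )
            for atom in seen_sub:
                if atom not in sub_atoms:
                    violations.append(
                        f"{rid}/{el}: pair references invalid substrate atom {atom[0]} {el}{atom[1]}"
                    )
            for atom in prod_atoms:
                c = seen_prod.count(atom)
                if c == 0:
                    violations.append(f"{rid}/{el}: product atom {atom[0]} {el}{atom[1]} unfilled")
                elif c > 1:
                    violations.append(
                        f"{rid}/{el}: product atom {atom[0]} {el}{atom[1]} filled {c} times"
                    )
            for atom in seen_prod:
                if atom not in prod_atoms:
                    violations.append(
                        f"{rid}/{el}: pair references invalid product atom {atom[0]} {el}{atom[1]}"
                    )
    for src in net.sources:
        if src not in net.metabolites:
            violations.append(f"source {src!r} not declared")
    for snk in net.sinks:
        if snk not in net.metabolites:
            violations.append(f"sink {snk!r} not declared")
    return violations


# ---------------------------------------------------------------------------
# canonical network

def _ident(element: str, sub: str, prod: str, n: int) -> list[tuple[str, int, str, int]]:
    return [(sub, i, prod, i) for i in range(1, n + 1)]


_CANONICAL_METABOLITES = [
    ("glucose", "C6H12O6"),
    ("g6p", "C6H13O9P"),
    ("f6p", "C6H13O9P"),
    ("fbp", "C6H14O12P2"),
    ("dhap", "C3H7O6P"),
    ("gap", "C3H7O6P"),
    ("pyruvate", "C3H4O3"),
    ("lactate", "C3H6O3"),
    ("accoa", "C2H3O"),  # 2-carbon acetyl labeling unit; CoA moiety carries no tracer atoms
    ("citrate", "C6H8O7"),
    ("aconitate", "C6H6O6"),
    ("akg", "C5H6O5"),
    ("succinate", "C4H6O4"),
    ("fumarate", "C4H4O4"),
    ("malate", "C4H6O5"),
    ("oaa", "C4H4O5"),
    ("glutamine", "C5H10N2O3"),
    ("glutamate", "C5H9NO4"),
    ("alanine", "C3H7NO2"),
    ("aspartate", "C4H7NO4"),
    ("r5p", "C5H11O8P"),
    ("e4p", "C4H9O7P"),
    ("nucleotide", "C5H11O8P"),  # ribose moiety of newly made nucleotides
    ("co2", "CO2"),
    ("nh3", "H3N"),
]


def _canonical_reactions() -> list[Reaction]:
    R, A = Reaction, AtomMap
    rxns: list[Reaction] = []

    # Glycolysis. Upper steps are carbon-identity; the aldol split sends FBP
    # C1-C3 to DHAP and C4-C6 to GAP, and triose-phosphate isomerase inverts
    # DHAP (C1<->C3) into GAP, merging the two triose pools.
    rxns.append(R("hk", ("glucose",), ("g6p",), (A("C", _ident("C", "glucose", "g6p", 6)),)))
    rxns.append(R("pgi", ("g6p",), ("f6p",), (A("C", _ident("C", "g6p", "f6p", 6)),)))
    rxns.append(R("pfk", ("f6p",), ("fbp",), (A("C", _ident("C", "f6p", "fbp", 6)),)))
    rxns.append(
        R(
            "aldolase",
            ("fbp",),
            ("dhap", "gap"),
            (
                A(
                    "C",
                    (
                        ("fbp", 1, "dhap", 1),
                        ("fbp", 2, "dhap", 2),
                        ("fbp", 3, "dhap", 3),
                        ("fbp", 4, "gap", 1),
                        ("fbp", 5, "gap", 2),
                        ("fbp", 6, "gap", 3),
                    ),
                ),
            ),
        )
    )
    rxns.append(
        R(
            "tpi",
            ("dhap",),
            ("gap",),
            (A("C", (("dhap", 1, "gap", 3), ("dhap", 2, "gap", 2), ("dhap", 3, "gap", 1))),),
        )
    )
    # lower glycolysis lumped: GAP C1 (aldehyde) becomes the pyruvate carboxyl
    rxns.append(R("pk", ("gap",), ("pyruvate",), (A("C", _ident("C", "gap", "pyruvate", 3)),)))

    # Lactate dehydrogenase (both directions)
    ldh = R(
        "ldh_f", ("pyruvate",), ("lactate",),
        (A("C", _ident("C", "pyruvate", "lactate", 3)),), reversible=True
    )
    rxns.append(ldh)
    rxns.append(ldh.reversed("ldh_r"))

    # Pyruvate dehydrogenase: carboxyl (C1) leaves as CO2, C2/C3 become acetyl
    rxns.append(
        R(
            "pdh",
            ("pyruvate",),
            ("accoa", "co2"),
            (
                A(
                    "C",
                    (("pyruvate", 1, "co2", 1), ("pyruvate", 2, "accoa", 1), ("pyruvate", 3, "accoa", 2)),
                ),
            ),
        )
    )

    # Citrate synthase condensation: citrate C1-C4 from oxaloacetate, C5-C6 from acetyl
    rxns.append(
        R(
            "cs",
            ("accoa", "oaa"),
            ("citrate",),
            (
                A(
                    "C",
                    tuple(("oaa", i, "citrate", i) for i in range(1, 5))
                    + (("accoa", 1, "citrate", 5), ("accoa", 2, "citrate", 6)),
                ),
            ),
        )
    )
    rxns.append(R("aco", ("citrate",), ("aconitate",), (A("C", _ident("C", "citrate", "aconitate", 6)),)))
    # Isocitrate dehydrogenase (oxidative): the CO2 released on the first turn
    # is oxaloacetate-derived (aconitate C1); acetyl carbons are retained.
    rxns.append(
        R(
            "idh",
            ("aconitate",),
            ("akg", "co2"),
            (
                A(
                    "C",
                    (("aconitate", 1, "co2", 1),)
                    + tuple(("aconitate", i + 1, "akg", i) for i in range(1, 6)),
                ),
            ),
        )
    )
    # alpha-KG dehydrogenase + succinyl-CoA synthetase lumped
    rxns.append(
        R(
            "akgdh",
            ("akg",),
            ("succinate", "co2"),
            (
                A(
                    "C",
                    (("akg", 1, "co2", 1),)
                    + tuple(("akg", i + 1, "succinate", i) for i in range(1, 5)),
                ),
            ),
        )
    )
    rxns.append(R("sdh", ("succinate",), ("fumarate",), (A("C", _ident("C", "succinate", "fumarate", 4)),)))
    rxns.append(R("fh", ("fumarate",), ("malate",), (A("C", _ident("C", "fumarate", "malate", 4)),)))
    rxns.append(R("mdh", ("malate",), ("oaa",), (A("C", _ident("C", "malate", "oaa", 4)),)))

    # Reductive carboxylation: alpha-KG + CO2 -> citrate, retaining all five
    # alpha-KG carbons (inverse of the oxidative IDH mapping).
    rxns.append(
        R(
            "rc",
            ("akg", "co2"),
            ("citrate",),
            (
                A(
                    "C",
                    (("co2", 1, "citrate", 1),)
                    + tuple(("akg", i, "citrate", i + 1) for i in range(1, 6)),
                ),
            ),
        )
    )

    # Malic enzyme: malate -> pyruvate + CO2 (C4 carboxyl leaves)
    rxns.append(
        R(
            "me",
            ("malate",),
            ("pyruvate", "co2"),
            (
                A(
                    "C",
                    tuple(("malate", i, "pyruvate", i) for i in range(1, 4))
                    + (("malate", 4, "co2", 1),),
                ),
            ),
        )
    )

    # Glutaminase: amide nitrogen (N2) leaves as NH3; alpha nitrogen retained
    rxns.append(
        R(
            "gls",
            ("glutamine",),
            ("glutamate", "nh3"),
            (
                A("C", _ident("C", "glutamine", "glutamate", 5)),
                A("N", (("glutamine", 1, "glutamate", 1), ("glutamine", 2, "nh3", 1))),
            ),
        )
    )

    # Alanine transaminase: carbon skeletons swap amino groups
    alt = R(
        "alt_f",
        ("pyruvate", "glutamate"),
        ("alanine", "akg"),
        (
            A(
                "C",
                tuple(("pyruvate", i, "alanine", i) for i in range(1, 4))
                + tuple(("glutamate", i, "akg", i) for i in range(1, 6)),
            ),
            A("N", (("glutamate", 1, "alanine", 1),)),
        ),
        reversible=True,
    )
    rxns.append(alt)
    rxns.append(alt.reversed("alt_r"))

    # Aspartate transaminase
    ast = R(
        "ast_f",
        ("oaa", "glutamate"),
        ("aspartate", "akg"),
        (
            A(
                "C",
                tuple(("oaa", i, "aspartate", i) for i in range(1, 5))
                + tuple(("glutamate", i, "akg", i) for i in range(1, 6)),
            ),
            A("N", (("glutamate", 1, "aspartate", 1),)),
        ),
        reversible=True,
    )
    rxns.append(ast)
    rxns.append(ast.reversed("ast_r"))

    # Oxidative PPP: G6P C1 is lost as CO2, so glucose C2 becomes ribose C1
    rxns.append(
        R(
            "oxppp",
            ("g6p",),
            ("r5p", "co2"),
            (
                A(
                    "C",
                    (("g6p", 1, "co2", 1),)
                    + tuple(("g6p", i + 1, "r5p", i) for i in range(1, 6)),
                ),
            ),
        )
    )
    # Non-oxidative PPP entry (transketolase-type, lumped): F6P C1-C2 plus a
    # triose give a pentose with no carbon loss; F6P C3-C6 leave as erythrose.
    rxns.append(
        R(
            "tkt",
            ("f6p", "gap"),
            ("r5p", "e4p"),
            (
                A(
                    "C",
                    (
                        ("f6p", 1, "r5p", 1),
                        ("f6p", 2, "r5p", 2),
                        ("f6p", 3, "e4p", 1),
                        ("f6p", 4, "e4p", 2),
                        ("f6p", 5, "e4p", 3),
                        ("f6p", 6, "e4p", 4),
                        ("gap", 1, "r5p", 3),
                        ("gap", 2, "r5p", 4),
                        ("gap", 3, "r5p", 5),
                    ),
                ),
            ),
        )
    )
    # Ribose incorporation into nucleotides (PRPP route, carbon-identity)
    rxns.append(R("prpp", ("r5p",), ("nucleotide",), (A("C", _ident("C", "r5p", "nucleotide", 5)),)))
    return rxns


def build_canonical_network(
    exclude: Iterable[str] = (),
    extra_metabolites: Sequence[Metabolite] = (),
    extra_reactions: Sequence[Reaction] = (),
) -> ReactionNetwork:
    """Build the packaged central-carbon network.

    Covers glycolysis with the aldol split, LDH, PDH, the oxidative TCA cycle,
    reductive carboxylation, malic enzyme, glutaminase, alanine/aspartate
    transaminases, oxidative and non-oxidative PPP, and ribose incorporation
    into nucleotides. ``exclude`` drops reactions by id; extras are validated
    against the assembled network.
    """
    net = ReactionNetwork(sources=("glucose", "glutamine"), sinks=("co2", "nh3"))
    for mid, formula in _CANONICAL_METABOLITES:
        net.add_metabolite(Metabolite(mid, formula))
    for met in extra_metabolites:
        net.add_metabolite(met)
    exclude = set(exclude)
    known = {r.id for r in _canonical_reactions()}
    unknown = exclude - known
    if unknown:
        raise NetworkConfigError(f"exclude names unknown reactions: {sorted(unknown)}")
    for rxn in _canonical_reactions():
        if rxn.id not in exclude:
            net.add_reaction(rxn)
    for rxn in extra_reactions:
        net.add_reaction(rxn)
    problems = validate_network(net)
    if problems:
        raise NetworkConfigError("invalid network override: " + "; ".join(problems))
    return net


# ---------------------------------------------------------------------------
# serialization (human-editable YAML; round-trips byte-stable)

def dump_network(net: ReactionNetwork) -> str:
    doc = {
        "metabolites": [
            {"id": m.id, "formula": m.formula}
            for m in sorted(net.metabolites.values(), key=lambda m: m.id)
        ],
        "sources": sorted(net.sources),
        "sinks": sorted(net.sinks),
        "reactions": [
            {
                "id": r.id,
                "substrates": list(r.substrates),
                "products": list(r.products),
                "reversible": r.reversible,
                "atom_maps": {
                    am.element: [list(p) for p in am.pairs] for am in r.atom_maps
                },
            }
            for r in sorted(net.reactions.values(), key=lambda r: r.id)
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False, default_flow_style=None)


def load_network(text: str) -> ReactionNetwork:
    doc = yaml.safe_load(text)
    net = ReactionNetwork(
        sources=tuple(doc.get("sources", ())), sinks=tuple(doc.get("sinks", ()))
    )
    for m in doc["metabolites"]:
        net.add_metabolite(Metabolite(m["id"], m["formula"], m.get("compartment", "")))
    for r in doc["reactions"]:
        maps = tuple(
            AtomMap(el, tuple(tuple(p) for p in pairs))
            for el, pairs in r.get("atom_maps", {}).items()
        )
        net.add_reaction(
            Reaction(
                r["id"],
                tuple(r["substrates"]),
                tuple(r["products"]),
                maps,
                r.get("reversible", False),
            )
        )
    return net


# ---------------------------------------------------------------------------
# graph export for viewing

def to_networkx(net: ReactionNetwork) -> nx.DiGraph:
    g = nx.DiGraph()
    for m in net.metabolites.values():
        g.add_node(m.id, kind="metabolite", formula=m.formula)
    for r in net.reactions.values():
        g.add_node(r.id, kind="reaction", reversible=r.reversible)
        for s in r.substrates:
            g.add_edge(s, r.id)
        for p in r.products:
            g.add_edge(r.id, p)
    return g


def export_sif(net: ReactionNetwork, path: str) -> None:
    lines = []
    for r in sorted(net.reactions.values(), key=lambda r: r.id):
        for s in r.substrates:
            lines.append(f"{s}\tsubstrate_of\t{r.id}")
        for p in r.products:
            lines.append(f"{r.id}\tproduces\t{p}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def export_graphml(net: ReactionNetwork, path: str) -> None:
    nx.write_graphml(to_networkx(net), path)
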