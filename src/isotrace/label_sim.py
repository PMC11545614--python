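"""Steady-state propagation of tracer label through an atom-mapped network.

The simulator tracks, for every metabolite, a probability distribution over
positional labeling patterns of its mapped atoms (all carbons and nitrogens
jointly, encoded as a bitmask; carbons occupy the low bits, nitrogens follow).
Source metabolites are clamped to the tracer pattern (attenuated by enrichment
fraction and per-atom purity), and each non-source metabolite's distribution
is the source-fraction-weighted mixture of the distributions its producing
reactions emit. Condensations combine substrate patterns assuming pool
independence (the standard isotopomer-balance assumption); cleavages
marginalize over the atoms leaving in other products. The fixed point of this
map is the steady-state positional isotopomer state; mass-isotopologue
distributions (MIDs) and joint C×N grids are marginals of it.

``brute_force_isotopomers`` is an independently coded reference: pure-Python
dictionaries over explicit pattern tuples, solved exactly in topological order
for acyclic route configurations and by long Jacobi iteration otherwise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from graphlib import CycleError, TopologicalSorter
from typing import Mapping

import numpy as np
import pandas as pd

from .atom_network import (
    NetworkConfigError,
    Reaction,
    ReactionNetwork,
    TracerSpec,
    build_canonical_network,
    glucose_12_13c,
    glutamine_13c5_15n2,
)

__all__ = [
    "SourceFractionConfig",
    "LabelingState",
    "simulate_labeling",
    "brute_force_isotopomers",
    "predict_isotopomer_table",
    "expected_patterns",
]

# Per-metabolite map of producing-reaction id -> fractional contribution.
SourceFractionConfig = Mapping[str, Mapping[str, float]]

_FRACTION_TOL = 1e-9


class SizeError(ValueError):
    """Network too large for exhaustive positional enumeration."""


def _popcounts(n_bits: int, mask: int) -> np.ndarray:
    """Number of set bits within ``mask`` for every pattern 0..2^n_bits-1."""
    idx = np.arange(1 << n_bits)
    out = np.zeros(idx.size, dtype=np.int64)
    for b in range(n_bits):
        if mask >> b & 1:
            out += (idx >> b) & 1
    return out


@dataclass
class LabelingState:
    """Positional isotopomer distributions plus convergence diagnostics."""

    network: ReactionNetwork
    distributions: dict[str, np.ndarray]
    converged: bool
    iterations: int
    unreachable: tuple[str, ...] = ()
    residual: float = float("nan")

    def _met_bits(self, met_id: str) -> tuple[int, int]:
        met = self.network.metabolites[met_id]
        return met.n_carbon, met.n_nitrogen

    def mid(self, met_id: str, element: str = "C") -> np.ndarray:
        """Mass-isotopologue distribution M+0..M+n for one element."""
        n_c, n_n = self._met_bits(met_id)
        n_bits = n_c + n_n
        if element == "C":
            mask, n = (1 << n_c) - 1, n_c
        elif element == "N":
            mask, n = ((1 << n_n) - 1) << n_c, n_n
        else:
            raise ValueError(f"element must be C or N, got {element!r}")
        shifts = _popcounts(n_bits, mask)
        dist = self.distributions[met_id]
        return np.bincount(shifts, weights=dist, minlength=n + 1)

    def joint_mid(self, met_id: str) -> np.ndarray:
        """Joint C×N mass-shift grid, shape (n_carbon+1, n_nitrogen+1)."""
        n_c, n_n = self._met_bits(met_id)
        n_bits = n_c + n_n
        c_shift = _popcounts(n_bits, (1 << n_c) - 1)
        n_shift = _popcounts(n_bits, ((1 << n_n) - 1) << n_c)
        grid = np.zeros((n_c + 1, n_n + 1))
        np.add.at(grid, (c_shift, n_shift), self.distributions[met_id])
        return grid

    def labeled_fraction(self, met_id: str, element: str = "C") -> float:
        return float(1.0 - self.mid(met_id, element)[0])

    def to_frame(self) -> pd.DataFrame:
        """Tidy long table: metabolite, element, mass_shift, fraction."""
        rows = []
        for met_id in sorted(self.distributions):
            met = self.network.metabolites[met_id]
            for el in ("C", "N"):
                n = met.n_atoms(el)
                if n == 0:
                    continue
                for shift, frac in enumerate(self.mid(met_id, el)):
                    rows.append((met_id, el, shift, float(frac)))
        return pd.DataFrame(rows, columns=["metabolite", "element", "mass_shift", "fraction"])


def _clamp_distribution(net: ReactionNetwork, tracer: TracerSpec) -> np.ndarray:
    """Pattern distribution of a clamped source pool."""
    met = net.metabolites[tracer.metabolite]
    atoms = met.tracer_atoms()
    n_bits = len(atoms)
    labeled_bits = [
        atoms.index((el, p)) for el, ps in tracer.element_labels.items() for p in ps
    ]
    dist = np.zeros(1 << n_bits)
    # labeled molecules: each nominally labeled atom is heavy w.p. purity
    lab = np.array([1.0])
    lab_patterns = np.array([0], dtype=np.int64)
    for b in labeled_bits:
        lab = np.concatenate([lab * (1 - tracer.purity), lab * tracer.purity])
        lab_patterns = np.concatenate([lab_patterns, lab_patterns | (1 << b)])
    np.add.at(dist, lab_patterns, tracer.enrichment_fraction * lab)
    dist[0] += 1.0 - tracer.enrichment_fraction
    return dist


def _resolve_fractions(
    net: ReactionNetwork,
    fractions: SourceFractionConfig | None,
    clamped: set[str],
) -> dict[str, list[tuple[Reaction, float]]]:
    """Producing routes and weights per free metabolite.

    Metabolites absent from the config default to an equal split over their
    producing reactions; configured metabolites must name actual producers and
    sum to 1.
    """
    fractions = dict(fractions or {})
    routes: dict[str, list[tuple[Reaction, float]]] = {}
    for met_id in net.metabolites:
        if met_id in clamped:
            continue
        producers = net.producers_of(met_id)
        if met_id in fractions:
            conf = dict(fractions[met_id])
            ids = {r.id: r for r in producers}
            unknown = set(conf) - set(ids)
            if unknown:
                raise NetworkConfigError(
                    f"{met_id}: configured reactions {sorted(unknown)} do not produce it"
                )
            total = sum(conf.values())
            if abs(total - 1.0) > _FRACTION_TOL:
                raise NetworkConfigError(
                    f"{met_id}: source fractions sum to {total}, expected 1"
                )
            if any(v < 0 for v in conf.values()):
                raise NetworkConfigError(f"{met_id}: negative source fraction")
            routes[met_id] = [(ids[rid], v) for rid, v in sorted(conf.items()) if v > 0]
        elif producers:
            w = 1.0 / len(producers)
            routes[met_id] = [(r, w) for r in sorted(producers, key=lambda r: r.id)]
        else:
            routes[met_id] = []
    return routes


def _transfer_index(net: ReactionNetwork, rxn: Reaction, product: str) -> tuple[list[str], np.ndarray]:
    """Joint substrate-pattern -> product-pattern index array for one product.

    Returns the substrate ids (axis order) and an integer array of shape
    (2^a1, ..., 2^ak) giving the product pattern for every combination of
    substrate patterns.
    """
    subs = list(rxn.substrates)
    sub_atoms = {s: net.metabolites[s].tracer_atoms() for s in subs}
    prod_atoms = net.metabolites[product].tracer_atoms()
    dims = [1 << len(sub_atoms[s]) for s in subs]
    idx = np.zeros(dims, dtype=np.int64)
    for am in rxn.atom_maps:
        for (s, i, p, j) in am.pairs:
            if p != product:
                continue
            si = subs.index(s)
            src_bit = sub_atoms[s].index((am.element, i))
            dst_bit = prod_atoms.index((am.element, j))
            bit = (np.arange(dims[si], dtype=np.int64) >> src_bit) & 1
            shape = [1] * len(dims)
            shape[si] = dims[si]
            idx |= (bit << dst_bit).reshape(shape)
    return subs, idx


def simulate_labeling(
    net: ReactionNetwork,
    tracer: TracerSpec | list[TracerSpec],
    fractions: SourceFractionConfig | None = None,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> LabelingState:
    """Fixed-point solve of the positional isotopomer balance.

    Source metabolites named by tracers are clamped to the tracer pattern;
    declared sources without a tracer, and sink metabolites appearing as
    substrates, are clamped unlabeled. Iteration order is sorted metabolite
    ids (deterministic); convergence is the max absolute change of any pattern
    probability between sweeps.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    tracers = [tracer] if isinstance(tracer, TracerSpec) else list(tracer)
    for t in tracers:
        t.validate_against(net)
    clamped: dict[str, np.ndarray] = {}
    for t in tracers:
        clamp = _clamp_distribution(net, t)
        if t.metabolite in clamped:  # two tracers on one pool: mix is undefined
            raise NetworkConfigError(f"duplicate tracer for {t.metabolite}")
        clamped[t.metabolite] = clamp
    for src in net.sources:
        if src not in clamped:
            n_bits = len(net.metabolites[src].tracer_atoms())
            d = np.zeros(1 << n_bits)
            d[0] = 1.0
            clamped[src] = d

    routes = _resolve_fractions(net, fractions, set(clamped))
    sink_set = set(net.sinks)

    dists: dict[str, np.ndarray] = {}
    for met_id, met in net.metabolites.items():
        n_bits = len(met.tracer_atoms())
        d = np.zeros(1 << n_bits)
        d[0] = 1.0
        dists[met_id] = clamped[met_id] if met_id in clamped else d

    unreachable = tuple(
        m for m in sorted(routes) if not routes[m] and m not in clamped
    )

    transfers: dict[tuple[str, str], tuple[list[str], np.ndarray]] = {}
    for met_id, rts in routes.items():
        for rxn, _ in rts:
            transfers[(rxn.id, met_id)] = _transfer_index(net, rxn, met_id)

    def substrate_dist(s: str) -> np.ndarray:
        if s in sink_set and s not in clamped:
            d = np.zeros(dists[s].size)
            d[0] = 1.0
            return d
        return dists[s]

    order = sorted(routes)
    converged = False
    delta = float("nan")
    it = 0
    for it in range(1, max_iter + 1):
        delta = 0.0
        for met_id in order:
            rts = routes[met_id]
            if not rts:
                continue
            new = np.zeros(dists[met_id].size)
            for rxn, w in rts:
                subs, idx = transfers[(rxn.id, met_id)]
                joint = substrate_dist(subs[0])
                for s in subs[1:]:
                    joint = np.multiply.outer(joint, substrate_dist(s))
                new += w * np.bincount(
                    idx.ravel(), weights=joint.ravel(), minlength=new.size
                )
            # project back onto the simplex: the exact balance preserves total
            # probability, but through condensation cycles the sum direction
            # is neutrally/unstably coupled, so rounding drift must not grow
            new /= new.sum()
            delta = max(delta, float(np.max(np.abs(new - dists[met_id]))))
            dists[met_id] = new
        if delta < tol:
            converged = True
            break
    return LabelingState(net, dists, converged, it, unreachable, delta)


# ---------------------------------------------------------------------------
# brute-force oracle

def brute_force_isotopomers(
    net: ReactionNetwork,
    tracer: TracerSpec | list[TracerSpec],
    fractions: SourceFractionConfig | None = None,
    max_atoms: int = 8,
) -> LabelingState:
    """Reference solver over explicit positional patterns (dict arithmetic).

    Exact single-pass solve in topological order when the selected routes form
    a DAG; otherwise Jacobi iteration to 1e-13. Independent of the vectorized
    fixed-point path; intended for verification on small networks.
    """
    for met in net.metabolites.values():
        if len(met.tracer_atoms()) > max_atoms:
            raise SizeError(
                f"{met.id} has {len(met.tracer_atoms())} mapped atoms (> {max_atoms})"
            )
    tracers = [tracer] if isinstance(tracer, TracerSpec) else list(tracer)
    for t in tracers:
        t.validate_against(net)

    def atoms_of(m: str):
        return net.metabolites[m].tracer_atoms()

    clamped: dict[str, dict] = {}
    for t in tracers:
        met = net.metabolites[t.metabolite]
        labeled = {(el, p) for el, ps in t.element_labels.items() for p in ps}
        dist: dict[tuple, float] = {}
        # enumerate heavy/light outcomes of every nominally labeled atom
        for combo in itertools.product([0, 1], repeat=len(labeled)):
            prob = t.enrichment_fraction
            pat = set()
            for atom, on in zip(sorted(labeled), combo):
                prob *= t.purity if on else (1 - t.purity)
                if on:
                    pat.add(atom)
            key = tuple(1 if a in pat else 0 for a in atoms_of(t.metabolite))
            dist[key] = dist.get(key, 0.0) + prob
        zero = tuple(0 for _ in atoms_of(t.metabolite))
        dist[zero] = dist.get(zero, 0.0) + (1 - t.enrichment_fraction)
        clamped[t.metabolite] = dist
    for src in net.sources:
        if src not in clamped:
            clamped[src] = {tuple(0 for _ in atoms_of(src)): 1.0}

    routes = _resolve_fractions(net, fractions, set(clamped))
    sink_set = set(net.sinks)

    def unlabeled(m: str) -> dict:
        return {tuple(0 for _ in atoms_of(m)): 1.0}

    state: dict[str, dict] = {}
    for m in net.metabolites:
        state[m] = dict(clamped[m]) if m in clamped else unlabeled(m)

    def produce(m: str, current: dict[str, dict]) -> dict:
        out: dict[tuple, float] = {}
        for rxn, w in routes[m]:
            subs = list(rxn.substrates)
            sub_dists = []
            for s in subs:
                if s in sink_set and s not in clamped:
                    sub_dists.append(unlabeled(s))
                else:
                    sub_dists.append(current[s])
            # mapping: product atom index -> (substrate index, substrate atom index)
            pmap: dict[int, tuple[int, int]] = {}
            p_atoms = atoms_of(m)
            for am in rxn.atom_maps:
                for (s, i, p, j) in am.pairs:
                    if p != m:
                        continue
                    pmap[p_atoms.index((am.element, j))] = (
                        subs.index(s),
                        atoms_of(s).index((am.element, i)),
                    )
            for combo in itertools.product(*[d.items() for d in sub_dists]):
                prob = w
                pats = []
                for pat, pr in combo:
                    prob *= pr
                    pats.append(pat)
                if prob == 0.0:
                    continue
                key = tuple(
                    pats[pmap[k][0]][pmap[k][1]] if k in pmap else 0
                    for k in range(len(p_atoms))
                )
                out[key] = out.get(key, 0.0) + prob
        total = sum(out.values())
        if total > 0:  # renormalize: keep the distribution on the simplex
            out = {k: v / total for k, v in out.items()}
        return out

    # dependency graph over free metabolites through their selected routes
    deps = {
        m: {
            s
            for rxn, _ in routes[m]
            for s in rxn.substrates
            if s not in clamped and not (s in sink_set)
        }
        for m in routes
    }
    try:
        order = list(TopologicalSorter(deps).static_order())
        for m in order:
            if m in routes and routes[m]:
                state[m] = produce(m, state)
        converged, iterations = True, 1
    except CycleError:
        converged, iterations = False, 0
        for iterations in range(1, 100_001):
            new_state = dict(state)
            delta = 0.0
            for m in sorted(routes):
                if not routes[m]:
                    continue
                new = produce(m, state)
                keys = set(new) | set(state[m])
                delta = max(
                    delta,
                    max(abs(new.get(k, 0.0) - state[m].get(k, 0.0)) for k in keys),
                )
                new_state[m] = new
            state = new_state
            if delta < 1e-13:
                converged = True
                break

    dists = {}
    for m in net.metabolites:
        n_bits = len(atoms_of(m))
        vec = np.zeros(1 << n_bits)
        for pat, pr in state[m].items():
            idx = sum(b << k for k, b in enumerate(pat))
            vec[idx] += pr
        dists[m] = vec
    unreachable = tuple(m for m in sorted(routes) if not routes[m] and m not in clamped)
    return LabelingState(net, dists, converged, iterations, unreachable, 0.0)


# ---------------------------------------------------------------------------
# qualitative expectation table

def expected_patterns() -> list[dict]:
    """Mass shifts that must be reachable per (tracer, route, metabolite)
    under pure single-route configurations.

    Semantics are subset-style: each listed shift must carry probability in
    the simulated route (recursive routes such as repeated TCA turns can make
    additional shifts reachable beyond the first-turn ones listed here).

    These are the analytically forced outcomes of the tracing design:
    [1,2-13C]glucose gives 50% M+2 pyruvate (one labeled triose per glucose)
    mirrored exactly in lactate and alanine, M+1 ribose via the oxidative PPP
    (glucose C1 lost as CO2) versus M+2 via the non-oxidative branch;
    [13C5,15N2]glutamine gives 13C5,15N1 glutamate via glutaminase, M+4
    succinate/oxaloacetate after one oxidative turn, M+4 citrate via the
    oxidative route versus M+5 via reductive carboxylation, and M+3
    lactate/alanine via malic-enzyme return.
    """
    return [
        {"tracer": "glucose", "route": "glycolysis", "metabolite": "pyruvate", "element": "C", "shifts": (0, 2)},
        {"tracer": "glucose", "route": "glycolysis", "metabolite": "lactate", "element": "C", "shifts": (0, 2)},
        {"tracer": "glucose", "route": "glycolysis", "metabolite": "alanine", "element": "C", "shifts": (0, 2)},
        {"tracer": "glucose", "route": "oxidative_ppp", "metabolite": "r5p", "element": "C", "shifts": (1,)},
        {"tracer": "glucose", "route": "oxidative_ppp", "metabolite": "nucleotide", "element": "C", "shifts": (1,)},
        {"tracer": "glucose", "route": "nonoxidative_ppp", "metabolite": "r5p", "element": "C", "shifts": (2,)},
        {"tracer": "glucose", "route": "tca_oxidative", "metabolite": "citrate", "element": "C", "shifts": (0, 2)},
        {"tracer": "glucose", "route": "tca_oxidative", "metabolite": "akg", "element": "C", "shifts": (0, 2)},
        {"tracer": "glutamine", "route": "glutaminase", "metabolite": "glutamate", "element": "C", "shifts": (5,)},
        {"tracer": "glutamine", "route": "glutaminase", "metabolite": "glutamate", "element": "N", "shifts": (1,)},
        {"tracer": "glutamine", "route": "tca_oxidative", "metabolite": "succinate", "element": "C", "shifts": (4,)},
        {"tracer": "glutamine", "route": "tca_oxidative", "metabolite": "oaa", "element": "C", "shifts": (4,)},
        {"tracer": "glutamine", "route": "tca_oxidative", "metabolite": "citrate", "element": "C", "shifts": (4,)},
        {"tracer": "glutamine", "route": "reductive_carboxylation", "metabolite": "citrate", "element": "C", "shifts": (5,)},
        {"tracer": "glutamine", "route": "malic_enzyme", "metabolite": "lactate", "element": "C", "shifts": (3,)},
        {"tracer": "glutamine", "route": "malic_enzyme", "metabolite": "alanine", "element": "C", "shifts": (3,)},
    ]


# pure single-route source-fraction configurations used to evaluate the table
_ROUTE_FRACTIONS: dict[tuple[str, str], SourceFractionConfig] = {
    ("glucose", "glycolysis"): {
        "pyruvate": {"pk": 1.0},
        "lactate": {"ldh_f": 1.0},
        "alanine": {"alt_f": 1.0},
    },
    ("glucose", "oxidative_ppp"): {"r5p": {"oxppp": 1.0}},
    ("glucose", "nonoxidative_ppp"): {"r5p": {"tkt": 1.0}},
    ("glucose", "tca_oxidative"): {
        "pyruvate": {"pk": 1.0},
        "citrate": {"cs": 1.0},
        "akg": {"idh": 1.0},
        "glutamate": {"gls": 1.0},
    },
    ("glutamine", "glutaminase"): {"glutamate": {"gls": 1.0}},
    ("glutamine", "tca_oxidative"): {
        "glutamate": {"gls": 1.0},
        "akg": {"alt_f": 1.0},
        "citrate": {"cs": 1.0},
        "pyruvate": {"pk": 1.0},
    },
    ("glutamine", "reductive_carboxylation"): {
        "glutamate": {"gls": 1.0},
        "akg": {"alt_f": 1.0},
        "citrate": {"rc": 1.0},
    },
    ("glutamine", "malic_enzyme"): {
        "glutamate": {"gls": 1.0},
        "akg": {"alt_f": 1.0},
        "pyruvate": {"me": 1.0},
        "lactate": {"ldh_f": 1.0},
        "alanine": {"alt_f": 1.0},
    },
}

_TRACERS = {"glucose": glucose_12_13c, "glutamine": glutamine_13c5_15n2}


def predict_isotopomer_table(
    net: ReactionNetwork | None = None,
    tracer_name: str | None = None,
    threshold: float = 1e-9,
) -> pd.DataFrame:
    """Simulated reachable mass shifts per route, as a machine-readable table.

    For every pure single-route source configuration, runs the simulator and
    reports the mass shifts carrying more than ``threshold`` of the pool.
    Columns: tracer, route, metabolite, element, mass_shift, fraction.
    """
    net = net or build_canonical_network()
    rows = []
    for (trc, route), fracs in _ROUTE_FRACTIONS.items():
        if tracer_name is not None and trc != tracer_name:
            continue
        state = simulate_labeling(net, _TRACERS[trc](), fracs)
        mets = {e["metabolite"] for e in expected_patterns() if e["tracer"] == trc and e["route"] == route}
        for met in sorted(mets):
            for el in ("C", "N"):
                if net.metabolites[met].n_atoms(el) == 0:
                    continue
                for shift, frac in enumerate(state.mid(met, el)):
                    if frac > threshold:
                        rows.append((trc, route, met, el, shift, float(frac)))
    return pd.DataFrame(
        rows, columns=["tracer", "route", "metabolite", "element", "mass_shift", "fraction"]
    )
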