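"""Shared fixtures: canonical network, toy networks, random net generator."""

from __future__ import annotations

import numpy as np
import pytest

from isotrace.atom_network import (
    AtomMap,
    Metabolite,
    Reaction,
    ReactionNetwork,
    TracerSpec,
    build_canonical_network,
    validate_network,
)


@pytest.fixture(scope="session")
def canonical():
    return build_canonical_network()


def make_linear_net(n_atoms: int = 3) -> ReactionNetwork:
    """src -> a -> b chain with identity carbon maps."""
    net = ReactionNetwork(sources=("src",))
    for name in ("src", "a", "b"):
        net.add_metabolite(Metabolite(name, f"C{n_atoms}"))
    ident = lambda s, p: AtomMap("C", tuple((s, i, p, i) for i in range(1, n_atoms + 1)))
    net.add_reaction(Reaction("r1", ("src",), ("a",), (ident("src", "a"),)))
    net.add_reaction(Reaction("r2", ("a",), ("b",), (ident("a", "b"),)))
    assert validate_network(net) == []
    return net


@pytest.fixture
def linear_net():
    return make_linear_net()


def random_toy_network(seed: int):
    """Random small network + tracer + fractions for oracle comparisons.

    Topologies cover linear chains with random atom permutations, cleavage,
    condensation (recombination) and optional cycles via a back edge; all
    metabolites have <= 3 carbons so exhaustive enumeration stays tiny.
    """
    rng = np.random.default_rng(seed)
    sizes: dict[str, int] = {"src": int(rng.integers(2, 4))}
    reactions: list[Reaction] = []

    def perm_pairs(sub: str, prod: str) -> AtomMap:
        n = sizes[sub]
        perm = rng.permutation(n) + 1
        return AtomMap("C", tuple((sub, i + 1, prod, int(perm[i])) for i in range(n)))

    prev = "src"
    for i in range(int(rng.integers(1, 4))):
        name = f"chain{i}"
        sizes[name] = sizes[prev]
        reactions.append(Reaction(f"lin{i}", (prev,), (name,), (perm_pairs(prev, name),)))
        prev = name
    terminal = prev

    fractions: dict[str, dict[str, float]] = {}
    if sizes[terminal] >= 2 and rng.random() < 0.7:
        a = int(rng.integers(1, sizes[terminal]))
        b = sizes[terminal] - a
        sizes["cl_a"], sizes["cl_b"] = a, b
        order = rng.permutation(sizes[terminal]) + 1
        pairs = tuple(
            (terminal, int(order[k]), "cl_a", k + 1) if k < a
            else (terminal, int(order[k]), "cl_b", k - a + 1)
            for k in range(sizes[terminal])
        )
        reactions.append(Reaction("cleave0", (terminal,), ("cl_a", "cl_b"), (AtomMap("C", pairs),)))
        if rng.random() < 0.8:
            sizes["cond"] = sizes[terminal]
            order2 = rng.permutation(sizes[terminal]) + 1
            pairs2 = tuple(
                ("cl_a", k + 1, "cond", int(order2[k])) if k < a
                else ("cl_b", k - a + 1, "cond", int(order2[k]))
                for k in range(sizes[terminal])
            )
            reactions.append(Reaction("cond0", ("cl_a", "cl_b"), ("cond",), (AtomMap("C", pairs2),)))
            if rng.random() < 0.5:
                # back edge: cond feeds the terminal again -> cycle
                reactions.append(
                    Reaction("back0", ("cond",), (terminal,), (perm_pairs("cond", terminal),))
                )
                w = float(rng.uniform(0.1, 0.7))
                feeder = f"lin{len([r for r in reactions if r.id.startswith('lin')]) - 1}"
                fractions[terminal] = {feeder: 1.0 - w, "back0": w}

    net = ReactionNetwork(sources=("src",))
    for name, n in sizes.items():
        net.add_metabolite(Metabolite(name, f"C{n}H{n}"))
    for rxn in reactions:
        net.add_reaction(rxn)
    assert validate_network(net) == []

    n_src = sizes["src"]
    k = int(rng.integers(1, n_src + 1))
    positions = tuple(sorted(rng.choice(np.arange(1, n_src + 1), size=k, replace=False).tolist()))
    tracer = TracerSpec(
        "src",
        {"C": positions},
        enrichment_fraction=float(rng.uniform(0.3, 1.0)),
        purity=float(rng.uniform(0.9, 1.0)),
    )
    return net, tracer, fractions
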