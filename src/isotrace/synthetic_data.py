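"""Synthetic isotopologue ion-count datasets with known ground truth.

The generator runs the forward model the analysis inverts: per group, true
MIDs come from the label simulator under a group-specific source-fraction
configuration, are mixed with a pre-existing unlabeled pool by a turnover
fraction (emulating finite labeling time), convolved with natural abundance
and tracer impurity, scaled by true pool sizes and cell counts, and observed
as Poisson ion counts under a multiplicative lognormal per-sample effect.
Three presets emulate the study designs: cell-cycle phases (G1/S/G2 with an
S-phase surge of lactate, nucleotides, alanine and α-ketoglutarate), a
non-malignant lymphoblastoid line versus two lymphoma lines (alanine 4-fold
and lactate 2–4-fold higher in lymphoma), and ± fludarabine (lymphoma-only
collapse of TCA and nucleotide pools with upstream glycolytic accumulation).

All randomness flows through one numpy Generator seeded from the scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .atom_network import (
    ReactionNetwork,
    TracerSpec,
    build_canonical_network,
    glucose_12_13c,
)
from .enrichment_metrics import SampleTable
from .isotope_correction import CorrectionMatrix, build_correction_matrix, forward_convolve
from .label_sim import LabelingState, SourceFractionConfig, simulate_labeling

__all__ = [
    "GroupSpec",
    "Scenario",
    "GeneratedDataset",
    "generate_dataset",
    "preset_scenarios",
    "DEFAULT_PANEL",
    "CELLS_PER_SAMPLE",
]

CELLS_PER_SAMPLE = 5.0e5  # cells plated per replicate well

# Measured metabolite panel (central carbon + products); base per-cell pool
# sizes in arbitrary units, ordered roughly by typical LC-MS pool abundance.
DEFAULT_PANEL: dict[str, float] = {
    "g6p": 1.0,
    "f6p": 0.6,
    "dhap": 0.8,
    "pyruvate": 1.5,
    "lactate": 6.0,
    "alanine": 2.0,
    "glutamine": 4.0,
    "glutamate": 8.0,
    "aspartate": 1.5,
    "akg": 0.5,
    "citrate": 1.2,
    "succinate": 0.8,
    "fumarate": 0.6,
    "malate": 1.0,
    "r5p": 0.4,
    "nucleotide": 1.0,
}

# Physiological source-fraction configuration used by the presets: pyruvate is
# glycolytic, alpha-KG is mostly transaminase-fed from glutamine-derived
# glutamate, citrate splits between oxidative synthesis and reductive
# carboxylation, and ribose splits between oxidative and non-oxidative PPP.
DEFAULT_FRACTIONS: dict[str, dict[str, float]] = {
    "pyruvate": {"pk": 1.0},
    "lactate": {"ldh_f": 1.0},
    "alanine": {"alt_f": 1.0},
    "glutamate": {"gls": 0.8, "alt_r": 0.1, "ast_r": 0.1},
    "akg": {"alt_f": 0.6, "ast_f": 0.2, "idh": 0.2},
    "citrate": {"cs": 0.7, "rc": 0.3},
    "oaa": {"mdh": 0.9, "ast_r": 0.1},
    "r5p": {"oxppp": 0.7, "tkt": 0.3},
    "aspartate": {"ast_f": 1.0},
    "nucleotide": {"prpp": 1.0},
}


@dataclass(frozen=True)
class GroupSpec:
    """One experimental group: replicate count, true pools, labeling regime."""

    name: str
    pool_means: Mapping[str, float]
    n_reps: int = 3
    fractions: SourceFractionConfig | None = None
    turnover: float = 0.8  # fraction of each pool at steady-state label

    def __post_init__(self) -> None:
        if self.n_reps < 3:
            raise ValueError("replicate counts below 3 are not supported (triplicate design)")
        if not 0.0 <= self.turnover <= 1.0:
            raise ValueError("turnover must be in [0, 1]")
        object.__setattr__(self, "pool_means", dict(self.pool_means))


@dataclass(frozen=True)
class Scenario:
    """Full description of a synthetic experiment."""

    name: str
    groups: tuple[GroupSpec, ...]
    tracer: TracerSpec
    pool_cv: float = 0.10  # biological lognormal CV of replicate pools
    sample_cv: float = 0.10  # technical lognormal per-sample scale effect
    depth: float = 1.0e6  # mean total ion count at pool size 1.0
    poisson: bool = True  # False: emit expected counts (noise-free)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pool_cv < 0 or self.sample_cv < 0:
            raise ValueError("CVs must be non-negative")
        object.__setattr__(self, "groups", tuple(self.groups))

    @property
    def metabolites(self) -> tuple[str, ...]:
        mets: list[str] = []
        for g in self.groups:
            for m in g.pool_means:
                if m not in mets:
                    mets.append(m)
        return tuple(mets)


@dataclass
class GeneratedDataset:
    """Raw counts plus the retained ground truth they were generated from."""

    scenario: Scenario
    raw: pd.DataFrame  # sample, metabolite, element, mass_shift, ion_count
    normalizers: pd.Series  # cells per sample
    truth: SampleTable  # true per-sample pools (per cell) + true MIDs
    true_states: dict[str, LabelingState]  # per group

    def raw_totals(self, element: str = "C") -> pd.DataFrame:
        sub = self.raw[self.raw["element"] == element]
        return (
            sub.pivot_table(
                index="sample", columns="metabolite", values="ion_count", aggfunc="sum"
            )
            .loc[sorted(sub["sample"].unique())]
        )


_canonical_cache: ReactionNetwork | None = None
_labeling_cache: dict[tuple, LabelingState] = {}
_matrix_cache: dict[tuple, CorrectionMatrix] = {}


def _canonical() -> ReactionNetwork:
    global _canonical_cache
    if _canonical_cache is None:
        _canonical_cache = build_canonical_network()
    return _canonical_cache


def _labeling_key(tracer: TracerSpec, fractions: SourceFractionConfig | None) -> tuple:
    frac_key = tuple(
        (m, tuple(sorted(conf.items()))) for m, conf in sorted((fractions or {}).items())
    )
    lab_key = tuple(sorted((el, ps) for el, ps in tracer.element_labels.items()))
    return (tracer.metabolite, lab_key, tracer.enrichment_fraction, tracer.purity, frac_key)


def _simulate_cached(
    net: ReactionNetwork | None,
    tracer: TracerSpec,
    fractions: SourceFractionConfig | None,
) -> LabelingState:
    if net is not None:
        return simulate_labeling(net, tracer, fractions)
    key = _labeling_key(tracer, fractions)
    if key not in _labeling_cache:
        _labeling_cache[key] = simulate_labeling(_canonical(), tracer, fractions)
    return _labeling_cache[key]


def _matrix_for(met_id: str, element: str, purity: float) -> CorrectionMatrix:
    key = (met_id, element, purity)
    if key not in _matrix_cache:
        formula = _canonical().metabolites[met_id].formula
        _matrix_cache[key] = build_correction_matrix(
            formula, element, purity=purity, metabolite=met_id
        )
    return _matrix_cache[key]


def true_mid(state: LabelingState, met_id: str, element: str, turnover: float) -> np.ndarray:
    """Steady-state MID mixed with the pre-existing unlabeled pool."""
    mid = turnover * state.mid(met_id, element)
    mid[0] += 1.0 - turnover
    return mid


def generate_dataset(
    scenario: Scenario,
    seed: int | None = None,
    net: ReactionNetwork | None = None,
) -> GeneratedDataset:
    """Draw one dataset from a scenario (reproducible from the seed)."""
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    panel = scenario.metabolites
    network = net or _canonical()
    unknown = [m for m in panel if m not in network.metabolites]
    if unknown:
        raise KeyError(f"scenario references unknown metabolites: {unknown}")

    elements = ["C"]
    if "N" in scenario.tracer.element_labels:
        elements.append("N")

    states: dict[str, LabelingState] = {}
    rows = []
    truth_pools: dict[str, dict[str, float]] = {}
    truth_mids = []
    groups_map: dict[str, str] = {}
    # lognormal with mean 1 and the requested CV
    def lognorm(cv: float, size=None):
        if cv == 0:
            return np.ones(size) if size is not None else 1.0
        sigma = np.sqrt(np.log(1 + cv**2))
        return rng.lognormal(-(sigma**2) / 2, sigma, size)

    # The labeling truth is simulated with an ideal (pure) tracer; tracer
    # impurity enters through the forward correction matrix instead, matching
    # the convention that corrected MIDs are impurity-corrected and therefore
    # comparable to pure-tracer simulations.
    sim_tracer = replace(scenario.tracer, purity=1.0)
    for grp in scenario.groups:
        states[grp.name] = _simulate_cached(net, sim_tracer, grp.fractions)
        for rep in range(1, grp.n_reps + 1):
            sample = f"{grp.name}_{rep}"
            groups_map[sample] = grp.name
            sample_factor = float(lognorm(scenario.sample_cv))
            truth_pools[sample] = {}
            for met in panel:
                mean = grp.pool_means.get(met, 0.0)
                if mean <= 0:
                    raise ValueError(f"{grp.name}/{met}: pool mean must be positive")
                pool = mean * float(lognorm(scenario.pool_cv))
                truth_pools[sample][met] = pool
                for el in elements:
                    if network.metabolites[met].n_atoms(el) == 0:
                        continue
                    t_mid = true_mid(states[grp.name], met, el, grp.turnover)
                    matrix = _matrix_for(met, el, scenario.tracer.purity)
                    observed = forward_convolve(t_mid, matrix)
                    lam = scenario.depth * pool * sample_factor * observed
                    counts = rng.poisson(lam) if scenario.poisson else lam
                    for shift, c in enumerate(counts):
                        rows.append((sample, met, el, shift, float(c)))
                    if rep == 1:
                        for shift, f in enumerate(t_mid):
                            truth_mids.append((grp.name, met, el, shift, float(f)))

    raw = pd.DataFrame(rows, columns=["sample", "metabolite", "element", "mass_shift", "ion_count"])
    samples = list(truth_pools)
    normalizers = pd.Series(CELLS_PER_SAMPLE, index=samples, name="cells")
    pools = pd.DataFrame(truth_pools).T.loc[samples, list(panel)]
    truth = SampleTable(
        pools=pools,
        groups=pd.Series(groups_map, name="group"),
        mids=pd.DataFrame(
            truth_mids, columns=["group", "metabolite", "element", "mass_shift", "fraction"]
        ),
    )
    return GeneratedDataset(scenario, raw, normalizers, truth, states)


# ---------------------------------------------------------------------------
# presets emulating the study's three designs

def _scaled(base: Mapping[str, float], factors: Mapping[str, float]) -> dict[str, float]:
    return {m: v * factors.get(m, 1.0) for m, v in base.items()}


def preset_scenarios(seed: int = 0) -> dict[str, Scenario]:
    """The three packaged experimental designs.

    Effect sizes follow the stated fold differences where printed (alanine
    4-fold and lactate 2–4-fold above the non-malignant line; roughly 2-fold
    and 4-fold pool drops under fludarabine split between glycolytic end
    products and TCA/nucleotide pools); remaining contrasts default to 2-fold.
    """
    base = dict(DEFAULT_PANEL)
    fr = DEFAULT_FRACTIONS
    glc = glucose_12_13c(enrichment=1.0, purity=0.99)

    cell_cycle = Scenario(
        "cell_cycle",
        groups=(
            GroupSpec("G1", base, fractions=fr),
            GroupSpec(
                "S",
                _scaled(base, {"lactate": 2.0, "nucleotide": 2.0, "r5p": 2.0, "alanine": 2.0, "akg": 2.0, "pyruvate": 2.0}),
                fractions=fr,
            ),
            GroupSpec("G2", _scaled(base, {"nucleotide": 2.0, "lactate": 1.5}), fractions=fr),
        ),
        tracer=glc,
        seed=seed,
    )

    lymphoma_factors_ca46 = {
        "alanine": 4.0, "lactate": 2.0, "pyruvate": 2.0, "g6p": 2.0,
        "glutamate": 2.0, "nucleotide": 2.0, "r5p": 2.0, "citrate": 2.0, "akg": 2.0,
    }
    lymphoma_factors_sudhl4 = dict(lymphoma_factors_ca46, lactate=4.0)
    # lymphoma uses the oxidative PPP and transaminase routes more heavily
    fr_lym = dict(fr, r5p={"oxppp": 0.8, "tkt": 0.2})
    lcl_vs_lymphoma = Scenario(
        "lcl_vs_lymphoma",
        groups=(
            GroupSpec("LCL", base, fractions=fr),
            GroupSpec("CA46", _scaled(base, lymphoma_factors_ca46), fractions=fr_lym),
            GroupSpec("SUDHL4", _scaled(base, lymphoma_factors_sudhl4), fractions=fr_lym),
        ),
        tracer=glc,
        seed=seed,
    )

    # Untreated lymphoma here mirrors the +/- drug design: glycolytic
    # intermediates and glutamate pools are LOWER than in the non-malignant
    # line while TCA intermediates, nucleotides, lactate and alanine run
    # higher; the drug reverses both features (glycolytic accumulation, TCA
    # and nucleotide collapse), moving treated lymphoma toward the LCL state.
    lym_base = _scaled(
        base,
        {
            "g6p": 0.5, "f6p": 0.5, "dhap": 0.5, "glutamate": 0.5,
            "alanine": 4.0, "lactate": 2.0, "pyruvate": 2.0,
            "citrate": 2.0, "akg": 2.0, "succinate": 2.0, "fumarate": 2.0,
            "malate": 2.0, "r5p": 2.0, "nucleotide": 2.0,
        },
    )
    flu_factors = {
        # glycolytic accumulation; transaminase products and TCA/nucleotides drop
        "g6p": 2.0, "f6p": 2.0, "dhap": 2.0, "glutamine": 2.0,
        "pyruvate": 0.5, "lactate": 0.5, "alanine": 0.5,
        "citrate": 0.25, "akg": 0.25, "succinate": 0.25, "fumarate": 0.25,
        "malate": 0.25, "r5p": 0.25, "nucleotide": 0.25,
    }
    fludarabine = Scenario(
        "fludarabine",
        groups=(
            GroupSpec("LCL_ctrl", base, fractions=fr),
            GroupSpec("LCL_flu", base, fractions=fr),
            GroupSpec("LYM_ctrl", lym_base, fractions=fr_lym),
            GroupSpec("LYM_flu", _scaled(lym_base, flu_factors), fractions=fr),
        ),
        tracer=glc,
        seed=seed,
    )
    return {s.name: s for s in (cell_cycle, lcl_vs_lymphoma, fludarabine)}
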