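"""End-to-end orchestration: correct → enrich → contribution → stats.

``analyze_dataset`` inverts the synthetic generator's forward model on raw
ion counts: natural-abundance/impurity correction per sample and metabolite,
pool normalization by cell count, enrichment summaries, and the univariate
screen. ``run_tracer_analysis`` wraps it with file output and a manifest
(inputs, seed, checksums) so a run is reproducible and attributable.
``run_expectation_check`` verifies the packaged expectation table (the
analytically forced labeling outcomes) against fresh simulations.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .atom_network import ReactionNetwork, build_canonical_network
from .enrichment_metrics import (
    SampleTable,
    fractional_enrichment,
    log2_fold_change,
    normalize_pools,
    relative_contribution,
)
from .isotope_correction import build_correction_matrix, correct_mid
from .label_sim import expected_patterns, simulate_labeling, _ROUTE_FRACTIONS, _TRACERS
from .stats_suite import anova_fdr_lsd
from .synthetic_data import GeneratedDataset

__all__ = [
    "AnalysisResult",
    "analyze_dataset",
    "run_tracer_analysis",
    "run_expectation_check",
    "dual_tracer_contributions",
]


@dataclass
class AnalysisResult:
    table: SampleTable  # recovered pools + corrected MIDs
    corrected: pd.DataFrame  # sample, metabolite, element, mass_shift, fraction, residual
    enrichment: pd.DataFrame  # sample, metabolite, element, labeled_fraction, mean_atom_enrichment
    anova: pd.DataFrame  # metabolite, F, p, q, degenerate


def analyze_dataset(
    dataset: GeneratedDataset,
    net: ReactionNetwork | None = None,
    alpha: float = 0.05,
) -> AnalysisResult:
    """Correct raw counts, normalize pools and run the univariate screen."""
    net = net or build_canonical_network()
    purity = dataset.scenario.tracer.purity
    matrices: dict[tuple[str, str], object] = {}
    corrected_rows = []
    enrich_rows = []
    for (sample, met, el), sub in dataset.raw.groupby(
        ["sample", "metabolite", "element"], sort=True
    ):
        counts = (
            sub.sort_values("mass_shift")["ion_count"].to_numpy().astype(float)
        )
        key = (met, el)
        if key not in matrices:
            matrices[key] = build_correction_matrix(
                net.metabolites[met].formula, el, purity=purity, metabolite=met
            )
        mid, residual = correct_mid(counts, matrices[key])
        for shift, f in enumerate(mid):
            corrected_rows.append((sample, met, el, shift, float(f), residual))
        rec = fractional_enrichment(mid, metabolite=met)
        enrich_rows.append(
            (sample, met, el, rec.labeled_fraction, rec.mean_atom_enrichment)
        )
    corrected = pd.DataFrame(
        corrected_rows,
        columns=["sample", "metabolite", "element", "mass_shift", "fraction", "residual"],
    )
    enrichment = pd.DataFrame(
        enrich_rows,
        columns=["sample", "metabolite", "element", "labeled_fraction", "mean_atom_enrichment"],
    )
    pools = normalize_pools(dataset.raw_totals("C"), dataset.normalizers)
    table = SampleTable(
        pools=pools,
        groups=dataset.truth.groups.loc[pools.index],
        mids=corrected.drop(columns=["residual"]),
    )
    anova = pd.DataFrame(
        [
            {
                "metabolite": r.metabolite,
                "F": r.f_statistic,
                "p": r.p_value,
                "q": r.q_value,
                "degenerate": r.degenerate,
            }
            for r in anova_fdr_lsd(table, alpha=alpha)
        ]
    )
    return AnalysisResult(table, corrected, enrichment, anova)


def dual_tracer_contributions(
    glucose_enrichment: pd.DataFrame, glutamine_enrichment: pd.DataFrame
) -> pd.DataFrame:
    """Relative carbon contributions from parallel glucose/glutamine runs.

    Inputs are per-sample enrichment tables from ``analyze_dataset`` (carbon
    rows); contributions divide each source's mean atom enrichment, averaged
    across samples, by the sum over the two sources.
    """
    def mean_enrich(df: pd.DataFrame) -> pd.Series:
        sub = df[df["element"] == "C"]
        return sub.groupby("metabolite")["mean_atom_enrichment"].mean()

    glc, gln = mean_enrich(glucose_enrichment), mean_enrich(glutamine_enrichment)
    rows = []
    for met in sorted(set(glc.index) & set(gln.index)):
        if glc[met] + gln[met] <= 0:
            continue
        contrib = relative_contribution({"glucose": glc[met], "glutamine": gln[met]})
        rows.append((met, contrib["glucose"], contrib["glutamine"]))
    return pd.DataFrame(rows, columns=["metabolite", "glucose", "glutamine"])


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_tracer_analysis(
    dataset: GeneratedDataset,
    out_dir: str | Path,
    net: ReactionNetwork | None = None,
    alpha: float = 0.05,
) -> AnalysisResult:
    """Analyze a dataset and write results plus a checksummed manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = analyze_dataset(dataset, net=net, alpha=alpha)
    files = {
        "corrected_mids.csv": result.corrected,
        "enrichment.csv": result.enrichment,
        "pools.csv": result.table.pools.reset_index(names="sample"),
        "anova.csv": result.anova,
    }
    for name, df in files.items():
        df.to_csv(out / name, index=False)
    manifest = {
        "tool": f"isotrace {__version__}",
        "scenario": dataset.scenario.name,
        "seed": dataset.scenario.seed,
        "tracer": {
            "metabolite": dataset.scenario.tracer.metabolite,
            "labels": {k: list(v) for k, v in dataset.scenario.tracer.element_labels.items()},
            "purity": dataset.scenario.tracer.purity,
        },
        "alpha": alpha,
        "n_samples": int(len(result.table.pools)),
        "outputs": {name: _sha256(out / name) for name in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return result


def run_expectation_check(
    net: ReactionNetwork | None = None, threshold: float = 1e-6
) -> pd.DataFrame:
    """Check every packaged labeling expectation against fresh simulations.

    For each (tracer, route, metabolite) entry, simulates the pure
    single-route configuration and asserts that every expected mass shift is
    reachable (fraction above ``threshold``). Returns a table with a boolean
    ``passed`` column; callers treat any False row as failure.
    """
    net = net or build_canonical_network()
    states = {}
    rows = []
    for entry in expected_patterns():
        key = (entry["tracer"], entry["route"])
        if key not in states:
            states[key] = simulate_labeling(net, _TRACERS[key[0]](), _ROUTE_FRACTIONS[key])
        state = states[key]
        mid = state.mid(entry["metabolite"], entry["element"])
        for shift in entry["shifts"]:
            ok = shift < mid.size and mid[shift] > threshold
            rows.append(
                {
                    "tracer": entry["tracer"],
                    "route": entry["route"],
                    "metabolite": entry["metabolite"],
                    "element": entry["element"],
                    "mass_shift": shift,
                    "fraction": float(mid[shift]) if shift < mid.size else 0.0,
                    "passed": bool(ok),
                }
            )
    return pd.DataFrame(rows)
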