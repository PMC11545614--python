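"""Quantitative summaries of corrected tracing data.

Pool sizes are total (isotope-summed) ion counts normalized per cell or per
unit protein. Fractional labeling is summarized two ways: the labeled
fraction 1 - M+0 and the atom-weighted mean enrichment sum(i * M+i) / n_atoms.
Relative source contributions divide each source's mean atom enrichment of a
metabolite by the sum across sources, so a fully labeled 5-carbon isotopomer
counts five times a singly labeled one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SampleTable",
    "EnrichmentRecord",
    "normalize_pools",
    "fractional_enrichment",
    "relative_contribution",
    "log2_fold_change",
]


@dataclass
class SampleTable:
    """Normalized pool sizes and corrected MIDs across grouped samples.

    ``pools``: DataFrame, index = sample id, columns = metabolites, values =
    normalized pool sizes (linear scale). ``groups``: Series mapping sample id
    to group label. ``mids``: optional tidy table with columns sample,
    metabolite, element, mass_shift, fraction.
    """

    pools: pd.DataFrame
    groups: pd.Series
    mids: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = set(self.pools.index) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without a group label: {sorted(missing)}")
        self.groups = self.groups.loc[self.pools.index]

    def log2_pools(self) -> pd.DataFrame:
        if (self.pools <= 0).any().any():
            raise ValueError("pool sizes must be positive for log2 transform")
        return np.log2(self.pools)

    def group_means(self) -> pd.DataFrame:
        return self.pools.groupby(self.groups).mean()


@dataclass(frozen=True)
class EnrichmentRecord:
    metabolite: str
    labeled_fraction: float
    mean_atom_enrichment: float
    fractions: tuple[float, ...] = field(default=(), repr=False)


def normalize_pools(
    raw_totals: pd.DataFrame,
    normalizers: Mapping[str, float] | pd.Series,
    log2: bool = False,
) -> pd.DataFrame:
    """Divide per-sample total ion counts by cell number or protein mass.

    ``raw_totals``: index = sample, columns = metabolite. Raises a KeyError
    naming the sample if its normalizer is missing or non-positive.
    """
    normalizers = pd.Series(dict(normalizers))
    out = {}
    for sample in raw_totals.index:
        if sample not in normalizers.index or pd.isna(normalizers[sample]):
            raise KeyError(f"no normalizer for sample {sample!r}")
        norm = float(normalizers[sample])
        if norm <= 0:
            raise ValueError(f"non-positive normalizer for sample {sample!r}")
        out[sample] = raw_totals.loc[sample] / norm
    pools = pd.DataFrame(out).T.loc[raw_totals.index]
    return np.log2(pools) if log2 else pools


def fractional_enrichment(
    mid: np.ndarray, n_atoms: int | None = None, metabolite: str = ""
) -> EnrichmentRecord:
    """Labeled fraction and mean atom enrichment of a MID.

    Both statistics are invariant under renormalization of the MID; ``n_atoms``
    defaults to len(mid) - 1.
    """
    mid = np.asarray(mid, dtype=float)
    if mid.sum() <= 0:
        raise ValueError("MID sums to zero")
    mid = mid / mid.sum()
    if n_atoms is None:
        n_atoms = mid.size - 1
    if n_atoms < mid.size - 1:
        raise ValueError(f"MID has shifts beyond {n_atoms} atoms")
    labeled = float(1.0 - mid[0])
    mean_atom = float(np.dot(np.arange(mid.size), mid) / n_atoms) if n_atoms else 0.0
    return EnrichmentRecord(metabolite, labeled, mean_atom, tuple(mid))


def relative_contribution(
    enrichments: Mapping[str, float], use_labeled_fraction: bool = False
) -> dict[str, float]:
    """Per-source contribution fractions from per-source enrichments.

    ``enrichments`` maps source name (glucose, glutamine, or a route) to that
    source's mean atom enrichment of the metabolite (or labeled fraction when
    ``use_labeled_fraction`` styled inputs are passed — the formula is the
    same division either way). Contributions sum to 1 and are invariant under
    common scaling of the inputs.
    """
    vals = {k: float(v) for k, v in enrichments.items()}
    if any(v < 0 for v in vals.values()):
        raise ValueError("enrichments must be non-negative")
    total = sum(vals.values())
    if total <= 0:
        raise ValueError("all source enrichments are zero: contribution undefined")
    return {k: v / total for k, v in vals.items()}


def log2_fold_change(
    table: SampleTable, group_a: str, group_b: str, min_reps: int = 2
) -> pd.Series:
    """log2(mean_b / mean_a) of normalized pools, per metabolite.

    Group means are taken on the linear scale before the log transform.
    """
    for g in (group_a, group_b):
        n = int((table.groups == g).sum())
        if n < min_reps:
            raise ValueError(f"group {g!r} has {n} samples (< {min_reps})")
    means = table.group_means()
    a, b = means.loc[group_a], means.loc[group_b]
    if (a <= 0).any() or (b <= 0).any():
        raise ValueError("zero or negative group mean pool size")
    return np.log2(b / a).rename(f"log2fc[{group_b}/{group_a}]")
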