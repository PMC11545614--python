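"""Natural-abundance and tracer-impurity correction of isotopologue data.

Measured mass-isotopologue distributions are inflated by naturally occurring
heavy isotopes (1.07% 13C, 0.364% 15N, ...) in every atom of the molecule and
deflated by imperfect tracer purity in the labeled positions. The correction
matrix maps a true tracer MID to the expected observed MID at unit (nominal)
mass resolution: column j is the observed envelope when exactly j tracer
atoms are truly labeled, combining a binomial purity loss over the j labeled
atoms with natural-abundance mass shifts from all remaining atoms of every
element (18O and 34S contribute +2). Correction solves the resulting linear
system by non-negative least squares, which avoids the negative fractions
plain inversion produces on noisy data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import nnls
from scipy.stats import binom

from .atom_network import parse_formula

__all__ = [
    "DEFAULT_ABUNDANCES",
    "CorrectionMatrix",
    "RawMIDRecord",
    "build_correction_matrix",
    "correct_mid",
    "forward_convolve",
]

# Natural heavy-isotope abundances; per element, a list of (mass shift,
# fraction). Values are the standard terrestrial abundances.
DEFAULT_ABUNDANCES: dict[str, tuple[tuple[int, float], ...]] = {
    "C": ((1, 0.0107),),
    "H": ((1, 0.000115),),
    "N": ((1, 0.00364),),
    "O": ((1, 0.00038), (2, 0.00205)),
    "S": ((1, 0.0075), (2, 0.0425)),
    "P": (),  # monoisotopic
}


class UndefinedMIDError(ValueError):
    """Raised when a MID cannot be computed (e.g. all-zero ion counts)."""


@dataclass(frozen=True)
class RawMIDRecord:
    """Raw ion counts per mass shift for one metabolite in one sample."""

    sample: str
    metabolite: str
    counts: tuple[float, ...]

    def __post_init__(self) -> None:
        counts = tuple(float(c) for c in self.counts)
        if any(c < 0 for c in counts):
            raise ValueError(f"{self.sample}/{self.metabolite}: negative ion count")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> float:
        return float(sum(self.counts))


@dataclass(frozen=True)
class CorrectionMatrix:
    """Linear map from true tracer MID to expected observed MID.

    Square of dimension n_tracer_atoms + 1; columns sum to at most 1 (mass can
    shift beyond the observed window) and are non-negative.
    """

    metabolite: str
    tracer_element: str
    matrix: np.ndarray = field(repr=False)

    @property
    def n(self) -> int:
        return self.matrix.shape[0] - 1


def _atom_pmf(shifts: tuple[tuple[int, float], ...]) -> np.ndarray:
    """Mass-shift pmf of a single atom of one element."""
    if not shifts:
        return np.array([1.0])
    max_shift = max(s for s, _ in shifts)
    pmf = np.zeros(max_shift + 1)
    pmf[0] = 1.0 - sum(p for _, p in shifts)
    for s, p in shifts:
        pmf[s] += p
    return pmf


def _natural_pmf(
    composition: Mapping[str, int],
    abundances: Mapping[str, tuple[tuple[int, float], ...]],
) -> np.ndarray:
    """Mass-shift pmf from natural abundance over the given atoms."""
    pmf = np.array([1.0])
    for el, count in sorted(composition.items()):
        if count <= 0:
            continue
        atom = _atom_pmf(abundances.get(el, ()))
        for _ in range(count):
            pmf = np.convolve(pmf, atom)
    return pmf


def build_correction_matrix(
    formula: str | Mapping[str, int],
    tracer_element: str = "C",
    n_tracer_atoms: int | None = None,
    purity: float = 0.99,
    abundances: Mapping[str, tuple[tuple[int, float], ...]] | None = None,
    metabolite: str = "",
) -> CorrectionMatrix:
    """Correction matrix for one metabolite and tracer element.

    ``n_tracer_atoms`` defaults to the formula's count of the tracer element.
    ``purity`` is the per-atom probability that a labeled position actually
    carries the heavy isotope (vendor spec is typically 0.99).
    """
    comp = parse_formula(formula) if isinstance(formula, str) else dict(formula)
    abundances = dict(DEFAULT_ABUNDANCES) if abundances is None else dict(abundances)
    n_el = comp.get(tracer_element, 0)
    if n_tracer_atoms is None:
        n_tracer_atoms = n_el
    if n_tracer_atoms > n_el:
        raise ValueError(
            f"{n_tracer_atoms} tracer atoms exceeds the {n_el} "
            f"{tracer_element} atoms of {formula!r}"
        )
    if not 0.0 < purity <= 1.0:
        raise ValueError("purity must be in (0, 1]")
    n = n_tracer_atoms
    mat = np.zeros((n + 1, n + 1))
    for j in range(n + 1):
        # (a) binomial purity loss over the j labeled atoms
        pmf = binom.pmf(np.arange(j + 1), j, purity)
        # (b) natural abundance over all remaining atoms (unlabeled tracer
        #     atoms and every atom of the other elements)
        rest = dict(comp)
        rest[tracer_element] = rest.get(tracer_element, 0) - j
        pmf = np.convolve(pmf, _natural_pmf(rest, abundances))
        mat[: min(n + 1, pmf.size), j] = pmf[: n + 1]
    return CorrectionMatrix(metabolite, tracer_element, mat)


def forward_convolve(true_mid: np.ndarray, matrix: CorrectionMatrix) -> np.ndarray:
    """Expected observed MID for a true tracer MID (generator-side model)."""
    true_mid = np.asarray(true_mid, dtype=float)
    if true_mid.size != matrix.n + 1:
        raise ValueError(
            f"MID length {true_mid.size} does not match matrix dimension {matrix.n + 1}"
        )
    return matrix.matrix @ true_mid


def correct_mid(
    raw: RawMIDRecord | np.ndarray,
    matrix: CorrectionMatrix,
) -> tuple[np.ndarray, float]:
    """Recover the tracer-attributable MID from observed ion counts.

    Solves ``matrix @ x ≈ observed`` by non-negative least squares on the
    normalized observation, clips at zero by construction and renormalizes to
    sum 1. Returns (corrected MID, residual norm of the NNLS fit).
    """
    counts = np.asarray(raw.counts if isinstance(raw, RawMIDRecord) else raw, dtype=float)
    if counts.size != matrix.n + 1:
        raise ValueError(
            f"count vector length {counts.size} does not match matrix dimension {matrix.n + 1}"
        )
    total = counts.sum()
    if total <= 0:
        raise UndefinedMIDError("all-zero ion counts: MID undefined")
    observed = counts / total
    x, residual = nnls(matrix.matrix, observed)
    s = x.sum()
    if s <= 0:
        raise UndefinedMIDError("correction produced an all-zero solution")
    return x / s, float(residual)
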