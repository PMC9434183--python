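"""Natural-abundance correction of mass-isotopologue distributions (MIDs).

A GC–MS fragment measured after ¹³C-glucose feeding carries mass shifts from
two sources: tracer-derived ¹³C on its carbon backbone, and naturally
occurring heavy isotopes of every atom in the (derivatized) fragment.  The
measured MID ``m`` (fractions of M+0 … M+n, n = number of tracer carbons)
is modelled as

    m = C @ x,

where ``x`` is the tracer-labelling distribution we want and column ``j`` of
the correction matrix ``C`` is the natural-abundance mass-shift distribution
of the species with ``j`` backbone carbons fixed as ¹³C.  The correction
solves the non-negative least-squares problem ``min ||C x - m||, x >= 0``
and renormalizes ``x`` to sum to one; non-negativity is imposed in the fit
rather than by clipping a plain inverse, which would break the sum-to-one
guarantee under noise.

The mean fractional enrichment is then ``E = sum_j j * x_j / n``, and the
tracer-derived amount of a metabolite pool is ``pool_amount * E``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.optimize

from .config import NATURAL_ABUNDANCE

__all__ = [
    "ElementalFormula",
    "MIDRecord",
    "CorrectionResult",
    "natural_mid",
    "correction_matrix",
    "correct_mid",
    "labeled_amount",
]

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """Elemental composition of a measured fragment.

    ``n_tracer_carbons`` is the number of backbone carbons that can carry
    tracer label; it defaults to the full carbon count and may be smaller
    when a derivatization agent contributes unlabelable carbons.
    """

    counts: Mapping[str, int]
    n_tracer_carbons: int = None

    def __post_init__(self) -> None:
        counts = {el: int(n) for el, n in self.counts.items() if n}
        object.__setattr__(self, "counts", counts)
        if any(n < 0 for n in counts.values()):
            raise ValueError("element counts must be non-negative")
        if counts.get("C", 0) < 1:
            raise ValueError("formula must contain at least one carbon")
        if self.n_tracer_carbons is None:
            object.__setattr__(self, "n_tracer_carbons", counts["C"])
        if not 1 <= self.n_tracer_carbons <= counts["C"]:
            raise ValueError("n_tracer_carbons must be in [1, C count]")

    @classmethod
    def parse(cls, hill: str, n_tracer_carbons: int | None = None) -> "ElementalFormula":
        """Parse a Hill-notation string such as ``"C6H12O6"`` or ``"C9H21NO2Si2"``."""
        pos, counts = 0, {}
        for m in _FORMULA_RE.finditer(hill):
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {hill!r} at position {pos}")
            counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
            pos = m.end()
        if pos != len(hill) or not counts:
            raise ValueError(f"cannot parse formula {hill!r}")
        return cls(counts, n_tracer_carbons)

    def __str__(self) -> str:
        return "".join(
            f"{el}{n if n > 1 else ''}" for el, n in sorted(self.counts.items())
        )


@dataclass
class MIDRecord:
    """A measured mass-isotopologue fraction vector with its formula."""

    metabolite: str
    formula: ElementalFormula
    measured: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.measured, dtype=float)
        n = self.formula.n_tracer_carbons
        if m.shape != (n + 1,):
            raise ValueError(
                f"measured MID must have length n_tracer_carbons+1 = {n + 1}, got {m.shape}"
            )
        if (m < 0).any():
            raise ValueError("measured fractions must be non-negative")
        if abs(m.sum() - 1.0) > 1e-6:
            raise ValueError(f"measured fractions must sum to 1 (got {m.sum():.8f})")
        self.measured = m


@dataclass
class CorrectionResult:
    """Outcome of a natural-abundance correction."""

    corrected: np.ndarray  #: tracer-labelling fractions, >= 0, sum to 1
    mean_enrichment: float  #: carbon-weighted mean fraction of tracer carbons
    residual_norm: float  #: ||C x - m|| of the NNLS fit, before renormalization


def _element_shift_dist(element: str, abundances: Mapping[str, Sequence[float]]) -> np.ndarray:
    if element not in abundances:
        raise KeyError(f"no isotope abundances known for element {element!r}")
    heavy = np.asarray(abundances[element], dtype=float)
    p0 = 1.0 - heavy.sum()
    if p0 < 0.5:
        raise ValueError(f"heavy-isotope abundances for {element!r} exceed 0.5")
    return np.concatenate([[p0], heavy])


def _power_convolve(dist: np.ndarray, n: int, max_len: int) -> np.ndarray:
    """n-fold self-convolution of a shift distribution, truncated to max_len."""
    out = np.zeros(max_len)
    out[0] = 1.0
    base = dist[:max_len]
    while n:
        if n & 1:
            out = np.convolve(out, base)[:max_len]
        n >>= 1
        if n:
            base = np.convolve(base, base)[:max_len]
    return out


def natural_mid(
    formula: ElementalFormula,
    abundances: Mapping[str, Sequence[float]] | None = None,
    max_shift: int | None = None,
) -> np.ndarray:
    """Mass-shift distribution of the unlabelled molecule.

    The distribution of the total mass shift is the convolution, over every
    atom in the formula, of that atom's isotope-shift distribution.  The
    result sums to 1 up to truncation at ``max_shift`` (default: enough to
    hold >1-1e-12 of the mass).
    """
    if abundances is None:
        abundances = NATURAL_ABUNDANCE
    # worst case every atom shifts maximally; cap generously
    total_atoms_shift = sum(
        n * len(_element_shift_dist(el, abundances) if el in abundances else [1])
        for el, n in formula.counts.items()
    )
    length = (max_shift + 1) if max_shift is not None else total_atoms_shift + 1
    out = np.zeros(length)
    out[0] = 1.0
    for el, n in formula.counts.items():
        dist = _element_shift_dist(el, abundances)
        out = np.convolve(out, _power_convolve(dist, n, length))[:length]
    return out


def correction_matrix(
    formula: ElementalFormula,
    abundances: Mapping[str, Sequence[float]] | None = None,
    tracer_purity: float = 1.0,
) -> np.ndarray:
    """Natural-abundance correction matrix, shape (n+1, n+1).

    Column ``j`` is the mass-shift distribution of the species whose first
    ``j`` tracer carbons are tracer-derived (heavy with probability
    ``tracer_purity``) while the remaining atoms sit at natural abundance,
    truncated to mass shifts 0..n.  Columns sum to <= 1 because shifts
    beyond M+n fall outside the measured window.
    """
    if abundances is None:
        abundances = NATURAL_ABUNDANCE
    if not 0.0 < tracer_purity <= 1.0:
        raise ValueError("tracer_purity must be in (0, 1]")
    n = formula.n_tracer_carbons
    residual_counts = dict(formula.counts)
    mat = np.zeros((n + 1, n + 1))
    for j in range(n + 1):
        counts_j = dict(residual_counts)
        counts_j["C"] = formula.counts["C"] - j
        if counts_j["C"] == 0:
            del counts_j["C"]
        # natural-abundance shifts of the residual (non-tracer) atoms
        res = _atoms_mid(counts_j, abundances, n)
        # tracer carbons: each heavy with probability = purity; the convolution
        # with the residual shifts already places the column at mass j + k
        tracer = _power_convolve(np.array([1.0 - tracer_purity, tracer_purity]), j, n + 1)
        mat[:, j] = np.convolve(tracer, res)[: n + 1]
    return mat


def _atoms_mid(counts: Mapping[str, int], abundances, max_shift: int) -> np.ndarray:
    """Natural mass-shift distribution of an arbitrary atom set (may be empty)."""
    out = np.zeros(max_shift + 1)
    out[0] = 1.0
    for el, n in counts.items():
        dist = _element_shift_dist(el, abundances)
        out = np.convolve(out, _power_convolve(dist, n, max_shift + 1))[: max_shift + 1]
    return out


def correct_mid(
    record: MIDRecord,
    abundances: Mapping[str, Sequence[float]] | None = None,
    tracer_purity: float = 1.0,
) -> CorrectionResult:
    """Remove natural-abundance contributions from a measured MID.

    Solves ``min ||C x - m||`` with ``x >= 0`` (non-negative least squares),
    renormalizes ``x`` to sum to one, and reports the carbon-weighted mean
    enrichment ``E = sum_j j x_j / n``.
    """
    C = correction_matrix(record.formula, abundances, tracer_purity)
    x, residual = scipy.optimize.nnls(C, record.measured)
    total = x.sum()
    if total <= 0:
        raise ArithmeticError("degenerate correction: all fractions fit to zero")
    corrected = x / total
    n = record.formula.n_tracer_carbons
    enrichment = float(np.arange(n + 1) @ corrected / n)
    return CorrectionResult(corrected, enrichment, float(residual))


def labeled_amount(pool_amount: float, enrichment: float) -> float:
    """Tracer-derived amount of a pool: ``pool_amount * E`` (same units as pool).

    With the pool in ng per mg fresh weight, this is the ¹³C accumulation of
    the metabolite in ng·mg⁻¹ FW.
    """
    if pool_amount < 0:
        raise ValueError("pool_amount must be non-negative")
    if not 0.0 <= enrichment <= 1.0:
        raise ValueError("enrichment must lie in [0, 1]")
    return pool_amount * enrichment
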