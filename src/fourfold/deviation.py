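"""Deviation of fourfold-degenerate codon usage from the mutational
expectation.

For a fourfold family s (four codons sharing their first two positions) the
deviation is the chi-square-inspired statistic

    F_{pi|s} = sum_i |pi_i - pi^sel_{s_i} / pi^sel_s| / pi_i ,   i in {A,T,G,C}

where pi^sel_{s_i}/pi^sel_s is the relative frequency of the third-position
nucleotide i within the family after selection and pi_i its expectation under
mutation alone (product-form stationarity makes the within-family expectation
exactly pi).  The total F_pi sums the family terms.  F_pi >= 0 with equality
iff every family's relative usage equals pi (the identity condition).

Two family sets are supported.  The five canonical fourfold-degenerate
families are the amino acids coded *only* by one fourfold box (Gly, Val, Thr,
Ala, Pro).  The full set of eight fourfold boxes adds the fourfold sub-boxes
of the sixfold-degenerate amino acids (Leu CTN, Ser TCN, Arg CGN), whose third
position is equally silent.  Which set a statistic uses is always explicit in
the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .grid import NUCLEOTIDES, NucleotideDistribution, StationaryGrid, select_subgrid

#: Canonical fourfold families: amino acids encoded by a single fourfold box.
CANONICAL_FAMILIES: dict[str, str] = {
    "Gly": "GG",
    "Val": "GT",
    "Thr": "AC",
    "Ala": "GC",
    "Pro": "CC",
}

#: All eight fourfold-degenerate codon boxes of the standard code.
ALL_FOURFOLD_BOXES: dict[str, str] = {
    **CANONICAL_FAMILIES,
    "Leu4": "CT",
    "Ser4": "TC",
    "Arg4": "CG",
}


@dataclass
class DeviationResult:
    per_family: dict[str, float]
    total: float
    pi: NucleotideDistribution
    variant: str                  # "SL" | "SM" | other provenance tag
    family_set: str               # "canonical5" | "boxes8"

    def __post_init__(self) -> None:
        if abs(self.total - sum(self.per_family.values())) > 1e-12:
            raise ValueError("total must equal the sum of family deviations")


def _family_relative(pi_sel: np.ndarray, states, prefix: str) -> np.ndarray:
    pos_of = {c: i for i, c in enumerate(states)}
    mass = np.array([pi_sel[pos_of[prefix + n]] for n in NUCLEOTIDES])
    total = mass.sum()
    if total <= 0:
        raise ValueError(f"family {prefix}N has zero stationary mass")
    return mass / total


def family_deviation(
    pi: NucleotideDistribution, pi_sel: np.ndarray, states, prefix: str
) -> float:
    """Deviation of one fourfold family, given a codon distribution."""
    rel = _family_relative(pi_sel, states, prefix)
    p = pi.as_array()
    return float(np.sum(np.abs(p - rel) / p))


def total_deviation(
    pi: NucleotideDistribution,
    pi_sel: np.ndarray,
    states,
    variant: str = "SM",
    family_set: str = "canonical5",
) -> DeviationResult:
    """Per-family and total F for a post-selection codon distribution.

    ``family_set`` selects the five canonical families ("canonical5") or all
    eight fourfold boxes (available for cross-checks).
    """
    fams = _families(family_set)
    per = {
        name: family_deviation(pi, pi_sel, states, prefix)
        for name, prefix in fams.items()
    }
    return DeviationResult(per, float(sum(per.values())), pi, variant, family_set)


def _families(family_set: str) -> dict[str, str]:
    if family_set == "canonical5":
        return CANONICAL_FAMILIES
    if family_set == "boxes8":
        return ALL_FOURFOLD_BOXES
    raise ValueError(f"unknown family set {family_set!r}")


def alt_divergences(
    pi: NucleotideDistribution,
    pi_sel: np.ndarray,
    states,
    family_set: str = "canonical5",
) -> dict[str, float]:
    """Comparator divergences between family usage and the expectation.

    Per family, the Kullback-Leibler divergence KL(rel || pi) and the total
    variation distance; both summed over families.  Useful to confirm that
    conclusions do not hinge on the particular deviation statistic.
    """
    p = pi.as_array()
    kl = tv = 0.0
    for prefix in _families(family_set).values():
        rel = _family_relative(pi_sel, states, prefix)
        if np.any(p <= 0):
            raise ValueError("KL undefined for zero expected components")
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(rel > 0, rel * np.log(rel / p), 0.0)
        kl += float(terms.sum())
        tv += float(0.5 * np.abs(rel - p).sum())
    return {"kl": kl, "tv": tv}


def measure_concordance(values_f, values_alt) -> float:
    """Spearman rank correlation between F and a comparator over many models."""
    rho, _ = spearmanr(values_f, values_alt)
    return float(rho)


def median_profiles(
    results: list[tuple[NucleotideDistribution, float]],
    grid: StationaryGrid,
    grouping: tuple,
) -> pd.DataFrame:
    """Median of a per-distribution statistic along one grid direction.

    ``grouping`` is a subgrid-specification template whose last element is
    filled with each lattice value in turn, e.g. ``("fixed", "A", None)`` or
    ``("aggregate", "AT", None)``.  Returns raw medians with group counts
    (no smoothing); empty groups are omitted.
    """
    by_pi = {}
    for pi, value in results:
        by_pi.setdefault(pi.freqs, []).append(value)
    kind = grouping[0]
    if kind not in ("fixed", "aggregate"):
        raise ValueError("grouping must be 'fixed' or 'aggregate'")
    steps = round((grid.upper - grid.lower) / grid.step)
    rows = []
    for k in range(steps * 2 + 1):
        value = grid.lower + k * grid.step
        if value > 2 * grid.upper + 1e-12:
            break
        sub = select_subgrid(grid, (kind, grouping[1], value))
        vals = [v for m in sub for v in by_pi.get(m.freqs, [])]
        if vals:
            rows.append(
                {
                    "group_value": value,
                    "median": float(np.median(vals)),
                    "n": len(vals),
                }
            )
    return pd.DataFrame(rows)
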