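"""Lattices of candidate nucleotide stationary distributions.

The mutation models downstream are parameterized by a nucleotide stationary
distribution pi = (pi_A, pi_T, pi_G, pi_C).  Sweeps run over a dense lattice of
such distributions: every 4-tuple on a fixed step grid whose components lie in
[lower, upper] and sum to one.  All lattice arithmetic is done in integer step
units so that membership tests, de-duplication and subgrid filters are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

NUCLEOTIDES = ("A", "T", "G", "C")

COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


@dataclass(frozen=True)
class NucleotideDistribution:
    """A probability vector over (A, T, G, C)."""

    freqs: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        arr = np.asarray(self.freqs, dtype=float)
        if arr.shape != (4,):
            raise ValueError("expected exactly four frequencies (A, T, G, C)")
        if np.any(arr <= 0) or np.any(arr >= 1):
            raise ValueError(f"frequencies must lie in (0, 1): {self.freqs}")
        if abs(arr.sum() - 1.0) > 1e-12:
            raise ValueError(f"frequencies must sum to 1: sum={arr.sum()!r}")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.freqs, dtype=float)

    def __getitem__(self, nucleotide: str) -> float:
        return self.freqs[NUCLEOTIDES.index(nucleotide)]

    def __iter__(self):
        return iter(self.freqs)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        inner = ", ".join(f"{n}={f:.4f}" for n, f in zip(NUCLEOTIDES, self.freqs))
        return f"NucleotideDistribution({inner})"


@dataclass
class StationaryGrid:
    """An ordered, duplicate-free collection of lattice distributions."""

    members: list[NucleotideDistribution]
    step: float
    lower: float
    upper: float
    label: str = "grid"

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def __getitem__(self, i: int) -> NucleotideDistribution:
        return self.members[i]

    def to_frame(self) -> pd.DataFrame:
        data = np.array([m.freqs for m in self.members])
        return pd.DataFrame(data, columns=[f"pi_{n}" for n in NUCLEOTIDES])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.4f")


def _step_units(step: float, lower: float, upper: float) -> tuple[int, int, int]:
    """Convert (step, lower, upper) to exact integer units of the step."""
    fstep = Fraction(step).limit_denominator(10**6)
    lo = Fraction(lower).limit_denominator(10**6) / fstep
    hi = Fraction(upper).limit_denominator(10**6) / fstep
    total = Fraction(1) / fstep
    if lo.denominator != 1 or hi.denominator != 1 or total.denominator != 1:
        raise ValueError(
            "lower, upper and 1.0 must all be integer multiples of step"
        )
    return int(lo), int(hi), int(total)


def enumerate_grid(
    step: float = 0.01, lower: float = 0.05, upper: float = 0.85, label: str = "full"
) -> StationaryGrid:
    """Enumerate every lattice distribution with components in [lower, upper].

    Components are integer multiples of ``step``; the four components sum to
    exactly one.  Ordering is lexicographic in (pi_A, pi_T, pi_G); pi_C is the
    remainder.  With the default bounds and a 0.01 step the natural lattice has
    C(83, 3) = 91,881 members.  (A published sweep over this same box reports
    88,560 = C(82, 3) distributions; the pruning behind that count is not
    recoverable, so this function enumerates the full lattice and callers that
    care can compare both counts via :func:`expected_counts`.)
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if not (0 < lower <= upper < 1):
        raise ValueError("bounds must satisfy 0 < lower <= upper < 1")
    lo, hi, total = _step_units(step, lower, upper)
    fstep = Fraction(step).limit_denominator(10**6)

    def as_float(units: int) -> float:
        # exact rational -> nearest float, so 5 steps of 0.01 is exactly 0.05
        return float(units * fstep)

    members: list[NucleotideDistribution] = []
    for a in range(lo, hi + 1):
        for t in range(lo, hi + 1):
            rem_gt = total - a - t
            if rem_gt < 2 * lo or rem_gt > 2 * hi:
                continue
            for g in range(max(lo, rem_gt - hi), min(hi, rem_gt - lo) + 1):
                c = rem_gt - g
                members.append(
                    NucleotideDistribution(
                        (as_float(a), as_float(t), as_float(g), as_float(c))
                    )
                )
    if not members:
        raise ValueError("bounds admit no valid distribution")
    return StationaryGrid(members, step, lower, upper, label)


def expected_counts(step: float = 0.01, lower: float = 0.05, upper: float = 0.85) -> dict:
    """Lattice size by direct enumeration, next to the published 88,560.

    Returns both numbers so sweeps can surface the discrepancy rather than
    silently reconcile it.
    """
    n = len(enumerate_grid(step, lower, upper).members)
    return {"lattice": n, "published": 88_560}


def select_subgrid(grid: StationaryGrid, constraint: tuple) -> StationaryGrid:
    """Filter a grid by an exact lattice constraint.

    ``constraint`` is one of::

        ("fixed", nucleotide, value)        pi_N == value
        ("equal_complementary",)            pi_A == pi_T and pi_G == pi_C
        ("aggregate", pair, value)          pi_X + pi_Y == value, pair like "AT"

    Comparisons are exact in step units (tolerance 1e-12 on the floats).
    """
    kind = constraint[0]
    tol = 1e-12

    if kind == "fixed":
        _, nuc, value = constraint
        if nuc not in NUCLEOTIDES:
            raise ValueError(f"unknown nucleotide {nuc!r}")
        keep = [m for m in grid if abs(m[nuc] - value) <= tol]
        label = f"{grid.label}[{nuc}={value:g}]"
    elif kind == "equal_complementary":
        keep = [
            m
            for m in grid
            if abs(m["A"] - m["T"]) <= tol and abs(m["G"] - m["C"]) <= tol
        ]
        label = f"{grid.label}[A=T,G=C]"
    elif kind == "aggregate":
        _, pair, value = constraint
        if len(pair) != 2 or any(n not in NUCLEOTIDES for n in pair):
            raise ValueError(f"unknown nucleotide pair {pair!r}")
        keep = [m for m in grid if abs(m[pair[0]] + m[pair[1]] - value) <= tol]
        label = f"{grid.label}[{pair[0]}+{pair[1]}={value:g}]"
    else:
        raise ValueError(f"unknown constraint kind {kind!r}")

    return StationaryGrid(keep, grid.step, grid.lower, grid.upper, label)


def read_grid_tsv(path, step: float, lower: float, upper: float) -> StationaryGrid:
    df = pd.read_csv(path, sep="\t")
    members = [
        NucleotideDistribution(tuple(row))
        for row in df[[f"pi_{n}" for n in NUCLEOTIDES]].to_numpy()
    ]
    return StationaryGrid(members, step, lower, upper, label="from_tsv")
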