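"""Amino-acid-level selection layered on the codon mutation chain.

Selection is a symmetric acceptance matrix D over the 20 amino acids:
d_{m->n} is the probability that a replacement of amino acid m by n is fixed.
Synonymous changes are always accepted (unit diagonal), so selection acts only
through nonsynonymous flux.  D is derived from Grantham's (1974) chemical
distance G by a monotone transform, by default d = 1 - G/215 (215 is the
largest Grantham distance, Cys-Trp).  Substitutions to and from stop codons
follow one of two policies: SL treats them as lethal (acceptance 0, and the
chain is restricted to the 61 sense codons to stay irreducible), SM gives them
the smallest positive acceptance in D (all 64 codons kept).

Note on calibration: reference class means of 0.538 (transitions) and 0.409
(transversions) have been reported for a Morton-style acceptance matrix over
the fourfold-degenerate mutation census.  No monotone transform of the
Grantham distances reproduces those means under this census (see
``calibration_report``), so the linear default is retained and the transform
is pluggable.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Callable

import numpy as np
import pandas as pd

from .grid import NUCLEOTIDES
from .mutation import (
    CODONS_64,
    GENETIC_CODE,
    STOP_CODONS,
    CodonTransitionMatrix,
    is_transition,
    stationary,
)

AMINO_ACIDS = tuple(sorted(set(GENETIC_CODE.values())))

#: The five fourfold-degenerate codon family prefixes (first two positions).
FOURFOLD_PREFIXES = ("GG", "GT", "AC", "GC", "CC")  # Gly Val Thr Ala Pro

GRANTHAM_MAX = 215.0


def grantham_distances() -> pd.DataFrame:
    """The packaged Grantham (1974) chemical distance table, 20x20."""
    path = resources.files("fourfold.data") / "grantham.tsv"
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t", index_col=0)
    df = df.loc[list(AMINO_ACIDS), list(AMINO_ACIDS)]
    assert (df.values == df.values.T).all(), "distance table must be symmetric"
    return df


def linear_transform(gmax: float = GRANTHAM_MAX) -> Callable[[float], float]:
    """d = 1 - G/gmax, the default acceptance transform."""
    return lambda g: 1.0 - g / gmax


def clipped_linear_transform(scale: float) -> Callable[[float], float]:
    """d = max(0, 1 - G/scale): acceptance hits zero at distance `scale`."""
    return lambda g: max(0.0, 1.0 - g / scale)


def power_transform(k: float, gmax: float = GRANTHAM_MAX) -> Callable[[float], float]:
    """d = (1 - G/gmax)^k, sharpening (k>1) or flattening (k<1) selection."""
    return lambda g: (1.0 - g / gmax) ** k


@dataclass
class AcceptanceMatrix:
    accept: pd.DataFrame          # symmetric 20x20, unit diagonal
    stop_policy: str              # "SL" | "SM"
    stop_accept: float

    def __post_init__(self) -> None:
        a = self.accept.values
        if not np.allclose(np.diag(a), 1.0):
            raise ValueError("acceptance diagonal must be exactly one")
        if not np.allclose(a, a.T):
            raise ValueError("acceptance matrix must be symmetric")
        if a.min() < 0 or a.max() > 1:
            raise ValueError("acceptance values must lie in [0, 1]")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        m, n = pair
        return float(self.accept.at[m, n])


def acceptance_matrix(
    stop_policy: str = "SM",
    transform: Callable[[float], float] | None = None,
) -> AcceptanceMatrix:
    """Build the acceptance matrix from the packaged Grantham table.

    Under SM the stop acceptance is the smallest *positive* off-diagonal
    acceptance (the linear transform maps the Cys-Trp distance to exactly
    zero, and a zero stop acceptance would disconnect the stop codons, i.e.
    collapse SM onto SL); under SL it is zero.
    """
    if stop_policy not in ("SL", "SM"):
        raise ValueError("stop_policy must be 'SL' or 'SM'")
    f = transform or linear_transform()
    G = grantham_distances()
    vals = np.ones((20, 20))
    for i, m in enumerate(AMINO_ACIDS):
        for j, n in enumerate(AMINO_ACIDS):
            if m != n:
                vals[i, j] = f(float(G.at[m, n]))
    if vals.min() < 0 or vals.max() > 1:
        raise ValueError("transform produced acceptance values outside [0, 1]")
    df = pd.DataFrame(vals, index=AMINO_ACIDS, columns=AMINO_ACIDS)
    if stop_policy == "SL":
        stop_accept = 0.0
    else:
        off = vals[~np.eye(20, dtype=bool)]
        positive = off[off > 0]
        if len(positive) == 0:
            raise ValueError("no positive acceptance values; SM undefined")
        stop_accept = float(positive.min())
    return AcceptanceMatrix(df, stop_policy, stop_accept)


@dataclass
class MutationSelectionMatrix:
    probs: np.ndarray
    state_labels: tuple[str, ...]
    pi_sel: np.ndarray
    source: CodonTransitionMatrix
    acceptance: AcceptanceMatrix


def _acceptance_for(ci: str, cj: str, D: AcceptanceMatrix) -> float:
    si, sj = ci in STOP_CODONS, cj in STOP_CODONS
    if si and sj:
        return 1.0
    if si or sj:
        return D.stop_accept
    m, n = GENETIC_CODE[ci], GENETIC_CODE[cj]
    return 1.0 if m == n else D[m, n]


def combine(P_star: CodonTransitionMatrix, D: AcceptanceMatrix) -> MutationSelectionMatrix:
    """Mutation-selection matrix C: c_{k->l} = p*_{k->l} d_{m->n}.

    Synonymous off-diagonals are copied unchanged, nonsynonymous ones damped
    by the acceptance of the amino-acid change, sense<->stop ones by the stop
    acceptance; diagonals complete the rows.  Under SL the source chain must
    already live on the 61 sense codons.
    """
    states = P_star.state_labels
    if D.stop_policy == "SL" and len(states) != 61:
        raise ValueError("SL requires the 61-sense-codon state space")
    n = len(states)
    C = np.zeros((n, n))
    src = P_star.probs
    for i in range(n):
        for j in range(n):
            if i == j or src[i, j] == 0.0:
                continue
            C[i, j] = src[i, j] * _acceptance_for(states[i], states[j], D)
    np.fill_diagonal(C, 0.0)
    np.fill_diagonal(C, 1.0 - C.sum(axis=1))
    pi_sel = stationary(C)
    return MutationSelectionMatrix(C, states, pi_sel, P_star, D)


@dataclass
class MutationCensus:
    """Nonsynonymous single-nucleotide mutation opportunities of 4FD codons.

    One case per (codon, position, target nucleotide) over the 20 codons of
    the five fourfold families and their first two positions; cases whose
    target is a stop codon are kept and flagged (``target_aa`` is None).
    """

    cases: list[tuple[str, str, str, str, str, str | None]]
    # (codon, mutant, from_nt, to_nt, from_aa, to_aa-or-None)

    @property
    def counts(self) -> dict[tuple[str, str], int]:
        out: dict[tuple[str, str], int] = {}
        for _, _, x, y, _, _ in self.cases:
            out[(x, y)] = out.get((x, y), 0) + 1
        return out

    @property
    def total(self) -> int:
        return len(self.cases)


def mutation_census() -> MutationCensus:
    """Enumerate the 120 nonsynonymous single-nucleotide mutations of the
    fourfold-degenerate codons (first and second codon positions)."""
    cases = []
    for prefix in FOURFOLD_PREFIXES:
        for third in NUCLEOTIDES:
            codon = prefix + third
            aa = GENETIC_CODE[codon]
            for pos in (0, 1):
                x = codon[pos]
                for y in NUCLEOTIDES:
                    if y == x:
                        continue
                    mutant = codon[:pos] + y + codon[pos + 1 :]
                    to_aa = GENETIC_CODE.get(mutant)  # None for stops
                    cases.append((codon, mutant, x, y, aa, to_aa))
    return MutationCensus(cases)


def acceptance_class_means(
    D: AcceptanceMatrix, census: MutationCensus, include_stop_cases: bool = False
) -> dict[str, float]:
    """Mean acceptance over transition vs transversion census cases.

    Each (codon, position, target) case is weighted equally.  The single
    census case whose target is a stop codon (GGA->TGA) is excluded by
    default; with ``include_stop_cases`` it enters at the stop acceptance.
    """
    ti, tv = [], []
    for _, _, x, y, m, n in census.cases:
        if n is None:
            if not include_stop_cases:
                continue
            d = D.stop_accept
        else:
            d = D[m, n]
        (ti if is_transition(x, y) else tv).append(d)
    if not ti or not tv:
        raise ValueError("empty substitution class")
    return {"transition": float(np.mean(ti)), "transversion": float(np.mean(tv))}


def calibration_report(
    transforms: dict[str, Callable[[float], float]] | None = None,
) -> pd.DataFrame:
    """Class means of candidate acceptance transforms under two weightings.

    Rows: one per (transform, weighting).  The 'census' weighting averages
    over the 120-case fourfold census; 'all_nonsyn' over every nonsynonymous
    single-nucleotide change among the 61 sense codons.  This is the
    diagnostic used when a reference calibration cannot be matched.
    """
    if transforms is None:
        transforms = {
            "linear_215": linear_transform(),
            "power_2": power_transform(2.0),
            "clipped_100": clipped_linear_transform(100.0),
        }
    census = mutation_census()
    all_cases = []
    for codon in CODONS_64:
        if codon in STOP_CODONS:
            continue
        for pos in range(3):
            for y in NUCLEOTIDES:
                if y == codon[pos]:
                    continue
                mutant = codon[:pos] + y + codon[pos + 1 :]
                if mutant in STOP_CODONS:
                    continue
                if GENETIC_CODE[mutant] != GENETIC_CODE[codon]:
                    all_cases.append(
                        (codon, mutant, codon[pos], y,
                         GENETIC_CODE[codon], GENETIC_CODE[mutant])
                    )
    rows = []
    for name, f in transforms.items():
        D = acceptance_matrix("SM", transform=f)
        for wname, cases in [("census", census.cases), ("all_nonsyn", all_cases)]:
            ti, tv = [], []
            for _, _, x, y, m, n in cases:
                if n is None:
                    continue
                (ti if is_transition(x, y) else tv).append(D[m, n])
            rows.append(
                {
                    "transform": name,
                    "weighting": wname,
                    "mean_transition": float(np.mean(ti)),
                    "mean_transversion": float(np.mean(tv)),
                    "n_transition": len(ti),
                    "n_transversion": len(tv),
                }
            )
    return pd.DataFrame(rows)
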