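"""Unrestricted (UNREST) nucleotide substitution models with a fixed
stationary distribution, and their lift to the codon level.

The mutation process is a homogeneous continuous-time Markov chain on
{A, T, G, C} with generator Q whose 12 off-diagonal rates are free up to the
three independent balance constraints pi Q = 0.  Feasible rate vectors are
therefore points of a 9-dimensional linear subspace intersected with the
positive orthant; we parameterize them by coefficients in an orthonormal
null-space basis.  The generator is turned into a discrete-time transition
matrix by uniformization with the global rate q = sum_i |q_ii| (so the
off-diagonal mass of P sums to exactly one), and lifted to a 64- or 61-state
codon chain in which only single-nucleotide changes have positive probability.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy.linalg import null_space

from .grid import NUCLEOTIDES, NucleotideDistribution

#: Fixed ordering of the 12 substitution rates
#: [q_AT, q_AG, q_AC, q_TA, q_TG, q_TC, q_GA, q_GT, q_GC, q_CA, q_CT, q_CG].
BETA_ORDER: tuple[tuple[str, str], ...] = tuple(
    (x, y) for x in NUCLEOTIDES for y in NUCLEOTIDES if x != y
)

_IDX = {n: i for i, n in enumerate(NUCLEOTIDES)}

STOP_CODONS = ("TAA", "TAG", "TGA")

#: All 64 codons, alphabetically; the deterministic state ordering everywhere.
CODONS_64: tuple[str, ...] = tuple(
    sorted("".join(c) for c in product("ACGT", repeat=3))
)
CODONS_61: tuple[str, ...] = tuple(c for c in CODONS_64 if c not in STOP_CODONS)

# Standard genetic code (translation table 1), written out rather than pulled
# from biopython at import time so the mapping used is visible and fixed.
from Bio.Data.CodonTable import unambiguous_dna_by_id as _tables

GENETIC_CODE: dict[str, str] = dict(_tables[1].forward_table)


@dataclass
class RateCoefficients:
    """A feasible rate vector and its null-space representation."""

    beta: np.ndarray            # 12 strictly positive rates in BETA_ORDER
    basis_coeffs: np.ndarray    # 9 coefficients in `basis`
    basis: np.ndarray           # (12, 9) orthonormal null-space basis
    pi: NucleotideDistribution

    def __post_init__(self) -> None:
        recon = self.basis @ self.basis_coeffs
        if not np.allclose(recon, self.beta, atol=1e-10):
            raise ValueError("beta is not the stated combination of basis vectors")
        if np.any(self.beta <= 0):
            raise ValueError("all 12 substitution rates must be strictly positive")


@dataclass
class RateMatrix:
    rates: np.ndarray  # (4, 4) generator, rows sum to zero
    pi: NucleotideDistribution

    def __post_init__(self) -> None:
        if np.max(np.abs(self.rates.sum(axis=1))) > 1e-10:
            raise ValueError("generator rows must sum to zero")


@dataclass
class NucleotideTransitionMatrix:
    probs: np.ndarray           # (4, 4) row-stochastic
    uniformization_rate: float
    pi: NucleotideDistribution

    def __post_init__(self) -> None:
        if np.max(np.abs(self.probs.sum(axis=1) - 1.0)) > 1e-12:
            raise ValueError("transition matrix rows must sum to one")
        resid = self.pi.as_array() @ self.probs - self.pi.as_array()
        if np.max(np.abs(resid)) > 1e-8:
            raise ValueError("pi is not stationary for this transition matrix")


@dataclass
class CodonTransitionMatrix:
    probs: np.ndarray            # (n, n) row-stochastic, n in {61, 64}
    state_labels: tuple[str, ...]
    pi_cod: np.ndarray

    def __post_init__(self) -> None:
        if np.max(np.abs(self.probs.sum(axis=1) - 1.0)) > 1e-12:
            raise ValueError("codon matrix rows must sum to one")


@dataclass
class MatrixSummary:
    titv_ratio: float
    dev_rev: float


def constraint_matrix(pi: NucleotideDistribution) -> np.ndarray:
    """The 3x12 matrix V with V beta^T = 0 encoding pi Q = 0.

    Row k is the stationarity balance for nucleotide k (A, T, G); the fourth
    balance equation is linearly dependent and omitted.
    """
    p = pi.as_array()
    V = np.zeros((3, 12))
    for row, target in enumerate(NUCLEOTIDES[:3]):
        for col, (x, y) in enumerate(BETA_ORDER):
            if x == target:
                V[row, col] -= p[_IDX[target]]   # outflow from target
            elif y == target:
                V[row, col] += p[_IDX[x]]        # inflow into target
    return V


def nullspace_basis(V: np.ndarray) -> np.ndarray:
    """Orthonormal (12, 9) basis of the null space of V, deterministic sign.

    Raises if the null space does not have dimension 9 (which would mean the
    constraint matrix is degenerate).
    """
    B = null_space(V)
    if B.shape != (12, 9):
        raise ValueError(f"null space has dimension {B.shape[1]}, expected 9")
    # SVD sign is arbitrary per vector; fix it so repeated calls agree.
    for j in range(B.shape[1]):
        k = np.argmax(np.abs(B[:, j]))
        if B[k, j] < 0:
            B[:, j] = -B[:, j]
    return B


def sample_coefficients(
    basis: np.ndarray,
    pi: NucleotideDistribution,
    rng: np.random.Generator,
    max_attempts: int = 500_000,
) -> RateCoefficients:
    """Draw a random feasible rate vector.

    Coefficients are i.i.d. standard normal in the null-space basis, rejected
    until every induced rate is strictly positive, then scaled so the rate
    vector has unit Euclidean norm (scale does not matter after
    uniformization).  The acceptance probability of a draw falls to ~1e-4
    for strongly skewed pi, hence the large attempt cap; draws are batched,
    so rejection is cheap.
    """
    batch = 2_000
    attempts = 0
    while attempts < max_attempts:
        coeffs = rng.standard_normal((9, batch))
        betas = basis @ coeffs
        feasible = np.where(np.all(betas > 0, axis=0))[0]
        if len(feasible):
            j = feasible[0]
            beta = betas[:, j]
            norm = np.linalg.norm(beta)
            return RateCoefficients(beta / norm, coeffs[:, j] / norm, basis, pi)
        attempts += batch
    raise RuntimeError(
        f"no feasible rate vector found in {max_attempts} attempts"
    )


def coefficients_from_beta(
    beta: np.ndarray, basis: np.ndarray, pi: NucleotideDistribution
) -> RateCoefficients:
    """Project a known feasible rate vector onto the basis."""
    beta = np.asarray(beta, dtype=float)
    coeffs = basis.T @ beta
    return RateCoefficients(basis @ coeffs, coeffs, basis, pi)


def build_rate_matrix(coeffs: RateCoefficients) -> RateMatrix:
    """Place the 12 rates into the 4x4 generator; diagonals close the rows."""
    Q = np.zeros((4, 4))
    for (x, y), rate in zip(BETA_ORDER, coeffs.beta):
        Q[_IDX[x], _IDX[y]] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    resid = coeffs.pi.as_array() @ Q
    if np.max(np.abs(resid)) > 1e-8:
        raise ValueError("pi Q = 0 violated beyond tolerance")
    return RateMatrix(Q, coeffs.pi)


def uniformize(Q: RateMatrix) -> NucleotideTransitionMatrix:
    """Discrete-time transition matrix sharing Q's stationary distribution.

    Uses the global rate q = sum_i |q_ii| (the sum of leaving rates), so the
    off-diagonal entries of P sum to exactly one and the diagonal entries sum
    to exactly three.
    """
    q = float(np.abs(np.diag(Q.rates)).sum())
    if q == 0:
        raise ValueError("all-zero generator cannot be uniformized")
    P = Q.rates / q + np.eye(4)
    return NucleotideTransitionMatrix(P, q, Q.pi)


def stationary(matrix: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Unique stationary distribution of a row-stochastic matrix.

    Solved by left-eigendecomposition with a bordered-linear-system
    cross-check; raises if the unit eigenvalue is not simple (a reducible
    chain, e.g. a stop-codon policy that disconnects states).
    """
    M = np.asarray(matrix, dtype=float)
    n = M.shape[0]
    w, v = np.linalg.eig(M.T)
    close = np.where(np.abs(w - 1.0) < 1e-8)[0]
    if len(close) != 1:
        raise ValueError(
            f"unit eigenvalue has multiplicity {len(close)}; "
            "chain is reducible or matrix is not stochastic"
        )
    pi = np.real(v[:, close[0]])
    pi = pi / pi.sum()
    # independent route: solve (I - M^T) pi = 0 with the normalization row
    A = np.vstack([np.eye(n) - M.T, np.ones((1, n))])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi_ls, *_ = np.linalg.lstsq(A, b, rcond=None)
    if np.max(np.abs(pi - pi_ls)) > 1e-8:
        raise ValueError("eigen and linear-system stationary vectors disagree")
    pi = np.clip(pi, 0.0, None)
    pi = pi / pi.sum()
    resid = np.max(np.abs(pi @ M - pi))
    if resid > tol:
        raise ValueError(f"stationarity residual {resid:.2e} exceeds {tol:.0e}")
    return pi


def codon_matrix(
    P: NucleotideTransitionMatrix, state_space: str = "64-all"
) -> CodonTransitionMatrix:
    """Lift a nucleotide transition matrix to the codon level.

    Codon pairs differing at exactly one position, with nucleotide change
    x -> y, get probability p_xy / 3; pairs differing at two or more positions
    get exactly zero; diagonals complete the rows.  The 1/3 factor (choose a
    position uniformly, then substitute there) keeps every row sum feasible
    and makes the product measure prod_j pi_(codon_j) stationary, so the
    relative third-position frequencies within each fourfold family equal pi.
    """
    if state_space == "64-all":
        states = CODONS_64
    elif state_space == "61-sense":
        states = CODONS_61
    else:
        raise ValueError(f"unknown state space {state_space!r}")
    pos_of = {c: i for i, c in enumerate(states)}
    n = len(states)
    M = np.zeros((n, n))
    for i, codon in enumerate(states):
        for pos in range(3):
            for y in NUCLEOTIDES:
                if y == codon[pos]:
                    continue
                other = codon[:pos] + y + codon[pos + 1 :]
                j = pos_of.get(other)
                if j is not None:
                    M[i, j] = P.probs[_IDX[codon[pos]], _IDX[y]] / 3.0
        off = M[i].sum()
        if off > 1.0 + 1e-12:
            raise ValueError("off-diagonal codon mass exceeds one")  # pragma: no cover
        M[i, i] = 1.0 - off
    pi_cod = stationary(M)
    return CodonTransitionMatrix(M, states, pi_cod)


def product_codon_measure(
    pi: NucleotideDistribution, states: tuple[str, ...]
) -> np.ndarray:
    """The product measure prod_j pi_(codon_j), normalized over `states`."""
    p = pi.as_array()
    w = np.array([np.prod([p[_IDX[n]] for n in codon]) for codon in states])
    return w / w.sum()


def reversible_transition_matrix(
    pi: NucleotideDistribution, exchangeabilities: np.ndarray
) -> NucleotideTransitionMatrix:
    """GTR-style time-reversible transition matrix with stationary pi.

    ``exchangeabilities`` are the 6 symmetric positive factors r_xy for the
    unordered pairs in the order (AT, AG, AC, TG, TC, GC); q_xy = r_xy pi_y.
    """
    r = np.asarray(exchangeabilities, dtype=float)
    if r.shape != (6,) or np.any(r <= 0):
        raise ValueError("expected 6 strictly positive exchangeabilities")
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    p = pi.as_array()
    Q = np.zeros((4, 4))
    for (i, j), rij in zip(pairs, r):
        Q[i, j] = rij * p[j]
        Q[j, i] = rij * p[i]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    P = uniformize(RateMatrix(Q, pi))
    db = p[:, None] * P.probs - (p[:, None] * P.probs).T
    if np.max(np.abs(db)) > 1e-10:
        raise ValueError("detailed balance violated beyond tolerance")
    return P


_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def is_transition(x: str, y: str) -> bool:
    return (x, y) in _TRANSITIONS


def matrix_summary(P: NucleotideTransitionMatrix) -> MatrixSummary:
    """Transition/transversion probability ratio and reversibility deviation.

    The unbiased reference for the ti/tv ratio is 0.5 (eight transversion
    cells against four transition cells).  Dev_rev sums |p_xy - p_yx| over the
    six unordered nucleotide pairs.
    """
    ti = tv = 0.0
    for x, y in BETA_ORDER:
        p = P.probs[_IDX[x], _IDX[y]]
        if is_transition(x, y):
            ti += p
        else:
            tv += p
    if tv == 0:
        raise ValueError("transversion mass is zero; ti/tv undefined")
    dev = 0.0
    for i in range(4):
        for j in range(i + 1, 4):
            dev += abs(P.probs[i, j] - P.probs[j, i])
    return MatrixSummary(ti / tv, dev)


def read_matrix_tsv(path) -> NucleotideTransitionMatrix:
    """Read a 4x4 transition matrix TSV (header row/column of labels).

    Rows are renormalized to sum to exactly one (printed matrices carry
    rounding error) and the stationary distribution is recomputed.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    M = df.loc[list(NUCLEOTIDES), list(NUCLEOTIDES)].to_numpy(dtype=float)
    M = M / M.sum(axis=1, keepdims=True)
    pi = NucleotideDistribution(tuple(stationary(M)))
    q = 4.0 - np.trace(M)  # off-diagonal mass; informational only
    return NucleotideTransitionMatrix(M, q, pi)


def write_matrix_tsv(path, M: np.ndarray, labels) -> None:
    import pandas as pd

    pd.DataFrame(M, index=list(labels), columns=list(labels)).to_csv(
        path, sep="\t", float_format="%.6f"
    )
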