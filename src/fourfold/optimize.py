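"""Evolutionary-strategy search over feasible mutation matrices.

For a fixed nucleotide stationary distribution pi the feasible rate vectors
form the positive part of a 9-dimensional subspace; different points of it
give different post-selection codon distributions and hence different
deviations F_pi.  The optimizer searches this space with a generational ES:
Gaussian perturbation of the 9 null-space coefficients, BLX-style linear
crossover (offspring = alpha p1 + (1-alpha) p2), binary tournament
survival, and one elite carried over, maximizing (or minimizing) F_pi.
Infeasible offspring (any non-positive rate) are retried and finally fall
back to the parent, so fitness is only ever evaluated on feasible matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .deviation import _families, total_deviation
from .grid import NUCLEOTIDES, NucleotideDistribution
from .mutation import (
    BETA_ORDER,
    CODONS_61,
    CODONS_64,
    GENETIC_CODE,
    STOP_CODONS,
    NucleotideTransitionMatrix,
    RateCoefficients,
    build_rate_matrix,
    codon_matrix,
    constraint_matrix,
    nullspace_basis,
    sample_coefficients,
    uniformize,
)
from .selection import AcceptanceMatrix, _acceptance_for

_IDX = {n: i for i, n in enumerate(NUCLEOTIDES)}


@dataclass
class ESConfig:
    population_size: int = 100
    sigma: float = 0.05
    generations: int = 1000
    tournament_size: int = 2
    crossover_rate: float = 0.7
    crossover_alpha: tuple[float, float] = (-0.25, 1.25)
    elitism: int = 1
    stall_generations: int = 200
    sigma_decay: float = 0.95
    decay_every: int = 50
    improvement_tol: float = 1e-6
    feasibility_retries: int = 50
    seed: int = 0
    direction: str = "maximize"
    family_set: str = "canonical5"

    def __post_init__(self) -> None:
        if self.population_size < 2 or self.tournament_size < 2:
            raise ValueError("population_size and tournament_size must be >= 2")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.direction not in ("maximize", "minimize"):
            raise ValueError("direction must be 'maximize' or 'minimize'")


@dataclass
class OptimizationResult:
    best_coeffs: RateCoefficients
    best_matrix: NucleotideTransitionMatrix
    best_value: float
    history: list[float]
    evaluations: int
    config: ESConfig


class Evaluator:
    """Precompiled F_pi evaluation for one (pi, acceptance, family set).

    Precomputes the sparse link structure of the codon chain (which cell of
    the nucleotide matrix feeds each codon pair, damped by which acceptance)
    so each evaluation is a vectorized fill plus one dense linear solve.
    Produces the same numbers as the step-by-step module chain; the agreement
    is asserted in the test suite.
    """

    def __init__(
        self,
        pi: NucleotideDistribution,
        D: AcceptanceMatrix,
        family_set: str = "canonical5",
    ):
        self.pi = pi
        self.D = D
        self.family_set = family_set
        self.states = CODONS_61 if D.stop_policy == "SL" else CODONS_64
        pos_of = {c: i for i, c in enumerate(self.states)}
        I, J, X, Y, A = [], [], [], [], []
        for i, ci in enumerate(self.states):
            for pos in range(3):
                for y in NUCLEOTIDES:
                    if y == ci[pos]:
                        continue
                    cj = ci[:pos] + y + ci[pos + 1 :]
                    j = pos_of.get(cj)
                    if j is None:
                        continue
                    I.append(i)
                    J.append(j)
                    X.append(_IDX[ci[pos]])
                    Y.append(_IDX[y])
                    A.append(_acceptance_for(ci, cj, D))
        self._I = np.array(I)
        self._J = np.array(J)
        self._X = np.array(X)
        self._Y = np.array(Y)
        self._A = np.array(A)
        self._fam_idx = {
            name: [pos_of[prefix + n] for n in NUCLEOTIDES]
            for name, prefix in _families(family_set).items()
        }
        self._p = pi.as_array()
        self.evaluations = 0

    def value_from_beta(self, beta: np.ndarray) -> float:
        Q = np.zeros((4, 4))
        for (x, y), b in zip(BETA_ORDER, beta):
            Q[_IDX[x], _IDX[y]] = b
        np.fill_diagonal(Q, -Q.sum(axis=1))
        q = np.abs(np.diag(Q)).sum()
        P = Q / q + np.eye(4)
        n = len(self.states)
        C = np.zeros((n, n))
        C[self._I, self._J] = P[self._X, self._Y] / 3.0 * self._A
        np.fill_diagonal(C, 0.0)
        np.fill_diagonal(C, 1.0 - C.sum(axis=1))
        # stationary vector via the bordered linear system (I - C^T with the
        # last balance equation replaced by normalization); much faster than
        # an eigen-solve and equivalent for an irreducible chain
        A = np.eye(n) - C.T
        A[-1, :] = 1.0
        b = np.zeros(n)
        b[-1] = 1.0
        pi_sel = np.linalg.solve(A, b)
        pi_sel = np.abs(pi_sel) / np.abs(pi_sel).sum()
        self.evaluations += 1
        total = 0.0
        for ids in self._fam_idx.values():
            mass = pi_sel[ids]
            rel = mass / mass.sum()
            total += float(np.sum(np.abs(self._p - rel) / self._p))
        return total

    def __call__(self, coeffs: RateCoefficients) -> float:
        return self.value_from_beta(coeffs.beta)


def evaluate(
    coeffs: RateCoefficients,
    D: AcceptanceMatrix,
    family_set: str = "canonical5",
) -> float:
    """F_pi for one rate vector, via the explicit module chain.

    Runs Q -> P -> P* -> C -> pi_sel -> F.  Slower than :class:`Evaluator`
    but built from the individually tested pieces; used for spot checks and
    as the optimizer's cross-validation oracle.
    """
    from .selection import combine

    Q = build_rate_matrix(coeffs)
    P = uniformize(Q)
    space = "61-sense" if D.stop_policy == "SL" else "64-all"
    P_star = codon_matrix(P, space)
    C = combine(P_star, D)
    res = total_deviation(
        coeffs.pi, C.pi_sel, C.state_labels, D.stop_policy, family_set
    )
    return res.total


def mutate(
    individual: RateCoefficients,
    sigma: float,
    rng: np.random.Generator,
    retries: int = 50,
) -> RateCoefficients:
    """Gaussian perturbation of the null-space coefficients.

    Adds i.i.d. N(0, sigma) noise to the 9 coefficients and renormalizes;
    infeasible proposals (any non-positive rate) are retried and, past the
    retry cap, the parent is returned unchanged.
    """
    basis = individual.basis
    for _ in range(retries):
        coeffs = individual.basis_coeffs + rng.normal(0.0, sigma, size=9)
        beta = basis @ coeffs
        if np.all(beta > 0):
            norm = np.linalg.norm(beta)
            return RateCoefficients(beta / norm, coeffs / norm, basis, individual.pi)
    return individual


def crossover(
    parent1: RateCoefficients,
    parent2: RateCoefficients,
    rng: np.random.Generator,
    alpha_range: tuple[float, float] = (-0.25, 1.25),
    retries: int = 50,
) -> RateCoefficients:
    """Linear (BLX/LBGA-style) crossover in coefficient space.

    The offspring is alpha p1 + (1 - alpha) p2 with alpha uniform on
    ``alpha_range``; infeasible draws are retried, falling back to parent1.
    """
    if parent1.basis is not parent2.basis and not np.array_equal(
        parent1.basis, parent2.basis
    ):
        raise ValueError("parents must share the same null-space basis")
    basis = parent1.basis
    for _ in range(retries):
        alpha = rng.uniform(*alpha_range)
        coeffs = alpha * parent1.basis_coeffs + (1 - alpha) * parent2.basis_coeffs
        beta = basis @ coeffs
        if np.all(beta > 0):
            norm = np.linalg.norm(beta)
            return RateCoefficients(beta / norm, coeffs / norm, basis, parent1.pi)
    return parent1


def optimize(
    pi: NucleotideDistribution,
    D: AcceptanceMatrix,
    config: ESConfig,
) -> OptimizationResult:
    """Generational ES over feasible rate matrices at fixed pi.

    Stops at ``generations`` or once ``stall_generations`` pass without an
    improvement larger than ``improvement_tol``; sigma decays multiplicatively
    every ``decay_every`` stalled generations.  Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    V = constraint_matrix(pi)
    basis = nullspace_basis(V)
    ev = Evaluator(pi, D, config.family_set)
    sign = 1.0 if config.direction == "maximize" else -1.0

    pop = [
        sample_coefficients(basis, pi, rng) for _ in range(config.population_size)
    ]
    fit = np.array([sign * ev(ind) for ind in pop])

    best_i = int(np.argmax(fit))
    best, best_fit = pop[best_i], fit[best_i]
    history = [sign * best_fit]
    sigma = config.sigma
    stalled = 0

    for _ in range(config.generations):
        order = np.argsort(fit)[::-1]
        elite = [pop[i] for i in order[: config.elitism]]
        children = list(elite)
        while len(children) < config.population_size:
            contenders = rng.integers(0, len(pop), size=config.tournament_size)
            p1 = pop[max(contenders, key=lambda i: fit[i])]
            if rng.random() < config.crossover_rate:
                contenders = rng.integers(0, len(pop), size=config.tournament_size)
                p2 = pop[max(contenders, key=lambda i: fit[i])]
                child = crossover(p1, p2, rng, config.crossover_alpha)
            else:
                child = p1
            children.append(mutate(child, sigma, rng, config.feasibility_retries))
        pop = children
        fit = np.array([sign * ev(ind) for ind in pop])
        gen_best = int(np.argmax(fit))
        if fit[gen_best] > best_fit + config.improvement_tol:
            best, best_fit = pop[gen_best], fit[gen_best]
            stalled = 0
        else:
            stalled += 1
            if stalled % config.decay_every == 0:
                sigma *= config.sigma_decay
        history.append(sign * best_fit)
        if stalled >= config.stall_generations:
            break

    Q = build_rate_matrix(best)
    return OptimizationResult(
        best_coeffs=best,
        best_matrix=uniformize(Q),
        best_value=float(sign * best_fit),
        history=history,
        evaluations=ev.evaluations,
        config=config,
    )


def optimize_multi_seed(
    pi: NucleotideDistribution,
    D: AcceptanceMatrix,
    config: ESConfig,
    seeds: list[int],
) -> OptimizationResult:
    """Best result over independent seeded runs (keeps the extreme one)."""
    results = [optimize(pi, D, replace(config, seed=s)) for s in seeds]
    key = (max if config.direction == "maximize" else min)
    return key(results, key=lambda r: r.best_value)
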