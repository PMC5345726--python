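"""Canned experiments at configurable scale.

Each function recomputes one headline quantity of the study from scratch:
the genetic-code census calibration, the deterministic reference-matrix
chain, single-distribution ES optima, the random-matrix baseline, trend and
concordance summaries, and the sequence-level consistency checks.  The
analysis drivers, the acceptance harness and the test suite all call these,
so the numbers they report come from one code path.
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from . import pipeline
from .deviation import alt_divergences, measure_concordance, total_deviation
from .grid import NucleotideDistribution, enumerate_grid
from .mutation import (
    build_rate_matrix,
    codon_matrix,
    constraint_matrix,
    nullspace_basis,
    read_matrix_tsv,
    sample_coefficients,
    uniformize,
)
from .optimize import ESConfig, Evaluator, optimize
from .selection import acceptance_class_means, acceptance_matrix, combine, mutation_census
from .sequences import codon_usage, sequence_deviation, skew_segments
from .simulate import (
    SyntheticSpec,
    codon_distribution_from_pi,
    codon_distribution_from_vector,
    sample_cds,
    synthetic_genome,
)

#: Stationary distributions at which published extreme optima are quoted.
PI_MAX_SM = (0.19, 0.69, 0.05, 0.07)
PI_EQUAL_COMPLEMENTARY = (0.41, 0.41, 0.09, 0.09)
PI_MIN_SM = (0.05, 0.08, 0.22, 0.65)


def reference_matrix():
    path = resources.files("fourfold.data") / "max_deviation_matrix.tsv"
    with resources.as_file(path) as p:
        return read_matrix_tsv(p)


def census_class_means() -> dict[str, float]:
    """Mean acceptance of the default (linear Grantham) matrix over the
    transition and transversion cases of the fourfold census."""
    D = acceptance_matrix("SM")
    return acceptance_class_means(D, mutation_census())


def reference_chain_deviation(variant: str = "SM", family_set: str = "canonical5"):
    """Full pipeline on the packaged maximum-deviation matrix."""
    P = reference_matrix()
    D = acceptance_matrix(variant)
    space = "61-sense" if variant == "SL" else "64-all"
    C = combine(codon_matrix(P, space), D)
    return total_deviation(P.pi, C.pi_sel, C.state_labels, variant, family_set)


def optimize_at(
    freqs,
    seeds,
    variant: str = "SM",
    generations: int = 1000,
    population: int = 100,
    direction: str = "maximize",
) -> float:
    """Best F over independent ES runs at one stationary distribution."""
    pi = NucleotideDistribution(tuple(freqs))
    D = acceptance_matrix(variant)
    values = []
    for seed in seeds:
        config = ESConfig(
            population_size=population,
            generations=generations,
            seed=int(seed) % (2**31),
            direction=direction,
        )
        values.append(optimize(pi, D, config).best_value)
    return max(values) if direction == "maximize" else min(values)


def random_baseline_mean(
    n: int = 200, master_seed: int = 0, variant: str = "SM"
) -> tuple[float, int]:
    """Mean F of one random feasible matrix per grid distribution.

    Distributions are a uniform random subsample of the full lattice,
    matrices are sampled with per-index derived seeds; returns (mean, n).
    """
    grid = enumerate_grid()
    rng = np.random.default_rng(master_seed)
    picks = rng.choice(len(grid), size=n, replace=False)
    pis = [grid[int(i)].freqs for i in picks]
    frame = pipeline.random_baseline(pis, variant=variant, master_seed=master_seed)
    return float(frame["F_total"].mean()), n


def at_content_profile(
    master_seed: int = 0,
    generations: int = 250,
    population: int = 40,
    at_values=None,
) -> list[tuple[float, float]]:
    """F_max along the equal-complementary diagonal (pi_A = pi_T,
    pi_G = pi_C) as a function of A+T content."""
    if at_values is None:
        at_values = [0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8]
    D = acceptance_matrix("SM")
    out = []
    for k, at in enumerate(at_values):
        a = at / 2
        g = (1 - at) / 2
        pi = NucleotideDistribution((a, a, g, g))
        config = ESConfig(
            population_size=population,
            generations=generations,
            seed=pipeline.worker_seed(master_seed, k),
        )
        out.append((at, optimize(pi, D, config).best_value))
    return out


def comparator_concordance(
    n_models: int = 200, master_seed: int = 0
) -> dict[str, float]:
    """Spearman correlation of F with KL and total-variation comparators
    over random mutation-selection models."""
    D = acceptance_matrix("SM")
    rng = np.random.default_rng(master_seed)
    f_vals, kl_vals, tv_vals = [], [], []
    while len(f_vals) < n_models:
        freqs = rng.dirichlet(np.ones(4)) * 0.8 + 0.05
        pi = NucleotideDistribution(tuple(freqs / freqs.sum()))
        basis = nullspace_basis(constraint_matrix(pi))
        coeffs = sample_coefficients(basis, pi, rng)
        P = uniformize(build_rate_matrix(coeffs))
        C = combine(codon_matrix(P), D)
        dev = total_deviation(pi, C.pi_sel, C.state_labels)
        div = alt_divergences(pi, C.pi_sel, C.state_labels)
        f_vals.append(dev.total)
        kl_vals.append(div["kl"])
        tv_vals.append(div["tv"])
    return {
        "spearman_kl": measure_concordance(f_vals, kl_vals),
        "spearman_tv": measure_concordance(f_vals, tv_vals),
        "n": n_models,
    }


def sequence_consistency(master_seed: int = 0) -> dict[str, float]:
    """F-hat from ~1e5 synthetic codons against the analytic statistic.

    Uses a deliberately asymmetric model (best of 300 random draws at a
    moderate pi) so the true deviation dominates counting noise; the
    Monte-Carlo standard error comes from multinomial bootstrap.
    """
    rng = np.random.default_rng(master_seed)
    pi = NucleotideDistribution((0.3, 0.3, 0.2, 0.2))
    D = acceptance_matrix("SM")
    basis = nullspace_basis(constraint_matrix(pi))
    ev = Evaluator(pi, D)
    best, best_v = None, -1.0
    for _ in range(300):
        c = sample_coefficients(basis, pi, rng)
        v = ev(c)
        if v > best_v:
            best_v, best = v, c
    P = uniformize(build_rate_matrix(best))
    C = combine(codon_matrix(P), D)
    dist = codon_distribution_from_vector(C.pi_sel, C.state_labels)
    spec = SyntheticSpec(
        codon_distribution=dist, n_genes=300, gene_length_codons=(300, 400)
    )
    table = codon_usage(sample_cds(spec, rng))
    _, f_hat = sequence_deviation(table)

    fams = {"Gly": "GG", "Val": "GT", "Thr": "AC", "Ala": "GC", "Pro": "CC"}
    idx = {c: i for i, c in enumerate(C.state_labels)}
    rel = {
        name: np.array([C.pi_sel[idx[p + n]] for n in "ATGC"])
        for name, p in fams.items()
    }
    rel = {k: v / v.sum() for k, v in rel.items()}
    e = np.mean(list(rel.values()), axis=0)
    analytic = float(sum(np.sum(np.abs(e - r) / e) for r in rel.values()))

    # multinomial bootstrap of the codon counts
    codons = sorted(table.counts)
    n_codons = sum(table.counts.values())
    p = np.array([table.counts[c] for c in codons], dtype=float) / n_codons
    reps = []
    for _ in range(30):
        draw = dict(zip(codons, rng.multinomial(n_codons, p).tolist()))
        rels = []
        for prefix in fams.values():
            fam = np.array([draw.get(prefix + n, 0) for n in "ATGC"], dtype=float)
            rels.append(fam / fam.sum())
        e_b = np.mean(rels, axis=0)
        reps.append(float(sum(np.sum(np.abs(e_b - r) / e_b) for r in rels)))
    return {
        "f_hat": f_hat,
        "analytic": analytic,
        "mc_se": float(np.std(reps)),
        "n_codons": n_codons,
    }


def boundary_recovery(master_seed: int = 0) -> dict[str, float]:
    """Strand-boundary recovery error on a known-truth toy genome."""
    lead = codon_distribution_from_pi(NucleotideDistribution((0.2, 0.3, 0.35, 0.15)))
    spec = SyntheticSpec(
        codon_distribution=lead,
        n_genes=60,
        gene_length_codons=(150, 250),
        strand_bias=(lead, lead),
    )
    genome, genes, meta = synthetic_genome(spec, np.random.default_rng(master_seed))
    seg = skew_segments(genome, genes)
    n = meta["length"]

    def circ(a, b):
        return min(abs(a - b), n - abs(a - b))

    found = [b % n for b in seg.boundaries]
    true = [b % n for b in meta["true_boundaries"]]
    direct = max(circ(found[0], true[0]), circ(found[1], true[1]))
    crossed = max(circ(found[0], true[1]), circ(found[1], true[0]))
    return {
        "relative_error": min(direct, crossed) / n,
        "reliable": bool(seg.reliable),
        "genome_length": n,
    }
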