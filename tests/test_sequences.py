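"""Sequence-level statistics: codon usage, deviation, skew segmentation."""

import numpy as np
import pandas as pd
import pytest

import fourfold as ff
from fourfold.grid import NucleotideDistribution
from fourfold.sequences import (
    codon_usage,
    gene_set_difference,
    sequence_deviation,
    skew_segments,
)
from fourfold.simulate import (
    SyntheticSpec,
    codon_distribution_from_pi,
    extract_cds,
    sample_cds,
    synthetic_genome,
)


def bootstrap_se(table, rng, replicates=30):
    """Monte-Carlo standard error of the F statistic by multinomial
    resampling of the observed codon counts."""
    import copy

    codons = sorted(table.counts)
    n = sum(table.counts.values())
    p = np.array([table.counts[c] for c in codons], dtype=float) / n
    values = []
    for _ in range(replicates):
        draw = rng.multinomial(n, p)
        t = copy.copy(table)
        t.counts = dict(zip(codons, draw.tolist()))
        t.family_totals = {
            name: int(sum(t.counts.get(prefix + x, 0) for x in "ATGC"))
            for name, prefix in
            {"Gly": "GG", "Val": "GT", "Thr": "AC", "Ala": "GC", "Pro": "CC"}.items()
        }
        rels = []
        for prefix in ("GG", "GT", "AC", "GC", "CC"):
            fam = np.array([t.counts.get(prefix + x, 0) for x in "ATGC"], dtype=float)
            rels.append(fam / fam.sum())
        t.expected = np.mean(rels, axis=0)
        _, f = sequence_deviation(t)
        values.append(f)
    return float(np.std(values))


class TestCodonUsage:
    def test_hand_counted_gene(self):
        """ATG GGA GGA GGC TAA: Gly counts A:2, C:1, G:0, T:0; the terminal
        stop is dropped."""
        table = codon_usage(["ATGGGAGGAGGCTAA"])
        assert table.counts.get("GGA") == 2
        assert table.counts.get("GGC") == 1
        assert table.family_totals["Gly"] == 3
        assert "TAA" not in table.counts
        assert table.n_genes == 1

    def test_uniform_families_give_uniform_expectation(self):
        seq = "".join(p + n for p in ("GG", "GT", "AC", "GC", "CC") for n in "ATGC")
        table = codon_usage([seq])
        assert np.allclose(table.expected, 0.25)
        per, total = sequence_deviation(table)
        assert total == pytest.approx(0.0, abs=1e-12)

    def test_filters_and_report(self):
        records = [
            "ATGGGATAA",      # ok
            "ATGGGA",         # ok (no stop)
            "ATGGG",          # bad length
            "ATGNNGTAA",      # bad characters
            "ATGTAAGGGTAA",   # internal stop
        ]
        table = codon_usage(records)
        r = table.filter_report
        assert (r.kept, r.bad_length, r.bad_characters, r.internal_stop) == (2, 1, 1, 1)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError, match="no records"):
            codon_usage(["ATGG"])

    def test_sampled_counts_match_distribution(self):
        """Codon frequencies of sampled CDS converge to the generating
        distribution (chi-square goodness of fit not rejected)."""
        from scipy.stats import chisquare

        rng = np.random.default_rng(11)
        pi = NucleotideDistribution((0.3, 0.3, 0.2, 0.2))
        dist = codon_distribution_from_pi(pi)
        spec = SyntheticSpec(codon_distribution=dist, n_genes=120,
                             gene_length_codons=(150, 350))
        records = sample_cds(spec, rng)
        table = codon_usage(records)
        total = sum(table.counts.values())
        assert total > 1e5 * 0.2
        codons = sorted(dist)
        # drop the fixed start/stop contribution: interior codons dominate,
        # compare only interior-codon expectation by removing one ATG per gene
        observed = np.array([table.counts.get(c, 0) for c in codons], dtype=float)
        observed[codons.index("ATG")] -= table.n_genes
        expected = np.array([dist[c] for c in codons]) * observed.sum()
        _, p = chisquare(observed, expected * observed.sum() / expected.sum())
        assert p > 0.001


class TestSequenceDeviation:
    def test_hand_example(self):
        """Uniform expectation, one family at (0.4, 0.2, 0.2, 0.2): F = 1.2."""
        genes = []
        for prefix in ("GT", "AC", "GC", "CC"):
            genes.append("".join(prefix + n for n in "ATGC") * 5)
        genes.append("GGA" * 8 + "GGT" * 4 + "GGG" * 4 + "GGC" * 4)
        table = codon_usage(genes)
        assert np.allclose(table.expected, [0.28, 0.24, 0.24, 0.24])
        per, total = sequence_deviation(table)
        oracle = 0.0
        for fam, prefix in (
            ("Gly", (0.4, 0.2, 0.2, 0.2)),
            ("Val", (0.25,) * 4),
            ("Thr", (0.25,) * 4),
            ("Ala", (0.25,) * 4),
            ("Pro", (0.25,) * 4),
        ):
            oracle_f = sum(
                abs(e - o) / e for e, o in zip(table.expected, prefix)
            )
            assert per[fam] == pytest.approx(oracle_f)

    def test_estimator_consistency(self, acceptance_sm):
        """F-hat from ~1e5 synthetic codons sampled from a model's pi_sel
        matches the analytic statistic within three Monte-Carlo standard
        errors (bootstrap over codon counts)."""
        from fourfold.optimize import Evaluator
        from fourfold.simulate import codon_distribution_from_vector

        rng = np.random.default_rng(7)
        pi = NucleotideDistribution((0.3, 0.3, 0.2, 0.2))
        B = ff.nullspace_basis(ff.constraint_matrix(pi))
        # a deliberately asymmetric model (best of random draws) so the true
        # deviation dominates the counting noise
        ev = Evaluator(pi, acceptance_sm)
        best, best_v = None, -1.0
        for _ in range(300):
            c = ff.sample_coefficients(B, pi, rng)
            v = ev(c)
            if v > best_v:
                best_v, best = v, c
        P = ff.uniformize(ff.build_rate_matrix(best))
        C = ff.combine(ff.codon_matrix(P), acceptance_sm)
        dist = codon_distribution_from_vector(C.pi_sel, C.state_labels)
        spec = SyntheticSpec(codon_distribution=dist, n_genes=300,
                             gene_length_codons=(300, 400))
        records = sample_cds(spec, rng)
        table = codon_usage(records)
        _, f_hat = sequence_deviation(table)

        # analytic value under the same convention: expectations are the
        # family-averaged relative usage of pi_sel itself
        fams = {"Gly": "GG", "Val": "GT", "Thr": "AC", "Ala": "GC", "Pro": "CC"}
        idx = {c: i for i, c in enumerate(C.state_labels)}
        rel = {
            name: np.array([C.pi_sel[idx[p + n]] for n in "ATGC"])
            for name, p in fams.items()
        }
        rel = {k: v / v.sum() for k, v in rel.items()}
        e = np.mean(list(rel.values()), axis=0)
        analytic = float(sum(np.sum(np.abs(e - r) / e) for r in rel.values()))

        se = bootstrap_se(table, rng)
        assert abs(f_hat - analytic) < 3 * se


class TestGeneSetDifference:
    def test_identical_tables_give_zero(self):
        seq = "".join(p + n for p in ("GG", "GT", "AC", "GC", "CC") for n in "ATGC")
        t1 = codon_usage([seq])
        t2 = codon_usage([seq * 2])
        assert gene_set_difference(t1, t2) == pytest.approx(0.0)

    def test_disjoint_family_usage_contributes_two(self):
        base = "".join(p + n for p in ("GT", "AC", "GC", "CC") for n in "ATGC")
        t1 = codon_usage([base + "GGA" * 4])
        t2 = codon_usage([base + "GGT" * 4])
        assert gene_set_difference(t1, t2) == pytest.approx(2.0)

    def test_sampled_sets_approach_analytic_difference(self):
        rng = np.random.default_rng(77)
        pi1 = NucleotideDistribution((0.4, 0.3, 0.15, 0.15))
        pi2 = NucleotideDistribution((0.15, 0.15, 0.3, 0.4))
        tables = []
        for pi in (pi1, pi2):
            dist = codon_distribution_from_pi(pi)
            spec = SyntheticSpec(codon_distribution=dist, n_genes=150,
                                 gene_length_codons=(200, 300))
            tables.append(codon_usage(sample_cds(spec, rng)))
        observed = gene_set_difference(tables[0], tables[1])
        # per family the relative third-position usage is the conditional
        # product measure of each pi, identical across families
        p1, p2 = pi1.as_array(), pi2.as_array()
        analytic = 5 * np.abs(p1 - p2).sum()
        assert observed == pytest.approx(analytic, abs=0.15)


@pytest.fixture(scope="module")
def toy_genome():
    # both arcs carry leading-type (GT-rich) gene composition; arc-2
    # genes sit on the reverse strand, so the forward-strand skew flips
    lead = codon_distribution_from_pi(NucleotideDistribution((0.2, 0.3, 0.35, 0.15)))
    spec = SyntheticSpec(
        codon_distribution=lead,
        n_genes=60,
        gene_length_codons=(150, 250),
        strand_bias=(lead, lead),
    )
    rng = np.random.default_rng(99)
    return synthetic_genome(spec, rng)


class TestSkewSegments:

    def test_boundaries_recovered_within_one_percent(self, toy_genome):
        genome, genes, meta = toy_genome
        seg = skew_segments(genome, genes)
        assert seg.reliable
        n = meta["length"]
        found = [b % n for b in seg.boundaries]
        true = [b % n for b in meta["true_boundaries"]]

        def circ(a, b):
            return min(abs(a - b), n - abs(a - b))

        # boundaries are a circular, unordered pair; match the closer way
        direct = max(circ(found[0], true[0]), circ(found[1], true[1]))
        crossed = max(circ(found[0], true[1]), circ(found[1], true[0]))
        assert min(direct, crossed) < 0.01 * n

    def test_strand_assignment_matches_arcs(self, toy_genome):
        genome, genes, meta = toy_genome
        seg = skew_segments(genome, genes)
        # all genes were placed in leading orientation on both arcs
        frac_leading = (seg.assignment["replichore"] == "leading").mean()
        assert frac_leading > 0.95

    def test_strand_flip_flips_assignment(self, toy_genome):
        genome, genes, _ = toy_genome
        flipped = genes.copy()
        flipped["strand"] = flipped["strand"].map({"+": "-", "-": "+"})
        a = skew_segments(genome, genes).assignment["replichore"]
        b = skew_segments(genome, flipped).assignment["replichore"]
        assert (a != b).all()

    def test_iid_genome_flagged_unreliable(self):
        rng = np.random.default_rng(1234)
        genome = "".join(rng.choice(list("ACGT"), size=60_000))
        genes = pd.DataFrame(
            [{"gene_id": "g0", "start": 0, "end": 300, "strand": "+"}]
        )
        seg = skew_segments(genome, genes)
        assert not seg.reliable
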