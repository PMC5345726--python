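"""Synthetic coding sequences and toy two-replichore genomes.

Every sequence-level statistic in this package is a function of codon counts,
so the generator draws interior codons i.i.d. from a specified sense-codon
distribution (no autocorrelation, no indels, no intergenic realism).  Genes
are start codon + interior codons + stop codon, with lengths uniform over a
configured range.  The toy genome concatenates genes into two arcs with
different codon distributions and opposite strands, recording the true arc
boundaries so strand-segmentation can be tested against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .grid import NucleotideDistribution
from .mutation import CODONS_61, STOP_CODONS


@dataclass
class SyntheticSpec:
    codon_distribution: dict[str, float]
    n_genes: int = 100
    gene_length_codons: tuple[int, int] = (100, 400)
    start_codon: str = "ATG"
    stop_codon: str = "TAA"
    strand_bias: tuple[dict[str, float], dict[str, float]] | None = None

    def __post_init__(self) -> None:
        self._validate(self.codon_distribution)
        if self.strand_bias is not None:
            for dist in self.strand_bias:
                self._validate(dist)
        lo, hi = self.gene_length_codons
        if not (0 < lo <= hi):
            raise ValueError("gene length range must be positive and ordered")

    @staticmethod
    def _validate(dist: dict[str, float]) -> None:
        total = sum(dist.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"codon distribution sums to {total}, not 1")
        for stop in STOP_CODONS:
            if dist.get(stop, 0.0) > 0:
                raise ValueError("stop codons may not have interior probability")


def codon_distribution_from_pi(pi: NucleotideDistribution) -> dict[str, float]:
    """Product-measure codon distribution on the 61 sense codons.

    The natural 'mutation-only' synthetic input: codon probabilities
    proportional to pi_a pi_b pi_c, renormalized without stops.
    """
    p = pi.as_array()
    idx = {"A": 0, "T": 1, "G": 2, "C": 3}
    w = {c: p[idx[c[0]]] * p[idx[c[1]]] * p[idx[c[2]]] for c in CODONS_61}
    total = sum(w.values())
    return {c: v / total for c, v in w.items()}


def codon_distribution_from_vector(
    pi_codon: np.ndarray, states
) -> dict[str, float]:
    """Sense-codon distribution from a stationary codon vector (stops, if
    present in `states`, are dropped and the rest renormalized)."""
    dist = {
        c: float(v) for c, v in zip(states, pi_codon) if c not in STOP_CODONS
    }
    total = sum(dist.values())
    return {c: v / total for c, v in dist.items()}


def _draw_codons(
    dist: dict[str, float], k: int, rng: np.random.Generator
) -> list[str]:
    codons = list(dist)
    probs = np.array([dist[c] for c in codons])
    return [codons[i] for i in rng.choice(len(codons), size=k, p=probs)]


def sample_cds(
    spec: SyntheticSpec, rng: np.random.Generator, id_prefix: str = "gene"
) -> list[SeqRecord]:
    """Sample ``n_genes`` coding sequences from the spec's distribution."""
    lo, hi = spec.gene_length_codons
    records = []
    for g in range(spec.n_genes):
        k = int(rng.integers(lo, hi + 1))
        interior = _draw_codons(spec.codon_distribution, k, rng)
        seq = spec.start_codon + "".join(interior) + spec.stop_codon
        records.append(
            SeqRecord(Seq(seq), id=f"{id_prefix}{g:05d}", description="")
        )
    return records


def synthetic_genome(
    spec: SyntheticSpec, rng: np.random.Generator
) -> tuple[str, pd.DataFrame, dict]:
    """A circular toy genome with two replichore-like arcs.

    ``strand_bias = (arc1_dist, arc2_dist)`` gives the codon usage of the
    genes on each arc.  Arc-1 genes sit on the forward strand, arc-2 genes on
    the reverse strand (their reverse complement is what appears in the
    forward genome).  Feeding both arcs the same GT-rich usage emulates a
    bacterial chromosome whose leading strand flips at the replication
    boundaries: the forward-strand composition is then GT-rich on arc 1 and
    AC-rich on arc 2, which is exactly what cumulative skew walks detect.
    True boundaries are returned in the metadata for oracle tests.
    """
    if spec.strand_bias is None:
        raise ValueError("synthetic_genome requires strand_bias distributions")
    lead_dist, lag_dist = spec.strand_bias
    half = spec.n_genes // 2
    lo, hi = spec.gene_length_codons

    pieces: list[str] = []
    rows = []
    pos = 0
    for g in range(spec.n_genes):
        arc1 = g < half
        dist = lead_dist if arc1 else lag_dist
        k = int(rng.integers(lo, hi + 1))
        cds = spec.start_codon + "".join(_draw_codons(dist, k, rng)) + spec.stop_codon
        placed = cds if arc1 else str(Seq(cds).reverse_complement())
        pieces.append(placed)
        rows.append(
            {
                "gene_id": f"gene{g:05d}",
                "start": pos,
                "end": pos + len(cds),
                "strand": "+" if arc1 else "-",
                "arc": 1 if arc1 else 2,
            }
        )
        pos += len(cds)
        if g == half - 1:
            boundary = pos
    genome = "".join(pieces)
    meta = {
        "true_boundaries": (0, boundary),
        "length": len(genome),
        "n_genes": spec.n_genes,
    }
    return genome, pd.DataFrame(rows), meta


def extract_cds(genome: str, genes: pd.DataFrame) -> list[SeqRecord]:
    """Recover CDS records from a genome and its gene table."""
    records = []
    for _, g in genes.iterrows():
        segment = genome[int(g["start"]) : int(g["end"])]
        if str(g["strand"]) == "-":
            segment = str(Seq(segment).reverse_complement())
        records.append(SeqRecord(Seq(segment), id=str(g["gene_id"]), description=""))
    return records


def write_fasta(records, path) -> None:
    from Bio import SeqIO

    SeqIO.write(records, str(path), "fasta")
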