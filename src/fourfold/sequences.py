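"""Empirical fourfold-degenerate usage statistics on coding sequences.

The sequence-level analogue of the model deviation replaces stationary
distributions by codon counts: for each fourfold family s, f_s compares the
observed within-family relative frequencies o_{s_i}/o_s with an expectation
e_i estimated from the data itself, and F sums the family terms.  A second
statistic compares the fourfold usage of two gene sets directly.  The module
also places replication-strand boundaries on a circular genome from
cumulative [G-C] and [A-T] skew walks, the standard DNA-walk construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

from .deviation import _families
from .grid import NUCLEOTIDES
from .mutation import GENETIC_CODE, STOP_CODONS

_VALID = set("ACGT")


@dataclass
class FilterReport:
    kept: int = 0
    bad_length: int = 0
    bad_characters: int = 0
    internal_stop: int = 0

    @property
    def dropped(self) -> int:
        return self.bad_length + self.bad_characters + self.internal_stop


@dataclass
class CodonUsageTable:
    counts: dict[str, int]              # all codons, frame 0
    family_totals: dict[str, int]       # per family name
    expected: np.ndarray                # e_i over (A, T, G, C)
    n_genes: int
    source: str = ""
    family_set: str = "canonical5"
    filter_report: FilterReport = field(default_factory=FilterReport)


def _clean_cds(seq: str) -> tuple[str | None, str]:
    """Validate one CDS; returns (codon string or None, reason)."""
    s = seq.upper().replace("U", "T")
    if len(s) < 3 or len(s) % 3 != 0:
        return None, "bad_length"
    if not set(s) <= _VALID:
        return None, "bad_characters"
    codons = [s[i : i + 3] for i in range(0, len(s), 3)]
    if codons[-1] in STOP_CODONS:
        codons = codons[:-1]   # terminal stop is dropped, not counted
    if any(c in STOP_CODONS for c in codons):
        return None, "internal_stop"
    return "".join(codons), "ok"


def codon_usage(
    cds_records,
    source: str = "",
    family_set: str = "canonical5",
    pooled_expected: bool = False,
) -> CodonUsageTable:
    """Frame-0 codon counts and the fourfold expectation vector.

    ``cds_records`` is an iterable of sequences (strings, Seq objects or
    SeqRecords).  Records failing the filters (length not a positive multiple
    of three, non-ACGT characters, internal stop) are dropped and counted in
    the filter report.  The expectation e_i is the unweighted mean over the
    families of the within-family relative frequency of third-position
    nucleotide i; with ``pooled_expected`` the families are pooled by raw
    count instead.
    """
    counts: dict[str, int] = {}
    report = FilterReport()
    for rec in cds_records:
        seq = str(getattr(rec, "seq", rec))
        cleaned, reason = _clean_cds(seq)
        if cleaned is None:
            setattr(report, reason, getattr(report, reason) + 1)
            continue
        report.kept += 1
        for i in range(0, len(cleaned), 3):
            codon = cleaned[i : i + 3]
            counts[codon] = counts.get(codon, 0) + 1
    if report.kept == 0:
        raise ValueError(f"no records survived filtering ({source or 'input'})")

    fams = _families(family_set)
    family_totals = {}
    rel = np.zeros((len(fams), 4))
    pooled = np.zeros(4)
    for k, (name, prefix) in enumerate(fams.items()):
        fam_counts = np.array(
            [counts.get(prefix + n, 0) for n in NUCLEOTIDES], dtype=float
        )
        family_totals[name] = int(fam_counts.sum())
        pooled += fam_counts
        if fam_counts.sum() > 0:
            rel[k] = fam_counts / fam_counts.sum()
    nonzero = rel.sum(axis=1) > 0
    if pooled_expected:
        expected = pooled / pooled.sum() if pooled.sum() > 0 else pooled
    else:
        expected = rel[nonzero].mean(axis=0) if nonzero.any() else pooled
    return CodonUsageTable(
        counts, family_totals, expected, report.kept, source, family_set, report
    )


def sequence_deviation(table: CodonUsageTable) -> tuple[dict[str, float], float]:
    """Per-family f_s and total F from a codon usage table.

    f_s = sum_i |e_i - o_{s_i}/o_s| / e_i; requires every family total and
    every expectation component to be positive.
    """
    fams = _families(table.family_set)
    if np.any(table.expected <= 0):
        raise ValueError("expected frequencies must all be positive")
    per: dict[str, float] = {}
    for name, prefix in fams.items():
        total = table.family_totals[name]
        if total == 0:
            raise ValueError(f"family {name} has zero observed codons")
        obs = np.array(
            [table.counts.get(prefix + n, 0) for n in NUCLEOTIDES], dtype=float
        )
        rel = obs / total
        per[name] = float(np.sum(np.abs(table.expected - rel) / table.expected))
    return per, float(sum(per.values()))


def gene_set_difference(table1: CodonUsageTable, table2: CodonUsageTable) -> float:
    """Summed absolute difference in within-family relative fourfold usage.

    sum_s sum_i |r1_{s_i} - r2_{s_i}| with r the relative frequency within
    family s; the statistic used to compare, e.g., ribosomal against
    non-ribosomal gene sets or leading- against lagging-strand genes.
    """
    if table1.family_set != table2.family_set:
        raise ValueError("tables use different family sets")
    fams = _families(table1.family_set)
    diff = 0.0
    for name, prefix in fams.items():
        for table in (table1, table2):
            if table.family_totals[name] == 0:
                raise ValueError(f"family {name} has zero observed codons")
        r1 = np.array(
            [table1.counts.get(prefix + n, 0) for n in NUCLEOTIDES], dtype=float
        ) / table1.family_totals[name]
        r2 = np.array(
            [table2.counts.get(prefix + n, 0) for n in NUCLEOTIDES], dtype=float
        ) / table2.family_totals[name]
        diff += float(np.abs(r1 - r2).sum())
    return diff


@dataclass
class StrandSegments:
    boundaries: tuple[int, int]        # (origin-like, terminus-like) positions
    assignment: pd.DataFrame           # gene table plus a 'replichore' column
    reliable: bool
    amplitude: float                   # walk amplitude in noise units


def skew_segments(
    genome: str,
    genes: pd.DataFrame,
    noise_threshold: float = 6.0,
) -> StrandSegments:
    """Replication-strand segmentation from cumulative skew walks.

    Computes the combined cumulative [G-C] + [A-T] walk along the (circular)
    genome; the global minimum marks the origin-like boundary and the global
    maximum the terminus-like one.  A gene on the forward strand between
    origin and terminus is 'leading', on the reverse strand 'lagging', and
    vice versa on the other arc.  The result is flagged unreliable when the
    walk amplitude is below ``noise_threshold`` random-walk standard
    deviations (an i.i.d. genome has amplitude O(sqrt(N))).

    ``genes`` needs columns gene_id, start, end (0-based half-open) and
    strand (+/-).
    """
    s = genome.upper()
    n = len(s)
    if n == 0:
        raise ValueError("empty genome")
    arr = np.frombuffer(s.encode(), dtype="S1")
    gc = (arr == b"G").astype(int) - (arr == b"C").astype(int)
    at = (arr == b"A").astype(int) - (arr == b"T").astype(int)

    def detrended(steps):
        w = np.cumsum(steps, dtype=float)
        # remove the linear trend so the circular walk closes on itself
        return w - w[-1] * (np.arange(1, n + 1) / n)

    w_gc = detrended(gc)
    w_at = detrended(at)
    # the two skews need not share a sign convention (leading strands are
    # typically G-rich but T-rich); align the weaker walk with the stronger
    # before summing so they reinforce instead of cancelling
    if np.dot(w_gc, w_at) < 0:
        w_at = -w_at
    walk = w_gc + w_at
    ori = int(np.argmin(walk))
    ter = int(np.argmax(walk))
    amplitude = float(walk[ter] - walk[ori])
    # an i.i.d. genome gives a +/-1 step with prob ~1/2 each in each of the
    # two walks; the combined step variance is ~2 under uniform composition
    noise_units = amplitude / np.sqrt(2.0 * n)
    reliable = noise_units >= noise_threshold

    def on_first_arc(pos: int) -> bool:
        if ori <= ter:
            return ori <= pos < ter
        return pos >= ori or pos < ter

    rows = []
    for _, g in genes.iterrows():
        start, end = int(g["start"]), int(g["end"])
        if not (0 <= start < n):
            raise ValueError(f"gene {g['gene_id']} start outside genome")
        mid = ((start + end) // 2) % n
        forward = str(g["strand"]) == "+"
        leading = on_first_arc(mid) == forward
        rows.append({**g, "replichore": "leading" if leading else "lagging"})
    assignment = pd.DataFrame(rows)
    return StrandSegments((ori, ter), assignment, reliable, noise_units)


def read_fasta(path):
    return list(SeqIO.parse(str(path), "fasta"))


def read_gene_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "start", "end", "strand"}
    if not required <= set(df.columns):
        raise ValueError(f"gene table must have columns {sorted(required)}")
    return df
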