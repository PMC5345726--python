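"""End-to-end experiment drivers: grid sweeps and empirical reports.

A sweep optimizes F_pi independently for each nucleotide stationary
distribution in scope; per-distribution worker seeds are derived from the
master seed and the grid index through numpy's SeedSequence spawning, so
serial and resumed executions give identical tables.  Results are appended
incrementally and a re-run with the same output path resumes where it
stopped.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .deviation import total_deviation
from .grid import NucleotideDistribution
from .mutation import (
    codon_matrix,
    constraint_matrix,
    matrix_summary,
    nullspace_basis,
    sample_coefficients,
    build_rate_matrix,
    uniformize,
    write_matrix_tsv,
)
from .optimize import ESConfig, optimize
from .selection import acceptance_matrix, combine
from .sequences import (
    codon_usage,
    gene_set_difference,
    read_fasta,
    read_gene_table,
    sequence_deviation,
    skew_segments,
)


@dataclass
class RunConfig:
    pis: list[tuple[float, float, float, float]]
    variant: str = "SM"
    es: ESConfig = field(default_factory=ESConfig)
    master_seed: int = 0
    out_dir: str | None = None
    minimize_too: bool = False
    family_set: str = "canonical5"


def worker_seed(master_seed: int, index: int) -> int:
    """Deterministic per-distribution seed below 2**31."""
    ss = np.random.SeedSequence([master_seed, index])
    return int(ss.generate_state(1)[0] % (2**31))


def run_sweep(config: RunConfig) -> pd.DataFrame:
    """Optimize F_pi for every distribution in the config.

    Returns one row per (pi, direction) with the optimum, per-family values
    and matrix summaries.  With an output directory the table is appended
    row-by-row (resume-safe) and each best matrix is written as TSV.
    """
    D = acceptance_matrix(config.variant)
    out_dir = Path(config.out_dir) if config.out_dir else None
    table_path = out_dir / "sweep.tsv" if out_dir else None
    done = set()
    if table_path and table_path.exists():
        prev = pd.read_csv(table_path, sep="\t")
        done = set(zip(prev["index"], prev["direction"]))
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        D.accept.to_csv(out_dir / "acceptance_matrix.tsv", sep="\t")
        (out_dir / "config.json").write_text(
            json.dumps(
                {
                    "variant": config.variant,
                    "master_seed": config.master_seed,
                    "family_set": config.family_set,
                    "es": asdict(config.es),
                    "n_pis": len(config.pis),
                },
                indent=2,
                default=str,
            )
        )

    rows = []
    directions = ["maximize"] + (["minimize"] if config.minimize_too else [])
    for i, freqs in enumerate(config.pis):
        pi = NucleotideDistribution(tuple(freqs))
        for direction in directions:
            if (i, direction) in done:
                continue
            es = replace(
                config.es,
                seed=worker_seed(config.master_seed, 2 * i + (direction == "minimize")),
                direction=direction,
                family_set=config.family_set,
            )
            try:
                result = optimize(pi, D, es)
            except Exception as exc:  # pragma: no cover - defensive
                rows.append(
                    {"index": i, "direction": direction, "error": str(exc)}
                )
                continue
            summary = matrix_summary(result.best_matrix)
            space = "61-sense" if config.variant == "SL" else "64-all"
            P_star = codon_matrix(result.best_matrix, space)
            C = combine(P_star, D)
            dev = total_deviation(
                pi, C.pi_sel, C.state_labels, config.variant, config.family_set
            )
            row = {
                "index": i,
                "direction": direction,
                **{f"pi_{n}": v for n, v in zip("ATGC", freqs)},
                "variant": config.variant,
                "F_total": result.best_value,
                **{f"F_{name}": v for name, v in dev.per_family.items()},
                "titv_ratio": summary.titv_ratio,
                "dev_rev": summary.dev_rev,
                "generations": len(result.history) - 1,
                "evaluations": result.evaluations,
                "seed": es.seed,
            }
            rows.append(row)
            if out_dir:
                write_matrix_tsv(
                    out_dir / f"best_matrix_{i:05d}_{direction}.tsv",
                    result.best_matrix.probs,
                    "ATGC",
                )
                pd.DataFrame([row]).to_csv(
                    table_path,
                    sep="\t",
                    index=False,
                    mode="a",
                    header=not table_path.exists(),
                )
    frame = pd.DataFrame(rows)
    if table_path and table_path.exists():
        frame = pd.read_csv(table_path, sep="\t")
    return frame


def random_baseline(
    pis: list[tuple[float, float, float, float]],
    variant: str = "SM",
    master_seed: int = 0,
    family_set: str = "canonical5",
) -> pd.DataFrame:
    """F for one random (unoptimized) feasible matrix per distribution.

    The pre-optimization reference level: how much fourfold-usage deviation
    amino-acid selection produces under a typical, rather than an extreme,
    mutation process.
    """
    D = acceptance_matrix(variant)
    space = "61-sense" if variant == "SL" else "64-all"
    rows = []
    for i, freqs in enumerate(pis):
        pi = NucleotideDistribution(tuple(freqs))
        rng = np.random.default_rng(worker_seed(master_seed, i))
        basis = nullspace_basis(constraint_matrix(pi))
        coeffs = sample_coefficients(basis, pi, rng)
        P = uniformize(build_rate_matrix(coeffs))
        C = combine(codon_matrix(P, space), D)
        dev = total_deviation(pi, C.pi_sel, C.state_labels, variant, family_set)
        rows.append(
            {
                "index": i,
                **{f"pi_{n}": v for n, v in zip("ATGC", freqs)},
                "F_total": dev.total,
                **{f"F_{name}": v for name, v in dev.per_family.items()},
            }
        )
    return pd.DataFrame(rows)


def run_empirical(
    fasta_path,
    gene_table_path=None,
    genome_path=None,
    family_set: str = "canonical5",
) -> dict:
    """Sequence-level fourfold deviation report.

    Always reports the whole-set F; with a genome and gene table it also
    splits genes by replication strand and reports per-strand F plus the
    two-set usage difference.
    """
    records = read_fasta(fasta_path)
    if not records:
        raise ValueError(f"empty FASTA input: {fasta_path}")
    table = codon_usage(records, source=str(fasta_path), family_set=family_set)
    per, total = sequence_deviation(table)
    report = {
        "n_genes": table.n_genes,
        "filters": vars(table.filter_report),
        "per_family": per,
        "F": total,
    }
    if genome_path is not None and gene_table_path is not None:
        genome = str(read_fasta(genome_path)[0].seq)
        genes = read_gene_table(gene_table_path)
        segments = skew_segments(genome, genes)
        report["skew_reliable"] = segments.reliable
        report["boundaries"] = list(segments.boundaries)
        by_id = {r.id: r for r in records}
        split = {}
        for side in ("leading", "lagging"):
            ids = segments.assignment.query(f"replichore == '{side}'")["gene_id"]
            recs = [by_id[g] for g in ids if g in by_id]
            if recs:
                t = codon_usage(recs, source=side, family_set=family_set)
                p, f = sequence_deviation(t)
                split[side] = {"n_genes": t.n_genes, "per_family": p, "F": f}
                report.setdefault("_tables", {})[side] = t
        report["strands"] = split
        tables = report.pop("_tables", {})
        if len(tables) == 2:
            report["strand_difference"] = gene_set_difference(
                tables["leading"], tables["lagging"]
            )
    return report
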