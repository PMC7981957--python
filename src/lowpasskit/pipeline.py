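"""End-to-end synthetic benchmark mirroring the array-vs-sequencing study design.

One call simulates a phased panel and a diploid cohort, sequences each
individual at a base coverage, thins the reads down a coverage ladder,
imputes every sample at every coverage, simulates array genotypes as truth,
and evaluates concordance (stratified), dosage r^2 by MAF bin, and the
array-side leave-one-out r^2.  Everything is a deterministic function of the
top-level seed: per-stage and per-sample seeds are spawned from it.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .impute import HMMParams, impute_sample
from .likelihood import ReadErrorModel
from .metrics import (
    DEFAULT_MAF_BIN_EDGES,
    R2Table,
    bin_r2_by_maf,
    cohort_maf,
    concordance_report,
    imputation_r2,
    leave_one_out_r2,
)
from .panel_io import GenotypeCalls, VariantSet
from .simulate import (
    SimConfig,
    downsample_counts,
    simulate_array,
    simulate_individual,
    simulate_panel,
    simulate_reads,
)

DEFAULT_COVERAGE_FRACTIONS = (1.0, 0.8, 0.6, 0.4)

#: Number of sites tagged as the pharmacogenetics-like ("ADME") subset.
ADME_SUBSET_SIZE = 216


@dataclass
class BenchmarkConfig:
    """Benchmark design: simulation settings, coverage ladder, HMM settings."""

    sim: SimConfig
    coverages: tuple[float, ...] = DEFAULT_COVERAGE_FRACTIONS
    hmm: HMMParams = field(default_factory=HMMParams)
    bin_edges: tuple[float, ...] = DEFAULT_MAF_BIN_EDGES
    subset_size: int = ADME_SUBSET_SIZE
    output_dir: str | None = None

    def __post_init__(self) -> None:
        cov = tuple(self.coverages)
        if not cov or any(not (0.0 < f <= 1.0) for f in cov):
            raise ValueError("coverage fractions must lie in (0, 1]")
        if list(cov) != sorted(cov, reverse=True):
            raise ValueError("coverage fractions must be sorted descending")
        self.coverages = cov


@dataclass
class CoverageResult:
    coverage: float  # actual mean depth (fraction * base coverage)
    fraction: float
    concordance: dict  # stratum -> ConcordanceReport
    r2_table: R2Table
    mean_common_r2: float


@dataclass
class BenchmarkReport:
    config: BenchmarkConfig
    per_coverage: list[CoverageResult]
    array_loo_r2: R2Table
    array_mean_common_r2: float
    metadata: dict


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def run_benchmark(config: BenchmarkConfig) -> BenchmarkReport:
    """Simulate, impute along the coverage ladder, and evaluate."""
    sim = config.sim
    n = sim.n_samples
    seeds = _spawn_seeds(sim.seed, 4 + 3 * n)
    panel_seed, subset_seed = seeds[0], seeds[1]
    ind_seeds = seeds[4 : 4 + n]
    read_seeds = seeds[4 + n : 4 + 2 * n]
    array_seeds = seeds[4 + 2 * n : 4 + 3 * n]

    panel = simulate_panel(dataclasses.replace(sim, seed=panel_seed))
    error_model = ReadErrorModel(sim.read_error)

    truths = [
        simulate_individual(panel, sim.mosaic_switch_rate, sim.mosaic_miscopy, s)
        for s in ind_seeds
    ]
    base_counts = [
        simulate_reads(t, sim.coverage, sim.read_error, s)
        for t, s in zip(truths, read_seeds)
    ]
    array_calls = [
        simulate_array(
            t, sim.array_error, sim.array_missing_rate, s, sites=panel.sites,
            sample=f"ind{i}",
        )
        for i, (t, s) in enumerate(zip(truths, array_seeds))
    ]

    subset_rng = np.random.default_rng(subset_seed)
    k = min(config.subset_size, panel.M)
    subset_idx = subset_rng.choice(panel.M, size=k, replace=False)
    subset = VariantSet(
        members=frozenset(panel.sites[int(i)].key for i in subset_idx), label="ADME"
    )

    truth_matrix = np.stack([gc.calls for gc in array_calls], axis=0)
    maf = cohort_maf(array_calls)

    per_coverage: list[CoverageResult] = []
    for ci, fraction in enumerate(config.coverages):
        dosage_rows = []
        imputed_calls = []
        for i in range(n):
            thin_seed = (read_seeds[i] + 7919 * (ci + 1)) % (2**31)
            counts = downsample_counts(base_counts[i], fraction, thin_seed)
            res = impute_sample(counts, panel, error_model, config.hmm)
            dosage_rows.append(res.dosages)
            imputed_calls.append(
                GenotypeCalls(sites=panel.sites, calls=res.hard_calls, sample=f"ind{i}")
            )
        conc = concordance_report(array_calls, imputed_calls, subset=subset)
        r2 = imputation_r2(np.stack(dosage_rows, axis=0), truth_matrix)
        table = bin_r2_by_maf(r2, maf, config.bin_edges)
        per_coverage.append(
            CoverageResult(
                coverage=fraction * sim.coverage,
                fraction=fraction,
                concordance=conc,
                r2_table=table,
                mean_common_r2=table.mean_r2_over(0.05),
            )
        )

    loo = leave_one_out_r2(array_calls, panel, config.hmm, sim.array_error)
    array_table = bin_r2_by_maf(loo, maf, config.bin_edges)

    report = BenchmarkReport(
        config=config,
        per_coverage=per_coverage,
        array_loo_r2=array_table,
        array_mean_common_r2=array_table.mean_r2_over(0.05),
        metadata={
            "version": "0.1.0",
            "seed": sim.seed,
            "n_samples": n,
            "panel_K": panel.K,
            "panel_M": panel.M,
            "coverages": [fraction * sim.coverage for fraction in config.coverages],
            "hmm": dataclasses.asdict(config.hmm),
            "sim": dataclasses.asdict(sim),
        },
    )
    if config.output_dir is not None:
        write_report(report, config.output_dir)
    return report


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _nan_to_none(x: float) -> float | None:
    return None if (x is None or (isinstance(x, float) and math.isnan(x))) else x


def concordance_table(report: BenchmarkReport) -> pd.DataFrame:
    rows = []
    for cov in report.per_coverage:
        for stratum, rep in cov.concordance.items():
            rows.append(
                {
                    "coverage": cov.coverage,
                    "stratum": stratum,
                    "ppa_pct": rep.ppa_pct,
                    "npa_pct": rep.npa_pct,
                    "mean_no_calls": rep.mean_no_calls,
                }
            )
    return pd.DataFrame(rows, columns=["coverage", "stratum", "ppa_pct", "npa_pct", "mean_no_calls"])


def r2_tables(report: BenchmarkReport) -> pd.DataFrame:
    rows = []
    entries = [(f"{cov.coverage:g}x", cov.r2_table) for cov in report.per_coverage]
    entries.append(("array", report.array_loo_r2))
    for label, table in entries:
        for b in table.bins:
            rows.append(
                {
                    "coverage": label,
                    "maf_low": b.maf_low,
                    "maf_high": b.maf_high,
                    "n_variants": b.n_variants,
                    "mean_r2": b.mean_r2,
                }
            )
    return pd.DataFrame(rows, columns=["coverage", "maf_low", "maf_high", "n_variants", "mean_r2"])


def report_to_dict(report: BenchmarkReport) -> dict:
    return {
        "metadata": report.metadata,
        "per_coverage": [
            {
                "coverage": cov.coverage,
                "fraction": cov.fraction,
                "mean_common_r2": _nan_to_none(cov.mean_common_r2),
                "concordance": {
                    stratum: {
                        "ppa_pct": _nan_to_none(rep.ppa_pct),
                        "npa_pct": _nan_to_none(rep.npa_pct),
                        "mean_no_calls": rep.mean_no_calls,
                        "n_sites": rep.n_sites,
                    }
                    for stratum, rep in cov.concordance.items()
                },
                "r2_bins": [
                    {
                        "maf_low": b.maf_low,
                        "maf_high": b.maf_high,
                        "n_variants": b.n_variants,
                        "mean_r2": _nan_to_none(b.mean_r2),
                    }
                    for b in cov.r2_table.bins
                ],
            }
            for cov in report.per_coverage
        ],
        "array_loo": {
            "mean_common_r2": _nan_to_none(report.array_mean_common_r2),
            "r2_bins": [
                {
                    "maf_low": b.maf_low,
                    "maf_high": b.maf_high,
                    "n_variants": b.n_variants,
                    "mean_r2": _nan_to_none(b.mean_r2),
                }
                for b in report.array_loo_r2.bins
            ],
        },
    }


def write_report(report: BenchmarkReport, output_dir: str) -> list[str]:
    """Write the master JSON report plus concordance/r^2 TSV tables.

    Files are written atomically (tmp file + rename) so a failed run never
    leaves a truncated report.  Returns the written paths.
    """
    os.makedirs(output_dir, exist_ok=True)
    written = []

    def _atomic_write(name: str, text: str) -> None:
        path = os.path.join(output_dir, name)
        tmp = path + ".tmp"
        with open(tmp, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
        written.append(path)

    _atomic_write("benchmark.json", json.dumps(report_to_dict(report), indent=2, sort_keys=True))
    _atomic_write("concordance.tsv", concordance_table(report).to_csv(sep="\t", index=False))
    _atomic_write("r2_by_maf.tsv", r2_tables(report).to_csv(sep="\t", index=False))

    lines = ["coverage\tPPA %\tNPA %\tNo Calls"]
    for cov in report.per_coverage:
        rep = cov.concordance["all:all"]
        lines.append(
            f"{cov.coverage:g}x\t{rep.ppa_pct:.2f}\t{rep.npa_pct:.2f}\t{rep.mean_no_calls:.1f}"
        )
    _atomic_write("summary.txt", "\n".join(lines) + "\n")
    return written


def plot_r2(report: BenchmarkReport, path: str) -> None:
    """Optional r^2-vs-MAF chart (one line per coverage plus the array LOO)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    entries = [(f"{cov.coverage:g}x", cov.r2_table) for cov in report.per_coverage]
    entries.append(("array (LOO)", report.array_loo_r2))
    for label, table in entries:
        mids = [(b.maf_low + b.maf_high) / 2 for b in table.bins if b.n_variants]
        vals = [b.mean_r2 for b in table.bins if b.n_variants]
        ax.plot(mids, vals, marker="o", label=label)
    ax.set_xscale("log")
    ax.set_xlabel("minor allele frequency")
    ax.set_ylabel("mean imputation $r^2$")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
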