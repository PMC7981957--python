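"""Evaluation statistics for the array-vs-sequencing comparison.

Concordance follows FDA-style agreement definitions with the array treated
as truth: positive percent agreement (PPA) is the percent of truth
non-reference genotypes recovered identically by the test assay, negative
percent agreement (NPA) the percent of truth homozygous-reference genotypes
called reference, in both cases ignoring test no-calls.  Imputation quality
is the squared Pearson correlation between imputed dosages and truth
genotypes across samples at a variant, averaged within minor-allele-
frequency bins.  A leave-one-out r-squared gives the array-side analogue.
The module also carries the closed-form Poisson coverage and sequencing
budget arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .impute import HMMParams, forward_backward
from .likelihood import array_likelihood_matrix
from .panel_io import NO_CALL, GenotypeCalls, HaplotypePanel, VariantSet, check_aligned

DEFAULT_MAF_BIN_EDGES = (0.0, 0.005, 0.01, 0.02, 0.05, 0.1, 0.2, 0.5)

#: "Rare" = minor allele present in at most this many copies in the truth cohort.
RARE_THRESHOLD_COPIES = 5


@dataclass
class ConcordanceCounts:
    """Per-individual genotype agreement tallies against truth calls.

    Genotype-level matching: a truth het called hom-alt counts as a false
    negative (the truth variant genotype was not detected correctly), never
    as a false positive; false positives are reserved for non-reference test
    calls at truth hom-ref sites.  ``mismatch_nonref`` tallies the
    truth-non-ref / test-non-ref-but-different corner separately so
    alternative conventions can be recomputed.
    """

    tp: int = 0
    fn: int = 0
    fp: int = 0
    tn: int = 0
    no_calls_at_truth_variant: int = 0
    no_calls_at_truth_ref: int = 0
    mismatch_nonref: int = 0

    @property
    def n_truth_variant(self) -> int:
        return self.tp + self.fn + self.no_calls_at_truth_variant

    @property
    def n_truth_ref(self) -> int:
        return self.tn + self.fp + self.no_calls_at_truth_ref


@dataclass
class ConcordanceReport:
    """Cohort-level agreement for one stratum, averaged across individuals."""

    per_individual: list[ConcordanceCounts]
    ppa_pct: float | None
    npa_pct: float | None
    mean_no_calls: float
    n_sites: int
    stratum: str = "all"


class R2Bin(NamedTuple):
    maf_low: float
    maf_high: float
    n_variants: int
    mean_r2: float  # nan when the bin is empty


@dataclass
class R2Table:
    bins: list[R2Bin]

    def mean_r2_over(self, maf_min: float = 0.0) -> float:
        """Variant-weighted mean r^2 over bins whose lower edge is >= maf_min."""
        tot_n = sum(b.n_variants for b in self.bins if b.maf_low >= maf_min)
        if tot_n == 0:
            return float("nan")
        return (
            sum(b.n_variants * b.mean_r2 for b in self.bins if b.maf_low >= maf_min and b.n_variants)
            / tot_n
        )


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------

def classify_sites(
    truth: GenotypeCalls | np.ndarray,
    test: GenotypeCalls | np.ndarray,
    site_mask: np.ndarray | None = None,
) -> ConcordanceCounts:
    """Tally agreement between one individual's truth and test calls.

    Truth no-call sites are excluded entirely.  Each remaining compared site
    lands in exactly one cell (tp/fn/tn/fp) or one no-call tally.
    """
    if isinstance(truth, GenotypeCalls) and isinstance(test, GenotypeCalls):
        check_aligned(truth.sites, test.sites)
    t = np.asarray(truth.calls if isinstance(truth, GenotypeCalls) else truth)
    x = np.asarray(test.calls if isinstance(test, GenotypeCalls) else test)
    if t.shape != x.shape:
        raise ValueError(f"truth and test call vectors differ in length: {t.shape} vs {x.shape}")
    keep = t != NO_CALL
    if site_mask is not None:
        keep &= np.asarray(site_mask, dtype=bool)
    t, x = t[keep], x[keep]
    truth_var = t > 0
    truth_ref = t == 0
    test_nc = x == NO_CALL
    return ConcordanceCounts(
        tp=int((truth_var & (x == t)).sum()),
        fn=int((truth_var & ~test_nc & (x != t)).sum()),
        fp=int((truth_ref & ~test_nc & (x > 0)).sum()),
        tn=int((truth_ref & (x == 0)).sum()),
        no_calls_at_truth_variant=int((truth_var & test_nc).sum()),
        no_calls_at_truth_ref=int((truth_ref & test_nc).sum()),
        mismatch_nonref=int((truth_var & ~test_nc & (x > 0) & (x != t)).sum()),
    )


def ppa(counts: ConcordanceCounts) -> float | None:
    """Positive percent agreement: 100 * TP / (TP + FN); None when undefined."""
    denom = counts.tp + counts.fn
    return None if denom == 0 else 100.0 * counts.tp / denom


def npa(counts: ConcordanceCounts) -> float | None:
    """Negative percent agreement: 100 * TN / (TN + FP); None when undefined."""
    denom = counts.tn + counts.fp
    return None if denom == 0 else 100.0 * counts.tn / denom


def cohort_minor_allele_copies(truth_calls: Sequence[GenotypeCalls]) -> np.ndarray:
    """Minor-allele copy count per site in the truth cohort (no-calls excluded)."""
    calls = np.stack([gc.calls for gc in truth_calls], axis=0)  # (n, M)
    called = calls != NO_CALL
    alt = np.where(called, calls, 0).sum(axis=0)
    total = 2 * called.sum(axis=0)
    return np.minimum(alt, total - alt)


def cohort_maf(truth_calls: Sequence[GenotypeCalls]) -> np.ndarray:
    """Minor allele frequency per site from truth calls; nan where uncalled."""
    calls = np.stack([gc.calls for gc in truth_calls], axis=0)
    called = calls != NO_CALL
    alt = np.where(called, calls, 0).sum(axis=0).astype(float)
    total = (2 * called.sum(axis=0)).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = alt / total
    return np.where(total > 0, np.minimum(freq, 1.0 - freq), np.nan)


def _mean_or_none(values: list[float | None]) -> float | None:
    vals = [v for v in values if v is not None]
    return None if not vals else float(np.mean(vals))


def _stratum_report(
    truth_set: Sequence[GenotypeCalls],
    test_set: Sequence[GenotypeCalls],
    mask: np.ndarray,
    stratum: str,
) -> ConcordanceReport:
    per_ind = [
        classify_sites(t, x, site_mask=mask) for t, x in zip(truth_set, test_set)
    ]
    return ConcordanceReport(
        per_individual=per_ind,
        ppa_pct=_mean_or_none([ppa(c) for c in per_ind]),
        npa_pct=_mean_or_none([npa(c) for c in per_ind]),
        mean_no_calls=float(np.mean([c.no_calls_at_truth_variant for c in per_ind])),
        n_sites=int(mask.sum()),
        stratum=stratum,
    )


def concordance_report(
    truth_set: Sequence[GenotypeCalls],
    test_set: Sequence[GenotypeCalls],
    subset: VariantSet | None = None,
    rare_threshold_copies: int = RARE_THRESHOLD_COPIES,
) -> dict[str, ConcordanceReport]:
    """Stratified cohort concordance: {all, subset} x {all, rare, common}.

    "Rare" means the minor allele is present in at most
    ``rare_threshold_copies`` copies in the truth cohort (5 copies in 79
    diploids is a frequency of about 3%).  Percentages are unweighted
    arithmetic means across individuals; individuals with an empty
    denominator are left out of the corresponding mean.
    """
    if not truth_set:
        raise ValueError("need at least one individual")
    if len(truth_set) != len(test_set):
        raise ValueError("truth and test cohorts differ in size")
    for t, x in zip(truth_set, test_set):
        check_aligned(t.sites, x.sites)
    sites = truth_set[0].sites
    M = len(sites)
    minor_copies = cohort_minor_allele_copies(truth_set)
    rare = minor_copies <= rare_threshold_copies
    scopes: list[tuple[str, np.ndarray]] = [("all", np.ones(M, dtype=bool))]
    if subset is not None:
        scopes.append((subset.label, subset.resolve(sites)))
    freqs = [("all", np.ones(M, dtype=bool)), ("rare", rare), ("common", ~rare)]
    out: dict[str, ConcordanceReport] = {}
    for scope_name, scope_mask in scopes:
        for freq_name, freq_mask in freqs:
            name = f"{scope_name}:{freq_name}"
            out[name] = _stratum_report(truth_set, test_set, scope_mask & freq_mask, name)
    return out


# ---------------------------------------------------------------------------
# Imputation r^2
# ---------------------------------------------------------------------------

def imputation_r2(dosages: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between dosage and truth, per variant.

    ``dosages`` and ``truth`` are (n_samples, M); truth entries may be
    NO_CALL (excluded per variant).  Variants monomorphic in truth (or with
    fewer than two called samples) are reported nan; a degenerate
    constant-dosage variant at a polymorphic truth site gets r^2 = 0.
    """
    dosages = np.asarray(dosages, dtype=float)
    truth = np.asarray(truth)
    if dosages.shape != truth.shape:
        raise ValueError(f"shape mismatch: {dosages.shape} vs {truth.shape}")
    n, M = truth.shape
    out = np.full(M, np.nan)
    for m in range(M):
        keep = truth[:, m] != NO_CALL
        if keep.sum() < 2:
            continue
        t = truth[keep, m].astype(float)
        d = dosages[keep, m]
        vt = t.var()
        vd = d.var()
        if vt == 0.0:
            continue  # monomorphic truth: undefined, excluded from bin means
        if vd == 0.0:
            out[m] = 0.0  # flagged degenerate by convention
            continue
        cov = ((t - t.mean()) * (d - d.mean())).mean()
        out[m] = (cov * cov) / (vt * vd)
    return out


def bin_r2_by_maf(
    r2_per_variant: np.ndarray,
    truth_maf: np.ndarray,
    bin_edges: Sequence[float] = DEFAULT_MAF_BIN_EDGES,
) -> R2Table:
    """Unweighted mean r^2 within left-open MAF bins (lo, hi].

    A variant whose MAF equals an edge belongs to the bin having that edge
    as its upper bound.  Variants with nan r^2 or nan MAF are excluded;
    empty bins are reported with n = 0.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or (np.diff(edges) <= 0).any():
        raise ValueError("bin edges must be strictly increasing with >= 2 values")
    r2 = np.asarray(r2_per_variant, dtype=float)
    maf = np.asarray(truth_maf, dtype=float)
    keep = np.isfinite(r2) & np.isfinite(maf) & (maf > edges[0]) & (maf <= edges[-1])
    idx = np.searchsorted(edges, maf[keep], side="left") - 1
    bins = []
    for b in range(len(edges) - 1):
        vals = r2[keep][idx == b]
        bins.append(
            R2Bin(
                maf_low=float(edges[b]),
                maf_high=float(edges[b + 1]),
                n_variants=int(vals.size),
                mean_r2=float(vals.mean()) if vals.size else float("nan"),
            )
        )
    return R2Table(bins=bins)


def leave_one_out_r2(
    array_calls: Sequence[GenotypeCalls],
    panel: HaplotypePanel,
    params: HMMParams,
    epsilon: float,
) -> np.ndarray:
    """Array-side imputation r^2 at typed sites via leave-one-out masking.

    For each sample, every typed site's own observation is masked (flat
    likelihood) while all other sites keep their array-call likelihoods; the
    masked site's imputed dosage is then correlated with the observed array
    genotype across samples.  Implemented in a single forward-backward pass
    per sample using the factorization of emissions over sites.
    """
    for gc in array_calls:
        check_aligned(gc.sites, panel.sites)
    loo = np.empty((len(array_calls), panel.M))
    for i, gc in enumerate(array_calls):
        gls = array_likelihood_matrix(gc.calls, epsilon)
        res = forward_backward(gls, panel, params, compute_loo=True)
        loo[i] = res.loo_dosages
    truth = np.stack([gc.calls for gc in array_calls], axis=0)
    return imputation_r2(loo, truth)


# ---------------------------------------------------------------------------
# Coverage and budget arithmetic
# ---------------------------------------------------------------------------

def expected_covered_sites(coverage: float, n_sites: float) -> float:
    """Expected number of sites with >= 1 read under Poisson(coverage) depth."""
    if coverage < 0:
        raise ValueError("coverage must be >= 0")
    return float(n_sites) * float(-np.expm1(-coverage))


class SequencingBudget(NamedTuple):
    n_reads: float
    total_bases: float
    cost: float


def sequencing_budget(
    coverage: float,
    genome_length: float = 3.3e9,
    read_length: float = 150.0,
    cost_per_30x: float = 1000.0,
) -> SequencingBudget:
    """Reads, bases and cost to sequence a genome at the given mean coverage.

    n_reads = coverage * genome_length / read_length; cost scales linearly
    from the quoted price of a 30x genome.
    """
    if min(coverage, genome_length, read_length, cost_per_30x) <= 0:
        raise ValueError("all budget arguments must be positive")
    n_reads = coverage * genome_length / read_length
    return SequencingBudget(
        n_reads=n_reads,
        total_bases=n_reads * read_length,
        cost=cost_per_30x * coverage / 30.0,
    )
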