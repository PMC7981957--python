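"""Synthetic cohort generator for the low-pass-vs-array study design.

Emulates the study's inputs at desk scale:

* a phased reference panel with linkage disequilibrium and a rare-variant-
  enriched site frequency spectrum,
* diploid individuals whose haplotypes are mosaic copies of the panel (the
  data-generating process the copying HMM assumes),
* low-pass sequencing reads with Poisson site depth and symmetric base
  errors, plus binomial thinning to emulate coverage down-sampling,
* array-style hard genotype calls with a small error and missingness rate.

Every stochastic operation is a pure function of its inputs and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .panel_io import NO_CALL, GenotypeCalls, HaplotypePanel, Site

_NUCLEOTIDE_PAIRS = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]


@dataclass(kw_only=True)
class SimConfig:
    """Study-design parameters for the synthetic cohort.

    Defaults mirror the benchmark design: a 200-haplotype panel over 2000
    SNPs in a 20 Mb region, 79 diploid individuals sequenced at a base
    coverage of 1x (thinned to lower coverages downstream), genotyped on a
    simulated array with 0.5% genotype error and 1% missingness.
    """

    seed: int
    K: int = 200
    M: int = 2000
    n_samples: int = 79
    coverage: float = 1.0
    read_error: float = 0.01
    array_error: float = 0.005
    array_missing_rate: float = 0.01
    mosaic_switch_rate: float = 4e-8  # per bp, matched to the HMM default rho
    mosaic_miscopy: float = 1e-3  # per site, matched to the HMM default theta
    region_length: int = 20_000_000
    chrom: str = "1"
    panel_switch_rate: float = 1e-7  # per bp, template switching while building the panel
    panel_innovation: float = 0.02  # per site, fresh Bernoulli(p) draw instead of copying
    af_alpha: float = 0.2
    af_beta: float = 0.2

    def __post_init__(self) -> None:
        if self.K < 2 or self.M < 1:
            raise ValueError(f"need K >= 2 and M >= 1, got K={self.K}, M={self.M}")
        if self.n_samples < 1:
            raise ValueError("need at least one sample")
        if self.M > self.region_length:
            raise ValueError("more sites than base pairs in the region")
        for name in ("read_error", "array_error", "array_missing_rate", "mosaic_miscopy",
                     "panel_innovation"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.coverage < 0:
            raise ValueError("coverage must be >= 0")


@dataclass
class TruthSample:
    """A simulated diploid individual with known haplotypes and genotypes."""

    hap1: np.ndarray
    hap2: np.ndarray
    genotypes: np.ndarray
    hap1_templates: np.ndarray | None = None  # panel row copied at each site
    hap2_templates: np.ndarray | None = None


def _draw_positions(rng: np.random.Generator, M: int, region_length: int) -> np.ndarray:
    """M distinct sorted 1-based positions in [1, region_length]."""
    positions: np.ndarray = np.unique(rng.integers(1, region_length + 1, size=2 * M + 16))
    while positions.size < M:
        extra = rng.integers(1, region_length + 1, size=2 * M)
        positions = np.union1d(positions, extra)
    return np.sort(rng.choice(positions, size=M, replace=False))


def _truncated_beta(rng: np.random.Generator, alpha: float, beta: float,
                    lo: float, hi: float, size: int | None = None) -> np.ndarray | float:
    """Beta(alpha, beta) draws rejected outside [lo, hi]."""
    n = 1 if size is None else size
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.beta(alpha, beta, size=2 * (n - filled) + 8)
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(keep.size, n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return float(out[0]) if size is None else out


def _mosaic_path(rng: np.random.Generator, n_templates: int, switch_prob: np.ndarray) -> np.ndarray:
    """Template index per site; switch_prob[m] is the switch chance on gap m.

    switch_prob[0] is ignored (the first site always draws a fresh template).
    """
    M = switch_prob.shape[0]
    switch = rng.random(M) < switch_prob
    switch[0] = True
    draws = rng.integers(0, n_templates, size=M)
    last_switch = np.maximum.accumulate(np.where(switch, np.arange(M), -1))
    return draws[last_switch]


def simulate_panel(config: SimConfig) -> HaplotypePanel:
    """Generate a phased haplotype panel with LD and a skewed frequency spectrum.

    Per-site target allele frequencies are drawn from a Beta(0.2, 0.2)
    truncated to [1/K, 1 - 1/K] (rare-variant enriched relative to uniform).
    Haplotype 0 is sampled i.i.d. from those frequencies; each later
    haplotype copies a mosaic of the previously generated ones (template
    switches at ``panel_switch_rate`` per bp), injecting a fresh
    frequency-p allele with probability ``panel_innovation`` per site, which
    creates local correlation (LD) between haplotypes.  Monomorphic columns
    are redrawn along the same copying paths until polymorphic.
    """
    rng = np.random.default_rng(config.seed)
    K, M = config.K, config.M
    positions = _draw_positions(rng, M, config.region_length)
    lo = 1.0 / K
    p = _truncated_beta(rng, config.af_alpha, config.af_beta, lo, 1.0 - lo, size=M)

    gaps = np.diff(positions, prepend=positions[0]).astype(float)
    switch_prob = -np.expm1(-config.panel_switch_rate * gaps)

    alleles = np.zeros((K, M), dtype=np.uint8)
    # template_of[k, m]: panel row copied by haplotype k at site m; -1 = fresh draw
    template_of = np.full((K, M), -1, dtype=np.int32)
    alleles[0] = rng.random(M) < p
    for k in range(1, K):
        path = _mosaic_path(rng, k, switch_prob)
        innovate = rng.random(M) < config.panel_innovation
        copied = alleles[path, np.arange(M)]
        fresh = rng.random(M) < p
        alleles[k] = np.where(innovate, fresh, copied)
        template_of[k] = np.where(innovate, -1, path)

    # Redraw monomorphic columns re-using the stored copy structure so that
    # LD with neighbouring sites is preserved.
    colsum = alleles.sum(axis=0)
    for m in np.flatnonzero((colsum == 0) | (colsum == K)):
        for _attempt in range(100):
            pm = _truncated_beta(rng, config.af_alpha, config.af_beta, lo, 1.0 - lo)
            col = np.empty(K, dtype=np.uint8)
            col[0] = rng.random() < pm
            for k in range(1, K):
                t = template_of[k, m]
                col[k] = (rng.random() < pm) if t < 0 else col[t]
            if 0 < col.sum() < K:
                alleles[:, m] = col
                p[m] = pm
                break
        else:
            # Force a singleton rather than loop forever on an unlucky column.
            col = np.zeros(K, dtype=np.uint8)
            col[rng.integers(0, K)] = 1
            alleles[:, m] = col

    pair_idx = rng.integers(0, len(_NUCLEOTIDE_PAIRS), size=M)
    sites = [
        Site(
            chrom=config.chrom,
            pos=int(positions[m]),
            ref_allele=_NUCLEOTIDE_PAIRS[pair_idx[m]][0],
            alt_allele=_NUCLEOTIDE_PAIRS[pair_idx[m]][1],
            id=f"snp{m}",
        )
        for m in range(M)
    ]
    return HaplotypePanel(sites=sites, alleles=alleles)


def simulate_individual(
    panel: HaplotypePanel,
    mosaic_switch_rate: float,
    theta: float,
    seed: int,
) -> TruthSample:
    """A diploid individual whose haplotypes are mosaics of the panel.

    Each haplotype copies panel templates with exponential-distance switches
    at ``mosaic_switch_rate`` per bp, miscopying the template allele with
    probability ``theta`` per site.
    """
    rng = np.random.default_rng(seed)
    M = panel.M
    gaps = np.diff(panel.positions, prepend=panel.positions[0]).astype(float)
    switch_prob = -np.expm1(-mosaic_switch_rate * gaps)
    haps = []
    paths = []
    for _ in range(2):
        path = _mosaic_path(rng, panel.K, switch_prob)
        miscopy = rng.random(M) < theta
        hap = panel.alleles[path, np.arange(M)] ^ miscopy.astype(np.uint8)
        haps.append(hap.astype(np.int8))
        paths.append(path)
    return TruthSample(
        hap1=haps[0],
        hap2=haps[1],
        genotypes=(haps[0] + haps[1]).astype(np.int8),
        hap1_templates=paths[0],
        hap2_templates=paths[1],
    )


def simulate_reads(
    truth: TruthSample, coverage: float, read_error: float, seed: int
) -> np.ndarray:
    """Poisson-depth reads at each site -> (M, 2) (ref_count, alt_count).

    Site depth is Poisson(coverage); each read copies the allele of a
    uniformly chosen haplotype and is flipped with probability ``read_error``.
    """
    if coverage < 0:
        raise ValueError("coverage must be >= 0")
    rng = np.random.default_rng(seed)
    g = np.asarray(truth.genotypes)
    M = g.shape[0]
    depth = rng.poisson(coverage, size=M)
    alt_true = np.where(
        g == 1, rng.binomial(depth, 0.5), np.where(g == 2, depth, 0)
    )
    obs_alt = rng.binomial(alt_true, 1.0 - read_error) + rng.binomial(
        depth - alt_true, read_error
    )
    return np.stack([depth - obs_alt, obs_alt], axis=1).astype(np.int64)


def downsample_counts(counts, fraction: float, seed: int) -> np.ndarray:
    """Binomial thinning: keep each read independently with probability ``fraction``.

    The site-level equivalent of sampling reads at random; thinning
    Poisson(c) depth gives Poisson(c * fraction) depth exactly.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError(f"thinning fraction must be in [0, 1], got {fraction}")
    arr = np.asarray(counts, dtype=np.int64)
    if fraction == 1.0:
        return arr.copy()
    rng = np.random.default_rng(seed)
    return rng.binomial(arr, fraction).astype(np.int64)


def simulate_array(
    truth: TruthSample,
    epsilon_a: float,
    missing_rate: float,
    seed: int,
    sites: Sequence[Site] | None = None,
    sample: str = "sample",
) -> GenotypeCalls | np.ndarray:
    """Array-style hard calls: wrong with probability epsilon_a, missing at missing_rate.

    A wrong call is one of the other two genotypes, chosen uniformly.
    Returns a bare call vector, or a :class:`GenotypeCalls` when ``sites``
    is provided.
    """
    if not (0.0 <= epsilon_a <= 1.0 and 0.0 <= missing_rate <= 1.0):
        raise ValueError("array error and missing rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    g = np.asarray(truth.genotypes, dtype=np.int8)
    M = g.shape[0]
    calls = g.copy()
    err = rng.random(M) < epsilon_a
    offsets = rng.integers(1, 3, size=M).astype(np.int8)
    calls[err] = (g[err] + offsets[err]) % 3
    calls[rng.random(M) < missing_rate] = NO_CALL
    if sites is None:
        return calls
    return GenotypeCalls(sites=list(sites), calls=calls, sample=sample)
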