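"""Diploid Li-Stephens haplotype-copying HMM for low-pass genotype imputation.

The sample's two haplotypes are modelled as mosaics of the K reference
haplotypes.  The hidden state at each site is the *ordered* pair (i, j) of
templates being copied; each haplotype switches template independently with
probability driven by recombination intensity ``rho`` times the inter-site
distance, and copies its template's allele imperfectly with miscopy
probability ``theta``.  The emission at a site marginalizes the two copied
alleles against the genotype likelihoods of the observed reads.

Forward-backward over the K^2 pair states yields per-site genotype
posteriors, alternate-allele dosages, and posterior-thresholded hard calls.
The transition kernel factorizes per haplotype, so each recursion step costs
O(K^2) rather than O(K^4).  The forward pass is rescaled per site; the scale
factors accumulate into the sample log-likelihood.

A leave-one-out dosage (the imputed dosage at a site when that site's own
data is masked to a flat likelihood) falls out of the same pass: because
emissions factorize per site, the state posterior given all data *except*
site t is proportional to (T F_{t-1}) o B_t, where T F_{t-1} is the forward
prediction before site t's emission and B_t the backward message (which by
construction excludes site t's emission).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernel
from .likelihood import ReadErrorModel, likelihood_matrix
from .panel_io import NO_CALL, HaplotypePanel


class ImputationError(ValueError):
    """Invalid inputs or numerically impossible data for the HMM."""


@dataclass(frozen=True)
class HMMParams:
    """Copying-model parameters.

    rho
        Recombination intensity per bp; the probability that a haplotype's
        template survives a gap of d bp without switching is exp(-rho * d).
    theta
        Miscopy probability per site (template allele copied incorrectly).
    call_threshold
        Minimum posterior a single genotype needs for a hard call; sites
        below it are reported NO_CALL.
    """

    rho: float = 4e-8
    theta: float = 1e-3
    call_threshold: float = 0.90

    def __post_init__(self) -> None:
        if self.rho < 0:
            raise ImputationError(f"rho must be >= 0, got {self.rho}")
        if not (0.0 <= self.theta < 0.5):
            raise ImputationError(f"theta must be in [0, 0.5), got {self.theta}")
        if not (1.0 / 3.0 < self.call_threshold <= 1.0):
            raise ImputationError(
                f"call threshold must be in (1/3, 1], got {self.call_threshold}"
            )


@dataclass
class ImputationResult:
    """Per-site genotype posteriors, dosages and thresholded hard calls."""

    posteriors: np.ndarray  # (M, 3), rows sum to 1
    dosages: np.ndarray  # (M,), in [0, 2]
    hard_calls: np.ndarray  # (M,), {0, 1, 2, NO_CALL}
    log_likelihood: float
    loo_dosages: np.ndarray | None = None  # (M,), only when requested


def switch_probability(d: float, rho: float, K: int) -> tuple[float, float]:
    """Single-haplotype transition over a gap of ``d`` bp.

    With s = 1 - exp(-rho d), the chain stays on its template with
    probability (1 - s) + s/K and moves to each specific other template with
    probability s/K; stay + (K-1) * move = 1.
    """
    if d < 0:
        raise ImputationError(f"distance must be >= 0, got {d}")
    if K < 2:
        raise ImputationError(f"panel must have K >= 2 haplotypes, got {K}")
    s = -np.expm1(-rho * d)
    move = s / K
    stay = (1.0 - s) + move
    return float(stay), float(move)


def copy_weight_table(theta: float) -> np.ndarray:
    """W[c, g] = P(true genotype g | template allele sum c) under miscopy theta.

    c in {0, 1, 2} is a_i + a_j for the copied template pair; rows sum to 1.
    """
    t, u = theta, 1.0 - theta
    return np.asarray(
        [
            [u * u, 2 * t * u, t * t],
            [t * u, u * u + t * t, t * u],
            [t * t, 2 * t * u, u * u],
        ]
    )


def emission_probability(hap_alleles: tuple[int, int], gl, theta: float) -> float:
    """P(site data | copying templates with alleles (a_i, a_j)).

    Marginalizes the two true alleles over miscopy: sum over x1, x2 of
    m(x1|a_i) m(x2|a_j) L(x1 + x2) with m(x|a) = 1-theta if x == a else theta.
    """
    a_i, a_j = hap_alleles
    if a_i not in (0, 1) or a_j not in (0, 1):
        raise ImputationError("template alleles must be 0 or 1")
    gl = np.asarray(gl, dtype=float)
    total = 0.0
    for x1 in (0, 1):
        for x2 in (0, 1):
            m1 = 1.0 - theta if x1 == a_i else theta
            m2 = 1.0 - theta if x2 == a_j else theta
            total += m1 * m2 * gl[x1 + x2]
    return total


def _hard_call(post: np.ndarray, threshold: float) -> int:
    top = post.max()
    winners = np.flatnonzero(post == top)
    if len(winners) > 1:
        # A tied maximum can never uniquely reach a threshold > 1/2; with a
        # permissive threshold the tie breaks deterministically low.
        return int(winners[0]) if threshold <= 0.5 and top >= threshold else NO_CALL
    return int(winners[0]) if top >= threshold else NO_CALL


# The forward matrices dominate memory traffic (M * K^2 doubles); reusing one
# buffer across calls of the same shape avoids repeated page-fault costs when
# imputing a cohort sample by sample.
_workspace: dict[str, np.ndarray] = {}


def _forward_buffer(M: int, K: int) -> np.ndarray:
    buf = _workspace.get("F")
    if buf is None or buf.shape != (M, K, K):
        buf = np.empty((M, K, K))
        _workspace["F"] = buf
    return buf


def forward_backward(
    gls,
    panel: HaplotypePanel,
    params: HMMParams,
    compute_loo: bool = False,
) -> ImputationResult:
    """Run the diploid copying HMM and return genotype posteriors.

    ``gls`` is an (M, 3) array (or list of triplets) of genotype likelihoods
    aligned to the panel sites.  Chromosomes are independent chains: the
    state distribution restarts uniform at each chromosome boundary.  With
    ``compute_loo`` the per-site leave-one-out dosages are also returned.
    """
    gls = np.asarray(gls, dtype=float)
    K, M = panel.K, panel.M
    if M == 0:
        raise ImputationError("panel has no sites")
    if gls.shape != (M, 3):
        raise ImputationError(f"expected ({M}, 3) genotype likelihoods, got {gls.shape}")
    if not np.isfinite(gls).all() or (gls < 0).any():
        raise ImputationError("genotype likelihoods must be finite and non-negative")
    if (gls.max(axis=1) <= 0).any():
        m = int(np.flatnonzero(gls.max(axis=1) <= 0)[0])
        raise ImputationError(f"all-zero likelihood triplet at site index {m}")

    W = copy_weight_table(params.theta)  # (3, 3)
    evals = gls @ W.T  # evals[m, c] = sum_g W[c, g] L_m[g]
    af_t = np.ascontiguousarray(panel.alleles.T, dtype=np.float64)  # (M, K)
    positions = panel.positions

    seg_start = np.zeros(M, dtype=bool)
    for start, _ in panel.chrom_segments():
        seg_start[start] = True

    # Per-gap transition scalars (gap m connects site m-1 to site m within a
    # chromosome; boundary gaps are never used — the chain restarts there).
    stays = np.ones(M)
    moves = np.zeros(M)
    for m in range(1, M):
        if not seg_start[m]:
            stays[m], moves[m] = switch_probability(
                float(positions[m] - positions[m - 1]), params.rho, K
            )

    F = _forward_buffer(M, K)
    err = np.full(1, -1, dtype=np.int64)
    log_likelihood = float(
        _kernel.forward_pass(af_t, evals, stays, moves, seg_start, F, err)
    )
    if err[0] >= 0:
        raise ImputationError(
            f"forward probability vanished at site index {int(err[0])} "
            "(contradictory certain data with theta = 0?)"
        )

    posteriors = np.empty((M, 3))
    loo_dosages = np.empty(M) if compute_loo else None
    loo_buf = loo_dosages if compute_loo else np.empty(1)
    _kernel.backward_pass(
        gls, af_t, evals, stays, moves, seg_start, W, F, posteriors, loo_buf,
        compute_loo,
    )

    dosages = posteriors[:, 1] + 2.0 * posteriors[:, 2]
    hard_calls = np.asarray(
        [_hard_call(posteriors[m], params.call_threshold) for m in range(M)],
        dtype=np.int8,
    )
    return ImputationResult(
        posteriors=posteriors,
        dosages=dosages,
        hard_calls=hard_calls,
        log_likelihood=log_likelihood,
        loo_dosages=loo_dosages,
    )


def impute_sample(
    counts,
    panel: HaplotypePanel,
    error_model: ReadErrorModel | None = None,
    params: HMMParams | None = None,
) -> ImputationResult:
    """Impute one sample from (ref, alt) read counts aligned to the panel."""
    error_model = error_model or ReadErrorModel()
    params = params or HMMParams()
    gls = likelihood_matrix(counts, error_model)
    if gls.shape[0] != panel.M:
        raise ImputationError(
            f"counts cover {gls.shape[0]} sites but panel has {panel.M}"
        )
    return forward_backward(gls, panel, params)
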