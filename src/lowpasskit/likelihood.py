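"""Genotype likelihoods from low-pass read counts or array hard calls.

The read model is a symmetric per-base error: a read sampled from a template
allele reports the other allele with probability ``e``.  Writing a genotype
``g`` as the number of alternate-allele copies, each read at a site is an
independent draw from one of the two chromosomes, so

    P(read shows alt | g = 0) = e
    P(read shows alt | g = 1) = 1/2
    P(read shows alt | g = 2) = 1 - e

and the likelihood of observing ``ref_count`` + ``alt_count`` reads is the
product over reads.  Likelihood triplets are meaningful only up to a common
positive factor; downstream posteriors are invariant to rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .panel_io import NO_CALL


class SiteCounts(NamedTuple):
    """Reads supporting the reference and alternate allele at one site."""

    ref_count: int
    alt_count: int


class GenotypeLikelihoods(NamedTuple):
    """Relative likelihoods of the three genotypes (hom-ref, het, hom-alt)."""

    l_rr: float
    l_ra: float
    l_aa: float


@dataclass(frozen=True)
class ReadErrorModel:
    """Per-read substitution error rate, 0 <= e < 0.5."""

    error_rate: float = 0.01

    def __post_init__(self) -> None:
        if not (0.0 <= self.error_rate < 0.5):
            raise ValueError(f"read error rate must be in [0, 0.5), got {self.error_rate}")


def as_counts_array(counts) -> np.ndarray:
    """Coerce a list of SiteCounts / pairs or an (M, 2) array to int64 (M, 2)."""
    arr = np.asarray(counts, dtype=np.int64)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"counts must be (M, 2)-shaped, got {arr.shape}")
    if (arr < 0).any():
        raise ValueError("read counts must be non-negative")
    return arr


def likelihood_matrix(counts, model: ReadErrorModel) -> np.ndarray:
    """Per-site genotype likelihoods for an (M, 2) array of (ref, alt) counts.

    Returns an (M, 3) float array.  Each row is the raw product over reads,
    except where that product would underflow, in which case the row is
    rescaled by its maximum (a common positive factor, which downstream
    inference ignores).  A site with zero reads yields the flat row (1, 1, 1).
    """
    arr = as_counts_array(counts)
    e = model.error_rate
    r = arr[:, 0].astype(float)
    a = arr[:, 1].astype(float)
    with np.errstate(divide="ignore"):
        log_e = np.log(e) if e > 0 else -np.inf
        log_1e = np.log1p(-e)
    log_half = np.log(0.5)
    # log L(g) as r * log P(ref|g) + a * log P(alt|g); 0 * -inf := 0 (no reads
    # of that kind, certainty is never contradicted).
    def _mul(count: np.ndarray, logp: float) -> np.ndarray:
        out = count * logp
        out[count == 0] = 0.0
        return out

    log_l = np.stack(
        [
            _mul(r, log_1e) + _mul(a, log_e),
            (r + a) * log_half,
            _mul(r, log_e) + _mul(a, log_1e),
        ],
        axis=1,
    )
    top = log_l.max(axis=1, keepdims=True)
    shift = np.where(top < -700.0, top, 0.0)  # rescale only when underflowing
    return np.exp(log_l - shift)


def genotype_likelihoods(counts: SiteCounts, model: ReadErrorModel) -> GenotypeLikelihoods:
    """Likelihood triplet for a single site's read counts."""
    row = likelihood_matrix(np.asarray([counts], dtype=np.int64), model)[0]
    return GenotypeLikelihoods(*row)


def array_to_likelihoods(call: int, epsilon: float) -> GenotypeLikelihoods:
    """Likelihood triplet for an array hard call with symmetric error ``epsilon``.

    The called genotype gets 1 - epsilon; each other genotype epsilon / 2.
    A NO_CALL carries no information and yields the flat triplet.
    """
    if not (0.0 <= epsilon < 0.5):
        raise ValueError(f"array error rate must be in [0, 0.5), got {epsilon}")
    if call == NO_CALL:
        return GenotypeLikelihoods(1.0, 1.0, 1.0)
    if call not in (0, 1, 2):
        raise ValueError(f"genotype call must be 0, 1, 2 or NO_CALL, got {call}")
    triplet = [epsilon / 2.0] * 3
    triplet[call] = 1.0 - epsilon
    return GenotypeLikelihoods(*triplet)


def array_likelihood_matrix(calls: np.ndarray, epsilon: float) -> np.ndarray:
    """Vectorized :func:`array_to_likelihoods` over a call vector -> (M, 3)."""
    if not (0.0 <= epsilon < 0.5):
        raise ValueError(f"array error rate must be in [0, 0.5), got {epsilon}")
    calls = np.asarray(calls)
    out = np.full((calls.shape[0], 3), epsilon / 2.0)
    for g in (0, 1, 2):
        out[calls == g, g] = 1.0 - epsilon
    out[calls == NO_CALL] = 1.0
    return out
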