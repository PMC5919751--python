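"""Allele-frequency estimation from read counts.

Reads of an individual at a site are modelled as binomial draws from the
individual's allele frequency, so the read proportion is an unbiased
per-individual estimate.  A population's frequency is the weighted average
of its individuals' estimates with weights proportional to ``2n/(n+1)``
(n = read depth), the weighting that minimises the variance of the
estimate under diploid Hardy-Weinberg sampling plus binomial read
sampling.  Individuals with no reads at a site receive weight zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import BASE_INDEX, UndefinedFrequencyError


@dataclass(frozen=True)
class IndividualFrequency:
    """Read-proportion estimate of an individual's allele frequency."""

    x_hat: float
    n: int


def raw_weight(n):
    """Unnormalised minimal-variance weight ``2n/(n+1)`` for depth ``n``.

    Strictly increasing in n, zero at n = 0, saturating at 2: one extra
    read helps a lot when depth is low and barely at all when the
    individual is already well covered.
    """
    n = np.asarray(n, dtype=float)
    out = 2.0 * n / (n + 1.0)
    return float(out) if out.ndim == 0 else out


def individual_freq(counts, focal_allele) -> IndividualFrequency:
    """Frequency of the focal allele among one individual's reads."""
    counts = np.asarray(counts)
    n = int(counts.sum())
    if n == 0:
        raise UndefinedFrequencyError("no reads: individual frequency undefined")
    focal = BASE_INDEX[focal_allele] if isinstance(focal_allele, str) else int(focal_allele)
    return IndividualFrequency(x_hat=float(counts[focal]) / n, n=n)


def normalized_weights(depths) -> np.ndarray:
    """Weights over individuals (last axis), summing to 1 where any depth > 0."""
    w = raw_weight(depths)
    tot = w.sum(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore"):
        out = np.where(tot > 0, w / np.where(tot > 0, tot, 1.0), np.nan)
    return out


def population_freq(individual_counts, focal_allele):
    """Minimal-variance weighted population frequency for one site.

    ``individual_counts`` is a sequence of 4-vectors (one per individual).
    Returns ``(q_hat, weights)``; raises if no individual has reads.
    """
    counts = np.asarray(individual_counts, dtype=float)
    depths = counts.sum(axis=-1)
    if not (depths > 0).any():
        raise UndefinedFrequencyError("population frequency undefined: all depths zero")
    w = normalized_weights(depths)
    focal = BASE_INDEX[focal_allele] if isinstance(focal_allele, str) else int(focal_allele)
    with np.errstate(invalid="ignore", divide="ignore"):
        x_hat = np.where(depths > 0, counts[:, focal] / np.where(depths > 0, depths, 1.0), 0.0)
    return float((w * x_hat).sum()), w


def population_base_freqs(counts: np.ndarray) -> np.ndarray:
    """Weighted 4-base frequency simplex per site for one population.

    Parameters
    ----------
    counts
        Integer array of shape (S, N, 4): sites x individuals x bases.

    Returns
    -------
    ndarray of shape (S, 4); rows are simplex vectors, NaN where the
    population has no reads at the site.
    """
    counts = np.asarray(counts)
    depths = counts.sum(axis=-1)  # (S, N)
    w_raw = raw_weight(depths)
    tot = w_raw.sum(axis=-1)
    f = np.zeros((counts.shape[0], 4))
    # loop over the few individuals; avoids (S, N, 4) float temporaries
    for l in range(counts.shape[1]):
        scale = np.divide(w_raw[:, l], tot * depths[:, l],
                          out=np.zeros(len(f)), where=depths[:, l] > 0)
        f += scale[:, None] * counts[:, l, :]
    f[tot == 0] = np.nan
    return f


def major_allele(pooled_counts) -> int:
    """Most frequent base across pooled reads (ties broken A<C<G<T)."""
    pooled = np.asarray(pooled_counts)
    return int(np.argmax(pooled, axis=-1)) if pooled.ndim == 1 else np.argmax(pooled, axis=-1)
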