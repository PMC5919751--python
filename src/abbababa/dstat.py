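"""The extended D-statistic: site terms, blocks, jackknife, and pipeline.

For four populations (((H1,H2)H3)H4) with per-site focal-allele frequencies
``q1..q4``, each site contributes

    X_i = (q1 - q2)(q3 - q4)
    Y_i = (q1 + q2 - 2 q1 q2)(q3 + q4 - 2 q3 q4)

and D = sum(X) / sum(Y).  Under the null of a correct tree without gene
flow, E[X_i] = 0 at every site, and D divided by its block-jackknife
standard error is approximately standard normal.  X and Y are respectively
the difference and the sum of the BABA-like and ABBA-like pattern
probabilities, which is how the statistic generalises to the full
four-base alphabet: with per-population base-frequency simplex vectors,
the probability of a joint pattern (a1,a2,a3,a4) is the product of the
marginal frequencies, BABA-like patterns are the (x,y,x,y) with x != y and
ABBA-like patterns the (x,y,y,x).

Sign convention: D > 0 means an excess of BABA-like sharing (H1 with H3).
The widely used (nABBA - nBABA) orientation is the negation; inference is
two-tailed either way.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm

from . import freq as freq_mod
from .data_model import BASES, TRANSITION_PAIRS, UndefinedFrequencyError
from .error import GroupErrorOperator, correct_pattern_probs

__all__ = [
    "SiteTerms", "BlockStats", "DResult", "site_terms", "pattern_terms",
    "sample_one_base", "genotype_freq", "remove_transitions",
    "aggregate_blocks", "jackknife_D", "block_pattern_sums",
    "pattern_masses", "compute_D",
]


def _pattern_masks():
    """Boolean (4,4,4,4) masks of ABBA-like and BABA-like patterns.

    The transversion-only variants exclude patterns whose allele pair is a
    transition ({A,G} or {C,T}).
    """
    abba = np.zeros((4, 4, 4, 4), dtype=bool)
    baba = np.zeros((4, 4, 4, 4), dtype=bool)
    abba_tv = np.zeros((4, 4, 4, 4), dtype=bool)
    baba_tv = np.zeros((4, 4, 4, 4), dtype=bool)
    for x in range(4):
        for y in range(4):
            if x == y:
                continue
            tv = frozenset((BASES[x], BASES[y])) not in TRANSITION_PAIRS
            abba[x, y, y, x] = True
            baba[x, y, x, y] = True
            if tv:
                abba_tv[x, y, y, x] = True
                baba_tv[x, y, x, y] = True
    return abba, baba, abba_tv, baba_tv


ABBA_MASK, BABA_MASK, ABBA_TV_MASK, BABA_TV_MASK = _pattern_masks()


@dataclass(frozen=True)
class SiteTerms:
    """Per-site numerator/denominator terms and pattern probabilities."""

    X: float
    Y: float
    pABBA: float
    pBABA: float


@dataclass(frozen=True)
class BlockStats:
    """Sums of site terms over one genomic block."""

    block: int
    X: float
    Y: float
    n_sites: int


@dataclass
class DResult:
    """D-statistic with block-jackknife uncertainty.

    ``Z = D / SE``; the conventional significance threshold |Z| > 3
    corresponds to a two-tailed p-value of about 0.001.  ``Z`` and ``p``
    are NaN when the jackknife variance is zero or only one block exists.
    """

    D: float
    SE: float
    Z: float
    p: float
    n_blocks: int
    n_sites: int
    mode: str = "extended"
    abba_mass: float = float("nan")
    baba_mass: float = float("nan")
    corrections: dict = field(default_factory=dict)


def site_terms(q1, q2, q3, q4) -> SiteTerms:
    """Di-allelic site terms from focal-allele frequencies (scalars or arrays)."""
    q1, q2, q3, q4 = (np.asarray(q, dtype=float) for q in (q1, q2, q3, q4))
    X = (q1 - q2) * (q3 - q4)
    Y = (q1 + q2 - 2 * q1 * q2) * (q3 + q4 - 2 * q3 * q4)
    pABBA = q1 * q4 * (1 - q2) * (1 - q3) + (1 - q1) * (1 - q4) * q2 * q3
    pBABA = (1 - q1) * q2 * (1 - q3) * q4 + q1 * (1 - q2) * q3 * (1 - q4)
    if X.ndim == 0:
        return SiteTerms(float(X), float(Y), float(pABBA), float(pBABA))
    return SiteTerms(X, Y, pABBA, pBABA)


def pattern_terms(f1, f2, f3, f4, transversions_only: bool = False) -> SiteTerms:
    """Site terms from four 4-base frequency simplex vectors.

    The joint pattern probability factorises over populations; ABBA-like
    and BABA-like masses sum the 12 (x,y,y,x) and 12 (x,y,x,y) patterns.
    On di-allelic input this reproduces :func:`site_terms` exactly.
    """
    fs = [np.asarray(f, dtype=float) for f in (f1, f2, f3, f4)]
    for f in fs:
        if abs(f.sum() - 1.0) > 1e-6:
            raise ValueError("population base frequencies must lie on the simplex")
    t = np.einsum("a,b,c,d->abcd", *fs)
    abba_m, baba_m = (ABBA_TV_MASK, BABA_TV_MASK) if transversions_only else (ABBA_MASK, BABA_MASK)
    pABBA = float(t[abba_m].sum())
    pBABA = float(t[baba_m].sum())
    return SiteTerms(pBABA - pABBA, pBABA + pABBA, pABBA, pBABA)


def sample_one_base(pooled_counts: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample one base per site from pooled read proportions.

    ``pooled_counts`` has shape (..., 4); returns the sampled base index per
    site.  This reproduces the single-base sampling of the original
    D-statistic: the reads only define the sampling probabilities.
    """
    c = np.asarray(pooled_counts, dtype=float)
    tot = c.sum(axis=-1)
    if (tot <= 0).any():
        raise UndefinedFrequencyError("cannot sample a base from zero pooled depth")
    cdf = np.cumsum(c, axis=-1) / tot[..., None]
    u = rng.random(tot.shape)
    return (u[..., None] < cdf).argmax(axis=-1)


def genotype_freq(genotypes) -> float:
    """Focal-allele frequency from called diploid genotypes (NaN = missing)."""
    g = np.asarray(genotypes, dtype=float)
    called = ~np.isnan(g)
    if not called.any():
        raise UndefinedFrequencyError("all genotypes missing")
    return float(g[called].sum() / (2.0 * called.sum()))


def site_allele_pair(pooled_counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two most frequent bases across all pooled reads per site.

    Ties break in A<C<G<T order.  Returns (major, minor) index arrays; at
    monomorphic sites the minor allele is reported as the lowest-index
    other base (its count is zero).
    """
    c = np.asarray(pooled_counts)
    order = np.argsort(-c, axis=-1, kind="stable")
    return order[..., 0], order[..., 1]


def remove_transitions(major: np.ndarray, minor: np.ndarray) -> np.ndarray:
    """Mask of sites to keep: segregating pair is not {A,G} or {C,T}."""
    major = np.asarray(major)
    minor = np.asarray(minor)
    ag = ((major == 0) & (minor == 2)) | ((major == 2) & (minor == 0))
    ct = ((major == 1) & (minor == 3)) | ((major == 3) & (minor == 1))
    return ~(ag | ct)


def aggregate_blocks(block_index: np.ndarray, X: np.ndarray, Y: np.ndarray) -> list[BlockStats]:
    """Sum per-site terms into per-block statistics (empty blocks omitted)."""
    block_index = np.asarray(block_index)
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    out = []
    for b in np.unique(block_index):
        sel = block_index == b
        out.append(BlockStats(int(b), float(X[sel].sum()), float(Y[sel].sum()),
                              int(sel.sum())))
    return out


def jackknife_D(blocks: Sequence[BlockStats] | tuple) -> DResult:
    """D with weighted delete-one-block jackknife standard error.

    D is a ratio of block sums; the delete-m jackknife weights blocks by
    the number of usable sites they contain (given via BlockStats or as a
    third array), a strictly positive measure of block information.  With
    equal weights the estimator reduces to the textbook delete-one
    formula.  Blocks are excluded only when genuinely empty (no sites and
    no mass): per-block denominator mass can legitimately be negative
    after error or admixture correction, and selecting on its sign would
    bias the statistic, since such noise is shared between numerator and
    denominator.  SE = 0 (and Z undefined) when all leave-one-out
    estimates agree.
    """
    if isinstance(blocks, tuple):
        Xb, Yb = (np.asarray(a, dtype=float) for a in blocks[:2])
        m_sites = (np.asarray(blocks[2], dtype=float) if len(blocks) > 2
                   else np.zeros_like(Xb))
    else:
        Xb = np.array([b.X for b in blocks], dtype=float)
        Yb = np.array([b.Y for b in blocks], dtype=float)
        m_sites = np.array([b.n_sites for b in blocks], dtype=float)
    keep = (m_sites > 0) | (Xb != 0) | (Yb != 0)
    Xb, Yb, m_sites = Xb[keep], Yb[keep], m_sites[keep]
    g = len(Xb)
    totX, totY = Xb.sum(), Yb.sum()
    if g == 0 or totY <= 0:
        raise UndefinedFrequencyError("D undefined: total denominator mass is zero")
    D = totX / totY
    n_sites = int(m_sites.sum())
    if g == 1:
        return DResult(D=D, SE=float("nan"), Z=float("nan"), p=float("nan"),
                       n_blocks=1, n_sites=n_sites)
    with np.errstate(divide="ignore", invalid="ignore"):
        # if one block carries all denominator mass, its leave-one-out
        # estimate (and hence the jackknife) is undefined: SE comes out NaN
        theta_del = (totX - Xb) / (totY - Yb)
    # equal weights when site counts are absent or degenerate
    w = m_sites / m_sites.sum() if (m_sites > 0).all() else np.full(g, 1.0 / g)
    h = 1.0 / w
    theta_J = g * D - ((1.0 - w) * theta_del).sum()
    tau = h * D - (h - 1.0) * theta_del
    var = float(((tau - theta_J) ** 2 / (h - 1.0)).sum() / g)
    SE = float(np.sqrt(max(var, 0.0)))
    if SE == 0.0:
        Z = p = float("nan")
    else:
        Z = D / SE
        p = float(2.0 * norm.sf(abs(Z)))
    return DResult(D=float(D), SE=SE, Z=float(Z), p=p, n_blocks=g, n_sites=n_sites)


# ---------------------------------------------------------------------------
# vectorised pipeline
# ---------------------------------------------------------------------------

def _population_freq_vectors(counts: np.ndarray, indices: Sequence[int]) -> np.ndarray:
    """Weighted (S,4) base-frequency simplex for one population."""
    return freq_mod.population_base_freqs(counts[:, list(indices), :])


def _one_base_freq_vectors(counts, indices, rng) -> np.ndarray:
    pooled = counts[:, list(indices), :].sum(axis=1)
    ok = pooled.sum(axis=-1) > 0
    f = np.full((counts.shape[0], 4), np.nan)
    if ok.any():
        drawn = sample_one_base(pooled[ok], rng)
        fo = np.zeros((int(ok.sum()), 4))
        fo[np.arange(len(drawn)), drawn] = 1.0
        f[ok] = fo
    return f


def _genotype_freq_vectors(genotypes, anc_idx, der_idx) -> np.ndarray:
    """(S,4) simplex from true diploid genotypes and per-site allele pair."""
    g = np.asarray(genotypes, dtype=float)  # (S, N)
    q = g.sum(axis=1) / (2.0 * g.shape[1])
    f = np.zeros((len(q), 4))
    f[np.arange(len(q)), der_idx] = q
    f[np.arange(len(q)), anc_idx] += 1.0 - q
    return f


def pattern_masses(tensors: np.ndarray, transversions_only: bool = False):
    """(ABBA, BABA) mass per leading entry of (..., 4,4,4,4) pattern tensors."""
    t = np.asarray(tensors)
    abba_m, baba_m = (ABBA_TV_MASK, BABA_TV_MASK) if transversions_only else (ABBA_MASK, BABA_MASK)
    flat = t.reshape(t.shape[:-4] + (256,))
    return flat[..., abba_m.ravel()].sum(-1), flat[..., baba_m.ravel()].sum(-1)


def block_pattern_sums(freqs: Sequence[np.ndarray], block_index: np.ndarray,
                       site_mask: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Per-block sums of joint allele-pattern probabilities.

    ``freqs`` holds four (S,4) per-population simplex arrays.  Sites where
    any population frequency is undefined (NaN) are skipped.  Returns
    ``(tensors, block_ids, site_counts)`` where ``tensors`` has shape
    (B, 4, 4, 4, 4) and ``site_counts`` holds the usable sites per block
    (the jackknife weights).
    """
    f1, f2, f3, f4 = freqs
    ok = ~(np.isnan(f1).any(1) | np.isnan(f2).any(1) | np.isnan(f3).any(1)
           | np.isnan(f4).any(1))
    if site_mask is not None:
        ok &= site_mask
    block_index = np.asarray(block_index)
    blocks = np.unique(block_index[ok])
    tensors = np.zeros((len(blocks), 4, 4, 4, 4))
    site_counts = np.zeros(len(blocks), dtype=np.int64)
    for k, b in enumerate(blocks):
        sel = ok & (block_index == b)
        site_counts[k] = int(sel.sum())
        tensors[k] = np.einsum("sa,sb,sc,sd->abcd", f1[sel], f2[sel], f3[sel], f4[sel],
                               optimize=True)
    return tensors, blocks, site_counts


def _block_site_counts(block_index, ok, blocks):
    return np.array([int(((block_index == b) & ok).sum()) for b in blocks])


def compute_D(
    counts: np.ndarray,
    block_index: np.ndarray,
    populations: Mapping[str, Sequence[int]],
    *,
    mode: str = "extended",
    genotypes: Mapping[str, np.ndarray] | None = None,
    allele_pair: tuple[np.ndarray, np.ndarray] | None = None,
    remove_transitions_filter: bool = False,
    mono_outgroup: bool = False,
    error_matrices: Mapping[str, object] | None = None,
    h5: str | None = None,
    admixed: str = "H1",
    alpha: float | None = None,
    negativity_policy: str = "raw",
    min_pooled_depth: int = 1,
    seed: int | None = None,
) -> DResult:
    """Full D-statistic pipeline on a dense count tensor.

    Parameters
    ----------
    counts
        (S, I, 4) read counts; ignored (except for masking) in genotype mode.
    block_index
        Genomic block label per site (jackknife unit).
    populations
        Mapping H1..H4 (and optionally H5) to column indices into ``counts``.
    mode
        ``extended`` (weighted all-read frequencies), ``one_base`` (the
        original single-base statistic: one individual per population —
        the first configured — and one sampled read per site; requires
        ``seed``), or
        ``genotype`` (true genotypes; requires ``genotypes`` and
        ``allele_pair``).
    error_matrices
        Optional per-population mean :class:`ErrorMatrix`; group-level
        pattern correction is applied per block before any admixture
        correction.
    h5, admixed, alpha
        When given, remove a known admixture pulse of proportion ``alpha``
        from population ``admixed`` with source ``h5`` before testing.
    remove_transitions_filter
        Restrict ABBA/BABA masses to transversion allele pairs.
    negativity_policy
        Policy for negative corrected pattern mass: ``raw`` (default; keeps
        the statistic linear and unbiased) or ``clamp``.
    """
    counts = np.asarray(counts)
    S = counts.shape[0]
    labels = ("H1", "H2", "H3", "H4")

    if mode == "one_base":
        # the single-base statistic uses one individual per population;
        # its site intersection is that individual's coverage
        populations = {p: [idx[0]] for p, idx in populations.items()}

    pooled = {p: counts[:, list(populations[p]), :].sum(axis=1) for p in populations}
    mask = np.ones(S, dtype=bool)
    if mode != "genotype":
        for p in labels:
            mask &= pooled[p].sum(axis=-1) >= min_pooled_depth

    if mono_outgroup:
        h4 = pooled["H4"]
        mask &= (h4 > 0).sum(axis=-1) <= 1

    if mode == "extended":
        fv = {p: _population_freq_vectors(counts, populations[p]) for p in populations}
    elif mode == "one_base":
        if seed is None:
            raise ValueError("one_base mode needs an explicit seed")
        rng = np.random.default_rng(seed)
        fv = {p: _one_base_freq_vectors(counts, populations[p], rng) for p in populations}
    elif mode == "genotype":
        if genotypes is None or allele_pair is None:
            raise ValueError("genotype mode needs genotypes and the site allele pair")
        anc_idx, der_idx = allele_pair
        fv = {p: _genotype_freq_vectors(genotypes[p], anc_idx, der_idx) for p in genotypes}
    else:
        raise ValueError(f"unknown mode {mode!r}")

    corrections: dict = {}
    quartet = [fv[p] for p in labels]
    tensors, blocks, site_counts = block_pattern_sums(quartet, block_index, mask)

    if error_matrices:
        ems = [error_matrices.get(p) for p in labels]
        from .error import ErrorMatrix  # local to avoid cycle at import time
        ems = [m if m is not None else ErrorMatrix.identity() for m in ems]
        op = GroupErrorOperator.from_matrices(*ems)
        tensors = correct_pattern_probs(tensors, op, policy=negativity_policy)
        corrections["error"] = True

    if alpha is not None:
        if not (0.0 <= alpha < 1.0):
            raise ValueError("admixture proportion must lie in [0, 1)")
        if h5 is None:
            raise ValueError("admixture correction needs the source population h5")
        out_quartet = [fv[h5] if p == admixed else fv[p] for p in labels]
        out_tensors, out_blocks, _ = block_pattern_sums(out_quartet, block_index, mask)
        if not np.array_equal(blocks, out_blocks):
            common = np.intersect1d(blocks, out_blocks)
            keep14 = np.isin(blocks, common)
            tensors = tensors[keep14]
            site_counts = site_counts[keep14]
            out_tensors = out_tensors[np.isin(out_blocks, common)]
            blocks = common
        if error_matrices:
            from .error import ErrorMatrix
            ems_out = [error_matrices.get(h5 if p == admixed else p) for p in labels]
            ems_out = [m if m is not None else ErrorMatrix.identity() for m in ems_out]
            op_out = GroupErrorOperator.from_matrices(*ems_out)
            out_tensors = correct_pattern_probs(out_tensors, op_out, policy=negativity_policy)
        tensors = (tensors - alpha * out_tensors) / (1.0 - alpha)
        corrections["admixture_alpha"] = float(alpha)

    if remove_transitions_filter:
        corrections["transversions_only"] = True
    abba_b, baba_b = pattern_masses(tensors, transversions_only=remove_transitions_filter)
    Xb = baba_b - abba_b
    Yb = baba_b + abba_b
    result = jackknife_D((Xb, Yb, site_counts))
    result.mode = mode
    result.corrections = corrections
    result.abba_mass = float(abba_b.sum())
    result.baba_mass = float(baba_b.sum())
    result.n_sites = int(mask.sum())
    return result
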