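"""Replicate-level drivers for the simulated validation scenarios.

These compose the simulator with the statistic pipeline the way the
published validation experiments do: one function call runs one replicate
(simulate, estimate what must be estimated, correct, jackknife) and
returns the quantities a power or calibration study records.  They are
used by the test suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import dstat, freq
from .data_model import INGROUP_LABELS, UndefinedFrequencyError
from .error import ErrorMatrix, GroupErrorOperator, estimate_error_matrix, \
    mean_population_error
from .introgression import AlphaEstimate, corrected_D, estimate_alpha
from .simulate import SimulatedData, scenario_preset, simulate_dataset, \
    simulate_error_trio, substream

QUARTET = INGROUP_LABELS


def quartet_block_tensors(data: SimulatedData, order=QUARTET, extra_mask=None,
                          min_pooled_depth: int = 1):
    """Per-block pattern-mass tensors for a population ordering.

    Applies the usable-site rule (pooled depth >= ``min_pooled_depth`` in
    each of H1..H4) regardless of the ordering requested, so the tested
    tree and any substituted tree are computed over identical sites.
    """
    pops = data.scenario.population_indices()
    counts = data.counts.counts
    mask = np.ones(counts.shape[0], dtype=bool)
    for p in QUARTET:
        mask &= counts[:, pops[p], :].sum(axis=(1, 2)) >= min_pooled_depth
    if extra_mask is not None:
        mask &= extra_mask
    fv = [freq.population_base_freqs(counts[:, pops[p], :]) for p in order]
    return dstat.block_pattern_sums(fv, data.block_index, mask)


def null_replicate_Z(seed: int, n_blocks: int = 20, sites_per_block: int = 2000,
                     depth: float = 2.0) -> float:
    """Z-score of one no-gene-flow replicate (calibration study unit)."""
    sc = scenario_preset("fig2A", n_blocks=n_blocks, sites_per_block=sites_per_block,
                         depth=depth)
    data = simulate_dataset(sc, seed=seed)
    res = dstat.compute_D(data.counts.counts, data.block_index,
                          sc.population_indices(), mode="extended")
    return res.Z


def migration_replicate(seed: int, migration_rescaled: float, depth: float,
                        n_blocks: int = 20, sites_per_block: int = 2000,
                        modes=("extended", "one_base", "genotype")) -> dict:
    """Z-scores of the three statistic flavours on one migration replicate."""
    sc = scenario_preset("fig2A", migration_rescaled=migration_rescaled,
                         n_blocks=n_blocks, sites_per_block=sites_per_block,
                         depth=depth)
    data = simulate_dataset(sc, seed=seed)
    pops = sc.population_indices()
    out = {}
    for mode in modes:
        kw = {}
        if mode == "one_base":
            kw["seed"] = int(substream(seed, "one_base").integers(2 ** 31))
        if mode == "genotype":
            kw.update(genotypes=data.genotypes,
                      allele_pair=(data.anc_base, data.der_base))
        try:
            res = dstat.compute_D(data.counts.counts, data.block_index, pops,
                                  mode=mode, **kw)
            out[mode] = res.Z
        except UndefinedFrequencyError:
            # at very low depth the single-individual statistic can run out
            # of usable sites entirely: no evidence, no rejection
            out[mode] = float("nan")
    return out


@dataclass
class ErrorReplicate:
    """One error-injection replicate: uncorrected vs corrected statistic."""

    Z_uncorrected: float
    Z_corrected: float
    estimated_matrices: dict[str, ErrorMatrix]


def error_replicate(seed: int, n_blocks: int = 40, sites_per_block: int = 100_000,
                    trio_sites: int = 1_000_000,
                    min_pooled_depth: int = 2) -> ErrorReplicate:
    """Run one no-gene-flow replicate with A->G errors in H1 and H3.

    Each individual's error matrix is estimated from its own simulated
    ((T,R),O) trio (error-free individuals get a near-identity estimate),
    population means feed the group-level 256-pattern correction, applied
    per block before the jackknife.  The trio uses a genome-scale site
    count: the residual bias of the correction scales with the product of
    the monomorphic-site count and the matrix-estimation error, so
    under-powered trios leak a per-replicate offset into the corrected
    statistic that the jackknife cannot see.

    The usable-site rule here requires two pooled reads per population
    rather than one.  A population represented by a single erroneous read
    contributes a full unit of spurious pattern mass; at full genomic
    scale such coincidences are numerous enough to average out, but at
    desk scale they are rare single events that leave the corrected
    statistic heavy-tailed.  Requiring two reads bounds the per-site mass
    at 0.25 while keeping the error bias of the uncorrected statistic
    decisive.
    """
    sc = scenario_preset("fig2B", n_blocks=n_blocks, sites_per_block=sites_per_block)
    data = simulate_dataset(sc, seed=seed)

    tensors, _, n_sites = quartet_block_tensors(data, min_pooled_depth=min_pooled_depth)
    abba, baba = dstat.pattern_masses(tensors)
    res_unc = dstat.jackknife_D((baba - abba, baba + abba, n_sites))

    mats: dict[str, ErrorMatrix] = {}
    for ind in sc.individuals:
        true_e = sc.error_matrices.get(ind, ErrorMatrix.identity())
        rng = substream(seed, f"trio:{ind}")
        counts_T, counts_R = simulate_error_trio(true_e, trio_sites, rng)
        mats[ind] = estimate_error_matrix(counts_T, counts_R)
    pop_means = {
        p: mean_population_error([mats[ind] for ind in sc.individuals
                                  if ind.startswith(p + "_")])
        for p in QUARTET
    }
    op = GroupErrorOperator.from_matrices(*[pop_means[p] for p in QUARTET])
    corrected = op.apply_inverse(tensors)
    abba_c, baba_c = dstat.pattern_masses(corrected)
    res_corr = dstat.jackknife_D((baba_c - abba_c, baba_c + abba_c, n_sites))
    return ErrorReplicate(Z_uncorrected=res_unc.Z, Z_corrected=res_corr.Z,
                          estimated_matrices=mats)


@dataclass
class IntrogressionReplicate:
    """One external-introgression replicate (pulse from H5 into H1)."""

    Z_uncorrected: float
    Z_corrected: float
    alpha: AlphaEstimate | None


def introgression_replicate(seed: int, n_blocks: int = 20,
                            sites_per_block: int = 2000, alpha_true: float = 0.1,
                            estimate: bool = True) -> IntrogressionReplicate:
    """Run one replicate of the H5->H1 admixture scenario.

    The tested tree T1:4 and the substituted tree Tout (H5 in H1's slot)
    are evaluated over the same usable sites; the corrected statistic uses
    the true pulse proportion, and the proportion is optionally
    re-estimated by root-finding on D_un.
    """
    sc = scenario_preset("fig2C", alpha=alpha_true, n_blocks=n_blocks,
                         sites_per_block=sites_per_block)
    data = simulate_dataset(sc, seed=seed)
    t14, b14, n_sites = quartet_block_tensors(data, order=QUARTET)
    tout, bout, _ = quartet_block_tensors(data, order=("H5", "H2", "H3", "H4"))
    assert np.array_equal(b14, bout)
    abba, baba = dstat.pattern_masses(t14)
    res_unc = dstat.jackknife_D((baba - abba, baba + abba, n_sites))
    res_corr = corrected_D(t14, tout, alpha_true, site_counts=n_sites)
    est = estimate_alpha(t14, tout) if estimate else None
    return IntrogressionReplicate(Z_uncorrected=res_unc.Z, Z_corrected=res_corr.Z,
                                  alpha=est)
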