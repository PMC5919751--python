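"""Desk-scale synthetic data for the four(+one)-population tests.

The generator reproduces the structure the D-statistic probes without a
full coalescent: per-site ancestral allele frequencies are drawn from a
neutral-SFS-like density (proportional to 1/x), drift along each branch of
the population tree is Balding-Nichols with fixation index
F = 1 - exp(-t / 2Ne), admixture/migration pulses replace a fraction of
the target's frequency with the source's, diploid genotypes are binomial
draws from population frequencies, per-site read depth is Poisson, and
reads pass through per-individual type-specific error matrices.  Sites are
unlinked; genomic blocks are coordinate assignments used by the jackknife.

Times are expressed in units of 4Ne generations (the ms convention), so a
branch of duration tau has F = 1 - exp(-2 tau).

Three presets mirror the published validation scenarios:

``fig2A``
    (((H1,H2)H3)H4), splits at 0.5/0.75/1.0, with a migration pulse from
    H3 into H1 at 0.2 equivalent to a per-generation migration fraction
    m over a 0.001 x 4Ne-generation window (rescaled rate M = 4 Ne m; the
    grid 0..280 corresponds to 0..0.7%).
``fig2B``
    The same quartet without gene flow, two diploids per population, with
    an A->G error of 0.005 injected in every individual of H1 and H3;
    monomorphic sites are included (errors act on them too) at a
    desk-scale mixture ratio chosen to preserve the full-scale balance of
    error signal to polymorphism noise (see
    :data:`FIG2B_SEGREGATING_FRACTION`).
``fig2C``
    A fifth population H5, splitting at the root, whose sister branch
    (split 0.2) admixes into H1 at time 0.1 with proportion 0.1.  In a
    frequency-drift model all variation originates at the root, so the
    very deep outgroup split of the coalescent version is represented by a
    root at 1.25: H5 remains strongly diverged from the quartet
    (path F ~ 0.97) while within-quartet polymorphism survives, and the
    admixing branch drifts away from sampled H5 between the split and the
    pulse, as in the original scenario.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .data_model import BASES, CountData
from .error import ErrorMatrix

#: fraction of simulated sites that are polymorphic in the error-injection
#: scenario.  The bias a type-specific error induces grows linearly with
#: the number of (mostly monomorphic) sites while the sampling noise of
#: the statistic grows with the square root of the number of polymorphic
#: sites, so a desk-scale replica must preserve the ratio of error signal
#: to polymorphism noise rather than the per-bp SNP density of a full
#: 5-Mb region; 5e-5 over 2e6 sites keeps the uncorrected statistic as
#: decisively biased as it is at full scale.
FIG2B_SEGREGATING_FRACTION = 5e-5


def substream(seed, name: str) -> np.random.Generator:
    """Named child RNG stream derived from a single master seed."""
    tag = zlib.crc32(name.encode()) % (2 ** 31)
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2 ** 31), tag]))


@dataclass(frozen=True)
class Pulse:
    """Instantaneous unidirectional admixture: at ``time`` (4Ne units ago),
    a fraction ``rate`` of ``target`` is replaced by ``source``."""

    time: float
    target: str
    source: str
    rate: float


@dataclass
class SimulationScenario:
    """A population tree with drift, pulses, sampling and sequencing noise.

    ``joins`` are backward-in-time merge events (time, child, parent) as in
    ms: looking forward, the child lineage originates from the parent at
    that time.  Populations with ``sample_sizes`` 0 (e.g. an unsampled
    admixture source branch) participate in events but emit no data.
    """

    populations: tuple[str, ...]
    sample_sizes: dict[str, int]
    joins: tuple[tuple[float, str, str], ...]
    pulses: tuple[Pulse, ...] = ()
    Ne: int = 10_000
    depth: float = 2.0
    error_matrices: dict[str, ErrorMatrix] = field(default_factory=dict)
    n_blocks: int = 200
    sites_per_block: int = 400
    block_size: int = 5_000_000
    segregating_fraction: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("mean depth must be positive")
        for p in self.pulses:
            if not (0.0 <= p.rate < 1.0):
                raise ValueError("pulse rate must lie in [0, 1)")
        times = {t for t, _, _ in self.joins}
        for p in self.pulses:
            child_birth = {c: t for t, c, _ in self.joins}
            for pop in (p.target, p.source):
                if pop in child_birth and p.time > child_birth[pop]:
                    raise ValueError(
                        f"pulse at {p.time} involves {pop} before it exists "
                        f"(splits at {child_birth[pop]})"
                    )
        del times

    @property
    def individuals(self) -> list[str]:
        return [f"{p}_{i}" for p in self.populations
                for i in range(self.sample_sizes.get(p, 0))]

    def individual_population(self) -> dict[str, str]:
        return {f"{p}_{i}": p for p in self.populations
                for i in range(self.sample_sizes.get(p, 0))}

    def population_indices(self) -> dict[str, list[int]]:
        inds = self.individuals
        pop_of = self.individual_population()
        out: dict[str, list[int]] = {p: [] for p in self.populations
                                     if self.sample_sizes.get(p, 0)}
        for i, ind in enumerate(inds):
            out[pop_of[ind]].append(i)
        return out


@dataclass
class SimulatedData:
    """Counts plus the ground truth behind them."""

    counts: CountData
    block_index: np.ndarray
    freqs: dict[str, np.ndarray]  # derived-allele frequency per population
    genotypes: dict[str, np.ndarray]  # (S, N) derived-allele dosage
    anc_base: np.ndarray  # (S,) base index
    der_base: np.ndarray
    scenario: SimulationScenario


# ---------------------------------------------------------------------------
# allele-frequency drift
# ---------------------------------------------------------------------------

def sfs_ancestral_freq(n: int, Ne: int, rng: np.random.Generator) -> np.ndarray:
    """Ancestral derived-allele frequencies from a 1/x density on
    [1/(2Ne), 1 - 1/(2Ne)] (inverse-CDF sampling)."""
    xmin = 1.0 / (2 * Ne)
    xmax = 1.0 - xmin
    u = rng.random(n)
    return xmin * (xmax / xmin) ** u


def drift(p: np.ndarray, duration: float, rng: np.random.Generator) -> np.ndarray:
    """Balding-Nichols drift of frequencies ``p`` for ``duration`` (4Ne units).

    F = 1 - exp(-2 * duration); frequencies at 0 or 1 stay fixed, and
    F -> 1 degenerates to fixation (Bernoulli(p)).
    """
    p = np.asarray(p, dtype=float)
    if duration < 0:
        raise ValueError("negative branch duration")
    F = 1.0 - np.exp(-2.0 * duration)
    if F <= 0.0:
        return p.copy()
    out = p.copy()
    interior = (p > 0.0) & (p < 1.0)
    if F >= 1.0 - 1e-12:
        out[interior] = rng.binomial(1, p[interior]).astype(float)
        return out
    c = (1.0 - F) / F
    a = np.maximum(p[interior] * c, 1e-12)
    b = np.maximum((1.0 - p[interior]) * c, 1e-12)
    out[interior] = rng.beta(a, b)
    return out


def _order_tied_joins(events, root):
    """Reorder events so that within a tied time stamp every join's parent
    already exists (created by the root or an earlier join)."""
    out = []
    exists = {root}
    pending = list(events)
    while pending:
        t0 = pending[0][0]
        group = [e for e in pending if e[0] == t0]
        rest = [e for e in pending if e[0] != t0]
        progress = True
        while group and progress:
            progress = False
            for e in list(group):
                if e[2][0] != "join" or e[2][2] in exists:
                    out.append(e)
                    group.remove(e)
                    if e[2][0] == "join":
                        exists.add(e[2][1])
                    progress = True
        out.extend(group)  # unresolvable: surfaced later as a missing parent
        pending = rest
    return out


def simulate_freqs(scenario: SimulationScenario, n_sites: int,
                   rng: np.random.Generator) -> dict[str, np.ndarray]:
    """True per-site derived-allele frequencies for every sampled population.

    The tree is traversed forward in time from the deepest join; each
    lineage drifts between the events that involve it.  A pulse replaces
    the target frequency by (1-rate)*target + rate*source.
    """
    if not scenario.joins:
        raise ValueError("scenario needs at least one join event")
    children = {c for _, c, _ in scenario.joins}
    roots = {p for _, _, p in scenario.joins} - children
    if len(roots) != 1:
        raise ValueError(f"join events must define a single tree root, got {roots}")
    (root,) = roots
    events: list[tuple[float, int, tuple]] = []
    for t, child, parent in scenario.joins:
        events.append((t, 0, ("join", child, parent)))
    for p in scenario.pulses:
        events.append((p.time, 1, ("pulse", p.target, p.source, p.rate)))
    events.sort(key=lambda e: (-e[0], e[1]))
    # joins sharing a time stamp must create parents before their children
    events = _order_tied_joins(events, root)

    root_time = max(t for t, _, _ in scenario.joins)
    state: dict[str, np.ndarray] = {root: sfs_ancestral_freq(n_sites, scenario.Ne, rng)}
    t_last: dict[str, float] = {root: root_time}

    def advance(pop: str, t: float) -> None:
        dt = t_last[pop] - t
        if dt > 0:
            state[pop] = drift(state[pop], dt, rng)
            t_last[pop] = t

    for t, _, ev in events:
        if ev[0] == "join":
            _, child, parent = ev
            if parent not in state:
                raise ValueError(f"join parent {parent} does not exist at time {t}")
            advance(parent, t)
            state[child] = state[parent].copy()
            t_last[child] = t
        else:
            _, target, source, rate = ev
            if rate == 0.0:
                continue  # a zero-rate pulse is a no-op (same RNG stream)
            advance(target, t)
            advance(source, t)
            state[target] = (1.0 - rate) * state[target] + rate * state[source]
    for pop in scenario.populations:
        if pop not in state:
            raise ValueError(f"population {pop} never created by a join event")
        advance(pop, 0.0)
    return {p: state[p] for p in scenario.populations
            if scenario.sample_sizes.get(p, 0) > 0}


def _segregating(freqs: Mapping[str, np.ndarray]) -> np.ndarray:
    stack = np.stack(list(freqs.values()))
    return (stack.max(axis=0) > 0.0) & (stack.min(axis=0) < 1.0)


def simulate_segregating_freqs(scenario: SimulationScenario, n_sites: int,
                               rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Like :func:`simulate_freqs` but retaining only sites whose true
    frequencies segregate across populations."""
    collected: dict[str, list[np.ndarray]] = {}
    got = 0
    while got < n_sites:
        chunk = max(int((n_sites - got) * 1.4) + 64, 256)
        freqs = simulate_freqs(scenario, chunk, rng)
        keep = _segregating(freqs)
        for p, x in freqs.items():
            collected.setdefault(p, []).append(x[keep])
        got += int(keep.sum())
    return {p: np.concatenate(parts)[:n_sites] for p, parts in collected.items()}


def _simulate_sample_segregating(scenario: SimulationScenario, n_sites: int,
                                 rng_freq: np.random.Generator,
                                 rng_geno: np.random.Generator):
    """Frequencies and genotypes conditioned on sample polymorphism.

    "Segregating" means segregating in the sampled genotypes, as in
    coalescent-simulator output: under an SFS-like frequency density most
    true variants are too rare to be sampled at all, and sites that are
    monomorphic in the sample carry no pattern information.
    """
    sampled = [p for p in scenario.populations if scenario.sample_sizes.get(p, 0) > 0]
    freq_parts: dict[str, list[np.ndarray]] = {p: [] for p in sampled}
    geno_parts: dict[str, list[np.ndarray]] = {p: [] for p in sampled}
    total_copies = 2 * sum(scenario.sample_sizes[p] for p in sampled)
    got = 0
    while got < n_sites:
        # sample-level acceptance is low for rare variants: large chunks
        chunk = max(int((n_sites - got) * 4) + 256, 1024)
        freqs = simulate_freqs(scenario, chunk, rng_freq)
        genos = simulate_genotypes(freqs, scenario.sample_sizes, rng_geno)
        dosage = sum(genos[p].sum(axis=1) for p in sampled)
        keep = (dosage > 0) & (dosage < total_copies)
        for p in sampled:
            freq_parts[p].append(freqs[p][keep])
            geno_parts[p].append(genos[p][keep])
        got += int(keep.sum())
    freqs = {p: np.concatenate(freq_parts[p])[:n_sites] for p in sampled}
    genos = {p: np.concatenate(geno_parts[p])[:n_sites] for p in sampled}
    return freqs, genos


# ---------------------------------------------------------------------------
# genotypes and reads
# ---------------------------------------------------------------------------

def simulate_genotypes(freqs: Mapping[str, np.ndarray], sample_sizes: Mapping[str, int],
                       rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Diploid derived-allele dosages: genotype ~ Binomial(2, freq)."""
    out = {}
    for pop, x in freqs.items():
        n = sample_sizes.get(pop, 0)
        if n:
            out[pop] = rng.binomial(2, np.clip(x, 0.0, 1.0)[:, None],
                                    size=(len(x), n)).astype(np.int8)
    return out


def simulate_reads(genotypes: np.ndarray, anc_base: np.ndarray, der_base: np.ndarray,
                   depth: float, error: ErrorMatrix | None,
                   rng: np.random.Generator) -> np.ndarray:
    """Reads for one individual: depth ~ Poisson, allele ~ dosage/2, then the
    type-specific error channel.  Returns (S, 4) base counts."""
    g = np.asarray(genotypes)
    S = len(g)
    n = rng.poisson(depth, S)
    # derived-allele reads: dosage 0/2 are deterministic, only hets sample
    k_der = np.where(g == 2, n, 0)
    het = g == 1
    if het.any():
        k_der[het] = rng.binomial(n[het], 0.5)
    k_anc = n - k_der
    counts = np.zeros((S, 4), dtype=np.int64)
    e = None if error is None or np.allclose(error.e, np.eye(4)) else error.e
    for true_k, base_idx in ((k_der, der_base), (k_anc, anc_base)):
        for b in range(4):
            sel = base_idx == b
            if not sel.any():
                continue
            row = None if e is None else e[b]
            if row is None or row[b] == 1.0:
                counts[sel, b] += true_k[sel]
                continue
            support = np.flatnonzero(row > 0)
            if len(support) == 2:
                # two-outcome rows (one specific miscall) go through a
                # binomial draw, much cheaper than a full multinomial
                other = int(support[support != b][0]) if b in support else None
                if other is not None:
                    k_err = rng.binomial(true_k[sel], row[other])
                    counts[sel, b] += true_k[sel] - k_err
                    counts[sel, other] += k_err
                    continue
            counts[sel] += rng.multinomial(true_k[sel], row)
    return counts


def _site_positions(n_blocks: int, sites_per_block: int, block_size: int):
    """Evenly spaced 1-based positions tiling ``n_blocks`` blocks."""
    within = np.floor((np.arange(sites_per_block) + 0.5) * block_size
                      / sites_per_block).astype(np.int64) + 1
    pos = np.concatenate([b * block_size + within for b in range(n_blocks)])
    block_index = np.repeat(np.arange(n_blocks), sites_per_block)
    return pos, block_index


def simulate_dataset(scenario: SimulationScenario, seed: int | None = None) -> SimulatedData:
    """End-to-end generation: frequencies, genotypes, reads, coordinates.

    All randomness flows from one seed through named sub-streams, so the
    output is bit-reproducible.
    """
    if seed is None:
        seed = scenario.seed
    if seed is None:
        raise ValueError("a seed is required for reproducible simulation")
    S_block = scenario.sites_per_block
    S = scenario.n_blocks * S_block
    rng_tree = substream(seed, "tree")
    rng_sites = substream(seed, "sites")
    rng_geno = substream(seed, "genotypes")

    n_seg = int(round(scenario.segregating_fraction * S))
    sampled = [p for p in scenario.populations if scenario.sample_sizes.get(p, 0) > 0]
    freqs = {p: np.zeros(S) for p in sampled}
    genotypes = {p: np.zeros((S, scenario.sample_sizes[p]), dtype=np.int8)
                 for p in sampled}
    if n_seg:
        freqs_seg, genos_seg = _simulate_sample_segregating(
            scenario, n_seg, rng_tree, rng_geno)
        seg_idx = np.sort(rng_sites.choice(S, size=n_seg, replace=False)) \
            if n_seg < S else np.arange(S)
        for p in sampled:
            freqs[p][seg_idx] = freqs_seg[p]
            genotypes[p][seg_idx] = genos_seg[p]

    anc = rng_sites.integers(0, 4, S)
    der = (anc + rng_sites.integers(1, 4, S)) % 4

    pos, block_index = _site_positions(scenario.n_blocks, S_block, scenario.block_size)
    individuals = scenario.individuals
    counts = np.zeros((S, len(individuals), 4), dtype=np.int64)
    col = 0
    for p in sampled:
        for i in range(scenario.sample_sizes[p]):
            ind = f"{p}_{i}"
            rng_reads = substream(seed, f"reads:{ind}")
            counts[:, col, :] = simulate_reads(
                genotypes[p][:, i], anc, der, scenario.depth,
                scenario.error_matrices.get(ind), rng_reads)
            col += 1

    data = CountData(individuals=tuple(individuals),
                     chrom=np.repeat(np.array(["1"]), S),
                     pos=pos, counts=counts)
    return SimulatedData(counts=data, block_index=block_index, freqs=freqs,
                         genotypes=genotypes, anc_base=anc, der_base=der,
                         scenario=scenario)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def migration_percent(rescaled_rate: float, Ne: int = 10_000) -> float:
    """Per-generation migrant fraction (in %) from an ms-style rescaled
    rate M = 4 Ne m; M = 280 with Ne = 10000 gives 0.7%."""
    return rescaled_rate / (4.0 * Ne) * 100.0


def pulse_equivalent_fraction(m_per_generation: float, generations: float) -> float:
    """Total replaced fraction of a pulse equivalent to continuous
    migration at rate m over a window: 1 - (1 - m)^G."""
    return 1.0 - (1.0 - m_per_generation) ** generations


def scenario_preset(name: str, **overrides) -> SimulationScenario:
    """Published validation scenarios (see module docstring).

    ``fig2A`` accepts ``migration_rescaled`` (ms-style M, grid 0..280) or a
    direct ``migration_percent_per_gen``; other keyword arguments override
    scenario fields (e.g. ``n_blocks=20`` for desk scale).
    """
    Ne = int(overrides.pop("Ne", 10_000))
    if name == "fig2A":
        M = float(overrides.pop("migration_rescaled", 0.0))
        m_pct = float(overrides.pop("migration_percent_per_gen", migration_percent(M, Ne)))
        window_gen = 0.001 * 4 * Ne  # ms window [0.2, 0.201]
        rate = pulse_equivalent_fraction(m_pct / 100.0, window_gen)
        pulses = (Pulse(0.2, "H1", "H3", rate),) if rate > 0 else ()
        base = SimulationScenario(
            populations=("H1", "H2", "H3", "H4"),
            sample_sizes={p: 5 for p in ("H1", "H2", "H3", "H4")},
            joins=((0.5, "H1", "H2"), (0.75, "H2", "H3"), (1.0, "H3", "H4")),
            pulses=pulses, Ne=Ne, depth=2.0, n_blocks=200, sites_per_block=400,
            segregating_fraction=1.0,
        )
    elif name == "fig2B":
        rate = float(overrides.pop("error_rate", 0.005))
        err = ErrorMatrix.single_error("A", "G", rate)
        sizes = {p: 2 for p in ("H1", "H2", "H3", "H4")}
        mats = {f"{p}_{i}": err for p in ("H1", "H3") for i in range(sizes[p])}
        spb = int(overrides.pop("sites_per_block", 100_000))
        base = SimulationScenario(
            populations=("H1", "H2", "H3", "H4"),
            sample_sizes=sizes,
            joins=((0.5, "H1", "H2"), (0.75, "H2", "H3"), (1.0, "H3", "H4")),
            Ne=Ne, depth=2.0, error_matrices=mats, n_blocks=20,
            sites_per_block=spb,
            segregating_fraction=FIG2B_SEGREGATING_FRACTION,
        )
    elif name == "fig2C":
        alpha = float(overrides.pop("alpha", 0.1))
        sizes = {p: 5 for p in ("H1", "H2", "H3", "H4", "H5")}
        sizes["SRC"] = 0
        base = SimulationScenario(
            populations=("H1", "H2", "H3", "H4", "H5", "SRC"),
            sample_sizes=sizes,
            joins=((0.25, "H1", "H2"), (0.5, "H2", "H3"), (0.75, "H3", "H4"),
                   (0.2, "SRC", "H5"), (1.25, "H4", "H5")),
            pulses=(Pulse(0.1, "H1", "SRC", alpha),),
            Ne=Ne, depth=2.0, n_blocks=200, sites_per_block=400,
            segregating_fraction=1.0,
        )
    else:
        raise ValueError(f"unknown preset {name!r}; available: fig2A, fig2B, fig2C")
    if overrides.pop("sample_size", None) is not None:
        raise ValueError("override per-population sizes via sample_sizes=dict")
    sizes = overrides.pop("sample_sizes", None)
    if sizes is not None:
        merged = dict(base.sample_sizes)
        merged.update(sizes)
        base = replace(base, sample_sizes=merged)
    return replace(base, **overrides)


# ---------------------------------------------------------------------------
# error-estimation trio
# ---------------------------------------------------------------------------

def simulate_error_trio(error: ErrorMatrix, n_sites: int,
                        rng: np.random.Generator, depth: float = 5.0,
                        divergence_out: float = 0.01,
                        divergence_in: float = 0.005) -> tuple[np.ndarray, np.ndarray]:
    """Count tables for the ((T,R),O) error-estimation design.

    Each site has a uniformly random true ancestral base; the lineages to O
    and to each of T and R substitute it with the given probabilities
    (uniformly to another base).  T's reads (Poisson depth) pass through
    ``error``; R is error-free and contributes its true base.  Returns
    (counts_T_vs_O, counts_R_vs_O), 4x4 with rows = outgroup base and
    columns = observed base.  Because T and R sit at equal distance from O,
    their true-base distributions conditional on the outgroup base agree,
    which is the premise of the estimator.
    """
    anc = rng.integers(0, 4, n_sites)

    def mutate(base, prob):
        hit = rng.random(n_sites) < prob
        shifted = (base + rng.integers(1, 4, n_sites)) % 4
        return np.where(hit, shifted, base)

    o = mutate(anc, divergence_out)
    t_true = mutate(anc, divergence_in)
    r_true = mutate(anc, divergence_in)

    counts_R = np.zeros((4, 4), dtype=np.int64)
    np.add.at(counts_R, (o, r_true), 1)

    n_reads = rng.poisson(depth, n_sites)
    counts_T = np.zeros((4, 4), dtype=np.int64)
    for b in range(4):
        sel = t_true == b
        if not sel.any():
            continue
        reads = rng.multinomial(n_reads[sel], error.e[b])  # (m, 4)
        np.add.at(counts_T, o[sel], reads)
    return counts_T, counts_R
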