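"""Simulator: drift law, sampling layers, presets and an independent
coalescent cross-check."""

import numpy as np
import pytest

from abbababa.dstat import compute_D
from abbababa.error import ErrorMatrix
from abbababa.simulate import (
    Pulse,
    SimulationScenario,
    drift,
    migration_percent,
    pulse_equivalent_fraction,
    scenario_preset,
    sfs_ancestral_freq,
    simulate_dataset,
    simulate_freqs,
    simulate_genotypes,
    simulate_reads,
    substream,
)


class TestDrift:
    def test_zero_duration_is_identity(self, rng):
        p = rng.random(100)
        assert np.array_equal(drift(p, 0.0, rng), p)

    def test_mean_preserved_and_variance_matches_fixation_index(self, rng):
        """Balding-Nichols: E[x'] = x and Var[x'] = F x(1-x) with
        F = 1 - exp(-2 tau)."""
        p0, tau, n = 0.3, 0.25, 200_000
        x = drift(np.full(n, p0), tau, rng)
        F = 1 - np.exp(-2 * tau)
        mc_se = x.std() / np.sqrt(n)
        assert abs(x.mean() - p0) < 3 * mc_se
        v = F * p0 * (1 - p0)
        assert x.var() == pytest.approx(v, rel=0.03)

    def test_between_population_divergence_oracle(self, rng):
        """Two populations split tau ago: E[(x1-x2)^2] = 2 F p(1-p)."""
        p0, tau, n = 0.4, 0.2, 200_000
        x1 = drift(np.full(n, p0), tau, rng)
        x2 = drift(np.full(n, p0), tau, rng)
        F = 1 - np.exp(-2 * tau)
        assert ((x1 - x2) ** 2).mean() == pytest.approx(2 * F * p0 * (1 - p0),
                                                        rel=0.05)

    def test_fixed_frequencies_stay_fixed(self, rng):
        p = np.array([0.0, 1.0, 0.5])
        out = drift(p, 50.0, rng)
        assert out[0] == 0.0 and out[1] == 1.0
        assert out[2] in (0.0, 1.0)  # F ~ 1: fixation

    def test_sfs_density_bounds(self, rng):
        x = sfs_ancestral_freq(10_000, 10_000, rng)
        assert x.min() >= 1 / 20_000 and x.max() <= 1 - 1 / 20_000
        # 1/x density: median at sqrt(xmin * xmax)
        assert np.median(x) == pytest.approx(np.sqrt(x.min() * 1.0), rel=0.5)


class TestTreeTraversal:
    def quartet(self, **kw):
        defaults = dict(
            populations=("H1", "H2", "H3", "H4"),
            sample_sizes={p: 1 for p in ("H1", "H2", "H3", "H4")},
            joins=((0.5, "H1", "H2"), (0.75, "H2", "H3"), (1.0, "H3", "H4")),
        )
        defaults.update(kw)
        return SimulationScenario(**defaults)

    def test_zero_length_branches_copy_parent(self, rng):
        sc = self.quartet(joins=((0.0, "H1", "H2"), (0.0, "H2", "H3"),
                                 (0.0, "H3", "H4")))
        freqs = simulate_freqs(sc, 500, rng)
        assert np.array_equal(freqs["H1"], freqs["H4"])

    def test_zero_rate_pulse_identical_to_no_event(self):
        sc0 = self.quartet()
        sc1 = self.quartet(pulses=(Pulse(0.2, "H1", "H3", 0.0),))
        f0 = simulate_freqs(sc0, 300, substream(9, "tree"))
        f1 = simulate_freqs(sc1, 300, substream(9, "tree"))
        for p in f0:
            assert np.array_equal(f0[p], f1[p])

    def test_full_rate_pulse_copies_source(self, rng):
        sc = self.quartet(pulses=(Pulse(0.2, "H1", "H3", 0.999999),))
        freqs = simulate_freqs(sc, 2000, rng)
        # H1 is now essentially H3 at the pulse time plus later drift of H3:
        # correlation with H3 should far exceed correlation with H2
        c13 = np.corrcoef(freqs["H1"], freqs["H3"])[0, 1]
        c12 = np.corrcoef(freqs["H1"], freqs["H2"])[0, 1]
        assert c13 > c12

    def test_pulse_before_target_exists_rejected(self):
        with pytest.raises(ValueError, match="before it exists"):
            self.quartet(pulses=(Pulse(0.7, "H1", "H3", 0.1),))


class TestSamplingLayers:
    def test_fixed_frequency_gives_homozygotes(self, rng):
        g = simulate_genotypes({"P": np.ones(50)}, {"P": 3}, rng)["P"]
        assert (g == 2).all()

    def test_binomial_genotype_mean(self, rng):
        n = 100_000
        g = simulate_genotypes({"P": np.full(n, 0.5)}, {"P": 1}, rng)["P"]
        assert abs(g.mean() - 1.0) < 3 * g.std() / np.sqrt(n)

    def test_poisson_depth_and_pure_reads(self, rng):
        n = 20_000
        genos = np.full(n, 2, dtype=np.int8)
        anc = np.zeros(n, dtype=np.int64)
        der = np.full(n, 3, dtype=np.int64)  # derived = T
        counts = simulate_reads(genos, anc, der, 5.0, None, rng)
        assert counts[:, [0, 1, 2]].sum() == 0  # all reads carry the derived base
        depth = counts.sum(axis=1)
        assert abs(depth.mean() - 5.0) < 3 * depth.std() / np.sqrt(n)

    def test_type_specific_error_fraction(self, rng):
        n = 400_000
        genos = np.full(n, 2, dtype=np.int8)
        anc = np.full(n, 1, dtype=np.int64)
        der = np.zeros(n, dtype=np.int64)  # derived = A, all reads truly A
        e = ErrorMatrix.single_error("A", "G", 0.005)
        counts = simulate_reads(genos, anc, der, 2.0, e, rng)
        total = counts.sum()
        frac_g = counts[:, 2].sum() / total
        assert abs(frac_g - 0.005) < 3 * np.sqrt(0.005 / total)

    def test_zero_coverage_fraction_matches_poisson_mass(self, rng):
        n = 50_000
        counts = simulate_reads(np.zeros(n, dtype=np.int8), np.zeros(n, dtype=int),
                                np.ones(n, dtype=int), 0.2, None, rng)
        frac0 = (counts.sum(axis=1) == 0).mean()
        assert frac0 == pytest.approx(np.exp(-0.2), abs=3 * np.sqrt(0.2 / n) + 0.01)


class TestPresets:
    def test_migration_unit_conversion(self):
        assert migration_percent(280, 10_000) == pytest.approx(0.7)
        assert migration_percent(40, 10_000) == pytest.approx(0.1)

    def test_fig2a_pulse_fraction_matches_window(self):
        sc = scenario_preset("fig2A", migration_rescaled=280)
        (pulse,) = sc.pulses
        assert pulse.target == "H1" and pulse.source == "H3"
        assert pulse.rate == pytest.approx(pulse_equivalent_fraction(0.007, 40))

    def test_fig2b_injects_errors_in_h1_h3_only(self):
        sc = scenario_preset("fig2B")
        assert set(sc.error_matrices) == {"H1_0", "H1_1", "H3_0", "H3_1"}
        assert sc.error_matrices["H1_0"].e[0, 2] == 0.005

    def test_fig2c_has_admixture_event(self):
        sc = scenario_preset("fig2C")
        (pulse,) = sc.pulses
        assert (pulse.target, pulse.rate) == ("H1", 0.1)
        assert sc.sample_sizes["SRC"] == 0  # unsampled source branch

    def test_overrides_leave_other_fields_unchanged(self):
        base = scenario_preset("fig2A")
        mod = scenario_preset("fig2A", n_blocks=20)
        assert mod.n_blocks == 20
        assert mod.joins == base.joins
        assert mod.sites_per_block == base.sites_per_block

    def test_unknown_preset_lists_options(self):
        with pytest.raises(ValueError, match="fig2A"):
            scenario_preset("fig9Z")


class TestDeterminism:
    def test_same_seed_same_dataset(self):
        sc = scenario_preset("fig2A", n_blocks=4, sites_per_block=200)
        a = simulate_dataset(sc, seed=5)
        b = simulate_dataset(sc, seed=5)
        assert np.array_equal(a.counts.counts, b.counts.counts)
        assert np.array_equal(a.genotypes["H1"], b.genotypes["H1"])

    def test_different_seeds_differ(self):
        sc = scenario_preset("fig2A", n_blocks=4, sites_per_block=200)
        a = simulate_dataset(sc, seed=5)
        b = simulate_dataset(sc, seed=6)
        assert not np.array_equal(a.counts.counts, b.counts.counts)

    def test_high_depth_estimates_converge_to_truth(self):
        sc = scenario_preset("fig2A", n_blocks=2, sites_per_block=400, depth=200.0)
        data = simulate_dataset(sc, seed=8)
        from abbababa.freq import population_base_freqs
        pops = sc.population_indices()
        f = population_base_freqs(data.counts.counts[:, pops["H1"], :])
        q_der = f[np.arange(len(f)), data.der_base]
        assert np.corrcoef(q_der, data.freqs["H1"])[0, 1] > 0.99


class TestCoalescentCrossCheck:
    """Independent oracle: the same quartet simulated with msprime."""

    def _msprime_counts(self, migration):
        msprime = pytest.importorskip("msprime")
        Ne = 10_000
        demography = msprime.Demography()
        for name in ("H1", "H2", "H3", "H4", "A12", "A123", "A1234"):
            demography.add_population(name=name, initial_size=Ne)
        demography.add_population_split(time=0.5 * 4 * Ne, derived=["H1", "H2"],
                                        ancestral="A12")
        demography.add_population_split(time=0.75 * 4 * Ne, derived=["A12", "H3"],
                                        ancestral="A123")
        demography.add_population_split(time=1.0 * 4 * Ne, derived=["A123", "H4"],
                                        ancestral="A1234")
        if migration:
            # forward-time gene flow H3 -> H1: backward, H1 lineages jump to H3
            demography.add_mass_migration(time=0.2 * 4 * Ne, source="H1",
                                          dest="H3", proportion=migration)
        demography.sort_events()
        samples = {p: 5 for p in ("H1", "H2", "H3", "H4")}
        counts_blocks = []
        geno_blocks = []
        for rep, ts in enumerate(msprime.sim_ancestry(
                samples=samples, demography=demography, sequence_length=1_000_000,
                recombination_rate=1e-8, num_replicates=8, random_seed=97)):
            ts = msprime.sim_mutations(ts, rate=1e-8, random_seed=101 + rep,
                                       model=msprime.BinaryMutationModel())
            G = ts.genotype_matrix()  # (sites, 40 haplotypes)
            geno = G.reshape(G.shape[0], -1, 2).sum(axis=2)  # diploid dosage
            geno_blocks.append(geno)
        rng = np.random.default_rng(55)
        all_counts, blocks = [], []
        for b, geno in enumerate(geno_blocks):
            S = geno.shape[0]
            anc = np.zeros(S, dtype=int)
            der = np.full(S, 1, dtype=int)  # code alleles as A/C
            counts = np.zeros((S, 20, 4), dtype=np.int64)
            for i in range(20):
                counts[:, i, :] = simulate_reads(geno[:, i].astype(np.int8), anc,
                                                 der, 2.0, None, rng)
            all_counts.append(counts)
            blocks.append(np.full(S, b))
        return np.concatenate(all_counts), np.concatenate(blocks)

    def test_null_quartet_is_calibrated(self):
        counts, blocks = self._msprime_counts(migration=0.0)
        pops = {f"H{k + 1}": list(range(5 * k, 5 * k + 5)) for k in range(4)}
        res = compute_D(counts, blocks, pops, mode="extended")
        assert abs(res.Z) < 4.5

    def test_gene_flow_h3_to_h1_gives_positive_baba_excess(self):
        counts, blocks = self._msprime_counts(migration=0.15)
        pops = {f"H{k + 1}": list(range(5 * k, 5 * k + 5)) for k in range(4)}
        res = compute_D(counts, blocks, pops, mode="extended")
        assert res.D > 0 and res.Z > 3
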