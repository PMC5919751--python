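"""Core statistic: site terms, pattern terms, jackknife and pipeline."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from abbababa.data_model import BASES, UndefinedFrequencyError
from abbababa.dstat import (
    BlockStats,
    aggregate_blocks,
    compute_D,
    genotype_freq,
    jackknife_D,
    pattern_terms,
    remove_transitions,
    sample_one_base,
    site_allele_pair,
    site_terms,
)

unit = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


def brute_force_pattern_terms(f1, f2, f3, f4):
    """Independent oracle: enumerate all 256 joint patterns explicitly."""
    pabba = pbaba = 0.0
    for a, b, c, d in itertools.product(range(4), repeat=4):
        p = f1[a] * f2[b] * f3[c] * f4[d]
        if a == d and b == c and a != b:
            pabba += p
        if a == c and b == d and a != b:
            pbaba += p
    return pabba, pbaba


class TestSiteTerms:
    def test_pure_baba_configuration(self):
        t = site_terms(1, 0, 1, 0)
        assert (t.X, t.Y, t.pBABA, t.pABBA) == (1.0, 1.0, 1.0, 0.0)

    @given(unit, unit, unit)
    def test_equal_ingroup_frequencies_give_zero_numerator(self, q, q3, q4):
        assert site_terms(q, q, q3, q4).X == 0.0

    def test_half_frequencies(self):
        t = site_terms(0.5, 0.5, 0.5, 0.5)
        assert (t.X, t.Y) == (0.0, 0.25)

    @given(unit, unit, unit, unit)
    def test_numerator_denominator_are_pattern_difference_and_sum(self, q1, q2, q3, q4):
        t = site_terms(q1, q2, q3, q4)
        assert abs(t.X - (t.pBABA - t.pABBA)) < 1e-12
        assert abs(t.Y - (t.pBABA + t.pABBA)) < 1e-12

    @given(unit, unit, unit, unit)
    def test_allele_relabelling_invariance(self, q1, q2, q3, q4):
        t = site_terms(q1, q2, q3, q4)
        s = site_terms(1 - q1, 1 - q2, 1 - q3, 1 - q4)
        assert t.X == pytest.approx(s.X, abs=1e-12)
        assert t.Y == pytest.approx(s.Y, abs=1e-12)

    @given(unit, unit, unit, unit)
    def test_numerator_bounded_by_denominator(self, q1, q2, q3, q4):
        t = site_terms(q1, q2, q3, q4)
        assert abs(t.X) <= t.Y + 1e-12


class TestPatternTerms:
    def test_pure_abba(self):
        dA = np.eye(4)[0]
        dC = np.eye(4)[1]
        t = pattern_terms(dA, dC, dC, dA)
        assert t.pABBA == pytest.approx(1.0)
        assert t.X == pytest.approx(-1.0)

    def test_uniform_frequencies_against_enumeration(self):
        u = np.full(4, 0.25)
        t = pattern_terms(u, u, u, u)
        pabba, pbaba = brute_force_pattern_terms(u, u, u, u)
        assert pabba == pytest.approx(12 / 256)
        assert t.pABBA == pytest.approx(pabba, abs=1e-12)
        assert t.pBABA == pytest.approx(pbaba, abs=1e-12)
        assert t.X == pytest.approx(0.0, abs=1e-12)

    def test_random_simplexes_against_enumeration(self, rng):
        for _ in range(25):
            fs = rng.dirichlet(np.ones(4), size=4)
            t = pattern_terms(*fs)
            pabba, pbaba = brute_force_pattern_terms(*fs)
            assert t.pABBA == pytest.approx(pabba, abs=1e-12)
            assert t.pBABA == pytest.approx(pbaba, abs=1e-12)

    def test_diallelic_input_matches_scalar_site_terms(self, rng):
        for _ in range(50):
            q = rng.random(4)
            fs = [np.array([qi, 1 - qi, 0.0, 0.0]) for qi in q]
            t = pattern_terms(*fs)
            s = site_terms(*q)
            assert t.X == pytest.approx(s.X, abs=1e-12)
            assert t.Y == pytest.approx(s.Y, abs=1e-12)

    def test_simplex_violation_rejected(self):
        with pytest.raises(ValueError):
            pattern_terms([0.5, 0.5, 0.5, 0.0], *[np.full(4, 0.25)] * 3)


class TestOneBaseSampling:
    def test_degenerate_counts_always_yield_that_base(self, rng):
        drawn = sample_one_base(np.tile([5, 0, 0, 0], (100, 1)), rng)
        assert (drawn == 0).all()

    def test_proportional_sampling_matches_binomial(self, rng):
        n = 100_000
        drawn = sample_one_base(np.tile([1, 1, 0, 0], (n, 1)), rng)
        frac_a = (drawn == 0).mean()
        assert abs(frac_a - 0.5) < 3 * 0.5 / np.sqrt(n)

    def test_fixed_seed_reproducible(self):
        counts = np.random.default_rng(3).integers(0, 5, (50, 4)) + 1
        a = sample_one_base(counts, np.random.default_rng(11))
        b = sample_one_base(counts, np.random.default_rng(11))
        assert (a == b).all()

    def test_zero_depth_rejected(self, rng):
        with pytest.raises(UndefinedFrequencyError):
            sample_one_base(np.zeros((3, 4)), rng)


class TestGenotypeFreq:
    @pytest.mark.parametrize("genos,expected", [
        ([2, 2], 1.0), ([0, 1, 1], 1 / 3), ([1], 0.5),
    ])
    def test_dosage_ratio(self, genos, expected):
        assert genotype_freq(genos) == pytest.approx(expected)

    def test_missing_handled(self):
        assert genotype_freq([2, np.nan]) == 1.0
        with pytest.raises(UndefinedFrequencyError):
            genotype_freq([np.nan, np.nan])


class TestTransitionRemoval:
    def test_transition_pairs_dropped_transversions_kept(self):
        major = np.array([0, 0, 1, 2])  # A A C G
        minor = np.array([2, 1, 3, 0])  # G C T A
        keep = remove_transitions(major, minor)
        assert keep.tolist() == [False, True, False, False]

    def test_major_minor_ties_break_alphabetically(self):
        major, minor = site_allele_pair(np.array([[2, 2, 0, 0], [0, 1, 1, 0]]))
        assert major.tolist() == [0, 1]
        assert minor.tolist() == [1, 2]


class TestBlocks:
    def test_single_site_blocks_equal_site_terms(self):
        blocks = aggregate_blocks([0, 1], [0.5, -0.25], [0.5, 0.25])
        assert blocks[0] == BlockStats(0, 0.5, 0.5, 1)
        assert blocks[1] == BlockStats(1, -0.25, 0.25, 1)

    def test_terms_add_within_a_block(self):
        (b,) = aggregate_blocks([3, 3], [1.0, -1.0], [1.0, 1.0])
        assert (b.X, b.Y, b.n_sites) == (0.0, 2.0, 2)

    def test_block_boundaries_tile_from_position_one(self):
        from abbababa.data_model import CountData
        data = CountData(("i",), np.array(["1"] * 3),
                         np.array([1, 5_000_000, 5_000_001]),
                         np.zeros((3, 1, 4), dtype=np.int64))
        assert data.block_index(5_000_000).tolist() == [0, 0, 1]


class TestJackknife:
    def textbook_delete_one(self, Xb, Yb):
        """Independent implementation of the unweighted delete-1 jackknife."""
        g = len(Xb)
        theta = Xb.sum() / Yb.sum()
        loo = np.array([(Xb.sum() - Xb[i]) / (Yb.sum() - Yb[i]) for i in range(g)])
        var = (g - 1) / g * ((loo - loo.mean()) ** 2).sum()
        return theta, np.sqrt(var)

    def test_equal_weight_blocks_match_textbook_formula(self, rng):
        Xb = rng.normal(0, 0.3, 24)
        Yb = np.full(24, 2.0)
        res = jackknife_D((Xb, Yb))
        theta, se = self.textbook_delete_one(Xb, Yb)
        assert res.D == pytest.approx(theta, abs=1e-12)
        assert res.SE == pytest.approx(se, rel=1e-9)

    def test_identical_blocks_give_zero_variance_and_undefined_Z(self):
        res = jackknife_D((np.full(10, 0.5), np.full(10, 1.0)))
        assert res.SE == 0.0
        assert np.isnan(res.Z) and np.isnan(res.p)

    def test_single_block_has_undefined_se(self):
        res = jackknife_D((np.array([1.0]), np.array([2.0])))
        assert res.D == 0.5 and np.isnan(res.SE)

    def test_zero_total_denominator_rejected(self):
        with pytest.raises(UndefinedFrequencyError):
            jackknife_D((np.zeros(3), np.zeros(3)))

    def test_d_bounded_by_one_on_valid_blocks(self, rng):
        # per-site |X| <= Y carries through sums, so |D| <= 1 always
        for _ in range(50):
            Y = rng.random(8) + 1e-3
            X = (2 * rng.random(8) - 1) * Y
            res = jackknife_D((X, Y))
            assert abs(res.D) <= 1.0 + 1e-12


class TestComputeD:
    def _null_counts(self, rng, S=400, per_pop=2, depth=3.0):
        counts = rng.poisson(depth, (S, 4 * per_pop, 4)) * 0
        # all reads are base A everywhere: H1 == H2 identically
        counts[:, :, 0] = rng.poisson(depth, (S, 4 * per_pop))
        pops = {f"H{k + 1}": list(range(k * per_pop, (k + 1) * per_pop))
                for k in range(4)}
        return counts, pops

    def test_identical_ingroups_give_zero_numerator(self, rng):
        counts, pops = self._null_counts(rng)
        blocks = np.arange(400) // 40
        with pytest.raises(UndefinedFrequencyError):
            # monomorphic data: denominator mass is exactly zero
            compute_D(counts, blocks, pops, mode="extended")

    def test_genotype_mode_under_exact_null_gives_zero_D(self):
        """H1 and H2 with identical per-site frequencies: numerator vanishes."""
        S = 200
        rng = np.random.default_rng(5)
        g_in = rng.integers(0, 3, (S, 2))
        g_out = rng.integers(0, 3, (S, 2))
        genos = {"H1": g_in, "H2": g_in.copy(), "H3": g_out, "H4": g_out[:, ::-1]}
        counts = np.ones((S, 8, 4), dtype=np.int64)
        pops = {f"H{k + 1}": [2 * k, 2 * k + 1] for k in range(4)}
        anc = np.zeros(S, dtype=int)
        der = np.ones(S, dtype=int)
        res = compute_D(counts, np.arange(S) % 4, pops, mode="genotype",
                        genotypes=genos, allele_pair=(anc, der))
        assert res.D == pytest.approx(0.0, abs=1e-12)

    def test_single_read_individuals_make_extended_equal_one_base(self, rng):
        """With one individual per population and exactly one read each, the
        weighted frequency is the single read, which is also the only
        possible one-base draw."""
        S = 600
        counts = np.zeros((S, 4, 4), dtype=np.int64)
        base = rng.integers(0, 2, (S, 4))  # A or C
        for i in range(4):
            counts[np.arange(S), i, base[:, i]] = 1
        pops = {f"H{k + 1}": [k] for k in range(4)}
        blocks = np.arange(S) // 60
        ext = compute_D(counts, blocks, pops, mode="extended")
        one = compute_D(counts, blocks, pops, mode="one_base", seed=123)
        assert ext.D == pytest.approx(one.D, abs=1e-12)
        assert ext.SE == pytest.approx(one.SE, rel=1e-9)

    def test_transversion_filter_removes_transition_signal(self, rng):
        """Data whose only BABA-like signal sits on an A/G pair loses all
        mass under transversion filtering."""
        S = 200
        counts = np.zeros((S, 4, 4), dtype=np.int64)
        counts[:, 0, 0] = 1  # H1: A
        counts[:, 1, 2] = 1  # H2: G
        counts[:, 2, 0] = 1  # H3: A
        counts[:, 3, 2] = 1  # H4: G
        pops = {f"H{k + 1}": [k] for k in range(4)}
        blocks = np.arange(S) // 20
        plain = compute_D(counts, blocks, pops, mode="extended")
        assert plain.D == pytest.approx(1.0)
        with pytest.raises(UndefinedFrequencyError):
            compute_D(counts, blocks, pops, mode="extended",
                      remove_transitions_filter=True)

    def test_mono_outgroup_restriction_drops_polyallelic_outgroup_sites(self, rng):
        S = 100
        counts = np.zeros((S, 4, 4), dtype=np.int64)
        counts[:, :3, 0] = 2
        counts[:, 3, 0] = 1
        counts[: S // 2, 3, 1] = 1  # half the sites: outgroup sees two bases
        counts[S // 2:, 0, 1] = 1  # the rest: H1 and H3 share a C variant
        counts[S // 2:, 2, 1] = 1
        pops = {f"H{k + 1}": [k] for k in range(4)}
        res = compute_D(counts, np.arange(S) % 5, pops, mode="extended",
                        mono_outgroup=True)
        assert res.n_sites == S // 2
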