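import numpy as np
import pandas as pd
import pytest

import panelsmith as ps
from conftest import make_matrix
from oracles import brute_force_site_pi, tajimas_d_oracle, wc_fst_oracle


class TestSitePi:
    def test_balanced_counts(self):
        # 2 hom-ref, 2 hom-alt: allele counts 4/4 would be n=8; use two
        # samples het+het -> counts 2/2, pi = 4/6
        g = make_matrix(np.array([[1], [1]]))
        assert ps.site_pi(g, 0) == pytest.approx(4 / 6)

    def test_monomorphic(self):
        g = make_matrix(np.array([[0], [0], [0]]))
        assert ps.site_pi(g, 0) == 0.0

    def test_unbalanced_counts_brute_force(self):
        # one het + one hom-alt -> counts ref=1, alt=3
        g = make_matrix(np.array([[1], [2]]))
        assert ps.site_pi(g, 0) == pytest.approx(0.5)
        assert ps.site_pi(g, 0) == pytest.approx(brute_force_site_pi([0, 1, 1, 1]))

    def test_matches_pairwise_enumeration(self, rng):
        """Formula equals exhaustive mean pairwise difference for random
        sites with <= 20 samples."""
        for _ in range(25):
            n = int(rng.integers(2, 21))
            calls = rng.choice([0, 1, 2, -1], size=(n, 1), p=[0.3, 0.3, 0.3, 0.1])
            alleles = []
            for c in calls[:, 0]:
                if c != -1:
                    alleles += [0, 0] if c == 0 else ([0, 1] if c == 1 else [1, 1])
            if len(alleles) < 2:
                continue
            g = make_matrix(calls)
            assert ps.site_pi(g, 0) == pytest.approx(brute_force_site_pi(alleles))

    def test_too_few_alleles(self):
        g = make_matrix(np.array([[-1], [-1]]))
        with pytest.raises(ValueError):
            ps.site_pi(g, 0)


class TestWindowedPi:
    def test_per_bp_scaling(self):
        g = make_matrix(np.array([[1], [1]]), start_pos=50_000)
        df = ps.windowed_pi(g, {"chr1": 100_000}, window=100_000, step=100_000)
        assert len(df) == 1
        assert df["pi"][0] == pytest.approx((4 / 6) / 100_000)

    def test_empty_window_zero(self):
        g = make_matrix(np.array([[1], [1]]), start_pos=50_000)
        df = ps.windowed_pi(g, {"chr1": 300_000}, window=100_000, step=100_000)
        assert df["pi"][1] == 0.0 and df["n_snps"][1] == 0

    def test_sliding_site_in_ten_windows(self):
        g = make_matrix(np.array([[1], [1]]), start_pos=150_000)
        df = ps.windowed_pi(g, {"chr1": 400_000}, window=100_000, step=10_000)
        assert (df["n_snps"] > 0).sum() == 10

    def test_fragment_matches_window(self):
        g = make_matrix(np.array([[1], [1]]), start_pos=50_000)
        win = ps.windowed_pi(g, {"chr1": 100_000}, window=100_000, step=100_000)
        frag = ps.fragment_pi(g, [("chr1", 0, 100_000)])
        assert frag["pi"][0] == pytest.approx(win["pi"][0])

    def test_empty_fragment_zero(self):
        g = make_matrix(np.array([[1], [1]]), start_pos=50_000)
        frag = ps.fragment_pi(g, [("chr1", 200_000, 300_000)])
        assert frag["pi"][0] == 0.0


class TestFst:
    def test_identical_populations_near_zero(self, rng):
        # W&C carries a small negative finite-sample term of order
        # -1/(2n) when the groups coincide, so n must be large enough
        # for the |Fst| < 0.01 check to be meaningful
        calls = rng.choice([0, 1, 2], size=(100, 150), p=[0.25, 0.5, 0.25])
        calls = np.vstack([calls, calls])  # pop2 duplicates pop1
        g = make_matrix(calls)
        pops = {f"s{i}": ("A" if i < 100 else "B") for i in range(200)}
        assert abs(ps.fst_wc_global(g, pops)) < 0.01

    def test_fixed_difference_is_one(self):
        calls = np.vstack([np.zeros((10, 50)), np.full((10, 50), 2)])
        g = make_matrix(calls)
        pops = {f"s{i}": ("A" if i < 10 else "B") for i in range(20)}
        assert ps.fst_wc_global(g, pops) == pytest.approx(1.0)

    def test_matches_independent_transcription(self, rng):
        """Vectorized variance components equal a scalar per-site oracle
        coded independently from the same published formulas."""
        from panelsmith.popgen_eval import _wc_components

        calls = rng.choice([0, 1, 2], size=(20, 40), p=[0.4, 0.4, 0.2])
        g = make_matrix(calls)
        pops = {f"s{i}": ("A" if i < 10 else "B") for i in range(20)}
        a, b, c, usable = _wc_components(g, pops)
        for j in range(40):
            gp = [calls[:10, j], calls[10:, j]]
            p_all = np.concatenate(gp).sum() / (2 * 20)
            if p_all in (0.0, 1.0):
                continue
            ao, bo, co = wc_fst_oracle(gp)
            assert a[j] == pytest.approx(ao, abs=1e-12)
            assert b[j] == pytest.approx(bo, abs=1e-12)
            assert c[j] == pytest.approx(co, abs=1e-12)

    def test_windowed_flags_empty(self, pop_matrix):
        g, pops, _ = pop_matrix
        dfw, fst = ps.fst_wc(g, pops, {"chr1": 30_000, "chr2": 20_000},
                             window=5_000, step=5_000)
        assert np.isfinite(fst)
        empty = dfw[dfw["n_snps"] == 0]
        assert empty["fst"].isna().all()


class TestTajimasD:
    def test_no_segregating_sites_nan(self):
        g = make_matrix(np.zeros((5, 10)))
        assert np.isnan(ps.tajimas_d(g))

    def test_singletons_give_negative_d(self):
        # every site: one het sample among 10 -> all variants singletons
        calls = np.zeros((10, 20), dtype=int)
        for j in range(20):
            calls[j % 10, j] = 1
        g = make_matrix(calls)
        assert ps.tajimas_d(g) < 0

    def test_matches_closed_form_oracle(self):
        """D for a constructed region equals the independently
        transcribed constants formula at the same (n, S, theta_pi)."""
        rng = np.random.default_rng(5)
        calls = rng.choice([0, 1, 2], size=(5, 12), p=[0.5, 0.3, 0.2])
        g = make_matrix(calls)
        from panelsmith.variant_qc import allele_counts

        ref, alt = allele_counts(g)
        seg = (ref > 0) & (alt > 0)
        S = int(seg.sum())
        n = 10
        theta_pi = brute = 0.0
        for j in np.nonzero(seg)[0]:
            alleles = []
            for c in calls[:, j]:
                alleles += [0, 0] if c == 0 else ([0, 1] if c == 1 else [1, 1])
            theta_pi += brute_force_site_pi(alleles)
        expected = tajimas_d_oracle(n, S, theta_pi)
        assert ps.tajimas_d(g) == pytest.approx(expected)

    def test_neutral_coalescent_d_near_zero(self):
        """|D| is small on average under neutral constant-size msprime
        simulations (independent coalescent oracle)."""
        import msprime

        ds = []
        for seed in range(1, 11):
            ts = msprime.sim_ancestry(
                samples=25, sequence_length=2e5, recombination_rate=1e-8,
                population_size=1e4, random_seed=seed,
            )
            ts = msprime.sim_mutations(ts, rate=1e-8, random_seed=seed)
            gmat = ts.genotype_matrix()  # (sites, haplotypes)
            bial = [i for i in range(gmat.shape[0]) if set(gmat[i]) <= {0, 1}]
            gmat = gmat[bial]
            if gmat.shape[0] < 5:
                continue
            # pair haplotypes into diploids
            calls = (gmat[:, ::2] + gmat[:, 1::2]).T
            pos = [int(ts.site(i).position) + 1 for i in bial]
            sites = []
            seen = set()
            keep = []
            for k, p in enumerate(pos):
                if p in seen:
                    continue
                seen.add(p)
                keep.append(k)
                sites.append(ps.SiteRecord("chr1", p, "A", "G"))
            g = ps.GenotypeMatrix(
                [f"s{i}" for i in range(calls.shape[0])], sites,
                calls[:, keep].astype(np.int8),
            )
            ds.append(ps.tajimas_d(g))
        assert len(ds) >= 5
        assert abs(np.mean(ds)) < 0.5


class TestConcordance:
    def _win(self, vals):
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.arange(len(vals)) * 1000,
                "end": np.arange(1, len(vals) + 1) * 1000,
                "n_snps": 5,
                "pi": vals,
            }
        )

    def test_identity_r_one(self):
        w = self._win([1.0, 2.0, 3.0, 4.0])
        r, n = ps.concordance(w, w)
        assert r == pytest.approx(1.0) and n == 4

    def test_anticorrelated(self):
        a = self._win([1.0, 2.0, 3.0, 4.0])
        b = self._win([4.0, 3.0, 2.0, 1.0])
        r, _ = ps.concordance(a, b)
        assert r == pytest.approx(-1.0)

    def test_noise_attenuation(self, rng):
        x = rng.normal(0, 1, 200)
        noise_sd = 0.5
        y = x + rng.normal(0, noise_sd, 200)
        r, _ = ps.concordance(self._win(x), self._win(y))
        expected = 1 / np.sqrt(1 + noise_sd**2)  # analytic attenuation
        assert r == pytest.approx(expected, abs=0.1)

    def test_too_few_windows(self):
        w = self._win([1.0, 2.0])
        with pytest.raises(ValueError):
            ps.concordance(w, w)


def test_fst_recovers_balding_nichols_divergence(small_genome):
    """Genome-wide W&C Fst recovers the island-model F parameter."""
    ests = []
    for seed in range(3):
        g, pops, _ = ps.simulate_population(
            ps.PopulationConfig(n_pops=2, samples_per_pop=50, n_snps=1000,
                                divergence_F=0.1, maf_floor=0.05),
            small_genome, seed=100 + seed,
        )
        ests.append(ps.fst_wc_global(g, pops))
    assert np.mean(ests) == pytest.approx(0.1, abs=0.03)


def test_chip_fragments_inflate_pi(small_genome):
    """Restricting to high-MAF chip fragments inflates mean pi relative
    to the genome-wide value, as expected when low-frequency variants
    are excluded by design."""
    g, pops, _ = ps.simulate_population(
        ps.PopulationConfig(n_pops=1, samples_per_pop=40, n_snps=800,
                            divergence_F=0.0, maf_floor=0.02),
        small_genome, seed=77,
    )
    stats = ps.sites_stats(g)
    chip = stats["maf"] > 0.35
    frag_len = 200
    frags = [
        (s.chrom, max(s.pos - frag_len // 2, 0), s.pos + frag_len // 2)
        for s, m in zip(g.sites, chip) if m
    ]
    chip_pi = ps.fragment_pi(g, frags)["pi"].mean()
    genome_pi = ps.windowed_pi(
        g, {c: l for c, l in small_genome.lengths.items()},
        window=10_000, step=10_000,
    )["pi"].mean()
    assert chip_pi > genome_pi
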