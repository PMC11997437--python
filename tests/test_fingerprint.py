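import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import panelsmith as ps
from conftest import make_matrix


def _panel_on(chrom_sites, rng):
    """chrom_sites: {chrom: [pos, ...]}; random pic in [0.455, 0.5]."""
    sites, pics = [], []
    for chrom, positions in chrom_sites.items():
        for p in positions:
            sites.append(ps.SiteRecord(chrom, int(p), "A", "G"))
            pics.append(rng.uniform(0.455, 0.5))
    order = sorted(range(len(sites)), key=lambda i: (sites[i].chrom, sites[i].pos))
    sites = [sites[i] for i in order]
    stats = pd.DataFrame(
        {"pic_chip": np.array(pics)[order], "maf": np.array(pics)[order] / 2 + 0.25}
    )
    return ps.Panel(sites, stats, window_size=100_000)


class TestSelectFingerprint:
    def test_panel_of_exactly_k_retained(self, rng):
        panel = _panel_on({"chr1": np.arange(1, 11) * 200_000}, rng)
        fs = ps.select_fingerprint(panel, {"chr1": 2_500_000}, k=10, min_gap=1_000)
        assert len(fs) == 10

    def test_min_gap_excludes_close_pair(self, rng):
        panel = _panel_on({"chr1": [100_000, 100_001, 500_000, 900_000]}, rng)
        fs = ps.select_fingerprint(panel, {"chr1": 1_000_000}, k=3, min_gap=1_000)
        positions = sorted(s.pos for s in fs.loci)
        assert len(fs) == 3
        assert 100_000 in positions or 100_001 in positions
        assert not (100_000 in positions and 100_001 in positions)

    def test_proportional_allocation_15_chroms(self, rng):
        lengths = {f"c{i:02d}": (10 + i) * 1_000_000 for i in range(15)}
        chrom_sites = {
            c: rng.choice(np.arange(1, L, 10_000), size=80, replace=False)
            for c, L in lengths.items()
        }
        panel = _panel_on(chrom_sites, rng)
        fs = ps.select_fingerprint(panel, lengths, k=384, min_gap=10_000)
        assert len(fs) == 384
        counts = {c: sum(1 for s in fs.loci if s.chrom == c) for c in lengths}
        total_len = sum(lengths.values())
        for c, L in lengths.items():
            expected = 384 * L / total_len
            assert abs(counts[c] - expected) <= 1

    def test_loci_subset_of_panel(self, rng):
        panel = _panel_on({"chr1": np.arange(1, 21) * 50_000}, rng)
        fs = ps.select_fingerprint(panel, {"chr1": 1_100_000}, k=5, min_gap=10_000)
        panel_keys = {s.key for s in panel.sites}
        assert all(s.key in panel_keys for s in fs.loci)

    def test_too_small_panel_errors(self, rng):
        panel = _panel_on({"chr1": [100, 200]}, rng)
        with pytest.raises(ValueError):
            ps.select_fingerprint(panel, {"chr1": 1_000}, k=10, min_gap=1)


class TestQRProfile:
    @given(
        st.lists(st.sampled_from([0, 1, 2, -1]), min_size=1, max_size=400),
    )
    @settings(max_examples=50, deadline=None)
    def test_round_trip_identity(self, genotypes):
        prof = ps.encode_qr(np.array(genotypes), "X")
        assert np.array_equal(ps.decode_qr(prof), np.array(genotypes))

    def test_all_missing_round_trips(self):
        v = np.full(384, -1)
        prof = ps.encode_qr(v, "m")
        assert (prof.matrix[:-1].reshape(-1)[: 2 * 384] == 1).all()
        assert np.array_equal(ps.decode_qr(prof), v)

    def test_every_single_cell_flip_detected(self, rng):
        v = rng.choice([0, 1, 2, -1], size=96)
        prof = ps.encode_qr(v, "c")
        rows, cols = prof.matrix.shape
        for r in range(rows):
            for ccol in range(cols):
                corrupted = ps.QRProfile(prof.sample, prof.n_loci,
                                         prof.matrix.copy(), prof.version)
                corrupted.matrix[r, ccol] ^= 1
                with pytest.raises(ps.QRChecksumError):
                    ps.decode_qr(corrupted)

    def test_json_round_trip(self, rng):
        v = rng.choice([0, 1, 2, -1], size=384)
        prof = ps.encode_qr(v, "sampleA")
        prof2 = ps.QRProfile.from_json(prof.to_json())
        assert np.array_equal(ps.decode_qr(prof2), v)
        assert prof2.sample == "sampleA"


def _gene_drop_pairs(rng, k=384, n_pairs=50):
    """Simulated genotype pairs per relationship class at high-MAF loci."""
    p = rng.uniform(0.35, 0.5, k)
    out = {"clone": [], "parent_offspring": [], "full_sib": [], "unrelated": []}
    for _ in range(n_pairs):
        hapA = rng.binomial(1, p, (2, k))
        hapB = rng.binomial(1, p, (2, k))
        hapC = rng.binomial(1, p, (2, k))
        gA, gB = hapA.sum(0), hapB.sum(0)
        pick = lambda h: h[rng.integers(2, size=k), np.arange(k)]
        child1 = pick(hapA) + pick(hapB)
        child2 = pick(hapA) + pick(hapB)
        out["clone"].append((gA, gA.copy()))
        out["parent_offspring"].append((gA, child1))
        out["full_sib"].append((child1, child2))
        out["unrelated"].append((gA, hapC.sum(0)))
    return p, out


class TestIbdMom:
    def test_self_pihat_is_one(self, rng):
        p = rng.uniform(0.35, 0.5, 384)
        g = rng.binomial(2, p)
        est = ps.ibd_mom(g, g, p, n_alleles=400)
        assert est.pihat == 1.0

    def test_gene_drop_recovery(self, rng):
        p, pairs = _gene_drop_pairs(rng, n_pairs=30)
        means = {}
        for klass, lst in pairs.items():
            vals = [ps.ibd_mom(a, b, p, n_alleles=400).pihat for a, b in lst]
            means[klass] = np.mean(vals)
        assert means["clone"] >= 0.99
        assert means["parent_offspring"] == pytest.approx(0.5, abs=0.05)
        # bounding z to [0, 1] leaves a small positive floor at 384 loci
        # (raw moment estimates are unbiased; see docs/methods.md)
        assert abs(means["unrelated"]) < 0.1
        z0_po = np.mean(
            [ps.ibd_mom(a, b, p, n_alleles=400).z0 for a, b in pairs["parent_offspring"]]
        )
        assert z0_po < 0.05

    def test_low_confidence_flag(self, rng):
        p = rng.uniform(0.35, 0.5, 30)
        g = rng.binomial(2, p)
        est = ps.ibd_mom(g, g, p)
        assert est.low_confidence

    def test_missing_loci_skipped(self, rng):
        p = rng.uniform(0.35, 0.5, 384)
        g = rng.binomial(2, p)
        g2 = g.copy()
        g2[:100] = -1
        est = ps.ibd_mom(g, g2, p, n_alleles=400)
        assert est.n_informative == 284


class TestClassification:
    def _est(self, pihat, z0=0.0):
        z2 = max(pihat - (1 - pihat - z0) / 2, 0)
        return ps.IBDEstimate(("a", "b"), z0, 1 - z0 - z2, z2, pihat, 384)

    def test_clone_threshold(self):
        assert ps.classify_relationship(self._est(0.98)).klass == "clone_or_bud_sport"

    def test_parent_offspring(self):
        assert ps.classify_relationship(self._est(0.5, z0=0.01)).klass == "parent_offspring"

    def test_full_sib_like(self):
        assert ps.classify_relationship(self._est(0.5, z0=0.2)).klass == "first_degree_other"

    def test_unrelated(self):
        assert ps.classify_relationship(self._est(0.05)).klass == "unrelated"

    def test_related_band(self):
        assert ps.classify_relationship(self._est(0.25)).klass == "related"


class TestCloneGroups:
    def _call(self, a, b, klass="clone_or_bud_sport"):
        return ps.RelationshipCall((a, b), klass, 0.95, (0, 0, 1))

    def test_transitive_closure(self):
        groups = ps.clone_groups([self._call("A", "B"), self._call("B", "C")])
        assert groups == [{"A", "B", "C"}]

    def test_no_edges_empty(self):
        calls = [self._call("A", "B", klass="unrelated")]
        assert ps.clone_groups(calls) == []

    def test_three_planted_duplicate_pairs(self, rng):
        """A cohort with 3 duplicated samples yields exactly 3 groups of 2."""
        p = rng.uniform(0.35, 0.5, 384)
        genos = [rng.binomial(2, p) for _ in range(10)]
        samples = [f"v{i}" for i in range(10)] + ["d0", "d1", "d2"]
        calls_mat = np.array(genos + [genos[0], genos[1], genos[2]])
        sites = [ps.SiteRecord("chr1", 1000 + i * 1000, "A", "G") for i in range(384)]
        g = ps.GenotypeMatrix(samples, sites, calls_mat.astype(np.int8))
        ests = ps.pairwise_ibd(g)
        calls = [ps.classify_relationship(e) for e in ests]
        groups = ps.clone_groups(calls)
        assert len(groups) == 3
        assert all(len(gr) == 2 for gr in groups)
        assert {frozenset(gr) for gr in groups} == {
            frozenset({"v0", "d0"}), frozenset({"v1", "d1"}), frozenset({"v2", "d2"})
        }

    def test_groups_are_disjoint(self):
        groups = ps.clone_groups(
            [self._call("A", "B"), self._call("C", "D"), self._call("D", "E")]
        )
        seen = set()
        for gr in groups:
            assert not (gr & seen)
            seen |= gr


class TestHaplotypeGroups:
    def test_identical_strings_same_label(self):
        calls = np.array([[0, 1, 2], [0, 1, 2], [2, 1, 0]])
        g = make_matrix(calls)
        labels, freq = ps.haplotype_groups(g, ("chr1", 1, 10_000))
        assert labels["s0"] == labels["s1"] == "H001"
        assert labels["s2"] == "H002"

    def test_all_distinct_all_singletons(self):
        calls = np.array([[0, 0], [1, 0], [2, 0], [0, 1]])
        g = make_matrix(calls)
        labels, freq = ps.haplotype_groups(g, ("chr1", 1, 10_000))
        assert len(set(labels.values())) == 4

    def test_missing_unassigned(self):
        calls = np.array([[0, 1], [0, -1]])
        g = make_matrix(calls)
        labels, _ = ps.haplotype_groups(g, ("chr1", 1, 10_000))
        assert labels["s1"] is None

    def test_constructed_four_groups(self, rng):
        """A 6-SNP region with four genotype patterns at frequencies
        12/11/7/9 recovers four labels with those sizes."""
        patterns = [
            [0, 1, 2, 0, 1, 2],
            [1, 1, 1, 1, 1, 1],
            [2, 0, 2, 0, 2, 0],
            [0, 0, 0, 2, 2, 2],
        ]
        counts = [12, 11, 7, 9]
        rows = []
        for pat, n in zip(patterns, counts):
            rows += [pat] * n
        order = rng.permutation(len(rows))
        calls = np.array(rows)[order]
        g = make_matrix(calls)
        labels, freq = ps.haplotype_groups(g, ("chr1", 1, 10_000))
        assert list(freq["n"]) == sorted(counts, reverse=True)
        assert freq["haplotype"].tolist() == ["H001", "H002", "H003", "H004"]

    def test_empty_region_errors(self):
        g = make_matrix(np.array([[0], [1]]))
        with pytest.raises(ValueError):
            ps.haplotype_groups(g, ("chr2", 1, 10))
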