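"""Coalescent generator: closed-form expectations, selfing, sweeps, datasets."""

import numpy as np
import pytest

from drupepop import sfs
from drupepop import simulate as sim
from drupepop.windows import _callable_bulk, make_windows


class TestSimulateWindow:
    def test_zero_theta_gives_no_sites(self, rng):
        w = sim.simulate_window(10, 0.0, rng)
        assert w.haplotypes.shape == (10, 0)

    def test_expected_segregating_sites(self, rng):
        n, theta, reps = 26, 5.0, 2000
        S = np.array([sim.simulate_window(n, theta, rng).haplotypes.shape[1]
                      for _ in range(reps)])
        expect = theta * sfs.constants(n).a_n
        se = S.std(ddof=1) / np.sqrt(reps)
        assert abs(S.mean() - expect) < 3 * se

    def test_expected_tmrca(self, rng):
        n, reps = 10, 3000
        t = np.array([sim.simulate_window(n, 0.0, rng).tmrca
                      for _ in range(reps)])
        expect = 2.0 * (1.0 - 1.0 / n)
        se = t.std(ddof=1) / np.sqrt(reps)
        assert abs(t.mean() - expect) < 3 * se

    def test_integer_positions_are_distinct(self, rng):
        w = sim.simulate_window(12, 20.0, rng, L=500)
        assert len(np.unique(w.positions)) == len(w.positions)
        assert np.all(np.diff(w.positions) > 0)

    def test_matches_msprime_oracle(self, rng):
        # independent coalescent simulator as external cross-check
        import msprime

        n, theta, reps = 26, 5.0, 600
        ours_S, ours_pi = [], []
        for _ in range(reps):
            w = sim.simulate_window(n, theta, rng)
            d = w.haplotypes.sum(0)
            pi, _, _ = sfs.site_contributions(d, np.full(len(d), n))
            ours_S.append(len(d))
            ours_pi.append(pi.sum())
        ms_S, ms_pi = [], []
        for seed in range(1, reps + 1):
            # ploidy-1 samples with N=1: pairwise coalescence rate 1, the
            # same time scale as the package's coalescent-unit simulator
            ts = msprime.sim_ancestry(samples=n, ploidy=1, population_size=1.0,
                                      sequence_length=1.0, random_seed=seed)
            mts = msprime.sim_mutations(ts, rate=theta / 2.0,
                                        discrete_genome=False,
                                        random_seed=seed + 10_000)
            ms_S.append(mts.num_sites)
            ms_pi.append(float(mts.diversity(span_normalise=False)
                               * (n - 1) / n))
        # msprime's diversity uses 1/n(n-1) pairs weighting identical to ours
        for a, b in ((ours_S, ms_S),):
            a, b = np.asarray(a, float), np.asarray(b, float)
            se = np.hypot(a.std(ddof=1) / np.sqrt(reps),
                          b.std(ddof=1) / np.sqrt(reps))
            assert abs(a.mean() - b.mean()) < 3.5 * se
        a, b = np.asarray(ours_pi), np.asarray(ms_pi)
        se = np.hypot(a.std(ddof=1) / np.sqrt(reps), b.std(ddof=1) / np.sqrt(reps))
        assert abs(a.mean() - b.mean()) < 3.5 * se


class TestApplySelfing:
    def test_no_selfing_no_ibd(self, rng):
        hap = rng.integers(0, 2, size=(20, 30)).astype(np.int8)
        geno, ibd = sim.apply_selfing(hap, 0.0, rng)
        assert not ibd.any()
        np.testing.assert_array_equal(geno, hap[0::2] + hap[1::2])

    def test_complete_selfing_fully_homozygous(self, rng):
        hap = rng.integers(0, 2, size=(20, 50)).astype(np.int8)
        geno, ibd = sim.apply_selfing(hap, 1.0, rng)
        assert ibd.all()
        assert np.isin(geno, [0, 2]).all()

    def test_heterozygosity_reduced_by_one_minus_F(self, rng):
        # s = 0.5 -> F = 1/3 -> expected het = (2/3) * baseline
        n_rep, p = 400, 0.5
        het_out, het_self = [], []
        for _ in range(n_rep):
            hap = (rng.random((20, 40)) < p).astype(np.int8)
            g0, _ = sim.apply_selfing(hap, 0.0, rng)
            g5, _ = sim.apply_selfing(hap, 0.5, rng)
            het_out.append((g0 == 1).mean())
            het_self.append((g5 == 1).mean())
        ratio = np.mean(het_self) / np.mean(het_out)
        assert ratio == pytest.approx(2 / 3, abs=0.03)

    def test_odd_haplotype_count_errors(self, rng):
        with pytest.raises(ValueError):
            sim.apply_selfing(np.zeros((3, 5), dtype=np.int8), 0.1, rng)


class TestSplit:
    def test_zero_split_time_behaves_panmictic(self, rng):
        from drupepop.differentiation import fst_site, fst_weighted
        nums = dens = 0.0
        for _ in range(300):
            s = sim.simulate_split(16, 16, 10_000, 10_000, 0.0, 100_000,
                                   1e-8, 1000, rng, N_anc=10_000)
            d1, d2 = s.hap1.sum(0), s.hap2.sum(0)
            n = np.full(len(d1), 16)
            nu, de, ok = fst_site(d1, n, d2, n)
            nums += nu[ok].sum()
            dens += de[ok].sum()
        assert abs(nums / dens) < 0.03

    def test_outgroup_polarization_matches_truth_mostly(self, rng):
        # derived coding: allele 1 is derived by construction; the outgroup
        # carries 0 unless a mutation hit its own branch
        agree = total = 0
        for _ in range(50):
            s = sim.simulate_split(10, 10, 5_000, 5_000, 20_000, 100_000,
                                   1e-8, 1000, rng)
            agree += int((s.outgroup == 0).sum())
            total += len(s.outgroup)
        assert agree / total > 0.5


class TestSweeps:
    def test_reduction_scales_diversity(self, rng):
        kept = []
        base = []
        for _ in range(200):
            w = sim.simulate_window(26, 5.0, rng)
            d0 = w.haplotypes.sum(0)
            pi0, _, _ = sfs.site_contributions(d0, np.full(len(d0), 26))
            base.append(pi0.sum())
            block = w.haplotypes.copy()
            sim.sweep_reduction(block, 0.05, rng)
            d1 = block.sum(0)
            pi1, _, _ = sfs.site_contributions(d1, np.full(len(d1), 26))
            kept.append(pi1.sum())
        assert np.mean(kept) / np.mean(base) == pytest.approx(0.05, abs=0.02)

    def test_neutral_factor_changes_nothing(self, rng):
        w = sim.simulate_window(26, 5.0, rng)
        block = w.haplotypes.copy()
        sim.sweep_reduction(block, 1.0, rng)
        np.testing.assert_array_equal(block, w.haplotypes)

    def test_skew_directions_move_h_and_e_as_expected(self, rng):
        h_high, e_low, h_base, e_base = [], [], [], []
        for _ in range(300):
            w = sim.simulate_window(26, 5.0, rng)
            d0 = w.haplotypes.sum(0)
            n0 = np.full(len(d0), 26)
            h0, e0 = sfs.fay_wu_h(d0, n0), sfs.zengs_e(d0, n0)
            if np.isfinite(h0):
                h_base.append(h0)
            if np.isfinite(e0):
                e_base.append(e0)
            hi = w.haplotypes.copy()
            sim.sweep_skew(hi, rng, prob=0.8, direction="high")
            dh = hi.sum(0)
            hv = sfs.fay_wu_h(dh, np.full(len(dh), 26))
            if np.isfinite(hv):
                h_high.append(hv)
            lo = w.haplotypes.copy()
            sim.sweep_skew(lo, rng, prob=0.8, direction="low")
            dl = lo.sum(0)
            ev = sfs.zengs_e(dl, np.full(len(dl), 26))
            if np.isfinite(ev):
                e_low.append(ev)
        # high-frequency derived excess: H strongly negative
        se_h = np.std(h_high, ddof=1) / np.sqrt(len(h_high))
        assert np.mean(h_high) < 0
        assert np.mean(h_high) < np.mean(h_base) - 3 * se_h
        # rare-derived excess (post-sweep recovery): E strongly negative
        se_e = np.std(e_low, ddof=1) / np.sqrt(len(e_low))
        assert np.mean(e_low) < 0
        assert np.mean(e_low) < np.mean(e_base) - 3 * se_e


class TestConfig:
    def test_pop_size_solver_hits_targets(self):
        cfg = sim.prunus_preset()
        sizes = cfg.pop_sizes()
        two_n_anc = 2 * cfg.anc_size()
        for pop, th in cfg.theta.items():
            x = 2 * sizes[pop]
            T = cfg.split_time
            realized = 2 * cfg.mu * (x * (1 - np.exp(-T / x))
                                     + np.exp(-T / x) * two_n_anc)
            assert realized == pytest.approx(th, rel=1e-6)

    def test_equal_theta_fixed_point(self):
        cfg = sim.SimConfig(theta={"a": 0.0004, "b": 0.0004},
                            n_diploids={"a": 5, "b": 5},
                            selfing={"a": 0.0, "b": 0.0},
                            split_time=50_000, outgroup_join=200_000)
        sizes = cfg.pop_sizes()
        assert sizes["a"] == pytest.approx(10_000, rel=1e-4)

    def test_infeasible_theta_errors(self):
        cfg = sim.SimConfig(theta={"a": 0.5, "b": 0.0004},
                            n_diploids={"a": 5, "b": 5},
                            selfing={"a": 0.0, "b": 0.0},
                            split_time=1000, outgroup_join=2000)
        with pytest.raises(ValueError, match="infeasible"):
            cfg.pop_sizes()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            sim.SimConfig(split_time=10, outgroup_join=5)
        with pytest.raises(ValueError):
            sim.SimConfig(selfing={"almond": 1.5, "peach": 0.0})


class TestGenerateDataset:
    def _small_cfg(self, **kw):
        base = dict(chrom_lengths={"chr1": 20_000},
                    sweeps=[sim.SweepRegion("chr1", 5_000, 10_000, "peach")])
        base.update(kw)
        return sim.prunus_preset(**base)

    def test_same_seed_byte_identical(self, tmp_path):
        cfg = self._small_cfg()
        sim.generate_dataset(cfg, tmp_path / "a", 11)
        sim.generate_dataset(cfg, tmp_path / "b", 11)
        for name in ("variants.vcf", "popmap.tsv", "callable.bed",
                     "genes.gff3", "truth.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()

    def test_truth_records_selfing_and_sweeps(self, tmp_path):
        cfg = self._small_cfg()
        truth, paths = sim.generate_dataset(cfg, tmp_path / "d", 5)
        assert truth.F_expected["peach"] == pytest.approx(0.197, abs=0.002)
        assert truth.F_expected["almond"] == 0.0
        text = paths["truth"].read_text()
        assert "sweep\tchr1:5000-10000\tpeach" in text
        fracs = [v for k, v in truth.ibd_fraction.items() if k.startswith("peach")]
        assert 0.05 < np.mean(fracs) < 0.35

    def test_hole_punched_mask_drops_all_full_windows(self, tmp_path):
        # 86% holes leave 140 callable bp per 1 kb segment; every 1 kb
        # window then has exactly 140 < 150 callable bp (periodic pattern),
        # so the <150 bp rule removes every window
        cfg = self._small_cfg(mask_hole=0.86, sweeps=[])
        _, paths = sim.generate_dataset(cfg, tmp_path / "d", 3)
        from drupepop.genomic_io import read_mask
        mask = read_mask(paths["mask"])
        w = make_windows({"chr1": 20_000})
        cb = _callable_bulk(mask, "chr1", w["start"].to_numpy(),
                            w["end"].to_numpy())
        full = (w["end"] - w["start"]) == 1000
        assert (cb[full.to_numpy()] == 140).all()
        assert (cb < 150).all()

    def test_vcf_loads_and_polarizes(self, tmp_path):
        from drupepop import genomic_io as gio

        cfg = self._small_cfg()
        truth, paths = sim.generate_dataset(cfg, tmp_path / "d", 9)
        pops = gio.read_popmap(paths["popmap"])
        gm = gio.read_vcf(paths["vcf"], pops)
        assert gm.n_samples == 27
        aa_truth = gm.ancestral.copy()  # AA INFO written from the true root
        counts = gio.polarize(gm, outgroup="outgroup")
        # mutations private to the outgroup branch mislead polarization only
        # at sites that are monomorphic within the ingroup (zero weight in
        # every statistic); at ingroup-polymorphic sites the infinite-sites
        # model makes outgroup calls agree with the truth almost always
        known = gm.ancestral != -1
        ingroup_poly = (counts["almond"].m + counts["peach"].m) > 0
        sel = known & ingroup_poly
        agree = (gm.ancestral[sel] == aa_truth[sel]).mean()
        assert agree > 0.95
        assert set(counts) == {"almond", "peach"}
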