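"""Tests of the founder, meiosis, polycross and GBS simulators."""
import numpy as np
import pytest
from scipy import stats as sps

from polypat.core import MISSING
from polypat.simulate import (
    MatingDesign,
    SIModel,
    is_compatible,
    make_gamete,
    make_gametes,
    simulate_founders,
    simulate_gbs,
    simulate_polycross,
)


class TestCompatibilityRule:
    @pytest.mark.parametrize(
        "pollen_s,pollen_z,expected",
        [
            (0, 0, False),  # both match -> rejected
            (0, 8, True),   # Z absent from pistil -> accepted
            (6, 0, True),   # S absent from pistil -> accepted
            (1, 2, False),
            (5, 9, True),
        ],
    )
    def test_double_match_required_for_rejection(self, pollen_s, pollen_z,
                                                 expected):
        assert is_compatible(pollen_s, pollen_z, (0, 1), (0, 2)) is expected

    def test_matches_bruteforce_over_all_pollen_classes(self, small_founders):
        """Every father's four gametic S x Z classes agree with an
        explicit double-match oracle against every pistil."""
        f = small_founders
        for fa in range(f.n_parents):
            for mo in range(f.n_parents):
                pistil_s = tuple(f.si_s[mo])
                pistil_z = tuple(f.si_z[mo])
                for a in range(2):
                    for b in range(2):
                        s, z = f.si_s[fa, a], f.si_z[fa, b]
                        oracle = not (s in pistil_s and z in pistil_z)
                        assert is_compatible(s, z, pistil_s, pistil_z) == oracle


class TestFounders:
    def test_dimensions_and_determinism(self, si_model):
        a = simulate_founders(20, 5, 30, (0.1, 0.5), si_model, seed=7)
        b = simulate_founders(20, 5, 30, (0.1, 0.5), si_model, seed=7)
        assert a.haplotypes.shape == (20, 2, 150)
        assert len(a.gmap.chroms) == 5
        np.testing.assert_array_equal(a.haplotypes, b.haplotypes)
        np.testing.assert_array_equal(a.si_s, b.si_s)
        np.testing.assert_array_equal(a.allele_freqs, b.allele_freqs)

    def test_si_heterozygosity_enforced(self, small_founders):
        assert (small_founders.si_s[:, 0] != small_founders.si_s[:, 1]).all()
        assert (small_founders.si_z[:, 0] != small_founders.si_z[:, 1]).all()

    def test_single_si_allele_rejected(self):
        with pytest.raises(ValueError, match="single S or Z allele"):
            simulate_founders(
                10, 2, 10,
                si_model=SIModel(k_s=1, k_z=2, s_locus=("Chr01", 50.0),
                                 z_locus=("Chr02", 50.0)),
                seed=0,
            )

    def test_realized_maf_matches_drawn_frequency(self, si_model):
        """With every frequency pinned at 0.5 the realized mean MAF is a
        binomial average within three standard errors."""
        f = simulate_founders(100, 4, 100, (0.5, 0.5), si_model, seed=11)
        realized = f.genotype_dosages().mean(axis=0) / 2.0
        n_gametes = 2 * 100
        se = np.sqrt(0.25 / n_gametes) / np.sqrt(f.gmap.n_markers)
        assert abs(realized.mean() - 0.5) < 3 * se
        # folded (minor-allele) frequencies sit just below the 0.5 boundary
        maf_mean = np.minimum(realized, 1 - realized).mean()
        folded_shift = np.sqrt(0.25 / n_gametes) * np.sqrt(2 / np.pi)
        assert 0.5 - 3 * folded_shift < maf_mean <= 0.5

    def test_bottleneck_mode_creates_ld_with_si_locus(self, si_model):
        """Ancestral-pool founders show marker/SI-allele association near
        the S locus that independent-draw founders lack."""
        f = simulate_founders(80, 3, 60, (0.2, 0.5), si_model, seed=3,
                              n_ancestral_haplotypes=6,
                              copying_generations=2.0)
        pos = f.gmap.positions["Chr01"]
        near = np.nonzero(np.abs(pos - si_model.s_locus[1]) < 5.0)[0]
        sal = f.si_s.ravel()
        best = 0.0
        for j in near:
            hap = f.haplotypes[:, :, j].ravel()
            means = [hap[sal == k].mean() for k in range(si_model.k_s)
                     if (sal == k).sum() > 1]
            best = max(best, np.ptp(means))
        # some nearby marker's allele frequency differs across S-allele
        # classes (ancestry tagging)
        assert best > 0.2


class TestMeiosis:
    def test_zero_distance_always_coinherited(self):
        si = SIModel(k_s=2, k_z=2, s_locus=("Chr01", 0.0),
                     z_locus=("Chr02", 0.0))
        f = simulate_founders(2, 2, 5, (0.3, 0.5), si, seed=1,
                              chrom_length_cm=1e-9)
        # force distinguishable haplotypes
        f.haplotypes[0, 0, :] = 0
        f.haplotypes[0, 1, :] = 1
        rng = np.random.default_rng(0)
        haps, _, _ = make_gametes(f, 0, 200, rng)
        chr1 = haps[:, :5]
        assert ((chr1 == 0).all(axis=1) | (chr1 == 1).all(axis=1)).all()

    def test_long_distance_recombination_approaches_half(self):
        si = SIModel(k_s=2, k_z=2, s_locus=("Chr01", 0.0),
                     z_locus=("Chr02", 0.0))
        f = simulate_founders(2, 2, 2, (0.3, 0.5), si, seed=1,
                              chrom_length_cm=1000.0)
        f.haplotypes[0, 0, :] = 0
        f.haplotypes[0, 1, :] = 1
        rng = np.random.default_rng(5)
        haps, _, _ = make_gametes(f, 0, 4000, rng)
        rec_frac = (haps[:, 0] != haps[:, 1]).mean()
        assert abs(rec_frac - 0.5) < 3 * np.sqrt(0.25 / 4000)

    def test_marker_si_cotransmission_close_linkage(self):
        """A marker 1 cM from the S locus co-transmits with the S allele at
        the Haldane closed-form rate ~0.990."""
        si = SIModel(k_s=2, k_z=2, s_locus=("Chr01", 51.0),
                     z_locus=("Chr02", 50.0))
        f = simulate_founders(2, 2, 101, (0.3, 0.5), si, seed=1,
                              chrom_length_cm=100.0)
        j = 50  # marker at 50 cM, 1 cM from the S locus
        f.haplotypes[0, 0, j] = 0
        f.haplotypes[0, 1, j] = 1
        f.si_s[0] = [0, 1]  # S allele k on haplotype k
        rng = np.random.default_rng(9)
        haps, s_al, _ = make_gametes(f, 0, 20000, rng)
        co = (haps[:, j] == s_al).mean()
        expected = 1.0 - 0.5 * (1 - np.exp(-2 * 1.0 / 100))
        assert abs(co - expected) < 3 * np.sqrt(expected * (1 - expected)
                                                / 20000)

    def test_single_gamete_wrapper(self, small_founders):
        rng = np.random.default_rng(0)
        hap, s, z = make_gamete(small_founders, 3, rng)
        assert hap.shape == (small_founders.gmap.n_markers,)
        assert s in tuple(small_founders.si_s[3])
        assert z in tuple(small_founders.si_z[3])


class TestPolycross:
    def test_no_rejected_pollen_class_in_pedigree(self, small_founders,
                                                  equal_design):
        """Under SI enforcement, no accepted pollen doubly matches its
        pistil (auditable because transmitted S/Z alleles are recorded)."""
        prog = simulate_polycross(small_founders, equal_design,
                                  enforce_si=True, seed=3)
        idx = {p: i for i, p in enumerate(small_founders.ids)}
        for _, row in prog.pedigree.iterrows():
            mi = idx[row["mother"]]
            assert is_compatible(
                row["pollen_s"], row["pollen_z"],
                tuple(small_founders.si_s[mi]),
                tuple(small_founders.si_z[mi]),
            )

    def test_no_selfing_by_default(self, small_founders, equal_design):
        prog = simulate_polycross(small_founders, equal_design,
                                  enforce_si=False, seed=4)
        assert (prog.pedigree["mother"] != prog.pedigree["father"]).all()

    def test_saturated_incompatibility_yields_no_progeny(self):
        """If every founder is S1S2/Z1Z2 every pollen grain doubly matches
        every pistil, so all seeds are skipped."""
        si = SIModel(k_s=2, k_z=2, s_locus=("Chr01", 50.0),
                     z_locus=("Chr02", 50.0))
        f = simulate_founders(6, 2, 10, (0.3, 0.5), si, seed=0)
        design = MatingDesign(fecundity=np.ones(6), progeny_per_mother=3,
                              max_pollen_attempts=20)
        with pytest.warns(UserWarning, match="no compatible pollen"):
            prog = simulate_polycross(f, design, enforce_si=True, seed=1)
        assert prog.n_offspring == 0
        assert prog.skipped.sum() == 18

    def test_father_shares_follow_fecundity_when_si_off(self, si_model):
        """Without SI, per-father progeny counts fit the fecundity-share
        multinomial (chi-square goodness of fit)."""
        f = simulate_founders(10, 2, 10, (0.3, 0.5), si_model, seed=2)
        fec = np.array([1, 1, 1, 1, 1, 2, 2, 2, 2, 2], dtype=float)
        design = MatingDesign(fecundity=fec, progeny_per_mother=1000)
        prog = simulate_polycross(f, design, enforce_si=False, seed=6)
        counts = prog.pedigree["father"].value_counts()
        # expected share per father: sum over mothers of fec/others-total
        n = 10
        expected = np.zeros(n)
        for mo in range(n):
            w = fec.copy()
            w[mo] = 0
            expected += 1000 * w / w.sum()
        observed = np.array([counts.get(p, 0) for p in f.ids], dtype=float)
        chi2 = ((observed - expected) ** 2 / expected).sum()
        assert sps.chi2.sf(chi2, n - 1) > 1e-4

    def test_selfing_rate_produces_self_progeny(self, si_model):
        f = simulate_founders(8, 2, 10, (0.3, 0.5), si_model, seed=2)
        design = MatingDesign(fecundity=np.ones(8), progeny_per_mother=200,
                              selfing_rate=0.2)
        prog = simulate_polycross(f, design, enforce_si=False, seed=7)
        self_frac = (prog.pedigree["mother"] ==
                     prog.pedigree["father"]).mean()
        assert abs(self_frac - 0.2) < 0.03

    def test_determinism(self, small_founders, equal_design):
        a = simulate_polycross(small_founders, equal_design, seed=11)
        b = simulate_polycross(small_founders, equal_design, seed=11)
        np.testing.assert_array_equal(a.genotypes, b.genotypes)
        assert a.pedigree.equals(b.pedigree)


class TestGBS:
    def test_near_zero_depth_mostly_missing(self, small_founders):
        cm = simulate_gbs(small_founders.genotype_dosages(),
                          small_founders.ids, small_founders.gmap,
                          mean_depth=0.01, seed=0)
        assert (cm.genotypes == MISSING).mean() > 0.98

    def test_heterozygote_detection_at_high_depth(self, si_model):
        f = simulate_founders(50, 2, 50, (0.3, 0.5), si_model, seed=1)
        true = np.ones_like(f.genotype_dosages())  # all het
        cm = simulate_gbs(true, f.ids, f.gmap, mean_depth=50,
                          depth_dispersion=1e6,  # depth tightly near 50
                          per_read_error=0.0, seed=2)
        called = cm.genotypes[cm.genotypes != MISSING]
        # both alleles seen with prob 1 - 2 * 0.5^depth; at depth ~50 this
        # is essentially certain
        assert (called == 1).mean() > 0.999

    def test_depths_consistent_with_calls(self, small_founders):
        cm = simulate_gbs(small_founders.genotype_dosages(),
                          small_founders.ids, small_founders.gmap,
                          mean_depth=4, seed=3)
        total = cm.allele_depths.sum(axis=2)
        assert ((total == 0) == (cm.genotypes == MISSING)).all()

    def test_parents_at_double_depth_have_less_missing(self, small_founders):
        g = small_founders.genotype_dosages()
        lo = simulate_gbs(g, small_founders.ids, small_founders.gmap,
                          mean_depth=2, seed=4)
        hi = simulate_gbs(g, small_founders.ids, small_founders.gmap,
                          mean_depth=4, seed=4)
        assert (hi.genotypes == MISSING).mean() < (lo.genotypes ==
                                                   MISSING).mean()
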