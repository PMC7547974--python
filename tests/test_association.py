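"""Tests of SI encoding, diallel construction, PCA phenotypes, the GRM,
the mixed-model scan and FDR control."""
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from polypat.association import (
    binary_phenotype,
    build_diallel,
    encode_pair_locus,
    fdr_control,
    genomic_relationship,
    impute_parent_genotypes,
    mlm_scan,
    progeny_matrix_pcs,
    qvalues,
)
from polypat.core import MISSING

from .conftest import make_call_matrix


class TestEncoding:
    # the nine genotype pairs of the published compatibility table:
    # male x female -> code (+1 compatible / -1 incompatible)
    TABLE = [
        (0, 0, -1), (0, 1, -1), (0, 2, +1),
        (1, 0, +1), (1, 1, -1), (1, 2, +1),
        (2, 0, +1), (2, 1, -1), (2, 2, -1),
    ]

    @pytest.mark.parametrize("male,female,code", TABLE)
    def test_all_nine_rows(self, male, female, code):
        assert encode_pair_locus(male, female) == code

    def test_matches_single_locus_gsi_oracle(self):
        """+1 exactly when some male gamete class carries an allele not
        present in the female genotype (single-locus gametophytic rule:
        pollen rejected iff its allele is in the pistil genotype)."""
        alleles = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
        for male, female in itertools.product(range(3), repeat=2):
            pistil = set(alleles[female])
            accepted = any(a not in pistil for a in alleles[male])
            assert encode_pair_locus(male, female) == (1 if accepted else -1)

    def test_missing_rejected(self):
        with pytest.raises(ValueError):
            encode_pair_locus(MISSING, 0)

    def test_diallel_shape_and_asymmetry(self):
        g = np.array([[1, 0], [0, 2]], dtype=np.int8)  # P=2, m=2
        d = build_diallel(g)
        assert d.shape == (4, 2)
        # row order female-major: (0,0), (0,1), (1,0), (1,1)
        # marker 0: male het x female het -> -1; het male x hom female -> +1
        assert d[1, 0] == -1  # female 0 (het) x male 1 (hom_ref): hom x het
        assert d[2, 0] == +1  # female 1 (hom) x male 0 (het)
        assert (np.diag(d[[0, 3]][:, [0, 1]]) == -1).all()  # selfs always -1

    def test_eightynine_parents_give_7921_rows(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, size=(89, 5)).astype(np.int8)
        assert build_diallel(g).shape == (7921, 5)


class TestImputation:
    def test_complete_matrix_unchanged(self):
        g = np.array([[0, 1], [2, 1]], dtype=np.int8)
        out = impute_parent_genotypes(make_call_matrix(g), seed=0)
        np.testing.assert_array_equal(out.genotypes, g)

    def test_no_missing_after_imputation(self):
        rng = np.random.default_rng(1)
        g = rng.choice([-1, 0, 1, 2], size=(30, 20)).astype(np.int8)
        g[:, 0] = np.where(g[:, 0] == MISSING, 0, g[:, 0])  # keep 1 observed
        out = impute_parent_genotypes(make_call_matrix(g), seed=1)
        assert (out.genotypes != MISSING).all()
        observed = g != MISSING
        np.testing.assert_array_equal(out.genotypes[observed], g[observed])

    def test_all_missing_marker_dropped(self):
        g = np.array([[0, MISSING], [1, MISSING]], dtype=np.int8)
        with pytest.warns(UserWarning, match="no observed calls"):
            out = impute_parent_genotypes(make_call_matrix(g), seed=0)
        assert out.n_markers == 1

    def test_frequency_preserved(self):
        """Sampling imputation keeps the allele frequency within binomial
        error at 1000 imputed calls."""
        rng = np.random.default_rng(2)
        g = np.full((2000, 1), MISSING, dtype=np.int8)
        observed = rng.choice([0, 1, 2], size=1000, p=[0.49, 0.42, 0.09])
        g[:1000, 0] = observed
        out = impute_parent_genotypes(make_call_matrix(g), seed=3)
        f_obs = observed.mean() / 2
        f_imp = out.genotypes[1000:, 0].mean() / 2
        se = np.sqrt(f_obs * (1 - f_obs) / (2 * 1000))
        assert abs(f_imp - f_obs) < 4 * se


class TestPhenotypes:
    def test_binary_phenotype_alignment(self):
        m = pd.DataFrame([[0, 5], [0, 0]], index=["A", "B"],
                         columns=["A", "B"])
        y = binary_phenotype(m)
        np.testing.assert_array_equal(y, [0, 1, 0, 0])

    def test_sum_equals_ordered_families(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(0.5, size=(12, 12))
        m = pd.DataFrame(counts, index=[f"P{i}" for i in range(12)],
                         columns=[f"P{i}" for i in range(12)])
        assert binary_phenotype(m).sum() == (counts > 0).sum()

    def test_pcs_match_svd_oracle_up_to_sign(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(3.0, size=(10, 10)).astype(float)
        m = pd.DataFrame(counts, index=[f"P{i}" for i in range(10)],
                         columns=[f"P{i}" for i in range(10)])
        scores = progeny_matrix_pcs(m, k=3)
        x = counts - counts.mean(axis=0)
        u, s, vt = np.linalg.svd(x, full_matrices=False)
        oracle = u[:, :3] * s[:3]
        for j in range(3):
            assert (
                np.allclose(scores.iloc[:, j], oracle[:, j], atol=1e-8)
                or np.allclose(scores.iloc[:, j], -oracle[:, j], atol=1e-8)
            )

    def test_pc_scores_orthogonal(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(rng.poisson(2.0, size=(15, 15)).astype(float))
        scores = progeny_matrix_pcs(m, k=3).to_numpy()
        gram = scores.T @ scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_rank_one_matrix_pc1_dominates(self):
        u = np.arange(1, 9, dtype=float)
        v = np.arange(8, 0, -1, dtype=float)
        m = pd.DataFrame(np.outer(u, v))
        scores = progeny_matrix_pcs(m, k=2).to_numpy()
        assert (scores[:, 0] ** 2).sum() > 1e6 * (scores[:, 1] ** 2).sum()

    def test_constant_matrix_rejected(self):
        m = pd.DataFrame(np.full((5, 5), 3.0))
        with pytest.raises(ValueError, match="variance"):
            progeny_matrix_pcs(m, k=2)


class TestGRM:
    def test_hand_computed_additive(self):
        w = np.array([[0, 1, 2], [2, 1, 0], [1, 1, 1], [0, 1, 2]],
                     dtype=float)
        centered = w - w.mean(axis=0)
        p = w.mean(axis=0) / 2
        c = (2 * p * (1 - p)).sum()
        expected = centered @ centered.T / c
        got = genomic_relationship(w, coding="additive")
        np.testing.assert_allclose(got, expected)

    def test_pm1_coding_normalizes_by_marker_count(self):
        rng = np.random.default_rng(0)
        w = rng.choice([-1.0, 1.0], size=(6, 40))
        got = genomic_relationship(w, coding="pm1")
        centered = w - w.mean(axis=0)
        np.testing.assert_allclose(got, centered @ centered.T / 40)

    def test_symmetric_and_psd(self):
        rng = np.random.default_rng(1)
        w = rng.integers(0, 3, size=(20, 100)).astype(float)
        k = genomic_relationship(w)
        np.testing.assert_allclose(k, k.T)
        assert np.linalg.eigvalsh(k).min() > -1e-8

    def test_identical_individuals_share_row(self):
        rng = np.random.default_rng(2)
        w = rng.integers(0, 3, size=(5, 50)).astype(float)
        w[1] = w[0]
        k = genomic_relationship(w)
        assert k[0, 1] == pytest.approx(k[0, 0])


class TestMlmScan:
    def _data(self, n=80, m=60, seed=0):
        rng = np.random.default_rng(seed)
        s = rng.integers(0, 3, size=(n, m)).astype(float)
        info = pd.DataFrame(
            {"chrom": "Chr01", "pos": np.arange(m) + 1},
            index=[f"mk{j}" for j in range(m)],
        )
        y = rng.normal(size=n)
        return y, s, info

    def test_identity_kinship_matches_ols_f_test(self):
        """With K = I and no polygenic variance the scan reduces to OLS:
        p-values agree with the statsmodels F-test to 1e-6."""
        import statsmodels.api as sm

        y, s, info = self._data()
        n = len(y)
        res = mlm_scan(y, s, info, np.eye(n), n_pcs=0)
        for j in range(s.shape[1]):
            x = sm.add_constant(s[:, j])
            fit = sm.OLS(y, x).fit()
            assert res["p"].iloc[j] == pytest.approx(fit.pvalues[1],
                                                     abs=1e-6)
            assert res["effect"].iloc[j] == pytest.approx(fit.params[1],
                                                          abs=1e-8)

    def test_null_pvalues_uniform(self):
        """Permuted phenotypes give uniform p-values (KS test)."""
        rng = np.random.default_rng(7)
        n, m = 120, 2000
        s = rng.integers(0, 3, size=(n, m)).astype(float)
        info = pd.DataFrame({"chrom": "Chr01", "pos": np.arange(m) + 1},
                            index=[f"mk{j}" for j in range(m)])
        K = genomic_relationship(s)
        y = rng.normal(size=n)
        res = mlm_scan(rng.permutation(y), s, info, K, n_pcs=5)
        assert sps.kstest(res["p"], "uniform").pvalue > 0.01

    def test_planted_effect_recovered(self):
        rng = np.random.default_rng(8)
        n, m = 150, 100
        s = rng.integers(0, 3, size=(n, m)).astype(float)
        info = pd.DataFrame({"chrom": "Chr01", "pos": np.arange(m) + 1},
                            index=[f"mk{j}" for j in range(m)])
        y = 0.8 * s[:, 17] + rng.normal(size=n)
        res = mlm_scan(y, s, info, np.eye(n), n_pcs=2)
        assert res["p"].idxmin() == "mk17"

    def test_dimension_mismatch(self):
        y, s, info = self._data()
        with pytest.raises(ValueError, match="dimension"):
            mlm_scan(y[:-1], s, info, np.eye(len(y)))


class TestFdr:
    def test_bh_closed_form_all_equal(self):
        p = np.full(100, 0.01)
        np.testing.assert_allclose(qvalues(p), 0.01)

    def test_all_ones_no_flags(self):
        scan = pd.DataFrame(
            {"chrom": "Chr01", "pos": range(10), "p": np.ones(10)}
        )
        out = fdr_control(scan, 0.05)
        assert not out["sig_genome"].any()

    def test_matches_bruteforce_bh(self):
        """With the BH fallback (small m forces pi0 = 1), q-values equal an
        explicit step-up implementation."""
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        q = qvalues(p)
        m = len(p)
        order = np.argsort(p)
        brute = np.empty(m)
        prev = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            prev = min(prev, p[i] * m / rank)
            brute[i] = prev
        np.testing.assert_allclose(q, brute)

    def test_qvalues_monotone_in_p(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=500)
        q = qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_storey_pi0_scales_down_under_signal(self):
        """With many tiny p-values the estimated null proportion drops
        below 1, making Storey q-values no larger than plain BH."""
        rng = np.random.default_rng(4)
        p = np.concatenate([rng.uniform(0, 1e-4, 400),
                            rng.uniform(size=600)])
        q = qvalues(p)
        m = len(p)
        order = np.argsort(p)
        bh = np.empty(m)
        prev = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            prev = min(prev, p[i] * m / rank)
            bh[i] = prev
        assert (q <= bh + 1e-12).all()

    def test_chromosome_subset_flags(self):
        rng = np.random.default_rng(5)
        scan = pd.DataFrame(
            {
                "chrom": ["Chr01"] * 50 + ["Chr02"] * 50,
                "pos": list(range(50)) * 2,
                "p": rng.uniform(size=100),
            }
        )
        scan.loc[3, "p"] = 1e-9
        out = fdr_control(scan, 0.05, chromosome_subset=["Chr01"])
        assert out.loc[3, "sig_chrom"]
        assert out.loc[60:, "q_chrom"].isna().all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            qvalues(np.array([]))
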