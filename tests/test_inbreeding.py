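"""The ten genomic inbreeding coefficients and their correlations."""

import numpy as np
import pandas as pd
import pytest

from snpdiv.datamodel import MISSING
from snpdiv.inbreeding import (
    METRICS,
    correlation_matrix,
    f_grm,
    f_hom1,
    f_hom2,
    f_roh,
    f_uni,
    inbreeding_records,
)
from snpdiv.popgen import compute_grm
from snpdiv.sim import SimConfig, simulate_founders, simulate_inbred_lines

from conftest import make_gm


def _hwe_matrix(rng, n, m):
    p = rng.uniform(0.1, 0.9, size=m)
    return ((rng.random((n, m)) < p).astype(np.int8)
            + (rng.random((n, m)) < p).astype(np.int8))


class TestFGrm:
    def test_diagonal_minus_one(self, rng):
        gm = make_gm(_hwe_matrix(rng, 10, 50))
        grm = compute_grm(gm, "vanraden")
        np.testing.assert_allclose(f_grm(grm), np.diag(grm.values) - 1.0)

    def test_requires_vanraden(self, rng):
        gm = make_gm(_hwe_matrix(rng, 10, 50))
        with pytest.raises(ValueError):
            f_grm(compute_grm(gm, "variance_standardized"))

    def test_mean_near_zero_under_hwe(self, rng):
        gm = make_gm(_hwe_matrix(rng, 300, 3000))
        assert abs(f_grm(compute_grm(gm)).mean()) < 0.02


class TestFHom:
    def test_f_hom1_arithmetic(self):
        # 4 SNPs at p=0.5 (E_het = 2 per sample); sample 0 has 0 hets,
        # sample 1 has het count equal to expectation
        dosage = np.array([
            [0, 2, 0, 2],
            [1, 1, 0, 2],
            [1, 1, 1, 1],
            [2, 0, 1, 1],
            [0, 2, 2, 0],
            [2, 0, 1, 1],
        ], dtype=np.int8)
        gm = make_gm(dosage)
        p = dosage.sum(axis=0) / 12  # [6, 6, 5, 7] / 12
        e_het = (2 * p * (1 - p)).sum()
        f = f_hom1(gm)
        assert f[0] == pytest.approx(1.0)  # fully homozygous
        assert f[2] == pytest.approx((e_het - 4) / e_het)

    def test_f_hom2_single_snp_values(self):
        # p = 0.5 exactly; per-SNP value for a het is 1 - 1/(2*0.25) = -1
        dosage = np.array([[1], [1], [0], [2]], dtype=np.int8)
        gm = make_gm(dosage)
        f = f_hom2(gm)
        np.testing.assert_allclose(f, [-1, -1, 1, 1])

    def test_f_hom2_matches_loop_oracle(self, rng):
        dosage = _hwe_matrix(rng, 20, 50)
        dosage[rng.random(dosage.shape) < 0.05] = MISSING
        gm = make_gm(dosage)
        from snpdiv.popgen import allele_frequencies

        p = allele_frequencies(gm)
        expect = np.empty(20)
        for i in range(20):
            vals = []
            for j in range(50):
                x = dosage[i, j]
                if x == MISSING or not (0 < p[j] < 1):
                    continue
                vals.append(1 - x * (2 - x) / (2 * p[j] * (1 - p[j])))
            expect[i] = np.mean(vals)
        np.testing.assert_allclose(f_hom2(gm), expect, atol=1e-12)

    def test_f_uni_single_snp_values(self):
        dosage = np.array([[1], [2], [0], [1]], dtype=np.int8)  # p = 0.5
        f = f_uni(make_gm(dosage))
        # per Eq.-style evaluation at p=0.5: het -> -1, hom-alt -> +1
        np.testing.assert_allclose(f, [-1, 1, 1, -1])

    def test_f_uni_matches_loop_oracle(self, rng):
        dosage = _hwe_matrix(rng, 15, 40)
        gm = make_gm(dosage)
        from snpdiv.popgen import allele_frequencies

        p = allele_frequencies(gm)
        expect = np.empty(15)
        for i in range(15):
            num = den = 0.0
            for j in range(40):
                if not (0 < p[j] < 1):
                    continue
                x = float(dosage[i, j])
                num += x * x - (1 + 2 * p[j]) * x + 2 * p[j] ** 2
                den += 2 * p[j] * (1 - p[j])
            expect[i] = num / den
        np.testing.assert_allclose(f_uni(gm), expect, atol=1e-12)

    def test_mean_near_zero_under_hwe(self, rng):
        gm = make_gm(_hwe_matrix(rng, 300, 3000))
        assert abs(f_hom1(gm).mean()) < 0.02
        assert abs(f_hom2(gm).mean()) < 0.02
        assert abs(f_uni(gm).mean()) < 0.02


class TestFRoh:
    def _gm(self):
        # one chromosome spanning 1..25,000,001 (L_auto = 25,000,001)
        return make_gm(np.zeros((2, 2), dtype=np.int8),
                       positions=[1, 25_000_001])

    def test_fraction_of_genome(self):
        gm = self._gm()
        segs = pd.DataFrame([
            {"sample_id": "i0", "chromosome": "1", "start_bp": 1,
             "end_bp": 2_500_000, "length_bp": 2_500_000, "length_class": "2to4"},
        ])
        out = f_roh(segs, gm).set_index("sample_id")
        assert out.loc["i0", "f_roh"] == pytest.approx(2_500_000 / 25_000_001)
        assert out.loc["i0", "f_roh_2_4"] == out.loc["i0", "f_roh"]
        assert out.loc["i0", "f_roh_lt2"] == 0.0
        assert out.loc["i1", "f_roh"] == 0.0

    def test_no_segments_all_zero(self):
        out = f_roh(pd.DataFrame(columns=["sample_id", "length_class", "length_bp"]),
                    self._gm())
        assert (out[[c for c in out.columns if c != "sample_id"]] == 0).all().all()

    def test_class_decomposition_sums(self, rng):
        gm = self._gm()
        classes = ["lt2", "2to4", "4to8", "8to16", "gt16"]
        segs = pd.DataFrame([
            {"sample_id": "i0", "chromosome": "1", "start_bp": 1,
             "end_bp": L, "length_bp": L,
             "length_class": classes[int(rng.integers(0, 5))]}
            for L in rng.integers(500_000, 20_000_000, size=10)
        ])
        out = f_roh(segs, gm).set_index("sample_id")
        parts = out.loc["i0", ["f_roh_lt2", "f_roh_2_4", "f_roh_4_8",
                               "f_roh_8_16", "f_roh_gt16"]].sum()
        assert out.loc["i0", "f_roh"] == pytest.approx(parts, abs=1e-12)


class TestCorrelations:
    def _records(self, rng, n=30):
        base = rng.normal(0.1, 0.05, size=n)
        df = pd.DataFrame({m: base + rng.normal(0, 0.01, size=n) for m in METRICS})
        df.insert(0, "sample_id", [f"i{i}" for i in range(n)])
        return df

    def test_duplicate_and_negated_metrics(self, rng):
        rec = self._records(rng)
        rec["f_hom2"] = rec["f_hom1"]
        rec["f_uni"] = -rec["f_hom1"]
        corr = correlation_matrix(rec)
        assert corr.loc["f_hom1", "f_hom2"] == pytest.approx(1.0)
        assert corr.loc["f_hom1", "f_uni"] == pytest.approx(-1.0)

    def test_zero_variance_flagged_nan(self, rng):
        rec = self._records(rng)
        rec["f_roh_gt16"] = 0.0
        corr = correlation_matrix(rec)
        assert np.isnan(corr.loc["f_roh_gt16", "f_hom1"])

    def test_too_few_samples(self, rng):
        with pytest.raises(ValueError):
            correlation_matrix(self._records(rng, n=2))

    def test_inbreeding_gradient_strong_correlations(self):
        cfg = SimConfig(n_snps=2000, n_chromosomes=4, chrom_length_mb=50,
                        ne=150, seed=3)
        pool = simulate_founders(cfg)
        gens = [g for g in range(5) for _ in range(20)]
        sp, truth = simulate_inbred_lines(pool, gens)
        gm = sp.to_genotype_matrix()
        rec = pd.DataFrame({
            "sample_id": gm.sample_ids,
            "f_hom1": f_hom1(gm),
            "f_uni": f_uni(gm),
            "f_grm": f_grm(compute_grm(gm)),
        })
        c = rec[["f_hom1", "f_uni", "f_grm"]].corr()
        assert c.loc["f_hom1", "f_uni"] >= 0.67
        assert (c.values > 0.6).all()
        # realized inbreeding tracks pedigree expectation
        ped = np.array([truth.pedigree_f[s] for s in gm.sample_ids])
        assert np.corrcoef(ped, rec["f_hom1"])[0, 1] > 0.7


class TestRecords:
    def test_schema_and_decomposition(self, rng):
        from snpdiv.roh import detect_roh

        dosage = _hwe_matrix(rng, 12, 400)
        gm = make_gm(dosage, spacing_bp=50_000)
        rec = inbreeding_records(gm, detect_roh(gm))
        assert list(rec.columns) == ["sample_id"] + METRICS
        parts = rec[["f_roh_lt2", "f_roh_2_4", "f_roh_4_8",
                     "f_roh_8_16", "f_roh_gt16"]].sum(axis=1)
        np.testing.assert_allclose(rec["f_roh"], parts, atol=1e-12)
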