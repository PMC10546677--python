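"""Scan engine: LOD identities, thresholds, intervals, effects, colocalization."""

import numpy as np
import pandas as pd
import pytest

import microqtl as mq
from microqtl import qtl_scan as qs


def _covariates(n, rng):
    return mq.CovariateTable(
        pd.DataFrame(
            {
                "sex": np.where(rng.random(n) < 0.5, "male", "female"),
                "diet": np.where(rng.random(n) < 0.5, "American", "ketogenic"),
            },
            index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"),
        )
    )


def _random_design(rng, n=40):
    cov = _covariates(n, rng)
    g = rng.integers(0, 3, n)
    # guarantee all classes/strata populated
    g[:3] = [0, 1, 2]
    y = rng.normal(size=n)
    return y, cov, g


def _f_form_lod(y, cov, g, model):
    """Independent oracle: LOD from the F statistic of the nested fit."""
    male, keto = cov.male_indicator(), cov.keto_indicator()
    het, hom = (g == 1).astype(float), (g == 2).astype(float)
    one = np.ones(len(y))
    if model == "marginal":
        X0 = np.column_stack([one, male, keto, male * keto])
        X1 = np.column_stack([X0, het, hom])
    else:
        s = keto if model == "by_diet" else male
        X0 = np.column_stack([one, male, keto, het, hom])
        X1 = np.column_stack([X0, het * s, hom * s])
    def rss(X):
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        resid = y - X @ beta
        return float(resid @ resid)

    r0, r1 = rss(X0), rss(X1)
    d1 = np.linalg.matrix_rank(X1) - np.linalg.matrix_rank(X0)
    if d1 == 0:
        return 0.0
    d2 = len(y) - np.linalg.matrix_rank(X1)
    F = ((r0 - r1) / d1) / (r1 / d2)
    return (len(y) / 2) * np.log10(1 + F * d1 / d2)


class TestLodAtMarker:
    @pytest.mark.parametrize("model", qs.MODELS)
    def test_f_statistic_identity(self, model):
        """RSS-form LOD equals the F-statistic-form LOD to 1e-10."""
        rng = np.random.default_rng(1)
        for _ in range(100):
            y, cov, g = _random_design(rng)
            lod, *_ = qs.lod_at_marker(y, cov, g, model)
            assert lod == pytest.approx(_f_form_lod(y, cov, g, model), abs=1e-10)

    def test_constant_genotype_gives_zero(self):
        rng = np.random.default_rng(2)
        y, cov, _ = _random_design(rng)
        lod, r0, r1, _ = qs.lod_at_marker(y, cov, np.zeros(len(y), dtype=int), "marginal")
        assert lod == pytest.approx(0.0, abs=1e-10)
        assert r0 == pytest.approx(r1, abs=1e-10)

    def test_missing_rows_deleted(self):
        rng = np.random.default_rng(3)
        y, cov, g = _random_design(rng, n=60)
        g2 = g.copy()
        g2[:10] = -1
        _, _, _, n_used = qs.lod_at_marker(y, cov, g2, "marginal")
        assert n_used == 50

    def test_too_few_rows_skipped(self):
        rng = np.random.default_rng(4)
        y, cov, g = _random_design(rng, n=40)
        g2 = np.full(40, -1)
        g2[:5] = [0, 1, 2, 0, 1]
        lod, *_ = qs.lod_at_marker(y, cov, g2, "marginal")
        assert np.isnan(lod)


@pytest.fixture(scope="module")
def study():
    m = mq.simulate_map(3, 15, 90.0, seed=1)
    g = mq.simulate_f2_genotypes(m, 300, seed=2)
    cov = mq.simulate_covariates(300, seed=3)
    return m, g, cov


@pytest.fixture(scope="module")
def small_study():
    m = mq.simulate_map(3, 10, 90.0, seed=11)
    g = mq.simulate_f2_genotypes(m, 200, seed=12)
    cov = mq.simulate_covariates(200, seed=13)
    return g, cov


class TestGenomeScan:
    def test_planted_qtl_peak_near_truth(self, study):
        m, g, cov = study
        rng = np.random.default_rng(5)
        truth = 22
        y = 0.6 * g.genotypes[:, truth] + rng.normal(size=300)
        scan = mq.genome_scan(y, g, cov, "marginal", trait_id="t")
        peak = int(np.argmax(scan.lod))
        assert scan.chromosome[peak] == scan.chromosome[truth]
        assert abs(scan.position_cM[peak] - scan.position_cM[truth]) < 15

    def test_affine_invariance(self, study):
        _, g, cov = study
        rng = np.random.default_rng(6)
        y = rng.normal(size=300)
        a = mq.genome_scan(y, g, cov, "by_diet", trait_id="t")
        b = mq.genome_scan(-3.2 * y + 7, g, cov, "by_diet", trait_id="t")
        np.testing.assert_allclose(a.lod, b.lod, atol=1e-8)

    def test_sample_order_invariance(self, study):
        _, g, cov = study
        rng = np.random.default_rng(7)
        y = pd.Series(rng.normal(size=300), index=g.sample_ids)
        perm = rng.permutation(300)
        ids = [g.sample_ids[i] for i in perm]
        g2 = mq.GenotypeMatrix(ids, g.genotypes[perm], g.map)
        cov2 = cov.select_samples(ids)
        a = mq.genome_scan(y, g, cov, "marginal", trait_id="t")
        b = mq.genome_scan(y.loc[ids], g2, cov2, "marginal", trait_id="t")
        np.testing.assert_allclose(a.lod, b.lod, atol=1e-8)

    def test_fast_matrix_path_matches_per_marker(self, study):
        _, g, cov = study
        rng = np.random.default_rng(8)
        Y = rng.normal(size=(300, 3))
        for model in qs.MODELS:
            lodm = qs.scan_lod_matrix(Y, g, cov, model)
            for c in range(3):
                scan = mq.genome_scan(Y[:, c], g, cov, model, trait_id=f"c{c}")
                np.testing.assert_allclose(lodm[:, c], scan.lod, atol=1e-9)


class TestThresholds:
    def test_monotone_in_alpha_and_deterministic(self, small_study):
        g, cov = small_study
        rng = np.random.default_rng(14)
        tm = mq.TraitMatrix(
            pd.DataFrame({"t": rng.normal(size=200)}, index=g.sample_ids),
            {"t": "diversity"},
        )
        a = mq.permutation_thresholds(tm, g, cov, "marginal", n_perm=150, seed=9)
        b = mq.permutation_thresholds(tm, g, cov, "marginal", n_perm=150, seed=9)
        assert a.class_thresholds[0.01] >= a.class_thresholds[0.05]
        assert a.class_thresholds == b.class_thresholds

    def test_identical_columns_share_thresholds(self, small_study):
        g, cov = small_study
        rng = np.random.default_rng(15)
        y = rng.normal(size=200)
        tm = mq.TraitMatrix(
            pd.DataFrame({"t1": y, "t2": y.copy()}, index=g.sample_ids),
            {"t1": "diversity", "t2": "diversity"},
        )
        thr = mq.permutation_thresholds(tm, g, cov, "marginal", n_perm=100, seed=16)
        assert thr.per_trait["t1"] == thr.per_trait["t2"]

    def test_shared_null_shortcut_is_exact_for_qn_columns(self, small_study):
        """Quantile-normalized complete columns get one permutation batch,
        equal by construction to running each column separately."""
        from microqtl import trait_prep as tp

        g, cov = small_study
        rng = np.random.default_rng(17)
        raw = pd.DataFrame(
            {f"t{j}": rng.normal(size=200) for j in range(3)}, index=g.sample_ids
        )
        qn = tp.quantile_normalize(raw)
        tm = mq.TraitMatrix(qn, {c: "asv_abundance" for c in qn.columns})
        thr = mq.permutation_thresholds(tm, g, cov, "marginal", n_perm=100, seed=18)
        vals = [tuple(thr.per_trait[t].items()) for t in qn.columns]
        assert len(set(vals)) == 1
        solo = mq.permutation_thresholds(
            tm.subset(["t0"]), g, cov, "marginal", n_perm=100, seed=18
        )
        assert solo.per_trait["t0"] == thr.per_trait["t0"]

    def test_stratified_permutation_mode(self, small_study):
        g, cov = small_study
        rng = np.random.default_rng(19)
        tm = mq.TraitMatrix(
            pd.DataFrame({"t": rng.normal(size=200)}, index=g.sample_ids),
            {"t": "diversity"},
        )
        thr = mq.permutation_thresholds(
            tm, g, cov, "by_diet", n_perm=100, seed=20, stratify_by="diet"
        )
        assert thr.class_thresholds[0.05] > 0


class TestPeaksAndIntervals:
    def _scan(self, lods, chrom=None):
        m = len(lods)
        chrom = chrom if chrom is not None else np.ones(m, dtype=int)
        return qs.ScanResult(
            trait_id="t",
            model="marginal",
            marker_ids=[f"m{j}" for j in range(m)],
            chromosome=np.asarray(chrom),
            position_cM=np.arange(m, dtype=float),
            position_Mb=np.arange(m, dtype=float) * 2,
            lod=np.asarray(lods, dtype=float),
            n_used=np.full(m, 100),
            rss_null=np.full(m, np.nan),
            rss_alt=np.full(m, np.nan),
        )

    def _thresholds(self, t05=4.00, t01=5.19):
        return qs.Thresholds(
            trait_class="asv_abundance",
            model="marginal",
            n_perm=10000,
            alphas=(0.05, 0.01),
            class_thresholds={0.05: t05, 0.01: t01},
            per_trait={},
        )

    def test_peak_significance_classes(self):
        thr = self._thresholds()
        peaks = qs.call_peaks(self._scan([1.0, 4.5, 2.0]), thr)
        assert len(peaks) == 1 and peaks[0].significance_level == 0.05
        peaks = qs.call_peaks(self._scan([1.0, 5.88, 2.0]), thr)
        assert peaks[0].significance_level == 0.01

    def test_below_threshold_no_peaks(self):
        assert qs.call_peaks(self._scan([3.9, 3.5, 1.0]), self._thresholds()) == []

    def test_one_peak_per_chromosome(self):
        scan = self._scan([5.0, 1.0, 4.4, 6.0, 1.0], chrom=[1, 1, 1, 2, 2])
        peaks = qs.call_peaks(scan, self._thresholds())
        assert [p.chromosome for p in peaks] == [1, 2]
        assert [p.marker_id for p in peaks] == ["m0", "m3"]

    def test_interval_spans_flanks_below_drop(self):
        scan = self._scan([1.0, 5.0, 1.0])
        peak = qs.call_peaks(scan, self._thresholds())[0]
        assert qs.support_interval(scan, peak, 1.5) == ("m0", "m2")

    def test_interval_capped_at_chromosome_end(self):
        scan = self._scan([1.0, 3.0, 4.2, 5.5])
        peak = qs.call_peaks(scan, self._thresholds())[0]
        left, right = qs.support_interval(scan, peak, 1.5)
        assert (left, right) == ("m1", "m3")

    def test_plateau_fully_inside_interval(self):
        scan = self._scan([0.5, 5.0, 5.0, 5.0, 0.5])
        peak = qs.call_peaks(scan, self._thresholds())[0]
        left, right = qs.support_interval(scan, peak, 1.5)
        assert (left, right) == ("m0", "m4")

    def test_widening_drop_never_shrinks(self):
        rng = np.random.default_rng(30)
        lods = np.abs(np.cumsum(rng.normal(size=25))) + 4.2
        scan = self._scan(lods)
        peak = qs.call_peaks(scan, self._thresholds())[0]
        prev_span = None
        ids = scan.marker_ids
        for drop in (0.5, 1.5, 3.0, 6.0):
            left, right = qs.support_interval(scan, peak, drop)
            span = (ids.index(left), ids.index(right))
            assert span[0] <= ids.index(peak.marker_id) <= span[1]
            if prev_span is not None:
                assert span[0] <= prev_span[0] and span[1] >= prev_span[1]
            prev_span = span


class TestAlleleEffects:
    def test_exact_additive_recovery(self):
        rng = np.random.default_rng(40)
        n = 90
        cov = _covariates(n, rng)
        g = rng.integers(0, 3, n)
        g[:3] = [0, 1, 2]
        eff = mq.allele_effects(g.astype(float), cov, g, "marginal")
        assert eff.effect_het == pytest.approx(1.0, abs=1e-10)
        assert eff.effect_hom == pytest.approx(2.0, abs=1e-10)

    def test_planted_effect_recovery_within_3se(self):
        rng = np.random.default_rng(41)
        n = 400
        cov = _covariates(n, rng)
        g = rng.integers(0, 3, n)
        y = 0.5 * g + rng.normal(size=n)
        eff = mq.allele_effects(y, cov, g, "marginal")
        assert abs(eff.effect_het - 0.5) < 3 * eff.se_het
        assert abs(eff.effect_hom - 1.0) < 3 * eff.se_hom

    def test_by_diet_effects_within_american_stratum(self):
        rng = np.random.default_rng(42)
        n = 600
        cov = _covariates(n, rng)
        g = rng.integers(0, 3, n)
        am = 1.0 - cov.keto_indicator()
        y = 0.8 * g * am + rng.normal(size=n)  # genotype acts only on American diet
        eff = mq.allele_effects(y, cov, g, "by_diet")
        assert eff.stratum == "American"
        assert abs(eff.effect_het - 0.8) < 3 * eff.se_het
        assert abs(eff.effect_hom - 1.6) < 3 * eff.se_hom

    def test_empty_genotype_class_reported_missing(self):
        rng = np.random.default_rng(43)
        n = 60
        cov = _covariates(n, rng)
        g = rng.integers(0, 2, n)  # no hom-FVB class
        eff = mq.allele_effects(rng.normal(size=n), cov, g, "marginal")
        assert np.isnan(eff.effect_hom) and np.isfinite(eff.effect_het)


class TestVariancePartition:
    def test_orthogonal_design_closed_form(self, balanced_covariates):
        cov = balanced_covariates
        keto = cov.keto_indicator()
        y = 2.0 * keto  # diet explains everything
        g = np.tile([0, 1, 2, 1], 50)
        vp = mq.variance_partition(y, cov, g, "marginal")
        assert vp["diet"][0] == pytest.approx(100.0, abs=1e-8)
        for term in ("sex", "sex:diet"):
            assert vp[term][0] == pytest.approx(0.0, abs=1e-8)

    def test_percent_bounds_and_sum(self):
        rng = np.random.default_rng(50)
        n = 150
        cov = _covariates(n, rng)
        g = rng.integers(0, 3, n)
        y = rng.normal(size=n) + 0.3 * g
        for model in qs.MODELS:
            vp = mq.variance_partition(y, cov, g, model)
            pcts = [v[0] for v in vp.values()]
            assert all(-1e-9 <= p <= 100 + 1e-9 for p in pcts)
            assert sum(pcts) <= 100 + 1e-6

    def test_null_trait_small_components(self):
        rng = np.random.default_rng(51)
        n = 500
        cov = _covariates(n, rng)
        g = rng.integers(0, 3, n)
        pvals = []
        for rep in range(40):
            y = rng.normal(size=n)
            vp = mq.variance_partition(y, cov, g, "marginal")
            assert vp["marker"][0] < 5.0
            pvals.append(vp["marker"][1])
        # null p-values roughly uniform: mean near 0.5
        assert 0.3 < np.mean(pvals) < 0.7


class TestOverlap:
    def _call(self, qtl_id, chrom, left, right, trait="t", model="marginal"):
        return qs.QtlCall(
            qtl_id=qtl_id,
            trait_id=trait,
            model=model,
            chromosome=chrom,
            top_marker="m",
            top_Mb=(left + right) / 2,
            left_marker="l",
            left_Mb=left,
            right_marker="r",
            right_Mb=right,
            lod_peak=5.0,
            significance_level=0.05,
            effect_het=0.0,
            effect_hom=0.0,
        )

    def test_containment_flagged(self):
        a = self._call("inner", 1, 160.6, 185.1)
        b = self._call("outer", 1, 151.9, 193.3)
        groups = mq.overlap_qtl([a, b])
        assert len(groups) == 1
        assert groups[0]["members"] == ["inner", "outer"]
        assert ("inner", "outer") in groups[0]["contained_in"]

    def test_different_chromosomes_never_overlap(self):
        a = self._call("a", 1, 10, 20)
        b = self._call("b", 2, 10, 20)
        assert mq.overlap_qtl([a, b]) == []

    def test_touching_endpoints_overlap(self):
        a = self._call("a", 1, 10, 20)
        b = self._call("b", 1, 20, 30)
        groups = mq.overlap_qtl([a, b])
        assert len(groups) == 1 and groups[0]["members"] == ["a", "b"]

    def test_metabolic_calls_join_groups(self):
        a = self._call("asv", 16, 60, 80)
        met = self._call("fmg", 16, 70, 95, trait="fat_mass_gain")
        groups = mq.overlap_qtl([a], [met])
        assert groups[0]["members"] == ["asv", "fmg"]
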