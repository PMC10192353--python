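"""Single-locus association tests, candidate calling and the power driver."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from fundusmap.linkage import (
    MODELS,
    PedigreeConfig,
    bonferroni_threshold,
    call_candidates,
    encode_genotypes,
    ordinal_association_test,
    power_study,
    scan_pedigree,
    single_locus_test,
)
from fundusmap.pedigree import genotype_table, mutation_table
from fundusmap.phenotype import PhenotypeModel, phenotype_table, simulate_exams


def permutation_pvalue(y, x, n_perm, rng):
    """Monte-Carlo permutation p for the slope |t| with x held fixed."""
    y = np.asarray(y, float)
    xc = x - x.mean()
    sxx = float((xc**2).sum())

    def tstat(v):
        vc = v - v.mean()
        sxy = float(xc @ vc)
        syy = float((vc**2).sum())
        b1 = sxy / sxx
        sse = max(syy - b1 * sxy, 1e-300)
        return abs(b1 / math.sqrt(sse / (len(v) - 2) / sxx))

    t_obs = tstat(y)
    hits = sum(tstat(rng.permutation(y)) >= t_obs - 1e-12 for _ in range(n_perm))
    return hits / n_perm


class TestEncoding:
    @pytest.mark.parametrize(
        "model,expected",
        [
            ("recessive", [0.0, 0.0, 1.0]),
            ("semidominant", [0.0, 1.0, 2.0]),
            ("dominant", [0.0, 1.0, 1.0]),
        ],
    )
    def test_three_encodings(self, model, expected):
        assert encode_genotypes(["REF", "HET", "VAR"], model).tolist() == expected

    def test_unknown_call_and_model_rejected(self):
        with pytest.raises(ValueError):
            encode_genotypes(["REF", "het"], "recessive")
        with pytest.raises(ValueError):
            encode_genotypes(["REF"], "codominant")


class TestSingleLocusTest:
    def test_closed_form_toy(self):
        # x=[0,0,0,1,1,1], y=[1,2,3,7,8,9]: Sxx=1.5, Sxy=9, Syy=58
        # -> beta1=6, beta0=2, SSE=4, s^2=1, t=6*sqrt(1.5)
        calls = [0, 0, 0, 2, 2, 2]  # recessive encoding gives x=[0,0,0,1,1,1]
        y = [1, 2, 3, 7, 8, 9]
        res = single_locus_test(y, calls, "recessive")
        t_expected = 6 * math.sqrt(1.5)
        assert res.beta1 == pytest.approx(6.0, rel=1e-12)
        assert res.beta0 == pytest.approx(2.0, rel=1e-12)
        assert res.stat == pytest.approx(t_expected, rel=1e-12)
        assert res.df == 4
        assert res.p == pytest.approx(2 * stats.t.sf(t_expected, 4), rel=1e-12)
        assert res.neglog10p == pytest.approx(-math.log10(res.p))

    def test_matches_statsmodels_ols(self, rng):
        calls = rng.choice([0, 1, 2], size=30, p=[0.375, 0.5, 0.125])
        y = rng.normal(3, 2, size=30) + 1.5 * (calls == 2)
        for model in MODELS:
            x = encode_genotypes(calls, model)
            if np.ptp(x) == 0:
                continue
            ours = single_locus_test(y, calls, model)
            ref = sm.OLS(y, sm.add_constant(x)).fit()
            assert ours.beta1 == pytest.approx(ref.params[1], rel=1e-10)
            assert ours.stat == pytest.approx(ref.tvalues[1], rel=1e-10)
            assert ours.p == pytest.approx(ref.pvalues[1], rel=1e-10)

    def test_constant_phenotype_degenerate(self):
        res = single_locus_test([2, 2, 2, 2], [0, 1, 2, 1], "semidominant")
        assert res.status == "degenerate"
        assert math.isnan(res.p)

    def test_zero_variance_genotype_degenerate(self):
        res = single_locus_test([1, 2, 3, 4], [0, 1, 0, 1], "recessive")
        assert res.status == "degenerate"

    def test_input_validation(self):
        with pytest.raises(ValueError):
            single_locus_test([1, 2], [0, 1, 2], "recessive")
        with pytest.raises(ValueError):
            single_locus_test([1, 2], [0, 2], "recessive")

    def test_permutation_p_close_at_small_n(self, rng):
        # the normal-theory p and the permutation p differ by O(1/n) at n=8;
        # guard against gross errors with a finite-sample band
        for _ in range(3):
            calls = rng.choice([0, 1, 2], size=8, p=[0.375, 0.5, 0.125])
            if len(np.unique(encode_genotypes(calls, "semidominant"))) < 2:
                continue
            y = rng.normal(2, 1, size=8) + (calls == 2)
            res = single_locus_test(y, calls, "semidominant")
            p_perm = permutation_pvalue(y, encode_genotypes(calls, "semidominant"), 20_000, rng)
            assert abs(res.p - p_perm) <= 0.06


class TestOrdinalTest:
    def test_no_affected_mice_p_one(self):
        res = ordinal_association_test([False] * 10, [0, 1, 2, 0, 1, 2, 0, 1, 0, 1], "recessive")
        assert res.p == 1.0

    def test_matches_hypergeometric_enumeration(self):
        # both VAR mice affected, none of the 28 others: table [[2,0],[0,28]]
        affected = [True, True] + [False] * 28
        calls = [2, 2] + [0] * 14 + [1] * 14
        res = ordinal_association_test(affected, calls, "recessive")
        # brute-force two-sided Fisher: sum of P(table) <= P(observed)
        # over all tables with margins (2 affected, 2 susceptible, n=30)
        n, k_aff, k_susc = 30, 2, 2
        probs = [stats.hypergeom.pmf(a, n, k_aff, k_susc) for a in range(0, 3)]
        p_obs = stats.hypergeom.pmf(2, n, k_aff, k_susc)
        expected = sum(p for p in probs if p <= p_obs * (1 + 1e-12))
        assert res.p == pytest.approx(expected, rel=1e-9)

    def test_invariant_to_mouse_order(self, rng):
        affected = rng.choice([True, False], size=20)
        calls = rng.choice([0, 1, 2], size=20)
        res1 = ordinal_association_test(affected, calls, "dominant")
        perm = rng.permutation(20)
        res2 = ordinal_association_test(affected[perm], calls[perm], "dominant")
        assert res1.p == res2.p

    def test_empty_genotype_arm_degenerate(self):
        res = ordinal_association_test([True, False, True], [0, 0, 0], "recessive")
        assert res.status == "degenerate"


class TestBonferroni:
    def test_values_and_monotonicity(self):
        assert bonferroni_threshold(1, 1) == 0.05
        assert bonferroni_threshold(60, 3) == pytest.approx(0.05 / 180)
        assert bonferroni_threshold(61, 3) < bonferroni_threshold(60, 3)

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(10, 3, alpha=1.5)


class TestScanPedigree:
    @pytest.fixture()
    def scanned(self, screen_pedigree):
        rng = np.random.default_rng(23)
        causal = screen_pedigree.site_ids[30]
        exams = simulate_exams(screen_pedigree, causal, PhenotypeModel(), rng)
        pheno = phenotype_table(exams)
        geno = genotype_table(screen_pedigree, "G3")
        manhattan = scan_pedigree(pheno, geno, sites=mutation_table(screen_pedigree))
        return causal, pheno, geno, manhattan

    def test_row_per_site_no_missing(self, scanned):
        _, _, _, manhattan = scanned
        assert len(manhattan) == 60
        ok = manhattan[manhattan["status"] == "ok"]
        assert ok["best_p"].between(0, 1).all()
        assert np.isfinite(ok["neglog10p"]).all()

    def test_single_site_matches_single_locus_test(self, scanned):
        causal, pheno, geno, manhattan = scanned
        row = manhattan.set_index("site_id").loc[causal]
        ordered = geno.set_index("mouse_id").loc[pheno["mouse_id"]]
        res = single_locus_test(pheno["mouse_score"], ordered[causal].tolist(), "recessive")
        assert row["p_recessive"] == pytest.approx(res.p, rel=1e-12)

    def test_invariant_to_mouse_row_order(self, scanned, rng):
        _, pheno, geno, manhattan = scanned
        shuffled = pheno.sample(frac=1.0, random_state=3).reset_index(drop=True)
        manhattan2 = scan_pedigree(shuffled, geno, sites=None)
        merged = manhattan.merge(manhattan2, on="site_id", suffixes=("_a", "_b"))
        assert np.allclose(merged["best_p_a"], merged["best_p_b"], rtol=1e-12)

    def test_degenerate_recessive_sites_flagged_not_dropped(self, scanned):
        _, _, _, manhattan = scanned
        no_var = manhattan[manhattan["n_VAR"] == 0]
        if len(no_var):
            assert no_var["p_recessive"].isna().all()
            # dominant/semidominant still testable there
            assert (no_var["status"] == "ok").all()

    def test_mismatched_mice_rejected(self, scanned):
        _, pheno, geno, _ = scanned
        bad = pheno.copy()
        bad.loc[0, "mouse_id"] = "ghost"
        with pytest.raises(ValueError, match="ghost"):
            scan_pedigree(bad, geno)


class TestCallCandidates:
    @staticmethod
    def manhattan_from_logs(logs, genes=None):
        genes = genes or [f"g{i}" for i in range(len(logs))]
        return pd.DataFrame(
            {
                "site_id": [f"s{i}" for i in range(len(logs))],
                "gene": genes,
                "best_p": [10 ** (-v) for v in logs],
                "neglog10p": logs,
                "status": ["ok"] * len(logs),
            }
        )

    def test_single_site_margin_infinite(self):
        calls = call_candidates(self.manhattan_from_logs([5.0]), threshold=0.05)
        assert calls[0].is_candidate and calls[0].margin_logs == math.inf

    def test_three_log_margin_rule(self):
        passed = call_candidates(self.manhattan_from_logs([15.0, 11.0]), 1e-3)
        assert passed[0].is_candidate and passed[0].margin_logs == pytest.approx(4.0)
        failed = call_candidates(self.manhattan_from_logs([15.0, 13.0]), 1e-3)
        assert not failed[0].is_candidate
        assert failed[0].margin_logs == pytest.approx(2.0)

    def test_same_gene_peaks_do_not_defeat_candidate(self):
        table = self.manhattan_from_logs([15.0, 13.0, 2.0], genes=["gA", "gA", "gB"])
        calls = call_candidates(table, 1e-3)
        assert calls[0].is_candidate
        assert calls[0].margin_logs == pytest.approx(13.0)

    def test_below_threshold_not_candidate(self):
        calls = call_candidates(self.manhattan_from_logs([2.0, 1.0]), 1e-4)
        assert calls[0].above_threshold is False and not calls[0].is_candidate

    def test_all_degenerate_empty(self):
        table = self.manhattan_from_logs([1.0])
        table["status"] = "degenerate"
        assert call_candidates(table, 0.05) == []


class TestPowerStudy:
    def test_null_familywise_rate_controlled(self):
        report = power_study(
            PedigreeConfig(min_var_carriers=0),
            PhenotypeModel(effect_size=0.0),
            causal=False,
            n_reps=60,
            seed=31,
        )
        assert report.familywise_fp_rate <= 0.05

    def test_strong_effect_detected_with_recessive_model_best(self):
        report = power_study(
            PedigreeConfig(), PhenotypeModel(), causal=True, n_reps=40, seed=32
        )
        assert report.power >= 0.95
        assert report.per_model_power["recessive"] > 0.5

    def test_report_reproducible_for_fixed_seed(self):
        kwargs = dict(
            pedigree_config=PedigreeConfig(),
            phenotype_model=PhenotypeModel(),
            causal=True,
            n_reps=5,
            seed=33,
        )
        a, b = power_study(**kwargs), power_study(**kwargs)
        assert (a.power, a.familywise_fp_rate, a.per_model_power) == (
            b.power,
            b.familywise_fp_rate,
            b.per_model_power,
        )

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            power_study(PedigreeConfig(), PhenotypeModel(), True, 0)
        with pytest.raises(ValueError):
            power_study(PedigreeConfig(), PhenotypeModel(), True, 1, encoding_mode="binary")
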