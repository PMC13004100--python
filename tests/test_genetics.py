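"""Wald-ratio MR, Wakefield ABF, colocalization, credible sets, LD, prioritization.

Oracles: a parametric bootstrap for the NOME first-order standard error,
numerical quadrature for the Gaussian Bayes factor, and hand-evaluated
correlations for LD.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import norm

from epishift.genetics import (
    ColocResult,
    PrioritizationRecord,
    SummaryStatRecord,
    coloc_abf,
    credible_set_from_pips,
    ld_r2_matrix,
    prioritize_variants,
    read_summary_stats,
    wakefield_labf,
    wald_ratio_mr,
    write_summary_stats,
)
from epishift.synthetic import simulate_two_trait_summary_stats


def _rec(variant="rs1", beta=0.2, se=0.05, ea="A", oa="G", eaf=0.3, p=0.01, n=5000):
    return SummaryStatRecord(
        variant_id=variant, chromosome="17", position=66_212_167,
        effect_allele=ea, other_allele=oa, eaf=eaf, beta=beta, se=se, p=p, n=n,
    )


class TestWaldRatio:
    def test_zero_outcome_effect(self):
        res = wald_ratio_mr(_rec(beta=0.2), _rec(beta=0.0, se=0.04))
        assert res.ratio == 0.0

    def test_f_statistic_closed_form(self):
        res = wald_ratio_mr(_rec(beta=0.2, se=0.1), _rec(beta=0.1))
        assert res.f_statistic == pytest.approx(4.0)

    def test_sign_flips_with_outcome_allele_swap(self):
        out = _rec(beta=0.1, se=0.04)
        flipped = _rec(beta=-0.1, se=0.04, ea="G", oa="A", eaf=0.7)
        a = wald_ratio_mr(_rec(), out)
        b = wald_ratio_mr(_rec(), flipped)
        assert a.ratio == pytest.approx(b.ratio)
        assert a.se_ratio == pytest.approx(b.se_ratio)

    def test_unresolvable_alleles_rejected(self):
        with pytest.raises(ValueError, match="harmonized"):
            wald_ratio_mr(_rec(), _rec(ea="T", oa="C"))

    def test_zero_exposure_beta_rejected(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio_mr(_rec(beta=0.0), _rec())

    def test_strand_ambiguous_warns_but_keeps(self):
        with pytest.warns(UserWarning, match="ambiguous"):
            res = wald_ratio_mr(_rec(ea="A", oa="T", eaf=0.1), _rec(ea="A", oa="T", eaf=0.1))
        assert np.isfinite(res.ratio)

    def test_nome_se_matches_parametric_bootstrap(self, rng):
        """First-order NOME SE vs resampling only the outcome effect."""
        exp = _rec(beta=0.31, se=0.07)
        out = _rec(beta=-0.12, se=0.045)
        res = wald_ratio_mr(exp, out)
        draws = rng.normal(out.beta, out.se, size=100_000) / exp.beta
        assert res.se_ratio == pytest.approx(draws.std(ddof=1), rel=0.01)


class TestWakefieldAbf:
    def test_null_z_shrinks(self):
        labf = wakefield_labf(0.0, 0.1, prior_sd=0.2)
        r = 0.2**2 / (0.2**2 + 0.1**2)
        assert labf == pytest.approx(0.5 * np.log(1 - r))
        assert labf < 0

    def test_vanishing_prior_gives_zero(self):
        assert wakefield_labf(0.3, 0.1, prior_sd=1e-12) == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("beta,se,w", [(0.2, 0.05, 0.15), (-0.4, 0.11, 0.2), (0.01, 0.2, 0.3)])
    def test_matches_numerical_quadrature(self, beta, se, w):
        """ABF = marginal likelihood ratio of N(0, se^2+W^2) vs N(0, se^2)."""

        def integrand(b):
            return norm.pdf(beta, loc=b, scale=se) * norm.pdf(b, scale=w)

        marginal, _ = quad(integrand, -10 * w, 10 * w, limit=200)
        null = norm.pdf(beta, scale=se)
        assert wakefield_labf(beta, se, w) == pytest.approx(np.log(marginal / null), abs=1e-6)


class TestColoc:
    def _random_traits(self, rng, m=20):
        t1 = [_rec(variant=f"rs{i}", beta=rng.normal(0, 0.05), se=0.03) for i in range(m)]
        t2 = [_rec(variant=f"rs{i}", beta=rng.normal(0, 0.05), se=0.03) for i in range(m)]
        return t1, t2

    def test_posteriors_normalized(self, rng):
        t1, t2 = self._random_traits(rng)
        res = coloc_abf(t1, t2)
        assert res.pp.sum() == pytest.approx(1.0, abs=1e-8)
        assert res.per_variant_pp4.sum() == pytest.approx(1.0, abs=1e-8)
        assert np.all((res.pp >= 0) & (res.pp <= 1))

    def test_reordering_invariance(self, rng):
        t1, t2 = self._random_traits(rng)
        res1 = coloc_abf(t1, t2)
        perm = rng.permutation(len(t1))
        res2 = coloc_abf([t1[i] for i in perm], [t2[i] for i in perm])
        np.testing.assert_allclose(res1.pp, res2.pp, atol=1e-12)

    def test_null_trait_se_scaling_keeps_normalization(self, rng):
        t1, t2 = self._random_traits(rng)
        t2_scaled = [
            SummaryStatRecord(**{**r.__dict__, "se": r.se * 3.0}) for r in t2
        ]
        res = coloc_abf(t1, t2_scaled)
        assert res.pp.sum() == pytest.approx(1.0, abs=1e-8)

    def test_duplicate_variants_rejected(self):
        t = [_rec("rs1"), _rec("rs1")]
        with pytest.raises(ValueError, match="duplicate"):
            coloc_abf(t, t)

    def test_mismatched_variant_sets_rejected(self):
        with pytest.raises(ValueError, match="same variant set"):
            coloc_abf([_rec("rs1"), _rec("rs2")], [_rec("rs1"), _rec("rs3")])

    def test_single_variant_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            coloc_abf([_rec("rs1")], [_rec("rs1")])

    def test_shared_causal_simulation_recovers_pp4(self):
        t1, t2, truth = simulate_two_trait_summary_stats(shared=True, seed=5)
        res = coloc_abf(t1, t2)
        assert res.pp4 > 0.9
        assert res.lead_variant == truth.causal_variant

    def test_distinct_causal_simulation_favours_pp3(self):
        t1, t2, _ = simulate_two_trait_summary_stats(shared=False, seed=5)
        res = coloc_abf(t1, t2)
        assert int(np.argmax(res.pp)) == 3


class TestCredibleSet:
    # Printed fine-mapping worked example: lead variant 0.49, then
    # 0.06, 0.05, two 0.04s, two 0.03s and eleven 0.02s
    TABLE_PIPS = {
        "rs1801690": 0.49, "rs9902706": 0.06, "rs9906486": 0.05,
        "rs9905408": 0.04, "rs7211380": 0.04, "rs74934196": 0.03,
        "rs74531840": 0.03, "rs76375367": 0.02, "rs55657678": 0.02,
        "rs11651658": 0.02, "rs73992250": 0.02, "rs7216660": 0.02,
        "rs9891968": 0.02, "rs9908597": 0.02, "rs9895407": 0.02,
        "rs77620153": 0.02, "rs73992258": 0.02, "rs9911603": 0.02,
    }

    def test_published_pip_column_needs_all_18(self):
        cs = credible_set_from_pips(self.TABLE_PIPS, coverage=0.95)
        assert len(cs) == 18
        assert cs.cumulative_pip == pytest.approx(0.96)
        # top 17 fall short of the coverage level
        assert sum(sorted(self.TABLE_PIPS.values(), reverse=True)[:17]) == pytest.approx(0.94)
        assert cs.members[0] == ("rs1801690", 0.49)

    def test_single_certain_variant(self):
        cs = credible_set_from_pips({"rs1": 1.0, "rs2": 0.0})
        assert cs.variant_ids == ["rs1"]

    def test_uniform_pips_forced_full_set(self):
        cs = credible_set_from_pips({f"rs{i}": 0.1 for i in range(10)}, coverage=0.95)
        assert len(cs) == 10
        assert cs.cumulative_pip == pytest.approx(1.0)

    def test_insufficient_total_reports_achievable(self):
        with pytest.raises(ValueError, match="0.30"):
            credible_set_from_pips({"rs1": 0.2, "rs2": 0.1}, coverage=0.95)

    def test_ties_broken_lexicographically(self):
        cs = credible_set_from_pips({"rsB": 0.5, "rsA": 0.5}, coverage=0.5)
        assert cs.variant_ids == ["rsA"]

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        pips=st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=40),
        coverage=st.floats(0.05, 0.99),
    )
    def test_minimality_property(self, pips, coverage):
        """Dropping the smallest member always breaks coverage."""
        mapping = {f"v{i:03d}": p for i, p in enumerate(pips)}
        total = sum(pips)
        if total < coverage:
            with pytest.raises(ValueError):
                credible_set_from_pips(mapping, coverage)
            return
        cs = credible_set_from_pips(mapping, coverage)
        assert cs.cumulative_pip >= coverage - 1e-9
        without_last = cs.cumulative_pip - cs.members[-1][1]
        assert without_last < coverage


class TestLd:
    def test_duplicated_column_r2_one(self, rng):
        g = rng.integers(0, 3, size=(50, 2)).astype(float)
        g = np.column_stack([g[:, 0], g[:, 0], g[:, 1]])
        r2 = ld_r2_matrix(g)
        assert r2.iloc[0, 1] == pytest.approx(1.0)

    def test_independent_variants_near_zero(self, rng):
        g = rng.binomial(2, 0.3, size=(10_000, 4)).astype(float)
        r2 = ld_r2_matrix(g)
        off = r2.to_numpy()[~np.eye(4, dtype=bool)]
        assert np.all(off < 0.01)

    def test_four_sample_toy_hand_computed(self):
        g = pd.DataFrame({"a": [0.0, 1, 1, 2], "b": [0.0, 1, 2, 2]})
        r2 = ld_r2_matrix(g)
        expected = np.corrcoef(g["a"], g["b"])[0, 1] ** 2
        assert r2.loc["a", "b"] == pytest.approx(expected)
        assert r2.loc["a", "a"] == 1.0

    def test_monomorphic_variant_listed(self):
        g = np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 2.0]])
        with pytest.raises(ValueError, match="v1"):
            ld_r2_matrix(g)


class TestPrioritization:
    def test_no_criteria_not_prioritized(self):
        # the H3K4me1-gapped-peak-only record: regulatory overlap does not
        # count without narrow-peak support, expression effect is negative
        rec = PrioritizationRecord(variant_id="rs9902706")
        (out,) = prioritize_variants([rec])
        assert out.prioritized is False

    def test_coding_record_reports_deleterious_fraction(self):
        rec = PrioritizationRecord(
            variant_id="rs1801690", is_coding_nonsynonymous=True,
            deleterious_votes=7, total_predictors=9,
        )
        (out,) = prioritize_variants([rec])
        assert out.prioritized is True
        assert out.deleterious_fraction == pytest.approx(7 / 9)

    @pytest.mark.parametrize("n_true,expected", [(0, False), (1, False), (2, True), (3, True), (4, True)])
    def test_two_criteria_boundary(self, n_true, expected):
        flags = dict.fromkeys(
            ["regulatory_overlap", "re2g_link", "increases_expression", "qtl_colocalizes"], False
        )
        for key in list(flags)[:n_true]:
            flags[key] = True
        (out,) = prioritize_variants([PrioritizationRecord(variant_id="rsX", **flags)])
        assert out.prioritized is expected

    def test_votes_bounded_by_predictors(self):
        with pytest.raises(ValueError):
            PrioritizationRecord(variant_id="rs1", deleterious_votes=3, total_predictors=2)


class TestSummaryStatsIo:
    def test_round_trip(self, tmp_path):
        records = [_rec("rs1"), _rec("rs2", beta=-0.1, eaf=0.45)]
        path = tmp_path / "stats.tsv"
        write_summary_stats(records, path)
        back = read_summary_stats(path)
        assert back == records

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        pd.DataFrame({"variant_id": ["rs1"]}).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="missing columns"):
            read_summary_stats(path)

    @pytest.mark.parametrize(
        "kwargs",
        [dict(se=0.0), dict(eaf=0.0), dict(eaf=1.0), dict(ea="A", oa="A"), dict(p=0.0)],
    )
    def test_record_validation(self, kwargs):
        with pytest.raises(ValueError):
            _rec(**kwargs)
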