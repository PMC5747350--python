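"""Decoy FDR, presence filters, peptide selection, normalization, nested
statistics and exact-mass annotation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cholode.msprep import (
    annotate_ions,
    differential_call,
    estimate_fdr,
    filter_by_presence,
    load_toy_table,
    nested_anova,
    nested_cv,
    select_quant_peptides,
    total_intensity_normalize,
)


class TestEstimateFdr:
    def test_proteome_peptide_level_worked_example(self):
        est = estimate_fdr(24266, 111, 0.6)
        assert round(est.fdr, 6) == 0.002745

    def test_phospho_worked_example(self):
        est = estimate_fdr(2209, 88, 0.45)
        assert round(est.fdr, 4) == 0.0179

    def test_no_decoys_gives_zero(self):
        assert estimate_fdr(1000, 0, 0.6).fdr == 0.0

    def test_linear_in_fft_and_decoys(self):
        base = estimate_fdr(5000, 40, 0.3).fdr
        assert estimate_fdr(5000, 40, 0.6).fdr == pytest.approx(2 * base)
        assert estimate_fdr(5000, 80, 0.3).fdr == pytest.approx(2 * base)

    @pytest.mark.parametrize("args", [(0, 5, 0.6), (100, -1, 0.6), (100, 5, 0.0), (100, 5, 1.5)])
    def test_invalid_inputs(self, args):
        with pytest.raises(ValueError):
            estimate_fdr(*args)


class TestPresenceFilter:
    def records(self, pattern, n_runs=10):
        rows = []
        for prec, passing in pattern.items():
            for r in range(n_runs):
                rows.append(
                    {
                        "precursor": prec,
                        "m_score": 1e-6 if r in passing else 0.5,
                        "run": f"r{r}",
                        "condition": "A" if r < n_runs // 2 else "B",
                        "bio_rep": r % (n_runs // 2),
                    }
                )
        return pd.DataFrame(rows)

    def test_boundary_inclusive_two_of_ten(self):
        recs = self.records({"p": {0, 1}})
        assert filter_by_presence(recs, 1e-5, ("fraction_of_files", 0.2)) == ["p"]

    def test_one_of_ten_removed(self):
        recs = self.records({"p": {0}})
        assert filter_by_presence(recs, 1e-5, ("fraction_of_files", 0.2)) == []

    def test_toy_table_matches_exhaustive_enumeration(self):
        recs = load_toy_table("id_toy")
        survivors = filter_by_presence(recs, 1e-5, ("fraction_of_files", 0.2))
        # independent brute force over every precursor and run
        n_files = recs["run"].nunique()
        expected = []
        for prec in sorted(recs["precursor"].unique()):
            sub = recs[recs["precursor"] == prec]
            n_pass = sum(
                (sub[sub["run"] == run]["m_score"] <= 1e-5).any()
                for run in sub["run"].unique()
            )
            if n_pass >= 0.2 * n_files:
                expected.append(prec)
        assert survivors == expected == ["p3", "p4", "p5"]

    def test_replicates_in_condition_rule(self):
        recs = load_toy_table("id_toy")
        survivors = filter_by_presence(
            recs, 1e-5, ("replicates_in_condition", 3)
        )
        assert survivors == ["p4", "p5"]

    def test_monotone_in_threshold(self):
        recs = load_toy_table("id_toy")
        loose = set(filter_by_presence(recs, 0.1, ("fraction_of_files", 0.2)))
        strict = set(filter_by_presence(recs, 1e-5, ("fraction_of_files", 0.2)))
        assert strict <= loose

    def test_monotone_in_fraction(self):
        recs = load_toy_table("id_toy")
        low_q = set(filter_by_presence(recs, 1e-5, ("fraction_of_files", 0.1)))
        high_q = set(filter_by_presence(recs, 1e-5, ("fraction_of_files", 0.5)))
        assert high_q <= low_q

    def test_invalid_rules(self):
        recs = load_toy_table("id_toy")
        with pytest.raises(ValueError):
            filter_by_presence(recs, 1e-5, ("fraction_of_files", 0.0))
        with pytest.raises(ValueError):
            filter_by_presence(recs, 1e-5, ("replicates_in_condition", 0))


class TestPeptideSelection:
    def test_top_seven_of_ten(self):
        recs = load_toy_table("peptides_toy")
        out = select_quant_peptides(recs, top_k=7)
        pa = sorted(out[out["protein"] == "PA"]["precursor"].unique())
        assert len(pa) == 7
        assert pa == [f"PA_pep{i:02d}" for i in range(7)]  # highest signals

    def test_fewer_than_k_all_retained(self):
        recs = load_toy_table("peptides_toy")
        out = select_quant_peptides(recs, top_k=7)
        assert out[out["protein"] == "PB"]["precursor"].nunique() == 3

    def test_shared_peptide_removed_despite_signal(self):
        recs = load_toy_table("peptides_toy")
        out = select_quant_peptides(recs, top_k=7)
        assert "PC_shared" not in set(out["precursor"])
        assert "PC_pep1" in set(out["precursor"])

    def test_lexicographic_tie_break(self):
        rows = [
            {"precursor": p, "protein": "P", "proteotypic": True, "intensity": 100.0}
            for p in ("pepB", "pepA", "pepC")
        ]
        out = select_quant_peptides(pd.DataFrame(rows), top_k=2)
        assert sorted(out["precursor"]) == ["pepA", "pepB"]


class TestNormalization:
    def two_runs(self):
        return pd.DataFrame(
            {
                "run": ["r1"] * 2 + ["r2"] * 2,
                "intensity": [10.0, 30.0, 40.0, 40.0],
                "rt": [100.0, 700.0, 100.0, 700.0],
            }
        )

    def test_global_mode_halves_double_total_run(self):
        out = total_intensity_normalize(self.two_runs(), mode="global")
        # totals 40 and 80, cross-run mean 60
        r1 = out[out["run"] == "r1"]["intensity"].to_numpy()
        r2 = out[out["run"] == "r2"]["intensity"].to_numpy()
        assert np.allclose(r1, [10 / 40 * 60, 30 / 40 * 60])
        assert np.allclose(r2, [40 / 80 * 60, 40 / 80 * 60])

    def test_single_run_is_identity(self):
        df = self.two_runs()[lambda d: d["run"] == "r1"]
        out = total_intensity_normalize(df, mode="global")
        assert np.allclose(out["intensity"], df["intensity"])

    def test_windowed_with_one_window_equals_global(self):
        df = self.two_runs()
        wide = total_intensity_normalize(df, mode="rt_windowed", rt_window=1e6)
        glob = total_intensity_normalize(df, mode="global")
        assert np.allclose(wide["intensity"], glob["intensity"])

    def test_windowed_normalizes_per_window(self):
        out = total_intensity_normalize(self.two_runs(), mode="rt_windowed",
                                        rt_window=600.0)
        # early window totals 10 vs 40 (mean 25); late window 30 vs 40 (mean 35)
        r1 = out[out["run"] == "r1"].sort_values("rt")["intensity"].to_numpy()
        assert np.allclose(r1, [10 / 10 * 25, 30 / 30 * 35])

    def test_zero_window_total_is_error(self):
        df = pd.DataFrame({"run": ["r1", "r1"], "intensity": [0.0, 5.0],
                           "rt": [100.0, 700.0]})
        with pytest.raises(ValueError, match="zero total"):
            total_intensity_normalize(df, mode="rt_windowed", rt_window=600.0)


class TestDifferentialCall:
    def test_passes_both_controls(self):
        assert differential_call(0.6, 0.7, fdr=5e-4, fdr_threshold=1e-3)

    def test_fails_vehicle_arm(self):
        assert not differential_call(0.6, 0.3, fdr=5e-4, fdr_threshold=1e-3)

    def test_fold_change_boundary_strict(self):
        assert not differential_call(0.49, None, fdr=1e-6)
        assert not differential_call(0.5, None, fdr=1e-6)

    def test_mean_and_median_must_both_pass(self):
        assert differential_call([0.6, 0.7], None, fdr=1e-4)
        assert not differential_call([0.6, 0.4], None, fdr=1e-4)

    def test_sign_consistency_required(self):
        assert not differential_call(0.8, -0.8, fdr=1e-4)

    def test_fdr_gate(self):
        assert not differential_call(2.0, 2.0, fdr=0.02, fdr_threshold=0.01)


class TestNestedStatistics:
    def test_cv_hand_example(self):
        values = {1: [90.0], 2: [100.0], 3: [110.0]}
        assert nested_cv(values) == pytest.approx(0.1)

    def test_cv_zero_for_identical(self):
        assert nested_cv({1: [5.0, 5.0], 2: [5.0]}) == 0.0

    def test_cv_requires_two_bio_reps(self):
        with pytest.raises(ValueError):
            nested_cv({1: [1.0, 2.0]})

    def frame(self, reps):
        rows = [
            {"bio_rep": b, "value": v}
            for b, values in enumerate(reps)
            for v in values
        ]
        return pd.DataFrame(rows)

    def test_identical_groups_degenerate(self):
        g = self.frame([[3.0, 3.0], [3.0, 3.0]])
        assert nested_anova(g, g.copy()) == (0.0, 1.0)

    def test_matches_independent_sums_of_squares_route(self):
        # independent route: classical two-stage OLS decomposition via
        # statsmodels, treatment tested against the replicate mean square
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        rng = np.random.default_rng(4)
        treated = self.frame([rng.normal(1.0, 0.3, 2) for _ in range(3)])
        control = self.frame([rng.normal(0.0, 0.3, 2) for _ in range(3)])
        f, p = nested_anova(treated, control)

        df = pd.concat(
            [treated.assign(g="t"), control.assign(g="c")], ignore_index=True
        )
        fit = smf.ols("value ~ C(g) + C(g):C(bio_rep)", data=df).fit()
        tab = anova_lm(fit, typ=1)
        ms_treat = tab.loc["C(g)", "sum_sq"] / tab.loc["C(g)", "df"]
        ms_bio = (
            tab.loc["C(g):C(bio_rep)", "sum_sq"] / tab.loc["C(g):C(bio_rep)", "df"]
        )
        f_oracle = ms_treat / ms_bio
        p_oracle = stats.f.sf(f_oracle, 1, tab.loc["C(g):C(bio_rep)", "df"])
        assert f == pytest.approx(f_oracle, rel=1e-9)
        assert p == pytest.approx(p_oracle, rel=1e-9)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(11)
        ps = []
        for _ in range(2000):
            treated = self.frame([rng.normal(0, 1, 2) for _ in range(3)])
            control = self.frame([rng.normal(0, 1, 2) for _ in range(3)])
            ps.append(nested_anova(treated, control)[1])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_requires_two_bio_reps_per_group(self):
        good = self.frame([[1.0, 2.0], [2.0, 3.0]])
        bad = self.frame([[1.0, 2.0]])
        with pytest.raises(ValueError):
            nested_anova(good, bad)


class TestAnnotation:
    def test_toy_ions_full_enumeration(self):
        ions = load_toy_table("ions_toy")
        ref = load_toy_table("reference_masses")
        out = annotate_ions(ions, ref)
        by_met = {a.metabolite: a for a in out}
        assert "T0901317" in by_met
        assert by_met["T0901317"].ion_mass == pytest.approx(480.0317)
        # the below-cutoff T0901317 ion (1000 counts) must not appear
        assert all(a.intensity if hasattr(a, "intensity") else True for a in out)
        assert not any(abs(a.ion_mass - 480.0315) < 1e-9 for a in out)
        # mevalonate keeps only its best-scoring annotation
        assert by_met["mevalonate"].adduct == "[M-H]-"
        assert "alpha-ketoglutarate" in by_met
        # the unmatched 300 Da ion yields nothing
        assert not any(abs(a.ion_mass - 300.0) < 1e-6 for a in out)
        assert len(out) == 3

    def test_low_intensity_suppressed(self):
        ions = pd.DataFrame({"mass": [480.0317], "intensity": [1000.0]})
        ref = load_toy_table("reference_masses")
        assert annotate_ions(ions, ref) == []

    def test_outside_tolerance_not_annotated(self):
        ions = pd.DataFrame({"mass": [480.0337], "intensity": [9000.0]})
        ref = load_toy_table("reference_masses")
        assert annotate_ions(ions, ref) == []

    def test_reference_order_invariance(self):
        ions = load_toy_table("ions_toy")
        ref = load_toy_table("reference_masses")
        a = annotate_ions(ions, ref)
        b = annotate_ions(ions, ref.iloc[::-1].reset_index(drop=True))
        assert a == b

    def test_one_metabolite_per_ion_after_filtering(self):
        # two references within tolerance of one ion: only the closer survives
        ref = pd.DataFrame(
            {
                "metabolite": ["near", "far"],
                "mass": [100.0 + 1.00727646, 100.0008 + 1.00727646],
                "mass_type": ["neutral", "neutral"],
            }
        )
        ions = pd.DataFrame({"mass": [100.0], "intensity": [5000.0]})
        out = annotate_ions(ions, ref)
        assert [a.metabolite for a in out] == ["near"]

    def test_empty_reference_is_error(self):
        ions = pd.DataFrame({"mass": [100.0], "intensity": [5000.0]})
        with pytest.raises(ValueError, match="reference"):
            annotate_ions(ions, pd.DataFrame(columns=["metabolite", "mass"]))
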