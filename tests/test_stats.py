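"""Mixed-model ANOVA: oracle agreement, calibration, post-hoc structure."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from boutonquant.errors import DegenerateDesignError, InvalidParameterError
from boutonquant.stats import (
    bonferroni,
    fit_mixed_anova,
    posthoc_decomposition,
    report_text,
)
from boutonquant.synthetic import StudyDesign, simulate_site_table

REGIONS = ("PFC", "A1", "A2")


def balanced_rows(means, n_per_cell=5, sd=2.0, subject_sd=0.0, seed=0,
                  n_subjects=2):
    """Balanced two-way site-row table with known cell means."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        subj_dev = rng.normal(0, subject_sd) if subject_sd else 0.0
        for (t, r), mu in means.items():
            for i in range(n_per_cell):
                rows.append({"site_id": f"s{s}_{t}_{r}_{i}", "subject": f"s{s}",
                             "species": "m", "region": r, "bouton_type": t,
                             "mean_cb1r_adu": mu + subj_dev + rng.normal(0, sd)})
    return pd.DataFrame(rows)


def classical_two_way_anova(df):
    """Closed-form balanced two-way ANOVA from sums of squares."""
    g = df.mean_cb1r_adu.mean()
    a = df.groupby("region").mean_cb1r_adu.mean()
    b = df.groupby("bouton_type").mean_cb1r_adu.mean()
    cell = df.groupby(["region", "bouton_type"]).mean_cb1r_adu.mean()
    n_a = len(df) / len(a)
    n_b = len(df) / len(b)
    n_cell = len(df) / len(cell)
    ss_a = n_a * ((a - g) ** 2).sum()
    ss_b = n_b * ((b - g) ** 2).sum()
    ss_ab = n_cell * ((cell - g) ** 2).sum() - ss_a - ss_b
    resid = df.mean_cb1r_adu - df.set_index(["region", "bouton_type"]).index.map(cell)
    ss_e = (resid ** 2).sum()
    df_e = len(df) - len(cell)
    mse = ss_e / df_e
    return {
        "region": (ss_a / (len(a) - 1)) / mse,
        "cell_type": (ss_b / (len(b) - 1)) / mse,
        "cell_type:region": (ss_ab / ((len(a) - 1) * (len(b) - 1))) / mse,
        "df_e": df_e,
    }


DEFAULT_MEANS = {(t, r): m for t, ms in
                 {"vglut1": dict(zip(REGIONS, (10.0, 12.0, 11.0))),
                  "vgat": dict(zip(REGIONS, (20.0, 25.0, 22.0)))}.items()
                 for r, m in ms.items()}


def test_fixed_zero_subject_variance_matches_classical_anova_to_4sf():
    df = balanced_rows(DEFAULT_MEANS, seed=3)
    res = fit_mixed_anova(df, "m", fix_lambda=0.0, with_satterthwaite=False)
    oracle = classical_two_way_anova(df)
    for name in ("region", "cell_type", "cell_type:region"):
        assert res.effects[name].F == pytest.approx(oracle[name], rel=1e-4)
        assert res.effects[name].df_den == oracle["df_e"]
    assert res.effects["cell_type"].df_num == 1
    assert res.effects["region"].df_num == 2
    assert res.effects["cell_type:region"].df_num == 2


def test_free_fit_agrees_with_statsmodels_mixedlm():
    """Independent cross-check of the REML variance components and fixed
    effects against statsmodels."""
    smf = pytest.importorskip("statsmodels.formula.api")
    tab = simulate_site_table(StudyDesign(between_subject_sd=200.0), 5)
    res = fit_mixed_anova(tab, "monkey", with_satterthwaite=False)
    md = smf.mixedlm("mean_cb1r_adu ~ C(region)*C(bouton_type)", tab,
                     groups=tab["subject"]).fit(reml=True)
    assert res.random_subject_variance == pytest.approx(md.cov_re.iloc[0, 0], rel=1e-3)
    assert res.residual_variance == pytest.approx(md.scale, rel=1e-3)
    # grand mean (intercept of the sum-to-zero coding) equals the average of
    # statsmodels' predicted cell means
    cell_means = (tab.assign(fit=md.fittedvalues)
                  .groupby(["region", "bouton_type"]).mean_cb1r_adu.mean())
    assert res.fit.beta[0] == pytest.approx(cell_means.mean(), rel=0.05)


def test_interaction_type_i_error_is_calibrated():
    """Null design (all cell means equal): interaction p < 0.05 in ~5% of
    replicates."""
    null = StudyDesign(
        effect_table={("monkey", t, r): 800.0 for t in ("vglut1", "vgat")
                      for r in REGIONS},
        between_subject_sd=200.0, between_site_sd=100.0)
    hits = 0
    n = 400
    for s in range(n):
        tab = simulate_site_table(null, 50_000 + s)
        r = fit_mixed_anova(tab, "monkey", with_satterthwaite=False)
        hits += r.effects["cell_type:region"].p < 0.05
    assert 0.025 <= hits / n <= 0.075


def test_power_and_specificity_for_planted_effects():
    """Cell-type separation at 3x residual SD is detected (p < 0.001) while
    unplanted region and interaction effects stay non-significant, in >= 90%
    of replicates."""
    sd = 100.0
    table = {("monkey", "vglut1", r): 500.0 for r in REGIONS}
    table.update({("monkey", "vgat", r): 500.0 + 3 * sd for r in REGIONS})
    design = StudyDesign(effect_table=table, between_subject_sd=150.0,
                         between_site_sd=sd)
    ct_hits = region_null = inter_null = 0
    n = 40
    for s in range(n):
        tab = simulate_site_table(design, 60_000 + s)
        r = fit_mixed_anova(tab, "monkey", with_satterthwaite=False)
        ct_hits += r.effects["cell_type"].p < 0.001
        region_null += r.effects["region"].p > 0.05
        inter_null += r.effects["cell_type:region"].p > 0.05
    assert ct_hits >= 0.9 * n
    assert region_null >= 0.9 * n
    assert inter_null >= 0.9 * n


def test_single_subject_is_degenerate():
    df = balanced_rows(DEFAULT_MEANS, n_subjects=1)
    with pytest.raises(DegenerateDesignError):
        fit_mixed_anova(df, "m")


def test_missing_cell_type_is_degenerate():
    df = balanced_rows(DEFAULT_MEANS)
    with pytest.raises(DegenerateDesignError):
        fit_mixed_anova(df[df.bouton_type == "vgat"], "m")


def test_satterthwaite_df_bounded_by_residual_df():
    df = balanced_rows(DEFAULT_MEANS, subject_sd=5.0, seed=1)
    res = fit_mixed_anova(df, "m", with_satterthwaite=True)
    for t in res.effects.values():
        assert 1.0 <= t.df_den_satterthwaite <= t.df_den


class TestBonferroni:
    def test_arithmetic(self):
        assert bonferroni([0.01], 3)[0] == pytest.approx(0.03)
        assert bonferroni([0.5], 3)[0] == 1.0
        assert bonferroni([0.0], 10)[0] == 0.0

    def test_family_of_three(self):
        adj = bonferroni([0.001, 0.02, 0.4], 3)
        assert np.allclose(adj, [0.003, 0.06, 1.0])

    def test_invalid_inputs(self):
        with pytest.raises(InvalidParameterError):
            bonferroni([1.5], 2)
        with pytest.raises(InvalidParameterError):
            bonferroni([0.1, 0.2, 0.3], 2)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=8))
    def test_adjustment_preserves_ordering(self, ps):
        adj = bonferroni(ps, len(ps))
        order_raw = np.argsort(np.argsort(ps))
        assert np.all(adj >= np.asarray(ps))
        # monotone: larger raw p never gets a smaller adjusted p
        for i in range(len(ps)):
            for j in range(len(ps)):
                if ps[i] < ps[j]:
                    assert adj[i] <= adj[j]
        assert order_raw is not None


class TestPosthoc:
    def test_simple_effect_pattern_mirrors_planted_structure(self):
        """Region effect planted only in the inhibitory type: its
        simple-effect survives correction while the excitatory one does not,
        in >= 90% of replicates."""
        sd = 100.0
        table = {("monkey", "vglut1", r): 500.0 for r in REGIONS}
        table.update({("monkey", "vgat", "PFC"): 1000.0,
                      ("monkey", "vgat", "A1"): 1000.0 + 3 * sd,
                      ("monkey", "vgat", "A2"): 1000.0 + 1.5 * sd})
        design = StudyDesign(effect_table=table, between_subject_sd=150.0,
                             between_site_sd=sd)
        good = 0
        n = 30
        for s in range(n):
            tab = simulate_site_table(design, 70_000 + s)
            r = fit_mixed_anova(tab, "monkey", with_satterthwaite=False)
            ph = posthoc_decomposition(r)
            se = ph[ph.family == "simple_effect"].set_index("cell_type")
            good += (se.loc["vgat", "p_bonferroni"] < 0.05
                     and se.loc["vglut1", "p_bonferroni"] > 0.05)
        assert good >= 0.9 * n

    def test_null_pairwise_contrasts_stay_non_significant(self):
        table = {("monkey", t, r): 700.0 for t in ("vglut1", "vgat")
                 for r in REGIONS}
        design = StudyDesign(effect_table=table, between_subject_sd=100.0,
                             between_site_sd=80.0)
        ok = total = 0
        for s in range(30):
            tab = simulate_site_table(design, 80_000 + s)
            r = fit_mixed_anova(tab, "monkey", with_satterthwaite=False)
            ph = posthoc_decomposition(r)
            pw = ph[ph.family == "pairwise"]
            total += len(pw)
            ok += (pw.p_bonferroni > 0.05).sum()
        assert ok >= 0.94 * total

    def test_pairwise_estimates_recover_planted_differences(self):
        df = balanced_rows(DEFAULT_MEANS, n_per_cell=40, sd=1.0, seed=9)
        res = fit_mixed_anova(df, "m", with_satterthwaite=False)
        ph = posthoc_decomposition(res)
        row = ph[(ph.cell_type == "vgat") & (ph.contrast == "PFC-A1")].iloc[0]
        assert row.estimate == pytest.approx(-5.0, abs=0.5)


def test_cell_mean_recovery_within_two_standard_errors():
    """Planted cell means fall within 2 estimated SEs of their estimates in
    >= 95% of (replicate, cell) pairs when the subject variability is small
    enough for the plug-in SE to be well estimated."""
    from boutonquant.stats import _cell_mean_row

    design = StudyDesign(subjects_per_species=4, between_subject_sd=0.0,
                         between_site_sd=100.0)
    inside = total = 0
    for s in range(40):
        tab = simulate_site_table(design, 90_000 + s)
        r = fit_mixed_anova(tab, "monkey", with_satterthwaite=False)
        for (sp, t, reg), mu in design.effect_table.items():
            x = _cell_mean_row(reg, t, r.regions, r.cell_types)
            est = float(x @ r.fit.beta)
            se = float(np.sqrt(x @ r.fit.cov_beta @ x))
            total += 1
            inside += abs(est - mu) <= 2 * se
    assert inside >= 0.95 * total


def test_region_contrast_recovery_under_strong_subject_effects():
    """Region differences are within-subject contrasts: even with only two
    subjects and a large subject SD they are recovered within 2 SEs in
    >= 95% of cases (the random intercept cancels)."""
    from boutonquant.stats import _cell_mean_row

    design = StudyDesign(subjects_per_species=2, between_subject_sd=300.0,
                         between_site_sd=100.0)
    inside = total = 0
    for s in range(40):
        tab = simulate_site_table(design, 91_000 + s)
        r = fit_mixed_anova(tab, "monkey", with_satterthwaite=False)
        for t in r.cell_types:
            for a, b in (("PFC", "A1"), ("PFC", "A2"), ("A1", "A2")):
                x = (_cell_mean_row(a, t, r.regions, r.cell_types)
                     - _cell_mean_row(b, t, r.regions, r.cell_types))
                true = (design.effect_table[("monkey", t, a)]
                        - design.effect_table[("monkey", t, b)])
                est = float(x @ r.fit.beta)
                se = float(np.sqrt(x @ r.fit.cov_beta @ x))
                total += 1
                inside += abs(est - true) <= 2 * se
    assert inside >= 0.95 * total


def test_report_text_formats_the_effects():
    df = balanced_rows(DEFAULT_MEANS, seed=2)
    res = fit_mixed_anova(df, "m", with_satterthwaite=False)
    ph = posthoc_decomposition(res)
    text = report_text(res, ph)
    assert "main effect of cell type, F(1," in text
    assert "interaction" in text
    assert "region within vgat" in text
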