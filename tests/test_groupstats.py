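import itertools

import numpy as np
import pandas as pd
import pytest

from msntx import (RegionalCaseControl, aggregate_by_system, bh_fdr, classify_regions,
                   correlate_symptoms, generate_spins, make_atlas, make_truth,
                   map_concordance, simulate_cohort, strength_table)


def _bh_bruteforce(p):
    """Literal step-up definition: q_i = min over tail ranks of p*m/rank."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        prev = min(prev, p[idx] * m / rank)
        q[idx] = prev
    return q


# -- BH-FDR ------------------------------------------------------------------

def test_bh_handworked_example():
    assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])


def test_bh_single_and_tied_p():
    assert bh_fdr([0.3])[0] == pytest.approx(0.3)
    assert np.allclose(bh_fdr([0.2, 0.2, 0.2]), 0.2)


def test_bh_matches_bruteforce_on_grid_subsets():
    grid = [0.001, 0.01, 0.04, 0.2, 0.5, 0.9]
    for size in range(1, 7):
        for subset in itertools.combinations(grid, size):
            assert np.allclose(bh_fdr(list(subset)), _bh_bruteforce(list(subset)),
                               atol=1e-12)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_fdr([0.1, 1.2])


# -- regional case-control OLS ----------------------------------------------

def _null_data(rng, n=40, regions=12):
    strengths = pd.DataFrame(rng.normal(size=(n, regions)),
                             index=[f"s{i}" for i in range(n)],
                             columns=range(1, regions + 1))
    design = pd.DataFrame({
        "group": ["case"] * (n // 2) + ["control"] * (n // 2),
        "age": rng.uniform(18, 60, n), "sex": rng.integers(0, 2, n),
        "education": rng.normal(12, 3, n)}, index=strengths.index)
    return strengths, design


def test_tmap_matches_statsmodels_oracle(rng):
    import statsmodels.api as sm

    strengths, design = _null_data(rng)
    res = RegionalCaseControl(strengths, design).fit()
    g = (design["group"] == "case").astype(float)
    X = sm.add_constant(pd.DataFrame({"group": g, "age": design["age"],
                                      "sex": design["sex"].astype(float),
                                      "education": design["education"]}))
    for region in strengths.columns:
        fit = sm.OLS(strengths[region], X).fit()
        assert abs(res.table.loc[region, "t"] - fit.tvalues["group"]) < 1e-10
        assert abs(res.table.loc[region, "p"] - fit.pvalues["group"]) < 1e-10


def test_tmap_group_swap_negates_t(rng):
    strengths, design = _null_data(rng)
    res = RegionalCaseControl(strengths, design).fit()
    swapped = design.assign(group=design["group"].map({"case": "control", "control": "case"}))
    res2 = RegionalCaseControl(strengths, swapped).fit()
    assert np.allclose(res2.table["t"], -res.table["t"])


def test_orthogonal_covariate_leaves_t_unchanged(rng):
    strengths, design = _null_data(rng)
    res = RegionalCaseControl(strengths, design).fit()
    # a covariate orthogonal to everything: residualize noise against the design
    g = (design["group"] == "case").astype(float)
    D = np.column_stack([np.ones(len(design)), g, design["age"], design["sex"],
                         design["education"], strengths.to_numpy()])
    z = rng.normal(size=len(design))
    z = z - D @ np.linalg.lstsq(D, z, rcond=None)[0]
    design2 = design.assign(extra=z)
    res2 = RegionalCaseControl(strengths, design2,
                               covariates=("age", "sex", "education", "extra")).fit()
    # Frisch-Waugh: the group coefficient is untouched; t only rescales by the
    # residual-df change (RSS is identical since the covariate explains nothing)
    assert np.abs(res2.table["coef"] - res.table["coef"]).max() < 1e-10
    adj = np.sqrt(res.df_resid / res2.df_resid)
    assert np.abs(res2.table["t"] * adj - res.table["t"]).max() < 1e-8


def test_null_fixture_no_discoveries(rng):
    strengths, design = _null_data(rng, n=60, regions=30)
    res = RegionalCaseControl(strengths, design).fit()
    assert len(res.significant(0.05)) == 0
    assert res.table["t"].abs().mean() < 1.5


def test_singular_design_rejected(rng):
    strengths, design = _null_data(rng)
    design["dup"] = design["age"]
    with pytest.raises(ValueError, match="singular|rank"):
        RegionalCaseControl(strengths, design, covariates=("age", "sex", "education", "dup"))


# -- quadrants ---------------------------------------------------------------

def test_quadrant_definitions():
    t = pd.Series([-2.0, 2.0, 0.0, 1.5, -1.5], index=range(1, 6))
    m = pd.Series([3.0, -3.0, 1.0, 2.0, -2.0], index=range(1, 6))
    labels, fractions = classify_regions(t, m)
    assert labels.loc[1] == "decoupling"
    assert labels.loc[2] == "dedifferentiation"
    assert labels.loc[3] == "null"
    assert labels.loc[4] == "coupled_increase"
    assert labels.loc[5] == "differentiated_decrease"
    assert fractions.sum() == pytest.approx(1.0)


# -- system aggregation ------------------------------------------------------

def test_single_system_collapses_to_grand_mean(atlas, strengths, cohort):
    _, participants = cohort
    import dataclasses
    labels = {k: v for k, v in atlas.system_labels.items()}
    labels["one"] = np.ones(atlas.n_regions, dtype=int)
    one_atlas = dataclasses.replace(atlas, system_labels=labels)
    sysres = aggregate_by_system(strengths, one_atlas, "one", participants)
    grand = strengths.mean(axis=1).to_frame(name=1)
    direct = RegionalCaseControl(grand, participants).fit()
    assert sysres.table["t"].iloc[0] == pytest.approx(direct.table["t"].iloc[0])


def test_unknown_scheme_rejected(atlas, strengths, cohort):
    _, participants = cohort
    with pytest.raises(ValueError, match="scheme"):
        aggregate_by_system(strengths, atlas, "nope", participants)


def test_effect_confined_to_one_system_has_largest_t():
    """Planting inside one latitude band makes that system the extreme one."""
    hits = 0
    n_rep = 40
    for rep in range(n_rep):
        atlas = make_atlas(16, 4, seed=0)
        labels = pd.Series(atlas.system_labels["yeo7"], index=atlas.region_ids)
        target = labels[labels == 2].index.to_numpy()[:5]
        truth = make_truth(atlas, 1, 1, effect_size=3.5, seed=rep)
        truth = type(truth)(effect_regions=tuple(int(r) for r in target),
                            effect_direction={int(r): 1 for r in target},
                            planted_genes=truth.planted_genes,
                            effect_size=3.5, seed=rep)
        subjects, participants = simulate_cohort(atlas, 30, truth, seed=1000 + rep)
        st_ = strength_table(subjects)
        res = aggregate_by_system(st_, atlas, "yeo7", participants)
        hits += int(res.table["t"].abs().idxmax() == 2)
    assert hits >= int(0.9 * n_rep)


# -- symptom correlations ----------------------------------------------------

def test_symptom_self_correlation(strengths, cohort):
    _, participants = cohort
    scores = strengths[strengths.columns[3]]
    out = correlate_symptoms(strengths, scores, case_only=False)
    assert out.loc[strengths.columns[3], "r"] == pytest.approx(1.0)


def test_symptom_constant_scores_rejected(strengths, cohort):
    _, participants = cohort
    scores = pd.Series(5.0, index=strengths.index)
    with pytest.raises(ValueError, match="degenerate"):
        correlate_symptoms(strengths, scores, case_only=False)


def test_symptom_correlation_matches_direct_formula(strengths, cohort, rng):
    _, participants = cohort
    scores = pd.Series(rng.normal(size=len(strengths)), index=strengths.index)
    out = correlate_symptoms(strengths, scores, case_only=True, design=participants)
    cases = participants.index[participants["group"] == "case"]
    x = strengths.loc[cases, strengths.columns[0]].to_numpy()
    y = scores.loc[cases].to_numpy()
    r = (np.sum((x - x.mean()) * (y - y.mean()))
         / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)))
    assert out.iloc[0]["r"] == pytest.approx(r, abs=1e-12)


def test_symptom_null_no_discoveries(strengths, cohort, rng):
    _, participants = cohort
    scores = pd.Series(rng.normal(size=len(strengths)), index=strengths.index)
    out = correlate_symptoms(strengths, scores, case_only=False)
    assert (out["q"] < 0.05).sum() == 0


# -- concordance -------------------------------------------------------------

def test_map_concordance_trivial_extremes(atlas):
    spins = generate_spins(atlas, 99, seed=3, hemisphere_scope="both_mirrored")
    rng = np.random.default_rng(0)
    a = pd.Series(rng.normal(size=atlas.n_regions), index=atlas.region_ids)
    r, p = map_concordance(a, a, atlas, spins)
    assert r == pytest.approx(1.0)
    r2, _ = map_concordance(a, -a, atlas, spins)
    assert r2 == pytest.approx(-1.0)
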