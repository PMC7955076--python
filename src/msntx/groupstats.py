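"""Case-control statistics on regional MSN strengths.

The central object is :class:`RegionalCaseControl`: an OLS model fitted
independently in every region,

    strength_i = intercept + beta_g * group + beta_1*age + beta_2*sex + beta_3*education (+ TIV),

whose per-region two-sided group t-statistic (contrast = case - control) forms
the *t-map*.  Multiple comparisons across regions are controlled with
Benjamini-Hochberg FDR.  The module also classifies regions into
coupling/decoupling quadrants, aggregates strengths into labelled systems,
correlates strengths with symptom scores, and measures spatial concordance of
two maps under a spin null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .atlas import ParcelAtlas
from .spin import SpinSet, spin_correlation_test

__all__ = [
    "bh_fdr",
    "RegionalCaseControl",
    "TMapResults",
    "classify_regions",
    "aggregate_by_system",
    "correlate_symptoms",
    "map_concordance",
]

QUADRANTS = ("decoupling", "dedifferentiation", "coupled_increase",
             "differentiated_decrease", "null")

DEFAULT_COVARIATES = ("age", "sex", "education")


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _design_matrix(design: pd.DataFrame, covariates: tuple[str, ...],
                   case_label: str = "case") -> tuple[np.ndarray, list[str]]:
    if "group" not in design.columns:
        raise ValueError("design table needs a 'group' column")
    group = design["group"]
    if group.isna().any():
        raise ValueError("missing group labels")
    g = (group == case_label).to_numpy(float)
    if g.sum() == 0 or g.sum() == len(g):
        raise ValueError("both groups must be present in the design")
    cols = [np.ones(len(design)), g]
    names = ["intercept", "group"]
    for c in covariates:
        if c not in design.columns:
            raise ValueError(f"covariate {c!r} missing from design table")
        v = design[c]
        if v.isna().any():
            raise ValueError(f"covariate {c!r} has missing values")
        cols.append(v.to_numpy(float))
        names.append(c)
    return np.column_stack(cols), names


@dataclass
class TMapResults:
    """Per-region group-contrast results of :class:`RegionalCaseControl`.

    Attributes
    ----------
    table : DataFrame indexed by region_id with columns t, p, q (BH-FDR),
        plus the fitted group coefficient and its standard error.
    df_resid : residual degrees of freedom (n - k).
    fdr_family : human-readable description of the FDR family.
    """

    table: pd.DataFrame
    df_resid: int
    covariates: tuple[str, ...]
    fdr_family: str = "regions"
    metadata: dict = field(default_factory=dict)

    @property
    def t(self) -> pd.Series:
        return self.table["t"]

    @property
    def q(self) -> pd.Series:
        return self.table["q"]

    def significant(self, alpha: float = 0.05) -> pd.Index:
        return self.table.index[self.table["q"] < alpha]

    def summary(self) -> str:
        n_sig = int((self.table["q"] < 0.05).sum())
        lines = [
            "Regional case-control contrast (OLS, contrast = case - control)",
            f"  units: {len(self.table)} ({self.fdr_family}); residual df = {self.df_resid}",
            f"  covariates: {', '.join(self.covariates) or 'none'}",
            f"  significant at FDR<0.05: {n_sig}",
            f"  t range: [{self.table['t'].min():.3f}, {self.table['t'].max():.3f}]",
        ]
        return "\n".join(lines)


class RegionalCaseControl:
    """Mass-univariate OLS of regional strength on group plus covariates.

    Parameters
    ----------
    strengths : DataFrame, subjects x regions
        Regional MSN strengths; the index must match ``design``'s index.
    design : DataFrame
        Per-subject table with a ``group`` column (``"case"`` / ``"control"``)
        and the covariate columns.
    covariates : iterable of str
        Covariate columns entered in the model (default age, sex, education;
        add ``"TIV"`` to reproduce the intracranial-volume sensitivity model).
    """

    def __init__(self, strengths: pd.DataFrame, design: pd.DataFrame,
                 covariates: tuple[str, ...] = DEFAULT_COVARIATES,
                 case_label: str = "case"):
        if not strengths.index.equals(design.index):
            design = design.loc[strengths.index]
        self.strengths = strengths
        self.design = design
        self.covariates = tuple(covariates)
        self.case_label = case_label
        self._X, self._names = _design_matrix(design, self.covariates, case_label)
        n, k = self._X.shape
        if n <= k + 1:
            raise ValueError("need n subjects > n covariates + 2")
        if np.linalg.matrix_rank(self._X) < k:
            raise ValueError("singular design: design matrix is rank-deficient")

    def fit(self) -> TMapResults:
        X = self._X
        Y = self.strengths.to_numpy(float)
        n, k = X.shape
        xtx_inv = np.linalg.inv(X.T @ X)
        beta = xtx_inv @ X.T @ Y                      # k x regions
        resid = Y - X @ beta
        df = n - k
        sigma2 = (resid ** 2).sum(axis=0) / df
        gi = self._names.index("group")
        se = np.sqrt(sigma2 * xtx_inv[gi, gi])
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, beta[gi] / se, 0.0)
        p = 2.0 * stats.t.sf(np.abs(t), df)
        table = pd.DataFrame(
            {"coef": beta[gi], "se": se, "t": t, "p": p, "q": bh_fdr(p)},
            index=self.strengths.columns.rename("region_id"),
        )
        return TMapResults(table=table, df_resid=df, covariates=self.covariates,
                           metadata={"n_case": int((self.design["group"] == self.case_label).sum()),
                                     "n_total": n})


def classify_regions(tmap: TMapResults | pd.Series,
                     control_mean_strength: pd.Series) -> tuple[pd.Series, pd.Series]:
    """Quadrant labels combining the sign of t with the sign of mean strength.

    Negative t with positive mean strength is *decoupling* (cases less similar
    to an otherwise strongly coupled region); positive t with negative mean
    strength is *dedifferentiation*.  The remaining strict-sign quadrants are
    ``coupled_increase`` (+/+) and ``differentiated_decrease`` (-/-); exact
    zeros in either map give ``null``.  Returns (labels, fractions over all
    regions).
    """
    t = tmap.t if isinstance(tmap, TMapResults) else tmap
    t, m = t.align(control_mean_strength, join="inner")
    if len(t) != len(control_mean_strength):
        raise ValueError("t-map and mean-strength region sets differ")
    lab = np.full(len(t), "null", dtype=object)
    lab[(t.values < 0) & (m.values > 0)] = "decoupling"
    lab[(t.values > 0) & (m.values < 0)] = "dedifferentiation"
    lab[(t.values > 0) & (m.values > 0)] = "coupled_increase"
    lab[(t.values < 0) & (m.values < 0)] = "differentiated_decrease"
    labels = pd.Series(lab, index=t.index, name="quadrant")
    fractions = labels.value_counts(normalize=True).reindex(QUADRANTS, fill_value=0.0)
    return labels, fractions


def aggregate_by_system(strengths: pd.DataFrame, atlas: ParcelAtlas, scheme: str,
                        design: pd.DataFrame,
                        covariates: tuple[str, ...] = DEFAULT_COVARIATES) -> TMapResults:
    """System-level case-control contrast.

    Per subject, strengths are averaged within each labelled system of the
    requested scheme; the same OLS contrast is then fitted per system and FDR
    is applied across systems (a family distinct from the regional one).
    """
    if scheme not in atlas.system_labels:
        raise ValueError(f"unknown system scheme {scheme!r}")
    labels = pd.Series(atlas.system_labels[scheme], index=atlas.region_ids)
    labels = labels.reindex(strengths.columns)
    if labels.isna().any():
        raise ValueError("strength columns not covered by atlas system labels")
    by_system = strengths.T.groupby(labels.values).mean().T
    by_system.columns.name = "system"
    res = RegionalCaseControl(by_system, design, covariates=covariates).fit()
    res.fdr_family = f"systems ({scheme})"
    res.table.index.name = "system"
    return res


def correlate_symptoms(strengths: pd.DataFrame, scores: pd.Series,
                       case_only: bool = True,
                       design: pd.DataFrame | None = None,
                       region_subset=None) -> pd.DataFrame:
    """Per-region Pearson correlation of strength with a symptom score.

    By default only case subjects enter (symptom scales are meaningful in
    patients); pass ``case_only=False`` to pool.  Two-sided p-values use the
    t-transform with n-2 df; BH-FDR is applied across all regions and, when
    ``region_subset`` is given, additionally across that named subset
    (column ``q_subset``).
    """
    idx = strengths.index
    if case_only:
        if design is None:
            raise ValueError("case_only correlation needs the design table")
        idx = idx[(design.loc[idx, "group"] == "case").to_numpy()]
    S = strengths.loc[idx]
    y = scores.loc[idx].to_numpy(float)
    if len(idx) < 4:
        raise ValueError("need >=4 subjects after subsetting")
    if np.std(y) == 0:
        raise ValueError("degenerate input: constant symptom scores")
    X = S.to_numpy(float)
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    denom = np.linalg.norm(xc, axis=0) * np.linalg.norm(yc)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, xc.T @ yc / denom, 0.0)
    n = len(y)
    r_ = np.clip(r, -0.9999999999, 0.9999999999)
    t = r_ * np.sqrt((n - 2) / (1 - r_ ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    out = pd.DataFrame({"r": r, "p": p, "q": bh_fdr(p)}, index=S.columns)
    if region_subset is not None:
        sub = out.index.isin(region_subset)
        qs = pd.Series(np.nan, index=out.index)
        qs[sub] = bh_fdr(out.loc[sub, "p"])
        out["q_subset"] = qs
    return out


def map_concordance(map_a: pd.Series, map_b: pd.Series, atlas: ParcelAtlas,
                    spins: SpinSet, alternative: str = "two_sided") -> tuple[float, float]:
    """Spatial similarity of two regional maps with spin-test significance.

    Both maps must cover the spin set's region ids; returns (Pearson r, p_spin).
    """
    rid = pd.Index(spins.region_ids)
    try:
        a = map_a.loc[rid].to_numpy(float)
        b = map_b.loc[rid].to_numpy(float)
    except KeyError as exc:
        raise ValueError("maps do not cover the spin region set") from exc
    return spin_correlation_test(a, b, spins, method="pearson", alternative=alternative)
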