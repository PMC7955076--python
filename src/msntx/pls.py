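"""PLS1 regression linking regional gene expression to a case-control map.

:class:`TranscriptomicPLS` regresses a region-indexed response (typically the
case-control t-map) on the region x gene expression matrix and extracts the
first partial-least-squares component.  With a single response the PLS1
weight vector has the closed form

    w = X_c' y_c / || X_c' y_c ||

(X_c, y_c column-centered, X optionally z-scored), identical to what one
iteration of NIPALS yields; regional scores are X_c w and the variance
explained is the squared Pearson correlation of scores with y.  Inference:

* significance of the variance explained against a spatial-rotation (spin)
  null of the response map;
* per-gene bootstrap Z = weight / bootstrap SE over region resamples, with
  BH-FDR across genes, thresholded into the PLS1+ / PLS1- gene lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .expression import RegionGeneMatrix
from .groupstats import bh_fdr
from .spin import SpinSet, spin_pvalue

__all__ = ["TranscriptomicPLS", "PLSResults", "GeneLists", "gene_map_correlation"]


@dataclass(frozen=True)
class GeneLists:
    """Thresholded PLS1 gene lists (disjoint, ordered by |Z| descending)."""

    pls1_plus: tuple[str, ...]
    pls1_minus: tuple[str, ...]
    z_threshold: float
    fdr_threshold: float

    def write(self, plus_path, minus_path) -> None:
        for path, genes in ((plus_path, self.pls1_plus), (minus_path, self.pls1_minus)):
            with open(path, "w") as fh:
                fh.write("\n".join(genes) + ("\n" if genes else ""))


@dataclass
class PLSResults:
    """First-component PLS estimates and, once computed, their inference.

    Attributes
    ----------
    weights : Series, unit-norm PLS1 weight per gene.
    scores : Series, PLS1 regional score per region (centered X @ weights).
    var_explained : fraction of response variance explained by component 1.
    var_explained_X : fraction of (standardized) predictor-block variance
        captured by the component, reported alongside.
    p_spin : spin-test p-value for var_explained (None until computed).
    gene_table : per-gene weight, bootstrap SE, Z and BH-FDR q
        (None until :meth:`TranscriptomicPLS.bootstrap_z` has run).
    """

    weights: pd.Series
    scores: pd.Series
    var_explained: float
    var_explained_X: float
    model: "TranscriptomicPLS"
    p_spin: float | None = None
    gene_table: pd.DataFrame | None = None
    settings: dict = field(default_factory=dict)

    def gene_lists(self, z_threshold: float = 5.0, fdr_threshold: float = 0.005) -> GeneLists:
        """Genes with Z beyond +/- ``z_threshold`` and q below ``fdr_threshold``."""
        if self.gene_table is None:
            raise ValueError("run bootstrap_z() before extracting gene lists")
        tb = self.gene_table
        plus = tb[(tb["z"] > z_threshold) & (tb["q"] < fdr_threshold)]
        minus = tb[(tb["z"] < -z_threshold) & (tb["q"] < fdr_threshold)]
        order = lambda d: tuple(d.reindex(d["z"].abs().sort_values(ascending=False).index).index)
        return GeneLists(pls1_plus=order(plus), pls1_minus=order(minus),
                         z_threshold=z_threshold, fdr_threshold=fdr_threshold)

    def summary(self) -> str:
        lines = [
            "PLS1 imaging-transcriptomics regression",
            f"  regions: {len(self.scores)}   genes: {len(self.weights)}",
            f"  variance explained (response): {100 * self.var_explained:.1f}%",
            f"  variance captured (predictors): {100 * self.var_explained_X:.1f}%",
        ]
        if self.p_spin is not None:
            lines.append(f"  spin-test p (n={self.settings.get('n_spins', '?')}): "
                         f"{self.p_spin:.4g}")
        if self.gene_table is not None:
            gl = self.gene_lists()
            lines.append(f"  bootstrap (n={self.settings.get('n_boot', '?')}): "
                         f"{len(gl.pls1_plus)} PLS1+ / {len(gl.pls1_minus)} PLS1- genes "
                         f"(|Z| > {gl.z_threshold:g}, q < {gl.fdr_threshold:g})")
        return "\n".join(lines)

    def plot_scores(self, ax=None):
        """Scatter of PLS1 regional scores against the response map."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.scores, self.model.y.loc[self.scores.index], s=12)
        ax.set_xlabel("PLS1 regional score")
        ax.set_ylabel("response (t-map)")
        ax.set_title(f"var explained = {100 * self.var_explained:.1f}%")
        return ax


class TranscriptomicPLS:
    """PLS1 model of a regional response on a region x gene expression matrix.

    Parameters
    ----------
    X : RegionGeneMatrix or DataFrame (region_id x gene)
        Predictor block.
    y : Series indexed by region_id
        Response map; only regions present in both are used (>=3 required).
    standardize : bool
        Z-score predictor columns before fitting (default True; normalized
        expression columns have unequal variances otherwise).
    """

    def __init__(self, X: RegionGeneMatrix | pd.DataFrame, y: pd.Series,
                 standardize: bool = True):
        Xv = X.values if isinstance(X, RegionGeneMatrix) else X
        regions = Xv.index.intersection(y.index)
        if len(regions) < 3:
            raise ValueError("need >=3 regions shared between X and y")
        if Xv.shape[1] < 2:
            raise ValueError("need >=2 genes")
        self.X = Xv.loc[regions]
        self.y = y.loc[regions].astype(float)
        if float(self.y.std()) == 0.0:
            raise ValueError("degenerate input: zero-variance response")
        self.standardize = standardize

    # -- core fit ----------------------------------------------------------

    @staticmethod
    def _pls1(Xm: np.ndarray, yv: np.ndarray, standardize: bool):
        """Closed-form first component; returns (w, scores, R2_y, R2_X)."""
        Xc = Xm - Xm.mean(axis=0)
        if standardize:
            sd = Xc.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            Xc = Xc / sd
        yc = yv - yv.mean()
        w = Xc.T @ yc
        nrm = np.linalg.norm(w)
        if nrm == 0:
            raise ValueError("degenerate input: response orthogonal to all genes")
        w = w / nrm
        scores = Xc @ w
        r = np.corrcoef(scores, yv)[0, 1]
        ssX = (Xc ** 2).sum()
        # rank-1 reconstruction X_c ~ scores p' with loading p = X_c's / s's
        ss_component = (scores @ scores)
        r2x = float(((Xc.T @ scores) ** 2).sum() / ss_component / ssX) if ssX > 0 else 0.0
        return w, scores, float(r * r), r2x

    def fit(self, *, sign_align: bool = True) -> PLSResults:
        """Estimate the first component.

        The sign convention fixes the component so that the correlation of
        scores with the response is positive, making "PLS1-" reproducibly mean
        "expression high where the response is low".
        """
        w, scores, r2, r2x = self._pls1(self.X.to_numpy(float),
                                        self.y.to_numpy(float), self.standardize)
        if sign_align and np.corrcoef(scores, self.y)[0, 1] < 0:
            w, scores = -w, -scores
        return PLSResults(
            weights=pd.Series(w, index=self.X.columns, name="weight"),
            scores=pd.Series(scores, index=self.X.index, name="pls1_score"),
            var_explained=r2, var_explained_X=r2x, model=self,
            settings={"standardize": self.standardize},
        )

    # -- inference ---------------------------------------------------------

    def spin_test(self, results: PLSResults, spins: SpinSet) -> PLSResults:
        """Spin-permutation p-value for the variance explained.

        The response map (the spatially autocorrelated quantity) is spun; per
        spin the component is refitted and its variance explained recorded.
        """
        rid = pd.Index(spins.region_ids)
        if not rid.equals(self.X.index):
            if not self.X.index.isin(rid).all() or len(rid) != len(self.X.index):
                raise ValueError("spin region set does not match the model regions")
            # same ids, different order: align spins to X's region order
            raise ValueError("spin region order does not match the model regions")
        Xm = self.X.to_numpy(float)
        yv = self.y.to_numpy(float)
        null = np.empty(spins.n_spins)
        for s, perm in enumerate(spins.permutations):
            null[s] = self._pls1(Xm, yv[perm], self.standardize)[2]
        results.p_spin = spin_pvalue(results.var_explained, null, "greater")
        results.settings["n_spins"] = spins.n_spins
        return results

    def bootstrap_z(self, results: PLSResults, n_boot: int = 1000,
                    seed: int = 0) -> PLSResults:
        """Bootstrap gene weights over region resamples.

        Regions (the observational units of the regression) are resampled with
        replacement; each replicate's weights are sign-aligned to the original
        (all signs flipped when the dot product with the original weight
        vector is negative).  Z = original weight / bootstrap SE; q = BH-FDR
        over two-sided normal p-values of Z.
        """
        if n_boot < 2:
            raise ValueError("n_boot must be >= 2")
        n = len(self.y)
        if n < 10:
            import warnings
            warnings.warn("fewer than 10 regions: bootstrap SEs will be unstable")
        rng = np.random.default_rng(seed)
        Xm = self.X.to_numpy(float)
        yv = self.y.to_numpy(float)
        w0 = results.weights.to_numpy()
        W = np.empty((n_boot, Xm.shape[1]))
        b = 0
        while b < n_boot:
            idx = rng.integers(0, n, size=n)
            yb = yv[idx]
            if yb.std() == 0:
                continue  # degenerate resample: all regions identical
            try:
                w, scores, _, _ = self._pls1(Xm[idx], yb, self.standardize)
            except ValueError:
                continue
            if np.corrcoef(scores, yb)[0, 1] < 0:
                w = -w
            if w @ w0 < 0:
                w = -w
            W[b] = w
            b += 1
        se = W.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se > 0, w0 / se, 0.0)
        p = 2.0 * stats.norm.sf(np.abs(z))
        results.gene_table = pd.DataFrame(
            {"weight": w0, "se": se, "z": z, "q": bh_fdr(p)}, index=results.weights.index)
        results.settings.update({"n_boot": n_boot, "bootstrap_seed": seed})
        return results


def gene_map_correlation(genes, X: RegionGeneMatrix | pd.DataFrame, y: pd.Series,
                         spins: SpinSet) -> pd.DataFrame:
    """Per-gene spatial correlation with the response, spin p, FDR across genes.

    ``genes`` is the named gene family over which BH-FDR is applied (e.g. a
    prior disease-gene panel restricted to the analyzed universe).  Each
    gene's regional expression profile is spun against the fixed response map;
    the spin alternative is two-sided.
    """
    from .spin import spin_correlation_test

    Xv = X.values if isinstance(X, RegionGeneMatrix) else X
    genes = list(genes)
    missing = [g for g in genes if g not in Xv.columns]
    if missing:
        raise ValueError(f"unknown gene(s): {missing}")
    rid = pd.Index(spins.region_ids)
    rows = []
    for g in genes:
        r, p = spin_correlation_test(Xv.loc[rid, g].to_numpy(float),
                                     y.loc[rid].to_numpy(float), spins,
                                     method="pearson", alternative="two_sided")
        rows.append((g, r, p))
    out = pd.DataFrame(rows, columns=["gene", "r", "p_spin"]).set_index("gene")
    out["q"] = bh_fdr(out["p_spin"])
    return out
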