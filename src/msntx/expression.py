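"""Six-step preprocessing of multi-donor microarray bundles.

Turns an :class:`~msntx.ahba.ExpressionBundle` into a left-hemisphere
region x gene matrix of normalized expression:

(i)   re-annotate probes against an independent probe->gene mapping, dropping
      probes with missing, ambiguous or contradicted annotations;
(ii)  intensity-based filtering: keep probes whose detection ("present") call
      rate, pooled across all donors' samples, is at least ``min_fraction``
      (default 0.5);
(iii) probe selection: one probe per gene, the one whose region-averaged
      profile best matches (Spearman) an RNA-seq-like reference;
(iv)  sample assignment: each tissue sample is assigned to the nearest parcel
      representative point if within ``max_distance`` (default 2.0 distance
      units), left hemisphere only by default;
(v)   scaled-robust-sigmoid (SRS) normalization of each gene within each
      donor, rescaled to [0, 1] — outlier-robust and donor-specific;
(vi)  differential-stability (DS) filtering: genes whose regional profiles
      are reproducible across donors (mean pairwise inter-donor Spearman).

Step order is fixed; :func:`build_region_gene_matrix` runs the whole chain
and records per-step provenance counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

from .ahba import ExpressionBundle
from .atlas import ParcelAtlas

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionConfig",
    "RegionGeneMatrix",
    "reannotate_probes",
    "filter_probes_intensity",
    "select_probes",
    "assign_samples",
    "srs_normalize",
    "differential_stability",
    "differential_stability_filter",
    "build_region_gene_matrix",
]


class PipelineHaltError(RuntimeError):
    """A preprocessing stage emptied the data; names the stage."""


@dataclass
class ExpressionConfig:
    """Tunable parameters of the expression-preprocessing chain."""

    min_call_fraction: float = 0.5       # step (ii) detection-rate cut
    pool_donors_for_intensity: bool = True
    max_distance: float = 2.0            # step (iv), sample-frame distance units
    left_only: bool = True
    ds_mode: str = "top_fraction"        # or "ds_min"
    ds_threshold: float = 0.5            # fraction retained / minimum DS
    probe_selection_method: str = "spearman"


@dataclass
class RegionGeneMatrix:
    """Left-hemisphere region x gene normalized expression with provenance."""

    values: pd.DataFrame                 # region_id x gene_symbol, in [0, 1]
    ds: pd.Series                        # differential stability per retained gene
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = self.values.to_numpy(float)
        if np.isnan(v).any():
            raise ValueError("region x gene matrix contains missing values")
        if v.size and (v.min() < -1e-12 or v.max() > 1 + 1e-12):
            raise ValueError("normalized expression must lie in [0, 1]")

    @property
    def regions(self) -> pd.Index:
        return self.values.index

    @property
    def genes(self) -> pd.Index:
        return self.values.columns

    def write_tsv(self, path) -> None:
        self.values.rename_axis("region_id").to_csv(path, sep="\t")


# -- step (i) ---------------------------------------------------------------

def reannotate_probes(probes: pd.DataFrame, mapping: pd.DataFrame | None) -> pd.DataFrame:
    """Drop probes with missing, ambiguous or contradicted gene annotations.

    ``mapping`` is an independent probe_id -> gene_symbol table; a probe is
    kept only if its symbol is present, maps to exactly one gene, and (when
    the probe appears in ``mapping``) both sources agree.  Probes absent from
    a supplied mapping are dropped.
    """
    sym = probes["gene_symbol"]
    ok = sym.notna() & (sym.astype(str).str.strip() != "")
    # ambiguous: annotation listing several genes (separator-delimited)
    ok &= ~sym.astype(str).str.contains(r"[;,|/]", regex=True, na=False)
    if mapping is not None:
        mapped = mapping["gene_symbol"].reindex(probes.index)
        ok &= mapped.notna() & (mapped.astype(str) == sym.astype(str))
    kept = probes[ok]
    logger.info("reannotation: %d/%d probes kept", len(kept), len(probes))
    if kept.empty:
        raise PipelineHaltError("reannotation left no probes")
    return kept


# -- step (ii) --------------------------------------------------------------

def filter_probes_intensity(bundle: ExpressionBundle, min_fraction: float = 0.5,
                            probe_ids: pd.Index | None = None,
                            pool_donors: bool = True) -> pd.Index:
    """Probes detected above background in at least ``min_fraction`` of samples.

    Detection is the binary present/absent call matrix.  By default call rates
    are pooled across all donors' samples; with ``pool_donors=False`` a probe
    must pass the threshold within every donor.
    """
    probe_ids = bundle.probe_ids if probe_ids is None else probe_ids
    rates = []
    for d in bundle.donors:
        pac = d.pacall.reindex(probe_ids)
        rates.append(pac)
    if pool_donors:
        pooled = pd.concat(rates, axis=1)
        frac = pooled.mean(axis=1)
        keep = frac >= min_fraction
    else:
        keep = pd.Series(True, index=probe_ids)
        for pac in rates:
            keep &= pac.mean(axis=1) >= min_fraction
    kept = probe_ids[keep.to_numpy(bool)]
    logger.info("intensity filter: %d/%d probes kept", len(kept), len(probe_ids))
    return kept


# -- step (iv), needed by (iii) to form regional profiles --------------------

def assign_samples(bundle: ExpressionBundle, atlas: ParcelAtlas,
                   max_distance: float = 2.0, left_only: bool = True,
                   region_points: pd.DataFrame | None = None) -> dict[str, pd.Series]:
    """Assign each donor sample to its nearest parcel within ``max_distance``.

    ``region_points`` gives per-region representative points in the sample
    coordinate frame (columns x, y, z, indexed by region_id); by default the
    atlas centroids are used, scaled by ``bundle.truth['coordinate_scale']``
    when the bundle records one.  Samples farther than ``max_distance`` from
    every representative point stay unassigned (NaN); with ``left_only`` a
    sample whose nearest parcel is right-hemisphere is excluded.

    Returns one Series per donor mapping sample position -> region_id.
    """
    if region_points is None:
        scale = float(bundle.truth.get("coordinate_scale", 1.0))
        region_points = pd.DataFrame(atlas.centroids * scale, columns=["x", "y", "z"],
                                     index=pd.Index(atlas.region_ids, name="region_id"))
    pts = region_points[["x", "y", "z"]].to_numpy(float)
    rids = region_points.index.to_numpy()
    hemi = pd.Series(atlas.hemispheres, index=atlas.region_ids).reindex(region_points.index)
    out: dict[str, pd.Series] = {}
    n_assigned = 0
    for d in bundle.donors:
        coords = d.coordinates
        dist = np.linalg.norm(coords[:, None, :] - pts[None, :, :], axis=2)
        nearest = dist.argmin(axis=1)
        mind = dist[np.arange(len(coords)), nearest]
        region = rids[nearest].astype(float)
        region[mind > max_distance] = np.nan
        if left_only:
            region[(hemi.iloc[nearest] == "R").to_numpy()] = np.nan
        ser = pd.Series(region, index=d.samples.index, name="region_id")
        n_assigned += int(ser.notna().sum())
        out[d.donor_id] = ser
    logger.info("sample assignment: %d samples assigned", n_assigned)
    if n_assigned == 0:
        raise PipelineHaltError("sample assignment left no samples")
    return out


def _donor_region_means(d_expr: pd.DataFrame, assignment: pd.Series) -> pd.DataFrame:
    """Average a donor's samples within assigned regions: region x probe matrix."""
    assigned = assignment.dropna()
    if assigned.empty:
        return pd.DataFrame(index=pd.Index([], name="region_id"), columns=d_expr.index)
    # columns of d_expr are positional sample indices matching assignment's index
    sub = d_expr.loc[:, assigned.index]
    grouped = sub.T.groupby(assigned.astype(int).values).mean()
    grouped.index.name = "region_id"
    return grouped


# -- step (iii) --------------------------------------------------------------

def select_probes(bundle: ExpressionBundle, reference_expression: pd.DataFrame | None,
                  probes: pd.DataFrame, assignments: dict[str, pd.Series],
                  method: str = "spearman") -> pd.Series:
    """Pick one probe per gene: the most faithful to the reference expression.

    For every candidate probe the regional profile (samples averaged within
    region, donors pooled) is correlated with the reference profile of its
    gene over the shared regions; the probe with the highest correlation wins.
    Genes missing from the reference fall back to the probe with the highest
    mean intensity.  Ties break to the lowest probe_id.  Returns a Series
    gene_symbol -> probe_id.
    """
    donor_means = []
    mean_intensity = []
    for d in bundle.donors:
        dm = _donor_region_means(d.expression.reindex(probes.index), assignments[d.donor_id])
        donor_means.append(dm)
        mean_intensity.append(d.expression.reindex(probes.index).mean(axis=1))
    profile = pd.concat(donor_means).groupby(level=0).mean().T  # probe x region
    intensity = pd.concat(mean_intensity, axis=1).mean(axis=1)

    chosen: dict[str, object] = {}
    for gene, grp in probes.groupby("gene_symbol", sort=True):
        cand = grp.index.sort_values()
        if len(cand) == 1:
            chosen[gene] = cand[0]
            continue
        ref = None
        if reference_expression is not None and gene in reference_expression.index:
            ref = reference_expression.loc[gene]
        if ref is not None:
            shared = profile.columns.intersection(ref.index)
            best, best_r = None, -np.inf
            for pid in cand:
                prof = profile.loc[pid, shared]
                if len(shared) >= 3 and prof.std() > 0 and ref[shared].std() > 0:
                    if method == "spearman":
                        r = spearmanr(prof, ref[shared]).statistic
                    else:
                        r = np.corrcoef(prof, ref[shared])[0, 1]
                else:
                    r = -np.inf
                if r > best_r + 1e-15:
                    best, best_r = pid, r
            if best is not None and np.isfinite(best_r):
                chosen[gene] = best
                continue
        # fallback: highest mean intensity, ties to lowest probe_id
        ints = intensity.loc[cand]
        chosen[gene] = ints.index[np.argmax(ints.to_numpy())]
    if not chosen:
        raise PipelineHaltError("probe selection left no genes")
    out = pd.Series(chosen, name="probe_id")
    out.index.name = "gene_symbol"
    logger.info("probe selection: %d genes from %d probes", len(out), len(probes))
    return out


# -- step (v) ----------------------------------------------------------------

def srs_normalize(donor_matrix: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Scaled robust sigmoid per gene within one donor, rescaled to [0, 1].

    x' = 1 / (1 + exp(-(x - median(x)) / IQR(x))), then min-max rescaled.
    Genes with zero IQR are set to the constant 0.5 and reported as flagged
    (second return value) rather than failing.
    """
    x = donor_matrix.to_numpy(float)
    med = np.median(x, axis=0)
    q75, q25 = np.percentile(x, [75, 25], axis=0)
    iqr = q75 - q25
    flagged = [donor_matrix.columns[i] for i in np.flatnonzero(iqr == 0)]
    safe_iqr = np.where(iqr == 0, 1.0, iqr)
    s = 1.0 / (1.0 + np.exp(-(x - med) / safe_iqr))
    smin, smax = s.min(axis=0), s.max(axis=0)
    rng = np.where(smax > smin, smax - smin, 1.0)
    out = (s - smin) / rng
    out[:, iqr == 0] = 0.5
    return pd.DataFrame(out, index=donor_matrix.index, columns=donor_matrix.columns), flagged


# -- step (vi) ---------------------------------------------------------------

def differential_stability(per_donor: dict[str, pd.DataFrame],
                           min_shared_regions: int = 3) -> pd.Series:
    """Mean pairwise inter-donor Spearman correlation of regional profiles.

    For every gene and donor pair, the two donors' regional profiles are
    correlated over the regions both cover; DS is the mean over pairs.  Genes
    without any valid pair (fewer than ``min_shared_regions`` shared regions,
    or zero variance) get NaN.
    """
    if len(per_donor) < 2:
        raise ValueError("differential stability needs >=2 donors")
    donors = list(per_donor)
    genes = per_donor[donors[0]].columns
    for d in donors[1:]:
        genes = genes.union(per_donor[d].columns)
    sums = pd.Series(0.0, index=genes)
    counts = pd.Series(0, index=genes)
    for a in range(len(donors)):
        for b in range(a + 1, len(donors)):
            A, B = per_donor[donors[a]], per_donor[donors[b]]
            shared = A.index.intersection(B.index)
            if len(shared) < min_shared_regions:
                continue
            common = A.columns.intersection(B.columns)
            x = A.loc[shared, common].to_numpy(float)
            y = B.loc[shared, common].to_numpy(float)
            rx = np.apply_along_axis(rankdata, 0, x)
            ry = np.apply_along_axis(rankdata, 0, y)
            rx = rx - rx.mean(axis=0)
            ry = ry - ry.mean(axis=0)
            denom = np.linalg.norm(rx, axis=0) * np.linalg.norm(ry, axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                r = (rx * ry).sum(axis=0) / denom
            valid = denom > 0
            sums[common[valid]] += r[valid]
            counts[common[valid]] += 1
    ds = sums.where(counts > 0) / counts.replace(0, np.nan)
    ds.name = "ds"
    return ds


def differential_stability_filter(per_donor: dict[str, pd.DataFrame],
                                  threshold_mode: str = "top_fraction",
                                  threshold: float = 0.5) -> tuple[pd.Index, pd.Series]:
    """Retain reproducible genes by DS rank fraction or minimum-DS rule."""
    ds = differential_stability(per_donor)
    defined = ds.dropna()
    if threshold_mode == "top_fraction":
        if not (0.0 < threshold <= 1.0):
            raise ValueError("top_fraction threshold must be in (0, 1]")
        n_keep = max(1, int(np.ceil(threshold * len(defined))))
        kept = defined.sort_values(ascending=False, kind="stable").index[:n_keep]
        kept = defined.index.intersection(kept)  # restore column order
    elif threshold_mode == "ds_min":
        kept = defined.index[defined > threshold]
    else:
        raise ValueError("threshold_mode must be 'top_fraction' or 'ds_min'")
    logger.info("differential stability: %d/%d genes kept", len(kept), len(ds))
    return kept, ds


# -- full chain --------------------------------------------------------------

def build_region_gene_matrix(bundle: ExpressionBundle, atlas: ParcelAtlas,
                             config: ExpressionConfig | None = None) -> RegionGeneMatrix:
    """Run preprocessing steps (i)-(vi) and aggregate to region x gene.

    Per donor, retained samples are averaged within region and the resulting
    donor matrix is SRS-normalized per gene; DS filtering uses the normalized
    donor matrices (Spearman is invariant to the monotone SRS transform);
    finally donors are averaged per region, restricted to the left hemisphere.
    """
    cfg = config or ExpressionConfig()
    prov: dict[str, object] = {"probes_in": int(len(bundle.probes))}

    probes = reannotate_probes(bundle.probes, bundle.reannotation)
    prov["probes_after_reannotation"] = int(len(probes))
    prov["probes_dropped_reannotation"] = prov["probes_in"] - prov["probes_after_reannotation"]

    kept_ids = filter_probes_intensity(bundle, cfg.min_call_fraction,
                                       probe_ids=probes.index,
                                       pool_donors=cfg.pool_donors_for_intensity)
    prov["probes_after_intensity"] = int(len(kept_ids))
    prov["probes_dropped_intensity"] = int(len(probes) - len(kept_ids))
    probes = probes.loc[kept_ids]
    if probes.empty:
        raise PipelineHaltError("intensity filtering left no probes")

    assignments = assign_samples(bundle, atlas, cfg.max_distance, cfg.left_only)
    prov["samples_total"] = int(sum(len(a) for a in assignments.values()))
    prov["samples_assigned"] = int(sum(a.notna().sum() for a in assignments.values()))

    probe_of_gene = select_probes(bundle, bundle.reference_expression, probes,
                                  assignments, method=cfg.probe_selection_method)
    prov["genes_selected"] = int(len(probe_of_gene))

    per_donor: dict[str, pd.DataFrame] = {}
    flagged: dict[str, list] = {}
    for d in bundle.donors:
        dm = _donor_region_means(d.expression.reindex(probe_of_gene.to_numpy()),
                                 assignments[d.donor_id])
        if dm.empty:
            continue
        dm.columns = probe_of_gene.index  # relabel probes by their gene
        norm, flags = srs_normalize(dm)
        per_donor[d.donor_id] = norm
        if flags:
            flagged[d.donor_id] = [str(g) for g in flags]
    if len(per_donor) < 2:
        raise PipelineHaltError("donor aggregation left fewer than 2 donors")
    prov["donors_used"] = len(per_donor)
    if flagged:
        prov["srs_zero_iqr_genes"] = flagged

    kept_genes, ds = differential_stability_filter(per_donor, cfg.ds_mode, cfg.ds_threshold)
    prov["genes_after_ds"] = int(len(kept_genes))
    if len(kept_genes) == 0:
        raise PipelineHaltError("differential-stability filtering left no genes")

    stacked = pd.concat([m[kept_genes] for m in per_donor.values()])
    values = stacked.groupby(level=0).mean()
    left_ids = pd.Index(atlas.left_region_ids)
    values = values.loc[values.index.isin(left_ids)].sort_index()
    prov["regions_covered"] = int(len(values))
    if values.empty:
        raise PipelineHaltError("no left-hemisphere regions covered by samples")
    return RegionGeneMatrix(values=values, ds=ds.loc[kept_genes], provenance=prov)
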