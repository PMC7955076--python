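"""Morphometric similarity networks (MSN).

An MSN is a per-subject region x region matrix whose entry (i, j) is the
Pearson correlation between region i's and region j's multimodal morphometric
feature vectors, after each feature has been z-normalized across regions.  The
per-region statistic analysed downstream is the *regional strength*: the
signed sum of a region's correlation weights to all other regions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "SubjectFeatures",
    "MSNMatrix",
    "zscore_features",
    "build_msn",
    "threshold_msn",
    "regional_strength",
    "strength_table",
    "read_features_tsv",
    "write_strength_tsv",
]

#: The seven morphometric features used by multimodal MSN studies.
DEFAULT_FEATURES = (
    "surface_area",
    "cortical_thickness",
    "gray_matter_volume",
    "gaussian_curvature",
    "mean_curvature",
    "fractional_anisotropy",
    "mean_diffusivity",
)


@dataclass(frozen=True)
class SubjectFeatures:
    """Region x feature matrix for one subject.

    ``matrix[r, f]`` is feature ``feature_names[f]`` of region ``region_ids[r]``
    in that feature's native units; z-normalization across regions is a separate
    explicit step (:func:`zscore_features`).
    """

    subject_id: str
    region_ids: np.ndarray
    matrix: np.ndarray
    feature_names: tuple[str, ...]
    zscored: bool = False

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "region_ids", np.asarray(self.region_ids, dtype=int))
        if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 3:
            raise ValueError("feature matrix must be 2-D with >=2 regions and >=3 features")
        if m.shape != (self.region_ids.size, len(self.feature_names)):
            raise ValueError("matrix shape does not match region_ids/feature_names")
        if not np.isfinite(m).all():
            raise ValueError("feature matrix contains non-finite values")


@dataclass(frozen=True)
class MSNMatrix:
    """Symmetric region x region Pearson-correlation matrix, zero diagonal."""

    region_ids: np.ndarray
    weights: np.ndarray
    density: float = 1.0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "region_ids", np.asarray(self.region_ids, dtype=int))
        n = self.region_ids.size
        if w.shape != (n, n):
            raise ValueError("weights must be square and match region_ids")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0.0):
            raise ValueError("diagonal must be exactly zero")
        if not (0.0 < self.density <= 1.0):
            raise ValueError("density must be in (0, 1]")


def zscore_features(features: SubjectFeatures) -> SubjectFeatures:
    """Z-normalize each feature across regions (mean 0, sample SD 1, ddof=1).

    Raises
    ------
    ValueError
        If any feature is constant across regions (zero variance), naming it.
    """
    m = features.matrix
    sd = m.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0.0)
    if bad.size:
        names = ", ".join(features.feature_names[i] for i in bad)
        raise ValueError(f"degenerate input: constant feature column(s): {names}")
    z = (m - m.mean(axis=0)) / sd
    return replace(features, matrix=z, zscored=True)


def build_msn(features: SubjectFeatures, *, allow_raw: bool = False) -> MSNMatrix:
    """Correlate every pair of regions' z-scored feature vectors.

    ``weights[i, j]`` is the Pearson correlation over the F features between
    region i and region j; the diagonal is zeroed (a region's similarity to
    itself carries no information for the strength statistic).

    The input must already be z-normalized (``zscore_features``); pass
    ``allow_raw=True`` to correlate unstandardized features deliberately.
    """
    if not features.zscored and not allow_raw:
        raise ValueError("features are not z-scored; call zscore_features first "
                         "or pass allow_raw=True")
    m = features.matrix
    rows = m - m.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(rows, axis=1)
    if np.any(norms == 0.0):
        bad = features.region_ids[norms == 0.0]
        raise ValueError(f"degenerate input: constant feature vector for region(s) {bad.tolist()}")
    rows = rows / norms[:, None]
    w = rows @ rows.T
    np.clip(w, -1.0, 1.0, out=w)
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return MSNMatrix(region_ids=features.region_ids, weights=w, density=1.0)


def threshold_msn(msn: MSNMatrix, density: float, *, rank_by: str = "signed") -> MSNMatrix:
    """Keep the top ``density`` fraction of off-diagonal edges, zero the rest.

    Edges are ranked by signed weight by default (largest correlations kept;
    negative edges are dropped first), symmetrically.  ``rank_by="absolute"``
    ranks by magnitude instead.  Ties are broken by (row, column) lexicographic
    order of the upper-triangle entry.  ``density=1`` returns the input.
    """
    if not (0.0 < density <= 1.0):
        raise ValueError("density must be in (0, 1]")
    if density == 1.0:
        return msn
    if rank_by not in ("signed", "absolute"):
        raise ValueError("rank_by must be 'signed' or 'absolute'")
    n = msn.region_ids.size
    iu, ju = np.triu_indices(n, k=1)
    vals = msn.weights[iu, ju]
    key = vals if rank_by == "signed" else np.abs(vals)
    n_keep = int(np.ceil(density * vals.size))  # symmetric pairs kept
    # stable sort descending on key; ties fall back to (row, col) order
    order = np.argsort(-key, kind="stable")
    keep = order[:n_keep]
    w = np.zeros_like(msn.weights)
    w[iu[keep], ju[keep]] = vals[keep]
    w = w + w.T
    return MSNMatrix(region_ids=msn.region_ids, weights=w, density=density)


def regional_strength(msn: MSNMatrix) -> pd.Series:
    """Signed sum of each region's correlation weights to all other regions."""
    return pd.Series(msn.weights.sum(axis=1), index=pd.Index(msn.region_ids, name="region_id"),
                     name="strength")


def strength_table(subjects: list[SubjectFeatures], *, density: float = 1.0,
                   rank_by: str = "signed") -> pd.DataFrame:
    """Subject x region matrix of regional MSN strengths.

    Runs z-scoring, MSN construction and (optionally) density thresholding per
    subject and stacks the strength vectors; rows are subject ids, columns
    region ids.
    """
    rows = {}
    for subj in subjects:
        msn = build_msn(zscore_features(subj))
        if density < 1.0:
            msn = threshold_msn(msn, density, rank_by=rank_by)
        rows[subj.subject_id] = regional_strength(msn)
    out = pd.DataFrame(rows).T
    out.index.name = "subject_id"
    return out


# -- I/O -------------------------------------------------------------------

def read_features_tsv(path, feature_names: tuple[str, ...] | None = None) -> list[SubjectFeatures]:
    """Read a long-format features table (subject_id, region_id, f1..fK)."""
    df = pd.read_csv(path, sep="\t")
    feats = feature_names or tuple(c for c in df.columns if c not in ("subject_id", "region_id"))
    out = []
    for sid, grp in df.groupby("subject_id", sort=False):
        grp = grp.sort_values("region_id")
        out.append(SubjectFeatures(
            subject_id=str(sid),
            region_ids=grp["region_id"].to_numpy(),
            matrix=grp[list(feats)].to_numpy(float),
            feature_names=tuple(feats),
        ))
    return out


def write_strength_tsv(strengths: pd.DataFrame, path) -> None:
    """Write subject x region strengths in long form (subject_id, region_id, strength)."""
    long = strengths.stack().rename("strength").reset_index()
    long.columns = ["subject_id", "region_id", "strength"]
    long.to_csv(path, sep="\t", index=False)
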