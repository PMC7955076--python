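"""Synthetic inputs with known planted structure for the whole pipeline.

Every input the analysis consumes can be generated here with ground truth
attached: a spherical two-hemisphere parcellation, case-control cohorts of
regional morphometric features with group effects planted in chosen regions,
multi-donor multi-probe expression bundles with spatially autocorrelated gene
gradients and a planted gene subset tracking the group-effect map, a
differential-expression table rank-correlated with the planted loadings, and
cell-type gene sets enriched for planted genes.

Spatial autocorrelation is imposed with a squared-exponential kernel on the
great-circle distance between parcel centroids; ``smoothness`` is the kernel
length-scale in radians.  Spin tests are only meaningful on autocorrelated
maps, so every regional field drawn here is smooth by construction.

The group effect is planted in the subjects' latent feature profiles, not in
the strengths directly: in each effect region a case subject's feature vector
is shifted along (direction +1) or against (direction -1) the cohort's
consensus feature-profile direction, so the change in regional MSN strength
is an emergent, sign-controlled consequence of the MSN computation itself.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .ahba import DonorData, ExpressionBundle
from .atlas import ParcelAtlas, make_atlas
from .genesets import CELL_CLASSES
from .msn import DEFAULT_FEATURES, SubjectFeatures

__all__ = [
    "SimulationTruth",
    "make_truth",
    "smooth_fields",
    "simulate_cohort",
    "simulate_expression_bundle",
    "simulate_dge_table",
    "make_cell_sets",
    "strong_signal_settings",
]

# Plausible per-feature scale/offset pairs so raw features carry native units
# (mm^2, mm, mm^3, mm^-2, mm^-1, dimensionless, mm^2/s) and z-scoring matters.
_FEATURE_UNITS = {
    "surface_area": (60.0, 500.0),
    "cortical_thickness": (0.25, 2.6),
    "gray_matter_volume": (180.0, 1500.0),
    "gaussian_curvature": (0.04, 0.12),
    "mean_curvature": (0.03, 0.13),
    "fractional_anisotropy": (0.05, 0.35),
    "mean_diffusivity": (0.0001, 0.0008),
}


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth shared by the generators.

    ``effect_direction`` maps each effect region to +/-1 (the sign of the
    expected case-control strength change); ``planted_genes`` maps each
    planted gene symbol to its signed loading on the group-effect map.
    """

    effect_regions: tuple[int, ...]
    effect_direction: dict[int, int]
    planted_genes: dict[str, float]
    effect_size: float
    seed: int
    signal_map: dict[int, float] = field(default_factory=dict)

    def validate_against(self, atlas: ParcelAtlas) -> None:
        known = set(int(r) for r in atlas.region_ids)
        bad = [r for r in self.effect_regions if int(r) not in known]
        if bad:
            raise ValueError(f"effect regions not in atlas: {bad}")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=float)

    @classmethod
    def from_json(cls, path) -> "SimulationTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(effect_regions=tuple(d["effect_regions"]),
                   effect_direction={int(k): int(v) for k, v in d["effect_direction"].items()},
                   planted_genes={k: float(v) for k, v in d["planted_genes"].items()},
                   effect_size=float(d["effect_size"]), seed=int(d["seed"]),
                   signal_map={int(k): float(v) for k, v in d.get("signal_map", {}).items()})


def smooth_fields(atlas: ParcelAtlas, n_fields: int, smoothness: float,
                  rng: np.random.Generator, hemisphere: str | None = None) -> np.ndarray:
    """Draw zero-mean unit-variance Gaussian fields with squared-exponential
    covariance exp(-d^2 / (2 * smoothness^2)) over great-circle distance d."""
    d = atlas.geodesic_distances(hemisphere)
    K = np.exp(-(d ** 2) / (2.0 * smoothness ** 2))
    L = np.linalg.cholesky(K + 1e-8 * np.eye(K.shape[0]))
    return L @ rng.standard_normal((K.shape[0], n_fields))


def make_truth(atlas: ParcelAtlas, n_effect_regions: int, n_planted_genes: int,
               effect_size: float, seed: int, smoothness: float = 0.5,
               min_loading: float = 0.6, max_loading: float = 0.95) -> SimulationTruth:
    """Derive a coherent ground truth from one smooth left-hemisphere map.

    A smooth field is drawn over the left hemisphere; the effect regions are
    the ``n_effect_regions`` parcels where its magnitude is largest, with
    direction the sign of the field there.  The signal map handed to the
    expression generator is the signed indicator of those regions (the
    expected shape of the case-control contrast), so planted gene expression
    tracks where — and with which sign — the cohort effect is planted.
    """
    rng = np.random.default_rng(seed)
    left_ids = atlas.left_region_ids
    s = smooth_fields(atlas, 1, smoothness, rng, hemisphere="L")[:, 0]
    order = np.argsort(-np.abs(s), kind="stable")[:n_effect_regions]
    effect = tuple(int(left_ids[i]) for i in order)
    direction = {int(left_ids[i]): int(np.sign(s[i]) or 1) for i in order}
    contrast = {int(r): float(direction.get(int(r), 0)) for r in left_ids}
    genes = [f"GENE{i:05d}" for i in range(n_planted_genes)]
    mags = rng.uniform(min_loading, max_loading, size=n_planted_genes)
    signs = rng.choice([-1.0, 1.0], size=n_planted_genes)
    planted = {g: float(m * sg) for g, m, sg in zip(genes, mags, signs)}
    return SimulationTruth(effect_regions=effect, effect_direction=direction,
                           planted_genes=planted, effect_size=effect_size,
                           seed=seed, signal_map=contrast)


# -- cohort -----------------------------------------------------------------

def _plant_effect(m: np.ndarray, effect_idx: np.ndarray, directions: np.ndarray,
                  step: float) -> np.ndarray:
    """Rotate effect-region feature profiles toward/away from the consensus.

    A region's MSN strength equals the inner product of its standardized
    feature profile with the sum of all other regions' standardized profiles,
    so rotating the profile toward that sum (direction +1) strictly raises the
    region's strength and rotating away (-1) strictly lowers it.  The rotation
    operates in the column-standardized domain the MSN pipeline will see;
    ``step`` sets the un-normalized shift along the consensus direction.
    """
    mean, sd = m.mean(axis=0), m.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    mc = (m - mean) / sd
    row_means = mc.mean(axis=1, keepdims=True)
    rows = mc - row_means
    norms = np.linalg.norm(rows, axis=1)
    safe = np.where(norms == 0, 1.0, norms)
    z = rows / safe[:, None]
    S = z.sum(axis=0)
    out = m.copy()
    for r, d in zip(effect_idx, directions):
        s_other = S - z[r]
        ns = np.linalg.norm(s_other)
        if ns == 0:
            continue
        znew = z[r] + d * step * (s_other / ns)
        znew -= znew.mean()
        nz = np.linalg.norm(znew)
        if nz == 0:
            continue
        znew /= nz
        out[r] = (znew * safe[r] + row_means[r, 0]) * sd + mean
    return out


def simulate_cohort(atlas: ParcelAtlas, n_per_group: int, truth: SimulationTruth,
                    n_features: int = 7, covariate_spec: dict[str, float] | None = None,
                    noise_sd: float = 1.0, smoothness: float = 0.5,
                    seed: int | None = None) -> tuple[list[SubjectFeatures], pd.DataFrame]:
    """Simulate a case-control cohort of regional morphometric feature tables.

    Each subject's region x feature matrix is a shared smooth regional profile
    plus covariate effects plus subject noise; case subjects additionally have
    their feature vectors in the effect regions shifted along +/- the cohort
    consensus direction by ``truth.effect_size * noise_sd``.  Returns the
    subject list and a participant table (group, age, sex, education, TIV,
    HAMD, HAMA).
    """
    if n_features < 3:
        raise ValueError("n_features must be >= 3")
    truth.validate_against(atlas)
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    covariate_spec = covariate_spec if covariate_spec is not None else \
        {"age": 0.02, "sex": 0.2, "education": 0.05}

    base = smooth_fields(atlas, n_features, smoothness, rng)
    # correlate features (a random mixing with decaying spectrum) so regional
    # profiles share a dominant subspace, as multimodal morphometry does
    q, _ = np.linalg.qr(rng.standard_normal((n_features, n_features)))
    spectrum = np.linspace(2.0, 0.5, n_features)
    base = base @ (q * spectrum) @ q.T
    cov_loadings = {c: 0.5 * smooth_fields(atlas, n_features, smoothness, rng)
                    for c in sorted(covariate_spec)}

    n = 2 * n_per_group
    groups = np.array(["control"] * n_per_group + ["case"] * n_per_group, dtype=object)
    age = rng.uniform(18, 60, n)
    sex = rng.integers(0, 2, n)
    education = np.clip(np.round(rng.normal(12, 3, n)), 6, 22)
    tiv = rng.normal(1450, 120, n)
    hamd = np.where(groups == "case", np.clip(rng.normal(22, 4, n), 8, None),
                    np.clip(rng.normal(2, 1.5, n), 0, None))
    hama = np.where(groups == "case", np.clip(rng.normal(18, 4, n), 6, None),
                    np.clip(rng.normal(2, 1.5, n), 0, None))
    cov_values = {"age": age, "sex": sex.astype(float), "education": education}

    if n_features == 7:
        feat_names = DEFAULT_FEATURES
    else:
        feat_names = tuple(f"f{k + 1}" for k in range(n_features))
    scales = np.array([_FEATURE_UNITS.get(f, (1.0, 0.0))[0] for f in feat_names])
    offsets = np.array([_FEATURE_UNITS.get(f, (1.0, 0.0))[1] for f in feat_names])

    effect_idx = atlas.index_of(np.array(truth.effect_regions)) if truth.effect_regions else \
        np.array([], dtype=int)
    directions = np.array([truth.effect_direction[int(r)] for r in truth.effect_regions])

    subjects = []
    for s in range(n):
        m = base.copy()
        for c, beta in sorted(covariate_spec.items()):
            x = cov_values[c]
            xs = (x[s] - x.mean()) / (x.std() if x.std() > 0 else 1.0)
            m = m + beta * xs * cov_loadings[c]
        m = m + noise_sd * rng.standard_normal(m.shape)
        if groups[s] == "case" and truth.effect_size != 0 and effect_idx.size:
            step = truth.effect_size * noise_sd / np.sqrt(n_features)
            m = _plant_effect(m, effect_idx, directions, step)
        raw = m * scales[None, :] + offsets[None, :]
        subjects.append(SubjectFeatures(subject_id=f"sub-{s + 1:04d}",
                                        region_ids=atlas.region_ids,
                                        matrix=raw, feature_names=feat_names))
    participants = pd.DataFrame(
        {"group": groups, "age": age, "sex": sex, "education": education,
         "TIV": tiv, "HAMD": hamd, "HAMA": hama},
        index=pd.Index([f"sub-{s + 1:04d}" for s in range(n)], name="subject_id"))
    return subjects, participants


def write_features_tsv(subjects: list[SubjectFeatures], path) -> None:
    frames = []
    for s in subjects:
        df = pd.DataFrame(s.matrix, columns=list(s.feature_names))
        df.insert(0, "region_id", s.region_ids)
        df.insert(0, "subject_id", s.subject_id)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


# -- expression bundle -------------------------------------------------------

def simulate_expression_bundle(
    atlas: ParcelAtlas, n_genes: int, truth: SimulationTruth,
    probes_per_gene: int = 3, n_donors: int = 6, samples_per_donor: int | None = None,
    signal_map: pd.Series | None = None, smoothness: float = 0.5,
    seed: int | None = None, *,
    probe_noise_sd: float = 0.1, probe_decoy_mix: float = 0.3,
    sample_jitter: float = 0.6, far_fraction: float = 0.03,
    right_fraction: float = 0.03, n_bad_probes: int = 0,
    n_background_probes: int = 0, call_quantile: float = 0.2,
    coordinate_scale: float = 75.0, base_intensity: float = 6.0,
    intensity_gain: float = 1.5,
) -> ExpressionBundle:
    """Simulate a multi-donor microarray bundle in the AHBA dialect.

    Per gene, the regional profile over the left hemisphere is a smooth random
    field; planted genes (``truth.planted_genes``) instead mix the signal map
    in with weight |loading| and the loading's sign, so their expression
    tracks the planted group-effect map.  Each gene gets ``probes_per_gene``
    probes: probe 0 reproduces the gene profile with the highest fidelity, the
    others are degraded by mixing in an independent field
    (``probe_decoy_mix``) plus probe-specific bias and noise.  Samples sit at
    donor-jittered positions near the left-hemisphere centroids (scaled to a
    brain-sized sphere of radius ``coordinate_scale``); small configurable
    fractions are placed beyond the assignment threshold or in the right
    hemisphere to exercise the distance and left-only filters.  Detection
    calls are absent where intensity falls below the donor-specific
    ``call_quantile`` quantile.  ``n_bad_probes`` extra probes carry missing,
    ambiguous or contradicted annotations; ``n_background_probes`` extra
    probes sit at background intensity throughout.
    """
    if n_donors < 2:
        raise ValueError("n_donors must be >= 2")
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)
    left_ids = atlas.left_region_ids
    nL = left_ids.size
    if samples_per_donor is None:
        samples_per_donor = nL + max(10, nL // 4)

    if signal_map is None and truth.signal_map:
        signal_map = pd.Series(truth.signal_map)
    genes = [f"GENE{i:05d}" for i in range(n_genes)]
    missing_planted = set(truth.planted_genes) - set(genes)
    if missing_planted:
        raise ValueError("planted genes outside the simulated gene universe "
                         f"(n_genes too small): {sorted(missing_planted)[:5]}...")

    G = smooth_fields(atlas, n_genes, smoothness, rng, hemisphere="L")
    if truth.planted_genes:
        if signal_map is None:
            raise ValueError("planted genes require a signal_map")
        sm = signal_map.reindex(left_ids)
        if sm.isna().any():
            raise ValueError("signal_map must cover the left-hemisphere regions")
        smv = sm.to_numpy(float)
        smv = (smv - smv.mean()) / (smv.std(ddof=0) or 1.0)
        for g, loading in truth.planted_genes.items():
            j = genes.index(g)
            beta = abs(float(loading))
            G[:, j] = np.sign(loading) * beta * smv + np.sqrt(max(0.0, 1 - beta ** 2)) * G[:, j]

    reference = pd.DataFrame(G.T, index=pd.Index(genes, name="gene_symbol"),
                             columns=pd.Index(left_ids, name="region_id"))

    # probe definitions
    probe_rows = []
    for j, g in enumerate(genes):
        for k in range(probes_per_gene):
            probe_rows.append((f"P{j * probes_per_gene + k + 1:06d}", g, j, k, "good"))
    n_good = len(probe_rows)
    for b in range(n_bad_probes):
        kind = ("missing", "ambiguous", "contradicted")[b % 3]
        gsrc = rng.integers(0, n_genes)
        pid = f"PB{b + 1:05d}"
        if kind == "missing":
            sym = ""
        elif kind == "ambiguous":
            sym = f"{genes[gsrc]};{genes[(gsrc + 1) % n_genes]}"
        else:
            sym = genes[gsrc]
        probe_rows.append((pid, sym, int(gsrc), 0, kind))
    for b in range(n_background_probes):
        gsrc = rng.integers(0, n_genes)
        probe_rows.append((f"PN{b + 1:05d}", genes[gsrc], int(gsrc), 0, "background"))
    probe_df = pd.DataFrame(probe_rows, columns=["probe_id", "gene_symbol", "gene_idx",
                                                 "probe_rank", "kind"]).set_index("probe_id")
    decoys = smooth_fields(atlas, len(probe_df), smoothness, rng, hemisphere="L")
    probe_bias = rng.normal(0.0, 0.5, len(probe_df))
    probe_bias[(probe_df["probe_rank"] == 0) & (probe_df["kind"] == "good")] = 0.0

    # reannotation mapping: agrees for good probes, contradicts where planted
    reann_rows = {}
    for pid, row in probe_df.iterrows():
        if row["kind"] in ("good", "background"):
            reann_rows[pid] = row["gene_symbol"]
        elif row["kind"] == "contradicted":
            reann_rows[pid] = genes[(int(row["gene_idx"]) + 1) % n_genes]
        # missing/ambiguous probes absent from the mapping
    reannotation = pd.DataFrame({"gene_symbol": pd.Series(reann_rows)})
    reannotation.index.name = "probe_id"

    centroid_pts = atlas.centroids[atlas.hemisphere_mask("L")] * coordinate_scale
    background_floor = base_intensity - 8.0
    donors = []
    truth_counts = {"n_probes_good": n_good, "n_probes_bad_annotation": n_bad_probes,
                    "n_probes_background": n_background_probes}
    max_distance_hint = 2.0
    for di in range(n_donors):
        donor_id = f"donor{di + 1:02d}"
        # sample placement: cover regions in random order, then extras
        order = rng.permutation(nL)
        reg_pos = np.concatenate([order, rng.integers(0, nL, max(0, samples_per_donor - nL))])
        reg_pos = reg_pos[:samples_per_donor]
        n_far = int(round(far_fraction * samples_per_donor))
        n_right = int(round(right_fraction * samples_per_donor))
        coords = centroid_pts[reg_pos] + rng.normal(0.0, sample_jitter, (samples_per_donor, 3))
        tags = np.array(["near"] * samples_per_donor, dtype=object)
        # far samples: pushed radially outward well past the assignment threshold
        far_idx = np.arange(samples_per_donor - n_far - n_right, samples_per_donor - n_right)
        for i in far_idx:
            p = centroid_pts[reg_pos[i]]
            coords[i] = p * (1.0 + (2.5 * max_distance_hint + rng.uniform(0, 2)) / np.linalg.norm(p))
            tags[i] = "far"
        right_idx = np.arange(samples_per_donor - n_right, samples_per_donor)
        for i in right_idx:
            coords[i] = coords[i] * np.array([-1.0, 1.0, 1.0])
            tags[i] = "right"
        samples = pd.DataFrame({"mni_x": coords[:, 0], "mni_y": coords[:, 1],
                                "mni_z": coords[:, 2],
                                "structure": [f"region_{left_ids[r]}" for r in reg_pos],
                                "placement": tags})

        # intensities: probe profile evaluated at the sample's source region
        gene_vals = G[reg_pos]                      # samples x genes
        decoy_vals = decoys[reg_pos]                # samples x probes
        prof = gene_vals[:, probe_df["gene_idx"].to_numpy()]
        rank = probe_df["probe_rank"].to_numpy()
        kind = probe_df["kind"].to_numpy()
        mix = np.where((rank == 0) & (kind == "good"), 0.0, probe_decoy_mix)
        signal = (1.0 - mix)[None, :] * prof + mix[None, :] * decoy_vals
        inten = base_intensity + intensity_gain * signal + probe_bias[None, :]
        if probe_noise_sd > 0:
            inten = inten + rng.normal(0.0, probe_noise_sd, inten.shape)
        inten = inten.T                              # probes x samples
        is_bg = (kind == "background")
        if is_bg.any():
            bg = background_floor + 0.1 * rng.standard_normal((int(is_bg.sum()), samples_per_donor))
            inten[is_bg] = bg
        expr = pd.DataFrame(inten, index=probe_df.index, columns=range(samples_per_donor))
        thresh = np.quantile(inten, call_quantile)
        pacall = (expr >= thresh).astype(int)
        donors.append(DonorData(donor_id=donor_id, expression=expr, pacall=pacall,
                                samples=samples))

    # bookkeeping from the generated calls (pooled >=50% rule of the pipeline)
    pooled = pd.concat([d.pacall for d in donors], axis=1)
    annotated_ok = probe_df["kind"].isin(["good", "background"])
    frac = pooled.mean(axis=1)
    truth_counts["expected_probes_after_reannotation"] = int(annotated_ok.sum())
    truth_counts["expected_probes_dropped_intensity"] = int(
        ((frac < 0.5) & annotated_ok).sum())
    # bookkeeping for the documented default assignment threshold (2.0 units):
    # count samples geometrically within reach of a left-hemisphere centroid
    all_pts = atlas.centroids * coordinate_scale
    left_mask = atlas.hemisphere_mask("L")
    n_assignable = 0
    for d in donors:
        dist = np.linalg.norm(d.coordinates[:, None, :] - all_pts[None, :, :], axis=2)
        nearest = dist.argmin(axis=1)
        ok = (dist[np.arange(len(nearest)), nearest] <= max_distance_hint) & left_mask[nearest]
        n_assignable += int(ok.sum())
    truth_counts["expected_samples_assigned"] = n_assignable
    truth_counts["coordinate_scale"] = coordinate_scale
    truth_counts["n_genes"] = n_genes

    probes_out = probe_df[["gene_symbol"]].copy()
    return ExpressionBundle(donors=donors, probes=probes_out, reannotation=reannotation,
                            reference_expression=reference,
                            truth={**truth_counts, "coordinate_scale": coordinate_scale})


# -- DGE table ---------------------------------------------------------------

def simulate_dge_table(truth: SimulationTruth, n_background: int, corr_strength: float,
                       seed: int, gene_universe=None, disorder: str = "MDD") -> pd.DataFrame:
    """Differential-expression table rank-correlated with the planted loadings.

    Planted genes receive ``dge_value = c * loading + sqrt(1 - c^2) * noise``
    with ``c = corr_strength`` (so ``c = 1`` is an exact monotone map of the
    loadings); ``n_background`` additional genes (drawn from ``gene_universe``
    when supplied, synthetic symbols otherwise) receive pure noise.  Direction
    is ``up`` for positive values, ``down`` for negative.
    """
    if not (0.0 <= corr_strength <= 1.0):
        raise ValueError("corr_strength must be in [0, 1]")
    rng = np.random.default_rng(seed)
    planted = sorted(truth.planted_genes)
    if gene_universe is not None:
        pool = [g for g in gene_universe if g not in truth.planted_genes]
        if len(pool) < n_background:
            pool = pool + [f"XBG{i:05d}" for i in range(n_background - len(pool))]
        bg = list(rng.choice(np.array(pool, dtype=object), size=n_background, replace=False)) \
            if n_background else []
    else:
        bg = [f"XBG{i:05d}" for i in range(n_background)]
    loadings = np.array([truth.planted_genes[g] for g in planted])
    c = corr_strength
    vals_planted = c * loadings + np.sqrt(max(0.0, 1 - c * c)) * rng.standard_normal(len(planted))
    vals_bg = rng.standard_normal(len(bg))
    df = pd.DataFrame({
        "gene": planted + list(bg),
        "dge_value": np.concatenate([vals_planted, vals_bg]) if len(planted) + len(bg) else [],
        "disorder": disorder,
    })
    df["direction"] = np.where(df["dge_value"] >= 0, "up", "down")
    return df


# -- cell-type gene sets ------------------------------------------------------

def make_cell_sets(gene_universe, planted_genes, class_sizes, enrichment=None,
                   seed: int = 0, class_names=None) -> dict[str, set]:
    """Cell-type gene sets, optionally enriched for planted genes.

    ``class_sizes`` is one size per class; ``enrichment`` maps class name to
    the fraction of its genes drawn from ``planted_genes`` (default 0).
    Classes may overlap (real cell classes do); within a class genes are
    unique.  Defaults to the seven canonical cortical classes.
    """
    universe = np.array(sorted(set(gene_universe)), dtype=object)
    planted = np.array(sorted(set(planted_genes) & set(universe)), dtype=object)
    names = list(class_names) if class_names is not None else \
        list(CELL_CLASSES[:len(class_sizes)]) if len(class_sizes) <= len(CELL_CLASSES) \
        else [f"class{i + 1}" for i in range(len(class_sizes))]
    if len(names) != len(class_sizes):
        raise ValueError("class_names and class_sizes lengths differ")
    enrichment = enrichment or {}
    rng = np.random.default_rng(seed)
    out: dict[str, set] = {}
    nonplanted = np.array(sorted(set(universe) - set(planted)), dtype=object)
    for name, size in zip(names, class_sizes):
        if size > len(universe):
            raise ValueError(f"class {name!r} size {size} exceeds gene universe")
        frac = float(enrichment.get(name, 0.0))
        n_pl = min(int(round(frac * size)), len(planted))
        chosen = set(rng.choice(planted, size=n_pl, replace=False)) if n_pl else set()
        n_rest = size - len(chosen)
        pool = nonplanted if frac > 0 else np.array(
            sorted(set(universe) - chosen), dtype=object)
        chosen |= set(rng.choice(pool, size=n_rest, replace=False))
        out[name] = chosen
    return out


# -- the documented strong-signal study conditions ---------------------------

def strong_signal_settings() -> dict:
    """The shipped strong-signal study conditions used for parameter recovery.

    Two groups of 60 subjects on a 308-parcel atlas (154 per hemisphere),
    seven morphometric features, 16 effect regions planted at 3.5x the subject
    noise, 2000 genes with 5% planted at loadings 0.75-0.95, six donors.
    """
    return {
        "n_per_hemisphere": 154,
        "n_systems": 7,
        "n_per_group": 60,
        "n_features": 7,
        "n_effect_regions": 16,
        "effect_size": 3.5,
        "noise_sd": 1.0,
        "smoothness": 0.4,
        "n_genes": 2000,
        "n_planted_genes": 100,
        "min_loading": 0.75,
        "max_loading": 0.95,
        "probes_per_gene": 3,
        "n_donors": 6,
        "samples_per_donor": 200,
        "n_bad_probes": 30,
        "n_background_probes": 60,
        "n_boot": 1000,
        "n_spins": 999,
        "z_threshold": 5.0,
    }
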