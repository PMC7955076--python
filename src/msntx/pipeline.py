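"""End-to-end orchestration: config, staged execution, manifest.

A run is driven by a YAML config (:class:`RunConfig`).  Stages execute in
paper order — simulate -> msn -> tmap -> expression -> pls -> genelists —
each reading only the previous stages' on-disk outputs from the run
directory, so any stage can be re-run in isolation.  Every stochastic stage
has an explicit seed in the config; reruns with an identical config are
byte-identical (the manifest records the config hash, package version, seeds
and output checksums, and deliberately no wallclock timestamp).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ahba import read_bundle, write_bundle
from .atlas import make_atlas, read_atlas_tsv
from .expression import ExpressionConfig, build_region_gene_matrix
from .genesets import celltype_expression_maps, celltype_overlap_test, dge_spearman_test
from .groupstats import RegionalCaseControl, aggregate_by_system, classify_regions
from .msn import read_features_tsv, strength_table, write_strength_tsv
from .pls import TranscriptomicPLS
from .spin import generate_spins
from .synth import (SimulationTruth, make_cell_sets, make_truth, simulate_cohort,
                    simulate_dge_table, simulate_expression_bundle, write_features_tsv)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "validate_inputs", "STAGES"]

STAGES = ("simulate", "msn", "tmap", "expression", "pls", "genelists")

REQUIRED_SEEDS = ("truth", "cohort", "expression", "spins", "bootstrap", "dge", "cell_sets")


@dataclass
class RunConfig:
    """Validated pipeline configuration; round-trips to YAML losslessly."""

    out_dir: str
    seeds: dict
    atlas: dict = field(default_factory=lambda: {"n_per_hemisphere": 154, "n_systems": 7})
    cohort: dict = field(default_factory=dict)
    expression_sim: dict = field(default_factory=dict)
    msn: dict = field(default_factory=lambda: {"density": 1.0})
    tmap: dict = field(default_factory=lambda: {"covariates": ["age", "sex", "education"]})
    expression_prep: dict = field(default_factory=dict)
    pls: dict = field(default_factory=lambda: {"n_spins": 5000, "n_boot": 1000,
                                               "z_threshold": 5.0, "fdr_threshold": 0.005})
    genelists: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [s for s in REQUIRED_SEEDS if s not in self.seeds]
        if missing:
            raise ValueError(f"config missing seed(s): {missing}")
        d = self.msn.get("density", 1.0)
        if not (0 < d <= 1):
            raise ValueError("msn.density must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in ("out_dir", "seeds", "atlas", "cohort",
                                              "expression_sim", "msn", "tmap",
                                              "expression_prep", "pls", "genelists")}

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(canon.encode()).hexdigest()


def _out(cfg: RunConfig) -> Path:
    p = Path(cfg.out_dir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def _load_truth(cfg: RunConfig) -> SimulationTruth:
    return SimulationTruth.from_json(_out(cfg) / "truth.json")


# -- stages ------------------------------------------------------------------

def stage_simulate(cfg: RunConfig) -> None:
    out = _out(cfg)
    atlas = make_atlas(cfg.atlas.get("n_per_hemisphere", 154),
                       cfg.atlas.get("n_systems", 7), seed=cfg.seeds["truth"])
    co = dict(cfg.cohort)
    truth = make_truth(atlas,
                       n_effect_regions=co.pop("n_effect_regions", 12),
                       n_planted_genes=cfg.expression_sim.get("n_planted_genes", 100),
                       effect_size=co.pop("effect_size", 3.0),
                       seed=cfg.seeds["truth"],
                       smoothness=co.get("smoothness", 0.4))
    subjects, participants = simulate_cohort(atlas, truth=truth, seed=cfg.seeds["cohort"], **co)
    ex = dict(cfg.expression_sim)
    ex.pop("n_planted_genes", None)
    bundle = simulate_expression_bundle(atlas, truth=truth, seed=cfg.seeds["expression"], **ex)
    atlas.write_tsv(out / "atlas.tsv")
    truth.to_json(out / "truth.json")
    write_features_tsv(subjects, out / "features.tsv")
    participants.to_csv(out / "participants.tsv", sep="\t")
    write_bundle(bundle, out / "ahba")
    with open(out / "bundle_truth.json", "w") as fh:
        json.dump(bundle.truth, fh, indent=1, default=float)
    logger.info("simulate: %d subjects, %d regions, %d probes",
                len(subjects), atlas.n_regions, len(bundle.probes))


def stage_msn(cfg: RunConfig) -> None:
    out = _out(cfg)
    subjects = read_features_tsv(out / "features.tsv")
    strengths = strength_table(subjects, density=cfg.msn.get("density", 1.0),
                               rank_by=cfg.msn.get("rank_by", "signed"))
    write_strength_tsv(strengths, out / "msn_strength.tsv")
    logger.info("msn: strengths for %d subjects x %d regions", *strengths.shape)


def _read_strengths(out: Path) -> pd.DataFrame:
    long = pd.read_csv(out / "msn_strength.tsv", sep="\t")
    return long.pivot(index="subject_id", columns="region_id", values="strength")


def stage_tmap(cfg: RunConfig) -> None:
    out = _out(cfg)
    strengths = _read_strengths(out)
    design = pd.read_csv(out / "participants.tsv", sep="\t", index_col="subject_id")
    atlas = read_atlas_tsv(out / "atlas.tsv")
    covs = tuple(cfg.tmap.get("covariates", ["age", "sex", "education"]))
    res = RegionalCaseControl(strengths, design, covariates=covs).fit()
    res.table.to_csv(out / "tmap.tsv", sep="\t")
    control_mean = strengths[(design["group"] == "control").to_numpy()].mean(axis=0)
    labels, fractions = classify_regions(res, control_mean)
    pd.DataFrame({"quadrant": labels, "control_mean_strength": control_mean,
                  "t": res.t}).to_csv(out / "quadrants.tsv", sep="\t")
    fractions.rename("fraction").to_csv(out / "quadrant_fractions.tsv", sep="\t")
    frames = []
    for scheme in atlas.system_labels:
        sysres = aggregate_by_system(strengths, atlas, scheme, design, covariates=covs)
        df = sysres.table.copy()
        df.insert(0, "scheme", scheme)
        frames.append(df)
    pd.concat(frames).to_csv(out / "systems.tsv", sep="\t")
    logger.info("tmap: %d regions, %d significant at FDR<0.05",
                len(res.table), len(res.significant()))


def stage_expression(cfg: RunConfig) -> None:
    out = _out(cfg)
    atlas = read_atlas_tsv(out / "atlas.tsv")
    bundle = read_bundle(out / "ahba")
    bt = out / "bundle_truth.json"
    if bt.exists():
        with open(bt) as fh:
            bundle.truth.update(json.load(fh))
    prep = ExpressionConfig(**cfg.expression_prep)
    rgm = build_region_gene_matrix(bundle, atlas, prep)
    rgm.write_tsv(out / "region_gene_matrix.tsv")
    rgm.ds.rename_axis("gene_symbol").to_csv(out / "ds.tsv", sep="\t")
    with open(out / "provenance.json", "w") as fh:
        json.dump(rgm.provenance, fh, indent=1, default=str)
    logger.info("expression: %d regions x %d genes", *rgm.values.shape)


def stage_pls(cfg: RunConfig) -> None:
    out = _out(cfg)
    atlas = read_atlas_tsv(out / "atlas.tsv")
    tmap = pd.read_csv(out / "tmap.tsv", sep="\t", index_col="region_id")
    X = pd.read_csv(out / "region_gene_matrix.tsv", sep="\t", index_col="region_id")
    model = TranscriptomicPLS(X, tmap["t"], standardize=cfg.pls.get("standardize", True))
    res = model.fit()
    # spins over exactly the covered left-hemisphere regions, in X's order
    spins = generate_spins(atlas, cfg.pls.get("n_spins", 5000), cfg.seeds["spins"],
                           hemisphere_scope="left_only",
                           region_ids=model.X.index.to_numpy())
    spins.save(out / "spins.tsv", out / "spins.json")
    model.spin_test(res, spins)
    model.bootstrap_z(res, n_boot=cfg.pls.get("n_boot", 1000), seed=cfg.seeds["bootstrap"])
    gl = res.gene_lists(cfg.pls.get("z_threshold", 5.0), cfg.pls.get("fdr_threshold", 0.005))
    res.gene_table.rename_axis("gene_symbol").to_csv(out / "gene_z.tsv", sep="\t")
    gl.write(out / "pls1_plus.txt", out / "pls1_minus.txt")
    with open(out / "pls_result.json", "w") as fh:
        json.dump({"var_explained": res.var_explained,
                   "var_explained_X": res.var_explained_X,
                   "p_spin": res.p_spin, "settings": res.settings,
                   "n_plus": len(gl.pls1_plus), "n_minus": len(gl.pls1_minus)},
                  fh, indent=1, default=float)
    logger.info("pls: var explained %.3f (p_spin=%.4g), %d+/%d- genes",
                res.var_explained, res.p_spin, len(gl.pls1_plus), len(gl.pls1_minus))


def stage_genelists(cfg: RunConfig) -> None:
    out = _out(cfg)
    truth = _load_truth(cfg)
    gz = pd.read_csv(out / "gene_z.tsv", sep="\t", index_col="gene_symbol")
    X = pd.read_csv(out / "region_gene_matrix.tsv", sep="\t", index_col="region_id")
    universe = list(X.columns)
    glcfg = dict(cfg.genelists)
    with open(out / "pls1_minus.txt") as fh:
        minus = [ln.strip() for ln in fh if ln.strip()]
    with open(out / "pls1_plus.txt") as fh:
        plus = [ln.strip() for ln in fh if ln.strip()]

    dcfg = glcfg.get("dge", {})
    dge = simulate_dge_table(truth, n_background=dcfg.get("n_background", 500),
                             corr_strength=dcfg.get("corr_strength", 0.6),
                             seed=cfg.seeds["dge"], gene_universe=universe)
    dge.to_csv(out / "dge_table.tsv", sep="\t", index=False)
    target = minus if len(minus) >= 3 else gz.index.tolist()
    try:
        stats_row = dge_spearman_test(gz.loc[gz.index.intersection(target), "z"], dge,
                                      direction=dcfg.get("direction", "up"),
                                      n_perm=dcfg.get("n_perm", 5000),
                                      seed=cfg.seeds["dge"] + 1,
                                      alternative=dcfg.get("alternative", "two_sided"))
    except ValueError as exc:
        stats_row = {"error": str(exc)}
    pd.DataFrame([stats_row]).to_csv(out / "dge_stats.tsv", sep="\t", index=False)

    ccfg = glcfg.get("cell_sets", {})
    sizes = ccfg.get("sizes", [max(5, len(universe) // 20)] * 7)
    sets = make_cell_sets(universe, truth.planted_genes, sizes,
                          enrichment=ccfg.get("enrichment"), seed=cfg.seeds["cell_sets"])
    for cls, genes in sets.items():
        with open(out / f"cellset_{cls}.txt", "w") as fh:
            fh.write("\n".join(sorted(genes)) + "\n")
    target_list = minus if minus else plus
    overlap = celltype_overlap_test(target_list, sets, universe,
                                    n_perm=ccfg.get("n_perm", 5000),
                                    seed=cfg.seeds["cell_sets"] + 1)
    overlap.rename_axis("cell_class").to_csv(out / "overlap_stats.tsv", sep="\t")
    maps = celltype_expression_maps(X, target_list, sets)
    maps.rename_axis("region_id").to_csv(out / "celltype_maps.tsv", sep="\t")
    logger.info("genelists: %d cell classes, DGE rho=%s",
                len(sets), stats_row.get("rho"))


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "msn": stage_msn,
    "tmap": stage_tmap,
    "expression": stage_expression,
    "pls": stage_pls,
    "genelists": stage_genelists,
}


def run_pipeline(config: RunConfig, stages=STAGES) -> dict:
    """Run the requested stages in order and write the manifest.

    Returns the manifest dict (config hash, seeds, package version, and a
    sha256 checksum per output file).
    """
    out = _out(config)
    for stage in stages:
        if stage not in _STAGE_FUNCS:
            raise ValueError(f"unknown stage {stage!r}")
        try:
            _STAGE_FUNCS[stage](config)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    checksums = {}
    for f in sorted(out.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            checksums[str(f.relative_to(out))] = hashlib.sha256(f.read_bytes()).hexdigest()
    manifest = {"config_hash": config.config_hash(), "version": __version__,
                "seeds": config.seeds, "stages": list(stages), "outputs": checksums}
    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()).hexdigest()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


# -- input validation --------------------------------------------------------

def validate_inputs(paths: dict) -> dict:
    """Schema checks for pipeline inputs; returns a machine-readable report.

    ``paths`` may contain ``atlas``, ``features``, ``participants`` and
    ``bundle`` (a donor-directory root).  The report lists named failures; an
    empty ``failures`` list means all supplied inputs validate.
    """
    failures: list[str] = []
    counts: dict = {}
    atlas = None
    if "atlas" in paths:
        try:
            atlas = read_atlas_tsv(paths["atlas"])
            counts["n_regions"] = atlas.n_regions
            counts["n_left"] = int(atlas.hemisphere_mask("L").sum())
        except Exception as exc:
            failures.append(f"atlas: {exc}")
    if "features" in paths:
        try:
            df = pd.read_csv(paths["features"], sep="\t")
            need = {"subject_id", "region_id"}
            if not need <= set(df.columns):
                failures.append("features.tsv: missing subject_id/region_id columns")
            else:
                per_subj = df.groupby("subject_id")["region_id"].nunique()
                counts["n_subjects"] = int(per_subj.size)
                if atlas is not None:
                    bad = per_subj[per_subj != atlas.n_regions]
                    for sid in bad.index:
                        failures.append(f"features.tsv: subject {sid} covers "
                                        f"{per_subj[sid]}/{atlas.n_regions} regions")
                if df.isna().any().any():
                    failures.append("features.tsv: missing values")
        except Exception as exc:
            failures.append(f"features: {exc}")
    if "participants" in paths:
        try:
            df = pd.read_csv(paths["participants"], sep="\t")
            for col in ("subject_id", "group", "age", "sex", "education"):
                if col not in df.columns:
                    failures.append(f"participants.tsv: missing column {col!r}")
        except Exception as exc:
            failures.append(f"participants: {exc}")
    if "bundle" in paths:
        try:
            bundle = read_bundle(paths["bundle"])
            counts["n_donors"] = len(bundle.donors)
        except Exception as exc:
            failures.append(f"bundle: {exc}")
    return {"failures": failures, "counts": counts, "ok": not failures}
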