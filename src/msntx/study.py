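"""The strong-signal synthetic study, end to end.

Runs the whole analysis at the documented strong-signal conditions
(:func:`msntx.synth.strong_signal_settings`) on generated data with known
ground truth, and reports recovery and headline statistics: how many planted
effect regions the regional contrast finds, how many planted genes land in
the correct PLS1 list, the PLS1 variance explained and its spin p, the
strength/t-map spatial coupling, quadrant fractions, DGE correlation,
cell-type enrichment, and a discovery/replication split with t-map
concordance and gene-list overlap.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .atlas import make_atlas
from .expression import ExpressionConfig, build_region_gene_matrix
from .genesets import celltype_overlap_test, dge_spearman_test, list_overlap_or
from .groupstats import RegionalCaseControl, classify_regions, map_concordance
from .msn import strength_table
from .pls import TranscriptomicPLS
from .spin import generate_spins
from .synth import (make_cell_sets, make_truth, simulate_cohort, simulate_dge_table,
                    simulate_expression_bundle, strong_signal_settings)

__all__ = ["run_strong_signal_study"]


def _fit_cohort(atlas, truth, settings, seed):
    subjects, participants = simulate_cohort(
        atlas, settings["n_per_group"], truth, n_features=settings["n_features"],
        noise_sd=settings["noise_sd"], smoothness=settings["smoothness"], seed=seed)
    strengths = strength_table(subjects)
    res = RegionalCaseControl(strengths, participants).fit()
    return strengths, participants, res


def run_strong_signal_study(seed: int = 1, settings: dict | None = None,
                            replicate: bool = True) -> dict:
    """Run the strong-signal study and return its quantitative summary.

    All randomness derives from ``seed``.  With ``replicate=True`` an
    independent second cohort is simulated from the same ground truth and the
    discovery/replication concordance and gene-list overlap are reported.
    """
    s = dict(strong_signal_settings())
    if settings:
        s.update(settings)
    base = int(seed) * 1000 % (2 ** 31 - 10)

    atlas = make_atlas(s["n_per_hemisphere"], s["n_systems"], seed=base)
    truth = make_truth(atlas, s["n_effect_regions"], s["n_planted_genes"],
                       effect_size=s["effect_size"], seed=base + 1,
                       smoothness=s["smoothness"],
                       min_loading=s.get("min_loading", 0.6),
                       max_loading=s.get("max_loading", 0.95))

    # -- cohort, MSN strengths, regional contrast ---------------------------
    strengths, participants, tmap = _fit_cohort(atlas, truth, s, base + 2)
    sig = set(int(r) for r in tmap.significant(0.05))
    correct_sign = [r for r in truth.effect_regions
                    if int(r) in sig and np.sign(tmap.t.loc[r]) == truth.effect_direction[r]]
    region_recovery = 100.0 * len(correct_sign) / len(truth.effect_regions)

    control_mean = strengths[(participants["group"] == "control").to_numpy()].mean(axis=0)
    _, fractions = classify_regions(tmap, control_mean)

    spins_all = generate_spins(atlas, s["n_spins"], base + 3,
                               hemisphere_scope="both_mirrored")
    coupling_r, coupling_p = map_concordance(tmap.t, control_mean, atlas, spins_all)

    # -- expression and PLS -------------------------------------------------
    bundle = simulate_expression_bundle(
        atlas, s["n_genes"], truth, probes_per_gene=s["probes_per_gene"],
        n_donors=s["n_donors"], samples_per_donor=s["samples_per_donor"],
        seed=base + 4, n_bad_probes=s["n_bad_probes"],
        n_background_probes=s["n_background_probes"])
    rgm = build_region_gene_matrix(bundle, atlas, ExpressionConfig(ds_threshold=1.0))
    y = tmap.t.loc[rgm.regions]
    model = TranscriptomicPLS(rgm, y)
    pls = model.fit()
    spins_left = generate_spins(atlas, s["n_spins"], base + 5,
                                region_ids=rgm.regions.to_numpy())
    model.spin_test(pls, spins_left)
    model.bootstrap_z(pls, n_boot=s["n_boot"], seed=base + 6)
    lists = pls.gene_lists(z_threshold=s["z_threshold"])
    plus, minus = set(lists.pls1_plus), set(lists.pls1_minus)
    recovered = [g for g, loading in truth.planted_genes.items()
                 if (g in plus and loading > 0) or (g in minus and loading < 0)]
    gene_recovery = 100.0 * len(recovered) / len(truth.planted_genes)

    # -- downstream gene-list statistics ------------------------------------
    universe = list(rgm.genes)
    dge = simulate_dge_table(truth, n_background=500, corr_strength=0.7,
                             seed=base + 7, gene_universe=universe)
    z = pls.gene_table["z"]
    dge_stats = dge_spearman_test(z.loc[z.index.intersection(
        pd.Index(sorted(minus | plus)))], dge, direction="up",
        n_perm=1999, seed=base + 8, alternative="two_sided")

    sizes = [150, 100, 140, 120, 100, 40, 30]
    enrichment = {"astrocytes": 0.25, "excitatory_neurons": 0.2,
                  "inhibitory_neurons": 0.15}
    sets = make_cell_sets(universe, truth.planted_genes, sizes,
                          enrichment=enrichment, seed=base + 9)
    target = sorted(minus | plus)
    overlap = celltype_overlap_test(target, sets, universe, n_perm=1999, seed=base + 10)

    out = {
        "effect_region_recovery_pct": region_recovery,
        "planted_gene_recovery_pct": gene_recovery,
        "n_regions_significant_fdr05": len(sig),
        "pls1_var_explained_pct": 100.0 * pls.var_explained,
        "pls1_p_spin": pls.p_spin,
        "strength_tmap_coupling_r": coupling_r,
        "strength_tmap_coupling_p_spin": coupling_p,
        "decoupling_pct": 100.0 * fractions["decoupling"],
        "dedifferentiation_pct": 100.0 * fractions["dedifferentiation"],
        "n_pls1_plus": len(plus),
        "n_pls1_minus": len(minus),
        "dge_spearman_rho": dge_stats["rho"],
        "dge_p_perm": dge_stats["p_perm"],
        "astrocytes_overlap": int(overlap.loc["astrocytes", "overlap"]),
        "astrocytes_overlap_q": float(overlap.loc["astrocytes", "q"]),
        "n_regions": atlas.n_regions,
        "n_left_regions": len(rgm.regions),
        "n_genes_analyzed": len(universe),
    }

    if replicate:
        s_rep = dict(s)
        s_rep["n_per_group"] = max(20, s["n_per_group"] // 2)
        _, _, tmap_rep = _fit_cohort(atlas, truth, s_rep, base + 11)
        rep_r, rep_p = map_concordance(tmap.t, tmap_rep.t, atlas, spins_all)
        y_rep = tmap_rep.t.loc[rgm.regions]
        model_rep = TranscriptomicPLS(rgm, y_rep)
        pls_rep = model_rep.fit()
        model_rep.bootstrap_z(pls_rep, n_boot=s["n_boot"], seed=base + 12)
        lists_rep = pls_rep.gene_lists(z_threshold=s["z_threshold"])
        both = list_overlap_or(sorted(minus | plus),
                               sorted(set(lists_rep.pls1_plus) | set(lists_rep.pls1_minus)),
                               universe)
        out.update({
            "replication_tmap_r": rep_r,
            "replication_tmap_p_spin": rep_p,
            "gene_list_overlap_or": both["odds_ratio"],
            "gene_list_overlap_p": both["p"],
        })
    return out
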