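"""Downstream gene-list statistics.

Relates PLS1 gene lists to external resources: differential-expression (DGE)
tables from postmortem case-control transcriptomics (Spearman correlation
with a direction-relabelling permutation null), canonical cell-type gene sets
(size-matched resampling overlap test), cell-type regional expression maps,
and odds-ratio overlap between two gene lists (Fisher exact).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .expression import RegionGeneMatrix
from .groupstats import bh_fdr

logger = logging.getLogger(__name__)

__all__ = [
    "CELL_CLASSES",
    "dge_spearman_test",
    "dge_spearman_panel",
    "celltype_overlap_test",
    "celltype_expression_maps",
    "list_overlap_or",
    "read_gene_list",
    "read_cell_sets",
]

#: The seven canonical cortical cell classes.
CELL_CLASSES = ("astrocytes", "endothelial", "excitatory_neurons",
                "inhibitory_neurons", "microglia", "opcs", "oligodendrocytes")


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    ra, rb = stats.rankdata(a), stats.rankdata(b)
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    d = np.linalg.norm(ra) * np.linalg.norm(rb)
    return float(ra @ rb / d) if d > 0 else 0.0


def dge_spearman_test(weights: pd.Series, dge: pd.DataFrame, direction: str = "up",
                      n_perm: int = 5000, seed: int = 0,
                      alternative: str = "less") -> dict:
    """Spearman correlation of gene weights with DGE values, permutation p.

    ``weights`` is a PLS gene list's weight (or Z) per gene; ``dge`` has
    columns ``gene``, ``dge_value``, ``direction``.  The statistic uses genes
    common to the list and the direction-filtered DGE set.  The null randomly
    relabels the dysregulated sets across all differentially expressed genes
    ``n_perm`` times: each permutation shuffles which gene carries which
    (dge_value, direction) pair — values travel with their labels, so
    per-direction counts are preserved and, because direction is typically a
    function of the value's sign, label-value coupling is preserved too
    (relabelling direction alone against its own values would be
    anticonservative).  p uses the +1-corrected count for the stated
    alternative ('less' for a negative association, 'greater', 'two_sided').
    """
    if direction not in set(dge["direction"]):
        raise ValueError(f"direction {direction!r} not present in DGE table")
    dge = dge.drop_duplicates(subset="gene").set_index("gene")
    in_dir = dge.index[dge["direction"] == direction]
    common = weights.index.intersection(in_dir)
    if len(common) < 3:
        raise ValueError(f"insufficient overlap: only {len(common)} genes shared "
                         f"between the list and the {direction}-regulated set")
    rho = _spearman(weights.loc[common].to_numpy(), dge.loc[common, "dge_value"].to_numpy())

    rng = np.random.default_rng(seed)
    labels = dge["direction"].to_numpy()
    values = dge["dge_value"].to_numpy()
    genes = dge.index.to_numpy()
    in_list = np.isin(genes, weights.index.to_numpy())
    w_all = weights.reindex(dge.index).to_numpy()
    null = np.empty(n_perm)
    n_genes = len(genes)
    for i in range(n_perm):
        perm = rng.permutation(n_genes)          # gene -> shuffled (value, label)
        mask = (labels[perm] == direction) & in_list
        if mask.sum() < 3:
            null[i] = 0.0
            continue
        null[i] = _spearman(w_all[mask], values[perm][mask])
    from .spin import spin_pvalue

    p = spin_pvalue(rho, null, alternative)
    return {"rho": rho, "p_perm": p, "n_common": int(len(common)),
            "direction": direction, "n_perm": n_perm,
            "null_preserves_direction_counts": True}


def dge_spearman_panel(weights: pd.Series, tables: dict[str, pd.DataFrame],
                       direction: str = "up", n_perm: int = 5000, seed: int = 0,
                       alternative: str = "two_sided") -> pd.DataFrame:
    """Run :func:`dge_spearman_test` per disorder and BH-FDR across the panel."""
    rows = {}
    for k, (disorder, table) in enumerate(sorted(tables.items())):
        rows[disorder] = dge_spearman_test(weights, table, direction, n_perm,
                                           seed + k, alternative)
    out = pd.DataFrame(rows).T
    out["q"] = bh_fdr(out["p_perm"].astype(float))
    return out


def _null_overlaps(rng: np.random.Generator, in_list: np.ndarray, size: int,
                   n_perm: int) -> np.ndarray:
    """Overlap counts for size-matched draws (without replacement) from background."""
    n_bg = in_list.size
    null = np.empty(n_perm, dtype=int)
    # vectorize in chunks: random keys + argpartition = uniform subset per row
    chunk = max(1, int(2e7 // max(n_bg, 1)))
    for start in range(0, n_perm, chunk):
        m = min(chunk, n_perm - start)
        keys = rng.random((m, n_bg))
        pick = np.argpartition(keys, size - 1, axis=1)[:, :size] if size < n_bg \
            else np.tile(np.arange(n_bg), (m, 1))
        null[start:start + m] = in_list[pick].sum(axis=1)
    return null


def celltype_overlap_test(gene_list, sets: dict[str, set], background,
                          n_perm: int = 5000, seed: int = 0) -> pd.DataFrame:
    """Overlap of a gene list with each cell-type set against a resampling null.

    Observed = |gene_list ∩ set|.  The null resamples the *cell set*: draws of
    the same size from the background universe, overlapped with the fixed gene
    list; p = (1 + #{null >= observed}) / (n_perm + 1), one-sided for
    enrichment, BH-FDR across the classes.  Genes outside the background are
    logged and clipped.
    """
    background = pd.Index(sorted(set(background)))
    if len(background) == 0:
        raise ValueError("empty background universe")
    gl = set(gene_list) & set(background)
    if len(gl) < len(set(gene_list)):
        logger.warning("clipped %d list genes outside background",
                       len(set(gene_list)) - len(gl))
    rng = np.random.default_rng(seed)
    in_list = np.isin(background.to_numpy(), np.array(sorted(gl)))
    rows = {}
    for cls in sorted(sets):
        s = set(sets[cls]) & set(background)
        observed = len(gl & s)
        size = len(s)
        if size == 0:
            rows[cls] = {"overlap": 0, "set_size": 0, "p_perm": 1.0}
            continue
        null = _null_overlaps(rng, in_list, size, n_perm)
        p = (1.0 + np.sum(null >= observed)) / (n_perm + 1.0)
        rows[cls] = {"overlap": observed, "set_size": size, "p_perm": p}
    out = pd.DataFrame(rows).T
    out["q"] = bh_fdr(out["p_perm"].astype(float))
    out["overlap"] = out["overlap"].astype(int)
    out["set_size"] = out["set_size"].astype(int)
    return out


def celltype_expression_maps(X: RegionGeneMatrix | pd.DataFrame, gene_list,
                             sets: dict[str, set]) -> pd.DataFrame:
    """Mean regional expression over (gene_list ∩ set) per cell class.

    Classes with empty overlap are omitted (logged).  Returns region x class.
    """
    Xv = X.values if isinstance(X, RegionGeneMatrix) else X
    gl = set(gene_list)
    cols = {}
    for cls in sorted(sets):
        genes = sorted(gl & set(sets[cls]) & set(Xv.columns))
        if not genes:
            logger.info("cell class %s: no overlapping genes, omitted", cls)
            continue
        cols[cls] = Xv[genes].mean(axis=1)
    return pd.DataFrame(cols)


def list_overlap_or(list_a, list_b, background) -> dict:
    """Odds ratio and two-sided Fisher exact p for overlap of two gene lists.

    2x2 table over the background universe: (both, a-only, b-only, neither).
    The reported OR uses the Haldane 0.5 correction when any cell is zero;
    the Fisher p always uses the raw table.
    """
    bg = set(background)
    if not bg:
        raise ValueError("empty background universe")
    A, B = set(list_a) & bg, set(list_b) & bg
    a = len(A & B)
    b = len(A - B)
    c = len(B - A)
    d = len(bg) - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orr = (a * d) / (b * c)
    return {"odds_ratio": float(orr), "p": float(p),
            "table": {"both": a, "a_only": b, "b_only": c, "neither": d}}


# -- I/O -------------------------------------------------------------------

def read_gene_list(path) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]


def read_cell_sets(paths: dict[str, str]) -> dict[str, set]:
    """Map of class name -> gene-list file into class -> gene set."""
    return {cls: set(read_gene_list(p)) for cls, p in paths.items()}
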