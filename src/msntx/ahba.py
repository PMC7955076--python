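"""Multi-donor microarray expression bundles in the AHBA file dialect.

The Allen Human Brain Atlas microarray release ships, per donor, four CSVs:
``MicroarrayExpression.csv`` (probe x sample intensities, first column the
probe id), ``SampleAnnot.csv`` (one row per sample with MNI coordinates),
``Probes.csv`` (probe id -> gene symbol) and ``PACall.csv`` (binary
present/absent detection calls, same shape as the expression matrix).
:class:`ExpressionBundle` is the in-memory form of that layout, plus an
RNA-seq-like reference expression matrix used for probe selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["DonorData", "ExpressionBundle", "write_bundle", "read_bundle"]


@dataclass
class DonorData:
    """One donor's probe x sample intensities, calls, and sample annotations."""

    donor_id: str
    expression: pd.DataFrame     # probe_id x sample, log2-scale intensities
    pacall: pd.DataFrame         # same shape, 0/1 present calls
    samples: pd.DataFrame        # per sample: mni_x, mni_y, mni_z, structure

    def __post_init__(self) -> None:
        if self.expression.shape != self.pacall.shape:
            raise ValueError(f"donor {self.donor_id}: PACall shape "
                             f"{self.pacall.shape} != expression shape {self.expression.shape}")
        if len(self.samples) != self.expression.shape[1]:
            raise ValueError(f"donor {self.donor_id}: sample annotations do not "
                             "match expression columns")

    @property
    def coordinates(self) -> np.ndarray:
        return self.samples[["mni_x", "mni_y", "mni_z"]].to_numpy(float)


@dataclass
class ExpressionBundle:
    """Everything the expression-preprocessing pipeline consumes.

    ``probes`` annotates every probe id with a gene symbol (possibly blank or
    ambiguous — the reannotation step filters those); ``reannotation`` is an
    independent probe -> gene mapping emulating a re-annotation resource;
    ``reference_expression`` is a gene x region matrix emulating RNA-seq used
    to pick the most faithful probe per gene.
    """

    donors: list[DonorData]
    probes: pd.DataFrame                      # index probe_id, column gene_symbol
    reannotation: pd.DataFrame | None = None  # index probe_id, column gene_symbol
    reference_expression: pd.DataFrame | None = None  # gene x region_id
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.donors) < 2:
            raise ValueError("need >=2 donors (differential stability needs pairs)")
        for d in self.donors:
            missing = d.expression.index.difference(self.probes.index)
            if len(missing):
                raise ValueError(f"donor {d.donor_id}: {len(missing)} probes lack annotations")

    @property
    def donor_ids(self) -> list[str]:
        return [d.donor_id for d in self.donors]

    @property
    def probe_ids(self) -> pd.Index:
        return self.probes.index


def write_bundle(bundle: ExpressionBundle, root) -> None:
    """Write the bundle as per-donor AHBA-dialect CSV directories.

    Layout: ``<root>/<donor_id>/{MicroarrayExpression,SampleAnnot,Probes,PACall}.csv``
    plus ``<root>/reference_expression.csv`` and ``<root>/reannotation.csv``.
    """
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    for d in bundle.donors:
        ddir = root / d.donor_id
        ddir.mkdir(exist_ok=True)
        # first column probe_id, remaining columns samples (no header row for samples,
        # matching the AHBA convention of positional sample columns)
        d.expression.to_csv(ddir / "MicroarrayExpression.csv", header=False)
        d.pacall.astype(int).to_csv(ddir / "PACall.csv", header=False)
        ann = d.samples.copy()
        ann.insert(0, "donor_id", d.donor_id)
        ann.to_csv(ddir / "SampleAnnot.csv", index=False)
        bundle.probes.loc[d.expression.index].to_csv(ddir / "Probes.csv")
    if bundle.reference_expression is not None:
        bundle.reference_expression.to_csv(root / "reference_expression.csv")
    if bundle.reannotation is not None:
        bundle.reannotation.to_csv(root / "reannotation.csv")


def read_bundle(root) -> ExpressionBundle:
    """Read a per-donor AHBA-dialect directory tree written by :func:`write_bundle`."""
    root = Path(root)
    donors = []
    probes = None
    for ddir in sorted(p for p in root.iterdir() if p.is_dir()):
        expr = pd.read_csv(ddir / "MicroarrayExpression.csv", header=None, index_col=0)
        pac = pd.read_csv(ddir / "PACall.csv", header=None, index_col=0)
        ann = pd.read_csv(ddir / "SampleAnnot.csv")
        expr.index.name = pac.index.name = "probe_id"
        expr.columns = range(expr.shape[1])
        pac.columns = range(pac.shape[1])
        dprobes = pd.read_csv(ddir / "Probes.csv", index_col=0)
        probes = dprobes if probes is None else probes.combine_first(dprobes)
        donors.append(DonorData(donor_id=ddir.name, expression=expr, pacall=pac,
                                samples=ann.drop(columns=["donor_id"], errors="ignore")))
    if not donors:
        raise ValueError(f"no donor directories under {root}")
    ref_path = root / "reference_expression.csv"
    reann_path = root / "reannotation.csv"
    reference = pd.read_csv(ref_path, index_col=0) if ref_path.exists() else None
    if reference is not None:
        reference.columns = reference.columns.astype(int)
    reann = pd.read_csv(reann_path, index_col=0) if reann_path.exists() else None
    return ExpressionBundle(donors=donors, probes=probes, reannotation=reann,
                            reference_expression=reference)
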