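"""Spherical parcellation atlas: the spatial frame for every stage.

A :class:`ParcelAtlas` holds one centroid per cortical parcel on the unit
sphere, a hemisphere label per parcel, and optional system-label schemes
(functional networks, cytoarchitectonic classes).  Real parcellations such as
the 308-parcel subdivision of the Desikan-Killiany atlas can be loaded from a
TSV; :func:`make_atlas` builds a synthetic stand-in with the same contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))

__all__ = ["ParcelAtlas", "make_atlas", "read_atlas_tsv"]


@dataclass(frozen=True)
class ParcelAtlas:
    """Parcel centroids on the unit sphere plus hemisphere and system labels.

    Parameters
    ----------
    region_ids : ndarray of int
        1-based, contiguous, unique parcel identifiers.
    hemispheres : ndarray of str
        ``"L"`` or ``"R"`` per parcel.
    centroids : ndarray, shape (n_regions, 3)
        Unit-norm centroid per parcel (dimensionless spherical frame).
    system_labels : dict of str -> ndarray of int
        Optional labelling schemes, e.g. ``"yeo7"`` / ``"veconomo"``;
        each maps every parcel to an integer system id.
    """

    region_ids: np.ndarray
    hemispheres: np.ndarray
    centroids: np.ndarray
    system_labels: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        rid = np.asarray(self.region_ids, dtype=int)
        hemi = np.asarray(self.hemispheres, dtype=object)
        cen = np.asarray(self.centroids, dtype=float)
        object.__setattr__(self, "region_ids", rid)
        object.__setattr__(self, "hemispheres", hemi)
        object.__setattr__(self, "centroids", cen)
        if rid.ndim != 1 or len(np.unique(rid)) != rid.size:
            raise ValueError("region_ids must be a 1-D array of unique ids")
        if cen.shape != (rid.size, 3):
            raise ValueError("centroids must have shape (n_regions, 3)")
        norms = np.linalg.norm(cen, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("centroids must lie on the unit sphere (|norm-1| <= 1e-9)")
        for h in ("L", "R"):
            if not np.any(hemi == h):
                raise ValueError(f"hemisphere {h!r} is empty")
        for scheme, lab in self.system_labels.items():
            if np.asarray(lab).shape != rid.shape:
                raise ValueError(f"system labels {scheme!r} do not match regions")

    # -- basic queries -----------------------------------------------------

    @property
    def n_regions(self) -> int:
        return int(self.region_ids.size)

    def hemisphere_mask(self, hemisphere: str) -> np.ndarray:
        return self.hemispheres == hemisphere

    @property
    def left_region_ids(self) -> np.ndarray:
        return self.region_ids[self.hemisphere_mask("L")]

    def index_of(self, region_ids: np.ndarray) -> np.ndarray:
        """Positional indices of the given region ids."""
        lookup = {int(r): i for i, r in enumerate(self.region_ids)}
        try:
            return np.array([lookup[int(r)] for r in np.atleast_1d(region_ids)])
        except KeyError as exc:  # pragma: no cover - message path
            raise KeyError(f"region id {exc} not in atlas") from exc

    def geodesic_distances(self, hemisphere: str | None = None) -> np.ndarray:
        """Great-circle distance matrix (radians) between parcel centroids."""
        cen = self.centroids
        if hemisphere is not None:
            cen = cen[self.hemisphere_mask(hemisphere)]
        dot = np.clip(cen @ cen.T, -1.0, 1.0)
        return np.arccos(dot)

    # -- I/O ---------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "region_id": self.region_ids,
                "hemisphere": self.hemispheres,
                "cx": self.centroids[:, 0],
                "cy": self.centroids[:, 1],
                "cz": self.centroids[:, 2],
            }
        )
        for scheme, lab in self.system_labels.items():
            df[scheme] = lab
        return df

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_atlas_tsv(path) -> ParcelAtlas:
    """Load an atlas table (region_id, hemisphere, cx, cy, cz, schemes...)."""
    df = pd.read_csv(path, sep="\t")
    base = {"region_id", "hemisphere", "cx", "cy", "cz"}
    schemes = [c for c in df.columns if c not in base]
    return ParcelAtlas(
        region_ids=df["region_id"].to_numpy(),
        hemispheres=df["hemisphere"].to_numpy(dtype=object),
        centroids=df[["cx", "cy", "cz"]].to_numpy(float),
        system_labels={s: df[s].to_numpy(int) for s in schemes},
    )


def _hemisphere_lattice(n: int, sign: float) -> np.ndarray:
    """Quasi-uniform Fibonacci-style lattice on the hemisphere sign(x)=sign."""
    i = np.arange(n)
    x = sign * (1.0 - (i + 0.5) / n)  # |x| from ~1 down to ~0: pole to equator
    r = np.sqrt(np.maximum(0.0, 1.0 - x * x))
    phi = GOLDEN_ANGLE * i
    return np.column_stack([x, r * np.cos(phi), r * np.sin(phi)])


def make_atlas(n_per_hemisphere: int, n_systems: int = 7, seed: int = 0) -> ParcelAtlas:
    """Build a synthetic two-hemisphere spherical parcellation.

    Left-hemisphere centroids are laid out on a deterministic quasi-uniform
    (Fibonacci) lattice over the ``x < 0`` hemisphere; right-hemisphere
    centroids are their mirror images (``x -> -x``).  System labels are
    assigned by contiguous latitude (``z``) bands: ``n_systems`` bands for
    the functional scheme (``"yeo7"``) and five for the cytoarchitectonic
    scheme (``"veconomo"``).

    The layout is fully deterministic; ``seed`` is accepted for interface
    symmetry with the other generators.
    """
    if n_per_hemisphere < 4:
        raise ValueError("n_per_hemisphere must be >= 4")
    if n_systems < 1:
        raise ValueError("n_systems must be >= 1")
    left = _hemisphere_lattice(n_per_hemisphere, sign=-1.0)
    right = left * np.array([-1.0, 1.0, 1.0])
    centroids = np.vstack([left, right])
    centroids /= np.linalg.norm(centroids, axis=1, keepdims=True)
    n = 2 * n_per_hemisphere
    hemis = np.array(["L"] * n_per_hemisphere + ["R"] * n_per_hemisphere, dtype=object)

    def latitude_bands(k: int) -> np.ndarray:
        z = centroids[:, 2]
        edges = np.quantile(z, np.linspace(0, 1, k + 1)[1:-1]) if k > 1 else []
        return np.digitize(z, edges) + 1  # labels 1..k

    labels = {"yeo7": latitude_bands(n_systems), "veconomo": latitude_bands(5)}
    return ParcelAtlas(
        region_ids=np.arange(1, n + 1),
        hemispheres=hemis,
        centroids=centroids,
        system_labels=labels,
    )
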