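"""Geography: great-circle distances and a Mantel test.

Quantifies isolation by distance: whether genetic distances between
accessions increase with the great-circle distance between their collection
sites.  The Mantel statistic is the Pearson correlation over upper-triangle
entries, tested one-sided (positive association) by jointly permuting rows
and columns of one matrix.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

__all__ = [
    "EARTH_RADIUS_KM",
    "CollectionSite",
    "haversine",
    "geographic_distance_matrix",
    "mantel",
    "MantelResult",
]

EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class CollectionSite:
    sample: str
    latitude: float
    longitude: float

    def __post_init__(self) -> None:
        if not (abs(self.latitude) <= 90 and abs(self.longitude) <= 180):
            raise ValueError(
                f"invalid coordinates for {self.sample}: ({self.latitude}, {self.longitude})"
            )


def haversine(a, b) -> float:
    """Great-circle distance in km between two collection sites (WGS84 degrees)."""
    if isinstance(a, tuple):
        a = CollectionSite("a", *a)
    if isinstance(b, tuple):
        b = CollectionSite("b", *b)
    lat1, lon1, lat2, lon2 = map(
        np.radians, (a.latitude, a.longitude, b.latitude, b.longitude)
    )
    h = (
        np.sin((lat2 - lat1) / 2) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    )
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h)))


def geographic_distance_matrix(metadata: pd.DataFrame) -> DistanceMatrix:
    """Pairwise haversine distances from a (sample, lat, lon) table."""
    samples = list(metadata["sample"].astype(str))
    lat = np.radians(metadata["lat"].to_numpy(dtype=float))
    lon = np.radians(metadata["lon"].to_numpy(dtype=float))
    if np.any(np.abs(metadata["lat"].to_numpy(dtype=float)) > 90) or np.any(
        np.abs(metadata["lon"].to_numpy(dtype=float)) > 180
    ):
        raise ValueError("invalid coordinates in metadata")
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = np.sin(dlat / 2) ** 2 + np.cos(lat[:, None]) * np.cos(lat[None, :]) * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    return DistanceMatrix(d, ids=samples)


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_perm: int
    seed: int | None
    n: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def mantel(dgen, dgeo, n_perm: int = 999, seed: int | None = None) -> MantelResult:
    """One-sided Mantel test of positive association between two distance matrices.

    r is the Pearson correlation over strict upper-triangle entries;
    p = (1 + #{permuted r >= observed r}) / (1 + n_perm), with permutations
    relabelling rows and columns of the genetic matrix jointly.  A constant
    matrix has undefined r, reported as NaN.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if isinstance(dgen, DistanceMatrix) and isinstance(dgeo, DistanceMatrix):
        if set(dgen.ids) != set(dgeo.ids):
            raise ValueError("distance matrices cover different samples")
        dgeo = dgeo.filter(dgen.ids)  # align orders
    G = np.asarray(dgen.data if isinstance(dgen, DistanceMatrix) else dgen, dtype=float)
    H = np.asarray(dgeo.data if isinstance(dgeo, DistanceMatrix) else dgeo, dtype=float)
    if G.shape != H.shape or G.shape[0] != G.shape[1]:
        raise ValueError("matrices must be square and of equal size")
    n = G.shape[0]
    iu = np.triu_indices(n, k=1)
    g, h = G[iu], H[iu]
    if g.std() == 0 or h.std() == 0:
        return MantelResult(float("nan"), float("nan"), n_perm, seed, n)
    zg = (g - g.mean()) / g.std()
    zh = (h - h.mean()) / h.std()
    m = g.size
    r_obs = float(zg @ zh / m)
    # permuting rows/columns jointly only rearranges the same multiset of
    # off-diagonal values, so the permuted mean/std equal the observed ones
    rng = np.random.default_rng(seed)
    count = 0
    done = 0
    chunk = max(1, min(n_perm, int(5e7 // max(g.size, 1))))
    iu0, iu1 = iu
    while done < n_perm:
        k = min(chunk, n_perm - done)
        perms = np.argsort(rng.random((k, n)), axis=1)
        gp = G[perms[:, iu0], perms[:, iu1]]  # (k, m) permuted upper triangles
        r_perm = ((gp - g.mean()) / g.std()) @ zh / m
        count += int((r_perm >= r_obs).sum())
        done += k
    p = (1 + count) / (1 + n_perm)
    return MantelResult(r_obs, p, n_perm, seed, n)
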