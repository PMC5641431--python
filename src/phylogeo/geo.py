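"""Geographic pipeline: species centroids, ecoregion assignment,
curvature-aware distance matrices, neighbor joining, range areas and
short-range-endemism classes, and geographic constraint sets.

Distances are great-circle (haversine) kilometres on a sphere of mean radius
R = 6371.0088 km. Species centroids are normalized means of unit vectors on
the sphere, which behave correctly across the antimeridian. Range areas are
convex hulls of the locality cloud measured in a Lambert azimuthal
equal-area projection centred on the species centroid, so hull areas are
faithful to the spherical geometry at regional scales.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Point, Polygon, shape

from .core import ConstraintSet, PhylogeoError, Tree, TreeNode

__all__ = [
    "EARTH_RADIUS_KM",
    "LocalityRecord",
    "RegionMap",
    "DistanceMatrix",
    "read_localities",
    "species_centroid",
    "great_circle_km",
    "euclidean_km",
    "assign_region",
    "distance_matrix",
    "nj_tree",
    "ecoregion_distance_tree",
    "range_area_km2",
    "endemism_class",
    "endemism_table",
]

log = logging.getLogger("phylogeo.geo")

EARTH_RADIUS_KM = 6371.0088

SRE_KM2 = 10_000.0   # short-range endemic threshold (strict less-than)
MRE_KM2 = 1_000.0    # micro-range endemic threshold (strict less-than)


@dataclass(frozen=True)
class LocalityRecord:
    species: str
    lat: float
    lon: float

    def __post_init__(self):
        if not -90 <= self.lat <= 90:
            raise ValueError(f"latitude {self.lat} out of range for {self.species}")
        if not -180 <= self.lon <= 180:
            raise ValueError(f"longitude {self.lon} out of range for {self.species}")


def read_localities(path) -> list:
    """CSV with columns species, decimal_latitude, decimal_longitude."""
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        cols = {c.lower(): c for c in reader.fieldnames or []}

        def pick(*names):
            for n in names:
                if n in cols:
                    return cols[n]
            raise PhylogeoError(f"locality CSV lacks a column among {names}")

        sp = pick("species", "taxon")
        la = pick("decimal_latitude", "latitude", "lat")
        lo = pick("decimal_longitude", "longitude", "lon")
        for row in reader:
            out.append(LocalityRecord(row[sp].strip(),
                                      float(row[la]), float(row[lo])))
    if not out:
        raise PhylogeoError(f"no locality records in {path}")
    return out


def write_localities(records, path):
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["species", "decimal_latitude", "decimal_longitude"])
        for r in records:
            w.writerow([r.species, f"{r.lat:.6f}", f"{r.lon:.6f}"])


class RegionMap:
    """Named valid polygons in lon/lat (GeoJSON axis order)."""

    def __init__(self, polygons: dict):
        if len(set(polygons)) != len(polygons):
            raise PhylogeoError("duplicate region names")
        for name, poly in polygons.items():
            if not poly.is_valid:
                raise PhylogeoError(f"region polygon {name!r} is invalid")
        self.polygons = dict(polygons)

    def __len__(self):
        return len(self.polygons)

    @property
    def names(self):
        return list(self.polygons)

    @classmethod
    def from_geojson(cls, path) -> "RegionMap":
        with open(path) as fh:
            gj = json.load(fh)
        polys = {}
        feats = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
        for i, feat in enumerate(feats):
            name = (feat.get("properties") or {}).get("name", f"region_{i}")
            polys[name] = shape(feat["geometry"])
        return cls(polys)

    def to_geojson(self, path):
        feats = []
        for name, poly in self.polygons.items():
            feats.append({"type": "Feature", "properties": {"name": name},
                          "geometry": poly.__geo_interface__})
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)

    @classmethod
    def grid(cls, lon0, lat0, lon1, lat1, nx, ny, prefix="R") -> "RegionMap":
        """Rectangular grid of regions (test stand-in for ecoregion polygons)."""
        polys = {}
        xs = np.linspace(lon0, lon1, nx + 1)
        ys = np.linspace(lat0, lat1, ny + 1)
        for i in range(nx):
            for j in range(ny):
                polys[f"{prefix}{i}{j}"] = Polygon([
                    (xs[i], ys[j]), (xs[i + 1], ys[j]),
                    (xs[i + 1], ys[j + 1]), (xs[i], ys[j + 1])])
        return cls(polys)


# ---------------------------------------------------------------------------
# Spherical geometry
# ---------------------------------------------------------------------------

def _unit_vector(lat, lon):
    la, lo = math.radians(lat), math.radians(lon)
    return np.array([math.cos(la) * math.cos(lo),
                     math.cos(la) * math.sin(lo),
                     math.sin(la)])


def species_centroid(records) -> tuple[float, float]:
    """(lat, lon) of the normalized mean unit vector of the localities."""
    if not records:
        raise PhylogeoError("species has no locality records")
    v = np.mean([_unit_vector(r.lat, r.lon) for r in records], axis=0)
    norm = np.linalg.norm(v)
    if norm < 1e-9:
        raise PhylogeoError("degenerate (antipodal) locality cloud: "
                            "mean vector has no direction")
    v = v / norm
    lat = math.degrees(math.asin(np.clip(v[2], -1, 1)))
    lon = math.degrees(math.atan2(v[1], v[0]))
    return lat, lon


def great_circle_km(a, b) -> float:
    """Haversine distance in km between (lat, lon) pairs."""
    la1, lo1 = map(math.radians, a)
    la2, lo2 = map(math.radians, b)
    dla, dlo = la2 - la1, lo2 - lo1
    h = math.sin(dla / 2) ** 2 + math.cos(la1) * math.cos(la2) * math.sin(dlo / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def euclidean_km(a, b) -> float:
    """Flat-Earth chordal approximation (sensitivity-analysis alternative)."""
    la = math.radians((a[0] + b[0]) / 2)
    dy = (a[0] - b[0]) * 111.194927
    dx = (a[1] - b[1]) * 111.194927 * math.cos(la)
    return math.hypot(dx, dy)


def assign_region(centroid, regions: RegionMap) -> str:
    """Containing region name; boundary ties go to the lexicographically first
    region; a centroid outside the map is assigned the nearest polygon and
    logged."""
    if len(regions) == 0:
        raise PhylogeoError("empty region map")
    lat, lon = centroid
    pt = Point(lon, lat)
    hits = sorted(name for name, poly in regions.polygons.items()
                  if poly.covers(pt))
    if hits:
        return hits[0]
    best = min(sorted(regions.polygons),
               key=lambda n: regions.polygons[n].distance(pt))
    log.warning("centroid (%.4f, %.4f) outside all regions; "
                "assigned nearest region %r", lat, lon, best)
    return best


# ---------------------------------------------------------------------------
# Distance matrices and neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    labels: list
    matrix: np.ndarray  # km, symmetric, zero diagonal

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise PhylogeoError("distance matrix shape does not match labels")
        if np.abs(self.matrix - self.matrix.T).max() > 1e-9:
            raise PhylogeoError("distance matrix is asymmetric beyond tolerance")
        if np.abs(np.diag(self.matrix)).max() > 1e-12:
            raise PhylogeoError("distance matrix diagonal is non-zero")
        if (self.matrix < 0).any():
            raise PhylogeoError("negative distances")

    def to_tsv(self, path):
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.matrix):
                fh.write(lab + "\t" + "\t".join(f"{x:.6f}" for x in row) + "\n")

    def to_phylip(self, path):
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for lab, row in zip(self.labels, self.matrix):
                fh.write(f"{lab:<12}" + " ".join(f"{x:.6f}" for x in row) + "\n")


def distance_matrix(points: dict, metric=great_circle_km) -> DistanceMatrix:
    """Pairwise distances between named (lat, lon) points."""
    labels = list(points)
    n = len(labels)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = metric(points[labels[i]], points[labels[j]])
    return DistanceMatrix(labels, m)


def nj_tree(d: DistanceMatrix) -> Tree:
    """Neighbor joining with the Q-criterion.

    Ties are broken by the lowest index pair; negative branch-length
    estimates are clamped to zero with the deficit pushed onto the sibling
    edge, preserving the path length between the joined pair.
    """
    n = len(d.labels)
    if n < 3:
        raise PhylogeoError("neighbor joining needs >= 3 labels")
    D = d.matrix.astype(float).copy()
    nodes = [TreeNode(label=lab) for lab in d.labels]
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest-index tie-break: argmin scans row-major
        fi, fj = divmod(int(np.argmin(Q)), m)
        if fi > fj:
            fi, fj = fj, fi
        i, j = active[fi], active[fj]
        dij = D[i, j]
        vi = 0.5 * dij + (r[fi] - r[fj]) / (2 * (m - 2))
        vj = dij - vi
        if vi < 0:
            vj, vi = vj + vi, 0.0
        if vj < 0:
            vi, vj = vi + vj, 0.0
        parent = TreeNode()
        a, b = nodes[i], nodes[j]
        a.length, b.length = max(vi, 0.0), max(vj, 0.0)
        parent.add_child(a)
        parent.add_child(b)
        # distances from the new node
        new_row = 0.5 * (D[i, :] + D[j, :] - dij)
        D = np.vstack([D, new_row])
        D = np.column_stack([D, np.append(new_row, 0.0)])
        nodes.append(parent)
        active = [x for x in active if x not in (i, j)] + [len(nodes) - 1]
    root = TreeNode()
    if len(active) == 3:
        i, j, k = active
        # closed-form terminal branch lengths
        li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
        lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
        lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        for idx, ln in zip((i, j, k), (li, lj, lk)):
            nodes[idx].length = max(ln, 0.0)
            root.add_child(nodes[idx])
    else:  # exactly 2 remain (possible for n == 3 inputs is handled above)
        i, j = active
        nodes[i].length = D[i, j] / 2
        nodes[j].length = D[i, j] / 2
        root.add_child(nodes[i])
        root.add_child(nodes[j])
    return Tree(root, rooted=False)


# ---------------------------------------------------------------------------
# Ecoregion distance tree and constraints
# ---------------------------------------------------------------------------

def ecoregion_distance_tree(records, regions: RegionMap,
                            metric=great_circle_km):
    """NJ tree over occupied ecoregions plus per-region monophyly constraints.

    Species centroids are assigned to regions; each region's centroid is the
    spherical centroid of its member species' centroids; the NJ tree is built
    on the region-centroid distance matrix. The constraint set holds one
    monophyly constraint per region with >= 2 species (disjoint by
    construction, hence always compatible).
    """
    by_species: dict = {}
    for r in records:
        by_species.setdefault(r.species, []).append(r)
    members: dict = {}
    cent_of: dict = {}
    for sp, recs in sorted(by_species.items()):
        c = species_centroid(recs)
        cent_of[sp] = c
        members.setdefault(assign_region(c, regions), []).append(sp)
    if len(members) < 3:
        raise PhylogeoError(
            f"only {len(members)} occupied region(s); neighbor joining "
            "needs at least 3")
    region_centroids = {
        reg: species_centroid([LocalityRecord(reg, *cent_of[sp])
                               for sp in sps])
        for reg, sps in sorted(members.items())}
    dmat = distance_matrix(region_centroids, metric)
    tree = nj_tree(dmat)
    cset = ConstraintSet("EDT", [frozenset(sps) for sps in members.values()
                                 if len(sps) >= 2])
    return tree, cset, members


# ---------------------------------------------------------------------------
# Range areas and endemism
# ---------------------------------------------------------------------------

def _laea_xy(lat, lon, lat0, lon0):
    """Spherical Lambert azimuthal equal-area projection (km) about (lat0, lon0)."""
    phi, lam = math.radians(lat), math.radians(lon)
    phi0, lam0 = math.radians(lat0), math.radians(lon0)
    c = (1 + math.sin(phi0) * math.sin(phi)
         + math.cos(phi0) * math.cos(phi) * math.cos(lam - lam0))
    if c <= 1e-12:
        raise PhylogeoError("locality antipodal to projection centre")
    k = math.sqrt(2.0 / c)
    x = EARTH_RADIUS_KM * k * math.cos(phi) * math.sin(lam - lam0)
    y = EARTH_RADIUS_KM * k * (math.cos(phi0) * math.sin(phi)
                               - math.sin(phi0) * math.cos(phi)
                               * math.cos(lam - lam0))
    return x, y


def range_area_km2(records) -> float:
    """Convex-hull range area in km2 (0 for < 3 distinct localities)."""
    if not records:
        raise PhylogeoError("no locality records")
    pts = sorted({(r.lat, r.lon) for r in records})
    if len(pts) < 3:
        return 0.0
    lat0, lon0 = species_centroid(records)
    xy = [_laea_xy(la, lo, lat0, lon0) for la, lo in pts]
    hull = Polygon(xy).convex_hull
    return float(hull.area) if hull.geom_type == "Polygon" else 0.0


def endemism_class(area_km2: float) -> str:
    """MRE (< 1,000 km2), SRE (< 10,000 km2), else widespread.

    MRE is nested inside SRE: every MRE also qualifies as an SRE in summary
    counts.
    """
    if area_km2 < 0:
        raise ValueError("area must be non-negative")
    if area_km2 < MRE_KM2:
        return "MRE"
    if area_km2 < SRE_KM2:
        return "SRE"
    return "widespread"


def endemism_table(records) -> "object":
    """Per-species range area and endemism class as a DataFrame."""
    import pandas as pd
    by_species: dict = {}
    for r in records:
        by_species.setdefault(r.species, []).append(r)
    rows = []
    for sp, recs in sorted(by_species.items()):
        area = range_area_km2(recs)
        cls = endemism_class(area)
        rows.append({"species": sp, "n_localities": len(recs),
                     "area_km2": area, "class": cls,
                     "sre_qualifying": area < SRE_KM2})
    return pd.DataFrame(rows)
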