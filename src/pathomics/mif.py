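"""Quantitative and spatial multiplex-immunofluorescence (mIF) analysis.

Cells arrive as a table of nuclear-center coordinates in micrometres plus
boolean marker calls (the upstream imaging software's binarized signals are
an input contract here). This module calls immune phenotypes from marker
colocalization, partitions the field into tumor nest (TN), invasive margin
(IM, a 500 µm band on each side of the annotated tumor border) and normal
tissue (NLT), and computes per-region densities, Dunn's multiple
comparisons, nearest-neighbor proximity with a 300 µm elimination rule, and
inter-phenotype density correlations.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree
from shapely.geometry import LineString, Point, Polygon

# ---------------------------------------------------------------------------
# Phenotype calling
# ---------------------------------------------------------------------------

#: Phenotype definitions by marker colocalization, evaluated in priority
#: order (most specific first). A cell takes the first matching label:
#: Treg before CD4+T (CD3+CD4+FOXP3+ also satisfies CD3+CD4+), NK requires
#: CD3−, the CD11b+CD68+ double-positive class precedes monocyte and
#: macrophage, and the single-marker classes come last.
PHENOTYPE_RULES: tuple[tuple[str, dict[str, bool]], ...] = (
    ("Treg", {"CD3": True, "CD4": True, "FOXP3": True}),
    ("NK", {"CD3": False, "CD16": True, "CD56": True}),
    ("NKT", {"CD3": True, "CD56": True}),
    ("CD8T", {"CD3": True, "CD8": True}),
    ("CD4T", {"CD3": True, "CD4": True}),
    ("CD11b_CD68", {"CD11b": True, "CD68": True}),
    ("Macrophage", {"CD68": True}),
    ("Monocyte", {"CD11b": True}),
    ("cDC", {"CD11c": True}),
    ("B", {"CD20": True}),
    ("Neutrophil", {"MPO": True}),
    ("MemoryT", {"CD45RO": True}),
)

#: Markers the rule list consults; a cell table must provide all of them.
REQUIRED_MARKERS: tuple[str, ...] = tuple(
    sorted({m for _, rule in PHENOTYPE_RULES for m in rule})
)

PHENOTYPES: tuple[str, ...] = tuple(name for name, _ in PHENOTYPE_RULES) + ("other",)

CHECKPOINT_MARKERS: tuple[str, ...] = ("PD-1", "PD-L1", "TIM-3", "LAG-3", "CTLA-4", "IDO")


def call_phenotype(markers: dict[str, bool]) -> str:
    """Label a cell from its boolean marker calls; unmatched cells → 'other'."""
    missing = [m for m in REQUIRED_MARKERS if m not in markers]
    if missing:
        raise KeyError(f"missing required marker(s): {', '.join(missing)}")
    for name, rule in PHENOTYPE_RULES:
        if all(bool(markers[m]) == want for m, want in rule.items()):
            return name
    return "other"


def markers_for_phenotype(phenotype: str) -> dict[str, bool]:
    """Canonical marker profile whose call round-trips to ``phenotype``.

    Starts from the all-negative profile and switches on exactly the
    markers the phenotype's rule requires (NK additionally keeps CD3
    negative). 'other' is the all-negative profile.
    """
    profile = {m: False for m in REQUIRED_MARKERS}
    if phenotype == "other":
        return profile
    for name, rule in PHENOTYPE_RULES:
        if name == phenotype:
            for m, want in rule.items():
                profile[m] = want
            return profile
    raise ValueError(f"unknown phenotype {phenotype!r}")


def call_phenotypes(cells: pd.DataFrame) -> pd.DataFrame:
    """Vectorized phenotype calling over a cell table (adds 'phenotype')."""
    missing = [m for m in REQUIRED_MARKERS if m not in cells.columns]
    if missing:
        raise KeyError(f"missing required marker column(s): {', '.join(missing)}")
    out = cells.copy()
    labels = np.full(len(cells), "other", dtype=object)
    unassigned = np.ones(len(cells), dtype=bool)
    for name, rule in PHENOTYPE_RULES:
        match = unassigned.copy()
        for m, want in rule.items():
            match &= cells[m].to_numpy(dtype=bool) == want
        labels[match] = name
        unassigned &= ~match
    out["phenotype"] = labels
    return out


# ---------------------------------------------------------------------------
# Tumor-border annotation and TN / IM / NLT partition
# ---------------------------------------------------------------------------


@dataclass
class BorderAnnotation:
    """Manually annotated tumor border in µm.

    Open polylines carry a ``tumor_side`` flag ('left'/'right' relative to
    the vertex direction); closed polygons take their interior as tumor.
    """

    coords: list[tuple[float, float]]
    tumor_side: str = "right"
    closed: bool = False

    def __post_init__(self):
        if len(self.coords) < 2:
            raise ValueError("border needs at least two vertices")
        if LineString(self.coords).length == 0:
            raise ValueError("degenerate border: zero length")
        if not self.closed and self.tumor_side not in ("left", "right"):
            raise ValueError("tumor_side must be 'left' or 'right'")

    def geometry(self):
        if self.closed:
            return Polygon(self.coords)
        return LineString(self.coords)

    def to_geojson(self) -> dict:
        geom_type = "Polygon" if self.closed else "LineString"
        coords = [list(map(list, self.coords))] if self.closed else list(
            map(list, self.coords)
        )
        return {
            "type": "Feature",
            "geometry": {"type": geom_type, "coordinates": coords},
            "properties": {"tumor_side": self.tumor_side, "units": "um"},
        }

    @classmethod
    def from_geojson(cls, obj: dict) -> "BorderAnnotation":
        geom = obj["geometry"]
        closed = geom["type"] == "Polygon"
        coords = geom["coordinates"][0] if closed else geom["coordinates"]
        return cls(
            coords=[tuple(c) for c in coords],
            tumor_side=obj.get("properties", {}).get("tumor_side", "right"),
            closed=closed,
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_geojson(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "BorderAnnotation":
        with open(path) as fh:
            return cls.from_geojson(json.load(fh))


@dataclass
class RegionPartition:
    border: BorderAnnotation
    margin_width_um: float = 500.0
    field_bounds: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    region_areas_mm2: dict[str, float] = field(default_factory=dict)


def _polyline_side(border: BorderAnnotation, x: float, y: float) -> int:
    """+1 on the tumor side of an open polyline, -1 otherwise.

    The side is taken at the nearest border segment via the cross product of
    the segment direction with the offset to the point.
    """
    pts = np.asarray(border.coords, dtype=float)
    p = np.array([x, y])
    best_d2, best_cross = math.inf, 0.0
    for a, b in zip(pts[:-1], pts[1:]):
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0:
            continue
        t = float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
        proj = a + t * ab
        d2 = float(((p - proj) ** 2).sum())
        if d2 < best_d2 - 1e-12:
            best_d2 = d2
            best_cross = float(ab[0] * (p[1] - a[1]) - ab[1] * (p[0] - a[0]))
    left = best_cross > 0
    on_tumor = left if border.tumor_side == "left" else not left
    return 1 if on_tumor else -1


def partition_regions(
    cells: pd.DataFrame,
    border: BorderAnnotation,
    margin_width_um: float = 500.0,
    field_bounds: tuple[float, float, float, float] | None = None,
) -> tuple[pd.DataFrame, RegionPartition]:
    """Label each cell TN / IM / NLT by distance to the tumor border.

    A cell is IM iff its Euclidean distance to the border is at most the
    margin width (default 500 µm, applied on each side of the interface);
    otherwise TN on the tumor side, NLT on the normal side. Region areas
    (mm²) are estimated over the field bounds by intersecting shapely
    buffers, for downstream density computation.
    """
    geom = border.geometry()
    boundary = geom.exterior if border.closed else geom
    xs = cells["x_um"].to_numpy(dtype=float)
    ys = cells["y_um"].to_numpy(dtype=float)

    dist = np.array([boundary.distance(Point(x, y)) for x, y in zip(xs, ys)])
    if border.closed:
        inside = np.array([geom.contains(Point(x, y)) or geom.touches(Point(x, y))
                           for x, y in zip(xs, ys)])
        side = np.where(inside, 1, -1)
    else:
        side = np.array([_polyline_side(border, x, y) for x, y in zip(xs, ys)])

    labels = np.where(dist <= margin_width_um, "IM",
                      np.where(side > 0, "TN", "NLT"))
    out = cells.copy()
    out["region"] = labels
    out["border_distance_um"] = dist

    if field_bounds is None:
        pad = margin_width_um
        field_bounds = (
            float(xs.min() - pad) if len(xs) else 0.0,
            float(ys.min() - pad) if len(ys) else 0.0,
            float(xs.max() + pad) if len(xs) else pad,
            float(ys.max() + pad) if len(ys) else pad,
        )
    x0, y0, x1, y1 = field_bounds
    field_poly = Polygon([(x0, y0), (x1, y0), (x1, y1), (x0, y1)])
    band = boundary.buffer(margin_width_um)
    im_area = field_poly.intersection(band).area
    if border.closed:
        tumor_poly = geom
    else:
        # tumor half-plane approximated by splitting the field with the
        # polyline extended across the bounds; for density purposes sample
        # on a grid when the polyline is not straight
        tumor_poly = None
    if tumor_poly is not None:
        tn_area = field_poly.intersection(tumor_poly).difference(band).area
        nlt_area = field_poly.difference(tumor_poly).difference(band).area
    else:
        tn_area, nlt_area = _halfplane_areas(field_poly, border, margin_width_um)
    areas = {
        "TN": tn_area / 1e6,
        "IM": im_area / 1e6,
        "NLT": nlt_area / 1e6,
    }
    part = RegionPartition(
        border=border,
        margin_width_um=margin_width_um,
        field_bounds=field_bounds,
        region_areas_mm2=areas,
    )
    return out, part


def _halfplane_areas(field_poly, border, margin_width_um, n_grid: int = 120):
    """Monte-Carlo-free grid estimate of TN/NLT areas for open polylines."""
    x0, y0, x1, y1 = field_poly.bounds
    gx = np.linspace(x0, x1, n_grid, endpoint=False) + (x1 - x0) / (2 * n_grid)
    gy = np.linspace(y0, y1, n_grid, endpoint=False) + (y1 - y0) / (2 * n_grid)
    cell_area = (x1 - x0) * (y1 - y0) / (n_grid * n_grid)
    line = LineString(border.coords)
    tn = nlt = 0.0
    for x in gx:
        for y in gy:
            if line.distance(Point(x, y)) <= margin_width_um:
                continue
            if _polyline_side(border, x, y) > 0:
                tn += cell_area
            else:
                nlt += cell_area
    return tn, nlt


# ---------------------------------------------------------------------------
# Densities and group statistics
# ---------------------------------------------------------------------------


def region_density(
    cells: pd.DataFrame, partition: RegionPartition, phenotype: str
) -> dict[str, float | None]:
    """Cells/mm² of one phenotype in each region (None if area is zero)."""
    out: dict[str, float | None] = {}
    for region in ("TN", "IM", "NLT"):
        area = partition.region_areas_mm2.get(region, 0.0)
        if area <= 0:
            out[region] = None
            continue
        n = int(((cells["phenotype"] == phenotype)
                 & (cells["region"] == region)).sum())
        out[region] = n / area
    return out


def dunn_test(
    groups: Sequence[np.ndarray], labels: Sequence[str] | None = None,
    adjust: str = "bonferroni",
) -> pd.DataFrame:
    """Dunn's multiple-comparisons test on ≥2 groups of densities.

    Pools all observations, ranks them (ties → midranks), and compares mean
    ranks pairwise with the tie-corrected normal statistic. P-values are
    Bonferroni-adjusted by default.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least 2 observations")
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    # tie correction: sum over tied groups of (t^3 - t)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts ** 3 - counts).sum()) / (12.0 * (n_total - 1)))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    mean_ranks, sizes, offset = [], [], 0
    for g in groups:
        mean_ranks.append(ranks[offset : offset + len(g)].mean())
        sizes.append(len(g))
        offset += len(g)

    n_pairs = len(groups) * (len(groups) - 1) // 2
    rows = []
    for i, j in combinations(range(len(groups)), 2):
        se = math.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        if adjust == "bonferroni":
            p_adj = min(1.0, p * n_pairs)
        elif adjust == "none":
            p_adj = p
        else:
            raise ValueError(f"unknown adjustment {adjust!r}")
        rows.append({"a": labels[i], "b": labels[j], "z": z, "p": p, "p_adj": p_adj})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Spatial proximity
# ---------------------------------------------------------------------------


@dataclass
class ProximityResult:
    source: str
    target: str
    distances_um: np.ndarray        # per-source nearest distance, all sources
    retained_um: np.ndarray         # distances ≤ max_distance_um
    max_distance_um: float
    mean_um: float | None
    histogram: tuple[np.ndarray, np.ndarray]  # counts, bin edges


def nearest_neighbor(
    cells: pd.DataFrame,
    source: str,
    target: str,
    max_distance_um: float = 300.0,
    bin_width_um: float = 20.0,
) -> ProximityResult:
    """Closest nuclear-center distance from each source cell to any target.

    Distances above ``max_distance_um`` (default 300 µm) are eliminated;
    the mean and histogram are computed over retained distances only.
    """
    src = cells[cells["phenotype"] == source]
    tgt = cells[cells["phenotype"] == target]
    if len(tgt) == 0:
        raise ValueError(f"no target cells of phenotype {target!r}")
    if len(src) == 0:
        empty = np.empty(0)
        return ProximityResult(source, target, empty, empty, max_distance_um,
                               None, (np.zeros(0, dtype=int), np.zeros(1)))
    tree = cKDTree(tgt[["x_um", "y_um"]].to_numpy(dtype=float))
    d, _ = tree.query(src[["x_um", "y_um"]].to_numpy(dtype=float), k=1)
    d = np.asarray(d, dtype=float)
    retained = d[d <= max_distance_um]
    edges = np.arange(0.0, max_distance_um + bin_width_um, bin_width_um)
    counts, edges = np.histogram(retained, bins=edges)
    mean = float(retained.mean()) if len(retained) else None
    return ProximityResult(source, target, d, retained, max_distance_um,
                           mean, (counts, edges))


def density_correlation(
    densities: pd.DataFrame, method: str = "spearman"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise correlation of per-sample phenotype densities.

    ``densities`` is samples × phenotypes. Returns (rho, p) matrices;
    constant columns yield NaN off-diagonals (correlation undefined).
    """
    if len(densities) < 4:
        raise ValueError("need at least 4 samples for density correlation")
    cols = list(densities.columns)
    k = len(cols)
    rho = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    pval = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    for i, j in combinations(range(k), 2):
        x = densities[cols[i]].to_numpy(dtype=float)
        y = densities[cols[j]].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            r = p = np.nan
        elif method == "spearman":
            r, p = stats.spearmanr(x, y)
        elif method == "pearson":
            r, p = stats.pearsonr(x, y)
        else:
            raise ValueError(f"unknown method {method!r}")
        rho.iloc[i, j] = rho.iloc[j, i] = r
        pval.iloc[i, j] = pval.iloc[j, i] = p
    return rho, pval
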