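"""Projected range change and IUCN threat reclassification.

Species with a fitted distribution model are classified from the projected
range-loss fraction ``L = (A_current - A_future) / A_current`` following the
criterion-A3(c)-style rule table:

    EX  L = 1 (100% loss)        CR  0.8 <= L < 1
    EN  0.5 <= L < 0.8           VU  0.3 <= L < 0.5
    NT  0.1 <= L < 0.3           LC  L < 0.1 (including expansions)

Species too data-poor to model (1-3 records) are assessed from record
geometry instead and their baseline category is *elevated*:

* 3 records — by the area of the triangle they enclose: below 100 km^2
  three levels, below 500 km^2 two, below 10,000 km^2 one;
* 2 records — by the great-circle distance between them: below 10 km three
  levels, below 50 km two, below 500 km one;
* 1 record — three levels.

Elevation caps at CR: EX is reserved for demonstrated total range loss.
Data-poor statuses are held constant between the mid- and late-century
horizons (no model, hence no basis for a trend).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .grids import GridSpec, EARTH_RADIUS_KM
from .habitat import BinaryRange


class IUCNCategory(IntEnum):
    """Threat levels in increasing order; DD sits outside the order."""

    LC = 0
    NT = 1
    VU = 2
    EN = 3
    CR = 4
    EX = 5
    DD = -1

    def __str__(self) -> str:  # CSV-friendly
        return self.name


#: Loss-fraction lower bounds for each threatened category (upper-exclusive).
LOSS_THRESHOLDS = ((IUCNCategory.CR, 0.8), (IUCNCategory.EN, 0.5),
                   (IUCNCategory.VU, 0.3), (IUCNCategory.NT, 0.1))

_EX_TOL = 1e-12  # absorb floating-point dust in area sums at L = 1


@dataclass(frozen=True)
class RangeChange:
    species_id: str
    scenario: str
    horizon: str
    area_current_km2: float
    area_future_km2: float

    @property
    def loss_fraction(self) -> float:
        return (self.area_current_km2 - self.area_future_km2) / self.area_current_km2


@dataclass
class StatusAssessment:
    species_id: str
    scenario: str
    horizon: str
    category: IUCNCategory
    path: str                    # model_based | data_poor_{area,distance,single} | dd
    levels_elevated: int = 0
    loss_fraction: float | None = None
    geometry_statistic: float | None = None

    def __post_init__(self) -> None:
        if self.levels_elevated and not self.path.startswith("data_poor"):
            raise ValueError("levels_elevated > 0 requires a data-poor path")


def loss_fraction(current: BinaryRange, future: BinaryRange,
                  species_id: str = "", scenario: str = "",
                  horizon: str = "") -> RangeChange:
    """Geodesic range-loss fraction; negative means expansion."""
    if current.grid != future.grid:
        raise ValueError("ranges on different grids")
    if current.area_km2 <= 0:
        raise ZeroDivisionError(
            "current range empty; species belongs on the data-poor path")
    return RangeChange(species_id, scenario, horizon,
                       current.area_km2, future.area_km2)


def classify_loss(L: float) -> IUCNCategory:
    """Map a projected loss fraction onto the threat ladder."""
    if L > 1.0 + _EX_TOL:
        raise ValueError(f"loss fraction {L} exceeds 1")
    if L >= 1.0 - _EX_TOL:
        return IUCNCategory.EX
    for cat, lo in LOSS_THRESHOLDS:
        if L >= lo:
            return cat
    return IUCNCategory.LC


def distance_km(p1: tuple[float, float], p2: tuple[float, float]) -> float:
    """Great-circle (haversine) distance between (lon, lat) points, km."""
    lon1, lat1 = map(math.radians, p1)
    lon2, lat2 = map(math.radians, p2)
    a = (math.sin((lat2 - lat1) / 2) ** 2
         + math.cos(lat1) * math.cos(lat2) * math.sin((lon2 - lon1) / 2) ** 2)
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def polygon_area_km2(three_points) -> float:
    """Area of the triangle enclosed by three (lon, lat) records.

    Planar shoelace area under an equirectangular projection centered at the
    records' mean latitude — adequate at the sub-continental scales where
    the data-poor area rule bites.  Collinear or duplicate points give 0.
    """
    pts = list(three_points)
    if len(pts) != 3:
        raise ValueError("exactly three points required")
    if len({(round(x, 12), round(y, 12)) for x, y in pts}) < 3:
        import warnings
        warnings.warn("duplicate records in triangle; area 0", stacklevel=2)
        return 0.0
    lat0 = math.radians(sum(p[1] for p in pts) / 3.0)
    km_per_deg = EARTH_RADIUS_KM * math.pi / 180.0
    xy = [(p[0] * km_per_deg * math.cos(lat0), p[1] * km_per_deg) for p in pts]
    (x1, y1), (x2, y2), (x3, y3) = xy
    return abs((x2 - x1) * (y3 - y1) - (x3 - x1) * (y2 - y1)) / 2.0


#: (upper bound, levels) cascades; first matching bound wins.
AREA_CASCADE_KM2 = ((100.0, 3), (500.0, 2), (10_000.0, 1))
DISTANCE_CASCADE_KM = ((10.0, 3), (50.0, 2), (500.0, 1))


def data_poor_levels(n_records: int, geometry: float | None = None) -> int:
    """Elevation levels for a 1-3 record species.

    ``geometry`` is the triangle area (km^2) for 3 records or the pair
    distance (km) for 2; unused for single records.
    """
    if n_records == 1:
        return 3
    if n_records == 2:
        cascade = DISTANCE_CASCADE_KM
    elif n_records == 3:
        cascade = AREA_CASCADE_KM2
    else:
        raise ValueError(f"{n_records} records belong on the model path")
    if geometry is None:
        raise ValueError("geometry statistic required for 2-3 record species")
    for bound, levels in cascade:
        if geometry < bound:
            return levels
    return 0


def elevate(category: IUCNCategory, levels: int) -> IUCNCategory:
    """Move a category up the threat order, capped at CR."""
    if category == IUCNCategory.DD:
        raise ValueError("cannot elevate DD")
    if not (0 <= levels <= 3):
        raise ValueError("levels must be 0-3")
    return IUCNCategory(min(int(category) + levels, int(IUCNCategory.CR)))


def assess_data_poor(species_id: str, records, scenario: str, horizon: str,
                     baseline: IUCNCategory = IUCNCategory.LC) -> StatusAssessment:
    """Geometry-based assessment for a 1-3 record species."""
    pts = [(r.lon, r.lat) for r in records]
    n = len(pts)
    if n == 0:
        return StatusAssessment(species_id, scenario, horizon, IUCNCategory.DD, "dd")
    if n == 1:
        stat, path = None, "data_poor_single"
    elif n == 2:
        stat, path = distance_km(pts[0], pts[1]), "data_poor_distance"
    elif n == 3:
        stat, path = polygon_area_km2(pts), "data_poor_area"
    else:
        raise ValueError(f"{n} records belong on the model path")
    levels = data_poor_levels(n, stat)
    return StatusAssessment(species_id, scenario, horizon,
                            elevate(baseline, levels), path,
                            levels_elevated=levels, geometry_statistic=stat)


def assess_species(species_id: str, scenario: str, horizon: str, *,
                   current_range: BinaryRange | None = None,
                   future_range: BinaryRange | None = None,
                   records=None,
                   baseline: IUCNCategory = IUCNCategory.LC) -> StatusAssessment:
    """Route one species through the model-based or data-poor rule path.

    Model path needs both ranges with nonempty current area; otherwise the
    species falls back to record geometry (1-3 records), and with no usable
    inputs at all is Data Deficient.
    """
    if current_range is not None and future_range is not None \
            and current_range.area_km2 > 0:
        rc = loss_fraction(current_range, future_range, species_id,
                           scenario, horizon)
        return StatusAssessment(species_id, scenario, horizon,
                                classify_loss(rc.loss_fraction), "model_based",
                                loss_fraction=rc.loss_fraction)
    if records:
        if len(records) > 3:
            records = records[:3]  # modeled range vanished; fall back on geometry
        return assess_data_poor(species_id, records, scenario, horizon, baseline)
    return StatusAssessment(species_id, scenario, horizon, IUCNCategory.DD, "dd")


def transition_table(assessments: list[StatusAssessment],
                     baselines: dict[str, IUCNCategory]) -> "np.ndarray":
    """Counts indexed by (category_from, category_to); DD baseline row last.

    Returns a 7x7 integer matrix in the order LC,NT,VU,EN,CR,EX,DD.
    """
    order = [IUCNCategory.LC, IUCNCategory.NT, IUCNCategory.VU, IUCNCategory.EN,
             IUCNCategory.CR, IUCNCategory.EX, IUCNCategory.DD]
    idx = {c: i for i, c in enumerate(order)}
    table = np.zeros((7, 7), dtype=int)
    for a in assessments:
        frm = baselines.get(a.species_id, IUCNCategory.DD)
        table[idx[frm], idx[a.category]] += 1
    return table


TRANSITION_LABELS = ("LC", "NT", "VU", "EN", "CR", "EX", "DD")


@dataclass
class RichnessMap:
    grid: GridSpec
    counts: np.ndarray
    scenario: str
    horizon: str


def one_degree_grid(native: GridSpec) -> GridSpec:
    """The 1-degree grid covering the native grid's extent."""
    west = math.floor(native.west)
    south = math.floor(native.south)
    n_cols = math.ceil(native.east) - west
    n_rows = min(math.ceil(native.north), 90) - south
    return GridSpec(west=float(west), south=float(south), resolution_arcmin=60.0,
                    n_rows=n_rows, n_cols=n_cols)


def _overlap_counts(flags: np.ndarray, native: GridSpec, coarse: GridSpec) -> np.ndarray:
    """Boolean 1-degree occupancy: any overlapping flagged native cell counts."""
    occupied = np.zeros(coarse.shape, dtype=bool)
    res = native.resolution_deg
    rows, cols = np.nonzero(flags)
    for r, c in zip(rows, cols):
        w = native.west + c * res
        e = w + res
        s = native.north - (r + 1) * res
        n = s + res
        c0 = max(int(math.floor(w - coarse.west)), 0)
        c1 = min(int(math.ceil(e - coarse.west)), coarse.n_cols)
        r1 = coarse.n_rows - max(int(math.floor(s - coarse.south)), 0)
        r0 = coarse.n_rows - min(int(math.ceil(n - coarse.south)), coarse.n_rows)
        occupied[r0:r1, c0:c1] = True
    return occupied


def richness_map(binary_ranges: dict[str, BinaryRange],
                 scenario: str = "current", horizon: str = "current",
                 coarse: GridSpec | None = None) -> RichnessMap:
    """Species count per one-degree cell (a species counts in a cell iff any
    flagged native-resolution cell overlaps it)."""
    if not binary_ranges:
        raise ValueError("no ranges given")
    native = next(iter(binary_ranges.values())).grid
    coarse = coarse or one_degree_grid(native)
    counts = np.zeros(coarse.shape, dtype=int)
    for br in binary_ranges.values():
        if br.grid != native:
            raise ValueError("ranges on different grids")
        counts += _overlap_counts(br.flags, native, coarse)
    return RichnessMap(coarse, counts, scenario, horizon)


def richness_change(future: RichnessMap, current: RichnessMap) -> RichnessMap:
    """Signed per-cell change, future minus current."""
    if future.grid != current.grid:
        raise ValueError("richness maps on different grids")
    return RichnessMap(future.grid, future.counts - current.counts,
                       future.scenario, future.horizon)
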