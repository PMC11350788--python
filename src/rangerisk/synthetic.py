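"""Synthetic landscapes and virtual species with known range-change truth.

Every downstream stage of the pipeline (occurrence filtering, maximum-entropy
fitting, natural-breaks binarization, threat classification) is exercised
against species whose climatic niche — and therefore whose true current and
future range, and true range-loss fraction — is known exactly.

The generator emulates the structure of a global bioclimatic study:

* **Climate layers.**  The first variable is a temperature-like surface with
  a strong latitudinal gradient; the second is a precipitation-like surface
  varying longitudinally; further variables mix low-frequency lat/lon
  harmonics with seeded phases.  All layers carry smooth seeded noise.  A
  near-duplicate of an existing layer can be injected to exercise the
  correlation filter.
* **Scenario deltas.**  Future stacks are the current stack plus additive
  per-variable shifts, standing in for GCM projections under emission
  scenarios; defaults approximate mid/high-emission warming by the 2050s and
  2070s (about +1 to +3.7 degrees C, with modest precipitation shifts).
* **Virtual species.**  Suitability is a Gaussian function of climate,
  ``s(x) = exp(-(z-mu)' Sigma^-1 (z-mu) / 2)``, peaking at 1 at the niche
  center.  The true range under any stack is the superlevel set
  ``s >= s_star``; the default threshold ``s_star = 0.1`` treats the full
  tolerable climate envelope as range, matching the inclusive
  (low+medium+high habitability) range definition used downstream.
* **Presences** are drawn cell-wise with probability proportional to current
  suitability and placed at cell centers; 1-3 record species exercise the
  data-poor assessment path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import GridSpec, cell_area_km2
from .climate import ClimateStack
from .occurrences import OccurrenceRecord, OccurrenceSet

DEFAULT_GRID = GridSpec(west=-180.0, south=-90.0, resolution_arcmin=120.0,
                        n_rows=90, n_cols=180)


@dataclass(frozen=True)
class ScenarioDelta:
    """Additive per-variable climate shift defining a future scenario."""

    label: str
    shifts: dict[str, float]


#: Warming magnitudes loosely following CMIP6 global-mean projections for a
#: moderate (SSP2-4.5-like) and a high-emission (SSP5-8.5-like) pathway at
#: the mid- and late-century horizons; precipitation shifts are a few percent
#: of the global mean.
DEFAULT_SCENARIOS: dict[tuple[str, str], dict[str, float]] = {
    ("SSP2-4.5", "2050s"): {"temp": 1.4, "precip": 30.0},
    ("SSP2-4.5", "2070s"): {"temp": 1.9, "precip": 45.0},
    ("SSP5-8.5", "2050s"): {"temp": 2.0, "precip": 40.0},
    ("SSP5-8.5", "2070s"): {"temp": 3.3, "precip": 70.0},
}


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int],
                  sd: float, smoothing: int = 4) -> np.ndarray:
    """Low-frequency noise: white noise on a coarse grid, bilinearly upsampled."""
    if sd == 0:
        return np.zeros(shape)
    coarse = rng.normal(0.0, sd, (shape[0] // smoothing + 2, shape[1] // smoothing + 2))
    rows = np.linspace(0, coarse.shape[0] - 1.001, shape[0])
    cols = np.linspace(0, coarse.shape[1] - 1.001, shape[1])
    r0 = rows.astype(int)
    c0 = cols.astype(int)
    fr = (rows - r0)[:, None]
    fc = (cols - c0)[None, :]
    return ((1 - fr) * (1 - fc) * coarse[np.ix_(r0, c0)]
            + (1 - fr) * fc * coarse[np.ix_(r0, c0 + 1)]
            + fr * (1 - fc) * coarse[np.ix_(r0 + 1, c0)]
            + fr * fc * coarse[np.ix_(r0 + 1, c0 + 1)])


def generate_climate(grid: GridSpec = DEFAULT_GRID, n_variables: int = 2,
                     seed: int = 0, noise_sd: float = 0.5,
                     duplicate_of: str | None = None,
                     duplicate_noise_sd: float = 0.0) -> ClimateStack:
    """Generate a current-scenario climate stack.

    Layers are named ``temp``, ``precip``, ``aux3``, ``aux4``, ...  The
    temperature surface is ``28 - 0.52 * |lat|`` degrees C plus a gentle
    longitudinal harmonic; precipitation is ``1200 + 700 sin(2 pi lon/360)``
    mm plus a latitudinal harmonic.  ``duplicate_of`` appends a layer
    ``<name>_dup`` equal to an existing layer plus white noise of sd
    ``duplicate_noise_sd`` — the fodder for the correlation filter.
    """
    if n_variables < 2:
        raise ValueError("need at least two climate variables")
    rng = np.random.default_rng(seed)
    lat = grid.lat_centers()[:, None]
    lon = grid.lon_centers()[None, :]
    layers: dict[str, np.ndarray] = {}
    layers["temp"] = (28.0 - 0.52 * np.abs(lat) + 1.5 * np.sin(np.radians(2 * lon))
                      + _smooth_noise(rng, grid.shape, noise_sd)) + 0 * lon
    layers["precip"] = (1200.0 + 700.0 * np.sin(np.radians(lon))
                        + 250.0 * np.cos(np.radians(3 * lat))
                        + _smooth_noise(rng, grid.shape, 80.0 * noise_sd)) + 0 * lat
    for k in range(3, n_variables + 1):
        phase_lat, phase_lon = rng.uniform(0, 360, 2)
        amp_lat, amp_lon = rng.uniform(2.0, 8.0, 2)
        layers[f"aux{k}"] = (amp_lat * np.sin(np.radians(k * lat + phase_lat))
                             + amp_lon * np.cos(np.radians(k * lon + phase_lon))
                             + _smooth_noise(rng, grid.shape, noise_sd))
    if duplicate_of is not None:
        if duplicate_of not in layers:
            raise KeyError(f"no layer {duplicate_of!r} to duplicate")
        layers[f"{duplicate_of}_dup"] = (
            layers[duplicate_of] + rng.normal(0.0, duplicate_noise_sd, grid.shape))
    return ClimateStack(grid, layers, scenario="current", horizon="current")


def apply_delta(stack: ClimateStack, delta: ScenarioDelta) -> ClimateStack:
    """Future stack = current stack + per-variable additive shift."""
    unknown = [v for v in delta.shifts if v not in stack.layers]
    if unknown:
        raise KeyError(f"delta names variables absent from stack: {unknown}")
    layers = {name: arr + delta.shifts.get(name, 0.0)
              for name, arr in stack.layers.items()}
    scenario, _, horizon = delta.label.partition("/")
    return ClimateStack(stack.grid, layers, stack.mask.copy(),
                        scenario=scenario, horizon=horizon or scenario)


@dataclass
class VirtualSpecies:
    """A species with a known Gaussian climatic niche.

    ``true_ranges`` maps a scenario label ("current" plus each delta label)
    to the boolean truth range on the climate grid.
    """

    species_id: str
    mu: np.ndarray
    sigma: np.ndarray
    s_star: float
    niche_variables: list[str]
    grid: GridSpec
    true_ranges: dict[str, np.ndarray] = field(default_factory=dict)
    suitability: dict[str, np.ndarray] = field(default_factory=dict)
    n_presences: int = 200

    def suitability_on(self, stack: ClimateStack) -> np.ndarray:
        """Gaussian suitability of every cell under ``stack`` (masked cells 0)."""
        z = np.stack([stack.layers[v] for v in self.niche_variables], axis=-1)
        d = z - self.mu
        prec = np.linalg.inv(self.sigma)
        quad = np.einsum("...i,ij,...j->...", d, prec, d)
        s = np.exp(-0.5 * quad)
        s[stack.mask] = 0.0
        return s


def make_virtual_species(stack: ClimateStack, mu, sigma, s_star: float,
                         species_id: str, n_presences: int = 200,
                         niche_variables: list[str] | None = None,
                         future_stacks: dict[str, ClimateStack] | None = None,
                         ) -> VirtualSpecies:
    """Build a virtual species and its truth ranges under every stack."""
    niche_variables = niche_variables or stack.variable_names
    mu = np.asarray(mu, dtype=float)
    sigma = np.atleast_2d(np.asarray(sigma, dtype=float))
    if mu.size != len(niche_variables):
        raise ValueError("niche center length != number of niche variables")
    if not np.allclose(sigma, sigma.T):
        raise ValueError("niche covariance must be symmetric")
    eigvals = np.linalg.eigvalsh(sigma)
    if eigvals.min() <= 0:
        raise np.linalg.LinAlgError("niche covariance must be positive definite")
    if not (0.0 < s_star < 1.0):
        raise ValueError("suitability threshold must lie strictly inside (0, 1)")
    vs = VirtualSpecies(species_id, mu, sigma, s_star, list(niche_variables),
                        stack.grid, n_presences=n_presences)
    vs.suitability["current"] = vs.suitability_on(stack)
    vs.true_ranges["current"] = vs.suitability["current"] >= s_star
    for label, fut in (future_stacks or {}).items():
        vs.suitability[label] = vs.suitability_on(fut)
        vs.true_ranges[label] = vs.suitability[label] >= s_star
    return vs


def sample_presences(vs: VirtualSpecies, n: int, seed: int) -> OccurrenceSet:
    """Draw ``n`` presence records proportional to current suitability.

    Cells are drawn with replacement (real occurrence datasets repeat
    locations); records sit at cell centers.
    """
    if n < 1:
        raise ValueError("need at least one presence")
    s = vs.suitability["current"].ravel()
    total = s.sum()
    if total == 0:
        raise ValueError(f"species {vs.species_id}: suitability is zero everywhere")
    rng = np.random.default_rng(seed)
    cells = rng.choice(s.size, size=n, p=s / total)
    records = []
    for flat in cells:
        row, col = np.unravel_index(flat, vs.grid.shape)
        lon, lat = vs.grid.cell_center(int(row), int(col))
        records.append(OccurrenceRecord(vs.species_id, lon, lat, source="synthetic"))
    occ = OccurrenceSet({vs.species_id: records})
    occ.log(f"sampled {n} presences for {vs.species_id} (seed {seed})")
    return occ


@dataclass
class SyntheticStudy:
    """A complete synthetic experiment with ground truth."""

    current: ClimateStack
    futures: dict[str, ClimateStack]
    species: list[VirtualSpecies]
    occurrences: OccurrenceSet
    true_loss: dict[str, dict[str, float]]  # species -> scenario label -> L*


def synthesize_study(n_species: int = 20, n_data_poor: int = 3, seed: int = 0,
                     grid: GridSpec = DEFAULT_GRID, n_variables: int = 3,
                     inject_duplicate: bool = True, n_presences: int = 200,
                     s_star: float = 0.1,
                     mu_temp_range: tuple[float, float] = (-11.0, 22.0),
                     scenarios: dict[tuple[str, str], dict[str, float]] | None = None,
                     ) -> SyntheticStudy:
    """Build the reference synthetic experiment.

    ``n_species`` modelled species get Gaussian niches in (temp, precip)
    whose temperature centers sweep the gradient from cold-adapted (high
    latitude, poleward climate margin — these lose most of their range
    under warming) to warm-adapted (equatorial band — warming splits the
    band into two hemispheric ones, which can expand), so true loss
    fractions span strong contraction through expansion.  Niche centers are
    kept inside the landscape's realized climate envelope with roughly a
    two-sigma margin (default ``mu_temp_range``): a species whose optimum
    lies in climates that exist nowhere has a truncated niche that no
    presence-based model can identify, which would confound recovery
    experiments with an unlearnable truth.  ``n_data_poor`` extra species
    carry 1, 2 and 3 records (cycling) with fixed geometries that exercise
    every branch of the record-geometry cascade.
    """
    rng = np.random.default_rng(seed)
    current = generate_climate(grid, n_variables, seed,
                               duplicate_of="temp" if inject_duplicate else None,
                               duplicate_noise_sd=1.0 if inject_duplicate else 0.0)
    scenarios = scenarios if scenarios is not None else DEFAULT_SCENARIOS
    deltas = {}
    for (scen, hor), shifts in scenarios.items():
        label = f"{scen}/{hor}"
        full_shifts = dict(shifts)
        if inject_duplicate and "temp" in shifts:
            full_shifts["temp_dup"] = shifts["temp"]
        deltas[label] = ScenarioDelta(label, full_shifts)
    futures = {lbl: apply_delta(current, d) for lbl, d in deltas.items()}

    species: list[VirtualSpecies] = []
    occ = OccurrenceSet()
    true_loss: dict[str, dict[str, float]] = {}
    mu_temps = np.linspace(*mu_temp_range, n_species) if n_species > 1 \
        else np.array([np.mean(mu_temp_range)])
    for i in range(n_species):
        sp = f"vs{i:03d}"
        mu = np.array([mu_temps[i], float(rng.uniform(700.0, 1700.0))])
        sigma = np.diag([float(rng.uniform(2.5, 4.0)) ** 2,
                         float(rng.uniform(280.0, 450.0)) ** 2])
        vs = make_virtual_species(current, mu, sigma, s_star, sp,
                                  n_presences=n_presences,
                                  niche_variables=["temp", "precip"],
                                  future_stacks=futures)
        species.append(vs)
        occ = occ.merge(sample_presences(vs, n_presences, seed=seed * 7919 + i))
        true_loss[sp] = {lbl: true_loss_fraction(vs, lbl) for lbl in futures}

    # data-poor species with fixed record geometries (deterministic):
    # cycle through 1-record, 2-record (~30 km apart) and 3-record
    # (~1 degree triangle, ~6000 km^2) configurations.
    for i in range(n_data_poor):
        sp = f"dp{i:03d}"
        lon0 = -150.0 + 37.0 * i
        lat0 = -30.0 + 13.0 * i
        kind = i % 3
        if kind == 0:
            recs = [OccurrenceRecord(sp, lon0, lat0, "synthetic")]
        elif kind == 1:
            recs = [OccurrenceRecord(sp, lon0, lat0, "synthetic"),
                    OccurrenceRecord(sp, lon0 + 0.27, lat0, "synthetic")]
        else:
            recs = [OccurrenceRecord(sp, lon0, lat0, "synthetic"),
                    OccurrenceRecord(sp, lon0 + 1.0, lat0, "synthetic"),
                    OccurrenceRecord(sp, lon0, lat0 + 1.0, "synthetic")]
        occ.records[sp] = recs
    occ.log(f"synthesized {n_species} modelled + {n_data_poor} data-poor species "
            f"(seed {seed})")
    return SyntheticStudy(current, futures, species, occ, true_loss)


def true_loss_fraction(vs: VirtualSpecies, scenario_label: str) -> float:
    """(A_current - A_future) / A_current with geodesic cell areas.

    Negative values mean range expansion.
    """
    if "current" not in vs.true_ranges or scenario_label not in vs.true_ranges:
        raise KeyError(f"truth ranges missing for 'current' or {scenario_label!r}")
    areas = vs.grid.cell_areas_km2()
    a_cur = areas[vs.true_ranges["current"]].sum()
    a_fut = areas[vs.true_ranges[scenario_label]].sum()
    if a_cur == 0:
        raise ZeroDivisionError(f"{vs.species_id}: current truth range is empty")
    return float((a_cur - a_fut) / a_cur)
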