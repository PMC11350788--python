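"""Co-registered climate raster stacks and collinearity screening.

A :class:`ClimateStack` holds named bioclimatic layers (any subset of
BIO1..BIO19, altitude, or synthetic equivalents) sharing one grid and one
nodata mask, tagged with a scenario/horizon label.

Predictor screening is two-stage, run on the current-scenario stack:

1. **Pairwise Pearson correlation**: while any pair has |r| above the cutoff
   (0.8 by default), drop one member of the worst pair — the one with the
   larger mean |r| against all remaining variables, which is deterministic
   and independent of layer order.
2. **Iterative VIF elimination**: repeatedly drop the variable with the
   largest variance inflation factor VIF_j = 1/(1 - R^2_j) until all
   VIF <= 10.  VIF is recomputed after every drop; a one-shot pass can
   strand variables above the cutoff.

The retained set is then fixed for all scenario projections.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .grids import GridSpec, read_ascii_grid, write_ascii_grid


class GridMismatchError(ValueError):
    pass


@dataclass
class ClimateStack:
    grid: GridSpec
    layers: dict[str, np.ndarray]
    mask: np.ndarray | None = None
    scenario: str = "current"
    horizon: str = "current"

    def __post_init__(self) -> None:
        for name, arr in self.layers.items():
            if arr.shape != self.grid.shape:
                raise GridMismatchError(
                    f"layer {name!r} shape {arr.shape} != grid shape {self.grid.shape}")
        if self.mask is None:
            self.mask = np.zeros(self.grid.shape, dtype=bool)
        elif self.mask.shape != self.grid.shape:
            raise GridMismatchError("mask shape does not match grid")

    @property
    def variable_names(self) -> list[str]:
        return list(self.layers)

    @property
    def n_unmasked(self) -> int:
        return int((~self.mask).sum())

    def values_matrix(self, names: list[str] | None = None,
                      cells: np.ndarray | None = None) -> np.ndarray:
        """Unmasked cell values as an (n_cells, n_variables) matrix.

        ``cells`` are flat indices into the raveled grid; defaults to all
        unmasked cells in ravel order.
        """
        names = names if names is not None else self.variable_names
        if cells is None:
            cells = np.flatnonzero(~self.mask.ravel())
        return np.column_stack([self.layers[n].ravel()[cells] for n in names])

    def subset(self, names: list[str]) -> "ClimateStack":
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"variables not in stack: {missing}")
        return ClimateStack(self.grid, {n: self.layers[n] for n in names},
                            self.mask, self.scenario, self.horizon)

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, arr in self.layers.items():
            write_ascii_grid(directory / f"{name}.asc", self.grid, arr, self.mask)


def read_stack(paths: dict[str, str | Path], scenario: str = "current",
               horizon: str = "current", union_masks: bool = False) -> ClimateStack:
    """Assemble a stack from per-variable ASCII grid files.

    All rasters must share the grid.  Differing nodata masks are an error
    unless ``union_masks`` is set, in which case the union mask is applied.
    """
    if not paths:
        raise ValueError("no raster paths given")
    grid = None
    layers: dict[str, np.ndarray] = {}
    masks = []
    for name, p in paths.items():
        g, vals, m = read_ascii_grid(p)
        if grid is None:
            grid = g
        elif g != grid:
            raise GridMismatchError(
                f"layer {name!r} grid {g.resolution_arcmin}' {g.shape} does not match "
                f"first layer grid {grid.resolution_arcmin}' {grid.shape}")
        layers[name] = vals
        masks.append(m)
    mask = masks[0]
    for m in masks[1:]:
        if not np.array_equal(m, mask):
            if union_masks:
                mask = mask | m
            else:
                raise GridMismatchError(
                    "layer masks differ; pass union_masks=True to take the union")
    if union_masks:
        mask = np.logical_or.reduce(masks)
    return ClimateStack(grid, layers, mask, scenario, horizon)


def _sample_cells(stack: ClimateStack, sample_cells: int, seed: int) -> np.ndarray:
    unmasked = np.flatnonzero(~stack.mask.ravel())
    if sample_cells >= unmasked.size:
        return unmasked
    rng = np.random.default_rng(seed)
    return rng.choice(unmasked, size=sample_cells, replace=False)


def correlation_matrix(stack: ClimateStack, sample_cells: int = 10_000,
                       seed: int = 0, names: list[str] | None = None) -> np.ndarray:
    """Pearson correlation over a seeded sample of unmasked cells.

    Constant layers have undefined correlation; they are flagged with a
    warning and given correlation 0 against everything (1 on the diagonal).
    """
    names = names if names is not None else stack.variable_names
    if len(names) < 2:
        raise ValueError("need at least two layers")
    if sample_cells < 2:
        raise ValueError("need at least two sample cells")
    X = stack.values_matrix(names, _sample_cells(stack, sample_cells, seed))
    sd = X.std(axis=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"constant layers {[n for n, c in zip(names, constant) if c]}: "
            "correlation undefined, treated as 0", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X, rowvar=False)
    r[np.isnan(r)] = 0.0
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def vif(values_matrix: np.ndarray, column_j: int) -> float:
    """Variance inflation factor of one column regressed on the others.

    Returns ``1 / (1 - R^2_j)`` from an ordinary least-squares fit (with
    intercept).  Perfect collinearity returns ``inf``.
    """
    X = np.asarray(values_matrix, dtype=float)
    n, p = X.shape
    if p < 2:
        raise ValueError("need at least two columns")
    if n < p + 1:
        raise ValueError(f"need at least {p + 1} rows for {p} columns, got {n}")
    y = X[:, column_j]
    others = np.delete(X, column_j, axis=1)
    A = np.column_stack([np.ones(n), others])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        return 1.0  # constant column carries no variance to inflate
    r2 = 1.0 - np.sum(resid**2) / ss_tot
    if r2 >= 1.0 - 1e-12:
        return float("inf")
    return float(1.0 / (1.0 - r2))


@dataclass
class VariableSelection:
    """Outcome of the two-stage screen, with per-drop diagnostics."""

    retained: list[str]
    dropped: list[dict] = field(default_factory=list)  # {name, reason, statistic}
    correlation: np.ndarray | None = None
    names: list[str] | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "retained": self.retained,
            "dropped": self.dropped,
            "correlation_matrix": None if self.correlation is None
            else self.correlation.tolist(),
            "variable_order": self.names,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def select_variables(stack: ClimateStack, r_max: float = 0.8, vif_max: float = 10.0,
                     sample_cells: int = 10_000, seed: int = 0) -> VariableSelection:
    """Two-stage predictor screen (correlation cutoff, then iterative VIF)."""
    if not (0 < r_max < 1):
        raise ValueError("r_max must be in (0, 1)")
    if vif_max <= 1:
        raise ValueError("vif_max must exceed 1")
    names = list(stack.variable_names)
    full_corr = correlation_matrix(stack, sample_cells, seed, names)
    cells = _sample_cells(stack, sample_cells, seed)
    dropped: list[dict] = []

    # stage 1: pairwise correlation on the fixed cell sample
    keep_idx = list(range(len(names)))
    while len(keep_idx) >= 2:
        absr = np.abs(full_corr[np.ix_(keep_idx, keep_idx)])
        np.fill_diagonal(absr, 0.0)
        worst = np.unravel_index(np.argmax(absr), absr.shape)
        if absr[worst] <= r_max:
            break
        i, j = worst
        # drop the member with the larger mean |r| against all others
        mean_i = absr[i].sum() / (len(keep_idx) - 1)
        mean_j = absr[j].sum() / (len(keep_idx) - 1)
        victim = i if mean_i >= mean_j else j
        dropped.append({"name": names[keep_idx[victim]], "reason": "correlation",
                        "statistic": float(absr[worst])})
        keep_idx.pop(victim)
    keep = [names[i] for i in keep_idx]

    # stage 2: iterative VIF
    while len(keep) >= 2:
        X = stack.values_matrix(keep, cells)
        vifs = np.array([vif(X, j) for j in range(len(keep))])
        worst_j = int(np.argmax(vifs))
        if vifs[worst_j] <= vif_max:
            break
        dropped.append({"name": keep[worst_j], "reason": "vif",
                        "statistic": float(vifs[worst_j])})
        keep.pop(worst_j)

    if len(keep) < 2:
        raise ValueError(
            "fewer than 2 variables survive screening; relax r_max/vif_max "
            f"(dropped: {[d['name'] for d in dropped]})")
    return VariableSelection(retained=keep, dropped=dropped,
                             correlation=full_corr, names=names)
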