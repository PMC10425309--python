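"""Ground-truth iron-distribution phantoms.

Scenes emulate the adoptive-transfer experiment that the rest of the package
quantifies: superparamagnetic iron oxide (SPIO)-labeled dendritic cells are
injected into both hind footpads, a small fraction (3-5%) migrates to the
draining popliteal lymph node (pLN) within two days, and residual dietary iron
produces a confounding gastrointestinal (GI) source.  Every scene carries an
exact ground-truth table (label -> iron, cells) so each downstream stage of the
pipeline can be validated without any external data.

Coordinate convention: world positions are (z, x, y) in millimetres with Z the
scanner bore axis and the scanner isocenter at the origin; this matches the
array axis order used by the forward model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IronSource",
    "PhantomScene",
    "make_mouse_scene",
    "make_day0_scene",
    "make_calibration_series",
    "make_cell_pellet",
    "make_point_scene",
    "make_ln_section",
    "PER_CELL_IRON_PG",
    "FOOTPAD_Z_MM",
    "PLN_Z_MM",
    "GI_Z_MM",
    "LIMB_X_MM",
]

# --- anatomical layout constants (invented plumbing, documented) -------------
# Footpad -> popliteal node separation ~1 cm along the bore (Z) axis; both limbs
# offset laterally from the midline; the GI confounder sits near mid-body.
FOOTPAD_Z_MM = 45.0
PLN_Z_MM = 35.0
GI_Z_MM = 5.0
LIMB_X_MM = 8.0

#: Default iron load per labeled cell, pg.  Anchored to the pairing of 1,000
#: migrated cells with 4.4 ng of iron; configurable everywhere it is used.
PER_CELL_IRON_PG = 4.4

#: Fraction of the injected dose assumed to remain at the injection site on
#: day 2 (non-migrating / apoptotic cells).  Controls how strongly the
#: injection site shadows the pLN in a full-FOV scan.
INJECTION_RESIDUAL_FRACTION = 0.8

#: Default GI confounder iron (ng) and spatial spread (mm).
GI_IRON_NG = 500.0
GI_EXTENT_SIGMA_MM = 3.0

#: Default compact-source spread (mm) for footpad / pLN / pellet blobs.
SOURCE_EXTENT_SIGMA_MM = 0.5


@dataclass(frozen=True)
class IronSource:
    """A localized iron deposit.

    position : (z, x, y) world coordinates, mm
    iron_ng : iron mass, ng
    extent_sigma_mm : Gaussian spread; 0 means an ideal point source
    label : tag such as ``pLN_left``, ``injection_right``, ``GI``,
        ``calibration``, ``pellet``
    """

    position: tuple[float, float, float]
    iron_ng: float
    extent_sigma_mm: float = 0.0
    label: str = "source"

    def __post_init__(self) -> None:
        if self.iron_ng < 0:
            raise ValueError(f"iron_ng must be >= 0, got {self.iron_ng}")
        if self.extent_sigma_mm < 0:
            raise ValueError(
                f"extent_sigma_mm must be >= 0, got {self.extent_sigma_mm}"
            )
        if len(self.position) != 3:
            raise ValueError("position must be a 3-vector (z, x, y) in mm")


@dataclass(frozen=True)
class PhantomScene:
    """A collection of iron sources plus the exact bookkeeping behind them.

    ``ground_truth`` has one row per label with columns ``label``, ``iron_ng``
    and ``cells`` (NaN for labels that carry iron but no cells, e.g. GI).
    For every cell-bearing label the identity
    ``iron_ng == cells * per_cell_iron_pg * 1e-3`` holds exactly.
    """

    sources: tuple[IronSource, ...]
    per_cell_iron_pg: float = PER_CELL_IRON_PG
    ground_truth: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["label", "iron_ng", "cells"])
    )
    rng_seed: int = 0

    @property
    def total_iron_ng(self) -> float:
        return float(sum(s.iron_ng for s in self.sources))

    def truth_for(self, label: str) -> pd.Series:
        rows = self.ground_truth[self.ground_truth["label"] == label]
        if rows.empty:
            raise KeyError(f"no ground-truth entry for label {label!r}")
        return rows.iloc[0]


def _cells_to_ng(cells: float, per_cell_pg: float) -> float:
    return cells * per_cell_pg * 1e-3


def _truth_table(rows: list[tuple[str, float, float]]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["label", "iron_ng", "cells"])


def make_mouse_scene(
    dose_cells: float,
    migration_fraction: float | tuple[float, float],
    per_cell_iron_pg: float = PER_CELL_IRON_PG,
    gi_iron_ng: float = GI_IRON_NG,
    rng_seed: int = 0,
    residual_fraction: float = INJECTION_RESIDUAL_FRACTION,
    extent_sigma_mm: float = SOURCE_EXTENT_SIGMA_MM,
) -> PhantomScene:
    """Day-2 mouse scene: two injection sites, two pLN, one GI confounder.

    ``migration_fraction`` is the fraction of the injected dose found in each
    pLN (scalar, applied to both sides, or a ``(left, right)`` pair).  The
    injection sites retain ``residual_fraction`` of the dose.

    Raises ``ValueError`` for non-positive dose/iron-per-cell or fractions
    outside (0, 1).
    """
    if dose_cells <= 0:
        raise ValueError(f"dose_cells must be > 0, got {dose_cells}")
    if per_cell_iron_pg <= 0:
        raise ValueError(f"per_cell_iron_pg must be > 0, got {per_cell_iron_pg}")
    if gi_iron_ng < 0:
        raise ValueError(f"gi_iron_ng must be >= 0, got {gi_iron_ng}")
    if np.isscalar(migration_fraction):
        fractions = (float(migration_fraction), float(migration_fraction))
    else:
        fractions = tuple(float(f) for f in migration_fraction)  # type: ignore[arg-type]
        if len(fractions) != 2:
            raise ValueError("migration_fraction must be a scalar or a (left, right) pair")
    for f in fractions:
        if not 0.0 < f < 1.0:
            raise ValueError(f"migration_fraction must lie in (0, 1), got {f}")
    if not 0.0 < residual_fraction <= 1.0:
        raise ValueError(f"residual_fraction must lie in (0, 1], got {residual_fraction}")

    site_cells = residual_fraction * dose_cells
    site_ng = _cells_to_ng(site_cells, per_cell_iron_pg)
    sources: list[IronSource] = []
    truth_rows: list[tuple[str, float, float]] = []
    for side, sign, f in (("left", -1.0, fractions[0]), ("right", +1.0, fractions[1])):
        pln_cells = f * dose_cells
        pln_ng = _cells_to_ng(pln_cells, per_cell_iron_pg)
        sources.append(
            IronSource(
                (FOOTPAD_Z_MM, sign * LIMB_X_MM, 0.0),
                site_ng,
                extent_sigma_mm,
                f"injection_{side}",
            )
        )
        sources.append(
            IronSource(
                (PLN_Z_MM, sign * LIMB_X_MM, 0.0), pln_ng, extent_sigma_mm, f"pLN_{side}"
            )
        )
        truth_rows.append((f"injection_{side}", site_ng, site_cells))
        truth_rows.append((f"pLN_{side}", pln_ng, pln_cells))
    if gi_iron_ng > 0:
        sources.append(
            IronSource((GI_Z_MM, 0.0, 0.0), gi_iron_ng, GI_EXTENT_SIGMA_MM, "GI")
        )
        truth_rows.append(("GI", gi_iron_ng, np.nan))
    return PhantomScene(
        tuple(sources), per_cell_iron_pg, _truth_table(truth_rows), rng_seed
    )


def make_day0_scene(
    dose_cells: float,
    per_cell_iron_pg: float = PER_CELL_IRON_PG,
    gi_iron_ng: float = GI_IRON_NG,
    rng_seed: int = 0,
    extent_sigma_mm: float = SOURCE_EXTENT_SIGMA_MM,
) -> PhantomScene:
    """Immediately post-injection scene: full dose at both footpads, no pLN."""
    if dose_cells <= 0:
        raise ValueError(f"dose_cells must be > 0, got {dose_cells}")
    if per_cell_iron_pg <= 0:
        raise ValueError(f"per_cell_iron_pg must be > 0, got {per_cell_iron_pg}")
    site_ng = _cells_to_ng(dose_cells, per_cell_iron_pg)
    sources = [
        IronSource((FOOTPAD_Z_MM, -LIMB_X_MM, 0.0), site_ng, extent_sigma_mm, "injection_left"),
        IronSource((FOOTPAD_Z_MM, +LIMB_X_MM, 0.0), site_ng, extent_sigma_mm, "injection_right"),
    ]
    truth_rows = [
        ("injection_left", site_ng, float(dose_cells)),
        ("injection_right", site_ng, float(dose_cells)),
    ]
    if gi_iron_ng > 0:
        sources.append(IronSource((GI_Z_MM, 0.0, 0.0), gi_iron_ng, GI_EXTENT_SIGMA_MM, "GI"))
        truth_rows.append(("GI", gi_iron_ng, np.nan))
    return PhantomScene(tuple(sources), per_cell_iron_pg, _truth_table(truth_rows), rng_seed)


def make_point_scene(
    iron_ng: float,
    label: str = "calibration",
    position: tuple[float, float, float] = (0.0, 0.0, 0.0),
    extent_sigma_mm: float = 0.0,
    rng_seed: int = 0,
    per_cell_iron_pg: float = PER_CELL_IRON_PG,
) -> PhantomScene:
    """Single-source scene of known iron mass (no cell bookkeeping)."""
    if iron_ng <= 0:
        raise ValueError(f"iron_ng must be > 0, got {iron_ng}")
    src = IronSource(position, iron_ng, extent_sigma_mm, label)
    truth = _truth_table([(label, iron_ng, np.nan)])
    return PhantomScene((src,), per_cell_iron_pg, truth, rng_seed)


def make_calibration_series(
    iron_masses_ng: Sequence[float],
    rng_seed: int = 0,
    position: tuple[float, float, float] = (0.0, 0.0, 0.0),
    extent_sigma_mm: float = SOURCE_EXTENT_SIGMA_MM,
) -> list[PhantomScene]:
    """One single-source scene per calibration mass, centered at ``position``.

    A usable calibration line needs at least two strictly positive masses.
    """
    masses = [float(m) for m in iron_masses_ng]
    if len(masses) < 2:
        raise ValueError("need at least 2 calibration masses to fit a line")
    if any(m <= 0 for m in masses):
        raise ValueError("calibration masses must be strictly positive")
    return [
        make_point_scene(m, "calibration", position, extent_sigma_mm, rng_seed + i)
        for i, m in enumerate(masses)
    ]


#: Default calibration series, ng (0.5-8.8 ug, bracketing the 1e6-cell pellet).
DEFAULT_CALIBRATION_MASSES_NG = (500.0, 1000.0, 2200.0, 4400.0, 6600.0, 8800.0)


def make_cell_pellet(
    n_cells: float,
    per_cell_iron_pg: float = PER_CELL_IRON_PG,
    position: tuple[float, float, float] = (0.0, 0.0, 0.0),
    extent_sigma_mm: float = SOURCE_EXTENT_SIGMA_MM,
    rng_seed: int = 0,
) -> PhantomScene:
    """Pellet of ``n_cells`` labeled cells; iron = n_cells x per-cell-pg / 1000 ng."""
    if n_cells <= 0:
        raise ValueError(f"n_cells must be > 0, got {n_cells}")
    if per_cell_iron_pg <= 0:
        raise ValueError(f"per_cell_iron_pg must be > 0, got {per_cell_iron_pg}")
    iron_ng = _cells_to_ng(float(n_cells), per_cell_iron_pg)
    src = IronSource(position, iron_ng, extent_sigma_mm, "pellet")
    truth = _truth_table([("pellet", iron_ng, float(n_cells))])
    return PhantomScene((src,), per_cell_iron_pg, truth, rng_seed)


def make_ln_section(
    fluor_fraction: float,
    shape_seed: int = 0,
    shape: tuple[int, int] = (256, 256),
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic lymph-node cryosection for area-fraction morphometry.

    Returns ``(section, ln_mask)``: a boolean fluorescence image and an
    elliptical node mask.  The number of positive pixels inside the mask is
    exactly ``round(fluor_fraction * mask_area)``, drawn uniformly at random
    within the mask.
    """
    if not 0.0 <= fluor_fraction <= 1.0:
        raise ValueError(f"fluor_fraction must lie in [0, 1], got {fluor_fraction}")
    rng = np.random.default_rng(shape_seed)
    ny, nx = shape
    cy, cx = ny / 2.0, nx / 2.0
    # Randomly oriented ellipse occupying roughly half the frame.
    a = rng.uniform(0.28, 0.40) * nx
    b = rng.uniform(0.22, 0.34) * ny
    theta = rng.uniform(0, np.pi)
    yy, xx = np.mgrid[0:ny, 0:nx]
    u = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
    v = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
    mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    area = int(mask.sum())
    n_pos = int(round(fluor_fraction * area))
    section = np.zeros(shape, dtype=bool)
    idx = np.flatnonzero(mask)
    chosen = rng.choice(idx, size=n_pos, replace=False)
    section.flat[chosen] = True
    return section, mask
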