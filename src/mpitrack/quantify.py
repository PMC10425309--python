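"""ROI quantification chain: segment, measure, calibrate, iron, cells.

The chain mirrors standard MPI practice: total ROI signal is ROI volume times
mean signal (algebraically the voxel sum times voxel volume); the
signal-to-noise ratio is the ROI mean over the standard deviation of
background noise, with a strict SNR > 5 gate on detectability; iron mass is
total signal divided by the slope of a calibration line fitted under the same
imaging sequence; cell number is iron divided by a per-cell loading measured
from a pellet of known cell count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.stats import linregress

from .forward import ReconImage

__all__ = [
    "RoiMeasurement",
    "CalibrationLine",
    "CellQuantification",
    "segment_roi",
    "measure_roi",
    "fit_calibration",
    "signal_to_iron",
    "iron_to_cells",
    "measure_per_cell_iron",
    "corner_background_mask",
    "quantify_roi",
    "SNR_THRESHOLD",
]

#: Detectability gate: ROI mean must exceed this many background SDs.
SNR_THRESHOLD = 5.0


@dataclass(frozen=True)
class RoiMeasurement:
    voxel_count: int
    volume_mm3: float
    mean_signal: float
    total_signal: float  # volume x mean, a.u. mm^3
    snr: float
    detectable: bool


@dataclass(frozen=True)
class CalibrationLine:
    """OLS line of total ROI signal (a.u. mm^3) on iron mass (ng)."""

    slope: float
    intercept: float
    r2: float
    config_id: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope):
            raise ValueError("calibration slope must be finite")


@dataclass(frozen=True)
class CellQuantification:
    roi: RoiMeasurement
    iron_ng: float  # NaN when the ROI fails the SNR gate
    per_cell_pg: float
    cell_estimate: float  # NaN when the ROI fails the SNR gate


def _hill_climb(values: np.ndarray, seed: tuple[int, int, int]) -> tuple[int, int, int]:
    """Greedy 26-neighbourhood ascent from ``seed`` to a local maximum."""
    shape = values.shape
    cur = tuple(int(i) for i in seed)
    for _ in range(int(np.prod(shape))):
        z, x, y = cur
        sl = (
            slice(max(z - 1, 0), min(z + 2, shape[0])),
            slice(max(x - 1, 0), min(x + 2, shape[1])),
            slice(max(y - 1, 0), min(y + 2, shape[2])),
        )
        block = values[sl]
        best = np.unravel_index(np.argmax(block), block.shape)
        cand = (sl[0].start + best[0], sl[1].start + best[1], sl[2].start + best[2])
        if values[cand] <= values[cur]:
            return cur
        cur = cand
    return cur


def segment_roi(
    image: ReconImage,
    seed_point: tuple[int, int, int],
    threshold_fraction: float = 0.5,
) -> np.ndarray:
    """Seeded half-max-style region growing.

    Hill-climbs from the seed to the local peak, thresholds the image at
    ``threshold_fraction`` times the peak value, and keeps the 6-connected
    component containing the peak.  Returns an all-false mask when the peak
    value is non-positive.  Raises ``ValueError`` for a seed outside the grid.
    """
    values = image.values
    seed = tuple(int(i) for i in seed_point)
    if len(seed) != 3 or any(
        not 0 <= s < n for s, n in zip(seed, values.shape)
    ):
        raise ValueError(f"seed {seed_point} outside image grid {values.shape}")
    if not 0.0 < threshold_fraction <= 1.0:
        raise ValueError("threshold_fraction must lie in (0, 1]")
    peak = _hill_climb(values, seed)
    peak_val = values[peak]
    if peak_val <= 0:
        return np.zeros(values.shape, dtype=bool)
    binary = values >= threshold_fraction * peak_val
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    labels, _ = ndimage.label(binary, structure=structure)
    return labels == labels[peak]


def measure_roi(
    image: ReconImage,
    mask: np.ndarray,
    background_mask: np.ndarray,
    snr_threshold: float = SNR_THRESHOLD,
    inclusive_gate: bool = False,
) -> RoiMeasurement:
    """ROI statistics with SNR-gated detectability.

    ``detectable`` requires SNR strictly greater than ``snr_threshold``
    (set ``inclusive_gate=True`` for >=).  Raises on empty or overlapping
    masks and on zero background SD (SNR undefined).
    """
    mask = np.asarray(mask, dtype=bool)
    background_mask = np.asarray(background_mask, dtype=bool)
    if mask.shape != image.values.shape or background_mask.shape != image.values.shape:
        raise ValueError("masks must match the image grid")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("ROI mask is empty")
    if int(background_mask.sum()) == 0:
        raise ValueError("background mask is empty")
    if np.any(mask & background_mask):
        raise ValueError("ROI and background masks overlap")
    mean = float(image.values[mask].mean())
    volume = n * image.voxel_volume_mm3
    total = volume * mean
    bg_sd = float(image.values[background_mask].std(ddof=1))
    if bg_sd == 0:
        raise ValueError("background SD is zero; SNR undefined")
    snr = mean / bg_sd
    detectable = snr >= snr_threshold if inclusive_gate else snr > snr_threshold
    return RoiMeasurement(n, volume, mean, total, snr, bool(detectable))


def fit_calibration(
    samples: Sequence[tuple[float, float]], config_id: str = ""
) -> CalibrationLine:
    """OLS fit of total ROI signal on known iron mass.

    ``samples`` are ``(iron_ng, total_signal)`` pairs; at least two distinct
    iron values are required.
    """
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least two (iron_ng, total_signal) samples")
    iron, signal = arr[:, 0], arr[:, 1]
    if np.ptp(iron) == 0:
        raise ValueError("all iron values identical; line is under-determined")
    fit = linregress(iron, signal)
    return CalibrationLine(float(fit.slope), float(fit.intercept),
                           float(fit.rvalue ** 2), config_id)


def signal_to_iron(
    total_signal: float, line: CalibrationLine, use_intercept: bool = False
) -> float:
    """Convert total ROI signal to iron mass (ng).

    Default is division by the slope alone; ``use_intercept=True`` inverts the
    full line instead.
    """
    if line.slope <= 0:
        raise ValueError(f"calibration slope must be > 0, got {line.slope}")
    if use_intercept:
        return (total_signal - line.intercept) / line.slope
    return total_signal / line.slope


def iron_to_cells(iron_ng: float, per_cell_pg: float) -> float:
    """Cell-number estimate: iron (ng -> pg) divided by per-cell loading."""
    if per_cell_pg <= 0:
        raise ValueError(f"per_cell_pg must be > 0, got {per_cell_pg}")
    return iron_ng * 1e3 / per_cell_pg


def corner_background_mask(
    image: ReconImage,
    seeds: Sequence[tuple[int, int, int]] = (),
    size_mm: float = 6.0,
) -> np.ndarray:
    """Box mask in the FOV corner farthest from all seed points.

    Used as the default source-free background region for noise estimation.
    """
    shape = np.array(image.values.shape)
    size_vox = np.maximum(1, np.minimum(shape, int(round(size_mm / image.voxel_mm))))
    corners = [
        tuple(0 if bit else int(n - s) for bit, n, s in zip(bits, shape, size_vox))
        for bits in np.ndindex(2, 2, 2)
    ]
    if seeds:
        seed_arr = np.asarray(seeds, dtype=float)

        def score(corner):
            center = np.asarray(corner) + size_vox / 2.0
            return np.min(np.linalg.norm(seed_arr - center[None, :], axis=1))

        best = max(corners, key=score)
    else:
        best = corners[0]
    mask = np.zeros(image.values.shape, dtype=bool)
    z, x, y = best
    mask[z:z + size_vox[0], x:x + size_vox[1], y:y + size_vox[2]] = True
    return mask


def quantify_roi(
    image: ReconImage,
    seed_point: tuple[int, int, int],
    line: CalibrationLine,
    per_cell_pg: float,
    background_mask: Optional[np.ndarray] = None,
    threshold_fraction: float = 0.5,
    snr_threshold: float = SNR_THRESHOLD,
) -> CellQuantification:
    """Full chain for one ROI: segment, measure, gate, convert.

    Iron and cell values are only reported for ROIs passing the SNR gate;
    gated-out ROIs carry NaN.  Raises ``ValueError`` if the calibration line
    was fitted under a different imaging sequence than the image.
    """
    if line.config_id and image.config_id and line.config_id != image.config_id:
        raise ValueError(
            "calibration line is bound to a different imaging sequence "
            f"({line.config_id!r}) than the image ({image.config_id!r})"
        )
    if per_cell_pg <= 0:
        raise ValueError(f"per_cell_pg must be > 0, got {per_cell_pg}")
    mask = segment_roi(image, seed_point, threshold_fraction)
    if background_mask is None:
        background_mask = corner_background_mask(image, [seed_point])
    if not mask.any():
        empty = RoiMeasurement(0, 0.0, 0.0, 0.0, 0.0, False)
        return CellQuantification(empty, np.nan, per_cell_pg, np.nan)
    roi = measure_roi(image, mask, background_mask, snr_threshold)
    if not roi.detectable:
        return CellQuantification(roi, np.nan, per_cell_pg, np.nan)
    iron = signal_to_iron(roi.total_signal, line)
    cells = iron_to_cells(iron, per_cell_pg)
    return CellQuantification(roi, iron, per_cell_pg, cells)


def measure_per_cell_iron(
    pellet_image: ReconImage,
    n_cells: float,
    line: CalibrationLine,
    seed_point: tuple[int, int, int],
    background_mask: Optional[np.ndarray] = None,
    threshold_fraction: float = 0.5,
) -> float:
    """Per-cell iron loading (pg/cell) from a pellet of known cell number.

    Raises if the pellet fails the SNR gate — an undetectable pellet cannot
    calibrate per-cell loading.
    """
    if n_cells <= 0:
        raise ValueError(f"n_cells must be > 0, got {n_cells}")
    mask = segment_roi(pellet_image, seed_point, threshold_fraction)
    if background_mask is None:
        background_mask = corner_background_mask(pellet_image, [seed_point])
    if not mask.any():
        raise ValueError("pellet not segmentable (empty ROI)")
    roi = measure_roi(pellet_image, mask, background_mask)
    if not roi.detectable:
        raise ValueError(f"pellet SNR {roi.snr:.2f} fails the > {SNR_THRESHOLD} gate")
    iron_ng = signal_to_iron(roi.total_signal, line)
    return iron_ng * 1e3 / n_cells
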