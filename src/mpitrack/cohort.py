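"""Desk-scale cohort orchestration of the cell-migration imaging experiment.

For each simulated mouse: build a day-2 scene (footpad injection sites, two
popliteal lymph nodes carrying 3-5% of the dose, GI confounder), acquire and
reconstruct under three modes — whole-animal 12-cm FOV with native
reconstruction, pLN-focused 2-cm FOV with multichannel joint reconstruction,
and ex-vivo scans of each excised node alone in a clean full FOV — then push
every pLN through the SNR-gated quantification chain using a calibration line
fitted under the matching imaging sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import linregress

from . import phantoms
from .forward import ReconImage, ScanConfig, acquire_scan
from .phantoms import PhantomScene
from .quantify import (
    CalibrationLine,
    corner_background_mask,
    fit_calibration,
    measure_roi,
    segment_roi,
)
from .recon import ReconSettings, reconstruct

__all__ = [
    "CohortResult",
    "build_calibration",
    "run_cohort",
    "detection_rate",
    "regress_invivo_exvivo",
    "area_fraction",
    "FOV_MODES",
]

FOV_MODES = ("full12", "focused2", "exvivo")

#: Reconstruction paired with each FOV mode (the experiment's actual pairing;
#: full-FOV and ex-vivo scans have no edge signal so native recovery applies,
#: the focused window has strong edge signal and needs the joint method).
MODE_RECON = {"full12": "native", "focused2": "joint", "exvivo": "native"}

#: Migration-fraction range sampled per pLN (fraction of the injected dose).
MIGRATION_RANGE = (0.03, 0.05)

#: An ROI whose mask reaches within this distance of a competing source
#: (injection site, GI) has merged with it and cannot be quantified — the
#: analysis-time analogue of a node signal that "could not be separated" from
#: the injection-site signal.
MERGE_RADIUS_MM = 5.0


@dataclass
class CohortResult:
    """Cohort outputs: one table row per (mouse, side, fov_mode)."""

    table: pd.DataFrame
    calibration: dict[str, CalibrationLine]
    metadata: dict = field(default_factory=dict)
    day0: Optional[pd.DataFrame] = None


def _mask_separable(
    image: ReconImage, mask: np.ndarray, confounder_positions, radius_mm: float
) -> bool:
    """True unless the ROI mask reaches within ``radius_mm`` of a confounder."""
    if not confounder_positions or not mask.any():
        return True
    idx = np.argwhere(mask)
    world = np.asarray(image.origin_mm) + (idx + 0.5) * image.voxel_mm
    for pos in confounder_positions:
        d = np.linalg.norm(world - np.asarray(pos, dtype=float)[None, :], axis=1)
        if d.min() < radius_mm:
            return False
    return True


def _quantify_scene_source(
    image: ReconImage,
    position,
    line: CalibrationLine,
    per_cell_pg: float,
    background_seeds,
    snr_threshold: float,
    confounder_positions=(),
    merge_radius_mm: float = MERGE_RADIUS_MM,
) -> dict:
    """Quantify one source: segment, check separability, gate, convert.

    ``detectable`` in the returned record means quantifiable — the ROI passes
    the SNR gate *and* did not merge with a competing source region; iron and
    cell values are NaN otherwise.
    """
    seed = image.world_to_index(position)
    bg = corner_background_mask(image, background_seeds)
    mask = segment_roi(image, seed)
    rec = {
        "voxel_count": 0, "volume_mm3": 0.0, "mean_signal": 0.0,
        "total_signal": 0.0, "snr": 0.0, "snr_pass": False,
        "separable": True, "detectable": False,
        "iron_ng": np.nan, "cell_estimate": np.nan,
    }
    if not mask.any():
        return rec
    bg = bg & ~mask
    if not bg.any():  # ROI swallowed the background box: clearly merged
        rec["separable"] = False
        return rec
    roi = measure_roi(image, mask, bg, snr_threshold)
    separable = _mask_separable(image, mask, confounder_positions, merge_radius_mm)
    rec.update(
        voxel_count=roi.voxel_count, volume_mm3=roi.volume_mm3,
        mean_signal=roi.mean_signal, total_signal=roi.total_signal,
        snr=roi.snr, snr_pass=roi.detectable, separable=separable,
        detectable=roi.detectable and separable,
    )
    if rec["detectable"]:
        from .quantify import iron_to_cells, signal_to_iron

        if line.config_id and image.config_id and line.config_id != image.config_id:
            raise ValueError(
                "calibration line is bound to a different imaging sequence "
                f"({line.config_id!r}) than the image ({image.config_id!r})"
            )
        rec["iron_ng"] = signal_to_iron(roi.total_signal, line)
        rec["cell_estimate"] = iron_to_cells(rec["iron_ng"], per_cell_pg)
    return rec


def build_calibration(
    config: ScanConfig,
    method: str,
    masses_ng: Sequence[float] = phantoms.DEFAULT_CALIBRATION_MASSES_NG,
    seed: int = 0,
    recon_settings: Optional[ReconSettings] = None,
) -> CalibrationLine:
    """Fit a calibration line unique to one imaging sequence.

    Simulates a single-source scene per mass centered in the FOV, acquires and
    reconstructs it with the sequence's paired method, measures the ROI total
    signal at half-max, and fits total signal on iron mass.
    """
    scenes = phantoms.make_calibration_series(
        masses_ng, rng_seed=seed, position=config.fov_center
    )
    child_seeds = np.random.SeedSequence(seed).generate_state(len(scenes))
    samples = []
    for scene, s in zip(scenes, child_seeds):
        raw = acquire_scan(scene, config, seed=int(s % (2 ** 31)))
        img = reconstruct(raw, method, recon_settings)
        seed_vox = img.world_to_index(scene.sources[0].position)
        mask = segment_roi(img, seed_vox)
        if not mask.any():
            raise ValueError(
                f"calibration source of {scene.sources[0].iron_ng} ng not segmentable"
            )
        # Total signal = volume x mean = voxel sum x voxel volume; the SNR gate
        # does not apply to calibration phantoms of known iron.
        total = float(img.values[mask].sum() * img.voxel_volume_mm3)
        samples.append((scene.sources[0].iron_ng, total))
    return fit_calibration(samples, config.config_id)


def run_cohort(
    n_mice: int,
    doses: Sequence[float],
    config_full: Optional[ScanConfig] = None,
    config_focused: Optional[ScanConfig] = None,
    per_cell_pg: float = phantoms.PER_CELL_IRON_PG,
    master_seed: int = 0,
    migration_range: tuple[float, float] = MIGRATION_RANGE,
    calibration_masses_ng: Sequence[float] = phantoms.DEFAULT_CALIBRATION_MASSES_NG,
    include_day0: bool = True,
    snr_threshold: float = 5.0,
    gi_iron_ng: float = phantoms.GI_IRON_NG,
) -> CohortResult:
    """Simulate and quantify a full cohort.

    ``doses`` gives the injected cell dose per mouse: either one entry per
    mouse, or a set of group doses that divides ``n_mice`` evenly (e.g. two
    doses for six mice -> three mice per dose).  Everything derives from
    ``master_seed``; identical seeds reproduce the result bit-for-bit.
    """
    if n_mice < 1:
        raise ValueError("n_mice must be >= 1")
    doses = [float(d) for d in doses]
    if len(doses) == n_mice:
        mouse_doses = doses
    elif doses and n_mice % len(doses) == 0:
        per_group = n_mice // len(doses)
        mouse_doses = [d for d in doses for _ in range(per_group)]
    else:
        raise ValueError(
            f"doses (len {len(doses)}) must cover each of the {n_mice} mice"
        )
    config_full = config_full or ScanConfig.full_fov()
    config_focused = config_focused or ScanConfig.focused_fov()

    ss = np.random.SeedSequence(master_seed)
    seed_cal_full, seed_cal_foc, seed_mice = ss.spawn(3)
    cal = {
        "full12": build_calibration(
            config_full, MODE_RECON["full12"], calibration_masses_ng,
            int(seed_cal_full.generate_state(1)[0] % (2 ** 31)),
        ),
        "focused2": build_calibration(
            config_focused, MODE_RECON["focused2"], calibration_masses_ng,
            int(seed_cal_foc.generate_state(1)[0] % (2 ** 31)),
        ),
    }
    cal["exvivo"] = cal["full12"]  # ex-vivo scans reuse the full-FOV sequence

    mode_config = {"full12": config_full, "focused2": config_focused, "exvivo": config_full}

    rows = []
    day0_rows = []
    for mouse, (dose, mouse_ss) in enumerate(zip(mouse_doses, seed_mice.spawn(n_mice))):
        frac_rng = np.random.default_rng(mouse_ss.spawn(1)[0])
        fractions = {
            "left": float(frac_rng.uniform(*migration_range)),
            "right": float(frac_rng.uniform(*migration_range)),
        }
        scene = phantoms.make_mouse_scene(
            dose, (fractions["left"], fractions["right"]), per_cell_pg,
            gi_iron_ng=gi_iron_ng, rng_seed=mouse,
        )
        scan_seeds = mouse_ss.generate_state(6)

        # In-vivo scans: one acquisition per FOV mode, both pLN quantified.
        invivo_images = {}
        for i, mode in enumerate(("full12", "focused2")):
            cfg = mode_config[mode]
            raw = acquire_scan(scene, cfg, seed=int(scan_seeds[i] % (2 ** 31)))
            invivo_images[mode] = reconstruct(raw, MODE_RECON[mode])

        pln_positions = {
            side: next(
                s.position for s in scene.sources if s.label == f"pLN_{side}"
            )
            for side in ("left", "right")
        }
        confounders = [
            s.position for s in scene.sources
            if s.label.startswith("injection") or s.label == "GI"
        ]
        all_seeds = {
            mode: [img.world_to_index(p) for p in pln_positions.values()]
            for mode, img in invivo_images.items()
        }

        for j, side in enumerate(("left", "right")):
            truth = scene.truth_for(f"pLN_{side}")
            base = {
                "mouse": mouse,
                "side": side,
                "dose_cells": dose,
                "migration_fraction": fractions[side],
                "true_iron_ng": truth["iron_ng"],
                "true_cells": truth["cells"],
            }
            for mode in ("full12", "focused2"):
                img = invivo_images[mode]
                rec = _quantify_scene_source(
                    img, pln_positions[side], cal[mode], per_cell_pg,
                    all_seeds[mode], snr_threshold,
                    confounder_positions=confounders,
                )
                rows.append({**base, "fov_mode": mode, **rec})

            # Ex-vivo: the excised node alone, centered in a clean full FOV —
            # excision removes the shadowing sources.
            ex_scene = phantoms.make_point_scene(
                truth["iron_ng"], label=f"pLN_{side}",
                position=config_full.fov_center,
                extent_sigma_mm=phantoms.SOURCE_EXTENT_SIGMA_MM,
                rng_seed=mouse,
            )
            ex_raw = acquire_scan(
                ex_scene, config_full, seed=int(scan_seeds[2 + j] % (2 ** 31))
            )
            ex_img = reconstruct(ex_raw, MODE_RECON["exvivo"])
            rec = _quantify_scene_source(
                ex_img, config_full.fov_center, cal["exvivo"], per_cell_pg,
                [ex_img.world_to_index(config_full.fov_center)], snr_threshold,
            )
            rows.append({**base, "fov_mode": "exvivo", **rec})

        if include_day0:
            d0_scene = phantoms.make_day0_scene(dose, per_cell_pg, gi_iron_ng, mouse)
            d0_raw = acquire_scan(d0_scene, config_full, seed=int(scan_seeds[4] % (2 ** 31)))
            d0_img = reconstruct(d0_raw, "native")
            site_pos = [s.position for s in d0_scene.sources if s.label.startswith("injection")]
            site_seeds = [d0_img.world_to_index(p) for p in site_pos]
            for side, pos in zip(("left", "right"), site_pos):
                rec = _quantify_scene_source(
                    d0_img, pos, cal["full12"], per_cell_pg, site_seeds, snr_threshold
                )
                day0_rows.append({
                    "mouse": mouse, "side": side, "dose_cells": dose,
                    "true_iron_ng": d0_scene.truth_for(f"injection_{side}")["iron_ng"],
                    **rec,
                })

    table = pd.DataFrame(rows)
    table["recovered_fraction"] = table["cell_estimate"] / table["dose_cells"]
    metadata = {
        "n_mice": n_mice,
        "doses": mouse_doses,
        "per_cell_pg": per_cell_pg,
        "master_seed": master_seed,
        "migration_range": list(migration_range),
        "config_full": config_full.config_id,
        "config_focused": config_focused.config_id,
    }
    day0 = pd.DataFrame(day0_rows) if include_day0 else None
    return CohortResult(table, cal, metadata, day0)


def detection_limit_experiment(
    n_seeds: int = 20,
    base_seed: int = 0,
    config: Optional[ScanConfig] = None,
    iron_ng: float = 4.4,
    pellet_cells: float = 1e6,
    per_cell_pg: float = phantoms.PER_CELL_IRON_PG,
) -> np.ndarray:
    """Detection-limit round trip: recover the cell count of a weak node.

    Per seed: fit a calibration line to the default series under the focused
    sequence, measure per-cell iron from a simulated pellet of known cell
    number, then acquire a single ``iron_ng`` node-like source (default
    4.4 ng, the signal of 1,000 cells at 4.4 pg/cell), reconstruct with the
    joint method and quantify it through the full chain.  Returns the
    per-seed cell estimates.
    """
    from .quantify import measure_per_cell_iron

    config = config or ScanConfig.focused_fov()
    estimates = []
    for k in range(n_seeds):
        ss = np.random.SeedSequence([base_seed, k]).generate_state(3)
        line = build_calibration(config, "joint", seed=int(ss[0] % (2 ** 31)))
        pellet = phantoms.make_cell_pellet(
            pellet_cells, per_cell_pg, position=config.fov_center
        )
        praw = acquire_scan(pellet, config, seed=int(ss[1] % (2 ** 31)))
        pimg = reconstruct(praw, "joint")
        measured_per_cell = measure_per_cell_iron(
            pimg, pellet_cells, line, pimg.world_to_index(config.fov_center)
        )
        src = phantoms.make_point_scene(
            iron_ng, label="pLN", position=config.fov_center,
            extent_sigma_mm=phantoms.SOURCE_EXTENT_SIGMA_MM,
        )
        raw = acquire_scan(src, config, seed=int(ss[2] % (2 ** 31)))
        img = reconstruct(raw, "joint")
        rec = _quantify_scene_source(
            img, config.fov_center, line, measured_per_cell,
            [img.world_to_index(config.fov_center)], snr_threshold=5.0,
        )
        estimates.append(rec["cell_estimate"])
    return np.asarray(estimates)


def detection_rate(result: CohortResult, fov_mode: str) -> float:
    """Fraction of pLN passing the SNR gate for one FOV mode."""
    if fov_mode not in FOV_MODES:
        raise ValueError(f"unknown fov_mode {fov_mode!r}")
    sub = result.table[result.table["fov_mode"] == fov_mode]
    if sub.empty:
        raise ValueError(f"no rows for fov_mode {fov_mode!r}")
    return float(sub["detectable"].mean())


def regress_invivo_exvivo(result: CohortResult, fov_mode: str) -> tuple[float, float, float]:
    """OLS of in-vivo cell estimates on matched ex-vivo estimates.

    Restricted to (mouse, side) pairs detectable under both the in-vivo mode
    and ex vivo.  Returns ``(slope, intercept, r2)``; raises with fewer than
    two pairs or a constant ex-vivo column.
    """
    if fov_mode not in ("full12", "focused2"):
        raise ValueError("fov_mode must be an in-vivo mode ('full12' or 'focused2')")
    t = result.table
    inv = t[(t["fov_mode"] == fov_mode) & t["detectable"]]
    exv = t[(t["fov_mode"] == "exvivo") & t["detectable"]]
    merged = inv.merge(exv, on=["mouse", "side"], suffixes=("_inv", "_ex"))
    if len(merged) < 2:
        raise ValueError("need at least two detectable in-vivo/ex-vivo pairs")
    x = merged["cell_estimate_ex"].to_numpy(dtype=float)
    y = merged["cell_estimate_inv"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("ex-vivo estimates are constant; regression degenerate")
    fit = linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue ** 2)


def area_fraction(section: np.ndarray, ln_mask: np.ndarray) -> float:
    """Morphometric readout: positive pixels inside the node mask / mask area."""
    section = np.asarray(section, dtype=bool)
    ln_mask = np.asarray(ln_mask, dtype=bool)
    if section.shape != ln_mask.shape:
        raise ValueError("section and mask shapes differ")
    area = int(ln_mask.sum())
    if area == 0:
        raise ValueError("lymph-node mask is empty")
    return float((section & ln_mask).sum() / area)
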