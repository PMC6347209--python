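"""End-to-end orchestration: read → recalibrate → TIC → extract → line scan.

Defaults reproduce the standard whole-eye protocol: extraction of the
protonated atropine ion (m/z 290.17507) within a 0.0009-Da full-width
window, single-point lock-mass recalibration on the sodiated CHCA matrix
peak, TIC normalization over the m/z 200–310 acquisition range, 200-μm ROIs
every 400 μm of arc length from the corneal apex, and two-sided
Mann-Whitney comparisons at α = 0.05 / 0.01.  Identical config + seed
yields byte-identical TSV outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from . import __version__ as _pkg_version
from . import images, linescan, masses
from .imzml import MSIDataset, read_imzml, write_imzml
from .phantom import EyePhantomConfig, Hotspot, PhantomGroundTruth, generate_phantom

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "make_fixture"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    Exactly one of ``imzml_path`` or ``phantom`` must be set.  For real data
    the corneal apex and a superior-side hint (physical μm) are user inputs;
    for phantoms they default to the generator's ground truth.
    """

    imzml_path: Optional[str] = None
    phantom: Optional[EyePhantomConfig] = None
    # target ion
    target_formula: str = "C17H23NO3"  # atropine
    target_adduct: str = "[M+H]+"
    target_mz: Optional[float] = None  # overrides formula/adduct when set
    window_full_width_da: float = 0.0009
    # lock mass (CHCA sodium adduct by default)
    lock_formula: str = "C10H7NO3"
    lock_adduct: str = "[M+Na]+"
    lock_mz: Optional[float] = None
    lock_search_full_width_da: float = 0.1
    recalibrate: bool = True
    # normalization
    tic_range: Optional[Tuple[float, float]] = None  # default: acquisition range
    # line scan
    apex_xy: Optional[Tuple[float, float]] = None
    superior_hint_xy: Optional[Tuple[float, float]] = None
    roi_diameter_um: float = 200.0
    roi_spacing_um: float = 400.0
    max_arc_um: float = 14000.0
    simplify_tol_px: float = 1.0
    smooth_window: int = 0
    alpha_levels: Tuple[float, float] = (0.05, 0.01)
    mwu_method: str = "auto"
    # outputs
    outdir: Optional[str] = None
    seed: int = 0

    def resolved_target_mz(self) -> float:
        if self.target_mz is not None:
            return float(self.target_mz)
        return masses.adduct_mz(self.target_formula, self.target_adduct)

    def resolved_lock_mz(self) -> float:
        if self.lock_mz is not None:
            return float(self.lock_mz)
        return masses.adduct_mz(self.lock_formula, self.lock_adduct)


@dataclass
class PipelineResult:
    dataset: MSIDataset
    ion_image: images.IonImage
    boundary: linescan.BoundaryPath
    rois: linescan.ROISeries
    linescan: linescan.LineScanResult
    manifest: Dict[str, object]
    ground_truth: Optional[PhantomGroundTruth] = None


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(type(o).__name__)

    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all stages; write the artifact bundle when ``outdir`` is set."""
    if (config.imzml_path is None) == (config.phantom is None):
        raise ValueError("set exactly one of imzml_path or phantom")

    manifest: Dict[str, object] = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "versions": _versions(),
    }

    # --- stage: input ------------------------------------------------------
    ground_truth: Optional[PhantomGroundTruth] = None
    if config.phantom is not None:
        phantom_cfg = config.phantom
        if phantom_cfg.seed != config.seed:
            phantom_cfg = dataclasses.replace(phantom_cfg, seed=config.seed)
        dataset, ground_truth = generate_phantom(phantom_cfg)
        apex = config.apex_xy or ground_truth.apex_xy
        hint = config.superior_hint_xy or ground_truth.superior_hint_xy
    else:
        dataset = read_imzml(config.imzml_path)
        if config.apex_xy is None or config.superior_hint_xy is None:
            raise ValueError("apex_xy and superior_hint_xy are required for imzML input")
        apex, hint = config.apex_xy, config.superior_hint_xy
    logger.info("stage input: %d pixels, mode=%s, pitch=%.1f μm",
                len(dataset), dataset.mode, dataset.pitch_um)
    manifest["n_pixels"] = len(dataset)

    # --- stage: lock-mass recalibration -----------------------------------
    if config.recalibrate:
        lock = masses.LockMassSpec(
            reference_mz=config.resolved_lock_mz(),
            search_window=masses.MassWindow(
                config.resolved_lock_mz(), config.lock_search_full_width_da
            ),
        )
        recal_spectra = {}
        misses = 0
        for coord, spec in dataset.spectra.items():
            res = masses.lock_mass_recalibrate(spec, lock)
            recal_spectra[coord] = res.spectrum
            misses += not res.anchor_found
        dataset = MSIDataset(
            spectra=recal_spectra,
            mz_range=dataset.mz_range,
            mode=dataset.mode,
            pitch_um=dataset.pitch_um,
            metadata=dataset.metadata,
        )
        logger.info("stage recalibrate: lock m/z %.5f, %d pixel(s) without anchor",
                    lock.reference_mz, misses)
        manifest["lock_mz"] = lock.reference_mz
        manifest["anchor_missing_pixels"] = misses

    # --- stage: TIC + extraction ------------------------------------------
    tic = images.compute_tic(dataset, config.tic_range)
    center = config.resolved_target_mz()
    window = masses.MassWindow(center, config.window_full_width_da)
    ion = images.extract_ion_image(dataset, window, tic)
    logger.info("stage extract: center m/z %.5f, window %.4g Da, %d zero-TIC pixel(s)",
                center, config.window_full_width_da, len(ion.zero_tic_pixels))
    manifest["extraction_center_mz"] = center
    manifest["window_full_width_da"] = config.window_full_width_da
    manifest["zero_tic_pixels"] = len(ion.zero_tic_pixels)

    # --- stage: boundary + ROIs -------------------------------------------
    mask = dataset.occupancy_mask()
    path = linescan.trace_boundary(
        mask, dataset.pitch_um, config.simplify_tol_px, config.smooth_window
    )
    path = linescan.set_origin(path, apex, hint)
    rois = linescan.place_rois(
        path, config.roi_diameter_um, config.roi_spacing_um, config.max_arc_um
    )
    rois = linescan.assign_spots(rois, dataset, ion)
    logger.info("stage rois: perimeter %.0f μm, %d ROI(s) retained",
                path.total_length, len(rois))
    manifest["perimeter_um"] = path.total_length
    manifest["n_rois"] = len(rois)

    # --- stage: superior vs inferior comparison ---------------------------
    result = linescan.compare_symmetric_positions(
        rois, config.alpha_levels, config.mwu_method
    )
    n_tested = sum(c.tested for c in result.positions)
    logger.info("stage compare: %d matched position(s) tested", n_tested)
    manifest["n_positions_tested"] = n_tested

    out = PipelineResult(
        dataset=dataset,
        ion_image=ion,
        boundary=path,
        rois=rois,
        linescan=result,
        manifest=manifest,
        ground_truth=ground_truth,
    )
    if config.outdir:
        _write_bundle(out, config)
    return out


def _versions() -> Dict[str, str]:
    import pandas
    import scipy
    import skimage

    return {
        "oculims": _pkg_version,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "scikit-image": skimage.__version__,
    }


def _write_bundle(result: PipelineResult, config: PipelineConfig) -> None:
    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)
    result.linescan.to_tsv(os.path.join(outdir, "linescan.tsv"))
    images.write_image_tsv(result.ion_image, os.path.join(outdir, "ion_image.tsv"))
    images.write_image_png(result.ion_image, os.path.join(outdir, "ion_image.png"))
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
    logger.info("bundle written to %s", outdir)


def small_phantom_config(seed: int = 7) -> EyePhantomConfig:
    """A miniature eye phantom (≤ 60×50 pixels) for tests and documentation.

    Same structure as the default phantom — corneal layers, lens, vitreous,
    tear-meniscus and conjunctival-sac hotspots with the inferior/superior
    asymmetry — shrunk to a toy eyeball so everything runs in seconds.
    """
    return EyePhantomConfig(
        pitch_um=100.0,
        semi_axis_x_um=2300.0,
        semi_axis_y_um=2000.0,
        margin_um=100.0,
        cornea_arc_extent_um=900.0,
        lens_offset_x_um=600.0,
        lens_semi_axis_x_um=900.0,
        lens_semi_axis_y_um=800.0,
        decay_length_um=1500.0,
        posterior_decay_length_um=500.0,
        decay_changepoint_um=2500.0,
        hotspots=(
            Hotspot(500.0, "inferior", 2500.0, 150.0),
            Hotspot(1100.0, "superior", 1200.0, 200.0),
            Hotspot(2600.0, "inferior", 500.0, 250.0),
            Hotspot(3300.0, "superior", 350.0, 200.0),
        ),
        seed=seed,
    )


def make_fixture(name: str = "small", outdir: str = "fixtures") -> Dict[str, str]:
    """Write a deterministic phantom to disk (imzML/ibd + ground-truth TSV +
    label-map PNG).  ``name`` is ``"small"`` or ``"default"``."""
    import imageio.v3 as iio

    if name == "small":
        cfg = small_phantom_config()
    elif name == "default":
        cfg = EyePhantomConfig(seed=7)
    else:
        raise ValueError(f"unknown fixture {name!r}")
    os.makedirs(outdir, exist_ok=True)
    dataset, gt = generate_phantom(cfg)
    imzml_path = os.path.join(outdir, f"phantom_{name}.imzML")
    write_imzml(dataset, imzml_path, deterministic_uuid=True)
    gt_path = os.path.join(outdir, f"phantom_{name}_field.tsv")
    np.savetxt(gt_path, gt.field, fmt="%.6g", delimiter="\t")
    label_path = os.path.join(outdir, f"phantom_{name}_labels.png")
    iio.imwrite(label_path, (gt.labels.astype(np.uint16) * (65535 // 7)))
    return {"imzml": imzml_path, "field_tsv": gt_path, "labels_png": label_path}
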