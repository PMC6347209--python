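"""Synthetic whole-eye MSI phantoms with known ground truth.

The phantom emulates a sagittal whole-eye cryosection imaged by MALDI: an
elliptical eyeball outline whose outer 500-μm shell is cornea (three layers:
epithelium, stroma, endothelium) near the apex and sclera elsewhere, a lens,
an anterior chamber, and a vitreous body.  A topically applied drug-like ion
(default: protonated atropine, m/z 290.17507) decays exponentially with arc
length from the corneal apex along both the superior and inferior margins,
with Gaussian arc-length hotspots at the tear menisci and conjunctival sacs,
a decay-constant changepoint where the tissue re-enters the orbit (the sharp
posterior decline), a low uniform level in the anterior chamber, and zero
signal in the lens and vitreous.  Background matrix peaks, including the
sodiated CHCA lock-mass anchor, are present in every scanned pixel.

Stochastic components (one seeded generator, draws in a fixed order): a
per-pixel additive mass-axis drift shared by all peaks of a spectrum,
multiplicative log-normal intensity noise per peak, and an additive
exponential noise floor.  The same seed reproduces the dataset bit-exactly.

Default arc landmarks (μm from the apex) follow the anatomy of a rabbit eye
after eyedrop instillation: inferior tear meniscus ~2 000 (10–30 × 10²
band), superior tear meniscus ~4 500 (30–60 × 10²), inferior conjunctival
sac ~10 500 (90–120 × 10²), superior conjunctival sac ~13 000
(120–140 × 10²), with the sharp decline starting at 10 000.  The inferior
tear-meniscus hotspot is the largest (gravity pools the instilled drop in
the lower meniscus and conjunctival sac).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from functools import lru_cache
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt

from . import masses
from .imzml import MSIDataset, Spectrum

__all__ = [
    "Hotspot",
    "EyePhantomConfig",
    "PhantomGroundTruth",
    "LABELS",
    "generate_phantom",
    "expected_profile",
]

#: Compartment label codes used in the ground-truth label map.
LABELS: Dict[str, int] = {
    "background": 0,
    "cornea_epithelium": 1,
    "cornea_stroma": 2,
    "cornea_endothelium": 3,
    "sclera": 4,
    "anterior_chamber": 5,
    "lens": 6,
    "vitreous": 7,
}


@dataclass(frozen=True)
class Hotspot:
    """Gaussian arc-length accumulation site on one branch."""

    arc_center_um: float
    branch: str  # "superior" | "inferior"
    amplitude: float  # a.u., added to the surface field at the hotspot centre
    width_um: float  # Gaussian sigma


def _default_hotspots() -> Tuple[Hotspot, ...]:
    return (
        Hotspot(2000.0, "inferior", 2500.0, 400.0),   # lower tear meniscus (largest)
        Hotspot(4500.0, "superior", 1200.0, 600.0),   # upper tear meniscus
        Hotspot(10500.0, "inferior", 500.0, 700.0),   # lower conjunctival sac
        Hotspot(13000.0, "superior", 350.0, 600.0),   # upper conjunctival sac
    )


@dataclass(frozen=True)
class EyePhantomConfig:
    """Full generative specification of an eye-section phantom.

    All lengths in μm, intensities in arbitrary units.  The lens and
    vitreous drug amplitudes are structurally zero and not configurable.
    """

    # grid / geometry
    pitch_um: float = 50.0
    semi_axis_x_um: float = 8500.0  # anterior-posterior (apex on the +x side)
    semi_axis_y_um: float = 7800.0  # superior-inferior (superior = smaller y)
    margin_um: float = 200.0
    epithelium_um: float = 100.0
    stroma_um: float = 300.0
    endothelium_um: float = 100.0
    cornea_arc_extent_um: float = 3500.0
    lens_offset_x_um: float = 2500.0
    lens_semi_axis_x_um: float = 3000.0
    lens_semi_axis_y_um: float = 2800.0
    # drug field
    surface_amplitude: float = 1000.0
    decay_length_um: float = 6000.0
    posterior_decay_length_um: float = 2000.0
    decay_changepoint_um: float = 10000.0
    anterior_chamber_fraction: float = 0.03
    epithelium_multiplier: float = 1.0
    stroma_multiplier: float = 0.8
    endothelium_multiplier: float = 0.15
    sclera_multiplier: float = 0.6
    hotspots: Tuple[Hotspot, ...] = dc_field(default_factory=_default_hotspots)
    # spectra
    target_mz: Optional[float] = None  # default: atropine [M+H]+
    background_peaks: Optional[Tuple[Tuple[float, float], ...]] = None
    mz_range: Tuple[float, float] = (200.0, 310.0)
    # noise
    mass_drift_sigma_da: float = 0.0005  # clipped at ±4 sigma
    noise_sigma_log: float = 0.3
    noise_floor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_mz is None:
            object.__setattr__(
                self, "target_mz", masses.adduct_mz("C17H23NO3", "[M+H]+")
            )
        if self.background_peaks is None:
            object.__setattr__(
                self,
                "background_peaks",
                (
                    (masses.adduct_mz("C10H7NO3", "[M+Na]+"), 800.0),  # CHCA lock mass
                    (234.1, 120.0),
                    (250.5, 300.0),
                    (272.2, 150.0),
                    (304.8, 90.0),
                ),
            )
        self.validate()

    @property
    def shell_thickness_um(self) -> float:
        return self.epithelium_um + self.stroma_um + self.endothelium_um

    def validate(self) -> None:
        if min(self.pitch_um, self.semi_axis_x_um, self.semi_axis_y_um) <= 0:
            raise ValueError("pitch and semi-axes must be positive")
        if min(self.epithelium_um, self.stroma_um, self.endothelium_um) <= 0:
            raise ValueError("corneal layer thicknesses must be positive")
        if self.shell_thickness_um >= min(self.semi_axis_x_um, self.semi_axis_y_um):
            raise ValueError("tissue shell layers exceed the eyeball radius")
        if (
            self.lens_offset_x_um + self.lens_semi_axis_x_um
            > self.semi_axis_x_um - self.shell_thickness_um
            or self.lens_semi_axis_y_um
            > self.semi_axis_y_um - self.shell_thickness_um
        ):
            raise ValueError("lens does not fit inside the eyeball interior")
        if self.decay_length_um <= 0 or self.posterior_decay_length_um <= 0:
            raise ValueError("decay lengths must be positive")
        for m in (
            self.epithelium_multiplier,
            self.stroma_multiplier,
            self.endothelium_multiplier,
            self.sclera_multiplier,
        ):
            if m < 0:
                raise ValueError("layer multipliers must be >= 0")
        for hs in self.hotspots:
            if hs.branch not in ("superior", "inferior"):
                raise ValueError(f"unknown hotspot branch {hs.branch!r}")
            if hs.width_um <= 0:
                raise ValueError("hotspot width must be positive")
        lo, hi = self.mz_range
        peaks = [self.target_mz] if self.target_mz is not None else []
        if self.background_peaks is not None:
            peaks += [mz for mz, _amp in self.background_peaks]
        for mz in peaks:
            if not (lo <= mz <= hi):
                raise ValueError(
                    f"peak at m/z {mz} lies outside the acquisition range [{lo}, {hi}]"
                )

    def _geometry_key(self) -> tuple:
        return (
            self.pitch_um,
            self.semi_axis_x_um,
            self.semi_axis_y_um,
            self.margin_um,
            self.epithelium_um,
            self.stroma_um,
            self.endothelium_um,
            self.cornea_arc_extent_um,
            self.lens_offset_x_um,
            self.lens_semi_axis_x_um,
            self.lens_semi_axis_y_um,
        )


@dataclass
class _Geometry:
    nx: int
    ny: int
    cx: float
    cy: float
    X: np.ndarray
    Y: np.ndarray
    inside: np.ndarray
    labels: np.ndarray
    arc_um: np.ndarray  # |arc| of nearest boundary point, defined everywhere
    branch: np.ndarray  # +1 superior, -1 inferior
    t_grid: np.ndarray  # ellipse parameter for arc<->parameter interpolation
    s_grid: np.ndarray
    perimeter_um: float


@lru_cache(maxsize=8)
def _geometry_from_key(key: tuple) -> _Geometry:
    (
        pitch,
        a,
        b,
        margin,
        epi,
        stroma,
        endo,
        cornea_extent,
        lens_dx,
        lens_a,
        lens_b,
    ) = key
    shell = epi + stroma + endo
    nx = int(round(2 * (a + margin) / pitch)) + 1
    ny = int(round(2 * (b + margin) / pitch)) + 1
    cx = (nx - 1) / 2.0 * pitch
    cy = (ny - 1) / 2.0 * pitch
    xs = np.arange(nx) * pitch
    ys = np.arange(ny) * pitch
    X, Y = np.meshgrid(xs, ys)
    ex = (X - cx) / a
    ey = (Y - cy) / b
    inside = ex**2 + ey**2 <= 1.0

    # arc length along the ellipse from the apex (+x), by cumulative quadrature
    t_grid = np.linspace(0.0, math.pi, 4097)
    integrand = np.sqrt((a * np.sin(t_grid)) ** 2 + (b * np.cos(t_grid)) ** 2)
    s_grid = np.concatenate(
        [[0.0], np.cumsum((integrand[1:] + integrand[:-1]) / 2.0 * np.diff(t_grid))]
    )
    t_pix = np.arctan2(np.abs(ey), ex)  # fold branches together; t in [0, pi]
    arc = np.interp(t_pix, t_grid, s_grid)
    branch = np.where(Y < cy, 1, -1).astype(np.int8)  # superior is up (smaller y)

    depth_um = distance_transform_edt(inside) * pitch
    shell_mask = inside & (depth_um <= shell + 1e-9)
    cornea = shell_mask & (arc <= cornea_extent)
    labels = np.zeros((ny, nx), dtype=np.int8)
    labels[shell_mask] = LABELS["sclera"]
    labels[cornea & (depth_um <= epi)] = LABELS["cornea_epithelium"]
    labels[cornea & (depth_um > epi) & (depth_um <= epi + stroma)] = LABELS[
        "cornea_stroma"
    ]
    labels[cornea & (depth_um > epi + stroma)] = LABELS["cornea_endothelium"]
    interior = inside & ~shell_mask
    lens = ((X - cx - lens_dx) / lens_a) ** 2 + ((Y - cy) / lens_b) ** 2 <= 1.0
    labels[interior & lens] = LABELS["lens"]
    ac = interior & ~lens & (X - cx >= lens_dx + 0.5 * lens_a)
    labels[ac] = LABELS["anterior_chamber"]
    vit = interior & ~lens & ~ac
    labels[vit] = LABELS["vitreous"]

    return _Geometry(
        nx=nx,
        ny=ny,
        cx=cx,
        cy=cy,
        X=X,
        Y=Y,
        inside=inside,
        labels=labels,
        arc_um=arc,
        branch=branch,
        t_grid=t_grid,
        s_grid=s_grid,
        perimeter_um=2.0 * float(s_grid[-1]),
    )


def _geometry(config: EyePhantomConfig) -> _Geometry:
    return _geometry_from_key(config._geometry_key())


def surface_field(
    config: EyePhantomConfig, arc_um: np.ndarray, branch: np.ndarray
) -> np.ndarray:
    """Noiseless drug intensity at the tissue surface vs |arc| and branch.

    Piecewise-exponential decay from the apex (continuous at the
    changepoint) plus branch-specific Gaussian hotspots.
    """
    s = np.asarray(arc_um, dtype=np.float64)
    lam1 = config.decay_length_um
    lam2 = config.posterior_decay_length_um
    cp = config.decay_changepoint_um
    base = np.where(
        s <= cp,
        np.exp(-s / lam1),
        math.exp(-cp / lam1) * np.exp(-(s - cp) / lam2),
    )
    out = config.surface_amplitude * base
    for hs in config.hotspots:
        sign = 1 if hs.branch == "superior" else -1
        on_branch = np.asarray(branch) == sign
        out = out + np.where(
            on_branch,
            hs.amplitude * np.exp(-((s - hs.arc_center_um) ** 2) / (2 * hs.width_um**2)),
            0.0,
        )
    return out


def drug_field(config: EyePhantomConfig) -> np.ndarray:
    """Noiseless per-pixel drug intensity over the full grid (the ground truth)."""
    geo = _geometry(config)
    surf = surface_field(config, geo.arc_um, geo.branch)
    mult = np.zeros_like(surf)
    lab = geo.labels
    mult[lab == LABELS["cornea_epithelium"]] = config.epithelium_multiplier
    mult[lab == LABELS["cornea_stroma"]] = config.stroma_multiplier
    mult[lab == LABELS["cornea_endothelium"]] = config.endothelium_multiplier
    mult[lab == LABELS["sclera"]] = config.sclera_multiplier
    field = surf * mult
    field[lab == LABELS["anterior_chamber"]] = (
        config.surface_amplitude * config.anterior_chamber_fraction
    )
    # lens and vitreous carry no drug, by construction
    field[lab == LABELS["lens"]] = 0.0
    field[lab == LABELS["vitreous"]] = 0.0
    field[lab == LABELS["background"]] = 0.0
    return field


@dataclass
class PhantomGroundTruth:
    """Everything the generator knows: noiseless field, labels, landmarks."""

    config: EyePhantomConfig
    field: np.ndarray  # (ny, nx) noiseless drug intensity
    labels: np.ndarray  # (ny, nx) compartment codes, see LABELS
    mask: np.ndarray  # (ny, nx) scanned-pixel mask
    arc_um: np.ndarray
    branch: np.ndarray
    apex_xy: Tuple[float, float]  # physical μm
    superior_hint_xy: Tuple[float, float]
    background_total: float  # per-pixel noiseless background TIC
    perimeter_um: float

    def noiseless_tic(self) -> np.ndarray:
        tic = np.where(self.mask, self.background_total + self.field, 0.0)
        return tic

    def normalized_field(self) -> np.ndarray:
        """Noiseless TIC-normalized drug value per scanned pixel."""
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(self.mask, self.field / (self.background_total + self.field), 0.0)
        return out


def generate_phantom(
    config: EyePhantomConfig,
) -> Tuple[MSIDataset, PhantomGroundTruth]:
    """Generate the phantom dataset and its ground truth.

    Only tissue pixels (inside the eyeball outline) are scanned; the rest of
    the grid is absent, like regions outside the drawn measurement area.
    A fixed seed yields a bit-identical dataset.
    """
    geo = _geometry(config)
    field = drug_field(config)
    rng = np.random.default_rng(config.seed)

    iy, ix = np.nonzero(geo.inside)
    n = len(ix)
    truth = field[iy, ix]

    bg = np.asarray(config.background_peaks, dtype=np.float64)
    all_mz = np.concatenate([bg[:, 0], [float(config.target_mz)]])
    all_amp = np.concatenate([bg[:, 1], [0.0]])
    order = np.argsort(all_mz)
    base_mz = all_mz[order]
    target_col = int(np.nonzero(order == len(all_mz) - 1)[0][0])
    amp = np.tile(all_amp[order], (n, 1))
    amp[:, target_col] = truth

    # stochastic draws, fixed order: (1) drift, (2) multiplicative, (3) floor
    sigma_d = config.mass_drift_sigma_da
    drift = (
        np.clip(rng.normal(0.0, sigma_d, size=n), -4 * sigma_d, 4 * sigma_d)
        if sigma_d > 0
        else np.zeros(n)
    )
    if config.noise_sigma_log > 0:
        amp = amp * np.exp(rng.normal(0.0, config.noise_sigma_log, size=amp.shape))
    if config.noise_floor > 0:
        amp = amp + config.noise_floor * rng.exponential(size=amp.shape)

    spectra = {}
    amp32 = amp.astype(np.float32)
    for i in range(n):
        coord = (int(ix[i]) + 1, int(iy[i]) + 1)
        spectra[coord] = Spectrum(base_mz + drift[i], amp32[i])

    dataset = MSIDataset(
        spectra=spectra,
        mz_range=config.mz_range,
        mode="processed",
        pitch_um=config.pitch_um,
        metadata={"polarity": "positive", "phantom_seed": config.seed},
    )
    a, b = config.semi_axis_x_um, config.semi_axis_y_um
    gt = PhantomGroundTruth(
        config=config,
        field=field,
        labels=geo.labels,
        mask=geo.inside,
        arc_um=geo.arc_um,
        branch=geo.branch,
        apex_xy=(geo.cx + a, geo.cy),
        superior_hint_xy=(geo.cx, geo.cy - b),
        background_total=float(bg[:, 1].sum()),
        perimeter_um=geo.perimeter_um,
    )
    return dataset, gt


def expected_profile(
    config: EyePhantomConfig,
    diameter_um: float = 200.0,
    spacing_um: float = 400.0,
    max_arc_um: float = 14000.0,
    normalized: bool = True,
) -> pd.DataFrame:
    """Oracle line-scan profile from the analytic field (no pipeline involved).

    ROI centres are placed on the *analytic* ellipse at exact arc positions
    (the ellipse arc-length integral is inverted by interpolation); each
    expected mean averages the noiseless (optionally TIC-normalized) field
    over scanned pixel centres within the ROI disk.

    Returns a frame with columns ``arc_um``, ``branch``, ``expected_mean``,
    ``n_spots``.
    """
    geo = _geometry(config)
    field = drug_field(config)
    if normalized:
        bg_total = float(np.asarray(config.background_peaks)[:, 1].sum())
        value = field / (bg_total + field)
    else:
        value = field
    iy, ix = np.nonzero(geo.inside)
    px = geo.X[iy, ix]
    py = geo.Y[iy, ix]
    pv = value[iy, ix]

    a, b = config.semi_axis_x_um, config.semi_axis_y_um
    radius = diameter_um / 2.0
    rows = []
    n_positions = int(math.floor(max_arc_um / spacing_um + 1e-9))
    for k in range(0, n_positions + 1):
        s = k * spacing_um
        t = float(np.interp(s, geo.s_grid, geo.t_grid))
        for branch, ysign in (("superior", -1.0), ("inferior", 1.0)):
            cxy = (geo.cx + a * math.cos(t), geo.cy + ysign * b * math.sin(t))
            d2 = (px - cxy[0]) ** 2 + (py - cxy[1]) ** 2
            members = d2 <= radius**2
            if not members.any():
                continue
            rows.append(
                {
                    "arc_um": float(s),
                    "branch": "apex" if k == 0 else branch,
                    "expected_mean": float(pv[members].mean()),
                    "n_spots": int(members.sum()),
                }
            )
            if k == 0:
                break  # the apex ROI is shared between branches
    return pd.DataFrame(rows)
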