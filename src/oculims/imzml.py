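"""imzML input/output and in-memory containers for mass-spectrometry-imaging data.

An MSI dataset is a collection of mass spectra indexed by raster pixel
coordinates (1-based, per the imzML convention).  Physical positions are
derived as ``(index - 1) * pitch_um``.  Pixels that were never scanned
(e.g. regions previously ablated by the laser) are simply absent from the
collection; downstream operations tolerate absent pixels.

Reading and writing delegate to :mod:`pyimzml`; this module adds pixel-pitch
metadata, UUID consistency checking between the XML and the binary (ibd)
companion file, and dataset validation.
"""

from __future__ import annotations

import math
import os
import re
import uuid as _uuid
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np

__all__ = [
    "Spectrum",
    "MSIDataset",
    "ImzMLError",
    "read_imzml",
    "write_imzml",
    "validate_dataset",
]

Coord = Tuple[int, int]


class ImzMLError(RuntimeError):
    """Raised for malformed, inconsistent, or unreadable imzML/ibd input."""


@dataclass
class Spectrum:
    """One centroided mass spectrum: m/z values (Da, ascending) and intensities.

    m/z is stored as float64 and intensity as float32, matching the on-disk
    encoding, so a write/read round trip is bit-exact.
    """

    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float32)
        if self.mz.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("spectrum arrays must be one-dimensional")
        if self.mz.shape[0] != self.intensity.shape[0]:
            raise ValueError(
                f"m/z and intensity lengths differ ({self.mz.shape[0]} vs "
                f"{self.intensity.shape[0]})"
            )

    def __len__(self) -> int:
        return int(self.mz.shape[0])

    def __eq__(self, other: object) -> bool:  # value equality, for round-trip tests
        if not isinstance(other, Spectrum):
            return NotImplemented
        return bool(
            np.array_equal(self.mz, other.mz)
            and np.array_equal(self.intensity, other.intensity)
        )


@dataclass
class MSIDataset:
    """Pixel-indexed collection of mass spectra.

    Parameters
    ----------
    spectra
        Mapping from 1-based ``(x, y)`` pixel coordinates to :class:`Spectrum`.
    mz_range
        Acquisition mass range ``(low, high)`` in Da.
    mode
        imzML storage mode, ``"continuous"`` (shared m/z axis) or
        ``"processed"`` (per-pixel peak lists).
    pitch_um
        Physical center-to-center pixel spacing in micrometres.
    metadata
        Free-form acquisition metadata (polarity, instrument notes, ...).
    """

    spectra: Dict[Coord, Spectrum]
    mz_range: Tuple[float, float] = (200.0, 310.0)
    mode: str = "processed"
    pitch_um: float = 100.0
    metadata: Dict[str, object] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.spectra)

    def coordinates(self) -> List[Coord]:
        return list(self.spectra.keys())

    def physical_xy(self, coord: Coord) -> Tuple[float, float]:
        """Physical position (μm) of a pixel center; 1-based indices map to 0 μm."""
        x, y = coord
        return ((x - 1) * self.pitch_um, (y - 1) * self.pitch_um)

    def grid_shape(self) -> Tuple[int, int]:
        """(ny, nx) extent of the coordinate grid (max indices)."""
        if not self.spectra:
            return (0, 0)
        xs = [c[0] for c in self.spectra]
        ys = [c[1] for c in self.spectra]
        return (max(ys), max(xs))

    def occupancy_mask(self) -> np.ndarray:
        """Boolean (ny, nx) array, True where a pixel was scanned."""
        ny, nx = self.grid_shape()
        mask = np.zeros((ny, nx), dtype=bool)
        for x, y in self.spectra:
            mask[y - 1, x - 1] = True
        return mask

    def iter_items(self) -> Iterator[Tuple[Coord, Spectrum]]:
        return iter(self.spectra.items())


def _normalize_uuid(text: str) -> str:
    return re.sub(r"[{}\-]", "", text).upper()


def read_imzml(path: str, pitch_um: Optional[float] = None) -> MSIDataset:
    """Read an imzML file (and its ibd companion) into an :class:`MSIDataset`.

    Parameters
    ----------
    path
        Path to the ``.imzML`` XML file; the binary ``.ibd`` must sit next to it.
    pitch_um
        Pixel pitch override, used when the file carries no
        ``pixel size x`` scan setting.

    Raises
    ------
    ImzMLError
        Missing ibd, malformed XML, UUID mismatch between XML and ibd,
        duplicated pixel coordinates, or missing pitch information.
    """
    from lxml import etree
    from pyimzml.ImzMLParser import ImzMLParser

    ibd_path = os.path.splitext(path)[0] + ".ibd"
    if not os.path.exists(path):
        raise ImzMLError(f"imzML file not found: {path}")
    if not os.path.exists(ibd_path):
        raise ImzMLError(f"ibd companion file not found: {ibd_path}")

    from xml.etree.ElementTree import ParseError

    try:
        parser = ImzMLParser(path)
    except (etree.XMLSyntaxError, ParseError, SyntaxError) as exc:
        raise ImzMLError(f"malformed imzML XML in {path}: {exc}") from exc

    # UUID declared in the XML must match the first 16 bytes of the ibd.
    declared = None
    try:
        declared = parser.metadata.file_description.cv_params
    except AttributeError:
        pass
    declared_uuid = None
    mode = "processed"
    if declared:
        for name, _accession, value, *_rest in declared:
            if name == "universally unique identifier":
                declared_uuid = str(value)
            elif name in ("continuous", "processed"):
                mode = name
    with open(ibd_path, "rb") as fh:
        ibd_uuid = _uuid.UUID(bytes=fh.read(16))
    if declared_uuid is not None:
        if _normalize_uuid(declared_uuid) != _normalize_uuid(str(ibd_uuid)):
            raise ImzMLError(
                f"ibd UUID {ibd_uuid} does not match the UUID declared in "
                f"{path} ({declared_uuid})"
            )

    if pitch_um is None:
        pitch_um = parser.imzmldict.get("pixel size x")
    if pitch_um is None:
        raise ImzMLError(
            f"{path} carries no 'pixel size x' scan setting; pass pitch_um"
        )

    spectra: Dict[Coord, Spectrum] = {}
    lo, hi = math.inf, -math.inf
    for i, (x, y, _z) in enumerate(parser.coordinates):
        coord = (int(x), int(y))
        if coord in spectra:
            raise ImzMLError(f"duplicate pixel coordinate {coord} in {path}")
        mz, inten = parser.getspectrum(i)
        spectra[coord] = Spectrum(mz, inten)
        if len(mz):
            lo = min(lo, float(mz[0]))
            hi = max(hi, float(mz[-1]))

    meta: Dict[str, object] = {"source_path": path}
    if not spectra or lo is math.inf:
        mz_range = (0.0, 0.0)
    else:
        mz_range = (lo, hi)
    return MSIDataset(
        spectra=spectra,
        mz_range=mz_range,
        mode=mode,
        pitch_um=float(pitch_um),
        metadata=meta,
    )


def _inject_pixel_size(path: str, pitch_um: float) -> None:
    """Add IMS pixel-size cvParams to the scanSettings element of an imzML file,
    and normalize the run id to the file basename (path-independent output)."""
    from lxml import etree

    tree = etree.parse(path)
    root = tree.getroot()
    ns = {"mz": root.nsmap.get(None, "")}
    run = root.find(".//mz:run", ns)
    if run is not None:
        run.set("id", os.path.splitext(os.path.basename(path))[0])
    settings = root.findall(".//mz:scanSettings", ns)
    if not settings:
        tree.write(path, xml_declaration=True, encoding="ISO-8859-1")
        return
    for accession, name in (
        ("IMS:1000046", "pixel size (x)"),
        ("IMS:1000047", "pixel size y"),
    ):
        el = etree.SubElement(settings[0], f"{{{ns['mz']}}}cvParam")
        el.set("cvRef", "IMS")
        el.set("accession", accession)
        el.set("name", name)
        el.set("value", repr(float(pitch_um)))
    tree.write(path, xml_declaration=True, encoding="ISO-8859-1")


def _content_uuid(dataset: MSIDataset) -> _uuid.UUID:
    """UUID derived from the dataset content, for reproducible fixtures."""
    import hashlib

    digest = hashlib.sha256()
    for (x, y) in sorted(dataset.spectra, key=lambda c: (c[1], c[0])):
        spec = dataset.spectra[(x, y)]
        digest.update(f"{x},{y};".encode())
        digest.update(spec.mz.tobytes())
        digest.update(spec.intensity.tobytes())
    return _uuid.UUID(bytes=digest.digest()[:16], version=4)


def write_imzml(dataset: MSIDataset, path: str, deterministic_uuid: bool = False) -> str:
    """Write a dataset as imzML + ibd (64-bit m/z, 32-bit intensity).

    The dataset's own ``mode`` is used (``processed`` by default).  A
    write→read round trip reproduces all m/z values, intensities and
    coordinates bit-exactly.  With ``deterministic_uuid`` the file UUID is
    derived from the content, so regenerating an identical dataset yields a
    byte-identical file pair (versioned fixtures).

    Returns the imzML path written.
    """
    import pyimzml.ImzMLWriter as _writer_mod
    from pyimzml.ImzMLWriter import ImzMLWriter

    if len(dataset) == 0:
        raise ValueError("refusing to write an empty dataset")
    mode = dataset.mode if dataset.mode in ("continuous", "processed") else "processed"
    polarity = dataset.metadata.get("polarity", "positive")
    directory = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(directory):
        raise ImzMLError(f"output directory does not exist: {directory}")
    orig_uuid4 = _writer_mod.uuid.uuid4
    if deterministic_uuid:
        fixed = _content_uuid(dataset)
        _writer_mod.uuid.uuid4 = lambda: fixed
    try:
        with ImzMLWriter(
            path,
            mz_dtype=np.float64,
            intensity_dtype=np.float32,
            mode=mode,
            polarity=str(polarity),
        ) as writer:
            # sort for a stable, viewer-friendly pixel order
            for (x, y) in sorted(dataset.spectra, key=lambda c: (c[1], c[0])):
                spec = dataset.spectra[(x, y)]
                writer.addSpectrum(spec.mz, spec.intensity, (x, y, 1))
    except OSError as exc:
        raise ImzMLError(f"cannot write {path}: {exc}") from exc
    finally:
        _writer_mod.uuid.uuid4 = orig_uuid4
    _inject_pixel_size(path, dataset.pitch_um)
    return path


def validate_dataset(dataset: MSIDataset) -> List[str]:
    """Check type invariants; returns a list of human-readable violations.

    Reported rules: m/z strictly ascending, intensities non-negative,
    spectra within the declared mass range, positive pitch, valid 1-based
    coordinates, and (continuous mode) a shared m/z axis.
    """
    violations: List[str] = []
    if dataset.pitch_um <= 0:
        violations.append(f"pitch_um must be positive, got {dataset.pitch_um}")
    lo, hi = dataset.mz_range
    axis: Optional[np.ndarray] = None
    for coord, spec in dataset.spectra.items():
        x, y = coord
        if x < 1 or y < 1:
            violations.append(f"pixel {coord}: coordinates must be >= 1")
        if len(spec) == 0:
            continue
        if np.any(np.diff(spec.mz) <= 0):
            violations.append(f"pixel {coord}: m/z values not strictly ascending")
        if np.any(spec.intensity < 0):
            violations.append(f"pixel {coord}: negative intensity")
        if float(spec.mz[0]) < lo - 1e-9 or float(spec.mz[-1]) > hi + 1e-9:
            violations.append(
                f"pixel {coord}: m/z outside declared range [{lo}, {hi}]"
            )
        if dataset.mode == "continuous":
            if axis is None:
                axis = spec.mz
            elif not np.array_equal(axis, spec.mz):
                violations.append(
                    f"pixel {coord}: continuous-mode spectra must share one m/z axis"
                )
    return violations
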