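"""Image and ROI file I/O.

The intraoperative and macroscopic cameras store raw counts as FITS
(Flexible Image Transport System) primary HDUs; flatbed scans of FFPE
blocks and sections are single-channel 16-bit TIFF.  Label maps travel
as 8-bit TIFF with the tissue code map embedded in the description tag,
and hand-drawn ROIs as JSON polygon files rasterized with a
pixel-center even-odd rule.

The FITS support here is a deliberately minimal reader/writer for the
subset this pipeline emits: a single 2D primary HDU, BITPIX 16 with the
unsigned convention (BZERO 32768), and the header dialect LEVEL / EXPMS
/ GAIN / PATID / SLICE / PIXSZMM.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .core import TISSUE_CODES, FluorImage, TissueLabelMap

FITS_BLOCK = 2880
_HEADER_KEYS = {"LEVEL": "level", "EXPMS": "exposure_ms", "GAIN": "gain",
                "PATID": "patient_id", "SLICE": "slice_index", "PIXSZMM": "pixel_size_mm"}


@dataclass
class RoiSet:
    """Named polygon regions of interest indexing one image.

    Vertices are 0-based (row, col) with origin top-left; polygons close
    implicitly (last vertex joins the first).
    """

    rois: list[dict] = field(default_factory=list)
    image_ref: str | None = None

    def __post_init__(self) -> None:
        for roi in self.rois:
            poly = roi["polygon"]
            if len(poly) < 3:
                raise ValueError(f"ROI {roi.get('name')!r} has fewer than 3 vertices")
            if roi["tissue_class"] not in TISSUE_CODES:
                raise ValueError(f"ROI {roi.get('name')!r} has unknown tissue class")


# ------------------------------------------------------------------- FITS

def _fits_card(key: str, value) -> bytes:
    if isinstance(value, str):
        v = f"'{value:<8s}'"
    elif isinstance(value, bool):
        v = "T" if value else "F"
    elif isinstance(value, (int, np.integer)):
        v = str(int(value))
    else:
        v = repr(float(value))
    return f"{key:<8s}= {v:>20s}".ljust(80).encode("ascii")


def _write_fits(image: FluorImage, path: Path) -> None:
    data = image.counts
    cards = [
        _fits_card("SIMPLE", True),
        _fits_card("BITPIX", 16),
        _fits_card("NAXIS", 2),
        _fits_card("NAXIS1", data.shape[1]),
        _fits_card("NAXIS2", data.shape[0]),
        _fits_card("BZERO", 32768),
        _fits_card("BSCALE", 1),
    ]
    for key, attr in _HEADER_KEYS.items():
        val = getattr(image, attr)
        if val is not None:
            cards.append(_fits_card(key, val))
    cards.append(b"END".ljust(80))
    header = b"".join(cards)
    header += b" " * (-len(header) % FITS_BLOCK)
    # unsigned convention: stored = physical - BZERO, big-endian int16
    stored = (data.astype(np.int32) - 32768).astype(">i2")
    payload = stored.tobytes()
    payload += b"\x00" * (-len(payload) % FITS_BLOCK)
    path.write_bytes(header + payload)


def _parse_fits_value(raw: str):
    raw = raw.split("/")[0].strip()
    if raw.startswith("'"):
        return raw.strip("'").strip()
    if raw in ("T", "F"):
        return raw == "T"
    try:
        return int(raw)
    except ValueError:
        return float(raw)


def _read_fits(path: Path) -> FluorImage:
    blob = path.read_bytes()
    header: dict[str, object] = {}
    pos = 0
    done = False
    while not done:
        block = blob[pos:pos + FITS_BLOCK]
        if len(block) < FITS_BLOCK:
            raise ValueError(f"corrupt FITS file (truncated header): {path}")
        for i in range(0, FITS_BLOCK, 80):
            card = block[i:i + 80].decode("ascii", errors="replace")
            key = card[:8].strip()
            if key == "END":
                done = True
                break
            if "=" in card[8:10]:
                header[key] = _parse_fits_value(card[10:])
        pos += FITS_BLOCK
    if header.get("BITPIX") != 16 or header.get("NAXIS") != 2:
        raise ValueError(f"unsupported FITS layout (need 2D BITPIX 16): {path}")
    n1, n2 = int(header["NAXIS1"]), int(header["NAXIS2"])  # cols, rows
    count = n1 * n2
    raw = np.frombuffer(blob, dtype=">i2", count=count, offset=pos)
    if raw.size < count:
        raise ValueError(f"corrupt FITS file (truncated data): {path}")
    bzero = int(header.get("BZERO", 0))
    counts = (raw.astype(np.int32) + bzero).reshape(n2, n1)
    if counts.min() < 0 or counts.max() > 65535:
        raise ValueError(f"FITS payload outside unsigned 16-bit range: {path}")
    meta = {attr: header.get(key) for key, attr in _HEADER_KEYS.items()}
    level = meta.pop("level") or "fresh_slice"
    return FluorImage(counts=counts.astype(np.uint16), level=str(level), **meta)


# ------------------------------------------------------------------- TIFF

def _write_tiff(image: FluorImage, path: Path) -> None:
    meta = {attr: getattr(image, attr) for attr in _HEADER_KEYS.values()}
    kwargs = {}
    if image.pixel_size_mm:
        ppcm = 10.0 / image.pixel_size_mm  # pixels per centimeter
        kwargs = {"resolution": (ppcm, ppcm), "resolutionunit": "CENTIMETER"}
    tifffile.imwrite(path, image.counts, description=json.dumps(meta),
                     photometric="minisblack", **kwargs)


def _read_tiff(path: Path) -> FluorImage:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        if data.ndim != 2:
            raise ValueError(f"unsupported TIFF layout (multi-channel or 3D): {path}")
        meta: dict = {}
        desc = page.tags.get("ImageDescription")
        if desc is not None:
            try:
                meta = json.loads(desc.value)
            except (json.JSONDecodeError, TypeError):
                meta = {}
        pixel_size_mm = meta.get("pixel_size_mm")
        xres = page.tags.get("XResolution")
        unit = page.tags.get("ResolutionUnit")
        if pixel_size_mm is None and xres is not None and unit is not None:
            num, den = xres.value
            if num and getattr(unit.value, "name", str(unit.value)).upper().endswith("CENTIMETER"):
                pixel_size_mm = 10.0 * den / num
    if data.dtype != np.uint16:
        if np.issubdtype(data.dtype, np.integer) and data.min() >= 0 and data.max() <= 65535:
            data = data.astype(np.uint16)
        else:
            raise ValueError(f"TIFF payload not 16-bit unsigned counts: {path}")
    return FluorImage(counts=data, level=meta.get("level") or "section",
                      exposure_ms=meta.get("exposure_ms"), gain=meta.get("gain"),
                      patient_id=meta.get("patient_id"),
                      slice_index=meta.get("slice_index"),
                      pixel_size_mm=pixel_size_mm)


# ------------------------------------------------------------------- public API

def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        return format
    suffix = path.suffix.lower()
    if suffix in (".fits", ".fit"):
        return "fits"
    if suffix in (".tif", ".tiff"):
        return "tiff"
    raise ValueError(f"cannot infer image format from {path}")


def read_image(path, format: str | None = None) -> FluorImage:
    """Read a counts image; pixels are preserved bit-exactly.

    Acquisition metadata (level, exposure, gain, provenance) is read from
    the header when present, else left None.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if not path.exists():
        raise FileNotFoundError(path)
    return _read_fits(path) if fmt == "fits" else _read_tiff(path)


def write_image(image: FluorImage, path, format: str | None = None) -> Path:
    """Write a counts image losslessly with its acquisition header."""
    path = Path(path)
    fmt = _infer_format(path, format)
    try:
        if fmt == "fits":
            _write_fits(image, path)
        else:
            _write_tiff(image, path)
    except OSError as exc:
        raise OSError(f"cannot write image to {path}: {exc}") from exc
    return path


def write_label_map(label_map: TissueLabelMap, path) -> Path:
    """Label map as single-channel 8-bit TIFF, code map in the description."""
    path = Path(path)
    tifffile.imwrite(path, label_map.labels.astype(np.uint8),
                     description=json.dumps({"code_map": label_map.code_map}),
                     photometric="minisblack")
    return path


def read_label_map(path) -> TissueLabelMap:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        labels = page.asarray()
        code_map = dict(TISSUE_CODES)
        desc = page.tags.get("ImageDescription")
        if desc is not None:
            try:
                raw = json.loads(desc.value).get("code_map", {})
                code_map = {int(k): v for k, v in raw.items()}
            except (json.JSONDecodeError, TypeError, ValueError):
                pass
    return TissueLabelMap(labels.astype(np.int64), code_map=code_map)


def read_rois(path) -> RoiSet:
    data = json.loads(Path(path).read_text())
    return RoiSet(rois=data["rois"], image_ref=data.get("image_ref"))


def write_rois(rois: RoiSet, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps({"image_ref": rois.image_ref, "rois": rois.rois}, indent=1))
    return path


def _points_in_polygon(points_rc: np.ndarray, polygon: np.ndarray) -> np.ndarray:
    """Vectorized even-odd (ray casting) point-in-polygon test."""
    y, x = points_rc[:, 0], points_rc[:, 1]
    inside = np.zeros(len(points_rc), dtype=bool)
    n = len(polygon)
    for i in range(n):
        y1, x1 = polygon[i]
        y2, x2 = polygon[(i + 1) % n]
        crosses = (y1 > y) != (y2 > y)
        with np.errstate(divide="ignore", invalid="ignore"):
            xi = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (x < np.where(crosses, xi, np.inf))
    return inside


def rasterize_rois(rois: RoiSet, image_shape: tuple[int, int]) -> TissueLabelMap:
    """Rasterize polygons to a label map.

    A pixel belongs to a polygon iff its center lies inside under the
    even-odd rule; later ROIs overwrite earlier ones on overlap; pixels
    touched by no ROI stay 0.  A polygon capturing no pixel centers
    yields an empty region (warning, not an error).
    """
    import warnings

    labels = np.zeros(image_shape, dtype=np.int64)
    rr, cc = np.mgrid[0:image_shape[0], 0:image_shape[1]]
    centers = np.column_stack([rr.ravel().astype(float), cc.ravel().astype(float)])
    for roi in rois.rois:
        poly = np.asarray(roi["polygon"], dtype=float)
        if np.any(poly[:, 0] < -0.5) or np.any(poly[:, 1] < -0.5) \
                or np.any(poly[:, 0] > image_shape[0] - 0.5) \
                or np.any(poly[:, 1] > image_shape[1] - 0.5):
            raise ValueError(f"ROI {roi.get('name')!r} extends outside the image")
        mask = _points_in_polygon(centers, poly).reshape(image_shape)
        if not mask.any():
            warnings.warn(f"ROI {roi.get('name')!r} rasterizes to an empty region",
                          stacklevel=2)
        labels[mask] = roi["tissue_class"]
    return TissueLabelMap(labels)
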