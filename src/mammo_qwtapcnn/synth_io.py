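"""Synthetic mammogram phantoms, PGM image I/O and MIAS-style metadata.

The mini-MIAS distribution ships 8-bit grayscale mammograms as PGM files plus a
seven-column whitespace-delimited metadata table (reference id, background
tissue, abnormality class, severity, abnormality center x/y, radius).  This
module reads and writes both, and generates labelled synthetic phantoms --
an elliptical "breast" on a dark background with an optional bright mass
(smooth disc for benign, spiculated star for malignant) and an optional
pectoral wedge -- so the downstream denoising / segmentation / classification
stages can be exercised end to end without the external dataset.

Every phantom carries its ground-truth mass mask (exactly the pixels whose
intensity the mass painter incremented), a class label, a MIAS-like metadata
record, and nine tabular cytology-style attributes drawn from label-conditional
Gaussians (the classifier's "nine major inputs").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "PGMFormatError",
    "UnsupportedDepthError",
    "MIASParseError",
    "GeometryError",
    "MIASRecord",
    "NoiseSpec",
    "MassParams",
    "Phantom",
    "read_pgm",
    "write_pgm",
    "parse_mias_metadata",
    "format_mias_metadata",
    "generate_phantom",
    "add_noise",
    "save_phantom_dataset",
    "validate_gray_image",
]

TISSUE_CODES = frozenset("FGD")
ABNORMALITY_CODES = frozenset({"CALC", "CIRC", "SPIC", "MISC", "ARCH", "ASYM", "NORM"})
SEVERITY_CODES = frozenset("BM")

#: Number of tabular attributes attached to each phantom (clump thickness,
#: uniformity of cell size/shape, marginal adhesion, single epithelial cell
#: size, bare nuclei, bland chromatin, normal nucleoli, mitoses).
N_ATTRIBUTES = 9

#: Label-conditional attribute means/std-devs on the 1..10 cytology scale.
ATTRIBUTE_DISTRIBUTIONS = {
    "benign": (2.5, 1.2),
    "malignant": (7.0, 1.2),
    "normal": (1.5, 0.8),
}


class PGMFormatError(ValueError):
    """Malformed PGM header or truncated pixel stream."""


class UnsupportedDepthError(ValueError):
    """PGM maxval exceeds 255 (only 8-bit images are supported)."""


class MIASParseError(ValueError):
    """A metadata line could not be interpreted."""


class GeometryError(ValueError):
    """Requested mass does not fit inside the breast ellipse."""


def validate_gray_image(pixels: np.ndarray) -> np.ndarray:
    """Check an array is a valid 8-bit grayscale image and return it as uint8.

    Valid images are 2-D, at least 8x8, with all values in [0, 255].
    """
    arr = np.asarray(pixels)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D array, got shape {arr.shape}")
    if arr.shape[0] < 8 or arr.shape[1] < 8:
        raise ValueError(f"image must be at least 8x8, got {arr.shape}")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("pixel values must lie in [0, 255]")
    return arr.astype(np.uint8)


# ---------------------------------------------------------------------------
# PGM I/O
# ---------------------------------------------------------------------------

def _pgm_header_tokens(data: bytes):
    """Yield (token, end_offset) for whitespace-delimited header tokens,
    skipping '#' comments, starting from offset 0."""
    i = 0
    n = len(data)
    while i < n:
        c = data[i : i + 1]
        if c.isspace():
            i += 1
        elif c == b"#":
            while i < n and data[i : i + 1] not in (b"\n", b"\r"):
                i += 1
        else:
            j = i
            while j < n and not data[j : j + 1].isspace() and data[j : j + 1] != b"#":
                j += 1
            yield data[i:j], j
            i = j


def read_pgm(path) -> np.ndarray:
    """Read a PGM file (ASCII ``P2`` or binary ``P5``, maxval <= 255).

    Returns the pixel array as uint8, row-major with top-left origin.
    """
    data = Path(path).read_bytes()
    tokens = _pgm_header_tokens(data)
    try:
        magic, _ = next(tokens)
    except StopIteration:
        raise PGMFormatError(f"{path}: empty file") from None
    if magic not in (b"P2", b"P5"):
        raise PGMFormatError(f"{path}: bad magic {magic!r} (expected P2 or P5)")
    header = []
    end = 0
    try:
        for _ in range(3):
            tok, end = next(tokens)
            header.append(tok)
    except StopIteration:
        raise PGMFormatError(f"{path}: truncated header") from None
    try:
        width, height, maxval = (int(t) for t in header)
    except ValueError:
        raise PGMFormatError(f"{path}: non-integer header fields {header}") from None
    if width <= 0 or height <= 0:
        raise PGMFormatError(f"{path}: non-positive dimensions {width}x{height}")
    if maxval > 255:
        raise UnsupportedDepthError(f"{path}: maxval {maxval} > 255 unsupported")
    if maxval <= 0:
        raise PGMFormatError(f"{path}: non-positive maxval {maxval}")
    count = width * height
    if magic == b"P5":
        # Exactly one whitespace byte separates maxval from the raster.
        raster = data[end + 1 : end + 1 + count]
        if len(raster) < count:
            raise PGMFormatError(f"{path}: truncated pixel stream")
        pixels = np.frombuffer(raster, dtype=np.uint8, count=count)
    else:
        values = []
        for tok, _ in tokens:
            values.append(tok)
            if len(values) == count:
                break
        if len(values) < count:
            raise PGMFormatError(f"{path}: truncated pixel stream")
        try:
            pixels = np.array([int(v) for v in values], dtype=np.int64)
        except ValueError:
            raise PGMFormatError(f"{path}: non-integer pixel token") from None
        if pixels.min() < 0 or pixels.max() > maxval:
            raise PGMFormatError(f"{path}: pixel value outside [0, {maxval}]")
        pixels = pixels.astype(np.uint8)
    return pixels.reshape(height, width).copy()


def write_pgm(path, pixels: np.ndarray, binary: bool = True) -> None:
    """Write an 8-bit grayscale image as PGM (binary ``P5`` or ASCII ``P2``)."""
    arr = np.asarray(pixels)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D array, got shape {arr.shape}")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("pixel values must lie in [0, 255]")
    arr = arr.astype(np.uint8)
    h, w = arr.shape
    path = Path(path)
    if binary:
        header = f"P5\n{w} {h}\n255\n".encode("ascii")
        path.write_bytes(header + arr.tobytes())
    else:
        lines = [f"P2\n{w} {h}\n255"]
        for row in arr:
            lines.append(" ".join(str(int(v)) for v in row))
        path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# MIAS metadata
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MIASRecord:
    """One row of the MIAS metadata table.

    ``center_x``/``center_y`` are stored in *internal* convention: 0-based,
    top-left origin (``center_y`` counts rows downward).  The MIAS table uses
    a bottom-left origin; :func:`parse_mias_metadata` converts on read and
    :func:`format_mias_metadata` converts back on write.
    """

    ref_id: str
    tissue_character: str
    abnormality_class: str
    severity: Optional[str] = None
    center_x: Optional[int] = None
    center_y: Optional[int] = None
    radius: Optional[int] = None

    def __post_init__(self):
        if self.tissue_character not in TISSUE_CODES:
            raise ValueError(f"unknown tissue character {self.tissue_character!r}")
        if self.abnormality_class not in ABNORMALITY_CODES:
            raise ValueError(f"unknown abnormality class {self.abnormality_class!r}")
        if self.severity is not None and self.severity not in SEVERITY_CODES:
            raise ValueError(f"unknown severity {self.severity!r}")
        if self.abnormality_class == "NORM" and (
            self.severity is not None or self.center_x is not None or self.radius is not None
        ):
            raise ValueError("NORM records carry no severity/center/radius")
        if self.radius is not None and self.radius <= 0:
            raise ValueError("radius must be positive when present")


def parse_mias_metadata(text: str, image_height: int = 1024) -> list[MIASRecord]:
    """Parse the whitespace-delimited MIAS metadata table.

    Each non-empty line has 3-7 fields: reference id, tissue character
    (F/G/D), abnormality class, then optionally severity (B/M), center x, y
    (bottom-left origin, converted here to top-left rows using
    ``image_height``), and enclosing-circle radius in pixels.
    """
    records = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if not 3 <= len(fields) <= 7:
            raise MIASParseError(f"line {lineno}: expected 3-7 fields, got {len(fields)}")
        ref_id, tissue, abclass = fields[:3]
        if tissue not in TISSUE_CODES:
            raise MIASParseError(f"line {lineno}: unknown tissue character {tissue!r}")
        if abclass not in ABNORMALITY_CODES:
            raise MIASParseError(f"line {lineno}: unknown abnormality class {abclass!r}")
        severity = center_x = center_y = radius = None
        rest = fields[3:]
        if rest:
            severity = rest.pop(0)
            if severity not in SEVERITY_CODES:
                raise MIASParseError(f"line {lineno}: unknown severity {severity!r}")
        if rest:
            if len(rest) < 2:
                raise MIASParseError(f"line {lineno}: center needs both x and y")
            try:
                x, y = int(rest[0]), int(rest[1])
            except ValueError:
                raise MIASParseError(f"line {lineno}: non-integer coordinates") from None
            center_x, center_y = x, image_height - 1 - y
            rest = rest[2:]
        if rest:
            try:
                radius = int(rest[0])
            except ValueError:
                raise MIASParseError(f"line {lineno}: non-integer radius") from None
            if radius <= 0:
                raise MIASParseError(f"line {lineno}: radius must be positive")
        try:
            records.append(
                MIASRecord(ref_id, tissue, abclass, severity, center_x, center_y, radius)
            )
        except ValueError as exc:
            raise MIASParseError(f"line {lineno}: {exc}") from None
    return records


def format_mias_metadata(records: Sequence[MIASRecord], image_height: int = 1024) -> str:
    """Serialize records back to the MIAS table format (bottom-left y origin)."""
    lines = []
    for r in records:
        fields = [r.ref_id, r.tissue_character, r.abnormality_class]
        if r.severity is not None:
            fields.append(r.severity)
        if r.center_x is not None:
            fields.extend([str(r.center_x), str(image_height - 1 - r.center_y)])
        if r.radius is not None:
            fields.append(str(r.radius))
        lines.append(" ".join(fields))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Noise injection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseSpec:
    """Noise family and parameters.

    * ``salt_pepper`` -- a ``density`` fraction of pixels is replaced by 0 or
      255 with equal probability (impulse noise).
    * ``gaussian`` -- additive white noise with gray-level mean ``mean`` and
      standard deviation ``sigma``, clipped to [0, 255].
    * ``poisson`` -- each pixel is drawn from a Poisson distribution whose
      mean is the clean pixel value (quantum mottle), clipped.
    """

    family: str
    sigma: float = 0.0
    mean: float = 0.0
    density: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self):
        if self.family not in ("salt_pepper", "gaussian", "poisson"):
            raise ValueError(f"unknown noise family {self.family!r}")
        if self.family == "gaussian" and self.sigma <= 0:
            raise ValueError("gaussian noise requires sigma > 0")
        if not 0.0 <= self.density <= 1.0:
            raise ValueError("density must lie in [0, 1]")


def add_noise(image: np.ndarray, spec: NoiseSpec) -> np.ndarray:
    """Corrupt an 8-bit image according to ``spec``; deterministic given seed."""
    img = validate_gray_image(image)
    rng = np.random.default_rng(spec.seed)
    if spec.family == "salt_pepper":
        if spec.density == 0.0:
            return img.copy()
        out = img.copy()
        n = img.size
        k = int(round(spec.density * n))
        idx = rng.choice(n, size=k, replace=False)
        vals = rng.choice(np.array([0, 255], dtype=np.uint8), size=k)
        out.reshape(-1)[idx] = vals
        return out
    if spec.family == "gaussian":
        noisy = img.astype(np.float64) + rng.normal(spec.mean, spec.sigma, img.shape)
        return np.clip(np.rint(noisy), 0, 255).astype(np.uint8)
    # poisson
    return np.clip(rng.poisson(img.astype(np.float64)), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Phantom generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MassParams:
    """Geometry and contrast of the planted mass.

    ``center`` is (row, col); ``None`` places the mass randomly inside the
    central half of the breast ellipse.  ``radius`` is the nominal radius in
    pixels, ``contrast`` the peak intensity increment, ``n_spicules`` the
    number of star points used for malignant (spiculated) margins.
    """

    center: Optional[tuple] = None
    radius: float = 20.0
    contrast: float = 60.0
    n_spicules: int = 8


@dataclass
class Phantom:
    """A synthetic mammogram with its ground truth."""

    image: np.ndarray          # uint8, HxW
    mask: np.ndarray           # bool, HxW; pixels incremented by the mass painter
    label: str                 # benign | malignant | normal
    record: MIASRecord
    attributes: np.ndarray = field(default_factory=lambda: np.zeros(N_ATTRIBUTES))


def _mass_shape(size: int, center, radius: float, label: str, n_spicules: int,
                phase: float) -> np.ndarray:
    """Rasterize the mass support: a disc for benign, a spiculated star for
    malignant (base disc at 0.75 r plus cosine-lobe spikes reaching ~1.3 r)."""
    rr, cc = np.mgrid[0:size, 0:size]
    dy = rr - center[0]
    dx = cc - center[1]
    rho = np.hypot(dy, dx)
    if label == "benign":
        return rho <= radius
    theta = np.arctan2(dy, dx)
    lobe = np.maximum(0.0, np.cos(n_spicules * theta + phase)) ** 3
    return rho <= radius * (0.75 + 0.55 * lobe)


def synthesize_attributes(label: str, rng: np.random.Generator) -> np.ndarray:
    """Draw the nine cytology-style attributes from label-conditional Gaussians,
    clipped to the 1..10 scale."""
    mu, sd = ATTRIBUTE_DISTRIBUTIONS[label]
    return np.clip(rng.normal(mu, sd, N_ATTRIBUTES), 1.0, 10.0)


def generate_phantom(
    size: int = 256,
    label: str = "benign",
    mass_params: Optional[MassParams] = None,
    seed: int = 0,
    *,
    background_level: float = 10.0,
    tissue_level: float = 150.0,
    texture_sigma: float = 4.0,
    breast_axes: Optional[tuple] = None,
    pectoral: bool = False,
    pectoral_level: float = 185.0,
) -> Phantom:
    """Generate a MIAS-like synthetic mammogram phantom.

    The breast is an axis-aligned ellipse of intensity ~``tissue_level`` (with
    mild Gaussian texture, staying within roughly 120-180) on a dark
    background (~0-20).  ``label`` selects the mass geometry: a smooth
    circumscribed disc (benign, CIRC), a spiculated star (malignant, SPIC),
    or no mass (normal).  Deterministic for a fixed seed.

    Raises :class:`GeometryError` if the requested mass does not fit inside
    the breast ellipse.
    """
    if size < 64:
        raise ValueError("phantom size must be >= 64")
    if label not in ("benign", "malignant", "normal"):
        raise ValueError(f"unknown label {label!r}")
    rng = np.random.default_rng(seed)
    if breast_axes is None:
        breast_axes = (0.44 * size, 0.36 * size)
    ay, ax = breast_axes
    cy, cx = size / 2.0, size / 2.0

    rr, cc = np.mgrid[0:size, 0:size]
    ellipse = ((rr - cy) / ay) ** 2 + ((cc - cx) / ax) ** 2 <= 1.0

    img = np.full((size, size), background_level, dtype=np.float64)
    img += rng.normal(0.0, 1.5, img.shape)
    img[ellipse] = tissue_level + rng.normal(0.0, texture_sigma, int(ellipse.sum()))

    if pectoral:
        # wedge cutting the upper-left corner of the breast ellipse
        wedge = (rr + cc) < (cy + cx) - 0.8 * np.hypot(ay, ax) + 0.25 * size
        img[wedge & ellipse] = pectoral_level

    mask = np.zeros((size, size), dtype=bool)
    record_kwargs = {}
    attributes = synthesize_attributes(label, rng)

    if label != "normal":
        mp = mass_params or MassParams()
        reach = mp.radius * (1.3 if label == "malignant" else 1.0)
        if mp.center is None:
            for _ in range(100):
                u, v = rng.uniform(-0.5, 0.5, 2)
                center = (cy + u * ay, cx + v * ax)
                if (((center[0] - cy) / ay) ** 2 + ((center[1] - cx) / ax) ** 2
                        <= (1.0 - (reach + 2) / min(ay, ax)) ** 2):
                    break
            else:
                raise GeometryError("could not place mass inside breast ellipse")
        else:
            center = mp.center
            edge = (((center[0] - cy) / ay) ** 2 + ((center[1] - cx) / ax) ** 2) ** 0.5
            if edge > 1.0 - reach / min(ay, ax):
                raise GeometryError("mass (center, radius) extends outside breast ellipse")
        phase = rng.uniform(0, 2 * math.pi)
        mask = _mass_shape(size, center, mp.radius, label, mp.n_spicules, phase)
        dy = rr - center[0]
        dx = cc - center[1]
        rho = np.hypot(dy, dx)
        # Tapered but strictly positive increment: mask == {increment > 0}.
        increment = mp.contrast * (1.0 - 0.3 * np.minimum(rho / max(mp.radius, 1e-9), 1.0) ** 2)
        img[mask] += increment[mask]
        record_kwargs = dict(
            severity="M" if label == "malignant" else "B",
            center_x=int(round(center[1])),
            center_y=int(round(center[0])),
            radius=int(max(1, round(mp.radius))),
        )

    record = MIASRecord(
        ref_id=f"syn{seed % 100000:05d}",
        tissue_character="G",
        abnormality_class={"benign": "CIRC", "malignant": "SPIC", "normal": "NORM"}[label],
        **record_kwargs,
    )
    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return Phantom(image=image, mask=mask, label=label, record=record, attributes=attributes)


def save_phantom_dataset(directory, phantoms: Sequence[Phantom]) -> None:
    """Write phantoms as ``case###.pgm`` + ``case###_mask.pgm`` + one
    ``metadata.txt`` table (internal coordinates converted to the MIAS
    bottom-left convention for the phantom image height)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    records = []
    for i, ph in enumerate(phantoms):
        write_pgm(directory / f"case{i:03d}.pgm", ph.image)
        write_pgm(directory / f"case{i:03d}_mask.pgm", ph.mask.astype(np.uint8) * 255)
        records.append(ph.record)
        np.savetxt(directory / f"case{i:03d}_attrs.txt", ph.attributes[None], fmt="%.4f")
    height = phantoms[0].image.shape[0] if phantoms else 1024
    (directory / "metadata.txt").write_text(format_mias_metadata(records, image_height=height))
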