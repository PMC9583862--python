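"""Raster I/O, the benthic class alphabet, and label <-> color codecs.

Every stage of the mapping pipeline talks about the same five benthic cover
classes — eelgrass *Zostera marina* (ZM), dwarf eelgrass *Z. japonica* (ZJ),
green algae (GA), brown algae (BA) and bare substrate / no vegetation (NV) —
plus three brightness-derived ZM subclasses (ZM1..ZM3) that exist only inside
GAN training targets, and an UNLABELED sentinel excluded from all accuracy
computations.

Label maps are stored as small-integer index rasters; on disk they are
paletted PNGs whose palette entries are the display colors below.  The
display colors are chosen pairwise far apart in RGB (minimum Euclidean
distance >= 80) so that the continuous output of the image-translation
network can be decoded robustly by nearest-color lookup.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "CLASSES",
    "SUBCLASSES",
    "ALL_LABELS",
    "UNLABELED",
    "DISPLAY_COLORS",
    "BenthicClass",
    "OrthoImage",
    "LabelMap",
    "FormatError",
    "DecodeError",
    "label_index",
    "label_code",
    "read_image",
    "write_image",
    "encode_labels",
    "decode_labels",
    "write_labels",
    "read_labels",
    "nearest_class",
    "merge_subclasses",
]

# Fixed class order; also the tie-break order for nearest-color decoding.
CLASSES: tuple[str, ...] = ("ZM", "ZJ", "GA", "BA", "NV")
SUBCLASSES: tuple[str, ...] = ("ZM1", "ZM2", "ZM3")
UNLABELED = "UNLABELED"

# Decodable labels in tie-break order: ZM (and its subclasses) < ZJ < GA < BA < NV.
ALL_LABELS: tuple[str, ...] = ("ZM", "ZM1", "ZM2", "ZM3", "ZJ", "GA", "BA", "NV")

# Display palette.  All decodable entries are mutually >= 80 apart in RGB
# (verified by a palette self-consistency test); the UNLABELED sentinel is
# never decoded.
DISPLAY_COLORS: dict[str, tuple[int, int, int]] = {
    "ZM": (0, 100, 90),      # dark teal-green
    "ZM1": (0, 30, 0),       # ZM shade: darkest
    "ZM2": (0, 145, 0),      # ZM shade: mid
    "ZM3": (90, 230, 90),    # ZM shade: brightest
    "ZJ": (230, 230, 0),     # yellow
    "GA": (0, 190, 255),     # cyan-blue
    "BA": (200, 60, 40),     # red-brown
    "NV": (245, 245, 245),   # near-white grey
    UNLABELED: (255, 0, 255),
}

_LABEL_TO_INDEX = {c: i for i, c in enumerate(ALL_LABELS + (UNLABELED,))}
_INDEX_TO_LABEL = ALL_LABELS + (UNLABELED,)
UNLABELED_INDEX = _LABEL_TO_INDEX[UNLABELED]


class FormatError(ValueError):
    """Raised for rasters that violate the 8-bit RGB contract."""


class DecodeError(ValueError):
    """Raised when a label raster contains colors absent from the palette."""


@dataclass(frozen=True)
class BenthicClass:
    """A benthic cover class with its display color.

    Subclasses (ZM1..ZM3) are valid only inside cGAN training data and map
    back to ZM under :func:`merge_subclasses`.
    """

    code: str
    display_color: tuple[int, int, int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.code not in _LABEL_TO_INDEX:
            raise ValueError(f"unknown benthic class code {self.code!r}")
        if self.display_color is None:
            object.__setattr__(self, "display_color", DISPLAY_COLORS[self.code])

    @property
    def is_subclass(self) -> bool:
        return self.code in SUBCLASSES


def label_index(code: str) -> int:
    """Integer index of a class code in the fixed label order."""
    try:
        return _LABEL_TO_INDEX[code]
    except KeyError:
        raise ValueError(f"unknown benthic class code {code!r}") from None


def label_code(index: int) -> str:
    return _INDEX_TO_LABEL[index]


@dataclass
class OrthoImage:
    """An RGB orthoimage: H x W x 3 uint8 pixels, channel order R,G,B.

    ``pixel_size`` is optional ground-sample-distance metadata in meters per
    pixel (e.g. 0.00813 for an 8.13 mm/pix orthomosaic); it is carried along
    but never used in computation.
    """

    pixels: np.ndarray
    pixel_size: float | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise FormatError(
                f"expected H x W x 3 RGB array, got shape {self.pixels.shape}"
            )
        if self.pixels.dtype != np.uint8:
            raise FormatError(f"expected 8-bit pixels, got dtype {self.pixels.dtype}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise FormatError("image dimensions must be >= 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class LabelMap:
    """A categorical raster over the benthic label alphabet.

    ``labels`` holds small-integer indices into the fixed label order (see
    :func:`label_index`); ground truth and predictions share this type.
    """

    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError(f"labels must be 2-D, got shape {self.labels.shape}")
        if self.labels.dtype != np.uint8:
            if self.labels.min(initial=0) < 0 or self.labels.max(initial=0) >= len(
                _INDEX_TO_LABEL
            ):
                raise ValueError("label indices out of range")
            self.labels = self.labels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def codes_present(self) -> list[str]:
        return [label_code(i) for i in np.unique(self.labels)]

    @classmethod
    def from_codes(cls, codes: np.ndarray) -> "LabelMap":
        """Build from a 2-D array of class-code strings."""
        codes = np.asarray(codes)
        out = np.empty(codes.shape, dtype=np.uint8)
        for code in np.unique(codes):
            out[codes == code] = label_index(str(code))
        return cls(out)


# ---------------------------------------------------------------------------
# image I/O


def read_image(path: str | Path) -> OrthoImage:
    """Read an 8-bit RGB PNG or TIFF as an :class:`OrthoImage`.

    Raises :class:`FormatError` naming the offending property for non-RGB or
    non-8-bit input.
    """
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        arr = tifffile.imread(path)
        if arr.dtype != np.uint8:
            raise FormatError(f"{path.name}: expected 8-bit samples, got {arr.dtype}")
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise FormatError(
                f"{path.name}: expected RGB (3 channels), got shape {arr.shape}"
            )
        return OrthoImage(arr)
    with Image.open(path) as im:
        if im.mode != "RGB":
            raise FormatError(f"{path.name}: expected RGB mode, got {im.mode!r}")
        arr = np.asarray(im, dtype=np.uint8)
    return OrthoImage(arr)


def write_image(image: OrthoImage, path: str | Path) -> None:
    """Write an :class:`OrthoImage` as 8-bit RGB PNG (or TIFF by suffix)."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(path, image.pixels, photometric="rgb")
    else:
        Image.fromarray(image.pixels, mode="RGB").save(path)


# ---------------------------------------------------------------------------
# label <-> color codecs


def _palette_array(labels: tuple[str, ...] = ALL_LABELS + (UNLABELED,)) -> np.ndarray:
    return np.array([DISPLAY_COLORS[c] for c in labels], dtype=np.uint8)


def encode_labels(labelmap: LabelMap) -> np.ndarray:
    """Render a label map as an H x W x 3 uint8 raster of display colors."""
    return _palette_array()[labelmap.labels]


def decode_labels(raster: np.ndarray) -> LabelMap:
    """Invert :func:`encode_labels` exactly.

    Every pixel color must be a palette entry; an unknown color raises
    :class:`DecodeError` listing the color.
    """
    raster = np.asarray(raster, dtype=np.uint8)
    if raster.ndim != 3 or raster.shape[2] != 3:
        raise DecodeError(f"expected H x W x 3 color raster, got shape {raster.shape}")
    pal = _palette_array()
    flat = raster.reshape(-1, 3)
    # exact palette match via a color->index dict on the unique colors
    lut = {tuple(c): i for i, c in enumerate(pal)}
    uniq, inv = np.unique(flat, axis=0, return_inverse=True)
    idx_of_uniq = np.empty(len(uniq), dtype=np.uint8)
    for j, color in enumerate(uniq):
        key = tuple(int(v) for v in color)
        if key not in lut:
            raise DecodeError(f"color {key} not in label palette")
        idx_of_uniq[j] = lut[key]
    return LabelMap(idx_of_uniq[inv].reshape(raster.shape[:2]))


def write_labels(labelmap: LabelMap, path: str | Path) -> None:
    """Write a label map as a single-band paletted PNG."""
    im = Image.fromarray(labelmap.labels, mode="P")
    im.putpalette(_palette_array().flatten().tolist())
    im.save(Path(path))


def read_labels(path: str | Path) -> LabelMap:
    """Read a paletted label PNG written by :func:`write_labels`."""
    with Image.open(Path(path)) as im:
        if im.mode == "P":
            pal = np.array(im.getpalette(), dtype=np.uint8).reshape(-1, 3)
            idx = np.asarray(im, dtype=np.uint8)
            return decode_labels(pal[idx])
        if im.mode == "RGB":
            return decode_labels(np.asarray(im, dtype=np.uint8))
    raise DecodeError(f"{Path(path).name}: unsupported label raster mode")


def nearest_class(rgb, palette_labels: tuple[str, ...] = ALL_LABELS) -> str:
    """Decode an RGB triple to the class with the nearest display color.

    Euclidean distance in RGB; ties broken by the fixed class order
    ZM < ZJ < GA < BA < NV (subclasses sort with ZM).  Vectorized form:
    pass an (..., 3) array and get an index array back via
    :func:`nearest_class_indices`.
    """
    rgb = np.asarray(rgb, dtype=np.float64)
    pal = np.array([DISPLAY_COLORS[c] for c in palette_labels], dtype=np.float64)
    d2 = ((pal - rgb) ** 2).sum(axis=1)
    return palette_labels[int(np.argmin(d2))]  # argmin takes first minimum: tie rule


def nearest_class_indices(
    rgb: np.ndarray, palette_labels: tuple[str, ...] = ALL_LABELS
) -> np.ndarray:
    """Vectorized nearest-color decoding: (..., 3) RGB -> label indices."""
    rgb = np.asarray(rgb, dtype=np.float32)
    pal = np.array([DISPLAY_COLORS[c] for c in palette_labels], dtype=np.float32)
    d2 = ((rgb[..., None, :] - pal) ** 2).sum(axis=-1)
    choice = np.argmin(d2, axis=-1)
    label_idx = np.array([label_index(c) for c in palette_labels], dtype=np.uint8)
    return label_idx[choice]


_MERGE_LUT = np.arange(len(_INDEX_TO_LABEL), dtype=np.uint8)
for _sc in SUBCLASSES:
    _MERGE_LUT[label_index(_sc)] = label_index("ZM")


def merge_subclasses(labelmap: LabelMap) -> LabelMap:
    """Map ZM1/ZM2/ZM3 back to ZM; all other labels unchanged. Idempotent."""
    return LabelMap(_MERGE_LUT[labelmap.labels])
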