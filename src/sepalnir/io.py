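"""Reading and writing the on-disk formats shared by every pipeline stage.

Hyperspectral cubes travel as ENVI header/binary pairs (the native format of
pushbroom NIR line-scan cameras such as the SPECIM FX17): a plain-text ``.hdr``
describing dimensions, interleave and the wavelength list, next to a raw
binary file.  All three interleave dialects (BSQ, BIL, BIP) are supported on
read; cubes are written as BSQ.  Sepal identification masks and truth masks
travel as single-channel 16-bit PNG, 0 meaning background.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "HyperCube",
    "ReferenceSpectra",
    "read_envi",
    "write_envi",
    "read_label_mask",
    "write_label_mask",
]

# ENVI numeric "data type" codes <-> numpy dtypes (little-endian on write).
_ENVI_DTYPES = {
    1: np.dtype("u1"),
    2: np.dtype("<i2"),
    3: np.dtype("<i4"),
    4: np.dtype("<f4"),
    5: np.dtype("<f8"),
    12: np.dtype("<u2"),
    13: np.dtype("<u4"),
}
_DTYPE_CODES = {v: k for k, v in _ENVI_DTYPES.items()}

_INTERLEAVES = ("bsq", "bil", "bip")


@dataclass
class HyperCube:
    """A hyperspectral image: ``data[row, col, band]`` plus band-center wavelengths.

    ``kind`` distinguishes raw sensor intensity from flat-field-corrected
    reflectance; downstream stages require ``kind == "corrected"``.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    kind: str = "raw"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"cube must be rows x cols x bands, got shape {self.data.shape}")
        if self.wavelengths.ndim != 1 or self.wavelengths.size != self.data.shape[2]:
            raise ValueError(
                f"wavelength vector length {self.wavelengths.size} does not match "
                f"{self.data.shape[2]} bands"
            )
        if self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.kind not in ("raw", "corrected"):
            raise ValueError(f"kind must be 'raw' or 'corrected', got {self.kind!r}")
        if self.kind == "corrected" and not np.all(np.isfinite(self.data)):
            raise ValueError("corrected cube contains non-finite values")

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    def band_index(self, wavelength_nm: float) -> int:
        """Index of the band whose center is nearest to ``wavelength_nm``."""
        return int(np.argmin(np.abs(self.wavelengths - wavelength_nm)))

    def select(self, band_mask: np.ndarray) -> "HyperCube":
        """Sub-cube restricted to the bands flagged True in ``band_mask``."""
        band_mask = np.asarray(band_mask, dtype=bool)
        if band_mask.size != self.n_bands:
            raise ValueError("band mask length does not match band count")
        return HyperCube(self.data[:, :, band_mask], self.wavelengths[band_mask], self.kind)


@dataclass
class ReferenceSpectra:
    """Per-band white-panel and dark-current reference intensities."""

    white: np.ndarray
    black: np.ndarray

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white, dtype=float)
        self.black = np.asarray(self.black, dtype=float)
        if self.white.shape != self.black.shape or self.white.ndim != 1:
            raise ValueError("white and black references must be 1-D and equally long")

    @property
    def n_bands(self) -> int:
        return self.white.size


def _parse_header(text: str) -> dict:
    """Parse an ENVI header into a flat dict (keys lowercased).

    Values in ``{...}`` may span lines; everything else is a single token run.
    """
    # Brace-delimited values ({...}) may span lines, so scan line by line.
    fields: dict[str, str] = {}
    i = 0
    lines = text.splitlines()
    while i < len(lines):
        line = lines[i]
        if "=" not in line:
            i += 1
            continue
        key, _, value = line.partition("=")
        key = key.strip().lower()
        value = value.strip()
        if value.startswith("{") and "}" not in value:
            parts = [value]
            while i + 1 < len(lines):
                i += 1
                parts.append(lines[i])
                if "}" in lines[i]:
                    break
            value = "\n".join(parts)
        fields[key] = value
        i += 1
    return fields


def _find_binary(header_path: Path) -> Path:
    stem = header_path.with_suffix("")
    for suffix in (".raw", ".img", ".dat", ".bsq", ".bil", ".bip", ""):
        candidate = stem.with_suffix(suffix) if suffix else stem
        if candidate.exists() and candidate != header_path:
            return candidate
    raise FileNotFoundError(f"no companion binary found for ENVI header {header_path}")


def read_envi(header_path: str | Path, kind: str = "raw") -> HyperCube:
    """Read an ENVI header/binary pair into a :class:`HyperCube`.

    The header must declare ``samples``, ``lines``, ``bands``, ``data type``,
    ``interleave`` and a ``wavelength`` list; band order is preserved.
    """
    header_path = Path(header_path)
    fields = _parse_header(header_path.read_text())

    for required in ("samples", "lines", "bands", "data type", "interleave"):
        if required not in fields:
            raise ValueError(f"ENVI header {header_path} is missing '{required}'")
    if "wavelength" not in fields:
        raise ValueError(f"ENVI header {header_path} has no wavelength list")

    samples = int(fields["samples"])
    lines = int(fields["lines"])
    bands = int(fields["bands"])
    code = int(fields["data type"])
    interleave = fields["interleave"].strip().lower()
    if interleave not in _INTERLEAVES:
        raise ValueError(
            f"unsupported interleave {interleave!r} in {header_path}; "
            f"supported: {', '.join(sorted(_INTERLEAVES))}"
        )
    if code not in _ENVI_DTYPES:
        raise ValueError(f"unsupported ENVI data type code {code} in {header_path}")
    dtype = _ENVI_DTYPES[code]
    if int(fields.get("byte order", "0")) == 1:
        dtype = dtype.newbyteorder(">")

    wavelengths = np.array(
        [float(tok) for tok in re.split(r"[,\s]+", fields["wavelength"].strip("{} \n")) if tok],
        dtype=float,
    )
    if wavelengths.size != bands:
        raise ValueError(
            f"header declares {bands} bands but lists {wavelengths.size} wavelengths"
        )

    binary_path = _find_binary(header_path)
    flat = np.fromfile(binary_path, dtype=dtype)
    expected = samples * lines * bands
    if flat.size != expected:
        raise ValueError(
            f"binary {binary_path} holds {flat.size} values but header "
            f"{header_path} declares {lines}x{samples}x{bands} = {expected}"
        )

    if interleave == "bsq":  # (bands, lines, samples)
        data = flat.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":  # (lines, bands, samples)
        data = flat.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bip: (lines, samples, bands)
        data = flat.reshape(lines, samples, bands)
    return HyperCube(np.ascontiguousarray(data), wavelengths, kind=kind)


def write_envi(cube: HyperCube, header_path: str | Path) -> Path:
    """Write a cube as an ENVI BSQ header/binary pair; returns the binary path."""
    header_path = Path(header_path)
    dtype = np.dtype(cube.data.dtype).newbyteorder("<")
    if dtype not in _DTYPE_CODES:
        raise ValueError(f"dtype {cube.data.dtype} has no ENVI data type code")
    rows, cols, bands = cube.data.shape
    binary_path = header_path.with_suffix(".raw")

    wl = ", ".join(f"{w:.6g}" for w in cube.wavelengths)
    header = (
        "ENVI\n"
        "description = {sepalnir hyperspectral cube}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[dtype]}\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = nm\n"
        f"wavelength = {{{wl}}}\n"
    )
    header_path.write_text(header)
    cube.data.transpose(2, 0, 1).astype(dtype).tofile(binary_path)
    return binary_path


def read_label_mask(path: str | Path, spatial_shape: tuple[int, int] | None = None) -> np.ndarray:
    """Read a labeled raster (0 = background, positive integers = labels).

    If ``spatial_shape`` is given, the mask must match it exactly — a mismatch
    means the mask was drawn on a different image than the cube it is paired
    with.
    """
    arr = np.asarray(Image.open(Path(path))).astype(np.int64)
    if arr.ndim != 2:
        raise ValueError(f"label mask {path} is not single-channel (shape {arr.shape})")
    if arr.min() < 0:
        raise ValueError(f"label mask {path} contains negative labels")
    if spatial_shape is not None and arr.shape != tuple(spatial_shape):
        raise ValueError(
            f"label mask shape {arr.shape} does not match cube spatial shape "
            f"{tuple(spatial_shape)}"
        )
    return arr


def write_label_mask(mask: np.ndarray, path: str | Path) -> Path:
    """Write a labeled (or binary) raster as 16-bit single-channel PNG."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("label mask must be 2-D")
    if mask.min() < 0 or mask.max() > np.iinfo(np.uint16).max:
        raise ValueError("labels must fit in uint16")
    path = Path(path)
    Image.fromarray(mask.astype(np.uint16)).save(path, format="PNG")
    return path
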