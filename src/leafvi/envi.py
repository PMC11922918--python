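"""ENVI-format hyperspectral cube I/O.

Implements the de-facto standard ENVI container: a plain-text header
(``.hdr``) describing the geometry, sample encoding and band wavelengths,
plus a raw binary file in one of three interleaves:

* ``bsq`` — band sequential: whole band planes, one after another;
* ``bil`` — band interleaved by line: per image line, all bands of that line;
* ``bip`` — band interleaved by pixel: per pixel, all bands of that pixel.

In memory the cube is always a ``(lines, samples, bands)`` array so the value
at ``(row, col, band)`` is independent of the interleave it was stored in.

Coordinate convention used throughout the package: ``(row, col)``, 0-based,
with rectangles half-open ``[x1, x2) x [y1, y2)`` where ``x = col`` and
``y = row``.

Supported sample encodings are ENVI data type ``4`` (32-bit IEEE float) and
``12`` (16-bit unsigned integer); anything else raises
:class:`~leafvi.errors.UnsupportedDataType`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np

from .errors import (
    EnviHeaderError,
    InconsistentHeader,
    IOFailure,
    MissingField,
    SizeMismatch,
    UnsupportedDataType,
)

log = logging.getLogger(__name__)

#: ENVI data type code -> numpy dtype (endianness applied separately).
ENVI_DTYPES: Dict[int, np.dtype] = {
    4: np.dtype("float32"),
    12: np.dtype("uint16"),
}

INTERLEAVES = ("bsq", "bil", "bip")

#: |target - nearest band wavelength| above this (nm) logs a warning.
WAVELENGTH_WARN_NM = 10.0

_REQUIRED_KEYS = ("samples", "lines", "bands", "interleave", "data type")


@dataclass(frozen=True)
class CubeMeta:
    """Geometry and encoding of an ENVI cube.

    ``wavelengths`` is the per-band center wavelength in nm (strictly
    increasing) or ``None`` when the header carries no wavelength list; in
    that case wavelength-addressed VI computation refuses to run rather than
    assuming an axis.
    """

    samples: int
    lines: int
    bands: int
    interleave: str
    data_type: int
    byte_order: int = 0
    wavelengths: Optional[Tuple[float, ...]] = None
    extra: Tuple[Tuple[str, str], ...] = field(default=())

    def __post_init__(self) -> None:
        if self.samples < 1 or self.lines < 1 or self.bands < 1:
            raise InconsistentHeader(
                f"non-positive dimensions: samples={self.samples} "
                f"lines={self.lines} bands={self.bands}"
            )
        if self.interleave not in INTERLEAVES:
            raise InconsistentHeader(f"unknown interleave {self.interleave!r}")
        if self.data_type not in ENVI_DTYPES:
            raise UnsupportedDataType(
                f"ENVI data type {self.data_type} not supported "
                f"(supported: {sorted(ENVI_DTYPES)})"
            )
        if self.byte_order not in (0, 1):
            raise InconsistentHeader(f"byte order must be 0 or 1, got {self.byte_order}")
        if self.wavelengths is not None:
            if len(self.wavelengths) != self.bands:
                raise InconsistentHeader(
                    f"{len(self.wavelengths)} wavelengths listed for "
                    f"{self.bands} bands"
                )
            w = np.asarray(self.wavelengths, dtype=float)
            if w.size > 1 and not np.all(np.diff(w) > 0):
                raise InconsistentHeader("wavelengths must be strictly increasing")

    @property
    def dtype(self) -> np.dtype:
        """Numpy dtype including byte order."""
        return ENVI_DTYPES[self.data_type].newbyteorder("<" if self.byte_order == 0 else ">")

    @property
    def shape(self) -> Tuple[int, int, int]:
        """In-memory shape ``(lines, samples, bands)``."""
        return (self.lines, self.samples, self.bands)

    @property
    def nbytes(self) -> int:
        return self.samples * self.lines * self.bands * self.dtype.itemsize


@dataclass
class SpectralCube:
    """A reflectance hypercube: ``values[row, col, band]`` plus its metadata.

    Reflectance is dimensionless; against a white reference it normally lies
    in [0, ~1.2] (slight overshoot above 1 is physical).
    """

    meta: CubeMeta
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.meta.shape:
            raise InconsistentHeader(
                f"value grid shape {self.values.shape} != header shape {self.meta.shape}"
            )
        if np.issubdtype(self.values.dtype, np.floating) and not np.all(
            np.isfinite(self.values)
        ):
            raise InconsistentHeader("cube contains non-finite values")

    @property
    def wavelengths(self) -> Optional[np.ndarray]:
        if self.meta.wavelengths is None:
            return None
        return np.asarray(self.meta.wavelengths, dtype=float)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.values.shape


# --- header parsing ---------------------------------------------------------

def _normalize_key(key: str) -> str:
    return re.sub(r"\s+", " ", key.strip().lower())


def _split_header(text: str) -> Dict[str, str]:
    """Tokenize an ENVI header into a ``{key: raw value}`` mapping."""
    lines = text.splitlines()
    # locate magic
    idx = 0
    while idx < len(lines) and not lines[idx].strip():
        idx += 1
    if idx >= len(lines) or lines[idx].strip().upper() != "ENVI":
        raise EnviHeaderError("missing 'ENVI' magic line")
    fields: Dict[str, str] = {}
    i = idx + 1
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line or line.startswith(";"):
            continue
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        key = _normalize_key(key)
        value = value.strip()
        if value.startswith("{") and "}" not in value:
            parts = [value]
            while i < len(lines):
                parts.append(lines[i].strip())
                if "}" in lines[i]:
                    i += 1
                    break
                i += 1
            value = " ".join(parts)
        fields[key] = value
    return fields


def _parse_brace_list(value: str) -> Tuple[float, ...]:
    inner = value.strip()
    if inner.startswith("{"):
        inner = inner[1:]
    if inner.endswith("}"):
        inner = inner[:-1]
    items = [s for s in re.split(r"[,\s]+", inner.strip()) if s]
    return tuple(float(s) for s in items)


def parse_envi_header(text: str) -> CubeMeta:
    """Parse an ENVI header dialect into :class:`CubeMeta`.

    Keys are case-insensitive and whitespace-tolerant; brace-delimited lists
    (notably the wavelength list) may span multiple lines. Unknown keys are
    preserved so a parse/format round trip is lossless.
    """
    fields = _split_header(text)
    for key in _REQUIRED_KEYS:
        if key not in fields:
            raise MissingField(f"required header field {key!r} absent")

    try:
        samples = int(fields["samples"])
        lines_ = int(fields["lines"])
        bands = int(fields["bands"])
        data_type = int(fields["data type"])
    except ValueError as exc:
        raise EnviHeaderError(f"malformed numeric header field: {exc}") from None

    if data_type not in ENVI_DTYPES:
        raise UnsupportedDataType(
            f"ENVI data type {data_type} not supported (supported: {sorted(ENVI_DTYPES)})"
        )

    interleave = fields["interleave"].strip().lower()
    byte_order = int(fields.get("byte order", "0"))

    wavelengths: Optional[Tuple[float, ...]] = None
    if "wavelength" in fields:
        wavelengths = _parse_brace_list(fields["wavelength"])
        if len(wavelengths) != bands:
            raise InconsistentHeader(
                f"{len(wavelengths)} wavelengths listed for {bands} bands"
            )

    known = set(_REQUIRED_KEYS) | {"byte order", "wavelength"}
    extra = tuple((k, v) for k, v in fields.items() if k not in known)

    return CubeMeta(
        samples=samples,
        lines=lines_,
        bands=bands,
        interleave=interleave,
        data_type=data_type,
        byte_order=byte_order,
        wavelengths=wavelengths,
        extra=extra,
    )


def format_envi_header(meta: CubeMeta) -> str:
    """Render :class:`CubeMeta` back to header text (inverse of parsing)."""
    out = ["ENVI"]
    out.append(f"samples = {meta.samples}")
    out.append(f"lines = {meta.lines}")
    out.append(f"bands = {meta.bands}")
    out.append(f"data type = {meta.data_type}")
    out.append(f"interleave = {meta.interleave}")
    out.append(f"byte order = {meta.byte_order}")
    for key, value in meta.extra:
        out.append(f"{key} = {value}")
    if meta.wavelengths is not None:
        # repr() keeps full precision so parse(format(m)) == m bit-exactly
        body = ", ".join(repr(float(w)) for w in meta.wavelengths)
        out.append("wavelength = { " + body + " }")
    return "\n".join(out) + "\n"


# --- raw binary -------------------------------------------------------------

def read_cube(meta: CubeMeta, raw: Union[bytes, bytearray, memoryview]) -> SpectralCube:
    """Decode a raw interleaved buffer into a ``(lines, samples, bands)`` cube."""
    expected = meta.nbytes
    if len(raw) != expected:
        raise SizeMismatch(
            f"buffer is {len(raw)} bytes, header implies {expected} "
            f"({meta.lines}x{meta.samples}x{meta.bands} {meta.dtype})"
        )
    flat = np.frombuffer(bytes(raw), dtype=meta.dtype)
    if meta.interleave == "bsq":
        values = flat.reshape(meta.bands, meta.lines, meta.samples).transpose(1, 2, 0)
    elif meta.interleave == "bil":
        values = flat.reshape(meta.lines, meta.bands, meta.samples).transpose(0, 2, 1)
    else:  # bip
        values = flat.reshape(meta.lines, meta.samples, meta.bands)
    return SpectralCube(meta=meta, values=np.ascontiguousarray(values))


def write_cube(cube: SpectralCube, interleave: str = "bsq") -> Tuple[str, bytes]:
    """Serialize a cube as ``(header_text, raw_bytes)`` in the given interleave.

    float32 encoding round-trips bit-exactly; values are cast to the
    cube's declared sample type before writing.
    """
    if interleave not in INTERLEAVES:
        raise InconsistentHeader(f"unknown interleave {interleave!r}")
    meta = replace(cube.meta, interleave=interleave)
    values = np.ascontiguousarray(cube.values.astype(meta.dtype, copy=False))
    if interleave == "bsq":
        ordered = values.transpose(2, 0, 1)
    elif interleave == "bil":
        ordered = values.transpose(0, 2, 1)
    else:
        ordered = values
    return format_envi_header(meta), np.ascontiguousarray(ordered).tobytes()


def read_envi(header_path: Union[str, Path], data_path: Union[str, Path, None] = None) -> SpectralCube:
    """Read an ENVI cube from ``.hdr`` + raw file.

    When ``data_path`` is omitted, siblings with ``.dat``/``.raw``/``.img``
    extensions (in that order) are tried.
    """
    header_path = Path(header_path)
    try:
        meta = parse_envi_header(header_path.read_text())
    except OSError as exc:
        raise IOFailure(f"cannot read header {header_path}: {exc}") from exc
    if data_path is None:
        for ext in (".dat", ".raw", ".img"):
            candidate = header_path.with_suffix(ext)
            if candidate.exists():
                data_path = candidate
                break
        else:
            raise IOFailure(f"no raw data file found next to {header_path}")
    try:
        raw = Path(data_path).read_bytes()
    except OSError as exc:
        raise IOFailure(f"cannot read data {data_path}: {exc}") from exc
    return read_cube(meta, raw)


def write_envi(stem: Union[str, Path], cube: SpectralCube, interleave: str = "bsq") -> Tuple[Path, Path]:
    """Write ``<stem>.hdr`` + ``<stem>.dat``; returns the two paths."""
    stem = Path(stem)
    header, raw = write_cube(cube, interleave)
    hdr_path = stem.with_suffix(".hdr")
    dat_path = stem.with_suffix(".dat")
    try:
        hdr_path.write_text(header)
        dat_path.write_bytes(raw)
    except OSError as exc:
        raise IOFailure(f"cannot write {stem}: {exc}") from exc
    return hdr_path, dat_path


# --- wavelength resolution --------------------------------------------------

def nearest_band(wavelengths: Sequence[float], target: float) -> int:
    """Index of the band whose center wavelength is closest to ``target`` (nm).

    Exact distance ties resolve to the lower-wavelength index; out-of-range
    targets clamp to the nearest end. A warning is logged when the residual
    |Δλ| exceeds 10 nm, since the band then only loosely approximates the
    index's nominal wavelength.
    """
    w = np.asarray(wavelengths, dtype=float)
    if w.size == 0:
        raise InconsistentHeader("empty wavelength axis")
    if w.size > 1 and not np.all(np.diff(w) > 0):
        raise InconsistentHeader("wavelength axis must be strictly increasing")
    dist = np.abs(w - float(target))
    idx = int(np.argmin(dist))  # argmin returns the first (= lower) index on ties
    if dist[idx] > WAVELENGTH_WARN_NM:
        log.warning(
            "nearest band to %.1f nm is %.2f nm away (band %d at %.2f nm)",
            target, dist[idx], idx, w[idx],
        )
    return idx
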