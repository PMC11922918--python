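"""ROI transfer onto the spectral cube, mean-spectrum extraction and
vegetation-index computation.

A vegetation index (VI) is a scalar combination of reflectances at specific
wavelengths summarizing plant state. The four built-in indices are

* NDVI = (R860 − R650) / (R860 + R650)   — broadband greenness
* PRI  = (R531 − R570) / (R531 + R570)   — xanthophyll-cycle light-use efficiency
* ARI  = 1/R550 − 1/R700                 — anthocyanin content
* CRI  = 1/R510 − 1/R550                 — carotenoid content

where R_λ is the ROI-mean reflectance at the cube band nearest λ (no spectral
interpolation; a warning is logged when the nearest band is more than 10 nm
away). Further indices — simple ratio, green leaf index, etc. — can be added
through :func:`register_vi` without touching the pipeline.

The ROI mean averages *all* rectangle pixels (parity with classical rectangle
annotation); pass an explicit mask to restrict it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .envi import CubeMeta, SpectralCube, nearest_band
from .errors import (
    AlignmentError,
    DuplicateName,
    InvalidROI,
    NonPositiveReflectance,
    UnresolvableWavelength,
    ZeroDenominator,
)
from .segmentation import ROI

DEFAULT_VI_NAMES = ("NDVI", "PRI", "ARI", "CRI")


@dataclass(frozen=True)
class MeanSpectrum:
    """Per-band mean reflectance over an ROI."""

    values: np.ndarray  # float64, length = bands
    pixel_count: int


@dataclass(frozen=True)
class VIDefinition:
    """A named index: the wavelengths it needs and a formula over them.

    ``formula`` receives a mapping {nominal wavelength (nm): reflectance}.
    """

    name: str
    wavelengths: Tuple[float, ...]
    formula: Callable[[Mapping[float, float]], float]
    description: str = ""


@dataclass(frozen=True)
class VIResult:
    """Values of the computed indices plus the bands actually used."""

    values: Dict[str, float]
    bands: Dict[str, Tuple[int, ...]]
    wavelengths_used: Dict[str, Tuple[float, ...]]
    pixel_count: int
    roi: Optional[ROI] = None


# --- built-in formulas ------------------------------------------------------

def _normalized_difference(lam_a: float, lam_b: float) -> Callable[[Mapping[float, float]], float]:
    def formula(refl: Mapping[float, float]) -> float:
        a, b = refl[lam_a], refl[lam_b]
        den = a + b
        if den == 0:
            raise ZeroDenominator(f"R{lam_a:g} + R{lam_b:g} = 0")
        return (a - b) / den
    return formula


def _reciprocal_difference(lam_a: float, lam_b: float) -> Callable[[Mapping[float, float]], float]:
    def formula(refl: Mapping[float, float]) -> float:
        a, b = refl[lam_a], refl[lam_b]
        if a <= 0 or b <= 0:
            raise NonPositiveReflectance(
                f"reciprocal index needs positive reflectance, got "
                f"R{lam_a:g}={a:g}, R{lam_b:g}={b:g}"
            )
        return 1.0 / a - 1.0 / b
    return formula


def _builtin_registry() -> Dict[str, VIDefinition]:
    return {
        "NDVI": VIDefinition("NDVI", (860.0, 650.0), _normalized_difference(860.0, 650.0),
                             "normalized difference of NIR and red reflectance"),
        "PRI": VIDefinition("PRI", (531.0, 570.0), _normalized_difference(531.0, 570.0),
                            "normalized difference at 531/570 nm"),
        "ARI": VIDefinition("ARI", (550.0, 700.0), _reciprocal_difference(550.0, 700.0),
                            "1/R550 - 1/R700"),
        "CRI": VIDefinition("CRI", (510.0, 550.0), _reciprocal_difference(510.0, 550.0),
                            "1/R510 - 1/R550"),
    }


_REGISTRY: Dict[str, VIDefinition] = _builtin_registry()


def vi_registry() -> Dict[str, VIDefinition]:
    """The live registry (NDVI, PRI, ARI, CRI preloaded)."""
    return _REGISTRY


def reset_registry() -> None:
    """Restore the registry to the four built-in indices."""
    _REGISTRY.clear()
    _REGISTRY.update(_builtin_registry())


def register_vi(definition: VIDefinition, registry: Optional[Dict[str, VIDefinition]] = None) -> None:
    """Add an index definition; duplicate names are refused."""
    reg = _REGISTRY if registry is None else registry
    if definition.name in reg:
        raise DuplicateName(f"VI {definition.name!r} already registered")
    reg[definition.name] = definition


# --- operations -------------------------------------------------------------

def check_alignment(rgb_shape: Tuple[int, ...], cube_meta: CubeMeta) -> None:
    """Require identical spatial dimensions of RGB frame and cube.

    Orientation mismatches (transposed shapes) are reported, not auto-fixed:
    the ROI coordinates from the RGB frame are only meaningful on the cube
    when the frames are co-registered.
    """
    rgb_dims = tuple(rgb_shape[:2])
    cube_dims = (cube_meta.lines, cube_meta.samples)
    if rgb_dims != cube_dims:
        raise AlignmentError(
            f"RGB frame is {rgb_dims[1]}x{rgb_dims[0]} but cube is "
            f"{cube_dims[1]}x{cube_dims[0]} (cols x rows); re-register the inputs"
        )


def roi_mean_spectrum(cube: SpectralCube, roi: ROI, mask: Optional[np.ndarray] = None) -> MeanSpectrum:
    """Arithmetic mean reflectance of every band over the ROI rectangle.

    With ``mask`` given, only rectangle pixels where the mask is true enter
    the mean (mask-restricted mode).
    """
    roi.validate(cube.shape)
    block = cube.values[roi.slices].astype(np.float64)
    if mask is None:
        values = block.mean(axis=(0, 1))
        count = roi.width * roi.height
    else:
        sub = np.asarray(mask, dtype=bool)[roi.slices]
        if not sub.any():
            raise InvalidROI("mask-restricted ROI contains no pixels")
        values = block[sub].mean(axis=0)
        count = int(sub.sum())
    return MeanSpectrum(values=values, pixel_count=count)


def compute_vi(
    name: str,
    spectrum: MeanSpectrum,
    wavelengths: Optional[Sequence[float]],
    registry: Optional[Dict[str, VIDefinition]] = None,
) -> float:
    """Evaluate one registered index on a mean spectrum."""
    value, _, _ = _compute_vi_resolved(name, spectrum, wavelengths, registry)
    return value


def _compute_vi_resolved(
    name: str,
    spectrum: MeanSpectrum,
    wavelengths: Optional[Sequence[float]],
    registry: Optional[Dict[str, VIDefinition]] = None,
) -> Tuple[float, Tuple[int, ...], Tuple[float, ...]]:
    reg = _REGISTRY if registry is None else registry
    if name not in reg:
        raise KeyError(f"unknown VI {name!r}; registered: {sorted(reg)}")
    if wavelengths is None:
        raise UnresolvableWavelength(
            f"cube has no wavelength axis; cannot resolve bands for {name}"
        )
    defn = reg[name]
    w = np.asarray(wavelengths, dtype=float)
    band_idx = tuple(nearest_band(w, lam) for lam in defn.wavelengths)
    refl = {lam: float(spectrum.values[i]) for lam, i in zip(defn.wavelengths, band_idx)}
    value = float(defn.formula(refl))
    used = tuple(float(w[i]) for i in band_idx)
    return value, band_idx, used


def compute_all(
    cube: SpectralCube,
    roi: ROI,
    names: Optional[Sequence[str]] = None,
    registry: Optional[Dict[str, VIDefinition]] = None,
    mask: Optional[np.ndarray] = None,
) -> VIResult:
    """Mean spectrum once, then every requested index from it."""
    if names is None:
        names = list(DEFAULT_VI_NAMES)
    spectrum = roi_mean_spectrum(cube, roi, mask=mask)
    wl = cube.wavelengths
    values: Dict[str, float] = {}
    bands: Dict[str, Tuple[int, ...]] = {}
    used: Dict[str, Tuple[float, ...]] = {}
    for name in names:
        v, b, u = _compute_vi_resolved(name, spectrum, wl, registry)
        values[name] = v
        bands[name] = b
        used[name] = u
    return VIResult(values=values, bands=bands, wavelengths_used=used,
                    pixel_count=spectrum.pixel_count, roi=roi)
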