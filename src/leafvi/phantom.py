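"""Synthetic co-registered RGB + hyperspectral leaf scenes with known truth.

The phantom emulates the output of a 400–1000 nm, 204-band push-broom leaf
camera: an elliptical leaf on a soil-like background, an optional shaded
region, a reflectance cube, and the matching RGB frame rendered from that
cube. Every scene carries analytic ground-truth vegetation-index values, so
the whole pipeline — masking, thresholding, ROI placement, spectrum
extraction, VI computation — is testable without real camera data.

Spectral model
    The lit-leaf spectrum is a piecewise-linear interpolation of anchor
    reflectances at twelve wavelengths (400, 450, 510, 531, 550, 570, 650,
    700, 715, 750, 860, 1000 nm). Anchors are drawn so the four built-in
    indices hit sampled target values exactly, by inverting the index
    formulas (e.g. a drawn CRI* fixes R510 = 1/(CRI* + 1/R550)). This gives
    closed-form ground truth for exactly the quantities under test, which a
    biophysical radiative-transfer model would not.

Shadow model
    Multiplicative attenuation with a weak linear wavelength dependence,
    ``leaf(λ) × (s0 + s1 · (λ−400)/600)``. With s1 ≠ 0 the shaded region's
    normalized-difference indices genuinely differ from the lit region's —
    the minimal model reproducing the qualitative behaviour of real shaded
    leaf VIs — while reciprocal-form indices additionally scale.

RGB render
    Channel values are cube means over R: 620–680 nm, G: 520–580 nm,
    B: 430–490 nm, scaled by a fixed gain, clamped to [0, 1] and quantized
    to 8 bits. A draw is accepted only if the rendered lit leaf actually
    satisfies the pipeline's default greenness window and the rendered
    shadow falls below it, keeping the generator consistent with the scene
    semantics it advertises.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from PIL import Image

from .envi import CubeMeta, SpectralCube, nearest_band, read_envi, write_envi
from .errors import GenerationFailure, InvalidROI, IOFailure
from .indices import DEFAULT_VI_NAMES, MeanSpectrum, compute_vi
from .segmentation import DEFAULT_HSV_BOUNDS, ROI, rgb_to_hsv

ANCHOR_WAVELENGTHS = (400.0, 450.0, 510.0, 531.0, 550.0, 570.0,
                      650.0, 700.0, 715.0, 750.0, 860.0, 1000.0)

#: Index target sampling ranges (the observed spread of real leaf data).
TARGET_RANGES = {"PRI": (-0.03, 0.05), "ARI": (-0.7, 0.7), "CRI": (3.0, 9.0)}

#: RGB render: band windows (nm) and gain applied to the channel means.
RENDER_WINDOWS = {"R": (620.0, 680.0), "G": (520.0, 580.0), "B": (430.0, 490.0)}
RENDER_GAIN = 1.0 / 0.6

#: Acceptance margins for a sampled spectrum's rendering, relative to the
#: default greenness window (hue 60–170°, V >= 0.25): the lit leaf must pass
#: with headroom for per-pixel noise, the shadow must fail with headroom.
_LIT_HUE_RANGE = (63.0, 167.0)
_LIT_V_MIN = 0.27
_LIT_S_MIN = 0.20
_SHADOW_V_MAX = 0.23

SOIL_BASE, SOIL_SLOPE = 0.15, 0.15  # background ramp 0.15 + 0.15*(λ-400)/600

DEFAULT_SHADOW = (0.25, 0.10)  # (s0, s1) attenuation at 400 nm and its rise


@dataclass
class PhantomSpec:
    """Full description of one synthetic scene."""

    rows: int = 512
    cols: int = 512
    bands: int = 204
    anchors: Dict[float, float] = field(default_factory=dict)
    leaf_center: Tuple[float, float] = (256.0, 256.0)
    leaf_axes: Tuple[float, float] = (160.0, 110.0)  # semi-axes (a, b), pixels
    leaf_angle: float = 0.0  # radians
    shadow: bool = True
    shadow_angle: float = 0.0  # normal direction of the dividing half-plane
    shadow_offset: float = 0.0  # signed offset of the divider from the leaf center
    s0: float = DEFAULT_SHADOW[0]
    s1: float = DEFAULT_SHADOW[1]
    noise_sd: float = 0.005
    seed: int = 0
    targets: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 < self.s0 < 1):
            raise ValueError("s0 must be in (0, 1)")
        for lam, rho in self.anchors.items():
            if not (0 < rho < 1):
                raise ValueError(f"anchor reflectance R{lam:g}={rho:g} outside (0, 1)")

    @property
    def wavelengths(self) -> np.ndarray:
        """Evenly spaced band centers λ_i = 400 + i·600/(bands−1) nm."""
        return np.linspace(400.0, 1000.0, self.bands)


@dataclass
class SceneTruth:
    """A built scene: RGB frame, cube, region masks and analytic VI truth."""

    rgb: np.ndarray  # (rows, cols, 3) uint8
    cube: SpectralCube
    masks: Dict[str, np.ndarray]  # 'lit', 'shadow', 'background' — a partition
    truth: Dict[str, float]  # analytic VI values of the lit region
    spec: PhantomSpec


# --- spectra ----------------------------------------------------------------

def leaf_spectrum(spec: PhantomSpec) -> np.ndarray:
    """Lit-leaf reflectance per band: linear interpolation of the anchors."""
    lams = np.asarray(ANCHOR_WAVELENGTHS)
    vals = np.asarray([spec.anchors[l] for l in ANCHOR_WAVELENGTHS])
    return np.interp(spec.wavelengths, lams, vals)


def shadow_factor(spec: PhantomSpec) -> np.ndarray:
    """Per-band multiplicative shadow attenuation s0 + s1·(λ−400)/600."""
    frac = (spec.wavelengths - 400.0) / 600.0
    return spec.s0 + spec.s1 * frac


def soil_spectrum(wavelengths: np.ndarray) -> np.ndarray:
    """Background reflectance ramp: dim amber soil rising toward the NIR."""
    frac = (np.asarray(wavelengths) - 400.0) / 600.0
    return SOIL_BASE + SOIL_SLOPE * frac


def render_rgb(values: np.ndarray, wavelengths: np.ndarray) -> np.ndarray:
    """Render an 8-bit RGB frame from a reflectance cube (or single spectrum)."""
    values = np.asarray(values, dtype=np.float64)
    single = values.ndim == 1
    if single:
        values = values[None, None, :]
    wl = np.asarray(wavelengths)
    channels = []
    for name in ("R", "G", "B"):
        lo, hi = RENDER_WINDOWS[name]
        sel = (wl >= lo) & (wl <= hi)
        channels.append(values[:, :, sel].mean(axis=2))
    rgb = np.stack(channels, axis=-1) * RENDER_GAIN
    rgb = np.clip(rgb, 0.0, 1.0)
    out = np.rint(rgb * 255.0).astype(np.uint8)
    return out[0, 0] if single else out


def _render_ok(spec: PhantomSpec) -> bool:
    """Does this spectrum draw render as a green lit leaf / dark shadow?"""
    wl = spec.wavelengths
    lit32 = leaf_spectrum(spec).astype(np.float32).astype(np.float64)
    pixel = render_rgb(lit32, wl)
    h, s, v = rgb_to_hsv(pixel[None, None, :])[0, 0]
    if not (_LIT_HUE_RANGE[0] <= h <= _LIT_HUE_RANGE[1] and v >= _LIT_V_MIN
            and s >= _LIT_S_MIN):
        return False
    if spec.shadow:
        sh32 = (leaf_spectrum(spec) * shadow_factor(spec)).astype(np.float32)
        sh_pixel = render_rgb(sh32.astype(np.float64), wl)
        sv = rgb_to_hsv(sh_pixel[None, None, :])[0, 0, 2]
        if sv > _SHADOW_V_MAX:
            return False
    return True


# --- spec sampling ----------------------------------------------------------

def sample_spec(
    seed=None,
    *,
    size: Tuple[int, int] = (512, 512),
    bands: int = 204,
    noise_sd: float = 0.005,
    shadow: bool = True,
    target_ranges: Optional[Dict[str, Tuple[float, float]]] = None,
    max_attempts: int = 100,
) -> PhantomSpec:
    """Draw a random scene whose lit spectrum hits sampled VI targets exactly.

    Anchors: ρ_nir ∈ [0.40, 0.55] shared by R750/R860/R1000; R650 ∈
    [0.03, 0.12]; R550 ∈ [0.08, 0.20]; R400 = R450 ∈ [0.03, 0.05];
    R570 ∈ [0.8·R550, R550]; then the drawn CRI*, ARI*, PRI* targets are
    inverted into R510, R700 and R531, and R715 = (R700 + R750)/2. Draws are
    rejected (and redrawn, at most ``max_attempts`` times) when an anchor
    leaves (0, 1) or when the rendered scene would not present a green lit
    leaf over an excludable shadow.
    """
    ranges = dict(TARGET_RANGES)
    if target_ranges:
        ranges.update(target_ranges)
    rng = np.random.default_rng(seed)
    rows, cols = size
    half = min(rows, cols)

    for _ in range(max_attempts):
        rho_nir = rng.uniform(0.40, 0.55)
        r650 = rng.uniform(0.03, 0.12)
        r550 = rng.uniform(0.08, 0.20)
        r400 = rng.uniform(0.03, 0.05)
        cri = rng.uniform(*ranges["CRI"])
        ari = rng.uniform(*ranges["ARI"])
        pri = rng.uniform(*ranges["PRI"])
        r570 = rng.uniform(0.8, 1.0) * r550

        r510 = 1.0 / (cri + 1.0 / r550)
        r700 = 1.0 / (1.0 / r550 - ari)
        r531 = r570 * (1.0 + pri) / (1.0 - pri)

        anchors = {
            400.0: r400, 450.0: r400, 510.0: r510, 531.0: r531, 550.0: r550,
            570.0: r570, 650.0: r650, 700.0: r700, 715.0: (r700 + rho_nir) / 2.0,
            750.0: rho_nir, 860.0: rho_nir, 1000.0: rho_nir,
        }
        if not all(0.0 < rho < 1.0 for rho in anchors.values()):
            continue

        center = (rows / 2.0 + rng.uniform(-0.05, 0.05) * rows,
                  cols / 2.0 + rng.uniform(-0.05, 0.05) * cols)
        a = rng.uniform(0.26, 0.34) * half
        b = rng.uniform(0.18, 0.26) * half
        angle = rng.uniform(0.0, np.pi)
        shadow_angle = rng.uniform(0.0, 2.0 * np.pi)
        shadow_offset = rng.uniform(-0.2, 0.2) * b
        noise_seed = int(rng.integers(0, 2**31 - 1))

        spec = PhantomSpec(
            rows=rows, cols=cols, bands=bands, anchors=anchors,
            leaf_center=center, leaf_axes=(a, b), leaf_angle=angle,
            shadow=shadow, shadow_angle=shadow_angle, shadow_offset=shadow_offset,
            noise_sd=noise_sd, seed=noise_seed,
            targets={"CRI": cri, "ARI": ari, "PRI": pri},
        )
        if _render_ok(spec):
            return spec
    raise GenerationFailure(f"no acceptable spectrum after {max_attempts} draws")


# --- scene assembly ---------------------------------------------------------

def _region_masks(spec: PhantomSpec) -> Dict[str, np.ndarray]:
    rows, cols = spec.rows, spec.cols
    rr, cc = np.mgrid[0:rows, 0:cols].astype(np.float64)
    dr = rr - spec.leaf_center[0]
    dc = cc - spec.leaf_center[1]
    ct, st = np.cos(spec.leaf_angle), np.sin(spec.leaf_angle)
    u = dr * ct + dc * st
    v = -dr * st + dc * ct
    a, b = spec.leaf_axes
    leaf = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    if spec.shadow:
        n0, n1 = np.cos(spec.shadow_angle), np.sin(spec.shadow_angle)
        shadow_side = dr * n0 + dc * n1 >= spec.shadow_offset
        shadow = leaf & shadow_side
    else:
        shadow = np.zeros_like(leaf)
    lit = leaf & ~shadow
    background = ~leaf
    return {"lit": lit, "shadow": shadow, "background": background}


def build_scene(spec: PhantomSpec) -> SceneTruth:
    """Assemble cube, RGB frame, masks and analytic truth for one spec.

    The cube is float32 (camera parity); the analytic truth is computed from
    the same float32-quantized lit spectrum the cube stores, so a noiseless
    scene reproduces the truth to floating-point precision.
    """
    wl = spec.wavelengths
    masks = _region_masks(spec)

    lit32 = leaf_spectrum(spec).astype(np.float32)
    shadow32 = (leaf_spectrum(spec) * shadow_factor(spec)).astype(np.float32)
    soil32 = soil_spectrum(wl).astype(np.float32)

    cube_values = np.empty((spec.rows, spec.cols, spec.bands), dtype=np.float32)
    cube_values[masks["background"]] = soil32
    cube_values[masks["lit"]] = lit32
    if masks["shadow"].any():
        cube_values[masks["shadow"]] = shadow32
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        cube_values = cube_values + rng.normal(
            0.0, spec.noise_sd, cube_values.shape
        ).astype(np.float32)
        np.maximum(cube_values, 1e-4, out=cube_values)  # keep reciprocals defined

    rgb = render_rgb(cube_values, wl)

    truth_spectrum = MeanSpectrum(values=lit32.astype(np.float64), pixel_count=1)
    truth = {name: compute_vi(name, truth_spectrum, wl) for name in DEFAULT_VI_NAMES}

    meta = CubeMeta(
        samples=spec.cols, lines=spec.rows, bands=spec.bands,
        interleave="bsq", data_type=4, byte_order=0,
        wavelengths=tuple(float(w) for w in wl),
    )
    cube = SpectralCube(meta=meta, values=cube_values)
    return SceneTruth(rgb=rgb, cube=cube, masks=masks, truth=truth, spec=spec)


def scene_batch(
    n: int,
    seed: int,
    *,
    size: Tuple[int, int] = (512, 512),
    bands: int = 204,
    noise_sd: float = 0.005,
    shadow: bool = True,
) -> List[SceneTruth]:
    """n independent scenes from one master seed (per-scene spawned streams)."""
    root = np.random.SeedSequence(int(seed))
    return [
        build_scene(sample_spec(child, size=size, bands=bands,
                                noise_sd=noise_sd, shadow=shadow))
        for child in root.spawn(n)
    ]


def jittered_roi(roi: ROI, mask: np.ndarray, rng, max_offset: int = 5,
                 max_attempts: int = 100) -> ROI:
    """Same-size ROI offset by up to ``max_offset`` px, kept inside ``mask``.

    Surrogate for an independent manual annotation of the same leaf area.
    Falls back to the unshifted ROI if no jittered placement fits.
    """
    mask = np.asarray(mask, dtype=bool)
    rows, cols = mask.shape
    for _ in range(max_attempts):
        dr = int(rng.integers(-max_offset, max_offset + 1))
        dc = int(rng.integers(-max_offset, max_offset + 1))
        x1, y1 = roi.x1 + dc, roi.y1 + dr
        x2, y2 = roi.x2 + dc, roi.y2 + dr
        if x1 < 0 or y1 < 0 or x2 > cols or y2 > rows:
            continue
        cand = ROI(x1, y1, x2, y2)
        if mask[cand.slices].all():
            return cand
    return roi


# --- emission ---------------------------------------------------------------

def emit_scene(scene: SceneTruth, directory: Union[str, Path],
               stem: str = "scene") -> Dict[str, Path]:
    """Write a scene to disk: PNG, ENVI hdr+dat (float32 BSQ), mask PNGs, truth JSON."""
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        paths: Dict[str, Path] = {}
        rgb_path = directory / f"{stem}.png"
        Image.fromarray(scene.rgb).save(rgb_path)
        paths["rgb"] = rgb_path
        hdr, dat = write_envi(directory / stem, scene.cube, interleave="bsq")
        paths["header"], paths["data"] = hdr, dat
        for name, mask in scene.masks.items():
            p = directory / f"{stem}_mask_{name}.png"
            Image.fromarray((mask.astype(np.uint8)) * 255).save(p)
            paths[f"mask_{name}"] = p
        truth_path = directory / f"{stem}_truth.json"
        payload = {
            "vi": scene.truth,
            "targets": scene.spec.targets,
            "noise_sd": scene.spec.noise_sd,
            "seed": scene.spec.seed,
            "shadow": scene.spec.shadow,
            "anchors": {f"{lam:g}": rho for lam, rho in scene.spec.anchors.items()},
            "lit_area": int(scene.masks["lit"].sum()),
        }
        truth_path.write_text(json.dumps(payload, indent=1, sort_keys=True))
        paths["truth"] = truth_path
    except OSError as exc:
        raise IOFailure(f"cannot write scene under {directory}: {exc}") from exc
    return paths
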