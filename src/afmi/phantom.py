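"""Synthetic multichannel tissue phantoms.

Generates cohorts of multispectral image stacks with known class geometry
(normal / PTG / OSSN regions), per-patient affine spectral variability, and
camera/illumination degradations (background fluorescence, vignetting, dead
and saturated pixels, Poisson noise).  Ground truth for every injected
effect is retained so downstream corrections can be verified exactly.

Class mean spectra are nonnegative mixtures of smooth unimodal fluorophore
basis curves over channel index; the mixtures encode the qualitative
class contrasts the analysis is designed to detect:

* elastin channel (3): normal > PTG > OSSN
* lipopigment channel (12): OSSN elevated, normal ~= PTG
* flavins (30) and PPIX (52) channels: OSSN reduced, normal ~= PTG
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import ndimage

from .channels import ChannelTable, default_channel_table

__all__ = [
    "CLASS_NAMES",
    "CLASS_IDS",
    "PhantomSpec",
    "PhantomTruth",
    "PatientStack",
    "PhantomSpecError",
    "fluorophore_basis",
    "default_class_spectra",
    "vignette_field",
    "generate_clean_stack",
    "apply_degradations",
    "generate_patient",
    "generate_cohort",
    "default_cohort_spec",
    "write_patient_stack",
    "read_patient_stack",
]

CLASS_NAMES = ("normal", "PTG", "OSSN")
CLASS_IDS = {"normal": 1, "PTG": 2, "OSSN": 3}
ID_TO_CLASS = {v: k for k, v in CLASS_IDS.items()}

# fluorophore basis curves: (center channel, width in channels)
_BASIS_PARAMS = {
    "elastin": (3.0, 2.5),
    "lipopigment": (12.0, 2.5),
    "flavins": (30.0, 6.0),
    "PPIX": (52.0, 5.0),
    "background": (30.0, 40.0),
}

# class mixture weights; normal == PTG except elastin by construction so the
# lipopigment/flavins/PPIX channels carry no normal-vs-PTG contrast.
# Contrasts are moderate (10-20%): large enough for within-patient
# separation, small enough that raw cross-patient classification is
# genuinely degraded by the per-channel patient gain scatter.
_CLASS_WEIGHTS = {
    "normal": {"elastin": 1.000, "lipopigment": 0.500, "flavins": 1.000, "PPIX": 1.000, "background": 0.40},
    "PTG": {"elastin": 0.886, "lipopigment": 0.500, "flavins": 1.000, "PPIX": 1.000, "background": 0.40},
    "OSSN": {"elastin": 0.799, "lipopigment": 0.635, "flavins": 0.865, "PPIX": 0.850, "background": 0.40},
}


class PhantomSpecError(ValueError):
    """Degenerate or out-of-range phantom specification."""


def fluorophore_basis(n_channels: int = 59) -> dict[str, np.ndarray]:
    """Unit-peak Gaussian basis curves over 1-based channel index."""
    ch = np.arange(1, n_channels + 1, dtype=float)
    return {
        name: np.exp(-0.5 * ((ch - center) / width) ** 2)
        for name, (center, width) in _BASIS_PARAMS.items()
    }


def default_class_spectra(
    n_channels: int = 59, base_intensity: float = 1200.0
) -> dict[str, np.ndarray]:
    """Per-class mean emission spectra (photon counts per pixel)."""
    basis = fluorophore_basis(n_channels)
    spectra = {}
    for cls, weights in _CLASS_WEIGHTS.items():
        spectrum = np.zeros(n_channels)
        for name, w in weights.items():
            spectrum += w * basis[name]
        spectra[cls] = base_intensity * spectrum
    return spectra


@dataclass
class PhantomSpec:
    """Parameters of a synthetic cohort.

    ``patient_offset_sd`` of None means 10% of the grand mean class signal.
    ``texture_sd`` controls smooth multiplicative within-class biological
    texture (log-scale sd); set 0 for piecewise-constant tissue.
    """

    n_patients: int = 1
    image_shape: tuple[int, int] = (512, 512)
    channel_table: Optional[ChannelTable] = None
    class_spectra: Optional[dict[str, np.ndarray]] = None
    base_intensity: float = 1200.0
    patient_scale_sd: float = 0.25
    patient_offset_sd: Optional[float] = None
    vignette_strength: float = 0.3
    background_level: float = 40.0
    dead_pixel_fraction: float = 0.001
    saturated_pixel_fraction: float = 0.0005
    poisson: bool = True
    texture_sd: float = 0.12
    texture_scale_px: float = 8.0
    saturation_value: int = 65535
    layout: str = "bands"
    tissue_margin_frac: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.channel_table is None:
            self.channel_table = default_channel_table()
        if self.class_spectra is None:
            self.class_spectra = default_class_spectra(
                self.channel_table.n_channels, self.base_intensity
            )
        self.validate()

    @property
    def n_channels(self) -> int:
        return self.channel_table.n_channels

    @property
    def offset_sd(self) -> float:
        if self.patient_offset_sd is not None:
            return self.patient_offset_sd
        return 0.10 * float(
            np.mean([s.mean() for s in self.class_spectra.values()])
        )

    def validate(self) -> None:
        if self.n_patients < 1:
            raise PhantomSpecError("n_patients must be >= 1")
        rows, cols = self.image_shape
        if rows < 16 or cols < 16:
            raise PhantomSpecError("image_shape must be at least 16x16")
        for name in CLASS_NAMES:
            if name not in self.class_spectra:
                raise PhantomSpecError(f"class_spectra missing class {name!r}")
            spec = np.asarray(self.class_spectra[name], dtype=float)
            if spec.shape != (self.n_channels,):
                raise PhantomSpecError(
                    f"class_spectra[{name!r}] must have length {self.n_channels}"
                )
            if np.any(spec < 0):
                raise PhantomSpecError(f"class_spectra[{name!r}] must be nonnegative")
        for frac_name in ("dead_pixel_fraction", "saturated_pixel_fraction"):
            frac = getattr(self, frac_name)
            if not 0 <= frac < 1:
                raise PhantomSpecError(f"{frac_name} must be in [0, 1)")
        if not 0 <= self.vignette_strength <= 1:
            raise PhantomSpecError("vignette_strength must be in [0, 1]")
        if self.background_level < 0:
            raise PhantomSpecError("background_level must be >= 0")
        if self.layout not in ("bands", "blobs"):
            raise PhantomSpecError(f"unknown layout {self.layout!r}")
        if not 0 <= self.tissue_margin_frac < 0.5:
            raise PhantomSpecError("tissue_margin_frac must be in [0, 0.5)")


@dataclass
class PhantomTruth:
    """Everything injected into a degraded stack, for exact verification."""

    clean: np.ndarray  # (n_channels, rows, cols) noise-free textured signal
    gain: np.ndarray  # per-channel multiplicative patient gain
    offset: np.ndarray  # per-channel additive patient offset
    vignette: np.ndarray  # (rows, cols) illumination field, peak 1
    background_level: float
    dead_pixels: np.ndarray  # (n_dead, 2) row/col, applied to all channels
    saturated_pixels: np.ndarray  # (n_sat, 2)
    saturation_value: int


@dataclass
class PatientStack:
    """One patient's multichannel stack plus tissue label mask."""

    patient_id: str
    stack: np.ndarray  # (n_channels, rows, cols), photon counts >= 0
    mask: np.ndarray  # (rows, cols) int: 0 outside, 1 normal, 2 PTG, 3 OSSN
    channel_table: ChannelTable = field(default_factory=default_channel_table)
    truth: Optional[PhantomTruth] = None

    def __post_init__(self) -> None:
        if self.stack.ndim != 3:
            raise ValueError("stack must be (n_channels, rows, cols)")
        if self.stack.shape[0] != self.channel_table.n_channels:
            raise ValueError(
                f"stack has {self.stack.shape[0]} planes but channel table "
                f"defines {self.channel_table.n_channels}"
            )
        if self.mask.shape != self.stack.shape[1:]:
            raise ValueError("mask shape must match stack spatial shape")

    @property
    def n_channels(self) -> int:
        return self.stack.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.stack.shape[1:]


def vignette_field(shape: tuple[int, int], strength: float) -> np.ndarray:
    """Radial illumination falloff: 1 at center, 1 - strength at the corner.

    Quadratic in the pixel coordinates, so a degree-2 polynomial surface can
    represent it exactly.
    """
    rows, cols = shape
    r = np.arange(rows)[:, None] - (rows - 1) / 2.0
    c = np.arange(cols)[None, :] - (cols - 1) / 2.0
    d2 = r**2 + c**2
    return 1.0 - strength * d2 / d2.max()


def _class_mask(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    rows, cols = spec.image_shape
    mask = np.zeros((rows, cols), dtype=np.uint8)
    mr = int(round(spec.tissue_margin_frac * rows))
    mc = int(round(spec.tissue_margin_frac * cols))
    r0, r1 = mr, rows - mr
    c0, c1 = mc, cols - mc
    if r1 - r0 < 3 or c1 - c0 < 3:
        raise PhantomSpecError("tissue region degenerate; reduce margin")
    if spec.layout == "bands":
        width = c1 - c0
        b1 = c0 + width // 3
        b2 = c0 + (2 * width) // 3
        mask[r0:r1, c0:b1] = CLASS_IDS["normal"]
        mask[r0:r1, b1:b2] = CLASS_IDS["PTG"]
        mask[r0:r1, b2:c1] = CLASS_IDS["OSSN"]
    else:  # blobs: normal tissue slab with irregular PTG and OSSN lesions
        mask[r0:r1, c0:c1] = CLASS_IDS["normal"]
        yy = np.arange(rows)[:, None]
        xx = np.arange(cols)[None, :]
        for cls, cx_frac in (("PTG", 0.42), ("OSSN", 0.72)):
            cy = (r0 + r1) / 2 + rng.uniform(-0.1, 0.1) * (r1 - r0)
            cx = c0 + cx_frac * (c1 - c0) + rng.uniform(-0.05, 0.05) * (c1 - c0)
            ry = 0.30 * (r1 - r0) * rng.uniform(0.8, 1.2)
            rx = 0.16 * (c1 - c0) * rng.uniform(0.8, 1.2)
            angle = rng.uniform(0, np.pi)
            ca, sa = np.cos(angle), np.sin(angle)
            u = (xx - cx) * ca + (yy - cy) * sa
            v = -(xx - cx) * sa + (yy - cy) * ca
            blob = (u / rx) ** 2 + (v / ry) ** 2 <= 1.0
            blob &= mask > 0
            mask[blob] = CLASS_IDS[cls]
    for name, cid in CLASS_IDS.items():
        if not np.any(mask == cid):
            raise PhantomSpecError(f"layout produced zero-area class {name!r}")
    return mask


def _texture_field(
    shape: tuple[int, int], sd: float, scale_px: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth multiplicative log-normal texture with mean 1, pixel log-sd=sd."""
    if sd <= 0:
        return np.ones(shape)
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=scale_px, mode="reflect")
    smooth *= sd / smooth.std()
    return np.exp(smooth - 0.5 * sd**2)


def generate_clean_stack(
    spec: PhantomSpec, rng: np.random.Generator, patient_id: str = "P00"
) -> PatientStack:
    """Noise-free textured stack (no patient effects, no degradations)."""
    mask = _class_mask(spec, rng)
    texture = _texture_field(spec.image_shape, spec.texture_sd, spec.texture_scale_px, rng)
    rows, cols = spec.image_shape
    clean = np.zeros((spec.n_channels, rows, cols))
    for name, cid in CLASS_IDS.items():
        sel = mask == cid
        if np.any(sel):
            clean[:, sel] = np.asarray(spec.class_spectra[name])[:, None] * texture[sel]
    truth = PhantomTruth(
        clean=clean,
        gain=np.ones(spec.n_channels),
        offset=np.zeros(spec.n_channels),
        vignette=np.ones(spec.image_shape),
        background_level=0.0,
        dead_pixels=np.empty((0, 2), dtype=int),
        saturated_pixels=np.empty((0, 2), dtype=int),
        saturation_value=spec.saturation_value,
    )
    # stack shares memory with truth.clean; degradation never mutates in place
    return PatientStack(
        patient_id=patient_id,
        stack=clean,
        mask=mask,
        channel_table=spec.channel_table,
        truth=truth,
    )


def apply_degradations(
    clean: PatientStack, spec: PhantomSpec, rng: np.random.Generator
) -> PatientStack:
    """Inject patient effects and camera/illumination degradations.

    degraded = Poisson(vignette * (gain * clean + offset) + background),
    then dead pixels forced to 0 and saturated pixels to the full-well value.
    """
    if clean.truth is None:
        raise ValueError("clean stack must carry truth")
    n_ch = clean.n_channels
    rows, cols = clean.shape

    gain = np.exp(rng.normal(0.0, spec.patient_scale_sd, size=n_ch))
    offset = rng.normal(0.0, spec.offset_sd, size=n_ch)
    vig = vignette_field((rows, cols), spec.vignette_strength)

    signal = gain[:, None, None] * clean.truth.clean + offset[:, None, None]
    np.clip(signal, 0.0, None, out=signal)
    expected = vig[None] * signal + spec.background_level
    if spec.poisson:
        degraded = rng.poisson(expected).astype(np.float64)
    else:
        degraded = expected.copy()

    n_pix = rows * cols
    n_dead = int(round(spec.dead_pixel_fraction * n_pix))
    n_sat = int(round(spec.saturated_pixel_fraction * n_pix))
    flat = rng.choice(n_pix, size=n_dead + n_sat, replace=False) if n_dead + n_sat else np.empty(0, int)
    dead = np.column_stack(np.unravel_index(flat[:n_dead], (rows, cols))) if n_dead else np.empty((0, 2), int)
    sat = np.column_stack(np.unravel_index(flat[n_dead:], (rows, cols))) if n_sat else np.empty((0, 2), int)
    if n_dead:
        degraded[:, dead[:, 0], dead[:, 1]] = 0.0
    if n_sat:
        degraded[:, sat[:, 0], sat[:, 1]] = float(spec.saturation_value)

    truth = PhantomTruth(
        clean=clean.truth.clean,
        gain=gain,
        offset=offset,
        vignette=vig,
        background_level=spec.background_level,
        dead_pixels=dead,
        saturated_pixels=sat,
        saturation_value=spec.saturation_value,
    )
    return PatientStack(
        patient_id=clean.patient_id,
        stack=degraded,
        mask=clean.mask,
        channel_table=clean.channel_table,
        truth=truth,
    )


def generate_patient(
    spec: PhantomSpec, seed_seq: np.random.SeedSequence, patient_id: str
) -> PatientStack:
    rng = np.random.default_rng(seed_seq)
    clean = generate_clean_stack(spec, rng, patient_id=patient_id)
    return apply_degradations(clean, spec, rng)


def generate_cohort(spec: PhantomSpec) -> list[PatientStack]:
    """Generate ``spec.n_patients`` degraded stacks, reproducible from seed."""
    spec.validate()
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_patients)
    return [
        generate_patient(spec, child, patient_id=f"P{i + 1:02d}")
        for i, child in enumerate(children)
    ]


def default_cohort_spec(seed: int = 1, n_patients: int = 20) -> PhantomSpec:
    """The default evaluation cohort.

    256x256 frames (rather than the full 512x512 sensor default) keep a
    20-patient cohort generable in seconds while leaving >200 sectors per
    patient.
    """
    return PhantomSpec(n_patients=n_patients, image_shape=(256, 256), seed=seed)


# ---------------------------------------------------------------------------
# I/O: multichannel TIFF + mask + truth sidecar


def write_patient_stack(stack: PatientStack, out_dir: str | Path) -> dict[str, Path]:
    import tifffile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "stack": out_dir / f"{stack.patient_id}_stack.tif",
        "mask": out_dir / f"{stack.patient_id}_mask.tif",
    }
    tifffile.imwrite(paths["stack"], stack.stack.astype(np.float32))
    tifffile.imwrite(paths["mask"], stack.mask.astype(np.uint8))
    if stack.truth is not None:
        truth_path = out_dir / f"{stack.patient_id}_truth.json"
        payload = {
            "gain": stack.truth.gain.tolist(),
            "offset": stack.truth.offset.tolist(),
            "background_level": stack.truth.background_level,
            "dead_pixels": stack.truth.dead_pixels.tolist(),
            "saturated_pixels": stack.truth.saturated_pixels.tolist(),
            "saturation_value": stack.truth.saturation_value,
        }
        truth_path.write_text(json.dumps(payload))
        paths["truth"] = truth_path
    return paths


def read_patient_stack(
    stack_path: str | Path,
    mask_path: str | Path,
    channel_table: Optional[ChannelTable] = None,
    patient_id: Optional[str] = None,
) -> PatientStack:
    import tifffile

    stack_path = Path(stack_path)
    stack = np.asarray(tifffile.imread(stack_path), dtype=np.float64)
    mask = np.asarray(tifffile.imread(mask_path)).astype(np.int64)
    if patient_id is None:
        patient_id = stack_path.stem.replace("_stack", "")
    return PatientStack(
        patient_id=patient_id,
        stack=stack,
        mask=mask,
        channel_table=channel_table or default_channel_table(),
    )
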