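"""Image restoration ahead of signature extraction.

Pipeline order: bad-pixel repair -> background subtraction -> flat-field
(illumination) correction -> optional tile stitching.  Poisson noise is not
explicitly filtered; sector averaging downstream is the variance-reduction
step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .phantom import PatientStack

__all__ = [
    "PreprocessConfig",
    "PreprocessError",
    "FlatFieldFitError",
    "ChannelCorruptionError",
    "StitchRegistrationError",
    "BadPixelReport",
    "repair_bad_pixels",
    "correct_field",
    "preprocess_stack",
    "stitch_tiles",
]


class PreprocessError(ValueError):
    """Base class for preprocessing failures."""


class FlatFieldFitError(PreprocessError):
    """Fitted illumination field has non-positive values (over-aggressive fit)."""


class ChannelCorruptionError(PreprocessError):
    """More than the allowed fraction of a channel flagged as defective."""


class StitchRegistrationError(PreprocessError):
    """Estimated tile shift exceeds plausibility bound."""


@dataclass
class PreprocessConfig:
    background_mode: str = "constant_from_dark_region"  # or "percentile"
    background_percentile: float = 5.0
    flatfield_mode: str = "polynomial_fit"  # "provided_field" | "polynomial_fit" | "none"
    poly_degree: int = 2
    badpixel_detect: str = "zeros_and_saturated"  # or "mad_outlier"
    mad_k: float = 6.0
    saturation_value: int = 65535
    max_defect_fraction: float = 0.20
    smooth_sigma_frac: float = 1 / 16  # smoothing scale for maskless flat-field fit
    denoise: bool = False  # Anscombe + Gaussian smoothing (off: sector averaging suffices)
    denoise_sigma: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.background_percentile <= 50:
            raise PreprocessError("background_percentile must be in (0, 50]")
        if not 1 <= self.poly_degree <= 4:
            raise PreprocessError("poly_degree must be in [1, 4]")
        if self.background_mode not in ("constant_from_dark_region", "percentile", "none"):
            raise PreprocessError(f"unknown background_mode {self.background_mode!r}")
        if self.flatfield_mode not in ("provided_field", "polynomial_fit", "none"):
            raise PreprocessError(f"unknown flatfield_mode {self.flatfield_mode!r}")
        if self.badpixel_detect not in ("zeros_and_saturated", "mad_outlier"):
            raise PreprocessError(f"unknown badpixel_detect {self.badpixel_detect!r}")


@dataclass
class BadPixelReport:
    """Defect coordinates per channel: list of (channel_axis, row, col, kind)."""

    entries: list[tuple[int, int, int, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def coordinates(self, channel_axis: Optional[int] = None) -> set[tuple[int, int]]:
        return {
            (r, c)
            for ch, r, c, _ in self.entries
            if channel_axis is None or ch == channel_axis
        }

    def to_rows(self) -> list[dict]:
        return [
            {"channel": ch + 1, "row": r, "col": c, "kind": kind}
            for ch, r, c, kind in self.entries
        ]


def _median_of_neighbors(plane: np.ndarray, bad: np.ndarray) -> np.ndarray:
    """Median of the up-to-8 non-defective neighbors of each flagged pixel."""
    padded = np.pad(plane.astype(float), 1, mode="constant", constant_values=np.nan)
    bad_padded = np.pad(bad, 1, mode="constant", constant_values=True)
    padded[bad_padded] = np.nan
    shifts = [
        padded[1 + dr : padded.shape[0] - 1 + dr, 1 + dc : padded.shape[1] - 1 + dc]
        for dr in (-1, 0, 1)
        for dc in (-1, 0, 1)
        if (dr, dc) != (0, 0)
    ]
    stacked = np.stack(shifts)
    with np.errstate(all="ignore"):
        med = np.nanmedian(stacked, axis=0)
    # isolated clusters with no good neighbor: fall back to channel median
    fallback = np.median(plane[~bad]) if np.any(~bad) else 0.0
    return np.where(np.isnan(med), fallback, med)


def repair_bad_pixels(
    stack: PatientStack, cfg: PreprocessConfig
) -> tuple[PatientStack, BadPixelReport]:
    """Detect and repair dead/saturated (or MAD-outlier) pixels.

    Flagged pixels are replaced by the median of their available 8-neighbors.
    Raises :class:`ChannelCorruptionError` if more than
    ``cfg.max_defect_fraction`` of any channel is flagged.
    """
    out = stack.stack.astype(np.float64).copy()
    report = BadPixelReport()
    n_pix = out.shape[1] * out.shape[2]
    for ch in range(out.shape[0]):
        plane = out[ch]
        if cfg.badpixel_detect == "zeros_and_saturated":
            dead = plane == 0
            sat = plane >= cfg.saturation_value
        else:
            med = np.median(plane)
            mad = np.median(np.abs(plane - med))
            scale = 1.4826 * mad if mad > 0 else 1.0
            outlier = np.abs(plane - med) > cfg.mad_k * scale
            dead = outlier & (plane < med)
            sat = outlier & (plane >= med)
        bad = dead | sat
        n_bad = int(bad.sum())
        if n_bad == 0:
            continue
        if n_bad > cfg.max_defect_fraction * n_pix:
            raise ChannelCorruptionError(
                f"channel {ch + 1}: {n_bad}/{n_pix} pixels flagged "
                f"(> {cfg.max_defect_fraction:.0%}); input looks corrupted"
            )
        med8 = _median_of_neighbors(plane, bad)
        plane[bad] = med8[bad]
        for r, c in zip(*np.nonzero(dead)):
            report.entries.append((ch, int(r), int(c), "dead"))
        for r, c in zip(*np.nonzero(sat)):
            report.entries.append((ch, int(r), int(c), "saturated"))
    repaired = replace(stack, stack=out)
    return repaired, report


def _poly_design(shape: tuple[int, int], degree: int) -> np.ndarray:
    rows, cols = shape
    y = np.linspace(-1.0, 1.0, rows)[:, None] * np.ones((1, cols))
    x = np.linspace(-1.0, 1.0, cols)[None, :] * np.ones((rows, 1))
    terms = [
        (x**i) * (y**j)
        for i in range(degree + 1)
        for j in range(degree + 1 - i)
    ]
    return np.stack([t.ravel() for t in terms], axis=1)


class _IlluminationFitter:
    """Per-channel illumination estimation with shared spatial machinery.

    With a tissue label mask the image is modeled multiplicatively as
    level(label) x field(x, y), solved by alternating least squares: the
    polynomial field and the per-label levels are re-estimated in turn.
    Naively dividing each label region by its own mean would fold the
    label-dependent mean illumination into the tissue levels and bias
    region comparisons downstream.  Without a mask, a heavily smoothed
    copy of the image is fitted directly.
    """

    def __init__(
        self,
        shape: tuple[int, int],
        mask: Optional[np.ndarray],
        degree: int,
        smooth_sigma: float,
        n_iter: int = 10,
        tol: float = 1e-8,
    ):
        self.shape = shape
        self.degree = degree
        self.smooth_sigma = smooth_sigma
        self.n_iter = n_iter
        self.tol = tol
        self.design = _poly_design(shape, degree)
        self.label_sels: list[np.ndarray] = []
        if mask is not None and np.any(mask > 0):
            flat_mask = mask.ravel()
            self.label_sels = [
                flat_mask == lab for lab in np.unique(flat_mask) if lab != 0
            ]
            tissue = flat_mask > 0
            self.tissue = tissue
            # one pseudo-inverse reused across all channels and iterations
            self.pinv = np.linalg.pinv(self.design[tissue])
        else:
            self.tissue = None
            self.pinv = np.linalg.pinv(self.design)

    def fit(self, plane: np.ndarray) -> np.ndarray:
        flat = plane.ravel().astype(float)
        if self.tissue is None:
            smoothed = ndimage.gaussian_filter(
                plane.astype(float), sigma=self.smooth_sigma
            )
            coef = self.pinv @ smoothed.ravel()
            fitted = self.design @ coef
        else:
            field_t = np.ones(int(self.tissue.sum()))
            target = np.ones_like(field_t)
            # pixels clipped to zero upstream carry no illumination signal
            usable = flat[self.tissue] > 0
            prev = None
            for _ in range(self.n_iter):
                # per-label tissue levels given the current field
                for sel in self.label_sels:
                    sel_t = sel[self.tissue]
                    lv = np.mean(flat[sel] / np.maximum(field_t[sel_t], 1e-12))
                    target[sel_t] = flat[sel] / max(lv, 1e-12)
                target[~usable] = field_t[~usable]
                coef = self.pinv @ target
                field_t = self.design[self.tissue] @ coef
                if prev is not None and np.max(np.abs(field_t - prev)) < self.tol:
                    break
                prev = field_t
            fitted = self.design @ coef
        fitted = fitted.reshape(self.shape)
        if fitted.min() <= 0:
            raise FlatFieldFitError(
                "fitted illumination field is non-positive; "
                "reduce poly_degree or provide the field explicitly"
            )
        # peak-normalize: full illumination = 1, so intensity scale is kept
        return fitted / fitted.max()


def correct_field(
    stack: PatientStack,
    cfg: PreprocessConfig,
    illumination: Optional[np.ndarray] = None,
) -> PatientStack:
    """Subtract per-channel background then divide out the illumination field.

    Background: a constant per channel, estimated from the outside-tissue
    region (``constant_from_dark_region``, falling back to a whole-frame 1st
    percentile when the mask has no outside pixels) or from a whole-frame
    percentile.  Flat-field: a provided field, or a degree-``poly_degree``
    polynomial surface fitted per channel; the field is normalized to unit
    mean so overall intensity scale is preserved.
    """
    if np.any(stack.stack < 0):
        raise PreprocessError("correct_field expects a nonnegative stack")
    out = stack.stack.astype(np.float64).copy()
    rows, cols = stack.shape
    outside = stack.mask == 0
    fitter = None
    if cfg.flatfield_mode == "polynomial_fit":
        fitter = _IlluminationFitter(
            (rows, cols),
            stack.mask,
            cfg.poly_degree,
            smooth_sigma=cfg.smooth_sigma_frac * min(rows, cols),
        )

    for ch in range(out.shape[0]):
        plane = out[ch]
        if cfg.background_mode == "none":
            bg = 0.0
        elif cfg.background_mode == "constant_from_dark_region" and np.any(outside):
            bg = np.percentile(plane[outside], cfg.background_percentile)
        elif cfg.background_mode == "constant_from_dark_region":
            bg = np.percentile(plane, 1.0)
        else:
            bg = np.percentile(plane, cfg.background_percentile)
        plane -= bg
        np.clip(plane, 0.0, None, out=plane)

        if cfg.flatfield_mode == "provided_field":
            if illumination is None:
                raise PreprocessError("flatfield_mode='provided_field' needs a field")
            if illumination.min() <= 0:
                raise FlatFieldFitError("provided illumination field non-positive")
            fld = illumination
        elif cfg.flatfield_mode == "polynomial_fit":
            fld = fitter.fit(plane)
        else:
            fld = None
        if fld is not None:
            plane /= fld

        if cfg.denoise:
            # variance-stabilizing Anscombe transform, smooth, invert
            stabilized = 2.0 * np.sqrt(plane + 3.0 / 8.0)
            smoothed = ndimage.gaussian_filter(stabilized, sigma=cfg.denoise_sigma)
            plane[:] = np.maximum((smoothed / 2.0) ** 2 - 3.0 / 8.0, 0.0)
    return replace(stack, stack=out)


def preprocess_stack(
    stack: PatientStack,
    cfg: Optional[PreprocessConfig] = None,
    illumination: Optional[np.ndarray] = None,
) -> tuple[PatientStack, BadPixelReport]:
    """Full restoration chain: repair -> background -> flat-field."""
    cfg = cfg or PreprocessConfig()
    repaired, report = repair_bad_pixels(stack, cfg)
    corrected = correct_field(repaired, cfg, illumination=illumination)
    return corrected, report


# ---------------------------------------------------------------------------
# Stitching


def _register_pair(
    ref: np.ndarray, mov: np.ndarray
) -> tuple[int, int]:
    """Translation (dy, dx) aligning ``mov`` onto ``ref`` by phase correlation."""
    from skimage.registration import phase_cross_correlation

    shift, _, _ = phase_cross_correlation(ref, mov, normalization="phase")
    return int(round(shift[0])), int(round(shift[1]))


def stitch_tiles(
    tiles: Sequence[PatientStack],
    origins: Optional[Sequence[tuple[int, int]]] = None,
    overlap_px: int = 32,
    ref_channel: int = 1,
) -> PatientStack:
    """Assemble overlapping tiles into one stack.

    Tiles are placed at their nominal origins (row, col); each tile after the
    first is refined by phase correlation of its overlap with the already
    composited canvas on ``ref_channel`` (1-based).  Overlaps are blended by
    linear feathering.  A single tile is returned unchanged.
    """
    if len(tiles) == 0:
        raise PreprocessError("stitch_tiles needs at least one tile")
    if len(tiles) == 1:
        return tiles[0]
    if overlap_px < 8:
        raise PreprocessError("overlap_px must be >= 8 for multi-tile stitching")
    n_ch = tiles[0].n_channels
    for t in tiles:
        if t.n_channels != n_ch:
            raise PreprocessError("tiles must share a channel table")
    if origins is None:
        # default: left-to-right strip with nominal overlap
        origins = []
        col = 0
        for t in tiles:
            origins.append((0, col))
            col += t.shape[1] - overlap_px
    ref_axis = ref_channel - 1

    # refine origins sequentially against the first tile's frame
    refined = [tuple(origins[0])]
    canvas_tiles = [(tiles[0], refined[0])]
    for tile, nominal in zip(tiles[1:], origins[1:]):
        prev_tile, prev_origin = canvas_tiles[-1]
        # crop the nominal overlap window from both tiles on ref channel
        dy = nominal[0] - prev_origin[0]
        dx = nominal[1] - prev_origin[1]
        h = min(prev_tile.shape[0] - max(dy, 0), tile.shape[0] + min(dy, 0))
        w = min(prev_tile.shape[1] - max(dx, 0), tile.shape[1] + min(dx, 0))
        if h <= 0 or w <= 0:
            raise StitchRegistrationError("tiles do not overlap at nominal origins")
        ref_win = prev_tile.stack[ref_axis, max(dy, 0) : max(dy, 0) + h, max(dx, 0) : max(dx, 0) + w]
        mov_win = tile.stack[ref_axis, max(-dy, 0) : max(-dy, 0) + h, max(-dx, 0) : max(-dx, 0) + w]
        sy, sx = _register_pair(ref_win, mov_win)
        if abs(sy) > 2 * overlap_px or abs(sx) > 2 * overlap_px:
            raise StitchRegistrationError(
                f"estimated shift ({sy}, {sx}) exceeds 2x nominal overlap "
                f"({overlap_px} px)"
            )
        origin = (nominal[0] + sy, nominal[1] + sx)
        refined.append(origin)
        canvas_tiles.append((tile, origin))

    min_r = min(o[0] for o in refined)
    min_c = min(o[1] for o in refined)
    refined = [(o[0] - min_r, o[1] - min_c) for o in refined]
    max_r = max(o[0] + t.shape[0] for t, o in zip(tiles, refined))
    max_c = max(o[1] + t.shape[1] for t, o in zip(tiles, refined))

    acc = np.zeros((n_ch, max_r, max_c))
    wacc = np.zeros((max_r, max_c))
    mask_acc = np.zeros((max_r, max_c), dtype=np.int64)
    for tile, (orow, ocol) in zip(tiles, refined):
        h, w = tile.shape
        # feather weight: distance to tile edge, capped at the overlap width
        ry = np.minimum(np.arange(h) + 1, h - np.arange(h))
        rx = np.minimum(np.arange(w) + 1, w - np.arange(w))
        wt = np.minimum(
            np.minimum.outer(ry, rx).astype(float), float(overlap_px)
        )
        acc[:, orow : orow + h, ocol : ocol + w] += wt * tile.stack
        wacc[orow : orow + h, ocol : ocol + w] += wt
        sel = tile.mask > 0
        mask_acc[orow : orow + h, ocol : ocol + w][sel] = tile.mask[sel]
    wacc[wacc == 0] = 1.0
    stitched = acc / wacc

    return PatientStack(
        patient_id=tiles[0].patient_id,
        stack=stitched,
        mask=mask_acc,
        channel_table=tiles[0].channel_table,
    )
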