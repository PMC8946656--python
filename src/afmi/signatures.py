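"""Sector spectral signatures and per-patient relative normalization.

Images are tiled into non-overlapping square sectors (16x16 px by default);
the per-channel mean over each sector is its spectral signature (SS).  Each
patient's signatures are then normalized against that patient's own
normal-tissue reference:

    rss = (ss - med) / std        (elementwise per channel)

where ``med`` and ``std`` are the per-channel median and population standard
deviation of the patient's normal-sector signatures.  This removes
per-patient per-channel affine effects, allowing classifiers to be trained
across patients.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .phantom import ID_TO_CLASS, PatientStack

__all__ = [
    "SectorGrid",
    "NormalReference",
    "SignatureError",
    "NormalReferenceError",
    "tile_sectors",
    "extract_signatures",
    "relative_signatures",
    "cohort_relative_signatures",
    "training_rows",
    "signature_matrix",
    "rss_matrix",
    "signature_columns",
    "rss_columns",
]

#: minimum fraction of tissue pixels for a sector to count as tissue
TISSUE_FRACTION_MIN = 0.5
#: majority-share threshold below which a tissue sector is labeled "mixed"
DEFAULT_PURITY_THRESHOLD = 0.8
#: sectors below this tissue fraction are excluded from references/training:
#: their 256-pixel means are diluted by background pixels
FULL_TISSUE_MIN = 0.999


class SignatureError(ValueError):
    """Signature extraction contract violation."""


class NormalReferenceError(SignatureError):
    """Patient lacks enough normal sectors to build a reference."""


@dataclass
class SectorGrid:
    """Sector tiling of one patient's frame."""

    patient_id: str
    sector_px: int
    n_rows: int  # sectors vertically
    n_cols: int  # sectors horizontally
    labels: np.ndarray  # (n_rows, n_cols) strings
    majority: np.ndarray  # (n_rows, n_cols) majority tissue class (or "outside")
    purity: np.ndarray  # (n_rows, n_cols) floats
    tissue_fraction: np.ndarray  # (n_rows, n_cols) fraction of tissue pixels

    @property
    def n_sectors(self) -> int:
        return self.n_rows * self.n_cols

    def bbox(self, row: int, col: int) -> tuple[int, int, int, int]:
        """Half-open pixel rectangle (r0, r1, c0, c1) of a sector."""
        s = self.sector_px
        return row * s, (row + 1) * s, col * s, (col + 1) * s


@dataclass
class NormalReference:
    """Per-patient channelwise median/std of normal-sector signatures."""

    patient_id: str
    med: np.ndarray
    std: np.ndarray
    n_normal_sectors: int
    floored_channels: tuple[int, ...] = ()  # 1-based channels hitting the std floor

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "med": self.med.tolist(),
            "std": self.std.tolist(),
            "n_normal_sectors": self.n_normal_sectors,
            "floored_channels": list(self.floored_channels),
        }


def tile_sectors(
    mask: np.ndarray,
    sector_px: int = 16,
    patient_id: str = "",
    purity_threshold: float = DEFAULT_PURITY_THRESHOLD,
) -> SectorGrid:
    """Tile a label mask into sectors and assign sector labels.

    The grid is anchored at pixel (0, 0); partial edge sectors are dropped.
    A sector with fewer than half tissue pixels is "outside"; otherwise its
    majority class is recorded (with its purity = majority share among
    tissue pixels), and the label is "mixed" when purity falls below
    ``purity_threshold``.
    """
    if sector_px < 2:
        raise SignatureError("sector_px must be >= 2")
    rows, cols = mask.shape
    n_rows, n_cols = rows // sector_px, cols // sector_px
    if n_rows == 0 or n_cols == 0:
        raise SignatureError(
            f"image {rows}x{cols} smaller than one {sector_px}x{sector_px} sector"
        )
    trimmed = mask[: n_rows * sector_px, : n_cols * sector_px]
    blocks = trimmed.reshape(n_rows, sector_px, n_cols, sector_px)
    # per-sector counts of each label id
    counts = np.stack(
        [(blocks == lab).sum(axis=(1, 3)) for lab in (1, 2, 3)]
    )  # (3, n_rows, n_cols)
    tissue = counts.sum(axis=0)
    labels = np.full((n_rows, n_cols), "outside", dtype=object)
    majority = np.full((n_rows, n_cols), "outside", dtype=object)
    purity = np.zeros((n_rows, n_cols))
    is_tissue = tissue >= TISSUE_FRACTION_MIN * sector_px * sector_px
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(tissue > 0, counts / np.maximum(tissue, 1), 0.0)
    best = share.argmax(axis=0)
    best_share = share.max(axis=0)
    for r, c in zip(*np.nonzero(is_tissue)):
        cls = ID_TO_CLASS[int(best[r, c]) + 1]
        majority[r, c] = cls
        purity[r, c] = float(best_share[r, c])
        labels[r, c] = cls if best_share[r, c] >= purity_threshold else "mixed"
    return SectorGrid(
        patient_id=patient_id,
        sector_px=sector_px,
        n_rows=n_rows,
        n_cols=n_cols,
        labels=labels,
        majority=majority,
        purity=purity,
        tissue_fraction=tissue / float(sector_px * sector_px),
    )


def signature_columns(n_channels: int) -> list[str]:
    return [f"ch_{i}" for i in range(1, n_channels + 1)]


def rss_columns(n_channels: int) -> list[str]:
    return [f"rss_{i}" for i in range(1, n_channels + 1)]


def extract_signatures(
    stack: PatientStack,
    sector_px: int = 16,
    grid: Optional[SectorGrid] = None,
    purity_threshold: float = DEFAULT_PURITY_THRESHOLD,
) -> pd.DataFrame:
    """Per-sector mean spectra as a signature table.

    Returns a DataFrame with one row per sector and columns ``patient_id,
    sector_row, sector_col, label, majority_label, purity, ch_1..ch_N``.
    """
    if grid is None:
        grid = tile_sectors(
            stack.mask, sector_px, stack.patient_id, purity_threshold
        )
    if np.isnan(stack.stack).any():
        raise SignatureError("stack contains NaN pixels; preprocessing contract violated")
    s = grid.sector_px
    n_ch = stack.n_channels
    trimmed = stack.stack[:, : grid.n_rows * s, : grid.n_cols * s]
    means = trimmed.reshape(n_ch, grid.n_rows, s, grid.n_cols, s).mean(axis=(2, 4))
    rows = []
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            rows.append(
                {
                    "patient_id": stack.patient_id,
                    "sector_row": r,
                    "sector_col": c,
                    "label": grid.labels[r, c],
                    "majority_label": grid.majority[r, c],
                    "purity": grid.purity[r, c],
                    "tissue_fraction": grid.tissue_fraction[r, c],
                }
            )
    df = pd.DataFrame(rows)
    sig = means.reshape(n_ch, -1).T  # (n_sectors, n_ch)
    for i, col in enumerate(signature_columns(n_ch)):
        df[col] = sig[:, i]
    return df


def training_rows(
    df: pd.DataFrame,
    classes: Optional[tuple[str, ...]] = None,
    purity_threshold: float = DEFAULT_PURITY_THRESHOLD,
) -> pd.DataFrame:
    """Rows suitable for classifier training / group statistics.

    Pure-label sectors of the requested classes with full tissue coverage
    (partial-tissue border sectors carry background-diluted means).
    """
    sel = df["purity"] >= purity_threshold
    if classes is None:
        sel &= df["label"].isin(("normal", "PTG", "OSSN"))
    else:
        sel &= df["label"].isin(classes)
    if "tissue_fraction" in df.columns:
        sel &= df["tissue_fraction"] >= FULL_TISSUE_MIN
    return df[sel]


def signature_matrix(df: pd.DataFrame) -> np.ndarray:
    cols = [c for c in df.columns if c.startswith("ch_")]
    cols.sort(key=lambda c: int(c.split("_")[1]))
    return df[cols].to_numpy(dtype=float)


def rss_matrix(df: pd.DataFrame) -> np.ndarray:
    cols = [c for c in df.columns if c.startswith("rss_")]
    cols.sort(key=lambda c: int(c.split("_")[1]))
    return df[cols].to_numpy(dtype=float)


def relative_signatures(
    df: pd.DataFrame,
    min_normal: int = 10,
    purity_threshold: float = DEFAULT_PURITY_THRESHOLD,
    std_floor_rel: float = 1e-6,
) -> tuple[NormalReference, pd.DataFrame]:
    """Normalize one patient's signatures against their normal reference.

    ``med``/``std`` are computed per channel over the patient's normal
    sectors only (label == "normal", purity >= threshold); rss columns are
    added for every sector.  ``std`` is the population standard deviation
    (ddof=0); channels with std below ``std_floor_rel * median(med)`` are
    floored to that value and flagged.
    """
    patients = df["patient_id"].unique()
    if len(patients) != 1:
        raise SignatureError("relative_signatures expects a single patient's table")
    patient_id = patients[0]
    normal = df[(df["label"] == "normal") & (df["purity"] >= purity_threshold)]
    if "tissue_fraction" in normal.columns:
        normal = normal[normal["tissue_fraction"] >= FULL_TISSUE_MIN]
    if len(normal) < min_normal:
        raise NormalReferenceError(
            f"patient {patient_id}: {len(normal)} normal sectors "
            f"(minimum {min_normal})"
        )
    sig = signature_matrix(df)
    nsig = signature_matrix(normal)
    med = np.median(nsig, axis=0)
    std = nsig.std(axis=0, ddof=0)
    eps = std_floor_rel * max(float(np.median(med)), 1e-30)
    floored = tuple(int(i + 1) for i in np.nonzero(std < eps)[0])
    std = np.maximum(std, eps)
    rss = (sig - med) / std
    out = df.copy()
    for i, col in enumerate(rss_columns(sig.shape[1])):
        out[col] = rss[:, i]
    ref = NormalReference(
        patient_id=patient_id,
        med=med,
        std=std,
        n_normal_sectors=len(normal),
        floored_channels=floored,
    )
    return ref, out


def cohort_relative_signatures(
    df: pd.DataFrame,
    min_normal: int = 10,
    purity_threshold: float = DEFAULT_PURITY_THRESHOLD,
) -> tuple[dict[str, NormalReference], pd.DataFrame, list[str]]:
    """Apply :func:`relative_signatures` per patient over a cohort table.

    Patients lacking a normal reference are excluded; their ids are returned
    in the third element for logging.
    """
    refs: dict[str, NormalReference] = {}
    frames: list[pd.DataFrame] = []
    excluded: list[str] = []
    for pid, sub in df.groupby("patient_id", sort=False):
        try:
            ref, out = relative_signatures(sub, min_normal, purity_threshold)
        except NormalReferenceError:
            excluded.append(pid)
            continue
        refs[pid] = ref
        frames.append(out)
    if not frames:
        raise NormalReferenceError("no patient had enough normal sectors")
    return refs, pd.concat(frames, ignore_index=True), excluded
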