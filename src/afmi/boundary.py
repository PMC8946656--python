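"""Intra-patient boundary delineation and false-color rendering.

A classifier trained on one patient's annotated sectors is applied to that
patient's remaining tissue sectors; the predicted sector grid is rendered as
a red (OSSN) / orange (PTG) / green (normal) overlay on a single grayscale
base channel.  A PCA false-color rendering (top-3 scores -> RGB) is also
provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .classify import ClassifierBundle, PcaModel, train_classifier
from .phantom import CLASS_NAMES, PatientStack
from .signatures import (
    extract_signatures,
    relative_signatures,
    rss_matrix,
    signature_matrix,
)

__all__ = [
    "LEGEND_RGB",
    "BoundaryMap",
    "BoundaryError",
    "select_annotations",
    "detect_boundaries",
    "smooth_map",
    "render_overlay",
    "render_pca_falsecolor",
]

#: exact legend colors
LEGEND_RGB = {"OSSN": (255, 0, 0), "PTG": (255, 165, 0), "normal": (0, 255, 0)}


class BoundaryError(ValueError):
    """Boundary-detection contract violation."""


@dataclass
class BoundaryMap:
    patient_id: str
    grid: np.ndarray  # (n_rows, n_cols) predicted labels incl. "outside"
    base_channel: int = 10
    overlay_rgb: Optional[np.ndarray] = None
    agreement: Optional[float] = None
    training_index: frozenset = field(default_factory=frozenset)  # (row, col) pairs


def select_annotations(
    sig_df: pd.DataFrame,
    frac: float = 0.3,
    min_per_class: int = 20,
    purity_threshold: float = 0.8,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample high-purity training sectors per class from one patient."""
    rng = np.random.default_rng(seed)
    picks = []
    for cls in CLASS_NAMES:
        pool = sig_df[(sig_df["label"] == cls) & (sig_df["purity"] >= purity_threshold)]
        if "tissue_fraction" in pool.columns:
            pool = pool[pool["tissue_fraction"] >= 0.999]
        if len(pool) == 0:
            continue
        n = max(int(round(frac * len(pool))), min(min_per_class, len(pool)))
        n = min(n, len(pool))
        picks.append(pool.iloc[rng.choice(len(pool), size=n, replace=False)])
    if not picks:
        raise BoundaryError("no annotatable sectors found")
    return pd.concat(picks)


def detect_boundaries(
    stack: PatientStack,
    annotations: pd.DataFrame,
    sig_df: Optional[pd.DataFrame] = None,
    sector_px: int = 16,
    min_per_class: int = 20,
    min_normal: int = 10,
    pca_k: int = 5,
    svm_params: Optional[dict] = None,
    base_channel: int = 10,
    eval_band: Optional[int] = None,
) -> BoundaryMap:
    """Train on one patient's annotations, predict all other tissue sectors.

    ``annotations`` are rows of the patient's signature table (high-purity
    sectors of each present class).  rss normalization uses the patient's
    own normal reference computed from the annotated normal sectors.  The
    agreement fraction is computed over non-training tissue sectors against
    the majority ground-truth label; with ``eval_band=d`` it is restricted
    to sectors within Chebyshev distance d of a ground-truth class boundary.
    """
    if sig_df is None:
        sig_df = extract_signatures(stack, sector_px=sector_px)
    pids = set(annotations["patient_id"].unique()) | set(sig_df["patient_id"].unique())
    if len(pids) != 1:
        raise BoundaryError("annotations and stack must come from a single patient")
    classes_present = [
        c for c in CLASS_NAMES if (annotations["label"] == c).any()
    ]
    if len(classes_present) < 2:
        raise BoundaryError("annotations must contain at least two classes")
    for cls in classes_present:
        n = int((annotations["label"] == cls).sum())
        if n < min_per_class:
            raise BoundaryError(
                f"class {cls!r}: {n} annotated sectors (minimum {min_per_class})"
            )

    # normal reference from the annotated normal sectors only
    ref, _ = relative_signatures(annotations, min_normal=min_normal)
    sig_all = signature_matrix(sig_df)
    rss_all = (sig_all - ref.med) / ref.std
    train_key = set(zip(annotations["sector_row"], annotations["sector_col"]))
    key_index = {
        (r, c): i
        for i, (r, c) in enumerate(zip(sig_df["sector_row"], sig_df["sector_col"]))
    }
    train_rows = [key_index[k] for k in sorted(train_key)]

    # linear kernel: annotation sets are small (tens of sectors per class)
    # and an RBF at default C underfits the subtler class pair
    params = {"kernel": "linear"}
    params.update(svm_params or {})
    bundle = train_classifier(
        rss_all[train_rows],
        annotations.sort_values(["sector_row", "sector_col"])["label"].to_numpy(),
        framework="intra_patient",
        patient_ids=annotations.sort_values(["sector_row", "sector_col"])["patient_id"],
        pca_k=pca_k,
        svm_params=params,
    )

    n_rows = int(sig_df["sector_row"].max()) + 1
    n_cols = int(sig_df["sector_col"].max()) + 1
    grid = np.full((n_rows, n_cols), "outside", dtype=object)
    tissue = sig_df[sig_df["majority_label"] != "outside"]
    band_keys = (
        _boundary_band(sig_df, n_rows, n_cols, eval_band)
        if eval_band is not None
        else None
    )
    eval_rows = [
        key_index[(r, c)]
        for r, c in zip(tissue["sector_row"], tissue["sector_col"])
        if (r, c) not in train_key
    ]
    if eval_rows:
        preds = bundle.predict(rss_all[eval_rows])
    matches, total, j = 0, 0, 0
    has_tf = "tissue_fraction" in tissue.columns
    for _, row in tissue.iterrows():
        key = (row["sector_row"], row["sector_col"])
        if key in train_key:
            grid[key] = row["label"] if row["label"] in CLASS_NAMES else row["majority_label"]
            continue
        grid[key] = preds[j]
        # agreement scored on full-tissue held-out sectors only: border
        # sectors carry background-diluted means and ambiguous truth
        in_band = band_keys is None or key in band_keys
        if in_band and (not has_tf or row["tissue_fraction"] >= 0.999):
            matches += int(preds[j] == row["majority_label"])
            total += 1
        j += 1
    agreement = matches / total if total else None
    bmap = BoundaryMap(
        patient_id=stack.patient_id,
        grid=grid,
        base_channel=base_channel,
        agreement=agreement,
        training_index=frozenset(train_key),
    )
    bmap.overlay_rgb = render_overlay(bmap, stack)
    return bmap


def _boundary_band(
    sig_df: pd.DataFrame, n_rows: int, n_cols: int, d: int
) -> set[tuple[int, int]]:
    """Sectors within Chebyshev distance d of a ground-truth class boundary."""
    truth = np.full((n_rows, n_cols), "outside", dtype=object)
    for _, row in sig_df.iterrows():
        truth[row["sector_row"], row["sector_col"]] = row["majority_label"]
    on_boundary = []
    for r in range(n_rows):
        for c in range(n_cols):
            if truth[r, c] == "outside":
                continue
            for rr, cc in ((r + 1, c), (r, c + 1)):
                if (
                    rr < n_rows
                    and cc < n_cols
                    and truth[rr, cc] not in ("outside", truth[r, c])
                ):
                    on_boundary.append((r, c))
                    break
    band = set()
    for r, c in on_boundary:
        for rr in range(max(0, r - d), min(n_rows, r + d + 1)):
            for cc in range(max(0, c - d), min(n_cols, c + d + 1)):
                band.add((rr, cc))
    return band


def smooth_map(bmap: BoundaryMap, radius: int = 1, iterations: int = 1) -> BoundaryMap:
    """Majority filter over the (2r+1)^2 sector neighborhood.

    Ties keep the center label; "outside" sectors never change and do not
    vote.  Never introduces a label absent from the input.
    """
    grid = bmap.grid.copy()
    n_rows, n_cols = grid.shape
    for _ in range(iterations):
        new = grid.copy()
        for r in range(n_rows):
            for c in range(n_cols):
                center = grid[r, c]
                if center == "outside":
                    continue
                votes: dict[str, int] = {}
                for rr in range(max(0, r - radius), min(n_rows, r + radius + 1)):
                    for cc in range(max(0, c - radius), min(n_cols, c + radius + 1)):
                        lab = grid[rr, cc]
                        if lab != "outside":
                            votes[lab] = votes.get(lab, 0) + 1
                best = max(votes.values())
                winners = [lab for lab, v in votes.items() if v == best]
                if len(winners) == 1 and winners[0] != center:
                    new[r, c] = winners[0]
        grid = new
    return BoundaryMap(
        patient_id=bmap.patient_id,
        grid=grid,
        base_channel=bmap.base_channel,
        overlay_rgb=bmap.overlay_rgb,
        agreement=bmap.agreement,
        training_index=bmap.training_index,
    )


def render_overlay(
    bmap: BoundaryMap,
    stack: PatientStack,
    sector_px: int = 16,
    alpha: float = 1.0,
) -> np.ndarray:
    """Sector colors composited over the grayscale base channel (uint8 RGB).

    The base channel (1-based, default 10) is rescaled to its 1st-99th
    percentile.  ``alpha=1`` paints tissue sectors with the exact legend
    colors.
    """
    base = stack.stack[bmap.base_channel - 1].astype(float)
    lo, hi = np.percentile(base, [1, 99])
    gray = np.clip((base - lo) / max(hi - lo, 1e-12), 0, 1)
    rgb = np.stack([gray] * 3, axis=-1)
    n_rows, n_cols = bmap.grid.shape
    for r in range(n_rows):
        for c in range(n_cols):
            lab = bmap.grid[r, c]
            if lab not in LEGEND_RGB:
                continue
            color = np.array(LEGEND_RGB[lab]) / 255.0
            sl = (slice(r * sector_px, (r + 1) * sector_px),
                  slice(c * sector_px, (c + 1) * sector_px))
            rgb[sl] = (1 - alpha) * rgb[sl] + alpha * color
    return np.round(rgb[: n_rows * sector_px, : n_cols * sector_px] * 255).astype(np.uint8)


def render_pca_falsecolor(
    sig_df: pd.DataFrame,
    pca: PcaModel,
    sector_px: int = 16,
    use_rss: bool = False,
) -> np.ndarray:
    """Map per-sector top-3 PCA scores to RGB, upsampled to pixel resolution.

    Each score is linearly rescaled to [0, 1] over the image before 8-bit
    quantization.
    """
    if pca.k < 3:
        raise BoundaryError("false-color rendering needs PCA with k >= 3")
    X = rss_matrix(sig_df) if use_rss else signature_matrix(sig_df)
    scores = pca.transform(X)[:, :3]
    lo = scores.min(axis=0)
    span = scores.max(axis=0) - lo
    span[span == 0] = 1.0
    scaled = (scores - lo) / span
    n_rows = int(sig_df["sector_row"].max()) + 1
    n_cols = int(sig_df["sector_col"].max()) + 1
    img = np.zeros((n_rows, n_cols, 3))
    for (r, c), val in zip(
        zip(sig_df["sector_row"], sig_df["sector_col"]), scaled
    ):
        img[r, c] = val
    up = np.repeat(np.repeat(img, sector_px, axis=0), sector_px, axis=1)
    return np.round(up * 255).astype(np.uint8)
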