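"""Single-cell morphometry from cell-body and nucleus masks.

The effective surface area of a single cell (SA) is the total cell-covered
area of a binarised fluorescence image divided by the number of nuclei (the
cell count); the nucleus-to-cytoplasm ratio (N/C) relates nucleus area to
cell area — per image, the per-cell division cancels and N/C is simply
total nucleus area over total cell area.  Values near 1 mean the footprint
is nucleus-dominated.  Nuclei are counted automatically as 8-connected
components above a minimum size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from imageio.v3 import imread, imwrite
from skimage.filters import threshold_otsu
from skimage.measure import label

__all__ = [
    "MaskPair",
    "MorphometryResult",
    "binarize",
    "count_nuclei",
    "compute_morphometry",
    "read_mask",
    "write_mask",
]

DEFAULT_MIN_NUCLEUS_PX = 30


@dataclass
class MaskPair:
    """Registered cell-body and nucleus binary masks with pixel size (µm/px).

    Nuclei are expected inside cells; pixels violating that are counted and
    reported as a warning, not an error (staining and thresholding disagree
    at edges in real data).
    """

    cell_mask: np.ndarray
    nucleus_mask: np.ndarray
    pixel_size: float  # µm per pixel
    image_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.cell_mask = np.asarray(self.cell_mask).astype(bool)
        self.nucleus_mask = np.asarray(self.nucleus_mask).astype(bool)
        if self.cell_mask.shape != self.nucleus_mask.shape:
            raise ValueError(
                f"mask shapes differ: {self.cell_mask.shape} vs "
                f"{self.nucleus_mask.shape}"
            )
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        outside = int(np.sum(self.nucleus_mask & ~self.cell_mask))
        self.n_outside_px = outside
        if outside:
            warnings.warn(
                f"{outside} nucleus pixels fall outside the cell mask "
                f"(image {self.image_id!r})",
                stacklevel=2,
            )


@dataclass(frozen=True)
class MorphometryResult:
    """Areas in µm²; SA is per cell, N/C dimensionless."""

    total_cell_area: float
    total_nucleus_area: float
    nucleus_count: int
    sa: float  # effective surface area of a single cell
    nc_ratio: float
    image_id: str = ""
    group: str = ""


def binarize(
    image: np.ndarray,
    method: str = "otsu",
    threshold: float | None = None,
    percentile: float | None = None,
) -> np.ndarray:
    """Threshold a single-channel image to a boolean mask.

    ``otsu`` (default) is deterministic on any image with at least two gray
    levels; ``fixed`` uses ``threshold``; ``percentile`` thresholds at the
    given intensity percentile.  Boolean input is returned unchanged.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("binarize expects a single-channel 2-D image")
    if image.dtype == bool:
        return image.copy()
    if method == "otsu":
        if np.all(image == image.flat[0]):
            raise ValueError(
                "constant image: Otsu threshold undefined; use method='fixed'"
            )
        return image > threshold_otsu(image)
    if method == "fixed":
        if threshold is None:
            raise ValueError("method='fixed' requires a threshold")
        return image > threshold
    if method == "percentile":
        if percentile is None:
            raise ValueError("method='percentile' requires a percentile")
        return image > np.percentile(image, percentile)
    raise ValueError(f"unknown binarization method {method!r}")


def count_nuclei(
    nucleus_mask: np.ndarray, min_size_px: int = DEFAULT_MIN_NUCLEUS_PX
) -> int:
    """Number of 8-connected components with area >= ``min_size_px``."""
    mask = np.asarray(nucleus_mask).astype(bool)
    labels = label(mask, connectivity=2)
    if labels.max() == 0:
        return 0
    sizes = np.bincount(labels.ravel())[1:]
    return int(np.sum(sizes >= min_size_px))


def compute_morphometry(
    pair: MaskPair,
    min_size_px: int = DEFAULT_MIN_NUCLEUS_PX,
    per_component: bool = False,
) -> MorphometryResult:
    """SA and N/C for one mask pair.

    Default N/C is the per-image ratio of totals (algebraically identical to
    effective-nucleus-area over effective-cell-area).  ``per_component=True``
    instead averages per-nucleus ratios of matched nucleus/cell components —
    a stricter per-cell reading that requires separable cells.
    """
    px_area = pair.pixel_size**2
    cell_px = int(pair.cell_mask.sum())
    nuc_px = int(pair.nucleus_mask.sum())
    count = count_nuclei(pair.nucleus_mask, min_size_px)
    if count < 1:
        raise ValueError("zero nuclei: SA and N/C are undefined")
    total_cell = cell_px * px_area
    total_nuc = nuc_px * px_area
    sa = total_cell / count
    if per_component:
        nc = _per_component_nc(pair, min_size_px)
    else:
        if cell_px == 0:
            raise ValueError("empty cell mask: N/C undefined")
        nc = total_nuc / total_cell
    return MorphometryResult(
        total_cell_area=total_cell,
        total_nucleus_area=total_nuc,
        nucleus_count=count,
        sa=sa,
        nc_ratio=nc,
        image_id=pair.image_id,
        group=pair.group,
    )


def _per_component_nc(pair: MaskPair, min_size_px: int) -> float:
    """Mean per-cell N/C, matching each nucleus to its enclosing cell blob."""
    cell_labels = label(pair.cell_mask, connectivity=2)
    nuc_labels = label(pair.nucleus_mask, connectivity=2)
    cell_sizes = np.bincount(cell_labels.ravel())
    ratios = []
    for nid in range(1, nuc_labels.max() + 1):
        npx = nuc_labels == nid
        size = int(npx.sum())
        if size < min_size_px:
            continue
        host_ids, counts = np.unique(cell_labels[npx], return_counts=True)
        host = int(host_ids[np.argmax(counts)])
        if host == 0:
            continue  # nucleus outside any cell blob
        ratios.append(size / cell_sizes[host])
    if not ratios:
        raise ValueError("no nucleus could be matched to a cell component")
    return float(np.mean(ratios))


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    """Write a boolean mask as 8-bit PNG/TIFF (0/255)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    imwrite(path, (np.asarray(mask).astype(np.uint8) * 255))
    return path


def read_mask(path: str | Path) -> np.ndarray:
    """Read an 8-bit mask image back to boolean (any nonzero = foreground)."""
    arr = imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 0
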