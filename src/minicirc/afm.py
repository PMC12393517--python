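"""AFM height-image analysis: flattening, particle segmentation, the
centroid/center-of-mass offset delta, and the count-based relative affinity.

A scan is flattened by subtracting a low-order polynomial background, particles
are the 8-connected components above an intensity threshold, and each particle
is summarized by its unweighted mask centroid, its intensity-weighted center of
mass, and the offset delta = |r_centroid - r_COM| in nm.  Particles are sorted
into DNA / protein / DNA-protein complex / aggregate classes by area and mean
intensity windows, and per-scan counts yield the relative affinity
alpha = N_DP / (N_D * N_P).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import measure

from .errors import SegmentationError

LABELS = ("dna", "protein", "complex", "aggregate", "rejected")


@dataclass
class AFMImage:
    """A height image (nm per pixel value) with its physical pixel size."""

    heights: np.ndarray   # (rows, cols), nm
    pixel_size_nm: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise ValueError("height matrix must be 2D")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("non-finite heights")


@dataclass
class BlobRecord:
    """A segmented particle: mask pixels, moments, and offset delta."""

    blob_id: int
    coords: np.ndarray          # (k, 2) int pixel coordinates (row, col)
    intensities: np.ndarray     # (k,) heights at those pixels, nm
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col) exclusive
    pixel_size_nm: float
    label: str = "rejected"

    @property
    def area_px(self) -> int:
        return int(self.coords.shape[0])

    @property
    def area_nm2(self) -> float:
        return self.area_px * self.pixel_size_nm ** 2

    @property
    def mean_intensity(self) -> float:
        return float(np.mean(self.intensities))

    @property
    def centroid_px(self) -> np.ndarray:
        """Unweighted arithmetic mean of the mask pixel coordinates."""
        return self.coords.mean(axis=0)

    @property
    def com_px(self) -> np.ndarray:
        """Intensity-weighted center of mass over the same pixels."""
        total = float(np.sum(self.intensities))
        if total <= 0:
            raise SegmentationError("zero total intensity: center of mass undefined")
        return (self.coords * self.intensities[:, None]).sum(axis=0) / total

    @property
    def delta_nm(self) -> float:
        return offset_delta(self, self.pixel_size_nm)


@dataclass(frozen=True)
class ScanCounts:
    """Particle counts per scan: DNA, protein, DNA-protein complexes."""

    n_dna: int
    n_protein: int
    n_complex: int
    scan_area_nm2: float = 0.0

    def __post_init__(self) -> None:
        if min(self.n_dna, self.n_protein, self.n_complex) < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class AffinityResult:
    """Relative affinity alpha = N_DP / (N_D * N_P)."""

    alpha: float
    counts: ScanCounts

    def fold_over(self, other: "AffinityResult") -> float:
        if other.alpha == 0:
            raise SegmentationError("fold ratio undefined: reference alpha is 0")
        return self.alpha / other.alpha


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _poly_basis(rows: np.ndarray, cols: np.ndarray, order: int) -> np.ndarray:
    terms = [rows ** i * cols ** j
             for i in range(order + 1) for j in range(order + 1 - i)]
    return np.column_stack(terms)


def flatten_image(img: AFMImage, order: int = 2) -> AFMImage:
    """Subtract the least-squares 2D polynomial background of given degree
    (1 = tilt, 2 = tilt + bow)."""
    if order not in (1, 2):
        raise ValueError(f"order must be 1 or 2, got {order}")
    h, w = img.heights.shape
    n_terms = (order + 1) * (order + 2) // 2
    if h * w <= n_terms:
        raise SegmentationError("image smaller than polynomial basis")
    rr, cc = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float),
                         indexing="ij")
    # normalize coordinates for conditioning
    basis = _poly_basis(rr.ravel() / max(h - 1, 1), cc.ravel() / max(w - 1, 1), order)
    coef, *_ = np.linalg.lstsq(basis, img.heights.ravel(), rcond=None)
    background = (basis @ coef).reshape(h, w)
    meta = dict(img.metadata)
    meta["flatten_order"] = order
    return AFMImage(img.heights - background, img.pixel_size_nm, meta)


def segment_blobs(img: AFMImage, threshold_nm: float,
                  connectivity: int = 2) -> list[BlobRecord]:
    """Connected components (8-connectivity by default) of pixels strictly
    above the threshold, each with mask, area, mean intensity, bounding box."""
    if not math.isfinite(threshold_nm):
        raise ValueError("threshold must be finite")
    mask = img.heights > threshold_nm
    labeled = measure.label(mask, connectivity=connectivity)
    blobs: list[BlobRecord] = []
    for region in measure.regionprops(labeled, intensity_image=img.heights):
        coords = np.asarray(region.coords, dtype=int)
        blobs.append(BlobRecord(
            blob_id=int(region.label),
            coords=coords,
            intensities=img.heights[coords[:, 0], coords[:, 1]],
            bbox=tuple(region.bbox),
            pixel_size_nm=img.pixel_size_nm,
        ))
    return blobs


def classify_blobs(
    blobs: list[BlobRecord],
    area_range_nm2: tuple[float, float],
    intensity_range_nm: tuple[float, float],
    scan_area_nm2: float = 0.0,
) -> tuple[list[BlobRecord], ScanCounts]:
    """Assign labels by area / mean-intensity windows and tally scan counts.

    area < min -> protein; area > max -> aggregate (excluded from counts);
    in-range and dim (mean intensity < min) -> dna; in-range and bright
    (within the intensity window) -> complex; brighter than the window ->
    rejected.  Deterministic; returns the labeled blobs and ScanCounts.
    """
    amin, amax = area_range_nm2
    imin, imax = intensity_range_nm
    if amin > amax or imin > imax:
        raise ValueError("ranges must be well-ordered (min <= max)")
    n = {"dna": 0, "protein": 0, "complex": 0}
    for blob in blobs:
        if blob.area_nm2 < amin:
            blob.label = "protein"
        elif blob.area_nm2 > amax:
            blob.label = "aggregate"
        elif blob.mean_intensity < imin:
            blob.label = "dna"
        elif blob.mean_intensity <= imax:
            blob.label = "complex"
        else:
            blob.label = "rejected"
        if blob.label in n:
            n[blob.label] += 1
    counts = ScanCounts(n_dna=n["dna"], n_protein=n["protein"],
                        n_complex=n["complex"], scan_area_nm2=scan_area_nm2)
    return blobs, counts


def offset_delta(blob: BlobRecord, pixel_size_nm: float) -> float:
    """Euclidean distance between the unweighted centroid and the
    intensity-weighted center of mass of the mask, in nm."""
    if blob.area_px == 0:
        raise SegmentationError("empty mask")
    return float(np.linalg.norm(blob.centroid_px - blob.com_px)) * pixel_size_nm


def relative_affinity(counts: ScanCounts) -> AffinityResult:
    """alpha = N_DP / (N_D * N_P); undefined when either factor is zero."""
    if counts.n_dna == 0 or counts.n_protein == 0:
        raise SegmentationError(
            "relative affinity undefined: N_D and N_P must both be > 0")
    return AffinityResult(alpha=counts.n_complex / (counts.n_dna * counts.n_protein),
                          counts=counts)


# ---------------------------------------------------------------------------
# convenience pipeline and I/O
# ---------------------------------------------------------------------------

def analyze_image(
    img: AFMImage,
    threshold_nm: float,
    area_range_nm2: tuple[float, float],
    intensity_range_nm: tuple[float, float],
    flatten_order: int | None = 2,
    connectivity: int = 2,
) -> tuple[list[BlobRecord], ScanCounts, pd.DataFrame]:
    """flatten -> segment -> classify -> per-blob delta table."""
    flat = flatten_image(img, flatten_order) if flatten_order else img
    blobs = segment_blobs(flat, threshold_nm, connectivity)
    scan_area = flat.heights.size * flat.pixel_size_nm ** 2
    blobs, counts = classify_blobs(blobs, area_range_nm2, intensity_range_nm,
                                   scan_area_nm2=scan_area)
    return blobs, counts, blob_table(blobs)


def blob_table(blobs: list[BlobRecord]) -> pd.DataFrame:
    rows = []
    for b in blobs:
        cen = b.centroid_px
        try:
            com = b.com_px
            delta = b.delta_nm
        except SegmentationError:
            com = np.array([np.nan, np.nan])
            delta = np.nan
        rows.append({
            "id": b.blob_id, "label": b.label, "area_px": b.area_px,
            "area_nm2": b.area_nm2, "mean_intensity": b.mean_intensity,
            "centroid_row": cen[0], "centroid_col": cen[1],
            "com_row": com[0], "com_col": com[1], "delta_nm": delta,
        })
    columns = ["id", "label", "area_px", "area_nm2", "mean_intensity",
               "centroid_row", "centroid_col", "com_row", "com_col", "delta_nm"]
    return pd.DataFrame(rows, columns=columns)


def read_afm_image(path: str | Path, pixel_size_nm: float) -> AFMImage:
    """Read a single-channel TIFF or a whitespace-delimited text matrix."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        data = np.asarray(tifffile.imread(path), dtype=float)
    else:
        data = np.loadtxt(path, dtype=float)
    return AFMImage(data, pixel_size_nm, metadata={"source": str(path)})


def write_afm_image(img: AFMImage, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        tifffile.imwrite(path, img.heights.astype(np.float32))
    else:
        np.savetxt(path, img.heights)
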