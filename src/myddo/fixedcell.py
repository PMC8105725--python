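"""Fixed-cell segmentation, quality filtering and translocation scoring.

Nuclei are segmented from the DAPI channel by thresholding plus
marker-controlled watershed (seeds at smoothed DAPI maxima, so touching
nuclei with distinct maxima split); cell bodies are grown from the nuclei
by a second watershed on the cell-marker channel; cytoplasm = cell body
minus nucleus.

Quality rules (each individually toggleable; a cell passes iff all
enabled rules pass):

* equivalent-circle nucleus radius in [5.5, 10] um, cytoplasm radius < 15 um;
* ellipse aspect ratio (major/minor axis, >= 1) <= 1.66 for the nucleus
  and <= 2.25 for the cytoplasm;
* at most 5 nuclear centroids (including the cell's own) within a 16 um
  radius of the nuclear centroid — crowding is assessed against all
  segmented cells, pre-filter;
* the cell-body bounding box must not touch the image border.

Staining readouts: mean nuclear stain intensity (e.g. phospho-p38) and
the nuclear/cytoplasmic mean ratio (e.g. RelA translocation), optionally
normalized to the median of unstimulated cells from the same day.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import watershed


@dataclass
class SegmentedCell:
    cell_id: int
    nucleus_mask: np.ndarray          # boolean
    cytoplasm_mask: np.ndarray        # boolean, excludes the nucleus
    centroid_um: tuple[float, float]  # (x, y) of the nucleus
    nucleus_radius_um: float
    cyto_radius_um: float
    nucleus_ecc: float                # major/minor axis ratio, >= 1
    cyto_ecc: float
    n_neighbors_16um: int = 1         # nuclei within 16 um, self included
    touches_border: bool = False
    pass_filters: bool = True


@dataclass
class CellStain:
    cell_id: int
    nuclear_mean: float
    cyto_mean: float | None
    ratio: float | None
    normalized_value: float | None = None


@dataclass
class FilterRules:
    """Per-rule parameters; set a field to None to disable that rule."""

    nucleus_radius_um: tuple[float, float] | None = (5.5, 10.0)
    cyto_radius_max_um: float | None = 15.0
    nucleus_ecc_max: float | None = 1.66
    cyto_ecc_max: float | None = 2.25
    max_cells_16um: int | None = 5
    exclude_border: bool = True
    crowding_radius_um: float = 16.0


def _aspect_ratio(region) -> float:
    minor = region.axis_minor_length
    if minor <= 0:
        return math.inf
    return region.axis_major_length / minor


def max_project(stack: np.ndarray, plane_indices=None) -> np.ndarray:
    """Maximum projection over selected Z planes (all planes by default)."""
    stack = np.asarray(stack)
    if plane_indices is not None:
        stack = stack[list(plane_indices)]
    return stack.max(axis=0)


def segment(dapi_image: np.ndarray, cell_marker_image: np.ndarray,
            pixel_size_um: float = 0.2833, smoothing_sigma_px: float = 2.0,
            min_seed_distance_um: float = 5.0) -> list[SegmentedCell]:
    """Segment nuclei and cell bodies; returns one record per nucleus.

    Expects illumination-corrected, background-subtracted channels.  An
    empty DAPI channel yields an empty list.
    """
    dapi = np.asarray(dapi_image, dtype=float)
    marker = np.asarray(cell_marker_image, dtype=float)
    smooth = gaussian(dapi, smoothing_sigma_px, preserve_range=True)
    if smooth.max() <= 0 or np.allclose(smooth, smooth.flat[0]):
        return []
    thr = threshold_otsu(smooth)
    nuc_mask = smooth > thr
    if not nuc_mask.any():
        return []

    min_dist_px = max(1, int(round(min_seed_distance_um / pixel_size_um)))
    peaks = peak_local_max(smooth, min_distance=min_dist_px, labels=nuc_mask, exclude_border=False)
    if peaks.size == 0:
        return []
    seeds = np.zeros(dapi.shape, dtype=int)
    for i, (r, c) in enumerate(peaks, start=1):
        seeds[r, c] = i
    nuclei = watershed(-smooth, markers=seeds, mask=nuc_mask)

    marker_smooth = gaussian(marker, smoothing_sigma_px, preserve_range=True)
    if marker_smooth.max() > marker_smooth.min():
        cell_mask = marker_smooth > threshold_otsu(marker_smooth)
    else:
        cell_mask = np.zeros_like(nuc_mask)
    cell_mask = cell_mask | (nuclei > 0)
    cells = watershed(-marker_smooth, markers=nuclei, mask=cell_mask)

    out = []
    h, w = dapi.shape
    for region in regionprops(nuclei):
        lab = region.label
        nmask = nuclei == lab
        cmask = cells == lab
        cyto = cmask & ~nmask
        cy, cx = region.centroid
        r_nuc = math.sqrt(region.area / math.pi) * pixel_size_um
        cyto_area = int(cyto.sum())
        r_cyto = math.sqrt(cyto_area / math.pi) * pixel_size_um if cyto_area else 0.0
        cyto_regions = regionprops(cyto.astype(int))
        cyto_ecc = _aspect_ratio(cyto_regions[0]) if cyto_regions else math.inf
        rr = np.nonzero(cmask.any(axis=1))[0]
        cc = np.nonzero(cmask.any(axis=0))[0]
        touches = bool(rr.size and (rr[0] == 0 or rr[-1] == h - 1 or cc[0] == 0 or cc[-1] == w - 1))
        out.append(SegmentedCell(
            cell_id=lab,
            nucleus_mask=nmask,
            cytoplasm_mask=cyto,
            centroid_um=(cx * pixel_size_um, cy * pixel_size_um),
            nucleus_radius_um=r_nuc,
            cyto_radius_um=r_cyto,
            nucleus_ecc=_aspect_ratio(region),
            cyto_ecc=cyto_ecc,
            touches_border=touches,
        ))
    _count_neighbors(out)
    return out


def _count_neighbors(cells: list[SegmentedCell], radius_um: float = 16.0) -> None:
    if not cells:
        return
    pts = np.array([c.centroid_um for c in cells])
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    counts = (d2 <= radius_um**2).sum(axis=1)  # includes self
    for c, n in zip(cells, counts):
        c.n_neighbors_16um = int(n)


def apply_filters(cells: list[SegmentedCell], rules: FilterRules | None = None) -> list[SegmentedCell]:
    """Set ``pass_filters`` on every cell; returns the same list.

    Crowding is counted against all segmented nuclei (pre-filter),
    including the cell itself.
    """
    rules = rules or FilterRules()
    _count_neighbors(cells, rules.crowding_radius_um)
    for c in cells:
        ok = True
        if rules.nucleus_radius_um is not None:
            lo, hi = rules.nucleus_radius_um
            ok &= lo <= c.nucleus_radius_um <= hi
        if rules.cyto_radius_max_um is not None:
            ok &= c.cyto_radius_um < rules.cyto_radius_max_um
        if rules.nucleus_ecc_max is not None:
            ok &= c.nucleus_ecc <= rules.nucleus_ecc_max
        if rules.cyto_ecc_max is not None:
            ok &= c.cyto_ecc <= rules.cyto_ecc_max
        if rules.max_cells_16um is not None:
            ok &= c.n_neighbors_16um <= rules.max_cells_16um
        if rules.exclude_border:
            ok &= not c.touches_border
        c.pass_filters = bool(ok)
    return cells


def measure_stain(cells: list[SegmentedCell], stain_image: np.ndarray,
                  mode: str = "ratio", passing_only: bool = True) -> list[CellStain]:
    """Per-cell stain statistics from a corrected stain channel.

    ``mode='nuclear'`` reports the mean nuclear intensity only;
    ``mode='ratio'`` additionally reports the nuclear/cytoplasmic mean
    ratio (absent when the cytoplasm mask is empty or its mean is zero).
    """
    if mode not in ("ratio", "nuclear"):
        raise ValueError("mode must be 'ratio' or 'nuclear'")
    stain = np.asarray(stain_image, dtype=float)
    out = []
    for c in cells:
        if passing_only and not c.pass_filters:
            continue
        nuc_mean = float(stain[c.nucleus_mask].mean()) if c.nucleus_mask.any() else 0.0
        cyto_mean = float(stain[c.cytoplasm_mask].mean()) if c.cytoplasm_mask.any() else None
        ratio = None
        if mode == "ratio" and cyto_mean is not None and cyto_mean > 0:
            ratio = nuc_mean / cyto_mean
        out.append(CellStain(c.cell_id, nuc_mean, cyto_mean, ratio))
    return out


def normalize_to_unstimulated(values, unstimulated_values) -> np.ndarray:
    """Divide each value by the median of the unstimulated-cell values."""
    unstim = np.asarray(unstimulated_values, dtype=float)
    if unstim.size < 1:
        raise ValueError("need at least one unstimulated value")
    med = float(np.median(unstim))
    if med <= 0:
        raise ValueError("non-positive unstimulated median")
    return np.asarray(values, dtype=float) / med


def cells_to_dataframe(cells: list[SegmentedCell],
                       stains: list[CellStain] | None = None) -> pd.DataFrame:
    stain_by_id = {s.cell_id: s for s in stains} if stains else {}
    rows = []
    for c in cells:
        s = stain_by_id.get(c.cell_id)
        rows.append({
            "cell_id": c.cell_id, "x_um": c.centroid_um[0], "y_um": c.centroid_um[1],
            "nucleus_radius_um": c.nucleus_radius_um, "cyto_radius_um": c.cyto_radius_um,
            "nucleus_ecc": c.nucleus_ecc, "cyto_ecc": c.cyto_ecc,
            "n_neighbors_16um": c.n_neighbors_16um, "touches_border": c.touches_border,
            "pass_filters": c.pass_filters,
            "nuclear_mean": s.nuclear_mean if s else None,
            "cyto_mean": s.cyto_mean if s else None,
            "ratio": s.ratio if s else None,
            "normalized_value": s.normalized_value if s else None,
        })
    return pd.DataFrame(rows)
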