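"""Channel preprocessing, counterstain masking and FISH spot detection.

A countable spot in either probe channel is an object of the *preprocessed*
image (Gaussian smoothing -> white top-hat -> Laplacian-of-Gaussian edge
enhancement clipped at zero) that

* survives binarisation at ``intensity_frac`` of the channel's reference
  maximum (the 99.9th percentile of the preprocessed image, a robust
  maximum),
* has a thresholded area of at least ``min_area_um2``, and
* after merging of objects whose centroids lie closer than
  ``min_distance_um``, is reported once, ordered row-major by centroid.

In specimens amplified through homogeneously staining regions (HSR) the
HER2 signals form clusters in which individual spots cannot be resolved;
:func:`count_hsr_equivalents` converts such clusters into spot-equivalents
from their signal *area* relative to a reference single-spot area.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.morphology import disk, remove_small_objects, white_tophat

from .core import CEP17_SPOT_PARAMS, HER2_SPOT_PARAMS, InvalidInputError, SpotParams

__all__ = [
    "Spot",
    "build_counterstain_mask",
    "preprocess_channel",
    "threshold_objects",
    "detect_spots",
    "estimate_reference_spot_area",
    "count_hsr_equivalents",
    "params_for_channel",
]

# 8-connectivity throughout: diagonal pixels belong to the same object.
_STRUCT8 = np.ones((3, 3), bool)

#: minimum retained counterstain object, um^2 (debris smaller than any nucleus)
MIN_MASK_OBJECT_UM2 = 2.0

#: default preprocessing scales, um. The smoothing/LoG sigma is below the
#: diffraction-scale spot radius; the top-hat element passes objects up to
#: ~1 um diameter and removes nuclear-scale background.
SMOOTHING_SIGMA_UM = 0.1
TOPHAT_RADIUS_UM = 0.5
LOG_SIGMA_UM = 0.1


@dataclass(frozen=True)
class Spot:
    """A detected fluorescent signal.

    ``equivalents`` is 1 for a resolved single spot and >= 2 for an HSR
    cluster converted by area (see :func:`count_hsr_equivalents`).
    """

    channel: str
    centroid: tuple[float, float]
    area_um2: float
    peak_frac: float
    equivalents: int = 1


def params_for_channel(channel: str) -> SpotParams:
    """Built-in spot definition for ``"her2"`` (orange) or ``"cep17"`` (green)."""
    try:
        return {"her2": HER2_SPOT_PARAMS, "cep17": CEP17_SPOT_PARAMS}[channel]
    except KeyError:
        raise InvalidInputError(f"unknown channel {channel!r}") from None


def build_counterstain_mask(dapi: np.ndarray, um_per_px: float) -> np.ndarray:
    """Binary mask of DAPI-positive (nuclear) pixels.

    Otsu-thresholds the counterstain, fills holes and drops objects smaller
    than 2 um^2.  A constant image yields an all-false mask.
    """
    dapi = np.asarray(dapi)
    if dapi.ndim != 2 or dapi.size == 0:
        raise InvalidInputError("dapi must be a non-empty 2-D raster")
    if dapi.max() == dapi.min():
        return np.zeros(dapi.shape, bool)
    thr = threshold_otsu(dapi)
    mask = dapi > thr
    mask = ndi.binary_fill_holes(mask)
    min_px = max(1, int(round(MIN_MASK_OBJECT_UM2 / um_per_px**2)))
    mask = remove_small_objects(mask, max_size=min_px - 1, connectivity=2)
    return mask


def preprocess_channel(
    raster: np.ndarray,
    um_per_px: float,
    smoothing_sigma_um: float = SMOOTHING_SIGMA_UM,
    tophat_radius_um: float = TOPHAT_RADIUS_UM,
    log_sigma_um: float = LOG_SIGMA_UM,
) -> np.ndarray:
    """Spot-enhancing filter chain for a probe channel.

    Gaussian smoothing suppresses shot noise; the white top-hat (disc
    structuring element) removes any structure larger than the element, i.e.
    nuclear counterstain bleed-through and smooth background gradients; the
    negated Laplacian-of-Gaussian, clipped at zero, sharpens blob-like
    signals.  The output is a nonnegative float raster; constant inputs map
    to (near-)zero.
    """
    x = np.asarray(raster, dtype=np.float64)
    if x.ndim != 2 or x.size == 0:
        raise InvalidInputError("raster must be a non-empty 2-D image")
    sigma = smoothing_sigma_um / um_per_px
    if sigma > 0:
        x = ndi.gaussian_filter(x, sigma=sigma, mode="nearest")
    radius = max(1, int(round(tophat_radius_um / um_per_px)))
    footprint = disk(radius, decomposition="sequence")
    x = white_tophat(x, footprint=footprint)
    log_sigma = max(log_sigma_um / um_per_px, 0.5)
    x = -ndi.gaussian_laplace(x, sigma=log_sigma, mode="nearest")
    return np.clip(x, 0.0, None)


def _reference_max(enhanced: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Robust channel maximum: the 99.9th-percentile preprocessed intensity.

    When a counterstain mask is given the percentile is taken over nuclear
    pixels only: probe signal lives inside nuclei, and against a whole-field
    percentile a sparsely populated field would put the reference into the
    background noise."""
    if mask is not None and mask.any():
        return float(np.percentile(enhanced[mask], 99.9))
    return float(np.percentile(enhanced, 99.9))


def threshold_objects(
    enhanced: np.ndarray,
    params: SpotParams,
    um_per_px: float,
    mask: np.ndarray | None = None,
):
    """Candidate objects before the area and distance gates.

    Binarises the preprocessed raster at ``intensity_frac`` times the
    reference maximum and labels 8-connected components.  Returns a list of
    ``(centroid_rc, area_um2, peak_frac)`` triples; components whose centroid
    falls outside ``mask`` (when given) are dropped — signals outside nuclear
    material are artifacts.
    """
    ref = _reference_max(enhanced, mask)
    if ref <= 0:
        return []
    binary = enhanced >= params.intensity_frac * ref
    labels = sk_label(binary, connectivity=2)
    out = []
    for rp in regionprops(labels, intensity_image=enhanced):
        r, c = rp.centroid_weighted
        if mask is not None and not mask[int(round(r)), int(round(c))]:
            continue
        out.append(((r, c), rp.area * um_per_px**2, rp.intensity_max / ref))
    return out


def _merge_close(objects, min_distance_px: float):
    """Single-linkage merge of objects with centroid distance < the gate.

    Merging (rather than discarding the weaker object) preserves total
    signal and matches how a human scores an unresolved doublet as one spot.
    Uses union-find over all close pairs of *original* centroids.
    """
    n = len(objects)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    coords = np.array([o[0] for o in objects], dtype=float)
    if n > 1:
        from scipy.spatial import cKDTree

        tree = cKDTree(coords)
        for i, j in tree.query_pairs(r=min_distance_px * (1 - 1e-12)):
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    merged = []
    for members in groups.values():
        areas = np.array([objects[i][1] for i in members])
        cents = coords[members]
        w = areas / areas.sum()
        centroid = tuple((cents * w[:, None]).sum(axis=0))
        merged.append((centroid, float(areas.sum()), max(objects[i][2] for i in members)))
    return merged


def detect_spots(
    raster: np.ndarray,
    params: SpotParams,
    um_per_px: float,
    channel: str,
    mask: np.ndarray | None = None,
    enhanced: np.ndarray | None = None,
) -> list[Spot]:
    """Detect fluorescent spots in one probe channel.

    Parameters
    ----------
    raster
        Raw 8-bit channel image.  Ignored when ``enhanced`` is supplied.
    params
        Channel spot definition (area, merge distance, relative intensity).
    um_per_px
        Spatial calibration.
    channel
        Label stored on each :class:`Spot` (``"her2"`` or ``"cep17"``).
    mask
        Optional counterstain mask; candidate objects whose centroid falls
        outside it are discarded.
    enhanced
        Optional pre-computed output of :func:`preprocess_channel`, to avoid
        re-filtering when several detectors share one preprocessing pass.
    """
    if enhanced is None:
        enhanced = preprocess_channel(np.asarray(raster), um_per_px)
    candidates = threshold_objects(enhanced, params, um_per_px, mask=mask)
    candidates = [c for c in candidates if c[1] >= params.min_area_um2 * (1 - 1e-9)]
    if not candidates:
        return []
    merged = _merge_close(candidates, params.min_distance_um / um_per_px)
    merged.sort(key=lambda o: (o[0][0], o[0][1]))
    return [
        Spot(channel=channel, centroid=cen, area_um2=area, peak_frac=min(peak, 1.0))
        for cen, area, peak in merged
    ]


def consolidate_signal_objects(
    raster: np.ndarray,
    um_per_px: float,
    spots: list[Spot],
    intensity_frac: float,
    smoothing_sigma_um: float = SMOOTHING_SIGMA_UM,
    hsr_factor: float = 4.0,
    mask: np.ndarray | None = None,
) -> list[Spot]:
    """Measure signal area on the smoothed channel and unify HSR clusters.

    The spot-enhancing chain (top-hat, LoG) deliberately suppresses
    structure wider than a single probe signal, so an unresolvable HSR
    cluster fragments into several small objects whose combined thresholded
    area cannot carry the cluster's extent.  Signal area is therefore
    measured on the Gaussian-smoothed channel only, thresholded at
    ``intensity_frac`` of its robust maximum, and every spot's area is
    re-expressed on that footing:

    * spots alone in their smoothed component get the component's area;
    * spots sharing a component *larger* than ``hsr_factor`` times the
      typical single-signal area (the median over single-occupancy
      components) are one unresolvable object and are unified into a single
      spot carrying the full component area;
    * spots sharing a smaller component — resolvable neighbours whose
      smoothed supports happen to touch — stay separate, dividing the
      component's area in proportion to their thresholded areas;
    * spots below the smoothed threshold are kept as-is.
    """
    x = np.asarray(raster, dtype=np.float64)
    if smoothing_sigma_um > 0:
        x = ndi.gaussian_filter(x, sigma=smoothing_sigma_um / um_per_px, mode="nearest")
    ref = _reference_max(x, mask)
    if ref <= 0 or not spots:
        return list(spots)
    labels = sk_label(x >= intensity_frac * ref, connectivity=2)
    areas = np.bincount(labels.ravel())
    by_component: dict[int, list[Spot]] = {}
    out: list[Spot] = []
    for s in spots:
        r = min(max(int(round(s.centroid[0])), 0), labels.shape[0] - 1)
        c = min(max(int(round(s.centroid[1])), 0), labels.shape[1] - 1)
        lbl = int(labels[r, c])
        if lbl == 0:
            out.append(s)
        else:
            by_component.setdefault(lbl, []).append(s)
    u2 = um_per_px**2
    singles = [float(areas[lbl]) * u2 for lbl, m in by_component.items() if len(m) == 1]
    typical = float(np.median(singles)) if singles else 0.0
    for lbl, members in by_component.items():
        area = float(areas[lbl]) * u2
        if len(members) == 1:
            out.append(replace(members[0], area_um2=area))
        elif typical > 0 and area > hsr_factor * typical:
            w = np.array([m.area_um2 for m in members])
            w = w / w.sum()
            centroid = tuple(
                (np.array([m.centroid for m in members]) * w[:, None]).sum(axis=0)
            )
            out.append(
                replace(
                    members[0],
                    centroid=centroid,
                    area_um2=area,
                    peak_frac=max(m.peak_frac for m in members),
                )
            )
        else:
            total = sum(m.area_um2 for m in members)
            for m in members:
                out.append(replace(m, area_um2=area * m.area_um2 / total))
    out.sort(key=lambda s: (s.centroid[0], s.centroid[1]))
    return out


def estimate_reference_spot_area(
    spots: list[Spot], hsr_factor: float = 4.0, fallback_um2: float = 0.15
) -> float:
    """Reference single-spot area for HSR area-mode counting.

    The median area of isolated (non-cluster) spots of the case; a spot is
    treated as isolated when its area does not exceed ``hsr_factor`` times
    the median over all spots.  Falls back to ``fallback_um2`` when fewer
    than five isolated spots are available.
    """
    areas = np.array([s.area_um2 for s in spots], dtype=float)
    if areas.size == 0:
        return fallback_um2
    isolated = areas[areas <= hsr_factor * np.median(areas)]
    if isolated.size < 5:
        return fallback_um2
    return float(np.median(isolated))


def count_hsr_equivalents(
    spots_raw: list[Spot],
    ref_area_um2: float | None = None,
    hsr_factor: float = 4.0,
) -> tuple[list[Spot], bool]:
    """Convert HSR clusters to spot-equivalents by signal area.

    Objects with area <= ``hsr_factor * ref_area_um2`` pass through with
    ``equivalents = 1``; larger objects are taken to be unresolvable HSR
    clusters and get ``equivalents = round(area / ref_area_um2)`` (at least
    2).  Returns the converted spot list and a flag that is True when any
    cluster was converted (surfaced as the ``hsr_mode_used`` QC flag).
    """
    if hsr_factor <= 1:
        raise InvalidInputError("hsr_factor must exceed 1")
    if ref_area_um2 is None:
        ref_area_um2 = estimate_reference_spot_area(spots_raw, hsr_factor)
    if ref_area_um2 <= 0:
        raise InvalidInputError("ref_area_um2 must be positive")
    out = []
    converted = False
    for s in spots_raw:
        if s.area_um2 <= hsr_factor * ref_area_um2:
            out.append(replace(s, equivalents=1))
        else:
            converted = True
            out.append(replace(s, equivalents=max(2, int(round(s.area_um2 / ref_area_um2)))))
    return out, converted
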