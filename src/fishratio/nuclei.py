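"""Nuclei-sampling classifier.

Individual nuclei are segmented from the DAPI counterstain (connected
components of the counterstain mask, split by a distance-transform watershed
where concavity indicates touching nuclei).  A nucleus is *accepted* for
analysis when its area lies between 12 and 400 um^2, its circularity
(4*pi*A/P^2) is at least 0.60 and it carries at least one HER2 and one CEP17
signal; all other segmented nuclei remain *pre-segmented* and do not enter
the ratio.  Acceptance mirrors the manual-scoring convention that only
nuclei with at least one signal of each probe are enumerable.

Automated segmentation can be corrected by a human through five edit
operations — add, select, delete, split, merge — each of which triggers an
automatic update of the case ratio.  Edits are validated before any state is
touched and recorded in an ordered journal so a session is replayable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import line as draw_line
from skimage.draw import polygon as draw_polygon
from skimage.feature import peak_local_max
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .core import (
    CaseResult,
    InvalidInputError,
    NucleusParams,
    Thresholds,
    make_case_result,
)
from .spots import Spot

__all__ = [
    "ACCEPTED",
    "PRESEGMENTED",
    "DELETED",
    "USER_ADDED",
    "Nucleus",
    "EditOp",
    "EditError",
    "FieldState",
    "CaseState",
    "segment_nuclei",
    "gate_nuclei",
    "apply_edit",
    "nuclei_case_result",
]

ACCEPTED = "accepted"
PRESEGMENTED = "presegmented"
DELETED = "deleted"
USER_ADDED = "user_added"

#: watershed splitting triggers: concave component or oversized vs the
#: expected single-nucleus area
SPLIT_SOLIDITY = 0.9
SPLIT_AREA_FACTOR = 1.5
#: minimum separation of watershed seeds, um
SEED_SEPARATION_UM = 2.0


class EditError(InvalidInputError):
    """An edit operation is invalid against the current case state."""


@dataclass
class Nucleus:
    """A segmented DAPI object; its pixel region is ``labels == label`` in
    the label raster of field ``field_index``."""

    id: int
    field_index: int
    label: int
    area_um2: float
    roundness: float
    centroid: tuple[float, float]
    status: str = PRESEGMENTED
    her2_count: int = 0
    cep17_count: int = 0
    touches_border: bool = False

    @property
    def counted(self) -> bool:
        return self.status in (ACCEPTED, USER_ADDED)


@dataclass(frozen=True)
class EditOp:
    """One human-correction operation.

    ``kind`` is one of ``add`` (polygon outlines a new nucleus), ``select``
    (a pre-segmented nucleus enters the analysis), ``delete``, ``split``
    (polyline partitions an existing region) or ``merge`` (regions of the
    target nuclei are united).
    """

    kind: str
    targets: tuple[int, ...] = ()
    polygon: tuple[tuple[float, float], ...] = ()
    polyline: tuple[tuple[float, float], ...] = ()
    field_index: int = 0


@dataclass
class FieldState:
    """Per-field label raster plus the spots detected in that field."""

    labels: np.ndarray
    spots: list[Spot]
    um_per_px: float


def _measure(region_mask: np.ndarray, um_per_px: float):
    rp = regionprops(region_mask.astype(np.uint8))[0]
    area_um2 = rp.area * um_per_px**2
    perim = rp.perimeter
    roundness = 1.0 if perim == 0 else min(1.0, 4 * math.pi * rp.area / perim**2)
    return area_um2, roundness, rp.centroid


def _touches_border(region_mask: np.ndarray) -> bool:
    return bool(
        region_mask[0, :].any()
        or region_mask[-1, :].any()
        or region_mask[:, 0].any()
        or region_mask[:, -1].any()
    )


def segment_nuclei(
    dapi: np.ndarray,
    mask: np.ndarray,
    um_per_px: float,
    expected_area_um2: float | None = None,
) -> tuple[np.ndarray, list[Nucleus]]:
    """Segment individual nuclei from the counterstain mask.

    Connected components are split by a watershed on the distance transform
    when their solidity falls below 0.9 or their area exceeds 1.5 times the
    expected single-nucleus area (default: the median component area), with
    seeds at distance-transform maxima at least 2 um apart.  Regions touching
    the image border are marked pre-segmented and never accepted
    automatically.

    Returns the field label raster (0 = background) and the nucleus list;
    statuses are provisional (everything not border-touching is ``accepted``)
    until :func:`gate_nuclei` applies the area/roundness/signal gates.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        return np.zeros(mask.shape, np.int32), []
    comps = sk_label(mask, connectivity=2)
    px_area = um_per_px**2
    if expected_area_um2 is None:
        areas = np.bincount(comps.ravel())[1:]
        expected_area_um2 = float(np.median(areas[areas > 0])) * px_area
    seed_sep_px = max(1, int(round(SEED_SEPARATION_UM / um_per_px)))

    labels = np.zeros(mask.shape, np.int32)
    next_label = 1
    for rp in regionprops(comps):
        r0, c0, r1, c1 = rp.bbox
        region = comps[r0:r1, c0:c1] == rp.label
        pieces = [region]
        oversized = rp.area * px_area > SPLIT_AREA_FACTOR * expected_area_um2
        if rp.solidity < SPLIT_SOLIDITY or oversized:
            dist = ndi.distance_transform_edt(region)
            peaks = peak_local_max(
                dist, min_distance=seed_sep_px, labels=region.astype(np.uint8)
            )
            if len(peaks) >= 2:
                markers = np.zeros(region.shape, np.int32)
                for i, (pr, pc) in enumerate(peaks, start=1):
                    markers[pr, pc] = i
                ws = watershed(-dist, markers, mask=region)
                pieces = [ws == k for k in range(1, len(peaks) + 1) if (ws == k).any()]
        for piece in pieces:
            labels[r0:r1, c0:c1][piece] = next_label
            next_label += 1

    nuclei = []
    for rp in regionprops(labels):
        region_mask = labels == rp.label
        area_um2, roundness, centroid = _measure(region_mask, um_per_px)
        border = _touches_border(region_mask)
        nuclei.append(
            Nucleus(
                id=rp.label,
                field_index=0,
                label=rp.label,
                area_um2=area_um2,
                roundness=roundness,
                centroid=centroid,
                status=PRESEGMENTED if border else ACCEPTED,
                touches_border=border,
            )
        )
    return labels, nuclei


def _count_spots(labels: np.ndarray, spots: list[Spot]) -> dict[int, list[int]]:
    """Spot-equivalent totals per region label, by centroid membership."""
    h, w = labels.shape
    counts: dict[int, list[int]] = {}
    for s in spots:
        r = min(max(int(round(s.centroid[0])), 0), h - 1)
        c = min(max(int(round(s.centroid[1])), 0), w - 1)
        lbl = int(labels[r, c])
        if lbl == 0:
            continue
        entry = counts.setdefault(lbl, [0, 0])
        entry[0 if s.channel == "her2" else 1] += s.equivalents
    return counts


def gate_nuclei(
    nuclei: list[Nucleus],
    spots: list[Spot],
    params: NucleusParams,
    labels: np.ndarray,
) -> list[Nucleus]:
    """Attach spot counts and apply the size/shape/signal-quality gates.

    A nucleus is accepted iff its area lies in
    ``[min_area_um2, max_area_um2]``, its roundness is at least
    ``min_roundness``, and it carries at least one signal of each probe.
    User-added nuclei bypass the gates (the interactive phase overrides the
    automatic selection); deleted nuclei stay deleted.
    """
    counts = _count_spots(labels, spots)
    for n in nuclei:
        n.her2_count, n.cep17_count = counts.get(n.label, [0, 0])
        if n.status in (USER_ADDED, DELETED):
            continue
        ok = (
            not n.touches_border
            and params.min_area_um2 <= n.area_um2 <= params.max_area_um2
            and n.roundness >= params.min_roundness
            and n.her2_count >= 1
            and n.cep17_count >= 1
        )
        n.status = ACCEPTED if ok else PRESEGMENTED
    return nuclei


@dataclass
class CaseState:
    """All nuclei and spots of a case, with the result kept current.

    Any successful edit recomputes ``result`` so the ratio always reflects
    the accepted-nuclei totals.
    """

    fields: list[FieldState]
    params: NucleusParams
    thresholds: Thresholds
    nuclei: dict[int, Nucleus] = dc_field(default_factory=dict)
    journal: list[EditOp] = dc_field(default_factory=list)
    qc: list[str] = dc_field(default_factory=list)
    result: CaseResult | None = None
    _next_id: int = 1

    @classmethod
    def from_fields(
        cls,
        per_field: list[tuple[np.ndarray, list[Nucleus], list[Spot]]],
        params: NucleusParams,
        thresholds: Thresholds,
        um_per_px: float,
        qc: list[str] | None = None,
    ) -> "CaseState":
        """Assemble a case from per-field (labels, gated nuclei, spots)."""
        state = cls(fields=[], params=params, thresholds=thresholds, qc=list(qc or []))
        for fi, (labels, nuclei, spots) in enumerate(per_field):
            state.fields.append(FieldState(labels=labels, spots=spots, um_per_px=um_per_px))
            for n in nuclei:
                n.id = state._next_id
                n.field_index = fi
                state.nuclei[n.id] = n
                state._next_id += 1
        state.refresh()
        return state

    def refresh(self) -> CaseResult:
        self.result = nuclei_case_result(self, self.params, self.thresholds)
        return self.result

    def accepted_nuclei(self) -> list[Nucleus]:
        return [n for n in self.nuclei.values() if n.counted]

    # -- internal helpers -------------------------------------------------

    def _require(self, nid: int) -> Nucleus:
        try:
            return self.nuclei[nid]
        except KeyError:
            raise EditError(f"unknown nucleus id {nid}") from None

    def _new_nucleus_from_region(
        self, field_index: int, region_mask: np.ndarray, status: str
    ) -> Nucleus:
        fs = self.fields[field_index]
        lbl = int(fs.labels.max()) + 1
        fs.labels[region_mask] = lbl
        area_um2, roundness, centroid = _measure(region_mask, fs.um_per_px)
        n = Nucleus(
            id=self._next_id,
            field_index=field_index,
            label=lbl,
            area_um2=area_um2,
            roundness=roundness,
            centroid=centroid,
            status=status,
            touches_border=_touches_border(region_mask),
        )
        self._next_id += 1
        self.nuclei[n.id] = n
        self._regate(n)
        return n

    def _regate(self, n: Nucleus) -> None:
        fs = self.fields[n.field_index]
        region = fs.labels == n.label
        counts = _count_spots(np.where(region, n.label, 0), fs.spots)
        n.her2_count, n.cep17_count = counts.get(n.label, [0, 0])
        if n.status in (USER_ADDED, DELETED):
            return
        p = self.params
        ok = (
            not n.touches_border
            and p.min_area_um2 <= n.area_um2 <= p.max_area_um2
            and n.roundness >= p.min_roundness
            and n.her2_count >= 1
            and n.cep17_count >= 1
        )
        n.status = ACCEPTED if ok else PRESEGMENTED


def nuclei_case_result(
    state: CaseState, params: NucleusParams, thresholds: Thresholds
) -> CaseResult:
    """Pool accepted nuclei into a CaseResult; fewer than ``min_nuclei``
    accepted nuclei rejects the case."""
    acc = state.accepted_nuclei()
    total_h = sum(n.her2_count for n in acc)
    total_c = sum(n.cep17_count for n in acc)
    return make_case_result(
        total_h, total_c, len(acc), "nuclei", thresholds, params.min_nuclei, qc=state.qc
    )


# -- edit operations ------------------------------------------------------


def _validate_polygon(op: EditOp, shape: tuple[int, int]) -> None:
    if len(op.polygon) < 3:
        raise EditError("add requires a polygon with at least 3 vertices")
    for r, c in op.polygon:
        if not (0 <= r < shape[0] and 0 <= c < shape[1]):
            raise EditError("polygon vertex outside image bounds")


def _apply_add(state: CaseState, op: EditOp) -> None:
    if not (0 <= op.field_index < len(state.fields)):
        raise EditError(f"field index {op.field_index} out of range")
    fs = state.fields[op.field_index]
    _validate_polygon(op, fs.labels.shape)
    rr, cc = draw_polygon(
        [p[0] for p in op.polygon], [p[1] for p in op.polygon], shape=fs.labels.shape
    )
    region = np.zeros(fs.labels.shape, bool)
    region[rr, cc] = True
    region &= fs.labels == 0  # keep regions of distinct nuclei disjoint
    if not region.any():
        raise EditError("polygon encloses no free pixels")
    state._new_nucleus_from_region(op.field_index, region, USER_ADDED)


def _apply_select(state: CaseState, op: EditOp) -> None:
    n = state._require(op.targets[0])
    if n.status == PRESEGMENTED or n.status == DELETED:
        n.status = ACCEPTED
    # select on an already accepted nucleus is a no-op


def _apply_delete(state: CaseState, op: EditOp) -> None:
    n = state._require(op.targets[0])
    n.status = DELETED  # delete on a deleted nucleus is a no-op


def _apply_split(state: CaseState, op: EditOp) -> None:
    if len(op.polyline) < 2:
        raise EditError("split requires a polyline with at least 2 vertices")
    n = state._require(op.targets[0])
    if n.status == DELETED:
        raise EditError("cannot split a deleted nucleus")
    fs = state.fields[n.field_index]
    region = fs.labels == n.label
    cut = np.zeros(region.shape, bool)
    pts = [(int(round(r)), int(round(c))) for r, c in op.polyline]
    for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
        rr, cc = draw_line(r0, c0, r1, c1)
        keep = (rr >= 0) & (rr < region.shape[0]) & (cc >= 0) & (cc < region.shape[1])
        cut[rr[keep], cc[keep]] = True
    remainder = region & ~cut
    # 4-connectivity so a 1-px 8-connected polyline separates the halves
    comps = sk_label(remainder, connectivity=1)
    k = comps.max()
    if k < 2:
        raise EditError("split polyline does not partition the region")
    # line pixels inside the region are reassigned to the nearest part so
    # pixel area and any spots on the cut are conserved
    missing = region & (comps == 0)
    if missing.any():
        _, (ir, ic) = ndi.distance_transform_edt(comps == 0, return_indices=True)
        comps[missing] = comps[ir[missing], ic[missing]]
    fs.labels[region] = 0
    del state.nuclei[n.id]
    for part in range(1, k + 1):
        part_mask = comps == part
        if part_mask.any():
            state._new_nucleus_from_region(n.field_index, part_mask, PRESEGMENTED)


def _apply_merge(state: CaseState, op: EditOp) -> None:
    if len(op.targets) < 2:
        raise EditError("merge requires at least two nucleus ids")
    parts = [state._require(t) for t in op.targets]
    fi = parts[0].field_index
    if any(p.field_index != fi for p in parts):
        raise EditError("cannot merge nuclei from different fields")
    fs = state.fields[fi]
    region = np.isin(fs.labels, [p.label for p in parts])
    fs.labels[region] = 0
    for p in parts:
        del state.nuclei[p.id]
    state._new_nucleus_from_region(fi, region, PRESEGMENTED)


_EDIT_HANDLERS = {
    "add": _apply_add,
    "select": _apply_select,
    "delete": _apply_delete,
    "split": _apply_split,
    "merge": _apply_merge,
}


def apply_edit(state: CaseState, op: EditOp) -> CaseState:
    """Apply one human-correction operation and update the case result.

    Invalid operations raise :class:`EditError` and leave the state
    unchanged; validation happens before any mutation.  Successful edits are
    appended to the journal and the result is recomputed automatically.
    """
    handler = _EDIT_HANDLERS.get(op.kind)
    if handler is None:
        raise EditError(f"unknown edit kind {op.kind!r}")
    if op.kind in ("select", "delete", "split") and len(op.targets) != 1:
        raise EditError(f"{op.kind} takes exactly one target id")
    handler(state, op)
    state.journal.append(op)
    state.refresh()
    return state
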