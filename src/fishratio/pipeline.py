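"""End-to-end analysis of a case: fields in, CaseResult out.

This is the programmatic engine behind the ``fishratio analyze`` command.
For every field it builds the counterstain mask, preprocesses and detects
spots in both probe channels (inside nuclear material only), converts HSR
clusters to spot-equivalents by area, and then runs either the
tile-sampling or the nuclei-sampling classifier.  Tile mode pools accepted
tiles over all fields of the case; nuclei mode pools accepted nuclei, and
can replay a journal of human-correction edits before scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace

import numpy as np

from .config import Config
from .core import CalibratedImage, CaseResult
from .nuclei import CaseState, EditOp, Nucleus, apply_edit, gate_nuclei, segment_nuclei
from .spots import (
    Spot,
    build_counterstain_mask,
    count_hsr_equivalents,
    detect_spots,
    estimate_reference_spot_area,
    consolidate_signal_objects,
    preprocess_channel,
)
from .tiles import Tile, fill_tiles, place_tiles, reject_tiles, tile_case_result

__all__ = ["FieldAnalysis", "CaseAnalysis", "analyze_fields", "analyze_case", "detect_field_spots"]


@dataclass
class FieldAnalysis:
    """Per-field intermediates kept for reporting and editing."""

    mask: np.ndarray
    her2_spots: list[Spot]
    cep17_spots: list[Spot]
    tiles: list[Tile] = dc_field(default_factory=list)
    labels: np.ndarray | None = None
    nuclei: list[Nucleus] = dc_field(default_factory=list)


@dataclass
class CaseAnalysis:
    """Outcome of one case analysis."""

    result: CaseResult
    fields: list[FieldAnalysis]
    mode: str
    state: CaseState | None = None  # nuclei mode only
    config: Config | None = None


def detect_field_spots(
    image: CalibratedImage, mask: np.ndarray, cfg: Config
) -> tuple[list[Spot], list[Spot]]:
    """Detect HER2 (orange) and CEP17 (green) spots within the mask."""
    pp = cfg.preprocess
    kw = dict(
        smoothing_sigma_um=pp.smoothing_sigma_um,
        tophat_radius_um=pp.tophat_radius_um,
        log_sigma_um=pp.log_sigma_um,
    )
    her2 = detect_spots(
        image.orange,
        cfg.her2,
        image.um_per_px,
        "her2",
        mask=mask,
        enhanced=preprocess_channel(image.orange, image.um_per_px, **kw),
    )
    cep17 = detect_spots(
        image.green,
        cfg.cep17,
        image.um_per_px,
        "cep17",
        mask=mask,
        enhanced=preprocess_channel(image.green, image.um_per_px, **kw),
    )
    return her2, cep17


def analyze_fields(images: list[CalibratedImage], cfg: Config) -> tuple[list[FieldAnalysis], bool]:
    """Mask + spot detection for every field, with case-level HSR handling.

    The reference single-spot area for HSR area-mode counting is estimated
    from the HER2 spots pooled over all fields of the case; the returned
    flag is True when any cluster was converted to multiple equivalents.
    """
    analyses = []
    for image in images:
        mask = build_counterstain_mask(image.dapi, image.um_per_px)
        her2, cep17 = detect_field_spots(image, mask, cfg)
        # area-mode counting needs signal area, which only the smoothed
        # (not spot-enhanced) channel preserves for wide HSR clusters
        her2 = consolidate_signal_objects(
            image.orange,
            image.um_per_px,
            her2,
            cfg.her2.intensity_frac,
            cfg.preprocess.smoothing_sigma_um,
            cfg.hsr.hsr_factor,
            mask=mask,
        )
        analyses.append(FieldAnalysis(mask=mask, her2_spots=her2, cep17_spots=cep17))
    pooled = [s for fa in analyses for s in fa.her2_spots]
    ref_area = estimate_reference_spot_area(
        pooled, cfg.hsr.hsr_factor, cfg.hsr.fallback_ref_area_um2
    )
    hsr_used = False
    for fa in analyses:
        fa.her2_spots, converted = count_hsr_equivalents(
            fa.her2_spots, ref_area, cfg.hsr.hsr_factor
        )
        hsr_used = hsr_used or converted
    return analyses, hsr_used


def analyze_case(
    images: list[CalibratedImage],
    cfg: Config,
    mode: str = "nuclei",
    edits: list[EditOp] | None = None,
) -> CaseAnalysis:
    """Run the full classifier on the fields of one case.

    ``mode`` selects the tile-sampling or nuclei-sampling classifier; in
    nuclei mode an optional edit journal is replayed (emulating the
    interactive human-correction phase) before the final result is taken.
    Deterministic given images and configuration.
    """
    if mode not in ("tile", "nuclei"):
        raise ValueError(f"mode must be 'tile' or 'nuclei', got {mode!r}")
    analyses, hsr_used = analyze_fields(images, cfg)
    qc = ["hsr_mode_used"] if hsr_used else []

    if mode == "tile":
        accepted = []
        for image, fa in zip(images, analyses):
            tiles = place_tiles(fa.mask, cfg.tile.tile_px)
            tiles = fill_tiles(tiles, fa.her2_spots + fa.cep17_spots)
            acc = reject_tiles(tiles, cfg.tile)
            acc_origins = {t.origin for t in acc}
            fa.tiles = [replace(t, accepted=t.origin in acc_origins) for t in tiles]
            accepted.extend(acc)
        result = tile_case_result(accepted, cfg.tile, cfg.thresholds)
        result.qc.extend(qc)
        return CaseAnalysis(result=result, fields=analyses, mode=mode, config=cfg)

    per_field = []
    for image, fa in zip(images, analyses):
        labels, nuclei = segment_nuclei(image.dapi, fa.mask, image.um_per_px)
        spots = fa.her2_spots + fa.cep17_spots
        nuclei = gate_nuclei(nuclei, spots, cfg.nucleus, labels)
        fa.labels, fa.nuclei = labels, nuclei
        per_field.append((labels, nuclei, spots))
    state = CaseState.from_fields(
        per_field, cfg.nucleus, cfg.thresholds, images[0].um_per_px, qc=qc
    )
    for op in edits or []:
        apply_edit(state, op)
    return CaseAnalysis(result=state.result, fields=analyses, mode=mode, state=state, config=cfg)
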