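"""Tile-sampling classifier.

Non-overlapping, equal-sized square tiles (default 71 px, on the order of
one or two nuclei) are placed on the counterstain mask so as to cover as
much nuclear material and as little empty space as possible.  Spots are
counted per tile; tiles with less than 40% nuclear coverage or at most one
fluorescent signal are rejected, and a case with fewer than 32 accepted
tiles is rejected outright.  The case ratio is the quotient of the pooled
HER2 and CEP17 spot-equivalent totals over accepted tiles, identical to the
quotient of the per-tile averages.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import (
    CaseResult,
    InvalidInputError,
    Thresholds,
    TileParams,
    make_case_result,
)
from .spots import Spot

__all__ = ["Tile", "place_tiles", "fill_tiles", "reject_tiles", "tile_case_result"]

#: stride of the dense candidate lattice, px (the exact tiling lattice of
#: stride ``tile_px`` is always added as well)
CANDIDATE_STRIDE_PX = 8


@dataclass(frozen=True)
class Tile:
    """An axis-aligned square sampling window.

    ``origin`` is the (row, col) of the top-left pixel; the tile covers the
    half-open pixel box ``[origin, origin + side_px)``.
    """

    origin: tuple[int, int]
    side_px: int
    coverage: float
    her2_count: int = 0
    cep17_count: int = 0
    accepted: bool = False

    def contains(self, r: float, c: float) -> bool:
        r0, c0 = self.origin
        return r0 <= r < r0 + self.side_px and c0 <= c < c0 + self.side_px


def _candidate_origins(extent: int, tile_px: int) -> np.ndarray:
    dense = np.arange(0, extent - tile_px + 1, CANDIDATE_STRIDE_PX)
    exact = np.arange(0, extent - tile_px + 1, tile_px)
    return np.unique(np.concatenate([dense, exact]))


def place_tiles(mask: np.ndarray, tile_px: int) -> list[Tile]:
    """Greedy non-overlapping placement maximizing nuclear coverage.

    Candidate origins lie on a dense 8-px lattice plus the exact tiling
    lattice of stride ``tile_px``; candidates are taken in order of
    descending mask coverage (ties broken row-major) and accepted when they
    do not overlap an already placed tile.  Zero-coverage candidates are
    never emitted.  Deterministic for a given mask.
    """
    mask = np.asarray(mask, bool)
    h, w = mask.shape
    if tile_px > h or tile_px > w:
        raise InvalidInputError("tile side exceeds image dimensions")
    rows = _candidate_origins(h, tile_px)
    cols = _candidate_origins(w, tile_px)
    # integral image -> coverage of every candidate in O(1)
    ii = np.zeros((h + 1, w + 1), dtype=np.int64)
    ii[1:, 1:] = np.cumsum(np.cumsum(mask, axis=0), axis=1)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    covered = (
        ii[rr + tile_px, cc + tile_px]
        - ii[rr, cc + tile_px]
        - ii[rr + tile_px, cc]
        + ii[rr, cc]
    )
    area = tile_px * tile_px
    order = np.lexsort((cc.ravel(), rr.ravel(), -covered.ravel()))
    occupied = np.zeros((h, w), bool)
    tiles: list[Tile] = []
    cov_flat = covered.ravel()
    rr_flat, cc_flat = rr.ravel(), cc.ravel()
    for idx in order:
        if cov_flat[idx] == 0:
            break  # candidates are sorted by coverage; the rest are empty
        r, c = int(rr_flat[idx]), int(cc_flat[idx])
        window = occupied[r : r + tile_px, c : c + tile_px]
        if window.any():
            continue
        window[:] = True
        tiles.append(Tile(origin=(r, c), side_px=tile_px, coverage=cov_flat[idx] / area))
    # a dense greedy choice can block two lattice tiles worth more together;
    # fall back to the exact tiling lattice when it covers more mask overall
    lattice = [
        Tile(origin=(int(r), int(c)), side_px=tile_px,
             coverage=(ii[r + tile_px, c + tile_px] - ii[r, c + tile_px]
                       - ii[r + tile_px, c] + ii[r, c]) / area)
        for r in np.arange(0, h - tile_px + 1, tile_px)
        for c in np.arange(0, w - tile_px + 1, tile_px)
    ]
    lattice = [t for t in lattice if t.coverage > 0]
    if sum(t.coverage for t in lattice) > sum(t.coverage for t in tiles):
        tiles = lattice
    tiles.sort(key=lambda t: t.origin)
    return tiles


def fill_tiles(tiles: list[Tile], spots: list[Spot]) -> list[Tile]:
    """Attach per-channel spot-equivalent counts to each tile.

    A spot is counted in the tile whose half-open pixel box contains its
    centroid; tiles are non-overlapping, so each spot lands in at most one.
    """
    her2 = np.zeros(len(tiles), dtype=int)
    cep17 = np.zeros(len(tiles), dtype=int)
    for s in spots:
        r, c = s.centroid
        for i, t in enumerate(tiles):
            if t.contains(r, c):
                if s.channel == "her2":
                    her2[i] += s.equivalents
                else:
                    cep17[i] += s.equivalents
                break
    return [
        replace(t, her2_count=int(h), cep17_count=int(g))
        for t, h, g in zip(tiles, her2, cep17)
    ]


def reject_tiles(tiles: list[Tile], params: TileParams) -> list[Tile]:
    """Keep tiles with sufficient nuclear coverage and at least two signals.

    The coverage boundary is inclusive (rejection applies below 40%); tiles
    with at most one fluorescent signal in total are uninformative for a
    ratio and are rejected.
    """
    out = []
    for t in tiles:
        ok = t.coverage >= params.min_coverage - 1e-12 and t.her2_count + t.cep17_count >= 2
        if ok:
            out.append(replace(t, accepted=True))
    return out


def tile_case_result(
    accepted: list[Tile], params: TileParams, thresholds: Thresholds
) -> CaseResult:
    """Pool accepted tiles (over all fields of the case) into a CaseResult.

    Fewer than ``min_tiles`` accepted tiles rejects the whole case; raises
    :class:`~fishratio.core.UndefinedRatioError` when the CEP17 total is
    zero in a non-rejected case.
    """
    total_h = sum(t.her2_count for t in accepted)
    total_c = sum(t.cep17_count for t in accepted)
    return make_case_result(
        total_h, total_c, len(accepted), "tile", thresholds, params.min_tiles
    )
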