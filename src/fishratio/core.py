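"""Shared domain types for HER2/CEP17 FISH quantification.

The quantities modelled here follow the standard dual-probe HER2 FISH
workflow in breast-cancer diagnostics: fluorescent spots are counted in an
orange channel (HER2 locus probe) and a green channel (CEP17, the chromosome
17 centromere enumeration probe), pooled over sampling units (square tiles or
segmented nuclei), and the HER2/CEP17 ratio is mapped onto the clinical
categories *nonamplified* (< 1.8), *equivocal* (1.8–2.2, inclusive on both
ends) and *amplified* (> 2.2).  Equivocal cases with a ratio >= 2.0 are
flagged as potential candidates for targeted anti-HER2 therapy.

All physical parameters are stored in micrometres (or um^2) and converted to
pixels at use time through the image calibration ``um_per_px``, so one
configuration works at any magnification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NONAMPLIFIED",
    "EQUIVOCAL",
    "AMPLIFIED",
    "CATEGORIES",
    "InvalidInputError",
    "UndefinedRatioError",
    "ConfigError",
    "CalibratedImage",
    "SpotParams",
    "HER2_SPOT_PARAMS",
    "CEP17_SPOT_PARAMS",
    "TileParams",
    "NucleusParams",
    "Thresholds",
    "CaseResult",
    "classify_ratio",
    "compute_ratio",
]

NONAMPLIFIED = "nonamplified"
EQUIVOCAL = "equivocal"
AMPLIFIED = "amplified"
CATEGORIES = (NONAMPLIFIED, EQUIVOCAL, AMPLIFIED)


class InvalidInputError(ValueError):
    """An input violates a precondition (non-finite ratio, bad geometry...)."""


class UndefinedRatioError(ZeroDivisionError):
    """HER2/CEP17 ratio is undefined because the CEP17 total is zero."""


class ConfigError(ValueError):
    """A configuration value violates an invariant."""


def _as_channel(arr, name: str) -> np.ndarray:
    a = np.asarray(arr)
    if a.ndim != 2 or a.size == 0:
        raise InvalidInputError(f"{name} must be a non-empty 2-D raster")
    if a.dtype != np.uint8:
        if np.issubdtype(a.dtype, np.integer) and a.min() >= 0 and a.max() <= 255:
            a = a.astype(np.uint8)
        else:
            raise InvalidInputError(f"{name} must be 8-bit (values in [0, 255])")
    return a


@dataclass(frozen=True)
class CalibratedImage:
    """Three co-registered 8-bit channels plus the spatial calibration.

    Parameters
    ----------
    dapi, orange, green
        2-D uint8 rasters of identical shape: DAPI counterstain, Spectrum
        Orange (HER2) and Spectrum Green (CEP17).
    um_per_px
        Physical pixel size in micrometres; must be positive.
    """

    dapi: np.ndarray
    orange: np.ndarray
    green: np.ndarray
    um_per_px: float

    def __post_init__(self):
        object.__setattr__(self, "dapi", _as_channel(self.dapi, "dapi"))
        object.__setattr__(self, "orange", _as_channel(self.orange, "orange"))
        object.__setattr__(self, "green", _as_channel(self.green, "green"))
        if not (self.dapi.shape == self.orange.shape == self.green.shape):
            raise InvalidInputError("channel rasters must share one shape")
        if not (math.isfinite(self.um_per_px) and self.um_per_px > 0):
            raise InvalidInputError("um_per_px must be a positive finite scale")

    @property
    def shape(self) -> tuple[int, int]:
        return self.dapi.shape


@dataclass(frozen=True)
class SpotParams:
    """Definition of a countable fluorescent spot in one channel.

    ``min_area_um2`` is the smallest thresholded object area accepted as a
    spot; objects whose centroids lie closer than ``min_distance_um`` are
    merged into a single spot; ``intensity_frac`` is the relative intensity
    threshold (fraction of the channel's reference maximum) applied after
    image processing.
    """

    min_area_um2: float
    min_distance_um: float
    intensity_frac: float

    def __post_init__(self):
        if not (self.min_area_um2 > 0 and self.min_distance_um > 0):
            raise ConfigError("spot area and distance gates must be positive")
        if not (0 < self.intensity_frac <= 1):
            raise ConfigError("intensity_frac must lie in (0, 1]")


# Channel-specific spot definitions used by the original classifier.
HER2_SPOT_PARAMS = SpotParams(min_area_um2=0.05, min_distance_um=0.8, intensity_frac=0.33)
CEP17_SPOT_PARAMS = SpotParams(min_area_um2=0.18, min_distance_um=0.5, intensity_frac=0.30)


@dataclass(frozen=True)
class TileParams:
    """Tile-sampling parameters: 71-px squares, >=40% nuclear coverage,
    and at least 32 accepted tiles per case."""

    tile_px: int = 71
    min_coverage: float = 0.40
    min_tiles: int = 32

    def __post_init__(self):
        if self.tile_px < 1:
            raise ConfigError("tile_px must be >= 1")
        if not (0 <= self.min_coverage <= 1):
            raise ConfigError("min_coverage must lie in [0, 1]")
        if self.min_tiles < 1:
            raise ConfigError("min_tiles must be >= 1")


@dataclass(frozen=True)
class NucleusParams:
    """Nucleus eligibility gates: area window, circularity and the minimum
    number of accepted nuclei required to score a case."""

    min_area_um2: float = 12.0
    max_area_um2: float = 400.0
    min_roundness: float = 0.60
    min_nuclei: int = 20

    def __post_init__(self):
        if not (0 < self.min_area_um2 < self.max_area_um2):
            raise ConfigError("require 0 < min_area_um2 < max_area_um2")
        if not (0 < self.min_roundness <= 1):
            raise ConfigError("min_roundness must lie in (0, 1]")
        if self.min_nuclei < 1:
            raise ConfigError("min_nuclei must be >= 1")


@dataclass(frozen=True)
class Thresholds:
    """HER2/CEP17 ratio cut-offs for amplification calling.

    The equivocal band is closed on both ends: a ratio of exactly 1.8 or
    exactly 2.2 is equivocal; strictly below 1.8 is nonamplified and strictly
    above 2.2 is amplified.  ``eligibility_at`` marks equivocal ratios that
    still flag potential treatment eligibility.
    """

    nonamp_below: float = 1.8
    amp_above: float = 2.2
    eligibility_at: float = 2.0

    def __post_init__(self):
        if not (self.nonamp_below < self.eligibility_at <= self.amp_above):
            raise ConfigError("require nonamp_below < eligibility_at <= amp_above")


@dataclass
class CaseResult:
    """Aggregated outcome for one specimen.

    ``ratio``/``category``/``eligible`` are ``None`` when the case was
    rejected for insufficient sampling units (``"case_rejected"`` in ``qc``).
    """

    total_her2: int
    total_cep17: int
    n_units: int
    ratio: float | None
    category: str | None
    eligible: bool | None
    mode: str
    qc: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "n_units": self.n_units,
            "total_her2": self.total_her2,
            "total_cep17": self.total_cep17,
            "ratio": self.ratio,
            "category": self.category,
            "eligible": self.eligible,
            "qc": list(self.qc),
        }


def classify_ratio(ratio: float, thresholds: Thresholds = Thresholds()) -> tuple[str, bool]:
    """Map a HER2/CEP17 ratio onto an amplification category.

    Returns ``(category, eligible)`` where ``eligible`` is True for amplified
    cases and for equivocal cases with ratio >= ``thresholds.eligibility_at``.

    Raises
    ------
    InvalidInputError
        If the ratio is non-finite or negative.
    """
    ratio = float(ratio)
    if not math.isfinite(ratio) or ratio < 0:
        raise InvalidInputError(f"ratio must be finite and >= 0, got {ratio!r}")
    if ratio < thresholds.nonamp_below:
        return NONAMPLIFIED, False
    if ratio <= thresholds.amp_above:
        return EQUIVOCAL, ratio >= thresholds.eligibility_at
    return AMPLIFIED, True


def compute_ratio(total_her2: float, total_cep17: float) -> float:
    """HER2/CEP17 ratio from pooled spot-equivalent totals.

    Pooling totals before dividing is identical to the quotient of the
    per-unit averages (the unit count cancels) and avoids per-unit
    zero-division.

    Raises
    ------
    UndefinedRatioError
        If the CEP17 total is zero.
    """
    if total_her2 < 0 or total_cep17 < 0:
        raise InvalidInputError("spot totals must be nonnegative")
    if total_cep17 == 0:
        raise UndefinedRatioError("CEP17 total is zero; HER2/CEP17 ratio undefined")
    return float(total_her2) / float(total_cep17)


def make_case_result(
    total_her2: int,
    total_cep17: int,
    n_units: int,
    mode: str,
    thresholds: Thresholds,
    min_units: int,
    qc: list[str] | None = None,
) -> CaseResult:
    """Build a :class:`CaseResult`, applying case rejection and classification."""
    qc = list(qc or [])
    if n_units < min_units:
        qc.append("case_rejected")
        return CaseResult(total_her2, total_cep17, n_units, None, None, None, mode, qc)
    ratio = compute_ratio(total_her2, total_cep17)
    category, eligible = classify_ratio(ratio, thresholds)
    return CaseResult(total_her2, total_cep17, n_units, ratio, category, eligible, mode, qc)


__all__.append("make_case_result")
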