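"""Synthetic dual-probe FISH fields with known ground truth.

Emulates the imaging conditions of an automated HER2 FISH capture station:
1088 x 880 px, 8-bit fields containing textured elliptical DAPI nuclei with
per-nucleus planted HER2 (orange) and CEP17 (green) signal counts, optional
homogeneously-staining-region (HSR) clusters, optical blur and additive
background noise.  Each field comes with a :class:`GroundTruth` (nucleus
label raster, per-nucleus true counts, spot coordinates, planted case ratio
and category) so every pipeline stage can be validated without external
specimens.

Per-nucleus signal counts are drawn as ``1 + Poisson(lambda - 1)`` — a
shifted Poisson with mean exactly ``lambda`` and support >= 1.  Every real
nucleus carries at least one chromosome-17 centromere and one HER2 locus, so
zero-count nuclei would be artifacts of the count model, and the classifier's
>=1-of-each signal gate would silently bias the accepted-population ratio
away from the planted one.

Planted spot positions honour a minimum separation of 1.2x the channel's
merge distance (globally per channel), so planted count = detectable count:
no two planted signals can collapse into one detected spot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace

import numpy as np

from .core import (
    CEP17_SPOT_PARAMS,
    HER2_SPOT_PARAMS,
    CalibratedImage,
    InvalidInputError,
    Thresholds,
    classify_ratio,
    compute_ratio,
)

__all__ = [
    "GenerationError",
    "FieldSpec",
    "GroundTruth",
    "CaseTruth",
    "generate_field",
    "generate_case",
    "generate_cohort",
    "COHORT_PROFILES",
]


class GenerationError(RuntimeError):
    """Field generation failed (e.g. infeasible nucleus packing)."""


#: planted spots keep this multiple of the channel merge distance apart
SEPARATION_SAFETY = 1.2
#: rendered single-signal Gaussian widths, um (CEP17 alpha-satellite signals
#: are visibly larger than HER2 locus signals)
RENDER_SIGMA_UM = {"her2": 0.22, "cep17": 0.30}
#: rendered signal peak amplitude range (8-bit units)
SPOT_AMPLITUDE = (200, 240)
#: nuclei keep their signals at least this far inside the ellipse edge, um
SPOT_MARGIN_UM = 0.7
#: radial scale of the HSR cluster phyllotaxis layout, um.  The resulting
#: nearest-neighbour spacing (~1.6x this) stays below the HER2 merge
#: distance, so cluster members are unresolvable and collapse into one
#: reported object whose area carries the copy number
HSR_SPACING_UM = 0.35


def _hsr_cluster_radius_px(copies: int, px: float) -> float:
    return HSR_SPACING_UM / px * math.sqrt(copies)


def _sunflower(n: int, spacing: float, rot: float):
    """Phyllotaxis layout: n points, uniform density, nearest spacing ~= c."""
    golden = math.pi * (3 - math.sqrt(5))
    pts = []
    for k in range(1, n + 1):
        r = spacing * math.sqrt(k)
        th = k * golden + rot
        pts.append((r * math.sin(th), r * math.cos(th)))
    return pts


@dataclass(frozen=True)
class FieldSpec:
    """Parameters of one synthetic field.

    ``nucleus_diameter_um`` is (mean, sd) of the equivalent diameter;
    ``overlap_frac`` is the fraction of nuclei deliberately planted
    overlapping a neighbour; ``hsr`` is ``(fraction_of_nuclei, copy_number)``
    or ``None``; ``blurred_dapi`` adds strong counterstain blur to emulate
    poor-quality images (off by default).
    """

    width_px: int = 1088
    height_px: int = 880
    n_nuclei: int = 60
    nucleus_diameter_um: tuple[float, float] = (9.0, 1.0)
    overlap_frac: float = 0.0
    lambda_her2: float = 2.0
    lambda_cep17: float = 2.0
    hsr: tuple[float, int] | None = None
    background_noise_sd: float = 2.0
    blur_sigma_um: float = 0.1
    blurred_dapi: bool = False
    um_per_px: float = 0.16
    seed: int = 0

    def __post_init__(self):
        if self.width_px < 1 or self.height_px < 1:
            raise InvalidInputError("field dimensions must be positive")
        if self.n_nuclei < 0:
            raise InvalidInputError("n_nuclei must be >= 0")
        if not (0 <= self.overlap_frac <= 1):
            raise InvalidInputError("overlap_frac must lie in [0, 1]")
        if self.lambda_her2 < 1 or self.lambda_cep17 < 1:
            raise InvalidInputError("signal rates must be >= 1 (every nucleus carries >= 1 copy)")
        if self.hsr is not None:
            frac, copies = self.hsr
            if not (0 <= frac <= 1) or copies < 2:
                raise InvalidInputError("hsr must be (fraction in [0,1], copies >= 2)")


@dataclass
class GroundTruth:
    """Planted truth for one field."""

    labels: np.ndarray
    her2_counts: dict[int, int]
    cep17_counts: dict[int, int]
    her2_spots: list[tuple[float, float]]
    cep17_spots: list[tuple[float, float]]
    hsr_clusters: list[tuple[float, float, int]]
    total_her2: int = 0
    total_cep17: int = 0
    ratio: float | None = None
    category: str | None = None
    eligible: bool | None = None

    def finalize(self, thresholds: Thresholds = Thresholds()) -> "GroundTruth":
        self.total_her2 = sum(self.her2_counts.values())
        self.total_cep17 = sum(self.cep17_counts.values())
        if self.total_cep17 > 0:
            self.ratio = compute_ratio(self.total_her2, self.total_cep17)
            self.category, self.eligible = classify_ratio(self.ratio, thresholds)
        return self


@dataclass
class CaseTruth:
    """Pooled truth over the fields of one case."""

    fields: list[GroundTruth]
    total_her2: int
    total_cep17: int
    ratio: float | None
    category: str | None
    eligible: bool | None

    @classmethod
    def from_fields(cls, fields: list[GroundTruth], thresholds: Thresholds = Thresholds()):
        th = sum(f.total_her2 for f in fields)
        tc = sum(f.total_cep17 for f in fields)
        ratio = category = eligible = None
        if tc > 0:
            ratio = compute_ratio(th, tc)
            category, eligible = classify_ratio(ratio, thresholds)
        return cls(fields, th, tc, ratio, category, eligible)


def _shifted_poisson(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    """1 + Poisson(lam - 1): mean lam, support >= 1."""
    return 1 + rng.poisson(max(lam - 1.0, 0.0), size=size)


def _place_nuclei(spec: FieldSpec, rng: np.random.Generator):
    """Sample ellipse centers, semi-axes and orientations.

    Non-overlapping by default (center distance >= 1.05x the sum of the
    larger semi-axes); a fraction ``overlap_frac`` of nuclei is planted
    overlapping a previously placed neighbour.  Rejection sampling; raises
    :class:`GenerationError` when the field cannot hold the request.
    """
    mean_d, sd_d = spec.nucleus_diameter_um
    px = spec.um_per_px
    h, w = spec.height_px, spec.width_px
    placed = []  # (r, c, a_px, b_px, theta)
    n_overlap = int(round(spec.overlap_frac * spec.n_nuclei))
    for i in range(spec.n_nuclei):
        d_um = max(mean_d + sd_d * rng.standard_normal(), 0.7 * mean_d)
        q = rng.uniform(0.7, 1.0)  # axis ratio
        a = (d_um / 2) / math.sqrt(q) / px
        b = (d_um / 2) * math.sqrt(q) / px
        theta = rng.uniform(0, math.pi)
        margin = a + 2.0 / px
        if margin * 2 >= min(h, w):
            raise GenerationError("nucleus larger than the field")
        want_overlap = placed and i >= spec.n_nuclei - n_overlap
        for _ in range(2000):
            if want_overlap:
                nr, nc, na, _, _ = placed[rng.integers(len(placed))]
                ang = rng.uniform(0, 2 * math.pi)
                dist = 0.80 * (na + a)
                r, c = nr + dist * math.sin(ang), nc + dist * math.cos(ang)
                if not (margin <= r < h - margin and margin <= c < w - margin):
                    continue
                ok = all(
                    (r - pr) ** 2 + (c - pc) ** 2 >= (0.5 * (pa + a)) ** 2
                    for pr, pc, pa, _, _ in placed
                    if (pr, pc) != (nr, nc)
                )
            else:
                r = rng.uniform(margin, h - margin)
                c = rng.uniform(margin, w - margin)
                ok = all(
                    (r - pr) ** 2 + (c - pc) ** 2 >= (1.05 * (pa + a)) ** 2
                    for pr, pc, pa, _, _ in placed
                )
            if ok:
                placed.append((r, c, a, b, theta))
                break
        else:
            raise GenerationError(
                f"could not place nucleus {i + 1}/{spec.n_nuclei}: packing infeasible"
            )
    return placed


def _ellipse_interior(r, c, a, b, theta, frac, rng):
    """Uniform point inside the ellipse scaled by ``frac``.

    Uses the same implicit form as the raster draw:
    ((dr cos0 + dc sin0)/a)^2 + ((dr sin0 - dc cos0)/b)^2 < 1.
    """
    u = math.sqrt(rng.uniform()) * frac
    phi = rng.uniform(0, 2 * math.pi)
    x, y = a * u * math.cos(phi), b * u * math.sin(phi)
    return (
        r + x * math.cos(theta) + y * math.sin(theta),
        c + x * math.sin(theta) - y * math.cos(theta),
    )


def _render_gaussian(img: np.ndarray, r: float, c: float, amp: float, sigma_px: float):
    rad = int(math.ceil(4 * sigma_px))
    r0, r1 = max(int(r) - rad, 0), min(int(r) + rad + 1, img.shape[0])
    c0, c1 = max(int(c) - rad, 0), min(int(c) + rad + 1, img.shape[1])
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    img[r0:r1, c0:c1] += amp * np.exp(-((yy - r) ** 2 + (xx - c) ** 2) / (2 * sigma_px**2))


def generate_field(spec: FieldSpec) -> tuple[CalibratedImage, GroundTruth]:
    """Render one synthetic field and its ground truth.

    Deterministic given ``spec.seed``: calling twice yields bit-identical
    images.  8-bit quantisation is applied last so the noise statistics of
    the float rendering are honest.
    """
    from scipy import ndimage as ndi
    from skimage.draw import ellipse as draw_ellipse

    rng = np.random.default_rng(spec.seed)
    px = spec.um_per_px
    h, w = spec.height_px, spec.width_px
    dapi = np.zeros((h, w), np.float64)
    orange = np.zeros((h, w), np.float64)
    green = np.zeros((h, w), np.float64)
    labels = np.zeros((h, w), np.int32)

    nuclei = _place_nuclei(spec, rng)
    truth = GroundTruth(labels, {}, {}, [], [], [])

    # nucleus rasters + DAPI texture
    for lbl, (r, c, a, b, theta) in enumerate(nuclei, start=1):
        rr, cc = draw_ellipse(r, c, a, b, shape=(h, w), rotation=theta)
        labels[rr, cc] = lbl  # later nuclei overwrite in overlap zones
        base = rng.uniform(150, 200)
        dapi[rr, cc] = base + rng.normal(0, 8, size=rr.size)

    her2_counts = _shifted_poisson(rng, spec.lambda_her2, len(nuclei))
    cep17_counts = _shifted_poisson(rng, spec.lambda_cep17, len(nuclei))
    hsr_nuclei: set[int] = set()
    if spec.hsr is not None and len(nuclei) > 0:
        frac, copies = spec.hsr
        n_hsr = int(round(frac * len(nuclei)))
        hsr_nuclei = set(rng.choice(len(nuclei), size=n_hsr, replace=False).tolist())

    # planted signals must neither centroid-merge (1.2x the merge distance)
    # nor optically fuse into one thresholded object.  Two equal Gaussian
    # profiles bridge above the relative threshold up to ~3.5x their total
    # width on the LoG-sharpened image and up to ~4.3x on the smoothed-only
    # image used for signal-area consolidation (no LoG to carve the saddle).
    min_sep_px = {
        ch: max(
            SEPARATION_SAFETY * p.min_distance_um,
            3.5 * math.hypot(RENDER_SIGMA_UM[ch], 0.1, 0.1),
            4.3 * math.hypot(RENDER_SIGMA_UM[ch], 0.1),
        )
        / px
        for ch, p in (("her2", HER2_SPOT_PARAMS), ("cep17", CEP17_SPOT_PARAMS))
    }
    planted: dict[str, list[tuple[float, float]]] = {"her2": [], "cep17": []}

    def capacity(channel: str, lbl_idx: int) -> int:
        """Packing capacity of one nucleus for a channel's separation.

        Random sequential placement jams near 55% of the close-packing
        density; a drawn count above this bound is physically unplantable
        at the separation guarantee and is clamped (the ground truth always
        records the counts actually planted)."""
        _, _, a, b, _ = nuclei[lbl_idx]
        margin_frac = max(0.1, 1 - (SPOT_MARGIN_UM / px) / min(a, b))
        usable = math.pi * a * b * margin_frac**2
        sep = min_sep_px[channel]
        return max(1, int(0.55 * usable / (math.pi * (sep / 2) ** 2)))

    def plant_nucleus(
        channel: str, lbl_idx: int, k: int, keep_away: list | None = None
    ) -> list[tuple[float, float]]:
        """Place ``k`` spots of one channel inside nucleus ``lbl_idx``.

        Sequential placement can jam below the true packing capacity, so on
        failure the whole layout for this nucleus is resampled (the global
        separation registry is rolled back first).
        """
        r, c, a, b, theta = nuclei[lbl_idx]
        margin_frac = max(0.1, 1 - (SPOT_MARGIN_UM / px) / min(a, b))
        sep2 = min_sep_px[channel] ** 2
        for _round in range(30):
            new: list[tuple[float, float]] = []
            for _ in range(k):
                for _try in range(200):
                    pr, pc = _ellipse_interior(r, c, a, b, theta, margin_frac, rng)
                    if any(
                        (pr - qr) ** 2 + (pc - qc) ** 2 < sep2
                        for qr, qc in planted[channel] + new
                    ):
                        continue
                    if keep_away and any(
                        (pr - qr) ** 2 + (pc - qc) ** 2 < d2 for qr, qc, d2 in keep_away
                    ):
                        continue
                    new.append((pr, pc))
                    break
                else:
                    break  # jammed; resample this nucleus's layout
            if len(new) == k:
                planted[channel].extend(new)
                return new
        raise GenerationError(
            f"could not honour the spot separation guarantee "
            f"({k} {channel} signals in one nucleus): packing infeasible"
        )

    img_for = {"her2": orange, "cep17": green}
    for i in range(len(nuclei)):
        lbl = i + 1
        # CEP17 singles always
        kc = min(int(cep17_counts[i]), capacity("cep17", i))
        truth.cep17_counts[lbl] = kc
        for pr, pc in plant_nucleus("cep17", i, kc):
            truth.cep17_spots.append((pr, pc))
            _render_gaussian(
                green, pr, pc, rng.uniform(*SPOT_AMPLITUDE), RENDER_SIGMA_UM["cep17"] / px
            )
        if i in hsr_nuclei:
            # one tight cluster of `copies` signals replaces resolved singles
            copies = spec.hsr[1]
            r, c, a, b, theta = nuclei[i]
            cluster_r = _hsr_cluster_radius_px(copies, px)
            sep = min_sep_px["her2"]
            for _ in range(400):
                cr, cc_ = _ellipse_interior(r, c, a, b, theta, 0.4, rng)
                clear_singles = not any(
                    (cr - qr) ** 2 + (cc_ - qc) ** 2 < (cluster_r + sep) ** 2
                    for qr, qc in planted["her2"]
                )
                clear_clusters = not any(
                    (cr - qr) ** 2 + (cc_ - qc) ** 2
                    < (cluster_r + _hsr_cluster_radius_px(n, px) + sep) ** 2
                    for qr, qc, n in truth.hsr_clusters
                )
                if clear_singles and clear_clusters:
                    break
            else:
                raise GenerationError("could not place an HSR cluster clear of other signals")
            for dr, dc in _sunflower(copies, HSR_SPACING_UM / px, rng.uniform(0, 2 * math.pi)):
                _render_gaussian(
                    orange,
                    cr + dr,
                    cc_ + dc,
                    rng.uniform(*SPOT_AMPLITUDE),
                    RENDER_SIGMA_UM["her2"] / px,
                )
            truth.her2_counts[lbl] = copies
            truth.hsr_clusters.append((cr, cc_, copies))
            # later HER2 singles must stay clear of the cluster footprint
            planted["her2"].append((cr, cc_))
        else:
            kh = min(int(her2_counts[i]), capacity("her2", i))
            truth.her2_counts[lbl] = kh
            keep_away = [
                (qr, qc, (_hsr_cluster_radius_px(n, px) + min_sep_px["her2"]) ** 2)
                for qr, qc, n in truth.hsr_clusters
            ]
            for pr, pc in plant_nucleus("her2", i, kh, keep_away=keep_away):
                truth.her2_spots.append((pr, pc))
                _render_gaussian(
                    orange, pr, pc, rng.uniform(*SPOT_AMPLITUDE), RENDER_SIGMA_UM["her2"] / px
                )

    blur_px = spec.blur_sigma_um / px
    if blur_px > 0:
        orange = ndi.gaussian_filter(orange, blur_px)
        green = ndi.gaussian_filter(green, blur_px)
        dapi = ndi.gaussian_filter(dapi, max(blur_px, 1.0))
    if spec.blurred_dapi:
        dapi = ndi.gaussian_filter(dapi, 1.0 / px)
    if spec.background_noise_sd > 0:
        for img in (dapi, orange, green):
            img += rng.normal(0, spec.background_noise_sd, size=img.shape)

    def quantize(x):
        return np.clip(np.rint(x), 0, 255).astype(np.uint8)

    image = CalibratedImage(
        dapi=quantize(dapi), orange=quantize(orange), green=quantize(green), um_per_px=px
    )
    truth.labels = labels
    return image, truth.finalize()


def generate_case(
    spec: FieldSpec, n_fields: int = 5
) -> tuple[list[CalibratedImage], CaseTruth]:
    """Independent fields of one case, from per-field derived seeds."""
    if not (1 <= n_fields <= 20):
        raise InvalidInputError("n_fields must lie in [1, 20]")
    field_seeds = np.random.default_rng(spec.seed).integers(0, 2**31 - 1, size=n_fields)
    images, truths = [], []
    for s in field_seeds:
        img, tr = generate_field(replace(spec, seed=int(s)))
        images.append(img)
        truths.append(tr)
    return images, CaseTruth.from_fields(truths)


#: cohort presets emulating a validation-series design: clearly nonamplified,
#: clearly amplified (HSR in 80% of nuclei, copy number 12), the rarer
#: amplified-without-HSR pattern, and equivocal cases with planted ratio
#: constrained to [1.8, 2.2]
COHORT_PROFILES: dict[str, dict] = {
    "nonamplified": {"lambda_her2": 2.0, "lambda_cep17": 2.0, "hsr": None},
    "amplified": {"lambda_her2": 8.0, "lambda_cep17": 2.0, "hsr": (0.8, 12)},
    "amplified_no_hsr": {"lambda_her2": 8.0, "lambda_cep17": 2.0, "hsr": None},
    "equivocal": {"lambda_her2": 4.0, "lambda_cep17": 2.0, "hsr": None},
}


def generate_cohort(
    profile: str,
    n_cases: int,
    seed: int,
    n_fields: int = 1,
    base_spec: FieldSpec | None = None,
    thresholds: Thresholds = Thresholds(),
) -> list[tuple[list[CalibratedImage], CaseTruth]]:
    """Seeded cohort of labeled synthetic cases from a named profile.

    For the ``equivocal`` profile, cases are redrawn (from derived subseeds)
    until the realized planted ratio lies in the equivocal band, so planted
    labels match the profile by construction.
    """
    if profile not in COHORT_PROFILES:
        raise InvalidInputError(f"unknown profile {profile!r}")
    if n_cases < 1:
        raise InvalidInputError("n_cases must be >= 1")
    preset = COHORT_PROFILES[profile]
    base = base_spec if base_spec is not None else FieldSpec()
    rng = np.random.default_rng(seed)
    cases = []
    for _ in range(n_cases):
        for _attempt in range(50):
            spec = replace(base, seed=int(rng.integers(0, 2**31 - 1)), **preset)
            images, truth = generate_case(spec, n_fields=n_fields)
            if profile != "equivocal":
                break
            if (
                truth.ratio is not None
                and thresholds.nonamp_below <= truth.ratio <= thresholds.amp_above
            ):
                break
        else:
            raise GenerationError("could not realize an equivocal planted ratio")
        cases.append((images, truth))
    return cases
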