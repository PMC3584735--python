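"""Nucleus segmentation, eligibility gating, the five human-correction
edits with automatic ratio updates, and nuclei-mode case scoring."""

import numpy as np
import pytest
from skimage.draw import ellipse as draw_ellipse

from fishratio.core import (
    AMPLIFIED,
    EQUIVOCAL,
    NucleusParams,
    Thresholds,
    UndefinedRatioError,
)
from fishratio.nuclei import (
    ACCEPTED,
    DELETED,
    PRESEGMENTED,
    USER_ADDED,
    CaseState,
    EditError,
    EditOp,
    Nucleus,
    apply_edit,
    gate_nuclei,
    nuclei_case_result,
    segment_nuclei,
)
from fishratio.spots import Spot, build_counterstain_mask
from fishratio.synthetic import FieldSpec, generate_field

UPP = 0.16
PARAMS = NucleusParams()
TH = Thresholds()


def _spot(r, c, channel="her2", eq=1):
    return Spot(channel=channel, centroid=(float(r), float(c)), area_um2=0.2,
                peak_frac=1.0, equivalents=eq)


def _ellipse_image(centers, radii=(18, 14), shape=(256, 256), value=180):
    img = np.zeros(shape, np.uint8)
    for r, c in centers:
        rr, cc = draw_ellipse(r, c, radii[0], radii[1], shape=shape)
        img[rr, cc] = value
    return img


# ---------------------------------------------------------------- segmentation


def test_empty_mask_gives_no_nuclei():
    labels, nuclei = segment_nuclei(
        np.zeros((64, 64), np.uint8), np.zeros((64, 64), bool), UPP
    )
    assert nuclei == [] and labels.max() == 0


def test_separated_ellipses_are_recovered():
    centers = [(40 + 60 * (i // 3), 45 + 70 * (i % 3)) for i in range(9)]
    img = _ellipse_image(centers, shape=(256, 256))
    mask = build_counterstain_mask(img, UPP)
    labels, nuclei = segment_nuclei(img, mask, UPP)
    assert len(nuclei) == 9
    got = sorted(tuple(np.round(n.centroid).astype(int)) for n in nuclei)
    for (gr, gc), (er, ec) in zip(got, sorted(centers)):
        assert abs(gr - er) <= 2 and abs(gc - ec) <= 2


def test_touching_pair_is_split_by_watershed():
    """Two overlapping ellipses become two regions with centroids within
    2 um of the planted centers."""
    centers = [(60, 50), (60, 74)]  # overlap along the minor axis
    img = _ellipse_image(centers, radii=(20, 16), shape=(128, 128))
    mask = build_counterstain_mask(img, UPP)
    single_area = np.pi * 20 * 16 * UPP**2  # one planted ellipse
    labels, nuclei = segment_nuclei(img, mask, UPP, expected_area_um2=single_area)
    assert len(nuclei) == 2
    got = sorted(n.centroid for n in nuclei)
    for (gr, gc), (er, ec) in zip(got, sorted(centers)):
        assert np.hypot(gr - er, gc - ec) * UPP <= 2.0


def test_border_touching_regions_never_accepted():
    img = _ellipse_image([(10, 60), (70, 60)], radii=(16, 13), shape=(128, 128))
    mask = build_counterstain_mask(img, UPP)
    labels, nuclei = segment_nuclei(img, mask, UPP)
    spots = []
    for n in nuclei:
        r, c = n.centroid
        spots += [_spot(r, c, "her2"), _spot(r + 2, c + 2, "cep17")]
    nuclei = gate_nuclei(nuclei, spots, PARAMS, labels)
    by_border = {n.touches_border: n.status for n in nuclei}
    assert by_border[True] == PRESEGMENTED
    assert by_border[False] == ACCEPTED


def test_segmentation_recall_precision_on_synthetic_fields():
    """>= 95% of planted nuclei recovered and >= 95% of reported regions
    correspond to planted nuclei, at low (<= 5%) overlap."""
    for seed in (0, 1):
        spec = FieldSpec(n_nuclei=50, overlap_frac=0.05, seed=seed)
        img, truth = generate_field(spec)
        mask = build_counterstain_mask(img.dapi, img.um_per_px)
        labels, nuclei = segment_nuclei(img.dapi, mask, img.um_per_px)
        planted = np.array(
            [np.mean(np.argwhere(truth.labels == l), axis=0)
             for l in range(1, truth.labels.max() + 1)]
        )
        got = np.array([n.centroid for n in nuclei])
        d = np.sqrt(((planted[:, None] - got[None]) ** 2).sum(-1))
        matched_planted = (d.min(axis=1) * img.um_per_px < 3.0).sum()
        matched_got = (d.min(axis=0) * img.um_per_px < 3.0).sum()
        assert matched_planted / len(planted) >= 0.95
        assert matched_got / len(got) >= 0.95


# ---------------------------------------------------------------- gating


def _square_nucleus_state(side_px, spots, nid=1, shape=(120, 120)):
    labels = np.zeros(shape, np.int32)
    labels[10 : 10 + side_px, 10 : 10 + side_px] = nid
    region = labels == nid
    from fishratio.nuclei import _measure

    area, roundness, centroid = _measure(region, UPP)
    n = Nucleus(id=nid, field_index=0, label=nid, area_um2=area, roundness=roundness,
                centroid=centroid, status=ACCEPTED)
    return labels, [n]


@pytest.mark.parametrize(
    "side_px, expect_accept",
    [
        (20, False),  # 10.2 um^2, below the 12 um^2 gate
        (22, True),   # 12.4 um^2, just inside
        (125, True),  # exactly 400 um^2: upper bound inclusive
        (126, False),  # 406 um^2, above
    ],
)
def test_area_gates(side_px, expect_accept):
    labels, nuclei = _square_nucleus_state(side_px, [], shape=(150, 150))
    r, c = nuclei[0].centroid
    spots = [_spot(r, c, "her2"), _spot(r + 1, c + 1, "cep17")]
    # a square's circularity (~0.785) passes the 0.60 roundness gate
    out = gate_nuclei(nuclei, spots, PARAMS, labels)
    assert (out[0].status == ACCEPTED) == expect_accept


def test_signal_quality_gate_requires_both_probes():
    labels, nuclei = _square_nucleus_state(63, [])  # ~100 um^2
    r, c = nuclei[0].centroid
    only_her2 = [_spot(r, c, "her2"), _spot(r + 2, c, "her2"), _spot(r, c + 2, "her2")]
    out = gate_nuclei(nuclei, only_her2, PARAMS, labels)
    assert out[0].status == PRESEGMENTED
    both = only_her2[:1] + [_spot(r + 1, c + 1, "cep17"), _spot(r + 3, c, "cep17")]
    out = gate_nuclei(nuclei, both, PARAMS, labels)
    assert out[0].status == ACCEPTED
    assert (out[0].her2_count, out[0].cep17_count) == (1, 2)


def test_roundness_gate_rejects_elongated_region():
    labels = np.zeros((120, 120), np.int32)
    labels[20:24, 5:115] = 1  # long thin bar
    from fishratio.nuclei import _measure

    area, roundness, centroid = _measure(labels == 1, 0.4)  # scale into area window
    n = Nucleus(id=1, field_index=0, label=1, area_um2=area, roundness=roundness,
                centroid=centroid, status=ACCEPTED)
    r, c = centroid
    out = gate_nuclei([n], [_spot(r, c), _spot(r, c + 2, "cep17")], PARAMS, labels)
    assert out[0].roundness < 0.60
    assert out[0].status == PRESEGMENTED


# ---------------------------------------------------------------- edits


def _two_nucleus_state():
    """Two 40x40 square nuclei with known counts: #1 carries 6/2, #2 2/2."""
    labels = np.zeros((160, 160), np.int32)
    labels[20:60, 20:60] = 1
    labels[90:130, 90:130] = 2
    spots = (
        # nucleus 1: three HER2 + one CEP17 on each side of column 40
        [_spot(25, 25), _spot(35, 25), _spot(45, 25)]
        + [_spot(25, 50), _spot(35, 50), _spot(45, 50)]
        + [_spot(30, 30, "cep17"), _spot(30, 52, "cep17")]
        + [_spot(100, 100, "her2"), _spot(110, 100, "her2")]
        + [_spot(100, 115, "cep17"), _spot(110, 115, "cep17")]
    )
    from fishratio.nuclei import _measure

    nuclei = []
    for nid in (1, 2):
        region = labels == nid
        area, roundness, centroid = _measure(region, UPP)
        nuclei.append(Nucleus(id=nid, field_index=0, label=nid, area_um2=area,
                              roundness=roundness, centroid=centroid, status=ACCEPTED))
    params = NucleusParams(min_nuclei=1)
    nuclei = gate_nuclei(nuclei, spots, params, labels)
    return CaseState.from_fields([(labels, nuclei, spots)], params, TH, UPP)


def test_delete_updates_ratio_automatically():
    state = _two_nucleus_state()
    assert state.result.ratio == pytest.approx(8 / 4)
    her2_rich = next(n.id for n in state.nuclei.values() if n.her2_count == 6)
    apply_edit(state, EditOp(kind="delete", targets=(her2_rich,)))
    assert state.result.ratio == pytest.approx(2 / 2)
    assert state.result.n_units == 1


def test_add_then_delete_restores_ratio_exactly():
    state = _two_nucleus_state()
    before = state.result.ratio
    poly = ((140.0, 20.0), (140.0, 50.0), (155.0, 50.0), (155.0, 20.0))
    apply_edit(state, EditOp(kind="add", polygon=poly))
    added = next(n for n in state.nuclei.values() if n.status == USER_ADDED)
    assert added.counted  # user additions bypass the gates
    apply_edit(state, EditOp(kind="delete", targets=(added.id,)))
    assert state.result.ratio == before


def test_select_promotes_and_is_idempotent():
    state = _two_nucleus_state()
    nid = next(iter(state.nuclei))
    state.nuclei[nid].status = PRESEGMENTED
    state.refresh()
    apply_edit(state, EditOp(kind="select", targets=(nid,)))
    assert state.nuclei[nid].status == ACCEPTED
    snapshot = state.result.to_dict()
    apply_edit(state, EditOp(kind="select", targets=(nid,)))  # no-op
    assert state.result.to_dict() == snapshot


def test_delete_on_deleted_is_noop():
    state = _two_nucleus_state()
    nid = next(iter(state.nuclei))
    apply_edit(state, EditOp(kind="delete", targets=(nid,)))
    snapshot = state.result.to_dict()
    apply_edit(state, EditOp(kind="delete", targets=(nid,)))
    assert state.result.to_dict() == snapshot
    assert state.nuclei[nid].status == DELETED


def test_split_conserves_spots_and_regions_stay_disjoint():
    state = _two_nucleus_state()
    target = next(n for n in state.nuclei.values() if n.her2_count == 6)
    before_units = state.result.n_units
    before_total = state.result.total_her2 + state.result.total_cep17
    # vertical cut through the 40x40 region between the spot columns
    apply_edit(state, EditOp(kind="split", targets=(target.id,),
                             polyline=((18.0, 40.0), (62.0, 40.0))))
    assert state.result.n_units == before_units + 1
    assert state.result.total_her2 + state.result.total_cep17 == before_total
    # pixel-level disjointness: every labeled pixel belongs to one nucleus
    labels = state.fields[0].labels
    live = [n.label for n in state.nuclei.values()]
    assert len(live) == len(set(live))
    for n in state.nuclei.values():
        assert (labels == n.label).sum() > 0


def test_merge_unites_regions_and_conserves_spots():
    state = _two_nucleus_state()
    ids = tuple(state.nuclei)
    before_total = sum(n.her2_count + n.cep17_count for n in state.nuclei.values())
    apply_edit(state, EditOp(kind="merge", targets=ids))
    assert len(state.nuclei) == 1
    merged = next(iter(state.nuclei.values()))
    assert merged.her2_count + merged.cep17_count == before_total


def test_invalid_edits_leave_state_unchanged():
    state = _two_nucleus_state()
    snapshot = state.result.to_dict()
    n_before = len(state.nuclei)
    with pytest.raises(EditError):
        apply_edit(state, EditOp(kind="delete", targets=(999,)))
    with pytest.raises(EditError):
        apply_edit(state, EditOp(kind="add", polygon=((-5.0, 0.0), (0.0, 10.0), (10.0, 0.0))))
    with pytest.raises(EditError):  # polyline that does not cross the region
        apply_edit(state, EditOp(kind="split", targets=(1,),
                                 polyline=((0.0, 0.0), (5.0, 5.0))))
    with pytest.raises(EditError):
        apply_edit(state, EditOp(kind="warp", targets=(1,)))
    assert state.result.to_dict() == snapshot
    assert len(state.nuclei) == n_before
    assert state.journal == []


# ---------------------------------------------------------------- case level


def _bulk_state(n, h_each, c_each, min_nuclei=20):
    nuclei = {
        i: Nucleus(id=i, field_index=0, label=i, area_um2=100.0, roundness=0.9,
                   centroid=(float(i), 0.0), status=ACCEPTED,
                   her2_count=h_each, cep17_count=c_each)
        for i in range(1, n + 1)
    }
    state = CaseState(fields=[], params=NucleusParams(min_nuclei=min_nuclei),
                      thresholds=TH, nuclei=nuclei)
    return state


def test_case_rejected_below_min_nuclei():
    res = nuclei_case_result(_bulk_state(19, 2, 2), NucleusParams(), TH)
    assert "case_rejected" in res.qc and res.category is None


def test_case_scoring_examples():
    res = nuclei_case_result(_bulk_state(25, 6, 2), NucleusParams(), TH)
    assert res.ratio == pytest.approx(3.0) and res.category == AMPLIFIED
    res = nuclei_case_result(_bulk_state(60, 2, 1), NucleusParams(), TH)
    assert res.ratio == pytest.approx(2.0)
    assert res.category == EQUIVOCAL and res.eligible


def test_case_zero_cep17_raises():
    with pytest.raises(UndefinedRatioError):
        nuclei_case_result(_bulk_state(25, 2, 0), NucleusParams(), TH)
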