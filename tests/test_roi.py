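"""ROI protocol: mirroring, area gate, extraction, averaging, and ICC."""

import numpy as np
import pandas as pd
import pytest

from dkiasl.roi import (REGION_NAMES, average_replicates, default_atlas_specs,
                        extract_roi_values, icc_report, icc_two_rater,
                        mirror_roi, roi_area)


def test_default_atlas_has_24_bilateral_regions():
    specs = default_atlas_specs()
    assert len(specs) == 24
    assert len({(s.name, s.hemisphere) for s in specs}) == 24
    assert {s.name for s in specs} == set(REGION_NAMES)


def test_mirror_moves_left_mask_to_right_half():
    mask = np.zeros((10, 6, 4), dtype=bool)
    mask[1:4, 2, 1] = True
    flipped = mirror_roi(mask, flip_axis=0)
    assert flipped.sum() == mask.sum()
    assert not flipped[:5].any() and flipped[5:].any()
    # voxel i -> N-1-i
    assert flipped[6:9, 2, 1].all()


def test_mirror_is_involution_and_fixes_symmetric_masks(rng):
    mask = rng.random((8, 8, 3)) > 0.5
    assert np.array_equal(mirror_roi(mirror_roi(mask)), mask)
    sym = mask | mirror_roi(mask)
    assert np.array_equal(mirror_roi(sym), sym)


def test_roi_area_examples():
    mask = np.zeros((10, 10), dtype=bool)
    mask.flat[:20] = True
    area, ok = roi_area(mask, (1.0, 1.0))
    assert area == 20.0 and ok
    small = np.zeros((10, 10), dtype=bool)
    small.flat[:5] = True
    area, ok = roi_area(small, (1.0, 1.0))
    assert area == 5.0 and not ok


def test_roi_area_at_protocol_voxel_size():
    """22 voxels at 240 mm FOV / 256 matrix (0.9375 mm) -> 19.34 mm^2."""
    mask = np.zeros((16, 16), dtype=bool)
    mask.flat[:22] = True
    area, ok = roi_area(mask, (0.9375, 0.9375))
    assert area == pytest.approx(19.34, abs=0.005)
    assert ok


def test_roi_area_rejects_multislice():
    mask = np.zeros((4, 4, 3), dtype=bool)
    mask[1, 1, 0] = mask[1, 1, 2] = True
    with pytest.raises(ValueError, match="single-slice"):
        roi_area(mask, (1.0, 1.0))


def _toy_label_map():
    from dkiasl.roi import ROISpec

    label = np.zeros((6, 4, 2), dtype=int)
    label[0:2, 0:2, 0] = 1
    label[4:6, 0:2, 0] = 2
    specs = [ROISpec(1, "Hip (h)", "left"), ROISpec(2, "Hip (h)", "right")]
    return label, specs


def test_extract_constant_map():
    label, specs = _toy_label_map()
    table = extract_roi_values(np.full(label.shape, 3.7), label, specs)
    assert np.allclose(table["value"], 3.7)
    assert (table["n_valid"] == 4).all()


def test_extract_flags_all_missing_region():
    label, specs = _toy_label_map()
    pmap = np.full(label.shape, 2.0)
    pmap[label == 2] = np.nan
    table = extract_roi_values(pmap, label, specs)
    right = table[table["hemisphere"] == "right"].iloc[0]
    assert np.isnan(right["value"]) and right["n_valid"] == 0


def test_extract_invariant_to_label_renumbering(rng):
    from dkiasl.roi import ROISpec

    label, specs = _toy_label_map()
    pmap = rng.random(label.shape)
    before = extract_roi_values(pmap, label, specs)
    relabel = np.where(label == 1, 41, np.where(label == 2, 7, 0))
    specs2 = [ROISpec(41, "Hip (h)", "left"), ROISpec(7, "Hip (h)", "right")]
    after = extract_roi_values(pmap, relabel, specs2)
    assert np.allclose(before["value"], after["value"])


def test_extract_shape_mismatch():
    label, specs = _toy_label_map()
    with pytest.raises(ValueError):
        extract_roi_values(np.zeros((2, 2, 2)), label, specs)


def _measurement_table(values_by_rater):
    rows = []
    for rater, reps in values_by_rater.items():
        for i, v in enumerate(reps, start=1):
            rows.append({"subject_id": "s1", "region": "PCC",
                         "hemisphere": "left", "metric": "MK",
                         "rater": rater, "replicate": i, "value": v})
    return pd.DataFrame(rows)


def test_average_replicates_hand_example():
    """Rater means 2 and 4 average to 3 (replicates first, raters second)."""
    table = _measurement_table({1: [1, 2, 3], 2: [3, 4, 5]})
    combined, per_rater = average_replicates(table)
    assert combined["value"].iloc[0] == pytest.approx(3.0)
    assert sorted(per_rater["value"]) == [2.0, 4.0]


def test_average_replicates_matches_nested_groupby(rng):
    rows = []
    for subj in ("a", "b"):
        for region in ("PCC", "Pr"):
            for metric in ("MK", "CBF"):
                for rater in (1, 2):
                    for rep in (1, 2, 3):
                        rows.append({"subject_id": subj, "region": region,
                                     "hemisphere": "left", "metric": metric,
                                     "rater": rater, "replicate": rep,
                                     "value": rng.random()})
    table = pd.DataFrame(rows)
    combined, _ = average_replicates(table)
    # brute-force nested group-by
    for row in combined.itertuples():
        sel = table[(table.subject_id == row.subject_id)
                    & (table.region == row.region)
                    & (table.metric == row.metric)]
        expected = np.mean([sel[sel.rater == r]["value"].mean() for r in (1, 2)])
        assert row.value == pytest.approx(expected, rel=1e-12)
        # balanced design: equals the grand mean
        assert row.value == pytest.approx(sel["value"].mean(), rel=1e-12)


def test_average_replicates_missing_rater_errors():
    table = _measurement_table({1: [1, 2, 3]})
    table2 = _measurement_table({1: [1, 2, 3], 2: [3, 4, 5]})
    table2["subject_id"] = "s2"
    with pytest.raises(ValueError, match="rater"):
        average_replicates(pd.concat([table, table2], ignore_index=True))


def test_icc_identical_and_offset_raters(rng):
    x = rng.random(20)
    icc, good = icc_two_rater(x, x)
    assert icc == 1.0 and good
    icc_off, good_off = icc_two_rater(x, x + 0.5)
    assert icc_off == pytest.approx(1.0)  # consistency form ignores fixed offsets
    assert good_off


def test_icc_agreement_form_penalizes_offset(rng):
    x = rng.random(30)
    icc_agree, _ = icc_two_rater(x, x + 0.5, form="agreement")
    assert icc_agree < 0.75


def test_icc_independent_raters_near_zero():
    rng = np.random.default_rng(0)
    icc, good = icc_two_rater(rng.random(200), rng.random(200))
    assert abs(icc) < 0.15 and not good


def test_icc_matches_pingouin(rng):
    """Cross-check ICC(3,1) and ICC(2,1) against an independent implementation."""
    pingouin = pytest.importorskip("pingouin")
    x = rng.random(25)
    y = x + 0.2 * rng.random(25)
    frame = pd.DataFrame({
        "target": np.repeat(np.arange(25), 2),
        "rater": np.tile([1, 2], 25),
        "value": np.column_stack([x, y]).ravel(),
    })
    res = pingouin.intraclass_corr(frame, targets="target", raters="rater",
                                   ratings="value")
    icc3, _ = icc_two_rater(x, y, form="consistency")
    icc2, _ = icc_two_rater(x, y, form="agreement")
    assert icc3 == pytest.approx(
        res.loc[res.Type == "ICC(C,1)", "ICC"].iloc[0], abs=1e-10)
    assert icc2 == pytest.approx(
        res.loc[res.Type == "ICC(A,1)", "ICC"].iloc[0], abs=1e-10)


def test_icc_validation():
    with pytest.raises(ValueError):
        icc_two_rater([1.0, 2.0], [1.0, 2.0])
    with pytest.raises(ValueError):
        icc_two_rater([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])


def test_icc_report_per_region_metric(rng):
    rows = []
    for subj in range(8):
        for region, hemi in (("PCC", "left"), ("Pr", "right")):
            base = rng.random()
            for rater in (1, 2):
                noise = 0.0 if region == "PCC" else rng.normal(0, 1.0)
                for rep in (1, 2, 3):
                    rows.append({"subject_id": f"s{subj}", "region": region,
                                 "hemisphere": hemi, "metric": "MK",
                                 "rater": rater, "replicate": rep,
                                 "value": base + noise})
    _, per_rater = average_replicates(pd.DataFrame(rows))
    report = icc_report(per_rater)
    pcc = report[report.region == "PCC"].iloc[0]
    assert pcc["icc"] == pytest.approx(1.0) and pcc["good"]
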