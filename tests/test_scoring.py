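"""Threshold scoring: band mapping, pixel counting, Otsu, report assembly."""

import json

import numpy as np
import pytest
from hypothesis import given, strategies as st

from sinuslms.errors import ShapeMismatchError
from sinuslms.imaging import ImageVolume, LabelVolume
from sinuslms.regions import Region, Side
from sinuslms.scoring import (
    LundMackayScorer,
    ThresholdPolicy,
    map_score,
    opacification,
    resolve_threshold,
    score_volume,
)


class TestMapScore:
    @pytest.mark.parametrize(
        "fraction,expected",
        [
            (0.0, 0),
            (0.005, 0),
            (0.0099, 0),
            (0.01, 1),  # lower boundary is inclusive for score 1
            (0.5, 1),
            (0.95, 1),  # upper boundary still score 1
            (0.9501, 2),
            (0.96, 2),
            (1.0, 2),
        ],
    )
    def test_printed_bands(self, fraction, expected):
        assert map_score(fraction) == expected

    @pytest.mark.parametrize("bad", [-0.1, 1.0001, 2.0])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            map_score(bad)

    @given(st.floats(0, 1), st.floats(0, 1))
    def test_monotone_nondecreasing(self, a, b):
        lo, hi = sorted((a, b))
        assert map_score(lo) <= map_score(hi)

    def test_surjective_onto_three_scores(self):
        assert {map_score(f) for f in np.linspace(0, 1, 201)} == {0, 1, 2}


def _volume_with_labels(rng, shape=(6, 16, 16)):
    labels = rng.integers(0, 13, size=shape).astype(np.int16)
    intens = rng.uniform(-1000, 1000, size=shape).astype(np.float32)
    return ImageVolume(intens), LabelVolume(labels)


def test_opacification_equals_exhaustive_pixel_loop():
    """Oracle: an explicit per-pixel Python loop over a small volume."""
    rng = np.random.default_rng(5)
    vol, labels = _volume_with_labels(rng)
    res = opacification(vol, labels)
    counts = {int(r): [0, 0] for r in Region}
    for s in range(vol.shape[0]):
        for i in range(vol.shape[1]):
            for j in range(vol.shape[2]):
                code = int(labels.data[s, i, j])
                if code == 0:
                    continue
                counts[code][0] += 1
                if vol.data[s, i, j] > -300.0:
                    counts[code][1] += 1
    for r in Region:
        assert res.regions[r].total_pixels == counts[int(r)][0]
        assert res.regions[r].opacified_pixels == counts[int(r)][1]


def test_all_air_region_has_zero_fraction():
    labels = np.zeros((1, 10, 10), dtype=np.int16)
    labels[0, 2:8, 2:8] = int(Region.LEFT_MAXILLARY)
    intens = np.full((1, 10, 10), -1000.0, dtype=np.float32)
    res = opacification(ImageVolume(intens), LabelVolume(labels))
    assert res.fraction(Region.LEFT_MAXILLARY) == 0.0


def test_absent_region_flagged_without_fraction():
    labels = np.zeros((1, 10, 10), dtype=np.int16)
    labels[0, 2:8, 2:8] = int(Region.LEFT_MAXILLARY)
    res = opacification(ImageVolume(np.zeros((1, 10, 10), dtype=np.float32)), LabelVolume(labels))
    assert res.regions[Region.RIGHT_OMC].absent
    assert res.fraction(Region.RIGHT_OMC) is None


def test_shape_mismatch_rejected():
    with pytest.raises(ShapeMismatchError):
        opacification(
            ImageVolume(np.zeros((1, 4, 4), dtype=np.float32)),
            LabelVolume(np.zeros((1, 5, 5), dtype=np.int16)),
        )


def test_fixed_threshold_ignores_content():
    rng = np.random.default_rng(1)
    vol, labels = _volume_with_labels(rng)
    pol = ThresholdPolicy(fixed_cutoff=-123.0)
    present = next(r for r in Region if (labels.data == int(r)).any())
    assert resolve_threshold(vol, labels, present, pol) == -123.0


def test_otsu_separates_bimodal_region():
    labels = np.zeros((1, 25, 40), dtype=np.int16)
    labels[0] = int(Region.RIGHT_SPHENOID)
    intens = np.full((1, 25, 40), -1000.0, dtype=np.float32)
    intens.ravel()[:500] = 40.0  # half air, half soft tissue
    pol = ThresholdPolicy(method="otsu_per_region")
    thr = resolve_threshold(ImageVolume(intens), LabelVolume(labels), Region.RIGHT_SPHENOID, pol)
    assert -1000.0 < thr < 40.0

    # oracle: exhaustive scan of between-class variance over candidate cuts
    values = intens.ravel()
    candidates = np.unique(values)[:-1]
    best, best_var = None, -1.0
    for cut in candidates:
        lo, hi = values[values <= cut], values[values > cut]
        w0, w1 = len(lo) / len(values), len(hi) / len(values)
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var:
            best_var, best = var, cut
    # same induced partition as the exhaustively optimal threshold
    np.testing.assert_array_equal(values > thr, values > best)


def test_otsu_on_absent_region_errors():
    labels = LabelVolume(np.zeros((1, 5, 5), dtype=np.int16))
    vol = ImageVolume(np.zeros((1, 5, 5), dtype=np.float32))
    with pytest.raises(ValueError, match="empty"):
        resolve_threshold(vol, labels, Region.LEFT_OMC, ThresholdPolicy(method="otsu_per_region"))


def test_invalid_policy_rejected():
    with pytest.raises(ValueError):
        ThresholdPolicy(method="magic")
    with pytest.raises(ValueError):
        ThresholdPolicy(fixed_cutoff=-2000.0)


class TestScoreVolume:
    def _phantom_like(self, fractions):
        """One 400-pixel rectangular region per label code with designed fill."""
        labels = np.zeros((1, 60, 240), dtype=np.int16)
        intens = np.full((1, 60, 240), 700.0, dtype=np.float32)
        for k, region in enumerate(Region):
            r0, c0 = 5, 5 + k * 18
            block = np.s_[0, r0 : r0 + 40, c0 : c0 + 10]  # 400 px
            labels[block] = int(region)
            intens[block] = -1000.0
            n_fill = int(round(fractions[region] * 400))
            filled = np.full(400, False)
            filled[:n_fill] = True
            intens[block][filled.reshape(40, 10)] = 40.0
        return ImageVolume(intens), LabelVolume(labels)

    def test_all_clear_totals_zero(self):
        vol, labels = self._phantom_like({r: 0.0 for r in Region})
        rep = score_volume(vol, labels)
        assert rep.total == 0
        assert all(s.sub_score == 0 for s in rep.scores.values())

    def test_all_opacified_totals_24(self):
        vol, labels = self._phantom_like({r: 1.0 for r in Region})
        rep = score_volume(vol, labels)
        assert rep.total == 24
        assert rep.side_total(Side.LEFT) == 12
        assert rep.side_total(Side.RIGHT) == 12

    def test_suite_reports_match_truth_tables(self, small_suite):
        for pv in small_suite:
            rep = score_volume(pv.image, pv.labels)
            for region in Region:
                assert rep.sub_score(region) == pv.truth_sub_score(region), (
                    pv.name,
                    region.name,
                )
            assert rep.total == pv.truth_total

    def test_monotone_in_fraction(self):
        fracs = {r: 0.3 for r in Region}
        vol, labels = self._phantom_like(fracs)
        base = score_volume(vol, labels).sub_score(Region.LEFT_FRONTAL)
        fracs[Region.LEFT_FRONTAL] = 0.97
        vol2, labels2 = self._phantom_like(fracs)
        assert score_volume(vol2, labels2).sub_score(Region.LEFT_FRONTAL) >= base

    def test_omc_binary_collapses_partial_to_complete(self):
        vol, labels = self._phantom_like({r: 0.5 for r in Region})
        rep = score_volume(vol, labels, omc_binary=True)
        assert rep.sub_score(Region.RIGHT_OMC) == 2
        assert rep.sub_score(Region.RIGHT_MAXILLARY) == 1

    def test_absent_region_scored_zero_and_flagged(self):
        labels = np.zeros((1, 20, 20), dtype=np.int16)
        labels[0, 5:15, 5:15] = int(Region.LEFT_SPHENOID)
        vol = ImageVolume(np.full((1, 20, 20), 40.0, dtype=np.float32))
        rep = score_volume(vol, LabelVolume(labels))
        assert rep.scores[Region.RIGHT_SPHENOID].absent
        assert rep.sub_score(Region.RIGHT_SPHENOID) == 0
        assert rep.sub_score(Region.LEFT_SPHENOID) == 2


def test_report_serialization_round_trip(tmp_path, small_suite):
    pv = small_suite[3]  # mixed bands
    rep = score_volume(pv.image, pv.labels)
    jpath, cpath = rep.save(tmp_path / "case01_lms")
    payload = json.loads(jpath.read_text())
    assert payload["total"] == rep.total
    assert len(payload["regions"]) == 12
    import pandas as pd

    df = pd.read_csv(cpath)
    assert df.iloc[-1]["region"] == "TOTAL"
    assert int(df.iloc[-1]["sub_score"]) == rep.total


def test_scorer_estimator_api(small_suite):
    scorer = LundMackayScorer(fixed_cutoff=-250.0)
    assert scorer.get_params()["fixed_cutoff"] == -250.0
    scorer.set_params(fixed_cutoff=-300.0)
    reports = scorer.transform([(pv.image, pv.labels) for pv in small_suite[:2]])
    assert [r.total for r in reports] == [small_suite[0].truth_total, small_suite[1].truth_total]
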