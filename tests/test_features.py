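"""Unit tests for feature derivation, Bisgaard matching and scaling."""

import numpy as np
import pandas as pd
import pytest

from audioprofiles import bisgaard, features, synthetic
from audioprofiles.features import (FEATURE_NAMES, FeatureScaler,
                                    derive_features, encode_and_scale,
                                    identity_constraints,
                                    interpolate_thresholds)


def test_interpolation_fills_interior_gaps_linearly():
    row = np.array([10.0, np.nan, 30.0, np.nan, np.nan, 60.0])
    filled = interpolate_thresholds(row)
    assert filled[1] == pytest.approx(20.0)
    assert filled[3] == pytest.approx(40.0)
    assert filled[4] == pytest.approx(50.0)


def test_interpolation_leaves_edges_missing():
    row = np.array([np.nan, 20.0, np.nan, 40.0, np.nan])
    filled = interpolate_thresholds(row)
    assert np.isnan(filled[0]) and np.isnan(filled[-1])
    assert filled[2] == pytest.approx(30.0)


def test_each_standard_audiogram_matches_itself():
    freqs = np.array(bisgaard.AC_FREQUENCIES_KHZ)
    for name, idx in bisgaard.ORDINAL_INDEX.items():
        got_idx, got_name = bisgaard.match_standard(
            freqs, np.asarray(bisgaard.STANDARD_AUDIOGRAMS[name], float)
        )
        assert (got_idx, got_name) == (idx, name)


def test_standard_ordering_is_by_ascending_pta():
    ptas = [bisgaard.standard_pta(n) for n in bisgaard.ORDERED_STANDARDS]
    assert ptas == sorted(ptas)
    # the N4/S3 tie at equal PTA resolves with the N-standard first
    tied = [n for n in bisgaard.ORDERED_STANDARDS
            if bisgaard.standard_pta(n) == bisgaard.standard_pta("N4")]
    if "S3" in tied:
        assert tied.index("N4") < tied.index("S3")


def test_worse_ear_is_the_higher_pta_ear_with_right_tiebreak():
    cohort = synthetic.generate_cohort(
        synthetic.CohortSpec(n_patients=3, n_clusters=1, missing_rate=0.0, seed=1)
    )
    # patient 0: left clearly worse; patient 1: right worse; patient 2: tie
    for f in synthetic.AC_FREQS_HZ:
        cohort.loc[0, f"ac_l_{f}"] = 80.0
        cohort.loc[0, f"ac_r_{f}"] = 20.0
        cohort.loc[1, f"ac_l_{f}"] = 20.0
        cohort.loc[1, f"ac_r_{f}"] = 70.0
        cohort.loc[2, f"ac_l_{f}"] = 50.0
        cohort.loc[2, f"ac_r_{f}"] = 50.0
        cohort.loc[2, f"bc_l_{f}"] = 10.0 if f in synthetic.BC_FREQS_HZ else np.nan
    for f in synthetic.BC_FREQS_HZ:
        cohort.loc[2, f"bc_l_{f}"] = 10.0
        cohort.loc[2, f"bc_r_{f}"] = 40.0
    feats = derive_features(cohort)
    assert feats.loc[0, "ac_pta"] == pytest.approx(80.0)
    assert feats.loc[1, "ac_pta"] == pytest.approx(70.0)
    # tie -> right ear, so BC comes from the right ear too
    assert feats.loc[2, "bc_pta"] == pytest.approx(40.0)
    assert feats.loc[2, "asymmetry"] == pytest.approx(0.0)


def test_pta_requires_all_four_frequencies():
    cohort = synthetic.generate_cohort(
        synthetic.CohortSpec(n_patients=2, n_clusters=1, missing_rate=0.0, seed=2)
    )
    cohort.loc[0, "ac_r_500"] = np.nan   # interior gap: interpolated, PTA kept
    cohort.loc[1, "ac_r_250"] = np.nan
    cohort.loc[1, "ac_l_250"] = np.nan   # edge gap: stays missing but PTA ok
    feats = derive_features(cohort)
    assert np.isfinite(feats.loc[0, "ac_pta"])
    assert np.isfinite(feats.loc[1, "ac_pta"])


def test_scaler_maps_to_unit_interval_and_inverts():
    X = pd.DataFrame({"a": [0.0, 5.0, 10.0], "b": [-1.0, 0.0, 3.0]})
    scaler = FeatureScaler().fit(X)
    scaled = scaler.transform(X)
    assert scaled.min().min() == 0.0 and scaled.max().max() == 1.0
    pd.testing.assert_frame_equal(scaler.inverse_transform(scaled), X)


def test_constant_feature_scales_to_zero_with_warning():
    X = pd.DataFrame({"a": [5.0, 5.0, 5.0], "b": [1.0, 2.0, 3.0]})
    with pytest.warns(UserWarning, match="constant"):
        scaler = FeatureScaler().fit(X)
    scaled = scaler.transform(X)
    assert (scaled["a"] == 0.0).all()


def test_scaler_preserves_missing_cells():
    X = pd.DataFrame({"a": [0.0, np.nan, 10.0], "b": [1.0, 2.0, np.nan]})
    scaled = FeatureScaler().fit(X).transform(X)
    assert scaled.isna().equals(X.isna())


def test_derived_feature_order_matches_contract(small_cohort):
    _, feats, scaled, _ = small_cohort
    assert list(scaled.values.columns) == list(FEATURE_NAMES)
    assert set(features.CLASSIFICATION_FEATURES) <= set(FEATURE_NAMES)


def test_identity_constraints_reproduce_scaled_identities(small_cohort):
    _, feats, scaled, scaler = small_cohort
    spec = identity_constraints(scaler)
    assert set(spec) == {"abg", "l15m35_1500", "l15m35_4000"}
    vals = scaled.values
    for target, (coeffs, intercept) in spec.items():
        recon = sum(w * vals[c] for c, w in coeffs.items()) + intercept
        assert np.allclose(recon, vals[target], atol=1e-10)


def test_identity_constraints_without_scaler_are_raw_differences():
    spec = identity_constraints(None)
    assert spec["abg"] == ({"ac_pta": 1.0, "bc_pta": -1.0}, 0.0)
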