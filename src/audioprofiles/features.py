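"""Derivation of the 20 clustering features from raw audiological measurements.

Features span five domains: audiogram (AC/BC pure-tone averages, asymmetry,
air–bone gap, UCL PTA, Bisgaard standard-audiogram index), loudness scaling
(ACALOS L15/L35 and their differences at 1.5 and 4 kHz), speech tests (GOESA
SRT and slope, DTT SRT), cognitive measures (DemTect, WST) and anamnesis
(tinnitus, socio-economic status, age).

Conventions (fixed here because the underlying study leaves them open):
audiogram-derived features come from the *worse* ear, the ear with the higher
AC PTA, ties going to the right ear; the air–bone gap and UCL PTA use the same
ear; the Bisgaard index minimizes RMS distance over shared frequencies;
interpolation of interior missing thresholds is linear on the ordered
frequency index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import bisgaard, synthetic

#: The 20 clustering features, in canonical column order.
FEATURE_NAMES = synthetic.LATENT_FEATURES

#: The reduced 12-feature set available for classifying new patients
#: (ACALOS, GOESA, air-conduction audiogram summaries, age).
CLASSIFICATION_FEATURES = (
    "l15_1500", "l35_1500", "l15m35_1500",
    "l15_4000", "l35_4000", "l15m35_4000",
    "goesa_srt", "goesa_slope",
    "ac_pta", "asymmetry", "bisgaard_index",
    "age",
)

#: Definitional identities among derived features: each key is an exact
#: affine function of the listed parents (in original units, intercept 0).
DERIVED_IDENTITIES = {
    "abg": {"ac_pta": 1.0, "bc_pta": -1.0},
    "l15m35_1500": {"l15_1500": 1.0, "l35_1500": -1.0},
    "l15m35_4000": {"l15_4000": 1.0, "l35_4000": -1.0},
}


def identity_constraints(scaler: "FeatureScaler | None" = None) -> dict:
    """Passive-imputation spec for the derived-feature identities.

    Returns ``{target: (coeffs, intercept)}`` suitable for
    ``ImputationConfig.passive``. Without a scaler the identities are in
    original units; with a fitted min-max scaler they are re-expressed in
    scaled coordinates. Identities involving a constant (zero-span) feature
    are omitted, since scaling collapses them.
    """
    if scaler is None:
        return {t: (dict(c), 0.0) for t, c in DERIVED_IDENTITIES.items()}
    names = list(scaler.feature_names_in_)
    span = scaler.max_ - scaler.min_
    out = {}
    for target, coeffs in DERIVED_IDENTITIES.items():
        cols = [target, *coeffs]
        if any(c not in names for c in cols):
            continue
        idx = {c: names.index(c) for c in cols}
        if any(span[idx[c]] <= 0 for c in cols):
            continue
        sp_t, mn_t = span[idx[target]], scaler.min_[idx[target]]
        scaled_coeffs = {c: w * span[idx[c]] / sp_t for c, w in coeffs.items()}
        intercept = (
            sum(w * scaler.min_[idx[c]] for c, w in coeffs.items()) - mn_t
        ) / sp_t
        out[target] = (scaled_coeffs, intercept)
    return out


#: Ordinal features and their valid coded ranges (used for rounding/clipping
#: after imputation or noise augmentation).
ORDINAL_RANGES = {
    "bisgaard_index": (1, 10),
    "demtect": (0, 18),
    "wst": (0, 42),
    "tinnitus": (1, 3),
    "ses": (3, 21),
}


@dataclass
class Audiogram:
    """One ear's thresholds (dB HL) on a strictly increasing frequency grid."""

    frequencies_khz: np.ndarray
    thresholds: np.ndarray
    ear: str = "r"

    def __post_init__(self):
        self.frequencies_khz = np.asarray(self.frequencies_khz, dtype=float)
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if np.any(np.diff(self.frequencies_khz) <= 0):
            raise ValueError("frequencies must be strictly increasing")


def interpolate_thresholds(values: np.ndarray) -> np.ndarray:
    """Fill interior NaN runs linearly on the index; leave edges missing.

    Works row-wise on a 2-d array (patients x frequencies) or on a vector.
    """
    arr = np.atleast_2d(np.asarray(values, dtype=float))
    filled = (
        pd.DataFrame(arr)
        .interpolate(method="linear", axis=1, limit_area="inside")
        .to_numpy()
    )
    return filled[0] if np.asarray(values).ndim == 1 else filled


def interpolate_audiogram(audiogram: Audiogram) -> Audiogram:
    """Linearly fill interior missing thresholds (flanked on both sides)."""
    return Audiogram(
        frequencies_khz=audiogram.frequencies_khz,
        thresholds=interpolate_thresholds(audiogram.thresholds),
        ear=audiogram.ear,
    )


def _pta(freqs_khz: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Row-wise PTA over 0.5/1/2/4 kHz; NaN when any of the four is missing."""
    sel = np.isin(freqs_khz, bisgaard.PTA_FREQUENCIES_KHZ)
    vals = np.atleast_2d(thresholds)[:, sel]
    return vals.mean(axis=1)  # NaN propagates when any is missing


def derive_features(cohort: pd.DataFrame) -> pd.DataFrame:
    """Derive the 20 clustering features for every patient in a raw cohort.

    Audiograms are interpolated first; any feature whose inputs remain
    missing is NaN. The result has columns :data:`FEATURE_NAMES` (plus
    ``true_label`` if present) indexed like the input.
    """
    n = len(cohort)
    ac_khz = np.array(bisgaard.AC_FREQUENCIES_KHZ)
    bc_khz = np.array([f / 1000 for f in synthetic.BC_FREQS_HZ])
    ucl_khz = np.array([f / 1000 for f in synthetic.UCL_FREQS_HZ])

    def grab(prefix: str, ear: str, freqs_hz) -> np.ndarray:
        cols = [f"{prefix}_{ear}_{f}" for f in freqs_hz]
        return interpolate_thresholds(cohort[cols].to_numpy(dtype=float))

    ac = {e: grab("ac", e, synthetic.AC_FREQS_HZ) for e in ("l", "r")}
    bc = {e: grab("bc", e, synthetic.BC_FREQS_HZ) for e in ("l", "r")}
    ucl = {e: grab("ucl", e, synthetic.UCL_FREQS_HZ) for e in ("l", "r")}

    pta = {e: _pta(ac_khz, ac[e]) for e in ("l", "r")}
    # worse ear: higher AC PTA; ties and one-sided missingness -> right
    worse_is_left = pta["l"] > pta["r"]
    worse_is_left &= ~np.isnan(pta["l"]) & ~np.isnan(pta["r"])
    only_left = np.isnan(pta["r"]) & ~np.isnan(pta["l"])
    worse_is_left |= only_left

    def pick(per_ear: dict[str, np.ndarray]) -> np.ndarray:
        left, right = np.asarray(per_ear["l"]), np.asarray(per_ear["r"])
        if left.ndim == 1:
            return np.where(worse_is_left, left, right)
        return np.where(worse_is_left[:, None], left, right)

    ac_pta = pick(pta)
    bc_pta = pick({e: _pta(bc_khz, bc[e]) for e in ("l", "r")})
    ucl_pta = pick({e: _pta(ucl_khz, ucl[e]) for e in ("l", "r")})
    worse_ac = pick(ac)

    bis = np.full(n, np.nan)
    for i in range(n):
        try:
            bis[i], _ = bisgaard.match_standard(ac_khz, worse_ac[i])
        except ValueError:
            pass  # fully missing audiogram -> feature stays missing

    out = pd.DataFrame(index=cohort.index)
    out["ac_pta"] = ac_pta
    out["bc_pta"] = bc_pta
    out["asymmetry"] = np.abs(pta["l"] - pta["r"])
    out["abg"] = ac_pta - bc_pta
    out["ucl_pta"] = ucl_pta
    out["bisgaard_index"] = bis
    for f in ("1500", "4000"):
        l15 = cohort[f"l15_{f}"].to_numpy(dtype=float)
        l35 = cohort[f"l35_{f}"].to_numpy(dtype=float)
        out[f"l15_{f}"] = l15
        out[f"l35_{f}"] = l35
        out[f"l15m35_{f}"] = l15 - l35
    for c in ("goesa_srt", "goesa_slope", "dtt_srt",
              "demtect", "wst", "tinnitus", "ses", "age"):
        out[c] = cohort[c].to_numpy(dtype=float)
    out = out[list(FEATURE_NAMES)]
    if "true_label" in cohort.columns:
        out["true_label"] = cohort["true_label"].to_numpy()
    return out


@dataclass
class ScaledFeatureMatrix:
    """Min–max scaled feature matrix with its missingness mask and bounds."""

    values: pd.DataFrame          # entries in [0, 1] or NaN
    mask: pd.DataFrame            # True where missing
    bounds: pd.DataFrame          # rows 'min'/'max' per feature

    @property
    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


class FeatureScaler(TransformerMixin, BaseEstimator):
    """Min–max scaler to [0, 1] that tolerates and preserves missing cells.

    Bounds are learned on the fit rows ignoring NaNs; transform clamps
    values outside the fit range to [0, 1]. A feature that is constant on
    the fit rows scales to 0 (with a warning). Ordinal features are assumed
    already integer-coded.
    """

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        lo = X.min(axis=0, skipna=True)
        hi = X.max(axis=0, skipna=True)
        constant = (hi - lo) <= 0
        if constant.any():
            warnings.warn(
                "constant feature(s) scaled to 0: "
                + ", ".join(map(str, X.columns[constant])),
                stacklevel=2,
            )
        self.feature_names_in_ = np.asarray(X.columns)
        self.min_ = lo.to_numpy(dtype=float)
        self.max_ = hi.to_numpy(dtype=float)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X)[list(self.feature_names_in_)]
        span = self.max_ - self.min_
        safe = np.where(span > 0, span, 1.0)
        vals = (X.to_numpy(dtype=float) - self.min_) / safe
        vals = np.where(span > 0, vals, 0.0)
        with np.errstate(invalid="ignore"):
            vals = np.clip(vals, 0.0, 1.0)
        return pd.DataFrame(vals, index=X.index, columns=X.columns)

    def inverse_transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X)[list(self.feature_names_in_)]
        span = np.where(self.max_ - self.min_ > 0, self.max_ - self.min_, 0.0)
        vals = X.to_numpy(dtype=float) * span + self.min_
        return pd.DataFrame(vals, index=X.index, columns=X.columns)

    def bounds_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"min": self.min_, "max": self.max_}, index=self.feature_names_in_
        ).T


def encode_and_scale(
    features: pd.DataFrame, fit_rows: np.ndarray | None = None
) -> tuple[ScaledFeatureMatrix, FeatureScaler]:
    """Scale a derived-feature table to [0, 1], learning bounds on ``fit_rows``.

    Returns the scaled matrix (missing cells preserved as NaN) and the fitted
    scaler for reuse on new rows.
    """
    cols = [c for c in features.columns if c != "true_label"]
    table = features[cols]
    fit_table = table if fit_rows is None else table.iloc[fit_rows]
    if len(fit_table) == 0:
        raise ValueError("fit_rows must be nonempty")
    scaler = FeatureScaler().fit(fit_table)
    scaled = scaler.transform(table)
    return (
        ScaledFeatureMatrix(values=scaled, mask=scaled.isna(), bounds=scaler.bounds_frame()),
        scaler,
    )
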