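"""Synthetic audiological cohorts with known cluster structure.

The restricted clinical dataset behind the original profile study cannot be
shared, so this module generates cohorts that emulate its *structure*: raw
per-ear audiometric measurements, loudness scaling, speech tests, cognitive
and anamnesis variables, from which the 20 clustering features can be
derived.  Patients are drawn per cluster from a Gaussian on a latent feature
space and back-transformed to raw measurements so that the derived features
recover the latent values (up to rounding and the linear dependencies among
features, e.g. ABG = AC PTA − BC PTA).

The generator is a test fixture with controllable separation, covariance
style and missingness — not a claim about the clinical population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bisgaard
from ._seeds import rng_from
from .mixture import MixtureParams

# ---------------------------------------------------------------------------
# column dictionary

EARS = ("l", "r")
AC_FREQS_HZ = tuple(int(f * 1000) for f in bisgaard.AC_FREQUENCIES_KHZ)
BC_FREQS_HZ = (500, 1000, 2000, 4000)
UCL_FREQS_HZ = (500, 1000, 2000, 4000)

AC_COLUMNS = tuple(f"ac_{e}_{f}" for e in EARS for f in AC_FREQS_HZ)
BC_COLUMNS = tuple(f"bc_{e}_{f}" for e in EARS for f in BC_FREQS_HZ)
UCL_COLUMNS = tuple(f"ucl_{e}_{f}" for e in EARS for f in UCL_FREQS_HZ)
ACALOS_COLUMNS = ("l15_1500", "l35_1500", "l15_4000", "l35_4000")
SCALAR_COLUMNS = (
    "goesa_srt", "goesa_slope", "dtt_srt",
    "demtect", "wst", "tinnitus", "ses", "age",
)

#: Every measurement-bearing column (missingness may be injected here).
MEASUREMENT_COLUMNS = AC_COLUMNS + BC_COLUMNS + UCL_COLUMNS + ACALOS_COLUMNS + SCALAR_COLUMNS

#: Latent feature dimensions used to lay out cluster means (order matters:
#: it matches the clustering feature order of the feature-derivation stage).
LATENT_FEATURES = (
    "ac_pta", "bc_pta", "asymmetry", "abg", "ucl_pta", "bisgaard_index",
    "l15_1500", "l35_1500", "l15m35_1500",
    "l15_4000", "l35_4000", "l15m35_4000",
    "goesa_srt", "goesa_slope", "dtt_srt",
    "demtect", "wst", "tinnitus", "ses", "age",
)

# per-feature (location, scale) mapping from the standardized latent space
# to clinical units; chosen to span normal to severely impaired hearing
_FEATURE_BASE = {
    "ac_pta": (42.0, 10.0), "bc_pta": (30.0, 10.0),
    "asymmetry": (8.0, 4.0), "abg": (14.0, 10.0),
    "ucl_pta": (100.0, 7.0), "bisgaard_index": (5.0, 2.0),
    "l15_1500": (35.0, 9.0), "l35_1500": (75.0, 9.0), "l15m35_1500": (-40.0, 6.0),
    "l15_4000": (45.0, 9.0), "l35_4000": (85.0, 9.0), "l15m35_4000": (-40.0, 6.0),
    "goesa_srt": (-3.5, 2.5), "goesa_slope": (14.0, 4.0), "dtt_srt": (-7.0, 2.0),
    "demtect": (13.0, 3.0), "wst": (30.0, 5.0), "tinnitus": (1.8, 0.8),
    "ses": (12.0, 4.0), "age": (66.0, 10.0),
}

_COVARIANCE_STYLES = ("spherical", "diagonal-equal-shape", "diagonal-free")

#: Latent dimensions that carry the between-cluster mean separation.
_SEPARATION_FEATURES = (
    "ac_pta", "abg", "ucl_pta",
    "l15_1500", "l35_1500", "l15_4000", "l35_4000",
    "goesa_srt", "goesa_slope", "dtt_srt",
    "demtect", "wst", "ses", "age",
)


@dataclass
class CohortSpec:
    """Specification of a synthetic cohort.

    ``separation`` is the pairwise distance between cluster means in units
    of the within-cluster standard deviation on the latent feature space.
    ``missing_rate`` is the per-cell probability of masking a measurement
    (missing completely at random); the clinical dataset the generator
    emulates had on average 1.5% missing cells with a maximum of 2.5%.
    """

    n_patients: int
    n_clusters: int = 1
    cluster_weights: np.ndarray | None = None
    separation: float = 5.0
    missing_rate: float = 0.015
    covariance_style: str = "diagonal-equal-shape"
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < self.n_clusters or self.n_patients <= 0:
            raise ValueError("need n_patients >= n_clusters >= 1")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if not (0.0 <= self.missing_rate <= 0.05):
            raise ValueError("missing_rate must lie in [0, 0.05]")
        if self.covariance_style not in _COVARIANCE_STYLES:
            raise ValueError(f"covariance_style must be one of {_COVARIANCE_STYLES}")
        if self.cluster_weights is None:
            self.cluster_weights = np.full(self.n_clusters, 1.0 / self.n_clusters)
        self.cluster_weights = np.asarray(self.cluster_weights, dtype=float)
        if self.cluster_weights.shape != (self.n_clusters,) or np.any(self.cluster_weights < 0):
            raise ValueError("cluster_weights must be a nonnegative vector of length n_clusters")
        if abs(self.cluster_weights.sum() - 1.0) > 1e-12:
            raise ValueError("cluster_weights must sum to 1 within 1e-12")


def _simplex_vertices(k: int, d: int) -> np.ndarray:
    """k centered points in R^d with unit pairwise distance (k <= d + 1)."""
    if k == 1:
        return np.zeros((1, d))
    if k > d + 1:
        raise ValueError(f"cannot place {k} equidistant means in {d} dimensions")
    v = np.eye(k, d)
    v -= v.mean(axis=0)
    return v / np.sqrt(2.0)  # edge length of e_i - e_j is sqrt(2)


def _latent_sds(style: str, k: int, d: int, rng: np.random.Generator) -> np.ndarray:
    """Per-cluster per-dimension latent SDs, shape (k, d), mean variance ~1."""
    if style == "spherical":
        return np.ones((k, d))
    if style == "diagonal-equal-shape":
        # shared shape (det 1), per-cluster volume varying
        shape = np.exp(np.linspace(-0.4, 0.4, d))
        shape /= np.exp(np.mean(np.log(shape)))
        vols = np.exp(np.linspace(-0.2, 0.2, k)) if k > 1 else np.ones(1)
        return np.sqrt(vols[:, None] * shape[None, :])
    # diagonal-free
    return np.exp(rng.normal(0.0, 0.25, size=(k, d)))


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a raw cohort table from a CohortSpec, with ``true_label`` column.

    Cluster means sit at the vertices of a regular simplex in the latent
    space, scaled so pairwise distances equal ``spec.separation`` within-
    cluster SDs; each cluster gets a base standard-audiogram shape matched
    to its mean PTA, and raw measurements are reconstructed so the derived
    clustering features recover the latent draws.
    """
    rng = rng_from(spec.seed, 0)
    d = len(LATENT_FEATURES)
    k = spec.n_clusters
    # cluster separation lives on the continuous measures that the raw
    # back-transform reproduces faithfully; coarsely discretized (tinnitus,
    # Bisgaard) and derived (BC PTA, L15-L35) features stay at their base
    # means, as rounding/derivation would erode a separation placed there
    sep_dims = np.array([LATENT_FEATURES.index(f) for f in _SEPARATION_FEATURES])
    means_std = np.zeros((k, d))
    simplex = _simplex_vertices(k, len(sep_dims)) * spec.separation
    # distance-preserving rotation spreads the layout over those dimensions
    rot, _ = np.linalg.qr(rng.normal(size=(len(sep_dims), len(sep_dims))))
    sds = _latent_sds(spec.covariance_style, k, d, rng)
    # scale offsets by the average within-cluster SD per dimension so the
    # pairwise Mahalanobis separation equals spec.separation
    sd_avg = np.sqrt(np.mean(sds**2, axis=0))
    means_std[:, sep_dims] = (simplex @ rot.T) * sd_avg[sep_dims]

    labels = rng.choice(k, size=spec.n_patients, p=spec.cluster_weights)
    z = means_std[labels] + rng.normal(size=(spec.n_patients, d)) * sds[labels]

    feat = {}
    for j, name in enumerate(LATENT_FEATURES):
        base, scale = _FEATURE_BASE[name]
        feat[name] = base + scale * z[:, j]

    # hard physical/ordinal constraints on the latent draws
    feat["asymmetry"] = np.abs(feat["asymmetry"])
    feat["abg"] = np.clip(feat["abg"], 0.0, None)
    for f in ("l15_1500", "l15_4000"):
        hi = feat[f.replace("l15", "l35")]
        feat[f.replace("l15", "l35")] = np.maximum(hi, feat[f] + 1.0)
    # cluster-level PTA–SRT coupling: profiles with more hearing loss sit at
    # higher SRT (affine in the cluster's mean PTA, offsets and noise from
    # the SRT latent itself, keeping within-cluster covariances diagonal)
    cluster_pta_shift = _FEATURE_BASE["ac_pta"][1] * means_std[:, 0]
    feat["goesa_srt"] = feat["goesa_srt"] + 0.08 * cluster_pta_shift[labels]
    feat["goesa_slope"] = np.clip(feat["goesa_slope"], 1.0, None)
    feat["age"] = np.clip(feat["age"], 18.0, 105.0)

    n = spec.n_patients
    cols: dict[str, np.ndarray] = {"id": np.arange(n)}

    # audiograms: per-cluster base shape from the standard nearest the
    # cluster's mean PTA; per-frequency jitter centered over the PTA
    # frequencies so the derived PTA equals the latent value exactly
    ac_khz = np.array(bisgaard.AC_FREQUENCIES_KHZ)
    pta_mask = np.isin(ac_khz, bisgaard.PTA_FREQUENCIES_KHZ)
    cluster_mean_pta = _FEATURE_BASE["ac_pta"][0] + _FEATURE_BASE["ac_pta"][1] * means_std[:, 0]
    shapes = np.empty((k, len(ac_khz)))
    for g in range(k):
        std_name = bisgaard.nearest_standard_by_pta(float(cluster_mean_pta[g]))
        std = np.asarray(bisgaard.STANDARD_AUDIOGRAMS[std_name], dtype=float)
        shapes[g] = std - std[pta_mask].mean()

    def _centered_jitter(sd: float, nfreq: int, mask: np.ndarray) -> np.ndarray:
        jit = rng.normal(0.0, sd, size=(n, nfreq))
        return jit - jit[:, mask].mean(axis=1, keepdims=True)

    pta_r = feat["ac_pta"]                    # right = worse ear by construction
    pta_l = feat["ac_pta"] - feat["asymmetry"]
    for ear, pta in (("r", pta_r), ("l", pta_l)):
        thr = shapes[labels] + pta[:, None] + _centered_jitter(3.0, len(ac_khz), pta_mask)
        thr = np.round(np.clip(thr, -10.0, 120.0), 1)
        for j, f in enumerate(AC_FREQS_HZ):
            cols[f"ac_{ear}_{f}"] = thr[:, j]

    bc_mask = np.ones(len(BC_FREQS_HZ), dtype=bool)
    for ear, pta in (("r", pta_r), ("l", pta_l)):
        bc_pta = pta - feat["abg"]
        thr = bc_pta[:, None] + _centered_jitter(2.0, len(BC_FREQS_HZ), bc_mask)
        thr = np.round(np.clip(thr, -10.0, 120.0), 1)
        for j, f in enumerate(BC_FREQS_HZ):
            cols[f"bc_{ear}_{f}"] = thr[:, j]

    for ear in EARS:
        thr = feat["ucl_pta"][:, None] + _centered_jitter(3.0, len(UCL_FREQS_HZ), bc_mask)
        thr = np.round(np.clip(thr, -10.0, 120.0), 1)
        for j, f in enumerate(UCL_FREQS_HZ):
            cols[f"ucl_{ear}_{f}"] = thr[:, j]

    for c, f in zip(ACALOS_COLUMNS, ("l15_1500", "l35_1500", "l15_4000", "l35_4000")):
        cols[c] = np.round(feat[f], 1)
    cols["goesa_srt"] = np.round(feat["goesa_srt"], 2)
    cols["goesa_slope"] = np.round(feat["goesa_slope"], 2)
    cols["dtt_srt"] = np.round(feat["dtt_srt"], 2)
    cols["demtect"] = np.clip(np.round(feat["demtect"]), 0, 18).astype(float)
    cols["wst"] = np.clip(np.round(feat["wst"]), 0, 42).astype(float)
    cols["tinnitus"] = np.clip(np.round(feat["tinnitus"]), 1, 3).astype(float)
    cols["ses"] = np.clip(np.round(feat["ses"]), 3, 21).astype(float)
    cols["age"] = np.round(feat["age"], 1)

    cohort = pd.DataFrame(cols)
    cohort["true_label"] = labels
    if spec.missing_rate > 0:
        cohort = inject_missingness(cohort, spec.missing_rate, seed=spec.seed)
    return cohort


def inject_missingness(cohort: pd.DataFrame, rate: float, seed: int) -> pd.DataFrame:
    """Mask measurement cells independently with probability ``rate`` (MCAR).

    ``id`` and ``true_label`` are never masked; the mask is reproducible
    for a fixed seed. ``rate`` must lie in [0, 1).
    """
    if not (0.0 <= rate < 1.0):
        raise ValueError("rate must lie in [0, 1)")
    out = cohort.copy()
    if rate == 0.0:
        return out
    rng = rng_from(seed, 1)
    cols = [c for c in MEASUREMENT_COLUMNS if c in out.columns]
    mask = rng.random((len(out), len(cols))) < rate
    vals = out[cols].to_numpy(dtype=float)
    vals[mask] = np.nan
    out[cols] = vals
    return out


# ---------------------------------------------------------------------------
# direct mixture sampler (latent-space fixtures for the clustering engine)


@dataclass
class MixtureSample:
    X: np.ndarray
    labels: np.ndarray
    params: MixtureParams = field(repr=False, default=None)


def sample_mixture(
    n: int,
    d: int,
    k: int,
    model: str = "VEI",
    separation: float = 5.0,
    weights: np.ndarray | None = None,
    seed: int = 0,
) -> MixtureSample:
    """Draw from a constrained Gaussian mixture with known parameters.

    Cluster means sit on a regular simplex with pairwise distance
    ``separation`` times the average per-dimension SD. For VEI the shared
    shape is a fixed geometric ramp (det 1) and volumes vary across
    clusters, so volume/shape recovery can be checked against truth.
    """
    rng = rng_from(seed, 2)
    if weights is None:
        weights = np.full(k, 1.0 / k)
    weights = np.asarray(weights, dtype=float)

    shape = np.exp(np.linspace(-0.5, 0.5, d))
    shape /= np.exp(np.mean(np.log(shape)))
    if model == "EII":
        vols = np.ones(k)
        sigma2 = np.ones((k, d))
    elif model == "VII":
        vols = np.exp(np.linspace(-0.5, 0.5, k))
        sigma2 = np.repeat(vols[:, None], d, axis=1)
    elif model == "EEI":
        vols = np.ones(k)
        sigma2 = np.repeat(shape[None], k, axis=0)
    elif model == "VEI":
        vols = np.exp(np.linspace(-0.5, 0.5, k)) if k > 1 else np.ones(1)
        sigma2 = vols[:, None] * shape[None, :]
    elif model == "EVI":
        vols = np.ones(k)
        sigma2 = np.stack([np.roll(shape, g) for g in range(k)])
    elif model == "VVI":
        vols = np.exp(np.linspace(-0.5, 0.5, k)) if k > 1 else np.ones(1)
        sigma2 = vols[:, None] * np.stack([np.roll(shape, g) for g in range(k)])
    elif model in ("EEE", "VVV"):
        rho = 0.3
        base = rho + (1 - rho) * np.eye(d)
        if model == "EEE":
            covs = np.repeat(base[None], k, axis=0)
        else:
            scales = np.exp(np.linspace(-0.4, 0.4, k)) if k > 1 else np.ones(1)
            rhos = np.linspace(0.1, 0.5, k) if k > 1 else np.array([rho])
            covs = np.stack([
                s * (r + (1 - r) * np.eye(d)) for s, r in zip(scales, rhos)
            ])
        sd_bar = float(np.sqrt(np.mean([np.mean(np.diag(c)) for c in covs])))
        means = _simplex_vertices(k, d) * separation * sd_bar
        labels = rng.choice(k, size=n, p=weights)
        chol = np.stack([np.linalg.cholesky(c) for c in covs])
        X = means[labels] + np.einsum("nij,nj->ni", chol[labels], rng.normal(size=(n, d)))
        params = MixtureParams(model=model, weights=weights,
                               means=means, cov_full=covs)
        return MixtureSample(X=X, labels=labels, params=params)
    else:
        raise ValueError(f"unknown covariance model {model!r}")

    sd_bar = float(np.sqrt(np.mean(sigma2)))
    means = _simplex_vertices(k, d) * separation * sd_bar
    labels = rng.choice(k, size=n, p=weights)
    X = means[labels] + rng.normal(size=(n, d)) * np.sqrt(sigma2[labels])
    params = MixtureParams(
        model=model, weights=weights, means=means,
        sigma2=sigma2, volumes=vols,
        shapes=sigma2 / np.exp(np.mean(np.log(sigma2), axis=1))[:, None],
    )
    return MixtureSample(X=X, labels=labels, params=params)


def mask_mcar(X: np.ndarray, rate: float, seed: int) -> np.ndarray:
    """Return a copy of ``X`` with cells set to NaN independently at ``rate``."""
    rng = rng_from(seed, 3)
    out = np.array(X, dtype=float, copy=True)
    out[rng.random(out.shape) < rate] = np.nan
    return out


# ---------------------------------------------------------------------------
# cohort I/O (delimited text; empty string = missing)


def write_cohort(cohort: pd.DataFrame, path, labels_path=None) -> None:
    """Write the cohort as CSV; true labels optionally to a side file."""
    table = cohort
    if labels_path is not None and "true_label" in cohort.columns:
        cohort[["id", "true_label"]].to_csv(labels_path, index=False)
        table = cohort.drop(columns=["true_label"])
    table.to_csv(path, index=False, na_rep="")


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort`."""
    return pd.read_csv(path)
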