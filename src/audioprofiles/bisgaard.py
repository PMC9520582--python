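"""The ten Bisgaard standard audiograms, packaged as constants.

The standards (N1–N7 flat/moderately sloping, S1–S3 steeply sloping) are
canonical air-conduction audiogram shapes used to discretize audiogram
patterns into a single ordinal feature.  Threshold values follow the
published reference at 0.25–6 kHz; the reference does not tabulate 8 kHz,
so the 6 kHz value is carried flat to 8 kHz.

For the ordinal encoding the standards are ordered by ascending pure-tone
average (mean threshold at 0.5, 1, 2 and 4 kHz); N4 and S3 tie at
PTA = 62.5 dB HL and keep the reference's N-before-S listing order.
"""

from __future__ import annotations

import numpy as np

#: Audiogram frequencies used throughout the package (kHz).
AC_FREQUENCIES_KHZ = (0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0)
PTA_FREQUENCIES_KHZ = (0.5, 1.0, 2.0, 4.0)

#: dB HL thresholds per standard at AC_FREQUENCIES_KHZ.
STANDARD_AUDIOGRAMS: dict[str, tuple[float, ...]] = {
    "N1": (10, 10, 10, 10, 15, 20, 30, 40, 40),
    "N2": (20, 20, 25, 30, 35, 40, 45, 50, 50),
    "N3": (35, 35, 40, 45, 50, 55, 60, 65, 65),
    "N4": (55, 55, 55, 60, 65, 70, 75, 80, 80),
    "N5": (65, 70, 75, 80, 80, 80, 80, 80, 80),
    "N6": (75, 80, 85, 90, 90, 95, 100, 100, 100),
    "N7": (90, 95, 105, 105, 105, 105, 105, 105, 105),
    "S1": (10, 10, 10, 10, 15, 30, 55, 70, 70),
    "S2": (20, 20, 25, 35, 55, 75, 95, 95, 95),
    "S3": (30, 35, 60, 70, 75, 80, 80, 85, 85),
}


def standard_pta(name: str) -> float:
    """PTA (0.5/1/2/4 kHz) of one standard audiogram."""
    thr = dict(zip(AC_FREQUENCIES_KHZ, STANDARD_AUDIOGRAMS[name]))
    return float(np.mean([thr[f] for f in PTA_FREQUENCIES_KHZ]))


def _ordered_names() -> list[str]:
    # stable sort keeps the reference's N-before-S order on the N4/S3 PTA tie
    return sorted(STANDARD_AUDIOGRAMS, key=standard_pta)


#: Standards in ascending-PTA order; ordinal index = position + 1 (1..10).
ORDERED_STANDARDS: tuple[str, ...] = tuple(_ordered_names())

#: name -> ordinal index 1..10
ORDINAL_INDEX: dict[str, int] = {n: i + 1 for i, n in enumerate(ORDERED_STANDARDS)}


def match_standard(
    frequencies_khz: np.ndarray, thresholds: np.ndarray
) -> tuple[int, str]:
    """Ordinal index and name of the standard nearest a measured audiogram.

    Distance is the RMS difference over the frequencies shared between the
    measured audiogram (missing thresholds excluded) and the standard grid;
    ties go to the lower ordinal index.

    Raises ``ValueError`` when no measured frequency lies on the grid.
    """
    frequencies_khz = np.asarray(frequencies_khz, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    grid = {f: j for j, f in enumerate(AC_FREQUENCIES_KHZ)}
    obs = [
        (grid[f], t)
        for f, t in zip(frequencies_khz, thresholds)
        if f in grid and np.isfinite(t)
    ]
    if not obs:
        raise ValueError("no overlapping frequencies for standard-audiogram matching")
    idx = np.array([j for j, _ in obs])
    vals = np.array([t for _, t in obs])
    best: tuple[float, int] | None = None
    for name in ORDERED_STANDARDS:
        std = np.asarray(STANDARD_AUDIOGRAMS[name], dtype=float)[idx]
        rms = float(np.sqrt(np.mean((std - vals) ** 2)))
        key = (rms, ORDINAL_INDEX[name])
        if best is None or key < best:
            best = key
            chosen = name
    return ORDINAL_INDEX[chosen], chosen


def nearest_standard_by_pta(pta: float) -> str:
    """The standard whose PTA is closest to ``pta`` (ties: lower index)."""
    return min(ORDERED_STANDARDS, key=lambda n: (abs(standard_pta(n) - pta), ORDINAL_INDEX[n]))
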