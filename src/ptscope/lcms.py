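"""Absolute PT dinucleotide quantification from LC-MS peak tables.

The targeted assay injects a nuclease-P1/phosphatase limit digest: canonical
2'-deoxyribonucleosides are quantified from their UV absorbance at 260 nm,
PT dinucleotides from their MRM signal.  External calibration with synthetic
standards gives a response factor (signal area per pmol) per analyte and
channel; absolute PT levels are then expressed per 10^6 nucleotides by
normalizing to the total injected canonical nucleoside pool.

Peak-quality triage ("distinct peak shape" in manual review) is implemented
programmatically: a signal-to-noise threshold plus a retention-time match
against the analyte's reference window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default programmatic surrogate for manual peak-shape review.
DEFAULT_SN_THRESHOLD = 3.0
DEFAULT_RT_TOLERANCE_MIN = 0.2

CANONICAL = ("dA", "dC", "dG", "dT")


@dataclass(frozen=True)
class CalibrationCurve:
    """Response factor (area per pmol) for one analyte on one channel."""

    analyte: str
    channel: str            # "MS" or "UV260"
    response_factor: float  # slope of area on pmol, through the origin
    r_squared: float = float("nan")
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.response_factor <= 0:
            raise ValueError("response factor must be positive")


@dataclass(frozen=True)
class ChromPeak:
    """One integrated chromatographic peak."""

    analyte: str
    rt_min: float
    area: float
    channel: str = "MS"
    snr: float = float("inf")

    def __post_init__(self) -> None:
        if self.area < 0 or self.rt_min < 0:
            raise ValueError("peak area and retention time must be >= 0")


@dataclass
class PTProfile:
    """PT dinucleotide levels in units per 10^6 nucleotides."""

    levels: dict[str, float]
    sample_id: str = ""

    def __post_init__(self) -> None:
        for label, level in self.levels.items():
            if level < 0:
                raise ValueError(f"negative level for {label}")

    @property
    def total(self) -> float:
        return float(sum(self.levels.values()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "dinucleotide": list(self.levels),
                "level_per_1e6": list(self.levels.values()),
            }
        )


def fit_response_factor(
    points: list[tuple[float, float]],
    analyte: str,
    channel: str = "MS",
    allow_single_point: bool = False,
) -> CalibrationCurve:
    """Least-squares response factor through the origin.

    ``points`` are (pmol, area) pairs from a dilution series of the synthetic
    standard.  The fit is constrained through the origin (blank-subtracted
    areas; zero analyte gives zero signal), so RF = sum(x*y)/sum(x^2).
    """
    x = np.asarray([p for p, _ in points], dtype=float)
    y = np.asarray([a for _, a in points], dtype=float)
    if np.any(x < 0):
        raise ValueError("pmol amounts must be >= 0")
    if len(np.unique(x[x > 0])) < 1 or np.sum(x**2) == 0:
        raise ValueError("calibration needs at least one nonzero pmol point")
    if len(points) < 2 and not allow_single_point:
        raise ValueError("calibration needs >= 2 points (or allow_single_point)")
    rf = float(np.sum(x * y) / np.sum(x * x))
    ss_res = float(np.sum((y - rf * x) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 and ss_res == 0 else 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return CalibrationCurve(analyte, channel, rf, r2, len(points))


def _rt_ok(peak: ChromPeak, window: tuple[float, float] | None, tol: float) -> bool:
    if window is None:
        return True
    lo, hi = window
    return (lo - tol) <= peak.rt_min <= (hi + tol)


def quantify_peaks(
    peaks: list[ChromPeak],
    curves: dict[tuple[str, str], CalibrationCurve] | dict[str, CalibrationCurve],
    sn_threshold: float = DEFAULT_SN_THRESHOLD,
    rt_tolerance_min: float = DEFAULT_RT_TOLERANCE_MIN,
    rt_windows: dict[str, tuple[float, float]] | None = None,
) -> dict[str, float]:
    """Convert retained peaks to pmol via their response factors.

    Peaks failing the S/N threshold or falling outside the analyte's
    retention window (within ``rt_tolerance_min``) are excluded and logged.
    A retained peak without a calibration curve is an error.  Multiple
    retained peaks of one analyte are summed.
    """
    out: dict[str, float] = {}
    for peak in peaks:
        if peak.snr < sn_threshold:
            logger.info("excluded %s peak: S/N %.2f < %.2f", peak.analyte, peak.snr, sn_threshold)
            continue
        window = (rt_windows or {}).get(peak.analyte)
        if not _rt_ok(peak, window, rt_tolerance_min):
            logger.info("excluded %s peak: RT %.2f outside %s", peak.analyte, peak.rt_min, window)
            continue
        key = (peak.analyte, peak.channel)
        curve = curves.get(key) if key in curves else curves.get(peak.analyte)
        if curve is None:
            raise KeyError(f"no calibration curve for {peak.analyte} ({peak.channel})")
        out[peak.analyte] = out.get(peak.analyte, 0.0) + peak.area / curve.response_factor
    return out


def pt_levels_per_million(
    pt_pmol: dict[str, float],
    canonical_pmol: dict[str, float],
    sample_id: str = "",
) -> PTProfile:
    """PT levels per 10^6 nucleotides from injected amounts.

    Each PT dinucleotide carries one PT linkage; the denominator is the
    total canonical nucleoside pool estimated from UV-260 (dinucleotide
    nucleotides, <= ~1e-4 of the total, are neglected).
    """
    total = float(sum(canonical_pmol.get(c, 0.0) for c in CANONICAL))
    if total <= 0:
        raise ValueError("total canonical nucleoside pmol must be positive")
    levels = {d: 1e6 * p / total for d, p in pt_pmol.items()}
    return PTProfile(levels, sample_id=sample_id)


def merge_coeluting(
    profile: PTProfile, groups: list[set[str] | frozenset[str]]
) -> PTProfile:
    """Sum chromatographically unresolved analytes under a joined label.

    E.g. A*G and G*A co-elute and are reported as "G*A/A*G".  Groups must
    not overlap; absent members contribute zero; labels outside any group
    pass through unchanged.  Total level is conserved exactly.
    """
    seen: set[str] = set()
    for grp in groups:
        if seen & set(grp):
            raise ValueError("overlapping merge groups")
        seen |= set(grp)
    levels = {d: v for d, v in profile.levels.items() if d not in seen}
    for grp in groups:
        present = [d for d in profile.levels if d in grp]
        if not present:
            continue
        label = "/".join(sorted(grp, reverse=True))
        levels[label] = sum(profile.levels[d] for d in present)
    return PTProfile(levels, sample_id=profile.sample_id)


def estimate_pt_fraction(
    profile: PTProfile, per_genome_density: float = 100.0
) -> dict[str, float]:
    """Fraction of the community carrying each PT class, plus "total".

    Individual PT-positive genomes carry roughly one PT per 10^4 nt (100 per
    10^6); a community-wide level of L per 10^6 therefore implies a fraction
    L / density of microbes carrying that mark, assuming each dinucleotide
    class tags a distinct genome class.  Fractions are capped at 1.
    """
    if per_genome_density <= 0:
        raise ValueError("per_genome_density must be positive")
    out: dict[str, float] = {}
    for d, level in profile.levels.items():
        frac = level / per_genome_density
        if frac > 1.0:
            logger.warning("%s fraction %.2f capped at 1.0", d, frac)
            frac = 1.0
        out[d] = frac
    out["total"] = min(1.0, profile.total / per_genome_density)
    return out


def load_lod_table() -> dict[str, float]:
    """Packaged per-dinucleotide limits of detection (per 10^6 nt)."""
    with resources.files("ptscope.data").joinpath("lcms_lod.csv").open() as fh:
        df = pd.read_csv(fh, comment="#")
    return dict(zip(df["dinucleotide"], df["lod_level_per_1e6"]))


def read_peak_table(path) -> list[ChromPeak]:
    """Read a peak CSV (sample_id, analyte, channel, rt_min, area, snr)."""
    df = pd.read_csv(path)
    return [
        ChromPeak(r.analyte, r.rt_min, r.area, r.channel, r.snr)
        for r in df.itertuples()
    ]
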