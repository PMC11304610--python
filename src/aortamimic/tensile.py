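"""Uniaxial tensile-test analysis for printed tissue-mimicking samples.

Implements the processing flow used for the printed-sample characterisation:
engineering stress/strain from load and clamp displacement, trimming of the
conditioning cycles, interpolation of all samples onto a common grid,
downsampling and zero-phase Butterworth low-pass filtering, averaging,
incremental elastic modulus via central differences, secant modulus, and
per-model summary statistics with one-tailed Welch t-tests.

Stress is in MPa (N / mm^2), strain is dimensionless internally and reported
as percent externally.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

__all__ = [
    "SpecimenGeometry",
    "TestProtocol",
    "TensileRecord",
    "StressStrainCurve",
    "IncrementalModulusCurve",
    "TensileSummary",
    "TTestResult",
    "read_tensile_csv",
    "write_tensile_csv",
    "compute_stress_strain",
    "align_curves",
    "filter_pipeline",
    "incremental_modulus",
    "secant_modulus",
    "summarize",
    "one_tailed_t_test",
    "classify_relation",
    "analyze_batch",
]

SAMPLING_HZ = 100.0
DOWNSAMPLE = 10
CUTOFF_HZ = 0.1
FILTER_ORDER = 2
WINDOW = (0.15, 0.90)
ALPHA = 0.05


@dataclass(frozen=True)
class SpecimenGeometry:
    """Measured specimen dimensions.

    Thickness is the average of five measurements taken at the stretching
    area; the initial cross-section A0 = width x mean thickness.
    """

    width: float
    thickness_measurements: tuple[float, ...]
    gauge_length: float

    def __post_init__(self):
        tm = tuple(float(t) for t in self.thickness_measurements)
        if len(tm) != 5:
            raise ValueError("exactly five thickness measurements are required")
        object.__setattr__(self, "thickness_measurements", tm)
        if self.width <= 0 or self.gauge_length <= 0 or min(tm) <= 0:
            raise ValueError("specimen dimensions must be positive")

    @property
    def thickness(self) -> float:
        return float(np.mean(self.thickness_measurements))

    @property
    def area(self) -> float:
        """Initial cross-sectional area A0 in mm^2."""
        return self.width * self.thickness


@dataclass(frozen=True)
class TestProtocol:
    """Instrument protocol: constant-rate stretch to rupture."""

    strain_rate_mm_per_min: float = 10.0
    sampling_hz: float = SAMPLING_HZ
    preload_mpa: float = 0.02
    conditioning_cycles: int = 3
    cycle_load_max_n: float = 1.0

    def __post_init__(self):
        if self.strain_rate_mm_per_min <= 0 or self.sampling_hz <= 0:
            raise ValueError("protocol rates must be positive")


@dataclass
class TensileRecord:
    """Raw time series of one tensile test plus specimen geometry."""

    time: np.ndarray
    load: np.ndarray
    displacement: np.ndarray
    geometry: SpecimenGeometry
    model_id: str = "sample"
    protocol: TestProtocol = field(default_factory=TestProtocol)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.load = np.asarray(self.load, dtype=float)
        self.displacement = np.asarray(self.displacement, dtype=float)
        n = len(self.time)
        if len(self.load) != n or len(self.displacement) != n:
            raise ValueError("time, load and displacement must have equal length")
        if n >= 2:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                raise ValueError("time must be strictly increasing")

    @property
    def sampling_hz(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time)))


@dataclass
class StressStrainCurve:
    """Engineering stress (MPa) against engineering strain (dimensionless)."""

    strain: np.ndarray
    stress: np.ndarray
    model_id: str = "sample"

    def __post_init__(self):
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if len(self.strain) != len(self.stress):
            raise ValueError("strain and stress must have equal length")

    def __len__(self) -> int:
        return len(self.strain)


@dataclass
class IncrementalModulusCurve:
    """Local slope d(sigma)/d(epsilon) of the averaged curve, in MPa."""

    strain: np.ndarray
    modulus: np.ndarray
    window: tuple[float, float] = WINDOW


@dataclass
class TensileSummary:
    """Per-model max stress and strain at max stress as mu +/- sigma."""

    model_id: str
    n: int
    max_stress_mean: float
    max_stress_sd: float
    strain_at_max_mean_pct: float
    strain_at_max_sd_pct: float
    secant_modulus_mpa: float | None = None

    @property
    def cov_stress(self) -> float:
        return self.max_stress_sd / self.max_stress_mean

    @property
    def cov_strain(self) -> float:
        return self.strain_at_max_sd_pct / self.strain_at_max_mean_pct


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    df: float
    reject: bool
    direction: str


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------
# File layout: a '#'-prefixed key: value header block (model_id, width_mm,
# thickness_mm as five comma-separated values, gauge_length_mm) followed by
# columns time_s, load_N, displacement_mm.


def write_tensile_csv(record: TensileRecord, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# model_id: {record.model_id}\n")
        fh.write(f"# width_mm: {record.geometry.width:.6g}\n")
        tms = ",".join(f"{t:.6g}" for t in record.geometry.thickness_measurements)
        fh.write(f"# thickness_mm: {tms}\n")
        fh.write(f"# gauge_length_mm: {record.geometry.gauge_length:.6g}\n")
        fh.write("time_s,load_N,displacement_mm\n")
        np.savetxt(
            fh,
            np.column_stack([record.time, record.load, record.displacement]),
            delimiter=",",
            fmt="%.9g",
        )
    return path


def read_tensile_csv(path) -> list[TensileRecord]:
    """Read one instrument export; returns a (length-1) list of records.

    A non-uniform or off-nominal time base triggers a warning and linear
    resampling to 100 Hz; a missing geometry header is a hard error.
    """
    path = Path(path)
    header: dict[str, str] = {}
    body = io.StringIO()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, val = line.lstrip("#").partition(":")
                header[key.strip()] = val.strip()
            else:
                body.write(line)
    body.seek(0)
    required = {"width_mm", "thickness_mm", "gauge_length_mm"}
    if not required.issubset(header):
        raise ValueError(f"{path}: missing geometry header keys {required - set(header)}")
    geometry = SpecimenGeometry(
        width=float(header["width_mm"]),
        thickness_measurements=tuple(
            float(t) for t in header["thickness_mm"].split(",")
        ),
        gauge_length=float(header["gauge_length_mm"]),
    )
    df = pd.read_csv(body)
    for col in ("time_s", "load_N", "displacement_mm"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col}")
    t = df["time_s"].to_numpy(float)
    load = df["load_N"].to_numpy(float)
    disp = df["displacement_mm"].to_numpy(float)
    if len(t) >= 2:
        dt = np.diff(t)
        nominal = 1.0 / SAMPLING_HZ
        if np.any(np.abs(dt - nominal) > 1e-6):
            warnings.warn(
                f"{path}: time base is not uniform 100 Hz; resampling",
                stacklevel=2,
            )
            tu = np.arange(t[0], t[-1] + 0.5 * nominal, nominal)
            load = np.interp(tu, t, load)
            disp = np.interp(tu, t, disp)
            t = tu
    record = TensileRecord(
        time=t,
        load=load,
        displacement=disp,
        geometry=geometry,
        model_id=header.get("model_id", path.stem),
    )
    return [record]


# ---------------------------------------------------------------------------
# Stress / strain
# ---------------------------------------------------------------------------


def _final_ramp_start(displacement: np.ndarray, tol: float | None = None) -> int:
    """Index where the final monotone loading ramp begins.

    Conditioning cycles load and unload before the test proper; the analysed
    segment is the last run over which displacement never decreases (within
    a small tolerance).
    """
    d = np.asarray(displacement, dtype=float)
    if len(d) < 2:
        return 0
    if tol is None:
        tol = 1e-9 * max(1.0, float(np.max(np.abs(d))))
    drops = np.nonzero(np.diff(d) < -tol)[0]
    return int(drops[-1] + 1) if len(drops) else 0


def compute_stress_strain(record: TensileRecord) -> StressStrainCurve:
    """Engineering stress sigma = F / A0 and strain eps = dL / L0.

    The record is trimmed to the final monotone loading ramp (conditioning
    cycles removed) and strain is referenced to the ramp start.
    """
    a0 = record.geometry.area
    if a0 <= 0:
        raise ZeroDivisionError("specimen cross-sectional area must be positive")
    start = _final_ramp_start(record.displacement)
    disp = record.displacement[start:]
    load = record.load[start:]
    strain = (disp - disp[0]) / record.geometry.gauge_length
    stress = load / a0  # N / mm^2 == MPa
    return StressStrainCurve(strain=strain, stress=stress, model_id=record.model_id)


# ---------------------------------------------------------------------------
# Curve alignment, filtering, incremental modulus
# ---------------------------------------------------------------------------


def align_curves(curves: Sequence[StressStrainCurve]) -> list[StressStrainCurve]:
    """Interpolate every curve onto a common grid of the median raw length.

    The common axis is the normalised test-duration fraction, so samples of
    different durations get equal vector sizes with endpoints preserved.
    """
    curves = list(curves)
    if len(curves) < 2:
        raise ValueError("alignment needs at least two curves")
    for c in curves:
        if len(c) < 10:
            raise ValueError(
                f"curve {c.model_id!r} has fewer than 10 samples and was rejected"
            )
    n_common = int(np.median([len(c) for c in curves]))
    grid = np.linspace(0.0, 1.0, n_common)
    out = []
    for c in curves:
        frac = np.linspace(0.0, 1.0, len(c))
        out.append(
            StressStrainCurve(
                strain=np.interp(grid, frac, c.strain),
                stress=np.interp(grid, frac, c.stress),
                model_id=c.model_id,
            )
        )
    return out


def _butter_sos(fs: float, cutoff: float = CUTOFF_HZ, order: int = FILTER_ORDER):
    if cutoff >= fs / 2.0:
        raise ValueError(f"cutoff {cutoff} Hz is at or above Nyquist ({fs / 2.0} Hz)")
    return signal.butter(order, cutoff, btype="low", fs=fs, output="sos")


def _zero_phase(x: np.ndarray, sos) -> np.ndarray:
    return signal.sosfiltfilt(sos, x)


def filter_pipeline(
    aligned: Sequence[StressStrainCurve],
    downsample: int = DOWNSAMPLE,
    cutoff_hz: float = CUTOFF_HZ,
    input_hz: float = SAMPLING_HZ,
    filter_before_average: bool = True,
) -> StressStrainCurve:
    """Downsample by 10, zero-phase 2nd-order Butterworth low-pass, average.

    The 0.1 Hz cutoff is taken at the post-downsample rate (10 Hz for 100 Hz
    input).  ``filter_before_average`` exposes the order of the last two
    steps; the default filters each sample and then averages.
    """
    curves = list(aligned)
    if not curves:
        raise ValueError("no curves to filter")
    fs = input_hz / downsample
    sos = _butter_sos(fs, cutoff_hz)
    eps = np.stack([c.strain[::downsample] for c in curves])
    sig = np.stack([c.stress[::downsample] for c in curves])
    if filter_before_average:
        eps = np.stack([_zero_phase(e, sos) for e in eps])
        sig = np.stack([_zero_phase(s, sos) for s in sig])
        strain = eps.mean(axis=0)
        stress = sig.mean(axis=0)
    else:
        strain = _zero_phase(eps.mean(axis=0), sos)
        stress = _zero_phase(sig.mean(axis=0), sos)
    model_id = curves[0].model_id
    return StressStrainCurve(strain=strain, stress=stress, model_id=model_id)


def incremental_modulus(
    avg_curve: StressStrainCurve,
    window: tuple[float, float] = WINDOW,
    cutoff_hz: float = CUTOFF_HZ,
    fs: float = SAMPLING_HZ / DOWNSAMPLE,
) -> IncrementalModulusCurve:
    """E_inc = (d sigma/dt) / (d eps/dt) via central differences.

    Both derivatives are re-filtered with the same zero-phase Butterworth
    before the ratio; the result is restricted to the given fraction of the
    test duration (default 15-90%).  Points where the strain rate vanishes
    are masked with a warning.
    """
    lo_f, hi_f = window
    if not (0.0 <= lo_f < hi_f <= 1.0):
        raise ValueError("window must satisfy 0 <= lo < hi <= 1")
    n = len(avg_curve)
    if n < 5:
        raise ValueError("averaged curve is too short for differentiation")
    sos = _butter_sos(fs, cutoff_hz)
    dt = 1.0 / fs
    dstress = np.gradient(avg_curve.stress, dt)
    dstrain = np.gradient(avg_curve.strain, dt)
    dstress = _zero_phase(dstress, sos)
    dstrain = _zero_phase(dstrain, sos)
    lo = int(np.floor(lo_f * n))
    hi = max(lo + 2, int(np.ceil(hi_f * n)))
    dstress, dstrain = dstress[lo:hi], dstrain[lo:hi]
    scale = max(float(np.max(np.abs(dstrain))), 1e-30)
    bad = np.abs(dstrain) < 1e-9 * scale
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} points with vanishing strain rate masked",
            stacklevel=2,
        )
    modulus = np.where(bad, np.nan, dstress / np.where(bad, 1.0, dstrain))
    return IncrementalModulusCurve(
        strain=avg_curve.strain[lo:hi], modulus=modulus, window=window
    )


def secant_modulus(curve: StressStrainCurve, strain_point: float) -> float:
    """Slope from the origin to the curve point at ``strain_point`` (MPa)."""
    if strain_point == 0:
        raise ZeroDivisionError("secant modulus is undefined at zero strain")
    lo, hi = float(np.min(curve.strain)), float(np.max(curve.strain))
    if not lo <= strain_point <= hi:
        raise ValueError(f"strain {strain_point} outside curve range [{lo}, {hi}]")
    s = float(np.interp(strain_point, curve.strain, curve.stress))
    return s / strain_point


# ---------------------------------------------------------------------------
# Summaries and statistics
# ---------------------------------------------------------------------------


def summarize(
    raw_curves: Sequence[StressStrainCurve],
    model_id: str,
    secant_at_strain: float | None = None,
) -> TensileSummary:
    """Max stress and strain at max stress across samples, mu +/- sigma.

    Computed from the raw (unfiltered) per-sample curves; ties in max stress
    resolve to the first occurrence.  With a single sample the dispersion is
    reported as NaN.
    """
    curves = list(raw_curves)
    if not curves:
        raise ValueError("summarize needs at least one curve")
    maxima, strains = [], []
    for c in curves:
        i = int(np.argmax(c.stress))
        maxima.append(float(c.stress[i]))
        strains.append(float(c.strain[i]) * 100.0)
    maxima = np.array(maxima)
    strains = np.array(strains)
    n = len(curves)
    sd_stress = float(np.std(maxima, ddof=1)) if n >= 2 else float("nan")
    sd_strain = float(np.std(strains, ddof=1)) if n >= 2 else float("nan")
    secant = None
    if secant_at_strain is not None:
        secant = float(
            np.mean([secant_modulus(c, secant_at_strain) for c in curves])
        )
    return TensileSummary(
        model_id=model_id,
        n=n,
        max_stress_mean=float(np.mean(maxima)),
        max_stress_sd=sd_stress,
        strain_at_max_mean_pct=float(np.mean(strains)),
        strain_at_max_sd_pct=sd_strain,
        secant_modulus_mpa=secant,
    )


def _welch_from_moments(m1, s1, n1, m2, s2, n2):
    se2 = s1**2 / n1 + s2**2 / n2
    t = (m1 - m2) / np.sqrt(se2)
    df = se2**2 / ((s1**2 / n1) ** 2 / (n1 - 1) + (s2**2 / n2) ** 2 / (n2 - 1))
    return t, df


def one_tailed_t_test(
    a: TensileSummary,
    b: TensileSummary,
    direction: str = "greater",
    metric: str = "max_stress",
    alpha: float = ALPHA,
) -> TTestResult:
    """Welch's one-tailed t-test between two summaries.

    ``direction='greater'`` tests H1: mean(a) > mean(b).  Both summaries
    must carry dispersion (n >= 2).
    """
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    m1, s1, n1 = _moments(a, metric)
    m2, s2, n2 = _moments(b, metric)
    if n1 < 2 or n2 < 2 or not np.isfinite(s1) or not np.isfinite(s2):
        raise ValueError(
            "both summaries need n >= 2 and a standard deviation; supply an "
            "assumed n / sd for literature entries without one"
        )
    if s1 == 0 and s2 == 0:
        t = 0.0 if m1 == m2 else math.copysign(math.inf, m1 - m2)
        df = float(n1 + n2 - 2)
        p = 0.5 if t == 0 else (0.0 if (t > 0) == (direction == "greater") else 1.0)
        return TTestResult(t=float(t), p=p, df=df, reject=p < alpha, direction=direction)
    res = stats.ttest_ind_from_stats(
        m1, s1, n1, m2, s2, n2, equal_var=False, alternative=direction
    )
    t, df = _welch_from_moments(m1, s1, n1, m2, s2, n2)
    return TTestResult(
        t=float(res.statistic),
        p=float(res.pvalue),
        df=float(df),
        reject=bool(res.pvalue < alpha),
        direction=direction,
    )


def _moments(s: TensileSummary, metric: str):
    if metric == "max_stress":
        return s.max_stress_mean, s.max_stress_sd, s.n
    if metric == "strain_at_max":
        return s.strain_at_max_mean_pct, s.strain_at_max_sd_pct, s.n
    raise ValueError(f"unknown metric {metric!r}")


def classify_relation(
    a: TensileSummary,
    b: TensileSummary,
    metric: str = "max_stress",
    alpha: float = ALPHA,
) -> str:
    """'greater', 'smaller' or 'equal' via two one-sided Welch tests at 5%."""
    if one_tailed_t_test(a, b, "greater", metric, alpha).reject:
        return "greater"
    if one_tailed_t_test(a, b, "less", metric, alpha).reject:
        return "smaller"
    return "equal"


def analyze_batch(
    records: Sequence[TensileRecord],
    model_id: str | None = None,
    window: tuple[float, float] = WINDOW,
    secant_at_strain: float | None = None,
) -> tuple[TensileSummary, StressStrainCurve, IncrementalModulusCurve]:
    """Full per-model pipeline: summary, averaged filtered curve, E_inc.

    Raw (trimmed, unfiltered) curves feed the summary; the averaged filtered
    curve feeds the incremental modulus.
    """
    records = list(records)
    if not records:
        raise ValueError("no records to analyse")
    model_id = model_id or records[0].model_id
    raw = [compute_stress_strain(r) for r in records]
    summary = summarize(raw, model_id, secant_at_strain=secant_at_strain)
    if len(raw) >= 2:
        aligned = align_curves(raw)
    else:
        aligned = raw
    avg = filter_pipeline(aligned)
    einc = incremental_modulus(avg, window=window)
    return summary, avg, einc
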