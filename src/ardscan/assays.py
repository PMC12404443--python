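"""Dose–response, single-channel and temperature quantification.

Covers the analysis layer of patch-clamp experiments on capsaicin- and
heat-activated channels:

* Hill fits of capsaicin dose–response relations normalized to the
  response at a saturating reference concentration (5 µM).
* Single-channel open probability (Po) by half-amplitude idealization of
  baseline-subtracted, concatenated +80 mV sweep segments.
* Approximate macroscopic Po as current under a condition divided by the
  maximal reference response (assumes Po ≈ 1 at the reference stimulus).
* Whole-cell current–temperature relations normalized per cell to the
  room-temperature mean and summarized in 2 °C bins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    FitError,
    MissingReferenceError,
    NoReferenceWindowError,
    SegmentError,
    WindowError,
    ZeroReferenceError,
)

REFERENCE_CAPSAICIN_UM = 5.0
ASSAY_CONCENTRATIONS_UM = (0.03, 0.1, 0.3, 1.0, 5.0, 10.0)


@dataclass(frozen=True)
class DoseResponsePoint:
    concentration_um: float
    current_pa: float
    normalized: float | None = None


@dataclass(frozen=True)
class HillFit:
    """Least-squares Hill parameters; the curve passes Imax/2 at EC50."""

    imax: float
    ec50_um: float
    n: float
    rss: float
    converged: bool

    def predict(self, conc_um):
        return hill_curve(np.asarray(conc_um, dtype=float), self.imax, self.ec50_um, self.n)


@dataclass
class ChannelTrace:
    """Sampled current with optional per-segment condition labels."""

    current_pa: np.ndarray
    sampling_rate_hz: float
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.current_pa = np.asarray(self.current_pa, dtype=float)
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling rate must be > 0")
        if not np.isfinite(self.current_pa).all():
            raise ValueError("non-finite samples")

    @property
    def duration_s(self) -> float:
        return len(self.current_pa) / self.sampling_rate_hz


@dataclass(frozen=True)
class IdealizedTrace:
    """Per-sample occupancy levels (0..k open channels) and Po."""

    levels: np.ndarray
    unitary_current_pa: float
    n_channels: int
    open_probability: float


@dataclass(frozen=True)
class TemperatureRelation:
    bin_centers_c: np.ndarray
    medians: np.ndarray  # median across cells of per-cell normalized current
    sems: np.ndarray
    n_cells: np.ndarray


def hill_curve(conc, imax, ec50, n):
    """I = Imax · [L]^n / (EC50^n + [L]^n)."""
    c = np.asarray(conc, dtype=float)
    cn = np.power(c, n)
    return imax * cn / (np.power(ec50, n) + cn)


def normalize_dose_response(
    points: list[DoseResponsePoint],
    reference_conc_um: float = REFERENCE_CAPSAICIN_UM,
) -> list[DoseResponsePoint]:
    """Divide every current by the response at the reference concentration."""
    ref = [p for p in points if np.isclose(p.concentration_um, reference_conc_um)]
    if not ref:
        raise MissingReferenceError(
            f"no point at reference concentration {reference_conc_um} µM"
        )
    ref_current = float(np.mean([p.current_pa for p in ref]))
    if ref_current == 0.0:
        raise ZeroReferenceError("reference current is zero")
    return [
        DoseResponsePoint(p.concentration_um, p.current_pa, p.current_pa / ref_current)
        for p in points
    ]


# multi-start grid for the Hill fit; the Hill coefficient floats
_EC50_STARTS = (0.03, 0.3, 3.0)
_N_STARTS = (1.0, 2.0, 4.0)
EC50_BOUNDS = (1e-9, 100.0)
N_BOUNDS = (1e-6, 10.0)


def hill_fit(points: list[DoseResponsePoint]) -> HillFit:
    """Fit the Hill equation to normalized dose–response points.

    Imax, EC50 and n all float, with EC50 ∈ (0, 100] µM and n ∈ (0, 10].
    Nine starts over an (EC50, n) grid guard against local minima; the
    best residual wins.  Non-convergence is flagged, never raised.
    """
    conc = np.array([p.concentration_um for p in points], float)
    resp = np.array(
        [p.normalized if p.normalized is not None else p.current_pa for p in points],
        float,
    )
    if len(np.unique(conc)) < 3:
        raise FitError("need at least 3 distinct concentrations")

    imax0 = max(resp.max(), 1e-6)
    lower = np.array([1e-9, EC50_BOUNDS[0], N_BOUNDS[0]])
    upper = np.array([10.0 * imax0, EC50_BOUNDS[1], N_BOUNDS[1]])

    def residuals(theta):
        return hill_curve(conc, *theta) - resp

    best = None
    for ec50_0 in _EC50_STARTS:
        for n0 in _N_STARTS:
            x0 = np.clip([imax0, ec50_0, n0], lower, upper)
            try:
                sol = least_squares(residuals, x0, bounds=(lower, upper), xtol=1e-14, ftol=1e-14, gtol=1e-14)
            except Exception:
                continue
            rss = float(np.sum(sol.fun**2))
            if best is None or rss < best[0]:
                best = (rss, sol)
    if best is None:
        return HillFit(np.nan, np.nan, np.nan, np.inf, False)
    rss, sol = best
    imax, ec50, n = sol.x
    return HillFit(float(imax), float(ec50), float(n), rss, bool(sol.success))


def concatenate_segments(
    sweeps: list[ChannelTrace],
    segment_tag: str = "+80mV",
) -> ChannelTrace:
    """Append the tagged segment of every sweep in sweep order.

    Each sweep's ``labels`` must map ``segment_tag`` to a ``(start, stop)``
    sample slice of that sweep.  Condition labels other than segment
    slices are carried over from the first sweep.
    """
    if not sweeps:
        raise SegmentError("no sweeps")
    pieces = []
    for i, sweep in enumerate(sweeps):
        if segment_tag not in sweep.labels:
            raise SegmentError(f"sweep {i} lacks segment {segment_tag!r}")
        start, stop = sweep.labels[segment_tag]
        pieces.append(sweep.current_pa[start:stop])
    labels = {k: v for k, v in sweeps[0].labels.items() if k != segment_tag}
    labels["segment"] = segment_tag
    return ChannelTrace(np.concatenate(pieces), sweeps[0].sampling_rate_hz, labels)


def subtract_baseline(
    trace: ChannelTrace,
    window_seconds: float = 1.0,
    percentile: float = 10.0,
) -> ChannelTrace:
    """Remove slow baseline drift with a rolling low-percentile estimate.

    A low percentile tracks the closed-state level even when the channel
    spends much of its time open; the per-block percentile is linearly
    interpolated back to every sample and subtracted.  Because a low
    percentile of noisy closed-state samples sits below their mean, the
    detrended trace is finally re-zeroed on the peak of its amplitude
    histogram — the closed-state level, provided the channel is shut more
    than half the time.
    """
    n = len(trace.current_pa)
    win = int(round(window_seconds * trace.sampling_rate_hz))
    if win < 2 or win >= n:
        raise WindowError(f"window of {win} samples does not fit trace of {n}")
    x = trace.current_pa
    # percentile per quarter-window block, interpolated between block centers
    step = max(win // 4, 1)
    starts = np.arange(0, n - win + 1, step)
    if starts[-1] != n - win:
        starts = np.append(starts, n - win)
    centers = starts + win / 2.0
    levels = np.array([np.percentile(x[s:s + win], percentile) for s in starts])
    y = x - np.interp(np.arange(n), centers, levels)
    y -= _modal_level(y)
    return ChannelTrace(y, trace.sampling_rate_hz, dict(trace.labels))


def _modal_level(y: np.ndarray) -> float:
    """Center of the most occupied amplitude bin (the closed-state peak).

    Bin width is tied to the sample-to-sample noise so the open and closed
    peaks stay resolved; a noise-free flat trace falls back to its median.
    """
    sigma = 1.4826 * np.median(np.abs(np.diff(y))) / math.sqrt(2.0)
    if sigma < 1e-12:
        return float(np.median(y))
    width = sigma / 4.0
    edges = np.arange(y.min(), y.max() + width, width)
    if len(edges) < 3:
        return float(np.median(y))
    counts, edges = np.histogram(y, bins=edges)
    peak = int(np.argmax(counts))
    return float(0.5 * (edges[peak] + edges[peak + 1]))


def idealize_half_amplitude(
    trace: ChannelTrace,
    unitary_current_pa: float,
    n_channels: int = 1,
    openings_positive: bool = True,
) -> IdealizedTrace:
    """Idealize a baseline-subtracted trace by half-amplitude thresholds.

    With unitary current ``i``, the thresholds sit at (m − ½)·i, i.e. the
    occupancy level is round(sample/i) clipped to [0, k].  Po is the mean
    occupancy divided by the channel count.  Openings are positive
    deflections at +80 mV; set ``openings_positive=False`` for −80 mV
    segments.
    """
    if unitary_current_pa <= 0:
        raise ZeroReferenceError("unitary current must be > 0")
    if n_channels < 1:
        raise ValueError("n_channels must be ≥ 1")
    x = trace.current_pa if openings_positive else -trace.current_pa
    # floor(x/i + 1/2) puts thresholds exactly at (m − ½)·i
    levels = np.floor(x / unitary_current_pa + 0.5)
    levels = np.clip(levels, 0, n_channels).astype(np.int64)
    po = float(levels.mean() / n_channels)
    return IdealizedTrace(levels, unitary_current_pa, n_channels, po)


def macro_open_probability(
    current_pa: float, max_reference_pa: float
) -> tuple[float, bool]:
    """Approximate Po of a macroscopic patch as I / I(reference stimulus).

    Assumes Po ≈ 1 under the reference stimulus (saturating capsaicin).
    Returns ``(po, over_unity)``; ratios above 1 are reported as-is with
    the flag set rather than clipped.
    """
    if max_reference_pa <= 0:
        raise ZeroReferenceError("reference current must be > 0")
    po = current_pa / max_reference_pa
    return po, po > 1.0


ROOM_TEMPERATURE_WINDOW_C = (20.0, 25.0)


def temperature_relation(
    sweeps,
    room_window_c: tuple[float, float] = ROOM_TEMPERATURE_WINDOW_C,
    bin_width_c: float = 2.0,
) -> TemperatureRelation:
    """Per-cell normalized current–temperature relation, binned at 2 °C.

    ``sweeps``: iterable of ``(cell_id, temperature_C, current_pA)``.
    Each cell's currents are divided by that cell's mean current inside
    the room-temperature window; per 2 °C bin (half-open, centered on
    multiples of the width) the median and the standard error across cell
    means are reported.
    """
    import pandas as pd

    df = pd.DataFrame(list(sweeps), columns=["cell", "temp_c", "current_pa"])
    if df.empty:
        raise NoReferenceWindowError("no sweeps")
    lo, hi = room_window_c
    room = df[(df.temp_c >= lo) & (df.temp_c <= hi)]
    if room.empty:
        raise NoReferenceWindowError(f"no sweep inside room window [{lo}, {hi}] °C")
    ref = room.groupby("cell")["current_pa"].mean()
    df = df[df.cell.isin(ref.index)].copy()
    df["norm"] = df.current_pa / df.cell.map(ref)
    # half-open bins [c − w/2, c + w/2) centered on multiples of the width
    df["bin"] = np.floor(df.temp_c / bin_width_c + 0.5) * bin_width_c

    per_cell = df.groupby(["bin", "cell"])["norm"].mean().reset_index()
    grouped = per_cell.groupby("bin")["norm"]
    med = grouped.median()
    sem = grouped.sem(ddof=1).fillna(0.0)
    n = grouped.count()
    return TemperatureRelation(
        med.index.to_numpy(float), med.to_numpy(), sem.to_numpy(), n.to_numpy()
    )


# --- delimited-text I/O ---------------------------------------------------

def read_dose_response_csv(path) -> list[DoseResponsePoint]:
    """CSV with columns ``conc_uM,current_pA``."""
    import pandas as pd

    df = pd.read_csv(path)
    return [
        DoseResponsePoint(float(r.conc_uM), float(r.current_pA))
        for r in df.itertuples()
    ]


def read_trace_csv(path, segments_path=None) -> list[ChannelTrace]:
    """Trace CSV ``time_s,current_pA`` plus an optional sidecar segment table.

    The sidecar columns are ``sweep_id,segment,start_s,end_s,voltage_mV,
    ligand_uM,pH``; each sweep id becomes one ChannelTrace whose labels
    map segment names to sample slices.
    """
    import pandas as pd

    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(float)
    x = df["current_pA"].to_numpy(float)
    if len(t) < 2:
        raise WindowError("trace needs at least 2 samples")
    fs = 1.0 / float(np.median(np.diff(t)))
    if segments_path is None:
        return [ChannelTrace(x, fs)]
    seg = pd.read_csv(segments_path)
    sweeps = []
    for sweep_id, group in seg.groupby("sweep_id", sort=True):
        lo = group.start_s.min()
        hi = group.end_s.max()
        mask = (t >= lo) & (t < hi)
        labels: dict = {"sweep_id": sweep_id}
        for r in group.itertuples():
            a = int(round((r.start_s - lo) * fs))
            b = int(round((r.end_s - lo) * fs))
            labels[str(r.segment)] = (a, b)
            labels.setdefault("ligand_uM", getattr(r, "ligand_uM", None))
            labels.setdefault("pH", getattr(r, "pH", None))
        sweeps.append(ChannelTrace(x[mask], fs, labels))
    if not sweeps:
        raise SegmentError("segment table matched no samples")
    return sweeps
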