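"""Calcium-imaging responder counts.

In the imaging protocol, a field of dye-loaded cells is perfused with the
agonist (capsaicin, 500 nM) at 30 s and with the ionophore ionomycin at
120 s; ionomycin saturates the calcium indicator in every live cell, so a
cell that brightens for neither stimulus is excluded as unhealthy.  The
response fraction is capsaicin responders over all healthy cells, then
normalized to a same-day control fraction to cancel day-to-day
transfection variability.

The published counting was manual on contrast-adjusted movies; here each
cell contributes a fluorescence time series and the qualitative brightness
judgment is replaced by a relative-rise rule, ΔF/F0 ≥ θ (default 0.5),
with F0 the mean pre-capsaicin fluorescence.  θ must be reported with any
result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DuplicateCellError, NoHealthyCellsError, ZeroControlError

logger = logging.getLogger(__name__)

CAPSAICIN_TIME_S = 30.0
IONOMYCIN_TIME_S = 120.0
FRAME_INTERVAL_S = 0.5
DEFAULT_THETA = 0.5

LABEL_RESPONDER = "capsaicin_responder"
LABEL_IONO_ONLY = "ionomycin_only"
LABEL_EXCLUDED = "excluded"


@dataclass
class CellTrace:
    cell_id: str
    fluorescence: np.ndarray
    frame_interval_s: float = FRAME_INTERVAL_S
    capsaicin_time_s: float = CAPSAICIN_TIME_S
    ionomycin_time_s: float = IONOMYCIN_TIME_S

    def __post_init__(self) -> None:
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        end = len(self.fluorescence) * self.frame_interval_s
        if not (0 < self.capsaicin_time_s < self.ionomycin_time_s < end):
            raise ValueError(
                f"need 0 < capsaicin ({self.capsaicin_time_s}) < ionomycin "
                f"({self.ionomycin_time_s}) < end ({end})"
            )
        if not np.isfinite(self.fluorescence).all() or (self.fluorescence < 0).any():
            raise ValueError("fluorescence must be finite and non-negative")


@dataclass(frozen=True)
class ResponseCounts:
    n_capsaicin_responders: int
    n_ionomycin_only: int
    n_excluded: int
    response_fraction: float
    normalized_fraction: float | None = None


def classify_cell(trace: CellTrace, theta: float = DEFAULT_THETA) -> str:
    """Label one cell by its relative fluorescence rise.

    Capsaicin responder if max ΔF/F0 between the capsaicin and ionomycin
    additions reaches θ; otherwise ionomycin-only if the post-ionomycin
    rise reaches θ; otherwise excluded.  Dead cells and cells that start
    bright and stay flat never rise, so both fall into "excluded".
    """
    if theta <= 0:
        raise ValueError("theta must be > 0")
    t = np.arange(len(trace.fluorescence)) * trace.frame_interval_s
    f = trace.fluorescence
    pre = f[t < trace.capsaicin_time_s]
    f0 = float(pre.mean()) if len(pre) else 0.0
    if f0 <= 0:
        logger.info("cell %s excluded: zero baseline", trace.cell_id)
        return LABEL_EXCLUDED
    cap_window = (t >= trace.capsaicin_time_s) & (t < trace.ionomycin_time_s)
    iono_window = t >= trace.ionomycin_time_s
    dff = (f - f0) / f0
    if cap_window.any() and dff[cap_window].max() >= theta:
        return LABEL_RESPONDER
    if iono_window.any() and dff[iono_window].max() >= theta:
        return LABEL_IONO_ONLY
    return LABEL_EXCLUDED


def classify_field(traces: list[CellTrace], theta: float = DEFAULT_THETA) -> dict[str, str]:
    """Classify every cell; duplicate cell ids are structural errors."""
    labels: dict[str, str] = {}
    for trace in traces:
        if trace.cell_id in labels:
            raise DuplicateCellError(f"duplicate cell id {trace.cell_id!r}")
        labels[trace.cell_id] = classify_cell(trace, theta)
    return labels


def response_fraction(labels) -> ResponseCounts:
    """Capsaicin responders over healthy (capsaicin- or ionomycin-responding) cells."""
    values = list(labels.values()) if isinstance(labels, dict) else list(labels)
    n_resp = values.count(LABEL_RESPONDER)
    n_iono = values.count(LABEL_IONO_ONLY)
    n_excl = values.count(LABEL_EXCLUDED)
    healthy = n_resp + n_iono
    if healthy == 0:
        raise NoHealthyCellsError("no healthy cells in field")
    return ResponseCounts(n_resp, n_iono, n_excl, n_resp / healthy)


def normalize_to_control(fraction: float, control_fraction: float) -> float:
    """Ratio to the same-day control fraction; control vs itself gives 1.0."""
    if control_fraction <= 0:
        raise ZeroControlError("control fraction must be > 0")
    return fraction / control_fraction


def read_cell_traces_csv(
    path,
    frame_interval_s: float = FRAME_INTERVAL_S,
    capsaicin_time_s: float = CAPSAICIN_TIME_S,
    ionomycin_time_s: float = IONOMYCIN_TIME_S,
) -> list[CellTrace]:
    """Wide CSV: ``frame_time_s, <cell_id>, <cell_id>, ...`` one row per frame."""
    import pandas as pd

    df = pd.read_csv(path)
    time_col = df.columns[0]
    dt = float(np.median(np.diff(df[time_col].to_numpy(float))))
    if not np.isclose(dt, frame_interval_s, rtol=0.01):
        logger.info("frame interval from file: %.3f s", dt)
        frame_interval_s = dt
    return [
        CellTrace(
            str(col), df[col].to_numpy(float), frame_interval_s,
            capsaicin_time_s, ionomycin_time_s,
        )
        for col in df.columns[1:]
    ]
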