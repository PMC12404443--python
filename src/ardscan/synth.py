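"""Synthetic inputs with the statistical structure the analysis assumes.

Every generator here emulates one experimental data stream so the whole
pipeline runs and is testable with no downloads:

* missense-variant tables whose per-residue variant-type count rises with
  solvent exposure (Poisson with log-link on fractional SASA), with
  optional planted buried outliers;
* ideal α-helix coordinates as valid PDB text, for SASA fixtures;
* continuous-time two-state (closed/open) Markov gating sampled into a
  noisy, optionally drifting current trace;
* Hill-curve dose–response tables with additive Gaussian noise;
* two-state van 't Hoff temperature-activation current tables on a
  10–60 °C heating ramp;
* calcium-imaging cell fields with planted responder / ionomycin-only /
  excluded fractions.

All randomness flows through ``numpy.random.default_rng(seed)``; the same
seed and parameters give bit-identical output.  Ground truth is returned
alongside each dataset so recovery tests can close the loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .assays import ChannelTrace, DoseResponsePoint, ASSAY_CONCENTRATIONS_UM, hill_curve
from .cells import (
    CAPSAICIN_TIME_S,
    FRAME_INTERVAL_S,
    IONOMYCIN_TIME_S,
    LABEL_EXCLUDED,
    LABEL_IONO_ONLY,
    LABEL_RESPONDER,
    CellTrace,
)
from .variants import CANONICAL_AA, MissenseVariant

_AA = sorted(CANONICAL_AA)

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


# --- variant tables -------------------------------------------------------

@dataclass
class VariantTableTruth:
    sequence: str
    start: int
    fractional_sasa: np.ndarray
    n_types: np.ndarray  # per residue, ground truth


def simulate_variant_table(
    n_residues: int,
    fractional_sasa=None,
    intercept: float = -1.0,
    slope: float = 2.0,
    outliers: list[tuple[int, int]] | None = None,
    seed: int = 0,
    start: int = 1,
    geometric_p: float = 0.3,
    source_release: str = "synthetic",
) -> tuple[list[MissenseVariant], VariantTableTruth]:
    """Variant list whose type counts follow Poisson(exp(a + b·fSASA)).

    ``outliers`` plants extra variant types at given positions — the
    buried-but-variable signature the discordance score must flag.
    Allele counts per type are geometric on {1, 2, ...} (one success plus
    the failures before it), mimicking the heavy-tailed allele-count
    spectrum of population databases.
    """
    if slope < 0:
        raise ValueError("slope must be ≥ 0")
    rng = np.random.default_rng(seed)
    if fractional_sasa is None:
        fractional_sasa = rng.beta(1.2, 2.0, size=n_residues)
    fsasa = np.asarray(fractional_sasa, dtype=float)
    if len(fsasa) != n_residues:
        raise ValueError("fractional_sasa length mismatch")

    sequence = "".join(rng.choice(_AA, size=n_residues))
    lam = np.exp(intercept + slope * fsasa)
    n_types = np.minimum(rng.poisson(lam), 19)
    extra = dict(outliers or [])
    variants: list[MissenseVariant] = []
    for idx in range(n_residues):
        pos = start + idx
        ref = sequence[idx]
        k = int(min(n_types[idx] + extra.get(pos, 0), 19))
        n_types[idx] = k
        if k == 0:
            continue
        alts = rng.choice([a for a in _AA if a != ref], size=k, replace=False)
        for alt in alts:
            count = int(rng.geometric(geometric_p))
            variants.append(MissenseVariant(ref, pos, alt, count, source_release))
    return variants, VariantTableTruth(sequence, start, fsasa, n_types)


# --- ideal helix structure ------------------------------------------------

def _nerf(a, b, c, bond, angle_deg, torsion_deg):
    """Place atom D from A–B–C with bond C–D, angle B–C–D, torsion A–B–C–D."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(torsion),
            bond * math.sin(angle) * math.sin(torsion),
        ]
    )
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def generate_helix_structure(
    n_residues: int,
    sequence: str | None = None,
    phi: float = -57.0,
    psi: float = -47.0,
    chain_id: str = "A",
    start: int = 1,
) -> str:
    """Ideal α-helix backbone (+ Cβ, + carbonyl O) as PDB text.

    Dihedrals default to the canonical α-helix (φ = −57°, ψ = −47°);
    bond lengths and angles are standard peptide values.  Glycine gets no
    Cβ.  The text round-trips through :func:`ardscan.structure.read_structure`.
    """
    if not (3 <= n_residues <= 500):
        raise ValueError("n_residues must be in [3, 500]")
    if sequence is None:
        sequence = "A" * n_residues
    if len(sequence) != n_residues:
        raise ValueError("sequence length mismatch")
    bad = set(sequence) - set(ONE_TO_THREE)
    if bad:
        raise ValueError(f"unsupported residue letters {sorted(bad)}")

    # backbone by sequential natural-extension placement
    n_atoms = [np.array([0.0, 0.0, 0.0])]
    ca_atoms = [np.array([1.458, 0.0, 0.0])]
    c0 = ca_atoms[0] + 1.525 * np.array(
        [math.cos(math.radians(180 - 111.2)), math.sin(math.radians(180 - 111.2)), 0.0]
    )
    c_atoms = [c0]
    for _ in range(1, n_residues):
        n_next = _nerf(n_atoms[-1], ca_atoms[-1], c_atoms[-1], 1.329, 116.2, psi)
        ca_next = _nerf(ca_atoms[-1], c_atoms[-1], n_next, 1.458, 121.7, 180.0)
        c_next = _nerf(c_atoms[-1], n_next, ca_next, 1.525, 111.2, phi)
        n_atoms.append(n_next)
        ca_atoms.append(ca_next)
        c_atoms.append(c_next)

    lines = []
    serial = 1

    def emit(name, element, pos, resname, resnum):
        nonlocal serial
        lines.append(
            f"ATOM  {serial:5d}  {name:<3s} {resname} {chain_id}{resnum:4d}    "
            f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {element:>2s}"
        )
        serial += 1

    for i in range(n_residues):
        resname = ONE_TO_THREE[sequence[i]]
        resnum = start + i
        n_i, ca_i, c_i = n_atoms[i], ca_atoms[i], c_atoms[i]
        emit("N", "N", n_i, resname, resnum)
        emit("CA", "C", ca_i, resname, resnum)
        emit("C", "C", c_i, resname, resnum)
        # carbonyl O opposite the next N (torsion ψ + 180 about CA–C)
        o_i = _nerf(n_i, ca_i, c_i, 1.231, 120.5, psi + 180.0)
        emit("O", "O", o_i, resname, resnum)
        if sequence[i] != "G":
            b_vec = ca_i - n_i
            c_vec = c_i - ca_i
            a_vec = np.cross(b_vec, c_vec)
            cb = ca_i - 0.58273431 * a_vec + 0.56802827 * b_vec - 0.54067466 * c_vec
            emit("CB", "C", cb, resname, resnum)
    lines.append("END")
    return "\n".join(lines) + "\n"


# --- two-state channel gating ---------------------------------------------

@dataclass
class ChannelSimTruth:
    occupancy: np.ndarray  # per-sample number of open channels (noise-free)
    true_po: float  # time-averaged open probability of the continuous paths
    stationary_po: float  # α / (α + β)


def simulate_two_state_channel(
    open_rate_per_s: float = 30.0,
    close_rate_per_s: float = 70.0,
    unitary_current_pa: float = 8.0,
    sampling_rate_hz: float = 20_000.0,
    duration_s: float = 60.0,
    noise_sigma_pa: float = 0.8,
    drift_pa_per_s: float = 0.0,
    n_channels: int = 1,
    seed: int = 0,
) -> tuple[ChannelTrace, ChannelSimTruth]:
    """Continuous-time closed⇌open gating sampled into a current trace.

    Per channel, dwell times are exponential with rate α (closed→open) and
    β (open→closed); the stationary open probability is α/(α+β).  The
    recorded current is ``i × (open channels) + Gaussian noise + linear
    drift``, mimicking a patch at +80 mV where openings are positive.
    """
    if open_rate_per_s <= 0 or close_rate_per_s <= 0:
        raise ValueError("rates must be > 0")
    rng = np.random.default_rng(seed)
    n_samples = int(round(duration_s * sampling_rate_hz))
    t = np.arange(n_samples) / sampling_rate_hz
    occupancy = np.zeros(n_samples, dtype=np.int64)
    open_time_total = 0.0
    alpha, beta = open_rate_per_s, close_rate_per_s
    p_open = alpha / (alpha + beta)

    for _ in range(n_channels):
        state = int(rng.random() < p_open)  # start at stationarity
        now = 0.0
        # event times and the state entered at each event
        times = [0.0]
        states = [state]
        while now < duration_s:
            rate = beta if state else alpha
            now += rng.exponential(1.0 / rate)
            state = 1 - state
            times.append(min(now, duration_s))
            states.append(state)
        times_arr = np.array(times)
        states_arr = np.array(states[:-1])  # state held on [t_j, t_{j+1})
        open_time_total += float(np.sum(np.diff(times_arr)[states_arr == 1]))
        idx = np.searchsorted(times_arr[1:], t, side="right")
        occupancy += states_arr[np.minimum(idx, len(states_arr) - 1)]

    current = (
        unitary_current_pa * occupancy
        + rng.normal(0.0, noise_sigma_pa, size=n_samples)
        + drift_pa_per_s * t
    )
    trace = ChannelTrace(
        current, sampling_rate_hz,
        {"unitary_pa": unitary_current_pa, "n_channels": n_channels},
    )
    truth = ChannelSimTruth(
        occupancy, open_time_total / (duration_s * n_channels), p_open
    )
    return trace, truth


# --- dose–response ---------------------------------------------------------

def simulate_dose_response(
    imax: float = 1.0,
    ec50_um: float = 0.3,
    n: float = 2.0,
    concentrations_um=ASSAY_CONCENTRATIONS_UM,
    noise_sigma: float = 0.05,
    replicates: int = 1,
    seed: int = 0,
) -> list[list[DoseResponsePoint]]:
    """Normalized Hill-curve responses with additive Gaussian noise."""
    if min(imax, ec50_um, n) <= 0:
        raise ValueError("Hill parameters must be positive")
    rng = np.random.default_rng(seed)
    conc = np.asarray(concentrations_um, dtype=float)
    ideal = hill_curve(conc, imax, ec50_um, n)
    out = []
    for _ in range(replicates):
        noisy = ideal + rng.normal(0.0, noise_sigma, size=len(conc))
        out.append(
            [
                DoseResponsePoint(float(c), float(y), float(y))
                for c, y in zip(conc, noisy)
            ]
        )
    return out


# --- temperature activation ------------------------------------------------

GAS_CONSTANT_KCAL = 1.987204e-3  # kcal / (mol·K)


def vant_hoff_occupancy(temp_c, delta_h_kcal: float, t_half_c: float):
    """Two-state open-state occupancy; exactly 0.5 at the midpoint."""
    t = np.asarray(temp_c, dtype=float) + 273.15
    t_half = t_half_c + 273.15
    k = np.exp(-(delta_h_kcal / GAS_CONSTANT_KCAL) * (1.0 / t - 1.0 / t_half))
    return k / (1.0 + k)


def simulate_temperature_currents(
    delta_h_kcal: float = 60.0,
    t_half_c: float = 44.0,
    leak_fraction: float = 0.05,
    n_cells: int = 11,
    noise_sigma: float = 0.05,
    seed: int = 0,
    ramp_c=(10.0, 60.0),
    step_c: float = 0.5,
) -> list[tuple[str, float, float]]:
    """Whole-cell heating-ramp currents, one sweep per 0.5 °C per cell.

    Each cell gets a log-normal maximal current (expression varies
    cell-to-cell, which is what the room-temperature normalization must
    cancel); the open-state occupancy follows a two-state van 't Hoff
    relation with enthalpy ``delta_h_kcal`` and midpoint ``t_half_c``.
    Returns ``(cell_id, temp_C, current_pA)`` rows.
    """
    if delta_h_kcal <= 0:
        raise ValueError("delta_h_kcal must be > 0")
    rng = np.random.default_rng(seed)
    temps = np.arange(ramp_c[0], ramp_c[1] + step_c / 2, step_c)
    rows = []
    for c in range(n_cells):
        imax = float(rng.lognormal(math.log(1000.0), 0.5))  # pA
        occ = vant_hoff_occupancy(temps, delta_h_kcal, t_half_c)
        current = imax * (occ + leak_fraction) * (
            1.0 + rng.normal(0.0, noise_sigma, size=len(temps))
        )
        cell_id = f"cell_{c:03d}"
        rows.extend((cell_id, float(t), float(i)) for t, i in zip(temps, current))
    return rows


# --- calcium-imaging cell fields -------------------------------------------

def simulate_cell_field(
    n_cells: int = 200,
    responder_fraction: float = 0.5,
    iono_only_fraction: float = 0.4,
    excluded_fraction: float = 0.1,
    response_amplitude: float = 2.0,
    iono_amplitude: float = 4.0,
    baseline_f: float = 100.0,
    noise_sigma: float = 2.0,
    duration_s: float = 180.0,
    frame_interval_s: float = FRAME_INTERVAL_S,
    capsaicin_time_s: float = CAPSAICIN_TIME_S,
    ionomycin_time_s: float = IONOMYCIN_TIME_S,
    seed: int = 0,
) -> tuple[list[CellTrace], dict[str, str]]:
    """Cell fluorescence traces with planted ground-truth labels.

    Responders step up at the capsaicin time and again at ionomycin;
    ionomycin-only cells rise only at ionomycin; excluded cells stay flat
    (half of them dim, half start-bright — neither ever rises).  Labels
    are multinomial draws from the given fractions.
    """
    if not math.isclose(
        responder_fraction + iono_only_fraction + excluded_fraction, 1.0,
        abs_tol=1e-9,
    ):
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration_s / frame_interval_s))
    t = np.arange(n_frames) * frame_interval_s
    labels_pool = [LABEL_RESPONDER, LABEL_IONO_ONLY, LABEL_EXCLUDED]
    probs = np.clip([responder_fraction, iono_only_fraction, excluded_fraction], 0, None)
    probs = probs / probs.sum()
    traces: list[CellTrace] = []
    truth: dict[str, str] = {}
    for c in range(n_cells):
        label = rng.choice(labels_pool, p=probs)
        f0 = baseline_f * float(rng.uniform(0.8, 1.2))
        f = np.full(n_frames, f0)
        if label == LABEL_RESPONDER:
            f = f + f0 * response_amplitude * (t >= capsaicin_time_s)
            f = f + f0 * (iono_amplitude - response_amplitude) * (t >= ionomycin_time_s)
        elif label == LABEL_IONO_ONLY:
            f = f + f0 * iono_amplitude * (t >= ionomycin_time_s)
        else:  # excluded: flat — alternately dim ("dead") or start-bright
            if rng.random() < 0.5:
                f = np.full(n_frames, 0.05 * f0)
            else:
                f = np.full(n_frames, 3.0 * f0)
        # noise grows with intensity (shot-noise-like), so dim cells stay dim
        sigma = noise_sigma * f / baseline_f
        f = np.clip(f + rng.normal(0.0, 1.0, size=n_frames) * sigma, 0.0, None)
        cell_id = f"cell_{c:03d}"
        traces.append(
            CellTrace(cell_id, f, frame_interval_s, capsaicin_time_s, ionomycin_time_s)
        )
        truth[cell_id] = str(label)
    return traces, truth
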