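"""Burial-versus-variability profiles.

The core idea: across an ankyrin repeat domain, the number of distinct
missense amino acids seen in the human population at a residue rises with
that residue's solvent exposure — buried side chains tolerate fewer
substitutions.  Sorting residues by fractional SASA and smoothing the
per-residue variant-type counts along that rank axis turns the trend into
a profile; a buried residue whose raw count stands far above the local
smoothed expectation is a candidate functional site (the analysis that
singles out the TRPV1 ARD methionine M308).

The published analysis identified such outliers visually; the permutation
``discordance`` score here is this package's formalization of that reading
and is labeled as such in outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, EmptySeriesError
from .structure import ResidueSASA

DEFAULT_WINDOW = 20


@dataclass(frozen=True)
class BurialRecord:
    rank: int  # 1-based, ascending fractional SASA (most buried first)
    position: int
    residue_type: str
    fractional_sasa: float
    n_types: int = 0
    smoothed_n_types: float = 0.0


@dataclass
class BurialProfile:
    """Residues ordered from most buried to most exposed."""

    records: list[BurialRecord]

    def __len__(self) -> int:
        return len(self.records)

    def rank_of_position(self, position: int) -> int:
        for r in self.records:
            if r.position == position:
                return r.rank
        raise KeyError(position)


@dataclass(frozen=True)
class DiscordanceScore:
    position: int
    rank: int
    raw_score: float  # n_types − smoothed expectation at this rank
    p_value: float


@dataclass(frozen=True)
class AlignmentColumn:
    reference_id: str
    reference_position: int
    column_index: int  # 0-based alignment column
    letters: dict[str, str]  # sequence id → letter (may be a gap)
    identity_fraction: float


def rank_by_burial(residues: list[ResidueSASA]) -> BurialProfile:
    """Sort ascending by fractional SASA; ties broken by residue number."""
    if not residues:
        raise EmptySeriesError("no residues to rank")
    if not all(np.isfinite(r.fractional_sasa) for r in residues):
        raise ValueError("non-finite fractional SASA")
    ordered = sorted(residues, key=lambda r: (r.fractional_sasa, r.residue_number))
    return BurialProfile(
        [
            BurialRecord(i + 1, r.residue_number, r.residue_type, r.fractional_sasa)
            for i, r in enumerate(ordered)
        ]
    )


def smooth_counts(counts, window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Centered moving mean along the rank axis, truncated at the edges.

    The divisor is the number of in-window points, so a constant series is
    preserved exactly and the interior impulse response is ``1/window``.
    Accepts a 1-D series or a 2-D array smoothed along the last axis.
    """
    x = np.asarray(counts, dtype=float)
    if x.size == 0:
        raise EmptySeriesError("empty series")
    if window < 1:
        raise ValueError(f"window {window} < 1")
    left, right = window // 2, (window - 1) // 2
    n = x.shape[-1]
    # cumulative-sum windows: [i-left, i+right] clipped to the series
    cs = np.cumsum(x, axis=-1)
    zeros = np.zeros(x.shape[:-1] + (1,))
    cs = np.concatenate([zeros, cs], axis=-1)
    lo = np.clip(np.arange(n) - left, 0, n)
    hi = np.clip(np.arange(n) + right + 1, 0, n)
    sums = cs[..., hi] - cs[..., lo]
    return sums / (hi - lo)


def attach_counts(
    profile: BurialProfile,
    n_types_by_position: dict[int, int],
    window: int = DEFAULT_WINDOW,
) -> BurialProfile:
    """Fill in raw and smoothed variant-type counts along the rank axis.

    Positions absent from the variant table have zero types (no missense
    variant observed), not missing data.
    """
    raw = np.array(
        [n_types_by_position.get(r.position, 0) for r in profile.records], float
    )
    smoothed = smooth_counts(raw, window)
    return BurialProfile(
        [
            BurialRecord(
                r.rank, r.position, r.residue_type, r.fractional_sasa,
                int(raw[i]), float(smoothed[i]),
            )
            for i, r in enumerate(profile.records)
        ]
    )


def discordance(
    profile: BurialProfile,
    n_permutations: int = 999,
    seed: int = 0,
    window: int = DEFAULT_WINDOW,
) -> list[DiscordanceScore]:
    """Permutation scores for burial/variability discordance.

    The raw score of a residue is its variant-type count minus the locally
    smoothed expectation at its burial rank.  The null model permutes the
    type counts across ranks (exchangeability); the reference statistic is
    the *maximum* raw score over the buried (lowest-SASA) half, so the
    p-value attached to a residue answers: how often does an exchangeable
    profile produce a buried residue at least this discordant anywhere?

        p = (1 + #{perm: max buried raw ≥ observed}) / (n_permutations + 1)
    """
    if n_permutations < 99:
        raise ValueError(f"n_permutations {n_permutations} < 99")
    raw = np.array([r.n_types for r in profile.records], float)
    smoothed = np.array([r.smoothed_n_types for r in profile.records])
    observed = raw - smoothed
    n = len(raw)
    half = n // 2

    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(raw) for _ in range(n_permutations)])
    perm_scores = perms - smooth_counts(perms, window)
    null_max = perm_scores[:, :half].max(axis=1)

    scores = []
    for i, rec in enumerate(profile.records):
        p = (1.0 + np.count_nonzero(null_max >= observed[i])) / (n_permutations + 1.0)
        scores.append(DiscordanceScore(rec.position, rec.rank, float(observed[i]), p))
    return scores


def conditional_discordance_p(
    profile: BurialProfile,
    position: int,
    n_permutations: int = 999,
    seed: int = 0,
    window: int = DEFAULT_WINDOW,
) -> float:
    """Permutation p-value for one *pre-specified* residue.

    :func:`discordance` calibrates discovery: its null permutes every
    count, including the candidate's own, so a residue first *selected*
    as the most discordant is judged against profiles that still contain
    its extreme count somewhere.  For a residue chosen in advance the
    sharper question is conditional: holding this residue's count where
    it is, how often does a permutation of the *other* counts put an
    equally discordant residue anywhere in the buried half?

        p = (1 + #{perm: max buried raw over other residues ≥ observed})
            / (n_permutations + 1)
    """
    raw = np.array([r.n_types for r in profile.records], float)
    idx = next(
        (i for i, r in enumerate(profile.records) if r.position == position), None
    )
    if idx is None:
        raise KeyError(position)
    observed = raw[idx] - smooth_counts(raw, window)[idx]
    n = len(raw)
    half = n // 2

    others = np.delete(raw, idx)
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(others) for _ in range(n_permutations)])
    full = np.insert(perms, idx, raw[idx], axis=1)
    scores = full - smooth_counts(full, window)
    scores[:, idx] = -np.inf  # the candidate itself is not part of its null
    null_max = scores[:, :half].max(axis=1)
    return float(
        (1.0 + np.count_nonzero(null_max >= observed)) / (n_permutations + 1.0)
    )


def profile_frame(profile: BurialProfile, scores: list[DiscordanceScore] | None = None):
    """Profile (and optional discordance scores) as a DataFrame."""
    import pandas as pd

    df = pd.DataFrame(
        [
            (r.rank, r.position, r.residue_type, r.fractional_sasa,
             r.n_types, r.smoothed_n_types)
            for r in profile.records
        ],
        columns=["rank", "position", "restype", "frac_sasa", "n_types", "smoothed"],
    )
    if scores is not None:
        by_pos = {s.position: s for s in scores}
        df["discordance"] = [by_pos[p].raw_score for p in df["position"]]
        df["p_value"] = [by_pos[p].p_value for p in df["position"]]
    return df


# --- alignment-column conservation ---------------------------------------

def column_identity(
    alignment_path,
    reference_id: str,
    reference_position: int,
    reference_start: int = 1,
) -> AlignmentColumn:
    """Conservation of the alignment column holding a reference residue.

    The column is located by counting the reference sequence's non-gap
    letters from ``reference_start``.  Identity is the fraction of
    sequences (reference included) carrying the reference's letter among
    those with a non-gap letter in the column.
    """
    from Bio import SeqIO

    records = list(SeqIO.parse(str(alignment_path), "fasta"))
    if not records:
        raise AlignmentError(f"no sequences in {alignment_path}")
    ref = next((r for r in records if r.id == reference_id), None)
    if ref is None:
        raise AlignmentError(f"reference id {reference_id!r} not in alignment")

    target_ordinal = reference_position - reference_start  # 0-based among non-gaps
    if target_ordinal < 0:
        raise AlignmentError(
            f"position {reference_position} precedes start {reference_start}"
        )
    seen = -1
    col = -1
    for i, letter in enumerate(str(ref.seq)):
        if letter != "-":
            seen += 1
            if seen == target_ordinal:
                col = i
                break
    if col < 0:
        raise AlignmentError(
            f"position {reference_position} beyond end of {reference_id}"
        )

    letters = {r.id: str(r.seq)[col].upper() for r in records}
    ref_letter = letters[reference_id]
    non_gap = [aa for aa in letters.values() if aa != "-"]
    identity = sum(1 for aa in non_gap if aa == ref_letter) / len(non_gap)
    return AlignmentColumn(reference_id, reference_position, col, letters, identity)
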