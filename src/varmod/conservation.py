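"""Per-column residue conservation via Jensen-Shannon divergence.

Each query-aligned column is summarised as a 20-way amino-acid frequency
profile and scored against a background distribution with the
Jensen-Shannon divergence (base-2 logarithms, so the divergence itself is
bounded by 1).  Gappy columns are down-weighted by ``1 - gap_fraction``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from varmod.core_io import AA20, AA_INDEX, Alignment

# BLOSUM62-derived background amino-acid frequencies, in AA20 order
# (A C D E F G H I K L M N P Q R S T V W Y); renormalised to sum to 1.
_BLOSUM62_BG = {
    "A": 0.078, "C": 0.024, "D": 0.052, "E": 0.059, "F": 0.044,
    "G": 0.083, "H": 0.025, "I": 0.062, "K": 0.056, "L": 0.092,
    "M": 0.024, "N": 0.041, "P": 0.043, "Q": 0.034, "R": 0.051,
    "S": 0.059, "T": 0.055, "V": 0.072, "W": 0.014, "Y": 0.034,
}

BLOSUM62_BACKGROUND = np.array([_BLOSUM62_BG[a] for a in AA20], dtype=float)
BLOSUM62_BACKGROUND /= BLOSUM62_BACKGROUND.sum()

UNIFORM_BACKGROUND = np.full(20, 1.0 / 20.0)


@dataclass(frozen=True)
class ColumnProfile:
    """Amino-acid frequency profile of one query-aligned column."""

    position: int  # 1-based query position
    freqs: np.ndarray  # 20-vector, unit sum over non-gap symbols
    gap_fraction: float

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if f.shape != (20,):
            raise ValueError("profile must be a 20-vector")
        if (f < 0).any():
            raise ValueError("profile frequencies must be >= 0")


@dataclass(frozen=True)
class ConservationScore:
    position: int
    score: float
    no_data: bool = False


def column_profile(alignment: Alignment, position: int) -> ColumnProfile:
    """Frequency profile of the alignment column aligned to a query position.

    Non-standard letters (including X, B, Z) are counted as gaps.
    """
    cols = alignment.query_columns()
    if not 1 <= position <= len(cols):
        raise IndexError(f"position {position} outside query length {len(cols)}")
    column = alignment.column(cols[position - 1])
    counts = np.zeros(20, dtype=float)
    gaps = 0
    for ch in column.upper():
        idx = AA_INDEX.get(ch)
        if idx is None:
            gaps += 1
        else:
            counts[idx] += 1.0
    total = counts.sum()
    freqs = counts / total if total > 0 else counts
    return ColumnProfile(
        position=position,
        freqs=freqs,
        gap_fraction=gaps / len(column),
    )


def jensen_shannon_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """JSD(p, q) = 1/2 KL(p||m) + 1/2 KL(q||m), m = (p+q)/2, log base 2.

    0 * log 0 is taken as 0.  Bounded in [0, 1].
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    m = 0.5 * (p + q)
    with np.errstate(divide="ignore", invalid="ignore"):
        kl_pm = np.where(p > 0, p * (np.log2(p) - np.log2(m)), 0.0)
        kl_qm = np.where(q > 0, q * (np.log2(q) - np.log2(m)), 0.0)
    return float(0.5 * kl_pm.sum() + 0.5 * kl_qm.sum())


def jsd_score(
    profile: ColumnProfile, background: np.ndarray = BLOSUM62_BACKGROUND
) -> ConservationScore:
    """Conservation score of one column: (1 - gap_fraction) * JSD(p, bg).

    All-gap columns get score 0 with the no-data flag raised.  The result
    is clamped to [0, 1].
    """
    background = np.asarray(background, dtype=float)
    if background.shape != (20,) or (background <= 0).any():
        raise ValueError("background must be a strictly positive 20-vector")
    if not np.isclose(background.sum(), 1.0):
        raise ValueError("background must sum to 1")
    if profile.gap_fraction >= 1.0 or profile.freqs.sum() == 0:
        return ConservationScore(profile.position, 0.0, no_data=True)
    raw = jensen_shannon_divergence(profile.freqs, background)
    score = (1.0 - profile.gap_fraction) * raw
    return ConservationScore(profile.position, float(np.clip(score, 0.0, 1.0)))


def conservation_track(
    alignment: Alignment,
    background: np.ndarray = BLOSUM62_BACKGROUND,
    window: int | None = None,
) -> list[ConservationScore]:
    """One conservation score per degapped query position.

    ``window`` optionally applies a centred moving average (endpoints
    truncated); off by default.
    """
    n = len(alignment.query_sequence)
    scores = [jsd_score(column_profile(alignment, pos), background)
              for pos in range(1, n + 1)]
    if window is None or window <= 1:
        return scores
    half = window // 2
    vals = np.array([s.score for s in scores])
    smoothed = []
    for i, s in enumerate(scores):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        smoothed.append(
            ConservationScore(s.position, float(vals[lo:hi].mean()), s.no_data)
        )
    return smoothed


def write_conservation_tsv(alignment: Alignment, scores, path) -> None:
    query = alignment.query_sequence
    with open(path, "w") as fh:
        fh.write("position\tresidue\tscore\n")
        for s in scores:
            fh.write(f"{s.position}\t{query[s.position - 1]}\t{s.score:.6f}\n")
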