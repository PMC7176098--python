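"""Hydropathy profiles, TMS prediction and MSA-level topology summaries.

The native TMS caller is a windowed-hydropathy peak finder: it is the
testable stand-in for an external topology predictor (HMMTOP-style), and
imported annotations always take precedence over predictions when supplied.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .core_io import ConfigError, ProteinRecord, RunConfig, TopologyAnnotation

#: Kyte-Doolittle hydropathy values
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

#: Goldman-Engelman-Steitz transfer free energies (kcal/mol, sign flipped
#: so that hydrophobic is positive, as for Kyte-Doolittle)
GES = {
    "F": 3.7, "M": 3.4, "I": 3.1, "L": 2.8, "V": 2.6, "C": 2.0, "W": 1.9,
    "A": 1.6, "T": 1.2, "G": 1.0, "S": 0.6, "P": -0.2, "Y": -0.7,
    "H": -3.0, "Q": -4.1, "N": -4.8, "E": -8.2, "K": -8.8, "D": -9.2,
    "R": -12.3,
}

SCALES: dict[str, dict[str, float]] = {
    "kyte-doolittle": KYTE_DOOLITTLE,
    "ges": GES,
}


@dataclass(frozen=True)
class HydropathyProfile:
    """Per-residue window-averaged hydropathy for one protein."""

    protein: str
    values: tuple[float, ...]
    scale: str
    window: int
    #: positions (0-based) where the averaging window was truncated by a
    #: sequence end
    truncated: tuple[int, ...] = ()


@dataclass(frozen=True)
class MsaProfile:
    """Per-column (avg hydropathy, avg similarity, gap fraction) of an MSA.

    Hydropathy is averaged over non-gap residues only; similarity is the
    mean pairwise substitution score of non-gap residues, min/max-normalised
    to [0, 1]; columns with fewer than two residues get similarity NaN.
    """

    avg_hydropathy: tuple[float, ...]
    avg_similarity: tuple[float, ...]
    gap_fraction: tuple[float, ...]
    n_sequences: int

    def __post_init__(self) -> None:
        if any(not (0.0 <= g <= 1.0) for g in self.gap_fraction):
            raise ValueError("gap fractions must lie in [0, 1]")


def _scale_values(scale: str) -> dict[str, float]:
    try:
        return SCALES[scale]
    except KeyError as exc:
        raise ConfigError(f"unknown hydropathy scale {scale!r}") from exc


def hydropathy_profile(record: ProteinRecord | str, scale: str = "kyte-doolittle",
                       window: int = 19) -> HydropathyProfile:
    """Window-averaged hydropathy; the window shrinks at sequence ends.

    Residues without a scale value (X and other non-standard letters)
    contribute 0.
    """
    seq = record.sequence if isinstance(record, ProteinRecord) else str(record).upper()
    name = record.accession if isinstance(record, ProteinRecord) else "seq"
    if window % 2 == 0 or window < 1:
        raise ConfigError("window must be odd")
    if window > len(seq):
        raise ConfigError("window exceeds sequence length")
    table = _scale_values(scale)
    vals = np.array([table.get(res, 0.0) for res in seq])
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    n = len(seq)
    out = np.empty(n)
    truncated = []
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = (csum[hi] - csum[lo]) / (hi - lo)
        if hi - lo < window:
            truncated.append(i)
    return HydropathyProfile(name, tuple(out.tolist()), scale, window,
                             truncated=tuple(truncated))


def predict_tms(profile: HydropathyProfile, config: RunConfig | None = None,
                ) -> TopologyAnnotation:
    """Call TMS intervals as hydrophobic peaks of a profile.

    Maximal runs with profile >= the peak threshold are found; runs
    separated by fewer than ``tms_merge_gap`` residues are merged; runs
    longer than ``tms_max_len`` are split recursively at their interior
    hydropathy minimum; finally runs shorter than ``tms_min_len`` are
    dropped.  Ordering (merge, split, then length filter) keeps fragments
    that belong to one helix together before any are discarded.
    """
    config = config or RunConfig()
    vals = np.asarray(profile.values)
    above = vals >= config.tms_peak
    runs: list[list[int]] = []
    i = 0
    n = len(vals)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            runs.append([i, j])
            i = j + 1
        else:
            i += 1
    # merge runs separated by short dips
    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 < config.tms_merge_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    # split over-long runs at interior minima
    final: list[tuple[int, int]] = []

    def _split(lo: int, hi: int) -> None:
        if hi - lo + 1 <= config.tms_max_len:
            final.append((lo, hi))
            return
        interior = vals[lo + 1: hi]
        cut = lo + 1 + int(np.argmin(interior))
        _split(lo, cut - 1)
        _split(cut + 1, hi)

    for lo, hi in merged:
        _split(lo, hi)
    intervals = tuple(
        (lo + 1, hi + 1) for lo, hi in final if hi - lo + 1 >= config.tms_min_len
    )
    return TopologyAnnotation(profile.protein, intervals, source="predicted",
                              sequence_length=n)


def msa_profile(rows: Sequence[str], scale: str = "kyte-doolittle",
                window: int = 1, matrix: str = "BLOSUM50") -> MsaProfile:
    """Average hydropathy / similarity / gap fraction per MSA column.

    ``window`` > 1 additionally smooths the per-column hydropathy with a
    centred moving average over columns (AveHAS-style curves).
    """
    if not rows:
        raise ValueError("empty MSA")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("MSA rows must have equal length")
    table = _scale_values(scale)
    mat = substitution_matrices.load(matrix)
    standard = [a for a in mat.alphabet if a in KYTE_DOOLITTLE]
    scores = np.array([[mat[a, b] for b in standard] for a in standard])
    s_min, s_max = scores.min(), scores.max()
    idx = {a: k for k, a in enumerate(standard)}

    hyd, sim, gaps = [], [], []
    for c in range(width):
        col = [r[c] for r in rows]
        residues = [a for a in col if a != "-"]
        gaps.append(1.0 - len(residues) / len(rows))
        hyd.append(
            float(np.mean([table.get(a, 0.0) for a in residues])) if residues else 0.0
        )
        known = [idx[a] for a in residues if a in idx]
        if len(known) >= 2:
            pair_scores = [
                scores[known[i], known[j]]
                for i in range(len(known)) for j in range(i + 1, len(known))
            ]
            sim.append(float((np.mean(pair_scores) - s_min) / (s_max - s_min)))
        else:
            sim.append(float("nan"))
    hyd_arr = np.array(hyd)
    if window > 1:
        if window % 2 == 0:
            raise ConfigError("smoothing window must be odd")
        half = window // 2
        csum = np.concatenate([[0.0], np.cumsum(hyd_arr)])
        hyd_arr = np.array([
            (csum[min(width, i + half + 1)] - csum[max(0, i - half)])
            / (min(width, i + half + 1) - max(0, i - half))
            for i in range(width)
        ])
    return MsaProfile(tuple(hyd_arr.tolist()), tuple(sim), tuple(gaps), len(rows))


def trim_msa(rows: Sequence[str], max_gap_fraction: float = 0.30) -> list[str]:
    """Remove MSA columns whose gap fraction is >= ``max_gap_fraction``.

    Keeps positions with *less than* the threshold fraction of gaps (so a
    column exactly at the threshold is removed).  Row order is preserved;
    idempotent.
    """
    if not rows:
        return []
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("MSA rows must have equal length")
    n = len(rows)
    keep = [
        c for c in range(width)
        if sum(r[c] == "-" for r in rows) / n < max_gap_fraction
    ]
    return ["".join(r[c] for c in keep) for r in rows]


def classify_tms(record: ProteinRecord | str, interval: tuple[int, int],
                 scale: str = "kyte-doolittle",
                 simple_entropy: float = 2.0, complex_entropy: float = 3.0,
                 simple_hydropathy: float = 2.0, twilight_hydropathy: float = 1.0,
                 ) -> str:
    """Classify a TMS segment as ``simple``, ``twilight`` or ``complex``.

    An approximation of TMSOC-style classification from two measures of the
    segment: mean hydropathy and Shannon entropy (bits, 20-letter alphabet).
    Highly hydrophobic, low-complexity segments are *simple* (bias-prone,
    weak homology evidence); segments with both measures in an intermediate
    band are *twilight*; everything else is *complex*.
    """
    seq = record.sequence if isinstance(record, ProteinRecord) else str(record).upper()
    start, end = interval
    if not (1 <= start <= end <= len(seq)):
        raise ValueError(f"interval {interval} out of bounds for length {len(seq)}")
    segment = seq[start - 1: end]
    table = _scale_values(scale)
    mean_h = float(np.mean([table.get(a, 0.0) for a in segment]))
    counts = Counter(segment)
    total = len(segment)
    entropy = -sum((c / total) * math.log2(c / total) for c in counts.values())
    if entropy < simple_entropy and mean_h > simple_hydropathy:
        return "simple"
    if (simple_entropy <= entropy <= complex_entropy
            or twilight_hydropathy <= mean_h <= simple_hydropathy):
        return "twilight"
    return "complex"


def write_profile_tsv(profile: HydropathyProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {profile.protein}\tscale={profile.scale}\twindow={profile.window}\n")
        fh.write("# position\thydropathy\ttruncated\n")
        trunc = set(profile.truncated)
        for i, v in enumerate(profile.values):
            fh.write(f"{i + 1}\t{v:.4f}\t{int(i in trunc)}\n")
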