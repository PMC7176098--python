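"""Local pairwise alignment with shuffle-calibrated significance.

Smith-Waterman alignment with affine gaps is delegated to Biopython's
C-backed :class:`Bio.Align.PairwiseAligner`; this module owns the scoring
conventions, the deterministic tie-break among co-optimal alignments, the
shuffle-based E-value calibration (Gumbel maximum-likelihood fit to scores
against composition-preserving shuffles), bit-score conversion, and greedy
redundancy reduction.

Gap convention: a gap of length L costs ``gap_open + L * gap_extend``
(the SSEARCH/FASTA convention for "-10/-2" penalties).
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.stats import gumbel_r

from .core_io import ConfigError, ProteinRecord, RunConfig

#: residues absent from the BLOSUM alphabets, scored as X
_TO_X = str.maketrans("UOJ*", "XXXX")

#: ungapped Karlin-Altschul (lambda, K) constants per matrix, used for
#: bit-score conversion when no empirical Gumbel fit is supplied
KARLIN_ALTSCHUL: dict[str, tuple[float, float]] = {
    "BLOSUM50": (0.232, 0.112),
    "BLOSUM62": (0.318, 0.134),
    "BLOSUM80": (0.343, 0.177),
}

#: cap on co-optimal alignments examined for the deterministic tie-break
_MAX_COOPTIMAL = 100


@dataclass(frozen=True)
class GumbelFit:
    """Extreme-value parameters fitted to shuffled alignment scores."""

    mu: float        # location
    lam: float       # scale parameter, 1/beta in scipy's parametrisation
    n_samples: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate and self.lam <= 0:
            raise ValueError("Gumbel scale parameter must be positive")

    def sf(self, score: float) -> float:
        """P(S >= score) under the fitted null."""
        if self.degenerate:
            return 1.0 / self.n_samples
        return float(gumbel_r.sf(score, loc=self.mu, scale=1.0 / self.lam))


@dataclass(frozen=True)
class LocalAlignment:
    """A scored local pairwise alignment.

    Coordinates are 1-based inclusive; an empty alignment (no positive-
    scoring cell) has zero coordinates and empty aligned strings.
    ``coverage_shorter`` is the number of alignment columns (gaps included)
    divided by the length of the shorter sequence — the quantity the 40%
    screening criterion is applied to.
    """

    query: str
    subject: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    q_aln: str
    s_aln: str
    raw_score: float
    bit_score: float
    identity: float
    coverage_shorter: float
    evalue: float | None = None
    z_score: float | None = None
    shuffles: int = 0
    evalue_is_bound: bool = False

    def __post_init__(self) -> None:
        if len(self.q_aln) != len(self.s_aln):
            raise ValueError("aligned strings must have equal length")
        if self.raw_score < 0:
            raise ValueError("local alignment raw score cannot be negative")
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError("identity must lie in [0, 1]")
        if self.evalue is not None and self.evalue <= 0:
            raise ValueError("computed E-value must be positive")

    @property
    def n_columns(self) -> int:
        return len(self.q_aln)

    @property
    def is_empty(self) -> bool:
        return self.n_columns == 0


@lru_cache(maxsize=8)
def _make_aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    try:
        mat = substitution_matrices.load(matrix)
    except FileNotFoundError as exc:
        raise ConfigError(f"unknown substitution matrix {matrix!r}") from exc
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = mat
    # Biopython charges open_gap_score for the first gap residue; fold one
    # extension in so a length-L gap costs gap_open + L * gap_extend.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _seq(x: ProteinRecord | str) -> str:
    s = x.sequence if isinstance(x, ProteinRecord) else str(x).upper()
    return s.translate(_TO_X)


def _acc(x: ProteinRecord | str, default: str) -> str:
    return x.accession if isinstance(x, ProteinRecord) else default


def raw_score(seq_a: ProteinRecord | str, seq_b: ProteinRecord | str,
              config: RunConfig) -> float:
    """Optimal local alignment score only (no traceback); fast path."""
    a, b = _seq(seq_a), _seq(seq_b)
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aligner = _make_aligner(config.matrix, config.gap_open, config.gap_extend)
    return float(aligner.score(a, b))


def smith_waterman(seq_a: ProteinRecord | str, seq_b: ProteinRecord | str,
                   config: RunConfig) -> LocalAlignment:
    """Optimal local alignment of two sequences under affine-gap scoring.

    Deterministic: among co-optimal alignments the one ending at the
    smallest ``(q_end, s_end)`` (lexicographic) is returned, examining at
    most 100 co-optimal candidates.
    """
    a, b = _seq(seq_a), _seq(seq_b)
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aligner = _make_aligner(config.matrix, config.gap_open, config.gap_extend)
    score = float(aligner.score(a, b))
    name_a, name_b = _acc(seq_a, "query"), _acc(seq_b, "subject")
    if score <= 0:
        return LocalAlignment(name_a, name_b, 0, 0, 0, 0, "", "", 0.0,
                              bit_score=bit_score(0.0, config), identity=0.0,
                              coverage_shorter=0.0)
    alignments = aligner.align(a, b)
    best = min(
        itertools.islice(alignments, _MAX_COOPTIMAL),
        key=lambda aln: (int(aln.coordinates[0][-1]), int(aln.coordinates[1][-1])),
    )
    coords = best.coordinates
    q_start, q_end = int(coords[0][0]) + 1, int(coords[0][-1])
    s_start, s_end = int(coords[1][0]) + 1, int(coords[1][-1])
    q_aln, s_aln = str(best[0]), str(best[1])
    matches = sum(1 for x, y in zip(q_aln, s_aln) if x == y and x != "-")
    identity = matches / len(q_aln)
    coverage = len(q_aln) / min(len(a), len(b))
    return LocalAlignment(
        name_a, name_b, q_start, q_end, s_start, s_end, q_aln, s_aln,
        raw_score=score, bit_score=bit_score(score, config),
        identity=identity, coverage_shorter=coverage,
    )


def bit_score(raw: float, config_or_params: RunConfig | tuple[float, float] | GumbelFit,
              ) -> float:
    """Convert a raw alignment score to bits: ``(lambda*S - ln K) / ln 2``.

    ``config_or_params`` may be a :class:`RunConfig` (published matrix
    constants looked up by name), an explicit ``(lambda, K)`` pair, or a
    :class:`GumbelFit` (whose location/scale imply lambda and K).
    """
    if isinstance(config_or_params, RunConfig):
        try:
            lam, k = KARLIN_ALTSCHUL[config_or_params.matrix]
        except KeyError as exc:
            raise ConfigError(
                f"no published (lambda, K) constants for {config_or_params.matrix!r}; "
                "supply a GumbelFit"
            ) from exc
    elif isinstance(config_or_params, GumbelFit):
        fit = config_or_params
        if fit.degenerate:
            raise ConfigError("cannot derive bit scores from a degenerate fit")
        # Gumbel sf ~ K' exp(-lambda S) in the tail with lambda = fit.lam
        lam, k = fit.lam, float(np.exp(fit.lam * fit.mu))
    else:
        lam, k = config_or_params
    return (lam * raw - np.log(k)) / np.log(2.0)


def _pair_rng(seed: int, *keys: str) -> np.random.Generator:
    """Deterministic RNG for one sequence pair, independent of call order."""
    digest = zlib.crc32("\x1f".join(keys).encode())
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, digest]))


def shuffle_evalue(
    seq_a: ProteinRecord | str,
    seq_b: ProteinRecord | str,
    observed_score: float,
    config: RunConfig,
    kprime: int = 1,
    rng: np.random.Generator | None = None,
) -> tuple[float, float, GumbelFit]:
    """Significance of an observed score against shuffles of ``seq_b``.

    ``seq_b`` is permuted uniformly (composition-preserving) ``config.shuffles``
    times; a Gumbel distribution is fitted to the shuffled optimal scores by
    maximum likelihood, and ``evalue = kprime * P(S >= observed)`` where
    ``kprime`` is the number of pairwise comparisons in the search context
    (1 for a single pair).  Returns ``(evalue, z_score, fit)``.

    If the score distribution is degenerate (zero variance) the E-value is
    reported as the ``kprime / K`` upper bound and the fit is flagged.
    """
    if config.shuffles < 1:
        raise ConfigError("E-value requested with zero shuffles")
    a, b = _seq(seq_a), _seq(seq_b)
    if rng is None:
        rng = _pair_rng(config.seed, a, b)
    aligner = _make_aligner(config.matrix, config.gap_open, config.gap_extend)
    b_arr = np.frombuffer(b.encode(), dtype="S1")
    scores = np.empty(config.shuffles)
    for i in range(config.shuffles):
        shuffled = rng.permutation(b_arr).tobytes().decode()
        scores[i] = aligner.score(a, shuffled)
    mean, sd = float(scores.mean()), float(scores.std(ddof=1)) if len(scores) > 1 else 0.0
    if sd == 0.0:
        fit = GumbelFit(mu=mean, lam=0.0, n_samples=config.shuffles, degenerate=True)
        evalue = kprime / config.shuffles
        z = float("inf") if observed_score > mean else 0.0
        return evalue, z, fit
    loc, scale = gumbel_r.fit(scores)
    fit = GumbelFit(mu=float(loc), lam=1.0 / float(scale), n_samples=config.shuffles)
    evalue = kprime * fit.sf(observed_score)
    evalue = max(evalue, 1e-300)  # keep strictly positive under underflow
    z = (observed_score - mean) / sd
    return float(evalue), float(z), fit


def align_with_evalue(
    seq_a: ProteinRecord | str,
    seq_b: ProteinRecord | str,
    config: RunConfig,
    kprime: int = 1,
) -> LocalAlignment:
    """Full alignment plus shuffle-calibrated E-value in one call."""
    aln = smith_waterman(seq_a, seq_b, config)
    if aln.is_empty:
        return aln
    evalue, z, fit = shuffle_evalue(seq_a, seq_b, aln.raw_score, config, kprime=kprime)
    return LocalAlignment(
        aln.query, aln.subject, aln.q_start, aln.q_end, aln.s_start, aln.s_end,
        aln.q_aln, aln.s_aln, aln.raw_score, aln.bit_score, aln.identity,
        aln.coverage_shorter, evalue=evalue, z_score=z, shuffles=config.shuffles,
        evalue_is_bound=fit.degenerate,
    )


def reduce_redundancy(
    records: Sequence[ProteinRecord],
    identity_threshold: float = 0.90,
    coverage_threshold: float = 0.80,
    config: RunConfig | None = None,
) -> list[ProteinRecord]:
    """Greedy longest-first redundancy reduction (CD-HIT style).

    Records are considered longest-first; a record joins an existing
    representative when their local alignment has identity >= the threshold
    over >= ``coverage_threshold`` of the shorter sequence.  Representatives
    are returned in input order.
    """
    if not (0.0 < identity_threshold <= 1.0):
        raise ValueError("identity threshold must be in (0, 1]")
    config = config or RunConfig()
    order = sorted(range(len(records)), key=lambda i: -len(records[i]))
    reps: list[int] = []
    for i in order:
        redundant = False
        for j in reps:
            aln = smith_waterman(records[i], records[j], config)
            if (not aln.is_empty
                    and aln.identity >= identity_threshold
                    and aln.coverage_shorter >= coverage_threshold):
                redundant = True
                break
        if not redundant:
            reps.append(i)
    return [records[i] for i in sorted(reps)]


def write_alignment_tsv(alignments: Iterable[LocalAlignment], path) -> None:
    with open(path, "w") as fh:
        fh.write("# query\tsubject\tq_start\tq_end\ts_start\ts_end\traw\tbits\t"
                 "identity%\tcoverage%\tevalue\tz\tshuffles\n")
        for a in alignments:
            ev = f"{a.evalue:.3g}" if a.evalue is not None else "NA"
            z = f"{a.z_score:.2f}" if a.z_score is not None else "NA"
            fh.write(
                f"{a.query}\t{a.subject}\t{a.q_start}\t{a.q_end}\t{a.s_start}\t"
                f"{a.s_end}\t{a.raw_score:.0f}\t{a.bit_score:.1f}\t"
                f"{100*a.identity:.1f}\t{100*a.coverage_shorter:.1f}\t{ev}\t{z}\t"
                f"{a.shuffles}\n"
            )
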