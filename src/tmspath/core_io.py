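"""Domain types and readers/writers shared by every pipeline stage.

Coordinate convention: every residue coordinate in this package is 1-based
and inclusive, matching the conventions of HMMTOP output and HMMER's
domtblout envelope columns.  Parsers that consume 0-based formats convert
at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SearchIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("tmspath")

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
#: residues kept in records but scored as X under the substitution matrix
NONSTANDARD = set("BZUOJX*")
GAP_CHARS = set("-.")


class ParseError(ValueError):
    """Malformed input file."""


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with an accession and optional family label."""

    accession: str
    sequence: str
    description: str = ""
    family: str | None = None

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        if not self.sequence:
            raise ValueError(f"{self.accession}: sequence must be non-empty")
        seq = self.sequence.upper()
        bad = set(seq) - AMINO_ACIDS - NONSTANDARD
        if bad & GAP_CHARS:
            raise ValueError(f"{self.accession}: gap characters not allowed in a sequence")
        if bad:
            raise ValueError(f"{self.accession}: invalid residues {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)
        if set(seq) & NONSTANDARD:
            logger.debug("%s contains non-standard residues (scored as X)", self.accession)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TopologyAnnotation:
    """Ordered transmembrane-segment intervals on one protein.

    ``tms`` holds (start, end) residue intervals, 1-based inclusive, sorted
    and non-overlapping.  ``source`` records provenance: *predicted* by the
    native hydropathy caller, *imported* from an external predictor, or
    *planted* by the synthetic-family generator (ground truth).
    """

    protein: str
    tms: tuple[tuple[int, int], ...]
    source: str = "predicted"
    sequence_length: int | None = None

    def __post_init__(self) -> None:
        if self.source not in {"predicted", "imported", "planted"}:
            raise ValueError(f"unknown topology source {self.source!r}")
        tms = tuple((int(a), int(b)) for a, b in self.tms)
        prev_end = 0
        for start, end in tms:
            if start < 1 or end < start:
                raise ValueError(f"{self.protein}: invalid TMS interval ({start}, {end})")
            if start <= prev_end:
                raise ValueError(f"{self.protein}: overlapping or unsorted TMS intervals")
            prev_end = end
        if self.sequence_length is not None and tms and tms[-1][1] > self.sequence_length:
            raise ValueError(
                f"{self.protein}: TMS interval {tms[-1]} exceeds sequence length "
                f"{self.sequence_length}"
            )
        object.__setattr__(self, "tms", tms)

    @property
    def n_tms(self) -> int:
        return len(self.tms)


@dataclass(frozen=True)
class DomainHit:
    """A domain (e.g. Pfam) hit on a protein, direct or projected."""

    protein: str
    domain_acc: str
    env_start: int
    env_end: int
    evalue: float
    clan: str | None = None
    origin: str = "direct"
    projected_from: str | None = None

    def __post_init__(self) -> None:
        if self.origin not in {"direct", "projected"}:
            raise ValueError(f"unknown hit origin {self.origin!r}")
        if not (1 <= self.env_start <= self.env_end):
            raise ValueError(
                f"{self.protein}/{self.domain_acc}: invalid envelope "
                f"({self.env_start}, {self.env_end})"
            )
        if self.origin == "projected" and not self.projected_from:
            raise ValueError("projected hit must record its donor (projected_from)")


@dataclass
class RunConfig:
    """Global thresholds and scoring parameters for a run.

    The defaults mirror the screening protocol of the underlying method:
    BLAST-level candidate screening at E < 1e-4 with >= 40% coverage of the
    shorter sequence, 90% identity redundancy reduction, Smith-Waterman
    E-values from 1000 composition-preserving shuffles, and E < 1e-5
    throughout a transitivity path with >= 3 aligned TMSs.
    """

    matrix: str = "BLOSUM50"
    gap_open: float = 10.0
    gap_extend: float = 2.0
    shuffles: int = 1000
    seed: int = 0
    # hydropathy / TMS calling
    scale: str = "kyte-doolittle"
    window: int = 19
    tms_peak: float = 1.0
    tms_min_len: int = 15
    tms_max_len: int = 30
    tms_merge_gap: int = 4
    # screening (criterion 1 pre-filter)
    screen_evalue: float = 1e-4
    screen_coverage: float = 0.40
    redundancy_identity: float = 0.90
    # transitivity path
    path_evalue: float = 1e-5
    min_aligned_tms: int = 3
    tms_overlap_fraction: float = 0.5
    # repeats
    repeat_evalue: float = 1e-3
    bundle_flank: int = 5
    # domain projection
    projection_evalue: float = 1e-5
    projection_coverage: float = 0.40

    def __post_init__(self) -> None:
        if self.shuffles < 1:
            raise ConfigError("shuffle count must be >= 1 when E-values are requested")
        if self.window < 5 or self.window % 2 == 0:
            raise ConfigError("hydropathy window must be odd and >= 5")

    def log(self, stage: str) -> None:
        """Log the thresholds in effect so a run is reconstructable."""
        logger.info(
            "%s: matrix=%s gaps=%g/%g shuffles=%d seed=%d screen(E<%g,cov>=%g) "
            "path(E<%g,tms>=%d)",
            stage, self.matrix, self.gap_open, self.gap_extend, self.shuffles,
            self.seed, self.screen_evalue, self.screen_coverage,
            self.path_evalue, self.min_aligned_tms,
        )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, family: str | None = None) -> list[ProteinRecord]:
    """Read protein records from a FASTA file.

    Sequences are uppercased; gap characters and duplicate accessions are
    rejected.  An empty file yields an empty list with a warning.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if set(seq) & GAP_CHARS:
            raise ParseError(
                f"{path}: gap characters in sequence {rec.id!r} "
                f"(near line {_find_header_line(path, rec.id)})"
            )
        if rec.id in seen:
            raise ParseError(
                f"{path}: duplicate accession {rec.id!r} "
                f"(near line {_find_header_line(path, rec.id)})"
            )
        seen[rec.id] = 1
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        try:
            records.append(ProteinRecord(rec.id, seq, desc, family=family))
        except ValueError as exc:
            raise ParseError(
                f"{path}: {exc} (near line {_find_header_line(path, rec.id)})"
            ) from exc
    if not records:
        logger.warning("%s: no FASTA records found", path)
    return records


def _find_header_line(path: Path, accession: str) -> int:
    """Best-effort line number of a FASTA header, for error messages."""
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if line.startswith(">") and line[1:].split()[0:1] == [accession]:
                return i
    return 0


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.accession, description=r.description)
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Topology


def read_topology(
    path: str | Path,
    dialect: str = "hmmtop",
    sequence_lengths: dict[str, int] | None = None,
) -> list[TopologyAnnotation]:
    """Read TMS annotations from HMMTOP one-line output or a simple TSV.

    The TSV dialect has one interval per row: ``accession<TAB>start<TAB>end``
    (1-based inclusive).  Both dialects produce ``source="imported"``.
    """
    path = Path(path)
    if dialect == "hmmtop":
        per_protein = _parse_hmmtop(path)
    elif dialect == "tsv":
        per_protein = _parse_topology_tsv(path)
    else:
        raise ConfigError(f"unknown topology dialect {dialect!r}")
    out = []
    for acc, intervals in per_protein.items():
        length = sequence_lengths.get(acc) if sequence_lengths else None
        out.append(
            TopologyAnnotation(acc, tuple(intervals), source="imported", sequence_length=length)
        )
    return out


def _parse_hmmtop(path: Path) -> dict[str, list[tuple[int, int]]]:
    # one-line format: ">HP: <len> <name> [desc]  IN|OUT  <N>  <2N positions>"
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if not line.startswith(">HP:"):
                raise ParseError(f"{path}:{lineno}: not an HMMTOP one-line record")
            tokens = line[4:].split()
            side_idx = None
            for i, tok in enumerate(tokens):
                if tok in {"IN", "OUT"}:
                    side_idx = i
            if side_idx is None or side_idx + 1 >= len(tokens):
                raise ParseError(f"{path}:{lineno}: missing IN/OUT field")
            acc = tokens[1]
            try:
                n = int(tokens[side_idx + 1])
                coords = [int(t) for t in tokens[side_idx + 2: side_idx + 2 + 2 * n]]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed helix coordinates") from exc
            if len(coords) != 2 * n:
                raise ParseError(f"{path}:{lineno}: expected {2*n} coordinates")
            out[acc] = [(coords[i], coords[i + 1]) for i in range(0, 2 * n, 2)]
    return out


def _parse_topology_tsv(path: Path) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected 'accession start end'")
            acc, start, end = parts[0], int(parts[1]), int(parts[2])
            out.setdefault(acc, []).append((start, end))
    return out


def write_topology_tsv(annotations: Iterable[TopologyAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# accession\tstart\tend\tsource\n")
        for ann in annotations:
            for start, end in ann.tms:
                fh.write(f"{ann.protein}\t{start}\t{end}\t{ann.source}\n")


# ---------------------------------------------------------------------------
# Domain hits (HMMER3 domtblout)


def read_domtblout(
    path: str | Path, clans: dict[str, str] | None = None
) -> list[DomainHit]:
    """Read per-domain hits from HMMER3 ``--domtblout`` output (hmmscan).

    One :class:`DomainHit` per domain row, using envelope coordinates and
    the independent (i-)E-value.  Domain accession versions are stripped
    (``PF03773.15`` -> ``PF03773``).  ``clans`` optionally maps domain
    accessions to clan identifiers (domtblout itself carries none).
    """
    path = Path(path)
    hits: list[DomainHit] = []
    try:
        results = list(SearchIO.parse(str(path), "hmmscan3-domtab"))
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    for qresult in results:
        for hit in qresult:
            acc = hit.accession.split(".")[0] if hit.accession != "-" else hit.id
            for hsp in hit:
                hits.append(
                    DomainHit(
                        protein=qresult.id,
                        domain_acc=acc,
                        env_start=hsp.env_start + 1,  # SearchIO is 0-based
                        env_end=hsp.env_end,
                        evalue=hsp.evalue,
                        clan=(clans or {}).get(acc),
                        origin="direct",
                    )
                )
    return hits


# ---------------------------------------------------------------------------
# Family membership tables


def read_family_table(path: str | Path) -> dict[str, str]:
    """Read ``accession<TAB>family`` rows into a mapping."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 'accession<TAB>family'")
            out[parts[0]] = parts[1]
    return out


def attach_families(
    records: Sequence[ProteinRecord], families: dict[str, str]
) -> list[ProteinRecord]:
    return [
        ProteinRecord(r.accession, r.sequence, r.description,
                      family=families.get(r.accession, r.family))
        for r in records
    ]


# ---------------------------------------------------------------------------
# Aligned FASTA (MSA)


def read_msa(path: str | Path) -> tuple[list[str], list[str]]:
    """Read an aligned FASTA file; returns (labels, rows).

    All rows must have equal length; gaps are '-' or '.'.
    """
    labels, rows = [], []
    for rec in SeqIO.parse(str(Path(path)), "fasta"):
        labels.append(rec.id)
        rows.append(str(rec.seq).upper().replace(".", "-"))
    if rows and len({len(r) for r in rows}) != 1:
        raise ParseError(f"{path}: MSA rows have unequal lengths")
    return labels, rows


def write_msa(labels: Sequence[str], rows: Sequence[str], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(r), id=l, description="") for l, r in zip(labels, rows)]
    SeqIO.write(seqs, str(path), "fasta")
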