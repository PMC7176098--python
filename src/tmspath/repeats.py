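"""Detection of internal TMS repeat units (tmsRepeat-style).

A protein's TMSs are cut into contiguous bundles of a predefined size
(e.g. 4, the ancestral repeat-unit size in many transporter superfamilies);
non-overlapping bundles are aligned locally against each other, and
significant alignments evidence an intragenic duplication.  The
cross-protein variant compares bundles of two homologs at *offset* TMS
positions, which can reveal a repeat even when neither protein retains a
clean internal signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .align import LocalAlignment, align_with_evalue
from .core_io import ProteinRecord, RunConfig, TopologyAnnotation


@dataclass(frozen=True)
class BundleSlice:
    """A contiguous window of k TMSs, with flanking residues."""

    protein: str
    tms_indices: tuple[int, ...]   # 1-based TMS ordinals, contiguous
    seq_start: int                 # residue coordinates incl. flanks, 1-based
    seq_end: int

    def __post_init__(self) -> None:
        idx = self.tms_indices
        if any(b - a != 1 for a, b in zip(idx, idx[1:])):
            raise ValueError("bundle TMS ordinals must be contiguous")
        if not (1 <= self.seq_start <= self.seq_end):
            raise ValueError("invalid bundle residue span")

    def overlaps(self, other: "BundleSlice") -> bool:
        return not (self.seq_end < other.seq_start or other.seq_end < self.seq_start)


@dataclass(frozen=True)
class RepeatHit:
    """A significant alignment between two TMS bundles.

    ``intra_protein`` marks hits from a within-protein search, whose
    bundles must not overlap in residue coordinates; cross-protein hits
    may cover the same residue range on two (even identical) homologs.
    """

    bundle_1: BundleSlice
    bundle_2: BundleSlice
    alignment: LocalAlignment
    intra_protein: bool = False

    def __post_init__(self) -> None:
        if self.intra_protein and self.bundle_1.overlaps(self.bundle_2):
            raise ValueError("intra-protein repeat bundles must not overlap")


def enumerate_bundles(record: ProteinRecord, topology: TopologyAnnotation,
                      k: int, flank: int = 5) -> list[BundleSlice]:
    """All contiguous windows of ``k`` TMSs, spans extended by ``flank``.

    A protein with n TMSs yields n-k+1 bundles (empty list if n < k).
    Spans are clamped to sequence bounds.
    """
    if k < 1:
        raise ValueError("bundle size must be >= 1")
    tms = topology.tms
    out = []
    for i in range(len(tms) - k + 1):
        start = max(1, tms[i][0] - flank)
        end = min(len(record), tms[i + k - 1][1] + flank)
        out.append(BundleSlice(record.accession, tuple(range(i + 1, i + k + 1)),
                               start, end))
    return out


def _bundle_record(record: ProteinRecord, bundle: BundleSlice) -> ProteinRecord:
    return ProteinRecord(
        f"{record.accession}[{bundle.tms_indices[0]}-{bundle.tms_indices[-1]}]",
        record.sequence[bundle.seq_start - 1: bundle.seq_end],
    )


def find_repeats(record: ProteinRecord, topology: TopologyAnnotation, k: int,
                 config: RunConfig | None = None) -> list[RepeatHit]:
    """Align every non-overlapping bundle pair within one protein.

    Hits with E-value <= ``config.repeat_evalue`` are returned sorted by
    E-value.  Reported hits never overlap in residue coordinates.
    """
    config = config or RunConfig()
    bundles = enumerate_bundles(record, topology, k, flank=config.bundle_flank)
    hits: list[RepeatHit] = []
    for i in range(len(bundles)):
        for j in range(i + 1, len(bundles)):
            if bundles[i].overlaps(bundles[j]):
                continue
            aln = align_with_evalue(
                _bundle_record(record, bundles[i]),
                _bundle_record(record, bundles[j]),
                config,
            )
            if aln.evalue is not None and aln.evalue <= config.repeat_evalue:
                hits.append(RepeatHit(bundles[i], bundles[j], aln,
                                      intra_protein=True))
    hits.sort(key=lambda h: h.alignment.evalue)
    return hits


def cross_repeat(record_a: ProteinRecord, topo_a: TopologyAnnotation,
                 record_b: ProteinRecord, topo_b: TopologyAnnotation,
                 k: int, config: RunConfig | None = None) -> list[RepeatHit]:
    """Align bundles of two homologs at offset TMS positions.

    Pairs whose TMS ordinal ranges are identical are excluded — only
    offset pairs (e.g. TMSs 1-4 of A against 5-8 of B) evidence an internal
    repeat rather than plain homology.  Sorted by E-value.
    """
    config = config or RunConfig()
    bundles_a = enumerate_bundles(record_a, topo_a, k, flank=config.bundle_flank)
    bundles_b = enumerate_bundles(record_b, topo_b, k, flank=config.bundle_flank)
    hits: list[RepeatHit] = []
    for ba in bundles_a:
        for bb in bundles_b:
            if ba.tms_indices == bb.tms_indices:
                continue
            aln = align_with_evalue(
                _bundle_record(record_a, ba), _bundle_record(record_b, bb), config
            )
            if aln.evalue is not None and aln.evalue <= config.repeat_evalue:
                hits.append(RepeatHit(ba, bb, aln))
    hits.sort(key=lambda h: h.alignment.evalue)
    return hits


def write_repeat_tsv(hits: Sequence[RepeatHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("# protein1\ttms1\tspan1\tprotein2\ttms2\tspan2\tevalue\t"
                 "identity%\tcoverage%\n")
        for h in hits:
            b1, b2, a = h.bundle_1, h.bundle_2, h.alignment
            fh.write(
                f"{b1.protein}\t{b1.tms_indices[0]}-{b1.tms_indices[-1]}\t"
                f"{b1.seq_start}-{b1.seq_end}\t"
                f"{b2.protein}\t{b2.tms_indices[0]}-{b2.tms_indices[-1]}\t"
                f"{b2.seq_start}-{b2.seq_end}\t"
                f"{a.evalue:.3g}\t{100*a.identity:.1f}\t{100*a.coverage_shorter:.1f}\n"
            )
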