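"""Synthetic membrane-protein families with known evolutionary history.

Proteins are built as alternating hydrophilic loops and hydrophobic
transmembrane segments (TMSs), then evolved by the events this methodology
reasons about: intragenic duplication of a TMS bundle (4 -> 4+4), loss of
the N-terminal TMS (4+4 -> 3+4), insertion of central TMSs (4+N+4), and
fusion with an unrelated unit.  Point substitutions are drawn with
probabilities proportional to substitution-matrix exchangeability; indels
are confined to loops so planted TMS coordinates remain exact ground truth
(TMS gain/loss is an explicit event, not drift).

Every output is reproducible from ``(spec, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import numpy as np
from Bio.Align import substitution_matrices

from .core_io import ProteinRecord, TopologyAnnotation

HYDROPHOBIC = "ILVFAM"
HYDROPHILIC = "DEKRNQSTGPH"
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

# residue-usage weights approximating real membrane proteins: TM helices
# are Leu/Ile/Val/Phe-rich, loops Gly/Ser/Thr/Pro-rich with charged residues
_TMS_WEIGHTS = (0.20, 0.30, 0.20, 0.15, 0.10, 0.05)          # I L V F A M
_LOOP_WEIGHTS = (0.08, 0.08, 0.08, 0.05, 0.08, 0.08, 0.15, 0.10, 0.15, 0.10, 0.05)

TMS_LEN = (18, 24)    # inclusive range of planted TMS lengths
LOOP_LEN = (8, 40)    # inclusive range of planted loop lengths


@dataclass(frozen=True)
class FamilySpec:
    """Recipe for one synthetic family.

    ``events`` are applied in order to the ancestral unit before members
    diverge; each member then receives independent per-site substitutions
    at ``mutation_prob`` and loop-confined indels at ``indel_prob`` per
    loop residue.
    """

    ancestral_tms: int = 4
    events: tuple = ()            # e.g. ("duplicate",), ("duplicate", "lose_n_terminal_tms")
    n_members: int = 4
    mutation_prob: float = 0.2
    indel_prob: float = 0.01
    seed: int = 0
    label: str = "FAM"

    def __post_init__(self) -> None:
        if not (0.0 <= self.mutation_prob < 1.0 and 0.0 <= self.indel_prob < 1.0):
            raise ValueError("probabilities must lie in [0, 1)")
        n = self.ancestral_tms
        for ev in self.events:
            kind = ev[0] if isinstance(ev, tuple) else ev
            if kind == "duplicate":
                n *= 2
            elif kind == "lose_n_terminal_tms":
                n -= 1
            elif kind == "insert_central_tms":
                n += ev[1]
            elif kind == "fuse":
                n += self.ancestral_tms
            else:
                raise ValueError(f"unknown event {ev!r}")
        if n < 1:
            raise ValueError("event list leaves no TMSs")


# internal representation: alternating ("loop"|"tms", sequence) pieces
_Pieces = list[tuple[str, str]]


def _rng(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *tags]))


def _draw_tms(rng: np.random.Generator) -> str:
    length = int(rng.integers(TMS_LEN[0], TMS_LEN[1] + 1))
    return "".join(rng.choice(list(HYDROPHOBIC), size=length, p=_TMS_WEIGHTS))


def _draw_loop(rng: np.random.Generator) -> str:
    length = int(rng.integers(LOOP_LEN[0], LOOP_LEN[1] + 1))
    return "".join(rng.choice(list(HYDROPHILIC), size=length, p=_LOOP_WEIGHTS))


def _draw_unit(n_tms: int, rng: np.random.Generator) -> _Pieces:
    pieces: _Pieces = [("loop", _draw_loop(rng))]
    for _ in range(n_tms):
        pieces.append(("tms", _draw_tms(rng)))
        pieces.append(("loop", _draw_loop(rng)))
    return pieces


def _merge_loops(pieces: _Pieces) -> _Pieces:
    out: _Pieces = []
    for kind, seq in pieces:
        if out and kind == "loop" and out[-1][0] == "loop":
            out[-1] = ("loop", out[-1][1] + seq)
        else:
            out.append((kind, seq))
    return out


def _assemble(accession: str, pieces: _Pieces, source: str = "planted",
              family: str | None = None) -> tuple[ProteinRecord, TopologyAnnotation]:
    seq_parts: list[str] = []
    intervals: list[tuple[int, int]] = []
    pos = 0
    for kind, seq in pieces:
        if kind == "tms":
            intervals.append((pos + 1, pos + len(seq)))
        seq_parts.append(seq)
        pos += len(seq)
    record = ProteinRecord(accession, "".join(seq_parts), family=family)
    topo = TopologyAnnotation(accession, tuple(intervals), source=source,
                              sequence_length=len(record))
    return record, topo


def parse_topology_string(topology: str) -> list[int]:
    """Parse a unit-structure string like ``"4+4"`` into unit sizes."""
    try:
        units = [int(tok) for tok in topology.split("+")]
    except ValueError as exc:
        raise ValueError(f"malformed topology string {topology!r}") from exc
    if not units or any(u < 1 for u in units):
        raise ValueError(f"malformed topology string {topology!r}")
    return units


def make_protein(topology: str, seed: int, accession: str | None = None,
                 family: str | None = None) -> tuple[ProteinRecord, TopologyAnnotation]:
    """Build one protein with the given TMS unit structure (e.g. ``"4+4"``).

    TMS segments are drawn from hydrophobic residues (length 18-24), loops
    from hydrophilic residues (length 8-40).  Planted intervals are returned
    with ``source="planted"``.  Deterministic in ``(topology, seed)``.
    """
    units = parse_topology_string(topology)
    rng = _rng(seed, 1)
    pieces: _Pieces = []
    for u in units:
        pieces.extend(_draw_unit(u, rng))
    pieces = _merge_loops(pieces)
    acc = accession or f"SYN_{topology.replace('+', 'p')}_{seed}"
    return _assemble(acc, pieces, family=family)


# ---------------------------------------------------------------------------
# Events


def _apply_event(pieces: _Pieces, event, spec: FamilySpec,
                 rng: np.random.Generator) -> _Pieces:
    kind = event[0] if isinstance(event, tuple) else event
    if kind == "duplicate":
        return _merge_loops(pieces + [p for p in pieces])
    if kind == "lose_n_terminal_tms":
        idx = next(i for i, (k, _) in enumerate(pieces) if k == "tms")
        return _merge_loops(pieces[:idx] + pieces[idx + 1:])
    if kind == "insert_central_tms":
        n_insert = event[1]
        tms_positions = [i for i, (k, _) in enumerate(pieces) if k == "tms"]
        mid = tms_positions[len(tms_positions) // 2]  # insert before this TMS
        insert: _Pieces = []
        for _ in range(n_insert):
            insert.append(("tms", _draw_tms(rng)))
            insert.append(("loop", _draw_loop(rng)))
        return _merge_loops(pieces[:mid] + insert + pieces[mid:])
    if kind == "fuse":
        return _merge_loops(pieces + _draw_unit(spec.ancestral_tms, rng))
    raise ValueError(f"unknown event {event!r}")


# ---------------------------------------------------------------------------
# Divergence


def _substitution_probs(matrix_name: str = "BLOSUM50") -> tuple[np.ndarray, dict[str, int]]:
    """Replacement distributions: P(b | a) proportional to 2^(S(a,b)/2), b != a."""
    mat = substitution_matrices.load(matrix_name)
    idx = {a: i for i, a in enumerate(STANDARD_AA)}
    probs = np.zeros((20, 20))
    for a in STANDARD_AA:
        w = np.array([0.0 if b == a else 2.0 ** (mat[a, b] / 2.0) for b in STANDARD_AA])
        probs[idx[a]] = w / w.sum()
    return probs, idx


_SUB_PROBS, _AA_IDX = _substitution_probs()
_AA_ARR = np.array(list(STANDARD_AA))


def _mutate_segment(seq: str, p: float, rng: np.random.Generator) -> str:
    if p <= 0 or not seq:
        return seq
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < p)[0]
    for i in hits:
        a = chars[i]
        if a in _AA_IDX:
            chars[i] = str(rng.choice(_AA_ARR, p=_SUB_PROBS[_AA_IDX[a]]))
    return "".join(chars)


def _indel_loop(seq: str, p: float, rng: np.random.Generator) -> str:
    """Geometric-length insertions/deletions within one loop."""
    if p <= 0 or len(seq) < 4:
        return seq
    out = list(seq)
    n_events = int(rng.binomial(len(seq), p))
    for _ in range(n_events):
        length = int(rng.geometric(0.5))
        pos = int(rng.integers(0, len(out)))
        if rng.random() < 0.5 and len(out) - length >= 4:
            del out[pos: pos + length]
        else:
            insert = rng.choice(list(HYDROPHILIC), size=length)
            out[pos:pos] = list(insert)
    return "".join(out)


def _diverge(pieces: _Pieces, mutation_prob: float, indel_prob: float,
             rng: np.random.Generator) -> _Pieces:
    out: _Pieces = []
    for kind, seq in pieces:
        seq = _mutate_segment(seq, mutation_prob, rng)
        if kind == "loop":
            seq = _indel_loop(seq, indel_prob, rng)
        out.append((kind, seq))
    return out


# ---------------------------------------------------------------------------
# Families and benchmarks


def make_founder(spec: FamilySpec) -> _Pieces:
    """Ancestral unit with the spec's events applied (the family founder)."""
    rng = _rng(spec.seed, 2)
    pieces = _draw_unit(spec.ancestral_tms, rng)
    for event in spec.events:
        pieces = _apply_event(pieces, event, spec, rng)
    return pieces


def evolve_family(spec: FamilySpec, founder: _Pieces | None = None,
                  ) -> list[tuple[ProteinRecord, TopologyAnnotation]]:
    """Generate family members by independent divergence from the founder.

    With ``mutation_prob == 0`` and ``indel_prob == 0`` every member equals
    the post-event founder.
    """
    if founder is None:
        founder = make_founder(spec)
    members = []
    for m in range(spec.n_members):
        rng = _rng(spec.seed, 3, m)
        pieces = _diverge(founder, spec.mutation_prob, spec.indel_prob, rng)
        acc = f"{spec.label}_{m}"
        members.append(_assemble(acc, pieces, family=spec.label))
    return members


@dataclass(frozen=True)
class Benchmark:
    """Labelled dataset of related families plus composition-matched decoys."""

    families: dict[str, list[tuple[ProteinRecord, TopologyAnnotation]]]
    related_pairs: frozenset[frozenset[str]]


def _shuffle_record(record: ProteinRecord, accession: str, family: str,
                    rng: np.random.Generator) -> ProteinRecord:
    arr = np.frombuffer(record.sequence.encode(), dtype="S1")
    return ProteinRecord(accession, rng.permutation(arr).tobytes().decode(),
                         family=family)


def make_benchmark(
    seed: int,
    related_spec: FamilySpec | None = None,
    n_decoy_families: int = 2,
) -> Benchmark:
    """Two families descended from one ancestor, plus shuffled decoys.

    The related families share a founder (default: a duplicated 4-TMS unit,
    i.e. 4+4) and diverge independently, so their pairwise divergence is
    roughly twice the member mutation probability.  Decoy families are
    residue-shuffled copies of real members — composition-matched, as random
    alignment scores are inflated by compositional bias — with topologies
    left to prediction.
    """
    base = related_spec or FamilySpec(events=("duplicate",))
    fam_a = replace(base, seed=seed * 31 + 1 & 0x3FFFFFFF, label="REL_A")
    fam_d = replace(base, seed=seed * 31 + 2 & 0x3FFFFFFF, label="REL_D")
    # shared ancestor: founder drawn from the benchmark seed, not the family seeds
    founder = make_founder(replace(base, seed=seed & 0x3FFFFFFF))
    families = {
        "REL_A": evolve_family(fam_a, founder=founder),
        "REL_D": evolve_family(fam_d, founder=founder),
    }
    from .topology import hydropathy_profile, predict_tms  # local import, no cycle

    for d in range(n_decoy_families):
        label = f"DECOY_{d}"
        src = families["REL_A" if d % 2 == 0 else "REL_D"]
        rng = _rng(seed, 4, d)
        members = []
        for k, (rec, _) in enumerate(src):
            shuffled = _shuffle_record(rec, f"{label}_{k}", label, rng)
            topo = predict_tms(hydropathy_profile(shuffled))
            members.append((shuffled, topo))
        families[label] = members
    return Benchmark(families, frozenset({frozenset({"REL_A", "REL_D"})}))
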