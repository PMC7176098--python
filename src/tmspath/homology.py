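"""Transitive homology inference between protein families.

Two families are compared through a path A -> B -> C -> D: A and D are the
family queries, B and C are screened homologs of each.  A candidate
inference requires significant alignments throughout the path (each
shuffle-calibrated E-value below the path threshold) and a B-C alignment
spanning at least a minimum number of topologically matched TMSs.  Four of
the method's five decision criteria are automated here as checks:

1. *similarity* — E-value thresholds along the whole path;
2. *topology* — TMS correspondence across the B-C alignment (colinear
   matched pairs; final congruence with a family's repeat-unit history is
   a recorded manual verdict);
3. *domain_overlap* — shared domain content within the aligned region,
   with clan identity counting as support;
4. *motif* — a recorded flag from external motif evidence.

Criterion 5 (structural superposition) is likewise a recorded flag.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .align import LocalAlignment, align_with_evalue, reduce_redundancy, smith_waterman
from .core_io import DomainHit, ProteinRecord, RunConfig, TopologyAnnotation
from .netscore import confidence_score

logger = logging.getLogger("tmspath")

#: a (record, topology) pair; topology may be None (pair is then skipped)
Member = tuple[ProteinRecord, TopologyAnnotation | None]

CRITERIA = ("similarity", "topology", "domain_overlap", "motif", "structure")
FLAGS = {"pass", "fail", "manual", "not_applicable"}


@dataclass(frozen=True)
class TmsCorrespondence:
    """Colinear pairing of TMS ordinals across a pairwise alignment.

    ``pairs`` holds (ordinal_in_query, ordinal_in_subject, overlap_columns);
    ``n_aligned_tms`` counts pairs meeting the overlap rule.  The spanned
    counts report, for each protein separately, how many of its TMSs
    intersect the aligned region — the looser "hydrophobic peaks in the
    alignment" reading; both conventions are reported.
    """

    pairs: tuple[tuple[int, int, int], ...]
    n_spanned_query: int = 0
    n_spanned_subject: int = 0

    def __post_init__(self) -> None:
        ords_q = [p[0] for p in self.pairs]
        ords_s = [p[1] for p in self.pairs]
        if sorted(ords_q) != ords_q or sorted(ords_s) != ords_s or \
                len(set(ords_q)) != len(ords_q) or len(set(ords_s)) != len(ords_s):
            raise ValueError("TMS correspondence must be strictly colinear")

    @property
    def n_aligned_tms(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class DomainOverlapResult:
    verdict: str                 # pass | fail
    reason: str = ""
    clan_support: bool = False


@dataclass(frozen=True)
class HomologyInference:
    """One A->B->C->D candidate path between two families."""

    family_a: str
    family_d: str
    path: tuple[str, str, str, str]
    aln_ab: LocalAlignment
    aln_bc: LocalAlignment
    aln_cd: LocalAlignment
    correspondence: TmsCorrespondence
    criteria: Mapping[str, str]
    raw_score: float
    norm_score: float | None = None
    level: str | None = None
    verdict: str | None = None

    def __post_init__(self) -> None:
        for name in CRITERIA:
            if self.criteria.get(name) not in FLAGS:
                raise ValueError(f"criterion {name!r} missing or invalid")
        if self.norm_score is not None and not (0.0 < self.norm_score <= 1.0):
            raise ValueError("normalised score must lie in (0, 1]")

    @property
    def n_tms(self) -> int:
        return self.correspondence.n_aligned_tms

    @property
    def evalue_bc(self) -> float:
        return self.aln_bc.evalue


# ---------------------------------------------------------------------------
# Screening (criterion 1 pre-filter)


def screen_homologs(
    queries: Sequence[ProteinRecord],
    database_records: Sequence[ProteinRecord],
    config: RunConfig | None = None,
) -> dict[str, list[ProteinRecord]]:
    """Collect candidate homologs of each query from a sequence database.

    A database record is kept when its alignment to the query has
    E-value < ``screen_evalue`` (calibrated with the database size as the
    number of comparisons) and covers at least ``screen_coverage`` of the
    shorter sequence; surviving hits are redundancy-reduced at
    ``redundancy_identity``.
    """
    config = config or RunConfig()
    if not database_records:
        raise ValueError("empty database")
    config.log("screen_homologs")
    kprime = len(database_records)
    out: dict[str, list[ProteinRecord]] = {}
    for query in queries:
        kept: list[ProteinRecord] = []
        for rec in database_records:
            aln = align_with_evalue(query, rec, config, kprime=kprime)
            if aln.is_empty or aln.evalue is None:
                continue
            if aln.evalue < config.screen_evalue and \
                    aln.coverage_shorter >= config.screen_coverage:
                kept.append(rec)
        out[query.accession] = reduce_redundancy(
            kept, config.redundancy_identity, config=config
        )
    return out


# ---------------------------------------------------------------------------
# TMS correspondence (criterion 2 machinery)


def _position_columns(gapped: str, start: int) -> dict[int, int]:
    """Map 1-based sequence positions to alignment column indices."""
    out = {}
    pos = start
    for col, ch in enumerate(gapped):
        if ch != "-":
            out[pos] = col
            pos += 1
    return out


def map_tms_correspondence(
    aln: LocalAlignment,
    topo_q: TopologyAnnotation,
    topo_s: TopologyAnnotation,
    min_overlap_fraction: float = 0.5,
) -> TmsCorrespondence:
    """Pair TMSs of the two aligned proteins through alignment columns.

    TMS i of the query pairs with TMS j of the subject when their images in
    alignment columns overlap by at least ``min_overlap_fraction`` of the
    shorter image.  Crossing candidate pairs are resolved greedily by
    largest column overlap (alignments are colinear; crossings arise only
    from marginal overlaps).
    """
    if aln.is_empty:
        return TmsCorrespondence(())
    q_cols = _position_columns(aln.q_aln, aln.q_start)
    s_cols = _position_columns(aln.s_aln, aln.s_start)

    def images(topo: TopologyAnnotation, colmap: dict[int, int]) -> dict[int, set[int]]:
        out = {}
        for ordinal, (start, end) in enumerate(topo.tms, 1):
            cols = {colmap[p] for p in range(start, end + 1) if p in colmap}
            if cols:
                out[ordinal] = cols
        return out

    img_q, img_s = images(topo_q, q_cols), images(topo_s, s_cols)
    candidates = []
    for i, ci in img_q.items():
        for j, cj in img_s.items():
            overlap = len(ci & cj)
            if overlap and overlap >= min_overlap_fraction * min(len(ci), len(cj)):
                candidates.append((overlap, i, j))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    accepted: list[tuple[int, int, int]] = []
    for overlap, i, j in candidates:
        ok = all(
            (i < ai) == (j < aj) and i != ai and j != aj
            for ai, aj, _ in accepted
        )
        if ok:
            accepted.append((i, j, overlap))
    accepted.sort()
    return TmsCorrespondence(
        tuple(accepted),
        n_spanned_query=len(img_q),
        n_spanned_subject=len(img_s),
    )


# ---------------------------------------------------------------------------
# Domain overlap and projection (criterion 3 machinery)


def _span_overlap(a: tuple[int, int], b: tuple[int, int]) -> tuple[int, int] | None:
    lo, hi = max(a[0], b[0]), min(a[1], b[1])
    return (lo, hi) if lo <= hi else None


def _side_overlap(hits: Sequence[DomainHit], span: tuple[int, int],
                  topo: TopologyAnnotation, min_tms: int = 3) -> DomainHit | None:
    """Best hit whose envelope meets the overlap rule within ``span``."""
    for hit in sorted(hits, key=lambda h: h.evalue):
        env = (hit.env_start, hit.env_end)
        inter = _span_overlap(env, span)
        if inter is None:
            continue
        tms_in_domain = sum(1 for t in topo.tms if _span_overlap(t, env))
        tms_in_inter = sum(1 for t in topo.tms if _span_overlap(t, inter))
        if tms_in_inter >= min_tms:
            return hit
        if tms_in_domain < min_tms and inter == env:
            return hit  # domain smaller than the rule size, fully inside
    return None


def check_domain_overlap(
    aln_bc: LocalAlignment,
    hits_b: Sequence[DomainHit],
    hits_c: Sequence[DomainHit],
    topo_b: TopologyAnnotation,
    topo_c: TopologyAnnotation,
    min_tms: int = 3,
) -> DomainOverlapResult:
    """Check shared domain content within the aligned region.

    Each side's domain must intersect the aligned span over at least
    ``min_tms`` TMSs, or over the full domain when the domain itself covers
    fewer.  Identical accessions pass outright; distinct accessions in the
    same clan pass with the clan flag set.
    """
    if not hits_b and not hits_c:
        return DomainOverlapResult("fail", reason="no domains")
    span_b = (aln_bc.q_start, aln_bc.q_end)
    span_c = (aln_bc.s_start, aln_bc.s_end)
    best_b = _side_overlap(hits_b, span_b, topo_b, min_tms) if hits_b else None
    best_c = _side_overlap(hits_c, span_c, topo_c, min_tms) if hits_c else None
    if hits_b and best_b is None:
        return DomainOverlapResult("fail", reason=f"no domain overlap on {aln_bc.query}")
    if hits_c and best_c is None:
        return DomainOverlapResult("fail", reason=f"no domain overlap on {aln_bc.subject}")
    if best_b and best_c:
        if best_b.domain_acc == best_c.domain_acc:
            return DomainOverlapResult("pass")
        if best_b.clan and best_b.clan == best_c.clan:
            return DomainOverlapResult(
                "pass", reason=f"clan {best_b.clan}", clan_support=True
            )
        return DomainOverlapResult(
            "fail",
            reason=f"different domains {best_b.domain_acc}/{best_c.domain_acc}, no shared clan",
        )
    return DomainOverlapResult("pass", reason="single-sided domain evidence")


@dataclass(frozen=True)
class DomainRegion:
    """A sequence slice carrying a direct domain hit, usable as a donor."""

    protein: str
    domain_acc: str
    start: int
    end: int
    sequence: str
    clan: str | None = None


def extract_domain_regions(
    hits: Iterable[DomainHit], records: Mapping[str, ProteinRecord],
    domain_acc: str | None = None,
) -> list[DomainRegion]:
    out = []
    for hit in hits:
        if hit.origin != "direct":
            continue
        if domain_acc and hit.domain_acc != domain_acc:
            continue
        rec = records.get(hit.protein)
        if rec is None:
            continue
        out.append(DomainRegion(hit.protein, hit.domain_acc, hit.env_start,
                                hit.env_end,
                                rec.sequence[hit.env_start - 1: hit.env_end],
                                clan=hit.clan))
    return out


def most_common_domain(
    hits: Iterable[DomainHit], family_members: Sequence[str],
    min_fraction: float = 0.5,
) -> str | None:
    """The family's characteristic domain: highest member fraction >= 0.5.

    Ties are broken by the lower median E-value.
    """
    members = set(family_members)
    per_domain: dict[str, dict[str, float]] = {}
    for hit in hits:
        if hit.protein in members:
            d = per_domain.setdefault(hit.domain_acc, {})
            d[hit.protein] = min(d.get(hit.protein, float("inf")), hit.evalue)
    best, best_key = None, None
    for acc, prot_ev in per_domain.items():
        frac = len(prot_ev) / len(members)
        if frac < min_fraction:
            continue
        key = (-frac, statistics.median(prot_ev.values()))
        if best_key is None or key < best_key:
            best, best_key = acc, key
    return best


def project_domain(
    donor_regions: Sequence[DomainRegion],
    target: ProteinRecord,
    config: RunConfig | None = None,
) -> DomainHit | None:
    """Transfer a domain annotation onto a protein lacking a direct hit.

    Each donor region (sequence slice under a direct hit elsewhere in the
    family) is aligned to the target; the projection succeeds when some
    alignment has E-value < ``projection_evalue`` and covers at least
    ``projection_coverage`` of the donor region.  The resulting hit is
    placed at the target's aligned span and records the best donor.
    """
    config = config or RunConfig()
    if not donor_regions:
        raise ValueError("empty donor set")
    best: tuple[float, DomainRegion, LocalAlignment] | None = None
    for region in donor_regions:
        aln = align_with_evalue(region.sequence, target, config)
        if aln.is_empty or aln.evalue is None:
            continue
        donor_cov = (aln.q_end - aln.q_start + 1) / len(region.sequence)
        if aln.evalue < config.projection_evalue and donor_cov >= config.projection_coverage:
            if best is None or aln.evalue < best[0]:
                best = (aln.evalue, region, aln)
    if best is None:
        return None
    evalue, region, aln = best
    return DomainHit(
        protein=target.accession, domain_acc=region.domain_acc,
        env_start=aln.s_start, env_end=aln.s_end, evalue=evalue,
        clan=region.clan, origin="projected", projected_from=region.protein,
    )


# ---------------------------------------------------------------------------
# Family-vs-family comparison


def compare_families(
    list_a: Sequence[Member],
    list_d: Sequence[Member],
    config: RunConfig | None = None,
    hits_by_protein: Mapping[str, Sequence[DomainHit]] | None = None,
    family_a: str | None = None,
    family_d: str | None = None,
) -> list[HomologyInference]:
    """Rank candidate transitivity paths between two homolog lists.

    The first member of each list is the family query (A resp. D).  All
    B x C pairs are aligned; a pair is a candidate when every E-value on
    the path (A-B, B-C, C-D) is below ``path_evalue`` — B-C calibrated with
    the number of B x C comparisons, A-B and C-D with the list sizes — and
    the B-C alignment has at least ``min_aligned_tms`` matched TMS pairs.
    Candidates are sorted by (B-C E-value, matched TMSs desc, identity desc).
    """
    config = config or RunConfig()
    if not list_a or not list_d:
        raise ValueError("both homolog lists must be non-empty")
    config.log("compare_families")
    rec_a, _ = list_a[0]
    rec_d, _ = list_d[0]
    family_a = family_a or rec_a.family or rec_a.accession
    family_d = family_d or rec_d.family or rec_d.accession
    kprime_bc = len(list_a) * len(list_d)
    ab_cache: dict[str, LocalAlignment] = {}
    cd_cache: dict[str, LocalAlignment] = {}
    candidates: list[HomologyInference] = []
    for rec_b, topo_b in list_a:
        for rec_c, topo_c in list_d:
            if topo_b is None or topo_c is None:
                logger.warning("skipping %s x %s: missing topology",
                               rec_b.accession, rec_c.accession)
                continue
            aln_bc = align_with_evalue(rec_b, rec_c, config, kprime=kprime_bc)
            if aln_bc.is_empty or aln_bc.evalue is None or \
                    aln_bc.evalue >= config.path_evalue:
                continue
            corr = map_tms_correspondence(aln_bc, topo_b, topo_c,
                                          config.tms_overlap_fraction)
            if corr.n_aligned_tms < config.min_aligned_tms:
                continue
            if rec_b.accession not in ab_cache:
                ab_cache[rec_b.accession] = align_with_evalue(
                    rec_a, rec_b, config, kprime=len(list_a))
            aln_ab = ab_cache[rec_b.accession]
            if aln_ab.is_empty or aln_ab.evalue is None or \
                    aln_ab.evalue >= config.path_evalue:
                continue
            if rec_c.accession not in cd_cache:
                cd_cache[rec_c.accession] = align_with_evalue(
                    rec_c, rec_d, config, kprime=len(list_d))
            aln_cd = cd_cache[rec_c.accession]
            if aln_cd.is_empty or aln_cd.evalue is None or \
                    aln_cd.evalue >= config.path_evalue:
                continue
            criteria = {
                "similarity": "pass",
                "topology": "manual",       # congruence with repeat units is a human call
                "motif": "not_applicable",
                "structure": "not_applicable",
            }
            if hits_by_protein is not None:
                result = check_domain_overlap(
                    aln_bc,
                    hits_by_protein.get(rec_b.accession, ()),
                    hits_by_protein.get(rec_c.accession, ()),
                    topo_b, topo_c,
                )
                criteria["domain_overlap"] = result.verdict
            else:
                criteria["domain_overlap"] = "not_applicable"
            candidates.append(HomologyInference(
                family_a=family_a, family_d=family_d,
                path=(rec_a.accession, rec_b.accession,
                      rec_c.accession, rec_d.accession),
                aln_ab=aln_ab, aln_bc=aln_bc, aln_cd=aln_cd,
                correspondence=corr, criteria=criteria,
                raw_score=confidence_score(corr.n_aligned_tms, aln_bc.evalue),
            ))
    candidates.sort(key=lambda c: (c.evalue_bc, -c.n_tms, -c.aln_bc.identity))
    return candidates


def evaluate_criteria(inference: HomologyInference,
                      structures_available: bool) -> HomologyInference:
    """Apply the final decision rule to an inference's criteria flags.

    With structures available, a family pair is accepted when at least 4 of
    the 5 criteria pass; without structures, criterion 5 is not considered
    and all of criteria 1-4 must pass.  Flags still marked ``manual`` (or
    ``not_applicable`` among the required criteria) block an automatic
    accept: the inference is marked ``needs_review`` unless enough criteria
    already fail to force a reject.
    """
    flags = inference.criteria
    considered = CRITERIA if structures_available else CRITERIA[:4]
    n_pass = sum(1 for c in considered if flags[c] == "pass")
    n_fail = sum(1 for c in considered if flags[c] == "fail")
    required = 4 if structures_available else 4
    max_fail = len(considered) - required
    if n_fail > max_fail:
        verdict = "reject"
    elif n_pass >= required:
        verdict = "accept"
    else:
        verdict = "needs_review"
    return replace(inference, verdict=verdict)


def write_inference_tsv(inferences: Sequence[HomologyInference], path) -> None:
    with open(path, "w") as fh:
        fh.write("# family_a\tA\tB\tC\tD\tfamily_d\tE_ab\tE_bc\tE_cd\tn_tms\t"
                 "tms_spanned_b\ttms_spanned_c\traw_score\tnorm_score\tlevel\t"
                 + "\t".join(CRITERIA) + "\tverdict\n")
        for inf in inferences:
            a, b, c, d = inf.path
            fh.write(
                f"{inf.family_a}\t{a}\t{b}\t{c}\t{d}\t{inf.family_d}\t"
                f"{inf.aln_ab.evalue:.3g}\t{inf.aln_bc.evalue:.3g}\t"
                f"{inf.aln_cd.evalue:.3g}\t{inf.n_tms}\t"
                f"{inf.correspondence.n_spanned_query}\t"
                f"{inf.correspondence.n_spanned_subject}\t"
                f"{inf.raw_score:.2f}\t"
                f"{'' if inf.norm_score is None else f'{inf.norm_score:.3f}'}\t"
                f"{inf.level or ''}\t"
                + "\t".join(inf.criteria[c] for c in CRITERIA)
                + f"\t{inf.verdict or ''}\n"
            )
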