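import numpy as np
import pytest

from tmspath import RunConfig
from tmspath.align import LocalAlignment, smith_waterman
from tmspath.core_io import DomainHit, ProteinRecord, TopologyAnnotation
from tmspath.fixtures import (FamilySpec, _mutate_segment, _rng, evolve_family,
                              make_benchmark, make_founder, make_protein)
from tmspath.homology import (DomainRegion, HomologyInference, TmsCorrespondence,
                              check_domain_overlap, compare_families,
                              evaluate_criteria, map_tms_correspondence,
                              most_common_domain, project_domain,
                              screen_homologs)

from conftest import random_protein


def identity_alignment(query, subject, q_span, s_span, seq):
    """Hand-built gapless alignment for correspondence unit tests."""
    frag = seq[q_span[0] - 1:q_span[1]]
    return LocalAlignment(query, subject, q_span[0], q_span[1], s_span[0],
                          s_span[1], frag, frag, raw_score=10.0, bit_score=5.0,
                          identity=1.0, coverage_shorter=0.5, evalue=1e-10)


class TestTmsCorrespondence:
    def test_self_alignment_pairs_identically(self, fourfour, fast_config):
        rec, topo = fourfour
        aln = smith_waterman(rec, rec, fast_config)
        corr = map_tms_correspondence(aln, topo, topo)
        assert [(i, j) for i, j, _ in corr.pairs] == [(i, i) for i in range(1, 9)]
        assert corr.n_aligned_tms == 8

    def test_n_terminal_loss_shifts_pairs_by_one(self, fast_config):
        base = FamilySpec(events=("duplicate",), n_members=1, mutation_prob=0.0,
                          indel_prob=0.0, seed=13, label="PARENT")
        lost = FamilySpec(events=("duplicate", "lose_n_terminal_tms"),
                          n_members=1, mutation_prob=0.0, indel_prob=0.0,
                          seed=13, label="CHILD")
        parent_rec, parent_topo = evolve_family(base)[0]
        child_rec, child_topo = evolve_family(lost)[0]
        aln = smith_waterman(child_rec, parent_rec, fast_config)
        corr = map_tms_correspondence(aln, child_topo, parent_topo)
        assert [(i, j) for i, j, _ in corr.pairs] == \
               [(i, i + 1) for i in range(1, 8)]

    def test_loop_confined_alignment_has_no_pairs(self):
        seq = "ACDEFGHIKLMNPQRSTVWY" * 5
        topo = TopologyAnnotation("p", ((5, 25),), sequence_length=100)
        aln = identity_alignment("p", "q", (40, 80), (40, 80), seq)
        corr = map_tms_correspondence(aln, topo, topo)
        assert corr.n_aligned_tms == 0

    def test_symmetric_under_alignment_swap(self, fourfour, fast_config):
        rec, topo = fourfour
        other, other_topo = make_protein("4+4", seed=4)
        aln = smith_waterman(rec, other, fast_config)
        swapped = LocalAlignment(aln.subject, aln.query, aln.s_start, aln.s_end,
                                 aln.q_start, aln.q_end, aln.s_aln, aln.q_aln,
                                 aln.raw_score, aln.bit_score, aln.identity,
                                 aln.coverage_shorter)
        fwd = map_tms_correspondence(aln, topo, other_topo)
        rev = map_tms_correspondence(swapped, other_topo, topo)
        assert {(i, j) for i, j, _ in fwd.pairs} == \
               {(j, i) for i, j, _ in rev.pairs}

    def test_colinearity_enforced(self):
        with pytest.raises(ValueError):
            TmsCorrespondence(((1, 2, 5), (2, 1, 5)))


class TestDomainOverlap:
    def setup_method(self):
        self.rec, self.topo = make_protein("4", seed=6)
        cfg = RunConfig(shuffles=1)
        self.full_aln = smith_waterman(self.rec, self.rec, cfg)
        span = (self.topo.tms[0][0], self.topo.tms[-1][1])
        self.hit = DomainHit("p", "PF_A", span[0], span[1], 1e-20)

    def test_domain_covering_alignment_passes(self):
        result = check_domain_overlap(self.full_aln, [self.hit], [self.hit],
                                      self.topo, self.topo)
        assert result.verdict == "pass"

    def test_domain_outside_span_fails(self):
        end = len(self.rec)
        outside = DomainHit("p", "PF_A", end - 4, end, 1e-20)
        aln = identity_alignment("p", "q", (1, 40), (1, 40), self.rec.sequence)
        result = check_domain_overlap(aln, [outside], [outside],
                                      self.topo, self.topo)
        assert result.verdict == "fail"

    def test_same_clan_counts_with_flag(self):
        other = DomainHit("q", "PF_B", self.hit.env_start, self.hit.env_end,
                          1e-15, clan="CL0141")
        mine = DomainHit("p", "PF_A", self.hit.env_start, self.hit.env_end,
                         1e-20, clan="CL0141")
        result = check_domain_overlap(self.full_aln, [mine], [other],
                                      self.topo, self.topo)
        assert result.verdict == "pass"
        assert result.clan_support

    def test_no_hits_fails_with_reason(self):
        result = check_domain_overlap(self.full_aln, [], [], self.topo, self.topo)
        assert result.verdict == "fail"
        assert result.reason == "no domains"

    def test_small_domain_fully_inside_passes(self):
        # domain covering a single TMS, entirely within the aligned span
        start, end = self.topo.tms[1]
        small = DomainHit("p", "PF_A", start, end, 1e-8)
        result = check_domain_overlap(self.full_aln, [small], [small],
                                      self.topo, self.topo)
        assert result.verdict == "pass"


class TestProjectDomain:
    def test_mutated_copy_projected(self):
        rec, _ = make_protein("4", seed=30)
        donor_seq = rec.sequence[40:200]
        rng = _rng(99, 7)
        mutated = _mutate_segment(donor_seq, 0.15, rng)
        target = ProteinRecord("T1", "KDES" * 10 + mutated + "GRNT" * 10)
        donors = [DomainRegion(rec.accession, "PF_X", 41, 200, donor_seq)]
        cfg = RunConfig(shuffles=100, seed=1)
        hit = project_domain(donors, target, cfg)
        assert hit is not None
        assert hit.origin == "projected"
        assert hit.projected_from == rec.accession
        assert hit.domain_acc == "PF_X"
        # target envelope should sit on the mutated copy
        assert abs(hit.env_start - 41) <= 10
        assert (hit.env_end - hit.env_start + 1) / len(donor_seq) > 0.9

    def test_random_target_not_projected(self):
        rec, _ = make_protein("4", seed=31)
        donors = [DomainRegion(rec.accession, "PF_X", 41, 200,
                               rec.sequence[40:200])]
        rng = np.random.default_rng(17)
        target = ProteinRecord("T2", random_protein(rng, 250))
        cfg = RunConfig(shuffles=100, seed=1)
        assert project_domain(donors, target, cfg) is None

    def test_empty_donor_set_rejected(self):
        with pytest.raises(ValueError):
            project_domain([], ProteinRecord("T", "ACDEF"), RunConfig())


class TestMostCommonDomain:
    def test_majority_domain_selected(self):
        hits = [DomainHit(f"p{i}", "PF_A", 1, 50, 1e-10) for i in range(3)] + \
               [DomainHit("p0", "PF_B", 60, 90, 1e-5)]
        assert most_common_domain(hits, [f"p{i}" for i in range(4)]) == "PF_A"

    def test_below_half_fraction_yields_none(self):
        hits = [DomainHit("p0", "PF_A", 1, 50, 1e-10)]
        assert most_common_domain(hits, ["p0", "p1", "p2"]) is None


class TestScreenHomologs:
    def test_verbatim_query_retained(self, fast_config):
        rec, _ = make_protein("4", seed=40)
        rng = np.random.default_rng(3)
        db = [rec] + [ProteinRecord(f"d{i}", random_protein(rng, 200))
                      for i in range(3)]
        result = screen_homologs([rec], db, fast_config)
        assert rec.accession in {r.accession for r in result[rec.accession]}

    def test_coverage_boundary_excluded(self, fast_config):
        rng = np.random.default_rng(44)
        common = random_protein(rng, 39)
        query = ProteinRecord("Q", common + "K" * 61)
        low_cov = ProteinRecord("L", common + "P" * 61)            # coverage 0.39
        ok_cov = ProteinRecord("O", common + random_protein(rng, 6) + "P" * 55)
        hits = screen_homologs([query], [query, low_cov, ok_cov], fast_config)
        accs = {r.accession for r in hits["Q"]}
        assert "L" not in accs
        assert "Q" in accs

    def test_family_members_but_not_decoys_retained(self, fast_config):
        bench = make_benchmark(seed=5)
        family = [rec for rec, _ in bench.families["REL_A"]]
        decoys = [rec for rec, _ in bench.families["DECOY_0"]]
        query = family[0]
        result = screen_homologs([query], family + decoys, fast_config)
        accs = {r.accession for r in result[query.accession]}
        assert accs == {rec.accession for rec in family}

    def test_empty_database_rejected(self, fast_config):
        with pytest.raises(ValueError):
            screen_homologs([], [], fast_config)


class TestCompareFamilies:
    def test_related_families_produce_candidate(self):
        cfg = RunConfig(shuffles=80, seed=11)
        bench = make_benchmark(seed=7)
        candidates = compare_families(bench.families["REL_A"],
                                      bench.families["REL_D"], cfg)
        assert candidates
        top = candidates[0]
        assert top.evalue_bc < cfg.path_evalue
        assert top.n_tms >= cfg.min_aligned_tms
        assert top.aln_ab.evalue < cfg.path_evalue
        assert top.aln_cd.evalue < cfg.path_evalue
        assert top.criteria["similarity"] == "pass"
        assert top.raw_score > 0

    def test_decoy_comparison_yields_nothing(self):
        cfg = RunConfig(shuffles=80, seed=11)
        bench = make_benchmark(seed=7)
        assert compare_families(bench.families["REL_A"],
                                bench.families["DECOY_0"], cfg) == []

    def test_candidates_sorted_by_bc_evalue(self):
        cfg = RunConfig(shuffles=80, seed=12)
        bench = make_benchmark(seed=9)
        candidates = compare_families(bench.families["REL_A"],
                                      bench.families["REL_D"], cfg)
        evalues = [c.evalue_bc for c in candidates]
        assert evalues == sorted(evalues)


def make_inference(criteria):
    seq = "ACDEFGHIKLMNPQRSTVWY"
    aln = identity_alignment("b", "c", (1, 20), (1, 20), seq)
    corr = TmsCorrespondence(((1, 1, 20), (2, 2, 20), (3, 3, 18)))
    return HomologyInference(
        family_a="F1", family_d="F2", path=("a", "b", "c", "d"),
        aln_ab=aln, aln_bc=aln, aln_cd=aln, correspondence=corr,
        criteria=criteria, raw_score=30.0,
    )


class TestEvaluateCriteria:
    def test_all_four_pass_without_structures_accepts(self):
        inf = make_inference({"similarity": "pass", "topology": "pass",
                              "domain_overlap": "pass", "motif": "pass",
                              "structure": "not_applicable"})
        assert evaluate_criteria(inf, structures_available=False).verdict == "accept"

    def test_motif_failure_without_structures_rejects(self):
        inf = make_inference({"similarity": "pass", "topology": "pass",
                              "domain_overlap": "pass", "motif": "fail",
                              "structure": "not_applicable"})
        assert evaluate_criteria(inf, structures_available=False).verdict == "reject"

    def test_four_of_five_with_structures_accepts(self):
        inf = make_inference({"similarity": "pass", "topology": "pass",
                              "domain_overlap": "pass", "motif": "fail",
                              "structure": "pass"})
        assert evaluate_criteria(inf, structures_available=True).verdict == "accept"

    def test_manual_flag_blocks_automatic_accept(self):
        inf = make_inference({"similarity": "pass", "topology": "manual",
                              "domain_overlap": "pass", "motif": "pass",
                              "structure": "not_applicable"})
        result = evaluate_criteria(inf, structures_available=False)
        assert result.verdict == "needs_review"
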