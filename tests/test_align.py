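import math

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from scipy.stats import gumbel_r

from tmspath import RunConfig
from tmspath.align import (GumbelFit, align_with_evalue, bit_score, raw_score,
                           reduce_redundancy, shuffle_evalue, smith_waterman)
from tmspath.core_io import ConfigError, ProteinRecord

from conftest import random_protein


def sw_oracle(a: str, b: str, matrix, gap_open: float, gap_extend: float) -> float:
    """Exhaustive Gotoh dynamic programme; a gap of length L costs
    gap_open + L * gap_extend.  No optimisations — the independent oracle."""
    n, m = len(a), len(b)
    neg = -1e9
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[neg] * (m + 1) for _ in range(n + 1)]
    F = [[neg] * (m + 1) for _ in range(n + 1)]
    first = gap_open + gap_extend
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - first, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - first, F[i - 1][j] - gap_extend)
            H[i][j] = max(0.0, H[i - 1][j - 1] + matrix[a[i - 1], b[j - 1]],
                          E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


class TestSmithWaterman:
    def test_self_alignment_full_length(self, fast_config):
        aln = smith_waterman("ACDEFGH", "ACDEFGH", fast_config)
        assert aln.identity == 1.0
        assert (aln.q_start, aln.q_end) == (1, 7)
        assert (aln.s_start, aln.s_end) == (1, 7)
        assert aln.coverage_shorter == 1.0

    def test_textbook_pair_matches_oracle(self, fast_config):
        mat = substitution_matrices.load("BLOSUM50")
        expected = sw_oracle("HEAGAWGHEE", "PAWHEAE", mat, 10, 2)
        aln = smith_waterman("HEAGAWGHEE", "PAWHEAE", fast_config)
        assert aln.raw_score == expected

    def test_all_x_yields_empty_alignment(self, fast_config):
        aln = smith_waterman("XXXX", "XXXX", fast_config)
        assert aln.is_empty
        assert aln.raw_score == 0.0

    def test_random_pairs_match_oracle(self, fast_config):
        mat = substitution_matrices.load("BLOSUM50")
        rng = np.random.default_rng(42)
        for _ in range(50):
            a = random_protein(rng, int(rng.integers(1, 21)))
            b = random_protein(rng, int(rng.integers(1, 21)))
            assert raw_score(a, b, fast_config) == sw_oracle(a, b, mat, 10, 2)

    def test_score_symmetry(self, fast_config):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = random_protein(rng, 30)
            b = random_protein(rng, 25)
            assert raw_score(a, b, fast_config) == raw_score(b, a, fast_config)

    def test_unknown_matrix_rejected(self):
        with pytest.raises(ConfigError):
            smith_waterman("ACD", "ACD", RunConfig(matrix="NOSUCH"))

    def test_empty_sequence_rejected(self, fast_config):
        with pytest.raises(ValueError):
            smith_waterman("", "ACD", fast_config)


class TestBitScore:
    def test_zero_score_closed_form(self):
        lam, k = 0.5, 0.2
        assert bit_score(0.0, (lam, k)) == pytest.approx(-math.log(k) / math.log(2))

    def test_collapsing_parameters(self):
        assert bit_score(10.0, (math.log(2), 1.0)) == pytest.approx(10.0)

    def test_blosum50_fixture_matches_hand_formula(self, fast_config):
        s = raw_score("ACDEFGHIKLMNP", "ACDEFGHIKLMNP", fast_config)
        lam, k = 0.232, 0.112
        expected = (lam * s - math.log(k)) / math.log(2)
        assert bit_score(s, fast_config) == pytest.approx(expected)

    def test_missing_constants_rejected(self):
        cfg = RunConfig(matrix="PAM250")
        with pytest.raises(ConfigError):
            bit_score(10.0, cfg)


class TestShuffleEvalue:
    def test_self_similarity_dominates(self):
        cfg = RunConfig(shuffles=100, seed=1)
        rng = np.random.default_rng(8)
        seq = random_protein(rng, 80)
        obs = raw_score(seq, seq, cfg)
        evalue, z, fit = shuffle_evalue(seq, seq, obs, cfg)
        assert evalue < 1.0 / cfg.shuffles or fit.degenerate
        assert z > 5

    def test_gumbel_ml_fit_recovers_known_parameters(self):
        """Numerical ML on synthetic Gumbel draws as oracle (K = 10,000)."""
        rng = np.random.default_rng(3)
        mu, beta = 30.0, 4.0
        draws = gumbel_r.rvs(loc=mu, scale=beta, size=10_000, random_state=rng)
        loc, scale = gumbel_r.fit(draws)
        assert loc == pytest.approx(mu, rel=0.05)
        assert scale == pytest.approx(beta, rel=0.05)

    def test_deterministic_for_fixed_seed(self):
        cfg = RunConfig(shuffles=60, seed=99)
        rng = np.random.default_rng(12)
        a, b = random_protein(rng, 60), random_protein(rng, 70)
        obs = raw_score(a, b, cfg)
        e1 = shuffle_evalue(a, b, obs, cfg)[0]
        e2 = shuffle_evalue(a, b, obs, cfg)[0]
        assert e1 == e2

    def test_evalue_decreasing_in_score(self):
        fit = GumbelFit(mu=25.0, lam=0.3, n_samples=100)
        svals = [20.0, 25.0, 30.0, 40.0, 60.0]
        evals = [fit.sf(s) for s in svals]
        assert all(x > y for x, y in zip(evals, evals[1:]))

    def test_kprime_scales_evalue(self):
        cfg = RunConfig(shuffles=60, seed=4)
        rng = np.random.default_rng(13)
        a, b = random_protein(rng, 60), random_protein(rng, 60)
        obs = raw_score(a, b, cfg)
        e1 = shuffle_evalue(a, b, obs, cfg, kprime=1)[0]
        e10 = shuffle_evalue(a, b, obs, cfg, kprime=10)[0]
        assert e10 == pytest.approx(10 * e1)


class TestReduceRedundancy:
    def test_identical_sequences_collapse(self, fast_config):
        recs = [ProteinRecord("a", "ACDEFGHIKLMNPQRSTVWY" * 3),
                ProteinRecord("b", "ACDEFGHIKLMNPQRSTVWY" * 3)]
        reps = reduce_redundancy(recs, 0.90, config=fast_config)
        assert len(reps) == 1

    def test_planted_near_identical_pair_collapses(self, fast_config):
        rng = np.random.default_rng(21)
        base = random_protein(rng, 100)
        # one pair at ~95% identity, the rest unrelated
        mutated = list(base)
        for i in rng.choice(100, size=5, replace=False):
            mutated[i] = "W" if base[i] != "W" else "Y"
        recs = [ProteinRecord("q", base), ProteinRecord("m", "".join(mutated))] + [
            ProteinRecord(f"r{i}", random_protein(rng, 100)) for i in range(4)
        ]
        reps = reduce_redundancy(recs, 0.90, config=fast_config)
        assert len(reps) == len(recs) - 1
        assert sum(r.accession in {"q", "m"} for r in reps) == 1

    def test_threshold_one_keeps_distinct(self, fast_config):
        rng = np.random.default_rng(2)
        recs = [ProteinRecord(f"r{i}", random_protein(rng, 60)) for i in range(4)]
        assert len(reduce_redundancy(recs, 1.0, config=fast_config)) == 4

    def test_invalid_threshold(self, fast_config):
        with pytest.raises(ValueError):
            reduce_redundancy([], 0.0, config=fast_config)


def test_align_with_evalue_populates_statistics(fast_config):
    rng = np.random.default_rng(30)
    a = random_protein(rng, 80)
    aln = align_with_evalue(a, a, fast_config)
    assert aln.evalue is not None and aln.evalue > 0
    assert aln.shuffles == fast_config.shuffles
    assert aln.z_score > 0
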