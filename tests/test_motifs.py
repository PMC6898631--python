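import itertools

import numpy as np
import pytest

from reprodyn import motifs
from reprodyn.io import PWM, MotifLibrary
from reprodyn.simulate import SimConfig, generate_fluctuation_experiment, generate_motif_library


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def enumerate_pvalue(pwm: PWM, score: float) -> float:
    """Brute-force tail probability over all 4^L background words."""
    s = np.log2(pwm.matrix / pwm.background[None, :])
    total = 0.0
    for word in itertools.product(range(4), repeat=pwm.length):
        w_score = sum(s[j, b] for j, b in enumerate(word))
        if w_score >= score - 1e-9:
            total += np.prod([pwm.background[b] for b in word])
    return total


class TestScan:
    def test_consensus_hit_score(self, near_consensus_acgt):
        hits = motifs.scan_pwm("TTACGTTT", near_consensus_acgt, 5.0)
        fwd = [h for h in hits if h.strand == "+"]
        assert len(fwd) == 1
        assert fwd[0].offset == 2
        assert fwd[0].score == pytest.approx(4 * np.log2(0.97 / 0.25), rel=1e-12)

    def test_uniform_pwm_scores_zero(self, uniform_pwm):
        hits = motifs.scan_pwm("ACGTACGT", uniform_pwm, 0.0)
        assert len(hits) == 2 * (8 - 4 + 1)
        assert all(h.score == 0.0 for h in hits)

    def test_windows_with_n_skipped(self, near_consensus_acgt):
        hits = motifs.scan_pwm("ACGNACGT", near_consensus_acgt, -100.0)
        # offsets 0..3 all overlap the N; only offset 4 remains
        assert {h.offset for h in hits} == {4}

    def test_short_sequence_empty(self, near_consensus_acgt):
        assert motifs.scan_pwm("ACG", near_consensus_acgt, 0.0) == []

    def test_invalid_character_rejected(self, near_consensus_acgt):
        with pytest.raises(ValueError):
            motifs.scan_pwm("ACGU", near_consensus_acgt, 0.0)

    @pytest.mark.parametrize("seq", ["TTACGTTTGGA", "AAAACCCGGTT", "ACGTNNACGT"])
    def test_strand_symmetry(self, seq, rng):
        """Scanning the reverse complement mirrors hits exactly."""
        m = rng.dirichlet(np.ones(4) * 5, size=5)
        pwm = PWM("m", m)
        fwd = motifs.scan_pwm(seq, pwm, -10.0)
        rev = motifs.scan_pwm(revcomp(seq), pwm, -10.0)
        L = pwm.length
        mirrored = sorted(
            (len(seq) - L - h.offset, {"+": "-", "-": "+"}[h.strand], round(h.score, 9))
            for h in rev
        )
        assert mirrored == sorted((h.offset, h.strand, round(h.score, 9)) for h in fwd)


class TestScorePvalue:
    def test_uniform_pwm_ties(self, uniform_pwm):
        assert motifs.score_pvalue(uniform_pwm, 0.0) == 1.0

    @pytest.mark.parametrize("L", [2, 4, 6])
    def test_matches_enumeration(self, L, rng):
        """The lattice DP agrees with full 4^L enumeration.  Thresholds
        are taken between distinct achievable word scores: a threshold
        inside the lattice discretization width (1e-3 bits) of a word
        score is ambiguous by construction."""
        m = rng.dirichlet(np.ones(4) * 2, size=L)
        pwm = PWM("m", m)
        s = np.log2(pwm.matrix / pwm.background[None, :])
        word_scores = np.unique(
            [
                round(sum(s[j, b] for j, b in enumerate(word)), 9)
                for word in itertools.product(range(4), repeat=L)
            ]
        )
        mids = (word_scores[:-1] + word_scores[1:]) / 2
        mids = mids[np.diff(word_scores) > 0.01]
        for score in mids[:: max(1, len(mids) // 10)]:
            assert motifs.score_pvalue(pwm, score) == pytest.approx(
                enumerate_pvalue(pwm, score), abs=1e-3
            )

    def test_nonincreasing_in_score(self, near_consensus_acgt):
        scores = np.linspace(-5, 9, 30)
        ps = [motifs.score_pvalue(near_consensus_acgt, s) for s in scores]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_above_maximum_bounded(self, near_consensus_acgt):
        p = motifs.score_pvalue(near_consensus_acgt, 100.0)
        assert 0 < p <= 1 / 4**4 + 1e-12

    def test_threshold_calibration(self, near_consensus_acgt):
        thr = motifs.score_threshold(near_consensus_acgt, 0.01)
        assert motifs.score_pvalue(near_consensus_acgt, thr) <= 0.01
        assert motifs.score_pvalue(near_consensus_acgt, thr - 0.1) > 0.01


class TestPresence:
    def test_planted_site_detected(self, near_consensus_acgt):
        lib = MotifLibrary([near_consensus_acgt])
        proms = {"g1": "TT" + "ACGT" + "TTTTTT", "g2": "TTTTTTTTTTTT"}
        pres = motifs.promoter_motif_presence(proms, lib, presence_p=0.01)
        assert bool(pres.loc["g1", "acgt"]) is True
        assert bool(pres.loc["g2", "acgt"]) is False

    def test_empty_promoters_rejected(self, near_consensus_acgt):
        with pytest.raises(ValueError, match="empty"):
            motifs.promoter_motif_presence({}, MotifLibrary([near_consensus_acgt]))

    def test_batch_and_scalar_paths_agree(self, rng):
        cfg = SimConfig(seed=5, n_decoy_motifs=3)
        lib = generate_motif_library(cfg)
        seqs = {f"s{i}": "".join(rng.choice(list("ACGT"), 60)) for i in range(8)}
        batch = motifs.promoter_motif_presence(seqs, lib, 1e-3)
        mixed = dict(seqs)
        mixed["odd"] = "ACGT" * 20  # different length forces the scalar path
        scalar = motifs.promoter_motif_presence(mixed, lib, 1e-3)
        assert batch.equals(scalar.loc[list(seqs)])


class TestDirectEffect:
    def _presence(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "Oct4": [False, True, False],
                "Sox2": [True, False, False],
                "Klf4": [False, False, False],
                "cMyc": [False, False, False],
                "Oct4-Sox2": [False, False, False],
            },
            index=["gA", "gB", "gC"],
        )

    def test_definition(self):
        out = motifs.direct_effect_genes({3.0: ["gA", "gC"]}, self._presence())
        assert out == {3.0: ["gA"]}  # gB has a motif but is not DE

    def test_unknown_motif_rejected(self):
        with pytest.raises(KeyError, match="unknown motif"):
            motifs.direct_effect_genes({3.0: ["gA"]}, self._presence(), motif_ids=["Nanog"])

    def test_gene_without_promoter_rejected(self):
        with pytest.raises(ValueError, match="no promoter"):
            motifs.direct_effect_genes({3.0: ["gZ"]}, self._presence())


class TestEnrichment:
    def test_hypergeometric_example(self, near_consensus_acgt):
        """8 of 10 targets vs 10 of 90 background with the motif gives
        the exact upper tail of Hypergeom(N=100, K=18, n=10)."""
        site, plain = "TTACGTTTTT", "TTTTTTTTTT"
        targets = {f"t{i}": site if i < 8 else plain for i in range(10)}
        background = {f"b{i}": site if i < 10 else plain for i in range(90)}
        p = motifs.motif_enrichment(targets, background, near_consensus_acgt, presence_p=0.01)
        # independent exact tail from the hypergeometric pmf
        from math import comb

        expected = sum(comb(18, k) * comb(82, 10 - k) for k in range(8, 11)) / comb(100, 10)
        assert p == pytest.approx(expected, rel=1e-12)

    def test_motif_absent_everywhere(self, near_consensus_acgt):
        targets = {"t": "TTTTTTTT"}
        background = {"b": "GGGGGGGG"}
        assert motifs.motif_enrichment(targets, background, near_consensus_acgt, 0.01) == 1.0

    def test_motif_everywhere(self, near_consensus_acgt):
        targets = {"t": "TTACGTTT"}
        background = {"b": "GGACGTGG"}
        assert motifs.motif_enrichment(targets, background, near_consensus_acgt, 0.01) == 1.0

    def test_empty_sets_rejected(self, near_consensus_acgt):
        with pytest.raises(ValueError):
            motifs.motif_enrichment({}, {"b": "ACGT"}, near_consensus_acgt)


class TestFluctuation:
    def test_constant_series_scores_zero(self):
        s = [
            motifs.EnrichmentSeries("const", [3, 6, 12, 24], [1e-3] * 4),
            motifs.EnrichmentSeries("varies", [3, 6, 12, 24], [1e-10, 1, 1e-10, 1]),
        ]
        out = motifs.fluctuation_rank(s, top_k=1)
        assert out[0].motif_id == "varies" and out[1].score == 0.0

    def test_rank_permutation_and_determinism(self):
        series = [
            motifs.EnrichmentSeries(f"m{i}", [3, 6], [10.0 ** -(i % 4), 1.0])
            for i in range(9)
        ]
        out1 = motifs.fluctuation_rank(series, top_k=3)
        out2 = motifs.fluctuation_rank(list(reversed(series)), top_k=3)
        assert sorted(r.rank for r in out1) == list(range(1, 10))
        assert [r.motif_id for r in out1] == [r.motif_id for r in out2]
        scores = [r.score for r in out1]
        assert scores == sorted(scores, reverse=True)

    def test_tie_break_lexicographic(self):
        series = [
            motifs.EnrichmentSeries("b", [3, 6], [0.5, 0.5]),
            motifs.EnrichmentSeries("a", [3, 6], [0.5, 0.5]),
        ]
        out = motifs.fluctuation_rank(series, top_k=1)
        assert [r.motif_id for r in out] == ["a", "b"]

    def test_mismatched_grids_rejected(self):
        series = [
            motifs.EnrichmentSeries("a", [3, 6], [0.5, 0.5]),
            motifs.EnrichmentSeries("b", [3, 12], [0.5, 0.5]),
        ]
        with pytest.raises(ValueError, match="time grid"):
            motifs.fluctuation_rank(series, top_k=1)

    def test_planted_oscillating_motif_ranks_first(self):
        """One motif whose target membership oscillates across time
        outranks 50 static decoys."""
        cfg = SimConfig(seed=9)
        lib = generate_motif_library(cfg)
        seqs, targets, planted = generate_fluctuation_experiment(cfg, seed=77)
        pres = motifs.presence_matrix(seqs, lib, 1e-4)
        ranking = motifs.fluctuation_rank(motifs.enrichment_series(pres, targets), top_k=20)
        assert ranking[0].motif_id == planted
        assert ranking[0].top
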