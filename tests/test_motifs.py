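"""PWM scoring, exact p-values, scanning and the occupancy matrix."""

import itertools

import numpy as np
import pytest

from crckit.intervals import GenomeAssembly, GenomicInterval, RegionSet
from crckit.motifs import (
    MotifHit,
    MotifModel,
    occupancy_matrix,
    reverse_complement,
    scan_regions,
)


def random_motif(rng, w, name="M", concentration=0.5, **kw):
    probs = rng.dirichlet(np.full(4, concentration), size=w).T
    return MotifModel(name, probs, **kw)


def enumerate_pvalue(motif: MotifModel, score_bits: float) -> float:
    """Brute-force oracle: sum background probabilities of all w-mers whose
    integerized score reaches the query score."""
    units = int(np.rint(score_bits / motif.granularity))
    total = 0.0
    for word in itertools.product(range(4), repeat=motif.width):
        s = sum(motif.int_scores[b, j] for j, b in enumerate(word))
        if s >= units:
            p = 1.0
            for b in word:
                p *= motif.background[b]
            total += p
    return total


class TestLogOdds:
    def test_uniform_motif_scores_zero(self):
        m = MotifModel("U", np.full((4, 5), 0.25))
        assert m.log_odds_score("ACGTA") == pytest.approx(0.0, abs=1e-9)

    def test_consensus_window_bits(self):
        # near-deterministic columns, vanishing pseudocount: 4 * log2(4) bits
        probs = np.zeros((4, 4))
        probs[0, :] = 1.0  # AAAA
        m = MotifModel("C", probs, pseudocount=1e-12)
        assert m.log_odds_score("AAAA") == pytest.approx(8.0, abs=1e-2)

    def test_hand_summed_columns(self):
        rng = np.random.default_rng(5)
        m = random_motif(rng, 5)
        window = "ACGTT"
        codes = [0, 1, 2, 3, 3]
        expected = sum(m.int_scores[b, j] for j, b in enumerate(codes)) \
            * m.granularity
        assert m.log_odds_score(window) == pytest.approx(expected, abs=1e-12)

    def test_n_contributes_zero(self):
        rng = np.random.default_rng(6)
        m = random_motif(rng, 4)
        full = m.log_odds_score("ACGT")
        with_n = m.log_odds_score("ANGT")
        drop = m.int_scores[1, 1] * m.granularity
        assert with_n == pytest.approx(full - drop, abs=1e-12)


class TestScorePvalue:
    def test_uniform_motif_nonpositive_score(self):
        m = MotifModel("U", np.full((4, 6), 0.25))
        assert m.score_pvalue(0.0) == 1.0
        assert m.score_pvalue(-3.0) == 1.0

    def test_consensus_max_score_single_word(self):
        probs = np.zeros((4, 4))
        probs[1, :] = 1.0
        m = MotifModel("C", probs, pseudocount=1e-9)
        assert m.score_pvalue(m.max_score()) == pytest.approx(0.25 ** 4, rel=1e-9)

    def test_min_score_has_p_one(self):
        rng = np.random.default_rng(7)
        m = random_motif(rng, 5)
        min_score = m.int_scores.min(axis=0).sum() * m.granularity
        assert m.score_pvalue(min_score) == 1.0

    def test_nonincreasing_in_score(self):
        rng = np.random.default_rng(8)
        m = random_motif(rng, 6)
        scores = np.linspace(-10, m.max_score(), 50)
        ps = [m.score_pvalue(s) for s in scores]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    @pytest.mark.parametrize("w", [2, 3, 4, 5, 6])
    def test_dp_matches_enumeration(self, w):
        rng = np.random.default_rng(100 + w)
        for trial in range(4):
            bg = rng.dirichlet(np.full(4, 2.0))
            m = random_motif(rng, w, background=bg)
            for q in (0.1, 0.5, 0.9):
                s = np.quantile(
                    [m.int_scores[:, j] @ np.eye(4)[k] for j in range(w)
                     for k in range(4)], q) * w * m.granularity / 2
                assert m.score_pvalue(s) == pytest.approx(
                    enumerate_pvalue(m, s), abs=1e-9)


def make_genome(seq: str) -> GenomeAssembly:
    return GenomeAssembly.from_sequences({"chr1": seq})


class TestScanRegions:
    def _implant_genome(self, rng, site, length=4000, pos=1000):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, length))
        seq = seq[:pos] + site + seq[pos + len(site):]
        return make_genome(seq)

    def _strong_motif(self, name="S", w=14, seed=9):
        rng = np.random.default_rng(seed)
        consensus = rng.integers(0, 4, w)
        probs = np.full((4, w), 0.01)
        probs[consensus, np.arange(w)] = 0.97
        probs /= probs.sum(axis=0)
        return MotifModel(name, probs)

    def test_implanted_consensus_recovered(self):
        rng = np.random.default_rng(10)
        m = self._strong_motif()
        genome = self._implant_genome(rng, m.consensus)
        regions = RegionSet([GenomicInterval("chr1", 900, 1200)])
        hits = scan_regions(m, regions, genome)[m.name]
        assert len(hits) == 1
        assert hits[0].region.start == 1000
        assert hits[0].strand == "+"
        assert hits[0].q < 1e-5

    def test_all_n_region_no_hits(self):
        genome = make_genome("N" * 500)
        m = self._strong_motif()
        regions = RegionSet([GenomicInterval("chr1", 0, 500)])
        assert scan_regions(m, regions, genome)[m.name] == []

    def test_reverse_complement_found_on_minus(self):
        rng = np.random.default_rng(11)
        m = self._strong_motif()
        genome = self._implant_genome(rng, reverse_complement(m.consensus))
        regions = RegionSet([GenomicInterval("chr1", 900, 1200)])
        hits = scan_regions(m, regions, genome)[m.name]
        assert len(hits) == 1
        assert hits[0].strand == "-"
        assert hits[0].region.start == 1000

    def test_mirror_image_under_reverse_complement(self):
        rng = np.random.default_rng(12)
        m = self._strong_motif(w=16, seed=13)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 600))
        seq = seq[:100] + m.consensus + seq[100 + m.width:]
        fwd = scan_regions(m, RegionSet([GenomicInterval("chr1", 0, 600)]),
                           make_genome(seq), background=np.full(4, 0.25))
        rev = scan_regions(m, RegionSet([GenomicInterval("chr1", 0, 600)]),
                           make_genome(reverse_complement(seq)),
                           background=np.full(4, 0.25))
        f, r = fwd[m.name], rev[m.name]
        assert len(f) == len(r) == 1
        assert r[0].region.start == 600 - f[0].region.end
        assert {f[0].strand, r[0].strand} == {"+", "-"}
        assert f[0].score_bits == pytest.approx(r[0].score_bits, abs=1e-12)

    def test_missing_sequence_names_chrom(self):
        genome = make_genome("ACGT" * 100)
        m = self._strong_motif()
        regions = RegionSet([GenomicInterval("chr9", 0, 50)])
        with pytest.raises(Exception, match="chr9"):
            scan_regions(m, regions, genome)

    def test_bh_q_monotone_in_p(self):
        rng = np.random.default_rng(14)
        m = self._strong_motif(w=10, seed=15)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
        seq = seq[:50] + m.consensus + seq[50 + m.width:]
        hits = scan_regions(m, RegionSet([GenomicInterval("chr1", 0, 2000)]),
                            make_genome(seq), q_max=1.01)[m.name]
        by_p = sorted(hits, key=lambda h: h.p)
        qs = [h.q for h in by_p]
        assert all(a <= b + 1e-15 for a, b in zip(qs, qs[1:]))
        assert all(h.q >= h.p - 1e-15 for h in hits)


def hit(start, end, tf="A"):
    return MotifHit(tf, GenomicInterval("chr1", start, end), "+", 10.0,
                    1e-9, 1e-7)


class TestOccupancyMatrix:
    def test_single_tf_disjoint_hits(self):
        hits = {"A": [hit(100, 110), hit(500, 510), hit(900, 910)]}
        mat, corr, order = occupancy_matrix(hits)
        assert mat.shape == (3, 1)
        assert (mat.to_numpy() == 1).all()

    def test_identical_hit_sets_correlate(self):
        hits = {"A": [hit(100, 110), hit(500, 510)],
                "B": [hit(100, 110, "B"), hit(500, 510, "B")]}
        _, corr, _ = occupancy_matrix(hits)
        assert corr.loc["A", "B"] == pytest.approx(1.0)

    def test_disjoint_hit_sets_anticorrelate(self):
        k = 8
        hits = {"A": [hit(2000 * i, 2000 * i + 10) for i in range(k)],
                "B": [hit(2000 * (i + k), 2000 * (i + k) + 10, "B")
                      for i in range(k)]}
        _, corr, _ = occupancy_matrix(hits)
        # complementary binary columns over 2k regions, k each
        assert corr.loc["A", "B"] == pytest.approx(-1.0)

    def test_zero_hit_tf_dropped(self):
        hits = {"A": [hit(0, 10)], "B": []}
        mat, _, _ = occupancy_matrix(hits)
        assert list(mat.columns) == ["A"]
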