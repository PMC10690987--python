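"""Tests of PWM models, exact p-values, promoter extraction and scanning."""

import itertools

import numpy as np
import pytest

import saltmem as sm
from saltmem.motifscan import (
    SCALE,
    MotifModel,
    read_promoters_fasta,
    reverse_complement,
    write_meme,
    write_promoters_fasta,
)


def exhaustive_pvalues(model):
    """Enumerate all 4^w words; return dict integer-score -> P(score >= s)."""
    w = model.width
    probs = {}
    for word in itertools.product(range(4), repeat=w):
        s = int(sum(model.int_scores[b, j] for j, b in enumerate(word)))
        p = np.prod([model.background[b] for b in word])
        probs[s] = probs.get(s, 0.0) + p
    scores = sorted(probs)
    sf = {}
    acc = 0.0
    for s in reversed(scores):
        acc += probs[s]
        sf[s] = acc
    return sf


class TestMotifModel:
    def test_deterministic_motif_max_score_and_p(self):
        m = MotifModel.from_consensus("det", "ACG", epsilon=0.0)
        assert m.max_score == 6 * SCALE  # 2 bits per column
        assert m.pvalue(m.max_score) == pytest.approx(1 / 64)

    def test_uninformative_single_column(self):
        m = MotifModel(name="flat", probs=np.full((4, 1), 0.25), background=np.full(4, 0.25))
        assert m.max_score == 0
        assert m.pvalue(0) == pytest.approx(1.0)

    def test_dp_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(3)
        for w in (2, 3, 4, 5):
            counts = rng.integers(1, 20, size=(4, w)).astype(float)
            m = MotifModel.from_counts(f"rand{w}", counts)
            expected = exhaustive_pvalues(m)
            for s, p in expected.items():
                assert m.pvalue(s) == pytest.approx(p, abs=1e-12)
            pmf_scores, pmf = m.score_pmf()
            assert pmf.sum() == pytest.approx(1.0, abs=1e-9)

    def test_pvalue_non_increasing_in_score(self):
        m = MotifModel.from_consensus("det", "ACGTACGT")
        scores, _ = m.score_pmf()
        pv = m.pvalue(scores)
        assert (np.diff(pv) <= 1e-15).all()

    def test_bad_column_sum_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            MotifModel(
                name="bad",
                probs=np.array([[0.5], [0.5], [0.5], [0.5]]),
                background=np.full(4, 0.25),
            )


class TestMemeIo:
    def test_roundtrip_preserves_motifs(self, tmp_path):
        path = tmp_path / "motifs.meme"
        write_meme({"M1": "ACGTACGT", "M2": "TTTTGGGG"}, path)
        models = sm.read_meme(path)
        assert [m.name for m in models] == ["M1", "M2"]
        assert models[0].width == 8
        # consensus column dominated by the consensus base
        assert models[0].probs[0, 0] > 0.99  # A at position 0

    def test_malformed_matrix_names_motif(self, tmp_path):
        path = tmp_path / "bad.meme"
        path.write_text(
            "MEME version 4\n\nALPHABET= ACGT\n\n"
            "Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n"
            "MOTIF BROKEN\n"
            "letter-probability matrix: alength= 4 w= 2 nsites= 20 E= 0\n"
            "0.9 0.9 0.9 0.9\n0.25 0.25 0.25 0.25\n"
        )
        with pytest.raises(ValueError, match="BROKEN"):
            sm.read_meme(path)


class TestExtractPromoters:
    @pytest.fixture()
    def toy_genome(self, tmp_path):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=5000))
        fasta = tmp_path / "genome.fasta"
        fasta.write_text(">chr1\n" + "\n".join(seq[i : i + 80] for i in range(0, 5000, 80)) + "\n")
        gff = tmp_path / "genes.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t2001\t2500\t.\t+\t.\tID=plusgene\n"
            "chr1\tsrc\tgene\t2600\t3000\t.\t-\t.\tID=minusgene\n"
            "chr1\tsrc\tgene\t500\t900\t.\t+\t.\tID=edgegene\n"
            "chr1\tsrc\tgene\t1\t100\t.\t+\t.\tID=emptygene\n"
        )
        return seq, fasta, gff

    def test_plus_strand_interval(self, toy_genome):
        seq, fasta, gff = toy_genome
        with pytest.warns(UserWarning, match="emptygene"):
            promoters = sm.extract_promoters(fasta, gff, length=1000)
        p = promoters["plusgene"]
        assert (p.start, p.end) == (1001, 2000)
        assert p.seq == seq[1000:2000]

    def test_minus_strand_reverse_complemented(self, toy_genome):
        seq, fasta, gff = toy_genome
        with pytest.warns(UserWarning):
            promoters = sm.extract_promoters(fasta, gff, length=1000)
        p = promoters["minusgene"]
        assert (p.start, p.end) == (3001, 4000)
        assert p.seq == reverse_complement(seq[3000:4000])

    def test_contig_edge_truncation(self, toy_genome):
        _, fasta, gff = toy_genome
        with pytest.warns(UserWarning):
            promoters = sm.extract_promoters(fasta, gff, length=1000)
        p = promoters["edgegene"]
        assert (p.start, p.end) == (1, 499)
        assert len(p.seq) == 499

    def test_missing_contig_raises(self, tmp_path, toy_genome):
        _, fasta, _ = toy_genome
        gff = tmp_path / "bad.gff3"
        gff.write_text("chrX\tsrc\tgene\t2001\t2500\t.\t+\t.\tID=lost\n")
        with pytest.raises(ValueError, match="chrX"):
            sm.extract_promoters(fasta, gff)


class TestScan:
    def test_planted_consensus_found_at_offset(self):
        rng = np.random.default_rng(0)
        word = "ACGTACGT"
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        seq = seq[:100] + word + seq[108:]
        m = MotifModel.from_consensus("det", word)
        hits = sm.scan(m, {"gene1": seq})
        best = [h for h in hits if h.offset == 100 and h.strand == "+"]
        assert len(best) == 1
        assert best[0].score == pytest.approx(m.max_score / SCALE)

    def test_all_n_promoter_yields_nothing(self):
        m = MotifModel.from_consensus("det", "ACGTACGT")
        assert sm.scan(m, {"gene1": "N" * 500}) == []

    def test_reverse_complement_symmetry(self):
        rng = np.random.default_rng(4)
        m = MotifModel.from_consensus("det", "ACGTTGCA")
        seqs = {
            f"g{i}": "".join(rng.choice(list("ACGT"), size=300)) for i in range(5)
        }
        hits_fwd = sm.scan(m, seqs, p_threshold=1e-2)
        hits_rc = sm.scan(
            m, {g: reverse_complement(s) for g, s in seqs.items()}, p_threshold=1e-2
        )
        w = m.width
        mirrored = {
            (h.gene, len(seqs[h.gene]) - w - h.offset, "+" if h.strand == "-" else "-")
            for h in hits_rc
        }
        assert {(h.gene, h.offset, h.strand) for h in hits_fwd} == mirrored

    def test_false_positive_rate_matches_threshold(self):
        rng = np.random.default_rng(8)
        m = MotifModel.from_consensus("det", "ACGTTGCA")
        n_pos = 10**6
        seq = "".join(rng.choice(list("ACGT"), size=n_pos + m.width - 1))
        p_thr = 1e-3
        hits = sm.scan(m, {"bg": seq}, p_threshold=p_thr)
        # attainable tail mass just below the threshold
        scores, pmf = m.score_pmf()
        pv = m.pvalue(scores)
        eff_p = max(pv[pv < p_thr])
        expected = eff_p * n_pos * 2
        assert abs(len(hits) - expected) <= 3 * np.sqrt(expected)

    def test_planted_simulation_recovery(self, strong_sim):
        truth = strong_sim["truth"]
        promoters = strong_sim["promoters"]
        found = 0
        total = 0
        for fam, word in strong_sim["consensi"].items():
            m = MotifModel.from_consensus(fam, word)
            hitset = {
                (h.gene, h.offset, h.strand) for h in sm.scan(m, promoters)
            }
            planted = [
                (g, o, s) for f, g, o, s in truth.motif_instances if f == fam
            ]
            total += len(planted)
            found += sum(1 for x in planted if x in hitset)
        assert total > 0
        assert found / total >= 0.95


class TestTargetsAndOverlap:
    def test_overlap_patterns(self):
        table = sm.overlap_table({"x": {"a", "b"}, "y": {"b", "c"}})
        assert table.common == ("b",)
        assert table.patterns[(1, 0)] == 1
        assert table.patterns[(1, 1)] == 1
        assert table.patterns[(0, 1)] == 1

    def test_identical_sets_all_common(self):
        sets = {f"tf{i}": {"a", "b", "c", "d", "e"} for i in range(6)}
        table = sm.overlap_table(sets)
        assert table.n_common == 5

    def test_targets_require_one_hit(self):
        hits = [
            sm.MotifHit("g1", 5, "+", 10.0, 1e-5),
            sm.MotifHit("g1", 40, "-", 9.0, 5e-5),
            sm.MotifHit("g2", 7, "+", 10.0, 1e-5),
        ]
        assert sm.targets_of(hits) == {"g1", "g2"}

    def test_promoter_fasta_roundtrip(self, tmp_path):
        promoters = {
            "gA": sm.PromoterRecord("gA", "ACGTACGTAC", "chr1", 1, 10, "+"),
            "gB": sm.PromoterRecord("gB", "TTTTGGGGCC", "chr2", 5, 14, "-"),
        }
        path = tmp_path / "prom.fasta"
        write_promoters_fasta(promoters, path)
        back = read_promoters_fasta(path)
        assert back["gA"].seq == "ACGTACGTAC"
        assert back["gB"].seq == "TTTTGGGGCC"
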