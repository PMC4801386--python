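import numpy as np
import pytest
from Bio.Seq import reverse_complement

from _oracle import exhaustive_map
from conftest import random_dna
from sialoquant import readmap
from sialoquant.errors import InputError
from sialoquant.readmap import (
    Assignment,
    CdsRecord,
    MapParams,
    ReadRecord,
    build_count_matrix,
    map_read,
    trim_read,
)


def _read(seq, quals=None, read_id="r", lib="FSG"):
    return ReadRecord(read_id, seq, quals if quals is not None else [40] * len(seq), lib)


class TestTrim:
    def test_high_quality_read_unchanged(self):
        read = _read("A" * 101)
        assert trim_read(read) is read

    def test_low_quality_tail_removed(self):
        read = _read("A" * 101, [30] * 91 + [2] * 10)
        trimmed = trim_read(read)
        assert len(trimmed.sequence) == 91
        assert len(trimmed.qualities) == 91

    def test_dropped_below_seed_length(self):
        read = _read("A" * 30, [30] * 20 + [2] * 10)
        assert trim_read(read) is None  # 20 < 25

    def test_internal_low_quality_base_survives(self):
        quals = [30] * 101
        quals[50] = 2
        assert len(trim_read(_read("A" * 101, quals)).sequence) == 101

    def test_discard_mode_drops_whole_read(self):
        quals = [30] * 101
        quals[50] = 2
        assert trim_read(_read("A" * 101, quals), mode="discard") is None
        assert trim_read(_read("A" * 101), mode="discard") is not None


class TestMapRead:
    def test_exact_unique_substring(self, rng):
        cds = CdsRecord("C1", random_dna(rng, 300))
        hits = map_read(_read(cds.sequence[100:160]), [cds])
        assert len(hits) == 1
        assert hits[0].identity == 100.0 and hits[0].gaps == 0

    def test_identity_threshold_boundary(self, rng):
        cds = CdsRecord("C1", random_dna(rng, 300))
        frag = list(cds.sequence[50:151])
        flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
        for i in (10, 30, 60, 90):  # 4 substitutions: 97/101 = 96.0% >= 95
            frag[i] = flip[frag[i]]
        hits = map_read(_read("".join(frag)), [cds])
        assert len(hits) == 1 and hits[0].identity == pytest.approx(9700 / 101)
        for i in (20, 75):  # 6 substitutions: 95/101 = 94.1% < 95
            frag[i] = flip[frag[i]]
        assert map_read(_read("".join(frag)), [cds]) == []

    def test_multi_hit_cap_is_lexicographic(self, rng):
        seq = random_dna(rng, 250)
        copies = [CdsRecord(f"D{i}", seq) for i in (5, 3, 0, 4, 2, 1)]
        hits = map_read(_read(seq[10:111]), copies)
        assert [h.cds_id for h in hits] == ["D0", "D1", "D2", "D3", "D4"]
        assert len({h.score for h in hits}) == 1

    def test_empty_reference(self):
        assert map_read(_read("ACGT" * 30), []) == []

    def test_single_gap_alignment_recovered(self, rng):
        cds = CdsRecord("C1", random_dna(rng, 400))
        # read with a 2-base deletion relative to the reference
        frag = cds.sequence[100:203]
        read = frag[:40] + frag[42:]
        hits = map_read(_read(read), [cds])
        assert len(hits) == 1 and hits[0].gaps == 1
        assert hits[0].identity == pytest.approx(100 * 101 / 103)

    def test_strand_symmetry(self, rng):
        cds = [CdsRecord(f"C{i}", random_dna(rng, 300)) for i in range(5)]
        for source in cds[:3]:
            fwd = _read(source.sequence[30:131], read_id="f")
            rev = _read(reverse_complement(source.sequence[30:131]), read_id="v")
            fwd_hits = {(h.cds_id, h.score, h.identity) for h in map_read(fwd, cds)}
            rev_hits = {(h.cds_id, h.score, h.identity) for h in map_read(rev, cds)}
            assert fwd_hits == rev_hits
            strands = {h.cds_id: h.strand for h in map_read(fwd, cds)}
            flipped = {h.cds_id: h.strand for h in map_read(rev, cds)}
            assert all(strands[c] != flipped[c] for c in strands)

    def test_identity_threshold_monotonicity(self, rng):
        cds = [CdsRecord(f"C{i}", random_dna(rng, 300)) for i in range(8)]
        reads = []
        flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
        for i, source in enumerate(cds):
            frag = list(source.sequence[20:121])
            for pos in rng.choice(101, size=int(rng.integers(0, 6)), replace=False):
                frag[pos] = flip[frag[pos]]
            reads.append(_read("".join(frag), read_id=f"r{i}"))
        counts = []
        for threshold in (90.0, 95.0, 99.0):
            params = MapParams(min_identity=threshold)
            counts.append(sum(len(map_read(r, cds, params)) for r in reads))
        assert counts[0] >= counts[1] >= counts[2]

    def test_agrees_with_exhaustive_oracle_on_small_instances(self, rng):
        flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
        for _ in range(3):
            n = int(rng.integers(5, 12))
            cds = [CdsRecord(f"C{i:02d}", random_dna(rng, int(rng.integers(130, 250)))) for i in range(n)]
            cds.append(CdsRecord(f"C{n:02d}", cds[0].sequence))  # exact duplicate
            for j in range(20):
                src = cds[int(rng.integers(0, len(cds)))]
                L = int(rng.integers(60, 102))
                start = int(rng.integers(0, src.length - L + 1))
                frag = list(src.sequence[start : start + L])
                for pos in rng.choice(L, size=int(rng.integers(0, 5)), replace=False):
                    frag[pos] = flip[frag[pos]]
                seq = "".join(frag)
                if rng.random() < 0.5:
                    seq = reverse_complement(seq)
                read = _read(seq, read_id=f"r{j}")
                got = sorted((h.cds_id, h.score) for h in map_read(read, cds))
                want = sorted(exhaustive_map(read, cds))
                assert got == want


class TestCountMatrix:
    def test_empty_assignments_give_zero_matrix(self):
        m = build_count_matrix({}, ["A", "B"])
        assert m.counts.to_numpy().sum() == 0
        assert (m.totals == 0).all()

    def test_whole_count_policy_for_ties(self):
        hits = [
            Assignment("r1", "A", 200, 100.0, 0, "+"),
            Assignment("r1", "B", 200, 100.0, 0, "+"),
        ]
        m = build_count_matrix({"FSG": hits}, ["A", "B"])
        assert m.counts.loc["A", "FSG"] == 1 and m.counts.loc["B", "FSG"] == 1
        assert m.totals["FSG"] == 2

    def test_fractional_policy_for_ties(self):
        hits = [
            Assignment("r1", "A", 200, 100.0, 0, "+"),
            Assignment("r1", "B", 200, 100.0, 0, "+"),
            Assignment("r2", "A", 180, 99.0, 0, "-"),
        ]
        m = build_count_matrix({"FSG": hits}, ["A", "B"], policy="fractional")
        assert m.counts.loc["A", "FSG"] == pytest.approx(1.5)
        assert m.totals["FSG"] == pytest.approx(2.0)

    def test_unique_reads_count_once(self):
        hits = [Assignment(f"r{i}", "A", 200, 100.0, 0, "+") for i in range(10)]
        m = build_count_matrix({"FSG": hits}, ["A"])
        assert m.totals["FSG"] == 10

    def test_unknown_library_label_rejected(self):
        with pytest.raises(InputError):
            build_count_matrix({"XXX": []}, ["A"])

    def test_totals_equal_column_sums(self, rng):
        cds_ids = [f"C{i}" for i in range(6)]
        hits = {
            lib: [
                Assignment(f"{lib}r{i}", cds_ids[int(rng.integers(0, 6))], 200, 100.0, 0, "+")
                for i in range(30)
            ]
            for lib in ("FSG", "MSG")
        }
        m = build_count_matrix(hits, cds_ids, libraries=["FSG", "MSG"])
        assert (m.totals == m.counts.sum(axis=0)).all()


class TestFastaFastqIo:
    def test_reference_and_fastq_round_trip(self, tmp_path, rng):
        from sialoquant import synthio

        cds = [CdsRecord(f"C{i}", random_dna(rng, 150)) for i in range(3)]
        synthio.write_fasta(cds, tmp_path / "ref.fasta")
        back = readmap.read_reference_fasta(tmp_path / "ref.fasta")
        assert [(r.cds_id, r.sequence) for r in back] == [
            (r.cds_id, r.sequence) for r in cds
        ]
        reads = [_read(cds[0].sequence[:101], read_id=f"r{i}") for i in range(4)]
        synthio.write_fastq(reads, tmp_path / "lib.fastq")
        back_reads = list(readmap.read_fastq(tmp_path / "lib.fastq", "FSG"))
        assert [r.sequence for r in back_reads] == [r.sequence for r in reads]
        assert all(list(r.qualities) == [40] * 101 for r in back_reads)
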