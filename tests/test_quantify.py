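"""Mapping and counting semantics: seed alignment, tolerances, NTA, miRGFF3."""

import io

import numpy as np
import pytest

from smallrna.preprocess import CollapsedRead
from smallrna.quantify import (AlignmentRecord, CountMatrix, IsomirRecord,
                               MappingParams, count_class_sample, count_mirnas,
                               count_mirnas_sample, map_reads,
                               quantify_isomirs_sample, read_mirgff3,
                               write_mirgff3)
from smallrna.references import MatureAnnotation, ReferenceBundle, build_index, reverse_complement


def brute_force_map(read: str, ref: str, seed_len: int, cap: int):
    """Exhaustive ungapped search (independent mapping oracle)."""
    hits = []
    for oriented, strand in ((read, "+"), (reverse_complement(read), "-")):
        target = oriented if strand == "+" else read  # compare in read orientation
        for pos in range(len(ref) - len(read) + 1):
            window = ref[pos:pos + len(read)]
            if strand == "-":
                window = reverse_complement(window)
            mism = sum(1 for a, b in zip(read, window) if a != b)
            seed_mism = sum(1 for a, b in zip(read[:seed_len], window[:seed_len]) if a != b)
            if seed_mism == 0 and mism <= cap:
                hits.append((pos, strand, mism))
    return sorted(set(hits))


class TestMapReads:
    def test_unique_exact_hit(self, rng):
        ref = "".join(rng.choice(list("ACGT"), size=300))
        read = ref[100:122]
        idx = build_index({"c": ref}, 18)
        alns, stats = map_reads([CollapsedRead(read, 1)], idx, {"c": ref}, MappingParams())
        plus = [a for a in alns if a.strand == "+"]
        assert len(plus) == 1 and plus[0].pos == 100 and plus[0].mismatches == 0

    def test_multimapper_over_cap_discarded(self):
        unit = "ACGTTGCAACGGTTACCGGA"  # 20 nt, 6 copies separated by spacers
        ref = ("TTTTT".join([unit] * 6))
        idx = build_index({"c": ref}, 18)
        alns, stats = map_reads([CollapsedRead(unit, 3)], idx, {"c": ref},
                                MappingParams(max_hits=5), max_mismatches=0, both_strands=False)
        assert stats["multimapper_over_cap"] == 1 and alns == []

    def test_mismatch_position_relative_to_seed(self, rng):
        ref = "".join(rng.choice(list("ACGT"), size=200))
        read = list(ref[50:72])
        # substitution outside the 18-nt seed is tolerated with cap 1
        read20 = read.copy()
        read20[20] = {"A": "C"}.get(read20[20], "A")
        idx = build_index({"c": ref}, 18)
        alns, _ = map_reads([CollapsedRead("".join(read20), 1)], idx, {"c": ref},
                            MappingParams(), max_mismatches=1, both_strands=False)
        assert any(a.pos == 50 and a.mismatches == 1 for a in alns)
        # the same substitution inside the seed kills the alignment at 50
        read10 = read.copy()
        read10[10] = {"A": "C"}.get(read10[10], "A")
        alns, _ = map_reads([CollapsedRead("".join(read10), 1)], idx, {"c": ref},
                            MappingParams(), max_mismatches=1, both_strands=False)
        assert not any(a.pos == 50 for a in alns)

    def test_short_read_unmapped(self):
        idx = build_index({"c": "ACGTACGTACGTACGTACGTACGT"}, 18)
        _, stats = map_reads([CollapsedRead("ACGTACG", 1)], idx,
                             {"c": "ACGTACGTACGTACGTACGTACGT"}, MappingParams())
        assert stats["too_short"] == 1

    def test_matches_brute_force_on_random_reference(self, rng):
        """Oracle equivalence on a random 10 kb reference."""
        ref = "".join(rng.choice(list("ACGT"), size=10_000))
        params = MappingParams(max_hits=50)
        idx = build_index({"c": ref}, 18)
        reads = []
        for i in range(60):
            pos = int(rng.integers(0, len(ref) - 22))
            seq = list(ref[pos:pos + 22])
            if i % 3 == 1:  # mutate one base
                j = int(rng.integers(0, 22))
                seq[j] = "ACGT"[(("ACGT".index(seq[j])) + 1) % 4]
            if i % 3 == 2:
                seq = list(reverse_complement("".join(seq)))
            reads.append("".join(seq))
        for seq in reads:
            alns, _ = map_reads([CollapsedRead(seq, 1)], idx, {"c": ref}, params,
                                max_mismatches=1)
            got = sorted({(a.pos, a.strand, a.mismatches) for a in alns})
            assert got == brute_force_map(seq, ref, 18, 1)


@pytest.fixture(scope="module")
def mirna_reference(rng=np.random.default_rng(5)):
    """One precursor with a 22-nt mature flanked by 10 nt on both sides."""
    prec = "".join(rng.choice(list("ACGT"), size=60))
    mature = MatureAnnotation("prec", "mir-a", 10, 32, "5p")
    return prec, mature


class TestCountMirnas:
    def _aln(self, prec, start, end, mism=0):
        return AlignmentRecord(prec[start:end], 1, "prec", start, "+", mism)

    @pytest.mark.parametrize("d5,d3", [(d5, d3) for d5 in range(4) for d3 in range(7)])
    def test_tolerance_boundary_lattice(self, mirna_reference, d5, d3):
        """Counted iff 5' offset <= 2 and 3' offset <= 5 (defaults)."""
        prec, m = mirna_reference
        aln = self._aln(prec, m.start - d5, m.end + d3)
        counts = count_mirnas_sample([aln], [m], MappingParams())
        assert (counts.get("mir-a", 0) == 1) == (d5 <= 2 and d3 <= 5)

    def test_exact_mature_counted(self, mirna_reference):
        prec, m = mirna_reference
        counts = count_mirnas_sample([self._aln(prec, m.start, m.end)], [m], MappingParams())
        assert counts["mir-a"] == 1

    def test_mismatch_cap(self, mirna_reference):
        prec, m = mirna_reference
        aln = self._aln(prec, m.start, m.end, mism=2)
        assert count_mirnas_sample([aln], [m], MappingParams()) == {}

    def test_monotone_in_tolerances(self, mirna_reference, rng):
        """Relaxing offsets or the mismatch cap never decreases counts."""
        prec, m = mirna_reference
        alns = [self._aln(prec, m.start - int(d5), m.end + int(d3), int(mm))
                for d5, d3, mm in zip(rng.integers(0, 4, 30), rng.integers(0, 7, 30),
                                      rng.integers(0, 3, 30))]
        base = sum(count_mirnas_sample(alns, [m], MappingParams()).values())
        for kwargs in ({"offset5": 3}, {"offset3": 6}, {"total_mismatches_mirna": 2}):
            relaxed = sum(count_mirnas_sample(alns, [m], MappingParams(**kwargs)).values())
            assert relaxed >= base


class TestIsomirs:
    def _bundle(self, prec):
        b = ReferenceBundle(precursors={"prec": prec})
        return b

    def test_nta_not_counted_as_mismatch(self, mirna_reference):
        """mature + A where the template continues with G -> NTA, retained."""
        prec, m = mirna_reference
        cont = prec[m.end]
        added = "A" if cont != "A" else "C"
        seq = prec[m.start:m.end] + added
        aln = AlignmentRecord(seq, 1, "prec", m.start, "+", 1,
                              [(len(seq) - 1, cont, added)])
        recs = quantify_isomirs_sample([aln], [m], self._bundle(prec), MappingParams())
        assert len(recs) == 1
        assert recs[0].nta == added
        assert f"iso_add3p:1" in recs[0].variant_label

    def test_templated_extension_is_3p_shift(self, mirna_reference):
        prec, m = mirna_reference
        seq = prec[m.start:m.end + 1]  # extension matches the template
        aln = AlignmentRecord(seq, 1, "prec", m.start, "+", 0, [])
        recs = quantify_isomirs_sample([aln], [m], self._bundle(prec), MappingParams())
        assert recs[0].nta == ""
        assert "iso_3p:+1" in recs[0].variant_label

    def test_two_internal_substitutions_rejected(self, mirna_reference):
        prec, m = mirna_reference
        seq = prec[m.start:m.end]
        aln = AlignmentRecord(seq, 1, "prec", m.start, "+", 2,
                              [(5, prec[m.start + 5], "N"), (8, prec[m.start + 8], "N")])
        recs = quantify_isomirs_sample([aln], [m], self._bundle(prec), MappingParams())
        assert recs == []

    def test_canonical_variant_is_na(self, mirna_reference):
        prec, m = mirna_reference
        aln = AlignmentRecord(prec[m.start:m.end], 1, "prec", m.start, "+", 0, [])
        recs = quantify_isomirs_sample([aln], [m], self._bundle(prec), MappingParams())
        assert recs[0].variant_label == "NA"


class TestCountClass:
    def test_lowest_mismatch_wins(self):
        alns = [AlignmentRecord("AAAA", 2, "featA", 0, "+", 0),
                AlignmentRecord("AAAA", 2, "featB", 0, "+", 1)]
        counts = count_class_sample(alns)
        assert counts == {"featA": 2}

    def test_ties_count_everywhere(self):
        alns = [AlignmentRecord("AAAA", 2, "featA", 0, "+", 0),
                AlignmentRecord("AAAA", 2, "featB", 0, "+", 0)]
        counts = count_class_sample(alns)
        assert counts == {"featA": 2, "featB": 2}

    def test_no_alignment_counts_nowhere(self):
        assert count_class_sample([]) == {}


class TestMirgff3:
    def test_empty_document(self):
        buf = io.StringIO()
        write_mirgff3([], buf, ["s1"])
        text = buf.getvalue()
        assert text.startswith("## mirGFF3")
        assert read_mirgff3(io.StringIO(text)) == []

    def test_round_trip(self, rng):
        recs = []
        for i in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=22))
            nta = "A" if i % 4 == 0 else ""
            label = f"iso_add3p:1" if nta else "NA"
            recs.append(IsomirRecord(f"mir-{i % 7}", f"prec-{i % 7}", label,
                                     seq + nta, nta, 3, 25 + len(nta),
                                     {"s1": int(rng.integers(0, 99)), "s2": int(rng.integers(0, 99))}))
        buf = io.StringIO()
        write_mirgff3(recs, buf, ["s1", "s2"])
        back = read_mirgff3(io.StringIO(buf.getvalue()))
        key = lambda r: (r.mature_id, r.sequence)
        for a, b in zip(sorted(recs, key=key), sorted(back, key=key)):
            assert (a.mature_id, a.precursor_id, a.variant_label, a.sequence,
                    a.nta, a.start, a.end, a.count_per_sample) == \
                   (b.mature_id, b.precursor_id, b.variant_label, b.sequence,
                    b.nta, b.start, b.end, b.count_per_sample)

    def test_unserializable_variant_raises(self):
        rec = IsomirRecord("m", "p", "bad variant", "ACGT", "", 0, 4, {"s": 1})
        with pytest.raises(ValueError, match="m"):
            write_mirgff3([rec], io.StringIO(), ["s"])


class TestSamIngestion:
    def test_reads_ungapped_primary_records(self, tmp_path):
        sam = tmp_path / "toy.sam"
        sam.write_text(
            "@HD\tVN:1.6\tSO:unsorted\n"
            "@SQ\tSN:chr1\tLN:1000\n"
            "seq1_x7\t0\tchr1\t101\t42\t22M\t*\t0\t0\t"
            "ACGTACGTACGTACGTACGTAC\t*\tNM:i:1\n"
            "seq2_x3\t16\tchr1\t201\t42\t22M\t*\t0\t0\t"
            "ACGTACGTACGTACGTACGTAC\t*\tNM:i:0\n"
            "seq3_x1\t0\tchr1\t301\t42\t10M2D12M\t*\t0\t0\t"
            "ACGTACGTACGTACGTACGTAC\t*\tNM:i:2\n"  # gapped: skipped
        )
        from smallrna.quantify import read_sam
        alns = read_sam(str(sam))
        assert len(alns) == 2
        first = alns[0]
        assert (first.ref_id, first.pos, first.strand, first.count,
                first.mismatches) == ("chr1", 100, "+", 7, 1)
        assert alns[1].strand == "-" and alns[1].count == 3
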