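"""Hairpin discovery: stacks, excision, folding, Dicer consistency, ranking."""

import numpy as np
import pandas as pd
import pytest

from smallrna.discovery import (PAIR_WEIGHTS, DiscoveryParams, PrecursorCandidate,
                                ReadStack, assess_dicer_consistency,
                                candidate_features, categorize_candidate,
                                default_feature_reference, derive_arms, discover,
                                excise_precursors, find_read_stacks, fold_hairpin,
                                pairing_map, rank_candidates)
from smallrna.preprocess import CollapsedRead
from smallrna.quantify import AlignmentRecord, MappingParams, map_reads
from smallrna.references import ReferenceBundle, build_index
from smallrna.simulate import SimulationSpec, make_toy_bundle


def _aln(contig, pos, length, count, strand="+"):
    return AlignmentRecord("A" * length, count, contig, pos, strand, 0)


class TestReadStacks:
    def test_single_group(self):
        alns = [_aln("c", 100, 22, 10)]
        stacks = find_read_stacks(alns, DiscoveryParams(min_stack_height=5))
        assert len(stacks) == 1 and stacks[0].height == 10

    def test_local_maximum_suppresses_neighbour(self):
        alns = [_aln("c", 100, 22, 10), _aln("c", 130, 22, 4)]
        stacks = find_read_stacks(alns, DiscoveryParams(min_stack_height=4, window_len=70))
        assert [(s.start, s.height) for s in stacks] == [(100, 10)]

    def test_distant_groups_both_reported(self):
        alns = [_aln("c", 100, 22, 10), _aln("c", 300, 22, 10)]
        stacks = find_read_stacks(alns, DiscoveryParams(min_stack_height=5, window_len=70))
        assert len(stacks) == 2

    def test_tie_broken_to_five_prime_most(self):
        alns = [_aln("c", 100, 22, 10), _aln("c", 130, 22, 10)]
        stacks = find_read_stacks(alns, DiscoveryParams(min_stack_height=5, window_len=70))
        assert [s.start for s in stacks] == [100]

    def test_raising_min_height_is_monotone_restrictive(self, rng):
        alns = [_aln("c", int(p), 22, int(c))
                for p, c in zip(rng.integers(0, 2000, 40), rng.integers(1, 20, 40))]
        prev = None
        for h in (1, 5, 10, 15):
            stacks = find_read_stacks(alns, DiscoveryParams(min_stack_height=h))
            keys = {(s.contig, s.strand, s.start) for s in stacks}
            if prev is not None:
                assert keys <= prev
            prev = keys


class TestExcision:
    GENOME = {"c": "ACGT" * 250}

    def test_interval_arithmetic(self):
        stack = ReadStack("c", "+", 100, 122, 10)
        cands = excise_precursors(stack, self.GENOME, DiscoveryParams())
        by_arm = {c.arm_of_stack: c for c in cands}
        assert (by_arm["5p"].window_start, by_arm["5p"].window_end) == (90, 160)
        assert (by_arm["3p"].window_start, by_arm["3p"].window_end) == (62, 132)

    def test_contig_edge_omits_candidate(self):
        # a stack 15 nt from the contig start keeps only the window that
        # fits inside the contig (the one placing the stack on the 5' arm)
        stack = ReadStack("c", "+", 15, 37, 10)
        cands = excise_precursors(stack, self.GENOME, DiscoveryParams())
        assert [c.arm_of_stack for c in cands] == ["5p"]
        # 5 nt from the start, both windows run off the contig
        stack = ReadStack("c", "+", 5, 27, 10)
        assert excise_precursors(stack, self.GENOME, DiscoveryParams()) == []

    def test_minus_strand_reverse_complement(self):
        stack = ReadStack("c", "-", 100, 122, 10)
        cands = excise_precursors(stack, self.GENOME, DiscoveryParams())
        from smallrna.references import reverse_complement
        for c in cands:
            assert c.sequence == reverse_complement(self.GENOME["c"][c.window_start:c.window_end])


def oracle_best_weight(seq, i, j, memo):
    """Independent max-weight nested pairing: interval recursion pairing i
    with every admissible k (no bifurcation table, no left/right trimming
    symmetry with the production DP)."""
    if i >= j:
        return 0
    key = (i, j)
    if key not in memo:
        best = oracle_best_weight(seq, i + 1, j, memo)  # i unpaired
        for k in range(i + 4, j + 1):
            w = PAIR_WEIGHTS.get((seq[i], seq[k]), 0)
            if w:
                best = max(best, w + oracle_best_weight(seq, i + 1, k - 1, memo)
                           + oracle_best_weight(seq, k + 1, j, memo))
        memo[key] = best
    return memo[key]


def enumerate_structures(seq):
    """Exhaustive enumeration of every nested pairing (small n only)."""
    n = len(seq)

    def rec(i, pairs):
        if i >= n:
            yield pairs
            return
        yield from rec(i + 1, pairs)  # i unpaired is handled by skipping
        return

    # full exhaustive: recursively decide partner of leftmost free position
    def gen(free):
        if not free:
            yield []
            return
        i = free[0]
        # i unpaired
        for rest in gen(free[1:]):
            yield rest
        for idx, k in enumerate(free[1:], start=1):
            if k - i > 3 and PAIR_WEIGHTS.get((seq[i], seq[k]), 0):
                inner = [x for x in free[1:idx]]
                outer = [x for x in free[idx + 1:]]
                for a in gen(inner):
                    for b in gen(outer):
                        yield [(i, k)] + a + b
    yield from gen(list(range(n)))


class TestFolding:
    def test_no_complementarity(self):
        assert fold_hairpin("AAAAAAAAAA") == ("..........", 0.0)

    def test_gc_stem_with_minimal_loop(self):
        structure, energy = fold_hairpin("GGGGAAAACCCC")
        assert structure == "((((....))))"
        assert energy == -12.0

    def test_too_short_rejected(self):
        assert fold_hairpin("ACGTACG") is None

    def test_structure_is_balanced_and_consistent(self, rng):
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), size=40))
            structure, energy = fold_hairpin(seq)
            pairs = pairing_map(structure)
            weight = sum(PAIR_WEIGHTS[(seq[i], seq[j])] for i, j in pairs.items() if i < j)
            assert energy == -float(weight)
            assert structure.count("(") == structure.count(")")
            assert all(abs(i - j) > 3 for i, j in pairs.items())

    def test_matches_exhaustive_enumeration_small(self, rng):
        """DP optimum equals brute-force enumeration of all nested pairings."""
        for _ in range(6):
            seq = "".join(rng.choice(list("ACGT"), size=12))
            _, energy = fold_hairpin(seq)
            best = max(sum(PAIR_WEIGHTS[(seq[i], seq[j])] for i, j in s)
                       for s in enumerate_structures(seq))
            assert -energy == best

    def test_matches_interval_recursion_oracle(self, rng):
        """DP optimum equals an independently formulated interval recursion
        on every sequence of a fixed random set up to 18 nt."""
        for n in (14, 16, 18):
            for _ in range(4):
                seq = "".join(rng.choice(list("ACGT"), size=n))
                _, energy = fold_hairpin(seq)
                assert -energy == oracle_best_weight(seq, 0, n - 1, {})


class TestDicerConsistency:
    def _candidate(self):
        # perfect hairpin: 22-nt arm, 8-nt loop, revcomp arm, 9-nt flanks
        arm = "GCTAGCTAGGATCCTAGCTAGC"
        from smallrna.references import reverse_complement
        hp = arm + "AAATTTAA" + reverse_complement(arm)
        seq = "ATATATATA" + hp + "ATATATATA"
        cand = PrecursorCandidate("c", "+", 0, len(seq), seq, "5p")
        cand.structure, cand.energy = fold_hairpin(seq)
        assert derive_arms(cand, (9, 31))
        return cand

    def test_all_reads_on_cut_sites(self):
        cand = self._candidate()
        reads = [(9, 31, 5), (cand.star_interval[0], cand.star_interval[0] + 22, 5)]
        assert assess_dicer_consistency(cand, reads, DiscoveryParams()) == 1.0

    def test_eight_of_ten(self):
        cand = self._candidate()
        reads = [(9, 31, 4), (10, 32, 2), (cand.star_interval[0], cand.star_interval[0] + 22, 2),
                 (34, 56, 1), (36, 58, 1)]  # last two scattered in the loop
        assert assess_dicer_consistency(cand, reads, DiscoveryParams()) == pytest.approx(0.8)

    def test_scattered_reads_fail_threshold(self):
        cand = self._candidate()
        reads = [(i, i + 22, 1) for i in range(0, 45, 5)]
        frac = assess_dicer_consistency(cand, reads, DiscoveryParams())
        assert frac < 0.66


class TestCategorize:
    def _cand(self, seq=None, mature=(10, 32)):
        seq = seq or ("ATATATATA" + "GCTAGCTAGGATCCTAGCTAGC" + "AAATTTAA"
                      + "GCTAGCTAGGATCCTAGCTAGC"[::-1] + "ATATATATA")
        cand = PrecursorCandidate("c", "+", 1000, 1000 + len(seq), seq, "5p")
        cand.mature_interval = mature
        return cand

    def test_empty_known_set_is_novel(self):
        bundle = ReferenceBundle()
        assert categorize_candidate(self._cand(), bundle) == "novel"

    def test_similar_mature_not_novel(self):
        cand = self._cand()
        m_s, m_e = cand.mature_interval
        known = cand.sequence[m_s:m_e]
        mutated = "A" + known[1:] if known[0] != "A" else "C" + known[1:]
        bundle = ReferenceBundle(known_mature_seqs={mutated})
        assert categorize_candidate(cand, bundle) == "overlaps_known"

    def test_known_precursor_new_mature(self):
        cand = self._cand()
        bundle = ReferenceBundle()
        known_genomic = [("c", 990, 1060, "precursor")]  # 5p annotated elsewhere
        assert categorize_candidate(cand, bundle, known_genomic) == "known_precursor_new_mature"


class TestRanking:
    def _cand_with_features(self, ref, sd_away=0.0, feature="gc_fraction"):
        # build a candidate whose features equal the reference means, except
        # one feature shifted by sd_away reference SDs
        cand = PrecursorCandidate("c", "+", 0, 70, "G" * 70, "5p")
        feats = {f: ref.loc[f, "mean"] for f in ref.index}
        feats[feature] += sd_away * ref.loc[feature, "sd"]
        import smallrna.discovery as disc
        orig = disc.candidate_features
        disc.candidate_features = lambda c: dict(feats)
        try:
            out = rank_candidates([cand], ref)
        finally:
            disc.candidate_features = orig
        return out[0]

    def test_all_at_reference_mean_scores_zero(self):
        ref = default_feature_reference()
        assert self._cand_with_features(ref).rank_score == pytest.approx(0.0)

    def test_one_feature_two_sd_away(self):
        ref = default_feature_reference()
        assert self._cand_with_features(ref, 2.0).rank_score == pytest.approx(0.4)

    def test_zero_sd_feature_skipped_with_warning(self):
        ref = default_feature_reference()
        ref.loc["gc_fraction", "sd"] = 0.0
        cand = PrecursorCandidate("c", "+", 0, 70, "G" * 70, "5p")
        cand.structure = "." * 70
        with pytest.warns(UserWarning, match="gc_fraction"):
            rank_candidates([cand], ref)


class TestPlantedRecovery:
    def test_planted_hairpins_recovered_decoys_rejected(self):
        spec = SimulationSpec(seed=3, n_mirnas=5, n_other={}, genome_len=20_000)
        bundle, truth = make_toy_bundle(spec)
        reads = [CollapsedRead(bundle.mature_sequence(m), 12 if m.arm == "5p" else 8)
                 for m in bundle.matures]
        # decoy: same read placement on a non-hairpin locus
        reads.append(CollapsedRead(bundle.genome["chr1"][15000:15022], 12))
        idx = build_index(bundle.genome, 18)
        alns, _ = map_reads(reads, idx, bundle.genome, MappingParams(), max_mismatches=0)
        empty_known = ReferenceBundle(genome=bundle.genome)
        cands = discover(alns, bundle.genome, empty_known, DiscoveryParams())
        recovered = {pid for c in cands if c.dicer_fraction >= 0.8 and c.category == "novel"
                     for pid, (ctg, s, e) in truth.precursor_loci.items()
                     if c.window_start < e and s < c.window_end}
        assert recovered == set(truth.precursor_loci)
        # the decoy window must not be reported
        assert not any(c.window_start < 15022 + 70 and 15000 - 70 < c.window_end
                       for c in cands
                       if not any(c.window_start < e and s < c.window_end
                                  for (ctg, s, e) in truth.precursor_loci.values()))

    def test_min_stack_height_monotone_on_candidates(self):
        spec = SimulationSpec(seed=5, n_mirnas=4, n_other={}, genome_len=16_000)
        bundle, truth = make_toy_bundle(spec)
        reads = [CollapsedRead(bundle.mature_sequence(m), 12 if m.arm == "5p" else 8)
                 for m in bundle.matures]
        idx = build_index(bundle.genome, 18)
        alns, _ = map_reads(reads, idx, bundle.genome, MappingParams(), max_mismatches=0)
        empty_known = ReferenceBundle(genome=bundle.genome)
        prev = None
        for h in (5, 9, 13):
            ids = {c.candidate_id for c in
                   discover(alns, bundle.genome, empty_known, DiscoveryParams(min_stack_height=h))}
            if prev is not None:
                assert ids <= prev
            prev = ids
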