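"""Novel miRNA precursor discovery from genome alignments.

The procedure follows the classic hairpin-excision recipe: locally maximal
read stacks seed candidate precursors; two windows (default 70 nt) are
excised per stack, one placing the stack on the 5' arm and one on the 3'
arm; each window is folded; the star arm is derived from the mature arm's
pairing partners with the canonical 2-nt 3' overhang; the fraction of reads
whose 5' ends fall on the mature or star cut sites (within a tolerance)
measures consistency with Dicer processing; candidates are categorized
against the known annotation and ranked by how miRNA-like their sequence
features are (mean absolute z-score against a reference feature table).

The internal folding backend is a weighted Nussinov dynamic program
(GC = 3, AU = 2, GU = 1, minimum hairpin loop 3 nt) producing a dot-bracket
structure and a unit-free stability score (more negative = more stable).  An
external thermodynamic folder (e.g. RNAfold) can be plugged in through the
``fold`` argument wherever physical kcal/mol energies are needed.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quantify import AlignmentRecord
from .references import ReferenceBundle, reverse_complement

PAIR_WEIGHTS = {("G", "C"): 3, ("C", "G"): 3, ("A", "T"): 2, ("T", "A"): 2,
                ("G", "T"): 1, ("T", "G"): 1,
                ("A", "U"): 2, ("U", "A"): 2, ("G", "U"): 1, ("U", "G"): 1}
MIN_LOOP = 3


@dataclass
class DiscoveryParams:
    window_len: int = 70
    flank: int = 10
    min_stack_height: int = 5
    mature_min_len: int = 18
    mature_max_len: int = 25
    min_dicer_fraction: float = 0.66
    boundary_tolerance: int = 2
    similarity_max_edits: int = 2


@dataclass
class ReadStack:
    contig: str
    strand: str
    start: int
    end: int
    height: int


@dataclass
class PrecursorCandidate:
    contig: str
    strand: str
    window_start: int
    window_end: int
    sequence: str
    arm_of_stack: str  # 5p | 3p
    structure: str = ""
    energy: float = 0.0
    mature_interval: tuple[int, int] | None = None  # window coordinates
    star_interval: tuple[int, int] | None = None
    loop_interval: tuple[int, int] | None = None
    dicer_fraction: float = 0.0
    category: str = ""
    rank_score: float = np.nan

    @property
    def candidate_id(self) -> str:
        return f"{self.contig}:{self.window_start}-{self.window_end}({self.strand}){self.arm_of_stack}"


def find_read_stacks(alignments: list[AlignmentRecord], params: DiscoveryParams) -> list[ReadStack]:
    """Locally maximal read stacks from genome alignments.

    Reads sharing a 5' start position (per contig and strand; for minus
    strand reads the 5' end is the rightmost coordinate) form a group.  A
    group becomes a stack when its summed collapsed count reaches
    ``min_stack_height`` and is strictly maximal among groups within
    +- ``window_len`` on the same strand, ties broken to the 5'-most group.
    """
    groups: dict[tuple[str, str, int], list[AlignmentRecord]] = defaultdict(list)
    for a in alignments:
        five = a.pos if a.strand == "+" else a.end - 1
        groups[(a.ref_id, a.strand, five)].append(a)

    by_cs: dict[tuple[str, str], list[tuple[int, int, list[AlignmentRecord]]]] = defaultdict(list)
    for (contig, strand, five), alns in groups.items():
        height = sum(a.count for a in alns)
        by_cs[(contig, strand)].append((five, height, alns))

    W = params.window_len
    stacks = []
    for (contig, strand), entries in sorted(by_cs.items()):
        entries.sort()
        for i, (five, height, alns) in enumerate(entries):
            if height < params.min_stack_height:
                continue
            is_max = True
            for ofive, oheight, _ in entries:
                if ofive == five or abs(ofive - five) > W:
                    continue
                # ties broken to the 5'-most group (strand-aware direction)
                upstream = ofive < five if strand == "+" else ofive > five
                if oheight > height or (oheight == height and upstream):
                    is_max = False
                    break
            if not is_max:
                continue
            start = min(a.pos for a in alns)
            end = max(a.end for a in alns)
            stacks.append(ReadStack(contig, strand, start, end, height))
    return stacks


def excise_precursors(stack: ReadStack, genome: dict[str, str],
                      params: DiscoveryParams) -> list[PrecursorCandidate]:
    """Excise the two candidate windows for a stack (stack as 5' or 3' arm).

    Candidate A: window [stack.start - flank, stack.start - flank + W);
    candidate B: window [stack.end + flank - W, stack.end + flank).  Windows
    extending beyond the contig are omitted.  Minus-strand windows are
    reverse-complemented so the candidate sequence reads 5'->3'.
    """
    contig_seq = genome[stack.contig]
    W, flank = params.window_len, params.flank
    raw = []
    if stack.strand == "+":
        raw = [(stack.start - flank, "5p"), (stack.end + flank - W, "3p")]
    else:
        # on the minus strand the 5' arm lies at higher forward coordinates
        raw = [(stack.end + flank - W, "5p"), (stack.start - flank, "3p")]
    out = []
    for wstart, arm in raw:
        wend = wstart + W
        if wstart < 0 or wend > len(contig_seq):
            continue
        seq = contig_seq[wstart:wend]
        if stack.strand == "-":
            seq = reverse_complement(seq)
        out.append(PrecursorCandidate(stack.contig, stack.strand, wstart, wend, seq, arm))
    return out


# ---------------------------------------------------------------------------
# Folding

def fold_hairpin(sequence: str) -> tuple[str, float] | None:
    """Weighted Nussinov fold: maximal weighted nested pairing, min loop 3 nt.

    Returns (dot_bracket, energy) with energy = -(sum of pair weights), or
    None for sequences shorter than 10 nt.
    """
    seq = sequence.upper().replace("U", "T")
    n = len(seq)
    if n < 10:
        return None
    dp = np.zeros((n, n), dtype=np.int64)
    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = dp[i + 1, j] if i + 1 <= j else 0
            best = max(best, dp[i, j - 1])
            w = PAIR_WEIGHTS.get((seq[i], seq[j]), 0)
            if w and j - i > MIN_LOOP:
                inner = dp[i + 1, j - 1] if i + 1 <= j - 1 else 0
                best = max(best, inner + w)
            for k in range(i + 1, j):
                best = max(best, dp[i, k] + dp[k + 1, j])
            dp[i, j] = best

    structure = ["."] * n

    def traceback(i: int, j: int) -> None:
        while i < j:
            if dp[i, j] == (dp[i + 1, j] if i + 1 <= j else 0):
                i += 1
                continue
            if dp[i, j] == dp[i, j - 1]:
                j -= 1
                continue
            w = PAIR_WEIGHTS.get((seq[i], seq[j]), 0)
            inner = dp[i + 1, j - 1] if i + 1 <= j - 1 else 0
            if w and j - i > MIN_LOOP and dp[i, j] == inner + w:
                structure[i], structure[j] = "(", ")"
                i, j = i + 1, j - 1
                continue
            for k in range(i + 1, j):
                if dp[i, j] == dp[i, k] + dp[k + 1, j]:
                    traceback(i, k)
                    i = k + 1
                    break
            else:  # pragma: no cover - defensive
                return

    traceback(0, n - 1)
    return "".join(structure), -float(dp[0, n - 1])


def pairing_map(structure: str) -> dict[int, int]:
    """Partner index per paired position from a dot-bracket string."""
    stack: list[int] = []
    pairs: dict[int, int] = {}
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            j = stack.pop()
            pairs[i] = j
            pairs[j] = i
    return pairs


def derive_arms(candidate: PrecursorCandidate, mature: tuple[int, int]) -> bool:
    """Derive star and loop intervals from the fold given the mature interval.

    The star arm spans the partners of the mature's paired bases, extended
    by the canonical 2-nt 3' overhang at its 3' end; the loop is the
    unpaired span between the arms.  Returns False (rejecting the candidate)
    when the structure leaves most of the mature arm unpaired or the derived
    arms overlap.
    """
    pairs = pairing_map(candidate.structure)
    m_s, m_e = mature
    paired = [(i, pairs[i]) for i in range(m_s, m_e) if i in pairs]
    # the duplex is the longest antiparallel run of partners; spurious pairs
    # (e.g. the mature's terminal base caught by a loop helix) are discarded
    best_run: list[tuple[int, int]] = []
    run: list[tuple[int, int]] = []
    for item in paired:
        step = item[0] - run[-1][0] if run else 0
        drop = run[-1][1] - item[1] if run else 0
        if run and 0 < drop <= step + 2:  # antiparallel, small bulges allowed
            run.append(item)
        else:
            run = [item]
        if len(run) > len(best_run):
            best_run = list(run)
    if len(best_run) < (m_e - m_s) // 2:  # mature arm must sit in a stem
        return False
    partners = [p for _, p in best_run]
    lo, hi = min(partners), max(partners) + 1
    n = len(candidate.sequence)
    star = (max(lo, 0), min(hi + 2, n))  # 2-nt 3' overhang
    if star[0] < m_e and m_s < star[1]:  # arms must not overlap
        return False
    candidate.mature_interval = (m_s, m_e)
    candidate.star_interval = star
    if m_e <= star[0]:
        candidate.loop_interval = (m_e, star[0])
    else:
        candidate.loop_interval = (star[1], m_s)
    return True


def assess_dicer_consistency(candidate: PrecursorCandidate,
                             reads_in_window: list[tuple[int, int, int]],
                             params: DiscoveryParams) -> float:
    """Fraction of window reads whose 5' ends hit the mature/star cut sites.

    ``reads_in_window`` holds (start, end, count) in window coordinates
    (already strand-oriented).  The 5' end of a read is its start.
    """
    if candidate.mature_interval is None or candidate.star_interval is None:
        return 0.0
    cut5 = {candidate.mature_interval[0], candidate.star_interval[0]}
    tol = params.boundary_tolerance
    total = sum(c for _, _, c in reads_in_window)
    if total == 0:
        return 0.0
    hit = sum(c for s, _, c in reads_in_window
              if any(abs(s - cut) <= tol for cut in cut5))
    frac = hit / total
    candidate.dicer_fraction = frac
    return frac


def _edit_distance_leq(a: str, b: str, cap: int) -> bool:
    """Banded edit distance: True iff dist(a, b) <= cap."""
    if abs(len(a) - len(b)) > cap:
        return False
    prev = list(range(len(b) + 1))
    for i in range(1, len(a) + 1):
        cur = [i] + [0] * len(b)
        lo = max(1, i - cap - 1)
        hi = min(len(b), i + cap + 1)
        for j in range(1, len(b) + 1):
            if j < lo or j > hi:
                cur[j] = cap + 1
                continue
            cur[j] = min(prev[j - 1] + (a[i - 1] != b[j - 1]),
                         prev[j] + 1, cur[j - 1] + 1)
        if min(cur) > cap:
            return False
        prev = cur
    return prev[len(b)] <= cap


def categorize_candidate(candidate: PrecursorCandidate, bundle: ReferenceBundle,
                         known_genomic: list[tuple[str, int, int, str]] | None = None,
                         params: DiscoveryParams | None = None) -> str:
    """Assign a category relative to the known miRNA annotation.

    * ``novel`` — no genomic overlap with known precursors/matures AND the
      predicted mature is not within the similarity threshold (edit distance
      <= 2) of any known mature sequence of the species.
    * ``known_precursor_new_mature`` — overlaps a known precursor whose
      opposite arm is unannotated while the predicted mature is new.
    * ``overlaps_known`` — any other overlap or similarity.

    ``known_genomic`` lists known miRNA loci as (contig, start, end, kind)
    with kind ``precursor`` or ``mature``; arm-level annotation presence is
    looked up in the bundle's mature records.
    """
    params = params or DiscoveryParams()
    mature_seq = ""
    if candidate.mature_interval is not None:
        m_s, m_e = candidate.mature_interval
        mature_seq = candidate.sequence[m_s:m_e]

    similar = any(_edit_distance_leq(mature_seq, known, params.similarity_max_edits)
                  for known in bundle.known_mature_seqs) if mature_seq else False

    overlapping = []
    for contig, start, end, kind in known_genomic or []:
        if contig == candidate.contig and start < candidate.window_end and candidate.window_start < end:
            overlapping.append((contig, start, end, kind))

    if not overlapping and not similar:
        candidate.category = "novel"
    elif overlapping and not similar and all(k == "precursor" for *_, k in overlapping):
        candidate.category = "known_precursor_new_mature"
    elif overlapping or similar:
        candidate.category = "overlaps_known"
    else:  # pragma: no cover
        candidate.category = "ambiguous"
    return candidate.category


# ---------------------------------------------------------------------------
# Ranking

RANK_FEATURES = ("precursor_length", "gc_fraction", "energy_per_nt",
                 "mature_length", "paired_fraction")


def candidate_features(candidate: PrecursorCandidate) -> dict[str, float]:
    seq = candidate.sequence
    gc = sum(1 for b in seq if b in "GC") / len(seq)
    paired = candidate.structure.count("(") * 2 / len(seq) if candidate.structure else 0.0
    m_len = (candidate.mature_interval[1] - candidate.mature_interval[0]
             if candidate.mature_interval else 0)
    return {"precursor_length": float(len(seq)), "gc_fraction": gc,
            "energy_per_nt": candidate.energy / len(seq),
            "mature_length": float(m_len), "paired_fraction": paired}


def default_feature_reference() -> pd.DataFrame:
    """Feature means/SDs of a typical miRNA precursor population.

    A synthetic reference table standing in for a curated known-miRNA
    feature distribution; users can supply their own via
    :func:`rank_candidates`.
    """
    return pd.DataFrame(
        {"mean": [70.0, 0.45, -1.5, 22.0, 0.6],
         "sd": [12.0, 0.08, 0.4, 1.5, 0.12]},
        index=list(RANK_FEATURES))


def rank_candidates(candidates: list[PrecursorCandidate],
                    feature_reference: pd.DataFrame | None = None) -> list[PrecursorCandidate]:
    """NovoMiRank-style score: mean |z| of candidate features against the
    reference distribution; smaller = more miRNA-like."""
    import warnings as _w

    ref = feature_reference if feature_reference is not None else default_feature_reference()
    usable = []
    for feat in ref.index:
        if ref.loc[feat, "sd"] == 0:
            _w.warn(f"reference feature {feat!r} has zero SD; skipped in ranking")
        else:
            usable.append(feat)
    for cand in candidates:
        feats = candidate_features(cand)
        zs = [abs((feats[f] - ref.loc[f, "mean"]) / ref.loc[f, "sd"]) for f in usable]
        cand.rank_score = float(np.mean(zs)) if zs else np.nan
    return sorted(candidates, key=lambda c: (c.rank_score, c.candidate_id))


# ---------------------------------------------------------------------------
# Orchestration

def discover(alignments: list[AlignmentRecord], genome: dict[str, str],
             bundle: ReferenceBundle, params: DiscoveryParams | None = None,
             known_genomic: list[tuple[str, int, int, str]] | None = None,
             fold=fold_hairpin,
             feature_reference: pd.DataFrame | None = None) -> list[PrecursorCandidate]:
    """Full discovery pipeline: stacks -> excision -> fold -> Dicer filter ->
    categorize -> rank.  Returns retained candidates sorted by rank score."""
    params = params or DiscoveryParams()
    stacks = find_read_stacks(alignments, params)
    by_contig_strand: dict[tuple[str, str], list[AlignmentRecord]] = defaultdict(list)
    for a in alignments:
        by_contig_strand[(a.ref_id, a.strand)].append(a)

    retained = []
    for stack in stacks:
        mature_len = stack.end - stack.start
        if not (params.mature_min_len <= mature_len <= params.mature_max_len):
            continue
        for cand in excise_precursors(stack, genome, params):
            folded = fold(cand.sequence)
            if folded is None:
                continue
            cand.structure, cand.energy = folded
            # stack interval in (strand-oriented) window coordinates
            if stack.strand == "+":
                m_s = stack.start - cand.window_start
            else:
                m_s = cand.window_end - stack.end
            m_e = m_s + mature_len
            if m_s < 0 or m_e > len(cand.sequence):
                continue
            if not derive_arms(cand, (m_s, m_e)):
                continue
            window_reads = []
            for a in by_contig_strand[(stack.contig, stack.strand)]:
                if a.pos >= cand.window_start and a.end <= cand.window_end:
                    if stack.strand == "+":
                        window_reads.append((a.pos - cand.window_start, a.end - cand.window_start, a.count))
                    else:
                        window_reads.append((cand.window_end - a.end, cand.window_end - a.pos, a.count))
            frac = assess_dicer_consistency(cand, window_reads, params)
            if frac < params.min_dicer_fraction:
                continue
            categorize_candidate(cand, bundle, known_genomic, params)
            retained.append(cand)
    return rank_candidates(retained, feature_reference)


def candidate_table(candidates: list[PrecursorCandidate]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        rows.append({"candidate_id": c.candidate_id, "contig": c.contig,
                     "strand": c.strand, "window_start": c.window_start,
                     "window_end": c.window_end, "arm_of_stack": c.arm_of_stack,
                     "category": c.category, "dicer_fraction": c.dicer_fraction,
                     "rank_score": c.rank_score, "energy": c.energy,
                     "structure": c.structure, "sequence": c.sequence})
    return pd.DataFrame(rows)
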