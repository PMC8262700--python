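"""FASTQ preprocessing: adapter trimming, quality filtering, UMI handling, read collapsing.

The stage turns raw small-RNA FASTQ records into collapsed, adapter-free read
sets.  Processing order per read: 3' adapter trimming, quality trimming,
removal of fixed bases (5' barcode, adapter barcode, UMI), N policy, minimum
length filter.  Surviving inserts are collapsed to unique sequences; when a
UMI is configured the collapsed count is the number of distinct UMIs seen for
a sequence (exact-match deduplication, no error-correction clustering).
"""

from __future__ import annotations

import gzip
import io
import zlib
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Sequence


@dataclass
class RawRead:
    """A FASTQ record with Phred-scale integer qualities."""

    id: str
    sequence: str
    quality: list[int]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(
                f"read {self.id}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.quality)}"
            )


@dataclass
class PreprocessConfig:
    """Knobs of the preprocessing stage.

    Defaults are community-conventional small-RNA settings; every value can
    be overridden (CLI expert mode).
    """

    adapter3: str | None = None
    barcode5_len: int = 0
    adapter_barcode_len: int = 0
    umi_len: int = 0
    umi_side: str = "five_prime"  # or "three_prime"
    min_read_len: int = 18
    max_adapter_edit_dist: int = 1
    min_overlap: int = 10
    qual_window: int = 4
    qual_threshold: int = 20
    n_policy: str = "trim_ends"  # trim_ends | drop_read | keep

    def __post_init__(self) -> None:
        if self.min_read_len < 1:
            raise ValueError("min_read_len must be >= 1")
        if self.qual_window < 1:
            raise ValueError("qual_window must be >= 1")
        if self.adapter3 is not None and self.max_adapter_edit_dist >= len(self.adapter3):
            raise ValueError("max_adapter_edit_dist must be < adapter length")
        if self.umi_side not in ("five_prime", "three_prime"):
            raise ValueError(f"unknown umi_side {self.umi_side!r}")
        if self.n_policy not in ("trim_ends", "drop_read", "keep"):
            raise ValueError(f"unknown n_policy {self.n_policy!r}")


@dataclass
class CollapsedRead:
    """A unique insert sequence with its multiplicity and UMI evidence."""

    sequence: str
    count: int
    umis: Counter = field(default_factory=Counter)


@dataclass
class SampleQCStats:
    n_raw: int
    n_kept: int
    length_histogram: dict[int, int]
    gc_percent: float | None
    mean_quality_by_position: list[float]
    dropped: dict[str, int] = field(default_factory=dict)


def _adapter_distance(read_seq: str, adapter: str, pos: int) -> int:
    """Edit distance of the adapter aligned semi-globally starting at ``pos``.

    Free ends on either side: the adapter may run off the 3' end of the read
    (truncated adapter, unmatched adapter suffix free) or the read may
    continue past a complete adapter (unmatched read suffix free — everything
    downstream of the adapter is trimmed anyway).  Standard DP over
    adapter x read-suffix.
    """
    suffix = read_seq[pos:]
    n, m = len(adapter), len(suffix)
    prev = list(range(m + 1))
    best = prev[m]
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        for j in range(1, m + 1):
            sub = prev[j - 1] + (adapter[i - 1] != suffix[j - 1])
            cur[j] = min(sub, prev[j] + 1, cur[j - 1] + 1)
        prev = cur
        best = min(best, cur[m])  # adapter truncated at the read 3' end
    best = min(best, min(prev))  # read continues past a complete adapter
    return int(best)


def trim_adapter(read: RawRead, cfg: PreprocessConfig) -> tuple[RawRead, bool]:
    """Remove the 3' adapter, returning (read, trimmed-flag).

    The adapter is aligned semi-globally against every suffix of the read;
    the leftmost start position whose edit distance is within
    ``cfg.max_adapter_edit_dist`` and whose read overlap is at least
    ``cfg.min_overlap`` wins.  The adapter may run off the 3' end of the read
    (partial occurrence), but everything from the start position to the read
    end must be adapter-derived.  Untrimmable reads pass through unchanged.
    """
    if cfg.adapter3 is None:
        return read, False
    seq = read.sequence
    adapter = cfg.adapter3
    L = len(seq)
    # fast path: a distance-0 occurrence (full adapter anywhere, or an
    # adapter prefix anchored at the read 3' end) cannot be beaten, and
    # str.find already yields the leftmost full occurrence
    exact = seq.find(adapter)
    candidates = [exact] if exact != -1 else []
    for o in range(min(L, len(adapter)), cfg.min_overlap - 1, -1):
        if seq.endswith(adapter[:o]):
            candidates.append(L - o)
            break
    if candidates:
        pos = min(candidates)
        if min(L - pos, len(adapter)) >= cfg.min_overlap:
            return RawRead(read.id, seq[:pos], read.quality[:pos]), True
    best_pos, best_dist = None, None
    for pos in range(0, L):
        overlap = min(L - pos, len(adapter))
        if overlap < cfg.min_overlap:
            break
        dist = _adapter_distance(seq, adapter, pos)
        if dist <= cfg.max_adapter_edit_dist and (best_dist is None or dist < best_dist):
            best_pos, best_dist = pos, dist
            if dist == 0:
                break
    if best_pos is None:
        return read, False
    return RawRead(read.id, seq[:best_pos], read.quality[:best_pos]), True


def quality_trim(read: RawRead, cfg: PreprocessConfig) -> RawRead:
    """Truncate the 3' end at the first sliding window of low mean quality.

    Windows of width ``qual_window`` slide 5'->3' in steps of one base; the
    read is cut at the first base of the first window whose mean Phred score
    drops below ``qual_threshold``.  Trailing partial windows are included so
    a low-quality tail shorter than the window is still removed.
    """
    q = read.quality
    w = cfg.qual_window
    for start in range(len(q)):
        window = q[start : start + w]
        if not window:
            break
        if sum(window) / len(window) < cfg.qual_threshold:
            return RawRead(read.id, read.sequence[:start], q[:start])
    return read


def extract_fixed_bases(read: RawRead, cfg: PreprocessConfig) -> tuple[RawRead, str] | None:
    """Strip 5' barcode, adapter barcode and UMI; return (insert, umi).

    The 5' barcode occupies the first ``barcode5_len`` bases; the adapter
    barcode the last ``adapter_barcode_len`` bases (adjacent to the trimmed
    adapter).  The UMI of length ``umi_len`` sits immediately inside the
    5' barcode or the adapter barcode depending on ``umi_side``.  Returns
    None when the read is shorter than the fixed bases (dropped, counted in
    QC).
    """
    fixed = cfg.barcode5_len + cfg.adapter_barcode_len + cfg.umi_len
    if len(read.sequence) < fixed:
        return None
    seq, qual = read.sequence, read.quality
    if cfg.adapter_barcode_len:
        seq, qual = seq[: len(seq) - cfg.adapter_barcode_len], qual[: len(qual) - cfg.adapter_barcode_len]
    umi = ""
    if cfg.umi_len:
        if cfg.umi_side == "five_prime":
            umi = seq[cfg.barcode5_len : cfg.barcode5_len + cfg.umi_len]
            seq = seq[: cfg.barcode5_len] + seq[cfg.barcode5_len + cfg.umi_len :]
            qual = qual[: cfg.barcode5_len] + qual[cfg.barcode5_len + cfg.umi_len :]
        else:
            umi = seq[len(seq) - cfg.umi_len :]
            seq, qual = seq[: len(seq) - cfg.umi_len], qual[: len(qual) - cfg.umi_len]
    if cfg.barcode5_len:
        seq, qual = seq[cfg.barcode5_len :], qual[cfg.barcode5_len :]
    return RawRead(read.id, seq, qual), umi


def apply_n_policy(read: RawRead, cfg: PreprocessConfig) -> RawRead | None:
    """Handle N bases: trim from both ends, drop the read, or keep as-is."""
    if cfg.n_policy == "keep":
        return read
    if cfg.n_policy == "drop_read":
        return None if "N" in read.sequence else read
    seq = read.sequence
    start = 0
    while start < len(seq) and seq[start] == "N":
        start += 1
    end = len(seq)
    while end > start and seq[end - 1] == "N":
        end -= 1
    return RawRead(read.id, seq[start:end], read.quality[start:end])


def preprocess_read(read: RawRead, cfg: PreprocessConfig,
                    _adapter_cache: dict[str, int | None] | None = None
                    ) -> tuple[RawRead, str] | tuple[None, str]:
    """Run the full per-read chain; returns (insert, umi) or (None, drop_reason).

    ``_adapter_cache`` memoizes the adapter cut position per sequence (the
    search depends only on the sequence); :func:`preprocess_sample` shares
    one cache across a sample's reads.
    """
    if _adapter_cache is not None and read.sequence in _adapter_cache:
        cut = _adapter_cache[read.sequence]
        if cut is not None:
            read = RawRead(read.id, read.sequence[:cut], read.quality[:cut])
    else:
        seq_before = read.sequence
        read, trimmed = trim_adapter(read, cfg)
        if _adapter_cache is not None:
            _adapter_cache[seq_before] = len(read.sequence) if trimmed else None
    read = quality_trim(read, cfg)
    extracted = extract_fixed_bases(read, cfg)
    if extracted is None:
        return None, "too_short_for_fixed_bases"
    read, umi = extracted
    read = apply_n_policy(read, cfg)
    if read is None:
        return None, "contains_n"
    if len(read.sequence) < cfg.min_read_len:
        return None, "below_min_length"
    return read, umi


def collapse_reads(reads: Iterable[tuple[str, str]]) -> list[CollapsedRead]:
    """Collapse (sequence, umi) pairs to unique sequences.

    Without UMIs (empty strings) the count is the plain multiplicity; with
    UMIs it is the number of distinct UMIs observed for that sequence.
    Output is ordered by decreasing count, then sequence.
    """
    umis_per_seq: dict[str, Counter] = defaultdict(Counter)
    plain: Counter = Counter()
    for seq, umi in reads:
        if umi:
            umis_per_seq[seq][umi] += 1
        else:
            plain[seq] += 1
    out = []
    for seq in set(plain) | set(umis_per_seq):
        umis = umis_per_seq.get(seq, Counter())
        count = len(umis) if umis else plain[seq]
        out.append(CollapsedRead(seq, count, umis))
    out.sort(key=lambda r: (-r.count, r.sequence))
    return out


def compute_qc(raw: Sequence[RawRead], kept: Sequence[RawRead],
               dropped: dict[str, int] | None = None) -> SampleQCStats:
    """Aggregate per-sample QC: length histogram, GC%, per-position quality means.

    GC is computed over kept bases with N excluded from the denominator;
    with zero kept reads (or only-N reads) GC is reported as missing (None).
    """
    hist: Counter = Counter()
    gc = 0
    acgt = 0
    qual_sums: list[float] = []
    qual_counts: list[int] = []
    for r in kept:
        hist[len(r.sequence)] += 1
        for base in r.sequence:
            if base in "GC":
                gc += 1
            if base in "ACGT":
                acgt += 1
        for i, q in enumerate(r.quality):
            if i >= len(qual_sums):
                qual_sums.append(0.0)
                qual_counts.append(0)
            qual_sums[i] += q
            qual_counts[i] += 1
    return SampleQCStats(
        n_raw=len(raw),
        n_kept=len(kept),
        length_histogram=dict(hist),
        gc_percent=(100.0 * gc / acgt) if acgt else None,
        mean_quality_by_position=[s / c for s, c in zip(qual_sums, qual_counts)],
        dropped=dict(dropped or {}),
    )


def compress_collapsed(reads: Sequence[CollapsedRead], raw_fastq_bytes: int) -> tuple[bytes, float]:
    """Serialize collapsed reads (sequence + count) and DEFLATE them.

    Returns (payload, ratio) with ratio = 1 - compressed / raw FASTQ bytes.
    Lossless for the (sequence, count) multiset; an empty sample yields an
    empty payload and ratio 0.
    """
    if not reads:
        return b"", 0.0
    text = "".join(f"{r.sequence}\t{r.count}\n" for r in reads)
    payload = zlib.compress(text.encode("ascii"), level=9)
    ratio = 1.0 - len(payload) / raw_fastq_bytes if raw_fastq_bytes else 0.0
    return payload, ratio


def decompress_collapsed(payload: bytes) -> list[CollapsedRead]:
    """Inverse of :func:`compress_collapsed` (empty payload -> empty list)."""
    if not payload:
        return []
    out = []
    for line in zlib.decompress(payload).decode("ascii").splitlines():
        seq, count = line.split("\t")
        out.append(CollapsedRead(seq, int(count)))
    return out


# ---------------------------------------------------------------------------
# FASTQ / collapsed-FASTA I/O

def parse_fastq(handle: IO[str]) -> Iterator[RawRead]:
    """Parse 4-line FASTQ records with Phred+33 qualities."""
    while True:
        header = handle.readline()
        if not header:
            return
        seq = handle.readline().strip()
        handle.readline()  # '+'
        qual = handle.readline().strip()
        yield RawRead(header.strip()[1:].split()[0], seq, [ord(c) - 33 for c in qual])


def open_fastq(path: str) -> IO[str]:
    if str(path).endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


def read_fastq(path: str) -> list[RawRead]:
    with open_fastq(path) as fh:
        return list(parse_fastq(fh))


def write_collapsed_fasta(reads: Sequence[CollapsedRead], handle: IO[str]) -> None:
    """Write collapsed reads in the ``>seq<i>_x<count>`` FASTA dialect."""
    for i, r in enumerate(reads, start=1):
        handle.write(f">seq{i}_x{r.count}\n{r.sequence}\n")


def read_collapsed_fasta(path: str) -> list[CollapsedRead]:
    reads = []
    with open(path) as fh:
        header = None
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                header = line
            elif line:
                count = int(header.rsplit("_x", 1)[1])
                reads.append(CollapsedRead(line, count))
    return reads


def preprocess_sample(path: str, cfg: PreprocessConfig) -> tuple[list[CollapsedRead], SampleQCStats]:
    """Full per-sample preprocessing from a FASTQ(.gz) path."""
    raw = read_fastq(path)
    kept: list[RawRead] = []
    pairs: list[tuple[str, str]] = []
    dropped: Counter = Counter()
    adapter_cache: dict[str, int | None] = {}
    for read in raw:
        result, info = preprocess_read(read, cfg, adapter_cache)
        if result is None:
            dropped[info] += 1
        else:
            kept.append(result)
            pairs.append((result.sequence, info))
    qc = compute_qc(raw, kept, dropped)
    return collapse_reads(pairs), qc
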