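"""Read mapping and quantification of miRNAs, isomiRs, and other ncRNA classes.

The internal mapper is an ungapped exact-seed aligner: the first ``seed_len``
bases of a read must match the reference exactly (both strands); mismatches
are then counted over the remaining bases and capped per RNA class.  Reads
hitting more than ``max_hits`` loci are discarded as over-cap multimappers.
Indels are out of scope for the internal mapper; externally produced SAM
alignments (with indels, NM-based) are accepted through :func:`read_sam`.

Counting semantics:

* miRNAs — a read counts toward a mature annotation when its 5' end lies
  within ``offset5`` (default 2 nt) and its 3' end within ``offset3``
  (default 5 nt) of the annotated mature boundaries, with at most
  ``total_mismatches_mirna`` (default 1) mismatches.
* isomiRs — mapping runs with one additional mismatch; 3'-terminal
  mismatches that disagree with the templated precursor continuation are
  reclassified as non-templated additions (NTA) and excluded from the
  mismatch count.
* other ncRNA classes — quantified without mismatches by default; all
  multimapping alignments achieving the read's lowest mismatch count each
  receive the full collapsed count.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import CollapsedRead
from .references import ClassInterval, KmerIndex, MatureAnnotation, ReferenceBundle, reverse_complement


@dataclass
class AlignmentRecord:
    sequence: str
    count: int
    ref_id: str
    pos: int  # 0-based leftmost reference coordinate
    strand: str
    mismatches: int
    edits: list[tuple[int, str, str]] = field(default_factory=list)  # (ref_offset, ref_base, read_base)

    @property
    def end(self) -> int:
        return self.pos + len(self.sequence)


@dataclass
class MappingParams:
    max_hits: int = 5
    seed_len: int = 18
    seed_mismatches: int = 0
    total_mismatches_mirna: int = 1
    total_mismatches_isomir: int = 2
    total_mismatches_other: int = 0
    offset5: int = 2
    offset3: int = 5


@dataclass
class IsomirRecord:
    mature_id: str
    precursor_id: str
    variant_label: str
    sequence: str
    nta: str
    start: int  # 0-based on precursor
    end: int    # exclusive, includes NTA bases
    count_per_sample: dict[str, int] = field(default_factory=dict)


@dataclass
class CountMatrix:
    feature_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # features x samples, int
    rna_class: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.feature_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, rna_class: str = "") -> "CountMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=np.int64), rna_class)


def _align_at(read: str, ref: str, contig: str, pos: int, strand: str,
              seed_len: int, max_mismatches: int, count: int) -> AlignmentRecord | None:
    """Extend an exact seed hit over the full read, ungapped."""
    L = len(read)
    if strand == "+":
        start = pos
        if start + L > len(ref):
            return None
        window = ref[start:start + L]
        oriented = window
    else:
        start = pos + seed_len - L
        if start < 0:
            return None
        window = ref[start:pos + seed_len]
        oriented = reverse_complement(window)
    edits = []
    for i in range(seed_len, L):
        if read[i] != oriented[i]:
            edits.append(i)
            if len(edits) > max_mismatches:
                return None
    # record edits with reference-forward offsets and bases
    edit_list: list[tuple[int, str, str]] = []
    for i in edits:
        if strand == "+":
            edit_list.append((i, window[i], read[i]))
        else:
            ref_off = L - 1 - i
            edit_list.append((ref_off, window[ref_off], read[i]))
    return AlignmentRecord(read, count, contig, start, strand, len(edits), edit_list)


def map_reads(reads: list[CollapsedRead], index: KmerIndex,
              sequences: dict[str, str], params: MappingParams,
              max_mismatches: int | None = None,
              both_strands: bool = True) -> tuple[list[AlignmentRecord], dict[str, int]]:
    """Map collapsed reads with the exact-seed ungapped aligner.

    Returns (alignments, stats) where stats counts unmapped reads, reads
    discarded for exceeding ``max_hits``, and reads shorter than the seed.
    """
    cap = params.total_mismatches_mirna if max_mismatches is None else max_mismatches
    out: list[AlignmentRecord] = []
    stats = Counter(mapped=0, unmapped=0, too_short=0, multimapper_over_cap=0)
    for read in reads:
        if len(read.sequence) < index.k:
            stats["too_short"] += 1
            continue
        seed = read.sequence[:index.k]
        hits = []
        for contig, pos, strand in index.lookup(seed):
            if strand == "-" and not both_strands:
                continue
            aln = _align_at(read.sequence, sequences[contig], contig, pos, strand,
                            index.k, cap, read.count)
            if aln is not None:
                hits.append(aln)
        if not hits:
            stats["unmapped"] += 1
        elif len(hits) > params.max_hits:
            stats["multimapper_over_cap"] += 1
        else:
            stats["mapped"] += 1
            out.extend(hits)
    return out, dict(stats)


def _best_alignments_per_read(alignments: list[AlignmentRecord]) -> list[list[AlignmentRecord]]:
    """Group alignments by read sequence, keeping only each read's
    minimum-mismatch alignments (the lowest-mismatch multimapper rule)."""
    by_read: dict[str, list[AlignmentRecord]] = defaultdict(list)
    for a in alignments:
        by_read[a.sequence].append(a)
    groups = []
    for alns in by_read.values():
        best = min(a.mismatches for a in alns)
        groups.append([a for a in alns if a.mismatches == best])
    return groups


def count_mirnas_sample(alignments: list[AlignmentRecord], matures: list[MatureAnnotation],
                        params: MappingParams) -> Counter:
    """Count reads per mature miRNA for one sample (precursor-space alignments).

    A read contributes its full collapsed count to every mature annotation
    on its best-mismatch precursors whose boundaries it matches within the
    5'/3' positional tolerances.
    """
    matures_by_prec: dict[str, list[MatureAnnotation]] = defaultdict(list)
    for m in matures:
        matures_by_prec[m.precursor_id].append(m)
    counts: Counter = Counter()
    for group in _best_alignments_per_read(alignments):
        if group[0].mismatches > params.total_mismatches_mirna:
            continue
        for aln in group:
            if aln.strand != "+":
                continue
            for m in matures_by_prec.get(aln.ref_id, []):
                if abs(aln.pos - m.start) <= params.offset5 and abs(aln.end - m.end) <= params.offset3:
                    counts[m.mature_id] += aln.count
    return counts


def count_mirnas(per_sample_alignments: dict[str, list[AlignmentRecord]],
                 matures: list[MatureAnnotation], params: MappingParams) -> CountMatrix:
    samples = list(per_sample_alignments)
    counters = {s: count_mirnas_sample(per_sample_alignments[s], matures, params)
                for s in samples}
    features = sorted({m.mature_id for m in matures})
    mat = np.array([[counters[s].get(f, 0) for s in samples] for f in features], dtype=np.int64)
    return CountMatrix(features, samples, mat, "miRNA")


def _split_nta(aln: AlignmentRecord, read_len: int) -> tuple[str, list[int]]:
    """Reclassify terminal 3' mismatches as non-templated additions.

    Walks inward from the last read base while every base is a mismatch
    against the templated reference continuation; stops at the first
    templated match.  Only plus-strand precursor alignments carry isomiR
    semantics here.  Returns (nta_suffix, remaining_mismatch_read_offsets).
    """
    mism_offsets = {off for off, _, _ in aln.edits}  # read offset == ref offset on + strand
    nta_start = read_len
    while nta_start - 1 in mism_offsets:
        nta_start -= 1
    nta = aln.sequence[nta_start:]
    remaining = sorted(off for off in mism_offsets if off < nta_start)
    return nta, remaining


def _variant_label(aln: AlignmentRecord, m: MatureAnnotation, nta: str,
                   n_subs: int) -> str:
    """mirGFF3-style Variant attribute for one isomiR.

    Positive iso_5p means extra templated bases at the 5' end relative to
    the annotated mature; positive iso_3p likewise at the 3' end (before any
    NTA bases).
    """
    parts = []
    d5 = m.start - aln.pos           # >0: read extends 5' of the mature
    templated_end = aln.end - len(nta)
    d3 = templated_end - m.end       # >0: read extends 3' of the mature
    if d5:
        parts.append(f"iso_5p:{d5:+d}")
    if d3:
        parts.append(f"iso_3p:{d3:+d}")
    if n_subs:
        parts.append("iso_snv")
    if nta:
        parts.append(f"iso_add3p:{len(nta)}")
    return ",".join(parts) if parts else "NA"


def quantify_isomirs_sample(alignments: list[AlignmentRecord],
                            matures: list[MatureAnnotation],
                            bundle: ReferenceBundle,
                            params: MappingParams) -> list[IsomirRecord]:
    """isomiR records for one sample from precursor-space alignments.

    Alignments should come from mapping with ``total_mismatches_isomir``;
    after NTA reclassification at most ``total_mismatches_mirna`` true
    mismatches may remain, and the positional tolerances are measured on the
    templated portion of the read (NTA bases excluded at the 3' end).
    """
    matures_by_prec: dict[str, list[MatureAnnotation]] = defaultdict(list)
    for m in matures:
        matures_by_prec[m.precursor_id].append(m)
    records: dict[tuple[str, str], IsomirRecord] = {}
    for group in _best_alignments_per_read(alignments):
        for aln in group:
            if aln.strand != "+":
                continue
            nta, remaining = _split_nta(aln, len(aln.sequence))
            if len(remaining) > params.total_mismatches_mirna:
                continue
            templated_end = aln.end - len(nta)
            for m in matures_by_prec.get(aln.ref_id, []):
                if abs(aln.pos - m.start) > params.offset5:
                    continue
                if abs(templated_end - m.end) > params.offset3:
                    continue
                label = _variant_label(aln, m, nta, len(remaining))
                key = (m.mature_id, aln.sequence)
                rec = records.get(key)
                if rec is None:
                    records[key] = IsomirRecord(
                        m.mature_id, m.precursor_id, label, aln.sequence, nta,
                        aln.pos, aln.end, {"sample": aln.count})
                else:
                    rec.count_per_sample["sample"] += aln.count
    return list(records.values())


def quantify_isomirs(per_sample_alignments: dict[str, list[AlignmentRecord]],
                     matures: list[MatureAnnotation], bundle: ReferenceBundle,
                     params: MappingParams) -> list[IsomirRecord]:
    """Merge per-sample isomiR quantifications into multi-sample records."""
    merged: dict[tuple[str, str], IsomirRecord] = {}
    samples = list(per_sample_alignments)
    for sample in samples:
        for rec in quantify_isomirs_sample(per_sample_alignments[sample], matures, bundle, params):
            key = (rec.mature_id, rec.sequence)
            if key not in merged:
                merged[key] = IsomirRecord(rec.mature_id, rec.precursor_id,
                                           rec.variant_label, rec.sequence, rec.nta,
                                           rec.start, rec.end, {})
            merged[key].count_per_sample[sample] = rec.count_per_sample["sample"]
    for rec in merged.values():
        for s in samples:
            rec.count_per_sample.setdefault(s, 0)
    return sorted(merged.values(), key=lambda r: (r.mature_id, r.sequence))


def count_class_sample(alignments: list[AlignmentRecord],
                       class_intervals: list[ClassInterval] | None = None) -> Counter:
    """Count one sample's reads for a non-miRNA class.

    With ``class_intervals`` the alignments are genomic and a read counts
    toward every overlapping same-strand feature; without, alignments are in
    sequence space and the reference id is the feature.  Only each read's
    lowest-mismatch alignments contribute, each with the full collapsed
    count.
    """
    counts: Counter = Counter()
    by_contig: dict[str, list[ClassInterval]] = defaultdict(list)
    for iv in class_intervals or []:
        by_contig[iv.contig].append(iv)
    for group in _best_alignments_per_read(alignments):
        for aln in group:
            if class_intervals is None:
                counts[aln.ref_id] += aln.count
            else:
                for iv in by_contig.get(aln.ref_id, []):
                    if iv.strand == aln.strand and aln.pos < iv.end and iv.start < aln.end:
                        counts[iv.feature_id] += aln.count
    return counts


def count_class(per_sample_alignments: dict[str, list[AlignmentRecord]],
                rna_class: str,
                class_intervals: list[ClassInterval] | None = None,
                feature_ids: list[str] | None = None) -> CountMatrix:
    samples = list(per_sample_alignments)
    counters = {s: count_class_sample(per_sample_alignments[s], class_intervals)
                for s in samples}
    if feature_ids is None:
        if class_intervals is not None:
            feature_ids = sorted({iv.feature_id for iv in class_intervals})
        else:
            feature_ids = sorted({f for c in counters.values() for f in c})
    mat = np.array([[counters[s].get(f, 0) for s in samples] for f in feature_ids],
                   dtype=np.int64)
    return CountMatrix(feature_ids, samples, mat, rna_class)


# ---------------------------------------------------------------------------
# miRGFF3 (mirtop-style) export / import

def write_mirgff3(isomirs: list[IsomirRecord], handle, sample_ids: list[str] | None = None) -> None:
    """Emit a miRGFF3 document: header pragmas plus one feature line per isomiR."""
    if sample_ids is None:
        seen: list[str] = []
        for rec in isomirs:
            for s in rec.count_per_sample:
                if s not in seen:
                    seen.append(s)
        sample_ids = seen
    handle.write("## mirGFF3. VERSION 1.2\n")
    handle.write("## source-ontology: smallrna\n")
    handle.write(f"## COLDATA: {','.join(sample_ids)}\n")
    for rec in isomirs:
        if any(ch.isspace() or ch in ";=" for ch in rec.variant_label):
            raise ValueError(f"unserializable variant label for {rec.mature_id}: {rec.variant_label!r}")
        ftype = "ref_miRNA" if rec.variant_label == "NA" else "isomiR"
        expr = ",".join(str(rec.count_per_sample.get(s, 0)) for s in sample_ids)
        total = sum(rec.count_per_sample.get(s, 0) for s in sample_ids)
        attrs = (f"Read={rec.sequence}; UID={rec.sequence}; Name={rec.mature_id}; "
                 f"Parent={rec.precursor_id}; Variant={rec.variant_label}; Expression={expr}")
        handle.write(f"{rec.precursor_id}\t.\t{ftype}\t{rec.start + 1}\t{rec.end}\t"
                     f"{total}\t+\t.\t{attrs}\n")


def read_mirgff3(handle) -> list[IsomirRecord]:
    """Parse a document written by :func:`write_mirgff3` back into records."""
    sample_ids: list[str] = []
    records = []
    for line in handle:
        line = line.rstrip("\n")
        if line.startswith("## COLDATA:"):
            cols = line.split(":", 1)[1].strip()
            sample_ids = cols.split(",") if cols else []
            continue
        if line.startswith("#") or not line.strip():
            continue
        f = line.split("\t")
        attrs = {}
        for part in f[8].split(";"):
            if "=" in part:
                k, v = part.strip().split("=", 1)
                attrs[k] = v
        expr = [int(x) for x in attrs.get("Expression", "").split(",")] if attrs.get("Expression") else []
        counts = dict(zip(sample_ids, expr))
        label = attrs["Variant"]
        seq = attrs["Read"]
        nta = ""
        for part in label.split(","):
            if part.startswith("iso_add3p:"):
                nta = seq[len(seq) - int(part.split(":")[1]):]
        records.append(IsomirRecord(attrs["Name"], attrs["Parent"], label, seq, nta,
                                    int(f[3]) - 1, int(f[4]), counts))
    return records


# ---------------------------------------------------------------------------
# External SAM ingestion

def read_sam(path: str, count_from_name: bool = True) -> list[AlignmentRecord]:
    """Load ungapped primary/secondary alignments from a headered SAM file.

    Supplementary and hard-clipped records are ignored, as are gapped
    alignments (any CIGAR besides a single M run).  Mismatch counts come
    from the NM tag when present.  When ``count_from_name`` the collapsed
    multiplicity is parsed from the ``..._x<count>`` read-name dialect.
    """
    import pysam

    out = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_supplementary:
                continue
            if not rec.cigartuples or len(rec.cigartuples) != 1 or rec.cigartuples[0][0] != 0:
                continue
            count = 1
            if count_from_name and "_x" in rec.query_name:
                try:
                    count = int(rec.query_name.rsplit("_x", 1)[1])
                except ValueError:
                    pass
            seq = rec.query_sequence or ""
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            out.append(AlignmentRecord(seq, count, rec.reference_name,
                                       rec.reference_start,
                                       "-" if rec.is_reverse else "+", int(nm)))
    return out
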