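"""Reference bundle loading and k-mer seed indexing.

A bundle holds the genome, miRNA precursors with mature-arm coordinates, and
per-class ncRNA annotations.  Internal coordinates are 0-based half-open
everywhere; GFF3 (1-based inclusive) and BED conversions happen only at the
I/O boundary.  Mature miRNA annotations follow the miRBase GFF3 dialect:
``miRNA`` features carrying a ``Derives_from`` link to their precursor.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field

from Bio import SeqIO

SUPPORTED_CLASSES = {
    "miRNA", "tRNA", "piRNA", "rRNA", "scaRNA",
    "lncRNA", "snoRNA", "snRNA", "miscRNA", "circRNA",
}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MatureAnnotation:
    """A mature miRNA interval on its precursor (0-based half-open)."""

    precursor_id: str
    mature_id: str
    start: int
    end: int
    arm: str = "unknown"  # 5p | 3p | unknown


@dataclass
class ClassInterval:
    """A genomic ncRNA feature interval (0-based half-open)."""

    contig: str
    start: int
    end: int
    strand: str
    feature_id: str


@dataclass
class ReferenceBundle:
    genome: dict[str, str] = field(default_factory=dict)
    precursors: dict[str, str] = field(default_factory=dict)
    matures: list[MatureAnnotation] = field(default_factory=list)
    ncrna_classes: dict[str, list[ClassInterval]] = field(default_factory=dict)
    class_sequences: dict[str, dict[str, str]] = field(default_factory=dict)
    known_mature_seqs: set[str] = field(default_factory=set)

    def validate(self) -> None:
        for m in self.matures:
            if m.precursor_id not in self.precursors:
                raise ValueError(f"mature {m.mature_id}: unknown precursor {m.precursor_id}")
            plen = len(self.precursors[m.precursor_id])
            if not (0 <= m.start < m.end <= plen):
                raise ValueError(
                    f"mature {m.mature_id}: interval [{m.start},{m.end}) outside "
                    f"precursor {m.precursor_id} of length {plen}"
                )
        for cls in list(self.ncrna_classes) + list(self.class_sequences):
            if cls not in SUPPORTED_CLASSES:
                raise ValueError(f"unsupported ncRNA class {cls!r}")

    def mature_sequence(self, m: MatureAnnotation) -> str:
        return self.precursors[m.precursor_id][m.start:m.end]


def _read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper().replace("U", "T")
            for rec in SeqIO.parse(path, "fasta")}


def _parse_gff3_attrs(attrs: str) -> dict[str, str]:
    out = {}
    for part in attrs.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def parse_mature_gff3(path: str) -> list[MatureAnnotation]:
    """Parse miRBase-dialect mature annotations (coordinates on precursors)."""
    matures = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "miRNA":
                continue
            attrs = _parse_gff3_attrs(fields[8])
            seqid, start, end = fields[0], int(fields[3]), int(fields[4])
            precursor = attrs.get("Derives_from", seqid)
            mature_id = attrs.get("ID") or attrs.get("Name") or f"{precursor}:{start}-{end}"
            arm = "unknown"
            if mature_id.endswith("-5p"):
                arm = "5p"
            elif mature_id.endswith("-3p"):
                arm = "3p"
            matures.append(MatureAnnotation(precursor, mature_id, start - 1, end, arm))
    return matures


def parse_class_gff3(path: str) -> list[ClassInterval]:
    """Parse generic GFF3 feature intervals for one ncRNA class."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                continue
            attrs = _parse_gff3_attrs(f[8])
            fid = attrs.get("ID") or attrs.get("Name") or f"{f[0]}:{f[3]}-{f[4]}"
            out.append(ClassInterval(f[0], int(f[3]) - 1, int(f[4]), f[6], fid))
    return out


def parse_class_bed(path: str) -> list[ClassInterval]:
    """Parse BED6 intervals (already 0-based half-open)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            name = f[3] if len(f) > 3 else f"{f[0]}:{f[1]}-{f[2]}"
            strand = f[5] if len(f) > 5 else "+"
            out.append(ClassInterval(f[0], int(f[1]), int(f[2]), strand, name))
    return out


def load_bundle(genome_fasta: str, precursor_fasta: str, mature_gff3: str,
                class_files: dict[str, str] | None = None,
                class_fastas: dict[str, str] | None = None) -> ReferenceBundle:
    """Load and validate a reference bundle from disk.

    ``class_files`` maps class name -> GFF3/BED path (genomic intervals);
    ``class_fastas`` maps class name -> FASTA path (sequence-space
    references, as piRNA/circRNA sets are usually distributed).
    """
    bundle = ReferenceBundle(
        genome=_read_fasta(genome_fasta),
        precursors=_read_fasta(precursor_fasta),
        matures=parse_mature_gff3(mature_gff3),
    )
    for cls, path in (class_files or {}).items():
        parser = parse_class_bed if str(path).endswith(".bed") else parse_class_gff3
        bundle.ncrna_classes[cls] = parser(path)
    for cls, path in (class_fastas or {}).items():
        bundle.class_sequences[cls] = _read_fasta(path)
    bundle.validate()
    bundle.known_mature_seqs = {bundle.mature_sequence(m) for m in bundle.matures}
    return bundle


def write_bundle(bundle: ReferenceBundle, genome_fasta: str, precursor_fasta: str,
                 mature_gff3: str) -> None:
    """Write the bundle back to FASTA/GFF3 (round-trip counterpart of load)."""
    with open(genome_fasta, "w") as fh:
        for cid, seq in bundle.genome.items():
            fh.write(f">{cid}\n{seq}\n")
    with open(precursor_fasta, "w") as fh:
        for pid, seq in bundle.precursors.items():
            fh.write(f">{pid}\n{seq}\n")
    with open(mature_gff3, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in bundle.matures:
            fh.write(
                f"{m.precursor_id}\t.\tmiRNA\t{m.start + 1}\t{m.end}\t.\t+\t.\t"
                f"ID={m.mature_id};Derives_from={m.precursor_id}\n"
            )


@dataclass
class KmerIndex:
    """Exact-seed lookup table: k-mer -> (contig, position, strand) postings.

    Minus-strand postings record the leftmost reference coordinate of the
    k-mer window; the stored key is the reverse complement of the reference
    substring, i.e. the sequence a minus-strand read would start with.
    """

    k: int
    postings: dict[str, list[tuple[str, int, str]]]
    contig_lengths: dict[str, int]

    def lookup(self, kmer: str) -> list[tuple[str, int, str]]:
        return self.postings.get(kmer, [])


def build_index(sequences: dict[str, str], k: int) -> KmerIndex:
    """Index every length-k substring of every contig on both strands."""
    if k < 1:
        raise ValueError("seed length must be >= 1")
    postings: dict[str, list[tuple[str, int, str]]] = defaultdict(list)
    for contig, seq in sequences.items():
        if len(seq) < k:
            warnings.warn(f"contig {contig} shorter than seed length {k}; not indexed")
            continue
        for pos in range(len(seq) - k + 1):
            sub = seq[pos:pos + k]
            postings[sub].append((contig, pos, "+"))
            postings[reverse_complement(sub)].append((contig, pos, "-"))
    return KmerIndex(k, dict(postings), {c: len(s) for c, s in sequences.items()})
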