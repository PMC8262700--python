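"""Synthetic data generation: toy reference bundles and simulated FASTQ.

The generator emulates the structure of a multi-sample small RNA-seq study:
a toy genome with planted hairpin precursors (perfectly complementary 22-nt
arms around an 8-nt loop), interval annotations for the other ncRNA classes,
and per-sample FASTQ reads drawn from mature sequences under a Zipf
abundance model with optional planted group fold changes, multiplicative
per-(feature, batch) log-normal batch shifts, per-base sequencing errors, a
3' adapter, and 5' UMIs.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import gzip
import zlib
from dataclasses import dataclass, field

import numpy as np

from .preprocess import RawRead
from .references import ClassInterval, MatureAnnotation, ReferenceBundle, reverse_complement

BASES = np.array(list("ACGT"))
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"  # common small-RNA 3' adapter


@dataclass
class SimulationSpec:
    seed: int = 0
    n_samples: int = 8
    groups: dict[str, str] = field(default_factory=dict)    # sample -> level
    batches: dict[str, str] = field(default_factory=dict)   # sample -> batch
    n_mirnas: int = 20
    n_other: dict[str, int] = field(default_factory=lambda: {"rRNA": 10, "tRNA": 10, "snoRNA": 10})
    genome_len: int = 50_000
    depth_per_sample: int = 20_000
    zipf_exponent: float = 1.2
    planted_fc: dict[str, float] = field(default_factory=dict)  # feature -> log2 FC (level B over A)
    batch_shift_sd: float = 0.0
    error_rate: float = 0.0
    adapter: str | None = DEFAULT_ADAPTER
    umi_len: int = 0
    arm_len: int = 22
    loop_len: int = 8

    def __post_init__(self) -> None:
        if not self.groups:
            half = self.n_samples // 2
            self.groups = {f"s{i + 1}": ("A" if i < half else "B")
                           for i in range(self.n_samples)}
        self.sample_ids = list(self.groups)
        if not self.batches:
            self.batches = {s: "batch1" for s in self.sample_ids}


@dataclass
class TruthTable:
    counts: dict[str, dict[str, int]]          # sample -> feature -> true read count
    planted_fc: dict[str, float]
    precursor_loci: dict[str, tuple[str, int, int]]  # precursor -> (contig, start, end)
    mature_intervals: dict[str, tuple[str, int, int]]  # mature -> (precursor, start, end)
    read_origin: dict[str, list[str]] = field(default_factory=dict)  # sample -> per-read feature


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


def make_toy_bundle(spec: SimulationSpec) -> tuple[ReferenceBundle, TruthTable]:
    """Build a toy genome with planted hairpins plus other-class annotations.

    Each planted miRNA precursor is arm + loop + reverse-complement(arm);
    both arms are annotated as matures (5p and 3p).  Other ncRNA classes get
    random genomic intervals whose sequences also serve as sequence-space
    references.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    genome = list(_random_seq(rng, spec.genome_len))
    prec_len = 2 * spec.arm_len + spec.loop_len

    n_features = spec.n_mirnas + sum(spec.n_other.values())
    spacing = spec.genome_len // max(n_features + 1, 1)
    positions = [(i + 1) * spacing for i in range(n_features)]

    bundle = ReferenceBundle(genome={})
    truth = TruthTable({}, dict(spec.planted_fc), {}, {})

    for i in range(spec.n_mirnas):
        arm = _random_seq(rng, spec.arm_len)
        loop = _random_seq(rng, spec.loop_len)
        hairpin = arm + loop + reverse_complement(arm)
        start = positions[i]
        genome[start:start + prec_len] = list(hairpin)
        pid = f"toy-mir-{i + 1}"
        bundle.precursors[pid] = hairpin
        m5 = MatureAnnotation(pid, f"{pid}-5p", 0, spec.arm_len, "5p")
        m3 = MatureAnnotation(pid, f"{pid}-3p", spec.arm_len + spec.loop_len, prec_len, "3p")
        bundle.matures.extend([m5, m3])
        truth.precursor_loci[pid] = ("chr1", start, start + prec_len)
        truth.mature_intervals[m5.mature_id] = (pid, m5.start, m5.end)
        truth.mature_intervals[m3.mature_id] = (pid, m3.start, m3.end)

    idx = spec.n_mirnas
    for cls, n in spec.n_other.items():
        intervals = []
        seqs = {}
        for j in range(n):
            start = positions[idx]
            length = int(rng.integers(60, 120))
            fid = f"toy-{cls}-{j + 1}"
            intervals.append(ClassInterval("chr1", start, start + length, "+", fid))
            seqs[fid] = "".join(genome[start:start + length])
            idx += 1
        bundle.ncrna_classes[cls] = intervals
        bundle.class_sequences[cls] = seqs

    bundle.genome["chr1"] = "".join(genome)
    # class sequences may have been overwritten by later planting; re-extract
    for cls, intervals in bundle.ncrna_classes.items():
        for iv in intervals:
            bundle.class_sequences[cls][iv.feature_id] = bundle.genome["chr1"][iv.start:iv.end]
    bundle.validate()
    bundle.known_mature_seqs = {bundle.mature_sequence(m) for m in bundle.matures}
    return bundle, truth


def _feature_catalog(bundle: ReferenceBundle) -> dict[str, str]:
    """Expressed unit per feature: mature miRNA sequences plus 22-nt
    fragments of the other-class references."""
    catalog = {}
    for m in bundle.matures:
        catalog[m.mature_id] = bundle.mature_sequence(m)
    for cls, seqs in bundle.class_sequences.items():
        for fid, seq in seqs.items():
            catalog[fid] = seq[:22]
    return catalog


def simulate_sample_reads(bundle: ReferenceBundle, truth: TruthTable,
                          spec: SimulationSpec, sample: str) -> list[RawRead]:
    """Simulate one sample's reads (exactly ``depth_per_sample`` of them).

    Feature abundances follow a Zipf law (rank r gets weight r^-a); planted
    log2 fold changes multiply non-reference levels by 2^fc; batch shifts
    multiply by per-(feature, batch) log-normal factors shared within a
    batch.  Reads carry substitution errors, the 3' adapter, optional 5'
    UMIs, and high qualities with a degraded 3' tail.
    """
    sample_index = spec.sample_ids.index(sample)
    rng = np.random.default_rng((spec.seed, 1000 + sample_index))
    catalog = _feature_catalog(bundle)
    features = sorted(catalog)

    rank_rng = np.random.default_rng((spec.seed, 7))
    ranks = rank_rng.permutation(len(features))
    weights = (ranks + 1.0) ** (-spec.zipf_exponent)

    level = spec.groups[sample]
    ref_level = sorted(set(spec.groups.values()))[0]
    for i, f in enumerate(features):
        if f in spec.planted_fc and level != ref_level:
            weights[i] *= 2.0 ** spec.planted_fc[f]

    if spec.batch_shift_sd > 0:
        batch = spec.batches[sample]
        batch_rng = np.random.default_rng((spec.seed, 13, zlib.crc32(batch.encode())))
        weights = weights * np.exp(batch_rng.normal(0.0, spec.batch_shift_sd, size=len(features)))

    probs = weights / weights.sum()
    draws = rng.choice(len(features), size=spec.depth_per_sample, p=probs)
    counts = np.bincount(draws, minlength=len(features))
    truth.counts[sample] = {features[i]: int(c) for i, c in enumerate(counts) if c}
    truth.read_origin[sample] = [features[i] for i in draws]

    reads = []
    for ridx, fi in enumerate(draws):
        insert = catalog[features[fi]]
        if spec.error_rate > 0:
            bases = list(insert)
            errs = rng.random(len(bases)) < spec.error_rate
            for bi in np.flatnonzero(errs):
                choices = [b for b in "ACGT" if b != bases[bi]]
                bases[bi] = choices[rng.integers(3)]
            insert = "".join(bases)
        seq = insert
        if spec.umi_len:
            seq = _random_seq(rng, spec.umi_len) + seq
        if spec.adapter:
            seq = seq + spec.adapter
        qual = [int(q) for q in np.clip(rng.normal(38, 1.5, len(seq)), 2, 40)]
        for tail in range(max(len(seq) - 3, 0), len(seq)):  # mild 3' degradation
            qual[tail] = max(qual[tail] - 4, 2)
        reads.append(RawRead(f"{sample}_r{ridx + 1}", seq, qual))
    return reads


def write_fastq(reads: list[RawRead], path: str) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{''.join(chr(q + 33) for q in r.quality)}\n")


def simulate_study(spec: SimulationSpec) -> tuple[ReferenceBundle, TruthTable, dict[str, list[RawRead]]]:
    """Bundle + truth + per-sample reads for a whole study."""
    bundle, truth = make_toy_bundle(spec)
    reads = {s: simulate_sample_reads(bundle, truth, spec, s) for s in spec.sample_ids}
    return bundle, truth, reads


def low_complexity_fastq_bytes(n_reads: int = 1_000_000, n_sequences: int = 500,
                               zipf_exponent: float = 1.5, read_len: int = 22,
                               seed: int = 0) -> tuple[bytes, list[str]]:
    """A low-read-complexity FASTQ sample as raw bytes.

    ``n_reads`` reads drawn from ``n_sequences`` distinct ``read_len``-mers
    under a Zipf abundance model with uniform high qualities — the regime in
    which collapsing plus compression shrinks a library by well over 90%.
    Returns (fastq_bytes, drawn_sequences).
    """
    rng = np.random.default_rng(seed)
    seqs = ["".join(rng.choice(BASES, size=read_len)) for _ in range(n_sequences)]
    weights = np.arange(1, n_sequences + 1, dtype=float) ** (-zipf_exponent)
    probs = weights / weights.sum()
    draws = rng.choice(n_sequences, size=n_reads, p=probs)
    qual = "I" * read_len
    chunks = []
    for i, d in enumerate(draws):
        chunks.append(f"@r{i + 1}\n{seqs[d]}\n+\n{qual}\n")
    payload = "".join(chunks).encode("ascii")
    return payload, [seqs[d] for d in draws]
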