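"""Pipeline orchestration: run configuration, stage sequencing, report bundle.

The orchestrator runs preprocess -> map -> quantify -> filter/normalize ->
statistics -> structure exploration -> discovery and writes every table of
the report bundle as TSV.  Two runs with identical inputs, configuration and
seed produce byte-identical outputs.
"""

from __future__ import annotations

import configparser
import logging
import sys
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import discovery as disc
from . import preprocess as pp
from . import quantify as qt
from . import stats as st
from . import structure as sx
from .references import ReferenceBundle, build_index

log = logging.getLogger("smallrna")


@dataclass
class RunConfig:
    preprocess: pp.PreprocessConfig = field(default_factory=pp.PreprocessConfig)
    mapping: qt.MappingParams = field(default_factory=qt.MappingParams)
    discovery: disc.DiscoveryParams = field(default_factory=disc.DiscoveryParams)
    de_variable: str | None = None
    min_reads: int = 3
    detection_fraction: float = 0.5
    pc_variance_threshold: float = 0.6
    top_variance_k: int = 50
    umap_neighbors: int = 15
    output_dir: str = "smallrna_out"
    threads: int = 1
    seed: int = 42
    expert_mode: bool = False
    run_discovery: bool = True
    run_umap: bool = True

    def to_file(self, path: str) -> None:
        cp = configparser.ConfigParser()
        for section in ("preprocess", "mapping", "discovery"):
            sub = getattr(self, section)
            cp[section] = {f.name: str(getattr(sub, f.name)) for f in dc_fields(sub)}
        # output_dir is a run location, not an analysis parameter
        cp["run"] = {f.name: str(getattr(self, f.name)) for f in dc_fields(self)
                     if f.name not in ("preprocess", "mapping", "discovery", "output_dir")}
        with open(path, "w") as fh:
            cp.write(fh)

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        cp = configparser.ConfigParser()
        cp.read(path)
        cfg = cls()
        for section, sub in (("preprocess", cfg.preprocess), ("mapping", cfg.mapping),
                             ("discovery", cfg.discovery)):
            if section not in cp:
                continue
            for f in dc_fields(sub):
                if f.name in cp[section]:
                    raw = cp[section][f.name]
                    setattr(sub, f.name, _coerce(raw, getattr(sub, f.name)))
        if "run" in cp:
            for f in dc_fields(cfg):
                if f.name in cp["run"] and f.name not in ("preprocess", "mapping", "discovery"):
                    setattr(cfg, f.name, _coerce(cp["run"][f.name], getattr(cfg, f.name)))
        return cfg


def _coerce(raw: str, current):
    if raw == "None":
        return None
    if isinstance(current, bool):
        return raw in ("True", "true", "1")
    if isinstance(current, int):
        return int(raw)
    if isinstance(current, float):
        return float(raw)
    return raw


def validate_annotation(table: pd.DataFrame, samples: list[str],
                        de_variable: str | None = None) -> dict[str, st.GroupDesign]:
    """Turn an annotation table (index: sample id) into GroupDesigns.

    Every sample must be covered; the DE column, when named, needs at least
    two non-empty levels.
    """
    missing = [s for s in samples if s not in table.index]
    if missing:
        raise ValueError(f"annotation is missing samples: {missing}")
    designs = {}
    for col in table.columns:
        assignment = {s: str(table.loc[s, col]) for s in samples}
        designs[col] = st.GroupDesign(col, assignment)
    if de_variable is not None:
        if de_variable not in designs:
            raise ValueError(f"DE variable {de_variable!r} not in annotation columns {list(table.columns)}")
        levels = [l for l in designs[de_variable].levels if l and l != "nan"]
        if len(levels) < 2:
            raise ValueError(f"DE variable {de_variable!r} has fewer than 2 levels")
    return designs


def read_annotation(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return df.set_index(df.columns[0])


@dataclass
class ReportBundle:
    output_dir: Path
    qc: dict[str, pp.SampleQCStats] = field(default_factory=dict)
    count_matrices: dict[str, qt.CountMatrix] = field(default_factory=dict)
    normalized: dict[str, st.NormalizedMatrix] = field(default_factory=dict)
    de_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    pvca: sx.VarianceDecomposition | None = None
    candidates: pd.DataFrame | None = None


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g")


def run_pipeline(config: RunConfig, fastqs: dict[str, str], bundle: ReferenceBundle,
                 annotation: pd.DataFrame | None = None) -> ReportBundle:
    """Execute the full pipeline on per-sample FASTQ paths.

    ``fastqs`` maps sample id -> FASTQ(.gz) path.  Fails before any compute
    when a DE variable is requested without an annotation table.
    """
    if config.de_variable and annotation is None:
        raise ValueError("a DE variable was requested but no annotation table given")
    samples = list(fastqs)
    designs = validate_annotation(annotation, samples, config.de_variable) if annotation is not None else {}

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = ReportBundle(out)
    log.info("run: %d samples, seed=%d, expert_mode=%s", len(samples), config.seed, config.expert_mode)

    # --- preprocess ------------------------------------------------------
    collapsed: dict[str, list[pp.CollapsedRead]] = {}
    qc_rows = []
    for sample in samples:
        try:
            reads, qc = pp.preprocess_sample(fastqs[sample], config.preprocess)
        except Exception as exc:
            raise RuntimeError(f"stage preprocess failed for sample {sample}: {exc}") from exc
        collapsed[sample] = reads
        report.qc[sample] = qc
        qc_rows.append({"sample": sample, "n_raw": qc.n_raw, "n_kept": qc.n_kept,
                        "gc_percent": qc.gc_percent,
                        **{f"dropped_{k}": v for k, v in qc.dropped.items()}})
        with open(out / f"{sample}.collapsed.fa", "w") as fh:
            pp.write_collapsed_fasta(reads, fh)
    _write_tsv(pd.DataFrame(qc_rows).set_index("sample"), out / "qc.tsv")

    # --- mapping + quantification ---------------------------------------
    params = config.mapping
    prec_index = build_index(bundle.precursors, params.seed_len)
    genome_index = build_index(bundle.genome, params.seed_len)

    mirna_alns: dict[str, list[qt.AlignmentRecord]] = {}
    genome_alns: dict[str, list[qt.AlignmentRecord]] = {}
    depths: dict[str, int] = {}
    map_rows = []
    for sample in samples:
        alns, stats = qt.map_reads(collapsed[sample], prec_index, bundle.precursors,
                                   params, max_mismatches=params.total_mismatches_isomir,
                                   both_strands=False)
        mirna_alns[sample] = alns
        galns, gstats = qt.map_reads(collapsed[sample], genome_index, bundle.genome, params,
                                     max_mismatches=params.total_mismatches_mirna)
        genome_alns[sample] = galns
        depths[sample] = sum(a.count for g in qt._best_alignments_per_read(galns) for a in g[:1])
        map_rows.append({"sample": sample, **{f"precursor_{k}": v for k, v in stats.items()},
                         **{f"genome_{k}": v for k, v in gstats.items()}})
    _write_tsv(pd.DataFrame(map_rows).set_index("sample"), out / "mapping_stats.tsv")

    matrices: dict[str, qt.CountMatrix] = {}
    matrices["miRNA"] = qt.count_mirnas(mirna_alns, bundle.matures, params)
    isomirs = qt.quantify_isomirs(mirna_alns, bundle.matures, bundle, params)
    with open(out / "isomirs.gff3", "w") as fh:
        qt.write_mirgff3(isomirs, fh, samples)

    for cls, seqs in bundle.class_sequences.items():
        if cls == "miRNA" or not seqs:
            continue
        cls_index = build_index(seqs, params.seed_len)
        cls_alns = {}
        for sample in samples:
            alns, _ = qt.map_reads(collapsed[sample], cls_index, seqs, params,
                                   max_mismatches=params.total_mismatches_other,
                                   both_strands=False)
            cls_alns[sample] = alns
        matrices[cls] = qt.count_class(cls_alns, cls, feature_ids=sorted(seqs))

    for cls, mat in matrices.items():
        _write_tsv(mat.to_frame(), out / f"counts_{cls}.tsv")
    report.count_matrices = matrices

    # --- filtering, normalization, statistics ---------------------------
    design = designs.get(config.de_variable) if config.de_variable else None
    depth_arr = np.array([max(depths[s], 1) for s in samples], dtype=float)
    for cls, mat in matrices.items():
        filtered = st.detection_filter(mat, design, config.min_reads, config.detection_fraction)
        if not filtered.feature_ids:
            continue
        norm = st.normalize(filtered, depth_arr)
        report.normalized[cls] = norm
        _write_tsv(norm.to_frame(), out / f"normalized_{cls}.tsv")
        if design is not None:
            for (la, lb), table in st.differential_expression(norm, design).items():
                name = f"de_{cls}_{la}_vs_{lb}"
                _write_tsv(table, out / f"{name}.tsv")
                _write_tsv(st.volcano_table(table), out / f"volcano_{cls}_{la}_vs_{lb}.tsv")
                report.de_tables[name] = table

    # --- structure exploration ------------------------------------------
    norm_mi = report.normalized.get("miRNA")
    if norm_mi is not None and len(norm_mi.sample_ids) >= 3 and len(norm_mi.feature_ids) >= 2:
        emb = sx.pca_embed(norm_mi)
        _write_tsv(emb.to_frame(), out / "pca_miRNA.tsv")
        if config.run_umap:
            uemb = sx.umap_embed(norm_mi, n_neighbors=min(config.umap_neighbors,
                                                          len(samples) - 1), seed=config.seed)
            _write_tsv(uemb.to_frame(), out / "umap_miRNA.tsv")
        corr = sx.sample_correlation(norm_mi.rpm, norm_mi.sample_ids)
        _write_tsv(corr, out / "sample_correlation_miRNA.tsv")
        dend = sx.cluster_samples_by_correlation(norm_mi)
        (out / "sample_dendrogram_miRNA.nwk").write_text(dend.to_newick() + "\n")
        top = sx.top_variance_subset(norm_mi, min(config.top_variance_k, len(norm_mi.feature_ids)))
        _write_tsv(top.to_frame(), out / "top_variance_miRNA.tsv")
        if designs:
            report.pvca = sx.pvca(norm_mi, list(designs.values()), config.pc_variance_threshold)
            _write_tsv(report.pvca.to_frame(), out / "pvca_miRNA.tsv")

    # --- discovery -------------------------------------------------------
    if config.run_discovery:
        all_genome_alns = [a for s in samples for a in genome_alns[s]]
        cands = disc.discover(all_genome_alns, bundle.genome, bundle,
                              config.discovery, known_genomic=None)
        report.candidates = disc.candidate_table(cands)
        _write_tsv(report.candidates, out / "novel_candidates.tsv")
        with open(out / "novel_candidates.fa", "w") as fh:
            for c in cands:
                fh.write(f">{c.candidate_id}\n{c.sequence}\n{c.structure}\n")

    config.to_file(str(out / "run_config.ini"))
    return report


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(stream=sys.stderr, level=logging.DEBUG if verbose else logging.INFO,
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")
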