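"""File formats, configuration and the end-to-end pipelines.

Plain-text formats only: FASTA/FASTQ (via Biopython), TSV tables (via
pandas), GMT gene-set collections and a JSON run configuration. The two
pipeline drivers chain the stages — demultiplex, trim/align, indel filter,
conversion counting, background correction, Grubbs test for the read
pipeline; normalization, pairing, moderated t, BH, calls, overlaps and
enrichment for the expression pipeline — writing every intermediate as TSV
and echoing parameters into a run report.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

from . import __version__
from .amplicon_align import (
    AlignedRead,
    FastqRecord,
    FilterThresholds,
    ReferenceAmplicon,
    ScoringScheme,
    align_read,
    demultiplex,
)
from .methylation_calling import (
    MethylationCall,
    SiteMethylationTable,
    call_methylation,
    count_conversion,
)
from . import te_analysis as te

logger = logging.getLogger("riboseed")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_fastq(path: str | Path) -> list[FastqRecord]:
    """Read a FASTQ file (Sanger quality) into records."""
    records = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        records.append(FastqRecord(rec.id, str(rec.seq).upper(), qual))
    return records


def write_fastq(path: str | Path, reads: Iterable[FastqRecord]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{r.qual}\n")


def read_fasta_reference(
    path: str | Path, target_position: int, coordinate_offset: int = 0
) -> ReferenceAmplicon:
    """Load the first FASTA record as the reference amplicon."""
    recs = list(SeqIO.parse(str(path), "fasta"))
    if not recs:
        raise ValueError(f"{path}: no FASTA record found")
    rec = recs[0]
    return ReferenceAmplicon(
        id=rec.id,
        sequence=str(rec.seq).upper(),
        target_position=target_position,
        coordinate_offset=coordinate_offset,
    )


def write_fasta(path: str | Path, ref: ReferenceAmplicon) -> None:
    with open(path, "w") as fh:
        fh.write(f">{ref.id}\n{ref.sequence}\n")


def read_barcode_table(path: str | Path) -> dict[str, str]:
    """Read a two-column (sample, barcode) TSV without header."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "barcode"],
                     dtype=str, comment="#")
    table = dict(zip(df["sample"], df["barcode"]))
    if len(table) != len(df):
        raise ValueError(f"{path}: duplicate sample names")
    return table


def write_tsv(path: str | Path, frame: pd.DataFrame, index: bool = True) -> None:
    frame.to_csv(path, sep="\t", index=index)


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples log2 matrix TSV; duplicate gene ids reject."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicated gene id {dup!r}")
    return df


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file (name, description, members...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: GMT line needs >= 3 fields")
            sets[parts[0]] = set(parts[2:])
    return sets


def write_gmt(path: str | Path, sets: dict[str, set[str]]) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "na", *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# configuration and reports
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """All tunables of both pipelines, JSON-serializable."""

    reads_path: str = ""
    reference_path: str = ""
    barcodes_path: str = ""
    matrix_path: str = ""
    gene_sets_path: str = ""
    output_dir: str = "riboseed_out"
    target_position: int = 0
    coordinate_offset: int = 0
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    alpha: float = 0.01
    min_coverage: int = 10
    grubbs_two_sided: bool = False
    fc_threshold: float = 2.0
    p_threshold: float = 0.05
    n_permutations: int = 1000
    min_set_size: int = 5
    max_set_size: int = 1000
    seed: int = 0
    verbosity: str = "INFO"

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if "scoring" in raw:
            raw["scoring"] = ScoringScheme(**raw["scoring"])
        if "thresholds" in raw:
            raw["thresholds"] = FilterThresholds(**raw["thresholds"])
        return cls(**raw)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


@dataclass
class StageCount:
    stage: str
    count: int
    seconds: float


@dataclass
class RunReport:
    """Per-stage counts, parameter echo and wall-clock times."""

    stages: list[StageCount] = field(default_factory=list)
    parameters: dict = field(default_factory=dict)
    version: str = __version__

    def add(self, stage: str, count: int, seconds: float) -> None:
        self.stages.append(StageCount(stage, count, seconds))
        logger.info("%s: %d items (%.2fs)", stage, count, seconds)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(s) for s in self.stages]).set_index("stage")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "version": self.version,
            "parameters": self.parameters,
            "stages": [asdict(s) for s in self.stages],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True, default=str)


class StageError(RuntimeError):
    """An error in a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


# ---------------------------------------------------------------------------
# pipelines (library-level; the CLI wraps these)
# ---------------------------------------------------------------------------

def run_meth_analysis(
    reads: list[FastqRecord],
    ref: ReferenceAmplicon,
    barcode_table: dict[str, str],
    scoring: ScoringScheme = ScoringScheme(),
    thresholds: FilterThresholds = FilterThresholds(),
    alpha: float = 0.01,
    min_coverage: int = 10,
    grubbs_two_sided: bool = False,
) -> tuple[dict[str, MethylationCall], dict[str, SiteMethylationTable], RunReport]:
    """Demultiplex, align, filter, count and call methylation per sample."""
    report = RunReport(parameters={
        "alpha": alpha, "min_coverage": min_coverage,
        "scoring": asdict(scoring), "thresholds": asdict(thresholds),
    })
    t0 = time.perf_counter()
    report.add("input", len(reads), 0.0)
    try:
        demux = demultiplex(reads, barcode_table)
    except Exception as exc:
        raise StageError("demultiplex", exc) from exc
    n_assigned = sum(len(v) for v in demux.assigned.values())
    report.add("demultiplexed", n_assigned, time.perf_counter() - t0)

    calls: dict[str, MethylationCall] = {}
    tables: dict[str, SiteMethylationTable] = {}
    n_aligned = n_passed = 0
    t0 = time.perf_counter()
    for sample, sample_reads in demux.assigned.items():
        alns: list[AlignedRead] = []
        for read in sample_reads:
            try:
                aln = align_read(read, ref, scoring, thresholds)
            except Exception as exc:
                raise StageError("align", exc) from exc
            if aln is not None:
                alns.append(aln)
        n_aligned += len(alns)
        passing = [a for a in alns if a.passed_filter]
        n_passed += len(passing)
        try:
            table = count_conversion(passing, ref, sample_id=sample)
        except Exception as exc:
            raise StageError("count", exc) from exc
        tables[sample] = table
        if passing:
            try:
                calls[sample] = call_methylation(
                    table, ref, alpha=alpha, min_coverage=min_coverage,
                    two_sided=grubbs_two_sided,
                )
            except Exception as exc:
                raise StageError("call", exc) from exc
    dt = time.perf_counter() - t0
    report.add("aligned", n_aligned, dt)
    report.add("filtered", n_passed, 0.0)
    report.add("called_samples", len(calls), 0.0)
    return calls, tables, report


def run_te_analysis(
    matrix: pd.DataFrame,
    gene_sets: dict[str, set[str]] | None = None,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    n_permutations: int = 1000,
    min_set_size: int = 5,
    max_set_size: int = 1000,
    seed: int = 0,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame | None,
           dict[str, te.EnrichmentResult], RunReport]:
    """Normalize, pair, test and (optionally) enrich per condition.

    Returns per-condition TEResult tables, an overlap table over the
    regulated-gene sets (when >= 2 conditions), per-condition enrichment
    results (when gene sets are given), and the run report.
    """
    report = RunReport(parameters={
        "fc_threshold": fc_threshold, "p_threshold": p_threshold,
        "n_permutations": n_permutations, "min_set_size": min_set_size,
        "max_set_size": max_set_size, "seed": seed,
    })
    t0 = time.perf_counter()
    report.add("genes", matrix.shape[0], 0.0)
    try:
        samples = te.parse_sample_labels(list(matrix.columns))
        norm = te.normalize(matrix)
        ti = te.compute_te(norm, samples)
    except Exception as exc:
        raise StageError("normalize/pair", exc) from exc
    report.add("lysate_pairs", ti.shape[1], time.perf_counter() - t0)

    results: dict[str, pd.DataFrame] = {}
    t0 = time.perf_counter()
    conditions = sorted({c.split("|")[0] for c in ti.columns})
    for cond in conditions:
        cols = [c for c in ti.columns if c.split("|")[0] == cond]
        try:
            results[cond] = te.te_test(
                ti[cols], fc_threshold=fc_threshold, p_threshold=p_threshold
            )
        except Exception as exc:
            raise StageError(f"te_test[{cond}]", exc) from exc
    report.add("conditions_tested", len(results), time.perf_counter() - t0)

    overlap = None
    if len(results) >= 2:
        regulated = {
            cond: set(res.index[res["call"] != "unchanged"])
            for cond, res in results.items()
        }
        if sum(bool(s) for s in regulated.values()) >= 1:
            overlap = te.overlap_sets(regulated)

    enrichments: dict[str, te.EnrichmentResult] = {}
    if gene_sets:
        t0 = time.perf_counter()
        for cond, res in results.items():
            ranking = res["log2_te"]
            try:
                enrichments[cond] = te.preranked_enrichment(
                    ranking, gene_sets, n_perm=n_permutations,
                    min_size=min_set_size, max_size=max_set_size, seed=seed,
                )
            except Exception as exc:
                raise StageError(f"enrichment[{cond}]", exc) from exc
        report.add("enriched_conditions", len(enrichments),
                   time.perf_counter() - t0)
    return results, overlap, enrichments, report


# ---------------------------------------------------------------------------
# file-level drivers (read config, write every intermediate)
# ---------------------------------------------------------------------------

def _calls_frame(calls: dict[str, MethylationCall]) -> pd.DataFrame:
    rows = []
    for sample in sorted(calls):
        c = calls[sample]
        rows.append({
            "sample": sample,
            "target_position": c.target_position,
            "raw_fraction": round(c.raw_fraction, 6),
            "background_rate": round(c.background_rate, 6),
            "corrected_value": round(c.corrected_value, 6),
            "grubbs_statistic": round(c.grubbs_statistic, 6),
            "grubbs_critical": round(c.grubbs_critical, 6),
            "is_outlier": c.is_outlier,
            "alpha": c.alpha,
        })
    return pd.DataFrame(rows).set_index("sample")


def run_meth_pipeline(config: PipelineConfig) -> pd.DataFrame:
    """File-level read pipeline: FASTQ in, per-sample TSVs + summary out."""
    logging.basicConfig(level=config.verbosity)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    reads = read_fastq(config.reads_path)
    ref = read_fasta_reference(
        config.reference_path, config.target_position, config.coordinate_offset
    )
    barcodes = read_barcode_table(config.barcodes_path)
    calls, tables, report = run_meth_analysis(
        reads, ref, barcodes,
        scoring=config.scoring, thresholds=config.thresholds,
        alpha=config.alpha, min_coverage=config.min_coverage,
        grubbs_two_sided=config.grubbs_two_sided,
    )
    report.parameters["seed"] = config.seed
    for sample, table in sorted(tables.items()):
        frame = table.counts.copy()
        frame.index = frame.index + config.coordinate_offset
        frame.index.name = "absolute_position"
        write_tsv(out / f"methylation_{sample}.tsv", frame.round(6))
    summary = _calls_frame(calls) if calls else pd.DataFrame()
    write_tsv(out / "methylation_calls.tsv", summary)
    report.to_json(out / "run_report_meth.json")
    return summary


def run_te_pipeline(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """File-level expression pipeline: matrix TSV in, result TSVs out."""
    logging.basicConfig(level=config.verbosity)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix = read_matrix(config.matrix_path)
    gene_sets = read_gmt(config.gene_sets_path) if config.gene_sets_path else None
    results, overlap, enrichments, report = run_te_analysis(
        matrix, gene_sets,
        fc_threshold=config.fc_threshold, p_threshold=config.p_threshold,
        n_permutations=config.n_permutations,
        min_set_size=config.min_set_size, max_set_size=config.max_set_size,
        seed=config.seed,
    )
    report.parameters["seed"] = config.seed
    for cond, res in sorted(results.items()):
        write_tsv(out / f"te_results_{cond}.tsv", res.round(6))
    if overlap is not None:
        write_tsv(out / "overlap_regulated.tsv", overlap, index=False)
    for cond, enr in sorted(enrichments.items()):
        write_tsv(out / f"enrichment_{cond}.tsv", enr.table.round(6))
    report.to_json(out / "run_report_te.json")
    return results
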