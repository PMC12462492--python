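"""End-to-end curation pipeline over a consensus library and a genome.

Per input consensus: find genomic copies (a supplied 12-column hit table
or the internal search), gate on copy number, sample hits, extract and
stack the copies, split the alignment into variant clusters, extend each
cluster to recover the full element, define boundaries, emit and evaluate
a curated consensus.  Inputs that fail at any stage are routed to a failed
list; the batch never aborts.  After all inputs, the collected records are
de-duplicated into the merged library.

Inputs are processed sequentially in file order and all randomness derives
from the single pipeline seed, so a rerun with the same seed reproduces
the output byte for byte; the ``threads`` setting is accepted for
interface compatibility and does not alter results.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .boundary import (
    BoundaryParams,
    ConsensusRecord,
    NoTeRegionError,
    define_boundaries,
    detect_terminal_repeats,
    finalize_consensus,
    find_orfs,
    orient_consensus,
)
from .cleaning import GapColumnParams, remove_gap_columns
from .clustering import ClusteringParams, partition_msa
from .evaluation import (
    DedupParams,
    EvaluationRules,
    count_full_length_hits,
    dedup_library,
    evaluate_record,
    greedy_cluster,
    low_copy_gate,
)
from .extension import ExtensionParams, run_extension, stack_by_anchor
from .genome import (
    Genome,
    HitRecord,
    interval_id,
    naive_search,
    parse_hit_table,
    sample_hits,
)
from .msa import Msa, boundary_report

__all__ = ["PipelineConfig", "PipelineResult", "process_one_input", "run_pipeline"]


@dataclass
class PipelineConfig:
    genome_path: str | Path = ""
    input_path: str | Path = ""
    output_dir: str | Path = "tecurate_out"
    seed: int = 0
    threads: int = 1  # accepted for compatibility; execution is sequential
    dedup_input: bool = False
    hits_path: str | Path | None = None
    min_hits_for_msa: int = 10  # an MSA is built only with more hits than this
    search_k: int = 15
    search_min_identity: float = 0.8
    clustering: ClusteringParams = field(default_factory=ClusteringParams)
    gap_column: GapColumnParams = field(default_factory=GapColumnParams)
    extension: ExtensionParams = field(default_factory=ExtensionParams)
    boundary: BoundaryParams = field(default_factory=BoundaryParams)
    rules: EvaluationRules = field(default_factory=EvaluationRules)
    dedup: DedupParams = field(default_factory=DedupParams)
    orf_min_len: int = 300


@dataclass
class PipelineResult:
    records: list[ConsensusRecord]
    merged: list[ConsensusRecord]
    failed: list[tuple[str, str]]  # (input id, reason)
    output_dir: Path | None = None


def _parse_header(header: str) -> tuple[str, str]:
    """Split a ``name#Class/Subclass`` FASTA id."""
    if "#" in header:
        name, classification = header.split("#", 1)
        return name, classification
    return header, "Unknown"


def _low_copy_record(
    name: str,
    seq: str,
    classification: str,
    hits: list[HitRecord],
    config: PipelineConfig,
) -> ConsensusRecord | None:
    tr = detect_terminal_repeats(seq, config.boundary)
    fl = count_full_length_hits(seq, hits, config.rules)
    verdict = low_copy_gate(len(hits), tr is not None, fl, config.rules)
    if verdict == "discard":
        return None
    record = ConsensusRecord(
        name=f"{name}_lc",
        consensus=seq,
        classification=classification,
        terminal_repeat=tr,
        msa_size=len(hits),
        input_id=name,
        evaluation="Low_copy",
    )
    return record


def process_one_input(
    name: str,
    seq: str,
    classification: str,
    genome: Genome,
    config: PipelineConfig,
    hits: list[HitRecord] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[ConsensusRecord], list[tuple[str, str]], list[str]]:
    """Curate one input consensus; returns (records, failures, reports)."""
    rng = rng or np.random.default_rng(config.seed)
    records: list[ConsensusRecord] = []
    failures: list[tuple[str, str]] = []
    reports: list[str] = []

    if hits is None:
        hits = naive_search(
            seq,
            genome,
            query_id=name,
            k=config.search_k,
            min_identity=config.search_min_identity,
        )
    if not hits:
        return [], [(name, "no genomic hits")], []

    if len(hits) <= config.min_hits_for_msa:
        rec = _low_copy_record(name, seq, classification, hits, config)
        if rec is None:
            return [], [(name, "low-copy gate: discarded")], []
        return [rec], [], []

    sampled = sample_hits(hits, seed=rng)
    ids, spans, seqs, provenance, anchors = [], {}, {}, {}, {}
    for hit in sampled:
        iv = genome.clamp(hit.interval)
        sid = interval_id(iv)
        if sid in spans:
            continue
        ids.append(sid)
        spans[sid] = (hit.q_start, hit.q_start + iv.length)
        seqs[sid] = genome.fetch(iv)
        provenance[sid] = iv
        anchors[sid] = hit.q_start
    stacked = stack_by_anchor(spans, seqs)
    stacked.provenance = provenance

    cleaned, _ = remove_gap_columns(stacked, config.gap_column)
    cleaned.provenance = provenance
    clusters = partition_msa(cleaned, config.clustering)

    for idx, cluster in enumerate(clusters):
        rec_name = f"{name}_c{idx}"
        try:
            ext = run_extension(
                cluster, genome, config.extension, anchors=anchors
            )
            bres = define_boundaries(ext.msa, classification, config.boundary)
            record = finalize_consensus(
                bres.msa,
                bres.start_col,
                bres.end_col,
                config.boundary,
                name=rec_name,
                classification=classification,
                terminal_repeat=bres.terminal_repeat,
                tail=bres.tail,
                left_ext=ext.left_total,
                right_ext=ext.right_total,
                input_id=name,
                cluster_index=idx,
            )
            sub = bres.msa.take_columns(range(bres.start_col, bres.end_col))
            record, sub = orient_consensus(record, sub, orf_min_len=config.orf_min_len)

            fl_hits = naive_search(
                record.consensus,
                genome,
                query_id=record.name,
                k=config.search_k,
                min_identity=config.search_min_identity,
            )
            fl = count_full_length_hits(record.consensus, fl_hits, config.rules)
            if cluster.n_rows < config.rules.low_copy_msa_size:
                verdict = low_copy_gate(
                    cluster.n_rows, record.terminal_repeat is not None, fl, config.rules
                )
                if verdict == "discard":
                    failures.append((rec_name, "low-copy gate: discarded"))
                    continue
                record.evaluation = "Low_copy"
            else:
                evidence = bool(find_orfs(record.consensus, config.orf_min_len))
                record.evaluation = evaluate_record(
                    record, cluster.n_rows, fl, config.rules, has_evidence=evidence
                )
            records.append(record)
            reports.extend(
                _report_lines(record.name, bres.msa, bres.start_col, bres.end_col)
            )
        except NoTeRegionError as exc:
            failures.append((rec_name, str(exc)))
        except Exception as exc:  # noqa: BLE001 - batch must not abort
            failures.append((rec_name, f"{type(exc).__name__}: {exc}"))
    return records, failures, reports


def _report_lines(name: str, msa: Msa, start_col: int, end_col: int) -> list[str]:
    """Boundary-region report rows for one record (flanks around the two
    boundary columns joined by ten hyphens)."""
    rep = boundary_report(msa, start_col, end_col)
    return [f"{name}\t{sid}\t{seq}\n" for sid, seq in rep.rows()]


def _dedup_inputs(
    entries: list[tuple[str, str, str]], params: DedupParams
) -> list[tuple[str, str, str]]:
    clusters = greedy_cluster(
        [e[2] for e in entries], params.input_identity, "all", params.input_coverage
    )
    keep = sorted(cluster[0] for cluster in clusters)
    return [entries[i] for i in keep]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full pipeline and write the output directory.

    Outputs: ``consensus_all.fasta`` (every curated record),
    ``consensus_merged.fasta`` (after library de-duplication),
    ``summary.tsv``, ``boundary_reports.tsv``, ``failed.txt`` and
    ``run_log.json``.  Reruns with the same seed are byte-identical.
    """
    from Bio import SeqIO

    genome = Genome.from_fasta(config.genome_path)
    entries = [
        (*_parse_header(rec.id), str(rec.seq).upper())
        for rec in SeqIO.parse(str(config.input_path), "fasta")
    ]  # (name, classification, sequence)
    if not entries:
        raise ValueError(f"no input sequences in {config.input_path}")

    if config.dedup_input:
        entries = _dedup_inputs(entries, config.dedup)

    hits_by_query: dict[str, list[HitRecord]] = {}
    if config.hits_path:
        for hit in parse_hit_table(config.hits_path):
            hits_by_query.setdefault(hit.query_id, []).append(hit)

    records: list[ConsensusRecord] = []
    failed: list[tuple[str, str]] = []
    reports: list[str] = []
    for idx, (name, classification, seq) in enumerate(entries):
        rng = np.random.default_rng([config.seed, idx])
        recs, fails, reps = process_one_input(
            name,
            seq,
            classification,
            genome,
            config,
            hits=hits_by_query.get(name),
            rng=rng,
        )
        records.extend(recs)
        failed.extend(fails)
        reports.extend(reps)

    merged = dedup_library(records, config.dedup)

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_library(records, outdir / "consensus_all.fasta")
    _write_library(merged, outdir / "consensus_merged.fasta")
    _write_summary(records, outdir / "summary.tsv")
    (outdir / "boundary_reports.tsv").write_text(
        "record\treport\n" + "".join(reports)
    )
    (outdir / "failed.txt").write_text(
        "".join(f"{name}\t{reason}\n" for name, reason in failed)
    )
    log = {
        "inputs": len(entries),
        "records": len(records),
        "merged": len(merged),
        "failed": len(failed),
        "seed": config.seed,
        "levels": {
            level: sum(1 for r in records if r.evaluation == level)
            for level in ("Perfect", "Good", "Reco_check", "Need_check", "Low_copy")
        },
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2) + "\n")
    return PipelineResult(records=records, merged=merged, failed=failed, output_dir=outdir)


def _write_library(records: list[ConsensusRecord], path: Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(
                f">{rec.name}#{rec.classification} "
                f"evaluation={rec.evaluation or 'NA'} length={rec.length}\n"
            )
            for i in range(0, len(rec.consensus), 60):
                fh.write(rec.consensus[i : i + 60] + "\n")


def _write_summary(records: list[ConsensusRecord], path: Path) -> None:
    rows = [
        {
            "record": r.name,
            "input_id": r.input_id,
            "cluster_index": r.cluster_index,
            "msa_size": r.msa_size,
            "consensus_length": r.length,
            "terminal_repeat": r.terminal_repeat.kind if r.terminal_repeat else "none",
            "tail": r.tail.kind if r.tail else "none",
            "left_ext": r.left_ext,
            "right_ext": r.right_ext,
            "reclassify": r.reclassify,
            "evaluation": r.evaluation,
            "classification": r.classification,
        }
        for r in records
    ]
    pd.DataFrame(
        rows,
        columns=[
            "record",
            "input_id",
            "cluster_index",
            "msa_size",
            "consensus_length",
            "terminal_repeat",
            "tail",
            "left_ext",
            "right_ext",
            "reclassify",
            "evaluation",
            "classification",
        ],
    ).to_csv(path, sep="\t", index=False)
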