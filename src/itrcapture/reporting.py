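"""End-to-end pipeline orchestration, configuration and report writing.

A run is described by one configuration mapping (YAML/TOML on disk) naming
a pipeline (``amplicon``, ``genomewide`` or ``clones``), a seed, and the
simulation/analysis parameters.  All randomness flows from the single
top-level seed; reruns with the same configuration are byte-identical.
Every run writes a manifest with the configuration snapshot, input
checksums and a per-stage read-accounting table in which every discarded
read is attributed to exactly one reason.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .amplicon_analysis import quantify_indels, summarize_amplicon
from .architecture_profiles import classify_clone, vector_coverage_profile
from .fusion_detection import (
    AlignParams,
    merge_pairs,
    vector_breakpoint_profile,
)
from .genomewide_analysis import (
    ReadAccounting,
    annotate_sites,
    call_sites,
    filter_itr_evidence,
    filter_shared_homology,
    recurrence,
    summarize_condition,
)
from .io import write_fastq, write_table
from .synthetic_data import (
    DecoyLocus,
    PlantedSite,
    SimConfig,
    attach_itr_primer,
    make_toy_host,
    make_toy_locus,
    simulate_aavseq_reads,
    simulate_amplicon_reads,
    simulate_clones,
)
from .vector_model import aav_lambda_465

logger = logging.getLogger("itrcapture")

__all__ = [
    "ConfigError",
    "InputParseError",
    "AnalysisError",
    "RunManifest",
    "run_end_to_end",
    "write_report",
    "load_config",
]


class ConfigError(ValueError):
    """Invalid configuration; exit code 2."""


class InputParseError(ValueError):
    """Malformed input file; exit code 3."""


class AnalysisError(RuntimeError):
    """Failure inside an analysis stage; exit code 4."""


@dataclass
class RunManifest:
    command: str
    config: dict
    seed: int
    version: str = __version__
    input_checksums: dict[str, str] = field(default_factory=dict)
    accounting: dict[str, int] = field(default_factory=dict)
    status: str = "running"

    def write(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")


def _checksum(data: str) -> str:
    return hashlib.sha256(data.encode()).hexdigest()[:16]


def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        cfg = yaml.safe_load(text)
    elif path.suffix == ".toml":
        import tomllib

        cfg = tomllib.loads(text)
    else:
        raise ConfigError(f"unsupported config format: {path.suffix}")
    if not isinstance(cfg, dict):
        raise ConfigError("configuration must be a mapping")
    return cfg


def _sim_config(cfg: dict, seed: int) -> SimConfig:
    sim = dict(cfg.get("simulate", {}))
    sim.setdefault("seed", seed)
    known = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(sim) - known
    if unknown:
        raise ConfigError(f"unknown simulate keys: {sorted(unknown)}")
    try:
        return SimConfig(**sim)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def run_end_to_end(config: dict, outdir) -> Path:
    """Execute simulate -> analyze -> report for one configured pipeline.

    Returns the output directory.  The manifest is written even when a
    stage fails (with ``status: failed``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pipeline = config.get("pipeline")
    if pipeline not in ("amplicon", "genomewide", "clones"):
        raise ConfigError(f"pipeline must be amplicon|genomewide|clones, got {pipeline!r}")
    seed = int(config.get("seed", 1))
    manifest = RunManifest(command=f"run {pipeline}", config=config, seed=seed)
    try:
        if pipeline == "amplicon":
            _run_amplicon(config, seed, outdir, manifest)
        elif pipeline == "genomewide":
            _run_genomewide(config, seed, outdir, manifest)
        else:
            _run_clones(config, seed, outdir, manifest)
        manifest.status = "ok"
    except Exception:
        manifest.status = "failed"
        manifest.write(outdir / "manifest.json")
        raise
    manifest.write(outdir / "manifest.json")
    return outdir


def _merge_or_first(pairs):
    """Merge read pairs; unmergeable pairs are analyzed as read 1 only."""
    merged, n_merged, n_unmerged = [], 0, 0
    for r1, r2 in pairs:
        m = merge_pairs(r1, r2)
        if m is None:
            n_unmerged += 1
            merged.append(r1)
        else:
            n_merged += 1
            merged.append(m)
    return merged, n_merged, n_unmerged


def _run_amplicon(config, seed, outdir, manifest):
    sim = _sim_config(config, seed)
    locus = make_toy_locus()
    vector = aav_lambda_465()
    reads, truth = simulate_amplicon_reads(sim, locus, vector)
    if sim.paired:
        write_fastq([r for p in reads for r in (p[0],)], outdir / "reads_R1.fastq")
        write_fastq([p[1] for p in reads], outdir / "reads_R2.fastq")
        reads, n_merged, n_unmerged = _merge_or_first(reads)
        manifest.accounting.update(n_merged=n_merged, n_unmerged=n_unmerged)
    else:
        write_fastq(reads, outdir / "reads.fastq")
    write_table(truth, outdir / "truth.tsv")
    manifest.input_checksums["reads"] = _checksum("".join(r.sequence for r in reads))
    params = AlignParams(**config.get("align", {}))
    outcomes = quantify_indels(
        [(r.name, r.sequence) for r in reads],
        locus,
        vector,
        window_halfwidth=int(config.get("window_halfwidth", 5)),
        params=params,
    )
    summary = summarize_amplicon(outcomes, locus)
    manifest.accounting.update(
        n_input=summary.n_total,
        n_unmodified=summary.n_unmodified,
        n_substitution_only=summary.n_substitution_only,
        n_small_indel=summary.n_small_indel,
        n_fusion=summary.n_fusion,
        n_unaligned=summary.n_unaligned,
    )
    calls = [o.fusion for o in outcomes if o.outcome == "vector_fusion"]
    profile = vector_breakpoint_profile(calls, vector)
    prof_df = pd.DataFrame(
        {"itr_local_position": np.arange(profile.itr.size), "count": profile.itr}
    )
    write_table(prof_df, outdir / "itr_breakpoint_profile.tsv")
    per_read = pd.DataFrame(
        [
            {
                "read_id": o.read_id,
                "outcome": o.outcome,
                "net_indel_size": o.net_indel_size,
                "host_breakpoint_1based": (
                    o.fusion.host_breakpoint + 1 if o.fusion else ""
                ),
                "vector_breakpoint_1based": (
                    o.fusion.vector_breakpoint + 1 if o.fusion else ""
                ),
                "itr_overlap": o.fusion.itr_overlap if o.fusion else "",
            }
            for o in outcomes
        ]
    )
    write_table(per_read, outdir / "per_read.tsv")
    write_report({"amplicon": summary.to_dict()}, outdir)
    logger.info(
        "amplicon: %d reads, %d indel, %d fusion, capture ratio %.4f",
        summary.n_total,
        summary.n_small_indel,
        summary.n_fusion,
        summary.capture_ratio,
    )


def _run_genomewide(config, seed, outdir, manifest):
    sim = _sim_config(config, seed)
    vector = attach_itr_primer(aav_lambda_465())
    host = make_toy_host(seed=seed + 100)
    gw = config.get("genomewide", {})
    rng = np.random.default_rng(seed + 7)
    chroms = sorted(host.sequences)
    n_sites = int(gw.get("n_true_sites", 3))
    planted = [
        PlantedSite(
            chroms[i % len(chroms)],
            int(rng.integers(5000, len(host.sequences[chroms[i % len(chroms)]]) - 5000)),
            "+",
            int(gw.get("reads_per_site", 5)),
        )
        for i in range(n_sites)
    ]
    decoys = [
        DecoyLocus(chroms[-1], 30000 + 500 * i, 30, int(gw.get("reads_per_decoy", 4)))
        for i in range(int(gw.get("n_decoys", 1)))
    ]
    from .synthetic_data import plant_decoy_homology

    for d in decoys:
        plant_decoy_homology(host, vector, d)
    reads, truth = simulate_aavseq_reads(sim, host, vector, planted, decoys)
    write_fastq(reads, outdir / "reads.fastq")
    write_table(truth, outdir / "truth.tsv")
    acct = ReadAccounting()
    raw = call_sites(
        [(r.name, r.sequence) for r in reads],
        vector,
        host,
        primer=vector.primer_sites[0][0],
        accounting=acct,
    )
    sites = filter_shared_homology(raw, vector)
    sites = filter_itr_evidence(sites, vector)
    sites = annotate_sites(sites, host)
    manifest.accounting.update(dataclasses.asdict(acct))
    summary = summarize_condition(
        sites, total_reads=max(len(reads), 1), condition_id="demo"
    )
    site_df = pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "position_1based": s.breakpoint + 1,
                "strand": s.strand,
                "reads": s.read_count,
                "normalized_per_million": s.normalized_count,
                "category": s.category,
                "filter_status": s.filter_status,
            }
            for s in sites
        ]
    )
    write_table(site_df, outdir / "sites.tsv")
    excluded = site_df[site_df["filter_status"] != "pass"]
    write_table(excluded, outdir / "excluded_sites.tsv")
    bed = pd.DataFrame(
        [
            {
                "chrom": c.chrom,
                "start": c.position,
                "end": c.position + 1,
                "name": f"site_{i}",
                "score": c.read_count,
                "strand": "+",
            }
            for i, c in enumerate(summary.clusters)
        ]
    )
    write_table(bed, outdir / "sites.bed")
    write_report({"genomewide": summary.to_dict()}, outdir)
    logger.info(
        "genomewide: %d reads -> %d raw sites -> %d unique passing sites",
        len(reads),
        len(raw),
        summary.n_unique_sites,
    )


def _run_clones(config, seed, outdir, manifest):
    sim = _sim_config(config, seed)
    vector = aav_lambda_465()
    host = make_toy_host(seed=seed + 100)
    flank_left = host.sequences["chr1"][1000:1080]
    flank_right = host.sequences["chr1"][1080:1160]
    clones, truth = simulate_clones(sim, vector, (flank_left, flank_right))
    from .io import write_fasta

    write_fasta(clones, outdir / "clones.fasta")
    write_table(truth, outdir / "truth.tsv")
    calls = [
        classify_clone(seq, vector, (flank_left, flank_right), clone_id=cid)
        for cid, seq in clones
    ]
    per_clone = pd.DataFrame(
        [
            {
                "clone_id": c.clone_id,
                "type": c.type,
                "itr_count": c.itr_count,
                "cargo_coverage": round(c.cargo_coverage, 4),
                "vector_copies": c.vector_copies,
                "microhomology_left": c.microhomology_left,
                "microhomology_right": c.microhomology_right,
                "host_indel": c.host_indel,
            }
            for c in calls
        ]
    )
    write_table(per_clone, outdir / "clones.tsv")
    profile = vector_coverage_profile(calls, vector)
    write_table(
        pd.DataFrame(
            {"vector_position_1based": np.arange(1, len(profile.counts) + 1),
             "count": profile.counts}
        ),
        outdir / "vector_coverage_profile.tsv",
    )
    from collections import Counter

    type_counts = Counter(c.type for c in calls)
    manifest.accounting.update(n_input=len(clones), **type_counts)
    write_report(
        {"clones": {"n_clones": len(clones), "type_counts": dict(type_counts)}},
        outdir,
    )
    logger.info("clones: %d classified, counts %s", len(clones), dict(type_counts))


REPORT_SCHEMA_VERSION = 1


def write_report(summaries: dict, outdir) -> Path:
    """Write the machine-readable JSON report (schema-versioned).

    Ratio fields are always accompanied by explicit numerator/denominator
    entries so every reported fraction can be recomputed exactly.
    """
    if not summaries:
        raise ValueError("write_report requires at least one summary")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    doc = {"schema_version": REPORT_SCHEMA_VERSION, "tool_version": __version__}
    for name, summary in summaries.items():
        block = dict(summary)
        if "capture_ratio" in block:
            block["capture_ratio_numerator"] = block.get("n_fusion")
            block["capture_ratio_denominator"] = (
                block.get("n_fusion", 0) + block.get("n_small_indel", 0)
            )
        doc[name] = block
    path = outdir / "report.json"
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")
    return path


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, set):
        return sorted(obj)
    return str(obj)


def recurrence_report(per_condition_clusters: dict, outdir, k: int = 3) -> pd.DataFrame:
    """Cross-condition recurrence table written alongside the report."""
    table = recurrence(per_condition_clusters, k=k)
    df = pd.DataFrame(
        [
            {
                "chrom": chrom,
                "position_1based": pos + 1,
                "n_conditions": len(conds),
                "conditions": ",".join(sorted(conds)),
                "recurrent": len(conds) >= table.k,
            }
            for (chrom, pos), conds in sorted(table.entries.items())
        ]
    )
    write_table(df, Path(outdir) / "recurrence.tsv")
    return df
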