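"""End-to-end orchestration: stages, config, sentinels, reports.

No new computation lives here; the pipeline wires the stages
(process-reads -> call-insertions -> cluster -> cooccur) with explicit
seeds, structured JSON-lines logging, and versioned outputs.  Every
output file carries the configuration hash in a header line, identical
(inputs, config, seed) yield byte-identical outputs, and a rerun resumes
from the last completed stage via per-stage sentinel files.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import calling, cooccurrence, readproc, reference, subclones

STAGES = ("process_reads", "call_insertions", "cluster", "cooccur")


@dataclass
class PipelineConfig:
    """Paths, thresholds and seeds for a full run; serialised alongside outputs."""

    genome: str
    r1: str
    r2: str
    outdir: str
    sample_id: str = "sample"
    genes: str | None = None
    drivers: str | None = None
    transposon_tag: str = "TCGTTAGAACGCGTAATACG"
    min_reads_per_site: int = 10
    min_sites: int = 2
    min_support: int = 2
    cut: float = 0.5
    min_cluster_sites: int = 2
    promoter_window: int = 40_000
    n_iter: int = 10_000
    seed: int = 0
    run_cooccurrence: bool = True

    def validate(self) -> None:
        for name in ("genome", "r1", "r2"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"config.{name}: no such file {p!r}")
        for name in ("genes", "drivers"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config.{name}: no such file {p!r}")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        if self.run_cooccurrence and self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = json.load(fh)
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


class _Log:
    def __init__(self, path: Path):
        self.path = path

    def event(self, stage: str, status: str, **extra) -> None:
        record = {"stage": stage, "status": status, **extra}
        with open(self.path, "a") as fh:
            fh.write(json.dumps(record, sort_keys=True) + "\n")


def _write_tsv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"#config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: PipelineConfig, resume: bool = True) -> Path:
    """Run all stages in order, resuming from the last completed stage."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    with open(outdir / "config.json", "w") as fh:
        json.dump(asdict(config), fh, indent=2, sort_keys=True)
    log = _Log(outdir / "pipeline_log.jsonl")

    def done(stage: str) -> Path:
        return outdir / f".{stage}.done"

    genome = reference.load_genome(config.genome)

    try:
        if not (resume and done("process_reads").exists()):
            t0 = time.monotonic()
            junctions, audit = readproc.process_read_pairs(
                readproc.read_pairs(config.r1, config.r2),
                genome,
                config.transposon_tag,
            )
            readproc.write_junctions(junctions, outdir / "junctions.tsv")
            _write_tsv(
                pd.DataFrame(sorted(audit.items()), columns=["category", "count"]),
                outdir / "read_audit.tsv",
                chash,
            )
            done("process_reads").touch()
            log.event("process_reads", "ok", seconds=round(time.monotonic() - t0, 3),
                      kept=audit.get("kept", 0))

        if not (resume and done("call_insertions").exists()):
            t0 = time.monotonic()
            junctions = readproc.read_junctions(outdir / "junctions.tsv")
            cells = calling.aggregate_cells(junctions)
            sample = calling.build_sample(
                cells,
                config.sample_id,
                min_reads_per_site=config.min_reads_per_site,
                min_sites=config.min_sites,
            )
            rows = [
                {"cell_barcode": c.cell_barcode, "site_key": s.key, "reads": n}
                for c in sample.cells
                for s, n in sorted(c.site_counts.items())
            ]
            _write_tsv(pd.DataFrame(rows), outdir / "cells.tsv", chash)
            _write_tsv(
                pd.DataFrame({"site_key": [s.key for s in sample.nonredundant_sites]}),
                outdir / "nonredundant_sites.tsv",
                chash,
            )
            with open(outdir / "qc_audit.json", "w") as fh:
                json.dump(sample.audit, fh, indent=2, sort_keys=True)
            done("call_insertions").touch()
            log.event("call_insertions", "ok", seconds=round(time.monotonic() - t0, 3),
                      cells=sample.n_cells)

        if not (resume and done("cluster").exists()):
            t0 = time.monotonic()
            sample = _load_sample(outdir, config)
            adjacency = subclones.build_adjacency(sample)
            subs, pooled = subclones.cluster_sites(
                adjacency,
                min_support=config.min_support,
                cut=config.cut,
                min_cluster_sites=config.min_cluster_sites,
            )
            assignment = subclones.assign_cells(
                sample.cells, subs, min_reads_per_site=config.min_reads_per_site
            )
            if config.genes and config.drivers:
                genes = reference.load_genes(config.genes)
                annotation = reference.AnnotationIndex(
                    genes, promoter_window=config.promoter_window
                )
                subclones.annotate_drivers(
                    subs, subclones.load_driver_list(config.drivers), annotation
                )
            _write_tsv(
                pd.DataFrame(
                    [
                        {
                            "subclone_id": sc.subclone_id,
                            "n_sites": len(sc.site_set),
                            "n_cells": len(sc.assigned_cells),
                            "driver_genes": ",".join(sorted(sc.driver_genes)),
                        }
                        for sc in subs
                    ]
                ),
                outdir / "subclones.tsv",
                chash,
            )
            _write_tsv(
                pd.DataFrame(
                    sorted(assignment.items()), columns=["cell_barcode", "label"]
                ),
                outdir / "assignments.tsv",
                chash,
            )
            tri = [
                {"site_i": adjacency.sites[i].key, "site_j": adjacency.sites[j].key,
                 "n_cells": int(adjacency.matrix[i, j])}
                for i in range(len(adjacency.sites))
                for j in range(i, len(adjacency.sites))
                if adjacency.matrix[i, j]
            ]
            _write_tsv(pd.DataFrame(tri), outdir / "adjacency.tsv", chash)
            done("cluster").touch()
            log.event("cluster", "ok", seconds=round(time.monotonic() - t0, 3),
                      subclones=len(subs))

        if config.run_cooccurrence and not (resume and done("cooccur").exists()):
            t0 = time.monotonic()
            if not config.genes:
                raise ValueError("cooccurrence stage requires a gene-model file")
            sample = _load_sample(outdir, config)
            genes = reference.load_genes(config.genes)
            annotation = reference.AnnotationIndex(
                genes, promoter_window=config.promoter_window
            )
            ta_index = reference.build_ta_index(genome)
            pairs = cooccurrence.discover_recurrent_pairs([sample], annotation)
            if pairs:
                results = cooccurrence.analyze_cooccurrence(
                    [sample], pairs, annotation, ta_index,
                    n_iter=config.n_iter, seed=config.seed,
                )
            else:
                results = pd.DataFrame(
                    columns=["sample_id", "gene_a", "gene_b", "k", "c",
                             "p_raw", "p_raw_is_bound", "p_adj", "p_est"]
                )
            _write_tsv(results, outdir / "cooccurrence.tsv", chash)
            with open(outdir / "permutation_audit.json", "w") as fh:
                json.dump(
                    {"seed": config.seed, "n_iter": config.n_iter,
                     "n_pairs": len(pairs)},
                    fh, indent=2, sort_keys=True,
                )
            done("cooccur").touch()
            log.event("cooccur", "ok", seconds=round(time.monotonic() - t0, 3),
                      pairs=len(pairs))
    except Exception as exc:  # log the failing stage, then re-raise
        log.event("pipeline", "failed", error=str(exc))
        raise
    return outdir


def _load_sample(outdir: Path, config: PipelineConfig) -> calling.SampleDataset:
    df = pd.read_csv(outdir / "cells.tsv", sep="\t", comment="#")
    cells: dict[str, dict] = {}
    for _, row in df.iterrows():
        contig, pos, orient = str(row["site_key"]).rsplit(":", 2)
        site = calling.InsertionSite(contig, int(pos), orient)
        cells.setdefault(str(row["cell_barcode"]), {})[site] = int(row["reads"])
    profiles = [calling.CellProfile(bc, sites) for bc, sites in sorted(cells.items())]
    return calling.build_sample(
        profiles,
        config.sample_id,
        min_reads_per_site=config.min_reads_per_site,
        min_sites=config.min_sites,
    )


def report(run_dir: str | Path) -> dict:
    """Summarise a finished (or partial) run as a JSON-able dict + TSV."""
    run_dir = Path(run_dir)
    summary: dict = {"run_dir": str(run_dir), "stages_completed": []}
    for stage in STAGES:
        if (run_dir / f".{stage}.done").exists():
            summary["stages_completed"].append(stage)
    incomplete = [s for s in STAGES if s not in summary["stages_completed"]]
    summary["incomplete_stages"] = incomplete
    if (run_dir / "qc_audit.json").exists():
        with open(run_dir / "qc_audit.json") as fh:
            summary["qc"] = json.load(fh)
    if (run_dir / "subclones.tsv").exists():
        subs = pd.read_csv(run_dir / "subclones.tsv", sep="\t", comment="#")
        asn = pd.read_csv(run_dir / "assignments.tsv", sep="\t", comment="#")
        n = len(asn)
        summary["subclones"] = {
            "count": len(subs),
            "sizes": subs["n_cells"].tolist(),
            "site_counts": subs["n_sites"].tolist(),
            "pct_unassigned": round(100.0 * (asn["label"] == "UNASSIGNED").sum() / n, 2)
            if n else 0.0,
            "pct_multi": round(100.0 * (asn["label"] == "MULTI").sum() / n, 2)
            if n else 0.0,
        }
    if (run_dir / "cooccurrence.tsv").exists():
        co = pd.read_csv(run_dir / "cooccurrence.tsv", sep="\t", comment="#")
        summary["cooccurrence"] = {
            "n_pairs_evaluated": int(co[["gene_a", "gene_b"]].drop_duplicates().shape[0]),
            "n_significant": int((co["p_adj"] <= 0.05).sum()) if len(co) else 0,
        }
    else:
        summary["cooccurrence"] = {"skipped": True}
    with open(run_dir / "report.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
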