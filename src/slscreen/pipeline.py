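"""End-to-end orchestration: simulate -> count -> call -> enrich.

Each stage reads and writes plain TSV/JSON files so any stage can be re-run
or audited on its own; there is no opaque intermediate state.  Filtering is
never silent — excluded clones and unassigned reads are logged and counted in
the summary.  Re-running with an identical config and seed reproduces the
TSV outputs byte for byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import enrichment as enr
from . import hitcall, quantify, simulate
from .config import PipelineConfig
from .library import ShRNALibrary, library_summary, read_library, write_library

__all__ = ["run_pipeline", "StageError"]

logger = logging.getLogger(__name__)

_FAIL_MARKER = "PIPELINE_FAILED"


class StageError(RuntimeError):
    """A stage failed; carries the stage tag for CLI exit messages."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - tag and re-raise
                raise StageError(name, str(exc)) from exc
            logger.info("stage %s: done", name)
            return out

        return wrapped

    return deco


@_stage("library")
def _load_library(cfg: PipelineConfig, outdir: Path) -> ShRNALibrary:
    if cfg.paths.library:
        lib = read_library(cfg.paths.library)
        logger.info("library: read %d clones from %s", len(lib), cfg.paths.library)
    elif cfg.simulate is not None:
        lib = simulate.simulate_library(cfg.simulate)
        write_library(lib, outdir / "library.tsv")
        logger.info("library: simulated %d clones", len(lib))
    else:
        raise ValueError("no library path and no simulate block")
    s = library_summary(lib)
    logger.info(
        "library: %d clones, %d genes, %d controls (clones/gene %d-%d)",
        s.n_clones, s.n_genes, s.n_controls,
        s.min_clones_per_gene, s.max_clones_per_gene,
    )
    return lib


@_stage("counts")
def _obtain_counts(cfg: PipelineConfig, lib: ShRNALibrary, outdir: Path):
    truth = None
    if cfg.paths.counts:
        cm = quantify.read_counts(cfg.paths.counts, lib)
        logger.info("counts: read %s", cfg.paths.counts)
    elif cfg.paths.fastq:
        cm = quantify.count_reads(
            cfg.paths.fastq, lib,
            max_mismatch=cfg.count.max_mismatch,
            offset=cfg.count.offset,
            try_revcomp=cfg.count.try_revcomp,
        )
        for sample in cm.sample_ids:
            ua = cm.unassigned.loc[sample]
            logger.info(
                "counts: %s assigned=%d no_match=%d ambiguous=%d",
                sample, int(cm.counts[sample].sum()),
                int(ua["no_match"]), int(ua["ambiguous"]),
            )
    elif cfg.simulate is not None:
        sim = cfg.simulate.model_copy(update={"seed": cfg.seed})
        cm, truth = simulate.simulate_counts(lib, sim)
        truth.write(outdir / "truth.tsv", lib)
        if cfg.emit_fastq:
            fq = simulate.simulate_fastq(cm, lib, sim, outdir / "fastq")
            cm = quantify.count_reads(
                fq, lib,
                max_mismatch=cfg.count.max_mismatch,
                offset=cfg.count.offset,
            )
            logger.info("counts: re-derived from emitted FASTQ")
        logger.info("counts: simulated (%d SL genes)",
                    len(truth.sl_genes) if truth else 0)
    else:  # pragma: no cover - schema forbids this
        raise ValueError("no counts, fastq, or simulate input")
    quantify.write_counts(cm, outdir / "counts.tsv")
    return cm, truth


@_stage("hitcall")
def _call_hits(cfg: PipelineConfig, cm, lib, outdir: Path):
    design = hitcall.ScreenDesign(
        ko_samples=cfg.design.ko_samples,
        control_samples=cfg.design.control_samples,
    )
    hc = cfg.hitcall
    stats = hitcall.compute_ratios(
        cm, lib, design,
        pseudocount=hc.pseudocount,
        normalization=hc.normalization,
        min_count=hc.min_count,
    )
    stats = hitcall.flag_fivefold(stats, fold_threshold=hc.fold_threshold)
    stats = hitcall.compute_zscores(stats, include_controls=hc.include_controls)
    calls = hitcall.call_genes(
        stats, lib, min_depleted=hc.min_depleted, min_fivefold=hc.min_fivefold
    )
    summary = hitcall.report(stats, calls, outdir, threshold_z=hc.threshold_z)
    logger.info(
        "hitcall: %d/%d genes candidate; %d clones below z=%s; "
        "%d low-abundance clones excluded from standardization",
        summary["n_candidates"], summary["n_genes"],
        summary["n_clones_below_threshold_z"], hc.threshold_z,
        summary["n_low_abundance_clones"],
    )
    return stats, calls, summary


@_stage("enrich")
def _enrich(cfg: PipelineConfig, lib, calls, truth, outdir: Path):
    if cfg.paths.gmt:
        gsc = enr.read_gmt(cfg.paths.gmt)
    elif truth is not None:
        # Simulated run without a user GMT: draw gene sets over the simulated
        # universe (some loaded with the true SL genes) so the enrichment
        # stage exercises a real signal.
        gsc = enr.GeneSetCollection.from_dict(
            simulate.simulate_gene_sets(lib, truth, seed=cfg.seed),
            source="simulated",
        )
    else:
        logger.info("enrich: no GMT supplied; stage skipped")
        return None
    hits = calls.loc[calls["candidate"], "gene"].tolist()
    results = enr.enrich(hits, lib.genes, gsc, alpha=cfg.enrich.alpha)
    results.to_csv(outdir / "enrichment.tsv", sep="\t", index=False,
                   float_format="%.6g", lineterminator="\n")
    enr.export_network(results, outdir, edge_threshold=cfg.enrich.edge_threshold)
    logger.info(
        "enrich: %d sets tested, %d significant at p<%g",
        len(results), int(results["significant_p"].sum()) if len(results) else 0,
        cfg.enrich.alpha,
    )
    return results


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Run all configured stages; returns the summary record.

    On failure the partial outputs are retained alongside a marker file
    naming the failed stage, and the ``StageError`` propagates.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    log_handler = logging.FileHandler(outdir / "pipeline.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("slscreen")
    root.addHandler(log_handler)
    try:
        cfg.write_resolved(outdir / "resolved_config.yaml")
        lib = _load_library(cfg, outdir)
        cm, truth = _obtain_counts(cfg, lib, outdir)
        stats, calls, summary = _call_hits(cfg, cm, lib, outdir)
        _enrich(cfg, lib, calls, truth, outdir)
        marker = outdir / _FAIL_MARKER
        if marker.exists():
            marker.unlink()
        return summary
    except StageError as exc:
        (outdir / _FAIL_MARKER).write_text(f"{exc}\n")
        raise
    finally:
        root.removeHandler(log_handler)
        log_handler.close()


def load_summary(outdir: str | Path) -> dict:
    with open(Path(outdir) / "summary.json") as fh:
        return json.load(fh)
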