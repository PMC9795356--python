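"""End-to-end orchestration: filter → SNR → tracks → profiles/readthrough.

A :class:`RunConfig` names the inputs and parameters; :func:`run_pipeline`
executes a requested subset of stages in dependency order and writes a
machine-readable run report (input/output checksums, filter statistics,
event counts, package version). The report asserts the end-to-end
conservation law: retained reads == SNR events == SNR track mass.
Re-running with an identical config reproduces identical non-log outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

from . import __version__
from .annotation import parse_gene_models, read_chrom_sizes, select_representative
from .filtering import filter_alignments, read_sam
from .profiles import (
    METAGENE_SCHEME,
    TES_SCHEME,
    aggregate_matrix,
    compute_point_matrix,
    compute_scaled_matrix,
    density_scale,
    write_matrix_tsv,
)
from .readthrough import compare_groups, readthrough_ratio, results_table, usable_ratios
from .snr import extract_snr
from .tracks import (
    accumulate_read_track,
    accumulate_snr_track,
    unstranded,
    write_bedgraph,
    write_bigwig,
)

logger = logging.getLogger("elcap")

STAGES = ("filter", "snr", "tracks", "profiles", "readthrough")
_DEPS = {
    "filter": (),
    "snr": ("filter",),
    "tracks": ("snr",),
    "profiles": ("tracks",),
    "readthrough": ("tracks",),
}


@dataclass
class RunConfig:
    alignments: str
    chrom_sizes: str
    output_dir: str
    annotation: Optional[str] = None
    mode: str = "single"
    seed: int = 0
    downstream_bp: int = 50_000
    min_length: int = 0
    write_bigwig: bool = False

    def validate(self, stages: Sequence[str]) -> None:
        if self.mode not in {"single", "paired"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        for path in (self.alignments, self.chrom_sizes):
            if not os.path.exists(path):
                raise FileNotFoundError(path)
        needs_annotation = {"profiles", "readthrough"} & set(stages)
        if needs_annotation and (
            self.annotation is None or not os.path.exists(self.annotation)
        ):
            raise FileNotFoundError(
                f"stages {sorted(needs_annotation)} require an annotation file"
            )


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, stages: Sequence[str] = STAGES) -> dict:
    """Run the requested stages and return the run report (also written to disk).

    An empty stage list validates the configuration and returns without
    producing outputs. Stage dependencies are checked before any work starts.
    """
    stages = list(stages)
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}")
        missing = [d for d in _DEPS[s] if d not in stages]
        if missing:
            raise ValueError(f"stage {s!r} requires {missing} in the same run")
    config.validate(stages)
    if not stages:
        logger.info("validation-only run: configuration OK")
        return {"stages": [], "seed": config.seed, "version": __version__}

    os.makedirs(config.output_dir, exist_ok=True)
    genome = read_chrom_sizes(config.chrom_sizes)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "mode": config.mode,
        "stages": stages,
        "inputs": {
            "alignments": _sha256(config.alignments),
            "chrom_sizes": _sha256(config.chrom_sizes),
        },
        "outputs": {},
    }
    if config.annotation:
        report["inputs"]["annotation"] = _sha256(config.annotation)

    retained, stats = filter_alignments(
        read_sam(config.alignments), config.mode, config.min_length
    )
    report["filter_stats"] = stats.as_dict()
    logger.info("filter: %d/%d records retained", stats.retained, stats.input)

    outputs: dict[str, str] = {}

    def emit(name: str, path: str) -> None:
        outputs[name] = path

    stats_path = os.path.join(config.output_dir, "filter_stats.tsv")
    with open(stats_path, "w") as out:
        out.write("reason\tcount\n")
        for k, v in stats.as_dict().items():
            out.write(f"{k}\t{v}\n")
    emit("filter_stats", stats_path)

    events = None
    if "snr" in stages:
        events, n_events = extract_snr(retained, config.mode)
        report["snr_events"] = n_events
        n_units = stats.retained if config.mode == "single" else stats.retained // 2
        if n_events != n_units:
            raise AssertionError(
                f"conservation violated: {n_events} events from "
                f"{n_units} retained units"
            )

    if "tracks" in stages:
        plus, minus = accumulate_snr_track(events, genome)
        both = unstranded(plus, minus)
        report["snr_track_mass"] = plus.mass() + minus.mass()
        if report["snr_track_mass"] != report["snr_events"]:
            raise AssertionError("conservation violated: track mass != event count")
        rplus, rminus = accumulate_read_track(retained, genome, config.mode)
        for label, track in (
            ("snr_plus", plus), ("snr_minus", minus), ("snr_unstranded", both),
            ("read_plus", rplus), ("read_minus", rminus),
            ("read_unstranded", unstranded(rplus, rminus)),
        ):
            path = os.path.join(config.output_dir, f"{label}.bedgraph")
            write_bedgraph(track, path)
            emit(label, path)
            if config.write_bigwig:
                bw_path = os.path.join(config.output_dir, f"{label}.bw")
                write_bigwig(track, bw_path)
                emit(label + "_bw", bw_path)

    models = reps = None
    if config.annotation and ({"profiles", "readthrough"} & set(stages)):
        models = parse_gene_models(config.annotation, chromosomes=list(genome))
        reps = {g: select_representative(ts) for g, ts in models.items()}

    if "profiles" in stages:
        matrix = compute_scaled_matrix((plus, minus), list(reps.values()), METAGENE_SCHEME)
        mat_path = os.path.join(config.output_dir, "metagene_matrix.tsv")
        write_matrix_tsv(matrix, mat_path)
        emit("metagene_matrix", mat_path)
        profile = density_scale(aggregate_matrix(matrix), METAGENE_SCHEME)
        prof_path = os.path.join(config.output_dir, "metagene_profile.tsv")
        with open(prof_path, "w") as out:
            out.write("bin\tdensity\n")
            for i, v in enumerate(profile.bins):
                out.write(f"{i}\t{v:.10g}\n")
        emit("metagene_profile", prof_path)

    if "readthrough" in stages:
        bodies = {
            g: (reps[g].chrom, reps[g].start, reps[g].end) for g in reps
        }
        results = []
        for g, rep in reps.items():
            from .annotation import GenomicInterval

            others = [
                GenomicInterval(c, s, e)
                for og, (c, s, e) in bodies.items() if og != g
            ]
            results.append(
                readthrough_ratio(
                    (plus, minus), rep, config.downstream_bp, genome,
                    all_transcripts=models[g], other_gene_bodies=others,
                )
            )
        rt_path = os.path.join(config.output_dir, "readthrough.tsv")
        results_table(results).to_csv(rt_path, sep="\t", index=False)
        emit("readthrough", rt_path)
        report["readthrough_ok"] = int(sum(r.status == "ok" for r in results))
        report["readthrough_dropped"] = int(sum(r.status != "ok" for r in results))

    report["outputs"] = {name: _sha256(path) for name, path in outputs.items()}
    report["output_paths"] = outputs
    report_path = os.path.join(config.output_dir, "run_report.json")
    with open(report_path, "w") as out:
        json.dump(report, out, indent=2, sort_keys=True)
    return report
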