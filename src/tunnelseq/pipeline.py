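"""End-to-end pipeline: simulate → detect → call → map → quantify.

Configuration is a single validated JSON document (unknown keys are
rejected); every stage writes its outputs under the run directory and a
manifest records versions, the seed, a parameter hash and per-stage status
and counts, so a run is auditable and resumable: stages whose outputs are
already present and marked complete are skipped, and re-running a run
directory after deleting one stage's outputs recomputes only that stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import __version__
from .calibration import ConductanceTable, default_table, load_table
from .calling import BaseCaller
from .detection import EventDetector, LevelSegmenter
from .io import (
    read_levels,
    read_motifs,
    read_reads,
    read_trace,
    write_levels,
    write_mappings,
    write_reads,
    write_trace,
)
from .motifs import MotifSpec, map_read, p53_motif
from .quantify import (
    incorporation_rate,
    plot_profile,
    position_profile,
    tally_t_site_calls,
)
from .simulate import SimulationConfig, simulate_dataset

logger = logging.getLogger("tunnelseq")

STAGES = ("simulate", "detect", "call", "map", "quantify")


class SimulationBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    template_sequence: str = "AGACATGCCCAGACATGCCC"
    ftd_substitution_prob: float = Field(0.0, ge=0.0, le=1.0)
    n_events: int = Field(100, ge=0)
    sampling_rate_hz: float = Field(10_000.0, gt=0)
    baseline_pS: float = Field(5.0, ge=0)
    baseline_sd_pS: float = Field(2.0, ge=0)
    dwell_ms: tuple[str, dict] = ("lognormal", {"median_ms": 1.0, "sigma_log": 0.5})
    inter_event_gap_ms: tuple[str, dict] = ("lognormal", {"median_ms": 10.0, "sigma_log": 0.5})
    read_truncation: Optional[tuple[int, int]] = None
    noise_scale: float = Field(1.0, ge=0)

    def to_config(self, seed: int) -> SimulationConfig:
        return SimulationConfig(seed=seed, **self.model_dump())


class DetectionBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    k_sigma: float = 5.0
    min_event_samples: int = 10
    min_gap: int = 5
    penalty: float | Literal["bic"] = "bic"
    min_level_samples: int = 5
    log_transform: bool = True
    homopolymer_split_samples: Optional[int] = None


class CallingBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    no_call_threshold: float = Field(0.5, ge=0.0, le=1.0)
    phred_cap: float = 40.0
    use_empirical_prior: bool = False


class QuantificationBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    convention: Literal["exclusive", "inclusive"] = "exclusive"
    rel_g_bins: int = 50
    rel_g_max: float = 1.2
    min_score: int = 4
    max_mismatch_frac: float = 0.2
    heatmap: bool = True


class PipelineConfig(BaseModel):
    """Validated pipeline configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    calibration_path: Optional[str] = None
    motif_path: Optional[str] = None  # FASTA; default: built-in p53 target
    traces_path: Optional[str] = None  # pre-recorded trace TSV; else simulate
    label: str = "run"
    simulation: SimulationBlock = SimulationBlock()
    detection: DetectionBlock = DetectionBlock()
    calling: CallingBlock = CallingBlock()
    quantification: QuantificationBlock = QuantificationBlock()

    @field_validator("calibration_path", "motif_path", "traces_path")
    @classmethod
    def _exists(cls, v):
        if v is not None and not Path(v).exists():
            raise ValueError(f"path does not exist: {v}")
        return v

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.model_validate(json.load(fh))

    def param_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and an exit code."""

    EXIT_CODES = {name: i + 10 for i, name in enumerate(STAGES)}

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage
        self.exit_code = self.EXIT_CODES.get(stage, 1)


def _load_manifest(path: Path) -> dict:
    if path.exists():
        with open(path) as fh:
            return json.load(fh)
    return {"stages": {}}


def _save_manifest(manifest: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _table_for(config: PipelineConfig) -> ConductanceTable:
    if config.calibration_path:
        return load_table(config.calibration_path)
    return default_table()


def _motif_for(config: PipelineConfig) -> MotifSpec:
    if config.motif_path:
        return read_motifs(config.motif_path)[0]
    return p53_motif()


def run_pipeline(
    config: PipelineConfig, outdir, resume: bool = True, until: str | None = None
) -> dict:
    """Execute the pipeline into ``outdir``; returns the manifest.

    With ``resume``, stages whose outputs exist and are marked complete in
    the manifest are skipped (delete a stage's outputs to recompute it; the
    seed makes recomputation bit-identical). ``until`` stops after the named
    stage, enabling the stage-wise subcommands. Any stage failure raises
    :class:`StageError` after marking the stage incomplete in the manifest.
    """
    if until is not None and until not in STAGES:
        raise ValueError(f"unknown stage {until!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    manifest = _load_manifest(manifest_path)
    manifest.update(
        {
            "tunnelseq_version": __version__,
            "numpy_version": np.__version__,
            "seed": config.seed,
            "param_hash": config.param_hash(),
            "config": config.model_dump(mode="json"),
        }
    )

    table = _table_for(config)
    motif = _motif_for(config)

    paths = {
        "trace": outdir / "trace.tsv",
        "ground_truth": outdir / "ground_truth.json",
        "events": outdir / "events.tsv",
        "levels": outdir / "levels.tsv",
        "reads": outdir / "reads.fastq",
        "calls": outdir / "calls.tsv",
        "mappings": outdir / "mappings.tsv",
        "rates": outdir / "rates.tsv",
        "rates_json": outdir / "rates.json",
        "profile_matrix": outdir / "profile_matrix.tsv",
        "heatmap": outdir / "heatmap.png",
    }

    def stage_done(name: str, outputs: list[Path]) -> bool:
        info = manifest["stages"].get(name, {})
        return (
            resume
            and info.get("complete", False)
            and info.get("param_hash") == manifest["param_hash"]
            and all(p.exists() for p in outputs)
        )

    def run_stage(name: str, outputs: list[Path], fn) -> None:
        if stage_done(name, outputs):
            logger.info("stage %s: outputs present, skipping", name)
            return
        t0 = time.perf_counter()
        manifest["stages"][name] = {"complete": False, "param_hash": manifest["param_hash"]}
        _save_manifest(manifest, manifest_path)
        try:
            counts = fn() or {}
        except Exception as exc:
            _save_manifest(manifest, manifest_path)
            raise StageError(name, str(exc)) from exc
        manifest["stages"][name].update(
            {"complete": True, "seconds": round(time.perf_counter() - t0, 3), **counts}
        )
        _save_manifest(manifest, manifest_path)
        logger.info("stage %s: %s", name, counts)

    # -- simulate (or ingest) ---------------------------------------------
    def do_simulate():
        if config.traces_path:
            trace = read_trace(config.traces_path)
            write_trace(trace, paths["trace"])
            return {"n_samples": len(trace), "source": "ingested"}
        sim_cfg = config.simulation.to_config(seed=config.seed)
        trace, truth = simulate_dataset(sim_cfg, table=table)
        write_trace(trace, paths["trace"])
        truth.to_json(paths["ground_truth"])
        return {"n_samples": len(trace), "n_events_true": len(truth.events)}

    run_stage("simulate", [paths["trace"]], do_simulate)
    if until == "simulate":
        _save_manifest(manifest, manifest_path)
        return manifest

    # -- detect + segment --------------------------------------------------
    det = config.detection

    def do_detect():
        trace = read_trace(paths["trace"])
        detector = EventDetector(
            k_sigma=det.k_sigma,
            min_event_samples=det.min_event_samples,
            min_gap=det.min_gap,
        )
        events = detector.fit_predict(trace)
        segmenter = LevelSegmenter(
            penalty=det.penalty,
            min_level_samples=det.min_level_samples,
            log_transform=det.log_transform,
            homopolymer_split_samples=det.homopolymer_split_samples,
        )
        levels = segmenter.transform(trace, events)
        import pandas as pd

        pd.DataFrame(
            [
                {
                    "event_id": i,
                    "start_idx": ev.start_idx,
                    "end_idx": ev.end_idx,
                    "baseline_pS": ev.baseline_pS,
                }
                for i, ev in enumerate(events)
            ],
            columns=["event_id", "start_idx", "end_idx", "baseline_pS"],
        ).to_csv(paths["events"], sep="\t", index=False)
        write_levels(levels, paths["levels"])
        return {
            "n_events": len(events),
            "n_levels": sum(len(l) for l in levels),
            "baseline_pS": round(detector.baseline_pS_, 3),
        }

    run_stage("detect", [paths["events"], paths["levels"]], do_detect)
    if until == "detect":
        _save_manifest(manifest, manifest_path)
        return manifest

    # -- call ---------------------------------------------------------------
    def do_call():
        levels = read_levels(paths["levels"])
        caller = BaseCaller(
            table=table,
            no_call_threshold=config.calling.no_call_threshold,
            phred_cap=config.calling.phred_cap,
        ).fit()
        if config.calling.use_empirical_prior:
            from .calling import empirical_prior

            flat = [lv for evt in levels for lv in evt]
            caller = BaseCaller(
                table=table,
                prior=empirical_prior(flat, table),
                no_call_threshold=config.calling.no_call_threshold,
                phred_cap=config.calling.phred_cap,
            ).fit()
        reads = [caller.call(evt, source_event=i) for i, evt in enumerate(levels) if evt]
        write_reads(reads, paths["reads"], sidecar_path=paths["calls"])
        return {"n_reads": len(reads), "n_calls": sum(len(r) for r in reads)}

    run_stage("call", [paths["reads"], paths["calls"]], do_call)
    if until == "call":
        _save_manifest(manifest, manifest_path)
        return manifest

    # -- map ----------------------------------------------------------------
    def do_map():
        reads = read_reads(paths["reads"], sidecar_path=paths["calls"])
        q = config.quantification
        mapped = [
            map_read(r, motif, min_score=q.min_score, max_mismatch_frac=q.max_mismatch_frac)
            if len(r) <= len(motif)
            else None
            for r in reads
        ]
        write_mappings(mapped, paths["mappings"])
        return {"n_mapped": sum(m is not None for m in mapped), "n_reads": len(reads)}

    run_stage("map", [paths["mappings"]], do_map)
    if until == "map":
        _save_manifest(manifest, manifest_path)
        return manifest

    # -- quantify -----------------------------------------------------------
    def do_quantify():
        import pandas as pd

        reads = read_reads(paths["reads"], sidecar_path=paths["calls"])
        q = config.quantification
        mapped = [
            m
            for r in reads
            if len(r) <= len(motif)
            if (m := map_read(r, motif, min_score=q.min_score, max_mismatch_frac=q.max_mismatch_frac))
            is not None
        ]
        profile = position_profile(
            mapped, motif, bins=q.rel_g_bins, rel_g_range=(0.0, q.rel_g_max)
        )
        per_site, pooled = tally_t_site_calls(mapped, motif)
        n_f, n_t, n_other = pooled  # zero tallies yield an empty rate table
        rows = []
        result_json: dict = {"motif": motif.name, "label": config.label, "per_site": {}}
        for convention in ("exclusive", "inclusive"):
            if (n_f + n_t if convention == "exclusive" else n_f + n_t + n_other) > 0:
                res = incorporation_rate(n_f, n_t, n_other, convention=convention)
                rows.append(
                    {
                        "motif": motif.name,
                        "label": config.label,
                        "scope": "pooled",
                        "convention": convention,
                        "n_F": res.n_F,
                        "n_T": res.n_T,
                        "n_other": res.n_other,
                        "rate": res.rate,
                        "ci_low": res.ci_low,
                        "ci_high": res.ci_high,
                    }
                )
                result_json[f"rate_{convention}"] = res.rate
        for pos, (f, t, o) in per_site.items():
            result_json["per_site"][str(pos)] = {"n_F": f, "n_T": t, "n_other": o}
            if f + t > 0:
                res = incorporation_rate(f, t, o, convention=config.quantification.convention)
                rows.append(
                    {
                        "motif": motif.name,
                        "label": config.label,
                        "scope": f"site_{pos}",
                        "convention": res.convention,
                        "n_F": res.n_F,
                        "n_T": res.n_T,
                        "n_other": res.n_other,
                        "rate": res.rate,
                        "ci_low": res.ci_low,
                        "ci_high": res.ci_high,
                    }
                )
        pd.DataFrame(
            rows,
            columns=[
                "motif",
                "label",
                "scope",
                "convention",
                "n_F",
                "n_T",
                "n_other",
                "rate",
                "ci_low",
                "ci_high",
            ],
        ).to_csv(paths["rates"], sep="\t", index=False, float_format="%.10g")
        with open(paths["rates_json"], "w") as fh:
            json.dump(result_json, fh, indent=2, sort_keys=True)
        pd.DataFrame(profile.histogram).to_csv(paths["profile_matrix"], sep="\t", index=False)
        if q.heatmap:
            plot_profile(profile, paths["heatmap"])
        return {"n_mapped": len(mapped), "n_F": n_f, "n_T": n_t, "n_other": n_other}

    run_stage("quantify", [paths["rates"], paths["rates_json"]], do_quantify)

    manifest["complete"] = True
    _save_manifest(manifest, manifest_path)
    return manifest
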