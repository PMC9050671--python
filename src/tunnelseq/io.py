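"""Standard-format I/O: trace TSV, FASTQ reads, FASTA motifs, result tables.

Traces travel as two-column TSV (time_s, conductance_pS) with '#'-prefixed
``key=value`` metadata headers; round trips are lossless (samples are
written with shortest-exact float representation). Reads are FASTQ with
the extended alphabet (F for the thymidine analogue, N for no-calls) and
Phred+33 qualities, written/read through Biopython; a sidecar TSV carries
per-call rel G and posteriors.
"""

from __future__ import annotations

import ast
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .calibration import CALLABLE_CLASSES
from .calling import BaseCall, Read
from .detection import Level, TranslocationEvent
from .motifs import MappedRead, MotifSpec
from .simulate import Trace

__all__ = [
    "write_trace",
    "read_trace",
    "write_traces",
    "read_traces",
    "write_reads",
    "read_reads",
    "read_motifs",
    "write_motifs",
    "write_levels",
    "read_levels",
    "write_mappings",
]


# ---------------------------------------------------------------------------
# Traces
# ---------------------------------------------------------------------------

def write_trace(trace: Trace, path) -> None:
    """Write one trace as '#'-headered TSV (time_s, conductance_pS)."""
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate_hz={trace.sampling_rate_hz!r}\n")
        for key, value in trace.metadata.items():
            fh.write(f"# {key}={value!r}\n")
        fh.write("time_s\tconductance_pS\n")
        rate = float(trace.sampling_rate_hz)
        for i, v in enumerate(trace.samples):
            fh.write(f"{i / rate!r}\t{float(v)!r}\n")


def read_trace(path) -> Trace:
    """Read a single-trace TSV; raises naming the offending line on errors."""
    path = Path(path)
    metadata: dict = {}
    sampling_rate = None
    samples: list[float] = []
    with open(path) as fh:
        saw_header = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" not in body:
                    raise ValueError(f"{path.name}:{lineno}: malformed metadata line {line!r}")
                key, _, value = body.partition("=")
                key = key.strip()
                try:
                    parsed = ast.literal_eval(value.strip())
                except (ValueError, SyntaxError):
                    parsed = value.strip()
                if key == "sampling_rate_hz":
                    sampling_rate = float(parsed)
                else:
                    metadata[key] = parsed
                continue
            if not saw_header:
                cols = line.split("\t")
                if cols != ["time_s", "conductance_pS"]:
                    raise ValueError(
                        f"{path.name}:{lineno}: expected header 'time_s\\tconductance_pS', got {line!r}"
                    )
                saw_header = True
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path.name}:{lineno}: expected 2 columns, got {len(parts)}")
            try:
                samples.append(float(parts[1]))
            except ValueError as exc:
                raise ValueError(
                    f"{path.name}:{lineno}: non-numeric conductance {parts[1]!r}"
                ) from exc
    if sampling_rate is None:
        raise ValueError(f"{path.name}: missing '# sampling_rate_hz=' header")
    if not saw_header:
        raise ValueError(f"{path.name}: missing column header line")
    return Trace(samples=np.array(samples), sampling_rate_hz=sampling_rate, metadata=metadata)


def write_traces(traces: Sequence[Trace], directory, prefix: str = "trace") -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, trace in enumerate(traces):
        p = directory / f"{prefix}_{i:04d}.tsv"
        write_trace(trace, p)
        paths.append(p)
    return paths


def read_traces(path) -> list[Trace]:
    """Read a trace TSV file, or every ``*.tsv`` in a directory."""
    path = Path(path)
    if path.is_dir():
        return [read_trace(p) for p in sorted(path.glob("*.tsv"))]
    return [read_trace(path)]


# ---------------------------------------------------------------------------
# Reads (FASTQ + sidecar)
# ---------------------------------------------------------------------------

def write_reads(reads: Sequence[Read], path, sidecar_path=None) -> None:
    """Write reads as FASTQ (extended alphabet, Phred+33).

    ``sidecar_path`` optionally receives a TSV with per-call rel G and the
    full class posterior, which FASTQ cannot carry.
    """
    records = []
    for i, read in enumerate(reads):
        rec = SeqRecord(
            Seq(read.sequence),
            id=f"read_{i:05d}_ev{read.source_event}",
            description="",
        )
        rec.letter_annotations["phred_quality"] = [
            int(round(c.phred_q)) for c in read.calls
        ]
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")
    if sidecar_path is not None:
        rows = []
        for i, read in enumerate(reads):
            for j, call in enumerate(read.calls):
                row = {
                    "read_id": f"read_{i:05d}_ev{read.source_event}",
                    "pos": j,
                    "call": call.call,
                    "phred_q": call.phred_q,
                    "rel_G": call.rel_G,
                }
                for cls in CALLABLE_CLASSES:
                    row[f"p_{cls}"] = call.posterior.get(cls, float("nan"))
                rows.append(row)
        pd.DataFrame(rows).to_csv(sidecar_path, sep="\t", index=False)


def read_reads(path, sidecar_path=None) -> list[Read]:
    """Read FASTQ reads back; posteriors/rel G restored from the sidecar."""
    sidecar = None
    if sidecar_path is not None and Path(sidecar_path).exists():
        try:
            sidecar = pd.read_csv(sidecar_path, sep="\t").groupby("read_id")
        except pd.errors.EmptyDataError:
            sidecar = None
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = rec.letter_annotations["phred_quality"]
        seq = str(rec.seq)
        source_event = -1
        if "_ev" in rec.id:
            try:
                source_event = int(rec.id.rsplit("_ev", 1)[1])
            except ValueError:
                pass
        if sidecar is not None and rec.id in sidecar.groups:
            rows = sidecar.get_group(rec.id).sort_values("pos")
            calls = tuple(
                BaseCall(
                    call=row["call"],
                    posterior={c: row[f"p_{c}"] for c in CALLABLE_CLASSES},
                    phred_q=float(row["phred_q"]),
                    rel_G=float(row["rel_G"]),
                )
                for _, row in rows.iterrows()
            )
        else:
            calls = tuple(
                BaseCall(call=s, posterior={}, phred_q=float(q), rel_G=float("nan"))
                for s, q in zip(seq, quals)
            )
        reads.append(Read(calls=calls, source_event=source_event))
    return reads


# ---------------------------------------------------------------------------
# Motifs (FASTA, extended alphabet)
# ---------------------------------------------------------------------------

def read_motifs(path) -> list[MotifSpec]:
    """Read motifs from FASTA; a ``t_sites=6,16`` token in the description
    pins the analogue-susceptible thymines, otherwise every T is used."""
    motifs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        t_sites: tuple[int, ...] = ()
        for token in rec.description.split():
            if token.startswith("t_sites="):
                t_sites = tuple(int(x) for x in token.split("=", 1)[1].split(","))
        motifs.append(MotifSpec(name=rec.id, sequence=str(rec.seq).upper(), t_sites=t_sites))
    if not motifs:
        raise ValueError(f"no motif records found in {path}")
    return motifs


def write_motifs(motifs: Sequence[MotifSpec], path) -> None:
    records = []
    for m in motifs:
        desc = "t_sites=" + ",".join(str(p) for p in m.t_sites) if m.t_sites else ""
        records.append(SeqRecord(Seq(m.sequence), id=m.name, description=desc))
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Levels / events / mappings tables
# ---------------------------------------------------------------------------

def write_levels(levels_per_event: Sequence[Sequence[Level]], path) -> None:
    rows = []
    for event_id, levels in enumerate(levels_per_event):
        for idx, lv in enumerate(levels):
            rows.append(
                {
                    "event_id": event_id,
                    "level_idx": idx,
                    "start_idx": lv.start_idx,
                    "end_idx": lv.end_idx,
                    "mean_pS": lv.mean_pS,
                    "sd_pS": lv.sd_pS,
                    "n_samples": lv.n_samples,
                }
            )
    pd.DataFrame(
        rows,
        columns=[
            "event_id",
            "level_idx",
            "start_idx",
            "end_idx",
            "mean_pS",
            "sd_pS",
            "n_samples",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_levels(path) -> list[list[Level]]:
    df = pd.read_csv(path, sep="\t")
    out: list[list[Level]] = []
    if df.empty:
        return out
    for event_id, group in df.groupby("event_id", sort=True):
        levels = [
            Level(
                start_idx=int(r.start_idx),
                end_idx=int(r.end_idx),
                mean_pS=float(r.mean_pS),
                sd_pS=float(r.sd_pS),
            )
            for r in group.sort_values("level_idx").itertuples()
        ]
        out.append(levels)
    return out


def write_mappings(mapped: Sequence[MappedRead | None], path) -> None:
    rows = []
    for i, mr in enumerate(mapped):
        if mr is None:
            rows.append(
                {
                    "read_id": i,
                    "mapped": 0,
                    "offset_1based": -1,
                    "matches": 0,
                    "mismatches": 0,
                    "n_calls": 0,
                }
            )
        else:
            rows.append(
                {
                    "read_id": i,
                    "mapped": 1,
                    "offset_1based": mr.offset_1based,
                    "matches": mr.matches,
                    "mismatches": mr.mismatches,
                    "n_calls": mr.n_calls,
                }
            )
    pd.DataFrame(
        rows,
        columns=["read_id", "mapped", "offset_1based", "matches", "mismatches", "n_calls"],
    ).to_csv(path, sep="\t", index=False)
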