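"""Synthetic conductance–time traces with ground-truth annotations.

Emulates oligonucleotide translocation through a nanogap tunneling sensor:
a low-conductance baseline interrupted by discrete translocation events,
each event a succession of per-base constant-conductance plateaus whose
sample values are drawn around the calibrated nominal for the base class.
Thymine positions of the template may be substituted by trifluridine (F)
with a configurable probability, emulating analogue incorporation.

The defaults encode the study conditions: 10 kHz sampling, a 20-mer
target template, partial reads (contiguous sub-strings of the template),
log-normal dwell times (median 1 ms), and a baseline far below the least
conductive base class so event detection is well-posed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
import numpy as np

from .calibration import CALLABLE_CLASSES, ConductanceTable, default_table

__all__ = [
    "SimulationConfig",
    "LevelTruth",
    "EventTruth",
    "GroundTruth",
    "Trace",
    "substitute_ftd",
    "simulate_event",
    "simulate_dataset",
]

#: 20-mer target for the p53 binding region (thymines at 1-based 6 and 16).
P53_TARGET = "AGACATGCCCAGACATGCCC"

_TEMPLATE_ALPHABET = set("GACT")
_REALIZED_ALPHABET = set("GACTF")

#: Minimum number of samples a plateau must span to be resolvable.
MIN_LEVEL_SAMPLES = 5
_MAX_DWELL_RETRIES = 100


@dataclass
class Trace:
    """A sampled conductance–time signal.

    ``samples`` are conductances in pS at a fixed ``sampling_rate_hz``;
    ``metadata`` carries free-form acquisition context (bias voltage, label).
    """

    samples: np.ndarray
    sampling_rate_hz: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("trace must be a non-empty 1-D sample array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate_hz

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class LevelTruth:
    """True plateau: [start, end) sample indices (trace coords) and class."""

    start_idx: int
    end_idx: int
    base: str


@dataclass(frozen=True)
class EventTruth:
    """One simulated translocation: realized bases, window, level bounds."""

    sequence: str  # realized bases, F where substituted
    start_idx: int
    end_idx: int
    levels: tuple[LevelTruth, ...]
    template_offset: int  # 0-based start of the read on the template


@dataclass
class GroundTruth:
    template_sequence: str
    events: list[EventTruth]

    def n_levels(self) -> int:
        return sum(len(ev.levels) for ev in self.events)

    def realized_t_site_fraction(self) -> tuple[int, int]:
        """(n_F, n_T_sites) over emitted template-thymine sites."""
        n_f = n_sites = 0
        for ev in self.events:
            for pos, base in enumerate(ev.sequence):
                if self.template_sequence[ev.template_offset + pos] == "T":
                    n_sites += 1
                    n_f += base == "F"
        return n_f, n_sites

    def to_json(self, path) -> None:
        payload = {
            "template_sequence": self.template_sequence,
            "events": [
                {
                    "sequence": ev.sequence,
                    "start_idx": ev.start_idx,
                    "end_idx": ev.end_idx,
                    "template_offset": ev.template_offset,
                    "levels": [[lv.start_idx, lv.end_idx, lv.base] for lv in ev.levels],
                }
                for ev in self.events
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        events = [
            EventTruth(
                sequence=ev["sequence"],
                start_idx=ev["start_idx"],
                end_idx=ev["end_idx"],
                template_offset=ev["template_offset"],
                levels=tuple(LevelTruth(*lv) for lv in ev["levels"]),
            )
            for ev in payload["events"]
        ]
        return cls(template_sequence=payload["template_sequence"], events=events)


@dataclass
class SimulationConfig:
    """Study conditions for a simulated dataset.

    ``dwell_ms`` / ``inter_event_gap_ms`` are ``(distribution, params)``
    pairs; supported distributions are ``constant`` ({value_ms}),
    ``lognormal`` ({median_ms, sigma_log}) and ``exponential`` ({mean_ms}).
    ``read_truncation`` bounds the length of the contiguous template
    sub-string each event emits. ``noise_scale`` multiplies every noise sd
    (0 gives noiseless step traces for diagnostics).
    """

    template_sequence: str = P53_TARGET
    ftd_substitution_prob: float = 0.0
    n_events: int = 100
    sampling_rate_hz: float = 10_000.0
    baseline_pS: float = 5.0
    baseline_sd_pS: float = 2.0
    dwell_ms: tuple[str, dict] = ("lognormal", {"median_ms": 1.0, "sigma_log": 0.5})
    inter_event_gap_ms: tuple[str, dict] = ("lognormal", {"median_ms": 10.0, "sigma_log": 0.5})
    read_truncation: tuple[int, int] | None = None  # (min_len, max_len); None = full length
    noise_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.template_sequence:
            raise ValueError("template_sequence must be non-empty")
        bad = set(self.template_sequence) - _TEMPLATE_ALPHABET
        if bad:
            raise ValueError(f"template contains invalid symbols: {sorted(bad)}")
        if not 0.0 <= self.ftd_substitution_prob <= 1.0:
            raise ValueError("ftd_substitution_prob must be in [0, 1]")
        if self.n_events < 0:
            raise ValueError("n_events must be >= 0")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.baseline_pS < 0 or self.baseline_sd_pS < 0 or self.noise_scale < 0:
            raise ValueError("baseline and noise parameters must be >= 0")
        if self.read_truncation is not None:
            lo, hi = self.read_truncation
            if lo < 3:
                raise ValueError("read_truncation min length must be >= 3")
            if hi > len(self.template_sequence):
                raise ValueError("read_truncation max length exceeds template length")
            if lo > hi:
                raise ValueError("read_truncation bounds are infeasible (min > max)")
        for name, (dist, params) in (
            ("dwell_ms", self.dwell_ms),
            ("inter_event_gap_ms", self.inter_event_gap_ms),
        ):
            if dist not in ("constant", "lognormal", "exponential"):
                raise ValueError(f"{name}: unknown distribution {dist!r}")
            _typical_ms(dist, params)  # raises on malformed params

    @property
    def read_bounds(self) -> tuple[int, int]:
        if self.read_truncation is None:
            n = len(self.template_sequence)
            return (n, n)
        return self.read_truncation


def _typical_ms(dist: str, params: dict) -> float:
    if dist == "constant":
        return float(params["value_ms"])
    if dist == "lognormal":
        float(params["sigma_log"])
        return float(params["median_ms"])
    if dist == "exponential":
        return float(params["mean_ms"])
    raise ValueError(f"unknown distribution {dist!r}")


def _draw_ms(dist: str, params: dict, rng: np.random.Generator) -> float:
    if dist == "constant":
        return float(params["value_ms"])
    if dist == "lognormal":
        return float(
            np.exp(rng.normal(np.log(params["median_ms"]), params["sigma_log"]))
        )
    if dist == "exponential":
        return float(rng.exponential(params["mean_ms"]))
    raise ValueError(f"unknown distribution {dist!r}")


def substitute_ftd(sequence: str, p: float, rng: np.random.Generator) -> str:
    """Independently replace each T by F with probability ``p``.

    Non-T positions are never touched. Draws consume ``rng`` reproducibly:
    one uniform draw per T site, none for other positions.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    bad = set(sequence) - _TEMPLATE_ALPHABET
    if bad:
        raise ValueError(f"sequence contains invalid symbols: {sorted(bad)}")
    if not 0.0 <= p <= 1.0:
        raise ValueError("substitution probability must be in [0, 1]")
    out = []
    for base in sequence:
        if base == "T" and rng.uniform() < p:
            out.append("F")
        else:
            out.append(base)
    return "".join(out)


def simulate_event(
    realized_sequence: str,
    table: ConductanceTable,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[tuple[int, int, str]]]:
    """Simulate one translocation: one plateau per base.

    Plateau durations are drawn from the dwell distribution (redrawn, up to
    a bounded number of retries, if shorter than ``MIN_LEVEL_SAMPLES``);
    samples are i.i.d. Normal(nominal, noise_scale * noise_sd) truncated at 0.

    Returns the event samples and ``(start, end, base)`` level annotations
    in event-local coordinates.
    """
    bad = set(realized_sequence) - _REALIZED_ALPHABET
    if bad:
        raise ValueError(f"realized sequence contains invalid symbols: {sorted(bad)}")
    dist, params = cfg.dwell_ms
    chunks: list[np.ndarray] = []
    annotations: list[tuple[int, int, str]] = []
    cursor = 0
    for base in realized_sequence:
        n = 0
        for _ in range(_MAX_DWELL_RETRIES):
            dwell = _draw_ms(dist, params, rng)
            n = int(round(dwell * 1e-3 * cfg.sampling_rate_hz))
            if n >= MIN_LEVEL_SAMPLES:
                break
        else:
            raise RuntimeError(
                f"dwell distribution produced < {MIN_LEVEL_SAMPLES} samples "
                f"in {_MAX_DWELL_RETRIES} retries; raise the dwell scale or sampling rate"
            )
        sd = cfg.noise_scale * table.noise_sd(base)
        values = rng.normal(table.nominal(base), sd, size=n) if sd > 0 else np.full(
            n, table.nominal(base)
        )
        np.maximum(values, 0.0, out=values)
        chunks.append(values)
        annotations.append((cursor, cursor + n, base))
        cursor += n
    return np.concatenate(chunks), annotations


def _baseline_chunk(n: int, cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    sd = cfg.noise_scale * cfg.baseline_sd_pS
    values = rng.normal(cfg.baseline_pS, sd, size=n) if sd > 0 else np.full(
        n, float(cfg.baseline_pS)
    )
    np.maximum(values, 0.0, out=values)
    return values


def simulate_dataset(
    cfg: SimulationConfig,
    table: ConductanceTable | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[Trace, GroundTruth]:
    """Simulate a full trace: ``n_events`` partial reads separated by baseline.

    Each event takes a fresh FTD-substituted copy of the template, then emits
    a uniformly chosen contiguous sub-string respecting ``read_truncation``.
    Fully reproducible from ``cfg.seed`` (or an explicitly supplied generator).
    """
    cfg.validate()
    if table is None:
        table = default_table()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    gap_dist, gap_params = cfg.inter_event_gap_ms
    lo, hi = cfg.read_bounds
    template = cfg.template_sequence

    chunks: list[np.ndarray] = []
    events: list[EventTruth] = []
    cursor = 0

    def emit_gap() -> None:
        nonlocal cursor
        gap_ms = max(_draw_ms(gap_dist, gap_params, rng), 0.0)
        n = max(int(round(gap_ms * 1e-3 * cfg.sampling_rate_hz)), 1)
        chunks.append(_baseline_chunk(n, cfg, rng))
        cursor += n

    emit_gap()
    for _ in range(cfg.n_events):
        realized_template = substitute_ftd(template, cfg.ftd_substitution_prob, rng)
        length = int(rng.integers(lo, hi + 1))
        offset = int(rng.integers(0, len(template) - length + 1))
        read = realized_template[offset : offset + length]
        samples, annotations = simulate_event(read, table, cfg, rng)
        start = cursor
        levels = tuple(
            LevelTruth(start + s, start + e, b) for (s, e, b) in annotations
        )
        chunks.append(samples)
        cursor += samples.size
        events.append(
            EventTruth(
                sequence=read,
                start_idx=start,
                end_idx=cursor,
                levels=levels,
                template_offset=offset,
            )
        )
        emit_gap()

    trace = Trace(
        samples=np.concatenate(chunks),
        sampling_rate_hz=cfg.sampling_rate_hz,
        metadata={"label": "simulated", "bias_V": 0.1, "seed": cfg.seed},
    )
    return trace, GroundTruth(template_sequence=template, events=events)
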