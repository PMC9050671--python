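"""Per-nucleotide conductance calibration and relative-conductance normalization.

Each base class (the four canonical deoxyribonucleosides plus the thymidine
analogue trifluridine, FTD) carries a nominal single-molecule tunneling
conductance in picosiemens and a noise width. Conductances are empirical
calibration constants measured at the peak of single-molecule conductance
histograms; no physical tunneling model (bias voltage, gap distance) is
implied. All downstream normalization ("relative G") divides by the
guanosine nominal, the most conductive class.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

__all__ = [
    "CALLABLE_CLASSES",
    "NO_CALL",
    "DEFAULT_NOMINAL_PS",
    "DEFAULT_NOISE_FRACTION",
    "ConductanceTable",
    "default_table",
    "load_table",
    "relative_conductance",
    "round_half_up",
]

#: The five callable base classes, ordered by descending nominal conductance.
#: F denotes trifluridine (FTD); N is an ambiguous/no-call symbol that is
#: never simulated, only emitted by the base-caller.
CALLABLE_CLASSES: tuple[str, ...] = ("G", "A", "C", "T", "F")
NO_CALL = "N"

#: Nominal single-molecule conductances (pS) per class.
DEFAULT_NOMINAL_PS: dict[str, float] = {
    "G": 86.7,
    "A": 66.8,
    "C": 59.5,
    "T": 39.1,
    "F": 17.9,
}

#: Default noise width as a fraction of the nominal conductance. The
#: calibration source gives peak positions but no widths; 10% of nominal
#: yields mildly overlapping class distributions (T and F separated by
#: roughly three combined standard deviations), so calling is non-trivial
#: but accurate.
DEFAULT_NOISE_FRACTION = 0.10


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (display convention for relative G)."""
    factor = 10.0**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class ConductanceTable:
    """Calibration table: nominal conductance and noise width per base class.

    Parameters
    ----------
    entries
        Map from each callable class to ``(nominal_pS, noise_sd_pS)``.
    reference_base
        The class used for relative-conductance normalization; must carry
        the maximal nominal conductance (guanosine by default).
    """

    entries: Mapping[str, tuple[float, float]]
    reference_base: str = "G"

    def __post_init__(self) -> None:
        missing = [c for c in CALLABLE_CLASSES if c not in self.entries]
        if missing:
            raise ValueError(f"calibration table missing classes: {missing}")
        extra = [c for c in self.entries if c not in CALLABLE_CLASSES]
        if extra:
            raise ValueError(f"calibration table has unknown classes: {extra}")
        for cls, (nominal, sd) in self.entries.items():
            if not (math.isfinite(nominal) and math.isfinite(sd)):
                raise ValueError(f"non-finite calibration entry for {cls!r}")
            if nominal <= 0:
                raise ValueError(f"nominal conductance for {cls!r} must be > 0, got {nominal}")
            if sd <= 0:
                raise ValueError(f"noise sd for {cls!r} must be > 0, got {sd}")
        if self.reference_base not in self.entries:
            raise ValueError(f"reference base {self.reference_base!r} not in table")
        ref_nominal = self.entries[self.reference_base][0]
        top = max(v[0] for v in self.entries.values())
        if ref_nominal < top:
            raise ValueError(
                f"reference base {self.reference_base!r} ({ref_nominal} pS) does not "
                f"carry the maximal nominal conductance ({top} pS)"
            )

    # -- accessors ---------------------------------------------------------
    def nominal(self, cls: str) -> float:
        return self.entries[cls][0]

    def noise_sd(self, cls: str) -> float:
        return self.entries[cls][1]

    @property
    def classes(self) -> tuple[str, ...]:
        """Callable classes ordered by descending nominal conductance."""
        return tuple(sorted(self.entries, key=self.nominal, reverse=True))

    @property
    def reference_nominal(self) -> float:
        return self.nominal(self.reference_base)

    def relative(self, cls: str) -> float:
        """Relative conductance (rel G) of a class's nominal value."""
        return self.nominal(cls) / self.reference_nominal

    def to_dict(self) -> dict:
        return {
            "reference_base": self.reference_base,
            "classes": {
                c: {"nominal_pS": n, "noise_sd_pS": s} for c, (n, s) in self.entries.items()
            },
        }


def default_table(noise_fraction: float = DEFAULT_NOISE_FRACTION) -> ConductanceTable:
    """The packaged calibration (guanosine 86.7 pS down to FTD 17.9 pS)."""
    entries = {c: (n, noise_fraction * n) for c, n in DEFAULT_NOMINAL_PS.items()}
    return ConductanceTable(entries=entries)


def relative_conductance(table: ConductanceTable, g_pS: float) -> float:
    """Normalize a conductance (pS) by the reference-base nominal.

    Strictly monotone in ``g_pS`` for a fixed table; 0 maps to 0.

    Raises
    ------
    ValueError
        If ``g_pS`` is negative or not finite.
    """
    g_pS = float(g_pS)
    if not math.isfinite(g_pS):
        raise ValueError(f"conductance must be finite, got {g_pS}")
    if g_pS < 0:
        raise ValueError(f"conductance must be >= 0, got {g_pS}")
    return g_pS / table.reference_nominal


def load_table(config_path: str | Path) -> ConductanceTable:
    """Load a calibration table from a JSON config.

    Schema: ``{"reference_base": "G", "classes": {"G": {"nominal_pS": 86.7,
    "noise_sd_pS": 8.67}, ...}}``. A class entry may omit ``noise_sd_pS``,
    in which case it defaults to ``DEFAULT_NOISE_FRACTION`` times nominal.

    Raises
    ------
    ValueError
        Naming the offending entry for a missing class or a non-numeric or
        non-positive value.
    """
    path = Path(config_path)
    with open(path) as fh:
        raw = json.load(fh)
    classes = raw.get("classes", raw)  # tolerate a bare class map
    entries: dict[str, tuple[float, float]] = {}
    for cls in CALLABLE_CLASSES:
        if cls not in classes:
            raise ValueError(f"calibration config {path.name}: missing class {cls!r}")
        entry = classes[cls]
        try:
            nominal = float(entry["nominal_pS"])
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(
                f"calibration config {path.name}: bad nominal_pS for class {cls!r}"
            ) from exc
        if "noise_sd_pS" in entry:
            try:
                sd = float(entry["noise_sd_pS"])
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"calibration config {path.name}: bad noise_sd_pS for class {cls!r}"
                ) from exc
        else:
            sd = DEFAULT_NOISE_FRACTION * nominal
        if not math.isfinite(nominal) or nominal <= 0:
            raise ValueError(
                f"calibration config {path.name}: nominal_pS for {cls!r} must be > 0"
            )
        if not math.isfinite(sd) or sd <= 0:
            raise ValueError(
                f"calibration config {path.name}: noise_sd_pS for {cls!r} must be > 0"
            )
        entries[cls] = (nominal, sd)
    return ConductanceTable(entries=entries, reference_base=raw.get("reference_base", "G"))
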