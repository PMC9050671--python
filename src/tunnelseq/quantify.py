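"""Position-wise conductance profiles and analogue-incorporation statistics.

Downstream of mapping, three quantities summarize a dataset:

* a position profile — the distribution of relative conductance (rel G,
  level conductance normalized by the guanosine nominal) at each motif
  position, rendered as a position x rel-G histogram (heat map);
* the incorporation rate at motif thymine sites, under a *named*
  denominator convention: ``exclusive`` = n_F / (n_F + n_T), counting only
  confident T/F calls, or ``inclusive`` = n_F / n_total over every call
  tallied at the sites. Both appear in the literature for this assay and
  differ whenever other/no-call signals land on a thymine site, so every
  result names its convention. A 95% Wilson score interval accompanies the
  rate;
* a 2x2 enrichment comparison of F counts between two groups (e.g.
  antibody-bound vs supernatant DNA), with a sample odds ratio and a
  two-sided Fisher exact p-value (hypergeometric two-tail by probability
  ordering).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .motifs import MappedRead, MotifSpec

__all__ = [
    "PositionProfile",
    "IncorporationResult",
    "EnrichmentResult",
    "position_profile",
    "tally_t_site_calls",
    "incorporation_rate",
    "compare_fractions",
    "exposure_trend",
]

DEFAULT_REL_G_BINS = 50
DEFAULT_REL_G_RANGE = (0.0, 1.2)


@dataclass
class PositionProfile:
    """Per-position rel-G observations plus a display histogram.

    ``histogram[i, j]`` counts observations at motif position i+1 falling
    in rel-G bin j; row sums equal per-position observation counts. The
    histogram is for rendering only and never feeds statistics.
    """

    motif_name: str
    motif_length: int
    values: dict[int, list[float]]  # 1-based position -> rel_G observations
    bin_edges: np.ndarray
    histogram: np.ndarray

    @property
    def n_observations(self) -> int:
        return sum(len(v) for v in self.values.values())


def position_profile(
    mapped_reads: Iterable[MappedRead],
    motif: MotifSpec,
    bins: int = DEFAULT_REL_G_BINS,
    rel_g_range: tuple[float, float] = DEFAULT_REL_G_RANGE,
) -> PositionProfile:
    """Accumulate each call's rel G at its motif position.

    An empty input yields a valid empty profile. Values outside the
    histogram range are kept in ``values`` but clipped into the edge bins
    for display.
    """
    values: dict[int, list[float]] = {p: [] for p in range(1, len(motif) + 1)}
    for mr in mapped_reads:
        if mr.motif.name != motif.name:
            raise ValueError(
                f"read mapped to {mr.motif.name!r}, profile is for {motif.name!r}"
            )
        for pos, call in mr.positions():
            if np.isfinite(call.rel_G):
                if call.rel_G < 0:
                    raise ValueError("rel_G must be >= 0")
                values[pos].append(float(call.rel_G))
    edges = np.linspace(*rel_g_range, bins + 1)
    hist = np.zeros((len(motif), bins), dtype=np.int64)
    for pos, obs in values.items():
        if obs:
            clipped = np.clip(obs, rel_g_range[0], np.nextafter(rel_g_range[1], 0))
            hist[pos - 1], _ = np.histogram(clipped, bins=edges)
    return PositionProfile(
        motif_name=motif.name,
        motif_length=len(motif),
        values=values,
        bin_edges=edges,
        histogram=hist,
    )


def tally_t_site_calls(
    mapped_reads: Iterable[MappedRead], motif: MotifSpec
) -> tuple[dict[int, tuple[int, int, int]], tuple[int, int, int]]:
    """Count (n_F, n_T, n_other) calls covering each motif thymine site.

    Returns per-site counts keyed by 1-based position and the pooled
    totals. "Other" pools every non-T, non-F call including N.
    """
    per_site = {pos: [0, 0, 0] for pos in motif.t_sites}
    for mr in mapped_reads:
        for pos, call in mr.positions():
            if pos in per_site:
                if call.call == "F":
                    per_site[pos][0] += 1
                elif call.call == "T":
                    per_site[pos][1] += 1
                else:
                    per_site[pos][2] += 1
    pooled = tuple(int(sum(per_site[p][k] for p in per_site)) for k in range(3))
    return {p: tuple(v) for p, v in per_site.items()}, pooled  # type: ignore[return-value]


@dataclass(frozen=True)
class IncorporationResult:
    """Analogue incorporation rate at thymine sites, with Wilson 95% CI."""

    n_F: int
    n_T: int
    n_other: int
    convention: str  # "exclusive" or "inclusive"
    rate: float
    ci_low: float
    ci_high: float

    @property
    def denominator(self) -> int:
        if self.convention == "exclusive":
            return self.n_F + self.n_T
        return self.n_F + self.n_T + self.n_other

    @property
    def percent(self) -> float:
        return 100.0 * self.rate


def incorporation_rate(
    n_F: int,
    n_T: int,
    n_other_at_T_sites: int = 0,
    convention: str = "exclusive",
) -> IncorporationResult:
    """Incorporation rate under a named denominator convention.

    ``exclusive``: rate = n_F / (n_F + n_T) — the written definition, over
    confident T/F signals only. ``inclusive``: rate = n_F / n_total with
    n_total = n_F + n_T + n_other. The Wilson 95% interval uses the same
    denominator. The exclusive rate is never smaller than the inclusive one.
    """
    if min(n_F, n_T, n_other_at_T_sites) < 0:
        raise ValueError("counts must be non-negative")
    if convention not in ("exclusive", "inclusive"):
        raise ValueError(f"unknown convention {convention!r}")
    denom = n_F + n_T if convention == "exclusive" else n_F + n_T + n_other_at_T_sites
    if denom <= 0:
        raise ValueError("denominator is zero; no tallied calls")
    rate = n_F / denom
    lo, hi = proportion_confint(n_F, denom, alpha=0.05, method="wilson")
    # guard float round-off at the boundaries so the interval always
    # contains the point estimate and stays inside [0, 1]
    lo = min(max(float(lo), 0.0), rate)
    hi = max(min(float(hi), 1.0), rate)
    return IncorporationResult(
        n_F=int(n_F),
        n_T=int(n_T),
        n_other=int(n_other_at_T_sites),
        convention=convention,
        rate=rate,
        ci_low=float(lo),
        ci_high=float(hi),
    )


@dataclass(frozen=True)
class EnrichmentResult:
    """2x2 comparison of F counts between two groups."""

    table: tuple[tuple[int, int], tuple[int, int]]  # rows: groups; cols: (F, not-F)
    odds_ratio: float
    p_two_sided: float


def compare_fractions(
    n_F_a: int, n_notF_a: int, n_F_b: int, n_notF_b: int
) -> EnrichmentResult:
    """Fisher exact comparison of F fractions between groups a and b.

    The two-sided p sums hypergeometric probabilities of tables (at fixed
    margins) no more probable than the observed one. The odds ratio is the
    sample estimate (a*d)/(b*c), with a 0.5 continuity correction applied
    to every cell for the point estimate only when any cell is zero. A
    degenerate column margin (no F at all, or no not-F at all) carries no
    contrast: p = 1 with a warning.
    """
    cells = (n_F_a, n_notF_a, n_F_b, n_notF_b)
    if min(cells) < 0:
        raise ValueError("counts must be non-negative")
    if n_F_a + n_notF_a == 0 or n_F_b + n_notF_b == 0:
        raise ValueError("both group totals must be positive")
    a, b, c, d = cells
    if a + c == 0 or b + d == 0:
        warnings.warn("degenerate column margin; comparison carries no information")
        p = 1.0
    else:
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(cells) == 0:
        a_, b_, c_, d_ = (x + 0.5 for x in cells)
    else:
        a_, b_, c_, d_ = (float(x) for x in cells)
    return EnrichmentResult(
        table=((a, b), (c, d)),
        odds_ratio=(a_ * d_) / (b_ * c_),
        p_two_sided=float(p),
    )


def exposure_trend(
    results: Mapping[str, IncorporationResult] | Iterable[tuple[str, IncorporationResult]],
    order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Tabulate incorporation rates by exposure condition, in a given order.

    No fitting is performed; the table simply orders conditions (e.g.
    P, F1, F5) and flags whether the rate is strictly monotone increasing
    (``df.attrs['monotone_increasing']``).
    """
    pairs = list(results.items()) if isinstance(results, Mapping) else list(results)
    labels = [lab for lab, _ in pairs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate condition labels")
    if order is not None:
        missing = set(order) - set(labels)
        if missing:
            raise ValueError(f"order references unknown labels: {sorted(missing)}")
        pairs = sorted(pairs, key=lambda kv: order.index(kv[0]))
    df = pd.DataFrame(
        {
            "condition": [lab for lab, _ in pairs],
            "n_F": [r.n_F for _, r in pairs],
            "n_T": [r.n_T for _, r in pairs],
            "n_other": [r.n_other for _, r in pairs],
            "convention": [r.convention for _, r in pairs],
            "rate": [r.rate for _, r in pairs],
            "ci_low": [r.ci_low for _, r in pairs],
            "ci_high": [r.ci_high for _, r in pairs],
        }
    )
    rates = df["rate"].to_numpy()
    df.attrs["monotone_increasing"] = bool(np.all(np.diff(rates) > 0)) if len(rates) > 1 else True
    return df


def plot_profile(profile: PositionProfile, path) -> None:
    """Render a position x rel-G heat map to ``path`` (PNG/SVG)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    extent = (
        0.5,
        profile.motif_length + 0.5,
        float(profile.bin_edges[0]),
        float(profile.bin_edges[-1]),
    )
    ax.imshow(
        profile.histogram.T,
        origin="lower",
        aspect="auto",
        extent=extent,
        cmap="viridis",
    )
    ax.set_xlabel("base position")
    ax.set_ylabel("relative conductance (G = 1)")
    ax.set_title(f"{profile.motif_name}: {profile.n_observations} calls")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
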