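"""Five-class Phred-style base-calling from conductance levels.

Each plateau is attributed to one of five classes (G, A, C, T, F — the
latter the thymidine analogue trifluridine) by a Gaussian measurement
model: the plateau's sample mean is Normal(nominal, noise_sd / sqrt(n))
under each class hypothesis, and the posterior is the prior-weighted,
normalized set of class densities. Calls whose maximum posterior does not
exceed the no-call threshold are emitted as N. Quality is Phred-encoded:
Q = -10 log10(1 - max posterior), capped.

This probabilistic definition is this package's own; levels are treated as
conditionally independent given their class (single-nucleotide resolution,
no k-mer context).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .calibration import CALLABLE_CLASSES, NO_CALL, ConductanceTable, default_table
from .detection import Level

__all__ = ["BaseCall", "Read", "BaseCaller", "call_level", "call_read", "empirical_prior"]

DEFAULT_NO_CALL_THRESHOLD = 0.5
DEFAULT_PHRED_CAP = 40.0


@dataclass(frozen=True)
class BaseCall:
    """One called base: symbol, class posterior, Phred quality, relative G."""

    call: str
    posterior: Mapping[str, float]
    phred_q: float
    rel_G: float


@dataclass(frozen=True)
class Read:
    """Ordered base calls from one translocation event."""

    calls: tuple[BaseCall, ...]
    source_event: int = -1

    def __post_init__(self) -> None:
        if len(self.calls) < 1:
            raise ValueError("a read must contain at least one call")

    @property
    def sequence(self) -> str:
        return "".join(c.call for c in self.calls)

    def __len__(self) -> int:
        return len(self.calls)


class BaseCaller(BaseEstimator):
    """Gaussian five-class caller over level means.

    Parameters
    ----------
    table : ConductanceTable, optional
        Conductance calibration; packaged default if omitted.
    prior : mapping class -> probability, optional
        Flat over the five classes if omitted. Must sum to 1.
    no_call_threshold : float
        Calls whose maximum posterior is <= this are emitted as N
        (below a majority belief the argmax is not trusted).
    phred_cap : float
        Saturation for the Phred quality (avoids infinities in the
        noiseless limit).

    Notes
    -----
    The classes are ordered by descending nominal conductance, so posterior
    ties break deterministically toward the higher-conductance class.
    """

    def __init__(
        self,
        table: ConductanceTable | None = None,
        prior: Mapping[str, float] | None = None,
        no_call_threshold: float = DEFAULT_NO_CALL_THRESHOLD,
        phred_cap: float = DEFAULT_PHRED_CAP,
    ):
        self.table = table
        self.prior = prior
        self.no_call_threshold = no_call_threshold
        self.phred_cap = phred_cap

    # -- fitting -----------------------------------------------------------
    def fit(self, levels: Sequence[Level] | None = None, y=None):
        """Freeze class parameters; no data are required.

        The model is fully specified by the calibration table and prior.
        ``levels`` is accepted for API symmetry and ignored.
        """
        table = self.table if self.table is not None else default_table()
        self.classes_ = np.array(table.classes)  # descending conductance
        self.means_ = np.array([table.nominal(c) for c in self.classes_])
        self.sds_ = np.array([table.noise_sd(c) for c in self.classes_])
        self.reference_nominal_ = table.reference_nominal
        if self.prior is None:
            self.log_prior_ = np.full(len(self.classes_), -np.log(len(self.classes_)))
        else:
            p = np.array([float(self.prior[c]) for c in self.classes_])
            if not np.isclose(p.sum(), 1.0, atol=1e-9):
                raise ValueError(f"prior must sum to 1, got {p.sum()}")
            if (p < 0).any():
                raise ValueError("prior probabilities must be >= 0")
            with np.errstate(divide="ignore"):
                self.log_prior_ = np.log(p)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "classes_"):
            self.fit()

    # -- inference ---------------------------------------------------------
    def _posterior_matrix(self, means: np.ndarray, ns: np.ndarray) -> np.ndarray:
        """Posterior over classes for each (level mean, n_samples) row."""
        means = np.asarray(means, dtype=float)[:, None]
        ns = np.asarray(ns, dtype=float)[:, None]
        eff_sd = self.sds_[None, :] / np.sqrt(ns)
        with np.errstate(divide="ignore", invalid="ignore"):
            loglik = (
                -0.5 * ((means - self.means_[None, :]) / eff_sd) ** 2
                - np.log(eff_sd)
                - 0.5 * np.log(2 * np.pi)
            )
        logpost = loglik + self.log_prior_[None, :]
        # Rows where every class underflows to -inf have no information.
        bad = ~np.isfinite(logpost).any(axis=1)
        logpost[bad] = 0.0
        post = np.exp(logpost - logsumexp(logpost, axis=1, keepdims=True))
        post[bad] = np.nan
        return post

    def predict_proba(self, levels: Sequence[Level]) -> np.ndarray:
        """(n_levels, n_classes) posterior matrix, classes as ``classes_``."""
        self._check_fitted()
        means = np.array([lv.mean_pS for lv in levels])
        ns = np.array([lv.n_samples for lv in levels])
        if (ns < 1).any():
            raise ValueError("every level must contain at least one sample")
        return self._posterior_matrix(means, ns)

    def predict(self, levels: Sequence[Level]) -> np.ndarray:
        """Called symbols per level (N where below the no-call threshold)."""
        post = self.predict_proba(levels)
        return self._symbols(post)

    def _symbols(self, post: np.ndarray) -> np.ndarray:
        out = np.empty(post.shape[0], dtype="<U1")
        nan_rows = np.isnan(post).any(axis=1)
        # argmax returns the first maximum: ties break to higher conductance.
        idx = np.nanargmax(np.where(nan_rows[:, None], 0.0, post), axis=1)
        pmax = post[np.arange(post.shape[0]), idx]
        out[:] = self.classes_[idx]
        # small tolerance so an exact 50/50 split lands on N despite
        # normalization round-off
        out[nan_rows | (pmax <= self.no_call_threshold + 1e-12)] = NO_CALL
        return out

    def call(self, levels: Sequence[Level], source_event: int = -1) -> Read:
        """Full per-level calls (symbol, posterior, Phred quality, rel G)."""
        post = self.predict_proba(levels)
        symbols = self._symbols(post)
        calls = []
        for lv, row, sym in zip(levels, post, symbols):
            if np.isnan(row).any():
                posterior = {c: float("nan") for c in self.classes_}
                q = 0.0
            else:
                posterior = {c: float(p) for c, p in zip(self.classes_, row)}
                pmax = float(row.max())
                if pmax >= 1.0:
                    q = self.phred_cap
                else:
                    q = min(-10.0 * np.log10(1.0 - pmax), self.phred_cap)
            if sym == NO_CALL and np.isnan(row).any():
                q = 0.0
            calls.append(
                BaseCall(
                    call=str(sym),
                    posterior=posterior,
                    phred_q=float(q),
                    rel_G=lv.mean_pS / self.reference_nominal_,
                )
            )
        return Read(calls=tuple(calls), source_event=source_event)


def call_level(
    level: Level,
    table: ConductanceTable | None = None,
    prior: Mapping[str, float] | None = None,
    no_call_threshold: float = DEFAULT_NO_CALL_THRESHOLD,
    phred_cap: float = DEFAULT_PHRED_CAP,
) -> BaseCall:
    """Call a single level (thin wrapper over :class:`BaseCaller`)."""
    caller = BaseCaller(
        table=table, prior=prior, no_call_threshold=no_call_threshold, phred_cap=phred_cap
    ).fit()
    return caller.call([level]).calls[0]


def call_read(
    levels: Sequence[Level],
    table: ConductanceTable | None = None,
    prior: Mapping[str, float] | None = None,
    no_call_threshold: float = DEFAULT_NO_CALL_THRESHOLD,
    source_event: int = -1,
) -> Read:
    """Call an ordered level sequence as one read."""
    if not levels:
        raise ValueError("cannot call an empty level list")
    caller = BaseCaller(table=table, prior=prior, no_call_threshold=no_call_threshold).fit()
    return caller.call(levels, source_event=source_event)


def empirical_prior(
    levels: Sequence[Level], table: ConductanceTable | None = None
) -> dict[str, float]:
    """One EM-style reweighting pass: mean flat-prior posterior per class.

    Optional refinement for datasets with skewed base composition; the
    default pipeline keeps the flat prior.
    """
    caller = BaseCaller(table=table).fit()
    post = caller.predict_proba(levels)
    post = post[~np.isnan(post).any(axis=1)]
    if post.size == 0:
        return {c: 1.0 / len(caller.classes_) for c in caller.classes_}
    weights = post.mean(axis=0)
    weights = weights / weights.sum()
    return {c: float(w) for c, w in zip(caller.classes_, weights)}
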