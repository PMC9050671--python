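"""Capture-probe design and ungapped read-to-motif mapping.

Motifs are short transcription-factor binding consensus sequences over
{A, C, G, T} plus the two-fold redundancy codes X (A or G) and Y (C or T).
Capture probes are reverse complements with code complementation (the
complement of X is Y) and with abasic "dSpacer" residues (symbol ``s``)
placed opposite designated thymine positions, so the probe pairs equally
with T and its fluorinated analogue F at those sites.

Mapping is an exhaustive ungapped scan of a called read over all motif
offsets. An F call matches a motif T (the analogue substitutes thymidine);
the F/T distinction is resolved downstream by the call tally, never by
mapping, so mapping does not bias the incorporation rate. N calls count
neither as match nor mismatch. Positions are reported 1-based to users
(the p53 target's thymines are #6 and #16); internal coordinates are
0-based, half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .calling import Read

__all__ = [
    "MotifSpec",
    "MappedRead",
    "design_capture_probe",
    "spacer_coverage",
    "map_read",
    "P53_CONSENSUS",
    "p53_motif",
    "nfkb3_motif",
    "cmyc_motif",
]

#: Code sets: which called bases satisfy each motif symbol.
CODE_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("TF"),  # analogue F sits at thymine positions
    "X": frozenset("AG"),
    "Y": frozenset("CTF"),
}

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G", "X": "Y", "Y": "X", "s": "s"}

#: p53 binding consensus (two half-sites, X = A|G); Table-style worked input.
P53_CONSENSUS = "AXXCATGCCCAXXCATGCCC"


@dataclass(frozen=True)
class MotifSpec:
    """A target consensus with annotated thymine (analogue-susceptible) sites.

    ``t_sites`` are 1-based positions that must hold T in ``sequence``.
    """

    name: str
    sequence: str
    t_sites: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        bad = set(self.sequence) - set("ACGTXY")
        if bad:
            raise ValueError(f"motif {self.name!r} has invalid symbols: {sorted(bad)}")
        if not self.t_sites:
            object.__setattr__(
                self,
                "t_sites",
                tuple(i + 1 for i, b in enumerate(self.sequence) if b == "T"),
            )
        for pos in self.t_sites:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(f"t_site {pos} outside motif {self.name!r}")
            if self.sequence[pos - 1] != "T":
                raise ValueError(
                    f"t_site {pos} of motif {self.name!r} is "
                    f"{self.sequence[pos - 1]!r}, not T"
                )

    def __len__(self) -> int:
        return len(self.sequence)


def p53_motif() -> MotifSpec:
    """The 20-mer p53-binding target (thymines at #6 and #16)."""
    return MotifSpec(name="p53", sequence="AGACATGCCCAGACATGCCC", t_sites=(6, 16))


def nfkb3_motif() -> MotifSpec:
    return MotifSpec(name="NFKB3", sequence="CGGAGATTCC")


def cmyc_motif() -> MotifSpec:
    return MotifSpec(name="c-Myc", sequence="ACCACGTGC")


@dataclass(frozen=True)
class MappedRead:
    """A read placed on a motif: 0-based offset, match/mismatch counts."""

    read: Read
    motif: MotifSpec
    offset: int
    matches: int
    mismatches: int
    n_calls: int

    def __post_init__(self) -> None:
        if self.offset < 0 or self.offset + len(self.read) > len(self.motif):
            raise ValueError("read placement exceeds motif bounds")
        if self.matches + self.mismatches + self.n_calls != len(self.read):
            raise ValueError("match + mismatch + N counts must equal read length")

    @property
    def offset_1based(self) -> int:
        return self.offset + 1

    @property
    def score(self) -> int:
        return self.matches - self.mismatches

    def positions(self):
        """Yield (1-based motif position, BaseCall) for each call."""
        for i, call in enumerate(self.read.calls):
            yield self.offset + i + 1, call


def design_capture_probe(
    consensus: str, spacer_opposite: Sequence[int] = ()
) -> str:
    """Reverse-complement capture probe with abasic spacers.

    ``consensus`` is the target consensus 5'→3' over {A,C,G,T,X,Y};
    ``spacer_opposite`` lists 1-based consensus positions (thymines subject
    to analogue substitution) whose opposing probe residue becomes the
    abasic spacer ``s``. Complementation maps X (A|G) to Y (C|T) and vice
    versa; the probe is returned 5'→3' and has the input's length.

    Note: when the consensus carries non-redundant bases at positions a
    published probe shows as Y, design from the consensus (with X codes),
    not from a concrete target realization — code placement in the output
    follows the input codes exactly.
    """
    bad = set(consensus) - set("ACGTXY")
    if bad:
        raise ValueError(f"consensus contains invalid symbols: {sorted(bad)}")
    n = len(consensus)
    for pos in spacer_opposite:
        if not 1 <= pos <= n:
            raise ValueError(f"spacer position {pos} outside consensus of length {n}")
    probe = [_COMPLEMENT[b] for b in reversed(consensus)]
    for pos in spacer_opposite:
        probe[n - pos] = "s"
    return "".join(probe)


def spacer_coverage(counts: Sequence[int], max_spacers: int = 1) -> float:
    """Fraction of binding-site samples with at most ``max_spacers`` spacers.

    ``counts[k]`` is the number of observed sites whose two half-sites are
    separated by k spacer nucleotides (the last entry may pool "k or more").
    """
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    total = sum(counts)
    if total == 0:
        raise ValueError("total count must be positive")
    return sum(counts[: max_spacers + 1]) / total


def _sequence_of(read) -> str:
    if isinstance(read, Read):
        return read.sequence
    return str(read)


def score_offset(read_seq: str, motif: MotifSpec, offset: int) -> tuple[int, int, int]:
    """(matches, mismatches, n_calls) for one ungapped placement."""
    matches = mismatches = ns = 0
    for i, call in enumerate(read_seq):
        if call == "N":
            ns += 1
            continue
        motif_sym = motif.sequence[offset + i]
        if call in CODE_SETS[motif_sym]:
            matches += 1
        else:
            mismatches += 1
    return matches, mismatches, ns


def map_read(
    read,
    motif: MotifSpec,
    min_score: int = 4,
    max_mismatch_frac: float = 0.2,
) -> MappedRead | None:
    """Best ungapped placement of a read on a motif, or None.

    Scans every offset; score = matches - mismatches, with a call matching
    a motif position iff it is in that symbol's code set (F matches T, X
    admits A|G, Y admits C|T, and F at a Y since Y spans T). N calls score
    zero. The best-scoring offset is returned (ties to the smallest offset)
    provided score >= ``min_score`` and mismatches / read length <=
    ``max_mismatch_frac``; otherwise None.
    """
    seq = _sequence_of(read)
    if not seq:
        raise ValueError("cannot map an empty read")
    if len(seq) > len(motif):
        raise ValueError(
            f"read length {len(seq)} exceeds motif length {len(motif)}"
        )
    best: tuple[int, int, int, int] | None = None  # (score, -offset) ordering
    for offset in range(len(motif) - len(seq) + 1):
        m, mm, ns = score_offset(seq, motif, offset)
        score = m - mm
        if best is None or score > best[0]:
            best = (score, offset, m, mm)
    assert best is not None
    score, offset, m, mm = best
    if score < min_score or mm / len(seq) > max_mismatch_frac:
        return None
    read_obj = read if isinstance(read, Read) else None
    if read_obj is None:
        from .calling import BaseCall

        read_obj = Read(
            calls=tuple(
                BaseCall(call=c, posterior={}, phred_q=0.0, rel_G=float("nan"))
                for c in seq
            )
        )
    return MappedRead(
        read=read_obj,
        motif=motif,
        offset=offset,
        matches=m,
        mismatches=mm,
        n_calls=len(seq) - m - mm,
    )
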