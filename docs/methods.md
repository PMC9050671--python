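# Methods

`tunnelseq` analyses single-molecule tunneling-conductance measurements of
short DNA oligonucleotides. A molecule translocating a sub-nanometre
electrode gap modulates the tunneling current; each nucleotide class has a
characteristic conductance, so a conductance–time trace encodes the base
sequence, including the thymidine analogue trifluridine (FTD, symbol `F`),
which reads far below thymidine. The package covers the full chain from
raw (or simulated) traces to incorporation-rate statistics at
transcription-factor binding motifs.

## Measurement model

Per-class nominal conductances (pS) are empirical calibration constants
taken from single-molecule conductance histogram peaks:

| class | nominal (pS) | relative G |
|-------|-------------:|-----------:|
| G (guanosine)  | 86.7 | 1.00 |
| A (adenosine)  | 66.8 | 0.77 |
| C (cytidine)   | 59.5 | 0.69 |
| T (thymidine)  | 39.1 | 0.45 |
| F (FTD)        | 17.9 | 0.21 |

"Relative G" is conductance normalized by the guanosine nominal; display
rounding is half-up to 2 d.p., computation is full precision. The
calibration source supplies no noise widths; the package defaults each
class's noise sd to 10% of its nominal, which leaves the class
distributions mildly overlapping (T and F sit about three combined
standard deviations apart) so calling is non-trivial but accurate. Both the
nominal set and the widths are configurable via a JSON calibration file; a
secondary config with the rounded values (87/67/60/36/18 pS) occasionally
quoted for this sensor is packaged as `rounded_calibration.json`. No
physical tunneling model (bias-voltage or gap-distance dependence) is
implied anywhere.

## Synthetic traces

The simulator emulates the study conditions: 10 kHz sampling; a baseline of
Normal(5, 2) pS truncated at zero, far below the least conductive class so
event pickup is well-posed; discrete translocation events, each one plateau
per base with i.i.d. Normal(nominal, sd) samples truncated at zero;
log-normal dwell times (median 1 ms, sigma_log 0.5 — single-molecule dwell
phenomenology; redrawn when shorter than 5 samples so every plateau is
resolvable); log-normal inter-event gaps (median 10 ms); and partial reads,
drawn as uniform contiguous sub-strings of the 20-mer template within
configurable length bounds, emulating molecules read over only part of
their length. FTD substitution applies independently at each template
thymine with a configurable probability, and the realized sequence of every
event is recorded as ground truth together with exact level boundaries.
Reads are single-orientation (5'→3'); one integer seed drives one
generator for all draws.

What the simulator does *not* emulate: 100 kHz acquisition, electrode
drift, 1/f noise, co-translocation of multiple molecules, or
context-dependent (k-mer) conductance. Passing tests therefore demonstrate
correctness of the analysis chain under the stated measurement model, not
performance on real device data.

## Event pickup

The baseline is estimated by one-sided sigma clipping seeded from the
lower quartile: iteratively keep samples below median + 4·(1.4826·MAD) of
the kept set. This converges onto the lower (baseline) mode even when half
the trace is event signal. Events are maximal runs above
baseline + k_sigma·baseline_sd (default k_sigma = 5); runs separated by
fewer than `min_gap` = 5 samples are merged *before* runs shorter than
`min_event_samples` = 10 are discarded, so a brief dip through threshold
inside one molecule's passage (possible for the least conductive class)
cannot split or delete the event. Coordinates are 0-based half-open
everywhere internally; only user-facing motif positions are 1-based.

## Level segmentation

Within an event, plateaus are found by change-point segmentation
minimizing total within-segment squared error plus a penalty per change
point. The minimizer is exact: an O(n²) dynamic program over all
admissible boundary placements (minimum segment length 5 samples), which
is ample for events of a few hundred samples and avoids the known
miss/cascade failure modes of greedy binary splitting. Because noise
scales with the conductance level (10% of nominal), the cost is computed
on log-conductance by default, equalizing noise across classes; level
means and sds are reported in pS.

The default penalty is `sigma_hat² · log n`, with `sigma_hat` estimated
robustly from first differences (median absolute difference / √2, scaled).
This is half the classical Gaussian BIC penalty — chosen deliberately: the
adenosine–cytidine separation is only 7.3 pS (1.2 per-sample sds in log
space), and at the default median dwell of ~10 samples per level that
boundary is only detectable with a permissive penalty. The penalty is
floored just above the floating-point error of the prefix-sum cost so that
noiseless step traces segment exactly. The level-count calibration test
sweeps the penalty factor, as any working point for a new device would
have to be.

Two segmentation limits are inherent and documented rather than hidden:

* adjacent identical bases produce statistically identical plateaus and
  cannot be separated from means alone. For constant-dwell acquisitions the
  optional `homopolymer_split_samples` divides each plateau by the known
  per-base duration, recovering run lengths from dwell (the same idea
  nanopore callers use for homopolymers); it is off by default because it is
  only meaningful when dwell is fixed;
* A–C boundaries at short dwells are missed or misplaced at an
  irreducible rate, which shortens and garbles some reads. Downstream
  mapping absorbs this by discarding reads that no longer fit the motif
  (mismatch fraction above threshold); the loss is class-symmetric in T/F
  and so does not bias incorporation rates (verified by the parameter
  recovery test).

## Base calling

Each level is called by a five-class Gaussian model: under class `c` the
level's sample mean is Normal(nominal_c, sd_c/√n). The posterior is the
prior-weighted normalized set of class densities (flat prior by default; an
optional one-pass empirical reweighting is available but off by default,
since the target composition is not known a priori). The call is the
argmax, with ties broken deterministically toward the higher-conductance
class; if the maximum posterior does not exceed 0.5 the call is `N` (the
argmax is not a majority belief). Quality is Phred-encoded,
Q = −10·log10(1 − p_max), capped at 40 to avoid infinities in the
noiseless limit. Degenerate levels for which every class log-density
underflows produce `N` with Q = 0. This probabilistic definition is the
package's own; because the simulator draws from exactly this model, the
posteriors are calibrated by construction, which the Phred-calibration test
verifies empirically (binned error within twice the implied rate).

## Probe design and mapping

Capture probes are reverse complements of the binding consensus with
code complementation — X (A|G) pairs with Y (C|T) — and with abasic
"dSpacer" residues (`s`) placed opposite designated thymines so the probe
pairs indifferently with T and F there. Design takes the *consensus* (with
X codes) as canonical input: the published probe's Y positions arise from
consensus X positions, not from the concrete target realization, so
designing from a fully resolved target yields concrete bases at those
positions instead. Spacer coverage is simple count arithmetic over the
published spacer-length distribution of binding sites.

Mapping is an exhaustive ungapped scan of a called read over all motif
offsets: score = matches − mismatches, where a call matches a motif symbol
iff it lies in the symbol's code set; F matches T positions (and Y, which
spans T), because the analogue substitutes thymidine — the F/T distinction
is resolved by the downstream tally, never by mapping, so mapping cannot
bias the rate. `N` calls score zero. The best offset is reported when
score ≥ 4 and mismatches/length ≤ 0.2 (defaults that admit 5-mers while
leaving random 5-mers mostly unmapped); ties go to the smallest offset.
Insertions/deletions are out of scope by design: with one level per base
there is no gap process to model, and deletion-tolerant alignment is
explicitly a non-goal. Multi-motif competitive assignment is likewise out
of scope — each motif is quantified independently.

## Quantification

For each mapped read, every call contributes its relative conductance to
its 1-based motif position; the position × rel-G histogram (default 50
bins on [0, 1.2]) is display-only and never feeds statistics. At the
motif's annotated thymine sites, calls are tallied as F, T, or other
(including N), per site and pooled.

The incorporation rate is reported under a *named* denominator convention,
because published values mix two: `exclusive` = n_F/(n_F + n_T) (the
written definition) and `inclusive` = n_F/n_total over all tallied calls.
Exclusive ≥ inclusive, with equality iff no other/no-call signals land on
the sites; the package default is exclusive and every output row names its
convention. Intervals are 95% Wilson score (well-behaved at small counts),
clamped to contain the point estimate against boundary round-off.

The bound/unbound comparison is a two-sided Fisher exact test
(hypergeometric two-tail by probability ordering, delegated to
`scipy.stats.fisher_exact` and cross-checked in the tests against an
independent enumeration oracle). The odds ratio is the sample estimate
(ad)/(bc), with a 0.5 continuity correction applied to the point estimate
only when a cell is zero; a degenerate column margin yields p = 1 with a
warning. Exposure-condition tables are ordered, flagged for monotone
increase, and never fitted.

## Pipeline and reproducibility

The five stages (simulate/ingest → detect → call → map → quantify) run
from a single validated JSON config that rejects unknown keys. Each stage
writes plain-text outputs (trace TSV, level TSV, FASTQ with the extended
alphabet and a posterior sidecar TSV, mapping TSV, rate TSV/JSON) plus a
manifest with versions, the seed, a parameter hash and per-stage counts.
Runs are deterministic given (config, seed) — byte-identical rate tables —
and resumable: a stage whose outputs exist under the same parameter hash
is skipped.

## Problem sizes

Simulation-backed tests use 150–1000 events per dataset and 20 datasets
for the parameter-recovery study; the Phred-calibration check uses 10⁵
directly simulated levels; the Fisher cross-check enumerates every 2×2
table with group sizes up to 30. These sizes give the quoted statistical
resolutions (e.g. ~220 pooled T-site calls per 1000-event dataset, hence
3-SE bands of roughly ±6 percentage points at a 10% rate) while keeping
the whole suite fast on a single CPU.

## Known limitations

* Conductance calibration is per-nucleotide and context-free; real
  single-molecule data show k-mer context effects the model ignores.
* Homopolymer run lengths are unrecoverable without fixed dwell.
* Mapping of heavily garbled reads fails closed (reads drop out) rather
  than being rescued by gapped alignment; coverage, not accuracy, suffers.
* Consensus assembly of overlapping reads is not implemented; reads are
  mapped independently.
* Per-site (as opposed to pooled) incorporation rates are produced but have
  no published counterpart to validate against.
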