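# tunnelseq

Single-molecule tunneling-conductance sequencing analysis: from
conductance–time traces of DNA oligonucleotides translocating a nanogap
sensor to base-analogue incorporation statistics at transcription-factor
binding motifs.

## The problem

A DNA molecule passing between sub-nanometre tunneling electrodes
modulates the current base by base: each nucleotide class has a
characteristic single-molecule conductance (guanosine 86.7 pS, adenosine
66.8, cytidine 59.5, thymidine 39.1), and the anticancer thymidine
analogue trifluridine (FTD) reads far lower still, at 17.9 pS. A
conductance–time trace therefore encodes the base sequence *including
analogue incorporation*, with no amplification step. The scientific
question this supports: at what rate does FTD replace thymidine inside a
transcription factor's binding motif (e.g. the p53 20-mer
`AGACATGCCCAGACATGCCC`, thymines at positions 6 and 16), and does that
incorporation weaken factor binding?

`tunnelseq` is for analysts of such measurements (and of simulated stand-ins
for them). It provides:

* **calibration** — per-class conductance tables and relative-G
  (guanosine-normalized) arithmetic;
* **simulation** — traces with baseline noise, per-base plateaus, dwell
  variation, partial reads, and controllable FTD substitution, with exact
  ground truth;
* **signal detection** — robust baseline estimation, threshold event
  pickup, and exact change-point segmentation of events into levels
  (`EventDetector`, `LevelSegmenter`, scikit-learn style);
* **base calling** — a five-class (G/A/C/T/F) Gaussian caller with class
  posteriors and Phred qualities (`BaseCaller`), emitting FASTQ with an
  extended alphabet;
* **motif tools** — capture-probe design with degenerate codes and abasic
  dSpacers, and exhaustive ungapped read-to-motif mapping in which F
  matches a motif T (the tally, not the mapping, separates F from T);
* **quantification** — position × relative-G heat-map profiles, FTD
  incorporation rates n_F/(n_F+n_T) (or n_F/n_total; the convention is
  always named) with Wilson 95% intervals, and exact Fisher comparison of
  F fractions between two DNA fractions.

## Worked example

The packaged demo simulates 500 translocation events of the p53 target at
10% FTD substitution, then runs the full pipeline:

```
tunnelseq run --config src/tunnelseq/data/demo_config.json --out demo_run
tunnelseq report --run-dir demo_run
```

which prints:

```
tunnelseq 0.1.0 run, seed 7
  simulate   ok         {'n_events_true': 500, 'n_samples': 129717}
  detect     ok         {'baseline_pS': 4.997, 'n_events': 500, 'n_levels': 4973}
  call       ok         {'n_calls': 4973, 'n_reads': 500}
  map        ok         {'n_mapped': 114, 'n_reads': 500}
  quantify   ok         {'n_F': 10, 'n_T': 96, 'n_mapped': 114, 'n_other': 0}
motif  label  scope    convention  n_F  n_T  n_other  rate           ci_low        ci_high
p53    demo   pooled   exclusive   10   96   0        0.09433962264  0.05205250265 0.1650008675
p53    demo   pooled   inclusive   10   96   0        0.09433962264  0.05205250265 0.1650008675
p53    demo   site_6   exclusive   9    70   0        0.1139240506   0.06110579328 0.2025479271
p53    demo   site_16  exclusive   1    26   0        0.03703703704  0.006568145981 0.1828346593
```

Reading the output: all 500 simulated molecule passages were detected and
segmented into 4973 plateaus; 114 called reads fit the p53 motif under the
ungapped mapping criteria (hard-to-segment reads drop out rather than
misalign — see `docs/methods.md`); of the 106 confident T/F calls pooled
over the two thymine sites, 10 were FTD, an exclusive incorporation rate
of 9.4% (Wilson 95% CI 5.2–16.5%), consistent with the simulated 10%.
The run directory also holds the reads (`reads.fastq`), per-call
posteriors (`calls.tsv`), the position × relative-G heat map
(`heatmap.png`) and a manifest making the run resumable and byte-for-byte
reproducible from its seed.

The same machinery answers the probe-design and enrichment questions from
the library:

```python
>>> from tunnelseq import design_capture_probe, compare_fractions
>>> design_capture_probe("AXXCATGCCCAXXCATGCCC", spacer_opposite=(6, 16))
'GGGCsTGYYTGGGCsTGYYT'
>>> res = compare_fractions(35, 2003, 118, 1642)  # bound vs unbound DNA
>>> res.odds_ratio, res.p_two_sided < 0.001
(0.24321628926864523, True)
```

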