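# Packaged study data

- `events.tsv` — the 20 organogenesis events scored across lepidosaurs
  (shortened labels).
- `species.tsv` — the 29 sampled species with their higher taxon; the four
  snakes are marked limbless (limb events 9, 12, 14, 18 are inapplicable
  in them).
- `calibrations.csv` — fossil total-group ages used for the
  time-calibrated analyses (stem semantics; see the file header).
- `hypothesis_molecular_assembled.nwk`, `hypothesis_morphological_assembled.nwk`
  — **synthetic stand-in topologies**: 29-tip trees assembled here from the
  published backbone hypotheses (molecular: gekkotans-first with Toxicofera;
  morphological: Iguania sister to Scleroglossa) and the family-level clades
  the study names.  They are *not* the original working trees of any single
  published analysis and are shipped so the full pipeline is runnable
  end-to-end; conclusions tied to exact published topologies should not be
  drawn from them.
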