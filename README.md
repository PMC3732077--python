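# exofrag

Probe-wise microarray analysis of exosomal mRNA fragmentation.

Exosomes — 50–150 nm vesicles secreted by most cell types — carry RNA cargo
whose size distribution (mostly < 700 nt) is far below that of intact mRNAs
(~2,100 nt on average). One explanation is that much of the exported mRNA
consists of 3′-end–derived fragments rather than full-length molecules.
Because each 60-mer probe of a whole-genome expression array interrogates a
specific region of a transcript, probe-level expression in matched
exosome and cell samples can resolve *which part* of a transcript is
exported. `exofrag` implements that analysis for computational biologists
working with two-compartment expression data, together with a synthetic-data
generator that plants known fragmentation so every statistic can be
validated against ground truth.

## The statistics

For probe *p* with mean linear-scale intensities over exosome and cell
samples, the **exosome-to-cell enrichment ratio** is

    ECER_p = mean_exosome(p) / max(mean_cell(p), ε),

with a small floor ε (default: half the smallest positive intensity). A
probe is **secreted** when `ECER_p ≥ c` (default cutoff c = 3, "strong"
preset 10; boundary inclusive). Each transcript with ≥ 2 probes is then
classified by its secreted-probe count: all secreted, exactly half, a
majority, a minority, or none; the half/majority/minority classes are the
*fragmented* ones, and the **fragmented fraction** is their share of
secreted transcripts.

Positional structure is measured with Kendall's τ-b (tie-corrected; exact
permutation p-values for n ≤ 8, tie-adjusted normal approximation above)
between each probe's relative location ℓ ∈ [0, 1] (0 = 5′ end, 1 = 3′ end,
binned at step 0.02 for the expression landscape) and its ECER — overall,
within UTR vs CDS strata, within transcript classes, and across an ECER
cutoff sweep (default 1..32). Finally, probe positions and region borders
bound the length of each secreted 3′-terminal fragment: the distance from
the transcript 3′ end to the closest non-secreted 3′-UTR probe.

## Worked example

```sh
python examples/01_simulate_and_classify.py
```

```
fragmentation classes at ECER >= 3:
  all_secreted   295
  half           1028
  majority       41
  minority       282
  not_secreted   354
fragmented fraction of secreted transcripts: 82.1%
half-class breakdown (n_secreted -> transcripts): {1: 1014, 2: 13, 3: 1}
recovery of planted fragmentation: sensitivity 0.971, specificity 0.962
```

A 2,000-transcript cohort with planted 3′-fragment secretion is simulated,
ECERs computed, and transcripts classified at cutoff 3. Most secreted
transcripts are only partially secreted (82.1% fragmented fraction), the
half class is dominated by two-probe transcripts with one secreted probe,
and comparing calls against the planted labels shows the probe patterns
recover fragmentation almost perfectly. The other examples cover the
positional statistics (`02`), the cutoff sweep with its trend statistics
(`03`), and fragment-length bounds (`04`).

The same analyses are scriptable from a shell:

```sh
exofrag simulate --out fixtures/ --n-transcripts 2000 --seed 1
exofrag classify --transcripts fixtures/transcripts.tsv --probes fixtures/probes.tsv \
    --expression fixtures/expression.tsv --groups fixtures/groups.tsv --cutoff 3
exofrag run --config run.yaml   # full pipeline + report.txt / report.json
```

## Layout

- `src/exofrag/probemap.py` — transcript-space coordinate model, TSV I/O, validation
- `src/exofrag/ecer.py` — enrichment ratios and secretion calls
- `src/exofrag/fragmentation.py` — transcript classes, cutoff sweeps, fragment-length bounds
- `src/exofrag/positional.py` / `kendall.py` — positional statistics and the τ-b engine
- `src/exofrag/synthetic.py` — planted-fragmentation data generator
- `src/exofrag/pipeline.py` / `cli.py` — orchestration, reports, thin CLI
- `docs/methods.md` — model assumptions, parameter choices, limitations
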