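# Methods

## Coordinate model

All coordinates are 0-based half-open intervals in transcript space. A
transcript model is (length, cds_start, cds_end); UTR5 = [0, cds_start),
CDS = [cds_start, cds_end), UTR3 = [cds_end, length). A probe is represented
by its midpoint: the relative location is midpoint/length, and a midpoint
exactly on a region boundary belongs to the 3′-ward region. The 0.02-step
binned location is the relative location rounded down to the grid, with 1.0
assigned to the top bin (0.98). Inputs are tab-separated tables with header
rows; `#` lines are comments. Genomic (chromosome-space) probe placement is
out of scope: the pipeline consumes transcript-space mappings, and the
generator produces them directly.

## Enrichment and classification

ECER is the ratio of a probe's arithmetic mean intensity over exosome
samples to its mean over cell samples, on linear-scale processed
intensities (log-transformed inputs would turn the ratio into a
difference; the readers validate non-negativity but deliberately do not
transform). Division by a zero cell mean is prevented by a floor ε,
defaulting to half the smallest strictly positive intensity in the matrix —
a data-derived value with no unit assumption. Secretion calls use an
inclusive boundary (`ECER ≥ cutoff`), cutoff 3 by default and 10 for the
"strongly secreted" preset. "Retained" means *not secreted* (ECER below the
cutoff), not cell-enriched (ECER ≤ 1/cutoff); the complement definition
keeps the five transcript classes exhaustive. Transcripts need ≥ 2 distinct
probes (`filter_min_probes`, default k = 2) to be classifiable.

The five classes are a pure function of (n_secreted, n_probes): none / all
/ exactly half / majority / minority secreted. Class-fraction curves
re-call secretion and re-classify at every cutoff of the grid (default
1..32, step 1) — fractions are recomputed per cutoff, not accumulated —
with fractions taken among secreted transcripts only (n_secreted ≥ 1).
Cutoffs where nothing is secreted are recorded as missing, and trend
statistics drop them.

## Kendall τ-b engine

τ-b is computed from concordant/discordant pair counts with tie corrections
in both margins (chunked vectorised O(n²); the analyses here run up to a
few tens of thousands of probes, where this is a second or less). Two-sided
p-values: for n ≤ 8, exact enumeration of all n! permutations of one margin
— valid under ties, where textbook exact tables are not — comparing |S|;
for larger n, the normal approximation with the tie-adjusted variance of S.
p-values are reported unadjusted, as is conventional for these correlation
analyses. All-tied margins raise an undefined-result error rather than
returning 0.

## Positional statistics

The primary location statistic correlates every probe's relative location
with its ECER; stratifications restrict by region (UTR = UTR5 ∪ UTR3
versus CDS, with UTR3-only available), by transcript class (e.g. the
majority-secreted class), or by transcript strength (max probe ECER ≥ 10
under the default "any" mode; an "all probes" mode is available). The
per-probe form is the primary statistic because it uses every record;
representative probe pairs (max-ECER vs min-ECER probe per transcript, ECER
ties broken toward the 3′-ward probe, then probe id) are emitted alongside
with their 3′/5′ exosomal expression ratios. The expression landscape bins
mean exosomal intensity over (location bin × ECER bin), location step 0.02
and log2-spaced ECER edges 1..32 plus an open top bin and a below-1 bin;
empty cells are missing, not zero. The probe-design control correlates raw
exosomal mean expression with location separately below and at/above the
split cutoff (default 3): near-zero τ in both strata indicates the
positional secretion signal is not a placement artefact.

## Fragment-length bounds

Probe positions and region borders are the only landmarks, so the bound for
a transcript is the distance from its 3′ end to the interval end of the
3′-most non-secreted probe in its 3′ UTR, or to the UTR 5′ border (the gene
5′ end under `limit_border="gene"`) when every UTR probe is secreted. Only
transcripts with ≥ 3 UTR probes (configurable) are informative enough to
include, optionally restricted to UTRs ≤ 1000 nt; transcripts with no
secreted UTR probe carry no fragment evidence and are excluded, as are
degenerate zero bounds (a non-secreted probe flush against the 3′ end,
which contradicts a secreted probe 5′ of it and would violate bound
positivity). Bounds are non-increasing in the cutoff because secretion
calls are. Probe-sparse designs qualify few transcripts — itself an honest
reflection of how rarely UTRs carry three probes — so fragment-length
illustrations use a denser probe design (3–8 probes, uniform counts,
transcripts ≥ 1200 nt).

## Synthetic data: what it emulates

The generator mimics a two-compartment whole-genome array study of
glioblastoma-like cells and their exosomes:

- **Transcript lengths**: lognormal (log-mean ln 2100, log-sd 0.65)
  truncated to [400, 12000] nt, matching the mammalian mRNA length regime;
  the empirical median sits near 2,100 nt. UTR fractions default to 10%
  (5′) and 35% (3′) of the length, typical for human mRNAs.
- **Probes**: 60-mers, 2–6 per transcript with counts decaying
  geometrically from 2 (`probe_count_decay` 0.25; 1.0 recovers a uniform
  distribution). The decay reflects filtered array designs, where two-probe
  transcripts dominate overwhelmingly. One probe sits flush at each
  terminus and the rest pack uniformly without overlap (a stars-and-bars
  draw), so each transcript's probe set brackets its full length and an
  interior breakpoint always falls between two probes — planted
  fragmentation is then detectable in principle for every transcript, and
  recovery scores measure the statistics rather than probe-design luck.
- **Secretion**: each transcript is fragmented with probability 0.7; the
  exported piece is [breakpoint, 3′ end] with the relative breakpoint drawn
  as lo + (hi − lo)·Beta(1 + bias_beta, 1) — uniform at bias_beta = 0,
  increasingly 3′-ward as it grows (default 5) — where hi caps the fragment
  at ≥ 100 nt (shorter pieces would not be detectable mRNA fragments) and
  lo rises to the UTR3 start under `breakpoint_region="utr3"`. Unfragmented
  transcripts are secreted intact with probability 0.6, else retained.
- **Export efficiency**: per-transcript gain = 8 × lognormal(0, 0.5),
  damped by 0.6 for intact molecules — whole-mRNA secretion is weaker than
  3′-fragment export, which is what makes strong enrichment fragment-rich
  and populates the full 1..32 cutoff sweep. Probes outside the fragment
  leak at 0.05 of the cellular signal. The applied gain is recorded in the
  ground truth.
- **Noise**: cellular intensity = transcript baseline (lognormal, log-sd 1)
  × probe efficiency (log-sd 0.3, cancelling in the ratio) × replicate
  noise; exosomal intensity = baseline × efficiency × gain-or-leak ×
  replicate noise. Replicate noise (total log-sd 0.2 per measurement,
  3 + 3 samples) decomposes into a transcript-level component shared by a
  transcript's probes within one sample (biological/loading variation of
  that RNA species; 65% of the variance) and an independent probe-level
  hybridisation residual. Fully independent probe noise would be
  unrealistic for probes reporting one molecular species and creates a
  max-of-m survival selection at extreme cutoffs that distorts class
  composition.
- **Determinism**: all randomness flows from the single config seed through
  named generators; identical configs give byte-identical fixture files.

### What the generator does not emulate

No nucleotide sequences, motifs, or miRNA interactions; no between-array
normalisation artefacts, batch effects, background subtraction or
saturation; no genomic mapping ambiguity (probes map uniquely in transcript
space); breakpoints are single and 3′-terminal (no 5′ fragments or multiple
cleavage products); compartments are independently noisy rather than
paired. Passing tests therefore show that the statistics behave correctly
when their assumptions hold and detect what was planted — not that real
array data are free of the artefacts listed above.

## Calibration and experiment design

- **Null calibration** (no fragmentation, no bias) uses *unanchored*
  placement: terminal anchoring gives every transcript a near-identical
  location multiset, and combined with transcript-level expression
  correlation the cross-transcript pair contributions cancel, making the
  plain test markedly conservative (under-dispersed τ). With exchangeable
  placement, p-values from 200 independent cohorts (~2000 probes each) are
  uniform by a Kolmogorov–Smirnov check at the 1% level and the median |τ|
  stays an order of magnitude below 0.05. The conservativeness under
  anchored designs is worth knowing in its own right: clustered probe
  designs make the unadjusted test err toward missing signal, not
  fabricating it.
- **Trend statistics** on the cutoff sweep are evaluated on the mean
  class-fraction curve over ten replicate cohorts of 4,000 transcripts:
  single desk-scale cohorts leave so few secreted transcripts at extreme
  cutoffs that the trend τ carries Monte Carlo noise of ±0.3, while the
  averaged curve is stable. On reference-config data the half-class trend
  is strongly positive and the all-secreted trend strongly negative.
- **Recovery experiments** use ten cohorts of 2,000 transcripts
  (sensitivity/specificity of fragmented-transcript calls at cutoff 3,
  scored against planted labels), and the per-probe τ saturates around
  0.38 under bracketing placement for every bias level — raising the
  breakpoint bias reshapes which interior probes flip without strengthening
  the correlation, so τ is flat (non-decreasing within Monte Carlo error)
  in bias_beta rather than strictly increasing.

## Numerical and interface choices

Exit codes: 0 success, 2 configuration error, 3 format/validation error,
4 insufficient data. Logs go to stderr, tables never do. Pipeline runs are
reproducible byte-for-byte given identical inputs, and a failed stage
removes partial outputs. The ΔCT helper assumes the idealised amplification
efficiency of 2 per cycle: relative abundance = 2^−(CT_gene − CT_spike),
and the 3′/5′ amplicon ratio is the quotient of two such abundances.

## Known limitations

ECER is a ratio of means without a significance model, so probe-level
differential-expression uncertainty is not propagated; the fragment-length
rule assumes a single contiguous 3′-terminal fragment; the τ engine's
p-values assume exchangeability across probes and are conservative for
clustered designs (see above); and published class counts and τ magnitudes
depend on the original arrays they were computed from, so only directions,
orderings and arithmetic identities — not dataset-specific magnitudes — are
meaningful comparisons for synthetic cohorts.
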