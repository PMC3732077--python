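"""Where along the transcript does the secreted signal sit?

Correlates each probe's relative location (0 = 5' end, 1 = 3' end) with its
exosome/cell enrichment ratio, overall and stratified by region, and runs
the probe-design control that guards against placement artefacts.
"""

import exofrag as xf

# breakpoints restricted to the 3' UTR: only UTR probes carry the signal
bundle = xf.simulate_bundle(
    xf.SimConfig(seed=2, n_transcripts=3000, breakpoint_region="utr3")
)
secretion = xf.probe_secretion(bundle.matrix, bundle.mappings, cutoff=None)

overall = xf.location_secretion_correlation(secretion, bundle.mappings)
print(f"all probes:  tau = {overall.tau:+.3f}  (p = {overall.p_value:.2g}, "
      f"n = {overall.n})")
for region in ("utr", "cds"):
    res = xf.location_secretion_correlation(secretion, bundle.mappings, region=region)
    print(f"{region.upper():>10}:  tau = {res.tau:+.3f}  (p = {res.p_value:.2g}, "
          f"n = {res.n})")
print("positive tau = probes closer to the 3' end are more exosome-enriched;")
print("with UTR-restricted breakpoints the signal lives in the UTR stratum only.")

bias = xf.probe_design_bias_check(secretion, bundle.mappings)
for label, res in bias.items():
    print(f"design control [{label}]: tau = {res.tau:+.3f}" if res else
          f"design control [{label}]: stratum empty")
print("near-zero control tau = expression does not track probe position per se.")

pairs = xf.pair_table(secretion, bundle.mappings, min_strength=10.0)
frac_3p = pairs["hi_is_3prime"].mean()
print(f"strong secretors (max ECER >= 10): {len(pairs)} transcripts; "
      f"max-ECER probe is the 3'-closer one in {100 * frac_3p:.0f}% of pairs, "
      f"median 3'/5' expression ratio {pairs['ratio_3p_5p'].median():.1f}")
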