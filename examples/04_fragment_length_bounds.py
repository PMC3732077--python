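"""Bound the length of secreted 3'-terminal fragments from probe positions.

Probe positions and region borders are the only landmarks an array offers,
so per transcript the fragment length is bounded by the distance from the
3' end to the closest non-secreted probe in the 3' UTR (or the UTR border
if every UTR probe is secreted).  Needs probe-dense UTRs, so this cohort
uses a denser design than the default.
"""

import exofrag as xf

config = xf.SimConfig(
    seed=4, n_transcripts=3000, probes_min=3, probes_max=8,
    probe_count_decay=1.0, length_min=1200,
)
bundle = xf.simulate_bundle(config)
secretion = xf.probe_secretion(bundle.matrix, bundle.mappings, cutoff=None)

for cutoff in (2.0, 3.0):
    summary = xf.fragment_length_bounds(
        secretion, bundle.mappings, bundle.transcripts,
        cutoff=cutoff, min_probes_per_utr=3, max_utr_length=1000,
    )
    print(f"ECER >= {cutoff:g}: {summary.n_transcripts} transcripts with >= 3 probes "
          f"in a <= 1000 nt UTR; median bound {summary.median_length:.1f} nt, "
          f"IQR {summary.iqr_length:.1f} nt")
print("each bound caps how far the secreted 3'-terminal region can extend;")
print("raising the cutoff can only shrink a transcript's bound.")
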