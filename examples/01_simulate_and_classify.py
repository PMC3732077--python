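"""Simulate a two-compartment cohort and classify transcript fragmentation.

Builds a synthetic exosome/cell expression dataset with planted 3'-terminal
fragment secretion, computes per-probe enrichment ratios (ECER), classifies
every transcript by how many of its probes are secreted at ECER >= 3, and
scores the classification against the planted ground truth.
"""

import exofrag as xf

bundle = xf.simulate_bundle(xf.SimConfig(seed=1, n_transcripts=2000))
secretion = xf.probe_secretion(bundle.matrix, bundle.mappings, cutoff=3.0)
classes, counts = xf.classify_all(secretion)

print("fragmentation classes at ECER >= 3:")
for klass, n in counts.items():
    print(f"  {klass:<14} {n}")
print(f"fragmented fraction of secreted transcripts: "
      f"{xf.fragmented_fraction(counts):.1f}%")

breakdown = xf.half_class_breakdown(classes)
print("half-class breakdown (n_secreted -> transcripts):", breakdown.to_dict())

truth = bundle.truth.transcripts.set_index("transcript_id")
predicted = classes.set_index("transcript_id")["klass"].isin(xf.FRAGMENTED_CLASSES)
actual = truth.loc[predicted.index, "fragmented"]
sens = (predicted & actual).sum() / actual.sum()
spec = (~predicted & ~actual).sum() / (~actual).sum()
print(f"recovery of planted fragmentation: sensitivity {sens:.3f}, "
      f"specificity {spec:.3f}")
print("(a fragmented call = some but not all of a transcript's probes secreted;")
print(" high sensitivity/specificity mean probe patterns recover the planted labels)")
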