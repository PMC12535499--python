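"""Generating a synthetic feature table and curating it for modelling.

The generator draws a realistic untargeted HILIC export: a mostly
unidentified feature list with retention-time artifacts, dual-polarity
duplicates of identified metabolites, and class-conditional (m/z, %A)
structure.  Curation then applies the three cleaning rules (RT window,
polarity preference, taxonomy labelling) and accounts for every feature.
"""

from mzlipid import GradientProgram, annotate_gradient, curate, generate, scenario

program = GradientProgram()
config = scenario("default", n_features=2000, seed=42)
table, taxonomy, truth = generate(config, program)

print(f"generated {len(table)} features "
      f"({len(truth)} identified, {len(taxonomy)} taxonomy entries)\n")

annotated = annotate_gradient(table, program)
examples, report = curate(annotated, taxonomy)

for line in report.summary_lines():
    print(line)
assert report.counts_partition_input()

lipid_pa = [ex.gradient_pct_a for ex in examples if ex.label == "lipid"]
other_pa = [ex.gradient_pct_a for ex in examples if ex.label == "non_lipid"]
print(f"\nmean %A at elution: {sum(lipid_pa) / len(lipid_pa):.1f} (lipid) vs "
      f"{sum(other_pa) / len(other_pa):.1f} (non-lipid)")
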