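"""Recompute the survey's printed-table arithmetic from the bundled
fixtures: plasmid totals, fungal BGC class split, plasmid-BGC genes."""

import json

from natminer import fixture_summary, fraction_by_group, load_fixture

print(json.dumps(fixture_summary(), indent=2))

t1 = load_fixture("table1_fungal_bgc")
gmap = load_fixture("genus_class_map")
klass = dict(zip(gmap.df["genus"], gmap.df["class"]))
df = t1.df.assign(klass=t1.df["genus"].map(klass))
print("Eurotiomycetes share of fungal NAT BGCs:",
      fraction_by_group(df, "klass", "Eurotiomycetes", rounded=True), "%")
print("Sordariomycetes share:",
      fraction_by_group(df, "klass", "Sordariomycetes", rounded=True), "%")
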