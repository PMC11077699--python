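"""Physicochemical profile of the family: MW, pI, GRAVY, AI, II, classes.

Writes results/property_summary.tsv with per-subfamily means and the
acidity / hydropathy tallies the family-level characterization reports.
"""

import pandas as pd

from _common import get_family, results_dir
from pcfam.properties import profile_table

fam = get_family()
df = profile_table(fam.proteins)
df["subfamily"] = df.protein_id.map({g: t.subfamily for g, t in fam.truth.items()})

print(f"{len(df)} proteins profiled")
print(f"pI range: {df.pI.min():.2f} - {df.pI.max():.2f}")
print(f"MW range: {df.molecular_weight.min()/1000:.2f} - {df.molecular_weight.max()/1000:.2f} kDa")
print("\nAcidity classes:")
print(df.acidity_class.value_counts().to_string())
print("\nHydropathy classes:")
print(df.hydropathy_class.value_counts().to_string())

summary = df.groupby("subfamily")[
    ["length", "molecular_weight", "pI", "gravy", "aliphatic_index", "instability_index"]
].mean().round(3)
summary.to_csv(results_dir() / "property_summary.tsv", sep="\t")
print("\nPer-subfamily means written to results/property_summary.tsv")
print(summary.to_string())
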