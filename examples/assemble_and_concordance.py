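"""Binarize concern categories, merge duplicate records, enrich with a
second label source, and quantify cross-source label agreement.

The concern categories collapse to a binary toxicity label (most/less
-> 1, no -> 0, ambiguous removed); duplicates collapse toxic-wins; a
SIDER-style binary source adds compounds without overriding existing
labels, and the concordance report measures how well the two sources
agree on shared compounds.
"""

import pandas as pd

from dictox import (
    binarize_concern,
    collapse_duplicates,
    concordance,
    enrich_with_sider,
)

dictrank = pd.DataFrame(
    {
        "key": ["k1", "k1", "k2", "k3", "k4"],
        "std_smiles": ["CCO", "OCC", "CCN", "CCC", "CCS"],
        "concern": ["no", "most", "less", "no", "most"],
        "source": ["DICTrank"] * 5,
    }
)
dictrank["label"] = dictrank["concern"].map(binarize_concern)
ds = collapse_duplicates(dictrank)
print("after binarize + dedupe:")
print(ds.to_string(index=False))

sider = pd.DataFrame(
    {
        "key": ["k2", "k3", "k9"],
        "std_smiles": ["CCN", "CCC", "CCCl"],
        "concern": ["unknown"] * 3,
        "label": [1, 0, 1],
        "source": ["SIDER"] * 3,
    }
)
rep = concordance(ds, sider)
print(f"\nconcordance on {rep.n_overlap} shared compounds: "
      f"{rep.percent_concordant:.1f}%  (F1 of SIDER vs truth: "
      f"{rep.f1_of_sider_vs_dictrank:.2f})")

enriched = enrich_with_sider(ds, sider, mode="toxic_only")
print(f"\nenriched (toxic_only): {len(enriched)} compounds "
      f"({len(enriched) - len(ds)} added from SIDER)")
print("Overlapping keys keep the primary label; only SIDER-only toxic "
      "compounds were added.")
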