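"""Mine substructure alerts from a synthetic study with a planted
toxicophore, then screen new compounds against them.

The generator plants a nitro-aromatic ring in toxic compounds (with 5%
label noise).  Recursive fragmentation + PPV filtering should recover
it — the printed top alerts all contain the planted ring.
"""

from dictox import SyntheticStudyConfig, generate_study, screen_compounds
from dictox.alerts import filter_and_merge, mine_alert_settings, reporting_view

cfg = SyntheticStudyConfig(n_compounds=250, seed=8)
study = generate_study(cfg)
ds = study["compounds"]
print(f"study: {len(ds)} compounds, "
      f"{ds['label'].sum()} toxic / {(ds['label'] == 0).sum()} nontoxic")

mined = mine_alert_settings(ds, min_occurrence=5)
merged = filter_and_merge(mined["all_compounds"], mined["toxic_only"])
view = reporting_view(merged)  # occurrences > 10 and PPV > 0.6
print(f"merged alerts: {len(merged)}; high-confidence view: {len(view)}")
print("\ntop alerts (pattern, occurrences, PPV):")
for alert in view[:5]:
    print(f"  {alert.pattern:38s} {alert.occurrences:4d}  {alert.ppv:.2f}")

hits = screen_compounds(
    {"query_tox": "CCOc1ccc([N+](=O)[O-])cc1", "query_clean": "CCO"},
    view,
)
print("\nscreening new compounds:")
for _, row in hits.iterrows():
    print(f"  {row['key']}: {row['n_hits']} alert hit(s)")
print("A PPV of 1.00 means every training compound containing the "
      "pattern was toxic.")
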