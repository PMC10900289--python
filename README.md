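# dictox

Analysis toolkit for **drug-induced cardiotoxicity (DICT)** classification
from chemical structure and auxiliary biological data.

Cardiotoxicity is a leading cause of drug attrition and market withdrawal.
Regulatory concern rankings grade drugs into *most*, *less*, *no* and
*ambiguous* concern categories; pharmacovigilance databases record cardiac
adverse events for marketed drugs. `dictox` implements the full analysis
chain that turns such label tables plus raw SMILES into interpretable
statistics and predictive models:

1. **Standardization** (`dictox.chemstd`) — iterative cleanup /
   neutralization / tautomer canonicalization of SMILES to a fixed point,
   followed by protonation at physiological pH 7.4 via a pKa rule table;
   the standard InChI of the result is the join key for all
   cross-dataset matching.
2. **Dataset assembly** (`dictox.data_assembly`) — concern binarization
   (most/less → 1, no → 0, ambiguous removed), toxic-wins duplicate
   collapsing, enrichment with a second binary source (primary label wins
   on conflict), and cross-source concordance (% agreement and F1).
3. **Feature spaces** (`dictox.features`) — 2048-bit Morgan (radius-2)
   fingerprints, 2-D physicochemical descriptors with a deterministic
   NaN/infinity policy, one-hot mechanism/target annotations with
   variance filtering (threshold 0.001), median aggregation of replicate
   omics profiles, and Tanimoto-conditional **v-NN imputation**: a
   missing profile is the elementwise median over all library compounds
   with similarity > 0.70, held-out compounds excluded from the pool.
4. **Association statistics** (`dictox.stats`) — per-feature tests
   against concern categories or binary labels: chi-squared for
   categorical features, Kruskal–Wallis across the three concern groups,
   two-sided Mann–Whitney U for pairwise contrasts with Bonferroni
   correction over contrasts.
5. **Structural alerts** (`dictox.alerts`) — recursive fragmentation
   (acyclic single bonds cut, rings kept; 2–18 heavy atoms, minimum
   occurrence 5), PPV = toxic occurrences / occurrences, merging of the
   all-compounds and toxic-only mining settings, filters (PPV ≥ 0.5,
   > 4 atoms, generic-scaffold blocklist), and screening of external
   compound sets with overlap exclusion.
6. **Modeling** (`dictox.modeling`) — random forests per feature space
   with successive-halving random hyperparameter search under stratified
   5-fold CV, minority oversampling inside training folds only, decision
   threshold chosen on out-of-fold probabilities by **Youden's J**
   (J = TPR − FPR), metrics (balanced accuracy, sensitivity, specificity,
   F1, MCC, AUC-ROC, AUCPR), soft-voting ensembles over
   threshold-rescaled probabilities, and an applicability-domain report
   binning test compounds by nearest same-label training-set Tanimoto
   similarity.
7. **Synthetic studies** (`dictox.synthetic`) — a generator producing
   offline datasets with the statistical structure the analysis assumes
   (planted toxicophore, class-shifted Cmax, enriched annotations,
   partially missing omics profiles), so every stage is testable without
   downloads.
8. **Pipeline** (`dictox.pipeline`, `dictox` CLI) — one-config
   orchestration of all stages with a deterministic run manifest and a
   leak audit.

## Worked example

`examples/mine_structural_alerts.py` generates a 250-compound synthetic
study in which toxic compounds carry a nitro-aromatic toxicophore (5 %
label noise), mines alerts, and screens two new compounds:

```
study: 250 compounds, 198 toxic / 52 nontoxic
merged alerts: 245; high-confidence view: 106

top alerts (pattern, occurrences, PPV):
  O=[N+]([O-])c1ccccc1                    194  1.00
  Cc1ccc([N+](=O)[O-])cc1                  84  1.00
  Cc1cccc([N+](=O)[O-])c1                  81  1.00
  CCc1ccc([N+](=O)[O-])cc1                 45  1.00
  CCc1cccc(N)c1                            43  1.00

screening new compounds:
  query_tox: 5 alert hit(s)
  query_clean: 0 alert hit(s)
```

The top alert is exactly the planted nitro-aromatic ring: it occurs in
194 training compounds, every one of them toxic (PPV 1.00), and a new
nitro-aromatic query triggers five alerts while ethanol triggers none.
The other examples cover standardization (`standardize_compounds.py`),
label assembly and concordance (`assemble_and_concordance.py`), and model
training with threshold optimization and applicability-domain reporting
(`train_and_evaluate.py`).

A full pipeline run from the shell:

```bash
dictox synth --out-dir study/ --n-compounds 300 --seed 0
cat > pipeline.yaml <<EOF
dictrank_csv: study/dictrank.csv
omics_csv: study/omics.csv
out_dir: study/run
feature_spaces: [structure, omics_morphology]
seed: 0
EOF
dictox run --config pipeline.yaml
```

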