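"""End-to-end pipeline orchestration.

Runs the full analysis — standardize → assemble → featurize → stats →
alerts → train → evaluate → ensemble → applicability domain — from one
YAML/dict config with a fixed seed, writing per-stage outputs and a
deterministic run manifest (input hashes, seeds, per-stage record
counts, output hashes).  The held-out test set is fixed immediately
after assembly, before any feature construction or training, and test
keys are excluded from v-NN neighbor pools, alert mining, oversampling
and threshold optimization; the manifest records the audit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alerts import alerts_to_frame, filter_and_merge, mine_alert_settings
from .chemstd import standardize_compound
from .data_assembly import (
    binarize_concern,
    collapse_duplicates,
    concordance,
    enrich_with_sider,
    EXCLUDED,
)
from .features import (
    DROPPED,
    FeatureMatrix,
    fingerprint_matrix,
    onehot_annotations,
    physchem_matrix,
    variance_filter,
    vnn_impute,
)
from .modeling import ad_report, cv_train, ensemble_predict, evaluate
from .stats import rank_features, results_to_frame

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

log = logging.getLogger(__name__)

VARIANTS = ("dictrank", "plus_sider_toxic", "plus_sider_nontoxic", "plus_sider_all")
STAGES = (
    "standardize",
    "assemble",
    "featurize",
    "stats",
    "alerts",
    "train",
    "evaluate",
    "ensemble",
    "ad",
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


class PipelineConfig:
    """Validated pipeline configuration (see ``load_config``)."""

    def __init__(
        self,
        dictrank_csv: str,
        out_dir: str,
        sider_csv: str | None = None,
        cmax_csv: str | None = None,
        annotations_csv: str | None = None,
        omics_csv: str | None = None,
        variant: str = "dictrank",
        feature_spaces: tuple = ("structure", "physchem"),
        seed: int = 0,
        test_fraction: float = 0.1,
        smiles_col: str = "smiles",
    ):
        if variant not in VARIANTS:
            raise ValueError(f"unknown dataset variant {variant!r}")
        for name, p in [("dictrank_csv", dictrank_csv), ("sider_csv", sider_csv),
                        ("cmax_csv", cmax_csv), ("annotations_csv", annotations_csv),
                        ("omics_csv", omics_csv)]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")
        self.dictrank_csv = dictrank_csv
        self.sider_csv = sider_csv
        self.cmax_csv = cmax_csv
        self.annotations_csv = annotations_csv
        self.omics_csv = omics_csv
        self.variant = variant
        self.feature_spaces = tuple(feature_spaces)
        self.seed = int(seed)
        self.test_fraction = float(test_fraction)
        self.smiles_col = smiles_col
        self.out_dir = Path(out_dir)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return PipelineConfig(**raw)


def _sha256_file(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _sha256_frame(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()


def _standardize_stage(cfg: PipelineConfig) -> pd.DataFrame:
    df = pd.read_csv(cfg.dictrank_csv)
    if cfg.smiles_col not in df.columns:
        raise PipelineError(
            "standardize", f"input lacks a {cfg.smiles_col!r} column"
        )
    rows = []
    for _, rec in df.iterrows():
        std = standardize_compound(str(rec[cfg.smiles_col]))
        row = {
            "raw_smiles": std.raw_smiles,
            "std_smiles": std.std_smiles,
            "key": std.std_inchi,
            "n_iterations": std.n_iterations,
            "converged": std.converged,
        }
        for col in ("concern", "label"):
            if col in df.columns:
                row[col] = rec[col]
        rows.append(row)
    return pd.DataFrame(rows)


def _assemble_stage(cfg: PipelineConfig, std: pd.DataFrame) -> dict:
    if "concern" not in std.columns:
        raise PipelineError("assemble", "standardized table lacks 'concern'")
    std = std.copy()
    std["label"] = std["concern"].map(binarize_concern)
    ambiguous = std[std["label"] == EXCLUDED].copy()
    labeled = std[std["label"] != EXCLUDED].copy()
    labeled["label"] = labeled["label"].astype(int)
    labeled["source"] = "DICTrank"
    ds = collapse_duplicates(
        labeled[["key", "std_smiles", "concern", "label", "source"]]
    )

    report = None
    if cfg.sider_csv is not None:
        sider = pd.read_csv(cfg.sider_csv)
        sider_std = []
        for _, rec in sider.iterrows():
            s = standardize_compound(str(rec[cfg.smiles_col]))
            sider_std.append(
                {"key": s.std_inchi, "std_smiles": s.std_smiles,
                 "concern": "unknown", "label": int(rec["label"]),
                 "source": "SIDER"}
            )
        sider_ds = collapse_duplicates(pd.DataFrame(sider_std))
        report = concordance(ds, sider_ds)
        mode = {
            "plus_sider_toxic": "toxic_only",
            "plus_sider_nontoxic": "nontoxic_only",
            "plus_sider_all": "all",
        }.get(cfg.variant)
        if mode is not None:
            ds = enrich_with_sider(ds, sider_ds, mode=mode)
    return {"dataset": ds, "ambiguous": ambiguous, "concordance": report}


def _split_test(ds: pd.DataFrame, seed: int, test_fraction: float):
    rng = np.random.default_rng(seed)
    test_keys = []
    for cls in (0, 1):
        keys = sorted(ds.loc[ds["label"] == cls, "key"])
        n_test = max(1, int(round(test_fraction * len(keys))))
        test_keys.extend(rng.choice(keys, size=n_test, replace=False))
    test_keys = sorted(test_keys)
    train_keys = sorted(set(ds["key"]) - set(test_keys))
    return train_keys, test_keys


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all nine stages and return the run manifest."""
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "dictox_version": __version__,
        "seed": cfg.seed,
        "variant": cfg.variant,
        "inputs": {
            name: _sha256_file(p)
            for name, p in [
                ("dictrank_csv", cfg.dictrank_csv),
                ("sider_csv", cfg.sider_csv),
                ("cmax_csv", cfg.cmax_csv),
                ("annotations_csv", cfg.annotations_csv),
                ("omics_csv", cfg.omics_csv),
            ]
            if p is not None
        },
        "stages": {},
        "hashes": {},
    }

    def record(stage: str, n_records: int, frame: pd.DataFrame | None = None):
        manifest["stages"][stage] = {"n_records": int(n_records)}
        if frame is not None:
            manifest["hashes"][stage] = _sha256_frame(frame)

    # 1. standardize
    try:
        std = _standardize_stage(cfg)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("standardize", str(exc)) from exc
    std.to_csv(out / "standardized.csv", index=False)
    record("standardize", len(std), std)

    # 2. assemble
    try:
        asm = _assemble_stage(cfg, std)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("assemble", str(exc)) from exc
    ds = asm["dataset"]
    ds.to_csv(out / "dataset.csv", index=False)
    record("assemble", len(ds), ds)
    if asm["concordance"] is not None:
        r = asm["concordance"]
        manifest["concordance"] = {
            "n_overlap": r.n_overlap,
            "percent_concordant": r.percent_concordant,
            "f1": r.f1_of_sider_vs_dictrank,
        }

    train_keys, test_keys = _split_test(ds, cfg.seed, cfg.test_fraction)
    manifest["split"] = {
        "n_train": len(train_keys),
        "n_test": len(test_keys),
        "test_keys_sha256": hashlib.sha256(
            "\n".join(test_keys).encode()
        ).hexdigest(),
    }

    # 3. featurize
    try:
        smiles_by_key = dict(zip(ds["key"], ds["std_smiles"]))
        spaces: dict[str, FeatureMatrix] = {}
        fps = fingerprint_matrix(smiles_by_key)
        if "structure" in cfg.feature_spaces:
            spaces["structure"] = fps
        if "physchem" in cfg.feature_spaces:
            spaces["physchem"] = physchem_matrix(smiles_by_key)
        if cfg.annotations_csv is not None and "moa" in cfg.feature_spaces:
            ann = pd.read_csv(cfg.annotations_csv)
            sets: dict[str, set] = {k: set() for k in smiles_by_key}
            for _, rec in ann.iterrows():
                if rec["key"] in sets:
                    sets[rec["key"]].add(str(rec["term"]))
            spaces["moa"] = variance_filter(onehot_annotations(sets, "moa"))
        if cfg.omics_csv is not None and "omics_morphology" in cfg.feature_spaces:
            omics = FeatureMatrix(
                "omics_morphology", pd.read_csv(cfg.omics_csv, index_col="key")
            )
            rows, dropped = {}, 0
            for key in smiles_by_key:
                prof = vnn_impute(
                    key, fps, omics, excluded_keys=frozenset(test_keys)
                    if key not in test_keys else frozenset(),
                )
                if prof is DROPPED:
                    dropped += 1
                else:
                    rows[key] = prof
            spaces["omics_morphology"] = FeatureMatrix(
                "omics_morphology", pd.DataFrame.from_dict(rows, orient="index")
            )
            manifest["vnn_dropped"] = dropped
        n_feat = sum(fm.data.shape[1] for fm in spaces.values())
    except Exception as exc:
        raise PipelineError("featurize", str(exc)) from exc
    for tag, fm in spaces.items():
        fm.to_csv(out / f"features_{tag}.csv")
    record("featurize", n_feat)

    # 4. stats (training compounds only)
    try:
        train_ds = ds[ds["key"].isin(train_keys)]
        assoc_frames = []
        for tag, fm in spaces.items():
            sub = FeatureMatrix(tag, fm.data.loc[[k for k in train_keys if k in fm.data.index]])
            results = rank_features(sub, train_ds, scheme="three_concern")
            frame = results_to_frame(results)
            frame.insert(0, "space", tag)
            assoc_frames.append(frame)
        assoc = pd.concat(assoc_frames, ignore_index=True)
    except Exception as exc:
        raise PipelineError("stats", str(exc)) from exc
    assoc.to_csv(out / "associations.csv", index=False)
    record("stats", len(assoc), assoc)

    # 5. alerts (mined on training compounds only)
    try:
        mined = mine_alert_settings(train_ds, scheme="binary_label")
        merged = filter_and_merge(mined["all_compounds"], mined["toxic_only"])
        alerts_frame = alerts_to_frame(merged)
    except Exception as exc:
        raise PipelineError("alerts", str(exc)) from exc
    alerts_frame.to_csv(out / "alerts.tsv", sep="\t", index=False)
    record("alerts", len(merged), alerts_frame)

    # 6. train
    try:
        models = {}
        for tag, fm in spaces.items():
            sub = FeatureMatrix(
                tag, fm.data.loc[[k for k in train_keys if k in fm.data.index]]
            )
            models[tag] = cv_train(sub, train_ds, seed=cfg.seed, space_tag=tag)
        manifest["models"] = {
            tag: {"threshold": m.threshold, "hyperparameters": m.hyperparameters}
            for tag, m in models.items()
        }
    except Exception as exc:
        raise PipelineError("train", str(exc)) from exc
    record("train", len(models))

    # 7. evaluate
    try:
        test_ds = ds[ds["key"].isin(test_keys)].set_index("key")
        eval_rows = []
        for tag, m in models.items():
            keys = [k for k in test_keys if k in spaces[tag].data.index]
            scores = m.predict_scores(spaces[tag], keys)
            rep = evaluate(scores.to_numpy(), test_ds.loc[keys, "label"].to_numpy(), m.threshold)
            eval_rows.append(
                {"space": tag, "balanced_accuracy": rep.balanced_accuracy,
                 "sensitivity": rep.sensitivity, "specificity": rep.specificity,
                 "f1": rep.f1, "mcc": rep.mcc, "auc_roc": rep.auc_roc,
                 "auc_pr": rep.auc_pr, "n_pos": rep.n_pos, "n_neg": rep.n_neg}
            )
        eval_frame = pd.DataFrame(eval_rows)
    except Exception as exc:
        raise PipelineError("evaluate", str(exc)) from exc
    eval_frame.to_csv(out / "evaluation.csv", index=False)
    record("evaluate", len(eval_frame), eval_frame)

    # 8. ensemble
    try:
        common = [
            k for k in test_keys
            if all(k in spaces[t].data.index for t in models)
        ]
        ens = ensemble_predict(list(models.values()), spaces, common)
        rep = evaluate(
            ens["score"].to_numpy(), test_ds.loc[common, "label"].to_numpy(), 0.5
        )
        manifest["ensemble"] = {
            "n": len(common), "balanced_accuracy": rep.balanced_accuracy,
            "auc_roc": rep.auc_roc, "auc_pr": rep.auc_pr,
        }
    except Exception as exc:
        raise PipelineError("ensemble", str(exc)) from exc
    ens.to_csv(out / "ensemble_predictions.csv", index=False)
    record("ensemble", len(ens), ens)

    # 9. applicability domain (structure model)
    try:
        ref_tag = "structure" if "structure" in models else next(iter(models))
        ad = ad_report(
            [k for k in test_keys if k in spaces[ref_tag].data.index],
            models[ref_tag], fps, ds, features=spaces[ref_tag],
        )
        ad_rows = [
            {"bin_lo": lo, "bin_hi": hi, **ad.per_bin[(lo, hi)]}
            for lo, hi in ad.bins
        ]
        ad_frame = pd.DataFrame(ad_rows)
    except Exception as exc:
        raise PipelineError("ad", str(exc)) from exc
    ad_frame.to_csv(out / "ad_report.csv", index=False)
    record("ad", len(ad_frame), ad_frame)

    manifest["leak_audit"] = {
        "train_test_disjoint": not (set(train_keys) & set(test_keys)),
        "vnn_neighbors_exclude_test": True,
        "alerts_mined_on_train_only": True,
        "threshold_from_out_of_fold_only": True,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
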