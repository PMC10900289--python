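"""Self-contained synthetic cardiotoxicity studies.

Generates datasets with the statistical structure the analysis
pipeline assumes, so every stage can be exercised and verified
offline: a three-category concern label with the real-world class
balance (most : less : no ≈ 299 : 443 : 278), a planted toxicophore
substructure carried by toxic compounds up to label noise,
class-shifted lognormal Cmax exposure, sparse multi-label mechanism
annotations enriched among toxic compounds, and partially missing
continuous omics profiles with a mean shift on a subset of
informative features (the targets for similarity-based imputation).

Molecules are assembled from a fixed vocabulary of chemically valid
building blocks so that fragment mining has realistic combinatorics;
all generated SMILES pass full standardization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .chemstd import StandardizationError, standardize_compound
from .features import FeatureMatrix

__all__ = ["SyntheticStudyConfig", "generate_compounds", "generate_auxiliary", "generate_study"]

# Building blocks: SMILES pieces that remain valid under plain string
# concatenation.  "Open" pieces can be extended by appending another
# piece; "terminal" pieces must end the molecule.
_OPEN_FRAGMENTS = [
    "C", "CC", "CCC", "CCCC", "C(C)C", "C(C)(C)C",
    "CO", "CCO", "OC", "CN", "CCN", "NC",
    "CS", "OCC", "N(C)C", "C=C", "CC=C",
    "C(=O)C", "C(=O)N", "C(=O)OC", "C(=O)NC",
    "c1ccccc1", "c1ccncc1", "c1ccc(C)cc1", "c1ccc(O)cc1",
    "c1ccc(N)cc1", "c1ccc(F)cc1", "c1ccc(Cl)cc1",
    "C1CCCCC1", "C1CCNCC1", "C1CCOCC1", "c1ccsc1", "c1ccoc1",
]
_TERMINAL_FRAGMENTS = [
    "F", "Cl", "Br", "C(F)(F)F", "C#N", "C(=O)O", "O", "N", "S",
]

#: The planted toxicophore: a nitro-aromatic ring (9 heavy atoms, so it
#: survives the small-fragment filter in alert merging).
DEFAULT_TOXICOPHORE = "O=[N+]([O-])c1ccccc1"
_TOXICOPHORE_PIECE = "c1ccc([N+](=O)[O-])cc1"  # connectable spelling

# DICTrank-like class balance: most 299, less 443, no 278.
_DEFAULT_PROPORTIONS = (299 / 1020, 443 / 1020, 278 / 1020)


@dataclass
class SyntheticStudyConfig:
    """Parameters of one synthetic study.

    Defaults mirror the real study conditions: 1020 compounds in the
    most/less/no proportions above; a 1 log10-unit class shift in Cmax
    (micromolar); 5% label noise on toxicophore carriage; 20
    annotation terms with 4-fold odds enrichment of the first three
    "mechanism" terms among toxic compounds; 100 omics features of
    which 10 are informative with a one-SD mean shift; 20% of
    compounds lacking an omics profile.
    """

    n_compounds: int = 1020
    concern_proportions: tuple = _DEFAULT_PROPORTIONS
    toxicophore_smarts: str = DEFAULT_TOXICOPHORE
    label_noise: float = 0.05
    cmax_log_mean_toxic: float = 0.5
    cmax_log_mean_nontoxic: float = -0.5
    cmax_log_sd: float = 1.0
    n_annotation_terms: int = 20
    annotation_enrichment: float = 4.0
    annotation_base_rate: float = 0.10
    n_mechanism_terms: int = 3
    n_omics_features: int = 100
    n_informative: int = 10
    omics_effect_size: float = 1.0
    missing_profile_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        total = float(sum(self.concern_proportions))
        if abs(total - 1.0) > 1e-6:
            raise ValueError("concern_proportions must sum to 1")
        if not 0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must lie in [0, 0.5)")
        if self.n_informative > self.n_omics_features:
            raise ValueError("n_informative exceeds n_omics_features")
        if not 0 <= self.missing_profile_fraction < 1:
            raise ValueError("missing_profile_fraction must lie in [0, 1)")
        if Chem.MolFromSmarts(self.toxicophore_smarts) is None:
            raise ValueError(
                f"invalid toxicophore pattern {self.toxicophore_smarts!r}"
            )


def _assemble_smiles(rng: np.random.Generator, with_toxicophore: bool) -> str:
    n_open = int(rng.integers(1, 4))
    pieces = [
        _OPEN_FRAGMENTS[rng.integers(len(_OPEN_FRAGMENTS))] for _ in range(n_open)
    ]
    if with_toxicophore:
        pos = int(rng.integers(0, len(pieces) + 1))
        pieces.insert(pos, _TOXICOPHORE_PIECE)
    if rng.random() < 0.5:
        pieces.append(_TERMINAL_FRAGMENTS[rng.integers(len(_TERMINAL_FRAGMENTS))])
    return "".join(pieces)


def generate_compounds(cfg: SyntheticStudyConfig) -> pd.DataFrame:
    """Generate the labeled compound table of a synthetic study.

    Concern categories are drawn from ``cfg.concern_proportions``
    (most/less → label 1, no → label 0); toxic compounds carry the
    toxicophore with probability 1 − label_noise, nontoxic compounds
    with probability label_noise.  All compounds standardize cleanly
    and match keys (standard InChI) are unique.  Deterministic in
    ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    patt = Chem.MolFromSmarts(cfg.toxicophore_smarts)
    categories = ("most", "less", "no")
    rows = []
    seen_keys: set[str] = set()
    for _ in range(cfg.n_compounds):
        concern = categories[
            rng.choice(3, p=np.asarray(cfg.concern_proportions, dtype=float))
        ]
        label = 0 if concern == "no" else 1
        wants_tox = (
            rng.random() > cfg.label_noise
            if label == 1
            else rng.random() < cfg.label_noise
        )
        for _attempt in range(200):
            raw = _assemble_smiles(rng, wants_tox)
            try:
                std = standardize_compound(raw)
            except StandardizationError:
                continue
            mol = Chem.MolFromSmiles(std.std_smiles)
            if mol is None or std.std_inchi in seen_keys:
                continue
            if mol.HasSubstructMatch(patt) != wants_tox:
                continue
            break
        else:  # pragma: no cover - vocabulary guarantees quick success
            raise RuntimeError("failed to assemble a valid synthetic compound")
        seen_keys.add(std.std_inchi)
        rows.append(
            {
                "key": std.std_inchi,
                "raw_smiles": raw,
                "std_smiles": std.std_smiles,
                "concern": concern,
                "label": label,
                "source": "DICTrank",
            }
        )
    return pd.DataFrame(rows)


def generate_auxiliary(cfg: SyntheticStudyConfig, compounds: pd.DataFrame) -> dict:
    """Generate the auxiliary data layers for a compound table.

    Returns a dict with ``cmax`` (DataFrame key/cmax_total/cmax_unbound,
    micromolar), ``annotations`` (key → set of term names) and
    ``omics`` (a FeatureMatrix missing a fraction of compounds).
    """
    rng = np.random.default_rng(cfg.seed + 1)
    labels = compounds["label"].to_numpy(dtype=int)
    keys = list(compounds["key"])
    n = len(keys)

    log_mean = np.where(
        labels == 1, cfg.cmax_log_mean_toxic, cfg.cmax_log_mean_nontoxic
    )
    log_total = rng.normal(log_mean, cfg.cmax_log_sd)
    fu = rng.uniform(0.01, 1.0, size=n)  # free (unbound) fraction
    cmax = pd.DataFrame(
        {
            "key": keys,
            "cmax_total": 10.0 ** log_total,
            "cmax_unbound": 10.0 ** log_total * fu,
        }
    )

    terms = [f"term_{i:02d}" for i in range(cfg.n_annotation_terms)]
    base_odds = cfg.annotation_base_rate / (1.0 - cfg.annotation_base_rate)
    p_enriched = (base_odds * cfg.annotation_enrichment) / (
        1.0 + base_odds * cfg.annotation_enrichment
    )
    annotations: dict[str, set] = {}
    for i, key in enumerate(keys):
        chosen = set()
        for j, term in enumerate(terms):
            p = (
                p_enriched
                if (labels[i] == 1 and j < cfg.n_mechanism_terms)
                else cfg.annotation_base_rate
            )
            if rng.random() < p:
                chosen.add(term)
        annotations[key] = chosen

    names = [f"omics_{i:03d}" for i in range(cfg.n_omics_features)]
    values = rng.normal(0.0, 1.0, size=(n, cfg.n_omics_features))
    values[labels == 1, : cfg.n_informative] += cfg.omics_effect_size
    n_missing = int(round(cfg.missing_profile_fraction * n))
    missing_idx = set(rng.choice(n, size=n_missing, replace=False)) if n_missing else set()
    present = [i for i in range(n) if i not in missing_idx]
    omics = FeatureMatrix(
        "omics_morphology",
        pd.DataFrame(values[present], index=[keys[i] for i in present], columns=names),
    )
    return {"cmax": cmax, "annotations": annotations, "omics": omics}


def generate_study(cfg: SyntheticStudyConfig | None = None) -> dict:
    """Generate a full synthetic study (compounds + auxiliary layers)."""
    cfg = cfg or SyntheticStudyConfig()
    compounds = generate_compounds(cfg)
    aux = generate_auxiliary(cfg, compounds)
    return {"config": cfg, "compounds": compounds, **aux}
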