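"""Structural-alert mining.

Substructures that discriminate cardiotoxic from noncardiotoxic
compounds are mined by recursive fragmentation: acyclic single bonds
are cleaved recursively (rings kept intact), producing every connected
fragment reachable by bond cuts, bounded to 2–18 heavy atoms.
Fragments pooled from a chosen compound set (all compounds, or toxic
compounds only) are counted over the full dataset; those occurring at
least five times are scored by positive predictive value
(PPV = toxic occurrences / occurrences).  Alert lists from the two
mining settings are merged, low-PPV and tiny/generic fragments
removed, and the surviving alerts can screen external compound sets
(with overlap exclusion to avoid information leakage).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from .chemstd import StandardizationError

__all__ = [
    "StructuralAlert",
    "enumerate_fragments",
    "mine_alerts",
    "mine_alert_settings",
    "filter_and_merge",
    "screen_compounds",
    "reporting_view",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class StructuralAlert:
    """A mined substructure pattern with its occurrence statistics."""

    pattern: str  # fragment as canonical SMILES, usable as SMARTS
    n_atoms: int
    occurrences: int
    positives: int
    ppv: float
    setting: str  # all_compounds | toxic_only
    scheme: str  # binary_label | most_concern


def _mol(smiles: str) -> Chem.Mol:
    m = Chem.MolFromSmiles(smiles)
    if m is None:
        raise StandardizationError(f"invalid SMILES: {smiles!r}")
    return m


def _cuttable_bonds(mol: Chem.Mol) -> list[int]:
    """Acyclic single, non-aromatic bonds — the only ones cleaved."""
    return [
        b.GetIdx()
        for b in mol.GetBonds()
        if b.GetBondType() == Chem.BondType.SINGLE
        and not b.GetIsAromatic()
        and not b.IsInRing()
    ]


def enumerate_fragments(
    std_smiles: str, min_atoms: int = 2, max_atoms: int = 18
) -> set[str]:
    """All connected fragments reachable by recursive single-bond cuts.

    Rings are never opened.  Fragments are returned as canonical
    SMILES (interpretable as substructure patterns) and restricted to
    ``min_atoms``–``max_atoms`` heavy atoms.  Every returned fragment
    substructure-matches its parent molecule.
    """
    parent = _mol(std_smiles)
    results: set[str] = set()
    visited: set[str] = set()

    def rec(mol: Chem.Mol) -> None:
        smi = Chem.MolToSmiles(mol)
        if smi in visited:
            return
        visited.add(smi)
        n = mol.GetNumHeavyAtoms()
        if min_atoms <= n <= max_atoms:
            results.add(smi)
        if n <= min_atoms:
            return
        for bidx in _cuttable_bonds(mol):
            try:
                broken = Chem.FragmentOnBonds(mol, [bidx], addDummies=False)
                pieces = Chem.GetMolFrags(
                    broken, asMols=True, sanitizeFrags=True
                )
            except Exception:  # rare sanitization failure on a cut piece
                continue
            for piece in pieces:
                rec(piece)

    rec(parent)
    # soundness guard: keep only fragments that match the parent
    sound = set()
    for smi in results:
        patt = Chem.MolFromSmarts(smi)
        if patt is not None and parent.HasSubstructMatch(patt):
            sound.add(smi)
        else:
            log.debug("dropping unsound fragment %r of %r", smi, std_smiles)
    return sound


class _SubstructureIndex:
    """Packed pattern-fingerprint prescreen + exact verification.

    A molecule can only contain a pattern if every bit of the
    pattern's RDKit pattern-fingerprint is set in the molecule's;
    the bitwise prescreen is vectorized over packed uint8 words and
    survivors are verified with a real substructure match.
    """

    def __init__(self, smiles: list[str]):
        self.mols = [_mol(s) for s in smiles]
        fps = [
            np.frombuffer(
                Chem.PatternFingerprint(m, fpSize=2048).ToBitString().encode(), "u1"
            )
            - ord("0")
            for m in self.mols
        ]
        self.packed = np.packbits(np.array(fps, dtype=np.uint8), axis=1)

    def match_mask(self, pattern_smiles: str) -> np.ndarray:
        pmol = Chem.MolFromSmiles(pattern_smiles)
        patt = Chem.MolFromSmarts(pattern_smiles)
        if pmol is None or patt is None:
            raise ValueError(f"invalid alert pattern {pattern_smiles!r}")
        pfp = (
            np.frombuffer(
                Chem.PatternFingerprint(pmol, fpSize=2048).ToBitString().encode(),
                "u1",
            )
            - ord("0")
        )
        ppacked = np.packbits(pfp.astype(np.uint8))
        candidates = np.where(
            ~np.any(ppacked & ~self.packed, axis=1)
        )[0]
        mask = np.zeros(len(self.mols), dtype=bool)
        for i in candidates:
            if self.mols[i].HasSubstructMatch(patt):
                mask[i] = True
        return mask


def _scheme_labels(ds: pd.DataFrame, scheme: str) -> pd.DataFrame:
    if scheme == "binary_label":
        out = ds[ds["label"].notna()]
    elif scheme == "most_concern":
        out = ds[ds["concern"].isin(["most", "no"])].copy()
        out["label"] = (out["concern"] == "most").astype(int)
    else:
        raise ValueError(f"unknown alert scheme {scheme!r}")
    return out.reset_index(drop=True)


def mine_alert_settings(
    ds: pd.DataFrame,
    min_occurrence: int = 5,
    scheme: str = "binary_label",
    min_atoms: int = 2,
    max_atoms: int = 18,
) -> dict[str, list[StructuralAlert]]:
    """Mine both settings (all_compounds, toxic_only) in one pass.

    Fragment enumeration and substructure counting are shared between
    the settings: the toxic-only candidate pool is a subset of the
    all-compounds pool and the occurrence counts are identical, so
    each pattern is matched against the dataset once.
    """
    if len(ds) == 0:
        raise ValueError("empty dataset")
    data = _scheme_labels(ds, scheme)
    if len(data) == 0:
        raise ValueError(f"no labeled compounds under scheme {scheme!r}")
    labels = data["label"].to_numpy(dtype=int)

    pool_all: set[str] = set()
    pool_toxic: set[str] = set()
    for smi, lab in zip(data["std_smiles"], labels):
        frags = enumerate_fragments(smi, min_atoms=min_atoms, max_atoms=max_atoms)
        pool_all |= frags
        if lab == 1:
            pool_toxic |= frags

    index = _SubstructureIndex(list(data["std_smiles"]))
    out: dict[str, list[StructuralAlert]] = {"all_compounds": [], "toxic_only": []}
    for pattern in sorted(pool_all):
        mask = index.match_mask(pattern)
        occ = int(mask.sum())
        if occ < min_occurrence:
            continue
        pos = int(labels[mask].sum())
        base = StructuralAlert(
            pattern=pattern,
            n_atoms=Chem.MolFromSmiles(pattern).GetNumHeavyAtoms(),
            occurrences=occ,
            positives=pos,
            ppv=pos / occ,
            setting="all_compounds",
            scheme=scheme,
        )
        out["all_compounds"].append(base)
        if pattern in pool_toxic:
            out["toxic_only"].append(replace(base, setting="toxic_only"))
    return out


def mine_alerts(
    ds: pd.DataFrame,
    min_occurrence: int = 5,
    setting: str = "all_compounds",
    scheme: str = "binary_label",
    min_atoms: int = 2,
    max_atoms: int = 18,
) -> list[StructuralAlert]:
    """Mine substructure alerts from a labeled dataset.

    ``setting`` selects whose fragments enter the candidate pool
    (``all_compounds`` or ``toxic_only``); occurrence and PPV counting
    always runs over the full dataset under the chosen label
    ``scheme`` (``binary_label``: toxic=1 vs nontoxic=0;
    ``most_concern``: most=1 vs no=0, less-concern excluded).
    Occurrences are counted per compound (a compound either contains
    the pattern or not).
    """
    if setting not in ("all_compounds", "toxic_only"):
        raise ValueError(f"unknown mining setting {setting!r}")
    if len(ds) == 0:
        raise ValueError("empty dataset")
    data = _scheme_labels(ds, scheme)
    if len(data) == 0:
        raise ValueError(f"no labeled compounds under scheme {scheme!r}")

    if setting == "toxic_only":
        sources = data[data["label"] == 1]["std_smiles"]
    else:
        sources = data["std_smiles"]

    pool: set[str] = set()
    for smi in sources:
        pool |= enumerate_fragments(smi, min_atoms=min_atoms, max_atoms=max_atoms)

    index = _SubstructureIndex(list(data["std_smiles"]))
    labels = data["label"].to_numpy(dtype=int)
    alerts = []
    for pattern in sorted(pool):
        mask = index.match_mask(pattern)
        occ = int(mask.sum())
        if occ < min_occurrence:
            continue
        pos = int(labels[mask].sum())
        alerts.append(
            StructuralAlert(
                pattern=pattern,
                n_atoms=Chem.MolFromSmiles(pattern).GetNumHeavyAtoms(),
                occurrences=occ,
                positives=pos,
                ppv=pos / occ,
                setting=setting,
                scheme=scheme,
            )
        )
    return alerts


_DEFAULT_BLOCKLIST = ("c1ccccc1",)  # generic scaffolds, e.g. benzene


def filter_and_merge(
    alerts_a: list[StructuralAlert],
    alerts_b: list[StructuralAlert],
    min_ppv: float = 0.5,
    min_atoms_keep: int = 5,
    blocklist: tuple[str, ...] = _DEFAULT_BLOCKLIST,
) -> list[StructuralAlert]:
    """Merge alert lists from the two mining settings and filter.

    Union by pattern (the higher-occurrence record wins a collision);
    drops alerts with PPV below ``min_ppv``, alerts smaller than
    ``min_atoms_keep`` heavy atoms, and generic scaffolds on the
    blocklist (default: benzene).
    """
    blocked = {Chem.MolToSmiles(_mol(s)) for s in blocklist}
    merged: dict[str, StructuralAlert] = {}
    for alert in list(alerts_a) + list(alerts_b):
        prev = merged.get(alert.pattern)
        if prev is None or alert.occurrences > prev.occurrences:
            merged[alert.pattern] = alert
    out = [
        a
        for a in merged.values()
        if a.ppv >= min_ppv and a.n_atoms >= min_atoms_keep and a.pattern not in blocked
    ]
    return sorted(out, key=lambda a: (-a.ppv, -a.occurrences, a.pattern))


def reporting_view(
    alerts: list[StructuralAlert], min_occurrences: int = 10, min_ppv: float = 0.6
) -> list[StructuralAlert]:
    """High-confidence view: occurrences > 10 and PPV > 0.6."""
    return [
        a for a in alerts if a.occurrences > min_occurrences and a.ppv > min_ppv
    ]


def screen_compounds(
    compounds: dict[str, str],
    alerts: list[StructuralAlert],
    exclude_keys: set[str] | frozenset[str] = frozenset(),
) -> pd.DataFrame:
    """Screen external compounds for alert substructures.

    ``compounds`` maps key → standardized SMILES.  Compounds whose key
    is in ``exclude_keys`` (overlap with the training data) are
    skipped with a logged count.  The hit table keeps zero-hit rows.
    """
    patterns = {}
    for a in alerts:
        q = Chem.MolFromSmarts(a.pattern)
        if q is None:
            raise ValueError(f"invalid alert pattern {a.pattern!r}")
        patterns[a.pattern] = q
    rows = []
    skipped = 0
    for key, smi in compounds.items():
        if key in exclude_keys:
            skipped += 1
            continue
        mol = _mol(smi)
        hits = [p for p, q in patterns.items() if mol.HasSubstructMatch(q)]
        rows.append({"key": key, "std_smiles": smi, "n_hits": len(hits), "hits": hits})
    if skipped:
        log.info("screen_compounds: skipped %d overlapping compounds", skipped)
    out = pd.DataFrame(rows, columns=["key", "std_smiles", "n_hits", "hits"])
    out.attrs["n_skipped"] = skipped
    return out


def alerts_to_frame(alerts: list[StructuralAlert]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (a.pattern, a.n_atoms, a.occurrences, a.positives, a.ppv, a.setting, a.scheme)
            for a in alerts
        ],
        columns=["pattern", "n_atoms", "occurrences", "positives", "ppv", "setting", "scheme"],
    )


def save_alerts(alerts: list[StructuralAlert], path: str | Path) -> None:
    alerts_to_frame(alerts).to_csv(path, sep="\t", index=False)
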