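"""Deterministic chemical standardization.

Every compound entering the analysis is reduced to a single canonical
representation: the raw SMILES is cleaned up, stripped to its largest
organic fragment, neutralized and tautomer-normalized, iterating until
the canonical SMILES reaches a fixed point; the result is then
protonated to its expected ionization state at physiological pH
(7.4) and a standard InChI is derived for cross-dataset matching.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass

from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "StandardizationError",
    "StandardizedCompound",
    "standardize_compound",
    "match_key",
]


class StandardizationError(ValueError):
    """Raised when a SMILES cannot be parsed or standardized."""


@dataclass(frozen=True)
class StandardizedCompound:
    """A compound after full standardization.

    Attributes
    ----------
    raw_smiles : str
        The input SMILES as supplied.
    std_smiles : str
        Canonical isomeric SMILES after the cleanup/neutralize/tautomer
        loop, protonated at the requested pH.
    std_inchi : str
        Standard InChI derived from ``std_smiles``; the join key used
        for all cross-dataset matching.
    n_iterations : int
        Number of standardization iterations performed (>= 1).
    converged : bool
        Whether consecutive iterations produced identical canonical
        SMILES within the iteration budget.
    """

    raw_smiles: str
    std_smiles: str
    std_inchi: str
    n_iterations: int
    converged: bool


# Ionization rules applied at physiological pH.  Each entry is
# (name, SMARTS for the ionizable atom, site pKa, 'acid'|'base').
# Acids with pKa < pH lose a proton; bases with conjugate-acid
# pKa > pH gain one.  Values are textbook numbers for the group.
_PKA_RULES: list[tuple[str, str, float, str]] = [
    ("sulfonic_acid", "[SX4](=O)(=O)[OX2H1]", -1.0, "acid"),
    ("sulfinic_acid", "[SX3](=O)[OX2H1]", 2.0, "acid"),
    ("phosphonic_acid_1", "[PX4](=O)([OX2H1])[OX2H1]", 2.0, "acid"),
    ("carboxylic_acid", "[CX3](=O)[OX2H1]", 4.8, "acid"),
    ("tetrazole", "[nX3H1]1nnnc1", 4.9, "acid"),
    ("phenol", "[c][OX2H1]", 10.0, "acid"),
    ("thiol", "[CX4][SX2H1]", 10.5, "acid"),
    # Guanidines / amidines: strongly basic.
    ("guanidine", "[NX3][CX3](=[NX2])[NX3]", 13.0, "base"),
    ("amidine", "[CX3](=[NX2])[NX3;!$(N[a])]", 11.0, "base"),
    # Aliphatic amines (not amide/sulfonamide N, not attached to
    # aromatic ring, not N-oxide/hydrazine-adjacent heteroatom).
    (
        "aliphatic_amine",
        "[NX3;H0,H1,H2;!$(NC=[O,S,N]);!$(NS(=O)=O);!$(N[a]);!$(N=*);"
        "!$(N[O,N]);!$(NC=C);$(N[CX4])]",
        10.5,
        "base",
    ),
    # Weak bases left neutral at 7.4: aniline (~4.6), pyridine (~5.2),
    # imidazole (~7.0).  Listed for documentation; no charge change.
    ("aniline", "[NX3;H1,H2;$(N[a])]", 4.6, "base"),
    ("pyridine", "[nX2;$(n1ccccc1)]", 5.2, "base"),
]

_CLEANUP_PARAMS = rdMolStandardize.CleanupParameters()
_LARGEST = rdMolStandardize.LargestFragmentChooser(preferOrganic=True)
_UNCHARGER = rdMolStandardize.Uncharger()
_TAUTOMER = rdMolStandardize.TautomerEnumerator()


def _parse(smiles: str) -> Chem.Mol:
    if not isinstance(smiles, str) or not smiles.strip():
        raise StandardizationError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StandardizationError(f"unparseable SMILES: {smiles!r}")
    return mol


def _standardize_once(mol: Chem.Mol) -> Chem.Mol:
    """One pass: cleanup -> largest organic fragment -> neutralize ->
    tautomer canonicalization."""
    mol = rdMolStandardize.Cleanup(mol, _CLEANUP_PARAMS)
    mol = _LARGEST.choose(mol)
    mol = _UNCHARGER.uncharge(mol)
    mol = _TAUTOMER.Canonicalize(mol)
    return mol


def protonate_at_ph(mol: Chem.Mol, ph: float = 7.4) -> Chem.Mol:
    """Set formal charges of ionizable groups to their dominant state at `ph`.

    A rule table of SMARTS patterns with group pKa values is applied:
    acidic sites with pKa < ph are deprotonated, basic sites whose
    conjugate acid has pKa > ph are protonated.  Each atom is modified
    at most once (first matching rule wins, rules ordered strongest
    first), which yields a single deterministic protomer.
    """
    mol = Chem.RWMol(mol)
    touched: set[int] = set()
    for _name, smarts, pka, kind in _PKA_RULES:
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:  # pragma: no cover - rules are static
            continue
        ionize = (kind == "acid" and pka < ph) or (kind == "base" and pka > ph)
        for match in mol.GetSubstructMatches(patt):
            if kind == "acid":
                # the H-bearing O/S/N atom in the pattern
                site = next(
                    (
                        i
                        for i in match
                        if mol.GetAtomWithIdx(i).GetSymbol() in ("O", "S", "N")
                        and mol.GetAtomWithIdx(i).GetTotalNumHs() > 0
                    ),
                    None,
                )
            else:
                site = next(
                    (
                        i
                        for i in match
                        if mol.GetAtomWithIdx(i).GetSymbol() == "N"
                        and mol.GetAtomWithIdx(i).GetFormalCharge() == 0
                        and not mol.GetAtomWithIdx(i).GetIsAromatic()
                    ),
                    None,
                )
            if site is None or site in touched:
                continue
            touched.add(site)
            if not ionize:
                continue
            atom = mol.GetAtomWithIdx(site)
            if kind == "acid":
                atom.SetFormalCharge(-1)
                atom.SetNumExplicitHs(max(0, atom.GetTotalNumHs() - 1))
                atom.SetNoImplicit(True)
            else:
                atom.SetFormalCharge(1)
                atom.SetNumExplicitHs(atom.GetTotalNumHs() + 1)
                atom.SetNoImplicit(True)
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return out


def standardize_compound(
    raw_smiles: str, max_iterations: int = 5, ph: float = 7.4
) -> StandardizedCompound:
    """Standardize a SMILES string to a canonical, pH-adjusted form.

    The cleanup → largest-fragment → neutralize → tautomer-normalize
    cycle is iterated until the canonical SMILES repeats (fixed point)
    or ``max_iterations`` is reached; on non-convergence the most
    frequent SMILES across iterations is used (ties broken by taking
    the lexicographically smallest).  Protonation at ``ph`` is applied
    once, after the loop, so that re-entering neutralization cannot
    undo it.

    Raises
    ------
    StandardizationError
        If ``raw_smiles`` is empty or does not parse.
    """
    mol = _parse(raw_smiles)

    seen: list[str] = []
    current = mol
    converged = False
    n_iter = 0
    for _ in range(max_iterations):
        n_iter += 1
        try:
            current = _standardize_once(current)
        except Exception as exc:  # rdkit sanitization failure
            raise StandardizationError(
                f"standardization failed for {raw_smiles!r}: {exc}"
            ) from exc
        smi = Chem.MolToSmiles(current)
        if seen and smi == seen[-1]:
            converged = True
            seen.append(smi)
            break
        seen.append(smi)

    if converged:
        final_smi = seen[-1]
    else:
        counts = collections.Counter(seen)
        top = max(counts.values())
        final_smi = min(s for s, c in counts.items() if c == top)

    final = protonate_at_ph(Chem.MolFromSmiles(final_smi), ph=ph)
    std_smiles = Chem.MolToSmiles(final)
    std_inchi = Chem.MolToInchi(final, treatWarningAsError=False)
    if not std_inchi:
        raise StandardizationError(f"InChI generation failed for {raw_smiles!r}")
    return StandardizedCompound(
        raw_smiles=raw_smiles,
        std_smiles=std_smiles,
        std_inchi=std_inchi,
        n_iterations=n_iter,
        converged=converged,
    )


def match_key(compound: StandardizedCompound) -> str:
    """Join key for cross-dataset matching: the standard InChI."""
    return compound.std_inchi
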