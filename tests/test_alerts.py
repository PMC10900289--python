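"""Fragment enumeration, alert mining, merging filters, screening."""

import itertools

import pandas as pd
import pytest
from rdkit import Chem

from dictox.alerts import (
    StructuralAlert,
    enumerate_fragments,
    filter_and_merge,
    mine_alert_settings,
    mine_alerts,
    reporting_view,
    screen_compounds,
)

TOXICOPHORE = "O=[N+]([O-])c1ccccc1"


def subset_oracle(smiles: str, min_atoms: int = 2, max_atoms: int = 18) -> set:
    """Independent fragment oracle: enumerate every connected atom subset
    whose boundary consists only of acyclic single bonds."""
    mol = Chem.MolFromSmiles(smiles)
    n = mol.GetNumAtoms()
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(),
         b.GetBondType() == Chem.BondType.SINGLE
         and not b.GetIsAromatic() and not b.IsInRing())
        for b in mol.GetBonds()
    ]
    frags = set()
    for mask in range(1, 1 << n):
        subset = {i for i in range(n) if mask >> i & 1}
        if not (min_atoms <= len(subset) <= max_atoms):
            continue
        internal = [(i, j) for i, j, _ in bonds if i in subset and j in subset]
        boundary_ok = all(
            cuttable
            for i, j, cuttable in bonds
            if (i in subset) != (j in subset)
        )
        if not boundary_ok:
            continue
        # connectivity over internal bonds
        seen = {next(iter(subset))}
        frontier = list(seen)
        while frontier:
            cur = frontier.pop()
            for i, j in internal:
                for a, b in ((i, j), (j, i)):
                    if a == cur and b not in seen:
                        seen.add(b)
                        frontier.append(b)
        if seen != subset:
            continue
        smi = Chem.MolFragmentToSmiles(mol, atomsToUse=sorted(subset))
        m2 = Chem.MolFromSmiles(smi)
        if m2 is not None:
            frags.add(Chem.MolToSmiles(m2))
    return frags


class TestEnumerateFragments:
    def test_ethane_has_single_fragment(self):
        assert enumerate_fragments("CC") == {"CC"}

    def test_ethanol_fragments_by_hand(self):
        # cuts of the 3-atom chain: C-C and C-O pieces plus the parent
        assert enumerate_fragments("CCO") == {"CCO", "CC", "CO"}

    @pytest.mark.parametrize(
        "smiles",
        ["CCOc1ccccc1", "CC(C)CC(=O)O", "c1ccc(CN)cc1", "C1CCCCC1CO",
         "CC(=O)Nc1ccsc1"],
    )
    def test_matches_exhaustive_subset_oracle(self, smiles):
        assert enumerate_fragments(smiles) == subset_oracle(smiles)

    @pytest.mark.parametrize(
        "smiles", ["CCOc1ccc([N+](=O)[O-])cc1", "CC(C)c1ccncc1CO"]
    )
    def test_every_fragment_matches_parent(self, smiles):
        parent = Chem.MolFromSmiles(smiles)
        for frag in enumerate_fragments(smiles):
            patt = Chem.MolFromSmarts(frag)
            assert parent.HasSubstructMatch(patt), frag

    def test_size_bounds_enforced(self):
        frags = enumerate_fragments("CCCCCCCC", min_atoms=3, max_atoms=5)
        sizes = {Chem.MolFromSmiles(f).GetNumHeavyAtoms() for f in frags}
        assert sizes <= {3, 4, 5}

    def test_invalid_smiles_rejected(self):
        with pytest.raises(Exception):
            enumerate_fragments("nope(")


def _planted_dataset():
    """20 toxic compounds all carrying a nitrophenyl, 20 plain nontoxic."""
    toxic = [f"{'C' * i}c1ccc([N+](=O)[O-])cc1" for i in range(1, 21)]
    nontoxic = [f"{'C' * i}O" for i in range(2, 22)]
    return pd.DataFrame(
        {
            "key": [f"t{i}" for i in range(20)] + [f"n{i}" for i in range(20)],
            "std_smiles": toxic + nontoxic,
            "concern": ["most"] * 20 + ["no"] * 20,
            "label": [1] * 20 + [0] * 20,
        }
    )


class TestMineAlerts:
    def test_planted_fragment_recovered_with_perfect_ppv(self):
        alerts = mine_alerts(_planted_dataset(), setting="all_compounds")
        patt = Chem.MolFromSmarts(TOXICOPHORE)
        hits = [
            a for a in alerts
            if Chem.MolFromSmiles(a.pattern).HasSubstructMatch(patt)
        ]
        assert hits
        assert any(a.occurrences == 20 and a.ppv == 1.0 for a in hits)

    def test_mixed_occurrence_ppv(self):
        # pyridine in 8 toxic + 2 nontoxic compounds -> ppv 0.8
        toxic = [f"{'C' * i}c1ccncc1" for i in range(1, 9)]
        nontoxic = [f"{'O' if i % 2 else 'N'}{'C' * i}c1ccncc1" for i in (3, 4)]
        filler = [f"{'C' * i}S" for i in range(2, 12)]
        ds = pd.DataFrame(
            {
                "key": [f"c{i}" for i in range(20)],
                "std_smiles": toxic + nontoxic + filler,
                "concern": ["most"] * 8 + ["no"] * 12,
                "label": [1] * 8 + [0] * 12,
            }
        )
        alerts = mine_alerts(ds, setting="all_compounds")
        pyridine = [a for a in alerts if a.pattern == "c1ccncc1"]
        assert len(pyridine) == 1
        assert pyridine[0].occurrences == 10
        assert pyridine[0].ppv == pytest.approx(0.8)

    def test_min_occurrence_threshold(self):
        ds = _planted_dataset()
        rare = mine_alerts(ds, min_occurrence=25, setting="all_compounds")
        assert all(a.occurrences >= 25 for a in rare)

    def test_toxic_only_pool_subset_of_all(self):
        ds = _planted_dataset()
        both = mine_alert_settings(ds)
        all_patterns = {a.pattern for a in both["all_compounds"]}
        toxic_patterns = {a.pattern for a in both["toxic_only"]}
        assert toxic_patterns <= all_patterns
        # nontoxic-only chains are not in the toxic pool
        assert any("[N+]" in p for p in toxic_patterns)

    def test_most_concern_scheme_excludes_less(self):
        ds = _planted_dataset()
        ds.loc[0:4, "concern"] = "less"
        alerts = mine_alerts(ds, scheme="most_concern", setting="all_compounds")
        # counting base shrinks: no alert can occur more than 35 times
        assert all(a.occurrences <= 35 for a in alerts)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            mine_alerts(_planted_dataset().iloc[0:0])


def _alert(pattern, n_atoms, occurrences, positives, setting="all_compounds"):
    return StructuralAlert(
        pattern=pattern, n_atoms=n_atoms, occurrences=occurrences,
        positives=positives, ppv=positives / occurrences,
        setting=setting, scheme="binary_label",
    )


class TestFilterAndMerge:
    def test_low_ppv_removed(self):
        kept = filter_and_merge([_alert("CCCCO", 5, 100, 49)], [])
        assert kept == []

    def test_small_fragment_removed(self):
        kept = filter_and_merge([_alert("CCCO", 4, 50, 50)], [])
        assert kept == []

    def test_benzene_blocklisted(self):
        kept = filter_and_merge([_alert("c1ccccc1", 6, 50, 50)], [])
        assert kept == []

    def test_duplicate_pattern_unions_to_higher_occurrence(self):
        a = _alert("CCCCN", 5, 30, 30)
        b = _alert("CCCCN", 5, 40, 36, setting="toxic_only")
        kept = filter_and_merge([a], [b])
        assert len(kept) == 1
        assert kept[0].occurrences == 40

    def test_filters_are_anti_monotone(self):
        alerts = [
            _alert("CCCCN", 5, 30, 20),
            _alert("CCCCO", 5, 12, 11),
            _alert("CCCCS", 5, 8, 5),
        ]
        loose = filter_and_merge(alerts, [], min_ppv=0.5)
        tight = filter_and_merge(alerts, [], min_ppv=0.9)
        assert len(tight) <= len(loose)

    def test_reporting_view_convention(self):
        alerts = [
            _alert("CCCCN", 5, 11, 8),   # occ > 10, ppv 0.73 -> in view
            _alert("CCCCO", 5, 10, 9),   # occ not > 10 -> out
            _alert("CCCCS", 5, 30, 17),  # ppv 0.57 -> out
        ]
        view = reporting_view(alerts)
        assert [a.pattern for a in view] == ["CCCCN"]


class TestScreenCompounds:
    def test_hits_and_zero_hit_rows(self):
        alerts = [_alert("O=[N+]([O-])c1ccccc1", 9, 20, 20)]
        table = screen_compounds(
            {"a": "CCc1ccc([N+](=O)[O-])cc1", "b": "CCCCO"}, alerts
        )
        assert table.loc[table["key"] == "a", "n_hits"].item() == 1
        assert table.loc[table["key"] == "b", "n_hits"].item() == 0

    def test_excluded_keys_skipped_and_counted(self):
        alerts = [_alert("CCO", 3, 5, 5)]
        table = screen_compounds(
            {"a": "CCO", "b": "CCO"}, alerts, exclude_keys={"a"}
        )
        assert set(table["key"]) == {"b"}
        assert table.attrs["n_skipped"] == 1

    def test_invalid_pattern_named(self):
        bad = _alert("C(((", 5, 5, 5)
        with pytest.raises(ValueError, match="C"):
            screen_compounds({"a": "CCO"}, [bad])
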