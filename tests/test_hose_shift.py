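from collections import Counter, deque

import numpy as np
import pytest
from rdkit import Chem

from nmrlogd.chemio import DataError, ShiftList
from nmrlogd.hose_shift import (ShiftTable, build_table, encode_hose,
                                predict_shifts, predict_shifts_detailed,
                                truncate_hose)
from nmrlogd.synthgen import generate_hose_world, molecule_with_shifts


def shell_multisets(mol, anchor, depth):
    """Independent brute-force oracle: per-shell multiset of atom environments.

    Shell k holds, for every atom at graph distance k from the anchor, a
    tuple (element, hydrogen count, sorted bond orders back to shell k-1).
    Anchors with graph-identical environments must agree on these
    multisets; distinct multisets prove distinct environments.
    """
    dist = {anchor: 0}
    q = deque([anchor])
    while q:
        i = q.popleft()
        for nbr in mol.GetAtomWithIdx(i).GetNeighbors():
            j = nbr.GetIdx()
            if j not in dist:
                dist[j] = dist[i] + 1
                q.append(j)
    shells = []
    for k in range(1, depth + 1):
        bag = []
        for j, d in dist.items():
            if d != k:
                continue
            atom = mol.GetAtomWithIdx(j)
            back = sorted(str(b.GetBondType()) for b in atom.GetBonds()
                          if dist.get(b.GetOtherAtom(atom).GetIdx(), -1) == k - 1)
            bag.append((atom.GetSymbol(),
                        atom.GetTotalNumHs(includeNeighbors=True), tuple(back)))
        shells.append(Counter(bag))
    return shells


def anchors(mol):
    return [a.GetIdx() for a in mol.GetAtoms()
            if a.GetTotalNumHs(includeNeighbors=True) > 0]


class TestEncodeHose:
    def test_ethane_symmetry(self):
        mol = Chem.MolFromSmiles("CC")
        for depth in (1, 2, 4):
            assert encode_hose(mol, 0, depth) == encode_hose(mol, 1, depth)

    def test_methane_vs_ethane_differ(self):
        methane = Chem.MolFromSmiles("C")
        ethane = Chem.MolFromSmiles("CC")
        assert encode_hose(methane, 0, 2) != encode_hose(ethane, 0, 2)

    def test_toluene_ortho_meta_distinct_with_oracle(self):
        tol = Chem.MolFromSmiles("Cc1ccccc1")
        # ring atom indices: 1 is ipso; 2 and 6 ortho; 3 and 5 meta; 4 para
        ortho, meta = 2, 3
        assert encode_hose(tol, ortho, 3) != encode_hose(tol, meta, 3)
        assert shell_multisets(tol, ortho, 3) != shell_multisets(tol, meta, 3)
        # and the symmetric pairs agree on both views
        assert encode_hose(tol, 2, 3) == encode_hose(tol, 6, 3)
        assert shell_multisets(tol, 2, 3) == shell_multisets(tol, 6, 3)

    @pytest.mark.parametrize("smiles", ["CCO", "CC(C)=O", "COc1ccc(CC)cc1",
                                        "C1CCOC1", "Cc1ccncc1"])
    def test_equal_codes_imply_equal_shell_multisets(self, smiles):
        mol = Chem.MolFromSmiles(smiles)
        for depth in (2, 4):
            for i in anchors(mol):
                for j in anchors(mol):
                    if encode_hose(mol, i, depth) == encode_hose(mol, j, depth):
                        assert shell_multisets(mol, i, depth) == \
                            shell_multisets(mol, j, depth)

    @pytest.mark.parametrize("smiles,groups", [
        ("c1ccccc1", [[0, 1, 2, 3, 4, 5]]),           # benzene: all equivalent
        ("CC", [[0, 1]]),                             # ethane
        ("CC(C)=O", [[0, 2]]),                        # acetone methyls
    ])
    def test_automorphic_protons_share_codes(self, smiles, groups):
        mol = Chem.MolFromSmiles(smiles)
        for group in groups:
            codes = {encode_hose(mol, i, 6) for i in group}
            assert len(codes) == 1

    @pytest.mark.parametrize("smiles", ["CCO", "Cc1ccccc1", "CC(C)=O",
                                        "C1CCOC1", "COc1ccc(CC)cc1"])
    def test_truncation_matches_shallow_encoding(self, smiles):
        mol = Chem.MolFromSmiles(smiles)
        for i in anchors(mol):
            deep = encode_hose(mol, i, 6)
            for s in range(1, 6):
                assert truncate_hose(deep, s) == encode_hose(mol, i, s)

    def test_anchor_without_hydrogen_rejected(self):
        acetone = Chem.MolFromSmiles("CC(C)=O")   # atom 1 = carbonyl C, no H
        with pytest.raises(DataError, match="no hydrogen"):
            encode_hose(acetone, 1, 3)


class TestBuildTable:
    def test_equivalent_protons_single_entry(self):
        benzene = Chem.MolFromSmiles("c1ccccc1")
        sl = ShiftList("benzene", [2.0] * 6, h_indices=list(range(6)))
        table = build_table([(benzene, sl)], max_spheres=3)
        for depth in (1, 2, 3):
            frame = table.to_frame()
            sub = frame[frame["spheres"] == depth]
            assert len(sub) == 1
            assert sub.iloc[0]["mean_shift_ppm"] == 2.0
            assert sub.iloc[0]["count"] == 6

    def test_shared_code_arithmetic_mean(self):
        m1 = Chem.MolFromSmiles("C")
        m2 = Chem.MolFromSmiles("C")
        table = build_table([
            (m1, ShiftList("a", [1.0] * 4, h_indices=[0] * 4)),
            (m2, ShiftList("b", [3.0] * 4, h_indices=[0] * 4)),
        ], max_spheres=2)
        code = encode_hose(m1, 0, 1)
        assert table.mean_and_count(1, code) == (2.0, 8)

    def test_empty_training_set_warns(self, caplog):
        with caplog.at_level("WARNING", logger="nmrlogd"):
            table = build_table([], max_spheres=2)
        assert table.is_empty()
        assert "empty" in caplog.text

    def test_unmapped_shifts_rejected(self):
        mol = Chem.MolFromSmiles("CC")
        with pytest.raises(DataError, match="atom mapping"):
            build_table([(mol, ShiftList("ethane", [0.9] * 6))])

    def test_csv_round_trip(self, tmp_path, hose_world):
        training, _ = hose_world
        table = build_table(training[:4], max_spheres=3)
        path = str(tmp_path / "table.csv")
        table.to_csv(path)
        back = ShiftTable.from_csv(path)
        for depth in (1, 2, 3):
            for code in table._obs[depth]:
                assert back.mean_and_count(depth, code) == \
                    pytest.approx(table.mean_and_count(depth, code))


class TestPredictShifts:
    def test_training_set_reproduced_exactly(self, hose_world):
        """Max-depth prediction on the training set returns per-code means."""
        training, _ = hose_world
        table = build_table(training)
        # independent per-code aggregation straight from the training pairs
        expected: dict[str, list[float]] = {}
        for mol, sl in training:
            for shift, anchor in zip(sl.shifts, sl.h_indices):
                expected.setdefault(encode_hose(mol, anchor, 6), []).append(shift)
        for mol, sl in training:
            pred = predict_shifts(mol, table)
            by_anchor = dict(zip(pred.h_indices, pred.shifts))
            for anchor in set(sl.h_indices):
                code = encode_hose(mol, anchor, 6)
                assert by_anchor[anchor] == pytest.approx(
                    np.mean(expected[code]), abs=1e-12)

    def test_benzene_from_benzene_table(self):
        benzene = Chem.MolFromSmiles("c1ccccc1")
        sl = ShiftList("benzene", [7.26] * 6, h_indices=list(range(6)))
        pred = predict_shifts(benzene, build_table([(benzene, sl)]))
        assert len(pred) == 6
        assert len(np.unique(pred.shifts)) == 1
        assert pred.shifts[0] == pytest.approx(7.26, abs=1e-12)

    def test_sphere_fallback_hand_trace(self):
        """A 3-entry toy table: the deepest available sphere wins."""
        propane = Chem.MolFromSmiles("CCC")
        ch3 = propane.GetAtomWithIdx(0).GetIdx()
        table = ShiftTable(max_spheres=3)
        code2 = encode_hose(propane, ch3, 2)
        table.add(1, truncate_hose(code2, 1), 5.0)   # shallow decoy
        table.add(2, code2, 1.1)                     # the depth-2 hit
        table.add(1, "CH9|-X", 9.9)                  # unrelated entry
        pred, n_fallback = predict_shifts_detailed(propane, table, max_spheres=3)
        by_anchor = dict(zip(pred.h_indices, pred.shifts))
        assert by_anchor[ch3] == 1.1                 # depth 2 beats depth 1
        assert n_fallback == 2                       # central CH2 missed entirely

    def test_fallback_monotone_in_table_size(self, hose_world):
        training, held = hose_world
        small = build_table(training[:2])
        large = build_table(training)
        for mol in held:
            _, nf_small = predict_shifts_detailed(mol, small)
            _, nf_large = predict_shifts_detailed(mol, large)
            assert nf_large <= nf_small

    def test_held_out_with_full_sphere2_coverage_no_fallback(self, hose_world):
        training, held = hose_world
        table = build_table(training)
        hexane = next(m for m in held if m.GetProp("_Name") == "hexane")
        covered = all(
            any(table.lookup(d, truncate_hose(encode_hose(hexane, a, 6), d))
                is not None for d in range(1, 7))
            for a in anchors(hexane))
        assert covered
        _, n_fallback = predict_shifts_detailed(hexane, table)
        assert n_fallback == 0

    def test_empty_table_rejected(self):
        with pytest.raises(DataError, match="empty"):
            predict_shifts(Chem.MolFromSmiles("CC"), ShiftTable())

    def test_prediction_length_equals_hydrogen_count(self, hose_world):
        training, held = hose_world
        table = build_table(training)
        from nmrlogd.chemio import hydrogen_count
        for mol in held:
            assert len(predict_shifts(mol, table)) == hydrogen_count(mol)
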