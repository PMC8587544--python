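import math
from statistics import median

import numpy as np
import pytest
from rdkit import Chem

from vscreen.chem_data import (
    ConfigurationError,
    CurationConfig,
    DecoySpec,
    InputError,
    MoleculeRecord,
    assign_labels,
    cluster_representatives,
    largest_remainder_sizes,
    parse_activity_table,
    read_curated_csv,
    read_sdf,
    read_smiles_file,
    record_from_mol,
    record_to_mol,
    select_decoys,
    split_dataset,
    write_curated_csv,
    write_sdf,
)
from vscreen.fingerprints import BitFingerprint, ecfp4, tanimoto


def write_table(path, rows, header="id,smiles,pKi"):
    path.write_text("\n".join([header] + rows) + "\n")


class TestParseActivityTable:
    def test_all_valid(self, tmp_path):
        p = tmp_path / "t.csv"
        write_table(p, ["a,CCO,8.5", "b,c1ccccc1,5.0", "c,CCN,7.0"])
        result = parse_activity_table(p)
        assert len(result.records) == 3
        assert not result.rejected

    def test_unclosed_ring_rejected_and_reported(self, tmp_path):
        p = tmp_path / "t.csv"
        write_table(p, ["a,CCO,8.5", "bad,C1CC,7.0"])
        result = parse_activity_table(p)
        assert [r.id for r in result.records] == ["a"]
        assert result.rejected[0][0] == "bad"

    def test_duplicate_id_median_pki(self, tmp_path):
        p = tmp_path / "t.csv"
        write_table(p, ["a,CCO,8.0", "a,CCO,6.0", "a,CCO,9.0", "b,CCN,5.0"])
        result = parse_activity_table(p)
        rec = next(r for r in result.records if r.id == "a")
        assert rec.pKi == median([8.0, 6.0, 9.0])
        assert ("a", 3) in result.duplicates

    def test_missing_column(self, tmp_path):
        p = tmp_path / "t.csv"
        write_table(p, ["a,CCO"], header="id,smiles")
        with pytest.raises(ConfigurationError):
            parse_activity_table(p)

    def test_zero_parseable_rows(self, tmp_path):
        p = tmp_path / "t.csv"
        write_table(p, ["a,C1CC,8.0"])
        with pytest.raises(InputError):
            parse_activity_table(p)

    def test_tsv_format(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("id\tsmiles\tpKi\na\tCCO\t8.5\n")
        assert len(parse_activity_table(p, "tsv").records) == 1


class TestAssignLabels:
    CASES = [
        (8.5, "active"),
        (5.0, "inactive"),
        (7.0, "excluded"),
        (8.0, "excluded"),  # strict inequality at the boundary
        (6.0, "excluded"),
        (None, "unknown"),
    ]

    @pytest.mark.parametrize("pki,expected", CASES)
    def test_thresholds(self, pki, expected):
        rec = MoleculeRecord(id="x", smiles="CCO", pKi=pki)
        out = assign_labels([rec])
        assert out[0].label == expected

    def test_labeling_is_partition(self, rng):
        records = [
            MoleculeRecord(id=f"m{i}", smiles="CCO", pKi=float(p))
            for i, p in enumerate(rng.uniform(0, 12, size=200))
        ]
        labeled = assign_labels(records)
        assert all(r.label in ("active", "inactive", "excluded") for r in labeled)


class TestSplitDataset:
    def _records(self, n, label="active"):
        return [
            MoleculeRecord(id=f"m{i}", smiles="CCO", pKi=9.0, label=label)
            for i in range(n)
        ]

    def test_exact_ratios(self):
        train, test, val = split_dataset(self._records(10))
        assert (len(train), len(test), len(val)) == (7, 2, 1)

    def test_largest_remainder_1573(self):
        # oracle: largest-remainder apportionment of 1573 * (0.7, 0.2, 0.1)
        assert largest_remainder_sizes(1573, (0.7, 0.2, 0.1)) == [1101, 315, 157]
        train, test, val = split_dataset(self._records(1573))
        assert (len(train), len(test), len(val)) == (1101, 315, 157)

    def test_partition_no_overlap(self):
        records = self._records(50, "active") + self._records(31, "inactive")
        for i, r in enumerate(records):
            r.id = f"u{i}"
        train, test, val = split_dataset(records)
        ids = [r.id for part in (train, test, val) for r in part]
        assert sorted(ids) == sorted(r.id for r in records)

    def test_deterministic(self):
        records = self._records(37)
        a = split_dataset(records, CurationConfig(seed=42))
        b = split_dataset(records, CurationConfig(seed=42))
        assert [[r.id for r in part] for part in a] == [[r.id for r in part] for part in b]

    def test_stratification_proportions(self):
        records = self._records(70, "active") + [
            MoleculeRecord(id=f"i{i}", smiles="CCO", pKi=4.0, label="inactive")
            for i in range(30)
        ]
        train, test, val = split_dataset(records)
        for part, size in ((train, 70), (test, 20), (val, 10)):
            n_active = sum(1 for r in part if r.label == "active")
            expected = 0.7 * size
            assert abs(n_active - expected) < 1.0

    def test_small_stratum_warns(self):
        records = self._records(20, "active") + [
            MoleculeRecord(id="lone", smiles="CCO", pKi=4.0, label="inactive")
        ]
        with pytest.warns(UserWarning):
            split_dataset(records)

    def test_too_few_records(self):
        with pytest.raises(InputError):
            split_dataset(self._records(2))


class TestClusterRepresentatives:
    def test_each_own_cluster(self):
        fps = [ecfp4(s) for s in ("CCO", "c1ccccc1", "CCN")]
        assert cluster_representatives(fps, 3) == [0, 1, 2]

    def test_two_blobs(self):
        # oracle: brute-force — two families of close analogs must each
        # contribute exactly one medoid
        blob_a = ["CCCCCCCO", "CCCCCCCCO", "CCCCCCCCCO"]
        blob_b = ["c1ccc2ccccc2c1", "Cc1ccc2ccccc2c1", "CCc1ccc2ccccc2c1"]
        fps = [ecfp4(s) for s in blob_a + blob_b]
        reps = cluster_representatives(fps, 2)
        assert len(reps) == 2
        assert (reps[0] < 3) != (reps[1] < 3)

    def test_medoid_is_max_mean_similarity(self):
        smiles = ["CCCCCC", "CCCCCCC", "CCCCCCCC", "CCCCCCCCC"]
        fps = [ecfp4(s) for s in smiles]
        reps = cluster_representatives(fps, 1)
        sims = np.array([[tanimoto(a, b) for b in fps] for a in fps])
        expected = int(np.argmax(sims.mean(axis=1)))
        assert reps == [expected]

    def test_count_contract(self):
        fps = [ecfp4("C" * (i + 1)) for i in range(12)]
        assert len(cluster_representatives(fps, 8)) == 8

    def test_invalid_n_clusters(self):
        with pytest.raises(ValueError):
            cluster_representatives([ecfp4("C")], 0)


class TestSelectDecoys:
    def _actives(self):
        return [
            MoleculeRecord(id="act1", smiles="CCCCCCO", pKi=9.0, label="active"),
            MoleculeRecord(id="act2", smiles="c1ccccc1CCN", pKi=9.0, label="active"),
        ]

    def test_self_pool_rejected_by_similarity(self):
        actives = self._actives()
        pool = [
            MoleculeRecord(id=f"p{i}", smiles=a.smiles) for i, a in enumerate(actives)
        ]
        assert select_decoys(actives, pool, DecoySpec(max_tc_to_actives=0.75)) == []

    def test_brute_force_window_check(self):
        # oracle: independent per-candidate window + similarity check
        actives = self._actives()
        rng = np.random.default_rng(0)
        pool_smiles = [
            "CCCCCCN", "CCCCCO", "CCCCCCCO", "c1ccccc1CCO", "c1ccccc1CCC",
            "CCCCCCCCCCCCCCCCCCCC", "O", "c1ccc2ccccc2c1", "CCCCOC", "NCCCCCC",
        ]
        pool = [MoleculeRecord(id=f"p{i}", smiles=s) for i, s in enumerate(pool_smiles)]
        spec = DecoySpec(max_tc_to_actives=0.6)
        got = {r.id for r in select_decoys(actives, pool, spec)}

        from rdkit.Chem import Crippen, Descriptors, Lipinski

        expected = set()
        seen_canon = set()
        for rec in sorted(pool, key=lambda r: r.id):
            canon = Chem.CanonSmiles(rec.smiles)
            if canon in seen_canon:
                continue
            mol = Chem.MolFromSmiles(rec.smiles)
            props = (
                Descriptors.MolWt(mol), Crippen.MolLogP(mol),
                Lipinski.NumHDonors(mol), Lipinski.NumHAcceptors(mol),
                Lipinski.NumRotatableBonds(mol),
            )
            fits = False
            for a in self._actives():
                amol = Chem.MolFromSmiles(a.smiles)
                aprops = (
                    Descriptors.MolWt(amol), Crippen.MolLogP(amol),
                    Lipinski.NumHDonors(amol), Lipinski.NumHAcceptors(amol),
                    Lipinski.NumRotatableBonds(amol),
                )
                if (abs(props[0] - aprops[0]) <= 25 and abs(props[1] - aprops[1]) <= 1.0
                        and abs(props[2] - aprops[2]) <= 1 and abs(props[3] - aprops[3]) <= 1
                        and abs(props[4] - aprops[4]) <= 1):
                    fits = True
            tc = max(
                tanimoto(ecfp4(rec.smiles), ecfp4(a.smiles)) for a in self._actives()
            )
            if fits and tc <= 0.6:
                expected.add(rec.id)
                seen_canon.add(canon)
        assert got == expected

    def test_pool_order_invariance(self):
        actives = self._actives()
        pool = [
            MoleculeRecord(id=f"p{i}", smiles=s)
            for i, s in enumerate(["CCCCCCN", "CCCCCO", "c1ccccc1CCO", "CCCCOC"])
        ]
        spec = DecoySpec(max_tc_to_actives=0.6)
        fwd = [r.id for r in select_decoys(actives, pool, spec)]
        rev = [r.id for r in select_decoys(actives, pool[::-1], spec)]
        assert fwd == rev

    def test_per_active_cap(self):
        actives = [MoleculeRecord(id="a", smiles="CCCCCCO", pKi=9.0)]
        pool = [
            MoleculeRecord(id=f"p{i}", smiles="CCCCC" + "N" * (i % 2) + "O" * ((i + 1) % 2))
            for i in range(6)
        ]
        spec = DecoySpec(n_per_active=1, max_tc_to_actives=0.9)
        assert len(select_decoys(actives, pool, spec)) <= 1

    def test_empty_pool_warns(self):
        with pytest.warns(UserWarning):
            assert select_decoys(self._actives(), []) == []


class TestRoundTrips:
    def test_curated_csv(self, tmp_path):
        records = assign_labels([
            MoleculeRecord(id="a", smiles="OCC", pKi=8.5),
            MoleculeRecord(id="b", smiles="c1ccccc1", pKi=5.0),
            MoleculeRecord(id="c", smiles="CCN"),
        ])
        path = tmp_path / "curated.csv"
        write_curated_csv(path, records, {"a": "train", "b": "test"})
        back, splits = read_curated_csv(path)
        for orig, rec in zip(records, back):
            assert rec.id == orig.id
            assert Chem.CanonSmiles(rec.smiles) == Chem.CanonSmiles(orig.smiles)
            assert rec.pKi == orig.pKi
            assert rec.label == orig.label
        assert splits == {"a": "train", "b": "test"}

    def test_sdf_round_trip_with_conformer(self, tmp_path):
        mol = Chem.MolFromSmiles("CC=O")
        conf = Chem.Conformer(3)
        coords = [(0.0, 0.0, 0.0), (1.5, 0.0, 0.0), (2.2, 1.1, 0.0)]
        for i, xyz in enumerate(coords):
            conf.SetAtomPosition(i, xyz)
        mol.AddConformer(conf)
        rec = record_from_mol(mol, "mol1", pKi=7.5, label="excluded")
        path = tmp_path / "out.sdf"
        write_sdf(path, [rec])
        back = read_sdf(path)
        assert len(back) == 1
        assert back[0].id == "mol1"
        assert back[0].pKi == 7.5
        assert back[0].label == "excluded"
        assert Chem.CanonSmiles(back[0].smiles) == Chem.CanonSmiles("CC=O")
        # coordinates survive up to atom-order mapping: compare distance sets
        d_orig = sorted(
            round(float(np.linalg.norm(np.array(a) - np.array(b))), 4)
            for i, a in enumerate(coords) for b in coords[:i]
        )
        got = back[0].conformers[0]
        d_back = sorted(
            round(float(np.linalg.norm(got[i] - got[j])), 4)
            for i in range(3) for j in range(i)
        )
        assert d_orig == d_back

    def test_smiles_file(self, tmp_path):
        p = tmp_path / "lib.smi"
        p.write_text("CCO mol_a\nc1ccccc1 mol_b\n")
        records = read_smiles_file(p)
        assert [r.id for r in records] == ["mol_a", "mol_b"]


class TestRecordConformers:
    def test_conformer_shape_checked(self):
        rec = MoleculeRecord(id="x", smiles="CCO", conformers=[np.zeros((2, 3))])
        with pytest.raises(InputError):
            record_to_mol(rec)

    def test_record_from_mol_remaps_coordinates(self):
        # the canonical SMILES reorders atoms; stored coordinates must follow
        mol = Chem.MolFromSmiles("OCC")
        conf = Chem.Conformer(3)
        positions = {"O": (0.0, 0.0, 0.0), "C1": (1.4, 0.0, 0.0), "C2": (2.8, 0.5, 0.0)}
        conf.SetAtomPosition(0, positions["O"])
        conf.SetAtomPosition(1, positions["C1"])
        conf.SetAtomPosition(2, positions["C2"])
        mol.AddConformer(conf)
        rec = record_from_mol(mol, "x")
        rebuilt = record_to_mol(rec)
        pos = rebuilt.GetConformer().GetPositions()
        for atom in rebuilt.GetAtoms():
            if atom.GetSymbol() == "O":
                assert tuple(pos[atom.GetIdx()]) == pytest.approx(positions["O"])
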