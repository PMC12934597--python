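import pytest

from mgvs.chemio import parse_molecule
from mgvs.fingerprints import circular_fingerprint, path_fingerprint, tanimoto_distance


def rec(smiles, mol_id="m"):
    return parse_molecule(smiles, mol_id)


def test_identical_molecules_have_zero_distance():
    a, b = rec("c1ccccc1CCO", "a"), rec("OCCc1ccccc1", "b")
    assert tanimoto_distance(path_fingerprint(a), path_fingerprint(b)) == 0.0
    assert tanimoto_distance(circular_fingerprint(a), circular_fingerprint(b)) == 0.0


def test_distance_bounds_and_symmetry():
    mols = [rec(s, s) for s in ["CCO", "c1ccccc1", "CC(=O)Nc1ccc(O)cc1", "C1CCCC1"]]
    for fp in (path_fingerprint, circular_fingerprint):
        fps = [fp(m) for m in mols]
        for i in range(len(fps)):
            for j in range(len(fps)):
                d = tanimoto_distance(fps[i], fps[j])
                assert 0.0 <= d <= 1.0
                assert d == tanimoto_distance(fps[j], fps[i])
                if i == j:
                    assert d == 0.0


def test_similar_molecules_are_closer_than_dissimilar():
    benzene, toluene, chain = rec("c1ccccc1"), rec("Cc1ccccc1"), rec("CCCCCCCC")
    d_close = tanimoto_distance(path_fingerprint(benzene), path_fingerprint(toluene))
    d_far = tanimoto_distance(path_fingerprint(benzene), path_fingerprint(chain))
    assert d_close < d_far


def test_kind_mismatch_rejected():
    a = rec("CCO")
    with pytest.raises(ValueError):
        tanimoto_distance(path_fingerprint(a), circular_fingerprint(a))
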