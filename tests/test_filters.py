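import math

import pytest

from mgvs.chemio import parse_molecule
from mgvs.filters import (
    ConfigurationError,
    FilterConfig,
    apply_filter_stack,
    cumulated_double_bond_check,
    drug_like_check,
    load_pains_catalog,
    pains_check,
    ring_system_check,
)


def rec(smiles, mol_id="m"):
    return parse_molecule(smiles, mol_id)


def test_cumulated_double_bonds():
    assert cumulated_double_bond_check(rec("C=C=C")) is not None
    assert cumulated_double_bond_check(rec("C=CC=C")) is None  # conjugated is fine
    assert cumulated_double_bond_check(rec("c1ccccc1")) is None


def test_ring_size_rule():
    assert [v.rule for v in ring_system_check(rec("C1CCC1"))] == ["ring_size"]
    assert [v.rule for v in ring_system_check(rec("C1CCCCCC1"))] == ["ring_size"]
    assert ring_system_check(rec("C1CCCC1")) == []
    assert ring_system_check(rec("c1ccccc1")) == []


def test_fused_ring_count_rule():
    tetracene = rec("c1ccc2cc3cc4ccccc4cc3cc2c1")
    pentacene = rec("c1ccc2cc3cc4cc5ccccc5cc4cc3cc2c1")
    assert ring_system_check(tetracene) == []
    assert "fused_count" in [v.rule for v in ring_system_check(pentacene)]
    relaxed = FilterConfig(max_fused_rings=5)
    assert ring_system_check(pentacene, relaxed) == []


def test_ring_loop_rule():
    adamantane = rec("C1C2CC3CC1CC(C2)C3")  # three rings pairwise fused
    norbornane = rec("C1CC2CCC1C2")
    assert "ring_loop" in [v.rule for v in ring_system_check(adamantane)]
    assert "ring_loop" not in [v.rule for v in ring_system_check(norbornane)]


def test_pains_catalog_flags_rhodanine():
    catalog = load_pains_catalog(FilterConfig())
    assert pains_check(rec("O=C1CSC(=S)N1"), catalog)  # classic PAINS scaffold
    assert not pains_check(rec("CC(=O)Nc1ccc(O)cc1"), catalog)


def test_drug_like_windows():
    assert [v.rule for v in drug_like_check(rec("CCO"))] == ["property:mw"]
    rules = {v.rule for v in drug_like_check(rec("CCCCCCCCCCCCCCCCCCCC"))}
    assert rules == {"property:logp", "property:rot_bonds"}
    assert drug_like_check(rec("CC(=O)Nc1ccc(C)cc1C")) == []


def test_drug_like_custom_ranges_and_validation():
    loose = {"mw": (0.0, math.inf), "logp": (-math.inf, math.inf),
             "hbd": (0, 99), "hba": (0, 99), "rot_bonds": (0, 99)}
    assert drug_like_check(rec("CCO"), loose) == []
    with pytest.raises(ConfigurationError):
        drug_like_check(rec("CCO"), {"mw": (500.0, 150.0)})


def test_stack_requires_all_subfilters_to_pass():
    records = [rec("CC(=O)Nc1ccc(O)cc1", "ok"), rec("C=C=CC(=O)Nc1ccc(O)cc1", "cum")]
    survivors, reports = apply_filter_stack(records)
    assert [r.id for r in survivors] == ["ok"]
    assert [r.passed for r in reports] == [True, False]
    assert reports[1].failures[0].rule == "cumulated_double_bond"


def test_stack_respects_enable_flags():
    records = [rec("C1CCC1CCCCCCCCC(N)C(=O)O", "x")]  # ring-size violation
    survivors, _ = apply_filter_stack(records, FilterConfig(enable_structure=False))
    assert [r.id for r in survivors] == ["x"]
    survivors, _ = apply_filter_stack(records)
    assert survivors == []


def test_stack_preserves_input_order():
    smiles = ["CC(=O)Nc1ccc(O)cc1", "Cc1ccccc1C(=O)Nc1ccccc1", "CC(C)Cc1ccc(C(C)C(=O)O)cc1"]
    records = [rec(s, f"m{i}") for i, s in enumerate(smiles)]
    survivors, _ = apply_filter_stack(records)
    assert [r.id for r in survivors] == ["m0", "m1", "m2"]
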