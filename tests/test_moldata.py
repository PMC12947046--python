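"""Structure I/O, grouping, molecule-level splitting and pair building."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from molrank.moldata import (ConformerGroup, ParseError, Structure,
                             filter_and_cap_groups, group_structures,
                             make_pairs, read_structures, split_by_molecule,
                             write_structures)

from conftest import random_structure


def make_group(rng, gid: str, n: int, prop: str = "energy",
               values=None) -> ConformerGroup:
    members = []
    for i in range(n):
        s = random_structure(rng, group_id=gid, structure_id=f"{gid}_{i}")
        s.properties[prop] = float(values[i]) if values is not None else float(
            rng.normal())
        members.append(s)
    return ConformerGroup(gid, members)


# -- Structure invariants ----------------------------------------------------

def test_structure_rejects_inconsistent_inputs():
    with pytest.raises(ValueError):
        Structure("s", "g", [1, 6], [[0, 0, 0]])          # count mismatch
    with pytest.raises(ValueError):
        Structure("s", "g", [0], [[0, 0, 0]])             # Z < 1
    with pytest.raises(ValueError):
        Structure("s", "g", [1], [[np.nan, 0, 0]])        # non-finite
    with pytest.raises(ValueError):
        Structure("s", "g", [1, 1], [[0, 0, 0], [0, 0, 0]])  # coincident


# -- I/O ---------------------------------------------------------------------

def test_extxyz_roundtrip(tmp_path, rng):
    structures = []
    for i in range(5):
        s = random_structure(rng, group_id=f"g{i % 2}", structure_id=f"s{i}")
        s.properties = {"energy": float(rng.normal()), "gap": float(rng.normal())}
        structures.append(s)
    path = tmp_path / "set.extxyz"
    write_structures(structures, path)
    back = read_structures(path, format="extxyz")
    assert len(back) == len(structures)
    for a, b in zip(structures, back):
        assert a.structure_id == b.structure_id
        assert a.group_id == b.group_id
        assert np.array_equal(a.atomic_numbers, b.atomic_numbers)
        assert np.allclose(a.positions, b.positions, atol=1e-6)
        for k, v in a.properties.items():
            assert b.properties[k] == pytest.approx(v, rel=1e-9)


def test_read_two_frame_xyz_with_sidecar(tmp_path):
    xyz = tmp_path / "two.xyz"
    xyz.write_text(
        "2\nframe 0\nC 0.0 0.0 0.0\nH 1.0 0.0 0.0\n"
        "3\nframe 1\nO 0.0 0.0 0.0\nH 1.0 0.0 0.0\nH 0.0 1.0 0.0\n")
    table = tmp_path / "props.csv"
    table.write_text("structure_id,group_id,energy\na,g1,1.5\nb,g2,-2.0\n")
    out = read_structures(xyz, format="xyz", property_table=table)
    assert len(out) == 2
    assert out[0].n_atoms == 2 and out[1].n_atoms == 3
    assert out[0].atomic_numbers[0] == 6       # C -> 6
    assert out[1].atomic_numbers[0] == 8       # O -> 8
    assert out[0].properties["energy"] == 1.5
    assert out[1].group_id == "g2"


def test_malformed_frame_errors_name_the_frame(tmp_path):
    # frame index 2 (third frame) has a NaN coordinate
    good = "1\ngroup_id=g\nH 0.0 0.0 0.0\n"
    bad = "1\ngroup_id=g\nH NaN 0.0 0.0\n"
    path = tmp_path / "bad.extxyz"
    path.write_text(good + good + bad)
    with pytest.raises(ParseError, match="frame 2"):
        read_structures(path, format="extxyz")


def test_unknown_element_symbol_errors(tmp_path):
    path = tmp_path / "elt.extxyz"
    path.write_text("1\ngroup_id=g\nXx 0.0 0.0 0.0\n")
    with pytest.raises(ParseError, match="Xx"):
        read_structures(path, format="extxyz")


# -- grouping ----------------------------------------------------------------

def test_group_structures_partitions(rng):
    structures = (
        [random_structure(rng, group_id="g1", structure_id=f"a{i}") for i in range(4)]
        + [random_structure(rng, group_id="g2", structure_id=f"b{i}") for i in range(2)]
    )
    groups = group_structures(structures)
    assert [g.group_id for g in groups] == ["g1", "g2"]
    assert sorted(len(g) for g in groups) == [2, 4]
    assert sum(len(g) for g in groups) == 6
    assert group_structures([]) == []


def test_group_structures_large_ensemble(rng):
    """One equilibrium + 100 perturbed copies collapse into a single group."""
    structures = [random_structure(rng, group_id="mol", structure_id=f"c{i}")
                  for i in range(101)]
    groups = group_structures(structures)
    assert len(groups) == 1 and len(groups[0]) == 101


# -- splitting ---------------------------------------------------------------

def test_split_95_5(rng):
    groups = [make_group(rng, f"g{i}", 2) for i in range(100)]
    split = split_by_molecule(groups, 0.05, seed=3)
    assert len(split.test_groups) == 5
    assert len(split.train_groups) == 95
    assert not set(split.test_groups) & set(split.train_groups)
    assert set(split.test_groups) | set(split.train_groups) == {
        g.group_id for g in groups}


def test_split_determinism_and_errors(rng):
    groups = [make_group(rng, f"g{i}", 2) for i in range(10)]
    s1 = split_by_molecule(groups, 0.3, seed=11)
    s2 = split_by_molecule(groups, 0.3, seed=11)
    assert s1 == s2
    assert split_by_molecule(groups, 0.3, seed=12) != s1
    with pytest.raises(ValueError):
        split_by_molecule(groups[:1], 0.5, seed=0)
    with pytest.raises(ValueError):
        split_by_molecule(groups, 1.5, seed=0)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(n=st.integers(2, 40), frac=st.floats(0.05, 0.95), seed=st.integers(0, 99))
def test_split_invariants_property(n, frac, seed):
    rng = np.random.default_rng(0)
    groups = [make_group(rng, f"g{i}", 2) for i in range(n)]
    split = split_by_molecule(groups, frac, seed)
    train, test = set(split.train_groups), set(split.test_groups)
    assert not train & test
    assert train | test == {g.group_id for g in groups}
    assert len(test) == max(1, round(frac * n))


# -- filtering / capping -----------------------------------------------------

def test_filter_and_cap(rng):
    groups = [make_group(rng, "small", 5), make_group(rng, "big", 20),
              make_group(rng, "mid", 8)]
    out = filter_and_cap_groups(groups, min_exclusive=5, cap=11, seed=1)
    by_id = {g.group_id: g for g in out}
    assert "small" not in by_id            # size 5 with min_exclusive 5 removed
    assert len(by_id["big"]) == 11         # capped
    assert len(by_id["mid"]) == 8          # untouched
    # subsampling draws existing members without replacement
    orig = {s.structure_id for s in groups[1].structures}
    kept = [s.structure_id for s in by_id["big"].structures]
    assert set(kept) <= orig and len(set(kept)) == 11


def test_filter_and_cap_never_grows_or_drops_large(rng):
    groups = [make_group(rng, f"g{i}", int(n)) for i, n in
              enumerate(np.random.default_rng(5).integers(2, 30, size=15))]
    out = filter_and_cap_groups(groups, min_exclusive=5, cap=11, seed=2)
    sizes_in = {g.group_id: len(g) for g in groups}
    assert all(len(g) <= sizes_in[g.group_id] for g in out)
    kept_ids = {g.group_id for g in out}
    for g in groups:
        if len(g) > 5:
            assert g.group_id in kept_ids


# -- pair construction -------------------------------------------------------

def test_make_pairs_labels(rng):
    g = make_group(rng, "g", 2, values=[3.0, 1.0])
    (pair,) = make_pairs(g, "energy", seed=0)
    if pair.a.structure_id == "g_0":
        assert pair.label == (1.0, 0.0) and pair.target_diff == pytest.approx(2.0)
    else:
        assert pair.label == (0.0, 1.0) and pair.target_diff == pytest.approx(-2.0)


def test_make_pairs_tie(rng):
    g = make_group(rng, "g", 2, values=[1.0, 1.0])
    (pair,) = make_pairs(g, "energy", seed=0)
    assert pair.label == (0.5, 0.5) and pair.target_diff == 0.0


def test_make_pairs_budget_and_consistency(rng):
    g = make_group(rng, "g", 4)
    pairs = make_pairs(g, "energy", budget=100, seed=0)
    assert len(pairs) == 6            # C(4,2)
    assert len(make_pairs(g, "energy", budget=3, seed=0)) == 3
    for p in pairs:
        if p.label == (1.0, 0.0):
            assert p.target_diff > 0
        elif p.label == (0.0, 1.0):
            assert p.target_diff < 0
        else:
            assert p.target_diff == 0
    # distinct unordered pairs
    keys = {frozenset((p.a.structure_id, p.b.structure_id)) for p in pairs}
    assert len(keys) == len(pairs)


def test_make_pairs_missing_property_names_structure(rng):
    g = make_group(rng, "g", 3)
    del g.structures[1].properties["energy"]
    with pytest.raises(KeyError, match="g_1"):
        make_pairs(g, "energy", seed=0)
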