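"""Binary parameter evaluation, ddG bands, active-site derivation, phi."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gldcscore import (
    DdgRecord,
    MissenseMutation,
    ParameterUnavailableError,
    categorize_ddg,
    compute_active_site,
    evaluate_parameters,
    phi_correlation,
    phi_matrix,
)
from gldcscore.parameters import ddg_provider, evaluate_table, property_change_provider


@pytest.mark.parametrize(
    "ddg,category",
    [
        (-6.0, "very_destabilizing"),
        (-5.0, "destabilizing"),  # band is [-5.0, -1.5)
        (-2.0, "destabilizing"),
        (-1.5, "unchanged"),  # destabilizing is strictly < -1.5
        (0.0, "unchanged"),
        (2.0, "stabilizing"),
        (6.0, "very_stabilizing"),
    ],
)
def test_ddg_categories_and_boundaries(ddg, category):
    assert categorize_ddg(ddg) == category


def test_ddg_rejects_non_finite_and_is_monotone_step():
    for bad in (float("nan"), float("inf"), -float("inf")):
        with pytest.raises(ValueError):
            categorize_ddg(bad)
    order = [
        "very_destabilizing",
        "destabilizing",
        "unchanged",
        "stabilizing",
        "very_stabilizing",
    ]
    grid = np.linspace(-10, 10, 401)
    ranks = [order.index(categorize_ddg(x)) for x in grid]
    assert ranks == sorted(ranks)  # monotone nondecreasing in ddG


def test_ddg_record_consistency_enforced():
    rec = DdgRecord(label="A2V", ddg=-6.0)
    assert rec.category == "very_destabilizing"
    with pytest.raises(ValueError, match="inconsistent"):
        DdgRecord(label="A2V", ddg=-6.0, category="stabilizing")


def test_evaluate_parameters_full_vector(registry, scored_cds_setup):
    _, muts, providers = scored_cds_setup
    v = evaluate_parameters(muts[0], providers, registry)
    assert set(v.values) == set(registry.names)
    assert all(val in (0, 1) for val in v.values.values())
    assert v.provenance["ddg_destabilizing"] == "ddg"


def test_proline_substitution_sets_property_indicator():
    prov = property_change_provider()
    to_pro = MissenseMutation(10, "A", "P")
    from_pro = MissenseMutation(10, "P", "A")
    no_pro = MissenseMutation(10, "A", "V")
    assert prov(to_pro, "prop_proline_change") == 1
    assert prov(from_pro, "prop_proline_change") == 1
    assert prov(no_pro, "prop_proline_change") == 0


def test_missing_ddg_surfaces_as_error_never_zero(registry, scored_cds_setup):
    _, muts, providers = scored_cds_setup
    providers = dict(providers)
    providers["ddg"] = ddg_provider({})  # empty lookup
    with pytest.raises(ParameterUnavailableError, match="parameter unavailable"):
        evaluate_parameters(muts[0], providers, registry)


def test_registry_shape(registry):
    assert len(registry) == 18
    negatives = [s.name for s in registry if s.sign == -1]
    assert negatives == ["conserved_substitution"]
    assert len(set(registry.names)) == 18


# ---------------------------------------------------------------------------
# Active site from a toy structure
# ---------------------------------------------------------------------------


def _atom_line(serial, name, resname, chain, resseq, xyz):
    x, y, z = xyz
    return (
        f"ATOM  {serial:5d}  {name:<3s}{resname:>3s} {chain}{resseq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {name[0]:>2s}"
    )


def _write_toy_pdb(path, coords):
    """coords: {resseq: [(atom_name, (x, y, z)), ...]} single chain A."""
    lines, serial = [], 1
    for resseq in sorted(coords):
        for name, xyz in coords[resseq]:
            lines.append(_atom_line(serial, name, "ALA", "A", resseq, xyz))
            serial += 1
    path.write_text("\n".join(lines) + "\nEND\n")


def test_active_site_matches_brute_force_distance_scan(tmp_path):
    rng = np.random.default_rng(3)
    coords = {
        i: [("CA", tuple(rng.uniform(0, 12, size=3))), ("CB", tuple(rng.uniform(0, 12, size=3)))]
        for i in range(1, 11)
    }
    pdb = tmp_path / "toy.pdb"
    _write_toy_pdb(pdb, coords)
    center = 5
    cutoff = 5.0
    ann = compute_active_site(pdb, centers=[center], cutoff=cutoff)
    # O(n^2) oracle on the coordinates we generated, independent of the parser
    center_atoms = np.array([xyz for _, xyz in coords[center]])
    expected = {
        res
        for res, atoms in coords.items()
        if any(
            np.linalg.norm(np.array(xyz) - c) <= cutoff
            for _, xyz in atoms
            for c in center_atoms
        )
    }
    assert ann.positions == frozenset(expected)
    assert center in ann  # zero distance to itself


def test_active_site_zero_cutoff_and_shared_atom(tmp_path):
    coords = {
        1: [("CA", (0.0, 0.0, 0.0))],
        2: [("CA", (0.0, 0.0, 0.0))],  # shares the center's position exactly
        3: [("CA", (9.0, 9.0, 9.0))],
    }
    pdb = tmp_path / "toy.pdb"
    _write_toy_pdb(pdb, coords)
    ann0 = compute_active_site(pdb, centers=[1], cutoff=0.0)
    assert ann0.positions == frozenset({1})
    ann = compute_active_site(pdb, centers=[1], cutoff=1.0)
    assert 2 in ann and 3 not in ann


def test_active_site_missing_center_rejected(tmp_path):
    pdb = tmp_path / "toy.pdb"
    _write_toy_pdb(pdb, {1: [("CA", (0.0, 0.0, 0.0))]})
    with pytest.raises(ValueError, match="no center residues"):
        compute_active_site(pdb, centers=[99], cutoff=5.0)


# ---------------------------------------------------------------------------
# Phi coefficient
# ---------------------------------------------------------------------------


def test_phi_self_complement_and_constant():
    a = [1, 1, 0, 0, 1, 0]
    assert phi_correlation(a, a) == pytest.approx(1.0)
    assert phi_correlation(a, [1 - x for x in a]) == pytest.approx(-1.0)
    assert math.isnan(phi_correlation([1, 1, 1], [0, 1, 0]))
    with pytest.raises(ValueError, match="length mismatch"):
        phi_correlation([0, 1], [0, 1, 1])


def test_phi_equals_pearson_on_2x2_counts():
    # counts (n11, n10, n01, n00) = (2, 1, 1, 2)
    a = [1, 1, 1, 0, 0, 0]
    b = [1, 1, 0, 1, 0, 0]
    expected = np.corrcoef(a, b)[0, 1]
    assert phi_correlation(a, b) == pytest.approx(expected, abs=1e-12)


@given(st.integers(min_value=0, max_value=2**32 - 1))
def test_phi_within_unit_interval_and_symmetric(seed):
    rng = np.random.default_rng(seed)
    a = rng.integers(0, 2, size=20)
    b = rng.integers(0, 2, size=20)
    phi_ab = phi_correlation(a, b)
    if not math.isnan(phi_ab):
        assert -1.0 <= phi_ab <= 1.0
        assert phi_ab == pytest.approx(phi_correlation(b, a))


def test_phi_matrix_symmetric_unit_diagonal(registry, scored_cds_setup):
    _, muts, providers = scored_cds_setup
    table = evaluate_table(muts[:60], providers, registry)
    mat = phi_matrix(table)
    arr = mat.to_numpy(dtype=float)
    finite = ~np.isnan(arr)
    assert (arr[finite] <= 1.0 + 1e-12).all() and (arr[finite] >= -1.0 - 1e-12).all()
    assert np.array_equal(np.isnan(arr), np.isnan(arr.T))
    np.testing.assert_allclose(
        np.where(np.isnan(arr), 0, arr), np.where(np.isnan(arr.T), 0, arr.T)
    )
    for i, col in enumerate(table.columns):
        if table[col].nunique() > 1:
            assert arr[i, i] == pytest.approx(1.0)


def test_phi_matrix_is_dataframe(registry, scored_cds_setup):
    _, muts, providers = scored_cds_setup
    table = evaluate_table(muts[:30], providers, registry)
    mat = phi_matrix(table)
    assert isinstance(mat, pd.DataFrame)
    assert list(mat.columns) == registry.names
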