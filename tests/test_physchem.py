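"""Reduced alphabet, composition, Henderson-Hasselbalch charge and pI."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mtsprofile.physchem import (
    GROUP_ORDER,
    NINE_GROUPS,
    ChargeModel,
    composition,
    isoelectric_point,
    net_charge,
    reduce_sequence,
    sequence_properties,
)

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
seqs = st.text(alphabet=RESIDUES, min_size=1, max_size=60)


@pytest.mark.parametrize(
    "seq, expected",
    [
        ("GAVIL", "aaaaa"),
        ("RHKDE", "bbbdd"),
        ("FWPCMSTYNQ", "ffpccssynn"),
        ("", ""),
        ("AXB", "a??"),
    ],
)
def test_reduce_sequence_examples(seq, expected):
    assert reduce_sequence(seq) == expected


def test_reduce_sequence_rejects_non_residue():
    with pytest.raises(ValueError, match="invalid residue"):
        reduce_sequence("A1C")


@settings(derandomize=True, max_examples=100)
@given(seqs)
def test_reduction_preserves_length_and_group_counts(seq):
    reduced = reduce_sequence(seq)
    assert len(reduced) == len(seq)
    fracs = composition(seq)
    assert math.isclose(sum(fracs.values()), 1.0, abs_tol=1e-9)
    # fractions computed on the reduced string must agree
    for g in GROUP_ORDER:
        assert math.isclose(fracs[g], reduced.count(g) / len(reduced), abs_tol=1e-12)


@pytest.mark.parametrize(
    "seq, expected",
    [
        ("DDEE", {"d": 1.0}),
        ("RKDESTAA", {"b": 0.25, "d": 0.25, "s": 0.25, "a": 0.25}),
    ],
)
def test_composition_hand_counts(seq, expected):
    fracs = composition(seq)
    for g in GROUP_ORDER:
        assert fracs[g] == pytest.approx(expected.get(g, 0.0))


def test_composition_excludes_unknowns_but_length_counts_them():
    assert composition("DXDX")["d"] == 1.0
    props = sequence_properties("DXDX")
    assert props.length == 4 and props.frac_d == 1.0


def test_composition_all_unknown_is_an_error():
    with pytest.raises(ValueError, match="classifiable"):
        composition("XXXX")


def test_net_charge_term_by_term_oracle():
    """Independent Henderson-Hasselbalch sum over the 7 side chains + termini."""
    model = ChargeModel.from_name("bjellqvist")
    pH = 7.5
    # deprotonated fraction for acids, protonated for bases, written as the
    # complementary algebraic form to the implementation's
    expected = 0.0
    for res in "DECY":
        ka = 10.0 ** (-model.pka[res])
        h = 10.0 ** (-pH)
        expected -= ka / (ka + h)
    for res in "KRH":
        ka = 10.0 ** (-model.pka[res])
        h = 10.0 ** (-pH)
        expected += h / (ka + h)
    expected += 10.0 ** (-pH) / (10.0 ** (-model.pka["nterm"]) + 10.0 ** (-pH))
    expected -= 10.0 ** (-model.pka["cterm"]) / (10.0 ** (-model.pka["cterm"]) + 10.0 ** (-pH))
    assert net_charge("DECYKRH", pH, model) == pytest.approx(expected, abs=1e-12)


def test_net_charge_low_ph_asymptote_is_plus_one():
    # N-terminus fully protonated, carboxyl neutral, no ionizable side chains
    assert net_charge("AAAA", 0.01) == pytest.approx(1.0, abs=0.01)


@settings(derandomize=True, max_examples=30)
@given(seqs)
def test_net_charge_strictly_decreasing_in_ph(seq):
    grid = np.linspace(0.5, 13.5, 27)
    charges = [net_charge(seq, ph) for ph in grid]
    assert all(a > b for a, b in zip(charges, charges[1:]))


def test_no_ionizable_side_chains_no_termini_is_exactly_zero():
    for ph in (2.0, 7.0, 12.0):
        assert net_charge("GGGG", ph, include_termini=False) == 0.0


def _grid_pi(seq, model, resolution=1e-4):
    grid = np.arange(resolution, 14.0, resolution)
    h = 10.0 ** (-grid)
    charge = np.zeros_like(grid)
    for res in ChargeModel.BASIC:
        charge += seq.count(res) * h / (10.0 ** (-model.pka[res]) + h)
    for res in ChargeModel.ACIDIC:
        ka = 10.0 ** (-model.pka[res])
        charge -= seq.count(res) * ka / (ka + h)
    charge += h / (10.0 ** (-model.pka["nterm"]) + h)
    ka = 10.0 ** (-model.pka["cterm"])
    charge -= ka / (ka + h)
    return float(grid[np.argmin(np.abs(charge))])


def test_pi_bisection_matches_grid_oracle_on_random_50mers():
    model = ChargeModel.from_name()
    rng = np.random.default_rng(42)
    for _ in range(20):
        seq = "".join(rng.choice(list(RESIDUES), size=50))
        assert abs(isoelectric_point(seq, model) - _grid_pi(seq, model)) <= 1e-3


def test_pi_orderings_and_charge_at_pi():
    model = ChargeModel.from_name()
    assert isoelectric_point("DDDD", model) < isoelectric_point("KKKK", model)
    pi_g = isoelectric_point("GGGG", model)
    assert model.pka["cterm"] < pi_g < model.pka["nterm"]
    for seq in ("GGGG", "DDKKHHCCYY", "MLRSSVVRSRDDEE"):
        assert abs(net_charge(seq, isoelectric_point(seq, model), model)) < 1e-3


def test_sequence_properties_signs_and_length():
    r = sequence_properties("RRRR")
    d = sequence_properties("DDDD")
    assert r.frac_b == 1.0 and r.charge_pH > 0
    assert d.frac_d == 1.0 and d.charge_pH < 0
    assert sequence_properties("MAAARSTK").length == 8


def test_alternative_pka_sets_load_and_differ():
    emboss = ChargeModel.from_name("emboss")
    bj = ChargeModel.from_name("bjellqvist")
    assert emboss.pka != bj.pka
    with pytest.raises(KeyError):
        ChargeModel.from_name("nonexistent")


def test_nine_groups_partition_the_alphabet():
    mapped = reduce_sequence(RESIDUES)
    assert "?" not in mapped and set(mapped) == set(GROUP_ORDER)
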