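import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rcaspot.annotate import (
    MarkerPanel,
    MarkerSet,
    SaturationModel,
    ThresholdRule,
    annotate_alveolar,
    annotate_by_panel,
    call_positivity,
    flag_saturated,
    positivity_threshold,
    saturation_capacity,
)
from rcaspot.simulate import CellType, simulate_truth

from conftest import small_sim_config

AIRWAY_PANEL = MarkerPanel(
    {
        "basal": MarkerSet(["Krt5", "Pdpn", "Trp63"]),
        "club": MarkerSet(["Scgb1a1"], min_positive=1, fixed_cutoff=3),
        "tuft": MarkerSet(["Gng13", "Trpm5", "Alox5ap"]),
    }
)


def _counts(rows, genes):
    return pd.DataFrame(rows, columns=genes,
                        index=pd.RangeIndex(1, len(rows) + 1, name="cell_id"))


@pytest.mark.parametrize(
    "max_dots,expected",
    [(40, 3.0), (0, 0.0), (20, 2.0), (31, 3.0), (32, 3.0), (10, 1.0)],
)
def test_positivity_threshold_rule(max_dots, expected):
    assert positivity_threshold(max_dots) == pytest.approx(expected)


def test_threshold_strictness_at_zero_max():
    # max 0 -> threshold 0; a zero-count cell is NOT positive (strict >)
    counts = _counts([[0], [0]], ["g"])
    assert not call_positivity(counts).any().any()


@given(st.integers(min_value=0, max_value=500))
@settings(deadline=None, max_examples=60)
def test_threshold_monotone_and_cap_binds(max_dots):
    rule = ThresholdRule()
    t = positivity_threshold(max_dots, rule)
    assert t <= positivity_threshold(max_dots + 1, rule) + 1e-12
    if max_dots > rule.cap / rule.fraction:
        assert t == rule.cap


def test_inconsistent_rule_rejected():
    with pytest.raises(ValueError, match="inconsistent"):
        ThresholdRule(fraction=0.05, cap=3.0, cap_trigger_max=31)


def test_call_positivity_documented_cases():
    counts = _counts([[0], [2], [40]], ["g"])
    pos = call_positivity(counts)["g"]
    # threshold = min(4, 3) = 3: only the 40-count cell passes; 2 <= 3
    assert pos.tolist() == [False, False, True]


def test_positivity_scale_invariance_below_cap():
    counts = _counts([[0], [3], [15]], ["g"])  # max 15 -> threshold 1.5
    doubled = counts * 2  # max 30 -> threshold 3.0
    pd.testing.assert_frame_equal(call_positivity(counts),
                                  call_positivity(doubled))


def test_all_zero_matrix_all_negative():
    counts = _counts(np.zeros((4, 3), dtype=int), ["a", "b", "c"])
    assert not call_positivity(counts).any().any()


def test_basal_called_from_two_markers():
    genes = ["Krt5", "Pdpn", "Trp63", "Scgb1a1", "Gng13", "Trpm5", "Alox5ap"]
    counts = _counts([[40, 0, 40, 0, 0, 0, 0]], genes)
    labels = annotate_by_panel(call_positivity(counts), counts, AIRWAY_PANEL)
    assert labels.label[1] == "basal"


def test_club_single_marker_exception():
    genes = ["Krt5", "Pdpn", "Trp63", "Scgb1a1", "Gng13", "Trpm5", "Alox5ap"]
    counts = _counts([[0, 0, 0, 5, 0, 0, 0], [0, 0, 0, 3, 0, 0, 0]], genes)
    labels = annotate_by_panel(call_positivity(counts), counts, AIRWAY_PANEL)
    assert labels.label[1] == "club"  # 5 > 3 dots
    assert labels.label[2] == "NA"  # exactly 3 dots fails the strict > 3 rule


def test_two_type_conflict_yields_na_with_competitors_recorded():
    genes = ["Krt5", "Pdpn", "Trp63", "Scgb1a1", "Gng13", "Trpm5", "Alox5ap"]
    counts = _counts([[40, 40, 0, 0, 40, 40, 0]], genes)
    labels = annotate_by_panel(call_positivity(counts), counts, AIRWAY_PANEL)
    # two basal markers AND two tuft markers: each type sees 2 foreign
    # positives (> max_foreign 1), so neither is satisfied
    assert labels.label[1] == "NA"
    assert labels.n_satisfied[1] == 0


def test_annotation_deterministic_and_permutation_equivariant(rng):
    genes = ["Krt5", "Pdpn", "Trp63", "Scgb1a1", "Gng13", "Trpm5", "Alox5ap"]
    counts = _counts(rng.poisson(2, size=(30, len(genes))), genes)
    pos = call_positivity(counts)
    l1 = annotate_by_panel(pos, counts, AIRWAY_PANEL)
    perm = rng.permutation(counts.index)
    l2 = annotate_by_panel(pos.loc[perm], counts.loc[perm], AIRWAY_PANEL)
    pd.testing.assert_series_equal(l1.label.loc[perm], l2.label)


def test_panel_with_missing_marker_errors():
    counts = _counts([[1, 2]], ["Krt5", "Pdpn"])
    with pytest.raises(ValueError, match="missing from counts"):
        annotate_by_panel(call_positivity(counts), counts, AIRWAY_PANEL)


def test_marker_panel_yaml_roundtrip(tmp_path):
    path = tmp_path / "panel.yaml"
    path.write_text(
        "types:\n"
        "  basal: {markers: [Krt5, Pdpn, Trp63]}\n"
        "  club: {markers: [Scgb1a1], min_positive: 1, fixed_cutoff: 3}\n"
    )
    panel = MarkerPanel.from_yaml(str(path))
    assert panel.types["club"].fixed_cutoff == 3
    assert panel.types["basal"].min_positive == 2


ALV = ["Ascl1", "Scgb1a1", "Cyp2f2", "Sftpc", "Lyz2", "Cd74", "Ager"]


@pytest.mark.parametrize(
    "row,expected",
    [
        ({"Ager": 9}, "AT1"),
        ({"Lyz2": 9, "Cd74": 9}, "macrophage"),
        ({}, "NA"),
        ({"Ascl1": 5, "Scgb1a1": 9, "Cyp2f2": 9}, "NE"),  # NE wins, fixed order
        ({"Scgb1a1": 9, "Cyp2f2": 9}, "secretory"),
        ({"Sftpc": 9, "Lyz2": 9, "Cd74": 9}, "AT2"),
        ({"Lyz2": 9}, "Lyz2_immune"),
        ({"Cd74": 9}, "Cd74_immune"),
        ({"Ager": 9, "Sftpc": 9, "Lyz2": 9, "Cd74": 9}, "AT2"),
    ],
)
def test_alveolar_boolean_rules(row, expected):
    counts = _counts([[row.get(g, 0) for g in ALV]], ALV)
    assert annotate_alveolar(counts).iloc[0] == expected


def test_alveolar_missing_gene_errors():
    counts = _counts([[0, 0]], ["Ascl1", "Sftpc"])
    with pytest.raises(ValueError, match="needs genes"):
        annotate_alveolar(counts)


@pytest.mark.parametrize(
    "cell,dot,expected", [(44.5, 0.55, 80), (1.0, 1.0, 1), (44.5, 0.57, 78)]
)
def test_saturation_capacity_worked_values(cell, dot, expected):
    assert saturation_capacity(cell, dot) == expected


def test_saturation_capacity_invalid_inputs():
    with pytest.raises(ValueError):
        saturation_capacity(0.0, 0.55)
    with pytest.raises(ValueError):
        saturation_capacity(44.5, -1.0)


def test_flag_saturated_rules():
    counts = _counts([[0, 80, 60]], ["a", "b", "c"])
    caps = pd.Series([80], index=counts.index)
    flags = flag_saturated(counts, caps, fraction=0.7)
    assert flags.iloc[0].tolist() == [False, True, True]  # 0 never; 80>=56; 60>=56
    flags_full = flag_saturated(counts, caps, fraction=1.0)
    assert flags_full.iloc[0].tolist() == [False, True, False]


def test_saturation_model_capacities():
    model = SaturationModel(mean_dot_area_um2=0.55)
    caps = model.capacities(pd.Series([44.5, 0.55], index=[1, 2]))
    assert caps.tolist() == [80, 1]


def test_annotation_recovery_on_simulated_types():
    # selective markers at rate 8, background 0.2: >=95% of non-NA truth
    # cells get their true label back from counts alone
    from rcaspot.simulate import default_airway_types
    from conftest import airway_panel

    types = default_airway_types(selective_rate=8.0, background_rate=0.2)
    genes = sorted({g for t in types for g in t.rates})
    panel_sets = {
        "basal": ["Krt5", "Pdpn", "Trp63"],
        "club": ["Scgb1a1", "Cyp2f2"],
        "tuft": ["Gng13", "Trpm5", "Alox5ap"],
        "ionocyte": ["Ascl3", "Foxi1", "Cftr"],
        "NE": ["Ascl1", "Calca"],
    }
    marker_panel = MarkerPanel(
        {k: MarkerSet(v) for k, v in panel_sets.items()}
    )
    cfg = small_sim_config(
        seed=31, n_cells=120, field_size_px=(768, 768),
        cell_types=types,
    )
    truth = simulate_truth(cfg)
    counts = truth.counts
    labels = annotate_by_panel(call_positivity(counts), counts, marker_panel)
    merged = labels.join(truth.cells.set_index("cell_id").cell_type)
    called = merged[merged.label != "NA"]
    assert len(called) / len(merged) > 0.5  # most cells get a call at all
    accuracy = (merged.label == merged.cell_type).mean()
    assert accuracy >= 0.95
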