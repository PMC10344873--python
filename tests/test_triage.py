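from collections import Counter

import pytest
from hypothesis import given, settings, strategies as st

from bindscan.triage import (
    HEATMAP_ROWS,
    TriageConfig,
    classify_disruption,
    heatmap_matrix,
    hotspot_rank,
    prioritize,
)


def call(pos, wt, target, deltas, path_class="single", cfg=None):
    return classify_disruption(
        deltas, path_class=path_class, cfg=cfg,
        position=pos, wildtype_aa=wt, target_aa=target,
    )


def test_single_variant_below_cutoff_is_disruptive():
    assert call(248, "R", "Q", [-4.46]).verdict == "disruptive"


def test_above_cutoff_is_non_disruptive():
    assert call(1, "A", "S", [-1.0]).verdict == "non_disruptive"


def test_boundary_counts_as_disruptive():
    assert call(1, "A", "S", [-3.0]).verdict == "disruptive"


def test_histidine_requires_all_three_states():
    assert call(84, "D", "H", [-3.5, -2.9, -4.1]).verdict == "non_disruptive"
    assert call(84, "D", "H", [-3.5, -3.1, -4.1]).verdict == "disruptive"
    cfg = TriageConfig(his_rule=False)
    assert call(84, "D", "H", [-3.5, -2.9, -4.1], cfg=cfg).verdict == "disruptive"


def test_complete_disruption_sentinel_is_disruptive():
    assert call(23, "G", "D", ["X"]).verdict == "disruptive"


def test_triple_exclusion_overrides_scores():
    c = call(10, "M", "W", [-50.0], path_class="triple")
    assert c.verdict == "excluded_triple"
    cfg = TriageConfig(exclude_triples=False)
    assert call(10, "M", "W", [-50.0], path_class="triple", cfg=cfg).verdict == "disruptive"


def test_empty_delta_list_is_an_error():
    with pytest.raises(ValueError):
        classify_disruption([], target_aa="S")


def test_variant_count_consistency():
    with pytest.raises(ValueError):
        call(1, "A", "H", [-4.0])  # His needs 3 values
    with pytest.raises(ValueError):
        call(1, "A", "S", [-4.0, -4.0])


def test_cutoff_must_be_negative():
    with pytest.raises(ValueError):
        TriageConfig(cutoff=1.0)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    st.lists(
        st.floats(min_value=-60, max_value=10, allow_nan=False), min_size=1, max_size=1
    ),
    st.floats(min_value=-10, max_value=-0.5),
    st.floats(min_value=0.1, max_value=10),
)
def test_tightening_cutoff_never_adds_disruptive_calls(deltas, cutoff, tighten):
    """Verdict monotonicity: a more negative cutoff only removes calls."""
    loose = classify_disruption(deltas, cfg=TriageConfig(cutoff=cutoff), target_aa="S")
    tight = classify_disruption(
        deltas, cfg=TriageConfig(cutoff=cutoff - tighten), target_aa="S"
    )
    if tight.verdict == "disruptive":
        assert loose.verdict == "disruptive"


def test_hotspot_counts_match_groupby_oracle():
    calls = (
        [call(84, "D", t, [-5.0]) for t in "GNVY"]
        + [call(23, "G", "S", [-4.0])]
        + [call(87, "R", "P", ["X"])]
        + [call(84, "D", "A", [-1.0])]  # non-disruptive: not counted
    )
    report = hotspot_rank(calls, top_k=1)
    oracle = Counter(c.position for c in calls if c.verdict == "disruptive")
    assert report.counts == dict(oracle)
    assert report.top_positions == [84]
    assert report.ranking == [84, 23, 87]


def test_hotspot_tie_break_by_position():
    calls = [call(20, "A", "S", [-4.0]), call(10, "A", "S", [-4.0]),
             call(20, "A", "T", [-4.0]), call(10, "A", "T", [-4.0])]
    assert hotspot_rank(calls).ranking == [10, 20]


def test_no_disruptive_calls_gives_empty_ranking():
    report = hotspot_rank([call(1, "A", "S", [-0.5])])
    assert report.ranking == [] and report.counts == {}


def test_heatmap_one_position_full_target_set():
    wt = "G"
    calls = []
    for aa in "ACDEFHIKLMNPQRSTVWY":
        deltas = [-1.0, -1.0, -1.0] if aa == "H" else [-1.0]
        calls.append(call(23, wt, aa, deltas))
    mat = heatmap_matrix(calls)
    assert list(mat.columns) == ["G23"]
    assert len(HEATMAP_ROWS) == 22  # 19 non-His + H1/H2/H3
    populated = (mat["G23"] != "").sum()
    assert populated == 22  # 21 target rows + the wildtype marker
    assert mat.at["G", "G23"] == "wt"


def test_heatmap_marks_triples_and_sentinels():
    calls = [
        call(5, "M", "W", [-9.0], path_class="triple"),
        call(5, "M", "C", ["X"]),
    ]
    mat = heatmap_matrix(calls)
    assert mat.at["W", "M5"] == "triple"
    assert mat.at["C", "M5"] == "X"
    assert mat.at["M", "M5"] == "wt"


def test_heatmap_rejects_duplicates():
    with pytest.raises(ValueError, match="duplicate"):
        heatmap_matrix([call(5, "M", "W", [-9.0]), call(5, "M", "W", [-8.0])])


class FakeProb:
    def __init__(self, pos, target, p):
        self.protein_position = pos
        self.target_aa = target
        self.relative_probability = p


def test_prioritize_probability_mode_orders_by_probability():
    calls = [call(84, "D", "G", [-5.0]), call(84, "D", "N", [-5.3])]
    hs = hotspot_rank(calls, top_k=1)
    probs = [FakeProb(84, "G", 0.001), FakeProb(84, "N", 0.02)]
    table = prioritize(calls, hs, probs)
    assert list(table["target_aa"]) == ["N", "G"]
    with pytest.raises(ValueError, match="probability"):
        prioritize(calls, hs, [FakeProb(84, "G", 0.001)])


def test_prioritize_no_probability_mode_orders_by_delta():
    calls = [call(248, "R", "W", [-53.49]), call(248, "R", "Q", [-4.46])]
    hs = hotspot_rank(calls, top_k=1)
    table = prioritize(calls, hs, None)
    assert list(table["target_aa"]) == ["W", "Q"]


def test_prioritize_empty_calls():
    table = prioritize([], hotspot_rank([]), None)
    assert len(table) == 0


def test_disruptive_calls_all_below_cutoff_posthoc():
    """Every disruptive verdict is backed by variant values <= cutoff (or X)."""
    cfg = TriageConfig()
    calls = [
        call(1, "A", "S", [-4.0], cfg=cfg),
        call(1, "A", "T", [-2.0], cfg=cfg),
        call(2, "G", "H", [-5.0, -4.0, "X"], cfg=cfg),
    ]
    for c in calls:
        if c.verdict == "disruptive":
            assert all(v is None or v <= cfg.cutoff for v in c.variant_deltas)
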