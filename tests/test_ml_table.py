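"""ML table: shared codes, positive rate, balancing, conversion, selection."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synlhs.ml_table import (
    BalanceConfig,
    ConversionMap,
    MLTable,
    VariableSelection,
    balance,
    build_table,
    convert_values,
    default_conversion_map,
    positive_rate,
    select_variables,
    shared_codes,
    target_background_ratio,
    variable_report,
)

from oracles import balance_filter, select_by_occurrence


def long_frame(rows):
    """(patient_id, label, code, value[, datatype]) tuples -> profile long frame."""
    out = []
    for row in rows:
        pid, label, code, value = row[:4]
        dtype = row[4] if len(row) > 4 else "categorical"
        out.append(
            {"patient_id": pid, "label": label, "code": code, "value": value, "unit": "", "datatype": dtype, "age_years": 50.0}
        )
    return pd.DataFrame(out)


def toy_table(frame_rows, datatypes=None):
    frame = pd.DataFrame(frame_rows).set_index("patient_id")
    dts = datatypes or {c: "categorical" for c in frame.columns if c != "label"}
    return MLTable(frame, dts)


# ---------------------------------------------------------------------
# shared_codes
# ---------------------------------------------------------------------


def test_shared_codes_is_intersection():
    t = long_frame([("t1", 1, "A", "x"), ("t1", 1, "B", "x")])
    b = long_frame([("b1", 0, "B", "x"), ("b1", 0, "C", "x")])
    assert shared_codes(t, b) == ["B"]


def test_disjoint_vocabularies_error():
    t = long_frame([("t1", 1, "A", "x")])
    b = long_frame([("b1", 0, "B", "x")])
    with pytest.raises(ValueError):
        shared_codes(t, b)


def test_shared_codes_ordered_by_patient_count_then_code():
    t = long_frame([("t1", 1, "A", "x"), ("t1", 1, "B", "x"), ("t2", 1, "B", "x"), ("t2", 1, "C", "x")])
    b = long_frame([("b1", 0, "A", "x"), ("b1", 0, "B", "x"), ("b1", 0, "C", "x")])
    # counts: A=2 patients, B=3, C=2 -> [B, A, C] (tie A<C lexicographic)
    assert shared_codes(t, b) == ["B", "A", "C"]


def test_shared_codes_random_matches_set_oracle():
    rng = np.random.default_rng(0)
    for _ in range(20):
        t = long_frame([(f"t{i}", 1, f"c{rng.integers(10)}", "x") for i in range(15)]).drop_duplicates(["patient_id", "code"])
        b = long_frame([(f"b{i}", 0, f"c{rng.integers(10)}", "x") for i in range(15)]).drop_duplicates(["patient_id", "code"])
        expect = set(t["code"]) & set(b["code"])
        if not expect:
            continue
        assert set(shared_codes(t, b)) == expect


# ---------------------------------------------------------------------
# build_table / positive_rate
# ---------------------------------------------------------------------


def test_build_table_toy():
    t = long_frame([("t1", 1, "A", "a1"), ("t1", 1, "B", "b1")])
    b = long_frame([("b1", 0, "B", "b2")])
    table = build_table(t, b, ["A", "B"])
    assert table.frame.shape == (2, 3)
    assert table.frame.loc["t1", "A"] == "a1"
    assert pd.isna(table.frame.loc["b1", "A"])
    assert table.frame.loc["b1", "label"] == 0


def test_all_missing_patient_keeps_row_with_label():
    t = long_frame([("t1", 1, "A", "a1")])
    b = long_frame([("b1", 0, "Z", "z")])  # no shared code cell
    table = build_table(t, b, ["A"])
    assert pd.isna(table.frame.loc["b1", "A"]) and table.frame.loc["b1", "label"] == 0


def test_duplicate_patient_across_sets_rejected():
    t = long_frame([("p1", 1, "A", "x")])
    b = long_frame([("p1", 0, "A", "y")])
    with pytest.raises(ValueError):
        build_table(t, b, ["A"])


def test_positive_rate_conventions():
    # reference case-control composition: 1,158 targets / 29,787 backgrounds
    n_t, n_b = 1158, 29787
    frame = pd.DataFrame({"patient_id": [f"p{i}" for i in range(n_t + n_b)], "label": [1] * n_t + [0] * n_b}).set_index("patient_id")
    table = MLTable(frame, {})
    assert positive_rate(table) == pytest.approx(0.037, abs=5e-4)
    # and the balanced set 1158/4221 read as a target:background ratio
    frame2 = pd.DataFrame({"patient_id": [f"p{i}" for i in range(1158 + 4221)], "label": [1] * 1158 + [0] * 4221}).set_index("patient_id")
    assert target_background_ratio(MLTable(frame2, {})) == pytest.approx(0.274, abs=5e-4)


def test_positive_rate_degenerate_cases():
    all_pos = MLTable(pd.DataFrame({"label": [1, 1]}, index=["a", "b"]), {})
    assert positive_rate(all_pos) == 1.0
    half = MLTable(pd.DataFrame({"label": [1, 0]}, index=["a", "b"]), {})
    assert positive_rate(half) == 0.5
    with pytest.raises(ValueError):
        positive_rate(MLTable(pd.DataFrame({"label": []}), {}))


# ---------------------------------------------------------------------
# balance
# ---------------------------------------------------------------------


def test_balance_threshold_inclusive():
    rows = [
        {"patient_id": "t1", "label": 1, **{f"c{i}": "x" for i in range(10)}},
        {"patient_id": "b1", "label": 0, **{f"c{i}": "x" for i in range(50)}},
        {"patient_id": "b2", "label": 0, **{f"c{i}": "x" for i in range(100)}},
        {"patient_id": "b3", "label": 0, **{f"c{i}": "x" for i in range(150)}},
    ]
    frame = pd.DataFrame(rows).set_index("patient_id")
    table = MLTable(frame, {c: "categorical" for c in frame.columns if c != "label"})
    out = balance(table, BalanceConfig(min_shared_codes=100))
    assert list(out.frame.index) == ["t1", "b2", "b3"]


def test_balance_identity_when_threshold_one():
    table = toy_table(
        [
            {"patient_id": "t1", "label": 1, "A": "x", "B": "y"},
            {"patient_id": "b1", "label": 0, "A": "x", "B": "y"},
        ]
    )
    out = balance(table, BalanceConfig(1))
    pd.testing.assert_frame_equal(out.frame, table.frame)


def test_balance_never_drops_targets_and_raises_when_no_background():
    table = toy_table(
        [
            {"patient_id": "t1", "label": 1, "A": None},
            {"patient_id": "b1", "label": 0, "A": None},
        ]
    )
    with pytest.raises(ValueError):
        balance(table, BalanceConfig(1))


@settings(max_examples=40, derandomize=True, deadline=None)
@given(
    cells=st.lists(
        st.tuples(st.booleans(), st.lists(st.booleans(), min_size=4, max_size=4)),
        min_size=3,
        max_size=20,
    ),
    thresh=st.integers(min_value=1, max_value=4),
)
def test_balance_monotonicity_property(cells, thresh):
    """For any table and threshold, balancing never lowers the positive
    rate (targets are kept, only code-poor backgrounds drop)."""
    rows = []
    for i, (label, present) in enumerate(cells):
        rows.append({f"c{j}": ("x" if p else None) for j, p in enumerate(present)} | {"label": int(label)})
    frame = pd.DataFrame(rows, index=[f"p{i}" for i in range(len(rows))])
    table = MLTable(frame, {f"c{j}": "categorical" for j in range(4)})
    if table.n_targets == 0 or table.n_backgrounds == 0:
        return
    try:
        out = balance(table, BalanceConfig(thresh))
    except ValueError:
        return  # no background survived: monotonicity is vacuous
    assert positive_rate(out) >= positive_rate(table)


def test_balance_monotonically_increases_positive_rate():
    rng = np.random.default_rng(1)
    for _ in range(20):
        rows = []
        for i in range(30):
            label = int(rng.random() < 0.3)
            cells = {f"c{j}": ("x" if rng.random() < 0.5 else None) for j in range(12)}
            rows.append({"patient_id": f"p{i}", "label": label, **cells})
        frame = pd.DataFrame(rows).set_index("patient_id")
        table = MLTable(frame, {c: "categorical" for c in frame.columns if c != "label"})
        if table.n_targets == 0:
            continue
        thresh = int(rng.integers(1, 8))
        try:
            out = balance(table, BalanceConfig(thresh))
        except ValueError:
            continue
        assert positive_rate(out) >= positive_rate(table)
        expect = balance_filter(frame, table.codes, thresh)
        assert list(out.frame.index) == expect


# ---------------------------------------------------------------------
# convert_values
# ---------------------------------------------------------------------


def test_cholesterol_and_age_rules():
    frame = pd.DataFrame(
        {"2093-3": [185.0, 210.0, None], "age": [49.9, 50.0, 30.0], "label": [1, 0, 0]},
        index=["p1", "p2", "p3"],
    )
    table = MLTable(frame, {"2093-3": "numeric", "age": "numeric"})
    out = convert_values(table, default_conversion_map())
    assert list(out.frame["2093-3"])[:2] == ["normal", "high"]
    assert pd.isna(out.frame.loc["p3", "2093-3"])
    assert list(out.frame["age"]) == ["under50", "over50", "under50"]


def test_breakpoint_boundary_goes_to_upper_bin():
    cmap = ConversionMap({"x": ((10.0,), ("lo", "hi"))})
    table = MLTable(pd.DataFrame({"x": [9.999, 10.0, 10.001], "label": [0, 0, 1]}, index=list("abc")), {"x": "numeric"})
    assert list(convert_values(table, cmap).frame["x"]) == ["lo", "hi", "hi"]


def test_conversion_is_idempotent_on_categorical_tables():
    table = toy_table([{"patient_id": "p1", "label": 1, "A": "x"}])
    out = convert_values(table, default_conversion_map())
    pd.testing.assert_frame_equal(out.frame, table.frame)


def test_unmapped_numeric_column_warns_and_bins():
    table = MLTable(pd.DataFrame({"q": [1.0, 2.0, 3.0, 4.0], "label": [0, 0, 1, 1]}, index=list("abcd")), {"q": "numeric"})
    with pytest.warns(UserWarning, match="median split"):
        out = convert_values(table, ConversionMap({}))
    assert set(out.frame["q"]) <= {"low", "high"}
    assert out.datatypes["q"] == "categorical"
    assert out.origin_datatypes["q"] == "numeric"


def test_non_numeric_cell_in_numeric_column_rejected():
    table = MLTable(pd.DataFrame({"q": ["oops"], "label": [1]}, index=["a"]), {"q": "numeric"})
    with pytest.raises(ValueError):
        convert_values(table, default_conversion_map())


def test_conversion_map_validation():
    with pytest.raises(ValueError):
        ConversionMap({"x": ((2.0, 1.0), ("a", "b", "c"))})
    with pytest.raises(ValueError):
        ConversionMap({"x": ((1.0,), ("a",))})


# ---------------------------------------------------------------------
# select_variables
# ---------------------------------------------------------------------


def _occurrence_table(occ: dict, n_rows: int):
    data = {}
    for code, k in occ.items():
        data[code] = ["x"] * k + [None] * (n_rows - k)
    data["label"] = [1] * (n_rows // 2) + [0] * (n_rows - n_rows // 2)
    frame = pd.DataFrame(data, index=[f"p{i}" for i in range(n_rows)])
    return MLTable(frame, {c: "categorical" for c in occ})


def test_selection_cutoff_and_ordering():
    table = _occurrence_table({"A": 10, "B": 3}, 12)
    assert select_variables(table, VariableSelection(5)) == ["A"]
    table2 = _occurrence_table({"A": 6, "B": 9, "C": 6}, 12)
    assert select_variables(table2, VariableSelection(5)) == ["B", "A", "C"]
    assert select_variables(table2, VariableSelection(5, n_top=1)) == ["B"]


def test_selection_zero_passing_raises():
    table = _occurrence_table({"A": 2}, 10)
    with pytest.raises(ValueError):
        select_variables(table, VariableSelection(5))


def test_selection_kind_categorical_excludes_converted_numeric():
    frame = pd.DataFrame({"cat": ["x"] * 6, "num": [1.0] * 6, "label": [1, 1, 1, 0, 0, 0]}, index=[f"p{i}" for i in range(6)])
    table = MLTable(frame, {"cat": "categorical", "num": "numeric"})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        conv = convert_values(table, ConversionMap({}))
    assert select_variables(conv, VariableSelection(2, kind="categorical")) == ["cat"]
    assert set(select_variables(conv, VariableSelection(2, kind="all"))) == {"cat", "num"}


def test_selection_matches_brute_force_oracle():
    rng = np.random.default_rng(2)
    for _ in range(20):
        occ = {f"c{i}": int(rng.integers(0, 15)) for i in range(8)}
        table = _occurrence_table(occ, 15)
        cutoff = int(rng.integers(1, 10))
        expect = select_by_occurrence(table.frame, table.codes, cutoff)
        if not expect:
            with pytest.raises(ValueError):
                select_variables(table, VariableSelection(cutoff))
        else:
            assert select_variables(table, VariableSelection(cutoff)) == expect


def test_variable_report_flags_selection():
    table = _occurrence_table({"A": 10, "B": 3}, 12)
    rep = variable_report(table, VariableSelection(5))
    assert rep.loc[rep["code"] == "A", "selected"].item()
    assert not rep.loc[rep["code"] == "B", "selected"].item()
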