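import numpy as np
import pandas as pd
import pytest

from ciequity import (
    PanelTable,
    RegistryError,
    StructuralError,
    VariableRoles,
    VariableTypeError,
    consistency_check,
    impute_missing,
    iqr_outlier_correct,
    read_panel,
    write_panel,
)


def test_roles_rejects_overlapping_sets():
    with pytest.raises(RegistryError):
        VariableRoles(outcomes=["BPK"], need=["MMR"], non_need=["MMR"],
                      rank_var="PCGDP")
    with pytest.raises(RegistryError):
        VariableRoles(outcomes=["BPK"], need=[], non_need=[], rank_var="BPK")


def test_roles_yaml_round_trip(tmp_path, toy_roles):
    path = tmp_path / "roles.yaml"
    toy_roles.to_yaml(path)
    back = VariableRoles.from_yaml(path)
    assert back == toy_roles


def test_read_write_round_trip(tmp_path, toy_panel):
    """read -> write -> read preserves all finite numerics bit-for-bit."""
    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    write_panel(toy_panel, p1)
    t1 = read_panel(p1, toy_panel.roles)
    assert len(t1) == 8
    write_panel(t1, p2)
    t2 = read_panel(p2, toy_panel.roles)
    pd.testing.assert_frame_equal(t1.data, t2.data)
    for col in ("BPK", "MMR", "PCGDP"):
        np.testing.assert_array_equal(
            t1.data[col].to_numpy(), toy_panel.data[col].to_numpy()
        )


def test_duplicate_region_year_is_structural_error(toy_panel):
    df = pd.concat([toy_panel.data, toy_panel.data.iloc[[0]]], ignore_index=True)
    with pytest.raises(StructuralError, match="duplicate"):
        PanelTable(data=df, roles=toy_panel.roles)


def test_missing_registered_column_is_registry_error(tmp_path, toy_panel):
    path = tmp_path / "panel.csv"
    toy_panel.data.drop(columns=["MMR"]).to_csv(path, index=False)
    with pytest.raises(RegistryError, match="MMR"):
        read_panel(path, toy_panel.roles)


def test_unparseable_cells_become_missing(tmp_path, toy_roles):
    path = tmp_path / "panel.csv"
    df = pd.DataFrame(
        {"region": ["A", "B", "C"], "year": [2009] * 3,
         "BPK": ["1.5", "oops", "2.0"], "MMR": [1, 2, 3], "PCGDP": [1, 2, 3]}
    )
    df.to_csv(path, index=False)
    table = read_panel(path, toy_roles)
    assert table.data["BPK"].isna().sum() == 1


def test_weights_validated(toy_panel):
    df = toy_panel.data.copy()
    df["weight"] = 0.0
    with pytest.raises(StructuralError, match="zero"):
        PanelTable(data=df, roles=toy_panel.roles)
    df["weight"] = [-1.0] + [1.0] * 7
    with pytest.raises(StructuralError, match="nonnegative"):
        PanelTable(data=df, roles=toy_panel.roles)


# ---------------------------------------------------------------------------
# IQR winsorization


def _one_year_panel(values, var="MMR"):
    n = len(values)
    data = pd.DataFrame(
        {"region": [f"R{i}" for i in range(n)], "year": [2009] * n,
         var: values, "BPK": 1.0, "PCGDP": np.arange(n, dtype=float) + 1}
    )
    roles = VariableRoles(outcomes=["BPK"], need=[var] if var != "BPK" else [],
                          non_need=[], rank_var="PCGDP")
    return PanelTable(data=data, roles=roles)


def test_iqr_winsorizes_to_upper_fence():
    # type-7 quartiles of {1,2,3,100}: Q1=1.75, Q3=27.25, upper fence 65.5
    table = _one_year_panel([1.0, 2.0, 3.0, 100.0])
    out, log = iqr_outlier_correct(table, ["MMR"], k=1.5)
    assert len(log) == 1
    assert log.iloc[0]["old"] == 100.0
    assert out.data["MMR"].max() == pytest.approx(65.5)


def test_iqr_no_op_inside_fences():
    table = _one_year_panel([1.0, 2.0, 3.0, 4.0])
    out, log = iqr_outlier_correct(table, ["MMR"])
    assert log.empty
    pd.testing.assert_frame_equal(out.data, table.data)


def test_iqr_constant_group_untouched():
    table = _one_year_panel([5.0, 5.0, 5.0, 5.0])
    out, log = iqr_outlier_correct(table, ["MMR"])
    assert log.empty  # IQR 0, fences [5,5], equality is inside


def test_iqr_small_group_skipped():
    table = _one_year_panel([1.0, 2.0, 200.0])
    out, log = iqr_outlier_correct(table, ["MMR"])
    assert log.empty
    assert out.data["MMR"].max() == 200.0


def test_iqr_idempotent_on_cross_section():
    """When the quartiles don't run through the corrected order statistics
    (the realistic 31-region screen), a second pass changes nothing."""
    rng = np.random.default_rng(5)
    values = np.concatenate([rng.normal(10, 1, 29), [60.0, -40.0]])
    table = _one_year_panel(values)
    once, log1 = iqr_outlier_correct(table, ["MMR"])
    assert len(log1) == 2
    twice, log2 = iqr_outlier_correct(once, ["MMR"])
    assert log2.empty
    pd.testing.assert_frame_equal(once.data, twice.data)


def test_iqr_rejects_non_numeric():
    table = _one_year_panel([1.0, 2.0, 3.0, 4.0])
    df = table.data.copy()
    df["MMR"] = df["MMR"].astype(str)
    broken = PanelTable(data=df, roles=table.roles)
    with pytest.raises(VariableTypeError):
        iqr_outlier_correct(broken, ["MMR"])


def test_iqr_rejects_nonpositive_k(toy_panel):
    with pytest.raises(ValueError):
        iqr_outlier_correct(toy_panel, ["MMR"], k=0.0)


# ---------------------------------------------------------------------------
# Imputation


def _series_panel(year_values, var="MMR"):
    rows = [
        {"region": "A", "year": y, var: v, "BPK": 1.0, "PCGDP": 1.0 + y - 2009}
        for y, v in year_values
    ]
    roles = VariableRoles(outcomes=["BPK"], need=[var], non_need=[],
                          rank_var="PCGDP")
    return PanelTable(data=pd.DataFrame(rows), roles=roles)


def test_linear_interpolation_fills_midpoint():
    table = _series_panel([(2014, 10.0), (2015, np.nan), (2016, 12.0)])
    out, log = impute_missing(table, "MMR", "linear_interpolation")
    assert out.data.loc[out.data["year"] == 2015, "MMR"].item() == pytest.approx(11.0)
    assert (log["status"] == "imputed").sum() == 1


def test_leading_gap_left_missing():
    table = _series_panel([(2009, np.nan), (2010, 5.0)])
    out, log = impute_missing(table, "MMR", "linear_interpolation")
    assert np.isnan(out.data.loc[out.data["year"] == 2009, "MMR"].item())
    assert (log["status"] == "left_missing").sum() == 1


def test_neighbor_mean_and_fluctuation_check():
    table = _series_panel([(2014, 100.0), (2015, np.nan), (2016, 104.0)])
    out, log = impute_missing(table, "MMR", "neighbor_mean")
    assert out.data.loc[out.data["year"] == 2015, "MMR"].item() == pytest.approx(102.0)
    fluct = log.loc[log["status"] == "imputed", "fluctuation"].item()
    assert fluct == pytest.approx(0.02)
    assert fluct < 0.05  # consistent with the adjacent-year screen


def test_all_missing_region_logged():
    table = _series_panel([(2009, np.nan), (2010, np.nan)])
    out, log = impute_missing(table, "MMR")
    assert out.data["MMR"].isna().all()
    assert (log["status"] == "all_missing").sum() == 1


@pytest.mark.parametrize("method", ["linear_interpolation", "neighbor_mean"])
def test_imputation_never_alters_observed_cells(method):
    rng = np.random.default_rng(9)
    rows = []
    for region in ("A", "B", "C"):
        for year in range(2009, 2016):
            v = np.nan if rng.random() < 0.3 else rng.normal(50, 5)
            rows.append({"region": region, "year": year, "MMR": v,
                         "BPK": 1.0, "PCGDP": rng.random() + 1})
    roles = VariableRoles(outcomes=["BPK"], need=["MMR"], non_need=[],
                          rank_var="PCGDP")
    table = PanelTable(data=pd.DataFrame(rows), roles=roles)
    out, _ = impute_missing(table, "MMR", method)
    observed = table.data["MMR"].notna()
    np.testing.assert_array_equal(
        out.data.loc[observed, "MMR"].to_numpy(),
        table.data.loc[observed, "MMR"].to_numpy(),
    )


# ---------------------------------------------------------------------------
# Consistency rules


def test_consistency_reports_violations(toy_panel):
    df = toy_panel.data.copy()
    df.loc[0, "BPK"] = 1e6  # beds exceed institution capacity
    table = PanelTable(data=df, roles=toy_panel.roles)
    report = consistency_check(table, [("BPK", "<=", "PCGDP", 1000.0)])
    assert len(report) == 1
    assert report.iloc[0]["region"] == "A"


def test_consistency_empty_rules_and_satisfied_rules(toy_panel):
    assert consistency_check(toy_panel, []).empty
    assert consistency_check(toy_panel, [("BPK", "<=", "PCGDP", 1000.0)]).empty


def test_consistency_does_not_mutate(toy_panel):
    before = toy_panel.data.copy()
    consistency_check(toy_panel, [("BPK", "<=", "MMR")])
    pd.testing.assert_frame_equal(toy_panel.data, before)


def test_consistency_unknown_column(toy_panel):
    with pytest.raises(RegistryError):
        consistency_check(toy_panel, [("BPK", "<=", "NOPE")])
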