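import json
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rbpmap import (
    ExperimentDesign,
    FormatError,
    QuantTable,
    RatioPair,
    TMT11_CHANNELS,
    ValidationError,
    apply_detection_filter,
    compute_ratios,
    read_gene_list,
    read_quant_table,
    write_gene_list,
    write_quant_table,
)


# ---------------------------------------------------------------------------
# quantification tables
# ---------------------------------------------------------------------------

def test_quant_table_roundtrip(small_table, tmp_path):
    path = tmp_path / "quant.tsv"
    write_quant_table(small_table, path)
    back = read_quant_table(path)
    assert len(back) == 3
    assert set(back.channels) == set(TMT11_CHANNELS)
    pd.testing.assert_frame_equal(
        back.data[list(small_table.data.columns)], small_table.data
    )


def test_missing_required_column_raises(small_table, tmp_path):
    path = tmp_path / "bad.tsv"
    small_table.data.drop(columns=["protein_score"]).to_csv(path, sep="\t", index=False)
    with pytest.raises(FormatError, match="protein_score absent"):
        read_quant_table(path)


def test_duplicate_symbols_strict_mode(tmp_path):
    df = pd.DataFrame({
        "protein_id": ["P1", "P2"],
        "gene_symbol": ["Srsf1", "SRSF1"],
        "n_distinct_peptides": [3, 4],
        "protein_score": [30.0, 40.0],
        "126C": [1.0, 2.0],
        "127N": [1.0, 2.0],
    })
    path = tmp_path / "dup.tsv"
    df.to_csv(path, sep="\t", index=False)
    with pytest.raises(ValidationError, match="SRSF1"):
        read_quant_table(path, strict=True)
    merged = read_quant_table(path, strict=False)
    assert merged.gene_symbols == ["SRSF1"]
    assert merged.data["protein_score"].iloc[0] == 40.0  # highest score kept


def test_negative_channel_value_rejected():
    df = pd.DataFrame({
        "protein_id": ["P1"], "gene_symbol": ["A"],
        "n_distinct_peptides": [2], "protein_score": [30.0],
        "126C": [-1.0], "127N": [1.0],
    })
    with pytest.raises(ValidationError, match="negative"):
        QuantTable(df)


# ---------------------------------------------------------------------------
# detection filter
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("peptides,score,kept", [
    (1, 99.0, False),   # peptide count below threshold despite high score
    (2, 20.0, True),    # both thresholds inclusive at the boundary
    (2, 19.9, False),
    (10, 20.0, True),
])
def test_detection_filter_boundaries(peptides, score, kept):
    df = pd.DataFrame({
        "protein_id": ["P1"], "gene_symbol": ["A"],
        "n_distinct_peptides": [peptides], "protein_score": [score],
        "126C": [1.0], "127N": [1.0],
    })
    out = apply_detection_filter(QuantTable(df), 2, 20.0)
    assert (len(out) == 1) == kept


def test_detection_filter_idempotent(small_table):
    once = apply_detection_filter(small_table, 3, 50.0)
    twice = apply_detection_filter(once, 3, 50.0)
    pd.testing.assert_frame_equal(once.data, twice.data)


# ---------------------------------------------------------------------------
# ratios
# ---------------------------------------------------------------------------

def _mini_table(vals_126C, vals_128N):
    n = len(vals_126C)
    return QuantTable(pd.DataFrame({
        "protein_id": [f"P{i}" for i in range(n)],
        "gene_symbol": [f"G{i}" for i in range(n)],
        "n_distinct_peptides": [3] * n,
        "protein_score": [30.0] * n,
        "126C": vals_126C,
        "128N": vals_128N,
    }))


def test_compute_ratios_hand_arithmetic():
    design = ExperimentDesign(
        channels=[("126C", "background_control"), ("128N", "experimental")],
        comparisons=[RatioPair("128N", "126C", 1)], min_replicates_k=1)
    table = _mini_table([500.0, 100.0, 0.0], [500.0, 400.0, 300.0])
    rt = compute_ratios(table, design)
    col = rt.values["128N/126C"]
    assert col["G0"] == 1.0                      # identity
    assert col["G1"] == 4.0                      # 400 / 100
    assert np.isnan(col["G2"])                   # zero denominator -> missing


def test_compute_ratios_missing_numerator_is_missing():
    design = ExperimentDesign(
        channels=[("126C", "background_control"), ("128N", "experimental")],
        comparisons=[RatioPair("128N", "126C", 1)], min_replicates_k=1)
    table = _mini_table([100.0], [np.nan])
    rt = compute_ratios(table, design)
    assert np.isnan(rt.values["128N/126C"]).all()


@given(scale=st.floats(min_value=0.01, max_value=100.0,
                       allow_nan=False, allow_infinity=False))
@settings(max_examples=30, deadline=None)
def test_ratios_invariant_to_global_row_rescaling(scale):
    design = ExperimentDesign(
        channels=[("126C", "background_control"), ("128N", "experimental")],
        comparisons=[RatioPair("128N", "126C", 1)], min_replicates_k=1)
    base = _mini_table([100.0, 250.0], [400.0, 125.0])
    scaled_df = base.data.copy()
    scaled_df[["126C", "128N"]] *= scale
    r1 = compute_ratios(base, design).values
    r2 = compute_ratios(QuantTable(scaled_df), design).values
    np.testing.assert_allclose(r1.to_numpy(), r2.to_numpy(), rtol=1e-9)


def test_relative_ratio_export_matches_direct_division():
    # channel values exported as ratios to a base channel give the same
    # pair ratio as raw intensities
    design = ExperimentDesign(
        channels=[("126C", "background_control"), ("128N", "experimental")],
        comparisons=[RatioPair("128N", "126C", 1)], min_replicates_k=1)
    raw = _mini_table([200.0, 80.0], [500.0, 240.0])
    base_channel = raw.data["126C"]
    rel_df = raw.data.copy()
    for ch in ("126C", "128N"):
        rel_df[ch] = raw.data[ch] / base_channel
    direct = compute_ratios(raw, design).values
    derived = compute_ratios(QuantTable(rel_df), design).values
    np.testing.assert_allclose(direct.to_numpy(), derived.to_numpy(), rtol=1e-12)


# ---------------------------------------------------------------------------
# gene lists
# ---------------------------------------------------------------------------

def test_gene_list_parsing_and_roundtrip(tmp_path):
    path = tmp_path / "genes.txt"
    path.write_text("# curated list\nsrsf1\nHNRNPC\nFBL\nFBL\n")
    genes = read_gene_list(path)
    assert genes == {"SRSF1", "HNRNPC", "FBL"}

    out = tmp_path / "out.txt"
    write_gene_list(genes, out)
    assert read_gene_list(out) == genes
    assert out.read_text().endswith("\n")


def test_gene_list_header_skipped_and_empty_warns(tmp_path):
    path = tmp_path / "withheader.txt"
    path.write_text("gene_symbol\nNCL\n")
    assert read_gene_list(path) == {"NCL"}
    empty = tmp_path / "empty.txt"
    empty.write_text("")
    with pytest.warns(UserWarning, match="empty"):
        assert read_gene_list(empty) == set()


@given(st.sets(st.text(alphabet="ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789",
                       min_size=1, max_size=8), min_size=1, max_size=40))
@settings(max_examples=25, deadline=None)
def test_gene_list_write_read_inverse(tmp_path_factory, symbols):
    path = tmp_path_factory.mktemp("gl") / "s.txt"
    write_gene_list(symbols, path)
    assert read_gene_list(path) == symbols


# ---------------------------------------------------------------------------
# experiment design
# ---------------------------------------------------------------------------

def test_design_json_roundtrip(tmp_path, simple_design):
    path = tmp_path / "design.json"
    simple_design.write_json(path)
    back = ExperimentDesign.read_json(path)
    assert back == simple_design
    assert back.config_hash() == simple_design.config_hash()
    # file is the documented schema
    raw = json.loads(path.read_text())
    assert {"channels", "comparisons", "min_replicates_k", "detection"} <= set(raw)


@pytest.mark.parametrize("kwargs,match", [
    (dict(channels=[("126C", "experimental")],
          comparisons=[RatioPair("126C", "127N", 1)]), "not declared"),
    (dict(channels=[("126C", "experimental"), ("127N", "background_control")],
          comparisons=[RatioPair("126C", "127N", 1)], min_replicates_k=5), "min_replicates_k"),
    (dict(channels=[("126C", "mystery_role")], comparisons=[]), "role"),
])
def test_design_validation_errors(kwargs, match):
    with pytest.raises(ValidationError, match=match):
        ExperimentDesign(**kwargs)


def test_ratio_pair_same_channel_rejected():
    with pytest.raises(ValidationError, match="must differ"):
        RatioPair("126C", "126C", 1)
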