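"""Perseus-style chain: filtering, imputation, normalization, volcano, join."""

import numpy as np
import pandas as pd
import pytest

from glyconodule.proteome_compare import (
    PipelineOrderError,
    QuantTable,
    impute,
    lewis_a_proteins,
    normalize,
    preprocess,
    read_quant_csv,
    volcano,
    volcano_table,
)
from glyconodule.synthetic_data import simulate_quant_table


def _tiny_table(values=None, n_pairs=3):
    wt = [f"wt_{i}" for i in range(1, n_pairs + 1)]
    mut = [f"mut_{i}" for i in range(1, n_pairs + 1)]
    if values is None:
        rng = np.random.default_rng(0)
        values = pd.DataFrame(
            rng.lognormal(10, 1, size=(8, 2 * n_pairs)),
            index=[f"P{i}" for i in range(8)], columns=wt + mut,
        )
    groups = {s: "WT" for s in wt} | {s: "MUT" for s in mut}
    pairs = {s: i + 1 for i, s in enumerate(wt)} | {
        s: i + 1 for i, s in enumerate(mut)
    }
    return QuantTable(data=values, groups=groups, pairs=pairs)


# ---------------------------------------------------------------------------
# preprocess
# ---------------------------------------------------------------------------

def test_preprocess_filter_rule():
    data = pd.DataFrame(
        {
            "wt_1": [8.0, 8.0, 8.0],
            "wt_2": [8.0, 8.0, np.nan],
            "wt_3": [8.0, np.nan, np.nan],
            "mut_1": [8.0, 8.0, np.nan],
            "mut_2": [8.0, 8.0, np.nan],
            "mut_3": [8.0, np.nan, np.nan],
        },
        index=["full", "two_two", "sparse"],
    )
    t = preprocess(_tiny_table(values=data))
    # 2 WT + 2 MUT observed -> dropped; 3 in one group -> kept
    assert list(t.data.index) == ["full"]
    assert t.data.loc["full", "wt_1"] == pytest.approx(3.0)  # log2(8)


def test_preprocess_keeps_three_in_single_group():
    data = pd.DataFrame(
        {
            "wt_1": [2.0], "wt_2": [2.0], "wt_3": [2.0],
            "mut_1": [np.nan], "mut_2": [np.nan], "mut_3": [np.nan],
        },
        index=["wt_only"],
    )
    t = preprocess(_tiny_table(values=data))
    assert list(t.data.index) == ["wt_only"]


def test_preprocess_rejects_nonpositive():
    data = pd.DataFrame(
        {c: [1.0] for c in ["wt_1", "wt_2", "wt_3", "mut_1", "mut_2", "mut_3"]},
        index=["P0"],
    )
    data.loc["P0", "mut_2"] = -4.0
    with pytest.raises(ValueError, match="mut_2"):
        preprocess(_tiny_table(values=data))


# ---------------------------------------------------------------------------
# impute
# ---------------------------------------------------------------------------

def test_impute_no_missing_is_identity():
    t = preprocess(_tiny_table())
    out = impute(t, seed=1)
    pd.testing.assert_frame_equal(out.data, t.data)


def test_impute_deterministic():
    t = preprocess(_tiny_table())
    t.data.iloc[0, 0] = np.nan
    a = impute(t, seed=5)
    b = impute(t, seed=5)
    pd.testing.assert_frame_equal(a.data, b.data)
    c = impute(t, seed=6)
    assert not a.data.equals(c.data)


def test_impute_downshift_width_moments():
    """10,000 draws in a column with mean 20, sd 1 land at 18.2 +- 0.05 with
    sd 0.3 +- 0.02 (downshift 1.8, width 0.3)."""
    rng = np.random.default_rng(11)
    observed = rng.normal(0.0, 1.0, 400)
    observed = (observed - observed.mean()) / observed.std(ddof=1) + 20.0
    col = np.concatenate([observed, np.full(10_000, np.nan)])
    t = QuantTable(
        data=pd.DataFrame({"s1": col}),
        groups={"s1": "WT"},
        pairs={"s1": 1},
        stage="preprocessed",
    )
    out = impute(t, width=0.3, downshift=1.8, seed=2)
    imputed = out.data["s1"].values[len(observed):]
    assert imputed.mean() == pytest.approx(18.2, abs=0.05)
    assert imputed.std(ddof=1) == pytest.approx(0.3, abs=0.02)


def test_impute_needs_two_observed():
    data = pd.DataFrame(
        {c: [np.nan, 4.0] for c in
         ["wt_1", "wt_2", "wt_3", "mut_1", "mut_2", "mut_3"]}
    )
    data["wt_1"] = [np.nan, np.nan]
    t = _tiny_table(values=data)
    t.stage = "preprocessed"
    with pytest.raises(ValueError, match="wt_1"):
        impute(t)


# ---------------------------------------------------------------------------
# normalize
# ---------------------------------------------------------------------------

def test_normalize_equalizes_sample_medians():
    t = impute(preprocess(_tiny_table()), seed=0)
    out = normalize(t)
    medians = out.data.median(axis=0)
    assert np.allclose(medians, medians.iloc[0], atol=1e-9)


def test_normalize_undoes_column_shift():
    """A constant added to one sample vanishes from all between-sample
    contrasts; the tables agree up to a single global offset from the
    data-dependent grand median."""
    t = impute(preprocess(_tiny_table()), seed=0)
    base = normalize(t).data
    shifted = QuantTable(t.data.copy(), t.groups, t.pairs, stage=t.stage)
    shifted.data["wt_2"] = shifted.data["wt_2"] + 1.0
    again = normalize(shifted).data
    diff = (again - base).values
    assert np.allclose(diff, diff.flat[0], atol=1e-12)  # constant matrix
    centered_base = base - base.median(axis=0)
    centered_again = again - again.median(axis=0)
    pd.testing.assert_frame_equal(centered_base, centered_again)


def test_aligned_table_unchanged():
    t = impute(preprocess(_tiny_table()), seed=0)
    aligned = normalize(t)
    twice = normalize(QuantTable(aligned.data, aligned.groups, aligned.pairs,
                                 stage="imputed"))
    pd.testing.assert_frame_equal(aligned.data, twice.data)


# ---------------------------------------------------------------------------
# chain order
# ---------------------------------------------------------------------------

def test_chain_order_enforced():
    t = _tiny_table()
    with pytest.raises(PipelineOrderError):
        impute(t)
    with pytest.raises(PipelineOrderError):
        normalize(t)
    with pytest.raises(PipelineOrderError):
        volcano(t)
    with pytest.raises(PipelineOrderError):
        preprocess(preprocess(t))


# ---------------------------------------------------------------------------
# volcano
# ---------------------------------------------------------------------------

def test_volcano_identical_groups_not_significant():
    rng = np.random.default_rng(3)
    base = rng.normal(20, 1, size=(5, 3))
    data = pd.DataFrame(
        np.hstack([base, base]),
        columns=["wt_1", "wt_2", "wt_3", "mut_1", "mut_2", "mut_3"],
        index=[f"P{i}" for i in range(5)],
    )
    t = _tiny_table(values=np.exp2(data))
    records = volcano(normalize(impute(preprocess(t), seed=0)))
    assert all(not r.significant for r in records)
    assert all(r.degenerate for r in records)  # zero within-pair variance


def test_volcano_constant_offset_degenerate():
    data = pd.DataFrame(
        {
            "wt_1": [10.0] , "wt_2": [10.0], "wt_3": [10.0],
            "mut_1": [11.0], "mut_2": [11.0], "mut_3": [11.0],
        },
        index=["P0"],
    )
    t = _tiny_table(values=np.exp2(data))
    t = normalize(impute(preprocess(t), seed=0))
    # undo normalization's median equalization to keep the planted offset
    recs = volcano(t)
    assert recs[0].degenerate and not recs[0].significant


def test_volcano_recovery_and_specificity():
    """Planted 2x shifts on 50/1000 rows: >=90% recovered, <=5% false."""
    table, _, truth = simulate_quant_table(
        n_proteins=1000, n_pairs=5, n_shifted=50, shift_log2=1.0,
        missingness=0.1, seed=7,
    )
    chain = normalize(impute(preprocess(table), seed=7))
    df = volcano_table(volcano(chain)).set_index("accession")
    planted = set(truth["shifted_accessions"]) & set(df.index)
    sens = df.loc[sorted(planted), "significant"].mean()
    fp = df.loc[~df.index.isin(planted), "significant"].mean()
    assert sens >= 0.90
    assert fp <= 0.05


def test_null_table_nominal_significance_rate():
    """With no missingness and no effect, ~5% of rows reach p < 0.05."""
    table, _, _ = simulate_quant_table(
        n_proteins=10_000, n_pairs=5, n_shifted=0, missingness=0.0, seed=13,
    )
    chain = normalize(impute(preprocess(table), seed=13))
    df = volcano_table(volcano(chain))
    frac_p = (df["p_value"] < 0.05).mean()
    assert frac_p == pytest.approx(0.05, abs=0.02)


# ---------------------------------------------------------------------------
# Lewis-a join
# ---------------------------------------------------------------------------

def test_lewis_a_proteins_selects_capacity_bearing():
    gp = pd.DataFrame(
        [
            {"accession": "A1", "peptide": "PEPK",
             "composition": "Hex:5 HexNAc:4 dHex:3 Pent:1"},
            {"accession": "A2", "peptide": "PEPR",
             "composition": "Hex:3 HexNAc:2 Pent:1"},
            {"accession": "A3", "peptide": "PEPX",
             "composition": "not a composition"},
        ]
    )
    result = lewis_a_proteins(gp)
    assert set(result) == {"A1"}
    assert result["A1"] == ["Hex:5 HexNAc:4 dHex:3 Pent:1"]


def test_lewis_a_empty_table():
    gp = pd.DataFrame(columns=["accession", "peptide", "composition"])
    assert lewis_a_proteins(gp) == {}


def test_designated_carriers_recovered():
    _, gp, truth = simulate_quant_table(seed=21)
    result = lewis_a_proteins(gp)
    assert set(result) == set(truth["lewis_a_accessions"])


def test_quant_csv_roundtrip(tmp_path):
    table, _, _ = simulate_quant_table(n_proteins=20, n_shifted=5, seed=1)
    table.data.to_csv(tmp_path / "quant.csv")
    pd.DataFrame(
        [
            {"sample": s, "group": table.groups[s], "pair": table.pairs[s]}
            for s in table.data.columns
        ]
    ).to_csv(tmp_path / "samples.csv", index=False)
    loaded = read_quant_csv(tmp_path / "quant.csv", tmp_path / "samples.csv")
    assert list(loaded.data.columns) == list(table.data.columns)
    assert loaded.groups == table.groups
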