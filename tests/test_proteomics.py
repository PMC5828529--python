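"""Differential-enrichment workflow: QC filters, normalization, MNAR
imputation, the moderated t against two independent oracles (closed-form
recomputation and Bioconductor limma), BH adjustment, gating and recovery."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chipms.proteomics import (
    IntensityTable,
    bh_adjust,
    classify_interactors,
    filter_proteins,
    impute_low_percentile,
    log2_median_center,
    moderated_ttest,
    read_intensity_table,
    recovery_score,
    run_enrichment,
    write_intensity_table,
)
from chipms.simulate import ProteomicsSimConfig, SimTruth, default_interactors, simulate_interactome_table

from oracles import brute_bh, brute_moderated_t, brute_percentile

SAMPLES = ["bait_1", "bait_2", "bait_3", "ctrl_1", "ctrl_2", "ctrl_3"]
CONDS = pd.Series(["bait"] * 3 + ["ctrl"] * 3, index=SAMPLES, name="condition")


def table_from_matrix(matrix, ids=None, log2=True, peptides=5, flags=None):
    matrix = np.asarray(matrix, dtype=float)
    ids = ids or [f"P{i:04d}" for i in range(1, len(matrix) + 1)]
    prot = pd.DataFrame(
        {
            "protein_id": ids,
            "is_reverse": False,
            "is_contaminant": False,
            "only_by_site": False,
            "unique_razor_peptides": peptides,
        }
    )
    if flags:
        for col, vals in flags.items():
            prot[col] = vals
    return IntensityTable(
        proteins=prot,
        intensities=pd.DataFrame(matrix, index=ids, columns=SAMPLES[: matrix.shape[1]]),
        conditions=CONDS[: matrix.shape[1]],
        log2_transformed=log2,
    )


# ---------------------------------------------------------------- filters


def test_flagged_and_low_peptide_proteins_removed():
    m = np.full((4, 6), 100.0)
    t = table_from_matrix(
        m,
        log2=False,
        flags={
            "is_reverse": [True, False, False, False],
            "unique_razor_peptides": [5, 1, 2, 5],
        },
    )
    out, counts = filter_proteins(t)
    kept = set(out.proteins["protein_id"])
    assert kept == {"P0003", "P0004"}  # flagged removed; 1 peptide removed; 2 kept
    assert counts["flagged"] == 1 and counts["few_peptides"] == 1


def test_valid_value_rule_boundaries():
    nan = np.nan
    m = np.array(
        [
            [10, 11, nan, 12, 13, nan],  # 2 bait + 2 ctrl -> removed under 'any'
            [10, 11, 12, nan, nan, nan],  # 3 bait + 0 ctrl -> kept under 'any'
            [10, 11, 12, 13, 14, 15],  # complete -> kept under both rules
        ]
    )
    t = table_from_matrix(m, log2=False)
    out, counts = filter_proteins(t)
    assert set(out.proteins["protein_id"]) == {"P0002", "P0003"}
    assert counts["too_few_valid_values"] == 1
    strict, _ = filter_proteins(t, valid_rule="all")
    assert set(strict.proteins["protein_id"]) == {"P0003"}


def test_empty_filter_result_errors():
    t = table_from_matrix(np.full((2, 6), 50.0), log2=False, flags={"is_reverse": [True, True]})
    with pytest.raises(ValueError, match="relax"):
        filter_proteins(t)


# --------------------------------------------------------- normalization


def test_median_centering_grand_median_arithmetic():
    # bait columns have medians 20 and 22 -> both move to the grand median
    m = np.array([[19, 21, 21, 21, 21, 21], [20, 22, 21, 21, 21, 21], [21, 23, 21, 21, 21, 21]])
    t = table_from_matrix(2.0 ** m, log2=False)
    out = log2_median_center(t)
    medians = out.intensities.median(axis=0)
    assert np.allclose(medians, 21.0)
    assert out.log2_transformed


def test_median_centering_shift_invariance_of_differences():
    rng = np.random.default_rng(0)
    m = rng.uniform(20, 30, size=(10, 6))
    base = log2_median_center(table_from_matrix(2.0**m, log2=False))
    shifted_in = m.copy()
    shifted_in[:, 0] += 3.0  # constant pre-centering offset on one column
    shifted = log2_median_center(table_from_matrix(2.0**shifted_in, log2=False))
    pd.testing.assert_frame_equal(base.intensities, shifted.intensities, atol=1e-9)


# -------------------------------------------------------------- imputation


def test_impute_examples_and_convention():
    nan = np.nan
    col = np.arange(10, 20, dtype=float)  # 10..19
    m = np.column_stack([col] + [np.full(10, 15.0)] * 5)
    m[3, 1] = nan
    t = table_from_matrix(m)
    out, mask = impute_low_percentile(t, q=2.5)
    assert not out.intensities.isna().any().any()
    assert mask.to_numpy().sum() == 1
    assert out.intensities.iloc[3, 1] == 15.0  # all observed equal c -> c
    # and the percentile convention itself, h=(n-1)q/100+1 on 10..19:
    assert brute_percentile(col, 2.5) == pytest.approx(10.225)
    assert np.percentile(col, 2.5) == pytest.approx(10.225)


def test_impute_no_missing_is_identity():
    m = np.random.default_rng(1).uniform(10, 20, (5, 6))
    t = table_from_matrix(m)
    out, mask = impute_low_percentile(t)
    pd.testing.assert_frame_equal(out.intensities, t.intensities)
    assert not mask.any().any()


def test_impute_uses_per_column_percentile():
    nan = np.nan
    m = np.column_stack([np.arange(10, 20, dtype=float)] * 6)
    m[0, 0] = nan
    t = table_from_matrix(m)
    out, _ = impute_low_percentile(t, q=2.5)
    # column 0's observed values are 11..19 (n=9): h = 8*0.025+1 = 1.2
    assert out.intensities.iloc[0, 0] == pytest.approx(brute_percentile(np.arange(11, 20), 2.5))


def test_impute_empty_column_errors():
    m = np.full((3, 6), 12.0)
    m[:, 2] = np.nan
    with pytest.raises(ValueError, match="entirely missing"):
        impute_low_percentile(table_from_matrix(m))


# ------------------------------------------------------------ moderated t


def test_identical_conditions_give_null_statistics():
    row = [14.0, 15.0, 16.0, 14.0, 15.0, 16.0]
    m = np.array([row] * 5) + np.arange(5)[:, None]  # spread across proteins
    rows = moderated_ttest(table_from_matrix(m))
    assert np.allclose(rows["log2_fc"], 0.0)
    assert np.allclose(rows["t_mod"], 0.0)
    assert np.allclose(rows["p"], 1.0)


def test_d0_infinity_limit_equals_common_variance_t():
    rng = np.random.default_rng(4)
    m = rng.normal(20, 1, size=(30, 6))
    m[:5, :3] += 3
    rows = moderated_ttest(table_from_matrix(m), d0_override=np.inf)
    s0_2 = rows["prior_s0_2"].iloc[0]
    expected_t = rows["log2_fc"] / np.sqrt(s0_2 * (1 / 3 + 1 / 3))
    np.testing.assert_allclose(rows["t_mod"], expected_t, atol=1e-9)


def test_moderated_t_matches_closed_form_oracle():
    rng = np.random.default_rng(11)
    m = rng.normal(22, 2, size=(20, 6)) + rng.normal(0, 0.5, size=(20, 6))
    rows = moderated_ttest(table_from_matrix(m))
    oracle = brute_moderated_t(m[:, :3], m[:, 3:])
    np.testing.assert_allclose(rows["log2_fc"], oracle["log2_fc"], atol=1e-10)
    np.testing.assert_allclose(rows["t_mod"], oracle["t"], rtol=1e-6)
    np.testing.assert_allclose(rows["p"], oracle["p"], rtol=1e-6)
    assert rows["prior_d0"].iloc[0] == pytest.approx(oracle["d0"], rel=1e-5)


def test_moderated_t_matches_limma(tmp_path):
    """Independent cross-check against Bioconductor limma's lmFit + eBayes."""
    rng = np.random.default_rng(7)
    m = rng.normal(25, 2, size=(30, 1)) + rng.normal(0, 0.4, size=(30, 6))
    m[:3, :3] += 5
    t = table_from_matrix(m)
    rows = moderated_ttest(t)
    csv = tmp_path / "m.csv"
    pd.DataFrame(m, index=t.proteins["protein_id"], columns=SAMPLES).to_csv(csv)
    script = tmp_path / "limma.R"
    script.write_text(
        f"""suppressMessages(library(limma))
m <- as.matrix(read.csv("{csv}", row.names=1))
design <- cbind(Intercept=1, bait=c(1,1,1,0,0,0))
fit <- eBayes(lmFit(m, design))
write.csv(data.frame(t=fit$t[,2], p=fit$p.value[,2],
                     d0=fit$df.prior, s02=fit$s2.prior),
          "{tmp_path / 'limma.csv'}")
"""
    )
    subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
    lim = pd.read_csv(tmp_path / "limma.csv", index_col=0)
    assert rows["prior_d0"].iloc[0] == pytest.approx(lim["d0"].iloc[0], rel=1e-9)
    assert rows["prior_s0_2"].iloc[0] == pytest.approx(lim["s02"].iloc[0], rel=1e-9)
    np.testing.assert_allclose(rows["t_mod"], lim["t"], rtol=1e-9)
    np.testing.assert_allclose(rows["p"], lim["p"], rtol=1e-9)


def test_moderated_t_refuses_incomplete_or_linear_table():
    m = np.full((3, 6), 15.0)
    m[0, 0] = np.nan
    with pytest.raises(ValueError, match="missing"):
        moderated_ttest(table_from_matrix(m))
    with pytest.raises(ValueError, match="log2"):
        moderated_ttest(table_from_matrix(np.full((3, 6), 100.0), log2=False))


# ---------------------------------------------------------------------- BH


def test_bh_examples():
    assert bh_adjust([0.04])[0] == pytest.approx(0.04)
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), 0.04)
    np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


@given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=10))
@settings(max_examples=100, deadline=None)
def test_bh_matches_step_up_oracle(p):
    adj = bh_adjust(p)
    np.testing.assert_allclose(adj, brute_bh(p), atol=1e-12)
    assert (adj >= np.asarray(p) - 1e-12).all()
    order = np.argsort(p)
    assert (np.diff(adj[order]) >= -1e-12).all()


# ----------------------------------------------------------------- gating


def test_methods_gate_boundaries():
    rows = pd.DataFrame(
        {
            "protein_id": ["a", "b", "c"],
            "log2_fc": [7.5, 7.5, 0.0],
            "t_mod": [10, 10, 0],
            "p": [1e-6, 1e-3, 0.9],
            "adj_p": [0.005, 0.02, 0.95],
        }
    )
    res = classify_interactors(rows)
    assert res.rows["significant"].tolist() == [True, False, False]
    assert res.gate == "methods"


def test_figure_gate_uses_raw_p():
    rows = pd.DataFrame(
        {
            "protein_id": ["a", "b"],
            "log2_fc": [3.5, 3.5],
            "t_mod": [8, 5],
            "p": [5e-5, 5e-4],
            "adj_p": [0.02, 0.05],
        }
    )
    res = classify_interactors(rows, gate="figure")
    assert res.rows["significant"].tolist() == [True, False]
    assert res.params["neg_log10_p"] == 4.0


def test_recovery_score_conventions():
    truth = SimTruth(planted_interactors=pd.DataFrame({"protein_id": ["a", "b"], "log2_fc": [8, 8]}))
    rows = pd.DataFrame({"protein_id": ["a", "b", "c"], "significant": [True, True, False]})
    from chipms.proteomics import EnrichmentResult

    perfect = EnrichmentResult(rows=rows, gate="methods", params={})
    assert recovery_score(perfect, truth) == (1.0, 1.0)
    none_called = EnrichmentResult(
        rows=rows.assign(significant=False), gate="methods", params={}
    )
    precision, recall = recovery_score(none_called, truth)
    assert np.isnan(precision) and recall == 0.0


# ------------------------------------------------------------- simulation


def test_null_simulation_has_matched_conditions():
    cfg = ProteomicsSimConfig(n_proteins=400, missing_enabled=False, seed=5)
    table, truth = simulate_interactome_table(cfg)
    assert truth.planted_interactors.empty
    log2 = np.log2(table.intensities)
    bait = log2[table.samples("bait")].to_numpy().ravel()
    ctrl = log2[table.samples("ctrl")].to_numpy().ravel()
    assert abs(bait.mean() - ctrl.mean()) < 0.2
    assert abs(bait.std() - ctrl.std()) < 0.2


def test_planted_fold_change_recovered_without_missingness():
    diffs = []
    for seed in range(10):
        cfg = ProteomicsSimConfig(
            n_proteins=50,
            interactors=[("P0010", 8.0)],
            missing_enabled=False,
            seed=seed,
        )
        table, _ = simulate_interactome_table(cfg)
        log2 = np.log2(table.intensities.loc["P0010"])
        diffs.append(log2[:3].mean() - log2[3:].mean())
    assert np.mean(diffs) == pytest.approx(8.0, abs=0.2)


def test_simulated_table_roundtrip_and_determinism(tmp_path):
    cfg = ProteomicsSimConfig(n_proteins=100, interactors=default_interactors(3), seed=9)
    t1, _ = simulate_interactome_table(cfg)
    t2, _ = simulate_interactome_table(cfg)
    pd.testing.assert_frame_equal(t1.intensities, t2.intensities)
    write_intensity_table(t1, tmp_path / "a.tsv")
    write_intensity_table(t2, tmp_path / "b.tsv")
    assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()
    back = read_intensity_table(tmp_path / "a.tsv")
    assert back.intensities.isna().equals(t1.intensities.isna())  # zeros -> missing


def test_strong_interactor_controls_mostly_missing_when_base_low():
    cfg = ProteomicsSimConfig(
        n_proteins=300,
        interactors=[(f"P{i:04d}", 8.0) for i in range(1, 31)],
        base_mean=18.0,  # low-abundance regime: controls below the dropout zone
        seed=3,
    )
    table, _ = simulate_interactome_table(cfg)
    ctrl = table.intensities[table.samples("ctrl")].loc[[f"P{i:04d}" for i in range(1, 31)]]
    assert ctrl.isna().to_numpy().mean() > 0.8


# ------------------------------------------------------------ full pipeline


def test_pipeline_stage_order_is_recorded():
    table, _ = simulate_interactome_table(
        ProteomicsSimConfig(n_proteins=200, interactors=default_interactors(3), seed=0)
    )
    filtered, _ = filter_proteins(table)
    centered = log2_median_center(filtered)
    imputed, _ = impute_low_percentile(centered)
    steps = [h.split("(")[0] for h in imputed.history]
    assert steps == ["filter", "log2_median_center", "impute_low_percentile"]
    with pytest.raises(ValueError, match="already log2"):
        log2_median_center(centered)


def test_pipeline_recovers_planted_interactors_single_seed():
    table, truth = simulate_interactome_table(
        ProteomicsSimConfig(interactors=default_interactors(9, 8.0), seed=0)
    )
    result = run_enrichment(table)
    precision, recall = recovery_score(result, truth)
    assert recall == 1.0 and precision == 1.0
    assert (result.rows["adj_p"] >= result.rows["p"] - 1e-12).all()
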