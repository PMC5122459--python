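"""Burden-association pipelines: enumeration oracles, planted recovery,
confounder controls, and invariances."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from conim.detection import (CNABurdenAssociation, Thresholds,
                             length_association, mutation_class_contrast,
                             pan_cancer_test, regression_control,
                             silent_control, type_specific_pipeline)
from conim.preprocess import compute_burden, prepare_burdens
from conim.simulate import SimConfig, generate_cohort
from conftest import make_toy_cohort

SMALL_TH = Thresholds(min_gene_mutations=1, min_type_samples=1, min_mut_samples=1)


def cohort_with_counts(counts_mut, counts_non, gene="GX", mut_class="missense"):
    """One cancer type; carriers of `gene` get counts_mut CNAs, rest counts_non."""
    specs, muts, segs = [], [], []
    for i, c in enumerate(list(counts_mut) + list(counts_non)):
        s = f"s{i}"
        specs.append((s, "t1", 100.0, 1, 2.0))
        if i < len(counts_mut):
            muts.append((s, gene, mut_class, 1, 30, 20))
        for j in range(c):
            segs.append((s, "chr1", j * 1000, j * 1000 + 500, 0.5))
    return make_toy_cohort(specs, muts, segs)


def test_point_mass_groups_not_significant():
    cohort = cohort_with_counts([5, 5, 5], [5, 5, 5, 5])
    res = pan_cancer_test(cohort, compute_burden(cohort), thresholds=SMALL_TH)
    assert res.loc[0, "p"] == pytest.approx(1.0)


def test_pan_cancer_p_equals_exhaustive_enumeration():
    """Separated 3-vs-7 toy: pipeline p must equal the exact rank-test p."""
    from test_stats import brute_force_mww_p
    counts_mut, counts_non = [1, 1, 2], [9, 10, 11, 12, 9, 10, 11]
    cohort = cohort_with_counts(counts_mut, counts_non)
    res = pan_cancer_test(cohort, compute_burden(cohort), thresholds=SMALL_TH)
    expected = brute_force_mww_p(counts_mut, counts_non)
    assert res.loc[0, "p"] == pytest.approx(expected, abs=1e-12)
    assert res.loc[0, "direction"] == "fewer"
    assert res.loc[0, "effect"] == pytest.approx(
        np.log2((np.mean(counts_mut) + 1) / (np.mean(counts_non) + 1)))


def test_planted_modifiers_recovered(small_cohort, small_burdens, small_config):
    model = CNABurdenAssociation(small_cohort, small_burdens,
                                 Thresholds(min_type_samples=100))
    res = model.fit()
    assert set(small_config.modifier_genes) <= set(res.significant_genes)
    false_pos = set(res.significant_genes) - set(small_config.modifier_genes)
    assert len(false_pos) <= 2  # FDR-controlled residue on 98 null genes


def test_no_gene_passes_filters_warns(toy_cohort):
    with pytest.warns(UserWarning, match="no gene passed"):
        res = pan_cancer_test(toy_cohort, compute_burden(toy_cohort))
    assert res.empty


def test_silent_control_identical_groups_removed():
    """Gene whose silent and non-silent carriers coincide is removed iff the
    non-silent association was significant."""
    specs, muts, segs = [], [], []
    rng = np.random.default_rng(0)
    for i in range(60):
        s = f"s{i}"
        specs.append((s, "t1", 100.0, 1, 2.0))
        carrier = i < 15
        if carrier:  # both a silent and a non-silent mutation, same samples
            muts.append((s, "GX", "missense", 1, 30, 20))
            muts.append((s, "GX", "silent", 2, 30, 20))
        n = 3 if carrier else 40 + int(rng.integers(5))
        for j in range(n):
            segs.append((s, "chr1", j * 1000, j * 1000 + 500, 0.5))
    cohort = make_toy_cohort(specs, muts, segs)
    burdens = compute_burden(cohort)
    cand = pan_cancer_test(cohort, burdens, thresholds=SMALL_TH)
    assert cand.loc[0, "q"] < 0.01
    out = silent_control(cohort, burdens, cand, thresholds=SMALL_TH)
    assert not out.loc[0, "silent_control_pass"]


def test_silent_control_vacuous_without_silent_mutations():
    cohort = cohort_with_counts([1, 1, 1, 1, 1], [30, 31, 32, 33, 34, 35])
    burdens = compute_burden(cohort)
    cand = pan_cancer_test(cohort, burdens, thresholds=SMALL_TH)
    out = silent_control(cohort, burdens, cand, thresholds=SMALL_TH)
    assert out["silent_control_pass"].all()


def test_silent_control_removes_burden_correlated_confounder():
    """TTN-like gene: mutation probability tracks total mutation burden (and
    is thus correlated with CNA-rich samples) with no planted effect; its
    silent mutations show the same association, so the control removes it."""
    rng = np.random.default_rng(1)
    specs, muts, segs = [], [], []
    for i in range(300):
        s = f"s{i}"
        specs.append((s, "t1", 100.0, 1, 2.0))
        high_burden = i % 2 == 0
        n_cna = int(rng.poisson(30 if high_burden else 5))
        # mutation probability tracks burden (confounded placement), for both
        # silent and non-silent mutations alike
        p_mut = 0.7 if high_burden else 0.05
        if rng.random() < p_mut:
            muts.append((s, "TTNLIKE", "missense", 1, 30, 20))
        if rng.random() < p_mut:
            muts.append((s, "TTNLIKE", "silent", 2, 30, 20))
        for j in range(n_cna):
            segs.append((s, "chr1", j * 1000, j * 1000 + 500, 0.5))
    cohort = make_toy_cohort(specs, muts, segs)
    burdens = compute_burden(cohort)
    cand = pan_cancer_test(cohort, burdens, thresholds=SMALL_TH)
    assert cand.loc[0, "q"] < 0.01  # confounder looks significant ...
    out = silent_control(cohort, burdens, cand, thresholds=SMALL_TH)
    assert not out.loc[0, "silent_control_pass"]  # ... and is removed


def test_regression_ols_matches_hand_computation():
    """6-point design with orthogonal status/mutation-number: the status
    coefficient and its t-test p must match the closed-form OLS solution."""
    specs, muts, segs = [], [], []
    status = [1, 1, 1, 0, 0, 0]
    n_mut = [2, 4, 6, 2, 4, 6]
    n_cna = [3, 5, 5, 9, 10, 12]  # not exactly linear in the predictors
    for i in range(6):
        s = f"s{i}"
        specs.append((s, "t1", 1.0, 1, 2.0))
        for _ in range(n_mut[i] - status[i]):
            muts.append((s, "FILLER", "missense", 1, 10, 10))
        if status[i]:
            muts.append((s, "GX", "missense", 1, 10, 10))
        for j in range(n_cna[i]):
            segs.append((s, "chr1", j * 1000, j * 1000 + 500, 0.5))
    cohort = make_toy_cohort(specs, muts, segs)
    burdens = compute_burden(cohort)
    out = regression_control(cohort, burdens, ["GX"],
                             Thresholds(min_mut_samples=1))
    # hand OLS: X = [1, status, n_mut]
    X = np.column_stack([np.ones(6), status, n_mut])
    y = np.asarray(n_cna, float)
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    s2 = resid @ resid / (6 - 3)
    se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
    t = beta[1] / se
    from scipy.stats import t as tdist
    p_hand = 2 * tdist.sf(abs(t), df=3)
    row = out.iloc[0]
    assert row["coef"] == pytest.approx(beta[1], rel=1e-9)
    assert row["t"] == pytest.approx(t, rel=1e-9)
    assert row["p"] == pytest.approx(p_hand, rel=1e-9)


def test_regression_control_keeps_genuine_modifier(small_cohort, small_burdens,
                                                   small_config):
    out = regression_control(small_cohort, small_burdens,
                             small_config.modifier_genes)
    kept = set(out.loc[out["keep"], "gene"])
    assert set(small_config.modifier_genes) <= kept


def test_type_specific_detects_single_type_modifier():
    """Modifier planted in one type only: found per-type, diluted pan-cancer."""
    rng = np.random.default_rng(2)
    specs, muts, segs = [], [], []
    i = 0
    for ct, has_effect in (("t1", True), ("t2", False), ("t3", False)):
        for _ in range(120):
            s = f"s{i}"; i += 1
            specs.append((s, ct, 100.0, 1, 2.0))
            carrier = rng.random() < 0.12
            if carrier:
                muts.append((s, "GX", "missense", 1, 30, 20))
            for k in range(int(rng.poisson(10))):  # background mutation load
                muts.append((s, f"BG{k}", "missense", 1, 30, 20))
            mean = 4 if (carrier and has_effect) else 20
            for j in range(int(rng.poisson(mean))):
                segs.append((s, "chr1", j * 1000, j * 1000 + 500, 0.5))
    cohort = make_toy_cohort(specs, muts, segs)
    burdens = prepare_burdens(cohort)
    th = dataclasses.replace(SMALL_TH, effect_cut=None)
    ts = type_specific_pipeline(cohort, burdens,
                                dataclasses.replace(th, min_mut_samples=5))
    sig = ts[ts["significant"]]
    assert ("GX", "t1") in set(zip(sig["gene"], sig["cancer_type"]))
    pan = pan_cancer_test(cohort, burdens, thresholds=dataclasses.replace(
        th, min_type_samples=100, min_mut_samples=5))
    q_pan = pan.loc[pan["gene"] == "GX", "q"].iloc[0]
    q_type = ts.loc[(ts["gene"] == "GX") & (ts["cancer_type"] == "t1"), "q"].iloc[0]
    assert q_pan > q_type


def test_type_specific_null_empty(small_config):
    cfg = dataclasses.replace(small_config, modifier_effect=1.0, seed=42)
    cohort = generate_cohort(cfg)
    burdens = prepare_burdens(cohort)
    ts = type_specific_pipeline(cohort, burdens)
    assert not ts["significant"].any()


def test_length_association_planted_length_effect():
    """Gene shifting CNA length (not number) appears only in the length set."""
    rng = np.random.default_rng(3)
    specs, muts, segs = [], [], []
    for i in range(240):
        s = f"s{i}"
        specs.append((s, "t1", 100.0, 1, 2.0))
        carrier = i < 60
        if carrier:
            muts.append((s, "LENGENE", "missense", 1, 30, 20))
        scale = 50_000 if carrier else 5_000
        for j in range(8):
            length = 200 + int(rng.exponential(scale))
            segs.append((s, "chr1", j * 60_000, j * 60_000 + length, 0.5))
    cohort = make_toy_cohort(specs, muts, segs)
    burdens = compute_burden(cohort)
    out = length_association(cohort, burdens, thresholds=dataclasses.replace(
        SMALL_TH, min_mut_samples=5))
    assert "LENGENE" in out["length_genes"]
    assert "LENGENE" not in out["number_genes"]


def test_length_overlap_chi2_matches_hand():
    from conim.stats import chi2_2x2
    a, b, c, d = 12, 30, 8, 400
    stat, p = chi2_2x2([[a, b], [c, d]])
    table = np.array([[a, b], [c, d]], float)
    rows = table.sum(1, keepdims=True); cols = table.sum(0, keepdims=True)
    E = rows * cols / table.sum()
    assert stat == pytest.approx(float(((table - E) ** 2 / E).sum()))


def test_mutation_class_contrast_planted_shift():
    rng = np.random.default_rng(4)
    specs, muts, segs = [], [], []
    for i in range(60):
        s = f"s{i}"
        specs.append((s, "t1", 100.0, 1, 2.0))
        in_domain = i < 30
        muts.append((s, "NIPBLLIKE", "missense", 50 if in_domain else 900, 30, 20))
        mean = 4 if in_domain else 14
        for j in range(int(rng.poisson(mean))):
            segs.append((s, "chr1", j * 1000, j * 1000 + 500, 0.5))
    cohort = make_toy_cohort(specs, muts, segs)
    burdens = compute_burden(cohort)
    assign = lambda row: "A" if row.protein_pos <= 100 else "B"
    res = mutation_class_contrast(cohort, burdens, "NIPBLLIKE", assign)
    assert res["p"] < 0.01
    assert res["mean_a"] < res["mean_b"]


def test_mutation_class_contrast_tie_goes_to_a(toy_cohort):
    burdens = compute_burden(toy_cohort)
    # sample 'a' has mutations in both classes -> must count as A only
    assign = {10: "A", 11: "B", 5: "B"}
    fn = lambda row: assign[row.protein_pos]
    with pytest.raises(ValueError, match="at least 2"):
        mutation_class_contrast(toy_cohort, burdens, "G1", fn)


def test_pipeline_invariant_under_sample_reordering(small_cohort, small_burdens):
    from conim.cohort import Cohort
    rng = np.random.default_rng(5)
    perm = rng.permutation(len(small_cohort.samples))
    shuffled = Cohort(
        samples=small_cohort.samples.iloc[perm].reset_index(drop=True),
        mutations=small_cohort.mutations.sample(frac=1, random_state=1).reset_index(drop=True),
        cna_segments=small_cohort.cna_segments.sample(frac=1, random_state=2).reset_index(drop=True),
        genome=small_cohort.genome)
    th = Thresholds(min_type_samples=100)
    a = pan_cancer_test(small_cohort, small_burdens, thresholds=th)
    b = pan_cancer_test(shuffled, prepare_burdens(shuffled), thresholds=th)
    merged = a.merge(b, on="gene", suffixes=("_a", "_b"))
    assert len(merged) == len(a)
    assert np.allclose(merged["p_a"], merged["p_b"])
    assert np.allclose(merged["effect_a"], merged["effect_b"])
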