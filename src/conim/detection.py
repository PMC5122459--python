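"""Detection of copy-number-instability modulator (CONIM) genes.

A CONIM gene is one whose non-silent mutation status is associated with a
significantly different per-sample CNA burden.  Three pipelines are provided:

``pan_cancer``
    Pooled Mann-Whitney-Wilcoxon test across cancer types (each type must have
    >= 200 samples and >= 5 mutated samples for the gene), genes restricted to
    >= 60 non-silent mutations overall; candidates must reach q < 0.01 (BH)
    with |log2 effect| > 0.5 and survive a silent-mutation control and a
    per-type multiple-regression control.
``type_specific``
    Hypermutator-excluded per-cancer-type tests with a per-type silent control.
``permutation``
    Margin-preserving permutation null (see :mod:`conim.permutation`).

The entry point is :class:`CNABurdenAssociation` whose :meth:`fit` returns a
:class:`CONIMResults` carrying the per-gene association table and the
significant gene set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import Cohort
from .stats import bh_fdr, chi2_2x2, mww_test

__all__ = [
    "Thresholds",
    "CNABurdenAssociation",
    "CONIMResults",
    "pan_cancer_test",
    "silent_control",
    "regression_control",
    "type_specific_pipeline",
    "length_association",
    "mutation_class_contrast",
]

ASSOC_COLS = ["gene", "metric", "n_mut_samples", "n_nonmut_samples",
              "effect", "p", "q", "direction", "pipeline", "silent_control_pass"]


@dataclass(frozen=True)
class Thresholds:
    """Detection thresholds; defaults are the published values."""

    min_gene_mutations: int = 60     # non-silent mutations per gene, pooled
    min_type_samples: int = 200      # samples per cancer type (pan-cancer pooling)
    min_mut_samples: int = 5         # mutated samples per included cancer type
    effect_cut: float | None = 0.5   # |log2 ratio| cutoff (None = no cutoff)
    q_cut: float = 0.01
    regression_q_cut: float = 0.1
    pseudocount: float = 1.0         # guards zero-CNA group means in the log ratio


def _log2_effect(mean_mut: float, mean_non: float, pseudocount: float) -> float:
    return float(np.log2((mean_mut + pseudocount) / (mean_non + pseudocount)))


def _metric_series(burdens: pd.DataFrame, metric: str) -> pd.Series:
    if metric == "cna_number":
        s = burdens.set_index("sample")["n_cna"].astype(float)
    elif metric == "cna_length":
        b = burdens[burdens["n_cna"] > 0]
        s = b.set_index("sample")["mean_cna_length"].astype(float)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return s


def _carrier_map(cohort: Cohort, silent: bool) -> dict[str, set[str]]:
    mut = cohort.silent_mutations() if silent else cohort.nonsilent_mutations()
    return {g: set(grp["sample"]) for g, grp in mut.groupby("gene")}


def _gene_universe(cohort: Cohort, min_gene_mutations: int) -> list[str]:
    counts = cohort.nonsilent_mutations().groupby("gene").size()
    return sorted(counts[counts >= min_gene_mutations].index)


def _run_gene_tests(genes, carriers, values: pd.Series, sample_type: pd.Series,
                    included_types_for, metric: str, pipeline: str,
                    thresholds: Thresholds) -> pd.DataFrame:
    """Shared MWW loop: for each gene, pool samples of its included types and
    compare carriers vs non-carriers on ``values``."""
    rows = []
    samples_by_type = {ct: set(idx) for ct, idx in
                       sample_type.groupby(sample_type).groups.items()}
    value_index = set(values.index)
    for gene in genes:
        cset = carriers.get(gene, set())
        inc = included_types_for(gene, cset)
        if not inc:
            continue
        pool = set().union(*(samples_by_type[ct] for ct in inc)) & value_index
        mut = sorted(pool & cset)
        non = sorted(pool - cset)
        if len(mut) == 0 or len(non) == 0:
            continue
        x = values.loc[mut].to_numpy()
        y = values.loc[non].to_numpy()
        res = mww_test(x, y)
        eff = _log2_effect(float(x.mean()), float(y.mean()), thresholds.pseudocount)
        rows.append([gene, metric, len(mut), len(non), eff, res.p, np.nan,
                     "fewer" if x.mean() < y.mean() else "more", pipeline, True])
    df = pd.DataFrame(rows, columns=ASSOC_COLS)
    if len(df):
        df["q"] = bh_fdr(df["p"])
    return df


def _significant(df: pd.DataFrame, thresholds: Thresholds) -> pd.Series:
    sig = df["q"] < thresholds.q_cut
    if thresholds.effect_cut is not None:
        sig &= df["effect"].abs() > thresholds.effect_cut
    return sig


# ---------------------------------------------------------------------------
# pan-cancer pipeline
# ---------------------------------------------------------------------------

def pan_cancer_test(cohort: Cohort, burdens: pd.DataFrame,
                    metric: str = "cna_number",
                    thresholds: Thresholds = Thresholds(),
                    silent: bool = False,
                    genes: list[str] | None = None) -> pd.DataFrame:
    """Pooled MWW burden-association test; returns the full per-gene table.

    With ``silent=True`` the groups are defined by silent mutations (the
    control contrast); the gene universe still requires >= 60 non-silent
    mutations unless ``genes`` is given explicitly.
    """
    values = _metric_series(burdens, metric)
    sample_type = burdens.set_index("sample")["cancer_type"]
    type_sizes = sample_type.value_counts()
    big_types = set(type_sizes[type_sizes >= thresholds.min_type_samples].index)
    carriers = _carrier_map(cohort, silent=silent)
    if genes is None:
        genes = _gene_universe(cohort, thresholds.min_gene_mutations)
    samples_by_type = {ct: set(grp.index) for ct, grp in
                       sample_type.groupby(sample_type)}

    def included(gene, cset):
        return [ct for ct in big_types
                if len(samples_by_type[ct] & cset) >= thresholds.min_mut_samples]

    df = _run_gene_tests(genes, carriers, values, sample_type, included,
                         metric, "pan_cancer", thresholds)
    if df.empty:
        warnings.warn("no gene passed the pan-cancer filters")
    return df


def silent_control(cohort: Cohort, burdens: pd.DataFrame,
                   candidates: pd.DataFrame,
                   thresholds: Thresholds = Thresholds(),
                   metric: str = "cna_number") -> pd.DataFrame:
    """Drop candidates that are also significant when groups are defined by
    silent mutations; sets ``silent_control_pass`` on the candidate table."""
    if candidates.empty:
        return candidates
    genes = list(candidates["gene"])
    sil = pan_cancer_test(cohort, burdens, metric=metric, thresholds=thresholds,
                          silent=True, genes=genes)
    failing = set()
    if len(sil):
        bad = sil[_significant(sil, thresholds)]
        failing = set(bad["gene"])
    out = candidates.copy()
    out["silent_control_pass"] = ~out["gene"].isin(failing)
    return out


def regression_control(cohort: Cohort, burdens: pd.DataFrame,
                       candidates, thresholds: Thresholds = Thresholds(),
                       min_mut_samples: int | None = None) -> pd.DataFrame:
    """Per-cancer-type OLS of CNA number on mutation status + mutation count.

    For every candidate gene and cancer type with enough mutated and
    non-mutated samples, fit ``n_cna ~ status + n_mutations`` and t-test the
    status coefficient; BH-correct across all fits and keep genes with at
    least one cancer type at q < ``regression_q_cut``.
    Returns the per-(gene, type) fit table with a ``keep`` column.
    """
    genes = list(candidates["gene"]) if isinstance(candidates, pd.DataFrame) else list(candidates)
    if min_mut_samples is None:
        min_mut_samples = thresholds.min_mut_samples
    carriers = _carrier_map(cohort, silent=False)
    b = burdens.set_index("sample")
    n_mut_per_sample = cohort.mutation_counts()
    rows = []
    for gene in genes:
        cset = carriers.get(gene, set())
        for ct, grp in b.groupby("cancer_type"):
            status = grp.index.isin(cset).astype(float)
            n_mut = int(status.sum())
            if n_mut < min_mut_samples or n_mut > len(grp) - 2 or len(grp) < 4:
                continue  # singular or underdetermined design
            X = sm.add_constant(np.column_stack([
                status, n_mut_per_sample.loc[grp.index].to_numpy(float)]))
            model = sm.OLS(grp["n_cna"].to_numpy(float), X)
            fit = model.fit()
            rows.append([gene, ct, float(fit.params[1]), float(fit.tvalues[1]),
                         float(fit.pvalues[1])])
    out = pd.DataFrame(rows, columns=["gene", "cancer_type", "coef", "t", "p"])
    if len(out):
        out["q"] = bh_fdr(out["p"])
        out["keep"] = out["q"] < thresholds.regression_q_cut
    else:
        out["q"] = []
        out["keep"] = []
    return out


# ---------------------------------------------------------------------------
# cancer-type-specific pipeline
# ---------------------------------------------------------------------------

def type_specific_pipeline(cohort: Cohort, burdens: pd.DataFrame,
                           thresholds: Thresholds | None = None,
                           metric: str = "cna_number") -> pd.DataFrame:
    """Per-cancer-type MWW after hypermutator removal, with a per-type silent
    control; returns one row per (gene, cancer type) test.

    Inference is at the gene level: each gene's p-value is the Bonferroni
    bound over its per-type tests and the BH family is the set of tested
    genes, so the reported discoveries are genes (the per-type rows carry the
    gene-level ``q`` and the driving type is flagged ``significant``).
    """
    if thresholds is None:
        # no pooled-sample-size or effect cut in the per-type run
        thresholds = Thresholds(min_type_samples=0, effect_cut=None)
    kept = burdens[~burdens["hypermutator_flag"]]
    values = _metric_series(kept, metric)
    carriers = _carrier_map(cohort, silent=False)
    silent_carriers = _carrier_map(cohort, silent=True)
    genes = _gene_universe(cohort, thresholds.min_gene_mutations)
    value_index = set(values.index)

    rows = []
    for ct, grp in kept.groupby("cancer_type"):
        type_samples = set(grp["sample"]) & value_index
        if not type_samples:
            warnings.warn(f"cancer type {ct!r} has no usable samples after exclusions")
            continue
        for gene in genes:
            mut = sorted(type_samples & carriers.get(gene, set()))
            non = sorted(type_samples - carriers.get(gene, set()))
            if len(mut) < thresholds.min_mut_samples or len(non) == 0:
                continue
            x = values.loc[mut].to_numpy()
            y = values.loc[non].to_numpy()
            res = mww_test(x, y)
            eff = _log2_effect(float(x.mean()), float(y.mean()), thresholds.pseudocount)
            rows.append([gene, ct, len(mut), len(non), eff, res.p,
                         "fewer" if x.mean() < y.mean() else "more"])
    df = pd.DataFrame(rows, columns=["gene", "cancer_type", "n_mut_samples",
                                     "n_nonmut_samples", "effect", "p", "direction"])
    if df.empty:
        return df.assign(q=[], significant=[], silent_control_pass=[])

    # gene-level inference: Bonferroni over each gene's tested types, BH
    # across genes
    per_gene = df.groupby("gene")["p"].agg(["min", "count"])
    p_gene = np.minimum(1.0, per_gene["min"] * per_gene["count"])
    q_gene = pd.Series(bh_fdr(p_gene), index=per_gene.index)
    df["q"] = df["gene"].map(q_gene)
    best_type = df.loc[df.groupby("gene")["p"].idxmin()].set_index("gene")
    sig_genes = set(q_gene.index[q_gene < thresholds.q_cut])
    if thresholds.effect_cut is not None:
        sig_genes = {g for g in sig_genes
                     if abs(best_type.loc[g, "effect"]) > thresholds.effect_cut}

    # silent control per significant gene, in its driving cancer type
    sil = []
    for gene in sorted(sig_genes):
        ct = best_type.loc[gene, "cancer_type"]
        type_samples = set(kept.loc[kept["cancer_type"] == ct, "sample"]) & value_index
        scar = silent_carriers.get(gene, set())
        mut = sorted(type_samples & scar)
        non = sorted(type_samples - scar)
        if len(mut) < 2 or len(non) < 2:
            sil.append((gene, 1.0))
        else:
            sil.append((gene, mww_test(values.loc[mut].to_numpy(),
                                       values.loc[non].to_numpy()).p))
    failing = set()
    if sil:
        genes_s, pvals = zip(*sil)
        for gene, q in zip(genes_s, bh_fdr(np.asarray(pvals))):
            if q < thresholds.q_cut:
                failing.add(gene)
    sig_genes -= failing
    df["silent_control_pass"] = ~df["gene"].isin(failing)
    driving = set(zip(best_type.index, best_type["cancer_type"]))
    df["significant"] = [
        (g in sig_genes) and ((g, ct) in driving)
        for g, ct in zip(df["gene"], df["cancer_type"])]
    return df


# ---------------------------------------------------------------------------
# CNA-length association and set overlap
# ---------------------------------------------------------------------------

def length_association(cohort: Cohort, burdens: pd.DataFrame,
                       thresholds: Thresholds = Thresholds()) -> dict:
    """MWW on per-sample mean CNA length (no effect-size or silent filters),
    plus the chi-square overlap with the unfiltered CNA-number-associated set.
    """
    plain = replace(thresholds, effect_cut=None, min_type_samples=0)
    length_df = pan_cancer_test(cohort, burdens, metric="cna_length", thresholds=plain)
    number_df = pan_cancer_test(cohort, burdens, metric="cna_number", thresholds=plain)
    length_set = set(length_df.loc[length_df["q"] < plain.q_cut, "gene"])
    number_set = set(number_df.loc[number_df["q"] < plain.q_cut, "gene"])
    universe = sorted(set(length_df["gene"]) | set(number_df["gene"]))
    overlap = None
    if number_set and length_set:
        a = len(length_set & number_set)
        b = len(length_set - number_set)
        c = len(number_set - length_set)
        d = len(universe) - a - b - c
        stat, p = chi2_2x2([[a, b], [c, d]])
        overlap = {"table": [[a, b], [c, d]], "chi2": stat, "p": p}
    else:
        warnings.warn("empty association set; overlap test skipped")
    return {"length": length_df, "number": number_df,
            "length_genes": length_set, "number_genes": number_set,
            "overlap": overlap}


# ---------------------------------------------------------------------------
# gene-region mutation-class contrast
# ---------------------------------------------------------------------------

def mutation_class_contrast(cohort: Cohort, burdens: pd.DataFrame, gene: str,
                            class_assignment) -> dict:
    """Compare CNA numbers of samples carrying class-A vs class-B mutations of
    one gene (e.g. domain missense vs N-terminal truncating).

    ``class_assignment(mutation_row) -> "A" | "B" | None`` is applied to each
    mutation record of the gene; a sample carrying both classes is assigned to
    class A (the anticipated stronger-impact class).
    """
    mut = cohort.mutations[cohort.mutations["gene"] == gene]
    a_samples, b_samples = set(), set()
    for row in mut.itertuples(index=False):
        cls = class_assignment(row)
        if cls == "A":
            a_samples.add(row.sample)
        elif cls == "B":
            b_samples.add(row.sample)
    b_samples -= a_samples  # both-class ties go to A
    values = _metric_series(burdens, "cna_number")
    a = values.reindex(sorted(a_samples)).dropna().to_numpy()
    b = values.reindex(sorted(b_samples)).dropna().to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each mutation class needs at least 2 samples")
    res = mww_test(a, b)
    return {"gene": gene, "n_a": len(a), "n_b": len(b),
            "mean_a": float(a.mean()), "mean_b": float(b.mean()),
            "u": res.u, "p": res.p}


# ---------------------------------------------------------------------------
# model / results facade
# ---------------------------------------------------------------------------

@dataclass
class CONIMResults:
    """Fitted burden-association results for one pipeline run."""

    pipeline: str
    metric: str
    thresholds: Thresholds
    table: pd.DataFrame
    significant_genes: list[str]
    regression: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            "CNA burden association" ,
            f"  pipeline: {self.pipeline}   metric: {self.metric}",
            f"  genes tested: {self.table['gene'].nunique() if len(self.table) else 0}",
            f"  significant (q < {self.thresholds.q_cut}"
            + (f", |log2 effect| > {self.thresholds.effect_cut}" if self.thresholds.effect_cut else "")
            + f"): {len(self.significant_genes)}",
        ]
        if self.significant_genes:
            show = self.table[self.table["gene"].isin(self.significant_genes)]
            if "direction" in show:
                fewer = (show.drop_duplicates("gene")["direction"] == "fewer").sum()
                lines.append(f"  direction: {fewer} fewer / "
                             f"{len(self.significant_genes) - fewer} more CNAs when mutated")
            lines.append("  genes: " + ", ".join(sorted(self.significant_genes)[:20])
                         + (" ..." if len(self.significant_genes) > 20 else ""))
        return "\n".join(lines)


class CNABurdenAssociation:
    """Model object binding a cohort + burden table to the detection pipelines.

    Examples
    --------
    >>> model = CNABurdenAssociation(cohort, burdens)
    >>> res = model.fit(pipeline="pan_cancer")
    >>> print(res.summary())
    """

    def __init__(self, cohort: Cohort, burdens: pd.DataFrame | None = None,
                 thresholds: Thresholds = Thresholds()):
        from .preprocess import prepare_burdens
        self.cohort = cohort
        self.burdens = prepare_burdens(cohort) if burdens is None else burdens
        self.thresholds = thresholds

    def fit(self, pipeline: str = "pan_cancer", metric: str = "cna_number",
            apply_silent_control: bool = True,
            apply_regression_control: bool = True,
            n_perm: int = 1000, seed: int = 0) -> CONIMResults:
        th = self.thresholds
        if pipeline == "pan_cancer":
            table = pan_cancer_test(self.cohort, self.burdens, metric, th)
            reg = None
            if len(table):
                cand = table[_significant(table, th)]
                if apply_silent_control and len(cand):
                    cand = silent_control(self.cohort, self.burdens, cand, th, metric)
                    failing = set(cand.loc[~cand["silent_control_pass"], "gene"])
                    cand = cand[cand["silent_control_pass"]]
                    table["silent_control_pass"] = ~table["gene"].isin(failing)
                if apply_regression_control and len(cand):
                    # BH family = every gene tested in this run, so that the
                    # handful of extreme candidates cannot drag marginal fits
                    # below the q cutoff by rank alone
                    reg = regression_control(self.cohort, self.burdens,
                                             list(table["gene"]), th)
                    keep = set(reg.loc[reg["keep"], "gene"]) if len(reg) else set()
                    cand = cand[cand["gene"].isin(keep)]
                sig = sorted(cand["gene"])
            else:
                sig = []
            return CONIMResults("pan_cancer", metric, th, table, sig, regression=reg)
        if pipeline == "type_specific":
            table = type_specific_pipeline(self.cohort, self.burdens)
            sig = sorted(table.loc[table.get("significant", pd.Series(dtype=bool)).fillna(False), "gene"].unique()) if len(table) else []
            return CONIMResults("type_specific", metric,
                                Thresholds(min_type_samples=0, effect_cut=None),
                                table, sig)
        if pipeline == "permutation":
            from .permutation import permutation_gene_test
            table = permutation_gene_test(self.cohort, self.burdens,
                                          n_perm=n_perm, seed=seed, thresholds=th)
            sig = sorted(table.loc[table["q"] < th.q_cut, "gene"]) if len(table) else []
            return CONIMResults("permutation", metric,
                                replace(th, effect_cut=None), table, sig)
        raise ValueError(f"unknown pipeline {pipeline!r}")
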