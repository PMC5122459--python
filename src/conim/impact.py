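"""Functional-impact and variant-allele-fraction comparisons.

The impact test asks whether mutations in a target gene set carry higher
Phred-scaled functional-impact scores than expected, via a
mutation-count-matched randomization: each target gene is replaced by a gene
with exactly the same number of missense mutations (requiring >= 25 such
peers), and the mean per-mutation score of the replacement sets forms the
null.  VAF = alt reads / total reads; group comparisons run per cancer type
with the published sample-size gates.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .cohort import Cohort
from .stats import chi2_2x2, empirical_p, mww_test

__all__ = ["matched_impact_test", "compute_vaf", "vaf_group_compare",
           "category_enrichment"]

MIN_COUNT_PEERS = 25


def matched_impact_test(impact_table: pd.DataFrame, target_genes, n_rand: int,
                        seed: int, min_peers: int = MIN_COUNT_PEERS) -> dict:
    """Mutation-count-matched randomization test on mean impact score.

    ``impact_table`` has one row per mutation with columns ``gene`` and
    ``score`` (Phred-like, >= 0).  Target genes with fewer than ``min_peers``
    other genes of exactly the same missense-mutation count are dropped with a
    warning.  One-sided: higher observed mean = more damaging.
    """
    if (impact_table["score"] < 0).any():
        raise ValueError("impact scores must be >= 0")
    counts = impact_table.groupby("gene").size()
    scores_by_gene = {g: grp["score"].to_numpy(float)
                      for g, grp in impact_table.groupby("gene")}
    by_count: dict[int, list[str]] = {}
    for g, c in counts.items():
        by_count.setdefault(int(c), []).append(g)
    for c in by_count:
        by_count[c].sort()

    retained, pools = [], []
    for g in target_genes:
        if g not in counts.index:
            warnings.warn(f"target gene {g!r} has no scored mutations; dropped")
            continue
        peers = [x for x in by_count[int(counts[g])] if x != g]
        if len(peers) < min_peers:
            warnings.warn(f"target gene {g!r} has only {len(peers)} count-matched "
                          f"peers (< {min_peers}); dropped")
            continue
        retained.append(g)
        pools.append(peers)
    if not retained:
        raise ValueError("all target genes dropped; no testable gene")

    obs_scores = np.concatenate([scores_by_gene[g] for g in retained])
    observed = float(obs_scores.mean())

    rng = np.random.default_rng(seed)
    null_means = np.empty(n_rand)
    for i in range(n_rand):
        repl_scores = [scores_by_gene[pool[int(rng.integers(len(pool)))]]
                       for pool in pools]
        null_means[i] = float(np.concatenate(repl_scores).mean())
    p = empirical_p(null_means, observed, alternative="greater")
    return {"observed_mean": observed, "null_means": null_means, "p": p,
            "genes": retained}


def compute_vaf(mutations: pd.DataFrame) -> pd.DataFrame:
    """Per-mutation variant allele fraction; zero-coverage rows are dropped."""
    if ((mutations["ref_count"] < 0) | (mutations["alt_count"] < 0)).any():
        raise ValueError("read counts must be non-negative")
    total = mutations["ref_count"] + mutations["alt_count"]
    n_dropped = int((total == 0).sum())
    if n_dropped:
        warnings.warn(f"{n_dropped} mutation(s) with zero total reads dropped")
    kept = mutations[total > 0]
    vaf = kept["alt_count"] / (kept["ref_count"] + kept["alt_count"])
    out = kept[["sample", "gene"]].copy()
    out["vaf"] = vaf.astype(float)
    return out.reset_index(drop=True)


def vaf_group_compare(cohort: Cohort, group_a_genes, group_b_genes,
                      min_mutations: int = 100,
                      min_gene_mutations: int = 15) -> pd.DataFrame:
    """Two-sided MWW of VAFs between two gene groups, per qualifying cancer type.

    A cancer type qualifies when group A contributes >= ``min_mutations``
    mutations among genes with >= ``min_gene_mutations`` non-silent mutations.
    """
    mut = cohort.nonsilent_mutations()
    gene_counts = mut.groupby("gene").size()
    eligible_genes = set(gene_counts[gene_counts >= min_gene_mutations].index)
    a_genes = set(group_a_genes) & eligible_genes
    b_genes = set(group_b_genes) & eligible_genes
    vafs = compute_vaf(mut)
    sample_type = cohort.samples.set_index("sample")["cancer_type"]
    vafs = vafs.assign(cancer_type=vafs["sample"].map(sample_type))

    rows = []
    for ct, grp in vafs.groupby("cancer_type"):
        a = grp.loc[grp["gene"].isin(a_genes), "vaf"].to_numpy()
        b = grp.loc[grp["gene"].isin(b_genes), "vaf"].to_numpy()
        if len(a) < min_mutations or len(b) == 0:
            continue
        res = mww_test(a, b)
        rows.append([ct, len(a), len(b), float(a.mean()), float(b.mean()),
                     res.p, "lower" if a.mean() < b.mean() else "higher"])
    if not rows:
        warnings.warn("no cancer type passed the VAF comparison thresholds")
    return pd.DataFrame(rows, columns=["cancer_type", "n_a", "n_b", "mean_vaf_a",
                                       "mean_vaf_b", "p", "direction"])


def category_enrichment(set_genes, category_genes, universe,
                        yates: bool = False) -> dict:
    """Chi-square enrichment of a gene category within a gene set.

    2x2 membership table over the universe: (in set x in category).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    s = set(set_genes) & universe
    c = set(category_genes) & universe
    a = len(s & c)
    b = len(s - c)
    cc = len(c - s)
    d = len(universe) - a - b - cc
    stat, p = chi2_2x2([[a, b], [cc, d]], yates=yates)
    frac_set = a / len(s) if s else 0.0
    frac_bg = len(c) / len(universe)
    return {"table": [[a, b], [cc, d]], "chi2": stat, "p": p,
            "fraction_in_set": frac_set, "fraction_in_universe": frac_bg}
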