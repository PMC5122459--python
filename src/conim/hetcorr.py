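"""Tissue heterochromatin fractions and their correlates.

The heterochromatin fraction of a tissue is the genome share labelled
"13_Het" in its 18-state segmentation.  Three screens link it to other
quantities: per-gene expression correlation across tissues (with a gene-set
contrast on |r|), cancer-type CNA burden correlation (Spearman, AS 89
p-values), and a reference-epigenome robustness test comparing admissible
tissue assignments against random assignments.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .cohort import EpigenomeTrack
from .stats import mww_test, spearman_as89

__all__ = ["heterochromatin_fraction", "TissueSummary", "tissue_summaries",
           "expression_het_screen", "burden_het_correlation",
           "epigenome_combination_test"]


def heterochromatin_fraction(track: EpigenomeTrack) -> float:
    """Het-state bp / total genome bp (requires a genome-covering track)."""
    return track.heterochromatin_fraction()


@dataclass
class TissueSummary:
    tissue: str
    het_fraction: float
    cancer_type: str
    mean_cna_number: float
    mean_cna_length: float


def tissue_summaries(burdens: pd.DataFrame, tracks: list[EpigenomeTrack],
                     type_tissue_map: dict[str, str],
                     apply_exclusions: bool = True) -> list[TissueSummary]:
    """Per-tissue burden/heterochromatin summary across mapped cancer types.

    Burden means are computed after hypermutator/aneuploid exclusion by
    default.
    """
    b = burdens
    if apply_exclusions:
        b = b[~(b["hypermutator_flag"] | b["aneuploid_flag"])]
    het = {t.tissue: t.heterochromatin_fraction() for t in tracks}
    out = []
    for ct, grp in b.groupby("cancer_type"):
        tissue = type_tissue_map.get(ct)
        if tissue is None or tissue not in het:
            continue
        out.append(TissueSummary(
            tissue=tissue, het_fraction=het[tissue], cancer_type=ct,
            mean_cna_number=float(grp["n_cna"].mean()),
            mean_cna_length=float(grp["mean_cna_length"].mean())))
    return out


def expression_het_screen(expression: pd.DataFrame, het_fractions: pd.Series,
                          gene_sets: dict[str, set] | None = None) -> dict:
    """Pearson r of each gene's expression with tissue heterochromatin fraction.

    ``expression`` is genes x tissues; ``het_fractions`` indexed by tissue.
    For each named gene set, |r| is compared against the complement with a
    two-sided MWW.  Genes with constant expression are excluded (count
    reported).
    """
    tissues = [t for t in expression.columns if t in het_fractions.index]
    if len(tissues) < 3:
        raise ValueError("need >= 3 tissues with both expression and het fraction")
    x = expression[tissues].to_numpy(float)
    h = het_fractions.loc[tissues].to_numpy(float)
    sd = x.std(axis=1)
    constant = sd == 0
    xc = x - x.mean(axis=1, keepdims=True)
    hc = h - h.mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ hc) / (np.sqrt((xc ** 2).sum(axis=1)) * np.sqrt((hc ** 2).sum()))
    r[constant] = np.nan
    table = pd.DataFrame({"gene": expression.index, "r": r})
    result = {"table": table, "n_excluded_constant": int(constant.sum()),
              "comparisons": {}}
    valid = table.dropna(subset=["r"]).set_index("gene")["r"].abs()
    for name, genes in (gene_sets or {}).items():
        in_set = valid.index.isin(set(genes))
        a = valid[in_set].to_numpy()
        b = valid[~in_set].to_numpy()
        if len(a) == 0 or len(b) == 0:
            continue
        res = mww_test(a, b)
        result["comparisons"][name] = {
            "n_set": len(a), "n_background": len(b),
            "mean_abs_r_set": float(a.mean()), "mean_abs_r_background": float(b.mean()),
            "p": res.p}
    return result


def burden_het_correlation(summaries: list[TissueSummary],
                           metric: str = "mean_cna_number",
                           exclude: list[str] | None = None,
                           method: str = "auto"):
    """Spearman correlation of per-cancer-type CNA burden with tissue
    heterochromatin fraction (AS 89 p-value); ``exclude`` drops tissues."""
    exclude = set(exclude or ())
    kept = [s for s in summaries if s.tissue not in exclude]
    if len(kept) < 4:
        raise ValueError("need >= 4 paired observations")
    x = np.asarray([s.het_fraction for s in kept])
    y = np.asarray([getattr(s, metric) for s in kept])
    return spearman_as89(x, y, method=method)


def epigenome_combination_test(burden_by_type: dict[str, float],
                               het_by_tissue: dict[str, float],
                               admissible: dict[str, list[str]],
                               n_random: int = 1000, seed: int = 0,
                               max_combinations: int = 10_000) -> dict:
    """Admissible reference-epigenome combinations vs random assignments.

    Distribution A: Spearman rho of burden vs het fraction over the Cartesian
    product of admissible tissue choices per cancer type (uniformly subsampled
    when the product exceeds ``max_combinations``).  Distribution B: rho over
    ``n_random`` uniformly random cancer-type -> tissue assignments.  Two-sided
    MWW of A vs B.
    """
    types = sorted(burden_by_type)
    if any(not admissible.get(ct) for ct in types):
        raise ValueError("every cancer type needs >= 1 admissible tissue")
    tissues = sorted(het_by_tissue)
    burden = np.asarray([burden_by_type[ct] for ct in types])
    rng = np.random.default_rng(seed)

    sizes = [len(admissible[ct]) for ct in types]
    total = int(np.prod(sizes))
    if total == 1 and n_random == 0:
        raise ValueError("nothing to compare: single combination, no random draws")

    def _rho(assign_het: np.ndarray) -> float:
        from scipy.stats import spearmanr
        return float(spearmanr(burden, assign_het).statistic)

    combo_rhos = []
    if total <= max_combinations:
        for combo in product(*(admissible[ct] for ct in types)):
            combo_rhos.append(_rho(np.asarray([het_by_tissue[t] for t in combo])))
    else:
        for _ in range(max_combinations):
            combo = [admissible[ct][int(rng.integers(len(admissible[ct])))]
                     for ct in types]
            combo_rhos.append(_rho(np.asarray([het_by_tissue[t] for t in combo])))

    random_rhos = []
    for _ in range(n_random):
        combo = [tissues[int(rng.integers(len(tissues)))] for _ in types]
        random_rhos.append(_rho(np.asarray([het_by_tissue[t] for t in combo])))

    a = np.asarray(combo_rhos)
    b = np.asarray(random_rhos)
    p = np.nan
    if len(a) and len(b):
        p = mww_test(a[~np.isnan(a)], b[~np.isnan(b)]).p
    return {"combination_rhos": a, "random_rhos": b, "p": p,
            "n_combinations": len(a), "n_random": len(b)}
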