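"""Per-sample CNA burden statistics with the published sample/segment filters.

A CNA segment is retained when its magnitude exceeds 0.1 (in units of
log2(copy number) - 1, strict inequality) and its length is at least 100 bp.
Hypermutators are samples whose somatic mutation count exceeds the cancer-type
median by more than two standard deviations; aneuploid samples have an
estimated ploidy above 2.9.  Flags never alter the burden statistics, only
mark samples for downstream exclusion.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .cohort import Cohort

__all__ = [
    "SEG_VALUE_CUT",
    "MIN_SEGMENT_LENGTH",
    "PLOIDY_CUT",
    "filter_segments",
    "compute_burden",
    "flag_hypermutators",
    "flag_aneuploid",
    "prepare_burdens",
]

SEG_VALUE_CUT = 0.1
MIN_SEGMENT_LENGTH = 100
PLOIDY_CUT = 2.9


def filter_segments(segments: pd.DataFrame,
                    seg_value_cut: float = SEG_VALUE_CUT,
                    min_length: int = MIN_SEGMENT_LENGTH) -> pd.DataFrame:
    """Retain segments with |seg_value| > cut (strict) and length >= min_length."""
    length = segments["end"] - segments["start"]
    keep = (segments["seg_value"].abs() > seg_value_cut) & (length >= min_length)
    return segments[keep].reset_index(drop=True)


def compute_burden(cohort: Cohort, segments: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-sample burden table: n_cna, mean_cna_length, n_mutations, ploidy.

    ``segments`` defaults to the cohort's segments filtered with the standard
    thresholds.  ``mean_cna_length`` is NaN when a sample has no retained
    segments.
    """
    if segments is None:
        segments = filter_segments(cohort.cna_segments)
    known = set(cohort.samples["sample"])
    unknown = set(segments["sample"]) - known
    if unknown:
        raise ValueError(f"segments reference unknown samples: {sorted(unknown)[:5]}")

    lengths = segments["end"] - segments["start"]
    per = segments.assign(length=lengths).groupby("sample")["length"]
    n_cna = per.size()
    mean_len = per.mean()

    out = cohort.samples[["sample", "cancer_type", "ploidy"]].copy()
    out["n_cna"] = out["sample"].map(n_cna).fillna(0).astype(int)
    out["mean_cna_length"] = out["sample"].map(mean_len)
    out["n_mutations"] = cohort.mutation_counts().to_numpy()
    out["hypermutator_flag"] = False
    out["aneuploid_flag"] = False
    return out


def flag_hypermutators(burdens: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Flag samples with n_mutations > within-type median + 2 * sd.

    ``ddof=1`` (sample standard deviation) by default.  Types with fewer than
    2 samples have an undefined sd and no sample is flagged (with a warning).
    """
    out = burdens.reset_index(drop=True).copy()
    flags = np.zeros(len(out), dtype=bool)
    for ct, grp in out.groupby("cancer_type"):
        counts = grp["n_mutations"].to_numpy(float)
        if len(counts) < 2:
            warnings.warn(f"cancer type {ct!r} has <2 samples; hypermutator sd undefined")
            continue
        med = float(np.median(counts))
        sd = float(np.std(counts, ddof=ddof))
        flags[grp.index] = counts > med + 2.0 * sd
    out["hypermutator_flag"] = flags
    return out


def flag_aneuploid(burdens: pd.DataFrame, ploidy_cut: float = PLOIDY_CUT) -> pd.DataFrame:
    """Flag samples with ploidy strictly above the cut; missing ploidy retained."""
    out = burdens.copy()
    ploidy = out["ploidy"]
    n_missing = int(ploidy.isna().sum())
    if n_missing:
        warnings.warn(f"{n_missing} samples lack ploidy; retained unflagged")
    out["aneuploid_flag"] = (ploidy > ploidy_cut).fillna(False).astype(bool)
    return out


def prepare_burdens(cohort: Cohort) -> pd.DataFrame:
    """Standard burden table: filter segments, aggregate, set both flags."""
    return flag_aneuploid(flag_hypermutators(compute_burden(cohort)))
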