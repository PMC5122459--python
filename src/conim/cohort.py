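"""In-memory containers for the study objects.

A :class:`Cohort` bundles the three per-sample tables the pipelines consume
(clinical/sample table, somatic mutation calls, copy-number segments) as pandas
DataFrames with fixed schemas.  An :class:`EpigenomeTrack` holds one tissue's
chromatin-state segmentation (a genome-covering set of labelled intervals) and
its per-histone-mark peak sets.  All internal coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import merge_intervals, overlap_bp, state_at

__all__ = [
    "MUTATION_CLASSES",
    "NON_SILENT_CLASSES",
    "STATE18_LABELS",
    "HET_STATE",
    "Cohort",
    "EpigenomeTrack",
]

MUTATION_CLASSES = ("missense", "nonsense", "frameshift", "silent", "other_nonsilent")
NON_SILENT_CLASSES = frozenset({"missense", "nonsense", "frameshift", "other_nonsilent"})

#: Roadmap-style 18-state chromHMM alphabet
STATE18_LABELS = (
    "1_TssA", "2_TssFlnk", "3_TssFlnkU", "4_TssFlnkD", "5_Tx", "6_TxWk",
    "7_EnhG1", "8_EnhG2", "9_EnhA1", "10_EnhA2", "11_EnhWk", "12_ZNF/Rpts",
    "13_Het", "14_TssBiv", "15_EnhBiv", "16_ReprPC", "17_ReprPCWk", "18_Quies",
)
HET_STATE = "13_Het"

SAMPLE_COLS = ["sample", "cancer_type", "time", "event", "ploidy"]
MUTATION_COLS = ["sample", "gene", "mut_class", "protein_pos", "ref_count", "alt_count"]
SEGMENT_COLS = ["sample", "chrom", "start", "end", "seg_value"]


def _check_frame(df: pd.DataFrame, cols: list[str], name: str) -> pd.DataFrame:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{name} table missing columns: {missing}")
    return df[cols].reset_index(drop=True)


@dataclass
class Cohort:
    """Per-sample mutation calls, CNA segments and clinical covariates."""

    samples: pd.DataFrame
    mutations: pd.DataFrame
    cna_segments: pd.DataFrame
    genome: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = _check_frame(self.samples, SAMPLE_COLS, "samples")
        self.mutations = _check_frame(self.mutations, MUTATION_COLS, "mutations")
        self.cna_segments = _check_frame(self.cna_segments, SEGMENT_COLS, "cna_segments")
        self.validate()

    def validate(self) -> None:
        seg = self.cna_segments
        if len(seg) and not (seg["start"] < seg["end"]).all():
            raise ValueError("CNA segments must satisfy start < end")
        known = set(self.samples["sample"])
        for name, df in (("mutations", self.mutations), ("cna_segments", seg)):
            unknown = set(df["sample"]) - known
            if unknown:
                raise ValueError(f"{name} reference unknown samples: {sorted(unknown)[:5]}")
        mut = self.mutations
        if len(mut) and ((mut["ref_count"] < 0) | (mut["alt_count"] < 0)).any():
            raise ValueError("read counts must be non-negative")
        bad = set(mut["mut_class"]) - set(MUTATION_CLASSES)
        if bad:
            raise ValueError(f"unknown mutation classes: {sorted(bad)}")

    # -- convenience views -------------------------------------------------
    def nonsilent_mutations(self) -> pd.DataFrame:
        return self.mutations[self.mutations["mut_class"].isin(NON_SILENT_CLASSES)]

    def silent_mutations(self) -> pd.DataFrame:
        return self.mutations[self.mutations["mut_class"] == "silent"]

    def mutation_counts(self, non_silent_only: bool = False) -> pd.Series:
        """Somatic mutation count per sample (0 for unmutated samples)."""
        mut = self.nonsilent_mutations() if non_silent_only else self.mutations
        counts = mut.groupby("sample").size()
        return counts.reindex(self.samples["sample"], fill_value=0)

    def carriers(self, gene: str, classes=NON_SILENT_CLASSES) -> set[str]:
        mut = self.mutations
        sel = mut[(mut["gene"] == gene) & mut["mut_class"].isin(classes)]
        return set(sel["sample"])

    def equals(self, other: "Cohort") -> bool:
        def norm(df, keys):
            return df.sort_values(keys, kind="stable").reset_index(drop=True)

        return (
            norm(self.samples, ["sample"]).equals(norm(other.samples, ["sample"]))
            and norm(self.mutations, MUTATION_COLS).equals(norm(other.mutations, MUTATION_COLS))
            and norm(self.cna_segments, SEGMENT_COLS).equals(norm(other.cna_segments, SEGMENT_COLS))
            and self.genome == other.genome
        )


@dataclass
class EpigenomeTrack:
    """One tissue's chromatin-state segmentation plus per-mark peak intervals."""

    tissue: str
    states: pd.DataFrame  # chrom, start, end, state
    peaks: dict[str, pd.DataFrame] = field(default_factory=dict)  # mark -> chrom,start,end
    genome: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.states = _check_frame(self.states, ["chrom", "start", "end", "state"], "states")
        self._state_index: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self._peak_index: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
        for chrom, grp in self.states.groupby("chrom", sort=False):
            grp = grp.sort_values("start", kind="stable")
            s = grp["start"].to_numpy(np.int64)
            e = grp["end"].to_numpy(np.int64)
            if np.any(e <= s):
                raise ValueError(f"state intervals on {chrom} must satisfy start < end")
            if np.any(s[1:] < e[:-1]):
                raise ValueError(f"state intervals overlap on {chrom}")
            self._state_index[chrom] = (s, e, grp["state"].to_numpy(object))

    def validate_coverage(self) -> None:
        """Require the state track to jointly cover every genome chromosome."""
        for chrom, length in self.genome.items():
            idx = self._state_index.get(chrom)
            if idx is None:
                raise ValueError(f"no state intervals for chromosome {chrom}")
            s, e, _ = idx
            if s[0] != 0 or e[-1] != length or np.any(s[1:] != e[:-1]):
                raise ValueError(f"state track does not cover chromosome {chrom}")

    def state_at(self, chrom: str, pos: int) -> str:
        idx = self._state_index.get(chrom)
        if idx is None:
            raise ValueError(f"position {chrom}:{pos} not covered by the state track")
        return state_at(pos, idx[0], idx[1], idx[2])

    def _peaks_for(self, mark: str, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        key = (mark, chrom)
        if key not in self._peak_index:
            df = self.peaks.get(mark)
            if df is None:
                raise KeyError(f"mark {mark!r} absent for tissue {self.tissue!r}")
            sub = df[df["chrom"] == chrom]
            self._peak_index[key] = merge_intervals(
                sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64))
        return self._peak_index[key]

    def peak_overlap_bp(self, mark: str, chrom: str, start: int, end: int) -> int:
        """bp of [start, end) covered by (merged) peaks of ``mark``."""
        s, e = self._peaks_for(mark, chrom)
        return overlap_bp(start, end, s, e)

    def has_peak_near(self, mark: str, chrom: str, pos: int, window: int) -> bool:
        half = window // 2
        return self.peak_overlap_bp(mark, chrom, max(0, pos - half), pos + half) > 0

    def heterochromatin_fraction(self) -> float:
        """Fraction of the genome labelled with the heterochromatin state."""
        if not self.genome:
            raise ValueError("genome sizes required")
        self.validate_coverage()
        st = self.states
        het = st[st["state"] == HET_STATE]
        total = float(sum(self.genome.values()))
        return float((het["end"] - het["start"]).sum()) / total
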