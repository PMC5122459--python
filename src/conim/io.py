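"""Readers and writers for the tab-delimited formats the pipelines consume.

Coordinate conventions at the I/O boundary: BED and narrowPeak are 0-based
half-open, SEG is 1-based inclusive; everything in memory is 0-based half-open
and converters live here.  Malformed lines raise :class:`ParseError` with the
offending line number.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd

from .cohort import Cohort, EpigenomeTrack

__all__ = [
    "ParseError",
    "write_cohort", "read_cohort",
    "write_seg", "read_seg",
    "write_maf", "read_maf",
    "write_clinical", "read_clinical",
    "write_bed_states", "read_bed_states",
    "write_narrowpeak", "read_narrowpeak",
    "write_epigenome", "read_epigenome",
    "read_edge_list",
    "read_gene_list",
]


class ParseError(ValueError):
    """Raised on malformed input lines; carries the 1-based line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


def _int(path, lineno, value, what):
    try:
        return int(value)
    except ValueError:
        raise ParseError(path, lineno, f"invalid integer {what}: {value!r}") from None


def _float(path, lineno, value, what):
    try:
        return float(value)
    except ValueError:
        raise ParseError(path, lineno, f"invalid number {what}: {value!r}") from None


# -- SEG (1-based inclusive on disk) ----------------------------------------

def write_seg(segments: pd.DataFrame, path) -> None:
    out = segments.copy()
    out["start"] = out["start"] + 1  # to 1-based inclusive
    out.to_csv(path, sep="\t", index=False,
               columns=["sample", "chrom", "start", "end", "seg_value"])


def read_seg(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("sample"):
            raise ParseError(path, 1, "missing SEG header")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5:
                raise ParseError(path, lineno, f"expected 5 columns, got {len(parts)}")
            start1 = _int(path, lineno, parts[2], "start")
            end1 = _int(path, lineno, parts[3], "end")
            start, end = start1 - 1, end1  # back to half-open
            if start >= end:
                raise ParseError(path, lineno, f"segment start >= end ({start1} >= {end1})")
            rows.append([parts[0], parts[1], start, end,
                         _float(path, lineno, parts[4], "seg_value")])
    return pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "seg_value"])


# -- MAF-like mutation table -------------------------------------------------

_MAF_COLS = ["sample", "gene", "class", "protein_pos", "ref_count", "alt_count"]


def write_maf(mutations: pd.DataFrame, path) -> None:
    out = mutations.rename(columns={"mut_class": "class"})
    out.to_csv(path, sep="\t", index=False, columns=_MAF_COLS)


def read_maf(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _MAF_COLS:
            raise ParseError(path, 1, f"unexpected MAF header: {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 6:
                raise ParseError(path, lineno, f"expected 6 columns, got {len(parts)}")
            ref = _int(path, lineno, parts[4], "ref_count")
            alt = _int(path, lineno, parts[5], "alt_count")
            if ref < 0 or alt < 0:
                raise ParseError(path, lineno, "negative read count")
            rows.append([parts[0], parts[1], parts[2],
                         _int(path, lineno, parts[3], "protein_pos"), ref, alt])
    df = pd.DataFrame(rows, columns=_MAF_COLS)
    return df.rename(columns={"class": "mut_class"})


# -- clinical ----------------------------------------------------------------

def write_clinical(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index=False,
                   columns=["sample", "cancer_type", "time", "event", "ploidy"])


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "cancer_type", "time", "event", "ploidy"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(path, 1, f"clinical table missing columns {sorted(missing)}")
    return df


# -- BED4 chromatin states ---------------------------------------------------

def write_bed_states(states: pd.DataFrame, path) -> None:
    states.to_csv(path, sep="\t", index=False, header=False,
                  columns=["chrom", "start", "end", "state"])


def read_bed_states(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise ParseError(path, lineno, f"BED4 needs 4 columns, got {len(parts)}")
            start = _int(path, lineno, parts[1], "start")
            end = _int(path, lineno, parts[2], "end")
            if start >= end:
                raise ParseError(path, lineno, "interval start >= end")
            rows.append([parts[0], start, end, parts[3]])
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])


# -- ENCODE narrowPeak -------------------------------------------------------

def write_narrowpeak(peaks: pd.DataFrame, path, name_prefix: str = "peak") -> None:
    with open(path, "w") as fh:
        for i, row in enumerate(peaks.itertuples(index=False)):
            fh.write("\t".join(map(str, [row.chrom, row.start, row.end,
                                         f"{name_prefix}{i}", 0, ".",
                                         0.0, -1, -1, -1])) + "\n")


def read_narrowpeak(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 10:
                raise ParseError(path, lineno,
                                 f"narrowPeak requires 10 columns, got {len(parts)}")
            start = _int(path, lineno, parts[1], "start")
            end = _int(path, lineno, parts[2], "end")
            if start >= end:
                raise ParseError(path, lineno, "peak start >= end")
            rows.append([parts[0], start, end])
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


# -- cohort directory round trip ---------------------------------------------

def write_cohort(cohort: Cohort, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_maf(cohort.mutations, d / "mutations.maf.tsv")
    write_seg(cohort.cna_segments, d / "segments.seg")
    write_clinical(cohort.samples, d / "clinical.tsv")
    pd.DataFrame(sorted(cohort.genome.items()),
                 columns=["chrom", "length"]).to_csv(d / "genome.tsv", sep="\t", index=False)


def read_cohort(directory) -> Cohort:
    d = Path(directory)
    genome_df = pd.read_csv(d / "genome.tsv", sep="\t")
    genome = dict(zip(genome_df["chrom"], genome_df["length"].astype(int)))
    return Cohort(samples=read_clinical(d / "clinical.tsv"),
                  mutations=read_maf(d / "mutations.maf.tsv"),
                  cna_segments=read_seg(d / "segments.seg"),
                  genome=genome)


# -- epigenome directory round trip ------------------------------------------

def write_epigenome(track: EpigenomeTrack, directory) -> None:
    d = Path(directory) / track.tissue
    d.mkdir(parents=True, exist_ok=True)
    write_bed_states(track.states, d / "states.bed")
    for mark, peaks in track.peaks.items():
        write_narrowpeak(peaks, d / f"{mark}.narrowPeak", name_prefix=f"{mark}_")
    pd.DataFrame(sorted(track.genome.items()),
                 columns=["chrom", "length"]).to_csv(d / "genome.tsv", sep="\t", index=False)


def read_epigenome(directory, tissue: str) -> EpigenomeTrack:
    d = Path(directory) / tissue
    genome_df = pd.read_csv(d / "genome.tsv", sep="\t")
    genome = dict(zip(genome_df["chrom"], genome_df["length"].astype(int)))
    peaks = {}
    for f in sorted(os.listdir(d)):
        if f.endswith(".narrowPeak"):
            peaks[f[:-len(".narrowPeak")]] = read_narrowpeak(d / f)
    return EpigenomeTrack(tissue=tissue, states=read_bed_states(d / "states.bed"),
                          peaks=peaks, genome=genome)


# -- misc --------------------------------------------------------------------

def read_edge_list(path, min_score: float | None = None) -> pd.DataFrame:
    """3-column PPI edge list (proteinA, proteinB, confidence score)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ParseError(path, lineno, f"edge list needs 3 columns, got {len(parts)}")
            score = _float(path, lineno, parts[2], "score")
            if min_score is None or score >= min_score:
                rows.append([parts[0], parts[1], score])
    return pd.DataFrame(rows, columns=["protein_a", "protein_b", "score"])


def read_gene_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
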