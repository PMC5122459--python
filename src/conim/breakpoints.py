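"""CNA breakpoints from recurrent regions, and their chromatin context.

Breakpoints are the two boundary coordinates ("region limits") of each
recurrent CNA region passing the recurrence q-value cutoff.  A breakpoint is
*associated* with the healthy tissue-of-origin of every cancer type in which
its source region is recurrent; breakpoints falling into centromere/telomere
gaps or associated with more than three tissues are excluded, and identical
(chromosome, position) breakpoints are merged with their tissue sets unioned.

The enrichment analyses then compare, per chromatin state or per histone-mark
window, the breakpoint context in associated versus non-associated tissues.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort, EpigenomeTrack
from .stats import chi2_2x2, mww_test

__all__ = ["BreakpointSet", "build_breakpoints", "state_enrichment",
           "window_mark_enrichment", "length_by_mark_context",
           "reader_mutation_fraction"]


@dataclass
class BreakpointSet:
    """Deduplicated breakpoints with tissue-association metadata.

    ``table`` columns: chrom, pos, tissues (frozenset), boundaries (tuple of
    "start"/"end" labels), region_ids (tuple), region_lengths (tuple of bp),
    q_min (best recurrence q across source regions).
    """

    table: pd.DataFrame
    n_excluded_position: int = 0
    n_excluded_tissues: int = 0

    def __len__(self) -> int:
        return len(self.table)


def _normalize_gaps(gaps) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom, v in (gaps or {}).items():
        if isinstance(v, tuple) and len(v) == 2 and np.isscalar(v[0]):
            out[chrom] = [tuple(v)]
        else:
            out[chrom] = [tuple(iv) for iv in v]
    return out


def _in_gap(chrom: str, pos: int, gaps: dict) -> bool:
    return any(s <= pos < e for s, e in gaps.get(chrom, ()))


def build_breakpoints(regions: pd.DataFrame, type_tissue_map: dict,
                      q_cut: float = 0.1, centromeres=None, telomeres=None,
                      max_tissues: int = 3) -> BreakpointSet:
    """Construct the tissue-associated breakpoint set from recurrent regions.

    ``regions`` columns: cancer_type, region_id, chrom, start, end, q.
    """
    if ((regions["start"] >= regions["end"])).any():
        raise ValueError("recurrent region with start >= end")
    cen = _normalize_gaps(centromeres)
    tel = _normalize_gaps(telomeres)
    rec = regions[regions["q"] < q_cut]

    merged: dict[tuple[str, int], dict] = {}
    for r in rec.itertuples(index=False):
        tissue = type_tissue_map[r.cancer_type]
        length = int(r.end - r.start)
        for pos, boundary in ((int(r.start), "start"), (int(r.end), "end")):
            key = (r.chrom, pos)
            info = merged.setdefault(key, {"tissues": set(), "boundaries": [],
                                           "region_ids": [], "region_lengths": [],
                                           "q_min": np.inf})
            info["tissues"].add(tissue)
            info["boundaries"].append(boundary)
            info["region_ids"].append(r.region_id)
            info["region_lengths"].append(length)
            info["q_min"] = min(info["q_min"], float(r.q))

    rows = []
    n_pos_excl = 0
    n_tis_excl = 0
    for (chrom, pos), info in sorted(merged.items()):
        if _in_gap(chrom, pos, cen) or _in_gap(chrom, pos, tel):
            n_pos_excl += 1
            continue
        if len(info["tissues"]) > max_tissues:
            n_tis_excl += 1
            continue
        rows.append([chrom, pos, frozenset(info["tissues"]),
                     tuple(info["boundaries"]), tuple(info["region_ids"]),
                     tuple(info["region_lengths"]), info["q_min"]])
    table = pd.DataFrame(rows, columns=["chrom", "pos", "tissues", "boundaries",
                                        "region_ids", "region_lengths", "q_min"])
    return BreakpointSet(table, n_pos_excl, n_tis_excl)


# ---------------------------------------------------------------------------
# chromatin-state enrichment
# ---------------------------------------------------------------------------

def state_enrichment(breakpoints: BreakpointSet, tracks: list[EpigenomeTrack],
                     min_nonassoc: int = 100) -> pd.DataFrame:
    """Per-state associated/non-associated breakpoint ratio with chi-square p.

    Every (breakpoint, tissue) pair contributes one observation: the chromatin
    state at the breakpoint position in that tissue's track.  The ratio is
    (state share among associated pairs) / (state share among non-associated
    pairs); states seen fewer than ``min_nonassoc`` times in non-associated
    tissues are flagged unreported.
    """
    for t in tracks:
        t.validate_coverage()
    counts: dict[str, np.ndarray] = {}
    totals = np.zeros(2)  # assoc, nonassoc
    for bp in breakpoints.table.itertuples(index=False):
        for t in tracks:
            state = t.state_at(bp.chrom, bp.pos)
            assoc = 0 if t.tissue in bp.tissues else 1
            counts.setdefault(state, np.zeros(2))[assoc] += 1
            totals[assoc] += 1
    rows = []
    for state, (n_a, n_n) in sorted(counts.items()):
        ratio = np.nan
        if totals[0] > 0 and totals[1] > 0 and n_n > 0:
            ratio = (n_a / totals[0]) / (n_n / totals[1])
        table = [[n_a, totals[0] - n_a], [n_n, totals[1] - n_n]]
        try:
            stat, p = chi2_2x2(table)
        except ValueError:
            stat, p = np.nan, np.nan
        rows.append([state, int(n_a), int(n_n), ratio, stat, p,
                     n_n >= min_nonassoc])
    return pd.DataFrame(rows, columns=["state", "assoc_count", "nonassoc_count",
                                       "ratio", "chi2", "p", "reported"])


# ---------------------------------------------------------------------------
# histone-mark window enrichment
# ---------------------------------------------------------------------------

def _window_fraction(track: EpigenomeTrack, mark: str, chrom: str, pos: int,
                     window: int) -> float:
    """Fraction of the (chromosome-clipped) window covered by mark peaks."""
    half = window // 2
    start = max(0, pos - half)
    end = min(track.genome[chrom], pos + half)
    if end <= start:
        return 0.0
    return track.peak_overlap_bp(mark, chrom, start, end) / (end - start)


def window_mark_enrichment(breakpoints: BreakpointSet,
                           tracks: list[EpigenomeTrack], mark: str,
                           window_sizes=(10_000, 100_000, 1_000_000)) -> pd.DataFrame:
    """Window-sweep enrichment of a histone mark around breakpoints.

    For each window size, the covered-bp fraction of the window is computed
    per (breakpoint, tissue) pair and compared between associated and
    non-associated tissues (two-sided MWW, Bonferroni across window sizes).
    """
    if any(w % 2 for w in window_sizes):
        raise ValueError("window sizes must be even")
    usable = [t for t in tracks if mark in t.peaks]
    if len(usable) < len(tracks):
        import warnings
        warnings.warn(f"{len(tracks) - len(usable)} tissue(s) lack mark {mark!r}; skipped")
    rows = []
    window_sizes = sorted(window_sizes)
    for w in window_sizes:
        assoc, nonassoc = [], []
        for bp in breakpoints.table.itertuples(index=False):
            for t in usable:
                frac = _window_fraction(t, mark, bp.chrom, bp.pos, w)
                (assoc if t.tissue in bp.tissues else nonassoc).append(frac)
        a = np.asarray(assoc) if assoc else np.asarray([np.nan])
        na = np.asarray(nonassoc) if nonassoc else np.asarray([np.nan])
        mean_a, mean_na = float(np.nanmean(a)), float(np.nanmean(na))
        testable = (len(assoc) > 0 and len(nonassoc) > 0
                    and max(assoc + nonassoc) > 0)
        p = mww_test(a, na).p if testable else np.nan
        fold = mean_a / mean_na if mean_na > 0 else np.nan
        rows.append([w, mean_a, mean_na, fold, p])
    out = pd.DataFrame(rows, columns=["window", "frac_assoc", "frac_nonassoc",
                                      "fold_change", "p"])
    out["p_bonferroni"] = np.minimum(1.0, out["p"] * out["p"].notna().sum())
    return out


# ---------------------------------------------------------------------------
# CNA length by H3K9me3 context
# ---------------------------------------------------------------------------

def length_by_mark_context(breakpoints: BreakpointSet,
                           tracks: list[EpigenomeTrack], mark: str = "H3K9me3",
                           window: int = 10_000,
                           end_exclusions=(1_000_000, 10_000_000)) -> dict:
    """Compare source-CNA lengths of mark-enriched vs mark-depleted breakpoints.

    A breakpoint is *enriched* when at least one of its associated tissues has
    >= 1 peak of ``mark`` in the window around it.  One observation per
    (breakpoint, source region).  Positional controls: MWW on the
    distance-to-nearest-chromosome-end between the groups, and re-tests after
    excluding breakpoints within each ``end_exclusions`` distance of the ends.
    """
    genome = tracks[0].genome
    track_of = {t.tissue: t for t in tracks}
    records = []  # (enriched, lengths, dist_to_end)
    for bp in breakpoints.table.itertuples(index=False):
        enriched = any(
            track_of[tis].has_peak_near(mark, bp.chrom, bp.pos, window)
            for tis in bp.tissues if tis in track_of)
        dist = min(bp.pos, genome[bp.chrom] - bp.pos)
        records.append((enriched, bp.region_lengths, dist))

    def _groups(min_dist=0):
        g_len = {True: [], False: []}
        g_dist = {True: [], False: []}
        n_bp = {True: 0, False: 0}
        for enr, lengths, dist in records:
            if dist < min_dist:
                continue
            g_len[enr].extend(lengths)
            g_dist[enr].append(dist)
            n_bp[enr] += 1
        if not g_len[True] or not g_len[False]:
            raise ValueError("a breakpoint group is empty")
        res = mww_test(g_len[True], g_len[False])
        return {
            "n_enriched": n_bp[True], "n_depleted": n_bp[False],
            "median_length_enriched": float(np.median(g_len[True])),
            "median_length_depleted": float(np.median(g_len[False])),
            "p_length": res.p,
            "p_distance_control": mww_test(g_dist[True], g_dist[False]).p,
        }

    out = {"main": _groups(0)}
    for cut in end_exclusions:
        out[f"exclude_{cut}bp"] = _groups(cut)
    return out


# ---------------------------------------------------------------------------
# H3K9me3-reader mutation fractions
# ---------------------------------------------------------------------------

def reader_mutation_fraction(cohort: Cohort, genes, enriched_types,
                             other_types) -> dict:
    """Chi-square on carrier fraction: mark-enriched vs other cancer types.

    Tests whether samples in the enriched cancer types more often carry a
    non-silent mutation in any of ``genes`` (pooled, plus per-gene tables).
    """
    enriched_types = set(enriched_types)
    other_types = set(other_types)
    if not enriched_types or not other_types:
        raise ValueError("both cancer-type groups must be non-empty")
    samples = cohort.samples
    in_enriched = samples["cancer_type"].isin(enriched_types)
    in_other = samples["cancer_type"].isin(other_types)

    def _table(gene_list):
        carriers = set()
        for g in gene_list:
            carriers |= cohort.carriers(g)
        carrier = samples["sample"].isin(carriers)
        a = int((carrier & in_enriched).sum())
        b = int((~carrier & in_enriched).sum())
        c = int((carrier & in_other).sum())
        d = int((~carrier & in_other).sum())
        stat, p = chi2_2x2([[a, b], [c, d]])
        return {"table": [[a, b], [c, d]], "chi2": stat, "p": p,
                "frac_enriched": a / max(1, a + b), "frac_other": c / max(1, c + d)}

    out = {"pooled": _table(list(genes)), "per_gene": {}}
    for g in genes:
        out["per_gene"][g] = _table([g])
    return out
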