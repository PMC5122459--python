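"""Synthetic cohorts, PPI networks and tissue epigenomes.

The generators emulate the statistical structure the analysis pipelines assume:

* per-cancer-type somatic mutation burdens with a hypermutator tail;
* per-sample CNA counts that are negative-binomially overdispersed, scaled
  multiplicatively by mutations in planted "modifier" genes and by the
  heterochromatin fraction of the tissue-of-origin;
* log-normal CNA lengths, inflated near planted H3K9me3 peaks;
* exponential survival times whose hazard rises across CNA-count quartiles;
* a heavy-tailed protein-interaction graph with a planted connected module;
* tissue epigenomes (18-state segmentations + histone peak sets) with a
  controlled heterochromatin fraction.

Every generator draws from its own RNG stream derived stably from
``SimConfig.seed``, so adding one generator never perturbs the others, and
identical seed + config yields byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx

from .cohort import (
    Cohort,
    EpigenomeTrack,
    HET_STATE,
    STATE18_LABELS,
)

__all__ = [
    "SimConfig",
    "default_genome",
    "generate_cohort",
    "generate_ppi_graph",
    "generate_epigenomes",
    "generate_expression",
    "BreakpointPanel",
    "simulate_breakpoint_panel",
]

_MARKS = ("H3K9me3", "H3K4me1", "H3K4me3", "H3K27me3", "H3K36me3", "H3K9ac", "H3K27ac")

# mutation-class mixture of the simulated calls
_CLASS_P = {
    "missense": 0.55,
    "silent": 0.25,
    "nonsense": 0.07,
    "frameshift": 0.07,
    "other_nonsilent": 0.06,
}


def default_genome() -> list[tuple[str, int]]:
    """A compact 4 x 50 Mb model genome."""
    return [(f"chr{i}", 50_000_000) for i in range(1, 5)]


@dataclass
class SimConfig:
    """Study conditions for the synthetic generators.

    ``modifier_effect`` multiplies the expected CNA count of a sample once per
    planted modifier gene it carries a non-silent mutation in (< 1 = "fewer
    CNAs" modifier).  ``h3k9me3_length_factor`` multiplies CNA length when the
    segment's start lies within ``h3k9me3_window`` of a planted H3K9me3 peak
    of the sample's tissue-of-origin.
    """

    n_cancer_types: int = 4
    samples_per_type: int = 300
    n_genes: int = 505
    genome: list[tuple[str, int]] = field(default_factory=default_genome)
    n_modifier_genes: int = 5
    modifier_effect: float = 0.3
    baseline_cna_mean: float = 46.0
    mutation_rate_range: tuple[float, float] = (20.0, 80.0)
    het_fraction_range: tuple[float, float] = (0.05, 0.35)
    h3k9me3_length_factor: float = 1.0
    seed: int = 0

    # secondary knobs (defaults are the study conditions; not tuned per run)
    cna_dispersion: float = 10.0          # NB size parameter; larger = closer to Poisson
    cna_length_log_mean: float = 13.8     # ln bp, ~1 Mb median
    cna_length_log_sd: float = 1.0
    h3k9me3_window: int = 10_000
    subthreshold_fraction: float = 0.05   # extra segments failing the magnitude/length filters
    hypermutator_fraction: float = 0.02
    aneuploid_fraction: float = 0.05
    survival_hazard_ratio: float = 3.0    # top vs bottom CNA-count quartile
    survival_median_time: float = 1000.0  # days, bottom quartile
    censor_time: float = 3000.0
    state_bin_bp: int = 100_000           # epigenome segmentation resolution
    length_weighted_mutations: bool = False
    min_carriers_per_type: int = 5

    def __post_init__(self) -> None:
        for name in ("n_cancer_types", "samples_per_type", "n_genes", "n_modifier_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_modifier_genes > self.n_genes:
            raise ValueError("n_modifier_genes cannot exceed n_genes")
        if self.modifier_effect <= 0:
            raise ValueError("modifier_effect must be > 0")
        lo, hi = self.het_fraction_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("het_fraction_range must be within [0, 1]")
        if any(length <= 0 for _, length in self.genome):
            raise ValueError("chromosome lengths must be positive")
        if self.mutation_rate_range[0] <= 0 or self.mutation_rate_range[1] < self.mutation_rate_range[0]:
            raise ValueError("invalid mutation_rate_range")

    # -- derived vocabulary -------------------------------------------------
    @property
    def modifier_genes(self) -> list[str]:
        return [f"MOD{i + 1}" for i in range(self.n_modifier_genes)]

    @property
    def null_genes(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes - self.n_modifier_genes)]

    @property
    def genes(self) -> list[str]:
        return self.modifier_genes + self.null_genes

    @property
    def cancer_types(self) -> list[str]:
        return [f"ct{i + 1}" for i in range(self.n_cancer_types)]

    @property
    def tissues(self) -> list[str]:
        return [f"tissue{i + 1}" for i in range(self.n_cancer_types)]

    def tissue_of(self, cancer_type: str) -> str:
        return "tissue" + cancer_type.removeprefix("ct")


def _stream(config_seed: int, name: str) -> np.random.Generator:
    """Stable, independent RNG stream per generator."""
    tag = int.from_bytes(name.encode(), "little") % (2**32)
    return np.random.default_rng(np.random.SeedSequence(entropy=config_seed,
                                                        spawn_key=(tag,)))


# ---------------------------------------------------------------------------
# shared tissue profiles: heterochromatin fractions and planted H3K9me3 peaks
# ---------------------------------------------------------------------------

def _tissue_profiles(config: SimConfig, n_tissues: int | None = None) -> list[dict]:
    """Per-tissue heterochromatin fraction, Het bin layout and H3K9me3 peaks.

    Shared between :func:`generate_cohort` and :func:`generate_epigenomes` so
    that the cohort's CNA-length coupling refers to the same peaks the
    epigenome tracks carry.
    """
    n = n_tissues if n_tissues is not None else config.n_cancer_types
    rng = _stream(config.seed, "tissues")
    lo, hi = config.het_fraction_range
    profiles = []
    bins = []
    for chrom, length in config.genome:
        n_bins = length // config.state_bin_bp
        for b in range(n_bins):
            bins.append((chrom, b * config.state_bin_bp,
                         min(length, (b + 1) * config.state_bin_bp)))
    n_bins_total = len(bins)
    for i in range(n):
        frac = float(rng.uniform(lo, hi))
        n_het = int(round(frac * n_bins_total))
        het_idx = rng.choice(n_bins_total, size=n_het, replace=False) if n_het else np.array([], dtype=int)
        peaks = []
        for bi in sorted(het_idx):
            chrom, s, e = bins[bi]
            center = (s + e) // 2
            peaks.append((chrom, max(0, center - 1000), center + 1000))
        profiles.append({
            "tissue": f"tissue{i + 1}",
            "het_fraction": frac,
            "het_bins": set(int(b) for b in het_idx),
            "bins": bins,
            "h3k9me3_peaks": peaks,
        })
    return profiles


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def generate_cohort(config: SimConfig) -> Cohort:
    """Simulate a multi-cancer-type cohort under the planted-modifier model."""
    rng = _stream(config.seed, "cohort")
    genome = dict(config.genome)
    min_len = min(genome.values())
    if min_len < 1000:
        raise ValueError("genome too small to place CNA segments")

    profiles = {p["tissue"]: p for p in _tissue_profiles(config)}
    mean_het = float(np.mean([p["het_fraction"] for p in profiles.values()])) or 1.0

    genes = config.genes
    gene_arr = np.asarray(genes, dtype=object)
    if config.length_weighted_mutations:
        glen = rng.lognormal(mean=7.0, sigma=1.0, size=len(genes))
        gene_w = glen / glen.sum()
    else:
        glen = np.full(len(genes), 500.0)
        gene_w = None
    gene_plen = {g: max(50, int(l)) for g, l in zip(genes, glen)}

    classes = list(_CLASS_P)
    class_p = np.asarray([_CLASS_P[c] for c in classes])

    sample_rows = []
    mut_rows = []
    seg_rows = []
    chrom_names = [c for c, _ in config.genome]
    chrom_lengths = np.asarray([l for _, l in config.genome], dtype=float)
    chrom_w = chrom_lengths / chrom_lengths.sum()

    modifier_set = set(config.modifier_genes)
    sid = 0
    per_type_samples: dict[str, list[str]] = {}
    sample_modifier_hits: dict[str, set[str]] = {}

    def _add_mutation(sample: str, gene: str, mut_class: str) -> None:
        depth = max(1, int(rng.poisson(60)))
        vaf = float(rng.beta(5, 7))
        alt = int(rng.binomial(depth, vaf))
        mut_rows.append((sample, gene, mut_class,
                         int(rng.integers(1, gene_plen[gene] + 1)),
                         depth - alt, alt))
        if mut_class != "silent" and gene in modifier_set:
            sample_modifier_hits[sample].add(gene)

    for ct in config.cancer_types:
        tissue = config.tissue_of(ct)
        per_type_samples[ct] = []
        for _ in range(config.samples_per_type):
            sample = f"s{sid:05d}"
            sid += 1
            per_type_samples[ct].append(sample)
            sample_modifier_hits[sample] = set()
            rate = float(rng.uniform(*config.mutation_rate_range))
            if rng.random() < config.hypermutator_fraction:
                rate *= 5.0
            m = int(rng.poisson(rate))
            if m:
                hit = rng.choice(len(genes), size=m, replace=True, p=gene_w)
                cls = rng.choice(len(classes), size=m, replace=True, p=class_p)
                for gi, ci in zip(hit, cls):
                    _add_mutation(sample, gene_arr[gi], classes[ci])
            if rng.random() < config.aneuploid_fraction:
                ploidy = float(rng.uniform(3.0, 4.2))
            else:
                ploidy = float(np.clip(rng.normal(2.0, 0.2), 1.5, 2.8))
            sample_rows.append([sample, ct, np.nan, 0, round(ploidy, 3)])

        # guarantee planted carriers per type
        for gene in config.modifier_genes:
            carriers = [s for s in per_type_samples[ct] if gene in sample_modifier_hits[s]]
            need = config.min_carriers_per_type - len(carriers)
            if need > 0:
                pool = [s for s in per_type_samples[ct] if gene not in sample_modifier_hits[s]]
                for sample in rng.choice(pool, size=need, replace=False):
                    _add_mutation(sample, gene, "missense")

    samples = pd.DataFrame(sample_rows, columns=["sample", "cancer_type", "time", "event", "ploidy"])

    # CNA counts and segments
    tissue_of = {row[0]: config.tissue_of(row[1]) for row in sample_rows}
    cna_counts = {}
    for sample in samples["sample"]:
        prof = profiles[tissue_of[sample]]
        k = len(sample_modifier_hits[sample])
        mu = (config.baseline_cna_mean
              * config.modifier_effect ** k
              * (prof["het_fraction"] / mean_het))
        r = config.cna_dispersion
        n_cna = int(rng.negative_binomial(r, r / (r + mu)))
        cna_counts[sample] = n_cna
        peaks_by_chrom: dict[str, np.ndarray] = {}
        if config.h3k9me3_length_factor != 1.0:
            for chrom in chrom_names:
                centers = np.asarray([(s + e) / 2 for c, s, e in prof["h3k9me3_peaks"]
                                      if c == chrom])
                peaks_by_chrom[chrom] = np.sort(centers)
        n_extra = int(rng.poisson(config.subthreshold_fraction * n_cna))
        for j in range(n_cna + n_extra):
            ci = int(rng.choice(len(chrom_names), p=chrom_w))
            chrom = chrom_names[ci]
            clen = int(chrom_lengths[ci])
            start = int(rng.integers(0, clen - 1000))
            length = float(rng.lognormal(config.cna_length_log_mean, config.cna_length_log_sd))
            if config.h3k9me3_length_factor != 1.0:
                centers = peaks_by_chrom[chrom]
                if centers.size:
                    i = int(np.searchsorted(centers, start))
                    near = min(
                        abs(start - centers[i - 1]) if i > 0 else np.inf,
                        abs(centers[i] - start) if i < centers.size else np.inf,
                    )
                    if near <= config.h3k9me3_window:
                        length *= config.h3k9me3_length_factor
            if j < n_cna:
                length = max(100.0, length)
                seg_value = float(rng.uniform(0.15, 1.0)) * (1 if rng.random() < 0.5 else -1)
            else:  # deliberately below the magnitude or length filter
                if rng.random() < 0.5:
                    seg_value = float(rng.uniform(-0.09, 0.09))
                    length = max(100.0, length)
                else:
                    seg_value = float(rng.uniform(0.15, 1.0))
                    length = float(rng.integers(1, 99))
            end = min(clen, start + max(1, int(length)))
            seg_rows.append([sample, chrom, start, end, round(seg_value, 4)])

    # survival: hazard rises across within-type CNA-count quartiles
    counts = pd.Series(cna_counts)
    times = np.empty(len(samples))
    events = np.empty(len(samples), dtype=int)
    base_h = np.log(2.0) / config.survival_median_time
    sample_idx = {s: i for i, s in enumerate(samples["sample"])}
    for ct in config.cancer_types:
        ids = per_type_samples[ct]
        vals = counts.loc[ids].to_numpy(float)
        q = np.quantile(vals, [0.25, 0.5, 0.75])
        for sample in ids:
            v = counts[sample]
            quart = int(np.searchsorted(q, v, side="right"))  # 0..3
            h = base_h * config.survival_hazard_ratio ** (quart / 3.0)
            t = float(rng.exponential(1.0 / h))
            idx = sample_idx[sample]
            if t > config.censor_time:
                times[idx], events[idx] = config.censor_time, 0
            else:
                times[idx], events[idx] = t, 1
    samples["time"] = np.round(times, 2)
    samples["event"] = events

    mutations = pd.DataFrame(mut_rows, columns=["sample", "gene", "mut_class",
                                                "protein_pos", "ref_count", "alt_count"])
    segments = pd.DataFrame(seg_rows, columns=["sample", "chrom", "start", "end", "seg_value"])
    return Cohort(samples=samples, mutations=mutations, cna_segments=segments,
                  genome=genome)


# ---------------------------------------------------------------------------
# PPI graph
# ---------------------------------------------------------------------------

def generate_ppi_graph(n_nodes: int, planted_module, seed: int,
                       node_names: list[str] | None = None,
                       module_edge_p: float = 0.3) -> nx.Graph:
    """Scale-free-ish PPI graph with a planted connected module.

    The base topology is Barabasi-Albert (heavy-tailed degrees); the planted
    module additionally receives a random spanning tree (guaranteeing
    connectivity of its induced subgraph) plus internal edges with probability
    ``module_edge_p``.
    """
    planted = list(planted_module)
    if len(planted) > n_nodes:
        raise ValueError("planted module larger than the graph")
    if node_names is None:
        node_names = [f"P{i:05d}" for i in range(n_nodes)]
    if len(node_names) != n_nodes:
        raise ValueError("node_names length must equal n_nodes")
    name_set = set(node_names)
    missing = [g for g in planted if g not in name_set]
    if missing:
        raise ValueError(f"planted module members not in node set: {missing[:5]}")

    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(7,)))
    base = nx.barabasi_albert_graph(n_nodes, m=3, seed=int(rng.integers(2**31)))
    g = nx.relabel_nodes(base, dict(zip(range(n_nodes), node_names)))

    if planted:
        order = list(rng.permutation(planted))
        for a, b in zip(order[:-1], order[1:]):  # spanning tree (path in random order)
            g.add_edge(a, b)
        for i in range(len(planted)):
            for j in range(i + 1, len(planted)):
                if rng.random() < module_edge_p:
                    g.add_edge(planted[i], planted[j])
    g.remove_edges_from(nx.selfloop_edges(g))
    return g


# ---------------------------------------------------------------------------
# epigenomes
# ---------------------------------------------------------------------------

def _states_from_het_bins(config: SimConfig, het_bins: set[int],
                          bins: list[tuple[str, int, int]],
                          rng: np.random.Generator) -> pd.DataFrame:
    other = [s for s in STATE18_LABELS if s != HET_STATE]
    rows = []
    for i, (chrom, s, e) in enumerate(bins):
        if i in het_bins:
            state = HET_STATE
        else:
            state = other[int(rng.integers(len(other)))]
        rows.append([chrom, s, e, state])
    # guarantee the full 18-label alphabet (when the genome has room):
    # place each missing state in a bin whose current state is duplicated
    from collections import Counter
    non_het = [i for i in range(len(bins)) if i not in het_bins]
    tally = Counter(rows[i][3] for i in non_het)
    missing = [s for s in other if tally[s] == 0]
    for state in missing:
        slot = next((i for i in non_het if tally[rows[i][3]] > 1), None)
        if slot is None:
            break
        tally[rows[slot][3]] -= 1
        rows[slot][3] = state
        tally[state] += 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])


def generate_epigenomes(config: SimConfig, tissues: int) -> list[EpigenomeTrack]:
    """Per-tissue 18-state segmentations with controlled heterochromatin fraction.

    H3K9me3 peaks are placed inside the Het bins; the other marks receive
    uniformly placed background peaks.
    """
    if tissues < 2:
        raise ValueError("need at least 2 tissues")
    rng = _stream(config.seed, "epigenomes")
    genome = dict(config.genome)
    tracks = []
    for prof in _tissue_profiles(config, n_tissues=tissues):
        states = _states_from_het_bins(config, prof["het_bins"], prof["bins"], rng)
        peaks = {"H3K9me3": pd.DataFrame(prof["h3k9me3_peaks"],
                                         columns=["chrom", "start", "end"])}
        for mark in _MARKS[1:]:
            rows = []
            for chrom, length in config.genome:
                n = max(1, length // 2_000_000)
                starts = rng.integers(0, length - 2000, size=n)
                for s in starts:
                    rows.append([chrom, int(s), int(s) + 1500])
            peaks[mark] = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        tracks.append(EpigenomeTrack(tissue=prof["tissue"], states=states,
                                     peaks=peaks, genome=genome))
    return tracks


def generate_expression(config: SimConfig, tracks: list[EpigenomeTrack],
                        n_genes: int = 200, n_coupled: int = 20,
                        coupling: float = 1.0, noise_sd: float = 0.1) -> pd.DataFrame:
    """Expression matrix (genes x tissues); the first ``n_coupled`` genes track
    the tissue heterochromatin fraction linearly (slope ``coupling``)."""
    rng = _stream(config.seed, "expression")
    het = np.asarray([t.heterochromatin_fraction() for t in tracks])
    names = [f"EXPR{i:04d}" for i in range(n_genes)]
    mat = rng.normal(5.0, 1.0, size=(n_genes, len(tracks)))
    for i in range(min(n_coupled, n_genes)):
        sign = 1.0 if i % 2 == 0 else -1.0
        mat[i] = 5.0 + sign * coupling * 10.0 * het + rng.normal(0, noise_sd, size=len(tracks))
    return pd.DataFrame(mat, index=names, columns=[t.tissue for t in tracks])


# ---------------------------------------------------------------------------
# recurrent-region / breakpoint panel
# ---------------------------------------------------------------------------

@dataclass
class BreakpointPanel:
    """Synthetic inputs for the breakpoint-epigenome analyses."""

    regions: pd.DataFrame            # cancer_type, region_id, chrom, start, end, q
    centromeres: dict[str, tuple[int, int]]
    telomeres: dict[str, list[tuple[int, int]]]
    type_tissue_map: dict[str, str]
    tracks: list[EpigenomeTrack]


def simulate_breakpoint_panel(config: SimConfig, n_tissues: int = 5,
                              regions_per_type: int = 40,
                              assoc_het_prob: float = 0.0,
                              nonassoc_het_prob: float = 0.0,
                              h3k9me3_peak_prob: float = 0.3,
                              shared_region_count: int = 2) -> BreakpointPanel:
    """Recurrent CNA regions with tissue associations plus matched epigenomes.

    ``assoc_het_prob`` / ``nonassoc_het_prob`` control how often the state bin
    under a breakpoint is forced to Het in associated / non-associated tissues
    (both 0 = exchangeable null).  ``h3k9me3_peak_prob`` is the probability
    that a region start gets an H3K9me3 peak nearby in its associated tissue,
    in which case the region length is multiplied by
    ``config.h3k9me3_length_factor``.
    """
    rng = _stream(config.seed, "breakpoint_panel")
    genome = dict(config.genome)
    chroms = list(genome)
    types = [f"ct{i + 1}" for i in range(n_tissues)]
    tissues = [f"tissue{i + 1}" for i in range(n_tissues)]
    type_tissue = dict(zip(types, tissues))

    centromeres = {}
    telomeres = {}
    for chrom, length in genome.items():
        mid = length // 2
        centromeres[chrom] = (mid - 500_000, mid + 500_000)
        telomeres[chrom] = [(0, 10_000), (length - 10_000, length)]

    rows = []
    rid = 0
    planted_peaks: dict[str, list[tuple[str, int, int]]] = {t: [] for t in tissues}

    def _draw_region(ct: str) -> None:
        nonlocal rid
        chrom = chroms[int(rng.integers(len(chroms)))]
        clen = genome[chrom]
        start = int(rng.integers(20_000, clen - 10_000_000))
        length = float(rng.lognormal(14.5, 0.6))  # ~2 Mb median
        near_peak = rng.random() < h3k9me3_peak_prob
        if near_peak:
            length *= config.h3k9me3_length_factor
            tissue = type_tissue[ct]
            peak_start = max(0, start + int(rng.integers(-4000, 3000)))
            planted_peaks[tissue].append((chrom, peak_start, peak_start + 1500))
        end = min(clen - 11_000, start + max(10_000, int(length)))
        q = float(rng.uniform(0, 0.1)) if rng.random() < 0.8 else float(rng.uniform(0.1, 0.5))
        rows.append([ct, f"r{rid:04d}", chrom, start, end, round(q, 5)])
        rid += 1

    for ct in types:
        for _ in range(regions_per_type):
            _draw_region(ct)
    # a few regions shared by >3 types to exercise the tissue-count exclusion
    for _ in range(shared_region_count):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(20_000, genome[chrom] - 10_000_000))
        end = start + 2_000_000
        for ct in types[:4]:
            rows.append([ct, f"r{rid:04d}", chrom, start, end, 0.01])
            rid += 1

    regions = pd.DataFrame(rows, columns=["cancer_type", "region_id", "chrom",
                                          "start", "end", "q"])

    # epigenome tracks with planted Het enrichment at associated breakpoints
    bin_bp = config.state_bin_bp
    bins = []
    for chrom, length in genome.items():
        for b in range(length // bin_bp):
            bins.append((chrom, b * bin_bp, min(length, (b + 1) * bin_bp)))
    bin_lookup = {(chrom, s // bin_bp): i for i, (chrom, s, e) in enumerate(bins)}

    breakpoints_by_type: dict[str, list[tuple[str, int]]] = {}
    for _, r in regions.iterrows():
        if r["q"] < 0.1:
            breakpoints_by_type.setdefault(r["cancer_type"], []).extend(
                [(r["chrom"], int(r["start"])), (r["chrom"], int(r["end"]))])

    tracks = []
    lo, hi = config.het_fraction_range
    for ct, tissue in type_tissue.items():
        frac = float(rng.uniform(lo, hi))
        n_het = int(round(frac * len(bins)))
        het_bins = set(int(b) for b in rng.choice(len(bins), size=n_het, replace=False))
        for other_ct, bps in breakpoints_by_type.items():
            p = assoc_het_prob if other_ct == ct else nonassoc_het_prob
            if p <= 0:
                continue
            for chrom, pos in bps:
                bi = bin_lookup.get((chrom, pos // bin_bp))
                if bi is not None and rng.random() < p:
                    het_bins.add(bi)
        states = _states_from_het_bins(config, het_bins, bins, rng)
        peak_rows = list(planted_peaks[tissue])
        for bi in sorted(het_bins):
            chrom, s, e = bins[bi]
            c = (s + e) // 2
            peak_rows.append((chrom, max(0, c - 1000), c + 1000))
        peaks = {"H3K9me3": pd.DataFrame(peak_rows, columns=["chrom", "start", "end"])}
        for mark in _MARKS[1:]:
            extra = []
            for chrom, length in genome.items():
                for s in rng.integers(0, length - 2000, size=max(1, length // 2_000_000)):
                    extra.append([chrom, int(s), int(s) + 1500])
            peaks[mark] = pd.DataFrame(extra, columns=["chrom", "start", "end"])
        tracks.append(EpigenomeTrack(tissue=tissue, states=states, peaks=peaks,
                                     genome=genome))
    return BreakpointPanel(regions=regions, centromeres=centromeres,
                           telomeres=telomeres, type_tissue_map=type_tissue,
                           tracks=tracks)
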