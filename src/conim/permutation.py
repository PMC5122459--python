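"""Margin-preserving permutation of the binary gene x sample mutation matrix.

The null ensemble fixes both margins: every gene keeps its number of mutated
samples and every sample keeps its number of mutated genes.  Sampling uses the
curveball algorithm (repeated random trades of the symmetric difference of two
rows), which leaves both margin vectors invariant by construction and whose
stationary distribution is uniform over the margin-fixed ensemble.  Cells that
are forced by the margins (all-ones rows or columns) can never move.

:func:`permutation_gene_test` is the permutation-based detection pipeline: the
test statistic is the absolute difference in mean CNA number between mutated
and non-mutated samples, permutations run per cancer type, and the empirical
p-value uses the add-one correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort
from .stats import bh_fdr

__all__ = ["MutationMatrix", "build_mutation_matrix", "permute_matrix",
           "CurveballSampler", "permutation_gene_test"]

BURN_IN_SWEEPS = 5
THIN_SWEEPS = 1


@dataclass
class MutationMatrix:
    """Binary incidence matrix (genes x samples) with named margins."""

    matrix: np.ndarray
    genes: list[str]
    samples: list[str]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if not np.isin(m, (0, 1)).all():
            raise ValueError("matrix entries must be 0/1")
        self.matrix = m.astype(np.int8)

    @property
    def row_sums(self) -> np.ndarray:
        return self.matrix.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.matrix.sum(axis=0)


def build_mutation_matrix(cohort: Cohort, genes, samples) -> MutationMatrix:
    """Non-silent mutation incidence for the given genes x samples."""
    genes = list(genes)
    samples = list(samples)
    gi = {g: i for i, g in enumerate(genes)}
    si = {s: i for i, s in enumerate(samples)}
    m = np.zeros((len(genes), len(samples)), dtype=np.int8)
    mut = cohort.nonsilent_mutations()
    for row in mut.itertuples(index=False):
        i, j = gi.get(row.gene), si.get(row.sample)
        if i is not None and j is not None:
            m[i, j] = 1
    return MutationMatrix(m, genes, samples)


class CurveballSampler:
    """Iterated curveball trades over one binary matrix.

    One *sweep* performs ``n_rows`` random pair trades.  ``matrix()``
    materialises the current state; margins are invariant across any number of
    sweeps.  Trades use a plain :mod:`random` generator (seeded from the numpy
    RNG) — its shuffle of small index lists is several times faster than the
    numpy equivalent, which dominates the permutation-pipeline runtime.
    """

    def __init__(self, matrix: np.ndarray, rng: np.random.Generator):
        self.n_rows, self.n_cols = matrix.shape
        self.rows = [set(np.flatnonzero(matrix[i]).tolist()) for i in range(self.n_rows)]
        self.rng = rng

    def sweep(self, n_sweeps: int = 1) -> None:
        if self.n_rows < 2:
            return
        n_trades = n_sweeps * self.n_rows
        rng = self.rng
        rows = self.rows
        pairs = rng.integers(0, self.n_rows, size=(n_trades, 2))
        # one bulk block of uniforms; each trade consumes len(pool) keys and
        # keeps the k smallest-keyed pool members for the first row (a uniform
        # k-subset, equivalent to shuffling the pool)
        keys = rng.random(n_trades * 8)
        cursor = 0
        argpartition = np.argpartition
        for a, b in pairs:
            if a == b:
                continue
            r1, r2 = rows[a], rows[b]
            inter = r1 & r2
            u1 = r1 - inter
            u2 = r2 - inter
            if not u1 or not u2:
                continue
            pool = list(u1)
            pool += u2
            m = len(pool)
            k = len(u1)
            if cursor + m > keys.size:
                keys = rng.random(max(n_trades * 8, m))
                cursor = 0
            kv = keys[cursor:cursor + m]
            cursor += m
            idx = argpartition(kv, k - 1)
            pick = {pool[i] for i in idx[:k]}
            rows[a] = inter | pick
            rows[b] = inter | {pool[i] for i in idx[k:]}

    def matrix(self, out: np.ndarray | None = None) -> np.ndarray:
        if out is None:
            out = np.zeros((self.n_rows, self.n_cols), dtype=np.int8)
        else:
            out.fill(0)
        for i, row in enumerate(self.rows):
            if row:
                out[i, list(row)] = 1
        return out


from numba import njit


@njit(cache=False)
def _curveball_chain(rows, lens, c, inc, mut_cnt, tot_sum, tot_n, obs_stat,
                     n_perm, sweeps_per_draw, burn_sweeps, seed, n_blocks,
                     n_genes):  # pragma: no cover - exercised via wrapper
    """Curveball chain over ``n_blocks`` stacked gene x sample incidence
    matrices (rows sorted, padded), recording the pooled burden statistic.

    Row r = block * n_genes + gene holds the (global) column indices of the
    mutated samples; row lengths (the margins) never change.  Returns the
    per-gene count of permutation statistics >= the observed statistic.
    """
    np.random.seed(seed)
    n_rows = rows.shape[0]
    cap = rows.shape[1]
    common = np.empty(cap, dtype=np.int64)
    pool = np.empty(2 * cap, dtype=np.int64)
    sums = np.zeros(n_rows)
    for r in range(n_rows):
        s = 0.0
        for j in range(lens[r]):
            s += c[rows[r, j]]
        sums[r] = s
    exceed = np.zeros(n_genes)

    total_sweeps = burn_sweeps + n_perm * sweeps_per_draw
    draw_done = 0
    for sweep_i in range(total_sweeps):
        for block in range(n_blocks):
            base = block * n_genes
            for _ in range(n_genes):
                a = base + np.random.randint(0, n_genes)
                b = base + np.random.randint(0, n_genes)
                if a == b:
                    continue
                la = lens[a]
                lb = lens[b]
                if la == 0 or lb == 0:
                    continue
                i = 0
                j = 0
                nc = 0
                npool = 0
                while i < la and j < lb:
                    x = rows[a, i]
                    y = rows[b, j]
                    if x == y:
                        common[nc] = x
                        nc += 1
                        i += 1
                        j += 1
                    elif x < y:
                        pool[npool] = x
                        npool += 1
                        i += 1
                    else:
                        pool[npool] = y
                        npool += 1
                        j += 1
                while i < la:
                    pool[npool] = rows[a, i]
                    npool += 1
                    i += 1
                while j < lb:
                    pool[npool] = rows[b, j]
                    npool += 1
                    j += 1
                ka = la - nc
                if ka == 0 or ka == npool:
                    continue  # one row's unique part is empty: forced cells
                # uniform ka-subset of the pool via partial Fisher-Yates
                for t in range(ka):
                    rpos = t + np.random.randint(0, npool - t)
                    tmp = pool[t]
                    pool[t] = pool[rpos]
                    pool[rpos] = tmp
                for t in range(nc):
                    rows[a, t] = common[t]
                    rows[b, t] = common[t]
                for t in range(ka):
                    rows[a, nc + t] = pool[t]
                for t in range(npool - ka):
                    rows[b, nc + t] = pool[ka + t]
                rows[a, :la].sort()
                rows[b, :lb].sort()
                sa = 0.0
                for t in range(la):
                    sa += c[rows[a, t]]
                sums[a] = sa
                sb = 0.0
                for t in range(lb):
                    sb += c[rows[b, t]]
                sums[b] = sb
        if sweep_i >= burn_sweeps:
            phase = sweep_i - burn_sweeps + 1
            if phase % sweeps_per_draw == 0 and draw_done < n_perm:
                draw_done += 1
                for g in range(n_genes):
                    if mut_cnt[g] <= 0.0 or tot_n[g] - mut_cnt[g] <= 0.0:
                        continue
                    ms = 0.0
                    for block in range(n_blocks):
                        if inc[block, g]:
                            ms += sums[block * n_genes + g]
                    stat = abs(ms / mut_cnt[g]
                               - (tot_sum[g] - ms) / (tot_n[g] - mut_cnt[g]))
                    if stat >= obs_stat[g] - 1e-12:
                        exceed[g] += 1.0
    return exceed


def permute_matrix(matrix: MutationMatrix, seed: int,
                   n_sweeps: int = BURN_IN_SWEEPS + 5) -> MutationMatrix:
    """One margin-preserving permutation of ``matrix`` (both margins exact)."""
    rng = np.random.default_rng(seed)
    sampler = CurveballSampler(matrix.matrix, rng)
    sampler.sweep(n_sweeps)
    return MutationMatrix(sampler.matrix(), list(matrix.genes), list(matrix.samples))


def permutation_gene_test(cohort: Cohort, burdens: pd.DataFrame,
                          n_perm: int = 1000, seed: int = 0,
                          thresholds=None, add_one: bool = False) -> pd.DataFrame:
    """Permutation-null burden association test.

    Genes require >= 60 non-silent mutations overall; for each gene only
    cancer types with >= 5 non-silently mutated samples contribute.  The test
    statistic is |mean CNA number (mutated) - mean CNA number (non-mutated)|
    over the pooled included samples; the margin-fixed permutations run within
    each cancer type.

    By default the empirical p-value is the plain fraction of permutations
    reaching the observed statistic, which can be exactly 0 (a gene never
    matched in ``n_perm`` draws) and lets BH-corrected q-values reach the
    detection cutoff at moderate ``n_perm``.  ``add_one=True`` switches to the
    conservative (1 + k) / (1 + n) estimate, which is strictly positive and
    super-uniform under the null.
    """
    from .detection import Thresholds, _gene_universe

    if thresholds is None:
        thresholds = Thresholds()
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives coarse p-value resolution")

    genes = _gene_universe(cohort, thresholds.min_gene_mutations)
    if not genes:
        warnings.warn("no gene passes the mutation-count filter")
        return pd.DataFrame(columns=["gene", "n_mut_samples", "statistic", "p", "q",
                                     "direction"])
    b = burdens.set_index("sample")
    cna = b["n_cna"].astype(float)
    # at least ~16 trades between recorded draws so that consecutive draws
    # decorrelate even on very small matrices (one sweep = n_rows trades)
    thin = max(THIN_SWEEPS, -(-16 // max(1, len(genes))))
    burn = max(BURN_IN_SWEEPS, 4 * thin)

    types = sorted(b["cancer_type"].unique())
    matrices, cvecs, incs = [], [], []
    for ct in types:
        t_samples = sorted(b.index[b["cancer_type"] == ct])
        mm = build_mutation_matrix(cohort, genes, t_samples)
        matrices.append(mm.matrix.astype(np.float64))
        cvecs.append(cna.loc[t_samples].to_numpy(np.float64))
        incs.append(mm.row_sums >= thresholds.min_mut_samples)

    n_genes = len(genes)
    n_blocks = len(types)
    inc_any = np.zeros(n_genes, dtype=bool)
    mut_cnt = np.zeros(n_genes)
    tot_sum = np.zeros(n_genes)
    tot_n = np.zeros(n_genes)
    for mm_f, c, inc in zip(matrices, cvecs, incs):
        inc_any |= inc
        mut_cnt += inc * mm_f.sum(axis=1)
        tot_sum += inc * c.sum()
        tot_n += inc * len(c)
    valid = inc_any & (mut_cnt > 0) & (tot_n - mut_cnt > 0)

    mut_sum_obs = np.zeros(n_genes)
    for mm_f, c, inc in zip(matrices, cvecs, incs):
        mut_sum_obs += inc * (mm_f @ c)
    with np.errstate(invalid="ignore", divide="ignore"):
        obs_diff = mut_sum_obs / mut_cnt - (tot_sum - mut_sum_obs) / (tot_n - mut_cnt)
    obs_stat = np.abs(obs_diff)

    # stacked, padded, sorted row representation with global column indices
    c_all = np.concatenate(cvecs)
    offsets = np.cumsum([0] + [len(c) for c in cvecs[:-1]])
    cap = 1
    for m in matrices:
        cap = max(cap, int(m.sum(axis=1).max()))
    rows = np.zeros((n_blocks * n_genes, cap), dtype=np.int64)
    lens = np.zeros(n_blocks * n_genes, dtype=np.int64)
    for blk, (m, off) in enumerate(zip(matrices, offsets)):
        for g in range(n_genes):
            cols = np.flatnonzero(m[g]) + off
            lens[blk * n_genes + g] = len(cols)
            rows[blk * n_genes + g, :len(cols)] = cols
    inc_mat = np.zeros((n_blocks, n_genes), dtype=np.bool_)
    for blk, inc in enumerate(incs):
        inc_mat[blk] = inc

    exceed = _curveball_chain(
        rows, lens, c_all, inc_mat, mut_cnt, tot_sum, tot_n,
        np.where(np.isnan(obs_stat), np.inf, obs_stat),
        n_perm, thin, burn, int(seed) % (2**31), n_blocks, n_genes)

    if add_one:
        p = (1.0 + exceed) / (1.0 + n_perm)
    else:
        p = exceed / n_perm
    out = pd.DataFrame({
        "gene": genes,
        "n_mut_samples": mut_cnt.astype(int),
        "statistic": obs_stat,
        "p": p,
        "direction": np.where(obs_diff < 0, "fewer", "more"),
    })
    out = out[valid].reset_index(drop=True)
    out["q"] = bh_fdr(out["p"])
    out["pipeline"] = "permutation"
    return out
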