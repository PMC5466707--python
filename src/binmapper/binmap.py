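"""Recombination bin maps and genetic linkage maps.

Population breakpoints are aligned along each chromosome on a 20-kb grid;
adjacent intervals whose genotype column is identical across every RIL merge
into a single recombination bin.  Bins then act as genetic markers: adjacent
recombination fractions are converted to centimorgans with Kosambi's map
function d = 25 ln((1+2r)/(1-2r)), linkage groups come from single-linkage
clustering, and within-group order from a minimum-spanning-tree path seeded
by physical order.  Bins whose linkage disagrees with their physical
neighbourhood are flagged for repositioning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import minimum_spanning_tree

from .codes import A, B, H, NOCALL

logger = logging.getLogger(__name__)

MIN_INFORMATIVE_PAIRS = 10
R_CAP = 0.4999


# ---------------------------------------------------------------------------
# Bin construction


@dataclass
class BinSet:
    """A recombination bin map: intervals plus the bins-x-RILs genotype matrix."""

    bins: pd.DataFrame        # bin_id, chrom, start, end (0-based half-open)
    genotypes: np.ndarray     # (n_bins, n_rils) int8 call codes

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def n_rils(self) -> int:
        return self.genotypes.shape[1]

    def lengths(self) -> np.ndarray:
        return (self.bins["end"] - self.bins["start"]).to_numpy()


def snap_to_grid(pos: np.ndarray, grid: int = 20_000) -> np.ndarray:
    """Snap breakpoint coordinates down to the enclosing grid cell start."""
    return (np.asarray(pos, dtype=np.int64) // grid) * grid


def _column_consensus(calls: np.ndarray) -> np.ndarray:
    """Per-RIL consensus of the SNP calls inside one interval.

    Majority over a/b/h; an interval with no called SNP, or with a tied
    majority, yields no call.
    """
    n_rils = calls.shape[0]
    out = np.full(n_rils, NOCALL, dtype=np.int8)
    if calls.shape[1] == 0:
        return out
    counts = np.stack([(calls == s).sum(axis=1) for s in (A, B, H)], axis=1)
    top = counts.max(axis=1)
    winner = counts.argmax(axis=1) + 1
    tied = (counts == top[:, None]).sum(axis=1) > 1
    ok = (top > 0) & ~tied
    out[ok] = winner[ok].astype(np.int8)
    return out


def build_bins(breakpoints: pd.DataFrame, tracks: np.ndarray, snps: pd.DataFrame,
               chrom_lengths: Dict[str, int], min_interval: int = 20_000) -> BinSet:
    """Partition each chromosome at snapped breakpoint midpoints and merge.

    Breakpoint midpoints from all RILs are snapped to the min_interval grid;
    the resulting intervals take their genotype column from the tracks and
    adjacent intervals with identical columns merge into one bin.  Nearly
    identical adjacent bins (differing only by no-call symbols) are logged.
    """
    n_rils = tracks.shape[0]
    rows = []
    cols = []
    bin_id = 0
    for chrom, L in chrom_lengths.items():
        bp = breakpoints.loc[breakpoints["chrom"] == chrom, "midpoint"].to_numpy()
        if np.any((bp < 0) | (bp >= L)):
            raise ValueError(f"breakpoint outside chromosome {chrom}")
        cuts = np.unique(snap_to_grid(bp, min_interval))
        cuts = cuts[(cuts > 0) & (cuts < L)]
        edges = np.concatenate([[0], cuts, [L]]).astype(np.int64)
        grp = snps[snps["chrom"] == chrom]
        snp_cols = grp.index.to_numpy()
        snp_pos0 = grp["pos"].to_numpy() - 1  # 0-based base index
        prev_col: Optional[np.ndarray] = None
        prev_row = None
        for s, e in zip(edges[:-1], edges[1:]):
            in_iv = snp_cols[(snp_pos0 >= s) & (snp_pos0 < e)]
            col = _column_consensus(tracks[:, in_iv])
            if prev_col is not None and np.array_equal(col, prev_col):
                prev_row[3] = int(e)  # extend the previous bin
                continue
            if prev_col is not None:
                informative = (col != NOCALL) & (prev_col != NOCALL)
                if informative.any() and np.array_equal(col[informative], prev_col[informative]):
                    logger.info("near-identical adjacent bins at %s:%d (differ only "
                                "in no-call symbols)", chrom, int(s))
            prev_row = [bin_id, chrom, int(s), int(e)]
            rows.append(prev_row)
            cols.append(col)
            prev_col = col
            bin_id += 1
    bins = pd.DataFrame(rows, columns=["bin_id", "chrom", "start", "end"])
    genotypes = np.vstack(cols) if cols else np.empty((0, n_rils), dtype=np.int8)
    return BinSet(bins=bins, genotypes=genotypes)


def bins_from_segments(truth, min_interval: int = 20_000) -> BinSet:
    """Bin map straight from simulator truth (no observation noise).

    Segment boundaries play the role of breakpoint midpoints; the genotype
    column is the true origin at the bin midpoint.  Used for recovery tests
    and noise-free scans.
    """
    bp = truth.breakpoints().rename(columns={"pos": "midpoint"})
    rows, cols = [], []
    bin_id = 0
    for chrom, L in truth.chrom_lengths.items():
        mids = bp.loc[bp["chrom"] == chrom, "midpoint"].to_numpy()
        cuts = np.unique(snap_to_grid(mids, min_interval))
        cuts = cuts[(cuts > 0) & (cuts < L)]
        edges = np.concatenate([[0], cuts, [L]]).astype(np.int64)
        centers = (edges[:-1] + edges[1:]) // 2 + 1  # 1-based midpoints
        geno = truth.genotype_at(chrom, centers)  # origin codes match call codes
        prev_col = None
        prev_row = None
        for k, (s, e) in enumerate(zip(edges[:-1], edges[1:])):
            col = geno[:, k].astype(np.int8)
            if prev_col is not None and np.array_equal(col, prev_col):
                prev_row[3] = int(e)
                continue
            prev_row = [bin_id, chrom, int(s), int(e)]
            rows.append(prev_row)
            cols.append(col)
            prev_col = col
            bin_id += 1
    bins = pd.DataFrame(rows, columns=["bin_id", "chrom", "start", "end"])
    return BinSet(bins=bins, genotypes=np.vstack(cols))


# ---------------------------------------------------------------------------
# Recombination fractions and map distances


def pairwise_r(col1: np.ndarray, col2: np.ndarray,
               min_informative: int = MIN_INFORMATIVE_PAIRS) -> float:
    """Recombination fraction between two genotype columns.

    Discordant a/b fraction among RILs informative (homozygous call) in both
    columns; het and no-call entries are excluded.  Returns NaN when fewer
    than min_informative RILs are jointly informative.
    """
    col1 = np.asarray(col1)
    col2 = np.asarray(col2)
    if col1.shape != col2.shape:
        raise ValueError("genotype columns differ in length")
    inf = np.isin(col1, (A, B)) & np.isin(col2, (A, B))
    n = int(inf.sum())
    if n < min_informative:
        logger.info("pairwise_r: only %d informative pairs, skipping", n)
        return float("nan")
    r = float(np.mean(col1[inf] != col2[inf]))
    return min(r, R_CAP)


def pairwise_r_matrix(genotypes: np.ndarray,
                      min_informative: int = MIN_INFORMATIVE_PAIRS) -> np.ndarray:
    """All-pairs recombination fractions (NaN where data are insufficient)."""
    is_a = (genotypes == A).astype(np.float64)
    is_b = (genotypes == B).astype(np.float64)
    inf = is_a + is_b
    n_inf = inf @ inf.T
    discord = is_a @ is_b.T + is_b @ is_a.T
    with np.errstate(invalid="ignore", divide="ignore"):
        r = discord / n_inf
    r[n_inf < min_informative] = np.nan
    return np.minimum(r, R_CAP)


def kosambi_cM(r) -> np.ndarray | float:
    """Kosambi map distance d = 25 ln((1+2r)/(1-2r)) in centimorgans."""
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < 0) or np.any(r_arr >= 0.5):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = 25.0 * np.log((1 + 2 * r_arr) / (1 - 2 * r_arr))
    return float(d) if np.isscalar(r) or r_arr.ndim == 0 else d


def kosambi_r(d) -> np.ndarray | float:
    """Inverse Kosambi: r = tanh(d/50) / 2."""
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr < 0):
        raise ValueError("map distance must be >= 0")
    r = 0.5 * np.tanh(d_arr / 50.0)
    return float(r) if np.isscalar(d) or d_arr.ndim == 0 else r


def ril_correct(R) -> np.ndarray | float:
    """Selfing-RIL map-expansion correction: per-meiosis r = R / (2 - 2R)."""
    R_arr = np.asarray(R, dtype=float)
    return R_arr / (2.0 - 2.0 * R_arr)


# ---------------------------------------------------------------------------
# Linkage map


@dataclass
class LinkageMap:
    """Ordered linkage groups with adjacent r and cumulative centimorgans."""

    table: pd.DataFrame  # group, order, bin_id, r_adjacent, cM_adjacent, cM_cumulative

    @property
    def n_groups(self) -> int:
        return self.table["group"].nunique()

    def total_cM(self) -> float:
        return float(self.table.groupby("group")["cM_cumulative"].max().sum())

    def group_of(self, bin_id: int) -> int:
        return int(self.table.loc[self.table["bin_id"] == bin_id, "group"].iloc[0])


def _linkage_groups(r: np.ndarray, link_threshold: float) -> List[List[int]]:
    """Single-linkage components of the graph {r < link_threshold}."""
    n = r.shape[0]
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    ii, jj = np.nonzero(np.nan_to_num(r, nan=1.0) < link_threshold)
    for i, j in zip(ii, jj):
        if i < j:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
    groups: Dict[int, List[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted(groups.values(), key=lambda g: min(g))


def _order_group(members: List[int], r: np.ndarray, phys_rank: np.ndarray) -> List[int]:
    """Order one linkage group along an MST path, seeded by physical order."""
    if len(members) <= 2:
        return sorted(members, key=lambda i: phys_rank[i])
    sub = r[np.ix_(members, members)]
    w = np.nan_to_num(sub, nan=1.0) + 1e-9  # keep zero-r edges in the graph
    mst = minimum_spanning_tree(csr_matrix(w)).toarray()
    adj = (mst > 0) | (mst.T > 0)
    deg = adj.sum(axis=1)
    leaves = np.flatnonzero(deg == 1)
    if leaves.size:
        start = min(leaves, key=lambda i: phys_rank[members[i]])
    else:
        start = int(np.argmin([phys_rank[m] for m in members]))
    # depth-first walk, nearest (smallest r) neighbour first
    order = []
    seen = np.zeros(len(members), dtype=bool)
    stack = [int(start)]
    while stack:
        node = stack.pop()
        if seen[node]:
            continue
        seen[node] = True
        order.append(node)
        nbrs = np.flatnonzero(adj[node] & ~seen)
        stack.extend(sorted(nbrs.tolist(), key=lambda j: -w[node, j]))
    order.extend(np.flatnonzero(~seen).tolist())
    ordered = [members[i] for i in order]
    if phys_rank[ordered[0]] > phys_rank[ordered[-1]]:
        ordered.reverse()
    return ordered


def construct_linkage_map(binset: BinSet, link_threshold: float = 0.25,
                          apply_ril_correction: bool = False,
                          r: Optional[np.ndarray] = None) -> LinkageMap:
    """Group, order and space the bins into a genetic linkage map.

    Groups are single-linkage clusters at r < link_threshold (unlinked bins
    become singleton groups, with a warning); order within a group follows an
    MST path seeded by physical order; adjacent distances apply Kosambi to
    the observed RIL recombination fraction (optionally corrected for RIL
    map expansion first).
    """
    if binset.n_bins < 2:
        raise ValueError("need at least two bins to build a map")
    if r is None:
        r = pairwise_r_matrix(binset.genotypes)
    chrom_order = {c: k for k, c in enumerate(binset.bins["chrom"].unique())}
    chrom_idx = binset.bins["chrom"].map(chrom_order).to_numpy()
    starts = binset.bins["start"].to_numpy()
    lex = np.lexsort((starts, chrom_idx))
    phys_rank = np.empty(len(lex), dtype=np.int64)
    phys_rank[lex] = np.arange(len(lex))
    groups = _linkage_groups(r, link_threshold)
    rows = []
    for gid, members in enumerate(groups):
        if len(members) == 1:
            logger.warning("bin %d is unlinked to every other bin; singleton group",
                           binset.bins["bin_id"].iloc[members[0]])
        ordered = _order_group(members, r, phys_rank)
        cum = 0.0
        prev = None
        for k, idx in enumerate(ordered):
            if prev is None:
                r_adj, d = np.nan, 0.0
            else:
                r_adj = r[prev, idx]
                rr = r_adj if not np.isnan(r_adj) else 0.0
                if apply_ril_correction:
                    rr = float(ril_correct(rr))
                d = float(kosambi_cM(min(rr, R_CAP)))
            cum += d
            rows.append((gid, k, int(binset.bins["bin_id"].iloc[idx]),
                         float(r_adj), d, cum))
            prev = idx
    table = pd.DataFrame(rows, columns=["group", "order", "bin_id", "r_adjacent",
                                        "cM_adjacent", "cM_cumulative"])
    return LinkageMap(table=table)


# ---------------------------------------------------------------------------
# Abnormal linkage


def flag_misplaced_bins(binset: BinSet, r: Optional[np.ndarray] = None,
                        neighbor_r: float = 0.15, partner_r: float = 0.05,
                        min_informative: int = MIN_INFORMATIVE_PAIRS) -> pd.DataFrame:
    """Flag bins whose linkage disagrees with their physical neighbourhood.

    A bin is flagged when its recombination fraction with both physical
    neighbours exceeds neighbor_r while some non-neighbour bin shows
    r < partner_r; the proposed new position is adjacent to that minimum-r
    partner.
    """
    if r is None:
        r = pairwise_r_matrix(binset.genotypes, min_informative)
    bins = binset.bins.reset_index(drop=True)
    rows = []
    for chrom, grp in bins.groupby("chrom", sort=False):
        idx = grp.sort_values("start").index.to_numpy()
        for k, i in enumerate(idx):
            nbrs = []
            if k > 0:
                nbrs.append(idx[k - 1])
            if k < len(idx) - 1:
                nbrs.append(idx[k + 1])
            if not nbrs:
                continue
            nbr_r = [r[i, j] for j in nbrs]
            if not all(np.isnan(v) or v > neighbor_r for v in nbr_r):
                continue
            if all(np.isnan(v) for v in nbr_r):
                continue
            others = np.setdiff1d(np.arange(len(bins)), np.array(nbrs + [i]))
            if others.size == 0:
                continue
            rv = r[i, others]
            if np.all(np.isnan(rv)):
                continue
            best = others[np.nanargmin(rv)]
            best_r = r[i, best]
            if best_r < partner_r:
                rows.append({
                    "bin_id": int(bins["bin_id"].iloc[i]),
                    "chrom": chrom,
                    "neighbor_r": float(np.nanmax(nbr_r)),
                    "partner_bin": int(bins["bin_id"].iloc[best]),
                    "partner_r": float(best_r),
                    "proposed_chrom": bins["chrom"].iloc[best],
                    "proposed_after_start": int(bins["start"].iloc[best]),
                })
    return pd.DataFrame(rows, columns=["bin_id", "chrom", "neighbor_r",
                                       "partner_bin", "partner_r",
                                       "proposed_chrom", "proposed_after_start"])
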