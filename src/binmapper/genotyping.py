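"""Sliding-window genotype calling and breakpoint detection for RILs.

Low-coverage observations assign most SNPs to one parent correctly but leave
many sites missing and a few ambiguous.  The smoothing rule evaluates windows
of 15 consecutive non-missing SNP observations: a window whose parental SNP
ratio is 11:4 or higher is called the paternal genotype (``a``), 4:11 or
lower the maternal genotype (``b``), anything between is heterozygous
(``h``).  Window labels are projected back to per-SNP calls and the
transitions between maximal runs of one genotype are the recombination
breakpoints.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
import pandas as pd

from .codes import A, B, H, HET, MISSING, NOCALL, P1, P2

logger = logging.getLogger(__name__)

_UNLABELED = -1


# ---------------------------------------------------------------------------
# SNP selection


def filter_snps(raw: pd.DataFrame, max_missing: float = 0.60) -> pd.DataFrame:
    """Keep sites segregating between the parents with missing data < 60%.

    `raw` needs columns chrom, pos, allele_p1, allele_p2 and missing_frac.
    Sites where either parental allele is unknown cannot be oriented and are
    dropped.
    """
    known = raw["allele_p1"].notna() & raw["allele_p2"].notna()
    segregating = raw["allele_p1"] != raw["allele_p2"]
    low_missing = raw["missing_frac"] < max_missing
    kept = raw[known & segregating & low_missing].reset_index(drop=True)
    logger.info("filter_snps: kept %d of %d sites", len(kept), len(raw))
    return kept


def infer_parent_alleles(site_alleles: pd.DataFrame, p2_col: str = "allele_p2") -> pd.DataFrame:
    """Impute the unobserved parent's allele as the non-P2 population allele.

    `site_alleles` needs columns chrom, pos, alleles (iterable of distinct
    alleles observed in the population) and the known parent's allele.  Sites
    that are not biallelic, or where the known parent's allele is absent from
    the population, are dropped with a logged reason.
    """
    rows = []
    dropped = {"not_biallelic": 0, "parent_absent": 0}
    for rec in site_alleles.itertuples(index=False):
        alleles = sorted(set(rec.alleles))
        p2 = getattr(rec, p2_col)
        if len(alleles) != 2:
            dropped["not_biallelic"] += 1
            continue
        if p2 not in alleles:
            dropped["parent_absent"] += 1
            continue
        p1 = alleles[0] if alleles[1] == p2 else alleles[1]
        rows.append((rec.chrom, rec.pos, p1, p2))
    for reason, n in dropped.items():
        if n:
            logger.info("infer_parent_alleles: dropped %d sites (%s)", n, reason)
    return pd.DataFrame(rows, columns=["chrom", "pos", "allele_p1", "allele_p2"])


# ---------------------------------------------------------------------------
# Window calling


def label_window(n_p1: float, n_p2: float, hi: int = 11, lo: int = 4) -> int:
    """Label one window from its (het-weighted) parental SNP counts.

    A ratio of hi:lo or higher in favour of P1 is ``a``, lo:hi or lower is
    ``b``, anything in between is ``h``.
    """
    if n_p1 >= hi:
        return A
    if n_p1 <= lo and n_p2 >= hi:
        return B
    return H


def call_windows(obs_row: np.ndarray, window: int = 15, hi: int = 11, lo: int = 4,
                 min_informative: int = 8) -> Tuple[np.ndarray, bool]:
    """Smooth one RIL's observation row for one chromosome into genotype calls.

    Windows slide SNP-by-SNP over the non-missing observations.  Within a
    window, P1 and P2 observations count 1 toward their side and HET counts
    0.5 to each; windows with fewer than `min_informative` homozygous
    observations emit no label.  Each non-missing SNP then takes the majority
    label of the labeled windows covering it (ties resolved toward the
    previous SNP's call), and missing SNPs inherit the nearest call.

    Returns (per-SNP calls, low_confidence flag).  Chromosomes with fewer
    non-missing observations than one window are called by simple majority
    and flagged low-confidence.
    """
    obs_row = np.asarray(obs_row)
    n = obs_row.size
    calls = np.full(n, NOCALL, dtype=np.int8)
    present = np.flatnonzero(obs_row != MISSING)
    m = present.size
    vals = obs_row[present]
    w1 = (vals == P1) + 0.5 * (vals == HET)
    w2 = (vals == P2) + 0.5 * (vals == HET)
    if m < window:
        n1, n2 = w1.sum(), w2.sum()
        if n1 + n2 > 0:
            frac = n1 / (n1 + n2)
            calls[:] = A if frac > 2 / 3 else B if frac < 1 / 3 else H
        return calls, True

    informative = (vals == P1) | (vals == P2)
    kernel = np.ones(window)
    c1 = np.convolve(w1, kernel, mode="valid")
    c2 = np.convolve(w2, kernel, mode="valid")
    cinf = np.convolve(informative.astype(float), kernel, mode="valid")
    n_win = m - window + 1
    win_labels = np.full(n_win, _UNLABELED, dtype=np.int8)
    ok = cinf >= min_informative
    lab = np.where(c1 >= hi, A, np.where((c1 <= lo) & (c2 >= hi), B, H))
    win_labels[ok] = lab[ok]

    # votes per non-missing slot: windows j in [i-window+1, i] cover slot i
    votes = np.zeros((m, 4), dtype=np.int32)
    for state in (A, B, H):
        ind = (win_labels == state).astype(np.int32)
        cum = np.concatenate([[0], np.cumsum(ind)])
        j_hi = np.minimum(np.arange(m), n_win - 1)
        j_lo = np.maximum(np.arange(m) - window + 1, 0)
        covered = j_hi >= j_lo
        votes[covered, state] = (cum[j_hi + 1] - cum[j_lo])[covered]

    slot_calls = np.full(m, NOCALL, dtype=np.int8)
    prev = NOCALL
    for i in range(m):
        v = votes[i, 1:]
        top = v.max()
        if top == 0:
            slot_calls[i] = NOCALL  # filled from neighbours below
            continue
        winners = np.flatnonzero(v == top) + 1
        if winners.size > 1 and prev in winners:
            slot_calls[i] = prev
        else:
            slot_calls[i] = winners[0]
        prev = slot_calls[i]

    # slots covered by no labeled window inherit the nearest called slot
    called = np.flatnonzero(slot_calls != NOCALL)
    if called.size == 0:
        return calls, True
    slot_calls = _fill_nearest(slot_calls, called)
    calls[present] = slot_calls
    # missing SNPs inherit the nearest non-missing call
    calls = _fill_nearest(calls, present)
    return calls, False


def _fill_nearest(values: np.ndarray, known_idx: np.ndarray) -> np.ndarray:
    """Fill every position with the value of the nearest known index (ties left)."""
    out = values.copy()
    pos = np.arange(values.size)
    right = np.searchsorted(known_idx, pos, side="left")
    left = np.clip(right - 1, 0, known_idx.size - 1)
    right = np.clip(right, 0, known_idx.size - 1)
    d_left = np.abs(pos - known_idx[left])
    d_right = np.abs(known_idx[right] - pos)
    nearest = np.where(d_left <= d_right, known_idx[left], known_idx[right])
    out[:] = values[nearest]
    return out


def call_population(obs: np.ndarray, snps: pd.DataFrame, window: int = 15,
                    hi: int = 11, lo: int = 4,
                    min_informative: int = 8) -> Tuple[np.ndarray, pd.DataFrame]:
    """Window-call every RIL on every chromosome.

    Returns (tracks matrix, flags frame listing low-confidence RIL/chromosome
    combinations).
    """
    n_rils = obs.shape[0]
    tracks = np.full(obs.shape, NOCALL, dtype=np.int8)
    flags = []
    for chrom, grp in snps.groupby("chrom", sort=False):
        cols = grp.index.to_numpy()
        for ril in range(n_rils):
            calls, low = call_windows(obs[ril, cols], window=window, hi=hi,
                                      lo=lo, min_informative=min_informative)
            tracks[ril, cols] = calls
            if low:
                flags.append((ril, chrom))
    return tracks, pd.DataFrame(flags, columns=["ril", "chrom"])


# ---------------------------------------------------------------------------
# Breakpoints


@dataclass(frozen=True)
class Breakpoint:
    ril: int
    chrom: str
    left_pos: int
    right_pos: int
    midpoint: int
    from_state: int
    to_state: int


def _runs(calls: np.ndarray) -> List[Tuple[int, int, int]]:
    """Maximal runs of equal call as (start_idx, end_idx_exclusive, state)."""
    if calls.size == 0:
        return []
    change = np.flatnonzero(calls[1:] != calls[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [calls.size]])
    return [(int(s), int(e), int(calls[s])) for s, e in zip(starts, ends)]


def _absorb_short_runs(runs: List[Tuple[int, int, int]], min_run: int) -> List[Tuple[int, int, int]]:
    """Merge runs shorter than min_run into their longer neighbour.

    Suppresses spurious double-crossovers produced by sparse noisy windows.
    Shortest runs are absorbed first; merging continues until every run has
    at least min_run SNPs or only one run remains.
    """
    runs = list(runs)
    while len(runs) > 1:
        lengths = [e - s for s, e, _ in runs]
        shortest = min(range(len(runs)), key=lambda i: (lengths[i], i))
        if lengths[shortest] >= min_run:
            break
        s, e, _ = runs[shortest]
        if shortest == 0:
            tgt = 1
        elif shortest == len(runs) - 1:
            tgt = shortest - 1
        else:
            left_len = lengths[shortest - 1]
            right_len = lengths[shortest + 1]
            tgt = shortest - 1 if left_len >= right_len else shortest + 1
        ts, te, tstate = runs[tgt]
        runs[tgt] = (min(s, ts), max(e, te), tstate)
        del runs[shortest]
        # re-merge adjacent runs that now share a state
        merged: List[Tuple[int, int, int]] = []
        for run in runs:
            if merged and merged[-1][2] == run[2]:
                merged[-1] = (merged[-1][0], run[1], run[2])
            else:
                merged.append(run)
        runs = merged
    return runs


def detect_breakpoints(calls: np.ndarray, positions: np.ndarray, ril: int = 0,
                       chrom: str = "chr1", min_run: int = 5) -> List[Breakpoint]:
    """Breakpoints at the boundaries between maximal genotype runs.

    The breakpoint coordinate is the floor of the mean of the two flanking
    SNP positions.  Runs shorter than min_run SNPs are absorbed into their
    longer neighbour before boundary extraction.
    """
    calls = np.asarray(calls)
    positions = np.asarray(positions)
    keep = calls != NOCALL
    if not keep.all():
        calls = calls[keep]
        positions = positions[keep]
    runs = _absorb_short_runs(_runs(calls), min_run)
    out = []
    for (s1, e1, st1), (s2, e2, st2) in zip(runs[:-1], runs[1:]):
        left = int(positions[e1 - 1])
        right = int(positions[s2])
        out.append(Breakpoint(ril=ril, chrom=chrom, left_pos=left,
                              right_pos=right, midpoint=(left + right) // 2,
                              from_state=st1, to_state=st2))
    return out


def detect_population_breakpoints(tracks: np.ndarray, snps: pd.DataFrame,
                                  min_run: int = 5) -> pd.DataFrame:
    """Breakpoints of every RIL as one table."""
    rows = []
    for chrom, grp in snps.groupby("chrom", sort=False):
        cols = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        for ril in range(tracks.shape[0]):
            for bp in detect_breakpoints(tracks[ril, cols], pos, ril=ril,
                                         chrom=chrom, min_run=min_run):
                rows.append((bp.ril, bp.chrom, bp.left_pos, bp.right_pos,
                             bp.midpoint, bp.from_state, bp.to_state))
    return pd.DataFrame(rows, columns=["ril", "chrom", "left_pos", "right_pos",
                                       "midpoint", "from_state", "to_state"])
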