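"""Trait mapping on recombination bins.

Quantitative traits are scanned bin by bin with a single-marker normal-model
likelihood ratio: LOD = (n/2) log10(SS0/SS1), where SS0 is the phenotype sum
of squares about the grand mean and SS1 the residual about the two genotype
class means (heterozygous and no-call lines are excluded).  QTL are called
where LOD exceeds a threshold (3.0 by default), with 1.5-LOD support
intervals.  Qualitative (monogenic) traits are mapped by co-segregation: the
bin minimising genotype/phenotype mismatches under the better of the two
class polarities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .binmap import BinSet
from .codes import A, B

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Quantitative scans


def lod_scan(binset: BinSet, phenotype: np.ndarray,
             min_informative: int = 10,
             cofactor_bins: Optional[Sequence[int]] = None) -> pd.DataFrame:
    """Single-marker likelihood-ratio scan over every bin.

    Returns one row per bin: n (informative lines), mean_a, mean_b, additive
    effect (mean_a - mean_b)/2, LOD and percent variance explained.  Bins
    with fewer than min_informative homozygous-called lines get NaN and a
    log entry.  A phenotype with zero variance yields LOD 0 everywhere.
    Optional cofactor bins residualise the phenotype on their genotype
    indicators first (a crude composite-scan approximation).
    """
    y = np.asarray(phenotype, dtype=float)
    if y.shape[0] != binset.n_rils:
        raise ValueError("phenotype length does not match the RIL roster")
    if cofactor_bins:
        y = _residualise(binset, y, cofactor_bins)
    G = binset.genotypes
    rows = []
    for i in range(binset.n_bins):
        col = G[i]
        inf = np.isin(col, (A, B)) & np.isfinite(y)
        n = int(inf.sum())
        if n < min_informative:
            logger.info("bin %d: only %d informative lines, no LOD",
                        int(binset.bins['bin_id'].iloc[i]), n)
            rows.append((n, np.nan, np.nan, np.nan, np.nan, np.nan))
            continue
        yy = y[inf]
        gg = col[inf]
        grand = yy.mean()
        ss0 = float(np.sum((yy - grand) ** 2))
        in_a = gg == A
        mean_a = float(yy[in_a].mean()) if in_a.any() else grand
        mean_b = float(yy[~in_a].mean()) if (~in_a).any() else grand
        fitted = np.where(in_a, mean_a, mean_b)
        ss1 = float(np.sum((yy - fitted) ** 2))
        if ss0 <= 0:
            lod, pve = 0.0, 0.0
        elif ss1 <= 0:
            lod, pve = np.inf, 100.0
        else:
            lod = (n / 2.0) * np.log10(ss0 / ss1)
            pve = 100.0 * (1.0 - ss1 / ss0)
        rows.append((n, mean_a, mean_b, (mean_a - mean_b) / 2.0, lod, pve))
    out = pd.DataFrame(rows, columns=["n", "mean_a", "mean_b", "effect", "lod", "pve"])
    return pd.concat([binset.bins.reset_index(drop=True), out], axis=1)


def _residualise(binset: BinSet, y: np.ndarray, cofactor_bins: Sequence[int]) -> np.ndarray:
    idx = [int(np.flatnonzero(binset.bins["bin_id"] == b)[0]) for b in cofactor_bins]
    X = [np.ones_like(y)]
    for i in idx:
        col = binset.genotypes[i]
        x = np.where(col == A, 1.0, np.where(col == B, -1.0, 0.0))
        X.append(x)
    X = np.column_stack(X)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta + y.mean()


@dataclass
class QTLCall:
    chrom: str
    peak_bin: int
    lod: float
    support_bins: Tuple[int, ...]
    start: int          # physical start of the support interval
    end: int            # physical end of the support interval


def call_qtls(scan: pd.DataFrame, threshold: float = 3.0,
              lod_drop: float = 1.5) -> List[QTLCall]:
    """Collapse super-threshold runs of the scan into QTL calls.

    Contiguous runs of bins with LOD above the threshold yield one call at
    their peak; independent peaks separated by a sub-threshold valley are
    separate calls.  The support interval extends from the peak in both
    directions while LOD stays within lod_drop of the peak.
    """
    calls: List[QTLCall] = []
    for chrom, grp in scan.groupby("chrom", sort=False):
        grp = grp.sort_values("start").reset_index(drop=True)
        lod = grp["lod"].to_numpy()
        above = np.nan_to_num(lod, nan=-np.inf) > threshold
        i = 0
        while i < len(grp):
            if not above[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(grp) and above[j + 1]:
                j += 1
            seg = lod[i:j + 1]
            peak_rel = int(np.nanargmax(seg))
            peak = i + peak_rel
            peak_lod = lod[peak]
            floor = peak_lod - lod_drop
            lo = peak
            while lo - 1 >= 0 and np.nan_to_num(lod[lo - 1], nan=-np.inf) >= floor:
                lo -= 1
            hi = peak
            while hi + 1 < len(grp) and np.nan_to_num(lod[hi + 1], nan=-np.inf) >= floor:
                hi += 1
            calls.append(QTLCall(
                chrom=chrom,
                peak_bin=int(grp["bin_id"].iloc[peak]),
                lod=float(peak_lod),
                support_bins=tuple(int(b) for b in grp["bin_id"].iloc[lo:hi + 1]),
                start=int(grp["start"].iloc[lo]),
                end=int(grp["end"].iloc[hi]),
            ))
            i = j + 1
    return calls


# ---------------------------------------------------------------------------
# Qualitative (monogenic) mapping


@dataclass
class QualitativeMapping:
    trait: str
    best_bin: int
    chrom: str
    mismatches: int
    polarity: Tuple[str, str]       # (class of a-genotype, class of b-genotype)
    chi_square_1to1: float
    region_start: int
    region_end: int
    region_bins: Tuple[int, ...]


def map_qualitative(binset: BinSet, classes: Sequence, trait: str = "trait",
                    min_class: int = 5) -> QualitativeMapping:
    """Locate the bin whose genotype column co-segregates with a binary trait.

    For every bin, lines whose a/b genotype disagrees with the class-to-
    parent assignment are counted under both polarities and the better one
    kept; the best bin minimises mismatches (ties broken by smaller physical
    span, then lower coordinate).  The candidate region is the contiguous run
    of bins around the best bin with the same minimal mismatch count — its
    edges are where a recombinant line's phenotype flips.  A 1:1 segregation
    chi-square over the classified lines is reported.
    """
    cls = pd.Series(classes)
    labels = [c for c in cls.dropna().unique()]
    if len(labels) != 2:
        raise ValueError("need exactly two phenotype classes")
    counts = cls.value_counts()
    if counts.min() < min_class:
        raise ValueError("each phenotype class needs at least %d lines" % min_class)
    if len(cls) != binset.n_rils:
        raise ValueError("phenotype classes do not match the RIL roster")
    is_c0 = (cls == labels[0]).to_numpy()
    is_c1 = (cls == labels[1]).to_numpy()
    G = binset.genotypes
    in_a = G == A
    in_b = G == B
    # polarity 1: a-genotype lines should be class0
    mm1 = (in_a & is_c1[None, :]).sum(axis=1) + (in_b & is_c0[None, :]).sum(axis=1)
    mm2 = (in_a & is_c0[None, :]).sum(axis=1) + (in_b & is_c1[None, :]).sum(axis=1)
    mm = np.minimum(mm1, mm2)
    spans = binset.lengths()
    order = np.lexsort((binset.bins["start"].to_numpy(), spans, mm))
    best = int(order[0])
    best_mm = int(mm[best])
    polarity = ((labels[0], labels[1]) if mm1[best] <= mm2[best]
                else (labels[1], labels[0]))
    n0, n1 = int(is_c0.sum()), int(is_c1.sum())
    chi2 = (n0 - n1) ** 2 / (n0 + n1)
    bins = binset.bins.reset_index(drop=True)
    chrom = bins["chrom"].iloc[best]
    same = bins.index[(bins["chrom"] == chrom)].to_numpy()
    same = same[np.argsort(bins["start"].to_numpy()[same])]
    k = int(np.flatnonzero(same == best)[0])
    lo = k
    while lo - 1 >= 0 and mm[same[lo - 1]] == best_mm:
        lo -= 1
    hi = k
    while hi + 1 < len(same) and mm[same[hi + 1]] == best_mm:
        hi += 1
    region = same[lo:hi + 1]
    return QualitativeMapping(
        trait=trait,
        best_bin=int(bins["bin_id"].iloc[best]),
        chrom=chrom,
        mismatches=best_mm,
        polarity=polarity,
        chi_square_1to1=float(chi2),
        region_start=int(bins["start"].iloc[region[0]]),
        region_end=int(bins["end"].iloc[region[-1]]),
        region_bins=tuple(int(b) for b in bins["bin_id"].iloc[region]),
    )


# ---------------------------------------------------------------------------
# PVE reporting across batches


def pve_report(scans: Dict[str, pd.DataFrame], threshold: float = 3.0,
               concordance_radius_bp: int = 1_000_000) -> pd.DataFrame:
    """Peak PVE per batch plus a cross-batch peak-concordance flag.

    `scans` maps batch label (e.g. year) to a scan frame.  Peaks are the
    highest-LOD bin per batch; batches are concordant when every peak lies
    on one chromosome within the configured radius.
    """
    rows = []
    peaks = {}
    for batch, scan in scans.items():
        lod = scan["lod"].to_numpy()
        if np.all(np.isnan(lod)):
            continue
        peak = int(np.nanargmax(lod))
        rec = scan.iloc[peak]
        peaks[batch] = (rec["chrom"], (rec["start"] + rec["end"]) / 2)
        rows.append({"batch": batch, "peak_bin": int(rec["bin_id"]),
                     "chrom": rec["chrom"], "lod": float(rec["lod"]),
                     "pve": float(rec["pve"]),
                     "significant": bool(rec["lod"] > threshold)})
    out = pd.DataFrame(rows, columns=["batch", "peak_bin", "chrom", "lod",
                                      "pve", "significant"])
    if len(peaks) >= 2:
        chroms = {c for c, _ in peaks.values()}
        positions = [p for _, p in peaks.values()]
        concordant = (len(chroms) == 1 and
                      max(positions) - min(positions) <= concordance_radius_bp)
    else:
        concordant = len(peaks) == 1
    out.attrs["concordant"] = bool(concordant)
    return out


def plot_scan(scan: pd.DataFrame, path=None, threshold: float = 3.0):
    """Genome-wide LOD profile, one panel track with chromosome boundaries.

    Needs matplotlib (the ``plot`` extra); returns the figure.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 2.5))
    offset = 0
    ticks, labels = [], []
    for chrom, grp in scan.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        x = offset + (grp["start"] + grp["end"]).to_numpy() / 2
        ax.plot(x, grp["lod"], lw=1)
        ticks.append(offset + grp["end"].max() / 2)
        labels.append(chrom)
        offset += grp["end"].max()
    ax.axhline(threshold, color="grey", ls="--", lw=0.8)
    ax.set_xticks(ticks, labels, rotation=45, fontsize=7)
    ax.set_ylabel("LOD")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig


def permutation_threshold(binset: BinSet, phenotype: np.ndarray,
                          n_permutations: int = 200, quantile: float = 0.95,
                          seed: int = 0, min_informative: int = 10) -> float:
    """Churchill-Doerge style genome-wide LOD threshold by permutation."""
    rng = np.random.default_rng(seed)
    y = np.asarray(phenotype, dtype=float)
    maxima = []
    for _ in range(n_permutations):
        perm = rng.permutation(y)
        scan = lod_scan(binset, perm, min_informative=min_informative)
        maxima.append(np.nanmax(scan["lod"].to_numpy()))
    return float(np.quantile(maxima, quantile))
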