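"""Map-guided assembly work: scaffold anchoring, error correction, gap filling.

The bin map doubles as a physical scaffolding device.  Unanchored scaffolds
carrying at least one bin are placed next to their tightest-linked chromosome
bin; blocks flagged for abnormal linkage are moved to the position their
linkage supports; and N-gaps in a target assembly are filled from a donor
assembly, but only conservatively — both gap flanks must match the donor
uniquely, on one donor sequence, in one orientation, in concordant order and
over a plausible span.  Filled bases are written in lowercase so their
provenance stays visible.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .binmap import BinSet
from .codes import A, B

logger = logging.getLogger(__name__)

_COMP = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# Scaffold anchoring


def _cross_r(g1: np.ndarray, g2: np.ndarray, min_informative: int = 10) -> np.ndarray:
    """Recombination fractions between two genotype matrices (rows x rows)."""
    a1, b1 = (g1 == A).astype(float), (g1 == B).astype(float)
    a2, b2 = (g2 == A).astype(float), (g2 == B).astype(float)
    n = (a1 + b1) @ (a2 + b2).T
    disc = a1 @ b2.T + b1 @ a2.T
    with np.errstate(invalid="ignore", divide="ignore"):
        r = disc / n
    r[n < min_informative] = np.nan
    return r


def anchor_scaffolds(scaffold_binset: BinSet, scaffold_lengths: Dict[str, int],
                     ref_binset: BinSet, link_threshold: float = 0.25) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Place scaffolds on chromosomes by linkage to the reference bin map.

    `scaffold_binset` holds bins on scaffold coordinates (its chrom column
    names scaffolds).  Each scaffold goes to the chromosome position of its
    minimum-r reference bin; orientation comes from the order of its internal
    bins (unknown with fewer than two informative bins).  Returns an anchor
    table and AGP rows assembling the anchored scaffolds per chromosome with
    100-N spacers; unplaceable scaffolds are reported unanchored.
    """
    r = _cross_r(scaffold_binset.genotypes, ref_binset.genotypes)
    ref_bins = ref_binset.bins.reset_index(drop=True)
    rows = []
    for scaffold, grp in scaffold_binset.bins.groupby("chrom", sort=False):
        idx = grp.sort_values("start").index.to_numpy()
        sub = r[idx]
        if np.all(np.isnan(sub)) or np.nanmin(sub) >= link_threshold:
            rows.append({"scaffold": scaffold, "chrom": None, "position": -1,
                         "orientation": "unknown", "n_bins": len(idx),
                         "best_r": float(np.nanmin(sub)) if not np.all(np.isnan(sub)) else np.nan})
            logger.warning("scaffold %s has no linked reference bin; left unanchored",
                           scaffold)
            continue
        partners = np.full(len(idx), -1)
        for k in range(len(idx)):
            if not np.all(np.isnan(sub[k])):
                partners[k] = int(np.nanargmin(sub[k]))
        valid = partners >= 0
        flat_best = np.nanargmin(np.where(np.isnan(sub), np.inf, sub)) // sub.shape[1]
        best_partner = partners[flat_best]
        chrom = ref_bins["chrom"].iloc[best_partner]
        position = int(ref_bins["start"].iloc[best_partner])
        orientation = "unknown"
        pvalid = partners[valid]
        if valid.sum() >= 2 and len(np.unique(ref_bins["start"].to_numpy()[pvalid])) >= 2:
            ref_pos = ref_bins["start"].to_numpy()[pvalid].astype(float)
            scaf_pos = grp.sort_values("start")["start"].to_numpy()[valid].astype(float)
            rho = np.corrcoef(scaf_pos, ref_pos)[0, 1]
            orientation = "+" if rho >= 0 else "-"
        rows.append({"scaffold": scaffold, "chrom": chrom, "position": position,
                     "orientation": orientation, "n_bins": int(len(idx)),
                     "best_r": float(np.nanmin(sub))})
    anchors = pd.DataFrame(rows, columns=["scaffold", "chrom", "position",
                                          "orientation", "n_bins", "best_r"])
    agp = agp_from_anchors(anchors, scaffold_lengths)
    return anchors, agp


def agp_from_anchors(anchors: pd.DataFrame, scaffold_lengths: Dict[str, int],
                     spacer: int = 100) -> pd.DataFrame:
    """AGP 2.1 rows assembling anchored scaffolds into pseudochromosomes."""
    rows = []
    placed = anchors[anchors["chrom"].notna()]
    for chrom, grp in placed.groupby("chrom", sort=True):
        grp = grp.sort_values(["position", "scaffold"])
        obj_pos = 0
        part = 0
        for i, rec in enumerate(grp.itertuples(index=False)):
            if i > 0:
                part += 1
                rows.append((chrom, obj_pos + 1, obj_pos + spacer, part, "U",
                             spacer, "scaffold", "yes", "map"))
                obj_pos += spacer
            L = scaffold_lengths[rec.scaffold]
            part += 1
            orient = rec.orientation if rec.orientation in "+-" else "?"
            rows.append((chrom, obj_pos + 1, obj_pos + L, part, "W",
                         rec.scaffold, 1, L, orient))
            obj_pos += L
    return pd.DataFrame(rows, columns=["object", "object_beg", "object_end",
                                       "part_number", "component_type",
                                       "component_id", "component_beg",
                                       "component_end", "orientation"])


# ---------------------------------------------------------------------------
# Assembly error correction


def apply_corrections(binset: BinSet, report: pd.DataFrame) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Move flagged blocks to their linkage-supported positions.

    Each report row moves one bin-sized block to sit immediately after its
    partner bin; coordinates are then re-laid per chromosome so blocks keep
    their lengths.  Returns (corrected bin table, liftover table old->new).
    Applying an empty report is the identity.  Overlapping moves (a bin moved
    twice, or a moved bin serving as another move's partner) are rejected.
    """
    bins = binset.bins.reset_index(drop=True).copy()
    if len(report):
        moved = report["bin_id"].tolist()
        if len(set(moved)) != len(moved):
            raise ValueError("overlapping corrections: a bin is moved twice")
        if set(moved) & set(report["partner_bin"].tolist()):
            raise ValueError("overlapping corrections: a moved bin is another move's partner")
    order: Dict[str, List[int]] = {
        chrom: grp.sort_values("start")["bin_id"].tolist()
        for chrom, grp in bins.groupby("chrom", sort=False)
    }
    for rec in (report.itertuples(index=False) if len(report) else []):
        src_chrom = bins.loc[bins["bin_id"] == rec.bin_id, "chrom"].iloc[0]
        order[src_chrom].remove(rec.bin_id)
        dst = rec.proposed_chrom
        order[dst].insert(order[dst].index(rec.partner_bin) + 1, rec.bin_id)
    lengths = dict(zip(bins["bin_id"], bins["end"] - bins["start"]))
    new_rows = []
    lift = []
    for chrom, ids in order.items():
        pos = 0
        for bid in ids:
            L = int(lengths[bid])
            old = bins.loc[bins["bin_id"] == bid].iloc[0]
            new_rows.append((bid, chrom, pos, pos + L))
            lift.append((bid, old["chrom"], int(old["start"]), int(old["end"]),
                         chrom, pos, pos + L))
            pos += L
    corrected = pd.DataFrame(new_rows, columns=["bin_id", "chrom", "start", "end"])
    corrected = corrected.sort_values(["chrom", "start"]).reset_index(drop=True)
    liftover = pd.DataFrame(lift, columns=["bin_id", "old_chrom", "old_start",
                                           "old_end", "new_chrom", "new_start",
                                           "new_end"])
    return corrected, liftover


# ---------------------------------------------------------------------------
# Gap filling


@dataclass(frozen=True)
class FlankMatch:
    donor_chrom: str
    start: int          # 0-based start of the aligned flank-length window
    strand: str         # "+" or "-"
    identity: float


class _DonorIndex:
    """Exact k-mer index of the donor used to seed flank alignment."""

    def __init__(self, donor: Dict[str, str], k: int = 31):
        self.k = k
        self.donor = donor
        self.index: Dict[str, List[Tuple[str, int]]] = {}
        for chrom, seq in donor.items():
            up = seq.upper()
            for i in range(len(up) - k + 1):
                kmer = up[i:i + k]
                if "N" in kmer:
                    continue
                self.index.setdefault(kmer, []).append((chrom, i))

    def seed_hits(self, kmer: str) -> List[Tuple[str, int]]:
        return self.index.get(kmer.upper(), [])


def _identity(a: str, b: str) -> float:
    if len(a) != len(b) or not a:
        return 0.0
    x = np.frombuffer(a.upper().encode(), dtype=np.uint8)
    y = np.frombuffer(b.upper().encode(), dtype=np.uint8)
    return float(np.mean(x == y))


def _match_flank(flank: str, idx: _DonorIndex, min_identity: float) -> List[FlankMatch]:
    """Unique-match search: k-mer seeds, ungapped extension, both strands."""
    k = idx.k
    L = len(flank)
    offsets = sorted({0, max(0, L // 2 - k // 2), L - k})
    candidates = set()
    for off in offsets:
        kmer = flank[off:off + k].upper()
        if len(kmer) < k or "N" in kmer:
            continue
        for chrom, p in idx.seed_hits(kmer):
            candidates.add((chrom, p - off, "+"))
        for chrom, p in idx.seed_hits(revcomp(kmer)):
            # donor[p:p+k] is the reverse complement of flank[off:off+k]
            candidates.add((chrom, p - (L - off - k), "-"))
    matches = []
    for chrom, start, strand in candidates:
        seq = idx.donor[chrom]
        if start < 0 or start + L > len(seq):
            continue
        window = seq[start:start + L]
        ident = _identity(flank, window if strand == "+" else revcomp(window))
        if ident >= min_identity:
            matches.append(FlankMatch(chrom, start, strand, ident))
    return matches


def find_gaps(seq: str, min_gap_len: int = 10) -> List[Tuple[int, int]]:
    """Maximal N-runs of at least min_gap_len bases (0-based half-open)."""
    return [(m.start(), m.end())
            for m in re.finditer("[Nn]{%d,}" % min_gap_len, seq)]


def fill_gaps(target: Dict[str, str], donor: Dict[str, str], flank_len: int = 500,
              k: int = 31, max_span_factor: float = 5.0, min_identity: float = 0.95,
              min_gap_len: int = 10) -> Tuple[Dict[str, str], pd.DataFrame]:
    """Fill N-gaps in the target from the donor by dual-flank matching.

    A gap is filled only when both flanks match the donor uniquely at
    min_identity or better, on the same donor sequence and strand, ordered
    concordantly, with the enclosed donor span between 0 and
    max_span_factor x gap length.  The inserted donor sequence is lowercased;
    every other base keeps its input case.  Every gap gets a record.
    """
    idx = _DonorIndex(donor, k=k)
    records = []
    filled: Dict[str, str] = {}
    for chrom, seq in target.items():
        gaps = find_gaps(seq, min_gap_len)
        pieces = []
        cursor = 0
        for gs, ge in gaps:
            gap_len = ge - gs
            rec = {"chrom": chrom, "start": gs, "end": ge, "gap_len": gap_len,
                   "status": None, "reason": "", "donor_chrom": "", "strand": "",
                   "donor_left_start": -1, "donor_right_start": -1, "fill_len": 0}
            left = seq[gs - flank_len:gs] if gs >= flank_len else ""
            right = seq[ge:ge + flank_len]
            fill = None
            if len(left) < flank_len or len(right) < flank_len:
                rec.update(status="unfilled_no_match", reason="flank_at_sequence_edge")
            elif "N" in left.upper() or "N" in right.upper():
                rec.update(status="unfilled_no_match", reason="flank_contains_gap")
            else:
                lm = _match_flank(left, idx, min_identity)
                rm = _match_flank(right, idx, min_identity)
                if not lm or not rm:
                    rec.update(status="unfilled_no_match", reason="flank_unmatched")
                elif len(lm) > 1 or len(rm) > 1:
                    rec.update(status="unfilled_ambiguous", reason="multiple_flank_matches")
                else:
                    l, r = lm[0], rm[0]
                    if l.donor_chrom != r.donor_chrom:
                        rec.update(status="unfilled_discordant", reason="flanks_on_different_sequences")
                    elif l.strand != r.strand:
                        rec.update(status="unfilled_discordant", reason="flanks_on_opposite_strands")
                    else:
                        dseq = donor[l.donor_chrom]
                        if l.strand == "+":
                            span = r.start - (l.start + flank_len)
                            fill_seq = dseq[l.start + flank_len:r.start]
                        else:
                            span = l.start - (r.start + flank_len)
                            fill_seq = revcomp(dseq[r.start + flank_len:l.start])
                        if span < 0 or span > max_span_factor * max(gap_len, 1):
                            rec.update(status="unfilled_discordant",
                                       reason="donor_span_out_of_bounds")
                        else:
                            fill = fill_seq.lower()
                            rec.update(status="filled", donor_chrom=l.donor_chrom,
                                       strand=l.strand, donor_left_start=l.start,
                                       donor_right_start=r.start, fill_len=span)
            pieces.append(seq[cursor:gs])
            pieces.append(fill if fill is not None else seq[gs:ge])
            cursor = ge
            records.append(rec)
        pieces.append(seq[cursor:])
        filled[chrom] = "".join(pieces)
    report = pd.DataFrame(records, columns=["chrom", "start", "end", "gap_len",
                                            "status", "reason", "donor_chrom",
                                            "strand", "donor_left_start",
                                            "donor_right_start", "fill_len"])
    return filled, report
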