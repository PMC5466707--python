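"""Synthetic two-parent RIL populations with known truth.

Emulates the study design the downstream analysis assumes: a biparental cross
(paternal line P1, maternal line P2) advanced by single-seed descent to F10,
resequenced at low depth so each RIL contributes sparse, parental-origin SNP
observations.  Everything carries an explicit seed so any run is reproducible,
and the ground truth (recombination segments, breakpoints, causal loci,
deleted gap sequences) is returned alongside the data for recovery tests.

The default genome is a 1/100-scale model of a nine-chromosome 416-Mb grass
genome so the full pipeline runs in seconds; the full-scale geometry is a
config away.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .codes import HET, MISSING, P1, P2

# 1/100-scale chromosome lengths (bp) of a 416-Mb nine-chromosome genome.
DEFAULT_CHROM_LENGTHS: Tuple[int, ...] = (
    446_035, 517_617, 540_900, 433_491, 495_605,
    369_284, 377_438, 380_666, 598_757,
)

# Per-meiosis genetic lengths (Morgans).  A selfing-RIL observed map expands
# roughly twofold (R = 2r/(1+2r)), so these are set to about half the observed
# per-chromosome map lengths of a dense grass RIL map, putting the simulated
# observed map on the familiar ~1900 cM scale.
DEFAULT_CHROM_MORGANS: Tuple[float, ...] = (
    0.836, 1.123, 1.109, 0.841, 1.338, 0.761, 0.842, 1.027, 1.763,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def chrom_names(n: int) -> List[str]:
    return [f"chr{i + 1}" for i in range(n)]


def ril_ids(n: int) -> List[str]:
    return [f"RIL{i + 1:03d}" for i in range(n)]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the simulated cross and sequencing experiment.

    mean_depth is expected reads per SNP per RIL; snp_density is markers per
    kb; crossover_rate scales crossovers per meiosis per Morgan (1.0 is the
    definition of the Morgan).
    """

    n_rils: int = 184
    chrom_lengths: Tuple[int, ...] = DEFAULT_CHROM_LENGTHS
    chrom_morgans: Tuple[float, ...] = DEFAULT_CHROM_MORGANS
    snp_density: float = 1.2
    selfing_generations: int = 9
    crossover_rate: float = 1.0
    mean_depth: float = 2.0
    seq_error: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_rils < 1:
            raise ValueError("n_rils must be >= 1")
        if len(self.chrom_lengths) < 1:
            raise ValueError("need at least one chromosome")
        if any(L <= 0 for L in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        if len(self.chrom_morgans) != len(self.chrom_lengths):
            raise ValueError("chrom_morgans must match chrom_lengths")
        if any(m < 0 for m in self.chrom_morgans):
            raise ValueError("chromosome map lengths must be >= 0")
        if self.snp_density <= 0:
            raise ValueError("snp_density must be > 0")
        if self.selfing_generations < 1:
            raise ValueError("selfing_generations must be >= 1")
        if self.crossover_rate < 0:
            raise ValueError("crossover_rate must be >= 0")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be >= 0")
        if not 0 <= self.seq_error < 0.5:
            raise ValueError("seq_error must be in [0, 0.5)")

    @property
    def chroms(self) -> List[str]:
        return chrom_names(len(self.chrom_lengths))

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class TraitConfig:
    """A simulated trait: its causal loci, effects and noise model.

    Qualitative traits are monogenic by default (one causal locus, dominance
    resolving residual heterozygotes); quantitative traits sum additive
    effects (+e for the P1 allele, -e for P2, 0 for het) plus Gaussian noise.
    """

    name: str
    kind: str  # "qualitative" | "quantitative"
    loci: Tuple[Tuple[str, int], ...]
    effects: Tuple[float, ...] = ()
    residual_sd: float = 0.0
    dominant: str = "P1"
    classes: Tuple[str, str] = ("P1", "P2")

    def __post_init__(self):
        if self.kind not in ("qualitative", "quantitative"):
            raise ValueError("kind must be qualitative or quantitative")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")
        if self.kind == "qualitative" and len(self.loci) != 1:
            raise ValueError("qualitative traits take exactly one causal locus")
        if self.kind == "quantitative" and len(self.effects) != len(self.loci):
            raise ValueError("one effect per causal locus required")
        if self.dominant not in ("P1", "P2"):
            raise ValueError("dominant must be P1 or P2")


def effect_for_pve(pve: float, residual_sd: float) -> float:
    """Additive effect size giving a target fraction of variance explained.

    For an inbred biparental population the genotype indicator is +-1 with
    equal frequency, so the genetic variance of a locus with effect e is e^2
    and PVE = e^2 / (e^2 + sd^2).
    """
    if not 0 < pve < 1:
        raise ValueError("pve must be in (0, 1)")
    return residual_sd * np.sqrt(pve / (1.0 - pve))


class TrueGenotypes:
    """Ground-truth parental-origin mosaic of every simulated RIL.

    Each (RIL, chromosome) is a tiling of half-open segments with origin
    P1, P2 or HET; segment ends double as the true breakpoint positions.
    """

    def __init__(self, chrom_lengths: Dict[str, int],
                 segments: List[Dict[str, Tuple[np.ndarray, np.ndarray]]]):
        self.chrom_lengths = dict(chrom_lengths)
        self._segments = segments

    @property
    def n_rils(self) -> int:
        return len(self._segments)

    @property
    def chroms(self) -> List[str]:
        return list(self.chrom_lengths)

    def segments_of(self, ril: int, chrom: str) -> Tuple[np.ndarray, np.ndarray]:
        """(ends, origin codes) for one RIL chromosome; starts are implicit."""
        return self._segments[ril][chrom]

    def segments_frame(self) -> pd.DataFrame:
        rows = []
        for ril, per_chrom in enumerate(self._segments):
            for chrom, (ends, origins) in per_chrom.items():
                start = 0
                for end, org in zip(ends.tolist(), origins.tolist()):
                    rows.append((ril, chrom, start, int(end), int(org)))
                    start = int(end)
        return pd.DataFrame(rows, columns=["ril", "chrom", "start", "end", "origin"])

    def breakpoints(self) -> pd.DataFrame:
        """True breakpoint coordinates (segment boundaries strictly inside)."""
        rows = []
        for ril, per_chrom in enumerate(self._segments):
            for chrom, (ends, _) in per_chrom.items():
                for pos in ends[:-1].tolist():
                    rows.append((ril, chrom, int(pos)))
        return pd.DataFrame(rows, columns=["ril", "chrom", "pos"])

    def genotype_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Origin codes (n_rils x n_positions) at 1-based positions."""
        pos0 = np.asarray(positions, dtype=np.int64) - 1
        out = np.empty((self.n_rils, len(pos0)), dtype=np.int8)
        for ril in range(self.n_rils):
            ends, origins = self._segments[ril][chrom]
            idx = np.searchsorted(ends, pos0, side="right")
            out[ril] = origins[idx]
        return out

    def het_fraction(self) -> float:
        """Genome fraction that is residually heterozygous, averaged over RILs."""
        total = sum(self.chrom_lengths.values()) * self.n_rils
        het = 0
        for per_chrom in self._segments:
            for chrom, (ends, origins) in per_chrom.items():
                starts = np.concatenate([[0], ends[:-1]])
                het += int(np.sum((ends - starts)[origins == HET]))
        return het / total


# ---------------------------------------------------------------------------
# Parents and markers


def simulate_parents(config: SimConfig, with_sequences: bool = True):
    """Draw SNP positions and parental alleles; optionally toy parent FASTAs.

    Returns (snp_table, sequences) where sequences maps parent name ("P1",
    "P2") to a dict of chromosome sequences differing exactly at the SNPs.
    """
    rng = np.random.default_rng(config.seed)
    frames = []
    seqs_p1: Dict[str, str] = {}
    seqs_p2: Dict[str, str] = {}
    for chrom, L in zip(config.chroms, config.chrom_lengths):
        n = rng.poisson(config.snp_density * L / 1000.0)
        n = min(n, L)
        pos = np.sort(rng.choice(L, size=n, replace=False)) + 1  # 1-based
        a1 = rng.integers(0, 4, size=n)
        a2 = (a1 + rng.integers(1, 4, size=n)) % 4  # always differs from a1
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "pos": pos.astype(np.int64),
            "allele_p1": _BASES[a1].astype("U1"),
            "allele_p2": _BASES[a2].astype("U1"),
        }))
        if with_sequences:
            backbone = rng.integers(0, 4, size=L)
            backbone[pos - 1] = a1
            seqs_p1[chrom] = _BASES[backbone].tobytes().decode()
            backbone[pos - 1] = a2
            seqs_p2[chrom] = _BASES[backbone].tobytes().decode()
    snps = pd.concat(frames, ignore_index=True)
    sequences = {"P1": seqs_p1, "P2": seqs_p2} if with_sequences else None
    return snps, sequences


# ---------------------------------------------------------------------------
# Meiosis and selfing

def _slice_hap(ends, origins, s, e, out_ends, out_origins):
    """Append the [s, e) portion of a haplotype to the output lists."""
    i0 = np.searchsorted(ends, s, side="right")
    i1 = np.searchsorted(ends, e, side="left")
    for i in range(i0, min(i1 + 1, len(ends))):
        seg_end = min(int(ends[i]), e)
        if out_origins and out_origins[-1] == origins[i]:
            out_ends[-1] = seg_end
        else:
            out_ends.append(seg_end)
            out_origins.append(int(origins[i]))


def _gamete(h1, h2, L, morgans, rng):
    """One meiotic product of a diploid (h1, h2), Poisson crossovers."""
    n_xo = rng.poisson(morgans)
    if n_xo == 0:
        return h1 if rng.integers(2) == 0 else h2
    xo = np.unique(rng.integers(1, L, size=n_xo))
    bounds = np.concatenate([[0], xo, [L]])
    cur = int(rng.integers(2))
    out_ends: List[int] = []
    out_origins: List[int] = []
    for i in range(len(bounds) - 1):
        hap = (h1, h2)[cur]
        _slice_hap(hap[0], hap[1], int(bounds[i]), int(bounds[i + 1]),
                   out_ends, out_origins)
        cur ^= 1
    return np.asarray(out_ends, dtype=np.int64), np.asarray(out_origins, dtype=np.int8)


def _pair_to_genotype(h1, h2, L):
    """Merge the two haplotypes of an individual into origin segments."""
    cuts = np.unique(np.concatenate([h1[0], h2[0]]))
    i1 = np.searchsorted(h1[0], cuts, side="left")
    i2 = np.searchsorted(h2[0], cuts, side="left")
    o1 = h1[1][i1]
    o2 = h2[1][i2]
    code = np.where(o1 == o2, np.where(o1 == 0, P1, P2), HET).astype(np.int8)
    # merge adjacent equal-code segments
    keep = np.concatenate([code[:-1] != code[1:], [True]])
    return cuts[keep], code[keep]


def simulate_ril_population(config: SimConfig, seed: int | None = None) -> TrueGenotypes:
    """Simulate F1 then `selfing_generations` rounds of single-seed descent.

    Residual heterozygosity arises naturally: the expected heterozygous
    genome fraction after g selfing generations is 0.5**g.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    xrate = config.crossover_rate
    lengths = dict(zip(config.chroms, config.chrom_lengths))
    morgans = dict(zip(config.chroms, config.chrom_morgans))
    population = []
    for _ in range(config.n_rils):
        per_chrom = {}
        for chrom, L in lengths.items():
            M = morgans[chrom] * xrate
            # F1: one P1 haplotype, one P2 haplotype
            hap_a = (np.array([L], dtype=np.int64), np.array([0], dtype=np.int8))
            hap_b = (np.array([L], dtype=np.int64), np.array([1], dtype=np.int8))
            for _gen in range(config.selfing_generations):
                g1 = _gamete(hap_a, hap_b, L, M, rng)
                g2 = _gamete(hap_a, hap_b, L, M, rng)
                hap_a, hap_b = g1, g2
            per_chrom[chrom] = _pair_to_genotype(hap_a, hap_b, L)
        population.append(per_chrom)
    return TrueGenotypes(lengths, population)


# ---------------------------------------------------------------------------
# Low-coverage observations


def simulate_observations(truth: TrueGenotypes, snps: pd.DataFrame,
                          config: SimConfig, seed: int | None = None) -> np.ndarray:
    """Per-RIL, per-SNP parental-origin observations at Poisson read depth.

    Depth 0 is MISSING; a site where both parental alleles were seen among
    the reads is HET; otherwise the single observed allele's parent.  Each
    read's allele flips with probability ``seq_error``.
    """
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    n_snps = len(snps)
    obs = np.empty((truth.n_rils, n_snps), dtype=np.int8)
    e = config.seq_error
    for chrom, grp in snps.groupby("chrom", sort=False):
        cols = grp.index.to_numpy()
        true = truth.genotype_at(chrom, grp["pos"].to_numpy())
        depth = rng.poisson(config.mean_depth, size=true.shape)
        p_read_p2 = np.where(true == P1, e, np.where(true == P2, 1.0 - e, 0.5))
        k_p2 = rng.binomial(depth, p_read_p2)
        block = np.where(depth == 0, MISSING,
                         np.where(k_p2 == 0, P1,
                                  np.where(k_p2 == depth, P2, HET)))
        obs[:, cols] = block.astype(np.int8)
    return obs


# ---------------------------------------------------------------------------
# Phenotypes


def simulate_phenotypes(truth: TrueGenotypes, traits: Sequence[TraitConfig],
                        seed: int = 0) -> pd.DataFrame:
    """Phenotype table (one row per RIL) for the configured traits."""
    rng = np.random.default_rng(seed)
    out = pd.DataFrame({"ril_id": ril_ids(truth.n_rils)})
    for trait in traits:
        for chrom, pos in trait.loci:
            if chrom not in truth.chrom_lengths:
                raise ValueError(f"causal locus chromosome {chrom!r} not simulated")
            if not 1 <= pos <= truth.chrom_lengths[chrom]:
                raise ValueError(f"causal locus {chrom}:{pos} outside chromosome")
        geno = np.column_stack([
            truth.genotype_at(chrom, np.array([pos]))[:, 0]
            for chrom, pos in trait.loci
        ])
        if trait.kind == "qualitative":
            g = geno[:, 0]
            dominant_code = P1 if trait.dominant == "P1" else P2
            cls = np.where(g == P1, trait.classes[0],
                           np.where(g == P2, trait.classes[1],
                                    trait.classes[0] if dominant_code == P1
                                    else trait.classes[1]))
            out[trait.name] = cls
        else:
            signs = np.where(geno == P1, 1.0, np.where(geno == P2, -1.0, 0.0))
            value = signs @ np.asarray(trait.effects, dtype=float)
            value = value + rng.normal(0.0, trait.residual_sd, size=truth.n_rils)
            out[trait.name] = value
    return out


# ---------------------------------------------------------------------------
# Fragmented assemblies with N-gaps


@dataclass(frozen=True)
class GapConfig:
    """Random gap placement for fragmenting a donor into a gapped target."""

    n_gaps: int = 20
    min_len: int = 50
    max_len: int = 500
    min_spacing: int = 2_000
    edge_margin: int = 1_000

    def __post_init__(self):
        if self.n_gaps < 0 or self.min_len < 1 or self.max_len < self.min_len:
            raise ValueError("invalid gap configuration")


def _count_occurrences(haystack: str, needle: str) -> int:
    """Overlapping occurrence count on both strands."""
    def fwd(h, n):
        count = start = 0
        while True:
            i = h.find(n, start)
            if i < 0:
                return count
            count += 1
            start = i + 1
    rc = _revcomp(needle)
    n = fwd(haystack, needle)
    if rc != needle:
        n += fwd(haystack, rc)
    return n


_COMP = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def simulate_fragmented_assembly(donor: Dict[str, str],
                                 gaps: "GapConfig | Dict[str, List[Tuple[int, int]]]" = GapConfig(),
                                 seed: int = 0, flank_len: int = 500):
    """Replace spans of a donor assembly with N-runs, keeping the truth.

    Returns (target sequences, truth table).  The truth table records each
    deleted span and whether its flanks occur uniquely in the donor (gaps
    with repeated flanks are expected to be refused by conservative filling).
    """
    rng = np.random.default_rng(seed)
    target: Dict[str, str] = {}
    rows = []
    for chrom, seq in donor.items():
        L = len(seq)
        if isinstance(gaps, GapConfig):
            spans = _draw_spans(gaps, L, rng)
        else:
            spans = sorted(gaps.get(chrom, []))
            prev_end = -1
            for s, e in spans:
                if s < 0 or e > L or s >= e:
                    raise ValueError(f"gap span ({s}, {e}) outside sequence {chrom}")
                if s < prev_end:
                    raise ValueError("overlapping gap spans")
                prev_end = e
        pieces = []
        cursor = 0
        for s, e in spans:
            pieces.append(seq[cursor:s])
            pieces.append("N" * (e - s))
            left = seq[max(0, s - flank_len):s]
            right = seq[e:e + flank_len]
            rows.append({
                "chrom": chrom, "start": s, "end": e,
                "deleted": seq[s:e],
                "left_flank_unique": _count_occurrences(seq, left) == 1 if len(left) == flank_len else False,
                "right_flank_unique": _count_occurrences(seq, right) == 1 if len(right) == flank_len else False,
            })
            cursor = e
        pieces.append(seq[cursor:])
        target[chrom] = "".join(pieces)
    truth = pd.DataFrame(rows, columns=["chrom", "start", "end", "deleted",
                                        "left_flank_unique", "right_flank_unique"])
    return target, truth


def _draw_spans(cfg: GapConfig, L: int, rng) -> List[Tuple[int, int]]:
    spans: List[Tuple[int, int]] = []
    lo = cfg.edge_margin
    hi = L - cfg.edge_margin - cfg.max_len
    if hi <= lo:
        return spans
    attempts = 0
    while len(spans) < cfg.n_gaps and attempts < cfg.n_gaps * 50:
        attempts += 1
        s = int(rng.integers(lo, hi))
        glen = int(rng.integers(cfg.min_len, cfg.max_len + 1))
        e = s + glen
        if all(e + cfg.min_spacing <= s2 or s >= e2 + cfg.min_spacing
               for s2, e2 in spans):
            spans.append((s, e))
    return sorted(spans)
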