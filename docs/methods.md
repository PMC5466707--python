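# Methods

This note documents the models and conventions behind each stage of
`binmapper`, the defaults and why they were chosen, and what the synthetic
data generator does and does not emulate.

## Population and sequencing model (simulate)

The simulator models a biparental cross advanced by single-seed descent.
The F1 carries one intact haplotype from each parent; each subsequent
generation is produced by selfing, with each gamete drawn by meiosis from
the individual's two haplotypes.  Crossovers per meiosis per chromosome are
Poisson with mean equal to the chromosome's genetic length in Morgans
(`chrom_morgans`), positions uniform, no interference.  No interference is
the simplest model compatible with applying the Kosambi map function
downstream (Kosambi tolerates, but does not require, moderate
interference); an interference model could be added without touching the
rest of the pipeline.  Because the generations are simulated explicitly,
residual heterozygosity arises naturally: after g selfing generations the
expected heterozygous genome fraction is 0.5^g (≈0.2% at the default g = 9,
i.e. F10 lines).

Default geometry is nine chromosomes at 1/100 physical scale of a 416-Mb
grass genome (4.16 Mb total), 184 lines, 1.2 SNPs/kb, so the whole pipeline
runs in seconds while keeping realistic marker density and population size;
full-scale lengths are a config away.  Per-meiosis genetic lengths default
to about half the observed per-chromosome RIL map lengths of a dense foxtail
millet map, because the observed map of a selfing-RIL population is expanded
roughly twofold relative to a single meiosis (R = 2r/(1+2r) ≈ 2r for small
r); with this choice the simulated observed map lands on the familiar
absolute scale (total in the 1500–1900 cM range at default settings).

Sequencing is modelled per SNP per line: read depth ~ Poisson(`mean_depth`,
default 2.0), each read reports the allele of the true local origin
(heterozygous segments emit either allele per read), and a read's allele
flips with probability `seq_error` (default 0 — no error model is assumed;
it is a knob).  A site with no reads is MISSING (expected fraction e^-2 ≈
13.5% at 2x); a site where both alleles were seen is HET; otherwise the
observed parent.  The generator does **not** emulate read-level artefacts:
no FASTQ, no mapping bias, no base-quality structure, no depth
autocorrelation along the genome, no segregation distortion, and no
structural variation.  Passing tests therefore demonstrate correctness of
the analysis logic under the stated statistical model, not robustness to
alignment pathology in real data.

Phenotypes: qualitative traits are deterministic functions of a single
causal genotype (heterozygotes resolved by a configurable dominant parent);
quantitative traits are sums of additive effects (+e for the paternal
allele, -e maternal, 0 het) plus Gaussian noise.  `effect_for_pve` converts
a target fraction of variance explained into an effect size via
PVE = e²/(e² + sd²), exact for an inbred population with balanced allele
frequencies.

Fragmented assemblies are made by replacing spans of a donor sequence with
N-runs while recording the deleted sequence and whether each 500-bp flank is
unique in the donor, giving gap-filling tests an exact oracle.

## Sliding-window genotyping

Windows span 15 consecutive **non-missing** observations and slide one SNP
at a time.  Sliding SNP-by-SNP (rather than base-by-base) is the only
reading under which consecutive windows differ in content, since windows are
defined over consecutive SNPs.  Within a window, P1 and P2 observations
count 1 to their side and HET counts 0.5 to each side, so the counts always
total 15; the window is labelled `a` when the paternal count reaches 11
(ratio ≥ 11:4), `b` when it is at most 4, `h` otherwise.  Windows with fewer
than 8 homozygous observations are considered underpowered and emit no
label.  Window labels are projected back to per-SNP calls by majority over
the covering labelled windows, ties resolved toward the previous SNP's call
(a label-symmetric rule); SNPs covered by no labelled window, and missing
SNPs, inherit the nearest call.  A chromosome with fewer non-missing SNPs
than one window is called by simple majority and flagged low-confidence.

Breakpoints are the boundaries between maximal runs of one genotype; the
assigned coordinate is the floor of the mean of the two flanking SNP
positions.  Runs shorter than `min_run` SNPs (default 5) are absorbed into
their longer neighbour before boundary extraction — at 2x depth, isolated
discordant stretches are overwhelmingly noise, and a 15-SNP majority rule
cannot resolve genuine segments that short anyway.  This sets the method's
resolution: true segments shorter than about one window span (~12.5 kb at
default density) are invisible at any depth, which is why breakpoint
recovery on the default design plateaus near 91% of all true breakpoints
but is 100% for breakpoints whose flanking segments exceed one window span.

## Bin map and linkage map

Breakpoint midpoints from all lines are snapped down to a 20-kb grid
(`floor(pos/20000)*20000`); the grid cells partition each chromosome, each
interval takes its genotype column from the tracks by per-line majority
(ties and empty intervals yield no call), and adjacent intervals with
identical columns merge into one bin.  Interior bins are therefore ≥ 20 kb;
only a chromosome's terminal bin can be shorter.  Columns differing only in
no-call symbols are treated as distinct but logged, so near-duplicate
adjacent bins are visible.

The recombination fraction between two columns is the discordant fraction
among lines homozygous-called in both (h and no-call excluded), capped at
0.4999, undefined below 10 jointly informative lines.  This estimator is a
deliberate, symmetric simplification; maximum-likelihood alternatives add
little for inbred lines.  Kosambi's function d = 25 ln((1+2r)/(1−2r))
converts fractions to centimorgans (inverse r = tanh(d/50)/2; the pair
round-trips to 1e-9).  By default Kosambi is applied to the observed RIL
fraction directly — consistent with how dense RIL maps are usually
reported — and `apply_ril_correction` applies r = R/(2−2R) first for users
who want per-meiosis distances.

Linkage groups are single-linkage components of the graph {r < 0.25};
within a group, bins are ordered along a minimum-spanning-tree path
(scipy's MST on the r matrix), walked depth-first from the physically first
leaf, nearest neighbour first, and oriented to match physical order.  This
heuristic recovers the physical order exactly on clean simulations; fully
de-novo ordering quality is not a design goal.  Bins whose recombination
with both physical neighbours exceeds 0.15 while some non-neighbour bin
shows r < 0.05 are flagged as misplaced, with the minimum-r partner as the
proposed new neighbour; both thresholds are configurable because their
natural scale depends on the genetic density of the map.

## Assembly anchoring, correction and gap filling

A scaffold carrying bins is anchored to the chromosome position of its
minimum-r reference bin; orientation is the sign of the correlation between
the scaffold's internal bin order and its partners' positions (unknown with
fewer than two informative bins).  AGP 2.1 rows assemble anchored scaffolds
with fixed 100-N spacers (a convention).  Corrections move flagged blocks
next to their linkage partner and re-lay coordinates, emitting a liftover
table; an empty report is the identity and overlapping moves are rejected.

Gap filling is deliberately conservative.  Gaps are maximal N-runs ≥ 10 bp.
Each 500-bp flank is searched in the donor by exact 31-mer seeds (three
seed offsets per flank, both strands) with ungapped extension and a 95%
identity floor.  A gap is filled only when *both* flanks match uniquely, on
one donor sequence, one strand, in concordant order, and the enclosed donor
span is between 0 (flanks abut: the gap closes) and 5x the gap length.
Fills are lowercased; all other bases keep their input case.  Every gap
receives a status (`filled`, `unfilled_no_match`, `unfilled_ambiguous`,
`unfilled_discordant`) with a reason.  All parameters are flags; the
defaults favour zero false fills (an unrelated random donor fills nothing)
over completeness.  Gapped/affine alignment is out of scope — flanks that
differ from the donor by indels will simply not match.

## Trait mapping

The quantitative scan fits, per bin, the one-way normal model with genotype
class means (h and no-call lines excluded — residual heterozygotes are
<1% of calls in an F10 population):
LOD = (n/2) log10(SS0/SS1), PVE = 100 (1 − SS1/SS0), additive effect
(mean_a − mean_b)/2.  Degenerate cases: zero phenotype variance gives LOD 0;
a perfect fit gives LOD ∞ with PVE 100.  Bins with fewer than 10 informative
lines are skipped.  QTL are called where LOD exceeds 3.0 (the conventional
fixed threshold; a Churchill–Doerge permutation threshold is available but
off by default), contiguous super-threshold runs collapse to their peak,
and the support interval extends while LOD stays within 1.5 of the peak —
the 1.5-LOD interval is a stated convention, not an inference guarantee.
A `cofactor_bins` option residualises the phenotype on user-chosen bins
first, a crude stand-in for composite interval mapping; with bins as dense
as a saturated map, positions between markers add little, which is why a
single-marker scan per bin is the core method.  F2-style three-class models
are not implemented.

Qualitative mapping counts, per bin, the lines whose a/b genotype disagrees
with the class-to-parent assignment under both polarities and keeps the
better; the best bin minimises mismatches with ties broken by smaller
physical span then lower coordinate.  The candidate region is the
contiguous run of bins sharing the minimal mismatch count — its edges are
exactly where some recombinant line's phenotype flips.  A 1:1 segregation
chi-square over the classified lines accompanies the call.

## Numerical and interface conventions

All internal intervals are 0-based half-open; VCF and AGP are 1-based on
output, BED 0-based, and conversions are covered by round-trip tests.
Genotype symbols in text outputs are fixed to `a`/`b`/`h`/`-`.  Every
stochastic routine takes an explicit seed and identical configuration
yields byte-identical outputs; the pipeline records a manifest (version,
config, input checksums, per-stage counts and timings) and skips recompute
when nothing changed.

## Problem sizes used by the test suite and acceptance script

The shared test population is the default design (184 RILs, 4.16-Mb
genome, 1.2 SNPs/kb, 2x depth, seed 1).  The QTL recovery study uses 50
replicates of a planted 30%-PVE locus scanned on noise-free truth bins —
the quantity under test is the scan, not the genotyper, and this isolates
it.  Gap filling is exercised on a 1-Mb random donor with 30 gaps.  These
sizes were chosen so the entire chain, including the recovery studies,
completes in about a minute on one core while leaving every rate estimated
from hundreds to thousands of events.

## Known limitations

- Resolution is bounded by the window: segments < ~1 window span are
  undetectable, and breakpoint positions are only localised to about the
  local inter-SNP spacing (then snapped to the 20-kb grid for bins).
- The r estimator ignores heterozygous calls entirely; maps from
  populations with substantial residual heterozygosity will lose a little
  information.
- Gap filling performs no gapped alignment and will leave indel-divergent
  gaps unfilled rather than risk a wrong fill.
- The simulator's idealisations (no interference, independent per-site
  depth, no distortion) mean recovery rates measured here are upper bounds
  for messy real data.
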