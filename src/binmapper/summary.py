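"""Summary statistics over bin maps and assemblies.

Reproduces the standard per-chromosome bookkeeping of a bin-map study: SNP
densities per kb, bin counts and mean bin length, total and mean genetic
distances, and assembly gap ratios.  The module also carries, as plain TSV
text, the published per-chromosome summary of the foxtail millet Zhanggu
bin map and the gap statistics of the Zhanggu/Yugu assembly editions, so
the arithmetic can be checked against an independently published dataset.
"""

from __future__ import annotations

from io import StringIO

import numpy as np
import pandas as pd

# Published per-chromosome summary of a 184-RIL foxtail millet bin map
# (chromosome length, bin count, genetic length, SNP count).
ZHANGGU_BINMAP_TSV = """\
chrom	length_bp	bin_number	linkage_cM	snp_number
chr1	44603498	408	167.117	42624
chr2	51761675	491	224.647	89674
chr3	54090027	396	221.738	81236
chr4	43349090	348	168.232	27932
chr5	49560508	480	267.52	60305
chr6	36928436	203	152.1	30946
chr7	37743793	242	168.48	56045
chr8	38066565	283	205.431	58149
chr9	59875680	586	352.58	36503
"""

# Published gap statistics of two foxtail millet assemblies before and after
# map-guided correction and gap filling.
ASSEMBLY_GAPS_TSV = """\
strain	chromosome_length_bp	gap_length_bp	gap_number	filled_gap_number
Zhanggu	399854594	26817695	31942	-1
Zhanggu_2nd	415979272	28962873	34452	-1
Yugu	401300876	4616102	6171	-1
Yugu_2nd	402520233	2175332	3297	2874
"""


def published_binmap_table() -> pd.DataFrame:
    return pd.read_csv(StringIO(ZHANGGU_BINMAP_TSV), sep="\t")


def published_assembly_table() -> pd.DataFrame:
    df = pd.read_csv(StringIO(ASSEMBLY_GAPS_TSV), sep="\t")
    return df.replace(-1, np.nan)


def snp_density_per_kb(snp_number, length_bp):
    """Markers per kilobase."""
    return np.asarray(snp_number, dtype=float) / (np.asarray(length_bp, dtype=float) / 1000.0)


def mean_bin_length_kb(total_length_bp: float, n_bins: int) -> float:
    return total_length_bp / n_bins / 1000.0


def mean_bin_interval_cM(total_cM: float, n_bins: int, n_groups: int) -> float:
    """Mean genetic interval between adjacent bins (n_bins - n_groups gaps)."""
    return total_cM / (n_bins - n_groups)


def gap_ratio_percent(gap_length_bp, chromosome_length_bp):
    """Gap length as a percentage of assembly length."""
    return 100.0 * np.asarray(gap_length_bp, dtype=float) / np.asarray(chromosome_length_bp, dtype=float)


def binmap_summary(table: pd.DataFrame | None = None) -> dict:
    """Totals and averages of a per-chromosome bin-map table.

    With no argument, summarises the published table.
    """
    t = published_binmap_table() if table is None else table
    total_len = int(t["length_bp"].sum())
    total_bins = int(t["bin_number"].sum())
    total_cM = float(t["linkage_cM"].sum())
    total_snps = int(t["snp_number"].sum())
    return {
        "total_length_bp": total_len,
        "total_bins": total_bins,
        "total_cM": total_cM,
        "total_snps": total_snps,
        "snp_density_per_kb": float(snp_density_per_kb(total_snps, total_len)),
        "mean_bin_length_kb": mean_bin_length_kb(total_len, total_bins),
        "mean_bin_interval_cM": mean_bin_interval_cM(total_cM, total_bins, len(t)),
    }
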