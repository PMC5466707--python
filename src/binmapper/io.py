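"""Readers and writers for the pipeline's interchange formats.

VCF 4.2 carries the SNPs and per-sample parental-origin genotypes (parents
first, RILs after); FASTA carries sequences; TSV carries genotype tracks,
breakpoints, bins, linkage maps, phenotypes and gap reports; AGP 2.1 carries
scaffold anchoring.  Internally every interval is 0-based half-open; VCF,
FASTA and AGP use their standards' 1-based conventions at the boundary.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codes import HET, MISSING, P1, P2, calls_to_symbols, symbols_to_calls


# ---------------------------------------------------------------------------
# VCF


def write_vcf(path, snps: pd.DataFrame, obs: np.ndarray, ril_names: List[str],
              chrom_lengths: Dict[str, int], p1_name: str = "P1",
              p2_name: str = "P2") -> None:
    """Write SNPs and observations as VCF 4.2, parents as the first samples.

    REF is the P1 allele and ALT the P2 allele, so P1-origin observations
    become 0/0, P2 becomes 1/1, het 0/1 and missing ./.
    """
    gt_map = {MISSING: "./.", P1: "0/0", P2: "1/1", HET: "0/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=binmapper\n")
        for chrom, L in chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={L}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = [p1_name, p2_name] + list(ril_names)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for j, rec in enumerate(snps.itertuples(index=False)):
            gts = ["0/0", "1/1"] + [gt_map[int(code)] for code in obs[:, j]]
            fh.write(f"{rec.chrom}\t{rec.pos}\t.\t{rec.allele_p1}\t{rec.allele_p2}"
                     f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")


def read_vcf(path, p1_name: str = "P1", p2_name: str = "P2"):
    """Read a biparental VCF into a SNP table and an observation matrix.

    Genotypes are re-expressed relative to the two named parent samples.
    Multi-allelic records and records where either parent is missing or
    heterozygous are skipped and counted.  Returns (snps, obs, ril_names,
    skip counts); the SNP table includes the per-RIL missing fraction.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = vcf.samples
    for name in (p1_name, p2_name):
        if name not in samples:
            raise ValueError(f"parent sample {name!r} absent from VCF")
    i_p1 = samples.index(p1_name)
    i_p2 = samples.index(p2_name)
    ril_idx = [i for i in range(len(samples)) if i not in (i_p1, i_p2)]
    ril_names = [samples[i] for i in ril_idx]
    skipped = {"multiallelic": 0, "parent_missing": 0, "parent_monomorphic": 0}
    snp_rows = []
    obs_cols = []
    for v in vcf:
        if len(v.ALT) != 1:
            skipped["multiallelic"] += 1
            continue
        gt = v.gt_types  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        t1, t2 = gt[i_p1], gt[i_p2]
        if t1 in (1, 2) or t2 in (1, 2):
            skipped["parent_missing"] += 1
            continue
        if t1 == t2:
            skipped["parent_monomorphic"] += 1
            continue
        p1_is_ref = t1 == 0
        codes = np.empty(len(ril_idx), dtype=np.int8)
        sub = gt[ril_idx]
        codes[sub == 2] = MISSING
        codes[sub == 1] = HET
        codes[sub == 0] = P1 if p1_is_ref else P2
        codes[sub == 3] = P2 if p1_is_ref else P1
        allele_p1 = v.REF if p1_is_ref else v.ALT[0]
        allele_p2 = v.ALT[0] if p1_is_ref else v.REF
        snp_rows.append((v.CHROM, v.POS, allele_p1, allele_p2,
                         float(np.mean(codes == MISSING))))
        obs_cols.append(codes)
    snps = pd.DataFrame(snp_rows, columns=["chrom", "pos", "allele_p1",
                                           "allele_p2", "missing_frac"])
    obs = (np.column_stack(obs_cols) if obs_cols
           else np.empty((len(ril_idx), 0), dtype=np.int8))
    return snps, obs, ril_names, skipped


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: Dict[str, str]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# TSV tables


def write_tracks(path, tracks: np.ndarray, snps: pd.DataFrame,
                 ril_names: List[str]) -> None:
    """Genotype-track TSV: rows are RILs, columns are chrom:pos markers."""
    cols = [f"{c}:{p}" for c, p in zip(snps["chrom"], snps["pos"])]
    df = pd.DataFrame(calls_to_symbols(tracks), index=ril_names, columns=cols)
    df.to_csv(path, sep="\t", index_label="ril_id")


def read_tracks(path) -> Tuple[np.ndarray, pd.DataFrame, List[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    chrom_pos = [c.rsplit(":", 1) for c in df.columns]
    snps = pd.DataFrame({"chrom": [c for c, _ in chrom_pos],
                         "pos": [int(p) for _, p in chrom_pos]})
    return symbols_to_calls(df.to_numpy()), snps, list(df.index)


def write_bins(bed_path, matrix_path, binset, ril_names: List[str]) -> None:
    """Bins as BED plus a bins-x-RILs genotype matrix TSV."""
    bed = binset.bins[["chrom", "start", "end", "bin_id"]]
    bed.to_csv(bed_path, sep="\t", header=False, index=False)
    mat = pd.DataFrame(calls_to_symbols(binset.genotypes),
                       index=binset.bins["bin_id"], columns=ril_names)
    mat.to_csv(matrix_path, sep="\t", index_label="bin_id")


def read_bins(bed_path, matrix_path):
    from .binmap import BinSet

    bed = pd.read_csv(bed_path, sep="\t", header=None,
                      names=["chrom", "start", "end", "bin_id"])
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
    bins = bed[["bin_id", "chrom", "start", "end"]]
    return BinSet(bins=bins, genotypes=symbols_to_calls(mat.to_numpy())), list(mat.columns)


def write_agp(path, agp: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        agp.to_csv(fh, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Truth / manifest JSON


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
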