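"""Readers and writers for the small set of text formats the pipeline exchanges.

Coordinate conventions follow each format: VCF-like variant tables and the
GWAS catalog are 1-based; BED and bedGraph are 0-based half-open.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from esnp.ld import HaplotypePanel, LdError

logger = logging.getLogger(__name__)

VARIANT_COLUMNS = ["snp_id", "chrom", "position", "ref", "alt"]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into a {name: uppercase sequence} dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Haplotype panel: matrix TSV + variants TSV, and a minimal VCF route
# ---------------------------------------------------------------------------

def write_panel(panel: HaplotypePanel, matrix_path: str | Path, variants_path: str | Path) -> None:
    """Write a panel as a haplotype matrix TSV (rows = haplotypes, columns =
    variants, values 0/1) plus a variants table TSV."""
    mat = pd.DataFrame(panel.matrix, columns=panel.variant_ids)
    mat.to_csv(matrix_path, sep="\t", index=False)
    pd.DataFrame({
        "snp_id": panel.variant_ids,
        "chrom": panel.chroms,
        "position": panel.positions,
        "ref": panel.ref_alleles,
        "alt": panel.alt_alleles,
    }).to_csv(variants_path, sep="\t", index=False)


def read_panel(matrix_path: str | Path, variants_path: str | Path) -> HaplotypePanel:
    mat = pd.read_csv(matrix_path, sep="\t")
    var = pd.read_csv(variants_path, sep="\t")
    missing = set(mat.columns) ^ set(var["snp_id"])
    if missing:
        raise LdError(f"matrix columns and variants table disagree on: {sorted(missing)}")
    var = var.set_index("snp_id").loc[list(mat.columns)].reset_index()
    return HaplotypePanel(
        variant_ids=list(var["snp_id"]),
        chroms=list(var["chrom"].astype(str)),
        positions=var["position"].to_numpy(),
        ref_alleles=list(var["ref"].astype(str)),
        alt_alleles=list(var["alt"].astype(str)),
        matrix=mat.to_numpy(),
    )


def write_vcf(panel: HaplotypePanel, path: str | Path) -> None:
    """Write the panel as a minimal phased VCF 4.2 (GT-only, one sample per
    haplotype pair; an odd trailing haplotype is dropped with a warning)."""
    n_hap = panel.n_haplotypes
    n_ind = n_hap // 2
    if n_hap % 2:
        logger.warning("odd haplotype count %d: last haplotype not representable in VCF", n_hap)
    samples = [f"S{i:04d}" for i in range(n_ind)]
    order = np.argsort(
        np.array([(c, p) for c, p in zip(panel.chroms, panel.positions)],
                 dtype=[("c", "U32"), ("p", np.int64)]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for vi in order:
            col = panel.matrix[:, vi]
            gts = "\t".join(f"{col[2*i]}|{col[2*i+1]}" for i in range(n_ind))
            fh.write(
                f"{panel.chroms[vi]}\t{panel.positions[vi]}\t{panel.variant_ids[vi]}\t"
                f"{panel.ref_alleles[vi]}\t{panel.alt_alleles[vi]}\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path: str | Path) -> tuple[HaplotypePanel | None, pd.DataFrame]:
    """Read a GT-only VCF.

    Returns ``(panel, genotypes)``: if every record is fully phased ("|"
    separators throughout), ``panel`` is a :class:`HaplotypePanel`;
    otherwise ``panel`` is None and callers should use the returned dosage
    table (variants x samples, values 0/1/2, -1 missing) with the EM route.
    """
    ids, chroms, poss, refs, alts = [], [], [], [], []
    hap_cols: list[list[int]] = []
    dose_cols: list[list[int]] = []
    all_phased = True
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, pos, vid, ref, alt = parts[0], int(parts[1]), parts[2], parts[3], parts[4]
            fmt = parts[8].split(":")
            gt_i = fmt.index("GT")
            if "," in alt:
                raise LdError(f"multi-allelic site {vid} not supported; "
                              "restrict the panel to the two RefSNP alleles")
            haps: list[int] = []
            doses: list[int] = []
            for sample in parts[9:]:
                gt = sample.split(":")[gt_i]
                phased = "|" in gt
                sep = "|" if phased else "/"
                alleles = gt.split(sep)
                if not phased:
                    all_phased = False
                vals = [-1 if a == "." else int(a) for a in alleles]
                if any(v > 1 for v in vals):
                    raise LdError(f"multi-allelic genotype at {vid}")
                haps.extend(vals)
                doses.append(-1 if any(v < 0 for v in vals) else sum(vals))
            ids.append(vid); chroms.append(chrom); poss.append(pos)
            refs.append(ref); alts.append(alt)
            hap_cols.append(haps)
            dose_cols.append(doses)
    genotypes = pd.DataFrame(
        np.array(dose_cols, dtype=np.int64),
        index=ids,
    )
    genotypes.insert(0, "chrom", chroms)
    genotypes.insert(1, "position", poss)
    panel = None
    if all_phased and hap_cols and all(-1 not in h for h in hap_cols):
        panel = HaplotypePanel(
            variant_ids=ids, chroms=chroms, positions=np.array(poss),
            ref_alleles=refs, alt_alleles=alts,
            matrix=np.array(hap_cols, dtype=np.int8).T,
        )
    return panel, genotypes


def read_variants(path: str | Path) -> pd.DataFrame:
    """Read a variants TSV (snp_id, chrom, position, ref, alt; 1-based)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(VARIANT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"variants table missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# bedGraph / BED
# ---------------------------------------------------------------------------

def _read_track_lines(path: str | Path, n_fields: int, names: list[str]) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            rows.append(parts[:n_fields])
    df = pd.DataFrame(rows, columns=names)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """bedGraph -> DataFrame[chrom, start, end, value] (0-based half-open)."""
    df = _read_track_lines(path, 4, ["chrom", "start", "end", "value"])
    df["value"] = df["value"].astype(float)
    return df


def read_bed(path: str | Path) -> pd.DataFrame:
    """BED (3+ columns; column 4 kept as ``name`` when present)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            rows.append(parts[:4] if len(parts) >= 4 else parts[:3] + [""])
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def write_bedgraph(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False,
              columns=["chrom", "start", "end", "value"], float_format="%.6g")


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = ["chrom", "start", "end"] + (["name"] if "name" in df.columns else [])
    df.to_csv(path, sep="\t", header=False, index=False, columns=cols)
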