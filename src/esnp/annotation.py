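"""Genomic-context classification of SNPs against gene models.

Categories follow the conventional annotation precedence
(exonic > splicing > UTR > intronic > upstream/downstream > intergenic);
upstream/downstream means within 1 kb of the transcript ends, splicing
within 2 bp of an exon boundary inside an intron.  The promoter filter
drops candidate enhancer SNPs lying in a strand-aware window around any
transcription start site (default 2 kb upstream to 500 bp downstream),
since promoters share much of the enhancer epigenetic signature.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

UPDOWNSTREAM_BP = 1000
SPLICE_BP = 2
PROMOTER_WINDOW = (2000, 500)  # (upstream_bp, downstream_bp) of the TSS

#: Category precedence, strongest first.
PRECEDENCE = ["exonic", "splicing", "5'UTR", "3'UTR", "intronic",
              "upstream", "downstream", "intergenic"]
_RANK = {c: i for i, c in enumerate(PRECEDENCE)}


class GeneModelError(ValueError):
    pass


@dataclass
class GeneModel:
    """One gene: transcript span, exons and optional CDS, 1-based inclusive."""

    gene_id: str
    chrom: str
    strand: str
    transcript: tuple[int, int]
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise GeneModelError(f"{self.gene_id}: strand must be + or -")
        t0, t1 = self.transcript
        for s, e in self.exons:
            if s < t0 or e > t1:
                raise GeneModelError(
                    f"{self.gene_id}: exon [{s},{e}] outside transcript [{t0},{t1}]")

    @property
    def tss(self) -> int:
        return self.transcript[0] if self.strand == "+" else self.transcript[1]


@dataclass
class LocationCall:
    snp_id: str
    category: str
    genes: list[str]
    tss_distance: float  # bp to nearest TSS; inf when no genes on the chromosome


def _classify_against_gene(pos: int, gene: GeneModel) -> str | None:
    t0, t1 = gene.transcript
    if t0 <= pos <= t1:
        for s, e in sorted(gene.exons):
            if s <= pos <= e:
                if gene.cds:
                    if any(cs <= pos <= ce for cs, ce in gene.cds):
                        return "exonic"
                    cds_lo = min(cs for cs, _ in gene.cds)
                    cds_hi = max(ce for _, ce in gene.cds)
                    if pos < cds_lo:
                        return "5'UTR" if gene.strand == "+" else "3'UTR"
                    if pos > cds_hi:
                        return "3'UTR" if gene.strand == "+" else "5'UTR"
                return "exonic"
        # intron: check splice proximity to flanking exon boundaries
        for s, e in sorted(gene.exons):
            if 0 < s - pos <= SPLICE_BP or 0 < pos - e <= SPLICE_BP:
                return "splicing"
        return "intronic"
    if gene.strand == "+":
        if 0 < t0 - pos <= UPDOWNSTREAM_BP:
            return "upstream"
        if 0 < pos - t1 <= UPDOWNSTREAM_BP:
            return "downstream"
    else:
        if 0 < pos - t1 <= UPDOWNSTREAM_BP:
            return "upstream"
        if 0 < t0 - pos <= UPDOWNSTREAM_BP:
            return "downstream"
    return None


def classify_location(snp_id: str, chrom: str, position: int,
                      genes: list[GeneModel]) -> LocationCall:
    """Assign one category per SNP by precedence over all overlapping genes.

    A SNP hitting features of several genes reports every such gene but a
    single category (the strongest by precedence).  With no gene models on
    the SNP's chromosome the call is intergenic with infinite TSS distance,
    flagged via a warning.
    """
    on_chrom = [g for g in genes if g.chrom == chrom]
    if not on_chrom:
        logger.warning("no gene models on %s; %s called intergenic by default", chrom, snp_id)
        return LocationCall(snp_id, "intergenic", [], math.inf)

    hits: list[tuple[str, str]] = []  # (category, gene_id)
    for g in sorted(on_chrom, key=lambda g: (g.transcript, g.gene_id)):
        cat = _classify_against_gene(position, g)
        if cat is not None:
            hits.append((cat, g.gene_id))
    tss_dist = min(abs(position - g.tss) for g in on_chrom)
    if not hits:
        nearest = min(abs(position - g.tss) for g in on_chrom)
        nearest_genes = sorted(g.gene_id for g in on_chrom
                               if abs(position - g.tss) == nearest)
        return LocationCall(snp_id, "intergenic", nearest_genes, float(tss_dist))
    best = min(_RANK[c] for c, _ in hits)
    category = PRECEDENCE[best]
    gene_ids = sorted({gid for c, gid in hits if _RANK[c] == best})
    return LocationCall(snp_id, category, gene_ids, float(tss_dist))


def promoter_filter(
    snps: pd.DataFrame, genes: list[GeneModel],
    promoter_window: tuple[int, int] = PROMOTER_WINDOW,
) -> pd.DataFrame:
    """Drop candidate eSNPs lying within a promoter window of any TSS.

    ``snps`` needs columns snp_id, chrom, position (1-based).  The window
    is strand-aware: for a + strand gene it is
    ``[tss - upstream, tss + downstream]``, mirrored for - strand.  Returns
    the input with ``retained`` and ``reason`` columns added.
    """
    up, down = promoter_window
    retained, reasons = [], []
    for _, row in snps.iterrows():
        pos, chrom = int(row["position"]), str(row["chrom"])
        hit = None
        for g in genes:
            if g.chrom != chrom:
                continue
            if g.strand == "+":
                lo, hi = g.tss - up, g.tss + down
            else:
                lo, hi = g.tss - down, g.tss + up
            if lo <= pos <= hi:
                hit = g
                break
        if hit is None:
            retained.append(True)
            reasons.append("outside_promoter_windows")
        else:
            retained.append(False)
            reasons.append(f"within_promoter_of_{hit.gene_id}")
    out = snps.copy()
    out["retained"] = retained
    out["reason"] = reasons
    return out


def promoter_filter_by_state(
    snps: pd.DataFrame, states: pd.DataFrame,
    window_bp: int = 500, promoter_label: str = "promoter",
) -> pd.DataFrame:
    """Alternative promoter exclusion using the chromatin-state segmentation.

    Drops SNPs whose centered window overlaps any interval labeled with the
    promoter state; mirrors judging promoter proximity from a segmentation
    track's coloring rather than from annotated TSS distance.
    """
    half = window_bp // 2
    retained, reasons = [], []
    for _, row in snps.iterrows():
        pos0 = int(row["position"]) - 1
        sub = states[(states["chrom"] == str(row["chrom"])) & (states["name"] == promoter_label)]
        hit = ((sub["start"] < pos0 + half) & (sub["end"] > pos0 - half)).any()
        retained.append(not hit)
        reasons.append("overlaps_promoter_state" if hit else "outside_promoter_state")
    out = snps.copy()
    out["retained"] = retained
    out["reason"] = reasons
    return out


# ---------------------------------------------------------------------------
# GFF-like gene-model reader (gene/mRNA/exon/CDS subset, 1-based inclusive)
# ---------------------------------------------------------------------------

def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Load gene models from a GFF3-subset file.

    Recognized feature types: ``gene`` (one per gene, gives strand and
    transcript span via ID=...), ``exon`` and ``CDS`` (Parent=...).
    Validation errors (exon outside its transcript) surface at load time.
    """
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise GeneModelError(f"malformed GFF line: {line!r}")
            chrom, _, ftype, start, end, _, strand, _, attrs = f[:9]
            att = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if ftype == "gene":
                gid = att.get("ID", f"gene{len(genes)}")
                genes[gid] = {"chrom": chrom, "strand": strand,
                              "transcript": (int(start), int(end)),
                              "exons": [], "cds": []}
            elif ftype in {"exon", "CDS"}:
                parent = att.get("Parent")
                if parent not in genes:
                    raise GeneModelError(f"{ftype} with unknown Parent {parent!r}")
                key = "exons" if ftype == "exon" else "cds"
                genes[parent][key].append((int(start), int(end)))
    return [GeneModel(gene_id=gid, **spec) for gid, spec in genes.items()]


def write_gene_models(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.transcript)):
            t0, t1 = g.transcript
            fh.write(f"{g.chrom}\t.\tgene\t{t0}\t{t1}\t.\t{g.strand}\t.\tID={g.gene_id}\n")
            for s, e in sorted(g.exons):
                fh.write(f"{g.chrom}\t.\texon\t{s}\t{e}\t.\t{g.strand}\t.\tParent={g.gene_id}\n")
            for s, e in sorted(g.cds):
                fh.write(f"{g.chrom}\t.\tCDS\t{s}\t{e}\t.\t{g.strand}\t.\tParent={g.gene_id}\n")
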