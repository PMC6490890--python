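"""GWAS catalog parsing, filtering, and grouping into independent signals.

An "independent signal" is a cluster of associated SNPs in strong LD,
separated from other clusters by more than ``gap_bp``; clustering is
single-linkage on the graph where two records link iff they share a
chromosome and are either within ``gap_bp`` of each other or in strong LD.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

P_MAX = 1e-5            # associations must be stronger than this (strict <)
PLATFORM_MIN = 100_000  # minimum SNPs assayed on the platform (inclusive >=)
GAP_BP = 100_000        # clusters further apart than this are independent
R2_STRONG = 0.8

#: Blood-lipid trait vocabulary used for the default trait filter.
LIPID_TRAITS = (
    "LDL", "HDL", "TG", "HDL-TG", "total cholesterol", "cholesterol",
    "lipid metabolism", "TG-BP", "response to statin",
)

CATALOG_COLUMNS = [
    "snp_id", "chrom", "position", "trait", "p_value", "ancestry",
    "platform_snp_count", "publication_id",
]


@dataclass(frozen=True)
class AssociationRecord:
    """One SNP-trait association as curated in a GWAS catalog."""

    snp_id: str
    chrom: str
    position: int  # 1-based bp
    trait: str
    p_value: float
    ancestry: str
    platform_snp_count: int
    publication_id: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.p_value <= 1):
            raise ValueError(f"p-value out of (0,1]: {self.p_value}")
        if self.position < 1:
            raise ValueError(f"position must be >= 1: {self.position}")


@dataclass
class SignalCluster:
    """A group of associated SNPs treated as one independent signal."""

    cluster_id: int
    chrom: str
    members: list[str]
    span: tuple[int, int]
    representative: str
    traits: list[str]


def _norm(name: str) -> str:
    return re.sub(r"\s+", " ", name.strip()).lower()


def read_catalog(path: str | Path, column_map: dict[str, str] | None = None) -> list[AssociationRecord]:
    """Read a GWAS-catalog-style TSV into association records.

    ``column_map`` maps our canonical field names to the file's column
    headers when they differ.  Records with unparseable p-values are
    rejected with a logged warning rather than aborting the load.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cmap = {c: c for c in CATALOG_COLUMNS}
    if column_map:
        cmap.update(column_map)
    records: list[AssociationRecord] = []
    for _, row in df.iterrows():
        try:
            p = float(row[cmap["p_value"]])
            rec = AssociationRecord(
                snp_id=str(row[cmap["snp_id"]]),
                chrom=str(row[cmap["chrom"]]),
                position=int(row[cmap["position"]]),
                trait=str(row[cmap["trait"]]),
                p_value=p,
                ancestry=str(row[cmap["ancestry"]]),
                platform_snp_count=int(row[cmap["platform_snp_count"]]),
                publication_id=str(row.get(cmap["publication_id"], "")),
            )
        except (ValueError, TypeError) as exc:
            logger.warning("rejecting catalog row %s: %s", dict(row), exc)
            continue
        records.append(rec)
    return records


def filter_catalog(
    records: Iterable[AssociationRecord],
    traits: Sequence[str] = LIPID_TRAITS,
    ancestries: Sequence[str] = ("European", "European-American"),
    p_max: float = P_MAX,
    platform_min: int = PLATFORM_MIN,
) -> list[AssociationRecord]:
    """Apply the four catalog filters and deduplicate.

    Keeps records whose trait and ancestry match the given vocabularies
    (case-insensitively, after whitespace normalization), whose p-value is
    strictly below ``p_max``, and whose platform assayed at least
    ``platform_min`` SNPs (inclusive).  Identical (snp, trait, publication)
    triples are kept once.
    """
    trait_set = {_norm(t) for t in traits}
    anc_set = {_norm(a) for a in ancestries}
    seen: set[tuple[str, str, str]] = set()
    out: list[AssociationRecord] = []
    for rec in records:
        if _norm(rec.trait) not in trait_set:
            continue
        if _norm(rec.ancestry) not in anc_set:
            continue
        if not (rec.p_value < p_max):
            continue
        if rec.platform_snp_count < platform_min:
            continue
        key = (rec.snp_id, _norm(rec.trait), rec.publication_id)
        if key in seen:
            continue
        seen.add(key)
        out.append(rec)
    return out


def cluster_signals(
    records: Sequence[AssociationRecord],
    ld_source: Callable[[str, str], float | None] | None = None,
    gap_bp: int = GAP_BP,
    r2_strong: float = R2_STRONG,
) -> list[SignalCluster]:
    """Group records into independent signals by single-linkage clustering.

    Two SNPs link iff they are on the same chromosome AND (their distance is
    <= ``gap_bp``, boundary inclusive, OR their r-squared from ``ld_source``
    is >= ``r2_strong``).  ``ld_source`` is an optional callable
    ``(snp1, snp2) -> r2 | None``; ``None`` (either the callable or its
    return) falls back to distance-only linkage for that pair, logged.
    The result is order-invariant: records are sorted internally.
    """
    recs = sorted(records, key=lambda r: (r.chrom, r.position, r.snp_id))
    n = len(recs)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    for i in range(n):
        for j in range(i + 1, n):
            if recs[i].chrom != recs[j].chrom:
                continue
            if abs(recs[i].position - recs[j].position) <= gap_bp:
                union(i, j)
                continue
            if ld_source is not None:
                r2 = ld_source(recs[i].snp_id, recs[j].snp_id)
                if r2 is None:
                    logger.debug("no LD available for %s-%s; distance-only linkage",
                                 recs[i].snp_id, recs[j].snp_id)
                elif r2 >= r2_strong:
                    union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    clusters: list[SignalCluster] = []
    for cid, root in enumerate(sorted(groups)):
        idx = groups[root]
        members = sorted({recs[i].snp_id for i in idx})
        rep = min(
            (recs[i] for i in idx),
            key=lambda r: (r.p_value, r.position, r.snp_id),
        )
        clusters.append(SignalCluster(
            cluster_id=cid,
            chrom=recs[idx[0]].chrom,
            members=members,
            span=(min(recs[i].position for i in idx), max(recs[i].position for i in idx)),
            representative=rep.snp_id,
            traits=sorted({recs[i].trait for i in idx}),
        ))
    return clusters


def clusters_to_frame(clusters: Sequence[SignalCluster]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "cluster_id": c.cluster_id,
            "chrom": c.chrom,
            "span_start": c.span[0],
            "span_end": c.span[1],
            "n_members": len(c.members),
            "representative": c.representative,
            "members": ",".join(c.members),
            "traits": ",".join(c.traits),
        }
        for c in clusters
    ])
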