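"""Two-locus linkage disequilibrium from phased haplotypes or unphased genotypes.

Statistics follow the classical definitions: for alleles A/a at locus 1 and
B/b at locus 2 with haplotype frequency p_AB,

    D   = p_AB - p_A * p_B
    D'  = |D| / D_max,  D_max = min(p_A q_B, q_A p_B) if D > 0
                               else min(p_A p_B, q_A q_B)
    r^2 = D^2 / (p_A q_A p_B q_B)

(q = 1 - p).  Phased panels are counted directly; unphased genotypes go
through the standard two-locus EM over the double-heterozygote phase
ambiguity.  Both routes return an :class:`LdStats`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EM_TOL = 1e-8
EM_MAX_ITER = 1000
PROXY_WINDOW_BP = 500_000  # default search radius around a seed SNP


class LdError(ValueError):
    """Raised when LD is undefined or inputs are malformed."""


class MonomorphicLocusError(LdError):
    """LD is undefined when either locus has allele frequency 0 or 1."""


@dataclass(frozen=True)
class LdStats:
    """D, D' and r-squared for one ordered locus pair.

    ``method`` records how haplotype frequencies were obtained:
    ``phased_count`` (direct counting) or ``em`` (maximum likelihood from
    unphased genotypes).  ``n_obs`` is the number of chromosomes used.
    """

    d: float
    d_prime: float
    r2: float
    n_obs: int
    method: str

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.r2 <= 1 + 1e-9):
            raise LdError(f"r2 out of range: {self.r2}")
        if not (-1e-9 <= self.d_prime <= 1 + 1e-9):
            raise LdError(f"D' out of range: {self.d_prime}")


@dataclass
class HaplotypePanel:
    """Phased biallelic haplotypes for a reference population.

    ``matrix`` is (n_haplotypes, n_variants) with entries 0 (reference-like
    allele) / 1 (alternate allele).  Positions are 1-based base pairs.
    """

    variant_ids: list[str]
    chroms: list[str]
    positions: np.ndarray  # 1-based bp, int
    ref_alleles: list[str]
    alt_alleles: list[str]
    matrix: np.ndarray  # (n_hap, n_var) of 0/1
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.variant_ids):
            raise LdError(
                "haplotype matrix shape does not match variant count: "
                f"{self.matrix.shape} vs {len(self.variant_ids)} variants"
            )
        bad = set(np.unique(self.matrix)) - {0, 1}
        if bad:
            raise LdError(f"haplotype matrix entries must be 0/1, found {sorted(bad)}")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}
        if len(self._index) != len(self.variant_ids):
            raise LdError("duplicate variant ids in panel")

    @property
    def n_haplotypes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_variants(self) -> int:
        return self.matrix.shape[1]

    def column(self, variant_id: str) -> np.ndarray:
        try:
            return self.matrix[:, self._index[variant_id]]
        except KeyError:
            raise KeyError(f"variant {variant_id!r} not in panel") from None

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def index_of(self, variant_id: str) -> int:
        return self._index[variant_id]


def ld_from_counts(
    n_ab_both: float, n_a_only: float, n_b_only: float, n_neither: float, method: str = "phased_count"
) -> LdStats:
    """LD statistics from the four haplotype counts (AB, Ab, aB, ab).

    Counts may be fractional (as produced by EM expected counts).
    """
    n = n_ab_both + n_a_only + n_b_only + n_neither
    if n <= 0:
        raise LdError("no observations")
    p_ab = n_ab_both / n
    p_a = (n_ab_both + n_a_only) / n
    p_b = (n_ab_both + n_b_only) / n
    return _ld_from_freqs(p_ab, p_a, p_b, int(round(n)), method)


def _ld_from_freqs(p_ab: float, p_a: float, p_b: float, n_obs: int, method: str) -> LdStats:
    q_a, q_b = 1.0 - p_a, 1.0 - p_b
    if p_a <= 0 or p_a >= 1 or p_b <= 0 or p_b >= 1:
        raise MonomorphicLocusError(
            f"LD undefined: allele frequencies p_A={p_a:.4g}, p_B={p_b:.4g} "
            "(each must lie strictly between 0 and 1)"
        )
    d = p_ab - p_a * p_b
    if d > 0:
        d_max = min(p_a * q_b, q_a * p_b)
    elif d < 0:
        d_max = min(p_a * p_b, q_a * q_b)
    else:
        d_max = 1.0  # D'=0 by convention
    d_prime = abs(d) / d_max if d_max > 0 else 0.0
    r2 = d * d / (p_a * q_a * p_b * q_b)
    # clamp tiny float excursions
    return LdStats(
        d=d,
        d_prime=min(max(d_prime, 0.0), 1.0),
        r2=min(max(r2, 0.0), 1.0),
        n_obs=n_obs,
        method=method,
    )


def ld_from_haplotypes(panel: HaplotypePanel, locus1: str, locus2: str) -> LdStats:
    """Count haplotypes for two panel loci and return their LD statistics.

    Raises :class:`MonomorphicLocusError` if either locus is fixed in the
    panel (LD would be 0/0, which we refuse to silently return as NaN).
    """
    h1 = panel.column(locus1)
    h2 = panel.column(locus2)
    n = len(h1)
    n11 = int(np.sum((h1 == 1) & (h2 == 1)))
    n10 = int(np.sum((h1 == 1) & (h2 == 0)))
    n01 = int(np.sum((h1 == 0) & (h2 == 1)))
    n00 = n - n11 - n10 - n01
    return ld_from_counts(n11, n10, n01, n00)


# ---------------------------------------------------------------------------
# EM for unphased genotypes
# ---------------------------------------------------------------------------

def genotype_table(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """3x3 cross-tabulation of genotype dosages; missing (<0 or NaN) dropped pairwise."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    keep = (
        np.isfinite(g1) & np.isfinite(g2) & (g1 >= 0) & (g2 >= 0)
    )
    g1, g2 = g1[keep].astype(int), g2[keep].astype(int)
    if np.any((g1 > 2) | (g2 > 2)):
        raise LdError("genotype codes must be in {0,1,2}")
    tab = np.zeros((3, 3), dtype=np.int64)
    np.add.at(tab, (g1, g2), 1)
    return tab


def genotype_loglik(freqs: np.ndarray, table: np.ndarray) -> float:
    """Multinomial log-likelihood of a 3x3 genotype table given haplotype freqs.

    ``freqs`` = (p_AB, p_Ab, p_aB, p_ab) under random mating (HWE at the
    haplotype level); genotype-class probabilities are sums over compatible
    ordered haplotype pairs.
    """
    pab, pAb, paB, paa = float(freqs[0]), float(freqs[1]), float(freqs[2]), float(freqs[3])
    p = {
        (2, 2): pab * pab,
        (2, 1): 2 * pab * pAb,
        (2, 0): pAb * pAb,
        (1, 2): 2 * pab * paB,
        (1, 1): 2 * pab * paa + 2 * pAb * paB,
        (1, 0): 2 * pAb * paa,
        (0, 2): paB * paB,
        (0, 1): 2 * paB * paa,
        (0, 0): paa * paa,
    }
    ll = 0.0
    for (i, j), prob in p.items():
        nij = table[i, j]
        if nij:
            if prob <= 0:
                return -math.inf
            ll += nij * math.log(prob)
    return ll


def em_haplotype_freqs(
    g1: np.ndarray,
    g2: np.ndarray,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
) -> tuple[np.ndarray, LdStats]:
    """Maximum-likelihood two-locus haplotype frequencies from unphased genotypes.

    Only double heterozygotes (1,1) are phase-ambiguous; the E step splits
    them between the AB/ab and Ab/aB phases in proportion to the current
    haplotype-frequency products, the M step re-counts.  Initialization is
    the linkage-equilibrium product of allele frequencies; convergence when
    the largest absolute frequency change drops below ``tol``.

    Returns ``(freqs, stats)`` with ``freqs = (p_AB, p_Ab, p_aB, p_ab)``
    summing to 1 and ``stats.method == "em"``.
    """
    tab = genotype_table(g1, g2)
    n_ind = int(tab.sum())
    if n_ind == 0:
        raise LdError("all genotypes missing: cannot estimate haplotype frequencies")
    n_chrom = 2 * n_ind

    # known haplotype counts from unambiguous genotype classes
    base = np.zeros(4)  # AB, Ab, aB, ab ; locus-1 dosage counts ALT as "A"
    for i in range(3):
        for j in range(3):
            nij = tab[i, j]
            if nij == 0 or (i == 1 and j == 1):
                continue
            # each individual contributes two gametes with known phase
            a_doses = [1] * i + [0] * (2 - i)
            b_doses = [1] * j + [0] * (2 - j)
            # for non-double-het classes the pairing is forced
            for a, b in zip(sorted(a_doses, reverse=True), sorted(b_doses, reverse=True)):
                base[_hap_index(a, b)] += nij
    n_dh = tab[1, 1]

    p_a = (2 * tab[2, :].sum() + tab[1, :].sum()) / n_chrom
    p_b = (2 * tab[:, 2].sum() + tab[:, 1].sum()) / n_chrom
    q_a, q_b = 1 - p_a, 1 - p_b
    le = np.array([p_a * p_b, p_a * q_b, q_a * p_b, q_a * q_b])
    # the LE point is a stationary point of the likelihood for symmetric
    # tables (EM can sit on the D=0 saddle), so also start from +/-D inits
    d_half = 0.5 * min(p_a * q_b, q_a * p_b)
    starts = [le]
    for d in (d_half, -0.5 * min(p_a * p_b, q_a * q_b)):
        cand = le + np.array([d, -d, -d, d])
        if np.all(cand > 0):
            starts.append(cand / cand.sum())

    best_freqs, best_ll = None, -math.inf
    for init in starts:
        freqs = init
        for _ in range(max_iter):
            if n_dh:
                w_cis = freqs[0] * freqs[3]
                w_trans = freqs[1] * freqs[2]
                denom = w_cis + w_trans
                frac_cis = 0.5 if denom <= 0 else w_cis / denom
            else:
                frac_cis = 0.0
            counts = base.copy()
            if n_dh:
                counts[0] += n_dh * frac_cis
                counts[3] += n_dh * frac_cis
                counts[1] += n_dh * (1 - frac_cis)
                counts[2] += n_dh * (1 - frac_cis)
            new = counts / n_chrom
            delta = np.max(np.abs(new - freqs))
            freqs = new
            if delta < tol:
                break
        ll = genotype_loglik(freqs, tab)
        if ll > best_ll:
            best_freqs, best_ll = freqs, ll

    freqs = best_freqs
    stats = _ld_from_freqs(freqs[0], freqs[0] + freqs[1], freqs[0] + freqs[2], n_chrom, "em")
    return freqs, stats


def _hap_index(a: int, b: int) -> int:
    return {(1, 1): 0, (1, 0): 1, (0, 1): 2, (0, 0): 3}[(a, b)]


# ---------------------------------------------------------------------------
# Pipeline filters
# ---------------------------------------------------------------------------

@dataclass
class ProxyExpansion:
    """Result of LD proxy expansion: one row per retained (seed, proxy) pair."""

    table: pd.DataFrame  # seed_snp, proxy_snp, chrom, position, distance_bp, d, d_prime, r2, n_obs, method
    skipped_seeds: list[str]


def expand_proxies(
    panel: HaplotypePanel,
    seed_snps: list[str],
    r2_min: float = 0.3,
    window_bp: int = PROXY_WINDOW_BP,
) -> ProxyExpansion:
    """Expand each GWAS seed SNP to all panel SNPs in LD with it.

    For every seed present in the panel, every panel variant on the same
    chromosome within ``window_bp`` whose r-squared with the seed is at
    least ``r2_min`` (inclusive) is returned; the seed itself is always
    included (r-squared 1 by definition).  Monomorphic partners are
    skipped (their LD is undefined).  Seeds absent from the panel are
    skipped with a warning and recorded in ``skipped_seeds``.
    """
    rows = []
    skipped: list[str] = []
    for seed in seed_snps:
        if seed not in panel:
            logger.warning("seed SNP %s absent from reference panel; skipped", seed)
            skipped.append(seed)
            continue
        si = panel.index_of(seed)
        s_chrom = panel.chroms[si]
        s_pos = int(panel.positions[si])
        for vi, vid in enumerate(panel.variant_ids):
            if panel.chroms[vi] != s_chrom:
                continue
            dist = abs(int(panel.positions[vi]) - s_pos)
            if dist > window_bp:
                continue
            if vid == seed:
                stats = LdStats(d=0.0, d_prime=1.0, r2=1.0, n_obs=panel.n_haplotypes,
                                method="phased_count")
                # self-pair: report the panel's own D for completeness
                try:
                    stats = ld_from_haplotypes(panel, seed, seed)
                except MonomorphicLocusError:
                    logger.warning("seed SNP %s is monomorphic in the panel", seed)
                    skipped.append(seed)
                    break
            else:
                try:
                    stats = ld_from_haplotypes(panel, seed, vid)
                except MonomorphicLocusError:
                    continue
                if stats.r2 < r2_min:
                    continue
            rows.append({
                "seed_snp": seed,
                "proxy_snp": vid,
                "chrom": s_chrom,
                "position": int(panel.positions[vi]),
                "distance_bp": dist,
                "d": stats.d,
                "d_prime": stats.d_prime,
                "r2": stats.r2,
                "n_obs": stats.n_obs,
                "method": stats.method,
            })
    cols = ["seed_snp", "proxy_snp", "chrom", "position", "distance_bp",
            "d", "d_prime", "r2", "n_obs", "method"]
    table = pd.DataFrame(rows, columns=cols)
    return ProxyExpansion(table=table, skipped_seeds=skipped)


def strong_ld_filter(
    pairs: pd.DataFrame,
    r2_min: float = 0.8,
    dprime_min: float = 0.9,
) -> pd.DataFrame:
    """Keep (eSNP, GWAS SNP) pairs in strong LD: r^2 >= r2_min AND D' >= dprime_min.

    Both thresholds are inclusive.  Rows whose ``d_prime`` is missing (NaN)
    are judged through the algebraic lower bound D' >= sqrt(r^2), which holds
    for any allele frequencies; this lets published tables that print r^2
    only be filtered without fabricating a D' value.
    """
    if "r2" not in pairs.columns:
        raise LdError("pairs table must have an 'r2' column")
    r2 = pairs["r2"].astype(float)
    if "d_prime" in pairs.columns:
        dp = pairs["d_prime"].astype(float)
        dp = dp.where(dp.notna(), np.sqrt(r2))
    else:
        dp = np.sqrt(r2)
    keep = (r2 >= r2_min) & (dp >= dprime_min)
    return pairs.loc[keep].reset_index(drop=True)
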