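"""Synthetic study generator: every pipeline input, with planted ground truth.

The generator emulates the data a regulatory fine-mapping study consumes —
a GWAS association catalog, a phased reference haplotype panel with known
pairwise LD between seed SNPs and their proxies, epigenomic signal/peak/
state tracks with planted enhancer windows, gene models, a genome sequence
carrying an allele-sensitive motif site, and a JASPAR motif battery —
entirely from one integer seed, so each downstream stage can be tested
against planted truth without any external download.

Haplotype model: each (seed, proxy) pair is drawn from the four-haplotype
multinomial whose frequencies solve D = sign * sqrt(r2 * pA qA pB qB);
proxies are conditionally independent given their seed, background SNPs are
independent.  Signal model: lognormal background noise per fixed-width bin
with an additive Gaussian bump over planted windows on the enhancer marks
(open chromatin at promoters too, plus the promoter mark H3K4me3).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from esnp import io as eio
from esnp.annotation import GeneModel, write_gene_models
from esnp.enhancer import DEFAULT_MARKS, DEFAULT_STATES, TrackSet
from esnp.ld import HaplotypePanel, ld_from_counts
from esnp.motif import (BASE_INDEX, BASES, PWM, revcomp, score_percentile,
                        write_jaspar)

logger = logging.getLogger(__name__)

ENHANCER_MARKS = ("dnase", "h3k4me1", "h3k27ac")
PROMOTER_MARKS = ("dnase", "h3k4me3")
BIN_BP = 100
LOGNORMAL_SIGMA = 0.5
SIGNATURE_STRENGTH = 8.0
PROMOTER_HALF_BP = 500


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Two-locus haplotype simulation
# ---------------------------------------------------------------------------

def pair_haplotype_freqs(p_a: float, p_b: float, target_r2: float,
                         sign: int = 1) -> np.ndarray:
    """Population haplotype frequencies (AB, Ab, aB, ab) for a target r^2.

    Solves D = sign * sqrt(target_r2 * pA qA pB qB) and checks feasibility
    against the frequency bound on D; an infeasible triple raises with the
    violated bound named.
    """
    if not (0 < p_a < 1 and 0 < p_b < 1):
        raise SimulationError(f"allele frequencies must be in (0,1): pA={p_a}, pB={p_b}")
    if not (0 <= target_r2 <= 1):
        raise SimulationError(f"target r2 must be in [0,1]: {target_r2}")
    q_a, q_b = 1 - p_a, 1 - p_b
    d = sign * math.sqrt(target_r2 * p_a * q_a * p_b * q_b)
    d_max = min(p_a * q_b, q_a * p_b) if d >= 0 else min(p_a * p_b, q_a * q_b)
    if abs(d) > d_max + 1e-12:
        raise SimulationError(
            f"target r2={target_r2} infeasible at pA={p_a}, pB={p_b}: "
            f"|D|={abs(d):.6f} exceeds Dmax={d_max:.6f} "
            f"(bound min(pA*qB, qA*pB) for D>0, min(pA*pB, qA*qB) for D<0)")
    freqs = np.array([
        p_a * p_b + d,
        p_a * q_b - d,
        q_a * p_b - d,
        q_a * q_b + d,
    ])
    freqs = np.clip(freqs, 0.0, 1.0)
    return freqs / freqs.sum()


def simulate_haplotype_pair(p_a: float, p_b: float, target_r2: float,
                            n: int, seed: int, sign: int = 1) -> HaplotypePanel:
    """Draw ``n`` two-locus haplotypes from the target-r^2 multinomial.

    The population r^2 equals ``target_r2`` exactly; the sample r^2
    converges to it as n grows.
    """
    freqs = pair_haplotype_freqs(p_a, p_b, target_r2, sign)
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, freqs)
    # haplotype classes: AB=(1,1), Ab=(1,0), aB=(0,1), ab=(0,0)
    classes = np.array([[1, 1], [1, 0], [0, 1], [0, 0]], dtype=np.int8)
    matrix = np.repeat(classes, counts, axis=0)
    return HaplotypePanel(
        variant_ids=["locusA", "locusB"],
        chroms=["chrSim", "chrSim"],
        positions=np.array([1000, 2000]),
        ref_alleles=["A", "A"],
        alt_alleles=["G", "G"],
        matrix=matrix,
    )


def _conditional_proxy(h_seed: np.ndarray, p_a: float, p_b: float,
                       target_r2: float, sign: int, rng: np.random.Generator) -> np.ndarray:
    """Draw a proxy column with the target LD to an existing seed column."""
    f_ab, f_a_only, f_b_only, f_none = pair_haplotype_freqs(p_a, p_b, target_r2, sign)
    p_b_given_a = f_ab / (f_ab + f_a_only)
    p_b_given_not_a = f_b_only / (f_b_only + f_none)
    u = rng.random(len(h_seed))
    return np.where(h_seed == 1, u < p_b_given_a, u < p_b_given_not_a).astype(np.int8)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedPair:
    """One (GWAS seed SNP, proxy SNP) pair with a target population r^2."""

    seed_snp: str
    proxy_snp: str
    seed_position: int
    proxy_position: int
    target_r2: float
    p_seed: float = 0.5
    p_proxy: float = 0.5
    sign: int = 1

    @property
    def target_dprime(self) -> float:
        freqs = pair_haplotype_freqs(self.p_seed, self.p_proxy, self.target_r2, self.sign)
        return ld_from_counts(*(freqs * 1e6)).d_prime


@dataclass(frozen=True)
class EnhancerWindow:
    start: int  # 0-based half-open
    end: int
    strength: float = SIGNATURE_STRENGTH


@dataclass(frozen=True)
class MotifPlant:
    """Plant an allele-sensitive motif site at a SNP position."""

    snp_id: str
    matrix_id: str
    position: int  # 1-based


@dataclass
class SimConfig:
    """Full description of one synthetic study; seed fixed => identical bytes."""

    seed: int = 0
    chrom: str = "chr1"
    chrom_length: int = 1_000_000
    n_haplotypes: int = 2000
    planted_pairs: list[PlantedPair] = field(default_factory=list)
    n_background_snps: int = 40
    background_freq_range: tuple[float, float] = (0.2, 0.8)
    enhancer_windows: list[EnhancerWindow] = field(default_factory=list)
    training_enhancer_centers: list[int] = field(default_factory=list)
    training_background_centers: list[int] = field(default_factory=list)
    gene_models: list[GeneModel] = field(default_factory=list)
    motif_plants: list[MotifPlant] = field(default_factory=list)
    bin_bp: int = BIN_BP
    lognormal_sigma: float = LOGNORMAL_SIGMA
    n_decoy_peaks: int = 6

    def validate(self) -> None:
        ivs = sorted((w.start, w.end) for w in self.enhancer_windows)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise SimulationError(
                    f"enhancer windows overlap: [{s1},{e1}) and [{s2},{e2})")
        for w in self.enhancer_windows:
            if not (0 <= w.start < w.end <= self.chrom_length):
                raise SimulationError(f"enhancer window [{w.start},{w.end}) outside chromosome")
        for p in self.planted_pairs:
            for pos in (p.seed_position, p.proxy_position):
                if not (1 <= pos <= self.chrom_length):
                    raise SimulationError(f"position {pos} outside [1,{self.chrom_length}]")
            pair_haplotype_freqs(p.p_seed, p.p_proxy, p.target_r2, p.sign)  # feasibility


# ---------------------------------------------------------------------------
# Demo study: the shipped end-to-end fixture
# ---------------------------------------------------------------------------

SEED_SNPS = {"rs_s1": 200_000, "rs_s2": 500_000, "rs_s3": 800_000}
SEED_TRAITS = {"rs_s1": ("HDL", 4e-9), "rs_s2": ("TG", 1e-12), "rs_s3": ("HDL", 7e-9)}
ENHANCER_PROXY_OFFSET = 6_000
WEAK_LD_OFFSET = -8_000        # seed rs_s1: enhancer proxy in sub-strong LD
PROMOTER_PROXY_OFFSET = -10_000  # seed rs_s3: enhancer proxy inside a promoter window
PROXY_OFFSETS = [o for k in range(1, 13) for o in (2000 * k, -2000 * k)]
DECOY_R2 = 0.15                # below the 0.3 proxy threshold
PROXY_R2_CYCLE = (0.75, 0.6, 0.45, 0.36, 0.55, 0.66)
STRONG_R2 = 0.9
WEAK_R2 = 0.49


def demo_config(seed: int = 0) -> SimConfig:
    """The shipped synthetic study: 3 GWAS seeds, 24 proxies each.

    Per seed, one proxy at population r^2 0.9 sits in a planted enhancer
    window (the recoverable eSNPs); seed rs_s1 additionally has an
    enhancer proxy at r^2 0.49 (dropped by the strong-LD filter) and seed
    rs_s3 one at r^2 0.9 inside a gene's promoter window (dropped by the
    promoter filter); three proxies per seed sit at r^2 0.15 (below the
    0.3 expansion threshold).  One enhancer SNP carries a planted
    allele-sensitive STAT-like motif site.
    """
    pairs: list[PlantedPair] = []
    windows: list[EnhancerWindow] = []
    special = {
        "rs_s1": {ENHANCER_PROXY_OFFSET: ("rs_e1", STRONG_R2, True),
                  WEAK_LD_OFFSET: ("rs_w1", WEAK_R2, True)},
        "rs_s2": {ENHANCER_PROXY_OFFSET: ("rs_e2", STRONG_R2, True)},
        "rs_s3": {ENHANCER_PROXY_OFFSET: ("rs_e3", STRONG_R2, True),
                  PROMOTER_PROXY_OFFSET: ("rs_p3", STRONG_R2, True)},
    }
    for si, (seed_snp, seed_pos) in enumerate(SEED_SNPS.items()):
        cycle = 0
        for oi, off in enumerate(PROXY_OFFSETS):
            pos = seed_pos + off
            if off in special[seed_snp]:
                name, r2, has_window = special[seed_snp][off]
            elif oi >= len(PROXY_OFFSETS) - 3:
                name, r2, has_window = f"{seed_snp}_d{oi}", DECOY_R2, False
            else:
                name, r2, has_window = f"{seed_snp}_x{oi}", PROXY_R2_CYCLE[cycle % len(PROXY_R2_CYCLE)], False
                cycle += 1
            pairs.append(PlantedPair(seed_snp, name, seed_pos, pos, r2))
            if has_window:
                windows.append(EnhancerWindow(pos - 1 - 250, pos - 1 + 250))

    training_enh = [50_000 + 6_000 * k for k in range(12)]
    training_bg = [130_000 + 4_000 * k for k in range(12)]
    windows += [EnhancerWindow(c - 250, c + 250) for c in training_enh]

    genes = [
        GeneModel("GENE_A", "chr1", "+", (195_000, 235_000),
                  exons=[(195_000, 195_200), (234_800, 235_000)]),
        GeneModel("GENE_B", "chr1", "+", (495_000, 535_000),
                  exons=[(495_000, 495_200), (534_800, 535_000)]),
        GeneModel("GENE_C", "chr1", "+", (795_000, 835_000),
                  exons=[(795_000, 795_200), (834_800, 835_000)]),
        # promoter-decoy gene: its promoter window covers proxy rs_p3
        GeneModel("GENE_D", "chr1", "+", (791_250, 793_000),
                  exons=[(791_250, 791_400), (792_800, 793_000)]),
    ]
    return SimConfig(
        seed=seed,
        planted_pairs=pairs,
        enhancer_windows=windows,
        training_enhancer_centers=training_enh,
        training_background_centers=training_bg,
        gene_models=genes,
        motif_plants=[MotifPlant("rs_e2", "SIM0001", SEED_SNPS["rs_s2"] + ENHANCER_PROXY_OFFSET)],
    )


def demo_pwms() -> list[PWM]:
    """Motif battery for the demo: a STAT-like planted matrix plus a decoy.

    The planted matrix has one high-information column (the allele-
    sensitive position) and moderate-information flanking columns, the
    shape under which a single-base change can move a borderline site
    across a score percentile threshold.
    """
    stat = np.array([
        #  T    T    C    C    N    G    G    A    A   (consensus row order A,C,G,T)
        [5, 5, 5, 5, 25, 5, 5, 60, 60],
        [5, 5, 60, 90, 25, 5, 5, 10, 10],
        [10, 10, 10, 2, 25, 60, 60, 10, 10],
        [80, 80, 25, 3, 25, 30, 30, 20, 20],
    ], dtype=float)
    decoy = np.array([
        [60, 10, 10, 60, 10, 10],
        [10, 60, 10, 10, 60, 10],
        [10, 10, 60, 10, 10, 60],
        [20, 20, 20, 20, 20, 20],
    ], dtype=float)
    return [PWM("STATX", "SIM0001", stat), PWM("NRDX", "SIM0002", decoy)]


# ---------------------------------------------------------------------------
# Sequence with planted allele-sensitive motif site
# ---------------------------------------------------------------------------

def _score_distribution(pwm: PWM) -> tuple[np.ndarray, np.ndarray]:
    """Sorted background scores and their cumulative probabilities."""
    from esnp.motif import _all_kmer_scores
    scores, probs = _all_kmer_scores(pwm)
    order = np.argsort(scores)
    return scores[order], np.cumsum(probs[order])


def _percentile_of(sorted_scores: np.ndarray, cum: np.ndarray, score: float) -> float:
    idx = int(np.searchsorted(sorted_scores, score + 1e-12, side="right"))
    return 100.0 * (cum[idx - 1] if idx > 0 else 0.0)


def _percentile_threshold_score(pwm: PWM, pct: float) -> float:
    sorted_scores, cum = _score_distribution(pwm)
    idx = int(np.searchsorted(cum, pct / 100.0))
    idx = min(idx, len(sorted_scores) - 1)
    return float(sorted_scores[idx])


def design_allelic_site(pwm: PWM, margin_low: float = 55.0,
                        margin_high: float = 65.0) -> tuple[str, int, str, str]:
    """Design a motif-length site whose score crosses the 60th percentile
    with the allele at the most allele-sensitive column.

    Because a full-consensus site scores near the top of the background
    distribution for *both* alleles, the planted site is deliberately a
    borderline match: the search enumerates base choices at the non-SNP
    columns and keeps the site maximizing the margin by which the
    high-allele score exceeds, and the low-allele score falls short of,
    the 60th-percentile score.  Returns
    ``(site, snp_column, high_allele, low_allele)``.

    Raises if no column separates two alleles (e.g. an equiprobable
    column) or if no base combination achieves the crossing.
    """
    lo = pwm.log_odds
    L = pwm.length
    deltas = lo.max(axis=0) - lo.min(axis=0)
    snp_col = int(np.argmax(deltas))
    if deltas[snp_col] < 1e-9:
        raise SimulationError(
            f"{pwm.matrix_id}: no column separates any two alleles; "
            "cannot guarantee allele-specific separation")
    high_b = int(lo[:, snp_col].argmax())
    low_b = int(lo[:, snp_col].argmin())
    sorted_scores, cum = _score_distribution(pwm)
    q60 = _percentile_threshold_score(pwm, 60.0)

    other_cols = [j for j in range(L) if j != snp_col]
    if len(other_cols) > 9:
        raise SimulationError("site design supports motifs up to length 10")
    best: tuple[float, tuple[int, ...]] | None = None
    # enumerate all base choices at non-SNP columns (4^(L-1))
    n_combos = 4 ** len(other_cols)
    for code in range(n_combos):
        c = code
        choice = []
        rest = 0.0
        for j in other_cols:
            b = c % 4
            c //= 4
            choice.append(b)
            rest += lo[b, j]
        s_high = rest + lo[high_b, snp_col]
        s_low = rest + lo[low_b, snp_col]
        if s_high > q60 + 1e-9 and s_low < q60 - 1e-9:
            p_high = _percentile_of(sorted_scores, cum, s_high)
            p_low = _percentile_of(sorted_scores, cum, s_low)
            if p_high > margin_high and p_low < margin_low:
                score = min(p_high - 60.0, 60.0 - p_low)
                if best is None or score > best[0]:
                    best = (score, tuple(choice))
    if best is None:
        raise SimulationError(
            f"{pwm.matrix_id}: no site crosses the 60th percentile with this "
            "column's alleles; motif too flat or too sharp for the rule")
    bases = {}
    for j, b in zip(other_cols, best[1]):
        bases[j] = BASES[b]
    site = "".join(bases.get(j, BASES[high_b] if j == snp_col else "N") for j in range(L))
    return site, snp_col, BASES[high_b], BASES[low_b]


def _design_context_window(pwm: PWM, context: int = 15) -> tuple[str, int, str, str]:
    """Design the full allelic context k-mer around a planted site.

    Places the designed site so the SNP sits at the k-mer center, then
    enumerates every combination of the free flank bases inside the k-mer
    and keeps the one maximizing the margin by which the low-allele
    k-mer's best placement (any offset, either strand) stays below the
    60th-percentile score — the condition the allele-specific verdict
    needs.  (The planted placement itself contains no flank bases, so its
    scores are fixed by the site design.)  Returns
    ``(window_with_high_allele, center_offset, high, low)``.
    """
    site, snp_col, high, low = design_allelic_site(pwm)
    q60 = _percentile_threshold_score(pwm, 60.0)
    half = context // 2
    L = pwm.length
    site_start = half - snp_col  # offset of the site within the k-mer
    if site_start < 0 or site_start + L > context:
        raise SimulationError("allele-sensitive column leaves the site outside the context")
    free = [i for i in range(context) if not (site_start <= i < site_start + L)]
    if len(free) > 8:
        raise SimulationError("motif too short for exhaustive flank design")

    template = ["N"] * context
    for j, b in enumerate(site):
        template[site_start + j] = b
    template[half] = high

    best: tuple[float, list[str]] | None = None
    for code in range(4 ** len(free)):
        c = code
        win = template[:]
        for i in free:
            win[i] = BASES[c % 4]
            c //= 4
        k_low = win[:half] + [low] + win[half + 1:]
        worst = -math.inf
        for strand_seq in ("".join(k_low), revcomp("".join(k_low))):
            for off in range(context - L + 1):
                if strand_seq == "".join(k_low) and off == site_start:
                    continue  # the planted placement: below q60 by design
                worst = max(worst, pwm.score(strand_seq[off:off + L]))
        margin = q60 - worst
        if best is None or margin > best[0]:
            best = (margin, win)
    if best is None or best[0] <= 1e-9:
        raise SimulationError(
            "no flank combination keeps every non-planted placement of the "
            "low-allele k-mer below the 60th-percentile score")
    return "".join(best[1]), half, high, low


def simulate_sequence_with_motif(
    pwm: PWM, snp_position: int, seed: int,
    length: int = 2_000, context: int = 15,
) -> tuple[str, str, str]:
    """Emit a sequence with an allele-sensitive motif site at a SNP.

    The high allele (the genome base at ``snp_position``, 1-based within
    the returned sequence) completes a planted borderline site scoring
    above the 60th background percentile; substituting the low allele
    pushes every placement of the context k-mer below it, guaranteeing
    both ``score(high) > score(low)`` and the allele-specific verdict.
    Sequence outside the context window is random (seeded).

    Returns ``(sequence, high_allele, low_allele)``.
    """
    if pwm.length > context:
        raise SimulationError("motif longer than the context window")
    window, center, high, low = _design_context_window(pwm, context)
    rng = np.random.default_rng(seed)
    pos0 = snp_position - 1
    win_start = pos0 - center
    if win_start < 0 or win_start + context > length:
        raise SimulationError("snp_position leaves no room for the planted context")
    seq = rng.choice(list(BASES), size=length)
    for j, b in enumerate(window):
        seq[win_start + j] = b
    return "".join(seq), high, low


def _site_col(pwm: PWM) -> int:
    lo = pwm.log_odds
    return int(np.argmax(lo.max(axis=0) - lo.min(axis=0)))


# ---------------------------------------------------------------------------
# Tracks
# ---------------------------------------------------------------------------

def simulate_tracks(config: SimConfig, rng: np.random.Generator) -> TrackSet:
    """Generate bedGraph signals, peak intervals and a state segmentation.

    Background bins get lognormal noise; planted enhancer windows add a
    Gaussian-shaped bump on the enhancer marks; TSS neighborhoods add one
    on open chromatin and H3K4me3 and are labeled with the promoter state.
    """
    config.validate()
    n_bins = config.chrom_length // config.bin_bp
    starts = np.arange(n_bins) * config.bin_bp
    centers = starts + config.bin_bp / 2

    promoter_windows = []
    for g in config.gene_models:
        if g.chrom != config.chrom:
            continue
        t0 = g.tss - 1  # 0-based
        promoter_windows.append((max(t0 - PROMOTER_HALF_BP, 0),
                                 min(t0 + PROMOTER_HALF_BP, config.chrom_length)))
    for (ps, pe) in promoter_windows:
        for w in config.enhancer_windows:
            if ps < w.end and w.start < pe:
                raise SimulationError(
                    f"promoter window [{ps},{pe}) overlaps enhancer window "
                    f"[{w.start},{w.end}); the segmentation must partition")

    signals: dict[str, pd.DataFrame] = {}
    for mark in DEFAULT_MARKS:
        values = rng.lognormal(mean=0.0, sigma=config.lognormal_sigma, size=n_bins)
        for w in config.enhancer_windows:
            if mark in ENHANCER_MARKS:
                mid, sd = (w.start + w.end) / 2, (w.end - w.start) / 4
                values += w.strength * np.exp(-0.5 * ((centers - mid) / sd) ** 2)
        for ps, pe in promoter_windows:
            if mark in PROMOTER_MARKS:
                mid, sd = (ps + pe) / 2, (pe - ps) / 4
                values += SIGNATURE_STRENGTH * np.exp(-0.5 * ((centers - mid) / sd) ** 2)
        signals[mark] = pd.DataFrame({
            "chrom": config.chrom, "start": starts,
            "end": starts + config.bin_bp, "value": np.round(values, 4),
        })

    # peaks: planted windows on their marks, plus decoys in free regions
    blocked = [(w.start, w.end) for w in config.enhancer_windows] + promoter_windows
    blocked += [(p.proxy_position - 1 - 1500, p.proxy_position - 1 + 1500)
                for p in config.planted_pairs]
    blocked += [(c - 1500, c + 1500) for c in config.training_background_centers]

    def free(s: int, e: int) -> bool:
        return all(e <= bs or s >= be for bs, be in blocked)

    decoys: list[tuple[int, int]] = []
    while len(decoys) < config.n_decoy_peaks:
        s = int(rng.integers(0, config.chrom_length - 300))
        if free(s, s + 300) and all(s + 300 <= ds or s >= de for ds, de in decoys):
            decoys.append((s, s + 300))
    decoys.sort()

    peaks: dict[str, pd.DataFrame] = {}
    for mark in DEFAULT_MARKS:
        ivs = []
        if mark in ENHANCER_MARKS:
            ivs += [(w.start, w.end) for w in config.enhancer_windows]
        if mark in PROMOTER_MARKS:
            ivs += promoter_windows
        ivs += decoys
        ivs.sort()
        peaks[mark] = pd.DataFrame(
            [{"chrom": config.chrom, "start": s, "end": e, "name": f"{mark}_peak"}
             for s, e in ivs])

    # chromatin-state segmentation partitioning the chromosome
    labeled = sorted(
        [(w.start, w.end, "strong_enhancer") for w in config.enhancer_windows]
        + [(s, e, "promoter") for s, e in promoter_windows])
    rows, cursor = [], 0
    for s, e, lab in labeled:
        if s > cursor:
            rows.append((config.chrom, cursor, s, "quiescent"))
        rows.append((config.chrom, s, e, lab))
        cursor = e
    if cursor < config.chrom_length:
        rows.append((config.chrom, cursor, config.chrom_length, "quiescent"))
    states = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])

    tf_rows = [(config.chrom, (w.start + w.end) // 2 - 100,
                (w.start + w.end) // 2 + 100, "TFX") for w in config.enhancer_windows]
    tf_rows += [(config.chrom, s + 50, e - 50, "TFX") for s, e in decoys]
    tf_peaks = pd.DataFrame(sorted(tf_rows), columns=["chrom", "start", "end", "name"])

    return TrackSet(signals=signals, peaks=peaks, states=states, tf_peaks=tf_peaks,
                    marks=DEFAULT_MARKS, state_labels=DEFAULT_STATES)


# ---------------------------------------------------------------------------
# Full study
# ---------------------------------------------------------------------------

def _build_panel(config: SimConfig, rng: np.random.Generator) -> HaplotypePanel:
    ids: list[str] = []
    positions: list[int] = []
    columns: list[np.ndarray] = []
    seed_cols: dict[str, np.ndarray] = {}
    for pair in config.planted_pairs:
        if pair.seed_snp not in seed_cols:
            seed_cols[pair.seed_snp] = (
                rng.random(config.n_haplotypes) < pair.p_seed).astype(np.int8)
            ids.append(pair.seed_snp)
            positions.append(pair.seed_position)
            columns.append(seed_cols[pair.seed_snp])
        proxy = _conditional_proxy(seed_cols[pair.seed_snp], pair.p_seed,
                                   pair.p_proxy, pair.target_r2, pair.sign, rng)
        ids.append(pair.proxy_snp)
        positions.append(pair.proxy_position)
        columns.append(proxy)

    used = set(positions)
    spacing = config.chrom_length // (config.n_background_snps + 1)
    for k in range(config.n_background_snps):
        pos = (k + 1) * spacing + int(rng.integers(-spacing // 4, spacing // 4))
        while pos in used or pos < 1 or pos > config.chrom_length:
            pos += 1
        used.add(pos)
        freq = rng.uniform(*config.background_freq_range)
        ids.append(f"rs_bg{k}")
        positions.append(pos)
        columns.append((rng.random(config.n_haplotypes) < freq).astype(np.int8))

    order = np.argsort(positions, kind="stable")
    return HaplotypePanel(
        variant_ids=[ids[i] for i in order],
        chroms=[config.chrom] * len(ids),
        positions=np.array(positions)[order],
        ref_alleles=["N"] * len(ids),  # assigned once the genome exists
        alt_alleles=["N"] * len(ids),
        matrix=np.stack([columns[i] for i in order], axis=1),
    )


def _build_catalog(config: SimConfig) -> pd.DataFrame:
    rows = []
    for seed_snp, seed_pos in sorted(
            {(p.seed_snp, p.seed_position) for p in config.planted_pairs},
            key=lambda t: t[1]):
        trait, p = SEED_TRAITS.get(seed_snp, ("HDL", 1e-8))
        rows.append((seed_snp, config.chrom, seed_pos, trait, p,
                     "European", 550_000, "GWAS_A"))
        # exact duplicate triple: must deduplicate
        rows.append((seed_snp, config.chrom, seed_pos, trait, p,
                     "European", 550_000, "GWAS_A"))
    # decoys rejected by each filter in turn
    rows += [
        ("rs_decoy_trait", config.chrom, 10_000, "height", 1e-9, "European", 550_000, "GWAS_B"),
        ("rs_decoy_p", config.chrom, 20_000, "HDL", 1e-5, "European", 550_000, "GWAS_B"),
        ("rs_decoy_platform", config.chrom, 30_000, "HDL", 1e-9, "European", 90_000, "GWAS_B"),
        ("rs_decoy_ancestry", config.chrom, 40_000, "HDL", 1e-9, "East Asian", 550_000, "GWAS_B"),
    ]
    return pd.DataFrame(rows, columns=[
        "snp_id", "chrom", "position", "trait", "p_value", "ancestry",
        "platform_snp_count", "publication_id"])


def simulate_study(config: SimConfig, outdir: str | Path,
                   pwms: list[PWM] | None = None) -> dict:
    """Write the full synthetic study to ``outdir`` and return its manifest.

    Artifacts: GWAS catalog TSV, haplotype panel (matrix TSV + variants TSV
    + phased VCF), genome FASTA, gene models GFF, JASPAR motif battery,
    per-mark bedGraph + peak BED, chromatin-state BED, TF-peak BED,
    training-window table, and ``manifest.json`` naming every artifact,
    the seed, and the planted truth.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    if pwms is None:
        pwms = demo_pwms()
    pwm_by_id = {p.matrix_id: p for p in pwms}

    # genome, with planted motif sites
    genome_arr = rng.choice(list(BASES), size=config.chrom_length)
    motif_truth = []
    for plant in config.motif_plants:
        pwm = pwm_by_id[plant.matrix_id]
        local_len, local_snp = 31, 16  # SNP at the local center
        local, high, low = simulate_sequence_with_motif(
            pwm, snp_position=local_snp,
            seed=int(rng.integers(2**31)), length=local_len)
        start0 = plant.position - 1 - (local_snp - 1)
        genome_arr[start0:start0 + local_len] = list(local)
        motif_truth.append({
            "snp_id": plant.snp_id, "matrix_id": plant.matrix_id,
            "position": plant.position, "high_allele": high, "low_allele": low,
        })
    genome = "".join(genome_arr)

    panel = _build_panel(config, rng)
    # alleles: ref = genome base at the position; alt = a different base
    motif_alleles = {m["snp_id"]: m for m in motif_truth}
    refs, alts = [], []
    for vid, pos in zip(panel.variant_ids, panel.positions):
        base = genome[pos - 1]
        if vid in motif_alleles:
            refs.append(motif_alleles[vid]["high_allele"])
            alts.append(motif_alleles[vid]["low_allele"])
        else:
            refs.append(base)
            alts.append(BASES[(BASE_INDEX[base] + 1 + int(rng.integers(3))) % 4])
    panel.ref_alleles, panel.alt_alleles = refs, alts

    tracks = simulate_tracks(config, rng)

    paths = {
        "catalog": "catalog.tsv", "panel_matrix": "panel.tsv",
        "panel_variants": "variants.tsv", "panel_vcf": "panel.vcf",
        "genome": "genome.fa", "genes": "genes.gff", "pwms": "pwms.jaspar",
        "states": "states.bed", "tf_peaks": "tf_peaks.bed",
        "training_windows": "training_windows.tsv",
    }
    for mark in tracks.marks:
        paths[f"signal_{mark}"] = f"{mark}.bedgraph"
        paths[f"peaks_{mark}"] = f"{mark}_peaks.bed"

    _build_catalog(config).to_csv(outdir / paths["catalog"], sep="\t", index=False)
    eio.write_panel(panel, outdir / paths["panel_matrix"], outdir / paths["panel_variants"])
    eio.write_vcf(panel, outdir / paths["panel_vcf"])
    eio.write_fasta({config.chrom: genome}, outdir / paths["genome"])
    write_gene_models(config.gene_models, outdir / paths["genes"])
    write_jaspar(pwms, outdir / paths["pwms"])
    for mark in tracks.marks:
        eio.write_bedgraph(tracks.signals[mark], outdir / paths[f"signal_{mark}"])
        eio.write_bed(tracks.peaks[mark], outdir / paths[f"peaks_{mark}"])
    eio.write_bed(tracks.states, outdir / paths["states"])
    eio.write_bed(tracks.tf_peaks, outdir / paths["tf_peaks"])

    training = pd.DataFrame(
        [{"window_id": f"enh{t}", "chrom": config.chrom, "position": c + 1, "label": 1}
         for t, c in enumerate(config.training_enhancer_centers)]
        + [{"window_id": f"bg{t}", "chrom": config.chrom, "position": c + 1, "label": 0}
           for t, c in enumerate(config.training_background_centers)])
    training.to_csv(outdir / paths["training_windows"], sep="\t", index=False)

    planted_esnps = sorted({
        p.proxy_snp for p in config.planted_pairs
        if p.target_r2 >= 0.8 and any(
            w.start <= p.proxy_position - 1 < w.end for w in config.enhancer_windows)
        and not _in_promoter(p.proxy_position, config.gene_models)})
    dropped_weak = sorted({
        p.proxy_snp for p in config.planted_pairs
        if p.target_r2 < 0.8 and any(
            w.start <= p.proxy_position - 1 < w.end for w in config.enhancer_windows)})
    dropped_promoter = sorted({
        p.proxy_snp for p in config.planted_pairs
        if p.target_r2 >= 0.8 and any(
            w.start <= p.proxy_position - 1 < w.end for w in config.enhancer_windows)
        and _in_promoter(p.proxy_position, config.gene_models)})

    manifest = {
        "seed": config.seed,
        "chrom": config.chrom,
        "chrom_length": config.chrom_length,
        "n_haplotypes": config.n_haplotypes,
        "artifacts": paths,
        "truth": {
            "gwas_seed_snps": sorted({p.seed_snp for p in config.planted_pairs}),
            "planted_esnps": planted_esnps,
            "esnps_dropped_by_strong_ld": dropped_weak,
            "esnps_dropped_by_promoter_filter": dropped_promoter,
            "allele_specific": motif_truth,
            "esnp_seed_links": {
                p.proxy_snp: p.seed_snp for p in config.planted_pairs
                if p.proxy_snp in planted_esnps},
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _in_promoter(position: int, genes: list[GeneModel],
                 window: tuple[int, int] = (2000, 500)) -> bool:
    up, down = window
    for g in genes:
        lo, hi = (g.tss - up, g.tss + down) if g.strand == "+" else (g.tss - down, g.tss + up)
        if lo <= position <= hi:
            return True
    return False
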