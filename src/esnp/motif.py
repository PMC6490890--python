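"""Allele-specific transcription-factor binding prediction with PWMs.

A SNP's two alleles are each embedded in a 15-mer centered on the variant
(center offset 7, 0-based); every full-length placement of the motif inside
the 15-mer is scored on both strands, and the best log-odds score per allele
is converted to a percentile of the motif's score distribution over random
L-mers under the background base composition.  A SNP is called
allele-specific for a motif when one allele's percentile lies strictly above
60 and the other's strictly below 60; both above is "shared", anything else
"none".
"""

from __future__ import annotations

import io as _io
import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import motifs as bio_motifs

logger = logging.getLogger(__name__)

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

CONTEXT_BP = 15           # allelic k-mer length
CENTER_OFFSET = 7         # SNP offset within the 15-mer (0-based)
PSEUDOCOUNT = 0.8         # split across bases by background frequency
PERCENTILE_THRESHOLD = 60.0
EXACT_MAX_LENGTH = 10     # 4^10 enumeration cap for exact percentiles
SAMPLED_N = 100_000


class MotifError(ValueError):
    """Raised for malformed matrices or unscoreable inputs."""


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))


@dataclass
class PWM:
    """A position count/frequency matrix with log-odds scoring.

    ``counts`` is 4 x L (rows A, C, G, T).  Frequencies add a total
    pseudocount per column split by the background composition; scores are
    log2 odds against that background.
    """

    tf_name: str
    matrix_id: str
    counts: np.ndarray
    pseudocount: float = PSEUDOCOUNT
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    _log_odds: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape[0] != 4 or self.counts.ndim != 2:
            raise MotifError(f"{self.matrix_id}: counts must be 4 x L, got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise MotifError(f"{self.matrix_id}: negative counts")
        bg = np.asarray(self.background, dtype=float)
        if not math.isclose(bg.sum(), 1.0, abs_tol=1e-9):
            raise MotifError("background frequencies must sum to 1")
        col_tot = self.counts.sum(axis=0)
        if np.any(col_tot <= 0) and self.pseudocount <= 0:
            raise MotifError(f"{self.matrix_id}: empty column with zero pseudocount")
        freqs = (self.counts + self.pseudocount * bg[:, None]) / (col_tot + self.pseudocount)
        with np.errstate(divide="ignore"):
            self._log_odds = np.log2(freqs / bg[:, None])

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        return self._log_odds

    @property
    def max_score(self) -> float:
        return float(self._log_odds.max(axis=0).sum())

    @property
    def min_score(self) -> float:
        return float(self._log_odds.min(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self._log_odds.argmax(axis=0))

    def score(self, kmer: str) -> float:
        """Log-odds score of a single L-length k-mer (forward strand)."""
        kmer = kmer.upper()
        if len(kmer) != self.length:
            raise MotifError(f"k-mer length {len(kmer)} != motif length {self.length}")
        try:
            idx = [BASE_INDEX[b] for b in kmer]
        except KeyError as exc:
            raise MotifError(f"non-ACGT base in k-mer {kmer!r}") from exc
        return float(self._log_odds[idx, range(self.length)].sum())

    def best_score_in(self, seq: str, require_positions: set[int] | None = None
                      ) -> tuple[float, int, str]:
        """Best log-odds over all full placements in ``seq``, both strands.

        ``require_positions``: if given, only placements covering at least
        one of these 0-based sequence positions are scored.  Returns
        ``(score, offset, strand)`` with the offset on the forward
        coordinates of ``seq``; ties break to the smallest offset, forward
        strand first.
        """
        L = self.length
        if len(seq) < L:
            raise MotifError(f"sequence shorter ({len(seq)}) than motif ({L})")
        best: tuple[float, int, str] | None = None
        for strand, s in (("+", seq.upper()), ("-", revcomp(seq))):
            for off in range(len(seq) - L + 1):
                fwd_off = off if strand == "+" else len(seq) - L - off
                if require_positions is not None and not any(
                        fwd_off <= p < fwd_off + L for p in require_positions):
                    continue
                sc = self.score(s[off:off + L])
                if best is None or sc > best[0] + 1e-12:
                    best = (sc, fwd_off, strand)
        if best is None:
            raise MotifError("no placement covers the required positions")
        return best


# ---------------------------------------------------------------------------
# JASPAR text format
# ---------------------------------------------------------------------------

def load_jaspar(path: str | Path, pseudocount: float = PSEUDOCOUNT,
                background: tuple[float, float, float, float] = (0.25,) * 4) -> list[PWM]:
    """Parse a JASPAR-text motif file (">ID name" headers, A/C/G/T rows)."""
    with open(path) as fh:
        text = fh.read()
    parsed = bio_motifs.parse(_io.StringIO(text), "jaspar")
    pwms: list[PWM] = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in BASES], dtype=float)
        lens = {len(m.counts[b]) for b in BASES}
        if len(lens) != 1:
            raise MotifError(f"{m.matrix_id}: row length mismatch across bases")
        pwms.append(PWM(
            tf_name=m.name or m.matrix_id,
            matrix_id=m.matrix_id or (m.name or "motif"),
            counts=counts,
            pseudocount=pseudocount,
            background=background,
        ))
    return pwms


def write_jaspar(pwms: list[PWM], path: str | Path) -> None:
    """Write motifs in JASPAR text format, preserving integral counts exactly."""
    def fmt(x: float) -> str:
        return str(int(x)) if float(x).is_integer() else f"{x:.6g}"

    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.matrix_id} {pwm.tf_name}\n")
            for bi, base in enumerate(BASES):
                row = " ".join(fmt(v) for v in pwm.counts[bi])
                fh.write(f"{base}  [ {row} ]\n")


# ---------------------------------------------------------------------------
# Allelic scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlleleScore:
    allele: str
    score: float
    percentile: float
    offset: int
    strand: str
    percentile_se: float | None = None


@dataclass(frozen=True)
class AlleleBindingCall:
    """Verdict for one (SNP, motif) pair under the 60th-percentile rule."""

    snp_id: str
    tf_name: str
    matrix_id: str
    allele1: AlleleScore
    allele2: AlleleScore
    verdict: str              # "allele_specific" | "shared" | "none"
    preferred_allele: str | None


def allelic_kmers(genome: dict[str, str], chrom: str, position: int,
                  ref: str, alt: str, context: int = CONTEXT_BP) -> tuple[str, str]:
    """Build the two allelic context k-mers around a SNP (1-based position).

    The reference allele must match the genome base at the SNP position;
    a mismatch indicates mis-specified coordinates and raises.
    """
    if context % 2 == 0:
        raise MotifError("context length must be odd so the SNP sits at the center")
    half = context // 2
    seq = genome[chrom]
    if not (position - 1 - half >= 0 and position - 1 + half < len(seq)):
        raise MotifError(
            f"SNP at {chrom}:{position} needs {half} bp of flank on each side")
    window = seq[position - 1 - half: position + half]
    if window[half].upper() != ref.upper():
        raise MotifError(
            f"reference allele {ref} does not match genome base "
            f"{window[half]} at {chrom}:{position}")
    make = lambda a: window[:half] + a.upper() + window[half + 1:]
    return make(ref), make(alt)


def score_alleles(pwm: PWM, genome: dict[str, str], chrom: str, position: int,
                  ref: str, alt: str, context: int = CONTEXT_BP,
                  require_snp_overlap: bool = False) -> tuple[tuple[float, int, str], tuple[float, int, str]]:
    """Best per-allele motif score within the SNP-centered context k-mer.

    By default every full placement inside the k-mer is scored; with
    ``require_snp_overlap`` only placements covering the SNP base count.
    Returns ``((score, offset, strand), ...)`` for (ref, alt).
    """
    if pwm.length > context:
        raise MotifError(f"motif length {pwm.length} exceeds context {context}")
    k_ref, k_alt = allelic_kmers(genome, chrom, position, ref, alt, context)
    need = {context // 2} if require_snp_overlap else None
    return pwm.best_score_in(k_ref, need), pwm.best_score_in(k_alt, need)


def _all_kmer_scores(pwm: PWM) -> tuple[np.ndarray, np.ndarray]:
    """Scores and background probabilities of all 4^L L-mers (vectorized)."""
    L = pwm.length
    grids = np.meshgrid(*[np.arange(4)] * L, indexing="ij")
    idx = np.stack([g.ravel() for g in grids], axis=1)  # (4^L, L)
    lo = pwm.log_odds
    scores = lo[idx, np.arange(L)].sum(axis=1)
    bg = np.log(np.asarray(pwm.background))
    probs = np.exp(bg[idx].sum(axis=1))
    return scores, probs


def score_percentile(pwm: PWM, score: float, mode: str = "exact",
                     seed: int = 0, n_samples: int = SAMPLED_N) -> tuple[float, float | None]:
    """Percentile of a log-odds score in the motif's background distribution.

    The reference distribution is the score of a single random L-mer drawn
    from the background base composition.  ``exact`` enumerates all 4^L
    L-mers (refused for L > 10); ``sampled`` draws ``n_samples`` seeded
    L-mers and additionally returns the Monte-Carlo standard error of the
    percentile.  Percentile = 100 x P(background score <= observed score).
    """
    if mode == "exact":
        if pwm.length > EXACT_MAX_LENGTH:
            raise MotifError(
                f"exact enumeration infeasible for L={pwm.length} (> {EXACT_MAX_LENGTH}); "
                "use mode='sampled'")
        scores, probs = _all_kmer_scores(pwm)
        p = float(probs[scores <= score + 1e-12].sum())
        return 100.0 * p, None
    if mode == "sampled":
        rng = np.random.default_rng(seed)
        L = pwm.length
        draws = rng.choice(4, size=(n_samples, L), p=np.asarray(pwm.background))
        sc = pwm.log_odds[draws, np.arange(L)].sum(axis=1)
        p = float(np.mean(sc <= score + 1e-12))
        se = 100.0 * math.sqrt(max(p * (1 - p), 1.0 / n_samples) / n_samples)
        return 100.0 * p, se
    raise MotifError(f"unknown percentile mode {mode!r}")


def call_allele_specific(
    snp_id: str, pwm: PWM,
    allele1: AlleleScore, allele2: AlleleScore,
    threshold: float = PERCENTILE_THRESHOLD,
) -> AlleleBindingCall:
    """Apply the percentile rule to two scored alleles.

    ``allele_specific`` iff exactly one allele's percentile is strictly
    above the threshold and the other's strictly below; ``shared`` iff both
    are strictly above; ``none`` otherwise.  A percentile exactly at the
    threshold never satisfies the strict inequalities, so it weakens the
    call by design.
    """
    p1, p2 = allele1.percentile, allele2.percentile
    if (p1 > threshold and p2 < threshold) or (p2 > threshold and p1 < threshold):
        verdict = "allele_specific"
        preferred = allele1.allele if p1 > p2 else allele2.allele
    elif p1 > threshold and p2 > threshold:
        verdict, preferred = "shared", None
    else:
        verdict, preferred = "none", None
    return AlleleBindingCall(
        snp_id=snp_id, tf_name=pwm.tf_name, matrix_id=pwm.matrix_id,
        allele1=allele1, allele2=allele2,
        verdict=verdict, preferred_allele=preferred,
    )


def score_snp_against_pwms(
    genome: dict[str, str], chrom: str, position: int, ref: str, alt: str,
    pwms: list[PWM], snp_id: str, seed: int = 0,
    context: int = CONTEXT_BP, threshold: float = PERCENTILE_THRESHOLD,
    require_snp_overlap: bool = False,
) -> list[AlleleBindingCall]:
    """Score one SNP against a motif battery and call allele specificity."""
    calls = []
    for pwm in pwms:
        try:
            (s1, o1, st1), (s2, o2, st2) = score_alleles(
                pwm, genome, chrom, position, ref, alt, context, require_snp_overlap)
        except MotifError as exc:
            logger.warning("skipping %s x %s: %s", snp_id, pwm.matrix_id, exc)
            continue
        mode = "exact" if pwm.length <= EXACT_MAX_LENGTH else "sampled"
        p1, se1 = score_percentile(pwm, s1, mode=mode, seed=seed)
        p2, se2 = score_percentile(pwm, s2, mode=mode, seed=seed)
        a1 = AlleleScore(ref, s1, p1, o1, st1, se1)
        a2 = AlleleScore(alt, s2, p2, o2, st2, se2)
        calls.append(call_allele_specific(snp_id, pwm, a1, a2, threshold))
    return calls
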