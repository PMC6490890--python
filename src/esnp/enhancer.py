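"""Enhancer-signature scoring of SNP-centered 500-bp windows.

Each candidate SNP is summarized by the epigenomic content of the 500-bp
window centered on it (0-based half-open ``[pos-250, pos+250)``):
length-weighted mean signal per mark (bedGraph), fraction of the window
covered by each mark's peaks, chromatin-state composition, and the count
of TF-binding peaks.  A regularized logistic classifier trained on labeled
windows turns the feature vector into an enhancer probability; windows at
or above the cutoff are called eSNPs.  Enhancer boundaries for reporting
are the merged DHS/histone intervals connected to the SNP.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

logger = logging.getLogger(__name__)

WINDOW_BP = 500
DEFAULT_CUTOFF = 0.5
MODEL_FORMAT_VERSION = 1
L2_ALPHA = 0.01  # per-sample ridge weight; keeps the fit duplication-invariant

#: Default epigenomic marks: open chromatin plus the canonical enhancer
#: histone marks, and H3K4me3 as the promoter-discriminating mark.
DEFAULT_MARKS = ("dnase", "h3k4me1", "h3k27ac", "h3k4me3")

#: Chromatin-state vocabulary for segmentation composition features.
DEFAULT_STATES = ("promoter", "strong_enhancer", "weak_enhancer",
                  "transcribed", "insulator", "quiescent")


class EnhancerError(ValueError):
    pass


@dataclass
class TrackSet:
    """Epigenomic evidence for one cell type.

    ``signals``: mark -> bedGraph DataFrame[chrom,start,end,value];
    ``peaks``: mark -> BED DataFrame; ``states``: BED DataFrame with the
    state label in ``name``; ``tf_peaks``: BED DataFrame of TF-binding peaks.
    """

    signals: dict[str, pd.DataFrame]
    peaks: dict[str, pd.DataFrame]
    states: pd.DataFrame
    tf_peaks: pd.DataFrame
    marks: tuple[str, ...] = DEFAULT_MARKS
    state_labels: tuple[str, ...] = DEFAULT_STATES


@dataclass
class WindowFeatures:
    """Feature vector for one SNP-centered window."""

    snp_id: str
    chrom: str
    start: int  # 0-based half-open window
    end: int
    truncated: bool
    features: dict[str, float]

    def vector(self, names: list[str]) -> np.ndarray:
        return np.array([self.features[n] for n in names], dtype=float)


def feature_names(marks=DEFAULT_MARKS, states=DEFAULT_STATES) -> list[str]:
    names = [f"{m}_mean" for m in marks]
    names += [f"{m}_peak_frac" for m in marks]
    names += [f"state_{s}_frac" for s in states]
    names.append("tf_peak_count")
    return names


def _overlap_lengths(df: pd.DataFrame, chrom: str, start: int, end: int) -> pd.DataFrame:
    sub = df[df["chrom"] == chrom]
    if sub.empty:
        return sub.assign(olap=pd.Series(dtype=np.int64))
    olap = np.minimum(sub["end"].to_numpy(), end) - np.maximum(sub["start"].to_numpy(), start)
    keep = olap > 0
    return sub.loc[keep].assign(olap=olap[keep])


def extract_features(
    snp_id: str, chrom: str, position: int, tracks: TrackSet,
    window_bp: int = WINDOW_BP, contig_lengths: dict[str, int] | None = None,
) -> WindowFeatures:
    """Compute window features for a SNP at a 1-based position.

    Signal means are length-weighted over the bedGraph intervals that
    intersect the window; uncovered window bases count as 0 signal.  An
    absent track contributes a zero feature with a logged flag.  Windows
    truncated at a contig edge are flagged and features are computed over
    the truncated extent.
    """
    half = window_bp // 2
    start = (position - 1) - half
    end = (position - 1) + half
    truncated = False
    if start < 0:
        start, truncated = 0, True
    if contig_lengths is not None and chrom in contig_lengths and end > contig_lengths[chrom]:
        end, truncated = contig_lengths[chrom], True
    width = end - start
    if width <= 0:
        raise EnhancerError(f"{snp_id}: empty window at {chrom}:{position}")

    known_chroms = set()
    for df in list(tracks.signals.values()) + list(tracks.peaks.values()) + [tracks.states, tracks.tf_peaks]:
        if df is not None and not df.empty:
            known_chroms.update(df["chrom"].unique())
    if known_chroms and chrom not in known_chroms:
        raise EnhancerError(f"{snp_id}: contig {chrom} absent from every track")

    feats: dict[str, float] = {}
    for mark in tracks.marks:
        sig = tracks.signals.get(mark)
        if sig is None:
            logger.warning("track %s absent; feature set to 0 for %s", mark, snp_id)
            feats[f"{mark}_mean"] = 0.0
        else:
            ov = _overlap_lengths(sig, chrom, start, end)
            feats[f"{mark}_mean"] = float((ov["value"] * ov["olap"]).sum() / width) if not ov.empty else 0.0
        pk = tracks.peaks.get(mark)
        if pk is None:
            feats[f"{mark}_peak_frac"] = 0.0
        else:
            ov = _overlap_lengths(pk, chrom, start, end)
            feats[f"{mark}_peak_frac"] = float(min(ov["olap"].sum() / width, 1.0)) if not ov.empty else 0.0

    ov = _overlap_lengths(tracks.states, chrom, start, end)
    covered = 0
    for label in tracks.state_labels:
        frac = float(ov.loc[ov["name"] == label, "olap"].sum() / width) if not ov.empty else 0.0
        feats[f"state_{label}_frac"] = frac
        covered += frac
    # uncovered window bases count toward the quiescent/background state
    if "quiescent" in tracks.state_labels and covered < 1.0:
        feats["state_quiescent_frac"] += 1.0 - covered

    ov = _overlap_lengths(tracks.tf_peaks, chrom, start, end)
    feats["tf_peak_count"] = float(len(ov))

    return WindowFeatures(snp_id=snp_id, chrom=chrom, start=start, end=end,
                          truncated=truncated, features=feats)


# ---------------------------------------------------------------------------
# Classifier
# ---------------------------------------------------------------------------

@dataclass
class EnhancerModel:
    """Standardized logistic enhancer classifier with JSON persistence.

    Scoring is closed-form from the stored parameters —
    ``sigmoid(coef . (x - mean) / scale + intercept)`` — so a JSON
    round-trip reproduces scores exactly.
    """

    feature_names: list[str]
    mean: np.ndarray
    scale: np.ndarray
    coef: np.ndarray
    intercept: float
    cutoff: float = DEFAULT_CUTOFF
    cv_accuracy: list[float] = field(default_factory=list)

    def score(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        z = (X - self.mean) / self.scale
        return 1.0 / (1.0 + np.exp(-(z @ self.coef + self.intercept)))

    def score_windows(self, windows: list[WindowFeatures]) -> np.ndarray:
        if not windows:
            return np.empty(0)
        X = np.array([w.vector(self.feature_names) for w in windows])
        return self.score(X)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "format_version": MODEL_FORMAT_VERSION,
            "feature_names": self.feature_names,
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "cutoff": self.cutoff,
            "cv_accuracy": self.cv_accuracy,
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "EnhancerModel":
        doc = json.loads(Path(path).read_text())
        if doc.get("format_version") != MODEL_FORMAT_VERSION:
            raise EnhancerError(f"unsupported model format: {doc.get('format_version')}")
        return cls(
            feature_names=list(doc["feature_names"]),
            mean=np.array(doc["mean"]),
            scale=np.array(doc["scale"]),
            coef=np.array(doc["coef"]),
            intercept=float(doc["intercept"]),
            cutoff=float(doc["cutoff"]),
            cv_accuracy=list(doc["cv_accuracy"]),
        )


def train_classifier(
    windows: list[WindowFeatures], labels: list[bool] | np.ndarray,
    cv_folds: int = 5, seed: int = 0, cutoff: float = DEFAULT_CUTOFF,
    names: list[str] | None = None,
) -> EnhancerModel:
    """Fit the enhancer classifier and report fold-wise CV accuracy.

    Features are standardized; the classifier is L2-regularized logistic
    regression.  Both classes must be present and ``n >= 2 * cv_folds``.
    """
    y = np.asarray(labels, dtype=int)
    if len(set(y.tolist())) < 2:
        raise EnhancerError("training labels contain a single class")
    if len(y) < 2 * cv_folds:
        raise EnhancerError(f"need at least {2 * cv_folds} examples for {cv_folds}-fold CV")
    if names is None:
        names = sorted(windows[0].features)
    X = np.array([w.vector(names) for w in windows])

    # C scales with 1/n so the penalty acts per sample: duplicating every
    # training example leaves the optimum unchanged
    pipe = Pipeline([
        ("scale", StandardScaler()),
        ("clf", LogisticRegression(C=1.0 / (L2_ALPHA * len(y)), max_iter=5000,
                                   tol=1e-8, random_state=seed)),
    ])
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    cv_acc = cross_val_score(pipe, X, y, cv=skf, scoring="accuracy")
    pipe.fit(X, y)

    scaler: StandardScaler = pipe.named_steps["scale"]
    clf: LogisticRegression = pipe.named_steps["clf"]
    return EnhancerModel(
        feature_names=list(names),
        mean=scaler.mean_.copy(),
        scale=scaler.scale_.copy(),
        coef=clf.coef_[0].copy(),
        intercept=float(clf.intercept_[0]),
        cutoff=cutoff,
        cv_accuracy=[float(a) for a in cv_acc],
    )


@dataclass(frozen=True)
class EnhancerCall:
    snp_id: str
    score: float
    cutoff: float
    is_esnp: bool


def call_esnps(windows: list[WindowFeatures], model: EnhancerModel,
               cutoff: float | None = None) -> list[EnhancerCall]:
    """Score windows and call eSNPs; the cutoff comparison is inclusive."""
    c = model.cutoff if cutoff is None else cutoff
    scores = model.score_windows(windows)
    return [EnhancerCall(w.snp_id, float(s), c, bool(s >= c))
            for w, s in zip(windows, scores)]


# ---------------------------------------------------------------------------
# Enhancer boundaries
# ---------------------------------------------------------------------------

def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or book-ended 0-based half-open intervals."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:  # book-ended (s == end) merges too
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(iv) for iv in merged]


def enhancer_boundaries(
    chrom: str, position: int,
    dhs: pd.DataFrame, marks: pd.DataFrame,
    window_bp: int = WINDOW_BP,
) -> tuple[tuple[int, int], bool]:
    """Delimit the enhancer element containing a SNP (1-based position).

    The boundary is the merged union of all DHS and histone-mark intervals
    in the connected overlap-component containing the SNP.  If no interval
    covers the SNP, the bare SNP-centered window is returned with a
    ``fallback`` flag of True.
    """
    pos0 = position - 1
    ivs: list[tuple[int, int]] = []
    for df in (dhs, marks):
        if df is None or df.empty:
            continue
        sub = df[df["chrom"] == chrom]
        ivs.extend(zip(sub["start"].astype(int), sub["end"].astype(int)))
    for s, e in merge_intervals(ivs):
        if s <= pos0 < e:
            return (s, e), False
    half = window_bp // 2
    return (max(pos0 - half, 0), pos0 + half), True
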