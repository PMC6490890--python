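"""Reporter-assay and ChIP-qPCR quantification arithmetic.

Dual-luciferase: each well's firefly counts are normalized by its Renilla
counts (transfection control); construct activity is expressed relative to
the mean normalized activity of an enhancer-less baseline construct, and
the two alleles of a construct are compared with Student's t test
(pooled-variance by default).

ChIP-qPCR: immunoprecipitated DNA is expressed as percent of the
dilution-adjusted input chromatin, assuming amplification efficiency 2 per
cycle; enrichment is the fold of the target antibody's percent input over
the nonspecific IgG control, which algebraically reduces to
``2 ** (Cp_IgG - Cp_target)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

EFFICIENCY = 2.0  # amplification factor per PCR cycle


class AssayError(ValueError):
    pass


@dataclass(frozen=True)
class LuciferaseWell:
    construct_id: str
    allele: str
    replicate: int
    firefly_counts: float
    renilla_counts: float


@dataclass(frozen=True)
class QpcrRecord:
    sample_id: str
    antibody: str          # "target" | "IgG" | "input"
    cp_value: float        # crossing-point cycles
    input_fraction: float  # e.g. 0.10 for a 10% input aliquot

    def __post_init__(self) -> None:
        if not (0 < self.cp_value < 45):
            raise AssayError(f"Cp out of range: {self.cp_value}")
        if not (0 < self.input_fraction <= 1):
            raise AssayError(f"input fraction out of (0,1]: {self.input_fraction}")


def relative_luciferase(
    wells: list[LuciferaseWell], baseline_construct: str,
    baseline_aggregate: str = "mean",
) -> pd.DataFrame:
    """Per-construct relative activity (mean, sd, n over replicates).

    normalized = firefly / renilla per well; relative = normalized divided
    by the aggregate normalized activity of the baseline construct (mean by
    default, median selectable).  The baseline's own relative mean is 1 by
    construction (for the mean aggregate).  Wells with zero Renilla are
    excluded with a warning.
    """
    usable = []
    for w in wells:
        if w.renilla_counts <= 0:
            logger.warning("excluding well %s/%s rep %d: nonpositive Renilla",
                           w.construct_id, w.allele, w.replicate)
            continue
        usable.append(w)
    df = pd.DataFrame([{
        "construct_id": w.construct_id, "allele": w.allele,
        "replicate": w.replicate,
        "normalized": w.firefly_counts / w.renilla_counts,
    } for w in usable])
    if df.empty:
        raise AssayError("no usable wells")
    base = df.loc[df["construct_id"] == baseline_construct, "normalized"]
    if base.empty:
        raise AssayError(f"baseline construct {baseline_construct!r} has no wells")
    denom = base.mean() if baseline_aggregate == "mean" else base.median()
    df["relative"] = df["normalized"] / denom
    out = (df.groupby(["construct_id", "allele"], as_index=False)["relative"]
             .agg(mean_relative="mean", sd_relative="std", n="count"))
    return out


def compare_alleles(
    activities1: np.ndarray, activities2: np.ndarray,
    welch: bool = False,
) -> tuple[float, float, float]:
    """Two-sided two-sample t test on per-allele replicate activities.

    Pooled-variance Student's t by default; Welch via ``welch=True``.
    Returns ``(t, df, p)``.  When both groups have zero variance and equal
    means the comparison is vacuous and ``(0, df, 1)`` is returned, logged.
    """
    x = np.asarray(activities1, dtype=float)
    y = np.asarray(activities2, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise AssayError("need at least 2 replicates per allele")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        dof = len(x) + len(y) - 2
        if np.mean(x) == np.mean(y):
            logger.info("zero variance and equal means: p = 1 by convention")
            return 0.0, float(dof), 1.0
        return math.inf if np.mean(x) > np.mean(y) else -math.inf, float(dof), 0.0
    res = stats.ttest_ind(x, y, equal_var=not welch)
    dof = float(res.df) if hasattr(res, "df") else float(len(x) + len(y) - 2)
    return float(res.statistic), dof, float(res.pvalue)


def percent_input(cp_antibody: float, cp_input: float, input_fraction: float,
                  efficiency: float = EFFICIENCY) -> float:
    """Percent-input of an immunoprecipitated sample.

    The input Cp is first adjusted for the input dilution
    (``cp_input - log_E(1 / input_fraction)``); percent input is then
    ``100 * E ** (adjusted_input_cp - cp_antibody)``.
    """
    adjusted = cp_input - math.log(1.0 / input_fraction, efficiency)
    return 100.0 * efficiency ** (adjusted - cp_antibody)


def chip_fold_enrichment(records: list[QpcrRecord],
                         efficiency: float = EFFICIENCY) -> pd.DataFrame:
    """Percent-input per antibody and target fold-enrichment over IgG.

    Expects one input, one IgG and one target record per ``sample_id``
    group.  With efficiency 2 the fold reduces algebraically to
    ``2 ** (Cp_IgG - Cp_target)``.  A group lacking IgG reports percent
    inputs with the fold left NaN and flagged.
    """
    rows = []
    by_sample: dict[str, dict[str, QpcrRecord]] = {}
    for r in records:
        grp = by_sample.setdefault(r.sample_id, {})
        if r.antibody in grp:
            raise AssayError(f"duplicate {r.antibody} record for sample {r.sample_id}")
        grp[r.antibody] = r
    for sample in sorted(by_sample):
        grp = by_sample[sample]
        if "input" not in grp or "target" not in grp:
            raise AssayError(f"sample {sample}: needs both input and target records")
        inp, tgt = grp["input"], grp["target"]
        pi_target = percent_input(tgt.cp_value, inp.cp_value, inp.input_fraction, efficiency)
        if "IgG" in grp:
            igg = grp["IgG"]
            pi_igg = percent_input(igg.cp_value, inp.cp_value, inp.input_fraction, efficiency)
            fold = pi_target / pi_igg
            flag = ""
        else:
            logger.warning("sample %s: no IgG control; fold undefined", sample)
            pi_igg, fold, flag = math.nan, math.nan, "no_igg_control"
        rows.append({
            "sample_id": sample,
            "percent_input_target": pi_target,
            "percent_input_igg": pi_igg,
            "fold_over_igg": fold,
            "flag": flag,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# TSV entry points
# ---------------------------------------------------------------------------

def read_luciferase_tsv(path) -> list[LuciferaseWell]:
    df = pd.read_csv(path, sep="\t")
    return [LuciferaseWell(str(r.construct_id), str(r.allele), int(r.replicate),
                           float(r.firefly), float(r.renilla))
            for r in df.itertuples()]


def read_qpcr_tsv(path) -> list[QpcrRecord]:
    df = pd.read_csv(path, sep="\t")
    return [QpcrRecord(str(r.sample_id), str(r.antibody), float(r.cp),
                       float(r.input_fraction))
            for r in df.itertuples()]
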