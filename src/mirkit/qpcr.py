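"""qPCR analysis: ΔΔCt fold changes and two-amplicon abundance ratios.

Both computations assume 100% amplification efficiency (one doubling per
cycle), the standard ``FC = 2^−ΔΔCt`` form; a per-amplicon efficiency
override exists but defaults off.  Technical replicates are averaged on
the Ct scale before any differencing.

The two-amplicon ratio quantifies the relative abundance of two regions of
one locus within the same RNA sample, e.g. the body of a lncRNA versus the
pre-miRNA hairpin at its 3' end.  For amplicons *a* and *b* in one sample,
``ratio = 2^(Ct_b − Ct_a)`` estimates abundance(a) : abundance(b); a large
ratio from the lncRNA-body : pre-miRNA comparison is the signature of
preferential proximal polyadenylation, which terminates most transcripts
before the miRNA hairpin.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from mirkit.errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

_CT_COLUMNS = ("sample_id", "condition", "amplicon", "replicate", "ct")

#: Technical replicates whose Ct spread exceeds this (cycles) are logged.
MAX_CT_SPREAD_WARN = 0.5


def _check_ct_table(measurements: pd.DataFrame) -> pd.DataFrame:
    for col in _CT_COLUMNS:
        if col not in measurements.columns:
            raise SchemaError(f"Ct table is missing column {col!r}")
    table = measurements.copy()
    table["ct"] = pd.to_numeric(table["ct"], errors="raise")
    if not np.isfinite(table["ct"]).all() or (table["ct"] <= 0).any():
        raise ValidationError("Ct values must be finite and positive")
    key = ["sample_id", "amplicon", "replicate"]
    if table.duplicated(subset=key).any():
        raise ValidationError("(sample_id, amplicon, replicate) must be unique")
    return table


def _mean_ct(table: pd.DataFrame, sample_id: str, amplicon: str) -> float:
    sub = table[(table["sample_id"] == sample_id) & (table["amplicon"] == amplicon)]
    if sub.empty:
        raise ValidationError(
            f"sample {sample_id!r}: amplicon {amplicon!r} not measured"
        )
    spread = float(sub["ct"].max() - sub["ct"].min())
    if spread > MAX_CT_SPREAD_WARN:
        logger.warning(
            "sample %s amplicon %s: replicate Ct spread %.2f cycles exceeds %.1f",
            sample_id,
            amplicon,
            spread,
            MAX_CT_SPREAD_WARN,
        )
    return float(sub["ct"].mean())


def delta_delta_ct(
    measurements: pd.DataFrame,
    target: str,
    control_amplicon: str,
    reference_condition: str,
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """Per-sample ΔΔCt fold changes of ``target`` against an endogenous control.

    For each sample, ``ΔCt = mean Ct(target) − mean Ct(control)`` over the
    technical replicates; ``ΔΔCt = ΔCt − mean ΔCt`` over the
    reference-condition samples; ``FC = efficiency^−ΔΔCt`` (efficiency 2 =
    the plain 2^−ΔΔCt form).  The mean ΔΔCt of the reference condition is 0
    by construction, so its fold changes average 1 on the log scale.
    """
    if efficiency <= 1:
        raise ValidationError("amplification efficiency must exceed 1")
    table = _check_ct_table(measurements)
    samples = (
        table[["sample_id", "condition"]].drop_duplicates().reset_index(drop=True)
    )
    if not (samples["condition"] == reference_condition).any():
        raise ValidationError(
            f"reference condition {reference_condition!r} absent from the table"
        )
    delta_ct = {
        row.sample_id: _mean_ct(table, row.sample_id, target)
        - _mean_ct(table, row.sample_id, control_amplicon)
        for row in samples.itertuples()
    }
    ref_mean = float(
        np.mean(
            [
                delta_ct[row.sample_id]
                for row in samples.itertuples()
                if row.condition == reference_condition
            ]
        )
    )
    out = samples.copy()
    out["amplicon"] = target
    out["delta_ct"] = out["sample_id"].map(delta_ct)
    out["delta_delta_ct"] = out["delta_ct"] - ref_mean
    out["fold_change"] = efficiency ** (-out["delta_delta_ct"])
    return out


@dataclass(frozen=True)
class RatioEstimate:
    """Condition-level abundance ratio of two amplicons (a : b)."""

    amplicon_a: str
    amplicon_b: str
    condition: str
    ratio: float  # geometric mean of per-sample ratios
    n_samples: int
    dispersion: float  # sd of per-sample log2 ratios (nan for one sample)
    per_sample_ratios: tuple[float, ...] = field(default=())

    @property
    def log2_ratio(self) -> float:
        return math.log2(self.ratio)


def per_sample_log2_ratios(
    measurements: pd.DataFrame,
    amplicon_a: str,
    amplicon_b: str,
    condition: str,
    efficiency: float = 2.0,
) -> pd.Series:
    """Per-sample ``log2`` abundance ratios a : b within one condition.

    ``log2 ratio = (mean Ct(b) − mean Ct(a)) · log2(efficiency)``; with the
    default efficiency of 2 this is just the Ct difference.
    """
    table = _check_ct_table(measurements)
    cond = table[table["condition"] == condition]
    if cond.empty:
        raise ValidationError(f"condition {condition!r} absent from the table")
    for amplicon in (amplicon_a, amplicon_b):
        if not (cond["amplicon"] == amplicon).any():
            raise ValidationError(
                f"amplicon {amplicon!r} not measured in condition {condition!r}"
            )
    ratios = {}
    for sample_id in cond["sample_id"].unique():
        dct = _mean_ct(cond, sample_id, amplicon_b) - _mean_ct(
            cond, sample_id, amplicon_a
        )
        ratios[sample_id] = dct * math.log2(efficiency)
    return pd.Series(ratios, name=f"log2({amplicon_a}:{amplicon_b})")


def amplicon_ratio(
    measurements: pd.DataFrame,
    amplicon_a: str,
    amplicon_b: str,
    condition: str,
    efficiency: float = 2.0,
) -> RatioEstimate:
    """Condition-level abundance ratio a : b (geometric mean over samples).

    Assumes equal amplification efficiency for both amplicons.  Dispersion
    is the sample sd of per-sample log2 ratios (nan with a single sample).
    """
    log2_ratios = per_sample_log2_ratios(
        measurements, amplicon_a, amplicon_b, condition, efficiency=efficiency
    )
    per_sample = tuple(float(2.0**r) for r in log2_ratios)
    dispersion = float(log2_ratios.std(ddof=1)) if len(log2_ratios) > 1 else float("nan")
    return RatioEstimate(
        amplicon_a=amplicon_a,
        amplicon_b=amplicon_b,
        condition=condition,
        ratio=float(2.0 ** log2_ratios.mean()),
        n_samples=len(log2_ratios),
        dispersion=dispersion,
        per_sample_ratios=per_sample,
    )


def compare_ratios(
    log2_ratios_a: Sequence[float],
    log2_ratios_b: Sequence[float],
    welch: bool = False,
) -> dict:
    """Two-sided two-sample Student's t-test on per-sample log2 ratios.

    Equal-variance by default; ``welch=True`` drops that assumption.  If
    both groups are constant, t is 0 (equal means) or ±inf, avoiding the
    0/0 form of the statistic.
    """
    a = np.asarray(log2_ratios_a, dtype=float)
    b = np.asarray(log2_ratios_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs at least 2 per-sample ratios")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a.mean() == b.mean():
            return {"t_statistic": 0.0, "p_value": 1.0}
        sign = 1.0 if a.mean() > b.mean() else -1.0
        return {"t_statistic": sign * float("inf"), "p_value": 0.0}
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return {"t_statistic": float(t), "p_value": float(p)}
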