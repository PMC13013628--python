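"""Signed maturity/aging indices, anxiety effect sizes, and their correlation.

A model's similarity to a reference signature (developmental timepoint,
aged timepoint, neural excitation/suppression panel, ...) is summarized as
a signed index: sign * -log10(overlap P), positive when the model's
expression changes are concordant with the reference and negative when
discordant. Anxiety is summarized per model as a polarity-adjusted Cohen's
d computed from published group summary statistics (pooled SD without
n-weighting), and the two axes are related by Pearson correlation with the
exact t-transform p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

P_FLOOR = 1e-300


class UndefinedEffectError(ValueError):
    """Both group SDs are zero: Cohen's d is undefined."""


def maturity_index(p: float, sign: int) -> float:
    """Signed -log10 of an overlap P value.

    The published index is -log10 of a "signed P value" (negative P for
    discordant overlap); since a probability cannot be negative, the sign
    is carried separately and the index is sign * -log10(p), giving the
    bidirectional axis used for all scatter plots.
    """
    if not 0 < p <= 1:
        raise ValueError(f"p must lie in (0, 1], got {p}")
    if sign not in (1, -1):
        raise ValueError("sign must be +1 or -1")
    return sign * -math.log10(max(p, P_FLOOR))


@dataclass(frozen=True)
class BehavioralMeasure:
    """Group summary statistics for one anxiety-related behavioral measure.

    polarity is +1 when a larger value means more anxiety (e.g. latency to
    enter the light box) and -1 otherwise (e.g. time in open arms).
    """

    model_id: str
    measure: str
    polarity: int
    mean_model: float
    sd_model: float
    n_model: int
    mean_control: float
    sd_control: float
    n_control: int

    def __post_init__(self) -> None:
        if self.polarity not in (1, -1):
            raise ValueError("polarity must be +1 or -1")
        if self.sd_model < 0 or self.sd_control < 0:
            raise ValueError("SDs must be nonnegative")
        if self.n_model < 1 or self.n_control < 1:
            raise ValueError("group sizes must be positive")

    @classmethod
    def from_sem(
        cls,
        model_id,
        measure,
        polarity,
        mean_model,
        sem_model,
        n_model,
        mean_control,
        sem_control,
        n_control,
    ) -> "BehavioralMeasure":
        """Build from SEM-reported groups via SD = SEM * sqrt(n)."""
        if n_model < 2 or n_control < 2:
            raise ValueError("SEM conversion requires n >= 2 per group")
        return cls(
            model_id=model_id,
            measure=measure,
            polarity=polarity,
            mean_model=mean_model,
            sd_model=sem_model * math.sqrt(n_model),
            n_model=n_model,
            mean_control=mean_control,
            sd_control=sem_control * math.sqrt(n_control),
            n_control=n_control,
        )


@dataclass(frozen=True)
class EffectSize:
    """Cohen's d for one measure: raw and polarity-adjusted."""

    model_id: str
    measure: str
    d_raw: float
    d_adjusted: float


def cohens_d(m: BehavioralMeasure) -> EffectSize:
    """Cohen's d with the unweighted pooled SD sqrt((s1^2 + s2^2)/2).

    d_raw = (M_model - M_control) / S_pooled; d_adjusted flips the sign so
    that positive always means more anxiety in the model group.
    """
    if m.sd_model == 0 and m.sd_control == 0:
        raise UndefinedEffectError(f"{m.model_id}/{m.measure}: both SDs zero")
    s_pooled = math.sqrt((m.sd_model**2 + m.sd_control**2) / 2.0)
    d_raw = (m.mean_model - m.mean_control) / s_pooled
    return EffectSize(
        model_id=m.model_id,
        measure=m.measure,
        d_raw=d_raw,
        d_adjusted=m.polarity * d_raw,
    )


def model_anxiety_index(measures) -> float:
    """Unweighted mean of polarity-adjusted d across a model's measures."""
    measures = list(measures)
    if not measures:
        raise ValueError("at least one behavioral measure required")
    return float(np.mean([cohens_d(m).d_adjusted for m in measures]))


@dataclass
class IndexTable:
    """Per-model signed indices against a panel of reference signatures.

    data: DataFrame of signed -log10 indices (rows = models, columns =
        reference ids).
    pvalues / signs: the underlying overlap P and sign per cell.
    reference_families: column -> family label ("development", "aging",
        "excitation", ...), used to summarize one value per model.
    """

    data: pd.DataFrame
    pvalues: pd.DataFrame
    signs: pd.DataFrame
    reference_families: dict

    @classmethod
    def from_overlaps(cls, overlaps: dict, reference_families: dict) -> "IndexTable":
        """Build from {(model_id, reference_id): SignedOverlap}."""
        models = sorted({m for m, _ in overlaps})
        refs = sorted({r for _, r in overlaps}, key=list(reference_families).index)
        data = pd.DataFrame(index=models, columns=refs, dtype=float)
        pvals = data.copy()
        signs = data.copy()
        for (m, r), ov in overlaps.items():
            pvals.loc[m, r] = ov.overall_p
            signs.loc[m, r] = ov.sign
            # use the exact log-space magnitude when available so very
            # strong overlaps stay distinguishable below the float floor
            log10p = getattr(ov, "overall_log10p", None)
            if log10p is None:
                data.loc[m, r] = maturity_index(ov.overall_p, ov.sign)
            else:
                data.loc[m, r] = ov.sign * -log10p
        if data.isna().any().any():
            missing = [
                (m, r) for m in models for r in refs if pd.isna(data.loc[m, r])
            ]
            raise ValueError(f"missing model-reference pairs: {missing[:5]}...")
        return cls(data, pvals, signs, dict(reference_families))

    def family_columns(self, family: str):
        cols = [c for c, f in self.reference_families.items() if f == family]
        if not cols:
            raise ValueError(f"no reference columns for family {family!r}")
        return cols


def model_maturity_summary(
    table: IndexTable, reference_family: str = "development", method: str = "most_significant"
) -> pd.Series:
    """One signed index per model for a reference family.

    method "most_significant" (default) takes the family index of largest
    absolute value, sign preserved — mirroring screening against "at least
    one" reference timepoint; "mean" averages; a concrete reference id
    selects that single column.
    """
    if method == "most_significant":
        sub = table.data[table.family_columns(reference_family)]
        idx = sub.abs().to_numpy().argmax(axis=1)
        return pd.Series(
            sub.to_numpy()[np.arange(len(sub)), idx], index=sub.index, name=reference_family
        )
    if method == "mean":
        return table.data[table.family_columns(reference_family)].mean(axis=1)
    if method in table.data.columns:
        return table.data[method]
    raise ValueError(f"unknown summary method {method!r}")


def pearson_p_from_r(r: float, n: int) -> float:
    """Two-sided p for a Pearson r via t = r*sqrt(n-2)/sqrt(1-r^2)."""
    if n < 3:
        raise ValueError("need n >= 3")
    if not -1 < r < 1:
        return 0.0 if abs(r) == 1 else float("nan")
    t = r * math.sqrt(n - 2) / math.sqrt(1 - r * r)
    return float(2 * stats.t.sf(abs(t), n - 2))


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_two_sided: float
    slope: float
    intercept: float
    n: int


def correlate_indices(x, y) -> CorrelationResult:
    """Pearson correlation with the exact t-transform two-sided p-value,
    plus the least-squares regression line."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1-d arrays, n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(np.dot(xc, yc) / math.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    slope = float(np.dot(xc, yc) / np.dot(xc, xc))
    intercept = float(y.mean() - slope * x.mean())
    return CorrelationResult(
        r=r,
        p_two_sided=pearson_p_from_r(r, len(x)),
        slope=slope,
        intercept=intercept,
        n=len(x),
    )
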