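"""Statistical layer: normalization, drug-effect inference, correlations.

Covers the measurement-side statistics that accompany the network work:

* total-protein (Fast Green dye) normalization of spot intensities,
* the two-stage drug-effect test — a linear model of intensity on time,
  treatment group and their interaction, followed (only when the
  interaction is significant) by a one-sided Wilcoxon rank-sum test for
  lower treated intensities at the final time point,
* optimal-treatment selection as the efficient treatment with the smallest
  end-point p-value, and
* Kendall tau-b association between two protein time courses.

No multiplicity adjustment is applied across proteins or treatments in this
layer; callers comparing many treatments should be aware the "efficient"
verdicts are per-test decisions at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
import statsmodels.api as sm

__all__ = [
    "DrugEffectResult",
    "fastgreen_normalize",
    "drug_effect_test",
    "optimal_treatment",
    "kendall_association",
]

ALPHA = 0.05


def fastgreen_normalize(signals, total_protein) -> np.ndarray:
    """Spot-wise total-protein correction with native-median rescaling.

    Each spot's signal is divided by its total-protein correction factor
    (stain value over the median stain value); the corrected values are
    then rescaled so their median equals the median of the raw signals.
    """
    signals = np.asarray(signals, dtype=float)
    stain = np.asarray(total_protein, dtype=float)
    if signals.shape != stain.shape:
        raise ValueError("signals and total_protein must have equal length")
    bad = np.nonzero(stain <= 0)[0]
    if bad.size:
        raise ValueError(f"nonpositive total-protein value at spot(s) {bad.tolist()}")
    factor = stain / np.median(stain)
    corrected = signals / factor
    scale = np.median(signals) / np.median(corrected)
    return corrected * scale


@dataclass(frozen=True)
class DrugEffectResult:
    """Two-stage verdict for one (protein, treatment) pair."""

    protein: str
    treatment: str
    interaction_p: float
    endpoint_p: float | None
    efficient: bool
    endpoint_tested: bool = True


def _series_frame(series) -> pd.DataFrame:
    df = pd.DataFrame(series, columns=["time", "replicate", "value"]) \
        if not isinstance(series, pd.DataFrame) else series
    if not {"time", "value"} <= set(df.columns):
        raise ValueError("series needs 'time' and 'value' columns")
    return df


def drug_effect_test(
    treated,
    untreated,
    final_time: float,
    protein: str = "",
    treatment: str = "",
    time_as_factor: bool = False,
) -> DrugEffectResult:
    """Interaction-gated one-sided end-point comparison.

    Stage 1 fits intensity ~ time + group + time:group over the pooled
    replicates (time continuous by default, categorical with
    ``time_as_factor``) and takes the F-test p of the interaction term(s).
    Stage 2, entered only when stage 1 is significant, is an exact
    one-sided Wilcoxon rank-sum test for smaller treated intensities among
    the final-time replicates.  ``efficient`` requires both p < 0.05.
    """
    tr = _series_frame(treated)
    un = _series_frame(untreated)
    if set(tr["time"].unique()) != set(un["time"].unique()):
        raise ValueError("treated and untreated must share the time grid")
    if final_time not in set(tr["time"]):
        raise ValueError(f"final time {final_time} not in the series")

    df = pd.concat([tr.assign(group=1.0), un.assign(group=0.0)],
                   ignore_index=True)
    y = df["value"].to_numpy(dtype=float)
    g = df["group"].to_numpy()
    t = df["time"].to_numpy(dtype=float)
    if time_as_factor:
        levels = np.unique(t)[1:]  # reference = first time point
        tdum = (t[:, None] == levels[None, :]).astype(float)
        X0 = np.column_stack([np.ones_like(y), tdum, g])
        X1 = np.column_stack([X0, tdum * g[:, None]])
        fit1 = sm.OLS(y, X1).fit()
        k = tdum.shape[1]
        R = np.zeros((k, X1.shape[1]))
        R[:, -k:] = np.eye(k)
        interaction_p = float(fit1.f_test(R).pvalue)
    else:
        X1 = np.column_stack([np.ones_like(y), t, g, t * g])
        fit1 = sm.OLS(y, X1).fit()
        interaction_p = float(fit1.pvalues[-1])

    endpoint_p: float | None = None
    endpoint_tested = False
    efficient = False
    if interaction_p < ALPHA:
        tr_end = tr.loc[tr["time"] == final_time, "value"].to_numpy()
        un_end = un.loc[un["time"] == final_time, "value"].to_numpy()
        if tr_end.size >= 2 and un_end.size >= 2:
            endpoint_tested = True
            endpoint_p = float(
                sstats.mannwhitneyu(tr_end, un_end, alternative="less",
                                    method="auto").pvalue
            )
            efficient = endpoint_p < ALPHA
    return DrugEffectResult(protein, treatment, interaction_p, endpoint_p,
                            efficient, endpoint_tested)


def optimal_treatment(results: list[DrugEffectResult]) -> str | None:
    """Efficient treatment with the smallest end-point p (None if none).

    Ties resolve to the lexicographically first treatment id.
    """
    proteins = {r.protein for r in results}
    if len(proteins) > 1:
        raise ValueError("results must belong to a single protein")
    efficient = [r for r in results if r.efficient and r.endpoint_p is not None]
    if not efficient:
        return None
    best = min(efficient, key=lambda r: (r.endpoint_p, r.treatment))
    return best.treatment


@dataclass(frozen=True)
class KendallResult:
    tau: float
    p_value: float
    defined: bool = True


def kendall_association(series_a, series_b) -> KendallResult:
    """Kendall tau-b with tie correction; exact p for small untied samples."""
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("series must have equal length >= 3")
    if np.all(a == a[0]) or np.all(b == b[0]):
        return KendallResult(float("nan"), float("nan"), defined=False)
    res = sstats.kendalltau(a, b)
    return KendallResult(float(res.statistic), float(res.pvalue))
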