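"""Behavioural filtering, condition rates, signal-detection indices, and
within-subject confidence intervals.

The two signal-detection indices quantify how strongly behaviour relies on
cue information in the DPX task:

* ``d'context = Z(AX correct rate) - Z(BX incorrect rate)`` — reliance on the
  cue (context) to drive performance;
* ``A-cue bias = 0.5 * [Z(AX correct rate) + Z(AY incorrect rate)]`` — the
  response bias induced by predictive A cues,

with ``Z`` the standard-normal quantile. Rates of exactly 0 or 1 are edge
corrected to ``1/(2N)`` and ``1 - 1/(2N)`` (N = responded trials in that
pair) so both indices stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import PAIRS


def filter_rt(trials: pd.DataFrame, lo: float = 0.1, hi: float = 1.0) -> pd.DataFrame:
    """Drop rows whose RT is strictly below ``lo`` or strictly above ``hi``.

    Rows without an RT (no response) are always retained; order is preserved.
    The default bounds are the conventional 100-1000 ms exclusion window.
    """
    if not lo < hi:
        raise ValueError("lo must be < hi")
    rt = trials["rt"]
    keep = rt.isna() | ((rt >= lo) & (rt <= hi))
    return trials.loc[keep]


@dataclass(frozen=True)
class ConditionRates:
    """Per-pair response counts and rates over responded trials."""

    table: pd.DataFrame  # index: pair; columns: n_trials, n_correct, n_incorrect,
    #                      rate_correct, rate_incorrect, defined

    def rate(self, pair: str, which: str) -> float:
        if not self.table.loc[pair, "defined"]:
            raise ValueError(f"rates undefined for pair {pair}: no responded trials")
        return float(self.table.loc[pair, f"rate_{which}"])

    def n(self, pair: str) -> int:
        return int(self.table.loc[pair, "n_trials"])


def condition_rates(trials: pd.DataFrame) -> ConditionRates:
    """Exact correct/incorrect counts and rates per pair, responded trials only.

    Pairs with no responded trials are flagged ``defined = False``.
    """
    rows = []
    responded = trials[trials["correct"].notna()]
    for pair in PAIRS:
        sub = responded[responded["pair"] == pair]
        n = len(sub)
        nc = int(sub["correct"].sum()) if n else 0
        ni = n - nc
        rows.append(
            dict(
                pair=pair,
                n_trials=n,
                n_correct=nc,
                n_incorrect=ni,
                rate_correct=nc / n if n else np.nan,
                rate_incorrect=ni / n if n else np.nan,
                defined=n > 0,
            )
        )
    return ConditionRates(pd.DataFrame(rows).set_index("pair"))


def _edge_corrected_z(rate: float, n: int) -> float:
    """Standard-normal quantile of a rate, edge-correcting 0 and 1 by 1/(2N)."""
    if rate <= 0.0:
        rate = 1.0 / (2.0 * n)
    elif rate >= 1.0:
        rate = 1.0 - 1.0 / (2.0 * n)
    return float(stats.norm.ppf(rate))


def dprime_context(rates: ConditionRates) -> float:
    """Z(AX correct rate) - Z(BX incorrect rate): reliance on cue information."""
    return _edge_corrected_z(
        rates.rate("AX", "correct"), rates.n("AX")
    ) - _edge_corrected_z(rates.rate("BX", "incorrect"), rates.n("BX"))


def a_cue_bias(rates: ConditionRates) -> float:
    """0.5 * [Z(AX correct rate) + Z(AY incorrect rate)]: A-cue response bias."""
    return 0.5 * (
        _edge_corrected_z(rates.rate("AX", "correct"), rates.n("AX"))
        + _edge_corrected_z(rates.rate("AY", "incorrect"), rates.n("AY"))
    )


def sdt_scores(trials: pd.DataFrame, subject_id: str = "") -> dict:
    """Both indices plus their probit terms for one subject's trials."""
    rates = condition_rates(trials)
    return {
        "subject_id": subject_id,
        "dprime_context": dprime_context(rates),
        "a_cue_bias": a_cue_bias(rates),
        "z_AX_correct": _edge_corrected_z(rates.rate("AX", "correct"), rates.n("AX")),
        "z_BX_incorrect": _edge_corrected_z(rates.rate("BX", "incorrect"), rates.n("BX")),
        "z_AY_incorrect": _edge_corrected_z(rates.rate("AY", "incorrect"), rates.n("AY")),
    }


def within_subject_ci(
    subject_condition_means: np.ndarray, level: float = 0.99
) -> np.ndarray:
    """Per-condition half-widths of the within-subject confidence interval.

    Implements the subject-centring recipe with the J/(J-1) small-sample
    variance correction for J conditions (Cousineau-Morey): each subject's
    row mean is removed (grand mean restored), the per-condition variance of
    the centred scores is rescaled by J/(J-1), and the half-width uses the
    Student-t quantile at the requested level with S-1 degrees of freedom.
    """
    m = np.asarray(subject_condition_means, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2:
        raise ValueError("need a (subjects x conditions) matrix with >= 2 subjects")
    S, J = m.shape
    if J < 2:
        raise ValueError("within-subject CI is undefined for a single condition")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    centred = m - m.mean(axis=1, keepdims=True) + m.mean()
    var = centred.var(axis=0, ddof=1) * J / (J - 1)
    tq = stats.t.ppf(0.5 + level / 2.0, df=S - 1)
    return tq * np.sqrt(var / S)
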