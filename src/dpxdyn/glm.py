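"""Two-level mass-univariate regression with bootstrap F-max FWER control.

Level 1 fits ``Y = X beta + eps`` per subject at every channel x time point
via the Moore-Penrose pseudo-inverse (SVD), so rank-deficient designs return
the minimum-norm solution. Level 2 contrasts condition-specific coefficient
maps across subjects with a paired t-test; family-wise error over all
channel-time points is controlled with the bootstrap maximum-F procedure:
condition maps are grand-mean centred across subjects (imposing the null),
whole subjects are resampled with replacement, the maximum F = t^2 over all
points is recorded per resample, and the (1 - alpha) quantile of the maxima
is the significance threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import SubjectEpochs, VectorisedData, vectorise_epochs

logger = logging.getLogger(__name__)

#: effect-coding reference maps for the two binary task factors
EFFECT_CODES = {"cue": {"A": -1.0, "B": 1.0}, "probe": {"X": -1.0, "Y": 1.0}}


@dataclass
class DesignMatrix:
    X: np.ndarray                 # (m, k)
    names: list[str]
    coding: str = "effect"
    reference_map: dict = field(default_factory=dict)
    rank_warnings: list[str] = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.X.shape[1]


@dataclass
class BetaMaps:
    subject_id: str
    beta: np.ndarray              # (k, n_channels, n_times)
    names: list[str]
    design_rank: int


@dataclass
class GroupTestResult:
    t_map: np.ndarray             # (n_channels, n_times)
    f_map: np.ndarray
    df: int
    alpha: float | None = None
    B: int | None = None
    f_crit: float | None = None
    max_f_distribution: np.ndarray | None = None
    mask: np.ndarray | None = None
    contrast: str = ""
    degenerate: np.ndarray | None = None  # zero-variance points, if any


@dataclass
class ModerationResult:
    b_map: np.ndarray             # slope, microvolts per covariate unit
    t_map: np.ndarray
    df: int
    covariate_name: str
    alpha: float | None = None
    B: int | None = None
    f_crit: float | None = None
    max_f_distribution: np.ndarray | None = None
    mask: np.ndarray | None = None


# --------------------------------------------------------------------------
# level 1

def build_design(
    trials: pd.DataFrame,
    factors: list[str],
    add_intercept: bool = True,
) -> DesignMatrix:
    """Effect-coded design matrix (A/X = -1, B/Y = +1) aligned with the trials.

    ``factors`` may name the binary factors ('cue', 'probe') and interactions
    as 'cue:probe' (the elementwise product of the parent columns). A factor
    with a single observed level is kept but recorded as a rank warning.
    """
    cols, names, warnings_ = [], [], []
    if add_intercept:
        cols.append(np.ones(len(trials)))
        names.append("intercept")
    coded = {}
    for f in ("cue", "probe"):
        if f in trials.columns:
            coded[f] = trials[f].map(EFFECT_CODES[f]).to_numpy(dtype=float)
    for f in factors:
        if ":" in f:
            a, b = f.split(":")
            col = coded[a] * coded[b]
        else:
            if f not in coded:
                raise ValueError(f"unknown factor {f!r}")
            col = coded[f]
        if len(trials) and np.unique(col).size < 2:
            warnings_.append(f"factor {f!r} has a single observed level")
        cols.append(col)
        names.append(f)
    X = np.column_stack(cols) if cols else np.empty((len(trials), 0))
    ref = {f: EFFECT_CODES[f] for f in ("cue", "probe") if f in "".join(factors)}
    return DesignMatrix(X=X, names=names, reference_map=ref, rank_warnings=warnings_)


def build_condition_design(trials: pd.DataFrame, by: str = "cue") -> DesignMatrix:
    """One indicator column per observed level of a factor or of 'pair'.

    The fitted coefficients are the condition-specific mean maps used by the
    second-level contrasts.
    """
    levels = sorted(trials[by].unique())
    cols = [(trials[by] == lev).to_numpy(dtype=float) for lev in levels]
    return DesignMatrix(
        X=np.column_stack(cols), names=list(levels), coding="indicator"
    )


def fit_first_level(Y, X: DesignMatrix, subject_id: str = "",
                    n_channels: int | None = None, n_times: int | None = None) -> BetaMaps:
    """``beta = pinv(X) Y`` reshaped to (k, channels, times).

    Accepts a :class:`VectorisedData` (shape metadata taken from it) or a
    plain (m, n) matrix with explicit ``n_channels``/``n_times``. Equals the
    OLS solution for full-rank designs and the minimum-norm solution
    otherwise.
    """
    if isinstance(Y, VectorisedData):
        n_channels, n_times = Y.n_channels, Y.n_times
        Y = Y.Y
    if n_channels is None or n_times is None:
        raise ValueError("n_channels and n_times required for a plain matrix")
    if Y.shape[0] != X.X.shape[0]:
        raise ValueError("Y and X row counts differ")
    rank = int(np.linalg.matrix_rank(X.X)) if X.X.size else 0
    if rank == 0:
        raise ValueError("degenerate design: rank 0")
    beta = np.linalg.pinv(X.X) @ Y
    return BetaMaps(
        subject_id=subject_id,
        beta=beta.reshape(X.k, n_channels, n_times),
        names=list(X.names),
        design_rank=rank,
    )


def condition_beta_stacks(
    subjects: list[SubjectEpochs], by: str = "cue", levels: tuple[str, str] | None = None,
    trial_filter=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject condition coefficient maps for a two-level factor.

    Fits the indicator design per subject and returns two stacks of shape
    (n_subjects, n_channels, n_times), one per level (in the order given by
    ``levels``; default is sorted order). ``trial_filter`` optionally
    restricts the trials entering the fit (e.g. A-cue trials only for the
    probe analysis).
    """
    stacks: dict[str, list[np.ndarray]] = {}
    for ep in subjects:
        trials = ep.trials
        data = ep.data
        if trial_filter is not None:
            keep = trial_filter(trials).to_numpy()
            trials = trials.loc[keep]
            data = data[keep]
        design = build_condition_design(trials, by=by)
        n_tr, n_ch, n_t = data.shape
        bm = fit_first_level(
            data.reshape(n_tr, n_ch * n_t), design, ep.subject_id, n_ch, n_t
        )
        for name, bmap in zip(bm.names, bm.beta):
            stacks.setdefault(name, []).append(bmap)
    if levels is None:
        levels = tuple(sorted(stacks))
    if len(levels) != 2:
        raise ValueError(f"expected two levels, got {levels}")
    return np.stack(stacks[levels[0]]), np.stack(stacks[levels[1]])


# --------------------------------------------------------------------------
# level 2

def _paired_t(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise paired t over axis 0; zero-variance points give signed inf."""
    S = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(S))
    degenerate = sd == 0
    if np.any(degenerate):
        with np.errstate(invalid="ignore"):
            t = np.where(degenerate, np.sign(mean) * np.inf, t)
        t = np.where(degenerate & (mean == 0), 0.0, t)
    return t, degenerate


def paired_t_second_level(
    betas_a: np.ndarray, betas_b: np.ndarray, contrast: str = ""
) -> GroupTestResult:
    """Paired t-test of two per-subject map stacks (a minus b) at every point."""
    if betas_a.shape != betas_b.shape:
        raise ValueError("condition stacks must have identical shapes")
    S = betas_a.shape[0]
    if S < 3:
        raise ValueError("need >= 3 subjects for a paired t-test")
    t, degenerate = _paired_t(betas_a - betas_b)
    if degenerate.any():
        logger.warning("paired t: %d zero-variance points flagged", degenerate.sum())
    return GroupTestResult(
        t_map=t, f_map=t ** 2, df=S - 1, contrast=contrast,
        degenerate=degenerate if degenerate.any() else None,
    )


def _bootstrap_max_f(diffs: np.ndarray, B: int, rng: np.random.Generator) -> np.ndarray:
    """Max F = t^2 over points for B subject-resamples of centred differences.

    ``diffs`` must already be centred (null imposed). Uses resample count
    vectors so each batch is two BLAS products; resamples whose only finite
    F values vanish (zero variance everywhere) fall back to the largest
    finite F seen in that resample.
    """
    S = diffs.shape[0]
    P = diffs.reshape(S, -1)
    P2 = P ** 2
    maxf = np.empty(B)
    batch = max(1, min(B, int(2e7 // max(P.shape[1], 1))))
    done = 0
    while done < B:
        b = min(batch, B - done)
        idx = rng.integers(0, S, size=(b, S))
        counts = np.zeros((b, S))
        for i in range(b):  # bincount per resample; b is small
            counts[i] = np.bincount(idx[i], minlength=S)
        mean = counts @ P / S
        ex2 = counts @ P2 / S
        var = (ex2 - mean ** 2) * (S / (S - 1))
        with np.errstate(divide="ignore", invalid="ignore"):
            f = mean ** 2 / (var / S)
        f[~np.isfinite(f)] = np.nan
        row_max = np.nanmax(np.where(np.isnan(f), -np.inf, f), axis=1)
        if not np.all(np.isfinite(row_max)):
            logger.warning("bootstrap: resample with no finite F; recorded 0")
            row_max[~np.isfinite(row_max)] = 0.0
        maxf[done : done + b] = row_max
        done += b
    return maxf


def fmax_bootstrap_threshold(
    betas_a: np.ndarray,
    betas_b: np.ndarray,
    alpha: float = 0.01,
    B: int = 2000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, np.ndarray]:
    """Bootstrap F-max critical value for the paired contrast a vs b.

    Each condition's coefficient maps are grand-mean centred across subjects
    at every point (imposing H0), whole subjects are resampled with
    replacement, and the maximum F = t^2 over all points is stored per
    resample; the critical value is the empirical (1 - alpha) quantile of
    the B maxima.
    """
    if B < 100:
        raise ValueError("B must be >= 100 for a stable tail quantile")
    if betas_a.shape[0] < 3:
        raise ValueError("need >= 3 subjects")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    centred = (betas_a - betas_a.mean(axis=0)) - (betas_b - betas_b.mean(axis=0))
    maxf = _bootstrap_max_f(centred, B, rng)
    f_crit = float(np.quantile(maxf, 1.0 - alpha))
    return f_crit, maxf


def significance_mask(result: GroupTestResult) -> np.ndarray:
    """Boolean map of points whose F strictly exceeds the critical value."""
    if result.f_crit is None:
        raise ValueError("result has no f_crit; run the bootstrap first")
    return result.f_map > result.f_crit


def group_contrast(
    betas_a: np.ndarray,
    betas_b: np.ndarray,
    alpha: float = 0.01,
    B: int = 2000,
    seed: int | np.random.Generator = 0,
    contrast: str = "",
) -> GroupTestResult:
    """Observed paired t/F maps plus the bootstrap F-max threshold and mask."""
    res = paired_t_second_level(betas_a, betas_b, contrast=contrast)
    f_crit, maxf = fmax_bootstrap_threshold(betas_a, betas_b, alpha, B, seed)
    res.alpha, res.B, res.f_crit, res.max_f_distribution = alpha, B, f_crit, maxf
    res.mask = significance_mask(res)
    return res


# --------------------------------------------------------------------------
# covariate moderation

def covariate_moderation(
    contrast_betas: np.ndarray,
    covariate: np.ndarray,
    alpha: float = 0.01,
    B: int = 2000,
    seed: int | np.random.Generator = 0,
    covariate_name: str = "covariate",
) -> ModerationResult:
    """Whole-scalp simple regression of subject contrast maps on a score.

    The covariate is mean-centred; per point, ``b`` is the regression slope
    and ``t`` its statistic with S - 2 degrees of freedom. The FWER threshold
    reuses the max-statistic bootstrap with the null imposed by removing the
    fitted intercept and slope (resampling subjects with replacement from the
    residual maps paired with the original covariate order).
    """
    S = contrast_betas.shape[0]
    if S < 4:
        raise ValueError("need >= 4 subjects")
    x = np.asarray(covariate, dtype=float)
    if x.shape != (S,):
        raise ValueError("covariate must have one value per subject")
    x = x - x.mean()
    sxx = float((x ** 2).sum())
    if sxx == 0:
        raise ValueError("constant covariate")
    D = contrast_betas.reshape(S, -1)
    b = (x @ D) / sxx
    resid = D - D.mean(axis=0) - np.outer(x, b)
    s2 = (resid ** 2).sum(axis=0) / (S - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = b / np.sqrt(s2 / sxx)
    t[~np.isfinite(t)] = 0.0

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    maxf = np.empty(B)
    for i in range(B):
        idx = rng.integers(0, S, size=S)
        Db = resid[idx]
        bb = (x @ Db) / sxx
        rb = Db - Db.mean(axis=0) - np.outer(x, bb)
        s2b = (rb ** 2).sum(axis=0) / (S - 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            fb = bb ** 2 / (s2b / sxx)
        fb = fb[np.isfinite(fb)]
        maxf[i] = fb.max() if fb.size else 0.0
    f_crit = float(np.quantile(maxf, 1.0 - alpha))
    shape = contrast_betas.shape[1:]
    t_map = t.reshape(shape)
    return ModerationResult(
        b_map=b.reshape(shape), t_map=t_map, df=S - 2,
        covariate_name=covariate_name, alpha=alpha, B=B, f_crit=f_crit,
        max_f_distribution=maxf, mask=(t_map ** 2 > f_crit),
    )


# --------------------------------------------------------------------------
# power

def paired_t_power(n: int, d: float, alpha: float) -> float:
    """Two-sided paired t-test power from the noncentral t distribution."""
    df = n - 1
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    nc = d * np.sqrt(n)
    return float(
        1.0 - stats.nct.cdf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc)
    )


def paired_t_sample_size(
    d: float, power: float, alpha: float, n_cap: int = 100_000
) -> int:
    """Smallest n >= 2 whose two-sided paired t-test power meets the target."""
    if d <= 0 or not 0 < power < 1 or not 0 < alpha < 1:
        raise ValueError("need d > 0 and power, alpha in (0, 1)")
    for n in range(2, n_cap + 1):
        if paired_t_power(n, d, alpha) >= power:
            return n
    raise ValueError(f"target power not attainable with n <= {n_cap}")


def solve_paired_t_n(d: float, power: float, alpha: float) -> float:
    """Continuous sample-size root (the convention of standard power tools).

    Solves ``power(n) = target`` over real n; the integer planning value in
    :func:`paired_t_sample_size` is the ceiling of this root.
    """
    if d <= 0 or not 0 < power < 1 or not 0 < alpha < 1:
        raise ValueError("need d > 0 and power, alpha in (0, 1)")
    from scipy.optimize import brentq

    f = lambda n: paired_t_power(n, d, alpha) - power
    hi = 4.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e7:
            raise ValueError("target power not attainable")
    return float(brentq(f, 2.0, hi, xtol=1e-8))


# --------------------------------------------------------------------------
# summaries

def cluster_summary(
    result: GroupTestResult, channel_labels, times: np.ndarray
) -> pd.DataFrame:
    """Contiguous significant runs per channel: channel, tmin, tmax, peak t."""
    rows = []
    mask = result.mask
    if mask is None:
        raise ValueError("result has no significance mask")
    for c, label in enumerate(channel_labels):
        m = mask[c]
        if not m.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate(([0], m.view(np.int8), [0]))))
        for start, stop in zip(edges[::2], edges[1::2]):
            seg_t = result.t_map[c, start:stop]
            peak = seg_t[np.argmax(np.abs(seg_t))]
            rows.append(
                dict(
                    channel=label,
                    tmin=float(times[start]),
                    tmax=float(times[stop - 1]),
                    n_samples=int(stop - start),
                    peak_t=float(peak),
                )
            )
    return pd.DataFrame(rows, columns=["channel", "tmin", "tmax", "n_samples", "peak_t"])
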