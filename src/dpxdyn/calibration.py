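"""Simulation studies that validate the statistical machinery end to end.

Each function runs the real pipeline components on generated data under the
package's default study conditions and returns the measured quantities:
family-wise error calibration of the bootstrap F-max threshold, recovery of
the injected condition effects, chance-level decoding calibration, the
transient-vs-sustained generalisation dissociation, and the behavioural
generator's fidelity to its target marginals. Problem sizes are chosen to
run on a single desktop core; see docs/methods.md.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import binary_dilation

from . import behaviour as beh
from . import decoding as dec
from . import glm
from . import simulate as sim
from .data import SubjectEpochs, TimeAxis, select_window


def _children(seed: int, n: int):
    return np.random.SeedSequence(seed).spawn(n)


# --------------------------------------------------------------------------
# F-max calibration

def fwer_calibration(
    n_datasets: int = 200,
    n_subjects: int = 16,
    n_channels: int = 16,
    n_times: int = 64,
    B: int = 500,
    alpha: float = 0.01,
    seed: int = 0,
    n_trials_per_condition: tuple[int, int] = (40, 20),
) -> dict:
    """Family-wise error rate of the F-max mask on simulated null datasets.

    Each replicate generates a dataset with no injected condition effects
    (noise-only epochs), runs the full two-level path (condition coefficient
    maps, paired t, bootstrap threshold), and records whether any point is
    flagged. The returned rate should match the nominal alpha up to binomial
    Monte-Carlo error.
    """
    channels = sim.grid_channel_set(n_channels)
    sfreq = 64.0
    span = (-0.5, (n_times - 1) / sfreq - 0.5)
    n_A, n_B = n_trials_per_condition
    block = sim.BlockSpec(
        n_AX=n_A - n_A // 2, n_AY=n_A // 2, n_BX=n_B - n_B // 2,
        n_BY=n_B // 2, n_blocks=1,
    )
    false_positives = 0
    for child in _children(seed, n_datasets):
        rng = np.random.default_rng(child)
        ds_seed = int(rng.integers(0, 2**31))
        subjects, _ = sim.make_dataset(
            n_subjects, block=block, components=[], seed=ds_seed,
            channels=channels, sfreq=sfreq, epoch_span=span,
        )
        a, b_ = glm.condition_beta_stacks(subjects, by="cue", levels=("B", "A"))
        res = glm.group_contrast(a, b_, alpha=alpha, B=B, seed=rng)
        false_positives += bool(res.mask.any())
    return {
        "fwer": false_positives / n_datasets,
        "n_datasets": n_datasets,
        "alpha": alpha,
    }


def single_test_threshold(
    n_subjects: int = 20, B: int = 2000, seed: int = 0
) -> dict:
    """Bootstrap F-max critical value in a single-test configuration.

    With one channel-time point and Gaussian null data the bootstrap
    threshold approximates the central F(1, S-1) upper-alpha quantile.
    """
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((n_subjects, 1, 1))
    b = rng.standard_normal((n_subjects, 1, 1))
    f_crit, _ = glm.fmax_bootstrap_threshold(a, b, alpha=0.01, B=B, seed=rng)
    return {"f_crit": f_crit, "n_subjects": n_subjects, "B": B}


# --------------------------------------------------------------------------
# pattern recovery

def pattern_recovery(
    n_subjects: int = 24,
    B: int = 2000,
    alpha: float = 0.01,
    seed: int = 0,
    sfreq: float = 128.0,
    cue_window: tuple[float, float] = (-0.5, 2.5),
) -> dict:
    """Recovery of the injected cue B-vs-A effects by the F-max mask.

    Generates the default dataset (subjects streamed one at a time to bound
    memory), contrasts the per-subject cue condition coefficient maps, and
    compares the significance mask against the generator's ground-truth
    support: coverage of the support, and the false-positive rate outside a
    one-sample temporal dilation of it.
    """
    channels = sim.default_channel_set()
    a_maps, b_maps = [], []
    gt = None
    for child in _children(seed, n_subjects):
        subj_seed = int(np.random.default_rng(child).integers(0, 2**31))
        subjects, gt_s = sim.make_dataset(
            1, seed=subj_seed, channels=channels, sfreq=sfreq
        )
        ep = select_window(subjects[0], *cue_window)
        if gt is None:
            gt = gt_s
            keep = (gt_s.timeaxis.times >= cue_window[0]) & (
                gt_s.timeaxis.times <= cue_window[1]
            )
        b_stack, a_stack = glm.condition_beta_stacks([ep], by="cue", levels=("B", "A"))
        a_maps.append(a_stack[0])
        b_maps.append(b_stack[0])
    a_arr, b_arr = np.stack(a_maps), np.stack(b_maps)
    res = glm.group_contrast(
        b_arr, a_arr, alpha=alpha, B=B, seed=np.random.default_rng(seed),
        contrast="B-A",
    )
    support = gt.masks["cue_B_minus_A"][:, keep]
    dilated = binary_dilation(support, structure=np.ones((1, 3), dtype=bool))
    mask = res.mask
    coverage = float(mask[support].mean()) if support.any() else float("nan")
    outside = ~dilated
    fp_rate = float(mask[outside].mean()) if outside.any() else 0.0
    peak = np.unravel_index(np.argmax(np.abs(res.t_map)), res.t_map.shape)
    diffs = b_arr - a_arr
    peak_d = float(
        diffs[:, peak[0], peak[1]].mean() / diffs[:, peak[0], peak[1]].std(ddof=1)
    )
    return {
        "coverage": coverage,
        "false_positive_rate": fp_rate,
        "n_significant": int(mask.sum()),
        "intersection_nonempty": bool((mask & support).any()),
        "peak_effect_size_d": peak_d,
        "f_crit": res.f_crit,
        "n_subjects": n_subjects,
    }


# --------------------------------------------------------------------------
# decoding

def null_decoding_auc(
    n_trials: int = 200,
    n_channels: int = 16,
    n_times: int = 24,
    seed: int = 0,
) -> dict:
    """Mean GAT AUC for random labels on pure-noise epochs (chance check)."""
    channels = sim.grid_channel_set(n_channels)
    sfreq = 64.0
    timeaxis = TimeAxis.from_span(-0.1, (n_times - 1) / sfreq - 0.1, sfreq)
    rng = np.random.default_rng(seed)
    noise_seed = int(rng.integers(0, 2**31))
    data = sim.simulate_noise(n_trials, channels, timeaxis, sim.NoiseSpec(), noise_seed)
    labels = rng.permutation(np.arange(n_trials) % 2)
    trials = sim.make_trial_sequence(
        sim.BlockSpec(n_AX=n_trials, n_AY=0, n_BX=0, n_BY=0, n_blocks=1), rng
    )
    ep = SubjectEpochs("null", data, channels, timeaxis, trials)
    auc = dec.fit_and_score_gat(ep, labels, dec.DecoderSpec(seed=int(rng.integers(0, 2**31))))
    return {"mean_auc": float(auc.mean()), "n_trials": n_trials}


def gat_dissociation(
    n_subjects: int = 12,
    seed: int = 0,
    sfreq: float = 64.0,
    decode_window: tuple[float, float] = (-0.1, 1.05),
    threshold: float = 0.55,
) -> dict:
    """Transient-vs-sustained generalisation on the default cue components.

    Decodes cue identity (A vs B) per subject over the early cue interval and
    summarises the group-mean GAT matrix: classifiers trained inside the
    transient window (0.18-0.25 s) should exceed the AUC threshold only
    within +-0.1 s of that window, while classifiers trained inside the
    sustained window (0.40-0.75 s) should stay above it across >= 0.2 s of
    off-diagonal test time.
    """
    channels = sim.default_channel_set()
    mats = []
    for i, child in enumerate(_children(seed, n_subjects)):
        subj_seed = int(np.random.default_rng(child).integers(0, 2**31))
        subjects, _ = sim.make_dataset(1, seed=subj_seed, channels=channels, sfreq=sfreq)
        ep = select_window(subjects[0], *decode_window)
        labels = (ep.trials["cue"] == "B").to_numpy(dtype=int)
        spec = dec.DecoderSpec(seed=(seed + 104729 * i) % (2**31))
        mats.append(dec.fit_and_score_gat(ep, labels, spec))
        times = ep.timeaxis.times
    gat = np.mean(mats, axis=0)

    transient, sustained = (0.18, 0.25), (0.40, 0.75)
    # the transient component peaks mid-window (half-cosine kernel), so the
    # representative transient classifier is the in-window row with the best
    # diagonal score, not the average over rows with near-zero expression
    tr_rows = np.flatnonzero((times >= transient[0]) & (times <= transient[1]))
    diag = np.diag(gat)
    tr_best = tr_rows[np.argmax(diag[tr_rows])]
    tr_curve = gat[tr_best]
    above = tr_curve > threshold
    in_margin = (times >= transient[0] - 0.1) & (times <= transient[1] + 0.1)
    tr_outside_s = float(np.sum(above & ~in_margin) / sfreq)
    tr_peak = float(tr_curve[tr_rows].max())

    su_rows = np.flatnonzero((times >= sustained[0]) & (times <= sustained[1]))
    spans = []
    for r in su_rows:
        off = np.abs(times - times[r]) > 1.5 / sfreq  # exclude diagonal vicinity
        spans.append(np.sum((gat[r] > threshold) & off) / sfreq)
    su_offdiag_s = float(np.max(spans))
    su_peak = float(gat[np.ix_(su_rows, su_rows)].max())
    return {
        "transient_above_outside_margin_s": tr_outside_s,
        "transient_peak_auc": tr_peak,
        "sustained_offdiagonal_generalisation_s": su_offdiag_s,
        "sustained_peak_auc": su_peak,
        "n_subjects": n_subjects,
    }


# --------------------------------------------------------------------------
# behavioural generator fidelity

def behaviour_fidelity(
    n_subjects_rt: int = 20, n_subjects_err: int = 100, seed: int = 0
) -> dict:
    """Grand-mean correct-AX RT and empirical AY error rate of the generator.

    Targets: 0.351 s (correct AX RT) and 0.17 (AY error rate), the marginal
    means the behavioural model defaults emulate. Uses 20 subjects x 180 AX
    trials for the RT check and 100 subjects x 26 AY trials for the error
    check.
    """
    block = sim.BlockSpec()
    spec = sim.BehaviourSpec()
    n_total = max(n_subjects_rt, n_subjects_err)
    rts, ay_err, ay_n = [], 0, 0
    for i, child in enumerate(_children(seed, n_total)):
        rng = np.random.default_rng(child)
        trials = sim.simulate_behaviour(sim.make_trial_sequence(block, rng), spec, rng)
        if i < n_subjects_rt:
            ax_correct = trials[(trials["pair"] == "AX") & (trials["correct"] == True)]
            rts.append(ax_correct["rt"].to_numpy())
        if i < n_subjects_err:
            ay = trials[trials["pair"] == "AY"]
            ay_err += int((~ay["correct"].astype(bool)).sum())
            ay_n += len(ay)
    rt_all = np.concatenate(rts)
    return {
        "mean_correct_ax_rt_s": float(rt_all.mean()),
        "n_ax_trials": int(rt_all.size),
        "ay_error_rate": ay_err / ay_n,
        "n_ay_trials": ay_n,
    }


# --------------------------------------------------------------------------
# worked identities

def sdt_worked_examples() -> dict:
    """The closed-form signal-detection identities on fixed rates."""
    from scipy import stats as st

    def make_rates(r_ax_correct, r_bx_inc, r_ay_inc, n=1000):
        import pandas as pd

        rows = []
        for pair, rc in (("AX", r_ax_correct), ("BX", 1 - r_bx_inc),
                         ("AY", 1 - r_ay_inc), ("BY", 0.97)):
            nc = int(round(rc * n))
            rows.append(dict(pair=pair, n_trials=n, n_correct=nc,
                             n_incorrect=n - nc, rate_correct=nc / n,
                             rate_incorrect=(n - nc) / n, defined=True))
        return beh.ConditionRates(pd.DataFrame(rows).set_index("pair"))

    sym = make_rates(0.5, 0.5, 0.5)
    ex = make_rates(0.98, 0.04, 0.17)
    return {
        "dprime_symmetric": beh.dprime_context(sym),
        "a_bias_symmetric": beh.a_cue_bias(sym),
        "dprime_098_004": beh.dprime_context(ex),
        "a_bias_098_017": beh.a_cue_bias(ex),
    }
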