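"""Synthetic DPX (AX-CPT) datasets with known ground truth.

The generator emulates the cue-probe task structure (70% AX pairs in blocks
of 129, cue at 0 s, probe at 2.5 s), evoked condition effects (transient
occipital-parietal, sustained parietal, and late fronto-central components),
spatially correlated 1/f background noise, and behavioural outcomes
(lognormal RTs, per-pair error probabilities). Every random draw flows from
a single seed, so identical seeds give bitwise-identical datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import (
    PAIRS,
    TRIAL_COLUMNS,
    ChannelSet,
    ConsistencyError,
    SubjectEpochs,
    TimeAxis,
    WindowError,
    select_window,
)

# --------------------------------------------------------------------------
# channel montages

# 32-channel 10-20 subset; positions are a schematic azimuthal projection
# (x: left->right, y: back->front) on the unit disc.
_MONTAGE_32 = [
    ("Fp1", -0.31, 0.95), ("Fp2", 0.31, 0.95),
    ("F7", -0.81, 0.59), ("F3", -0.43, 0.55), ("Fz", 0.0, 0.50),
    ("F4", 0.43, 0.55), ("F8", 0.81, 0.59),
    ("FC5", -0.67, 0.29), ("FC1", -0.22, 0.27), ("FCz", 0.0, 0.25),
    ("FC2", 0.22, 0.27), ("FC6", 0.67, 0.29),
    ("T7", -1.0, 0.0), ("C3", -0.50, 0.0), ("Cz", 0.0, 0.0),
    ("C4", 0.50, 0.0), ("T8", 1.0, 0.0),
    ("CP5", -0.67, -0.29), ("CP1", -0.22, -0.27), ("CP2", 0.22, -0.27),
    ("CP6", 0.67, -0.29),
    ("P7", -0.81, -0.59), ("P3", -0.43, -0.55), ("Pz", 0.0, -0.50),
    ("P4", 0.43, -0.55), ("P8", 0.81, -0.59),
    ("PO3", -0.35, -0.73), ("POz", 0.0, -0.75), ("PO4", 0.35, -0.73),
    ("O1", -0.31, -0.95), ("Oz", 0.0, -0.98), ("O2", 0.31, -0.95),
]


def default_channel_set() -> ChannelSet:
    """The built-in 32-channel 10-20 style montage."""
    labels = tuple(n for n, _, _ in _MONTAGE_32)
    pos = np.array([(x, y) for _, x, y in _MONTAGE_32])
    return ChannelSet(labels, pos)


def grid_channel_set(n: int) -> ChannelSet:
    """A generic n-channel set on a golden-angle spiral over the unit disc.

    Useful for size-controlled simulations that do not need named 10-20
    locations (e.g. null calibration runs).
    """
    k = np.arange(n)
    r = np.sqrt((k + 0.5) / n)
    theta = k * math.pi * (3.0 - math.sqrt(5.0))
    pos = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    labels = tuple(f"C{i + 1:02d}" for i in range(n))
    return ChannelSet(labels, pos)


def gaussian_topography(channels: ChannelSet, centers, sigma: float = 0.35) -> np.ndarray:
    """Scalp weight map peaking at the given channels, max |weight| = 1."""
    pos = channels.positions
    cpos = np.array([pos[channels.index(c)] for c in centers])
    d2 = ((pos[:, None, :] - cpos[None, :, :]) ** 2).sum(-1)
    w = np.exp(-d2 / (2.0 * sigma ** 2)).sum(axis=1)
    return w / np.abs(w).max()


# --------------------------------------------------------------------------
# specs

@dataclass(frozen=True)
class BlockSpec:
    """Per-block trial counts and timing of the cue-probe stream."""

    n_AX: int = 90
    n_AY: int = 13
    n_BX: int = 13
    n_BY: int = 13
    n_blocks: int = 2
    soa: float = 2.5                      # cue -> probe onset asynchrony, s
    iti_range: tuple[float, float] = (2.5, 3.5)

    def __post_init__(self):
        counts = (self.n_AX, self.n_AY, self.n_BX, self.n_BY)
        if any(c < 0 for c in counts):
            raise ValueError("trial counts must be >= 0")
        if self.soa <= 0:
            raise ValueError("soa must be > 0")
        if self.iti_range[0] > self.iti_range[1]:
            raise ValueError("iti_range must be ordered")

    @property
    def counts(self) -> dict[str, int]:
        return {"AX": self.n_AX, "AY": self.n_AY, "BX": self.n_BX, "BY": self.n_BY}

    @property
    def n_per_block(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class EffectComponent:
    """One evoked component: a scalp topography times a temporal kernel.

    ``amplitude_by_pair`` gives the signed peak amplitude (microvolts) this
    component contributes on each trial type; the topography is normalised
    to max |weight| = 1 and the kernel peaks at 1, so the contributed signal
    at the peak channel-time equals the stated amplitude.
    """

    name: str
    topography: np.ndarray
    window: tuple[float, float]
    kernel: str                      # 'bump' (half-cosine) or 'plateau'
    amplitude_by_pair: dict
    jitter_sd: float = 0.0

    def __post_init__(self):
        topo = np.asarray(self.topography, dtype=float)
        if topo.ndim != 1 or not np.any(topo):
            raise ValueError("topography must be 1-D with >= 1 nonzero weight")
        if not np.all(np.isfinite(topo)):
            raise ValueError("topography must be finite")
        object.__setattr__(self, "topography", topo / np.abs(topo).max())
        if self.window[0] >= self.window[1]:
            raise ValueError("window must be ordered (on < off)")
        if self.kernel not in ("bump", "plateau"):
            raise ValueError("kernel must be 'bump' or 'plateau'")
        amps = {p: float(self.amplitude_by_pair.get(p, 0.0)) for p in PAIRS}
        if not all(np.isfinite(v) for v in amps.values()):
            raise ValueError("amplitudes must be finite")
        object.__setattr__(self, "amplitude_by_pair", amps)

    def kernel_values(self, times: np.ndarray, onset_shift: float = 0.0) -> np.ndarray:
        """Temporal kernel evaluated on ``times`` (peak value 1)."""
        on, off = self.window
        u = (times - onset_shift - on) / (off - on)
        inside = (u >= 0.0) & (u <= 1.0)
        k = np.zeros_like(times)
        if self.kernel == "bump":
            k[inside] = 0.5 * (1.0 - np.cos(2.0 * np.pi * u[inside]))
        else:  # plateau with cosine ramps over 15% of the window at each end
            r = 0.15
            ui = u[inside]
            v = np.ones_like(ui)
            rise = ui < r
            fall = ui > 1.0 - r
            v[rise] = 0.5 * (1.0 - np.cos(np.pi * ui[rise] / r))
            v[fall] = 0.5 * (1.0 - np.cos(np.pi * (1.0 - ui[fall]) / r))
            k[inside] = v
        return k


@dataclass(frozen=True)
class NoiseSpec:
    """Background noise model: spatially correlated 1/f plus sensor white noise.

    ``background_sd`` is the marginal standard deviation (microvolts) of the
    coloured background at every channel and sample; ``spatial_corr_length``
    is the e-folding distance of the exponential inter-channel correlation in
    montage units (unit-disc scale). ``lowpass`` applies a cosine roll-off
    above the given frequency, emulating the band-limited (0.1-30 Hz
    filtered), average-referenced signal that epoched EEG statistics are
    computed on; defaults reproduce that smooth, spatially coherent regime.
    """

    background_sd: float = 5.0
    spectral_exponent: float = 1.5
    spatial_corr_length: float = 1.0
    sensor_white_sd: float = 1.5
    lowpass: float | None = 30.0

    def __post_init__(self):
        if self.background_sd < 0 or self.sensor_white_sd < 0:
            raise ValueError("noise sds must be >= 0")
        if self.spectral_exponent < 0:
            raise ValueError("spectral_exponent must be >= 0")
        if self.lowpass is not None and self.lowpass <= 0:
            raise ValueError("lowpass must be positive")


#: target marginal mean RTs (seconds) per pair and correctness
_RT_CORRECT = {"AX": 0.351, "AY": 0.491, "BX": 0.273, "BY": 0.278}
_RT_INCORRECT = {"AX": 0.534, "AY": 0.385, "BX": 0.592, "BY": 0.608}
_ERR = {"AX": 0.02, "AY": 0.17, "BX": 0.04, "BY": 0.03}


@dataclass(frozen=True)
class BehaviourSpec:
    """Behavioural model: lognormal RTs and per-pair error probabilities.

    ``rt_mean_*`` are the target marginal mean RTs per pair and correctness
    (defaults: correct AX 351 ms, AY 491 ms, BX 273 ms, BY 278 ms; errors
    AX 2%, AY 17%, BX 4%, BY 3%). The lognormal location is calibrated so
    the distribution mean — not the median — matches the target, since the
    emulated quantities are reported marginal means. Subject heterogeneity
    enters as an additive offset on the subject's mean RT (seconds) and on
    the log-odds of an error (logit units).
    """

    rt_mean_correct: dict = field(default_factory=lambda: dict(_RT_CORRECT))
    rt_mean_incorrect: dict = field(default_factory=lambda: dict(_RT_INCORRECT))
    rt_sigma: float = 0.2
    error_prob_by_pair: dict = field(default_factory=lambda: dict(_ERR))
    subject_sd_rt: float = 0.025
    subject_sd_error: float = 0.35

    def __post_init__(self):
        for p in PAIRS:
            if not 0.0 <= self.error_prob_by_pair[p] <= 1.0:
                raise ValueError("error probabilities must be in [0, 1]")
        if self.rt_sigma < 0 or self.subject_sd_rt < 0 or self.subject_sd_error < 0:
            raise ValueError("sds must be >= 0")


#: Condition groupings for the two standard contrasts (first minus second).
CONTRASTS = {
    "cue_B_minus_A": (("BX", "BY"), ("AX", "AY")),
    "probe_AY_minus_AX": (("AY",), ("AX",)),
}


@dataclass
class GroundTruth:
    """Where the generator injected condition differences.

    ``masks[contrast]`` is True at (channel, time) points where the injected
    between-condition signal difference exceeds half of its maximum for at
    least one component; ``component_masks`` holds the per-component support.
    ``subject_scales`` are the per-subject multiplicative amplitude effects.
    """

    channels: ChannelSet
    timeaxis: TimeAxis
    masks: dict
    component_masks: dict
    subject_scales: np.ndarray | None = None


# --------------------------------------------------------------------------
# default component sets

_CUE_AMP = 1.25   # half the B-minus-A peak difference, microvolts
_PROBE_AMP = 1.5  # half the AY-minus-AX peak difference, microvolts


def default_cue_components(channels: ChannelSet) -> list[EffectComponent]:
    """Cue-locked B-vs-A components: transient occipital-parietal negativity,
    sustained parietal positivity, late fronto-central negativity."""
    a, b = _CUE_AMP, -_CUE_AMP
    return [
        EffectComponent(
            "cue_occipital_parietal_negativity",
            gaussian_topography(channels, ["PO3", "PO4"], 0.30),
            (0.18, 0.25), "bump",
            {"AX": a, "AY": a, "BX": b, "BY": b},
        ),
        EffectComponent(
            "cue_parietal_positivity",
            gaussian_topography(channels, ["Pz"], 0.35),
            (0.40, 0.75), "plateau",
            {"AX": b, "AY": b, "BX": a, "BY": a},
        ),
        EffectComponent(
            "cue_frontocentral_negativity",
            gaussian_topography(channels, ["FCz", "FC1"], 0.30),
            (1.10, 1.45), "plateau",
            {"AX": a, "AY": a, "BX": b, "BY": b},
        ),
    ]


def default_probe_components(channels: ChannelSet, soa: float = 2.5) -> list[EffectComponent]:
    """Probe-locked AY-vs-AX components on the cue-locked time axis."""
    a, y = _PROBE_AMP, -_PROBE_AMP
    return [
        EffectComponent(
            "probe_occipital_parietal_negativity",
            gaussian_topography(channels, ["PO3", "PO4"], 0.30),
            (soa + 0.18, soa + 0.25), "bump",
            {"AX": a, "AY": y, "BX": 0.0, "BY": 0.0},
        ),
        EffectComponent(
            "probe_frontocentral_positivity",
            gaussian_topography(channels, ["FCz"], 0.30),
            (soa + 0.30, soa + 0.40), "bump",
            {"AX": y, "AY": a, "BX": 0.0, "BY": 0.0},
        ),
        EffectComponent(
            "probe_parietal_positivity",
            gaussian_topography(channels, ["Pz", "CP2"], 0.35),
            (soa + 0.45, soa + 0.75), "plateau",
            {"AX": y, "AY": a, "BX": 0.0, "BY": 0.0},
        ),
    ]


def default_components(channels: ChannelSet, soa: float = 2.5) -> list[EffectComponent]:
    return default_cue_components(channels) + default_probe_components(channels, soa)


# --------------------------------------------------------------------------
# generators

def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def make_trial_sequence(spec: BlockSpec, seed) -> pd.DataFrame:
    """Seeded trial sequence: exact per-block counts, uniform within-block order."""
    if spec.n_per_block == 0:
        raise ValueError("empty design: all per-block trial counts are zero")
    rng = _as_rng(seed)
    rows = []
    tid = 0
    for b in range(spec.n_blocks):
        pairs = np.repeat(list(spec.counts.keys()), list(spec.counts.values()))
        pairs = rng.permutation(pairs)
        for p in pairs:
            rows.append((tid, b, p[0], p[1], p, None, None, np.nan))
            tid += 1
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS).astype({"rt": float})


def simulate_noise(
    n_trials: int,
    channels: ChannelSet,
    timeaxis: TimeAxis,
    noise: NoiseSpec,
    seed,
) -> np.ndarray:
    """Zero-mean noise epochs: spatially correlated 1/f^a background + white.

    The coloured background is shaped in the frequency domain (power
    proportional to 1/f^a, DC removed) and scaled analytically so its
    marginal standard deviation equals ``background_sd`` exactly in
    expectation; spatial structure is an exponential correlation
    exp(-d / spatial_corr_length) across channels.
    """
    rng = _as_rng(seed)
    n_ch, n_t = len(channels), len(timeaxis)
    out = np.zeros((n_trials, n_ch, n_t))
    if n_trials == 0:
        return out
    if noise.background_sd > 0:
        white = rng.standard_normal((n_trials, n_ch, n_t))
        if noise.spatial_corr_length > 0 and n_ch > 1:
            K = np.exp(-channels.distances() / noise.spatial_corr_length)
            L = np.linalg.cholesky(K + 1e-10 * np.eye(n_ch))
            white = np.einsum("ij,njt->nit", L, white)
        freqs = np.fft.fftfreq(n_t, d=1.0 / timeaxis.sfreq)
        gain = np.zeros(n_t)
        nz = freqs != 0
        gain[nz] = np.abs(freqs[nz]) ** (-noise.spectral_exponent / 2.0)
        if noise.lowpass is not None:
            af = np.abs(freqs)
            edge = 1.25 * noise.lowpass  # cosine roll-off to zero at 1.25 x lowpass
            roll = (af > noise.lowpass) & (af < edge)
            gain[roll] *= 0.5 * (
                1.0 + np.cos(np.pi * (af[roll] - noise.lowpass)
                             / (edge - noise.lowpass))
            )
            gain[af >= edge] = 0.0
        # variance of filtered unit white noise is mean(gain^2)
        scale = noise.background_sd / np.sqrt(np.mean(gain ** 2))
        spec = np.fft.fft(white, axis=-1) * gain
        out += np.fft.ifft(spec, axis=-1).real * scale
    if noise.sensor_white_sd > 0:
        out += rng.standard_normal((n_trials, n_ch, n_t)) * noise.sensor_white_sd
    return out


def _component_support(comp: EffectComponent, channels: ChannelSet,
                       timeaxis: TimeAxis) -> np.ndarray:
    """(channel, time) points where |topography x kernel| >= half its max."""
    k = comp.kernel_values(timeaxis.times)
    s = np.abs(np.outer(comp.topography, k))
    return s >= 0.5 * s.max()


def simulate_evoked(
    trials: pd.DataFrame,
    components: list[EffectComponent],
    channels: ChannelSet,
    timeaxis: TimeAxis,
    seed,
) -> tuple[np.ndarray, GroundTruth]:
    """Deterministic evoked signal per trial plus ground-truth support masks.

    Each trial's signal is the sum over components of
    ``amplitude_by_pair[pair] * topography (x) kernel`` with an optional
    per-trial Gaussian onset jitter. Ground-truth masks mark, per contrast,
    the (channel, time) points where some component's injected difference
    exceeds half of its own maximum.
    """
    rng = _as_rng(seed)
    n_ch, n_t = len(channels), len(timeaxis)
    times = timeaxis.times
    data = np.zeros((len(trials), n_ch, n_t))
    pair_arr = trials["pair"].to_numpy()
    for comp in components:
        if not (times[0] <= comp.window[0] and comp.window[1] <= times[-1]):
            raise WindowError(
                f"component '{comp.name}' window {comp.window} outside the axis"
            )
        amps = np.array([comp.amplitude_by_pair[p] for p in pair_arr])
        if comp.jitter_sd > 0:
            shifts = rng.normal(0.0, comp.jitter_sd, size=len(trials))
            for i in range(len(trials)):
                if amps[i] != 0.0:
                    data[i] += amps[i] * np.outer(
                        comp.topography, comp.kernel_values(times, shifts[i])
                    )
        else:
            base = np.outer(comp.topography, comp.kernel_values(times))
            nz = amps != 0.0
            data[nz] += amps[nz, None, None] * base[None]

    component_masks = {
        c.name: _component_support(c, channels, timeaxis) for c in components
    }
    masks = {}
    for cname, (grp1, grp2) in CONTRASTS.items():
        m = np.zeros((n_ch, n_t), dtype=bool)
        for comp in components:
            a1 = np.mean([comp.amplitude_by_pair[p] for p in grp1])
            a2 = np.mean([comp.amplitude_by_pair[p] for p in grp2])
            if a1 != a2:
                m |= component_masks[comp.name]
        masks[cname] = m
    gt = GroundTruth(channels=channels, timeaxis=timeaxis, masks=masks,
                     component_masks=component_masks)
    return data, gt


def simulate_behaviour(trials: pd.DataFrame, spec: BehaviourSpec, seed) -> pd.DataFrame:
    """Fill response/correct/rt columns for one subject's trial sequence.

    Correctness is Bernoulli with a per-subject logit offset; RTs are
    lognormal with the location set so the distribution mean equals the
    pair-by-correctness target plus a per-subject additive offset.
    """
    rng = _as_rng(seed)
    out = trials.copy()
    err_off = rng.normal(0.0, spec.subject_sd_error)
    rt_off = rng.normal(0.0, spec.subject_sd_rt)
    pair_arr = out["pair"].to_numpy()
    p_err = np.array([spec.error_prob_by_pair[p] for p in pair_arr])
    # subject offset on the logit scale; p=0 and p=1 stay degenerate
    interior = (p_err > 0) & (p_err < 1)
    logit = np.log(p_err[interior] / (1.0 - p_err[interior])) + err_off
    p_err[interior] = 1.0 / (1.0 + np.exp(-logit))
    correct = rng.random(len(out)) >= p_err
    target_required = pair_arr == "AX"
    gave_target = np.where(correct, target_required, ~target_required)
    mean_c = np.array([spec.rt_mean_correct[p] for p in pair_arr])
    mean_i = np.array([spec.rt_mean_incorrect[p] for p in pair_arr])
    target_mean = np.maximum(np.where(correct, mean_c, mean_i) + rt_off, 1e-3)
    # lognormal median giving the target mean: mean = median * exp(sigma^2 / 2)
    median = target_mean / np.exp(spec.rt_sigma ** 2 / 2.0)
    rt = median * np.exp(rng.normal(0.0, spec.rt_sigma, size=len(out)))
    out["correct"] = pd.array(correct, dtype="boolean")
    out["response"] = np.where(gave_target, "target", "nontarget")
    out["rt"] = rt
    return out


def make_dataset(
    n_subjects: int,
    block: BlockSpec | None = None,
    components: list[EffectComponent] | None = None,
    noise: NoiseSpec | None = None,
    behaviour: BehaviourSpec | None = None,
    seed: int = 0,
    channels: ChannelSet | None = None,
    sfreq: float = 128.0,
    epoch_span: tuple[float, float] = (-0.5, 3.5),
    subject_amp_sd: float = 0.55,
) -> tuple[list[SubjectEpochs], GroundTruth]:
    """Generate a multi-subject cue-locked dataset with ground truth.

    Each subject gets an independent sub-seed; component amplitudes are
    scaled per subject by ``1 + N(0, subject_amp_sd)`` (a multiplicative
    random effect, floored at 0.1), and evoked signal plus noise are summed
    into epochs spanning ``epoch_span`` around cue onset.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    block = block or BlockSpec()
    noise = noise or NoiseSpec()
    behaviour = behaviour or BehaviourSpec()
    channels = channels or default_channel_set()
    if components is None:
        components = default_components(channels, block.soa)
    timeaxis = TimeAxis.from_span(epoch_span[0], epoch_span[1], sfreq)

    root = np.random.SeedSequence(seed)
    subjects = []
    scales = np.empty(n_subjects)
    gt = None
    for s, child in enumerate(root.spawn(n_subjects)):
        rng = np.random.default_rng(child)
        trials = make_trial_sequence(block, rng)
        trials = simulate_behaviour(trials, behaviour, rng)
        scale = max(1.0 + rng.normal(0.0, subject_amp_sd), 0.1)
        scales[s] = scale
        scaled = [
            EffectComponent(
                c.name, c.topography, c.window, c.kernel,
                {p: scale * a for p, a in c.amplitude_by_pair.items()},
                c.jitter_sd,
            )
            for c in components
        ]
        evoked, gt_s = simulate_evoked(trials, scaled, channels, timeaxis, rng)
        if gt is None:
            # support masks do not depend on the subject scale
            gt = gt_s
        data = evoked + simulate_noise(len(trials), channels, timeaxis, noise, rng)
        subjects.append(
            SubjectEpochs(
                subject_id=f"sub-{s + 1:02d}",
                data=data,
                channels=channels,
                timeaxis=timeaxis,
                trials=trials,
                lock_event="cue",
            )
        )
    if gt is None:  # no components at all
        gt = GroundTruth(channels, timeaxis, {}, {})
    gt.subject_scales = scales
    return subjects, gt


def relock_to_probe(epochs: SubjectEpochs, soa: float = 2.5,
                    tmin: float = -0.5, tmax: float = 1.0) -> SubjectEpochs:
    """Re-express cue-locked epochs relative to probe onset (at ``soa``)."""
    cut = select_window(epochs, soa + tmin, soa + tmax)
    new_axis = TimeAxis(cut.timeaxis.times - soa, cut.timeaxis.sfreq)
    return SubjectEpochs(
        subject_id=cut.subject_id,
        data=cut.data,
        channels=cut.channels,
        timeaxis=new_axis,
        trials=cut.trials,
        lock_event="probe",
    )
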