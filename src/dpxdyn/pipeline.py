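"""End-to-end orchestration: generate -> behaviour/SDT -> mass-univariate ->
moderation -> decoding -> report.

All randomness derives from the single master seed in the config. The master
seed fans out to one named sub-stream per stage via fixed spawn keys
(0 generator, 1 mass-univariate bootstrap, 2 moderation bootstrap, 3
decoding CV), so a stage can be re-run in isolation and reproduce the full
run's numbers.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import behaviour as beh
from . import decoding as dec
from . import glm
from . import simulate as sim
from .config import AnalysisConfig, dump_config
from .data import SubjectEpochs, TimeAxis, select_window
from .io import save_epochs, save_trials_csv

logger = logging.getLogger(__name__)

_STAGE_KEYS = {"simulate": 0, "massuni": 1, "moderation": 2, "decode": 3}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class RunReport:
    seed: int
    config: dict
    stages: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)

    def to_markdown(self) -> str:
        lines = ["# dpxdyn run report", "", f"- master seed: {self.seed}", ""]
        for stage, summary in self.stages.items():
            lines.append(f"## {stage}")
            for k, v in summary.items():
                lines.append(f"- {k}: {v}")
            if stage in self.artifacts:
                for p in self.artifacts[stage]:
                    lines.append(f"- artifact: {p}")
            lines.append("")
        return "\n".join(lines)


def _stage_seed(master: int, stage: str) -> np.random.Generator:
    ss = np.random.SeedSequence(master, spawn_key=(_STAGE_KEYS[stage],))
    return np.random.default_rng(ss)


def _specs_from_config(cfg: AnalysisConfig, channels):
    block = sim.BlockSpec(
        n_AX=cfg.block.n_AX, n_AY=cfg.block.n_AY, n_BX=cfg.block.n_BX,
        n_BY=cfg.block.n_BY, n_blocks=cfg.block.n_blocks, soa=cfg.block.soa,
        iti_range=tuple(cfg.block.iti_range),
    )
    noise = sim.NoiseSpec(**cfg.noise.model_dump())
    behaviour = sim.BehaviourSpec(**cfg.behaviour.model_dump())
    if cfg.components is None:
        components = None
    else:
        components = [
            sim.EffectComponent(
                c.name,
                sim.gaussian_topography(channels, c.centers, c.sigma),
                tuple(c.window), c.kernel, c.amplitude_by_pair, c.jitter_sd,
            )
            for c in cfg.components
        ]
    return block, components, noise, behaviour


def save_group_result(result, path, channel_labels, times) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("t_map", data=result.t_map)
        f.create_dataset("f_map", data=getattr(result, "f_map", result.t_map ** 2))
        f.create_dataset("mask", data=result.mask)
        f.create_dataset("max_f_distribution", data=result.max_f_distribution)
        f.create_dataset("times", data=np.asarray(times))
        f.create_dataset(
            "channel_labels", data=np.asarray(channel_labels, dtype=object),
            dtype=h5py.string_dtype("utf-8"),
        )
        f.attrs["alpha"] = result.alpha
        f.attrs["B"] = result.B
        f.attrs["df"] = result.df
        f.attrs["f_crit"] = result.f_crit
        f.attrs["contrast"] = getattr(result, "contrast", "") or getattr(
            result, "covariate_name", ""
        )


def _decimate(ep: SubjectEpochs, decim: int) -> SubjectEpochs:
    if decim == 1:
        return ep
    times = ep.timeaxis.times[::decim]
    return SubjectEpochs(
        subject_id=ep.subject_id, data=ep.data[:, :, ::decim], channels=ep.channels,
        timeaxis=TimeAxis(times, ep.timeaxis.sfreq / decim), trials=ep.trials,
        lock_event=ep.lock_event,
    )


_STAGE_ORDER = ["simulate", "behaviour", "massuni", "moderation", "decode", "report"]


def run_pipeline(cfg: AnalysisConfig, until: str = "report") -> RunReport:
    """Run the stages in order (optionally stopping after ``until``);
    deterministic given the seed."""
    if until not in _STAGE_ORDER:
        raise ValueError(f"unknown stage {until!r}")
    stop_at = _STAGE_ORDER.index(until)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=cfg.seed, config=cfg.model_dump(mode="json"))
    dump_config(cfg, out / "effective_config.yaml")

    def _finalise():
        (out / "report.md").write_text(report.to_markdown())
        (out / "report.json").write_text(json.dumps(
            {"seed": report.seed, "stages": report.stages}, indent=2, default=str
        ))
        return report

    channels = sim.default_channel_set()
    stage = "simulate"
    t0 = time.perf_counter()
    try:
        block, components, noise, behaviour_spec = _specs_from_config(cfg, channels)
        gen_seed = int(
            np.random.SeedSequence(cfg.seed, spawn_key=(0,)).generate_state(1)[0]
            % (2**31)
        )
        subjects, gt = sim.make_dataset(
            cfg.n_subjects, block=block, components=components, noise=noise,
            behaviour=behaviour_spec, seed=gen_seed, channels=channels,
            sfreq=cfg.sfreq, subject_amp_sd=cfg.subject_amp_sd,
        )
        epo_dir = out / "epochs"
        epo_dir.mkdir(exist_ok=True)
        paths = []
        for ep in subjects:
            p = epo_dir / f"{ep.subject_id}_epo.h5"
            save_epochs(ep, p)
            paths.append(str(p))
        report.stages[stage] = {
            "n_subjects": len(subjects),
            "n_trials_per_subject": subjects[0].n_trials,
            "n_channels": len(channels),
            "sfreq": cfg.sfreq,
        }
        report.artifacts[stage] = paths
        logger.info("simulate: %d subjects in %.1fs", len(subjects),
                    time.perf_counter() - t0)
    except Exception as e:
        raise StageError(stage, e) from e
    if stop_at <= _STAGE_ORDER.index("simulate"):
        return _finalise()


    stage = "behaviour"
    t0 = time.perf_counter()
    try:
        lo, hi = cfg.rt_exclusion
        rows, excluded = [], 0
        for ep in subjects:
            ft = beh.filter_rt(ep.trials, lo, hi)
            excluded += len(ep.trials) - len(ft)
            rows.append(beh.sdt_scores(ft, ep.subject_id))
        sdt = pd.DataFrame(rows)
        sdt_path = out / "sdt_scores.csv"
        sdt.to_csv(sdt_path, index=False)
        save_trials_csv(
            pd.concat([ep.trials for ep in subjects], ignore_index=True),
            out / "trials.csv",
        )
        report.stages[stage] = {
            "rt_excluded_trials": excluded,
            "mean_dprime_context": round(float(sdt["dprime_context"].mean()), 4),
            "mean_a_cue_bias": round(float(sdt["a_cue_bias"].mean()), 4),
        }
        report.artifacts[stage] = [str(sdt_path), str(out / "trials.csv")]
        logger.info("behaviour: %.1fs", time.perf_counter() - t0)
    except Exception as e:
        raise StageError(stage, e) from e
    if stop_at <= _STAGE_ORDER.index("behaviour"):
        return _finalise()


    stage = "massuni"
    t0 = time.perf_counter()
    try:
        rng = _stage_seed(cfg.seed, "massuni")
        contrast_stacks = {}
        paths = []
        for spec_str in cfg.contrasts:
            kind, expr = [s.strip() for s in spec_str.split(":", 1)]
            hi_lab, lo_lab = [s.strip() for s in expr.split("vs")]
            if kind == "cue":
                eps = [select_window(ep, *cfg.cue_window) for ep in subjects]
                a, b = glm.condition_beta_stacks(
                    eps, by="cue", levels=(hi_lab, lo_lab)
                )
            elif kind == "probe":
                eps = [sim.relock_to_probe(ep, cfg.block.soa, *cfg.probe_window)
                       for ep in subjects]
                a, b = glm.condition_beta_stacks(
                    eps, by="pair", levels=(hi_lab, lo_lab),
                    trial_filter=lambda t: t["pair"].isin([hi_lab, lo_lab]),
                )
            else:
                raise ValueError(f"unknown contrast kind {kind!r}")
            res = glm.group_contrast(
                a, b, alpha=cfg.alpha, B=cfg.B, seed=rng,
                contrast=f"{hi_lab}-{lo_lab}",
            )
            contrast_stacks[spec_str] = (a - b, eps[0])
            name = f"massuni_{kind}_{hi_lab}_minus_{lo_lab}"
            h5p = out / f"{name}.h5"
            save_group_result(res, h5p, channels.labels, eps[0].timeaxis.times)
            clusters = glm.cluster_summary(res, channels.labels, eps[0].timeaxis.times)
            csvp = out / f"{name}_clusters.csv"
            clusters.to_csv(csvp, index=False)
            paths += [str(h5p), str(csvp)]
            report.stages.setdefault(stage, {})[spec_str] = {
                "f_crit": round(res.f_crit, 3),
                "n_significant": int(res.mask.sum()),
                "n_clusters": len(clusters),
            }
        report.artifacts[stage] = paths
        logger.info("massuni: %.1fs", time.perf_counter() - t0)
    except Exception as e:
        raise StageError(stage, e) from e
    if stop_at <= _STAGE_ORDER.index("massuni"):
        return _finalise()


    stage = "moderation"
    t0 = time.perf_counter()
    try:
        rng = _stage_seed(cfg.seed, "moderation")
        paths = []
        for spec_str, (diff_stack, ref_ep) in contrast_stacks.items():
            for score in ("dprime_context", "a_cue_bias"):
                mod = glm.covariate_moderation(
                    diff_stack, sdt[score].to_numpy(), alpha=cfg.alpha, B=cfg.B,
                    seed=rng, covariate_name=score,
                )
                name = f"moderation_{score}_{spec_str.split(':')[0].strip()}"
                p = out / f"{name}.h5"
                save_group_result(mod, p, channels.labels, ref_ep.timeaxis.times)
                paths.append(str(p))
                report.stages.setdefault(stage, {})[name] = {
                    "f_crit": round(mod.f_crit, 3),
                    "n_significant": int(mod.mask.sum()),
                }
        report.artifacts[stage] = paths
        logger.info("moderation: %.1fs", time.perf_counter() - t0)
    except Exception as e:
        raise StageError(stage, e) from e
    if stop_at <= _STAGE_ORDER.index("moderation"):
        return _finalise()


    stage = "decode"
    t0 = time.perf_counter()
    try:
        dec_seed = int(
            np.random.SeedSequence(cfg.seed, spawn_key=(3,)).generate_state(1)[0]
            % (2**31)
        )
        paths = []
        for contrast in cfg.decode_contrasts:
            eps = [
                _decimate(select_window(ep, *cfg.decode_window), cfg.decode_decim)
                for ep in subjects
            ]
            gat = dec.gat_for_subjects(
                eps, contrast,
                dec.DecoderSpec(n_folds=cfg.n_folds, seed=dec_seed),
            )
            gat.diag_mask = dec.group_significance(
                gat.diagonal, gat.chance, cfg.alpha
            )
            gat.matrix_mask = dec.group_significance(
                gat.per_subject_auc, gat.chance, cfg.alpha
            )
            name = f"gat_{contrast.replace(' ', '_')}"
            p = out / f"{name}.h5"
            with h5py.File(p, "w") as f:
                f.create_dataset("auc", data=gat.per_subject_auc)
                f.create_dataset("group_mean", data=gat.group_mean_auc)
                f.create_dataset("diag_mask", data=gat.diag_mask)
                f.create_dataset("matrix_mask", data=gat.matrix_mask)
                f.create_dataset("times", data=gat.timeaxis.times)
                f.attrs.update(
                    contrast=contrast, n_folds=cfg.n_folds, C=1.0,
                    seed=dec_seed, alpha=cfg.alpha,
                )
            paths.append(str(p))
            diag = gat.diagonal.mean(axis=0)
            report.stages.setdefault(stage, {})[contrast] = {
                "peak_diagonal_auc": round(float(diag.max()), 4),
                "peak_time_s": round(float(gat.timeaxis.times[int(diag.argmax())]), 3),
                "n_significant_diagonal": int(gat.diag_mask.sum()),
            }
        report.artifacts[stage] = paths
        logger.info("decode: %.1fs", time.perf_counter() - t0)
    except Exception as e:
        raise StageError(stage, e) from e
    if stop_at <= _STAGE_ORDER.index("decode"):
        return _finalise()


    return _finalise()
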