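"""Config-driven end-to-end experiment runner.

An :class:`ExperimentConfig` mirrors each stage's options (simulate →
preprocess → decode → evaluate → track); a single global seed
deterministically derives per-stage seeds via ``numpy.random.SeedSequence
(global_seed).spawn`` in stage order (simulate=0, preprocess=1, decode=2,
evaluate=3, track=4), so one seed fixes every stochastic output.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np

from . import io as mio
from .containers import select_balanced_oddball, vectorize
from .decode import MismatchDecoder, TrainConfig
from .evaluate import auc_map, binomial_ci, searchlight
from .preprocess import PreprocConfig, run_pipeline
from .simulate import ParadigmSpec, SimConfig, simulate_recording
from .track import Tracker

__all__ = ["ExperimentConfig", "run_experiment"]

log = logging.getLogger("mmndecode")

_STAGE_ORDER = ("simulate", "preprocess", "decode", "evaluate", "track")

_ALLOWED_KEYS = {
    "": {"seed", "out_dir", "simulate", "preprocess", "decode", "evaluate",
         "track"},
    "simulate": {"enabled", "paradigm", "n_trials", "deviant_proportion",
                 "isi_ms", "noise_rms_uv", "line_amplitude_uv",
                 "blink_rate_hz", "subject", "session", "block"},
    "preprocess": {"enabled", "config"},
    "decode": {"enabled", "c_grid", "folds", "balance", "c"},
    "evaluate": {"enabled", "searchlight_axis", "auc", "alpha"},
    "track": {"enabled", "group_size", "fusion"},
}


@dataclass
class ExperimentConfig:
    seed: int = 0
    out_dir: str = "results"
    simulate: dict = field(default_factory=lambda: {"enabled": True})
    preprocess: dict = field(default_factory=lambda: {"enabled": True})
    decode: dict = field(default_factory=lambda: {"enabled": True})
    evaluate: dict = field(default_factory=lambda: {"enabled": True})
    track: dict = field(default_factory=lambda: {"enabled": True})

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        unknown = set(d) - _ALLOWED_KEYS[""]
        if unknown:
            raise KeyError(f"unknown config key(s): {sorted(unknown)}")
        for section in _STAGE_ORDER:
            sec = d.get(section, {})
            bad = set(sec) - _ALLOWED_KEYS[section]
            if bad:
                raise KeyError(
                    f"unknown key(s) in section {section!r}: {sorted(bad)}"
                )
        return cls(**{k: d[k] for k in d})

    def stage_seed(self, stage: str) -> int:
        idx = _STAGE_ORDER.index(stage)
        ss = np.random.SeedSequence(self.seed).spawn(idx + 1)[idx]
        return int(ss.generate_state(1)[0] % (2**31))


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Execute the enabled stages; write reports; return the bundle.

    Any stage error propagates after a ``FAILED`` marker file is written,
    preserving partial outputs.
    """
    os.makedirs(cfg.out_dir, exist_ok=True)
    bundle: dict = {"seed": cfg.seed}
    try:
        return _run(cfg, bundle)
    except Exception as exc:
        with open(os.path.join(cfg.out_dir, "FAILED"), "w") as fh:
            fh.write(f"{type(exc).__name__}: {exc}\n")
        raise


def _run(cfg: ExperimentConfig, bundle: dict) -> dict:
    out = cfg.out_dir
    rec = None
    if cfg.simulate.get("enabled", True):
        seed = cfg.stage_seed("simulate")
        log.info("simulate: seed=%d", seed)
        sim_cfg = SimConfig(
            seed=seed,
            noise_rms_uv=cfg.simulate.get("noise_rms_uv", 10.0),
            line_amplitude_uv=cfg.simulate.get("line_amplitude_uv", 2.0),
            blink_rate_hz=cfg.simulate.get("blink_rate_hz", 0.1),
        )
        spec = ParadigmSpec(
            kind=cfg.simulate.get("paradigm", "oddball"),
            n_trials=cfg.simulate.get("n_trials", 1000),
            deviant_proportion=cfg.simulate.get("deviant_proportion", 0.15),
            isi_ms=cfg.simulate.get("isi_ms", 500.0),
        )
        rec = simulate_recording(
            sim_cfg, spec,
            subject=cfg.simulate.get("subject", 0),
            session=cfg.simulate.get("session", 0),
            block=cfg.simulate.get("block", 0),
        )
        mio.write_recording(os.path.join(out, "recording.h5"), rec)
        with open(os.path.join(out, "ground_truth.json"), "w") as fh:
            json.dump(rec.meta.get("ground_truth", {}), fh, indent=2,
                      sort_keys=True)
        bundle["recording"] = rec

    epochs = None
    if cfg.preprocess.get("enabled", True):
        if rec is None:
            raise ValueError("preprocess stage needs a simulated recording")
        pp_cfg = PreprocConfig.from_flat(cfg.preprocess.get("config", {}))
        pp_cfg = PreprocConfig(**{
            **pp_cfg.__dict__, "ica_seed": cfg.stage_seed("preprocess")
        })
        epochs, report = run_pipeline(rec, pp_cfg)
        mio.write_epochs(os.path.join(out, "epochs.h5"), epochs)
        with open(os.path.join(out, "preprocess_report.json"), "w") as fh:
            fh.write(report.to_json(indent=2))
        bundle["epochs"] = epochs
        bundle["preprocess_report"] = report

    results = None
    if cfg.decode.get("enabled", True):
        if epochs is None:
            raise ValueError("decode stage needs preprocessed epochs")
        if cfg.decode.get("balance", True) and cfg.simulate.get(
            "paradigm", "oddball"
        ) == "oddball":
            epochs = select_balanced_oddball(epochs)
        fm = vectorize(epochs)
        tc = TrainConfig(
            c_grid=tuple(cfg.decode.get("c_grid", (0.001, 0.01, 0.1, 0, 1, 10, 1000))),
            folds=cfg.decode.get("folds", 10),
            seed=cfg.stage_seed("decode"),
        )
        model = MismatchDecoder(fm)
        results = model.fit_grid(tc)
        results.save(os.path.join(out, "model.json"))
        cv = model.cross_validate(tc, c=results.c)
        with open(os.path.join(out, "crossval.tsv"), "w") as fh:
            fh.write("fold\trate\n")
            for i, r in enumerate(cv.fold_rates):
                fh.write(f"{i}\t{r:.6f}\n")
            fh.write(f"mean\t{cv.mean_rate:.6f}\n")
        bundle["results"] = results
        bundle["cv"] = cv
        bundle["balanced_epochs"] = epochs

    if cfg.evaluate.get("enabled", True) and results is not None:
        alpha = cfg.evaluate.get("alpha", 0.05)
        k = bundle["balanced_epochs"].n_epochs
        summary = {
            "cv_rate": bundle["cv"].mean_rate,
            "chance_ci_half_width": binomial_ci(k, alpha=alpha),
            "n_trials": k,
            "significant": bundle["cv"].mean_rate
            > 0.5 + binomial_ci(k, alpha=alpha),
        }
        if cfg.evaluate.get("auc", True):
            amap = auc_map(bundle["balanced_epochs"])
            np.savetxt(
                os.path.join(out, "auc_map.tsv"), amap.auc, delimiter="\t",
                fmt="%.6f",
            )
            summary["max_mask_value"] = float(amap.mask_values.max())
        axis = cfg.evaluate.get("searchlight_axis")
        if axis:
            sl = searchlight(
                bundle["balanced_epochs"], axis,
                TrainConfig(folds=cfg.decode.get("folds", 10),
                            seed=cfg.stage_seed("evaluate")),
                c=results.c,
            )
            with open(os.path.join(out, f"searchlight_{axis}.tsv"), "w") as fh:
                fh.write("unit\trate\n")
                for u, r in zip(sl.units, sl.rates):
                    fh.write(f"{u}\t{r:.6f}\n")
            summary["searchlight_best"] = str(sl.units[sl.ranking[0]])
        with open(os.path.join(out, "evaluation.json"), "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        bundle["evaluation"] = summary

    if cfg.track.get("enabled", True) and results is not None:
        tracker = Tracker(
            model=results,
            group_size=cfg.track.get("group_size", 10),
            fusion=cfg.track.get("fusion", "sum"),
        )
        tracker.run(bundle["balanced_epochs"])
        with open(os.path.join(out, "tracking.tsv"), "w") as fh:
            fh.write("trial_index\tfused_f\tposterior\tprediction\n")
            for idx, f, p, pred in tracker.emissions:
                fh.write(f"{idx}\t{f:.6f}\t{p:.6f}\t{pred}\n")
        bundle["tracker"] = tracker
    return bundle
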