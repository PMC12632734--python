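"""Reproducible multi-stage pipeline over a session bundle.

``run_pipeline`` executes the selected analysis stages in dependency order on
a (typically simulated) session, writing every figure-analog output in a
machine-readable form plus a human-readable JSON summary.  Each random stage
consumes a named substream of the global seed, so toggling one stage never
changes another stage's draws.  A failed stage is recorded, its dependents
are skipped, and the run reports failure.
"""

from __future__ import annotations

import json
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import core, decoding, isi, mixture, pev, simulate, states
from .io import read_session, substream, write_session, _json_default

logger = logging.getLogger(__name__)

ALL_STAGES = ("pev", "decode", "states", "isi", "mixture", "psd", "rt")


@dataclass
class RunConfig:
    session_path: str | None = None  # None -> simulate a session
    out_dir: str = "wmstates_out"
    stages: tuple = ALL_STAGES
    seed: int = 0
    sim: simulate.SimConfig = field(default_factory=simulate.SimConfig)
    decoder: decoding.DecoderConfig = field(default_factory=decoding.DecoderConfig)
    n_label_shuffles: int = 50
    n_tuning_shuffles: int = 1000
    n_isi_shuffles: int = 10_000
    n_pseudo: int = 100
    min_population_size: int = 5
    n_rt_bootstrap: int = 10_000

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        cfg = cls()
        for k, v in raw.items():
            if k == "sim":
                cfg.sim = simulate.SimConfig(**v)
            elif k == "decoder":
                cfg.decoder = decoding.DecoderConfig(**v)
            elif hasattr(cfg, k):
                setattr(cfg, k, tuple(v) if k == "stages" else v)
            else:
                raise ValueError(f"unknown config key {k!r}")
        return cfg


def run_pipeline(cfg: RunConfig) -> int:
    """Run the configured stages; returns a process exit code (0 ok, 1 stage
    failure, 2 config error)."""
    out = Path(cfg.out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        unknown = set(cfg.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    except (OSError, ValueError) as e:
        logger.error("config error: %s", e)
        return 2

    summary: dict = {"seed": cfg.seed, "stages": {}, "exclusions": {}}
    failed = False

    try:
        if cfg.session_path:
            ds = read_session(cfg.session_path)
        else:
            ds = simulate.simulate_tuned_session(cfg.sim, substream(cfg.seed, "simulate"))
            write_session(ds, out / "session")
        summary["n_units"] = int(len(ds.units))
        summary["n_trials"] = int(len(ds.trials))
    except Exception as e:  # noqa: BLE001 - reported in summary
        logger.error("session load/simulate failed: %s", e)
        summary["stages"]["session"] = {"status": "failed", "error": str(e)}
        (out / "summary.json").write_text(json.dumps(summary, indent=1, default=_json_default))
        return 1

    labels = None
    series_by_pair = None

    def record(name: str, status: str, **kw):
        summary["stages"][name] = {"status": status, **kw}

    if "pev" in cfg.stages:
        try:
            res = pev.pev_timecourse(ds, seed=substream(cfg.seed, "pev"))
            res.to_frame().to_csv(out / "pev.csv", index=False)
            mean, sem = res.session_mean()
            delay = ds.epochs.delay
            m = (res.centers >= delay[0]) & (res.centers < delay[1])
            record("pev", "ok", delay_mean_omega2=float(mean[m].mean()))
        except Exception as e:  # noqa: BLE001
            record("pev", "failed", error=str(e))
            logger.error("pev failed:\n%s", traceback.format_exc())
            failed = True

    if "decode" in cfg.stages:
        try:
            comp = decoding.pseudo_population_decode(
                ds, cfg.decoder, n_pseudo=cfg.n_pseudo, rng=substream(cfg.seed, "decode")
            )
            pd.DataFrame(
                {
                    "bin_center_s": comp.centers,
                    "simultaneous": comp.simul_accuracy,
                    "pseudo_mean": comp.pseudo_accuracy.mean(axis=0),
                    "p_bin": comp.p_bin,
                    "significant_bonferroni": comp.significant_bonferroni,
                }
            ).to_csv(out / "decoding.csv", index=False)
            record(
                "decode",
                "ok",
                wilcoxon_p=comp.wilcoxon_p,
                epoch_diff=comp.epoch_diff,
            )
        except Exception as e:  # noqa: BLE001
            record("decode", "failed", error=str(e))
            logger.error("decode failed:\n%s", traceback.format_exc())
            failed = True

    if "states" in cfg.stages:
        try:
            labels, series_by_pair = states.label_states_all_pairs(
                ds,
                cfg.decoder,
                n_shuffles=cfg.n_label_shuffles,
                rng=substream(cfg.seed, "states"),
            )
            labels.to_frame().to_csv(out / "states.csv", index=False)
            tun = states.state_tuning(
                ds, labels, n_shuffles=cfg.n_tuning_shuffles, rng=substream(cfg.seed, "tuning")
            )
            record(
                "states",
                "ok",
                depth_on=tun.mean_depth_on,
                depth_off=tun.mean_depth_off,
                depth_reduction_pct=tun.depth_reduction_pct,
                n_units_excluded=tun.n_excluded,
            )
            summary["exclusions"]["units_without_off_time"] = tun.n_excluded
        except Exception as e:  # noqa: BLE001
            record("states", "failed", error=str(e))
            logger.error("states failed:\n%s", traceback.format_exc())
            failed = True

    if "isi" in cfg.stages:
        try:
            pops = isi.select_populations(ds, min_n=cfg.min_population_size)
            if len(pops) >= 3:
                trains = [
                    isi.trains_from_dataset(ds, uids) for uids in pops["unit_ids"]
                ]
                st = isi.collect_stats(
                    trains, n_iter=cfg.n_isi_shuffles, rng=substream(cfg.seed, "isi")
                )
                reg = isi.loglog_regression_and_test(st)
                pd.DataFrame(
                    {
                        "location_deg": pops["location_deg"],
                        "n_units": pops["n_units"],
                        "max_isi_s": st.max_empirical,
                        "rate_hz": st.freq_empirical,
                    }
                ).to_csv(out / "isi_populations.csv", index=False)
                record("isi", "ok", **reg.to_dict())
            else:
                record("isi", "skipped", reason=f"only {len(pops)} population(s) pass the gate")
        except Exception as e:  # noqa: BLE001
            record("isi", "failed", error=str(e))
            logger.error("isi failed:\n%s", traceback.format_exc())
            failed = True

    need_states = [s for s in ("mixture", "psd", "rt") if s in cfg.stages]
    if need_states and labels is None:
        for s in need_states:
            record(s, "skipped", reason="requires the states stage")
        if "states" not in cfg.stages:
            logger.error("stages %s require 'states'", need_states)
            failed = True
    else:
        if "mixture" in cfg.stages and series_by_pair is not None:
            try:
                delay = ds.epochs.delay
                conf = np.concatenate(
                    [
                        s.conf[:, (s.centers >= delay[0]) & (s.centers < delay[1])].ravel()
                        for s in series_by_pair.values()
                    ]
                )
                fit = mixture.fit_beta_mixture(conf, rng=substream(cfg.seed, "mixture"))
                record("mixture", "ok", **{k: v for k, v in fit.to_dict().items() if k != "two_state"})
            except Exception as e:  # noqa: BLE001
                record("mixture", "failed", error=str(e))
                failed = True
        if "psd" in cfg.stages and labels is not None:
            try:
                step = labels.centers[1] - labels.centers[0]
                freqs, psd_off, skipped = mixture.state_psd(
                    mixture.state_series_from_labels(labels, "off"), fs=1.0 / step
                )
                pd.DataFrame({"freq_hz": freqs, "psd_off": psd_off}).to_csv(
                    out / "psd.csv", index=False
                )
                record("psd", "ok", n_trials_skipped=skipped)
            except Exception as e:  # noqa: BLE001
                record("psd", "failed", error=str(e))
                failed = True
        if "rt" in cfg.stages and labels is not None:
            try:
                trials = _attach_go_state(ds, labels)
                eff = mixture.rt_state_bootstrap(
                    [trials], n_boot=cfg.n_rt_bootstrap, rng=substream(cfg.seed, "rt")
                )
                record("rt", "ok", **eff.to_dict())
            except Exception as e:  # noqa: BLE001
                record("rt", "skipped", reason=str(e))

    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=_json_default))
    return 1 if failed else 0


def _attach_go_state(ds, labels) -> pd.DataFrame:
    """Trials table with the on/off label of the bin containing the go cue."""
    go = ds.epochs.delay[1] - 1e-9
    step = labels.centers[1] - labels.centers[0]
    width = 2 * step
    in_bin = np.abs(labels.centers - go) <= width / 2
    on_m, off_m = labels.on_mask, labels.off_mask
    state = {}
    for i, tid in enumerate(labels.trial_ids):
        if in_bin.any() and on_m[i][in_bin].any():
            state[tid] = 1.0
        elif in_bin.any() and off_m[i][in_bin].any():
            state[tid] = 0.0
        else:
            state[tid] = np.nan
    trials = ds.trials.copy()
    trials["state_at_go"] = trials["trial_id"].map(state)
    return trials
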