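"""End-to-end orchestration: simulate -> behavior -> ERP -> stats.

``full_run`` chains every stage deterministically from the master seed and
writes all products (design TSVs, behavioral report, amplitude table,
ANOVA/Bayes tables, stopping-rule trace) plus a structured log of every
exclusion with the rule that triggered it.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as bhv
from . import erp as erpmod
from . import images, stats as statsmod
from .config import RunConfig
from .simulate import BehaviorGenParams, EEGGenParams, simulate_cohort

logger = logging.getLogger("maskerp")


def _stage(log, name):
    log.info("stage %-16s start", name)
    return time.time()


def full_run(config: RunConfig) -> dict:
    """Run the complete pipeline; returns the in-memory result bundle and
    writes TSV reports under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _full_run(config, out)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _full_run(config: RunConfig, out: Path) -> dict:
    config.to_yaml(out / "config.yaml")
    master = np.random.SeedSequence(config.seed)
    s_stim, s_cohort = (int(s.generate_state(1)[0] % 2**31) for s in master.spawn(2))

    # --- stimuli (optional; the EEG/behavioral stages do not consume pixels)
    if config.stimuli.generate:
        t0 = _stage(logger, "stimuli")
        manifest = images.generate_stimulus_set(
            n_exemplars=config.stimuli.n_exemplars,
            size=config.stimuli.size,
            block_px=config.stimuli.block_px,
            seed=s_stim,
            out_dir=out / "stimuli",
        )
        logger.info("stimuli: %d quadruples in %.1fs", len(manifest), time.time() - t0)
    else:
        manifest = None

    # --- cohort simulation
    t0 = _stage(logger, "simulate")
    cohort = simulate_cohort(
        config.cohort.n_participants,
        behavior=BehaviorGenParams(),
        eeg=EEGGenParams(),
        seed=s_cohort,
        scale=config.cohort.scale,
        outlier_participants=tuple(config.cohort.outlier_participants),
    )
    trials = cohort.behavioral_table()
    trials.to_csv(out / "trials.tsv", sep="\t", index=False)
    logger.info(
        "simulate: %d participants x %d trials in %.1fs",
        config.cohort.n_participants, len(trials) // config.cohort.n_participants,
        time.time() - t0,
    )

    # --- behavior
    t0 = _stage(logger, "behavior")
    behav = bhv.analyze_behavior(trials, q=config.stats.q)
    behav["sdt"].to_csv(out / "sdt.tsv", sep="\t", index=False)
    behav["group_tests"].to_csv(out / "behavior_tests.tsv", sep="\t", index=False)
    for pid in behav["excluded"]:
        logger.info("exclusion participant=%d rule=|z_c|>2.5", pid)
    behav_excluded = set(behav["excluded"])

    # --- ERP per participant (streamed to bound memory)
    t0 = _stage(logger, "erp")
    cfg = erpmod.PreprocessConfig(
        apply_filter=config.erp.apply_filter,
        filter_low_hz=config.erp.filter_low_hz,
        filter_high_hz=config.erp.filter_high_hz,
        rejection=erpmod.RejectionSpec(
            abs_max_uv=config.erp.abs_max_uv,
            gradient_max_uv=config.erp.gradient_max_uv,
            low_signal_min_uv=config.erp.low_signal_min_uv,
        ),
        bad_channels=tuple(config.erp.bad_channels),
        min_trials=config.erp.min_trials,
    )
    per_participant: dict[int, dict] = {}
    erp_excluded = []
    for p in cohort.iter_participants(with_eeg=True):
        pid = p["participant_id"]
        if pid in behav_excluded:
            continue
        res = erpmod.preprocess(p["epochs"], cfg)
        logger.info(
            "erp participant=%d rejected=%d/%d ok=%s",
            pid, res["n_rejected"], p["epochs"].n_trials, res["participant_ok"],
        )
        if not res["participant_ok"]:
            erp_excluded.append(pid)
            logger.info(
                "exclusion participant=%d rule=min_trials<%d", pid, config.erp.min_trials
            )
            continue
        per_participant[pid] = res
    logger.info("erp: %d participants retained in %.1fs", len(per_participant), time.time() - t0)
    amplitudes = erpmod.amplitude_table(per_participant)
    amplitudes.to_csv(out / "amplitudes.tsv", sep="\t", index=False)

    # --- stats
    t0 = _stage(logger, "stats")
    anova_rows = []
    for comp in ("P1", "N170"):
        sub = amplitudes[amplitudes["component"] == comp]
        for res in statsmod.rm_anova_3x2(sub):
            anova_rows.append(
                {
                    "component": comp,
                    "effect": res.effect,
                    "F": res.F,
                    "df1": res.df1,
                    "df2": res.df2,
                    "p": res.p,
                    "eta_p2": res.eta_p2,
                }
            )
    anova = pd.DataFrame(anova_rows)
    anova["significant_fdr"], _ = bhv.fdr_bh(anova["p"].to_numpy(), q=config.stats.q)
    anova.to_csv(out / "anova.tsv", sep="\t", index=False)

    comparisons = statsmod.planned_comparisons(amplitudes, r=config.stats.prior_scale)
    comparisons.to_csv(out / "bayes_comparisons.tsv", sep="\t", index=False)

    # stopping rule monitored on the nonconscious N170 face-vs-scramble BF
    mon = comparisons.query(
        "component == 'N170' and awareness == 'nonconscious' and contrast == 'face - scramble'"
    ).iloc[0]
    n_retained = amplitudes["participant_id"].nunique()
    decision = statsmod.sequential_stop(
        n_retained, mon["bf10"], min_n=config.stats.min_n,
        upper=config.stats.bf_upper, lower=config.stats.bf_lower,
    )
    pd.DataFrame(
        [{"n": decision.n, "monitored_bf10": decision.bf10, "decision": decision.decision}]
    ).to_csv(out / "stopping.tsv", sep="\t", index=False)
    logger.info(
        "stats: stopping decision %s at n=%d (bf10=%.3f) in %.1fs",
        decision.decision, decision.n, decision.bf10, time.time() - t0,
    )

    return {
        "manifest": manifest,
        "trials": trials,
        "behavior": behav,
        "amplitudes": amplitudes,
        "anova": anova,
        "comparisons": comparisons,
        "stopping": decision,
        "excluded_behavior": sorted(behav_excluded),
        "excluded_erp": erp_excluded,
    }
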