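"""End-to-end pipeline: simulate -> preprocess -> decode -> stats -> report.

Each stage reads and writes a fixed directory layout, so the CLI
subcommands and :func:`run_pipeline` compose to identical outputs:

    out/
      config.json                      run configuration + hash
      raw/sub-XX_recording.h5          continuous EEG container
      raw/sub-XX_events.tsv            BIDS-style events
      raw/trials.tsv, behaviour.tsv, vviq.tsv
      epochs/sub-XX_epochs.h5          one group per epoch role
      decoding/timecourses.tsv         subject x analysis accuracy curves
      decoding/genmatrix_<analysis>_sub-XX.h5
      stats/group_<analysis>.tsv       corrected p per time point
      stats/subject_perms_<analysis>.tsv
      stats/summary.json               onsets, peaks, behaviour, provenance

All randomness is spawned from the run seed, so a repeated run with the
same configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .decoding import (
    cross_decode,
    cv_timecourse,
    temporal_generalization,
)
from .design import (
    BehaviouralRecord,
    TrialPlan,
    score_vviq,
    summarize_behaviour,
    trial_table,
)
from .io import (
    AnalysisSpec,
    RunConfig,
    config_hash,
    events_to_tsv,
    load_epochs,
    load_recording,
    save_epochs,
    save_recording,
    vviq_from_frame,
    vviq_to_frame,
)
from .preprocess import preprocess_recording
from .stats import (
    ClusterResult,
    decoding_summary,
    group_cluster_test,
    subject_permutation_test,
    vividness_split_comparison,
)
from .synthetic import simulate_cohort

logger = logging.getLogger(__name__)

__all__ = [
    "ResultBundle",
    "default_analyses",
    "demo_config",
    "run_pipeline",
    "stage_simulate",
    "stage_preprocess",
    "stage_decode",
    "stage_stats",
    "stage_report",
]


@dataclass
class ResultBundle:
    """Everything a run produced, loaded back into memory."""

    timecourses: pd.DataFrame
    group: dict[str, ClusterResult]
    summary: dict
    provenance: dict


def default_analyses() -> tuple[AnalysisSpec, ...]:
    """The standard analysis battery over the four epoch types."""
    from .decoding import SchemeSpec

    loco = lambda contrast: SchemeSpec("leave_one_chunk_out", contrast)  # noqa: E731
    return (
        AnalysisSpec("vision_category", loco("category"), "vision"),
        AnalysisSpec(
            "vision_exemplar_face",
            loco("exemplar_within_category"), "vision", category_subset="face",
        ),
        AnalysisSpec(
            "vision_exemplar_place",
            loco("exemplar_within_category"), "vision", category_subset="place",
        ),
        AnalysisSpec("pattern_category", loco("category"), "pattern"),
        AnalysisSpec(
            "cue_category",
            SchemeSpec("leave_two_exemplar_out", "category"), "cue",
        ),
        AnalysisSpec(
            "response_category",
            SchemeSpec("leave_two_exemplar_out", "category"), "response",
        ),
        AnalysisSpec(
            "vision_to_cue",
            SchemeSpec("leave_one_out_cross", "category"), "vision", "cue",
        ),
        AnalysisSpec(
            "pattern_to_response",
            SchemeSpec("split_half_cross", "category"), "pattern", "response",
        ),
    )


def demo_config(
    n_subjects: int = 4, n_channels: int = 16, seed: int = 0
) -> RunConfig:
    """A reduced configuration that runs end-to-end in minutes.

    One block, fewer channels, and trimmed Monte-Carlo iteration counts;
    the timing of every event, the counterbalancing, and every analysis
    step are the full-size ones.
    """
    import dataclasses as dc

    from .design import DesignSpec
    from .stats import StatsConfig
    from .synthetic import SimConfig

    return RunConfig(
        design=DesignSpec(n_blocks=1, stream_count_per_block=1),
        sim=SimConfig(n_subjects=n_subjects, n_channels=n_channels, seed=seed),
        analyses=tuple(
            a for a in default_analyses()
            if a.name in ("vision_category", "cue_category", "vision_to_cue")
        ),
        stats=StatsConfig(n_montecarlo=1000, n_subject_perms=100),
        subject_perm_analyses=("cue_category",),
        seed=seed,
    )


def _subjects(cfg: RunConfig) -> list[str]:
    return [f"sub-{i + 1:02d}" for i in range(cfg.sim.n_subjects)]


def stage_simulate(cfg: RunConfig, out: str | Path) -> None:
    """Simulate the cohort and write recordings, events and behaviour."""
    out = Path(out)
    (out / "raw").mkdir(parents=True, exist_ok=True)
    cfg.to_json(out / "config.json")
    sim = dataclasses.replace(cfg.sim, seed=cfg.seed)
    cohort = simulate_cohort(sim, cfg.design)
    trials, behaviour, forms = [], [], {}
    for sub in cohort:
        save_recording(out / "raw" / f"{sub.subject}_recording.h5", sub.recording)
        events_to_tsv(
            sub.recording.events,
            out / "raw" / f"{sub.subject}_events.tsv",
            sub.recording.fs_hz,
        )
        t = trial_table(sub.plans)
        t.insert(0, "subject", sub.subject)
        trials.append(t)
        for rec in sub.behaviour:
            behaviour.append(
                dict(
                    subject=sub.subject,
                    block=rec.trial.block,
                    trial=rec.trial.trial,
                    target_id=rec.trial.target_id,
                    response_id=rec.response_id,
                    rt_cue_to_click_s=rec.rt_cue_to_click_s,
                )
            )
        forms[sub.subject] = sub.vviq
    pd.concat(trials).to_csv(out / "raw" / "trials.tsv", sep="\t", index=False)
    pd.DataFrame(behaviour).to_csv(
        out / "raw" / "behaviour.tsv", sep="\t", index=False
    )
    vviq_to_frame(forms).to_csv(out / "raw" / "vviq.tsv", sep="\t", index=False)


def stage_preprocess(cfg: RunConfig, out: str | Path) -> None:
    """Preprocess every recording and write the four epoch sets."""
    out = Path(out)
    (out / "epochs").mkdir(parents=True, exist_ok=True)
    for subject in _subjects(cfg):
        rec = load_recording(out / "raw" / f"{subject}_recording.h5")
        epochs = preprocess_recording(rec, cfg.preprocess, subject=subject)
        save_epochs(out / "epochs" / f"{subject}_epochs.h5", epochs)
        logger.info(
            "%s: %s", subject,
            {role: len(ep) for role, ep in epochs.items()},
        )


def _analysis_epochs(epochs: dict, spec: AnalysisSpec):
    """Select and filter the epoch sets an analysis trains/tests on."""
    train = epochs[spec.train_role]
    if spec.category_subset is not None:
        train = train.select(
            (train.labels["category"] == spec.category_subset).to_numpy()
        )
    if spec.scheme.contrast == "exemplar_within_category":
        train = train.select((train.labels["exemplar"] >= 0).to_numpy())
    test = epochs[spec.test_role] if spec.test_role else None
    return train, test


def _run_analysis(epochs: dict, spec: AnalysisSpec, classifier):
    train, test = _analysis_epochs(epochs, spec)
    if test is None:
        return cv_timecourse(train, spec.scheme, classifier)
    mode = "leave_one_out" if spec.scheme.name == "leave_one_out_cross" else "split_half"
    return cross_decode(train, test, mode, spec.scheme, classifier)


def stage_decode(cfg: RunConfig, out: str | Path) -> None:
    """Run every configured analysis for every subject."""
    if not cfg.analyses:
        raise ValueError("configuration lists no analyses to decode")
    out = Path(out)
    (out / "decoding").mkdir(parents=True, exist_ok=True)
    frames = []
    for subject in _subjects(cfg):
        epochs = load_epochs(out / "epochs" / f"{subject}_epochs.h5")
        for spec in cfg.analyses:
            tc = _run_analysis(epochs, spec, cfg.classifier)
            frame = tc.to_frame()
            frame.insert(1, "analysis", spec.name)
            frames.append(frame)
            if spec.generalize and spec.test_role:
                train, test = _analysis_epochs(epochs, spec)
                gm = temporal_generalization(train, test, spec.scheme, cfg.classifier)
                with h5py.File(
                    out / "decoding" / f"genmatrix_{spec.name}_{subject}.h5", "w"
                ) as f:
                    f.create_dataset("accuracy", data=gm.accuracy)
                    f.create_dataset("train_times_ms", data=gm.train_times_ms)
                    f.create_dataset("test_times_ms", data=gm.test_times_ms)
    pd.concat(frames).to_csv(
        out / "decoding" / "timecourses.tsv", sep="\t", index=False
    )


def stage_stats(cfg: RunConfig, out: str | Path) -> None:
    """Group cluster tests, subject permutation tests, vividness split."""
    out = Path(out)
    (out / "stats").mkdir(parents=True, exist_ok=True)
    tcs = pd.read_csv(out / "decoding" / "timecourses.tsv", sep="\t")
    vviq = vviq_from_frame(pd.read_csv(out / "raw" / "vviq.tsv", sep="\t"))
    open_scores = {s: score_vviq(f)["eyes_open"] for s, f in vviq.items()}
    summary: dict = {"analyses": {}, "vividness_split": {}}
    seed_root = np.random.SeedSequence([cfg.seed, 2029])
    for spec in cfg.analyses:
        sub = tcs[tcs["analysis"] == spec.name]
        pivot = sub.pivot_table(
            index="subject", columns="time_ms", values="accuracy", sort=True
        )
        data = pivot.to_numpy()
        times = pivot.columns.to_numpy(dtype=float)
        rng = np.random.default_rng(seed_root.spawn(1)[0])
        res = group_cluster_test(data, 0.5, cfg.stats, rng, times_ms=times)
        pd.DataFrame(
            {
                "time_ms": times,
                "statistic": res.stat,
                "corrected_p": res.p_corrected,
                "significant": res.mask.astype(int),
            }
        ).to_csv(out / "stats" / f"group_{spec.name}.tsv", sep="\t", index=False)
        summary["analyses"][spec.name] = decoding_summary(
            times, data.mean(axis=0), res.mask
        )
        scores = [open_scores[s] for s in pivot.index]
        try:
            vres = vividness_split_comparison(
                data, scores, cfg.stats,
                np.random.default_rng(seed_root.spawn(1)[0]), times_ms=times,
            )
            summary["vividness_split"][spec.name] = decoding_summary(
                times, data.mean(axis=0), vres.mask
            ) | {"n_significant": int(vres.mask.sum())}
        except ValueError as err:
            summary["vividness_split"][spec.name] = {"skipped": str(err)}
    for name in cfg.subject_perm_analyses:
        spec = next(a for a in cfg.analyses if a.name == name)
        rows = []
        for subject in _subjects(cfg):
            epochs = load_epochs(out / "epochs" / f"{subject}_epochs.h5")
            train, _ = _analysis_epochs(epochs, spec)
            res = subject_permutation_test(
                train, spec.scheme, cfg.stats,
                np.random.default_rng(seed_root.spawn(1)[0]), cfg.classifier,
            )
            rows.append(
                pd.DataFrame(
                    {
                        "subject": subject,
                        "time_ms": res.times_ms,
                        "accuracy": res.observed.accuracy,
                        "p_raw": res.p_raw,
                        "p_fdr": res.p_fdr,
                        "significant": res.mask.astype(int),
                    }
                )
            )
        perms = pd.concat(rows)
        perms.to_csv(
            out / "stats" / f"subject_perms_{name}.tsv", sep="\t", index=False
        )
        summary["analyses"].setdefault(name, {})
        summary["analyses"][name]["subject_significant_points"] = int(
            perms["significant"].sum()
        )
    behaviour = pd.read_csv(out / "raw" / "behaviour.tsv", sep="\t")
    trials = pd.read_csv(out / "raw" / "trials.tsv", sep="\t")
    summary["behaviour"] = _behaviour_summary(behaviour, trials)
    totals = {s: score_vviq(f)["total"] for s, f in vviq.items()}
    summary["vviq"] = {
        "mean_total": float(np.mean(list(totals.values()))),
        "min_total": int(min(totals.values())),
        "max_total": int(max(totals.values())),
    }
    summary["provenance"] = {
        "config_hash": config_hash(cfg),
        "package_version": __version__,
        "seed": cfg.seed,
    }
    (out / "stats" / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )


def _behaviour_summary(behaviour: pd.DataFrame, trials: pd.DataFrame) -> dict:
    records = []
    seq_cols = sorted(c for c in trials.columns if c.startswith("seq_pos"))
    merged = behaviour.merge(trials, on=["subject", "block", "trial", "target_id"])
    for row in merged.itertuples():
        plan = TrialPlan(
            block=row.block,
            trial=row.trial,
            sequence=tuple(getattr(row, c) for c in seq_cols),
            target_position=row.target_position,
            target_id=row.target_id,
        )
        records.append(
            BehaviouralRecord(
                trial=plan,
                response_id=row.response_id,
                rt_cue_to_click_s=row.rt_cue_to_click_s,
            )
        )
    s = summarize_behaviour(records)
    return {
        k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in s.items()
    }


def stage_report(cfg: RunConfig, out: str | Path, figures: bool = True) -> dict:
    """Collect the summary and draw simple accuracy/time figures."""
    out = Path(out)
    summary = json.loads((out / "stats" / "summary.json").read_text())
    (out / "report").mkdir(parents=True, exist_ok=True)
    (out / "report" / "report.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    if figures:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        tcs = pd.read_csv(out / "decoding" / "timecourses.tsv", sep="\t")
        for spec in cfg.analyses:
            sub = tcs[tcs["analysis"] == spec.name]
            pivot = sub.pivot_table(
                index="subject", columns="time_ms", values="accuracy"
            )
            grp = pd.read_csv(out / "stats" / f"group_{spec.name}.tsv", sep="\t")
            fig, ax = plt.subplots(figsize=(6, 3))
            times = pivot.columns.to_numpy(dtype=float)
            mean = pivot.to_numpy().mean(axis=0)
            sem = pivot.to_numpy().std(axis=0, ddof=1) / np.sqrt(len(pivot))
            ax.fill_between(times, mean - sem, mean + sem, alpha=0.3)
            ax.plot(times, mean)
            sig = grp["significant"].to_numpy(dtype=bool)
            if sig.any():
                ax.plot(times[sig], np.full(sig.sum(), 0.4), ".k", ms=3)
            ax.axhline(0.5, color="grey", lw=0.5)
            ax.axvline(0.0, color="grey", lw=0.5)
            ax.set(xlabel="time (ms)", ylabel="accuracy", title=spec.name)
            fig.tight_layout()
            fig.savefig(out / "report" / f"{spec.name}.png", dpi=100)
            plt.close(fig)
    return summary


def run_pipeline(cfg: RunConfig, out: str | Path, figures: bool = False) -> ResultBundle:
    """Run every stage in order and load the results back.

    Identical to invoking the CLI subcommands one after another on the
    same directory.
    """
    if not cfg.analyses:
        raise ValueError("configuration lists no analyses to decode")
    out = Path(out)
    stage_simulate(cfg, out)
    stage_preprocess(cfg, out)
    stage_decode(cfg, out)
    stage_stats(cfg, out)
    summary = stage_report(cfg, out, figures=figures)
    tcs = pd.read_csv(out / "decoding" / "timecourses.tsv", sep="\t")
    group = {}
    for spec in cfg.analyses:
        grp = pd.read_csv(out / "stats" / f"group_{spec.name}.tsv", sep="\t")
        group[spec.name] = ClusterResult(
            times_ms=grp["time_ms"].to_numpy(),
            stat=grp["statistic"].to_numpy(),
            p_corrected=grp["corrected_p"].to_numpy(),
            mask=grp["significant"].to_numpy(dtype=bool),
            alpha=cfg.stats.alpha,
        )
    return ResultBundle(
        timecourses=tcs,
        group=group,
        summary=summary,
        provenance=summary["provenance"],
    )
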