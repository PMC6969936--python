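"""Seeded synthetic EEG cohorts with injected class-specific evoked structure.

The generator emulates the recording conditions the analysis assumes:
64-channel, 1000 Hz continuous EEG over 4 blocks, each block holding 5 rapid
pattern-estimator streams (56 images, 200 ms SOA) followed by 24 imagery
trials (four 1500 ms presentations, retro-cue, mouse click, 3 s imagery
screen).  Class structure is injected as unit-norm spatial patterns (one per
exemplar, sharing a category component) multiplied by a half-cosine temporal
bump at a configurable latency and SNR, on top of 1/f ("pink") background,
white sensor noise and 50 Hz line noise.  Imagery-locked signal is injected
at the mouse click with optional latency jitter; its default amplitude is
zero, i.e. a true null, which is the regime the analysis must not turn into
false positives.

Everything is deterministic given the top-level seed; per-subject generators
are spawned from a :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence
import warnings

import numpy as np
import pandas as pd

from .design import (
    BehaviouralRecord,
    DesignSpec,
    StimulusSet,
    TrialPlan,
    VviqForm,
    allocate_targets,
    build_pattern_stream,
    enumerate_block_sequences,
    mirrored_id,
)

__all__ = [
    "NoiseConfig",
    "SimConfig",
    "ClassPatternSet",
    "Recording",
    "SubjectData",
    "make_class_patterns",
    "half_cosine_bump",
    "pink_noise",
    "simulate_noise",
    "simulate_subject",
    "simulate_cohort",
    "simulate_labelled_epochs",
    "EVENT_COLUMNS",
]

#: canonical event-table columns; onsets are samples at the recording rate
EVENT_COLUMNS = [
    "onset_sample",
    "epoch_role",
    "stimulus_id",
    "category",
    "exemplar",
    "block",
    "trial",
    "stream",
]


@dataclass(frozen=True)
class NoiseConfig:
    """Background noise mix: 1/f^exponent pink core, white floor, mains line."""

    pink_exponent: float = 1.0
    pink_sd: float = 1.0  # microvolt RMS of the pink component, per channel
    white_sd: float = 0.5
    line_hz: float = 50.0
    line_amp: float = 0.5  # microvolt amplitude of the mains sinusoid

    @property
    def rms(self) -> float:
        """Broadband (pink + white) RMS used as the SNR reference."""
        return float(np.hypot(self.pink_sd, self.white_sd))


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level simulation parameters.

    ``evoked_snr`` scales the peak of the visual evoked pattern relative to
    the broadband noise RMS; ``imagery_snr`` does the same for the
    imagery-locked pattern added at the mouse click (0 = true-null imagery).
    ``imagery_jitter_ms`` jitters the imagery signal's latency per trial,
    reflecting that image generation is not tightly time-locked.
    """

    n_subjects: int = 16
    n_channels: int = 64
    record_fs_hz: float = 1000.0
    evoked_onset_ms: float = 100.0
    evoked_duration_ms: float = 300.0
    evoked_snr: float = 1.0
    imagery_snr: float = 0.0
    imagery_jitter_ms: float = 200.0
    category_mix: float = 0.5  # weight of the shared category component
    rt_median_s: float = 2.0
    rt_sigma: float = 0.75  # log-normal shape of cue->click RTs
    p_correct: float = 0.92
    p_error_mirrored_target: float = 0.33  # rest of the errors pick another original
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.evoked_snr < 0 or self.imagery_snr < 0:
            raise ValueError("SNR values must be non-negative")
        if self.imagery_jitter_ms < 0:
            raise ValueError("imagery jitter must be non-negative")


@dataclass(frozen=True)
class ClassPatternSet:
    """Unit-norm spatial pattern per exemplar, grouped by category."""

    categories: tuple[str, str]
    exemplar_patterns: np.ndarray  # (n_categories, n_exemplars, n_channels)

    def pattern(self, category: str, exemplar: int) -> np.ndarray:
        ci = self.categories.index(category)
        if exemplar < 0:  # category filler image: use the category mean
            return self.category_pattern(category)
        return self.exemplar_patterns[ci, exemplar]

    def category_pattern(self, category: str) -> np.ndarray:
        ci = self.categories.index(category)
        mean = self.exemplar_patterns[ci].mean(axis=0)
        return mean / np.linalg.norm(mean)


@dataclass
class Recording:
    """Continuous multichannel EEG with an attached event table (microvolts)."""

    data: np.ndarray  # (n_channels, n_samples)
    fs_hz: float
    channel_labels: list[str]
    events: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels length must match data rows")
        ev = self.events
        missing = [c for c in EVENT_COLUMNS if c not in ev.columns]
        if missing:
            raise ValueError(f"event table missing columns: {missing}")
        if len(ev) and (
            ev["onset_sample"].min() < 0
            or ev["onset_sample"].max() >= self.data.shape[1]
        ):
            raise ValueError("event onsets fall outside the recording")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class SubjectData:
    """One simulated participant: EEG, design, behaviour, questionnaire."""

    subject: str
    recording: Recording
    plans: list[TrialPlan]
    behaviour: list[BehaviouralRecord]
    vviq: VviqForm
    patterns: ClassPatternSet


def make_class_patterns(
    n_channels: int,
    rng: np.random.Generator,
    categories: tuple[str, str] = ("face", "place"),
    n_exemplars: int = 2,
    category_mix: float = 0.5,
) -> ClassPatternSet:
    """Draw unit-norm exemplar patterns sharing a per-category component.

    Each exemplar pattern is ``normalize(mix * c_cat + (1 - mix) * e)`` with
    ``c_cat`` a category-level random direction and ``e`` exemplar-specific,
    so with 0 < mix < 1 exemplars within a category are more similar to each
    other than to the opposite category, making both category and exemplar
    contrasts decodable.
    """
    if n_channels < 2:
        raise ValueError("need at least 2 channels for spatial patterns")
    if not 0 <= category_mix <= 1:
        raise ValueError("category_mix must be in [0, 1]")
    pats = np.empty((len(categories), n_exemplars, n_channels))
    for ci in range(len(categories)):
        cat_dir = rng.standard_normal(n_channels)
        cat_dir /= np.linalg.norm(cat_dir)
        for ei in range(n_exemplars):
            ex_dir = rng.standard_normal(n_channels)
            ex_dir /= np.linalg.norm(ex_dir)
            p = category_mix * cat_dir + (1 - category_mix) * ex_dir
            pats[ci, ei] = p / np.linalg.norm(p)
    return ClassPatternSet(categories=tuple(categories), exemplar_patterns=pats)


def half_cosine_bump(duration_ms: float, fs_hz: float) -> np.ndarray:
    """Half-cosine (sine half-wave) bump: smooth, compactly supported, peak 1."""
    n = max(int(round(duration_ms * fs_hz / 1000.0)), 1)
    return np.sin(np.pi * (np.arange(n) + 0.5) / n)


def pink_noise(
    n_channels: int,
    n_samples: int,
    rng: np.random.Generator,
    exponent: float = 1.0,
    fs_hz: float = 1000.0,
) -> np.ndarray:
    """1/f^exponent noise, unit RMS per channel, via spectral shaping."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs_hz)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = np.fft.rfft(rng.standard_normal((n_channels, n_samples)), axis=1)
    out = np.fft.irfft(spec * shape, n=n_samples, axis=1)
    out /= out.std(axis=1, keepdims=True)
    return out


def simulate_noise(
    n_channels: int,
    n_samples: int,
    noise: NoiseConfig,
    rng: np.random.Generator,
    fs_hz: float,
) -> np.ndarray:
    """Pink + white + mains-line mixture with per-channel random line phase."""
    data = noise.pink_sd * pink_noise(
        n_channels, n_samples, rng, noise.pink_exponent, fs_hz
    )
    if noise.white_sd > 0:
        data += noise.white_sd * rng.standard_normal((n_channels, n_samples))
    if noise.line_amp > 0:
        t = np.arange(n_samples) / fs_hz
        phases = rng.uniform(0, 2 * np.pi, size=n_channels)
        data += noise.line_amp * np.sin(
            2 * np.pi * noise.line_hz * t[None, :] + phases[:, None]
        )
    return data


def _add_pattern(
    data: np.ndarray,
    onset_sample: int,
    pattern: np.ndarray,
    bump: np.ndarray,
    amplitude: float,
) -> None:
    """Add ``amplitude * pattern x bump`` in place, clipped to the recording."""
    n = data.shape[1]
    start, stop = onset_sample, onset_sample + len(bump)
    b0, b1 = max(0, -start), len(bump) - max(0, stop - n)
    if b1 <= b0:
        return
    data[:, max(start, 0) : min(stop, n)] += amplitude * np.outer(
        pattern, bump[b0:b1]
    )


def _simulate_vviq(rng: np.random.Generator) -> VviqForm:
    """Item ratings around a subject-level vividness trait (spans 32-160)."""
    trait = rng.uniform(2.0, 4.6)
    ratings = np.clip(
        np.rint(trait + rng.normal(0, 0.8, size=32)), 1, 5
    ).astype(int)
    return VviqForm(eyes_open=tuple(ratings[:16]), eyes_closed=tuple(ratings[16:]))


def _simulate_response(
    plan: TrialPlan, stimulus_set: StimulusSet, cfg: SimConfig, rng
) -> str:
    """Response-screen choice: mostly the target; errors split between the
    mirrored target and the other original images."""
    if rng.random() < cfg.p_correct:
        return plan.target_id
    if rng.random() < cfg.p_error_mirrored_target:
        return mirrored_id(plan.target_id)
    others = [t for t in stimulus_set.target_ids if t != plan.target_id]
    return str(rng.choice(others))


def simulate_subject(
    design: DesignSpec,
    plans: Sequence[TrialPlan],
    cfg: SimConfig,
    rng: np.random.Generator,
    stimulus_set: StimulusSet | None = None,
    patterns: ClassPatternSet | None = None,
    subject: str = "sub-01",
) -> SubjectData:
    """Simulate one participant's continuous recording plus behaviour.

    The event timeline follows the block structure: per block, the rapid
    streams, then the imagery trials.  Class-specific bumps are injected at
    every pattern/vision stimulus onset; the target's pattern is injected at
    the mouse click scaled by ``imagery_snr`` with per-trial jitter.
    """
    stimulus_set = stimulus_set or StimulusSet()
    if patterns is None:
        patterns = make_class_patterns(
            cfg.n_channels, rng, stimulus_set.categories,
            stimulus_set.exemplars_per_category, cfg.category_mix,
        )
    fs = cfg.record_fs_hz
    soa_gap = design.stream_soa_ms
    if cfg.evoked_onset_ms + cfg.evoked_duration_ms > soa_gap:
        warnings.warn(
            "evoked response outlives the stream SOA; pattern-estimator "
            "responses will overlap (as in real rapid streams)",
            stacklevel=2,
        )

    def ms2samp(t_ms: float) -> int:
        return int(round(t_ms * fs / 1000.0))

    events: list[dict] = []
    injections: list[tuple[int, np.ndarray, float]] = []  # onset, pattern, amp
    behaviour: list[BehaviouralRecord] = []
    bump = half_cosine_bump(cfg.evoked_duration_ms, fs)
    onset_off = ms2samp(cfg.evoked_onset_ms)
    rms = cfg.noise.rms
    t_ms = 500.0  # lead-in so the first pre-stimulus window exists

    by_block: dict[int, list[TrialPlan]] = {}
    for p in plans:
        by_block.setdefault(p.block, []).append(p)

    for block in sorted(by_block):
        for stream_i in range(design.stream_count_per_block):
            t_ms += design.fixation_ms
            stream = build_pattern_stream(stimulus_set, rng, design)
            for row in stream.itertuples():
                onset = ms2samp(t_ms + row.onset_ms)
                events.append(
                    dict(
                        onset_sample=onset,
                        epoch_role="pattern",
                        stimulus_id=row.image_id,
                        category=row.category,
                        exemplar=int(row.exemplar),
                        block=block,
                        trial=-1,
                        stream=stream_i,
                    )
                )
                if cfg.evoked_snr > 0:
                    injections.append(
                        (
                            onset + onset_off,
                            patterns.pattern(row.category, int(row.exemplar)),
                            cfg.evoked_snr * rms,
                        )
                    )
            t_ms += design.stream_duration_ms + 2000.0  # self-paced pause
        for plan in by_block[block]:
            t_ms += design.fixation_ms
            for sid in plan.sequence:
                onset = ms2samp(t_ms)
                cat = stimulus_set.category_of(sid)
                ex = stimulus_set.exemplar_of(sid)
                events.append(
                    dict(
                        onset_sample=onset,
                        epoch_role="vision",
                        stimulus_id=sid,
                        category=cat,
                        exemplar=ex,
                        block=block,
                        trial=plan.trial,
                        stream=-1,
                    )
                )
                if cfg.evoked_snr > 0:
                    injections.append(
                        (onset + onset_off, patterns.pattern(cat, ex),
                         cfg.evoked_snr * rms)
                    )
                t_ms += design.stim_duration_ms
            t_ms += design.fixation_ms
            cue_ms = t_ms
            tcat = stimulus_set.category_of(plan.target_id)
            tex = stimulus_set.exemplar_of(plan.target_id)
            tlabels = dict(
                stimulus_id=plan.target_id, category=tcat, exemplar=tex,
                block=block, trial=plan.trial, stream=-1,
            )
            events.append(
                dict(onset_sample=ms2samp(cue_ms), epoch_role="cue", **tlabels)
            )
            rt_s = float(
                np.exp(np.log(cfg.rt_median_s) + cfg.rt_sigma * rng.standard_normal())
            )
            click_ms = cue_ms + 1000.0 * rt_s
            events.append(
                dict(onset_sample=ms2samp(click_ms), epoch_role="response", **tlabels)
            )
            if cfg.imagery_snr > 0:
                jitter = cfg.imagery_jitter_ms * rng.standard_normal()
                injections.append(
                    (
                        ms2samp(click_ms + cfg.evoked_onset_ms + jitter),
                        patterns.pattern(tcat, tex),
                        cfg.imagery_snr * rms,
                    )
                )
            behaviour.append(
                BehaviouralRecord(
                    trial=plan,
                    response_id=_simulate_response(plan, stimulus_set, cfg, rng),
                    rt_cue_to_click_s=rt_s,
                )
            )
            t_ms = click_ms + design.imagery_screen_ms + 1500.0  # response screen
        t_ms += 2000.0  # inter-block break

    n_samples = ms2samp(t_ms + 2000.0)
    data = simulate_noise(cfg.n_channels, n_samples, cfg.noise, rng, fs).astype(
        np.float32
    )
    for onset, pat, amp in injections:
        _add_pattern(data, onset, pat, bump, amp)

    ev = pd.DataFrame(events, columns=EVENT_COLUMNS).sort_values(
        "onset_sample", kind="stable"
    )
    ev = ev.reset_index(drop=True)
    labels = [f"EEG{idx + 1:03d}" for idx in range(cfg.n_channels)]
    rec = Recording(data=data, fs_hz=fs, channel_labels=labels, events=ev)
    return SubjectData(
        subject=subject,
        recording=rec,
        plans=list(plans),
        behaviour=behaviour,
        vviq=_simulate_vviq(rng),
        patterns=patterns,
    )


def simulate_cohort(
    cfg: SimConfig, design: DesignSpec | None = None
) -> list[SubjectData]:
    """Simulate ``cfg.n_subjects`` participants, reproducibly from ``cfg.seed``.

    Each subject gets a spawned sub-seed, their own spatial patterns, their
    own counterbalanced target allocation, and an independent VVIQ draw, so
    the cohort spans the vividness range the median split needs.
    """
    if cfg.n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    design = design or DesignSpec()
    stimulus_set = StimulusSet()
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_subjects)
    cohort = []
    for i, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        orderings = enumerate_block_sequences(
            design.n_stimuli, stimulus_set.target_ids
        )
        plans = allocate_targets(orderings, design.n_blocks, rng)
        cohort.append(
            simulate_subject(
                design, plans, cfg, rng,
                stimulus_set=stimulus_set, subject=f"sub-{i + 1:02d}",
            )
        )
    return cohort


def simulate_labelled_epochs(
    n_chunks: int,
    cfg: SimConfig,
    rng: np.random.Generator,
    fs_hz: float = 250.0,
    window_ms: tuple[float, float] = (-300.0, 1500.0),
    patterns: ClassPatternSet | None = None,
    subject: str = "sub-01",
):
    """Directly simulate an epoched data set (no continuous timeline).

    Produces ``n_chunks`` chunks, each holding one epoch of every target
    stimulus (2 categories x 2 exemplars), with the evoked bump injected at
    ``cfg.evoked_onset_ms`` and pink+white noise backgrounds.  This is the
    fast path for statistical calibration studies that need many replicate
    cohorts; the continuous-recording path exercises the same injection
    model through the full preprocessing chain.
    """
    from .preprocess import EpochSet  # local import to avoid a cycle

    stimulus_set = StimulusSet()
    if patterns is None:
        patterns = make_class_patterns(
            cfg.n_channels, rng, stimulus_set.categories,
            stimulus_set.exemplars_per_category, cfg.category_mix,
        )
    n_t = int(round((window_ms[1] - window_ms[0]) * fs_hz / 1000.0))
    times_ms = window_ms[0] + np.arange(n_t) * 1000.0 / fs_hz
    targets = stimulus_set.target_ids
    n_epochs = n_chunks * len(targets)
    noise_cfg = replace(cfg.noise, line_amp=0.0)  # epochs are post-cleaning
    data = np.stack(
        [
            simulate_noise(cfg.n_channels, n_t, noise_cfg, rng, fs_hz)
            for _ in range(n_epochs)
        ]
    )
    bump = half_cosine_bump(cfg.evoked_duration_ms, fs_hz)
    i0 = int(round((cfg.evoked_onset_ms - window_ms[0]) * fs_hz / 1000.0))
    rows = []
    k = 0
    for chunk in range(n_chunks):
        for sid in targets:
            cat = stimulus_set.category_of(sid)
            ex = stimulus_set.exemplar_of(sid)
            if cfg.evoked_snr > 0:
                _add_pattern(
                    data[k], i0, patterns.pattern(cat, ex), bump,
                    cfg.evoked_snr * cfg.noise.rms,
                )
            rows.append(
                dict(
                    epoch_role="vision", stimulus_id=sid, category=cat,
                    exemplar=ex, chunk=f"c{chunk}", subject=subject,
                )
            )
            k += 1
    return EpochSet(data=data, times_ms=times_ms, labels=pd.DataFrame(rows))
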