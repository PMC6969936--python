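"""Experimental design: counterbalanced imagery sequences, pattern-estimator
streams, and behavioural instruments.

The experiment this package models presents four target images (2 categories
x 2 exemplars, e.g. two faces and two places) in 1500 ms sequences of four,
then retro-cues one of them for mental imagery.  Each block contains all 24
orderings of the four targets, and target positions are counterbalanced so
that every image is the target in every serial position equally often across
the four blocks.  Each block is preceded by rapid serial "pattern estimator"
streams of 56 images at 200 ms stimulus-onset asynchrony.  Imagery vividness
is measured with a 16-item questionnaire (VVIQ) administered twice
(eyes open / eyes closed), each item rated 1-5, for a summed total in
[32, 160].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StimulusSet",
    "DesignSpec",
    "TrialPlan",
    "VviqForm",
    "BehaviouralRecord",
    "enumerate_block_sequences",
    "allocate_targets",
    "build_pattern_stream",
    "score_vviq",
    "summarize_behaviour",
    "trial_table",
    "mirrored_id",
]

#: variant tags of each target image shown in the pattern-estimator streams
PATTERN_VARIANTS = ("original", "flipped", "inverted", "blurred")


def mirrored_id(stimulus_id: str) -> str:
    """Response-screen id of the horizontally mirrored version of a target."""
    return stimulus_id + "_mirror"


@dataclass(frozen=True)
class StimulusSet:
    """The four target stimuli plus the images filling the rapid streams.

    ``extra_images`` counts additional same-category filler images (other
    faces / other places) so that targets x variants + fillers reaches the
    configured stream size: 4 targets x 4 variants + 2 x 20 fillers = 56.
    """

    categories: tuple[str, str] = ("face", "place")
    exemplars_per_category: int = 2
    pattern_variants: tuple[str, ...] = PATTERN_VARIANTS
    extra_images_per_category: int = 20

    def __post_init__(self) -> None:
        if len(self.categories) != 2 or self.exemplars_per_category != 2:
            raise ValueError("design requires 2 categories x 2 exemplars")

    @property
    def target_ids(self) -> list[str]:
        """The 4 target stimulus ids, ordered by category then exemplar."""
        return [
            f"{cat}{i + 1}"
            for cat in self.categories
            for i in range(self.exemplars_per_category)
        ]

    def category_of(self, stimulus_id: str) -> str:
        for cat in self.categories:
            if stimulus_id.startswith(cat):
                return cat
        raise KeyError(f"unknown stimulus id: {stimulus_id!r}")

    def exemplar_of(self, target_id: str) -> int:
        """0-based exemplar index of a target id within its category."""
        cat = self.category_of(target_id)
        return int(target_id[len(cat):].split("_")[0]) - 1

    def pattern_images(self) -> pd.DataFrame:
        """All stream images: columns image_id, category, exemplar, variant.

        ``exemplar`` is the exemplar index for target-derived variants and
        -1 for category fillers.
        """
        rows = []
        for cat in self.categories:
            for ex in range(self.exemplars_per_category):
                for var in self.pattern_variants:
                    tid = f"{cat}{ex + 1}"
                    iid = tid if var == "original" else f"{tid}_{var}"
                    rows.append((iid, cat, ex, var))
            for k in range(self.extra_images_per_category):
                rows.append((f"{cat}_other{k + 1}", cat, -1, "filler"))
        return pd.DataFrame(
            rows, columns=["image_id", "category", "exemplar", "variant"]
        )

    @property
    def n_pattern_images(self) -> int:
        n_targets = len(self.categories) * self.exemplars_per_category
        return n_targets * len(self.pattern_variants) + len(
            self.categories
        ) * self.extra_images_per_category


@dataclass(frozen=True)
class DesignSpec:
    """Full experimental timing.

    Defaults reproduce the study conditions: 4 blocks of 24 imagery
    sequences (all orderings of the 4 targets, 1500 ms per image), each
    block preceded by 5 streams of 56 images at 200 ms SOA; EEG recorded
    at 1000 Hz from 64 channels and analysed at 250 Hz in [-300, +1500) ms
    epochs.
    """

    n_blocks: int = 4
    sequences_per_block: int = 24
    stim_duration_ms: float = 1500.0
    fixation_ms: float = 1000.0
    imagery_screen_ms: float = 3000.0
    stream_count_per_block: int = 5
    stream_length: int = 56
    stream_soa_ms: float = 200.0
    epoch_window_ms: tuple[float, float] = (-300.0, 1500.0)
    record_fs_hz: float = 1000.0
    analysis_fs_hz: float = 250.0
    n_channels: int = 64
    n_stimuli: int = 4

    def __post_init__(self) -> None:
        if self.sequences_per_block != math.factorial(self.n_stimuli):
            raise ValueError(
                "sequences_per_block must equal n_stimuli! for a fully "
                f"counterbalanced block (got {self.sequences_per_block}, "
                f"expected {math.factorial(self.n_stimuli)})"
            )
        if not self.epoch_window_ms[0] < 0 < self.epoch_window_ms[1]:
            raise ValueError("epoch window must straddle the alignment event")

    @property
    def stream_duration_ms(self) -> float:
        return self.stream_length * self.stream_soa_ms


@dataclass(frozen=True)
class TrialPlan:
    """One imagery trial: a 4-image sequence and its retro-cued target."""

    block: int
    trial: int
    sequence: tuple[str, ...]
    target_position: int  # 1-based serial position of the target
    target_id: str

    def __post_init__(self) -> None:
        if self.sequence[self.target_position - 1] != self.target_id:
            raise ValueError("target_id must equal sequence[target_position]")


@dataclass(frozen=True)
class VviqForm:
    """One subject's VVIQ: 16 items rated 1-5, eyes open and eyes closed."""

    eyes_open: tuple[int, ...]
    eyes_closed: tuple[int, ...]
    n_items: int = 16

    def __post_init__(self) -> None:
        for ratings in (self.eyes_open, self.eyes_closed):
            if len(ratings) != self.n_items:
                raise ValueError(f"each administration needs {self.n_items} items")
            for r in ratings:
                if not (1 <= int(r) <= 5) or int(r) != r:
                    raise ValueError(f"ratings must be integers in [1, 5], got {r!r}")


@dataclass(frozen=True)
class BehaviouralRecord:
    """Response-screen choice and cue-to-click reaction time for one trial."""

    trial: TrialPlan
    response_id: str
    rt_cue_to_click_s: float

    def __post_init__(self) -> None:
        if self.rt_cue_to_click_s < 0:
            raise ValueError("reaction time must be non-negative")

    @property
    def correct(self) -> bool:
        return self.response_id == self.trial.target_id

    @property
    def mirrored_target(self) -> bool:
        return self.response_id == mirrored_id(self.trial.target_id)


def enumerate_block_sequences(
    n_stimuli: int, stimulus_ids: Sequence[str] | None = None
) -> list[tuple[str, ...]]:
    """All n! orderings of the stimuli, lexicographically sorted.

    A fully counterbalanced block shows every ordering exactly once
    (24 sequences for 4 stimuli).
    """
    if n_stimuli < 1:
        raise ValueError("n_stimuli must be >= 1")
    if stimulus_ids is None:
        stimulus_ids = [f"s{i + 1}" for i in range(n_stimuli)]
    elif len(stimulus_ids) != n_stimuli:
        raise ValueError("stimulus_ids length must equal n_stimuli")
    return [tuple(p) for p in permutations(sorted(stimulus_ids))]


def allocate_targets(
    orderings: Sequence[tuple[str, ...]],
    n_blocks: int,
    rng: np.random.Generator,
) -> list[TrialPlan]:
    """Assign a target position to every (block, ordering) pair.

    Counterbalancing is a Latin square over blocks: each ordering receives a
    cyclically shifted position schedule, so within a block every ordering
    appears once, across blocks an ordering's target differs in every block,
    and every (stimulus, serial position) pair is targeted equally often
    (6 times for the 4-stimulus, 4-block design).  The random shift per
    ordering and the trial order within each block are drawn from ``rng``.
    """
    n_pos = len(orderings[0])
    if any(len(o) != n_pos for o in orderings):
        raise ValueError("all orderings must have the same length")
    if n_blocks < 1 or (n_blocks % n_pos != 0 and n_pos % n_blocks != 0):
        raise ValueError(
            f"cannot balance {n_pos} target positions over {n_blocks} blocks"
        )
    shifts = rng.integers(0, n_pos, size=len(orderings))
    plans: list[TrialPlan] = []
    for block in range(n_blocks):
        order = rng.permutation(len(orderings))
        for trial, idx in enumerate(order):
            seq = orderings[idx]
            pos = int((shifts[idx] + block) % n_pos)  # 0-based
            plans.append(
                TrialPlan(
                    block=block,
                    trial=trial,
                    sequence=tuple(seq),
                    target_position=pos + 1,
                    target_id=seq[pos],
                )
            )
    return plans


def build_pattern_stream(
    stimulus_set: StimulusSet,
    rng: np.random.Generator,
    design: DesignSpec | None = None,
) -> pd.DataFrame:
    """One rapid stream: every image exactly once, random order, fixed SOA.

    Returns a frame with columns image_id, category, exemplar, variant,
    order, onset_ms.  With the default 56-image set at 200 ms SOA the last
    onset is 11000 ms and the stream lasts 11.2 s.
    """
    design = design or DesignSpec()
    images = stimulus_set.pattern_images()
    if len(images) != design.stream_length:
        raise ValueError(
            f"stimulus set has {len(images)} images but the stream "
            f"length is {design.stream_length}"
        )
    stream = images.iloc[rng.permutation(len(images))].reset_index(drop=True)
    stream["order"] = np.arange(len(stream))
    stream["onset_ms"] = stream["order"] * design.stream_soa_ms
    return stream


def score_vviq(form: VviqForm) -> dict[str, int]:
    """Summed vividness scores: per-administration subtotals and the total.

    With 32 items rated 1-5 the attainable total spans [32, 160]; higher
    means more vivid imagery (reversed-scale convention).
    """
    eyes_open = int(sum(form.eyes_open))
    eyes_closed = int(sum(form.eyes_closed))
    return {
        "eyes_open": eyes_open,
        "eyes_closed": eyes_closed,
        "total": eyes_open + eyes_closed,
    }


def summarize_behaviour(
    records: Sequence[BehaviouralRecord], rt_bin_s: float = 0.5
) -> dict:
    """Accuracy, mirror-error composition and RT summary of a session.

    Returns fraction correct, the fraction of *errors* that chose the
    mirrored target, the fraction of *all* responses that chose the
    mirrored target, RT mean/SD, and RT histogram counts in right-open
    ``rt_bin_s``-wide bins starting at 0.
    """
    if len(records) == 0:
        raise ValueError("no behavioural records")
    correct = np.array([r.correct for r in records])
    mirrored = np.array([r.mirrored_target for r in records])
    rts = np.array([r.rt_cue_to_click_s for r in records], dtype=float)
    n_err = int((~correct).sum())
    edges = np.arange(0.0, rts.max() + 2 * rt_bin_s, rt_bin_s)
    counts, _ = np.histogram(rts, bins=edges)
    return {
        "n_trials": len(records),
        "accuracy": float(correct.mean()),
        "mirrored_fraction_of_errors": float(mirrored.sum() / n_err) if n_err else 0.0,
        "mirrored_fraction_of_responses": float(mirrored.mean()),
        "rt_mean_s": float(rts.mean()),
        "rt_sd_s": float(rts.std(ddof=1)) if len(rts) > 1 else 0.0,
        "rt_hist_edges_s": edges,
        "rt_hist_counts": counts,
    }


def trial_table(plans: Sequence[TrialPlan]) -> pd.DataFrame:
    """Trial plans as a flat table (block, trial, seq_pos1..4, target)."""
    n_pos = len(plans[0].sequence)
    rows = []
    for p in plans:
        row = {"block": p.block, "trial": p.trial}
        row.update({f"seq_pos{i + 1}": s for i, s in enumerate(p.sequence)})
        row["target_position"] = p.target_position
        row["target_id"] = p.target_id
        rows.append(row)
    cols = (
        ["block", "trial"]
        + [f"seq_pos{i + 1}" for i in range(n_pos)]
        + ["target_position", "target_id"]
    )
    return pd.DataFrame(rows, columns=cols)
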