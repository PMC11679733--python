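"""Affective-storm stimulus design on the valence-arousal circumplex.

The circumplex divides affect into four quadrants: A "Stress" (high
arousal, negative valence), B "Engagement" (high arousal, positive
valence), C "Boredom" (low arousal, negative valence) and D "Relaxation"
(low arousal, positive valence). An *affective storm* is a sequence of 13
image blocks whose 12 between-block transitions traverse every ordered
pair of distinct quadrants exactly once. Such a sequence is an Eulerian
circuit of the complete directed graph on {A, B, C, D} (every vertex has
in-degree = out-degree = 3, so a circuit exists and necessarily starts and
ends on the same quadrant); it is built with Hierholzer's algorithm over a
seed-shuffled edge order.

Images carry 1-9 Self-Assessment-Manikin valence/arousal norms and map to
a quadrant only when both ratings are decisive: above 6 for the high pole,
below 4 for the low pole (strict inequalities; mid-scale images map to no
quadrant). Each block shows 12 images for 10 s each: 156 images, 1560 s of
stimulation, framed by 2-min pre (T0) and post (T1) baselines. Images are
drawn without replacement across the whole run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, PoolExhaustedError

QUADRANT_LABELS = ("A", "B", "C", "D")

#: label -> (arousal pole, valence pole, colloquial name)
QUADRANT_POLES = {
    "A": ("high", "negative", "Stress"),
    "B": ("high", "positive", "Engagement"),
    "C": ("low", "negative", "Boredom"),
    "D": ("low", "positive", "Relaxation"),
}

HIGH_THRESHOLD = 6.0  # pole decisive only strictly above
LOW_THRESHOLD = 4.0  # pole decisive only strictly below

IMAGES_PER_BLOCK = 12
IMAGE_DURATION_S = 10.0
BASELINE_S = 120.0


@dataclass(frozen=True)
class Quadrant:
    label: str
    arousal_pole: str
    valence_pole: str
    name: str


QUADRANTS = {
    lab: Quadrant(lab, *QUADRANT_POLES[lab]) for lab in QUADRANT_LABELS
}


@dataclass(frozen=True)
class ImageMeta:
    """Image metadata with SAM valence/arousal norms (1-9)."""

    image_id: str
    valence: float
    arousal: float

    def __post_init__(self) -> None:
        for name in ("valence", "arousal"):
            v = getattr(self, name)
            if not (1.0 <= v <= 9.0):
                raise InvalidParameterError(f"{name}={v} outside SAM range [1, 9]")


def quadrant_of(img: ImageMeta) -> Quadrant | None:
    """Map an image to its circumplex quadrant, or None if not decisive.

    High arousal/positive valence require ratings strictly above 6; low
    arousal/negative valence strictly below 4.
    """
    if img.arousal > HIGH_THRESHOLD:
        if img.valence < LOW_THRESHOLD:
            return QUADRANTS["A"]
        if img.valence > HIGH_THRESHOLD:
            return QUADRANTS["B"]
    elif img.arousal < LOW_THRESHOLD:
        if img.valence < LOW_THRESHOLD:
            return QUADRANTS["C"]
        if img.valence > HIGH_THRESHOLD:
            return QUADRANTS["D"]
    return None


@dataclass
class StormSequence:
    """Ordered quadrant labels for the 13 blocks; first equals last."""

    blocks: list[str]
    seed: int

    def __post_init__(self) -> None:
        if len(self.blocks) != 13:
            raise InvalidParameterError("a storm sequence has exactly 13 blocks")
        transitions = self.transitions()
        if len(set(transitions)) != 12 or any(a == b for a, b in transitions):
            raise InvalidParameterError(
                "the 12 transitions must cover every ordered quadrant pair once"
            )

    def transitions(self) -> list[tuple[str, str]]:
        return list(zip(self.blocks[:-1], self.blocks[1:]))


def build_block_sequence(seed: int) -> StormSequence:
    """Eulerian circuit over the complete directed quadrant graph.

    Hierholzer's algorithm with a seed-shuffled adjacency order; every
    ordered pair of distinct quadrants appears as a transition exactly once
    and the circuit closes on its starting quadrant.
    """
    rng = np.random.default_rng(seed)
    adjacency = {}
    for v in QUADRANT_LABELS:
        succ = [w for w in QUADRANT_LABELS if w != v]
        rng.shuffle(succ)
        adjacency[v] = succ
    start = QUADRANT_LABELS[int(rng.integers(len(QUADRANT_LABELS)))]
    stack = [start]
    circuit: list[str] = []
    while stack:
        v = stack[-1]
        if adjacency[v]:
            stack.append(adjacency[v].pop())
        else:
            circuit.append(stack.pop())
    circuit.reverse()
    return StormSequence(blocks=circuit, seed=seed)


@dataclass(frozen=True)
class StimulusEvent:
    onset_s: float
    duration_s: float
    block_index: int
    image_id: str
    quadrant: str


@dataclass
class Schedule:
    """Timed image events plus baseline markers (onsets relative to stimulus start)."""

    events: list[StimulusEvent]
    sequence: StormSequence
    baseline_pre_s: float = BASELINE_S
    baseline_post_s: float = BASELINE_S
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.events) != 13 * IMAGES_PER_BLOCK:
            raise InvalidParameterError("a full schedule has 156 events")

    @property
    def total_stimulus_s(self) -> float:
        return sum(e.duration_s for e in self.events)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "onset_s": e.onset_s,
                    "duration_s": e.duration_s,
                    "block": e.block_index,
                    "quadrant": e.quadrant,
                    "image_id": e.image_id,
                }
                for e in self.events
            ]
        )


def assemble_schedule(
    seq: StormSequence,
    pool: list[ImageMeta],
    images_per_block: int = IMAGES_PER_BLOCK,
    image_duration: float = IMAGE_DURATION_S,
    seed: int = 0,
) -> Schedule:
    """Fill the block sequence with quadrant-matched images.

    Sampling is without replacement across the entire run; a quadrant whose
    eligible pool cannot cover all its blocks raises
    :class:`PoolExhaustedError`.
    """
    rng = np.random.default_rng(seed)
    eligible: dict[str, list[ImageMeta]] = {lab: [] for lab in QUADRANT_LABELS}
    for img in pool:
        q = quadrant_of(img)
        if q is not None:
            eligible[q.label].append(img)
    needed = {lab: seq.blocks.count(lab) * images_per_block for lab in QUADRANT_LABELS}
    for lab in QUADRANT_LABELS:
        if len(eligible[lab]) < needed[lab]:
            raise PoolExhaustedError(
                f"quadrant {lab}: need {needed[lab]} images, pool has "
                f"{len(eligible[lab])}"
            )
    for lab in QUADRANT_LABELS:
        order = rng.permutation(len(eligible[lab]))
        eligible[lab] = [eligible[lab][i] for i in order]
    events = []
    onset = 0.0
    for b, lab in enumerate(seq.blocks):
        for _ in range(images_per_block):
            img = eligible[lab].pop()
            events.append(
                StimulusEvent(
                    onset_s=onset,
                    duration_s=image_duration,
                    block_index=b,
                    image_id=img.image_id,
                    quadrant=lab,
                )
            )
            onset += image_duration
    return Schedule(events=events, sequence=seq, seed=seed)


def synth_image_pool(n_per_quadrant: int, seed: int) -> list[ImageMeta]:
    """Synthetic stand-in for a normatively rated image pool.

    Ratings are drawn uniformly inside each quadrant's open corner region
    (margin 0.05 off the thresholds), so every generated image maps back to
    its intended quadrant.
    """
    if n_per_quadrant < 1:
        raise InvalidParameterError("n_per_quadrant must be >= 1")
    rng = np.random.default_rng(seed)
    margin = 0.05
    ranges = {
        "high": (HIGH_THRESHOLD + margin, 9.0),
        "low": (1.0, LOW_THRESHOLD - margin),
    }
    pool = []
    for lab in QUADRANT_LABELS:
        a_pole, v_pole, _ = QUADRANT_POLES[lab]
        a_lo, a_hi = ranges["high"] if a_pole == "high" else ranges["low"]
        v_lo, v_hi = ranges["high"] if v_pole == "positive" else ranges["low"]
        for i in range(n_per_quadrant):
            img = ImageMeta(
                image_id=f"{lab}-{i:03d}",
                valence=float(rng.uniform(v_lo, v_hi)),
                arousal=float(rng.uniform(a_lo, a_hi)),
            )
            pool.append(img)
    return pool


# ---------------------------------------------------------------------------
# file I/O


def write_schedule_csv(schedule: Schedule, path) -> None:
    schedule.to_frame().to_csv(path, index=False)


def write_schedule_json(schedule: Schedule, path) -> None:
    payload = {
        "seed": schedule.seed,
        "blocks": schedule.sequence.blocks,
        "baseline_pre_s": schedule.baseline_pre_s,
        "baseline_post_s": schedule.baseline_post_s,
        "total_stimulus_s": schedule.total_stimulus_s,
        "events": schedule.to_frame().to_dict(orient="records"),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def write_pool_csv(pool: list[ImageMeta], path) -> None:
    pd.DataFrame(
        [
            {"image_id": im.image_id, "valence": im.valence, "arousal": im.arousal}
            for im in pool
        ]
    ).to_csv(path, index=False)


def read_pool_csv(path) -> list[ImageMeta]:
    df = pd.read_csv(path)
    return [
        ImageMeta(image_id=str(r.image_id), valence=float(r.valence),
                  arousal=float(r.arousal))
        for r in df.itertuples()
    ]
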