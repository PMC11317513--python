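"""Stimulus protocol generation.

Two experimental protocols are generated here:

* the SEQ-SIM protocol: 2-by-2 groups of square apertures in two diagonal
  quadrants, shown either sequentially (one square at a time, random order,
  33-ms inter-square interval) or simultaneously (all four at once), in two
  presentation timings (0.2 s / 1 s per square) and two sizes (2 deg / 4 deg),
  arranged in 8-s blocks separated by 12-s blanks;
* a retinotopic-mapping protocol: a bar aperture sweeping a circular field
  in 12 discrete 2-s steps along four orientations, both directions each.

The canonical stimulus representation is an *event list*: each event is an
axis-aligned rectangle with an on/off time in milliseconds.  This keeps exact
millisecond timing without materialising a 1-ms movie; rasterization to a
pixel grid is provided for oracles and for the bar protocol.

Coordinate convention: degrees of visual angle, fixation at the origin,
x rightward, y upward.  Rectangles are closed intervals; a pixel belongs to
a rectangle iff its *center* lies inside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Rect",
    "SquareLayout",
    "Condition",
    "ALL_CONDITIONS",
    "RunDesign",
    "SquareEvent",
    "Block",
    "BlockSchedule",
    "StimulusSequence",
    "GridSpec",
    "build_square_layout",
    "generate_seqsim_run",
    "generate_seqsim_pair",
    "count_transients",
    "on_time_per_square",
    "rasterize",
    "RetinotopyDesign",
    "RetinotopyStimulus",
    "generate_retinotopy_run",
]

# Protocol constants (milliseconds unless suffixed otherwise).
ISI_MS = 33
SHORT_MS = 200
LONG_MS = 1000
BLOCK_DUR_S = 8
BLANK_DUR_S = 12
COUNTDOWN_S = 6
BLOCK_PERIOD_S = BLOCK_DUR_S + BLANK_DUR_S
N_BLOCKS_PER_RUN = 16
RUN_DUR_S = BLANK_DUR_S + N_BLOCKS_PER_RUN * BLOCK_PERIOD_S  # 332 s, countdown trimmed
GAP_DEG = 0.82
SMALL_DEG = 2.0
BIG_DEG = 4.0
QUADRANT_CENTERS = ((5.0, 5.0), (-5.0, -5.0))
FIELD_OF_VIEW_DEG = 24.0


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Rect:
    """Closed axis-aligned rectangle in degrees of visual angle."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.x_max < self.x_min or self.y_max < self.y_min:
            raise ValueError(f"degenerate rectangle bounds: {self}")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def key(self) -> tuple[float, float, float, float]:
        """Coordinates-only identity, used for overlap caching and pooling."""
        return (self.x_min, self.x_max, self.y_min, self.y_max)

    def contains(self, x: float, y: float) -> bool:
        return self.x_min <= x <= self.x_max and self.y_min <= y <= self.y_max


@dataclass(frozen=True)
class SquareLayout:
    """A 2-by-2 group of congruent squares in one quadrant.

    Squares are indexed row-major from the low-x/low-y corner:
    0 = (low x, low y), 1 = (high x, low y), 2 = (low x, high y),
    3 = (high x, high y).
    """

    quadrant: str
    size_deg: float
    gap_deg: float
    center: tuple[float, float]
    squares: tuple[Rect, Rect, Rect, Rect]

    @property
    def bounding_box(self) -> Rect:
        xs = [s.x_min for s in self.squares] + [s.x_max for s in self.squares]
        ys = [s.y_min for s in self.squares] + [s.y_max for s in self.squares]
        return Rect(min(xs), max(xs), min(ys), max(ys), label=f"{self.quadrant}-bbox")

    @property
    def eccentricity_deg(self) -> float:
        return math.hypot(*self.center)


def _quadrant_name(cx: float, cy: float) -> str:
    if cx > 0:
        return "upper_right" if cy > 0 else "lower_right"
    return "upper_left" if cy > 0 else "lower_left"


def build_square_layout(
    size_deg: float,
    gap_deg: float = GAP_DEG,
    quadrant_center: tuple[float, float] = (5.0, 5.0),
) -> SquareLayout:
    """Build the 2-by-2 square group for one quadrant.

    The four squares are placed symmetrically around ``quadrant_center`` with
    inner edges at ``center +- gap/2`` and outer edges at
    ``center +- (size + gap/2)``, so the group bounding box has side
    ``2*size + gap``.

    Raises
    ------
    ValueError
        If ``size_deg`` is not positive, ``gap_deg`` is negative, or the
        center lies on a cardinal axis (the quadrant would be ambiguous).
    """
    if size_deg <= 0:
        raise ValueError(f"size_deg must be positive, got {size_deg}")
    if gap_deg < 0:
        raise ValueError(f"gap_deg must be non-negative, got {gap_deg}")
    cx, cy = float(quadrant_center[0]), float(quadrant_center[1])
    if cx == 0 or cy == 0:
        raise ValueError(f"quadrant center {quadrant_center} lies on an axis")

    hg = gap_deg / 2.0
    x_edges = ((cx - size_deg - hg, cx - hg), (cx + hg, cx + size_deg + hg))
    y_edges = ((cy - size_deg - hg, cy - hg), (cy + hg, cy + size_deg + hg))
    quadrant = _quadrant_name(cx, cy)
    squares = []
    for iy in (0, 1):
        for ix in (0, 1):
            idx = iy * 2 + ix
            squares.append(
                Rect(
                    x_edges[ix][0],
                    x_edges[ix][1],
                    y_edges[iy][0],
                    y_edges[iy][1],
                    label=f"{quadrant}:{size_deg:g}deg:{idx}",
                )
            )
    return SquareLayout(
        quadrant=quadrant,
        size_deg=size_deg,
        gap_deg=gap_deg,
        center=(cx, cy),
        squares=tuple(squares),
    )


# ---------------------------------------------------------------------------
# conditions and run design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Condition:
    """One of the 8 cells of the {SEQ, SIM} x {short, long} x {small, big} design."""

    seq_type: str  # "SEQ" or "SIM"
    timing: str    # "short" (0.2 s) or "long" (1 s)
    size: str      # "small" (2 deg) or "big" (4 deg)

    def __post_init__(self) -> None:
        if self.seq_type not in ("SEQ", "SIM"):
            raise ValueError(f"bad seq_type {self.seq_type!r}")
        if self.timing not in ("short", "long"):
            raise ValueError(f"bad timing {self.timing!r}")
        if self.size not in ("small", "big"):
            raise ValueError(f"bad size {self.size!r}")

    @property
    def label(self) -> str:
        return f"{self.seq_type}-{self.timing}-{self.size}"

    @property
    def pair_label(self) -> str:
        """Label of the matched SEQ/SIM pair this condition belongs to."""
        return f"{self.timing}-{self.size}"

    @property
    def dur_ms(self) -> int:
        return SHORT_MS if self.timing == "short" else LONG_MS

    @property
    def size_deg(self) -> float:
        return SMALL_DEG if self.size == "small" else BIG_DEG

    @property
    def n_trials(self) -> int:
        return 8 if self.timing == "short" else 2


ALL_CONDITIONS: tuple[Condition, ...] = tuple(
    Condition(s, t, z)
    for s in ("SEQ", "SIM")
    for t in ("short", "long")
    for z in ("small", "big")
)
PAIR_LABELS: tuple[str, ...] = ("short-small", "short-big", "long-small", "long-big")


@dataclass(frozen=True)
class RunDesign:
    """Parameters of one SEQ-SIM run.

    ``onset_matched`` is a testing mode in which (a) the per-trial square
    order is the identity instead of a random permutation, (b) SIM trial
    onsets are locked to the corresponding SEQ trial onsets, and (c) the
    SIM short-trial randomisation is disabled.  In this mode the first
    square of each quadrant has identical on/off times in the SEQ and SIM
    members of every condition pair, which is the construction used for
    linear-summation null tests.
    """

    seed: int = 0
    blocks_per_run: int = N_BLOCKS_PER_RUN
    block_dur_s: float = BLOCK_DUR_S
    blank_dur_s: float = BLANK_DUR_S
    countdown_s: float = COUNTDOWN_S
    isi_ms: int = ISI_MS
    sim_long_second_trial_onset_s: float = 4.0
    tr_s: float = 1.0
    gap_deg: float = GAP_DEG
    quadrant_centers: tuple[tuple[float, float], ...] = QUADRANT_CENTERS
    onset_matched: bool = False

    def __post_init__(self) -> None:
        if self.blocks_per_run != 2 * len(ALL_CONDITIONS):
            raise ValueError(
                "blocks_per_run must be twice the number of conditions "
                f"({2 * len(ALL_CONDITIONS)}), got {self.blocks_per_run}"
            )
        if self.block_dur_s <= 0 or self.blank_dur_s < 0:
            raise ValueError("block/blank durations must be positive")

    @property
    def block_period_s(self) -> float:
        return self.block_dur_s + self.blank_dur_s

    @property
    def run_dur_s(self) -> float:
        """Analyzed run duration: the leading countdown is trimmed."""
        return self.blank_dur_s + self.blocks_per_run * self.block_period_s

    def seq_trial_len_ms(self, condition: Condition) -> int:
        return 4 * condition.dur_ms + 3 * self.isi_ms

    def layouts(self) -> dict[tuple[str, str], SquareLayout]:
        """All four layouts keyed by (size label, quadrant name)."""
        out: dict[tuple[str, str], SquareLayout] = {}
        for size_label, size_deg in (("small", SMALL_DEG), ("big", BIG_DEG)):
            for center in self.quadrant_centers:
                lay = build_square_layout(size_deg, self.gap_deg, center)
                out[(size_label, lay.quadrant)] = lay
        return out


@dataclass(frozen=True)
class SquareEvent:
    """A single square presentation: quadrant, square index, rect, on/off ms (run time)."""

    quadrant: str
    square_index: int
    rect: Rect
    on_ms: int
    off_ms: int

    @property
    def duration_ms(self) -> int:
        return self.off_ms - self.on_ms


@dataclass(frozen=True)
class Block:
    condition: Condition
    onset_s: float
    offset_s: float
    events: tuple[SquareEvent, ...]

    @property
    def onset_ms(self) -> int:
        return int(round(self.onset_s * 1000))


@dataclass(frozen=True)
class BlockSchedule:
    blocks: tuple[Block, ...]
    run_dur_s: float
    tr_s: float

    def __len__(self) -> int:
        return len(self.blocks)

    def to_records(self) -> list[dict]:
        rows = []
        for i, b in enumerate(self.blocks):
            for ev in b.events:
                rows.append(
                    {
                        "block": i,
                        "condition": b.condition.label,
                        "quadrant": ev.quadrant,
                        "square": ev.square_index,
                        "rect": ev.rect.label,
                        "on_ms": ev.on_ms,
                        "off_ms": ev.off_ms,
                    }
                )
        return rows


@dataclass(frozen=True)
class StimulusSequence:
    """Event-list stimulus: rectangles with on/off times at 1-ms resolution."""

    events: tuple[tuple[Rect, int, int], ...]
    duration_ms: int
    field_of_view_deg: float = FIELD_OF_VIEW_DEG

    def __post_init__(self) -> None:
        for rect, on, off in self.events:
            if not (0 <= on <= off <= self.duration_ms):
                raise ValueError(
                    f"event [{on}, {off}] ms outside run [0, {self.duration_ms}] ms"
                )

    def clipped(self, t0_ms: int, t1_ms: int) -> "StimulusSequence":
        """Events intersected with [t0, t1), re-referenced to t0."""
        ev = []
        for rect, on, off in self.events:
            a, b = max(on, t0_ms), min(off, t1_ms)
            if a < b:
                ev.append((rect, a - t0_ms, b - t0_ms))
        return StimulusSequence(tuple(ev), t1_ms - t0_ms, self.field_of_view_deg)


def _seq_block_events(
    design: RunDesign,
    condition: Condition,
    layout: SquareLayout,
    block_on_ms: int,
    rng: np.random.Generator,
) -> list[SquareEvent]:
    dur = condition.dur_ms
    trial_len = design.seq_trial_len_ms(condition)
    events = []
    for j in range(condition.n_trials):
        trial_on = block_on_ms + j * (trial_len + design.isi_ms)
        if design.onset_matched:
            order = np.arange(4)
        else:
            order = rng.permutation(4)
        for pos, sq in enumerate(order):
            on = trial_on + pos * (dur + design.isi_ms)
            events.append(
                SquareEvent(layout.quadrant, int(sq), layout.squares[int(sq)], on, on + dur)
            )
    return events


def _sim_block_events(
    design: RunDesign,
    condition: Condition,
    layout: SquareLayout,
    block_on_ms: int,
    rng: np.random.Generator,
) -> list[SquareEvent]:
    dur = condition.dur_ms
    trial_len = design.seq_trial_len_ms(condition)
    onsets: list[int] = []
    if condition.timing == "long":
        second = (
            trial_len + design.isi_ms
            if design.onset_matched
            else int(round(design.sim_long_second_trial_onset_s * 1000))
        )
        onsets = [block_on_ms, block_on_ms + second]
    else:
        slot = trial_len + design.isi_ms if design.onset_matched else 1000
        for j in range(condition.n_trials):
            slot_on = block_on_ms + j * slot
            if j == 0 or design.onset_matched:
                onsets.append(slot_on)
            else:
                # stimulus onset drawn uniformly within the 1-s trial slot,
                # constrained so the stimulus ends inside the slot
                onsets.append(slot_on + int(rng.integers(0, slot - dur + 1)))
    events = []
    for on in onsets:
        for sq in range(4):
            events.append(
                SquareEvent(layout.quadrant, sq, layout.squares[sq], on, on + dur)
            )
    return events


def generate_seqsim_run(
    design: RunDesign, run_index: int = 0
) -> tuple[StimulusSequence, BlockSchedule]:
    """Generate one SEQ-SIM run.

    The run timeline is the analyzed timeline: the countdown has been
    trimmed, so the run starts with a 12-s blank and the k-th block onset is
    at ``blank + k * (block + blank)`` seconds.  The SEQ long blocks slightly
    exceed the nominal 8-s block (two back-to-back 4.099-s trials); the
    generator validates that every event ends well before the next block.

    Reproducible: the same ``(design.seed, run_index)`` gives a byte-identical
    schedule; the two unique runs of a session use run_index 0 and 1 and
    differ in block order and per-trial randomisation.
    """
    rng = np.random.default_rng([int(design.seed), int(run_index)])
    conditions = list(ALL_CONDITIONS) * 2
    order = rng.permutation(len(conditions))
    layouts = design.layouts()

    blocks: list[Block] = []
    period_ms = int(round(design.block_period_s * 1000))
    first_on_ms = int(round(design.blank_dur_s * 1000))
    for k, ci in enumerate(order):
        condition = conditions[int(ci)]
        block_on = first_on_ms + k * period_ms
        events: list[SquareEvent] = []
        for center in design.quadrant_centers:
            layout = layouts[(condition.size, _quadrant_name(*center))]
            if condition.seq_type == "SEQ":
                events.extend(_seq_block_events(design, condition, layout, block_on, rng))
            else:
                events.extend(_sim_block_events(design, condition, layout, block_on, rng))
        limit = block_on + period_ms - int(design.blank_dur_s * 1000 / 2)
        for ev in events:
            if ev.off_ms > limit:
                raise ValueError(
                    f"square event ends at {ev.off_ms} ms, beyond its block window "
                    f"(block onset {block_on} ms, limit {limit} ms)"
                )
        blocks.append(
            Block(
                condition=condition,
                onset_s=block_on / 1000.0,
                offset_s=block_on / 1000.0 + design.block_dur_s,
                events=tuple(sorted(events, key=lambda e: (e.on_ms, e.quadrant, e.square_index))),
            )
        )

    duration_ms = int(round(design.run_dur_s * 1000))
    seq_events = tuple(
        (ev.rect, ev.on_ms, ev.off_ms) for b in blocks for ev in b.events
    )
    sequence = StimulusSequence(seq_events, duration_ms)
    schedule = BlockSchedule(tuple(blocks), design.run_dur_s, design.tr_s)
    return sequence, schedule


def generate_seqsim_pair(
    design: RunDesign,
) -> tuple[tuple[StimulusSequence, BlockSchedule], tuple[StimulusSequence, BlockSchedule]]:
    """The two unique runs of a session (run indices 0 and 1)."""
    return generate_seqsim_run(design, 0), generate_seqsim_run(design, 1)


# ---------------------------------------------------------------------------
# schedule queries
# ---------------------------------------------------------------------------

def _merged_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    ivs = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for a, b in ivs:
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def count_transients(block: Block, footprint: Iterable[Rect]) -> int:
    """Count on/off switching events of the pooled drive over ``footprint``.

    The pooled drive is the union of the footprint rectangles' active
    intervals within the block; every merged interval contributes one onset
    and one offset.
    """
    keys = {r.key for r in footprint}
    if not keys:
        raise ValueError("footprint must contain at least one rectangle")
    intervals = [
        (ev.on_ms, ev.off_ms) for ev in block.events if ev.rect.key in keys
    ]
    return 2 * len(_merged_intervals(intervals))


def on_time_per_square(block: Block) -> dict[tuple[float, float, float, float], int]:
    """Total stimulus-on milliseconds per rectangle within a block."""
    totals: dict[tuple[float, float, float, float], int] = {}
    for ev in block.events:
        totals[ev.rect.key] = totals.get(ev.rect.key, 0) + ev.duration_ms
    return totals


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Pixel grid over a square window; pixel centers decide membership."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float
    pixel_deg: float

    def __post_init__(self) -> None:
        if self.pixel_deg <= 0:
            raise ValueError("pixel_deg must be positive")

    @property
    def xs(self) -> np.ndarray:
        n = int(round((self.x_max - self.x_min) / self.pixel_deg))
        return self.x_min + (np.arange(n) + 0.5) * self.pixel_deg

    @property
    def ys(self) -> np.ndarray:
        n = int(round((self.y_max - self.y_min) / self.pixel_deg))
        return self.y_min + (np.arange(n) + 0.5) * self.pixel_deg


def rasterize(
    sequence: StimulusSequence, grid: GridSpec, times_ms: Sequence[int]
) -> np.ndarray:
    """Binary movie (y, x, t) sampled at the given millisecond time points."""
    times = np.asarray(times_ms, dtype=np.int64)
    if times.size and (times.min() < 0 or times.max() >= sequence.duration_ms):
        raise ValueError("requested time slice outside the stimulus duration")
    xs, ys = grid.xs, grid.ys
    out = np.zeros((ys.size, xs.size, times.size), dtype=np.uint8)
    for rect, on, off in sequence.events:
        active = (times >= on) & (times < off)
        if not active.any():
            continue
        xi = (xs >= rect.x_min) & (xs <= rect.x_max)
        yi = (ys >= rect.y_min) & (ys <= rect.y_max)
        out[np.ix_(yi, xi, active)] = 1
    return out


# ---------------------------------------------------------------------------
# retinotopy bar protocol
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RetinotopyDesign:
    aperture_deg: float = FIELD_OF_VIEW_DEG
    bar_width_deg: float = 3.0
    n_steps: int = 12
    step_dur_s: float = 2.0
    orientations_deg: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)

    def __post_init__(self) -> None:
        if self.bar_width_deg > self.aperture_deg:
            raise ValueError("bar wider than aperture")
        if self.n_steps < 1:
            raise ValueError("need at least one bar step")

    @property
    def radius_deg(self) -> float:
        return self.aperture_deg / 2.0


@dataclass(frozen=True)
class RetinotopyStimulus:
    """Bar-aperture movie as a list of (orientation, offset) frames.

    Frame i shows a bar of width ``design.bar_width_deg`` whose axis-normal
    coordinate u = x cos(theta) + y sin(theta) lies within ``offset +- w/2``,
    clipped to the circular aperture.  Each frame lasts ``step_dur_s``.
    """

    design: RetinotopyDesign
    frames: tuple[tuple[float, float], ...]  # (theta_deg, offset_deg)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.design.step_dur_s

    def frame_mask(self, frame_index: int, grid: GridSpec) -> np.ndarray:
        theta_deg, offset = self.frames[frame_index]
        th = math.radians(theta_deg)
        X, Y = np.meshgrid(grid.xs, grid.ys)
        u = X * math.cos(th) + Y * math.sin(th)
        half = self.design.bar_width_deg / 2.0
        inside = (np.abs(u - offset) <= half) & (
            X**2 + Y**2 <= self.design.radius_deg**2
        )
        return inside.astype(np.uint8)

    def rasterize(self, grid: GridSpec) -> np.ndarray:
        """Binary movie (y, x, frame)."""
        out = np.stack(
            [self.frame_mask(i, grid) for i in range(self.n_frames)], axis=-1
        )
        return out


def generate_retinotopy_run(design: RetinotopyDesign = RetinotopyDesign()) -> RetinotopyStimulus:
    """Bar sweeps: for each orientation, a forward and a time-reversed sweep.

    Bar positions partition the aperture diameter into ``n_steps`` equal
    steps; offsets are the step centers.
    """
    R = design.radius_deg
    step = 2 * R / design.n_steps
    offsets = [-R + (i + 0.5) * step for i in range(design.n_steps)]
    frames: list[tuple[float, float]] = []
    for theta in design.orientations_deg:
        frames.extend((theta, o) for o in offsets)
        frames.extend((theta, o) for o in reversed(offsets))
    return RetinotopyStimulus(design=design, frames=tuple(frames))
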