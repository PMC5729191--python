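"""Event schedules for phase-encoded tonotopy and spectral-attention runs.

A run is a discretised traveling-wave design: five frequency bands are
visited once per 64 s cycle in 12.8 s blocks, eight cycles per run,
bracketed by 32 s silent baselines. In the attention conditions two bands
play simultaneously and a verbal prompt ("high"/"low") cues which one to
attend; the randomised control scrambles the prompts so that attention is
aperiodic across the run while the acoustics are unchanged.

Schedules are symbolic (band indices, prompts, repeat structure); no audio
is rendered.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "BAND_CENTERS_HZ",
    "MIN_PAIR_SEPARATION_SEMITONES",
    "FrequencyBand",
    "Block",
    "RunSchedule",
    "ScheduleError",
    "semitone_separation",
    "valid_band_pairs",
    "default_bands",
    "build_run_schedule",
    "validate_schedule",
    "schedule_to_events",
]

#: Center frequencies of the five stimulus bands (Hz).
BAND_CENTERS_HZ = (300.0, 566.0, 1068.0, 2016.0, 3805.0)

#: Minimum separation between simultaneously presented bands (semitones).
MIN_PAIR_SEPARATION_SEMITONES = 14.0

BLOCK_DURATION_S = 12.8
PROMPT_DURATION_S = 0.8
CUE_DURATION_S = 0.8
SLOT_DURATION_S = 0.8
N_SLOTS = 14
N_BANDS = 5
CYCLE_DURATION_S = 64.0
N_CYCLES = 8
BASELINE_S = 32.0
TR_S = 1.0
N_VOLUMES = 584
N_DISCARD = 8

CONDITIONS = ("tonotopy", "attn_stepped", "attn_random")
DIRECTIONS = ("up", "down")


class ScheduleError(ValueError):
    """Raised when a run schedule cannot be constructed or is malformed."""


def semitone_separation(f_low: float, f_high: float) -> float:
    """Separation between two frequencies in semitones, 12*log2(f_high/f_low).

    Raises ValueError for non-positive frequencies or f_high < f_low.
    """
    if f_low <= 0 or f_high <= 0:
        raise ValueError("frequencies must be positive")
    if f_high < f_low:
        raise ValueError("f_high must be >= f_low")
    return 12.0 * math.log2(f_high / f_low)


@dataclass(frozen=True)
class FrequencyBand:
    """One of the five seven-semitone stimulus bands."""

    index: int
    center_hz: float
    pool_width_semitones: float = 7.0

    def __post_init__(self) -> None:
        if not 0 <= self.index < N_BANDS:
            raise ValueError(f"band index {self.index} outside 0..{N_BANDS - 1}")
        if self.center_hz <= 0:
            raise ValueError("center frequency must be positive")


def default_bands() -> list[FrequencyBand]:
    """The five study bands (300, 566, 1068, 2016, 3805 Hz)."""
    return [FrequencyBand(i, f) for i, f in enumerate(BAND_CENTERS_HZ)]


def valid_band_pairs(
    bands: list[FrequencyBand],
    min_sep: float = MIN_PAIR_SEPARATION_SEMITONES,
) -> list[tuple[FrequencyBand, FrequencyBand]]:
    """All unordered band pairs at least `min_sep` semitones apart.

    Returned sorted by (low index, high index). With the study bands and the
    14-semitone constraint exactly six pairings are admissible.
    """
    if len(bands) < 2:
        raise ValueError("need at least two bands")
    pairs = []
    for a, b in itertools.combinations(sorted(bands, key=lambda x: x.index), 2):
        lo, hi = sorted((a.center_hz, b.center_hz))
        if semitone_separation(lo, hi) >= min_sep:
            pairs.append((a, b))
    return pairs


@dataclass
class Block:
    """A single 12.8 s block: prompt, cue/gap, then 14 mini-sequence slots."""

    onset_s: float
    band: FrequencyBand
    distractor_band: Optional[FrequencyBand]
    prompt: str  # "hear", "high" or "low"
    n_repeats: int
    repeat_positions: tuple[int, ...]
    isi_ms: tuple[float, ...] = ()
    duration_s: float = BLOCK_DURATION_S

    @property
    def attended_band(self) -> FrequencyBand:
        return self.band


@dataclass
class RunSchedule:
    """Forty timed blocks in eight cycles of five, plus silent baselines."""

    condition: str
    direction: str
    blocks: list[Block]
    baseline_s: float = BASELINE_S
    tr_s: float = TR_S
    n_volumes: int = N_VOLUMES
    n_discard: int = N_DISCARD
    seed: Optional[int] = None

    @property
    def n_retained(self) -> int:
        return self.n_volumes - self.n_discard

    @property
    def retained_duration_s(self) -> float:
        return N_CYCLES * CYCLE_DURATION_S + 2 * self.baseline_s

    @property
    def stim_window_s(self) -> tuple[float, float]:
        """Start/end of the 8-cycle stimulation period in retained time."""
        return (self.baseline_s, self.baseline_s + N_CYCLES * CYCLE_DURATION_S)


def _sample_repeats(rng: np.random.Generator) -> tuple[int, tuple[int, ...]]:
    """Number and slot positions of 1-back mini-sequence repeats.

    Repeat counts follow the 1:2:1 ratio over {1, 2, 3}. A repeat at slot i
    means slot i restates slot i-1; successive repeat pairs are separated by
    at least one intervening mini-sequence (positions differ by >= 3).
    """
    n = int(rng.choice([1, 2, 3], p=[0.25, 0.5, 0.25]))
    while True:
        pos = np.sort(rng.choice(np.arange(1, N_SLOTS), size=n, replace=False))
        if n == 1 or np.all(np.diff(pos) >= 3):
            return n, tuple(int(p) for p in pos)


def _sample_isis(rng: np.random.Generator) -> tuple[float, ...]:
    """Inter-sequence silences: Normal(240 ms, 10 ms) truncated at +/-3 SD."""
    out = []
    while len(out) < N_SLOTS - 1:
        x = rng.normal(240.0, 10.0)
        if abs(x - 240.0) <= 30.0:
            out.append(float(x))
    return tuple(out)


def _attended_order(direction: str) -> list[int]:
    order = list(range(N_BANDS))
    return order if direction == "up" else order[::-1]


def _build_stepped(
    condition: str, direction: str, rng: np.random.Generator
) -> list[Block]:
    bands = default_bands()
    partners: dict[int, list[int]] = {b.index: [] for b in bands}
    for a, b in valid_band_pairs(bands):
        partners[a.index].append(b.index)
        partners[b.index].append(a.index)
    order = _attended_order(direction)
    for _ in range(200):
        blocks = _build_stepped_once(condition, order, bands, partners, rng)
        if condition == "tonotopy":
            return blocks
        # balance guard: keep only pairings for which a count-preserving
        # half-swap of prompts (the randomised control) exists, so stepped
        # and randomised runs built from one seed share their acoustics
        counts: dict[tuple[int, int], int] = {}
        for blk in blocks:
            key = (blk.band.index, blk.distractor_band.index)
            counts[key] = counts.get(key, 0) + 1
        if _swap_feasible(counts):
            return blocks
    raise ScheduleError("could not draw a balanced distractor pairing")


def _build_stepped_once(
    condition: str,
    order: list[int],
    bands: list[FrequencyBand],
    partners: dict[int, list[int]],
    rng: np.random.Generator,
) -> list[Block]:
    blocks: list[Block] = []
    for cycle in range(N_CYCLES):
        for pos, band_idx in enumerate(order):
            onset = BASELINE_S + cycle * CYCLE_DURATION_S + pos * BLOCK_DURATION_S
            n_rep, rep_pos = _sample_repeats(rng)
            if condition == "tonotopy":
                distractor = None
                prompt = "hear"
            else:
                opts = partners[band_idx]
                if not opts:
                    raise ScheduleError(
                        f"band {band_idx} has no partner under the "
                        f"{MIN_PAIR_SEPARATION_SEMITONES}-semitone constraint"
                    )
                d_idx = int(opts[rng.integers(len(opts))])
                distractor = bands[d_idx]
                prompt = "high" if band_idx > d_idx else "low"
            blocks.append(
                Block(
                    onset_s=onset,
                    band=bands[band_idx],
                    distractor_band=distractor,
                    prompt=prompt,
                    n_repeats=n_rep,
                    repeat_positions=rep_pos,
                    isi_ms=_sample_isis(rng),
                )
            )
    return blocks


def _swap_block(block: Block) -> Block:
    """Swap the prompt: attention moves to the other band of the pair."""
    assert block.distractor_band is not None
    new_band = block.distractor_band
    new_dist = block.band
    prompt = "high" if new_band.index > new_dist.index else "low"
    return Block(
        onset_s=block.onset_s,
        band=new_band,
        distractor_band=new_dist,
        prompt=prompt,
        n_repeats=block.n_repeats,
        repeat_positions=block.repeat_positions,
        isi_ms=block.isi_ms,
    )


def _swap_flow(counts: dict[tuple[int, int], int]):
    """Max-flow solution of the swap transportation problem (value, flow).

    Nodes are small integers (source 0, sink 1, attended 2+b, distractor
    2+N_BANDS+b): integer hashes are value-stable, so networkx's internal
    set iteration, and with it the particular optimal flow returned, does
    not depend on the interpreter's per-process string hash seed.
    """
    import networkx as nx

    src, snk = 0, 1
    a_node = lambda b: 2 + b
    d_node = lambda b: 2 + N_BANDS + b
    g = nx.DiGraph()
    for b in range(N_BANDS):
        g.add_edge(src, a_node(b), capacity=4)
        g.add_edge(d_node(b), snk, capacity=4)
    for (a, d), n in counts.items():
        g.add_edge(a_node(a), d_node(d), capacity=n)
    value, flow = nx.maximum_flow(g, src, snk)
    named = {
        f"a{b}": {
            f"d{bd}": n
            for bd in range(N_BANDS)
            if (n := flow.get(a_node(b), {}).get(d_node(bd))) is not None
        }
        for b in range(N_BANDS)
    }
    return value, named


def _swap_feasible(counts: dict[tuple[int, int], int]) -> bool:
    value, _ = _swap_flow(counts)
    return value == 4 * N_BANDS


def _swap_allocation(
    counts: dict[tuple[int, int], int], rng: np.random.Generator
) -> dict[tuple[int, int], int]:
    """How many blocks of each (attended, distractor) category to swap.

    Solved as a transportation problem: each band must lose exactly 4
    attended blocks and gain exactly 4 (via its distractor slots), within
    the per-category block counts. Max-flow finds a feasible integer
    allocation; random cycle rotations then decorrelate it from the solver's
    deterministic choice.
    """
    value, flow = _swap_flow(counts)
    if value != 4 * N_BANDS:
        raise ScheduleError(
            "no count-preserving prompt randomisation exists for this pairing"
        )
    x = {(a, d): flow[f"a{a}"].get(f"d{d}", 0) for (a, d) in counts}
    # randomise among feasible allocations via cycle rotations
    keys = list(counts)
    for _ in range(100):
        (a1, d1), (a2, d2) = (keys[i] for i in rng.choice(len(keys), 2, replace=False))
        if a1 == a2 or d1 == d2:
            continue
        k12, k21 = (a1, d2), (a2, d1)
        if k12 in counts and k21 in counts:
            if x[(a1, d1)] > 0 and x[(a2, d2)] > 0 and x[k12] < counts[k12] and x[k21] < counts[k21]:
                x[(a1, d1)] -= 1
                x[(a2, d2)] -= 1
                x[k12] += 1
                x[k21] += 1
    return x


def _randomise_prompts(blocks: list[Block], rng: np.random.Generator) -> list[Block]:
    """Swap prompts on exactly half the blocks, preserving attended counts.

    Each band loses exactly 4 of its 8 attended blocks (so no band keeps its
    stepped within-cycle position in a majority of cycles) and gains exactly
    4 via blocks where it was the distractor (so every band is still
    attended 8 times).
    """
    by_cat: dict[tuple[int, int], list[int]] = {}
    for i, blk in enumerate(blocks):
        key = (blk.band.index, blk.distractor_band.index)
        by_cat.setdefault(key, []).append(i)
    counts = {k: len(v) for k, v in by_cat.items()}
    x = _swap_allocation(counts, rng)
    swap_set: set[int] = set()
    for key, n_swap in x.items():
        if n_swap > 0:
            chosen = rng.choice(by_cat[key], size=n_swap, replace=False)
            swap_set.update(int(i) for i in chosen)
    return [_swap_block(blk) if i in swap_set else blk for i, blk in enumerate(blocks)]


def build_run_schedule(condition: str, direction: str, seed: int) -> RunSchedule:
    """Construct a run schedule for one condition and sweep direction.

    The seed fixes repeat placement, distractor pairing and (for
    ``attn_random``) the prompt scramble. A randomised run built from seed s
    shares its acoustics (band pairs, repeats, timing) with the stepped run
    built from the same seed; only the prompt assignment differs.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if direction not in DIRECTIONS:
        raise ValueError(f"unknown direction {direction!r}")
    rng = np.random.default_rng(seed)
    base_condition = "attn_stepped" if condition == "attn_random" else condition
    blocks = _build_stepped(base_condition, direction, rng)
    if condition == "attn_random":
        # Separate stream so acoustics stay identical to the stepped run.
        swap_rng = np.random.default_rng((seed, 0x5741))
        blocks = _randomise_prompts(blocks, swap_rng)
    return RunSchedule(condition=condition, direction=direction, blocks=blocks, seed=seed)


def _attended_position_counts(run: RunSchedule) -> np.ndarray:
    """counts[band, within-cycle position] of attended assignments."""
    counts = np.zeros((N_BANDS, N_BANDS), dtype=int)
    for i, blk in enumerate(run.blocks):
        counts[blk.band.index, i % N_BANDS] += 1
    return counts


def validate_schedule(run: RunSchedule) -> dict:
    """Check every schedule invariant; returns a report, never raises.

    The report maps check names to booleans plus summary quantities
    (retained duration, per-band attended counts).
    """
    checks: dict[str, bool] = {}
    n_blocks = len(run.blocks)
    checks["n_blocks_40"] = n_blocks == N_CYCLES * N_BANDS

    onsets_ok = True
    for i, blk in enumerate(run.blocks):
        cycle, pos = divmod(i, N_BANDS)
        expect = run.baseline_s + cycle * CYCLE_DURATION_S + pos * BLOCK_DURATION_S
        if abs(blk.onset_s - expect) > 1e-9 or abs(blk.duration_s - BLOCK_DURATION_S) > 1e-9:
            onsets_ok = False
    checks["block_timing"] = onsets_ok

    # each cycle presents every band (as attended or distractor member)
    cycles_ok = True
    for c in range(n_blocks // N_BANDS):
        stimulated = set()
        for blk in run.blocks[c * N_BANDS : (c + 1) * N_BANDS]:
            stimulated.add(blk.band.index)
            if blk.distractor_band is not None:
                stimulated.add(blk.distractor_band.index)
        if stimulated != set(range(N_BANDS)):
            cycles_ok = False
    checks["each_cycle_visits_all_bands"] = cycles_ok

    attended_counts = np.zeros(N_BANDS, dtype=int)
    for blk in run.blocks:
        attended_counts[blk.band.index] += 1
    checks["each_band_attended_8"] = bool(np.all(attended_counts == N_CYCLES))

    pairing_ok = True
    for blk in run.blocks:
        if blk.distractor_band is not None:
            lo, hi = sorted((blk.band.center_hz, blk.distractor_band.center_hz))
            if semitone_separation(lo, hi) < MIN_PAIR_SEPARATION_SEMITONES:
                pairing_ok = False
    checks["pairs_at_least_14_semitones"] = pairing_ok

    repeats_ok = True
    for blk in run.blocks:
        pos = np.asarray(blk.repeat_positions)
        if len(pos) != blk.n_repeats or not (1 <= blk.n_repeats <= 3):
            repeats_ok = False
        elif np.any(pos < 1) or np.any(pos >= N_SLOTS):
            repeats_ok = False
        elif len(pos) > 1 and np.any(np.diff(np.sort(pos)) < 3):
            repeats_ok = False
    checks["repeats_separated"] = repeats_ok

    if run.condition == "attn_random":
        counts = _attended_position_counts(run)
        checks["attention_aperiodic"] = bool(counts.max() <= N_CYCLES // 2)

    total = run.retained_duration_s
    checks["retained_duration_576"] = abs(total - 576.0) < 1e-9
    checks["volumes"] = run.n_volumes == N_VOLUMES and run.n_discard == N_DISCARD

    return {
        "checks": checks,
        "all_pass": all(checks.values()),
        "retained_duration_s": total,
        "attended_counts": attended_counts.tolist(),
    }


def schedule_to_events(run: RunSchedule) -> pd.DataFrame:
    """BIDS-style events table (onset, duration, trial_type, bands, prompt)."""
    rows = []
    for blk in run.blocks:
        rows.append(
            {
                "onset": blk.onset_s,
                "duration": blk.duration_s,
                "trial_type": run.condition,
                "attended_band": blk.band.index,
                "distractor_band": -1 if blk.distractor_band is None else blk.distractor_band.index,
                "prompt": blk.prompt,
                "n_repeats": blk.n_repeats,
            }
        )
    return pd.DataFrame(rows)


def write_events_tsv(run: RunSchedule, path) -> None:
    schedule_to_events(run).to_csv(path, sep="\t", index=False)
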