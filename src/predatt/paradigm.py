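"""Stimulus-stream generation for the predictive-sequence detection paradigm.

The task presents a rapid stream of triangles (150 ms stimulus, 1000 ms blank;
stimulus-onset asynchrony 1150 ms). Each block contains 127 stimuli: 15%
targets (downward-facing triangles) and 85% standards (left-, up- and
right-facing triangles in equal numbers). A target is either *random* (randT),
embedded in an uninformative context, or *predicted* (predT), appearing as the
fourth element of a fixed three-standard run left -> up -> right that is 100%
predictive of a target. Stimuli inside the predictive run carry pred* labels
(predS1, predS2, predS3, predT); the physically identical triangles outside it
carry rand* labels.

Per-block composition (exact, not stochastic):

    randT: 11, randS1: 28, randS2: 28, randS3: 28,
    predT:  8, predS1:  8, predS2:  8, predS3:  8    -> 127 stimuli

The generator places the 8 predictive runs at uniformly random non-overlapping
positions and fills the remaining slots with a random permutation of the
non-predictive stimuli, rejecting any ordering in which the shape pattern
left, up, right, down arises by accident outside a labelled run (an unlabelled
run would contradict the analysis' assumption that prediction is fully
label-determined).
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

#: Stimulus-onset asynchrony in ms (150 ms stimulus + 1000 ms blank).
SOA_MS = 1150.0

#: Stimulus duration in ms (documentation; no display code exists).
STIMULUS_MS = 150.0

#: The eight stimulus category labels.
CATEGORIES = (
    "randS1", "randS2", "randS3", "randT",
    "predS1", "predS2", "predS3", "predT",
)

#: Triangle orientation for each category (S1=left, S2=up, S3=right, T=down).
SHAPE_OF = {
    "randS1": "left", "predS1": "left",
    "randS2": "up", "predS2": "up",
    "randS3": "right", "predS3": "right",
    "randT": "down", "predT": "down",
}

#: Exact per-block category counts.
BLOCK_COMPOSITION = {
    "randT": 11, "randS1": 28, "randS2": 28, "randS3": 28,
    "predT": 8, "predS1": 8, "predS2": 8, "predS3": 8,
}

BLOCK_LENGTH = sum(BLOCK_COMPOSITION.values())  # 127

TARGET_CATEGORIES = ("randT", "predT")
STANDARD_CATEGORIES = ("randS1", "randS2", "randS3", "predS1", "predS2", "predS3")
RANDOM_STANDARDS = ("randS1", "randS2", "randS3")

#: The predictive run, in order.
PREDICTIVE_RUN = ("predS1", "predS2", "predS3", "predT")

#: Shape pattern that must occur only as a labelled predictive run.
_RUN_SHAPES = ("left", "up", "right", "down")

_N_RUNS = BLOCK_COMPOSITION["predS1"]  # 8 runs per block


def _random_fill() -> list[str]:
    """The 95 non-predictive stimuli of one block, unordered."""
    fill = []
    for cat in ("randT", "randS1", "randS2", "randS3"):
        fill.extend([cat] * BLOCK_COMPOSITION[cat])
    return fill


def _has_spurious_run(categories: list[str]) -> bool:
    """True if the shape pattern left,up,right,down occurs outside a labelled run."""
    shapes = [SHAPE_OF[c] for c in categories]
    for i in range(len(shapes) - 3):
        if tuple(shapes[i:i + 4]) == _RUN_SHAPES and categories[i] != "predS1":
            return True
    return False


def generate_block(seed: int, block: int = 0, max_tries: int = 1000) -> pd.DataFrame:
    """Generate one 127-stimulus block as an event table.

    Parameters
    ----------
    seed
        Non-negative integer seed; the same seed reproduces the same block.
    block
        Block index written into the ``block`` column.
    max_tries
        Rejection-sampling budget for avoiding accidental left,up,right,down
        shape runs. The acceptance probability is high (> 0.5), so exhausting
        the budget signals a bug and raises ``RuntimeError``.

    Returns
    -------
    pandas.DataFrame
        Columns ``onset_ms`` (float, time from block start), ``category``,
        ``block``, ``position`` (0-based index within block). The 8 predictive
        runs are contiguous predS1,predS2,predS3,predT quadruples; no other
        left,up,right,down shape run exists.
    """
    if seed < 0:
        raise ValueError("seed must be a non-negative integer")
    rng = np.random.default_rng(seed)
    fill = _random_fill()
    for _ in range(max_tries):
        # 95 singleton units + 8 run units, shuffled uniformly: this places the
        # runs at uniformly random non-overlapping positions.
        units: list[tuple[str, ...]] = [(c,) for c in fill] + [PREDICTIVE_RUN] * _N_RUNS
        order = rng.permutation(len(units))
        categories = [c for i in order for c in units[i]]
        if not _has_spurious_run(categories):
            return pd.DataFrame({
                "onset_ms": np.arange(BLOCK_LENGTH) * SOA_MS,
                "category": pd.Categorical(categories, categories=CATEGORIES),
                "block": block,
                "position": np.arange(BLOCK_LENGTH),
            })
    raise RuntimeError(
        f"block ordering rejected {max_tries} times; this indicates a bug "
        "in the rejection-sampling constraint"
    )


def generate_session(n_blocks: int, seed: int) -> pd.DataFrame:
    """Generate a session of ``n_blocks`` independently ordered blocks.

    Onsets and positions restart at 0 in each block. Category totals equal
    ``n_blocks`` x the per-block composition (e.g. 15 blocks give 165 randTs
    and 120 predTs).
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_blocks)
    blocks = [
        generate_block(int(s), block=b) for b, s in enumerate(child_seeds)
    ]
    return pd.concat(blocks, ignore_index=True)


def category_counts(events: pd.DataFrame) -> dict[str, int]:
    """Category -> count over an event table."""
    counts = events["category"].value_counts()
    return {cat: int(counts.get(cat, 0)) for cat in CATEGORIES}


def find_shape_runs(events: pd.DataFrame) -> list[int]:
    """Start positions (row indices) of every left,up,right,down shape run.

    Scans within blocks only; used to verify that the only such runs are the
    labelled predictive sequences.
    """
    starts = []
    for _, blk in events.groupby("block", sort=True, observed=True):
        cats = blk["category"].astype(str).tolist()
        shapes = [SHAPE_OF[c] for c in cats]
        base = blk.index[0]
        for i in range(len(shapes) - 3):
            if tuple(shapes[i:i + 4]) == _RUN_SHAPES:
                starts.append(base + i)
    return starts


def write_events(events: pd.DataFrame, path) -> None:
    """Write an event table as tab-separated text with header."""
    events.to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    """Read an event table written by :func:`write_events`."""
    df = pd.read_csv(path, sep="\t")
    df["category"] = pd.Categorical(df["category"], categories=CATEGORIES)
    return df
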