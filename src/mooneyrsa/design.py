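"""Experimental-design scheduler for the Mooney disambiguation paradigm.

A session presents image *sets*; each set is one Mooney image plus a
grayscale image (the matching photograph for real sets, an arbitrarily
assigned non-matching photograph for catch sets).  Sets are introduced a few
per run: a set's Mooney image is shown pre-disambiguation in the run where
it is introduced, its grayscale image appears at the start of each block of
the *next* run, and the Mooney image is shown post-disambiguation in that
same next run.

Every full run consists of three blocks; a full-run block is ``s`` grayscale
trials, then the ``2s`` current Mooney images in random order, then the same
``2s`` Mooney images re-shuffled (15 trials for the default ``s = 3``).  The
first run only introduces Mooney images (no grayscale yet) and the last run
only disambiguates, so both are half runs.  Over a session each Mooney image
is seen exactly 6 times pre- and 6 times post-disambiguation and each
grayscale image exactly 3 times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

GRAY_PRESENTATIONS = 3
BLOCKS_PER_RUN = 3
MOONEY_REPEATS_PER_BLOCK = 2


class DesignError(ValueError):
    """Raised for infeasible design parameter combinations."""


@dataclass
class Design:
    """A fully scheduled session.

    ``trials`` has one row per trial in presentation order with columns
    ``run`` (1-based), ``block`` (1-based within run), ``trial`` (0-based
    global index), ``image_id``, ``image_type`` (``mooney``/``grayscale``),
    ``stage`` (``pre``/``post`` for Mooney, ``gray`` for grayscale trials),
    ``set_type`` (``real``/``catch``) and ``presentation`` (1-based counter
    per image and stage).
    """

    trials: pd.DataFrame
    n_real_sets: int
    n_catch_sets: int
    n_runs: int
    sets_per_run: int
    seed: int | None = None

    @property
    def n_sets(self) -> int:
        return self.n_real_sets + self.n_catch_sets

    @property
    def real_image_ids(self) -> np.ndarray:
        return np.arange(self.n_real_sets)

    @property
    def catch_image_ids(self) -> np.ndarray:
        return np.arange(self.n_real_sets, self.n_sets)

    def set_type_of(self, image_id: int) -> str:
        return "real" if image_id < self.n_real_sets else "catch"

    def validate(self) -> None:
        """Assert the structural invariants of the paradigm."""
        t = self.trials
        # stage labelling: a Mooney trial is "post" iff its grayscale came earlier
        first_gray = (
            t[t["image_type"] == "grayscale"].groupby("image_id")["trial"].min()
        )
        mooney = t[t["image_type"] == "mooney"]
        for _, row in mooney.iterrows():
            g = first_gray.get(row["image_id"], np.inf)
            expected = "post" if g < row["trial"] else "pre"
            if row["stage"] != expected:
                raise AssertionError(
                    f"trial {row['trial']}: stage {row['stage']}, expected {expected}"
                )
        # presentation counts
        gray_counts = (
            t[t["image_type"] == "grayscale"].groupby("image_id").size()
        )
        if not (gray_counts == GRAY_PRESENTATIONS).all() or len(gray_counts) != self.n_sets:
            raise AssertionError("each grayscale image must occur exactly 3 times")
        stage_counts = mooney.groupby(["image_id", "stage"]).size().unstack(fill_value=0)
        expected_m = MOONEY_REPEATS_PER_BLOCK * BLOCKS_PER_RUN
        if not ((stage_counts == expected_m).all().all() and len(stage_counts) == self.n_sets):
            raise AssertionError("each Mooney image must occur 6 pre and 6 post")
        # full-run blocks have s gray then 2s Mooney then the same 2s re-ordered
        s = self.sets_per_run
        for (run, block), grp in t.groupby(["run", "block"]):
            if run in (1, self.n_runs):
                continue
            types = grp["image_type"].tolist()
            if types != ["grayscale"] * s + ["mooney"] * (4 * s):
                raise AssertionError(f"run {run} block {block}: wrong trial layout")
            ids = grp[grp["image_type"] == "mooney"]["image_id"].to_numpy()
            if sorted(ids[: 2 * s]) != sorted(ids[2 * s :]):
                raise AssertionError(
                    f"run {run} block {block}: second Mooney sweep is not a re-ordering"
                )

    def to_events(self) -> pd.DataFrame:
        """Tab-separated-ready events table (one row per trial)."""
        return self.trials.copy()


def build_design(
    n_real_sets: int = 33,
    n_catch_sets: int = 6,
    n_runs: int = 14,
    seed: int | None = None,
    set_order: np.ndarray | None = None,
) -> Design:
    """Schedule a full session.

    Parameters
    ----------
    n_real_sets, n_catch_sets
        Numbers of real and catch image sets (defaults 33 and 6).
    n_runs
        Total runs including the two half runs (default 14); the total
        number of sets must divide evenly over the ``n_runs - 1``
        introducing runs.
    seed
        Seed for the set-introduction order and the within-block shuffles.
    set_order
        Optional explicit introduction order over image ids
        ``0 .. n_sets-1`` (real ids first, catch ids after); overrides the
        seeded shuffle and exposes set-to-run assignment directly.
    """
    if n_real_sets < 1:
        raise DesignError("need at least one real image set")
    if n_runs < 2:
        raise DesignError("need at least two runs (introduce, then disambiguate)")
    n_sets = n_real_sets + n_catch_sets
    if n_sets % (n_runs - 1):
        raise DesignError(
            f"{n_sets} sets cannot be divided over {n_runs - 1} introducing runs"
        )
    s = n_sets // (n_runs - 1)
    rng = np.random.default_rng(seed)
    if set_order is None:
        set_order = rng.permutation(n_sets)
    else:
        set_order = np.asarray(set_order)
        if sorted(set_order.tolist()) != list(range(n_sets)):
            raise DesignError("set_order must be a permutation of all set ids")

    groups = [set_order[i * s : (i + 1) * s] for i in range(n_runs - 1)]

    rows: list[dict] = []
    pres_counter: dict[tuple[int, str], int] = {}

    def emit(run: int, block: int, image_id: int, image_type: str, stage: str) -> None:
        key = (image_id, stage)
        pres_counter[key] = pres_counter.get(key, 0) + 1
        rows.append(
            {
                "run": run,
                "block": block,
                "trial": len(rows),
                "image_id": int(image_id),
                "image_type": image_type,
                "stage": stage,
                "set_type": "real" if image_id < n_real_sets else "catch",
                "presentation": pres_counter[key],
            }
        )

    for run in range(1, n_runs + 1):
        new = groups[run - 1] if run <= n_runs - 1 else np.empty(0, dtype=int)
        old = groups[run - 2] if run >= 2 else np.empty(0, dtype=int)
        for block in range(1, BLOCKS_PER_RUN + 1):
            for g in rng.permutation(old):
                emit(run, block, g, "grayscale", "gray")
            mooney_pool = np.concatenate([old, new]).astype(int)
            for _ in range(MOONEY_REPEATS_PER_BLOCK):
                for m in rng.permutation(mooney_pool):
                    stage = "post" if m in old else "pre"
                    emit(run, block, m, "mooney", stage)

    trials = pd.DataFrame(rows)
    return Design(
        trials=trials,
        n_real_sets=n_real_sets,
        n_catch_sets=n_catch_sets,
        n_runs=n_runs,
        sets_per_run=s,
        seed=seed,
    )
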