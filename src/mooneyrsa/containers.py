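"""Core data containers shared across the pipeline.

Conventions
-----------
* Conditions are ordered ``("pre", "post", "gray")`` everywhere: Mooney image
  before disambiguation, Mooney image after disambiguation, grayscale
  original.  RDMs over ``n`` image sets are ``3n x 3n`` matrices whose rows
  and columns are laid out as three consecutive condition blocks with an
  identical image order inside each block, so the diagonal of a
  between-condition block addresses matching image pairs (e.g. Post-Mooney
  image *i* vs. its own grayscale image *i*).
* Sensor epochs are stored as a dense ``subjects x trials x sensors x time``
  array plus a tidy per-trial events table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Fixed condition-block order of all RDMs.
CONDITIONS: tuple[str, ...] = ("pre", "post", "gray")

#: Required columns of an events table.
EVENT_COLUMNS = (
    "subject",
    "run",
    "block",
    "trial",
    "image_id",
    "image_type",
    "stage",
    "set_type",
    "presentation",
)


def rdm_labels(image_ids: Sequence[int]) -> list[tuple[str, int]]:
    """Return the ``(condition, image_id)`` label of every RDM row/column."""
    return [(cond, img) for cond in CONDITIONS for img in image_ids]


def _cond_index(cond: str) -> int:
    try:
        return CONDITIONS.index(cond)
    except ValueError:
        raise ValueError(
            f"unknown condition {cond!r}; expected one of {CONDITIONS}"
        ) from None


def condition_block(matrix: np.ndarray, cond_a: str, cond_b: str) -> np.ndarray:
    """View of the ``cond_a`` x ``cond_b`` square of a (stack of) RDM(s).

    ``matrix`` may be a single ``3n x 3n`` RDM or a ``... x 3n x 3n`` stack;
    the last two axes are sliced.
    """
    n3 = matrix.shape[-1]
    if matrix.shape[-2] != n3 or n3 % len(CONDITIONS):
        raise ValueError(f"matrix trailing axes {matrix.shape[-2:]} are not 3n x 3n")
    n = n3 // len(CONDITIONS)
    ia, ib = _cond_index(cond_a), _cond_index(cond_b)
    return matrix[..., ia * n : (ia + 1) * n, ib * n : (ib + 1) * n]


@dataclass
class SensorEpochs:
    """Epoched multichannel sensor data with per-trial metadata.

    Parameters
    ----------
    values
        ``subjects x trials x sensors x time`` array.
    time
        Time axis in seconds relative to stimulus onset (uniform, increasing).
    sfreq
        Sampling rate in Hz.
    events
        One row per (subject, trial) in trial order, with the columns of
        :data:`EVENT_COLUMNS` (plus optional behavior columns).
    band
        Frequency-band tag, e.g. ``"scp"`` or ``"erf"``.
    """

    values: np.ndarray
    time: np.ndarray
    sfreq: float
    events: pd.DataFrame
    band: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        if self.values.ndim != 4:
            raise ValueError("values must be subjects x trials x sensors x time")
        if self.time.shape != (self.values.shape[3],):
            raise ValueError("time axis length does not match values")
        dt = np.diff(self.time)
        if len(dt) and (np.any(dt <= 0) or not np.allclose(dt, dt[0])):
            raise ValueError("time axis must be strictly increasing and uniform")
        missing = [c for c in EVENT_COLUMNS if c not in self.events.columns]
        if missing:
            raise ValueError(f"events table missing columns: {missing}")
        if len(self.events) != self.n_subjects * self.n_trials:
            raise ValueError(
                "events table must have one row per (subject, trial): "
                f"expected {self.n_subjects * self.n_trials}, got {len(self.events)}"
            )

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_trials(self) -> int:
        return self.values.shape[1]

    @property
    def n_sensors(self) -> int:
        return self.values.shape[2]

    @property
    def n_times(self) -> int:
        return self.values.shape[3]

    def subject_events(self, subject: int) -> pd.DataFrame:
        """Events of one subject, indexed by that subject's trial axis."""
        ev = self.events[self.events["subject"] == subject]
        return ev.sort_values("trial").reset_index(drop=True)

    def copy(self) -> "SensorEpochs":
        return SensorEpochs(
            self.values.copy(), self.time.copy(), self.sfreq, self.events.copy(), self.band
        )


@dataclass
class RDMSeries:
    """Time-indexed stack of symmetric dissimilarity matrices.

    ``values`` has shape ``time x 3n x 3n`` with condition blocks ordered as
    :data:`CONDITIONS`.  Undefined cells (e.g. within-condition diagonals
    under the correlation metric) hold NaN.
    """

    time: np.ndarray
    values: np.ndarray
    metric: str
    image_ids: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.image_ids = np.asarray(self.image_ids)
        n3 = len(CONDITIONS) * self.n_images
        if self.values.shape != (len(self.time), n3, n3):
            raise ValueError(
                f"values shape {self.values.shape} != (time, {n3}, {n3})"
            )

    @property
    def n_images(self) -> int:
        return len(self.image_ids)

    @property
    def side(self) -> int:
        return self.values.shape[-1]

    def block(self, cond_a: str, cond_b: str) -> np.ndarray:
        """``time x n x n`` view of one condition square."""
        return condition_block(self.values, cond_a, cond_b)

    def labels(self) -> list[tuple[str, int]]:
        return rdm_labels(self.image_ids)


@dataclass
class ModelRDM:
    """A theoretical dissimilarity model over the 3n x 3n label grid.

    Entries take the discrete levels ``{0, 0.5, 1}``; excluded cells are
    carried in an explicit boolean ``missing`` mask (True = excluded) rather
    than as a sentinel value.
    """

    values: np.ndarray
    missing: np.ndarray
    kind: str
    image_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        self.image_ids = np.asarray(self.image_ids)
        if self.values.shape != self.missing.shape:
            raise ValueError("values and missing mask must share shape")

    @property
    def n_images(self) -> int:
        return len(self.image_ids)

    def masked(self) -> np.ndarray:
        """Values with excluded cells as NaN."""
        out = self.values.copy()
        out[self.missing] = np.nan
        return out

    def block(self, cond_a: str, cond_b: str) -> np.ndarray:
        return condition_block(self.masked(), cond_a, cond_b)


@dataclass
class ClusterResult:
    """Outcome of a cluster-based permutation test.

    ``clusters`` holds one index array per cluster (1-D: sample indices;
    2-D: ``(n_cells, 2)`` row/column index pairs).  ``summaries`` are the
    summed cluster-forming statistics, ``pvalues`` the permutation p-values,
    and ``mask`` marks the cells of clusters significant at ``alpha``.
    """

    clusters: list[np.ndarray]
    summaries: np.ndarray
    pvalues: np.ndarray
    mask: np.ndarray
    null: np.ndarray = field(default_factory=lambda: np.empty(0))
    alpha: float = 0.05

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def any_significant(self) -> bool:
        return bool(np.any(self.pvalues < self.alpha))
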