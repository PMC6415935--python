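"""Simulated recognition behavior and behaviorally constrained set selection.

Recognition of a Mooney image is modelled with a per-image latent state
("does this subject recognize the image in this stage?") plus per-report
lapse noise.  The latent states of the two stages are comonotonically
coupled (one uniform draw per image), so an image spontaneously recognized
pre-disambiguation stays recognized post-disambiguation while the stage
marginals equal the requested probabilities exactly.  Catch sets use the
spontaneous-recognition probability in both stages (disambiguation by a
non-matching photograph confers no prior), and the coupling makes their
latent state literally unchanged across stages.

With lapse noise around 0.1 the per-image recognition counts over six
probes are bimodal with modes at 0-1 and 5-6, which is what motivates the
"recognized >= 4 / not-recognized <= 2" classification used downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import Design

MOONEY_STAGES = ("pre", "post")
NOT_RECOGNIZED_MAX = 2
RECOGNIZED_MIN = 4


@dataclass
class BehaviorTable:
    """Per-presentation subjective reports and per-stage verbal identification.

    ``recognition``: columns ``subject, image_id, set_type, stage,
    presentation, response`` (response in {0, 1}).
    ``verbal``: columns ``subject, image_id, set_type, stage, correct``.
    """

    recognition: pd.DataFrame
    verbal: pd.DataFrame

    def counts(self) -> pd.DataFrame:
        """Recognition counts per (subject, image, stage)."""
        out = (
            self.recognition.groupby(["subject", "image_id", "set_type", "stage"])[
                "response"
            ]
            .agg(["sum", "count"])
            .rename(columns={"sum": "n_recognized", "count": "n_probes"})
            .reset_index()
        )
        return out

    @staticmethod
    def concat(tables: list["BehaviorTable"]) -> "BehaviorTable":
        return BehaviorTable(
            recognition=pd.concat([t.recognition for t in tables], ignore_index=True),
            verbal=pd.concat([t.verbal for t in tables], ignore_index=True),
        )


def simulate_behavior(
    design: Design,
    p_spontaneous: float = 0.34,
    p_post_recognize: float = 0.87,
    seed: int | None = None,
    lapse: float = 0.1,
    verbal_lapse: float = 0.05,
    subject: int = 0,
) -> BehaviorTable:
    """Draw subjective reports and verbal identification for one subject.

    Parameters
    ----------
    p_spontaneous
        Probability a Mooney image is (latently) recognized without its
        matching photograph; applies pre-disambiguation for real sets and
        in both stages for catch sets.
    p_post_recognize
        Probability a real Mooney image is recognized post-disambiguation.
    lapse
        Per-report flip probability around the latent state; produces the
        characteristic bimodal 0-1 / 5-6 recognition-count histogram.
    verbal_lapse
        Flip probability of the single per-stage verbal identification.
    """
    for p in (p_spontaneous, p_post_recognize, lapse, verbal_lapse):
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_sets = design.n_sets

    u = rng.uniform(size=n_sets)  # one draw per image couples the two stages
    is_real = np.arange(n_sets) < design.n_real_sets
    latent = {
        "pre": u < p_spontaneous,
        "post": np.where(is_real, u < p_post_recognize, u < p_spontaneous),
    }

    mooney = design.trials[design.trials["image_type"] == "mooney"]
    rec_rows = []
    for _, row in mooney.iterrows():
        state = bool(latent[row["stage"]][row["image_id"]])
        response = state ^ (rng.uniform() < lapse)
        rec_rows.append(
            {
                "subject": subject,
                "image_id": row["image_id"],
                "set_type": row["set_type"],
                "stage": row["stage"],
                "presentation": row["presentation"],
                "response": int(response),
            }
        )
    recognition = pd.DataFrame(rec_rows)

    verb_rows = []
    for img in range(n_sets):
        for stage in MOONEY_STAGES:
            state = bool(latent[stage][img])
            correct = state ^ (rng.uniform() < verbal_lapse)
            verb_rows.append(
                {
                    "subject": subject,
                    "image_id": img,
                    "set_type": design.set_type_of(img),
                    "stage": stage,
                    "correct": int(correct),
                }
            )
    verbal = pd.DataFrame(verb_rows)
    return BehaviorTable(recognition=recognition, verbal=verbal)


def select_disambiguated_sets(
    behavior: BehaviorTable, criterion: str = "subjective"
) -> dict[int, np.ndarray]:
    """Per subject, the real image sets that were genuinely disambiguated.

    ``subjective``: not-recognized pre-disambiguation (<= 2 of 6 probes) and
    recognized post-disambiguation (>= 4 of 6).  ``verbal``: identification
    incorrect pre and correct post.  Catch sets are never selected.
    """
    if criterion not in ("subjective", "verbal"):
        raise ValueError(f"unknown criterion {criterion!r}")
    out: dict[int, np.ndarray] = {}
    if criterion == "subjective":
        counts = behavior.counts()
        counts = counts[counts["set_type"] == "real"]
        wide = counts.pivot_table(
            index=["subject", "image_id"], columns="stage", values="n_recognized"
        )
        sel = wide[(wide["pre"] <= NOT_RECOGNIZED_MAX) & (wide["post"] >= RECOGNIZED_MIN)]
        subjects = wide.index.get_level_values("subject").unique()
        for s in subjects:
            imgs = sel.loc[s].index.to_numpy() if s in sel.index.get_level_values(0) else np.empty(0, int)
            out[int(s)] = np.sort(imgs.astype(int))
    else:
        verbal = behavior.verbal[behavior.verbal["set_type"] == "real"]
        wide = verbal.pivot_table(
            index=["subject", "image_id"], columns="stage", values="correct"
        )
        sel = wide[(wide["pre"] == 0) & (wide["post"] == 1)]
        for s in wide.index.get_level_values("subject").unique():
            imgs = sel.loc[s].index.to_numpy() if s in sel.index.get_level_values(0) else np.empty(0, int)
            out[int(s)] = np.sort(imgs.astype(int))
    for s, imgs in out.items():
        if len(imgs) == 0:
            warnings.warn(
                f"subject {s}: no image set passed the {criterion} disambiguation "
                "criterion; returning an empty selection",
                stacklevel=2,
            )
    return out
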