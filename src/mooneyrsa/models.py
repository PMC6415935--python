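"""The three theoretical model RDMs: stimulus, recognition, attention.

Each model assigns a discrete dissimilarity level to every cell of the
``3n x 3n`` (condition, image) grid — 0 (low), 0.5 (intermediate) or
1 (high) — with excluded cells carried in an explicit missing mask:

* **stimulus** — physical image features: the same Mooney image pre and
  post is identical (Pre-Post diagonal 0); different Mooney images and
  different grayscale images are moderately dissimilar (off-diagonals of
  Pre-Pre, Pre-Post, Post-Post, Gray-Gray at 0.5); a Mooney image and a
  non-matching grayscale differ most (off-diagonals of Pre-Gray and
  Post-Gray at 1).  The Pre-Gray and Post-Gray diagonals are excluded —
  the model makes no a-priori claim about a Mooney image vs. its own
  photograph.
* **recognition** — image-specific recognition content: two unrecognized
  images are alike (Pre-Pre off-diagonals 0), a post-disambiguation Mooney
  image shares its content with its own grayscale image (Post-Gray diagonal
  0), two recognized images with different contents are most distinct
  (off-diagonals of Post-Post, Post-Gray, Gray-Gray at 1), and
  recognized-vs-unrecognized pairs are intermediate (Pre-Post and Pre-Gray
  squares at 0.5).  Equating the Pre-Pre off-diagonals with the Post-Gray
  diagonal is a modelling convention; both levels are independently
  settable for sensitivity analysis.
* **attention** — recognition *status* regardless of content: recognized
  conditions (Post, Gray) are alike and unrecognized (Pre) is alike
  (those squares at 0); recognized-vs-unrecognized squares (Pre-Post,
  Pre-Gray) at 1.  No intermediate level.

The main diagonal is always excluded.
"""

from __future__ import annotations

import numpy as np

from .containers import CONDITIONS, ModelRDM

MODEL_KINDS = ("stimulus", "recognition", "attention")


class _Grid:
    def __init__(self, n: int):
        self.n = n
        side = 3 * n
        self.values = np.zeros((side, side))
        self.missing = np.zeros((side, side), dtype=bool)

    def _sl(self, cond: str) -> slice:
        i = CONDITIONS.index(cond)
        return slice(i * self.n, (i + 1) * self.n)

    def set_block(self, a: str, b: str, off: float | None, diag: float | None) -> None:
        """Assign one condition square (and mirror it); ``None`` = missing."""
        n = self.n
        block = np.empty((n, n))
        bmiss = np.zeros((n, n), dtype=bool)
        block[:] = 0.0 if off is None else off
        bmiss[:] = off is None
        di = np.diag_indices(n)
        block[di] = 0.0 if diag is None else diag
        bmiss[di] = diag is None
        sa, sb = self._sl(a), self._sl(b)
        self.values[sa, sb] = block
        self.missing[sa, sb] = bmiss
        self.values[sb, sa] = block.T
        self.missing[sb, sa] = bmiss.T

    def finish(self, kind: str, image_ids: np.ndarray) -> ModelRDM:
        np.fill_diagonal(self.missing, True)
        self.values[self.missing] = 0.0
        return ModelRDM(self.values, self.missing, kind, image_ids)


def build_model_rdm(
    kind: str,
    n_images: int = 33,
    recognition_low_levels: tuple[float, float] = (0.0, 0.0),
) -> ModelRDM:
    """Construct one of the three model RDMs over ``n_images`` image sets.

    ``recognition_low_levels`` optionally overrides the (Pre-Pre
    off-diagonal, Post-Gray diagonal) levels of the recognition model,
    which the default model equates at 0 by convention.
    """
    if n_images < 2:
        raise ValueError("model RDMs need at least 2 image sets")
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {kind!r}; expected one of {MODEL_KINDS}")
    g = _Grid(n_images)
    image_ids = np.arange(n_images)
    if kind == "stimulus":
        g.set_block("pre", "pre", off=0.5, diag=None)
        g.set_block("post", "post", off=0.5, diag=None)
        g.set_block("gray", "gray", off=0.5, diag=None)
        g.set_block("pre", "post", off=0.5, diag=0.0)
        g.set_block("pre", "gray", off=1.0, diag=None)
        g.set_block("post", "gray", off=1.0, diag=None)
    elif kind == "recognition":
        lo_prepre, lo_postgray = recognition_low_levels
        g.set_block("pre", "pre", off=lo_prepre, diag=None)
        g.set_block("post", "post", off=1.0, diag=None)
        g.set_block("gray", "gray", off=1.0, diag=None)
        g.set_block("pre", "post", off=0.5, diag=0.5)
        g.set_block("pre", "gray", off=0.5, diag=0.5)
        g.set_block("post", "gray", off=1.0, diag=lo_postgray)
    else:  # attention
        g.set_block("pre", "pre", off=0.0, diag=None)
        g.set_block("post", "post", off=0.0, diag=None)
        g.set_block("gray", "gray", off=0.0, diag=None)
        g.set_block("pre", "post", off=1.0, diag=1.0)
        g.set_block("pre", "gray", off=1.0, diag=1.0)
        g.set_block("post", "gray", off=0.0, diag=0.0)
    return g.finish(kind, image_ids)
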