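"""Minimum-image distance helpers for (possibly triclinic) periodic boxes.

All coordinates are in nm.  A box is a 3x3 array whose *rows* are the box
vectors, so cartesian = fractional @ box.  ``box=None`` means open boundaries.
"""

from __future__ import annotations

import numpy as np


def min_image_displacements(d: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors ``d``.

    Uses the general triclinic convention: wrap fractional coordinates to
    [-0.5, 0.5).  Exact for boxes that are not extremely skewed, which covers
    the rectangular and rhombic-dodecahedral boxes used in practice.
    """
    if box is None:
        return d
    inv = np.linalg.inv(box)
    frac = d @ inv
    frac -= np.round(frac)
    return frac @ box


def pair_distance_matrix(a: np.ndarray, b: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """All-pairs distances between point sets ``a`` (n,3) and ``b`` (m,3)."""
    d = a[:, None, :] - b[None, :, :]
    d = min_image_displacements(d, box)
    return np.linalg.norm(d, axis=-1)


def block_min_reduce(mat: np.ndarray, row_starts: np.ndarray, col_starts: np.ndarray) -> np.ndarray:
    """Reduce an atom-atom matrix to a block (e.g. residue-residue) minimum.

    ``row_starts``/``col_starts`` are the first atom index of each contiguous
    block along the respective axis.
    """
    red = np.minimum.reduceat(mat, row_starts, axis=0)
    return np.minimum.reduceat(red, col_starts, axis=1)
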