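"""Synthetic 2-D electrode layouts.

Real EEG caps project the scalp onto a disk; here we place scalp electrodes
on a sunflower (golden-angle) spiral inside the unit disk, which gives an
approximately uniform 10-20-like coverage for any channel count, and put the
two mastoid references just outside the head outline behind the ears. The
layout only needs to support distance-based channel interpolation, smooth
topography gain maps, and a Delaunay adjacency graph.
"""

from __future__ import annotations

import numpy as np

__all__ = ["make_layout", "MASTOID_LABELS"]

MASTOID_LABELS = ("M1", "M2")

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def make_layout(n_channels: int) -> tuple[list[str], np.ndarray]:
    """Labels and 2-D coordinates for ``n_channels`` electrodes.

    The last two channels are the left/right mastoids (labels ``M1``/``M2``)
    at (-1.05, -0.45) and (1.05, -0.45); the remaining ``n_channels - 2``
    scalp electrodes fill the unit disk. Nose is +y.
    """
    if n_channels < 4:
        raise ValueError("need at least 4 channels (2 scalp + 2 mastoids)")
    n_scalp = n_channels - 2
    k = np.arange(n_scalp)
    r = 0.95 * np.sqrt((k + 0.5) / n_scalp)
    theta = k * _GOLDEN_ANGLE
    coords = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    labels = [f"E{i + 1:02d}" for i in range(n_scalp)]
    coords = np.vstack([coords, [[-1.05, -0.45], [1.05, -0.45]]])
    labels += list(MASTOID_LABELS)
    return labels, coords
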