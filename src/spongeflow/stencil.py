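"""D3Q19 lattice stencil: 19 discrete velocities, weights, index maps."""

from __future__ import annotations

import numpy as np

__all__ = ["C", "W", "CS2", "OPP", "MIRROR_Z", "n_dirs"]

# rest + 6 face + 12 edge directions
C = np.array(
    [
        [0, 0, 0],
        [1, 0, 0], [-1, 0, 0],
        [0, 1, 0], [0, -1, 0],
        [0, 0, 1], [0, 0, -1],
        [1, 1, 0], [-1, -1, 0], [1, -1, 0], [-1, 1, 0],
        [1, 0, 1], [-1, 0, -1], [1, 0, -1], [-1, 0, 1],
        [0, 1, 1], [0, -1, -1], [0, 1, -1], [0, -1, 1],
    ],
    dtype=np.int64,
)

W = np.array(
    [1 / 3]
    + [1 / 18] * 6
    + [1 / 36] * 12,
    dtype=np.float64,
)

#: lattice speed of sound squared
CS2 = 1.0 / 3.0

n_dirs = 19


def _index_of(v: np.ndarray) -> int:
    return int(np.flatnonzero((C == v).all(axis=1))[0])


#: opposite direction: C[OPP[i]] == -C[i]
OPP = np.array([_index_of(-C[i]) for i in range(n_dirs)], dtype=np.int64)

#: z-mirrored direction: C[MIRROR_Z[i]] == C[i] * (1, 1, -1)
MIRROR_Z = np.array(
    [_index_of(C[i] * np.array([1, 1, -1])) for i in range(n_dirs)], dtype=np.int64
)
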