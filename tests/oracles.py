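"""Independent brute-force oracles for the texture matrices.

These enumerate pairs, runs, zones and neighborhoods voxel by voxel with
plain Python loops; they share no code with the vectorized engine and are
only feasible on tiny volumes.
"""

from __future__ import annotations

import numpy as np

DIRS_13 = [
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]
DIRS_26 = DIRS_13 + [(-a, -b, -c) for a, b, c in DIRS_13]


def _in_bounds(v, shape):
    return all(0 <= v[i] < shape[i] for i in range(3))


def glcm_oracle(levels: np.ndarray, ng: int) -> np.ndarray:
    """All distance-1 ordered pairs over the 26 offsets (== pooled 13
    directions, symmetrized), normalized."""
    counts = np.zeros((ng, ng), dtype=np.int64)
    shape = levels.shape
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                a = levels[x, y, z]
                if a == 0:
                    continue
                for d in DIRS_26:
                    w = (x + d[0], y + d[1], z + d[2])
                    if not _in_bounds(w, shape):
                        continue
                    b = levels[w]
                    if b == 0:
                        continue
                    counts[a - 1, b - 1] += 1
    total = counts.sum()
    return counts / total if total else counts.astype(float)


def glrlm_oracle(levels: np.ndarray, ng: int, max_len: int) -> np.ndarray:
    """Walk every maximal run of equal nonzero level along each of the 13
    directions."""
    counts = np.zeros((ng, max_len), dtype=np.int64)
    shape = levels.shape
    for d in DIRS_13:
        for x in range(shape[0]):
            for y in range(shape[1]):
                for z in range(shape[2]):
                    lev = levels[x, y, z]
                    if lev == 0:
                        continue
                    prev = (x - d[0], y - d[1], z - d[2])
                    if _in_bounds(prev, shape) and levels[prev] == lev:
                        continue  # not a run start
                    length = 1
                    cur = (x, y, z)
                    while True:
                        nxt = (cur[0] + d[0], cur[1] + d[1], cur[2] + d[2])
                        if _in_bounds(nxt, shape) and levels[nxt] == lev:
                            length += 1
                            cur = nxt
                        else:
                            break
                    counts[lev - 1, length - 1] += 1
    return counts


def glszm_oracle(levels: np.ndarray, ng: int, max_size: int) -> np.ndarray:
    """Flood-fill 26-connected zones of equal level."""
    counts = np.zeros((ng, max_size), dtype=np.int64)
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                lev = levels[x, y, z]
                if lev == 0 or seen[x, y, z]:
                    continue
                stack = [(x, y, z)]
                seen[x, y, z] = True
                size = 0
                while stack:
                    cx, cy, cz = stack.pop()
                    size += 1
                    for d in DIRS_26:
                        w = (cx + d[0], cy + d[1], cz + d[2])
                        if _in_bounds(w, shape) and not seen[w] and levels[w] == lev:
                            seen[w] = True
                            stack.append(w)
                counts[lev - 1, size - 1] += 1
    return counts


def ngtdm_oracle(levels: np.ndarray, ng: int):
    """Per-voxel mean over valid 26-neighbors."""
    s = np.zeros(ng)
    n = np.zeros(ng, dtype=np.int64)
    shape = levels.shape
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                lev = levels[x, y, z]
                if lev == 0:
                    continue
                nbrs = []
                for d in DIRS_26:
                    w = (x + d[0], y + d[1], z + d[2])
                    if _in_bounds(w, shape) and levels[w] != 0:
                        nbrs.append(levels[w])
                if not nbrs:
                    continue
                s[lev - 1] += abs(lev - sum(nbrs) / len(nbrs))
                n[lev - 1] += 1
    return s, n
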