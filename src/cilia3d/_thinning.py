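"""Distance-ordered homotopic thinning of 3D binary masks.

The centerline is obtained by deleting *simple points* — voxels whose
removal does not change the topology of the object — in order of
increasing Euclidean distance-map value, so the erosion front advances
from the surface inward and the surviving curve runs along the ridge of
the distance map.  Curve endpoints (voxels with exactly one foreground
neighbour) are never deleted, which lets elongated objects keep their
tips instead of collapsing to a single voxel.

Simplicity is decided by the standard pair of topological numbers for
(26, 6) connectivity: a voxel is simple iff its 26-neighbourhood contains
exactly one 26-connected foreground component and the background in its
18-neighbourhood has exactly one 6-connected component touching a face
neighbour.  The anisotropy of the voxel grid enters only through the
distance map (computed with physical spacing by the caller), never
through the connectivity.
"""

from __future__ import annotations

import numpy as np
from numba import njit


def _build_tables():
    off26 = np.array(
        [
            (dz, dy, dx)
            for dz in (-1, 0, 1)
            for dy in (-1, 0, 1)
            for dx in (-1, 0, 1)
            if (dz, dy, dx) != (0, 0, 0)
        ],
        dtype=np.int64,
    )
    adj26 = np.zeros((26, 26), np.uint8)
    for i in range(26):
        for j in range(26):
            if i != j and np.max(np.abs(off26[i] - off26[j])) <= 1:
                adj26[i, j] = 1
    off18 = np.array([o for o in off26 if np.sum(np.abs(o)) <= 2], dtype=np.int64)
    n18 = len(off18)
    adj6_18 = np.zeros((n18, n18), np.uint8)
    for i in range(n18):
        for j in range(n18):
            if i != j and np.sum(np.abs(off18[i] - off18[j])) == 1:
                adj6_18[i, j] = 1
    face18 = (np.abs(off18).sum(axis=1) == 1).astype(np.uint8)
    return off26, adj26, off18, adj6_18, face18


OFF26, ADJ26, OFF18, ADJ6_18, FACE18 = _build_tables()


@njit(cache=True)
def _simple_point(fg, z, y, x):
    # T26: foreground components in the 26-neighbourhood (centre excluded)
    flags = np.zeros(26, np.uint8)
    for i in range(26):
        flags[i] = fg[z + OFF26[i, 0], y + OFF26[i, 1], x + OFF26[i, 2]]
    visited = np.zeros(26, np.uint8)
    stack = np.empty(26, np.int64)
    t26 = 0
    for i in range(26):
        if flags[i] == 1 and visited[i] == 0:
            t26 += 1
            if t26 > 1:
                return False
            sp = 0
            stack[sp] = i
            sp += 1
            visited[i] = 1
            while sp > 0:
                sp -= 1
                j = stack[sp]
                for k in range(26):
                    if flags[k] == 1 and visited[k] == 0 and ADJ26[j, k] == 1:
                        visited[k] = 1
                        stack[sp] = k
                        sp += 1
    if t26 != 1:
        return False
    # T6: background 6-components in the 18-neighbourhood touching a face
    n18 = OFF18.shape[0]
    bg = np.zeros(n18, np.uint8)
    for i in range(n18):
        if fg[z + OFF18[i, 0], y + OFF18[i, 1], x + OFF18[i, 2]] == 0:
            bg[i] = 1
    visited18 = np.zeros(n18, np.uint8)
    stack18 = np.empty(n18, np.int64)
    t6 = 0
    for i in range(n18):
        if bg[i] == 1 and visited18[i] == 0:
            has_face = False
            sp = 0
            stack18[sp] = i
            sp += 1
            visited18[i] = 1
            while sp > 0:
                sp -= 1
                j = stack18[sp]
                if FACE18[j] == 1:
                    has_face = True
                for k in range(n18):
                    if bg[k] == 1 and visited18[k] == 0 and ADJ6_18[j, k] == 1:
                        visited18[k] = 1
                        stack18[sp] = k
                        sp += 1
            if has_face:
                t6 += 1
                if t6 > 1:
                    return False
    return t6 == 1


@njit(cache=True)
def _delete_pass(fg, coords):
    deleted = 0
    for n in range(coords.shape[0]):
        z, y, x = coords[n, 0], coords[n, 1], coords[n, 2]
        if fg[z, y, x] == 0:
            continue
        # only surface voxels (some face neighbour is background) are candidates
        if (
            fg[z - 1, y, x] == 1
            and fg[z + 1, y, x] == 1
            and fg[z, y - 1, x] == 1
            and fg[z, y + 1, x] == 1
            and fg[z, y, x - 1] == 1
            and fg[z, y, x + 1] == 1
        ):
            continue
        cnt = 0
        for i in range(26):
            cnt += fg[z + OFF26[i, 0], y + OFF26[i, 1], x + OFF26[i, 2]]
        if cnt <= 1:  # endpoint or isolated voxel: preserve
            continue
        if _simple_point(fg, z, y, x):
            fg[z, y, x] = 0
            deleted += 1
    return deleted


def thin(mask: np.ndarray, priority: np.ndarray) -> np.ndarray:
    """Thin ``mask`` to a one-voxel-wide 26-connected curve skeleton.

    ``priority`` (same shape, typically the anisotropic Euclidean distance
    map of the mask) fixes the deletion order: lower values erode first.
    Ties break on array order, so results are deterministic.
    """
    fg = np.pad(np.asarray(mask, bool), 1).astype(np.uint8)
    prio = np.pad(np.asarray(priority, np.float32), 1)
    coords = np.argwhere(fg == 1)
    order = np.argsort(prio[tuple(coords.T)], kind="stable")
    coords = np.ascontiguousarray(coords[order])
    while True:
        deleted = _delete_pass(fg, coords)
        if deleted == 0:
            break
        keep = fg[tuple(coords.T)] == 1
        coords = np.ascontiguousarray(coords[keep])
    return fg[1:-1, 1:-1, 1:-1].astype(bool)
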