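"""Sequential topology-preserving 3D thinning kernel.

Isthmus-anchored directional thinning.  A voxel may be deleted only if it
is a *simple point* — removal changes neither the 26-topology of the
foreground nor the 6-topology of the background.  Simplicity is decided by
the two topological numbers of the 3x3x3 neighbourhood
(Malandain-Bertrand): T26, the number of 26-connected foreground
components among the 26 neighbours, and Tb, the number of 6-connected
background components of the 18-neighbourhood touching a face neighbour;
the voxel is simple iff T26 == Tb == 1.

Before each directional subiteration every border voxel that is a curve
isthmus (T26 >= 2), a surface isthmus (Tb >= 2: locally one voxel thin,
separating two background sheets), an endpoint (<= 1 foreground
neighbour), or isolated is anchored permanently.  Anchoring is what makes
rods thin to their mid-curves and plates to their mid-surfaces instead of
collapsing to points.  Deletion then proceeds over the border voxels of
one face direction (z-, z+, y-, y+, x-, x+ in turn), sequentially in scan
order, and only where the opposite neighbour along the deletion axis is
foreground — so each subiteration peels a single one-voxel layer from one
side and opposite directions erode symmetrically.

The kernel operates in place on a zero-padded uint8 array.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["thin_sequential", "is_simple_point"]

_ANCHOR = np.uint8(2)


@njit(cache=True)
def _topo_numbers(vol: np.ndarray, z: int, y: int, x: int) -> tuple[int, int, int]:
    """(T26, Tb, n_fg) of the 3x3x3 neighbourhood of a voxel."""
    # local pattern; linear index s = 9*a + 3*b + c, centre s = 13
    lab = np.zeros(27, np.uint8)
    nfg = 0
    for a in range(3):
        for b in range(3):
            for c in range(3):
                s = 9 * a + 3 * b + c
                if vol[z + a - 1, y + b - 1, x + c - 1] != 0:
                    lab[s] = 1
                    nfg += 1
    if lab[13]:
        nfg -= 1
    lab[13] = 0

    seen = np.zeros(27, np.uint8)
    stack = np.empty(27, np.int64)

    # T26: 26-connected foreground components among the 26 neighbours
    t26 = 0
    for s in range(27):
        if s == 13 or lab[s] == 0 or seen[s]:
            continue
        t26 += 1
        top = 0
        stack[top] = s
        top += 1
        seen[s] = 1
        while top > 0:
            top -= 1
            cur = stack[top]
            ca, cb, cc = cur // 9, (cur // 3) % 3, cur % 3
            for t in range(27):
                if t == 13 or seen[t] or lab[t] == 0:
                    continue
                ta, tb_, tc = t // 9, (t // 3) % 3, t % 3
                if abs(ta - ca) <= 1 and abs(tb_ - cb) <= 1 and abs(tc - cc) <= 1:
                    seen[t] = 1
                    stack[top] = t
                    top += 1

    # Tb: 6-connected background components of the 18-neighbourhood that
    # touch a face neighbour
    for s in range(27):
        seen[s] = 0
    tb = 0
    for s in (4, 10, 12, 14, 16, 22):  # face neighbours
        if lab[s] != 0 or seen[s]:
            continue
        tb += 1
        top = 0
        stack[top] = s
        top += 1
        seen[s] = 1
        while top > 0:
            top -= 1
            cur = stack[top]
            ca, cb, cc = cur // 9, (cur // 3) % 3, cur % 3
            for t in range(27):
                if t == 13 or seen[t] or lab[t] != 0:
                    continue
                ta, tb_, tc = t // 9, (t // 3) % 3, t % 3
                if abs(ta - 1) + abs(tb_ - 1) + abs(tc - 1) > 2:
                    continue  # outside the 18-neighbourhood
                if abs(ta - ca) + abs(tb_ - cb) + abs(tc - cc) == 1:
                    seen[t] = 1
                    stack[top] = t
                    top += 1
    return t26, tb, nfg


@njit(cache=True)
def thin_sequential(vol: np.ndarray) -> None:
    """Thin a zero-padded binary uint8 volume in place."""
    nz, ny, nx = vol.shape
    dirs = ((-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1))
    cap = int(vol.sum())  # upper bound on border voxels
    cand = np.empty((max(cap, 1), 3), np.int64)
    changed = True
    while changed:
        changed = False
        for d in range(6):
            dz, dy, dx = dirs[d]
            ncand = 0
            for z in range(1, nz - 1):
                for y in range(1, ny - 1):
                    for x in range(1, nx - 1):
                        if vol[z, y, x] != 1:
                            continue  # background or already anchored
                        # border voxel in any direction?
                        if (vol[z - 1, y, x] != 0 and vol[z + 1, y, x] != 0
                                and vol[z, y - 1, x] != 0 and vol[z, y + 1, x] != 0
                                and vol[z, y, x - 1] != 0 and vol[z, y, x + 1] != 0):
                            continue
                        t26, tb, nfg = _topo_numbers(vol, z, y, x)
                        if nfg <= 1 or t26 >= 2 or tb >= 2:
                            vol[z, y, x] = _ANCHOR  # isthmus or endpoint
                            continue
                        # deletion candidate for this direction: border in d
                        # with foreground on the opposite side
                        if (vol[z + dz, y + dy, x + dx] == 0
                                and vol[z - dz, y - dy, x - dx] != 0):
                            cand[ncand, 0] = z
                            cand[ncand, 1] = y
                            cand[ncand, 2] = x
                            ncand += 1
            for i in range(ncand):
                z, y, x = cand[i, 0], cand[i, 1], cand[i, 2]
                if vol[z, y, x] != 1:
                    continue
                if vol[z + dz, y + dy, x + dx] != 0:
                    continue
                if vol[z - dz, y - dy, x - dx] == 0:
                    continue
                t26, tb, nfg = _topo_numbers(vol, z, y, x)
                if t26 == 1 and tb == 1:
                    vol[z, y, x] = 0
                    changed = True
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if vol[z, y, x] == _ANCHOR:
                    vol[z, y, x] = 1


def is_simple_point(vol: np.ndarray, z: int, y: int, x: int) -> bool:
    """Whether deleting voxel (z, y, x) preserves local topology.

    ``vol`` must be binary with a one-voxel zero border (or the query voxel
    must not touch the array boundary).
    """
    t26, tb, _ = _topo_numbers(np.ascontiguousarray(vol, dtype=np.uint8), z, y, x)
    return bool(t26 == 1 and tb == 1)
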