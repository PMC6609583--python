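"""Independent brute-force oracles used by the tests.

Deliberately naive (pure-Python triple loops and flood fill) and kept
separate from the package so they share no code path with the
implementation they check.
"""

from __future__ import annotations

import numpy as np


def _neighbours(connectivity: int):
    offsets = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                if (di, dj, dk) == (0, 0, 0):
                    continue
                order = abs(di) + abs(dj) + abs(dk)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((di, dj, dk))
    return offsets


def flood_fill_lesions(
    suv: np.ndarray,
    bone: np.ndarray,
    cutoff: float,
    connectivity: int = 26,
    voxel_volume_ml: float = 1.0,
):
    """Threshold + flood fill + arithmetic, the slow way.

    Returns a list of dicts with n_voxels, volume_ml, suv_mean, suv_max,
    tlg, sorted by smallest member flat index for a deterministic order.
    """
    ni, nj, nk = suv.shape
    candidate = np.zeros(suv.shape, dtype=bool)
    for i in range(ni):
        for j in range(nj):
            for k in range(nk):
                if bone[i, j, k] and suv[i, j, k] > cutoff:
                    candidate[i, j, k] = True

    offsets = _neighbours(connectivity)
    seen = np.zeros(suv.shape, dtype=bool)
    lesions = []
    for i in range(ni):
        for j in range(nj):
            for k in range(nk):
                if not candidate[i, j, k] or seen[i, j, k]:
                    continue
                stack = [(i, j, k)]
                seen[i, j, k] = True
                members = []
                while stack:
                    ci, cj, ck = stack.pop()
                    members.append((ci, cj, ck))
                    for di, dj, dk in offsets:
                        x, y, z = ci + di, cj + dj, ck + dk
                        if 0 <= x < ni and 0 <= y < nj and 0 <= z < nk:
                            if candidate[x, y, z] and not seen[x, y, z]:
                                seen[x, y, z] = True
                                stack.append((x, y, z))
                values = [suv[m] for m in members]
                n = len(members)
                mean = sum(values) / n
                volume = n * voxel_volume_ml
                lesions.append(
                    {
                        "n_voxels": n,
                        "volume_ml": volume,
                        "suv_mean": mean,
                        "suv_max": max(values),
                        "tlg": volume * mean,
                        "min_flat_index": min(
                            m[0] * nj * nk + m[1] * nk + m[2] for m in members
                        ),
                    }
                )
    lesions.sort(key=lambda d: d["min_flat_index"])
    return lesions


def flood_fill_wstlg(suv, bone, cutoff, connectivity=26, voxel_volume_ml=1.0):
    return sum(
        d["tlg"]
        for d in flood_fill_lesions(suv, bone, cutoff, connectivity, voxel_volume_ml)
    )


def sphere_volume_ml(radius_mm: float) -> float:
    return 4.0 / 3.0 * np.pi * radius_mm**3 / 1000.0
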