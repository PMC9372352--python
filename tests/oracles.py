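"""Brute-force reference implementations used only by the tests.

These deliberately trade speed for obviousness (all-pairs distances,
per-voxel tallies, explicit flood fill) and stay independent of the
library code paths they check.
"""

import numpy as np


def brute_min_distances(points_a: np.ndarray, points_b: np.ndarray,
                        spacing) -> np.ndarray:
    """For each row of points_a (voxel indices), the min Euclidean mm
    distance to any row of points_b."""
    sp = np.asarray(spacing, dtype=float)
    diffs = (points_a[:, None, :] - points_b[None, :, :]) * sp
    return np.sqrt((diffs ** 2).sum(axis=2)).min(axis=1)


def brute_hausdorff95(a_mask: np.ndarray, b_mask: np.ndarray, spacing) -> float:
    a = np.argwhere(a_mask)
    b = np.argwhere(b_mask)

    def directed(src, dst):
        d = np.sort(brute_min_distances(src, dst, spacing))
        rank = max(int(np.ceil(0.95 * d.size)), 1)
        return d[rank - 1]

    return max(directed(a, b), directed(b, a))


def flood_fill_components(mask: np.ndarray) -> list[set]:
    """3D connected components (26-neighbourhood) by explicit BFS."""
    mask = np.asarray(mask, dtype=bool)
    offsets = [(dz, dy, dx)
               for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
               if (dz, dy, dx) != (0, 0, 0)]
    remaining = {tuple(v) for v in np.argwhere(mask)}
    comps = []
    while remaining:
        seed = remaining.pop()
        comp, frontier = {seed}, [seed]
        while frontier:
            z, y, x = frontier.pop()
            for dz, dy, dx in offsets:
                nb = (z + dz, y + dy, x + dx)
                if nb in remaining:
                    remaining.discard(nb)
                    comp.add(nb)
                    frontier.append(nb)
        comps.append(comp)
    return comps


def brute_lesion_metrics(pred: np.ndarray, truth: np.ndarray):
    t_comps = flood_fill_components(truth)
    p_comps = flood_fill_components(pred)
    pred_set = {tuple(v) for v in np.argwhere(pred)}
    truth_set = {tuple(v) for v in np.argwhere(truth)}
    if not t_comps and not p_comps:
        return 1.0, 1.0
    detected = sum(1 for c in t_comps if c & pred_set)
    hits = sum(1 for c in p_comps if c & truth_set)
    recall = detected / len(t_comps) if t_comps else float("nan")
    precision = hits / len(p_comps) if p_comps else float("nan")
    if np.isnan(recall) or np.isnan(precision):
        return recall, float("nan")
    if recall + precision == 0:
        return recall, 0.0
    return recall, 2 * recall * precision / (recall + precision)


def nearest_rank_quantile_oracle(values, q) -> float:
    s = sorted(values)
    rank = max(int(np.ceil(q * len(s))), 1)
    return s[rank - 1]


def random_sparse_mask(rng: np.random.Generator, shape, n_voxels: int
                       ) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    idx = rng.choice(np.prod(shape), size=min(n_voxels, np.prod(shape)),
                     replace=False)
    mask.ravel()[idx] = True
    return mask
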