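"""Split-half reliability of group maps.

The cohort is repeatedly split into two equal random halves, the group map
is rebuilt within each half, and the halves' spatial agreement r_h is
measured with the Sørensen (Dice) index -- binary on thresholded maps,
fuzzy (2 sum min / (sum a + sum b)) on probability or membership maps.
Because each half uses only half the subjects, r_h underestimates the
full-cohort reliability; the Spearman-Brown prophecy formula

    R_SB = 2 r_h / (1 + r_h)

projects it back to the full sample size.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Callable, Dict, List, Sequence

import numpy as np
import pandas as pd

__all__ = ["ReliabilityReport", "sorensen", "spearman_brown", "split_half"]


def sorensen(a: np.ndarray, b: np.ndarray, mode: str = "binary") -> float:
    """Sørensen (Dice) overlap of two maps, in [0, 1].

    ``binary``: 2C/(A+B) with A, B the set sizes and C the intersection
    size; maps must be 0/1.  ``fuzzy``: 2 sum min(a, b) / (sum a + sum b)
    for maps with values in [0, 1]; reduces exactly to the binary form on
    0/1 maps.  Two empty maps are defined to overlap perfectly (1.0, with a
    warning) -- agreement on absence.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    if mode == "binary":
        for name, m in (("a", a), ("b", b)):
            if not np.all(np.isin(m, (0.0, 1.0))):
                raise ValueError(f"binary mode requires 0/1 values in map {name}")
        A, B = a.sum(), b.sum()
        C = np.logical_and(a, b).sum()
        if A + B == 0:
            warnings.warn("both maps empty; Sørensen defined as 1.0")
            return 1.0
        return float(2.0 * C / (A + B))
    if mode == "fuzzy":
        if a.min() < 0 or a.max() > 1 or b.min() < 0 or b.max() > 1:
            raise ValueError("fuzzy mode requires values in [0, 1]")
        denom = a.sum() + b.sum()
        if denom == 0:
            warnings.warn("both maps empty; Sørensen defined as 1.0")
            return 1.0
        return float(2.0 * np.minimum(a, b).sum() / denom)
    raise ValueError(f"unknown mode '{mode}'")


def spearman_brown(r_h: float) -> float:
    """Spearman-Brown prophecy: R_SB = 2 r_h / (1 + r_h), for r_h in [0, 1]."""
    if not (0.0 <= r_h <= 1.0):
        raise ValueError(f"r_h must be in [0, 1], got {r_h}")
    return 2.0 * r_h / (1.0 + r_h)


@dataclasses.dataclass
class ReliabilityReport:
    """Per-split, per-map overlap and Spearman-Brown coefficients."""

    entries: pd.DataFrame  # columns: map_id, split, r_h, r_sb
    n_splits: int
    split_seeds: List[int]

    @property
    def mean_r_sb(self) -> float:
        return float(self.entries["r_sb"].mean())

    def summary(self) -> Dict[str, float]:
        g = self.entries["r_sb"]
        return {
            "mean_r_sb": float(g.mean()),
            "min_r_sb": float(g.min()),
            "max_r_sb": float(g.max()),
            "mean_r_h": float(self.entries["r_h"].mean()),
        }

    def per_map(self) -> pd.DataFrame:
        return self.entries.groupby("map_id")[["r_h", "r_sb"]].mean().reset_index()


def split_half(
    cohort_maps: Dict[str, Sequence[np.ndarray]],
    map_builder: Callable[[Sequence[np.ndarray]], np.ndarray],
    n_splits: int = 100,
    seed: int = 0,
    mode: str = "fuzzy",
) -> ReliabilityReport:
    """Split-half reliability over random equal halves of the cohort.

    ``cohort_maps`` maps a map identifier (e.g. a seed label) to the list
    of per-subject maps; ``map_builder`` turns a subset of subject maps
    into one group map (it must be deterministic given the subjects, and in
    fuzzy mode must return values in [0, 1]).  For each split the subjects
    are randomly halved, the two half-cohort group maps are compared with
    the Sørensen index, and the Spearman-Brown formula is applied.
    """
    sizes = {len(v) for v in cohort_maps.values()}
    if len(sizes) != 1:
        raise ValueError("all map lists must cover the same subjects")
    n = sizes.pop()
    if n < 4:
        raise ValueError("need at least 4 subjects")
    if n % 2 != 0:
        raise ValueError(
            f"odd subject count ({n}): drop one subject to form equal halves"
        )
    rng = np.random.default_rng(seed)
    split_seeds = [int(s) for s in rng.integers(0, 2**31, size=n_splits)]
    rows = []
    for split_idx, s in enumerate(split_seeds):
        order = np.random.default_rng(s).permutation(n)
        half_a, half_b = order[: n // 2], order[n // 2 :]
        for map_id, maps in cohort_maps.items():
            ga = map_builder([maps[i] for i in half_a])
            gb = map_builder([maps[i] for i in half_b])
            r_h = sorensen(ga, gb, mode=mode)
            rows.append(
                {
                    "map_id": map_id,
                    "split": split_idx,
                    "r_h": r_h,
                    "r_sb": spearman_brown(r_h),
                }
            )
    return ReliabilityReport(
        entries=pd.DataFrame(rows), n_splits=n_splits, split_seeds=split_seeds
    )
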