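"""Two-stage stratified subsampling shared by the imaging and pERK tables.

Different treatment groups contribute different numbers of fish, and
different fish contribute different numbers of neurons; sampling a fixed
number per fish and then a fixed number per group evens out representation
before pooled spatial or distributional comparisons.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def two_stage_sample(
    df: pd.DataFrame,
    per_fish: int,
    per_group: int | None,
    seed: int,
    fish_col: str = "fish_id",
    group_col: str | None = None,
) -> np.ndarray:
    """Positional indices of a two-stage without-replacement sample.

    Stage 1 draws ``per_fish`` rows from each fish (all rows, with a
    warning, if a fish has fewer). Stage 2 draws ``per_group`` rows from
    each group's stage-1 pool (the whole table is one group when
    ``group_col`` is None); raises if a pool is smaller than ``per_group``.
    Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    pos = np.arange(len(df))

    stage1: list[np.ndarray] = []
    for _, idx in df.groupby(fish_col, sort=True).indices.items():
        idx = np.sort(pos[idx])
        if len(idx) < per_fish:
            warnings.warn(
                f"fish with {len(idx)} rows < per_fish={per_fish}; keeping all",
                stacklevel=2,
            )
            stage1.append(idx)
        else:
            stage1.append(rng.choice(idx, size=per_fish, replace=False))
    pool = np.sort(np.concatenate(stage1)) if stage1 else np.array([], dtype=int)

    if per_group is None:
        return pool

    groups = df.iloc[pool][group_col] if group_col is not None else pd.Series("all", index=pool)
    out: list[np.ndarray] = []
    for name, grp_idx in pd.Series(pool).groupby(groups.to_numpy(), sort=True):
        grp = grp_idx.to_numpy()
        if len(grp) < per_group:
            raise ValueError(
                f"group {name!r} pool of {len(grp)} is smaller than per_group={per_group}"
            )
        out.append(rng.choice(grp, size=per_group, replace=False))
    return np.sort(np.concatenate(out))
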