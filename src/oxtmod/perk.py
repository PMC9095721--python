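"""Normalized pERK quantification and the control-calibrated active-cell rule.

pERK (phosphorylated ERK) intensity in fixed tissue is a proxy for recent
neural activity. Per-cell intensities are normalised to control-fish means
— either pooled over the preoptic (PO) and posterior-tuberculum (PT)
populations or per region — and a cell counts as "active" when its
normalised intensity exceeds the threshold that marks exactly the top
``alpha`` fraction (10% by default) of control cells.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .sampling import two_stage_sample

__all__ = [
    "normalize_perk",
    "active_cell_threshold",
    "ap_distribution",
    "stratified_sample",
    "group_summary",
]


def normalize_perk(
    pt: pd.DataFrame, scheme: str = "pooled_po_pt", control_group: str = "group"
) -> pd.DataFrame:
    """Populate the ``normalized`` column.

    ``pooled_po_pt`` divides every intensity by the mean over all control
    cells (PO and PT combined); ``per_region`` divides by the control mean
    of the cell's own region. The control group's normalised mean is 1 by
    construction (per stratum under ``per_region``). Raises, naming the
    stratum, when a control stratum is empty.
    """
    out = pt.copy()
    ctl = out[out["group"] == control_group]
    if scheme == "pooled_po_pt":
        if ctl.empty:
            raise ValueError(f"empty control stratum: group {control_group!r}")
        out["normalized"] = out["intensity"] / ctl["intensity"].mean()
    elif scheme == "per_region":
        out["normalized"] = np.nan
        for region in out["region"].unique():
            ref = ctl[ctl["region"] == region]
            if ref.empty:
                raise ValueError(
                    f"empty control stratum: group {control_group!r}, region {region!r}"
                )
            mask = out["region"] == region
            out.loc[mask, "normalized"] = (
                out.loc[mask, "intensity"] / ref["intensity"].mean()
            )
    else:
        raise ValueError("scheme must be 'pooled_po_pt' or 'per_region'")
    return out


def active_cell_threshold(
    pt: pd.DataFrame, control_group: str = "group", alpha: float = 0.10
) -> tuple[float, pd.DataFrame]:
    """Control-calibrated activity threshold and per-cell active flags.

    The threshold is the empirical ``1 - alpha`` quantile
    (linear-interpolation convention) of control normalised intensities;
    a cell is active iff its normalised value strictly exceeds it. By
    construction the control active count is ``floor(alpha * n_control)``
    up to ties. Requires >= 10 control cells and a ``normalized`` column.
    """
    if "normalized" not in pt.columns:
        raise ValueError("run normalize_perk first")
    ctl = pt.loc[pt["group"] == control_group, "normalized"].to_numpy()
    if ctl.size < 10:
        raise ValueError(f"need >= 10 control cells, got {ctl.size}")
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    if alpha == 0:
        threshold = np.inf
    else:
        threshold = float(np.quantile(ctl, 1.0 - alpha, method="linear"))
    out = pt.copy()
    out["active"] = out["normalized"] > threshold
    return threshold, out


def ap_distribution(pt: pd.DataFrame, groups=None, bins=10) -> pd.DataFrame:
    """Binned counts of active cells along the anterior-posterior axis.

    ``bins`` follows numpy's histogram convention (count or monotone
    edges). Returns tidy rows (group, bin_left, bin_right, count, density);
    per-group counts sum to the group's active total.
    """
    if "active" not in pt.columns:
        raise ValueError("run active_cell_threshold first")
    act = pt[pt["active"]]
    groups = sorted(act["group"].unique()) if groups is None else list(groups)
    edges = np.histogram_bin_edges(pt["ap_um"], bins=bins)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bins must be monotone")
    rows = []
    for g in groups:
        vals = act.loc[act["group"] == g, "ap_um"]
        counts, _ = np.histogram(vals, bins=edges)
        dens = counts / counts.sum() if counts.sum() else np.zeros_like(counts, dtype=float)
        for i in range(len(counts)):
            rows.append(
                {
                    "group": g,
                    "bin_left": edges[i],
                    "bin_right": edges[i + 1],
                    "count": int(counts[i]),
                    "density": dens[i],
                }
            )
    return pd.DataFrame(rows)


def stratified_sample(
    pt: pd.DataFrame, per_fish: int, per_group: int | None, seed: int = 0
) -> pd.DataFrame:
    """Two-stage without-replacement sample of cells (per fish, then per group)."""
    idx = two_stage_sample(
        pt, per_fish, per_group, seed, fish_col="fish_id", group_col="group"
    )
    return pt.iloc[idx].reset_index(drop=True)


def group_summary(pt: pd.DataFrame, value: str = "normalized") -> pd.DataFrame:
    """Median and IQR per group (the boxplot statistics)."""
    def _s(v: pd.Series) -> pd.Series:
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        return pd.Series({"median": med, "q1": q1, "q3": q3, "iqr": q3 - q1, "n": len(v)})

    out = pt.groupby("group")[value].apply(_s).unstack().reset_index()
    out["n"] = out["n"].astype(int)
    return out
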