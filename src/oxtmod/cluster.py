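"""K-means clustering of neuron x regressor correlation matrices.

Neurons are clustered on their correlation-coefficient vectors (k = 12 for
the headline analyses); BIC/AIC over a spherical-Gaussian approximation of
the k-means solution is provided as a diagnostic for the number of
clusters. Clusters are then grouped into broad activity classes by
explicit rules over their centroid correlations — making reproducible what
is otherwise a by-inspection step.

Broad classes (stimulus axis = correlation with the TRPA1/UV regressor,
motor axis = max correlation with the spontaneous-movement regressors):

====== =============================================================
i_a    strongly stimulus-tuned (r >= 0.5), not motor-correlated
i_b    moderately stimulus-tuned (0.2 <= r < 0.5)
i_c    weakly stimulus-tuned (0.05 <= r < 0.2)
ii_a   stimulus-tuned (r >= 0.5) and motor-correlated (>= 0.2)
ii_b   moderately stimulus-tuned (0.2-0.5) and motor-correlated
iii    primarily motor-correlated (motor >= 0.2, stimulus < 0.2)
iv     unresponsive (everything weak)
v      anticorrelated with the stimulus (r <= -0.2)
====== =============================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = [
    "ClusterModel",
    "fit_kmeans",
    "select_k",
    "cluster_summary",
    "assign_classes",
    "DEFAULT_CLASS_RULES",
]


@dataclass
class ClusterModel:
    k: int
    assignments: np.ndarray  # neuron -> 0-based cluster id
    centroids: np.ndarray  # k x n_regressors
    inertia: float
    seed: int
    n_init: int
    regressor_names: list[str] = field(default_factory=list)
    neuron_ids: np.ndarray | None = None

    def counts(self) -> np.ndarray:
        return np.bincount(self.assignments, minlength=self.k)

    def centroid_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.centroids, columns=self.regressor_names or None)
        df.index.name = "cluster"
        return df

    def assignment_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "neuron_id": self.neuron_ids
                if self.neuron_ids is not None
                else np.arange(len(self.assignments)),
                "cluster": self.assignments,
            }
        )


def _as_matrix(corr) -> tuple[np.ndarray, list[str], np.ndarray | None]:
    if isinstance(corr, pd.DataFrame):
        return corr.to_numpy(dtype=float), list(corr.columns), corr.index.to_numpy()
    x = np.asarray(corr, dtype=float)
    return x, [f"r{j}" for j in range(x.shape[1])], None


def fit_kmeans(corr, k: int = 12, seed: int = 0, n_init: int = 50) -> ClusterModel:
    """Lloyd's algorithm with k-means++ seeding, best of ``n_init`` restarts.

    ``corr`` is a neuron x regressor matrix (DataFrame keeps names and
    neuron ids). Deterministic under ``seed``.
    """
    x, names, ids = _as_matrix(corr)
    if not np.all(np.isfinite(x)):
        raise ValueError("correlation matrix contains non-finite entries")
    if k > x.shape[0]:
        raise ValueError(f"k={k} exceeds number of rows {x.shape[0]}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(x)
    return ClusterModel(
        k=k,
        assignments=km.labels_.astype(int),
        centroids=km.cluster_centers_,
        inertia=float(km.inertia_),
        seed=seed,
        n_init=n_init,
        regressor_names=names,
        neuron_ids=ids,
    )


def _spherical_loglik(x: np.ndarray, model: ClusterModel) -> float:
    """Hard-assignment spherical-Gaussian log-likelihood (X-means form).

    One pooled variance (MLE from the within-cluster sum of squares) plus a
    multinomial cluster-proportion term; without the proportion term every
    split of a single Gaussian would look favourable.
    """
    n, d = x.shape
    k = model.k
    if n <= k:
        raise ValueError("need more points than clusters for the likelihood")
    var = model.inertia / (d * (n - k))
    var = max(var, 1e-12)
    counts = model.counts()
    counts = counts[counts > 0]
    prop_term = float(np.sum(counts * np.log(counts / n)))
    return prop_term - 0.5 * n * d * np.log(2.0 * np.pi * var) - 0.5 * d * (n - k)


def select_k(corr, k_range, seed: int = 0, n_init: int = 10) -> pd.DataFrame:
    """BIC/AIC table over ``k_range`` (never silently picks a k).

    BIC = -2 logL + p log n and AIC = -2 logL + 2p with p = k*d + 1 free
    parameters (centroids plus the pooled variance). Returns one row per
    k with ``bic``, ``aic``, ``inertia`` and boolean argmin flags.
    """
    x, _, _ = _as_matrix(corr)
    n, d = x.shape
    rows = []
    for k in k_range:
        if not 2 <= k <= n - 1:
            raise ValueError(f"k={k} outside 2..{n - 1}")
        model = fit_kmeans(x, k=k, seed=seed, n_init=n_init)
        logl = _spherical_loglik(x, model)
        p = k * d + 1
        rows.append(
            {
                "k": k,
                "loglik": logl,
                "bic": -2.0 * logl + p * np.log(n),
                "aic": -2.0 * logl + 2.0 * p,
                "inertia": model.inertia,
            }
        )
    out = pd.DataFrame(rows)
    out["bic_argmin"] = out["bic"] == out["bic"].min()
    out["aic_argmin"] = out["aic"] == out["aic"].min()
    return out


def cluster_summary(
    model: ClusterModel,
    t=None,
    schedule=None,
    label: str | None = None,
    window=None,
) -> dict:
    """Counts and percentages per cluster, optionally with per-cluster STAs.

    Empty clusters are excluded from the percentages and listed under
    ``empty_clusters``. Percentages sum to 100 over non-empty clusters.
    """
    counts = model.counts()
    nonempty = np.flatnonzero(counts > 0)
    total = counts.sum()
    table = pd.DataFrame(
        {
            "cluster": nonempty,
            "n": counts[nonempty],
            "percent": 100.0 * counts[nonempty] / total,
        }
    )
    out = {"table": table, "empty_clusters": np.flatnonzero(counts == 0).tolist()}
    if t is not None and schedule is not None and label is not None and window is not None:
        from .traces import stimulus_triggered_average

        stas = {}
        for c in nonempty:
            sub = t.select(np.flatnonzero(model.assignments == c))
            stas[int(c)] = stimulus_triggered_average(sub, schedule, label, window)
        out["stas"] = stas
    return out


#: Ordered, exhaustive centroid rules: first match wins. ``stim`` is the
#: centroid's correlation with the stimulus regressor, ``motor`` the max
#: over spontaneous-motor regressors. Band edges: high 0.5, moderate 0.2,
#: weak 0.05, anticorrelated -0.2.
DEFAULT_CLASS_RULES: list[dict] = [
    {"class": "v", "stim_max": -0.2},
    {"class": "ii_a", "stim_min": 0.5, "motor_min": 0.2},
    {"class": "ii_b", "stim_min": 0.2, "motor_min": 0.2},
    {"class": "iii", "motor_min": 0.2},
    {"class": "i_a", "stim_min": 0.5},
    {"class": "i_b", "stim_min": 0.2},
    {"class": "i_c", "stim_min": 0.05},
    {"class": "iv"},
]


def _match_rule(rule: dict, stim: float, motor: float) -> bool:
    if "stim_min" in rule and not stim >= rule["stim_min"]:
        return False
    if "stim_max" in rule and not stim <= rule["stim_max"]:
        return False
    if "motor_min" in rule and not motor >= rule["motor_min"]:
        return False
    if "motor_max" in rule and not motor <= rule["motor_max"]:
        return False
    return True


def assign_classes(
    model: ClusterModel,
    rules: list[dict] | None = None,
    stim_key: str = "stim_uv",
    motor_keys: tuple[str, ...] = ("motor_spon_S", "motor_spon_L", "motor_spon"),
) -> tuple[dict[int, str], pd.DataFrame]:
    """Map each cluster to a broad class via its centroid correlations.

    Returns the cluster -> class map and a per-class fraction table
    (fractions of neurons, not of clusters). Raises if a centroid matches
    no rule — the rule list must be exhaustive.
    """
    rules = DEFAULT_CLASS_RULES if rules is None else rules
    names = model.regressor_names
    if stim_key not in names:
        raise KeyError(f"stimulus regressor {stim_key!r} not among {names}")
    motor_idx = [names.index(m) for m in motor_keys if m in names]
    stim_idx = names.index(stim_key)

    mapping: dict[int, str] = {}
    counts = model.counts()
    for c in range(model.k):
        if counts[c] == 0:
            continue
        stim = float(model.centroids[c, stim_idx])
        motor = float(np.max(model.centroids[c, motor_idx])) if motor_idx else 0.0
        for rule in rules:
            if _match_rule(rule, stim, motor):
                mapping[c] = rule["class"]
                break
        else:
            raise ValueError(
                f"centroid {c} (stim={stim:.3f}, motor={motor:.3f}) matches no rule"
            )

    total = counts.sum()
    class_counts: dict[str, int] = {}
    for c, cls in mapping.items():
        class_counts[cls] = class_counts.get(cls, 0) + int(counts[c])
    fractions = pd.DataFrame(
        {
            "class": sorted(class_counts),
            "n": [class_counts[c] for c in sorted(class_counts)],
        }
    )
    fractions["fraction"] = fractions["n"] / total
    return mapping, fractions
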