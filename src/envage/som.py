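"""Exposure-pattern subpopulations via a self-organizing map (SOM).

A rectangular SOM is trained in batch mode on z-scored exposures: each epoch
assigns every observation to its best-matching unit (BMU) and moves each
codebook vector to the neighborhood-weighted mean of the data, with a
Gaussian neighborhood whose radius decays linearly across epochs.  The
occupied codebook units are then grouped by Ward hierarchical clustering;
the number of subpopulations k is chosen from the within/between sum of
squares of the induced participant partition (WSS/BSS, with
WSS + BSS = TSS), taking the elbow as the largest second difference of
WSS(k)/TSS.  Clusters are named after the exposure family (air pollution,
green space, blue space, noise) with the largest-magnitude mean standardized
exposure; a cluster moderate in everything is the rural-urban fringe.
Aging metrics are finally contrasted against a reference subpopulation
(green space, as the most favourable profile) by covariate-adjusted OLS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist

from .aging_metrics import zscore
from .wqs import build_design

__all__ = [
    "SOMModel",
    "KSelectionResult",
    "SubpopulationAssignment",
    "standardize",
    "train_som",
    "bmu",
    "select_k",
    "assign",
    "name_subpopulations",
    "compare_subpopulations",
    "EXPOSURE_FAMILIES",
]

EXPOSURE_FAMILIES = {
    "air pollution": ("pm10", "pm2_5", "pm_coarse", "no2", "nox"),
    "green space": ("green_300m", "green_1000m"),
    "blue space": ("blue_300m", "blue_1000m"),
    "noise": ("noise_24h", "noise_night"),
}


@dataclass
class SOMModel:
    grid: tuple[int, int]
    codebook: np.ndarray            # (rows*cols) x d
    seed: int
    n_epochs: int
    sigma_start: float
    sigma_end: float
    quantization_errors: list[float] = field(default_factory=list)

    @property
    def unit_coords(self) -> np.ndarray:
        r, c = self.grid
        return np.array([(i, j) for i in range(r) for j in range(c)], dtype=float)


@dataclass
class KSelectionResult:
    k_values: list[int]
    wss: dict[int, float]
    bss: dict[int, float]
    tss: float
    selected_k: int
    unit_labels: dict[int, np.ndarray]   # per k: cluster id per occupied unit
    occupied_units: np.ndarray
    trace: str


@dataclass
class SubpopulationAssignment:
    labels: np.ndarray                  # per-participant cluster id in {1..k}
    names: dict[int, str]
    reference: str

    def named_labels(self) -> np.ndarray:
        return np.asarray([self.names[int(l)] for l in self.labels])


def standardize(X: pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-scoring (sample SD) for SOM distance comparability."""
    return pd.DataFrame({c: zscore(X[c].to_numpy()) for c in X.columns}, index=X.index)


def train_som(
    X,
    grid: tuple[int, int] = (10, 10),
    n_epochs: int = 20,
    seed: int = 0,
    sigma_start: float | None = None,
    sigma_end: float = 0.5,
) -> SOMModel:
    """Batch-train a SOM on standardized data.

    Codebook initialized from a seeded random sample of the data. Each epoch:
    BMU assignment, then codebook update to the Gaussian-neighborhood-
    weighted mean of the observations, with the radius decaying linearly from
    ``sigma_start`` (default max(grid)/2) to ``sigma_end``. Deterministic per
    seed; raises on degenerate (constant) data.
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    units = grid[0] * grid[1]
    if grid[0] < 2 or grid[1] < 2:
        raise ValueError("grid must be at least 2x2")
    if n <= units:
        raise ValueError(f"need more observations ({n}) than SOM units ({units})")
    if np.any(X.std(axis=0) == 0):
        raise ValueError("degenerate data: a column is constant")

    rng = np.random.default_rng(seed)
    codebook = X[rng.choice(n, size=units, replace=False)].copy()
    sigma_start = max(grid) / 2.0 if sigma_start is None else sigma_start

    coords = np.array([(i, j) for i in range(grid[0]) for j in range(grid[1])], dtype=float)
    grid_d2 = cdist(coords, coords, "sqeuclidean")

    model = SOMModel(grid=grid, codebook=codebook, seed=seed, n_epochs=n_epochs,
                     sigma_start=sigma_start, sigma_end=sigma_end)
    dists = cdist(X, codebook)
    model.quantization_errors.append(float(dists.min(axis=1).mean()))

    for epoch in range(n_epochs):
        sigma = sigma_start + (sigma_end - sigma_start) * (epoch / max(n_epochs - 1, 1))
        bmus = dists.argmin(axis=1)
        H = np.exp(-grid_d2 / (2.0 * sigma * sigma))      # units x units
        counts = np.bincount(bmus, minlength=units).astype(float)
        sums = np.zeros((units, d))
        np.add.at(sums, bmus, X)
        numer = H.T @ sums
        denom = H.T @ counts
        nonzero = denom > 0
        codebook[nonzero] = numer[nonzero] / denom[nonzero, None]
        dists = cdist(X, codebook)
        model.quantization_errors.append(float(dists.min(axis=1).mean()))

    model.codebook = codebook
    return model


def bmu(x, model: SOMModel) -> int:
    """Best-matching unit: argmin Euclidean distance; ties -> lowest unit index."""
    d = np.linalg.norm(model.codebook - np.asarray(x, dtype=float), axis=1)
    return int(d.argmin())


def _bmus(X: np.ndarray, model: SOMModel) -> np.ndarray:
    return cdist(np.asarray(X, float), model.codebook).argmin(axis=1)


def _partition_ss(X: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    """(WSS, BSS, TSS) of a partition: Huygens decomposition holds by construction."""
    grand = X.mean(axis=0)
    tss = float(((X - grand) ** 2).sum())
    wss = bss = 0.0
    for lab in np.unique(labels):
        sub = X[labels == lab]
        mu = sub.mean(axis=0)
        wss += float(((sub - mu) ** 2).sum())
        bss += sub.shape[0] * float(((mu - grand) ** 2).sum())
    return wss, bss, tss


def select_k(model: SOMModel, X, k_range=range(2, 9)) -> KSelectionResult:
    """Choose the number of subpopulations from WSS/BSS over candidate k.

    Occupied codebook units are Ward-clustered (empty units carry zero
    weight and are excluded); each candidate k induces a participant
    partition through the BMU map, whose WSS(k)/TSS is evaluated on the
    data. k is the largest second difference (elbow) of that curve; a
    k_range too short for an interior point falls back to the smallest k.
    """
    X = np.asarray(X, dtype=float)
    bmus = _bmus(X, model)
    occupied = np.unique(bmus)
    k_values = [k for k in k_range if 2 <= k <= occupied.size - 1]
    if not k_values:
        raise ValueError("k_range has no feasible values below the occupied-unit count")

    Z = linkage(model.codebook[occupied], method="ward")
    unit_of = {u: i for i, u in enumerate(occupied)}
    ratios, wss_d, bss_d, unit_labels = [], {}, {}, {}
    tss = None
    for k in k_values:
        ulab = fcluster(Z, t=k, criterion="maxclust")
        labels = np.asarray([ulab[unit_of[u]] for u in bmus])
        wss, bss, tss = _partition_ss(X, labels)
        wss_d[k], bss_d[k], unit_labels[k] = wss, bss, ulab
        ratios.append(wss / tss)

    if len(k_values) >= 3:
        # elbow = max curvature of log(WSS/TSS): scale-invariant, so the
        # geometric shrinkage of early drops does not mask the flattening point
        logr = np.log(ratios)
        second_diff = [logr[i - 1] - 2 * logr[i] + logr[i + 1] for i in range(1, len(k_values) - 1)]
        pick = int(np.argmax(second_diff)) + 1
        selected = k_values[pick]
        trace = (f"elbow on log WSS/TSS over k={k_values}: ratios={np.round(ratios, 4).tolist()}, "
                 f"log-curvatures={np.round(second_diff, 4).tolist()} -> k={selected}")
    else:
        selected = k_values[0]
        trace = f"k_range {k_values} too short for an elbow comparison; defaulting to k={selected}"
    return KSelectionResult(k_values=k_values, wss=wss_d, bss=bss_d, tss=float(tss),
                            selected_k=selected, unit_labels=unit_labels,
                            occupied_units=occupied, trace=trace)


def assign(X, model: SOMModel, selection: KSelectionResult, k: int | None = None) -> np.ndarray:
    """Participant labels {1..k}: the Ward cluster of each participant's BMU."""
    k = selection.selected_k if k is None else k
    ulab = selection.unit_labels[k]
    unit_of = {u: i for i, u in enumerate(selection.occupied_units)}
    bmus = _bmus(np.asarray(X, float), model)
    # a BMU unseen at selection time maps to the cluster of the nearest occupied unit
    out = np.empty(bmus.size, dtype=int)
    for i, u in enumerate(bmus):
        if u in unit_of:
            out[i] = ulab[unit_of[u]]
        else:
            d = np.linalg.norm(model.codebook[selection.occupied_units] - model.codebook[u], axis=1)
            out[i] = ulab[int(d.argmin())]
    return out


def name_subpopulations(
    labels: np.ndarray,
    Xz: pd.DataFrame,
    moderate_threshold: float = 0.25,
    reference: str = "green space",
) -> SubpopulationAssignment:
    """Name clusters by their dominant exposure family.

    For each cluster, the mean standardized exposure is averaged within each
    family and centered at the across-cluster median of that family (so a
    single heavy-tailed cluster cannot shift everyone else's apparent
    profile); the family with the largest-magnitude centered mean names the
    cluster. A cluster with every centered family mean below
    ``moderate_threshold`` in magnitude is the "rural-urban fringe".
    Duplicate names get -2, -3... suffixes.
    """
    clusters = np.unique(labels)
    fam_by_cluster: dict[int, dict[str, float]] = {}
    for lab in clusters:
        mean_z = Xz[labels == lab].mean(axis=0)
        fam_by_cluster[int(lab)] = {
            fam: float(np.mean([mean_z[c] for c in cols if c in Xz.columns]))
            for fam, cols in EXPOSURE_FAMILIES.items()
            if any(c in Xz.columns for c in cols)
        }
    # a median "typical profile" needs >= 3 clusters to be meaningful;
    # with fewer, raw means are used directly
    if len(clusters) >= 3:
        fam_median = {
            fam: float(np.median([fam_by_cluster[int(l)][fam] for l in clusters]))
            for fam in fam_by_cluster[int(clusters[0])]
        }
    else:
        fam_median = {fam: 0.0 for fam in fam_by_cluster[int(clusters[0])]}
    names: dict[int, str] = {}
    used: dict[str, int] = {}
    for lab in clusters:
        fam_means = {f: v - fam_median[f] for f, v in fam_by_cluster[int(lab)].items()}
        if all(abs(v) < moderate_threshold for v in fam_means.values()):
            base = "rural-urban fringe"
        else:
            base = max(fam_means, key=lambda f: abs(fam_means[f]))
        used[base] = used.get(base, 0) + 1
        names[int(lab)] = base if used[base] == 1 else f"{base}-{used[base]}"
    if reference not in names.values():
        reference = names[int(np.unique(labels)[0])]
    return SubpopulationAssignment(labels=np.asarray(labels), names=names, reference=reference)


def compare_subpopulations(
    assignment: SubpopulationAssignment,
    cohort: pd.DataFrame,
    outcome: str,
    covariates: list[str] | None = None,
    reference: str | None = None,
) -> pd.DataFrame:
    """Covariate-adjusted OLS contrasts of each subpopulation vs the reference.

    Returns one row per non-reference subpopulation with beta, SE, 95% CI
    (beta +- 1.96 SE) and two-sided p for the group dummy.
    """
    import statsmodels.api as sm

    reference = reference or assignment.reference
    named = assignment.named_labels()
    groups = [g for g in dict.fromkeys(assignment.names.values()) if g != reference]
    y = cohort[outcome].to_numpy(dtype=float)
    C, cov_names = build_design(cohort, covariates or [])
    dummies = np.column_stack([(named == g).astype(float) for g in groups])
    X = np.column_stack([np.ones(y.size), dummies] + ([C] if C is not None else []))
    fit = sm.OLS(y, X).fit()
    rows = []
    for i, g in enumerate(groups):
        b, se = float(fit.params[1 + i]), float(fit.bse[1 + i])
        rows.append({"subpopulation": g, "reference": reference, "beta": b, "se": se,
                     "ci_low": b - 1.959963984540054 * se, "ci_high": b + 1.959963984540054 * se,
                     "p_value": float(fit.pvalues[1 + i]),
                     "n": int((named == g).sum()), "outcome": outcome})
    return pd.DataFrame(rows)
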