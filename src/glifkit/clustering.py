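"""Cell-type clustering on GLIF parameters or ephys features.

Cells are clustered by iterative binary splitting: at each node, candidate
two-way splits come from Ward-linkage agglomerative clustering of the
standardized columns, and a split is accepted only if a linear support
vector machine, trained on a random half of the node's cells over 100
rounds, classifies the held-out half with a minimum accuracy above
threshold (and both children are large enough).  Partitions are compared
with the adjusted Rand index (ARI) and the adjusted variation of
information (AVOI), an information-theoretic score baselined against
shuffled labels: positive values beat chance, 0 is chance, and the upper
bound for n elements is ln(n).

Because only two of the five library decay rates are chosen per cell, the
after-spike currents enter clustering through their total charges
Q_j = delta_I_j / k_j (continuous quantities) rather than their rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import AffinityPropagation
from sklearn.metrics import adjusted_rand_score
from sklearn.svm import SVC

__all__ = [
    "FeatureMatrix",
    "Partition",
    "SplitConfig",
    "build_feature_matrix",
    "iterative_binary_split",
    "affinity_propagation_partition",
    "adjusted_rand_index",
    "variation_of_information",
    "adjusted_variation_of_information",
    "avoi_upper_bound",
    "composition_table",
    "LEVEL_CLUSTER_COLUMNS",
]

#: Parameter columns entering clustering at each GLIF level.  Charges are
#: delta_I_j / k_j; R means R_ASC at the levels fitting after-spike currents.
LEVEL_CLUSTER_COLUMNS = {
    1: ("R", "C", "E_L", "theta_inf", "spike_cut"),
    2: ("R", "C", "E_L", "f_v", "delta_V", "theta_inf", "spike_cut"),
    3: ("R", "C", "E_L", "theta_inf", "spike_cut", "Q1", "Q2"),
    4: ("R", "C", "E_L", "theta_inf", "spike_cut", "f_v", "delta_V", "Q1", "Q2"),
}

#: Strictly positive scale parameters log-transformed before z-scoring.
LOG_COLUMNS = frozenset({"R", "C", "spike_cut", "tau_m", "R_i"})


@dataclass
class FeatureMatrix:
    """Standardized cells-by-parameters table with its transform record."""

    values: np.ndarray  # standardized
    columns: tuple[str, ...]
    cell_ids: tuple
    transforms: dict[str, dict]  # per column: {"log": bool, "mean":, "sd":}
    raw: pd.DataFrame

    def inverse_transform(self) -> pd.DataFrame:
        """Undo standardization (and log), recovering the raw table."""
        out = {}
        for j, col in enumerate(self.columns):
            tr = self.transforms[col]
            x = self.values[:, j] * tr["sd"] + tr["mean"]
            out[col] = np.exp(x) if tr["log"] else x
        return pd.DataFrame(out, index=list(self.cell_ids))


@dataclass
class Partition:
    """Assignment of cells to clusters."""

    labels: np.ndarray
    cell_ids: tuple

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.size != len(self.cell_ids):
            raise ValueError("one label per cell required")

    @property
    def n_clusters(self) -> int:
        return int(np.unique(self.labels).size)

    @property
    def n_cells(self) -> int:
        return int(self.labels.size)


def _params_to_row(params) -> dict:
    q1, q2 = params.total_charges
    return {
        "R": params.R,
        "C": params.C,
        "E_L": params.E_L,
        "theta_inf": params.theta_inf,
        "spike_cut": params.spike_cut,
        "f_v": params.f_v,
        "delta_V": params.delta_V,
        "Q1": q1,
        "Q2": q2,
    }


def build_feature_matrix(
    cells: dict | pd.DataFrame,
    level: int | None = None,
    columns: tuple[str, ...] | None = None,
) -> FeatureMatrix:
    """Assemble and standardize the clustering matrix.

    ``cells`` maps cell ids to fitted GLIFParameters (or is a raw DataFrame
    of feature values).  Columns default to the per-level clustering set;
    strictly positive scale parameters are log-transformed before z-scoring.
    Raises an assembly error naming cells with missing values.
    """
    if isinstance(cells, pd.DataFrame):
        raw = cells.copy()
    else:
        raw = pd.DataFrame({cid: _params_to_row(p) for cid, p in cells.items()}).T
    if columns is None:
        if level is None:
            columns = tuple(raw.columns)
        else:
            if level not in LEVEL_CLUSTER_COLUMNS:
                raise ValueError(f"no clustering column set for level {level}")
            columns = LEVEL_CLUSTER_COLUMNS[level]
    missing_cols = [c for c in columns if c not in raw.columns]
    if missing_cols:
        raise ValueError(f"missing columns for clustering: {missing_cols}")
    sub = raw.loc[:, list(columns)]
    bad = sub.index[sub.isna().any(axis=1)].tolist()
    if bad:
        raise ValueError(f"cells with missing values: {bad}")

    values = np.empty(sub.shape)
    transforms = {}
    for j, col in enumerate(columns):
        x = sub[col].to_numpy(dtype=float)
        use_log = col in LOG_COLUMNS and np.all(x > 0)
        if use_log:
            x = np.log(x)
        mean = x.mean()
        sd = x.std()
        if sd <= 1e-10 * max(abs(mean), 1e-30):  # constant up to rounding
            sd = 1.0
            x = np.full_like(x, mean)
        values[:, j] = (x - mean) / sd
        transforms[col] = {"log": use_log, "mean": float(mean), "sd": float(sd)}
    return FeatureMatrix(
        values=values,
        columns=tuple(columns),
        cell_ids=tuple(sub.index),
        transforms=transforms,
        raw=sub,
    )


@dataclass
class SplitConfig:
    linkage_method: str = "ward"
    accept_threshold: float = 0.90  # minimum-of-rounds test accuracy
    min_cluster_size: int = 5
    n_validation_rounds: int = 100
    seed: int = 0
    max_depth: int = 10


def _validate_split(
    x: np.ndarray, y: np.ndarray, config: SplitConfig, rng: np.random.Generator
) -> float:
    """Minimum held-out accuracy of a linear SVM over random half splits."""
    n = x.shape[0]
    worst = 1.0
    for _ in range(config.n_validation_rounds):
        perm = rng.permutation(n)
        half = n // 2
        train, test = perm[:half], perm[half:]
        if np.unique(y[train]).size < 2:
            worst = 0.0
            break
        clf = SVC(kernel="linear")
        clf.fit(x[train], y[train])
        acc = float((clf.predict(x[test]) == y[test]).mean())
        worst = min(worst, acc)
        if worst < config.accept_threshold:
            break
    return worst


def iterative_binary_split(
    matrix: FeatureMatrix, config: SplitConfig | None = None
) -> tuple[Partition, dict]:
    """Recursive two-way Ward splits with SVM node validation.

    Each candidate split is accepted only if the minimum test accuracy over
    ``n_validation_rounds`` random half/half train/test rounds reaches the
    threshold and both children meet the minimum cluster size; leaves of the
    accepted splits form the partition.  Degenerate input yields one cluster.
    """
    config = config or SplitConfig()
    rng = np.random.default_rng(config.seed)
    x = matrix.values
    labels = np.zeros(x.shape[0], dtype=int)
    node_scores: dict[str, float] = {}
    next_label = [1]

    def split(idx: np.ndarray, node: str, depth: int) -> None:
        if depth >= config.max_depth or idx.size < 2 * config.min_cluster_size:
            return
        sub = x[idx]
        if np.allclose(sub.var(axis=0), 0):
            return
        z = linkage(sub, method=config.linkage_method)
        cand = fcluster(z, t=2, criterion="maxclust") - 1
        sizes = np.bincount(cand, minlength=2)
        if sizes.min() < config.min_cluster_size:
            return
        score = _validate_split(sub, cand, config, rng)
        node_scores[node] = score
        if score < config.accept_threshold:
            return
        left = idx[cand == 0]
        right = idx[cand == 1]
        labels[right] = next_label[0]
        next_label[0] += 1
        split(left, node + "0", depth + 1)
        split(right, node + "1", depth + 1)

    split(np.arange(x.shape[0]), "r", 0)
    # compact labels
    _, labels = np.unique(labels, return_inverse=True)
    return Partition(labels=labels, cell_ids=matrix.cell_ids), node_scores


def affinity_propagation_partition(
    matrix: FeatureMatrix, seed: int = 0, **kwargs
) -> Partition:
    """Exemplar-based clustering backend behind the same Partition contract."""
    ap = AffinityPropagation(random_state=seed, **kwargs)
    labels = ap.fit_predict(matrix.values)
    return Partition(labels=labels, cell_ids=matrix.cell_ids)


def _check_same_cells(p: Partition, q: Partition) -> None:
    if p.cell_ids != q.cell_ids:
        raise ValueError("partitions must cover the same cells in the same order")


def adjusted_rand_index(p: Partition, q: Partition) -> float:
    """Chance-corrected pairwise agreement: 1 = identical, ~0 = chance."""
    _check_same_cells(p, q)
    return float(adjusted_rand_score(p.labels, q.labels))


def _entropy_and_mi(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Natural-log entropies H(a), H(b) and mutual information I(a, b)."""
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    ka = ai.max() + 1
    kb = bi.max() + 1
    joint = np.bincount(ai * kb + bi, minlength=ka * kb).astype(float)
    joint /= joint.sum()
    pa = joint.reshape(ka, kb).sum(axis=1)
    pb = joint.reshape(ka, kb).sum(axis=0)

    def h(p):
        p = p[p > 0]
        return -(p * np.log(p)).sum()

    hj = h(joint)
    ha, hb = h(pa), h(pb)
    return float(ha), float(hb), float(ha + hb - hj)


def variation_of_information(p: Partition | np.ndarray, q: Partition | np.ndarray) -> float:
    """VI(p, q) = H(p) + H(q) - 2 I(p, q), in nats."""
    a = p.labels if isinstance(p, Partition) else np.asarray(p)
    b = q.labels if isinstance(q, Partition) else np.asarray(q)
    if isinstance(p, Partition) and isinstance(q, Partition):
        _check_same_cells(p, q)
    if a.size != b.size:
        raise ValueError("label vectors must have equal length")
    if a.size == 0:
        raise ValueError("empty partitions")
    ha, hb, mi = _entropy_and_mi(a, b)
    return ha + hb - 2.0 * mi


def adjusted_variation_of_information(
    p: Partition | np.ndarray,
    q: Partition | np.ndarray,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> float:
    """Shuffled-baseline-corrected VI, in nats.

    AVOI = mean over shuffles of VI(p, shuffled q) - VI(p, q): positive means
    the partitions predict each other better than chance, 0 is chance level.
    The attainable upper bound grows with the number of elements as ln(n)
    (see :func:`avoi_upper_bound`).
    """
    a = p.labels if isinstance(p, Partition) else np.asarray(p)
    b = q.labels if isinstance(q, Partition) else np.asarray(q)
    if isinstance(p, Partition) and isinstance(q, Partition):
        _check_same_cells(p, q)
    if a.size == 0:
        raise ValueError("empty partitions")
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be positive")
    rng = np.random.default_rng(seed)
    vi = variation_of_information(a, b)
    baseline = np.mean(
        [variation_of_information(a, rng.permutation(b)) for _ in range(n_shuffles)]
    )
    return float(baseline - vi)


def avoi_upper_bound(n: int) -> float:
    """Largest attainable AVOI for a clustering of n elements: ln(n) nats."""
    if n <= 0:
        raise ValueError("n must be positive")
    return float(np.log(n))


def composition_table(
    p: Partition, labels: dict | pd.Series
) -> pd.DataFrame:
    """Fraction of cells of each label falling into each cluster.

    Rows are clusters, columns labels (e.g. transgenic-line-style tags);
    each column sums to 1.
    """
    lab = pd.Series(labels)
    missing = [c for c in p.cell_ids if c not in lab.index]
    if missing:
        raise ValueError(f"unlabeled cells: {missing}")
    df = pd.DataFrame(
        {"cluster": p.labels, "label": lab.loc[list(p.cell_ids)].to_numpy()}
    )
    counts = pd.crosstab(df["cluster"], df["label"])
    return counts / counts.sum(axis=0)
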