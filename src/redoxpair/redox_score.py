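"""Weighted rank-correlation composite score for redox-active disulphides.

Each candidate cysteine pair k carries descriptors x_ik.  On a labelled
training set (pairs known to form redox-dependent disulphides vs pairs known
not to), each descriptor receives a Spearman correlation r_i with the class
label (positive = 1).  Highly inter-correlated descriptors
(|Spearman| >= 0.80 pairwise, by default) are grouped; within a group,
weights w_i are proportional to the descriptor's variance and sum to 1, so a
group contributes like a single descriptor; ungrouped descriptors have
w_i = 1.  The raw score is

    S_k = sum_i  w_i * r_i * x_ik

and is reported as a percentage Redox Score after min-max normalisation over
the scored set:

    RedoxScore_k = 100 * (S_k - S_min) / (S_max - S_min).

Descriptors are min-max scaled to [0, 1] on the training ranges before
weighting (raw descriptor units span three orders of magnitude; without a
commensurate scale the B-factor column would dominate the sum).  A ``raw``
mode applying the weights to unscaled values is available.

Missing descriptor values are imputed with training medians and flagged.
Within a group, descriptor columns that are identical after scaling share a
single variance-weight slot, split equally among the copies, so duplicating
a column never changes any S_k.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig, DEFAULT_CONFIG
from .descriptors import DESCRIPTOR_NAMES

__all__ = [
    "TrainingExample",
    "ScoreModel",
    "ScoredPair",
    "spearman_r",
    "group_descriptors",
    "fit_score_model",
    "score_dataset",
    "compare_groups",
    "descriptor_comparison_table",
]

_POSITIVE_TOKENS = {"positive", "pos", "1", "true", "yes"}
_NEGATIVE_TOKENS = {"negative", "neg", "0", "false", "no"}


@dataclass
class TrainingExample:
    key: tuple
    descriptors: dict[str, float | None]
    label: int  # 1 positive, 0 negative


def parse_label(value) -> int:
    if isinstance(value, (bool, np.bool_)):
        return int(value)
    if isinstance(value, (int, np.integer, float, np.floating)):
        if value in (0, 1):
            return int(value)
        raise ValueError(f"label must be 0/1, got {value!r}")
    token = str(value).strip().lower()
    if token in _POSITIVE_TOKENS:
        return 1
    if token in _NEGATIVE_TOKENS:
        return 0
    raise ValueError(f"unrecognised class label {value!r}")


def spearman_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Tie-corrected Spearman correlation (Pearson on average ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors with >= 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


# ---------------------------------------------------------------------------
# grouping and fitting


def group_descriptors(
    table: pd.DataFrame, threshold: float = 0.80
) -> tuple[list[list[str]], list[str]]:
    """Partition descriptor columns into inter-correlation groups.

    Groups are the connected components of the graph whose edges join
    descriptor pairs with |pairwise Spearman| >= ``threshold``.  Constant
    columns are treated as uncorrelated with everything (singletons) and
    returned as flagged.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    names = list(table.columns)
    if len(names) < 2:
        return [names], []
    constants = [n for n in names if np.all(table[n].to_numpy() == table[n].iloc[0])]
    g = nx.Graph()
    g.add_nodes_from(names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if a in constants or b in constants:
                continue
            rho = stats.spearmanr(table[a], table[b]).statistic
            if np.isfinite(rho) and abs(rho) >= threshold:
                g.add_edge(a, b)
    components = [sorted(c, key=names.index) for c in nx.connected_components(g)]
    components.sort(key=lambda c: names.index(c[0]))
    return components, constants


@dataclass
class ScoreModel:
    descriptor_names: list[str]
    r: dict[str, float]
    groups: list[list[str]]
    w: dict[str, float]
    scale_ranges: dict[str, tuple[float, float]]
    impute_values: dict[str, float]
    s_min: float | None = None
    s_max: float | None = None
    frozen: bool = False
    scaled: bool = True
    constant_descriptors: list[str] = field(default_factory=list)
    schema_version: int = 1

    def to_json(self) -> str:
        d = {
            "schema_version": self.schema_version,
            "descriptor_names": self.descriptor_names,
            "r": self.r,
            "groups": self.groups,
            "w": self.w,
            "scale_ranges": {k: list(v) for k, v in self.scale_ranges.items()},
            "impute_values": self.impute_values,
            "s_min": self.s_min,
            "s_max": self.s_max,
            "frozen": self.frozen,
            "scaled": self.scaled,
            "constant_descriptors": self.constant_descriptors,
        }
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ScoreModel":
        d = json.loads(text)
        if d.get("schema_version") != 1:
            raise ValueError(f"unsupported model schema {d.get('schema_version')!r}")
        return cls(
            descriptor_names=d["descriptor_names"],
            r=d["r"],
            groups=d["groups"],
            w=d["w"],
            scale_ranges={k: tuple(v) for k, v in d["scale_ranges"].items()},
            impute_values=d["impute_values"],
            s_min=d["s_min"],
            s_max=d["s_max"],
            frozen=d["frozen"],
            scaled=d["scaled"],
            constant_descriptors=d.get("constant_descriptors", []),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "ScoreModel":
        return cls.from_json(Path(path).read_text())

    @property
    def content_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def _to_frame(
    training, descriptor_names: Sequence[str] | None
) -> tuple[pd.DataFrame, np.ndarray]:
    if isinstance(training, pd.DataFrame):
        if "label" not in training.columns:
            raise ValueError("training table needs a 'label' column")
        labels = np.array([parse_label(v) for v in training["label"]])
        names = list(descriptor_names or [c for c in training.columns if c != "label"])
        return training[names].astype(float).copy(), labels
    rows = []
    labels_list = []
    for ex in training:
        rows.append(ex.descriptors)
        labels_list.append(parse_label(ex.label))
    df = pd.DataFrame(rows)
    names = list(descriptor_names or df.columns)
    return df[names].astype(float), np.array(labels_list)


def _impute(df: pd.DataFrame, medians: dict[str, float]) -> pd.DataFrame:
    out = df.copy()
    for name in out.columns:
        out[name] = out[name].fillna(medians[name])
    return out


def _scale(df: pd.DataFrame, ranges: dict[str, tuple[float, float]]) -> pd.DataFrame:
    out = df.copy()
    for name in out.columns:
        lo, hi = ranges[name]
        if hi > lo:
            out[name] = (out[name] - lo) / (hi - lo)
        else:
            out[name] = 0.0  # constant on the training range
    return out


def _identity_clusters(group: list[str], table: pd.DataFrame) -> list[list[str]]:
    """Cluster columns of a group that are numerically identical."""
    clusters: list[list[str]] = []
    for name in group:
        col = table[name].to_numpy()
        for cluster in clusters:
            if np.allclose(col, table[cluster[0]].to_numpy(), rtol=0.0, atol=1e-12):
                cluster.append(name)
                break
        else:
            clusters.append([name])
    return clusters


def _group_weights(
    groups: list[list[str]], table: pd.DataFrame
) -> dict[str, float]:
    """Variance-proportional weights within a group, summing to 1 per group.

    Identical columns share one variance slot split equally, which makes the
    score invariant to duplicating any descriptor column.
    """
    w: dict[str, float] = {}
    for group in groups:
        if len(group) == 1:
            w[group[0]] = 1.0
            continue
        clusters = _identity_clusters(group, table)
        variances = np.array(
            [float(np.var(table[c[0]].to_numpy())) for c in clusters]
        )
        total = variances.sum()
        if total == 0.0:
            warnings.warn(
                f"zero-variance descriptor group {group}; splitting weight equally",
                stacklevel=3,
            )
            shares = np.full(len(clusters), 1.0 / len(clusters))
        else:
            shares = variances / total
        for cluster, share in zip(clusters, shares):
            for name in cluster:
                w[name] = float(share / len(cluster))
    return w


def fit_score_model(
    training,
    config: RunConfig = DEFAULT_CONFIG,
    descriptor_names: Sequence[str] | None = None,
) -> ScoreModel:
    """Fit the score model on labelled examples.

    ``training`` is a DataFrame with descriptor columns and a ``label``
    column, or a list of :class:`TrainingExample`.  Requires >= 3 examples
    with both classes present.
    """
    df, labels = _to_frame(training, descriptor_names)
    if len(df) < 3:
        raise ValueError("need at least 3 training examples")
    if labels.min() == labels.max():
        raise ValueError("training set must contain both positive and negative examples")

    medians: dict[str, float] = {}
    for name in df.columns:
        observed = df[name].dropna()
        if observed.empty:
            raise ValueError(f"descriptor {name!r} has no observed training values")
        medians[name] = float(observed.median())
    imputed = _impute(df, medians)

    ranges = {
        name: (float(imputed[name].min()), float(imputed[name].max()))
        for name in imputed.columns
    }
    table = _scale(imputed, ranges) if config.scale_descriptors else imputed

    r: dict[str, float] = {}
    constants: list[str] = []
    for name in table.columns:
        col = table[name].to_numpy()
        if np.all(col == col[0]):
            r[name] = 0.0
            constants.append(name)
        else:
            r[name] = spearman_r(col, labels)

    groups, const_in_grouping = group_descriptors(
        table, threshold=config.group_threshold
    )
    w = _group_weights(groups, table)

    model = ScoreModel(
        descriptor_names=list(df.columns),
        r=r,
        groups=groups,
        w=w,
        scale_ranges=ranges,
        impute_values=medians,
        scaled=config.scale_descriptors,
        constant_descriptors=sorted(set(constants) | set(const_in_grouping)),
    )
    s = _raw_scores(model, df)
    if float(s.max()) == float(s.min()):
        raise ValueError(
            "degenerate training set: all raw scores identical (S_max == S_min)"
        )
    model.s_min = float(s.min())
    model.s_max = float(s.max())
    return model


def _raw_scores(model: ScoreModel, df: pd.DataFrame) -> np.ndarray:
    unknown = set(df.columns) - set(model.descriptor_names) - {"label"}
    missing_cols = set(model.descriptor_names) - set(df.columns)
    if missing_cols:
        raise ValueError(f"scoring table lacks descriptors {sorted(missing_cols)}")
    if unknown:
        raise ValueError(f"unknown descriptor columns {sorted(unknown)}")
    values = df[model.descriptor_names].astype(float)
    values = _impute(values, model.impute_values)
    if model.scaled:
        values = _scale(values, model.scale_ranges)
    s = np.zeros(len(values))
    for name in model.descriptor_names:
        s += model.w[name] * model.r[name] * values[name].to_numpy()
    return s


@dataclass
class ScoredPair:
    key: tuple
    raw_score: float
    redox_score: float


def score_dataset(
    model: ScoreModel, table: pd.DataFrame, freeze: bool = False
) -> pd.DataFrame:
    """Score a candidate table; returns a copy with raw_score and redox_score.

    On the first (non-frozen) application, S_min/S_max are set to the
    extremes of this scored set and persisted on the model; subsequent
    scoring against a frozen model clamps the percentage to [0, 100].
    """
    feature_cols = [c for c in table.columns if c in model.descriptor_names]
    s = _raw_scores(model, table[feature_cols])
    if not freeze and not model.frozen:
        model.s_min = float(s.min())
        model.s_max = float(s.max())
        model.frozen = True
    if model.s_min is None or model.s_max is None:
        raise ValueError("model has no S_min/S_max; score a dataset first")
    span = model.s_max - model.s_min
    if span <= 0:
        raise ValueError("degenerate score normalisation (S_max == S_min)")
    redox = 100.0 * (s - model.s_min) / span
    out = table.copy()
    out["raw_score"] = s
    out["redox_score"] = np.clip(redox, 0.0, 100.0)
    return out


# ---------------------------------------------------------------------------
# group comparisons (evaluation)


def compare_groups(
    values_a: Sequence[float], values_b: Sequence[float], test: str = "welch_t"
) -> tuple[float, float]:
    """Two-sided comparison of two groups.

    ``welch_t``: Welch's unequal-variance t-test (Welch-Satterthwaite df).
    ``mann_whitney_u``: Mann-Whitney U with normal approximation and tie
    correction (no continuity correction).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if test == "welch_t":
        if a.size < 2 or b.size < 2:
            raise ValueError("Welch's t-test needs >= 2 values per group")
        res = stats.ttest_ind(a, b, equal_var=False)
        t = float(res.statistic)
        p = float(res.pvalue)
        if a.size == b.size and np.allclose(np.sort(a), np.sort(b)) and np.isnan(t):
            return 0.0, 1.0
        return t, p
    if test == "mann_whitney_u":
        if a.size < 1 or b.size < 1:
            raise ValueError("Mann-Whitney U needs >= 1 value per group")
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test {test!r}")


def descriptor_comparison_table(
    table: pd.DataFrame,
    labels: Sequence,
    descriptor_names: Sequence[str] = DESCRIPTOR_NAMES,
    test: str = "welch_t",
) -> pd.DataFrame:
    """Per-descriptor positive-vs-negative comparison (evaluation report)."""
    y = np.array([parse_label(v) for v in labels])
    rows = []
    for name in descriptor_names:
        if name not in table.columns:
            continue
        col = table[name].astype(float)
        a = col[y == 1].dropna().to_numpy()
        b = col[y == 0].dropna().to_numpy()
        stat, p = compare_groups(a, b, test=test)
        rows.append(
            {
                "descriptor": name,
                "n_positive": a.size,
                "n_negative": b.size,
                "mean_positive": a.mean() if a.size else np.nan,
                "mean_negative": b.mean() if b.size else np.nan,
                "statistic": stat,
                "p_value": p,
                "test": test,
            }
        )
    return pd.DataFrame(rows)
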