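"""Feature ranking and incremental feature selection (IFS).

High-dimensional fused encodings carry redundant and noisy coordinates.
The selection protocol is two-stage: (1) rank all features by importance —
the built-in rankers are gradient-boosting gain (total impurity decrease
attributed to splits on a feature over the ensemble) and the one-way
ANOVA F statistic; (2) walk the ranked list, evaluating nested top-i
subsets by cross-validation, and pick the smallest subset attaining the
maximal fitness (F-measure by default).

Both rankers break score ties by ascending original column index so that
rankings are fully reproducible. Other rankers (ReliefF, LinearSVR weights,
XGBoost importance) can be plugged in: any callable producing a
:class:`RankedFeatureList` fits the IFS stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import CVResult, MetricsBundle, cross_validate, default_classifier


@dataclass(frozen=True)
class RankedFeatureList:
    """Feature names ordered by non-increasing importance."""

    names: tuple[str, ...]
    scores: tuple[float, ...]
    ranker: str

    def __post_init__(self) -> None:
        if len(self.names) != len(self.scores):
            raise ValueError("names and scores must align")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate feature names in ranking")
        finite = [s for s in self.scores if np.isfinite(s)]
        if any(b > a + 1e-12 for a, b in zip(finite, finite[1:])):
            raise ValueError("scores must be non-increasing")

    def top(self, i: int) -> tuple[str, ...]:
        return self.names[:i]

    def __len__(self) -> int:
        return len(self.names)


def _as_frame(X, feature_names=None) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(X.shape[1])]
    return pd.DataFrame(X, columns=list(feature_names))


def _check_y(y) -> np.ndarray:
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels are degenerate (single class)")
    return y


def _order(scores: np.ndarray) -> np.ndarray:
    # descending score, ties by ascending original column index
    return np.lexsort((np.arange(len(scores)), -scores))


def rank_by_gain(X, y, classifier=None, feature_names=None,
                 seed: int = 0) -> RankedFeatureList:
    """Rank features by total gain in one boosted ensemble fit on all of X.

    The default ranking model is the package's 100-iteration LightGBM
    classifier with a fixed seed; pass ``classifier`` to override its
    hyperparameters.
    """
    df = _as_frame(X, feature_names)
    y = _check_y(y)
    if classifier is None:
        classifier = default_classifier(seed=seed)
    model = classifier
    model.fit(df.to_numpy(), y)
    gains = np.asarray(
        model.booster_.feature_importance(importance_type="gain"), dtype=float
    )
    order = _order(gains)
    return RankedFeatureList(
        names=tuple(df.columns[i] for i in order),
        scores=tuple(gains[order]),
        ranker="gain",
    )


def rank_by_anova(X, y, feature_names=None) -> RankedFeatureList:
    """Rank features by the one-way ANOVA F statistic between classes.

    A feature with zero within-group variance but distinct group means has
    infinite F and ranks first; an all-constant feature scores 0.
    """
    df = _as_frame(X, feature_names)
    y = _check_y(y)
    V = df.to_numpy(dtype=float)
    n, _ = V.shape
    classes = np.unique(y)
    grand = V.mean(axis=0)
    ss_between = np.zeros(V.shape[1])
    ss_within = np.zeros(V.shape[1])
    for c in classes:
        g = V[y == c]
        ss_between += len(g) * (g.mean(axis=0) - grand) ** 2
        ss_within += ((g - g.mean(axis=0)) ** 2).sum(axis=0)
    df_between = len(classes) - 1
    df_within = n - len(classes)
    msb = ss_between / df_between
    msw = ss_within / df_within
    with np.errstate(divide="ignore", invalid="ignore"):
        F = msb / msw
    F[(msw == 0) & (msb > 0)] = np.inf
    F[(msw == 0) & (msb == 0)] = 0.0
    order = _order(F)
    return RankedFeatureList(
        names=tuple(df.columns[i] for i in order),
        scores=tuple(F[order]),
        ranker="anova",
    )


@dataclass(frozen=True)
class IFSCurve:
    """Per-subset-size CV metrics along a ranked feature list.

    ``optimum_index`` points into ``sizes``; the optimum is the smallest
    subset size attaining the maximal fitness (preferring fewer features
    on ties).
    """

    sizes: tuple[int, ...]
    bundles: tuple[MetricsBundle, ...]
    fitness_metric: str
    optimum_index: int
    ranker: str

    @property
    def optimum_size(self) -> int:
        return self.sizes[self.optimum_index]

    @property
    def optimum_bundle(self) -> MetricsBundle:
        return self.bundles[self.optimum_index]

    @property
    def fitness_values(self) -> tuple[float, ...]:
        return tuple(b[self.fitness_metric] for b in self.bundles)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([b.as_dict() for b in self.bundles])
        df.insert(0, "n_features", self.sizes)
        return df

    def write_tsv(self, path) -> None:
        df = self.to_frame()
        df.columns = ["n_features", "ACC", "Recall", "Precision", "MCC", "F-measure"]
        df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def pick_optimum(fitness_values) -> int:
    """Index of the first maximizer (ties resolve to fewer features)."""
    values = list(fitness_values)
    if not values:
        raise ValueError("empty fitness sequence")
    best = max(values)
    return values.index(best)


def run_ifs(ranked: RankedFeatureList, X, y, classifier=None,
            k: int = 10, seed: int = 0, step: int = 1,
            max_size: int | None = None,
            fitness_metric: str = "f_measure",
            aggregate: str = "pooled") -> IFSCurve:
    """Evaluate nested top-i feature subsets by k-fold CV.

    Subset sizes run i = step, 2·step, ... up to ``max_size`` (clipped to
    the ranking length with a warning if larger). Every evaluation reuses
    the same CV seed so curves are comparable across subset sizes and fully
    reproducible.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    df = _as_frame(X)
    missing = [n for n in ranked.names if n not in df.columns]
    if missing:
        raise ValueError(f"ranked features absent from X: {missing[:5]}")
    limit = len(ranked)
    if max_size is not None:
        if max_size > limit:
            warnings.warn(
                f"max_size={max_size} exceeds the {limit} ranked features; clipping"
            )
        limit = min(max_size, limit)

    sizes = list(range(step, limit + 1, step))
    bundles: list[MetricsBundle] = []
    for i in sizes:
        cols = list(ranked.top(i))
        res: CVResult = cross_validate(
            df[cols].to_numpy(), y, classifier=classifier, k=k, seed=seed
        )
        bundles.append(res.pooled if aggregate == "pooled" else res.macro)

    opt = pick_optimum([b[fitness_metric] for b in bundles])
    return IFSCurve(
        sizes=tuple(sizes),
        bundles=tuple(bundles),
        fitness_metric=fitness_metric,
        optimum_index=opt,
        ranker=ranked.ranker,
    )


def plot_ifs_curve(curve: IFSCurve, path=None, metrics=("accuracy", "f_measure")):
    """Render the IFS curve (metric vs. subset size); returns the figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for m in metrics:
        ax.plot(curve.sizes, [b[m] for b in curve.bundles], label=m)
    ax.axvline(curve.optimum_size, color="grey", linestyle="--",
               label=f"optimum ({curve.optimum_size})")
    ax.set_xlabel("number of top-ranked features")
    ax.set_ylabel("cross-validated metric")
    ax.set_title(f"IFS curve ({curve.ranker} ranking)")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
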