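"""Feature ranking by mRMR and prefix selection by IFS.

Relevance and redundancy are measured with the plug-in (maximum-likelihood)
discrete mutual information in nats:

    I(X; Y) = sum_{x,y} p(x, y) ln[ p(x, y) / (p(x) p(y)) ],   0·ln 0 = 0,

over the empirical joint distribution. REO profiles are already discrete
(ternary {1, 0, -1}), so no discretisation or bias correction is applied.

The mRMR objective — maximal relevance to the phenotype with minimal
redundancy to already-chosen features — is realised by the standard greedy
incremental "difference" scheme (MID): the first feature maximises
I(g, T); each next feature g maximises

    I(g, T) - (1/|S|) * sum_{s in S} I(g, s)

over the selected set S. Ties break lexicographically on pair id, so the
ranking is fully deterministic.

IFS (incremental feature selection) then evaluates stratified k-fold
cross-validated SVM accuracy on growing prefixes of the ranking and picks
the smallest prefix attaining the maximum accuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .io import SampleLabels
from .reo import REOProfile
from .svm import SvmConfig, train


def mutual_information(feature: np.ndarray, labels: np.ndarray) -> float:
    """Plug-in discrete mutual information in nats.

    Both arguments are treated as categorical; values may be any hashable
    integers (ternary codes, 0/1 labels, ...). Returns a non-negative float,
    0 for a constant input or empirical independence.
    """
    x = np.asarray(feature).ravel()
    y = np.asarray(labels).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    n = x.shape[0]
    if n == 0:
        raise ValueError("need at least one sample")
    xs, xi = np.unique(x, return_inverse=True)
    ys, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((xs.size, ys.size))
    np.add.at(joint, (xi, yi), 1.0)
    joint /= n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    mi = 0.0
    for i in range(xs.size):
        for j in range(ys.size):
            p = joint[i, j]
            if p > 0.0:
                mi += p * math.log(p / (px[i] * py[j]))
    return max(mi, 0.0)  # clip tiny negative rounding residue


@dataclass
class RankedFeatures:
    """mRMR-ordered pair ids with the greedy selection score at each step."""

    pair_ids: list[str]
    scores: list[float]

    def __post_init__(self) -> None:
        if len(self.pair_ids) != len(self.scores):
            raise ValueError("pair_ids and scores length mismatch")
        if len(set(self.pair_ids)) != len(self.pair_ids):
            raise ValueError("duplicate pair ids in ranking")

    def __len__(self) -> int:
        return len(self.pair_ids)

    def write_tsv(self, path) -> None:
        import pandas as pd

        genes = [p.split("|") for p in self.pair_ids]
        pd.DataFrame(
            {
                "rank": np.arange(1, len(self) + 1),
                "gene_a": [g[0] for g in genes],
                "gene_b": [g[1] for g in genes],
                "selection_score": self.scores,
            }
        ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def _aligned_labels(profile: REOProfile, labels: SampleLabels) -> np.ndarray:
    aligned = labels.subset(profile.sample_ids)
    return aligned.labels.astype(int)


def mrmr_rank(profile: REOProfile, labels: SampleLabels) -> RankedFeatures:
    """Rank all profile features by greedy mRMR (difference form).

    Requires both classes present. Returns a permutation of the profile's
    pair ids together with the greedy objective value at each selection.
    """
    y = _aligned_labels(profile, labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present for mRMR ranking")
    X = profile.values
    ids = list(profile.pair_ids)
    n_feat = len(ids)

    relevance = np.array([mutual_information(X[i], y) for i in range(n_feat)])
    remaining = list(range(n_feat))
    selected: list[int] = []
    scores: list[float] = []
    # redundancy_sum[i] accumulates sum over selected s of I(g_i, g_s)
    redundancy_sum = np.zeros(n_feat)

    while remaining:
        if not selected:
            objective = {i: relevance[i] for i in remaining}
        else:
            k = len(selected)
            objective = {i: relevance[i] - redundancy_sum[i] / k for i in remaining}
        # deterministic: max objective, ties by lexicographic pair id
        best = min(remaining, key=lambda i: (-objective[i], ids[i]))
        selected.append(best)
        scores.append(float(objective[best]))
        remaining.remove(best)
        if remaining:
            for i in remaining:
                redundancy_sum[i] += mutual_information(X[i], X[best])
    return RankedFeatures([ids[i] for i in selected], scores)


@dataclass
class IFSResult:
    """Accuracy curve over ranking prefixes and the chosen signature."""

    ks: list[int]
    accuracies: list[float]
    chosen_k: int
    signature: list[str]
    folds: int = 5
    seed: int = 0

    @property
    def peak_accuracy(self) -> float:
        return max(self.accuracies)

    def write_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"k": self.ks, "cv_accuracy": self.accuracies}).to_csv(
            path, sep="\t", index=False, float_format="%.10g"
        )

    def plot(self, path) -> None:
        """Render the accuracy-vs-prefix-size curve."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(self.ks, self.accuracies, "-o", ms=3, color="tab:blue")
        ax.axvline(self.chosen_k, color="tab:red", ls="--", lw=1,
                   label=f"chosen k = {self.chosen_k}")
        ax.set_xlabel("number of top-ranked gene pairs")
        ax.set_ylabel(f"{self.folds}-fold CV accuracy")
        ax.set_ylim(0, 1.05)
        ax.legend()
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def ifs_select(
    ranked: RankedFeatures,
    profile: REOProfile,
    labels: SampleLabels,
    folds: int = 5,
    step: int = 1,
    seed: int = 0,
    cfg: SvmConfig | None = None,
) -> IFSResult:
    """Incremental feature selection over mRMR ranking prefixes.

    For k = step, 2·step, ..., |ranked| the stratified ``folds``-fold
    cross-validated accuracy of the SVM on the top-k features is computed
    with one shared fold split (seeded), and the smallest k attaining the
    maximum accuracy is chosen. The final prefix |ranked| is always
    evaluated even when step does not divide it.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if step < 1:
        raise ValueError("step must be >= 1")
    cfg = cfg or SvmConfig()
    y = _aligned_labels(profile, labels)
    n_minority = int(min((y == 1).sum(), (y == 0).sum()))
    if folds > n_minority:
        raise ValueError(
            f"{folds} folds exceed the minority class size {n_minority}"
        )
    prof = profile.restrict(ranked.pair_ids)
    X = prof.values.T.astype(float)  # samples × features
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    split = list(splitter.split(X, y))  # identical folds reused across all k

    ks = list(range(step, len(ranked) + 1, step))
    if ks[-1] != len(ranked):
        ks.append(len(ranked))
    accuracies = []
    for k in ks:
        correct = 0
        for train_idx, test_idx in split:
            model = _fit_raw(X[train_idx, :k], y[train_idx], cfg)
            pred = model.predict(X[test_idx, :k])
            correct += int((pred == y[test_idx]).sum())
        accuracies.append(correct / len(y))
    best = max(accuracies)
    chosen_k = ks[int(np.argmax(np.asarray(accuracies) >= best))]
    return IFSResult(
        ks=ks,
        accuracies=accuracies,
        chosen_k=chosen_k,
        signature=ranked.pair_ids[:chosen_k],
        folds=folds,
        seed=seed,
    )


def _fit_raw(X: np.ndarray, y: np.ndarray, cfg: SvmConfig):
    """Fit the RBF SVM on a plain numeric array (internal CV helper)."""
    from sklearn.svm import SVC

    clf = SVC(kernel="rbf", C=cfg.C, gamma=cfg.gamma)
    clf.fit(X, y)
    return clf
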