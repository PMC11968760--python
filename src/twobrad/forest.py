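"""Random-forest discrimination between the two study groups.

Covers the marker-selection workflow: variable-importance ranking, a
cross-validation error curve over nested top-k feature sets (with the
ranking recomputed inside every training fold, so the curve is honest under
the null), the per-sample probability of disease (POD, out-of-bag vote
fraction for the disease class), and ROC/AUC by pair counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import StratifiedKFold

from .stats import wilcoxon_two_group
from .tables import AbundanceMatrix


@dataclass(frozen=True)
class ClassifierConfig:
    n_trees: int = 500
    cv_folds: int = 5
    cv_repeats: int = 10
    candidate_pool: int = 30   # top-k abundant taxa entering selection
    positive_group: str | None = None  # disease class; default: first label sorted
    pod_form: str = "fraction"         # "fraction" (votes_M share) or "odds"
    pod_test: str = "permutation"      # "permutation" (calibrated) or "wilcoxon"
    pod_permutations: int = 99
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.n_trees < 1 or self.cv_repeats < 1 or self.candidate_pool < 1:
            raise ValueError("n_trees, cv_repeats and candidate_pool must be positive")


@dataclass
class ClassifierReport:
    importance: pd.Series            # taxon -> importance, descending
    cv_curve: pd.Series              # set size -> mean CV error
    selected_markers: list[str]
    pod: pd.Series                   # sample -> POD
    pod_group_p: float
    auc: float
    roc: pd.DataFrame = field(default_factory=pd.DataFrame)


def _design(matrix: AbundanceMatrix, config: ClassifierConfig,
            taxa: list[str] | None = None):
    groups = matrix.group_labels()
    if len(groups) != 2:
        raise ValueError("classifier requires exactly two groups")
    pos = config.positive_group or groups[0]
    if pos not in groups:
        raise ValueError(f"positive_group {pos!r} not among {groups}")
    taxa = taxa if taxa is not None else matrix.top_taxa(
        min(config.candidate_pool, len(matrix.taxon_ids)))
    X = matrix.values[taxa].to_numpy(dtype=float)
    y = (matrix.groups == pos).to_numpy().astype(int)
    if min((y == 1).sum(), (y == 0).sum()) < 3:
        raise ValueError("each group needs at least 3 samples")
    return X, y, taxa, pos


def _forest(config: ClassifierConfig, seed: int, oob: bool = False) -> RandomForestClassifier:
    return RandomForestClassifier(n_estimators=config.n_trees, random_state=seed,
                                  oob_score=oob, bootstrap=True)


def _effective_folds(config: ClassifierConfig, y: np.ndarray) -> int:
    # stratified folds cannot exceed the smaller class size
    return min(config.cv_folds, int((y == 1).sum()), int((y == 0).sum()))


def rank_importance(matrix: AbundanceMatrix, config: ClassifierConfig) -> pd.Series:
    """Permutation importance of the candidate-pool taxa, descending.

    Deterministic given ``config.seed``.
    """
    X, y, taxa, _ = _design(matrix, config)
    rf = _forest(config, config.seed).fit(X, y)
    imp = permutation_importance(rf, X, y, n_repeats=10, random_state=config.seed)
    s = pd.Series(imp.importances_mean, index=taxa)
    return s.sort_values(ascending=False, kind="mergesort")


def select_markers(matrix: AbundanceMatrix, config: ClassifierConfig,
                   sizes: list[int] | None = None
                   ) -> tuple[pd.Series, list[str]]:
    """Cross-validation error curve over nested top-s feature sets.

    Within every training fold the features are re-ranked (by the training
    forest's impurity importances) before the top-s subset is evaluated on
    the held-out fold -- ranking outside the folds would leak selection into
    the error estimate.  The selected set is the top-s* features of the
    full-data *impurity* ranking (the same criterion the folds optimise;
    permutation importance can vanish for redundant discriminative features
    and would pick arbitrarily), where s* is the smallest size attaining the
    minimum mean error (parsimony tie-break).
    """
    X, y, taxa, _ = _design(matrix, config)
    p = X.shape[1]
    sizes = sorted(set(sizes)) if sizes else list(range(1, p + 1))
    if any(s < 1 or s > p for s in sizes):
        raise ValueError("sizes must lie in [1, candidate_pool]")

    rng = np.random.default_rng(config.seed)
    folds = _effective_folds(config, y)
    errors = {s: [] for s in sizes}
    for rep in range(config.cv_repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=int(rng.integers(2**31)))
        for train, test in skf.split(X, y):
            ranker = _forest(config, int(rng.integers(2**31))).fit(X[train], y[train])
            order = np.argsort(ranker.feature_importances_)[::-1]
            for s in sizes:
                cols = order[:s]
                clf = _forest(config, int(rng.integers(2**31)))
                clf.fit(X[train][:, cols], y[train])
                pred = clf.predict(X[test][:, cols])
                errors[s].append(float(np.mean(pred != y[test])))

    curve = pd.Series({s: float(np.mean(errors[s])) for s in sizes}).sort_index()
    best_size = int(curve.index[np.flatnonzero(curve.values == curve.min())[0]])
    full = _forest(config, config.seed).fit(X, y)
    order = np.argsort(full.feature_importances_)[::-1]
    selected = [taxa[i] for i in order[:best_size]]
    return curve, selected


def _oob_vote_fraction(X: np.ndarray, y: np.ndarray, group_labels: np.ndarray,
                       config: ClassifierConfig) -> np.ndarray:
    """Out-of-bag disease-vote fraction from a stratified-bootstrap forest.

    Each tree resamples every group to its own size, so class balance is
    identical in every bootstrap.  A plain bootstrap leaves an out-of-bag
    sample's class under-represented in the trees that judge it, biasing OOB
    votes against the sample's own label even on uninformative features;
    stratification removes that artifact, which matters at cohort sizes of
    tens of samples.  Groups are iterated in sorted label order, so the
    ensemble is identical under relabeling and POD maps exactly to 1 - POD.
    """
    from sklearn.tree import DecisionTreeClassifier

    rng = np.random.default_rng(config.seed)
    n = len(y)
    by_group = [np.flatnonzero(group_labels == g) for g in sorted(set(group_labels))]
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    votes_pos = np.zeros(n)
    votes_tot = np.zeros(n)
    for _ in range(config.n_trees):
        boot = np.concatenate([
            idx[rng.integers(0, len(idx), size=len(idx))] for idx in by_group
        ])
        mask = np.ones(n, dtype=bool)
        mask[boot] = False
        oob = np.flatnonzero(mask)
        tree_seed = int(rng.integers(2**31))
        if len(oob) == 0:
            continue
        tree = DecisionTreeClassifier(max_features="sqrt", random_state=tree_seed)
        tree.fit(X32[boot], y[boot], check_input=False)
        pred = tree.predict(X32[oob], check_input=False)
        votes_pos[oob] += pred == 1
        votes_tot[oob] += 1
    if (votes_tot == 0).any():
        raise RuntimeError("some samples have no out-of-bag trees; increase n_trees")
    return votes_pos / votes_tot


def _pod_scores(frac: np.ndarray, form: str) -> np.ndarray:
    if form == "fraction":
        return frac
    if form == "odds":
        with np.errstate(divide="ignore"):
            return np.where(frac < 1.0, frac / (1.0 - frac), np.inf)
    raise ValueError("pod_form must be 'fraction' or 'odds'")


def pod(matrix: AbundanceMatrix, selected_markers: list[str],
        config: ClassifierConfig) -> tuple[pd.Series, float]:
    """Per-sample probability of disease and the between-group p-value.

    POD of a sample is the fraction of out-of-bag trees voting the disease
    class (``pod_form="odds"`` reports the literal vote odds M:H instead,
    unbounded when no tree votes H).  The group comparison uses the rank-sum
    statistic; because every sample's POD depends on the *other* samples'
    labels (the forest was trained on them), the theoretical rank-test null
    is invalid, so by default the statistic is calibrated by refitting the
    forest under label permutations (``pod_test="permutation"``).
    ``pod_test="wilcoxon"`` reports the plain two-sided rank-test p instead.
    """
    if not selected_markers:
        raise ValueError("selected_markers must be non-empty")
    X, y, _, posname = _design(matrix, config, taxa=list(selected_markers))
    group_labels = matrix.groups.to_numpy()
    frac = _oob_vote_fraction(X, y, group_labels, config)
    pod_series = pd.Series(_pod_scores(frac, config.pod_form),
                           index=matrix.sample_ids)

    # Tie-free test statistic: the centred rank-sum (U is integer-valued, so
    # permutations tie frequently) broken lexicographically by the continuous
    # vote-mean difference, with a per-sample jitter removing vote-fraction
    # ties.  Both refinements are part of the statistic and identical for the
    # observed and permuted fits, so the permutation test remains exact while
    # its mid-p becomes lattice-uniform.
    jitter = np.linspace(0.0, 1e-9, len(y))

    def rank_stat(votes: np.ndarray, yy: np.ndarray) -> float:
        v = votes + jitter
        u, _ = wilcoxon_two_group(v[yy == 1], v[yy == 0])
        primary = abs(u - (yy == 1).sum() * (yy == 0).sum() / 2.0)
        return primary + 1e-6 * abs(v[yy == 1].mean() - v[yy == 0].mean())

    u_obs, p_wilcoxon = wilcoxon_two_group(frac[y == 1], frac[y == 0])
    if config.pod_test == "wilcoxon":
        return pod_series, float(p_wilcoxon)
    if config.pod_test != "permutation":
        raise ValueError("pod_test must be 'permutation' or 'wilcoxon'")

    obs = rank_stat(frac, y)
    rng = np.random.default_rng(config.seed + 7)
    greater = equal = 0
    for _ in range(config.pod_permutations):
        perm = rng.permutation(len(y))
        sub = ClassifierConfig(**{**config.__dict__,
                                  "seed": int(rng.integers(2**31))})
        frac_p = _oob_vote_fraction(X, y[perm], group_labels[perm], sub)
        stat = rank_stat(frac_p, y[perm])
        if stat > obs + 1e-12:
            greater += 1
        elif stat >= obs - 1e-12:
            equal += 1
    # mid-p: half-weight for ties (incl. the observed statistic itself), which
    # keeps the discrete permutation p close to uniform under the null
    p = (greater + 0.5 * (equal + 1)) / (config.pod_permutations + 1)
    return pod_series, float(p)


def roc_auc(scores, labels) -> tuple[pd.DataFrame, float]:
    """ROC points and AUC by concordant-pair counting (ties count 1/2).

    ``labels`` are truthy for the positive class.  The AUC equals the
    Mann-Whitney U statistic scaled by 1/(n_pos * n_neg).
    """
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels).astype(bool)
    pos, neg = s[lab], s[~lab]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    greater = (pos[:, None] > neg[None, :]).sum()
    equal = (pos[:, None] == neg[None, :]).sum()
    auc = (greater + 0.5 * equal) / (len(pos) * len(neg))

    thresholds = np.concatenate([[np.inf], np.unique(s)[::-1]])
    points = [
        {"threshold": float(t),
         "fpr": float((neg >= t).mean()),
         "tpr": float((pos >= t).mean())}
        for t in thresholds
    ]
    return pd.DataFrame(points), float(auc)


def cross_validated_auc(matrix: AbundanceMatrix, selected_markers: list[str],
                        config: ClassifierConfig) -> float:
    """Mean out-of-fold AUC of the selected-marker forest over CV repeats."""
    X, y, _, _ = _design(matrix, config, taxa=list(selected_markers))
    rng = np.random.default_rng(config.seed + 1)
    folds = _effective_folds(config, y)
    aucs = []
    for rep in range(config.cv_repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=int(rng.integers(2**31)))
        oof = np.zeros(len(y))
        for train, test in skf.split(X, y):
            clf = _forest(config, int(rng.integers(2**31))).fit(X[train], y[train])
            pos_col = list(clf.classes_).index(1)
            oof[test] = clf.predict_proba(X[test])[:, pos_col]
        _, auc = roc_auc(oof, y)
        aucs.append(auc)
    return float(np.mean(aucs))


def classify(matrix: AbundanceMatrix, config: ClassifierConfig,
             sizes: list[int] | None = None) -> ClassifierReport:
    """Full workflow: rank, select by CV curve, POD, cross-validated AUC."""
    importance = rank_importance(matrix, config)
    curve, selected = select_markers(matrix, config, sizes=sizes)
    pod_series, pod_p = pod(matrix, selected, config)
    auc = cross_validated_auc(matrix, selected, config)
    roc_df, _ = roc_auc(pod_series.to_numpy(),
                        (matrix.groups == (config.positive_group
                                           or matrix.group_labels()[0])).to_numpy())
    return ClassifierReport(importance=importance, cv_curve=curve,
                            selected_markers=selected, pod=pod_series,
                            pod_group_p=pod_p, auc=auc, roc=roc_df)
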