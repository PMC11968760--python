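"""Two-group inference: power, Wilcoxon differential abundance, Spearman
co-occurrence, and LEfSe-style LDA effect-size scoring.

The study design these serve is a two-arm comparison (disease group M vs
comparison group H) of per-sample taxon abundance profiles.  Raw p-values
are the primary output (mirroring how such tables are conventionally
reported); Benjamini-Hochberg q-values are computed alongside but do not
drive filtering by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from statsmodels.stats.multitest import multipletests

from .tables import AbundanceMatrix


@dataclass(frozen=True)
class PowerParams:
    """Inputs to the two-sample normal-approximation sample-size formula."""

    z_alpha: float = 1.96   # two-sided alpha = 0.05
    z_beta: float = 0.84    # power = 0.80
    sigma: float = 1.0      # pooled standard deviation
    delta: float = 1.0      # difference in means (effect size)

    def __post_init__(self) -> None:
        if min(self.z_alpha, self.z_beta, self.sigma, self.delta) <= 0:
            raise ValueError("all power parameters must be positive")


def required_sample_size(params: PowerParams) -> float:
    """Per-group n for a two-sample comparison of means, equal variances.

    n1 = n2 = 2 * ((z_alpha + z_beta) * sigma / delta)^2, returned unrounded.
    """
    return 2.0 * ((params.z_alpha + params.z_beta) * params.sigma / params.delta) ** 2


def sample_size_report(params: PowerParams) -> dict[str, float]:
    n = required_sample_size(params)
    return {"n": n, "n_one_decimal": round(n, 1), "n_ceiling": float(np.ceil(n))}


# ---------------------------------------------------------------------------
# Rank tests

_EXACT_LIMIT = 16  # total n at or below which the exact null distribution is used


def _has_ties(x, y) -> bool:
    pooled = np.concatenate([x, y])
    return len(np.unique(pooled)) < len(pooled)


def wilcoxon_two_group(x, y, paired: bool = False) -> tuple[float, float]:
    """Two-sided rank test between two groups; returns (statistic, p).

    Unpaired (default): Mann-Whitney U, exact when m+n <= 16 and tie-free,
    otherwise the tie-corrected normal approximation with continuity
    correction.  ``paired=True`` runs the signed-rank test on differences
    (requires equal lengths).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    if paired:
        if len(x) != len(y):
            raise ValueError("paired test requires equal group sizes")
        d = x - y
        if np.all(d == 0):
            return 0.0, 1.0
        res = sps.wilcoxon(x, y)
        return float(res.statistic), float(res.pvalue)
    if np.array_equal(np.sort(x), np.sort(y)):
        # identical multisets: U at its null mean, no evidence either way
        return len(x) * len(y) / 2.0, 1.0
    ties = _has_ties(x, y)
    if np.unique(np.concatenate([x, y])).size == 1:
        return len(x) * len(y) / 2.0, 1.0
    method = "exact" if (len(x) + len(y) <= _EXACT_LIMIT and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def differential_abundance(
    matrix: AbundanceMatrix,
    alpha: float = 0.05,
    adjust: str = "bh",
    scale: float = 100.0,
) -> pd.DataFrame:
    """Per-taxon two-group Wilcoxon comparison of abundances.

    Returns one row per taxon, ascending p: group mean abundances (on the
    ``scale`` of choice, default percent), the U statistic, raw p, BH q
    (when ``adjust="bh"``), the enriched group (larger mean), and whether
    the taxon passes p < alpha.
    """
    groups = matrix.group_labels()
    if len(groups) != 2:
        raise ValueError("differential abundance requires exactly two groups")
    a, b = groups
    split = matrix.split()
    rows = []
    for taxon in matrix.taxon_ids:
        x = split[a][taxon].to_numpy()
        y = split[b][taxon].to_numpy()
        u, p = wilcoxon_two_group(x, y)
        mx, my = float(x.mean()), float(y.mean())
        rows.append({
            "taxon": taxon,
            f"mean_{a}": mx * scale,
            f"mean_{b}": my * scale,
            "U": u,
            "p": p,
            "direction": a if mx > my else (b if my > mx else "none"),
        })
    out = pd.DataFrame(rows)
    if adjust == "bh":
        out["q"] = multipletests(out["p"].values, method="fdr_bh")[1]
    elif adjust != "none":
        raise ValueError("adjust must be 'bh' or 'none'")
    out["significant"] = out["p"] < alpha
    return out.sort_values(["p", "taxon"], kind="mergesort").reset_index(drop=True)


def spearman_matrix(matrix: AbundanceMatrix, top_k: int = 30
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman correlation among the top_k most abundant taxa.

    Returns (rho, p) DataFrames; ties are handled by average ranks and the
    diagonal is exactly 1 / 0.
    """
    if len(matrix.sample_ids) < 3:
        raise ValueError("Spearman correlation requires at least 3 samples")
    taxa = matrix.top_taxa(min(top_k, len(matrix.taxon_ids)))
    sub = matrix.values[taxa]
    # Pearson correlation of average ranks == Spearman with tie handling;
    # constant taxa have undefined correlation (NaN off-diagonal).
    rho = sub.rank(axis=0).corr(method="pearson")
    k = len(taxa)
    p = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            xi, xj = sub.iloc[:, i], sub.iloc[:, j]
            if xi.nunique() < 2 or xj.nunique() < 2:
                p[i, j] = p[j, i] = np.nan
                continue
            p[i, j] = p[j, i] = sps.spearmanr(xi, xj).pvalue
    np.fill_diagonal(p, 0.0)
    rho_arr = rho.to_numpy()
    np.fill_diagonal(rho_arr, 1.0)
    return (pd.DataFrame(rho_arr, index=taxa, columns=taxa),
            pd.DataFrame(p, index=taxa, columns=taxa))


# ---------------------------------------------------------------------------
# LEfSe-style LDA effect size

CPM = 1e6  # per-sample rescaling convention for effect sizes


def lefse(
    matrix: AbundanceMatrix,
    alpha: float = 0.05,
    lda_threshold: float = 2.0,
    n_boot: int = 30,
    seed: int = 0,
) -> pd.DataFrame:
    """Kruskal-Wallis screen followed by bootstrapped LDA effect sizing.

    Abundances are first rescaled per sample to sum to 1e6 (per-million
    convention).  Features with KW p < alpha proceed to the effect-size
    stage: in each of ``n_boot`` iterations, 2/3 of the samples of each
    group are subsampled, a shrinkage LDA is fitted on the surviving
    features, and each feature's effect is the mean of (a) its contribution
    to the projected class-mean difference and (b) its raw class-mean
    difference.  The reported score is log10(1 + mean |effect|) and features
    with score >= lda_threshold are returned, per enriched group, descending.
    """
    groups = matrix.group_labels()
    if len(groups) != 2:
        raise ValueError("lefse requires exactly two groups")
    a, b = groups
    labels = matrix.groups
    for g in groups:
        if (labels == g).sum() < 3:
            raise ValueError(f"group {g!r} has fewer than 3 samples; "
                             "bootstrap LDA is undefined")

    vals = matrix.values.to_numpy(dtype=float)
    row_sums = vals.sum(axis=1, keepdims=True)
    if (row_sums <= 0).any():
        raise ValueError("every sample must have positive total abundance")
    cpm = vals / row_sums * CPM

    taxa = np.asarray(matrix.taxon_ids)
    ia = np.flatnonzero((labels == a).to_numpy())
    ib = np.flatnonzero((labels == b).to_numpy())

    kw_p = np.ones(len(taxa))
    for j in range(len(taxa)):
        xa, xb = cpm[ia, j], cpm[ib, j]
        if np.unique(np.concatenate([xa, xb])).size == 1:
            continue
        kw_p[j] = sps.kruskal(xa, xb).pvalue
    survivors = np.flatnonzero(kw_p < alpha)
    if survivors.size == 0:
        return _empty_lefse_frame()

    rng = np.random.default_rng(seed)
    sub = cpm[:, survivors]
    na, nb = max(len(ia) * 2 // 3, 2), max(len(ib) * 2 // 3, 2)
    effects = np.zeros((n_boot, survivors.size))
    for it in range(n_boot):
        sa = rng.choice(ia, size=na, replace=False)
        sb = rng.choice(ib, size=nb, replace=False)
        X = np.vstack([sub[sa], sub[sb]])
        y = np.array([0] * na + [1] * nb)
        dm = sub[sb].mean(axis=0) - sub[sa].mean(axis=0)  # b minus a
        try:
            lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
            lda.fit(X, y)
            w = lda.coef_.ravel()
            norm = np.linalg.norm(w)
            w = w / norm if norm > 0 else w
            proj = float(w @ dm)
            contrib = w * proj
        except Exception:  # degenerate subsample; fall back to raw difference
            contrib = dm
        effects[it] = (contrib + dm) / 2.0

    score = np.log10(1.0 + np.abs(effects).mean(axis=0))
    mean_a = cpm[ia][:, survivors].mean(axis=0)
    mean_b = cpm[ib][:, survivors].mean(axis=0)
    enriched = np.where(mean_b > mean_a, b, a)

    keep = score >= lda_threshold
    out = pd.DataFrame({
        "taxon": taxa[survivors][keep],
        "kw_p": kw_p[survivors][keep],
        "lda_score": score[keep],
        "enriched_group": enriched[keep],
    })
    return out.sort_values(["enriched_group", "lda_score"],
                           ascending=[True, False], kind="mergesort"
                           ).reset_index(drop=True)


def _empty_lefse_frame() -> pd.DataFrame:
    return pd.DataFrame(columns=["taxon", "kw_p", "lda_score", "enriched_group"])
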