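"""Non-parametric cohort statistics for steatosis analysis.

Implements the analysis a hepatology morphometry study runs on a patient
table: mFPA bracket categorisation (<5 / 5-9.9 / 10-19.9 / >=20 %),
Spearman rank correlations, Mann-Whitney U and Kruskal-Wallis tests, and
ROC curves for transaminases as predictors of steatosis thresholds.

scipy.stats provides the test statistics and large-sample p-values; exact
small-sample Spearman p-values and Monte-Carlo Kruskal-Wallis p-values are
computed by explicit (seeded) permutation here.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "BRACKET_LABELS",
    "BRACKET_EDGES",
    "RocCurve",
    "categorize_mfpa",
    "categorize_mfpa_series",
    "spearman",
    "mann_whitney",
    "kruskal_wallis",
    "roc",
    "sensitivity_specificity",
    "cohort_report",
    "DEFAULT_CUTOFFS_U_L",
]

#: mFPA bracket edges (%): boundaries are assigned upward, so 5.0 falls in
#: the 5-9.9 bracket — steatosis being conventionally defined as >5% fat
#: with 5% as the first steatotic category floor.
BRACKET_EDGES = (5.0, 10.0, 20.0)
BRACKET_LABELS = ("<5", "5-9.9", "10-19.9", ">=20")

#: Default transaminase cut-offs (U/L) at which sensitivity/specificity are
#: reported: 31 and 33 are conventional upper normal limits for AST and ALT;
#: 41, 67 and 75 are higher working cut-offs.
DEFAULT_CUTOFFS_U_L = (31.0, 33.0, 41.0, 67.0, 75.0)

#: Variables correlated with mFPA and compared across brackets.
ANALYSIS_VARIABLES = ("alt_u_l", "ast_u_l", "ha_um2", "lr_um", "hpl")

EXACT_SPEARMAN_MAX_N = 9
EXACT_MANN_WHITNEY_MAX_N = 14


def categorize_mfpa(mfpa_pct: float) -> str:
    """Bracket label for one mFPA percentage; boundaries go upward."""
    if not 0.0 <= mfpa_pct <= 100.0:
        raise ValueError(f"mfpa_pct must lie in [0, 100], got {mfpa_pct}")
    if mfpa_pct < BRACKET_EDGES[0]:
        return BRACKET_LABELS[0]
    if mfpa_pct < BRACKET_EDGES[1]:
        return BRACKET_LABELS[1]
    if mfpa_pct < BRACKET_EDGES[2]:
        return BRACKET_LABELS[2]
    return BRACKET_LABELS[3]


def categorize_mfpa_series(mfpa_pct: Sequence[float]) -> pd.Categorical:
    """Vectorised bracket assignment preserving bracket order."""
    values = np.asarray(mfpa_pct, dtype=float)
    if ((values < 0) | (values > 100)).any():
        raise ValueError("all mfpa_pct values must lie in [0, 100]")
    labels = [categorize_mfpa(v) for v in values]
    return pd.Categorical(labels, categories=list(BRACKET_LABELS), ordered=True)


def _pairwise_complete(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rs_obs: float) -> float:
    """Two-sided exact permutation p for Spearman's rs at small n.

    Enumerates all n! pairings of the rank vectors (vectorised); ties are
    handled through average ranks, so the statistic is Pearson's r on ranks.
    """
    n = x.size
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    perms = np.array(list(itertools.permutations(range(n))), dtype=np.intp)
    permuted = rx[perms]  # (n!, n)
    ry_c = ry - ry.mean()
    pc = permuted - permuted.mean(axis=1, keepdims=True)
    denom = np.sqrt((pc**2).sum(axis=1) * (ry_c**2).sum())
    rs_all = (pc @ ry_c) / denom
    return float(np.mean(np.abs(rs_all) >= abs(rs_obs) - 1e-12))


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Ties get average ranks.  For n <= 9 the p-value is exact (full
    permutation enumeration); above that it uses the t approximation.
    Missing values are dropped pairwise.
    """
    x, y = _pairwise_complete(x, y)
    n = x.size
    if n < 3:
        raise ValueError(f"spearman requires at least 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: an input vector is constant")
    res = sps.spearmanr(x, y)
    rs = float(res.statistic)
    if n <= EXACT_SPEARMAN_MAX_N:
        p = _exact_spearman_p(x, y, rs)
    else:
        p = float(res.pvalue)
    return rs, p


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U for group a, p).

    Tie-free samples with a combined size of at most 14 get the exact null
    distribution; otherwise the normal approximation with tie and
    continuity corrections is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (tie_free and pooled.size <= EXACT_MANN_WHITNEY_MAX_N) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(
    groups: Sequence[Sequence[float]],
    monte_carlo: bool = False,
    n_resamples: int = 9999,
    seed: int = 0,
) -> tuple[float, float]:
    """Kruskal-Wallis H test across three or more groups.

    Default p-value is the chi-square approximation with k-1 degrees of
    freedom (ties corrected).  ``monte_carlo=True`` replaces it with a
    seeded permutation p-value, useful at small group sizes.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    groups = [g[~np.isnan(g)] for g in groups]
    if len(groups) < 3:
        raise ValueError("kruskal_wallis needs at least 3 groups; use mann_whitney for 2")
    if any(g.size == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    h, p = sps.kruskal(*groups)
    h = float(h)
    if not monte_carlo:
        return h, float(p)

    rng = np.random.default_rng(seed)
    pooled = np.concatenate(groups)
    sizes = [g.size for g in groups]
    edges = np.cumsum(sizes)[:-1]
    count = 0
    for _ in range(n_resamples):
        perm = rng.permutation(pooled)
        h_perm, _ = sps.kruskal(*np.split(perm, edges))
        if h_perm >= h - 1e-12:
            count += 1
    return h, (1 + count) / (1 + n_resamples)


@dataclass(frozen=True)
class RocCurve:
    """ROC threshold sweep for a score predicting a binary label.

    The positive call convention is ``score >= threshold``; thresholds run
    from +inf (nothing called positive) down through every unique score, so
    sensitivity rises from 0 to 1 while specificity falls from 1 to 0.
    ``auroc`` is the trapezoidal area, which equals the tie-adjusted
    concordance probability P(score+ > score-) + 0.5 P(equal).
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auroc: float


def roc(scores: Sequence[float], labels: Sequence[int]) -> RocCurve:
    """ROC curve and AUROC with higher scores predicting the positive label."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    keep = ~np.isnan(scores)
    scores, labels = scores[keep], labels[keep]
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both label classes must be present")

    thresholds = np.r_[np.inf, np.unique(scores)[::-1]]
    pos_scores = np.sort(scores[labels])
    neg_scores = np.sort(scores[~labels])
    # at threshold t: positive call iff score >= t
    tp = n_pos - np.searchsorted(pos_scores, thresholds, side="left")
    fp = n_neg - np.searchsorted(neg_scores, thresholds, side="left")
    sens = tp / n_pos
    spec = (n_neg - fp) / n_neg
    fpr = 1.0 - spec
    auroc = float(np.trapezoid(sens, fpr))
    return RocCurve(thresholds=thresholds, sensitivity=sens, specificity=spec, auroc=auroc)


def sensitivity_specificity(
    scores: Sequence[float], labels: Sequence[int], cutoff: float
) -> tuple[float, float]:
    """Sensitivity and specificity with a positive call at score >= cutoff."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    keep = ~np.isnan(scores)
    scores, labels = scores[keep], labels[keep]
    if labels.all() or not labels.any():
        raise ValueError("both label classes must be present")
    call = scores >= cutoff
    tp = int((call & labels).sum())
    fn = int((~call & labels).sum())
    tn = int((~call & ~labels).sum())
    fp = int((call & ~labels).sum())
    return tp / (tp + fn), tn / (tn + fp)


# ---------------------------------------------------------------------------
# full cohort report
# ---------------------------------------------------------------------------

REQUIRED_COLUMNS = (
    "patient_id", "sex", "mfpa_pct", "ha_um2", "lr_um", "hpl", "alt_u_l", "ast_u_l",
)


def _summary(df: pd.DataFrame, variables: Sequence[str]) -> dict:
    out: dict = {"n": int(len(df))}
    for var in variables:
        vals = df[var].dropna().to_numpy(dtype=float)
        if vals.size == 0:
            out[var] = {"n": 0}
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        out[var] = {"median": float(med), "q1": float(q1), "q3": float(q3), "n": int(vals.size)}
    return out


def _correlations(df: pd.DataFrame) -> dict:
    out: dict = {}
    for var in ANALYSIS_VARIABLES:
        sub = df[["mfpa_pct", var]].dropna()
        if len(sub) < 3 or sub["mfpa_pct"].nunique() < 2 or sub[var].nunique() < 2:
            out[var] = {"skipped": True, "reason": "fewer than 3 complete, varying pairs"}
            continue
        rs, p = spearman(sub["mfpa_pct"], sub[var])
        out[var] = {"rs": rs, "p": p, "n": int(len(sub))}
    return out


def _holm(pairs: dict) -> None:
    tested = [(k, v) for k, v in pairs.items() if "p" in v]
    m = len(tested)
    order = sorted(tested, key=lambda kv: kv[1]["p"])
    running = 0.0
    for rank, (key, entry) in enumerate(order):
        adj = min(1.0, (m - rank) * entry["p"])
        running = max(running, adj)
        pairs[key]["p_holm"] = running


def cohort_report(
    records: pd.DataFrame,
    cutoffs_u_l: Sequence[float] = DEFAULT_CUTOFFS_U_L,
    holm: bool = False,
) -> dict:
    """Full statistical report for a patient cohort table.

    Produces (a) median/IQR summaries overall, by sex and by the 5% mFPA
    split; (b) Spearman correlations of mFPA with transaminases and
    morphometry, pooled and sex-stratified; (c) bracket medians with
    adjacent-bracket Mann-Whitney tests and an overall Kruskal-Wallis per
    variable; (d) ROC analyses of ALT and AST against the 5% and 20% mFPA
    thresholds with sensitivity/specificity at the configured cut-offs.
    Raw (unadjusted) p-values are reported by default; ``holm=True`` adds
    Holm-adjusted values for the pairwise family of each variable.

    The report is a plain nested dict of floats/strings, deterministic for a
    given table, and JSON-serialisable as-is.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"cohort table is missing required columns: {missing}")
    df = records.copy()
    n_with_mfpa = int(df["mfpa_pct"].notna().sum())
    if n_with_mfpa < 10:
        raise ValueError(f"cohort report requires >= 10 records with mFPA, got {n_with_mfpa}")
    df = df[df["mfpa_pct"].notna()]
    df["bracket"] = categorize_mfpa_series(df["mfpa_pct"])

    summary_vars = [
        c for c in (
            "age", "mfpa_pct", "alt_u_l", "ast_u_l", "ggt_u_l", "bilirubin_mmol_l",
            "albumin_g_l", "alp_u_l", "ha_um2", "lr_um", "hpl",
        ) if c in df.columns
    ]
    report: dict = {
        "n_patients": int(len(df)),
        "summary": {
            "all": _summary(df, summary_vars),
            "male": _summary(df[df["sex"] == "male"], summary_vars),
            "female": _summary(df[df["sex"] == "female"], summary_vars),
            "mfpa_lt5": _summary(df[df["mfpa_pct"] < 5.0], summary_vars),
            "mfpa_ge5": _summary(df[df["mfpa_pct"] >= 5.0], summary_vars),
        },
        "correlations": {
            "pooled": _correlations(df),
            "male": _correlations(df[df["sex"] == "male"]),
            "female": _correlations(df[df["sex"] == "female"]),
        },
    }

    # bracket tables and tests
    counts = df["bracket"].value_counts().reindex(list(BRACKET_LABELS)).fillna(0)
    brackets: dict = {"counts": {k: int(v) for k, v in counts.items()}}
    occupied = [b for b in BRACKET_LABELS if counts[b] > 0]
    medians: dict = {}
    kruskal: dict = {}
    pairwise: dict = {}
    for var in ANALYSIS_VARIABLES:
        medians[var] = {
            b: _summary(df[df["bracket"] == b], [var])[var] for b in BRACKET_LABELS
        }
        groups = [
            df.loc[df["bracket"] == b, var].dropna().to_numpy(dtype=float)
            for b in occupied
        ]
        groups = [g for g in groups if g.size > 0]
        if len(groups) >= 3:
            h, p = kruskal_wallis(groups)
            kruskal[var] = {"H": h, "p": p, "k": len(groups)}
        else:
            kruskal[var] = {"skipped": True, "reason": "fewer than 3 occupied brackets"}
        pairs: dict = {}
        for lo, hi in zip(BRACKET_LABELS[:-1], BRACKET_LABELS[1:]):
            key = f"{lo} vs {hi}"
            a = df.loc[df["bracket"] == lo, var].dropna().to_numpy(dtype=float)
            b = df.loc[df["bracket"] == hi, var].dropna().to_numpy(dtype=float)
            if a.size == 0 or b.size == 0:
                pairs[key] = {"skipped": True, "reason": "empty bracket"}
            else:
                u, p = mann_whitney(a, b)
                pairs[key] = {"U": u, "p": p, "n": [int(a.size), int(b.size)]}
        if holm:
            _holm(pairs)
        pairwise[var] = pairs
    brackets.update(medians=medians, kruskal_wallis=kruskal, pairwise_mann_whitney=pairwise)
    report["brackets"] = brackets

    # ROC of transaminases against the steatosis thresholds
    roc_section: dict = {}
    for score_col, enzyme in (("alt_u_l", "alt"), ("ast_u_l", "ast")):
        if score_col not in df.columns:
            continue
        for threshold in (5.0, 20.0):
            key = f"{enzyme}_vs_mfpa_ge_{threshold:g}"
            sub = df[[score_col, "mfpa_pct"]].dropna()
            labels = (sub["mfpa_pct"] >= threshold).to_numpy()
            if labels.all() or not labels.any():
                roc_section[key] = {"skipped": True, "reason": "single label class"}
                continue
            scores = sub[score_col].to_numpy(dtype=float)
            curve = roc(scores, labels)
            cut_table = {}
            for cut in cutoffs_u_l:
                sens, spec = sensitivity_specificity(scores, labels, cut)
                cut_table[f"{cut:g}"] = {"sensitivity": sens, "specificity": spec}
            roc_section[key] = {
                "auroc": curve.auroc,
                "n_positive": int(labels.sum()),
                "n_negative": int((~labels).sum()),
                "cutoffs": cut_table,
            }
    report["roc"] = roc_section
    return report
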