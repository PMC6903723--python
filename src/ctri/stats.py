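"""Statistical layer over CTRI result tables and clinical covariates.

Implements the analysis battery used to relate the reticulation index to
clinical measures: normality triage (Shapiro-Wilk for small samples,
Lilliefors otherwise), Spearman rank correlation (with a log transform of
non-normal variables; note that a strictly increasing transform cannot change
a rank correlation — the transform is kept for fidelity and reported),
two-sided Mann-Whitney U for binary factors, ROC/AUC with a Youden-J cutoff
for the lymphoscintigraphy dichotomies, and the normalized between-limb
difference used by the bio-impedance (BEI) ratio and the standardized
circumference difference ratio (SCDR).

No multiple-testing correction is applied to the primary p-values; a
Benjamini-Hochberg column is emitted alongside, clearly labelled as an
addition.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# normalized between-limb difference (BEI ratio / SCDR helper)
# ---------------------------------------------------------------------------

def normalized_difference(affected: float, unaffected: float, mode: str = "bei") -> float:
    """Between-limb difference normalised by the unaffected limb.

    ``mode="bei"``: (unaffected - affected) / unaffected — impedance drops in
    the affected limb, so the ratio is positive in lymphedema.
    ``mode="scdr"``: (affected - unaffected) / unaffected — circumference
    grows in the affected limb.
    """
    if unaffected == 0:
        raise ValueError("unaffected value must be nonzero")
    if mode == "bei":
        return (unaffected - affected) / unaffected
    if mode == "scdr":
        return (affected - unaffected) / unaffected
    raise ValueError(f"mode must be 'bei' or 'scdr', got {mode!r}")


# ---------------------------------------------------------------------------
# normality triage
# ---------------------------------------------------------------------------

def normality_triage(x: Sequence[float], alpha: float = 0.05) -> str:
    """Classify a sample as ``"normal"`` or ``"non_normal"``.

    Shapiro-Wilk for n <= 50, Lilliefors (Kolmogorov-Smirnov with estimated
    parameters) for larger samples; ``non_normal`` iff p < alpha. A constant
    vector is non-normal by convention (with a warning).
    """
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 3:
        raise ValueError(f"normality triage needs n >= 3, got n = {x.size}")
    if np.ptp(x) == 0:
        warnings.warn("constant vector: classified non_normal", stacklevel=2)
        return "non_normal"
    if x.size <= 50:
        _, p = sps.shapiro(x)
    else:
        _, p = lilliefors(x, dist="norm")
    return "non_normal" if p < alpha else "normal"


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

def _pairwise_complete(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact p by enumerating all permutations of y (n <= 9).

    The permutation distribution is conditional on the observed rank
    multisets, so ties are handled naturally (average ranks).
    """
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rx = rx - rx.mean()
    sx = math.sqrt(float(rx @ rx))
    n = rx.size
    perms = np.array(list(itertools.permutations(ry)), dtype=float)
    perms -= perms.mean(axis=1, keepdims=True)
    sy = np.sqrt(np.einsum("ij,ij->i", perms, perms))
    with np.errstate(invalid="ignore", divide="ignore"):
        rhos = (perms @ rx) / (sx * sy)
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    log_transform: bool = False,
    x_name: str = "x",
    y_name: str = "y",
) -> tuple[float, float, int]:
    """Spearman rank correlation with average-rank ties.

    Returns ``(rho, p, n)`` on the pairwise-complete observations. The p-value
    is exact (full permutation enumeration) for n <= 9 and uses the
    t-approximation otherwise. With ``log_transform`` both variables are
    log-transformed first (all values must be positive; the offending variable
    is named otherwise). Ranks are invariant under strictly increasing
    transforms, so the transform cannot change rho; it is applied for protocol
    fidelity.
    """
    x, y = _pairwise_complete(x, y)
    n = x.size
    if n < 4:
        raise ValueError(f"Spearman needs pairwise-complete n >= 4, got n = {n}")
    if log_transform:
        for name, v in ((x_name, x), (y_name, y)):
            if (v <= 0).any():
                raise ValueError(f"log transform requires positive values: {name} has nonpositive entries")
        x, y = np.log(x), np.log(y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman undefined for a constant variable")
    rho, p_t = sps.spearmanr(x, y)
    if n <= 9:
        p = _spearman_exact_p(x, y, float(rho))
    else:
        p = float(p_t)
    return float(rho), p, int(n)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns ``(U, p)`` with the min-U convention.

    The exact null distribution is used when ``n_a * n_b <= 400`` and there
    are no ties across the pooled sample; otherwise the normal approximation
    with tie correction (and continuity correction) is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size * b.size <= 400 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u1 = float(res.statistic)
    u_min = min(u1, a.size * b.size - u1)
    return u_min, float(res.pvalue)


# ---------------------------------------------------------------------------
# ROC analysis
# ---------------------------------------------------------------------------

@dataclass
class ROCResult:
    auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    ci_low: float
    ci_high: float
    positive_definition: str = ""
    n_pos: int = 0
    n_neg: int = 0


def empirical_roc(
    scores: Sequence[float], labels: Sequence[bool]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Empirical ROC: ``(fpr, tpr, thresholds)`` with ``score >= t`` positive.

    Thresholds are the unique scores in descending order; a leading
    ``(0, 0)`` point (threshold +inf) is included.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    pos = np.sort(scores[labels])
    neg = np.sort(scores[~labels])
    if pos.size == 0 or neg.size == 0:
        raise ValueError("ROC needs both classes present")
    thr = np.unique(scores)[::-1]
    tp = pos.size - np.searchsorted(pos, thr, side="left")
    fp = neg.size - np.searchsorted(neg, thr, side="left")
    tpr = np.concatenate([[0.0], tp / pos.size])
    fpr = np.concatenate([[0.0], fp / neg.size])
    thresholds = np.concatenate([[np.inf], thr])
    return fpr, tpr, thresholds


def _auc_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC via the rank (Mann-Whitney concordance) formula, ties as 1/2."""
    ranks = sps.rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    r_pos = ranks[labels].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_analysis(
    scores: Sequence[float],
    labels: Sequence[bool],
    n_boot: int = 1000,
    seed: int = 0,
    positive_definition: str = "",
) -> ROCResult:
    """ROC curve analysis with Youden-J cutoff and bootstrap AUC interval.

    AUC is the trapezoidal area under the empirical ROC (equal to the
    Mann-Whitney concordance with ties counted 1/2). The cutoff maximises
    Youden's J = sensitivity + specificity - 1; ties are broken toward higher
    specificity (then the higher cutoff). Positivity convention:
    ``score >= cutoff``. The AUC confidence interval is a stratified
    percentile bootstrap (seeded).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    fpr, tpr, thresholds = empirical_roc(scores, labels)
    auc = float(np.trapezoid(tpr, fpr))
    j = tpr - fpr
    # fpr is non-decreasing along thresholds (descending), so the first J
    # maximiser has the highest specificity and the highest cutoff.
    best = int(np.flatnonzero(j == j.max())[0])
    cutoff = float(thresholds[best])
    sensitivity = float(tpr[best])
    specificity = float(1.0 - fpr[best])

    pos = scores[labels]
    neg = scores[~labels]
    ci_low = ci_high = float("nan")
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        aucs = np.empty(n_boot)
        for i in range(n_boot):
            bp = rng.choice(pos, size=pos.size, replace=True)
            bn = rng.choice(neg, size=neg.size, replace=True)
            bs = np.concatenate([bp, bn])
            bl = np.concatenate([np.ones(bp.size, bool), np.zeros(bn.size, bool)])
            aucs[i] = _auc_rank(bs, bl)
        ci_low, ci_high = (float(q) for q in np.quantile(aucs, [0.025, 0.975]))
    return ROCResult(
        auc=auc,
        cutoff=cutoff,
        sensitivity=sensitivity,
        specificity=specificity,
        ci_low=ci_low,
        ci_high=ci_high,
        positive_definition=positive_definition,
        n_pos=int(labels.sum()),
        n_neg=int((~labels).sum()),
    )


# ---------------------------------------------------------------------------
# cohort report
# ---------------------------------------------------------------------------

@dataclass
class ReportConfig:
    """Which columns enter which analysis.

    ``continuous`` columns are correlated with each CTRI type by Spearman
    (log-transforming variables triaged non-normal, when positive);
    ``binary`` columns define two groups compared by Mann-Whitney U;
    ``roc_dichotomies`` are ``(name, column, positive_min)`` triples: patients
    with ``column >= positive_min`` are positives, scored by each CTRI type.
    """

    ctri_columns: tuple[str, ...] = ("ctri_max", "ctri_mean", "ctri_min")
    continuous: tuple[str, ...] = (
        "letoct",
        "optoct",
        "optole",
        "isl_substage",
        "bei_ratio",
        "scdr_proximal",
        "scdr_distal",
        "lsg_stage",
        "albumin",
    )
    binary: tuple[str, ...] = ("radiotherapy", "rehabilitative_management", "anti_edemic_drug")
    roc_dichotomies: tuple[tuple[str, str, float], ...] = (
        ("lsg_iv_vs_i_iii", "lsg_stage", 4),
        ("lsg_iii_iv_vs_i_ii", "lsg_stage", 3),
    )
    n_boot: int = 1000
    seed: int = 0
    alpha: float = 0.05


def analysis_report(table: pd.DataFrame, config: Optional[ReportConfig] = None) -> pd.DataFrame:
    """Run the full analysis battery over a cohort covariate table.

    Returns one row per (CTRI type x covariate) analysis with the chosen
    test, statistic, p and per-analysis n; ROC rows for each dichotomy; and a
    Benjamini-Hochberg adjusted column ``p_bh`` (an addition to the primary,
    uncorrected p-values). Analyses that cannot run (too few observations,
    one class absent) are reported with a reason instead of failing.
    """
    if config is None:
        config = ReportConfig()
    wanted = set(config.ctri_columns) | set(config.continuous) | set(config.binary)
    wanted |= {col for _, col, _ in config.roc_dichotomies}
    missing = sorted(wanted - set(table.columns))
    if missing:
        raise KeyError(f"covariate table is missing columns: {missing}")

    rows: list[dict] = []
    for ctri_col in config.ctri_columns:
        for cov in config.continuous:
            rows.append(_spearman_row(table, ctri_col, cov, config))
        for cov in config.binary:
            rows.append(_mw_row(table, ctri_col, cov))
        for name, col, cut in config.roc_dichotomies:
            rows.append(_roc_row(table, ctri_col, name, col, cut, config))

    report = pd.DataFrame(rows)
    ok = report["p"].notna()
    report["p_bh"] = np.nan
    if ok.any():
        report.loc[ok, "p_bh"] = multipletests(report.loc[ok, "p"], method="fdr_bh")[1]
    return report


def _spearman_row(table, ctri_col, cov, config) -> dict:
    x = table[ctri_col].to_numpy(dtype=float)
    y = table[cov].to_numpy(dtype=float)
    xs, ys = _pairwise_complete(x, y)
    base = {"ctri": ctri_col, "covariate": cov, "analysis": "spearman", "n": int(xs.size)}
    if xs.size < 4:
        return {**base, "statistic": np.nan, "p": np.nan, "note": "skipped: n < 4"}
    try:
        log_flag = False
        if (xs > 0).all() and (ys > 0).all():
            log_flag = (
                normality_triage(xs, config.alpha) == "non_normal"
                or normality_triage(ys, config.alpha) == "non_normal"
            )
        rho, p, n = spearman(xs, ys, log_transform=log_flag, x_name=ctri_col, y_name=cov)
    except ValueError as exc:
        return {**base, "statistic": np.nan, "p": np.nan, "note": f"skipped: {exc}"}
    note = "log-transformed (rank correlation unchanged)" if log_flag else ""
    return {**base, "statistic": rho, "p": p, "note": note}


def _mw_row(table, ctri_col, cov) -> dict:
    sub = table[[ctri_col, cov]].dropna()
    groups = sub[cov].astype(float)
    a = sub.loc[groups > 0, ctri_col].to_numpy(dtype=float)
    b = sub.loc[groups <= 0, ctri_col].to_numpy(dtype=float)
    base = {"ctri": ctri_col, "covariate": cov, "analysis": "mann_whitney", "n": int(sub.shape[0])}
    if a.size == 0 or b.size == 0:
        return {**base, "statistic": np.nan, "p": np.nan, "note": "skipped: a group is empty"}
    u, p = mann_whitney(a, b)
    return {**base, "statistic": u, "p": p, "note": ""}


def _roc_row(table, ctri_col, name, col, cut, config) -> dict:
    sub = table[[ctri_col, col]].dropna()
    scores = sub[ctri_col].to_numpy(dtype=float)
    labels = sub[col].to_numpy(dtype=float) >= cut
    base = {"ctri": ctri_col, "covariate": name, "analysis": "roc", "n": int(sub.shape[0])}
    if labels.all() or not labels.any():
        return {**base, "statistic": np.nan, "p": np.nan, "note": "skipped: one class absent"}
    res = roc_analysis(
        scores,
        labels,
        n_boot=config.n_boot,
        seed=config.seed,
        positive_definition=f"{col} >= {cut}",
    )
    return {
        **base,
        "statistic": res.auc,
        "p": np.nan,
        "cutoff": res.cutoff,
        "sensitivity": res.sensitivity,
        "specificity": res.specificity,
        "auc_ci_low": res.ci_low,
        "auc_ci_high": res.ci_high,
        "note": f"positive: {res.positive_definition}",
    }


def render_report(report: pd.DataFrame) -> str:
    """Human-readable summary of an :func:`analysis_report` table."""
    lines = ["CTRI cohort analysis", "=" * 60]
    for _, r in report.iterrows():
        if pd.isna(r["statistic"]):
            lines.append(f"{r['ctri']} vs {r['covariate']}: {r.get('note', 'skipped')}")
            continue
        if r["analysis"] == "spearman":
            lines.append(
                f"{r['ctri']} vs {r['covariate']}: rho = {r['statistic']:+.3f}, "
                f"p = {r['p']:.4g}, n = {int(r['n'])}"
                + (f" [{r['note']}]" if r.get("note") else "")
            )
        elif r["analysis"] == "mann_whitney":
            lines.append(
                f"{r['ctri']} by {r['covariate']}: U = {r['statistic']:.1f}, "
                f"p = {r['p']:.4g}, n = {int(r['n'])}"
            )
        else:
            lines.append(
                f"{r['ctri']} ROC {r['covariate']}: AUC = {r['statistic']:.3f} "
                f"(95% CI {r['auc_ci_low']:.2f}-{r['auc_ci_high']:.2f}), "
                f"cutoff = {r['cutoff']:.2f}, sens = {r['sensitivity']:.2f}, "
                f"spec = {r['specificity']:.2f}, n = {int(r['n'])}"
            )
    return "\n".join(lines)


def simulate_cohort(
    n_patients: int = 24,
    link_sd: float = 0.8,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic covariate table with known monotone CTRI-covariate links.

    CTRI_MEAN is lognormal; duration (``letoct``) and the ordinal substage
    increase monotonically with log CTRI plus Gaussian noise; the BEI ratio
    decreases with CTRI_MIN; distal SCDR and albumin are pure noise; the
    binary factors are random. Used for recovery tests of the analysis
    battery, not as a model of real patients.
    """
    rng = np.random.default_rng(seed)
    z = rng.normal(0.0, link_sd, size=n_patients)
    ctri_mean = np.exp(2.5 + z)
    ctri_max = ctri_mean * rng.uniform(2.0, 8.0, size=n_patients)
    ctri_min = ctri_mean * rng.uniform(0.15, 0.5, size=n_patients)
    noise = lambda: rng.normal(0.0, noise_sd, size=n_patients)  # noqa: E731
    letoct = np.maximum(3.0, 50 + 25 * (z + noise()))
    substage_score = z + noise()
    isl = 1 + np.digitize(substage_score, np.quantile(substage_score, [0.33, 0.87]))
    lsg = 1 + np.digitize(z + 2.0 * noise(), np.quantile(z, [0.3, 0.6, 0.85]))
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:03d}" for i in range(n_patients)],
            "ctri_max": ctri_max,
            "ctri_mean": ctri_mean,
            "ctri_min": ctri_min,
            "letoct": letoct,
            "optoct": np.maximum(3.0, 80 + 50 * noise()),
            "optole": np.maximum(1.0, 34 + 30 * noise()),
            "isl_substage": isl.astype(float),
            "bei_ratio": 0.2 - 0.1 * (np.log(ctri_min) + noise()) / 3.0,
            "scdr_proximal": np.maximum(0.0, 0.1 + 0.05 * (np.log(ctri_min) + noise()) / 3.0),
            "scdr_distal": np.maximum(0.0, 0.08 + 0.05 * noise()),
            "lsg_stage": lsg.astype(float),
            "albumin": 4.2 + 0.3 * noise(),
            "radiotherapy": (rng.random(n_patients) < 0.75).astype(int),
            "rehabilitative_management": (rng.random(n_patients) < 0.7).astype(int),
            "anti_edemic_drug": (rng.random(n_patients) < 0.7).astype(int),
        }
    )
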