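"""Polygenic risk scores and their case/control and transmission statistics.

The score of a genome is the natural log of the product of the odds ratios
of the risk alleles it carries: a homozygous risk locus contributes twice,
a heterozygous one once, an absent one nothing. Subtype-specific scores use
only loci with an odds ratio for that subtype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .errors import ValidationError
from .io_formats import GenotypePanel, LocusWeight, Pedigree

__all__ = [
    "compute_prs",
    "risk_score_table",
    "carrier_risk",
    "wilcoxon_one_sided",
    "roc_auc",
    "nagelkerke_r2",
    "TransmissionRecord",
    "transmission_analysis",
    "family_summary",
]

#: Exact rank-sum enumeration up to this combined sample size.
WILCOXON_EXACT_N = 12


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------

def _risk_allele_counts(panel: GenotypePanel, w: LocusWeight) -> np.ndarray:
    """Risk-allele counts per sample; missing genotypes count 0."""
    j = panel.locus_index.get(w.locus_id)
    if j is None:
        return np.zeros(len(panel.samples))
    locus = panel.loci[j]
    g = panel.counts[:, j].astype(float)
    missing = g < 0
    if w.risk_allele == locus.alt:
        counts = g
    elif w.risk_allele == locus.ref:
        counts = 2.0 - g
    else:
        raise ValidationError(
            f"{w.locus_id}: risk allele {w.risk_allele!r} matches neither "
            f"ref {locus.ref!r} nor alt {locus.alt!r}")
    counts[missing] = 0.0
    return counts


def compute_prs(panel: GenotypePanel, weights: Sequence[LocusWeight],
                subtype: str) -> pd.Series:
    """Per-individual polygenic risk score for ``subtype`` ("CD" or "UC").

    ``sum_i g_i * ln(OR_i)`` over loci with an odds ratio for the subtype;
    loci absent from the panel or with missing genotype contribute 0.
    """
    if subtype not in ("CD", "UC"):
        raise ValidationError(f"subtype must be CD or UC, got {subtype!r}")
    total = np.zeros(len(panel.samples))
    for w in weights:
        oddsr = w.odds_ratio(subtype)
        if oddsr is None:
            continue
        total += _risk_allele_counts(panel, w) * np.log(oddsr)
    return pd.Series(total, index=panel.samples, name=f"s_{subtype.lower()}")


def risk_score_table(panel: GenotypePanel,
                     weights: Sequence[LocusWeight]) -> pd.DataFrame:
    """Both subtype scores per individual (columns ``s_cd``, ``s_uc``)."""
    return pd.concat([compute_prs(panel, weights, "CD"),
                      compute_prs(panel, weights, "UC")], axis=1)


def carrier_risk(baseline_risk: float, odds_ratio: float) -> float:
    """Disease risk for a carrier: baseline risk converted to odds,
    multiplied by the odds ratio, and converted back to a probability."""
    if not (0.0 < baseline_risk < 1.0):
        raise ValidationError("baseline_risk must be in (0,1)")
    if odds_ratio <= 0:
        raise ValidationError("odds_ratio must be > 0")
    odds = baseline_risk / (1.0 - baseline_risk) * odds_ratio
    return odds / (1.0 + odds)


# ---------------------------------------------------------------------------
# Case/control statistics
# ---------------------------------------------------------------------------

def wilcoxon_one_sided(cases: Sequence[float],
                       controls: Sequence[float]) -> float:
    """One-sided Wilcoxon rank-sum p-value, alternative "cases greater".

    Exact enumeration for combined n <= 12 without ties; otherwise the
    normal approximation with mid-ranks, tie correction and continuity
    correction. Fully degenerate data (all values identical) returns 1.0
    with a warning.
    """
    x = np.asarray(cases, dtype=float)
    y = np.asarray(controls, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("degenerate data: all values identical", stacklevel=2)
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= WILCOXON_EXACT_N and not has_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="greater", method=method,
                             use_continuity=True)
    return float(res.pvalue)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC as the Mann-Whitney probability P(case score > control score),
    ties counted 1/2; equals the trapezoidal area under the empirical ROC."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValidationError("both label classes must be present")
    ranks = stats.rankdata(s)  # mid-ranks
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _logistic_irls(X: np.ndarray, y: np.ndarray, tol: float = 1e-8,
                   max_iter: int = 100) -> tuple[np.ndarray, float, bool]:
    """Newton/IRLS logistic fit; returns (beta, loglik, converged)."""
    beta = np.zeros(X.shape[1])
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        p = expit(eta)
        w = np.clip(p * (1 - p), 1e-12, None)
        z = eta + (y - p) / w
        wx = X * w[:, None]
        try:
            new = np.linalg.solve(X.T @ wx, wx.T @ z)
        except np.linalg.LinAlgError:
            break
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            converged = True
            break
        beta = new
    eta = np.clip(X @ beta, -700, 700)
    ll = float(np.sum(y * eta - np.log1p(np.exp(eta))))
    return beta, ll, converged


def nagelkerke_r2(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Nagelkerke pseudo R-squared of labels regressed on scores.

    Cox-Snell ``1 - (L0/L1)**(2/n)`` rescaled by its maximum
    ``1 - L0**(2/n)``; the null model is intercept-only.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    n = len(y)
    if n < 4:
        raise ValidationError("need n >= 4")
    if y.min() == y.max():
        raise ValidationError("both label classes must be present")
    pbar = y.mean()
    ll0 = n * (pbar * np.log(pbar) + (1 - pbar) * np.log(1 - pbar))
    X = np.column_stack([np.ones(n), s])
    _, ll1, converged = _logistic_irls(X, y)
    if not converged:
        warnings.warn("logistic fit did not converge (possible separation); "
                      "using capped-iteration estimate", stacklevel=2)
    r2_cs = 1.0 - np.exp(2.0 * (ll0 - ll1) / n)
    denom = 1.0 - np.exp(2.0 * ll0 / n)
    return float(min(max(r2_cs / denom, 0.0), 1.0))


# ---------------------------------------------------------------------------
# Transmission analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransmissionRecord:
    """Observed vs expected (parental-mean) score for one offspring."""

    offspring: str
    affected: bool
    observed: float
    expected: float

    @property
    def ratio(self) -> float:
        return self.observed / self.expected


def transmission_analysis(pedigree: Pedigree, scores: pd.Series,
                          ) -> tuple[list[TransmissionRecord], float, int]:
    """Offspring score transmission records plus a two-sided Welch t-test
    p-value comparing affected vs unaffected offspring ratios.

    Expected score is the mean of the two parental scores; offspring whose
    expected score is 0 (or with an unscored parent) are excluded and
    counted in the third return value.
    """
    records: list[TransmissionRecord] = []
    n_excluded = 0
    for m in pedigree.members:
        if m.father is None or m.mother is None:
            continue
        if m.iid not in scores.index:
            continue
        if m.father not in scores.index or m.mother not in scores.index:
            n_excluded += 1
            continue
        if m.affection == "unknown":
            continue
        expected = (scores[m.father] + scores[m.mother]) / 2.0
        if expected == 0:
            n_excluded += 1
            continue
        records.append(TransmissionRecord(
            m.iid, m.is_affected, float(scores[m.iid]), float(expected)))
    if not records:
        raise ValidationError("no eligible offspring for transmission analysis")
    aff = [r.ratio for r in records if r.affected]
    una = [r.ratio for r in records if not r.affected]
    if aff and una:
        p = float(stats.ttest_ind(aff, una, equal_var=False).pvalue)
    else:
        p = float("nan")
    return records, p, n_excluded


def family_summary(pedigrees: Sequence[Pedigree], scores: pd.DataFrame,
                   control_means: tuple[float, float]) -> pd.DataFrame:
    """Per-family mean CD/UC scores over affected members vs control means.

    ``control_means`` is (mean control s_cd, mean control s_uc). A family is
    flagged ``low`` when both its subtype means fall below the respective
    control means.
    """
    ctrl_cd, ctrl_uc = control_means
    rows = []
    for ped in pedigrees:
        aff = [i for i in ped.affected() if i in scores.index]
        if not aff:
            raise ValidationError(
                f"family {ped.family_id}: no scored affected member")
        mean_cd = float(scores.loc[aff, "s_cd"].mean())
        mean_uc = float(scores.loc[aff, "s_uc"].mean())
        rows.append({
            "family_id": ped.family_id,
            "n_affected": len(aff),
            "mean_cd": mean_cd,
            "mean_uc": mean_uc,
            "control_cd": ctrl_cd,
            "control_uc": ctrl_uc,
            "low": bool(mean_cd < ctrl_cd and mean_uc < ctrl_uc),
        })
    return pd.DataFrame(rows).set_index("family_id")
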