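"""Design-based (survey-weighted) estimation.

Point estimates are weighted (Hajek) ratio means. Standard errors use
first-order Taylor linearization with between-PSU variation within
strata — the standard design-based variance for a stratified
multistage sample analysed with sampling weights:

    var = sum_h  n_h / (n_h - 1) * sum_j (z_hj - zbar_h)^2

where z_hj is the PSU total of the linearized scores
z_i = w_i (x_i - xbar_w) / W. Both the estimate and the SE are
invariant to rescaling all weights by a constant. Strata contributing a
single PSU are handled by centring their PSU total at the grand mean of
all PSU totals (a certainty-unit convention); if every stratum is
single-PSU the caller is advised to collapse strata.

Observed-vs-counterfactual comparisons use a weighted *paired* t-test
on per-person differences — both arms are the same individuals — with
design degrees of freedom (number of PSUs minus number of strata) and
Bonferroni correction for the number of cells tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SurveyEstimate",
    "ComparisonResult",
    "weighted_mean",
    "taylor_se",
    "survey_mean",
    "design_df",
    "paired_t",
    "weighted_prevalence",
]


@dataclass(frozen=True)
class SurveyEstimate:
    estimate: float
    se: float
    n_unweighted: int
    domain: str = ""
    design_based: bool = True


@dataclass(frozen=True)
class ComparisonResult:
    statistic: Optional[float]
    p_raw: Optional[float]
    p_bonferroni: Optional[float]
    m_comparisons: int
    significant: bool
    df: float
    flagged: str = ""


def _as_arrays(values, weights):
    x = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if x.shape != w.shape or x.ndim != 1:
        raise ValueError("values and weights must be 1-d arrays of equal length")
    if x.size == 0:
        raise ValueError("empty input")
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    return x, w


def weighted_mean(values, weights) -> float:
    """Hajek weighted mean: sum(w x) / sum(w)."""
    x, w = _as_arrays(values, weights)
    return float(np.sum(w * x) / np.sum(w))


def taylor_se(values, weights, strata, psus) -> float:
    """Taylor-linearized SE of the weighted mean under the stratified design."""
    x, w = _as_arrays(values, weights)
    W = np.sum(w)
    mean = np.sum(w * x) / W
    z = w * (x - mean) / W
    return _taylor_from_scores(z, strata, psus)


def _taylor_from_scores(z, strata, psus) -> float:
    """SE from linearized scores z_i; between-PSU variance within strata."""
    z = np.asarray(z, dtype=float)
    strata = np.asarray(strata)
    psus = np.asarray(psus)
    if strata.shape != z.shape or psus.shape != z.shape:
        raise ValueError("strata and psus must match values in length")

    # PSU totals of the linearized scores, by (stratum, psu)
    cells: dict[tuple, float] = {}
    for zi, h, j in zip(z, strata, psus):
        cells[(h, j)] = cells.get((h, j), 0.0) + zi
    by_stratum: dict = {}
    for (h, _j), tot in cells.items():
        by_stratum.setdefault(h, []).append(tot)

    if all(len(tots) < 2 for tots in by_stratum.values()):
        raise ValueError(
            "all strata contain a single PSU; collapse strata before variance estimation"
        )

    grand = float(np.mean([t for tots in by_stratum.values() for t in tots]))
    var = 0.0
    for tots in by_stratum.values():
        n_h = len(tots)
        if n_h >= 2:
            center = float(np.mean(tots))
            var += n_h / (n_h - 1) * sum((t - center) ** 2 for t in tots)
        else:
            # single-PSU stratum: centre at the grand mean of PSU totals
            var += (tots[0] - grand) ** 2
    return float(np.sqrt(var))


def survey_mean(
    values, weights, strata=None, psus=None, domain: str = "", domain_mask=None
) -> SurveyEstimate:
    """Weighted mean with a design-based SE (iid-weighted fallback if no design).

    ``domain_mask`` selects a subpopulation while keeping the full design:
    non-domain persons contribute zero linearized score but their PSUs
    stay in the variance computation (the standard subpopulation
    estimator, rather than subsetting the file).
    """
    x, w = _as_arrays(values, weights)
    if domain_mask is not None:
        mask = np.asarray(domain_mask, dtype=bool)
        if mask.shape != x.shape:
            raise ValueError("domain_mask must match values in length")
        if not mask.any():
            raise ValueError(f"empty domain {domain!r}")
    else:
        mask = np.ones_like(x, dtype=bool)
    W = float(np.sum(w[mask]))
    est = float(np.sum(w[mask] * x[mask]) / W)
    n_dom = int(mask.sum())
    z = np.where(mask, w * (x - est), 0.0) / W
    if strata is not None and psus is not None:
        se = _taylor_from_scores(z, strata, psus)
        return SurveyEstimate(est, se, n_dom, domain, design_based=True)
    # fallback: linearized SE ignoring clustering, flagged as non-design
    n = x.size
    se = float(np.sqrt(n / (n - 1) * np.sum(z**2))) if n > 1 else float("nan")
    return SurveyEstimate(est, se, n_dom, domain, design_based=False)


def design_df(strata, psus) -> int:
    """Design degrees of freedom: #PSUs − #strata."""
    pairs = {(h, j) for h, j in zip(np.asarray(strata), np.asarray(psus))}
    n_strata = len({h for h, _ in pairs})
    return len(pairs) - n_strata


def paired_t(
    observed,
    predicted,
    weights,
    strata=None,
    psus=None,
    m_comparisons: int = 1,
    alpha: float = 0.05,
    domain_mask=None,
) -> ComparisonResult:
    """Weighted paired t-test of observed vs predicted on the same persons.

    The statistic is the weighted mean per-person difference over its
    design-based SE; p-values are two-sided on the design df and
    Bonferroni-corrected: p_bonf = min(1, m * p_raw).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must pair the same persons")
    d = obs - pred
    w = np.asarray(weights, dtype=float)
    if strata is not None and psus is not None:
        res = survey_mean(d, w, strata, psus, domain_mask=domain_mask)
        est, se = res.estimate, res.se
        df = design_df(strata, psus)
    else:
        fallback = survey_mean(d, w, domain_mask=domain_mask)
        est, se = fallback.estimate, fallback.se
        df = d.size - 1
    if se == 0.0:
        if est == 0.0:
            # no differences at all: trivially non-significant
            return ComparisonResult(0.0, 1.0, 1.0, m_comparisons, False, df)
        return ComparisonResult(
            None, None, None, m_comparisons, False, df, flagged="zero-variance differences"
        )
    t = est / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    p_bonf = min(1.0, m_comparisons * p)
    return ComparisonResult(float(t), p, p_bonf, m_comparisons, p_bonf < alpha, df)


def weighted_prevalence(
    categories: Sequence,
    weights,
    strata=None,
    psus=None,
    levels: Sequence | None = None,
    domain_mask=None,
) -> dict[object, SurveyEstimate]:
    """Weighted percent prevalence of each category level (sums to 100)."""
    cats = list(categories)
    if levels is None:
        levels = sorted(set(cats), key=str)
    out = {}
    for level in levels:
        ind = np.asarray([100.0 if c == level else 0.0 for c in cats])
        out[level] = survey_mean(
            ind, weights, strata, psus, domain=str(level), domain_mask=domain_mask
        )
    return out
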