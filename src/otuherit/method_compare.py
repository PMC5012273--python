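"""Cross-method comparison of heritability-estimate distributions.

Clustering methods are contrasted by pairwise Mann-Whitney U tests over their
per-OTU A/C/E estimate distributions, with one Benjamini-Hochberg FDR
correction across the family of pairwise tests for each component.  A
"heritable unit" filter retains OTUs whose A exceeds the pooled across-method
mean and whose lower 95% profile CI clears a floor (default 1%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde, mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .ace import HeritabilityProfile

logger = logging.getLogger(__name__)

_EXACT_MAX_N = 12


@dataclass
class ComparisonTable:
    rows: pd.DataFrame  # method_a, method_b, component, U, p, q


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    U counts (i, j) with x_i > y_j plus half the ties.  The p-value is exact
    (full enumeration) when |x| + |y| <= 12 and there are no ties, otherwise
    the normal approximation with tie-corrected variance and continuity
    correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty input to Mann-Whitney U")
    no_ties = np.unique(np.concatenate([x, y])).size == x.size + y.size
    method = "exact" if (x.size + y.size <= _EXACT_MAX_N and no_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def compare_profiles(profiles: Sequence[HeritabilityProfile], component: str = "A") -> ComparisonTable:
    """Pairwise MWU of per-OTU component estimates, BH-corrected as one family."""
    if len(profiles) < 2:
        raise ValueError("need at least two profiles to compare")
    usable = []
    for p in profiles:
        if len(p.estimates) < 2:
            logger.warning("profile %s has < 2 OTUs; excluded from comparison", p.method_label)
            continue
        usable.append(p)
    rows = []
    for pa, pb in combinations(usable, 2):
        U, pval = mann_whitney_u(pa.component_values(component), pb.component_values(component))
        rows.append(dict(method_a=pa.method_label, method_b=pb.method_label,
                         component=component, U=U, p=pval))
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = bh_adjust(df["p"].to_numpy())
    else:
        df["q"] = []
    return ComparisonTable(df)


def pooled_mean_A(profiles: Sequence[HeritabilityProfile]) -> float:
    """Mean A over the pooled OTUs of all methods under comparison."""
    values = np.concatenate([p.component_values("A") for p in profiles])
    return float(values.mean())


def heritable_subset(
    profile: HeritabilityProfile,
    global_mean: float,
    ci_floor: float = 0.01,
) -> HeritabilityProfile:
    """OTUs with A strictly above the pooled mean and CI lower bound >= floor."""
    kept = [
        e
        for e in profile.estimates
        if e.ci_A is not None and e.A > global_mean and e.ci_A[0] >= ci_floor
    ]
    return HeritabilityProfile(method_label=profile.method_label, estimates=kept)


def summarize_profile(profile: HeritabilityProfile, density_points: int = 256) -> dict:
    """Per-component summary statistics plus a Gaussian-KDE density export.

    The KDE uses Silverman's bandwidth rule; the density grid spans the data
    range padded by three bandwidths so the curve integrates to ~1.
    """
    out: dict = {"method_label": profile.method_label, "n_otus": len(profile.estimates)}
    for component in ("A", "C", "E"):
        v = profile.component_values(component)
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        summary = dict(mean=float(v.mean()), median=float(med), q1=float(q1), q3=float(q3))
        if v.size > 1 and v.std() > 1e-9 * max(1.0, np.abs(v).max()):
            kde = gaussian_kde(v, bw_method="silverman")
            bw = kde.factor * v.std(ddof=1)
            grid = np.linspace(v.min() - 3 * bw, v.max() + 3 * bw, density_points)
            summary["density"] = (grid, kde(grid))
        out[component] = summary
    return out
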