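"""Taxonomic collapse of OTU tables and taxon/method modelling of heritability.

Collapsing sums member-OTU counts within each unique lineage prefix at the
requested rank (phylum .. genus), conserving per-sample totals.  OTUs whose
lineage is unassigned at that rank are grouped under their deepest assigned
parent (``unclassified_<parent lineage>``) so unrelated unclassified taxa are
not merged.

``heritability_glm`` fits the Gaussian linear model
``A ~ taxon + method`` (treatment coding, alphabetical reference levels) to
ask whether taxon identity — rather than the clustering method that produced
the table — predicts heritability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .ace import HeritabilityProfile
from .tables_io import RANKS, OtuTable

logger = logging.getLogger(__name__)

_COLLAPSE_LEVELS = RANKS[1:]  # phylum .. genus


@dataclass
class GlmResult:
    coefficients: pd.DataFrame  # index term; columns estimate, se, t, p
    reference_levels: dict
    n_obs: int
    r_squared: float

    def significant_terms(self, prefix: str, alpha: float = 0.05) -> list[str]:
        mask = self.coefficients.index.str.startswith(prefix) & (self.coefficients["p"] < alpha)
        return list(self.coefficients.index[mask])


def lineage_label(lineage: Sequence[str], level: str) -> str:
    """Lineage prefix label at ``level``; unassigned ranks fall back to the
    deepest assigned parent, prefixed ``unclassified_``."""
    depth = RANKS.index(level)
    prefix = [str(r).strip() for r in lineage[: depth + 1]]
    if prefix and prefix[depth]:
        return ";".join(prefix)
    assigned = [r for r in prefix if r]
    return "unclassified_" + (";".join(assigned) if assigned else "unknown")


def collapse_by_taxonomy(
    table: OtuTable,
    taxonomy: Mapping[str, Sequence[str]],
    level: str,
) -> OtuTable:
    """Sum OTU counts into taxa at ``level``; column totals are conserved."""
    if level not in _COLLAPSE_LEVELS:
        raise ValueError(f"level must be one of {_COLLAPSE_LEVELS}, got {level!r}")
    missing = [o for o in table.otu_ids if o not in taxonomy]
    if missing:
        raise ValueError(f"OTUs without taxonomy: {missing[:5]}")
    groups: dict[str, np.ndarray] = {}
    for i, otu in enumerate(table.otu_ids):
        label = lineage_label(list(taxonomy[otu]), level)
        if label in groups:
            groups[label] = groups[label] + table.counts[i]
        else:
            groups[label] = table.counts[i].copy()
    labels = sorted(groups)
    counts = np.vstack([groups[t] for t in labels])
    return OtuTable(table.method_label, labels, list(table.sample_ids), counts)


def shared_taxa(profiles: Sequence[HeritabilityProfile]) -> list[str]:
    """Taxa present in every profile, alphabetically ordered."""
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    common = set(e.otu_id for e in profiles[0].estimates)
    for p in profiles[1:]:
        common &= {e.otu_id for e in p.estimates}
    return sorted(common)


def heritability_glm(observations: pd.DataFrame) -> GlmResult:
    """Gaussian linear model ``A ~ taxon + method`` with Wald t-tests.

    ``observations`` needs columns taxon, method, A.  Taxa observed under a
    single method are collinear with the method factor in unbalanced designs
    only when alone; genuinely collinear taxa are dropped with a warning.
    """
    df = observations.copy()
    for col in ("taxon", "method", "A"):
        if col not in df.columns:
            raise ValueError(f"observations require a {col!r} column")
    if df["taxon"].nunique() < 2 or df["method"].nunique() < 2:
        raise ValueError("need at least 2 taxa and 2 methods")

    def design(frame: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
        taxa = sorted(frame["taxon"].unique())
        methods = sorted(frame["method"].unique())
        X = pd.DataFrame({"intercept": np.ones(len(frame))}, index=frame.index)
        for t in taxa[1:]:
            X[f"taxon[{t}]"] = (frame["taxon"] == t).astype(float)
        for m in methods[1:]:
            X[f"method[{m}]"] = (frame["method"] == m).astype(float)
        return X, {"taxon": taxa[0], "method": methods[0]}

    X, refs = design(df)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # drop taxa seen under a single method until full rank
        counts = df.groupby("taxon")["method"].nunique()
        lonely = list(counts.index[counts < 2])
        if lonely:
            logger.warning("dropping collinear taxa observed under one method: %s", lonely)
            df = df[~df["taxon"].isin(lonely)]
            X, refs = design(df)
        if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
            raise ValueError("design remains collinear after dropping single-method taxa")

    model = sm.OLS(df["A"].to_numpy(), X.to_numpy())
    fit = model.fit()
    coef = pd.DataFrame(
        {"estimate": fit.params, "se": fit.bse, "t": fit.tvalues, "p": fit.pvalues},
        index=X.columns,
    )
    return GlmResult(coef, refs, int(fit.nobs), float(fit.rsquared))
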