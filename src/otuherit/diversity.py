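"""Rarefaction-based alpha diversity and cross-method concordance.

Each sample is rarefied (multivariate-hypergeometric subsampling without
replacement) to a fixed depth — 10,000 reads, 25 times by default — and the
Shannon (log base 2), Simpson (1 - sum p^2), Chao1 (bias-corrected) and
observed-OTU metrics are averaged over the rarefactions.  Methods are then
contrasted on absolute values (pairwise Mann-Whitney U, BH-corrected) and on
sample rankings (Kendall tau-b), the latter being what matters for diversity
association analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import kendalltau
from skbio.diversity import alpha as _alpha

from .method_compare import bh_adjust, mann_whitney_u
from .tables_io import OtuTable

logger = logging.getLogger(__name__)

METRICS = ("shannon", "simpson", "chao1", "observed_otus")


@dataclass
class DiversityProfile:
    method_label: str
    values: pd.DataFrame  # index sample_id, one column per metric (means over reps)
    depth: int
    n_reps: int
    dropped_samples: list = field(default_factory=list)


def rarefy(column: np.ndarray, depth: int, seed=None) -> np.ndarray:
    """Subsample a count vector to ``depth`` reads without replacement."""
    column = np.asarray(column)
    if depth <= 0:
        raise ValueError("depth must be positive")
    total = int(column.sum())
    if total < depth:
        raise ValueError(f"column total {total} below rarefaction depth {depth}")
    rng = np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(column.astype(np.int64), depth)


def shannon(counts: np.ndarray, base: float = 2.0) -> float:
    """Shannon entropy H = -sum p_i log_base p_i over nonzero categories."""
    counts = np.asarray(counts, dtype=float)
    if counts.sum() <= 0:
        raise ValueError("counts must sum to > 0")
    return float(_alpha.shannon(counts, base=base))


def simpson(counts: np.ndarray) -> float:
    """Simpson diversity 1 - sum p_i^2."""
    counts = np.asarray(counts, dtype=float)
    if counts.sum() <= 0:
        raise ValueError("counts must sum to > 0")
    return float(_alpha.simpson(counts))


def chao1(counts: np.ndarray, bias_corrected: bool = True) -> float:
    """Chao1 richness; classic form falls back to bias-corrected when F2 = 0."""
    counts = np.asarray(counts)
    if counts.sum() <= 0:
        raise ValueError("counts must sum to > 0")
    if not bias_corrected:
        singles = int((counts == 1).sum())
        doubles = int((counts == 2).sum())
        if doubles == 0 and singles > 0:
            logger.warning("classic Chao1 undefined with no doubletons; using bias-corrected form")
            return float(_alpha.chao1(counts, bias_corrected=True))
    return float(_alpha.chao1(counts, bias_corrected=bias_corrected))


def observed_otus(counts: np.ndarray) -> int:
    """Number of OTUs with nonzero counts."""
    return int(_alpha.sobs(np.asarray(counts)))


_METRIC_FUNCS = {
    "shannon": shannon,
    "simpson": simpson,
    "chao1": chao1,
    "observed_otus": observed_otus,
}


def alpha_diversity(
    table: OtuTable,
    depth: int = 10_000,
    reps: int = 25,
    seed: int = 0,
    shannon_base: float = 2.0,
    chao1_bias_corrected: bool = True,
) -> DiversityProfile:
    """Mean alpha diversity over ``reps`` rarefactions per sample.

    Rarefaction r of sample j uses seed ``seed + r`` combined with the sample
    index, so reruns are bit-identical.  Samples with fewer than ``depth``
    total reads are dropped (listed on the profile), not imputed.
    """
    dropped = []
    rows = {}
    totals = table.counts.sum(axis=0)
    for j, sample in enumerate(table.sample_ids):
        if totals[j] < depth:
            dropped.append(sample)
            continue
        acc = {m: 0.0 for m in METRICS}
        for r in range(reps):
            sub = rarefy(table.counts[:, j], depth, seed=np.random.SeedSequence((seed + r, j)))
            acc["shannon"] += shannon(sub, base=shannon_base)
            acc["simpson"] += simpson(sub)
            acc["chao1"] += chao1(sub, bias_corrected=chao1_bias_corrected)
            acc["observed_otus"] += observed_otus(sub)
        rows[sample] = {m: acc[m] / reps for m in METRICS}
    if not rows:
        raise ValueError("every sample falls below the rarefaction depth")
    if dropped:
        logger.info("%s: %d samples below depth %d dropped", table.method_label, len(dropped), depth)
    return DiversityProfile(table.method_label, pd.DataFrame.from_dict(rows, orient="index"),
                            depth=depth, n_reps=reps, dropped_samples=dropped)


def compare_alpha(
    profiles: Sequence[DiversityProfile],
    metric: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Absolute-value MWU table (BH-corrected) and Kendall tau-b matrix.

    Comparisons are restricted to samples retained (not dropped) in every
    profile; at least 3 shared samples are required.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    shared = set(profiles[0].values.index)
    for p in profiles[1:]:
        shared &= set(p.values.index)
    shared = sorted(shared)
    if len(shared) < 3:
        raise ValueError("fewer than 3 samples shared across profiles")
    labels = [p.method_label for p in profiles]
    series = {p.method_label: p.values.loc[shared, metric].to_numpy() for p in profiles}

    rows = []
    for a, b in combinations(labels, 2):
        U, pval = mann_whitney_u(series[a], series[b])
        rows.append(dict(method_a=a, method_b=b, metric=metric, U=U, p=pval))
    mwu = pd.DataFrame(rows)
    if len(mwu):
        mwu["q"] = bh_adjust(mwu["p"].to_numpy())

    tau = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
    for a, b in combinations(labels, 2):
        t = kendalltau(series[a], series[b]).statistic
        tau.loc[a, b] = tau.loc[b, a] = t
    return mwu, tau
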