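"""Raw OTU counts -> per-OTU model-ready residual traits.

The pipeline mirrors the standard twin-microbiome heritability workflow:

1. record prevalence (count > 0) on the *raw* counts;
2. add a pseudo-count of 1 to every cell, so abundances are strictly positive;
3. convert to within-sample relative abundances;
4. subset to OTUs prevalent in at least 50% of samples;
5. per OTU: pick the Box-Cox exponent lambda maximizing the profile
   log-likelihood of the linear model ``y(lambda) ~ covariates`` (gender, age,
   sequencing run, sequencing depth, collection method, technician), then take
   OLS residuals of the transformed abundance, standardized to unit variance.

The residuals are the traits passed to the twin ACE model; covariate
adjustment happens here, not inside the variance-components likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .tables_io import OtuTable, SampleRecord

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = [
    "gender",
    "age",
    "sequencing_run",
    "sequencing_depth",
    "collection_method",
    "technician",
]

LAMBDA_RANGE = (-5.0, 5.0)
_COARSE_STEP = 0.1
_DEGENERATE_VAR = 1e-12


class CollinearDesignError(ValueError):
    """Design matrix is rank deficient; offending columns are named."""

    def __init__(self, columns: list[str]):
        self.columns = columns
        super().__init__(f"collinear design columns: {columns}")


@dataclass
class AbundanceTable:
    """Within-sample relative abundances (columns sum to 1, all cells > 0)."""

    otu_ids: list[str]
    sample_ids: list[str]
    rel_abundance: np.ndarray

    def __post_init__(self) -> None:
        ra = np.asarray(self.rel_abundance, dtype=float)
        colsums = ra.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise ValueError("relative-abundance columns must sum to 1")
        if (ra <= 0).any():
            raise ValueError("relative abundances must be strictly positive (pseudo-count upstream)")
        self.rel_abundance = ra


@dataclass
class TransformResult:
    otu_id: str
    lam: float
    profile_loglik_at_lambda: float
    residuals: np.ndarray
    design_columns: list[str]
    degenerate: bool = False


@dataclass
class TraitMatrix:
    """Per-OTU standardized residual traits, samples in table order."""

    otu_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    provenance: str = ""

    def trait(self, otu_id: str) -> dict[str, float]:
        row = self.values[self.otu_ids.index(otu_id)]
        return dict(zip(self.sample_ids, row))


def prevalence_filter(table: OtuTable, min_fraction: float = 0.5) -> OtuTable:
    """Keep OTUs with nonzero counts in at least ``min_fraction`` of samples."""
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must be in (0, 1]")
    frac = (table.counts > 0).mean(axis=1)
    keep = [o for o, f in zip(table.otu_ids, frac) if f >= min_fraction]
    return table.subset_otus(keep)


def add_pseudocount(table: OtuTable, value: int = 1) -> OtuTable:
    if value < 1:
        raise ValueError("pseudo-count must be a positive integer")
    return OtuTable(table.method_label, list(table.otu_ids), list(table.sample_ids), table.counts + value)


def to_relative_abundance(table: OtuTable) -> AbundanceTable:
    totals = table.counts.sum(axis=0)
    if (totals == 0).any():
        bad = [s for s, t in zip(table.sample_ids, totals) if t == 0]
        raise ValueError(f"zero column total for samples {bad}")
    return AbundanceTable(list(table.otu_ids), list(table.sample_ids), table.counts / totals)


def build_design(
    records: Sequence[SampleRecord],
    covariate_names: Sequence[str],
    sample_order: Sequence[str],
) -> tuple[np.ndarray, list[str]]:
    """Intercept + covariate design matrix in the given sample order.

    Numeric covariates enter as-is; categorical covariates are one-hot encoded
    with the alphabetically first level dropped as reference.
    """
    by_id = {r.sample_id: r for r in records}
    missing = [s for s in sample_order if s not in by_id]
    if missing:
        raise ValueError(f"samples without metadata records: {missing[:5]}")
    cols: list[np.ndarray] = [np.ones(len(sample_order))]
    names: list[str] = ["intercept"]
    for name in covariate_names:
        values = [by_id[s].covariates.get(name) for s in sample_order]
        if any(v is None for v in values):
            bad = [s for s, v in zip(sample_order, values) if v is None]
            raise ValueError(f"covariate {name!r} missing for samples {bad[:5]}")
        if all(isinstance(v, (int, float)) for v in values):
            cols.append(np.asarray(values, dtype=float))
            names.append(name)
        else:
            levels = sorted({str(v) for v in values})
            for level in levels[1:]:
                cols.append(np.asarray([1.0 if str(v) == level else 0.0 for v in values]))
                names.append(f"{name}[{level}]")
    X = np.column_stack(cols)
    _check_rank(X, names)
    return X, names


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    bad = [names[i] for i in np.flatnonzero(diag < tol)]
    if bad:
        raise CollinearDesignError(bad)


def boxcox_transform(y: np.ndarray, lam: float) -> np.ndarray:
    """Power transform y(lambda) = (y^lambda - 1)/lambda, log y at lambda=0."""
    logy = np.log(y)
    if abs(lam) < 1e-10:
        return logy
    return np.expm1(lam * logy) / lam


def boxcox_profile_loglik(y: np.ndarray, lam: float, Q: np.ndarray) -> float:
    """Profile log-likelihood of ``y(lambda) ~ design`` at one lambda.

    ``Q`` is an orthonormal basis of the design column space; the profile
    log-likelihood is -(n/2) log(RSS/n) + (lambda - 1) sum(log y), with the
    variance profiled out.
    """
    n = y.size
    z = boxcox_transform(y, lam)
    resid = z - Q @ (Q.T @ z)
    rss = float(resid @ resid)
    if rss <= 0:
        return np.inf
    return -0.5 * n * np.log(rss / n) + (lam - 1.0) * float(np.log(y).sum())


def boxcox_lambda(
    y: np.ndarray,
    design: np.ndarray,
    design_names: Sequence[str] | None = None,
    lambda_range: tuple[float, float] = LAMBDA_RANGE,
) -> tuple[float, float]:
    """Maximize the Box-Cox profile log-likelihood over lambda.

    Coarse grid (step 0.1) over ``lambda_range`` followed by bounded scalar
    refinement within the bracketing grid cells.  Returns (lambda, loglik).
    """
    y = np.asarray(y, dtype=float)
    if (y <= 0).any():
        raise ValueError("Box-Cox requires strictly positive values")
    X = np.asarray(design, dtype=float)
    if y.size != X.shape[0]:
        raise ValueError("length of y must match design rows")
    _check_rank(X, list(design_names) if design_names is not None else [f"x{i}" for i in range(X.shape[1])])
    Q, _ = np.linalg.qr(X)

    lo, hi = lambda_range
    grid = np.arange(lo, hi + _COARSE_STEP / 2, _COARSE_STEP)
    ll = np.array([boxcox_profile_loglik(y, lam, Q) for lam in grid])
    k = int(np.argmax(ll))
    a = grid[max(k - 1, 0)]
    b = grid[min(k + 1, grid.size - 1)]
    res = minimize_scalar(
        lambda lam: -boxcox_profile_loglik(y, lam, Q),
        bounds=(a, b),
        method="bounded",
        options={"xatol": 1e-6},
    )
    lam_hat = float(res.x)
    best = boxcox_profile_loglik(y, lam_hat, Q)
    if ll[k] > best:  # refinement must not do worse than the grid
        lam_hat, best = float(grid[k]), float(ll[k])
    return lam_hat, float(best)


def covariate_residuals(
    y_transformed: np.ndarray,
    design: np.ndarray,
    design_names: Sequence[str] | None = None,
    standardize: bool = True,
) -> tuple[np.ndarray, bool]:
    """OLS residuals of the transformed trait, scaled to unit variance.

    Returns (residuals, degenerate); degenerate flags residual variance below
    1e-12 (trait fully explained by covariates), in which case the raw
    residuals are returned unscaled.
    """
    y = np.asarray(y_transformed, dtype=float)
    X = np.asarray(design, dtype=float)
    if y.size != X.shape[0]:
        raise ValueError("length of y must match design rows")
    _check_rank(X, list(design_names) if design_names is not None else [f"x{i}" for i in range(X.shape[1])])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    var = float(resid.var(ddof=1)) if resid.size > 1 else 0.0
    if var < _DEGENERATE_VAR:
        return resid, True
    if standardize:
        resid = (resid - resid.mean()) / np.sqrt(var)
    return resid, False


def prepare_traits(
    table: OtuTable,
    records: Sequence[SampleRecord],
    covariate_names: Sequence[str] | None = None,
    min_prevalence: float = 0.5,
    pseudocount: int = 1,
) -> tuple[TraitMatrix, list[TransformResult]]:
    """Full preprocessing pipeline for one OTU table.

    Prevalence is assessed on the raw counts, the pseudo-count and
    relative-abundance conversion are applied to the full table, and only then
    is the table subset to prevalent OTUs — so each OTU's relative abundance
    reflects the complete community.  Degenerate traits (residual variance
    below 1e-12) are excluded with a warning.
    """
    if covariate_names is None:
        covariate_names = [c for c in DEFAULT_COVARIATES if any(c in r.covariates for r in records)]
    by_id = {r.sample_id: r for r in records}
    sample_order = [
        s
        for s in table.sample_ids
        if s in by_id and all(by_id[s].covariates.get(c) is not None for c in covariate_names)
    ]
    if len(sample_order) < 3:
        raise ValueError("fewer than 3 samples with complete metadata")
    table = table.subset_samples(sample_order)

    prevalent = set(prevalence_filter(table, min_prevalence).otu_ids)
    abundance = to_relative_abundance(add_pseudocount(table, pseudocount))
    X, names = build_design(records, covariate_names, sample_order)
    Q, _ = np.linalg.qr(X)

    kept_ids: list[str] = []
    rows: list[np.ndarray] = []
    log: list[TransformResult] = []
    for i, otu in enumerate(abundance.otu_ids):
        if otu not in prevalent:
            continue
        y = abundance.rel_abundance[i]
        lam, ll = boxcox_lambda(y, X, names)
        resid, degenerate = covariate_residuals(boxcox_transform(y, lam), X, names)
        log.append(TransformResult(otu, lam, ll, resid, list(names), degenerate))
        if degenerate:
            logger.warning("OTU %s: degenerate residual variance; excluded from traits", otu)
            continue
        kept_ids.append(otu)
        rows.append(resid)
    values = np.vstack(rows) if rows else np.empty((0, len(sample_order)))
    return TraitMatrix(kept_ids, sample_order, values, provenance=table.method_label), log


def write_transform_log(log: Sequence[TransformResult], path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "otu_id": [t.otu_id for t in log],
            "lambda": [t.lam for t in log],
            "loglik": [t.profile_loglik_at_lambda for t in log],
            "n_samples": [t.residuals.size for t in log],
        }
    ).to_csv(path, sep="\t", index=False)
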