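"""Synthetic twin-paired OTU tables with known A/C/E structure.

The generator produces the data shape of a large twin 16S study — by default
473 MZ and 402 DZ complete pairs (1,750 samples) at a mean library size of
91,170 reads — with a known per-OTU variance decomposition, so every stage of
the heritability pipeline can be validated against ground truth.

Per OTU j, a latent standard-normal trait is built from the twin model:
``z = sqrt(A_j) g + sqrt(C_j) c + sqrt(E_j) e`` with the additive genetic
value g correlated 1 within MZ pairs and 0.5 within DZ pairs, c shared
exactly within a pair, and e independent.  The latent trait maps to expected
relative abundance log-linearly (``p_ij ∝ exp(base_j + covariate effects +
scale * z_ij)``), abundances are therefore positively skewed and the Box-Cox
stage has something to do.  Structural absences (zero inflation) are
abundance-dependent — OTU j is absent from the samples where its latent
trait falls in its lower ``zero_inflation_j`` tail — and counts are drawn
multinomially at a Poisson library size.

``perturb_clustering`` emulates what alternative OTU-clustering methods do to
the same reads: *split* divides an OTU's reads among child OTUs with
sample-dependent Dirichlet proportions (noisy read misassignment), *merge*
sums unrelated OTUs.  Both conserve per-sample totals.  ``drop_rare_reads``
emulates reference-based read discarding by zeroing singleton/doubleton
cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .ace import PairedTrait
from .tables_io import OtuTable, SampleRecord, Zygosity

DEFAULT_A_GRID = (0.0, 0.1, 0.2, 0.3, 0.4)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic twin-microbiome dataset."""

    n_mz: int = 473
    n_dz: int = 402
    n_otus: int = 50
    A: np.ndarray | None = None          # per-OTU additive proportion; default cycles DEFAULT_A_GRID
    C: np.ndarray | float = 0.1          # per-OTU shared-environment proportion
    base_abundance: np.ndarray | None = None  # per-OTU mean log-abundance; default N(0, 1.5^2)
    base_abundance_sd: float = 1.5
    zero_inflation: np.ndarray | float = 0.1  # per-OTU structural-absence probability
    covariate_effects: Mapping[str, np.ndarray] | None = None  # covariate -> per-OTU slope
    latent_scale: float = 1.0            # latent trait -> log-abundance scale
    library_size: float = 91_170.0       # mean reads per sample (Poisson)
    seed: int = 0

    def resolve(self, rng: np.random.Generator) -> "SimulationConfig":
        """Fill array defaults; validates the A/C/E simplex."""
        A = self.A
        if A is None:
            A = np.array([DEFAULT_A_GRID[j % len(DEFAULT_A_GRID)] for j in range(self.n_otus)])
        A = np.broadcast_to(np.asarray(A, dtype=float), (self.n_otus,)).copy()
        C = np.broadcast_to(np.asarray(self.C, dtype=float), (self.n_otus,)).copy()
        if (A < 0).any() or (C < 0).any() or (A + C > 1).any():
            raise ValueError("per-OTU A, C must be >= 0 with A + C <= 1")
        base = self.base_abundance
        if base is None:
            base = rng.normal(0.0, self.base_abundance_sd, size=self.n_otus)
        base = np.broadcast_to(np.asarray(base, dtype=float), (self.n_otus,)).copy()
        zi = np.broadcast_to(np.asarray(self.zero_inflation, dtype=float), (self.n_otus,)).copy()
        if (zi < 0).any() or (zi > 1).any():
            raise ValueError("zero_inflation probabilities must lie in [0, 1]")
        effects = self.covariate_effects
        if effects is None:
            effects = {
                "age": rng.normal(0.0, 0.01, size=self.n_otus),
                "sequencing_run": rng.normal(0.0, 0.3, size=self.n_otus),
            }
        effects = {k: np.broadcast_to(np.asarray(v, dtype=float), (self.n_otus,)).copy()
                   for k, v in effects.items()}
        if self.library_size < 1:
            raise ValueError("library_size must be >= 1")
        return SimulationConfig(
            self.n_mz, self.n_dz, self.n_otus, A, C, base, self.base_abundance_sd,
            zi, effects, self.latent_scale, self.library_size, self.seed,
        )


@dataclass
class SimulatedDataset:
    table: OtuTable
    records: list[SampleRecord]
    truth: SimulationConfig
    latent: np.ndarray = field(repr=False, default=None)  # n_otus x n_samples latent traits


def simulate_twin_traits(
    n_mz: int,
    n_dz: int,
    A: float,
    C: float,
    E: float,
    seed=None,
) -> PairedTrait:
    """Latent twin-pair traits with exact (A, C, E) variance decomposition."""
    if min(A, C, E) < 0 or abs(A + C + E - 1.0) > 1e-9:
        raise ValueError("A, C, E must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    # MZ: identical additive genetic values
    g1 = rng.standard_normal(n_mz)
    c = rng.standard_normal(n_mz)
    e = rng.standard_normal((n_mz, 2))
    mz = np.sqrt(A) * g1[:, None] + np.sqrt(C) * c[:, None] + np.sqrt(E) * e
    # DZ: additive genetic correlation 1/2
    x = rng.standard_normal(n_dz)
    xp = rng.standard_normal(n_dz)
    gdz = np.column_stack([x, 0.5 * x + np.sqrt(0.75) * xp])
    c = rng.standard_normal(n_dz)
    e = rng.standard_normal((n_dz, 2))
    dz = np.sqrt(A) * gdz + np.sqrt(C) * c[:, None] + np.sqrt(E) * e
    return PairedTrait(mz, dz)


def simulate_twin_otu_table(config: SimulationConfig, method_label: str = "truth") -> SimulatedDataset:
    """Generate the OTU count table, twin metadata, and the generating truth."""
    rng = np.random.default_rng(config.seed)
    cfg = config.resolve(rng)
    n_pairs = cfg.n_mz + cfg.n_dz
    n_samples = 2 * n_pairs

    sample_ids = [f"S{k:04d}" for k in range(n_samples)]
    family_ids = [f"F{p:04d}" for p in range(n_pairs)]
    zygosity = [Zygosity.MZ] * cfg.n_mz + [Zygosity.DZ] * cfg.n_dz

    # covariates: age shared within a pair (twins are the same age); MZ pairs
    # share sex; runs/collection/technician vary per sample
    age_pair = rng.uniform(20.0, 80.0, size=n_pairs)
    sex_pair = rng.choice(["F", "M"], size=n_pairs)
    sex = np.empty(n_samples, dtype=object)
    run = rng.choice(["run1", "run2"], size=n_samples)
    collect = rng.choice(["home", "clinic"], size=n_samples)
    tech = rng.choice(["tech1", "tech2"], size=n_samples)
    for p in range(n_pairs):
        i1, i2 = 2 * p, 2 * p + 1
        if zygosity[p] is Zygosity.MZ:
            sex[i1] = sex[i2] = sex_pair[p]
        else:
            sex[i1], sex[i2] = rng.choice(["F", "M"], size=2)

    # latent traits per OTU, arranged sample-wise (pair p -> columns 2p, 2p+1)
    latent = np.empty((cfg.n_otus, n_samples))
    trait_rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 1)))
    for j in range(cfg.n_otus):
        A_j, C_j = cfg.A[j], cfg.C[j]
        pt = simulate_twin_traits(cfg.n_mz, cfg.n_dz, A_j, C_j, 1.0 - A_j - C_j, seed=trait_rng)
        stacked = np.vstack([pt.mz, pt.dz])  # n_pairs x 2
        latent[j] = stacked.reshape(-1)

    # log-linear expected abundance with covariate effects
    covariate_numeric = {
        "age": np.repeat(age_pair, 2),
        "sequencing_run": (run == "run2").astype(float),
        "gender": np.array([1.0 if s == "M" else 0.0 for s in sex]),
        "collection_method": (collect == "clinic").astype(float),
        "technician": (tech == "tech2").astype(float),
    }
    eta = cfg.base_abundance[:, None] + cfg.latent_scale * latent
    for name, slopes in cfg.covariate_effects.items():
        if name not in covariate_numeric:
            raise ValueError(f"unknown covariate in effects: {name!r}")
        eta = eta + slopes[:, None] * covariate_numeric[name][None, :]

    weights = np.exp(eta - eta.max(axis=0, keepdims=True))
    # structural absence is abundance-dependent: OTU j is absent from the
    # samples where its latent trait falls in the lower zero_inflation_j tail,
    # so absence carries the same twin signal as abundance (real taxa are
    # absent where conditions — including host genotype — disfavour them)
    thresholds = norm.ppf(np.clip(cfg.zero_inflation, 0.0, 1.0))
    present = latent > thresholds[:, None]
    weights = np.where(present, weights, 0.0)
    # a sample with every OTU structurally absent would be unusable; keep the
    # highest-weight OTU present
    dead = weights.sum(axis=0) == 0
    if dead.any():
        weights[eta.argmax(axis=0)[dead], np.flatnonzero(dead)] = 1.0
    probs = weights / weights.sum(axis=0, keepdims=True)

    depths = trait_rng.poisson(cfg.library_size, size=n_samples)
    depths = np.maximum(depths, 1)
    counts = np.empty((cfg.n_otus, n_samples), dtype=np.int64)
    for i in range(n_samples):
        counts[:, i] = trait_rng.multinomial(depths[i], probs[:, i])

    records = []
    for i, sid in enumerate(sample_ids):
        p = i // 2
        records.append(
            SampleRecord(
                sid,
                family_ids[p],
                zygosity[p],
                covariates={
                    "gender": str(sex[i]),
                    "age": float(covariate_numeric["age"][i]),
                    "sequencing_run": str(run[i]),
                    "sequencing_depth": float(counts[:, i].sum()),
                    "collection_method": str(collect[i]),
                    "technician": str(tech[i]),
                },
            )
        )
    otu_ids = [f"OTU{j:03d}" for j in range(cfg.n_otus)]
    table = OtuTable(method_label, otu_ids, sample_ids, counts)
    return SimulatedDataset(table, records, cfg, latent)


def perturb_clustering(
    table: OtuTable,
    mode: str,
    k: int = 2,
    noise: float = 0.0,
    seed: int = 0,
) -> OtuTable:
    """Emulate an alternative clustering of the same reads.

    ``split``: every OTU's reads are reassigned among k child OTUs with
    per-sample Dirichlet proportions (noise=0 gives deterministic equal
    shares; larger noise gives noisier misassignment).  ``merge``: random
    groups of k unrelated OTUs are summed.  Per-sample totals are conserved.
    """
    rng = np.random.default_rng(seed)
    if mode == "split":
        if k < 2:
            raise ValueError("split requires k >= 2")
        if not (0 <= noise < 1):
            raise ValueError("noise must lie in [0, 1)")
        new_ids: list[str] = []
        rows: list[np.ndarray] = []
        for i, otu in enumerate(table.otu_ids):
            parent = table.counts[i]
            children = np.zeros((k, parent.size), dtype=np.int64)
            if noise == 0:
                base = parent // k
                rem = parent - base * k
                children[:] = base
                # leftover reads go to the first children, deterministically
                for child in range(k):
                    children[child] += (rem > child).astype(np.int64)
            else:
                alpha = (1.0 / noise - 1.0) * np.ones(k)
                for s in np.flatnonzero(parent > 0):
                    w = rng.dirichlet(alpha)
                    children[:, s] = rng.multinomial(parent[s], w)
            for child in range(k):
                new_ids.append(f"{otu}.{child}")
                rows.append(children[child])
        return OtuTable(f"{table.method_label}_split", new_ids, list(table.sample_ids), np.vstack(rows))
    if mode == "merge":
        if len(table.otu_ids) < 2:
            raise ValueError("merge requires at least 2 OTUs")
        order = rng.permutation(len(table.otu_ids))
        new_ids, rows = [], []
        for start in range(0, len(order), k):
            group = order[start : start + k]
            new_ids.append("+".join(table.otu_ids[g] for g in sorted(group)))
            rows.append(table.counts[group].sum(axis=0))
        return OtuTable(f"{table.method_label}_merge", new_ids, list(table.sample_ids), np.vstack(rows))
    raise ValueError(f"unknown perturbation mode {mode!r}")


def drop_rare_reads(table: OtuTable, max_count: int = 2) -> OtuTable:
    """Zero every cell with count <= max_count (discard singleton/doubleton reads).

    Emulates clustering approaches that discard rare reads (closed-reference
    matching, minimum-abundance filters), which depresses richness metrics
    while leaving evenness metrics nearly untouched.
    """
    counts = np.where(table.counts <= max_count, 0, table.counts)
    return OtuTable(f"{table.method_label}_norare", list(table.otu_ids), list(table.sample_ids), counts)


def write_truth(dataset: SimulatedDataset, path) -> None:
    cfg = dataset.truth
    pd.DataFrame(
        {
            "otu_id": dataset.table.otu_ids,
            "A": cfg.A,
            "C": cfg.C,
            "E": 1.0 - cfg.A - cfg.C,
            "base_abundance": cfg.base_abundance,
            "zero_inflation": cfg.zero_inflation,
        }
    ).to_csv(path, sep="\t", index=False)
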