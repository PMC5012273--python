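"""Reading and pairing of OTU tables, twin metadata, and taxonomy maps.

The canonical on-disk format for an OTU table is TSV: first header cell
``#OTU_ID``, remaining header cells sample ids, one row per OTU with integer
counts.  BIOM-JSON v1.0 (dense or sparse) is supported read-only.  Twin
metadata is TSV with columns ``sample_id``, ``family_id``, ``zygosity``
(MZ/DZ, case-insensitive) followed by covariate columns; covariates are typed
numeric when every value parses as a number, categorical otherwise.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

OTU_HEADER = "#OTU_ID"


class FormatError(ValueError):
    """Malformed input file (duplicate ids, bad header, bad JSON layout)."""


class EmptyDesignError(ValueError):
    """No usable twin pairs remain after matching and exclusion."""


class Zygosity(str, Enum):
    MZ = "MZ"
    DZ = "DZ"

    @classmethod
    def parse(cls, text: str) -> "Zygosity":
        try:
            return cls(str(text).strip().upper())
        except ValueError:
            raise ValueError(f"unknown zygosity code: {text!r}") from None


@dataclass
class OtuTable:
    """Integer count matrix (OTUs x samples) with a method provenance label."""

    method_label: str
    otu_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.otu_ids = [str(o) for o in self.otu_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        for name, ids in (("OTU", self.otu_ids), ("sample", self.sample_ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise FormatError(f"duplicate {name} id: {i!r}")
                seen.add(i)
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.otu_ids)} OTUs x {len(self.sample_ids)} samples"
            )
        if len(self.otu_ids) < 1 or len(self.sample_ids) < 2:
            raise ValueError("need at least 1 OTU and 2 samples")
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if not np.allclose(counts, rounded, rtol=0, atol=1e-9):
                raise ValueError("non-integral count values present")
            counts = rounded.astype(np.int64)
        if (counts < 0).any():
            raise ValueError("negative count values present")
        self.counts = counts.astype(np.int64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.otu_ids, columns=self.sample_ids)

    def subset_otus(self, keep: Sequence[str]) -> "OtuTable":
        keep_set = set(keep)
        idx = [i for i, o in enumerate(self.otu_ids) if o in keep_set]
        return OtuTable(
            self.method_label,
            [self.otu_ids[i] for i in idx],
            list(self.sample_ids),
            self.counts[idx, :],
        )

    def subset_samples(self, keep: Sequence[str]) -> "OtuTable":
        keep_set = set(keep)
        idx = [j for j, s in enumerate(self.sample_ids) if s in keep_set]
        return OtuTable(
            self.method_label,
            list(self.otu_ids),
            [self.sample_ids[j] for j in idx],
            self.counts[:, idx],
        )


@dataclass
class SampleRecord:
    """One sample of one twin, with family link, zygosity, and covariates."""

    sample_id: str
    family_id: str
    zygosity: Zygosity
    covariates: dict = field(default_factory=dict)


@dataclass
class TwinPairSet:
    """Complete twin pairs (both members sampled), partitioned by zygosity."""

    pairs: list[tuple[str, str, str, Zygosity]]
    n_mz: int
    n_dz: int
    exclusions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_mz + self.n_dz != len(self.pairs):
            raise ValueError("n_mz + n_dz must equal the number of pairs")

    @property
    def sample_ids(self) -> list[str]:
        out: list[str] = []
        for s1, s2, _, _ in self.pairs:
            out.extend((s1, s2))
        return out


TaxonomyMap = Mapping[str, list[str]]

RANKS = ["kingdom", "phylum", "class", "order", "family", "genus"]
_RANK_PREFIXES = ["k__", "p__", "c__", "o__", "f__", "g__"]


def read_otu_table(path: str | Path, format: str = "tsv", method_label: str | None = None) -> OtuTable:
    """Read an OTU count table from TSV or BIOM-JSON v1.0.

    ``method_label`` defaults to the file stem (the clustering method that
    produced the table).
    """
    path = Path(path)
    label = method_label if method_label is not None else path.stem
    if format == "tsv":
        return _read_otu_tsv(path, label)
    if format == "biom_json":
        return _read_biom_json(path, label)
    raise ValueError(f"unknown OTU table format: {format!r}")


def _read_otu_tsv(path: Path, label: str) -> OtuTable:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if not header or len(header) < 2:
        raise FormatError(f"{path}: expected a tab-separated header with sample ids")
    sample_ids = header[1:]
    seen: set[str] = set()
    for s in sample_ids:
        if s in seen:
            raise FormatError(f"{path}: duplicate sample column {s!r}")
        seen.add(s)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate OTU id {dup!r}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError(f"{path}: non-numeric count cells")
    return OtuTable(label, [str(i) for i in df.index], [str(c) for c in df.columns], values)


def _read_biom_json(path: Path, label: str) -> OtuTable:
    with open(path) as fh:
        doc = json.load(fh)
    try:
        otu_ids = [str(r["id"]) for r in doc["rows"]]
        sample_ids = [str(c["id"]) for c in doc["columns"]]
        n_rows, n_cols = doc["shape"]
        mtype = doc["matrix_type"]
        data = doc["data"]
    except (KeyError, TypeError) as exc:
        raise FormatError(f"{path}: not a BIOM-JSON v1.0 table ({exc})") from None
    counts = np.zeros((n_rows, n_cols))
    if mtype == "dense":
        counts[:] = np.asarray(data)
    elif mtype == "sparse":
        for i, j, v in data:
            counts[int(i), int(j)] = v
    else:
        raise FormatError(f"{path}: unknown matrix_type {mtype!r}")
    return OtuTable(label, otu_ids, sample_ids, counts)


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    """Write an OTU table as canonical TSV (round-trips exactly)."""
    df = table.to_dataframe()
    df.index.name = OTU_HEADER
    df.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> list[SampleRecord]:
    """Read the twin metadata TSV into typed sample records."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "family_id", "zygosity"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing metadata columns {missing}")
    covariate_cols = [c for c in df.columns if c not in required]
    typed: dict[str, pd.Series] = {}
    for col in covariate_cols:
        numeric = pd.to_numeric(df[col], errors="coerce")
        # blank cells stay missing under either typing
        typed[col] = numeric if numeric.notna().equals(df[col].notna()) else df[col]

    records = []
    for i, row in df.iterrows():
        zyg = Zygosity.parse(row["zygosity"])
        cov = {}
        for col in covariate_cols:
            v = typed[col].iloc[i]
            if pd.isna(v):
                cov[col] = None
            elif isinstance(v, (int, float, np.integer, np.floating)):
                cov[col] = float(v)
            else:
                cov[col] = str(v)
        records.append(SampleRecord(str(row["sample_id"]), str(row["family_id"]), zyg, cov))

    by_family: dict[str, list[SampleRecord]] = {}
    for r in records:
        by_family.setdefault(r.family_id, []).append(r)
    for fam, members in by_family.items():
        if len(members) > 2:
            raise ValueError(f"family {fam!r} has {len(members)} samples; at most 2 allowed")
        if len({m.zygosity for m in members}) > 1:
            raise ValueError(f"family {fam!r} has inconsistent zygosity")
    return records


def read_taxonomy(path: str | Path) -> dict[str, list[str]]:
    """Read a two-column taxonomy TSV: otu_id TAB Greengenes-style lineage.

    Lineages like ``k__Bacteria; p__Firmicutes; ...`` are split into the six
    ranks kingdom..genus; missing trailing ranks become empty strings.
    """
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            otu_id, _, lineage = line.partition("\t")
            out[otu_id] = parse_lineage(lineage)
    return out


def parse_lineage(lineage: str) -> list[str]:
    parts = [p.strip() for p in lineage.split(";")]
    ranks = []
    for k, prefix in enumerate(_RANK_PREFIXES):
        name = ""
        if k < len(parts):
            p = parts[k]
            name = p[len(prefix):] if p.startswith(prefix) else p
        ranks.append(name)
    return ranks


def pair_samples(
    table: OtuTable,
    records: Sequence[SampleRecord],
    covariate_names: Sequence[str] | None = None,
) -> TwinPairSet:
    """Assemble complete twin pairs present in the table.

    Only families contributing exactly two samples, both present in the OTU
    table and both with complete covariates (for ``covariate_names``; all
    covariates if None), are retained.  A missing co-twin or a missing
    covariate value excludes the whole family; exclusion counts are reported
    on the result.
    """
    in_table = set(table.sample_ids)
    matched = [r for r in records if r.sample_id in in_table]
    by_family: dict[str, list[SampleRecord]] = {}
    for r in matched:
        by_family.setdefault(r.family_id, []).append(r)

    def complete(rec: SampleRecord) -> bool:
        names = covariate_names if covariate_names is not None else list(rec.covariates)
        return all(rec.covariates.get(n) is not None for n in names)

    pairs: list[tuple[str, str, str, Zygosity]] = []
    # counts are samples, so excluded + 2*len(pairs) == len(matched)
    excl = {"unpaired_samples": 0, "incomplete_covariate_samples": 0}
    for fam, members in sorted(by_family.items()):
        if len(members) != 2:
            excl["unpaired_samples"] += len(members)
            continue
        if not all(complete(m) for m in members):
            excl["incomplete_covariate_samples"] += len(members)
            continue
        a, b = members
        pairs.append((a.sample_id, b.sample_id, fam, a.zygosity))
    if any(excl.values()):
        logger.info("pair_samples exclusions: %s", excl)
    if not pairs:
        raise EmptyDesignError("no complete twin pairs with full covariates")
    n_mz = sum(1 for p in pairs if p[3] is Zygosity.MZ)
    return TwinPairSet(pairs, n_mz=n_mz, n_dz=len(pairs) - n_mz, exclusions=excl)
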