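"""Reading, validation, filtering and harmonization of DEG tables and gene sets.

A differential-expression signature is represented as a :class:`DEGList`:
one row per gene with a signed log2 fold change and a raw p-value. DEG
tables are plain TSV with header ``gene_id  log2fc  pvalue`` (a signed
linear ``fold_change`` column is accepted and converted). Gene identity is
by symbol, uppercased, which doubles as a crude cross-species match; an
optional two-column ortholog map can override symbols at read time.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("gene_id", "log2fc", "pvalue")


class FormatError(ValueError):
    """A file does not conform to the expected table/GMT layout."""


class ParseError(ValueError):
    """A cell could not be parsed; carries the offending line number."""


class InconsistencyError(ValueError):
    """Inputs contradict each other (e.g. universe smaller than its DEGs)."""


@dataclass(frozen=True)
class FilterCriteria:
    """Significance filter applied to every DEG list before comparison.

    ``min_abs_fold_change`` is on the linear scale and both inequalities are
    strict: a gene survives iff 2**|log2fc| > min_abs_fold_change and
    pvalue < max_pvalue.
    """

    min_abs_fold_change: float = 1.2
    max_pvalue: float = 0.05

    def __post_init__(self) -> None:
        if not self.min_abs_fold_change > 1:
            raise ValueError("min_abs_fold_change must be > 1 (linear scale)")
        if not (0 < self.max_pvalue <= 1):
            raise ValueError("max_pvalue must lie in (0, 1]")

    @property
    def min_abs_log2fc(self) -> float:
        return math.log2(self.min_abs_fold_change)


@dataclass
class DEGList:
    """One dataset's signed differential-expression signature.

    ``records`` holds columns gene_id / log2fc / pvalue with unique,
    uppercased gene ids, finite fold changes and p-values in (0, 1].
    ``universe`` is the optional set of all measured genes.
    """

    dataset_id: str
    records: pd.DataFrame
    species: str = "mouse"
    region: str = "hippocampus"
    life_stage: str = "adult"
    universe: frozenset | None = None

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"records missing columns {missing}")
        df = df.loc[:, list(REQUIRED_COLUMNS)].reset_index(drop=True)
        if df["gene_id"].duplicated().any():
            dupes = df.loc[df["gene_id"].duplicated(), "gene_id"].head().tolist()
            raise InconsistencyError(f"duplicate gene_ids after harmonization: {dupes}")
        if len(df) and not np.isfinite(df["log2fc"].to_numpy(float)).all():
            raise ValueError("log2fc must be finite")
        p = df["pvalue"].to_numpy(float)
        if len(df) and not ((p > 0) & (p <= 1)).all():
            raise ValueError("pvalues must lie in (0, 1]")
        if self.universe is not None:
            extra = set(df["gene_id"]) - set(self.universe)
            if extra:
                raise InconsistencyError(
                    f"{len(extra)} record gene_ids outside the universe"
                )
        self.records = df

    def __len__(self) -> int:
        return len(self.records)

    @property
    def genes(self) -> set:
        return set(self.records["gene_id"])

    def with_records(self, records: pd.DataFrame) -> "DEGList":
        return replace(self, records=records.reset_index(drop=True))


@dataclass(frozen=True)
class GeneSetCollection:
    """A named collection of gene sets (e.g. one GMT file)."""

    name: str
    sets: dict  # term_id -> (term_name, frozenset of gene_ids)

    def __post_init__(self) -> None:
        for term_id, (_, genes) in self.sets.items():
            if not genes:
                raise ValueError(f"empty gene set {term_id!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def genes_of(self, term_id: str) -> frozenset:
        return self.sets[term_id][1]


def _coerce_numeric(df: pd.DataFrame, column: str, path) -> pd.Series:
    out = pd.to_numeric(df[column], errors="coerce")
    bad = out.isna() & df[column].notna()
    if bad.any():
        # +2 = header line plus 1-based numbering
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise ParseError(f"{path}: non-numeric {column!r} at line {line}")
    if out.isna().any():
        line = int(np.flatnonzero(out.isna().to_numpy())[0]) + 2
        raise ParseError(f"{path}: missing {column!r} at line {line}")
    return out.astype(float)


def read_deg_table(
    path,
    dataset_id: str,
    *,
    species: str = "mouse",
    region: str = "hippocampus",
    life_stage: str = "adult",
    ortholog_map: dict | None = None,
    universe: frozenset | None = None,
) -> DEGList:
    """Read a TSV DEG table into a validated :class:`DEGList`.

    Accepts either a ``log2fc`` column or a signed linear ``fold_change``
    column (negative = down-regulated; converted via sign * log2|FC|).
    Duplicate gene ids are collapsed keeping the smallest p-value.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    df.columns = [c.strip().lower() for c in df.columns]
    if "gene_id" not in df.columns or "pvalue" not in df.columns:
        raise FormatError(f"{path}: required columns gene_id/pvalue not found")
    if "log2fc" in df.columns:
        log2fc = _coerce_numeric(df, "log2fc", path)
    elif "fold_change" in df.columns:
        fc = _coerce_numeric(df, "fold_change", path)
        if (fc.abs() < 1).any() or (fc == 0).any():
            raise ParseError(
                f"{path}: linear fold_change must have |FC| >= 1 (signed convention)"
            )
        log2fc = np.sign(fc) * np.log2(fc.abs())
    else:
        raise FormatError(f"{path}: need a log2fc or fold_change column")
    out = pd.DataFrame(
        {
            "gene_id": df["gene_id"].str.strip().str.upper(),
            "log2fc": np.asarray(log2fc, dtype=float),
            "pvalue": _coerce_numeric(df, "pvalue", path),
        }
    )
    if ortholog_map:
        out["gene_id"] = out["gene_id"].map(lambda g: ortholog_map.get(g, g))
    # collapse duplicates, keeping the most significant record
    out = (
        out.sort_values(["pvalue", "gene_id"], kind="mergesort")
        .drop_duplicates("gene_id", keep="first")
        .sort_index()
        .reset_index(drop=True)
    )
    return DEGList(
        dataset_id=dataset_id,
        records=out,
        species=species,
        region=region,
        life_stage=life_stage,
        universe=universe,
    )


def write_deg_table(deg: DEGList, path) -> None:
    """Write a DEGList back to its TSV form (6-decimal reals)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    deg.records.to_csv(path, sep="\t", index=False, float_format="%.6g")


def apply_filter(deg: DEGList, crit: FilterCriteria = FilterCriteria()) -> DEGList:
    """Keep records with 2**|log2fc| > min FC and p < max p (both strict)."""
    df = deg.records
    keep = (np.abs(df["log2fc"].to_numpy()) > crit.min_abs_log2fc) & (
        df["pvalue"].to_numpy() < crit.max_pvalue
    )
    return deg.with_records(df.loc[keep])


def negate(deg: DEGList) -> DEGList:
    """Flip the sign of every fold change (up becomes down and vice versa)."""
    df = deg.records.copy()
    df["log2fc"] = -df["log2fc"]
    return deg.with_records(df)


def read_gmt(path, name: str | None = None) -> GeneSetCollection:
    """Parse a GMT file (term, description, member genes; tab-separated)."""
    path = Path(path)
    sets: dict = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: fewer than 3 fields")
            term_id, term_name = fields[0].strip(), fields[1].strip()
            genes = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
            if not genes:
                warnings.warn(f"{path}: line {lineno}: empty set {term_id!r} dropped")
                continue
            if term_id in sets:
                warnings.warn(
                    f"{path}: line {lineno}: duplicate term {term_id!r} rejected"
                )
                continue
            sets[term_id] = (term_name, genes)
    return GeneSetCollection(name=name or path.stem, sets=sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for term_id, (term_name, genes) in collection.sets.items():
            fh.write("\t".join([term_id, term_name, *sorted(genes)]) + "\n")


def harmonize_universe(a: DEGList, b: DEGList, fallback_n: int = 20000) -> int:
    """Effective universe size N for an overlap test between two datasets.

    Uses the intersection of the measured-gene universes when both are
    known; otherwise ``fallback_n``. Raises if the claimed universe cannot
    contain the observed DEGs.
    """
    union_degs = a.genes | b.genes
    if a.universe is not None and b.universe is not None:
        n = len(a.universe & b.universe)
    else:
        n = fallback_n
    if n < len(union_degs):
        raise InconsistencyError(
            f"universe size {n} smaller than {len(union_degs)} distinct DEGs"
        )
    return n
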