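"""On-disk formats and in-memory containers.

Every table is tab-separated text with a header row.  Documented schemas:

* ``variants.tsv``  — variant_id, chrom, pos, allele_other, allele_effect, maf[, info]
* ``genes.tsv``     — gene_id, chrom, start, end, strand
* ``genotypes.tsv`` — individual_id, then one column per variant_id; dosages in
  [0, 2], missing encoded as ``NA``
* ``sumstats.tsv``  — variant metadata plus n_used, beta_main, se_main, p_main
  and, for interaction scans, beta_int, se_int, p_int
* ``weights.tsv``   — score_name, p_threshold, variant_id, allele_effect, weight
* ``scores.tsv``    — individual_id, then one column per score
* pathway gene sets — standard GMT (name, description, gene IDs; tab-separated)

Coordinates are 1-based, fully closed.  Floats are written with 10+
significant digits so write-then-read is identity to text precision.
Readers reject malformed input with errors naming file, line, and field;
they never silently coerce.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .config import ConfigurationError

log = logging.getLogger(__name__)

__all__ = [
    "ParseError", "GenotypeMatrix", "PathwayCollection", "WeightSet", "ScoreMatrix",
    "read_gmt", "write_gmt",
    "read_variant_table", "write_variant_table",
    "read_gene_table", "write_gene_table",
    "read_genotype_matrix", "write_genotype_matrix",
    "read_sumstats", "write_sumstats",
    "read_weights", "write_weights",
    "read_scores", "write_scores",
    "read_vector", "write_vector", "read_covariates", "write_covariates",
    "apply_variant_filters",
]

FLOAT_FMT = "%.12g"
NA = "NA"

VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "allele_other", "allele_effect", "maf"]
GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]
ALLELES = {"A", "C", "G", "T"}


class ParseError(ValueError):
    """Malformed on-disk input; message carries file, line and field."""

    def __init__(self, path, line: Optional[int], message: str):
        loc = f"{path}" + (f", line {line}" if line is not None else "")
        super().__init__(f"{loc}: {message}")
        self.path = str(path)
        self.line = line


# ---------------------------------------------------------------------------
# In-memory containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Dosage matrix (individuals x variants); NaN marks missing dosages."""

    dosages: np.ndarray
    individual_ids: list[str]
    variant_ids: list[str]

    def __post_init__(self) -> None:
        n, m = self.dosages.shape
        if n != len(self.individual_ids) or m != len(self.variant_ids):
            raise ValueError("dosage matrix shape does not match id lists")
        with np.errstate(invalid="ignore"):
            bad = np.nansum((self.dosages < 0) | (self.dosages > 2))
        if bad:
            raise ValueError(f"{bad} dosage values outside [0, 2]")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def subset_variants(self, keep: Iterable[str]) -> "GenotypeMatrix":
        keep = list(keep)
        idx = {v: i for i, v in enumerate(self.variant_ids)}
        cols = [idx[v] for v in keep]
        return GenotypeMatrix(self.dosages[:, cols], list(self.individual_ids), keep)


@dataclass
class PathwayCollection:
    """Ordered map: pathway name -> (description, gene IDs)."""

    names: list[str] = field(default_factory=list)
    descriptions: dict = field(default_factory=dict)
    genes: dict = field(default_factory=dict)  # name -> tuple of gene IDs (unique, ordered)

    def add(self, name: str, description: str, gene_ids: Iterable[str]) -> None:
        if name in self.genes:
            raise ValueError(f"duplicate pathway name {name!r}")
        seen: dict[str, None] = {}
        for g in gene_ids:
            seen.setdefault(g, None)
        if not seen:
            raise ValueError(f"pathway {name!r} has no genes")
        self.names.append(name)
        self.descriptions[name] = description
        self.genes[name] = tuple(seen)

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self.genes

    def __eq__(self, other) -> bool:
        return (isinstance(other, PathwayCollection)
                and self.names == other.names
                and self.descriptions == other.descriptions
                and self.genes == other.genes)

    def gene_sets(self) -> dict[str, frozenset]:
        return {n: frozenset(self.genes[n]) for n in self.names}


@dataclass
class WeightSet:
    """P&T-selected variant weights for one score."""

    score_name: str
    p_threshold: float
    entries: pd.DataFrame  # variant_id, allele_effect, weight

    def __post_init__(self) -> None:
        need = ["variant_id", "allele_effect", "weight"]
        if list(self.entries.columns) != need:
            self.entries = self.entries[need]
        if self.entries["variant_id"].duplicated().any():
            raise ValueError(f"duplicate variant IDs in weight set {self.score_name!r}")
        if len(self.entries) and not np.isfinite(self.entries["weight"].to_numpy()).all():
            raise ValueError(f"non-finite weight in weight set {self.score_name!r}")

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class ScoreMatrix:
    """Per-individual score values, one column per score."""

    values: pd.DataFrame  # index = individual_id, columns = score names
    variant_counts: dict = field(default_factory=dict)

    @property
    def score_names(self) -> list[str]:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path) -> PathwayCollection:
    """Read a GMT gene-set file (one pathway per line: name, description, genes).

    Duplicate gene IDs within a line are collapsed; duplicate pathway names and
    lines with fewer than three fields are errors.
    """
    coll = PathwayCollection()
    n_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            n_lines += 1
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(path, lineno,
                                 f"expected >= 3 tab-separated fields, got {len(fields)}")
            name, desc = fields[0], fields[1]
            genes = [g for g in fields[2:] if g]
            if not genes:
                raise ParseError(path, lineno, f"pathway {name!r} lists no gene IDs")
            try:
                coll.add(name, desc, genes)
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from exc
    if n_lines == 0:
        log.warning("GMT file %s is empty; returning empty collection", path)
    return coll


def write_gmt(coll: PathwayCollection, path) -> None:
    with open(path, "w") as fh:
        for name in coll.names:
            fields = [name, coll.descriptions[name], *coll.genes[name]]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Generic TSV helpers
# ---------------------------------------------------------------------------

def _read_tsv(path, required: list[str], optional: list[str] = ()) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(path, None, f"could not parse TSV: {exc}") from exc
    cols = list(df.columns)
    missing = [c for c in required if c not in cols]
    if missing:
        raise ParseError(path, 1, f"missing required column(s): {', '.join(missing)}")
    unknown = [c for c in cols if c not in required and c not in optional]
    if unknown:
        raise ParseError(path, 1, f"unknown column(s): {', '.join(unknown)}")
    return df


def _to_float(df: pd.DataFrame, col: str, path, allow_na: bool = False) -> np.ndarray:
    raw = df[col].to_numpy()
    out = np.empty(len(raw), dtype=float)
    for i, v in enumerate(raw):
        if allow_na and (v == NA or v == ""):
            out[i] = np.nan
            continue
        try:
            out[i] = float(v)
        except ValueError:
            raise ParseError(path, i + 2, f"field {col!r}: non-numeric value {v!r}") from None
    return out


def _to_int(df: pd.DataFrame, col: str, path) -> np.ndarray:
    raw = df[col].to_numpy()
    out = np.empty(len(raw), dtype=np.int64)
    for i, v in enumerate(raw):
        try:
            out[i] = int(v)
        except ValueError:
            raise ParseError(path, i + 2, f"field {col!r}: non-integer value {v!r}") from None
    return out


# ---------------------------------------------------------------------------
# Variant table
# ---------------------------------------------------------------------------

def validate_variant_table(df: pd.DataFrame, path="<memory>") -> None:
    for i, (a, b) in enumerate(zip(df["allele_other"], df["allele_effect"])):
        if a not in ALLELES or b not in ALLELES:
            raise ParseError(path, i + 2, f"invalid allele pair ({a!r}, {b!r})")
        if a == b:
            raise ParseError(path, i + 2, f"alleles must differ, got ({a!r}, {b!r})")
    maf = df["maf"].to_numpy()
    bad = np.where((maf <= 0) | (maf > 0.5))[0]
    if bad.size:
        raise ParseError(path, int(bad[0]) + 2, f"maf {maf[bad[0]]} outside (0, 0.5]")
    key = df[["chrom", "pos", "allele_other", "allele_effect"]]
    if key.duplicated().any():
        raise ParseError(path, None, "duplicate (chrom, pos, alleles) rows")
    # sorted by (chrom, pos)
    by = df.sort_values(["chrom", "pos"], kind="stable")
    if not (by.index == df.index).all():
        raise ParseError(path, None, "variant table is not sorted by (chrom, pos)")


def read_variant_table(path) -> pd.DataFrame:
    df = _read_tsv(path, VARIANT_COLUMNS, optional=["info"])
    out = pd.DataFrame({
        "variant_id": df["variant_id"],
        "chrom": df["chrom"],
        "pos": _to_int(df, "pos", path),
        "allele_other": df["allele_other"],
        "allele_effect": df["allele_effect"],
        "maf": _to_float(df, "maf", path),
    })
    if "info" in df.columns:
        info = _to_float(df, "info", path, allow_na=True)
        with np.errstate(invalid="ignore"):
            bad = np.where((info < 0) | (info > 1))[0]
        if bad.size:
            raise ParseError(path, int(bad[0]) + 2, f"info {info[bad[0]]} outside [0, 1]")
        out["info"] = info
    validate_variant_table(out, path)
    return out


def write_variant_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT, na_rep=NA)


# ---------------------------------------------------------------------------
# Gene table
# ---------------------------------------------------------------------------

def read_gene_table(path) -> pd.DataFrame:
    df = _read_tsv(path, GENE_COLUMNS)
    out = pd.DataFrame({
        "gene_id": df["gene_id"],
        "chrom": df["chrom"],
        "start": _to_int(df, "start", path),
        "end": _to_int(df, "end", path),
        "strand": df["strand"],
    })
    validate_gene_table(out, path)
    return out


def validate_gene_table(df: pd.DataFrame, path="<memory>") -> None:
    bad = np.where(df["start"].to_numpy() > df["end"].to_numpy())[0]
    if bad.size:
        raise ParseError(path, int(bad[0]) + 2, "start > end")
    for i, s in enumerate(df["strand"]):
        if s not in ("+", "-"):
            raise ParseError(path, i + 2, f"field 'strand': expected + or -, got {s!r}")
    if df["gene_id"].duplicated().any():
        raise ParseError(path, None, "duplicate gene_id values")


def write_gene_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Genotype matrix
# ---------------------------------------------------------------------------

def read_genotype_matrix(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns[0] != "individual_id":
        raise ParseError(path, 1, "first column must be 'individual_id'")
    variant_ids = list(df.columns[1:])
    individual_ids = list(df["individual_id"])
    raw = df.iloc[:, 1:].to_numpy()
    dos = np.empty(raw.shape, dtype=float)
    for j in range(raw.shape[1]):
        col = raw[:, j]
        for i, v in enumerate(col):
            if v == NA or v == "":
                dos[i, j] = np.nan
                continue
            try:
                x = float(v)
            except ValueError:
                raise ParseError(path, i + 2,
                                 f"field {variant_ids[j]!r}: non-numeric dosage {v!r}") from None
            if not (0.0 <= x <= 2.0):
                raise ParseError(path, i + 2,
                                 f"field {variant_ids[j]!r}: dosage {x} outside [0, 2]")
            dos[i, j] = x
    return GenotypeMatrix(dos, individual_ids, variant_ids)


def write_genotype_matrix(gm: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(gm.dosages, columns=gm.variant_ids)
    df.insert(0, "individual_id", gm.individual_ids)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT, na_rep=NA)


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

SUMSTATS_BASE = ["variant_id", "chrom", "pos", "allele_other", "allele_effect",
                 "maf", "n_used", "beta_main", "se_main", "p_main"]
SUMSTATS_INT = ["beta_int", "se_int", "p_int"]


def read_sumstats(path) -> pd.DataFrame:
    df = _read_tsv(path, SUMSTATS_BASE, optional=SUMSTATS_INT)
    out = pd.DataFrame({
        "variant_id": df["variant_id"],
        "chrom": df["chrom"],
        "pos": _to_int(df, "pos", path),
        "allele_other": df["allele_other"],
        "allele_effect": df["allele_effect"],
        "maf": _to_float(df, "maf", path),
        "n_used": _to_int(df, "n_used", path),
    })
    for col in ["beta_main", "se_main", "p_main"]:
        out[col] = _to_float(df, col, path, allow_na=True)
    for col in SUMSTATS_INT:
        if col in df.columns:
            out[col] = _to_float(df, col, path, allow_na=True)
    return out


def write_sumstats(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT, na_rep=NA)


# ---------------------------------------------------------------------------
# Weights / scores
# ---------------------------------------------------------------------------

def write_weights(weight_sets: list[WeightSet], path) -> None:
    rows = []
    for ws in weight_sets:
        for _, r in ws.entries.iterrows():
            rows.append((ws.score_name, ws.p_threshold, r["variant_id"],
                         r["allele_effect"], r["weight"]))
    df = pd.DataFrame(rows, columns=["score_name", "p_threshold", "variant_id",
                                     "allele_effect", "weight"])
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_weights(path) -> list[WeightSet]:
    df = _read_tsv(path, ["score_name", "p_threshold", "variant_id",
                          "allele_effect", "weight"])
    df = df.assign(p_threshold=_to_float(df, "p_threshold", path),
                   weight=_to_float(df, "weight", path))
    out = []
    for name, grp in df.groupby("score_name", sort=False):
        out.append(WeightSet(
            score_name=name,
            p_threshold=float(grp["p_threshold"].iloc[0]),
            entries=grp[["variant_id", "allele_effect", "weight"]].reset_index(drop=True),
        ))
    return out


def write_scores(sm: ScoreMatrix, path) -> None:
    df = sm.values.reset_index().rename(columns={"index": "individual_id"})
    if df.columns[0] != "individual_id":
        df = df.rename(columns={df.columns[0]: "individual_id"})
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_scores(path) -> ScoreMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str})
    if df.columns[0] != "individual_id":
        raise ParseError(path, 1, "first column must be 'individual_id'")
    values = df.set_index("individual_id")
    values.index.name = None
    return ScoreMatrix(values=values)


# ---------------------------------------------------------------------------
# Phenotype / exposure / covariates
# ---------------------------------------------------------------------------

def write_vector(values: np.ndarray, name: str, path) -> None:
    pd.DataFrame({name: values}).to_csv(path, sep="\t", index=False,
                                        float_format=FLOAT_FMT)


def read_vector(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] != 1:
        raise ParseError(path, 1, f"expected a single column, got {df.shape[1]}")
    return df.iloc[:, 0].to_numpy(dtype=float)


def write_covariates(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_covariates(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if df.isna().all().any():
        bad = df.columns[df.isna().all()][0]
        raise ParseError(path, None, f"column {bad!r} is entirely missing")
    return df


# ---------------------------------------------------------------------------
# Variant filters
# ---------------------------------------------------------------------------

def apply_variant_filters(variants: pd.DataFrame, genotypes: GenotypeMatrix,
                          maf_min: float = 0.01, info_min: float = 0.5
                          ) -> tuple[pd.DataFrame, GenotypeMatrix]:
    """Keep variants with maf > maf_min and (if present) info > info_min.

    Strict inequalities on both thresholds; the genotype columns are subset
    consistently.  An empty result is permitted and logged.
    """
    if not (0.0 <= maf_min <= 1.0) or not (0.0 <= info_min <= 1.0):
        raise ConfigurationError("filter thresholds must lie in [0, 1]")
    keep = variants["maf"].to_numpy() > maf_min
    if "info" in variants.columns:
        info = variants["info"].to_numpy()
        keep &= np.isnan(info) | (info > info_min)
    kept = variants.loc[keep].reset_index(drop=True)
    if kept.empty:
        log.warning("variant filters (maf>%g, info>%g) removed every variant",
                    maf_min, info_min)
    gm = genotypes.subset_variants(kept["variant_id"].tolist())
    return kept, gm
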