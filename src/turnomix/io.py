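"""Readers and writers for every table the pipeline touches.

All tables are long-format, UTF-8, header-required text files ('.' decimal):
TSV for peptide reports, transcript matrices, interactome lists and results;
CSV for lipid quantification tables; standard GMT for gene sets. Floats are
written with 12 significant digits so that write -> read round-trips are
stable to 1e-12 relative.

Sample metadata (genotype / condition / replicate) travels inside the
peptide and lipid tables rather than in a sidecar design file, so a single
file is a complete fixture.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("turnomix")

__all__ = [
    "TurnomixError",
    "FormatError",
    "ValidationError",
    "ExperimentDesign",
    "GeneSet",
    "RunConfig",
    "PEPTIDE_COLUMNS",
    "LIPID_COLUMNS",
    "INTERACTOME_COLUMNS",
    "read_peptide_report",
    "read_lipid_table",
    "read_interactome",
    "read_gmt",
    "read_contaminant_ids",
    "read_feature_matrix",
    "write_feature_matrix",
    "write_table",
    "write_results",
    "read_config",
    "write_config",
    "log_stage",
]


class TurnomixError(Exception):
    """Base class for pipeline errors."""


class FormatError(TurnomixError):
    """A file does not conform to the expected dialect."""


class ValidationError(TurnomixError):
    """A parsed table violates a documented invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentDesign:
    """Pulse-labelling design: who was pulsed, for how long, how many times.

    Parameters
    ----------
    pulse_time_days
        Sampling time t_s after the media switch to heavy label, in days.
    genotypes
        Ordered group labels; the first entry is the reference (isogenic)
        group for direction calls.
    conditions
        Culture conditions (e.g. complete medium ``CM`` vs glucose
        starvation ``GS``).
    replicates_per_group
        Biological replicates per genotype x condition cell.
    """

    pulse_time_days: float = 2.0
    genotypes: tuple[str, ...] = ("isogenic", "P497H", "P506T")
    conditions: tuple[str, ...] = ("CM", "GS")
    replicates_per_group: int = 4

    def __post_init__(self) -> None:
        if self.pulse_time_days <= 0:
            raise ValidationError("pulse_time_days must be > 0")
        if len(self.genotypes) < 2:
            raise ValidationError("need >= 2 genotypes for differential testing")
        if self.replicates_per_group < 1:
            raise ValidationError("replicates_per_group must be >= 1")

    @property
    def reference_genotype(self) -> str:
        return self.genotypes[0]

    def sample_ids(self, condition: str | None = None) -> list[str]:
        """Deterministic sample naming: ``<genotype>_<condition>_r<replicate>``."""
        conds = [condition] if condition is not None else list(self.conditions)
        return [
            f"{g}_{c}_r{r}"
            for c in conds
            for g in self.genotypes
            for r in range(1, self.replicates_per_group + 1)
        ]


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} has no members")


@dataclass
class RunConfig:
    """All tunable thresholds of the pipeline, with the study defaults.

    ``ratio_min``/``ratio_max`` bound the heavy-to-light ratio (retention at
    the exact bounds is inclusive); ``intensity_floor`` is the raw-intensity
    floor applied to either channel; ``alpha`` the BH-adjusted significance
    level; ``min_enrichment`` the strict pulldown-ratio cutoff defining
    interactors; ``r_threshold`` the absolute cross-omics correlation cutoff;
    ``mad_quantile`` the MAD percentile for feature selection.
    """

    pulse_days: float = 2.0
    ratio_min: float = 0.02
    ratio_max: float = 100.0
    intensity_floor: float = 1000.0
    min_peptides: int = 1
    alpha: float = 0.05
    fc_threshold: float = 2.0
    min_enrichment: float = 10.0
    r_threshold: float = 0.6
    mad_quantile: float = 0.75
    n_perm: int = 1000
    gsea_weight: float = 1.0
    moderate_variance: bool = True
    log_scale: bool = True
    candidate_condition: str = "GS"
    direction_mode: str = "either"  # or "both": mutants required to agree
    seed: int = 0
    out_dir: str = "results"
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.ratio_min < self.ratio_max):
            raise ValidationError("require 0 < ratio_min < ratio_max")
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must lie in (0, 1)")
        if not (0 < self.mad_quantile < 1):
            raise ValidationError("mad_quantile must lie in (0, 1)")
        if self.min_enrichment <= 0:
            raise ValidationError("min_enrichment must be > 0")
        if not (0 <= self.r_threshold <= 1):
            raise ValidationError("r_threshold must lie in [0, 1]")
        if self.n_perm < 100:
            raise ValidationError("n_perm must be >= 100")
        if self.direction_mode not in ("either", "both"):
            raise ValidationError("direction_mode must be 'either' or 'both'")


# ---------------------------------------------------------------------------
# Column dialects
# ---------------------------------------------------------------------------

PEPTIDE_COLUMNS = [
    "protein_id",
    "peptide_seq",
    "sample_id",
    "genotype",
    "condition",
    "replicate",
    "light_intensity",
    "heavy_intensity",
    "is_contaminant",
]

LIPID_COLUMNS = [
    "species",
    "lipid_class",
    "internal_standard_id",
    "run_id",
    "sample_id",
    "genotype",
    "condition",
    "replicate",
    "intensity",
    "is_internal_standard",
]

INTERACTOME_COLUMNS = ["protein_id", "enrichment_ratio"]

_FLOAT_FMT = "%.13g"


def log_stage(stage: str, n_in: int, n_out: int,
              removed: Mapping[str, int] | None = None,
              seed: int | None = None) -> None:
    """Structured per-stage log line: counts in/out and per-rule removals."""
    parts = [f"stage={stage}", f"rows_in={n_in}", f"rows_out={n_out}"]
    for rule, n in (removed or {}).items():
        parts.append(f"removed[{rule}]={n}")
    if seed is not None:
        parts.append(f"seed={seed}")
    logger.info(" ".join(parts))


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")


def _read_delim(path, sep: str) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                         encoding="utf-8")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: file is empty") from None
    return df


def _to_bool(series: pd.Series) -> pd.Series:
    truthy = {"true", "1", "yes", "t"}
    return series.str.strip().str.lower().isin(truthy)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_peptide_report(path, design: ExperimentDesign | None = None) -> pd.DataFrame:
    """Read a long-format peptide quantification report (TSV).

    Rows whose intensity fields do not parse as numbers are dropped and
    counted in the log; a missing required column is a :class:`FormatError`.
    Both channels missing on one row violates the table invariant.
    """
    df = _read_delim(path, "\t")
    _require_columns(df, PEPTIDE_COLUMNS, path)
    n_in = len(df)

    light = pd.to_numeric(df["light_intensity"], errors="coerce")
    heavy = pd.to_numeric(df["heavy_intensity"], errors="coerce")
    ok = ~(light.isna() & df["light_intensity"].str.strip().ne("")) \
        & ~(heavy.isna() & df["heavy_intensity"].str.strip().ne(""))
    # empty strings denote genuinely missing channels; non-numeric junk is dropped
    unparseable = int((~ok).sum())
    df = df.loc[ok].copy()
    light, heavy = light[ok], heavy[ok]

    out = pd.DataFrame({
        "protein_id": df["protein_id"],
        "peptide_seq": df["peptide_seq"],
        "sample_id": df["sample_id"],
        "genotype": df["genotype"],
        "condition": df["condition"],
        "replicate": pd.to_numeric(df["replicate"]).astype(int),
        "light_intensity": light.astype(float),
        "heavy_intensity": heavy.astype(float),
        "is_contaminant": _to_bool(df["is_contaminant"]),
    }).reset_index(drop=True)

    both_missing = out["light_intensity"].isna() & out["heavy_intensity"].isna()
    if both_missing.any():
        raise ValidationError(
            f"{path}: {int(both_missing.sum())} rows have both channels missing")
    neg = (out["light_intensity"] < 0) | (out["heavy_intensity"] < 0)
    if neg.any():
        raise ValidationError(f"{path}: negative intensities on {int(neg.sum())} rows")

    if design is not None:
        key = out["genotype"] + "_" + out["condition"] + "_r" + out["replicate"].astype(str)
        mismatch = key.ne(out["sample_id"])
        if mismatch.any():
            raise ValidationError(
                f"{path}: sample_id inconsistent with (genotype, condition, "
                f"replicate) on {int(mismatch.sum())} rows")

    log_stage("read_peptide_report", n_in, len(out),
              {"unparseable_intensity": unparseable})
    return out


def read_lipid_table(path) -> pd.DataFrame:
    """Read a lipid quantification table (CSV); validates the IS mapping.

    Every non-standard species must reference an internal standard that is
    itself measured in the table.
    """
    df = _read_delim(path, ",")
    _require_columns(df, LIPID_COLUMNS, path)
    n_in = len(df)

    out = pd.DataFrame({
        "species": df["species"],
        "lipid_class": df["lipid_class"],
        "internal_standard_id": df["internal_standard_id"],
        "run_id": df["run_id"],
        "sample_id": df["sample_id"],
        "genotype": df["genotype"],
        "condition": df["condition"],
        "replicate": pd.to_numeric(df["replicate"]).astype(int),
        "intensity": pd.to_numeric(df["intensity"], errors="raise").astype(float),
        "is_internal_standard": _to_bool(df["is_internal_standard"]),
    })
    if (out["intensity"] < 0).any():
        raise ValidationError(f"{path}: negative lipid intensities")

    standards = set(out.loc[out["is_internal_standard"], "species"])
    cited = out.loc[~out["is_internal_standard"], "internal_standard_id"]
    missing = sorted(set(cited) - standards)
    if missing:
        raise ValidationError(
            f"{path}: species cite internal standards absent from the table: "
            + ", ".join(missing))

    log_stage("read_lipid_table", n_in, len(out))
    return out.reset_index(drop=True)


def read_interactome(path) -> pd.DataFrame:
    """Read a pulldown interactome table: protein_id, enrichment_ratio (TSV)."""
    df = _read_delim(path, "\t")
    _require_columns(df, INTERACTOME_COLUMNS, path)
    ratio = pd.to_numeric(df["enrichment_ratio"], errors="raise").astype(float)
    bad = ratio <= 0
    if bad.any():
        raise ValidationError(
            f"{path}: non-positive enrichment_ratio for "
            + ", ".join(df.loc[bad, "protein_id"].tolist()))
    out = pd.DataFrame({"protein_id": df["protein_id"], "enrichment_ratio": ratio})
    log_stage("read_interactome", len(df), len(out))
    return out


def read_gmt(path) -> list[GeneSet]:
    """Parse a GMT gene-set file: name <tab> description <tab> member...

    Duplicate members are deduplicated; a line with fewer than three fields
    is a :class:`FormatError` carrying the line number.
    """
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 tab-separated "
                                  f"fields, got {len(fields)}")
            name, _desc, *members = fields
            members = [m for m in members if m]
            sets.append(GeneSet(name=name, members=frozenset(members)))
    log_stage("read_gmt", len(sets), len(sets))
    return sets


def read_contaminant_ids(path) -> frozenset[str]:
    """Contaminant accession list, one id per line; '#' comments allowed."""
    with open(path, encoding="utf-8") as fh:
        ids = {ln.strip() for ln in fh
               if ln.strip() and not ln.lstrip().startswith("#")}
    return frozenset(ids)


def read_feature_matrix(path) -> pd.DataFrame:
    """Feature x sample matrix (TSV, first column = feature id)."""
    df = pd.read_csv(path, sep="\t", index_col=0, encoding="utf-8")
    return df.astype(float)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_feature_matrix(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label="feature_id")
    return path


def write_table(df: pd.DataFrame, path, columns: Sequence[str] | None = None,
                sep: str | None = None) -> Path:
    """Write one result table with a fixed column order.

    The separator follows the extension (.csv -> comma, else tab). Floats use
    12 significant digits; an empty table still gets its header row.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if columns is not None:
        df = df.loc[:, list(columns)]
    if sep is None:
        sep = "," if path.suffix == ".csv" else "\t"
    df.to_csv(path, sep=sep, index=False, float_format=_FLOAT_FMT)
    return path


def write_results(tables: Mapping[str, pd.DataFrame], out_dir) -> dict[str, Path]:
    """Write a named set of result tables to ``out_dir`` as TSV files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, df in tables.items():
        written[name] = write_table(df, out_dir / f"{name}.tsv")
    log_stage("write_results", len(tables), len(written))
    return written


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

def read_config(path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise FormatError(f"{path}: unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def write_config(cfg: RunConfig, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)
    return path
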