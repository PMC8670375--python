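"""Reading, validation and writing of quantification tables, annotation maps
and plate-reader exports.

Internally everything is long ("tidy") format: one row per detected
measurement.  Wide MaxQuant-style exports are melted on ingest.  Intensities
are stored linear unless the source is declared pre-logged, in which case a
table-level flag (``df.attrs["is_log2"]``) records it so the log transform is
applied exactly once downstream.  Missing values are represented by row
absence after ingest regardless of the input encoding; a zero intensity means
"not quantified" only in the declared MaxQuant dialect and is otherwise a
hard error.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .simulate import CONDITIONS, FRACTIONS

PIPELINE_VERSION = "0.1.0"

QUANT_COLUMNS = [
    "protein",
    "strain",
    "condition",
    "fraction",
    "replicate",
    "intensity",
    "unique_peptides",
]

LOCALIZATION_CLASSES = (
    "Cytoplasmic",
    "CytoplasmicMembrane",
    "Cellwall",
    "Extracellular",
    "Unknown",
)

_MODE_ALIASES = {
    "activation": "activation",
    "positive": "activation",
    "+": "activation",
    "repression": "repression",
    "negative": "repression",
    "-": "repression",
}

MAX_CATEGORY_LEVELS = 4


class ValidationError(ValueError):
    """Raised when an input table violates its contract."""


@dataclass
class Design:
    """Declared experimental design an ingested table must conform to."""

    strains: Sequence[str] = ("168", "midi")
    conditions: Sequence[str] = CONDITIONS
    fractions: Sequence[str] = FRACTIONS
    n_replicates: int = 3


@dataclass
class AnnotationMaps:
    """Protein-level annotation: localization, Sec signal peptides,
    hierarchical functional categories (up to 4 levels) and regulons."""

    localization: dict[str, str] = field(default_factory=dict)
    sec_sp: dict[str, bool] = field(default_factory=dict)
    categories: dict[str, list[tuple[str, ...]]] = field(default_factory=dict)
    regulons: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    @property
    def sec_positive(self) -> set[str]:
        return {p for p, flag in self.sec_sp.items() if flag}


@dataclass
class IngestReport:
    """Accounting of an ingest: rows in = rows kept + rows rejected."""

    n_input: int = 0
    n_kept: int = 0
    n_rejected: int = 0
    n_zero_dropped: int = 0
    rejected: pd.DataFrame | None = None


def _read_frame(path, fmt=None, **kwargs) -> pd.DataFrame:
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower().lstrip(".")
        fmt = {"tsv": "tsv", "txt": "tsv", "csv": "csv", "xlsx": "xlsx"}.get(
            suffix, "tsv"
        )
    if fmt == "xlsx":
        return pd.read_excel(path, **kwargs)
    sep = "\t" if fmt == "tsv" else ","
    return pd.read_csv(path, sep=sep, comment="#", **kwargs)


def read_quant_table(
    path,
    fmt: str | None = None,
    design: Design | None = None,
    column_map: Mapping[str, str] | None = None,
    intensities_log2: bool = False,
    dialect: str = "strict",
    return_report: bool = False,
):
    """Read and validate a long-format quantification table.

    Parameters
    ----------
    column_map
        Maps canonical column names (``protein``, ``strain``, ...) to the
        actual columns in the file.
    intensities_log2
        Declare the intensity column as already log2-transformed.
    dialect
        ``"strict"`` (default): non-positive intensity is a hard error.
        ``"maxquant"``: zero intensity means "not quantified" and the row is
        dropped as absent (counted in the report); negative remains an error.
    """
    design = design or Design()
    df = _read_frame(path, fmt)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in QUANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"quantification table lacks columns: {missing}")
    df = df[QUANT_COLUMNS].copy()
    # identifiers are strings even when they look numeric (e.g. strain "168")
    for col in ("protein", "strain", "condition", "fraction"):
        df[col] = df[col].astype(str)
    report = IngestReport(n_input=len(df))

    if dialect == "maxquant":
        zero = df["intensity"] == 0
        report.n_zero_dropped = int(zero.sum())
        df = df[~zero]

    if not intensities_log2 and (df["intensity"] <= 0).any():
        raise ValidationError("non-positive intensity in quantification table")

    unknown_fraction = ~df["fraction"].isin(design.fractions)
    if unknown_fraction.any():
        bad = sorted(df.loc[unknown_fraction, "fraction"].unique())
        raise ValidationError(f"unknown fraction label(s): {bad}")

    in_design = (
        df["strain"].isin(design.strains)
        & df["condition"].isin(design.conditions)
        & df["replicate"].between(1, design.n_replicates)
    )
    report.rejected = df[~in_design].copy()
    report.n_rejected = int((~in_design).sum())
    df = df[in_design].reset_index(drop=True)
    report.n_kept = len(df)

    key = ["protein", "strain", "condition", "fraction", "replicate"]
    if df.duplicated(key).any():
        dup = df[df.duplicated(key, keep=False)].head(5)
        raise ValidationError(f"duplicate measurement keys, e.g.\n{dup}")

    df["replicate"] = df["replicate"].astype(int)
    df["unique_peptides"] = df["unique_peptides"].astype(int)
    df.attrs["is_log2"] = bool(intensities_log2)
    if return_report:
        return df, report
    return df


def read_wide_quant_table(
    path,
    sample_columns: Mapping[str, tuple[str, str, str, int]],
    protein_column: str = "protein",
    unique_peptides_column: str | None = None,
    fmt: str | None = None,
    design: Design | None = None,
    intensities_log2: bool = False,
    dialect: str = "maxquant",
    return_report: bool = False,
):
    """Melt a wide (MaxQuant / supplementary-style) table into the long format.

    ``sample_columns`` maps each intensity column name to its
    ``(strain, condition, fraction, replicate)`` coordinates.  Blank / NaN
    cells become absent rows; in the (default) MaxQuant dialect zeros do too.
    """
    df = _read_frame(path, fmt)
    if protein_column not in df.columns:
        raise ValidationError(f"missing protein column {protein_column!r}")
    records = []
    for col, (strain, condition, fraction, replicate) in sample_columns.items():
        if col not in df.columns:
            raise ValidationError(f"missing sample column {col!r}")
        sub = pd.DataFrame(
            {
                "protein": df[protein_column],
                "strain": strain,
                "condition": condition,
                "fraction": fraction,
                "replicate": replicate,
                "intensity": pd.to_numeric(df[col], errors="coerce"),
                "unique_peptides": (
                    df[unique_peptides_column] if unique_peptides_column else 0
                ),
            }
        )
        records.append(sub)
    long = pd.concat(records, ignore_index=True)
    long = long.dropna(subset=["intensity"])
    # melting cannot produce duplicates the long reader would miss; reuse its
    # validation by round-tripping through an in-memory buffer-free path
    long.attrs["is_log2"] = bool(intensities_log2)
    return _validate_long(
        long, design or Design(), intensities_log2, dialect, return_report
    )


def _validate_long(df, design, intensities_log2, dialect, return_report):
    df = df.copy()
    for col in ("protein", "strain", "condition", "fraction"):
        df[col] = df[col].astype(str)
    report = IngestReport(n_input=len(df))
    if dialect == "maxquant":
        zero = df["intensity"] == 0
        report.n_zero_dropped = int(zero.sum())
        df = df[~zero]
    if not intensities_log2 and (df["intensity"] <= 0).any():
        raise ValidationError("non-positive intensity in quantification table")
    unknown_fraction = ~df["fraction"].isin(design.fractions)
    if unknown_fraction.any():
        bad = sorted(df.loc[unknown_fraction, "fraction"].unique())
        raise ValidationError(f"unknown fraction label(s): {bad}")
    in_design = (
        df["strain"].isin(design.strains)
        & df["condition"].isin(design.conditions)
        & df["replicate"].between(1, design.n_replicates)
    )
    report.rejected = df[~in_design].copy()
    report.n_rejected = int((~in_design).sum())
    df = df[in_design].reset_index(drop=True)
    report.n_kept = len(df)
    key = ["protein", "strain", "condition", "fraction", "replicate"]
    if df.duplicated(key).any():
        raise ValidationError("duplicate measurement keys after melting")
    df.attrs["is_log2"] = bool(intensities_log2)
    if return_report:
        return df, report
    return df


# ---------------------------------------------------------------------------
# annotation maps
# ---------------------------------------------------------------------------


def read_annotation_maps(
    localization_path=None,
    sec_sp_path=None,
    categories_path=None,
    regulons_path=None,
    fmt: str | None = None,
) -> AnnotationMaps:
    """Read the protein annotation maps; every file is optional.

    Expected layouts (TSV/CSV, header required):
      localization: protein, localization
      sec_sp:       protein, sec_sp (truthy/falsy)
      categories:   protein, category  (path levels joined by "/", <= 4)
      regulons:     protein, regulon, mode
    """
    maps = AnnotationMaps()
    if localization_path is not None:
        df = _read_frame(localization_path, fmt)
        maps.localization = dict(zip(df["protein"], df["localization"]))
    if sec_sp_path is not None:
        df = _read_frame(sec_sp_path, fmt)
        truthy = {"1", "true", "yes", "y"}
        maps.sec_sp = {
            p: str(v).strip().lower() in truthy
            for p, v in zip(df["protein"], df["sec_sp"])
        }
    if categories_path is not None:
        df = _read_frame(categories_path, fmt)
        cats: dict[str, list[tuple[str, ...]]] = {}
        for p, raw in zip(df["protein"], df["category"]):
            if pd.isna(raw) or not str(raw).strip():
                continue
            path = tuple(s.strip() for s in str(raw).split("/") if s.strip())
            if len(path) > MAX_CATEGORY_LEVELS:
                raise ValidationError(
                    f"category path deeper than {MAX_CATEGORY_LEVELS} levels: {raw!r}"
                )
            cats.setdefault(p, []).append(path)
        maps.categories = cats
    if regulons_path is not None:
        df = _read_frame(regulons_path, fmt)
        regs: dict[str, list[tuple[str, str]]] = {}
        for p, r, m in zip(df["protein"], df["regulon"], df["mode"]):
            mode = _MODE_ALIASES.get(str(m).strip().lower(), "other")
            regs.setdefault(p, []).append((str(r), mode))
        maps.regulons = regs
    return maps


def write_annotation_maps(maps: AnnotationMaps, outdir, prefix: str = "") -> dict:
    """Write the four annotation maps as TSVs; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    if maps.localization:
        df = pd.DataFrame(
            {"protein": list(maps.localization), "localization": list(maps.localization.values())}
        )
        paths["localization"] = outdir / f"{prefix}localization.tsv"
        df.to_csv(paths["localization"], sep="\t", index=False)
    if maps.sec_sp:
        df = pd.DataFrame(
            {"protein": list(maps.sec_sp), "sec_sp": [int(v) for v in maps.sec_sp.values()]}
        )
        paths["sec_sp"] = outdir / f"{prefix}sec_sp.tsv"
        df.to_csv(paths["sec_sp"], sep="\t", index=False)
    if maps.categories:
        rows = [
            {"protein": p, "category": "/".join(path)}
            for p, paths_ in maps.categories.items()
            for path in paths_
        ]
        paths["categories"] = outdir / f"{prefix}categories.tsv"
        pd.DataFrame(rows).to_csv(paths["categories"], sep="\t", index=False)
    if maps.regulons:
        rows = [
            {"protein": p, "regulon": r, "mode": m}
            for p, regs in maps.regulons.items()
            for r, m in regs
        ]
        paths["regulons"] = outdir / f"{prefix}regulons.tsv"
        pd.DataFrame(rows).to_csv(paths["regulons"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# plate series
# ---------------------------------------------------------------------------

PLATE_COLUMNS = ["well", "strain", "role", "time_min", "od600", "gfp"]


def read_plate_series(
    path,
    fmt: str | None = None,
    column_map: Mapping[str, str] | None = None,
    control_wells: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Read a long-format plate-reader export.

    If the file has no ``role`` column, ``control_wells`` designates the
    reporter-free background wells.
    """
    df = _read_frame(path, fmt)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    if "role" not in df.columns:
        if control_wells is None:
            raise ValidationError("plate series needs a role column or control_wells")
        df["role"] = ["control" if w in set(control_wells) else "reporter" for w in df["well"]]
    if "strain" not in df.columns:
        df["strain"] = df["well"]
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"plate series lacks columns: {missing}")
    df = df[PLATE_COLUMNS].copy()
    if (df["od600"] <= 0).any():
        raise ValidationError("non-positive OD600 in plate series")
    spacing = (
        df.sort_values(["well", "time_min"]).groupby("well")["time_min"].diff().dropna()
    )
    if spacing.nunique() > 1 and spacing.std() > 1e-9:
        raise ValidationError("non-uniform time spacing in plate series")
    return df


# ---------------------------------------------------------------------------
# stage-output writer
# ---------------------------------------------------------------------------


def config_hash(config) -> str:
    """Stable short hash of any JSON-serializable configuration object."""
    try:
        payload = json.dumps(config, sort_keys=True, default=str)
    except TypeError:
        payload = repr(config)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, config=None) -> Path:
    """Write a stage-result TSV with a header comment carrying the pipeline
    version and configuration hash."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(
            f"# subproteo {PIPELINE_VERSION} config={config_hash(config)}\n"
        )
        df.to_csv(fh, sep="\t", index=False)
    return path


def read_table(path) -> pd.DataFrame:
    """Read back a stage-result TSV (skipping header comments)."""
    return pd.read_csv(path, sep="\t", comment="#")
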