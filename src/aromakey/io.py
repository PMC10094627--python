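"""CSV/YAML readers and writers for peak tables, catalogs and matrices.

All files are UTF-8, comma-separated, ``.`` decimal, first row header.

Schemas
-------
``peaks.csv`` (long format), one row per (injection, compound)::

    sample_id,group,replicate,dry_mass_g,is_peak_area,compound_id,peak_area

``compounds.csv``, one row per catalog entry::

    compound_id,name,chem_class,odor_note,odor_threshold_air

``odor_threshold_air`` may be empty (unknown threshold); missing thresholds
are only an error once OAV computation touches that compound.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Optional, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    DEFAULT_IS_MASS_NG,
    CompoundCatalog,
    CompoundRecord,
    InjectionRecord,
    PeakTable,
    RunConfig,
    SchemaError,
    ValidationError,
)

__all__ = [
    "read_catalog",
    "write_catalog",
    "read_peak_table",
    "write_peak_table",
    "read_matrix",
    "write_matrix",
    "load_config",
    "save_config",
    "load_table1_oav",
]

PathLike = Union[str, Path]

_PEAKS_COLUMNS = (
    "sample_id",
    "group",
    "replicate",
    "dry_mass_g",
    "is_peak_area",
    "compound_id",
    "peak_area",
)
_CATALOG_COLUMNS = (
    "compound_id",
    "name",
    "chem_class",
    "odor_note",
    "odor_threshold_air",
)


def _require_columns(frame: pd.DataFrame, required, path: PathLike) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def read_catalog(path: PathLike) -> CompoundCatalog:
    """Load a compound catalog from ``compounds.csv``."""
    frame = pd.read_csv(path, dtype={"compound_id": str, "name": str})
    _require_columns(frame, _CATALOG_COLUMNS, path)
    records = []
    for row in frame.itertuples(index=False):
        threshold = row.odor_threshold_air
        if threshold is None or (isinstance(threshold, float) and np.isnan(threshold)):
            threshold = None
        else:
            threshold = float(threshold)
        note = "" if pd.isna(row.odor_note) else str(row.odor_note)
        records.append(
            CompoundRecord(
                compound_id=str(row.compound_id),
                name=str(row.name),
                chem_class=str(row.chem_class),
                odor_note=note,
                odor_threshold_air=threshold,
            )
        )
    return CompoundCatalog(records)


def write_catalog(catalog: CompoundCatalog, path: PathLike) -> None:
    rows = [
        {
            "compound_id": r.compound_id,
            "name": r.name,
            "chem_class": r.chem_class,
            "odor_note": r.odor_note,
            "odor_threshold_air": r.odor_threshold_air,
        }
        for r in catalog
    ]
    pd.DataFrame(rows, columns=list(_CATALOG_COLUMNS)).to_csv(path, index=False)


def read_peak_table(
    path: PathLike,
    catalog_path: PathLike,
    config: Optional[RunConfig] = None,
    is_mass_ng: float = DEFAULT_IS_MASS_NG,
) -> PeakTable:
    """Load and validate a long-format peak table.

    Raises
    ------
    SchemaError
        If a required column is absent.
    ValidationError
        On unknown compound ids, negative areas, non-positive masses, or
        group labels outside ``config.group_labels``.
    """
    catalog = read_catalog(catalog_path)
    frame = pd.read_csv(path, dtype={"sample_id": str, "compound_id": str, "group": str})
    _require_columns(frame, _PEAKS_COLUMNS, path)

    injections = []
    keys = ["sample_id", "group", "replicate", "dry_mass_g", "is_peak_area"]
    for (sample_id, group, replicate, dry_mass, is_area), sub in frame.groupby(
        keys, sort=False
    ):
        areas = {}
        for row in sub.itertuples(index=False):
            cid = str(row.compound_id)
            if cid in areas:
                raise ValidationError(
                    f"{path}: duplicate compound {cid!r} in injection "
                    f"{sample_id}/r{replicate}"
                )
            areas[cid] = float(row.peak_area)
        injections.append(
            InjectionRecord(
                sample_id=str(sample_id),
                group=str(group),
                replicate=int(replicate),
                dry_mass_g=float(dry_mass),
                is_peak_area=float(is_area),
                peak_areas=areas,
            )
        )
    table = PeakTable(injections=injections, catalog=catalog, is_mass_ng=is_mass_ng)
    table.validate(group_labels=config.group_labels if config is not None else None)
    return table


def write_peak_table(
    table: PeakTable, peaks_path: PathLike, compounds_path: Optional[PathLike] = None
) -> None:
    """Write a peak table (and optionally its catalog) in the long CSV schema."""
    rows = []
    for inj in table.injections:
        for cid, area in inj.peak_areas.items():
            rows.append(
                (
                    inj.sample_id,
                    inj.group,
                    inj.replicate,
                    inj.dry_mass_g,
                    inj.is_peak_area,
                    cid,
                    area,
                )
            )
    pd.DataFrame(rows, columns=list(_PEAKS_COLUMNS)).to_csv(peaks_path, index=False)
    if compounds_path is not None:
        write_catalog(table.catalog, compounds_path)


def write_matrix(matrix: pd.DataFrame, path: PathLike) -> None:
    """Write a labeled 2-D matrix as CSV (row labels in column 1).

    Values survive a round-trip through :func:`read_matrix` to better than 12
    significant digits (full ``repr`` precision is written).
    """
    if matrix.index.has_duplicates:
        raise ValidationError("duplicate row labels")
    if matrix.columns.has_duplicates:
        raise ValidationError("duplicate column labels")
    matrix.to_csv(path, index=True)


def read_matrix(path: PathLike) -> pd.DataFrame:
    """Inverse of :func:`write_matrix`."""
    return pd.read_csv(path, index_col=0)


def load_config(path: PathLike) -> RunConfig:
    """Load a :class:`RunConfig` from YAML."""
    with open(path, "r", encoding="utf-8") as handle:
        data = yaml.safe_load(handle) or {}
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: expected a mapping at the top level")
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        yaml.safe_dump(config.to_dict(), handle, sort_keys=False)


def load_table1_oav() -> Tuple[pd.DataFrame, pd.Series]:
    """Load the packaged per-district OAV reference table for the eight key
    aroma-active compounds.

    Censored entries printed as ``<1`` are mapped to 0.0; any value in
    ``[0, 1)`` is equivalent under the strict ``OAV > 1`` screening rule.

    Returns
    -------
    (oav, odor_notes)
        ``oav`` is a compounds x groups DataFrame; ``odor_notes`` maps
        compound name to its odor descriptor.
    """
    ref = importlib.resources.files("aromakey.data").joinpath("table1_oav.csv")
    with importlib.resources.as_file(ref) as fp:
        frame = pd.read_csv(fp, index_col=0)
    notes = frame.pop("odor_notes")
    oav = frame.apply(
        lambda col: col.map(lambda v: 0.0 if isinstance(v, str) and v.strip().startswith("<") else float(v))
    )
    return oav, notes
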