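"""Readers and writers for the package's tabular formats, plus run config.

Two delimited-text formats are canonical (RFC-4180 CSV; TSV accepted on
read, auto-detected or forced via ``delimiter``):

* species catalogues — header ``species_id,region,length_mm``, one row per
  species with its mean adult body length in mm;
* occurrence tables — long format ``sample_id,species_id[,length_mm]``,
  one row per species observation in a sample, optionally joined against a
  separate species-length lookup catalogue.

Files always store raw lengths in mm; logging happens at analysis time so
a value can never be logged twice.  Structured results (mode analyses,
ratio sets) are written as JSON / CSV with 10-significant-digit floats so
read-back reproduces written values to serialization precision.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .mode_analysis import ModeAnalysisResult
from .ratio_pipeline import OccurrenceSample, RatioSet
from .synthetic_data import SpeciesRecord

logger = logging.getLogger("nichelumps")

CATALOGUE_COLUMNS = ["species_id", "region", "length_mm"]
OCCURRENCE_COLUMNS = ["sample_id", "species_id"]

__all__ = [
    "read_species_catalogue",
    "write_species_catalogue",
    "read_occurrence_table",
    "write_occurrence_table",
    "write_results",
    "load_config",
    "RunConfig",
]


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Resolved run configuration: per-subcommand parameter blocks."""

    seed: int = 0
    out_dir: Path = Path(".")
    log_level: str = "INFO"
    params: Mapping[str, Any] = dataclasses.field(default_factory=dict)


def load_config(path: str | Path) -> RunConfig:
    """Load a flat YAML config file into a RunConfig."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path}: expected a mapping at top level")
    seed = raw.pop("seed", 0)
    if not isinstance(seed, int):
        raise ValueError(f"config {path}: seed must be an integer")
    return RunConfig(
        seed=seed,
        out_dir=Path(raw.pop("out_dir", ".")),
        log_level=str(raw.pop("log_level", "INFO")),
        params=raw,
    )


def _read_table(path: str | Path, delimiter: str | None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty file")
    if delimiter is None:
        # sniff comma vs tab from the header line
        header = path.open().readline()
        delimiter = "\t" if header.count("\t") > header.count(",") else ","
    return pd.read_csv(path, sep=delimiter, dtype=str, skipinitialspace=True)


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def _parse_lengths(df: pd.DataFrame, path) -> np.ndarray:
    lengths = pd.to_numeric(df["length_mm"], errors="coerce")
    bad = df.index[lengths.isna() | (lengths <= 0)]
    if len(bad):
        # +2: header line plus 1-based numbering
        rows = ", ".join(str(i + 2) for i in bad[:5])
        raise ValueError(
            f"{path}: missing or non-positive length_mm in row(s) {rows}"
        )
    return lengths.to_numpy()


def read_species_catalogue(
    path: str | Path, delimiter: str | None = None
) -> list[SpeciesRecord]:
    """Read and validate a species catalogue CSV/TSV.

    Rows with missing or non-positive lengths and duplicated
    ``(species_id, region)`` keys are rejected with row-numbered messages.
    """
    df = _read_table(path, delimiter)
    _require_columns(df, CATALOGUE_COLUMNS, path)
    lengths = _parse_lengths(df, path)
    dup = df.duplicated(subset=["species_id", "region"], keep=False)
    if dup.any():
        keys = df.loc[dup, ["species_id", "region"]].drop_duplicates()
        listing = ", ".join(f"({r.species_id}, {r.region})" for r in keys.itertuples())
        raise ValueError(f"{path}: duplicate (species_id, region) key(s): {listing}")
    return [
        SpeciesRecord(str(sid), str(region), float(length))
        for sid, region, length in zip(df["species_id"], df["region"], lengths)
    ]


def write_species_catalogue(
    records: Sequence[SpeciesRecord], path: str | Path, force: bool = False
) -> None:
    _check_writable(path, force)
    pd.DataFrame(
        [(r.species_id, r.region, _fmt(r.length_mm)) for r in records],
        columns=CATALOGUE_COLUMNS,
    ).to_csv(path, index=False)


def read_occurrence_table(
    path: str | Path,
    lookup_path: str | Path | None = None,
    delimiter: str | None = None,
) -> list[OccurrenceSample]:
    """Read a long-format occurrence table into OccurrenceSample objects.

    Lengths come from an inline ``length_mm`` column, a lookup catalogue,
    or both — but inline and lookup values that disagree for a species are
    an error, never silently resolved.  A species repeated within a sample
    collapses to one member with a warning.
    """
    df = _read_table(path, delimiter)
    _require_columns(df, OCCURRENCE_COLUMNS, path)
    has_inline = "length_mm" in df.columns

    lookup: dict[str, float] = {}
    if lookup_path is not None:
        for rec in read_species_catalogue(lookup_path):
            lookup[rec.species_id] = rec.length_mm

    inline = _parse_lengths(df, path) if has_inline else None
    samples: dict[str, dict[str, float]] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        sid, sp = str(row.sample_id), str(row.species_id)
        if inline is not None:
            length = float(inline[i])
            if sp in lookup and abs(lookup[sp] - length) > 1e-9:
                raise ValueError(
                    f"{path}: species {sp!r} has inline length {length} but "
                    f"lookup length {lookup[sp]} — resolve the conflict"
                )
        elif sp in lookup:
            length = lookup[sp]
        else:
            raise ValueError(
                f"{path}: species {sp!r} has no length (no inline column "
                "and not in the lookup catalogue)"
            )
        members = samples.setdefault(sid, {})
        if sp in members:
            if abs(members[sp] - length) > 1e-9:
                raise ValueError(
                    f"{path}: species {sp!r} repeated in sample {sid!r} "
                    "with conflicting lengths"
                )
            warnings.warn(
                f"{path}: species {sp!r} repeated in sample {sid!r}; "
                "collapsed to one member",
                stacklevel=2,
            )
        members[sp] = length
    return [
        OccurrenceSample(sid, tuple(sorted(members.items())))
        for sid, members in samples.items()
    ]


def write_occurrence_table(
    samples: Sequence[OccurrenceSample], path: str | Path, force: bool = False
) -> None:
    _check_writable(path, force)
    rows = [
        (s.sample_id, sp, _fmt(length))
        for s in samples
        for sp, length in s.members
    ]
    pd.DataFrame(rows, columns=["sample_id", "species_id", "length_mm"]).to_csv(
        path, index=False
    )


def _fmt(x: float) -> str:
    """Serialize a float with 10 significant digits."""
    return f"{x:.10g}"


def _check_writable(path: str | Path, force: bool) -> None:
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(
            f"{path} exists; pass force=True (or --force) to overwrite"
        )


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.floating, float)):
        return float(_fmt(float(obj)))
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def mode_result_document(result: ModeAnalysisResult) -> dict[str, Any]:
    """A JSON-ready document for a mode-analysis result.

    Contains the fits table for every attempted k, the selected class
    count, mode locations on both log and linear (mm / ratio) scales, and
    the peak-to-peak ratios.
    """
    return {
        "criterion": result.criterion,
        "best_k": result.best_k,
        "skipped_k": list(result.skipped_k),
        "fits": [
            {
                "k": f.k,
                "loglik": f.loglik,
                "bic": f.bic,
                "aic": f.aic,
                "converged": f.converged,
                "weights": f.weights,
                "means_log": f.means,
                "sds_log": f.sds,
            }
            for f in result.fits
        ],
        "modes_log": result.modes,
        "modes_linear": result.modes_linear,
        "peak_to_peak_ratios": result.peak_to_peak_ratios,
    }


def ratio_set_frame(ratio_set: RatioSet) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (sid, a, b, _fmt(r))
            for (sid, a, b), r in zip(ratio_set.provenance, ratio_set.ratios)
        ],
        columns=["sample_id", "species_a", "species_b", "ratio"],
    )


def write_results(
    document: Any, path: str | Path, format: str = "auto", force: bool = False
) -> None:
    """Write a result object to disk.

    Tabular objects (DataFrame, RatioSet) go to CSV; mode-analysis results
    and plain mappings go to JSON.  ``format`` may force "csv" or "json".
    Refuses to overwrite without ``force``.
    """
    path = Path(path)
    _check_writable(path, force)
    if isinstance(document, RatioSet):
        document = ratio_set_frame(document)
    if isinstance(document, ModeAnalysisResult):
        document = mode_result_document(document)
    if format == "auto":
        format = "csv" if isinstance(document, pd.DataFrame) else "json"
    if format == "csv":
        if not isinstance(document, pd.DataFrame):
            raise TypeError("csv output requires a tabular document")
        document.to_csv(path, index=False)
    elif format == "json":
        path.write_text(json.dumps(_jsonable(document), indent=2) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")
    logger.info("wrote %s", path)
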