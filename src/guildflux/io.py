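"""File I/O for series, count tables, annotations, profiles and configs.

All tabular formats are plain TSV with a documented header; lines starting
with ``#`` are reproducibility comments (tool version, seed, config hash)
and are skipped on read.  GFF3 CDS annotations use 1-based inclusive
coordinates, so length = end - start + 1.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diversity import AbundanceProfile
from .expression import AlignmentRecord, CDSRecord, FunctionMap
from .stoichiometry import MeasurementSeries, RateVector, ReactorConfig

__all__ = [
    "read_series",
    "write_series",
    "read_counts",
    "write_counts",
    "read_cds_table",
    "write_cds_table",
    "read_cds_gff3",
    "read_alignments",
    "read_function_map",
    "read_profiles",
    "write_profiles",
    "read_reactor_config",
    "provenance_header",
    "config_hash",
]


def config_hash(obj) -> str:
    """Short deterministic hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_header(seed: Optional[int] = None, config: Optional[Mapping] = None) -> str:
    """Comment line recording tool version, seed and config hash."""
    parts = [f"guildflux v{__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config is not None:
        parts.append(f"config_hash={config_hash(config)}")
    return "# " + " ".join(parts)


def _read_tsv(path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def _to_float(df: pd.DataFrame, column: str, path) -> pd.Series:
    try:
        return df[column].astype(float)
    except ValueError as exc:
        for i, raw in enumerate(df[column]):
            try:
                float(raw)
            except ValueError:
                raise ValueError(
                    f"{path}: malformed value {raw!r} in column {column!r} "
                    f"at data row {i + 1}"
                ) from exc
        raise


def _write_tsv(df: pd.DataFrame, path, seed=None, config=None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(provenance_header(seed, config) + "\n")
        df.to_csv(fh, sep="\t", index=False)


# -- measurement series ------------------------------------------------------

def read_series(path) -> MeasurementSeries:
    """Read a tidy (time_d, species, value, unit) measurement series."""
    df = _read_tsv(path, MeasurementSeries.REQUIRED_COLUMNS)
    df["time_d"] = _to_float(df, "time_d", path)
    df["value"] = _to_float(df, "value", path)
    units = set(df["unit"])
    allowed = {"mg_N/L", "mmol/L"}
    bad = units - allowed
    if bad:
        raise ValueError(
            f"{path}: unsupported unit(s) {sorted(bad)}; expected one of {sorted(allowed)}"
        )
    return MeasurementSeries(df)


def write_series(series: MeasurementSeries, path, seed=None, config=None) -> None:
    _write_tsv(series.data, path, seed, config)


# -- counts and CDS tables ---------------------------------------------------

def read_counts(path) -> Dict[str, int]:
    """Read a per-CDS count table (columns cds_id, count)."""
    df = _read_tsv(path, ("cds_id", "count"))
    counts = {}
    for i, row in df.iterrows():
        try:
            c = int(float(row["count"]))
        except ValueError:
            raise ValueError(
                f"{path}: malformed count {row['count']!r} at data row {i + 1}"
            )
        if c < 0:
            raise ValueError(f"{path}: negative count at data row {i + 1}")
        counts[row["cds_id"]] = c
    return counts


def write_counts(counts: Mapping[str, int], path, seed=None, config=None) -> None:
    df = pd.DataFrame(
        {"cds_id": list(counts.keys()), "count": list(counts.values())}
    )
    _write_tsv(df, path, seed, config)


_CDS_COLUMNS = ("cds_id", "genome_id", "gene_symbol", "complex_id", "length", "strand")


def read_cds_table(path) -> List[CDSRecord]:
    """Read a flat TSV of CDS annotations."""
    df = _read_tsv(path, _CDS_COLUMNS)
    records = []
    for i, row in df.iterrows():
        try:
            length = int(float(row["length"]))
        except ValueError:
            raise ValueError(
                f"{path}: malformed length {row['length']!r} at data row {i + 1}"
            )
        try:
            records.append(
                CDSRecord(
                    cds_id=row["cds_id"],
                    genome_id=row["genome_id"],
                    gene_symbol=row["gene_symbol"] if pd.notna(row["gene_symbol"]) else "",
                    complex_id=row["complex_id"] if pd.notna(row["complex_id"]) else "",
                    length=length,
                    strand=row["strand"],
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: data row {i + 1}: {exc}") from exc
    return records


def write_cds_table(records: Sequence[CDSRecord], path, seed=None, config=None) -> None:
    df = pd.DataFrame(
        [
            (r.cds_id, r.genome_id, r.gene_symbol, r.complex_id, r.length, r.strand)
            for r in records
        ],
        columns=_CDS_COLUMNS,
    )
    _write_tsv(df, path, seed, config)


def read_cds_gff3(path) -> List[CDSRecord]:
    """Read CDS annotations from a GFF3 file (1-based inclusive coordinates).

    Attributes ``ID``, ``gene_symbol``, ``complex_id`` and ``genome_id``
    are honoured; ``genome_id`` falls back to the seqid column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seqid, _, ftype, start, end, _, strand, _, attrs = fields
            if ftype != "CDS":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates")
            if end_i < start_i:
                raise ValueError(f"{path}:{lineno}: end < start")
            attr_map = {}
            for chunk in attrs.split(";"):
                chunk = chunk.strip()
                if not chunk:
                    continue
                if "=" not in chunk:
                    raise ValueError(f"{path}:{lineno}: malformed attribute {chunk!r}")
                key, val = chunk.split("=", 1)
                attr_map[key] = val
            if "ID" not in attr_map:
                raise ValueError(f"{path}:{lineno}: CDS feature lacks ID attribute")
            records.append(
                CDSRecord(
                    cds_id=attr_map["ID"],
                    genome_id=attr_map.get("genome_id", seqid),
                    gene_symbol=attr_map.get("gene_symbol", ""),
                    complex_id=attr_map.get("complex_id", ""),
                    length=end_i - start_i + 1,
                    strand=strand if strand in ("+", "-") else "+",
                )
            )
    return records


# -- alignments --------------------------------------------------------------

def read_alignments(path) -> List[AlignmentRecord]:
    """Read SAM-derived alignment summaries.

    Columns: read_id, target_id, read_length, aligned_length, identity.
    """
    df = _read_tsv(path, ("read_id", "target_id", "read_length", "aligned_length", "identity"))
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                AlignmentRecord(
                    read_id=row["read_id"],
                    target_id=row["target_id"],
                    read_length=int(float(row["read_length"])),
                    aligned_length=int(float(row["aligned_length"])),
                    identity=float(row["identity"]),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: data row {i + 1}: {exc}") from exc
    return records


# -- function map ------------------------------------------------------------

def read_function_map(path) -> FunctionMap:
    """Read the complex/reaction/pathway hierarchy from YAML."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with path.open() as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: function map must be a mapping")
    allowed = {"complexes", "reactions", "pathways"}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"{path}: unknown key {sorted(unknown)[0]!r}")
    if "complexes" not in raw:
        raise ValueError(f"{path}: function map requires a 'complexes' section")
    return FunctionMap(
        complexes={k: tuple(v) for k, v in raw["complexes"].items()},
        reactions={k: tuple(v) for k, v in raw.get("reactions", {}).items()},
        pathways={k: tuple(v) for k, v in raw.get("pathways", {}).items()},
    )


# -- abundance profiles ------------------------------------------------------

def read_profiles(path) -> Dict[str, AbundanceProfile]:
    """Read a sample x category abundance matrix (first column = sample id)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: profile matrix needs >= 1 category column")
    sample_col = df.columns[0]
    labels = list(df.columns[1:])
    profiles = {}
    for i, row in df.iterrows():
        values = row[labels].to_numpy(float)
        if np.any(values < 0):
            raise ValueError(f"{path}: negative abundance at data row {i + 1}")
        profiles[str(row[sample_col])] = AbundanceProfile(labels, values)
    return profiles


def write_profiles(
    profiles: Mapping[str, AbundanceProfile], path, seed=None, config=None
) -> None:
    labels = None
    rows = []
    for sample, prof in profiles.items():
        if labels is None:
            labels = list(prof.labels)
        elif list(prof.labels) != labels:
            raise ValueError("all profiles must share one category set")
        rows.append([sample, *prof.proportions])
    df = pd.DataFrame(rows, columns=["sample", *labels])
    _write_tsv(df, path, seed, config)


# -- configs -----------------------------------------------------------------

def _check_keys(raw: Mapping, allowed: set, required: set, where: str) -> None:
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"{where}: unknown key {sorted(unknown)[0]!r}")
    missing = required - set(raw)
    if missing:
        raise ValueError(f"{where}: missing required key {sorted(missing)[0]!r}")


def read_reactor_config(path) -> ReactorConfig:
    """Read reactor operating parameters from YAML."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with path.open() as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: reactor config must be a mapping")
    _check_keys(raw, {"hrt_days", "influent", "volume_l"}, {"hrt_days", "influent"}, str(path))
    return ReactorConfig(
        hrt_days=float(raw["hrt_days"]),
        influent={k: float(v) for k, v in raw["influent"].items()},
        volume_l=float(raw.get("volume_l", 1.0)),
    )
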