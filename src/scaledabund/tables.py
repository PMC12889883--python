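"""Reading, validating and writing abundance tables and analysis configuration.

The universal currency of the package is a samples x taxa matrix of
sequencing read counts (or measured relative abundances).  Tables travel as
:class:`CountTable`; the analysis configuration (which taxon is the internal
standard, at what known concentration, plus optional spike-in ground truth
and sample metadata) travels as small dataclasses parsed from YAML or JSON.

Tables are samples-as-rows by default; ``transpose=True`` reads the other
orientation.  Taxon identifiers are opaque strings — the framework is
rank-agnostic and applies equally at strain, species or genus level.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, ParseError, ValidationError

__all__ = [
    "CountTable",
    "SampleMetadata",
    "InternalStandardSpec",
    "SpikeTruth",
    "read_count_table",
    "read_analysis_config",
    "write_table",
]

#: Row sums within this band of 1 are treated as proportions on auto-detection.
PROPORTION_DETECT_TOL = 1e-6
#: Validation tolerance for proportion row sums.
PROPORTION_SUM_TOL = 1e-9


def _check_unique(labels: Iterable[str], what: str) -> None:
    labels = list(labels)
    seen: set = set()
    dups = []
    for x in labels:
        if x in seen:
            dups.append(x)
        seen.add(x)
    if dups:
        raise ValidationError(f"duplicate {what} ids: {sorted(set(map(str, dups)))}")


def _validate_matrix(data: pd.DataFrame, *, what: str) -> None:
    """Shared invariant checks for any samples x taxa value matrix."""
    if data.shape[0] < 1:
        raise ValidationError(f"{what} must contain at least one sample")
    _check_unique(data.index, "sample")
    _check_unique(data.columns, "taxon")
    values = data.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        r, c = np.argwhere(~np.isfinite(values))[0]
        raise ValidationError(
            f"non-finite value at sample {data.index[r]!r}, taxon {data.columns[c]!r}"
        )
    if (values < 0).any():
        r, c = np.argwhere(values < 0)[0]
        raise ValidationError(
            f"negative value {values[r, c]} at sample {data.index[r]!r}, "
            f"taxon {data.columns[c]!r}"
        )


@dataclass
class CountTable:
    """A samples x taxa matrix of read counts or relative abundances.

    Parameters
    ----------
    data:
        DataFrame with sample ids on the index and taxon ids on the columns.
        Values are nonnegative and finite.
    mode:
        ``"counts"`` for raw read counts, ``"proportions"`` when every sample
        row sums to 1 (within ``1e-9``).
    """

    data: pd.DataFrame
    mode: str = "counts"

    def __post_init__(self) -> None:
        if self.mode not in ("counts", "proportions"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        self.data = self.data.astype(float)
        if self.data.shape[1] < 2:
            raise ValidationError("a count table needs at least two taxa")
        _validate_matrix(self.data, what="count table")
        if self.mode == "proportions":
            sums = self.data.sum(axis=1)
            bad = sums[(sums - 1.0).abs() > PROPORTION_SUM_TOL]
            if len(bad):
                raise ValidationError(
                    "proportions rows must sum to 1: sample "
                    f"{bad.index[0]!r} sums to {bad.iloc[0]!r}"
                )

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()


@dataclass
class SampleMetadata:
    """Per-sample design annotations: replicate group, background, dilution.

    ``dilution_fraction`` is the fraction of undiluted material in the sample
    (1.0 = undiluted) and may be absent (NaN).
    """

    data: pd.DataFrame  # indexed by sample_id

    COLUMNS = ("replicate_group", "background_id", "dilution_fraction")

    def __post_init__(self) -> None:
        df = self.data.copy()
        for col in self.COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        _check_unique(df.index, "sample")
        frac = pd.to_numeric(df["dilution_fraction"], errors="coerce")
        bad = frac[(frac <= 0) | (frac > 1)].dropna()
        if len(bad):
            raise ValidationError(
                f"dilution_fraction must lie in (0, 1]: sample {bad.index[0]!r} "
                f"has {bad.iloc[0]}"
            )
        df["dilution_fraction"] = frac
        self.data = df

    def check_against(self, table: CountTable) -> None:
        missing = set(self.data.index) - set(table.sample_ids)
        if missing:
            raise ValidationError(
                f"metadata refers to samples absent from the table: {sorted(missing)}"
            )

    def samples_in_group(self, replicate_group: str) -> list:
        sel = self.data["replicate_group"] == replicate_group
        return list(self.data.index[sel])

    def dilution_fractions(self) -> pd.Series:
        return self.data["dilution_fraction"]


@dataclass(frozen=True)
class InternalStandardSpec:
    """Identity and known concentration of the exogenous internal standard."""

    taxon_id: str
    actual_abundance: float
    units: str = "copies/mcL"
    uncertainty: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.taxon_id:
            raise ConfigError("internal standard taxon_id must be nonempty")
        if not (self.actual_abundance > 0):
            raise ConfigError(
                f"internal standard actual_abundance must be > 0, "
                f"got {self.actual_abundance}"
            )
        if self.uncertainty is not None and self.uncertainty < 0:
            raise ConfigError("uncertainty must be nonnegative")


@dataclass
class SpikeTruth:
    """Known actual abundances of spiked-in taxa.

    Each entry applies either to one sample or to all samples
    (``sample_id="ALL"``).  Units must be consistent with the internal
    standard's units.
    """

    entries: pd.DataFrame  # columns: taxon_id, sample_id, actual_abundance, units
    units: str = "copies/mcL"

    def __post_init__(self) -> None:
        df = self.entries.copy()
        required = {"taxon_id", "actual_abundance"}
        if not required <= set(df.columns):
            raise ConfigError(f"spike truth needs columns {sorted(required)}")
        if "sample_id" not in df.columns:
            df["sample_id"] = "ALL"
        df["sample_id"] = df["sample_id"].fillna("ALL")
        if "units" not in df.columns:
            df["units"] = self.units
        if (df["actual_abundance"] <= 0).any():
            bad = df[df["actual_abundance"] <= 0].iloc[0]
            raise ConfigError(
                f"spike truth abundance must be > 0: taxon {bad['taxon_id']!r} "
                f"has {bad['actual_abundance']}"
            )
        other = set(df["units"]) - {self.units}
        if other:
            raise ConfigError(
                f"spike truth units {sorted(other)} inconsistent with {self.units!r}"
            )
        self.entries = df.reset_index(drop=True)

    @property
    def taxon_ids(self) -> list:
        return list(dict.fromkeys(self.entries["taxon_id"]))

    def abundance_for(self, taxon_id: str, sample_id: str = "ALL") -> float:
        df = self.entries
        hit = df[(df["taxon_id"] == taxon_id) & (df["sample_id"] == sample_id)]
        if hit.empty and sample_id != "ALL":
            hit = df[(df["taxon_id"] == taxon_id) & (df["sample_id"] == "ALL")]
        if hit.empty:
            raise ConfigError(f"no spike truth for taxon {taxon_id!r}")
        return float(hit["actual_abundance"].iloc[0])

    @classmethod
    def uniform(
        cls, abundances: Mapping[str, float], units: str = "copies/mcL"
    ) -> "SpikeTruth":
        """Truth table for taxa spiked at the same concentration in every sample."""
        df = pd.DataFrame(
            {
                "taxon_id": list(abundances),
                "sample_id": "ALL",
                "actual_abundance": list(abundances.values()),
                "units": units,
            }
        )
        return cls(df, units=units)


def _infer_delimiter(path: Path, delimiter: Optional[str]) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_count_table(
    path: Union[str, Path],
    mode_hint: Optional[str] = None,
    *,
    transpose: bool = False,
    delimiter: Optional[str] = None,
) -> CountTable:
    """Read a delimited samples x taxa abundance table.

    The first column holds sample ids and the header row holds taxon ids
    (``transpose=True`` for the opposite orientation).  The delimiter is
    inferred from the extension (``.csv`` -> comma, otherwise tab) unless
    given explicitly.

    Whether the table holds counts or proportions is auto-detected: if every
    row sums to 1 within ``1e-6`` the table is treated as proportions.  Pass
    ``mode_hint`` ("counts" or "proportions") to override detection —
    recommended whenever the provenance of the table is known, since silent
    misinterpretation corrupts every downstream number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _infer_delimiter(path, delimiter)

    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) < 2:
        raise ParseError(f"{path}: need a header line and at least one data row")
    width = len(lines[0].split(sep))
    for i, ln in enumerate(lines[1:], start=2):
        if len(ln.split(sep)) != width:
            raise ParseError(
                f"{path}: line {i} has {len(ln.split(sep))} fields, expected {width}"
            )

    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:  # pragma: no cover - pandas raises rarely after checks
        raise ParseError(f"{path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        if converted.isna().any() and not df[col].isna().any():
            bad = df.index[converted.isna()][0]
            raise ParseError(
                f"{path}: non-numeric value at sample {bad!r}, taxon {col!r}"
            )
        df[col] = converted
    if transpose:
        df = df.T

    if mode_hint is not None:
        if mode_hint not in ("counts", "proportions"):
            raise ValidationError(f"unknown mode_hint {mode_hint!r}")
        mode = mode_hint
    else:
        sums = df.sum(axis=1).to_numpy(dtype=float)
        mode = (
            "proportions"
            if np.all(np.abs(sums - 1.0) <= PROPORTION_DETECT_TOL)
            else "counts"
        )
    if mode == "proportions":
        # Renormalise within detection tolerance so validation's tighter
        # 1e-9 band holds for tables stored at lower precision.
        sums = df.sum(axis=1)
        if ((sums - 1.0).abs() <= PROPORTION_DETECT_TOL).all():
            df = df.div(sums, axis=0)
    return CountTable(df, mode=mode)


def write_table(
    table: Union[CountTable, "object", pd.DataFrame],
    path: Union[str, Path],
    *,
    delimiter: Optional[str] = None,
) -> Path:
    """Write a table (anything with a ``data`` DataFrame) to TSV/CSV.

    Floats are written with 17 significant digits — enough to reproduce any
    double exactly on a read/write round trip.
    """
    path = Path(path)
    df = table if isinstance(table, pd.DataFrame) else getattr(table, "data")
    sep = _infer_delimiter(path, delimiter)
    try:
        df.to_csv(path, sep=sep, float_format="%.17g", index_label="sample_id")
    except OSError as exc:
        raise OSError(f"cannot write table to {path}: {exc}") from exc
    return path


def _load_structured(path: Path) -> dict:
    text = path.read_text()
    if path.suffix.lower() == ".json":
        try:
            return json.loads(text)
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: invalid JSON ({exc})") from exc
    try:
        loaded = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ParseError(f"{path}: invalid YAML ({exc})") from exc
    if not isinstance(loaded, dict):
        raise ParseError(f"{path}: expected a mapping at the top level")
    return loaded


def read_analysis_config(
    path: Union[str, Path],
) -> tuple[InternalStandardSpec, Optional[SpikeTruth], Optional[SampleMetadata]]:
    """Read the analysis configuration (YAML or JSON).

    The file must contain an ``internal_standard`` block with ``taxon_id``
    and ``actual_abundance``; ``spike_truth`` (list of entries) and
    ``sample_metadata`` (list of per-sample records) blocks are optional and
    return ``None`` when absent.
    """
    path = Path(path)
    cfg = _load_structured(path)

    block = cfg.get("internal_standard")
    if not isinstance(block, dict):
        raise ConfigError(f"{path}: missing 'internal_standard' block")
    if "taxon_id" not in block or "actual_abundance" not in block:
        raise ConfigError(
            f"{path}: internal_standard needs 'taxon_id' and 'actual_abundance'"
        )
    is_spec = InternalStandardSpec(
        taxon_id=str(block["taxon_id"]),
        actual_abundance=float(block["actual_abundance"]),
        units=str(block.get("units", "copies/mcL")),
        uncertainty=(
            float(block["uncertainty"]) if block.get("uncertainty") is not None else None
        ),
    )

    truth = None
    if cfg.get("spike_truth"):
        rows = []
        for entry in cfg["spike_truth"]:
            rows.append(
                {
                    "taxon_id": str(entry["taxon_id"]),
                    "sample_id": str(entry.get("sample_id", "ALL")),
                    "actual_abundance": float(entry["actual_abundance"]),
                    "units": str(entry.get("units", is_spec.units)),
                }
            )
        truth = SpikeTruth(pd.DataFrame(rows), units=is_spec.units)

    metadata = None
    if cfg.get("sample_metadata"):
        rows = []
        for entry in cfg["sample_metadata"]:
            if "sample_id" not in entry:
                raise ConfigError(f"{path}: sample_metadata entry missing 'sample_id'")
            rows.append(
                {
                    "sample_id": str(entry["sample_id"]),
                    "replicate_group": entry.get("replicate_group", np.nan),
                    "background_id": entry.get("background_id", np.nan),
                    "dilution_fraction": entry.get("dilution_fraction", np.nan),
                }
            )
        df = pd.DataFrame(rows).set_index("sample_id")
        metadata = SampleMetadata(df)

    return is_spec, truth, metadata
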