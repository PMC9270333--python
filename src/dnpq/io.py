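"""Readers, writers and configuration.

The package standardizes on plain CSV integral tables (the two
spectrometer vendors export differently; producing these tables is
documented in the README):

* signal series — header ``time_s,signal``
* sweeps — header ``setting,response``
* multi-run tables — named numeric columns
  (``conc_mM,tdnp_s,ttrans_s,s_hp,s_tp,enhancement,p_meas_pct,p0_pct,t1_s,ph``)

Reports are JSON with stable key order; every numeric result carries a
unit and the bundle records provenance (input digests, config snapshot,
package version, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import pandas as pd
import yaml

from dnpq._fitting import SignalSeries
from dnpq.sweep_analysis import SweepSeries

__all__ = [
    "ParseError",
    "read_signal_series",
    "read_sweep",
    "read_runs_table",
    "ReportBundle",
    "write_report",
    "read_report",
    "file_digest",
    "load_yaml_config",
]


class ParseError(ValueError):
    """An input file violated the documented CSV contract."""


def _read_csv(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise ParseError(f"{path}: file not found") from None
    except Exception as exc:  # malformed CSV
        raise ParseError(f"{path}: not parseable as CSV ({exc})") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {', '.join(missing)}")
    for col in required:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad) > 0:
            raise ParseError(
                f"{path}: non-numeric value in column {col!r}, row {int(bad[0]) + 2}"
            )
        if coerced.isna().any():
            row = int(df.index[coerced.isna()][0]) + 2
            raise ParseError(f"{path}: empty cell in column {col!r}, row {row}")
        df[col] = coerced
    return df


def read_signal_series(path: str | Path, phase_label: str = "liquid_decay") -> SignalSeries:
    """Read a ``time_s,signal`` CSV into a validated, time-sorted series.

    Duplicate timestamps are rejected; fewer than 3 rows is an error.
    """
    df = _read_csv(path, ("time_s", "signal"))
    if len(df) < 3:
        raise ParseError(f"{path}: need >= 3 rows, got {len(df)}")
    df = df.sort_values("time_s", kind="stable")
    times = df["time_s"].to_numpy(float)
    if pd.Series(times).duplicated().any():
        dup = times[pd.Series(times).duplicated()][0]
        raise ParseError(f"{path}: duplicate timestamp time_s = {dup:g}")
    return SignalSeries(times, df["signal"].to_numpy(float), phase_label)


def read_sweep(path: str | Path, sweep_kind: str) -> SweepSeries:
    """Read a ``setting,response`` CSV into a sweep series."""
    df = _read_csv(path, ("setting", "response"))
    df = df.sort_values("setting", kind="stable")
    try:
        return SweepSeries(
            df["setting"].to_numpy(float), df["response"].to_numpy(float), sweep_kind
        )
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None


def read_runs_table(path: str | Path) -> pd.DataFrame:
    """Read a multi-run table (named numeric columns, one row per run)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise ParseError(f"{path}: file not found") from None
    except Exception as exc:
        raise ParseError(f"{path}: not parseable as CSV ({exc})") from None
    if df.shape[0] < 1 or df.shape[1] < 1:
        raise ParseError(f"{path}: empty table")
    return df


def file_digest(path: str | Path) -> str:
    """SHA-256 hex digest of a file, for provenance records."""
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass(frozen=True)
class ReportBundle:
    """Structured results plus provenance.

    ``results`` maps result names to ``{"value": number, "unit": str}``
    entries (nested sections of such entries are allowed); ``provenance``
    records input digests, the config snapshot, package version and seed.
    """

    results: dict
    provenance: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_units(self.results, path="results")


def _check_units(node: dict, path: str) -> None:
    if not isinstance(node, dict):
        raise ValueError(f"{path}: expected a mapping")
    if "value" in node:
        if "unit" not in node:
            raise ValueError(f"{path}: numeric result lacks a unit")
        return
    for key, child in node.items():
        _check_units(child, f"{path}.{key}")


def write_report(bundle: ReportBundle, path: str | Path) -> None:
    """Write a bundle as deterministic JSON (sorted keys, fixed format)."""
    doc = {"results": bundle.results, "provenance": bundle.provenance}
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_report(path: str | Path) -> ReportBundle:
    doc = json.loads(Path(path).read_text())
    return ReportBundle(results=doc["results"], provenance=doc.get("provenance", {}))


def load_yaml_config(path: str | Path) -> dict:
    """Load a YAML analysis config (nucleus, field, schemes, conventions)."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ParseError(f"{path}: config must be a mapping")
    return doc
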