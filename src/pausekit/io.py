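"""Shared IO: validated tables, gel CSV format, FASTA reads, RNG streams.

File conventions:

* gel CSV — first column is the band label (transcript position or
  "termination"/"runoff"), the header row holds the timepoints, cells are
  intensities; an optional leading comment ``# time_unit=min`` declares
  the time unit (default seconds).
* traces — TSV with columns ``time_s``, ``distance_nm``, ``force_pn``
  (or ``position_bp`` directly), one file per tether.
* restarts — TSV with columns ``tether_id``, ``force_pn``,
  ``restart_time_s``.
* reads — gapless equal-length FASTA plus a reference FASTA.

Randomness is organised as one root seed per run, forked into named
substreams so that adding a stage never perturbs the draws of another.
"""

from __future__ import annotations

import json
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from .gel import GelTimeCourse

__all__ = [
    "named_rng",
    "read_table",
    "read_gel_csv",
    "write_gel_csv",
    "read_trace_tsv",
    "read_fasta",
    "write_json_report",
]


def named_rng(seed: int, name: str) -> np.random.Generator:
    """Deterministic per-stage substream of the run-level seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


def read_table(path, columns: dict, sep: str = "\t") -> pd.DataFrame:
    """Read a delimited table and validate its schema.

    ``columns`` maps required column names to dtypes.  Raises ValueError
    naming every missing column; rows that fail dtype coercion are
    reported with their (1-based, header-exclusive) line numbers.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep, comment="#")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing column(s) {missing}")
    for col, dtype in columns.items():
        coerced = pd.to_numeric(df[col], errors="coerce") \
            if dtype in (float, int) else df[col].astype(dtype)
        if dtype in (float, int):
            bad = df.index[coerced.isna() & df[col].notna()]
            if len(bad):
                lines = [int(i) + 1 for i in bad[:10]]
                raise ValueError(
                    f"{path.name}: column {col!r} not {dtype.__name__} "
                    f"at line(s) {lines}")
            df[col] = coerced.astype(dtype)
    return df


def read_gel_csv(path) -> GelTimeCourse:
    """Read a band-intensity matrix; see module docstring for the format."""
    path = Path(path)
    time_unit = "s"
    with open(path) as fh:
        head = fh.readline()
        if head.startswith("#"):
            for token in head[1:].strip().split():
                if token.startswith("time_unit="):
                    time_unit = token.split("=", 1)[1]
        else:
            fh.seek(0)
        df = pd.read_csv(fh, index_col=0)
    df.columns = [float(c) for c in df.columns]
    df.index = [str(i) for i in df.index]
    labels = {lab: lab for lab in ("termination", "runoff") if lab in df.index}
    return GelTimeCourse(intensities=df, band_labels=labels,
                         time_unit=time_unit)


def write_gel_csv(gel: GelTimeCourse, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# time_unit={gel.time_unit}\n")
        gel.intensities.to_csv(fh, index_label="band")


def read_trace_tsv(path):
    """Read one tether record; returns (time, position_bp or None, distance,
    force).  Accepts either a pre-converted position_bp column or raw
    distance_nm + force_pn."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "position_bp" in df.columns:
        return df["time_s"].to_numpy(), df["position_bp"].to_numpy(), None, None
    df = read_table(path, {"time_s": float, "distance_nm": float,
                           "force_pn": float})
    return (df["time_s"].to_numpy(), None, df["distance_nm"].to_numpy(),
            float(df["force_pn"].iloc[0]))


def read_fasta(path) -> list:
    """Sequences from a FASTA file (Biopython-backed)."""
    from Bio import SeqIO
    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_json_report(payload: dict, path) -> None:
    """Write a machine-readable report with a provenance block."""
    with open(path, "w") as fh:
        json.dump(_jsonable(payload), fh, indent=2, sort_keys=True)
        fh.write("\n")
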