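"""Tab-separated readers and writers for evidence and profile tables.

Canonical on-disk format is UTF-8 TSV with "." as decimal point.  Profile
tables carry one row per protein: a ``protein_id`` column, abundance columns
``S001..Snnn`` (one per slice) and, optionally, parallel reliability columns
``R001..Rnnn``.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import PeptideEvidence, ProfileSet

logger = logging.getLogger(__name__)

EVIDENCE_COLUMNS = (
    "peptide_id",
    "protein_id",
    "run_index",
    "mz",
    "elution_time",
    "intensity",
    "is_specific",
)


class FormatError(ValueError):
    """Raised when an input table does not match the expected layout."""


def read_peptide_evidence(path: str | Path) -> list[PeptideEvidence]:
    """Read a peptide-evidence TSV into a list of :class:`PeptideEvidence`.

    Rows with non-positive intensity are rejected and counted in a log
    message; they are never silently dropped.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in EVIDENCE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")

    records: list[PeptideEvidence] = []
    n_rejected = 0
    for pos, row in enumerate(df.itertuples(index=False)):
        line_no = pos + 2  # header is line 1
        try:
            run_index = int(row.run_index)
            mz = float(row.mz)
            elution_time = float(row.elution_time)
            intensity = float(row.intensity)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}, line {line_no}: non-numeric cell ({exc})") from exc
        if not intensity > 0:
            n_rejected += 1
            continue
        records.append(
            PeptideEvidence(
                peptide_id=str(row.peptide_id),
                protein_id=str(row.protein_id),
                run_index=run_index,
                mz=mz,
                elution_time=elution_time,
                intensity=intensity,
                is_specific=_parse_bool(row.is_specific),
            )
        )
    if n_rejected:
        logger.warning(
            "%s: rejected %d row(s) with non-positive intensity", path, n_rejected
        )
    return records


def _parse_bool(value: object) -> bool:
    s = str(value).strip().lower()
    if s in {"1", "true", "yes", "y"}:
        return True
    if s in {"0", "false", "no", "n"}:
        return False
    raise FormatError(f"cannot interpret '{value}' as a boolean is_specific flag")


def write_peptide_evidence(
    evidence: Sequence[PeptideEvidence], path: str | Path
) -> None:
    """Write evidence records to TSV in the canonical column order."""
    df = pd.DataFrame(
        {
            "peptide_id": [e.peptide_id for e in evidence],
            "protein_id": [e.protein_id for e in evidence],
            "run_index": [e.run_index for e in evidence],
            "mz": [e.mz for e in evidence],
            "elution_time": [e.elution_time for e in evidence],
            "intensity": [e.intensity for e in evidence],
            "is_specific": [int(e.is_specific) for e in evidence],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def _slice_columns(prefix: str, n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def read_profile_table(path: str | Path) -> ProfileSet:
    """Read a profile TSV into a :class:`ProfileSet`.

    The number of slices is inferred from the abundance columns; if no
    reliability columns are present, reliability defaults to 1.0 everywhere.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: ragged row ({exc})") from exc
    if "protein_id" not in df.columns:
        raise FormatError(f"{path}: missing required column 'protein_id'")
    s_cols = [c for c in df.columns if c.startswith("S") and c[1:].isdigit()]
    r_cols = [c for c in df.columns if c.startswith("R") and c[1:].isdigit()]
    if not s_cols:
        raise FormatError(f"{path}: no abundance columns (S001..) found")
    s_cols.sort(key=lambda c: int(c[1:]))
    r_cols.sort(key=lambda c: int(c[1:]))

    abundance = df[s_cols].to_numpy(dtype=float)
    if np.any(np.isnan(abundance)):
        i, j = np.argwhere(np.isnan(abundance))[0]
        raise FormatError(
            f"{path}: missing/ragged value for row '{df['protein_id'].iloc[i]}', "
            f"column {s_cols[j]}"
        )
    if np.any(abundance < 0):
        i, j = np.argwhere(abundance < 0)[0]
        raise FormatError(
            f"{path}: negative abundance for row '{df['protein_id'].iloc[i]}', "
            f"column {s_cols[j]}"
        )
    reliability = None
    if r_cols:
        if len(r_cols) != len(s_cols):
            raise FormatError(
                f"{path}: {len(r_cols)} reliability columns for {len(s_cols)} "
                "abundance columns"
            )
        reliability = df[r_cols].to_numpy(dtype=float)
    extra = [c for c in df.columns if c not in s_cols and c not in r_cols and c != "protein_id"]
    annotations = df.set_index("protein_id")[extra] if extra else None
    return ProfileSet(
        df["protein_id"].astype(str).tolist(), abundance, reliability, annotations
    )


def write_profile_table(
    profiles: ProfileSet, path: str | Path, write_reliability: bool = True
) -> None:
    """Write a :class:`ProfileSet` as TSV; round-trips to 6+ significant digits."""
    n = profiles.n_slices
    data: dict[str, object] = {"protein_id": profiles.protein_ids}
    for j, col in enumerate(_slice_columns("S", n)):
        data[col] = profiles.abundance[:, j]
    if write_reliability:
        for j, col in enumerate(_slice_columns("R", n)):
            data[col] = profiles.reliability[:, j]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.9g")
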