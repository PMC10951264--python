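"""Serialization: long-format CSV, nested JSON, and the angle-bracket notation.

The canonical interchange format is a long CSV with one row per cell and
header ``source,alternative,criterion,mu_lo,mu_hi,nu_lo,nu_hi``.  A nested
JSON mirror (source -> alternative -> criterion -> 4 bounds) is also
supported.  Numbers are written with 9 significant digits.  A small parser
for the ``<[0.1, 0.3], [0.4, 0.5]>`` table notation is provided for fixture
transcription and CLI input.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import pandas as pd

from .core import ValidationError
from .matrix import BOUND_FIELDS, FuzzyDecisionMatrix

__all__ = [
    "read_matrices",
    "write_matrices",
    "matrices_from_frame",
    "matrices_to_frame",
    "parse_angle_bracket",
    "format_angle_bracket",
]

_CSV_COLUMNS = ["source", "alternative", "criterion", *BOUND_FIELDS]

_ANGLE_RE = re.compile(
    r"<\s*[\[(]\s*([\d.eE+-]+)\s*,\s*([\d.eE+-]+)\s*[\])]\s*,"
    r"\s*[\[(]\s*([\d.eE+-]+)\s*,\s*([\d.eE+-]+)\s*[\])]\s*>"
)


def parse_angle_bracket(text: str) -> tuple[float, float, float, float]:
    """Parse ``<[mu_lo, mu_hi], [nu_lo, nu_hi]>`` (round brackets also accepted)."""
    m = _ANGLE_RE.fullmatch(text.strip())
    if m is None:
        raise ValidationError(f"cannot parse fuzzy cell {text!r}")
    return tuple(float(g) for g in m.groups())


def format_angle_bracket(bounds) -> str:
    mu_lo, mu_hi, nu_lo, nu_hi = bounds
    return f"<[{mu_lo:.9g}, {mu_hi:.9g}], [{nu_lo:.9g}, {nu_hi:.9g}]>"


def matrices_from_frame(frame: pd.DataFrame, q: int = 2) -> list[FuzzyDecisionMatrix]:
    """Group a long-format frame by source into validated matrices.

    Label order follows first appearance in the frame.  Missing or duplicate
    cells raise with (source, alternative, criterion) coordinates.
    """
    missing_cols = [c for c in _CSV_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise ValidationError(f"missing columns {missing_cols}")
    alternatives = tuple(dict.fromkeys(frame["alternative"]))
    criteria = tuple(dict.fromkeys(frame["criterion"]))
    matrices = []
    for source, group in frame.groupby("source", sort=False):
        dup = group.duplicated(["alternative", "criterion"])
        if dup.any():
            row = group[dup].iloc[0]
            raise ValidationError(
                f"duplicate cell ({source}, {row['alternative']}, {row['criterion']})"
            )
        cells = {
            (row["alternative"], row["criterion"]): tuple(row[f] for f in BOUND_FIELDS)
            for _, row in group.iterrows()
        }
        matrices.append(
            FuzzyDecisionMatrix.from_cells(cells, alternatives, criteria, q=q,
                                           source_id=str(source))
        )
    return matrices


def matrices_to_frame(matrices: list[FuzzyDecisionMatrix]) -> pd.DataFrame:
    return pd.concat([m.to_frame() for m in matrices], ignore_index=True)


def read_matrices(path: str | Path, format: str | None = None, q: int = 2) -> list[FuzzyDecisionMatrix]:
    """Read matrices from long CSV or nested JSON (inferred from the suffix)."""
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "csv":
        frame = pd.read_csv(path)
        return matrices_from_frame(frame, q=q)
    if fmt == "json":
        payload = json.loads(path.read_text())
        q = payload.get("q", q)
        rows = []
        for source, alts in payload["sources"].items():
            for alt, crits in alts.items():
                for crit, bounds in crits.items():
                    rows.append((source, alt, crit, *bounds))
        frame = pd.DataFrame(rows, columns=_CSV_COLUMNS)
        return matrices_from_frame(frame, q=q)
    raise ValueError(f"unknown format {fmt!r}")


def write_matrices(
    matrices: list[FuzzyDecisionMatrix], path: str | Path, format: str | None = None
) -> None:
    """Write matrices as long CSV or nested JSON with 9 significant digits."""
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "csv":
        frame = matrices_to_frame(matrices)
        frame.to_csv(path, index=False, float_format="%.9g")
        return
    if fmt == "json":
        payload = {"q": matrices[0].q, "sources": {}}
        for m in matrices:
            payload["sources"][m.source_id] = {
                alt: {
                    crit: [round(float(b), 9) for b in m.values[i, j]]
                    for j, crit in enumerate(m.criteria)
                }
                for i, alt in enumerate(m.alternatives)
            }
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return
    raise ValueError(f"unknown format {fmt!r}")
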