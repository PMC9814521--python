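"""Reading and writing cohort files.

Abundance files are delimited text (comma for ``.csv``, tab for ``.tsv``/
``.txt``) with a leading ``sample_id`` column and one column per protein;
empty cells mean missing.  Clinical tables are CSV with the cohort columns as
named headers, and the ground truth is a two-column CSV kept in a separate
file so pipeline stages can be run blinded to it.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .cohort import AbundanceMatrix, GroundTruth, validate_cohort
from .errors import ParseError

__all__ = [
    "read_abundance",
    "write_abundance",
    "read_clinical",
    "write_clinical",
    "read_truth",
    "write_truth",
    "write_cohort",
    "read_cohort",
]

_TRIMESTERS = ("T2", "T3")


def _sep_for(path: str) -> str:
    return "\t" if str(path).lower().endswith((".tsv", ".txt")) else ","


def write_abundance(matrix: AbundanceMatrix, path: str) -> str:
    # %.17g guarantees float64 round-trips to stored precision
    matrix.to_frame().to_csv(path, sep=_sep_for(path), float_format="%.17g")
    return str(path)


def read_abundance(path: str, trimester: str) -> AbundanceMatrix:
    """Parse an abundance file, validating that every cell is numeric or empty."""
    try:
        raw = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed delimited text
        raise ParseError(f"{path}: cannot parse delimited text ({exc})") from exc
    if raw.shape[1] < 2 or raw.columns[0] != "sample_id":
        raise ParseError(f"{path}: first column must be 'sample_id'")
    sample_ids = raw["sample_id"].tolist()
    protein_ids = list(raw.columns[1:])
    values = np.empty((len(sample_ids), len(protein_ids)))
    for j, col in enumerate(protein_ids):
        # float() is correctly rounded, so stored values round-trip exactly
        for i, cell in enumerate(raw[col].str.strip()):
            if cell == "":
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric intensity {cell!r} at "
                    f"row {i + 2} (sample {sample_ids[i]!r}), column {col!r}"
                ) from None
    return AbundanceMatrix(
        sample_ids=sample_ids, protein_ids=protein_ids, values=values,
        trimester=trimester,
    )


def write_clinical(cohort: pd.DataFrame, path: str) -> str:
    cohort.to_csv(path, index=False)
    return str(path)


def read_clinical(path: str) -> pd.DataFrame:
    cohort = pd.read_csv(path)
    validate_cohort(cohort, source=str(path))
    cohort["previa_at_delivery"] = cohort["previa_at_delivery"].astype(bool)
    cohort["ultrasound_detected"] = cohort["ultrasound_detected"].astype(bool)
    return cohort


def write_truth(truth: GroundTruth, path: str) -> str:
    truth.to_frame().to_csv(path, index=False)
    return str(path)


def read_truth(path: str) -> GroundTruth:
    df = pd.read_csv(path)
    for col in ("protein_id", "effect_size"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column '{col}'")
    return GroundTruth(
        planted_protein_ids=tuple(df["protein_id"].astype(str)),
        effect_sizes=dict(zip(df["protein_id"].astype(str), df["effect_size"])),
    )


def write_cohort(matrices, cohort, truth, directory) -> dict[str, str]:
    """Write a full simulated cohort; returns the paths written, keyed by role."""
    os.makedirs(directory, exist_ok=True)
    paths = {}
    for t, matrix in matrices.items():
        paths[f"abundance_{t}"] = write_abundance(
            matrix, os.path.join(directory, f"abundance_{t}.csv")
        )
    paths["clinical"] = write_clinical(cohort, os.path.join(directory, "clinical.csv"))
    paths["ground_truth"] = write_truth(
        truth, os.path.join(directory, "ground_truth.csv")
    )
    return paths


def read_cohort(directory):
    """Inverse of :func:`write_cohort`; round-trips values to stored precision."""
    matrices = {
        t: read_abundance(os.path.join(directory, f"abundance_{t}.csv"), trimester=t)
        for t in _TRIMESTERS
        if os.path.exists(os.path.join(directory, f"abundance_{t}.csv"))
    }
    if not matrices:
        raise ParseError(f"{directory}: no abundance_T*.csv files found")
    cohort = read_clinical(os.path.join(directory, "clinical.csv"))
    truth = read_truth(os.path.join(directory, "ground_truth.csv"))
    return matrices, cohort, truth
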