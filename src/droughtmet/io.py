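"""Readers and writers for abundance matrices and sample metadata tables.

Both tables are plain delimited text (TSV or CSV, chosen by file extension).
The abundance matrix has metabolite ids in the first column and one column
per sample; missing cells are written as ``NA`` and read from either ``NA``
or an empty field. Metadata requires the columns ``sample_id, genotype,
tissue, regime, day, replicate, fresh_weight_mg`` (``batch`` optional).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .datamodel import AbundanceMatrix, SampleMeta, check_unique_design, meta_to_frame

NA_TOKENS = ("", "NA")
MANDATORY_META_COLUMNS = (
    "sample_id", "genotype", "tissue", "regime", "day", "replicate", "fresh_weight_mg",
)


def _sep_for(path: str) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


@dataclass
class LoadReport:
    """What was reconciled or dropped while loading a matrix/metadata pair."""

    samples_only_in_matrix: List[str] = field(default_factory=list)
    samples_only_in_meta: List[str] = field(default_factory=list)
    not_identified_by_tissue: dict = field(default_factory=dict)


def read_meta(path: str) -> List[SampleMeta]:
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str,
                     na_values=list(NA_TOKENS), keep_default_na=False)
    for col in MANDATORY_META_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{col} required: metadata column missing in {path}")
    meta = []
    for _, row in df.iterrows():
        fw = row["fresh_weight_mg"]
        if pd.isna(fw):
            raise ValueError(
                f"fresh_weight required: missing fresh weight for sample "
                f"{row['sample_id']!r} in {path}"
            )
        batch = row["batch"] if "batch" in df.columns and not pd.isna(row["batch"]) else None
        meta.append(
            SampleMeta(
                sample_id=str(row["sample_id"]),
                genotype=str(row["genotype"]),
                tissue=str(row["tissue"]),
                regime=str(row["regime"]),
                day=int(row["day"]),
                replicate=int(row["replicate"]),
                fresh_weight_mg=float(fw),
                batch=batch,
            )
        )
    check_unique_design(meta)
    return meta


def write_meta(meta: Sequence[SampleMeta], path: str) -> None:
    df = meta_to_frame(meta)
    df.to_csv(path, sep=_sep_for(path), index=False, na_rep="NA", float_format=lambda x: repr(float(x)))


def read_matrix(path: str, state: str = "raw_peak",
                internal_standard_id: Optional[str] = None) -> AbundanceMatrix:
    """Read an abundance matrix, reporting coordinates of unparseable cells."""
    raw = pd.read_csv(path, sep=_sep_for(path), dtype=str, index_col=0,
                      na_values=list(NA_TOKENS), keep_default_na=False)
    values = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    bad: List[str] = []

    def _parse(x):
        # Python float(): correctly-rounded parse, so read(write(v)) == v
        if pd.isna(x):
            return np.nan
        try:
            return float(x)
        except ValueError:
            return None

    for col in raw.columns:
        converted = raw[col].map(_parse)
        invalid = converted.isna() & ~raw[col].isna()
        for met in raw.index[invalid]:
            bad.append(f"(metabolite={met!r}, sample={col!r}, value={raw.loc[met, col]!r})")
        values[col] = converted.astype(float) if not invalid.any() else np.nan
    if bad:
        raise ValueError(f"non-numeric abundance cells in {path}: " + "; ".join(bad))
    values.index.name = raw.index.name or "metabolite_id"
    return AbundanceMatrix(values, state=state, internal_standard_id=internal_standard_id)


def write_matrix(abund: AbundanceMatrix, path: str) -> None:
    df = abund.values.copy()
    if df.index.name is None:
        df.index.name = "metabolite_id"
    # shortest round-trippable float repr so write-then-read is the identity
    df.to_csv(path, sep=_sep_for(path), na_rep="NA", float_format=lambda x: repr(float(x)))


def read_abundance(
    matrix_path: str, meta_path: str, state: str = "raw_peak",
    internal_standard_id: Optional[str] = None,
) -> Tuple[AbundanceMatrix, List[SampleMeta], LoadReport]:
    """Load a matrix + metadata pair and reconcile their sample ids.

    Samples present in only one of the two files are reported in the
    :class:`LoadReport` and dropped from both. The report also flags
    metabolites with no detected value in any sample of a tissue ("not
    identified in that tissue").
    """
    abund = read_matrix(matrix_path, state=state,
                        internal_standard_id=internal_standard_id)
    meta = read_meta(meta_path)

    matrix_ids = set(abund.sample_ids)
    meta_ids = {m.sample_id for m in meta}
    report = LoadReport(
        samples_only_in_matrix=sorted(matrix_ids - meta_ids),
        samples_only_in_meta=sorted(meta_ids - matrix_ids),
    )
    shared = [s for s in abund.sample_ids if s in meta_ids]
    abund = abund.subset_samples(shared)
    meta = [m for m in meta if m.sample_id in matrix_ids]
    report.not_identified_by_tissue = abund.not_identified_by_tissue(meta)
    return abund, meta, report
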