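"""Core data structures for a multifactorial drought metabolomics experiment.

The experimental design has four crossed factors: time (days 0..6), watering
regime (a well-watered control series and a water-withholding series, sharing
a single pre-treatment "basal" point at day 0), genotype, and tissue (shoot /
root), with several biological replicates per cell. Abundances are held as a
metabolites x samples matrix that tracks its processing state (raw peak
areas, internal-standard/fresh-weight normalized, or log-transformed).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

#: Genotypes of the emulated study: wild type, a line overexpressing the
#: vascular brassinosteroid receptor BRL3, and a quadruple mutant lacking
#: all BR receptors plus the co-receptor BAK1.
GENOTYPES = ("WT", "BRL3ox", "quad")
TISSUES = ("shoot", "root")
REGIMES = ("basal", "watered", "drought")

#: Processing states of an abundance matrix.
STATES = ("raw_peak", "normalized", "log")


@dataclass(frozen=True)
class SampleMeta:
    """Design coordinates and fresh weight of one physical sample.

    ``regime == "basal"`` if and only if ``day == 0``: day 0 is sampled once
    before water is withheld and serves as the shared origin of both the
    watered and the drought series.

    ``fresh_weight_mg`` may be ``None`` for purely combinatorial enumeration
    (no physical sample yet); it must be positive when present and is
    required for normalization.
    """

    sample_id: str
    genotype: str
    tissue: str
    regime: str
    day: int
    replicate: int
    fresh_weight_mg: Optional[float] = None
    batch: Optional[str] = None

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r}; expected one of {TISSUES}")
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}; expected one of {REGIMES}")
        if (self.regime == "basal") != (self.day == 0):
            raise ValueError(
                f"sample {self.sample_id}: regime 'basal' is the day-0 pre-treatment "
                f"point (got regime={self.regime!r}, day={self.day})"
            )
        if self.day < 0:
            raise ValueError(f"sample {self.sample_id}: day must be >= 0")
        if self.replicate < 1:
            raise ValueError(f"sample {self.sample_id}: replicate must be >= 1")
        if self.fresh_weight_mg is not None and not self.fresh_weight_mg > 0:
            raise ValueError(
                f"sample {self.sample_id}: fresh_weight_mg must be > 0, "
                f"got {self.fresh_weight_mg}"
            )

    @property
    def design_key(self) -> tuple:
        return (self.genotype, self.tissue, self.regime, self.day, self.replicate)


def check_unique_design(meta: Sequence[SampleMeta]) -> None:
    """Raise if two samples share (genotype, tissue, regime, day, replicate)."""
    seen: dict = {}
    for m in meta:
        if m.design_key in seen:
            raise ValueError(
                f"duplicate design coordinates {m.design_key} for samples "
                f"{seen[m.design_key]!r} and {m.sample_id!r}"
            )
        seen[m.design_key] = m.sample_id


def meta_to_frame(meta: Sequence[SampleMeta]) -> pd.DataFrame:
    """Tabular view of a sample metadata list, indexed by sample id."""
    df = pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in meta],
            "genotype": [m.genotype for m in meta],
            "tissue": [m.tissue for m in meta],
            "regime": [m.regime for m in meta],
            "day": [m.day for m in meta],
            "replicate": [m.replicate for m in meta],
            "fresh_weight_mg": [m.fresh_weight_mg for m in meta],
            "batch": [m.batch for m in meta],
        }
    )
    return df.set_index("sample_id", drop=False)


@dataclass
class AbundanceMatrix:
    """Metabolites x samples abundance matrix with a processing-state flag.

    ``values`` is a pandas DataFrame with metabolite ids on the index and
    sample ids on the columns; NaN marks a missing (not detected) cell and is
    never silently imputed. Raw peak areas and normalized abundances must be
    non-negative; log-transformed values may have any sign.
    """

    values: pd.DataFrame
    state: str = "raw_peak"
    internal_standard_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}; expected one of {STATES}")
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate metabolite ids: {dup}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dup}")
        self.values = self.values.astype(float)
        if self.state in ("raw_peak", "normalized"):
            vals = self.values.to_numpy()
            if np.any(vals[~np.isnan(vals)] < 0):
                raise ValueError(f"negative values not allowed in state {self.state!r}")

    @property
    def metabolite_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(
            self.values.copy(), state=self.state,
            internal_standard_id=self.internal_standard_id,
        )

    def subset_samples(self, sample_ids: Iterable[str]) -> "AbundanceMatrix":
        ids = [s for s in sample_ids]
        missing = set(ids) - set(self.values.columns)
        if missing:
            raise KeyError(f"samples not in matrix: {sorted(missing)}")
        return AbundanceMatrix(
            self.values[ids].copy(), state=self.state,
            internal_standard_id=self.internal_standard_id,
        )

    def not_identified_by_tissue(self, meta: Sequence[SampleMeta]) -> dict:
        """Metabolites that are missing in every sample of a tissue.

        A compound with no detected peak in any sample of a tissue was not
        identified in that tissue; downstream analyses must treat it as
        absent there rather than as zero.
        """
        out: dict = {}
        mdf = meta_to_frame(meta)
        for tissue in sorted(set(mdf["tissue"])):
            cols = [s for s in self.values.columns if s in mdf.index and mdf.loc[s, "tissue"] == tissue]
            if not cols:
                continue
            all_na = self.values[cols].isna().all(axis=1)
            out[tissue] = sorted(self.values.index[all_na])
        return out


def enumerate_design(
    genotypes: Iterable[str] = GENOTYPES,
    tissues: Iterable[str] = TISSUES,
    regimes: Iterable[str] = REGIMES,
    days: Iterable[int] = range(0, 7),
    replicates: Iterable[int] = range(1, 6),
) -> list:
    """Enumerate one :class:`SampleMeta` per cell of the factorial design.

    Day 0 ("basal") is emitted once per (genotype, tissue, replicate); each
    treatment series (watered / drought) covers the days >= 1 in ``days``.
    The full study design -- 3 genotypes x 2 tissues x 5 replicates x
    (1 basal + 6 watered + 6 drought days) -- yields 390 samples.

    Raises ``ValueError`` on empty factor sets, duplicated replicate ids, or
    a basal request without day 0.
    """
    genotypes = list(genotypes)
    tissues = list(tissues)
    regimes = list(regimes)
    days = sorted(set(int(d) for d in days))
    replicates = list(replicates)

    for name, vals in (
        ("genotypes", genotypes), ("tissues", tissues),
        ("regimes", regimes), ("days", days), ("replicates", replicates),
    ):
        if not vals:
            raise ValueError(f"empty factor set: {name}")
    if len(set(replicates)) != len(replicates):
        raise ValueError("duplicate replicate ids")
    unknown = set(regimes) - set(REGIMES)
    if unknown:
        raise ValueError(f"unknown regimes: {sorted(unknown)}")
    if "basal" in regimes and 0 not in days:
        raise ValueError("basal regime requested but day 0 not in days")

    series_days = [d for d in days if d >= 1]
    out = []
    for g, t, r in itertools.product(genotypes, tissues, replicates):
        if "basal" in regimes:
            out.append(SampleMeta(f"{g}_{t}_basal_d0_r{r}", g, t, "basal", 0, r))
        for regime in regimes:
            if regime == "basal":
                continue
            for d in series_days:
                out.append(SampleMeta(f"{g}_{t}_{regime}_d{d}_r{r}", g, t, regime, d, r))
    check_unique_design(out)
    return out
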