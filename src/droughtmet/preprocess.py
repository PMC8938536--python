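"""Normalization and quality control of raw GC-MS peak-area matrices.

The two-step normalization divides each peak area first by the sample's
internal-standard (ribitol) peak and then by the sample's fresh weight,
yielding abundance per mg fresh weight and cancelling per-sample
extraction/detector gain exactly. Matrices are then log-transformed, and
samples whose per-sample log-median falls outside the first/third quartile
of all pooled log values are flagged as artifacts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .datamodel import AbundanceMatrix, SampleMeta, meta_to_frame

LOG_BASES = {"e": math.e, "10": 10.0, "2": 2.0}


def normalize(
    peaks: AbundanceMatrix,
    meta: Sequence[SampleMeta],
    standard_id: Optional[str] = None,
) -> AbundanceMatrix:
    """Internal-standard then fresh-weight normalization.

    value'[m, s] = value[m, s] / value[standard, s] / fresh_weight[s].

    The standard row is consumed (removed from the output). Missing cells
    stay missing. Raises if the standard peak is missing or non-positive in
    any sample, or a fresh weight is unknown.
    """
    if peaks.state != "raw_peak":
        raise ValueError(f"normalize expects raw peak areas, got state {peaks.state!r}")
    standard_id = standard_id or peaks.internal_standard_id
    if standard_id is None:
        raise ValueError("no internal standard id given")
    if standard_id not in peaks.values.index:
        raise ValueError(f"internal standard row {standard_id!r} not in matrix")

    std = peaks.values.loc[standard_id]
    bad = [s for s in peaks.sample_ids if not std[s] > 0]  # catches NaN too
    if bad:
        raise ValueError(
            f"internal standard {standard_id!r} missing or non-positive in samples: {bad}"
        )
    fw: Dict[str, float] = {}
    for m in meta:
        if m.fresh_weight_mg is None:
            raise ValueError(f"fresh weight unknown for sample {m.sample_id!r}")
        fw[m.sample_id] = m.fresh_weight_mg
    missing_fw = [s for s in peaks.sample_ids if s not in fw]
    if missing_fw:
        raise ValueError(f"no metadata/fresh weight for samples: {missing_fw}")

    fw_series = pd.Series({s: fw[s] for s in peaks.sample_ids})
    out = peaks.values.drop(index=standard_id).div(std, axis=1).div(fw_series, axis=1)
    return AbundanceMatrix(out, state="normalized", internal_standard_id=None)


def log_transform(abund: AbundanceMatrix, base: str = "e") -> AbundanceMatrix:
    """Element-wise logarithm (base e, 10 or 2); missing values preserved.

    Zero or negative values are an error listing the offending cells -- no
    pseudo-count is ever added silently.
    """
    if abund.state != "normalized":
        raise ValueError(f"log_transform expects a normalized matrix, got {abund.state!r}")
    if base not in LOG_BASES:
        raise ValueError(f"base must be one of {sorted(LOG_BASES)}, got {base!r}")
    vals = abund.values.to_numpy()
    nonpos = (~np.isnan(vals)) & (vals <= 0)
    if nonpos.any():
        rows, cols = np.nonzero(nonpos)
        cells = [
            f"(metabolite={abund.values.index[i]!r}, sample={abund.values.columns[j]!r})"
            for i, j in zip(rows[:20], cols[:20])
        ]
        raise ValueError(
            f"{nonpos.sum()} non-positive values cannot be log-transformed: "
            + "; ".join(cells)
        )
    out = np.log(abund.values) / math.log(LOG_BASES[base])
    return AbundanceMatrix(out, state="log")


def flag_direction(log_median: float, q1: float, q3: float) -> Optional[str]:
    """Classify one sample's log-median against the pooled quartiles.

    Strict inequalities: a median exactly at Q1 or Q3 is kept.
    """
    if log_median > q3:
        return "above_q3"
    if log_median < q1:
        return "below_q1"
    return None


@dataclass
class OutlierReport:
    """Quantile outlier screen of a log-transformed matrix.

    ``dataset_median``/``q1``/``q3`` are computed over all pooled non-missing
    log values; ``per_sample_median`` over each sample's own values. A sample
    is flagged when its median is strictly above Q3 or strictly below Q1.
    """

    per_sample_median: pd.Series
    dataset_median: float
    dataset_q1: float
    dataset_q3: float
    flagged: Dict[str, str] = field(default_factory=dict)

    @property
    def flagged_ids(self) -> List[str]:
        return sorted(self.flagged)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"log_median": self.per_sample_median})
        df["flag"] = [self.flagged.get(s, "") for s in df.index]
        df.index.name = "sample_id"
        return df


def flag_outlier_samples(logged: AbundanceMatrix) -> OutlierReport:
    """Flag samples whose log-median lies outside the pooled Q1..Q3 band.

    Quartiles use linear interpolation between order statistics and are
    pooled over the whole dataset (all tissues together).
    """
    if logged.state != "log":
        raise ValueError(f"outlier screen expects a log matrix, got {logged.state!r}")
    if logged.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    empty = [s for s in logged.sample_ids if logged.values[s].isna().all()]
    if empty:
        raise ValueError(f"samples with no non-missing values: {empty}")

    pooled = logged.values.to_numpy().ravel()
    pooled = pooled[~np.isnan(pooled)]
    q1, med, q3 = np.quantile(pooled, [0.25, 0.5, 0.75])
    per_sample = logged.values.median(axis=0, skipna=True)
    flagged = {}
    for s, m in per_sample.items():
        direction = flag_direction(m, q1, q3)
        if direction is not None:
            flagged[s] = direction
    return OutlierReport(per_sample, float(med), float(q1), float(q3), flagged)


def drop_samples(
    abund: AbundanceMatrix, meta: Sequence[SampleMeta], sample_ids: Sequence[str]
) -> Tuple[AbundanceMatrix, List[SampleMeta], dict]:
    """Remove samples (e.g. flagged outliers) from matrix and metadata.

    Returns the filtered pair plus the recomputed not-identified-by-tissue
    report, so a metabolite losing its last observation in a tissue is
    surfaced rather than silently kept as an all-missing row.
    """
    drop = set(sample_ids)
    kept_meta = [m for m in meta if m.sample_id not in drop]
    kept = abund.subset_samples([s for s in abund.sample_ids if s not in drop])
    return kept, kept_meta, kept.not_identified_by_tissue(kept_meta)


def pca_scores(
    matrix: AbundanceMatrix, n_components: int = 2
) -> Tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on centered, unit-variance metabolite columns.

    Metabolites with any missing value are excluded listwise; zero-variance
    metabolites are excluded with a warning (they cannot be unit-scaled).
    Returns (samples x components score frame, explained-variance fractions).
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples for PCA")
    complete = matrix.values.dropna(axis=0)
    var = complete.var(axis=1, ddof=1)
    zero_var = list(complete.index[var == 0])
    if zero_var:
        warnings.warn(f"excluding zero-variance metabolites from PCA: {zero_var}")
        complete = complete.drop(index=zero_var)
    if complete.shape[0] < 2:
        raise ValueError("fewer than 2 metabolites remain after exclusions")

    X = complete.to_numpy().T  # samples x metabolites
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    n_components = min(n_components, *X.shape)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    frame = pd.DataFrame(
        scores, index=matrix.sample_ids,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    frame.index.name = "sample_id"
    return frame, pca.explained_variance_ratio_
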