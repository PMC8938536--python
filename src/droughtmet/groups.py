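"""Pairwise group comparisons and paired shoot-to-root ratio analysis.

Comparisons use two-sided pooled-variance Student's t-tests per metabolite,
screened at a raw-p threshold (default alpha = 0.025); Benjamini-Hochberg
adjusted q-values are reported alongside for transparency but play no role
in the default screen. Fold-changes are computed relative to the reference
group's median, matching how priming effects are usually displayed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import AbundanceMatrix, SampleMeta, meta_to_frame


def _apply_filter(mdf: pd.DataFrame, at: Optional[dict]) -> pd.DataFrame:
    if at:
        for col, val in at.items():
            if col not in mdf.columns:
                raise KeyError(f"unknown design factor {col!r}")
            mdf = mdf[mdf[col] == val]
    return mdf


@dataclass
class ComparisonResult:
    """Per-metabolite t-test table for one two-group contrast."""

    table: pd.DataFrame  # columns: n_a, n_b, log_fc, t, p, q, significant
    factor: str
    level_a: str
    level_b: str
    alpha: float
    skipped: List[str] = field(default_factory=list)

    @property
    def significant_ids(self) -> List[str]:
        return sorted(self.table.index[self.table["significant"]])


def _pooled_t(a: np.ndarray, b: np.ndarray) -> Tuple[float, float]:
    """Two-sided pooled-variance Student's t.

    Zero variance in both groups: equal means give (0, 1) by convention,
    unequal means an infinite statistic and p = 0.
    """
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, b.mean() - a.mean()), 0.0
    t, p = stats.ttest_ind(b, a, equal_var=True)
    return float(t), float(p)


def compare_groups(
    abund: AbundanceMatrix,
    meta: Sequence[SampleMeta],
    factor: str,
    level_a: str,
    level_b: str,
    at: Optional[dict] = None,
    alpha: float = 0.025,
) -> ComparisonResult:
    """Per-metabolite Student's t-test between two levels of a design factor.

    ``at`` fixes the other factors, e.g. ``{"tissue": "root", "day": 0}`` for
    a basal-conditions genotype contrast. The log fold-change is
    log(median_b / median_a) on the normalized scale (level_a is the
    reference), or the median difference if the matrix is already in log
    state. Metabolites with fewer than 2 non-missing values in either group
    are skipped and reported, never tested.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    mdf = _apply_filter(meta_to_frame(meta), at)
    if factor not in mdf.columns:
        raise KeyError(f"unknown design factor {factor!r}")
    ids_a = [s for s in mdf.index[mdf[factor] == level_a] if s in abund.values.columns]
    ids_b = [s for s in mdf.index[mdf[factor] == level_b] if s in abund.values.columns]
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValueError(
            f"need >= 2 samples per group, got {len(ids_a)} ({level_a}) "
            f"and {len(ids_b)} ({level_b})"
        )

    rows, skipped = {}, []
    for met in abund.metabolite_ids:
        a = abund.values.loc[met, ids_a].dropna().to_numpy(float)
        b = abund.values.loc[met, ids_b].dropna().to_numpy(float)
        if len(a) < 2 or len(b) < 2:
            skipped.append(met)
            continue
        t, p = _pooled_t(a, b)
        med_a, med_b = np.median(a), np.median(b)
        if abund.state == "log":
            log_fc = med_b - med_a
        else:
            log_fc = math.log(med_b / med_a) if med_a > 0 and med_b > 0 else math.nan
        rows[met] = {"n_a": len(a), "n_b": len(b), "log_fc": log_fc, "t": t, "p": p}

    table = pd.DataFrame.from_dict(rows, orient="index")
    if len(table):
        table["q"] = multipletests(table["p"], method="fdr_bh")[1]
        table["significant"] = table["p"] < alpha
    else:
        table = pd.DataFrame(
            columns=["n_a", "n_b", "log_fc", "t", "p", "q", "significant"]
        )
    table.index.name = "metabolite_id"
    return ComparisonResult(table, factor, level_a, level_b, alpha, skipped)


@dataclass
class RatioMatrix:
    """Shoot/root log-ratios over paired replicates.

    Columns are pairing keys ``genotype_regime_dD_rR`` for replicates where
    BOTH tissues survived QC; pairs lacking one tissue are listed in
    ``dropped_pairs`` (if a shoot sample was discarded as an outlier, its
    root counterpart is unusable for the ratio and vice versa).
    """

    log_ratios: pd.DataFrame
    pair_keys: List[tuple]
    dropped_pairs: List[tuple] = field(default_factory=list)
    n_zero_denominator: int = 0


def shoot_root_ratios(
    abund: AbundanceMatrix, meta: Sequence[SampleMeta]
) -> RatioMatrix:
    """Paired shoot-to-root partitioning variable.

    ratio[m, pair] = log(shoot / root) (natural log on the normalized scale,
    difference if the matrix is in log state). Pairing is by (genotype,
    regime, day, replicate). Metabolites not identified in one tissue and
    zero root values yield missing ratios; the latter are counted and warned
    about.
    """
    if abund.state == "raw_peak":
        raise ValueError("ratios require a normalized or log matrix")
    by_key: Dict[tuple, Dict[str, str]] = {}
    for m in meta:
        if m.sample_id not in abund.values.columns:
            continue
        key = (m.genotype, m.regime, m.day, m.replicate)
        by_key.setdefault(key, {})[m.tissue] = m.sample_id

    pair_keys, dropped = [], []
    columns = {}
    n_zero = 0
    for key in sorted(by_key, key=lambda k: (k[0], k[1], k[2], k[3])):
        tissues = by_key[key]
        if "shoot" in tissues and "root" in tissues:
            shoot = abund.values[tissues["shoot"]]
            root = abund.values[tissues["root"]]
            if abund.state == "log":
                ratio = shoot - root
            else:
                with np.errstate(divide="ignore", invalid="ignore"):
                    ratio = np.log(shoot / root)
                zero_root = (root == 0) & shoot.notna()
                n_zero += int(zero_root.sum())
                ratio[zero_root | (root == 0)] = np.nan
                ratio[shoot.isna() | root.isna()] = np.nan
            g, regime, day, rep = key
            columns[f"{g}_{regime}_d{day}_r{rep}"] = ratio
            pair_keys.append(key)
        else:
            dropped.append(key)
    if n_zero:
        warnings.warn(f"{n_zero} ratios undefined (zero root value), set to missing")
    log_ratios = pd.DataFrame(columns, index=abund.values.index)
    log_ratios.index.name = "metabolite_id"
    return RatioMatrix(log_ratios, pair_keys, dropped, n_zero)


def compare_ratio_groups(
    ratios: RatioMatrix,
    factor_index: int,
    level_a: str,
    level_b: str,
    at: Optional[dict] = None,
    alpha: float = 0.025,
) -> ComparisonResult:
    """t-test on shoot/root log-ratios between two levels of a pairing factor.

    ``factor_index`` selects the pairing-key component (0 genotype, 1 regime,
    2 day, 3 replicate); ``at`` may fix others by index, e.g. ``{2: 6}`` to
    compare regimes after six days.
    """
    factor_names = {0: "genotype", 1: "regime", 2: "day", 3: "replicate"}
    keep_a, keep_b = [], []
    for key, col in zip(ratios.pair_keys, ratios.log_ratios.columns):
        if at and any(key[i] != v for i, v in at.items()):
            continue
        if key[factor_index] == level_a:
            keep_a.append(col)
        elif key[factor_index] == level_b:
            keep_b.append(col)
    if len(keep_a) < 2 or len(keep_b) < 2:
        raise ValueError(
            f"need >= 2 pairs per group, got {len(keep_a)} and {len(keep_b)}"
        )
    rows, skipped = {}, []
    for met in ratios.log_ratios.index:
        a = ratios.log_ratios.loc[met, keep_a].dropna().to_numpy(float)
        b = ratios.log_ratios.loc[met, keep_b].dropna().to_numpy(float)
        if len(a) < 2 or len(b) < 2:
            skipped.append(met)
            continue
        t, p = _pooled_t(a, b)
        rows[met] = {
            "n_a": len(a), "n_b": len(b),
            "log_fc": float(np.median(b) - np.median(a)), "t": t, "p": p,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    if len(table):
        table["q"] = multipletests(table["p"], method="fdr_bh")[1]
        table["significant"] = table["p"] < alpha
    else:
        table = pd.DataFrame(
            columns=["n_a", "n_b", "log_fc", "t", "p", "q", "significant"]
        )
    table.index.name = "metabolite_id"
    return ComparisonResult(
        table, factor_names.get(factor_index, str(factor_index)),
        str(level_a), str(level_b), alpha, skipped,
    )
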