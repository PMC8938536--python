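"""Differential time-course dynamics via polynomial regression.

For each metabolite, abundance is regressed on a polynomial in drought day
with genotype-specific coefficients,

    y ~ sum_k beta_k day^k  +  sum_g sum_k gamma_{g,k} day^k 1[genotype=g],

day treated as a continuous covariate (k = 0..degree; g over non-reference
genotypes). Two nested F-tests are reported per metabolite: a global test of
any time/genotype structure (full model vs intercept-only) and a
differential test of the genotype x time interaction terms (full model vs a
single shared curve). P-values are Benjamini-Hochberg adjusted across
metabolites; selection combines a q-value threshold with a goodness-of-fit
(R^2) gate so that significant but badly-fitting profiles are not called.

This is a deliberately compact take on the two-step polynomial-regression
idea used for time-course omics screens (global fit, then coefficient
comparison); there is no stepwise variable selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .datamodel import AbundanceMatrix, SampleMeta, meta_to_frame


def _series_samples(
    mdf: pd.DataFrame, series: str, tissue: Optional[str]
) -> pd.DataFrame:
    """Samples of one treatment series (basal day 0 belongs to both)."""
    if series not in ("drought", "watered"):
        raise ValueError("series must be 'drought' or 'watered'")
    keep = mdf[mdf["regime"].isin(["basal", series])]
    if tissue is not None:
        keep = keep[keep["tissue"] == tissue]
    return keep


def _design_matrices(
    days: np.ndarray, genos: np.ndarray, degree: int, reference: str
) -> Tuple[np.ndarray, np.ndarray, List[str]]:
    """(full, reference-only) design matrices and full-model column names."""
    powers = np.vstack([days**k for k in range(degree + 1)]).T  # n x (deg+1)
    cols = [f"day^{k}" for k in range(degree + 1)]
    blocks = [powers]
    for g in sorted(set(genos) - {reference}):
        ind = (genos == g).astype(float)[:, None]
        blocks.append(powers * ind)
        cols += [f"{g}:day^{k}" for k in range(degree + 1)]
    return np.hstack(blocks), powers, cols


def _f_test(rss_r: float, rss_f: float, df_num: int, df_den: int) -> float:
    if df_den <= 0:
        return float("nan")
    if rss_f <= 0:  # perfect fit: any reduction is infinitely significant
        return 0.0 if rss_r > rss_f else 1.0
    f = ((rss_r - rss_f) / df_num) / (rss_f / df_den)
    return float(stats.f.sf(f, df_num, df_den))


@dataclass
class DynamicsFit:
    """Polynomial fit of one metabolite's time course."""

    metabolite_id: str
    coefficients: Dict[str, float]
    p_global: float
    p_differential: float
    r_squared: float
    q_global: float = float("nan")
    q_differential: float = float("nan")


def fit_time_course(
    abund: AbundanceMatrix,
    meta: Sequence[SampleMeta],
    degree: int = 2,
    reference_genotype: str = "WT",
    series: str = "drought",
    tissue: Optional[str] = None,
) -> pd.DataFrame:
    """Fit genotype-specific polynomial curves to each metabolite's series.

    Returns a per-metabolite table with coefficient columns, ``p_global`` /
    ``p_differential`` and their BH-adjusted ``q_`` counterparts, and ``r2``.
    Metabolites with no usable values are recorded in ``df.attrs['skipped']``.
    Requires at least degree + 2 distinct time points in the series.
    """
    mdf = _series_samples(meta_to_frame(meta), series, tissue)
    mdf = mdf[mdf["sample_id"].isin(abund.values.columns)]
    n_days = mdf["day"].nunique()
    if n_days < degree + 2:
        raise ValueError(
            f"need >= degree + 2 = {degree + 2} distinct time points, got {n_days}"
        )
    sample_ids = list(mdf.index)
    days = mdf["day"].to_numpy(float)
    genos = mdf["genotype"].to_numpy()
    if reference_genotype not in set(genos):
        raise ValueError(f"reference genotype {reference_genotype!r} absent from series")

    X_full_all, X_ref_all, colnames = _design_matrices(days, genos, degree, reference_genotype)
    p_full, p_ref = X_full_all.shape[1], X_ref_all.shape[1]

    rows: Dict[str, dict] = {}
    skipped: List[str] = []
    Y = abund.values[sample_ids]
    for met in abund.metabolite_ids:
        y = Y.loc[met].to_numpy(float)
        ok = ~np.isnan(y)
        n = int(ok.sum())
        if n < p_full + 1:
            skipped.append(met)
            continue
        yy = y[ok]
        Xf, Xr = X_full_all[ok], X_ref_all[ok]
        beta_f, *_ = np.linalg.lstsq(Xf, yy, rcond=None)
        rss_f = float(np.sum((yy - Xf @ beta_f) ** 2))
        beta_r, *_ = np.linalg.lstsq(Xr, yy, rcond=None)
        rss_r = float(np.sum((yy - Xr @ beta_r) ** 2))
        tss = float(np.sum((yy - yy.mean()) ** 2))

        p_glob = _f_test(tss, rss_f, p_full - 1, n - p_full)
        p_diff = _f_test(rss_r, rss_f, p_full - p_ref, n - p_full)
        r2 = 1.0 - rss_f / tss if tss > 0 else 0.0
        row = {name: b for name, b in zip(colnames, beta_f)}
        row.update({"p_global": p_glob, "p_differential": p_diff, "r2": r2, "n": n})
        rows[met] = row

    fits = pd.DataFrame.from_dict(rows, orient="index")
    if len(fits):
        fits["q_global"] = multipletests(fits["p_global"].fillna(1.0), method="fdr_bh")[1]
        fits["q_differential"] = multipletests(
            fits["p_differential"].fillna(1.0), method="fdr_bh"
        )[1]
    else:
        fits = pd.DataFrame(columns=colnames + [
            "p_global", "p_differential", "r2", "n", "q_global", "q_differential",
        ])
    fits.index.name = "metabolite_id"
    fits.attrs["skipped"] = skipped
    fits.attrs["series"] = series
    fits.attrs["degree"] = degree
    fits.attrs["reference_genotype"] = reference_genotype
    return fits


def select_differential(
    fits: pd.DataFrame, q_threshold: float = 0.05, r2_min: float = 0.6
) -> Set[str]:
    """Metabolites with differential-dynamics q below threshold and R^2 gate."""
    if len(fits) == 0:
        return set()
    keep = (fits["q_differential"] < q_threshold) & (fits["r2"] >= r2_min)
    return set(fits.index[keep])


def cluster_profiles(
    abund: AbundanceMatrix,
    meta: Sequence[SampleMeta],
    selected: Sequence[str],
    k: int,
    series: str = "drought",
    tissue: Optional[str] = None,
) -> Dict[str, int]:
    """Cluster selected metabolites by their stereotypical time profile.

    Profiles are per-day medians across replicates (all genotypes pooled),
    standardized per metabolite, and clustered by complete-linkage
    hierarchical clustering on Euclidean distance, cut into ``k`` clusters.
    """
    selected = sorted(set(selected))
    if not 1 <= k <= len(selected):
        raise ValueError(f"need 1 <= k <= |selected| = {len(selected)}, got k={k}")
    mdf = _series_samples(meta_to_frame(meta), series, tissue)
    mdf = mdf[mdf["sample_id"].isin(abund.values.columns)]
    days = sorted(mdf["day"].unique())
    profiles = np.empty((len(selected), len(days)))
    for i, met in enumerate(selected):
        for j, d in enumerate(days):
            cols = list(mdf.index[mdf["day"] == d])
            profiles[i, j] = np.nanmedian(abund.values.loc[met, cols].to_numpy(float))
    sd = profiles.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0  # flat profile stays a zero vector after centering
    z = (profiles - profiles.mean(axis=1, keepdims=True)) / sd[:, None]
    if len(selected) == 1:
        return {selected[0]: 1}
    link = hierarchy.linkage(z, method="complete")
    labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
    return {met: int(lab) for met, lab in zip(selected, labels)}
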