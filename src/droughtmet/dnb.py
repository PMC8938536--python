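"""Dynamical Network Biomarker (DNB) detection for drought time courses.

A critical transition of a dynamical system is preceded by a dominant group
of molecules that (i) sharply increase their average standard deviation
(SDin), (ii) sharply increase their intra-group correlation (mean absolute
Pearson coefficient, PCCin) and (iii) decouple from the remaining molecules
(PCCout). The three signals are merged per cluster and time point into the
composite index

    CI = SDin * PCCin / PCCout,

and the CI maximum along the time course marks the critical point -- an
early-warning signal of the transition (here, drought-stress progression).

Statistics are computed on a day-0-standardized scale: basal samples act as
controls, and each metabolite is z-scored with its reference mean and SD so
that a "drastic increase" in variance is measured relative to the control
state. Metabolite clusters are formed per time point by complete-linkage
hierarchical clustering on the correlation distance 1 - |r| over replicates
at that day, and cluster identities are chained across days by maximal
member overlap to produce CI trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .datamodel import AbundanceMatrix, SampleMeta, meta_to_frame


def compute_ci(sdin: float, pccin: float, pccout: float) -> float:
    """Composite index CI = SDin * PCCin / PCCout.

    Undefined (error) when the member/non-member correlation PCCout is not
    strictly positive.
    """
    if sdin < 0:
        raise ValueError("SDin must be >= 0")
    if not 0 <= pccin <= 1 or not 0 <= pccout <= 1:
        raise ValueError("PCCin and PCCout are mean absolute correlations in [0, 1]")
    if pccout <= 0:
        raise ValueError("undefined composite index: PCCout must be > 0")
    return sdin * pccin / pccout


def standardize_to_reference(
    abund: AbundanceMatrix,
    meta: Sequence[SampleMeta],
    reference: Optional[dict] = None,
) -> Tuple[pd.DataFrame, List[str]]:
    """z-score each metabolite with the mean/SD of a reference condition.

    ``reference`` is a metadata filter, by default ``{"day": 0}`` (basal
    controls). Metabolites whose reference SD is zero (or with fewer than 2
    reference observations) cannot be standardized and are excluded;
    returns (standardized matrix, excluded metabolite ids).
    """
    if abund.state != "log":
        raise ValueError("standardization expects a log-transformed matrix")
    reference = reference if reference is not None else {"day": 0}
    mdf = meta_to_frame(meta)
    mdf_ref = mdf
    for col, val in reference.items():
        mdf_ref = mdf_ref[mdf_ref[col] == val]
    ref_ids = [s for s in mdf_ref.index if s in abund.values.columns]
    if not ref_ids:
        raise ValueError(f"reference filter {reference} matches no samples")

    ref = abund.values[ref_ids]
    n_ref = ref.notna().sum(axis=1)
    mean = ref.mean(axis=1, skipna=True)
    sd = ref.std(axis=1, ddof=1, skipna=True)
    bad = (n_ref < 2) | (sd == 0) | sd.isna()
    excluded = sorted(abund.values.index[bad])
    kept = abund.values.drop(index=excluded)
    z = kept.sub(mean.drop(excluded), axis=0).div(sd.drop(excluded), axis=0)
    return z, excluded


@dataclass
class DNBClusterStats:
    """Composite-index ingredients for one cluster at one time point."""

    day: int
    members: Tuple[str, ...]
    sdin: float
    pccin: float
    pccout: float
    ci: Optional[float]  # None when PCCout == 0 makes CI undefined
    chain_id: int = -1  # trajectory identity across days

    def to_dict(self) -> dict:
        return {
            "day": self.day, "members": list(self.members), "sdin": self.sdin,
            "pccin": self.pccin, "pccout": self.pccout, "ci": self.ci,
            "chain_id": self.chain_id,
        }


@dataclass
class DNBResult:
    """Per-day per-cluster statistics plus the identified critical point."""

    stats: List[DNBClusterStats]
    critical_day: int
    dnb_members: Tuple[str, ...]
    excluded_metabolites: List[str] = field(default_factory=list)

    def trajectory_frame(self) -> pd.DataFrame:
        rows = [s.to_dict() for s in self.stats]
        df = pd.DataFrame(rows)
        df["members"] = df["members"].map(lambda m: ";".join(m))
        return df


def _abs_corr(x: np.ndarray) -> np.ndarray:
    """|Pearson r| between rows; rows with zero variance correlate as 0."""
    sd = x.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    r = np.atleast_2d(r)
    r[np.isnan(r)] = 0.0
    np.fill_diagonal(r, 1.0)
    bad = sd == 0
    r[bad, :] = 0.0
    r[:, bad] = 0.0
    return np.abs(np.clip(r, -1.0, 1.0))


def cluster_day_stats(
    z_day: pd.DataFrame, day: int, k_clusters: int, min_cluster_size: int
) -> List[DNBClusterStats]:
    """Cluster metabolites at one day and score every admissible cluster.

    ``z_day`` is metabolites x replicates on the standardized scale. SDin is
    the mean over members of the replicate SD; PCCin the mean absolute
    pairwise correlation among members; PCCout the mean absolute correlation
    between members and all non-members.
    """
    n_m = z_day.shape[0]
    x = z_day.to_numpy(float)
    absr = _abs_corr(x)
    dist = 1.0 - absr
    np.fill_diagonal(dist, 0.0)
    link = hierarchy.linkage(squareform(dist, checks=False), method="complete")
    labels = hierarchy.fcluster(link, t=min(k_clusters, n_m), criterion="maxclust")

    sds = x.std(axis=1, ddof=1)
    out: List[DNBClusterStats] = []
    for lab in np.unique(labels):
        idx = np.where(labels == lab)[0]
        if len(idx) < min_cluster_size:
            continue
        members = tuple(sorted(z_day.index[idx]))
        sdin = float(sds[idx].mean())
        pair = absr[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        pccin = float(pair[iu].mean())
        rest = np.setdiff1d(np.arange(n_m), idx)
        if len(rest):
            pccout = float(absr[np.ix_(idx, rest)].mean())
        else:
            pccout = 0.0
        ci = sdin * pccin / pccout if pccout > 0 else None
        out.append(DNBClusterStats(day, members, sdin, pccin, pccout, ci))
    return out


def _chain_clusters(per_day: Dict[int, List[DNBClusterStats]]) -> None:
    """Assign chain ids linking clusters across consecutive days by overlap."""
    next_chain = 0
    prev: List[DNBClusterStats] = []
    for day in sorted(per_day):
        current = per_day[day]
        taken = set()
        # best-overlap greedy matching, larger overlaps first
        candidates = []
        for c in current:
            for p in prev:
                ov = len(set(c.members) & set(p.members))
                if ov > 0:
                    candidates.append((ov, p.chain_id, c))
        for ov, chain_id, c in sorted(
            candidates, key=lambda t: (-t[0], t[1], t[2].members)
        ):
            if c.chain_id == -1 and chain_id not in taken:
                c.chain_id = chain_id
                taken.add(chain_id)
        for c in current:
            if c.chain_id == -1:
                c.chain_id = next_chain
                next_chain += 1
        next_chain = max(next_chain, max((c.chain_id for c in current), default=-1) + 1)
        prev = current


def detect_dnb(
    abund: AbundanceMatrix,
    meta: Sequence[SampleMeta],
    genotype: str,
    tissue: str,
    k_clusters: int = 10,
    min_cluster_size: int = 2,
    days: Sequence[int] = (1, 2, 3, 4, 5, 6),
) -> DNBResult:
    """Identify the DNB and critical point for one genotype/tissue series.

    Uses day-0 basal samples as the standardization reference and the
    drought samples of each analyzed day as cases. Requires at least 3
    replicates at every analyzed day (correlations over fewer are
    meaningless). The critical point is the day of the global CI maximum,
    ties broken toward the earliest day (early-warning semantics).
    """
    mdf = meta_to_frame(meta)
    sel = mdf[(mdf["genotype"] == genotype) & (mdf["tissue"] == tissue)]
    sel = sel[sel["sample_id"].isin(abund.values.columns)]
    sub = abund.subset_samples(list(sel.index))
    sub_meta = [m for m in meta if m.sample_id in set(sel.index)]

    z, excluded = standardize_to_reference(sub, sub_meta, reference={"day": 0})

    per_day: Dict[int, List[DNBClusterStats]] = {}
    for day in sorted(days):
        ids = list(sel.index[(sel["regime"] == "drought") & (sel["day"] == day)])
        if len(ids) < 3:
            raise ValueError(
                f"day {day}: {len(ids)} drought replicates, need >= 3 for "
                "stable correlations"
            )
        z_day = z[ids].dropna(axis=0)
        if z_day.shape[0] < min_cluster_size * 2:
            raise ValueError(f"day {day}: too few complete metabolites to cluster")
        per_day[day] = cluster_day_stats(z_day, day, k_clusters, min_cluster_size)

    if all(len(v) == 0 for v in per_day.values()):
        raise ValueError(
            f"no cluster reached min_cluster_size={min_cluster_size} at any day"
        )
    _chain_clusters(per_day)

    stats = [s for day in sorted(per_day) for s in per_day[day]]
    scored = [s for s in stats if s.ci is not None]
    if not scored:
        raise ValueError("composite index undefined for every cluster (PCCout == 0)")
    best = max(scored, key=lambda s: (s.ci, -s.day))
    # earliest day wins on exact ties
    best = min(
        (s for s in scored if s.ci == best.ci), key=lambda s: (s.day, s.members)
    )
    return DNBResult(
        stats=stats, critical_day=best.day, dnb_members=best.members,
        excluded_metabolites=excluded,
    )
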