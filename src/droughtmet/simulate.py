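"""Synthetic GC-MS peak-area datasets with the structure of the drought study.

The generator emits a raw peak-area matrix, the matching sample metadata and
a ground-truth record, emulating the 390-sample factorial design (3
genotypes x 2 tissues x 5 replicates x (basal day 0 + 6 watered + 6 drought
days)) with:

* log-uniform baseline abundances spanning several orders of magnitude,
  lognormal replicate noise of configurable coefficient of variation;
* a per-sample multiplicative detector/extraction factor applied to every
  row including the spiked internal standard, so that internal-standard
  normalization can cancel it exactly;
* peak areas proportional to sample fresh weight (shoots ~55 mg, roots
  ~30 mg, +/- 5 mg jitter), cancelled by the fresh-weight normalization step;
* osmoprotectant metabolites accumulating exponentially with drought day at
  genotype-specific rates (steeper in the BRL3ox line), flat when watered;
* a planted dynamical-network-biomarker (DNB) cluster whose members, at one
  chosen critical day of the drought series, have their replicate noise SD
  inflated and are mutually correlated through a shared latent factor;
* a few outlier samples whose metabolite rows (not the internal standard)
  are globally shifted by a configurable number of orders of magnitude,
  mimicking extraction artifacts that survive normalization.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .datamodel import AbundanceMatrix, SampleMeta, enumerate_design, GENOTYPES, TISSUES

#: Default genotype-specific exponential accumulation rates (per day) of the
#: osmoprotectant set under drought. The receptor-overexpressing line
#: accumulates markedly steeper than wild type; the receptor-null quadruple
#: mutant tracks wild type.
DEFAULT_OSMO_RATES: Dict[str, float] = {"WT": 0.3, "BRL3ox": 0.7, "quad": 0.3}

DEFAULT_OSMOPROTECTANTS = (
    "Raffinose", "Galactinol", "Proline", "Sucrose", "Galactose", "Maltose",
)


@dataclass
class DNBSpec:
    """Planted dynamical-network-biomarker cluster.

    At ``critical_day`` of the drought series the members' replicate noise SD
    is multiplied by ``sd_inflation`` and their pairwise correlation (across
    replicates, induced by a single shared latent factor with loading
    sqrt(intra_correlation)) is approximately ``intra_correlation``; at all
    other days members are mutually independent.
    """

    member_ids: Tuple[str, ...] = ("M001", "M002", "M003")
    critical_day: int = 5
    sd_inflation: float = 3.0
    intra_correlation: float = 0.8

    def __post_init__(self) -> None:
        if len(self.member_ids) < 2:
            raise ValueError("dnb cluster needs >= 2 members (pairwise correlation undefined)")
        if not 1 <= self.critical_day <= 6:
            raise ValueError("critical_day must be in 1..6")
        if not self.sd_inflation > 1:
            raise ValueError("sd_inflation must be > 1")
        if not 0 < self.intra_correlation < 1:
            raise ValueError("intra_correlation must be in (0, 1)")


@dataclass
class OutlierSpec:
    """Samples whose metabolite rows are globally shifted on the log10 scale.

    Shift signs alternate (+, -, +, ...) so that both directions of the
    quantile outlier rule are exercised.
    """

    n_samples: int = 8
    log10_shift: float = 2.0


@dataclass
class SimulationConfig:
    seed: int = 0
    n_metabolites: int = 60
    baseline_log10_range: Tuple[float, float] = (-3.0, 3.0)
    replicate_cv: float = 0.2
    osmoprotectant_rates: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {m: dict(DEFAULT_OSMO_RATES) for m in DEFAULT_OSMOPROTECTANTS}
    )
    dnb: Optional[DNBSpec] = field(default_factory=DNBSpec)
    outliers: Optional[OutlierSpec] = field(default_factory=OutlierSpec)
    standard_id: str = "Ribitol"
    standard_amount: float = 1000.0
    fresh_weight_mean_by_tissue: Dict[str, float] = field(
        default_factory=lambda: {"shoot": 55.0, "root": 30.0}
    )
    fresh_weight_jitter: float = 5.0
    detector_factor_range: Tuple[float, float] = (0.5, 2.0)
    genotypes: Tuple[str, ...] = GENOTYPES
    tissues: Tuple[str, ...] = TISSUES
    replicates: Tuple[int, ...] = (1, 2, 3, 4, 5)
    days: Tuple[int, ...] = (0, 1, 2, 3, 4, 5, 6)

    def metabolite_ids(self) -> List[str]:
        named = list(self.osmoprotectant_rates)
        if self.dnb is not None:
            named += [m for m in self.dnb.member_ids if m not in named]
        n_fill = self.n_metabolites - len(named)
        if n_fill < 0:
            raise ValueError(
                f"n_metabolites={self.n_metabolites} smaller than the "
                f"{len(named)} named (osmoprotectant + DNB) metabolites"
            )
        width = max(3, len(str(self.n_metabolites)))
        fillers, i = [], 1
        while len(fillers) < n_fill:
            mid = f"M{i:0{width}d}"
            if mid not in named:
                fillers.append(mid)
            i += 1
        return named + fillers

    def validate(self) -> None:
        lo, hi = self.baseline_log10_range
        if not lo < hi:
            raise ValueError("baseline_log10_range must be an increasing interval")
        if not self.replicate_cv > 0:
            raise ValueError("replicate_cv must be > 0")
        ids = set(self.metabolite_ids())
        if self.standard_id in ids:
            raise ValueError("standard_id collides with a metabolite id")
        if self.dnb is not None and not set(self.dnb.member_ids) <= ids:
            raise ValueError("dnb member ids must be a subset of metabolite ids")


@dataclass
class GroundTruth:
    """Planted structure of a simulated dataset, for recovery tests."""

    osmoprotectant_rates: Dict[str, Dict[str, float]]
    dnb_member_ids: List[str]
    dnb_critical_day: Optional[int]
    outlier_sample_ids: List[str]
    outlier_log10_shifts: Dict[str, float]
    baseline_means: Dict[str, float]

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def simulate_dataset(
    config: SimulationConfig, seed: Optional[int] = None
) -> Tuple[AbundanceMatrix, List[SampleMeta], GroundTruth]:
    """Generate a raw peak-area matrix, metadata and ground truth.

    Deterministic given the seed (``seed`` argument overrides
    ``config.seed``). The peak area of metabolite m in sample s is

        baseline_m * profile(m, s) * exp(noise) * fresh_weight_s * detector_s

    and the internal-standard row is ``standard_amount * detector_s``: both
    nuisance factors cancel under standard/fresh-weight normalization.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    met_ids = config.metabolite_ids()
    n_m = len(met_ids)
    met_index = {m: i for i, m in enumerate(met_ids)}

    design = enumerate_design(
        genotypes=config.genotypes, tissues=config.tissues,
        days=config.days, replicates=config.replicates,
    )
    meta: List[SampleMeta] = []
    for m in design:
        fw = config.fresh_weight_mean_by_tissue[m.tissue] + rng.uniform(
            -config.fresh_weight_jitter, config.fresh_weight_jitter
        )
        meta.append(SampleMeta(m.sample_id, m.genotype, m.tissue, m.regime,
                               m.day, m.replicate, fresh_weight_mg=fw))
    n_s = len(meta)

    lo, hi = config.baseline_log10_range
    baselines = 10.0 ** rng.uniform(lo, hi, size=n_m)
    # lognormal multiplicative noise with the requested CV
    sigma = math.sqrt(math.log(1.0 + config.replicate_cv**2))

    dnb = config.dnb
    dnb_rows = np.array([met_index[m] for m in dnb.member_ids], dtype=int) if dnb else None
    # one shared latent factor per critical-day drought sample induces the
    # intra-DNB correlation; loading sqrt(rho) on the shared part
    if dnb is not None:
        rho = dnb.intra_correlation
        load_shared, load_own = math.sqrt(rho), math.sqrt(1.0 - rho)

    log_noise = rng.normal(0.0, sigma, size=(n_m, n_s))
    concentrations = np.empty((n_m, n_s))
    for j, m in enumerate(meta):
        noise_j = log_noise[:, j]
        if dnb is not None and m.regime == "drought" and m.day == dnb.critical_day:
            shared = rng.normal()
            own = rng.normal(size=len(dnb_rows))
            noise_j = noise_j.copy()
            noise_j[dnb_rows] = dnb.sd_inflation * sigma * (
                load_shared * shared + load_own * own
            )
        profile = np.ones(n_m)
        if m.regime == "drought":
            for osmo, rates in config.osmoprotectant_rates.items():
                rate = rates.get(m.genotype, 0.0)
                profile[met_index[osmo]] = math.exp(rate * m.day)
        concentrations[:, j] = baselines * profile * np.exp(noise_j)

    fw = np.array([m.fresh_weight_mg for m in meta])
    d_lo, d_hi = config.detector_factor_range
    detector = np.exp(rng.uniform(math.log(d_lo), math.log(d_hi), size=n_s))
    peaks = concentrations * fw[None, :] * detector[None, :]

    outlier_ids: List[str] = []
    shifts: Dict[str, float] = {}
    if config.outliers is not None and config.outliers.n_samples > 0:
        chosen = rng.choice(n_s, size=config.outliers.n_samples, replace=False)
        for i, j in enumerate(sorted(chosen)):
            shift = config.outliers.log10_shift * (1.0 if i % 2 == 0 else -1.0)
            peaks[:, j] *= 10.0**shift
            outlier_ids.append(meta[j].sample_id)
            shifts[meta[j].sample_id] = shift

    standard_row = config.standard_amount * detector
    values = pd.DataFrame(
        np.vstack([standard_row, peaks]),
        index=pd.Index([config.standard_id] + met_ids, name="metabolite_id"),
        columns=[m.sample_id for m in meta],
    )
    abund = AbundanceMatrix(values, state="raw_peak",
                            internal_standard_id=config.standard_id)
    truth = GroundTruth(
        osmoprotectant_rates={k: dict(v) for k, v in config.osmoprotectant_rates.items()},
        dnb_member_ids=list(dnb.member_ids) if dnb else [],
        dnb_critical_day=dnb.critical_day if dnb else None,
        outlier_sample_ids=outlier_ids,
        outlier_log10_shifts=shifts,
        baseline_means={m: float(b) for m, b in zip(met_ids, baselines)},
    )
    return abund, meta, truth
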