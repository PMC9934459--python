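"""Synthetic postmortem cohort and count-matrix generator.

Every downstream stage of the pipeline is exercised on data from this module:
a cohort of donors with a clock time of death, a season of death and the
covariates used in the differential models (sex, age, BMI, postmortem
interval), plus per-tissue negative-binomial count matrices with planted
temporal structure.

The defaults emulate the study cohort: 932 donors, death times uniform over
the 24-h clock, season counts proportional to (190, 221, 282, 239) for
spring/summer/fall/winter, and a male-biased, older population.  Planted
effects come in four classes:

``daynight``
    log2 mean expression carries ``amplitude * cos(2*pi*(t - phase)/24)``
    with t the death time in hours — a cosine peaking at ``phase``.
``seasonal``
    a log2 offset of ``+-amplitude`` in one target season.
``covariate_only``
    a linear log2 term in one standardized covariate (no temporal signal).
``null``
    baseline expression only.

Counts for gene g in sample s are negative binomial with mean
``lib_s * 2**eta_gs / Z`` (Z normalizes the baseline so library sizes land in
the configured range) and variance ``mu + dispersion * mu**2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .labels import SEASONS

#: Season sampling probabilities proportional to the study's donor counts.
DEFAULT_SEASON_COUNTS = (190, 221, 282, 239)

EFFECT_CLASSES = ("daynight", "seasonal", "covariate_only", "null")

_COVARIATES = ("sex", "age", "bmi", "postmortem_interval")


@dataclass(frozen=True)
class DonorRecord:
    """One donor: the unit of temporal labelling."""

    donor_id: str
    time_of_death: int          # minutes since midnight, [0, 1440)
    season: str                 # spring / summer / fall / winter
    sex: str                    # male / female
    age: float                  # years
    bmi: float                  # kg/m^2
    postmortem_interval: float  # minutes

    def __post_init__(self) -> None:
        if not 0 <= self.time_of_death < 1440:
            raise ValueError(f"time_of_death out of range: {self.time_of_death}")
        if self.season not in SEASONS:
            raise ValueError(f"unknown season: {self.season!r}")
        if self.sex not in ("male", "female"):
            raise ValueError(f"unknown sex: {self.sex!r}")
        for name in ("age", "bmi"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"{name} must be finite and > 0")
        if not np.isfinite(self.postmortem_interval) or self.postmortem_interval < 0:
            raise ValueError("postmortem_interval must be finite and >= 0")


@dataclass(frozen=True)
class PlantedEffect:
    """Ground truth for one gene."""

    gene_id: str
    effect_class: str
    amplitude: float = 0.0       # log2 units
    phase: float | None = None   # hours in [0, 24), daynight class only
    season_target: str | None = None
    direction: str | None = None  # up / down, seasonal class only
    covariate: str | None = None  # covariate_only class only

    def __post_init__(self) -> None:
        if self.effect_class not in EFFECT_CLASSES:
            raise ValueError(f"unknown effect class: {self.effect_class!r}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if (self.phase is not None) != (self.effect_class == "daynight"):
            raise ValueError("phase is set iff effect_class is 'daynight'")
        if (self.season_target is not None) != (self.effect_class == "seasonal"):
            raise ValueError("season_target is set iff effect_class is 'seasonal'")


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration; the seed fully determines every output."""

    n_donors: int = 932
    n_genes: int = 2000
    tissues: tuple[tuple[str, float], ...] = (("tissue", 1.0),)
    frac_daynight: float = 0.05
    frac_seasonal: float = 0.05
    frac_covariate: float = 0.05
    dispersion: float = 0.1
    library_size_range: tuple[float, float] = (1.0e6, 2.0e6)
    amplitude_range: tuple[float, float] = (0.5, 1.5)
    seasonal_amplitude_range: tuple[float, float] = (0.5, 1.5)
    covariate_effect: float = 0.3
    baseline_log2_range: tuple[float, float] = (3.0, 9.0)
    season_probs: tuple[float, ...] = tuple(np.asarray(DEFAULT_SEASON_COUNTS) / sum(DEFAULT_SEASON_COUNTS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_donors < 1:
            raise ValueError("n_donors must be >= 1")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        total = self.frac_daynight + self.frac_seasonal + self.frac_covariate
        if total > 1 + 1e-12:
            raise ValueError("effect-class fractions must sum to <= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    # independent streams per stage, all pinned to the config seed
    return np.random.default_rng([int(config.seed), stage])


def generate_cohort(config: SimConfig) -> list[DonorRecord]:
    """Draw donors: uniform death times, multinomial seasons, covariates.

    Ages are normal around 55 y (the cohort median), two-thirds male, BMI
    normal around 27, postmortem interval uniform 1-24 h.
    """
    rng = _rng(config, 0)
    n = config.n_donors
    times = rng.integers(0, 1440, size=n)
    seasons = rng.choice(SEASONS, size=n, p=np.asarray(config.season_probs))
    sexes = np.where(rng.random(n) < 0.67, "male", "female")
    ages = np.clip(rng.normal(55, 12, size=n), 21, 80)
    bmis = np.clip(rng.normal(27, 4.5, size=n), 16, 45)
    pmis = rng.uniform(60, 1440, size=n)
    width = len(str(n))
    return [
        DonorRecord(
            donor_id=f"D{i:0{width}d}",
            time_of_death=int(times[i]),
            season=str(seasons[i]),
            sex=str(sexes[i]),
            age=float(np.round(ages[i], 1)),
            bmi=float(np.round(bmis[i], 1)),
            postmortem_interval=float(np.round(pmis[i], 1)),
        )
        for i in range(n)
    ]


def cohort_to_frame(cohort: Sequence[DonorRecord]) -> pd.DataFrame:
    """Donor metadata as a DataFrame indexed by donor id."""
    return pd.DataFrame(
        {
            "time_of_death": [d.time_of_death for d in cohort],
            "season": [d.season for d in cohort],
            "sex": [d.sex for d in cohort],
            "age": [d.age for d in cohort],
            "bmi": [d.bmi for d in cohort],
            "postmortem_interval": [d.postmortem_interval for d in cohort],
        },
        index=pd.Index([d.donor_id for d in cohort], name="donor_id"),
    )


def generate_truth(config: SimConfig) -> list[PlantedEffect]:
    """Assign every gene to exactly one effect class and draw its parameters."""
    rng = _rng(config, 1)
    g = config.n_genes
    n_dn = int(round(config.frac_daynight * g))
    n_se = int(round(config.frac_seasonal * g))
    n_cov = int(round(config.frac_covariate * g))
    width = len(str(g))
    truth: list[PlantedEffect] = []
    for i in range(g):
        gene = f"G{i:0{width}d}"
        if i < n_dn:
            truth.append(
                PlantedEffect(
                    gene_id=gene,
                    effect_class="daynight",
                    amplitude=float(rng.uniform(*config.amplitude_range)),
                    phase=float(rng.uniform(0, 24)),
                )
            )
        elif i < n_dn + n_se:
            truth.append(
                PlantedEffect(
                    gene_id=gene,
                    effect_class="seasonal",
                    amplitude=float(rng.uniform(*config.seasonal_amplitude_range)),
                    season_target=str(rng.choice(SEASONS)),
                    direction=str(rng.choice(["up", "down"])),
                )
            )
        elif i < n_dn + n_se + n_cov:
            truth.append(
                PlantedEffect(
                    gene_id=gene,
                    effect_class="covariate_only",
                    amplitude=config.covariate_effect,
                    covariate=str(rng.choice(_COVARIATES)),
                    direction=str(rng.choice(["up", "down"])),
                )
            )
        else:
            truth.append(PlantedEffect(gene_id=gene, effect_class="null"))
    return truth


def truth_to_frame(truth: Sequence[PlantedEffect]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "effect_class": [t.effect_class for t in truth],
            "amplitude": [t.amplitude for t in truth],
            "phase": [t.phase if t.phase is not None else np.nan for t in truth],
            "season_target": [t.season_target or "" for t in truth],
            "direction": [t.direction or "" for t in truth],
            "covariate": [t.covariate or "" for t in truth],
        },
        index=pd.Index([t.gene_id for t in truth], name="gene"),
    )


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def generate_expression(
    cohort: Sequence[DonorRecord],
    truth: Sequence[PlantedEffect],
    config: SimConfig,
    tissue: str | None = None,
) -> ExpressionMatrix:
    """Negative-binomial counts with the planted log2 mean structure.

    One sample per donor per tissue; donors are Bernoulli-thinned by the
    tissue's sampling probability, emulating an incomplete donor x tissue
    grid.  Gene lengths are log-normal with median 2 kb, solely so the TPM
    path is exercised.
    """
    tissue_map = dict(config.tissues)
    if tissue is None:
        tissue = next(iter(tissue_map))
    if tissue not in tissue_map:
        raise ValueError(f"tissue {tissue!r} not in config.tissues")
    p_sample = tissue_map[tissue]

    tissue_idx = list(tissue_map).index(tissue)
    rng = _rng(config, 10 + tissue_idx)

    keep = rng.random(len(cohort)) < p_sample
    donors = [d for d, k in zip(cohort, keep) if k]
    if not donors:
        raise ValueError(f"tissue {tissue!r}: no donors sampled")
    n = len(donors)
    samples = [f"{d.donor_id}-{tissue}" for d in donors]

    t_hours = np.array([d.time_of_death for d in donors]) / 60.0
    season = np.array([d.season for d in donors])
    sex = np.array([1.0 if d.sex == "male" else 0.0 for d in donors])
    cov = {
        "sex": sex - sex.mean(),
        "age": _standardize(np.array([d.age for d in donors])),
        "bmi": _standardize(np.array([d.bmi for d in donors])),
        "postmortem_interval": _standardize(np.array([d.postmortem_interval for d in donors])),
    }

    g = len(truth)
    lo, hi = config.baseline_log2_range
    baseline = rng.uniform(lo, hi, size=g)
    eta = np.tile(baseline[:, None], (1, n))
    for i, eff in enumerate(truth):
        if eff.effect_class == "daynight":
            eta[i] += eff.amplitude * np.cos(2 * np.pi * (t_hours - eff.phase) / 24.0)
        elif eff.effect_class == "seasonal":
            sgn = 1.0 if eff.direction == "up" else -1.0
            eta[i] += sgn * eff.amplitude * (season == eff.season_target)
        elif eff.effect_class == "covariate_only":
            sgn = 1.0 if eff.direction == "up" else -1.0
            eta[i] += sgn * eff.amplitude * cov[eff.covariate]
        elif eff.effect_class != "null":
            raise ValueError(f"unknown effect class: {eff.effect_class!r}")

    lib = rng.uniform(*config.library_size_range, size=n)
    rel = np.exp2(eta)
    mu = lib[None, :] * rel / np.exp2(baseline).sum()

    if config.dispersion <= 0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / config.dispersion
        counts = rng.negative_binomial(r, r / (r + mu))

    lengths = np.exp(rng.normal(np.log(2000.0), 0.6, size=g))
    gene_ids = pd.Index([t.gene_id for t in truth], name="gene")
    return ExpressionMatrix(
        counts=pd.DataFrame(counts, index=gene_ids, columns=samples),
        gene_lengths=pd.Series(np.round(lengths).astype(int), index=gene_ids, name="length"),
        sample_donor=pd.Series([d.donor_id for d in donors], index=pd.Index(samples, name="sample")),
        tissue=tissue,
    )


def simulate_tissue(config: SimConfig, tissue: str | None = None):
    """Convenience wrapper: cohort + truth + one tissue's counts."""
    cohort = generate_cohort(config)
    truth = generate_truth(config)
    matrix = generate_expression(cohort, truth, config, tissue=tissue)
    return cohort, truth, matrix
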