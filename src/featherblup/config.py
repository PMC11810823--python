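"""Configuration for the synthetic recurrent-testing generator and pipeline.

The generator emulates a layer-breeding recurrent test: paternal half-sib
daughters of each test sire are housed together in cages (one sire per
cage, unknown dams from a single dam line), feather score (FS) is recorded
as a three-level categorical trait (10 intact / 15 damaged / 20 bald
patches) on the back and neck at 45 and 70 weeks, and survival to each
scoring age is genetically correlated with FS.

FS is generated by cutting a Gaussian liability at two thresholds per
trait.  Default thresholds are calibrated so the realized trait means match
the descriptive means of the motivating data (11.32 / 12.42 at 45 wk and
13.98 / 14.78 at 70 wk for back / neck); only the means are pinned down, so
the split between the two damaged categories is a generator choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from scipy.stats import norm

TRAITS = ("BACK45", "NECK45", "BACK70", "NECK70")

#: Descriptive trait means the threshold calibration reproduces.
TRAIT_MEANS = {"BACK45": 11.32, "NECK45": 12.42, "BACK70": 13.98, "NECK70": 14.78}

#: Chosen fraction of birds in the worst category (bald patches, score 20).
#: The source statistics constrain only the mean score, which fixes
#: P(>=15) + P(=20); the bald fraction itself is a free generator choice,
#: taken to grow with the trait mean.
BALD_FRACTIONS = {"BACK45": 0.04, "NECK45": 0.08, "BACK70": 0.18, "NECK70": 0.24}


def calibrate_thresholds(mean_fs: float, p_bald: float) -> tuple[float, float]:
    """Standardized liability cutpoints (z1, z2) hitting a target mean score.

    With scores 10/15/20 the mean is ``10 + 5 (p1 + p2)`` where
    ``p1 = P(L > z1)`` (damaged or worse) and ``p2 = P(L > z2)`` (bald), so
    the target mean and a chosen bald fraction determine both cutpoints.
    """
    p_total = (mean_fs - 10.0) / 5.0
    p1 = p_total - p_bald
    if not (0 < p_bald < p1 < 1):
        raise ValueError("inconsistent mean / bald-fraction calibration")
    return float(norm.ppf(1 - p1)), float(norm.ppf(1 - p_bald))


def default_thresholds() -> dict[str, tuple[float, float]]:
    return {
        t: calibrate_thresholds(TRAIT_MEANS[t], BALD_FRACTIONS[t]) for t in TRAITS
    }


@dataclass
class SimConfig:
    """All generator and design parameters.

    Variance components are on the standardized FS liability scale
    (total non-fixed liability variance 1 by default).  ``sigma2_S`` is the
    sire (transmitting-ability) variance; the implied animal-scale additive
    variance is ``sigma2_A = 4 sigma2_S``.  ``sigma2_e`` absorbs the dam
    contribution and Mendelian sampling (3/4 sigma2_A) plus environment,
    because dams are never identified in this design.  Defaults reproduce
    the study design: 6 cages and 53 daughters per sire, cages of 3-22
    birds, 98% / 94% survival to the 45- and 70-week scorings, and sire
    variance calibrated so the cage-level sire-model expected accuracy of
    progeny testing is ~0.62 (the moderate-accuracy regime reported for
    this design).
    """

    n_sires: int = 200
    pedigree_depth: int = 4
    dams_per_sire: int = 20          # d: only enters expected-accuracy formulas
    daughters_per_sire: int = 53     # n
    cages_per_sire: int = 6          # m
    cage_size_range: tuple[int, int] = (3, 22)

    # liability-scale variance components (FS)
    sigma2_S: float = 0.026
    sigma2_c: float = 0.05
    sigma2_e: float = 0.924

    # survival liability (variance standardized to 1)
    sigma2_S_surv: float = 0.015
    r_g_fs_surv: float = 0.4
    surv_rate_45: float = 0.98
    surv_rate_70: float = 0.94

    # FS thresholds: standardized cutpoints (z1, z2) per trait on the
    # marginal liability (fixed effects included)
    thresholds: dict = field(default_factory=default_thresholds)

    # fixed-effect structure
    n_rt_numbers: int = 24
    n_farms: int = 20
    n_crosses: int = 2
    sigma_rt: float = 0.15           # SD of test-batch (RT number) effects
    sigma_fdc: float = 0.15          # SD of farm x housing-date x cross effects
    feather_gene_freq: float = 0.3
    feather_gene_effect: float = 0.2  # liability shift of the fast-feathering allele class

    seed: int = 1

    # --- derived quantities -------------------------------------------------
    @property
    def sigma2_A(self) -> float:
        """Animal-scale additive variance implied by the sire variance."""
        return 4.0 * self.sigma2_S

    @property
    def fixed_effect_variance(self) -> float:
        p = self.feather_gene_freq
        return (
            self.sigma_rt**2
            + self.sigma_fdc**2
            + self.feather_gene_effect**2 * p * (1 - p)
        )

    @property
    def marginal_liability_sd(self) -> float:
        """SD of the marginal FS liability, fixed effects included.

        Thresholds are expressed on this scale so that realized category
        frequencies (and hence trait means) match their targets regardless
        of how much fixed-effect variance the design carries.
        """
        return float(
            np.sqrt(
                self.sigma2_S + self.sigma2_c + self.sigma2_e
                + self.fixed_effect_variance
            )
        )

    def validate(self) -> None:
        if self.n_sires < 1:
            raise ValueError("n_sires must be >= 1")
        if self.pedigree_depth < 1:
            raise ValueError("pedigree_depth must be >= 1")
        for name in ("sigma2_S", "sigma2_c", "sigma2_e", "sigma2_S_surv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.sigma2_e < 3 * self.sigma2_S:
            # sigma2_e absorbs 3/4 sigma2_A = 3 sigma2_S of genetic variation
            raise ValueError("sigma2_e must be at least 3*sigma2_S")
        if not -1.0 <= self.r_g_fs_surv <= 1.0:
            raise ValueError("r_g_fs_surv must be in [-1, 1]")
        lo, hi = self.cage_size_range
        if not (3 <= lo <= hi):
            raise ValueError("cage_size_range must satisfy 3 <= min <= max")
        if not lo <= self.daughters_per_sire / self.cages_per_sire <= hi:
            raise ValueError("mean cage size outside cage_size_range")
        for rate in (self.surv_rate_45, self.surv_rate_70):
            if not 0 < rate <= 1:
                raise ValueError("survival rates must be in (0, 1]")
        if self.surv_rate_70 > self.surv_rate_45:
            raise ValueError("survival is cumulative: surv_rate_70 <= surv_rate_45")
        for trait, (z1, z2) in self.thresholds.items():
            if not z1 < z2:
                raise ValueError(f"thresholds for {trait} must be increasing")

    # --- (de)serialization --------------------------------------------------
    def to_dict(self) -> dict:
        out = asdict(self)
        out["cage_size_range"] = list(self.cage_size_range)
        out["thresholds"] = {t: list(v) for t, v in self.thresholds.items()}
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        data = dict(data)
        if "cage_size_range" in data:
            data["cage_size_range"] = tuple(data["cage_size_range"])
        if "thresholds" in data:
            data["thresholds"] = {
                t: tuple(v) for t, v in data["thresholds"].items()
            }
        cfg = cls(**data)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def stage_seeds(seed: int, n: int = 8) -> list[np.random.SeedSequence]:
    """Expand one global seed into independent per-stage seed sequences.

    Lets pipeline stages (pedigree, population, folds, ...) be re-run
    independently while staying reproducible from the single recorded seed.
    """
    return np.random.SeedSequence(seed).spawn(n)
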