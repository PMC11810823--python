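"""Synthetic recurrent-test data: pedigree, liabilities, scores, survival.

The generator mirrors how the motivating data arise.  A closed sire line is
bred for ``pedigree_depth`` generations; the terminal-generation males are
the test sires.  Each test sire gets ``daughters_per_sire`` crossbred
daughters (dams unknown, treated as unrelated founders) housed in
``cages_per_sire`` cages.  Each daughter carries, per feather-score trait, a
Gaussian liability

    L = fixed effects + s(sire) + c(cage) + e,

with sire transmitting abilities ``s ~ N(0, sigma2_S * A)`` over the sire
pedigree, independent cage effects and residuals.  The liability is cut at
two thresholds into scores 10 / 15 / 20.  A correlated survival liability
(shared sire effects, genetic correlation ``r_g_fs_surv``) with two
cutpoints produces monotone survival to the 45- and 70-week scorings; birds
dead at a scoring age have no FS record at that age.

Two "working datasets" are then built exactly as an analyst would from the
raw cage-count records: an individual-level dataset in which per-cage score
counts are re-allocated to random surviving cage members (equivalent for
genetic analysis because cage mates share the same pedigree), and a
cage-level dataset of cage mean scores and survival fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .config import TRAITS, SimConfig, stage_seeds
from .pedigree import _inbreeding_and_d, pedigree_codes

__all__ = [
    "SimTruth",
    "SimData",
    "simulate_pedigree",
    "sires_under_test",
    "simulate_population",
    "aggregate_cage_counts",
    "make_individual_dataset",
    "make_cage_dataset",
    "continuous_cage_dataset",
    "simulate_dataset",
]

#: age (weeks) at which each trait is scored
TRAIT_AGE = {"BACK45": 45, "NECK45": 45, "BACK70": 70, "NECK70": 70}
SCORES = (10, 15, 20)


def _trait_col(trait: str) -> str:
    return f"fs_{trait.lower()}"


def _surv_col(age: int) -> str:
    return f"surv{age}"


def simulate_pedigree(config: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Sire-line pedigree: columns animal, sire, dam, generation, sex.

    Generation 0 holds unrelated founder males and females; each later
    animal draws its sire and dam at random from the previous generation
    (full sibs can occur, as in a real closed line).  The terminal
    generation consists of the ``n_sires`` test sires; females are only
    produced for generations that still breed.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    depth, n = config.pedigree_depth, config.n_sires
    rows = []
    prev_m: list[str] = []
    prev_f: list[str] = []
    for g in range(depth):
        males = [f"G{g}M{i:04d}" for i in range(n)]
        females = [f"G{g}F{i:04d}" for i in range(n)] if g < depth - 1 else []
        for sex, ids in (("M", males), ("F", females)):
            for a in ids:
                if g == 0:
                    s = d = None
                else:
                    s = prev_m[rng.integers(len(prev_m))]
                    d = prev_f[rng.integers(len(prev_f))]
                rows.append((a, s, d, g, sex))
        prev_m, prev_f = males, females
    return pd.DataFrame(rows, columns=["animal", "sire", "dam", "generation", "sex"])


def sires_under_test(pedigree: pd.DataFrame) -> list[str]:
    """The terminal-generation males, i.e. the sires under test."""
    last = pedigree["generation"].max()
    mask = (pedigree["generation"] == last) & (pedigree["sex"] == "M")
    return list(pedigree.loc[mask, "animal"])


def _chol_psd(G: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(G)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(G)
        return V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def _simulate_sire_effects(
    pedigree: pd.DataFrame, G0: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    """Bivariate (FS, survival) transmitting abilities over the pedigree.

    Gene-dropping recursion: each animal is the parent average plus a
    Mendelian term with covariance ``d_i * G0``, so that the stacked
    effects have covariance ``G0 (x) A`` exactly.
    """
    ids, sire, dam = pedigree_codes(pedigree)
    _, d = _inbreeding_and_d(sire, dam)
    L0 = _chol_psd(G0)
    n = len(ids)
    bv = np.zeros((n, 2))
    z = rng.standard_normal((n, 2))
    for i in range(n):
        mu = np.zeros(2)
        if sire[i] >= 0:
            mu += 0.5 * bv[sire[i]]
        if dam[i] >= 0:
            mu += 0.5 * bv[dam[i]]
        bv[i] = mu + np.sqrt(d[i]) * (L0 @ z[i])
    return pd.DataFrame({"animal": ids, "s_fs": bv[:, 0], "s_surv": bv[:, 1]})


def _cage_sizes(rng, n: int, m: int, lo: int, hi: int) -> np.ndarray:
    """Split n daughters over m cages with each size in [lo, hi]."""
    if not lo * m <= n <= hi * m:
        raise ValueError("daughters_per_sire incompatible with cage bounds")
    sizes = rng.multinomial(n, np.full(m, 1.0 / m))
    for _ in range(10 * m):
        if sizes.min() >= lo and sizes.max() <= hi:
            break
        give, take = np.argmin(sizes), np.argmax(sizes)
        sizes[give] += 1
        sizes[take] -= 1
    return sizes


@dataclass
class SimTruth:
    """Ground truth behind a simulated population (for validation oracles)."""

    sire_effects: pd.DataFrame     # animal, s_fs, s_surv (liability scale)
    cage_effects: pd.DataFrame     # cage_id, cage_effect
    liabilities: pd.DataFrame      # animal_id + liab_<trait> + liab_surv
    config: SimConfig


def simulate_population(
    config: SimConfig,
    pedigree: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate daughters with FS scores and survival for every test sire.

    Returns the individual table (one row per bird, score columns NaN when
    the bird was dead at that scoring age) and the :class:`SimTruth` used
    to generate it.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sires = sires_under_test(pedigree)

    cov_sv = config.r_g_fs_surv * np.sqrt(config.sigma2_S * config.sigma2_S_surv)
    G0 = np.array([[config.sigma2_S, cov_sv], [cov_sv, config.sigma2_S_surv]])
    sire_fx = _simulate_sire_effects(pedigree, G0, rng)
    s_fs = dict(zip(sire_fx["animal"], sire_fx["s_fs"]))
    s_sv = dict(zip(sire_fx["animal"], sire_fx["s_surv"]))

    # fixed-effect structure: RT batches (each at one farm on one date),
    # farm x date x cross interaction, and a sire-line feathering gene.
    # An RT number identifies batch, farm and row; the rows of one batch
    # share the batch's farm and housing date, so the RT factor is not
    # nested inside the farm x date x cross interaction.
    n_rt, n_cross = config.n_rt_numbers, config.n_crosses
    rt_levels = [f"RT{r:03d}" for r in range(n_rt)]
    batch_of = {lev: r // 2 for r, lev in enumerate(rt_levels)}
    rt_farm = {lev: f"F{b % config.n_farms:02d}" for lev, b in batch_of.items()}
    rt_date = {lev: f"D{b:02d}" for lev, b in batch_of.items()}
    rt_eff = rng.normal(0.0, config.sigma_rt, n_rt)
    rt_eff -= rt_eff.mean()
    fdc_eff = rng.normal(0.0, config.sigma_fdc, (n_rt, n_cross))
    fdc_eff -= fdc_eff.mean()
    gene_of_sire = {
        s: ("fast" if u < config.feather_gene_freq else "slow")
        for s, u in zip(sires, rng.random(len(sires)))
    }
    p = config.feather_gene_freq
    gene_eff = {
        "fast": config.feather_gene_effect * (1 - p),
        "slow": -config.feather_gene_effect * p,
    }

    lo, hi = config.cage_size_range
    cage_rows, bird_meta = [], []
    for s in sires:
        sizes = _cage_sizes(rng, config.daughters_per_sire, config.cages_per_sire, lo, hi)
        for j, size in enumerate(sizes):
            cage = f"C{s}_{j}"
            r = rt_levels[rng.integers(n_rt)]
            cross = f"X{rng.integers(n_cross)}"
            cage_rows.append((cage, s, r, cross, int(size)))
            for k in range(size):
                bird_meta.append((f"{cage}_{k:02d}", cage, s, r, cross))

    cages = pd.DataFrame(cage_rows, columns=["cage_id", "sire_id", "rt_number", "cross", "n"])
    cage_eff = rng.normal(0.0, np.sqrt(config.sigma2_c), len(cages))
    c_of_cage = dict(zip(cages["cage_id"], cage_eff))

    ind = pd.DataFrame(bird_meta, columns=["animal_id", "cage_id", "sire_id", "rt_number", "cross"])
    ind["farm"] = ind["rt_number"].map(rt_farm)
    ind["housing_date"] = ind["rt_number"].map(rt_date)
    ind["feather_gene"] = ind["sire_id"].map(gene_of_sire)
    nb = len(ind)

    rt_idx = ind["rt_number"].str.slice(2).astype(int).to_numpy()
    cross_idx = ind["cross"].str.slice(1).astype(int).to_numpy()
    fixed = (
        rt_eff[rt_idx]
        + fdc_eff[rt_idx, cross_idx]
        + ind["feather_gene"].map(gene_eff).to_numpy()
    )
    s_vec = ind["sire_id"].map(s_fs).to_numpy()
    c_vec = ind["cage_id"].map(c_of_cage).to_numpy()

    # survival: one liability, two cutpoints, monotone (dead at 45 => dead at 70)
    liab_surv = ind["sire_id"].map(s_sv).to_numpy() + rng.normal(
        0.0, np.sqrt(max(1.0 - config.sigma2_S_surv, 0.0)), nb
    )
    alive45 = liab_surv < norm.ppf(config.surv_rate_45)
    alive70 = liab_surv < norm.ppf(config.surv_rate_70)
    ind["surv45"] = np.where(alive45, 2, 1)
    ind["surv70"] = np.where(alive70, 2, 1)

    sd_marg = config.marginal_liability_sd
    liab_cols = {"animal_id": ind["animal_id"], "liab_surv": liab_surv}
    for trait in TRAITS:
        e = rng.normal(0.0, np.sqrt(config.sigma2_e), nb)
        liab = fixed + s_vec + c_vec + e
        z1, z2 = config.thresholds[trait]
        score = np.full(nb, 10.0)
        score[liab > z1 * sd_marg] = 15.0
        score[liab > z2 * sd_marg] = 20.0
        alive = alive45 if TRAIT_AGE[trait] == 45 else alive70
        ind[_trait_col(trait)] = np.where(alive, score, np.nan)
        liab_cols[f"liab_{trait.lower()}"] = liab

    truth = SimTruth(
        sire_effects=sire_fx,
        cage_effects=pd.DataFrame({"cage_id": cages["cage_id"], "cage_effect": cage_eff}),
        liabilities=pd.DataFrame(liab_cols),
        config=config,
    )
    return ind, truth


_META_COLS = ["sire_id", "rt_number", "farm", "cross", "housing_date", "feather_gene"]


def aggregate_cage_counts(individuals: pd.DataFrame) -> pd.DataFrame:
    """Collapse an individual table to raw-data style per-cage score counts.

    One row per cage: metadata, original size, dead counts per scoring age
    and, per trait, the number of survivors with each score.
    """
    rows = []
    for cage, grp in individuals.groupby("cage_id", sort=True):
        row = {"cage_id": cage, "n_original": len(grp)}
        for col in _META_COLS:
            row[col] = grp[col].iloc[0]
        for age in (45, 70):
            row[f"n_dead{age}"] = int((grp[_surv_col(age)] == 1).sum())
        for trait in TRAITS:
            counts = grp[_trait_col(trait)].value_counts()
            for s in SCORES:
                row[f"{trait}_n{s}"] = int(counts.get(float(s), 0))
        rows.append(row)
    return pd.DataFrame(rows)


def make_individual_dataset(
    cage_counts: pd.DataFrame, rng: np.random.Generator | int | None = None
) -> pd.DataFrame:
    """Individual-level working dataset from per-cage score counts.

    Scores are allocated to random surviving members of each cage (dead
    members get a missing record), exactly as the working data are built
    from the raw counts; the allocation is equivalent for genetic analysis
    because all cage members share the same pedigree.  Survival is coded 2
    (alive) / 1 (dead) and is monotone across scoring ages.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    rows = []
    for rec in cage_counts.itertuples(index=False):
        rec = rec._asdict()
        n = int(rec["n_original"])
        dead45, dead70 = int(rec["n_dead45"]), int(rec["n_dead70"])
        if not 0 <= dead45 <= dead70 <= n:
            raise ValueError(f"inconsistent dead counts in cage {rec['cage_id']}")
        members = [f"{rec['cage_id']}_{k:02d}" for k in range(n)]
        order = rng.permutation(n)
        dead70_set = set(order[:dead70])     # dead-at-45 is a subset: monotone
        dead45_set = set(order[:dead45])
        scores = {}
        for trait in TRAITS:
            counts = {s: int(rec[f"{trait}_n{s}"]) for s in SCORES}
            dead = dead45_set if TRAIT_AGE[trait] == 45 else dead70_set
            alive_idx = [i for i in range(n) if i not in dead]
            if sum(counts.values()) != len(alive_idx):
                raise ValueError(
                    f"score counts for {trait} in cage {rec['cage_id']} do not "
                    f"sum to the number of survivors"
                )
            pool = np.repeat(list(counts.keys()), list(counts.values())).astype(float)
            rng.shuffle(pool)
            col = np.full(n, np.nan)
            col[alive_idx] = pool
            scores[trait] = col
        for i, animal in enumerate(members):
            row = {"animal_id": animal, "cage_id": rec["cage_id"]}
            for c in _META_COLS:
                row[c] = rec[c]
            row["surv45"] = 1 if i in dead45_set else 2
            row["surv70"] = 1 if i in dead70_set else 2
            for trait in TRAITS:
                row[_trait_col(trait)] = scores[trait][i]
            rows.append(row)
    return pd.DataFrame(rows)


def make_cage_dataset(
    individuals: pd.DataFrame, rng: np.random.Generator | int | None = None
) -> pd.DataFrame:
    """Cage-level working dataset: mean survivor scores and survival fractions.

    ``mean_<trait>`` is the arithmetic mean over members alive at that
    scoring age (missing when no survivors).  ``surv_frac<age>`` is the
    number alive divided by the original cage size.  One random member is
    recorded as ``representative_animal_id`` for the cage-level animal
    model, which assigns the cage record to that animal.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    rows = []
    for cage, grp in individuals.groupby("cage_id", sort=True):
        row = {"cage_id": cage, "n_original": len(grp)}
        for col in _META_COLS:
            row[col] = grp[col].iloc[0]
        row["representative_animal_id"] = grp["animal_id"].iloc[
            rng.integers(len(grp))
        ]
        for age in (45, 70):
            alive = grp[_surv_col(age)] == 2
            row[f"n_alive{age}"] = int(alive.sum())
            row[f"surv_frac{age}"] = alive.sum() / len(grp)
        for trait in TRAITS:
            vals = grp[_trait_col(trait)].dropna()
            row[f"mean_{trait.lower()}"] = vals.mean() if len(vals) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def continuous_cage_dataset(individuals: pd.DataFrame, truth: SimTruth) -> pd.DataFrame:
    """Cage dataset whose records are cage means of the *continuous* liability.

    Skipping the threshold step yields data that exactly satisfy the linear
    cage-level model assumptions (Gaussian record = fixed effects + sire
    effect + mean cage/residual deviation), which is what calibration
    checks of BLUP properties require.  Only survivors at the trait age
    enter each mean, mirroring the categorical pipeline.
    """
    merged = individuals.merge(truth.liabilities, on="animal_id", validate="1:1")
    base = make_cage_dataset(individuals, rng=0)
    for trait in TRAITS:
        alive = merged[_surv_col(TRAIT_AGE[trait])] == 2
        means = (
            merged[alive]
            .groupby("cage_id")[f"liab_{trait.lower()}"]
            .mean()
        )
        base[f"mean_{trait.lower()}"] = base["cage_id"].map(means)
    return base


@dataclass
class SimData:
    """A complete simulated recurrent test plus its generating truth."""

    pedigree: pd.DataFrame
    individuals: pd.DataFrame    # working dataset (scores re-allocated)
    cages: pd.DataFrame
    truth: SimTruth
    config: SimConfig


def simulate_dataset(config: SimConfig) -> SimData:
    """Run the full generator: pedigree -> population -> working datasets.

    The global seed is expanded into independent per-stage streams so each
    stage is individually reproducible.
    """
    seeds = stage_seeds(config.seed)
    ped = simulate_pedigree(config, np.random.default_rng(seeds[0]))
    ind_true, truth = simulate_population(config, ped, np.random.default_rng(seeds[1]))
    counts = aggregate_cage_counts(ind_true)
    individuals = make_individual_dataset(counts, np.random.default_rng(seeds[2]))
    cages = make_cage_dataset(individuals, np.random.default_rng(seeds[3]))
    return SimData(pedigree=ped, individuals=individuals, cages=cages, truth=truth, config=config)
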