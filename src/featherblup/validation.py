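"""Cage-masked cross-validation of estimated sire effects.

The validation design: cages are split into k folds (identical folds for
every model and trait at a given seed); for each fold the masked cages'
phenotypes are removed from training, the model is refit, and the
estimated sire effects are compared against the masked cages' proxy
phenotypes — cage-average residuals of a fixed-effects-only cage-level
model computed once on the complete dataset.

Reported statistics per fold:

* ``r(s_hat, Ybar_obs)`` — Pearson correlation of estimated sire effects
  with masked cage proxies;
* accuracy ``r(s, s_hat) = r(s_hat, Ybar)/r(s, Ybar)``, where the
  correction ``r(s, Ybar) = sqrt[ (1/4 sA2) / (1/4 sA2 + sc2 +
  (3/4 sA2 + se2)/n_bar) ]`` uses individual-level variance components and
  the realized mean cage size;
* dispersion — OLS slope of proxies on estimated sire effects (expected 1
  for correctly dispersed BLUP, < 1 means over-dispersion);
* the total-heritable-variance ratio T2 and the theoretical expected
  accuracy of the model family.

Fold-level metrics are summarized as estimated marginal means over the
model x fold grid with fold as a blocking factor, with Tukey-adjusted
pairwise comparisons and compact letter display.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lmm import DEFAULT_FIXED, ModelData, VarianceComponents, fixed_design, reml_fit
from .models import ModelSpec, spec_for

__all__ = [
    "assign_folds",
    "precorrect",
    "r_true_proxy",
    "fold_accuracy",
    "dispersion_slope",
    "expected_accuracy",
    "total_heritable_ratio",
    "emmean_compare",
    "cross_validate",
    "ValidationResult",
    "EmmeanSummary",
]

logger = logging.getLogger(__name__)

#: individual-level univariate sire model: not one of the six compared
#: models, but a cheap, statistically equivalent source of the variance
#: components entering the r(s, Ybar_obs) correction.
IUSIM = ModelSpec("IUSiM", "individual", "sire", False, True)


def assign_folds(cages: pd.DataFrame, k: int = 10, seed: int = 0) -> pd.DataFrame:
    """Randomly partition cages into k folds of near-equal size.

    Returns a frame with columns ``cage_id`` and ``fold`` (1..k); sizes
    differ by at most one.  Deterministic given the seed, so the same
    assignment serves every model and trait.
    """
    if k < 2:
        raise ValueError("need at least 2 folds")
    ids = np.asarray(cages["cage_id"])
    if len(ids) < k:
        raise ValueError("fewer cages than folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    folds = np.empty(len(ids), dtype=int)
    folds[perm] = np.arange(len(ids)) % k + 1
    return pd.DataFrame({"cage_id": ids, "fold": folds})


def precorrect(cages: pd.DataFrame, trait: str, fixed=DEFAULT_FIXED) -> pd.DataFrame:
    """Proxy phenotypes: cage-mean residuals of a fixed-effects-only model.

    Fit once on the complete cage dataset; masked-fold proxies are looked
    up from this table, never recomputed per fold.  Returns columns
    ``cage_id``, ``sire_id``, ``y_obs`` (cages without a defined mean are
    omitted).
    """
    col = f"mean_{trait.lower()}"
    obs = cages.loc[cages[col].notna()].reset_index(drop=True)
    X, _ = fixed_design(obs, fixed)
    y = obs[col].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return pd.DataFrame(
        {"cage_id": obs["cage_id"], "sire_id": obs["sire_id"], "y_obs": resid}
    )


def r_true_proxy(varcomp: VarianceComponents, n_bar: float) -> float:
    """Correlation between true sire effects and cage-average proxies.

    Square root of the fraction of proxy variance explained by the sire:
    the sire contribution (1/4 of the additive variance) is shared by all
    cage members, while the dam + Mendelian part (3/4 of the additive
    variance) and the residual average over the ``n_bar`` birds of a cage.
    Accepts components from an individual-level animal model (sigma2_A) or
    sire model (sigma2_S = 1/4 sigma2_A absorbed accordingly).
    """
    if varcomp.scale == "animal":
        sA2 = varcomp.genetic[0, 0]
        sire_var = 0.25 * sA2
        averaged = 0.75 * sA2 + varcomp.residual[0, 0]
    else:
        sire_var = varcomp.genetic[0, 0]
        averaged = varcomp.residual[0, 0]
    cage_var = varcomp.cage[0, 0] if varcomp.cage is not None else 0.0
    denom = sire_var + cage_var + averaged / n_bar
    if denom <= 0:
        raise ValueError("all variance components are zero: r(s, Ybar) undefined")
    if sire_var == 0:
        logger.warning("zero sire variance: r(s, Ybar) degenerate at 0")
        return 0.0
    return float(np.sqrt(sire_var / denom))


def _matched(s_hat: pd.Series, proxies: pd.DataFrame):
    merged = proxies.dropna(subset=["y_obs"]).copy()
    merged["s_hat"] = merged["sire_id"].map(s_hat)
    return merged.dropna(subset=["s_hat"])


def fold_accuracy(s_hat: pd.Series, proxies: pd.DataFrame) -> float:
    """Pearson correlation of estimated sire effects with masked proxies.

    ``s_hat`` is indexed by sire id; ``proxies`` holds the masked cages
    only.  Each masked cage contributes one point (its sire's estimate vs
    its proxy).  Returns NaN — the fold is skipped — when fewer than three
    matched cages remain.
    """
    m = _matched(s_hat, proxies)
    if len(m) < 3:
        logger.warning("fold skipped: only %d masked cages with defined proxies", len(m))
        return np.nan
    return float(np.corrcoef(m["s_hat"], m["y_obs"])[0, 1])


def dispersion_slope(proxies: pd.DataFrame, s_hat: pd.Series) -> float:
    """OLS slope of masked proxies on estimated sire effects.

    Expected value 1 for BLUP under the generating model; slopes below one
    indicate over-dispersed (too spread out) sire-effect estimates, above
    one under-dispersion.
    """
    m = _matched(s_hat, proxies)
    if len(m) < 3 or np.var(m["s_hat"].to_numpy()) == 0:
        logger.warning("dispersion undefined for this fold")
        return np.nan
    res = stats.linregress(m["s_hat"], m["y_obs"])
    return float(res.slope)


def expected_accuracy(
    spec: ModelSpec, varcomp: VarianceComponents, d: float, n: float, m: float
) -> float:
    """Theoretical accuracy sqrt(R2) of a sire's estimate for each family.

    R2 is the fraction of variance of the information mean (daughter mean
    for individual-level models, cage mean for cage-level models, where
    n = m cage records per sire) explained by the sire effect; d = dams
    per sire, n = daughters per sire, m = cages per sire.
    """
    if min(d, n, m) <= 0:
        raise ValueError("d, n, m must be positive")
    g = varcomp.genetic[0, 0]
    e = varcomp.residual[0, 0]
    c = varcomp.cage[0, 0] if varcomp.cage is not None else 0.0
    if spec.level == "individual" and spec.genetic == "animal":
        sA2 = g
        denom = sA2 / 4 + sA2 / (4 * d) + sA2 / (2 * n) + e / n + c / m
        r2 = (sA2 / 4) / denom
    elif spec.level == "individual":  # IBSiM
        sS2 = g
        if e < 3 * sS2:
            raise ValueError(
                "inconsistent components: residual variance smaller than the "
                "3*sigma2_S it must absorb"
            )
        denom = sS2 + sS2 / d + 2 * sS2 / n + (e - 3 * sS2) / n + c / m
        r2 = sS2 / denom
    elif spec.genetic == "animal":  # CUAM
        sA2 = g
        r2 = (sA2 / 4) / (sA2 / 4 + (0.75 * sA2 + e) / m)
    else:  # CUSiM, CBSiM
        r2 = g / (g + e / m)
    return float(np.sqrt(r2))


def total_heritable_ratio(varcomp: VarianceComponents, spec: ModelSpec) -> float:
    """T2: total heritable variance over phenotypic variance.

    Animal models: sigma2_A / sigma2_P; sire models: 4 sigma2_S / sigma2_P,
    with sigma2_P the sum of the fitted genetic, cage (when present) and
    residual variances.  Because cage mates are sibs, the genetic variance
    captured here is the *total* (direct + social) heritable variance, so
    T2 is the group-housing analogue of heritability.
    """
    sP2 = varcomp.phenotypic(0)
    if sP2 <= 0:
        raise ValueError("phenotypic variance is zero: T2 undefined")
    g = varcomp.genetic[0, 0]
    return float((g if spec.genetic == "animal" else 4.0 * g) / sP2)


# --------------------------------------------------------------------------
# EMMEAN summaries over the model x fold grid
# --------------------------------------------------------------------------

@dataclass
class EmmeanSummary:
    """Marginal means per model with Tukey groupings for one metric."""

    table: pd.DataFrame       # model, emmean, se, letters [, t_vs_ref, p_vs_ref]
    contrasts: pd.DataFrame   # model_a, model_b, estimate, p_adj, significant
    metric: str = ""

    def __str__(self) -> str:
        return self.table.to_string(index=False, float_format=lambda v: f"{v:.4f}")


def _letters_from_pairs(models: list[str], sig: dict) -> dict:
    """Compact letter display: models sharing a letter are not sig. different."""
    groups: list[set] = [set(models)]
    for (a, b), s in sig.items():
        if not s:
            continue
        next_groups = []
        for grp in groups:
            if a in grp and b in grp:
                next_groups += [grp - {a}, grp - {b}]
            else:
                next_groups.append(grp)
        # absorb subsets
        groups = []
        for grp in sorted(next_groups, key=len, reverse=True):
            if grp and not any(grp <= g for g in groups):
                groups.append(grp)
    groups.sort(key=lambda g: min(models.index(x) for x in g))
    letters = {m: "" for m in models}
    for i, grp in enumerate(groups):
        for m in grp:
            letters[m] += chr(ord("a") + i)
    return letters


def emmean_compare(
    metrics: pd.DataFrame,
    value: str = "value",
    reference: float | None = None,
    alpha: float = 0.05,
) -> EmmeanSummary:
    """EMMEANs of a per-fold metric across models, fold as blocking factor.

    ``metrics`` has columns ``model``, ``fold`` and the metric value.
    Because all models share identical training folds, treating fold as a
    block removes the common fold-to-fold noise.  Pairwise model contrasts
    use Tukey's studentized range on the two-way residual; ``reference``
    adds a per-model t-test of the marginal mean against that constant
    (e.g. 1.0 for dispersion slopes).
    """
    df = metrics.dropna(subset=[value]).copy()
    models = list(pd.unique(df["model"]))
    wide = df.pivot_table(index="fold", columns="model", values=value)
    wide = wide.dropna(axis=0)  # complete fold blocks only
    if wide.empty:
        raise ValueError("no complete fold blocks to compare")
    n_f, n_m = wide.shape
    means = wide.mean(axis=0)

    if n_m == 1:
        m = models[0]
        se = wide[m].std(ddof=1) / np.sqrt(n_f) if n_f > 1 else np.nan
        table = pd.DataFrame(
            {"model": [m], "emmean": [means[m]], "se": [se], "letters": ["a"]}
        )
        contrasts = pd.DataFrame(
            columns=["model_a", "model_b", "estimate", "p_adj", "significant"]
        )
        if reference is not None and np.isfinite(se) and se > 0:
            t = (means[m] - reference) / se
            table["t_vs_ref"] = [t]
            table["p_vs_ref"] = [2 * stats.t.sf(abs(t), n_f - 1)]
        return EmmeanSummary(table=table, contrasts=contrasts, metric=value)

    resid = wide.to_numpy() - means.to_numpy() - wide.mean(axis=1).to_numpy()[:, None] + wide.to_numpy().mean()
    dfe = (n_f - 1) * (n_m - 1)
    mse = float((resid**2).sum() / dfe)
    se_mean = np.sqrt(mse / n_f)

    rows, sig = [], {}
    order = [m for m in models if m in wide.columns]
    for i, a in enumerate(order):
        for b in order[i + 1:]:
            diff = means[a] - means[b]
            qstat = abs(diff) / se_mean
            p = float(stats.studentized_range.sf(qstat, n_m, dfe))
            sig[(a, b)] = p < alpha
            rows.append(
                {"model_a": a, "model_b": b, "estimate": diff, "p_adj": p,
                 "significant": p < alpha}
            )
    letters = _letters_from_pairs(order, sig)
    table = pd.DataFrame(
        {
            "model": order,
            "emmean": [means[m] for m in order],
            "se": se_mean,
            "letters": [letters[m] for m in order],
        }
    )
    if reference is not None:
        # against a constant the fold blocks do not cancel, so use the plain
        # over-fold standard error of each model's mean
        se_ref = wide[order].std(axis=0, ddof=1).to_numpy() / np.sqrt(n_f)
        tvals = (table["emmean"].to_numpy() - reference) / se_ref
        table["t_vs_ref"] = tvals
        table["p_vs_ref"] = 2 * stats.t.sf(np.abs(tvals), n_f - 1)
    return EmmeanSummary(table=table, contrasts=pd.DataFrame(rows), metric=value)


# --------------------------------------------------------------------------
# cross-validation driver
# --------------------------------------------------------------------------

@dataclass
class ValidationResult:
    """Per-fold metrics and their aggregates for one model x trait."""

    model: str
    trait: str
    folds: pd.DataFrame  # fold, r_proxy, r_true, slope, T2, expected_acc, converged
    n_bar: float

    @property
    def accuracy(self) -> float:
        """EMMEAN fold correlation divided by EMMEAN r(s, Ybar) correction."""
        f = self.folds.dropna(subset=["r_proxy"])
        return float(f["r_proxy"].mean() / f["r_true"].mean())

    @property
    def mean_slope(self) -> float:
        return float(self.folds["slope"].mean())

    @property
    def se_slope(self) -> float:
        s = self.folds["slope"].dropna()
        return float(s.std(ddof=1) / np.sqrt(len(s)))

    @property
    def mean_T2(self) -> float:
        return float(self.folds["T2"].mean())

    @property
    def mean_expected_accuracy(self) -> float:
        return float(self.folds["expected_acc"].dropna().mean())

    def summary(self) -> dict:
        return {
            "model": self.model,
            "trait": self.trait,
            "accuracy": self.accuracy,
            "expected_accuracy": self.mean_expected_accuracy,
            "mean_dispersion_slope": self.mean_slope,
            "se_dispersion_slope": self.se_slope,
            "mean_T2": self.mean_T2,
            "n_folds": int(len(self.folds)),
            "n_bar": self.n_bar,
        }


def _component_spec(name: str) -> ModelSpec:
    if name == "IUSiM":
        return IUSIM
    spec = spec_for(name)
    if spec.level != "individual":
        raise ValueError("the r(s, Ybar) correction needs individual-level components")
    return spec


def mask_cages(data: ModelData, spec: ModelSpec, trait: str, cage_ids) -> ModelData:
    """Training copy with the masked cages' phenotypes removed.

    All trait columns the model uses are blanked for those cages (the fold
    masks *cages*); pedigree links always remain.
    """
    masked = set(cage_ids)
    age = trait[-2:]
    out = ModelData(pedigree=data.pedigree)
    if data.individuals is not None:
        ind = data.individuals.copy()
        hit = ind["cage_id"].isin(masked)
        ind.loc[hit, f"fs_{trait.lower()}"] = np.nan
        if spec.bivariate:
            ind.loc[hit, f"surv{age}"] = np.nan
        out.individuals = ind
    if data.cages is not None:
        cg = data.cages.copy()
        hit = cg["cage_id"].isin(masked)
        cg.loc[hit, f"mean_{trait.lower()}"] = np.nan
        if spec.bivariate:
            cg.loc[hit, f"surv_frac{age}"] = np.nan
        out.cages = cg
    return out


def cross_validate(
    data: ModelData,
    spec: ModelSpec | str,
    trait: str,
    k: int = 10,
    seed: int = 0,
    component_model: str = "IBAM",
    d: float = 20.0,
    n: float | None = None,
    m: float | None = None,
    fixed=DEFAULT_FIXED,
) -> ValidationResult:
    """Run the k-fold cage-masked cross-validation for one model and trait.

    ``component_model`` names the individual-level model whose per-fold
    variance components feed the r(s, Ybar) correction (the correction is
    a fixed scalar shared by all models, so the choice does not affect
    model ranking; 'IUSiM' is an equivalent cheaper alternative to the
    default).  ``d``/``n``/``m`` are the design constants of the
    expected-accuracy formulas; ``n`` and ``m`` default to their realized
    values.
    """
    if isinstance(spec, str):
        spec = spec_for(spec)
    if data.cages is None:
        raise ValueError("cross-validation needs the cage-level dataset")
    age = trait[-2:]
    cages = data.cages
    proxies_all = precorrect(cages, trait, fixed)
    folds = assign_folds(cages, k=k, seed=seed)
    n_bar = float(cages[f"n_alive{age}"].mean())
    sires_per_cage = cages.groupby("sire_id")["cage_id"].count()
    if m is None:
        m = float(sires_per_cage.mean())
    if n is None:
        n = float(cages.groupby("sire_id")["n_original"].sum().mean())

    comp_spec = _component_spec(component_model)
    rows = []
    for fold_id, cage_ids in folds.groupby("fold")["cage_id"]:
        train = mask_cages(data, spec, trait, cage_ids)
        fit = reml_fit(train, spec, trait, fixed=fixed)
        masked_proxies = proxies_all[proxies_all["cage_id"].isin(set(cage_ids))]
        s_hat = fit.sire_transmitting(masked_proxies["sire_id"].unique())
        if comp_spec.name == spec.name:
            comp_fit = fit
        else:
            comp_train = mask_cages(data, comp_spec, trait, cage_ids)
            comp_fit = reml_fit(comp_train, comp_spec, trait, fixed=fixed)
        r_true = r_true_proxy(comp_fit.varcomp, n_bar)
        try:
            exp_acc = expected_accuracy(spec, fit.varcomp, d, n, m)
        except ValueError:
            exp_acc = np.nan
        rows.append(
            {
                "fold": fold_id,
                "r_proxy": fold_accuracy(s_hat, masked_proxies),
                "r_true": r_true,
                "slope": dispersion_slope(masked_proxies, s_hat),
                "T2": total_heritable_ratio(fit.varcomp, spec),
                "expected_acc": exp_acc,
                "converged": fit.converged,
            }
        )
    return ValidationResult(
        model=spec.name, trait=trait, folds=pd.DataFrame(rows), n_bar=n_bar
    )
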