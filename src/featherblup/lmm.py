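"""Henderson mixed-model equations, REML variance components and BLUP.

Supports the model family used for recurrent-test feather score: univariate
or bivariate (FS + survival) linear mixed models at the individual or cage
level, with a pedigree-structured genetic effect (animal breeding values or
sire transmitting abilities) and optionally an independent random cage
effect.

Estimation maximizes the restricted log-likelihood directly over a
log-Cholesky parameterization of the covariance blocks (positive
semi-definiteness by construction, variances floored at 1e-8 of the
phenotypic variance).  Each likelihood evaluation costs one sparse
factorization of the mixed-model equations via the standard identity

    -2 logL_R = log|C| + log|R| + log|G| + y'Py + (n - p) log(2 pi),

where C is the MME coefficient matrix; cross-product matrices are
pre-computed once per fit, so an evaluation only rescales them.  Missing
records (dead birds have no FS) contribute no equations for that trait but
keep their survival record in bivariate models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .models import ModelSpec
from .pedigree import build_A_inverse

__all__ = [
    "ModelData",
    "VarianceComponents",
    "MMESystem",
    "FitResult",
    "fixed_design",
    "assemble_mme",
    "restricted_loglik",
    "reml_fit",
]

logger = logging.getLogger(__name__)

DEFAULT_FIXED = ("rt_number", "farm_date_cross", "feather_gene")
VARIANCE_FLOOR = 1e-8  # relative to phenotypic variance

_LOG2PI = float(np.log(2.0 * np.pi))


def _factorize(C: sp.spmatrix):
    """Sparse LU of the (symmetric PD) MME matrix.

    The minimum-degree ordering on C + C' keeps fill-in low for the
    arrow-shaped MME structure (dense fixed-effect rows bordering sparse
    pedigree blocks), where the default column ordering does not.
    """
    return spla.splu(
        C.tocsc(), permc_spec="MMD_AT_PLUS_A", options=dict(SymmetricMode=True)
    )


@dataclass
class ModelData:
    """The tables one fit may need: sire pedigree plus working datasets."""

    pedigree: pd.DataFrame
    individuals: pd.DataFrame | None = None
    cages: pd.DataFrame | None = None

    @classmethod
    def from_sim(cls, sim) -> "ModelData":
        return cls(pedigree=sim.pedigree, individuals=sim.individuals, cages=sim.cages)


@dataclass
class VarianceComponents:
    """Estimated covariance blocks, each a (t x t) matrix (t = #traits).

    ``genetic`` is on the animal scale (sigma2_A) for animal models and the
    sire scale (sigma2_S) for sire models; ``cage`` is None when the model
    has no cage term.
    """

    genetic: np.ndarray
    residual: np.ndarray
    cage: np.ndarray | None = None
    scale: str = "animal"
    traits: tuple = ("FS",)

    @property
    def n_traits(self) -> int:
        return self.genetic.shape[0]

    def component(self, name: str) -> np.ndarray | None:
        return {"genetic": self.genetic, "cage": self.cage, "residual": self.residual}[name]

    def phenotypic(self, trait_index: int = 0) -> float:
        """Phenotypic variance: genetic + residual (+ cage when fitted)."""
        tot = self.genetic[trait_index, trait_index] + self.residual[trait_index, trait_index]
        if self.cage is not None:
            tot += self.cage[trait_index, trait_index]
        return float(tot)

    def as_dict(self) -> dict:
        out = {"scale": self.scale, "traits": list(self.traits)}
        for name in ("genetic", "cage", "residual"):
            block = self.component(name)
            out[name] = None if block is None else np.asarray(block).tolist()
        return out


@dataclass
class MMESystem:
    """Assembled mixed-model equations C x = rhs with a solution map."""

    coeff: sp.csr_matrix
    rhs: np.ndarray
    partition: dict  # name -> (slice, labels); names like 'fixed:FS', 'genetic:FS'
    n_records: int
    p_fixed: int
    log_det_R: float
    log_det_G: float
    y_Rinv_y: float

    def solve(self) -> np.ndarray:
        return _factorize(self.coeff).solve(self.rhs)


# --------------------------------------------------------------------------
# design construction
# --------------------------------------------------------------------------

def _with_fdc(df: pd.DataFrame) -> pd.DataFrame:
    if "farm_date_cross" not in df.columns:
        df = df.copy()
        df["farm_date_cross"] = (
            df["farm"].astype(str)
            + "|"
            + df["housing_date"].astype(str)
            + "|"
            + df["cross"].astype(str)
        )
    return df


def fixed_design(df: pd.DataFrame, factors=DEFAULT_FIXED):
    """Full-rank fixed-effect design: intercept + treatment-coded factors.

    Returns ``(X, names)``.  The first level of each factor is dropped
    (treatment constraints); any remaining dependent columns (confounded
    levels) are removed via pivoted QR and reported in the names actually
    kept.  ``factors=None`` yields an empty design (no fixed effects).
    """
    if factors is None:
        return np.empty((len(df), 0)), []
    df = _with_fdc(df)
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for fac in factors:
        dummies = pd.get_dummies(df[fac].astype(str), prefix=fac, drop_first=True)
        for c in dummies.columns:
            cols.append(dummies[c].to_numpy(dtype=float))
            names.append(c)
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    return _full_rank(X, names)


def _full_rank(X: np.ndarray, names: list[str]):
    """Drop linearly dependent columns (pivoted QR), keeping original order."""
    if X.shape[1] == 0:
        return X, list(names)
    _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    keep = np.sort(piv[:rank])
    dropped = [names[i] for i in piv[rank:]]
    if dropped:
        logger.info(
            "dropping %d confounded fixed-effect columns (e.g. %s)",
            len(dropped),
            dropped[:3],
        )
    return X[:, keep], [names[i] for i in keep]


def _indicator(levels: pd.Series, index: pd.Index) -> sp.csr_matrix:
    """Sparse one-hot matrix mapping each record to its level column."""
    codes = index.get_indexer(levels)
    if (codes < 0).any():
        raise KeyError("record refers to a level missing from the index")
    n = len(levels)
    return sp.csr_matrix(
        (np.ones(n), (np.arange(n), codes)), shape=(n, len(index))
    )


def _extended_pedigree(pedigree: pd.DataFrame, extra_ids, extra_sires) -> pd.DataFrame:
    """Append daughters (known sire, unknown dam) to the sire pedigree."""
    extra = pd.DataFrame(
        {
            "animal": list(extra_ids),
            "sire": list(extra_sires),
            "dam": None,
            "generation": pedigree["generation"].max() + 1
            if "generation" in pedigree
            else None,
        }
    )
    base = pedigree[["animal", "sire", "dam"]].copy()
    base["generation"] = pedigree.get("generation")
    return pd.concat([base, extra[base.columns]], ignore_index=True)


# --------------------------------------------------------------------------
# prepared problem
# --------------------------------------------------------------------------

class _Frame:
    """A model + dataset prepared for repeated likelihood evaluations."""

    def __init__(self, data: ModelData, spec: ModelSpec, trait: str, fixed=DEFAULT_FIXED):
        self.spec, self.trait = spec, trait
        age = trait[-2:]
        df = data.individuals if spec.level == "individual" else data.cages
        if df is None:
            raise ValueError(f"{spec.name} needs {spec.level}-level records")
        df = _with_fdc(df).reset_index(drop=True)

        y1col = f"fs_{trait.lower()}" if spec.level == "individual" else f"mean_{trait.lower()}"
        y1 = df[y1col].to_numpy(dtype=float)
        if spec.bivariate:
            y2col = f"surv{age}" if spec.level == "individual" else f"surv_frac{age}"
            y2 = df[y2col].to_numpy(dtype=float)
            used = ~(np.isnan(y1) & np.isnan(y2))
        else:
            y2 = None
            used = ~np.isnan(y1)
        df = df.loc[used].reset_index(drop=True)
        y1 = y1[used]
        y2 = y2[used] if y2 is not None else None

        self.t = 2 if spec.bivariate else 1
        self.n_units = len(df)
        self.y = [y1, y2][: self.t]
        self.obs = [~np.isnan(y1)] + ([~np.isnan(y2)] if self.t == 2 else [])
        self.n_records = int(sum(m.sum() for m in self.obs))
        self.traits = (trait, f"SURV{age}") if self.t == 2 else (trait,)

        # genetic structure
        if spec.genetic == "sire":
            ped = data.pedigree
            gen_levels = df["sire_id"]
        elif spec.level == "individual":
            ped = _extended_pedigree(data.pedigree, df["animal_id"], df["sire_id"])
            gen_levels = df["animal_id"]
        else:  # CUAM: record assigned to the cage's representative animal
            ped = _extended_pedigree(
                data.pedigree, df["representative_animal_id"], df["sire_id"]
            )
            gen_levels = df["representative_animal_id"]
        rel = build_A_inverse(ped)
        self.Ainv = rel.values.tocoo()
        self.log_det_A = rel.log_det_A
        self.genetic_ids = pd.Index(rel.ids)
        self.n_gen = len(self.genetic_ids)
        Zg = _indicator(gen_levels, self.genetic_ids)

        self.cage_ids = pd.Index(df["cage_id"].unique()) if spec.cage_effect else None
        Zc = _indicator(df["cage_id"], self.cage_ids) if spec.cage_effect else None

        # per-trait fixed design, rank-fixed on that trait's observed rows
        self.X, self.xnames = [], []
        for k in range(self.t):
            Xf, names = fixed_design(df.loc[self.obs[k]], fixed)
            self.X.append(Xf)
            self.xnames.append(names)
        self.p_fixed = int(sum(x.shape[1] for x in self.X))

        # column layout: fixed per trait, then genetic per trait, then cage
        self.partition = {}
        off = 0
        for k in range(self.t):
            self.partition[f"fixed:{self.traits[k]}"] = (
                slice(off, off + self.X[k].shape[1]),
                self.xnames[k],
            )
            off += self.X[k].shape[1]
        self.gen_off = off
        for k in range(self.t):
            self.partition[f"genetic:{self.traits[k]}"] = (
                slice(off, off + self.n_gen),
                list(self.genetic_ids),
            )
            off += self.n_gen
        self.cage_off = off
        if spec.cage_effect:
            for k in range(self.t):
                self.partition[f"cage:{self.traits[k]}"] = (
                    slice(off, off + len(self.cage_ids)),
                    list(self.cage_ids),
                )
                off += len(self.cage_ids)
        self.ncols = off

        # per-trait design over that trait's observed rows
        self.W = []
        for k in range(self.t):
            rows = np.flatnonzero(self.obs[k])
            parts = []
            for j in range(self.t):
                sl = self.partition[f"fixed:{self.traits[j]}"][0]
                if j == k:
                    parts.append(sp.csr_matrix(self.X[k]))
                else:
                    parts.append(sp.csr_matrix((len(rows), sl.stop - sl.start)))
            for j in range(self.t):
                parts.append(Zg[rows] if j == k else sp.csr_matrix((len(rows), self.n_gen)))
            if spec.cage_effect:
                for j in range(self.t):
                    parts.append(
                        Zc[rows] if j == k else sp.csr_matrix((len(rows), len(self.cage_ids)))
                    )
            self.W.append(sp.hstack(parts, format="csr"))

        # residual patterns and pre-computed cross-products
        if self.t == 1:
            self.patterns = {"only1": np.flatnonzero(self.obs[0])}
        else:
            both = self.obs[0] & self.obs[1]
            self.patterns = {
                "both": np.flatnonzero(both),
                "only1": np.flatnonzero(self.obs[0] & ~self.obs[1]),
                "only2": np.flatnonzero(self.obs[1] & ~both),
            }
        self._precompute()
        self.varP = [float(np.nanvar(self.y[k][self.obs[k]])) for k in range(self.t)]

    # -- cross-products ----------------------------------------------------
    def _rows_in_W(self, k: int, unit_rows: np.ndarray) -> np.ndarray:
        """Positions of the given unit rows inside W[k] (trait-k observed)."""
        pos = np.full(self.n_units, -1)
        pos[np.flatnonzero(self.obs[k])] = np.arange(self.obs[k].sum())
        return pos[unit_rows]

    def _precompute(self):
        self.M = {}  # (pattern, j, k) -> W_j' W_k over pattern rows
        self.u = {}  # (pattern, j, k) -> W_j' y_k
        self.q = {}  # (pattern, j, k) -> y_j' y_k
        self.pat_n = {name: len(rows) for name, rows in self.patterns.items()}
        for name, rows in self.patterns.items():
            traits_here = {"both": (0, 1), "only1": (0,), "only2": (1,)}[name]
            sub = {k: self.W[k][self._rows_in_W(k, rows)] for k in traits_here}
            yv = {k: self.y[k][rows] for k in traits_here}
            for j in traits_here:
                for k in traits_here:
                    if j <= k:
                        self.M[(name, j, k)] = (sub[j].T @ sub[k]).tocsr()
                    self.u[(name, j, k)] = sub[j].T @ yv[k]
                    self.q[(name, j, k)] = float(yv[j] @ yv[k])

    # -- assembly at given covariance blocks --------------------------------
    def _rinv_weights(self, R0: np.ndarray):
        """Per-pattern scalar weights of R^-1 blocks."""
        w, logdetR = {}, 0.0
        if self.t == 1:
            r = R0[0, 0]
            w[("only1", 0, 0)] = 1.0 / r
            logdetR += self.pat_n["only1"] * np.log(r)
            return w, logdetR
        S = np.linalg.inv(R0)
        w[("both", 0, 0)], w[("both", 0, 1)], w[("both", 1, 1)] = S[0, 0], S[0, 1], S[1, 1]
        w[("only1", 0, 0)] = 1.0 / R0[0, 0]
        w[("only2", 1, 1)] = 1.0 / R0[1, 1]
        logdetR += self.pat_n["both"] * np.log(np.linalg.det(R0))
        logdetR += self.pat_n["only1"] * np.log(R0[0, 0])
        logdetR += self.pat_n["only2"] * np.log(R0[1, 1])
        return w, logdetR

    def _offset_coo(self, m: sp.coo_matrix, roff: int, coff: int, scale: float):
        return m.row + roff, m.col + coff, m.data * scale

    def assemble(self, vc: VarianceComponents) -> MMESystem:
        G0g = np.atleast_2d(np.asarray(vc.genetic, dtype=float))
        R0 = np.atleast_2d(np.asarray(vc.residual, dtype=float))
        w, log_det_R = self._rinv_weights(R0)

        C = sp.csr_matrix((self.ncols, self.ncols))
        rhs = np.zeros(self.ncols)
        yry = 0.0
        for (name, j, k), wt in w.items():
            M = self.M[(name, j, k)]
            if j == k:
                C = C + wt * M
                rhs += wt * self.u[(name, j, k)]
                yry += wt * self.q[(name, j, k)]
            else:
                C = C + wt * (M + M.T)
                rhs += wt * (self.u[(name, j, k)] + self.u[(name, k, j)])
                yry += 2.0 * wt * self.q[(name, j, k)]

        # genetic block: kron(G0^-1, A^-1)
        Gg_inv = np.linalg.inv(G0g)
        rows, cols, vals = [], [], []
        for j in range(self.t):
            for k in range(self.t):
                r, c, v = self._offset_coo(
                    self.Ainv,
                    self.gen_off + j * self.n_gen,
                    self.gen_off + k * self.n_gen,
                    Gg_inv[j, k],
                )
                rows.append(r)
                cols.append(c)
                vals.append(v)
        log_det_G = self.n_gen * float(np.log(np.linalg.det(G0g))) + self.t * self.log_det_A

        if self.spec.cage_effect:
            G0c = np.atleast_2d(np.asarray(vc.cage, dtype=float))
            Gc_inv = np.linalg.inv(G0c)
            nc = len(self.cage_ids)
            eye = sp.identity(nc, format="coo")
            for j in range(self.t):
                for k in range(self.t):
                    if Gc_inv[j, k] == 0.0:
                        continue
                    r, c, v = self._offset_coo(
                        eye, self.cage_off + j * nc, self.cage_off + k * nc, Gc_inv[j, k]
                    )
                    rows.append(r)
                    cols.append(c)
                    vals.append(v)
            log_det_G += nc * float(np.log(np.linalg.det(G0c)))

        Gterm = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.ncols, self.ncols),
        )
        C = (C + Gterm.tocsr()).tocsr()
        return MMESystem(
            coeff=C,
            rhs=rhs,
            partition=self.partition,
            n_records=self.n_records,
            p_fixed=self.p_fixed,
            log_det_R=log_det_R,
            log_det_G=log_det_G,
            y_Rinv_y=yry,
        )

    def loglik_and_solution(self, vc: VarianceComponents):
        mme = self.assemble(vc)
        lu = _factorize(mme.coeff)
        log_det_C = float(np.sum(np.log(np.abs(lu.U.diagonal()))))
        sol = lu.solve(mme.rhs)
        y_Py = mme.y_Rinv_y - float(sol @ mme.rhs)
        m2ll = (
            log_det_C
            + mme.log_det_R
            + mme.log_det_G
            + y_Py
            + (mme.n_records - mme.p_fixed) * _LOG2PI
        )
        return -0.5 * m2ll, sol, mme


# --------------------------------------------------------------------------
# covariance-block parameterization (log-Cholesky)
# --------------------------------------------------------------------------

class _BlockParam:
    """Maps an unconstrained vector to a PSD (t x t) block and back.

    t=1: theta = [log sd].  t=2 free covariance: [l11, l21, l22] with
    Sigma = L L', L = [[e^l11, 0], [l21, e^l22]].  t=2 diagonal (residual
    covariance fixed at zero): [l11, l22].
    """

    def __init__(self, t: int, diagonal: bool, floors: np.ndarray, scale_sd: np.ndarray):
        self.t, self.diagonal = t, diagonal
        self.n = 1 if t == 1 else (2 if diagonal else 3)
        self.floors = floors          # minimum variance per trait
        self.scale_sd = scale_sd      # typical sd per trait, for bounds

    def to_matrix(self, theta: np.ndarray) -> np.ndarray:
        if self.t == 1:
            return np.array([[np.exp(2.0 * theta[0])]])
        if self.diagonal:
            return np.diag(np.exp(2.0 * np.asarray(theta)))
        l11, l21, l22 = theta
        L = np.array([[np.exp(l11), 0.0], [l21, np.exp(l22)]])
        return L @ L.T

    def from_matrix(self, S: np.ndarray) -> np.ndarray:
        S = np.atleast_2d(S)
        if self.t == 1:
            return np.array([0.5 * np.log(max(S[0, 0], self.floors[0]))])
        if self.diagonal:
            return 0.5 * np.log(np.maximum(np.diag(S), self.floors))
        L = np.linalg.cholesky(S + 1e-12 * np.eye(2))
        return np.array([np.log(L[0, 0]), L[1, 0], np.log(L[1, 1])])

    def bounds(self):
        lo_var = 0.5 * np.log(self.floors)
        hi_var = np.log(self.scale_sd * 30.0)
        if self.t == 1:
            return [(lo_var[0], hi_var[0])]
        if self.diagonal:
            return [(lo_var[0], hi_var[0]), (lo_var[1], hi_var[1])]
        lim = 30.0 * self.scale_sd[1]
        return [(lo_var[0], hi_var[0]), (-lim, lim), (lo_var[1], hi_var[1])]


@dataclass
class FitResult:
    """REML variance components plus BLUP/BLUE solutions for one model."""

    spec: ModelSpec
    trait: str
    varcomp: VarianceComponents
    fixed_solutions: pd.Series
    genetic_solutions: pd.Series   # index (trait, animal)
    cage_solutions: pd.Series | None
    loglik: float
    converged: bool
    n_iterations: int
    n_records: int
    boundary: list = field(default_factory=list)

    def sire_transmitting(self, sire_ids, trait_index: int = 0) -> pd.Series:
        """Estimated sire effects (transmitting abilities) for given sires.

        Sire models return the sire solutions directly; animal models
        return half the sire's estimated breeding value.
        """
        tname = self.varcomp.traits[trait_index]
        sol = self.genetic_solutions.xs(tname, level=0).reindex(sire_ids)
        return sol if self.spec.genetic == "sire" else 0.5 * sol

    def sire_ebv(self, sire_ids, trait_index: int = 0) -> pd.Series:
        """Estimated breeding values of sires (twice the transmitting ability)."""
        return 2.0 * self.sire_transmitting(sire_ids, trait_index)

    def summary(self) -> dict:
        return {
            "model": self.spec.name,
            "trait": self.trait,
            "loglik": self.loglik,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "n_records": self.n_records,
            "boundary": self.boundary,
            "varcomp": self.varcomp.as_dict(),
        }


def _param_layout(frame: _Frame, diagonal_only: bool = False):
    """Block parameterizations for genetic, cage (optional) and residual.

    ``diagonal_only`` fixes every covariance at zero — used as a
    well-identified first stage before releasing the covariances, which
    keeps the optimizer off the near-flat residual-covariance ridge that
    arises because birds with an FS record all share the same survival
    code.
    """
    t = frame.t
    varP = np.asarray(frame.varP)
    floors = VARIANCE_FLOOR * varP
    blocks = [("genetic", _BlockParam(t, diagonal_only, floors, np.sqrt(varP)))]
    if frame.spec.cage_effect:
        blocks.append(("cage", _BlockParam(t, t == 1 or diagonal_only, floors, np.sqrt(varP))))
    diag_res = frame.spec.bivariate and frame.spec.residual_cov == "fixed_zero"
    blocks.append(
        ("residual", _BlockParam(t, t == 1 or diag_res or diagonal_only, floors, np.sqrt(varP)))
    )
    return blocks


def _theta_to_vc(frame: _Frame, blocks, theta: np.ndarray) -> VarianceComponents:
    parts, off = {}, 0
    for name, bp in blocks:
        parts[name] = bp.to_matrix(theta[off : off + bp.n])
        off += bp.n
    return VarianceComponents(
        genetic=parts["genetic"],
        residual=parts["residual"],
        cage=parts.get("cage"),
        scale=frame.spec.genetic,
        traits=frame.traits,
    )


def _initial_vc(frame: _Frame, init: VarianceComponents | None) -> VarianceComponents:
    if init is not None:
        return init
    t = frame.t
    varP = np.asarray(frame.varP)
    g_frac = 0.2 if frame.spec.genetic == "animal" else 0.05
    c_frac = 0.1 if frame.spec.cage_effect else 0.0
    genetic = np.diag(g_frac * varP)
    cage = np.diag(c_frac * varP) if frame.spec.cage_effect else None
    residual = np.diag((1.0 - g_frac - c_frac) * varP)
    return VarianceComponents(
        genetic=genetic, residual=residual, cage=cage,
        scale=frame.spec.genetic, traits=frame.traits,
    )


def _solutions_to_series(frame: _Frame, sol: np.ndarray):
    fixed, genetic, cage = [], [], []
    for key, (sl, labels) in frame.partition.items():
        kind, tname = key.split(":")
        series = pd.Series(
            sol[sl], index=pd.MultiIndex.from_product([[tname], labels])
        )
        {"fixed": fixed, "genetic": genetic, "cage": cage}[kind].append(series)
    return (
        pd.concat(fixed) if fixed else pd.Series(dtype=float),
        pd.concat(genetic),
        pd.concat(cage) if cage else None,
    )


def assemble_mme(
    data: ModelData,
    spec: ModelSpec,
    trait: str,
    varcomp: VarianceComponents,
    fixed=DEFAULT_FIXED,
) -> MMESystem:
    """Build Henderson's mixed-model equations at given variance components."""
    return _Frame(data, spec, trait, fixed).assemble(varcomp)


def restricted_loglik(
    data: ModelData,
    spec: ModelSpec,
    trait: str,
    varcomp: VarianceComponents,
    fixed=DEFAULT_FIXED,
) -> float:
    """Restricted log-likelihood (constants included) at given components."""
    frame = _Frame(data, spec, trait, fixed)
    return frame.loglik_and_solution(varcomp)[0]


def reml_fit(
    data: ModelData,
    spec: ModelSpec,
    trait: str,
    init: VarianceComponents | None = None,
    fixed=DEFAULT_FIXED,
    max_iter: int = 200,
    tol: float = 1e-9,
) -> FitResult:
    """Estimate variance components by REML and solve the MME at the optimum.

    Non-convergence within ``max_iter`` is flagged on the result, not
    raised; components that end on the variance floor are listed in
    ``boundary``.
    """
    frame = _Frame(data, spec, trait, fixed)
    vc0 = _initial_vc(frame, init)

    def _optimize(blocks, start_vc, eps):
        theta0 = np.concatenate(
            [bp.from_matrix(start_vc.component(name)) for name, bp in blocks]
        )
        bounds = [b for _, bp in blocks for b in bp.bounds()]

        def negloglik(theta):
            vc = _theta_to_vc(frame, blocks, theta)
            try:
                ll, _, _ = frame.loglik_and_solution(vc)
            except (RuntimeError, np.linalg.LinAlgError):
                return 1e12
            if not np.isfinite(ll):
                return 1e12
            return -ll

        return scipy.optimize.minimize(
            negloglik,
            theta0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-7, "eps": eps},
        )

    # Finite-difference steps trade roundoff in the likelihood (which grows
    # with the record count) against truncation error; the wider step for
    # the bivariate stage keeps the gradient usable on its flatter surface.
    n_stage1 = 0
    if frame.t == 2 and init is None:
        # stage 1: variances only (covariances fixed at 0) — well identified
        diag_blocks = _param_layout(frame, diagonal_only=True)
        res1 = _optimize(diag_blocks, vc0, eps=1e-5)
        vc0 = _theta_to_vc(frame, diag_blocks, res1.x)
        n_stage1 = int(res1.nit)
    blocks = _param_layout(frame)
    res = _optimize(blocks, vc0, eps=1e-5 if frame.t == 1 else 1e-4)
    # restarting resets the quasi-Newton Hessian, which escapes premature
    # stalls on the nearly flat residual-covariance ridge of bivariate fits
    restarts = 0
    while frame.t == 2 and restarts < 3:
        res2 = _optimize(blocks, _theta_to_vc(frame, blocks, res.x), eps=1e-4)
        improved = res.fun - res2.fun
        res2.nit += res.nit
        res = res2
        restarts += 1
        if improved < 1e-4:
            break
    res.nit += n_stage1
    vc = _theta_to_vc(frame, blocks, res.x)
    ll, sol, _ = frame.loglik_and_solution(vc)
    fixed_s, genetic_s, cage_s = _solutions_to_series(frame, sol)

    boundary = []
    off = 0
    for name, bp in blocks:
        th = res.x[off : off + bp.n]
        block = bp.to_matrix(th)
        for k in range(frame.t):
            # within two orders of magnitude of the floor: effectively zero
            if block[k, k] <= 100.0 * bp.floors[k]:
                boundary.append(f"{name}:{frame.traits[k]}")
        off += bp.n
    return FitResult(
        spec=spec,
        trait=trait,
        varcomp=vc,
        fixed_solutions=fixed_s,
        genetic_solutions=genetic_s,
        cage_solutions=cage_s,
        loglik=float(ll),
        converged=bool(res.success),
        n_iterations=int(res.nit),
        n_records=frame.n_records,
        boundary=boundary,
    )
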