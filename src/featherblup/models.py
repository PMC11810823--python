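"""Catalogue of the six linear mixed models compared for feather score.

Naming: I/C = individual- or cage-level records, B/U = bivariate (FS with
survival at the matching scoring age) or univariate, AM/SiM = animal or
sire genetic parameterization.

* IBAM  — individual bivariate animal model: per-animal breeding values
  (pedigree A over sires *and* daughters), random cage effect, FS +
  survival.  The FS-survival residual covariance is fixed at zero: birds
  with an FS record are exactly the survivors, whose survival record is
  constant, so that covariance carries no information.
* IUAM  — individual univariate animal model (FS only), random cage effect.
* CUAM  — cage univariate animal model: the cage-mean record is assigned to
  one random member of the cage ("representative animal"); no cage effect
  (one record per cage).
* IBSiM — individual bivariate sire model: per-sire effects with A over the
  sire pedigree, random cage effect; residual covariance free (3/4 of the
  additive variance sits in the residual, which leaves information to
  estimate it).
* CBSiM — cage bivariate sire model: cage means of FS and the cage survival
  fraction; no cage effect.
* CUSiM — cage univariate sire model: the simplest model, y = Xb + Zs + e.

Fixed effects are identical across models: test batch (RT number), the
farm x housing-date x cross interaction (one combined factor level per
unique triple), and the fast-feathering gene.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ModelSpec", "MODEL_NAMES", "spec_for", "all_specs", "FIXED_EFFECTS"]

#: factors of the shared fixed-effect structure (column names after adding
#: the combined farm x housing-date x cross factor, see lmm.fixed_design)
FIXED_EFFECTS = ("rt_number", "farm_date_cross", "feather_gene")

MODEL_NAMES = ("IBAM", "IUAM", "CUAM", "IBSiM", "CBSiM", "CUSiM")


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one model.

    ``level``: 'individual' or 'cage' records; ``genetic``: 'animal'
    (pedigree-structured effect per recorded animal) or 'sire';
    ``bivariate``: fit FS jointly with survival at the same scoring age;
    ``cage_effect``: independent random cage term (individual level only);
    ``residual_cov``: 'free' or 'fixed_zero' for the bivariate FS-survival
    residual covariance.
    """

    name: str
    level: str
    genetic: str
    bivariate: bool
    cage_effect: bool
    residual_cov: str = "free"

    def __post_init__(self):
        assert self.level in ("individual", "cage")
        assert self.genetic in ("animal", "sire")
        if self.level == "cage":
            assert not self.cage_effect, "cage-level models have no cage term"

    @property
    def traits_label(self) -> str:
        return "FS+survival" if self.bivariate else "FS"


_CATALOGUE = {
    "IBAM": ModelSpec("IBAM", "individual", "animal", True, True, "fixed_zero"),
    "IUAM": ModelSpec("IUAM", "individual", "animal", False, True),
    "CUAM": ModelSpec("CUAM", "cage", "animal", False, False),
    "IBSiM": ModelSpec("IBSiM", "individual", "sire", True, True, "free"),
    "CBSiM": ModelSpec("CBSiM", "cage", "sire", True, False, "free"),
    "CUSiM": ModelSpec("CUSiM", "cage", "sire", False, False),
}


def spec_for(name: str) -> ModelSpec:
    """Look up a model by name; raises with the list of valid names."""
    try:
        return _CATALOGUE[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; valid models: {', '.join(MODEL_NAMES)}"
        ) from None


def all_specs() -> list[ModelSpec]:
    return [_CATALOGUE[n] for n in MODEL_NAMES]
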