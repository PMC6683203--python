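"""Submodel block registry and the joint parameter set.

The experiment is modelled as a collection of independent *blocks*, one per
outcome: four stage-conditional mortality logits per generation, normal or
log-normal models for development time and body masses, and beta models with a
logistic link for the three body-composition fractions.  Every block is a
fixed-effects GLM on a small set of named covariate terms; the registry below
is the single source of truth for block structure (family, generation,
response column, stage-inclusion rule and covariate order) used by the
simulator, the likelihood code and the sampler alike.

Coding conventions (shared by every block):

* mortality blocks model **death** (death = 1), so survival odds ratios are
  ``exp(-coefficient)``;
* treatment indicators: control = 0, insecticide = 1 (own treatment ``within``
  and maternal treatment ``trans``);
* sex indicator: female = 0, male = 1;
* body-mass covariates (``maternal_mass``, ``larval_mass``) enter uncentered,
  in mg.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

#: Recognised covariate term names, in canonical order.
TERMS = (
    "intercept",
    "within",
    "trans",
    "male",
    "maternal_mass",
    "larval_mass",
    "within_x_trans",
    "male_x_trans",
)

#: Life stages in chronological order.  "24h" is the treatment-exposure window.
STAGES = ("24h", "larval", "pupal", "adult")

#: Interaction terms between the two insecticide treatments are never dropped
#: during model reduction.
TREATMENT_INTERACTIONS = frozenset({"within_x_trans"})


@dataclass(frozen=True)
class BlockDef:
    """Static definition of one submodel block."""

    name: str
    family: str                # "mortality" | "normal" | "lognormal" | "beta"
    generation: int            # 1 or 2
    outcome: str               # response column in the cohort table
    inclusion: str             # stage-survival predicate, see model.build_design
    covariates: tuple[str, ...]

    @property
    def scale_term(self) -> str | None:
        """Name of the nuisance scale parameter, if the family has one."""
        if self.family in ("normal", "lognormal"):
            return "sigma"
        if self.family == "beta":
            return "phi"
        return None

    @property
    def terms(self) -> tuple[str, ...]:
        st = self.scale_term
        return self.covariates + ((st,) if st else ())


def _b(name, family, generation, outcome, inclusion, covariates):
    return name, BlockDef(name, family, generation, outcome, inclusion,
                          tuple(covariates))


_G1_SURV = ("intercept", "within")
_G2_SURV = ("intercept", "within", "trans", "maternal_mass", "within_x_trans")
_G1_TRAIT = ("intercept", "within", "male")
_G2_TRAIT = ("intercept", "within", "male", "male_x_trans", "trans",
             "within_x_trans", "maternal_mass")
_G2_BETA = ("intercept", "within", "male", "trans", "within_x_trans",
            "maternal_mass")

#: Full-model registry.  The adult-stage mortality block of generation 2 has no
#: treatment interaction: too few deaths remained to estimate it.
BLOCKS: "OrderedDict[str, BlockDef]" = OrderedDict([
    _b("g1_surv_24h", "mortality", 1, "died_24h", "all",
       ("intercept", "within", "larval_mass")),
    _b("g1_surv_larval", "mortality", 1, "died_larval", "survived_24h", _G1_SURV),
    _b("g1_surv_pupal", "mortality", 1, "died_pupal", "survived_larval", _G1_SURV),
    _b("g1_surv_adult", "mortality", 1, "died_adult", "survived_pupal", _G1_SURV),
    _b("g1_devtime", "lognormal", 1, "dev_time_days", "survived_pupal", _G1_TRAIT),
    _b("g1_mass_emergence", "normal", 1, "mass_emergence_mg", "survived_pupal",
       _G1_TRAIT),
    _b("g1_mass_day10", "normal", 1, "mass_day10_mg", "survived_adult", _G1_TRAIT),
    _b("g2_surv_24h", "mortality", 2, "died_24h", "all", _G2_SURV),
    _b("g2_surv_larval", "mortality", 2, "died_larval", "survived_24h", _G2_SURV),
    _b("g2_surv_pupal", "mortality", 2, "died_pupal", "survived_larval", _G2_SURV),
    _b("g2_surv_adult", "mortality", 2, "died_adult", "survived_pupal",
       ("intercept", "within", "trans", "maternal_mass")),
    _b("g2_devtime", "lognormal", 2, "dev_time_days", "survived_pupal", _G2_TRAIT),
    _b("g2_mass_emergence", "normal", 2, "mass_emergence_mg", "survived_pupal",
       _G2_TRAIT),
    _b("g2_mass_day7", "normal", 2, "mass_day7_mg", "survived_adult", _G2_TRAIT),
    _b("g2_mass_day14", "normal", 2, "mass_day14_mg", "survived_adult", _G2_TRAIT),
    _b("g2_lipid", "beta", 2, "lipid_frac", "survived_adult", _G2_BETA),
    _b("g2_water", "beta", 2, "water_frac", "survived_adult", _G2_BETA),
    _b("g2_drymass", "beta", 2, "drymass_frac", "survived_adult", _G2_BETA),
])

SURVIVAL_BLOCKS = tuple(n for n, b in BLOCKS.items() if b.family == "mortality")
GEN1_BLOCKS = tuple(n for n, b in BLOCKS.items() if b.generation == 1)
GEN2_BLOCKS = tuple(n for n, b in BLOCKS.items() if b.generation == 2)


def param_name(block: str, term: str) -> str:
    """Canonical flat name for one coefficient, ``"block:term"``."""
    return f"{block}:{term}"


def split_param_name(name: str) -> tuple[str, str]:
    block, _, term = name.partition(":")
    if not term:
        raise ValueError(f"not a 'block:term' parameter name: {name!r}")
    return block, term


@dataclass
class ParameterSet:
    """Every coefficient of every submodel, keyed by block and term.

    ``blocks[name]`` maps term names (covariates plus the block's scale
    parameter where applicable) to values.  A ParameterSet may cover only a
    subset of the registry — validation is performed against the blocks a
    caller actually needs.
    """

    blocks: dict[str, dict[str, float]] = field(default_factory=dict)

    def validate(self, required: "list[str] | tuple[str, ...] | None" = None) -> None:
        """Check completeness and positivity of scales.

        Raises :class:`ConfigurationError` naming the first missing block or
        term.
        """
        names = list(required) if required is not None else list(self.blocks)
        for name in names:
            if name not in BLOCKS:
                raise ConfigurationError(f"unknown submodel block {name!r}")
            if name not in self.blocks:
                raise ConfigurationError(f"parameter block {name!r} is missing")
            have = self.blocks[name]
            for term in BLOCKS[name].terms:
                if term not in have:
                    raise ConfigurationError(
                        f"parameter block {name!r} is missing term {term!r}")
            st = BLOCKS[name].scale_term
            if st is not None and not have[st] > 0:
                raise ConfigurationError(
                    f"scale parameter {param_name(name, st)} must be positive "
                    f"(got {have[st]!r})")

    def coef(self, block: str, covariates: "tuple[str, ...] | None" = None) -> np.ndarray:
        """Coefficient vector for ``block`` in covariate order."""
        if block not in self.blocks:
            raise ConfigurationError(f"parameter block {block!r} is missing")
        covs = covariates if covariates is not None else BLOCKS[block].covariates
        vals = self.blocks[block]
        missing = [t for t in covs if t not in vals]
        if missing:
            raise ConfigurationError(
                f"parameter block {block!r} is missing terms {missing}")
        return np.array([vals[t] for t in covs], dtype=float)

    def scale(self, block: str) -> float:
        st = BLOCKS[block].scale_term
        if st is None:
            raise ConfigurationError(f"block {block!r} has no scale parameter")
        return float(self.blocks[block][st])

    def flatten(self) -> "OrderedDict[str, float]":
        out: "OrderedDict[str, float]" = OrderedDict()
        for name in BLOCKS:
            if name in self.blocks:
                for term in BLOCKS[name].terms:
                    if term in self.blocks[name]:
                        out[param_name(name, term)] = float(self.blocks[name][term])
        # preserve any reduced/extra blocks not in registry order
        for name, vals in self.blocks.items():
            for term, v in vals.items():
                out.setdefault(param_name(name, term), float(v))
        return out

    @classmethod
    def from_flat(cls, flat: dict) -> "ParameterSet":
        blocks: dict[str, dict[str, float]] = {}
        for name, value in flat.items():
            block, term = split_param_name(name)
            blocks.setdefault(block, {})[term] = float(value)
        return cls(blocks)

    def updated(self, flat: dict) -> "ParameterSet":
        """Copy with flat ``block:term`` entries overriding current values."""
        blocks = {b: dict(v) for b, v in self.blocks.items()}
        for name, value in flat.items():
            block, term = split_param_name(name)
            blocks.setdefault(block, {})[term] = float(value)
        return ParameterSet(blocks)

    def copy(self) -> "ParameterSet":
        return ParameterSet({b: dict(v) for b, v in self.blocks.items()})
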