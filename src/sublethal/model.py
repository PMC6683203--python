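"""Joint probability model: design matrices, likelihoods, priors, reduction.

The joint log-likelihood of a two-generation cohort factorises over submodel
blocks because each block owns a disjoint outcome and survival at each life
stage is modelled *conditionally* on having survived all earlier stages:
individuals dead before a stage simply never enter that stage's design
matrix.  This module builds those stage-conditional design matrices, provides
the per-family log-likelihood kernels (death-logit Bernoulli, (log-)normal,
and beta with a logistic link on the mean), the prior machinery (including
using a first-generation posterior as the second generation's prior), and the
interaction-dropping model-reduction rule.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

from .blocks import BLOCKS, TREATMENT_INTERACTIONS, BlockDef, ParameterSet, param_name
from .errors import ConfigurationError, ReductionError, SchemaError

_LOG_2PI = math.log(2.0 * math.pi)

#: covariate term -> cohort-table column it is computed from
TERM_SOURCES = {
    "within": "within_treatment",
    "trans": "maternal_treatment",
    "male": "sex",
    "maternal_mass": "maternal_mass10_mg",
    "larval_mass": "larval_mass_mg",
}

_INTERACTIONS = {
    "within_x_trans": ("within", "trans"),
    "male_x_trans": ("male", "trans"),
}

_STAGE_PREREQS = {
    "all": (),
    "survived_24h": ("died_24h",),
    "survived_larval": ("died_24h", "died_larval"),
    "survived_pupal": ("died_24h", "died_larval", "died_pupal"),
    "survived_adult": ("died_24h", "died_larval", "died_pupal", "died_adult"),
}


@dataclass(frozen=True)
class SubmodelSpec:
    """One outcome's regression specification.

    ``inclusion`` names the stages an individual must have survived to
    contribute (one of ``all``, ``survived_24h``, ``survived_larval``,
    ``survived_pupal``, ``survived_adult``).
    """

    name: str
    outcome: str
    family: str
    generation: int
    covariates: tuple[str, ...]
    inclusion: str

    def __post_init__(self):
        if self.family not in ("mortality", "normal", "lognormal", "beta"):
            raise ConfigurationError(f"unknown family {self.family!r}")
        if self.inclusion not in _STAGE_PREREQS:
            raise ConfigurationError(f"unknown inclusion rule {self.inclusion!r}")
        if not self.covariates or self.covariates[0] != "intercept":
            raise ConfigurationError(
                f"submodel {self.name!r}: covariates must start with 'intercept'")
        for term, mains in _INTERACTIONS.items():
            if term in self.covariates:
                missing = [m for m in mains if m not in self.covariates]
                if missing:
                    raise ConfigurationError(
                        f"submodel {self.name!r}: interaction {term!r} requires "
                        f"main effects {missing}")

    @property
    def scale_term(self) -> str | None:
        if self.family in ("normal", "lognormal"):
            return "sigma"
        if self.family == "beta":
            return "phi"
        return None

    @classmethod
    def from_block(cls, block: BlockDef) -> "SubmodelSpec":
        return cls(block.name, block.outcome, block.family, block.generation,
                   block.covariates, block.inclusion)

    def drop_covariates(self, terms) -> "SubmodelSpec":
        keep = tuple(c for c in self.covariates if c not in set(terms))
        return dataclasses.replace(self, covariates=keep)


def submodel_specs(names=None) -> list[SubmodelSpec]:
    """Full-model specifications for the registry blocks (default: all)."""
    names = list(BLOCKS) if names is None else list(names)
    bad = [n for n in names if n not in BLOCKS]
    if bad:
        raise ConfigurationError(f"unknown submodel blocks {bad}")
    return [SubmodelSpec.from_block(BLOCKS[n]) for n in names]


def survival_specs() -> list[SubmodelSpec]:
    """The eight mortality blocks plus the gen-1 10-day-mass block.

    The mass block is included because it is the prior of the within-sampler
    imputation of missing maternal 10-day mass, which the gen-2 mortality
    blocks consume as a covariate.
    """
    names = [n for n, b in BLOCKS.items() if b.family == "mortality"]
    return submodel_specs(names + ["g1_mass_day10"])


def squeeze_fractions(y, n: int):
    """Boundary smoothing for unit-interval outcomes.

    Maps ``y`` to ``(y * (n - 1) + 0.5) / n`` so values touch neither 0 nor 1;
    applied symmetrically when simulating and when fitting beta submodels.
    """
    y = np.asarray(y, dtype=float)
    if n < 1:
        raise ValueError("n must be a positive count")
    return (y * (n - 1) + 0.5) / n


def inclusion_mask(frame: pd.DataFrame, spec: SubmodelSpec) -> pd.Series:
    """Boolean mask of individuals eligible for ``spec``'s design matrix."""
    if "generation" not in frame.columns:
        raise SchemaError("cohort table has no 'generation' column")
    mask = frame["generation"].astype(float) == spec.generation
    for col in _STAGE_PREREQS[spec.inclusion]:
        if col not in frame.columns:
            raise SchemaError(f"cohort table has no {col!r} column")
        mask &= frame[col].astype(float) == 0.0
    return mask


@dataclass
class DesignMatrix:
    """Stage-conditional design data for one submodel."""

    spec: SubmodelSpec
    y: np.ndarray | None
    X: np.ndarray
    index: pd.Index
    columns: tuple[str, ...]
    missing_mass: np.ndarray    # rows flagged for maternal-mass imputation

    @property
    def n(self) -> int:
        return self.X.shape[0]


def _indicator(sub: pd.DataFrame, term: str, spec: SubmodelSpec) -> np.ndarray:
    col = TERM_SOURCES[term]
    if col not in sub.columns:
        raise SchemaError(
            f"covariate {term!r} of submodel {spec.name!r} needs column {col!r}")
    vals = sub[col]
    if vals.isna().any():
        raise SchemaError(
            f"column {col!r} has missing values among individuals included in "
            f"submodel {spec.name!r}")
    positive = {"within": "insecticide", "trans": "insecticide", "male": "male"}
    levels = {"within": ("control", "insecticide"),
              "trans": ("control", "insecticide"),
              "male": ("female", "male")}
    bad = set(vals.unique()) - set(levels[term])
    if bad:
        raise SchemaError(f"column {col!r} has unexpected levels {sorted(bad)}")
    return (vals == positive[term]).to_numpy(dtype=float)


def build_design(data, spec: SubmodelSpec, response: bool = True) -> DesignMatrix:
    """Build (response, covariate matrix, row index) for one submodel.

    Rows are exactly the individuals of the spec's generation that survived
    all stages named by the inclusion rule (and, when ``response`` is True,
    have a non-missing outcome).  Rows with missing maternal 10-day mass are
    retained and flagged in ``missing_mass`` for within-sampler imputation
    rather than dropped; the corresponding matrix entries are NaN until the
    sampler fills them.
    """
    if not isinstance(data, pd.DataFrame):
        from .cohort import cohort_to_frame
        data = cohort_to_frame(data)
    mask = inclusion_mask(data, spec)
    if response:
        if spec.outcome not in data.columns:
            raise SchemaError(f"cohort table has no outcome column {spec.outcome!r}")
        mask &= data[spec.outcome].notna()
    sub = data.loc[mask]
    n = len(sub)

    cols = []
    missing_mass = np.zeros(n, dtype=bool)
    base: dict[str, np.ndarray] = {}
    for term in spec.covariates:
        if term == "intercept":
            arr = np.ones(n)
        elif term in ("within", "trans", "male"):
            arr = _indicator(sub, term, spec)
            base[term] = arr
        elif term in ("maternal_mass", "larval_mass"):
            col = TERM_SOURCES[term]
            if col not in sub.columns:
                raise SchemaError(
                    f"covariate {term!r} of submodel {spec.name!r} needs "
                    f"column {col!r}")
            arr = sub[col].to_numpy(dtype=float)
            nan = np.isnan(arr)
            if nan.any():
                if term == "maternal_mass":
                    missing_mass |= nan
                else:
                    raise SchemaError(
                        f"column {col!r} has missing values among individuals "
                        f"included in submodel {spec.name!r}")
        elif term in _INTERACTIONS:
            a, b = _INTERACTIONS[term]
            for m in (a, b):
                if m not in base:
                    base[m] = _indicator(sub, m, spec)
            arr = base[a] * base[b]
        else:
            raise SchemaError(f"unknown covariate term {term!r}")
        cols.append(arr)

    X = np.column_stack(cols) if cols else np.empty((n, 0))
    y = None
    if response:
        y = sub[spec.outcome].to_numpy(dtype=float)
        if spec.family == "beta" and n > 0:
            y = squeeze_fractions(y, n)
    return DesignMatrix(spec, y, X, sub.index, tuple(spec.covariates), missing_mass)


# ---------------------------------------------------------------------------
# likelihood kernels


def loglik_mortality(coef, X, deaths) -> float:
    """Bernoulli log-likelihood of stage deaths on the logit scale.

    ``deaths`` is 1 for individuals that died at the stage, 0 for survivors;
    the death probability is ``expit(X @ coef)``.
    """
    coef = np.asarray(coef, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    d = np.asarray(deaths, dtype=float).ravel()
    if not np.isin(d, (0.0, 1.0)).all():
        raise ValueError("death indicators must be 0 or 1")
    eta = X @ coef
    return float(d @ eta - np.logaddexp(0.0, eta).sum())


def loglik_gaussian(coef, scale, X, y, log_transform: bool = False) -> float:
    """Normal log-likelihood of ``y`` (or ``log y``) around ``X @ coef``.

    With ``log_transform`` the Jacobian term ``-sum(log y)`` is included so
    that densities remain comparable across transformed and untransformed
    outcomes.
    """
    if not scale > 0:
        raise ValueError("scale must be positive")
    coef = np.asarray(coef, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if log_transform:
        if np.any(y <= 0):
            raise ValueError("log-transformed outcomes must be positive")
        t = np.log(y)
        jac = -t.sum()
    else:
        t = y
        jac = 0.0
    z = (t - X @ coef) / scale
    return float(-0.5 * (z @ z) - n * (math.log(scale) + 0.5 * _LOG_2PI) + jac)


def loglik_beta(coef, precision, X, y) -> float:
    """Beta log-likelihood with logistic link on the mean.

    ``y`` must lie strictly inside (0, 1); the density is
    ``Beta(mu * phi, (1 - mu) * phi)`` with ``mu = expit(X @ coef)``.
    """
    if not precision > 0:
        raise ValueError("precision must be positive")
    coef = np.asarray(coef, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if y.size and (y.min() <= 0.0 or y.max() >= 1.0):
        raise ValueError("beta outcomes must lie strictly inside (0, 1)")
    mu = expit(X @ coef)
    mu = np.clip(mu, 1e-12, 1.0 - 1e-12)
    a = mu * precision
    b = (1.0 - mu) * precision
    ll = (gammaln(precision) - gammaln(a) - gammaln(b)
          + (a - 1.0) * np.log(y) + (b - 1.0) * np.log1p(-y))
    return float(ll.sum())


def submodel_loglik(params: ParameterSet, dm: DesignMatrix) -> float:
    """Log-likelihood of one built design under a parameter set."""
    spec = dm.spec
    coef = params.coef(spec.name, spec.covariates)
    if spec.family == "mortality":
        return loglik_mortality(coef, dm.X, dm.y)
    if spec.family in ("normal", "lognormal"):
        return loglik_gaussian(coef, params.scale(spec.name), dm.X, dm.y,
                               log_transform=spec.family == "lognormal")
    return loglik_beta(coef, params.scale(spec.name), dm.X, dm.y)


def joint_loglik(params: ParameterSet, data, specs) -> float:
    """Sum of component log-likelihoods over submodels (they are disjoint)."""
    return sum(submodel_loglik(params, build_design(data, s)) for s in specs)


# ---------------------------------------------------------------------------
# priors


def _halfnormal_logpdf(x: float, scale: float) -> float:
    if x <= 0:
        return -math.inf
    return (math.log(2.0) - math.log(scale) - 0.5 * _LOG_2PI
            - 0.5 * (x / scale) ** 2)


def _gamma_logpdf(x: float, shape: float, rate: float) -> float:
    if x <= 0:
        return -math.inf
    return (shape * math.log(rate) - float(gammaln(shape))
            + (shape - 1.0) * math.log(x) - rate * x)


@dataclass
class PriorSpec:
    """Priors for every parameter, with per-coefficient normal overrides.

    Defaults are weakly informative *on the scale each block lives on*:
    Normal(0, 10^2) on intercepts and Normal(0, 2.5^2) on the other
    coefficients of the logit-scale blocks (mortality, beta and log-scale
    development time) — logit effects beyond a few units are not credible,
    and a 10-unit slope scale is known to inflate posterior means away from
    zero in rare-event stages; Normal(0, 100^2) on every coefficient of the
    mg-scale normal blocks (a 10-unit scale is *informative* for body masses
    around 100-180 mg and shrinks them visibly); Half-Normal(10) on residual
    scales; Gamma(0.01, 0.01) on beta precisions.  ``coef_overrides`` maps
    flat ``"block:term"`` names to ``(loc, scale)`` pairs; this is how a
    first-generation posterior is plugged in as the second generation's
    prior.

    With ``autoscale`` (default), slope priors of the logit/log-scale blocks
    are divided by the predictor's sample SD when the sampler sees data, in
    the style of rstanarm's autoscaled defaults: a balanced binary indicator
    gets an effective scale of ~5 while an uncentered mg-scale mass covariate
    gets ~2.5/18 — per-unit scales that mean the same thing whatever the
    covariate's units.  Explicit overrides are never autoscaled.
    """

    coef_loc: float = 0.0
    intercept_scale: float = 10.0
    coef_scale: float = 2.5
    normal_coef_scale: float = 100.0
    sigma_scale: float = 10.0
    phi_shape: float = 0.01
    phi_rate: float = 0.01
    autoscale: bool = True
    coef_overrides: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        for scale in (self.coef_scale, self.intercept_scale,
                      self.normal_coef_scale, self.sigma_scale,
                      self.phi_shape, self.phi_rate):
            if not scale > 0:
                raise ConfigurationError("prior scales must be positive")
        for name, (_, s) in self.coef_overrides.items():
            if not s > 0:
                raise ConfigurationError(
                    f"prior scale for {name} must be positive")

    def coef_params(self, block: str, covariates) -> tuple[np.ndarray, np.ndarray]:
        is_normal = block in BLOCKS and BLOCKS[block].family == "normal"
        locs, scales = [], []
        for term in covariates:
            if is_normal:
                default_scale = self.normal_coef_scale
            elif term == "intercept":
                default_scale = self.intercept_scale
            else:
                default_scale = self.coef_scale
            loc, sc = self.coef_overrides.get(
                param_name(block, term), (self.coef_loc, default_scale))
            locs.append(loc)
            scales.append(sc)
        return np.array(locs), np.array(scales)

    def coef_logpdf(self, block: str, covariates, values) -> float:
        locs, scales = self.coef_params(block, covariates)
        z = (np.asarray(values, dtype=float) - locs) / scales
        return float(-0.5 * (z @ z) - np.log(scales).sum()
                     - 0.5 * _LOG_2PI * len(locs))

    def scale_logpdf(self, family: str, value: float) -> float:
        if family == "beta":
            return _gamma_logpdf(value, self.phi_shape, self.phi_rate)
        return _halfnormal_logpdf(value, self.sigma_scale)

    @classmethod
    def from_summaries(cls, summaries, base: "PriorSpec | None" = None) -> "PriorSpec":
        """Normal priors centred on posterior summaries (mean, sd).

        ``summaries`` may be a DataFrame with ``parameter``/``mean``/``sd``
        columns or a mapping of flat parameter names to objects with ``mean``
        and ``sd`` attributes.  This implements carrying a generation-1
        posterior forward as the generation-2 prior.
        """
        base = base if base is not None else cls()
        overrides = dict(base.coef_overrides)
        if isinstance(summaries, pd.DataFrame):
            items = ((r["parameter"], r["mean"], r["sd"])
                     for _, r in summaries.iterrows())
        else:
            items = ((k, v.mean, v.sd) for k, v in summaries.items())
        for name, mean, sd in items:
            if sd > 0:
                overrides[name] = (float(mean), float(sd))
        return dataclasses.replace(base, coef_overrides=overrides)


def log_prior(params: ParameterSet, priors: PriorSpec, blocks=None) -> float:
    """Joint log prior density: product of independent marginals.

    Evaluates every block present in ``params`` (or the subset named by
    ``blocks``) using each block's registered covariate list.
    """
    names = list(params.blocks) if blocks is None else list(blocks)
    total = 0.0
    for name in names:
        if name not in BLOCKS:
            raise ConfigurationError(f"unknown submodel block {name!r}")
        bdef = BLOCKS[name]
        covs = tuple(t for t in bdef.covariates if t in params.blocks[name])
        total += priors.coef_logpdf(name, covs, params.coef(name, covs))
        st = bdef.scale_term
        if st is not None and st in params.blocks[name]:
            total += priors.scale_logpdf(bdef.family, params.blocks[name][st])
    return total


# ---------------------------------------------------------------------------
# model-specification files


def load_model_spec(path) -> tuple[list[SubmodelSpec], PriorSpec]:
    """Read submodel specifications and prior overrides from YAML/JSON.

    The file carries a ``submodels`` list (each entry either a registry block
    name, or a mapping with ``name``/``outcome``/``family``/``generation``/
    ``covariates``/``inclusion``) and an optional ``priors`` mapping of
    :class:`PriorSpec` fields, with ``coef_overrides`` given as
    ``{"block:term": [loc, scale]}``.  Entries are validated on load.
    """
    import yaml
    from pathlib import Path

    payload = yaml.safe_load(Path(path).read_text()) or {}
    entries = payload.get("submodels")
    if not entries:
        raise ConfigurationError(f"{path}: no 'submodels' entries")
    specs: list[SubmodelSpec] = []
    for entry in entries:
        if isinstance(entry, str):
            specs.extend(submodel_specs([entry]))
            continue
        entry = dict(entry)
        base = BLOCKS.get(entry.get("name", ""))
        if base is not None:
            merged = {"name": base.name, "outcome": base.outcome,
                      "family": base.family, "generation": base.generation,
                      "covariates": base.covariates,
                      "inclusion": base.inclusion}
            merged.update(entry)
            entry = merged
        try:
            specs.append(SubmodelSpec(
                name=entry["name"], outcome=entry["outcome"],
                family=entry["family"], generation=int(entry["generation"]),
                covariates=tuple(entry["covariates"]),
                inclusion=entry["inclusion"]))
        except KeyError as err:
            raise ConfigurationError(
                f"{path}: submodel entry missing field {err}") from err
    prior_kwargs = dict(payload.get("priors") or {})
    if "coef_overrides" in prior_kwargs:
        prior_kwargs["coef_overrides"] = {
            name: (float(v[0]), float(v[1]))
            for name, v in prior_kwargs["coef_overrides"].items()}
    return specs, PriorSpec(**prior_kwargs)


# ---------------------------------------------------------------------------
# model reduction


def _interval_lookup(summaries):
    if isinstance(summaries, pd.DataFrame):
        df = summaries.set_index("parameter") if "parameter" in summaries.columns \
            else summaries
        return {name: (float(row["lo"]), float(row["hi"]))
                for name, row in df.iterrows()}
    out = {}
    for name, s in summaries.items():
        if hasattr(s, "lo"):
            out[name] = (float(s.lo), float(s.hi))
        else:
            lo, hi = s
            out[name] = (float(lo), float(hi))
    return out


def reduce_model(summaries, specs) -> list[SubmodelSpec]:
    """Drop non-treatment interactions whose 95% interval contains zero.

    Interactions between the two insecticide treatments (within x maternal)
    are retained regardless of their interval, as they are a primary question
    of the analysis; main effects are never removed.  Raises
    :class:`ReductionError` if an interaction term has no summary.
    """
    intervals = _interval_lookup(summaries)
    reduced = []
    for spec in specs:
        drop = []
        for term in spec.covariates:
            if term not in _INTERACTIONS or term in TREATMENT_INTERACTIONS:
                continue
            name = param_name(spec.name, term)
            if name not in intervals:
                raise ReductionError(
                    f"no posterior summary for interaction term {name!r}")
            lo, hi = intervals[name]
            if lo <= 0.0 <= hi:
                drop.append(term)
        reduced.append(spec.drop_covariates(drop) if drop else spec)
    return reduced
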