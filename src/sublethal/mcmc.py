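"""Posterior sampling by adaptive Metropolis-within-Gibbs.

One proposal block per submodel (its regression coefficients plus, where the
family has one, the log residual scale or log beta precision), updated by
random-walk Metropolis with a diagonal preconditioner and Robbins-Monro
step-size adaptation during burn-in.  Missing maternal 10-day masses are
latent quantities redrawn every sweep from their conditional: the gen-1
10-day-mass model acts as their prior and every second-generation submodel
the mass enters contributes likelihood terms, so information flows between
the generations.

Internally each block is sampled in a centered parametrization of its
continuous covariates (pure reparametrization — priors are evaluated, and
draws reported, on the natural scale), which removes the near-collinearity
between intercepts and uncentered mg-scale masses.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

from .blocks import ParameterSet, param_name
from .errors import ConfigurationError, SamplerError, SchemaError
from .model import PriorSpec, SubmodelSpec, build_design

_LOG_2PI = math.log(2.0 * math.pi)
_MASS_TERMS = ("maternal_mass", "larval_mass")


@dataclass
class McmcConfig:
    """Sampling schedule and tuning knobs.

    ``keep * thin`` iterations are run after ``burn_in``.  The publication
    schedule is available as :meth:`publication_scale` (2,000,000 burn-in, every
    500th of 5,000,000 further draws retained); :meth:`desk_scale` is the
    default working schedule (20,000 burn-in, 2,000 draws at stride 10).
    """

    burn_in: int = 20_000
    keep: int = 2_000
    thin: int = 10
    n_chains: int = 1
    seed: int = 0
    adapt: bool = True
    target_accept: float = 0.30
    init_jitter: float = 0.1

    def validate(self) -> None:
        if min(self.burn_in, self.keep, self.thin, self.n_chains) < 1 \
                and not (self.burn_in >= 0 and min(self.keep, self.thin,
                                                   self.n_chains) >= 1):
            raise ConfigurationError("MCMC schedule counts must be positive")
        if not 0.0 < self.target_accept < 1.0:
            raise ConfigurationError("target_accept must lie in (0, 1)")

    @property
    def total_iterations(self) -> int:
        return self.burn_in + self.keep * self.thin

    @classmethod
    def desk_scale(cls, **kw) -> "McmcConfig":
        return cls(**{"burn_in": 20_000, "keep": 2_000, "thin": 10, **kw})

    @classmethod
    def publication_scale(cls, **kw) -> "McmcConfig":
        return cls(**{"burn_in": 2_000_000, "keep": 10_000, "thin": 500,
                      "n_chains": 1, **kw})


@dataclass
class PosteriorDraws:
    """Retained draws keyed by flat ``block:term`` parameter names."""

    names: list[str]
    draws: np.ndarray                      # (n_chains * keep, n_parameters)
    imputed_names: list[str] = field(default_factory=list)
    imputed: np.ndarray | None = None      # (n_chains * keep, n_missing_dams)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.draws.ndim != 2 or self.draws.shape[1] != len(self.names):
            raise ConfigurationError("draws must be (n_draws, n_parameters)")
        if not np.isfinite(self.draws).all():
            raise SamplerError("posterior draws contain non-finite values")

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    @property
    def n_chains(self) -> int:
        return int(self.meta.get("n_chains", 1))

    def param(self, name: str) -> np.ndarray:
        return self.draws[:, self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.draws, columns=self.names)

    def imputed_frame(self) -> pd.DataFrame:
        if self.imputed is None:
            return pd.DataFrame()
        return pd.DataFrame(self.imputed, columns=self.imputed_names)

    def parameter_set(self, i: int,
                      template: ParameterSet | None = None) -> ParameterSet:
        """Parameter set of draw ``i`` (optionally over a base template)."""
        flat = dict(zip(self.names, self.draws[i]))
        if template is None:
            return ParameterSet.from_flat(flat)
        return template.updated(flat)

    def save(self, directory) -> None:
        """Persist draws as CSV tables plus a JSON metadata sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(directory / "draws.csv", index=False)
        if self.imputed is not None and self.imputed.size:
            self.imputed_frame().to_csv(directory / "imputed.csv", index=False)
        (directory / "meta.json").write_text(json.dumps(self.meta, indent=2))

    @classmethod
    def load(cls, directory) -> "PosteriorDraws":
        directory = Path(directory)
        frame = pd.read_csv(directory / "draws.csv",
                            float_precision="round_trip")
        meta = json.loads((directory / "meta.json").read_text())
        imputed_path = directory / "imputed.csv"
        if imputed_path.exists():
            imp = pd.read_csv(imputed_path, float_precision="round_trip")
            return cls(list(frame.columns), frame.to_numpy(float),
                       [str(c) for c in imp.columns], imp.to_numpy(float), meta)
        return cls(list(frame.columns), frame.to_numpy(float), meta=meta)


# ---------------------------------------------------------------------------
# per-block sampler


class _BlockSampler:
    """State and Metropolis update for one submodel block."""

    def __init__(self, spec: SubmodelSpec, frame: pd.DataFrame,
                 priors: PriorSpec, config: McmcConfig,
                 rng: np.random.Generator, sample: bool = True,
                 fixed_values: dict | None = None):
        self.spec = spec
        self.sample = sample
        dm = build_design(frame, spec)
        self.index = dm.index
        self.y = dm.y
        self.n = dm.n
        self.p = len(spec.covariates)
        self.has_scale = spec.scale_term is not None
        self.dim = self.p + (1 if self.has_scale else 0)
        self.missing_rows = np.flatnonzero(dm.missing_mass)
        try:
            self.mass_col = spec.covariates.index("maternal_mass")
        except ValueError:
            self.mass_col = None

        # centered parametrization of continuous covariates
        self.center = np.zeros(self.p)
        X = dm.X.astype(float).copy()
        for j, term in enumerate(spec.covariates):
            if term in _MASS_TERMS and self.n:
                col = X[:, j]
                finite = np.isfinite(col)
                self.center[j] = float(col[finite].mean()) if finite.any() else 0.0
        self.X = X - self.center
        if self.missing_rows.size:
            # placeholder until the imputer pushes its initial state
            self.X[self.missing_rows, self.mass_col] = 0.0

        if spec.family == "lognormal":
            self.t = np.log(self.y) if self.n else np.zeros(0)
            self.jacobian = float(-self.t.sum())
        elif spec.family == "normal":
            self.t = self.y if self.n else np.zeros(0)
            self.jacobian = 0.0
        elif spec.family == "beta":
            self.log_y = np.log(self.y) if self.n else np.zeros(0)
            self.log1m_y = np.log1p(-self.y) if self.n else np.zeros(0)

        self.prior_loc, self.prior_scale = priors.coef_params(
            spec.name, spec.covariates)
        if priors.autoscale and spec.family != "normal" and self.n > 1:
            # rstanarm-style: per-SD slope scales, so the prior means the
            # same thing whatever units a covariate arrives in
            for j, term in enumerate(spec.covariates):
                if term == "intercept" or \
                        param_name(spec.name, term) in priors.coef_overrides:
                    continue
                col = dm.X[:, j]
                sd = float(np.nanstd(col))
                if sd > 1e-8:
                    self.prior_scale[j] = self.prior_scale[j] / sd
        self._prior_const = float(-np.log(self.prior_scale).sum()
                                  - 0.5 * _LOG_2PI * self.p)
        self.priors = priors

        # initial state: prior means with jitter (natural scale), or the
        # supplied fixed values
        if fixed_values is not None:
            coef_u = np.array([fixed_values[t] for t in spec.covariates])
            log_scale = (math.log(fixed_values[spec.scale_term])
                         if self.has_scale else None)
        else:
            coef_u = self.prior_loc + config.init_jitter * \
                self.prior_scale * rng.standard_normal(self.p) * 0.1
            log_scale = math.log(self._init_scale()) if self.has_scale else None
        self.vec = np.empty(self.dim)
        self.vec[:self.p] = coef_u
        self.vec[0] = coef_u[0] + self.center @ coef_u   # centered intercept
        if self.has_scale:
            self.vec[self.p] = log_scale

        self._build_proposal()
        self.step = 2.38 / math.sqrt(self.dim)
        # covariance adaptation: burn-in states are recorded (thinned) and a
        # full-covariance proposal is rebuilt periodically, which is what
        # lets strongly correlated blocks (main effects with their treatment
        # interaction) mix
        self.L: np.ndarray | None = None
        self._burn = config.burn_in
        self._hist = np.empty((config.burn_in // 10 + 2, self.dim))
        self._n_hist = 0
        # latent-state density hook (the imputer attaches the latent-mass
        # prior to the gen-1 mass model so both updates target the same joint)
        self.extra_logpost = None
        self.cur_lp = None  # filled by refresh() once imputer state is set
        self.n_prop = 0
        self.n_accept = 0

    # -- initial scales and proposal geometry --------------------------------

    def _init_scale(self) -> float:
        if self.spec.family == "beta":
            return 50.0
        if self.n > 1:
            s = float(np.std(self.t))
            if s > 0:
                return s
        return 1.0

    def _build_proposal(self) -> None:
        d = np.empty(self.dim)
        n = max(self.n, 1)
        if self.n == 0:
            d[:self.p] = self.prior_scale
        else:
            sd = self.X.std(axis=0)
            sd[sd <= 1e-12] = 1.0
            if self.spec.family == "mortality":
                d[:self.p] = 2.0 / (sd * math.sqrt(n))
            elif self.spec.family == "beta":
                d[:self.p] = 1.0 / (sd * math.sqrt(n * 25.0))
            else:
                d[:self.p] = math.exp(self.vec[self.p]) / (sd * math.sqrt(n))
        if self.has_scale:
            d[self.p] = 1.0 / math.sqrt(2 * n) if self.n else 1.0
        self.d = d

    # -- densities ------------------------------------------------------------

    def _loglik(self, vec: np.ndarray) -> float:
        if self.n == 0:
            return 0.0
        coef = vec[:self.p]
        eta = self.X @ coef
        fam = self.spec.family
        if fam == "mortality":
            return float(self.y @ eta - np.logaddexp(0.0, eta).sum())
        if fam in ("normal", "lognormal"):
            scale = math.exp(vec[self.p])
            z = (self.t - eta) / scale
            return float(-0.5 * (z @ z)
                         - self.n * (vec[self.p] + 0.5 * _LOG_2PI)
                         + self.jacobian)
        phi = math.exp(vec[self.p])
        mu = np.clip(expit(eta), 1e-12, 1.0 - 1e-12)
        a = mu * phi
        b = (1.0 - mu) * phi
        ll = (gammaln(phi) - gammaln(a) - gammaln(b)
              + (a - 1.0) * self.log_y + (b - 1.0) * self.log1m_y)
        return float(ll.sum())

    def uncentered_coef(self, vec: np.ndarray | None = None) -> np.ndarray:
        vec = self.vec if vec is None else vec
        coef = vec[:self.p].copy()
        coef[0] = coef[0] - self.center @ coef
        return coef

    def scale_value(self) -> float:
        return math.exp(self.vec[self.p])

    def _logprior(self, vec: np.ndarray) -> float:
        coef_u = self.uncentered_coef(vec)
        z = (coef_u - self.prior_loc) / self.prior_scale
        lp = float(-0.5 * (z @ z)) + self._prior_const
        if self.has_scale:
            s = vec[self.p]
            lp += self.priors.scale_logpdf(self.spec.family, math.exp(s)) + s
        return lp

    def logpost(self, vec: np.ndarray) -> float:
        lp = self._loglik(vec) + self._logprior(vec)
        if self.extra_logpost is not None:
            lp += self.extra_logpost(vec)
        return lp

    def refresh(self) -> None:
        self.cur_lp = self.logpost(self.vec)

    # -- MH update ------------------------------------------------------------

    def update(self, rng: np.random.Generator, adapt: bool) -> None:
        z = rng.standard_normal(self.dim)
        if self.L is None:
            prop = self.vec + self.step * (self.d * z)
        else:
            prop = self.vec + self.step * (self.L @ z)
        lp = self.logpost(prop)
        delta = lp - self.cur_lp
        accept_prob = 1.0 if delta >= 0 else math.exp(max(delta, -700.0))
        if rng.random() < accept_prob:
            self.vec = prop
            self.cur_lp = lp
            self.n_accept += 1
        self.n_prop += 1
        if adapt:
            gamma = (self.n_prop + 10) ** -0.6
            self.step *= math.exp(gamma * (accept_prob - 0.30))
            if self.n_prop % 10 == 0:
                self._hist[self._n_hist] = self.vec
                self._n_hist += 1
            # leave at least 1000 iterations to re-tune the step after the
            # last covariance refit
            if self.n_prop % 1000 == 0 and self._n_hist >= 100 \
                    and self.n_prop <= self._burn - 1000:
                self._refit_proposal()

    def _refit_proposal(self) -> None:
        hist = self._hist[self._n_hist // 2:self._n_hist]
        cov = np.cov(hist, rowvar=False).reshape(self.dim, self.dim)
        cov = cov * (2.38 ** 2 / self.dim)
        cov[np.diag_indices_from(cov)] += 1e-10 + 1e-6 * self.d ** 2
        try:
            L = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            return
        self.L = L
        self.step = 1.0

    # -- imputation hooks ------------------------------------------------------

    def set_mass(self, rows: np.ndarray, values: np.ndarray) -> None:
        """Overwrite the maternal-mass entries of ``rows`` (natural scale)."""
        self.X[rows, self.mass_col] = values - self.center[self.mass_col]

    def row_loglik_delta(self, rows: np.ndarray, new_mass: np.ndarray) -> np.ndarray:
        """Per-row log-likelihood change if those rows' mass became ``new_mass``."""
        coef = self.vec[:self.p]
        slope = coef[self.mass_col]
        eta_old = self.X[rows] @ coef
        eta_new = eta_old + slope * (new_mass - self.center[self.mass_col]
                                     - self.X[rows, self.mass_col])
        fam = self.spec.family
        if fam == "mortality":
            y = self.y[rows]
            return (y * eta_new - np.logaddexp(0.0, eta_new)) \
                - (y * eta_old - np.logaddexp(0.0, eta_old))
        if fam in ("normal", "lognormal"):
            scale = math.exp(self.vec[self.p])
            t = self.t[rows]
            return 0.5 * (((t - eta_old) / scale) ** 2
                          - ((t - eta_new) / scale) ** 2)
        phi = math.exp(self.vec[self.p])

        def beta_ll(eta):
            mu = np.clip(expit(eta), 1e-12, 1.0 - 1e-12)
            a, b = mu * phi, (1.0 - mu) * phi
            return (-gammaln(a) - gammaln(b) + (a - 1.0) * self.log_y[rows]
                    + (b - 1.0) * self.log1m_y[rows])

        return beta_ll(eta_new) - beta_ll(eta_old)

    def check_finite_init(self) -> None:
        if self.cur_lp is None:
            self.refresh()
        if np.isfinite(self.cur_lp):
            return
        # locate the offending row for the error message
        if self.n:
            coef = self.vec[:self.p]
            eta = self.X @ coef
            if self.spec.family == "mortality":
                with np.errstate(invalid="ignore"):
                    row_ll = self.y * eta - np.logaddexp(0.0, eta)
            elif self.spec.family in ("normal", "lognormal"):
                row_ll = -((self.t - eta) ** 2)
            else:
                row_ll = self.row_loglik_delta(np.arange(self.n),
                                               np.zeros(self.n))
            bad = np.flatnonzero(~np.isfinite(row_ll))
            if bad.size:
                raise SamplerError(
                    f"non-finite posterior at initialization in submodel "
                    f"{self.spec.name!r}, row {self.index[bad[0]]!r}")
        raise SamplerError(
            f"non-finite posterior at initialization in submodel "
            f"{self.spec.name!r}")


# ---------------------------------------------------------------------------
# within-sampler imputation of missing maternal mass


class _MassImputer:
    """Latent 10-day masses of dams whose weighing is missing.

    Each missing mass has the gen-1 mass model as its prior and picks up
    likelihood contributions from every gen-2 submodel row of that dam's
    offspring.  Updates are independent Metropolis steps across dams (their
    offspring sets are disjoint), proposed jointly and accepted per dam.
    """

    def __init__(self, frame: pd.DataFrame, samplers: dict[str, _BlockSampler],
                 rng: np.random.Generator):
        if "g1_mass_day10" not in samplers:
            raise ConfigurationError(
                "missing maternal masses require the 'g1_mass_day10' submodel "
                "for imputation")
        self.mass_model = samplers["g1_mass_day10"]

        dam_ids: list[str] = []
        for bs in samplers.values():
            if bs.missing_rows.size:
                rows = frame.loc[bs.index[bs.missing_rows]]
                if rows["mother_id"].isna().any():
                    raise SchemaError(
                        "rows with missing maternal mass must carry mother_id")
                dam_ids.extend(rows["mother_id"].tolist())
        self.dam_ids = sorted(set(dam_ids))
        ordinal = {d: k for k, d in enumerate(self.dam_ids)}
        self.k = len(self.dam_ids)

        g1 = frame[frame["generation"].astype(int) == 1].set_index("id")
        x_rows = []
        for dam in self.dam_ids:
            if dam not in g1.index:
                raise SchemaError(
                    f"dam {dam!r} has missing mass but no generation-1 record")
            row = g1.loc[dam]
            vals = {"intercept": 1.0,
                    "within": float(row["within_treatment"] == "insecticide"),
                    "male": 0.0, "trans": 0.0,
                    "within_x_trans": 0.0, "male_x_trans": 0.0}
            x_rows.append([vals[t] for t in self.mass_model.spec.covariates])
        self.x_dam = np.asarray(x_rows, dtype=float)

        self.blocks: list[tuple[_BlockSampler, np.ndarray, np.ndarray]] = []
        for bs in samplers.values():
            if bs.missing_rows.size:
                dams = frame.loc[bs.index[bs.missing_rows], "mother_id"]
                dam_of_row = np.array([ordinal[d] for d in dams])
                self.blocks.append((bs, bs.missing_rows, dam_of_row))

        observed = frame["maternal_mass10_mg"].dropna()
        if len(observed):
            init = float(observed.mean())
        else:
            g1_mass = g1["mass_day10_mg"].dropna()
            init = float(g1_mass.mean()) if len(g1_mass) else 150.0
        self.m = np.full(self.k, init)
        self.tau = max(init * 0.05, 1.0)
        self.n_prop = 0
        self.n_accept = 0
        self.push()
        self.mass_model.extra_logpost = self._latent_mass_logpdf

    def _latent_mass_logpdf(self, vec: np.ndarray) -> float:
        """Log density of the latent masses under the gen-1 mass model."""
        coef = self.mass_model.uncentered_coef(vec)
        sigma = math.exp(vec[self.mass_model.p])
        z = (self.m - self.x_dam @ coef) / sigma
        return float(-0.5 * (z @ z)
                     - self.k * (math.log(sigma) + 0.5 * _LOG_2PI))

    def push(self) -> None:
        for bs, rows, dam_of_row in self.blocks:
            bs.set_mass(rows, self.m[dam_of_row])

    def _prior_mu_sigma(self) -> tuple[np.ndarray, float]:
        coef = self.mass_model.uncentered_coef()
        return self.x_dam @ coef, self.mass_model.scale_value()

    def update(self, rng: np.random.Generator, adapt: bool) -> None:
        prop = self.m + self.tau * rng.standard_normal(self.k)
        mu, sigma = self._prior_mu_sigma()
        prior_delta = 0.5 * (((self.m - mu) / sigma) ** 2
                             - ((prop - mu) / sigma) ** 2)
        delta = prior_delta.copy()
        row_deltas = []
        for bs, rows, dam_of_row in self.blocks:
            rd = bs.row_loglik_delta(rows, prop[dam_of_row])
            row_deltas.append(rd)
            np.add.at(delta, dam_of_row, rd)
        accept = np.log(rng.random(self.k)) < delta
        if accept.any():
            self.m[accept] = prop[accept]
            for (bs, rows, dam_of_row), rd in zip(self.blocks, row_deltas):
                moved = accept[dam_of_row]
                if moved.any():
                    bs.set_mass(rows[moved], self.m[dam_of_row[moved]])
                    bs.cur_lp += float(rd[moved].sum())
            # the latent-mass prior lives in the mass model's log posterior
            if self.mass_model.cur_lp is not None:
                self.mass_model.cur_lp += float(prior_delta[accept].sum())
        rate = float(accept.mean())
        self.n_prop += 1
        self.n_accept += rate
        if adapt:
            gamma = (self.n_prop + 10) ** -0.6
            self.tau *= math.exp(gamma * (rate - 0.30))


def impute_missing(state: "_MassImputer", rng, adapt: bool = False) -> "_MassImputer":
    """One imputation sweep: redraw each missing maternal mass in place.

    With no missing values the state is untouched.  Observed masses are never
    altered — they live in the design matrices, not in the imputer.
    """
    if state is not None and state.k:
        state.update(np.random.default_rng(rng)
                     if not isinstance(rng, np.random.Generator) else rng,
                     adapt)
    return state


# ---------------------------------------------------------------------------
# the joint sampler


def _run_chain(frame, specs, priors, config, chain_seed, fixed, fixed_blocks):
    rng = np.random.default_rng(chain_seed)
    samplers: dict[str, _BlockSampler] = {}
    for spec in specs:
        is_fixed = spec.name in fixed_blocks
        fv = None
        if is_fixed:
            if fixed is None:
                raise ConfigurationError(
                    "fixed_blocks given without a fixed ParameterSet")
            fixed.validate([spec.name])
            fv = fixed.blocks[spec.name]
        samplers[spec.name] = _BlockSampler(
            spec, frame, priors, config, rng, sample=not is_fixed,
            fixed_values=fv)

    any_missing = any(bs.missing_rows.size for bs in samplers.values())
    imputer = _MassImputer(frame, samplers, rng) if any_missing else None

    for bs in samplers.values():
        bs.refresh()
        bs.check_finite_init()

    sampled = [bs for bs in samplers.values() if bs.sample]
    rec_names: list[str] = []
    for bs in sampled:
        rec_names += [param_name(bs.spec.name, t) for t in bs.spec.covariates]
        if bs.has_scale:
            rec_names.append(param_name(bs.spec.name, bs.spec.scale_term))

    burn, keep, thin = config.burn_in, config.keep, config.thin
    out = np.empty((keep, len(rec_names)))
    out_m = np.empty((keep, imputer.k)) if imputer else None
    row = 0
    for t in range(config.total_iterations):
        adapt = config.adapt and t < burn
        for bs in sampled:
            bs.update(rng, adapt)
        if imputer is not None:
            imputer.update(rng, adapt)
        if t >= burn and (t - burn + 1) % thin == 0:
            col = 0
            for bs in sampled:
                out[row, col:col + bs.p] = bs.uncentered_coef()
                col += bs.p
                if bs.has_scale:
                    out[row, col] = bs.scale_value()
                    col += 1
            if imputer is not None:
                out_m[row] = imputer.m
            row += 1

    acceptance = {bs.spec.name: bs.n_accept / max(bs.n_prop, 1)
                  for bs in sampled}
    if imputer is not None:
        acceptance["imputation"] = imputer.n_accept / max(imputer.n_prop, 1)
    return rec_names, out, imputer, out_m, acceptance


def sample_posterior(data, specs, priors: PriorSpec | None = None,
                     config: McmcConfig | None = None,
                     fixed: ParameterSet | None = None,
                     fixed_blocks=()) -> PosteriorDraws:
    """Sample the joint posterior of all submodels in ``specs``.

    Identical seed, config and data give bit-identical draws.  ``fixed`` and
    ``fixed_blocks`` hold the named blocks at supplied values (they still
    contribute to the imputation conditional) — useful for testing the
    imputation machinery in isolation.

    Parameters
    ----------
    data
        Cohort table or list of individuals; validated against the submodel
        schemas before any sampling.
    specs
        Submodel specifications (full or reduced).
    """
    from .cohort import cohort_to_frame

    priors = priors if priors is not None else PriorSpec()
    config = config if config is not None else McmcConfig.desk_scale()
    config.validate()
    frame = cohort_to_frame(data)
    if fixed_blocks == "all":
        fixed_blocks = {s.name for s in specs}
    else:
        fixed_blocks = set(fixed_blocks)

    t0 = time.perf_counter()
    chains_out = []
    imputed_out = []
    names = None
    imputer = None
    acceptance = {}
    for c in range(config.n_chains):
        names, out, imputer, out_m, acceptance = _run_chain(
            frame, specs, priors, config, [int(config.seed), c],
            fixed, fixed_blocks)
        chains_out.append(out)
        if out_m is not None:
            imputed_out.append(out_m)

    draws = np.vstack(chains_out)
    meta = {
        "config": asdict(config),
        "n_chains": config.n_chains,
        "seed": int(config.seed),
        "acceptance": acceptance,
        "runtime_s": round(time.perf_counter() - t0, 3),
        "submodels": [s.name for s in specs],
        "fixed_blocks": sorted(fixed_blocks),
    }
    if imputer is not None:
        return PosteriorDraws(names, draws, list(imputer.dam_ids),
                              np.vstack(imputed_out), meta)
    return PosteriorDraws(names, draws, meta=meta)


# ---------------------------------------------------------------------------
# diagnostics


@dataclass
class DiagnosticsReport:
    """Per-parameter mixing diagnostics of a set of retained draws."""

    summary: pd.DataFrame          # mean, sd, ess, lag-1 autocorr, flags
    autocorr: pd.DataFrame         # parameters x lags 0..max_lag

    @property
    def flagged(self) -> list[str]:
        return self.summary.index[self.summary["flag_low_ess"]].tolist()


def diagnostics(draws: PosteriorDraws, max_lag: int = 50,
                ess_threshold: float = 100.0) -> DiagnosticsReport:
    """Trace summaries, autocorrelation (lags <= ``max_lag``) and ESS.

    Parameters with effective sample size below ``ess_threshold`` are
    flagged; constant (degenerate) traces are flagged without error.
    Requires at least 100 retained draws.
    """
    if draws.n_draws < 100:
        raise ValueError("diagnostics require at least 100 retained draws")
    n_chains = draws.n_chains
    keep = draws.n_draws // n_chains
    rows = []
    acfs = {}
    lags = np.arange(max_lag + 1)
    for j, name in enumerate(draws.names):
        x = draws.draws[:, j]
        sd = float(x.std())
        degenerate = sd <= 1e-12 * max(1.0, abs(float(x.mean())))
        if degenerate:
            ess = float("nan")
            acf = np.full(max_lag + 1, np.nan)
            acf[0] = 1.0
        else:
            chains = x[:n_chains * keep].reshape(n_chains, keep)
            ess = float(az.ess(chains))
            per_chain = np.stack([az.autocorr(c)[:max_lag + 1] for c in chains])
            acf = per_chain.mean(axis=0)
        rows.append({"parameter": name, "mean": float(x.mean()), "sd": sd,
                     "ess": ess, "lag1": float(acf[1]) if max_lag else np.nan,
                     "degenerate": degenerate,
                     "flag_low_ess": degenerate or ess < ess_threshold})
        acfs[name] = acf
    summary = pd.DataFrame(rows).set_index("parameter")
    autocorr = pd.DataFrame(acfs, index=lags).T
    return DiagnosticsReport(summary, autocorr)


# ---------------------------------------------------------------------------
# posterior predictive replication


@dataclass
class PosteriorPredictive:
    """Replicate cohorts and the observed-vs-replicated discrepancy table."""

    replicates: list[pd.DataFrame]
    table: pd.DataFrame


def _discrepancy_stats(frame: pd.DataFrame, specs) -> dict[str, float]:
    stats: dict[str, float] = {}
    for spec in specs:
        if spec.family == "mortality":
            sub = frame[frame["generation"].astype(int) == spec.generation]
            stats[f"deaths_{spec.name}"] = float((sub[spec.outcome] == 1.0).sum())
        else:
            sub = frame[frame["generation"].astype(int) == spec.generation]
            vals = sub[spec.outcome].dropna()
            stats[f"mean_{spec.name}"] = float(vals.mean()) if len(vals) else np.nan
    return stats


def posterior_predictive(draws: PosteriorDraws, specs, data,
                         params_template: ParameterSet | None = None,
                         n_rep: int = 10, rng=0) -> PosteriorPredictive:
    """Simulate replicate cohorts from retained draws and compare.

    For each replicate one retained draw is selected, the cohort is
    re-simulated with observed covariates held fixed (missing maternal
    masses filled from the same draw's imputed values), and stage-wise death
    counts and trait means are tabulated against the observed data.
    """
    from .cohort import cohort_to_frame, resimulate

    if n_rep < 1:
        raise ValueError("n_rep must be at least 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) \
        else rng
    frame = cohort_to_frame(data)
    blocks = [s.name for s in specs]
    missing = frame["maternal_mass10_mg"].isna() & \
        (frame["generation"].astype(int) == 2)
    dam_col = frame["mother_id"]

    observed = _discrepancy_stats(frame, specs)
    replicates = []
    rep_stats = []
    for _ in range(n_rep):
        i = int(rng.integers(draws.n_draws))
        params = draws.parameter_set(i, template=params_template)
        filled = frame.copy()
        if missing.any():
            if not draws.imputed_names:
                raise SchemaError(
                    "cohort has missing maternal masses but draws carry no "
                    "imputed values")
            lookup = dict(zip(draws.imputed_names, draws.imputed[i]))
            fill = dam_col[missing].map(lookup)
            if fill.isna().any():
                raise SchemaError("imputed draws do not cover every missing dam")
            filled.loc[missing, "maternal_mass10_mg"] = fill.to_numpy(float)
        rep = resimulate(filled, params, rng, blocks=blocks)
        replicates.append(rep)
        rep_stats.append(_discrepancy_stats(rep, specs))

    rows = []
    for stat, obs in observed.items():
        vals = np.array([r[stat] for r in rep_stats], dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size:
            lo, hi = np.quantile(finite, [0.025, 0.975])
            mean, sd = float(finite.mean()), float(finite.std())
        else:
            lo = hi = mean = sd = float("nan")
        rows.append({"statistic": stat, "observed": obs, "rep_mean": mean,
                     "rep_sd": sd, "rep_lo": lo, "rep_hi": hi,
                     "inside_95": bool(lo <= obs <= hi)
                     if np.isfinite(obs) and np.isfinite(lo) else False})
    table = pd.DataFrame(rows).set_index("statistic")
    return PosteriorPredictive(replicates, table)
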