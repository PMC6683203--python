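"""Synthetic two-generation cohort generator.

Emulates the split-brood experiment the analysis was designed for: gen-1
second-instar larvae randomised to a water control or a sublethal
deltamethrin exposure, reared individually through larval, pupal and adult
stages; control sires each mated to dams from both maternal-treatment groups;
gen-2 offspring re-randomised to within-generation treatments.  Stage deaths
are Bernoulli draws from the mortality-logit blocks, development time is
log-normal, body masses normal, and composition fractions beta-distributed,
all from a single :class:`~sublethal.blocks.ParameterSet`.  Missingness is
structural: a trait is blank whenever the individual died before its
measurement age, and a dam that dies during the adult stage (before the
10-day weighing) leaves her offspring with a missing maternal-mass covariate
— the quantity the sampler later imputes.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .blocks import BLOCKS, GEN1_BLOCKS, GEN2_BLOCKS, STAGES, ParameterSet
from .errors import ConfigurationError, SchemaError, ShortfallError
from .model import build_design, squeeze_fractions, submodel_specs

#: Cohort CSV column order; one row per Individual, names match field names.
COLUMNS = (
    "id", "generation", "family_id", "mother_id", "within_treatment",
    "maternal_treatment", "sex", "larval_mass_mg", "maternal_mass10_mg",
    "died_24h", "died_larval", "died_pupal", "died_adult", "dev_time_days",
    "mass_emergence_mg", "mass_day7_mg", "mass_day10_mg", "mass_day14_mg",
    "fresh_mg", "dry_mg", "lean_mg", "lipid_frac", "water_frac",
    "drymass_frac",
)

_STRING_COLS = ("id", "family_id", "mother_id", "within_treatment",
                "maternal_treatment", "sex")
_DEATH_COLS = ("died_24h", "died_larval", "died_pupal", "died_adult")
_EMERGENCE_TRAITS = ("sex", "dev_time_days", "mass_emergence_mg")
_LATE_TRAITS = ("mass_day7_mg", "mass_day10_mg", "mass_day14_mg", "fresh_mg",
                "dry_mg", "lean_mg", "lipid_frac", "water_frac",
                "drymass_frac")


@dataclass
class CohortDesign:
    """Counts, mating structure and treatment allocation of the experiment.

    Defaults are the original study's design: 245 gen-1 larvae, 14 control
    sires each mated to 4 dams (two control, two insecticide-exposed; 56
    families), 842 gen-2 larvae, and a 50/50 treatment split within each
    generation.  The gen-1 pre-treatment larval mass distribution was not
    reported; a truncated Normal(4 mg, 1 mg) is the generator's default.
    """

    n_gen1_larvae: int = 245
    n_sires: int = 14
    dams_per_sire: int = 4
    n_gen2_larvae: int = 842
    treatment_allocation: float = 0.5
    seed: int = 0
    larval_mass_mean_mg: float = 4.0
    larval_mass_sd_mg: float = 1.0

    def validate(self) -> None:
        for name in ("n_gen1_larvae", "n_sires", "dams_per_sire"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be a positive count")
        if self.n_gen2_larvae < 0:
            raise ConfigurationError("n_gen2_larvae must be non-negative")
        if self.dams_per_sire % 2 != 0:
            raise ConfigurationError(
                "dams_per_sire must be even so broods split equally between "
                "maternal treatments")
        if not 0.0 < self.treatment_allocation < 1.0:
            raise ConfigurationError(
                "treatment_allocation must lie strictly inside (0, 1)")
        if self.larval_mass_mean_mg <= 0 or self.larval_mass_sd_mg <= 0:
            raise ConfigurationError("larval mass distribution must be positive")

    @property
    def n_families(self) -> int:
        return self.n_sires * self.dams_per_sire


@dataclass
class Individual:
    """One beetle: covariates, stage-wise fate and trait measurements.

    A stage-death indicator is ``None`` unless all earlier stages were
    survived; a trait is ``None`` unless the individual was alive at the
    trait's measurement age.  Sex is observable only at adult emergence.
    """

    id: str
    generation: int
    family_id: str | None = None
    mother_id: str | None = None
    within_treatment: str = "control"
    maternal_treatment: str | None = None
    sex: str | None = None
    larval_mass_mg: float | None = None
    maternal_mass10_mg: float | None = None
    died_24h: bool | None = None
    died_larval: bool | None = None
    died_pupal: bool | None = None
    died_adult: bool | None = None
    dev_time_days: float | None = None
    mass_emergence_mg: float | None = None
    mass_day7_mg: float | None = None
    mass_day10_mg: float | None = None
    mass_day14_mg: float | None = None
    fresh_mg: float | None = None
    dry_mg: float | None = None
    lean_mg: float | None = None
    lipid_frac: float | None = None
    water_frac: float | None = None
    drymass_frac: float | None = None


@dataclass
class Family:
    """One split-brood mating: a control sire paired with one dam."""

    family_id: str
    sire_id: str
    dam_id: str
    maternal_treatment: str
    maternal_mass10_mg: float | None = None


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


# ---------------------------------------------------------------------------
# list <-> frame conversion and Folch weight arithmetic


def cohort_to_frame(individuals) -> pd.DataFrame:
    """Cohort as a pandas table with the canonical column order."""
    if isinstance(individuals, pd.DataFrame):
        return individuals
    rows = []
    for ind in individuals:
        d = asdict(ind)
        for col in _DEATH_COLS:
            if d[col] is not None:
                d[col] = float(d[col])
        rows.append(d)
    frame = pd.DataFrame(rows, columns=list(COLUMNS))
    for col in COLUMNS:
        if col in _STRING_COLS:
            frame[col] = frame[col].map(
                lambda v: np.nan if v is None else v).astype(object)
        elif col != "generation":
            frame[col] = frame[col].astype(float)
    frame["generation"] = frame["generation"].astype(int)
    return frame


def individuals_from_frame(frame: pd.DataFrame) -> list[Individual]:
    valid = {f.name for f in fields(Individual)}
    out = []
    for _, row in frame.iterrows():
        d = {}
        for col, val in row.items():
            if col not in valid:
                continue
            if pd.isna(val):
                d[col] = None
            elif col in _DEATH_COLS:
                d[col] = bool(val)
            elif col == "generation":
                d[col] = int(val)
            else:
                d[col] = val
        out.append(Individual(**d))
    return out


def lipid_fraction(fresh_mg, dry_mg, lean_mg):
    """Relative lipid content from the Folch weighings: (dry - lean) / fresh."""
    fresh = np.asarray(fresh_mg, dtype=float)
    return (np.asarray(dry_mg, dtype=float)
            - np.asarray(lean_mg, dtype=float)) / fresh


def drymass_fraction(fresh_mg, dry_mg):
    """Relative dry mass from the Folch weighings: dry / fresh."""
    return np.asarray(dry_mg, dtype=float) / np.asarray(fresh_mg, dtype=float)


# ---------------------------------------------------------------------------
# conditional re-simulation (shared by the generator and posterior predictive)


def resimulate(frame: pd.DataFrame, params: ParameterSet, rng,
               blocks=None, keep_observed_sex: bool = True) -> pd.DataFrame:
    """Redraw outcomes for a cohort whose covariates are held fixed.

    Stage deaths are drawn sequentially (a stage's design matrix contains
    only replicate survivors of earlier stages), sex is drawn Bernoulli(0.5)
    at emergence unless an observed value is kept, and traits are drawn for
    survivors only.  ``blocks`` restricts which submodels are redrawn
    (default: every registry block whose generation appears in the frame).
    The returned frame has structural missingness applied.
    """
    rng = _as_rng(rng)
    gens = set(frame["generation"].astype(int).unique())
    if blocks is None:
        blocks = [n for n, b in BLOCKS.items() if b.generation in gens]
    specs = submodel_specs(blocks)
    specs = [s for s in specs if s.generation in gens]
    params.validate([s.name for s in specs])

    work = frame.copy()
    for col in COLUMNS:
        if col not in work.columns:
            work[col] = np.nan
    for col in _STRING_COLS:
        work[col] = work[col].astype(object)
    observed_sex = work["sex"].copy()
    for spec in specs:
        work[spec.outcome] = np.nan

    mortality = {s.outcome: s for s in specs if s.family == "mortality"}
    redraw_sex = any(s.family != "mortality" for s in specs) or \
        "died_adult" in mortality

    for gen in sorted(gens):
        for stage in STAGES:
            outcome = f"died_{stage}"
            spec = mortality.get(outcome)
            if spec is None or spec.generation != gen:
                spec = next((s for s in specs if s.outcome == outcome
                             and s.generation == gen), None)
            if spec is None:
                continue
            dm = build_design(work, spec, response=False)
            if dm.missing_mass.any():
                raise SchemaError(
                    f"maternal_mass10_mg must be filled before re-simulating "
                    f"{spec.name!r}; {int(dm.missing_mass.sum())} rows missing")
            p = expit(dm.X @ params.coef(spec.name, spec.covariates))
            died = (rng.random(dm.n) < p).astype(float)
            work.loc[dm.index, outcome] = died
        if redraw_sex:
            emerged = (work["generation"].astype(int) == gen)
            for col in ("died_24h", "died_larval", "died_pupal"):
                emerged &= work[col] == 0.0
            idx = work.index[emerged]
            drawn = np.where(rng.random(len(idx)) < 0.5, "male", "female")
            if keep_observed_sex:
                obs = observed_sex.loc[idx]
                work.loc[idx, "sex"] = np.where(obs.notna(), obs, drawn)
            else:
                work.loc[idx, "sex"] = drawn

    for spec in specs:
        if spec.family == "mortality":
            continue
        dm = build_design(work, spec, response=False)
        if dm.n == 0:
            continue
        if dm.missing_mass.any():
            raise SchemaError(
                f"maternal_mass10_mg must be filled before re-simulating "
                f"{spec.name!r}")
        mu = dm.X @ params.coef(spec.name, spec.covariates)
        scale = params.scale(spec.name)
        if spec.family == "normal":
            y = mu + scale * rng.standard_normal(dm.n)
        elif spec.family == "lognormal":
            y = np.exp(mu + scale * rng.standard_normal(dm.n))
        else:  # beta
            m = expit(mu)
            y = rng.beta(m * scale, (1.0 - m) * scale)
            y = squeeze_fractions(y, dm.n)
        work.loc[dm.index, spec.outcome] = y

    # Folch weighings consistent with the drawn fractions: the day-14 mass is
    # the fresh weight; lean weight is clipped at zero in the rare tail where
    # the independently drawn lipid fraction exceeds the dry-mass fraction.
    done = work["drymass_frac"].notna() & work["lipid_frac"].notna() \
        & work["mass_day14_mg"].notna()
    if done.any():
        fresh = work.loc[done, "mass_day14_mg"].to_numpy(dtype=float)
        dry = work.loc[done, "drymass_frac"].to_numpy(dtype=float) * fresh
        lean = np.clip(dry - work.loc[done, "lipid_frac"].to_numpy(float)
                       * fresh, 0.0, None)
        work.loc[done, "fresh_mg"] = fresh
        work.loc[done, "dry_mg"] = dry
        work.loc[done, "lean_mg"] = lean

    return _apply_missingness_frame(work)


# ---------------------------------------------------------------------------
# generation 1


def simulate_gen1(design: CohortDesign, params: ParameterSet, rng) -> list[Individual]:
    """Simulate the first-generation cohort.

    Larvae receive a pre-treatment mass draw and an exact-split treatment
    assignment, then pass through the four stage-mortality blocks; survivors
    receive sex, development time and the emergence/10-day masses.
    """
    design.validate()
    params.validate(list(GEN1_BLOCKS))
    rng = _as_rng(rng)
    n = design.n_gen1_larvae

    mass = rng.normal(design.larval_mass_mean_mg, design.larval_mass_sd_mg, n)
    while (bad := mass <= 0).any():        # truncation at zero
        mass[bad] = rng.normal(design.larval_mass_mean_mg,
                               design.larval_mass_sd_mg, int(bad.sum()))
    n_ins = int(round(n * design.treatment_allocation))
    within = np.full(n, "control", dtype=object)
    within[rng.permutation(n)[:n_ins]] = "insecticide"

    frame = pd.DataFrame({
        "id": [f"G1-{i + 1:04d}" for i in range(n)],
        "generation": np.ones(n, dtype=int),
        "within_treatment": within,
        "larval_mass_mg": mass,
    })
    work = resimulate(frame, params, rng, blocks=list(GEN1_BLOCKS),
                      keep_observed_sex=False)
    return individuals_from_frame(work)


def mate_design(gen1_survivors, design: CohortDesign, rng) -> list[Family]:
    """Draw the split-brood mating structure from gen-1 emerged adults.

    Sires are control males only; each sire is paired with
    ``dams_per_sire`` dams, half from each maternal-treatment group.  Raises
    :class:`ShortfallError` with the needed/available counts when the cohort
    cannot supply the design.
    """
    design.validate()
    rng = _as_rng(rng)
    frame = cohort_to_frame(gen1_survivors)
    emerged = (frame["generation"].astype(int) == 1)
    for col in ("died_24h", "died_larval", "died_pupal"):
        emerged &= frame[col] == 0.0

    males = frame[emerged & (frame["sex"] == "male")
                  & (frame["within_treatment"] == "control")]
    if len(males) < design.n_sires:
        raise ShortfallError(
            f"need {design.n_sires} control sires, only {len(males)} emerged "
            "control males available",
            needed=design.n_sires, available=len(males))
    half = design.dams_per_sire // 2
    dams: dict[str, pd.DataFrame] = {}
    for trt in ("control", "insecticide"):
        pool = frame[emerged & (frame["sex"] == "female")
                     & (frame["within_treatment"] == trt)]
        needed = design.n_sires * half
        if len(pool) < needed:
            raise ShortfallError(
                f"need {needed} {trt} dams, only {len(pool)} emerged {trt} "
                "females available",
                needed=needed, available=len(pool))
        dams[trt] = pool
    sire_ids = rng.choice(males["id"].to_numpy(), design.n_sires, replace=False)
    dam_rows = {trt: dams[trt].iloc[
        rng.choice(len(dams[trt]), design.n_sires * half, replace=False)]
        for trt in ("control", "insecticide")}

    families: list[Family] = []
    for i, sire in enumerate(sire_ids):
        for trt in ("control", "insecticide"):
            for j in range(half):
                dam = dam_rows[trt].iloc[i * half + j]
                mass = dam["mass_day10_mg"]
                families.append(Family(
                    family_id=f"F{len(families) + 1:02d}",
                    sire_id=str(sire), dam_id=str(dam["id"]),
                    maternal_treatment=trt,
                    maternal_mass10_mg=None if pd.isna(mass) else float(mass)))
    return families


# ---------------------------------------------------------------------------
# generation 2


def simulate_gen2(families: list[Family], design: CohortDesign,
                  params: ParameterSet, rng) -> list[Individual]:
    """Simulate the second-generation cohort from a mating design.

    Offspring are allocated near-uniformly across families, inherit the dam's
    treatment and 10-day mass, and are re-randomised to their own treatment.
    A dam with an unrecorded 10-day mass contributes through a latent mass
    drawn from the gen-1 10-day-mass model (the same conditional the sampler
    later imputes from); her offspring's recorded covariate is left missing.
    """
    design.validate()
    if design.n_gen2_larvae == 0:
        return []
    if not families:
        raise ConfigurationError("simulate_gen2 requires a non-empty mating design")
    params.validate(list(GEN2_BLOCKS) + ["g1_mass_day10"])
    rng = _as_rng(rng)
    n, n_fam = design.n_gen2_larvae, len(families)

    counts = np.full(n_fam, n // n_fam)
    rem = n - counts.sum()
    if rem > 0:
        counts[rng.choice(n_fam, rem, replace=False)] += 1

    alpha = params.blocks["g1_mass_day10"]
    latent_mass, observed = np.empty(n_fam), np.ones(n_fam, dtype=bool)
    for k, fam in enumerate(families):
        if fam.maternal_mass10_mg is None:
            mu = alpha["intercept"] + alpha["within"] * (
                fam.maternal_treatment == "insecticide")
            latent_mass[k] = mu + alpha["sigma"] * rng.standard_normal()
            observed[k] = False
        else:
            latent_mass[k] = fam.maternal_mass10_mg

    fam_idx = np.repeat(np.arange(n_fam), counts)
    n_ins = int(round(n * design.treatment_allocation))
    within = np.full(n, "control", dtype=object)
    within[rng.permutation(n)[:n_ins]] = "insecticide"

    frame = pd.DataFrame({
        "id": [f"G2-{i + 1:04d}" for i in range(n)],
        "generation": np.full(n, 2, dtype=int),
        "family_id": [families[k].family_id for k in fam_idx],
        "mother_id": [families[k].dam_id for k in fam_idx],
        "within_treatment": within,
        "maternal_treatment": [families[k].maternal_treatment for k in fam_idx],
        "maternal_mass10_mg": latent_mass[fam_idx],
    })
    work = resimulate(frame, params, rng, blocks=list(GEN2_BLOCKS),
                      keep_observed_sex=False)
    work.loc[~observed[fam_idx], "maternal_mass10_mg"] = np.nan
    return individuals_from_frame(work)


# ---------------------------------------------------------------------------
# missingness


def _apply_missingness_frame(frame: pd.DataFrame) -> pd.DataFrame:
    f = frame.copy()
    d24 = f["died_24h"] == 1.0
    dl = f["died_larval"] == 1.0
    dp = f["died_pupal"] == 1.0
    da = f["died_adult"] == 1.0
    f.loc[d24, "died_larval"] = np.nan
    f.loc[d24 | dl, "died_pupal"] = np.nan
    f.loc[d24 | dl | dp, "died_adult"] = np.nan
    pre_emergence = d24 | dl | dp
    f.loc[pre_emergence, list(_EMERGENCE_TRAITS)] = np.nan
    f.loc[pre_emergence | da, list(_LATE_TRAITS)] = np.nan

    g1 = f[f["generation"].astype(int) == 1]
    if len(g1) and f["mother_id"].notna().any():
        dam_mass = dict(zip(g1["id"], g1["mass_day10_mg"]))
        mapped = f["mother_id"].map(dam_mass)
        known_dam = f["mother_id"].notna() & f["mother_id"].isin(dam_mass)
        f.loc[known_dam & mapped.isna(), "maternal_mass10_mg"] = np.nan
    return f


def apply_missingness(cohort):
    """Blank every trait whose measurement age postdates death; idempotent.

    Also blanks the maternal-mass covariate of offspring whose dam's 10-day
    mass is missing (when the dam's record is present).  Accepts and returns
    either a list of :class:`Individual` or a cohort table.
    """
    if isinstance(cohort, pd.DataFrame):
        return _apply_missingness_frame(cohort)
    return individuals_from_frame(
        _apply_missingness_frame(cohort_to_frame(cohort)))


# ---------------------------------------------------------------------------
# full experiment


def simulate_cohort(design: CohortDesign, params: ParameterSet,
                    seed: int | None = None, max_attempts: int = 10):
    """Simulate the full two-generation experiment.

    Returns ``(individuals, families)`` with both generations concatenated.
    A realisation whose gen-1 survivors cannot supply the mating design is
    redrawn from a fresh substream (up to ``max_attempts`` times), mirroring
    the fact that the observed experiment was, by construction, feasible.
    """
    seed = design.seed if seed is None else seed
    last_err: ShortfallError | None = None
    for attempt in range(max_attempts):
        rng = np.random.default_rng([int(seed), attempt])
        gen1 = simulate_gen1(design, params, rng)
        try:
            families = mate_design(gen1, design, rng)
        except ShortfallError as err:
            last_err = err
            continue
        gen2 = (simulate_gen2(families, design, params, rng)
                if design.n_gen2_larvae > 0 else [])
        return gen1 + gen2, families
    raise ShortfallError(
        f"no feasible mating design in {max_attempts} attempts "
        f"(last shortfall: {last_err})",
        needed=getattr(last_err, "needed", None),
        available=getattr(last_err, "available", None))


# ---------------------------------------------------------------------------
# cohort CSV and design sidecar


def write_cohort(path, cohort) -> None:
    """Write a cohort CSV: one row per individual, missing values empty,
    stage-death booleans as 0/1."""
    frame = cohort_to_frame(cohort).copy()
    for col in _DEATH_COLS:
        frame[col] = frame[col].map(
            lambda v: "" if pd.isna(v) else str(int(v)))
    frame.to_csv(path, index=False, na_rep="")


def read_cohort(path, as_individuals: bool = False):
    """Read a cohort CSV written by :func:`write_cohort` (lossless)."""
    dtype = {c: "object" for c in _STRING_COLS}
    frame = pd.read_csv(path, dtype=dtype, float_precision="round_trip")
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"cohort CSV is missing columns {missing}")
    frame = frame[list(COLUMNS)]
    for col in COLUMNS:
        if col in _STRING_COLS:
            continue
        frame[col] = pd.to_numeric(frame[col], errors="raise")
    frame["generation"] = frame["generation"].astype(int)
    for col in COLUMNS:
        if col not in _STRING_COLS and col != "generation":
            frame[col] = frame[col].astype(float)
    if as_individuals:
        return individuals_from_frame(frame)
    return frame


def write_design_sidecar(path, design: CohortDesign,
                         params: ParameterSet | None = None,
                         seed: int | None = None) -> None:
    """Record the design, seed and true parameters next to a simulated cohort."""
    payload: dict = {"design": asdict(design)}
    if seed is not None:
        payload["seed"] = int(seed)
    if params is not None:
        payload["true_parameters"] = {
            b: {t: float(v) for t, v in terms.items()}
            for b, terms in params.blocks.items()}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def read_design_sidecar(path):
    """Read back a design sidecar; returns ``(design, params, seed)``."""
    payload = yaml.safe_load(Path(path).read_text())
    design = CohortDesign(**payload["design"])
    params = None
    if "true_parameters" in payload:
        params = ParameterSet({b: dict(t)
                               for b, t in payload["true_parameters"].items()})
    return design, params, payload.get("seed")
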