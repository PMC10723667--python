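"""Synthetic cohort generator.

Emulates the statistical structure the downstream hypergraph analysis
assumes, so the whole pipeline is testable without access to any real
primary/secondary-care extract:

* **Correlated binary disease flags** from a latent-factor threshold model.
  Each person draws independent standard-normal factor scores; disease
  ``i``'s latent score is ``eps_i + sum_k strength_k * loading_k[i] * f_k``
  and the flag is set when the standardised score exceeds the normal
  quantile matching the (age-adjusted) marginal prevalence.  With slope 0
  the configured marginals are recovered exactly in expectation; shared
  factors induce co-occurrence blocks without disturbing the marginals.
* **Age structure** of an adult (20+) population, drawn from configurable
  band probabilities with uniform ages within a band.
* **Utilisation counts** from a zero-inflated negative binomial whose
  log-mean rises linearly in the number of flagged diseases — a geometric-
  like frequency decay plus an enhanced zero count, the shape seen in
  routine outpatient/inpatient interaction data.
* **Planted structure**: a co-occurrence plant forces a whole disease set on
  with probability ``(boost - 1) x (product of member marginals)``, boosting
  the joint carriage probability by roughly the stated multiplier over the
  independence baseline; a cost plant adds a log-mean increment for persons
  whose *exact* profile equals the planted set, mirroring the exact-set
  stratification used by the HRU weights.

Everything is reproducible from ``config.seed`` alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from scipy.special import expit, logit, ndtri

from .catalogue import DiseaseCatalogue
from .cohort import Cohort

__all__ = [
    "DiseaseSpec", "LatentFactor", "PlantedCooccurrence", "PlantedCost",
    "HRUModel", "SimulationConfig", "generate_cohort", "default_config",
    "TABLE1_PREVALENCES",
]

# Marginal prevalences (fractions) of the order observed in a national adult
# multimorbidity cohort, keyed by post-merge Elixhauser disease.
TABLE1_PREVALENCES: dict[str, float] = {
    "Hypertension": 0.1330,
    "Diabetes": 0.0688,
    "Depression": 0.0669,
    "COPD": 0.0589,
    "Any Cancer": 0.0496,
    "Renal Disease": 0.0483,
    "Obesity": 0.0456,
    "Arrythmia": 0.0452,
    "Other Neurological Disorders": 0.0361,
    "Hypothyroidism": 0.0277,
    "Deficiency Anaemia": 0.0258,
    "Congestive heart failure": 0.0206,
    "Fluid & Electrolyte Disorders": 0.0198,
    "Weight Loss": 0.0187,
    "Valvular Disease": 0.0169,
    "Peripheral Vascular Disease": 0.0161,
    "Rheumatoid Arthritis": 0.0149,
    "Peptic Ulcer": 0.0094,
    "Liver Disease": 0.0073,
    "Pulmonary Circulation Disorder": 0.0067,
    "Paralysis": 0.0054,
    "Drug Abuse": 0.0053,
    "Psychosis": 0.0047,
    "Coagulopathy": 0.0034,
    "Lymphoma": 0.0022,
    "Blood loss anaemia": 0.0012,
}

_REFERENCE_AGE = 50.0  # age at which the configured marginal applies exactly


@dataclass(frozen=True)
class DiseaseSpec:
    name: str
    prevalence: float
    age_slope_per_decade: float = 0.0  # log-odds change per decade of age


@dataclass(frozen=True)
class LatentFactor:
    """One shared Gaussian factor: per-disease loadings and a strength >= 0."""
    loadings: tuple[float, ...]
    strength: float


@dataclass(frozen=True)
class PlantedCooccurrence:
    members: tuple[str, ...]
    boost: float  # joint-probability multiplier over the independence baseline, > 1


@dataclass(frozen=True)
class PlantedCost:
    members: tuple[str, ...]
    log_mean_increment: float  # gamma: applies only to exact-profile matches


@dataclass(frozen=True)
class HRUModel:
    """Zero-inflated negative-binomial utilisation model.

    log mean = log(baseline_mean) + per_disease_log_increment * (#diseases)
               + gamma_S when the person's exact profile equals a planted set S;
    the count is then zeroed with probability ``zero_inflation``.
    """
    zero_inflation: float = 0.0
    baseline_mean: float = 1.0
    per_disease_log_increment: float = 0.0
    dispersion: float = 1.0
    planted_cost_sets: tuple[PlantedCost, ...] = ()


@dataclass(frozen=True)
class SimulationConfig:
    n_persons: int
    diseases: tuple[DiseaseSpec, ...]
    latent_factors: tuple[LatentFactor, ...] = ()
    planted_cooccur_sets: tuple[PlantedCooccurrence, ...] = ()
    outpatient: HRUModel = field(default_factory=HRUModel)
    inpatient: HRUModel = field(default_factory=HRUModel)
    # (lower, upper-exclusive, probability); top band may use upper=None
    age_bands: tuple[tuple[int, int | None, float], ...] = ((20, 90, 1.0),)
    seed: int = 0

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        if self.n_persons <= 0:
            raise ValueError("n_persons must be positive")
        names = [d.name for d in self.diseases]
        if len(set(names)) != len(names) or not names:
            raise ValueError("disease names must be unique and non-empty")
        for d in self.diseases:
            if not (0.0 < d.prevalence < 1.0) or not np.isfinite(d.prevalence):
                raise ValueError(f"prevalence of {d.name!r} must lie strictly in (0,1)")
            if not np.isfinite(d.age_slope_per_decade):
                raise ValueError(f"non-finite age slope for {d.name!r}")
        for f in self.latent_factors:
            if len(f.loadings) != len(names):
                raise ValueError("factor loading length must match the disease list")
            if not np.all(np.isfinite(f.loadings)) or not np.isfinite(f.strength):
                raise ValueError("non-finite latent-factor parameters")
            if f.strength < 0:
                raise ValueError("factor strength must be >= 0")
        for p in self.planted_cooccur_sets:
            unknown = set(p.members) - set(names)
            if unknown:
                raise ValueError(f"planted set references unknown diseases: {sorted(unknown)}")
            if not np.isfinite(p.boost) or p.boost < 1.0:
                raise ValueError("co-occurrence boost must be finite and >= 1")
        for model, label in ((self.outpatient, "outpatient"), (self.inpatient, "inpatient")):
            if not (0.0 <= model.zero_inflation <= 1.0):
                raise ValueError(f"{label} zero_inflation must lie in [0,1]")
            if not (model.baseline_mean > 0 and np.isfinite(model.baseline_mean)):
                raise ValueError(f"{label} baseline_mean must be positive and finite")
            if not (model.dispersion > 0 and np.isfinite(model.dispersion)):
                raise ValueError(f"{label} dispersion must be positive and finite")
            if not np.isfinite(model.per_disease_log_increment):
                raise ValueError(f"{label} per-disease log increment must be finite")
            for p in model.planted_cost_sets:
                unknown = set(p.members) - set(names)
                if unknown:
                    raise ValueError(
                        f"{label} planted cost set references unknown diseases: {sorted(unknown)}"
                    )
                if not np.isfinite(p.log_mean_increment):
                    raise ValueError(f"{label} planted cost increment must be finite")
        probs = np.array([b[2] for b in self.age_bands], dtype=float)
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError(f"age-band probabilities must sum to 1 (got {probs.sum()})")

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        def hru(m):
            m = dict(m)
            m["planted_cost_sets"] = tuple(
                PlantedCost(tuple(p["members"]), float(p["log_mean_increment"]))
                for p in m.get("planted_cost_sets", ())
            )
            return HRUModel(**m)

        return cls(
            n_persons=int(d["n_persons"]),
            diseases=tuple(DiseaseSpec(**dict(x)) for x in d["diseases"]),
            latent_factors=tuple(
                LatentFactor(tuple(x["loadings"]), float(x["strength"]))
                for x in d.get("latent_factors", ())
            ),
            planted_cooccur_sets=tuple(
                PlantedCooccurrence(tuple(x["members"]), float(x["boost"]))
                for x in d.get("planted_cooccur_sets", ())
            ),
            outpatient=hru(d.get("outpatient", {})),
            inpatient=hru(d.get("inpatient", {})),
            age_bands=tuple(
                (int(b[0]), None if b[1] is None else int(b[1]), float(b[2]))
                for b in d.get("age_bands", ((20, 90, 1.0),))
            ),
            seed=int(d.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @property
    def catalogue(self) -> DiseaseCatalogue:
        return DiseaseCatalogue(tuple(d.name for d in self.diseases))


def _draw_ages(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    probs = np.array([b[2] for b in config.age_bands])
    band = rng.choice(len(config.age_bands), size=config.n_persons, p=probs)
    ages = np.empty(config.n_persons, dtype=np.int64)
    for i, (lo, hi, _) in enumerate(config.age_bands):
        mask = band == i
        hi_eff = (lo + 10) if hi is None else hi
        ages[mask] = rng.integers(lo, hi_eff, size=int(mask.sum()))
    return ages


def _draw_flags(config: SimulationConfig, ages: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
    n, d = config.n_persons, len(config.diseases)
    score = rng.standard_normal((n, d))
    var = np.ones(d)
    for f in config.latent_factors:
        load = f.strength * np.asarray(f.loadings)
        score += np.outer(rng.standard_normal(n), load)
        var += load**2
    sd = np.sqrt(var)
    prev = np.array([spec.prevalence for spec in config.diseases])
    slope = np.array([spec.age_slope_per_decade for spec in config.diseases])
    # age-adjusted marginal, anchored so the configured marginal holds at age 50
    lp = logit(prev)[None, :] + slope[None, :] * ((ages[:, None] - _REFERENCE_AGE) / 10.0)
    p_age = expit(lp)
    thresh = ndtri(1.0 - p_age) * sd[None, :]
    flags = (score > thresh).astype(np.int8)
    names = [spec.name for spec in config.diseases]
    for plant in config.planted_cooccur_sets:
        idx = [names.index(m) for m in plant.members]
        q = min(1.0, (plant.boost - 1.0) * float(np.prod(prev[idx])))
        force = rng.random(n) < q
        flags[np.ix_(force, idx)] = 1
    return flags


def _profile_keys(flags: np.ndarray) -> np.ndarray:
    d = flags.shape[1]
    if d > 62:
        raise ValueError("more than 62 diseases not supported")
    powers = (np.int64(1) << np.arange(d, dtype=np.int64))
    return flags.astype(np.int64) @ powers


def _draw_counts(model: HRUModel, flags: np.ndarray, names: list[str],
                 rng: np.random.Generator) -> np.ndarray:
    n = flags.shape[0]
    log_mean = (np.log(model.baseline_mean)
                + model.per_disease_log_increment * flags.sum(axis=1))
    if model.planted_cost_sets:
        keys = _profile_keys(flags)
        for plant in model.planted_cost_sets:
            idx = [names.index(m) for m in plant.members]
            target = np.sum(np.int64(1) << np.array(idx, dtype=np.int64))
            log_mean = log_mean + plant.log_mean_increment * (keys == target)
    mean = np.exp(log_mean)
    # gamma-Poisson mixture = negative binomial with shape `dispersion`
    lam = rng.gamma(shape=model.dispersion, scale=mean / model.dispersion, size=n)
    counts = rng.poisson(lam)
    zero = rng.random(n) < model.zero_inflation
    counts[zero] = 0
    return counts.astype(np.int64)


def generate_cohort(config: SimulationConfig) -> Cohort:
    """Draw a fully reproducible synthetic cohort from ``config``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    names = [spec.name for spec in config.diseases]
    ages = _draw_ages(config, rng)
    flags = _draw_flags(config, ages, rng)
    outpatient = _draw_counts(config.outpatient, flags, names, rng)
    inpatient = _draw_counts(config.inpatient, flags, names, rng)
    person_id = np.array([f"P{i:07d}" for i in range(config.n_persons)])
    return Cohort(flags, ages, outpatient, inpatient, config.catalogue,
                  person_id=person_id)


# Adult (20+) age-band probabilities of a broadly UK-2000-like population:
# 5-year bands 20-24 ... 90+, gently declining with age.
_DEFAULT_AGE_BANDS: tuple[tuple[int, int | None, float], ...] = (
    (20, 25, 0.085), (25, 30, 0.090), (30, 35, 0.095), (35, 40, 0.095),
    (40, 45, 0.090), (45, 50, 0.085), (50, 55, 0.085), (55, 60, 0.080),
    (60, 65, 0.070), (65, 70, 0.060), (70, 75, 0.055), (75, 80, 0.045),
    (80, 85, 0.032), (85, 90, 0.020), (90, None, 0.013),
)

# Co-occurrence blocks: cardiometabolic, respiratory/frailty, mental health.
_FACTOR_BLOCKS = (
    ({"Hypertension", "Diabetes", "Obesity", "Congestive heart failure",
      "Renal Disease", "Arrythmia", "Peripheral Vascular Disease",
      "Valvular Disease"}, 0.8),
    ({"COPD", "Congestive heart failure", "Fluid & Electrolyte Disorders",
      "Weight Loss", "Deficiency Anaemia", "Pulmonary Circulation Disorder"}, 0.7),
    ({"Depression", "Psychosis", "Drug Abuse", "Other Neurological Disorders"}, 0.6),
)

_CARDIO_AGE_SLOPE = {
    "Hypertension", "Diabetes", "Any Cancer", "Renal Disease", "Arrythmia",
    "Congestive heart failure", "Peripheral Vascular Disease", "Valvular Disease",
}


def default_config(n_persons: int = 20_000, seed: int = 0) -> SimulationConfig:
    """Default study conditions: 26 post-merge diseases with realistic
    marginals, three co-occurrence blocks, one planted co-occurrence triple
    and one planted high-cost pair, zero-inflated NB utilisation."""
    names = list(TABLE1_PREVALENCES)
    diseases = tuple(
        DiseaseSpec(name, TABLE1_PREVALENCES[name],
                    0.3 if name in _CARDIO_AGE_SLOPE else 0.0)
        for name in names
    )
    factors = tuple(
        LatentFactor(tuple(1.0 if n in block else 0.0 for n in names), strength)
        for block, strength in _FACTOR_BLOCKS
    )
    return SimulationConfig(
        n_persons=n_persons,
        diseases=diseases,
        latent_factors=factors,
        planted_cooccur_sets=(
            PlantedCooccurrence(("Diabetes", "Hypertension", "Obesity"), boost=50.0),
        ),
        outpatient=HRUModel(
            zero_inflation=0.25, baseline_mean=2.0,
            per_disease_log_increment=0.35, dispersion=1.2,
            planted_cost_sets=(
                PlantedCost(("Diabetes", "Hypertension"), log_mean_increment=1.5),
            ),
        ),
        inpatient=HRUModel(
            zero_inflation=0.50, baseline_mean=0.3,
            per_disease_log_increment=0.40, dispersion=0.8,
        ),
        age_bands=_DEFAULT_AGE_BANDS,
        seed=seed,
    )
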