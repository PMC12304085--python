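"""Individual-based forward simulation of migration-connected demes.

The life cycle mirrors an overlapping-generations, age-structured population
(a tuna-like marine fish by default): at every time step each deme applies, in
this fixed order,

1. age-dependent survival (independent Bernoulli draws from ``s_age``),
2. ageing by one year,
3. migration (each individual swaps demes with probability ``m``),
4. reproduction: exactly ``cohort_size`` newborns per deme, each drawing its
   mother among the deme's mature females and its father among the deme's
   mature males, independently and with replacement, with probability
   proportional to the age-specific fertility weight ``b_age``.

Migration precedes reproduction so that migrants breed in their destination
deme.  Recruitment is exact by default ("N0 descendants on average" enters
through parent assignment only); a Poisson-recruitment option exists but is
off by default.  Every individual ever alive is recorded in a pedigree table
(parents, sexes, birth/death steps, deme at birth, migration events), which is
the substrate for realized-Ne diagnostics, kin-pair censuses and gene
dropping.  Serial sampling draws, per deme, per step of the sampling window
and per age class 1..A, ``floor(rate * class abundance)`` distinct living
individuals, never re-sampling an individual across steps.

Runs are deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .demography import VitalRates, default_vital_rates, equilibrium_age_structure
from .errors import ConfigError, ExtinctionError

__all__ = [
    "SimConfig",
    "PedigreeTable",
    "PopulationState",
    "SimResult",
    "init_population",
    "step",
    "draw_samples",
    "run",
]

FEMALE, MALE = 0, 1
NO_PARENT = -1


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one forward run (defaults: the reference two-deme
    tuna-like population, m = 0.05, 100 steps, sampling 10% of each age
    class at steps 90..100)."""

    rates: VitalRates = field(default_factory=default_vital_rates)
    cohort_size: int = 5000
    n_demes: int = 2
    migration: float = 0.05
    n_steps: int = 100
    sampling_start: int = 90
    sampling_end: int = 100
    sampling_rate: float = 0.10
    seed: int = 0
    poisson_recruitment: bool = False

    def __post_init__(self):
        if not 0.0 <= self.migration <= 1.0:
            raise ConfigError("migration must lie in [0, 1]")
        if not 0.0 <= self.sampling_rate <= 1.0:
            raise ConfigError("sampling_rate must lie in [0, 1]")
        if self.cohort_size < 1:
            raise ConfigError("cohort_size must be >= 1")
        if self.n_demes < 1:
            raise ConfigError("n_demes must be >= 1")
        if self.n_steps < 0:
            raise ConfigError("n_steps must be >= 0")

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


class _PedigreeBuilder:
    """Append-only store of per-individual records (chunked numpy arrays)."""

    def __init__(self):
        self.sex: list[np.ndarray] = []
        self.birth_step: list[np.ndarray] = []
        self.deme_birth: list[np.ndarray] = []
        self.mother: list[np.ndarray] = []
        self.father: list[np.ndarray] = []
        self.n = 0
        self.death_step: list[np.ndarray] = []  # assembled at finalise
        self._death_records: list[tuple[np.ndarray, int]] = []
        self.migrations: list[tuple[np.ndarray, int, np.ndarray, np.ndarray]] = []

    def add(self, sex, birth_step, deme_birth, mother, father) -> np.ndarray:
        k = len(sex)
        ids = np.arange(self.n, self.n + k, dtype=np.int64)
        self.sex.append(np.asarray(sex, dtype=np.int8))
        self.birth_step.append(np.full(k, birth_step, dtype=np.int32))
        self.deme_birth.append(np.asarray(deme_birth, dtype=np.int16))
        self.mother.append(np.asarray(mother, dtype=np.int64))
        self.father.append(np.asarray(father, dtype=np.int64))
        self.n += k
        return ids

    def record_deaths(self, ids: np.ndarray, step: int) -> None:
        self._death_records.append((ids, step))

    def record_migration(self, ids, step, src, dst) -> None:
        self.migrations.append((ids.copy(), step, src.copy(), dst.copy()))

    def finalise(self, end_step: int) -> "PedigreeTable":
        death = np.full(self.n, end_step + 1, dtype=np.int32)  # alive at end
        alive_at_end = np.ones(self.n, dtype=bool)
        for ids, t in self._death_records:
            death[ids] = t
            alive_at_end[ids] = False
        mig_rows = []
        for ids, t, src, dst in self.migrations:
            mig_rows.append(
                pd.DataFrame(
                    {"id": ids, "step": t, "from_deme": src, "to_deme": dst}
                )
            )
        migrations = (
            pd.concat(mig_rows, ignore_index=True)
            if mig_rows
            else pd.DataFrame(columns=["id", "step", "from_deme", "to_deme"])
        )
        return PedigreeTable(
            sex=np.concatenate(self.sex) if self.sex else np.empty(0, np.int8),
            birth_step=np.concatenate(self.birth_step)
            if self.birth_step
            else np.empty(0, np.int32),
            deme_birth=np.concatenate(self.deme_birth)
            if self.deme_birth
            else np.empty(0, np.int16),
            mother=np.concatenate(self.mother)
            if self.mother
            else np.empty(0, np.int64),
            father=np.concatenate(self.father)
            if self.father
            else np.empty(0, np.int64),
            death_step=death,
            alive_at_end=alive_at_end,
            end_step=end_step,
            migrations=migrations,
        )


@dataclass
class PedigreeTable:
    """Immutable record of every simulated individual.

    Row index is the individual id.  ``mother``/``father`` are ``-1`` for
    founders.  ``death_step`` is the step during whose survival stage the
    individual died (``end_step + 1`` for individuals alive at the end;
    ``alive_at_end`` disambiguates).  ``migrations`` lists deme changes.
    """

    sex: np.ndarray
    birth_step: np.ndarray
    deme_birth: np.ndarray
    mother: np.ndarray
    father: np.ndarray
    death_step: np.ndarray
    alive_at_end: np.ndarray
    end_step: int
    migrations: pd.DataFrame

    def __len__(self) -> int:
        return len(self.sex)

    @property
    def is_founder(self) -> np.ndarray:
        return self.mother == NO_PARENT

    def age_at_death(self) -> np.ndarray:
        """Last age completed (age during the step in which death occurred,
        minus the year being entered); alive-at-end individuals get the age
        they hold at ``end_step``."""
        return self.death_step - self.birth_step - 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": np.arange(len(self), dtype=np.int64),
                "sex": self.sex,
                "birth_step": self.birth_step,
                "deme_birth": self.deme_birth,
                "mother": self.mother,
                "father": self.father,
                "death_step": self.death_step,
                "alive_at_end": self.alive_at_end.astype(int),
            }
        )

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# nebench pedigree end_step={self.end_step}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "PedigreeTable":
        with open(path) as fh:
            header = fh.readline().strip()
            end_step = int(header.rsplit("end_step=", 1)[1])
            df = pd.read_csv(fh, sep="\t")
        return cls(
            sex=df["sex"].to_numpy(np.int8),
            birth_step=df["birth_step"].to_numpy(np.int32),
            deme_birth=df["deme_birth"].to_numpy(np.int16),
            mother=df["mother"].to_numpy(np.int64),
            father=df["father"].to_numpy(np.int64),
            death_step=df["death_step"].to_numpy(np.int32),
            alive_at_end=df["alive_at_end"].to_numpy(bool),
            end_step=end_step,
            migrations=pd.DataFrame(columns=["id", "step", "from_deme", "to_deme"]),
        )


@dataclass
class PopulationState:
    """Mutable state of the living population during a run."""

    ids: np.ndarray
    ages: np.ndarray
    sexes: np.ndarray
    demes: np.ndarray
    step_index: int
    builder: _PedigreeBuilder
    sampled: set = field(default_factory=set)

    def census(self, n_demes: int) -> np.ndarray:
        return np.bincount(self.demes, minlength=n_demes)


@dataclass
class SimResult:
    config: SimConfig
    pedigree: PedigreeTable
    samples: pd.DataFrame  # id, step_sampled, age_at_sampling, deme
    census: pd.DataFrame  # step, deme, count


def init_population(config: SimConfig) -> PopulationState:
    """Populate every deme with the rounded equilibrium age structure.

    Founders carry ``birth_step = -age`` (so parent birth always precedes
    child birth in downstream checks) and null parents.  Sexes are assigned
    alternately within each age class so that both sexes are present even in
    tiny classes; the tiny departure from Bernoulli assignment only affects
    founders.
    """
    rng = np.random.default_rng(config.seed)
    structure = equilibrium_age_structure(config.rates, config.cohort_size)
    counts = structure.rounded_counts
    builder = _PedigreeBuilder()
    ids_l, ages_l, sexes_l, demes_l = [], [], [], []
    for deme in range(config.n_demes):
        for age, n_age in enumerate(counts):
            if n_age == 0:
                continue
            sexes = (np.arange(n_age) + rng.integers(0, 2)) % 2
            ids = builder.add(
                sexes.astype(np.int8),
                -age,
                np.full(n_age, deme),
                np.full(n_age, NO_PARENT),
                np.full(n_age, NO_PARENT),
            )
            ids_l.append(ids)
            ages_l.append(np.full(n_age, age, dtype=np.int16))
            sexes_l.append(sexes.astype(np.int8))
            demes_l.append(np.full(n_age, deme, dtype=np.int16))
    state = PopulationState(
        ids=np.concatenate(ids_l),
        ages=np.concatenate(ages_l),
        sexes=np.concatenate(sexes_l),
        demes=np.concatenate(demes_l),
        step_index=0,
        builder=builder,
    )
    state._rng = rng  # continue the same stream through the run
    return state


def step(state: PopulationState, config: SimConfig, rng: np.random.Generator) -> PopulationState:
    """Advance one time step: survival, ageing, migration, reproduction."""
    rates = config.rates
    t = state.step_index + 1
    s_full = np.concatenate([rates.survival, [0.0]])

    # 1. survival
    survive = rng.random(len(state.ids)) < s_full[state.ages]
    state.builder.record_deaths(state.ids[~survive], t)
    ids = state.ids[survive]
    ages = state.ages[survive]
    sexes = state.sexes[survive]
    demes = state.demes[survive]

    # 2. ageing
    ages = ages + 1

    # 3. migration
    if config.n_demes > 1 and config.migration > 0:
        move = rng.random(len(ids)) < config.migration
        if move.any():
            src = demes[move]
            if config.n_demes == 2:
                dst = 1 - src
            else:
                shift = rng.integers(1, config.n_demes, size=move.sum())
                dst = (src + shift) % config.n_demes
            demes = demes.copy()
            demes[move] = dst
            state.builder.record_migration(ids[move], t, src, dst.astype(np.int16))

    # 4. reproduction
    mature = ages >= rates.maturity_age
    weights = rates.fertility[ages]
    new_ids, new_ages, new_sexes, new_demes = [], [], [], []
    for deme in range(config.n_demes):
        in_deme = demes == deme
        fem = in_deme & mature & (sexes == FEMALE) & (weights > 0)
        mal = in_deme & mature & (sexes == MALE) & (weights > 0)
        if not fem.any():
            raise ExtinctionError(deme, t, "female")
        if not mal.any():
            raise ExtinctionError(deme, t, "male")
        n0 = (
            int(rng.poisson(config.cohort_size))
            if config.poisson_recruitment
            else config.cohort_size
        )
        if n0 == 0:
            continue
        wf = weights[fem]
        wm = weights[mal]
        mothers = rng.choice(ids[fem], size=n0, p=wf / wf.sum())
        fathers = rng.choice(ids[mal], size=n0, p=wm / wm.sum())
        child_sex = (rng.random(n0) >= rates.sex_ratio).astype(np.int8)  # 0=F
        ids_new = state.builder.add(
            child_sex, t, np.full(n0, deme), mothers, fathers
        )
        new_ids.append(ids_new)
        new_ages.append(np.zeros(n0, dtype=np.int16))
        new_sexes.append(child_sex)
        new_demes.append(np.full(n0, deme, dtype=np.int16))

    state.ids = np.concatenate([ids] + new_ids)
    state.ages = np.concatenate([ages] + new_ages)
    state.sexes = np.concatenate([sexes] + new_sexes)
    state.demes = np.concatenate([demes] + new_demes)
    state.step_index = t
    return state


def draw_samples(
    state: PopulationState, config: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Serial sampling of the current step (ages 1..A, per deme, per class).

    Takes ``floor(rate * class abundance)`` distinct living individuals per
    deme and age class, skipping individuals captured at an earlier step.
    """
    rows = []
    for deme in range(config.n_demes):
        for age in range(1, config.rates.max_age + 1):
            in_class = (state.demes == deme) & (state.ages == age)
            n_class = int(in_class.sum())
            n_take = int(np.floor(config.sampling_rate * n_class))
            if n_take == 0:
                continue
            cand = state.ids[in_class]
            fresh = np.array([i not in state.sampled for i in cand])
            cand = cand[fresh]
            n_take = min(n_take, len(cand))
            if n_take == 0:
                continue
            take = rng.choice(cand, size=n_take, replace=False)
            state.sampled.update(take.tolist())
            rows.append(
                pd.DataFrame(
                    {
                        "id": np.sort(take),
                        "step_sampled": state.step_index,
                        "age_at_sampling": age,
                        "deme": deme,
                    }
                )
            )
    if not rows:
        return pd.DataFrame(columns=["id", "step_sampled", "age_at_sampling", "deme"])
    return pd.concat(rows, ignore_index=True)


def run(config: SimConfig) -> SimResult:
    """Run the full simulation; deterministic given ``config.seed``."""
    state = init_population(config)
    rng = state._rng
    census_rows = [
        {"step": 0, "deme": d, "count": int(c)}
        for d, c in enumerate(state.census(config.n_demes))
    ]
    sample_frames = []
    for t in range(1, config.n_steps + 1):
        state = step(state, config, rng)
        for d, c in enumerate(state.census(config.n_demes)):
            census_rows.append({"step": t, "deme": d, "count": int(c)})
        if config.sampling_start <= t <= config.sampling_end:
            sample_frames.append(draw_samples(state, config, rng))
    pedigree = state.builder.finalise(config.n_steps)
    samples = (
        pd.concat(sample_frames, ignore_index=True)
        if sample_frames
        else pd.DataFrame(columns=["id", "step_sampled", "age_at_sampling", "deme"])
    )
    return SimResult(
        config=config,
        pedigree=pedigree,
        samples=samples,
        census=pd.DataFrame(census_rows),
    )
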