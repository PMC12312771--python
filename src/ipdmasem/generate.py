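"""Simulation of meta-analytic IPD collections.

A collection of k primary studies is generated in two stages: study means
are drawn i.i.d. from N(0, Sigma_B), then the n_j participants of study j
are drawn i.i.d. from N(mu_j, Sigma_W). Study sizes are sampled uniformly
(with replacement) from an integer range, by default [90, 1238], the
min/max observed in the health-behavior IPD collection the population
matrices are modeled on. Grand means are fixed at zero: the estimators
under study carry a free mean structure, so means are pure nuisance.

Variable-level missingness removes the behavior variable (BEH) entirely
from exactly half of the studies, mimicking primary studies that never
measured the outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .scenarios import VARIABLES, ScenarioID, TwoLevelPopulation, get_scenario

__all__ = [
    "ConditionSpec",
    "StudyData",
    "MetaDataset",
    "draw_study_sizes",
    "simulate_meta_dataset",
    "apply_missingness",
    "center_within",
    "rng_for_replication",
    "generate_replication",
    "to_frame",
    "from_frame",
]

_BEH = VARIABLES.index("BEH")


@dataclass(frozen=True)
class ConditionSpec:
    """One cell of the simulation design."""

    scenario: ScenarioID
    k: int
    missing: bool = False
    n_min: int = 90
    n_max: int = 1238
    reps: int = 1
    master_seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "scenario", ScenarioID(self.scenario))
        if self.k < 2:
            raise ValueError("need at least 2 studies")
        if not (0 < self.n_min <= self.n_max):
            raise ValueError("invalid study-size bounds")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")

    @property
    def label(self) -> str:
        return f"{self.scenario.value}|k={self.k}|missing={self.missing}"


@dataclass(frozen=True)
class StudyData:
    """Raw observations of one primary study.

    ``observations`` always has one column per model variable; columns of
    unobserved variables are NaN and flagged False in ``observed_mask``.
    """

    study_id: int
    observations: np.ndarray
    observed_mask: np.ndarray

    @property
    def n_j(self) -> int:
        return self.observations.shape[0]

    @property
    def observed_variables(self) -> tuple[str, ...]:
        return tuple(v for v, m in zip(VARIABLES, self.observed_mask) if m)


@dataclass(frozen=True)
class MetaDataset:
    """A simulated IPD collection: k studies from one condition/replication."""

    studies: tuple[StudyData, ...]
    condition: ConditionSpec
    replication: int = 0
    seed: int | None = None

    @property
    def k(self) -> int:
        return len(self.studies)

    @property
    def n_total(self) -> int:
        return sum(s.n_j for s in self.studies)


def draw_study_sizes(
    k: int, n_min: int, n_max: int, rng: np.random.Generator
) -> np.ndarray:
    """k study sizes, each uniform on the integers [n_min, n_max] inclusive."""
    if not (0 < n_min <= n_max):
        raise ValueError("invalid study-size bounds")
    return rng.integers(n_min, n_max + 1, size=k)


def simulate_meta_dataset(
    pop: TwoLevelPopulation,
    cond: ConditionSpec,
    rng: np.random.Generator,
    replication: int = 0,
) -> MetaDataset:
    """Draw one IPD collection under ``cond`` (missingness not yet applied)."""
    for name, sigma in (("sigma_w", pop.sigma_w), ("sigma_b", pop.sigma_b)):
        try:
            np.linalg.cholesky(sigma + 1e-12 * np.eye(sigma.shape[0]))
        except np.linalg.LinAlgError:
            raise ValueError(f"{name} is not positive definite") from None
    p = len(pop.variables)
    sizes = draw_study_sizes(cond.k, cond.n_min, cond.n_max, rng)
    means = rng.multivariate_normal(
        np.zeros(p), pop.sigma_b, size=cond.k, method="cholesky"
    )
    studies = []
    for j, (n_j, mu_j) in enumerate(zip(sizes, means)):
        obs = rng.multivariate_normal(mu_j, pop.sigma_w, size=int(n_j), method="cholesky")
        studies.append(
            StudyData(study_id=j, observations=obs, observed_mask=np.ones(p, dtype=bool))
        )
    return MetaDataset(tuple(studies), condition=cond, replication=replication)


def apply_missingness(ds: MetaDataset, rng: np.random.Generator) -> MetaDataset:
    """Mask BEH entirely in exactly half of the studies (chosen at random)."""
    if not ds.condition.missing:
        return ds
    if ds.k % 2:
        raise ValueError("variable-level missingness requires an even study count")
    masked_ids = set(rng.choice(ds.k, size=ds.k // 2, replace=False).tolist())
    studies = []
    for s in ds.studies:
        if s.study_id in masked_ids:
            obs = s.observations.copy()
            obs[:, _BEH] = np.nan
            mask = s.observed_mask.copy()
            mask[_BEH] = False
            studies.append(replace(s, observations=obs, observed_mask=mask))
        else:
            studies.append(s)
    return replace(ds, studies=tuple(studies))


def center_within(ds: MetaDataset) -> MetaDataset:
    """Subtract each study's own mean from its observed variables."""
    studies = []
    for s in ds.studies:
        obs = s.observations.copy()
        cols = np.flatnonzero(s.observed_mask)
        obs[:, cols] -= obs[:, cols].mean(axis=0, keepdims=True)
        studies.append(replace(s, observations=obs))
    return replace(ds, studies=tuple(studies))


def rng_for_replication(cond: ConditionSpec, replication: int) -> np.random.Generator:
    """Deterministic child stream for one (condition, replication) cell.

    The spawn key encodes the condition, so conditions and replications can
    be simulated in any order (or in parallel) with identical results.
    """
    scen_idx = list(ScenarioID).index(cond.scenario)
    key = (scen_idx, cond.k, int(cond.missing), replication)
    ss = np.random.SeedSequence(entropy=cond.master_seed, spawn_key=key)
    return np.random.default_rng(ss)


def generate_replication(cond: ConditionSpec, replication: int = 0) -> MetaDataset:
    """Generate one fully prepared dataset (including missingness) for a cell."""
    rng = rng_for_replication(cond, replication)
    ds = simulate_meta_dataset(get_scenario(cond.scenario), cond, rng, replication)
    return apply_missingness(ds, rng)


# ---------------------------------------------------------------------------
# long-format CSV interchange


def to_frame(ds: MetaDataset) -> pd.DataFrame:
    """Long format: study_id, participant_id, one column per variable."""
    frames = []
    for s in ds.studies:
        df = pd.DataFrame(s.observations, columns=list(VARIABLES))
        df.insert(0, "participant_id", np.arange(s.n_j))
        df.insert(0, "study_id", s.study_id)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def from_frame(df: pd.DataFrame, condition: ConditionSpec | None = None) -> MetaDataset:
    studies = []
    for sid, sub in df.groupby("study_id", sort=True):
        obs = sub[list(VARIABLES)].to_numpy(dtype=float)
        mask = ~np.all(np.isnan(obs), axis=0)
        studies.append(StudyData(int(sid), obs, mask))
    if condition is None:
        condition = ConditionSpec(ScenarioID.S4_high_equal, k=max(len(studies), 2))
    return MetaDataset(tuple(studies), condition=condition)


def dump_csv(ds: MetaDataset, path) -> None:
    to_frame(ds).to_csv(path, index=False)


def load_csv(path, condition: ConditionSpec | None = None) -> MetaDataset:
    return from_frame(pd.read_csv(path), condition)
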