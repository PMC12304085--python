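"""Diagnostics on the recorded pedigree.

Two purposes, mirroring the "diagnose your simulation" step of any
simulation-based Ne study: (1) the realized effective size, computed from the
variance in *actual* lifetime reproductive success of each fully-observed
birth cohort via ``Ne = 4 * N1 * T / (Vk + 2)``, to be compared with the
theoretical value from the vital rates; and (2) a census of related pairs
(parent-offspring, full-sib, half-sib, grandparent-linked) within a sample,
which quantifies how sampling design concentrates close kin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .demography import NeEstimate, VitalRates, generation_length
from .errors import IncompleteLifetimeError, NebenchError
from .forward_sim import NO_PARENT, PedigreeTable

__all__ = [
    "CohortRS",
    "KinPairCensus",
    "lifetime_rs",
    "realized_ne",
    "breeders_per_step",
    "kin_pair_census",
]


@dataclass
class CohortRS:
    """Lifetime reproductive success of one birth cohort (one deme)."""

    birth_step: int
    deme: int
    k: np.ndarray  # lifetime offspring count per cohort member
    n1: int  # members surviving to age 1

    @property
    def n(self) -> int:
        return len(self.k)

    @property
    def mean_k(self) -> float:
        return float(self.k.mean())

    @property
    def vk(self) -> float:
        """Population (ddof=0) variance of lifetime offspring counts."""
        return float(self.k.var())


@dataclass
class KinPairCensus:
    """Counts of unordered sample pairs by closest relationship.

    Categories are mutually exclusive with precedence parent-offspring >
    full-sib > half-sib > grandparent-linked (any shared ancestor within two
    generations, e.g. grandparent-grandchild, avuncular or cousin pairs);
    remaining pairs are unrelated at depth <= 2.
    """

    parent_offspring: int
    full_sib: int
    half_sib: int
    grandparent_linked: int
    unrelated: int

    @property
    def total_pairs(self) -> int:
        return (
            self.parent_offspring
            + self.full_sib
            + self.half_sib
            + self.grandparent_linked
            + self.unrelated
        )

    def as_dict(self) -> dict[str, int]:
        return {
            "parent_offspring": self.parent_offspring,
            "full_sib": self.full_sib,
            "half_sib": self.half_sib,
            "grandparent_linked": self.grandparent_linked,
            "unrelated": self.unrelated,
        }


def _offspring_counts(pedigree: PedigreeTable) -> np.ndarray:
    n = len(pedigree)
    counts = np.bincount(pedigree.mother[pedigree.mother != NO_PARENT], minlength=n)
    counts += np.bincount(pedigree.father[pedigree.father != NO_PARENT], minlength=n)
    return counts


def lifetime_rs(
    pedigree: PedigreeTable,
    birth_step: int,
    deme: int,
    max_age: int,
    allow_incomplete: bool = False,
) -> CohortRS:
    """Lifetime offspring counts for the cohort born in ``deme`` at
    ``birth_step``.

    Counts offspring over the whole life, regardless of where (which deme)
    they were produced.  Raises unless the cohort's full reproductive
    lifespan fits inside the simulation (``birth_step + max_age <=
    end_step``) or ``allow_incomplete`` is set.
    """
    if birth_step + max_age > pedigree.end_step and not allow_incomplete:
        raise IncompleteLifetimeError(
            f"cohort born at step {birth_step} can reproduce until step "
            f"{birth_step + max_age}, beyond the simulated {pedigree.end_step}"
        )
    members = np.flatnonzero(
        (pedigree.birth_step == birth_step) & (pedigree.deme_birth == deme)
    )
    if members.size == 0:
        raise NebenchError(f"no individuals born in deme {deme} at step {birth_step}")
    k = _offspring_counts(pedigree)[members]
    reached_1 = (
        pedigree.death_step[members] - pedigree.birth_step[members] - 1 >= 1
    ) | pedigree.alive_at_end[members]
    return CohortRS(
        birth_step=birth_step, deme=deme, k=k, n1=int(reached_1.sum())
    )


def realized_ne(
    pedigree: PedigreeTable,
    cohorts: list[tuple[int, int]],
    rates: VitalRates,
    allow_incomplete: bool = False,
) -> NeEstimate:
    """Realized per-generation Ne from observed reproductive-success variance.

    For every requested ``(birth_step, deme)`` cohort the per-cohort estimate
    is ``4 * N1 * T / (Vk + 2)`` with ``N1`` the cohort members reaching age
    1, ``T`` the generation length from the vital rates, and ``Vk`` the
    observed lifetime variance.  The returned point is the mean over cohorts;
    per-cohort and per-deme breakdowns are kept in ``aux``.
    """
    if not cohorts:
        raise NebenchError("at least one cohort is required")
    T = generation_length(rates)
    per_cohort, vks, rows = [], [], []
    for birth_step, deme in cohorts:
        rs = lifetime_rs(pedigree, birth_step, deme, rates.max_age, allow_incomplete)
        ne = 4.0 * rs.n1 * T / (rs.vk + 2.0)
        per_cohort.append(ne)
        vks.append(rs.vk)
        rows.append({"birth_step": birth_step, "deme": deme, "ne": ne, "vk": rs.vk,
                     "mean_k": rs.mean_k, "n1": rs.n1})
    table = pd.DataFrame(rows)
    per_deme = table.groupby("deme")["ne"].mean().to_dict()
    return NeEstimate(
        point=float(np.mean(per_cohort)),
        method="realized",
        aux={
            "T": T,
            "per_cohort_ne": per_cohort,
            "per_cohort_vk": vks,
            "per_deme_mean": per_deme,
            "table": table,
        },
    )


def breeders_per_step(pedigree: PedigreeTable, step: int) -> dict[str, int]:
    """Per-step breeder diagnostic: distinct mothers/fathers of the cohort
    born at ``step`` (pooled over demes).  Reported alongside, but not used
    for, the headline realized Ne."""
    born = pedigree.birth_step == step
    return {
        "n_offspring": int(born.sum()),
        "n_mothers": int(np.unique(pedigree.mother[born]).size),
        "n_fathers": int(np.unique(pedigree.father[born]).size),
    }


def kin_pair_census(pedigree: PedigreeTable, sample_ids) -> KinPairCensus:
    """Classify every unordered pair in a sample by closest kinship.

    Precedence: parent-offspring > full-sib > half-sib > grandparent-linked;
    anything else is unrelated at depth <= 2.  Founder gaps (parent ``-1``)
    never match.
    """
    ids = np.asarray(sample_ids, dtype=np.int64)
    if ids.size and (ids.min() < 0 or ids.max() >= len(pedigree)):
        raise KeyError("sample contains ids outside the pedigree")
    n = ids.size
    mo = pedigree.mother[ids]
    fa = pedigree.father[ids]

    # ancestor sets up to depth 2 (self excluded), with -1 entries dropped
    anc = np.stack([mo, fa] + [
        np.where(p != NO_PARENT, pedigree.mother[np.maximum(p, 0)], NO_PARENT)
        for p in (mo, fa)
    ] + [
        np.where(p != NO_PARENT, pedigree.father[np.maximum(p, 0)], NO_PARENT)
        for p in (mo, fa)
    ], axis=1)  # (n, 6): mother, father, 4 grandparents

    po = fs = hs = gp = 0
    self_plus = [set(a[a != NO_PARENT]) | {i} for i, a in zip(ids, anc)]
    parent_sets = [
        {p for p in (mo[i], fa[i]) if p != NO_PARENT} for i in range(n)
    ]
    for i in range(n):
        for j in range(i + 1, n):
            if ids[j] in parent_sets[i] or ids[i] in parent_sets[j]:
                po += 1
            else:
                shared = len(parent_sets[i] & parent_sets[j])
                if shared == 2:
                    fs += 1
                elif shared == 1:
                    hs += 1
                elif self_plus[i] & self_plus[j]:
                    gp += 1
    total = n * (n - 1) // 2
    return KinPairCensus(
        parent_offspring=po,
        full_sib=fs,
        half_sib=hs,
        grandparent_linked=gp,
        unrelated=total - po - fs - hs - gp,
    )
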