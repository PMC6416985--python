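"""Simulation configuration for the synthetic four-registry generator.

The generator emulates four positively dependent administrative capture
sources observing a hidden population of people who inject drugs (PWID):

* ``DR``    — a causes-of-death registry (capture = opioid-related death),
* ``PB``    — a police misdemeanour registry, heavily over-covered: most
  people it records are *not* members of the target population,
* ``HIF-T`` — health-insurance claims for overdose treatment,
* ``HIF-F`` — health-insurance claims for dependence treatment.

The joint capture distribution of a member over the four sources within a
calendar year is parameterised directly as a log-linear model on the 2^4
pattern space: the log-probability of pattern ``x`` is (up to a constant)
``sum_i x_i * lam_i + sum_{i<j} x_i x_j * lam_ij``, so pairwise interaction
coefficients are exactly log odds ratios between sources.  This puts the
simulation truth inside the model class fitted by the estimators, which
makes parameter recovery a sharp test.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

SOURCES: tuple[str, ...] = ("DR", "PB", "HIF-T", "HIF-F")
COUNTIES: tuple[str, ...] = ("Harju", "Ida-Viru", "other")
AGE_GROUPS: tuple[str, ...] = ("15-44", "45+")
SEXES: tuple[str, ...] = ("M", "F")

#: counties mapped to the residual "other" level in raw extracts
OTHER_COUNTY_POOL = ("Tartu", "Pärnu", "Lääne-Viru", "Viljandi")

SOURCE_PAIRS: tuple[tuple[str, str], ...] = tuple(
    (SOURCES[i], SOURCES[j]) for i in range(4) for j in range(i + 1, 4)
)


def _default_main_effects() -> dict[str, float]:
    # Chosen so that per-member annual capture probabilities are roughly
    # 0.05 (DR), 0.13 (PB), 0.04 (HIF-T), 0.35 (HIF-F): a small population
    # of a couple of thousand members then yields annual source counts on
    # the order of one to a few hundred members per source.
    return {"DR": -3.1, "PB": -2.2, "HIF-T": -3.6, "HIF-F": -0.8}


def _default_pair_effects() -> dict[tuple[str, str], float]:
    # Sparse conditional dependence: a strong link between the two
    # insurance-claim sources, death-registry links to treatment and
    # police contact, and a mild police-insurance link.  Remaining pairs
    # pick up positive *marginal* dependence through the shared covariate
    # gradients below, so pooled pairwise odds ratios land in roughly
    # 1.05-7 while the conditional structure stays identifiable at a
    # population of a few thousand.
    return {
        ("DR", "PB"): np.log(1.6),
        ("DR", "HIF-T"): np.log(2.5),
        ("PB", "HIF-F"): np.log(1.3),
        ("HIF-T", "HIF-F"): np.log(6.0),
    }


def _default_covariate_distribution() -> dict[str, dict[str, float]]:
    # Three quarters men, overwhelmingly 15-44, concentrated in the two
    # counties hosting the epidemic.
    return {
        "sex": {"M": 0.74, "F": 0.26},
        "age_group": {"15-44": 0.90, "45+": 0.10},
        "county": {"Harju": 0.50, "Ida-Viru": 0.35, "other": 0.15},
    }


def _default_covariate_capture_effects() -> dict[tuple[str, str, str], float]:
    # Additive shifts on source main effects (log scale) by covariate
    # level: the health registries run hotter in the county hosting the
    # concentrated epidemic (Ida-Viru), insurance claims slightly
    # over-represent women, and mortality rises with age.  The shared
    # county gradient also induces mild positive marginal dependence
    # between sources with no direct interaction.
    return {
        ("DR", "county", "Ida-Viru"): 0.3,
        ("HIF-T", "county", "Ida-Viru"): 0.3,
        ("HIF-F", "county", "Ida-Viru"): 0.3,
        ("HIF-F", "sex", "F"): 0.25,
        ("HIF-T", "sex", "F"): 0.25,
        ("DR", "age_group", "45+"): 0.4,
    }


@dataclass
class SimulationConfig:
    """Parameters of the synthetic four-registry capture simulation.

    Parameters
    ----------
    true_population_size
        Number of living members each year.  A single integer applies to
        every year; a mapping ``{year: size}`` sets per-year targets.
        After deaths, the membership is topped up with new recruits to
        meet the target.
    years
        Calendar years simulated.
    capture_main_effects, capture_pair_effects
        Log-linear parameters of the joint capture distribution (see
        module docstring).  Pair keys are ``(source_a, source_b)`` in the
        canonical source order.
    covariate_distribution
        Proportions for sex (M/F), age group (15-44/45+) and county of
        residence (Harju/Ida-Viru/other); each block sums to 1.
    covariate_capture_effects
        Additive log-scale shifts ``(source, covariate, level) -> delta``
        applied to that source's main effect for members at that level.
    member_fraction_pb
        Target fraction of PB-captured individuals who are true members.
        Used to derive ``overcoverage_count`` when the latter is None.
    overcoverage_count
        Number of non-member contaminants appearing in PB each year.
        Contaminants are never captured by any other source.
    mortality_rate
        Optional per-year probability that a member dies (appears in DR).
        When set, the DR main effect is recalibrated so the member DR
        marginal equals this rate; when None the DR main effect is used
        as given.
    frailty_sd
        Standard deviation of an optional per-member normal frailty added
        to all four main effects; default 0 (homogeneous members beyond
        the three covariates).
    initials_alphabet
        Letters from which two-letter initials are drawn; shrinking the
        alphabet raises the study-ID collision rate.
    unique_study_ids
        When True, redraw identities until every simulated person has a
        distinct (dob, sex, initials) triple, so linkage can be tested
        free of collisions.
    seed
        Root RNG seed; identical config + seed gives byte-identical output.
    """

    true_population_size: int | Mapping[int, int] = 2000
    years: Sequence[int] = tuple(range(2010, 2016))
    capture_main_effects: dict[str, float] = field(default_factory=_default_main_effects)
    capture_pair_effects: dict[tuple[str, str], float] = field(
        default_factory=_default_pair_effects
    )
    covariate_distribution: dict[str, dict[str, float]] = field(
        default_factory=_default_covariate_distribution
    )
    covariate_capture_effects: dict[tuple[str, str, str], float] = field(
        default_factory=_default_covariate_capture_effects
    )
    member_fraction_pb: float = 0.13
    overcoverage_count: int | None = None
    mortality_rate: float | None = None
    frailty_sd: float = 0.0
    initials_alphabet: str = "ABCDEFGHIJKLMNOPRSTUV"
    unique_study_ids: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for year, n in self.population_by_year().items():
            if n < 1:
                raise ValueError(f"true_population_size must be >= 1 (year {year}: {n})")
        if not (0.0 < self.member_fraction_pb <= 1.0):
            raise ValueError("member_fraction_pb must be in (0, 1]")
        if self.overcoverage_count is not None and self.overcoverage_count < 0:
            raise ValueError("overcoverage_count must be non-negative")
        if self.mortality_rate is not None and not (0.0 <= self.mortality_rate <= 1.0):
            raise ValueError("mortality_rate must be a probability")
        if self.frailty_sd < 0:
            raise ValueError("frailty_sd must be non-negative")
        for src in SOURCES:
            if src not in self.capture_main_effects:
                raise ValueError(f"missing main effect for source {src!r}")
        for pair in self.capture_pair_effects:
            if tuple(pair) not in SOURCE_PAIRS:
                raise ValueError(f"unknown source pair {pair!r}")
        expected_levels = {"sex": SEXES, "age_group": AGE_GROUPS, "county": COUNTIES}
        for cov, levels in expected_levels.items():
            if cov not in self.covariate_distribution:
                raise ValueError(f"covariate_distribution missing {cov!r}")
            block = self.covariate_distribution[cov]
            if set(block) != set(levels):
                raise ValueError(f"covariate {cov!r} must have levels {levels}")
            probs = np.array([block[lv] for lv in levels], dtype=float)
            if (probs < 0).any() or (probs > 1).any():
                raise ValueError(f"covariate {cov!r} proportions must lie in [0, 1]")
            if abs(probs.sum() - 1.0) > 1e-8:
                raise ValueError(f"covariate {cov!r} proportions must sum to 1")

    def population_by_year(self) -> dict[int, int]:
        if isinstance(self.true_population_size, Mapping):
            return {int(y): int(self.true_population_size[y]) for y in self.years}
        return {int(y): int(self.true_population_size) for y in self.years}

    # ------------------------------------------------------------------
    # serialisation

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["capture_pair_effects"] = {
            "|".join(k): float(v) for k, v in self.capture_pair_effects.items()
        }
        d["covariate_capture_effects"] = {
            "|".join(k): float(v) for k, v in self.covariate_capture_effects.items()
        }
        d["years"] = list(self.years)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "capture_pair_effects" in d:
            d["capture_pair_effects"] = {
                tuple(k.split("|")): float(v)
                for k, v in d["capture_pair_effects"].items()
            }
        if "covariate_capture_effects" in d:
            d["covariate_capture_effects"] = {
                tuple(k.split("|")): float(v)
                for k, v in d["covariate_capture_effects"].items()
            }
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False, allow_unicode=True)
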