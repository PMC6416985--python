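"""Synthetic four-registry capture data with known ground truth.

Members of a hidden population are captured each year by four sources
(DR, PB, HIF-T, HIF-F) with a joint pattern distribution given by a
log-linear model on the 2^4 pattern space (see :mod:`recapture.config`).
A DR capture is a death: the member's other events that year strictly
precede the death date and the member is removed from later years, the
population being replenished with recruits to hold the yearly target
size.  Over-coverage is emulated by injecting non-member contaminants
into PB — and only PB — with demographics drawn from the same pools as
members, so deterministic linkage cannot trivially separate them.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .config import (
    AGE_GROUPS,
    COUNTIES,
    OTHER_COUNTY_POOL,
    SEXES,
    SOURCES,
    SOURCE_PAIRS,
    SimulationConfig,
)

#: all 2^4 capture patterns; row p has bit i = (p >> i) & 1, columns in SOURCES order
PATTERNS = np.array(
    [[(p >> i) & 1 for i in range(4)] for p in range(16)], dtype=float
)

_PAIR_INDEX = {pair: (SOURCES.index(pair[0]), SOURCES.index(pair[1])) for pair in SOURCE_PAIRS}


def pattern_probabilities(
    main_effects: np.ndarray, pair_effects: dict[tuple[str, str], float]
) -> np.ndarray:
    """Joint probabilities of the 16 capture patterns under the log-linear model."""
    logw = PATTERNS @ np.asarray(main_effects, dtype=float)
    for pair, lam in pair_effects.items():
        i, j = _PAIR_INDEX[tuple(pair)]
        logw = logw + lam * PATTERNS[:, i] * PATTERNS[:, j]
    w = np.exp(logw - logw.max())
    return w / w.sum()


def _strata(config: SimulationConfig):
    """Iterate (sex, age_group, county, weight) over the 12 covariate strata."""
    dist = config.covariate_distribution
    for sex in SEXES:
        for ag in AGE_GROUPS:
            for county in COUNTIES:
                w = dist["sex"][sex] * dist["age_group"][ag] * dist["county"][county]
                yield sex, ag, county, w


def _stratum_main_effects(config: SimulationConfig, sex: str, ag: str, county: str) -> np.ndarray:
    main = np.array([config.capture_main_effects[s] for s in SOURCES], dtype=float)
    levels = {"sex": sex, "age_group": ag, "county": county}
    for (src, cov, level), delta in config.covariate_capture_effects.items():
        if levels.get(cov) == level:
            main[SOURCES.index(src)] += delta
    return main


def marginal_capture_probabilities(config: SimulationConfig) -> dict[str, float]:
    """Per-source member capture probability, averaged over covariate strata.

    Analytic expectation used both to derive the over-coverage count from
    ``member_fraction_pb`` and as the oracle for calibration tests.
    """
    config = _calibrated(config)
    p = np.zeros(4)
    for sex, ag, county, w in _strata(config):
        probs = pattern_probabilities(
            _stratum_main_effects(config, sex, ag, county), config.capture_pair_effects
        )
        p += w * (probs @ PATTERNS)
    return dict(zip(SOURCES, p))


def _calibrated(config: SimulationConfig) -> SimulationConfig:
    """Recalibrate the DR main effect to hit a requested mortality rate."""
    if config.mortality_rate is None:
        return config
    target = config.mortality_rate

    def dr_marginal(lam_dr: float) -> float:
        p = 0.0
        for sex, ag, county, w in _strata(config):
            main = _stratum_main_effects(config, sex, ag, county)
            main[SOURCES.index("DR")] += lam_dr - config.capture_main_effects["DR"]
            probs = pattern_probabilities(main, config.capture_pair_effects)
            p += w * (probs @ PATTERNS)[SOURCES.index("DR")]
        return p - target

    if target <= 0.0:
        lam = -np.inf
    else:
        lam = brentq(dr_marginal, -30.0, 10.0)
    import dataclasses

    mains = dict(config.capture_main_effects)
    mains["DR"] = lam
    return dataclasses.replace(config, capture_main_effects=mains, mortality_rate=None)


# ----------------------------------------------------------------------
# identity generation


def _draw_identities(rng: np.random.Generator, n: int, config: SimulationConfig, year: int):
    """Demographics for n new people, with mid-year age in the drawn group."""
    dist = config.covariate_distribution
    sex = rng.choice(SEXES, size=n, p=[dist["sex"][s] for s in SEXES])
    ag = rng.choice(AGE_GROUPS, size=n, p=[dist["age_group"][a] for a in AGE_GROUPS])
    county = rng.choice(COUNTIES, size=n, p=[dist["county"][c] for c in COUNTIES])
    age = np.where(ag == "15-44", rng.integers(15, 45, size=n), rng.integers(45, 70, size=n))
    back_days = rng.integers(0, 365, size=n)
    dob = np.array(
        [
            dt.date(year - a, 7, 1) - dt.timedelta(days=int(d))
            for a, d in zip(age, back_days)
        ]
    )
    letters = list(config.initials_alphabet)
    initials = np.array(
        ["".join(pair) for pair in rng.choice(letters, size=(n, 2))]
    )
    # the raw registry extract carries a concrete county name; the 3-level
    # factor is recovered downstream by the linkage module
    raw_county = np.array(
        [
            c if c != "other" else rng.choice(OTHER_COUNTY_POOL)
            for c in county
        ]
    )
    return pd.DataFrame(
        {
            "sex": sex,
            "dob": dob,
            "initials": initials,
            "county": county,
            "raw_county": raw_county,
        }
    )


def _age_group_in_year(dob: pd.Series, year: int) -> np.ndarray:
    mid = dt.date(year, 7, 1)
    age = np.array(
        [
            mid.year - d.year - ((mid.month, mid.day) < (d.month, d.day))
            for d in dob
        ]
    )
    return age


@dataclass
class SimulationResult:
    """Output of :func:`simulate_population`."""

    config: SimulationConfig
    truth: pd.DataFrame  # one row per (person, year) with capture indicators
    persons: pd.DataFrame  # one row per simulated person
    extracts: dict[str, pd.DataFrame]  # source -> registry extract

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for src, df in self.extracts.items():
            df.to_csv(outdir / f"extract_{src.replace('-', '_')}.csv", index=False)
        self.truth.to_csv(outdir / "truth.csv", index=False)
        self.persons.to_csv(outdir / "persons.csv", index=False)
        self.config.to_yaml(outdir / "config.yaml")


def derive_overcoverage_count(config: SimulationConfig) -> int:
    """Contaminants per year implied by ``member_fraction_pb``.

    Solves f = E[member PB captures] / (E[member PB captures] + C) for C.
    """
    if config.overcoverage_count is not None:
        return int(config.overcoverage_count)
    f = config.member_fraction_pb
    if f >= 1.0:
        return 0
    p_pb = marginal_capture_probabilities(config)["PB"]
    mean_n = np.mean(list(config.population_by_year().values()))
    expected_members = mean_n * p_pb
    return int(round(expected_members * (1.0 - f) / f))


def simulate_population(config: SimulationConfig) -> SimulationResult:
    """Simulate members and contaminants through all configured years.

    Returns the ground truth (per person-year capture indicators and the
    member flag) together with four registry extracts carrying only the
    fields a real extract would: dob, sex, initials, event date, county,
    and a registry-internal person identifier for DR and PB.
    """
    config.validate()
    cal = _calibrated(config)
    rng = np.random.default_rng(config.seed)
    years = [int(y) for y in config.years]
    pop_by_year = config.population_by_year()
    n_contam = derive_overcoverage_count(config)

    # persistent identity table ---------------------------------------
    persons = _draw_identities(rng, pop_by_year[years[0]], config, years[0])
    persons["member"] = True
    # contaminant pool: larger than the per-year count so some recur
    pool_size = max(int(np.ceil(n_contam * 1.5)), n_contam)
    if pool_size > 0:
        contam = _draw_identities(rng, pool_size, config, years[0])
        contam["member"] = False
        persons = pd.concat([persons, contam], ignore_index=True)
    persons.index.name = "person_idx"

    if config.unique_study_ids:
        _force_unique_ids(persons, rng, config, years[0])

    frailty = (
        rng.normal(0.0, config.frailty_sd, size=len(persons))
        if config.frailty_sd > 0
        else np.zeros(len(persons))
    )

    member_ids = list(persons.index[persons["member"]])
    contaminant_ids = np.array(persons.index[~persons["member"]])
    dead: set[int] = set()
    death_date: dict[int, dt.date] = {}

    truth_rows: list[pd.DataFrame] = []
    events: dict[str, list] = {s: [] for s in SOURCES}

    for year in years:
        # replenish membership to the yearly target
        alive = [i for i in member_ids if i not in dead]
        target = pop_by_year[year]
        if len(alive) < target:
            recruits = _draw_identities(rng, target - len(alive), config, year)
            recruits["member"] = True
            start = len(persons)
            recruits.index = range(start, start + len(recruits))
            if config.unique_study_ids:
                _force_unique_ids(
                    pd.concat([persons, recruits]), rng, config, year, only=recruits
                )
            persons = pd.concat([persons, recruits])
            frailty = np.concatenate(
                [
                    frailty,
                    rng.normal(0.0, config.frailty_sd, size=len(recruits))
                    if config.frailty_sd > 0
                    else np.zeros(len(recruits)),
                ]
            )
            member_ids.extend(recruits.index)
            alive.extend(recruits.index)
        elif len(alive) > target:
            alive = alive[:target]

        alive = np.array(alive)
        sub = persons.loc[alive]
        age = _age_group_in_year(sub["dob"], year)
        ag = np.where(age <= 44, "15-44", "45+")

        # draw joint capture patterns, stratum by stratum
        pattern_idx = np.zeros(len(alive), dtype=int)
        for sex, agrp, county, _w in _strata(cal):
            mask = (
                (sub["sex"].to_numpy() == sex)
                & (ag == agrp)
                & (sub["county"].to_numpy() == county)
            )
            if not mask.any():
                continue
            main = _stratum_main_effects(cal, sex, agrp, county)
            if config.frailty_sd > 0:
                for pos in np.flatnonzero(mask):
                    probs = pattern_probabilities(
                        main + frailty[alive[pos]], cal.capture_pair_effects
                    )
                    pattern_idx[pos] = rng.choice(16, p=probs)
            else:
                probs = pattern_probabilities(main, cal.capture_pair_effects)
                pattern_idx[np.flatnonzero(mask)] = rng.choice(
                    16, size=int(mask.sum()), p=probs
                )

        captures = PATTERNS[pattern_idx].astype(int)  # (n_alive, 4)

        # event dates; deaths sampled first, other events strictly before
        year_start = dt.date(year, 1, 1)
        dr_col = SOURCES.index("DR")
        death_day = rng.integers(5, 365, size=len(alive))
        for k, pid in enumerate(alive):
            pat = captures[k]
            dies = bool(pat[dr_col])
            dday = int(death_day[k]) if dies else None
            if dies:
                d = year_start + dt.timedelta(days=dday)
                dead.add(int(pid))
                death_date[int(pid)] = d
                events["DR"].append((pid, d))
            for si, src in enumerate(SOURCES):
                if src == "DR" or not pat[si]:
                    continue
                n_ev = 1 + (int(rng.poisson(0.25)) if src == "PB" else 0)
                hi = dday if dies else 365
                days = rng.integers(0, hi, size=n_ev)
                for day in days:
                    events[src].append((pid, year_start + dt.timedelta(days=int(day))))

        # contaminants: fixed count injected into PB this year
        if n_contam > 0:
            chosen = rng.choice(contaminant_ids, size=n_contam, replace=False)
            contam_cap = np.zeros((len(chosen), 4), dtype=int)
            contam_cap[:, SOURCES.index("PB")] = 1
            for pid in chosen:
                n_ev = 1 + int(rng.poisson(0.25))
                days = rng.integers(0, 365, size=n_ev)
                for day in days:
                    events["PB"].append((pid, year_start + dt.timedelta(days=int(day))))
        else:
            chosen = np.array([], dtype=int)
            contam_cap = np.zeros((0, 4), dtype=int)

        idx = np.concatenate([alive, chosen]).astype(int)
        caps = np.vstack([captures, contam_cap])
        block = persons.loc[idx, ["sex", "dob", "initials", "county", "member"]].copy()
        block.insert(0, "person_id", idx)
        block.insert(1, "year", year)
        block["age_midyear"] = _age_group_in_year(block["dob"], year)
        block["age_group"] = np.where(block["age_midyear"] <= 44, "15-44", "45+")
        for si, src in enumerate(SOURCES):
            block[src] = caps[:, si]
        truth_rows.append(block.reset_index(drop=True))

    truth = pd.concat(truth_rows, ignore_index=True)
    extracts = _build_extracts(persons, events)
    persons_out = persons.reset_index().rename(columns={"index": "person_id"})
    if "person_idx" in persons_out.columns:
        persons_out = persons_out.rename(columns={"person_idx": "person_id"})
    return SimulationResult(config=config, truth=truth, persons=persons_out, extracts=extracts)


def _force_unique_ids(
    persons: pd.DataFrame,
    rng: np.random.Generator,
    config: SimulationConfig,
    year: int,
    only: pd.DataFrame | None = None,
) -> None:
    """Redraw identities in-place until (dob, sex, initials) triples are unique."""
    target = persons if only is None else only
    for _ in range(100):
        key = (
            persons["dob"].astype(str)
            + "|"
            + persons["sex"].astype(str)
            + "|"
            + persons["initials"].astype(str)
        )
        dup = key.duplicated(keep="first")
        dup = dup & dup.index.isin(target.index)
        if not dup.any():
            return
        redraw = _draw_identities(rng, int(dup.sum()), config, year)
        for col in ("sex", "dob", "initials", "county", "raw_county"):
            persons.loc[dup[dup].index, col] = redraw[col].to_numpy()
            if only is not None:
                in_target = dup[dup].index.intersection(target.index)
                target.loc[in_target, col] = persons.loc[in_target, col]
    raise RuntimeError("could not de-duplicate study IDs; enlarge the alphabet")


def _build_extracts(persons: pd.DataFrame, events: dict[str, list]) -> dict[str, pd.DataFrame]:
    out = {}
    for src in SOURCES:
        evs = events[src]
        if evs:
            pids = [int(p) for p, _ in evs]
            dates = [d for _, d in evs]
            info = persons.loc[pids]
            df = pd.DataFrame(
                {
                    "dob": [d.isoformat() for d in info["dob"]],
                    "sex": info["sex"].to_numpy(),
                    "initials": info["initials"].to_numpy(),
                    "event_date": [d.isoformat() for d in dates],
                    "county": info["raw_county"].to_numpy(),
                }
            )
            if src in ("DR", "PB"):
                df["internal_id"] = [f"{src}-{p:06d}" for p in pids]
            df = df.sort_values(["event_date", "dob", "initials"], kind="stable").reset_index(
                drop=True
            )
        else:
            cols = ["dob", "sex", "initials", "event_date", "county"]
            if src in ("DR", "PB"):
                cols.append("internal_id")
            df = pd.DataFrame(columns=cols)
        out[src] = df
    return out


# ----------------------------------------------------------------------
# dependence diagnostics on the truth


def empirical_capture_ors(truth: pd.DataFrame) -> pd.DataFrame:
    """Pairwise capture odds ratios among member person-years.

    The cross-product ratio of the 2x2 member capture table for each
    source pair; a Haldane-Anscombe 0.5 continuity correction is applied
    (and flagged) whenever a margin cell is zero.
    """
    members = truth[truth["member"]]
    active = [s for s in SOURCES if members[s].sum() > 0]
    if len(active) < 2:
        raise ValueError("need at least two sources with nonzero member captures")
    rows = []
    for sa, sb in SOURCE_PAIRS:
        a = int(((members[sa] == 1) & (members[sb] == 1)).sum())
        b = int(((members[sa] == 1) & (members[sb] == 0)).sum())
        c = int(((members[sa] == 0) & (members[sb] == 1)).sum())
        d = int(((members[sa] == 0) & (members[sb] == 0)).sum())
        corrected = 0 in (a, b, c, d)
        if corrected:
            a, b, c, d = (x + 0.5 for x in (a, b, c, d))
        rows.append(
            {
                "source_a": sa,
                "source_b": sb,
                "odds_ratio": (a * d) / (b * c),
                "n11": a,
                "n10": b,
                "n01": c,
                "n00": d,
                "continuity_corrected": corrected,
            }
        )
    return pd.DataFrame(rows)
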