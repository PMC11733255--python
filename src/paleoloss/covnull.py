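"""Database-coverage null and refugium arithmetic bounding true extinctions.

A taxon can be a "lost non-dbtaxon" simply because the reference database
does not cover it, not because it went extinct. To bound how many lost
non-dbtaxa incomplete coverage alone explains, a synthetic record is
resampled from a GBIF-like species pool (each species carrying a
covered/uncovered flag): an evolving taxon set starts from the oldest
slice's richness and, at every slice transition, applies the observed
total gains and losses by uniform random draws. The simulated
covered/uncovered proportions among taxa present in (vs absent from) the
modern slice give the expected number of lost non-dbtaxa under pure
coverage effects; subtracting it from the observed count gives the
minimum number of potential extinctions.

The maximum is bounded from the other side by refugium likelihood: for
lost non-dbtaxa that match global databases, the species overlap at
family level between the matching region and the study region estimates
the chance each survives in an outside refugium; the expected refugium
count is removed from the observed losses.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .timeslice import TaxonOccupancy


def round_half_away(x: float) -> int:
    """Round half away from zero (5.5 -> 6, -5.5 -> -6)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass
class GainLossSchedule:
    """Observed taxon gains/losses per slice transition, split by db flag.

    ``transitions`` is indexed by transition t (slice t -> t+1) with
    columns ``db_gain``, ``db_loss``, ``nondb_gain``, ``nondb_loss``;
    ``initial_richness`` is the taxon count of the oldest slice.
    """

    initial_richness: int
    transitions: pd.DataFrame

    @property
    def n_transitions(self) -> int:
        return len(self.transitions)

    def total_gains(self) -> pd.Series:
        return self.transitions["db_gain"] + self.transitions["nondb_gain"]

    def total_losses(self) -> pd.Series:
        return self.transitions["db_loss"] + self.transitions["nondb_loss"]


def derive_schedule(median_presence: pd.DataFrame, db_flag: pd.Series) -> GainLossSchedule:
    """Gains and losses between consecutive slices of a median occupancy.

    ``median_presence`` is taxon x slice boolean; ``db_flag`` aligns with
    its index. Gains at transition t are taxa absent at t and present at
    t+1; losses the reverse.
    """
    P = median_presence.to_numpy(dtype=bool)
    db = np.asarray(db_flag, dtype=bool)
    rows = []
    for t in range(P.shape[1] - 1):
        gain = ~P[:, t] & P[:, t + 1]
        loss = P[:, t] & ~P[:, t + 1]
        rows.append(
            {
                "db_gain": int((gain & db).sum()),
                "db_loss": int((loss & db).sum()),
                "nondb_gain": int((gain & ~db).sum()),
                "nondb_loss": int((loss & ~db).sum()),
            }
        )
    return GainLossSchedule(int(P[:, 0].sum()), pd.DataFrame(rows))


@dataclass
class CoverageNullResult:
    """Simulated covered/uncovered proportions among modern-present/absent taxa.

    Percentages are per iteration; ``median_*`` summarise them. The
    expected number of lost non-dbtaxa for an observed total loss count is
    ``round(total_lost * median absent-stratum non-db fraction)``.
    """

    present_db_pct: np.ndarray
    absent_db_pct: np.ndarray

    @property
    def median_present_db_pct(self) -> float:
        return float(np.nanmedian(self.present_db_pct))

    @property
    def median_absent_db_pct(self) -> float:
        return float(np.nanmedian(self.absent_db_pct))

    def expected_lost_nondb(self, total_observed_lost: int) -> int:
        frac_nondb = 1.0 - self.median_absent_db_pct / 100.0
        return round_half_away(total_observed_lost * frac_nondb)


def simulate_coverage_null(
    pool: pd.DataFrame,
    schedule: GainLossSchedule,
    n_iter: int = 1000,
    seed: int = 0,
) -> CoverageNullResult:
    """Resample the species pool along the observed gain/loss schedule.

    Each iteration starts from ``initial_richness`` species drawn
    uniformly from the pool; at each transition the total losses are
    removed uniformly from the current set and the total gains drawn
    uniformly from the pool outside it (a previously lost species can
    re-enter, mimicking reappearance). Gains and losses are applied as
    totals with pool-random covered/uncovered attribution: the null asks
    whether coverage alone explains the observed db/non-db split, so the
    split must not be imposed on the draws.
    """
    covered = pool["covered"].to_numpy(dtype=bool)
    n_pool = len(covered)
    if schedule.initial_richness > n_pool:
        raise ValueError("pool smaller than the initial richness")
    gains = schedule.total_gains().to_numpy()
    losses = schedule.total_losses().to_numpy()
    rng = np.random.default_rng(seed)
    present_db = np.full(n_iter, np.nan)
    absent_db = np.full(n_iter, np.nan)
    for it in range(n_iter):
        current = np.zeros(n_pool, dtype=bool)
        current[rng.choice(n_pool, size=schedule.initial_richness, replace=False)] = True
        ever = current.copy()
        for g, l in zip(gains, losses):
            members = np.flatnonzero(current)
            if l > len(members):
                raise ValueError(
                    f"schedule demands {l} removals but only {len(members)} taxa present"
                )
            if l:
                current[rng.choice(members, size=l, replace=False)] = False
            outside = np.flatnonzero(~current)
            if g > len(outside):
                raise ValueError("schedule demands more gains than the pool can supply")
            if g:
                current[rng.choice(outside, size=g, replace=False)] = True
            ever |= current
        absent = ever & ~current
        if current.any():
            present_db[it] = 100.0 * covered[current].mean()
        if absent.any():
            absent_db[it] = 100.0 * covered[absent].mean()
    return CoverageNullResult(present_db, absent_db)


@dataclass
class RefugiumAssessment:
    """Outside-refugium likelihood for lost taxa matched in global databases.

    ``overlaps`` maps each matched taxon's family to the fraction of the
    match-region's family species (capped) shared with the study region.
    ``expected_refugium_count = round(n_matched * mean likelihood)``.
    """

    overlaps: pd.Series

    @property
    def n_matched(self) -> int:
        return len(self.overlaps)

    @property
    def mean_likelihood(self) -> float:
        return float(self.overlaps.mean())

    @property
    def expected_refugium_count(self) -> int:
        return round_half_away(self.n_matched * self.mean_likelihood)


def refugium_likelihood(
    matched_taxa: list[tuple[str, list, list]],
    cap: int = 100,
    seed: int = 0,
) -> RefugiumAssessment:
    """Species overlap between match region and study region per matched taxon.

    ``matched_taxa`` holds (family, match-region species list,
    study-region species list) per taxon. Lists longer than ``cap`` are
    subsampled uniformly (seeded); the overlap is the shared-species count
    divided by the match-region list considered. Empty lists skip the
    taxon with a warning.
    """
    rng = np.random.default_rng(seed)
    overlaps = {}
    for k, (family, match_sp, study_sp) in enumerate(matched_taxa):
        if not match_sp or not study_sp:
            warnings.warn(f"empty species list for matched taxon {family!r}; skipped")
            continue
        match_sp = list(match_sp)
        study_sp = list(study_sp)
        if len(match_sp) > cap:
            match_sp = list(rng.choice(match_sp, size=cap, replace=False))
        if len(study_sp) > cap:
            study_sp = list(rng.choice(study_sp, size=cap, replace=False))
        shared = set(match_sp) & set(study_sp)
        overlaps[f"{k}:{family}"] = len(shared) / len(match_sp)
    return RefugiumAssessment(pd.Series(overlaps, dtype=float))


def extinction_bounds(
    observed_lost_nondb: int,
    expected_from_coverage: int,
    refugium: RefugiumAssessment | int,
) -> tuple[int, int]:
    """(min, max) potentially extinct taxa.

    min = observed - expected-from-coverage (floored at 0);
    max = observed - expected refugium count.
    """
    ref_count = (
        refugium.expected_refugium_count
        if isinstance(refugium, RefugiumAssessment)
        else int(refugium)
    )
    lo = max(0, observed_lost_nondb - expected_from_coverage)
    hi = observed_lost_nondb - ref_count
    return lo, hi
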