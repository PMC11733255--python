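"""Per-slice loss estimates via a reappearance-delay null, and E/MSY rates.

Taxa flicker in and out of a resampled occupancy record even when they
never leave the region, so an absence run on its own is weak evidence of
loss. The number of slices a disappeared taxon needs to reappear is
therefore the key statistic: reference slices early in the record (by
default those with midpoints ~25,000, ~23,000 and ~21,000 cal yr BP,
which leave nine later slices for a taxon to reappear) provide an
empirical delay distribution, whose survival function gives the expected
fraction of disappearances that would still look "lost" after any given
remaining horizon. The observed fraction of never-reappearing taxa per
slice, minus that expectation, is the net loss; the fraction of
resampling iterations in which the observed exceeds the expected is the
confidence. Applied to dbtaxa the net loss measures extirpation, applied
to non-dbtaxa it measures potential extinction.

Rates are expressed as extinctions per million species-years:
``E / (S * T)`` with ``T`` in millions of years.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .timeslice import TaxonOccupancy

DEFAULT_REFERENCE_MIDPOINTS = (25_000.0, 23_000.0, 21_000.0)


def disappearance_events(occ: TaxonOccupancy) -> pd.DataFrame:
    """All disappearance events with their reappearance delays.

    An event is recorded when a taxon is present at slice ``t`` and absent
    at ``t + 1``. ``delay`` counts the consecutive absent slices before
    the next presence; ``censored`` marks events with no reappearance up
    to and including the modern slice (``delay`` is then the number of
    remaining slices). Columns: iteration, taxon (positional index),
    slice, delay, censored, db_flag.
    """
    pres = occ.presence
    n_iter, n_taxa, n_slices = pres.shape
    if n_slices < 2:
        raise ValueError("need occupancy over at least 2 slices")
    rows = {"iteration": [], "taxon": [], "slice": [], "delay": [], "censored": []}
    drops = pres[:, :, :-1] & ~pres[:, :, 1:]
    for it, tx, t in zip(*np.nonzero(drops)):
        later = pres[it, tx, t + 1 :]
        reappear = np.flatnonzero(later)
        if len(reappear):
            delay = int(reappear[0])
            censored = False
        else:
            delay = n_slices - 1 - t
            censored = True
        rows["iteration"].append(int(it))
        rows["taxon"].append(int(tx))
        rows["slice"].append(int(t))
        rows["delay"].append(delay)
        rows["censored"].append(censored)
    events = pd.DataFrame(rows)
    events["db_flag"] = occ.db_flag[events["taxon"]] if len(events) else pd.Series(dtype=bool)
    return events


@dataclass
class ReappearanceNull:
    """Empirical expected-loss curves from reference-slice delays.

    ``expected_loss[it, h]`` is the fraction of reference-slice
    disappearances in iteration ``it`` whose delay exceeds ``h`` slices
    (censored events exceed every horizon); it is the survival function of
    the delay distribution, non-increasing in ``h``. Iterations without
    reference events are flagged invalid and excluded from confidence
    denominators.
    """

    expected_loss: np.ndarray  # (n_iter, horizon + 1)
    valid: np.ndarray  # (n_iter,) bool
    reference_slices: tuple
    horizon: int

    def expected(self, iteration: int, remaining: int) -> float:
        h = min(remaining, self.horizon)
        return float(self.expected_loss[iteration, h])


def build_null(
    events: pd.DataFrame,
    reference_slices,
    n_iter: int,
    horizon: int = 9,
) -> ReappearanceNull:
    """Pool reference-slice delays per iteration into expected-loss curves."""
    reference_slices = tuple(int(s) for s in reference_slices)
    ref = events[events["slice"].isin(reference_slices)]
    if not len(ref):
        raise ValueError(f"no disappearance events at reference slices {reference_slices}")
    expected = np.zeros((n_iter, horizon + 1))
    valid = np.zeros(n_iter, dtype=bool)
    grouped = dict(tuple(ref.groupby("iteration")))
    for it in range(n_iter):
        g = grouped.get(it)
        if g is None or not len(g):
            continue
        valid[it] = True
        delay = g["delay"].to_numpy()
        censored = g["censored"].to_numpy()
        for h in range(horizon + 1):
            expected[it, h] = np.mean(censored | (delay > h))
    return ReappearanceNull(expected, valid, reference_slices, horizon)


@dataclass
class LossEstimate:
    """Per-slice net loss with confidence and percentile bands.

    ``table`` has one row per slice with columns ``observed`` (median
    observed never-reappearing fraction, %), ``expected`` (median expected
    loss, %), ``net`` (median observed - expected, percentage points),
    ``net_p5``/``net_p95`` and ``confidence`` (fraction of valid
    iterations with net > 0; 0.5 where no iteration had events).
    ``net_iter`` holds the per-iteration net values (NaN where undefined).
    """

    table: pd.DataFrame
    net_iter: np.ndarray

    def peak_slices(self, n: int = 2) -> list[int]:
        """Slices of the ``n`` highest median net losses."""
        return list(self.table["net"].nlargest(n).index)


def loss_estimates(
    events: pd.DataFrame,
    null: ReappearanceNull,
    occ: TaxonOccupancy,
    db: bool | None = None,
) -> LossEstimate:
    """Observed-minus-expected loss per slice over all iterations.

    ``db`` restricts the events to dbtaxa (True; extirpation) or
    non-dbtaxa (False; potential extinction); None uses all taxa.
    """
    n_iter = occ.n_iter
    n_slices = occ.grid.n_slices
    ev = events if db is None else events[events["db_flag"] == db]
    obs = np.full((n_iter, n_slices - 1), np.nan)
    exp = np.full((n_iter, n_slices - 1), np.nan)
    for (it, t), g in ev.groupby(["iteration", "slice"]):
        if not null.valid[it]:
            continue
        # reappearance opportunities after an event at t: slices t+2 .. modern
        remaining = n_slices - 2 - t
        obs[it, t] = g["censored"].mean()
        exp[it, t] = null.expected(it, remaining)
    net = (obs - exp) * 100.0
    rows = []
    for t in range(n_slices - 1):
        col = net[:, t]
        ok = np.isfinite(col)
        if ok.any():
            rows.append(
                {
                    "slice": t,
                    "observed": float(np.nanmedian(obs[:, t]) * 100),
                    "expected": float(np.nanmedian(exp[:, t]) * 100),
                    "net": float(np.median(col[ok])),
                    "net_p5": float(np.percentile(col[ok], 5)),
                    "net_p95": float(np.percentile(col[ok], 95)),
                    "confidence": float(np.mean(col[ok] > 0)),
                    "n_valid": int(ok.sum()),
                }
            )
        else:
            rows.append(
                {
                    "slice": t,
                    "observed": 0.0,
                    "expected": 0.0,
                    "net": 0.0,
                    "net_p5": 0.0,
                    "net_p95": 0.0,
                    "confidence": 0.5,
                    "n_valid": 0,
                }
            )
    return LossEstimate(pd.DataFrame(rows).set_index("slice"), net)


@dataclass(frozen=True)
class RateResult:
    """An extinction rate in extinctions per million species-years.

    ``E`` potentially lost taxa out of ``S`` observed over ``years``;
    ``rate = E / (S * years / 1e6)``.
    """

    E: int
    S: int
    years: float

    def __post_init__(self) -> None:
        if self.S <= 0:
            raise ValueError("S must be positive")
        if self.years <= 0:
            raise ValueError("duration must be positive")
        if self.E < 0:
            raise ValueError("E must be non-negative")
        if self.E > self.S:
            raise ValueError("cannot lose more taxa than observed (E > S)")

    @property
    def rate(self) -> float:
        return self.E / (self.S * self.years / 1e6)

    def rounded(self, ndigits: int = 1) -> float:
        return round(self.rate, ndigits)


def extinction_rate(E: int, S: int, years: float) -> RateResult:
    """E/MSY (or E/MGY for genera): losses per million taxon-years."""
    return RateResult(E=E, S=S, years=years)


def rate_ratio(a: RateResult, b: RateResult, ndigits: int = 1) -> float:
    """Ratio of two rates (e.g. megafauna over plants), rounded."""
    if b.rate == 0:
        raise ZeroDivisionError("reference rate is zero")
    return round(a.rate / b.rate, ndigits)
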