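"""Time-slice binning and balanced resampling of the record.

Samples are binned into contiguous 2000-year slices covering the last
28,000 calibrated years BP (14 slices by default; slice 0 is the oldest,
the last slice is the "modern" one covering 2000-0 cal yr BP). Because
cores differ in sample density and sequencing depth, taxon occupancy is
compared across slices only after a balanced resampling that equalises,
per slice, the number of cores, the number of samples per core and the
read depth per sample. Presence/absence per taxon, slice and resampling
iteration is the central object of all downstream loss inference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import TaxonTable


@dataclass(frozen=True)
class TimeSliceGrid:
    """Half-open 2000-yr age bins from the oldest bound down to 0 cal yr BP.

    Slice ``i`` covers ages ``[span - (i+1)*width, span - i*width)`` where
    ``span = n_slices * width_yr``; ages are calibrated years BP, so slice 0
    is the oldest and the last slice (ages ``[0, width)``) is the modern
    one. The exact upper bound ``span`` is included in slice 0 so that the
    grid covers ``[0, span]``.
    """

    n_slices: int = 14
    width_yr: int = 2000

    @property
    def span(self) -> int:
        return self.n_slices * self.width_yr

    @property
    def modern(self) -> int:
        """Index of the modern slice."""
        return self.n_slices - 1

    def midpoints(self) -> np.ndarray:
        """Slice midpoints in cal yr BP, oldest first (27,000 ... 1,000)."""
        return self.span - self.width_yr * (np.arange(self.n_slices) + 0.5)

    def bounds(self, i: int) -> tuple[int, int]:
        """(young, old) age bounds of slice ``i``."""
        old = self.span - i * self.width_yr
        return old - self.width_yr, old

    def slice_of(self, age: float) -> int | None:
        """Slice index containing ``age``, or None if older than the span."""
        if age < 0:
            raise ValueError(f"negative age: {age}")
        if age == self.span:
            return 0
        if age > self.span:
            return None
        return self.n_slices - 1 - int(age // self.width_yr)

    def slice_of_midpoint(self, midpoint: float) -> int:
        """Index of the slice whose midpoint is (closest to) ``midpoint``."""
        return int(np.argmin(np.abs(self.midpoints() - midpoint)))


def assign_slices(meta: pd.DataFrame, grid: TimeSliceGrid | None = None) -> pd.Series:
    """Map each sample to its time slice.

    Parameters
    ----------
    meta
        Sample metadata indexed by sample id with an ``age_cal_bp`` column.
    grid
        The slice grid (default: 14 x 2000 yr).

    Returns
    -------
    Integer series (sample id -> slice index). Samples older than the grid
    span are excluded with a warning; negative or non-finite ages raise.
    """
    grid = grid or TimeSliceGrid()
    ages = meta["age_cal_bp"]
    if not np.isfinite(ages).all():
        bad = list(ages.index[~np.isfinite(ages)])
        raise ValueError(f"non-finite ages for samples: {bad}")
    out = {}
    n_dropped = 0
    for sid, age in ages.items():
        s = grid.slice_of(float(age))
        if s is None:
            n_dropped += 1
        else:
            out[sid] = s
    if n_dropped:
        warnings.warn(
            f"excluded {n_dropped} sample(s) older than {grid.span} cal yr BP"
        )
    return pd.Series(out, dtype=int)


@dataclass
class TaxonOccupancy:
    """Per-iteration presence/absence of each taxon in each time slice.

    ``presence`` has shape (n_iter, n_taxa, n_slices); ``taxa`` and
    ``db_flag`` are aligned to axis 1, ``grid`` to axis 2.
    """

    presence: np.ndarray
    taxa: pd.Index
    db_flag: np.ndarray
    grid: TimeSliceGrid

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        self.db_flag = np.asarray(self.db_flag, dtype=bool)
        n_iter, n_taxa, n_slices = self.presence.shape
        if n_taxa != len(self.taxa) or n_taxa != len(self.db_flag):
            raise ValueError("taxa/db_flag not aligned with presence array")
        if n_slices != self.grid.n_slices:
            raise ValueError("grid not aligned with presence array")

    @property
    def n_iter(self) -> int:
        return self.presence.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.presence.shape[1]

    def subset_taxa(self, mask: np.ndarray) -> "TaxonOccupancy":
        mask = np.asarray(mask, dtype=bool)
        return TaxonOccupancy(
            self.presence[:, mask, :], self.taxa[mask], self.db_flag[mask], self.grid
        )

    def to_long(self) -> pd.DataFrame:
        """Long-format (iteration, taxon_id, slice_index, present) table."""
        n_iter, n_taxa, n_slices = self.presence.shape
        it, tx, sl = np.meshgrid(
            np.arange(n_iter), np.arange(n_taxa), np.arange(n_slices), indexing="ij"
        )
        return pd.DataFrame(
            {
                "iteration": it.ravel(),
                "taxon_id": np.asarray(self.taxa)[tx.ravel()],
                "slice_index": sl.ravel(),
                "present": self.presence.ravel().astype(int),
            }
        )


def _design(slice_map: pd.Series, meta: pd.DataFrame, n_slices: int):
    """Per-slice {core: [sample, ...]} layout; errors on empty slices."""
    cores = meta["core_id"]
    layout: list[dict] = [dict() for _ in range(n_slices)]
    for sid, sl in slice_map.items():
        layout[sl].setdefault(cores[sid], []).append(sid)
    empty = [i for i, d in enumerate(layout) if not d]
    if empty:
        raise ValueError(f"time slice(s) without any qualifying core/sample: {empty}")
    return layout


def balanced_resample(
    taxa: TaxonTable,
    meta: pd.DataFrame,
    slice_map: pd.Series,
    n_iter: int = 1000,
    seed: int = 0,
    grid: TimeSliceGrid | None = None,
    depth: int | None = None,
) -> TaxonOccupancy:
    """Three-step balanced resampling of the record into occupancy.

    Per iteration and slice: (1) draw, without replacement, the
    min-over-slices number of cores among cores with samples in the slice;
    (2) within each drawn core draw, without replacement, the
    min-over-(slice, core) number of samples; (3) rarefy each drawn
    sample's reads, without replacement (multivariate hypergeometric), to
    the common minimum sample depth. A taxon is present in a slice when at
    least one rarefied read of any of its member ASVs survives in any
    drawn sample.

    Samples with zero total reads are excluded from the design. The
    procedure equalises the total resampled reads per slice within an
    iteration (cores x samples x depth).
    """
    grid = grid or TimeSliceGrid()
    counts = taxa.counts
    slice_map = slice_map[slice_map.index.intersection(counts.columns)]
    totals = counts[slice_map.index].sum(axis=0)
    nonzero = totals[totals > 0].index
    if len(nonzero) < len(slice_map):
        warnings.warn(
            f"excluded {len(slice_map) - len(nonzero)} zero-read sample(s) from resampling"
        )
    slice_map = slice_map[nonzero]
    layout = _design(slice_map, meta, grid.n_slices)

    n_cores_min = min(len(d) for d in layout)
    n_samples_min = min(len(s) for d in layout for s in d.values())
    max_depth = int(totals[slice_map.index].min())
    if depth is None:
        depth = max_depth
    elif not 0 < depth <= max_depth:
        raise ValueError(f"depth must be in 1..{max_depth} (common minimum)")

    mat = counts[slice_map.index].to_numpy(dtype=np.int64)
    col_of = {sid: j for j, sid in enumerate(slice_map.index)}

    rng = np.random.default_rng(seed)
    n_taxa = taxa.n_taxa
    presence = np.zeros((n_iter, n_taxa, grid.n_slices), dtype=bool)
    for it in range(n_iter):
        for sl, per_core in enumerate(layout):
            core_ids = sorted(per_core)
            chosen_cores = rng.choice(len(core_ids), size=n_cores_min, replace=False)
            for ci in chosen_cores:
                samples = sorted(per_core[core_ids[ci]])
                chosen = rng.choice(len(samples), size=n_samples_min, replace=False)
                for si in chosen:
                    vec = mat[:, col_of[samples[si]]]
                    sub = rng.multivariate_hypergeometric(vec, depth)
                    presence[it, :, sl] |= sub > 0
    return TaxonOccupancy(presence, taxa.taxon_ids, taxa.db_flag.to_numpy(), grid)


def median_occupancy(occ: TaxonOccupancy) -> pd.DataFrame:
    """Majority-rule presence per taxon and slice (> 50% of iterations)."""
    frac = occ.presence.mean(axis=0)
    return pd.DataFrame(frac > 0.5, index=occ.taxa, columns=range(occ.grid.n_slices))


def percentile_band(values: np.ndarray, lo: float = 5, hi: float = 95) -> tuple[float, float]:
    """5-95 percentile band of a per-iteration scalar series."""
    return float(np.percentile(values, lo)), float(np.percentile(values, hi))
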