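"""Synthetic sedaDNA metabarcoding records with known ground truth.

The generator emulates the structure of a multi-core lake-sediment
metabarcoding record: several cores of dated samples spanning 28,000
calibrated years, ASVs assigned against a reference database at 90-100%
identity (100% = dbASV, 90-99% = non-dbASV), read counts that are
overdispersed (negative binomial), co-occurrence structure induced by
planted plant communities, independent low-prevalence noise/chimera ASVs,
and optional extinction pulses removing a known set of non-database taxa
from a known slice onward.

Community co-occurrence is produced by a shared per-sample latent
occupancy indicator: in a sample whose slice a community truly occupies,
the community is "on" with probability ``community_sample_prob``; member
ASVs are then each detected with probability ``detection_prob``. The
shared indicator yields the positive rank correlations that the network
stage thresholds, while distinct communities stay uncorrelated.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .tables import ASVTable, ReplicateMatrix

FUNCTIONAL_TYPES = ("forb", "graminoid", "shrub", "tree")

#: field-standard grouping: grasses, rushes and sedges are graminoids
_FAMILIES_BY_TYPE = {
    "graminoid": ["Poaceae", "Juncaceae", "Cyperaceae"],
    "forb": [
        "Asteraceae", "Ranunculaceae", "Boraginaceae", "Papaveraceae",
        "Polygonaceae", "Brassicaceae", "Saxifragaceae", "Orobanchaceae",
        "Fabaceae", "Rosaceae", "Caryophyllaceae",
    ],
    "shrub": ["Ericaceae", "Salicaceae"],
    "tree": ["Pinaceae", "Betulaceae"],
}

#: approximate mix of functional types in a full-glacial steppe record
_TYPE_PROBS = {"forb": 0.66, "graminoid": 0.08, "shrub": 0.19, "tree": 0.07}

#: share of taxa assigned at species / genus / family rank
_RANK_PROBS = {"species": 0.48, "genus": 0.37, "family": 0.15}


@dataclass
class SimConfig:
    """Parameters of the synthetic record.

    Defaults mirror the record structure the pipeline targets: eight cores
    of 63 samples (504 in total) binned into 14 x 2000-yr slices, ten
    planted communities, and a species pool with 70% reference-database
    coverage.
    """

    n_cores: int = 8
    samples_per_core: int = 63
    n_slices: int = 14
    slice_width_yr: int = 2000
    n_true_taxa: int = 360
    n_noise_asvs: int = 300
    coverage_fraction: float = 0.70
    community_sizes: list[int] | None = None
    extinction_pulses: list[tuple[int, int]] = field(default_factory=list)
    detection_prob: float = 0.95
    community_sample_prob: float = 0.60
    detection_beta: tuple[float, float] | None = (5.0, 2.0)
    abundance_sigma: float = 1.0
    mean_reads_per_sample: float = 10_000.0
    dispersion: float = 2.0
    extra_asv_fraction: float = 0.10
    noise_prevalence: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.coverage_fraction <= 1:
            raise ValueError("coverage_fraction must be in (0, 1]")
        if not 0 < self.detection_prob <= 1:
            raise ValueError("detection_prob must be in (0, 1]")
        if not 0 < self.community_sample_prob <= 1:
            raise ValueError("community_sample_prob must be in (0, 1]")
        for sl, n in self.extinction_pulses:
            if not 0 <= sl < self.n_slices:
                raise ValueError(f"pulse slice {sl} outside 0..{self.n_slices - 1}")
            if n < 1:
                raise ValueError("pulse size must be >= 1")
        if self.community_sizes is not None:
            if sum(self.community_sizes) != self.n_true_taxa:
                raise ValueError("community_sizes must sum to n_true_taxa")
        if self.samples_per_core < self.n_slices:
            raise ValueError(
                "need samples_per_core >= n_slices so every slice is populated"
            )

    def resolved_community_sizes(self) -> list[int]:
        if self.community_sizes is not None:
            return list(self.community_sizes)
        k = min(10, self.n_true_taxa)
        base, extra = divmod(self.n_true_taxa, k)
        return [base + (1 if i < extra else 0) for i in range(k)]


@dataclass
class GroundTruth:
    """What the generator planted, for downstream validation.

    ``taxa`` is indexed by taxon id with community, coverage, functional
    type, family/genus/name/rank and extinct flag; ``occupancy`` is the
    true taxon x slice presence; ``asv_to_taxon`` maps every non-noise
    ASV to its taxon.
    """

    taxa: pd.DataFrame
    occupancy: np.ndarray
    asv_to_taxon: pd.Series
    config: SimConfig

    def community_of_asvs(self, asv_ids) -> pd.Series:
        """Planted community id for each (non-noise) ASV."""
        comm = self.taxa["community_id"]
        return pd.Series(
            {a: comm[self.asv_to_taxon[a]] for a in asv_ids if a in self.asv_to_taxon.index}
        )

    def to_json(self, path) -> None:
        payload = {
            "config": asdict(self.config),
            "taxa": self.taxa.reset_index().to_dict(orient="list"),
            "occupancy": self.occupancy.astype(int).tolist(),
            "asv_to_taxon": self.asv_to_taxon.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _plant_taxa(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    sizes = cfg.resolved_community_sizes()
    community = np.repeat(np.arange(len(sizes)), sizes)
    covered = rng.random(cfg.n_true_taxa) < cfg.coverage_fraction
    types = rng.choice(
        list(_TYPE_PROBS), size=cfg.n_true_taxa, p=list(_TYPE_PROBS.values())
    )
    ranks = rng.choice(
        list(_RANK_PROBS), size=cfg.n_true_taxa, p=list(_RANK_PROBS.values())
    )
    rows = []
    for j in range(cfg.n_true_taxa):
        fam = _FAMILIES_BY_TYPE[types[j]][
            rng.integers(len(_FAMILIES_BY_TYPE[types[j]]))
        ]
        genus = f"Genus{j:04d}"
        rank = ranks[j]
        if rank == "species":
            name = f"{genus} species{j:04d}"
        elif rank == "genus":
            name = genus
        else:
            name, genus = fam, ""
        rows.append(
            {
                "taxon_id": f"T{j:04d}",
                "community_id": int(community[j]),
                "covered": bool(covered[j]),
                "functional_type": types[j],
                "family": fam,
                "genus": genus,
                "name": name,
                "rank": rank,
                "extinct": False,
            }
        )
    return pd.DataFrame(rows).set_index("taxon_id")


def _apply_pulses(
    cfg: SimConfig, taxa: pd.DataFrame, occupancy: np.ndarray, rng: np.random.Generator
) -> None:
    for sl, n in cfg.extinction_pulses:
        candidates = np.flatnonzero(
            (~taxa["covered"].to_numpy())
            & (~taxa["extinct"].to_numpy())
            & occupancy[:, sl]
        )
        if len(candidates) < n:
            raise ValueError(
                f"extinction pulse ({sl}, {n}): only {len(candidates)} uncovered "
                f"taxa available at slice {sl}"
            )
        chosen = rng.choice(candidates, size=n, replace=False)
        occupancy[chosen, sl:] = False
        taxa.iloc[chosen, taxa.columns.get_loc("extinct")] = True


def _sample_metadata(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Ages uniform within cores over the full span; every slice populated.

    Uniform dated depths give the uneven per-core, per-slice sample counts
    of real multi-core records (which is what makes the balanced
    resampling non-trivial). Draws leaving any slice empty are rejected
    and retried; persistently degenerate configurations raise.
    """
    span = cfg.n_slices * cfg.slice_width_yr
    for _ in range(100):
        ages = span * rng.uniform(0.0005, 0.9995, size=(cfg.n_cores, cfg.samples_per_core))
        occupied = np.zeros(cfg.n_slices, dtype=bool)
        occupied[
            cfg.n_slices - 1 - (ages.astype(int) // cfg.slice_width_yr).ravel()
        ] = True
        if occupied.all():
            break
    else:
        raise ValueError(
            "could not populate every time slice; increase samples_per_core"
        )
    rows = []
    for c in range(cfg.n_cores):
        core = f"core{c + 1}"
        for k in range(cfg.samples_per_core):
            rows.append(
                {
                    "sample_id": f"{core}_s{k:03d}",
                    "core_id": core,
                    "age_cal_bp": round(float(ages[c, k]), 1),
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


def _zero_truncated_nb(
    rng: np.random.Generator, mean: float, dispersion: float, size
) -> np.ndarray:
    """1 + NB(mean - 1): at least one read wherever an ASV is detected."""
    m = max(mean - 1.0, 1e-9)
    k = dispersion
    p = k / (k + m)
    return 1 + rng.negative_binomial(k, p, size=size)


def generate_record(cfg: SimConfig) -> tuple[ASVTable, pd.DataFrame, GroundTruth]:
    """Simulate a full multi-core record.

    Returns the sample-level ASV table, the sample metadata
    (``core_id``, ``age_cal_bp``) and the planted ground truth. Fully
    reproducible given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    taxa = _plant_taxa(cfg, rng)
    occupancy = np.ones((cfg.n_true_taxa, cfg.n_slices), dtype=bool)
    _apply_pulses(cfg, taxa, occupancy, rng)
    meta = _sample_metadata(cfg, rng)

    # one ASV per taxon, plus a second (non-db, coarser-rank) ASV for a fraction
    asv_rows = []
    asv_taxon_idx = []
    for j, (tid, row) in enumerate(taxa.iterrows()):
        ident = 100.0 if row["covered"] else float(rng.integers(90, 100))
        asv_rows.append(
            {
                "asv_id": f"ASV{len(asv_rows):05d}",
                "identity_pct": ident,
                "taxon_name": row["name"],
                "rank": row["rank"],
                "family": row["family"],
                "genus": row["genus"],
            }
        )
        asv_taxon_idx.append(j)
        if rng.random() < cfg.extra_asv_fraction:
            # a 90-99% variant of the same taxon, assigned at family rank
            asv_rows.append(
                {
                    "asv_id": f"ASV{len(asv_rows):05d}",
                    "identity_pct": float(rng.integers(90, 100)),
                    "taxon_name": row["family"],
                    "rank": "family",
                    "family": row["family"],
                    "genus": "",
                }
            )
            asv_taxon_idx.append(j)
    n_true_asvs = len(asv_rows)
    asv_taxon_idx = np.asarray(asv_taxon_idx)

    noise_fams = [f for fams in _FAMILIES_BY_TYPE.values() for f in fams]
    for k in range(cfg.n_noise_asvs):
        fam = noise_fams[rng.integers(len(noise_fams))]
        asv_rows.append(
            {
                "asv_id": f"ASV{len(asv_rows):05d}",
                "identity_pct": float(rng.integers(90, 100)),
                "taxon_name": fam,
                "rank": "family",
                "family": fam,
                "genus": "",
            }
        )
    info = pd.DataFrame(asv_rows).set_index("asv_id")

    # detection layer: shared community latent x per-ASV detection
    n_samples = len(meta)
    span = cfg.n_slices * cfg.slice_width_yr
    sample_slice = (
        cfg.n_slices
        - 1
        - np.minimum(
            (meta["age_cal_bp"].to_numpy() // cfg.slice_width_yr).astype(int),
            cfg.n_slices - 1,
        )
    )
    comm_of_taxon = taxa["community_id"].to_numpy()
    n_comm = comm_of_taxon.max() + 1
    z = rng.random((n_comm, n_samples)) < cfg.community_sample_prob
    # per-taxon detectability: common taxa are near cfg.detection_prob,
    # rare ones well below it, so occupancy flickers the way sparse
    # metabarcoding records do; detection_beta=None disables the spread
    if cfg.detection_beta is None:
        q = np.ones(cfg.n_true_taxa)
    else:
        q = rng.beta(*cfg.detection_beta, size=cfg.n_true_taxa)
    d_asv = cfg.detection_prob * q[asv_taxon_idx]
    det = rng.random((n_true_asvs, n_samples)) < d_asv[:, None]
    occ_sample = occupancy[:, sample_slice]  # taxon x sample
    present = occ_sample[asv_taxon_idx] & z[comm_of_taxon[asv_taxon_idx]] & det

    expected_detected = max(
        present.mean(axis=1).sum()
        + cfg.n_noise_asvs * cfg.noise_prevalence,
        1.0,
    )
    mu = max(cfg.mean_reads_per_sample / expected_detected, 2.0)
    # lognormal per-taxon abundance spectrum (rare-to-common), mean-normalised
    ab = rng.lognormal(0.0, cfg.abundance_sigma, size=cfg.n_true_taxa)
    ab /= ab.mean()
    mu_asv = np.maximum(mu * ab[asv_taxon_idx], 2.0)
    reads = np.empty(present.shape, dtype=np.int64)
    for i in range(n_true_asvs):
        reads[i] = _zero_truncated_nb(rng, mu_asv[i], cfg.dispersion, n_samples)
    true_counts = np.where(present, reads, 0)

    noise_present = rng.random((cfg.n_noise_asvs, n_samples)) < cfg.noise_prevalence
    noise_reads = _zero_truncated_nb(
        rng, max(mu / 4.0, 2.0), cfg.dispersion, noise_present.shape
    )
    noise_counts = np.where(noise_present, noise_reads, 0)

    counts = pd.DataFrame(
        np.vstack([true_counts, noise_counts]).astype(np.int64),
        index=info.index,
        columns=meta.index,
    )
    table = ASVTable(info, counts)
    truth = GroundTruth(
        taxa=taxa,
        occupancy=occupancy,
        asv_to_taxon=pd.Series(
            taxa.index.to_numpy()[asv_taxon_idx], index=info.index[:n_true_asvs]
        ),
        config=cfg,
    )
    return table, meta, truth


def true_taxon_table(table: ASVTable, truth: GroundTruth):
    """Collapse ASVs by their *planted* taxon (oracle route).

    Aggregates member-ASV counts per ground-truth taxon with the planted
    db flag, bypassing the co-occurrence stage; used to exercise the
    occupancy and loss stages against known truth, and as the reference
    when validating the community-based collapse.
    """
    from .tables import TaxonTable

    rows = []
    counts = []
    for tid, row in truth.taxa.iterrows():
        asvs = list(truth.asv_to_taxon.index[truth.asv_to_taxon == tid])
        asvs = [a for a in asvs if a in table.asv_ids]
        if not asvs:
            continue
        rows.append(
            {
                "taxon_id": tid,
                "name": row["name"],
                "rank": row["rank"],
                "family": row["family"],
                "genus": row["genus"],
                "db_flag": bool(row["covered"]),
                "community_id": int(row["community_id"]),
                "member_asvs": ";".join(asvs),
            }
        )
        counts.append(table.counts.loc[asvs].sum(axis=0))
    info = pd.DataFrame(rows).set_index("taxon_id")
    return TaxonTable(info, pd.DataFrame(counts, index=info.index))


def split_replicates(
    table: ASVTable,
    meta: pd.DataFrame,
    n_replicates: int = 3,
    bad_replicate_rate: float = 0.0,
    seed: int = 0,
) -> ReplicateMatrix:
    """Split sample counts into PCR replicates (multinomial thinning).

    With ``bad_replicate_rate`` > 0, a fraction of samples get one
    replicate replaced by a degenerate low-quality profile (< 100 reads
    over < 3 ASVs), emulating a failed PCR for the QC stage to catch.
    """
    rng = np.random.default_rng(seed)
    rep_counts = {}
    rep_meta = []
    for sid in table.sample_ids:
        vec = table.counts[sid].to_numpy()
        split = rng.multinomial(1, np.full(n_replicates, 1 / n_replicates), size=vec.sum())
        per_rep = np.zeros((len(vec), n_replicates), dtype=np.int64)
        reads_asv = np.repeat(np.arange(len(vec)), vec)
        for r in range(n_replicates):
            np.add.at(per_rep[:, r], reads_asv[split[:, r] == 1], 1)
        bad = rng.random() < bad_replicate_rate
        for r in range(n_replicates):
            rid = f"{sid}_r{r + 1}"
            if bad and r == 0:
                degenerate = np.zeros(len(vec), dtype=np.int64)
                alive = np.flatnonzero(vec)
                if len(alive):
                    pick = rng.choice(alive, size=min(2, len(alive)), replace=False)
                    degenerate[pick] = rng.integers(10, 45, size=len(pick))
                per_rep[:, r] = degenerate
            rep_counts[rid] = per_rep[:, r]
            rep_meta.append(
                {
                    "replicate_id": rid,
                    "sample_id": sid,
                    "core_id": meta.loc[sid, "core_id"],
                }
            )
    counts = pd.DataFrame(rep_counts, index=table.asv_ids)
    return ReplicateMatrix(
        table.info.copy(), counts, pd.DataFrame(rep_meta).set_index("replicate_id")
    )


def generate_species_pool(
    n_species: int,
    coverage_fraction: float = 0.70,
    occurrence_dist=None,
    seed: int = 0,
    exact: bool = False,
) -> pd.DataFrame:
    """A GBIF-like regional species pool with database-coverage flags.

    Each species carries a ``covered`` flag (Bernoulli ``coverage_fraction``,
    or exactly ``round(n * coverage_fraction)`` covered species when
    ``exact``) and an occurrence count drawn from ``occurrence_dist`` (a
    callable ``f(rng, n) -> array``; default: 10 + lognormal, i.e. only
    species with > 10 regional occurrences, skewed rare-to-common). The
    occurrence distribution is identical for covered and uncovered strata.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    if not 0 < coverage_fraction <= 1:
        raise ValueError("coverage_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    if occurrence_dist is None:
        occurrence_dist = lambda r, n: np.rint(10 + r.lognormal(3.0, 1.2, n)).astype(int)
    occurrences = occurrence_dist(rng, n_species)
    if exact:
        n_cov = int(round(n_species * coverage_fraction))
        covered = np.zeros(n_species, dtype=bool)
        covered[rng.choice(n_species, size=n_cov, replace=False)] = True
    else:
        covered = rng.random(n_species) < coverage_fraction
    families = [f"Family{k:03d}" for k in rng.integers(0, 40, size=n_species)]
    return pd.DataFrame(
        {
            "species": [f"species{i:05d}" for i in range(n_species)],
            "family": families,
            "covered": covered,
            "occurrences": occurrences,
        }
    )


def generate_tree(taxa: list[str], seed: int = 0) -> str:
    """A random ultrametric (coalescent) tree over the given tips, as Newick.

    Stand-in for a published vascular-plant mega-tree; used only to give
    the cophenetic comparisons a tree with realistic depth structure.
    """
    import random as _random

    import dendropy
    from dendropy.simulate import treesim

    if len(taxa) < 2:
        raise ValueError("need at least 2 taxa")
    if len(set(taxa)) != len(taxa):
        dupes = sorted({t for t in taxa if taxa.count(t) > 1})
        raise ValueError(f"duplicate tip names: {dupes}")
    tns = dendropy.TaxonNamespace([str(t) for t in taxa])
    tree = treesim.pure_kingman_tree(
        taxon_namespace=tns, pop_size=100, rng=_random.Random(seed)
    )
    return tree.as_string(schema="newick")
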