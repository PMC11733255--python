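"""Characterise lost taxa and screen drivers of the loss series.

Compares lost non-dbtaxa against the other taxa on community size, SCBD
and cophenetic distance, tabulates loss proportions per functional type
and family, computes the vegetation-turnover series, and screens drivers
(lagged turnover, a temperature-anomaly change series, a megafauna
extinction window) with pairwise binomial GLMs.
"""

import argparse
import json
import pathlib

import numpy as np
import pandas as pd

from paleoloss import lossrate, timeslice, traits
from paleoloss.tables import TaxonTable

SCRATCH = pathlib.Path("scratch/record")
RESULTS = pathlib.Path("results")
REFERENCE_MIDPOINTS = (25_000, 23_000, 21_000)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    data = np.load(SCRATCH / "occupancy.npz", allow_pickle=False)
    grid = timeslice.TimeSliceGrid()
    occ = timeslice.TaxonOccupancy(
        data["presence"], pd.Index(data["taxa"]), data["db_flag"], grid
    )
    taxa = TaxonTable.from_tsv(SCRATCH / "taxa.tsv")
    truth = json.loads((SCRATCH / "truth.json").read_text())
    truth_taxa = pd.DataFrame(truth["taxa"]).set_index("taxon_id")

    median = timeslice.median_occupancy(occ)
    lost = (median.iloc[:, :-1].any(axis=1) & ~median.iloc[:, -1]).to_numpy()
    lost_nondb = lost & ~occ.db_flag

    # community size: members of each taxon's co-occurrence community
    comm_sizes = taxa.info["community_id"].map(
        taxa.info["community_id"].value_counts()
    )
    cmp_size = traits.group_compare(
        comm_sizes[lost_nondb], comm_sizes[~lost_nondb], test="wilcoxon"
    )

    # SCBD on median-resampled per-slice abundance (reads summed per slice)
    slice_reads = pd.DataFrame(
        0.0, index=taxa.taxon_ids, columns=range(grid.n_slices)
    )
    from paleoloss.tables import read_sample_meta

    meta = read_sample_meta(SCRATCH / "samples.csv")
    slice_map = timeslice.assign_slices(meta, grid)
    for sid, sl in slice_map.items():
        slice_reads[sl] += taxa.counts[sid]
    scores = traits.scbd(slice_reads)
    cmp_scbd = traits.group_compare(
        scores[lost_nondb], scores[~lost_nondb], test="wilcoxon"
    )

    # cophenetic distances on the simulated phylogeny (planted-taxon tips)
    tree = (SCRATCH / "tree.nwk").read_text()
    # map collapsed taxa back to a planted taxon via their first member ASV
    asv_to_taxon = truth["asv_to_taxon"]
    tip_of = {
        t: asv_to_taxon.get(row["member_asvs"].split(";")[0])
        for t, row in taxa.info.iterrows()
    }
    lost_tips = sorted({tip_of[t] for t, f in zip(taxa.taxon_ids, lost_nondb) if f and tip_of[t]})
    other_tips = sorted(
        {tip_of[t] for t, f in zip(taxa.taxon_ids, lost_nondb) if not f and tip_of[t]}
        - set(lost_tips)
    )
    coph = traits.cophenetic_compare(tree, lost_tips, other_tips)

    # functional type / family loss proportions (traits from ground truth)
    trait_lookup = pd.DataFrame(
        {
            "functional_type": [
                truth_taxa.loc[tip_of[t], "functional_type"] if tip_of[t] else "forb"
                for t in taxa.taxon_ids
            ],
            "family": taxa.info["family"],
        },
        index=taxa.taxon_ids,
    )
    groups = traits.type_and_family_loss(occ, trait_lookup)

    # turnover series and driver screen
    turn = traits.turnover(occ)
    turn.round(4).to_csv(RESULTS / "06_turnover.tsv", sep="\t")
    events = lossrate.disappearance_events(occ)
    refs = [grid.slice_of_midpoint(m) for m in REFERENCE_MIDPOINTS]
    null = lossrate.build_null(events, refs, n_iter=occ.n_iter)
    est = lossrate.loss_estimates(events, null, occ, db=False)
    response = (np.nan_to_num(est.net_iter) > 0).astype(float)

    rng = np.random.default_rng(args.seed)
    n_tr = grid.n_slices - 1
    temperature_change = np.diff(
        np.cumsum(rng.normal(0, 0.5, n_tr + 1))
    )  # random-walk anomaly increments
    megafauna_window = ((grid.midpoints()[:-1] <= 15000) & (grid.midpoints()[:-1] >= 10000)).astype(float)
    covariates = pd.DataFrame(
        {
            "turnover_lag1": traits.lag_series(turn["median"].to_numpy(), 1),
            "temperature_change": temperature_change,
            "megafauna_window": megafauna_window,
        }
    )
    fit = traits.driver_glm(response, covariates)
    fit.table.round(4).to_csv(RESULTS / "06_driver_glm.tsv", sep="\t")

    report = {
        "community_size": {
            "median_lost_nondb": cmp_size.location_lost,
            "median_other": cmp_size.location_other,
            "pvalue": cmp_size.pvalue,
        },
        "scbd": {
            "median_lost_nondb": cmp_scbd.location_lost,
            "median_other": cmp_scbd.location_other,
            "pvalue": cmp_scbd.pvalue,
        },
        "cophenetic": coph,
        "type_loss_pct": groups["type_summary"]["median_pct"].round(1).to_dict(),
        "families_assessed": list(groups["family_summary"].index),
        "driver_chi2": fit.table["chi2"].round(1).to_dict(),
    }
    with open(RESULTS / "06_traits_summary.json", "w") as fh:
        json.dump(report, fh, indent=1)
    print(
        "lost non-dbtaxa: community size "
        f"{cmp_size.location_lost:.1f} vs {cmp_size.location_other:.1f} "
        f"(p={cmp_size.pvalue:.3g}); SCBD {cmp_scbd.location_lost:.2e} vs "
        f"{cmp_scbd.location_other:.2e} (p={cmp_scbd.pvalue:.3g}); "
        f"driver chi2: {report['driver_chi2']}"
    )


if __name__ == "__main__":
    main()
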