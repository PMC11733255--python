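# paleoloss

Inference of plant extirpation and potential extinction from sedimentary
ancient DNA (*sed*aDNA) metabarcoding time series.

## The problem

Plant extinctions leave almost no fossil trace: macrofossils are rare and
pollen rarely resolves below family level. Metabarcoding of DNA preserved
in dated lake-sediment cores recovers plant occurrences at high taxonomic
resolution — but a taxon that went extinct is, by definition, unlikely to
be in any modern reference database, so the standard practice of keeping
only 100%-identity matches silently discards exactly the taxa of
interest. `paleoloss` implements an inference chain that keeps 90–99%
identity sequences (candidate unknown taxa), separates them from PCR and
sequencing artefacts by their ecological co-occurrence structure, and
turns the resulting occupancy time series into per-slice loss estimates
with explicit nulls for the two obvious confounders: taxa that merely
flicker out of a sparse record, and taxa that only look "unknown" because
the reference database is incomplete.

It is written for palaeoecologists working with multi-core ASV tables
(OBITools3-style TSV) and for anyone who wants to stress-test this class
of extinction inference on synthetic records with known ground truth.

## The method

1. **QC and filtering** (`qc_filter`): PCR replicates with < 100 reads
   and < 3 distinct ASVs are dropped (after a Bray–Curtis divergence
   flag); survivors are summed into samples; ASVs are kept when identity
   ≥ 90%, occupancy ≥ 10 samples and total reads ≥ 100. ASVs at 100%
   identity are *dbASVs*, the rest *non-dbASVs*.
2. **Community validation** (`cooccur`): all-pairs Spearman correlations
   over samples (Holm-adjusted); edges where ρ > 0.4 and p_adj < 0.05;
   Louvain modularity communities; within each community of ≥ 5 ASVs,
   ASVs collapse into taxa (identical-name dbASVs merge; a non-dbASV
   joins a dbtaxon whose name matches at the coarser of the two ranks;
   leftover non-dbASVs with equal names merge). ASVs outside reported
   communities are treated as artefacts.
3. **Balanced resampling** (`timeslice`): samples are binned into 14 ×
   2000-yr slices (28,000–0 cal yr BP); per iteration and slice the same
   number of cores, samples per core and reads per sample
   (hypergeometric rarefaction) are drawn, giving taxon × slice ×
   iteration presence.
4. **Reappearance null** (`lossrate`): for disappearances at the
   reference slices (~25k, ~23k, ~21k cal yr BP, leaving nine slices to
   reappear) the empirical survival function of reappearance delays gives
   the expected fraction still "lost" after any remaining horizon. Net
   loss per slice is observed − expected (in percentage points);
   confidence is the fraction of iterations with positive net. Rates are
   E/MSY: `E / (S · T)` with `T` in Myr.
5. **Coverage null and bounds** (`covnull`): gains/losses between
   consecutive slices are replayed over a GBIF-like species pool with a
   known database-coverage fraction; the simulated covered/uncovered
   split among modern-absent taxa gives the losses expected from
   database incompleteness alone (lower bound of true extinctions), and
   family-level species overlap with regions where lost taxa still match
   gives the expected outside-refugium count (upper bound).
6. **Traits** (`traits`): community size, species contribution to beta
   diversity (SCBD, on Hellinger-transformed taxon × slice abundances),
   cophenetic distances, functional-type and family loss proportions,
   the replacement (turnover) component of compositional change, and
   pairwise binomial GLM screens of loss drivers.

The `synthdata` module generates complete multi-core records with planted
communities, database coverage, detection noise and extinction pulses, so
every stage is testable against known truth.

## Worked example

The `analysis/` scripts run the whole chain on a synthetic record with
extinction pulses planted at the slices whose midpoints are 17,000 and
9,000 cal yr BP:

```
python analysis/01_simulate.py --seed 1
python analysis/02_qc_communities.py --seed 1
python analysis/03_resample.py --seed 1
python analysis/04_loss_rates.py --seed 1
python analysis/05_coverage_null.py --seed 1
python analysis/06_traits.py --seed 1
```

which prints (seed 1):

```
record: 260 ASVs x 252 samples over 6 cores; 24 taxa planted extinct at slices 5 and 9
dropped 11 replicates; 181 ASVs -> 128 taxa in 11 communities (ARI vs planted 0.791; 0 noise ASVs admitted)
resampled 200 iterations; 128 taxa; lost from modern slice: 8 dbtaxa, 15 non-dbtaxa
non-db net-loss peaks at slices [4, 8] (midpoints [19000, 11000] cal yr BP), confidence [1.0, 1.0]; 15/128 lost non-dbtaxa -> 4.2 E/MSY
simulated modern stratum 70.2% db; 15 lost non-dbtaxa, 7 expected from coverage, 1 expected refugium -> bounds [8, 14]
```

Reading this: the two planted pulses are recovered as the two highest
net-loss peaks — a pulse at the 17k slice produces its disappearance
events at the preceding transition (slice 4, midpoint 19k) — both with
confidence 1.0; of the 15 non-dbtaxa absent from the modern slice, the
coverage null explains 7 and the refugium assessment removes 1 more, so
8–14 are inferred potentially extinct. Summary tables land in
`results/`.

A thin CLI (`paleoloss simulate | qc | communities | resample | loss |
null | refugia`) exposes the same stages for shell pipelines.

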