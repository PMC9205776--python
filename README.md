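# loopscreen

Aggregate Hi-C architecture analysis and haploid gene-trap screen statistics,
packaged as a tested pipeline with synthetic-data generators that carry
planted ground truth.

## The scientific problem

Cohesin enlarges chromatin loops by extrusion; CTCF sites anchor the process
and give rise to focal loops and *architectural stripes* — lines of enriched
contact emanating from an anchor.  How far extrusion reaches past an anchor
is regulated (acetylation of cohesin's SMC3 subunit, the release factor
WAPL, and the PDS5A "brake" all shift it), and that reach is visible in Hi-C
as the length of stripes, the strength of *extended loops* (a loop's 5′
anchor paired with 3′ anchors beyond its own), and the balance between
primary and extended loop enrichment.  A companion haploid gene-trap screen
asks which gene knockouts change cell fitness in a mutant background: sense
intronic insertions disrupt a gene, antisense ones do not, so genes whose
loss is advantageous accumulate an excess of sense insertions.

`loopscreen` implements both analysis arms:

* **Contact-map core** (`loopscreen.matrixcore`) — sparse one-chromosome cis
  matrices in a triplet text format; ICE balancing (iterative correction of
  bin marginals); scaling to a fixed total (default 10⁸ contacts);
  binomial-thinning subsampling; the expected-per-distance profile
  E(d) and the observed/expected transform O/E(i,j) = M(i,j)/E(|i−j|).
* **Aggregation** (`loopscreen.aggregates`) — APA (mean submatrix over loop
  anchor pairs, ±100 kb flank, central-3×3 score), extended-loop enumeration
  (every 5′ anchor × every other 3′ anchor within 3 Mb, primaries excluded),
  differential aggregate maps, aggregate stripe analysis (6-Mb
  submatrix centered on each anchor's diagonal pixel, divided by E(d) before
  averaging), and LOESS (local polynomial regression, tricube weights) with
  a pointwise 95% confidence band for stripe-profile quantification.
* **Screen statistics** (`loopscreen.screen`) — per-gene percent-sense;
  step 1: exact two-sided binomial test of the sense count against a null
  sense fraction with Benjamini–Hochberg correction (q < 0.05); step 2:
  two-sided Fisher exact test against every independent control; an
  odds-ratio floor (OR ≥ 0.7, Haldane-corrected) with a one-sided Fisher
  test on the aggregated controls; fitness-enhancer classification and
  ranking.
* **Synthetic data** (`loopscreen.simdata`) — Poisson contact maps with a
  power-law distance decay, planted CTCF-anchored loops, exponential stripes
  with decay length *L*, and genotype presets encoding the qualitative
  phenotype ordering (deacetylase knockout < wild type < acetyltransferase
  knockout < release-factor knockouts); gene-trap count tables with planted
  fitness enhancers.
* **Pipelines & CLI** (`loopscreen.pipeline`, `loopscreen.cli`) — end-to-end
  genotype comparison and screen calling with machine-readable reports;
  `loopscreen simulate-hic|simulate-screen|balance|apa|extended-loops|stripes|screen-call|run-all`.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (a 50-Mb chromosome at 100-kb resolution, ~10⁷ cis contacts per
genotype, one shared CTCF-site layout):

```sh
python analysis/01_simulate_genotypes.py   # maps + loops + sites -> results/simdata
python analysis/02_stripe_quantification.py
python analysis/03_extended_loop_apa.py
python analysis/04_screen_analysis.py
```

`02_stripe_quantification.py` prints (seed 0):

```
     genotype  stripe3_mean_1_3mb  decay_length_planted_mb  decay_length_estimated_mb
       dHDAC8               1.250                    0.300                      0.295
           WT               1.345                    0.600                      0.604
       dESCO1               1.539                    1.000                      0.982
        dWAPL               1.657                    1.400                      1.385
 dESCO1_dWAPL               1.823                    2.000                      2.040
       dPDS5A               1.499                    1.200                      1.234
dHDAC8_dPDS5A               1.469                    1.100                      1.085

planted ordering recovered: True
```

`stripe3_mean_1_3mb` is the mean O/E of the 3′ stripe 1–3 Mb from the
anchor: larger values mean longer-reaching extrusion.  The estimated decay
lengths recover the planted truth within a few percent.
`03_extended_loop_apa.py` shows the matching extended-loop APA ordering and
the PDS5A-knockout signature (primary-loop score drops from 877 to 594
while the extended-loop score rises), and `04_screen_analysis.py` flags
exactly the planted fitness-enhancer gene and ranks it first out of 20,000.

## Repository layout

```
src/loopscreen/     library (matrixcore, aggregates, screen, simdata,
                    pipeline, cli)
analysis/           numbered narrative drivers writing results/
tests/              pytest suite (unit, property, and end-to-end checks)
scripts/acceptance.py
docs/methods.md     model, parameter, and design documentation
```
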