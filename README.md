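# divtime

Diversification timing of regional faunas on dated phylogenies.

Given an ultrametric chronogram (branch lengths in Myr) and a table
classifying its species as endemic, non-endemic native, exotic or
outgroup, `divtime` answers the question: *did a given class of species
diversify earlier or later than expected by chance?* It was built around
the analysis shape used for Mediterranean teleosts — a few hundred
species on a tree ~125–160 Myr deep — but applies to any dated tree with
a categorical classification of its tips.

The core statistic: prune the chronogram to the n species of a class,
record the age of every split (a polytomy of k children counts as k−1
splits), and take the weighted median. The null model redraws n tips at
random without replacement from the full Mediterranean pool 1000 times
and recomputes the median each time; the observed median is significant
if it falls outside the central 95% of the resampled medians (two-tailed,
inclusive empirical quantiles, ties conservative). The test is repeated
reading node ages at the lower and upper 95% credibility bounds to check
robustness to dating uncertainty.

Around this sit: a taxonomic grafting procedure that attaches
sequence-less species as polytomies at the MRCA of their genus, family
or order (branch length = attachment-node age), producing a series of
chronograms of growing coverage; lineage-through-time curves and event
histograms; a conservation-based alignment block filter (min block 10,
max 5 contiguous nonconserved columns, >50%-gap columns excluded) with
partitioned supermatrix concatenation and missing-data accounting; and a
birth–death generator that simulates every input the pipeline consumes,
so the whole chain is testable without any sequence download.

## Worked example

```bash
python analysis/01_simulate_fauna.py   # synthetic 372-tip fauna
python analysis/02_timing_tests.py     # medians + randomization tests
python analysis/03_grafting_series.py  # four enriched chronograms
python analysis/04_supermatrix.py      # block filter + concatenation
```

`01` simulates a 372-tip chronogram (363 "Mediterranean" species + a few
outgroups, height ≈ 126 Myr), labels whole clades that originated around
10 Mya as endemics, synthesizes 15% node-age credibility intervals, and
generates 124 graft requests. `02` then prints:

```
all Mediterranean species (n=366): median split age mean=20.1, lower=18.1, upper=21.5 Myr
endemic (n=62): median mean=10.1, lower=9.5, upper=11.0 Myr
  [mean] observed 10.1 vs central 95% [46.3, 58.9] -> significant_young
  [lower] observed 9.5 vs central 95% [44.3, 55.4] -> significant_young
  [upper] observed 11.0 vs central 95% [49.2, 64.7] -> significant_young
native (n=247): median mean=26.7, lower=25.6, upper=28.5 Myr
  [mean] observed 26.7 vs central 95% [23.4, 27.6] -> not_significant
...
```

The endemics — whole recent radiations by construction — have a median
split age of ~10 Myr, far below the central 95% of medians from random
62-species draws (46–59 Myr), at all three age bounds; natives and
exotics, whose labels are spread over the tree, stay inside the null
band. `03` grafts the 124 extra species in four cumulative steps
(405, 417, 474, 496 tips) and shows the verdicts are unchanged on every
enriched chronogram. `04` demonstrates the block filter (a 60-column
alignment with two clean 15-column blocks → 30 columns retained, 50%)
and concatenates six loci at lengths 297 + 376 + 622 + 1107 + 437 + 1424
= 4,263 sites with ~59% of taxon-by-locus blocks missing.

The same steps are available as a CLI (`divtime simulate | events |
randtest | graft | supermatrix | run`) and as a one-shot YAML-driven
pipeline (`divtime run --config analysis.yaml --out-dir out/`), which
writes `report.json` plus per-category event/histogram/LTT/null TSVs.

## Layout

```
src/divtime/        library: chronogram_io, synthetic, diversification,
                    randomization, grafting, supermatrix, pipeline, cli
analysis/           numbered narrative drivers (write under results/)
tests/              pytest suite, including whole-method checks
scripts/acceptance.py   headline-quantity recomputation
docs/methods.md     model, conventions, parameter defaults, limitations
```
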