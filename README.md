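# rnaihts

Analysis toolkit for **dual-luciferase genome-wide RNAi screens**: plate
normalisation, robust Z-scoring, multi-rule hit selection, screen
comparison, circular off-target analysis, QC summaries, and a synthetic
screen generator.

## The problem

A genome-wide RNAi screen in *Drosophila* cells reads two luminescence
channels per 384-well plate well: a pathway-responsive Firefly luciferase
reporter (FL) and a constitutive Renilla luciferase (RL) that proxies cell
number. Knocking down a pathway regulator moves the FL/RL ratio; but plate
gain drift, edge effects, liquid-handling failures, Renilla-stability
artefacts and dsRNA off-target effects (OTEs) all mimic real hits. This
package implements the full post-screen workflow used by screening
facilities to separate biology from artefact.

## The method

Per replicate, well ratios are normalised by **intra-plate median
centering** and scored with the **robust Z-score**

```
Z = (x − median) / (1.4826 · MAD),   MAD = median(|x − median|)
```

against either all sample wells of a replicate (genome screens) or the
non-interacting control wells (re-screens whose plates are dominated by
interacting reagents). Wells named in a *screen log* are removed **before**
any reference statistic is computed, then replicate Z-scores are averaged.
A clone is a hit only if

1. |average Z(FL/RL)| ≥ 2.0,
2. at least two replicates individually reach |Z| ≥ 2.0 with a consistent
   sign,
3. the FL channel alone is significant with the same sign, and
4. the RL channel alone is **not** significant (rejecting Renilla-stability
   artefacts such as heat-shock/proteolysis genes).

Scores with 1.7 ≤ |Z| < 2.0 are reported as *trending*. A negative average
Z (reporter down on knockdown) marks a positive pathway regulator.

For off-target analysis, a hit clone is *circular* when one of its
predicted 19-nt off-target genes is itself a hit. The background rate is
estimated by repeatedly sampling 100 library clones and counting circular
clones within each sample (1000 iterations), with an add-one empirical
p-value for the observed rate.

## Worked example

The package ships reference tables transcribed from a published JAK/STAT
screen pair (a second-generation SRSF/HD2 library screen and a reanalysed
first-generation HFA screen). Reproducing its headline numbers:

```python
import rnaihts as r
from rnaihts import refdata

print(refdata.secondary_tier_summary())
# {'significant': 22, 'trending_same_direction': 7, 'not_significant': 13}

genome = refdata.srsf_genome_calls()
print((genome["direction"] == "positive_regulator").sum())   # 20

confirmed = r.tertiary_confirmation(
    genome, refdata.tertiary_calls(), refdata.tertiary_not_screened())
print(len(confirmed))                                         # 16

cmp = r.compare_screens(genome, refdata.hfa_genome_calls(),
                        refdata.hfa_availability())
print(cmp.overlap_count)                                      # 12

count, rate = r.observed_circularity(
    refdata.hfa_hit_clones(), refdata.reference_hit_genes(),
    refdata.reference_ote_graph())
print(count, round(100 * rate, 1))                            # 10 7.4
```

Of the 42 genome-screen hits, 22 re-verify in the control-referenced
secondary screen and 7 more trend the same way; 16 verify with an
independent dsRNA design; 12 overlap the first-generation screen once
wells lost to exclusions are accounted for; and 10 of the 136
first-generation hit clones (7.4%) — but only 1 of 43 second-generation
clones (2.3%) — have a predicted off-target that is itself a hit.

A fully synthetic pipeline run from the shell:

```sh
rnaihts simulate --seed 1 --out sim/
rnaihts score --layout sim/layout.tsv --measurements sim/measurements.tsv --out scores
rnaihts call-hits --scores scores --out hits.tsv
rnaihts qc --scores scores --out qc
```

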