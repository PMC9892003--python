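# polyneigh

Reciprocal neighborhood analysis of ribosome particle fields from
cryo-electron tomography.

Subtomogram averaging of ER-derived vesicles yields, for each ribosome, a
position, an orientation, a translational-state class (elongation-cycle
intermediates such as decoding, pre+, rotated, translocation, post, and
hibernating states) and a translocon-population class (SEC61–TRAP–OSTA,
SEC61–TRAP, multipass variants, soluble EBP1-bound). `polyneigh` turns
those particle tables into quantitative statements about polysome
organization, for structural biologists asking questions like *are
hibernating ribosomes excluded from polysomes?* or *which translocon
variants neighbor each other on the same mRNA?*

## Method

1. **Neighbor histograms.** For every ribosome, the vectors to its *n* = 4
   closest neighbors within 100 Å (same tomogram) are rotated with the
   inverse of the ribosome's orientation, giving neighbor coordinates in
   the particle frame (membrane in the *xy* plane for ER-bound ribosomes).
   Vectors are binned in 15 Å voxels and normalized by the total number of
   analysed neighbors, giving the probability of finding a neighbor in each
   voxel.
2. **Trailing/leading masks.** Supra-threshold clusters (*P* > 0.0005 for
   the membrane-bound histogram, *P* > 0.0003 for the soluble one) are
   assigned to the trailing or leading direction, dilated by two voxels and
   unioned across populations. A trailing–leading connection between
   ribosomes *i* and *j* is confirmed only reciprocally: *j* in *i*'s
   trailing mask **and** *i* in *j*'s leading mask (the inverse
   calculation). Confirmed links assemble into polysome chains.
3. **Association statistics.** Whether a ribosome of state *s* in tomogram
   *t* is in a polysome (or which class its confirmed neighbor has) is
   modelled as a multinomial mixed-effects logistic regression,
   log-odds(*k* vs reference) = β<sub>k,s</sub> + u<sub>k,t</sub> with
   u<sub>k,t</sub> ~ N(0, σ²<sub>k</sub>), the tomogram as a random effect.
   The package reports predicted probabilities with 95% CIs, two-sided Wald
   contrasts with Hochberg adjustment, and fold increases over the
   random-association probability (fractional abundance of the outcome).

A synthetic-scene generator builds ER vesicles carrying membrane-bound
polysome chains, soluble ribosomes and per-tomogram abundance variability,
with ground truth recorded before jitter — every stage is testable without
external data. See `docs/methods.md` for conventions, estimation details
and limitations.

## Worked example

Run the whole pipeline on a synthetic 20-tomogram dataset:

```sh
polyneigh run-all --seed 1 --n-tomograms 20 --outdir run
```

which prints the link-recovery summary against the generator's ground
truth:

```json
{
  "n_particles": 3834,
  "n_true_edges": 2355,
  "n_found_edges": 2375,
  "edge_recovery": 0.9995753715498938,
  "spurious_fraction": 0.008842105263157894
}
```

i.e. of 2,355 planted trailing→leading links, 99.96% are recovered by the
reciprocal-mask confirmation, and 0.9% of confirmed links are not planted
(chance co-localizations that satisfy the geometry). `run/` then contains
the per-stage artifacts — particle table (STAR), neighbor vectors,
histograms and *xy* projections, masks, links, chains, per-tomogram
frequencies, and the model outputs. `run/association.tsv` holds the
modelled polysome-membership probabilities per ribosome state:

```
state      outcome      probability  ci_low     ci_high
NR-H       in-polysome  0.0614522    0.0282539  0.1285
decoding   in-polysome  0.904724     0.863453   0.934468
pre+       in-polysome  0.873432     0.825306   0.909749
...
```

Elongating states (decoding, pre+, …) sit in polysomes with probability
≈ 0.9 while the hibernating states (NR-H, R-H) are essentially absent
(≈ 0.06), mirroring the biology the generator plants; the corresponding
fold increases over random association (`run/fold_increase.tsv`) are
≈ 0.07 for hibernating states against an in-polysome abundance baseline.
`run/contrasts.tsv` lists Hochberg-adjusted Wald p-values for all state
pairs. The same stages are available piecewise (`polyneigh simulate`,
`neighbors`, `histogram`) and as library functions
(`polyneigh.find_neighbors`, `build_direction_masks`, `confirm_links`,
`fit_association_model`, …).

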