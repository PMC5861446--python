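# smstoich

Single-molecule colocalization stoichiometry: how many protein molecules
are bound to each RNA?

`smstoich` implements the analysis chain for two-colour single-molecule
TIRF experiments in which surface-captured Cy5-labelled RNA (red channel)
is probed for binding by an mEGFP-tagged protein such as the splicing
activator SRSF1 (green channel).  Each colocalized green spot is bleached
to completion and the number of irreversible intensity drops — one per
fluorophore — reports the number of labelled molecules in the complex.
Because only a fraction `p` of the protein pool is tagged and a fraction
`d` of binding events are protein dimers, the observed step counts are a
distorted readout of the true stoichiometry; the package provides the
forward model and its inverse.

The toolkit covers, with synthetic ground-truth data generation for every
stage:

- **simulation** of two-channel movie stacks with Gaussian-PSF emitters,
  stepwise bleaching, reversible dark states, camera noise and a chromatic
  inter-channel offset (`smstoich.simulate`);
- **spot detection** by square-scan criteria (threshold over field mean,
  single-peak test, per-axis Gaussian conformity) on maximum-intensity
  projections, plus aperture-photometry trace extraction
  (`smstoich.detect`);
- **chromatic registration and colocalization** with an affine map fitted
  to fiducials, greedy nearest-neighbour pairing, and per-image random
  coincidence estimates (reported, not subtracted)
  (`smstoich.register`);
- **photobleaching step counting** by recursive Bayesian changepoint
  segmentation with conjugate-prior model comparison, and per-spot
  classification into 1–5, ">5" or "x" with blink-dip merging
  (`smstoich.steps`);
- **stoichiometry inference**: step histograms with binomial error bars,
  the labeling/dimerization model, the two-step/one-step ratio statistic,
  truncated-geometric fits of nonspecific binding, and a mixture model
  over true bound-molecule counts (`smstoich.stoichiometry`);
- a **pipeline and CLI** tying the stages into one seeded, reproducible
  run (`smstoich.pipeline`, `smstoich` command).

## The core model

A complex with `k` bound molecules shows `j` bleaching steps with
probability given by the k-fold convolution of the per-event labelled
count,

    q0 = (1−d)(1−p) + d(1−p)²,  q1 = (1−d)p + 2dp(1−p),  q2 = dp²,

conditioned on `j ≥ 1` (unlabelled complexes are invisible).  The dimer
fraction is inferred from protein-only control spots, of which a fraction

    f2 = d·p / (1 + d(1−p))

bleach in two steps, inverting to `d = f2 / (p − f2(1−p))`.

## Worked example

```python
>>> from smstoich import (LabelingModel, expected_step_distribution,
...                       infer_dimer_fraction)
>>> d = infer_dimer_fraction(f2_observed=0.12, p_label=0.58)
>>> round(d, 4)
0.2266
>>> dist = expected_step_distribution(k=2, p_label=0.58, d=d)
>>> [round(float(v), 3) for v in dist.conditional[1:5]]
[0.47, 0.425, 0.098, 0.007]
>>> round(dist.two_step_ratio(), 1)
90.2
```

Reading: with 58% of the protein labelled and 12% of visible protein-only
control spots bleaching in two steps, the true dimer fraction is ≈ 22.7%.
If every RNA carried two bound molecules, 47.0% of visible complexes
would bleach in one step, 42.5% in two, 9.8% in three and 0.7% in four —
so the number bleaching in two steps would be ≈ 90% of the number
bleaching in one.  Measured ratios well below 90% therefore indicate that
a substantial fraction of complexes hold a single molecule.

A full simulated experiment:

```python
from smstoich.pipeline import RunConfig, run_pipeline
from smstoich.simulate import ComplexPopulationSpec, SimulationConfig

config = RunConfig(
    seed=42, n_experiments=3, fields_per_experiment=5,
    simulation=SimulationConfig(image_size=(256, 256)),
    population=ComplexPopulationSpec(
        n_complexes=60, stoichiometry_weights={1: 0.6, 2: 0.4},
        p_label=0.58, dimer_fraction=0.227))
report = run_pipeline(config, output_dir="run_out")
```

The report carries per-experiment colocalized fractions with their SEM,
the pooled step histogram with binomial error bars, the chance
coincidence estimate, and the fitted mixture weights over true
stoichiometries.  The same run is available from the shell as
`smstoich run --config config.yaml --seed 42 --out run_out`, and each
stage (`simulate`, `detect`, `register`, `coloc`, `steps`, `stoich`) can
be invoked separately on intermediate CSV/TIFF files.

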