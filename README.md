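# embryoquant

Quantification of asymmetric nuclear protein localisation and
cell-cycle timing in time-lapse movies of the two-cell *C. elegans*
embryo — for researchers measuring how replication factors (SLD-2,
SLD-3 and similar CDK substrates) partition between the AB and P1
blastomeres, and how that relates to the two cells' asynchronous
divisions.

## What it computes

Given a 5D movie (time × z × channel × y × x) with a fluorescence and a
DIC channel, the pipeline:

- picks the best-focused z-slice per frame and channel (variance of the
  3×3 Laplacian);
- maps the embryo from the DIC channel via a smoothed local
  standard-deviation map and Otsu's threshold, then splits it into the
  two cells by a distance-transform watershed — falling back to the
  minor axis of a moment-fitted ellipse when the outline has no concave
  features — and names the larger cell AB, the smaller P1;
- detects at most one nucleus per cell from the maximum-intensity
  z-projection with a difference-of-Gaussians filter and Kapur's
  maximum-entropy threshold;
- measures background-corrected nuclear and cytoplasmic mean
  intensities over time, the per-embryo ratio

  **R = ⟨I_nuc(P1) − bg⟩ / ⟨I_nuc(AB) − bg⟩**

  averaged over pre-NEB frames, and reference normalizations (to the AB
  cytoplasm or to a named cell such as ABa);
- detects nuclear-envelope breakdown (NEB) as the first sustained
  disappearance of a nucleus and converts it to cell-cycle lengths,
  (NEB − fusion) × Δt, and the AB→P1 NEB delay;
- compares cohorts with an exact Mann–Whitney–Wilcoxon test (full
  enumeration for n₁+n₂ ≤ 12), paired t-tests, and t-based 95% CIs.

Because the raw recordings this kind of analysis runs on are rarely
shared, the package includes a seeded synthetic-movie generator
(`embryoquant.simulate`) that renders two-cell embryos with ground-truth
masks, intensities, asymmetry ratio and NEB frames, so every stage is
testable end to end. See `docs/methods.md` for the model, parameter
defaults and their rationale.

## Worked example

Simulate a movie with a true P1/AB ratio of 0.6 and quantify it:

```sh
embryoquant simulate --preset asym06 --seed 3 --out asym06.ome.tif
embryoquant quantify asym06.ome.tif --out results
```

The `quantify` command prints the run manifest:

```json
{
  "config_hash": "3a515cd12da5",
  "frame_interval_s": 8.0,
  "neb_frames": {
    "AB": 22,
    "P1": 26
  },
  "ratio_p1_over_ab": 0.5998496024733111,
  ...
}
```

Reading: the AB nucleus disappears at frame 22 and the P1 nucleus at
frame 26 (exactly the frames the simulation used), i.e. at 8 s/frame an
AB cycle of 176 s from movie start and an AB→P1 NEB delay of 32 s; the
measured nuclear P1/AB ratio is 0.600 against a ground truth of 0.6 —
the P1 nucleus holds ~60% of the AB nucleus' background-corrected
signal. `results/` also receives tidy per-frame CSV traces (nuclear,
cytoplasmic and background intensity per cell, with the split method
per frame), per-frame label masks as TIFF, and a JSON manifest that
fully reproduces the run.

Cycle metrics and statistics are available on their own:

```sh
embryoquant timing --fusion-frame 0 --ab-neb 100 --p1-neb 115 --interval 8
# -> {"ab_cycle_s": 800.0, "p1_cycle_s": 920.0, "ab_p1_delay_s": 120.0}
embryoquant stats groups.csv --test mann-whitney   # CSV: group,value
```

The same functionality is available as a library:

```python
from embryoquant import PipelineConfig, generate_two_cell_movie, preset
from embryoquant.pipeline import run_quantification

stack, truth = generate_two_cell_movie(preset("asym06", seed=3))
result = run_quantification(stack, PipelineConfig())
print(result.ratio, result.neb_frames, truth.true_ratio)
```

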