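# cellsizer

Quantification of cell-size homeostasis from single-cell growth data.

`cellsizer` implements the full analysis chain used to classify how growing,
dividing cells control their size:

- **`cellsizer.simulate`** — a stochastic simulator of exponentially growing,
  dividing lineages. Supports a linear-response parameterization (growth rate
  and cycle duration respond linearly to log birth volume, strengths `gamma`
  and `theta`) and the classic archetypes (sizer / adder / timer /
  mechanistic adder), G1 + S-G2 phase structure with a minimum G1 duration,
  division asymmetry, and rendering of sampled volume trajectories with
  measurement noise, segmentation spikes, a mitotic volume overshoot and a
  cell-cycle reporter channel.
- **`cellsizer.trajectory`** — processing of volume time series: Hampel-style
  despiking (11-frame window), 7-frame sliding-mean smoothing, per-frame
  instantaneous growth speed from a Theil–Sen fit on 9-frame windows,
  cell-cycle event annotation (birth = cytokinesis onset + 40 min, mitotic
  entry = next onset − 60 min, outside the mitotic overshoot), G1/S detection
  from the reporter channel, and pooled growth-speed-vs-volume binning.
- **`cellsizer.homeostasis`** — the statistical core: mean ± 3 s.d. and
  median ± 1.5·IQR filters, equal-width median/mean binning with
  dataset-size-dependent `(binn, minn)`, count-weighted least-squares fits on
  the bins, and the estimation of the homeostatic exponent `lambda`
  (−slope of ln(V_mitosis/V_birth) vs ln V_birth; 1 = sizer, 0.5 = adder,
  0 = timer), the timing-modulation strength `theta`, the growth-rate
  modulation strength `gamma` (direct, or derived via
  `gamma = lambda/<G> − theta`), sister-cell asymmetry, the mechanistic-adder
  test (ΔV_SG2 vs ΔV_G1, slope −1), steadiness QC and the normalized
  theta–gamma plane.
- **`cellsizer.fxm`** — cell volume from fluorescence-exclusion images
  (calibrate from roof/pillar masks, integrate the intensity deficit over the
  cell mask) and from microchannel cell lengths (length × cross-section),
  plus a synthetic chamber renderer used as the test oracle.
- **`cellsizer.io` / `cellsizer.cli`** — CSV/TSV/TOML plumbing and a
  `cellsizer` command with `simulate`, `fxm`, `process`, `estimate` and
  `report` subcommands.

Conventions: volumes in µm³, times in hours (trajectory sampling in
minutes), all logarithms natural, so replicative growth
`G = ln(V_mitosis/V_birth) = alpha * tau` exactly under exponential growth.

## Command line

```sh
# simulate an adder population and estimate lambda/theta/gamma
cellsizer simulate --mode adder --mode-sd 195 --n-founders 8 \
    --generations 11 --seed 1 --out lineages.csv
cellsizer estimate --lineages lineages.csv --organism-class animal \
    --filter 3sd --out summary.tsv

# process volume trajectories (despike -> smooth -> speed/events)
cellsizer process --trajectories traj.csv --out events.csv

# volumes from a fluorescence-exclusion image
cellsizer fxm --image img.tif --roof-mask roof.tif --pillar-mask pillar.tif \
    --cell-mask cell0.tif --h-max 20 --out volumes.csv

# full pipeline from a TOML config (seed mandatory)
cellsizer report --config pipeline.toml --out results/
```

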