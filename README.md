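# polagg

Quantification of polar protein aggregates and their fitness effects in
aging *Escherichia coli* lineages tracked in a mother-machine microfluidic
device.

## The problem

At every division an *E. coli* cell passes on one *old pole* (conserved
across generations) and one *new pole* (built at the last fission). The
old-pole cell — the **mother** — retains misfolded-protein aggregates,
ages, and grows more slowly; the new-pole **daughter** is born largely
damage-free. `polagg` implements the single-cell analysis chain for this
system, for researchers working with tracked mother-machine data
(per-cycle length series plus a 1D fluorescence transect per cycle, as
produced downstream of segmentation/tracking tools such as DeLTA):

- **Growth**: per-cycle elongation rates r from OLS on
  ln L(t) = ln L₀ + r·t, division intervals, and the morphological
  asymmetry A = L₀(mother)/L₀(daughter) of cells born at the same
  fission.
- **Aggregates**: robust outlier detection of the polar fluorescence
  focus on each old-pole→new-pole transect — diameter d, distance to the
  old pole, mean/peak intensity, relative aggregate length ρ = d/L — and
  an exact partition of cell fluorescence into aggregated vs dispersed
  components.
- **Statistics**: the linear aggregate-growth fit d(t) = k·t + d₀,
  AIC-ranked additive-model comparisons (role, aggregate presence, time
  smooths, tensor interactions; Gaussian or negative-binomial
  identity-link families), Kolmogorov–Smirnov and Welch tests, and
  n ≥ 10 binned summaries.
- **Synthetic data**: a seeded generator of full lineage tables and
  transects with the same generative structure (asymmetric pole
  inheritance, exponential growth, linear diameter growth at 0.01 µm/h
  from 0.4 µm, off-center fission), so every stage is testable against
  ground truth without any raw imagery.

See `docs/methods.md` for the model, parameter defaults, and numerical
choices.

## Worked example

```python
import numpy as np
import polagg as pg

# 40 wells, 24 h, focus present from the start of every mother lineage
cfg = pg.SimConfig(seed=1, n_wells=40, duration=24.0, nucleate_at_start=True)
table, log = pg.simulate_lineages(cfg)
cells = pg.filter_complete_cycles(table)

params = pg.DetectionParams()
rates, calls = {}, []
for rec in cells:
    rates[rec.cycle_id] = pg.fit_elongation_rate(rec.length_series)
    if rec.transect is not None:
        calls.append((rec, pg.detect_aggregate(rec.transect, params)))

mothers = [(r, c) for r, c in calls if r.role == pg.Role.MOTHER]
bearing = [(r, c) for r, c in mothers if c.present]
pts = [(r.birth_time / 60.0, c.diameter) for r, c in bearing]
fit = pg.fit_diameter_growth(pts, time_cutoff=40.0)
pairs = pg.pair_divisions(cells)
```

Output of the full script (`rates`, `calls`, `fit`, `pairs` printed as in
the snippet):

```
complete cycles: 2243  (removed: {'incomplete': 75, 'pre_imaging': 0})
mother cycles with a detected focus: 1205/1205 (100.0%)
diameter growth: 0.0100 um/h, intercept 0.402 um (R2=0.60)
mean focus distance to old pole: 0.219 um
division pairs: 1033, mean asymmetry A = 1.013
```

Reading: incomplete cycles (truncated by the end of imaging) are
excluded before analysis; every mother transect carries a detectable
focus in this early-nucleation configuration; pooled detected diameters
regress to the generative growth law (0.01 µm/h from 0.4 µm — the
residual scatter is the per-generation jitter plus pixel quantization);
foci sit ~0.22 µm from the old pole; and divisions are measurably
off-center (A > 1) because the aggregate displaces the septum.

## Command line

A thin CLI mirrors the library stages:

```bash
polagg simulate --seed 1 --n-wells 50 --duration 40 --outdir run/
polagg quantify-growth --cycles run/cycles.csv --series run/series.csv --out run/growth.csv
polagg detect --transects run/transects.csv --cycles run/cycles.csv \
              --series run/series.csv --out run/calls.csv
polagg run --seed 1 --outdir run/        # end to end, incl. model comparison
polagg report --outdir run/
```

All tables are plain CSV with a comment header recording the package
version, seed, and config hash; `truth.csv` carries the generator's
ground truth for every simulated cycle.

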