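# helixsub

Desk-scale helical cryo-EM reconstruction with neighbor signal subtraction
and subparticle single-particle analysis, for flexible helical polymers —
plus the fluorescence-puncta and spot-assay statistics that accompany such
a study.

## The problem

A helical polymer of D1-symmetric protomers (the motivating system is a
vacuole-associated TORC1 polymer with twist ≈ 46.9–47.7° and rise ≈
25.2–28.2 Å per unit, pitch = rise·360/twist ≈ 192–215 Å) can behave like a
spring with varying pitch.  Conventional helical reconstruction then fails
quietly: imposing one (twist, rise) on flexible filaments averages
misplaced density, and the symmetry search shows a characteristically broad
basin in its mean-squared-error surface instead of a sharp minimum.  The
remedy is to subtract the modeled density of every protomer except one from
each filament segment, recenter and crop the isolated protomer (with a
defocus correction for its beam-axis offset), and refine the subparticles
as ordinary single particles with gold-standard FSC (threshold 0.143) and
same-helix half-set splitting.

`helixsub` implements that entire route on synthetic data with known ground
truth: a Gaussian-blob protomer generator and variable-pitch filament
simulator (`scene`), CTF/dose/noise models and helical-geometry defocus
correction (`optics`), projection, direct Fourier reconstruction,
symmetrization and the twist/rise grid search (`helix`), masking,
subtraction and subparticle extraction (`subtract`), half-set SPA
refinement and FSC estimation (`spa`), colocalization/kinetics/EC50
statistics (`fluor`), and MRC/STAR I/O with a CLI and pipeline driver
(`io`, `cli`, `pipeline`).

## Worked example: the symmetry search degeneracy diagnostic

```python
import numpy as np
from helixsub.scene import (default_protomer, sample_pitch_profile,
                            assemble_filament, render_volume)
from helixsub.helix import symmetry_search
from helixsub.core import substream

protomer = default_protomer()
grids = dict(start=(47.3, 26.7), z_span_angstrom=170.0,
             r_max_px=(45.0 + protomer.support_radius + 6.0) / 4.5)
twist_grid = np.arange(45.0, 50.0 + 1e-9, 0.1)
rise_grid = np.arange(24.0, 30.0 + 1e-9, 0.05)

# rigid filament: constant twist 47.2 deg, rise 26.75 A
profile = sample_pitch_profile((47.2, 47.2), (26.75, 26.75), "constant",
                               10, substream(0, "demo"))
volume = render_volume(assemble_filament(protomer, profile, 45.0), 96, 4.5)
surface = symmetry_search(volume, twist_grid, rise_grid, **grids)
print(surface.argmin, surface.basin_size())

# flexible filament: random-walk pitch inside the observed ranges
profile = sample_pitch_profile((46.9, 47.7), (25.2, 28.2), "random_walk",
                               10, substream(2, "walk"))
volume = render_volume(assemble_filament(protomer, profile, 45.0), 96, 4.5)
surface = symmetry_search(volume, twist_grid, rise_grid, **grids)
print(surface.argmin, surface.basin_size())
```

prints (argmin as (twist°, rise Å), then the number of grid points scoring
within 1.1× of the minimum):

```
(47.20000000000003, 26.80000000000004) 14
(47.10000000000003, 26.350000000000033) 61
```

The rigid filament is recovered at the generator parameters to within one
grid step with a 3-point basin; the flexible filament's basin is several
times broader in both axes — the diagnostic that distinguishes a flexible
polymer from a poorly sampled rigid one.

## End-to-end pipeline

```sh
helixsub pipeline --seed 11 --out-dir runs/demo
```

simulates a segment dataset (24 filaments × 16 overlapping boxes, SNR 0.1,
CTF with 1.0–2.5 µm defocus), runs helical refinement, the symmetry search,
signal subtraction, subparticle recentering with corrected defocus,
filament-aware half-set SPA, and writes maps (MRC), particle tables (STAR)
and a `summary.json` containing both routes' map-versus-ground-truth
resolutions and the symmetry-search argmin.  On the default flexible
dataset the helical route degrades by over two Fourier shells relative to a
rigid-pitch control at otherwise identical conditions (9.95 Å vs 7.63 Å at
seed 11), while the symmetry search still lands inside the generating
parameter ranges — see `docs/methods.md` for what these toy-scale numbers
do and do not mean.

Individual stages are available as subcommands (`simulate`, `extract`,
`refine-helical`, `symsearch`, `subtract`, `refine-spa`, `fsc`,
`quant-puncta`, `coloc`, `ec50`), all honoring `--seed`.

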