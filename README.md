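# ermech

Mechanics and dynamics of endoplasmic-reticulum (ER) tubules from
fluorescence microscopy.

The peripheral ER is a network of membrane nanotubes (~44 nm outer radius)
joined at three-way junctions. This package implements the image-analysis
pipeline that turns fluorescence data into the tubules' mechanical
parameters, for cell biophysicists who have tubule images, STORM
localization tables, or tracked tubule motion:

* **trace** tubule centerlines with an open active contour (ridge-filter
  initialisation, semi-implicit snake, free ends) and detect junctions;
* **persistence length**: per fibre, measure contour length `L_c` and
  end-to-end distance `R`, then fit the worm-like-chain relation
  `⟨R²⟩ = 2L_p(L_c − L_p[1 − e^{−L_c/L_p}])` for `L_p`;
* **membrane rigidity**: convert via the thin-hollow-cylinder relation
  `L_p = 2κ_mem πR / k_BT` (and `κ_pol = L_p k_BT` for the filament view),
  plus honeycomb-foam scaling of the network moduli
  `E_in/E = (2r/L)³`;
* **tube radius**: fit perpendicular cross-sections with the projected
  hollow-cylinder model (annular shell ⊗ Gaussian PSF), from super-resolved
  images or localization tables;
* **dynamics**: time-averaged MSD of transverse tubule motion, power-law
  exponents `⟨Δr⊥²(τ)⟩ ∼ τ^α`, splitting of sub-diffusive (tensioned,
  equilibrium) and super-diffusive (motor-driven) populations, and tension
  stress from the fluctuation amplitude
  `⟨Δr⊥²(τ)⟩ = (k_BT/σ)^{3/4} L_p^{1/4} τ^{1/2} / (2η^{1/2})`;
* **synthetic data** for all of the above — WLC chains and branched
  networks with prescribed `L_p`, PSF-convolved noisy tube renderings,
  localization clouds on tube surfaces, and exact-OU Langevin simulation of
  tensioned-filament transverse fluctuations — so every stage is testable
  with known ground truth.

## Worked example

Convert measured tubule geometry to membrane bending rigidity:

```sh
$ ermech mechanics --lp 3.03 --radius 44.1
kappa_mem = 10.9 kT = 4.5e-20 J; kappa_pol = 1.25e-26 J m
```

A persistence length of 3.03 µm on a hollow tube of 44.1 nm outer radius
corresponds to a membrane bending modulus of 10.9 k_BT (≈ 45 zJ) — a very
soft membrane, at the low end of the lipid-bilayer range. Excluding
branch-point regions (`--lp 4.71`) gives 17.0 kT.

The same from Python, end to end on synthetic data:

```python
import numpy as np
from ermech import synthetic, persistence, mechanics

# 1000 worm-like chains with L_p = 3.03 um, L_c between 0.5x and 3x L_p
geoms = []
for j, Lc in enumerate(np.geomspace(1.5, 9.1, 20)):
    p = synthetic.WLCParams(3.03, Lc, Lc / 60, "3D", seed=j)
    v = synthetic.generate_wlc_ensemble(p, 50)
    Lc_d = p.n_segments * p.segment_length
    for r in np.linalg.norm(v[:, -1] - v[:, 0], axis=1):
        geoms.append(persistence.ChainGeometry(Lc_d, min(r, Lc_d)))

fit = persistence.fit_persistence_length(geoms, method="ensemble_binned")
kT, joules = mechanics.kappa_mem_from_lp(fit.L_p, R_nm=44.1)
print(f"L_p = {fit.L_p:.2f} +/- {fit.stderr:.2f} um -> kappa_mem = {kT:.1f} kT")
```

prints

```
L_p = 3.08 +/- 0.04 um -> kappa_mem = 11.1 kT
```

i.e. the fit recovers the generator's persistence length to under 2%
(one realization at 1000 chains; the sampling spread at this size is
~2–3%), and the rigidity conversion follows.

## Analysis scripts

`analysis/01_simulate_inputs.py` … `05_mechanics_summary.py` run the whole
study on synthetic data: generate inputs, trace and fit persistence lengths,
measure radii (30/44.1/60 nm ladder, recovered to ~1%), classify track
populations (the super-diffusive ensemble shows the short-lag ≈ 0.6 /
long-lag ≈ 1.5 two-regime structure) and produce the mechanical summary.
Each writes its tables under `results/`.

## Command line

`ermech` exposes subcommands `simulate`, `trace`, `persistence`, `radius`,
`dynamics`, `mechanics`, `report`. File dialects: localization CSV with
`"x [nm]","y [nm]","uncertainty [nm]"` headers (tolerantly matched); chain
CSV `chain_id,vertex_index,x_um,y_um`; track CSV `t_s,x_um,y_um,track_id`
(for transverse tracks `y_um` carries the signed perpendicular coordinate);
16-bit TIFF images; JSON reports.

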