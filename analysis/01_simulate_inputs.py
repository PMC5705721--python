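#!/usr/bin/env python
"""Generate the synthetic study inputs for the downstream analyses.

Produces, under results/inputs/:
  * WLC chain ensembles at four persistence lengths (0.5, 3.03, 4.71,
    10 um) with contour lengths 0.5-3x L_p — the regime where most of the
    bending information sits in the longest modes;
  * a branched (honeycomb-topology) network with 1-5 um junction spacing;
  * a rendered diffraction-limited sinusoidal tube (SNR ~ 6) and a
    STORM-like straight tube (10 nm pixels) with localization tables;
  * transverse-fluctuation track populations (passive tensioned +
    actively driven).
"""

import json
from dataclasses import replace
from pathlib import Path

import numpy as np

from ermech import fileio, synthetic
from ermech.chains import FiberChain, resample_polyline

OUT = Path(__file__).resolve().parent.parent / "results" / "inputs"
OUT.mkdir(parents=True, exist_ok=True)
SEED = 20170


def simulate_chain_ensembles():
    for L_p in (0.5, 3.03, 4.71, 10.0):
        chains = []
        for j, Lc in enumerate(np.geomspace(0.5 * L_p, 3.0 * L_p, 20)):
            p = synthetic.WLCParams(L_p, Lc, Lc / 60, "3D", seed=SEED + j)
            verts = synthetic.generate_wlc_ensemble(p, 50)
            for i, v in enumerate(verts):
                chains.append(FiberChain(v[:, :2], p.segment_length,
                                         chain_id=f"lp{L_p}-b{j}-c{i}"))
        fileio.write_chains(chains, OUT / f"chains_lp{L_p}.csv")
        # full 3D geometry summarised separately for the fit scripts
        rows = []
        for j, Lc in enumerate(np.geomspace(0.5 * L_p, 3.0 * L_p, 20)):
            p = synthetic.WLCParams(L_p, Lc, Lc / 60, "3D", seed=SEED + j)
            v = synthetic.generate_wlc_ensemble(p, 50)
            Lc_d = p.n_segments * p.segment_length
            R = np.minimum(np.linalg.norm(v[:, -1] - v[:, 0], axis=1), Lc_d)
            rows.extend((Lc_d, r) for r in R)
        np.savetxt(OUT / f"geometry_lp{L_p}.tsv", rows, header="L_c_um\tR_um",
                   comments="", delimiter="\t")
        print(f"  L_p={L_p} um: 1000 chains")


def simulate_network():
    net = synthetic.generate_branched_network(4, (1.0, 5.0), 3.03, seed=SEED)
    fileio.write_chains(net.chains, OUT / "network_chains.csv")
    fileio.write_json({"junctions": net.junctions}, OUT / "network_junctions.json")
    print(f"  network: {net.n_chains} edges, {len(net.junctions)} junctions")


def simulate_images():
    x = np.linspace(0.0, 16.0, 321)
    sinus = FiberChain(resample_polyline(
        np.stack([x, np.sin(2 * np.pi * x / 8.0)], 1), 0.05), 0.05)
    params = synthetic.RenderParams(pixel_size=0.1, psf_sigma=0.125,
                                    tube_outer_radius=44.1, wall_thickness=0.0,
                                    photon_peak=50, background=10,
                                    noise_model="poisson", seed=SEED)
    img, gt = synthetic.render_image(sinus, params)
    fileio.write_image(img, OUT / "sinusoid_tube.tif")
    fileio.write_json(gt, OUT / "sinusoid_tube_gt.json")

    xs = np.linspace(0.0, 4.0, 81)
    straight = FiberChain(np.stack([xs, np.zeros_like(xs)], 1), 0.05)
    for R in (30.0, 44.1, 60.0):
        sp = synthetic.RenderParams(pixel_size=0.01, psf_sigma=0.02,
                                    tube_outer_radius=R, wall_thickness=0.0,
                                    photon_peak=1000, background=5,
                                    noise_model="poisson", seed=SEED + int(R))
        img, gt = synthetic.render_image(straight, sp)
        fileio.write_image(img, OUT / f"storm_tube_R{R}.tif")
        fileio.write_json(gt, OUT / f"storm_tube_R{R}_gt.json")
        locs = synthetic.generate_localizations(straight, R, 10.0, 3000.0,
                                                seed=SEED + int(R))
        fileio.write_localizations(locs, OUT / f"locs_R{R}.csv")
    fileio.write_chains([straight], OUT / "straight_chain.csv")
    fileio.write_chains([sinus], OUT / "sinusoid_chain.csv")
    print("  images: 1 diffraction-limited sinusoid, 3 STORM-like tubes + localizations")


def simulate_tracks():
    pop = synthetic.FluctuationParams(filament_length=30.0, dt=0.02,
                                      duration=12.0, n_modes=50,
                                      tension_stress=58.3)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tracks, labels = synthetic.generate_track_population(
            20, 20, pop, seed=SEED, active_drift=0.2)
    fileio.write_transverse_tracks(tracks, OUT / "tracks_population.csv")
    fileio.write_json({t.track_id: l for t, l in zip(tracks, labels)},
                      OUT / "tracks_population_labels.json")
    print(f"  tracks: {labels.count('passive')} passive + {labels.count('active')} active")


if __name__ == "__main__":
    print("simulating study inputs ->", OUT)
    simulate_chain_ensembles()
    simulate_network()
    simulate_images()
    simulate_tracks()
    (OUT / "seed.json").write_text(json.dumps({"seed": SEED}) + "\n")
    print("done")
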