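#!/usr/bin/env python
"""Simulate the synthetic specimen: labelled scene, TCSPC cube, Raman spectra.

Generates the default two-tissue scene (branched arbuscule-like fungal
structure, conducting-tissue vesicle, plant-tissue disc on dim background),
its seeded TCSPC photon cube, and arbuscule + off-structure reference Raman
spectra at the six excitation wavelengths.  Everything is written under
results/analysis/ for the downstream steps.
"""

import sys
from pathlib import Path

from paleoflim import io as pio
from paleoflim import scenes as sc
from paleoflim.flim import default_irf

OUT = Path("results/analysis")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
WAVELENGTHS = (325.0, 457.0, 488.0, 514.0, 532.0, 633.0)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = sc.default_scene(seed=SEED)
    label = sc.generate_structure_masks(spec)
    cube, truth = sc.generate_flim_cube(label, irf=default_irf(), seed=SEED)
    pio.save_cube(OUT / "cube.tif", cube, seed=SEED)
    pio.save_mask(OUT / "labels.tif", label, spec.pixel_size_um, sc.CLASS_IDS)

    for wl in WAVELENGTHS:
        arb = sc.generate_raman_spectrum(sc.arbuscule_material(), wl, noise="none")
        ref = sc.generate_raman_spectrum(sc.background_material(), wl, noise="none")
        pio.save_spectrum(OUT / f"arbuscule_{int(wl)}nm.csv", arb)
        pio.save_spectrum(OUT / f"background_{int(wl)}nm.csv", ref)

    n_px = {name: int((label == cid).sum()) for name, cid in sc.CLASS_IDS.items()}
    print(f"scene {spec.width_px}x{spec.height_px} px at {spec.pixel_size_um} um/px, "
          f"seed {SEED}")
    print(f"pixels per class: {n_px}")
    print(f"cube: {cube.counts.shape[0]} bins x {cube.counts.shape[1]}x"
          f"{cube.counts.shape[2]} px, {int(cube.counts.sum()):,} photons total")
    print(f"spectra written for {len(WAVELENGTHS)} excitations under {OUT}/")


if __name__ == "__main__":
    main()
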