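# paleoflim

Fluorescence-lifetime (FLIM) decay decomposition, multi-wavelength Raman
carbon characterization, and calibrated morphometry for permineralized
plant–fungal fossils — with a seeded synthetic-specimen generator that makes
every stage of the analysis testable against known ground truth.

## The problem

Fossil fungi preserved inside early land plants in silica (chert) are hard
to distinguish from their host tissue: both are reduced to carbonaceous
residues with similar appearance under brightfield and confocal microscopy.
Two physical signals still separate them:

* **Fluorescence lifetime.** Under pulsed excitation, the photon-arrival
  histogram at each pixel follows a triple-exponential decay.  A very short
  (picosecond-range, ~0.3 ns) component is characteristic of fungal
  structures (arbuscules, hyphae) and of the vesicles of the plant's
  water-conducting cells; a long (>6 ns) component comes from fungus plus
  surrounding plant tissue; an intermediate low-ns component is dim
  background.
* **Raman spectra of the residual carbon.**  Disordered sp² carbon shows D
  (~1358 cm⁻¹) and G (~1608 cm⁻¹) bands plus carbon-chain subbands near
  1266 and 1450 cm⁻¹.  Band positions Pos(D)/Pos(G), FWHM(G), the
  dispersion Disp = dPos/dE over excitation photon energy (cm⁻¹/eV), and
  the height ratio I(D)/I(G) together characterize the carbon: the mean sp²
  cluster size follows Lₐ(Å) = √(I(D)/I(G) / C′(E)) in the nanocrystalline
  regime (C′(2.41 eV) = 0.0055 Å⁻²) or Lₐ(Å) = C(λ)/(I(D)/I(G)) in the
  graphitic regime (C(514 nm) = 44 Å).

`paleoflim` implements this whole chain — TCSPC cube simulation and
Poisson-MLE reconvolution fitting, FastFLIM average-lifetime maps,
short-lifetime segmentation, Si-line calibration, off-ROI baseline
correction, simultaneous Lorentzian band fitting, dispersion regression, Lₐ
estimation, and distance-transform morphometry of spores, walls and hyphae
— as a library (`src/paleoflim/`), a set of numbered analysis drivers
(`analysis/`), and a `paleoflim` CLI.

## Worked example

```bash
python analysis/01_simulate_scene.py 1
python analysis/02_flim_decomposition.py
python analysis/03_raman_carbon.py
python analysis/04_morphometry.py
```

prints (seed 1):

```
pooled 3-component fits (lifetimes in ns):
       tissue  tau1_ns  tau2_ns  tau3_ns  tau_avg_intensity_ns
       fungal 0.300714 2.068946 6.480369              1.484692
plant_vesicle 0.300203 2.055996 6.556424              1.877763
  plant_other 0.047225 1.693756 6.485066              6.371226

short-lifetime mask (tau<=1 ns, fraction>=0.5) IoU vs truth: 1.000
514 nm anchors: Pos(D)=1358.0  Pos(G)=1608.0  FWHM(G)=56.0 cm-1
dispersions: Disp(D)=4.05  Disp(G)=8.27 cm-1/eV
I(D)/I(G)=0.550 -> La=1.00 nm (nanocrystalline_FR)
spore equivalent diameter: 74.01 um (fixture: 74 um)
spore wall thickness: 3.098 +- 0.041 um (fixture: 3.1 um)
```

Reading: the pooled fungal and vesicle decays recover the generator's
0.3 ns picosecond component exactly, while other plant tissue is dominated
by the 6.5 ns component (intensity-weighted average 6.37 ns > 6 ns), so
thresholding on the short component segments fungal + vesicle structures
perfectly (IoU 1.0).  The Raman pipeline recovers the generator's band
anchors and dispersions; the broad G band (56 cm⁻¹) selects the
nanocrystalline regime, giving sp² clusters of ~1 nm — heavily altered
organic matter.  The morphometry recovers the rendered diagnosis dimensions
to well under a percent.

`python analysis/05_full_report.py 1` (or `paleoflim report --seed 1 --out
results/run`) runs all stages into a self-contained run directory with a
config snapshot.

## Layout

```
src/paleoflim/      flim.py (TCSPC fitting, maps, masks)
                    raman.py (calibration, baseline, bands, dispersion, La)
                    scenes.py (synthetic specimens + ground truth)
                    morphometry.py, pipeline.py, cli.py, io.py
analysis/           numbered drivers reproducing the full analysis
tests/              unit, property and end-to-end recovery tests
docs/methods.md     model assumptions, defaults, numerical choices
```
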