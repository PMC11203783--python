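# beechoice

Tools for analysing how wild bees choose between artificial flowers that
differ in a single floral cue — colour hue, achromatic contrast, corolla
size, scent-bouquet complexity, or floral depth. The package is aimed at
pollination ecologists running two-choice assays with bee species such as
*Bombus terrestris*, *Osmia bicornis*, and *Lasioglossum villosulum*, and at
anyone who needs the bee-subjective colour description of their stimuli.

It covers four analysis stages plus a seeded synthetic-data generator, so the
whole pipeline runs end to end without any measured data:

1. **Colour-hexagon vision model** (`beechoice.hexagon`). A stimulus
   reflectance R(λ) viewed against an adapting background R_B(λ) under an
   illuminant I(λ) gives each photoreceptor class *i* ∈ {UV, blue, green} a
   von Kries-adapted quantum catch

       P_i = ∫ I(λ) R(λ) S_i(λ) dλ  /  ∫ I(λ) R_B(λ) S_i(λ) dλ,

   receptor excitation E_i = P_i / (P_i + 1), and a hexagon locus

       x = (√3/2)(E_G − E_U),   y = E_B − (E_U + E_G)/2.

   The background sits at the centre; distance from the centre is the
   stimulus's contrast against the background and the direction is its hue
   angle (0° vertical-up, clockwise by default). Receptor sensitivities are
   honeybee-peak (344/436/544 nm) visual-pigment nomogram templates, or your
   own measured curves from CSV. Illuminant: CIE D65, flat, or from file
   (`beechoice.spectral`).

2. **Two-choice preference statistics** (`beechoice.preference`). One
   binomial logistic GLM per trait: per-species intercept-only fits give the
   log-odds of choosing one variant, tested with a two-sided Wald z; global
   fits add species (and optionally block) as fixed factors. Because reports
   usually print coefficients but not counts, `recover_counts` inverts a
   printed (estimate, SE) pair back to the integer choice counts via the
   closed forms estimate = ln(a/b), SE = √(1/a + 1/b).

3. **GC-EAD activity scoring** (`beechoice.eag`). Binary antenna × compound
   response tables are summarised per species; a volatile is
   electrophysiologically active when at least 50% of tested antennae
   responded. Includes the 12-compound floral-volatile panel (3 simple
   mixtures of 4, balanced by substance class) and mixture dosing math.

4. **Consumption analysis** (`beechoice.preference`). Flower weighings at
   0/40 min/2 h become mg/h rates; flat vs deep flowers are compared with a
   Mann–Whitney U test (exact enumeration for combined n ≤ 12, tie-corrected
   normal approximation otherwise).

## Worked example

```python
from beechoice import (
    ChoiceDataset, ReceptorSet, contrast_report, fit_two_choice,
    gen_cardboard_spectra, recover_counts, standard_illuminant_d65,
)

# bee-subjective description of the synthetic cardboard palette
spectra = gen_cardboard_spectra()
bg = spectra["green_background"]
report = contrast_report(
    [spectra[k] for k in ("yellow", "light_yellow", "blue", "light_blue")],
    bg, standard_illuminant_d65(bg.grid), ReceptorSet.honeybee(bg.grid),
)
print(report.loci.round(3).to_string(index=False))
```

```
        name      x      y  center_distance  angle_deg  green_contrast
      yellow  0.125 -0.143            0.189    138.845           0.137
light_yellow  0.072 -0.074            0.103    135.881           0.079
        blue -0.165  0.182            0.246    317.910           0.190
  light_blue -0.069  0.088            0.112    321.740           0.080
```

Yellow and blue sit on nearly opposite sides of the hexagon (hue angles 139°
vs 318°), and each "light" variant keeps its parent's hue (Δ < 5°) at a
smaller centre distance — the light colours differ from the intense ones in
contrast against the green background, not in hue.

```python
# invert a printed coefficient row back to choice counts and refit
rec = recover_counts(0.937, 0.155)     # -> 148 of 206 chose yellow
ds = ChoiceDataset.from_counts(rec.successes, rec.failures)
coef = fit_two_choice(ds, "hue", species="species").intercept
print(f"estimate={coef.estimate:.3f} SE={coef.std_error:.3f} "
      f"z={coef.z_value:.3f} p={coef.p_value:.2e}")
```

```
estimate=0.937 SE=0.155 z=6.047 p=1.48e-09
```

A log-odds of 0.937 means yellow was chosen 148:58 over blue — a strong,
highly significant hue preference.

The command line mirrors the library:

```sh
beechoice run-all --simulate --seed 0 --outdir out/
beechoice hexagon --spectra out/data/spectra.csv --out loci.csv
beechoice prefs --choices out/data/choices.csv --out table1.csv
```

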