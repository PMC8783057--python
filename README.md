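# polfret

Simulation and kinetic analysis of single-molecule FRET traces of
DNA-polymerase fingers dynamics during DNA synthesis.

## The problem

In a TIRF smFRET assay, a doubly labelled Klenow fragment (KF) of DNA
polymerase I binds transiently to surface-immobilised primer-template DNA
while two camera channels record donor (DD) and acceptor (DA) emission at
40 ms per frame. The apparent FRET efficiency

    E* = DA / (DA + DD)

reports the conformation of the KF fingers subdomain: E* ≈ 0.4
fingers-open, E* ≈ 0.6 fingers-closed. Without nucleotides the KF–DNA
binary complex interconverts between the conformations
(k_close ≈ 1.4 s⁻¹, k_open ≈ 5.3 s⁻¹ on extensible DNA; k_open ≈ 29 s⁻¹
when the primer 3′-OH is absent). When nucleotides are added, bound KF
closes and polymerises the template; the first fingers-closed dwell is
the apparent polymerisation time, and its single-exponential rate for a
single dTTP addition is ≈ 3.4 s⁻¹.

No raw experimental movies accompany these numbers, so the package pairs
the full analysis pipeline with a generative simulator of the experiment
(Gillespie kinetics; label-stoichiometry mixture; photobleaching; camera
noise, backgrounds and frame integration; red-laser localisation window;
persistent-binder contaminants), giving every stage a known-answer input.
It is written for single-molecule biophysicists who want a tested,
reproducible reimplementation of this style of trace analysis, or a
test-bed for estimator behaviour at 25 Hz time resolution.

The pipeline stages, each an importable module under `src/polfret/`:

| stage | module | method |
|---|---|---|
| synthetic data | `simulate` | exact stochastic state paths → rendered DD/DA traces |
| trace extraction | `extraction`, `movies` | spot localisation + aperture photometry (movie mode) |
| event detection | `events` | adaptive median-window intensity thresholding, 0.5 s filter |
| segmentation | `hmm` | variational-Bayes Gaussian HMMs (K = 1–3), maximum-evidence selection, Viterbi dwells |
| kinetics | `kinetics` | censored exponential/geometric dwell MLEs, hypoexponential extension models, post-synchronised mean-E* decay, Arrhenius ΔE |
| ensemble views | `ensemble` | per-frame FRET classification, sorted heat-map, molecule grouping |
| orchestration | `pipeline`, `cli` | YAML-configured runs with manifests and seed fan-out |

## Worked example

Binary-complex fingers kinetics, recovered by the full pipeline
(simulate → detect → segment → dwell fits) from synthetic fields of view
generated at the rates above:

```sh
$ python analysis/02_binary_complex_rates.py --molecules 150 --duration 60
binary_extensible: k_close = 1.11 ± 0.04 /s, k_open = 4.69 ± 0.15 /s
binary_dideoxy: k_close = 0.19 ± 0.01 /s, k_open = 19.60 ± 1.25 /s
opening-rate fold change (dideoxy / 3'-OH): 4.2
implied ddG from 3'-OH contact: 0.85 kcal/mol
```

Reading this: the extensible-DNA closing and opening rates come back
near their generative values (1.4, 5.3 s⁻¹) minus the dead-time bias any
dwell census carries at 40 ms frames (dwells shorter than ~1–2 frames
merge their neighbours; see `docs/methods.md`). The dideoxy opening rate
(generative 29 s⁻¹, mean dwell 1.2 frames) is recovered as a lower
bound, ~0.6–0.7× — the frame-rate resolution limit, quantified and
asserted in the tests. At the generative rates the fold change is 5.5
and ΔE = k_B·T·ln(29/5.3) = 1.0 kcal/mol, a hydrogen-bond-scale
stabilisation of the closed state by the 3′-OH.

Single-nucleotide incorporation and its controls:

```sh
$ python analysis/05_single_nt_kinetics.py --molecules 150
dTTP incorporation (dwell fit): 3.40 ± 0.41 /s (n=73)
mean-E* decay fit: 5.22 ± 1.29 /s (E_inf 0.46)
mismatch: 10 begin-closed events (25% of matched)
no_dntp: 10 begin-closed events (25% of matched)
3'-OH opening-rate fold change 5.5 -> ddE 1.01 kcal/mol
```

The dwell fit recovers the generative 3.4 s⁻¹; the post-synchronised
mean-E* decay gives an independent, noisier estimate of the same exit
process and relaxes to E∞ ≈ 0.46, the binary-complex mixture level; the
mismatch/no-nucleotide controls produce far fewer begin-closed events.

Multi-nucleotide extensions (`analysis/04_polymerisation_kinetics.py`)
print first-closed-dwell means and nt/s rates for the 5/10/15-nt
scenarios, e.g. `extension_10nt: n=63, mean 3.18 s -> 3.1 nt/s`, and fit
the sum-of-exponentials extension models.
`analysis/03_ensemble_heatmap.py` renders the sorted, colour-coded
ensemble heat-map (white unbound, blue donor-only, green open, red
closed, black high-FRET) with the a/b_bright/b_dark/c molecule grouping.

A `polfret` command-line tool wraps the same stages
(`polfret run config.yaml`, `polfret detect/segment/kinetics/heatmap`,
`polfret demo-configs`).

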