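# twistspacer

Bacterial promoters carry a "spacer" of 15–19 nucleotides between the −35
and −10 hexamers recognized by the RNA polymerase sigma70 holoenzyme.
Because DNA is helical, the spacer length sets the relative torsional
orientation of the two hexamers, and the global DNA supercoiling level σ
modulates it: supercoiling can rotate an ill-phased promoter into (or out
of) the orientation RNAP needs to form the closed complex.  `twistspacer`
implements a quantitative, almost parameter-free model of this coupling and
the statistical pipelines needed to test it on titration, reporter-shock
and genome-scale differential-expression data.  It is written for
researchers in bacterial gene regulation and DNA mechanics who want to
predict or analyse supercoiling responses of promoters as a function of
spacer length.

## The model

Treating the spacer as *n* harmonic basepair steps of torsional stiffness
k<sub>θ</sub> = 71.4 k<sub>B</sub>T·rad⁻² and relaxed twist
α₀(1 + σ) with α₀ = 34°, while RNAP imposes a total twist angle
θ<sub>P</sub> across the spacer, the elastic (orientational) free energy of
closed-complex formation is

    ΔG_or(σ, n) = (n/2) · k_θ · (θ_P/n − α₀(1 + σ))²   [k_B·T]

Transcription rates follow a thermodynamic (Boltzmann) law
k = k₀·exp(−ΔG), so every *relative* quantity is parameter-free:

- normalized to the 17-nt reference, the log expression of an *n*-nt mutant
  is linear in σ with slope −k<sub>θ</sub>α₀²(n − 17)(1 + σ)
  (≈ −25 per extra nucleotide);
- under a superhelical shock σ₀ → σ₀ + Δσ the log-fold-change difference
  between spacers is ≈ −k<sub>θ</sub>α₀²·Δn·Δσ, i.e. a relaxation of
  Δσ = 0.03 changes expression by a factor ≈ 2 per nucleotide of spacer.

Promoter-specific terms enter only as a σ-independent intercept Q_sp and a
spacer-independent shock term R_sc (fold-change contribution exp(−R_sc)).

The modules mirror the analysis chain: `torsion` (the model),
`sequence` (dinucleotide-resolved twist refinement and its ablations),
`invitro` (σ-titration normalization and slope tests), `invivo`
(reporter fold-changes and the effective (Δσ, R_sc) fit), `genome`
(promoter-map filtering, response classification, spacer statistics), and
`simulate` (synthetic generators for all three input kinds).

## Worked example

Predict the response of a 19-nt-spacer promoter to an overtwisting shock
(Δσ = −0.02 from σ₀ = −0.06, with a fitted spacer-independent term
R_sc = −0.97):

```sh
$ twistspacer predict --n 19 --sigma0 -0.06 --dsigma -0.02 --r-sc -0.97
orientational_energy(sigma=-0.06, n=19) = 2.3385 kBT
logFC(dsigma=-0.02, R_sc=-0.97) = 1.8198
fold_change = 6.1708
```

The 19-nt promoter pays 2.34 k<sub>B</sub>T of orientational energy before
the shock; overtwisting relieves part of it, and together with the
spacer-independent activation the model predicts a ~6.2-fold induction
(while the same shock leaves a 15-nt promoter nearly unchanged).

A genome-scale run on a synthetic relaxation cohort:

```sh
$ twistspacer simulate genome --seed 1 --out demo
$ twistspacer genome --promoters demo/promoters.tsv --responses demo/responses.tsv --out demo/report
```

`demo/report/report.json` then contains (seed 1): mean spacer lengths
15.34 (activated), 17.27 (unaffected), 18.29 (repressed), Welch
p ≈ 7e−52 for activated vs repressed, and an activation-proportion slope of
−0.263 per nucleotide (p ≈ 0.044) — relaxation selectively activates
short-spacer promoters and represses long ones, as the model predicts.

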