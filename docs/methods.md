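# Methods

## Model and assumptions

The package models the closed-complex step of transcription initiation at
sigma70 promoters.  RNA polymerase is assumed to bind the −35 and −10
hexamers simultaneously only once the spacer between them has been twisted
to a fixed total angle θ_P; the spacer is treated as a one-dimensional
torsional spring (no writhe — the spacer is too short to writhe before
binding — no RNAP flexibility, no twist–stretch coupling), and the whole
superhelical density σ is assumed available as twisting torque, so each of
the n basepair steps is deformed from α₀(1+σ) to θ_P/n.  The orientational
free energy is then

    ΔG_or(σ, n) = (n/2)·k_θ·(θ_P/n − α₀(1+σ))²  [k_B·T].

All other influences are split into a spacer-independent σ term (promoter
opening etc.) and a σ-independent spacer term; both cancel in the relative
quantities the pipelines compute, entering only as the intercept Q_sp
(normalized titrations) and the shock term R_sc (fold-changes,
contribution exp(−R_sc)).  The model is only claimed valid for spacers of
15–19 nt; 16-nt spacers are empirically anomalous (their supercoiling
response is likely dominated by open-complex effects and they correlate
with G/C-rich discriminators) and are excluded from the genome statistics
by default.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| k_θ | 71.4 | k_B·T·rad⁻² per step | sequence-averaged torsional stiffness of B-DNA |
| α₀ | 34° (0.5934 rad) | per step | mean helical twist |
| θ_P | 543.32° | total | RNAP-preferred twist across the spacer |
| n_ref | 17 | nt | optimal spacer length |
| σ_ref | −0.06 | – | physiological superhelical density |

Angles are radians internally; degree-valued I/O converts at the boundary
(k_θ is published per rad², α₀ in degrees).  θ_P is stored unrounded as
17·α₀·(1−0.06) so the reference promoter is exactly strain-free at
(n, σ) = (17, −0.06); the conventional rounded value 543° is presentation
only.  Almost all pipeline outputs (slopes, fold-change differences) are
independent of θ_P and of Q_sp/R_sc — this is checked by parameter
perturbation in the tests.  Natural logarithms are used for every
log-fold-change; log2 is a display conversion only.

A documented inconsistency: with R_sc = −0.97 the model's spacer-
independent activation factor is exp(0.97) ≈ 2.64, while the quoted factor
for that condition in the experimental literature is 2.1; the pair
R_sc = 0.4 ↔ factor 0.67 is self-consistent and is the one asserted in
tests.  Fits expose `r_sc_factor = exp(−R_sc)` and make no attempt to
force 2.1.

## Linearized forms and their accuracy

Because ΔG_or is exactly quadratic in σ, the shock log-fold-change
difference between spacer lengths obeys the identity

    exact = −k_θα₀²·Δn·Δσ·(1 + σ₀ + Δσ/2),

so the widely quoted linearized rule −k_θα₀²·Δn·Δσ ≈ −25·Δn·Δσ carries a
relative error of exactly |σ₀ + Δσ/2|: 4.5% for a relaxation Δσ = +0.03
from σ₀ = −0.06, but 7.5% for an overtwisting Δσ = −0.03.  The unit tests
assert a 7% band on the relaxation branch and the exact error identity on
both branches.  `logfc_under_shock` always evaluates the exact energy
difference; linearized forms are explicit opt-ins.

## Sequence-dependent refinement

The dinucleotide extension models the spacer as torsional springs in
series, step i having intrinsic twist α_i and stiffness k_i, with RNAP
imposing the total angle.  Minimizing the quadratic energy under the
total-angle constraint (Lagrange) gives

    E = ½·k_eff·(θ_P − (1+σ)·Σα_i)²,  k_eff = 1/Σ(1/k_i),

which reduces bit-for-bit to the uniform model and is verified against an
independent KKT linear-system solve.  Steps are counted between
consecutive spacer nucleotides (n−1 steps) by default; boundary steps into
the hexamers are included only when flanking bases are supplied
(`include_flanks`), since the step count of a sequence-resolved spacer is
otherwise ambiguous.  The ablations replace α_i (or k_i) by the average
over all steps of the analysed panel — a per-sequence average would leave
the total twist unchanged and ablate nothing.  With realistic twist
tables, averaging α removes nearly the whole sequence effect while
averaging k leaves it intact: the sequence acts through DNA structure, not
elasticity, and its span stays below the effect of one spacer nucleotide.
The shipped default table carries crystallographic mean twist angles
(provenance in the data file header) and uniform stiffnesses; every test
uses uniform or synthetic tables so correctness never depends on those
numbers.

## Pipelines: numerical choices

*In vitro*: reference matching over σ is exact by default (titrations are
prepared at discrete σ); `sigma_tol` enables nearest-σ matching (0.002
suggested) for digitized data.  Reference activities are geometric means
over replicates.  Q_sp is the mean residual after subtracting the
parameter-free orientational part (the slope is never fitted); the slope
consistency check is an unweighted OLS with a z-statistic against the
exact derivative evaluated at the dataset's mean σ, with the pure −25·Δn
constant reported alongside.  Fits are unweighted because source tables
are typically means without errors.

*In vivo*: fold-change is evaluated at a single post-shock time
(presets: 60 min for relaxation drugs, 5 min for overtwisting drugs), at
the nearest sample within half a sampling interval.  The point estimate is
the ratio of arm means; the 95% CI is a Student interval on index-paired
log-ratios (Welch variant available) — in principle the ratio of means can
fall outside the log-scale CI under heavy noise; in practice the two
estimators coincide closely.  The (Δσ, R_sc) fit offers a joint
least-squares inversion and the two-step protocol (Δσ from
reference-anchored differences where R_sc cancels, then R_sc from the
reference alone); both agree exactly on noise-free panels.  The ~45-min
luciferase lifetime is *not* deconvolved in analysis — fitted Δσ values are
effective values — but it is modelled in the generator as a first-order
lag, which provably pulls repressive readouts toward unity.

*Genome*: coordinates are 1-based inclusive; spacer length is the hexamer
gap (m10_start − m35_end − 1 on +, mirrored on −), with a curated
`spacer_len` column taking precedence (mismatches logged).  The
discriminator is taken as the sequence between the −10 element and the
TSS, exclusive of both.  Classification uses padj < α with the sign of
logFC (α = 0.05; 0.1 is appropriate for low-powered evolved-strain data).
"Responsive" in the proportion regression means padj < α regardless of
sign.  Group comparisons report both Welch (default) and pooled-variance
t-tests; binomial CIs are Wilson intervals; the proportion regression is
unweighted OLS with a weighted option (group sizes differ, but the
unweighted fit matches the conventional presentation).  All intervals are
95%.

## Synthetic data

The generators emulate the statistical structure of the real assays, not
their chemistry.  In vitro: model rates times log-normal noise, reference
included at every σ.  Reporter wells: logistic growth (od0 = 0.05,
K = 1.5, r = 0.02 min⁻¹), piecewise-constant per-cell activity switching
by the model fold-change at shock time, first-order reporter filtering,
multiplicative noise; the vehicle arm gets Δσ = 0.  Genome cohorts: spacer
lengths drawn from a distribution peaked at 17 nt (27% mode; the other
masses are illustrative configuration), per-promoter R_sc ~
N(0, 0.5 k_B·T), triplicate log-noise 0.2, per-promoter t-tests against
zero with Benjamini–Hochberg adjustment — so the α-threshold semantics
match the analysis pipeline exactly.  When Δσ = 0 the R_sc draw is forced
to zero: no superhelical shift means no true response, making null cohorts
a genuine global null.  The default cohort size (420) leaves roughly 300
responsive promoters under the default Δσ = 0.03 relaxation, the scale of
a curated-map analysis.  Not emulated: real microarray intensity
distributions, growth-phase programs, transcription-factor regulation,
promoter mis-annotation, and the anomalous behaviour of real 16-nt
spacers (synthetic 16-nt promoters follow the model; they are excluded
from the statistics regardless).  Passing cohort tests therefore
demonstrates the statistical machinery and the model's internal
consistency, not agreement with any particular organism's data.

## Known limitations

- θ_P, Q_sp and R_sc are effective parameters; the model makes no claim
  about absolute expression levels or about promoters whose −35 element is
  ill-defined (extended −10 promoters).
- The one-dimensional twist treatment ignores writhe partition, roll/tilt
  structure, A-tract curvature and open-complex energetics; 16-nt spacers
  mark where those omissions bite.
- Fitted Δσ values from buffered reporter data underestimate the true
  superhelical shift (observed directly in the synthetic round-trip, where
  a generated Δσ = 0.005 with the 45-min reporter lag reads back smaller).
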