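# Methods

## Opening-energy model

The package models open-complex formation as a two-state,
imposed-bubble transition: a fixed window of `n_bubble = 14` bp,
starting at and including the −10 hexamer, is either fully duplex or
fully denatured. The opening cost at superhelical density σ is

    G_open(σ, s) = a_nuc + G_melt(s) + g_twist(σ)

**Duplex term.** `G_melt` sums the 15 dinucleotide stacks spanning the
bubble (including both boundary stacks; a flanking base outside the
available promoter window is taken as G, which emulates G-tract flanks
and makes the boundary contribution sequence independent). Stack
stabilities come from the unified nearest-neighbor ΔG°(37 °C, 1 M NaCl)
table (SantaLucia 1998), embedded as data and treated by the tests as
fixed regression constants. Salt enters per stack as
`m_salt · ln(salt)` with `m_salt = 0.114 kcal/mol` per ln-unit, the
standard per-phosphate-pair logarithmic correction. At sub-molar salt
this makes opening cheaper; for the weakest stack (TA) the net opening
cost can become slightly negative below ~6 mM, which is physically
unremarkable for an effective low-salt description.

**Torsional term.** In the closed state a topological domain of N bp
carries linking difference α = σ·N/h and superhelical energy
`E_sc = B·R·T·α²/N` (Depew–Wang-type quadratic, B = 1100). Opening n
bases removes their duplex twist (n/h turns) and lets the single
strands take a twist τ (rad/bp) at torsional cost `C_ss·n·τ²/2`, while
the residual linking difference `α_r = α + n/h − n·τ/(2π)` stays in the
duplex. The total is quadratic in τ, minimized in closed form:

    τ* = (K/π)(α + n/h) / (C_ss + K·n/(2π²)),   K = B·R·T/N

and `g_twist = f(τ*) − K·α²`. A brute-force grid search over τ is kept
in the test suite as an independent oracle. The total σ of the domain
is assumed available to the bubble (no twist/writhe partitioning), so
`g_twist` — and therefore `G_open` — is an exactly quadratic, strictly
increasing function of σ on the physiological range [−0.12, 0].

**Parameters** (defaults, adjustable via `MeltingParams` / TOML
`[melting]`):

| parameter | default | units | role |
|---|---|---|---|
| h | 10.5 | bp/turn | helical repeat |
| N | 3000 | bp | plasmid-like topological domain |
| B | 1100 | – | quadratic superhelical coefficient |
| C_ss | 1.0 | kcal/(mol·bp·rad²) | single-strand torsional stiffness |
| a_nuc | 10.0 | kcal/mol | bubble nucleation penalty |
| salt | 5e-4 | mol/L | effective salt (calibrated, see below) |
| T | 310.15 | K | temperature |
| m_salt | 0.114 | kcal/mol per ln-unit | per-stack salt coefficient |

`a_nuc` is sequence independent for a fixed 14-bp bubble and therefore
degenerate with the RNAP assistance energy of the rate law; it is kept
separate for physical bookkeeping only and is not identifiable from
expression data.

**Effective-salt calibration.** The salt concentration is an effective
parameter absorbing the simplified solvent and chain description, not a
physiological concentration. The packaged default (0.5 mM) was
calibrated once against the model's intended operating regime: the
opening transition of an average promoter sits near σ ≈ −0.045, both
predicted activation and repression occur under a genome-wide
relaxation of Δσ = +0.015 with the activated fraction concentrated in
A/T-rich discriminators, and the predicted calls remain stable under
global σ shifts of ±0.01 (the sharp rate-law hinge would otherwise make
the all-suppressed state degenerate — every normalized fold change
exactly 1 — when no promoter remains at its maximal rate).
`fit_effective_salt` re-estimates salt from expression-versus-σ curves
by bounded scalar minimization on a log10 scale in [1e-4, 1] M.

## Rate law and fold changes

    k(σ, s) = k0 · exp(min((ΔG_P0·k_BT − G_open(σ, s)) / k_BT, 0))

with ΔG_P0 = 3.5 k_BT (≈ 2 kcal/mol at 310 K) shared by all promoters
(the sequence dependence of the RNAP–discriminator interaction is
neglected) and k_BT = R·T = 0.6163 kcal/mol at 310.15 K. The rate is
continuous in σ, bounded by k0, and exactly k0 whenever opening costs
less than the RNAP assistance. Fold changes across a σ shift cancel k0
always, and cancel ΔG_P0 whenever both states are suppressed.

**Shock fit.** `fit_shock_parameters` estimates an initial σ per growth
medium plus one shared relaxation magnitude Δσ from observed fold
changes, minimizing squared log-FC error with a fixed-start-grid
Nelder-Mead search (4×4×3 starts, bounds σ ∈ [−0.1, 0],
Δσ ∈ [1e-5, 0.05], followed by a polish restart), so the fit is
deterministic. Because `G_open` is exactly quadratic in σ, promoters
suppressed at both σ levels constrain only a combination of the three
parameters; identifiability comes from promoters near the plateau
hinge, whose fold changes pin the σ levels individually. Recovery
tests therefore use a calibration parameter set (`a_nuc = 4`) that
places the hinge in the fitted regime — mirroring the physical
situation in reporter assays, where discriminator mutants visibly
modulate the repression factor. All-flat fold changes are detected
up front and returned with Δσ at its lower bound and a flag.

## Genome-wide prediction and sensitivity gain

Rates at σ0 and σ0+Δσ are normalized by their sum under each condition
(transcriptome protocols fix total mRNA), the normalized fold change is
their ratio, and the predicted call is act/rep by comparison with 1
(exact ties, |FC−1| ≤ 1e-9, are flagged and excluded from accuracy
denominators). The sensitivity gain is the sign-prediction accuracy
among observed responsive promoters minus the mean accuracy over seeded
permutations of the predicted labels (a frequency-preserving random
null), reported in percentage points.

## Sequence statistics

Promoters are aligned at the −10 element (hexamer start at position
−12) or at the TSS; a global integer shift can re-register species with
offset signals. Internally positions are contiguous with the TSS at 0;
displayed positions skip 0 (TSS = +1). Windows are contiguous on the
internal axis, so the default discriminator window "5 nt centered at
−2" covers internal offsets [−4, 0], and the downstream variant
centered at +4 covers [+1, +5]. A/T% profiles use 5-nt sliding windows
restricted to positions covered by every promoter (constant n per
group). Activated and repressed groups are compared per position with
Welch's unequal-variance t-test; the unaffected group is profiled for
display but never tested (its false-negative composition is
heterogeneous). Binned activated proportions carry Wilson 95%
intervals; the regression of outcome (act = 1, rep = 0) on per-promoter
A/T% is ordinary least squares (a binned-proportion mode is provided as
an alternative); the chi-square independence test drops empty bins and
merges bins with expected counts below 5 into their smaller adjacent
neighbor; no continuity correction. Positionwise tests are reported
without multiple-testing correction, by design. Significance stars:
*** p<0.001, ** p<0.01, * p<0.05. The −10 binding score is a log-odds
PWM (pseudocount 1, background = base frequencies of the full promoter
windows) built from the input set itself and correlated (Pearson) with
discriminator A/T%.

## Synthetic data

The generator emulates a genome-wide relaxation assay: promoters of
71 nt (50 up / 20 down) with a TATAAT-derived −10 hexamer (per-base
mutation rate 0.15), a 5-nt discriminator of controlled A/T count
(uniform over the six levels by default) and random flanks at 50% G/C;
responses are the model's own normalized log2 fold changes at
σ0 = −0.045, Δσ = +0.015 plus Normal(0, 0.3) observation noise, with
30% of promoters replaced by discriminator-independent confounders
drawn at doubled spread (TF-driven or other supercoiling-independent
responders). P-values come analytically from a triplicate-design
z-model and are Benjamini–Hochberg adjusted; every output is a pure
function of the configuration seed. An optional coupling knob plants
the negative correlation between −10 consensus match and discriminator
A/T content used to exercise the PWM analysis.

What the generator does **not** emulate: read counts and library-size
effects, operon structure, topological-domain heterogeneity, local
supercoiling generated by elongating polymerases, competing structural
transitions (cruciforms, Z-DNA, G-quadruplexes) and kinetic effects of
promoter escape. Passing tests therefore demonstrate internal
consistency of the method and its ability to recover planted effects of
realistic size and noise — not performance on real transcriptomes,
where those mechanisms dilute the discriminator signal.

## Problem sizes and numerical choices

The default test and reproduction sizes are 2000 promoters for the
genome-scale analyses, 300 promoters × 200 replicate seeds for the
null-calibration check, 6 promoters × 19 σ points for the salt
calibration and 40 promoters per medium for the shock fit — sizes at
which every check runs in seconds while the planted effects are
detected with wide margins. Torsional minimization is validated against
a τ grid of step 1e-5 over [−2, 2] rad/bp (agreement well below
1e-6 kcal/mol). Optimizer tolerances: salt fit xatol 1e-10 on log10
salt; shock fit xatol 1e-9 / fatol 1e-14 per start, 1e-11 / 1e-16 for
the polish.

## Known limitations

* The hinge rate law has a kink at G_open = ΔG_P0·k_BT; real opening
  kinetics are smooth, and per-promoter predicted calls near the hinge
  flip more readily under σ shifts than aggregate statistics do.
* The two-state bubble ignores the ensemble of partial and displaced
  bubbles (no partition function over positions/sizes), so absolute
  opening energies are effective quantities; the effective salt absorbs
  much of this, as evidenced by the sub-mM calibrated value.
* `a_nuc` and ΔG_P0 are jointly unidentifiable from expression data.
* The quadratic σ dependence makes multi-parameter σ fits
  ridge-degenerate when no promoter crosses the plateau hinge; the fit
  reports flags but cannot manufacture identifiability from flat data.
* Observed A/T% distributions, sigma-factor mixtures and TSS annotation
  errors in real promoter catalogs are outside the generator's scope.
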