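# discrimsc

Quantitative modeling and genome-wide statistics of how DNA supercoiling
regulates bacterial promoters through the **discriminator** — the 5–8 nt
sequence between the −10 element and the transcription start site (TSS)
that is melted in the open complex. The package is aimed at researchers
in bacterial gene regulation who want to (i) predict how a promoter's
expression responds to a change of superhelical density σ from its
sequence, and (ii) test, on transcriptome-scale data, whether
activation/repression under a supercoiling shift correlates with
discriminator A/T content.

## The model

Open-complex formation requires denaturing a fixed 14-bp bubble starting
at (and including) the −10 hexamer. Its free-energy cost at superhelical
density σ is

```
G_open(σ, s) = a_nuc + Σ_stacks [ −ΔG°_NN(stack, 1 M) + m_salt·ln(salt) ] + g_twist(σ)
```

– a nucleation penalty, the nearest-neighbor duplex stability lost over
the 15 stacks spanning the bubble (unified NN table with a per-stack
log-salt correction; neighbors outside the promoter window are taken as
G, emulating G-tract flanks), and a torsional term obtained by
minimizing, in closed form, the trade-off between single-strand twisting
of the open bases and the quadratic superhelical energy
`E_sc(ΔLk) = B·R·T·ΔLk²/N` of the residual linking difference in a
topological domain of N bp. Negative σ pays part of the opening cost, so
G/C-rich discriminators (expensive bubbles) need stronger negative
supercoiling to open than A/T-rich ones.

The transcription rate follows a hinge-exponential law,

```
k(σ, s) = k0 · exp( min( (ΔG_P0·k_B T − G_open(σ, s)) / k_B T, 0 ) )
```

where ΔG_P0 = 3.5 k_B T (≈ 2 kcal/mol) is the opening assistance by RNA
polymerase, shared by all promoters. When opening is cheaper than that
assistance the promoter runs at its maximal rate k0; otherwise it is
exponentially suppressed. Fold changes between two σ levels in the
suppressed regime depend only on the opening-cost difference — not on
ΔG_P0 or k0.

Genome-wide predictions mimic transcriptomic normalization: rates are
divided by their sum under each condition before fold changes are
computed, so that under DNA relaxation (σ → less negative) the least
repressed, A/T-rich promoters appear *activated* by competition with the
strongly repressed G/C-rich ones.

The statistical layer aligns promoters at their −10 element (or TSS),
computes A/T% in sliding 5-nt windows, compares activated and repressed
groups with Welch tests per position, classifies promoters by the A/T%
of the 5-nt window centered at position −2, and quantifies the relation
with activation by linear regression, chi-square tests and Wilson
confidence intervals. A seeded synthetic-data generator produces
promoter sets and supercoiling-response transcriptomes with known ground
truth (model-driven responses plus noise and a confounded fraction), so
the whole pipeline is testable without external data.

## Worked example

```python
import numpy as np
from discrimsc import (MeltingParams, TranscriptionParams, SynthConfig,
    PromoterRecord, opening_cost, activation_curve, generate_promoters,
    generate_response, call_expression, align_promoters, position_ttest,
    classify_and_regress, predict_genomewide, sensitivity_gain)

mp, tp = MeltingParams(), TranscriptionParams()

# a stable-RNA-like promoter (G/C-rich discriminator) and its A/T mutant
ctx = "ACGTTGCAGATCCATGGTACCAGTCGACTTAGGCATCGTAAGCTTGGATCCACGTGCAGTCCTAGACGTTA"
def prom(disc, pid):
    s = list(ctx); s[38:44] = "TATAAT"; s[46:51] = disc
    return PromoterRecord(id=pid, seq="".join(s), up=50, minus10_offset=-12)
gc, at = prom("CGCGC", "wt"), prom("ATATC", "mutant")

for sig in (-0.06, -0.045, -0.03):
    print(sig, opening_cost(gc, sig, mp), opening_cost(at, sig, mp))
```

prints opening costs (kcal/mol) that fall with negative σ and are always
≈6 kcal/mol apart (four C/G→A/T swaps):

```
sigma=-0.060  G_open(GC)=  1.03  G_open(AT)= -5.09
sigma=-0.045  G_open(GC)=  7.27  G_open(AT)=  1.15
sigma=-0.030  G_open(GC)= 12.36  G_open(AT)=  6.24
```

so the wild type reaches half-maximal expression at σ = −0.0565 and the
A/T mutant already at σ = −0.0410 — the activation curve shifts toward
weaker supercoiling, exactly the behavior seen for discriminator mutants
of stable-RNA promoters.

At the genome scale, a synthetic relaxation transcriptome (2000
promoters, σ: −0.045 → −0.030, noise 0.3, 30% confounders, seed 1):

```python
cfg = SynthConfig()
proms = generate_promoters(cfg)
calls = call_expression(generate_response(proms, cfg, mp, tp).records)
aligned = align_promoters(proms)
print(position_ttest(aligned, calls, -2))
res = classify_and_regress(aligned, calls)
print(res.bins[["at_pct", "proportion_act"]])
gain = sensitivity_gain(predict_genomewide(proms, cfg.sigma0, cfg.dsigma, mp, tp),
                        calls, seed=0)
print(gain.gain_percent)
```

yields 249 activated / 1475 repressed / 276 unaffected promoters; the
activated-vs-repressed A/T% difference at position −2 is highly
significant (Welch t = 7.15, p = 5.9e-12), the proportion of activated
promoters rises with discriminator A/T% from 0.086 (0% A/T) to 0.332
(100% A/T) with regression p = 1.1e-13 (***), and the model's sign
predictions beat a frequency-matched random predictor by 7.5 percentage
points over 1724 responsive promoters.

A `discrimsc` command-line tool exposes the same steps
(`simulate`, `energy`, `predict`, `fit salt|shock`, `profile`,
`classify`, `predict-genome`; see `discrimsc --help`).

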