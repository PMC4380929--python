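# hepg1s

Hepatocyte-specific modeling and analysis of the HGF-driven G1/S
transition.

Adult hepatocytes are quiescent; during liver regeneration they re-enter
the cell cycle in response to hepatocyte growth factor (HGF). The puzzle
is specificity: isolation and plating stress already activate PI3K/Akt
and MEK/ERK signaling and drive the accumulation of G1/S components
(Cyclin D1:CDK4, Cyclin E:CDK2, p21, Rb, E2F-1), yet DNA replication
occurs only with the growth factor. `hepg1s` is a toolkit for studying
the mechanism behind that threshold: which step of cell-cycle entry
demands full pathway activation, and therefore gate-keeps proliferation.
It is written for systems biologists who want a self-contained, testable
re-implementation of this analysis pipeline — from raw replicate tables
to calibrated model and threshold ranking — with a synthetic-data module
standing in for the wet-lab measurements.

## The model

A two-layer model of cell-cycle entry:

**Input layer (algebraic).** HGF dose *u* (ng/ml) maps to bounded
activities of five signaling nodes,

```
Akt(u)  = α_akt + (1 − α_akt) · u / (k_akt + u)        ∈ [0, 1]
ERK(u)  = α_erk + (1 − α_erk) · u / (k_erk + u)
GSK3β   = 1 − Akt                                       (inhibitory edge)
TF      = tf_basal + (1 − tf_basal) · Akt · ERK         (AND gate, lumped AP-1/Myc/p53)
p53     = TF
```

with basal activities α fixed from inhibitor-controlled measurements.
Pharmacological treatments are clamps on these nodes (Akt inhibitor VIII,
U0126, Pifithrin-α) or a CDK4-activity flag (PD0332991).

**Dynamic layer (rule-based ODEs).** Pattern rules for synthesis,
binding, p21-mediated nuclear import, CDK2 T160 phosphorylation by CAK,
sequential Rb phosphorylation (CDK4-class site, then CDK2-class site),
Rb:E2F-1 sequestration/release and degradation expand deterministically
into a reaction network of **24 dynamic species, 69 reactions and 55
kinetic parameters**, observed through **10 observables** (nine scaled
immunoblot-style readouts plus DNA content). DNA synthesis requires free
E2F-1 AND active pCDK2 T160 and saturates at one duplication:

```
dDNA/dt = k_dna · [E2F-1]_free · [pCDK2 T160] · (2 − DNA),   DNA(0) = 1.
```

**Estimation.** Weighted least squares, χ² = Σ ((model − mean)/SEM)²,
minimized by bounded trust-region steps in log₁₀ parameter space from
multi-start initializations p·10^(s·ε), ε ~ N(0,1), s = 1.5; 52 of the
parameters are free (45 kinetic, 4 scaling, 3 input). The best ten runs
form the ensemble for sensitivity analysis (control coefficients
[x(f·p) − x(p)]/[(f−1)·x(p)], f = 0.9/1.1), dose–response EC50 ranking
and two-input response surfaces. Single-cell Fucci-style tracks are
classified into G1, G1/S, S/G2/M and early-G1 quadrants, and a G1/S
transition event is four consecutive G1/S samples followed by four
consecutive S/G2/M samples.

## Worked example

```python
import numpy as np, hepg1s as h

network = h.default_network()          # expand rules -> 24 species, 69 reactions
params  = h.default_parameters()

doses = np.array([0, 0.2, 0.5, 1, 2, 4, 8, 16, 30, 60, 120, 400.0])
curves = h.dose_response(network, [params], doses)
for obs, c in sorted(curves.items(), key=lambda kv: kv[1].median_ec50):
    print(f"{obs:12s} EC50 = {c.median_ec50:6.2f} ng/ml")
```

prints

```
prb_s788     EC50 =   1.33 ng/ml
rb_total     EC50 =   1.47 ng/ml
prb_s800     EC50 =   3.10 ng/ml
e2f1_total   EC50 =   4.89 ng/ml
dna          EC50 =   8.32 ng/ml
cyce_cdk2    EC50 =   8.49 ng/ml
p21_cdk2     EC50 =   8.56 ng/ml
cycd1_cdk4   EC50 =   9.77 ng/ml
p21_total    EC50 =  10.39 ng/ml
pcdk2_t160   EC50 =  12.43 ng/ml
```

Each number is the HGF dose at which that observable reaches half of its
maximal response over a 72-h window. Rb and its phosphoforms saturate at
sub-ng/ml doses — they are already engaged by stress signaling — whereas
pCDK2 T160 needs an order of magnitude more HGF than any other protein
observable, and DNA content tracks it: T-loop phosphorylation of CDK2 is
the gate-keeping step that keeps DNA synthesis growth-factor-dependent.

The `examples/` directory holds one narrative script per capability:
network construction and simulation, replicate processing and error
models, multi-start calibration, sensitivity/EC50 analysis, and
single-cell track statistics. Each prints the numbers it computes and a
line on what they mean.

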