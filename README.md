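# pgpkit

Quantitative analysis toolkit for characterizing an ATP-dependent efflux
transporter (P-glycoprotein / Abcb1) end to end: from the cloned cDNA,
through in-vitro bidirectional transport across cell monolayers, to the
in-vivo pharmacokinetic consequences of efflux inhibition, plus tissue
expression profiling. It is written for pharmacologists and molecular
biologists who have the bench data (or want realistic synthetic data) and
need the downstream numbers computed reproducibly.

## What it computes

**Transport assays** (`pgpkit.transport`). Apparent permeability of a drug
across a monolayer, Papp = (dQ/dt)/(A·C₀) in cm/s, from a single terminal
receiver sample; the efflux ratio ER = Papp(BL→AP)/Papp(AP→BL); and the net
efflux ratio NER = ER(transfected)/ER(parental), which isolates the
transfected transporter from the host cell's background. TEER-based QC
(monolayers kept only above 150 Ω·cm²) and a pooled-variance Student's
t-test round out the module.

**Oral pharmacokinetics** (`pgpkit.pk`). The one-compartment oral (Bateman)
model

    C(t) = D·Ka / (V/F·(Ka−Ke)) · (e^(−Ke·t) − e^(−Ka·t)),

fit per animal by bounded nonlinear least squares with curve-stripping
initialization, LOQ-censored observations excluded. Closed-form secondary
parameters: T½ka = ln2/Ka, T½ke = ln2/Ke, Tpeak = ln(Ka/Ke)/(Ka−Ke),
Cmax = C(Tpeak), AUC = D/(V/F·Ke), CL/F = V/F·Ke. A two-compartment oral
model (biexponential plus absorption) is the alternative candidate, and the
least-squares AIC, n·ln(RSS/n) + 2k, selects between them.

**Sequence characterization** (`pgpkit.sequences`). In-silico fusion of
overlapping cDNA fragments, longest-ORF search on both strands, standard
translation, average-mass molecular weight, theoretical pI by bisection on
the Bjellqvist pKa set, N-glycosylation sequon scan (N-X-S/T, X ≠ P), and
global protein alignment with percent identity.

**Phylogenetics** (`pgpkit.phylo`). Poisson-corrected protein distances
d = −ln(1−p), Saitou–Nei neighbor joining, column-resampling bootstrap
support (1,000 replicates by default in the CLI), Newick output.

**Expression** (`pgpkit.expression`). Relative mRNA by the 2^−ΔΔCt method,
densitometric protein ratios, and Pearson (or Spearman) mRNA–protein
correlation.

**Synthetic data** (`pgpkit.simulate`). Seeded generators that emulate each
assay's statistical structure — lognormal replicate noise on transport
wells, Bateman curves with proportional noise and LOQ censoring, Gaussian
Ct noise, Poisson substitution along a tree — and invert exactly at zero
noise, so every stage is testable without any external download.

## Worked example

```python
import numpy as np
from pgpkit import pk, simulate, transport

# Net efflux ratio from the per-line efflux ratios of a bidirectional assay
ner = transport.net_efflux_ratio(2.58, 1.04)
print(round(ner, 2))                      # 2.48

# Closed-form PK at the verapamil-group rate constants
params = pk.PKParams(ka=2.08, ke=0.25, v_f=1.96)
der = pk.derived_parameters(params, pk.DoseRegimen(10.0))
print(round(der.t_peak, 3), round(der.c_max, 2))   # 1.158 3.82

# Simulate a 4-animal oral study (5% noise, LOQ 0.05) and refit
series = simulate.simulate_pk_study(params, cv=0.05, n_animals=4, seed=20)
fits = [pk.fit_one_compartment(s, pk.DoseRegimen(10.0)) for s in series]
print(round(float(np.mean([f.params.ka for f in fits])), 3))   # 2.148
```

The printed 2.48 is the transfected line's efflux ratio over the parental
line's: the transporter under study triples apically directed efflux. Tpeak
of 1.158 h and Cmax of 3.82 μg/mL are the analytic peak of the Bateman
curve at those rate constants. The refitted mean Ka (2.148 1/h at this
seed) recovers the generating 2.08 1/h to within the simulation noise.

A CLI mirrors the library: `pgpkit seq|phylo|transport|pk|expr|simulate`,
each writing its result plus a JSON manifest (inputs, parameters, seed,
version) for reproducibility. For example:

```bash
pgpkit simulate --kind pk --seed 3 --out plasma.csv
pgpkit pk --in plasma.csv --dose 10 --model auto --out params.csv
```

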