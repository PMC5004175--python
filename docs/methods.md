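# Methods

This note documents the models, defaults, numerical choices and known
limitations behind each pgpkit module, and what the synthetic-data
generators do and do not emulate.

## Transport statistics

A well is a single terminal measurement: the amount of drug that appeared
in the receiver chamber after a fixed incubation, Q = C_receiver × V_receiver,
so dQ/dt = Q/t and Papp = Q/(t·A·C₀). This single-interval slope matches a
design that samples the receiver once; it assumes transport stayed in the
initial linear regime (sink conditions, no back-flux correction — none is
applied, and `papp_from_slope` accepts an externally fitted multi-timepoint
slope when a richer design warrants it). Units: with volume in mL (= cm³),
area in cm² and time in s, Papp is in cm/s, and the two concentrations
cancel so any single concentration unit works.

Defaults that matter: membrane area 0.33 cm² (a 6.5 mm-diameter 24-well
insert, πr² ≈ 0.332 — assay protocols typically give the diameter, not the
area), donor concentration 12 μM, 0.2 mL receiver sample at 120 min, TEER
gate strictly above 150 Ω·cm².

Efflux-ratio aggregation: the default pairs the two directions by replicate
and averages the per-replicate ratios, which is what a mean ± SEM column of
per-replicate efflux ratios implies; ratio-of-direction-means is available
(`er_mode="ratio-of-means"`). The two differ by Jensen's inequality; both
are exact at zero noise. The net efflux ratio always divides the
transfected line's ER by the parental line's within the same inhibitor
condition.

The t-test is the classical pooled-variance two-sample test. Zero pooled
variance is degenerate: p = 1 when the means agree, p = 0 (infinite t)
otherwise, never an exception.

## Pharmacokinetics

The one-compartment oral model is the Bateman function (first-order
absorption into, and first-order elimination from, a single well-stirred
compartment). Bioavailability F is structurally unidentifiable from oral
data alone, so the volume parameter is V/F throughout, in
(mg/kg)/(μg/mL), and CL/F = V/F·Ke. When |Ka−Ke| < 1e-8 the implementation
switches to the analytic limit C(t) = (D·Ka·t/(V/F))·e^(−Ka·t); the branch
is continuous to well below measurement precision.

The Bateman curve is invariant under exchanging Ka and Ke with V/F rescaled
by Ke/Ka ("flip-flop"). Fits are canonicalized to Ka ≥ Ke, the regime of a
rapidly absorbed, more slowly eliminated oral drug, which is the regime of
every dataset this package targets; genuinely flip-flop kinetics would need
external information (e.g. intravenous data) to resolve, which is out of
scope.

Fitting: unweighted least squares on uncensored points (the convention of
classical compartmental PK software; 1/C² weighting available), using
bounded trust-region least squares with Ka, Ke ∈ (1e-4, 50) 1/h and
V/F ∈ (1e-3, 100). Initialization is classical curve stripping: the
terminal log-linear slope estimates Ke and its intercept V/F; the method of
residuals on the absorption phase estimates Ka, falling back to 5·Ke when
the residuals are unusable. A fit that ends on a parameter bound is flagged
non-converged rather than reported silently. Observations below the limit
of quantification (default 0.05 μg/mL) are censored — flagged and excluded
from the objective, never zero-filled or LOQ/2-substituted.

The two-compartment oral candidate is
C(t) = A·e^(−αt) + B·e^(−βt) − (A+B)·e^(−Ka·t) (5 parameters; C(0) = 0 by
construction). It nests the one-compartment model at B = 0, so the fit is
multi-started from both a generic stripping start and the embedded
one-compartment solution, guaranteeing RSS(2-cmt) ≤ RSS(1-cmt) up to solver
tolerance. Solutions are canonicalized to α ≥ β.

Model selection uses the least-squares AIC, n·ln(RSS/n) + 2k, smaller wins,
ties to fewer parameters; AICc is available for very small n. A candidate
that failed to converge drops out of the comparison; if only one candidate
converged it is selected by default. On data truly generated by the
one-compartment model with 5% noise at the 14-point schedule, the
one-compartment model wins ≈95% of replicates.

Group tables follow the per-animal convention: secondary parameters are
derived per animal from that animal's fit, then averaged (mean ± SEM,
SEM = SD/√n). The mean of per-animal Tpeak values is not the Tpeak of the
mean rate constants; closed-form spot checks against group-mean parameters
therefore carry a ~2% tolerance.

AUC: closed form D/(V/F·Ke) from a fit, or linear trapezoid over observed
points with optional terminal extrapolation C_last/Ke.

## Sequence characterization

Fragment assembly finds exact suffix–prefix overlaps of at least
`min_overlap` bases between every ordered fragment pair, then requires a
unique Hamiltonian chain through the overlap graph; no chain is a gap
error, more than one distinct assembled sequence is an ambiguity error.
This is the in-silico analog of fusing sequenced overlapping PCR fragments;
it assumes exact agreement in the overlaps (real chromatogram disagreements
are upstream of this tool).

ORF search scans both strands in all three frames for ATG-to-stop frames,
stop codon included in the length; ties break to the + strand, then the
smallest start. Coordinates are 0-based half-open internally; reported
positions (e.g. sequon sites) are 1-based.

Molecular weight sums standard average (isotope-abundance-weighted) residue
masses plus one water, 18.01524 Da — average rather than monoisotopic
masses, as mass estimates quoted for intact proteins are average-mass. The
isoelectric point solves net charge = 0 by bisection on pH ∈ [0, 14] to
1e-4, with Henderson–Hasselbalch group charges over the termini and
D/E/C/Y/H/K/R side chains using the Bjellqvist pKa set (the table behind
the classic ExPASy tool; the table is a function argument, so other sets
drop in). The charge function is strictly decreasing in pH, so the root is
unique. Both agree with Biopython's independent implementations to ~1e-5
relative (MW) and ~0.01 pH units.

The sequon scan is the bare N-X-S/T (X ≠ P) rule, overlaps included; it
deliberately applies no topology filtering (an extracellular-loop filter
would need a membrane-topology prediction, which is out of scope), so its
site count can exceed that of topology-aware annotation tools.

Pairwise global alignment wraps an exact affine-gap Needleman–Wunsch
(BLOSUM62, gap open 10, extend 0.5 by default — conventional protein
alignment parameters; no single standard exists and published identity
percentages depend on the tool, so identity values are descriptive).
Identity is matched columns over all alignment columns, gaps included.

## Phylogenetics

Distances: p is the fraction of differing residues among comparable
columns; gap handling defaults to pairwise deletion (columns gapped in
either of the two rows are dropped pair by pair), with complete deletion
(drop every column gapped in any row) selectable — distance-matrix programs
differ in their default, so both are exposed. The Poisson correction
d = −ln(1−p) assumes substitutions arrive as a Poisson process and every
hit changes the residue (no rate variation among sites, no back-substitution
correction); p = 1 saturates and raises, naming the offending pair.

Neighbor joining is the standard Saitou–Nei agglomeration on the
Q-criterion Q(i,j) = (n−2)d(i,j) − Σd(i,·) − Σd(j,·), with limb lengths
from the usual closed forms. Q ties break to the lowest label-sorted index
pair, making topologies reproducible regardless of input order. Negative
limb estimates (possible on non-additive inputs) are clamped to zero with
the deficit moved to the sister limb, preserving path lengths through the
joined node. On additive matrices the algorithm is exact: the tree's
path-length matrix reproduces the input to 1e-9, and the topology matches
exhaustive minimum-evolution search.

Bootstrap: columns resampled with replacement, tree rebuilt per replicate,
support of an internal edge = fraction of completed replicates containing
the same leaf bipartition. Replicates in which a pair saturates are dropped
and counted; the support denominator is completed replicates only. One
seeded generator drives the whole run.

## Expression quantification

2^−ΔΔCt: technical replicates are averaged arithmetically on the Ct scale
first; ΔCt = Ct(target) − Ct(reference gene) per tissue;
ΔΔCt = ΔCt − ΔCt(calibrator); fold = 2^−ΔΔCt. The calibrator is exactly 1
by construction and any plate-wide Ct offset cancels. Amplification
efficiency is fixed at exactly 2 — the method's defining assumption;
efficiency-corrected variants are out of scope. The calibrator tissue is a
required argument, not a default. Densitometry: target band over loading
control, relative to a calibrator sample. Correlation defaults to Pearson
(with p from the exact t transform); Spearman by flag.

## Synthetic data

Generators exist so every analysis stage has inputs with the right
statistical structure, and each is the right inverse of its stage at zero
noise. Noise conventions: lognormal (multiplicative) on anything that is a
positive concentration — the standard multiplicative-error model of
bioanalytical assays, parameterized so the arithmetic mean and CV are the
requested ones — and additive Gaussian on Ct, which is already a log2
scale.

Default conditions (chosen once to mirror the emulated study designs):
transport wells at C₀ = 12 μM, 120 min, 0.2 mL, 0.33 cm², replicate CV 10%,
n = 3; PK at 10 mg/kg over the 14-point 0.083–24 h schedule with 5%
proportional residual noise (the emulated assays report no residual
magnitude; 5% is a typical HPLC plasma-assay precision and is recorded
here as the package's stand-in) and LOQ 0.05 μg/mL; Ct noise SD 0.2 with
triplicate wells, reference-gene Ct 18 and calibrator ΔCt 3 (typical qPCR
bench values). Protein evolution places Poisson(rate·branch·sites)
substitutions per branch with uniform replacement among the other 19
residues; expected corrected distances equal rate × path length up to a
small back-substitution bias (≈ d²/19), so test trees keep paths ≲ 0.6.

What the generators do not emulate: between-well geometry variation,
non-sink transport kinetics, absorption lag times, correlated residuals or
between-animal covariance in PK, qPCR efficiency differences between
genes, indels or rate heterogeneity in sequence evolution. Passing tests
therefore demonstrate correctness of the estimators under their own
assumptions, not robustness to these violations.

All generators are bit-for-bit reproducible from (parameters, seed); a
single top-level seed spawns independent substreams via numpy's
SeedSequence.

## Problem sizes in the shipped tests

The test and acceptance runs use study-scale or smaller sizes chosen for
desk-scale runtimes: 4-animal PK groups (the emulated design), 100
replicates for the model-selection rate, 200 single-animal fits for the
bias check, 2,000–3,000-site simulated alignments for distance/topology
consistency, ≤6-taxon exhaustive oracles (15–105 topologies), and ≤7-residue
peptides for the brute-force alignment oracle (~10⁴ gapped pairings).

## Known limitations

- The accession-based characterization chain (`characterize_cdna`) is
  exercised on synthetic transcripts; running it on a real GenBank record
  requires the user to download the FASTA themselves and pass it to
  `pgpkit seq`.
- Efflux ratios from single-terminal-sample designs inherit that design's
  blindness to nonlinearity in time; the multi-timepoint entry point
  exists but is not the default.
- NJ produces a single point-estimate topology; no likelihood or Bayesian
  alternative is provided.
- The PK module is single-dose, single-analyte, non-compartmental-free:
  no metabolite kinetics, no population (mixed-effects) modeling.
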