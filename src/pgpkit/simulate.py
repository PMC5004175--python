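"""Synthetic-data generators for every analysis stage.

Each generator is the right inverse of its analysis stage at zero noise:
fragmenting then assembling returns the input sequence, simulated transport
wells at cv = 0 reproduce the requested Papp exactly, noise-free plasma
profiles refit to the generating parameters, and noiseless Ct tables return
the requested fold changes. Noise conventions: lognormal (multiplicative)
wherever the quantity is a positive concentration — the standard error model
of bioanalytical assays — and additive Gaussian on Ct, which is already a
log2 scale.

Default study conditions: bidirectional transport wells with C0 = 12 uM,
120 min single terminal sample of 0.2 mL across a 0.33 cm^2 insert,
replicate CV 10%, n = 3; oral PK at 10 mg/kg sampled at 0.083-24 h with 5%
proportional residual noise and LOQ censoring at 0.05 ug/mL; qPCR Ct noise
SD 0.2 with triplicate wells.

A single top-level seed deterministically spawns independent substreams per
generator (numpy SeedSequence).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phylo import MultipleAlignment, PhyloTree, TreeNode
from .pk import DEFAULT_SCHEDULE_H, ConcTimeSeries, DoseRegimen, PKParams, \
    bateman_concentration
from .sequences import AA_ALPHABET, NucSeq, ProtSeq
from .transport import DEFAULT_MEMBRANE_AREA_CM2, TransportWell
from .expression import CtRecord

AA = sorted(AA_ALPHABET)


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Default study conditions for all generators."""

    seed: int = 0
    transport_cv: float = 0.10
    transport_n: int = 3
    transport_c0_um: float = 12.0
    transport_elapsed_s: float = 7200.0
    transport_volume_ml: float = 0.2
    transport_area_cm2: float = DEFAULT_MEMBRANE_AREA_CM2
    pk_dose: float = 10.0
    pk_schedule_h: tuple = DEFAULT_SCHEDULE_H
    pk_noise_cv: float = 0.05
    pk_loq: float = 0.05
    pk_n_animals: int = 4
    ct_noise_sd: float = 0.2
    ct_n_replicates: int = 3
    ct_reference_mean: float = 18.0
    ct_calibrator_delta: float = 3.0

    def __post_init__(self) -> None:
        for name in ("transport_cv", "pk_noise_cv", "ct_noise_sd"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        if np.any(np.diff(self.pk_schedule_h) <= 0):
            raise SimulationError("pk schedule must be strictly increasing")


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """n independent reproducible substreams from one seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size=None):
    """Lognormal draws with the requested arithmetic mean and CV."""
    if cv == 0:
        return mean if size is None else np.full(size, mean)
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2
    return rng.lognormal(mu, np.sqrt(sigma2), size=size)


# ---------------------------------------------------------------------------
# sequences

def fragment_sequence(seq: NucSeq, n_fragments: int, overlap: int,
                      seed: int) -> list[NucSeq]:
    """Split a sequence into overlapping pieces (adjacent pieces share
    exactly ``overlap`` bases) and shuffle their order."""
    rng = np.random.default_rng(seed)
    L = len(seq)
    if n_fragments < 1:
        raise SimulationError("need at least one fragment")
    if n_fragments == 1:
        return [seq]
    if overlap < 1 or L < n_fragments * (overlap + 1):
        raise SimulationError(
            f"cannot cut {L} bp into {n_fragments} pieces with {overlap} bp overlaps")
    # interior cut points, kept >= overlap apart and away from the ends
    while True:
        cuts = np.sort(rng.choice(
            np.arange(overlap + 1, L - 1), size=n_fragments - 1, replace=False))
        if np.all(np.diff(cuts) > overlap):
            break
    bounds = [0, *cuts.tolist(), L]
    frags = []
    for i in range(n_fragments):
        start = bounds[i] - (overlap if i > 0 else 0)
        frags.append(NucSeq(f"{seq.id}_frag{i + 1}",
                            seq.residues[start:bounds[i + 1]]))
    rng.shuffle(frags)
    return frags


def random_nucleotide(length: int, seed: int, id: str = "random") -> NucSeq:
    rng = np.random.default_rng(seed)
    return NucSeq(id, "".join(rng.choice(list("ACGT"), size=length)))


def random_protein(length: int, seed: int, id: str = "random") -> ProtSeq:
    rng = np.random.default_rng(seed)
    return ProtSeq(id, "".join(rng.choice(AA, size=length)))


# ---------------------------------------------------------------------------
# phylogeny

def evolve_on_tree(root_seq: ProtSeq, tree: PhyloTree, rate: float,
                   seed: int) -> MultipleAlignment:
    """Evolve a protein down a tree by Poisson substitution (no indels).

    Each branch of length L receives Poisson(rate * L * n_sites) substitution
    events at uniform positions, each replacing the residue with a uniform
    draw from the other 19 amino acids. The expected Poisson-corrected
    distance between two leaves approximates rate * path length (exact in the
    infinite-alphabet limit; slight downward bias from back substitution).
    """
    if rate < 0:
        raise SimulationError("rate must be >= 0")
    rng = np.random.default_rng(seed)
    sites = len(root_seq.chain)
    taxa, rows = [], []

    def descend(node: TreeNode, residues: list[str]) -> None:
        if node.is_leaf():
            taxa.append(node.label)
            rows.append("".join(residues))
            return
        for child, length in node.children:
            child_res = residues.copy()
            n_events = rng.poisson(rate * length * sites)
            for pos in rng.integers(0, sites, size=n_events):
                current = child_res[pos]
                choices = [a for a in AA if a != current]
                child_res[pos] = choices[rng.integers(0, 19)]
            descend(child, child_res)

    descend(tree.root, list(root_seq.chain))
    order = np.argsort(taxa)
    return MultipleAlignment(tuple(taxa[i] for i in order),
                             tuple(rows[i] for i in order))


# ---------------------------------------------------------------------------
# transport

def simulate_transport_assay(true_papp: dict, cv: float | None = None,
                             n_replicates: int | None = None,
                             config: SimulationConfig | None = None,
                             seed: int | None = None) -> list[TransportWell]:
    """Wells whose measured Papp values are lognormal around per-condition
    truths.

    ``true_papp`` maps (cell_line, direction, inhibitor) -> Papp in cm/s.
    Receiver concentrations are back-computed so that
    ``apparent_permeability`` recovers each drawn Papp exactly.
    """
    cfg = config or SimulationConfig()
    cv = cfg.transport_cv if cv is None else cv
    n = cfg.transport_n if n_replicates is None else n_replicates
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    wells = []
    for (line, direction, inhibitor), papp in sorted(true_papp.items()):
        draws = np.atleast_1d(_lognormal(rng, papp, cv, size=n))
        for rep, p in enumerate(draws):
            receiver = (p * cfg.transport_area_cm2 * cfg.transport_c0_um
                        * cfg.transport_elapsed_s / cfg.transport_volume_ml)
            wells.append(TransportWell(
                cell_line=line, direction=direction, inhibitor=inhibitor,
                receiver_conc=float(receiver),
                receiver_volume=cfg.transport_volume_ml,
                membrane_area=cfg.transport_area_cm2,
                donor_conc_c0=cfg.transport_c0_um,
                elapsed=cfg.transport_elapsed_s,
                replicate_id=rep,
            ))
    return wells


# ---------------------------------------------------------------------------
# pharmacokinetics

def simulate_pk_study(params: PKParams, dose: float | None = None,
                      schedule=None, cv: float | None = None,
                      loq: float | None = None, n_animals: int | None = None,
                      inter_animal_cv: float = 0.0,
                      config: SimulationConfig | None = None,
                      seed: int | None = None) -> list[ConcTimeSeries]:
    """Per-animal plasma profiles from the one-compartment oral model.

    Optional lognormal inter-animal variability on (ka, ke, v_f), then
    multiplicative lognormal residual noise per observation; values below the
    LOQ are censored (flagged, retained).
    """
    cfg = config or SimulationConfig()
    dose = cfg.pk_dose if dose is None else dose
    schedule = np.asarray(cfg.pk_schedule_h if schedule is None else schedule,
                          dtype=float)
    cv = cfg.pk_noise_cv if cv is None else cv
    loq = cfg.pk_loq if loq is None else loq
    n_animals = cfg.pk_n_animals if n_animals is None else n_animals
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    regimen = DoseRegimen(dose=dose)
    out = []
    for i in range(n_animals):
        if inter_animal_cv > 0:
            p = PKParams(
                ka=float(_lognormal(rng, params.ka, inter_animal_cv)),
                ke=float(_lognormal(rng, params.ke, inter_animal_cv)),
                v_f=float(_lognormal(rng, params.v_f, inter_animal_cv)),
            )
        else:
            p = params
        clean = np.asarray(bateman_concentration(p, regimen, schedule))
        if cv > 0:
            noisy = clean * _lognormal(rng, 1.0, cv, size=len(schedule))
        else:
            noisy = clean.copy()
        out.append(ConcTimeSeries.from_observations(
            f"animal_{i + 1}", schedule.tolist(), noisy.tolist(), loq))
    return out


# ---------------------------------------------------------------------------
# qPCR

def simulate_qpcr(fold_changes: dict, calibrator_tissue: str,
                  ct_reference_mean: float | None = None,
                  ct_noise_sd: float | None = None,
                  n_replicates: int | None = None,
                  config: SimulationConfig | None = None,
                  seed: int | None = None) -> list[CtRecord]:
    """Ct tables whose 2^-ddCt analysis recovers the requested fold changes
    in expectation.

    Ct(target) = Ct(reference) + dCt(calibrator) - log2(fold) + noise, with
    additive Gaussian noise of the stated SD on every well.
    """
    cfg = config or SimulationConfig()
    ref_mean = cfg.ct_reference_mean if ct_reference_mean is None else ct_reference_mean
    sd = cfg.ct_noise_sd if ct_noise_sd is None else ct_noise_sd
    n = cfg.ct_n_replicates if n_replicates is None else n_replicates
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    if calibrator_tissue not in fold_changes:
        raise SimulationError("calibrator tissue must have a fold change (1.0)")
    if any(f <= 0 for f in fold_changes.values()):
        raise SimulationError("fold changes must be positive")
    records = []
    for tissue in sorted(fold_changes):
        fold = fold_changes[tissue]
        ct_target = (ref_mean + cfg.ct_calibrator_delta - np.log2(fold)
                     + rng.normal(0, sd, size=n))
        ct_ref = ref_mean + rng.normal(0, sd, size=n)
        records.append(CtRecord(f"s_{tissue}", tissue, "target",
                                tuple(ct_target.tolist())))
        records.append(CtRecord(f"s_{tissue}", tissue, "reference",
                                tuple(ct_ref.tolist())))
    return records
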