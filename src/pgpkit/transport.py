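"""Bidirectional monolayer transport statistics.

Apparent permeability of a drug across a cell monolayer is
Papp = (dQ/dt) / (A * C0), with dQ/dt the rate of appearance of drug in the
receiver chamber, A the filter membrane area and C0 the initial donor
concentration. The efflux ratio ER = Papp(BL->AP) / Papp(AP->BL) exceeds 1
when an apically directed efflux transporter is active, and the net efflux
ratio NER = ER(transporter-expressing line) / ER(parental line) isolates the
transfected transporter's contribution from any endogenous background.

dQ/dt is taken from the single terminal receiver sample (concentration x
receiver volume over elapsed time), matching an assay design with one
sampling point; a multi-timepoint slope can be supplied directly via
``papp_from_slope``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_MEMBRANE_AREA_CM2 = 0.33   # 6.5 mm diameter insert, pi r^2 ~ 0.332
DEFAULT_TEER_THRESHOLD = 150.0     # ohm * cm^2, strict >


class TransportError(ValueError):
    pass


@dataclass(frozen=True)
class TransportWell:
    """One monolayer well: a single terminal receiver measurement.

    Concentrations may be in any single consistent unit (they cancel in
    Papp); volume in mL (= cm^3), area in cm^2, elapsed time in seconds.
    """

    cell_line: str              # 'parental' | 'transfected'
    direction: str              # 'AP-BL' | 'BL-AP'
    inhibitor: bool
    receiver_conc: float
    receiver_volume: float
    membrane_area: float
    donor_conc_c0: float
    elapsed: float
    replicate_id: int = 0

    def __post_init__(self) -> None:
        if self.direction not in ("AP-BL", "BL-AP"):
            raise TransportError(f"unknown direction {self.direction!r}")
        if self.cell_line not in ("parental", "transfected"):
            raise TransportError(f"unknown cell line {self.cell_line!r}")
        if self.receiver_conc < 0:
            raise TransportError("receiver concentration must be >= 0")
        for name in ("receiver_volume", "membrane_area", "donor_conc_c0",
                     "elapsed"):
            if getattr(self, name) <= 0:
                raise TransportError(f"{name} must be positive")


@dataclass(frozen=True)
class PappResult:
    papp: float  # cm/s
    well: TransportWell


@dataclass(frozen=True)
class TeerRecord:
    well_id: str
    teer: float  # ohm * cm^2


def apparent_permeability(well: TransportWell) -> PappResult:
    """Papp from the single terminal receiver sample, cm/s."""
    q = well.receiver_conc * well.receiver_volume      # amount, conc * cm^3
    dq_dt = q / well.elapsed
    papp = dq_dt / (well.membrane_area * well.donor_conc_c0)
    if not math.isfinite(papp):
        raise TransportError("non-finite Papp")
    return PappResult(papp=papp, well=well)


def papp_from_slope(slope_amount_per_s: float, area: float,
                    c0: float) -> float:
    """Papp from an externally fitted receiver-amount slope (multi-timepoint
    designs)."""
    if area <= 0 or c0 <= 0:
        raise TransportError("area and C0 must be positive")
    return slope_amount_per_s / (area * c0)


def efflux_ratio(papp_ba: float, papp_ab: float) -> float:
    """ER = Papp(BL->AP) / Papp(AP->BL)."""
    if papp_ab <= 0:
        raise TransportError("AP->BL Papp must be positive")
    return papp_ba / papp_ab


def net_efflux_ratio(er_transfected: float, er_parental: float) -> float:
    """NER = ER in the transporter-expressing line / ER in the parental line."""
    if er_parental <= 0 or er_transfected <= 0:
        raise TransportError("efflux ratios must be positive")
    return er_transfected / er_parental


def two_sample_t_test(group_a, group_b) -> tuple[float, int, float]:
    """Pooled-variance Student's t-test, two-sided.

    Returns (t, df, p) with df = n_a + n_b - 2. With zero pooled variance the
    test degenerates: p = 1 for equal means, p = 0 otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise TransportError("each group needs n >= 2")
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if sp2 == 0:
        return (0.0, df, 1.0) if diff == 0 else (math.inf, df, 0.0)
    t = diff / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p


def qc_filter_teer(records: list[TeerRecord],
                   threshold: float = DEFAULT_TEER_THRESHOLD) -> list[str]:
    """Ids of wells with TEER strictly above the threshold."""
    return [r.well_id for r in records if r.teer > threshold]


def _sem(values: np.ndarray) -> float:
    return float(values.std(ddof=1) / math.sqrt(len(values))) if len(values) > 1 else float("nan")


def summarize_assay(wells: list[TransportWell],
                    er_mode: str = "per-replicate") -> pd.DataFrame:
    """Per-condition Papp summary with efflux and net efflux ratios.

    One row per (cell_line, inhibitor): mean +/- SEM of Papp in each
    direction, the efflux ratio, and the net efflux ratio against the
    parental line of the same inhibitor condition.

    ``er_mode='per-replicate'`` pairs the two directions by replicate_id,
    forms a ratio per replicate, and averages the ratios (ER carries its own
    SEM). ``er_mode='ratio-of-means'`` divides the direction means instead.
    """
    if er_mode not in ("per-replicate", "ratio-of-means"):
        raise TransportError(f"unknown er_mode {er_mode!r}")
    rows = []
    for well in wells:
        res = apparent_permeability(well)
        rows.append({"cell_line": well.cell_line, "direction": well.direction,
                     "inhibitor": well.inhibitor,
                     "replicate_id": well.replicate_id, "papp": res.papp})
    df = pd.DataFrame(rows)
    out = []
    for (line, inh), grp in df.groupby(["cell_line", "inhibitor"]):
        ab = grp[grp.direction == "AP-BL"].set_index("replicate_id").papp
        ba = grp[grp.direction == "BL-AP"].set_index("replicate_id").papp
        if ab.empty or ba.empty:
            raise TransportError(
                f"condition ({line}, inhibitor={inh}) lacks one direction")
        if er_mode == "per-replicate":
            common = ab.index.intersection(ba.index)
            if common.empty:
                raise TransportError(
                    f"condition ({line}, inhibitor={inh}): no replicate_id "
                    "pairs the two directions")
            ratios = (ba[common] / ab[common]).to_numpy()
            er, er_sem = float(ratios.mean()), _sem(ratios)
        else:
            er, er_sem = efflux_ratio(ba.mean(), ab.mean()), float("nan")
        out.append({
            "cell_line": line, "inhibitor": inh,
            "papp_ab_mean": float(ab.mean()), "papp_ab_sem": _sem(ab.to_numpy()),
            "papp_ba_mean": float(ba.mean()), "papp_ba_sem": _sem(ba.to_numpy()),
            "n_ab": int(len(ab)), "n_ba": int(len(ba)),
            "efflux_ratio": er, "efflux_ratio_sem": er_sem,
        })
    summary = pd.DataFrame(out)
    ner = []
    for _, row in summary.iterrows():
        if row.cell_line == "parental":
            ner.append(float("nan"))
            continue
        ref = summary[(summary.cell_line == "parental")
                      & (summary.inhibitor == row.inhibitor)]
        ner.append(net_efflux_ratio(row.efflux_ratio, float(ref.efflux_ratio.iloc[0]))
                   if len(ref) else float("nan"))
    summary["net_efflux_ratio"] = ner
    return summary


def read_wells_csv(path, *, area: float | None = None) -> list[TransportWell]:
    """Load wells from CSV with columns matching TransportWell fields.

    ``area`` overrides/fills the membrane_area column.
    """
    df = pd.read_csv(path)
    wells = []
    for _, r in df.iterrows():
        wells.append(TransportWell(
            cell_line=str(r.cell_line), direction=str(r.direction),
            inhibitor=bool(r.inhibitor),
            receiver_conc=float(r.receiver_conc),
            receiver_volume=float(r.receiver_volume),
            membrane_area=float(area if area is not None else r.membrane_area),
            donor_conc_c0=float(r.donor_conc_c0),
            elapsed=float(r.elapsed),
            replicate_id=int(r.replicate_id),
        ))
    return wells
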