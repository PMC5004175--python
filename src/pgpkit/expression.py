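"""Relative expression quantification.

mRNA: the 2^-ddCt method. Per tissue, dCt = mean Ct(target) - mean
Ct(reference gene); ddCt = dCt(tissue) - dCt(calibrator tissue); fold
change = 2^-ddCt, so the calibrator is exactly 1 and plate-wide Ct offsets
cancel. Amplification efficiency is taken as exactly 2 (the method's base).

Protein: densitometric band intensities normalized to a loading control and
expressed relative to a calibrator sample. mRNA-protein concordance is a
Pearson (optionally Spearman) correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class ExpressionError(ValueError):
    pass


@dataclass(frozen=True)
class CtRecord:
    sample_id: str
    tissue: str
    gene: str                    # 'target' | 'reference'
    ct_values: tuple[float, ...]  # technical replicates

    def __post_init__(self) -> None:
        if not self.ct_values:
            raise ExpressionError("need at least one Ct replicate")
        if any(not (0 < ct < 45) for ct in self.ct_values):
            raise ExpressionError("Ct values must lie in (0, 45)")
        if self.gene not in ("target", "reference"):
            raise ExpressionError(f"gene must be target/reference, got {self.gene!r}")

    @property
    def mean_ct(self) -> float:
        return float(np.mean(self.ct_values))


@dataclass(frozen=True)
class RelExpression:
    tissue: str
    delta_ct: float
    delta_delta_ct: float
    fold_change: float


@dataclass(frozen=True)
class DensitometryRecord:
    tissue: str
    target_intensity: float
    loading_intensity: float

    def __post_init__(self) -> None:
        if self.target_intensity <= 0 or self.loading_intensity <= 0:
            raise ExpressionError("band intensities must be positive")

    @property
    def relative_protein(self) -> float:
        return self.target_intensity / self.loading_intensity


def delta_delta_ct(records: list[CtRecord],
                   calibrator_tissue: str) -> list[RelExpression]:
    """Fold change per tissue by 2^-ddCt against a calibrator tissue."""
    by_tissue: dict[str, dict[str, list[float]]] = {}
    for rec in records:
        by_tissue.setdefault(rec.tissue, {}).setdefault(rec.gene, []).append(rec.mean_ct)
    if calibrator_tissue not in by_tissue:
        raise ExpressionError(f"calibrator tissue {calibrator_tissue!r} absent")

    def dct(tissue: str) -> float:
        genes = by_tissue[tissue]
        for need in ("target", "reference"):
            if need not in genes:
                raise ExpressionError(f"tissue {tissue!r} lacks {need} gene Ct")
        return float(np.mean(genes["target"]) - np.mean(genes["reference"]))

    dct_cal = dct(calibrator_tissue)
    out = []
    for tissue in by_tissue:
        d = dct(tissue)
        ddct = d - dct_cal
        out.append(RelExpression(tissue=tissue, delta_ct=d,
                                 delta_delta_ct=ddct,
                                 fold_change=2.0 ** (-ddct)))
    return out


def densitometry_ratio(rec: DensitometryRecord,
                       calibrator: DensitometryRecord) -> float:
    """Loading-normalized band intensity relative to a calibrator sample."""
    return rec.relative_protein / calibrator.relative_protein


def correlation(x, y, method: str = "pearson") -> tuple[float, float]:
    """Correlation between paired measurements; returns (r, two-sided p).

    Pearson p comes from t = r * sqrt((n-2)/(1-r^2)) on n-2 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ExpressionError("x and y must be paired (equal length)")
    if len(x) < 3:
        raise ExpressionError("need n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ExpressionError("zero variance: correlation undefined")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ExpressionError(f"unknown method {method!r}")
    return float(r), float(p)


def read_ct_csv(path) -> list[CtRecord]:
    """CSV with columns sample_id, tissue, gene, ct; technical replicates are
    rows sharing (sample_id, tissue, gene)."""
    df = pd.read_csv(path)
    out = []
    for (sample, tissue, gene), grp in df.groupby(
            ["sample_id", "tissue", "gene"], sort=True):
        out.append(CtRecord(str(sample), str(tissue), str(gene),
                            tuple(float(v) for v in grp.ct)))
    return out


def fold_changes_frame(rels: list[RelExpression]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"tissue": r.tissue, "delta_ct": r.delta_ct,
          "delta_delta_ct": r.delta_delta_ct, "fold_change": r.fold_change}
         for r in rels]
    ).sort_values("tissue").reset_index(drop=True)
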