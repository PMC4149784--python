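"""Abundance normalisation, replicate fold changes and the Fra2 statistic.

The analysis operates on RPKM abundances compared between a test group and
a reference group (wild-type untreated).  Per gene, each test replicate is
divided by the (floored) reference-group mean; the replicate ratios are
summarised by their mean and sample standard deviation.  Down-regulated
genes are summarised on the reciprocal (fold-decrease) scale so that a
5-fold repression reads as 5.0, and plotted as a *signed fold*: +fold for
up-regulation, -fold for down (no values strictly inside (-1, 1)).

A change is called significant when the fold change minus one standard
deviation still exceeds the threshold (default 2-fold) on the direction
scale — the strict reading of "significant if 1 SD > 2-fold change".

The Fra2-dependence fraction partitions a gene's total response to the
ionophore into the part already present as de-repression in an untreated
*fra2*delta mutant (Fra2-dependent) and the remainder:

    f_dep = (S_untreated - 1) / (S_treated - 1)

with S the linear fold change of the *fra2*delta sample versus wild-type
untreated cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "compute_rpkm",
    "fold_changes",
    "apply_significance",
    "threshold_table",
    "fra2_fraction",
    "signed_to_linear",
    "linear_to_signed",
]

FC_COLUMNS = ["mean_fc", "sd_fc", "direction", "fold", "fold_sd",
              "signed_fold", "significant", "low_reference"]


@dataclass
class ExpressionMatrix:
    """Gene x sample abundance matrix with its sample sheet.

    ``values``: DataFrame, genes as index, samples as columns, >= 0.
    ``samples``: DataFrame indexed by sample id with columns genotype,
    condition, replicate.  ``unit`` is ``"counts"`` or ``"RPKM"``; raw
    counts additionally carry per-gene lengths (nt) and per-sample total
    mapped reads for RPKM conversion.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    unit: str = "RPKM"
    gene_lengths: pd.Series | None = None
    total_reads: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("abundance values must be non-negative")
        missing = set(self.samples.index) - set(self.values.columns)
        if missing:
            raise ValueError(f"samples in sheet but not in matrix: {sorted(missing)}")
        for col in ("genotype", "condition", "replicate"):
            if col not in self.samples.columns:
                raise ValueError(f"sample sheet lacks column {col!r}")
        if self.unit == "counts":
            if self.gene_lengths is not None and (self.gene_lengths <= 0).any():
                raise ValueError("gene lengths must be positive")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def group_columns(self, genotype: str, condition: str) -> list[str]:
        sheet = self.samples
        cols = sheet.index[(sheet["genotype"] == genotype)
                           & (sheet["condition"] == condition)]
        return list(cols)

    def group(self, genotype: str, condition: str) -> pd.DataFrame:
        cols = self.group_columns(genotype, condition)
        if not cols:
            raise KeyError(f"no samples for genotype={genotype!r}, "
                           f"condition={condition!r}")
        return self.values[cols]

    def write(self, values_path: str | Path, samples_path: str | Path) -> None:
        self.values.rename_axis("gene").to_csv(values_path, sep="\t")
        self.samples.rename_axis("sample").to_csv(samples_path, sep="\t")

    @classmethod
    def read(cls, values_path: str | Path, samples_path: str | Path,
             unit: str = "RPKM") -> "ExpressionMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col=0, comment="#")
        samples = pd.read_csv(samples_path, sep="\t", index_col=0, comment="#")
        return cls(values=values, samples=samples, unit=unit)


def compute_rpkm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Reads-per-kilobase-per-million normalisation of a raw count matrix.

    RPKM = count * 1e9 / (gene_length_nt * total_mapped_reads).
    """
    if matrix.unit != "counts":
        raise ValueError("compute_rpkm expects a counts matrix")
    if matrix.gene_lengths is None or matrix.total_reads is None:
        raise ValueError("counts matrix must carry gene lengths and per-sample totals")
    lengths = matrix.gene_lengths.reindex(matrix.values.index)
    if lengths.isna().any():
        raise ValueError("gene lengths missing for some genes")
    totals = matrix.total_reads.reindex(matrix.values.columns)
    if totals.isna().any() or (totals <= 0).any():
        raise ValueError("positive total mapped reads required for every sample")
    rpkm = matrix.values.mul(1e9).div(lengths, axis=0).div(totals, axis=1)
    return ExpressionMatrix(values=rpkm, samples=matrix.samples.copy(), unit="RPKM")


def fold_changes(matrix: ExpressionMatrix,
                 reference: tuple[str, str],
                 test: tuple[str, str],
                 floor: float = 0.1,
                 significance_threshold: float | None = 2.0) -> pd.DataFrame:
    """Per-gene replicate fold changes of ``test`` versus ``reference``.

    Each test replicate is divided by the reference-group mean (floored at
    ``floor`` to tame negligibly expressed genes, which are flagged
    ``low_reference``).  Ratios are summarised as mean and sample SD; for
    down-regulated genes (mean ratio < 1) the summary is recomputed on the
    reciprocal scale so ``fold`` is always the fold change *in the direction
    of the effect*.  ``signed_fold`` is +fold for up, -fold for down, +1 for
    no change.

    Returns a DataFrame indexed by gene with columns
    mean_fc, sd_fc, direction, fold, fold_sd, signed_fold, significant,
    low_reference; reference/test/floor recorded in ``.attrs``.
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    ref = matrix.group(*reference)
    tst = matrix.group(*test)

    ref_mean = ref.mean(axis=1)
    low = ref_mean < floor
    ref_mean = ref_mean.clip(lower=floor)

    ratios = tst.div(ref_mean, axis=0)
    mean_fc = ratios.mean(axis=1)
    sd_fc = ratios.std(axis=1, ddof=1).fillna(0.0)

    direction = pd.Series(np.where(mean_fc > 1, "up",
                                   np.where(mean_fc < 1, "down", "none")),
                          index=mean_fc.index)
    # down-regulated genes: summarise replicate ratios on the reciprocal scale
    recip = 1.0 / ratios.where(ratios > 0)
    fold = mean_fc.copy()
    fold_sd = sd_fc.copy()
    down = direction == "down"
    fold[down] = recip.mean(axis=1)[down]
    fold_sd[down] = recip.std(axis=1, ddof=1).fillna(0.0)[down]

    signed = np.where(direction == "up", fold,
                      np.where(direction == "down", -fold, 1.0))
    table = pd.DataFrame({
        "mean_fc": mean_fc,
        "sd_fc": sd_fc,
        "direction": direction,
        "fold": fold,
        "fold_sd": fold_sd,
        "signed_fold": signed,
        "significant": False,
        "low_reference": low,
    })
    table.index.name = "gene"
    table.attrs.update(reference=reference, test=test, floor=floor)
    if significance_threshold is not None:
        table = apply_significance(table, threshold=significance_threshold)
    return table


def apply_significance(table: pd.DataFrame, threshold: float = 2.0) -> pd.DataFrame:
    """Flag significant fold changes: fold minus one SD must exceed threshold.

    On the direction scale — a gene is significant iff
    ``fold - fold_sd > threshold`` and its direction is not 'none'.
    """
    if threshold <= 1:
        raise ValueError("significance threshold must exceed 1-fold")
    out = table.copy()
    out["significant"] = ((out["direction"] != "none")
                          & (out["fold"] - out["fold_sd"] > threshold))
    out.attrs.update(table.attrs, significance_threshold=threshold)
    return out


def threshold_table(table: pd.DataFrame, cutoff: float = 4.5,
                    direction: str = "up") -> pd.DataFrame:
    """Significant genes changed at least ``cutoff``-fold in ``direction``,
    sorted by descending fold (the strong-responder table)."""
    if cutoff < 1:
        raise ValueError("cutoff must be >= 1-fold")
    sel = table[(table["direction"] == direction)
                & table["significant"]
                & (table["fold"] >= cutoff)]
    return sel.sort_values("fold", ascending=False)


def signed_to_linear(signed: float | np.ndarray) -> np.ndarray:
    """Signed fold (+f up / -f down) to linear fold relative to 1.

    +5 -> 5.0 (5-fold up), -5 -> 0.2 (5-fold down), +1 -> 1.0.
    """
    s = np.asarray(signed, dtype=float)
    return np.where(s >= 1, s, -1.0 / s)


def linear_to_signed(linear: float | np.ndarray) -> np.ndarray:
    """Linear fold relative to 1 to the signed-fold plotting convention."""
    x = np.asarray(linear, dtype=float)
    return np.where(x >= 1, x, -1.0 / x)


def fra2_fraction(fc_fra2_untreated: pd.DataFrame,
                  fc_fra2_treated: pd.DataFrame,
                  tolerance: float = 0.1) -> pd.DataFrame:
    """Fra2-dependent fraction of each gene's response to the ionophore.

    Both tables must be fold changes of *fra2*delta samples (untreated and
    ionophore-treated) against the same wild-type untreated reference.
    With S the linear fold change, ``f_dep = (S_untreated-1)/(S_treated-1)``;
    genes whose treated response is within ``tolerance`` of no change are
    flagged ``undefined`` and not divided.  ``out_of_range`` marks fractions
    outside [0, 1] (possible under noise or non-monotone regulation).
    """
    if not fc_fra2_untreated.index.equals(fc_fra2_treated.index):
        raise ValueError("fold-change tables cover different gene sets")
    s_unt = signed_to_linear(fc_fra2_untreated["signed_fold"].to_numpy())
    s_trt = signed_to_linear(fc_fra2_treated["signed_fold"].to_numpy())
    undefined = np.abs(s_trt - 1.0) < tolerance
    f_dep = np.full(s_unt.shape, np.nan)
    np.divide(s_unt - 1.0, s_trt - 1.0, out=f_dep, where=~undefined)
    out = pd.DataFrame({
        "f_dep": f_dep,
        "f_indep": 1.0 - f_dep,
        "undefined": undefined,
        "out_of_range": ~undefined & ((f_dep < 0) | (f_dep > 1)),
    }, index=fc_fra2_untreated.index)
    out.index.name = "gene"
    return out
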