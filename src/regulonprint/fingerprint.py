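"""Two-condition regulon fingerprint and candidate-target nomination.

Plotting each strongly responding gene at
(x = signed fold under copper + ionophore, y = signed fold under copper
alone), both versus untreated wild type, separates the two physiological
programmes: copper-regulon genes (Ace1, Mac1) respond identically in both
conditions and fall on the diagonal, while iron-regulon genes (Aft1/2,
Cth2) respond only when the ionophore induces functional iron deficiency
and fall on a near-horizontal line.  Unweighted ordinary least squares of
y on x within each group quantifies the two slopes.

Candidate targets are nominated by joining the expression calls with motif
scans: genes of unknown metalloregulation, significantly down at least
2-fold with an ARE in the 3'-UTR (candidate Cth2 targets) or significantly
up at least 2-fold with an Aft1 consensus site in the promoter (candidate
Aft1/2 targets).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupLine",
    "CandidateReport",
    "assemble_fingerprint",
    "fit_group_lines",
    "nominate_candidates",
    "plot_fingerprint",
    "IRON_CLASSES",
    "COPPER_CLASSES",
]

IRON_CLASSES = frozenset({"Aft", "Cth2"})
COPPER_CLASSES = frozenset({"Ace1", "Mac1"})


@dataclass
class GroupLine:
    """Best-fit line through one regulon group of the fingerprint."""

    group: str
    slope: float
    intercept: float
    n: int
    residual_sd: float

    def to_dict(self) -> dict:
        return {"group": self.group, "slope": self.slope,
                "intercept": self.intercept, "n": self.n,
                "residual_sd": self.residual_sd}


def assemble_fingerprint(fc_cubpq: pd.DataFrame, fc_cuonly: pd.DataFrame,
                         annotation: pd.Series,
                         min_fold: float = 2.0) -> pd.DataFrame:
    """One fingerprint point per gene responding >= ``min_fold`` to the
    ionophore condition (significantly), on signed-fold axes.

    Both fold-change tables must cover the same gene universe and be
    computed against the same (wild-type untreated) reference.  Classes come
    from ``annotation``; genes without an entry are 'unknown'.
    """
    if not fc_cubpq.index.equals(fc_cuonly.index):
        raise ValueError("fold-change tables cover different gene universes")
    keep = fc_cubpq["significant"] & (fc_cubpq["fold"] >= min_fold)
    points = pd.DataFrame({
        "x": fc_cubpq.loc[keep, "signed_fold"],
        "y": fc_cuonly.loc[keep, "signed_fold"],
        "regulon": annotation.reindex(fc_cubpq.index[keep]).fillna("unknown"),
    })
    points.index.name = "gene"
    points.attrs["min_fold"] = min_fold
    return points


def fit_group_lines(points: pd.DataFrame,
                    iron_classes: Iterable[str] = IRON_CLASSES,
                    copper_classes: Iterable[str] = COPPER_CLASSES,
                    ) -> dict[str, GroupLine]:
    """OLS y-on-x lines through the iron- and copper-regulated points.

    Yap5 and unknown-class points are members of neither group and are
    excluded from both fits.
    """
    lines: dict[str, GroupLine] = {}
    for group, classes in (("iron", set(iron_classes)),
                           ("copper", set(copper_classes))):
        sub = points[points["regulon"].isin(classes)]
        if len(sub) < 2:
            raise ValueError(f"need at least 2 points to fit the {group} line")
        x, y = sub["x"].to_numpy(), sub["y"].to_numpy()
        if np.ptp(x) == 0:
            raise ValueError(f"degenerate x variance in the {group} group")
        fit = stats.linregress(x, y)
        resid = y - (fit.intercept + fit.slope * x)
        dof = max(len(sub) - 2, 1)
        lines[group] = GroupLine(group=group, slope=float(fit.slope),
                                 intercept=float(fit.intercept), n=len(sub),
                                 residual_sd=float(np.sqrt(resid @ resid / dof)))
    return lines


@dataclass
class CandidateReport:
    """Nominated candidate targets with their supporting motif matches."""

    cth2_candidates: list[str]
    aft_candidates: list[str]
    support: pd.DataFrame  # motif matches of nominated genes

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "cth2_candidates": self.cth2_candidates,
            "aft_candidates": self.aft_candidates,
            "support": self.support.to_dict(orient="records"),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def nominate_candidates(points: pd.DataFrame, matches: pd.DataFrame,
                        annotation: pd.Series | None = None,
                        min_fold: float = 2.0,
                        are_name: str = "ARE",
                        aft_name: str = "Aft1") -> CandidateReport:
    """Join expression calls with motif hits to nominate unknown-class targets.

    Candidate Cth2 targets: unknown class, significantly down >= min_fold
    under the ionophore, >= 1 ARE match in the 3'-UTR.  Candidate Aft
    targets: unknown class, up >= min_fold, >= 1 Aft-site match in the
    promoter.  ``points`` must come from :func:`assemble_fingerprint` (its
    rows are already the significant >= 2-fold responders).
    """
    regulon = points["regulon"] if annotation is None \
        else annotation.reindex(points.index).fillna("unknown")
    unknown = points.index[regulon == "unknown"]

    def hits(gene, consensus_name, region):
        m = matches[(matches["gene"] == gene)
                    & (matches["consensus"] == consensus_name)
                    & (matches["region"] == region)]
        return m

    down = [g for g in unknown if points.at[g, "x"] <= -min_fold]
    up = [g for g in unknown if points.at[g, "x"] >= min_fold]
    cth2, aft, support = [], [], []
    for g in down:
        m = hits(g, are_name, "utr3")
        if len(m):
            cth2.append(g)
            support.append(m)
    for g in up:
        m = hits(g, aft_name, "promoter")
        if len(m):
            aft.append(g)
            support.append(m)
    support_df = (pd.concat(support, ignore_index=True) if support
                  else matches.iloc[0:0].copy())
    return CandidateReport(cth2_candidates=sorted(cth2),
                           aft_candidates=sorted(aft), support=support_df)


def plot_fingerprint(points: pd.DataFrame,
                     lines: dict[str, GroupLine] | None = None,
                     path: str | Path | None = None):
    """Scatter of the two-condition fingerprint with the group lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    palette = {"Aft": "tab:red", "Cth2": "tab:red", "Ace1": "tab:blue",
               "Mac1": "tab:blue", "Yap5": "tab:green", "unknown": "0.6"}
    fig, ax = plt.subplots(figsize=(5, 5))
    for cls, sub in points.groupby("regulon"):
        filled = cls in IRON_CLASSES | COPPER_CLASSES
        ax.scatter(sub["x"], sub["y"], s=22,
                   c=palette.get(cls, "0.6") if filled else "none",
                   edgecolors=palette.get(cls, "0.6"), label=cls)
    if lines:
        xs = np.linspace(points["x"].min(), points["x"].max(), 50)
        colors = {"iron": "tab:red", "copper": "tab:blue"}
        for name, line in lines.items():
            ax.plot(xs, line.intercept + line.slope * xs,
                    color=colors.get(name, "k"), lw=1.2,
                    label=f"{name} (slope {line.slope:.2f})")
    ax.axhline(0, color="0.8", lw=0.5)
    ax.axvline(0, color="0.8", lw=0.5)
    ax.set_xlabel("signed fold change, Cu + ionophore")
    ax.set_ylabel("signed fold change, Cu alone")
    ax.legend(fontsize=7, loc="best")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
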