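"""Regulon class annotation: gene -> regulator.

Classes used throughout the package:

* ``Aft`` — Aft1/2 low-iron regulons (iron uptake/mobilisation),
* ``Cth2`` — Cth2 iron-sparing targets (ARE-mediated transcript decay),
* ``Ace1`` — high-copper metallothionein induction,
* ``Mac1`` — low-copper uptake regulon,
* ``Yap5`` — high-iron sequestration regulon,
* ``unknown`` — no previously characterised metalloregulation.

``DEFAULT_REGULONS`` ships the assignments for the named strong responders
of the study system (regulon memberships as established by Gross et al.,
Puig et al. and the Aft/Ace compilations), so candidate nomination can
exclude genes of known metalloregulation out of the box.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

__all__ = ["REGULON_CLASSES", "DEFAULT_REGULONS", "make_annotation",
           "read_annotation", "write_annotation"]

REGULON_CLASSES = ("Aft", "Cth2", "Ace1", "Mac1", "Yap5", "unknown")

DEFAULT_REGULONS: Mapping[str, str] = {
    # Aft1/2 regulon (low iron)
    "FIT1": "Aft", "FIT2": "Aft", "FIT3": "Aft", "ARN1": "Aft", "ARN2": "Aft",
    "SIT1": "Aft", "FTR1": "Aft", "FET3": "Aft", "CCC2": "Aft", "HMX1": "Aft",
    "BIO5": "Aft", "CTH2": "Aft", "TIS11": "Aft",
    # Ace1 regulon (high copper)
    "CUP1-1": "Ace1", "CUP1-2": "Ace1", "CRS5": "Ace1",
    # Mac1 regulon (low copper)
    "CTR1": "Mac1", "FRE7": "Mac1", "REE1": "Mac1", "IRC7": "Mac1",
    # Cth2 targets (iron sparing)
    "LEU1": "Cth2",
    # Yap5 regulon (high iron)
    "GRX4": "Yap5", "CCC1": "Yap5", "TYW1": "Yap5",
}


def make_annotation(genes: Iterable[str],
                    known: Mapping[str, str] | None = None) -> pd.Series:
    """Class label per gene; genes absent from ``known`` become 'unknown'."""
    known = DEFAULT_REGULONS if known is None else known
    ann = pd.Series({g: known.get(g, "unknown") for g in genes}, name="regulon")
    bad = set(ann.unique()) - set(REGULON_CLASSES)
    if bad:
        raise ValueError(f"unknown regulon classes: {sorted(bad)}")
    ann.index.name = "gene"
    return ann


def read_annotation(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", comment="#")
    return make_annotation(df.iloc[:, 0],
                           dict(zip(df.iloc[:, 0], df.iloc[:, 1])))


def write_annotation(annotation: pd.Series, path) -> None:
    annotation.rename_axis("gene").to_csv(path, sep="\t")
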