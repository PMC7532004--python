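"""Photolabeling-efficiency quantification from chromatographic area pairs.

A photoreactive neurosteroid analogue adducts a small fraction of a target
peptide; extracted-ion chromatograms of the labeled and unlabeled forms give
areas from which the labeling efficiency is the labeled fraction.  Competition
experiments (reagent with/without excess unlabeled competitor) are summarized
as percent prevention of labeling.  Raw chromatogram integration and mass
spectral identification are upstream; the input here is the area table
(``peptide_id,condition,labeled_area,unlabeled_area,replicate``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PeptideAreas",
    "labeling_efficiency",
    "percent_prevention",
    "summarize_efficiencies",
]


@dataclass(frozen=True)
class PeptideAreas:
    """Labeled/unlabeled extracted-chromatogram areas for one peptide."""

    peptide_id: str
    labeled_area: float
    unlabeled_area: float
    condition: str = ""

    def __post_init__(self) -> None:
        if self.labeled_area < 0 or self.unlabeled_area < 0:
            raise ValueError("areas must be non-negative")
        if self.labeled_area + self.unlabeled_area == 0:
            raise ValueError("labeled and unlabeled areas cannot both be zero")


def labeling_efficiency(areas: PeptideAreas) -> float:
    """Percent of the peptide pool carrying the label: 100 * L / (L + U)."""
    return 100.0 * areas.labeled_area / (areas.labeled_area + areas.unlabeled_area)


def percent_prevention(
    efficiency_control: float, efficiency_with_competitor: float
) -> float:
    """Percent reduction of labeling efficiency by a competitor ligand."""
    if efficiency_control <= 0:
        raise ValueError("control labeling efficiency must be positive")
    if efficiency_with_competitor < 0:
        raise ValueError("labeling efficiency must be non-negative")
    return 100.0 * (1.0 - efficiency_with_competitor / efficiency_control)


def summarize_efficiencies(table: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SEM labeling efficiency per peptide and condition.

    ``table`` follows the area-table CSV schema.  Group-comparison statistics
    are deliberately descriptive only.
    """
    required = {"peptide_id", "condition", "labeled_area", "unlabeled_area"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"area table missing columns: {sorted(missing)}")
    df = table.copy()
    df["efficiency_percent"] = 100.0 * df["labeled_area"] / (
        df["labeled_area"] + df["unlabeled_area"]
    )
    out = (
        df.groupby(["peptide_id", "condition"])["efficiency_percent"]
        .agg(
            mean="mean",
            sem=lambda s: s.std(ddof=1) / np.sqrt(len(s)) if len(s) > 1 else np.nan,
            n="count",
        )
        .reset_index()
    )
    return out
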