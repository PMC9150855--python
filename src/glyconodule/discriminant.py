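"""Per-glycan ROC–AUC discrimination between WT and mutant section groups.

AUC here is oriented so that values above 0.5 mean the glycan is more intense
in the mutant group: ``AUC = P(X_mut > X_wt) + 0.5 * P(X_mut = X_wt)``,
computed by the midrank (Mann–Whitney) formula. Calls use the thresholds
standard in tissue-microarray glycan imaging — AUC > 0.6 up-regulated,
< 0.4 down-regulated, the 0.4–0.6 band non-significant — and discriminative
quality bands (poor/fair/good/excellent) are assigned on max(AUC, 1−AUC) so
both directions are banded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .glycan_model import GlycanRecord, SODIUM_ADDUCT, AdductSpec, adduct_mz
from .msi_io import MsiDataset, section_intensity_vector

__all__ = [
    "DiscriminantRecord",
    "roc_auc",
    "classify_change",
    "quality_band",
    "compare_groups",
    "discriminant_table",
]

Call = Literal["up_in_mutant", "down_in_mutant", "nonsignificant"]
Band = Literal["poor", "fair", "good", "excellent", "none"]

#: Change-call thresholds on AUC.
AUC_UP_THRESHOLD = 0.6
AUC_DOWN_THRESHOLD = 0.4

#: Quality-band edges on the effective AUC max(auc, 1-auc).
BAND_EDGES: tuple[tuple[float, str], ...] = (
    (0.9, "excellent"),
    (0.8, "good"),
    (0.7, "fair"),
    (0.6, "poor"),
)


@dataclass(frozen=True)
class DiscriminantRecord:
    glycan_id: str
    composition: str
    auc: float
    call: Call
    band: Band
    n_wt: int
    n_mut: int


def roc_auc(mut_values: Sequence[float], wt_values: Sequence[float]) -> float:
    """Midrank Mann–Whitney AUC: P(mut > wt) with ties counted half.

    Exactly satisfies roc_auc(a, b) + roc_auc(b, a) == 1.
    """
    mut = np.asarray(mut_values, dtype=float)
    wt = np.asarray(wt_values, dtype=float)
    if mut.size == 0 or wt.size == 0:
        raise ValueError("both groups must be non-empty")
    n_mut, n_wt = mut.size, wt.size
    ranks = rankdata(np.concatenate([mut, wt]), method="average")
    rank_sum_mut = ranks[:n_mut].sum()
    u = rank_sum_mut - n_mut * (n_mut + 1) / 2.0
    return float(u / (n_mut * n_wt))


def classify_change(auc: float) -> Call:
    """Change call from AUC; boundaries 0.4/0.6 are inclusive to nonsignificant."""
    if not 0.0 <= auc <= 1.0:
        raise ValueError(f"AUC must be in [0, 1], got {auc}")
    if auc > AUC_UP_THRESHOLD:
        return "up_in_mutant"
    if auc < AUC_DOWN_THRESHOLD:
        return "down_in_mutant"
    return "nonsignificant"


def quality_band(auc: float) -> Band:
    """Discriminative-quality band on the effective AUC max(auc, 1−auc)."""
    if not 0.0 <= auc <= 1.0:
        raise ValueError(f"AUC must be in [0, 1], got {auc}")
    effective = max(auc, 1.0 - auc)
    for edge, name in BAND_EDGES:
        if effective >= edge:
            return name  # type: ignore[return-value]
    return "none"


def compare_groups(
    dataset: MsiDataset,
    glycans: Sequence[GlycanRecord],
    tol_ppm: float = 3.0,
    unit: Literal["pixel", "section"] = "pixel",
    adduct: AdductSpec = SODIUM_ADDUCT,
) -> list[DiscriminantRecord]:
    """Per-glycan AUC between mutant and WT groups.

    ``unit='pixel'`` pools occupied-pixel intensities across each group's
    sections (the default, mirroring ROC over all spectra); ``'section'``
    compares section-mean intensities. Output is sorted by |AUC − 0.5|
    descending.
    """
    wt_sections = dataset.sections_in_group("WT")
    mut_sections = dataset.sections_in_group("MUT")
    if not wt_sections or not mut_sections:
        raise ValueError("dataset must contain at least one section per group")
    if unit not in ("pixel", "section"):
        raise ValueError(f"unit must be 'pixel' or 'section', got {unit!r}")
    records: list[DiscriminantRecord] = []
    for g in glycans:
        mz = adduct_mz(g.neutral_mass, adduct)

        def group_values(sections):
            vecs = [
                section_intensity_vector(dataset, s.label, mz, tol_ppm)
                for s in sections
            ]
            if unit == "pixel":
                return np.concatenate(vecs)
            return np.array([v.mean() for v in vecs])

        wt = group_values(wt_sections)
        mut = group_values(mut_sections)
        auc = roc_auc(mut, wt)
        records.append(
            DiscriminantRecord(
                glycan_id=g.id,
                composition=str(g.composition),
                auc=auc,
                call=classify_change(auc),
                band=quality_band(auc),
                n_wt=len(wt),
                n_mut=len(mut),
            )
        )
    records.sort(key=lambda r: abs(r.auc - 0.5), reverse=True)
    return records


def discriminant_table(records: Sequence[DiscriminantRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "glycan": r.glycan_id,
                "composition": r.composition,
                "auc": r.auc,
                "call": r.call,
                "band": r.band,
                "n_wt": r.n_wt,
                "n_mut": r.n_mut,
            }
            for r in records
        ]
    )


def write_discriminant_csv(
    records: Sequence[DiscriminantRecord], path: str | Path
) -> None:
    discriminant_table(records).to_csv(path, index=False)
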