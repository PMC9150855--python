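"""Precursor → product intensity ratios of late N-glycan maturation.

Two late-stage reactions are probed at composition level:

* **truncation** — vacuolar/apoplastic hexosaminidases trim antennal GlcNAc,
  converting complex precursors into paucimannose products;
* **conversion** — trans-Golgi Lewis-a decoration extends antennae with
  Gal + Fuc.

For a (product, precursor) pair the reported quantity is the ratio of mean
pixel intensities over the listed sections, computed per genotype, plus the
WT/MUT fold of those ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .glycan_model import (
    Composition,
    SODIUM_ADDUCT,
    AdductSpec,
    adduct_mz,
    neutral_mass,
    parse_composition,
)
from .msi_io import MsiDataset, section_intensity_vector

__all__ = [
    "RatioPair",
    "DEFAULT_RATIO_PAIRS",
    "pair_ratio",
    "genotype_ratio_table",
    "read_pairs_csv",
]

PairLabel = Literal["truncation", "conversion"]


@dataclass(frozen=True)
class RatioPair:
    """One biosynthetic product/precursor pair."""

    product: Composition
    precursor: Composition
    label: PairLabel

    def __post_init__(self) -> None:
        if self.product == self.precursor:
            raise ValueError("product and precursor must differ")


#: Default pair set covering both late-maturation branches:
#: truncation (complex precursor -> paucimannose product sharing core
#: modifications) and Lewis-a conversion (same-antenna precursor -> Lewis-a
#: product).
DEFAULT_RATIO_PAIRS: tuple[RatioPair, ...] = (
    RatioPair(Composition(3, 2, 1, 1), Composition(3, 3, 1, 1), "truncation"),
    RatioPair(Composition(3, 2, 0, 1), Composition(3, 3, 0, 1), "truncation"),
    RatioPair(Composition(4, 3, 2, 1), Composition(3, 3, 1, 1), "conversion"),
    RatioPair(Composition(5, 4, 3, 1), Composition(4, 4, 2, 1), "conversion"),
)


def pair_ratio(
    dataset: MsiDataset,
    sections: Sequence[str],
    pair: RatioPair,
    tol_ppm: float = 3.0,
    mask: np.ndarray | None = None,
    adduct: AdductSpec = SODIUM_ADDUCT,
    statistic: Literal["mean", "median"] = "mean",
) -> float:
    """Product/precursor ratio of pixel-intensity means over sections.

    A zero-mean precursor makes the ratio undefined; NaN is returned (batch
    callers flag the row rather than aborting).
    """
    if not sections:
        raise ValueError("no sections given")
    reduce = np.mean if statistic == "mean" else np.median

    def pooled(c: Composition) -> float:
        mz = adduct_mz(neutral_mass(c), adduct)
        chunks = []
        for label in sections:
            vec = section_intensity_vector(dataset, label, mz, tol_ppm)
            if mask is not None:
                sec = dataset.section(label)
                if mask.shape != (sec.height, sec.width):
                    raise ValueError("mask shape does not match section grid")
                keep = mask[sec.coords[:, 1], sec.coords[:, 0]]
                vec = vec[keep]
            chunks.append(vec)
        return float(reduce(np.concatenate(chunks)))

    precursor_mean = pooled(pair.precursor)
    if precursor_mean <= 0:
        return float("nan")
    return pooled(pair.product) / precursor_mean


def genotype_ratio_table(
    dataset: MsiDataset,
    pairs: Sequence[RatioPair] = DEFAULT_RATIO_PAIRS,
    tol_ppm: float = 3.0,
    adduct: AdductSpec = SODIUM_ADDUCT,
    statistic: Literal["mean", "median"] = "mean",
) -> pd.DataFrame:
    """Per-pair ratios in each genotype and their WT/MUT fold.

    Rows with an undefined ratio (zero precursor signal) carry NaN and
    ``flagged=True``; the run completes regardless.
    """
    wt = [s.label for s in dataset.sections_in_group("WT")]
    mut = [s.label for s in dataset.sections_in_group("MUT")]
    if not wt or not mut:
        raise ValueError("dataset must contain both WT and MUT sections")
    rows = []
    for pair in pairs:
        r_wt = pair_ratio(dataset, wt, pair, tol_ppm, adduct=adduct, statistic=statistic)
        r_mut = pair_ratio(dataset, mut, pair, tol_ppm, adduct=adduct, statistic=statistic)
        fold = r_wt / r_mut if (np.isfinite(r_wt) and np.isfinite(r_mut) and r_mut > 0) else float("nan")
        rows.append(
            {
                "product": str(pair.product),
                "precursor": str(pair.precursor),
                "label": pair.label,
                "wt_ratio": r_wt,
                "mut_ratio": r_mut,
                "wt_over_mut_fold": fold,
                "flagged": not np.isfinite(fold),
            }
        )
    return pd.DataFrame(rows)


def read_pairs_csv(path: str | Path) -> list[RatioPair]:
    """Load a pairs config CSV with columns product, precursor, label."""
    df = pd.read_csv(path)
    return [
        RatioPair(
            parse_composition(row["product"]),
            parse_composition(row["precursor"]),
            row["label"],
        )
        for _, row in df.iterrows()
    ]
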