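"""Per-composition MSI annotation: MSM scoring and decoy-adduct FDR.

Each candidate (composition, adduct) pair is scored per section by the
metabolite-signal-match (MSM) score, the product of three components in
[0, 1]:

* **spectral** — agreement between theoretical and observed relative
  isotopologue intensities (1 minus total variation distance);
* **spatial** — abundance-weighted colocalization (Pearson correlation,
  clipped at 0) of each isotopologue ion image with the principal image;
* **chaos** — spatial structure of the principal image, measured by counting
  connected components across intensity level sets: a coherent anatomical
  blob scores near 1, salt-and-pepper noise near 0.

False-discovery rates come from re-scoring the database with implausible
("decoy") adducts and comparing the score distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .glycan_model import (
    DECOY_ADDUCTS,
    SODIUM_ADDUCT,
    AdductSpec,
    GlycanRecord,
    adduct_mz,
    isotope_pattern,
)
from .msi_io import IonImage, MsiDataset, extract_ion_image

logger = logging.getLogger("glyconodule")

__all__ = [
    "AnnotationResult",
    "DecoySpec",
    "spectral_score",
    "spatial_score",
    "chaos_score",
    "annotate",
    "fdr_estimate",
    "annotation_table",
    "FDR_REPORTING_LEVELS",
]

#: FDR levels at which annotations are conventionally reported.
FDR_REPORTING_LEVELS: tuple[float, ...] = (0.05, 0.1, 0.2, 0.5)


@dataclass
class AnnotationResult:
    """MSM score components for one (section, composition, adduct) triple."""

    glycan_id: str
    composition: str
    section: str
    adduct: str
    spectral: float
    spatial: float
    chaos: float
    msm: float
    fdr: float = float("nan")
    absent: bool = False
    principal_image: IonImage | None = field(default=None, repr=False, compare=False)


@dataclass(frozen=True)
class DecoySpec:
    """Decoy-adduct FDR configuration.

    ``adducts`` are implausible mass deltas (disjoint from the target adduct
    by far more than the ppm tolerance at all database masses); for each
    target annotation, ``draws_per_target`` decoy adducts are sampled with a
    fixed seed.
    """

    adducts: tuple[AdductSpec, ...] = DECOY_ADDUCTS
    draws_per_target: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.draws_per_target < 1:
            raise ValueError("draws_per_target must be >= 1")
        if not self.adducts:
            raise ValueError("decoy adduct list is empty")


# ---------------------------------------------------------------------------
# Score components
# ---------------------------------------------------------------------------

def spectral_score(theoretical: Sequence[float], observed: Sequence[float]) -> float:
    """Isotope-envelope agreement: 1 − total-variation distance in [0, 1].

    Both vectors are normalized to sum 1 over the k compared peaks. An
    all-zero observed envelope scores 0 (the ion is absent).
    """
    p = np.asarray(theoretical, dtype=float)
    q = np.asarray(observed, dtype=float)
    if p.shape != q.shape:
        raise ValueError("theoretical and observed envelopes differ in length")
    if len(p) < 2:
        raise ValueError("need at least 2 isotopologue peaks")
    if q.sum() <= 0:
        return 0.0
    p = p / p.sum()
    q = q / q.sum()
    return float(1.0 - 0.5 * np.abs(p - q).sum())


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    # Constant images have undefined correlation; score 0 by convention.
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def spatial_score(
    principal: IonImage | np.ndarray,
    isotope_images: Sequence[IonImage | np.ndarray],
    weights: Sequence[float],
    mask: np.ndarray | None = None,
) -> float:
    """Abundance-weighted colocalization of isotopologues with the principal.

    Pearson correlation of each subsequent isotopologue image against the
    principal image over occupied pixels, negatives clipped to 0, averaged
    with the theoretical abundances as weights.
    """
    if len(isotope_images) < 1:
        raise ValueError("need at least one subsequent isotopologue image")
    if len(isotope_images) != len(weights):
        raise ValueError("one weight per isotopologue image required")
    pv = principal.values if isinstance(principal, IonImage) else np.asarray(principal)
    if mask is None:
        flat_p = pv.ravel()
    else:
        if mask.shape != pv.shape:
            raise ValueError("mask shape mismatch")
        flat_p = pv[mask]
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise ValueError("weights must have positive sum")
    w = w / w.sum()
    score = 0.0
    for img, wi in zip(isotope_images, w):
        iv = img.values if isinstance(img, IonImage) else np.asarray(img)
        if iv.shape != pv.shape:
            raise ValueError("isotopologue image shape mismatch")
        flat_i = iv.ravel() if mask is None else iv[mask]
        score += wi * max(0.0, _pearson(flat_p, flat_i))
    return float(min(1.0, score))


def chaos_score(
    image: IonImage | np.ndarray,
    n_levels: int = 30,
    mask: np.ndarray | None = None,
) -> float:
    """Spatial-structure score from level-set connected components.

    The image is binarized at ``n_levels`` upper-quantile thresholds of its
    positive values; at each level the 4-connected components are counted.
    With N occupied pixels, ``score = 1 − (mean count − 1)/(N/2 − 1)``
    clipped to [0, 1]: a single coherent blob scores near 1, scattered
    isolated pixels near 0. All-zero images score 0 (absent).
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    vals = image.values if isinstance(image, IonImage) else np.asarray(image, float)
    if np.any(vals < 0):
        raise ValueError("image must be non-negative")
    occupied = int(vals.size if mask is None else mask.sum())
    positive = vals[vals > 0] if mask is None else vals[mask & (vals > 0)]
    if positive.size == 0:
        return 0.0
    if occupied <= 2:
        return 1.0
    # 4-connectivity structuring element
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    qs = np.linspace(0.0, 1.0, n_levels, endpoint=False)
    thresholds = np.quantile(positive, qs)
    counts = []
    for t in thresholds:
        binary = vals >= t if t > 0 else vals > 0
        if mask is not None:
            binary = binary & mask
        _, n_comp = ndimage.label(binary, structure=structure)
        counts.append(n_comp)
    mean_count = float(np.mean(counts))
    score = 1.0 - (mean_count - 1.0) / (occupied / 2.0 - 1.0)
    return float(np.clip(score, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def _score_candidate(
    dataset: MsiDataset,
    section: str,
    record: GlycanRecord,
    adduct: AdductSpec,
    tol_ppm: float,
    k_isotopes: int,
    n_levels: int,
) -> AnnotationResult:
    pattern = isotope_pattern(record.formula, n_peaks=k_isotopes)
    base_mz = adduct_mz(record.neutral_mass, adduct)
    abundances = [a for _, a in pattern]
    images = [
        extract_ion_image(dataset, section, base_mz + off / adduct.charge, tol_ppm)
        for off, _ in pattern
    ]
    observed = [float(img.values.sum()) for img in images]
    principal = images[0]
    absent = observed[0] <= 0
    if absent:
        spec = spat = cha = 0.0
    else:
        spec = spectral_score(abundances, observed)
        spat = spatial_score(principal, images[1:], abundances[1:])
        cha = chaos_score(principal, n_levels=n_levels)
    msm = spec * spat * cha
    return AnnotationResult(
        glycan_id=record.id,
        composition=str(record.composition),
        section=section,
        adduct=adduct.name,
        spectral=spec,
        spatial=spat,
        chaos=cha,
        msm=msm,
        absent=absent,
        principal_image=principal,
    )


def annotate(
    dataset: MsiDataset,
    database: Sequence[GlycanRecord],
    adduct: AdductSpec = SODIUM_ADDUCT,
    tol_ppm: float = 3.0,
    k_isotopes: int = 4,
    n_levels: int = 30,
    sections: Sequence[str] | None = None,
) -> list[AnnotationResult]:
    """Score every database composition against every section.

    Candidates whose adduct m/z falls outside the dataset m/z range are
    skipped (logged). Results are sorted by MSM descending.
    """
    if not database:
        raise ValueError("empty database")
    if not dataset.sections:
        raise ValueError("empty dataset")
    labels = sections if sections is not None else dataset.section_labels
    lo, hi = dataset.mz_range
    results: list[AnnotationResult] = []
    skipped = 0
    for record in database:
        mz = adduct_mz(record.neutral_mass, adduct)
        if not lo <= mz <= hi:
            skipped += 1
            continue
        for label in labels:
            results.append(
                _score_candidate(
                    dataset, label, record, adduct, tol_ppm, k_isotopes, n_levels
                )
            )
    if skipped:
        logger.info("annotate: skipped %d candidates outside m/z range", skipped)
    results.sort(key=lambda r: r.msm, reverse=True)
    return results


# ---------------------------------------------------------------------------
# Decoy FDR
# ---------------------------------------------------------------------------

def fdr_estimate(
    targets: Sequence[AnnotationResult],
    decoy_spec: DecoySpec,
    dataset: MsiDataset,
    database: Sequence[GlycanRecord],
    tol_ppm: float = 3.0,
    k_isotopes: int = 4,
    n_levels: int = 30,
) -> list[AnnotationResult]:
    """Attach decoy-adduct FDR values to target annotations.

    For every (composition, section) target, ``draws_per_target`` decoy
    adducts are sampled (seeded) and scored through the identical MSM
    pipeline. For a target score s::

        FDR(s) = (#decoys >= s / draws_per_target) / (#targets >= s)

    monotonized to be non-increasing in s and capped at 1.
    """
    if not targets:
        raise ValueError("no target annotations to estimate FDR for")
    rng = np.random.default_rng(decoy_spec.seed)
    by_id = {r.id: r for r in database}
    decoy_msms: list[float] = []
    for t in targets:
        record = by_id.get(t.glycan_id)
        if record is None:
            raise KeyError(f"annotation {t.glycan_id} not found in database")
        picks = rng.choice(len(decoy_spec.adducts), size=decoy_spec.draws_per_target)
        for j in picks:
            res = _score_candidate(
                dataset,
                t.section,
                record,
                decoy_spec.adducts[int(j)],
                tol_ppm,
                k_isotopes,
                n_levels,
            )
            decoy_msms.append(res.msm)
    decoys = np.sort(np.asarray(decoy_msms))
    target_scores = np.asarray([t.msm for t in targets])
    order = np.argsort(-target_scores, kind="stable")
    fdrs = np.empty(len(targets))
    for rank, i in enumerate(order):
        s = target_scores[i]
        n_decoy_ge = len(decoys) - np.searchsorted(decoys, s, side="left")
        n_target_ge = rank + 1  # sorted descending: targets with score >= s
        fdrs[i] = min(1.0, (n_decoy_ge / decoy_spec.draws_per_target) / n_target_ge)
    # Monotonize: walking down the score ranking, FDR must not decrease.
    running = 0.0
    for i in order:
        running = max(running, fdrs[i])
        fdrs[i] = running
    return [replace(t, fdr=float(fdrs[i])) for i, t in enumerate(targets)]


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def annotation_table(results: Sequence[AnnotationResult]) -> pd.DataFrame:
    """Tabulate annotations (one row per section × composition × adduct)."""
    return pd.DataFrame(
        [
            {
                "section": r.section,
                "composition": r.composition,
                "adduct": r.adduct,
                "spectral": r.spectral,
                "spatial": r.spatial,
                "chaos": r.chaos,
                "msm": r.msm,
                "fdr": r.fdr,
                "absent": r.absent,
            }
            for r in results
        ]
    )


def write_annotation_csv(results: Sequence[AnnotationResult], path: str | Path) -> None:
    annotation_table(results).to_csv(path, index=False)
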