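"""Nodule-phantom MSI simulation and companion proteomics tables.

The phantom emulates a legume root nodule cross-section: an outer cortex, a
thin (~40–50 μm) sclerenchyma ring of thick-walled cells, an inner cortex
with vascular bundles, and a central infection zone tiled by a mosaic of
large infected cells and smaller uninfected interstitial cells, with an
uninfected aggregation at the very center. Glycan abundances follow a
per-zone profile (sclerenchyma and infected cells high; cortex, vasculature
and uninfected cells low) multiplied by per-genotype effect factors:
Lewis-a and oligomannose glycans elevated in the nitrogen-fixation-deficient
mutant, paucimannose conserved.

Simulated spectra are centroided: for each planted glycan the first k
isotopologue peaks of the sodiated ion (ppm-jittered), plus hexose-oligomer
(starch) interference peaks and uniform random noise peaks. Everything is
deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from enum import IntEnum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .glycan_model import (
    Composition,
    SODIUM_ADDUCT,
    AdductSpec,
    adduct_mz,
    elemental_formula,
    isotope_pattern,
    neutral_mass,
    parse_composition,
    RESIDUE_MASSES,
    WATER_MASS,
)
from .msi_io import MsiDataset, Section
from .pathway_ratios import RatioPair
from .proteome_compare import QuantTable

__all__ = [
    "Zone",
    "NodulePhantom",
    "PlantedGlycan",
    "NoiseSpec",
    "GroundTruth",
    "DEFAULT_ZONE_PROFILE",
    "default_glycan_panel",
    "make_phantom",
    "simulate_dataset",
    "simulate_quant_table",
]


class Zone(IntEnum):
    """Anatomical zone labels of the nodule phantom."""

    BACKGROUND = 0
    OUTER_CORTEX = 1
    SCLERENCHYMA = 2
    INNER_CORTEX = 3
    INFECTION_ZONE = 4  # interstitial infection-zone tissue
    INFECTED_CELL = 5
    UNINFECTED_CELL = 6
    CENTRAL_REGION = 7
    VASCULAR_BUNDLE = 8


#: Relative glycan abundance per zone: sclerenchyma and infected cells high,
#: cortex/vasculature/uninfected cells low, central aggregation lowest.
DEFAULT_ZONE_PROFILE: Mapping[int, float] = {
    Zone.BACKGROUND: 0.0,
    Zone.OUTER_CORTEX: 0.15,
    Zone.SCLERENCHYMA: 1.0,
    Zone.INNER_CORTEX: 0.20,
    Zone.INFECTION_ZONE: 0.30,
    Zone.INFECTED_CELL: 0.80,
    Zone.UNINFECTED_CELL: 0.25,
    Zone.CENTRAL_REGION: 0.12,
    Zone.VASCULAR_BUNDLE: 0.10,
}

#: Target sclerenchyma ring thickness in micrometers.
SCLERENCHYMA_THICKNESS_UM = 45.0


@dataclass
class NodulePhantom:
    """Labeled zone image of one synthetic nodule section."""

    zone_image: np.ndarray  # (height, width) int labels
    pixel_pitch_um: float
    seed: int

    @property
    def tissue_mask(self) -> np.ndarray:
        return self.zone_image != Zone.BACKGROUND

    @property
    def infection_zone_mask(self) -> np.ndarray:
        """Everything inside the sclerenchyma-bounded central compartment."""
        return np.isin(
            self.zone_image,
            (Zone.INFECTION_ZONE, Zone.INFECTED_CELL, Zone.UNINFECTED_CELL,
             Zone.CENTRAL_REGION),
        )


def make_phantom(
    width: int,
    height: int,
    pixel_pitch_um: float = 50.0,
    seed: int = 0,
    central_aggregation: bool = True,
) -> NodulePhantom:
    """Generate one nodule phantom section.

    Concentric near-circular zones: nodule boundary at 0.46·min(w, h); the
    sclerenchyma ring has thickness round(45 μm / pitch) pixels; infected
    cells are a seeded blob process (disks of 2–4 px radius) inside the
    infection zone, the remainder being uninfected interstitial tissue;
    vascular bundles are small disks in the inner cortex.
    """
    if pixel_pitch_um <= 0:
        raise ValueError("pixel_pitch_um must be positive")
    t_px = max(1, round(SCLERENCHYMA_THICKNESS_UM / pixel_pitch_um))
    r_nodule = 0.46 * min(width, height)
    r_scl_out = 0.80 * r_nodule
    r_scl_in = r_scl_out - t_px
    r_iz = 0.62 * r_nodule
    if r_scl_in <= r_iz + 1:
        min_dim = int(np.ceil((t_px + 2) / (0.46 * (0.80 - 0.62))))
        raise ValueError(
            f"grid too small for a {t_px}-pixel sclerenchyma ring at "
            f"{pixel_pitch_um} um pitch; need min(width, height) >= {min_dim}"
        )
    rng = np.random.default_rng(seed)
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    yy, xx = np.mgrid[0:height, 0:width]
    r = np.hypot(xx - cx, yy - cy)

    zones = np.full((height, width), int(Zone.BACKGROUND), dtype=np.int16)
    zones[r <= r_nodule] = Zone.OUTER_CORTEX
    # Digital (rounded-radius) shells keep the thin ring topologically
    # closed: a 4-connected path cannot jump across t_px consecutive shells.
    shell = np.round(r).astype(int)
    s_out = int(round(r_scl_out))
    zones[(shell <= s_out) & (shell > s_out - t_px)] = Zone.SCLERENCHYMA
    zones[shell <= s_out - t_px] = Zone.INNER_CORTEX
    zones[r <= r_iz] = Zone.INFECTION_ZONE

    # Vascular bundles: small disks at fixed angles in the inner cortex.
    r_vb = max(1.5, 0.03 * r_nodule)
    r_vb_orbit = (r_iz + r_scl_in) / 2.0
    for angle in rng.uniform(0, 2 * np.pi, size=4):
        vx = cx + r_vb_orbit * np.cos(angle)
        vy = cy + r_vb_orbit * np.sin(angle)
        disk = np.hypot(xx - vx, yy - vy) <= r_vb
        zones[disk & (zones == Zone.INNER_CORTEX)] = Zone.VASCULAR_BUNDLE

    # Infected-cell mosaic: seeded disk blobs covering ~55% of the zone.
    iz_mask = zones == Zone.INFECTION_ZONE
    area_iz = int(iz_mask.sum())
    mean_blob_r = max(2.0, 35.0 / pixel_pitch_um)  # infected cells ~70 um wide
    n_blobs = max(1, int(0.55 * area_iz / (np.pi * mean_blob_r**2)))
    infected = np.zeros_like(iz_mask)
    centers_y = rng.uniform(cy - r_iz, cy + r_iz, size=n_blobs * 3)
    centers_x = rng.uniform(cx - r_iz, cx + r_iz, size=n_blobs * 3)
    radii = rng.uniform(0.7 * mean_blob_r, 1.4 * mean_blob_r, size=n_blobs * 3)
    placed = 0
    for by, bx, br in zip(centers_y, centers_x, radii):
        if placed >= n_blobs:
            break
        if np.hypot(bx - cx, by - cy) > r_iz - br:
            continue
        infected |= np.hypot(xx - bx, yy - by) <= br
        placed += 1
    zones[iz_mask & infected] = Zone.INFECTED_CELL
    zones[iz_mask & ~infected] = Zone.UNINFECTED_CELL

    if central_aggregation:
        central = r <= 0.15 * r_nodule
        zones[central & (zones != Zone.BACKGROUND)] = Zone.CENTRAL_REGION

    return NodulePhantom(zone_image=zones, pixel_pitch_um=pixel_pitch_um, seed=seed)


# ---------------------------------------------------------------------------
# Planted glycans and noise
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedGlycan:
    """One simulated glycan: composition, base intensity, mutant effect."""

    composition: Composition
    base_intensity: float = 100.0
    mutant_factor: float = 1.0  # multiplicative MUT/WT abundance ratio
    role: str = ""  # free-text label: lewis-a, paucimannose, oligomannose, ...

    def __post_init__(self) -> None:
        if self.base_intensity <= 0 or self.mutant_factor <= 0:
            raise ValueError("base_intensity and mutant_factor must be positive")


@dataclass(frozen=True)
class NoiseSpec:
    """Spectrum-level noise model.

    ``lognormal_sigma`` — multiplicative pixel noise on abundances;
    ``ppm_jitter`` — SD (ppm) of per-peak mass error (<= 2 ppm);
    ``n_noise_peaks`` — uniform random peaks per spectrum;
    ``baseline`` — scale of additive intensity baseline;
    ``interference`` — include hexose-oligomer (Hex8–Hex12 starch) peaks.
    """

    lognormal_sigma: float = 0.3
    ppm_jitter: float = 1.0
    n_noise_peaks: int = 20
    baseline: float = 1.0
    interference: bool = True

    def __post_init__(self) -> None:
        if self.ppm_jitter > 2.0:
            raise ValueError("ppm_jitter must be <= 2 ppm")
        if self.lognormal_sigma < 0 or self.baseline < 0 or self.n_noise_peaks < 0:
            raise ValueError("noise parameters must be non-negative")


def default_glycan_panel() -> list[PlantedGlycan]:
    """The 12-glycan study panel.

    Four conserved paucimannose glycans (mutant factor 1), two complex
    truncation precursors elevated 2× in the mutant (making the WT truncation
    yield twice the mutant's), four Lewis-a glycans and two oligomannose
    glycans elevated 3× in the mutant.
    """
    def g(text: str, factor: float, role: str, base: float = 100.0) -> PlantedGlycan:
        return PlantedGlycan(parse_composition(text), base, factor, role)

    return [
        g("Hex:3 HexNAc:2 Pent:1", 1.0, "paucimannose"),
        g("Hex:3 HexNAc:2 dHex:1", 1.0, "paucimannose"),
        g("Hex:3 HexNAc:2 dHex:1 Pent:1", 1.0, "paucimannose"),
        g("Hex:4 HexNAc:2 Pent:1", 1.0, "paucimannose"),
        g("Hex:3 HexNAc:3 dHex:1 Pent:1", 2.0, "precursor", 80.0),
        g("Hex:3 HexNAc:3 Pent:1", 2.0, "precursor", 80.0),
        g("Hex:4 HexNAc:3 dHex:2 Pent:1", 3.0, "lewis-a", 120.0),
        g("Hex:4 HexNAc:4 dHex:2 Pent:1", 3.0, "lewis-a", 120.0),
        g("Hex:5 HexNAc:4 dHex:2 Pent:1", 3.0, "lewis-a", 90.0),
        g("Hex:5 HexNAc:4 dHex:3 Pent:1", 3.0, "lewis-a", 150.0),
        g("Hex:5 HexNAc:2", 3.0, "oligomannose", 70.0),
        g("Hex:9 HexNAc:2", 3.0, "oligomannose", 60.0),
    ]


#: Truncation ratio pairs planted by the default panel (product conserved,
#: precursor 2x in mutant, hence WT/MUT truncation-ratio fold = 2).
DEFAULT_TRUNCATION_PAIRS: tuple[RatioPair, ...] = (
    RatioPair(
        parse_composition("Hex:3 HexNAc:2 dHex:1 Pent:1"),
        parse_composition("Hex:3 HexNAc:3 dHex:1 Pent:1"),
        "truncation",
    ),
    RatioPair(
        parse_composition("Hex:3 HexNAc:2 Pent:1"),
        parse_composition("Hex:3 HexNAc:3 Pent:1"),
        "truncation",
    ),
)


@dataclass
class GroundTruth:
    """Planted parameters of one simulated dataset."""

    glycans: list[PlantedGlycan]
    zone_profile: Mapping[int, float]
    ratio_pairs: list[RatioPair]
    ratio_folds: list[float]  # planted WT/MUT fold per pair
    seed: int

    @property
    def discriminant_up(self) -> list[str]:
        """Compositions planted with mutant_factor > 1 (expected up calls)."""
        return [str(g.composition) for g in self.glycans if g.mutant_factor > 1]

    @property
    def conserved(self) -> list[str]:
        return [str(g.composition) for g in self.glycans if g.mutant_factor == 1]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "zone_profile": {int(k): v for k, v in self.zone_profile.items()},
            "glycans": [
                {
                    "composition": str(g.composition),
                    "base_intensity": g.base_intensity,
                    "mutant_factor": g.mutant_factor,
                    "role": g.role,
                }
                for g in self.glycans
            ],
            "ratio_pairs": [
                {
                    "product": str(p.product),
                    "precursor": str(p.precursor),
                    "label": p.label,
                    "planted_wt_over_mut_fold": f,
                }
                for p, f in zip(self.ratio_pairs, self.ratio_folds)
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            [
                {
                    "composition": str(g.composition),
                    "base_intensity": g.base_intensity,
                    "mutant_factor": g.mutant_factor,
                    "role": g.role,
                }
                for g in self.glycans
            ]
        ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# MSI dataset simulation
# ---------------------------------------------------------------------------

def _hexose_oligomer_mzs(adduct: AdductSpec) -> np.ndarray:
    """Sodiated Hex8–Hex12 starch-fragment m/z values."""
    return np.array(
        [
            adduct_mz(n * RESIDUE_MASSES["Hex"] + WATER_MASS, adduct)
            for n in range(8, 13)
        ]
    )


def simulate_dataset(
    n_sections_per_genotype: int = 3,
    width: int = 120,
    height: int = 120,
    pixel_pitch_um: float = 50.0,
    glycans: Sequence[PlantedGlycan] | None = None,
    noise: NoiseSpec = NoiseSpec(),
    k_isotopes: int = 3,
    mz_range: tuple[float, float] = (1000.0, 5000.0),
    adduct: AdductSpec = SODIUM_ADDUCT,
    seed: int = 0,
    ratio_pairs: Sequence[RatioPair] = DEFAULT_TRUNCATION_PAIRS,
) -> tuple[MsiDataset, GroundTruth]:
    """Simulate a two-genotype nodule MSI dataset with known ground truth.

    Each section gets its own phantom (sections share the seed lineage but
    differ in blob mosaic). Pixel abundance of glycan g =
    zone_profile[zone] · base_intensity · genotype_factor · LogNormal(σ),
    emitted as the first k sodiated isotopologue peaks with ppm jitter, plus
    starch interference and uniform noise peaks. Background pixels carry no
    spectrum (off-tissue).
    """
    # An empty panel is allowed: it yields a decoy-null dataset carrying only
    # interference and noise peaks.
    panel = list(glycans) if glycans is not None else default_glycan_panel()
    base_mzs = []
    envelopes = []
    for g in panel:
        mz0 = adduct_mz(neutral_mass(g.composition), adduct)
        if not mz_range[0] <= mz0 <= mz_range[1]:
            raise ValueError(
                f"planted glycan {g.composition} has m/z {mz0:.3f} outside "
                f"the configured range {mz_range}"
            )
        pattern = isotope_pattern(elemental_formula(g.composition), k_isotopes)
        base_mzs.append([mz0 + off / adduct.charge for off, _ in pattern])
        envelopes.append([a for _, a in pattern])
    base_mzs_arr = np.asarray(base_mzs).reshape(len(panel), k_isotopes)  # (G, k)
    env_arr = np.asarray(envelopes).reshape(len(panel), k_isotopes)  # (G, k)
    interference_mzs = _hexose_oligomer_mzs(adduct)
    interference_mzs = interference_mzs[
        (interference_mzs >= mz_range[0]) & (interference_mzs <= mz_range[1])
    ]

    root = np.random.SeedSequence(seed)
    section_seeds = root.spawn(2 * n_sections_per_genotype)
    profile_lut = np.zeros(max(int(z) for z in Zone) + 1)
    for z, v in DEFAULT_ZONE_PROFILE.items():
        profile_lut[int(z)] = v

    sections: list[Section] = []
    for gi, group in enumerate(("WT", "MUT")):
        for si in range(n_sections_per_genotype):
            ss = section_seeds[gi * n_sections_per_genotype + si]
            rng = np.random.default_rng(ss)
            phantom = make_phantom(
                width, height, pixel_pitch_um,
                seed=int(ss.generate_state(1)[0] % (2**31)),
                central_aggregation=(group == "MUT"),
            )
            mask = phantom.tissue_mask
            ys, xs = np.nonzero(mask)
            order = np.lexsort((xs, ys))
            ys, xs = ys[order], xs[order]
            n_pix = len(xs)
            zone_vals = profile_lut[phantom.zone_image[ys, xs]]  # (P,)

            factors = np.array(
                [g.mutant_factor if group == "MUT" else 1.0 for g in panel]
            )
            bases = np.array([g.base_intensity for g in panel])
            # (P, G) mean abundance then multiplicative lognormal pixel noise
            mean_ab = zone_vals[:, None] * bases[None, :] * factors[None, :]
            ab = mean_ab * rng.lognormal(
                -noise.lognormal_sigma**2 / 2.0, noise.lognormal_sigma,
                size=mean_ab.shape,
            )

            # planted isotopologue peaks: (P, G*k)
            pk_int = (ab[:, :, None] * env_arr[None, :, :]).reshape(n_pix, -1)
            jitter = rng.normal(0.0, noise.ppm_jitter, size=pk_int.shape) * 1e-6
            pk_mz = base_mzs_arr.reshape(1, -1) * (1.0 + jitter)
            if noise.baseline > 0:
                pk_int = pk_int + rng.exponential(noise.baseline, size=pk_int.shape)

            blocks_mz = [pk_mz]
            blocks_int = [pk_int]
            if noise.interference and len(interference_mzs):
                i_int = 40.0 * rng.lognormal(
                    0.0, noise.lognormal_sigma, size=(n_pix, len(interference_mzs))
                )
                i_jit = rng.normal(0, noise.ppm_jitter, size=i_int.shape) * 1e-6
                blocks_mz.append(interference_mzs[None, :] * (1.0 + i_jit))
                blocks_int.append(i_int)
            if noise.n_noise_peaks:
                blocks_mz.append(
                    rng.uniform(mz_range[0], mz_range[1],
                                size=(n_pix, noise.n_noise_peaks))
                )
                blocks_int.append(
                    rng.exponential(2.0, size=(n_pix, noise.n_noise_peaks))
                )
            all_mz = np.concatenate(blocks_mz, axis=1)
            all_int = np.concatenate(blocks_int, axis=1)
            sort_idx = np.argsort(all_mz, axis=1)
            all_mz = np.take_along_axis(all_mz, sort_idx, axis=1)
            all_int = np.take_along_axis(all_int, sort_idx, axis=1)
            # enforce strictly increasing m/z within each spectrum
            eps = 1e-7
            np.maximum.accumulate(all_mz + eps * np.arange(all_mz.shape[1]),
                                  axis=1, out=all_mz)

            spectra = [
                (all_mz[i].copy(), all_int[i].copy()) for i in range(n_pix)
            ]
            sections.append(
                Section(
                    label=f"{group.lower()}_{si + 1}",
                    group=group,  # type: ignore[arg-type]
                    width=width,
                    height=height,
                    coords=np.column_stack([xs, ys]),
                    spectra=spectra,
                )
            )

    dataset = MsiDataset(
        sections=sections,
        polarity="positive",
        mz_range=mz_range,
        pixel_pitch_um=pixel_pitch_um,
    )
    folds = []
    by_comp = {str(g.composition): g for g in panel}
    for pair in ratio_pairs:
        prod = by_comp.get(str(pair.product))
        prec = by_comp.get(str(pair.precursor))
        if prod is None or prec is None:
            folds.append(float("nan"))
        else:
            wt_ratio = prod.base_intensity / prec.base_intensity
            mut_ratio = wt_ratio * prod.mutant_factor / prec.mutant_factor
            folds.append(wt_ratio / mut_ratio)
    truth = GroundTruth(
        glycans=panel,
        zone_profile=dict(DEFAULT_ZONE_PROFILE),
        ratio_pairs=list(ratio_pairs),
        ratio_folds=folds,
        seed=seed,
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# Proteomics simulation
# ---------------------------------------------------------------------------

#: Accessions designated as Lewis-a glycoprotein carriers in simulations
#: (synthetic stand-ins; labels follow UniProt-style formatting).
SYNTHETIC_LEWIS_A_ACCESSIONS: tuple[str, ...] = tuple(
    f"SYN{i:05d}" for i in range(1, 10)
)

_LEWIS_A_COMPOSITIONS = (
    "Hex:5 HexNAc:4 dHex:3 Pent:1",
    "Hex:4 HexNAc:4 dHex:2 Pent:1",
    "Hex:4 HexNAc:3 dHex:2 Pent:1",
)


def simulate_quant_table(
    n_proteins: int = 1000,
    n_pairs: int = 5,
    n_shifted: int = 50,
    shift_log2: float = 1.0,
    missingness: float = 0.1,
    seed: int = 0,
    baseline_log2_mean: float = 20.0,
    baseline_log2_sd: float = 2.0,
    replicate_sd: float = 0.25,
    pair_effect_sd: float = 0.15,
) -> tuple[QuantTable, pd.DataFrame, dict]:
    """Simulate a paired WT/MUT protein quantitation table with ground truth.

    Protein log2 abundances: protein baseline ~ N(baseline mean, sd), a
    shared per-pair batch effect, replicate noise, and a planted MUT−WT
    shift of ``shift_log2`` on ``n_shifted`` rows (the first three planted
    rows double as designated Lewis-a carrier accessions). Planted rows draw
    their baselines from the upper half of the abundance distribution,
    mirroring the fact that differential glycoprotein candidates come from
    the well-quantified, abundant part of a label-free proteome. Missingness
    is left-censored: within each sample, the lowest-abundance cells are by
    far the most likely to be missing. Returns (raw QuantTable, glycopeptide
    table, truth dict).
    """
    if n_pairs < 3:
        raise ValueError("n_pairs must be >= 3")
    if not 0 <= missingness < 0.5:
        raise ValueError("missingness must be in [0, 0.5)")
    if n_shifted > n_proteins:
        raise ValueError("n_shifted exceeds n_proteins")
    rng = np.random.default_rng(seed)

    lewis_acc = list(SYNTHETIC_LEWIS_A_ACCESSIONS)
    accessions = lewis_acc + [
        f"PRT{i:05d}" for i in range(1, n_proteins - len(lewis_acc) + 1)
    ]
    shifted = list(accessions[:3]) + list(
        accessions[len(lewis_acc):len(lewis_acc) + max(0, n_shifted - 3)]
    )

    wt_samples = [f"wt_{i + 1}" for i in range(n_pairs)]
    mut_samples = [f"mut_{i + 1}" for i in range(n_pairs)]
    baseline = rng.normal(baseline_log2_mean, baseline_log2_sd, size=n_proteins)
    is_shifted = np.isin(accessions, shifted)
    # abundant planted rows: baseline folded to the upper half
    baseline[is_shifted] = baseline_log2_mean + np.abs(
        baseline[is_shifted] - baseline_log2_mean
    )
    pair_fx = rng.normal(0.0, pair_effect_sd, size=(n_proteins, n_pairs))
    shift_mask = is_shifted.astype(float) * shift_log2

    log2 = {}
    for j, (wt_s, mut_s) in enumerate(zip(wt_samples, mut_samples)):
        wt_vals = baseline + pair_fx[:, j] + rng.normal(0, replicate_sd, n_proteins)
        mut_vals = (
            baseline + pair_fx[:, j] + shift_mask
            + rng.normal(0, replicate_sd, n_proteins)
        )
        log2[wt_s] = wt_vals
        log2[mut_s] = mut_vals
    data = pd.DataFrame({k: np.exp2(v) for k, v in log2.items()}, index=accessions)

    # Left-censored missingness: weight ∝ 4th power of reverse abundance rank,
    # concentrating dropouts in the low-abundance tail.
    if missingness > 0:
        n_missing = int(round(missingness * n_proteins))
        for col in data.columns:
            ranks = data[col].rank(ascending=True).values  # low abundance = low rank
            w = (1.0 - (ranks - 1) / n_proteins) ** 4
            w = w / w.sum()
            drop = rng.choice(n_proteins, size=n_missing, replace=False, p=w)
            data.iloc[drop, data.columns.get_loc(col)] = np.nan

    groups = {s: "WT" for s in wt_samples} | {s: "MUT" for s in mut_samples}
    pairs = {s: i + 1 for i, s in enumerate(wt_samples)} | {
        s: i + 1 for i, s in enumerate(mut_samples)
    }
    table = QuantTable(data=data, groups=groups, pairs=pairs)

    # Glycopeptide identifications: Lewis-a carriers plus non-Lewis rows.
    gp_rows = []
    for i, acc in enumerate(lewis_acc):
        comp = _LEWIS_A_COMPOSITIONS[i % len(_LEWIS_A_COMPOSITIONS)]
        gp_rows.append(
            {"accession": acc, "peptide": f"SYNPEPT{i + 1}K", "composition": comp}
        )
    for i, acc in enumerate(accessions[len(lewis_acc):len(lewis_acc) + 12]):
        comp = "Hex:3 HexNAc:2 Pent:1" if i % 2 else "Hex:9 HexNAc:2"
        gp_rows.append(
            {"accession": acc, "peptide": f"PLAINPEPT{i + 1}R", "composition": comp}
        )
    glycopeptides = pd.DataFrame(gp_rows)

    truth = {
        "shifted_accessions": sorted(shifted),
        "shift_log2": shift_log2,
        "lewis_a_accessions": sorted(lewis_acc),
        "seed": seed,
    }
    return table, glycopeptides, truth
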