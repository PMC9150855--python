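"""Differential proteomics (Perseus-style chain) and Lewis-a glycoprotein join.

The processing chain is the one standard for label-free nodule proteomics:
log2 transform, filter to rows with >= 3 observed values in at least one
group, column-wise downshifted-normal imputation (width 0.3, downshift 1.8
in units of the column SD), median normalization, then a paired two-tailed
Student t-test per protein. A protein is called significant when
|log2 fold change| > 0.5 and p < 0.05.

The glycoproteomics join returns accessions carrying at least one peptide
whose glycan composition has Lewis-a capacity >= 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import log
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .glycan_model import CompositionError, classify, parse_composition

import logging

logger = logging.getLogger("glyconodule")

__all__ = [
    "QuantTable",
    "VolcanoRecord",
    "PipelineOrderError",
    "preprocess",
    "impute",
    "normalize",
    "volcano",
    "volcano_table",
    "lewis_a_proteins",
    "read_quant_csv",
    "read_glycopeptide_csv",
]

#: Volcano significance thresholds.
LOG2FC_THRESHOLD = 0.5
P_THRESHOLD = 0.05

_STAGES = ("raw", "preprocessed", "imputed", "normalized")


class PipelineOrderError(RuntimeError):
    """Raised when chain stages are invoked out of order."""


@dataclass
class QuantTable:
    """Protein quantitation matrix plus the sample sheet.

    ``data``: proteins × samples (NaN = missing). ``groups`` maps sample id
    to WT|MUT; ``pairs`` maps sample id to a pairing index that must be
    bijective across groups for the paired t-test.
    ``stage`` tracks progress through the processing chain.
    """

    data: pd.DataFrame
    groups: Mapping[str, str]
    pairs: Mapping[str, int]
    stage: str = "raw"

    def __post_init__(self) -> None:
        for col in self.data.columns:
            if col not in self.groups:
                raise ValueError(f"sample {col!r} missing from the sample sheet")
            if self.groups[col] not in ("WT", "MUT"):
                raise ValueError(f"sample {col!r}: group must be WT or MUT")

    def group_columns(self, group: str) -> list[str]:
        return [c for c in self.data.columns if self.groups[c] == group]

    def paired_columns(self) -> list[tuple[str, str]]:
        """(WT sample, MUT sample) pairs matched by pairing index."""
        wt = {self.pairs[c]: c for c in self.group_columns("WT")}
        mut = {self.pairs[c]: c for c in self.group_columns("MUT")}
        if set(wt) != set(mut):
            raise ValueError("pairing indices are not bijective across groups")
        return [(wt[i], mut[i]) for i in sorted(wt)]


def _require_stage(t: QuantTable, expected: str, op: str) -> None:
    if t.stage != expected:
        raise PipelineOrderError(
            f"{op} expects a {expected!r} table but got {t.stage!r}; the chain "
            "is preprocess -> impute -> normalize -> volcano"
        )


# ---------------------------------------------------------------------------
# Chain stages
# ---------------------------------------------------------------------------

def preprocess(t: QuantTable) -> QuantTable:
    """log2-transform and keep rows with >= 3 observed values in some group."""
    _require_stage(t, "raw", "preprocess")
    bad = (t.data <= 0) & t.data.notna()
    if bad.any().any():
        row, col = np.argwhere(bad.values)[0]
        raise ValueError(
            f"non-positive abundance at protein {t.data.index[row]!r}, "
            f"sample {t.data.columns[col]!r}"
        )
    logged = np.log2(t.data)
    wt_cols = t.group_columns("WT")
    mut_cols = t.group_columns("MUT")
    keep = (logged[wt_cols].notna().sum(axis=1) >= 3) | (
        logged[mut_cols].notna().sum(axis=1) >= 3
    )
    return replace(t, data=logged.loc[keep], stage="preprocessed")


def impute(
    t: QuantTable, width: float = 0.3, downshift: float = 1.8, seed: int = 0
) -> QuantTable:
    """Column-wise downshifted-normal imputation of missing values.

    Missing entries in each sample column are drawn from
    ``Normal(mean - downshift * sd, (width * sd)^2)`` where mean/sd are that
    column's observed moments — the standard model for left-censored
    label-free missingness. Deterministic given the seed.
    """
    _require_stage(t, "preprocessed", "impute")
    rng = np.random.default_rng(seed)
    data = t.data.copy()
    for col in data.columns:
        observed = data[col].dropna()
        n_missing = int(data[col].isna().sum())
        if n_missing == 0:
            continue
        if len(observed) < 2:
            raise ValueError(
                f"column {col!r} has {len(observed)} observed values; "
                "cannot estimate an imputation distribution"
            )
        mu, sd = observed.mean(), observed.std(ddof=1)
        draws = rng.normal(mu - downshift * sd, width * sd, size=n_missing)
        data.loc[data[col].isna(), col] = draws
    return replace(t, data=data, stage="imputed")


def normalize(t: QuantTable) -> QuantTable:
    """Median-align samples: subtract each sample median, add grand median.

    On the log2 scale this equalizes per-sample (and hence per-group) medians
    while preserving within-sample contrasts — the interpretation adopted for
    global-abundance scaling.
    """
    _require_stage(t, "imputed", "normalize")
    medians = t.data.median(axis=0)
    grand = float(np.median(t.data.values))
    data = t.data - medians + grand
    return replace(t, data=data, stage="normalized")


# ---------------------------------------------------------------------------
# Volcano
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VolcanoRecord:
    accession: str
    log2_fc: float  # MUT - WT mean on log2 scale
    p_value: float
    neg_ln_p: float
    significant: bool
    degenerate: bool = False  # zero within-pair variance; p undefined


def volcano(t: QuantTable) -> list[VolcanoRecord]:
    """Paired two-tailed t-test per protein with the volcano call rule."""
    _require_stage(t, "normalized", "volcano")
    pairs = t.paired_columns()
    if len(pairs) < 2:
        raise ValueError("need at least 2 sample pairs for a paired t-test")
    wt_cols = [p[0] for p in pairs]
    mut_cols = [p[1] for p in pairs]
    wt = t.data[wt_cols].values
    mut = t.data[mut_cols].values
    records: list[VolcanoRecord] = []
    for i, accession in enumerate(t.data.index):
        diffs = mut[i] - wt[i]
        fc = float(diffs.mean())
        if np.allclose(diffs, diffs[0]):
            records.append(
                VolcanoRecord(str(accession), fc, float("nan"), float("nan"),
                              significant=False, degenerate=True)
            )
            continue
        _, p = stats.ttest_rel(mut[i], wt[i])
        p = float(p)
        records.append(
            VolcanoRecord(
                accession=str(accession),
                log2_fc=fc,
                p_value=p,
                neg_ln_p=-log(p),
                significant=bool(abs(fc) > LOG2FC_THRESHOLD and p < P_THRESHOLD),
            )
        )
    return records


def volcano_table(records: Sequence[VolcanoRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "accession": r.accession,
                "log2_fc": r.log2_fc,
                "p_value": r.p_value,
                "neg_ln_p": r.neg_ln_p,
                "significant": r.significant,
                "degenerate": r.degenerate,
            }
            for r in records
        ]
    )


def volcano_png(records: Sequence[VolcanoRecord], path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = volcano_table(records).dropna(subset=["p_value"])
    fig, ax = plt.subplots(figsize=(5, 4))
    colors = np.where(df["significant"], "crimson", "grey")
    ax.scatter(df["log2_fc"], df["neg_ln_p"], s=8, c=colors, alpha=0.7)
    ax.axhline(-log(P_THRESHOLD), ls="--", lw=0.8, c="k")
    for x in (-LOG2FC_THRESHOLD, LOG2FC_THRESHOLD):
        ax.axvline(x, ls="--", lw=0.8, c="k")
    ax.set_xlabel("log2 fold change (MUT − WT)")
    ax.set_ylabel("−ln p")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


# ---------------------------------------------------------------------------
# Lewis-a glycoprotein join
# ---------------------------------------------------------------------------

def lewis_a_proteins(glycopeptides: pd.DataFrame) -> dict[str, list[str]]:
    """Accessions with >= 1 peptide whose composition has Lewis-a capacity.

    ``glycopeptides`` needs columns accession, peptide, composition. Rows
    whose composition fails to parse are skipped with a log message.
    Returns accession -> sorted list of supporting composition strings.
    """
    out: dict[str, set[str]] = {}
    for row in glycopeptides.itertuples():
        acc = str(row.accession)
        if not acc:
            continue
        try:
            comp = parse_composition(str(row.composition))
        except CompositionError as exc:
            logger.warning("skipping glycopeptide row (%s): %s", acc, exc)
            continue
        _, capacity = classify(comp)
        if capacity >= 1:
            out.setdefault(acc, set()).add(str(comp))
    return {acc: sorted(comps) for acc, comps in sorted(out.items())}


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_quant_csv(
    quant_path: str | Path, sample_sheet_path: str | Path
) -> QuantTable:
    """Load a protein quantitation CSV/TSV plus its sample sheet.

    The quant table's first column is the accession; the sample sheet has
    columns sample, group, pair.
    """
    sep = "\t" if str(quant_path).endswith((".tsv", ".txt")) else ","
    data = pd.read_csv(quant_path, sep=sep, index_col=0)
    sheet = pd.read_csv(sample_sheet_path)
    groups = dict(zip(sheet["sample"].astype(str), sheet["group"]))
    pairs = dict(zip(sheet["sample"].astype(str), sheet["pair"].astype(int)))
    return QuantTable(data=data, groups=groups, pairs=pairs)


def read_glycopeptide_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"accession", "peptide", "composition"}
    if not required.issubset(df.columns):
        raise ValueError(f"glycopeptide table must have columns {sorted(required)}")
    return df
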