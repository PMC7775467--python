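"""Knockdown quantification by nested delta-delta-Ct, and EMSA densitometry stats.

The qPCR design has four conditions run in parallel plates within each
biological replicate: growth control (untreated), transfection-agent control,
target siRNA, and scrambled siRNA.  Per plate,

    dCt = Ct[target amplicon] - Ct[housekeeping amplicon]

(after averaging technical duplicates).  Within a biological replicate the
transfection-agent effect is

    ddCt[agent] = dCt[growth control] - dCt[transfection control]

over all 3 x 3 plate combinations, and a treatment's effect is

    ddCt[treatment] = (dCt[treatment] - dCt[transfection control]) - mean ddCt[agent]

again over all nine combinations.  Because the nine combinations share plates,
only an *unrelated subset* — a perfect matching of treatment and control
plates, index-matched and hence deterministic — enters the signed-rank test,
pooled across biological replicates (3 values per replicate).

Densitometry: band intensities are normalized to the paired isotype-control
signal within each experiment and compared between the two probe alleles with
an exact two-sided Mann-Whitney U test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, wilcoxon

GROWTH_CONTROL = "growth_control"
TRANSFECTION_CONTROL = "transfection_control"
SIRNA_TARGET = "sirna_target"
SIRNA_SCRAMBLED = "sirna_scrambled"

CONDITIONS = (
    GROWTH_CONTROL,
    TRANSFECTION_CONTROL,
    SIRNA_TARGET,
    SIRNA_SCRAMBLED,
)

CT_COLUMNS = ["replicate", "plate", "condition", "amplicon", "ct"]


def average_technical_duplicates(records: pd.DataFrame) -> pd.DataFrame:
    """Mean Ct over technical duplicates -> one row per (replicate, plate, condition, amplicon)."""
    keys = ["replicate", "plate", "condition", "amplicon"]
    return records.groupby(keys, as_index=False)["ct"].mean()


def delta_ct(
    records: pd.DataFrame,
    target_amplicon: str,
    housekeeping: str = "housekeeping",
) -> pd.DataFrame:
    """dCt = Ct[target] - Ct[housekeeping] per (replicate, plate, condition).

    Plates missing the housekeeping amplicon are excluded with a warning.
    """
    keys = ["replicate", "plate", "condition"]
    wide = records.pivot_table(
        index=keys, columns="amplicon", values="ct", aggfunc="mean"
    )
    if housekeeping not in wide.columns:
        raise ValueError(f"no {housekeeping!r} measurements in the table")
    missing = wide[housekeeping].isna() | wide.get(
        target_amplicon, pd.Series(np.nan, index=wide.index)
    ).isna()
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} samples lack target or housekeeping Ct; excluded",
            stacklevel=2,
        )
    out = (
        (wide[target_amplicon] - wide[housekeeping])
        .dropna()
        .rename("delta_ct")
        .reset_index()
    )
    return out


@dataclass
class DdctResult:
    amplicon: str
    treatment: str
    ddct_values: list[float]
    provenance: list[tuple[str, int, int]]  # (replicate, case plate, reference plate)
    unrelated_indices: list[int] = field(default_factory=list)
    p_value: float = float("nan")
    direction: str = "none"


def _plate_values(dct: pd.DataFrame, replicate, condition) -> dict[int, float]:
    sel = dct[(dct["replicate"] == replicate) & (dct["condition"] == condition)]
    return dict(zip(sel["plate"].astype(int), sel["delta_ct"]))


def ddct_nested(
    dct: pd.DataFrame,
    treatment: str,
    amplicon: str = "",
    min_valid: int = 2,
) -> DdctResult:
    """All 3x3 treatment-vs-control ddCt combinations, agent-corrected, with provenance.

    Biological replicates with fewer than ``min_valid`` valid plates in any
    required condition are excluded (the published validity rule).
    """
    values: list[float] = []
    prov: list[tuple[str, int, int]] = []
    for rep in sorted(dct["replicate"].unique()):
        growth = _plate_values(dct, rep, GROWTH_CONTROL)
        trans = _plate_values(dct, rep, TRANSFECTION_CONTROL)
        treat = _plate_values(dct, rep, treatment)
        if min(len(growth), len(trans), len(treat)) < min_valid:
            warnings.warn(f"replicate {rep}: too few valid plates; excluded", stacklevel=2)
            continue
        agent = [
            growth[i] - trans[j] for i in sorted(growth) for j in sorted(trans)
        ]
        mean_agent = float(np.mean(agent))
        for i in sorted(treat):
            for j in sorted(trans):
                values.append((treat[i] - trans[j]) - mean_agent)
                prov.append((rep, i, j))
    return DdctResult(
        amplicon=amplicon, treatment=treatment, ddct_values=values, provenance=prov
    )


def unrelated_subset(result: DdctResult) -> DdctResult:
    """Index-matched perfect matching (case_i vs ref_i) + exact Wilcoxon vs 0.

    Within each biological replicate the selected combinations share no case
    plate and no reference plate; values are pooled across replicates for the
    two-sided signed-rank test (exact for n <= 25).
    """
    chosen: list[int] = []
    for rep in sorted({p[0] for p in result.provenance}):
        idx = [k for k, p in enumerate(result.provenance) if p[0] == rep]
        cases = sorted({result.provenance[k][1] for k in idx})
        refs = sorted({result.provenance[k][2] for k in idx})
        n = min(len(cases), len(refs))
        if len(cases) != len(refs):
            warnings.warn(
                f"replicate {rep}: incomplete design, matching only {n} combinations",
                stacklevel=2,
            )
        for ci, rj in zip(cases[:n], refs[:n]):
            for k in idx:
                if result.provenance[k][1] == ci and result.provenance[k][2] == rj:
                    chosen.append(k)
                    break
    vals = np.array([result.ddct_values[k] for k in chosen])
    result.unrelated_indices = chosen
    if vals.size == 0:
        result.p_value = float("nan")
        return result
    if np.allclose(vals, 0.0):
        result.p_value = 1.0
        result.direction = "none"
        return result
    method = "exact" if vals.size <= 25 else "auto"
    result.p_value = float(
        wilcoxon(vals, alternative="two-sided", method=method).pvalue
    )
    med = float(np.median(vals))
    result.direction = "down" if med < 0 else ("up" if med > 0 else "none")
    return result


def random_matching_subset(result: DdctResult, seed: int) -> list[int]:
    """A seeded random perfect matching, to show conclusions are matching-invariant."""
    rng = np.random.default_rng(seed)
    chosen: list[int] = []
    for rep in sorted({p[0] for p in result.provenance}):
        idx = [k for k, p in enumerate(result.provenance) if p[0] == rep]
        cases = sorted({result.provenance[k][1] for k in idx})
        refs = list(sorted({result.provenance[k][2] for k in idx}))
        rng.shuffle(refs)
        for ci, rj in zip(cases, refs):
            for k in idx:
                if result.provenance[k][1] == ci and result.provenance[k][2] == rj:
                    chosen.append(k)
                    break
    return chosen


# ---------------------------------------------------------------------------
# EMSA band densitometry


@dataclass(frozen=True)
class BandIntensity:
    experiment_id: str
    allele: str
    antibody: str  # "specific" | "isotype_control"
    intensity: float

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError("intensities must be >= 0")


def normalized_intensities(bands: list[BandIntensity]) -> pd.DataFrame:
    """Specific / paired-isotype ratio per (experiment, allele).

    Experiments lacking an isotype pair, or with a zero isotype signal, are
    excluded (ratio undefined), not imputed.
    """
    df = pd.DataFrame([vars(b) for b in bands])
    wide = df.pivot_table(
        index=["experiment_id", "allele"],
        columns="antibody",
        values="intensity",
        aggfunc="mean",
    )
    if "isotype_control" not in wide.columns or "specific" not in wide.columns:
        raise ValueError("need both specific and isotype_control measurements")
    ok = wide["isotype_control"].notna() & (wide["isotype_control"] > 0)
    ok &= wide["specific"].notna()
    if (~ok).any():
        warnings.warn(
            f"{int((~ok).sum())} experiment/allele pairs excluded (missing or zero isotype)",
            stacklevel=2,
        )
    out = (
        (wide.loc[ok, "specific"] / wide.loc[ok, "isotype_control"])
        .rename("normalized")
        .reset_index()
    )
    return out


def compare_band_intensities(
    bands: list[BandIntensity], allele_a: str, allele_b: str
) -> tuple[float, pd.DataFrame]:
    """Exact two-sided Mann-Whitney U on normalized intensities of two alleles."""
    norm = normalized_intensities(bands)
    xs = norm.loc[norm["allele"] == allele_a, "normalized"].to_numpy()
    ys = norm.loc[norm["allele"] == allele_b, "normalized"].to_numpy()
    if len(xs) < 3 or len(ys) < 3:
        raise ValueError("need >= 3 usable experiments per allele")
    p = float(
        mannwhitneyu(xs, ys, alternative="two-sided", method="exact").pvalue
    )
    return p, norm
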