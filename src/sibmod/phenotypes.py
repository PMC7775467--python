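"""Extreme-phenotype selection: cohort centiles, severity classes, sibling-pair classes.

Patients are graded on two quantitative clinical parameters (e.g. FEV1 %
predicted and weight-for-height % predicted).  A patient is *severe* when both
parameters fall strictly below the 25th cohort centile, *mild* when both lie
strictly above the 75th, otherwise unclassified.  Sibling pairs are then
concordant-mild, concordant-severe, discordant (one of each), or unclassified.
Centiles are computed over the full cohort, not within families.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

MILD = "mild"
SEVERE = "severe"
UNCLASSIFIED = "unclassified"

CONCORDANT_MILD = "concordant_mild"
CONCORDANT_SEVERE = "concordant_severe"
DISCORDANT = "discordant"


def empirical_centiles(values) -> np.ndarray:
    """Centile per entry: 100 * mean-rank / n over non-missing values.

    Missing in -> missing out.  All-missing input is an error.
    """
    values = np.asarray(values, dtype=float)
    out = np.full(values.shape, np.nan)
    mask = ~np.isnan(values)
    if not mask.any():
        raise ValueError("all-missing phenotype vector")
    ranks = rankdata(values[mask], method="average")
    out[mask] = 100.0 * ranks / mask.sum()
    return out


def classify_patient(centiles, low: float = 25.0, high: float = 75.0) -> str:
    """Severity from a per-phenotype centile pair; strict inequalities at the cuts."""
    cents = np.asarray(centiles, dtype=float)
    if np.isnan(cents).any():
        warnings.warn("missing centile -> unclassified", stacklevel=2)
        return UNCLASSIFIED
    if (cents < low).all():
        return SEVERE
    if (cents > high).all():
        return MILD
    return UNCLASSIFIED


def classify_pair(sev1: str, sev2: str) -> str:
    """Symmetric pair class; any unclassified sib renders the pair unclassified."""
    pair = {sev1, sev2}
    if UNCLASSIFIED in pair:
        return UNCLASSIFIED
    if pair == {MILD}:
        return CONCORDANT_MILD
    if pair == {SEVERE}:
        return CONCORDANT_SEVERE
    return DISCORDANT


@dataclass(frozen=True)
class SibPair:
    family_id: str
    sib1_id: str
    sib2_id: str
    pair_class: str

    def __post_init__(self) -> None:
        if self.sib1_id == self.sib2_id:
            raise ValueError("a pair needs two distinct sibs")


def classify_cohort(
    phenotypes: pd.DataFrame,
    pairs: list[tuple[str, str, str]],
    low: float = 25.0,
    high: float = 75.0,
) -> tuple[pd.DataFrame, list[SibPair]]:
    """Full selection stage: centiles -> severity -> pair classes.

    ``pairs`` lists (family_id, sib1_id, sib2_id).  Returns a per-patient
    table (centiles + severity) and classified SibPair records.  For
    discordant pairs, sib1 is reordered to be the mild sib so downstream
    intrapair contrasts can rely on the orientation.
    """
    cents = phenotypes.apply(
        lambda col: empirical_centiles(col.to_numpy()), axis=0
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        severity = cents.apply(
            lambda row: classify_patient(row.to_numpy(), low, high), axis=1
        )
    table = cents.add_suffix("_centile")
    table["severity"] = severity
    out_pairs = []
    for fam, s1, s2 in pairs:
        sev1 = severity.get(s1, UNCLASSIFIED)
        sev2 = severity.get(s2, UNCLASSIFIED)
        cls = classify_pair(sev1, sev2)
        if cls == DISCORDANT and sev1 == SEVERE:
            s1, s2 = s2, s1  # orient mild-first
        out_pairs.append(SibPair(fam, s1, s2, cls))
    return table, out_pairs
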