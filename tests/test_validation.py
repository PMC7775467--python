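import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu, wilcoxon

from sibmod.simulate import knockdown_effects, simulate_ct
from sibmod.validation import (
    GROWTH_CONTROL,
    SIRNA_SCRAMBLED,
    SIRNA_TARGET,
    TRANSFECTION_CONTROL,
    BandIntensity,
    average_technical_duplicates,
    compare_band_intensities,
    ddct_nested,
    delta_ct,
    random_matching_subset,
    unrelated_subset,
)


def _records(dct_by_cond, amplicon="target_wildtype"):
    """Build a Ct table with housekeeping fixed at 20 and target = 20 + dCt."""
    rows = []
    for cond, per_rep in dct_by_cond.items():
        for rep, plates in per_rep.items():
            for plate, dct in plates.items():
                rows.append({"replicate": rep, "plate": plate, "condition": cond,
                             "amplicon": amplicon, "ct": 20.0 + dct})
                rows.append({"replicate": rep, "plate": plate, "condition": cond,
                             "amplicon": "housekeeping", "ct": 20.0})
    return pd.DataFrame(rows)


def test_delta_ct_is_elementwise_subtraction():
    rng = np.random.default_rng(0)
    shifts = {c: {"bio1": {p: float(rng.normal()) for p in (1, 2, 3)}}
              for c in (GROWTH_CONTROL, TRANSFECTION_CONTROL)}
    df = _records(shifts)
    out = delta_ct(df, "target_wildtype")
    for _, row in out.iterrows():
        expected = shifts[row["condition"]][row["replicate"]][row["plate"]]
        assert row["delta_ct"] == pytest.approx(expected)
    assert delta_ct(_records({GROWTH_CONTROL: {"b": {1: 8.0}}}),
                    "target_wildtype")["delta_ct"].iloc[0] == pytest.approx(8.0)


def test_missing_housekeeping_excludes_sample():
    df = _records({GROWTH_CONTROL: {"b": {1: 2.0, 2: 3.0}}})
    df = df[~((df["plate"] == 2) & (df["amplicon"] == "housekeeping"))]
    with pytest.warns(UserWarning):
        out = delta_ct(df, "target_wildtype")
    assert list(out["plate"]) == [1]


def test_technical_duplicates_average_before_delta():
    df = pd.DataFrame(
        [
            {"replicate": "b", "plate": 1, "condition": GROWTH_CONTROL,
             "amplicon": "t", "ct": 28.0},
            {"replicate": "b", "plate": 1, "condition": GROWTH_CONTROL,
             "amplicon": "t", "ct": 29.0},
        ]
    )
    out = average_technical_duplicates(df)
    assert len(out) == 1 and out["ct"].iloc[0] == pytest.approx(28.5)


def _triplicate_design(vals):
    """vals[(cond)] = [dCt plate1..3] within one biological replicate."""
    return _records({c: {"bio1": dict(enumerate(v, 1))} for c, v in vals.items()})


def test_ddct_all_identical_is_null():
    df = _triplicate_design(
        {GROWTH_CONTROL: [5, 5, 5], TRANSFECTION_CONTROL: [5, 5, 5],
         SIRNA_TARGET: [5, 5, 5]}
    )
    res = ddct_nested(delta_ct(df, "target_wildtype"), SIRNA_TARGET)
    assert len(res.ddct_values) == 9
    assert np.allclose(res.ddct_values, 0.0)
    res = unrelated_subset(res)
    assert res.p_value == pytest.approx(1.0)


def test_ddct_recovers_constant_shift():
    df = _triplicate_design(
        {GROWTH_CONTROL: [5, 5, 5], TRANSFECTION_CONTROL: [5, 5, 5],
         SIRNA_TARGET: [4, 4, 4]}
    )
    res = ddct_nested(delta_ct(df, "target_wildtype"), SIRNA_TARGET)
    assert np.allclose(res.ddct_values, -1.0)


def test_ddct_matches_hand_enumeration():
    rng = np.random.default_rng(2)
    g, t, s = rng.normal(size=(3, 3)).round(3)
    df = _triplicate_design(
        {GROWTH_CONTROL: g, TRANSFECTION_CONTROL: t, SIRNA_TARGET: s}
    )
    res = ddct_nested(delta_ct(df, "target_wildtype"), SIRNA_TARGET)
    agent = [g[i] - t[j] for i in range(3) for j in range(3)]
    expected = {
        (i + 1, j + 1): (s[i] - t[j]) - np.mean(agent)
        for i in range(3) for j in range(3)
    }
    assert len(res.ddct_values) == 9
    for val, (rep, ci, rj) in zip(res.ddct_values, res.provenance):
        assert val == pytest.approx(expected[(ci, rj)])


def test_ddct_equivariant_under_constant_ct_offset():
    rng = np.random.default_rng(3)
    vals = {c: rng.normal(size=3) for c in
            (GROWTH_CONTROL, TRANSFECTION_CONTROL, SIRNA_SCRAMBLED)}
    df1 = _triplicate_design(vals)
    df2 = df1.copy()
    mask = df2["amplicon"] == "target_wildtype"
    df2.loc[mask, "ct"] += 7.5  # shift every Ct of one amplicon
    r1 = ddct_nested(delta_ct(df1, "target_wildtype"), SIRNA_SCRAMBLED)
    r2 = ddct_nested(delta_ct(df2, "target_wildtype"), SIRNA_SCRAMBLED)
    # a uniform shift changes every dCt but cancels from every ddCt combination
    np.testing.assert_allclose(r1.ddct_values, r2.ddct_values, atol=1e-9)


def test_too_few_valid_plates_excludes_replicate():
    df = _triplicate_design(
        {GROWTH_CONTROL: [5, 5, 5], TRANSFECTION_CONTROL: [5, 5, 5],
         SIRNA_TARGET: [4.0]}
    )
    with pytest.warns(UserWarning):
        res = ddct_nested(delta_ct(df, "target_wildtype"), SIRNA_TARGET)
    assert res.ddct_values == []


def test_unrelated_subset_disjoint_and_pooled():
    rng = np.random.default_rng(4)
    conds = {GROWTH_CONTROL: {}, TRANSFECTION_CONTROL: {}, SIRNA_TARGET: {}}
    for c in conds:
        for rep in ("bio1", "bio2", "bio3"):
            conds[c][rep] = dict(enumerate(rng.normal(size=3), 1))
    df = _records(conds)
    res = unrelated_subset(ddct_nested(delta_ct(df, "target_wildtype"), SIRNA_TARGET))
    assert len(res.unrelated_indices) == 9  # 3 per biological replicate
    for rep in ("bio1", "bio2", "bio3"):
        chosen = [res.provenance[k] for k in res.unrelated_indices
                  if res.provenance[k][0] == rep]
        cases = [c for _, c, _ in chosen]
        refs = [r for _, _, r in chosen]
        assert len(set(cases)) == len(cases)
        assert len(set(refs)) == len(refs)
    # a seeded random matching is also disjoint
    alt = random_matching_subset(res, seed=1)
    for rep in ("bio1", "bio2", "bio3"):
        chosen = [res.provenance[k] for k in alt if res.provenance[k][0] == rep]
        assert len({c for _, c, _ in chosen}) == len(chosen)


def test_wilcoxon_exact_matches_bruteforce_enumeration():
    rng = np.random.default_rng(5)
    for n in (4, 6, 8):
        x = rng.normal(0.3, 1.0, size=n).round(3)
        while np.any(x == 0) or len(set(np.abs(x))) < n:  # avoid zeros/ties
            x = rng.normal(0.3, 1.0, size=n).round(3)
        p_scipy = wilcoxon(x, alternative="two-sided", method="exact").pvalue
        # brute force: enumerate all sign assignments of the ranked |x|
        ranks = np.argsort(np.argsort(np.abs(x))) + 1
        w_obs = ranks[x > 0].sum()
        total = ranks.sum()
        stats = []
        for signs in itertools.product([0, 1], repeat=n):
            w = ranks[np.array(signs, dtype=bool)].sum()
            stats.append(min(w, total - w))
        w_min = min(w_obs, total - w_obs)
        p_brute = np.mean([s <= w_min for s in stats])
        assert p_scipy == pytest.approx(p_brute, abs=1e-9)


def test_mannwhitney_exact_matches_enumeration_and_separation_value():
    x = [1.0, 2.0, 3.0]
    y = [4.0, 5.0, 6.0]
    p = mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
    assert p == pytest.approx(0.1)  # complete separation at n = 3 vs 3
    rng = np.random.default_rng(6)
    xs = rng.normal(size=4).round(3)
    ys = rng.normal(size=4).round(3)
    p_scipy = mannwhitneyu(xs, ys, alternative="two-sided", method="exact").pvalue
    pooled = np.concatenate([xs, ys])
    u_obs = sum((a > b) for a in xs for b in ys)
    us = []
    for combo in itertools.combinations(range(8), 4):
        gx = pooled[list(combo)]
        gy = pooled[[i for i in range(8) if i not in combo]]
        us.append(sum((a > b) for a in gx for b in gy))
    us = np.array(us)
    p_brute = np.mean(np.minimum(us, 16 - us) <= min(u_obs, 16 - u_obs))
    assert p_scipy == pytest.approx(p_brute, abs=1e-9)


def test_band_intensity_normalization_and_identical_sets():
    bands = []
    for e in range(3):
        for allele in ("C", "T"):
            bands.append(BandIntensity(f"e{e}", allele, "specific", 10.0))
            bands.append(BandIntensity(f"e{e}", allele, "isotype_control", 5.0))
    p, norm = compare_band_intensities(bands, "C", "T")
    assert p == pytest.approx(1.0)
    assert np.allclose(norm["normalized"], 2.0)


def test_band_intensity_zero_isotype_excluded():
    bands = []
    for e in range(4):
        for allele in ("C", "T"):
            iso = 0.0 if (e == 3 and allele == "C") else 5.0
            bands.append(BandIntensity(f"e{e}", allele, "specific", 10.0 + e))
            bands.append(BandIntensity(f"e{e}", allele, "isotype_control", iso))
    with pytest.warns(UserWarning):
        p, norm = compare_band_intensities(bands, "C", "T")
    assert (norm["allele"] == "C").sum() == 3


def test_band_intensity_power_for_planted_allele_effect():
    rng = np.random.default_rng(7)
    hits = 0
    n_sim = 60
    for s in range(n_sim):
        bands = []
        for e in range(6):
            iso = rng.uniform(4, 6)
            bands.append(BandIntensity(f"e{e}", "C", "specific", iso * rng.lognormal(0, 0.2)))
            bands.append(BandIntensity(f"e{e}", "C", "isotype_control", iso))
            iso2 = rng.uniform(4, 6)
            bands.append(BandIntensity(f"e{e}", "T", "specific", 2 * iso2 * rng.lognormal(0, 0.2)))
            bands.append(BandIntensity(f"e{e}", "T", "isotype_control", iso2))
        p, _ = compare_band_intensities(bands, "C", "T")
        hits += p < 0.05
    assert hits / n_sim > 0.5


def test_simulated_knockdown_recovery():
    df = simulate_ct(knockdown_effects(-1.2, -1.2), seed=8)
    df = average_technical_duplicates(df)
    for amp in ("target_wildtype", "target_alternative"):
        res = ddct_nested(delta_ct(df, amp), SIRNA_TARGET, amplicon=amp)
        assert np.mean(res.ddct_values) == pytest.approx(-1.2, abs=0.5)
        res = unrelated_subset(res)
        assert res.direction == "down"


def test_simulated_ct_determinism_and_null_centering():
    a = simulate_ct({}, seed=9)
    b = simulate_ct({}, seed=9)
    pd.testing.assert_frame_equal(a, b)
    res = ddct_nested(
        delta_ct(average_technical_duplicates(a), "target_wildtype"), SIRNA_SCRAMBLED
    )
    assert np.mean(res.ddct_values) == pytest.approx(0.0, abs=0.5)
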