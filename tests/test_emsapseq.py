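import io

import numpy as np
import pandas as pd
import pytest

from sibmod.emsapseq import (
    MsSample,
    ProteinHit,
    filter_candidates,
    flag_spliceosome,
    order_of_magnitude,
    presence_matrix,
    read_hits_table,
    score_to_probability,
    unique_signal,
)
from sibmod.simulate import PlantedBinder, default_sample_layout, simulate_emsapseq


@pytest.mark.parametrize(
    "score,p,order",
    [(119, 10 ** -11.9, -12), (92, 10 ** -9.2, -9), (0, 1.0, 0), (78, 10 ** -7.8, -8)],
)
def test_mascot_score_probability_conversion(score, p, order):
    assert score_to_probability(score) == pytest.approx(p)
    assert order_of_magnitude(score) == order


def test_negative_score_rejected():
    with pytest.raises(ValueError):
        score_to_probability(-1)
    with pytest.raises(ValueError):
        ProteinHit("s", "p", -5.0)


@pytest.fixture
def small_design():
    samples = [
        MsSample("s1", probe=("rs1", "C")),
        MsSample("s2", probe=("rs1", "T")),
        MsSample("s3", probe=("rs2", "C")),
        MsSample("s4", control="empty_negative"),
        MsSample("s5", control="consensus_probe"),
        MsSample("s6", probe=("rs2", "T"), gel="denaturing"),
    ]
    hits = [
        ProteinHit("s1", "BINDER", 119),
        ProteinHit("s2", "BINDER", 92),
        ProteinHit("s1", "STICKY", 60),
        ProteinHit("s3", "STICKY", 55),
        ProteinHit("s1", "CONTAM", 70),
        ProteinHit("s4", "CONTAM", 65),
        ProteinHit("s1", "ABUNDANT", 80),
        ProteinHit("s1", "NONNA", 50),
        ProteinHit("s6", "DENAT_ONLY", 45),
        ProteinHit("s1", "BINDER", 100),  # duplicate cell
    ]
    abundance = {"BINDER": 50.0, "STICKY": 10.0, "CONTAM": 20.0,
                 "ABUNDANT": 200.0, "DENAT_ONLY": 5.0}
    annotation = pd.DataFrame(
        {
            "nucleic_acid_binding": [True, True, True, True, False, True],
            "spliceosome_component": [False, True, False, False, False, False],
        },
        index=["BINDER", "STICKY", "CONTAM", "ABUNDANT", "NONNA", "DENAT_ONLY"],
    )
    return samples, hits, abundance, annotation


def test_presence_matrix_tabulation_and_idempotence(small_design):
    samples, hits, _, _ = small_design
    m = presence_matrix(hits, samples)
    assert m.loc["BINDER", "s1"] and m.loc["BINDER", "s2"]
    assert not m.loc["BINDER", "s3"]
    assert m.to_numpy().sum() == 9  # duplicate collapses to one presence
    with pytest.raises(ValueError):
        presence_matrix([ProteinHit("ghost", "X", 10)], samples)


def test_filter_cascade_flags(small_design):
    samples, hits, abundance, annotation = small_design
    m = presence_matrix(hits, samples)
    report = filter_candidates(m, samples, abundance, annotation, "rs1", hits=hits)
    rec = {r.protein_id: r for r in report.records}
    assert report.candidates == ["BINDER"]
    assert rec["BINDER"].scores_per_allele == {"C": 119.0, "T": 92.0}
    # each contaminant fails exactly its designed criterion
    assert not rec["CONTAM"].criteria["absent_from_negative_controls"]
    assert not rec["STICKY"].criteria["absent_from_other_snp_probes"]
    assert not rec["ABUNDANT"].criteria["low_abundance"]  # 200 is not < 200
    assert not rec["NONNA"].criteria["nucleic_acid_binding"]
    # unknown abundance fails criterion 3
    report2 = filter_candidates(m, samples, {}, annotation, "rs1")
    assert all(not r.criteria["low_abundance"] for r in report2.records)


def test_filter_monotone_in_negative_control_presence(small_design):
    samples, hits, abundance, annotation = small_design
    m = presence_matrix(hits + [ProteinHit("s4", "BINDER", 30)], samples)
    report = filter_candidates(m, samples, abundance, annotation, "rs1")
    assert report.candidates == []


def test_abundance_only_toggles_criterion_three(small_design):
    samples, hits, abundance, annotation = small_design
    m = presence_matrix(hits, samples)
    r1 = filter_candidates(m, samples, abundance, annotation, "rs1")
    r2 = filter_candidates(m, samples, {**abundance, "BINDER": 500.0},
                           annotation, "rs1")
    for a, b in zip(r1.records, r2.records):
        for crit in ("absent_from_negative_controls", "absent_from_other_snp_probes",
                     "nucleic_acid_binding"):
            assert a.criteria[crit] == b.criteria[crit]
    rb = {r.protein_id: r for r in r2.records}["BINDER"]
    assert not rb.criteria["low_abundance"]


def test_denaturing_samples_excluded_from_evidence_by_default(small_design):
    samples, hits, abundance, annotation = small_design
    # protein seen in a denaturing sample of rs2 plus the rs1 target lane
    extra = hits + [ProteinHit("s6", "BINDER", 40)]
    m = presence_matrix(extra, samples)
    r_default = filter_candidates(m, samples, abundance, annotation, "rs1")
    assert "BINDER" in r_default.candidates
    r_incl = filter_candidates(
        m, samples, abundance, annotation, "rs1", include_denaturing=True
    )
    assert "BINDER" not in r_incl.candidates


def test_missing_control_class_is_an_error(small_design):
    samples, hits, abundance, annotation = small_design
    no_neg = [s for s in samples if s.control != "empty_negative"]
    m = presence_matrix([h for h in hits if h.sample_id != "s4"], no_neg)
    with pytest.raises(ValueError, match="negative"):
        filter_candidates(m, no_neg, abundance, annotation, "rs1")


def test_unique_signal_grouping(small_design):
    samples, hits, _, _ = small_design
    m = presence_matrix(hits, samples)
    assert unique_signal("BINDER", m, samples) == (True, "rs1")
    assert unique_signal("STICKY", m, samples) == (False, None)  # two SNP groups
    assert unique_signal("CONTAM", m, samples) == (False, None)  # negative control
    # brute-force check over the whole matrix
    for protein in m.index:
        groups = set()
        disqualified = False
        for s in samples:
            if m.loc[protein, s.sample_id]:
                if s.control == "empty_negative":
                    disqualified = True
                else:
                    groups.add(s.probe_group)
        expected = (not disqualified) and len(groups) == 1
        assert unique_signal(protein, m, samples)[0] == expected


def test_spliceosome_flagging_retains_candidates(small_design):
    samples, hits, abundance, annotation = small_design
    m = presence_matrix(hits, samples)
    # let STICKY pass by restricting to rs1 absence... instead flag on full report
    report = filter_candidates(m, samples, abundance, annotation, "rs1")
    report = flag_spliceosome(report, annotation)
    rec = {r.protein_id: r for r in report.records}
    assert rec["STICKY"].spliceosome_excluded
    assert not rec["BINDER"].spliceosome_excluded
    assert "BINDER" in report.candidates  # flags never delete records


def test_hits_table_round_trip():
    src = "sample\tprotein\tscore\tpeptides\ns1\tESRP2\t119\t5\ns2\tESRP2\t92\t3\n"
    hits = read_hits_table(io.StringIO(src))
    assert hits[0].mascot_score == 119 and hits[0].n_peptides == 5


def test_planted_binder_recovered_from_synthetic_dataset():
    ds = simulate_emsapseq(
        [PlantedBinder("ESRP2_like", "rs152731")], n_background=30, seed=5
    )
    m = presence_matrix(ds.hits, ds.samples)
    report = filter_candidates(
        m, ds.samples, ds.abundance, ds.annotation, "rs152731", hits=ds.hits
    )
    assert report.candidates == ["ESRP2_like"]
    assert unique_signal("ESRP2_like", m, ds.samples) == (True, "rs152731")


def test_zero_background_yields_exactly_the_planted_binders():
    ds = simulate_emsapseq(
        [PlantedBinder("B1", "rs152730"), PlantedBinder("B2", "rs152744")],
        n_background=0, seed=1,
    )
    m = presence_matrix(ds.hits, ds.samples)
    for snp, binder in (("rs152730", "B1"), ("rs152744", "B2")):
        rep = filter_candidates(m, ds.samples, ds.abundance, ds.annotation, snp)
        assert rep.candidates == [binder]


def test_binder_injected_into_negative_control_is_filtered():
    ds = simulate_emsapseq([PlantedBinder("B1", "rs152730")], n_background=0, seed=2)
    neg = next(s for s in ds.samples if s.control == "empty_negative")
    ds.hits.append(ProteinHit(neg.sample_id, "B1", 50))
    m = presence_matrix(ds.hits, ds.samples)
    rep = filter_candidates(m, ds.samples, ds.abundance, ds.annotation, "rs152730")
    assert rep.candidates == []


def test_default_layout_has_25_native_samples():
    samples = default_sample_layout()
    native = [s for s in samples if s.gel == "native"]
    assert len(native) == 25
    assert sum(1 for s in native if s.control == "empty_negative") == 5
    assert sum(1 for s in samples if s.gel == "denaturing") == 3
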