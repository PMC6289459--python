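"""Nested primer design: enumeration, specificity, diagnostics, ranking."""

import dataclasses

import pytest

from gofish.design import (
    M13_FORWARD_TAIL,
    M13_REVERSE_TAIL,
    CandidatePrimer,
    DesignCriteria,
    NoDesignPossible,
    add_m13_tails,
    audit_design,
    design_assay,
    diagnostic_positions,
    enumerate_candidates,
    specificity_check,
)
from gofish.iupac import revcomp
from gofish.refpanel import Alignment, extract_region
from gofish.thermo import melting_temperature

OBSERVED = DesignCriteria.preset("observed")


def test_homopolymer_amplicon_yields_no_candidates():
    # no window of an A-homopolymer reaches the Tm floor
    assert enumerate_candidates("A" * 80, DesignCriteria()) == []


def test_short_amplicon_warns_and_returns_empty():
    with pytest.warns(UserWarning):
        assert enumerate_candidates("ACGTACGTAC", DesignCriteria()) == []


def test_widening_tm_window_grows_candidate_set(synth_default):
    _, panel, _, _ = synth_default
    amplicon = panel.records[0].sequence[21:-27]
    narrow = enumerate_candidates(amplicon, DesignCriteria(tm_min=50, tm_max=52))
    wide = enumerate_candidates(amplicon, DesignCriteria(tm_min=48, tm_max=56))
    narrow_keys = {(c.start, c.end) for c in narrow}
    wide_keys = {(c.start, c.end) for c in wide}
    assert narrow_keys <= wide_keys
    assert len(wide) >= len(narrow)


def test_candidate_count_matches_brute_force_window_scan():
    amplicon = "GCATTGACCGTAGCATTGACGGTACCATGGCTAGCTAGGCTTAACGGATCCAGTTAGCAT"  # 60 bp
    crit = DesignCriteria(tm_min=48, tm_max=58, primer_len_min=17, primer_len_max=20)
    got = enumerate_candidates(amplicon, crit, "forward")
    expected = 0
    for ln in range(17, 21):
        for start in range(0, 60 - ln + 1):
            tm = melting_temperature(amplicon[start : start + ln])
            if 48 <= tm <= 58:
                expected += 1
    assert len(got) == expected
    # reverse candidates are reverse complements of the sense windows
    rev = enumerate_candidates(amplicon, crit, "reverse")
    for c in rev:
        assert c.core == revcomp(amplicon[c.start : c.end])


def candidate(core, start=0, orientation="forward"):
    return CandidatePrimer(
        core=core,
        orientation=orientation,
        start=start,
        end=start + len(core),
        tm=51.0,
    )


def test_specificity_two_transversions_pass():
    core = "GCATTGACCGTAGCATTGAC"
    # non-target differing by two transversions in the 3'-terminal 5 bases
    site = core[:-2] + "TG"  # sense differs at the last two positions
    assert site[-5:] != core[-5:]
    ok, audited = specificity_check(candidate(core), {"nt": site}, DesignCriteria())
    assert ok
    assert audited.audit["nt"][1] >= 2


def test_specificity_wobble_only_fails():
    core = "GCATTGACCGTAGCATTGAG"
    # forward primer G over sense A pairs G.T (wobble) — not specific
    site = core[:-1] + "A"
    ok, audited = specificity_check(candidate(core), {"nt": site}, DesignCriteria())
    assert not ok
    assert audited.audit["nt"][1] == 0  # zero penalized, the wobble never counts
    assert audited.audit["nt"][0] == 1  # but it is still a mismatch


def test_specificity_identical_nontarget_fails_with_zero():
    core = "GCATTGACCGTAGCATTGAC"
    ok, audited = specificity_check(candidate(core), {"nt": core}, DesignCriteria())
    assert not ok
    assert audited.audit["nt"] == (0, 0)


def test_specificity_gap_site_auto_passes_with_flag():
    core = "GCATTGACCGTAGCATTGAC"
    gapped = core[:10] + "-" + core[11:]
    ok, audited = specificity_check(candidate(core), {"nt": gapped}, DesignCriteria())
    assert ok
    assert "nt" in audited.no_site


def test_diagnostic_positions_match_naive_comparison():
    target = "ACGTACGTACGTACGTACGT"
    nts = {
        "same": target,
        "one": target[:7] + "C" + target[8:],
        "many": "TGCATGCATGCATGCATGCA",
    }
    span = (3, 15)
    got = diagnostic_positions(target, nts, span)
    for taxon, seq in nts.items():
        naive = [j for j in range(*span) if target[j] != seq[j]]
        assert got[taxon] == naive
    assert got["same"] == []
    assert got["one"] == [7]
    with pytest.raises(ValueError):
        diagnostic_positions(target, nts, (5, 5))


def test_m13_tails():
    f, r = add_m13_tails("AGAGTGGTTAAGGAAAGCCTG", "TCGTGGGGTCAGGAATGG")
    assert f == "TGTAAAACGACGGCCAGT" + "AGAGTGGTTAAGGAAAGCCTG"
    assert r == "CAGGAAACAGCTATGAC" + "TCGTGGGGTCAGGAATGG"
    assert len(M13_FORWARD_TAIL) == 18 and len(M13_REVERSE_TAIL) == 17
    f2, r2 = add_m13_tails("AAA", "CCC", enabled=False)
    assert (f2, r2) == ("AAA", "CCC")


def test_published_bluefish_tailed_sequences_reproduced():
    from gofish.primers import published_assays

    blfi = next(a for a in published_assays() if a.code == "blfi")
    f, r = add_m13_tails(blfi.fwd.core, blfi.rev.core)
    assert f == blfi.fwd.full
    assert r == blfi.rev.full


@pytest.fixture(scope="module")
def synth_interior():
    from gofish.synth import SynthPanelSpec, generate_panel

    panel, aln, truth = generate_panel(SynthPanelSpec(seed=7))
    interior = extract_region(aln, 21, aln.length - 27)
    taxon_of = {r.id: r.taxon for r in panel}
    return panel, interior, taxon_of, truth


def test_design_assay_succeeds_and_reaudits_on_divergent_panel(synth_interior):
    panel, interior, taxon_of, truth = synth_interior
    target = panel.records[0].taxon
    designs = design_assay(interior, target, OBSERVED, taxon_of=taxon_of, max_designs=10)
    assert designs
    for d in designs:
        assert d.fwd_tailed.startswith(M13_FORWARD_TAIL)
        assert d.rev_tailed.startswith(M13_REVERSE_TAIL)
        assert OBSERVED.amplicon_min <= d.amplicon_size_incl_tails <= OBSERVED.amplicon_max
        assert d.amplicon_size_incl_tails == d.amplicon_length + 35
        assert audit_design(d, interior, OBSERVED, taxon_of=taxon_of)


def test_design_assay_twin_target_raises_naming_the_twin(synth_interior):
    panel, interior, taxon_of, truth = synth_interior
    twin_a, twin_b = truth.twins[0]
    with pytest.raises(NoDesignPossible) as exc:
        design_assay(interior, twin_a, OBSERVED, taxon_of=taxon_of)
    assert exc.value.indistinguishable == {twin_b}


def test_design_assay_all_identical_fails_for_every_target():
    rows = {f"t{i}": "GCATTGACCGTAGCATTGAC" * 9 for i in range(4)}
    aln = Alignment(rows)
    for target in rows:
        with pytest.raises(NoDesignPossible) as exc:
            design_assay(aln, target, OBSERVED)
        assert exc.value.indistinguishable == set(rows) - {target}


def test_design_assay_pairs_match_brute_force_on_toy_panel(synth_interior):
    panel, interior, taxon_of, _ = synth_interior
    # restrict to a 4-taxon sub-alignment for the exhaustive oracle
    ids = [r.id for r in panel.records[:4]]
    sub = Alignment({i: interior.rows[i] for i in ids})
    sub_taxa = {i: taxon_of[i] for i in ids}
    target = sub_taxa[ids[0]]
    crit = dataclasses.replace(OBSERVED, amplicon_min=100, amplicon_max=160)
    designs = design_assay(sub, target, crit, taxon_of=sub_taxa)
    got = {(d.fwd.start, d.fwd.end, d.rev.start, d.rev.end) for d in designs}

    # brute force: every candidate pair, each independently re-audited
    target_seq = sub.rows[ids[0]]
    nontargets = {sub_taxa[i]: sub.rows[i] for i in ids[1:]}
    expected = set()
    fwd = enumerate_candidates(target_seq, crit, "forward")
    rev = enumerate_candidates(target_seq, crit, "reverse")
    for f in fwd:
        sites_f = {t: s[f.start : f.end] for t, s in nontargets.items()}
        if not specificity_check(f, sites_f, crit)[0]:
            continue
        for r in rev:
            if r.start < f.end:
                continue
            if not (crit.amplicon_min <= r.end - f.start + 35 <= crit.amplicon_max):
                continue
            sites_r = {t: s[r.start : r.end] for t, s in nontargets.items()}
            if not specificity_check(r, sites_r, crit)[0]:
                continue
            expected.add((f.start, f.end, r.start, r.end))
    assert got == expected


def test_tightening_criteria_never_enlarges_design_set(synth_interior):
    panel, interior, taxon_of, _ = synth_interior
    target = panel.records[1].taxon
    loose = dataclasses.replace(OBSERVED, min_penalized_3p=1)
    tight = dataclasses.replace(OBSERVED, min_penalized_3p=2)

    def keyset(crit):
        try:
            return {
                (d.fwd.start, d.fwd.end, d.rev.start, d.rev.end)
                for d in design_assay(interior, target, crit, taxon_of=taxon_of)
            }
        except NoDesignPossible:
            return set()

    assert keyset(tight) <= keyset(loose)


def test_no_design_reports_limiting_reason():
    # divergent enough to pass identity, but no Tm-window candidates exist
    rows = {
        "t0": "GCATTGACCGTAGCATTGAC" * 9,
        "t1": "GCATTGACCGTAGCATTGAC" * 4 + "TTTTTTTTTTTTTTTTTTTT" + "GCATTGACCGTAGCATTGAC" * 4,
    }
    crit = DesignCriteria(tm_min=90.0, tm_max=91.0)  # unreachable window
    with pytest.raises(NoDesignPossible) as exc:
        design_assay(Alignment(rows), "t0", crit)
    assert exc.value.indistinguishable == frozenset()
    assert exc.value.reasons
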