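"""Reference-panel construction: digestion, masses, modified forms, decoys,
taxonomic diagnosticity."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from milkstone.masses import (
    ACETYL_NTERM,
    CARBAMIDOMETHYL,
    DEAMIDATION,
    OXIDATION_M,
    PYROGLUTAMATE,
    WATER,
    peptide_mass,
)
from milkstone.panel import (
    Peptide,
    ProteinRecord,
    ReferencePanel,
    Taxonomy,
    build_consensus,
    build_decoys,
    cleavage_sites,
    collapse,
    digest,
    enumerate_modified_forms,
    load_fasta,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# digestion vs brute-force oracle


def oracle_digest(seq, max_missed, min_len, max_len, semi):
    """Exhaustive substring enumeration with the cleavage-rule predicate."""
    n = len(seq)
    sites = {
        i for i in range(1, n) if seq[i - 1] in "KR" and seq[i] != "P"
    }
    bounds = sites | {0, n}
    out = set()
    for s in range(n):
        for e in range(s + 1, n + 1):
            if not (min_len <= e - s <= max_len):
                continue
            if sum(1 for p in sites if s < p < e) > max_missed:
                continue
            nt, ct = s in bounds, e in bounds
            if nt and ct:
                out.add((s, e, "tryptic"))
            elif semi and (nt or ct):
                out.add((s, e, "semi"))
    return out


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    seq=st.text(alphabet=AA, min_size=0, max_size=50),
    max_missed=st.sampled_from([0, 1, 2]),
    semi=st.booleans(),
    min_len=st.integers(1, 4),
)
def test_digest_matches_bruteforce_oracle(seq, max_missed, semi, min_len):
    got = {
        (p.start, p.end, p.termini)
        for p in digest(seq, max_missed, min_len, 30, semi)
    }
    assert got == oracle_digest(seq, max_missed, min_len, 30, semi)


@pytest.mark.parametrize(
    "seq,missed,expected",
    [
        ("AKCR", 1, {"AK", "CR", "AKCR"}),
        ("MKPR", 0, {"MKPR"}),  # K before P is not a cleavage site
        ("", 2, set()),
    ],
)
def test_digest_small_examples(seq, missed, expected):
    got = {p.sequence for p in digest(seq, missed, min_len=1, max_len=30, semi=False)}
    assert got == expected


def test_digest_reports_missed_cleavage_counts():
    by_seq = {
        p.sequence: p.missed_cleavages
        for p in digest("AKCRDK", 2, min_len=1, max_len=30, semi=False)
    }
    assert by_seq["AKCR"] == 1 and by_seq["AKCRDK"] == 2 and by_seq["DK"] == 0


def test_digest_rejects_invalid_residues():
    with pytest.raises(ValueError):
        digest("AKZ", 0, 1, 30, False)


# ---------------------------------------------------------------------------
# masses


def test_glycine_monoisotopic_mass():
    assert peptide_mass("G") == pytest.approx(75.03203, abs=2e-5)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(a=st.text(alphabet=AA, min_size=1, max_size=10),
       b=st.text(alphabet=AA, min_size=1, max_size=10))
def test_mass_additivity_and_il_invariance(a, b):
    # concatenation forms one peptide bond: loses one water
    assert peptide_mass(a + b) == pytest.approx(
        peptide_mass(a) + peptide_mass(b) - WATER, abs=1e-9
    )
    assert peptide_mass(a.replace("I", "L")) == pytest.approx(peptide_mass(a))
    assert peptide_mass(a) > 0


def test_deamidation_mass_shift():
    base = peptide_mass("ANQK")
    assert peptide_mass("ANQK", [(1, DEAMIDATION)]) - base == pytest.approx(0.98402)


def test_unknown_residue_raises_without_fallback():
    with pytest.raises(ValueError):
        peptide_mass("AXK")
    assert peptide_mass("AXK", x_mass=110.0) == pytest.approx(
        peptide_mass("AK") + 110.0
    )


# ---------------------------------------------------------------------------
# modified forms


def _pep(seq, start=10):
    return Peptide(seq, "P", start, start + len(seq), 0, "tryptic")


def test_no_eligible_sites_yields_only_the_peptide():
    forms = enumerate_modified_forms(_pep("GAVK"), max_variable=2)
    assert len(forms) == 1 and forms[0].mods == ()


def test_deamidation_enumeration_counts():
    forms = enumerate_modified_forms(_pep("NQAK"), specs=[DEAMIDATION], max_variable=2)
    # 0, 1 (two choices), 2 deamidations
    assert len(forms) == 4


def test_fixed_carbamidomethyl_on_every_form():
    forms = enumerate_modified_forms(
        _pep("CNQK"), specs=[CARBAMIDOMETHYL, DEAMIDATION], max_variable=1
    )
    assert all(
        any(s.name == "carbamidomethyl" and pos == 0 for pos, s in f.mods)
        for f in forms
    )
    base = peptide_mass("CNQK")
    assert all(f.mono_mass >= base + 57.02146 - 1e-9 for f in forms)


def test_pyroglutamate_only_on_nterminal_gln():
    with_q = enumerate_modified_forms(_pep("QAK"), specs=[PYROGLUTAMATE], max_variable=1)
    without = enumerate_modified_forms(_pep("AQK"), specs=[PYROGLUTAMATE], max_variable=1)
    assert any(s.name == "pyroglu" for f in with_q for _, s in f.mods)
    assert not any(s.name == "pyroglu" for f in without for _, s in f.mods)


def test_acetyl_only_on_protein_nterminal_peptide():
    at_start = enumerate_modified_forms(_pep("MAK", start=0), specs=[ACETYL_NTERM], max_variable=1)
    internal = enumerate_modified_forms(_pep("MAK", start=5), specs=[ACETYL_NTERM], max_variable=1)
    assert any(s.name == "acetyl" for f in at_start for _, s in f.mods)
    assert not any(s.name == "acetyl" for f in internal for _, s in f.mods)


def test_variable_budget_respected():
    forms = enumerate_modified_forms(
        _pep("MNQM"), specs=[DEAMIDATION, OXIDATION_M], max_variable=2
    )
    assert max(len(f.mods) for f in forms) == 2


# ---------------------------------------------------------------------------
# decoys


def test_decoys_are_reversed_and_flagged(toy_records):
    decoys = build_decoys(toy_records)
    assert len(decoys) == len(toy_records)
    for t, d in zip(toy_records, decoys):
        assert d.sequence == t.sequence[::-1]
        assert d.is_decoy
        assert sorted(d.sequence) == sorted(t.sequence)  # same composition


def test_palindromic_decoy_still_flagged():
    rec = ProteinRecord("P", "Sp", ("Root", "Sp"), "AKA")
    (d,) = build_decoys([rec])
    assert d.sequence == "AKA" and d.is_decoy


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seq=st.text(alphabet="ACDEFGHMNSTVWY", min_size=5, max_size=40))
def test_decoy_digest_count_matches_target_without_kr(seq):
    # without K/R (and hence no cleavage asymmetry) the reversed sequence
    # digests into exactly as many peptides as the target
    fwd = digest(seq, 2, 1, 30, True)
    rev = digest(seq[::-1], 2, 1, 30, True)
    assert len(fwd) == len(rev)


# ---------------------------------------------------------------------------
# taxonomy and diagnosticity


def test_lca_basics(toy_panel):
    tx = toy_panel.taxonomy
    assert tx.lca(["Sp1", "Sp2"]) == "CladeA"
    assert tx.lca(["Sp1", "Sp3"]) == "Root"
    assert tx.lca(["Sp2"]) == "Sp2"
    assert tx.lca(["CladeA", "Sp1"]) == "CladeA"


def _brute_force_diagnostic(peptide_seq, records, taxonomy, aware=True):
    carriers = []
    for rec in records:
        peps = oracle_digest(rec.sequence, 2, 5, 20, True)
        seqs = {collapse(rec.sequence[s:e], aware) for s, e, _ in peps}
        if collapse(peptide_seq, aware) in seqs:
            carriers.append(rec.species)
    if not carriers:
        return None
    return taxonomy.lca(carriers)


@pytest.mark.parametrize(
    "pep,expected",
    [
        ("GGGWWK", "Root"),
        ("SPAAR", "CladeA"),
        ("FFFYYK", "Sp1"),
        ("HHHSSK", "Sp2"),
        ("MMMTTK", "Sp3"),
        ("WWWWWW", None),
    ],
)
def test_diagnostic_level_toy_examples(toy_panel, pep, expected):
    assert toy_panel.diagnostic_level(pep) == expected


def test_diagnostic_level_agrees_with_bruteforce_on_bundled_panel(panel):
    # every 50th base peptide, checked against an oracle that recomputes
    # carrier species and the LCA from scratch
    peps = [p for p in panel.base_peptides(include_decoys=False)][::50]
    for p in peps:
        want = _brute_force_diagnostic_full(p.sequence, panel)
        assert panel.diagnostic_level(p.sequence) == want


def _brute_force_diagnostic_full(peptide_seq, panel):
    carriers = []
    key = collapse(peptide_seq, True)
    for rec in panel.records:
        peps = oracle_digest(
            rec.sequence, panel.max_missed, panel.min_len, panel.max_len, panel.semi
        )
        if key in {collapse(rec.sequence[s:e], True) for s, e, _ in peps}:
            carriers.append(rec.species)
    if not carriers:
        return None
    lca = panel.taxonomy.lca(carriers)
    # minimality: no child of the LCA is also an ancestor of all carriers
    for taxon in panel.taxonomy.parent:
        if panel.taxonomy.parent[taxon] == lca:
            assert not all(
                panel.taxonomy.is_ancestor_or_equal(taxon, c) for c in carriers
            )
    return lca


def test_diagnostic_respects_deamidation_flag(panel):
    # fully deamidated rendering of a Pecora-shared peptide (IDALNENK)
    assert panel.diagnostic_level("IDALDEDK", deamidation_aware=True) == "Pecora"
    assert panel.diagnostic_level("IDALDEDK", deamidation_aware=False) is None


# ---------------------------------------------------------------------------
# FASTA + consensus


def test_load_fasta_roundtrip(tmp_path):
    p = tmp_path / "panel.fasta"
    p.write_text(
        ">A1|SpA|lineage:Root>CladeX>SpA\nacdefk*\n"
        ">B1|SpB|lineage:Root>CladeX>SpB\nACDEFR\n"
    )
    recs = load_fasta(p)
    assert [r.species for r in recs] == ["SpA", "SpB"]
    assert recs[0].sequence == "ACDEFK"  # uppercased, stop stripped
    assert recs[0].lineage == ("Root", "CladeX", "SpA")


def test_load_fasta_empty_file(tmp_path):
    p = tmp_path / "empty.fasta"
    p.write_text("")
    assert load_fasta(p) == []


def test_load_fasta_malformed_header(tmp_path):
    p = tmp_path / "bad.fasta"
    p.write_text(">justaname\nACDEF\n")
    with pytest.raises(ValueError, match="justaname"):
        load_fasta(p)


def test_load_fasta_duplicate_species(tmp_path):
    p = tmp_path / "dup.fasta"
    p.write_text(
        ">A|Sp|lineage:Root>Sp\nAAAK\n>B|Sp|lineage:Root>Sp\nCCCK\n"
    )
    with pytest.raises(ValueError, match="duplicate"):
        load_fasta(p)


def test_consensus_majority_vote():
    mk = lambda acc, sp, seq: ProteinRecord(acc, sp, ("Root", sp), seq)
    recs = [
        mk("A", "S1", "AAAAKCCCCK"),
        mk("B", "S2", "AAAAKCCCCK"),
        mk("C", "S3", "AAAAKCCWCK"),
    ]
    assert build_consensus(recs) == "AAAAKCCCCK"
    # tie between two variants resolves to the earlier record's residue
    recs_tie = [mk("A", "S1", "AAWAK"), mk("B", "S2", "AAFAK")]
    assert build_consensus(recs_tie) == "AAWAK"


def test_panel_invariants(panel):
    assert len(panel.decoy_records) == len(panel.records)
    assert len(panel.consensus) == len(panel.records[0].sequence)
    for rec in panel.records:
        assert rec.lineage[-1] == rec.species
        assert panel.taxonomy.is_ancestor_or_equal("Mammalia", rec.species)
    for p in panel.base_peptides():
        assert 600.0 <= p.mono_mass <= 3500.0
        assert panel.min_len <= len(p.sequence) <= panel.max_len
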