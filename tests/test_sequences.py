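"""Saturation-mutagenesis enumeration, translation, and census bookkeeping."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gldcscore import (
    CodingSequence,
    PrematureStopError,
    enumerate_missense,
    parse_label,
    translate,
)

# Independent table-driven translator: the oracle against which the
# library translation path is checked.  Written from the standard genetic
# code, not from the implementation.
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def oracle_translate(seq: str) -> str:
    return "".join(CODON_TABLE[seq[i : i + 3]] for i in range(0, len(seq), 3))


def random_orf(rng: np.random.Generator, n_codons: int) -> str:
    """Random in-frame, stop-free coding sequence starting with ATG."""
    sense = [c for c, aa in CODON_TABLE.items() if aa != "*"]
    return "ATG" + "".join(rng.choice(sense, size=n_codons - 1))


@pytest.mark.parametrize(
    "seq,protein",
    [("ATGAAA", "MK"), ("ATGTAA", "M"), ("ATGGGTTGA", "MG")],
)
def test_translate_drops_single_trailing_stop(seq, protein):
    assert translate(seq) == protein


def test_translate_rejects_internal_stop_and_bad_length():
    with pytest.raises(PrematureStopError, match="premature stop"):
        translate("ATGTAAAAA")
    with pytest.raises(ValueError, match="multiple of 3"):
        translate("ATGAA")


def test_translate_agrees_with_codon_table_oracle():
    rng = np.random.default_rng(0)
    for _ in range(20):
        seq = random_orf(rng, 100)
        assert translate(seq) == oracle_translate(seq)


def test_enumerate_toy_census_and_mutations(toy_cds):
    muts, census = enumerate_missense(toy_cds)
    assert sorted(m.label for m in muts) == sorted(
        ["M1L", "M1V", "M1K", "M1T", "M1R", "M1I", "K2Q", "K2E", "K2I", "K2T", "K2R", "K2N"]
    )
    assert census.n_total == 18
    assert census.n_silent == 1  # AAA -> AAG
    assert census.n_nonsense == 1  # AAA -> TAA
    assert census.n_leader_excluded == 0
    assert census.n_missense_unique == 12


def test_enumerate_leader_filter_excludes_first_codon():
    cds = CodingSequence(id="toy", nucleotides="ATGAAA", leader_length=1)
    muts, census = enumerate_missense(cds)
    assert {m.protein_position for m in muts} == {2}
    assert len(muts) == 6
    assert census.n_leader_excluded == 9  # the nine M1 missense routes


def test_emitted_ref_aa_matches_translation(bundle):
    cds = bundle.human_cds
    protein = translate(cds)
    muts, _ = enumerate_missense(cds)
    assert muts, "expected mutations from a real-length toy sequence"
    for m in muts:
        assert m.ref_aa == protein[m.protein_position - 1]
        assert m.label == f"{m.ref_aa}{m.protein_position}{m.alt_aa}"


@given(
    st.integers(min_value=0, max_value=2**32 - 1),
    st.integers(min_value=2, max_value=20),
    st.integers(min_value=0, max_value=3),
)
def test_census_partitions_all_substitutions(seed, n_codons, leader):
    """The four outcome classes partition the 3L attempted substitutions."""
    rng = np.random.default_rng(seed)
    cds = CodingSequence(
        id="r", nucleotides=random_orf(rng, n_codons), leader_length=min(leader, n_codons - 1)
    )
    muts, c = enumerate_missense(cds)
    assert c.n_total == 3 * len(cds.nucleotides)
    assert c.n_total == c.n_silent + c.n_nonsense + c.n_leader_excluded + c.n_missense_raw
    assert c.n_missense_unique == len(muts) == len({m.protein_key for m in muts})
    assert c.n_missense_unique <= c.n_missense_raw
    # idempotence: enumerating twice yields identical sets
    muts2, c2 = enumerate_missense(cds)
    assert muts == muts2 and c == c2


def brute_force_missense(cds: CodingSequence) -> set[tuple[int, str, str]]:
    """Naive string-mutation oracle: mutate, retranslate whole sequence, diff."""
    ref = oracle_translate(cds.nucleotides)
    out = set()
    for i in range(len(cds.nucleotides)):
        for b in "ACGT":
            if b == cds.nucleotides[i]:
                continue
            mutant = cds.nucleotides[:i] + b + cds.nucleotides[i + 1 :]
            alt = oracle_translate(mutant)
            diffs = [j for j, (x, y) in enumerate(zip(ref, alt)) if x != y]
            if len(diffs) != 1:
                continue
            j = diffs[0]
            if alt[j] == "*" or ref[j] == "*":
                continue
            if j + 1 <= cds.leader_length:
                continue
            out.add((j + 1, ref[j], alt[j]))
    return out


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_enumeration_agrees_with_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    n_codons = int(rng.integers(4, 20))  # sequences <= 60 nt
    cds = CodingSequence(
        id="bf", nucleotides=random_orf(rng, n_codons), leader_length=int(rng.integers(0, 3))
    )
    muts, _ = enumerate_missense(cds)
    assert {m.protein_key for m in muts} == brute_force_missense(cds)


def test_fragment_without_atg_warns_not_errors():
    with pytest.warns(UserWarning, match="ATG"):
        CodingSequence(id="frag", nucleotides="AAATTT")


def test_label_parser_round_trip_and_rejections():
    m = parse_label("A394V")
    assert (m.protein_position, m.ref_aa, m.alt_aa) == (394, "A", "V")
    with pytest.raises(ValueError, match="three-letter"):
        parse_label("Ala394Val")
    with pytest.raises(ValueError, match="malformed"):
        parse_label("394AV")
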