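"""In-silico saturation mutagenesis of a coding sequence.

Every single-nucleotide substitution in a cDNA is enumerated, translated, and
classified as silent, nonsense, or missense.  Missense changes falling in the
N-terminal mitochondrial leader peptide (residues 1..``leader_length``) are
excluded from analysis, and distinct nucleotide changes producing the same
protein substitution are collapsed to a single record.

Coordinates are 1-based and inclusive throughout, for both cDNA and protein.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from Bio.Seq import Seq

__all__ = [
    "CodingSequence",
    "MissenseMutation",
    "SubstitutionCensus",
    "translate",
    "enumerate_missense",
]

BASES = ("A", "C", "G", "T")


class PrematureStopError(ValueError):
    """Raised when a reference coding sequence contains an internal stop codon."""


@dataclass(frozen=True)
class CodingSequence:
    """A protein-coding DNA sequence.

    Parameters
    ----------
    id : str
        Sequence label (FASTA record id).
    nucleotides : str
        The coding sequence, A/C/G/T only, length divisible by 3.
    leader_length : int
        Number of N-terminal residues belonging to the mitochondrial leader
        peptide; missense mutations at residues 1..leader_length are excluded
        from analysis.  GLDC uses 35.
    """

    id: str
    nucleotides: str
    leader_length: int = 0

    def __post_init__(self) -> None:
        seq = self.nucleotides.upper().replace("U", "T")
        object.__setattr__(self, "nucleotides", seq)
        if not seq:
            raise ValueError("empty coding sequence")
        bad = set(seq) - set(BASES)
        if bad:
            raise ValueError(f"non-ACGT characters in sequence: {sorted(bad)}")
        if len(seq) % 3 != 0:
            raise ValueError(f"length {len(seq)} is not a multiple of 3")
        if not seq.startswith("ATG"):
            warnings.warn(
                f"{self.id!r} does not begin with ATG; treating as a fragment",
                stacklevel=3,
            )
        n_codons = len(seq) // 3
        if not 0 <= self.leader_length < n_codons:
            raise ValueError(
                f"leader_length {self.leader_length} outside [0, {n_codons})"
            )

    def __len__(self) -> int:
        return len(self.nucleotides)

    @property
    def n_codons(self) -> int:
        return len(self.nucleotides) // 3

    def codon(self, residue: int) -> str:
        """Return the codon for 1-based residue index ``residue``."""
        return self.nucleotides[3 * (residue - 1) : 3 * residue]


@dataclass(frozen=True, order=True)
class MissenseMutation:
    """One amino-acid substitution with its cDNA provenance.

    ``cdna_position``/``ref_base``/``alt_base`` may be ``None`` for mutations
    known only at the protein level (e.g. after cross-species transfer).
    """

    protein_position: int
    ref_aa: str
    alt_aa: str
    cdna_position: int | None = None
    ref_base: str | None = None
    alt_base: str | None = None

    def __post_init__(self) -> None:
        if self.ref_aa == self.alt_aa:
            raise ValueError(f"not a missense change: {self.ref_aa}=={self.alt_aa}")
        if self.protein_position < 1:
            raise ValueError("protein_position is 1-based, must be >= 1")
        if self.cdna_position is not None:
            codon_start = 3 * (self.protein_position - 1) + 1
            if not codon_start <= self.cdna_position <= codon_start + 2:
                raise ValueError(
                    f"cDNA position {self.cdna_position} outside codon of "
                    f"residue {self.protein_position}"
                )

    @property
    def label(self) -> str:
        """Canonical one-letter label, e.g. ``'A394V'``."""
        return f"{self.ref_aa}{self.protein_position}{self.alt_aa}"

    @property
    def protein_key(self) -> tuple[int, str, str]:
        """Deduplication key ignoring cDNA provenance."""
        return (self.protein_position, self.ref_aa, self.alt_aa)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


_LABEL_AA = set("ACDEFGHIKLMNPQRSTVWY")


def parse_label(label: str) -> MissenseMutation:
    """Parse a one-letter mutation label such as ``'A394V'``.

    Three-letter labels (``Ala394Val``) are rejected with guidance.
    """
    s = label.strip()
    if len(s) >= 7 and s[:3].isalpha() and s[-3:].isalpha():
        raise ValueError(
            f"{label!r} looks like a three-letter code; use one-letter form e.g. A394V"
        )
    if len(s) < 3 or s[0] not in _LABEL_AA or s[-1] not in _LABEL_AA or not s[1:-1].isdigit():
        raise ValueError(f"malformed mutation label {label!r}; expected e.g. A394V")
    return MissenseMutation(protein_position=int(s[1:-1]), ref_aa=s[0], alt_aa=s[-1])


@dataclass
class SubstitutionCensus:
    """Bookkeeping of every attempted single-nucleotide substitution.

    The four outcome classes partition the 3L attempted substitutions:
    ``n_total == n_silent + n_nonsense + n_leader_excluded + n_missense_raw``.
    ``n_leader_excluded`` counts missense substitutions discarded because they
    fall in the leader peptide; ``n_missense_raw`` counts missense
    substitutions outside the leader before duplicate collapse.
    """

    n_total: int = 0
    n_silent: int = 0
    n_nonsense: int = 0
    n_leader_excluded: int = 0
    n_missense_raw: int = 0
    n_missense_unique: int = 0
    # same protein change reachable through a different nucleotide change,
    # including within-leader duplicates for the record
    n_duplicates_removed: int = field(default=0)

    def validate(self) -> None:
        if self.n_total != (
            self.n_silent + self.n_nonsense + self.n_leader_excluded + self.n_missense_raw
        ):
            raise AssertionError("census classes do not partition total substitutions")
        if self.n_missense_unique > self.n_missense_raw:
            raise AssertionError("unique missense exceeds raw missense")


def translate(cds: CodingSequence | str) -> str:
    """Translate a coding sequence with the standard genetic code.

    A single trailing stop codon is dropped.  An internal stop raises
    :class:`PrematureStopError` ("premature stop in reference").
    """
    seq = cds.nucleotides if isinstance(cds, CodingSequence) else str(cds).upper()
    if len(seq) % 3 != 0:
        raise ValueError(f"length {len(seq)} is not a multiple of 3")
    protein = str(Seq(seq).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        raise PrematureStopError(
            f"premature stop in reference at codon {protein.index('*') + 1}"
        )
    return protein


def enumerate_missense(
    cds: CodingSequence, *, collapse: bool = True
) -> tuple[list[MissenseMutation], SubstitutionCensus]:
    """Enumerate all theoretical missense mutations of ``cds``.

    Each of the 3L single-nucleotide substitutions is attempted and
    classified.  Silent and nonsense changes are discarded, as are missense
    changes within the leader peptide.  With ``collapse=True`` (default)
    distinct nucleotide routes to the same protein substitution are reduced
    to one record (the lowest cDNA position), mirroring duplicate removal in
    a theoretical-mutation table; ``collapse=False`` keeps every cDNA
    provenance.

    Returns the mutation list (cDNA order) and a :class:`SubstitutionCensus`.
    """
    protein = translate(cds)  # also rejects internal stops
    census = SubstitutionCensus()
    seen: set[tuple[int, str, str]] = set()
    out: list[MissenseMutation] = []

    seq = cds.nucleotides
    for i, ref_base in enumerate(seq):  # 0-based nucleotide index
        res_idx = i // 3  # 0-based residue index
        codon = seq[3 * res_idx : 3 * res_idx + 3]
        within = i % 3
        ref_aa = protein[res_idx] if res_idx < len(protein) else "*"
        for alt_base in BASES:
            if alt_base == ref_base:
                continue
            census.n_total += 1
            alt_codon = codon[:within] + alt_base + codon[within + 1 :]
            alt_aa = str(Seq(alt_codon).translate())
            if alt_aa == ref_aa:
                census.n_silent += 1
                continue
            if alt_aa == "*":
                census.n_nonsense += 1
                continue
            if ref_aa == "*":
                # substitution in the terminal stop codon creating a residue:
                # a read-through, not a missense change; count as silent class
                census.n_silent += 1
                continue
            if res_idx + 1 <= cds.leader_length:
                census.n_leader_excluded += 1
                continue
            census.n_missense_raw += 1
            m = MissenseMutation(
                protein_position=res_idx + 1,
                ref_aa=ref_aa,
                alt_aa=alt_aa,
                cdna_position=i + 1,
                ref_base=ref_base,
                alt_base=alt_base,
            )
            if collapse:
                if m.protein_key in seen:
                    census.n_duplicates_removed += 1
                    continue
                seen.add(m.protein_key)
            out.append(m)

    census.n_missense_unique = len({m.protein_key for m in out})
    census.validate()
    return out, census
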