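"""Binary mutation parameters: evaluation, ΔΔG categories, active site, phi.

Each mutation is scored against a registry of binary indicators drawn from
four general categories — protein-stability effects (ΔΔG classes), mutation
position (secondary structure, dimerization interface, active site),
evolutionary conservation, and change in amino-acid properties — plus a
conserved-substitution indicator (the single negatively-signed parameter)
and codon/tRNA availability.  Indicators are strictly 0/1; a parameter whose
underlying data is missing raises, never silently scores 0.

The canonical 18-parameter registry ships as ``data/registry.yaml``;
the engine itself works with a registry of any width.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from Bio.Align import substitution_matrices
from Bio.PDB import PDBParser
from Bio.PDB.NeighborSearch import NeighborSearch

from .sequences import MissenseMutation

__all__ = [
    "DDG_CATEGORIES",
    "DdgRecord",
    "ParameterSpec",
    "ParameterRegistry",
    "ParameterVector",
    "ActiveSiteAnnotation",
    "ParameterUnavailableError",
    "categorize_ddg",
    "default_registry",
    "load_registry",
    "evaluate_parameters",
    "evaluate_table",
    "compute_active_site",
    "phi_correlation",
    "phi_matrix",
]

# ΔΔG bands in kcal/mol.  Destabilizing bounds follow the published scheme
# (< -5.0 very destabilizing; [-5.0, -1.5) destabilizing, i.e. "< -1.5" is
# strict); the stabilizing side is mirrored at +1.5 / +5.0.
DDG_CATEGORIES = (
    "very_destabilizing",
    "destabilizing",
    "unchanged",
    "stabilizing",
    "very_stabilizing",
)
_VERY_DESTAB_MAX = -5.0
_DESTAB_MAX = -1.5  # exclusive
_STAB_MIN = 1.5  # exclusive
_VERY_STAB_MIN = 5.0  # exclusive


def categorize_ddg(ddg: float) -> str:
    """Assign a folding free-energy change (kcal/mol) to its severity band.

    Bands: (-inf, -5.0) very_destabilizing; [-5.0, -1.5) destabilizing;
    [-1.5, 1.5] unchanged; (1.5, 5.0] stabilizing; (5.0, inf) very_stabilizing.
    """
    ddg = float(ddg)
    if not math.isfinite(ddg):
        raise ValueError(f"non-finite ddG: {ddg}")
    if ddg < _VERY_DESTAB_MAX:
        return "very_destabilizing"
    if ddg < _DESTAB_MAX:
        return "destabilizing"
    if ddg <= _STAB_MIN:
        return "unchanged"
    if ddg <= _VERY_STAB_MIN:
        return "stabilizing"
    return "very_stabilizing"


@dataclass(frozen=True)
class DdgRecord:
    label: str
    ddg: float
    category: str = ""

    def __post_init__(self) -> None:
        expected = categorize_ddg(self.ddg)
        if not self.category:
            object.__setattr__(self, "category", expected)
        elif self.category != expected:
            raise ValueError(
                f"{self.label}: category {self.category!r} inconsistent with "
                f"ddG {self.ddg} ({expected})"
            )


class ParameterUnavailableError(KeyError):
    """Underlying data for a parameter is missing for this mutation."""


@dataclass(frozen=True)
class ParameterSpec:
    name: str
    category: str
    provider: str
    sign: int = 1
    description: str = ""


@dataclass
class ParameterRegistry:
    """Ordered collection of binary parameter definitions.

    Exactly one parameter must carry ``sign == -1`` (the conserved-substitution
    indicator, which subtracts from the score).
    """

    specs: list[ParameterSpec]

    def __post_init__(self) -> None:
        names = [s.name for s in self.specs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameter names in registry")
        negatives = [s.name for s in self.specs if s.sign == -1]
        if len(negatives) != 1:
            raise ValueError(
                f"registry must contain exactly one sign=-1 parameter, got {negatives}"
            )

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.specs]

    @property
    def signs(self) -> dict[str, int]:
        return {s.name: s.sign for s in self.specs}

    def __len__(self) -> int:
        return len(self.specs)

    def __iter__(self):
        return iter(self.specs)


@dataclass
class ParameterVector:
    """The binary indicator values of one mutation, with provenance."""

    label: str
    values: dict[str, int]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, v in self.values.items():
            if v not in (0, 1):
                raise ValueError(f"parameter {name!r} is not binary: {v!r}")

    def check_complete(self, registry: ParameterRegistry) -> None:
        missing = set(registry.names) - set(self.values)
        extra = set(self.values) - set(registry.names)
        if missing or extra:
            raise ValueError(
                f"{self.label}: parameter names do not match registry "
                f"(missing={sorted(missing)}, extra={sorted(extra)})"
            )


def load_registry(path: str | Path | None = None) -> ParameterRegistry:
    """Load a parameter registry from YAML (default: the canonical 18)."""
    if path is None:
        text = resources.files("gldcscore.data").joinpath("registry.yaml").read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    specs = [
        ParameterSpec(
            name=p["name"],
            category=p["category"],
            provider=p["provider"],
            sign=int(p.get("sign", 1)),
            description=p.get("description", ""),
        )
        for p in doc["parameters"]
    ]
    return ParameterRegistry(specs)


def default_registry() -> ParameterRegistry:
    """The canonical 18-parameter registry shipped with the package."""
    return load_registry(None)


Provider = Callable[[MissenseMutation, str], int]


def evaluate_parameters(
    m: MissenseMutation,
    providers: Mapping[str, Provider],
    registry: ParameterRegistry,
) -> ParameterVector:
    """Evaluate every registered parameter for one mutation.

    ``providers`` maps provider ids (as named in the registry) to callables
    ``(mutation, parameter_name) -> 0 | 1``.  Missing providers or missing
    per-mutation data raise :class:`ParameterUnavailableError` — a mutation is
    never silently scored 0.
    """
    values: dict[str, int] = {}
    provenance: dict[str, str] = {}
    for spec in registry:
        if spec.provider not in providers:
            raise ParameterUnavailableError(
                f"no provider {spec.provider!r} for parameter {spec.name!r}"
            )
        v = providers[spec.provider](m, spec.name)
        values[spec.name] = int(bool(v))
        provenance[spec.name] = spec.provider
    return ParameterVector(label=m.label, values=values, provenance=provenance)


def evaluate_table(
    mutations: Iterable[MissenseMutation],
    providers: Mapping[str, Provider],
    registry: ParameterRegistry,
) -> pd.DataFrame:
    """Parameter matrix (mutations x registry) as a DataFrame indexed by label."""
    rows = {}
    for m in mutations:
        rows[m.label] = evaluate_parameters(m, providers, registry).values
    return pd.DataFrame.from_dict(rows, orient="index", columns=registry.names)


# ---------------------------------------------------------------------------
# Built-in providers
# ---------------------------------------------------------------------------

# Amino-acid property classes used for change-in-property indicators.
# Size by side-chain volume tercile; polarity and charge at physiological pH.
AA_SIZE = {
    **{a: "small" for a in "AGSCPND"},
    **{a: "medium" for a in "TVEQHIL"},
    **{a: "large" for a in "MKRFYW"},
}
AA_POLAR = set("STNQYCDEKRH")
AA_CHARGE = {**{a: 1 for a in "KRH"}, **{a: -1 for a in "DE"}}


def ddg_provider(table: Mapping[str, float]) -> Provider:
    """Stability indicators from a per-mutation ΔΔG lookup (kcal/mol)."""

    param_to_category = {
        "ddg_very_destabilizing": "very_destabilizing",
        "ddg_destabilizing": "destabilizing",
        "ddg_stabilizing": "stabilizing",
        "ddg_very_stabilizing": "very_stabilizing",
    }

    def provider(m: MissenseMutation, name: str) -> int:
        if m.label not in table:
            raise ParameterUnavailableError(f"parameter unavailable: no ddG for {m.label}")
        return int(categorize_ddg(table[m.label]) == param_to_category[name])

    return provider


def position_class_provider(
    *,
    helix: Iterable[int] = (),
    sheet: Iterable[int] = (),
    dimer_interface: Iterable[int] = (),
    active_site: "Iterable[int] | ActiveSiteAnnotation" = (),
) -> Provider:
    """Positional indicators from per-residue annotation sets."""
    if isinstance(active_site, ActiveSiteAnnotation):
        active_site = active_site.positions
    sets = {
        "pos_helix": frozenset(helix),
        "pos_sheet": frozenset(sheet),
        "pos_dimer_interface": frozenset(dimer_interface),
        "pos_active_site": frozenset(active_site),
    }

    def provider(m: MissenseMutation, name: str) -> int:
        return int(m.protein_position in sets[name])

    return provider


def consurf_provider(
    grades: Mapping[int, int], functional: Iterable[int] = ()
) -> Provider:
    """Conservation indicators from per-residue ConSurf grades (1-9)."""
    functional = frozenset(functional)

    def provider(m: MissenseMutation, name: str) -> int:
        if name == "cons_functional_residue":
            return int(m.protein_position in functional)
        if m.protein_position not in grades:
            raise ParameterUnavailableError(
                f"parameter unavailable: no ConSurf grade for residue {m.protein_position}"
            )
        g = grades[m.protein_position]
        if name == "cons_grade_conserved":
            return int(g >= 7)
        if name == "cons_grade_highly_conserved":
            return int(g >= 8)
        if name == "cons_grade_maximal":
            return int(g == 9)
        raise KeyError(name)

    return provider


def property_change_provider() -> Provider:
    """Change-in-amino-acid-property indicators (computed, no data needed)."""

    def provider(m: MissenseMutation, name: str) -> int:
        r, a = m.ref_aa, m.alt_aa
        if name == "prop_proline_change":
            return int(("P" in (r, a)))
        if name == "prop_size_change":
            return int(AA_SIZE[r] != AA_SIZE[a])
        if name == "prop_polarity_change":
            return int((r in AA_POLAR) != (a in AA_POLAR))
        if name == "prop_charge_change":
            return int(AA_CHARGE.get(r, 0) != AA_CHARGE.get(a, 0))
        raise KeyError(name)

    return provider


def conserved_substitution_provider(
    matrix: str = "BLOSUM62", min_score: float = 1.0
) -> Provider:
    """Evolutionarily tolerated exchange: substitution-matrix score >= min_score."""
    mat = substitution_matrices.load(matrix)

    def provider(m: MissenseMutation, name: str) -> int:
        return int(mat[m.ref_aa, m.alt_aa] >= min_score)

    return provider


def codon_usage_provider(
    cds, usage: Mapping[str, float], min_fraction: float = 0.1
) -> Provider:
    """Mutant-codon availability from a codon-usage table.

    ``cds`` is the :class:`~gldcscore.sequences.CodingSequence` the mutation
    was enumerated from; ``usage`` maps codons to within-family usage
    fractions.  The indicator fires when the mutant codon is rare
    (< ``min_fraction``), flagging poor tRNA availability in the target
    species.  Requires cDNA provenance on the mutation.
    """

    def provider(m: MissenseMutation, name: str) -> int:
        if m.cdna_position is None or m.alt_base is None:
            raise ParameterUnavailableError(
                f"parameter unavailable: {m.label} has no cDNA provenance"
            )
        codon = cds.codon(m.protein_position)
        within = (m.cdna_position - 1) % 3
        mutant_codon = codon[:within] + m.alt_base + codon[within + 1 :]
        if mutant_codon not in usage:
            raise ParameterUnavailableError(
                f"parameter unavailable: no usage entry for codon {mutant_codon}"
            )
        return int(usage[mutant_codon] < min_fraction)

    return provider


def table_provider(table: Mapping[str, Mapping[str, int]]) -> Provider:
    """Generic provider reading pre-computed 0/1 values keyed by mutation label.

    ``table[label][parameter_name]`` -> 0/1.  This is how supplementary-style
    parameter tables plug in directly.
    """

    def provider(m: MissenseMutation, name: str) -> int:
        if m.label not in table:
            raise ParameterUnavailableError(f"parameter unavailable: {m.label} not in table")
        row = table[m.label]
        if name not in row:
            raise ParameterUnavailableError(
                f"parameter unavailable: {name!r} missing for {m.label}"
            )
        return int(row[name])

    return provider


# ---------------------------------------------------------------------------
# Active site from structure
# ---------------------------------------------------------------------------


@dataclass
class ActiveSiteAnnotation:
    """Residues within ``cutoff`` angstroms of the catalytic center atoms."""

    positions: frozenset[int]
    cutoff: float
    centers: tuple = ()

    def __post_init__(self) -> None:
        self.positions = frozenset(int(p) for p in self.positions)

    def __contains__(self, position: int) -> bool:
        return int(position) in self.positions


def compute_active_site(
    structure,
    centers: Iterable,
    cutoff: float = 5.0,
) -> ActiveSiteAnnotation:
    """Derive the active-site region from 3-D coordinates.

    A residue belongs to the region iff any of its atoms lies within
    ``cutoff`` angstroms of any atom of a center residue (the catalytic
    lysine, the bound cofactor or the substrate, when present in the file).

    Parameters
    ----------
    structure : path or Bio.PDB entity
        PDB file path, or an already-parsed structure/model.
    centers : iterable
        Center selectors: an ``int`` residue number (matched in any chain),
        a ``(chain_id, resseq)`` tuple, or a residue name string such as
        ``"PLP"`` for hetero groups.
    cutoff : float
        Distance cutoff in angstroms (the GLDC analysis uses 5).
    """
    if isinstance(structure, (str, Path)):
        structure = PDBParser(QUIET=True).get_structure("s", str(structure))
    residues = list(structure.get_residues())
    centers = list(centers)

    def is_center(res) -> bool:
        chain_id = res.get_parent().id
        resseq = res.id[1]
        for c in centers:
            if isinstance(c, str) and res.get_resname().strip() == c:
                return True
            if isinstance(c, tuple) and (chain_id, resseq) == (c[0], c[1]):
                return True
            if isinstance(c, int) and resseq == c:
                return True
        return False

    center_residues = [r for r in residues if is_center(r)]
    if not center_residues:
        raise ValueError(f"no center residues found for selectors {centers!r}")

    positions: set[int] = set()
    # center residues always belong to their own region (distance 0)
    for r in center_residues:
        if r.id[0] == " ":
            positions.add(r.id[1])

    atoms = [a for r in residues for a in r.get_atoms()]
    if cutoff > 0:
        ns = NeighborSearch(atoms)
        for cr in center_residues:
            for atom in cr.get_atoms():
                for near in ns.search(atom.coord, float(cutoff)):
                    res = near.get_parent()
                    if res.id[0] == " ":  # standard residue, not het/water
                        positions.add(res.id[1])
    return ActiveSiteAnnotation(
        positions=frozenset(positions), cutoff=float(cutoff), centers=tuple(centers)
    )


# ---------------------------------------------------------------------------
# Phi coefficient
# ---------------------------------------------------------------------------


def phi_correlation(a, b) -> float:
    """Phi (mean-square contingency) coefficient of two binary vectors.

    phi = (n11*n00 - n10*n01) / sqrt(n1. * n0. * n.1 * n.0).  Equals the
    Pearson correlation of the 0/1 vectors.  Returns NaN when either vector
    is constant (undefined).
    """
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("need at least 2 observations")
    if not (np.isin(a, (0, 1)).all() and np.isin(b, (0, 1)).all()):
        raise ValueError("inputs must be binary 0/1 vectors")
    n11 = int(np.sum((a == 1) & (b == 1)))
    n10 = int(np.sum((a == 1) & (b == 0)))
    n01 = int(np.sum((a == 0) & (b == 1)))
    n00 = int(np.sum((a == 0) & (b == 0)))
    denom = (n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00)
    if denom == 0:
        return float("nan")
    return (n11 * n00 - n10 * n01) / math.sqrt(denom)


def phi_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Symmetric phi-correlation matrix over the columns of a 0/1 table."""
    cols = list(table.columns)
    out = pd.DataFrame(np.nan, index=cols, columns=cols)
    for i, ci in enumerate(cols):
        for cj in cols[i:]:
            out.loc[ci, cj] = out.loc[cj, ci] = phi_correlation(table[ci], table[cj])
    return out
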