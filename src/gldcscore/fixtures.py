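"""Deterministic synthetic data emulating the GLDC study inputs.

No accession is attached to the analyzed cDNAs and the per-mutation data
tables are not redistributable, so every test runs against synthetic
material built here: a short "human-like" coding sequence and a "mouse-like"
copy differing by point substitutions plus one in-frame 15-nt insertion
(five glycines, echoing the mouse-specific glycine run at residues 43-47);
a binary parameter table with planted linear weights; and clinical outcome
scores on a noisy line.  Regeneration with the same seed is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .parameters import default_registry
from .scoring import WeightSet
from .sequences import CodingSequence, translate

__all__ = ["FixtureBundle", "generate_fixture"]

# Line used to synthesize clinical outcome scores from planted WMMS;
# mirrors the published attenuated/severe trend.
LINE_SLOPE = 0.76
LINE_INTERCEPT = -2.5

_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
_GLYCINE_INSERT = "GGAGGCGGTGGAGGC"  # five glycines, in frame


@dataclass
class FixtureBundle:
    """Synthetic inputs for one seeded test scenario."""

    seed: int
    human_cds: CodingSequence
    mouse_cds: CodingSequence
    parameters: pd.DataFrame  # mutations x parameters, 0/1
    planted_weights: WeightSet
    training_cos: pd.Series  # X @ w + noise: target for weight recovery
    wmms: pd.Series  # X @ w, the planted scores
    outcome_pairs: pd.DataFrame  # columns cos, wmms on a noisy line
    noise_sd: float

    def write(self, outdir: str | Path) -> None:
        """Materialize the bundle as plain-text files."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "sequences.fasta", "w") as fh:
            for cds in (self.human_cds, self.mouse_cds):
                fh.write(f">{cds.id}\n{cds.nucleotides}\n")
        self.parameters.rename_axis("label").to_csv(outdir / "parameters.tsv", sep="\t")
        pd.Series(self.planted_weights.coefficients, name="weight").rename_axis(
            "parameter"
        ).to_csv(outdir / "planted_weights.tsv", sep="\t")
        pd.DataFrame(
            {"label": self.training_cos.index, "cos": self.training_cos.values}
        ).to_csv(outdir / "training_cos.tsv", sep="\t", index=False)
        self.outcome_pairs.to_csv(outdir / "outcome_pairs.tsv", sep="\t", index=False)


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """In-frame cDNA: ATG + random non-stop codons + TAA."""
    body = rng.choice(_CODONS, size=n_codons - 1)
    return "ATG" + "".join(body) + "TAA"


def _mutate_point(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    """Apply n random single-base substitutions that keep the frame stop-free."""
    seq = list(seq)
    n_codons = len(seq) // 3 - 1  # exclude the stop codon
    done = 0
    while done < n_subs:
        i = int(rng.integers(3, 3 * n_codons))  # keep ATG intact
        alt = str(rng.choice([b for b in "ACGT" if b != seq[i]]))
        old = seq[i]
        seq[i] = alt
        codon_start = 3 * (i // 3)
        codon = "".join(seq[codon_start : codon_start + 3])
        if codon in ("TAA", "TAG", "TGA"):
            seq[i] = old
            continue
        done += 1
    return "".join(seq)


def generate_fixture(
    seed: int,
    n_mutations: int = 40,
    k_parameters: int = 18,
    noise_sd: float = 0.5,
    *,
    n_codons: int = 60,
    bernoulli_p: float = 0.3,
    n_point_substitutions: int = 6,
    insertion_after_codon: int = 42,
) -> FixtureBundle:
    """Generate the full synthetic bundle for one seed.

    Defaults emulate the study's conditions at test scale: a training set of
    40 mutations over the 18-parameter registry with indicator density 0.3,
    outcome noise of 0.5 score units, and a mouse-like sequence carrying a
    five-glycine in-frame insertion after codon 42.
    """
    if n_mutations < 2 or k_parameters < 1:
        raise ValueError("need n_mutations >= 2 and k_parameters >= 1")
    # one labelled mutation per residue at most; grow the toy protein if needed
    n_codons = max(n_codons, n_mutations + 3)
    rng = np.random.default_rng(seed)

    human_seq = _random_cds(rng, n_codons)
    mouse_seq = _mutate_point(rng, human_seq, n_point_substitutions)
    ins_at = 3 * insertion_after_codon
    if ins_at >= len(mouse_seq) - 3:
        raise ValueError("insertion point beyond sequence end")
    mouse_seq = mouse_seq[:ins_at] + _GLYCINE_INSERT + mouse_seq[ins_at:]
    human_cds = CodingSequence(id="human_like", nucleotides=human_seq)
    mouse_cds = CodingSequence(id="mouse_like", nucleotides=mouse_seq)

    if k_parameters == 18:
        param_names = default_registry().names
    else:
        param_names = [f"p{i + 1}" for i in range(k_parameters)]

    # plausible mutation labels drawn from the translated human-like protein
    protein = translate(human_cds)
    positions = rng.choice(np.arange(2, len(protein) + 1), size=n_mutations, replace=False)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    labels = []
    for pos in np.sort(positions):
        ref = protein[int(pos) - 1]
        alt = str(rng.choice([a for a in aas if a != ref]))
        labels.append(f"{ref}{int(pos)}{alt}")

    X = rng.binomial(1, bernoulli_p, size=(n_mutations, k_parameters))
    params = pd.DataFrame(X, index=labels, columns=param_names)

    w = rng.normal(0.0, 1.5, size=k_parameters)
    weights = WeightSet(
        coefficients={n: float(c) for n, c in zip(param_names, w)}, intercept=0.0
    )
    wmms = pd.Series(X @ w, index=labels, name="wmms")
    training_cos = pd.Series(
        X @ w + rng.normal(0.0, noise_sd, size=n_mutations),
        index=labels,
        name="cos",
    )
    outcome_pairs = pd.DataFrame(
        {
            "cos": (wmms.values - LINE_INTERCEPT) / LINE_SLOPE
            + rng.normal(0.0, noise_sd, size=n_mutations),
            "wmms": wmms.values,
        }
    )
    return FixtureBundle(
        seed=int(seed),
        human_cds=human_cds,
        mouse_cds=mouse_cds,
        parameters=params,
        planted_weights=weights,
        training_cos=training_cos,
        wmms=wmms,
        outcome_pairs=outcome_pairs,
        noise_sd=float(noise_sd),
    )
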