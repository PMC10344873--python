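"""Deterministic synthetic inputs: toy dimers, genes and signature catalogs.

The toy complex is two short facing chains whose closest heavy-atom
separation equals ``interface_gap`` exactly (the backbone N/C planes of the
two chains face each other; side chains point away from the interface), so
interface membership under a distance cutoff is known by construction.
Residue identities are drawn from small side-chain types only, keeping the
geometry self-consistent without energy minimisation.

Engineered "known disruptive" mutations are expressed as complex-energy
offsets in the ground-truth notes and injected through the workflow's
synthetic-offset hook (equivalently, the energy-matrix TSV interface), so
the ground truth is exact rather than emergent from the toy force field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .mutprob import BASES, CODON_TO_AA, GeneSequence, SignatureCatalog, all_class_keys

FIXTURE_RESIDUES = ("GLY", "ALA", "SER")

# explicit local coordinates (x offset, y, z) per residue type; y is the
# inter-chain axis, side chains at negative y point away from the partner
_RESIDUE_ATOMS: Dict[str, List[Tuple[str, str, Tuple[float, float, float]]]] = {
    "GLY": [
        ("N", "N", (-1.2, 0.8, 0.0)),
        ("CA", "C", (0.0, 0.0, 0.0)),
        ("C", "C", (1.2, 0.8, 0.0)),
        ("O", "O", (1.9, 0.8, 1.0)),
    ],
    "ALA": [
        ("N", "N", (-1.2, 0.8, 0.0)),
        ("CA", "C", (0.0, 0.0, 0.0)),
        ("C", "C", (1.2, 0.8, 0.0)),
        ("O", "O", (1.9, 0.8, 1.0)),
        ("CB", "C", (0.0, -1.0, 1.1)),
    ],
    "SER": [
        ("N", "N", (-1.2, 0.8, 0.0)),
        ("CA", "C", (0.0, 0.0, 0.0)),
        ("C", "C", (1.2, 0.8, 0.0)),
        ("O", "O", (1.9, 0.8, 1.0)),
        ("CB", "C", (0.0, -1.0, 1.1)),
        ("OG", "O", (0.0, -2.2, 1.9)),
    ],
}

RESIDUE_SPACING = 6.0  # Å along x between neighbouring residues


@dataclass
class FixtureRecipe:
    n_residues_per_partner: int = 3
    interface_gap: float = 4.0  # closest heavy-atom separation, Å
    seed: int = 1
    # (site label "A:2", target 1-letter aa, complex-energy offset kcal/mol)
    perturbed_mutations: List[Tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_residues_per_partner < 1:
            raise ValueError("need at least one residue per partner")
        if self.interface_gap <= 0:
            raise ValueError("interface_gap must be positive")
        for _, _, off in self.perturbed_mutations:
            if not np.isfinite(off):
                raise ValueError("perturbation offsets must be finite")


def _format_atom(serial: int, name: str, res: str, chain: str, resnum: int,
                 x: float, y: float, z: float, element: str) -> str:
    pname = name if len(name) == 4 else f" {name:<3s}"
    return (
        f"ATOM  {serial:>5d} {pname} {res:>3s} {chain:1s}{resnum:>4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          {element:>2s}"
    )


def make_toy_complex(recipe: FixtureRecipe) -> Tuple[str, Dict]:
    """Toy two-chain complex PDB text plus ground-truth notes.

    Chain A residue i and chain B residue i are aligned in x; the N and C
    atoms of facing residues are separated by exactly ``interface_gap``
    along y, and every other inter-chain atom pair is farther.  Hence a
    residue pair is in contact at cutoff c iff interface_gap ≤ c, and the
    ground truth lists all residues as interface residues in that case.
    """
    rng = np.random.default_rng(recipe.seed)
    n = recipe.n_residues_per_partner
    types = [FIXTURE_RESIDUES[i] for i in rng.integers(0, len(FIXTURE_RESIDUES), 2 * n)]
    lines: List[str] = []
    serial = 1
    # chain A occupies y <= 0.8 (N/C plane at +0.8); chain B mirrored above
    y_b = recipe.interface_gap + 1.6
    for chain, offset in (("A", 0), ("B", n)):
        for i in range(n):
            res = types[offset + i]
            x0 = RESIDUE_SPACING * i
            for name, element, (dx, dy, dz) in _RESIDUE_ATOMS[res]:
                if chain == "A":
                    x, y, z = x0 + dx, dy, dz
                else:
                    x, y, z = x0 + dx, y_b - dy, -dz
                lines.append(
                    _format_atom(serial, name, res, chain, i + 1, x, y, z, element)
                )
                serial += 1
        lines.append("TER")
    lines.append("END")
    pdb_text = "\n".join(lines) + "\n"

    interface_labels = (
        [f"{c}:{i + 1}" for c in ("A", "B") for i in range(n)]
        if recipe.interface_gap <= 5.0
        else []
    )
    ground_truth = {
        "residue_types": {
            f"{'A' if k < n else 'B'}:{k % n + 1}": types[k] for k in range(2 * n)
        },
        "interface_sites_at_5A": interface_labels,
        "min_interchain_distance": recipe.interface_gap,
        "perturbed_mutations": list(recipe.perturbed_mutations),
    }
    return pdb_text, ground_truth


def make_uniform_catalog(signature_ids: Tuple[str, ...] = ("S1",)) -> SignatureCatalog:
    """All 96 classes equally likely, for closed-form probability oracles."""
    keys = all_class_keys()
    data = {sig: [1.0 / 96.0] * 96 for sig in signature_ids}
    return SignatureCatalog(pd.DataFrame(data, index=keys))


def make_random_catalog(seed: int, n_signatures: int = 3) -> SignatureCatalog:
    rng = np.random.default_rng(seed)
    keys = all_class_keys()
    data = {}
    for s in range(n_signatures):
        v = rng.random(96)
        data[f"S{s + 1}"] = v / v.sum()
    return SignatureCatalog(pd.DataFrame(data, index=keys))


def make_toy_gene(n_codons: int, seed: int = 1) -> GeneSequence:
    """Random coding sequence (no stop codons) with random single-base flanks."""
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    rng = np.random.default_rng(seed)
    codons = []
    while len(codons) < n_codons:
        codon = "".join(BASES[i] for i in rng.integers(0, 4, 3))
        if CODON_TO_AA[codon] != "*":
            codons.append(codon)
    flank5 = BASES[rng.integers(0, 4)]
    flank3 = BASES[rng.integers(0, 4)]
    return GeneSequence("".join(codons), flank5, flank3)


def write_fixture_tree(out_dir: str, seed: int = 1) -> List[str]:
    """Materialise a standard fixture set (PDB/FASTA/TSV) under ``out_dir``."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    written = []
    recipe = FixtureRecipe(n_residues_per_partner=3, interface_gap=4.0, seed=seed)
    pdb_text, truth = make_toy_complex(recipe)
    p = os.path.join(out_dir, "toy_dimer.pdb")
    with open(p, "w") as fh:
        fh.write(pdb_text)
    written.append(p)

    gene = make_toy_gene(12, seed=seed)
    p = os.path.join(out_dir, "toy_gene.fa")
    with open(p, "w") as fh:
        fh.write(f">toy_gene flank5={gene.flank5} flank3={gene.flank3}\n")
        fh.write(gene.coding + "\n")
    written.append(p)

    # a coding sequence consistent with the toy dimer's chain A, so scans
    # can run the codon-path and probability stages coherently
    from .confspace import AA3_TO_1
    from .mutprob import AA_TO_CODONS

    rng = np.random.default_rng(seed + 1)
    n = recipe.n_residues_per_partner
    chain_a_aa = [AA3_TO_1[truth["residue_types"][f"A:{i + 1}"]] for i in range(n)]
    codons = [
        AA_TO_CODONS[aa][int(rng.integers(0, len(AA_TO_CODONS[aa])))]
        for aa in chain_a_aa
    ]
    p = os.path.join(out_dir, "toy_gene_chainA.fa")
    with open(p, "w") as fh:
        fh.write(">toy_gene_chainA flank5=A flank3=G\n")
        fh.write("".join(codons) + "\n")
    written.append(p)

    p = os.path.join(out_dir, "uniform_signatures.tsv")
    with open(p, "w") as fh:
        fh.write(make_uniform_catalog(("S1", "S2", "S3")).to_tsv())
    written.append(p)

    p = os.path.join(out_dir, "random_signatures.tsv")
    with open(p, "w") as fh:
        fh.write(make_random_catalog(seed).to_tsv())
    written.append(p)

    p = os.path.join(out_dir, "weights.tsv")
    with open(p, "w") as fh:
        fh.write("cancer_type\tS1\tS2\tS3\n")
        fh.write("toy_cancer\t0.5\t0.3\t0.2\n")
    written.append(p)

    p = os.path.join(out_dir, "ground_truth.txt")
    with open(p, "w") as fh:
        for k, v in truth.items():
            fh.write(f"{k}\t{v}\n")
    written.append(p)
    return written
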