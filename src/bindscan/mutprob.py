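"""Cancer-type-specific relative probabilities of amino-acid mutations.

A mutational signature is a probability distribution over the 96
pyrimidine-centred trinucleotide substitution classes (4 × 6 × 4).  Mixing
the signatures active in a cancer type by their burden contributions gives
the relative probability of any single base exchange in its local context.
An amino-acid mutation is scored by summing over every codon substitution
path that realises it with at most two base exchanges; a change reachable
only by substituting all three codon bases is excluded as extremely
unlikely rather than given a number.

Probabilities are relative, not absolute: they rank mutations against each
other within a scan, which is all the downstream prioritisation needs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
from Bio.Data import CodonTable

PYRIMIDINES = ("C", "T")
BASES = ("A", "C", "G", "T")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

_standard = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: Dict[str, str] = dict(_standard.forward_table)
for _stop in _standard.stop_codons:
    CODON_TO_AA[_stop] = "*"
AA_TO_CODONS: Dict[str, List[str]] = {}
for _codon in sorted(CODON_TO_AA):
    AA_TO_CODONS.setdefault(CODON_TO_AA[_codon], []).append(_codon)


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def class_key(five: str, ref: str, three: str, alt: str) -> str:
    """Canonical pyrimidine-centred class label, e.g. ``A[C>A]A``.

    Purine-centred contexts are folded onto the opposite strand first.
    """
    for b in (five, ref, three, alt):
        if b not in BASES:
            raise ValueError(f"invalid base {b!r}")
    if alt == ref:
        raise ValueError("alt base equals reference base")
    if ref not in PYRIMIDINES:
        five, ref, three = _COMPLEMENT[three], _COMPLEMENT[ref], _COMPLEMENT[five]
        alt = _COMPLEMENT[alt]
    return f"{five}[{ref}>{alt}]{three}"


def all_class_keys() -> List[str]:
    keys = []
    for ref in PYRIMIDINES:
        for alt in BASES:
            if alt == ref:
                continue
            for five in BASES:
                for three in BASES:
                    keys.append(f"{five}[{ref}>{alt}]{three}")
    return sorted(keys)


class SignatureCatalog:
    """96-class substitution probabilities per signature (wide table)."""

    def __init__(self, table: pd.DataFrame):
        expected = set(all_class_keys())
        if set(table.index) != expected:
            missing = sorted(expected - set(table.index))[:3]
            raise ValueError(f"catalog must index all 96 classes (missing e.g. {missing})")
        if (table.values < 0).any():
            raise ValueError("signature probabilities must be non-negative")
        sums = table.sum(axis=0)
        bad = sums[(sums - 1.0).abs() > 1e-6]
        if len(bad):
            raise ValueError(f"signatures must sum to 1: {list(bad.index)}")
        self.table = table.sort_index()

    @classmethod
    def from_tsv(cls, text: str) -> "SignatureCatalog":
        from io import StringIO

        return cls(pd.read_csv(StringIO(text), sep="\t", index_col=0))

    def to_tsv(self) -> str:
        return self.table.to_csv(sep="\t")

    @property
    def signature_ids(self) -> List[str]:
        return list(self.table.columns)

    def value(self, signature: str, key: str) -> float:
        return float(self.table.at[key, signature])


@dataclass
class CancerWeights:
    """Per-cancer-type signature contributions, renormalised to sum 1."""

    cancer_type: str
    weights: Dict[str, float]

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("signature weights must be non-negative")
        total = sum(self.weights.values())
        if total <= 0:
            raise ValueError("signature weights sum to zero")
        self.weights = {k: w / total for k, w in self.weights.items()}


@dataclass
class GeneSequence:
    """Coding sequence plus one flanking base on each side for context."""

    coding: str
    flank5: str = "A"
    flank3: str = "A"

    def __post_init__(self) -> None:
        self.coding = self.coding.upper()
        self.flank5 = self.flank5.upper()
        self.flank3 = self.flank3.upper()
        if len(self.coding) % 3 != 0:
            raise ValueError("coding sequence length must be divisible by 3")
        for b in self.coding + self.flank5 + self.flank3:
            if b not in BASES:
                raise ValueError(f"invalid base {b!r} in gene sequence")
        if len(self.flank5) != 1 or len(self.flank3) != 1:
            raise ValueError("flanks must be single bases")

    @property
    def n_codons(self) -> int:
        return len(self.coding) // 3

    def codon(self, protein_position: int) -> str:
        if not 1 <= protein_position <= self.n_codons:
            raise ValueError(f"protein position {protein_position} out of range")
        i = (protein_position - 1) * 3
        return self.coding[i : i + 3]

    def translate(self) -> str:
        return "".join(CODON_TO_AA[self.codon(i + 1)] for i in range(self.n_codons))

    @property
    def padded(self) -> str:
        return self.flank5 + self.coding + self.flank3


def base_change_probability(
    five: str,
    ref: str,
    three: str,
    alt: str,
    weights: CancerWeights,
    catalog: SignatureCatalog,
) -> float:
    """Signature-mixture probability of one contextual single base exchange."""
    key = class_key(five, ref, three, alt)
    return sum(
        w * catalog.value(sig, key) for sig, w in weights.weights.items()
    )


@dataclass(frozen=True)
class CodonPath:
    """One way to reach a target codon: the set of base substitutions."""

    target_codon: str
    changes: Tuple[Tuple[int, str], ...]  # (0-based position in codon, alt base)

    @property
    def n_changes(self) -> int:
        return len(self.changes)

    @property
    def path_class(self) -> str:
        return {1: "single", 2: "double", 3: "triple"}[self.n_changes]


def codon_paths(codon: str, target_aa: str) -> List[CodonPath]:
    """All codon substitutions realising ``target_aa``, by Hamming distance.

    Paths are listed in codon-table order; each is annotated single, double
    or triple by the number of bases that must change.
    """
    codon = codon.upper()
    if codon not in CODON_TO_AA:
        raise ValueError(f"invalid codon {codon!r}")
    if CODON_TO_AA[codon] == target_aa:
        raise ValueError("target amino acid equals the wildtype")
    if target_aa not in AA_TO_CODONS:
        raise ValueError(f"no codons encode {target_aa!r}")
    paths = []
    for tc in AA_TO_CODONS[target_aa]:
        changes = tuple(
            (i, tc[i]) for i in range(3) if tc[i] != codon[i]
        )
        paths.append(CodonPath(tc, changes))
    return paths


EXCLUDED_TRIPLE = "EXCLUDED_TRIPLE"


@dataclass
class MutationProbability:
    protein_position: int
    wildtype_aa: str
    target_aa: str
    paths: List[Tuple[CodonPath, Optional[float]]] = field(default_factory=list)
    relative_probability: Optional[float] = None  # None == excluded triple
    cancer_type: Optional[str] = None

    @property
    def is_excluded_triple(self) -> bool:
        return self.relative_probability is None

    @property
    def label(self) -> str:
        return f"{self.wildtype_aa}{self.protein_position}{self.target_aa}"

    @property
    def display(self) -> str:
        if self.is_excluded_triple:
            return EXCLUDED_TRIPLE
        return repr(self.relative_probability)


def _path_probability(
    gene_seq: str,
    flank5: str,
    flank3: str,
    codon_start: int,
    path: CodonPath,
    weights: CancerWeights,
    catalog: SignatureCatalog,
) -> float:
    """Probability of one ≤2-change path, context windows on the raw sequence.

    Single changes use the genomic flanking context directly.  Double
    changes sum over both substitution orders the product of the two step
    probabilities, the second step evaluated in the context left by the
    first — adjacent substitutions therefore see each other.
    """
    padded = flank5 + gene_seq + flank3  # index i in gene -> i+1 in padded

    def step(seq_padded: str, gene_index: int, alt: str) -> float:
        p = gene_index + 1
        return base_change_probability(
            seq_padded[p - 1], seq_padded[p], seq_padded[p + 1], alt, weights, catalog
        )

    changes = [(codon_start + off, alt) for off, alt in path.changes]
    if len(changes) == 1:
        idx, alt = changes[0]
        return step(padded, idx, alt)
    total = 0.0
    for order in itertools.permutations(changes):
        seq = padded
        prob = 1.0
        for idx, alt in order:
            prob *= step(seq, idx, alt)
            p = idx + 1
            seq = seq[:p] + alt + seq[p + 1 :]
        total += prob
    return total


def mutation_probability(
    gene: GeneSequence,
    protein_position: int,
    target_aa: str,
    weights: CancerWeights,
    catalog: SignatureCatalog,
) -> MutationProbability:
    """Relative probability that the DNA changes encoding one amino-acid
    mutation arise, summed over all ≤2-base-exchange codon paths."""
    codon = gene.codon(protein_position)
    wt_aa = CODON_TO_AA[codon]
    paths = codon_paths(codon, target_aa)
    codon_start = (protein_position - 1) * 3
    scored: List[Tuple[CodonPath, Optional[float]]] = []
    total: Optional[float] = None
    for path in paths:
        if path.n_changes >= 3:
            scored.append((path, None))
            continue
        p = _path_probability(
            gene.coding, gene.flank5, gene.flank3, codon_start, path, weights, catalog
        )
        scored.append((path, p))
        total = p if total is None else total + p
    return MutationProbability(
        protein_position=protein_position,
        wildtype_aa=wt_aa,
        target_aa=target_aa,
        paths=scored,
        relative_probability=total,
        cancer_type=weights.cancer_type,
    )


def rank_probabilities(
    mutations: Iterable[MutationProbability],
) -> List[MutationProbability]:
    """Descending by relative probability; excluded triples last; ties by
    protein position then target residue."""
    return sorted(
        mutations,
        key=lambda m: (
            m.is_excluded_triple,
            -(m.relative_probability or 0.0),
            m.protein_position,
            m.target_aa,
        ),
    )


def probability_table(mutations: Sequence[MutationProbability]) -> pd.DataFrame:
    rows = []
    for m in mutations:
        rows.append(
            {
                "position": m.protein_position,
                "wildtype_aa": m.wildtype_aa,
                "target_aa": m.target_aa,
                "relative_probability": (
                    "" if m.is_excluded_triple else m.relative_probability
                ),
                "status": EXCLUDED_TRIPLE if m.is_excluded_triple else "OK",
                "n_paths_scored": sum(1 for _, p in m.paths if p is not None),
                "paths": ";".join(
                    f"{p.target_codon}:{p.path_class}" for p, _ in m.paths
                ),
            }
        )
    return pd.DataFrame(rows)


def load_weights_tsv(text: str, cancer_type: str) -> CancerWeights:
    """Weights table: rows = cancer types, columns = signature ids."""
    from io import StringIO

    df = pd.read_csv(StringIO(text), sep="\t", index_col=0)
    if cancer_type not in df.index:
        raise KeyError(f"cancer type {cancer_type!r} not in weights table")
    row = df.loc[cancer_type]
    return CancerWeights(cancer_type, {k: float(v) for k, v in row.items() if v > 0})
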