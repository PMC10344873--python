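"""Mutation enumeration and discrete-rotamer conformation spaces.

Each K* evaluation needs three conformation spaces — the bound complex and
the two unbound partners — sharing the same rigid template atoms apart from
the partner split.  Mutable residues contribute flexible positions whose
side chains are rebuilt from the rotamer library; all other residues (and
the mutable residues' backbones) form the rigid template.  DNA residues are
always rigid and cannot be mutated.

Continuous side-chain flexibility is approximated by discrete rotamers with
optional ±10° sub-sampling per chi (off by default).
"""

from __future__ import annotations

import importlib.resources
import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from . import geometry
from .structures import Atom, ResidueSite, Structure, lookup_params

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
ALL_AA1 = sorted(AA1_TO_3)
HIS_VARIANTS = ("H1", "H2", "H3")


@dataclass(frozen=True)
class MutationSpec:
    """One amino-acid substitution at a site, with His protonation variant."""

    site: ResidueSite
    target_aa: str  # 1-letter
    protonation_variant: Optional[str] = None  # None | H1 | H2 | H3

    def __post_init__(self) -> None:
        if self.target_aa not in AA1_TO_3:
            raise ValueError(f"unknown amino acid {self.target_aa!r}")
        if (self.protonation_variant is not None) != (self.target_aa == "H"):
            raise ValueError("protonation variant set iff target is histidine")
        if self.protonation_variant is not None and self.protonation_variant not in HIS_VARIANTS:
            raise ValueError(f"unknown protonation variant {self.protonation_variant}")

    @property
    def residue_type(self) -> str:
        """3-letter template/parameter key (His variants get their own)."""
        if self.protonation_variant is not None:
            return f"HIS_{self.protonation_variant}"
        return AA1_TO_3[self.target_aa]

    @property
    def is_reference(self) -> bool:
        return self.target_aa == AA3_TO_1.get(self.site.residue_type)

    @property
    def label(self) -> str:
        wt = AA3_TO_1.get(self.site.residue_type, "?")
        base = f"{wt}{self.site.residue_number}{self.target_aa}"
        if self.protonation_variant:
            base += f".{self.protonation_variant}"
        return base


class RotamerLibrary:
    """Backbone-independent chi-angle rotamers per amino-acid type.

    ``subsample=True`` expands every chi into {chi−10°, chi, chi+10°}.
    """

    def __init__(self, rotamers: Dict[str, List[Tuple[float, ...]]], subsample: bool = False):
        self._rot: Dict[str, List[Tuple[float, ...]]] = {}
        for aa3, rots in rotamers.items():
            if not rots:
                raise ValueError(f"{aa3}: at least one rotamer required")
            if subsample:
                expanded: List[Tuple[float, ...]] = []
                for rot in rots:
                    for combo in itertools.product(*[(c - 10.0, c, c + 10.0) for c in rot]):
                        expanded.append(tuple(combo))
                rots = expanded or [()]
            self._rot[aa3] = [tuple(float(c) for c in r) for r in rots]

    @classmethod
    def default(cls, subsample: bool = False) -> "RotamerLibrary":
        text = (
            importlib.resources.files("bindscan.data")
            .joinpath("rotamers.tsv")
            .read_text()
        )
        rot: Dict[str, List[Tuple[float, ...]]] = {}
        for line in text.splitlines():
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            aa3 = parts[0]
            chis = parts[1] if len(parts) > 1 else ""
            tup = tuple(float(x) for x in chis.split(",")) if chis.strip() else ()
            rot.setdefault(aa3, []).append(tup)
        return cls(rot, subsample=subsample)

    def rotamers(self, res_type: str) -> List[Tuple[float, ...]]:
        base = "HIS" if res_type.startswith("HIS") else res_type
        try:
            return list(self._rot[base])
        except KeyError:
            raise KeyError(f"no rotamers for residue type {res_type}") from None


def enumerate_mutations(site: ResidueSite, allowed: Iterable[str]) -> List[MutationSpec]:
    """Expand an allowed-mutation set into scan entries for one site.

    The wildtype is always included once as the reference entry; every
    non-wildtype histidine target expands into the three protonation
    variants H1/H2/H3.
    """
    allowed = set(allowed)
    if not allowed:
        raise ValueError("allowed amino-acid set is empty")
    if not site.is_protein():
        raise ValueError(f"site {site.label} is a nucleotide; mutations are protein-side only")
    wt1 = AA3_TO_1.get(site.residue_type)
    if wt1 is None:
        raise ValueError(f"site {site.label} has non-standard residue type {site.residue_type}")
    bad = allowed - set(AA1_TO_3)
    if bad:
        raise ValueError(f"unknown amino-acid codes {sorted(bad)}")
    specs = [MutationSpec(site, wt1, "H2" if wt1 == "H" else None)]
    for aa in sorted(allowed):
        if aa == wt1:
            continue
        if aa == "H":
            specs.extend(MutationSpec(site, "H", v) for v in HIS_VARIANTS)
        else:
            specs.append(MutationSpec(site, aa))
    return specs


@dataclass
class Position:
    """One flexible position: a site, its allowed residue types, and for each
    type the concrete rotamer conformations (side-chain atom lists)."""

    site: ResidueSite
    allowed_types: List[str]  # template keys, e.g. "SER", "HIS_H1"
    conformers: Dict[str, List[List[Atom]]]  # type -> rotamer -> atoms

    def n_conformations(self) -> int:
        return sum(len(self.conformers[t]) for t in self.allowed_types)


@dataclass
class ConformationSpace:
    state: str  # complex | partner_A | partner_B
    positions: List[Position]
    template: List[Tuple[ResidueSite, List[Atom]]]  # rigid atoms
    mutable_backbones: Dict[ResidueSite, List[Atom]] = field(default_factory=dict)

    def n_conformations(self) -> int:
        n = 1
        for p in self.positions:
            n *= p.n_conformations()
        return n


def _backbone_coords(atoms: Sequence[Atom]) -> Dict[str, np.ndarray]:
    coords = {a.name: a.coords for a in atoms}
    missing = [n for n in ("N", "CA", "C") if n not in coords]
    if missing:
        raise ValueError(f"backbone atoms {missing} missing; cannot place side chain")
    return coords


def build_rotamer_atoms(
    res_type: str, chis: Sequence[float], backbone_atoms: Sequence[Atom]
) -> List[Atom]:
    """Side-chain heavy atoms for one rotamer, parameterised for ``res_type``."""
    placed = geometry.build_sidechain(res_type, chis, _backbone_coords(backbone_atoms))
    out: List[Atom] = []
    for name, pos in placed:
        q, r, eps = lookup_params(res_type, name)
        out.append(Atom(name=name, element=name[0], coords=pos,
                        partial_charge=q, vdw_radius=r, vdw_welldepth=eps))
    return out


def _make_position(
    site: ResidueSite,
    allowed_types: List[str],
    backbone_atoms: List[Atom],
    library: RotamerLibrary,
) -> Position:
    conformers: Dict[str, List[List[Atom]]] = {}
    for t in allowed_types:
        conformers[t] = [
            build_rotamer_atoms(t, chis, backbone_atoms) for chis in library.rotamers(t)
        ]
    return Position(site=site, allowed_types=allowed_types, conformers=conformers)


def build_conf_spaces(
    s: Structure,
    mutable: Sequence[ResidueSite],
    mutation: Optional[MutationSpec],
    library: Optional[RotamerLibrary] = None,
) -> Tuple[ConformationSpace, ConformationSpace, ConformationSpace]:
    """Build (complex, partner_A, partner_B) spaces for one scan entry.

    Every mutable residue is flexible; the residue named by ``mutation`` (if
    any) allows both its wildtype and the target type, all other mutable
    residues allow wildtype only.  Non-mutable residues and the mutable
    residues' backbones form the rigid template.
    """
    library = library or RotamerLibrary.default()
    if not 1 <= len(mutable) <= 2:
        raise ValueError("mutable site count must be 1 or 2")
    site_set = set(s.sites)
    for m in mutable:
        if m not in site_set:
            raise ValueError(f"mutable site {m.label} not in structure")
        if not m.is_protein():
            raise ValueError(f"mutable site {m.label} is not a protein residue")
    if mutation is not None and mutation.site not in set(mutable):
        raise ValueError(
            f"mutation at {mutation.site.label} but that site is not listed mutable"
        )

    mutable_sorted = sorted(mutable, key=ResidueSite.sort_key)
    backbone_names = set(geometry.BACKBONE_ATOMS)

    def spaces_for(state: str, keep_partner: Optional[str]) -> ConformationSpace:
        positions: List[Position] = []
        template: List[Tuple[ResidueSite, List[Atom]]] = []
        mut_bb: Dict[ResidueSite, List[Atom]] = {}
        for site in s.sites:
            if keep_partner is not None and s.partner_of(site) != keep_partner:
                continue
            atoms = s.atoms_by_site[site]
            if site in set(mutable_sorted):
                bb = [a for a in atoms if a.name in backbone_names]
                mut_bb[site] = bb
                template.append((site, bb))
                wt_type = site.residue_type
                if mutation is not None and site == mutation.site and not mutation.is_reference:
                    allowed_types = [wt_type, mutation.residue_type]
                else:
                    allowed_types = [wt_type]
                positions.append(_make_position(site, allowed_types, bb, library))
            else:
                template.append((site, list(atoms)))
        return ConformationSpace(state=state, positions=positions,
                                 template=template, mutable_backbones=mut_bb)

    return (
        spaces_for("complex", None),
        spaces_for("partner_A", "A"),
        spaces_for("partner_B", "B"),
    )


def restrict_to_sequence(
    space: ConformationSpace, sequence: Dict[ResidueSite, str]
) -> ConformationSpace:
    """Sub-space with each position restricted to one residue type.

    K* partition functions are per-sequence quantities; this selects the
    single-type slice of a space built with {wildtype, target} at the
    mutated position.  Positions not named in ``sequence`` keep all types.
    """
    positions = []
    for p in space.positions:
        if p.site in sequence:
            t = sequence[p.site]
            if t not in p.allowed_types:
                raise ValueError(f"type {t} not allowed at {p.site.label}")
            positions.append(Position(p.site, [t], {t: p.conformers[t]}))
        else:
            positions.append(p)
    return ConformationSpace(space.state, positions, space.template, space.mutable_backbones)
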