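"""Structure I/O, residue addressing, interface detection and shell trimming.

A :class:`Structure` is a two-partner complex: every chain belongs to exactly
one of the two partner chain sets.  Atoms carry the nonbonded parameters
(partial charge, vdW rmin/2 and well depth) assigned from the embedded
per-residue template table at read time.  Only heavy atoms are kept; waters,
buffer components and chains outside the two partner sets are dropped.
Alternate locations collapse to the highest-occupancy conformer (ties broken
by altloc letter).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Dict, FrozenSet, Iterable, List, Optional, Set, Tuple

import gemmi
import numpy as np

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}
DNA_TYPES = {"DA", "DC", "DG", "DT"}


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray  # (3,) Å
    partial_charge: float  # elementary charges
    vdw_radius: float  # rmin/2, Å
    vdw_welldepth: float  # kcal/mol

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: non-finite coordinates")
        if self.vdw_radius <= 0:
            raise ValueError(f"atom {self.name}: vdw_radius must be > 0")
        if self.vdw_welldepth < 0:
            raise ValueError(f"atom {self.name}: well depth must be >= 0")


@dataclass(frozen=True)
class ResidueSite:
    """Address of one residue: author chain id, number and insertion code."""

    chain_id: str
    residue_number: int
    insertion_code: str = ""
    residue_type: str = field(default="", compare=False)

    def sort_key(self) -> Tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.insertion_code)

    @property
    def label(self) -> str:
        icode = f":{self.insertion_code}" if self.insertion_code else ""
        return f"{self.chain_id}:{self.residue_number}{icode}"

    def is_protein(self) -> bool:
        return self.residue_type not in DNA_TYPES


@dataclass
class Structure:
    sites: List[ResidueSite]
    atoms_by_site: Dict[ResidueSite, List[Atom]]
    partner_a: FrozenSet[str]
    partner_b: FrozenSet[str]

    def __post_init__(self) -> None:
        if set(self.partner_a) & set(self.partner_b):
            raise ValueError("partner chain sets overlap")
        seen = set()
        for s in self.sites:
            if s in seen:
                raise ValueError(f"duplicate residue address {s.label}")
            seen.add(s)
        for p in ("A", "B"):
            if not any(self.partner_of(s) == p for s in self.sites):
                raise ValueError(f"partner {p} has no residues")

    def partner_of(self, site: ResidueSite) -> str:
        if site.chain_id in self.partner_a:
            return "A"
        if site.chain_id in self.partner_b:
            return "B"
        raise KeyError(f"chain {site.chain_id} not in either partner set")

    def partner_sites(self, partner: str) -> List[ResidueSite]:
        return [s for s in self.sites if self.partner_of(s) == partner]

    def site_by_label(self, label: str) -> ResidueSite:
        for s in self.sites:
            if s.label == label:
                return s
        raise KeyError(f"no residue {label} in structure")

    def subset(self, keep: Iterable[ResidueSite]) -> "Structure":
        keep = set(keep)
        sites = [s for s in self.sites if s in keep]
        return Structure(
            sites=sites,
            atoms_by_site={s: list(self.atoms_by_site[s]) for s in sites},
            partner_a=self.partner_a,
            partner_b=self.partner_b,
        )

    @property
    def n_atoms(self) -> int:
        return sum(len(v) for v in self.atoms_by_site.values())


@lru_cache(maxsize=1)
def parameter_table() -> Dict[Tuple[str, str], Tuple[float, float, float]]:
    """(residue_type, atom_name) -> (charge, rmin/2, well depth)."""
    table: Dict[Tuple[str, str], Tuple[float, float, float]] = {}
    text = (
        importlib.resources.files("bindscan.data")
        .joinpath("ff_params.tsv")
        .read_text()
    )
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        res, name, q, r, eps = line.split("\t")
        table[(res, name)] = (float(q), float(r), float(eps))
    return table


def lookup_params(res_type: str, atom_name: str) -> Tuple[float, float, float]:
    table = parameter_table()
    try:
        return table[(res_type, atom_name)]
    except KeyError:
        raise KeyError(
            f"no nonbonded parameters for atom {atom_name} of residue type {res_type}"
        ) from None


def _pick_altloc(atoms: List[gemmi.Atom]) -> List[gemmi.Atom]:
    """Collapse altlocs: keep highest occupancy, ties by altloc letter order."""
    by_name: Dict[str, gemmi.Atom] = {}
    for a in atoms:
        cur = by_name.get(a.name)
        if cur is None:
            by_name[a.name] = a
        else:
            if (a.occ, -ord(a.altloc or "z")) > (cur.occ, -ord(cur.altloc or "z")):
                by_name[a.name] = a
    return list(by_name.values())


def read_structure(
    pdb_text: str,
    partner_a_chains: Iterable[str],
    partner_b_chains: Iterable[str],
) -> Structure:
    """Parse PDB text into a parameterised two-partner :class:`Structure`.

    Waters and any chain outside the two partner sets are dropped; hydrogens
    are discarded (the energy model is heavy-atom only).  An unknown residue
    type raises, naming the offending site.
    """
    a_set = frozenset(partner_a_chains)
    b_set = frozenset(partner_b_chains)
    if not a_set or not b_set:
        raise ValueError("both partner chain sets must be non-empty")
    if a_set & b_set:
        raise ValueError(f"partner chain sets overlap: {sorted(a_set & b_set)}")

    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise ValueError("no models in PDB input")
    model = st[0]

    sites: List[ResidueSite] = []
    atoms_by_site: Dict[ResidueSite, List[Atom]] = {}
    for chain in model:
        if chain.name not in a_set and chain.name not in b_set:
            continue
        for res in chain:
            if res.name in WATER_NAMES:
                continue
            icode = res.seqid.icode.strip()
            site = ResidueSite(chain.name, res.seqid.num, icode, res.name)
            atoms: List[Atom] = []
            for ga in _pick_altloc(list(res)):
                el = ga.element.name.upper()
                if el in ("H", "D"):
                    continue
                if (res.name, ga.name) not in parameter_table():
                    raise KeyError(
                        f"no parameters for atom {ga.name} in residue "
                        f"{res.name} at {site.label}"
                    )
                q, r, eps = lookup_params(res.name, ga.name)
                atoms.append(
                    Atom(
                        name=ga.name,
                        element=el,
                        coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        partial_charge=q,
                        vdw_radius=r,
                        vdw_welldepth=eps,
                    )
                )
            if atoms:
                sites.append(site)
                atoms_by_site[site] = atoms
    sites.sort(key=ResidueSite.sort_key)
    return Structure(sites, atoms_by_site, a_set, b_set)


def write_structure(s: Structure) -> str:
    """Serialise to PDB text (ATOM records, TER per chain)."""
    lines: List[str] = []
    serial = 1
    last_chain: Optional[str] = None
    for site in s.sites:
        if last_chain is not None and site.chain_id != last_chain:
            lines.append("TER")
        last_chain = site.chain_id
        for atom in s.atoms_by_site[site]:
            x, y, z = atom.coords
            name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
            lines.append(
                f"ATOM  {serial:>5d} {name}{'':1s}{site.residue_type:>3s} "
                f"{site.chain_id:1s}{site.residue_number:>4d}"
                f"{site.insertion_code or '':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {atom.element:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def _coords_matrix(s: Structure, sites: Iterable[ResidueSite]) -> Dict[ResidueSite, np.ndarray]:
    return {
        site: np.array([a.coords for a in s.atoms_by_site[site]]) for site in sites
    }


def find_interface_residues(s: Structure, cutoff: float = 5.0) -> Set[ResidueSite]:
    """Residues on either partner with any heavy atom within ``cutoff`` of the
    opposite partner (closed boundary: exactly at the cutoff counts)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    a_sites = s.partner_sites("A")
    b_sites = s.partner_sites("B")
    coords = _coords_matrix(s, s.sites)
    result: Set[ResidueSite] = set()
    for sa in a_sites:
        ca = coords[sa]
        for sb in b_sites:
            if sa in result and sb in result:
                continue
            d = np.linalg.norm(ca[:, None, :] - coords[sb][None, :, :], axis=-1)
            if d.min() <= cutoff:
                result.add(sa)
                result.add(sb)
    return result


def trim_to_shell(
    s: Structure, interface: Iterable[ResidueSite], radius: float = 12.0
) -> Structure:
    """Keep residues with a heavy atom within ``radius`` of any interface atom.

    Interface residues are always retained (self-distance zero).
    """
    interface = list(interface)
    if radius <= 0:
        raise ValueError("radius must be positive")
    if not interface:
        raise ValueError("empty interface: nothing to trim against")
    site_set = set(s.sites)
    for site in interface:
        if site not in site_set:
            raise ValueError(f"interface site {site.label} not in structure")
    iface_coords = np.vstack(
        [np.array([a.coords for a in s.atoms_by_site[site]]) for site in interface]
    )
    keep: List[ResidueSite] = []
    iface_set = set(interface)
    for site in s.sites:
        if site in iface_set:
            keep.append(site)
            continue
        c = np.array([a.coords for a in s.atoms_by_site[site]])
        d = np.linalg.norm(c[:, None, :] - iface_coords[None, :, :], axis=-1)
        if d.min() <= radius:
            keep.append(site)
    return s.subset(keep)
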