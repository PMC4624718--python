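"""Two-chain protein complexes: parsing, solvent accessibility and interface extraction.

A binding interface is defined geometrically: a residue belongs to the
interface when any of its heavy atoms lies within a cutoff distance
(default 4.0 Å) of a heavy atom of the partner chain.  Interface residues
are further classified by how their relative solvent accessibility changes
upon complex formation (core / rim / support / interior / surface), which
is the natural energetic classification of interface positions: core
residues (exposed in the free monomer, buried in the complex) carry most
of the binding free energy, rim residues tune affinity and specificity.

Solvent accessible surface area is computed with the Shrake-Rupley
rolling-probe algorithm on a deterministic spherical point grid, so every
number in this module is exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.spatial import cKDTree

# ---------------------------------------------------------------------------
# reference tables
# ---------------------------------------------------------------------------

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: van der Waals radii (Å), Bondi-style, for the heavy elements found in
#: protein chains.  Hydrogens are never placed and never scored.
ELEMENT_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}

#: Theoretical maximum solvent accessibility per residue type (Å²),
#: Gly-X-Gly extended-tripeptide reference values (Tien et al. style).
MAX_SASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

PROBE_RADIUS = 1.4          # water probe, Å
SASA_N_POINTS = 960         # Shrake-Rupley sphere points
INTERFACE_CUTOFF = 4.0      # interface membership, any heavy atom, Å
CONTACT_CUTOFF = 4.5        # cross-chain residue-residue contacts, Å
RASA_THRESHOLD = 0.25       # exposed/buried boundary; ties count as buried

ResRef = tuple[str, int]    # (chain id, 0-based residue index within chain)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray  # shape (3,), Å

    @property
    def radius(self) -> float:
        return element_radius(self.element)


@dataclass
class Residue:
    name: str                # three-letter code
    aa: str                  # one-letter code
    seqid: int               # author numbering
    icode: str
    atoms: list[Atom]

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.name}{self.seqid} has no atom {name!r}")

    @property
    def ca(self) -> np.ndarray:
        return self.atom("CA").coord

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms])


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue]

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class ComplexStructure:
    """A dimeric protein complex, waters and non-protein ligands removed."""

    id: str
    chains: tuple[Chain, Chain]

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"chain {chain_id!r} not found in complex {self.id}")

    def residue(self, ref: ResRef) -> Residue:
        return self.chain(ref[0]).residues[ref[1]]

    def all_refs(self) -> list[ResRef]:
        return [(c.chain_id, i) for c in self.chains for i in range(len(c))]


@dataclass
class ResidueAccessibility:
    sasa_monomer: float   # Å², residue SASA with its own chain isolated
    sasa_complex: float   # Å², residue SASA in the assembled complex
    rasa: float           # sasa_monomer / reference maximum
    rasa_c: float         # sasa_complex / reference maximum


@dataclass
class InterfaceModel:
    """Interface residue sets, burial classes and the cross-chain contact map."""

    complex: ComplexStructure
    interface_residues: dict[str, list[ResRef]]       # per chain, ordered
    classes: dict[ResRef, str]                        # every residue classified
    contacts: frozenset[tuple[ResRef, ResRef]]        # (chain0 ref, chain1 ref)
    accessibility: dict[ResRef, ResidueAccessibility]

    @property
    def L_Q(self) -> int:
        """Total number of interface residues (both chains)."""
        return sum(len(v) for v in self.interface_residues.values())

    def positions(self) -> list[ResRef]:
        """Interface positions in canonical order: first chain then second."""
        out: list[ResRef] = []
        for c in self.complex.chains:
            out.extend(self.interface_residues[c.chain_id])
        return out

    def contact_partners(self) -> dict[ResRef, set[ResRef]]:
        partners: dict[ResRef, set[ResRef]] = {}
        for a, b in self.contacts:
            partners.setdefault(a, set()).add(b)
            partners.setdefault(b, set()).add(a)
        return partners


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def element_radius(element: str) -> float:
    try:
        return ELEMENT_RADII[element.upper()]
    except KeyError:
        raise ValueError(f"no van der Waals radius for element {element!r}") from None


def parse_complex(pdb_text: str, chain_ids: tuple[str, str],
                  complex_id: str = "complex") -> ComplexStructure:
    """Parse a two-chain complex from PDB text.

    Waters, non-protein ligands (HETATM groups) and hydrogens are stripped.
    Residues keep their author numbering and insertion codes; internally
    they are addressed by contiguous 0-based indices.
    """
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"failed to parse PDB: {exc}") from exc
    if len(st) == 0:
        raise ValueError("failed to parse PDB: no model found")
    model = st[0]
    by_id: dict[str, list] = {}
    for ch in model:          # same-name chains (e.g. split-off waters) merge
        by_id.setdefault(ch.name, []).extend(ch)
    chains: list[Chain] = []
    for cid in chain_ids:
        if cid not in by_id:
            raise ValueError(f"chain {cid!r} not found (file has "
                             f"{sorted(by_id)})")
        residues: list[Residue] = []
        for res in by_id[cid]:
            if res.is_water() or res.het_flag == "H":
                continue
            aa = THREE_TO_ONE.get(res.name)
            if aa is None:        # non-protein ligand in an ATOM record
                continue
            atoms = []
            for at in res:
                if at.element.is_hydrogen:
                    continue
                atoms.append(Atom(at.name, at.element.name,
                                  np.array([at.pos.x, at.pos.y, at.pos.z])))
            if atoms:
                residues.append(Residue(res.name, aa, res.seqid.num,
                                        res.seqid.icode.strip(), atoms))
        if not residues:
            raise ValueError(f"chain {cid!r} contains no protein residues")
        residues.sort(key=lambda r: (r.seqid, r.icode))
        chains.append(Chain(cid, residues))
    return ComplexStructure(complex_id, (chains[0], chains[1]))


# ---------------------------------------------------------------------------
# solvent accessibility (Shrake-Rupley)
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def compute_sasa(coords: np.ndarray, radii: np.ndarray,
                 probe_radius: float = PROBE_RADIUS,
                 n_points: int = SASA_N_POINTS) -> np.ndarray:
    """Per-atom solvent accessible surface area (Å²), Shrake-Rupley.

    Each atom is inflated by the probe radius and sampled on ``n_points``
    sphere points; a point is accessible when it falls outside every
    inflated neighbor sphere.
    """
    if probe_radius <= 0:
        raise ValueError("probe_radius must be positive")
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = len(coords)
    if n == 0:
        return np.zeros(0)
    pts = _sphere_points(n_points)
    inflated = radii + probe_radius
    tree = cKDTree(coords)
    out = np.zeros(n)
    for i in range(n):
        ri = inflated[i]
        surface = coords[i] + ri * pts
        accessible = np.ones(n_points, dtype=bool)
        for j in tree.query_ball_point(coords[i], ri + inflated.max()):
            if j == i:
                continue
            d2 = np.sum((surface - coords[j]) ** 2, axis=1)
            accessible &= d2 > inflated[j] ** 2
        out[i] = 4.0 * np.pi * ri * ri * accessible.mean()
    return out


def _residue_sasa(residues: list[Residue], probe_radius: float = PROBE_RADIUS,
                  n_points: int = SASA_N_POINTS) -> np.ndarray:
    coords, radii, owner = [], [], []
    for k, res in enumerate(residues):
        for a in res.atoms:
            coords.append(a.coord)
            radii.append(a.radius)
            owner.append(k)
    per_atom = compute_sasa(np.array(coords), np.array(radii),
                            probe_radius, n_points)
    out = np.zeros(len(residues))
    np.add.at(out, owner, per_atom)
    return out


def relative_accessibility(complex: ComplexStructure
                           ) -> dict[ResRef, ResidueAccessibility]:
    """rASA (chain in isolation) and rASA_c (assembled complex) per residue."""
    all_res: list[Residue] = []
    refs: list[ResRef] = []
    for ch in complex.chains:
        all_res.extend(ch.residues)
        refs.extend((ch.chain_id, i) for i in range(len(ch)))
    sasa_cplx = _residue_sasa(all_res)
    out: dict[ResRef, ResidueAccessibility] = {}
    pos = 0
    for ch in complex.chains:
        sasa_mono = _residue_sasa(ch.residues)
        for i, res in enumerate(ch.residues):
            if res.aa not in MAX_SASA:
                raise ValueError(f"no reference maximum SASA for residue "
                                 f"type {res.name!r}")
            ref_max = MAX_SASA[res.aa]
            out[(ch.chain_id, i)] = ResidueAccessibility(
                sasa_monomer=float(sasa_mono[i]),
                sasa_complex=float(sasa_cplx[pos + i]),
                rasa=float(sasa_mono[i] / ref_max),
                rasa_c=float(sasa_cplx[pos + i] / ref_max),
            )
        pos += len(ch)
    return out


# ---------------------------------------------------------------------------
# interface extraction and classification
# ---------------------------------------------------------------------------

def classify_residue(acc: ResidueAccessibility, in_contact: bool) -> str:
    """Burial-change class of a residue (total partition, deterministic ties).

    core:     exposed free (rASA > 25%), buried in the complex (rASA_c < 25%)
    rim:      exposed in both, in cross-chain contact
    surface:  exposed in both, no contact
    support:  buried free (rASA <= 25%), in cross-chain contact
    interior: buried free, no contact
    """
    rasa = min(acc.rasa, 1.0)
    rasa_c = min(acc.rasa_c, 1.0)
    if rasa > RASA_THRESHOLD:
        if rasa_c < RASA_THRESHOLD:
            return "core"
        return "rim" if in_contact else "surface"
    return "support" if in_contact else "interior"


def extract_interface(complex: ComplexStructure,
                      cutoff: float = INTERFACE_CUTOFF,
                      contact_cutoff: float = CONTACT_CUTOFF,
                      classify: bool = True) -> InterfaceModel:
    """Extract the binding interface of a dimeric complex.

    A residue is interfacial iff any of its heavy atoms lies within
    ``cutoff`` of any heavy atom of the other chain.  Cross-chain
    residue-residue contacts (used for contact-overlap scoring) are
    collected among interface residues at the slightly looser
    ``contact_cutoff`` so that every interface residue keeps at least one
    contact in densely packed interfaces.

    ``classify=False`` skips the solvent-accessibility computation and
    leaves ``classes``/``accessibility`` empty — enough for alignment and
    profile construction, where only geometry and contacts matter.
    """
    ch0, ch1 = complex.chains

    def _atoms(ch: Chain):
        coords, owner = [], []
        for i, res in enumerate(ch.residues):
            for a in res.atoms:
                coords.append(a.coord)
                owner.append(i)
        return np.array(coords), np.array(owner)

    c0, o0 = _atoms(ch0)
    c1, o1 = _atoms(ch1)
    t0, t1 = cKDTree(c0), cKDTree(c1)
    pairs = t0.sparse_distance_matrix(t1, max_distance=contact_cutoff,
                                      output_type="coo_matrix")
    if pairs.nnz == 0:
        raise ValueError("no interface: no cross-chain heavy-atom pair "
                         f"within {contact_cutoff} Å")

    # min cross-chain heavy-atom distance per residue pair
    min_d: dict[tuple[int, int], float] = {}
    for ai, bi, d in zip(pairs.row, pairs.col, pairs.data):
        key = (int(o0[ai]), int(o1[bi]))
        if d < min_d.get(key, np.inf):
            min_d[key] = d

    if0 = sorted({i for (i, _), d in min_d.items() if d <= cutoff})
    if1 = sorted({j for (_, j), d in min_d.items() if d <= cutoff})
    if not if0 or not if1:
        raise ValueError(f"no interface: no cross-chain heavy-atom pair "
                         f"within {cutoff} Å")
    if0_set, if1_set = set(if0), set(if1)
    contacts = frozenset(
        ((ch0.chain_id, i), (ch1.chain_id, j))
        for (i, j), d in min_d.items()
        if d <= contact_cutoff and i in if0_set and j in if1_set
    )

    if classify:
        acc = relative_accessibility(complex)
        in_contact = {ref for pair in contacts for ref in pair}
        classes = {ref: classify_residue(acc[ref], ref in in_contact)
                   for ref in complex.all_refs()}
    else:
        acc, classes = {}, {}
    return InterfaceModel(
        complex=complex,
        interface_residues={ch0.chain_id: [(ch0.chain_id, i) for i in if0],
                            ch1.chain_id: [(ch1.chain_id, j) for j in if1]},
        classes=classes,
        contacts=contacts,
        accessibility=acc,
    )


# ---------------------------------------------------------------------------
# plain-text PDB writing (used by fixtures and the CLI)
# ---------------------------------------------------------------------------

def write_pdb(complex: ComplexStructure) -> str:
    lines = []
    serial = 1
    for ch in complex.chains:
        for res in ch.residues:
            for a in res.atoms:
                name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
                lines.append(
                    f"ATOM  {serial:5d} {name}{' '}{res.name:>3s} "
                    f"{ch.chain_id}{res.seqid:4d}{res.icode or ' ':1s}   "
                    f"{a.coord[0]:8.3f}{a.coord[1]:8.3f}{a.coord[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}"
                )
                serial += 1
        lines.append(f"TER   {serial:5d}      {ch.residues[-1].name:>3s} "
                     f"{ch.chain_id}{ch.residues[-1].seqid:4d}")
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"
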