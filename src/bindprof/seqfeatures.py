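"""Sequence-derived mutation features and the energy-combination contract.

Pharmacophore count differences between mutant and wild-type residues
(hydrophobic, aromatic, charged, H-bond acceptor, H-bond donor — the
categories deliberately overlap: tryptophan is hydrophobic, aromatic and a
donor at once) plus the residue-volume difference.  External potential
scores (all-atom or residue-level) are never computed here; they enter the
feature table as optional numeric columns combined through the standard
thermodynamic-cycle arithmetic below.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

from .structmodel import AA_INDEX

#: Pharmacophore category membership (overlapping by design).
HYDROPHOBIC = set("VILMFWC")
AROMATIC = set("YFW")
CHARGED = set("RKDE")
ACCEPTORS = set("DENHQSTY")
DONORS = set("RKWNQHSTY")

#: Mean residue volumes (Å³), Zamyatnin.
RESIDUE_VOLUME = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
}

_MUTATION_TOKEN = re.compile(r"^([A-Z])(\d+)([A-Z])$")


@dataclass(frozen=True)
class Substitution:
    chain: str
    position: int        # author numbering
    wt: str
    mut: str

    def __post_init__(self):
        for aa in (self.wt, self.mut):
            if aa not in AA_INDEX:
                raise ValueError(f"nonstandard amino acid {aa!r}")
        if self.wt == self.mut:
            raise ValueError(f"substitution {self.wt}{self.position}{self.mut} "
                             "does not change the residue")


@dataclass
class MutationRecord:
    """One mutation event (possibly multi-site, all sites on one chain)."""

    complex_id: str
    substitutions: tuple[Substitution, ...]
    ddg_exp: float | None = None      # kcal/mol
    temperature: float | None = None  # K

    def __post_init__(self):
        if not self.substitutions:
            raise ValueError("a mutation record needs at least one substitution")

    @property
    def chains(self) -> set[str]:
        return {s.chain for s in self.substitutions}

    def key(self) -> tuple:
        return (self.complex_id, frozenset(
            (s.chain, s.position, s.wt, s.mut) for s in self.substitutions))


def parse_mutation_token(token: str, default_chain: str) -> Substitution:
    """Parse an 'L45D' or 'A:L45D' token."""
    chain = default_chain
    if ":" in token:
        chain, token = token.split(":", 1)
    m = _MUTATION_TOKEN.match(token.strip())
    if m is None:
        raise ValueError(f"malformed mutation token {token!r}")
    return Substitution(chain=chain, position=int(m.group(2)),
                        wt=m.group(1), mut=m.group(3))


@dataclass
class SequenceFeatureSet:
    d_hydrophobic: int
    d_aromatic: int
    d_charged: int
    d_acceptors: int
    d_donors: int
    d_volume: float   # Å³

    FIELDS = ("d_hydrophobic", "d_aromatic", "d_charged",
              "d_acceptors", "d_donors", "d_volume")

    def as_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in self.FIELDS}


def pharmacophore_deltas(mut: MutationRecord) -> SequenceFeatureSet:
    """Signed pharmacophore count changes (mutant minus wild type), summed
    over substitutions, plus the residue-volume difference."""
    counts = dict.fromkeys(("hyd", "aro", "chg", "acc", "don"), 0)
    dvol = 0.0
    for s in mut.substitutions:
        for key, members in (("hyd", HYDROPHOBIC), ("aro", AROMATIC),
                             ("chg", CHARGED), ("acc", ACCEPTORS),
                             ("don", DONORS)):
            counts[key] += (s.mut in members) - (s.wt in members)
        dvol += RESIDUE_VOLUME[s.mut] - RESIDUE_VOLUME[s.wt]
    return SequenceFeatureSet(
        d_hydrophobic=counts["hyd"], d_aromatic=counts["aro"],
        d_charged=counts["chg"], d_acceptors=counts["acc"],
        d_donors=counts["don"], d_volume=dvol,
    )


def volume_delta(mut: MutationRecord) -> float:
    """Σ (V_mut − V_wt) over substitutions, Å³ (Zamyatnin mean volumes)."""
    return float(sum(RESIDUE_VOLUME[s.mut] - RESIDUE_VOLUME[s.wt]
                     for s in mut.substitutions))


def combine_energy_terms(e_wt_complex: float, e_mut_complex: float,
                         e_wt_monomers: float | None = None,
                         e_mut_monomers: float | None = None) -> float:
    """ΔΔG from external energy evaluations (kcal/mol).

    Four-term thermodynamic cycle:
        ΔΔG = [E_WT(complex) − E_WT(monomers)] − [E_Mut(complex) − E_Mut(monomers)]
    Two-term variant (potentials that score binding internally):
        ΔΔG = E_WT(complex) − E_Mut(complex)
    """
    vals = [e_wt_complex, e_mut_complex]
    if (e_wt_monomers is None) != (e_mut_monomers is None):
        raise ValueError("provide both monomer energies or neither")
    if e_wt_monomers is not None:
        vals += [e_wt_monomers, e_mut_monomers]
    if not all(math.isfinite(v) for v in vals):
        raise ValueError("energy terms must be finite")
    if e_wt_monomers is None:
        return e_wt_complex - e_mut_complex
    return (e_wt_complex - e_wt_monomers) - (e_mut_complex - e_mut_monomers)
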