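"""Synthetic structures, template families and mutation tables.

The generator builds toy dimers with a controlled binding interface: two
extended chains run antiparallel to the z-axis separation, with Cβ-like
pseudo-atoms pointing across the gap so that facing residue pairs sit
~3.2 Å apart (inside the 4 Å interface cutoff) while sequence neighbors
stay outside it.  Every residue, including glycine, carries the Cβ
pseudo-atom — the geometry is a scaffold for exercising interface
detection, alignment and profile formulas, not a physical protein model.

Template families emulate a structure library: copies of a base dimer
with graded per-residue coordinate noise (so interface similarity spans
from 1.0 down past the loose profile cutoff), a random global rigid
motion, and interface sequences redrawn from a known per-position
amino-acid distribution π(p,·).  π is BLOSUM-shaped around a per-position
preferred residue (π(p,a) ∝ exp(M(a*,a)/τ)): interface positions tolerate
chemically similar residues, which is exactly the signal an interface
profile is meant to recover — the stored π is the ground truth for
recovery tests.

Mutation tables emulate curated experimental ΔΔG data: rows in the
tab-separated dialect with replicate groups, injected high outliers, and
a known linear ground truth (sequence-feature weights plus optional
protein-specific offsets) stored alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .profiles import substitution_matrix
from .seqfeatures import MutationRecord, Substitution, pharmacophore_deltas
from .structmodel import (AA_ORDER, Atom, Chain, ComplexStructure, ONE_TO_THREE,
                          Residue, extract_interface, write_pdb)

CA_SPACING = 3.8        # Å along the chain axis
CHAIN_SEPARATION = 5.8  # Å between the two chain planes
ZIGZAG_AMPLITUDE = 1.4  # Å, chain A only: breaks the 2-fold pseudosymmetry
JITTER = 0.05           # Å deterministic coordinate jitter per seed

DEFAULT_TRUTH_WEIGHTS = {
    "d_hydrophobic": -0.6, "d_aromatic": 0.3, "d_charged": 0.4,
    "d_acceptors": -0.2, "d_donors": 0.25, "d_volume": 0.012,
}


@dataclass
class FixtureSpec:
    seed: int
    interface_length: int = 14        # facing residues per chain
    flank: int = 4                    # extra non-interface residues on chain A
    n_templates: int = 50
    noise_sigma: float = 1.0          # max per-component coordinate noise, Å
    pi_temperature: float = 2.0       # softness of π around the preferred residue
    frac_low_similarity: float | None = None
    duplicate_rate: float = 0.0       # exact-duplicate template sequences
    n_mutations: int = 200
    n_complexes: int = 10
    replicate_rate: float = 0.0
    outlier_rate: float = 0.0
    noise_sd: float = 0.1             # kcal/mol, observational noise on ΔΔG
    protein_sd: float = 0.0           # kcal/mol, per-complex offset spread

    def __post_init__(self):
        for rate in (self.duplicate_rate, self.replicate_rate,
                     self.outlier_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


# ---------------------------------------------------------------------------
# toy dimer geometry
# ---------------------------------------------------------------------------

def _residue(aa: str, seqid: int, x: float, y0: float, z0: float, flip: bool,
             jitter: np.ndarray) -> Residue:
    s = -1.0 if flip else 1.0
    local = {
        "N": (-1.2, 0.8, 0.0),
        "CA": (0.0, 0.0, 0.0),
        "C": (1.2, 0.8, 0.0),
        "O": (1.2, 2.0, 0.2 * s),
        "CB": (0.0, -0.7, 1.3 * s),
    }
    elements = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}
    atoms = []
    for k, (name, (dx, dy, dz)) in enumerate(local.items()):
        coord = np.array([x + dx, y0 + dy, z0 + dz]) + jitter[k]
        atoms.append(Atom(name, elements[name], coord))
    return Residue(ONE_TO_THREE[aa], aa, seqid, "", atoms)


def make_toy_dimer(spec: FixtureSpec, sequences: tuple[str, str] | None = None,
                   complex_id: str = "toy") -> ComplexStructure:
    """Two facing extended chains with ``interface_length`` contacting
    residue pairs; chain A carries ``flank`` extra residues on each end."""
    if spec.interface_length < 1 or spec.flank < 0:
        raise ValueError("infeasible geometry: interface_length >= 1 and "
                         "flank >= 0 required")
    rng = np.random.default_rng(spec.seed)
    L = spec.interface_length
    la, lb = L + 2 * spec.flank, L
    if sequences is None:
        seq_a = "".join(rng.choice(list(AA_ORDER), size=la))
        seq_b = "".join(rng.choice(list(AA_ORDER), size=lb))
    else:
        seq_a, seq_b = sequences
        if len(seq_a) != la or len(seq_b) != lb:
            raise ValueError("sequence lengths do not match the geometry")
    jitter = rng.normal(0.0, JITTER, size=(la + lb, 5, 3))
    # chain A zigzags in y while chain B runs straight: without this the
    # two traces are congruent and the dimer has an artificial 2-fold
    # symmetry under which swapped chain pairings align as well as the
    # true one (and straight-line traces make superposition degenerate)
    res_a = [_residue(seq_a[i], i + 1, CA_SPACING * i,
                      ZIGZAG_AMPLITUDE * (-1.0) ** i, 0.0, False, jitter[i])
             for i in range(la)]
    res_b = [_residue(seq_b[j], j + 1, CA_SPACING * (j + spec.flank), 0.0,
                      CHAIN_SEPARATION, True, jitter[la + j])
             for j in range(lb)]
    return ComplexStructure(complex_id, (Chain("A", res_a), Chain("B", res_b)))


def _copy_complex(c: ComplexStructure, new_id: str) -> ComplexStructure:
    chains = []
    for ch in c.chains:
        residues = [Residue(r.name, r.aa, r.seqid, r.icode,
                            [Atom(a.name, a.element, a.coord.copy())
                             for a in r.atoms])
                    for r in ch.residues]
        chains.append(Chain(ch.chain_id, residues))
    return ComplexStructure(new_id, tuple(chains))


def _random_rotation(rng) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def make_position_distribution(spec: FixtureSpec, n_positions: int
                               ) -> np.ndarray:
    """Known per-position amino-acid distribution π(p,·): Boltzmann over
    substitution-matrix similarity to a per-position preferred residue."""
    rng = np.random.default_rng(spec.seed + 1)
    M = substitution_matrix("BLOSUM62")
    pi = np.zeros((n_positions, 20))
    for p in range(n_positions):
        a_star = rng.integers(20)
        w = np.exp(M[a_star] / spec.pi_temperature)
        pi[p] = w / w.sum()
    return pi


@dataclass
class TemplateFamily:
    templates: list[tuple[str, ComplexStructure]]
    pi: np.ndarray                  # ground-truth π over base interface positions
    positions: list                 # base interface position refs (π row order)
    sigmas: np.ndarray              # per-template coordinate noise, Å


def make_template_family(base: ComplexStructure, spec: FixtureSpec
                         ) -> TemplateFamily:
    """Family of geometrically perturbed, sequence-resampled templates."""
    rng = np.random.default_rng(spec.seed + 2)
    base_model = extract_interface(base)
    positions = base_model.positions()
    pi = make_position_distribution(spec, len(positions))
    n = spec.n_templates
    if spec.frac_low_similarity is None:
        sigmas = (spec.noise_sigma * np.arange(n) / max(1, n - 1))
    else:
        n_low = int(round(spec.frac_low_similarity * n))
        mid = spec.noise_sigma / 2.0
        sigmas = np.concatenate([
            np.linspace(0.0, mid, n - n_low, endpoint=False),
            np.linspace(mid, spec.noise_sigma, max(1, n_low))[:n_low],
        ])
    templates: list[tuple[str, ComplexStructure]] = []
    prev_choices: np.ndarray | None = None
    for t in range(n):
        tmpl = _copy_complex(base, f"tmpl{t:03d}")
        # resample the interface sequence from π (or duplicate the previous)
        if (prev_choices is not None and t > 0
                and rng.random() < spec.duplicate_rate):
            choices = prev_choices
        else:
            choices = np.array([rng.choice(20, p=pi[p])
                                for p in range(len(positions))])
        prev_choices = choices
        for p, ref in enumerate(positions):
            res = tmpl.residue(ref)
            aa = AA_ORDER[choices[p]]
            res.aa = aa
            res.name = ONE_TO_THREE[aa]
        # per-residue coordinate noise + global rigid motion
        sigma = sigmas[t]
        R = _random_rotation(rng)
        shift = rng.uniform(-20.0, 20.0, size=3)
        for ch in tmpl.chains:
            for res in ch.residues:
                offset = rng.normal(0.0, sigma, size=3) if sigma > 0 else 0.0
                for a in res.atoms:
                    a.coord = R @ (a.coord + offset) + shift
        templates.append((tmpl.id, tmpl))
    return TemplateFamily(templates=templates, pi=pi, positions=positions,
                          sigmas=sigmas)


# ---------------------------------------------------------------------------
# mutation tables with known truth
# ---------------------------------------------------------------------------

def _true_ddg(sub: Substitution, weights: dict[str, float]) -> float:
    feats = pharmacophore_deltas(
        MutationRecord("x", (sub,), None, None)).as_dict()
    return float(sum(w * feats[k] for k, w in weights.items()))


def make_mutation_table(spec: FixtureSpec,
                        truth_weights: dict[str, float] | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Mutation rows with replicates, high outliers and linear ground truth.

    Returns ``(rows, truth, proteins)``: the raw table in the tab-separated
    dialect, a per-row frame with the noiseless true ΔΔG and a flag for
    injected outliers, and a per-complex frame with the protein covariate
    and the protein-specific offset.
    """
    weights = truth_weights or DEFAULT_TRUTH_WEIGHTS
    rng = np.random.default_rng(spec.seed + 3)
    complexes = [f"CPX{i:03d}" for i in range(spec.n_complexes)]
    covariate = rng.uniform(0.0, 1.0, size=spec.n_complexes)
    offsets = rng.normal(0.0, spec.protein_sd, size=spec.n_complexes)
    proteins = pd.DataFrame({"complex_id": complexes,
                             "protein_covariate": covariate,
                             "protein_effect": offsets})
    aas = list(AA_ORDER)
    rows, truth = [], []
    seen: set[tuple] = set()
    for _ in range(spec.n_mutations):
        ci = rng.integers(spec.n_complexes)
        wt, mut = rng.choice(aas, size=2, replace=False)
        pos = int(rng.integers(1, 31))
        key = (ci, wt, pos, mut)
        if key in seen:
            continue
        seen.add(key)
        sub = Substitution("A", pos, wt, mut)
        base_ddg = _true_ddg(sub, weights) + offsets[ci]
        n_rep = 1
        outlier = False
        if rng.random() < spec.outlier_rate:
            n_rep, outlier = 2, True      # 2 concordant + 1 high outlier
        elif rng.random() < spec.replicate_rate:
            n_rep = 2
        token = f"{wt}{pos}{mut}"
        for _ in range(n_rep):
            obs = base_ddg + rng.normal(0.0, spec.noise_sd)
            rows.append({"complex_id": complexes[ci], "chain": "A",
                         "mutations": token, "ddg_exp": round(obs, 4),
                         "temperature": 298.0})
            truth.append({"complex_id": complexes[ci], "mutations": token,
                          "ddg_true": base_ddg, "is_outlier": False})
        if outlier:
            obs = base_ddg + 4.0 + abs(rng.normal(0.0, 0.5))
            rows.append({"complex_id": complexes[ci], "chain": "A",
                         "mutations": token, "ddg_exp": round(obs, 4),
                         "temperature": 298.0})
            truth.append({"complex_id": complexes[ci], "mutations": token,
                          "ddg_true": base_ddg, "is_outlier": True})
    return (pd.DataFrame(rows), pd.DataFrame(truth), proteins)


# ---------------------------------------------------------------------------
# bundle writer (CLI)
# ---------------------------------------------------------------------------

def write_fixture_bundle(spec: FixtureSpec, out_dir) -> dict:
    """Write a complete fixture set: query PDB, template library PDBs with
    an index TSV, a mutation table and the ground truth as JSON/TSV."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base = make_toy_dimer(spec)
    (out / "query.pdb").write_text(write_pdb(base))
    family = make_template_family(base, spec)
    lib = out / "library"
    lib.mkdir(exist_ok=True)
    index_rows = []
    for tid, tmpl in family.templates:
        (lib / f"{tid}.pdb").write_text(write_pdb(tmpl))
        index_rows.append({"id": tid, "chains": "AB"})
    pd.DataFrame(index_rows).to_csv(lib / "index.tsv", sep="\t", index=False)
    rows, truth, proteins = make_mutation_table(spec)
    rows.to_csv(out / "mutations.tsv", sep="\t", index=False)
    truth.to_csv(out / "mutations_truth.tsv", sep="\t", index=False)
    proteins.to_csv(out / "proteins.tsv", sep="\t", index=False)
    (out / "truth.json").write_text(json.dumps({
        "pi": family.pi.tolist(),
        "positions": [[ref[0], ref[1]] for ref in family.positions],
        "sigmas": family.sigmas.tolist(),
        "seed": spec.seed,
    }, indent=1))
    return {"query": str(out / "query.pdb"), "library": str(lib),
            "mutations": str(out / "mutations.tsv")}
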