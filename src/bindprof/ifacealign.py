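"""Structural alignment of binding interfaces and interface similarity scores.

Two dimeric interfaces are compared by superposing their interface Cα
traces and scoring the residue correspondence with three related metrics:

* iTM-score — a TM-score restricted to interface residues:
  ``1/L_Q · Σ 1/(1 + d_i²/d0²)``, normalized by the query interface
  length ``L_Q``, with the standard length-dependent scale
  ``d0 = max(0.5, 1.24·(L_Q−15)^(1/3) − 1.8)``.
* Iscore — the same sum weighted per pair by the fraction ``f_i`` of
  conserved cross-chain contacts, ``f_i = (c_i/a_i + c_i/b_i)/2``.
* PCscore — a physicochemistry-aware variant with a fixed 4 Å scale and a
  0.25 penalty for aligning residues of different chemical classes,
  scaled by the common-contact ratio ``f_c``.

The correspondence search is a heuristic: gapless-threading seeds in both
chain pairings, then iterative {Kabsch superposition → dynamic-programming
re-alignment on S(i,j) = 1/(1+d_ij²/d0²) with zero gap penalty} until the
pair set is stable (at most 20 rounds).  The pairing and alignment
maximizing the requested metric is returned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .structmodel import InterfaceModel, ResRef

MAX_REFINE_ITER = 20
PC_D0 = 4.0          # fixed distance scale of the PCscore
PC_PENALTY = 0.25    # chemistry-mismatch penalty of the PCscore
D0_MIN = 0.5

#: Six non-overlapping chemical classes used by the PCscore.
CHEMICAL_CLASSES = {
    "pos": set("KR"),
    "neg": set("ED"),
    "donor_acceptor": set("NQST"),
    "aromatic": set("FW"),
    "hydrophobic": set("CAILMPVG"),
    "his_tyr": set("HY"),
}
_AA_TO_CLASS = {aa: name for name, members in CHEMICAL_CLASSES.items()
                for aa in members}


@dataclass
class InterfaceAlignment:
    pairs: list[tuple[ResRef, ResRef]]   # (query residue, template residue)
    d: np.ndarray                        # per-pair Cα distance after superposition, Å
    f: np.ndarray                        # per-pair contact-overlap fraction
    I: np.ndarray                        # per-pair chemical-match indicator, 0/1
    rotation: np.ndarray                 # applied to template coords
    translation: np.ndarray
    rmsd: float
    f_c: float                           # common-contact ratio (Eq for PCscore)

    @property
    def N_a(self) -> int:
        return len(self.pairs)


@dataclass
class SimilarityReport:
    itm: float
    iscore: float
    pcscore: float
    alignment: InterfaceAlignment
    chain_pairing: tuple[tuple[str, str], tuple[str, str]]


# ---------------------------------------------------------------------------
# rigid superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of B onto A (Kabsch, proper rotation).

    Returns (rotation, translation, rmsd) with the convention
    ``B_fit = B @ rotation.T + translation``.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape:
        raise ValueError("coordinate sets must have equal shapes")
    if len(A) < 3:
        raise ValueError("at least 3 points are required for superposition")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    H = B0.T @ A0
    U, S, Vt = np.linalg.svd(H)
    # degenerate (rank-deficient) input: rotation about the null direction
    # is unconstrained; proceed with the canonical SVD solution
    if S[1] < 1e-10 * max(S[0], 1e-30):
        warnings.warn("collinear or degenerate coordinates: superposition "
                      "is not unique", stacklevel=2)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = ca - R @ cb
    diff = A - (B @ R.T + t)
    rmsd = float(np.sqrt((diff ** 2).sum() / len(A)))
    return R, t, rmsd


def d0(L_Q: int, d0_min: float = D0_MIN) -> float:
    """Length-dependent distance scale of the interface TM-score family."""
    if L_Q < 1:
        raise ValueError("L_Q must be >= 1")
    return max(d0_min, 1.24 * np.cbrt(L_Q - 15.0) - 1.8)


# ---------------------------------------------------------------------------
# score formulas
# ---------------------------------------------------------------------------

def itm_score(aln: InterfaceAlignment, L_Q: int) -> float:
    """iTM-score: 1/L_Q Σ 1/(1 + d_i²/d0²)."""
    if L_Q <= 0:
        raise ValueError("L_Q must be positive")
    scale = d0(L_Q)
    return float(np.sum(1.0 / (1.0 + (aln.d / scale) ** 2)) / L_Q)


def i_score(aln: InterfaceAlignment, L_Q: int) -> float:
    """Iscore: 1/L_Q Σ f_i/(1 + d_i²/d0²)."""
    if L_Q <= 0:
        raise ValueError("L_Q must be positive")
    scale = d0(L_Q)
    return float(np.sum(aln.f / (1.0 + (aln.d / scale) ** 2)) / L_Q)


def pc_score(aln: InterfaceAlignment, L_Q: int, f_c: float | None = None) -> float:
    """PCscore: f_c/L_Q Σ 1/(1 + 0.25(1−I_i) + d_i²/4²)."""
    if L_Q <= 0:
        raise ValueError("L_Q must be positive")
    if f_c is None:
        f_c = aln.f_c
    terms = 1.0 / (1.0 + PC_PENALTY * (1.0 - aln.I) + (aln.d / PC_D0) ** 2)
    return float(f_c * np.sum(terms) / L_Q)


def chemical_class(aa: str) -> str:
    """Chemical class of a standard amino acid (one of six, non-overlapping)."""
    try:
        return _AA_TO_CLASS[aa]
    except KeyError:
        raise ValueError(f"nonstandard amino acid {aa!r}") from None


def contact_overlap(pair: tuple[ResRef, ResRef],
                    query_partners: dict[ResRef, set[ResRef]],
                    template_partners: dict[ResRef, set[ResRef]],
                    pair_map: dict[ResRef, ResRef]) -> float:
    """Contact-overlap fraction f_i = (c_i/a_i + c_i/b_i)/2 of one pair.

    ``b_i`` counts the query residue's cross-chain contacts, ``a_i`` the
    template residue's, and ``c_i`` those query contacts whose partner is
    aligned onto a template residue in contact with the template member of
    the pair.
    """
    q, t = pair
    q_contacts = query_partners.get(q, set())
    t_contacts = template_partners.get(t, set())
    b, a = len(q_contacts), len(t_contacts)
    if a == 0 or b == 0:
        return 0.0
    c = sum(1 for p in q_contacts
            if p in pair_map and pair_map[p] in t_contacts)
    return 0.5 * (c / a + c / b)


def common_contact_ratio(query: InterfaceModel,
                         template: InterfaceModel,
                         pair_map: dict[ResRef, ResRef]) -> float:
    """f_c: fraction of query interface contacts preserved under the alignment."""
    if not query.contacts:
        return 0.0
    t_contact_set = {frozenset(p) for p in template.contacts}
    kept = sum(
        1 for a, b in query.contacts
        if a in pair_map and b in pair_map
        and frozenset((pair_map[a], pair_map[b])) in t_contact_set
    )
    return kept / len(query.contacts)


# ---------------------------------------------------------------------------
# correspondence search
# ---------------------------------------------------------------------------

def _dp_align(S: np.ndarray) -> list[tuple[int, int]]:
    """Global alignment maximizing Σ S over order-preserving pairs, gap 0."""
    n, m = S.shape
    H = np.zeros((n + 1, m + 1))
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            H[i, j] = max(H[i - 1, j - 1] + S[i - 1, j - 1],
                          H[i - 1, j], H[i, j - 1])
    pairs = []
    i, j = n, m
    while i > 0 and j > 0:
        if H[i, j] == H[i - 1, j - 1] + S[i - 1, j - 1]:
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif H[i, j] == H[i - 1, j]:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    return pairs


def _thread_seeds(lq: int, lt: int) -> list[int]:
    """Gapless threading offsets of the shorter list along the longer."""
    span = lt - lq
    return sorted({0, span // 2, span})


def _zero_report(pairing) -> SimilarityReport:
    empty = InterfaceAlignment(pairs=[], d=np.zeros(0), f=np.zeros(0),
                               I=np.zeros(0), rotation=np.eye(3),
                               translation=np.zeros(3), rmsd=0.0, f_c=0.0)
    return SimilarityReport(0.0, 0.0, 0.0, empty, pairing)


def align_interfaces(query: InterfaceModel, template: InterfaceModel,
                     metric: str = "iscore",
                     max_iter: int = MAX_REFINE_ITER) -> SimilarityReport:
    """Align two binding interfaces and compute iTM-score, Iscore and PCscore.

    Both chain pairings are tried; within a pairing the alignment is
    refined by iterating superposition and dynamic programming from
    gapless-threading seeds.  All scores are normalized by the *query*
    interface length.
    """
    if metric not in ("itm", "iscore", "pcscore"):
        raise ValueError(f"unknown metric {metric!r}")
    L_Q = query.L_Q
    scale = d0(L_Q)
    qc = [c.chain_id for c in query.complex.chains]
    tc = [c.chain_id for c in template.complex.chains]

    def chain_data(model: InterfaceModel, cid: str):
        refs = model.interface_residues[cid]
        coords = np.array([model.complex.residue(r).ca for r in refs])
        return refs, coords

    q_partners = query.contact_partners()
    t_partners = template.contact_partners()

    best: SimilarityReport | None = None
    best_key: tuple[float, float] | None = None

    for t_order in ((tc[0], tc[1]), (tc[1], tc[0])):
        pairing = ((qc[0], t_order[0]), (qc[1], t_order[1]))
        chain_pairs = []
        for (qcid, tcid) in pairing:
            qrefs, qxyz = chain_data(query, qcid)
            trefs, txyz = chain_data(template, tcid)
            chain_pairs.append((qrefs, qxyz, trefs, txyz))

        seeds = set()
        for off0 in _thread_seeds(min(len(chain_pairs[0][0]), len(chain_pairs[0][2])),
                                  max(len(chain_pairs[0][0]), len(chain_pairs[0][2]))):
            seeds.add(off0)
        for seed_off in sorted(seeds):
            idx_pairs = _seed_pairs(chain_pairs, seed_off)
            if len(idx_pairs) < 3:
                continue
            aln_idx = _refine(chain_pairs, idx_pairs, scale, max_iter)
            if aln_idx is None or len(aln_idx[0]) < 3:
                continue
            pairs_idx, R, t, rmsd = aln_idx
            report = _build_report(query, template, chain_pairs, pairs_idx,
                                   R, t, rmsd, q_partners, t_partners,
                                   pairing, L_Q)
            key = ({"itm": report.itm, "iscore": report.iscore,
                    "pcscore": report.pcscore}[metric], -report.alignment.rmsd)
            if best_key is None or key > best_key:
                best, best_key = report, key

    if best is None:
        return _zero_report(((qc[0], tc[0]), (qc[1], tc[1])))
    return best


def _seed_pairs(chain_pairs, offset: int) -> list[tuple[int, tuple[int, int]]]:
    """Gapless index pairs per chain pair at the given threading offset."""
    out = []
    for k, (qrefs, _, trefs, _) in enumerate(chain_pairs):
        lq, lt = len(qrefs), len(trefs)
        for qi in range(lq):
            ti = qi + offset if lq <= lt else qi - offset
            if 0 <= ti < lt:
                out.append((k, (qi, ti)))
    return out


def _refine(chain_pairs, idx_pairs, scale: float, max_iter: int):
    """Iterate superposition + DP until the pair set stabilizes."""
    current = idx_pairs
    R = t = None
    rmsd = 0.0
    for _ in range(max_iter):
        qxyz = np.array([chain_pairs[k][1][qi] for k, (qi, ti) in current])
        txyz = np.array([chain_pairs[k][3][ti] for k, (qi, ti) in current])
        if len(qxyz) < 3:
            return None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            R, t, rmsd = kabsch_superpose(qxyz, txyz)
        new_pairs = []
        for k, (qrefs, qx, trefs, tx) in enumerate(chain_pairs):
            tx_fit = tx @ R.T + t
            diff = qx[:, None, :] - tx_fit[None, :, :]
            D2 = np.sum(diff * diff, axis=2)
            S = 1.0 / (1.0 + D2 / (scale * scale))
            for qi, ti in _dp_align(S):
                new_pairs.append((k, (qi, ti)))
        if new_pairs == current:
            break
        current = new_pairs
    return current, R, t, rmsd


def _build_report(query, template, chain_pairs, pairs_idx, R, t, rmsd,
                  q_partners, t_partners, pairing, L_Q) -> SimilarityReport:
    pairs: list[tuple[ResRef, ResRef]] = []
    d_list = []
    for k, (qi, ti) in pairs_idx:
        qrefs, qx, trefs, tx = chain_pairs[k]
        pairs.append((qrefs[qi], trefs[ti]))
        d_list.append(np.linalg.norm(qx[qi] - (tx[ti] @ R.T + t)))
    pair_map = dict(pairs)
    f = np.array([contact_overlap(p, q_partners, t_partners, pair_map)
                  for p in pairs])
    I = np.array([
        1.0 if chemical_class(query.complex.residue(q).aa)
        == chemical_class(template.complex.residue(tr).aa) else 0.0
        for q, tr in pairs
    ])
    f_c = common_contact_ratio(query, template, pair_map)
    aln = InterfaceAlignment(pairs=pairs, d=np.array(d_list), f=f, I=I,
                             rotation=R, translation=t, rmsd=rmsd, f_c=f_c)
    return SimilarityReport(
        itm=itm_score(aln, L_Q),
        iscore=i_score(aln, L_Q),
        pcscore=pc_score(aln, L_Q),
        alignment=aln,
        chain_pairing=pairing,
    )
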