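"""Mutation-table curation and template-library construction.

Curation implements the replicate rules used for experimental binding
data: only mutations confined to one side of the interface are kept,
replicate measurements of the same mutation are grouped, replicates more
than one standard deviation above the group mean are discarded (high
outliers only — the rule is deliberately asymmetric) and the remainder
averaged.

The template library keeps non-redundant dimers: higher-order assemblies
are split into all pairwise dimers, dimers with fewer than ten interface
residues on either chain are dropped, and a dimer is pruned when it shares
at least 70% sequence identity AND a whole-complex TM-score of at least
0.8 with an earlier library entry (first kept wins).
"""

from __future__ import annotations

import io
import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ifacealign import d0, kabsch_superpose
from .structmodel import Chain, ComplexStructure, InterfaceModel, extract_interface
from .seqfeatures import MutationRecord, parse_mutation_token

MIN_INTERFACE_RESIDUES = 10
IDENTITY_THRESHOLD = 0.70
TM_THRESHOLD = 0.80

MUTATION_COLUMNS = ["complex_id", "chain", "mutations", "ddg_exp", "temperature"]


# ---------------------------------------------------------------------------
# mutation-table parsing and curation
# ---------------------------------------------------------------------------

def read_mutation_table(text_or_df) -> pd.DataFrame:
    if isinstance(text_or_df, pd.DataFrame):
        df = text_or_df.copy()
    else:
        df = pd.read_csv(io.StringIO(text_or_df), sep="\t", dtype=str)
    missing = [c for c in MUTATION_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"mutation table is missing columns {missing}")
    if "temperature" not in df.columns:
        df["temperature"] = np.nan
    return df


def _row_to_record(row, idx) -> MutationRecord:
    try:
        subs = tuple(parse_mutation_token(tok, str(row["chain"]).strip())
                     for tok in str(row["mutations"]).split(";") if tok.strip())
        ddg = float(row["ddg_exp"])
        temp = row.get("temperature")
        temp = float(temp) if temp is not None and not pd.isna(temp) else None
        return MutationRecord(str(row["complex_id"]), subs, ddg, temp)
    except (ValueError, KeyError) as exc:
        raise ValueError(f"malformed mutation row {idx}: {exc}") from exc


@dataclass
class CuratedDataset:
    records: list[MutationRecord]
    provenance: dict[tuple, list[int]] = field(default_factory=dict)
    excluded: list[tuple[int, str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            chain = next(iter(r.chains))
            muts = ";".join(f"{s.wt}{s.position}{s.mut}"
                            for s in sorted(r.substitutions,
                                            key=lambda s: s.position))
            rows.append({"complex_id": r.complex_id, "chain": chain,
                         "mutations": muts, "ddg_exp": r.ddg_exp,
                         "temperature": r.temperature})
        return pd.DataFrame(rows, columns=MUTATION_COLUMNS)


def average_replicates(values: list[float]) -> float:
    """Group average after discarding values more than one standard
    deviation above the group mean (population sd, single pass)."""
    v = np.asarray(values, dtype=float)
    if len(v) == 1:
        return float(v[0])
    mean, sd = v.mean(), v.std()
    kept = v[v <= mean + sd]
    return float(kept.mean())


def curate_mutations(raw) -> CuratedDataset:
    """Curate a raw mutation table (TSV text or DataFrame).

    Multi-chain records (mutations on both sides of the interface) are
    excluded; identical (complex, mutation-set) entries are merged by the
    high-outlier averaging rule.
    """
    df = read_mutation_table(raw)
    groups: dict[tuple, list[tuple[int, MutationRecord]]] = {}
    excluded: list[tuple[int, str]] = []
    for idx, row in df.iterrows():
        rec = _row_to_record(row, idx)
        if len(rec.chains) > 1:
            excluded.append((idx, "mutations on both chains"))
            continue
        groups.setdefault(rec.key(), []).append((idx, rec))
    records, provenance = [], {}
    for key, members in groups.items():
        values = [rec.ddg_exp for _, rec in members]
        ddg = average_replicates(values)
        first = members[0][1]
        records.append(MutationRecord(first.complex_id, first.substitutions,
                                      ddg, first.temperature))
        provenance[key] = [idx for idx, _ in members]
    return CuratedDataset(records=records, provenance=provenance,
                          excluded=excluded)


def split_dataset(records: list, fractions=(0.60, 0.15, 0.25),
                  seed: int = 0) -> tuple[list, list, list]:
    """Deterministic disjoint train/test/validation partition."""
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    n = len(records)
    n_train = round(fractions[0] * n)
    n_test = round(fractions[1] * n)
    idx = [order[:n_train], order[n_train:n_train + n_test],
           order[n_train + n_test:]]
    return tuple([records[i] for i in part] for part in idx)


# ---------------------------------------------------------------------------
# template library
# ---------------------------------------------------------------------------

@dataclass
class TemplateLibrary:
    entries: list[tuple[ComplexStructure, InterfaceModel]]

    def __iter__(self):
        return ((c.id, m) for c, m in self.entries)

    def index(self) -> pd.DataFrame:
        rows = []
        for c, m in self.entries:
            rows.append({
                "id": c.id,
                "chains": "".join(ch.chain_id for ch in c.chains),
                "n_interface_0": len(m.interface_residues[c.chains[0].chain_id]),
                "n_interface_1": len(m.interface_residues[c.chains[1].chain_id]),
            })
        return pd.DataFrame(rows, columns=["id", "chains", "n_interface_0",
                                           "n_interface_1"])


def split_to_dimers(entry_id: str, chains: list[Chain]) -> list[ComplexStructure]:
    """All pairwise dimers of a (possibly higher-order) assembly."""
    out = []
    for a, b in itertools.combinations(chains, 2):
        out.append(ComplexStructure(f"{entry_id}_{a.chain_id}{b.chain_id}", (a, b)))
    return out


def _aligner():
    from Bio import Align
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 1.0
    al.mismatch_score = 0.0
    al.open_gap_score = -1.0
    al.extend_gap_score = -0.5
    return al


def sequence_identity(seq_a: str, seq_b: str, aligner=None) -> float:
    """Global-alignment identity, normalized by the shorter sequence."""
    if not seq_a or not seq_b:
        return 0.0
    aligner = aligner or _aligner()
    aln = aligner.align(seq_a, seq_b)[0]
    matches = sum(
        1
        for (a0, a1), (b0, b1) in zip(aln.aligned[0], aln.aligned[1])
        for i in range(a1 - a0)
        if seq_a[a0 + i] == seq_b[b0 + i]
    )
    return matches / min(len(seq_a), len(seq_b))


def _aligned_ca_pairs(ca_a: Chain, ca_b: Chain, aligner) -> list[tuple[int, int]]:
    aln = aligner.align(ca_a.sequence, ca_b.sequence)[0]
    pairs = []
    for (a0, a1), (b0, b1) in zip(aln.aligned[0], aln.aligned[1]):
        pairs.extend((a0 + i, b0 + i) for i in range(a1 - a0))
    return pairs


def complex_tm_score(a: ComplexStructure, b: ComplexStructure) -> float:
    """Approximate whole-complex TM-score.

    Chains are paired by best summed sequence identity, aligned chainwise
    by global sequence alignment, jointly superposed once, and scored with
    the TM-score formula normalized by the shorter complex.  This is a
    sequence-guided single-superposition approximation to a full
    structural alignment of the complex.
    """
    aligner = _aligner()
    pairings = [((0, 0), (1, 1)), ((0, 1), (1, 0))]

    def ident(pairing):
        return sum(sequence_identity(a.chains[i].sequence,
                                     b.chains[j].sequence, aligner)
                   for i, j in pairing)

    pairing = max(pairings, key=ident)
    coords_a, coords_b = [], []
    for i, j in pairing:
        for ia, ib in _aligned_ca_pairs(a.chains[i], b.chains[j], aligner):
            coords_a.append(a.chains[i].residues[ia].ca)
            coords_b.append(b.chains[j].residues[ib].ca)
    if len(coords_a) < 3:
        return 0.0
    A, B = np.array(coords_a), np.array(coords_b)
    R, t, _ = kabsch_superpose(A, B)
    d = np.linalg.norm(A - (B @ R.T + t), axis=1)
    L_min = min(sum(len(c) for c in a.chains), sum(len(c) for c in b.chains))
    scale = d0(L_min)
    return float(np.sum(1.0 / (1.0 + (d / scale) ** 2)) / L_min)


def library_identity(a: ComplexStructure, b: ComplexStructure) -> float:
    """Sequence identity of two complexes over concatenated chains in the
    best-identity chain pairing."""
    aligner = _aligner()
    best = 0.0
    for pairing in [((0, 0), (1, 1)), ((0, 1), (1, 0))]:
        seq_a = "".join(a.chains[i].sequence for i, _ in pairing)
        seq_b = "".join(b.chains[j].sequence for _, j in pairing)
        best = max(best, sequence_identity(seq_a, seq_b, aligner))
    return best


def build_template_library(entries, min_interface: int = MIN_INTERFACE_RESIDUES,
                           identity_threshold: float = IDENTITY_THRESHOLD,
                           tm_threshold: float = TM_THRESHOLD) -> TemplateLibrary:
    """Build the non-redundant dimer library.

    ``entries`` yields either ``ComplexStructure`` dimers or
    ``(entry_id, [Chain, ...])`` assemblies to be split into dimers.
    Redundancy is tested in input order against already-kept entries with
    the conjunctive identity-AND-TM rule.
    """
    candidates: list[ComplexStructure] = []
    for entry in entries:
        if isinstance(entry, ComplexStructure):
            candidates.append(entry)
        else:
            entry_id, chains = entry
            candidates.extend(split_to_dimers(entry_id, list(chains)))

    kept: list[tuple[ComplexStructure, InterfaceModel]] = []
    for cand in candidates:
        try:
            model = extract_interface(cand)
        except ValueError:
            continue
        sizes = [len(model.interface_residues[ch.chain_id])
                 for ch in cand.chains]
        if min(sizes) < min_interface:
            continue
        redundant = False
        for prev, _ in kept:
            if (library_identity(cand, prev) >= identity_threshold
                    and complex_tm_score(cand, prev) >= tm_threshold):
                redundant = True
                break
        if not redundant:
            kept.append((cand, model))
    return TemplateLibrary(kept)
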