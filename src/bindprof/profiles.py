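"""Interface structure profiles and the mutant profile score.

A profile is built from the interface sequences of structurally similar
complexes (template hits), aligned position-by-position onto the query
interface.  Per position ``p`` the Henikoff-weighted amino-acid frequency
``g(p,a)`` is smoothed through a substitution matrix,

    F(p,A) = Σ_a g(p,a) · M(A,a),

so that sparse template coverage is compensated by substitution
statistics.  The predicted binding free-energy change of a mutation is the
drop in profile score,

    ΔΔG_calc = F(p, A_WT) − F(p, A_Mut),

summed over sites for multi-site mutations (the score is linearly
additive by construction).

The adaptive profile mixes template hits from two similarity levels: every
hit above a strict cutoff plus up to ``n`` hits between a looser and the
strict cutoff — strict similarity guarantees relevance, the extra
lower-similarity sequences fill in positions the strict set covers too
thinly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ifacealign import SimilarityReport, align_interfaces
from .structmodel import AA_INDEX, AA_ORDER, InterfaceModel, extract_interface

GAP = "-"

STRICT_CUTOFF = 0.25   # adaptive profile, strict interface-similarity level
LOOSE_CUTOFF = 0.19    # adaptive profile, loose level
N_ADD = 80             # max lower-similarity sequences added adaptively

#: Background amino-acid frequencies of the BLOSUM62 derivation, used as
#: the reference distribution for the Jensen-Shannon conservation measure.
BLOSUM62_BACKGROUND = {
    "A": 0.074, "R": 0.052, "N": 0.045, "D": 0.054, "C": 0.025,
    "Q": 0.034, "E": 0.054, "G": 0.074, "H": 0.026, "I": 0.068,
    "L": 0.099, "K": 0.058, "M": 0.025, "F": 0.047, "P": 0.039,
    "S": 0.057, "T": 0.051, "W": 0.013, "Y": 0.032, "V": 0.073,
}

_MATRX_CACHE: dict[str, np.ndarray] = {}

#: Finite sentinels for profile-quality features at sites no template
#: covers; n_seq_at_site = 0 marks them so a downstream model can
#: down-weight such rows.
UNCOVERED_RMSD = -1.0
UNCOVERED_CONTACTS = 0.0
UNCOVERED_JS = 1.0


def substitution_matrix(name: str = "BLOSUM62") -> np.ndarray:
    """20x20 substitution matrix in AA_ORDER (loaded from Biopython)."""
    if name not in _MATRX_CACHE:
        from Bio.Align import substitution_matrices
        m = substitution_matrices.load(name)
        idx = [m.alphabet.index(a) for a in AA_ORDER]
        _MATRX_CACHE[name] = np.asarray(m)[np.ix_(idx, idx)].astype(float)
    return _MATRX_CACHE[name]


def background_distribution() -> np.ndarray:
    bg = np.array([BLOSUM62_BACKGROUND[a] for a in AA_ORDER])
    return bg / bg.sum()


# ---------------------------------------------------------------------------
# template hits
# ---------------------------------------------------------------------------

@dataclass
class TemplateHit:
    """One template interface aligned onto the query interface positions."""

    template_id: str
    similarity: SimilarityReport
    aligned_sequence: str     # one char per query interface position, '-' = gap
    d: np.ndarray             # per-position Cα distance, NaN at gaps
    f: np.ndarray             # per-position contact overlap, NaN at gaps

    def score(self, metric: str) -> float:
        return {"itm": self.similarity.itm, "iscore": self.similarity.iscore,
                "pcscore": self.similarity.pcscore}[metric]


def make_hit(query: InterfaceModel, template: InterfaceModel,
             template_id: str, metric: str = "iscore") -> TemplateHit:
    """Align one template interface to the query and project it onto
    the query interface positions."""
    report = align_interfaces(query, template, metric=metric)
    positions = query.positions()
    pos_index = {ref: i for i, ref in enumerate(positions)}
    seq = [GAP] * len(positions)
    d = np.full(len(positions), np.nan)
    f = np.full(len(positions), np.nan)
    for k, (qref, tref) in enumerate(report.alignment.pairs):
        i = pos_index.get(qref)
        if i is None:
            continue
        seq[i] = template.complex.residue(tref).aa
        d[i] = report.alignment.d[k]
        f[i] = report.alignment.f[k]
    return TemplateHit(template_id, report, "".join(seq), d, f)


def collect_templates(query: InterfaceModel, library, metric: str = "iscore",
                      cutoff: float = 0.0) -> list[TemplateHit]:
    """Align every library complex to the query and keep hits at or above
    the similarity cutoff, sorted by descending similarity then id, with
    exactly redundant aligned interface sequences removed (first kept).

    ``library`` yields ``(template_id, ComplexStructure | InterfaceModel)``.
    """
    hits: list[TemplateHit] = []
    for template_id, entry in library:
        model = (entry if isinstance(entry, InterfaceModel)
                 else extract_interface(entry, classify=False))
        hit = make_hit(query, model, template_id, metric)
        if hit.score(metric) >= cutoff:
            hits.append(hit)
    hits.sort(key=lambda h: (-h.score(metric), h.template_id))
    seen: set[str] = set()
    unique = []
    for h in hits:
        if h.aligned_sequence in seen:
            continue
        seen.add(h.aligned_sequence)
        unique.append(h)
    return unique


# ---------------------------------------------------------------------------
# Henikoff position-based weights
# ---------------------------------------------------------------------------

def henikoff_weights(msa: list[str]) -> np.ndarray:
    """Position-based sequence weights (Henikoff & Henikoff), normalized.

    Per column, a sequence showing residue type ``a`` receives 1/(r·s)
    where ``r`` is the number of distinct residue types in the column and
    ``s`` the number of sequences sharing type ``a``; gap cells contribute
    nothing.  Weights are summed over columns and normalized to 1.
    """
    if not msa:
        raise ValueError("empty alignment")
    n = len(msa)
    L = len(msa[0])
    if any(len(s) != L for s in msa):
        raise ValueError("aligned sequences must have equal length")
    w = np.zeros(n)
    for col in range(L):
        column = [s[col] for s in msa]
        counts: dict[str, int] = {}
        for ch in column:
            if ch != GAP:
                counts[ch] = counts.get(ch, 0) + 1
        r = len(counts)
        if r == 0:
            continue
        for i, ch in enumerate(column):
            if ch != GAP:
                w[i] += 1.0 / (r * counts[ch])
    total = w.sum()
    if total <= 0:
        return np.full(n, 1.0 / n)
    return w / total


# ---------------------------------------------------------------------------
# profile construction and scoring
# ---------------------------------------------------------------------------

@dataclass
class InterfaceProfile:
    positions: list            # query interface residue refs
    g: np.ndarray              # positions x 20 weighted frequencies
    F: np.ndarray              # positions x 20 profile scores
    n_seq: np.ndarray          # per-position count of non-gap sequences
    matrix_name: str

    def position_index(self, ref) -> int:
        try:
            return self.positions.index(ref)
        except ValueError:
            raise ValueError(f"{ref} is not an interface position") from None


def build_profile(hits: list[TemplateHit], substitution: str = "BLOSUM62",
                  positions: list | None = None) -> InterfaceProfile:
    """Henikoff-weighted frequency profile mixed through a substitution matrix."""
    if not hits:
        raise ValueError("cannot build a profile from zero template hits")
    msa = [h.aligned_sequence for h in hits]
    L = len(msa[0])
    w = henikoff_weights(msa)
    g = np.zeros((L, 20))
    n_seq = np.zeros(L, dtype=int)
    for seq, wi in zip(msa, w):
        for p, ch in enumerate(seq):
            if ch == GAP:
                continue
            g[p, AA_INDEX[ch]] += wi
            n_seq[p] += 1
    if n_seq.sum() == 0:
        raise ValueError("all-gap profile: no position is covered by any hit")
    covered = n_seq > 0
    g[covered] /= g[covered].sum(axis=1, keepdims=True)
    M = substitution_matrix(substitution)
    F = g @ M.T        # F[p, A] = sum_a g[p, a] * M[A, a]
    if positions is None:
        positions = list(range(L))
    return InterfaceProfile(positions=list(positions), g=g, F=F,
                            n_seq=n_seq, matrix_name=substitution)


def mutant_profile_score(profile: InterfaceProfile, site, wt: str, mut: str
                         ) -> float:
    """Predicted ΔΔG of a substitution: F(p, WT) − F(p, Mut).

    ``site`` is an interface position (index or residue ref).  Positions no
    template covers fall back to the raw substitution-matrix difference
    M(WT,WT) − M(WT,Mut).  Multi-site mutations are scored with
    :func:`mutant_profile_score_multi` (the score is additive over sites).
    """
    if wt not in AA_INDEX or mut not in AA_INDEX:
        raise ValueError(f"nonstandard amino acid in {wt!r}->{mut!r}")
    p = site if isinstance(site, (int, np.integer)) else profile.position_index(site)
    if not 0 <= p < len(profile.positions):
        raise ValueError(f"site {site} is not an interface position")
    if profile.n_seq[p] == 0:
        M = substitution_matrix(profile.matrix_name)
        return float(M[AA_INDEX[wt], AA_INDEX[wt]] - M[AA_INDEX[wt], AA_INDEX[mut]])
    return float(profile.F[p, AA_INDEX[wt]] - profile.F[p, AA_INDEX[mut]])


def mutant_profile_score_multi(profile: InterfaceProfile,
                               sites_wt_mut: list[tuple]) -> float:
    """Sum of single-site profile scores over a multi-site mutation."""
    return sum(mutant_profile_score(profile, s, w, m) for s, w, m in sites_wt_mut)


# ---------------------------------------------------------------------------
# adaptive profile
# ---------------------------------------------------------------------------

def select_adaptive(hits_sorted: list[TemplateHit], strict: float,
                    loose: float, n: int, metric: str = "iscore"
                    ) -> list[TemplateHit]:
    """Adaptive template selection: all hits ≥ strict plus up to ``n``
    hits with loose ≤ similarity < strict (hits must be sorted descending)."""
    if strict <= loose:
        raise ValueError("strict cutoff must exceed the loose cutoff")
    strict_set = [h for h in hits_sorted if h.score(metric) >= strict]
    middle = [h for h in hits_sorted if loose <= h.score(metric) < strict]
    selected = strict_set + middle[:max(0, n)]
    if not selected:
        raise ValueError("no usable templates: no hit reaches the loose cutoff")
    return selected


def adaptive_profile(hits_sorted: list[TemplateHit], strict: float = STRICT_CUTOFF,
                     loose: float = LOOSE_CUTOFF, n: int = N_ADD,
                     metric: str = "iscore", substitution: str = "BLOSUM62",
                     positions: list | None = None) -> InterfaceProfile:
    selected = select_adaptive(hits_sorted, strict, loose, n, metric)
    return build_profile(selected, substitution, positions)


# ---------------------------------------------------------------------------
# profile-quality features
# ---------------------------------------------------------------------------

def js_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence, base 2, equal-weight mixture (bits, in [0,1])."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    p = p / p.sum()
    q = q / q.sum()
    m = 0.5 * (p + q)

    def _kl(x, y):
        mask = x > 0
        return float(np.sum(x[mask] * np.log2(x[mask] / y[mask])))

    return 0.5 * _kl(p, m) + 0.5 * _kl(q, m)


@dataclass
class SiteQuality:
    mean_rmsd_at_site: float        # mean Cα deviation of hits covering the site, Å
    mean_preserved_contacts: float  # mean contact-overlap f_i at the site
    n_seq_at_site: int              # hits aligning the site
    js_divergence: float            # conservation vs background, bits
    js_zscore: float                # JS z-scored across interface sites


def profile_quality_features(hits: list[TemplateHit], profile: InterfaceProfile,
                             site, background: np.ndarray | None = None
                             ) -> SiteQuality:
    """The five per-site profile-quality features.

    Sites covered by no hit get finite sentinels (negative RMSD, zero
    contacts, JS of 1 bit) and ``n_seq_at_site = 0``.
    """
    p = site if isinstance(site, (int, np.integer)) else profile.position_index(site)
    if background is None:
        background = background_distribution()
    d_vals = np.array([h.d[p] for h in hits if not np.isnan(h.d[p])])
    f_vals = np.array([h.f[p] for h in hits if not np.isnan(h.f[p])])
    n_here = int(profile.n_seq[p])

    covered = profile.n_seq > 0
    js_all = np.full(len(profile.positions), np.nan)
    for i in np.where(covered)[0]:
        js_all[i] = js_divergence(profile.g[i], background)
    if covered[p]:
        js_here = js_all[p]
        vals = js_all[covered]
        sd = float(np.std(vals))
        z = 0.0 if sd == 0 else float((js_here - np.mean(vals)) / sd)
    else:
        js_here, z = UNCOVERED_JS, 0.0
    return SiteQuality(
        mean_rmsd_at_site=float(d_vals.mean()) if len(d_vals) else UNCOVERED_RMSD,
        mean_preserved_contacts=float(f_vals.mean()) if len(f_vals) else UNCOVERED_CONTACTS,
        n_seq_at_site=n_here,
        js_divergence=float(js_here),
        js_zscore=z,
    )


# ---------------------------------------------------------------------------
# the 13-feature profile set
# ---------------------------------------------------------------------------

@dataclass
class ProfileFeatureSet:
    """Three profile scores plus five quality features at each of the two
    fixed similarity levels: 13 features total."""

    score_high: float
    score_low: float
    score_adaptive: float
    high_mean_rmsd: float
    high_preserved_contacts: float
    high_n_seq: float
    high_js: float
    high_js_z: float
    low_mean_rmsd: float
    low_preserved_contacts: float
    low_n_seq: float
    low_js: float
    low_js_z: float

    FIELDS = ("score_high", "score_low", "score_adaptive",
              "high_mean_rmsd", "high_preserved_contacts", "high_n_seq",
              "high_js", "high_js_z",
              "low_mean_rmsd", "low_preserved_contacts", "low_n_seq",
              "low_js", "low_js_z")

    def as_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in self.FIELDS}


def _level_profile(hits_sorted, cutoff, metric, substitution, positions):
    level = [h for h in hits_sorted if h.score(metric) >= cutoff]
    if not level:
        return None, []
    return build_profile(level, substitution, positions), level


def _score_or_fallback(profile, sites_wt_mut, substitution):
    if profile is not None:
        return mutant_profile_score_multi(profile, sites_wt_mut)
    M = substitution_matrix(substitution)
    return float(sum(M[AA_INDEX[w], AA_INDEX[w]] - M[AA_INDEX[w], AA_INDEX[m]]
                     for _, w, m in sites_wt_mut))


def _mean_quality(hits, profile, sites) -> SiteQuality:
    if profile is None:
        return SiteQuality(UNCOVERED_RMSD, UNCOVERED_CONTACTS, 0,
                           UNCOVERED_JS, 0.0)
    qs = [profile_quality_features(hits, profile, s) for s in sites]
    return SiteQuality(
        mean_rmsd_at_site=float(np.mean([q.mean_rmsd_at_site for q in qs])),
        mean_preserved_contacts=float(np.mean([q.mean_preserved_contacts for q in qs])),
        n_seq_at_site=int(np.min([q.n_seq_at_site for q in qs])),
        js_divergence=float(np.mean([q.js_divergence for q in qs])),
        js_zscore=float(np.mean([q.js_zscore for q in qs])),
    )


def profile_feature_set(hits_sorted: list[TemplateHit],
                        sites_wt_mut: list[tuple],
                        strict: float = STRICT_CUTOFF,
                        loose: float = LOOSE_CUTOFF,
                        n: int = N_ADD,
                        metric: str = "iscore",
                        substitution: str = "BLOSUM62",
                        positions: list | None = None) -> ProfileFeatureSet:
    """Assemble the 13 profile features of one (possibly multi-site) mutation.

    ``sites_wt_mut`` is a list of (site, wt, mut) tuples; sites are indices
    into the query interface positions or residue refs matching
    ``positions``.  Quality features of multi-site mutations are averaged
    over sites (n_seq takes the minimum, the conservative choice).
    """
    high_profile, high_hits = _level_profile(hits_sorted, strict, metric,
                                             substitution, positions)
    low_profile, low_hits = _level_profile(hits_sorted, loose, metric,
                                           substitution, positions)
    try:
        ada_profile = adaptive_profile(hits_sorted, strict, loose, n,
                                       metric, substitution, positions)
    except ValueError:
        ada_profile = None
    sites = [s for s, _, _ in sites_wt_mut]
    hq = _mean_quality(high_hits, high_profile, sites)
    lq = _mean_quality(low_hits, low_profile, sites)
    return ProfileFeatureSet(
        score_high=_score_or_fallback(high_profile, sites_wt_mut, substitution),
        score_low=_score_or_fallback(low_profile, sites_wt_mut, substitution),
        score_adaptive=_score_or_fallback(ada_profile, sites_wt_mut, substitution),
        high_mean_rmsd=hq.mean_rmsd_at_site,
        high_preserved_contacts=hq.mean_preserved_contacts,
        high_n_seq=hq.n_seq_at_site,
        high_js=hq.js_divergence,
        high_js_z=hq.js_zscore,
        low_mean_rmsd=lq.mean_rmsd_at_site,
        low_preserved_contacts=lq.mean_preserved_contacts,
        low_n_seq=lq.n_seq_at_site,
        low_js=lq.js_divergence,
        low_js_z=lq.js_zscore,
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def profile_to_tsv(profile: InterfaceProfile, model: InterfaceModel | None = None
                   ) -> str:
    """Tab-separated profile: one row per interface position with the 20
    profile scores F(p,A) and the per-position sequence count."""
    header = ["chain", "resnum"] + list(AA_ORDER) + ["n_seq"]
    lines = ["\t".join(header)]
    for i, ref in enumerate(profile.positions):
        if model is not None and isinstance(ref, tuple):
            res = model.complex.residue(ref)
            chain, num = ref[0], f"{res.seqid}{res.icode}"
        else:
            chain, num = "-", str(ref)
        row = [chain, num] + [f"{x:.6f}" for x in profile.F[i]] + [str(int(profile.n_seq[i]))]
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


def profile_from_tsv(text: str) -> InterfaceProfile:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    rows = [ln.split("\t") for ln in lines[1:]]
    F = np.array([[float(x) for x in r[2:22]] for r in rows])
    n_seq = np.array([int(r[22]) for r in rows])
    positions = [(r[0], r[1]) for r in rows]
    return InterfaceProfile(positions=positions, g=np.zeros_like(F), F=F,
                            n_seq=n_seq, matrix_name="BLOSUM62")
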