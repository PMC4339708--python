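"""Profile hidden Markov models for protein domain and motif detection.

A profile HMM is built from a multiple alignment of a sequence family:
alignment columns that are mostly occupied become *match* states with
position-specific emission probabilities; mostly-gap columns feed *insert*
states; rows that skip a match column pass through silent *delete* states.
Searching is Smith-Waterman-style local Viterbi: the alignment may enter
the model at any match state and leave at any match state, so a partial
domain in the middle of a long protein is found without penalty for the
flanks.  Scores are log2-odds ("bits") against a background residue
distribution, and are converted to E-values through an empirical Gumbel
(extreme-value) calibration on shuffled background sequences.

The node architecture is Plan-7-like (M/I/D per node, no D<->I edges, no
flanking self-loop states); local behaviour comes entirely from the free
entry/exit convention.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
GAP_CHARS = frozenset("-.")
WILDCARD = "X"

MODEL_SCHEMA = "bhlh-hmm/1"

# transition slots, indexed by source node k (0 = begin): probabilities of
# moving to states of node k+1 (or END at node L)
TRANS_NAMES = ("mm", "mi", "md", "im", "ii", "dm", "dd")


class AlphabetError(ValueError):
    """A sequence or alignment contains a symbol outside the 20 amino acids."""


class CalibrationError(RuntimeError):
    """The shuffled-score distribution is degenerate and cannot be fit."""


@dataclass
class MotifAlignment:
    """A named gapped alignment (rows of equal length, 20 AA + gap)."""

    name: str
    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError(f"alignment {self.name!r} is empty")
        widths = {len(seq) for _, seq in self.rows}
        if len(widths) != 1:
            raise ValueError(f"alignment {self.name!r} has unequal row lengths {sorted(widths)}")
        for rid, seq in self.rows:
            for col, ch in enumerate(seq.upper()):
                if ch not in AA_INDEX and ch not in GAP_CHARS:
                    raise AlphabetError(
                        f"alignment {self.name!r}: illegal symbol {ch!r} in row {rid!r}, column {col + 1}"
                    )

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def column(self, j: int) -> list[str]:
        return [seq[j].upper() for _, seq in self.rows]

    def gap_fraction(self, j: int) -> float:
        col = self.column(j)
        return sum(c in GAP_CHARS for c in col) / len(col)


@dataclass
class ProfileHMM:
    """Position-specific model of a sequence family.

    ``match_emissions``/``insert_emissions`` have shape (L, 20) / (L+1, 20)
    (insert node 0 precedes match 1); ``transitions`` has shape (L+1, 7) in
    :data:`TRANS_NAMES` order, row k giving the outgoing probabilities of
    node k's states.
    """

    name: str
    L: int
    match_emissions: np.ndarray
    insert_emissions: np.ndarray
    transitions: np.ndarray
    background: np.ndarray
    build_metadata: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.L < 1:
            raise ValueError("model must have at least one match state")
        if self.match_emissions.shape != (self.L, 20):
            raise ValueError("match emission table has wrong shape")
        if self.insert_emissions.shape != (self.L + 1, 20):
            raise ValueError("insert emission table has wrong shape")
        if self.transitions.shape != (self.L + 1, 7):
            raise ValueError("transition table has wrong shape")
        for mat in (self.match_emissions, self.insert_emissions):
            if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("emission rows must sum to 1")
        t = self.transitions
        for sl, label in (((0, 1, 2), "M"), ((3, 4), "I"), ((5, 6), "D")):
            if not np.allclose(t[:, sl].sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"outgoing {label} transitions must sum to 1")
        if not np.allclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")

    # -- serialization ("bhlh-hmm/1") --------------------------------------

    def to_json(self) -> str:
        doc = {
            "schema": MODEL_SCHEMA,
            "name": self.name,
            "L": self.L,
            "alphabet": AMINO_ACIDS,
            "match_emissions": self.match_emissions.tolist(),
            "insert_emissions": self.insert_emissions.tolist(),
            "transitions": self.transitions.tolist(),
            "background": self.background.tolist(),
            "build_metadata": self.build_metadata,
        }
        return json.dumps(doc, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ProfileHMM":
        doc = json.loads(text)
        if doc.get("schema") != MODEL_SCHEMA:
            raise ValueError(f"unsupported model schema {doc.get('schema')!r}")
        hmm = cls(
            name=doc["name"],
            L=int(doc["L"]),
            match_emissions=np.asarray(doc["match_emissions"], dtype=float),
            insert_emissions=np.asarray(doc["insert_emissions"], dtype=float),
            transitions=np.asarray(doc["transitions"], dtype=float),
            background=np.asarray(doc["background"], dtype=float),
            build_metadata=doc.get("build_metadata", {}),
        )
        hmm.validate()
        return hmm


@dataclass
class DomainHit:
    """A local alignment of a model to a protein.

    ``env_start``/``env_end`` are 0-based half-open protein coordinates,
    ``model_start``/``model_end`` 1-based inclusive match-state coordinates.
    ``state_path`` lists ``(kind, model_node, protein_index)`` triples with
    kind in {"M", "I", "D"}; protein_index is None for deletes.
    """

    target_id: str
    env_start: int
    env_end: int
    model_start: int
    model_end: int
    bit_score: float
    state_path: list[tuple[str, int, int | None]]
    evalue: float | None = None


@dataclass
class MotifHit:
    motif: str
    target_id: str
    bit_score: float
    evalue: float | None
    env_start: int
    env_end: int


@dataclass(frozen=True)
class GumbelCalibration:
    """Empirical extreme-value fit of maximal bit scores of background sequences."""

    mu: float
    lam: float
    n_shuffles: int
    length: int
    seed: int

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("Gumbel scale lambda must be positive")
        if self.n_shuffles < 100:
            raise ValueError("need at least 100 shuffles for a stable fit")

    def pvalue(self, bit_score: float) -> float:
        # Gumbel survival 1 - exp(-exp(-z)); computed with expm1 so the far
        # tail keeps full precision instead of cancelling to 0
        z = self.lam * (bit_score - self.mu)
        if z < -700:
            return 1.0
        return float(-math.expm1(-math.exp(-z)))

    def evalue(self, bit_score: float, n_targets: int = 1) -> float:
        return n_targets * self.pvalue(bit_score)


# ---------------------------------------------------------------------------
# model building


def _emission_vector(counts: np.ndarray, pseudo: float) -> np.ndarray:
    v = counts + pseudo
    return v / v.sum()


def build_profile(
    aln: MotifAlignment,
    match_threshold: float = 0.5,
    pseudocount: str = "laplace",
    background: np.ndarray | None = None,
) -> ProfileHMM:
    """Build a profile HMM from a gapped alignment.

    Columns whose gap fraction is below ``match_threshold`` become match
    states; the rest feed insert states.  ``pseudocount`` names the
    regularization scheme: "laplace" adds +1 to emission counts and +0.1 to
    transition counts before normalizing.
    """
    if not 0 < match_threshold <= 1:
        raise ValueError("match_threshold must be in (0, 1]")
    if pseudocount != "laplace":
        raise ValueError(f"unknown pseudocount scheme {pseudocount!r}")
    em_pseudo, tr_pseudo = 1.0, 0.1

    ncol = aln.n_columns
    match_cols = [j for j in range(ncol) if aln.gap_fraction(j) < match_threshold]
    if not match_cols:
        raise ValueError(f"alignment {aln.name!r}: no columns pass the match threshold")
    L = len(match_cols)
    is_match = [False] * ncol
    for j in match_cols:
        is_match[j] = True
    # node owning each insert column = number of match columns to its left
    node_of_col = []
    k = 0
    for j in range(ncol):
        if is_match[j]:
            k += 1
            node_of_col.append(k)
        else:
            node_of_col.append(k)

    m_counts = np.zeros((L, 20))
    i_counts = np.zeros((L + 1, 20))
    t_counts = np.zeros((L + 1, 7))

    for _, seq in aln.rows:
        seq = seq.upper()
        # per-row state sequence: (kind, node)
        states: list[tuple[str, int]] = [("M", 0)]  # begin acts as M at node 0
        mk = 0
        for j, ch in enumerate(seq):
            if is_match[j]:
                mk += 1
                if ch in GAP_CHARS:
                    states.append(("D", mk))
                else:
                    states.append(("M", mk))
                    m_counts[mk - 1, AA_INDEX[ch]] += 1
            elif ch not in GAP_CHARS:
                states.append(("I", node_of_col[j]))
                i_counts[node_of_col[j], AA_INDEX[ch]] += 1
        states.append(("M", L + 1))  # end acts as M at node L+1
        for (kind1, n1), (kind2, _n2) in zip(states, states[1:]):
            slot = {
                ("M", "M"): 0, ("M", "I"): 1, ("M", "D"): 2,
                ("I", "M"): 3, ("I", "I"): 4,
                ("D", "M"): 5, ("D", "D"): 6,
            }.get((kind1, kind2))
            if slot is None:  # D->I / I->D edges collapsed onto D->M / I->M
                slot = 5 if kind1 == "D" else 3
            t_counts[n1, slot] += 1

    match_em = np.vstack([_emission_vector(m_counts[i], em_pseudo) for i in range(L)])
    insert_em = np.vstack([_emission_vector(i_counts[i], em_pseudo) for i in range(L + 1)])

    trans = np.zeros((L + 1, 7))
    for k in range(L + 1):
        for sl in ((0, 1, 2), (3, 4), (5, 6)):
            v = t_counts[k, list(sl)] + tr_pseudo
            trans[k, list(sl)] = v / v.sum()

    bg = np.full(20, 1 / 20) if background is None else np.asarray(background, dtype=float)
    hmm = ProfileHMM(
        name=aln.name,
        L=L,
        match_emissions=match_em,
        insert_emissions=insert_em,
        transitions=trans,
        background=bg,
        build_metadata={
            "match_threshold": match_threshold,
            "pseudocount": pseudocount,
            "match_columns": match_cols,
            "n_rows": aln.n_rows,
        },
    )
    hmm.validate()
    return hmm


# ---------------------------------------------------------------------------
# search


def encode_protein(protein: str, context: str = "") -> np.ndarray:
    """Map residues to alphabet indices; X becomes -1 (background wildcard)."""
    if not protein:
        raise ValueError(f"empty protein sequence {context}")
    idx = np.empty(len(protein), dtype=np.int64)
    for i, ch in enumerate(protein.upper()):
        if ch == WILDCARD:
            idx[i] = -1
        elif ch in AA_INDEX:
            idx[i] = AA_INDEX[ch]
        else:
            raise AlphabetError(f"illegal residue {ch!r} at position {i + 1} {context}".rstrip())
    return idx


def _log_odds(emissions: np.ndarray, background: np.ndarray) -> np.ndarray:
    # extra 0-score column for the X wildcard (index -1)
    lo = np.log2(emissions / background[None, :])
    return np.hstack([lo, np.zeros((lo.shape[0], 1))])


def viterbi_search(
    hmm: ProfileHMM,
    protein: str,
    target_id: str = "",
    report_floor: float | None = None,
) -> DomainHit | None:
    """Best local alignment of ``hmm`` to ``protein`` in bits.

    Free entry into and exit from any match state (unscored); transitions
    and emissions inside the alignment are scored as log2 odds against the
    background.  Returns None only when the best score falls below
    ``report_floor`` (default: report everything).
    """
    x = encode_protein(protein, f"in {target_id!r}" if target_id else "")
    n, L = len(x), hmm.L
    m_lo = _log_odds(hmm.match_emissions, hmm.background)  # (L, 21)
    i_lo = _log_odds(hmm.insert_emissions, hmm.background)  # (L+1, 21)
    with np.errstate(divide="ignore"):
        lt = np.log2(hmm.transitions)  # (L+1, 7)

    NEG = -np.inf
    VM = np.full((n + 1, L + 1), NEG)
    VI = np.full((n + 1, L + 1), NEG)
    VD = np.full((n + 1, L + 1), NEG)

    # delete-chain scan constants: VD[i,k] = max_{j<k}(VM[i,j] + md[j] + sum dd) via
    # cumulative dd offsets
    dd = lt[:, 6]
    cdd = np.concatenate([[0.0], np.cumsum(dd[1:L])])  # cdd[k-1] = sum dd[1..k-1]

    for i in range(1, n + 1):
        em = m_lo[:, x[i - 1]]  # (L,)
        ei = i_lo[:, x[i - 1]]  # (L+1,)
        prevM, prevI, prevD = VM[i - 1], VI[i - 1], VD[i - 1]
        # match: from M/I/D at node k-1 (position i-1), or fresh local entry (0)
        fromM = prevM[:L] + lt[:L, 0]
        fromI = prevI[:L] + lt[:L, 3]
        fromD = prevD[:L] + lt[:L, 5]
        best_prev = np.maximum.reduce([fromM, fromI, fromD, np.zeros(L)])
        VM[i, 1:] = em + best_prev
        # insert: stay at node k, from M or I at position i-1
        VI[i] = ei + np.maximum(prevM + lt[:, 1], prevI + lt[:, 4])
        # delete chain along k at fixed i
        seed = VM[i, :L] + lt[:L, 2] - cdd  # entering D_{k+1} from M_k
        run = np.maximum.accumulate(seed)
        VD[i, 1:] = run + cdd

    best_flat = int(np.argmax(VM))
    bi, bk = divmod(best_flat, L + 1)
    best = float(VM[bi, bk])
    if report_floor is not None and best < report_floor:
        return None
    if not np.isfinite(best):
        return None

    # traceback from (bi, bk) in state M
    path: list[tuple[str, int, int | None]] = []
    i, k, state = bi, bk, "M"
    while True:
        if state == "M":
            path.append(("M", k, i - 1))
            # ties resolved toward local entry (max picks the first maximum),
            # mirroring the forward recurrence's use of a plain max
            cands = [
                ("entry", 0.0),
                ("M", VM[i - 1, k - 1] + lt[k - 1, 0]),
                ("I", VI[i - 1, k - 1] + lt[k - 1, 3]),
                ("D", VD[i - 1, k - 1] + lt[k - 1, 5]),
            ]
            kind, _ = max(cands, key=lambda c: c[1])
            if kind == "entry":
                break
            state = kind
            i, k = i - 1, k - 1
        elif state == "I":
            path.append(("I", k, i - 1))
            ei = i_lo[k, x[i - 1]]
            a = VM[i - 1, k] + lt[k, 1]
            b = VI[i - 1, k] + lt[k, 4]
            state = "M" if a >= b else "I"
            i = i - 1
        else:  # D
            path.append(("D", k, None))
            a = VM[i, k - 1] + lt[k - 1, 2]
            b = VD[i, k - 1] + lt[k - 1, 6]
            state = "M" if a >= b else "D"
            k = k - 1
    path.reverse()

    emitted = [p for p in path if p[2] is not None]
    matches = [p for p in path if p[0] == "M"]
    return DomainHit(
        target_id=target_id,
        env_start=emitted[0][2],
        env_end=emitted[-1][2] + 1,
        model_start=matches[0][1],
        model_end=matches[-1][1],
        bit_score=best,
        state_path=path,
    )


def enumerate_paths_score(hmm: ProfileHMM, protein: str) -> float:
    """Exhaustive local-alignment score by brute-force path enumeration.

    Independent oracle for :func:`viterbi_search`; feasible only for tiny
    models (L <= ~4) and short sequences.
    """
    x = encode_protein(protein)
    n, L = len(x), hmm.L
    m_lo = _log_odds(hmm.match_emissions, hmm.background)
    i_lo = _log_odds(hmm.insert_emissions, hmm.background)
    with np.errstate(divide="ignore"):
        lt = np.log2(hmm.transitions)

    best = -np.inf

    def extend(node: int, kind: str, pos: int, score: float) -> None:
        # alignment currently ends at `node` in state `kind`, having consumed
        # protein[:pos]; free exit is allowed from any match state
        nonlocal best
        if kind == "M":
            best = max(best, score)
        # insert at the current node (only reachable after M/I)
        if kind in ("M", "I") and pos < n:
            slot = 1 if kind == "M" else 4
            extend(node, "I", pos + 1, score + lt[node, slot] + i_lo[node, x[pos]])
        # advance to node+1
        if node < L:
            if pos < n:  # match at node+1
                slot = {"M": 0, "I": 3, "D": 5}[kind]
                extend(node + 1, "M", pos + 1,
                       score + lt[node, slot] + m_lo[node, x[pos]])
            if kind in ("M", "D"):  # delete at node+1 (no I->D edge)
                slot = 2 if kind == "M" else 6
                extend(node + 1, "D", pos, score + lt[node, slot])

    for k1 in range(1, L + 1):
        for p1 in range(n):
            extend(k1, "M", p1 + 1, m_lo[k1 - 1, x[p1]])
    return float(best)


# ---------------------------------------------------------------------------
# E-value calibration


def calibrate_evalues(
    hmm: ProfileHMM,
    length: int = 400,
    n_shuffles: int = 200,
    seed: int = 0,
) -> GumbelCalibration:
    """Fit a Gumbel distribution to maximal scores of background sequences.

    Deterministic given ``seed``; the fitted tail converts any bit score to
    an E-value via :meth:`GumbelCalibration.evalue`.
    """
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be at least 100")
    rng = np.random.default_rng(seed)
    scores = np.empty(n_shuffles)
    aas = np.array(list(AMINO_ACIDS))
    for s in range(n_shuffles):
        seq = "".join(rng.choice(aas, size=length, p=hmm.background))
        hit = viterbi_search(hmm, seq)
        scores[s] = hit.bit_score if hit else 0.0
    if np.ptp(scores) < 1e-12:
        raise CalibrationError("degenerate shuffled-score distribution (all scores equal)")
    loc, scale = stats.gumbel_r.fit(scores)
    return GumbelCalibration(mu=float(loc), lam=float(1.0 / scale),
                             n_shuffles=n_shuffles, length=length, seed=seed)


def scan_motifs(
    protein: str,
    models: list[ProfileHMM],
    calibrations: dict[str, GumbelCalibration] | None = None,
    target_id: str = "",
    max_evalue: float | None = None,
) -> list[MotifHit]:
    """Best hit of each motif model in one protein.

    Ambiguity codes other than X are rejected; with ``max_evalue`` None all
    hits are reported with scores (corroboration downstream applies its own
    threshold).
    """
    for ch in protein.upper():
        if ch not in AA_INDEX and ch != WILDCARD:
            raise AlphabetError(f"illegal residue {ch!r} in motif scan of {target_id!r}")
    hits: list[MotifHit] = []
    for hmm in models:
        hit = viterbi_search(hmm, protein, target_id=target_id)
        if hit is None:
            continue
        ev = None
        if calibrations and hmm.name in calibrations:
            ev = calibrations[hmm.name].evalue(hit.bit_score)
        if max_evalue is not None and (ev is None or ev > max_evalue):
            continue
        hits.append(MotifHit(motif=hmm.name, target_id=target_id, bit_score=hit.bit_score,
                             evalue=ev, env_start=hit.env_start, env_end=hit.env_end))
    return hits
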