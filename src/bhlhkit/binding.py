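"""DNA-binding classification and subfamily assignment of bHLH domains.

Binding prediction reads four basic-region residues on the canonical
scheme: H or K at position 5, E at position 9, and R at positions 12 and
13.  E9 together with R12 marks an E-box (CANNTG) binder; the
H/K5-E9-R13 triad marks candidates for the G-box subtype (CACGTG).
Domains without E9 are split on the number of basic residues in the basic
region: five or more suggests binding at some non-E-box site, four or
fewer marks a non-binding (atypical) HLH that dimerizes but does not
contact DNA.

Subfamily assignment replaces a full phylogenetic bootstrap with a
distance surrogate: each domain is assigned the family of its nearest
reference exemplar (p-distance on shared canonical columns), with the
margin to the best other-family exemplar and any family-diagnostic motif
hits deciding whether the call is ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import skbio
from skbio import DistanceMatrix as _SkbioDM

from .anatomy import BASIC_RESIDUES, GAP, CanonicalDomain, count_basic_residues
from .hmm import MotifHit


class BindingCategory(str, Enum):
    G_BOX_BINDER = "G_BOX_BINDER"
    E_BOX_BINDER = "E_BOX_BINDER"
    NON_EBOX_BINDER = "NON_EBOX_BINDER"
    NON_BINDING_HLH = "NON_BINDING_HLH"


@dataclass
class BindingCall:
    """Rule flags and derived category for one domain.

    Flags are True/False/None, None meaning the rule position is a gap
    (a gap never satisfies a rule).  ``gbox_rule_raw`` is the bare
    H/K5 ^ E9 ^ R13 motif; the G_BOX_BINDER category additionally
    requires R12 so that G-box callers are a subset of E-box callers.
    """

    target_id: str
    hk5: bool | None
    e9: bool | None
    r12: bool | None
    r13: bool | None
    basic_count: int
    category: BindingCategory
    gbox_rule_raw: bool


def classify_binding(
    dom: CanonicalDomain, basic_set: frozenset[str] = BASIC_RESIDUES
) -> BindingCall:
    """Apply the basic-region residue rules to one canonical domain.

    Precedence: E9 ^ R12 ^ (H/K5 ^ E9 ^ R13) -> G_BOX_BINDER; else
    E9 ^ R12 -> E_BOX_BINDER; otherwise the basic-residue count decides
    between NON_EBOX_BINDER (>= 5) and NON_BINDING_HLH (<= 4).  The rare
    E9-without-R12 configuration therefore falls through to the
    basic-count branch and stays distinguishable through its flags.
    """

    def flag(pos: int, allowed: str) -> bool | None:
        r = dom.residue(pos)
        return None if r == GAP else r in allowed

    hk5, e9, r12, r13 = flag(5, "HK"), flag(9, "E"), flag(12, "R"), flag(13, "R")
    basic = count_basic_residues(dom, basic_set)
    raw = bool(hk5) and bool(e9) and bool(r13)
    if e9 and r12 and raw:
        cat = BindingCategory.G_BOX_BINDER
    elif e9 and r12:
        cat = BindingCategory.E_BOX_BINDER
    elif basic >= 5:
        cat = BindingCategory.NON_EBOX_BINDER
    else:
        cat = BindingCategory.NON_BINDING_HLH
    return BindingCall(dom.target_id, hk5, e9, r12, r13, basic, cat, raw)


def binding_census(calls: list[BindingCall]) -> dict:
    """Counts and percentages of the rule flags and categories.

    ``gbox_raw`` is the bare H/K5-E9-R13 count (the figure a census of the
    family reports); the stricter G_BOX_BINDER category count appears under
    the category table.  Permutation-invariant by construction.
    """
    if not calls:
        raise ValueError("census needs at least one binding call")
    n = len(calls)

    def pct(k: int) -> float:
        return round(100.0 * k / n, 1)

    counts = {
        "n": n,
        "e9": sum(bool(c.e9) for c in calls),
        "e9_and_r12": sum(bool(c.e9) and bool(c.r12) for c in calls),
        "gbox_raw": sum(c.gbox_rule_raw for c in calls),
        "e9_not_r12": sum(bool(c.e9) and not bool(c.r12) for c in calls),
        "non_e9_basic_ge5": sum(not bool(c.e9) and c.basic_count >= 5 for c in calls),
        "basic_le4": sum(c.basic_count <= 4 for c in calls),
    }
    categories = {cat.value: sum(c.category == cat for c in calls) for cat in BindingCategory}
    return {
        "counts": counts,
        "categories": categories,
        "percentages": {k: pct(v) for k, v in counts.items() if k != "n"},
        "category_percentages": {k: pct(v) for k, v in categories.items()},
    }


# ---------------------------------------------------------------------------
# distances and trees


class UndefinedDistanceError(ValueError):
    """A sequence pair shares no non-gap columns."""


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray
    model: str
    low_overlap_pairs: list[tuple[str, str]] = field(default_factory=list)

    def distance(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.matrix[i, j])


MIN_SHARED_COLUMNS = 20


def p_distance(a: str, b: str) -> tuple[float, int]:
    """Mismatch fraction over shared non-gap columns; returns (p, n_shared)."""
    if len(a) != len(b):
        raise ValueError("sequences must lie on an identical column set")
    shared = [(x, y) for x, y in zip(a.upper(), b.upper())
              if x not in "-." and y not in "-."]
    if not shared:
        raise UndefinedDistanceError("no shared non-gap columns")
    mism = sum(x != y for x, y in shared)
    return mism / len(shared), len(shared)


def pairwise_distances(
    rows: list[tuple[str, str]], model: str = "p"
) -> DistanceMatrix:
    """All pairwise distances of aligned sequences.

    ``model`` is "p" (raw mismatch fraction) or "poisson"
    (-ln(1-p), the multiple-hit correction; may violate the triangle
    inequality).  Pairs sharing fewer than 20 columns are flagged.
    """
    if model not in ("p", "poisson"):
        raise ValueError(f"unknown distance model {model!r}")
    ids = [rid for rid, _ in rows]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    n = len(rows)
    mat = np.zeros((n, n))
    low: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            p, shared = p_distance(rows[i][1], rows[j][1])
            if shared < MIN_SHARED_COLUMNS:
                low.append((ids[i], ids[j]))
            d = p if model == "p" else -np.log(max(1.0 - p, 1e-10))
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(ids=ids, matrix=mat, model=model, low_overlap_pairs=low)


def nj_tree(dm: DistanceMatrix) -> str:
    """Neighbor-joining tree of a distance matrix, serialized as Newick.

    Standard agglomeration (exact on additive matrices); branch lengths
    retained, no internal node labels.
    """
    if len(dm.ids) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    tree = skbio.tree.nj(_SkbioDM(dm.matrix, ids=dm.ids))
    return str(tree).strip()


# ---------------------------------------------------------------------------
# family assignment

FAMILY_LABELS = ["Ia", "Ib", "II", "III", "IV", "V", "VIa", "VIb", "VIIa/b",
                 "VIII", "IX", "X", "XI", "XII", "XIII", "XV"]

#: motifs diagnostic of a family (used to corroborate narrow-margin calls)
DEFAULT_MOTIF_FAMILY_MAP = {"Motif40": "X"}


@dataclass
class FamilyAssignment:
    target_id: str
    family: str
    nearest_reference: str
    distance: float
    margin: float
    motif_support: list[str]
    ambiguous: bool


def assign_family(
    dom: CanonicalDomain,
    references: list[tuple[str, str, str]],
    motif_hits: list[MotifHit] | None = None,
    motif_family_map: dict[str, str] | None = None,
    margin_threshold: float = 0.05,
    motif_max_evalue: float = 1e-4,
) -> FamilyAssignment:
    """Nearest-reference family call with margin and motif corroboration.

    ``references`` rows are (family, id, aligned 57-column string).  The
    domain takes the family of its minimum-distance exemplar; distances
    tied to within 1e-12 break to the lexicographically smaller (family,
    id).  The call is ambiguous when the margin to the best other-family
    exemplar is below ``margin_threshold`` and no family-diagnostic motif
    (E-value <= ``motif_max_evalue``) corroborates it.
    """
    if not references:
        raise ValueError("family assignment needs at least one reference")
    query = dom.aligned_string()
    scored = []
    for family, rid, aligned in references:
        p, _ = p_distance(query, aligned)
        scored.append((round(p, 12), family, rid))
    scored.sort()
    best_p, best_family, best_id = scored[0]
    other = [s for s in scored if s[1] != best_family]
    margin = (other[0][0] - best_p) if other else float("inf")

    fam_map = DEFAULT_MOTIF_FAMILY_MAP if motif_family_map is None else motif_family_map
    support = sorted({
        h.motif for h in (motif_hits or [])
        if fam_map.get(h.motif) == best_family
        and h.evalue is not None and h.evalue <= motif_max_evalue
    })
    ambiguous = margin < margin_threshold and not support
    return FamilyAssignment(
        target_id=dom.target_id,
        family=best_family,
        nearest_reference=best_id,
        distance=float(best_p),
        margin=float(margin),
        motif_support=support,
        ambiguous=ambiguous,
    )
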