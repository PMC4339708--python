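"""Homeolog grouping, reciprocal-best-hit orthologs, and expression categories.

Soybean went through whole-genome duplications roughly 59 and 13 million
years ago, so most of its bHLH genes exist in homeologous copies that can
remain ~98% identical at the DNA level.  Homeolog groups are built here as
the transitive closure of validated gene pairs (sequence identity above a
threshold, optionally restricted to pairs inside the same duplication
block).  Cross-species orthologs are called from precomputed 12-column
similarity tables with the classic reciprocal-best-hit heuristic.
Expression profiles over a small tissue vocabulary are reduced to
categories (ubiquitous, nodule-preferential, seed-enriched, pod-wall-only,
tissue-restricted, not expressed) with explicit, configurable thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import pandas as pd


class InputError(ValueError):
    pass


class ParseError(ValueError):
    pass


class VocabularyError(ValueError):
    pass


# ---------------------------------------------------------------------------
# homeolog groups


@dataclass(frozen=True)
class HomeologEvidence:
    gene_a: str
    gene_b: str
    percent_identity: float
    block_id: str | None = None

    @property
    def same_duplication_block(self) -> bool:
        return self.block_id is not None and self.block_id != ""


@dataclass
class HomeologGroup:
    group_id: str
    members: tuple[str, ...]

    @property
    def copy_number(self) -> int:
        return len(self.members)


def read_homeolog_evidence(path: str | Path) -> list[HomeologEvidence]:
    """Read evidence TSV with columns gene_a, gene_b, pident, block_id."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["gene_a", "gene_b", "pident", "block_id"],
                     dtype={"gene_a": str, "gene_b": str, "block_id": str})
    rows = []
    for t in df.itertuples(index=False):
        block = None if pd.isna(t.block_id) else str(t.block_id)
        rows.append(HomeologEvidence(t.gene_a, t.gene_b, float(t.pident), block))
    return rows


def group_homeologs(
    genes: list[str],
    evidence: list[HomeologEvidence],
    min_identity: float = 90.0,
    require_block: bool = True,
) -> list[HomeologGroup]:
    """Union-find closure over qualifying evidence pairs.

    A pair qualifies when identity >= ``min_identity`` and, if
    ``require_block``, when it carries a duplication-block id.  Genes with
    no qualifying partner become singletons; the output partitions the
    gene set, sorted by their smallest member.
    """
    known = set(genes)
    unknown = sorted({g for ev in evidence for g in (ev.gene_a, ev.gene_b)} - known)
    if unknown:
        raise InputError(f"evidence names unknown genes: {', '.join(unknown)}")

    parent = {g: g for g in genes}

    def find(g: str) -> str:
        while parent[g] != g:
            parent[g] = parent[parent[g]]
            g = parent[g]
        return g

    for ev in evidence:
        if ev.percent_identity < min_identity:
            continue
        if require_block and not ev.same_duplication_block:
            continue
        ra, rb = find(ev.gene_a), find(ev.gene_b)
        if ra != rb:
            # deterministic union: smaller id becomes the root
            lo, hi = sorted((ra, rb))
            parent[hi] = lo

    clusters: dict[str, list[str]] = {}
    for g in genes:
        clusters.setdefault(find(g), []).append(g)
    groups = []
    for i, root in enumerate(sorted(clusters), start=1):
        groups.append(HomeologGroup(group_id=f"HG{i:04d}",
                                    members=tuple(sorted(clusters[root]))))
    return groups


def copy_number_histogram(groups: list[HomeologGroup]) -> dict:
    """Copy-number spectrum: per copy number, group and gene counts."""
    hist: dict[int, dict[str, int]] = {}
    for g in groups:
        cell = hist.setdefault(g.copy_number, {"groups": 0, "genes": 0})
        cell["groups"] += 1
        cell["genes"] += g.copy_number
    total_genes = sum(c["genes"] for c in hist.values())
    multi = sum(c["genes"] for k, c in hist.items() if k > 1)
    return {"histogram": dict(sorted(hist.items())),
            "total_genes": total_genes,
            "multi_copy_genes": multi}


# ---------------------------------------------------------------------------
# reciprocal best hits

BLAST_TAB_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
                     "qstart", "qend", "sstart", "send", "evalue", "bitscore"]


@dataclass(frozen=True)
class SimilarityHit:
    qseqid: str
    sseqid: str
    pident: float
    length: int
    evalue: float
    bitscore: float


def read_blast_tab(path: str | Path) -> list[SimilarityHit]:
    """Parse a 12-column tab-separated similarity table."""
    hits = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 12:
            raise ParseError(f"{path}:{lineno}: expected 12 columns, got {len(parts)}")
        try:
            hits.append(SimilarityHit(
                qseqid=parts[0], sseqid=parts[1], pident=float(parts[2]),
                length=int(parts[3]), evalue=float(parts[10]), bitscore=float(parts[11])))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return hits


def _best_hits(hits: list[SimilarityHit], max_evalue: float | None,
               min_identity: float | None) -> dict[str, str]:
    kept = [h for h in hits
            if (max_evalue is None or h.evalue < max_evalue)
            and (min_identity is None or h.pident > min_identity)]
    best: dict[str, SimilarityHit] = {}
    for h in kept:
        cur = best.get(h.qseqid)
        # bit score, then e-value, then lexicographic subject id
        if cur is None or (-h.bitscore, h.evalue, h.sseqid) < (-cur.bitscore, cur.evalue, cur.sseqid):
            best[h.qseqid] = h
    return {q: h.sseqid for q, h in best.items()}


def reciprocal_best_hits(
    ab: list[SimilarityHit],
    ba: list[SimilarityHit],
    max_evalue: float | None = 1e-25,
    min_identity: float | None = None,
) -> list[tuple[str, str]]:
    """Mutual-best ortholog pairs from two similarity tables.

    (x, y) is reported iff y is x's best surviving hit in ``ab`` and x is
    y's best in ``ba``.  Filters are strict (evalue < max_evalue, identity
    > min_identity); ties break by bit score, then e-value, then subject
    id.  Output is sorted and symmetric under swapping the two tables.
    """
    if not ab or not ba:
        raise InputError("both similarity tables must be non-empty")
    fwd = _best_hits(ab, max_evalue, min_identity)
    rev = _best_hits(ba, max_evalue, min_identity)
    pairs = [(x, y) for x, y in fwd.items() if rev.get(y) == x]
    return sorted(pairs)


# ---------------------------------------------------------------------------
# expression

TISSUES = ("root", "nodule", "leaf", "seed_early", "seed_mid", "seed_late", "pod_wall")
SEED_TISSUES = frozenset(t for t in TISSUES if t.startswith("seed"))
#: tissues counted as aerial for the nodule-preferential rule; root is
#: deliberately excluded (root and nodule expression commonly co-occur)
AERIAL_TISSUES = frozenset({"leaf", "pod_wall"} | SEED_TISSUES)


class ExpressionCategory(str, Enum):
    NOT_EXPRESSED = "NOT_EXPRESSED"
    UBIQUITOUS = "UBIQUITOUS"
    TISSUE_RESTRICTED = "TISSUE_RESTRICTED"
    NODULE_PREFERENTIAL = "NODULE_PREFERENTIAL"
    SEED_ENRICHED = "SEED_ENRICHED"
    POD_WALL_ONLY = "POD_WALL_ONLY"


@dataclass
class ExpressionProfile:
    gene_id: str
    abundance: dict[str, float]

    def __post_init__(self) -> None:
        bad = sorted(set(self.abundance) - set(TISSUES))
        if bad:
            raise VocabularyError(f"{self.gene_id}: unknown tissue labels {bad}")
        if any(v < 0 for v in self.abundance.values()):
            raise ValueError(f"{self.gene_id}: abundances must be nonnegative")


@dataclass
class ExpressionCall:
    gene_id: str
    expressed: bool
    tissues_detected: frozenset[str]
    category: ExpressionCategory


def read_expression_tsv(path: str | Path) -> list[ExpressionProfile]:
    """Read a genes x tissues TSV (first column gene id, header = tissue labels)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return [ExpressionProfile(gene_id=str(gid),
                              abundance={t: float(v) for t, v in row.items()})
            for gid, row in df.iterrows()]


def classify_expression(
    profile: ExpressionProfile,
    detect_threshold: float = 1.0,
    enrich_fold: float = 5.0,
) -> ExpressionCall:
    """Categorize one expression profile.

    Detection is abundance >= ``detect_threshold``.  Precedence:
    NOT_EXPRESSED > POD_WALL_ONLY > NODULE_PREFERENTIAL > SEED_ENRICHED
    (max seed >= ``enrich_fold`` x max non-seed, boundary inclusive) >
    UBIQUITOUS (root, leaf, and at least one seed stage detected) >
    TISSUE_RESTRICTED.
    """
    ab = profile.abundance
    detected = frozenset(t for t, v in ab.items() if v >= detect_threshold)

    def level(t: str) -> float:
        return ab.get(t, 0.0)

    max_aerial = max((level(t) for t in AERIAL_TISSUES), default=0.0)
    max_seed = max((level(t) for t in SEED_TISSUES), default=0.0)
    max_non_seed = max((v for t, v in ab.items() if t not in SEED_TISSUES), default=0.0)

    if not detected:
        cat = ExpressionCategory.NOT_EXPRESSED
    elif detected == {"pod_wall"}:
        cat = ExpressionCategory.POD_WALL_ONLY
    elif "nodule" in detected and max_aerial < detect_threshold:
        cat = ExpressionCategory.NODULE_PREFERENTIAL
    elif max_seed >= detect_threshold and max_seed >= enrich_fold * max_non_seed:
        cat = ExpressionCategory.SEED_ENRICHED
    elif {"root", "leaf"} <= detected and detected & SEED_TISSUES:
        cat = ExpressionCategory.UBIQUITOUS
    else:
        cat = ExpressionCategory.TISSUE_RESTRICTED
    return ExpressionCall(gene_id=profile.gene_id, expressed=bool(detected),
                          tissues_detected=detected, category=cat)


def expression_census(calls: list[ExpressionCall]) -> dict:
    """Counts per category plus the expressed total; order-invariant."""
    if not calls:
        raise ValueError("census needs at least one expression call")
    n = len(calls)
    counts = {cat.value: sum(c.category == cat for c in calls) for cat in ExpressionCategory}
    expressed = sum(c.expressed for c in calls)
    return {
        "n": n,
        "counts": counts,
        "expressed_total": expressed,
        "expressed_pct": round(100.0 * expressed / n, 1),
        "percentages": {k: round(100.0 * v / n, 1) for k, v in counts.items()},
    }
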