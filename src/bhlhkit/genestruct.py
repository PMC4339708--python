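"""Intron/exon structure of bHLH genes in canonical domain coordinates.

Most plant bHLH genes carry up to three anciently conserved introns inside
the domain.  Each intron of a gene model is projected to the canonical
position of the codon immediately 5' of it (with the codon phase recorded
separately), and the resulting placements are matched against configured
canonical intron positions to label the gene's pattern: A (all three
conserved introns), B/C/E (two of the three), D (exactly one), F (a single
intron at an alternative site), G/H (a second conserved pair, or only its
first member), NONE (intron-free domain) or OTHER.

Genomic intervals are stored 0-based half-open internally; GFF3 input is
converted from its 1-based inclusive convention exactly once, at parse
time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .anatomy import CanonicalDomain


class GeneModelError(ValueError):
    """A gene model is structurally inconsistent."""


@dataclass
class GeneModel:
    """One protein-coding gene model.

    ``exons`` and ``cds`` are 0-based half-open genomic intervals sorted in
    transcription order (descending genomic coordinate on the minus
    strand); ``cds`` rows are (start, end, phase).
    """

    gene_id: str
    seq_id: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int, int]]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise GeneModelError(f"{self.gene_id}: strand must be + or -")
        for s, e in self.exons:
            if e <= s:
                raise GeneModelError(f"{self.gene_id}: empty or inverted exon [{s}, {e})")
        key = (lambda iv: iv[0]) if self.strand == "+" else (lambda iv: -iv[0])
        if self.exons != sorted(self.exons, key=key):
            raise GeneModelError(f"{self.gene_id}: exons not in transcription order")

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e, _ in self.cds)


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene models from GFF3 (gene/mRNA/exon/CDS; phase column honored).

    Coordinates are converted from GFF3's 1-based inclusive convention to
    0-based half-open here, and nowhere else.  One transcript per gene is
    assumed (the first mRNA of each gene).
    """
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True, keep_order=True,
                            merge_strategy="create_unique")
    models = []
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
        parent = mrnas[0] if mrnas else gene
        rev = gene.strand == "-"
        exons = sorted(((f.start - 1, f.end)
                        for f in db.children(parent, featuretype="exon")), reverse=rev)
        cds = sorted(((f.start - 1, f.end, 0 if f.frame == "." else int(f.frame))
                      for f in db.children(parent, featuretype="CDS")), reverse=rev)
        models.append(GeneModel(gene_id=gene.id, seq_id=gene.seqid, strand=gene.strand,
                                exons=exons, cds=cds))
    return sorted(models, key=lambda m: m.gene_id)


# ---------------------------------------------------------------------------
# intron projection


@dataclass(frozen=True)
class IntronPlacement:
    """One intron in domain coordinates.

    ``domain_position`` is the canonical position of the codon immediately
    5' of the intron (for phase 1/2 introns, the interrupted codon);
    ``codon_phase`` counts coding bases of that codon upstream of the
    intron (0 = between codons).
    """

    intron_index: int
    domain_position: int
    codon_phase: int


def project_introns(
    gm: GeneModel,
    dom: CanonicalDomain,
    protein_length: int | None = None,
) -> list[IntronPlacement]:
    """Place a gene model's introns onto the canonical domain coordinates.

    Walks the CDS in transcription order (strand-aware, so the result is
    identical for a gene and its reverse-complement mirror); introns whose
    flanking codon falls outside the detected domain are excluded.
    """
    if gm.cds_length % 3 != 0:
        raise GeneModelError(f"{gm.gene_id}: CDS length {gm.cds_length} not a multiple of 3")
    n_codons = gm.cds_length // 3
    if protein_length is not None and n_codons not in (protein_length, protein_length + 1):
        raise GeneModelError(
            f"{gm.gene_id}: CDS codes for {n_codons} codons but the protein has "
            f"{protein_length} residues")

    # canonical position by 0-based protein index
    canon_by_protein = {idx: pos for pos, idx in dom.protein_positions.items()}

    placements: list[IntronPlacement] = []
    bases = 0
    for i, (s, e, _ph) in enumerate(gm.cds[:-1]):
        bases += e - s
        phase = bases % 3
        codon_1based = bases // 3 if phase == 0 else bases // 3 + 1
        pos = canon_by_protein.get(codon_1based - 1)
        if pos is not None:
            placements.append(IntronPlacement(intron_index=i, domain_position=pos,
                                              codon_phase=phase))
    return placements


# ---------------------------------------------------------------------------
# pattern classification


@dataclass(frozen=True)
class IntronPatternDef:
    """Configured canonical intron sites (domain coordinates).

    ``canonical_positions`` are the three conserved sites (c1 < c2 < c3);
    ``alt_position`` defines pattern F; ``g_positions`` the pattern-G pair
    (pattern H = first of the pair only).  An intron matches a site when
    its domain position is within ``tolerance`` columns.  The letters are
    presentation labels over the authoritative matched-site sets; which
    two-site subset is called B, C or E is given by ``subset_labels``.
    """

    canonical_positions: tuple[int, int, int] = (16, 25, 48)
    alt_position: int = 5
    g_positions: tuple[int, int] = (20, 52)
    tolerance: int = 2
    subset_labels: tuple[tuple[frozenset[int], str], ...] = ()

    def __post_init__(self) -> None:
        c1, c2, c3 = self.canonical_positions
        sites = {c1, c2, c3, self.alt_position, *self.g_positions}
        if len(sites) != 6:
            raise ValueError("intron pattern sites must be distinct")
        if not (c1 < c2 < c3):
            raise ValueError("canonical positions must be increasing")
        if self.tolerance < 0:
            raise ValueError("tolerance must be nonnegative")
        if not self.subset_labels:
            object.__setattr__(self, "subset_labels", (
                (frozenset({c1, c2}), "B"),
                (frozenset({c1, c3}), "C"),
                (frozenset({c2, c3}), "E"),
            ))


DEFAULT_PATTERN_DEF = IntronPatternDef()

PATTERN_LABELS = ["A", "B", "C", "D", "E", "F", "G", "H", "NONE", "OTHER"]


@dataclass
class IntronPatternCall:
    gene_id: str
    placements: list[IntronPlacement]
    pattern: str
    matched_canonicals: frozenset[int] = field(default_factory=frozenset)


def classify_pattern(
    gene_id: str,
    placements: list[IntronPlacement],
    defs: IntronPatternDef = DEFAULT_PATTERN_DEF,
) -> IntronPatternCall:
    """Label the intron pattern of one gene from its in-domain placements."""

    def near(pos: int, site: int) -> bool:
        return abs(pos - site) <= defs.tolerance

    c1, c2, c3 = defs.canonical_positions
    g1, g2 = defs.g_positions
    matched: set[int] = set()
    extras: list[IntronPlacement] = []
    for pl in placements:
        site = next((c for c in (c1, c2, c3) if near(pl.domain_position, c)), None)
        if site is not None:
            matched.add(site)
        else:
            extras.append(pl)

    n = len(placements)
    if n == 0:
        pattern = "NONE"
    elif not extras and matched == {c1, c2, c3} and n == 3:
        pattern = "A"
    elif not extras and len(matched) == 2 and n == 2:
        pattern = dict(defs.subset_labels).get(frozenset(matched), "OTHER")
    elif not extras and len(matched) == 1 and n == 1:
        pattern = "D"
    elif not matched and n == 1 and near(placements[0].domain_position, defs.alt_position):
        pattern = "F"
    elif (not matched and n == 2
          and any(near(p.domain_position, g1) for p in placements)
          and any(near(p.domain_position, g2) for p in placements)):
        pattern = "G"
    elif not matched and n == 1 and near(placements[0].domain_position, g1):
        pattern = "H"
    else:
        pattern = "OTHER"
    return IntronPatternCall(gene_id=gene_id, placements=list(placements),
                             pattern=pattern, matched_canonicals=frozenset(matched))


def pattern_census(calls: list[IntronPatternCall]) -> dict:
    """Count and percentage (1 decimal) per pattern label; order-invariant."""
    if not calls:
        raise ValueError("census needs at least one pattern call")
    n = len(calls)
    counts = {label: 0 for label in PATTERN_LABELS}
    for c in calls:
        counts[c.pattern] += 1
    return {
        "n": n,
        "counts": counts,
        "percentages": {label: round(100.0 * k / n, 1) for label, k in counts.items()},
    }
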