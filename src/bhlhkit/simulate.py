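"""Synthetic bHLH gene-family generator with a ground-truth manifest.

Emulates the inputs of a genome-wide bHLH survey so the whole pipeline is
testable without downloads: a proteome of bHLH proteins with planted
domains of known family and DNA-binding class plus domain-free decoys,
gene models (GFF3 + CDS) with chosen intron patterns on both strands,
homeolog groups at a controlled CDS identity, and an expression matrix
with planted tissue categories.  Every planted attribute is recorded in a
JSON manifest ("bhlh-truth/1") keyed by gene id.

The family structure is a star: one master domain consensus, from which
each family's consensus diverges at a fixed rate, so that family exemplars
are mutually distant while genes stay close to their own family.  Default
mixture weights for binding classes, intron patterns, copy numbers and
expression categories follow the proportions reported for the soybean
family, so synthetic censuses resemble the real ones.  All randomness
flows through one seeded generator; outputs are byte-identical across
runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .anatomy import DEFAULT_SCHEME, CanonicalScheme
from .binding import FAMILY_LABELS, BindingCategory
from .dupexpr import SEED_TISSUES, TISSUES, ExpressionCategory
from .genestruct import DEFAULT_PATTERN_DEF, IntronPatternDef
from .hmm import AMINO_ACIDS, MotifAlignment

MANIFEST_SCHEMA = "bhlh-truth/1"

MOTIF40_CONSENSUS = "GLCLVPVSCTQQVGSENGADYWAPAYGGG"
MOTIF40_FAMILY = "X"

BASIC = "RKH"
NONBASIC = "".join(a for a in AMINO_ACIDS if a not in BASIC)
HYDROPHOBIC_ANCHORS = {23: "L", 45: "ILV", 52: "ILV", 55: "L"}
RULE_POSITIONS = (5, 9, 12, 13)

_CODONS = {aa: sorted(c for c, a in standard_dna_table.forward_table.items() if a == aa)
           for aa in AMINO_ACIDS}


class ConfigError(ValueError):
    pass


def _normalize(mix: dict) -> dict:
    total = sum(mix.values())
    if total <= 0:
        raise ConfigError("mixture weights must be positive")
    return {k: v / total for k, v in mix.items()}


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic bundle.

    Mixture defaults follow the reported soybean proportions: ~58% G-box
    candidates and ~21% non-binding HLHs; intron patterns dominated by A
    (31%) and D (43%) with 12% intron-free domains; a copy-number
    spectrum of {1, 2, 3, 4, 6} homeologous copies; and 88% of genes with
    detectable expression, 47% of those ubiquitous.
    """

    seed: int
    n_bhlh: int = 200
    n_decoys: int = 300
    family_labels: tuple[str, ...] = tuple(FAMILY_LABELS)
    family_divergence: float = 0.30
    mutation_rate: float = 0.05
    refs_per_family: int = 3
    binding_mix: dict = field(default_factory=lambda: {
        "G_BOX_BINDER": 0.583, "E_BOX_BINDER": 0.182,
        "NON_EBOX_BINDER": 0.025, "NON_BINDING_HLH": 0.210})
    intron_mix: dict = field(default_factory=lambda: {
        "A": 0.310, "B": 0.013, "C": 0.013, "D": 0.431, "E": 0.014,
        "F": 0.030, "G": 0.025, "H": 0.022, "NONE": 0.122, "OTHER": 0.009})
    copy_spectrum: dict = field(default_factory=lambda: {
        1: 106, 2: 135, 3: 21, 4: 52, 6: 6})  # gene-count weights
    target_identity: float = 96.0
    flank_mutation_rate: float = 0.03
    expression_mix: dict = field(default_factory=lambda: {
        "NOT_EXPRESSED": 0.119, "UBIQUITOUS": 0.414, "TISSUE_RESTRICTED": 0.395,
        "NODULE_PREFERENTIAL": 0.016, "SEED_ENRICHED": 0.047, "POD_WALL_ONLY": 0.009})
    expression_noise_sd: float = 0.10
    n_internal_stop: int = 5
    n_truncated: int = 5
    other_intron_position: int = 44

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("a seed is mandatory")
        for name in ("binding_mix", "intron_mix", "expression_mix"):
            setattr(self, name, _normalize(getattr(self, name)))
        for cat in self.binding_mix:
            BindingCategory(cat)
        for cat in self.expression_mix:
            ExpressionCategory(cat)


# ---------------------------------------------------------------------------
# family consensus structure


@dataclass
class FamilySet:
    """Master consensus plus per-family diverged consensi on the 57-column scheme."""

    labels: tuple[str, ...]
    master: str
    loop_lengths: dict[str, int]
    consensus: dict[str, str]  # ungapped family consensus (basic+helix1+loop+helix2)
    scheme: CanonicalScheme = DEFAULT_SCHEME

    @classmethod
    def from_seed(cls, seed: int, labels: tuple[str, ...] = tuple(FAMILY_LABELS),
                  divergence: float = 0.30,
                  scheme: CanonicalScheme = DEFAULT_SCHEME) -> "FamilySet":
        rng = np.random.default_rng(seed)
        aas = list(AMINO_ACIDS)
        n = scheme.n_positions
        master = [str(rng.choice(aas)) for _ in range(n)]
        for pos, allowed in HYDROPHOBIC_ANCHORS.items():
            master[pos - 1] = str(rng.choice(list(allowed)))
        # the ancestral domain is a binder: conserved rule residues plus a
        # basic-leaning basic region (most family members keep these)
        for pos, res in ((5, "H"), (9, "E"), (12, "R"), (13, "R"),
                         (2, "R"), (7, "K"), (10, "R")):
            master[pos - 1] = res
        loop_a, loop_b = scheme.loop_span
        loops, cons = {}, {}
        for fam in labels:
            ll = int(rng.integers(scheme.loop_length_range[0],
                                  scheme.loop_length_range[1] + 1))
            loops[fam] = ll
            seq = []
            for p in range(1, n + 1):
                if loop_a <= p <= loop_b and p - loop_a >= ll:
                    continue  # this family's loop is shorter than the column span
                r = master[p - 1]
                if (p not in HYDROPHOBIC_ANCHORS and p not in RULE_POSITIONS
                        and rng.random() < divergence):
                    r = str(rng.choice([a for a in aas if a != r]))
                seq.append(r)
            cons[fam] = "".join(seq)
        return cls(labels=labels, master="".join(master), loop_lengths=loops,
                   consensus=cons, scheme=scheme)

    def aligned_consensus(self, fam: str) -> str:
        """Family consensus padded to the full 57 columns (gaps in the loop tail)."""
        seq = self.consensus[fam]
        ll = self.loop_lengths[fam]
        a = self.scheme.loop_span[0] - 1  # residues before the loop
        pad = (self.scheme.loop_span[1] - self.scheme.loop_span[0] + 1) - ll
        return seq[: a + ll] + "-" * pad + seq[a + ll:]

    def protein_offset(self, fam: str, canonical_pos: int) -> int:
        """0-based offset of a canonical position within the family's domain string."""
        loop_a, loop_b = self.scheme.loop_span
        ll = self.loop_lengths[fam]
        if canonical_pos < loop_a:
            return canonical_pos - 1
        if canonical_pos <= loop_b:
            if canonical_pos - loop_a >= ll:
                raise ConfigError(f"canonical position {canonical_pos} lies beyond "
                                  f"family {fam}'s loop of length {ll}")
            return canonical_pos - 1
        return (loop_a - 1) + ll + (canonical_pos - loop_b - 1)


def _enforce_category(dom: list[str], category: BindingCategory, rng) -> None:
    """Set rule positions 5/9/12/13 and the basic-residue count in place.

    Binders are planted with 7 basic residues and non-binders with at most
    3, leaving headroom so point mutations rarely cross the 5-vs-4
    boundary.
    """
    def setpos(p: int, choices: str) -> None:
        dom[p - 1] = str(rng.choice(list(choices)))

    if category == BindingCategory.G_BOX_BINDER:
        setpos(5, "HK"); setpos(9, "E"); setpos(12, "R"); setpos(13, "R")
        target = (7, "ge")
    elif category == BindingCategory.E_BOX_BINDER:
        setpos(5, "".join(a for a in NONBASIC if a != "E")); setpos(9, "E"); setpos(12, "R")
        target = (7, "ge")
    elif category == BindingCategory.NON_EBOX_BINDER:
        setpos(9, "".join(a for a in AMINO_ACIDS if a != "E"))
        target = (7, "ge")
    elif category == BindingCategory.NON_BINDING_HLH:
        setpos(5, "".join(a for a in NONBASIC if a != "E"))
        setpos(9, "".join(a for a in NONBASIC if a != "E"))
        setpos(12, NONBASIC); setpos(13, NONBASIC)
        target = (3, "le")
    else:  # pragma: no cover - enum is closed
        raise ConfigError(f"contradictory or unknown binding request {category!r}")

    want, sense = target
    free = [p for p in range(1, 14) if p not in RULE_POSITIONS]
    count = sum(dom[p - 1] in BASIC for p in range(1, 14))
    order = list(rng.permutation(free))
    if sense == "ge":
        for p in order:
            if count >= want:
                break
            if dom[p - 1] not in BASIC:
                dom[p - 1] = str(rng.choice(list("RK")))
                count += 1
    else:
        for p in order:
            if count <= want:
                break
            if dom[p - 1] in BASIC:
                dom[p - 1] = str(rng.choice([a for a in NONBASIC if a != "E"]))
                count -= 1


def generate_domain_from(famset: FamilySet, family: str, category: BindingCategory,
                         mutation_rate: float, rng) -> str:
    """One domain: family consensus, category rules enforced, then point
    mutations at non-rule positions and a 0.97-probability hydrophobic
    draw at the anchor positions."""
    if family not in famset.consensus:
        raise ConfigError(f"unknown family {family!r}")
    scheme = famset.scheme
    ll = famset.loop_lengths[family]
    loop_a, loop_b = scheme.loop_span
    dom = list(famset.consensus[family])
    positions = [p for p in range(1, scheme.n_positions + 1)
                 if not (loop_a <= p <= loop_b and p - loop_a >= ll)]
    off = {p: famset.protein_offset(family, p) for p in positions}
    # category rules live in the basic region (positions 1-13 map 1:1)
    basic_list = [dom[off[p]] for p in range(1, 14)]
    _enforce_category(basic_list, category, rng)
    for p in range(1, 14):
        dom[off[p]] = basic_list[p - 1]
    # point mutations at non-rule positions
    for p in positions:
        if p in RULE_POSITIONS:
            continue
        if rng.random() < mutation_rate:
            o = off[p]
            dom[o] = str(rng.choice([a for a in AMINO_ACIDS if a != dom[o]]))
    # hydrophobic anchor draw
    for p, allowed in HYDROPHOBIC_ANCHORS.items():
        if rng.random() < 0.97:
            dom[off[p]] = str(rng.choice(list(allowed)))
    return "".join(dom)


def generate_domain(family: str, binding_category: str, mutation_rate: float,
                    seed: int) -> str:
    """Standalone domain draw (builds a fresh family set from ``seed``)."""
    famset = FamilySet.from_seed(seed)
    rng = np.random.default_rng(seed + 1)
    return generate_domain_from(famset, family, BindingCategory(binding_category),
                                mutation_rate, rng)


# ---------------------------------------------------------------------------
# proteome + manifest


@dataclass
class SyntheticGene:
    gene_id: str
    protein: str
    fate: str  # clean / internal_stop / truncated_domain / decoy
    family: str | None = None
    binding_category: str | None = None
    intron_pattern: str | None = None
    homeolog_group: str | None = None
    expression_category: str | None = None
    domain_start: int | None = None  # 0-based protein index
    loop_length: int | None = None
    cds: str | None = None
    intron_after_bases: list[int] = field(default_factory=list)
    intron_domain_positions: list[int] = field(default_factory=list)
    strand: str = "+"


@dataclass
class SyntheticBundle:
    cfg: GeneratorConfig
    famset: FamilySet
    genes: list[SyntheticGene]
    training_alignment: MotifAlignment
    family_references: list[tuple[str, str, str]]  # (family, id, aligned57)
    motif_alignments: list[MotifAlignment]
    evidence_rows: list[tuple[str, str, float, str]]
    expression: dict[str, dict[str, float]]

    def manifest(self) -> dict:
        per_gene = {}
        for g in self.genes:
            if g.fate == "decoy":
                per_gene[g.gene_id] = {"curation_fate": "decoy"}
                continue
            per_gene[g.gene_id] = {
                "curation_fate": g.fate,
                "family": g.family,
                "binding_category": g.binding_category,
                "intron_pattern": g.intron_pattern,
                "homeolog_group": g.homeolog_group,
                "expression_category": g.expression_category,
                "domain_start": g.domain_start,
                "loop_length": g.loop_length,
            }
        return {"schema": MANIFEST_SCHEMA, "seed": self.cfg.seed, "genes": per_gene}


def _random_flank(rng, lo: int, hi: int) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "".join(rng.choice(list(AMINO_ACIDS), size=n))


def _mutate_protein(seq: str, rate: float, rng, protect: set[int]) -> str:
    out = list(seq)
    for i in range(len(out)):
        if i in protect or out[i] == "*":
            continue
        if rng.random() < rate:
            out[i] = str(rng.choice([a for a in AMINO_ACIDS if a != out[i]]))
    return "".join(out)


def _draw(rng, mix: dict):
    keys = sorted(mix)
    probs = np.array([mix[k] for k in keys])
    return keys[int(rng.choice(len(keys), p=probs / probs.sum()))]


def _group_sizes(rng, spectrum: dict[int, float], n_genes: int) -> list[int]:
    # convert gene-count weights to group weights, then sample sizes
    sizes = sorted(spectrum)
    gw = np.array([spectrum[s] / s for s in sizes], dtype=float)
    gw /= gw.sum()
    out: list[int] = []
    remaining = n_genes
    while remaining > 0:
        s = sizes[int(rng.choice(len(sizes), p=gw))]
        out.append(min(s, remaining))
        remaining -= out[-1]
    return out


def generate_proteome(cfg: GeneratorConfig) -> SyntheticBundle:
    """Generate the full synthetic bundle (proteins, truth, references, motifs).

    Homeolog group members share their founder's family, binding class and
    intron pattern (the domain is identical within a group; flanks drift),
    which mirrors the strong conservation of recently duplicated copies.
    """
    rng = np.random.default_rng(cfg.seed)
    famset = FamilySet.from_seed(int(rng.integers(2**31)), cfg.family_labels,
                                 cfg.family_divergence)

    # reference material
    references = [(fam, f"ref_{fam.replace('/', '_')}", famset.aligned_consensus(fam))
                  for fam in cfg.family_labels]
    # training rows are category-enforced family members (not bare consensi),
    # so basic-region emission columns reflect the real binder/non-binder
    # mixture and atypical domains still align end to end
    training_rows = []
    for fam in cfg.family_labels:
        ll = famset.loop_lengths[fam]
        a = famset.scheme.loop_span[0] - 1
        pad = 14 - ll
        for r in range(cfg.refs_per_family):
            cat = BindingCategory(_draw(rng, cfg.binding_mix))
            row = generate_domain_from(famset, fam, cat, 0.05, rng)
            padded = row[: a + ll] + "-" * pad + row[a + ll:]
            training_rows.append((f"trn_{fam.replace('/', '_')}_{r}", padded))
    training = MotifAlignment("HLH_domain", training_rows)

    motif_rows = [("motif40_consensus", MOTIF40_CONSENSUS)]
    for r in range(2):
        motif_rows.append((f"motif40_var{r}", _mutate_protein(MOTIF40_CONSENSUS, 0.05, rng, set())))
    motif40 = MotifAlignment("Motif40", motif_rows)

    # homeolog group structure over the bHLH genes
    sizes = _group_sizes(rng, {int(k): float(v) for k, v in cfg.copy_spectrum.items()},
                         cfg.n_bhlh)
    genes: list[SyntheticGene] = []
    gid_counter = 0

    for gi, size in enumerate(sizes, start=1):
        group_id = f"HG{gi:04d}"
        family = str(_draw(rng, {f: 1.0 for f in cfg.family_labels}))
        category = BindingCategory(_draw(rng, cfg.binding_mix))
        pattern = str(_draw(rng, cfg.intron_mix))
        domain = generate_domain_from(famset, family, category, cfg.mutation_rate, rng)
        flank_n = _random_flank(rng, 30, 120)
        flank_c = _random_flank(rng, 40, 180)
        if family == MOTIF40_FAMILY:
            ins = int(rng.integers(5, max(6, len(flank_c) - len(MOTIF40_CONSENSUS) - 5)))
            motif = _mutate_protein(MOTIF40_CONSENSUS, 0.03, rng, set())
            flank_c = flank_c[:ins] + motif + flank_c[ins:]
        founder_protein = flank_n + domain + flank_c
        for m in range(size):
            gid_counter += 1
            gid = f"SYNBHLH{gid_counter:04d}"
            if m == 0:
                protein = founder_protein
            else:
                # flank drift only; the domain itself is conserved in-copy
                protect = set(range(len(flank_n), len(flank_n) + len(domain)))
                protein = _mutate_protein(founder_protein, cfg.flank_mutation_rate,
                                          rng, protect)
            g = SyntheticGene(
                gene_id=gid, protein=protein, fate="clean", family=family,
                binding_category=category.value, intron_pattern=pattern,
                homeolog_group=group_id,
                expression_category=str(_draw(rng, cfg.expression_mix)),
                domain_start=len(flank_n), loop_length=famset.loop_lengths[family])
            genes.append(g)

    # planted curation failures: internal stops and truncated domains
    clean = list(genes)
    pick = rng.permutation(len(clean))
    stop_idx = set(int(i) for i in pick[: cfg.n_internal_stop])
    trunc_idx = set(int(i) for i in pick[cfg.n_internal_stop:
                                         cfg.n_internal_stop + cfg.n_truncated])
    for i in stop_idx:
        g = clean[i]
        # stop marker in the C-terminal flank, past the domain
        dom_end = g.domain_start + len(famset.consensus[g.family])
        pos = int(rng.integers(dom_end + 3, len(g.protein) - 2))
        g.protein = g.protein[:pos] + "*" + g.protein[pos + 1:]
        g.fate = "internal_stop"
    for i in trunc_idx:
        g = clean[i]
        # cut at the end of helix1: the loop and second helix are missing,
        # so curation must flag the domain as incomplete
        keep = g.domain_start + 28
        g.protein = g.protein[:keep]
        g.fate = "truncated_domain"
        g.intron_pattern = "NONE"

    # decoys
    for d in range(1, cfg.n_decoys + 1):
        genes.append(SyntheticGene(gene_id=f"SYNDECOY{d:04d}",
                                   protein=_random_flank(rng, 100, 500), fate="decoy"))

    genes.sort(key=lambda g: g.gene_id)

    bundle = SyntheticBundle(cfg=cfg, famset=famset, genes=genes,
                             training_alignment=training,
                             family_references=references,
                             motif_alignments=[motif40],
                             evidence_rows=[], expression={})
    _generate_gene_models(bundle, rng)
    _generate_homeologs_and_expression(bundle, rng)
    return bundle


# ---------------------------------------------------------------------------
# gene models


def _pattern_sites(pattern: str, defs: IntronPatternDef, other_pos: int, rng) -> list[int]:
    c1, c2, c3 = defs.canonical_positions
    g1, g2 = defs.g_positions
    table = {"A": [c1, c2, c3], "B": [c1, c2], "C": [c1, c3], "E": [c2, c3],
             "F": [defs.alt_position], "G": [g1, g2], "H": [g1],
             "NONE": [], "OTHER": [other_pos]}
    if pattern == "D":
        return [int(rng.choice([c1, c2, c3]))]
    if pattern not in table:
        raise ConfigError(f"unknown intron pattern {pattern!r}")
    return table[pattern]


def _reverse_translate(protein: str, rng, template: str | None = None) -> str:
    """Random codon choice per residue; reuse ``template`` codons where the
    residue is unchanged (keeps homeolog copies close at the DNA level)."""
    codons = []
    for i, aa in enumerate(protein):
        if aa == "*":
            codons.append("TGA")
            continue
        if template is not None:
            tmpl = template[3 * i: 3 * i + 3]
            if len(tmpl) == 3 and str(Seq(tmpl).translate()) == aa:
                codons.append(tmpl)
                continue
        opts = _CODONS[aa]
        codons.append(opts[int(rng.integers(len(opts)))])
    return "".join(codons) + "TAA"


def _identity(a: str, b: str) -> float:
    n = min(len(a), len(b))
    return 100.0 * sum(a[i] == b[i] for i in range(n)) / n


def _tune_identity(cds: str, reference: str, target: float, rng) -> str:
    """Add synonymous substitutions until CDS identity to ``reference`` is
    within +-1% of ``target`` (substitutions only ever lower it)."""
    out = list(cds)
    n_codons = len(cds) // 3 - 1  # exclude the stop
    guard = 0
    while _identity("".join(out), reference) > target + 1.0 and guard < 10000:
        guard += 1
        ci = int(rng.integers(n_codons))
        codon = "".join(out[3 * ci: 3 * ci + 3])
        aa = str(Seq(codon).translate())
        if aa == "*" or len(_CODONS.get(aa, [])) < 2:
            continue
        alt = [c for c in _CODONS[aa] if c != codon]
        new = alt[int(rng.integers(len(alt)))]
        out[3 * ci: 3 * ci + 3] = list(new)
    return "".join(out)


def _generate_gene_models(bundle: SyntheticBundle, rng) -> None:
    """Attach CDS sequences and intron placements to every gene.

    Intron positions are planted exactly at the configured canonical sites
    (phase 0, after the codon of the flanking residue); minus-strand genes
    alternate with plus-strand ones so both orientations are exercised.
    """
    cfg, famset = bundle.cfg, bundle.famset
    defs = DEFAULT_PATTERN_DEF
    founder_cds: dict[str, str] = {}
    for idx, g in enumerate(sorted((g for g in bundle.genes if g.fate != "decoy"),
                                   key=lambda g: g.gene_id)):
        template = founder_cds.get(g.homeolog_group)
        cds = _reverse_translate(g.protein, rng, template=template)
        if template is None:
            founder_cds[g.homeolog_group] = cds
        else:
            cds = _tune_identity(cds, template, cfg.target_identity, rng)
        g.cds = cds
        g.strand = "+" if idx % 2 == 0 else "-"
        if g.fate == "truncated_domain":
            sites: list[int] = []
        else:
            sites = _pattern_sites(g.intron_pattern, defs, cfg.other_intron_position, rng)
        g.intron_domain_positions = sorted(sites)
        g.intron_after_bases = []
        for c in g.intron_domain_positions:
            p = g.domain_start + famset.protein_offset(g.family, c) + 1  # 1-based codon
            g.intron_after_bases.append(3 * p)
    for idx, g in enumerate(sorted((g for g in bundle.genes if g.fate == "decoy"),
                                   key=lambda g: g.gene_id)):
        g.cds = _reverse_translate(g.protein, rng)
        g.strand = "+" if idx % 2 == 0 else "-"


def _random_intron(rng) -> str:
    body = "".join(rng.choice(list("ACGT"), size=int(rng.integers(40, 200))))
    return "GT" + body + "AG"


def write_gff3_and_cds(bundle: SyntheticBundle, gff_path: Path, cds_path: Path) -> None:
    """Write mutually consistent GFF3 and spliced-CDS FASTA.

    Each gene sits on its own scaffold at offset 1000; minus-strand genes
    are laid out mirror-image (exon coordinates descending in
    transcription order in the GFF's ascending convention).
    """
    rng = np.random.default_rng(bundle.cfg.seed + 7919)
    gff = ["##gff-version 3"]
    fasta: list[str] = []
    for g in sorted(bundle.genes, key=lambda g: g.gene_id):
        segments: list[str] = []
        prev = 0
        for b in g.intron_after_bases:
            segments.append(g.cds[prev:b])
            prev = b
        segments.append(g.cds[prev:])
        introns = [_random_intron(rng) for _ in segments[:-1]]

        # transcription-order segment lengths -> genomic intervals
        piece_lens = []
        for i, seg in enumerate(segments):
            piece_lens.append(("cds", len(seg)))
            if i < len(introns):
                piece_lens.append(("intron", len(introns[i])))
        total = sum(n for _, n in piece_lens)
        offset = 1000  # 0-based genomic start of the transcript
        ivals = []  # transcription-order CDS intervals, 0-based half-open
        if g.strand == "+":
            pos = offset
            for kind, n in piece_lens:
                if kind == "cds":
                    ivals.append((pos, pos + n))
                pos += n
        else:
            pos = offset + total
            for kind, n in piece_lens:
                if kind == "cds":
                    ivals.append((pos - n, pos))
                pos -= n
        scaffold = f"scf_{g.gene_id}"
        gmin = min(s for s, _ in ivals)
        gmax = max(e for _, e in ivals)
        gff.append("\t".join([scaffold, "bhlhkit", "gene", str(gmin + 1), str(gmax),
                              ".", g.strand, ".", f"ID={g.gene_id}"]))
        gff.append("\t".join([scaffold, "bhlhkit", "mRNA", str(gmin + 1), str(gmax),
                              ".", g.strand, ".",
                              f"ID={g.gene_id}.t1;Parent={g.gene_id}"]))
        cum = 0
        for s, e in ivals:
            phase = (3 - cum % 3) % 3
            gff.append("\t".join([scaffold, "bhlhkit", "exon", str(s + 1), str(e),
                                  ".", g.strand, ".", f"Parent={g.gene_id}.t1"]))
            gff.append("\t".join([scaffold, "bhlhkit", "CDS", str(s + 1), str(e),
                                  ".", g.strand, str(phase),
                                  f"Parent={g.gene_id}.t1"]))
            cum += e - s
        fasta.append(_fasta_record(g.gene_id, g.cds))
    gff_path.write_text("\n".join(gff) + "\n")
    cds_path.write_text("".join(fasta))


# ---------------------------------------------------------------------------
# homeologs + expression


def _generate_homeologs_and_expression(bundle: SyntheticBundle, rng) -> None:
    cfg = bundle.cfg
    bhlh = [g for g in bundle.genes if g.fate != "decoy"]
    groups: dict[str, list[SyntheticGene]] = {}
    for g in bhlh:
        groups.setdefault(g.homeolog_group, []).append(g)

    rows: list[tuple[str, str, float, str]] = []
    for gid in sorted(groups):
        members = sorted(groups[gid], key=lambda g: g.gene_id)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i], members[j]
                ident = _identity(a.cds or "", b.cds or "") if a.cds and b.cds else 0.0
                rows.append((a.gene_id, b.gene_id, round(ident, 2), gid))
    # decoy negative evidence: distant cross-group pairs, no shared block
    ids = [g.gene_id for g in bhlh]
    for _ in range(20 if len(ids) >= 2 else 0):
        a, b = (ids[int(rng.integers(len(ids)))] for _ in range(2))
        lo, hi = sorted((a, b))
        if a == b or any(r[0] == lo and r[1] == hi for r in rows):
            continue
        rows.append((lo, hi, round(float(rng.uniform(40, 70)), 2), ""))
    bundle.evidence_rows = sorted(rows)

    # expression profiles
    S = 50.0
    sd = cfg.expression_noise_sd
    restricted_subsets = [("root", "leaf"), ("leaf",), ("root",)]
    for g in sorted(bhlh, key=lambda g: g.gene_id):
        cat = ExpressionCategory(g.expression_category)
        prof = {t: float(rng.uniform(0.0, 0.3)) for t in TISSUES}
        if cat == ExpressionCategory.UBIQUITOUS:
            prof = {t: float(S * rng.uniform(0.5, 1.5)) for t in TISSUES}
        elif cat == ExpressionCategory.NODULE_PREFERENTIAL:
            prof["nodule"] = float(S * rng.uniform(0.8, 1.2))
            prof["root"] = float(S * rng.uniform(0.2, 0.5))
        elif cat == ExpressionCategory.SEED_ENRICHED:
            for t in SEED_TISSUES:
                prof[t] = float(S * rng.uniform(0.8, 1.2))
            prof["root"] = float(rng.uniform(1.0, S / 15))
            prof["leaf"] = float(rng.uniform(1.0, S / 15))
        elif cat == ExpressionCategory.POD_WALL_ONLY:
            prof["pod_wall"] = float(S * rng.uniform(0.8, 1.2))
        elif cat == ExpressionCategory.TISSUE_RESTRICTED:
            subset = restricted_subsets[int(rng.integers(len(restricted_subsets)))]
            for t in subset:
                prof[t] = float(S * rng.uniform(0.5, 1.5))
        noisy = {t: max(0.0, v * (1.0 + sd * float(rng.standard_normal())))
                 for t, v in prof.items()}
        bundle.expression[g.gene_id] = noisy


# ---------------------------------------------------------------------------
# writers


def _fasta_record(rid: str, seq: str, width: int = 60) -> str:
    lines = [f">{rid}"]
    for i in range(0, len(seq), width):
        lines.append(seq[i:i + width])
    return "\n".join(lines) + "\n"


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the full bundle to ``outdir``; byte-identical for a given config."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "proteome": out / "proteome.faa",
        "cds": out / "cds.fna",
        "gff3": out / "genes.gff3",
        "training_alignment": out / "hlh_training_alignment.fasta",
        "family_references": out / "family_references.fasta",
        "motif40": out / "motif40_alignment.fasta",
        "evidence": out / "homeolog_evidence.tsv",
        "expression": out / "expression.tsv",
        "manifest": out / "manifest.json",
    }
    paths["proteome"].write_text("".join(
        _fasta_record(g.gene_id, g.protein)
        for g in sorted(bundle.genes, key=lambda g: g.gene_id)))
    write_gff3_and_cds(bundle, paths["gff3"], paths["cds"])
    paths["training_alignment"].write_text("".join(
        _fasta_record(rid, seq) for rid, seq in bundle.training_alignment.rows))
    paths["family_references"].write_text("".join(
        _fasta_record(f"{fam}|{rid}", aligned)
        for fam, rid, aligned in bundle.family_references))
    paths["motif40"].write_text("".join(
        _fasta_record(rid, seq) for rid, seq in bundle.motif_alignments[0].rows))
    paths["evidence"].write_text(
        "# gene_a\tgene_b\tpident\tblock_id\n" + "".join(
            f"{a}\t{b}\t{p:.2f}\t{blk}\n" for a, b, p, blk in bundle.evidence_rows))
    tissues = "\t".join(TISSUES)
    lines = [f"gene_id\t{tissues}"]
    for gid in sorted(bundle.expression):
        vals = "\t".join(f"{bundle.expression[gid][t]:.3f}" for t in TISSUES)
        lines.append(f"{gid}\t{vals}")
    paths["expression"].write_text("\n".join(lines) + "\n")
    paths["manifest"].write_text(json.dumps(bundle.manifest(), indent=1, sort_keys=True))
    return paths
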