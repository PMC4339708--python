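"""End-to-end bHLH annotation pipeline.

Composes the stages in survey order: build the domain model from a
training alignment, scan every protein, curate, map hits onto canonical
coordinates, classify DNA binding, scan secondary motifs, assign
subfamilies against reference exemplars, project gene-model introns,
group homeologs, categorize expression, and emit a per-gene ledger TSV
("bhlh-ledger/1") plus summary censuses and a neighbor-joining tree of
the detected domains.  Per-record failures are collected and logged, not
fatal; the ledger is a pure function of (inputs, config) and is sorted by
gene id, so repeated runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml
from Bio import SeqIO

from . import anatomy, binding, dupexpr, genestruct, hmm

log = logging.getLogger("bhlhkit")

LEDGER_SCHEMA = "bhlh-ledger/1"

LEDGER_COLUMNS = [
    "gene_id", "curation_passed", "curation_reasons", "domain_score", "domain_evalue",
    "env_start", "env_end", "loop_length", "basic_count", "hk5", "e9", "r12", "r13",
    "gbox_rule_raw", "binding_category", "family", "family_distance", "family_margin",
    "family_ambiguous", "motif_support", "intron_pattern", "matched_canonicals",
    "homeolog_group", "copy_number", "expression_category", "tissues_detected",
    "core11_mismatches", "defined19_mismatches",
]


@dataclass
class RunConfig:
    """All inputs and thresholds of one pipeline run.

    Threshold defaults equal the documented per-module defaults; the
    config is serialized verbatim into the output directory.
    """

    proteome: str
    training_alignment: str
    out_dir: str
    seed: int = 0
    gff3: str | None = None
    cds: str | None = None
    family_references: str | None = None
    motif_alignments: list[str] = field(default_factory=list)
    homeolog_evidence: str | None = None
    expression: str | None = None
    # thresholds (module defaults)
    match_threshold: float = 0.5
    max_domain_evalue: float = 1e-3
    calibration_length: int = 400
    calibration_shuffles: int = 200
    margin_threshold: float = 0.05
    motif_max_evalue: float = 1e-4
    min_identity: float = 90.0
    require_block: bool = True
    detect_threshold: float = 1.0
    enrich_fold: float = 5.0
    intron_tolerance: int = 2
    log_level: str = "info"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)


@dataclass
class GeneRecord:
    """Per-gene ledger row joining every stage's call."""

    gene_id: str
    verdict: anatomy.CurationVerdict | None = None
    hit: hmm.DomainHit | None = None
    domain: anatomy.CanonicalDomain | None = None
    binding_call: binding.BindingCall | None = None
    family: binding.FamilyAssignment | None = None
    intron_call: genestruct.IntronPatternCall | None = None
    homeolog_group: str | None = None
    copy_number: int | None = None
    expression_call: dupexpr.ExpressionCall | None = None
    motif_hits: list[hmm.MotifHit] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)


def scan_protein(model: hmm.ProfileHMM, protein: str, target_id: str) -> hmm.DomainHit | None:
    """Best domain hit in a protein that may contain stop markers.

    Each ``*``-free segment is searched separately and coordinates are
    shifted back onto the full sequence, so a premature stop never aborts
    the scan (curation flags it downstream).
    """
    best: hmm.DomainHit | None = None
    offset = 0
    for segment in protein.split("*"):
        if segment:
            h = hmm.viterbi_search(model, segment, target_id=target_id)
            if h is not None and (best is None or h.bit_score > best.bit_score):
                h.env_start += offset
                h.env_end += offset
                h.state_path = [(k, m, None if i is None else i + offset)
                                for k, m, i in h.state_path]
                best = h
        offset += len(segment) + 1
    return best


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def read_family_references(path: str | Path) -> list[tuple[str, str, str]]:
    """Aligned reference FASTA with headers ``FAMILY|id``."""
    refs = []
    for rid, seq in read_fasta(path):
        if "|" not in rid:
            raise ValueError(f"reference header {rid!r} lacks the FAMILY| prefix")
        fam, name = rid.split("|", 1)
        refs.append((fam, name, seq))
    return refs


def _fmt(value, nd: int = 2) -> str:
    if value is None:
        return "."
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return f"{value:.{nd}f}"
    return str(value)


def _flag(value: bool | None) -> str:
    return "." if value is None else ("1" if value else "0")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full annotation; returns the in-memory results.

    Writes to ``cfg.out_dir``: the ledger TSV, a summary report with the
    binding/intron/family/copy-number/expression censuses and conservation
    tiers, the domain NJ tree (Newick), the serialized run config, and the
    calibrated domain model.
    """
    logging.basicConfig(level=cfg.log_level.upper())
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.yaml").write_text(cfg.to_yaml())

    proteins = sorted(read_fasta(cfg.proteome))
    log.info("scanning %d proteins", len(proteins))

    training = _read_alignment(cfg.training_alignment, "HLH_domain")
    model = hmm.build_profile(training, match_threshold=cfg.match_threshold)
    m2c = [c + 1 for c in model.build_metadata["match_columns"]]
    cal = hmm.calibrate_evalues(model, length=cfg.calibration_length,
                                n_shuffles=cfg.calibration_shuffles, seed=cfg.seed)
    (out / "domain_model.json").write_text(model.to_json())

    motif_models, motif_cals = [], {}
    for i, mpath in enumerate(cfg.motif_alignments):
        maln = _read_alignment(mpath, Path(mpath).stem)
        mm = hmm.build_profile(maln, match_threshold=cfg.match_threshold)
        motif_models.append(mm)
        motif_cals[mm.name] = hmm.calibrate_evalues(
            mm, length=cfg.calibration_length,
            n_shuffles=cfg.calibration_shuffles, seed=cfg.seed + 1 + i)

    refs = read_family_references(cfg.family_references) if cfg.family_references else []
    table = anatomy.default_residue_table()

    gene_models = {m.gene_id: m for m in genestruct.read_gff3(cfg.gff3)} if cfg.gff3 else {}
    expr_profiles = ({p.gene_id: p for p in dupexpr.read_expression_tsv(cfg.expression)}
                     if cfg.expression else {})
    pattern_def = dataclasses.replace(genestruct.DEFAULT_PATTERN_DEF,
                                      tolerance=cfg.intron_tolerance)

    records: dict[str, GeneRecord] = {}
    for gene_id, protein in proteins:
        rec = GeneRecord(gene_id=gene_id)
        records[gene_id] = rec
        try:
            hit = scan_protein(model, protein, gene_id)
            if hit is not None:
                hit.evalue = cal.evalue(hit.bit_score)
                if hit.evalue > cfg.max_domain_evalue:
                    hit = None
            rec.hit = hit
            dom = None
            if hit is not None:
                dom = anatomy.map_to_canonical(hit, protein.replace("*", "X"),
                                               model_to_canonical=m2c)
                rec.domain = dom
            rec.verdict = anatomy.curate(protein, hit, dom, table)
            if dom is None:
                continue
            rec.binding_call = binding.classify_binding(dom)
            if motif_models:
                rec.motif_hits = hmm.scan_motifs(protein.replace("*", "X"), motif_models,
                                                 motif_cals, gene_id)
            if refs:
                rec.family = binding.assign_family(
                    dom, refs, rec.motif_hits,
                    margin_threshold=cfg.margin_threshold,
                    motif_max_evalue=cfg.motif_max_evalue)
            gm = gene_models.get(gene_id)
            if gm is not None and rec.verdict.passed:
                placements = genestruct.project_introns(gm, dom,
                                                        protein_length=len(protein))
                rec.intron_call = genestruct.classify_pattern(gene_id, placements,
                                                              pattern_def)
        except (hmm.AlphabetError, anatomy.MappingError,
                genestruct.GeneModelError, ValueError) as exc:
            rec.errors.append(str(exc))
            log.warning("stage error for %s: %s", gene_id, exc)

    # homeologs over all input genes
    if cfg.homeolog_evidence:
        evidence = dupexpr.read_homeolog_evidence(cfg.homeolog_evidence)
        # the partition covers every gene named in the evidence plus every
        # domain-bearing gene (which become singletons without evidence)
        evidence_genes = {g for e in evidence for g in (e.gene_a, e.gene_b)}
        domain_genes = {gid for gid, r in records.items() if r.domain is not None}
        grouped_ids = sorted(evidence_genes | domain_genes)
        groups = dupexpr.group_homeologs(grouped_ids, evidence,
                                         min_identity=cfg.min_identity,
                                         require_block=cfg.require_block)
        for grp in groups:
            for gid in grp.members:
                if gid in records:
                    records[gid].homeolog_group = grp.group_id
                    records[gid].copy_number = grp.copy_number
    else:
        groups = []

    for gid, prof in expr_profiles.items():
        if gid in records:
            records[gid].expression_call = dupexpr.classify_expression(
                prof, detect_threshold=cfg.detect_threshold, enrich_fold=cfg.enrich_fold)

    # censuses from detected, curation-passing domains
    passed = [r for r in records.values()
              if r.domain is not None and r.verdict is not None and r.verdict.passed]
    summary: dict = {"n_genes": len(records), "n_with_domain":
                     sum(r.domain is not None for r in records.values()),
                     "n_curation_passed": len(passed)}
    if passed:
        doms = [r.domain for r in passed]
        cons = anatomy.conservation_profile(doms)
        summary["conservation_tiers"] = {
            tier: sum(t == tier for t in cons.tiers.values())
            for tier in ("100%", ">=30%", "<30%", "gap")}
        summary["binding_census"] = binding.binding_census(
            [r.binding_call for r in passed if r.binding_call])
        intron_calls = [r.intron_call for r in passed if r.intron_call]
        if intron_calls:
            summary["intron_census"] = genestruct.pattern_census(intron_calls)
        fams = [r.family.family for r in passed if r.family]
        if fams:
            summary["family_sizes"] = {f: fams.count(f) for f in sorted(set(fams))}
        if groups:
            summary["copy_number"] = dupexpr.copy_number_histogram(groups)
        expr_calls = [r.expression_call for r in records.values() if r.expression_call]
        if expr_calls:
            summary["expression_census"] = dupexpr.expression_census(expr_calls)
        # NJ tree of passing domains (plus references for context)
        rows = [(r.gene_id, r.domain.aligned_string()) for r in passed]
        seen: dict[str, str] = {}
        for rid, s in rows:
            seen[rid] = s
        if len(seen) >= 3:
            dm = binding.pairwise_distances(sorted(seen.items()))
            (out / "domains.nwk").write_text(binding.nj_tree(dm) + "\n")

    _write_ledger(out / "ledger.tsv", records, cfg)
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    log.info("pipeline finished: %d genes, %d with domains",
             summary["n_genes"], summary["n_with_domain"])
    return {"records": records, "summary": summary, "groups": groups,
            "model": model, "calibration": cal}


def _read_alignment(path: str, name: str) -> hmm.MotifAlignment:
    from .io import read_alignment
    return read_alignment(path, name=name)


def _write_ledger(path: Path, records: dict[str, GeneRecord], cfg: RunConfig) -> None:
    lines = [f"# {LEDGER_SCHEMA} seed={cfg.seed} max_domain_evalue={cfg.max_domain_evalue} "
             f"min_identity={cfg.min_identity} detect_threshold={cfg.detect_threshold} "
             f"enrich_fold={cfg.enrich_fold} tolerance={cfg.intron_tolerance}",
             "\t".join(LEDGER_COLUMNS)]
    for gid in sorted(records):
        r = records[gid]
        b, f, ic, e = r.binding_call, r.family, r.intron_call, r.expression_call
        row = [
            gid,
            _fmt(r.verdict.passed) if r.verdict else ".",
            ",".join(sorted(r.verdict.reasons)) if r.verdict and r.verdict.reasons else ".",
            _fmt(r.hit.bit_score) if r.hit else ".",
            f"{r.hit.evalue:.3g}" if r.hit and r.hit.evalue is not None else ".",
            _fmt(r.hit.env_start) if r.hit else ".",
            _fmt(r.hit.env_end) if r.hit else ".",
            _fmt(r.domain.loop_length) if r.domain else ".",
            _fmt(b.basic_count) if b else ".",
            _flag(b.hk5) if b else ".", _flag(b.e9) if b else ".",
            _flag(b.r12) if b else ".", _flag(b.r13) if b else ".",
            _fmt(b.gbox_rule_raw) if b else ".",
            b.category.value if b else ".",
            f.family if f else ".",
            _fmt(f.distance, 4) if f else ".",
            (_fmt(f.margin, 4) if f.margin != float("inf") else "inf") if f else ".",
            _fmt(f.ambiguous) if f else ".",
            ",".join(f.motif_support) if f and f.motif_support else ".",
            ic.pattern if ic else ".",
            ",".join(str(c) for c in sorted(ic.matched_canonicals)) if ic and ic.matched_canonicals else ".",
            r.homeolog_group or ".",
            _fmt(r.copy_number) if r.copy_number else ".",
            e.category.value if e else ".",
            ",".join(sorted(e.tissues_detected)) if e and e.tissues_detected else ".",
            _fmt(r.verdict.core11_mismatches) if r.verdict and r.verdict.core11_mismatches is not None else ".",
            _fmt(r.verdict.defined19_mismatches) if r.verdict and r.verdict.defined19_mismatches is not None else ".",
        ]
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n")


def domain_alignment_report(path: str | Path) -> dict:
    """Conservation and binding statistics of a pre-aligned domain set.

    Reads a 57-column domain alignment (aligned FASTA or PHYLIP, e.g. a
    published full-family alignment), maps each row onto the canonical
    scheme, and returns the per-position conservation profile together
    with the binding census — the headline residue statistics of a family
    survey (fraction with E9, with the H/K5-E9-R13 motif, hydrophobic
    anchor conservation, and so on).
    """
    from .io import read_alignment

    aln = read_alignment(path)
    doms = [anatomy.CanonicalDomain.from_aligned(rid, seq) for rid, seq in aln.rows]
    cons = anatomy.conservation_profile(doms)
    calls = [binding.classify_binding(d) for d in doms]
    census = binding.binding_census(calls)
    anchors = {pos: {"consensus": cons.consensus[pos],
                     "frequency_pct": round(100 * max(cons.frequencies[pos].values(), default=0.0), 1),
                     "ilv_pct": round(100 * sum(cons.frequencies[pos].get(a, 0.0)
                                                for a in "ILV"), 1)}
               for pos in (23, 45, 52, 55)}
    return {"n_domains": len(doms), "binding_census": census,
            "hydrophobic_anchors": anchors,
            "tiers": {t: sum(v == t for v in cons.tiers.values())
                      for t in ("100%", ">=30%", "<30%", "gap")}}


# ---------------------------------------------------------------------------
# input validation


def validate_inputs(cfg: RunConfig) -> list[str]:
    """Structural checks of the input files; returns violations, mutates nothing."""
    violations: list[str] = []

    def check_fasta(path: str, label: str) -> dict[str, str]:
        seqs: dict[str, str] = {}
        try:
            for rid, seq in read_fasta(path):
                if rid in seqs:
                    violations.append(f"{label}: duplicate record id {rid!r}")
                seqs[rid] = seq
                if not seq:
                    violations.append(f"{label}: empty sequence for {rid!r}")
        except (OSError, ValueError) as exc:
            violations.append(f"{label}: unreadable ({exc})")
        return seqs

    prot = check_fasta(cfg.proteome, "proteome")
    cds = check_fasta(cfg.cds, "cds") if cfg.cds else {}
    for gid, seq in cds.items():
        if len(seq) % 3 != 0:
            violations.append(f"cds: {gid} length {len(seq)} not a multiple of 3")
        elif gid in prot:
            n_codons = len(seq) // 3
            plen = len(prot[gid])
            if n_codons not in (plen, plen + 1):
                violations.append(
                    f"cds/proteome: {gid} CDS codes {n_codons} codons but protein "
                    f"has {plen} residues")
    if cfg.gff3:
        for lineno, line in enumerate(Path(cfg.gff3).read_text().splitlines(), start=1):
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                violations.append(f"gff3 line {lineno}: {len(parts)} columns, expected 9")
                continue
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError:
                violations.append(f"gff3 line {lineno}: non-numeric coordinates")
                continue
            if end < start:
                violations.append(f"gff3 line {lineno}: end {end} < start {start}")
            if parts[6] not in "+-.":
                violations.append(f"gff3 line {lineno}: bad strand {parts[6]!r}")
    if cfg.homeolog_evidence:
        try:
            dupexpr.read_homeolog_evidence(cfg.homeolog_evidence)
        except (OSError, ValueError) as exc:
            violations.append(f"homeolog_evidence: {exc}")
    if cfg.expression:
        try:
            dupexpr.read_expression_tsv(cfg.expression)
        except (OSError, ValueError, dupexpr.VocabularyError) as exc:
            violations.append(f"expression: {exc}")
    return violations
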