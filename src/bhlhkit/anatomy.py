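"""Canonical bHLH domain coordinates, conservation, and curation.

The bHLH domain is described on a fixed coordinate scheme: a 13-residue
N-terminal basic region (positions 1-13, where the DNA-contact rules
live), a first helix of 15 residues (14-28), a loop of 5-14 residues
occupying columns 29-42 (left-aligned, gap-padded), and a second helix of
15 residues (43-57).  Every detected domain is projected onto these 57
columns so that residue rules ("E at position 9", "L at position 23", ...)
can be read off directly regardless of insertions or deletions in the hit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .hmm import AA_INDEX, AMINO_ACIDS, DomainHit

GAP = "-"


class MappingError(ValueError):
    """A hit cannot be projected onto the canonical scheme."""


@dataclass(frozen=True)
class CanonicalScheme:
    """The fixed bHLH column layout (1-based inclusive spans)."""

    basic_span: tuple[int, int] = (1, 13)
    helix1_span: tuple[int, int] = (14, 28)
    loop_span: tuple[int, int] = (29, 42)
    helix2_span: tuple[int, int] = (43, 57)
    loop_length_range: tuple[int, int] = (5, 14)

    @property
    def n_positions(self) -> int:
        return self.helix2_span[1]

    def region_of(self, pos: int) -> str:
        for name, (a, b) in (("basic", self.basic_span), ("helix1", self.helix1_span),
                             ("loop", self.loop_span), ("helix2", self.helix2_span)):
            if a <= pos <= b:
                return name
        raise ValueError(f"position {pos} outside the canonical domain")


DEFAULT_SCHEME = CanonicalScheme()


@dataclass
class CanonicalDomain:
    """A detected domain on the canonical 57-column scheme.

    ``residues[p]`` is the residue (or gap) at canonical position p;
    ``protein_positions[p]`` gives the 0-based protein index of that
    residue when it came from the target sequence.
    """

    target_id: str
    residues: dict[int, str]
    loop_length: int
    atypical_loop: bool = False
    hit: DomainHit | None = None
    protein_positions: dict[int, int] = field(default_factory=dict)
    scheme: CanonicalScheme = DEFAULT_SCHEME

    def residue(self, pos: int) -> str:
        return self.residues.get(pos, GAP)

    def region_string(self, span: tuple[int, int]) -> str:
        return "".join(self.residue(p) for p in range(span[0], span[1] + 1))

    @property
    def basic_region(self) -> str:
        return self.region_string(self.scheme.basic_span)

    def aligned_string(self) -> str:
        return "".join(self.residue(p) for p in range(1, self.scheme.n_positions + 1))

    @classmethod
    def from_aligned(cls, target_id: str, aligned: str,
                     scheme: CanonicalScheme = DEFAULT_SCHEME) -> "CanonicalDomain":
        """Adopt a pre-aligned 57-column row (e.g. from a reference alignment)."""
        if len(aligned) != scheme.n_positions:
            raise MappingError(
                f"{target_id!r}: aligned row has {len(aligned)} columns, "
                f"expected {scheme.n_positions}")
        residues = {p: aligned[p - 1].upper() if aligned[p - 1] not in "-." else GAP
                    for p in range(1, scheme.n_positions + 1)}
        a, b = scheme.loop_span
        loop_len = sum(residues[p] != GAP for p in range(a, b + 1))
        lo, hi = scheme.loop_length_range
        return cls(target_id=target_id, residues=residues, loop_length=loop_len,
                   atypical_loop=not (lo <= loop_len <= hi), scheme=scheme)


def map_to_canonical(
    hit: DomainHit,
    protein: str,
    scheme: CanonicalScheme = DEFAULT_SCHEME,
    model_to_canonical: list[int] | None = None,
) -> CanonicalDomain:
    """Project a domain hit onto the canonical position scheme.

    ``model_to_canonical[k-1]`` gives the canonical position of match state
    k (identity when the model was built directly on the 57-column layout).
    Match-aligned residues land on their canonical columns; residues
    emitted between the two helices (loop matches and loop insertions) are
    re-packed left-aligned into the loop columns, so the loop length is the
    emitted count, not the column count.  Canonical positions the local
    alignment trimmed at either end are extended from the flanking protein
    residues (never across the variable-length loop), mirroring how survey
    alignments are trimmed or extended to fit the canonical region.  Loops
    outside 5-14 are flagged atypical, never rejected.
    """
    n_pos = scheme.n_positions
    if model_to_canonical is None:
        model_to_canonical = list(range(1, n_pos + 1))
    canon_of = {k + 1: model_to_canonical[k] for k in range(len(model_to_canonical))}

    mapped = [(canon_of.get(k), idx) for kind, k, idx in hit.state_path
              if kind == "M" and canon_of.get(k) is not None]
    if not mapped:
        raise MappingError(f"hit on {hit.target_id!r} lies entirely outside the canonical region")

    loop_a, loop_b = scheme.loop_span
    h1_end, h2_start = scheme.helix1_span[1], scheme.helix2_span[0]

    residues: dict[int, str] = {p: GAP for p in range(1, n_pos + 1)}
    positions: dict[int, int] = {}

    # pass 1: match states outside the loop map 1:1
    for kind, k, idx in hit.state_path:
        if kind != "M":
            continue
        c = canon_of.get(k)
        if c is None or loop_a <= c <= loop_b:
            continue
        residues[c] = protein[idx].upper()
        positions[c] = idx

    # pass 2: everything emitted between helix1 and helix2 becomes the loop
    loop_emissions: list[int] = []
    for kind, k, idx in hit.state_path:
        if idx is None:
            continue
        if kind == "M":
            c = canon_of.get(k)
            in_loop = c is not None and loop_a <= c <= loop_b
        else:  # insertion after node k
            c = canon_of.get(k, 0)
            in_loop = c is not None and h1_end <= c < h2_start
        if in_loop:
            loop_emissions.append(idx)
    loop_emissions.sort()
    for offset, idx in enumerate(loop_emissions[: loop_b - loop_a + 1]):
        residues[loop_a + offset] = protein[idx].upper()
        positions[loop_a + offset] = idx

    # pass 3: extend into the flanks to fit the canonical region; offsets
    # are linear only within a contiguous segment, so extension stops at
    # the loop boundary on either side
    if positions:
        c_first = min(positions)
        i_first = positions[c_first]
        if c_first <= h1_end or c_first >= h2_start:
            back_limit = h2_start if c_first >= h2_start else 1
            for c in range(c_first - 1, back_limit - 1, -1):
                idx = i_first - (c_first - c)
                if idx < 0:
                    break
                residues[c] = protein[idx].upper()
                positions[c] = idx
        c_last = max(positions)
        i_last = positions[c_last]
        if c_last >= h2_start:
            for c in range(c_last + 1, n_pos + 1):
                idx = i_last + (c - c_last)
                if idx >= len(protein):
                    break
                residues[c] = protein[idx].upper()
                positions[c] = idx

    loop_len = len(loop_emissions)
    lo, hi = scheme.loop_length_range
    return CanonicalDomain(
        target_id=hit.target_id,
        residues=residues,
        loop_length=loop_len,
        atypical_loop=not (lo <= loop_len <= hi),
        hit=hit,
        protein_positions=positions,
        scheme=scheme,
    )


# ---------------------------------------------------------------------------
# residue counting and conservation

BASIC_RESIDUES = frozenset("RKH")


def count_basic_residues(dom: CanonicalDomain, basic_set: frozenset[str] = BASIC_RESIDUES) -> int:
    """Number of basic residues in the basic region (positions 1-13); gaps never count."""
    a, b = dom.scheme.basic_span
    return sum(dom.residue(p) in basic_set for p in range(a, b + 1))


@dataclass
class ConservationProfile:
    """Per-position residue frequencies over non-gap residues, with Fig-style tiers."""

    frequencies: dict[int, dict[str, float]]
    consensus: dict[int, str]
    tiers: dict[int, str]  # "100%", ">=30%", "<30%", or "gap" for all-gap columns
    n_domains: int

    def frequency(self, pos: int, residue: str) -> float:
        return self.frequencies.get(pos, {}).get(residue.upper(), 0.0)


def conservation_profile(domains: list[CanonicalDomain]) -> ConservationProfile:
    """Column-wise residue frequencies of a domain set.

    Frequencies are over non-gap residues only; tiers follow the convention
    of fully conserved (100%), moderately conserved (>=30%), and variable
    (<30%) consensus residues.
    """
    if not domains:
        raise ValueError("conservation profile needs at least one domain")
    n_pos = domains[0].scheme.n_positions
    freqs: dict[int, dict[str, float]] = {}
    consensus: dict[int, str] = {}
    tiers: dict[int, str] = {}
    for p in range(1, n_pos + 1):
        counts = np.zeros(20)
        for d in domains:
            r = d.residue(p)
            if r != GAP:
                counts[AA_INDEX[r]] += 1
        total = counts.sum()
        if total == 0:
            freqs[p], consensus[p], tiers[p] = {}, GAP, "gap"
            continue
        fv = counts / total
        freqs[p] = {AMINO_ACIDS[i]: float(fv[i]) for i in range(20) if counts[i] > 0}
        top = float(fv.max())
        # ties broken to the alphabetically first residue
        consensus[p] = AMINO_ACIDS[int(np.argmax(fv))]
        tiers[p] = "100%" if top >= 1.0 - 1e-12 else (">=30%" if top >= 0.30 else "<30%")
    return ConservationProfile(freqs, consensus, tiers, len(domains))


# ---------------------------------------------------------------------------
# canonical residue table and mismatch counting


@dataclass
class CanonicalResidueTable:
    """Allowed residues at the core-11 and defined-19 canonical positions.

    The exact residue identities of these historically defined sets are not
    fixed by this package; the table is configuration.  The shipped default
    is a synthetic reconstruction from the family consensus and is labelled
    as such.
    """

    core11: dict[int, frozenset[str]]
    defined19: dict[int, frozenset[str]]
    source: str = "unspecified"

    def __post_init__(self) -> None:
        if len(self.core11) != 11:
            raise ValueError(f"core table must cover 11 positions, got {len(self.core11)}")
        if len(self.defined19) != 19:
            raise ValueError(f"defined table must cover 19 positions, got {len(self.defined19)}")
        if not set(self.core11) <= set(self.defined19):
            raise ValueError("core-11 positions must be a subset of the defined-19 positions")

    @classmethod
    def from_json(cls, path: str | Path) -> "CanonicalResidueTable":
        doc = json.loads(Path(path).read_text())
        return cls(
            core11={int(p): frozenset(r) for p, r in doc["core11"].items()},
            defined19={int(p): frozenset(r) for p, r in doc["defined19"].items()},
            source=doc.get("source", str(path)),
        )


def default_residue_table() -> CanonicalResidueTable:
    return CanonicalResidueTable.from_json(
        Path(__file__).parent / "data" / "canonical_residue_table.synthetic.json")


def count_canonical_mismatches(
    dom: CanonicalDomain, table: CanonicalResidueTable
) -> tuple[int, int]:
    """Mismatches to the core-11 and defined-19 allowed-residue sets.

    A position mismatches when its residue is absent from the allowed set;
    a gap always mismatches.  Nesting (core <= defined) holds because the
    core positions are a subset of the defined positions.
    """
    def count(tab: dict[int, frozenset[str]]) -> int:
        return sum(dom.residue(p) == GAP or dom.residue(p) not in allowed
                   for p, allowed in tab.items())

    return count(table.core11), count(table.defined19)


# ---------------------------------------------------------------------------
# curation


@dataclass
class CurationVerdict:
    target_id: str
    passed: bool
    reasons: frozenset[str]
    core11_mismatches: int | None = None
    defined19_mismatches: int | None = None


CORE11_CUTOFF = 6
DEFINED19_CUTOFF = 11


def curate(
    protein: str,
    hit: DomainHit | None,
    dom: CanonicalDomain | None,
    table: CanonicalResidueTable | None = None,
    enforce_mismatch_cutoffs: bool = False,
) -> CurationVerdict:
    """Flag sequences unusable for domain-level analysis.

    ``internal_stop``: a ``*`` occurs before the final residue (a trailing
    stop marker is tolerated).  ``incomplete_domain``: no hit at all, or the
    mapped domain has no aligned residue in at least one of the basic,
    helix1, or helix2 spans.  Mismatch counts to the canonical residue
    table are recorded when available; the historical cutoffs (>6 core /
    >11 defined mismatches) are reported but NOT enforced unless
    ``enforce_mismatch_cutoffs`` is set, since enforcing them removes
    genuine atypical family members.
    """
    reasons: set[str] = set()
    if "*" in protein.rstrip("*"):
        reasons.add("internal_stop")
    if dom is None or hit is None:
        reasons.add("incomplete_domain")
    else:
        sch = dom.scheme
        for span in (sch.basic_span, sch.helix1_span, sch.helix2_span):
            if all(dom.residue(p) == GAP for p in range(span[0], span[1] + 1)):
                reasons.add("incomplete_domain")
                break
    c11 = c19 = None
    if dom is not None and table is not None:
        c11, c19 = count_canonical_mismatches(dom, table)
        if enforce_mismatch_cutoffs and (c11 > CORE11_CUTOFF or c19 > DEFINED19_CUTOFF):
            reasons.add("excess_mismatches")
    target = dom.target_id if dom else (hit.target_id if hit else "")
    return CurationVerdict(
        target_id=target,
        passed=not reasons,
        reasons=frozenset(reasons),
        core11_mismatches=c11,
        defined19_mismatches=c19,
    )
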