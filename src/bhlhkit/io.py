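"""Alignment readers/writers for the formats the pipeline consumes.

Motif and domain alignments arrive as aligned FASTA or Stockholm 1.0;
domain alignments are also exchanged as PHYLIP (relaxed names, so long
gene-model ids survive).  All parsing goes through Biopython's AlignIO.
"""

from __future__ import annotations

from pathlib import Path

from Bio import AlignIO

from .hmm import MotifAlignment

_EXT_FORMAT = {
    ".sto": "stockholm", ".stk": "stockholm", ".stockholm": "stockholm",
    ".phy": "phylip-relaxed", ".phylip": "phylip-relaxed",
    ".fasta": "fasta", ".fa": "fasta", ".afa": "fasta", ".aln": "fasta",
}


def sniff_format(path: str | Path) -> str:
    ext = Path(path).suffix.lower()
    if ext in _EXT_FORMAT:
        return _EXT_FORMAT[ext]
    head = Path(path).read_text()[:64]
    if head.startswith("# STOCKHOLM"):
        return "stockholm"
    if head.startswith(">"):
        return "fasta"
    return "phylip-relaxed"


def read_alignment(path: str | Path, name: str | None = None,
                   fmt: str | None = None) -> MotifAlignment:
    """Read one alignment; gap characters '.' are normalized to '-'."""
    fmt = fmt or sniff_format(path)
    aln = AlignIO.read(str(path), fmt)
    rows = [(rec.id, str(rec.seq).replace(".", "-")) for rec in aln]
    return MotifAlignment(name or Path(path).stem, rows)


def write_alignment(aln: MotifAlignment, path: str | Path,
                    fmt: str = "fasta") -> None:
    """Write an alignment as aligned FASTA or sequential PHYLIP."""
    path = Path(path)
    if fmt == "fasta":
        path.write_text("".join(f">{rid}\n{seq}\n" for rid, seq in aln.rows))
    elif fmt == "phylip":
        lines = [f" {aln.n_rows} {aln.n_columns}"]
        for rid, seq in aln.rows:
            lines.append(f"{rid[:50]:<50}  {seq}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unsupported alignment output format {fmt!r}")
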