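"""Multiple-sequence alignment container and readers/writers.

The container is deliberately minimal: an ordered list of taxon ids and
equal-length character strings.  Nucleotide alignments use IUPAC codes with
``N`` for missing; genotype-coded ("binary") alignments use the symbols
``0`` (homozygous reference), ``1`` (heterozygous), ``2`` (homozygous
alternate) and ``?`` (missing), the coding expected by SNP-based species
delimitation tools.

PHYLIP (relaxed names) and FASTA go through Biopython; the binary NEXUS
dialect (datatype=standard) is written and parsed here because it is a small
fixed template.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

FORMATS = ("phylip-relaxed", "fasta", "binary-nexus")


class DuplicateTaxonError(ValueError):
    """Two rows of an alignment share the same taxon id."""


@dataclass
class Alignment:
    """Taxa-by-characters matrix with ordered, unique taxon ids."""

    ids: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and seqs must have equal length")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise DuplicateTaxonError(f"duplicate taxon ids: {dupes}")
        if any(not i for i in self.ids):
            raise ValueError("taxon ids must be non-empty")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")

    @property
    def n_taxa(self) -> int:
        return len(self.ids)

    @property
    def n_sites(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def sequence(self, taxon: str) -> str:
        try:
            return self.seqs[self.ids.index(taxon)]
        except ValueError:
            raise KeyError(f"taxon {taxon!r} not in alignment") from None

    def take_columns(self, indices: Iterable[int]) -> "Alignment":
        idx = list(indices)
        return Alignment(list(self.ids), ["".join(s[i] for i in idx) for s in self.seqs])


def _to_biopython(a: Alignment) -> MultipleSeqAlignment:
    return MultipleSeqAlignment(
        SeqRecord(Seq(seq), id=tid, description="") for tid, seq in zip(a.ids, a.seqs)
    )


def write_alignment(a: Alignment, path: str | Path, fmt: str = "fasta") -> Path:
    """Write ``a`` to ``path`` in one of: phylip-relaxed, fasta, binary-nexus."""
    if fmt not in FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {FORMATS}")
    if len(set(a.ids)) != len(a.ids):  # container enforces this, but be explicit
        raise DuplicateTaxonError("duplicate taxon ids")
    path = Path(path)
    if fmt == "binary-nexus":
        _write_binary_nexus(a, path)
    elif fmt == "fasta":
        SeqIO.write(_to_biopython(a), str(path), "fasta")
    else:
        AlignIO.write(_to_biopython(a), str(path), "phylip-relaxed")
    return path


def read_alignment(path: str | Path, fmt: str = "fasta") -> Alignment:
    if fmt not in FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {FORMATS}")
    path = Path(path)
    if fmt == "binary-nexus":
        return _read_binary_nexus(path)
    msa = AlignIO.read(str(path), fmt)
    return Alignment([r.id for r in msa], [str(r.seq) for r in msa])


_NEXUS_TEMPLATE = """#NEXUS
BEGIN DATA;
DIMENSIONS NTAX={ntax} NCHAR={nchar};
FORMAT DATATYPE=STANDARD SYMBOLS="012" MISSING=? GAP=-;
MATRIX
{matrix}
;
END;
"""


def _write_binary_nexus(a: Alignment, path: Path) -> None:
    bad = sorted(set("".join(a.seqs)) - set("012?-"))
    if bad:
        raise ValueError(f"binary-nexus alignment may only contain 012?-; found {bad}")
    width = max((len(i) for i in a.ids), default=0)
    rows = "\n".join(f"{tid:<{width}}  {seq}" for tid, seq in zip(a.ids, a.seqs))
    path.write_text(_NEXUS_TEMPLATE.format(ntax=a.n_taxa, nchar=a.n_sites, matrix=rows))


def _read_binary_nexus(path: Path) -> Alignment:
    text = path.read_text()
    m = re.search(r"MATRIX\s*\n(.*?)\n\s*;", text, flags=re.S | re.I)
    if m is None:
        raise ValueError(f"{path}: no MATRIX block found")
    ids, seqs = [], []
    for line in m.group(1).splitlines():
        line = line.strip()
        if not line:
            continue
        tid, seq = line.split(None, 1)
        ids.append(tid)
        seqs.append(seq.strip())
    return Alignment(ids, seqs)
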