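"""Protein alignments, genetic-code translation and gene concatenation.

Alignments are rectangular matrices of one-letter residue codes over the
20-letter alphabet plus gap ``-``, unknown ``X`` and the ambiguity codes
``B``/``Z``/``J``.  Coordinates are 0-based half-open throughout the
library; partition files are written 1-based inclusive (the NEXUS charset
convention).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from Bio import AlignIO, BiopythonWarning
from Bio.Align import MultipleSeqAlignment
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import AMBIGUITY, AMINO_ACIDS, UNKNOWN_STATES

logger = logging.getLogger(__name__)

_ALLOWED = set(AMINO_ACIDS) | set(AMBIGUITY) | UNKNOWN_STATES

AlignmentFormat = Literal["fasta", "phylip"]


class AlignmentError(ValueError):
    pass


@dataclass
class ProteinAlignment:
    """Aligned amino-acid sequences: ordered unique taxa x sites."""

    taxa: list[str]
    sites: np.ndarray  # (n_taxa, n_sites) of single characters

    def __post_init__(self) -> None:
        self.taxa = [str(t) for t in self.taxa]
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise AlignmentError(f"duplicate taxon labels: {', '.join(dupes)}")
        self.sites = np.asarray(self.sites, dtype="U1")
        if self.sites.ndim != 2 or self.sites.shape[0] != len(self.taxa):
            raise AlignmentError(
                f"site matrix shape {self.sites.shape} does not match "
                f"{len(self.taxa)} taxa"
            )
        bad = ~np.isin(self.sites, sorted(_ALLOWED))
        if bad.any():
            n = int(bad.sum())
            logger.warning("mapped %d unrecognized residue(s) to 'X'", n)
            self.sites = self.sites.copy()
            self.sites[bad] = "X"
        # '*' carries no residue information once inside an alignment
        self.sites[self.sites == "*"] = "X"

    @classmethod
    def from_sequences(
        cls, records: Iterable[tuple[str, str]]
    ) -> "ProteinAlignment":
        taxa, rows = [], []
        for label, seq in records:
            taxa.append(label)
            rows.append(list(str(seq).upper()))
        if not rows:
            raise AlignmentError("empty alignment")
        lengths = {len(r) for r in rows}
        if len(lengths) > 1:
            raise AlignmentError(f"ragged alignment: row lengths {sorted(lengths)}")
        return cls(taxa, np.array(rows, dtype="U1"))

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return self.sites.shape[1]

    def sequence(self, taxon: str) -> str:
        return "".join(self.sites[self.taxa.index(taxon)])

    def subset(self, taxa: Sequence[str]) -> "ProteinAlignment":
        """Row subset in the given taxon order."""
        idx = [self.taxa.index(t) for t in taxa]
        return ProteinAlignment(list(taxa), self.sites[idx].copy())

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ProteinAlignment)
            and self.taxa == other.taxa
            and np.array_equal(self.sites, other.sites)
        )


@dataclass
class PartitionedAlignment:
    """An alignment plus named, disjoint, ordered column intervals.

    Intervals are 0-based half-open and cover every column.
    """

    alignment: ProteinAlignment
    partitions: list[tuple[str, tuple[int, int]]]

    def __post_init__(self) -> None:
        pos = 0
        for name, (start, stop) in self.partitions:
            if start != pos or stop <= start:
                raise AlignmentError(
                    f"partition {name!r} [{start},{stop}) is not contiguous at {pos}"
                )
            pos = stop
        if pos != self.alignment.n_sites:
            raise AlignmentError(
                f"partitions cover {pos} of {self.alignment.n_sites} columns"
            )

    def charset_block(self) -> str:
        """NEXUS sets block with 1-based inclusive charsets."""
        lines = ["#nexus", "begin sets;"]
        for name, (start, stop) in self.partitions:
            lines.append(f"  charset {name} = {start + 1}-{stop};")
        lines.append("end;")
        return "\n".join(lines) + "\n"


def _biopython_format(format: AlignmentFormat) -> str:
    return {"fasta": "fasta", "phylip": "phylip-relaxed"}[format]


def _infer_format(path: Path) -> AlignmentFormat:
    if path.suffix.lower() in {".phy", ".phylip"}:
        return "phylip"
    return "fasta"


def read_alignment(
    path: str | Path, format: AlignmentFormat | None = None
) -> ProteinAlignment:
    """Read a FASTA or (relaxed sequential) PHYLIP protein alignment."""
    path = Path(path)
    if format is None:
        format = _infer_format(path)
    try:
        msa = AlignIO.read(str(path), _biopython_format(format))
    except ValueError as exc:
        raise AlignmentError(f"{path}: {exc}") from exc
    return ProteinAlignment.from_sequences(
        (rec.id, str(rec.seq)) for rec in msa
    )


def write_alignment(
    aln: ProteinAlignment, path: str | Path, format: AlignmentFormat | None = None
) -> Path:
    path = Path(path)
    if format is None:
        format = _infer_format(path)
    msa = MultipleSeqAlignment(
        SeqRecord(Seq("".join(row)), id=taxon, description="")
        for taxon, row in zip(aln.taxa, aln.sites)
    )
    with open(path, "w") as fh:
        AlignIO.write(msa, fh, _biopython_format(format))
    return path


class TranslationError(ValueError):
    pass


def translate_cds(
    nucleotides: str, code: int = 5, force: bool = False
) -> str:
    """Translate a coding sequence under an NCBI genetic code.

    `code` is the NCBI translation-table number (1 = standard,
    5 = invertebrate mitochondrial).  A trailing partial codon is dropped
    with a warning; a terminal stop is removed; an internal stop raises
    unless `force`, in which case it becomes 'X'.
    """
    try:
        CodonTable.unambiguous_dna_by_id[code]
    except KeyError:
        raise TranslationError(f"unknown NCBI translation table {code}") from None
    seq = str(nucleotides).upper().replace("U", "T")
    if len(seq) % 3:
        logger.warning("dropping trailing partial codon (%d nt)", len(seq) % 3)
        seq = seq[: len(seq) - len(seq) % 3]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", BiopythonWarning)
        protein = str(Seq(seq).translate(table=code))
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        if not force:
            pos = protein.index("*")
            raise TranslationError(
                f"internal stop codon at codon {pos + 1} "
                f"({seq[3 * pos:3 * pos + 3]}) under table {code}"
            )
        protein = protein.replace("*", "X")
    return protein


def concatenate(
    alignments: Sequence[tuple[str, ProteinAlignment]]
) -> PartitionedAlignment:
    """Concatenate gene alignments column-wise over the union of taxa.

    Taxa keep first-appearance order; a taxon absent from a gene gets an
    all-gap block there.  One partition record is emitted per gene.
    """
    if not alignments:
        raise AlignmentError("nothing to concatenate")
    taxa: list[str] = []
    for _, aln in alignments:
        for t in aln.taxa:
            if t not in taxa:
                taxa.append(t)
    blocks, partitions, pos = [], [], 0
    for name, aln in alignments:
        block = np.full((len(taxa), aln.n_sites), "-", dtype="U1")
        for i, t in enumerate(aln.taxa):
            block[taxa.index(t)] = aln.sites[i]
        blocks.append(block)
        partitions.append((name, (pos, pos + aln.n_sites)))
        pos += aln.n_sites
    return PartitionedAlignment(
        ProteinAlignment(taxa, np.concatenate(blocks, axis=1)), partitions
    )
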