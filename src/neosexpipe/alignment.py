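"""Multi-taxon gametolog alignments.

Leaves carry labels of the form ``<species>|<tag>`` with tag ``Z``,
``W`` or ``OUT`` (outgroup ortholog).  Sequences are stored as a
(rows x columns) character matrix for cheap column operations
(trimming, masking, bootstrap resampling).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

TAG_Z = "Z"
TAG_W = "W"
TAG_OUT = "OUT"


def parse_label(label: str) -> tuple[str, str]:
    """Split ``species|tag`` (tag in {Z, W, OUT})."""
    species, _, tag = label.rpartition("|")
    if not species or tag not in (TAG_Z, TAG_W, TAG_OUT):
        raise ValueError(f"leaf label {label!r} is not '<species>|Z|W|OUT'")
    return species, tag


@dataclass
class GametologAlignment:
    gene_id: str
    names: list[str]
    matrix: np.ndarray  # (n_rows, n_cols) of single characters, dtype '<U1'
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype="<U1")
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.names):
            raise ValueError("matrix shape does not match names")

    @classmethod
    def from_sequences(cls, gene_id: str, records: Iterable[tuple[str, str]],
                       **meta) -> "GametologAlignment":
        names, seqs = [], []
        for name, seq in records:
            names.append(name)
            seqs.append(list(seq.upper()))
        lengths = {len(s) for s in seqs}
        if len(lengths) > 1:
            raise ValueError(f"{gene_id}: unequal sequence lengths {lengths}")
        return cls(gene_id, names, np.array(seqs, dtype="<U1"), dict(meta))

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cols(self) -> int:
        return self.matrix.shape[1]

    def sequence(self, name: str) -> str:
        return "".join(self.matrix[self.names.index(name)])

    def rows_by_tag(self, tag: str) -> list[str]:
        return [n for n in self.names if parse_label(n)[1] == tag]

    def species_rows(self, species: str) -> list[str]:
        return [n for n in self.names if parse_label(n)[0] == species]

    def subset_columns(self, keep: np.ndarray) -> "GametologAlignment":
        return GametologAlignment(self.gene_id, list(self.names),
                                  self.matrix[:, keep], dict(self.meta))

    def to_fasta(self, path: str) -> None:
        records = [SeqRecord(Seq("".join(row)), id=name, description="")
                   for name, row in zip(self.names, self.matrix)]
        SeqIO.write(records, path, "fasta")

    @classmethod
    def from_fasta(cls, path: str, gene_id: str | None = None) -> "GametologAlignment":
        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fasta")]
        if not records:
            raise ValueError(f"{path}: no FASTA records")
        if gene_id is None:
            import os
            gene_id = os.path.splitext(os.path.basename(path))[0]
        return cls.from_sequences(gene_id, records)
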