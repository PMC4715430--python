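"""Per-OTU multiple alignment.

The pipeline either ingests an externally produced aligned FASTA or builds a
center-star alignment: the most abundant haplotype is the center, every other
sequence is pairwise-aligned to it with the clustering scoring scheme, and the
pairwise alignments are merged under "once a gap, always a gap".  For ~275 bp
low-divergence amplicons this is adequate and keeps the pipeline
self-contained; downstream statistics use pairwise-valid sites, which limits
sensitivity to aligner choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import LinkError, ParseError, ValidationError
from .io_config import SampleTable
from .otu import _ALIGNER, UniqueSeq

ALIGN_ALPHABET = frozenset("ACGTN-")


@dataclass
class Alignment:
    """Equal-length rows over {A,C,G,T,N,-} with optional row metadata."""

    labels: list[str]
    rows: list[str]
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.rows):
            raise ValidationError("labels and rows differ in length")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ParseError(f"ragged alignment rows: widths {sorted(widths)}")
        for label, row in zip(self.labels, self.rows):
            if set(row) - ALIGN_ALPHABET:
                raise ValidationError(f"row {label!r} has characters outside {{ACGTN-}}")
            if set(row) == {"-"}:
                raise ValidationError(f"row {label!r} is all gaps")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def matrix(self) -> np.ndarray:
        """Rows as a uint8 character matrix."""
        return np.frombuffer("".join(self.rows).encode(), dtype=np.uint8).reshape(
            self.n_rows, self.n_cols
        )

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")

    def drop_all_gap_columns(self) -> "Alignment":
        mat = self.matrix()
        keep = ~(mat == ord("-")).all(axis=0)
        rows = [bytes(row[keep]).decode("ascii") for row in mat]
        return Alignment(list(self.labels), rows, self.meta)

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(row), id=label, description="")
            for label, row in zip(self.labels, self.rows)
        ]
        SeqIO.write(records, str(path), "fasta-2line")


def center_star_align(
    seqs: list[UniqueSeq], labels: list[str] | None = None
) -> Alignment:
    """Center-star multiple alignment of dereplicated haplotypes.

    The center is the highest-abundance sequence (ties broken by lexicographic
    order of the bases); gaps introduced by any pairwise alignment are
    propagated to every row.
    """
    if not seqs:
        raise ValidationError("center_star_align requires at least one sequence")
    if labels is None:
        labels = [f"h{i}" for i in range(len(seqs))]
    if len(seqs) == 1:
        return Alignment(list(labels), [seqs[0].bases])

    center_idx = min(range(len(seqs)), key=lambda i: (-seqs[i].abundance, seqs[i].bases))
    center = seqs[center_idx].bases
    n_pos = len(center)

    # Pairwise alignments to the center; record insertions relative to center
    # positions: ins[k][p] columns inserted before center base p (p == n_pos
    # means after the last base).
    pair_rows: dict[int, tuple[str, str]] = {}
    master_ins = np.zeros(n_pos + 1, dtype=int)
    for k, seq in enumerate(seqs):
        if k == center_idx:
            continue
        aln = _ALIGNER.align(center, seq.bases)[0]
        c_row, s_row = aln[0], aln[1]
        pair_rows[k] = (c_row, s_row)
        ins = _insertion_profile(c_row)
        np.maximum(master_ins, ins, out=master_ins)

    center_row = "".join(
        "-" * master_ins[p] + (center[p] if p < n_pos else "")
        for p in range(n_pos + 1)
    )
    rows: list[str] = []
    for k, seq in enumerate(seqs):
        if k == center_idx:
            rows.append(center_row)
        else:
            rows.append(_project_row(*pair_rows[k], master_ins))
    return Alignment(list(labels), rows)


def _insertion_profile(center_row: str) -> np.ndarray:
    n_pos = len(center_row) - center_row.count("-")
    ins = np.zeros(n_pos + 1, dtype=int)
    pos = 0
    for ch in center_row:
        if ch == "-":
            ins[pos] += 1
        else:
            pos += 1
    return ins


def _project_row(center_row: str, seq_row: str, master_ins: np.ndarray) -> str:
    """Re-emit one pairwise-aligned row on the master column grid.

    Each insertion slot (columns where the center has a gap) is left-justified
    and padded to the master width for that slot.
    """
    chunks: list[str] = []
    pos = 0
    slot: list[str] = []
    for c_ch, s_ch in zip(center_row, seq_row):
        if c_ch == "-":
            slot.append(s_ch)
        else:
            chunks.append("".join(slot) + "-" * (master_ins[pos] - len(slot)))
            chunks.append(s_ch)
            slot = []
            pos += 1
    chunks.append("".join(slot) + "-" * (master_ins[pos] - len(slot)))
    return "".join(chunks)


def ingest_alignment(path: str | Path, samples: SampleTable | None = None) -> Alignment:
    """Read an externally aligned FASTA and join sample metadata.

    Row labels follow the ``read_id|sample_id`` convention; metadata (locale,
    region) is resolved through the sample table when one is supplied.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"{path}: no alignment rows")
    labels = [rec.id for rec in records]
    rows = [str(rec.seq).upper() for rec in records]
    widths = {len(r) for r in rows}
    if len(widths) > 1:
        raise ParseError(f"{path}: rows of differing length {sorted(widths)}")
    meta = None
    if samples is not None:
        entries = []
        for label in labels:
            if "|" not in label:
                raise ParseError(f"row {label!r} not of the form 'read_id|sample_id'")
            _, sample_id = label.split("|", 1)
            locale = samples.locale_of_sample(sample_id)
            entries.append(
                {
                    "label": label,
                    "sample_id": sample_id,
                    "locale": locale,
                    "region": samples.region_of(locale),
                }
            )
        meta = pd.DataFrame(entries).set_index("label")
    return Alignment(labels, rows, meta)
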