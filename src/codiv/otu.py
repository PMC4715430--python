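"""Trimming, dereplication and greedy abundance-sorted OTU clustering.

Reads are trimmed to a fixed length, collapsed into unique haplotypes with
abundances, and clustered greedily: uniques are visited in decreasing abundance
order and either join the existing centroid of maximum global-alignment
identity (when that identity reaches the threshold) or found a new OTU.  An
optional single-crossover chimera screen discards queries that are better
explained as a splice of two existing centroids.  Identity is computed from a
global (Needleman-Wunsch) alignment with free terminal gaps, scored
match +1 / mismatch -1 / gap open -5 / gap extend -1; matching columns are
divided by the alignment columns excluding terminal-gap columns.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
from Bio import Align

from .errors import LinkError, StateError, ValidationError
from .io_config import SampleTable, SeqRead

log = logging.getLogger(__name__)

_GAP = ord("-")
_N = ord("N")


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_internal_gap_score = -5.0
    aligner.extend_internal_gap_score = -1.0
    # Terminal gaps are cheap but not free: with fully free end gaps the
    # optimal alignment of two unrelated sequences is a tiny staggered
    # overlap whose non-terminal core is spuriously identical.
    aligner.open_end_gap_score = -0.5
    aligner.extend_end_gap_score = -0.5
    return aligner


_ALIGNER = _make_aligner()


@dataclass
class UniqueSeq:
    """A dereplicated haplotype: identical reads collapsed with abundances."""

    bases: str
    abundance: int
    member_read_ids: list[str] = field(default_factory=list)
    locale_counts: Counter = field(default_factory=Counter)


@dataclass
class OtuCluster:
    """An OTU: centroid haplotype plus members with identities to the centroid."""

    otu_id: int
    centroid: str
    members: list[tuple[UniqueSeq, float]]
    annotation: str | None = None
    region_counts: dict[str, int] | None = None

    @property
    def size(self) -> int:
        return sum(u.abundance for u, _ in self.members)

    @property
    def locale_counts(self) -> Counter:
        total: Counter = Counter()
        for unique, _ in self.members:
            total.update(unique.locale_counts)
        return total


class ChimeraVerdict(NamedTuple):
    status: str  # "clean" or "chimeric"
    parent1: int | None = None
    parent2: int | None = None
    breakpoint: int | None = None


@dataclass
class ClusteringResult:
    clusters: list[OtuCluster]
    chimeras: list[tuple[UniqueSeq, ChimeraVerdict]]


def trim_reads(reads: list[SeqRead], trim_length: int) -> list[SeqRead]:
    """Truncate reads to ``trim_length`` from the start; drop shorter reads."""
    if trim_length <= 0:
        raise ValidationError("trim_length must be positive")
    kept = [
        SeqRead(r.read_id, r.sample_id, r.bases[:trim_length])
        for r in reads
        if len(r.bases) >= trim_length
    ]
    dropped = len(reads) - len(kept)
    if dropped:
        log.warning("trim_reads: discarded %d reads shorter than %d bp", dropped, trim_length)
    if not kept and reads:
        log.warning("trim_reads: all %d reads were below the trim length", len(reads))
    return kept


def dereplicate(reads: list[SeqRead], samples: SampleTable) -> list[UniqueSeq]:
    """Collapse identical reads into UniqueSeqs sorted by (abundance desc, bases asc)."""
    lengths = {len(r.bases) for r in reads}
    if len(lengths) > 1:
        raise ValidationError(f"reads must share one length, got {sorted(lengths)}")
    by_bases: dict[str, UniqueSeq] = {}
    for read in reads:
        locale = samples.locale_of_sample(read.sample_id)  # raises LinkError
        unique = by_bases.get(read.bases)
        if unique is None:
            unique = by_bases[read.bases] = UniqueSeq(bases=read.bases, abundance=0)
        unique.abundance += 1
        unique.member_read_ids.append(read.read_id)
        unique.locale_counts[locale] += 1
    return sorted(by_bases.values(), key=lambda u: (-u.abundance, u.bases))


def global_identity(a: str, b: str) -> float:
    """Fractional identity of the optimal global alignment of two sequences.

    Columns inside terminal-gap runs are excluded from the denominator; 'N'
    never counts as a match.
    """
    if not a or not b:
        raise ValidationError("global_identity requires non-empty sequences")
    if a == b:
        return 1.0
    alignment = _ALIGNER.align(a, b)[0]
    row0 = np.frombuffer(alignment[0].encode(), dtype=np.uint8)
    row1 = np.frombuffer(alignment[1].encode(), dtype=np.uint8)
    return _identity_from_rows(row0, row1)


def _identity_from_rows(row0: np.ndarray, row1: np.ndarray) -> float:
    nz0 = np.nonzero(row0 != _GAP)[0]
    nz1 = np.nonzero(row1 != _GAP)[0]
    start = max(nz0[0], nz1[0])
    stop = min(nz0[-1], nz1[-1])
    if stop < start:
        return 0.0
    a, b = row0[start : stop + 1], row1[start : stop + 1]
    matches = int(np.sum((a == b) & (a != _GAP) & (a != _N)))
    return matches / (stop - start + 1)


def screen_chimera(
    query: str, centroids: list[str], threshold: float, grid: int = 5, min_segment: int = 50
) -> ChimeraVerdict:
    """Single-crossover chimera model against existing centroids.

    For every ordered centroid pair and breakpoint on a coarse grid, the query
    prefix is compared (ungapped) to the first parent and the suffix to the
    second; the query is chimeric when the best spliced identity reaches the
    clustering threshold, beats the best single-centroid identity by >= 0.01,
    and both segments are at least ``min_segment`` bp.
    """
    if len(centroids) < 2:
        return ChimeraVerdict("clean")
    length = len(query)
    same_length = [c for c in centroids if len(c) == length]
    if len(same_length) < 2:
        return ChimeraVerdict("clean")
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    mat = np.frombuffer("".join(same_length).encode(), dtype=np.uint8).reshape(
        len(same_length), length
    )
    matches = (mat == q) & (mat != _N) & (q != _N)
    prefix = np.concatenate(
        [np.zeros((len(same_length), 1), dtype=int), np.cumsum(matches, axis=1)], axis=1
    )
    totals = prefix[:, -1]
    best_single = totals.max() / length
    breakpoints = range(min_segment, length - min_segment + 1, grid)
    best = (-1.0, None, None, None)
    for b in breakpoints:
        left = prefix[:, b]
        right = totals - prefix[:, b]
        combo = left[:, None] + right[None, :]
        np.fill_diagonal(combo, -1)
        idx = np.unravel_index(np.argmax(combo), combo.shape)
        score = combo[idx] / length
        if score > best[0]:
            best = (score, int(idx[0]), int(idx[1]), b)
    score, p1, p2, bp = best
    if score >= threshold and score - best_single >= 0.01 - 1e-12:
        orig = [centroids.index(same_length[i]) for i in (p1, p2)]
        return ChimeraVerdict("chimeric", orig[0], orig[1], bp)
    return ChimeraVerdict("clean")


def cluster_otus(
    uniques: list[UniqueSeq], threshold: float, chimera_check: bool = True
) -> ClusteringResult:
    """Greedy abundance-sorted clustering at the identity threshold.

    Input must already be in (abundance desc, bases asc) order, which makes the
    pass deterministic; permuting the underlying reads cannot change the
    result because dereplication canonicalises the order.
    """
    order = [(-u.abundance, u.bases) for u in uniques]
    if order != sorted(order):
        raise StateError("uniques must be sorted by (abundance desc, bases asc)")
    clusters: list[OtuCluster] = []
    chimeras: list[tuple[UniqueSeq, ChimeraVerdict]] = []
    for unique in uniques:
        if not clusters:
            clusters.append(OtuCluster(0, unique.bases, [(unique, 1.0)]))
            continue
        identities = np.array(
            [global_identity(unique.bases, c.centroid) for c in clusters]
        )
        best = int(np.argmax(identities))  # ties -> lowest otu_id
        if identities[best] >= threshold:
            clusters[best].members.append((unique, float(identities[best])))
            continue
        if chimera_check:
            verdict = screen_chimera(
                unique.bases, [c.centroid for c in clusters], threshold
            )
            if verdict.status == "chimeric":
                chimeras.append((unique, verdict))
                continue
        clusters.append(OtuCluster(len(clusters), unique.bases, [(unique, 1.0)]))
    return ClusteringResult(clusters=clusters, chimeras=chimeras)


def assign_region_counts(otus: Iterable[OtuCluster], samples: SampleTable) -> None:
    """Populate region_counts on each OTU from its locale counts."""
    for otu in otus:
        counts: dict[str, int] = {region: 0 for region in samples.regions}
        for locale, n in otu.locale_counts.items():
            counts[samples.region_of(locale)] += n
        otu.region_counts = counts


def filter_comparative(
    otus: list[OtuCluster], min_total: int, min_per_region: int
) -> list[OtuCluster]:
    """Keep OTUs with >= min_total sequences and >= min_per_region on each side."""
    kept = []
    for otu in otus:
        if otu.region_counts is None:
            raise StateError("region_counts not populated; call assign_region_counts")
        if len(otu.region_counts) != 2:
            raise StateError("comparative filter requires exactly two regions")
        if otu.size >= min_total and all(
            n >= min_per_region for n in otu.region_counts.values()
        ):
            kept.append(otu)
    return kept
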