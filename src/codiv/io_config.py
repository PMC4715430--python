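"""Readers, writers and run configuration.

Sequence data move as plain FASTA with headers of the form ``read_id|sample_id``
(a sidecar read->sample map is accepted as an alternative).  The sample table is
a TSV with columns ``sample_id, locale, region, month`` and is the grouping
backbone for every hierarchical test: each sample (a pitcher) belongs to a
locale, and each locale to exactly one region (the side of the biogeographic
barrier).  Geographic distances are either computed as great-circle km from
locale coordinates or ingested verbatim from a user matrix.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    ConfigError,
    ConsistencyError,
    LinkError,
    ParseError,
    SchemaError,
    ValidationError,
)

DNA_ALPHABET = frozenset("ACGTN")
EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class SeqRead:
    """A single demultiplexed amplicon read attributed to a sample."""

    read_id: str
    sample_id: str
    bases: str

    def __len__(self) -> int:
        return len(self.bases)


def read_sequences(
    path: str | Path,
    expected_alphabet: frozenset[str] = DNA_ALPHABET,
    sample_of: dict[str, str] | None = None,
) -> list[SeqRead]:
    """Read demultiplexed reads from FASTA, preserving input order.

    Headers are parsed as ``read_id|sample_id``; if ``sample_of`` is given it
    maps read_id -> sample_id instead and headers are taken as bare read ids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prevalidate_fasta(path)
    reads: list[SeqRead] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.id
        if sample_of is not None:
            read_id, sample_id = header, sample_of.get(header)
            if sample_id is None:
                raise LinkError(f"read {header!r} missing from read->sample map")
        else:
            if "|" not in header:
                raise ParseError(
                    f"header {header!r} not of the form 'read_id|sample_id' "
                    "and no sidecar map supplied"
                )
            read_id, sample_id = header.split("|", 1)
        bases = str(rec.seq).upper()
        if not bases:
            raise ValidationError(f"record {read_id!r} has an empty sequence")
        bad = set(bases) - expected_alphabet
        if bad:
            raise ValidationError(
                f"record {read_id!r} contains characters outside the alphabet: "
                f"{sorted(bad)}"
            )
        if read_id in seen:
            raise ConsistencyError(f"duplicate read id {read_id!r}")
        seen.add(read_id)
        reads.append(SeqRead(read_id=read_id, sample_id=sample_id, bases=bases))
    return reads


def _prevalidate_fasta(path: Path) -> None:
    """Cheap structural scan so malformed files fail with a line number."""
    with open(path) as fh:
        saw_header = False
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                saw_header = True
            elif not saw_header:
                raise ParseError(
                    f"{path}:{lineno}: sequence data before first FASTA header"
                )
        if not saw_header:
            raise ParseError(f"{path}:1: no FASTA records found")


def write_sequences(reads: list[SeqRead], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(r.bases), id=f"{r.read_id}|{r.sample_id}", description="")
        for r in reads
    ]
    SeqIO.write(records, str(path), "fasta-2line")


class SampleTable:
    """sample -> locale -> region -> month mapping with validation.

    Exactly two regions are required by the barrier analyses; tables with more
    regions load fine but ``require_two_regions`` rejects them at pipeline
    start.
    """

    REQUIRED = ("sample_id", "locale", "region", "month")

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in frame.columns]
        if missing:
            raise SchemaError(f"sample table missing columns: {missing}")
        if len(frame) == 0:
            raise SchemaError("sample table is empty")
        frame = frame.loc[:, list(self.REQUIRED)].astype(str).reset_index(drop=True)
        dupes = frame["sample_id"][frame["sample_id"].duplicated()]
        if len(dupes):
            raise ConsistencyError(
                f"duplicate sample ids: {sorted(set(dupes))}"
            )
        lr = frame.drop_duplicates(["locale", "region"])
        bad = lr["locale"][lr["locale"].duplicated()]
        if len(bad):
            raise ConsistencyError(
                f"locales mapped to more than one region: {sorted(set(bad))}"
            )
        self.frame = frame
        self._region_of = dict(zip(lr["locale"], lr["region"]))
        self._locale_of_sample = dict(zip(frame["sample_id"], frame["locale"]))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleTable":
        try:
            frame = pd.read_csv(path, sep="\t", dtype=str)
        except pd.errors.EmptyDataError as exc:
            raise SchemaError(f"{path}: empty sample table") from exc
        return cls(frame)

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @property
    def locales(self) -> list[str]:
        return sorted(self._region_of)

    @property
    def regions(self) -> list[str]:
        return sorted(set(self._region_of.values()))

    def region_of(self, locale: str) -> str:
        return self._region_of[locale]

    @property
    def region_map(self) -> dict[str, str]:
        return dict(self._region_of)

    def locale_of_sample(self, sample_id: str) -> str:
        try:
            return self._locale_of_sample[sample_id]
        except KeyError as exc:
            raise LinkError(f"unknown sample id {sample_id!r}") from exc

    def region_sizes(self) -> dict[str, int]:
        """Number of locales per region."""
        out: dict[str, int] = {}
        for region in self._region_of.values():
            out[region] = out.get(region, 0) + 1
        return out

    def require_two_regions(self) -> None:
        if len(self.regions) != 2:
            raise ConfigError(
                f"barrier analyses need exactly two regions, got {self.regions}"
            )

    def months_of_samples(self) -> dict[str, str]:
        return dict(zip(self.frame["sample_id"], self.frame["month"]))


def haversine_km(
    lat1: float, lon1: float, lat2: float, lon2: float, radius: float = EARTH_RADIUS_KM
) -> float:
    """Great-circle distance in km on a sphere of the given radius."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlam / 2) ** 2
    return 2 * radius * math.asin(math.sqrt(a))


class GeoMatrix:
    """Symmetric nonnegative locale-by-locale distances (km) with zero diagonal."""

    def __init__(self, frame: pd.DataFrame):
        if list(frame.index) != list(frame.columns):
            raise ValidationError("distance matrix rows and columns must match")
        values = frame.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValidationError("distance matrix contains non-finite entries")
        if np.any(values < 0):
            raise ValidationError("distances must be nonnegative")
        if not np.allclose(values, values.T, atol=1e-8):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(values), 0.0, atol=1e-8):
            raise ValidationError("distance matrix diagonal must be zero")
        self.frame = pd.DataFrame(
            (values + values.T) / 2.0, index=frame.index, columns=frame.columns
        )

    @classmethod
    def from_coords(cls, coords: dict[str, tuple[float, float]]) -> "GeoMatrix":
        return geo_distances(coords)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeoMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        frame.index = frame.index.astype(str)
        frame.columns = frame.columns.astype(str)
        return cls(frame)

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t")

    @property
    def locales(self) -> list[str]:
        return list(self.frame.index)

    def submatrix(self, locales: list[str]) -> np.ndarray:
        return self.frame.loc[locales, locales].to_numpy(dtype=float)


def geo_distances(coords: dict[str, tuple[float, float]]) -> GeoMatrix:
    """Great-circle (haversine) distance matrix in km from locale coordinates."""
    for locale, (lat, lon) in coords.items():
        if abs(lat) > 90:
            raise ValidationError(f"{locale}: latitude {lat} out of range")
        if abs(lon) > 180:
            raise ValidationError(f"{locale}: longitude {lon} out of range")
    names = list(coords)
    n = len(names)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = haversine_km(*coords[names[i]], *coords[names[j]])
            values[i, j] = values[j, i] = d
    return GeoMatrix(pd.DataFrame(values, index=names, columns=names))


@dataclass
class PipelineConfig:
    """Every threshold the pipeline depends on, pinned in one place.

    Defaults follow the study conditions: 275 bp trim, 97% identity OTUs,
    comparative filter of >=10 sequences with >=3 on each side of the barrier,
    10,000 permutations, alpha = 0.05.
    """

    trim_length: int = 275
    identity_threshold: float = 0.97
    min_otu_size: int = 10
    min_per_region: int = 3
    n_permutations: int = 10_000
    alpha: float = 0.05
    seed: int = 0
    month_filter: frozenset[str] | None = None
    chimera_check: bool = True
    amova_distance: str = "raw"  # "raw" or "k2p"
    gst_corrected: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.identity_threshold <= 1):
            raise ConfigError("identity_threshold must be in (0, 1]")
        if self.trim_length <= 0:
            raise ConfigError("trim_length must be positive")
        if self.n_permutations < 1:
            raise ConfigError("n_permutations must be >= 1")
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must be in (0, 1)")
        if self.min_otu_size < 2 or self.min_per_region < 1:
            raise ConfigError("min_otu_size >= 2 and min_per_region >= 1 required")
        if self.amova_distance not in ("raw", "k2p"):
            raise ConfigError("amova_distance must be 'raw' or 'k2p'")
        if self.month_filter is not None:
            object.__setattr__(self, "month_filter", frozenset(self.month_filter))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["month_filter"] is not None:
            d["month_filter"] = sorted(d["month_filter"])
        return d

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        if data.get("month_filter") is not None:
            data["month_filter"] = frozenset(data["month_filter"])
        return cls(**data)
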