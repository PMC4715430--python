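"""Structured-coalescent community simulator.

Generates communities of amplicon OTUs with known ground truth: each OTU's
genealogy is drawn from a structured coalescent over five demes (two west of a
barrier, three east), with within-region migration, optional cross-barrier
migration, and a merge of the two regions into one panmictic ancestral pool at
time tau looking backward.  Time is scaled so one pair of lineages within a
deme coalesces at rate 1 (deme-size-free units); tau and the migration rates
are in these units.  Sequences evolve under finite-sites Jukes-Cantor with
total mutation rate theta/2 per lineage per coalescent unit across the locus,
so the expected pairwise difference count in a panmictic deme is theta.

Genealogies come from msprime; mutation dropping is done directly on the tree
so that externally supplied genealogies can be mutated too.  Per-OTU totals
follow a truncated log-series (heavy-tailed, bounded to the observed 14-2507
range), and a configurable fraction of OTUs is "structured" (split at tau with
a clean or leaky barrier) while the rest are panmictic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import msprime
import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .io_config import SampleTable, SeqRead, write_sequences

#: locale -> (region, relative sampling effort); mirrors a five-locale design
#: with two western and three eastern sites and one heavily sampled eastern site
DEFAULT_DEMES: dict[str, tuple[str, int]] = {
    "K": ("west", 10),
    "C": ("west", 10),
    "L": ("east", 50),
    "A": ("east", 10),
    "T": ("east", 10),
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    n_otus: int = 31
    demes: dict[str, tuple[str, int]] = field(
        default_factory=lambda: dict(DEFAULT_DEMES)
    )
    theta: float = 3.0
    tau: float = 1.0
    m_within: float = 1.0
    m_between: float = 0.0
    seq_length: int = 275
    fraction_structured: float = 0.5
    logseries_p: float = 0.9965
    abundance_range: tuple[int, int] = (14, 2507)
    min_per_region: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seq_length < 1:
            raise ConfigError("seq_length must be >= 1")
        if min(self.theta, self.tau, self.m_within, self.m_between) < 0:
            raise ConfigError("rates and times must be nonnegative")
        if not (0 <= self.fraction_structured <= 1):
            raise ConfigError("fraction_structured must be in [0, 1]")
        regions = {r for r, _ in self.demes.values()}
        if len(regions) != 2:
            raise ConfigError("the simulator needs exactly two regions")

    @property
    def regions(self) -> dict[str, str]:
        return {d: r for d, (r, _) in self.demes.items()}

    @property
    def weights(self) -> dict[str, int]:
        return {d: w for d, (_, w) in self.demes.items()}


@dataclass
class SimulatedOtu:
    otu_id: str
    structured: bool
    tree: dendropy.Tree
    sequences: dict[str, str]  # tip label -> gap-free sequence
    deme_of_tip: dict[str, str]


@dataclass
class SimulatedCommunity:
    config: SimulationConfig
    otus: list[SimulatedOtu]
    reads: list[SeqRead]
    samples: SampleTable
    truth: pd.DataFrame

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "reads": outdir / "reads.fasta",
            "samples": outdir / "samples.tsv",
            "truth": outdir / "truth.tsv",
        }
        write_sequences(self.reads, paths["reads"])
        self.samples.to_tsv(paths["samples"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _subseed(rng: np.random.Generator) -> int:
    """A positive msprime-safe seed derived from the generator."""
    return int(rng.integers(1, 2**31 - 1))


def simulate_genealogy(
    sample_sizes: dict[str, int],
    regions: dict[str, str],
    tau: float,
    m_within: float,
    m_between: float,
    seed: int | np.random.Generator | None = None,
) -> tuple[dendropy.Tree, dict[str, str]]:
    """One structured-coalescent genealogy; returns (tree, tip -> deme map).

    tau <= 0 collapses to a single panmictic pool (deme labels are then pure
    bookkeeping).  Branch lengths are in coalescent units (pairwise
    coalescence rate 1 within a deme).
    """
    total = sum(sample_sizes.values())
    if total < 2:
        raise ValidationError("need at least two sampled lineages")
    demes = [d for d in sample_sizes if sample_sizes[d] > 0]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if tau > 0 and np.isinf(tau) and m_within == 0 and m_between == 0 and len(demes) > 1:
        raise ConfigError("isolated demes with tau = inf can never coalesce")

    if tau <= 0 or len(demes) == 1:
        ts = msprime.sim_ancestry(
            samples=total, population_size=1.0, ploidy=1, random_seed=_subseed(rng)
        )
        labels = []
        for deme in sample_sizes:
            labels.extend(f"{deme}.{i}" for i in range(sample_sizes[deme]))
        tip_of_node = {node: labels[k] for k, node in enumerate(ts.samples())}
    else:
        demography = msprime.Demography()
        for deme in sample_sizes:
            demography.add_population(name=deme, initial_size=1.0)
        demography.add_population(name="ancestral", initial_size=1.0)
        names = list(sample_sizes)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                rate = m_within if regions[a] == regions[b] else m_between
                if rate > 0:
                    demography.set_migration_rate(a, b, rate)
                    demography.set_migration_rate(b, a, rate)
        demography.add_population_split(
            time=tau, derived=names, ancestral="ancestral"
        )
        ts = msprime.sim_ancestry(
            samples={d: n for d, n in sample_sizes.items()},
            demography=demography,
            ploidy=1,
            random_seed=_subseed(rng),
        )
        counters = {d: 0 for d in sample_sizes}
        tip_of_node = {}
        pop_names = {pop.id: pop.metadata["name"] for pop in ts.populations()}
        for node in ts.samples():
            deme = pop_names[ts.node(node).population]
            tip_of_node[node] = f"{deme}.{counters[deme]}"
            counters[deme] += 1

    newick = ts.first().as_newick(node_labels={n: t for n, t in tip_of_node.items()})
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = True  # genealogies are rooted; dendropy defaults to unrooted
    deme_of_tip = {label: label.split(".")[0] for label in tip_of_node.values()}
    return tree, deme_of_tip


def mutate_sequences(
    tree: dendropy.Tree,
    theta: float,
    seq_length: int,
    seed: int | np.random.Generator | None = None,
) -> dict[str, str]:
    """Drop finite-sites Jukes-Cantor mutations on a genealogy.

    Mutation counts per branch are Poisson(theta/2 * length); each mutation
    hits a uniform site and substitutes a uniformly chosen different base.
    The ancestral sequence is uniform random.
    """
    if theta < 0:
        raise ValidationError("theta must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    root = tree.seed_node
    sequences: dict[int, np.ndarray] = {
        id(root): rng.choice(_BASES, size=seq_length)
    }
    out: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node is root:
            seq = sequences[id(root)]
        else:
            seq = sequences[id(node.parent_node)].copy()
            length = node.edge.length or 0.0
            n_mut = rng.poisson(theta / 2.0 * length)
            for _ in range(n_mut):
                site = int(rng.integers(seq_length))
                current = seq[site]
                choices = _BASES[_BASES != current]
                seq[site] = choices[int(rng.integers(3))]
        if node.is_leaf():
            out[node.taxon.label] = bytes(seq).decode("ascii")
        else:
            sequences[id(node)] = seq
    return out


def sample_abundances(
    n: int, rng: np.random.Generator, p: float = 0.9965, bounds: tuple[int, int] = (14, 2507)
) -> np.ndarray:
    """Per-OTU totals from a log-series truncated to ``bounds`` (heavy-tailed)."""
    lo, hi = bounds
    ks = np.arange(lo, hi + 1)
    weights = p**ks / ks
    weights /= weights.sum()
    return rng.choice(ks, size=n, p=weights)


def _allocate(
    total: int, weights: dict[str, int], regions: dict[str, str], min_per_region: int,
) -> dict[str, int]:
    """Largest-remainder proportional allocation with a per-region floor."""
    demes = list(weights)
    w = np.array([weights[d] for d in demes], dtype=float)
    w /= w.sum()
    raw = total * w
    counts = np.floor(raw).astype(int)
    remainder = total - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:remainder]] += 1
    alloc = dict(zip(demes, counts.tolist()))
    region_names = sorted(set(regions.values()))
    if total < 2 * min_per_region:
        raise ConfigError(f"total {total} cannot satisfy the per-region floor")
    for region in region_names:
        members = [d for d in demes if regions[d] == region]
        short = min_per_region - sum(alloc[d] for d in members)
        while short > 0:
            donors = [d for d in demes if regions[d] != region and alloc[d] > 0]
            donor = max(donors, key=lambda d: alloc[d])
            alloc[donor] -= 1
            alloc[members[0]] += 1
            short -= 1
    return alloc


def simulate_community(config: SimulationConfig) -> SimulatedCommunity:
    """Simulate a full community dataset (reads + sample table + truth labels).

    The first round(fraction_structured * n_otus) OTUs are barrier-structured
    (split at tau with migration m_between across the barrier); the rest are
    panmictic.  Reads replicate each simulated haplotype to its abundance and
    are spread over ten pitchers per locale.
    """
    rng = np.random.default_rng(config.seed)
    n_structured = int(round(config.fraction_structured * config.n_otus))
    totals = sample_abundances(
        config.n_otus, rng, p=config.logseries_p, bounds=config.abundance_range
    )
    regions = config.regions
    samples_frame = _pitcher_table(regions)
    samples = SampleTable(samples_frame)
    pitcher_of_locale: dict[str, list[str]] = {
        locale: samples_frame[samples_frame["locale"] == locale]["sample_id"].tolist()
        for locale in regions
    }

    otus: list[SimulatedOtu] = []
    reads: list[SeqRead] = []
    truth_rows = []
    for j in range(config.n_otus):
        structured = j < n_structured
        alloc = _allocate(
            int(totals[j]), config.weights, regions, config.min_per_region
        )
        tau = config.tau if structured else 0.0
        m_between = config.m_between if structured else config.m_within
        tree, deme_of_tip = simulate_genealogy(
            alloc, regions, tau, config.m_within, m_between, seed=rng
        )
        seqs = mutate_sequences(tree, config.theta, config.seq_length, seed=rng)
        otu_id = f"sim{j:03d}"
        otus.append(SimulatedOtu(otu_id, structured, tree, seqs, deme_of_tip))
        counters = {locale: 0 for locale in regions}
        for tip, seq in sorted(seqs.items()):
            locale = deme_of_tip[tip]
            pitchers = pitcher_of_locale[locale]
            pitcher = pitchers[counters[locale] % len(pitchers)]
            counters[locale] += 1
            reads.append(SeqRead(f"{otu_id}_{tip}", pitcher, seq))
        truth_rows.append(
            {
                "otu_id": otu_id,
                "structured": structured,
                "n_sequences": int(totals[j]),
                "tau": tau,
                "theta": config.theta,
            }
        )
    truth = pd.DataFrame(truth_rows)
    return SimulatedCommunity(config, otus, reads, samples, truth)


def _pitcher_table(regions: dict[str, str], pitchers_per_locale: int = 10) -> pd.DataFrame:
    """Ten pitchers per locale; one heavily sampled locale spans five months."""
    months_short = ["June", "August"]
    months_long = ["April", "May", "June", "July", "August"]
    rows = []
    for locale, region in regions.items():
        months = months_long if regions_is_focal(locale, regions) else months_short
        for k in range(pitchers_per_locale):
            rows.append(
                {
                    "sample_id": f"{locale}{k:02d}",
                    "locale": locale,
                    "region": region,
                    "month": months[k % len(months)],
                }
            )
    return pd.DataFrame(rows)


def regions_is_focal(locale: str, regions: dict[str, str]) -> bool:
    """The first eastern locale doubles as the temporally extended site."""
    east = [l for l, r in regions.items() if r == sorted(set(regions.values()))[0]]
    return bool(east) and locale == east[0]


def as_otu_cluster(sim_otu: SimulatedOtu, otu_id: int = 0):
    """View one simulated OTU as a clustered OTU (dereplicated haplotypes).

    Bridges the simulator to the per-OTU analysis path without running the
    clustering stage, for calibration and power studies.
    """
    from collections import Counter

    from .otu import OtuCluster, UniqueSeq

    by_bases: dict[str, UniqueSeq] = {}
    for tip, seq in sorted(sim_otu.sequences.items()):
        unique = by_bases.get(seq)
        if unique is None:
            unique = by_bases[seq] = UniqueSeq(bases=seq, abundance=0)
        unique.abundance += 1
        unique.member_read_ids.append(tip)
        unique.locale_counts[sim_otu.deme_of_tip[tip]] += 1
    members = sorted(by_bases.values(), key=lambda u: (-u.abundance, u.bases))
    return OtuCluster(
        otu_id=otu_id,
        centroid=members[0].bases,
        members=[(u, 1.0) for u in members],
    )
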