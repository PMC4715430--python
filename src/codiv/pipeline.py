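"""End-to-end orchestration with file-backed stages.

``run_pipeline`` chains the stage functions below; each stage reads its inputs
from and writes its outputs to the run directory, so the CLI subcommands (one
per stage) compose to exactly the same result as a single ``run-all``.  All
randomness is derived from the config seed plus fixed per-OTU/per-test stream
ids, so a rerun with the same inputs is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import community as comm
from . import popgen, structure
from .align import Alignment, center_star_align
from .errors import CodivError, SaturationError, ValidationError
from .io_config import GeoMatrix, PipelineConfig, SampleTable, read_sequences
from .otu import (
    OtuCluster,
    UniqueSeq,
    assign_region_counts,
    cluster_otus,
    dereplicate,
    filter_comparative,
    trim_reads,
)

log = logging.getLogger(__name__)

CLUSTERS_FILE = "clusters.json"
COMPARATIVE_FILE = "comparative.json"
DIVERSITY_FILE = "diversity.tsv"
STRUCTURE_FILE = "structure.tsv"


# ---------------------------------------------------------------------------
# stage: cluster


def stage_cluster(
    fasta: str | Path,
    samples_tsv: str | Path,
    config: PipelineConfig,
    outdir: str | Path,
    mode: str = "global",
) -> dict:
    """Trim, optionally month-filter, dereplicate and cluster; write clusters.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    samples = SampleTable.from_tsv(samples_tsv)
    samples.require_two_regions()
    reads = read_sequences(fasta)
    counts = {"reads_in": len(reads)}
    reads = trim_reads(reads, config.trim_length)
    counts["after_trim"] = len(reads)
    if config.month_filter is not None:
        months = samples.months_of_samples()
        reads = [r for r in reads if months[r.sample_id] in config.month_filter]
    counts["after_month_filter"] = len(reads)

    def one_pass(subset):
        uniques = dereplicate(subset, samples)
        result = cluster_otus(
            uniques, config.identity_threshold, chimera_check=config.chimera_check
        )
        return uniques, result

    payload: dict = {"mode": mode, "counts": counts, "config": config.to_dict()}
    if mode == "global":
        uniques, result = one_pass(reads)
        counts["uniques"] = len(uniques)
        counts["otus"] = len(result.clusters)
        counts["chimera_discarded_reads"] = sum(
            u.abundance for u, _ in result.chimeras
        )
        payload["otus"] = [_otu_to_json(o) for o in result.clusters]
        payload["chimeras"] = [
            {"bases": u.bases, "abundance": u.abundance, "parents": [v.parent1, v.parent2]}
            for u, v in result.chimeras
        ]
    elif mode == "per-locale":
        by_locale: dict[str, list] = {}
        for read in reads:
            by_locale.setdefault(samples.locale_of_sample(read.sample_id), []).append(read)
        payload["per_locale"] = {}
        for locale in sorted(by_locale):
            _, result = one_pass(by_locale[locale])
            payload["per_locale"][locale] = [_otu_to_json(o) for o in result.clusters]
        counts["locales"] = len(by_locale)
    else:
        raise ValidationError(f"unknown clustering mode {mode!r}")
    (outdir / CLUSTERS_FILE).write_text(json.dumps(payload, sort_keys=True))
    return payload


def _otu_to_json(otu: OtuCluster) -> dict:
    return {
        "otu_id": otu.otu_id,
        "centroid": otu.centroid,
        "annotation": otu.annotation,
        "members": [
            {
                "bases": u.bases,
                "abundance": u.abundance,
                "identity": identity,
                "locale_counts": dict(u.locale_counts),
                "read_ids": u.member_read_ids,
            }
            for u, identity in otu.members
        ],
    }


def _otu_from_json(data: dict) -> OtuCluster:
    from collections import Counter

    members = [
        (
            UniqueSeq(
                bases=m["bases"],
                abundance=m["abundance"],
                member_read_ids=list(m.get("read_ids", [])),
                locale_counts=Counter(m["locale_counts"]),
            ),
            m["identity"],
        )
        for m in data["members"]
    ]
    return OtuCluster(
        otu_id=data["otu_id"],
        centroid=data["centroid"],
        members=members,
        annotation=data.get("annotation"),
    )


# ---------------------------------------------------------------------------
# stage: comparative filter


def stage_filter(outdir: str | Path, config: PipelineConfig, samples_tsv: str | Path) -> dict:
    outdir = Path(outdir)
    payload = json.loads((outdir / CLUSTERS_FILE).read_text())
    samples = SampleTable.from_tsv(samples_tsv)
    otus = [_otu_from_json(o) for o in payload["otus"]]
    assign_region_counts(otus, samples)
    kept = filter_comparative(otus, config.min_otu_size, config.min_per_region)
    dropped = [o.otu_id for o in otus if o not in kept]
    out = {
        "otus": [
            {**_otu_to_json(o), "region_counts": o.region_counts} for o in kept
        ],
        "dropped_otu_ids": dropped,
        "counts": {"comparative_otus": len(kept), "dropped": len(dropped)},
    }
    (outdir / COMPARATIVE_FILE).write_text(json.dumps(out, sort_keys=True))
    return out


# ---------------------------------------------------------------------------
# stage: align


def stage_align(outdir: str | Path) -> list[Path]:
    """Center-star align each comparative OTU's haplotypes; write aligned FASTA."""
    outdir = Path(outdir)
    payload = json.loads((outdir / COMPARATIVE_FILE).read_text())
    aln_dir = outdir / "alignments"
    aln_dir.mkdir(exist_ok=True)
    paths = []
    for data in payload["otus"]:
        otu = _otu_from_json(data)
        uniques = [u for u, _ in otu.members]
        aln = center_star_align(uniques, labels=[f"h{i}" for i in range(len(uniques))])
        path = aln_dir / f"otu{otu.otu_id:04d}.fasta"
        aln.to_fasta(path)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# per-OTU analysis


def _expand_individuals(otu: OtuCluster) -> tuple[np.ndarray, np.ndarray]:
    """(hap_idx, locale) per individual, in deterministic member/locale order."""
    hap_idx: list[int] = []
    locales: list[str] = []
    for i, (unique, _) in enumerate(otu.members):
        for locale in sorted(unique.locale_counts):
            reps = unique.locale_counts[locale]
            hap_idx.extend([i] * reps)
            locales.extend([locale] * reps)
    return np.asarray(hap_idx), np.asarray(locales)


def _load_alignment(outdir: Path, otu: OtuCluster) -> Alignment:
    path = outdir / "alignments" / f"otu{otu.otu_id:04d}.fasta"
    if path.exists():
        from .align import ingest_alignment

        return ingest_alignment(path)
    uniques = [u for u, _ in otu.members]
    return center_star_align(uniques, labels=[f"h{i}" for i in range(len(uniques))])


def analyze_otu(
    otu: OtuCluster,
    samples: SampleTable,
    config: PipelineConfig,
    geo: GeoMatrix | None = None,
    alignment: Alignment | None = None,
    otu_index: int = 0,
) -> dict:
    """All per-OTU statistics as one community-table row (None = missing)."""
    notes: list[str] = []
    uniques = [u for u, _ in otu.members]
    weights = np.array([u.abundance for u in uniques], dtype=np.int64)
    if alignment is None:
        alignment = center_star_align(
            uniques, labels=[f"h{i}" for i in range(len(uniques))]
        )
    hap_idx, locales = _expand_individuals(otu)
    region_of = samples.region_map
    regions = np.array([region_of[l] for l in locales])
    row: dict = {
        "otu_id": otu.otu_id,
        "size": otu.size,
        "n_haplotypes": len(uniques),
        "group": otu.annotation or "all",
    }

    # diversity + Tajima's D
    try:
        stats = popgen.diversity_summary(alignment, weights)
        row.update(
            n=stats.n, S=stats.S, k_hat=stats.k_hat, pi=stats.pi, theta_w=stats.theta_w
        )
        D, null, reason = popgen.tajima_d(stats.n, stats.S, stats.k_hat)
        row["tajimas_d"] = D
        if D is not None:
            row["p_d"] = popgen.tajima_pvalue(
                D, null, S=stats.S,
                rng=np.random.default_rng([config.seed, otu_index, 1]),
            )
        else:
            row["p_d"] = None
            notes.append(f"D missing: {reason}")
    except CodivError as exc:
        notes.append(f"diversity failed: {exc}")
        row.update(n=None, S=None, k_hat=None, pi=None, theta_w=None,
                   tajimas_d=None, p_d=None)

    # raw pairwise differences among haplotypes
    diffs = valid = None
    if len(uniques) >= 2:
        diffs, valid = popgen.pairwise_diffs(alignment)

    # AMOVA
    row.update(phi_sc=None, phi_st=None, phi_ct=None,
               p_phi_sc=None, p_phi_st=None, p_phi_ct=None)
    try:
        if diffs is None:
            raise ValidationError("single haplotype; AMOVA undefined")
        dist = diffs
        if config.amova_distance == "k2p":
            dist = popgen.k2p(alignment)
        res = structure.amova(
            dist, locales, region_of, B=config.n_permutations,
            seed=np.random.default_rng([config.seed, otu_index, 2]),
            hap_idx=hap_idx,
        )
        row.update(
            phi_sc=res.phi_sc, phi_st=res.phi_st, phi_ct=res.phi_ct,
            p_phi_sc=res.p_sc, p_phi_st=res.p_st, p_phi_ct=res.p_ct,
        )
    except CodivError as exc:
        notes.append(f"AMOVA not computed: {exc}")

    # G_ST
    try:
        gst = popgen.gst_test(
            hap_idx, locales, B=config.n_permutations,
            seed=np.random.default_rng([config.seed, otu_index, 3]),
            corrected=config.gst_corrected,
        )
        row.update(gst=gst.G_ST, p_gst=gst.p_value)
        if gst.missing_reason:
            notes.append(f"G_ST missing: {gst.missing_reason}")
    except CodivError as exc:
        row.update(gst=None, p_gst=None)
        notes.append(f"G_ST not computed: {exc}")

    # GSI per region, on an NJ/K2P tree expanded to individuals
    for region in samples.regions:
        row[f"gsi_{region}"] = None
        row[f"p_gsi_{region}"] = None
    k2p_hap = None
    try:
        if len(uniques) < 3:
            raise ValidationError("fewer than 3 haplotypes; no tree")
        k2p_hap = popgen.k2p(alignment)
        tree = structure.nj_tree(
            [f"h{i}" for i in range(len(uniques))], k2p_hap
        )
        copies = {
            f"h{i}": [f"h{i}_{m}" for m in range(int(weights[i]))]
            for i in range(len(uniques))
        }
        tree = structure.expand_tips(structure.midpoint_root(tree), copies)
        # identical copies occupy distinct caterpillar positions; fill those
        # positions in seeded random order so the observed arrangement is
        # region-agnostic (a deterministic fill would cluster same-region
        # copies and bias the GSI upward)
        tip_rng = np.random.default_rng([config.seed, otu_index, 7])
        tip_region: dict[str, str] = {}
        for i in range(len(uniques)):
            hap_regions = regions[hap_idx == i]
            order = tip_rng.permutation(len(hap_regions))
            for m, reg in enumerate(hap_regions[order]):
                tip_region[f"h{i}_{m}"] = reg
        for gi, region in enumerate(samples.regions):
            if int(np.sum(regions == region)) < 2:
                notes.append(f"GSI {region}: fewer than 2 tips")
                continue
            res = structure.gsi_test(
                tree, tip_region, region, B=config.n_permutations,
                seed=np.random.default_rng([config.seed, otu_index, 4 + gi]),
            )
            row[f"gsi_{region}"] = res.gsi
            row[f"p_gsi_{region}"] = res.p_value
            if res.missing_reason:
                notes.append(f"GSI {region}: {res.missing_reason}")
    except SaturationError as exc:
        notes.append(f"K2P saturated: {exc}")
    except CodivError as exc:
        notes.append(f"GSI not computed: {exc}")

    # Mantel IBD on locale-level mean K2P
    row.update(mantel_r=None, p_mantel=None)
    try:
        if geo is None:
            raise ValidationError("no geographic distances supplied")
        present = sorted(set(locales))
        if len(present) < 3:
            raise ValidationError("fewer than 3 locales with sequences")
        if k2p_hap is None:
            k2p_hap = popgen.k2p(alignment)
        gen = _locale_mean_dist(k2p_hap, hap_idx, locales, present)
        res = structure.mantel_test(
            gen, geo.submatrix(present), B=config.n_permutations,
            seed=np.random.default_rng([config.seed, otu_index, 6]),
        )
        row.update(mantel_r=res.r, p_mantel=res.p_value)
    except SaturationError as exc:
        notes.append(f"Mantel: K2P saturated: {exc}")
    except CodivError as exc:
        notes.append(f"Mantel not computed: {exc}")

    row["notes"] = "; ".join(notes)
    return row


def _locale_mean_dist(
    hap_dist: np.ndarray, hap_idx: np.ndarray, locales: np.ndarray, order: list[str]
) -> np.ndarray:
    """Mean between-locale distance over individual pairs."""
    n_hap = hap_dist.shape[0]
    out = np.zeros((len(order), len(order)))
    counts = np.zeros((len(order), n_hap))
    for li, locale in enumerate(order):
        idx = hap_idx[locales == locale]
        counts[li] = np.bincount(idx, minlength=n_hap)
    sizes = counts.sum(axis=1)
    for a in range(len(order)):
        for b in range(a + 1, len(order)):
            total = counts[a] @ hap_dist @ counts[b]
            out[a, b] = out[b, a] = total / (sizes[a] * sizes[b])
    return out


# ---------------------------------------------------------------------------
# stage: stats + structure + community


def stage_stats(
    outdir: str | Path, config: PipelineConfig, samples_tsv: str | Path,
    geo: GeoMatrix | None = None,
) -> pd.DataFrame:
    outdir = Path(outdir)
    payload = json.loads((outdir / COMPARATIVE_FILE).read_text())
    samples = SampleTable.from_tsv(samples_tsv)
    rows = []
    for k, data in enumerate(payload["otus"]):
        otu = _otu_from_json(data)
        alignment = _load_alignment(outdir, otu)
        rows.append(
            analyze_otu(otu, samples, config, geo=geo, alignment=alignment, otu_index=k)
        )
    if rows:
        table = pd.DataFrame(rows)
    else:  # keep a stable header so downstream readers see an empty table
        table = pd.DataFrame(
            columns=[
                "otu_id", "size", "n_haplotypes", "group", "n", "S", "k_hat",
                "pi", "theta_w", "tajimas_d", "p_d", "phi_sc", "phi_st",
                "phi_ct", "p_phi_sc", "p_phi_st", "p_phi_ct", "gst", "p_gst",
                "mantel_r", "p_mantel", "notes",
            ]
        )
    table.to_csv(outdir / STRUCTURE_FILE, sep="\t", index=False, float_format="%.6g")
    return table


def stage_community(
    outdir: str | Path, config: PipelineConfig, table: pd.DataFrame | None = None,
    curves: list | None = None, metadata: dict | None = None,
) -> dict[str, Path]:
    outdir = Path(outdir)
    if table is None:
        table = pd.read_csv(outdir / STRUCTURE_FILE, sep="\t")
    tests = {
        name: pcol for name, pcol in comm.TEST_PCOLS.items() if pcol in table.columns
    }
    counts = comm.significance_counts(table, config.alpha, tests)
    gofs = [
        comm.chi_squared_gof(obs, total, config.alpha, test=name)
        for name, (obs, total) in counts.items()
        if total > 0
    ]
    return comm.build_report(
        outdir, table, gofs, curves or [], config, metadata=metadata
    )


# ---------------------------------------------------------------------------
# run-all


@dataclass
class RunManifest:
    config: dict
    counts: dict
    outputs: dict[str, str]

    def write(self, path: Path) -> None:
        path.write_text(
            json.dumps(
                {"config": self.config, "counts": self.counts, "outputs": self.outputs},
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )


def run_pipeline(
    fasta: str | Path,
    samples_tsv: str | Path,
    config: PipelineConfig,
    outdir: str | Path,
    mode: str = "global",
    geo: GeoMatrix | None = None,
) -> RunManifest:
    """Execute the full pipeline in ``outdir`` and return the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_json(outdir / "config.json")
    clusters = stage_cluster(fasta, samples_tsv, config, outdir, mode=mode)
    counts = dict(clusters["counts"])
    if mode == "per-locale":
        curves = []
        for locale, otus in sorted(clusters["per_locale"].items()):
            sizes = [
                sum(m["abundance"] for m in o["members"]) for o in otus
            ]
            total = sum(sizes)
            grid = _rarefaction_grid(total)
            curves.append(comm.rarefaction_curve(sizes, grid, locale=locale))
        paths = comm.build_report(
            outdir, pd.DataFrame(), [], curves, config,
            metadata={"counts": counts, "mode": mode},
        )
        manifest = RunManifest(config.to_dict(), counts, {k: str(v) for k, v in paths.items()})
        manifest.write(outdir / "manifest.json")
        return manifest

    filtered = stage_filter(outdir, config, samples_tsv)
    counts.update(filtered["counts"])
    stage_align(outdir)
    samples = SampleTable.from_tsv(samples_tsv)
    table = stage_stats(outdir, config, samples_tsv, geo=geo)

    # per-locale rarefaction of the global OTUs
    curves = []
    all_otus = [_otu_from_json(o) for o in clusters["otus"]]
    locale_sizes: dict[str, list[int]] = {}
    for otu in all_otus:
        for locale, n in otu.locale_counts.items():
            locale_sizes.setdefault(locale, []).append(n)
    for locale in sorted(locale_sizes):
        sizes = locale_sizes[locale]
        grid = _rarefaction_grid(sum(sizes))
        curves.append(comm.rarefaction_curve(sizes, grid, locale=locale))

    paths = stage_community(
        outdir, config, table=table, curves=curves,
        metadata={"counts": counts, "mode": mode, "seed": config.seed},
    )
    manifest = RunManifest(config.to_dict(), counts, {k: str(v) for k, v in paths.items()})
    manifest.write(outdir / "manifest.json")
    return manifest


def _rarefaction_grid(total: int, points: int = 12) -> list[int]:
    if total < 1:
        return []
    grid = np.unique(
        np.round(np.geomspace(1, total, num=min(points, total))).astype(int)
    )
    return grid.tolist()
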