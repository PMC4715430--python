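"""Community-level synthesis: significance matrix, chi-squared goodness-of-fit,
group aggregates, rarefaction and report emission.

The central question is whether more OTUs show significant structure (per
test) than the alpha * total expected under the community null of no shared
structure; that is a 1-df chi-squared goodness-of-fit on the
significant / not-significant split.  Totals are per test: an OTU only counts
toward a test's total when that test was computable for it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln

from .errors import ValidationError

#: community table column -> p-value column, for each reported test
TEST_PCOLS = {
    "phi_sc": "p_phi_sc",
    "phi_st": "p_phi_st",
    "phi_ct": "p_phi_ct",
    "gst": "p_gst",
    "gsi_east": "p_gsi_east",
    "gsi_west": "p_gsi_west",
    "mantel": "p_mantel",
}


@dataclass
class GofResult:
    test: str
    observed_significant: int
    total: int
    alpha: float
    expected_significant: float
    chi2: float
    df: int
    p_value: float


def significance_counts(
    table: pd.DataFrame, alpha: float, tests: dict[str, str] | None = None
) -> dict[str, tuple[int, int]]:
    """Per-test (observed significant, computable total) at strict p < alpha."""
    tests = tests or {k: v for k, v in TEST_PCOLS.items() if v in table.columns}
    out: dict[str, tuple[int, int]] = {}
    for name, pcol in tests.items():
        pvals = pd.to_numeric(table[pcol], errors="coerce")
        total = int(pvals.notna().sum())
        observed = int((pvals < alpha).sum())
        out[name] = (observed, total)
    return out


def chi_squared_gof(observed: int, total: int, alpha: float, test: str = "") -> GofResult:
    """1-df goodness-of-fit of the significant count against alpha * total."""
    if total <= 0:
        raise ValidationError("chi_squared_gof requires total > 0")
    if not (0 <= observed <= total):
        raise ValidationError("observed must lie in [0, total]")
    if not (0 < alpha < 1):
        raise ValidationError("alpha must be in (0, 1)")
    e1 = alpha * total
    e2 = (1.0 - alpha) * total
    chi2 = (observed - e1) ** 2 / e1 + ((total - observed) - e2) ** 2 / e2
    p = float(sps.chi2.sf(chi2, df=1))
    return GofResult(
        test=test,
        observed_significant=observed,
        total=total,
        alpha=alpha,
        expected_significant=e1,
        chi2=float(chi2),
        df=1,
        p_value=p,
    )


def group_aggregates(table: pd.DataFrame, group_col: str = "group") -> pd.DataFrame:
    """Median Tajima's D and mean pi / theta_w / G_ST per annotation group.

    Rows with a missing statistic are excluded from that statistic's
    aggregate; an "all" row summarises the whole table.
    """
    stats = {
        "tajimas_d": ("median_d", np.median),
        "pi": ("mean_pi", np.mean),
        "theta_w": ("mean_theta_w", np.mean),
        "gst": ("mean_gst", np.mean),
    }
    groups = [("all", table)]
    if group_col in table.columns:
        groups += [(g, sub) for g, sub in table.groupby(group_col, sort=True)]
    rows = []
    for name, sub in groups:
        row: dict[str, float | str | int] = {"group": name, "n_otus": len(sub)}
        for col, (out_name, fn) in stats.items():
            if col in sub.columns:
                vals = pd.to_numeric(sub[col], errors="coerce").dropna().to_numpy()
                row[out_name] = float(fn(vals)) if len(vals) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class RarefactionCurve:
    locale: str
    sizes: np.ndarray
    expected_richness: np.ndarray


def rarefaction_curve(otu_counts: list[int], grid: list[int], locale: str = "") -> RarefactionCurve:
    """Expected OTU richness in subsamples of each size on the grid.

    Hypergeometric expectation: E[S_m] = sum_i (1 - C(N-N_i, m) / C(N, m)).
    """
    counts = np.asarray(otu_counts, dtype=np.int64)
    if np.any(counts < 1):
        raise ValidationError("OTU counts must be >= 1")
    N = int(counts.sum())
    grid_arr = np.asarray(grid, dtype=np.int64)
    if np.any(grid_arr < 1) or np.any(grid_arr > N):
        raise ValidationError(f"subsample sizes must be in [1, {N}]")
    expected = np.empty(len(grid_arr))
    for gi, m in enumerate(grid_arr):
        terms = np.ones(len(counts))
        feasible = (N - counts) >= m  # otherwise the OTU is always seen
        nf = counts[feasible]
        log_ratio = (
            _log_comb(N - nf, m) - _log_comb(N, m)
        )
        terms[feasible] = 1.0 - np.exp(log_ratio)
        expected[gi] = terms.sum()
    return RarefactionCurve(locale=locale, sizes=grid_arr, expected_richness=expected)


def _log_comb(n, k) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def build_report(
    outdir: str | Path,
    table: pd.DataFrame,
    gofs: list[GofResult],
    curves: list[RarefactionCurve],
    config,
    metadata: dict | None = None,
    plot: bool = True,
) -> dict[str, Path]:
    """Write the community table, GOF table, significance matrix, rarefaction
    table (and plot), and run metadata; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["community_table"] = outdir / "community_table.tsv"
    table.to_csv(paths["community_table"], sep="\t", index=False, float_format="%.6g")

    gof_frame = pd.DataFrame(
        [
            {
                "test": g.test,
                "chi2": g.chi2,
                "df": g.df,
                "p_value": g.p_value,
                "observed_significant": g.observed_significant,
                "expected_significant": g.expected_significant,
                "total": g.total,
                "alpha": g.alpha,
            }
            for g in gofs
        ]
    )
    paths["gof_tests"] = outdir / "gof_tests.tsv"
    gof_frame.to_csv(paths["gof_tests"], sep="\t", index=False, float_format="%.6g")

    sig = table[["otu_id"]].copy() if "otu_id" in table.columns else pd.DataFrame()
    alpha = getattr(config, "alpha", 0.05)
    for name, pcol in TEST_PCOLS.items():
        if pcol in table.columns:
            pvals = pd.to_numeric(table[pcol], errors="coerce")
            sig[name] = np.where(pvals.isna(), "NA", (pvals < alpha).astype(int).astype(str))
    paths["significance_matrix"] = outdir / "significance_matrix.tsv"
    sig.to_csv(paths["significance_matrix"], sep="\t", index=False)

    if curves:
        rar = pd.concat(
            [
                pd.DataFrame(
                    {
                        "locale": c.locale,
                        "subsample_size": c.sizes,
                        "expected_richness": c.expected_richness,
                    }
                )
                for c in curves
            ],
            ignore_index=True,
        )
        paths["rarefaction"] = outdir / "rarefaction.tsv"
        rar.to_csv(paths["rarefaction"], sep="\t", index=False, float_format="%.6g")
        if plot:
            paths["rarefaction_plot"] = outdir / "rarefaction.png"
            _plot_rarefaction(curves, paths["rarefaction_plot"])

    meta = dict(metadata or {})
    meta["config"] = config.to_dict() if hasattr(config, "to_dict") else dict(config)
    meta["n_otus_reported"] = int(len(table))
    if len(table) == 0:
        meta["warnings"] = meta.get("warnings", []) + [
            "no OTUs passed the comparative filter; report is empty"
        ]
    paths["metadata"] = outdir / "run_metadata.json"
    paths["metadata"].write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return paths


def _plot_rarefaction(curves: list[RarefactionCurve], path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for curve in curves:
        ax.plot(curve.sizes, curve.expected_richness, marker="o", ms=3, label=curve.locale)
    ax.set_xlabel("sequences subsampled")
    ax.set_ylabel("expected OTU richness")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
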