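"""Bundled reference data from the published pitcher-plant community survey.

The 28S amplicon survey of the *Sarracenia alata* pitcher-fluid community
reported, for each of 31 operational taxonomic units spanning the Mississippi
River barrier (plus the host plant itself), per-OTU summary statistics and
per-test counts of OTUs with significant structure.  Those printed summaries
are bundled here as inputs for community-level recomputation: aggregate
statistics across taxonomic groups and chi-squared goodness-of-fit syntheses
of how many community members share structure with the host.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: per-test (number of OTUs significant at alpha = 0.05, number of OTUs for
#: which the test was computable) in the published community survey; the AMOVA
#: totals are 29 because two OTUs were excluded from that analysis
STRUCTURE_SIGNIFICANCE_COUNTS: dict[str, tuple[int, int]] = {
    "phi_sc": (7, 29),
    "phi_st": (12, 29),
    "phi_ct": (0, 29),
    "gst": (3, 31),
    "gsi_east": (7, 31),
    "gsi_west": (6, 31),
}


def load_community_stats(include_host: bool = False) -> pd.DataFrame:
    """Published per-OTU summary statistics (n, pi, theta_w, Tajima's D, G_ST).

    ``include_host`` keeps the host-plant chloroplast row; by default only the
    31 inquiline OTUs are returned.
    """
    with resources.files("codiv.data").joinpath("pitcher_community_stats.tsv").open() as fh:
        frame = pd.read_csv(fh, sep="\t")
    if not include_host:
        frame = frame[frame["group"] != "host_plant"].reset_index(drop=True)
    return frame
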