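"""IS-element insertion tallies and the site-preference randomization test.

Parallel IS150 insertions at the same base-pair site across
independently evolved genomes could reflect either selection or
insertion-site bias. The randomization test assumes the null model that
IS elements can only insert at sites where insertions were observed in
a catalog of sequenced genomes, with probability proportional to the
observed insertion count at each site, and asks how often a focal site
would collect at least the observed number of hits when the group's
total insertion count is held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .stats import mann_whitney_two_tailed, rng_for

__all__ = [
    "InsertionEvent",
    "SiteCatalog",
    "tally_insertions",
    "site_preference_test",
    "is150_accumulation",
]


@dataclass(frozen=True)
class InsertionEvent:
    """One new IS-element insertion in one evolved genome."""

    clone_id: str
    treatment: str
    element: str  # IS family: IS150, IS1, IS186, IS3, ISRSO11, ...
    site: int  # 1-based position (target-site duplications merged upstream)
    gene_label: str = ""
    relation: str = ""  # coding | promoter | spanning | ""

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError("element must be non-empty")


@dataclass(frozen=True)
class SiteCatalog:
    """Observed insertion sites with pooled insertion counts as weights.

    A site exists in the catalog only if at least one insertion was
    observed there, so every weight is >= 1. Sites that fall within one
    target-site duplication span should be merged into one site before
    construction (see :func:`merge_tsd_sites`).
    """

    sites: tuple[int, ...]
    weights: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sites) != len(self.weights):
            raise ValueError("sites and weights must align")
        if len(self.sites) == 0:
            raise ValueError("catalog must contain at least one site")
        if any(w < 1 for w in self.weights):
            raise ValueError("weights must be >= 1 (a site exists only if observed)")
        if len(set(self.sites)) != len(self.sites):
            raise ValueError("duplicate sites; merge counts first")

    def probabilities(self) -> np.ndarray:
        w = np.asarray(self.weights, dtype=float)
        return w / w.sum()

    def index_of(self, site: int) -> int:
        try:
            return self.sites.index(site)
        except ValueError:
            raise ValueError(f"site {site} not in catalog") from None


def merge_tsd_sites(
    positions: Iterable[int], tsd_span_bp: int = 0
) -> dict[int, int]:
    """Collapse positions within one target-site-duplication span.

    Positions within ``tsd_span_bp`` of a previously seen (smaller)
    position are mapped onto it; returns a position -> canonical-site
    map. With span 0 every position is its own site.
    """
    canon: dict[int, int] = {}
    anchor: Optional[int] = None
    for pos in sorted(set(positions)):
        if anchor is None or pos - anchor > tsd_span_bp:
            anchor = pos
        canon[pos] = anchor
    return canon


def tally_insertions(
    events: Sequence[InsertionEvent], group_by: str = "site"
) -> pd.DataFrame:
    """Exact insertion counts per site, gene, element or treatment.

    Returns a two-column frame (group value, count) in deterministic
    (sorted) order; empty input yields an empty frame.
    """
    field = {"site": "site", "gene": "gene_label", "element": "element",
             "treatment": "treatment"}.get(group_by)
    if field is None:
        raise ValueError(f"unknown grouping {group_by!r}")
    df = pd.DataFrame(
        [(getattr(e, field),) for e in events], columns=[group_by]
    )
    if df.empty:
        return pd.DataFrame(columns=[group_by, "count"])
    out = df.groupby(group_by).size().rename("count").reset_index()
    return out.sort_values(group_by, kind="stable").reset_index(drop=True)


def site_preference_test(
    catalog: SiteCatalog,
    n_insertions: int,
    observed_at_focal: int,
    focal_site: int,
    n_boot: int = 100_000,
    statistic: str = "focal",
    seed: int = 0,
) -> float:
    """Randomization p-value for parallel insertions at one site.

    Each of ``n_boot`` replicates draws ``n_insertions`` sites i.i.d.
    with probability proportional to catalog weights (one multinomial
    draw) and records either the count at the focal site
    (``statistic='focal'``) or the maximum count over all sites
    (``statistic='max'``, a family-wise reading). The p-value is the
    fraction of replicates whose statistic is at least
    ``observed_at_focal``. The group's total insertion count is held
    fixed.
    """
    if observed_at_focal < 0 or n_insertions < observed_at_focal:
        raise ValueError("need 0 <= observed_at_focal <= n_insertions")
    if n_insertions == 0:
        return 1.0  # only reachable when observed_at_focal == 0
    focal_idx = catalog.index_of(focal_site)
    probs = catalog.probabilities()
    rng = rng_for(seed, "is-site-preference")

    if statistic == "focal":
        # The focal count marginal of a multinomial is binomial.
        draws = rng.binomial(n_insertions, probs[focal_idx], size=n_boot)
        return float(np.mean(draws >= observed_at_focal))
    if statistic == "max":
        hits = 0
        chunk = max(1, min(n_boot, 20_000_000 // max(1, probs.size)))
        done = 0
        while done < n_boot:
            m = min(chunk, n_boot - done)
            counts = rng.multinomial(n_insertions, probs, size=m)
            hits += int(np.sum(counts.max(axis=1) >= observed_at_focal))
            done += m
        return hits / n_boot
    raise ValueError("statistic must be 'focal' or 'max'")


def is150_accumulation(
    events: Sequence[InsertionEvent], element: str = "IS150"
) -> tuple[pd.DataFrame, float]:
    """Per-genome IS150 counts by treatment, with a Mann-Whitney p-value.

    Genomes appear with their observed count of ``element`` insertions;
    the two-tailed Mann-Whitney U test compares the treatment groups.
    """
    df = pd.DataFrame(
        [(e.clone_id, e.treatment, e.element) for e in events],
        columns=["clone_id", "treatment", "element"],
    )
    roster = df[["clone_id", "treatment"]].drop_duplicates()
    counts = (
        df[df["element"] == element]
        .groupby("clone_id")
        .size()
        .reindex(roster["clone_id"], fill_value=0)
        .rename("n_insertions")
        .reset_index()
        .merge(roster, on="clone_id")
    )
    trts = sorted(counts["treatment"].unique())
    if len(trts) != 2:
        raise ValueError("is150_accumulation requires exactly 2 treatments")
    x = counts.loc[counts["treatment"] == trts[0], "n_insertions"].to_numpy()
    y = counts.loc[counts["treatment"] == trts[1], "n_insertions"].to_numpy()
    return counts, mann_whitney_two_tailed(x, y)


__all__.append("merge_tsd_sites")
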