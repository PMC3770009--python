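"""Feature-set attribution: tabulate a selected feature set by family, by
window site, or by subtype within one family.

These tables answer "which kinds of features, at which positions around the
central lysine, carry the signal" for any selected subset — e.g. the optimal
IFS prefix — mirroring the family/site/subtype breakdowns commonly reported
for window-based PTM predictors.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .encoding import FAMILIES
from .mrmr import RankedList

GROUPINGS = ("family", "site", "subtype")


@dataclass
class AttributionTable:
    grouping: str
    counts: dict
    total: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"group": list(self.counts), "count": list(self.counts.values())}
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def tabulate(selected, descriptors, grouping: str, family_filter: str | None = None) -> AttributionTable:
    """Count selected descriptors grouped by family, site, or subtype.

    ``selected`` holds 1-based feature indices. ``family_filter`` restricts
    the tabulation to one family first (e.g. PSSM features by target residue
    or by site). Group labels with zero counts are included for the full
    label set of the grouping, so tables are directly comparable.
    """
    if grouping not in GROUPINGS:
        raise ValueError(f"unknown grouping {grouping!r}")
    by_index = {d.index: d for d in descriptors}
    chosen = []
    for idx in selected:
        idx = int(idx)
        if idx not in by_index:
            raise ValueError(f"invalid feature index {idx}")
        chosen.append(by_index[idx])
    if family_filter is not None:
        if family_filter not in FAMILIES:
            raise ValueError(f"unknown family {family_filter!r}")
        chosen = [d for d in chosen if d.family == family_filter]
    if grouping == "family":
        labels = list(FAMILIES)
        key = lambda d: d.family  # noqa: E731
    elif grouping == "site":
        labels = sorted({d.site for d in descriptors})
        key = lambda d: d.site  # noqa: E731
    else:
        if family_filter is None:
            raise ValueError("subtype grouping requires family_filter")
        labels = list(dict.fromkeys(d.subtype for d in descriptors if d.family == family_filter))
        key = lambda d: d.subtype  # noqa: E731
    counts = {lab: 0 for lab in labels}
    for d in chosen:
        counts[key(d)] += 1
    return AttributionTable(grouping=grouping, counts=counts, total=len(chosen))


def top_features_report(ranked: RankedList, k: int, descriptors) -> pd.DataFrame:
    """The first k ranked features with their (site, family, subtype) addresses."""
    if k > len(ranked):
        raise ValueError(f"k={k} exceeds ranked-list length {len(ranked)}")
    by_index = {d.index: d for d in descriptors}
    rows = []
    for rank, idx in enumerate(ranked.top(k), start=1):
        d = by_index[int(idx)]
        rows.append(
            {
                "rank": rank,
                "feature_index": d.index,
                "site": d.site,
                "family": d.family,
                "subtype": d.subtype,
                "score": float(ranked.scores[rank - 1]),
            }
        )
    return pd.DataFrame(rows, columns=["rank", "feature_index", "site", "family", "subtype", "score"])


def plot_attribution(table: AttributionTable, ax=None, title: str | None = None):
    """Bar chart of an attribution table; returns the matplotlib axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3.2))
    labels = [str(k) for k in table.counts]
    ax.bar(labels, list(table.counts.values()), color="#4878a8")
    ax.set_xlabel(table.grouping)
    ax.set_ylabel("selected features")
    if title:
        ax.set_title(title)
    return ax
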