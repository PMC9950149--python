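"""CNV subclone partitioning of malignant spots and niche-dominance analysis.

Malignant spots are clustered by average-linkage hierarchical clustering on
their CNV score vectors (Euclidean distance on the fixed [0.7, 1.3] scale);
the dendrogram is descended until every cluster is pure with respect to its
signature-event presence pattern (per-spot event-region mean crossing the
1.2 gain / 0.8 loss threshold), and pattern-identical branches are merged.
Subclones are ordered parsimoniously, ancestral clones (fewest events) first.
A subclone is niche dominant when strictly more than 75% of its spots carry
one niche label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .cnv import CNVProfile, SignatureEvent, GAIN_THRESHOLD, LOSS_THRESHOLD


@dataclass
class SubcloneTable:
    assignments: pd.Series  # spot -> subclone id ("SC1", ...)
    patterns: pd.DataFrame  # subclone x event presence (bool)
    spot_counts: pd.Series  # subclone -> n spots
    niche_fractions: pd.DataFrame | None = None  # subclone x niche
    dominant: pd.Series | None = None  # subclone -> niche or None
    events: list[SignatureEvent] = field(default_factory=list)


def event_presence(profile: CNVProfile, events: list[SignatureEvent], spots=None) -> pd.DataFrame:
    """Per-spot boolean presence of each signature event (region mean crossing
    the event's gain/loss threshold)."""
    scores = profile.scores if spots is None else profile.scores.loc[spots]
    cols = {}
    for i, e in enumerate(events):
        a = scores.iloc[:, e.start_index : e.end_index].mean(axis=1)
        cols[f"{e.chrom}:{e.direction}:{i}"] = (
            a > GAIN_THRESHOLD if e.direction == "gain" else a < LOSS_THRESHOLD
        )
    return pd.DataFrame(cols, index=scores.index)


def cluster_subclones(
    profile: CNVProfile,
    malignant_mask: pd.Series,
    events: list[SignatureEvent],
) -> SubcloneTable:
    """Partition malignant spots into event-pattern-pure subclones."""
    if len(events) < 1:
        raise ValueError("need at least one signature event")
    mask = malignant_mask.reindex(profile.scores.index).fillna(False).astype(bool)
    spots = profile.scores.index[mask]
    if len(spots) < 2:
        raise ValueError("need at least two malignant spots")
    X = profile.scores.loc[spots].to_numpy()
    presence = event_presence(profile, events, spots)
    patterns = presence.to_numpy()

    link = hierarchy.linkage(X, method="average", metric="euclidean")
    tree = hierarchy.to_tree(link)

    groups: list[np.ndarray] = []

    def descend(node) -> None:
        leaves = np.asarray(node.pre_order(lambda n: n.id))
        pats = patterns[leaves]
        if (pats == pats[0]).all():
            groups.append(leaves)
        elif node.is_leaf():
            groups.append(leaves)
        else:
            descend(node.get_left())
            descend(node.get_right())

    descend(tree)

    # merge dendrogram branches that carry the identical event pattern
    merged: dict[tuple, list[int]] = {}
    for leaves in groups:
        key = tuple(patterns[leaves[0]])
        merged.setdefault(key, []).extend(leaves.tolist())

    # parsimonious order: ancestral subclones carry the fewest events
    ordered = sorted(merged.items(), key=lambda kv: (sum(kv[0]), -len(kv[1]), kv[0]))
    assignments = pd.Series(index=spots, dtype=object)
    pattern_rows, counts = {}, {}
    for rank, (key, members) in enumerate(ordered, start=1):
        name = f"SC{rank}"
        assignments.iloc[members] = name
        pattern_rows[name] = dict(zip(presence.columns, key))
        counts[name] = len(members)
    return SubcloneTable(
        assignments=assignments,
        patterns=pd.DataFrame(pattern_rows).T.astype(bool),
        spot_counts=pd.Series(counts, name="n_spots"),
        events=list(events),
    )


def niche_dominance(
    table: SubcloneTable, niche_labels: pd.Series, threshold: float = 0.75
) -> SubcloneTable:
    """Annotate each subclone with its niche distribution; a subclone is
    dominant in a niche iff strictly more than ``threshold`` of its spots
    carry that niche label."""
    labels = niche_labels.reindex(table.assignments.index)
    if labels.isna().any():
        bad = list(labels.index[labels.isna()])[:5]
        raise ValueError(f"spots without a niche label: {bad}")
    niches = sorted(labels.unique())
    rows, dominant = {}, {}
    for sc in table.spot_counts.index:
        members = labels[table.assignments == sc]
        if len(members) == 0:
            raise ValueError(f"subclone {sc} has no spots")
        frac = members.value_counts(normalize=True).reindex(niches, fill_value=0.0)
        rows[sc] = frac
        top = frac.idxmax()
        dominant[sc] = top if frac.loc[top] > threshold else None
    table.niche_fractions = pd.DataFrame(rows).T
    table.dominant = pd.Series(dominant, name="dominant_niche", dtype=object)
    return table
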