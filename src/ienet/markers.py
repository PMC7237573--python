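"""Edge-biomarker selection, the sCI composite index, and discrimination.

The per-sample composite index over a marker set M is

    sCI = (PCCin / PCCout) * SDin

where, for that sample,

* ``PCCin``  — mean |sPCC(x, y)| over unordered pairs with x, y in M;
* ``PCCout`` — mean |sPCC(x, y)| over pairs with x in M, y outside M;
* ``SDin``   — mean absolute deviation |x - mu_ref| over the members of M.

A large sCI flags a sample whose marker taxa are strongly co-perturbed
relative to their coupling with the rest of the community, and whose marker
abundances sit far from the reference means — the dynamic-network-biomarker
signature of a disturbed state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .edges import EdgePairScores, _canonical
from .exceptions import GroupError, MarkerError
from .reference import ReferenceNetwork


@dataclass
class MarkerSet:
    """Taxa belonging to the top-ranked edge-pairs of a sample or group."""

    members: frozenset
    origin: str = ""  # sample id or group label
    n_edge_pairs: int = 0  # the m used at selection
    support: dict = field(default_factory=dict)  # taxon -> contributing samples

    def __post_init__(self) -> None:
        if not self.members:
            raise MarkerError("marker set is empty")
        self.members = frozenset(self.members)

    def __iter__(self):
        return iter(sorted(self.members, key=str))

    def __len__(self) -> int:
        return len(self.members)

    def recurrent(self, min_samples: int = 2) -> list:
        """Members contributed by at least ``min_samples`` samples."""
        return sorted(
            (t for t, s in self.support.items() if len(s) >= min_samples), key=str
        )


@dataclass
class SCIScore:
    """One sample's composite index against one marker set, with components."""

    sample_id: str
    marker_id: str
    pcc_in: float
    pcc_out: float
    sd_in: float
    sci: float
    flags: list = field(default_factory=list)


def select_edge_biomarkers(scores: EdgePairScores, m: int = 10) -> MarkerSet:
    """Marker set = union of taxa in the top-m edge-pairs by |fourth-order sPCC|.

    Ties break lexicographically on the canonical (edge_1, edge_2) pair so the
    selection is deterministic.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    ranked = sorted(
        scores.pairs(), key=lambda t: (-abs(t[2]), _canonical(*t[0]), _canonical(*t[1]))
    )
    if not ranked:
        raise MarkerError("no edge-pairs available for biomarker selection")
    members: set = set()
    for e1, e2, _ in ranked[:m]:
        members.update(e1)
        members.update(e2)
    return MarkerSet(members=frozenset(members), origin=scores.sample_id, n_edge_pairs=m)


def compute_sci(
    ref: ReferenceNetwork,
    sample,
    marker: MarkerSet,
    spcc_matrix: pd.DataFrame | None = None,
    sample_id: str = "",
) -> SCIScore:
    """Evaluate the composite index of one sample against one marker set.

    ``spcc_matrix`` may be passed to reuse a precomputed full sPCC matrix;
    otherwise it is computed from the reference model. Degenerate situations
    follow fixed conventions, each recorded in ``flags``:

    * singleton marker — no in-pairs, ``pcc_in = 0`` hence ``sci = 0``;
    * ``pcc_out = 0`` with ``pcc_in > 0`` — sentinel ``sci = +inf``;
    * marker covering every retained taxon — rejected (PCCout undefined).
    """
    members = sorted(marker.members, key=str)
    unknown = [t for t in members if t not in ref.taxa_]
    if unknown:
        raise MarkerError(f"marker taxa not in reference model: {unknown[:5]}")
    outside = [t for t in ref.taxa_ if t not in marker.members]
    if not outside:
        raise MarkerError("marker set equals the taxon universe; PCCout is undefined")
    if spcc_matrix is None:
        spcc_matrix = ref.spcc_matrix(sample)
    flags: list = []

    if len(members) == 1:
        pcc_in = 0.0
        flags.append("singleton_marker")
    else:
        sub = spcc_matrix.loc[members, members].to_numpy()
        iu = np.triu_indices(len(members), k=1)
        pcc_in = float(np.mean(np.abs(sub[iu])))

    pcc_out = float(np.mean(np.abs(spcc_matrix.loc[members, outside].to_numpy())))

    dev = ref.deviation(sample)
    member_idx = [ref._index_of(t) for t in members]
    sd_in = float(np.mean(dev[member_idx]))

    if pcc_out == 0.0:
        if pcc_in == 0.0:
            sci = 0.0
            flags.append("zero_pcc_out")
        else:
            sci = math.inf
            flags.append("zero_pcc_out")
    else:
        sci = pcc_in / pcc_out * sd_in
    return SCIScore(
        sample_id=str(sample_id),
        marker_id=marker.origin,
        pcc_in=pcc_in,
        pcc_out=pcc_out,
        sd_in=sd_in,
        sci=sci,
        flags=flags,
    )


def union_markers(per_sample: dict, design, group: str) -> MarkerSet:
    """Union of per-sample marker sets across one group.

    ``per_sample`` maps sample id -> :class:`MarkerSet`. The returned set
    records, per taxon, which samples contributed it, so that taxa recurring
    across a whole disease group can be reported as robust.
    """
    samples = [s for s in design.samples_in(group) if s in per_sample]
    if not samples:
        raise GroupError(f"no marker sets available for group {group!r}")
    support: dict = {}
    for s in samples:
        for t in per_sample[s].members:
            support.setdefault(t, set()).add(s)
    m = max(per_sample[s].n_edge_pairs for s in samples)
    return MarkerSet(
        members=frozenset(support), origin=group, n_edge_pairs=m, support=support
    )


def sci_table(scores: list[SCIScore]) -> pd.DataFrame:
    """Long-format table of sCI scores (one row per sample x marker set)."""
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in scores],
            "marker_set": [s.marker_id for s in scores],
            "pcc_in": [s.pcc_in for s in scores],
            "pcc_out": [s.pcc_out for s in scores],
            "sd_in": [s.sd_in for s in scores],
            "sci": [s.sci for s in scores],
            "flags": [";".join(s.flags) for s in scores],
        }
    )
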