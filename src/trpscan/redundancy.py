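"""Greedy centroid clustering at an identity threshold.

Collapses a hit set into clusters whose members all exceed a pairwise
identity threshold to one representative (centroid) sequence, the standard
pre-phylogeny redundancy reduction.  Semantics follow the greedy first-match
scheme of the widely used centroid clusterers: sequences are processed in
decreasing length order (ties on id), each joins the first centroid it
exceeds the threshold against, otherwise it founds a new cluster.  Every
output is audited against the two defining properties: members are more than
``threshold`` identical to their centroid, and no two centroids exceed the
threshold against each other.
"""
from __future__ import annotations

import dataclasses
from typing import Sequence

from Bio import Align

from .io import ProteinRecord


class RedundancyError(ValueError):
    pass


@dataclasses.dataclass
class IdentityCluster:
    centroid_id: str
    member_ids: list[str]
    identities_to_centroid: dict[str, float]


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(a: str, b: str) -> float:
    """Percent identity under global alignment (match +1, mismatch -1, gap
    open -10, extend -1): 100 * matches / alignment columns, excluding
    columns that lie in a terminal gap run of either sequence.

    Symmetric by construction: the pair is ordered canonically before
    aligning so alternative optimal alignments cannot break the symmetry.
    """
    if not a or not b:
        raise RedundancyError("empty sequence")
    if b < a:
        a, b = b, a
    alignment = _ALIGNER.align(a, b)[0]
    ra, rb = str(alignment[0]), str(alignment[1])
    n = len(ra)

    def terminal_run(s: str) -> tuple[int, int]:
        lead = len(s) - len(s.lstrip("-"))
        trail = len(s) - len(s.rstrip("-"))
        return lead, n - trail

    la, ua = terminal_run(ra)
    lb, ub = terminal_run(rb)
    lo, hi = max(la, lb), min(ua, ub)
    matches = sum(1 for k in range(lo, hi) if ra[k] == rb[k] and ra[k] != "-")
    columns = hi - lo
    if columns == 0:
        return 0.0
    return 100.0 * matches / columns


def greedy_cluster(
    records: Sequence[ProteinRecord], threshold_percent: float = 80.0
) -> list[IdentityCluster]:
    """Greedy first-match centroid clustering; audited on return."""
    ordered = sorted(records, key=lambda r: (-len(r.seq), r.id))
    clusters: list[IdentityCluster] = []
    centroids: list[ProteinRecord] = []
    for rec in ordered:
        joined = False
        for cl, cen in zip(clusters, centroids):
            ident = pairwise_identity(rec.seq, cen.seq)
            if ident > threshold_percent:
                cl.member_ids.append(rec.id)
                cl.identities_to_centroid[rec.id] = ident
                joined = True
                break
        if not joined:
            clusters.append(
                IdentityCluster(
                    centroid_id=rec.id,
                    member_ids=[rec.id],
                    identities_to_centroid={rec.id: 100.0},
                )
            )
            centroids.append(rec)
    audit_clusters(clusters, records, threshold_percent)
    return clusters


def audit_clusters(
    clusters: Sequence[IdentityCluster],
    records: Sequence[ProteinRecord],
    threshold_percent: float,
) -> None:
    """Assert the centroid-clustering contract on an output.

    Every member exceeds the threshold against its centroid, and no centroid
    exceeds the threshold against another centroid (greedy join uses a strict
    '>', so a failed join proves '<=')."""
    by_id = {r.id: r for r in records}
    for cl in clusters:
        cen = by_id[cl.centroid_id]
        if cl.centroid_id not in cl.member_ids:
            raise RedundancyError(f"centroid {cl.centroid_id} is not a member of its cluster")
        for mid in cl.member_ids:
            if mid == cl.centroid_id:
                continue
            ident = pairwise_identity(by_id[mid].seq, cen.seq)
            if not ident > threshold_percent:
                raise RedundancyError(
                    f"member {mid} is only {ident:.2f}% identical to centroid {cl.centroid_id}"
                )
    for i, ca in enumerate(clusters):
        for cb in clusters[i + 1 :]:
            ident = pairwise_identity(by_id[ca.centroid_id].seq, by_id[cb.centroid_id].seq)
            if ident > threshold_percent:
                raise RedundancyError(
                    f"centroids {ca.centroid_id} and {cb.centroid_id} are "
                    f"{ident:.2f}% identical (> {threshold_percent}%)"
                )


def extract_centroids(
    clusters: Sequence[IdentityCluster], records: Sequence[ProteinRecord]
) -> list[ProteinRecord]:
    """One representative record per cluster, in cluster order."""
    by_id = {r.id: r for r in records}
    return [by_id[cl.centroid_id] for cl in clusters]


def clusters_to_tsv(clusters: Sequence[IdentityCluster], path) -> None:
    with open(path, "w") as fh:
        fh.write("member_id\tcentroid_id\tidentity\n")
        for cl in clusters:
            for mid in cl.member_ids:
                fh.write(f"{mid}\t{cl.centroid_id}\t{cl.identities_to_centroid[mid]:.2f}\n")
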