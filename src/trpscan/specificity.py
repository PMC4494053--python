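"""Mechanism-specific alignment positions: physico-chemical column
conservation (0-11), two-group multi-Relief (mR) scores with a permutation
z-test, the complete-disjunctness filter, and push/pull/neither calls for
query sequences.

The mR statistic used here is the all-pairs mismatch-difference form:

    mR(c) = D_between(c) - D_within(c)

where D_between is the fraction of cross-group sequence pairs whose residues
differ at column c, and D_within the corresponding fraction over within-group
pairs (both groups pooled).  Gaps count as a 21st symbol.  This replaces the
original method's nearest-neighbour weighting with a deterministic,
exhaustively checkable statistic that is equivalent in the two-group,
well-separated regime this analysis targets.
"""
from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io import Alignment, GAP_INDEX

N_SYMBOLS = 22  # 20 residues + gap + X

# ---------------------------------------------------------------------------
# Physico-chemical conservation (0..11)
# ---------------------------------------------------------------------------

#: the fixed 10-property table (Livingstone/Barton-style classes)
PROPERTY_TABLE: dict[str, frozenset[str]] = {
    "hydrophobic": frozenset("ILVCAGMFYWHKT"),
    "polar": frozenset("YWHKREQDNSTC"),
    "small": frozenset("VCAGDNSTP"),
    "tiny": frozenset("AGS"),
    "aliphatic": frozenset("ILV"),
    "aromatic": frozenset("FYWH"),
    "positive": frozenset("HKR"),
    "negative": frozenset("DE"),
    "charged": frozenset("HKRDE"),
    "proline": frozenset("P"),
}


def conservation_score_column(column: str) -> int | None:
    """Conservation of one column on the 0..11 scale.

    11 iff the column is a single repeated residue with no gaps; otherwise
    the number of properties (0..10) whose status is uniform across the
    column -- possessed by all residues, or possessed by none.  A gap carries
    no properties, so it breaks every all-have status but leaves none-have
    statuses checkable.  All-gap columns have no score (None).
    """
    symbols = set(column)
    residues = symbols - {"-"}
    if not residues:
        return None
    if len(residues) == 1 and "-" not in symbols:
        return 11
    score = 0
    has_gap = "-" in symbols
    for members in PROPERTY_TABLE.values():
        if all(r in members for r in residues) and not has_gap:
            score += 1
        elif all(r not in members for r in residues):
            score += 1
    return score


def conservation_scores(alignment: Alignment) -> list[int | None]:
    return [conservation_score_column(alignment.column(j)) for j in range(alignment.n_cols)]


# ---------------------------------------------------------------------------
# multi-Relief scores and permutation z-test
# ---------------------------------------------------------------------------


class SpecificityError(ValueError):
    pass


def _group_rows(alignment: Alignment, labels: Mapping[str, str]):
    push = [i for i, name in enumerate(alignment.ids) if labels.get(name) == "push"]
    pull = [i for i, name in enumerate(alignment.ids) if labels.get(name) == "pull"]
    if not push or not pull:
        raise SpecificityError("both push and pull groups must be non-empty")
    return push, pull


def _symbol_matrix(alignment: Alignment) -> np.ndarray:
    mat = alignment.to_indices().astype(np.int64)
    return mat  # 0..19 residues, 20 gap, 21 X; all are distinct symbols


def _mr_from_counts(cp: np.ndarray, cl: np.ndarray, n_push: int, n_pull: int) -> np.ndarray:
    """mR per column from per-group symbol counts (..., L, S)."""
    same_between = (cp * cl).sum(axis=-1) / (n_push * n_pull)
    d_between = 1.0 - same_between
    within_pairs = n_push * (n_push - 1) / 2 + n_pull * (n_pull - 1) / 2
    mism_within = (
        (n_push**2 - (cp**2).sum(axis=-1)) / 2 + (n_pull**2 - (cl**2).sum(axis=-1)) / 2
    )
    d_within = mism_within / within_pairs if within_pairs > 0 else 0.0
    return d_between - d_within


def mr_scores(alignment: Alignment, labels: Mapping[str, str]) -> np.ndarray:
    """Per-column mR = D_between - D_within over the push and pull groups.

    Rows not labelled push or pull (e.g. queries) are excluded from the
    statistic.  Gaps count as a 21st symbol.  mR lies in [-1, 1].
    """
    push, pull = _group_rows(alignment, labels)
    mat = _symbol_matrix(alignment)
    L = alignment.n_cols
    onehot = np.zeros((alignment.n_seqs, L, N_SYMBOLS))
    rows = np.arange(alignment.n_seqs)[:, None]
    cols = np.arange(L)[None, :]
    onehot[rows, cols, mat] = 1.0
    cp = onehot[push].sum(axis=0)
    cl = onehot[pull].sum(axis=0)
    return _mr_from_counts(cp, cl, len(push), len(pull))


def permutation_z(
    alignment: Alignment,
    labels: Mapping[str, str],
    n_permutations: int = 1000,
    z_threshold: float = 3.0,
    rng_seed: int = 0,
) -> tuple[np.ndarray, set[int]]:
    """Permutation z-scores for the per-column mR statistic.

    Group labels are shuffled n_permutations times over the push+pull rows;
    z(c) = (mR_obs(c) - mean_perm(c)) / sd_perm(c).  Columns whose permuted
    scores have zero spread get no z (NaN) and are never significant.  The
    significant set keeps columns with z strictly above z_threshold
    (one-sided).
    """
    if n_permutations < 100:
        raise SpecificityError("n_permutations must be >= 100")
    push, pull = _group_rows(alignment, labels)
    group_rows = push + pull
    n_push = len(push)
    mat = _symbol_matrix(alignment)[group_rows]  # (g, L)
    g, L = mat.shape
    onehot = np.zeros((g, L * N_SYMBOLS))
    rows = np.repeat(np.arange(g), L)
    flat = (np.arange(L)[None, :] * N_SYMBOLS + mat).ravel()
    onehot[rows, flat] = 1.0

    obs_sel = np.zeros((1, g))
    obs_sel[0, :n_push] = 1.0
    mr_obs = _mr_from_counts(
        (obs_sel @ onehot).reshape(L, N_SYMBOLS),
        ((1 - obs_sel) @ onehot).reshape(L, N_SYMBOLS),
        n_push,
        g - n_push,
    )

    rng = np.random.default_rng(rng_seed)
    sel = np.zeros((n_permutations, g))
    for p in range(n_permutations):
        sel[p, rng.permutation(g)[:n_push]] = 1.0
    cp = (sel @ onehot).reshape(n_permutations, L, N_SYMBOLS)
    cl = ((1 - sel) @ onehot).reshape(n_permutations, L, N_SYMBOLS)
    mr_perm = _mr_from_counts(cp, cl, n_push, g - n_push)  # (P, L)
    mean = mr_perm.mean(axis=0)
    sd = mr_perm.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (mr_obs - mean) / np.where(sd == 0, 1.0, sd), np.nan)
    significant = {int(c) for c in np.nonzero(np.nan_to_num(z, nan=-np.inf) > z_threshold)[0]}
    return z, significant


def disjunct_sites(
    alignment: Alignment,
    labels: Mapping[str, str],
    significant: set[int],
) -> tuple[set[int], dict[int, tuple[frozenset[str], frozenset[str]]]]:
    """Significant columns whose push and pull residue sets share nothing.

    Gaps, if present in either group at a column, participate in the
    disjointness test as a residue symbol.
    """
    push, pull = _group_rows(alignment, labels)
    result: set[int] = set()
    residue_sets: dict[int, tuple[frozenset[str], frozenset[str]]] = {}
    for c in sorted(significant):
        col = alignment.column(c)
        pset = frozenset(col[i] for i in push)
        lset = frozenset(col[i] for i in pull)
        if not pset & lset:
            result.add(c)
            residue_sets[c] = (pset, lset)
    return result, residue_sets


# ---------------------------------------------------------------------------
# Query classification
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class ColumnStats:
    column_index: int  # 0-based
    conservation: int | None
    mr_score: float
    z: float | None
    disjunct: bool
    push_residues: frozenset[str]
    pull_residues: frozenset[str]


@dataclasses.dataclass
class QueryCall:
    query_id: str
    call: str  # "push", "pull" or "ambiguous"
    votes: dict[int, str]  # 0-based column -> "push"/"pull"/"neither"


@dataclasses.dataclass
class SpecificityReport:
    columns: list[ColumnStats]
    significant_sites: list[int]
    disjunct_sites: list[int]
    query_calls: dict[str, QueryCall]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# column indices are 0-based\n")
            fh.write("column\tconservation\tmr\tz\tdisjunct\tpush_set\tpull_set\n")
            for cs in self.columns:
                cons = "" if cs.conservation is None else str(cs.conservation)
                z = "" if cs.z is None or math.isnan(cs.z) else f"{cs.z:.3f}"
                fh.write(
                    f"{cs.column_index}\t{cons}\t{cs.mr_score:.4f}\t{z}\t"
                    f"{int(cs.disjunct)}\t{''.join(sorted(cs.push_residues))}\t"
                    f"{''.join(sorted(cs.pull_residues))}\n"
                )

    def calls_to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("query_id\tcall\tvotes\n")
            for qid in sorted(self.query_calls):
                qc = self.query_calls[qid]
                votes = ",".join(f"{c}:{v}" for c, v in sorted(qc.votes.items()))
                fh.write(f"{qid}\t{qc.call}\t{votes}\n")


def classify_queries(
    alignment: Alignment,
    labels: Mapping[str, str],
    disjunct: set[int],
    residue_sets: Mapping[int, tuple[frozenset[str], frozenset[str]]],
    query_ids: Sequence[str],
) -> dict[str, QueryCall]:
    """Vote each query at every disjunct site; overall call is "pull" iff all
    sites vote pull, "push" iff all vote push, otherwise "ambiguous".  A gap
    or an unseen residue at a disjunct site votes "neither"."""
    calls: dict[str, QueryCall] = {}
    for qid in query_ids:
        row = alignment.row_of(qid)
        votes: dict[int, str] = {}
        for c in sorted(disjunct):
            res = row[c]
            pset, lset = residue_sets[c]
            if res == "-":
                votes[c] = "neither"
            elif res in pset:
                votes[c] = "push"
            elif res in lset:
                votes[c] = "pull"
            else:
                votes[c] = "neither"
        vals = set(votes.values())
        if votes and vals == {"pull"}:
            call = "pull"
        elif votes and vals == {"push"}:
            call = "push"
        else:
            call = "ambiguous"
        calls[qid] = QueryCall(qid, call, votes)
    return calls


def analyse(
    alignment: Alignment,
    labels: Mapping[str, str],
    n_permutations: int = 1000,
    z_threshold: float = 3.0,
    rng_seed: int = 0,
) -> SpecificityReport:
    """Full specificity pipeline: conservation, mR, permutation z,
    disjunctness filter and query calls."""
    cons = conservation_scores(alignment)
    mr = mr_scores(alignment, labels)
    z, significant = permutation_z(
        alignment, labels, n_permutations=n_permutations,
        z_threshold=z_threshold, rng_seed=rng_seed,
    )
    disjunct, residue_sets = disjunct_sites(alignment, labels, significant)
    push, pull = _group_rows(alignment, labels)
    group_rows = set(push) | set(pull)
    columns = []
    for c in range(alignment.n_cols):
        col = alignment.column(c)
        pset = frozenset(col[i] for i in push)
        lset = frozenset(col[i] for i in pull)
        columns.append(
            ColumnStats(
                column_index=c,
                conservation=cons[c],
                mr_score=float(mr[c]),
                z=float(z[c]) if not math.isnan(z[c]) else None,
                disjunct=c in disjunct,
                push_residues=pset,
                pull_residues=lset,
            )
        )
    query_ids = [
        name for i, name in enumerate(alignment.ids) if i not in group_rows
    ]
    calls = classify_queries(alignment, labels, disjunct, residue_sets, query_ids)
    return SpecificityReport(
        columns=columns,
        significant_sites=sorted(significant),
        disjunct_sites=sorted(disjunct),
        query_calls=calls,
    )
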