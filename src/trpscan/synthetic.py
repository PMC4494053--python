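"""Synthetic protein superfamilies with known ground truth.

The generator emulates the statistical regime of a metazoan ion-channel
superfamily study: six divergent subfamilies sharing a transmembrane
"channel" core, tandem N-terminal ankyrin repeat arrays of configurable
count, two mechanism groups ("push"/"pull") separated at a planted set of
completely disjunct alignment columns, fragmented variants missing
N-terminal repeats, and unrelated background decoys.

Mutation model: substitution only, uniform over the 19 alternative residues;
no indels inside the channel core, so planted alignments stay
column-addressable.  Indels enter only through :func:`fragment_records`.
Background residue frequencies are uniform over the 20 amino acids by
default (simplest null; real frequencies are a config option).
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import AMINO_ACIDS, Alignment, ProteinRecord

N_AA = 20


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the field."""


@dataclasses.dataclass
class SyntheticConfig:
    """Study conditions for the synthetic superfamily.

    Divergences are per-site substitution probabilities.  Subfamily
    consensuses are mutated from one ancestral core at
    ``subfamily_divergence``; members are mutated from their consensus at
    ``within_subfamily_divergence``.  The defaults give six clearly separated
    subfamilies whose members are ~90% identical within and ~10-30% identical
    between subfamilies.
    """

    n_subfamilies: int = 6
    seqs_per_subfamily: int = 30
    channel_length: int = 200
    subfamily_divergence: float = 0.7
    within_subfamily_divergence: float = 0.05
    #: map subfamily label -> number of tandem ankyrin units at the N-terminus
    ankyrin_repeat_count: dict[str, int] = dataclasses.field(
        default_factory=lambda: {"fam_N": 28, "fam_A": 8}
    )
    ankyrin_unit_length: int = 33
    ankyrin_unit_divergence: float = 0.10
    n_decoys: int = 60
    decoy_length_range: tuple[int, int] = (150, 600)
    rng_seed: int = 0
    background: np.ndarray | None = None

    def subfamily_labels(self) -> list[str]:
        base = ["fam_N", "fam_A", "fam_C", "fam_M", "fam_ML", "fam_V"]
        if self.n_subfamilies <= len(base):
            return base[: self.n_subfamilies]
        return base + [f"fam_X{k}" for k in range(self.n_subfamilies - len(base))]

    def validate(self) -> None:
        for field in ("n_subfamilies", "seqs_per_subfamily", "channel_length",
                      "ankyrin_unit_length", "n_decoys"):
            if getattr(self, field) < 0:
                raise ConfigError(f"{field} must be >= 0")
        for field in ("subfamily_divergence", "within_subfamily_divergence",
                      "ankyrin_unit_divergence"):
            v = getattr(self, field)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{field} must be in [0, 1]")
        if self.within_subfamily_divergence >= self.subfamily_divergence:
            raise ConfigError(
                "within_subfamily_divergence must be < subfamily_divergence "
                "(planted subfamilies would not be recoverable)"
            )
        lo, hi = self.decoy_length_range
        if lo <= 0 or hi < lo:
            raise ConfigError("decoy_length_range must be a positive (lo, hi) with lo <= hi")
        for lab, cnt in self.ankyrin_repeat_count.items():
            if cnt < 0:
                raise ConfigError(f"ankyrin_repeat_count[{lab!r}] must be >= 0")


@dataclasses.dataclass
class GroundTruth:
    """Planted labels for every generated record."""

    family_of: dict[str, str] = dataclasses.field(default_factory=dict)
    repeat_count_of: dict[str, int] = dataclasses.field(default_factory=dict)
    #: (0-based column index, push residue set, pull residue set)
    disjunct_columns: list[tuple[int, frozenset[str], frozenset[str]]] = dataclasses.field(
        default_factory=list
    )
    group_of: dict[str, str] = dataclasses.field(default_factory=dict)
    #: 1-based inclusive channel-core span on each family member
    channel_span_of: dict[str, tuple[int, int]] = dataclasses.field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("protein_id\tfamily\tgroup\trepeat_count\n")
            for pid in sorted(self.family_of):
                fh.write(
                    f"{pid}\t{self.family_of[pid]}\t{self.group_of.get(pid, '')}\t"
                    f"{self.repeat_count_of.get(pid, 0)}\n"
                )

    def site_plan_to_json(self, path: str | Path) -> None:
        """Disjunct-column plan; column indices are 0-based in this file."""
        obj = [
            {"column": c, "push": sorted(p), "pull": sorted(q)}
            for c, p, q in self.disjunct_columns
        ]
        Path(path).write_text(json.dumps(obj, indent=1))


def _random_seq(rng: np.random.Generator, length: int, bg: np.ndarray) -> np.ndarray:
    return rng.choice(N_AA, size=length, p=bg)


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    """Substitute each site with probability *rate*, uniformly over the 19
    alternatives."""
    out = seq.copy()
    hit = rng.random(seq.size) < rate
    n_hit = int(hit.sum())
    if n_hit:
        shifts = rng.integers(1, N_AA, size=n_hit)
        out[hit] = (out[hit] + shifts) % N_AA
    return out


def _decode(seq: np.ndarray) -> str:
    return "".join(AMINO_ACIDS[k] for k in seq)


def generate_superfamily(config: SyntheticConfig) -> tuple[list[ProteinRecord], GroundTruth]:
    """Generate labelled subfamily members plus decoys.

    One random ancestral channel core; each subfamily derives its consensus by
    mutating the ancestor at ``subfamily_divergence``; members mutate their
    consensus at ``within_subfamily_divergence``.  Families listed in
    ``ankyrin_repeat_count`` carry an N-terminal tandem array of mutated
    copies of one shared ankyrin unit consensus.  Decoys are i.i.d.
    background-frequency sequences.
    """
    config.validate()
    bg = np.full(N_AA, 1.0 / N_AA) if config.background is None else config.background
    rng = np.random.default_rng(config.rng_seed)
    ancestor = _random_seq(rng, config.channel_length, bg)
    unit_consensus = _random_seq(rng, config.ankyrin_unit_length, bg)
    records: list[ProteinRecord] = []
    truth = GroundTruth()
    for label in config.subfamily_labels():
        consensus = _mutate(rng, ancestor, config.subfamily_divergence)
        n_units = config.ankyrin_repeat_count.get(label, 0)
        for k in range(config.seqs_per_subfamily):
            pid = f"{label}_{k:03d}"
            channel = _mutate(rng, consensus, config.within_subfamily_divergence)
            units = [
                _mutate(rng, unit_consensus, config.ankyrin_unit_divergence)
                for _ in range(n_units)
            ]
            nterm = np.concatenate(units) if units else np.empty(0, dtype=channel.dtype)
            seq = _decode(np.concatenate([nterm, channel]))
            records.append(ProteinRecord(pid, seq))
            truth.family_of[pid] = label
            truth.repeat_count_of[pid] = n_units
            truth.channel_span_of[pid] = (nterm.size + 1, nterm.size + channel.size)
    for k in range(config.n_decoys):
        pid = f"decoy_{k:03d}"
        lo, hi = config.decoy_length_range
        length = int(rng.integers(lo, hi + 1))
        records.append(ProteinRecord(pid, _decode(_random_seq(rng, length, bg))))
        truth.family_of[pid] = "decoy"
        truth.repeat_count_of[pid] = 0
    return records, truth


def generate_unit_alignment(config: SyntheticConfig, n_rows: int = 12) -> Alignment:
    """Gapless alignment of mutated copies of the ankyrin unit consensus.

    Deterministic given the config seed (drawn from a dedicated child stream,
    so it does not disturb :func:`generate_superfamily`).
    """
    config.validate()
    bg = np.full(N_AA, 1.0 / N_AA) if config.background is None else config.background
    base_rng = np.random.default_rng(config.rng_seed)
    unit_rng = np.random.default_rng(config.rng_seed + 1_000_003)
    _ = _random_seq(base_rng, config.channel_length, bg)  # skip ancestor draw
    unit_consensus = _random_seq(base_rng, config.ankyrin_unit_length, bg)
    rows = [
        _decode(_mutate(unit_rng, unit_consensus, config.ankyrin_unit_divergence))
        for _ in range(n_rows)
    ]
    return Alignment([f"unit_{i:02d}" for i in range(n_rows)], rows)


def channel_alignment(
    records: Sequence[ProteinRecord], truth: GroundTruth, include: Sequence[str] | None = None
) -> Alignment:
    """Stack the (gapless, equal-length) channel cores of family members."""
    ids, rows = [], []
    for rec in records:
        if truth.family_of.get(rec.id) == "decoy":
            continue
        if include is not None and rec.id not in include:
            continue
        start, end = truth.channel_span_of[rec.id]
        ids.append(rec.id)
        rows.append(rec.seq[start - 1 : end])
    return Alignment(ids, rows)


# ---------------------------------------------------------------------------
# Push/pull alignments with planted disjunct columns
# ---------------------------------------------------------------------------

#: the pushpull-default preset plants the number of completely disjunct sites
#: observed in the study system this generator emulates
PUSHPULL_DEFAULT = dict(
    n_push=8, n_pull=8, n_query=4, n_columns=300, n_disjunct=17, noise=0.10
)


def generate_pushpull_alignment(
    n_push: int,
    n_pull: int,
    n_query: int,
    n_columns: int,
    n_disjunct: int,
    noise: float,
    rng_seed: int,
) -> tuple[Alignment, GroundTruth]:
    """Alignment of push-group, pull-group and query rows.

    At each planted disjunct column, push rows draw from a push residue set
    and pull rows from a disjoint pull set, with no cross-contamination.
    Other columns share one background residue with per-row substitution
    noise.  Query rows copy the pull residue at every disjunct site and are
    otherwise background-with-noise (mimicking query paralogs that comply
    with a pull mechanism).
    """
    if n_disjunct > n_columns:
        raise ConfigError("n_disjunct must be <= n_columns")
    if not 0.0 <= noise <= 1.0:
        raise ConfigError("noise must be in [0, 1]")
    if n_push <= 0 or n_pull <= 0:
        raise ConfigError("n_push and n_pull must be >= 1")
    rng = np.random.default_rng(rng_seed)
    n_rows = n_push + n_pull + n_query
    base = _random_seq(rng, n_columns, np.full(N_AA, 1.0 / N_AA))
    mat = np.tile(base, (n_rows, 1))
    # per-row noise on every column (disjunct columns are overwritten below)
    for r in range(n_rows):
        mat[r] = _mutate(rng, mat[r], noise)
    disjunct_cols = np.sort(rng.choice(n_columns, size=n_disjunct, replace=False))
    truth = GroundTruth()
    ids: list[str] = (
        [f"push_{i:02d}" for i in range(n_push)]
        + [f"pull_{i:02d}" for i in range(n_pull)]
        + [f"query_{i:02d}" for i in range(n_query)]
    )
    for i, pid in enumerate(ids):
        truth.group_of[pid] = "push" if i < n_push else ("pull" if i < n_push + n_pull else "query")
        truth.family_of[pid] = "pushpull"
    for c in disjunct_cols:
        perm = rng.permutation(N_AA)
        push_set = perm[:2]
        pull_set = perm[2:4]
        mat[:n_push, c] = rng.choice(push_set, size=n_push)
        mat[n_push : n_push + n_pull, c] = rng.choice(pull_set, size=n_pull)
        mat[n_push + n_pull :, c] = pull_set[0]  # queries copy a pull residue
        truth.disjunct_columns.append(
            (
                int(c),
                frozenset(AMINO_ACIDS[k] for k in push_set),
                frozenset(AMINO_ACIDS[k] for k in pull_set),
            )
        )
    rows = ["".join(AMINO_ACIDS[k] for k in mat[r]) for r in range(n_rows)]
    return Alignment(ids, rows), truth


def generate_pushpull_default(rng_seed: int) -> tuple[Alignment, GroundTruth]:
    return generate_pushpull_alignment(rng_seed=rng_seed, **PUSHPULL_DEFAULT)


# ---------------------------------------------------------------------------
# Fragmented gene-model variants
# ---------------------------------------------------------------------------


def fragment_records(
    records: Sequence[ProteinRecord],
    truth: GroundTruth,
    fraction: float,
    rng_seed: int,
    min_removed: int = 2,
) -> list[ProteinRecord]:
    """Truncate a fraction of repeat-bearing records from the N-terminus.

    Emulates fragmented gene models that lack N-terminal exons: a random
    number (>= min_removed) of whole ankyrin units is removed, leaving the
    channel core intact.  ``truth.repeat_count_of`` and channel spans are
    updated in place.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ConfigError("fraction must be in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    out: list[ProteinRecord] = []
    for rec in records:
        count = truth.repeat_count_of.get(rec.id, 0)
        if count < min_removed or rng.random() >= fraction:
            out.append(rec)
            continue
        n_removed = int(rng.integers(min_removed, count + 1))
        span = truth.channel_span_of.get(rec.id)
        unit_len = (span[0] - 1) // count if span else (len(rec.seq) // count)
        cut = n_removed * unit_len
        new = ProteinRecord(rec.id, rec.seq[cut:])
        out.append(new)
        truth.repeat_count_of[rec.id] = count - n_removed
        if span:
            truth.channel_span_of[rec.id] = (span[0] - cut, span[1] - cut)
    return out
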