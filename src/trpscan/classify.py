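"""Competitive family classification: scan proteins against the subfamily
models plus the unspecific model, filter hits on E-value and model coverage,
and assign each protein to the subfamily of its most significant hit.

A protein whose best hit is the unspecific (pooled) model is "excluded" -- it
likely belongs to a distantly related channel family rather than to any of
the modelled subfamilies.  "Most significant" means smallest E-value; exact
ties (including the common case of two E-values both underflowing to 0) are
broken on the larger bit score, then on the model name.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .io import ProteinRecord
from .profiles import Hit, ProfileModel, evalue, score_sequence


class ClassificationError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class ThresholdProfile:
    """Named E-value/coverage filter profile.

    "census" mirrors a database-wide census scan (strict E-value plus a model
    coverage requirement); "genome" mirrors a per-genome scan where fragmented
    gene models must still be caught (looser E-value, no coverage filter).
    """

    name: str
    evalue_threshold: float
    coverage_threshold: float


THRESHOLD_PROFILES = {
    "census": ThresholdProfile("census", 1e-25, 0.80),
    "genome": ThresholdProfile("genome", 1e-10, 0.0),
}


@dataclasses.dataclass
class ClassificationResult:
    protein_id: str
    verdict: str  # subfamily label, "excluded" or "unclassified"
    best_hit: Hit | None
    all_significant_hits: list[Hit]


def scan(
    models: Sequence[ProfileModel],
    records: Sequence[ProteinRecord],
    evalue_threshold: float = 1e-25,
    coverage_threshold: float = 0.80,
    database_size: int | None = None,
) -> list[Hit]:
    """All hits with E strictly below the threshold and model coverage
    (match columns used / consensus length) at or above the coverage
    threshold.  Coverage is measured on the model, not the protein."""
    db_size = len(records) if database_size is None else database_size
    hits: list[Hit] = []
    for rec in records:
        for model in models:
            h = score_sequence(model, rec)
            h.e_value = evalue(model, h.bit_score, db_size)
            coverage = h.model_cols_matched / model.consensus_length
            if h.e_value < evalue_threshold and coverage >= coverage_threshold:
                hits.append(h)
    return hits


def assign_family(
    hits_for_one_protein: Sequence[Hit],
    unspecific_name: str = "unspecific",
    protein_id: str = "",
) -> ClassificationResult:
    """Best-hit verdict for one protein's significant hits; an empty hit list
    yields "unclassified"."""
    hits = list(hits_for_one_protein)
    if not hits:
        return ClassificationResult(protein_id, "unclassified", None, [])
    ids = {h.protein_id for h in hits}
    if len(ids) > 1:
        raise ClassificationError(f"hits from multiple proteins: {sorted(ids)}")
    best = min(hits, key=lambda h: (h.e_value, -h.bit_score, h.model_name))
    verdict = "excluded" if best.model_name == unspecific_name else best.model_name
    return ClassificationResult(
        protein_id=hits[0].protein_id,
        verdict=verdict,
        best_hit=best,
        all_significant_hits=hits,
    )


def classify_records(
    models: Sequence[ProfileModel],
    unspecific: ProfileModel,
    records: Sequence[ProteinRecord],
    profile: ThresholdProfile | str = "census",
    database_size: int | None = None,
) -> list[ClassificationResult]:
    """Scan + competitive assignment; proteins without significant hits are
    "unclassified"."""
    if isinstance(profile, str):
        if profile not in THRESHOLD_PROFILES:
            raise ClassificationError(f"unknown threshold profile {profile!r}")
        profile = THRESHOLD_PROFILES[profile]
    hits = scan(
        list(models) + [unspecific],
        records,
        evalue_threshold=profile.evalue_threshold,
        coverage_threshold=profile.coverage_threshold,
        database_size=database_size,
    )
    by_protein: dict[str, list[Hit]] = {}
    for h in hits:
        by_protein.setdefault(h.protein_id, []).append(h)
    results = []
    for rec in records:
        mine = by_protein.get(rec.id, [])
        if not mine:
            results.append(ClassificationResult(rec.id, "unclassified", None, []))
        else:
            results.append(assign_family(mine, unspecific_name=unspecific.name))
    return results


def benchmark(
    results: Iterable[ClassificationResult], true_family_of: dict[str, str]
) -> pd.DataFrame:
    """Per-family sensitivity and selectivity plus a macro-average row.

    sensitivity_f = fraction of family-f proteins assigned verdict f;
    selectivity_f = fraction of verdict-f proteins truly in family f.
    Families without records get absent (NaN) metrics, not zero.
    """
    results = list(results)
    missing = [r.protein_id for r in results if r.protein_id not in true_family_of]
    if missing:
        raise ClassificationError(f"records without a true label: {missing[:5]}")
    families = sorted(set(true_family_of.values()) - {"decoy"})
    rows = []
    for fam in families:
        of_family = [r for r in results if true_family_of[r.protein_id] == fam]
        with_verdict = [r for r in results if r.verdict == fam]
        sens = (
            sum(1 for r in of_family if r.verdict == fam) / len(of_family)
            if of_family
            else float("nan")
        )
        sel = (
            sum(1 for r in with_verdict if true_family_of[r.protein_id] == fam)
            / len(with_verdict)
            if with_verdict
            else float("nan")
        )
        rows.append({"family": fam, "n": len(of_family), "sensitivity": sens, "selectivity": sel})
    frame = pd.DataFrame(rows)
    macro = {
        "family": "macro",
        "n": int(frame["n"].sum()),
        "sensitivity": frame["sensitivity"].mean(skipna=True),
        "selectivity": frame["selectivity"].mean(skipna=True),
    }
    return pd.concat([frame, pd.DataFrame([macro])], ignore_index=True)


def hits_to_tsv(hits: Sequence[Hit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tmodel\tbit_score\te_value\tenv_start\tenv_end\tcols_matched\n")
        for h in hits:
            fh.write(
                f"{h.protein_id}\t{h.model_name}\t{h.bit_score:.3f}\t{h.e_value:.3e}\t"
                f"{h.envelope_start}\t{h.envelope_end}\t{h.model_cols_matched}\n"
            )


def verdicts_to_tsv(results: Sequence[ClassificationResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tverdict\tbest_model\tbest_evalue\tbest_bits\tn_hits\n")
        for r in results:
            if r.best_hit is None:
                fh.write(f"{r.protein_id}\t{r.verdict}\t\t\t\t0\n")
            else:
                b = r.best_hit
                fh.write(
                    f"{r.protein_id}\t{r.verdict}\t{b.model_name}\t{b.e_value:.3e}\t"
                    f"{b.bit_score:.3f}\t{len(r.all_significant_hits)}\n"
                )
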