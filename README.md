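# trpscan

Subfamily-discriminative profile models for ion-channel superfamilies:
competitive best-hit classification, redundancy clustering, tandem
ankyrin-repeat counting and mechanism-specific alignment positions.

## The problem

TRP (transient receptor potential) channels form a metazoan superfamily of
six-transmembrane cation channels with several deeply diverged subfamilies
(TRP-A/C/M/ML/N/V/PKD).  Generic domain models match all of them at once, so
assigning a protein to a *specific* subfamily requires custom,
subfamily-discriminative profiles and a competitive assignment rule.  The
mechanosensory subfamily TRP-N additionally carries an N-terminal tandem
array of ~28 ankyrin repeats (the putative gating spring), whose count is a
strong marker for intact versus fragmented gene models, and its paralogs
split into "push" and "pull" gating mechanisms distinguishable at a small
set of completely disjunct alignment positions.

`trpscan` implements that analysis pipeline end to end, exercised on
synthetic superfamilies with planted ground truth so every stage is testable
without external databases:

1. **Profile models** — position-specific match/insert/delete profiles built
   from alignments with background-mixture pseudocounts, scored by local
   Viterbi log-odds in bits, with E-values from a method-of-moments Gumbel
   fit to random-sequence scores: `E = N · exp(−λ(S − μ))`.  An iterative
   inclusion search (default five iterations, inclusion at `E < 1e-20`) and
   Kyte–Doolittle transmembrane seed extraction (±20-residue flanks) are
   built on top.
2. **Subfamily detection** — agglomerative encoding-cost clustering of the
   homolog alignment: cluster cost = pseudocounted multinomial negative
   log-likelihood + a BIC-style per-cluster penalty; cheapest merge first;
   the partition at the trajectory cost minimum is returned and the largest
   clusters (≥5% of sequences) become one calibrated profile each, plus one
   pooled "unspecific" model.
3. **Classification** — every protein is scanned against all models; under
   the census profile hits need `E < 1e-25` and ≥80% model coverage (genome
   profile: `E < 1e-10`).  The verdict is the subfamily of the most
   significant hit; a best hit to the unspecific model excludes the protein.
4. **Redundancy clustering** — greedy centroid clustering at >80% pairwise
   identity (global alignment identity), with both centroid-clustering
   guarantees audited on every output.
5. **Repeat annotation** — ankyrin units counted by repeated best-local-hit
   profile scanning with greedy tiling; partial hits (<80% of the unit
   model) never count (the "lower number" convention); TRP-N-like proteins
   with fewer than 27 units are flagged as fragmented gene models.
6. **Specificity analysis** — per-column physico-chemical conservation
   (0–11), a two-group multi-Relief score `mR = D_between − D_within`, a
   permutation z-test (sites kept at `z > 3`), the complete-disjunctness
   filter, and push/pull/neither calls for query sequences.

## Worked example

```python
import trpscan as t

cfg = t.SyntheticConfig(rng_seed=1)
records, truth = t.generate_superfamily(cfg)
aln = t.channel_alignment(records, truth)
partition = t.detect_subfamilies(aln)
selected, coverage = t.select_major_subfamilies(partition)
print(f"major subfamilies: {len(selected)}  coverage: {coverage:.1%}")

models, unspecific = t.build_subfamily_models(aln, partition, selected, rng_seed=1)
rec = next(r for r in records if truth.family_of[r.id] == "fam_N")
hit = t.score_sequence(models[0], rec)
print(f"{rec.id} vs {models[0].name}: {hit.bit_score:.1f} bits, "
      f"envelope {hit.envelope_start}-{hit.envelope_end}")

unit_model = t.build_profile(t.generate_unit_alignment(cfg), name="ankyrin_unit")
t.calibrate(unit_model, rng_seed=2)
print(f"ankyrin repeats in {rec.id}: {t.count_repeats(rec, unit_model).ankyrin_count}")

pp_aln, pp_truth = t.generate_pushpull_default(rng_seed=3)
report = t.analyse(pp_aln, pp_truth.group_of, rng_seed=4)
print(f"disjunct mechanism-specific sites: {len(report.disjunct_sites)}")
```

prints

```
major subfamilies: 6  coverage: 100.0%
fam_N_000 vs c000: 787.7 bits, envelope 925-1124
ankyrin repeats in fam_N_000: 28
disjunct mechanism-specific sites: 17
```

All six planted subfamilies are recovered as pure clusters; the TRP-N-like
protein's channel core (its last 200 residues, envelope 925–1124) aligns to
its subfamily model at ~788 bits; its planted 28-unit ankyrin array is
counted exactly; and the mechanism analysis recovers exactly the 17 planted
completely disjunct push/pull sites (every query paralog is called "pull").

A CLI wraps the same stages:

```
trpscan run-all --seed 1 --outdir out/
trpscan report --outdir out/
```

Every run writes a `manifest.json` with the resolved configuration, derived
stage seeds and SHA-256 of each artifact; reruns with the same seed are
byte-identical.

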