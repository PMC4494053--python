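"""Shared fixtures: small synthetic data sets generated at test time."""
import pytest

import trpscan as t


@pytest.fixture(scope="session")
def default_superfamily():
    """Default six-subfamily superfamily with decoys, fixed seed."""
    cfg = t.SyntheticConfig(rng_seed=5)
    records, truth = t.generate_superfamily(cfg)
    return cfg, records, truth


@pytest.fixture(scope="session")
def unit_model(default_superfamily):
    """Calibrated ankyrin unit profile from the generator's unit alignment."""
    cfg, _, _ = default_superfamily
    aln = t.generate_unit_alignment(cfg)
    model = t.build_profile(aln, name="ankyrin_unit")
    t.calibrate(model, n_samples=200, rng_seed=11)
    return model


@pytest.fixture(scope="session")
def trained_models(default_superfamily):
    """Per-family profiles + pooled unspecific model from training halves,
    and the held-out record list."""
    cfg, records, truth = default_superfamily
    members: dict[str, list[str]] = {}
    for rec in records:
        fam = truth.family_of[rec.id]
        if fam != "decoy":
            members.setdefault(fam, []).append(rec.id)
    train, test = [], []
    for fam in sorted(members):
        half = len(members[fam]) // 2
        train += members[fam][:half]
        test += members[fam][half:]
    train_aln = t.channel_alignment(records, truth, include=train)
    idx = {n: k for k, n in enumerate(train_aln.ids)}
    models = []
    for j, fam in enumerate(sorted(members)):
        rows = [m for m in members[fam] if m in idx]
        model = t.build_profile(train_aln.subset([idx[m] for m in rows]), name=fam)
        t.calibrate(model, n_samples=200, rng_seed=100 + j)
        models.append(model)
    unspecific = t.build_profile(train_aln, name="unspecific")
    t.calibrate(unspecific, n_samples=200, rng_seed=99)
    held_out = [r for r in records if r.id in set(test)]
    return models, unspecific, held_out


@pytest.fixture(scope="session")
def pushpull_default():
    aln, truth = t.generate_pushpull_default(rng_seed=21)
    return aln, truth
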