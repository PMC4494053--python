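"""Position-specific profile models: building, local Viterbi scoring in bits,
Gumbel E-value calibration, iterative inclusion search and transmembrane seed
extraction.

The score reported for a model-vs-sequence comparison is the best *local*
alignment log-odds under a match/insert/delete profile HMM, in bits:

    S = max over paths  log2 P(path, residues | model) / P(residues | background)

Viterbi (best path), not forward, is used throughout: it is deterministic,
exactly checkable against exhaustive path enumeration on small models, and
sufficient for competitive ranking of models against one another.  Scores are
therefore not comparable to HMMER forward bit scores.

Local semantics: the path may enter any match state from the begin state and
leave any match state into the end state, both at zero cost; paths start and
end on a match state.  Insert emissions equal the background, so inserted
residues cost only their transition probabilities.
"""
from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import AA_INDEX, AMINO_ACIDS, GAP, Alignment, ProteinRecord, records_to_alignment

N_AA = 20
# state indices in the transition tensor
M, I, D = 0, 1, 2

NEG = -1.0e30  # effectively -inf, safe under addition

UNIFORM_BACKGROUND = np.full(N_AA, 1.0 / N_AA)


class ProfileError(ValueError):
    pass


class CalibrationError(RuntimeError):
    pass


@dataclasses.dataclass
class CalibrationParams:
    """Gumbel fit to the score distribution of random background sequences.

    mu is the location in bits, lam the scale in 1/bits; fitted by the method
    of moments: lam = pi / (sd * sqrt(6)), mu = mean - euler_gamma / lam.
    """

    mu: float
    lam: float
    n_samples: int
    sample_length: int

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise CalibrationError("lambda must be > 0")


@dataclasses.dataclass
class Hit:
    """A scored model-vs-sequence match.

    envelope_start/envelope_end are 1-based inclusive residue coordinates on
    the protein; model_cols_matched counts match states used by the optimal
    path (deletions do not count as matched columns).
    """

    protein_id: str
    model_name: str
    bit_score: float
    e_value: float | None
    envelope_start: int
    envelope_end: int
    model_cols_matched: int


@dataclasses.dataclass
class ProfileModel:
    name: str
    match_emissions: np.ndarray  # (L, 20)
    insert_emissions: np.ndarray  # (20,)
    transitions: np.ndarray  # (L+1, 3, 3): junction j, from-state, to-state
    background: np.ndarray  # (20,)
    calibration: CalibrationParams | None = None

    @property
    def consensus_length(self) -> int:
        return self.match_emissions.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[k] for k in self.match_emissions.argmax(axis=1))

    def check_normalised(self, atol: float = 1e-9) -> None:
        if not np.allclose(self.match_emissions.sum(axis=1), 1.0, atol=atol):
            raise ProfileError("match emissions do not sum to 1")
        if not math.isclose(float(self.insert_emissions.sum()), 1.0, abs_tol=atol):
            raise ProfileError("insert emissions do not sum to 1")
        if not np.allclose(self.transitions.sum(axis=2), 1.0, atol=atol):
            raise ProfileError("transitions do not sum to 1")


def _encode_ungapped(seq: str, context: str) -> np.ndarray:
    bad = sorted({c for c in seq if c not in AA_INDEX})
    if bad:
        raise ProfileError(f"{context}: non-amino-acid symbols {''.join(bad)!r}")
    return np.fromiter((AA_INDEX[c] for c in seq), dtype=np.int64, count=len(seq))


def match_columns(alignment: Alignment, max_gap_fraction: float = 0.5) -> np.ndarray:
    """0-based indices of columns with gap occupancy <= max_gap_fraction."""
    mat = alignment.to_indices()
    gap_frac = (mat >= N_AA).mean(axis=0)
    return np.nonzero(gap_frac <= max_gap_fraction)[0]


def build_profile(
    alignment: Alignment,
    pseudocount_weight: float = 2.0,
    name: str = "model",
    background: np.ndarray | None = None,
) -> ProfileModel:
    """Estimate a profile from an alignment.

    Match columns are those with at most 50% gaps.  Emissions use a single
    background-mixture pseudocount: p = (count + w*bg) / (n_observed + w).
    Transitions are counted from each row's match/insert/delete state path and
    smoothed with the same scheme (uniform 1/3 pseudo-distribution).
    """
    if pseudocount_weight < 0:
        raise ProfileError("pseudocount_weight must be >= 0")
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
    mat = alignment.to_indices()
    n, width = mat.shape
    cols = match_columns(alignment)
    if cols.size == 0:
        raise ProfileError("alignment has no match columns (all heavily gapped)")
    L = cols.size

    # --- match emissions ---
    emissions = np.empty((L, N_AA))
    for t, j in enumerate(cols):
        col = mat[:, j]
        residues = col[col < N_AA]
        counts = np.bincount(residues, minlength=N_AA).astype(float)
        emissions[t] = (counts + pseudocount_weight * bg) / (
            residues.size + pseudocount_weight
        )

    # --- transitions from observed state paths ---
    is_match_col = np.zeros(width, dtype=bool)
    is_match_col[cols] = True
    counts = np.zeros((L + 1, 3, 3))
    for r in range(n):
        row = mat[r]
        prev_state = M  # begin acts as match state at junction 0
        junction = 0
        insert_run = 0
        for j in range(width):
            if is_match_col[j]:
                cur = M if row[j] < N_AA else D
                if insert_run > 0:
                    counts[junction, prev_state, I] += 1
                    counts[junction, I, I] += insert_run - 1
                    counts[junction, I, cur] += 1
                else:
                    counts[junction, prev_state, cur] += 1
                prev_state = cur
                junction += 1
                insert_run = 0
            elif row[j] < N_AA:
                insert_run += 1
        # tail: transition into the end state (treated as a match)
        if insert_run > 0:
            counts[junction, prev_state, I] += 1
            counts[junction, I, I] += insert_run - 1
            counts[junction, I, M] += 1
        else:
            counts[junction, prev_state, M] += 1

    w = pseudocount_weight
    totals = counts.sum(axis=2, keepdims=True)
    transitions = (counts + w / 3.0) / (totals + w) if w > 0 else np.where(
        totals > 0, counts / np.where(totals == 0, 1.0, totals), 1.0 / 3.0
    )
    # rows never observed and w == 0: fall back to uniform so they normalise
    row_sums = transitions.sum(axis=2, keepdims=True)
    transitions = transitions / row_sums

    model = ProfileModel(
        name=name,
        match_emissions=emissions,
        insert_emissions=bg.copy(),
        transitions=transitions,
        background=bg.copy(),
    )
    model.check_normalised()
    return model


# ---------------------------------------------------------------------------
# Local Viterbi scoring
# ---------------------------------------------------------------------------


def _log_odds_tables(model: ProfileModel):
    lod_m = np.log2(model.match_emissions / model.background[None, :])
    lod_i = np.log2(model.insert_emissions / model.background)
    lod_t = np.log2(model.transitions)
    return lod_m, lod_i, lod_t


def _viterbi_fill(model: ProfileModel, idx: np.ndarray, masked: np.ndarray | None = None):
    """Fill DP matrices. Returns (Mx, Ix, Dx) each (n+1, L+1); row 0 and
    column 0 are padding (no residues emitted / no columns entered).
    Positions where *masked* is True cannot be emitted by any state."""
    lod_m, lod_i, lod_t = _log_odds_tables(model)
    n = idx.size
    L = model.consensus_length
    Mx = np.full((n + 1, L + 1), NEG)
    Ix = np.full((n + 1, L + 1), NEG)
    Dx = np.full((n + 1, L + 1), NEG)
    em = lod_m[:, idx].copy()  # (L, n)
    ei = lod_i[idx].copy()  # (n,)
    if masked is not None:
        em[:, masked] = NEG
        ei[masked] = NEG
    cum = np.concatenate([[0.0], np.cumsum(ei)])  # cum[i] = sum of ei[1..i]
    ks = np.arange(1, n + 1)
    for j in range(1, L + 1):
        t = lod_t[j - 1]  # junction before column j
        # match: enter free (0) or extend from (i-1, j-1)
        best_prev = np.maximum.reduce(
            [
                np.zeros(n),
                Mx[:-1, j - 1] + t[M, M],
                Ix[:-1, j - 1] + t[I, M],
                Dx[:-1, j - 1] + t[D, M],
            ]
        )
        Mx[1:, j] = em[j - 1] + best_prev
        # delete: same i, previous column
        Dx[:, j] = np.maximum(Mx[:, j - 1] + t[M, D], Dx[:, j - 1] + t[D, D])
        # insert after column j: I[i,j] = cum[i] + (i-1)*tII
        #   + max_{1<=k<=i-1} (M[k,j] + tMI - cum[k] - k*tII)  (prefix max scan)
        tj = lod_t[j]
        a = Mx[1:, j] + tj[M, I] - cum[1:] - ks * tj[I, I]
        running = np.maximum.accumulate(a)
        if n >= 2:
            Ix[2:, j] = cum[2:] + (ks[1:] - 1) * tj[I, I] + running[:-1]
    return Mx, Ix, Dx


def score_sequence(
    model: ProfileModel,
    seq: str | ProteinRecord,
    protein_id: str | None = None,
    masked: np.ndarray | None = None,
) -> Hit:
    """Best local alignment of *seq* to *model*, in bits, with envelope."""
    if isinstance(seq, ProteinRecord):
        protein_id = protein_id or seq.id
        seq = seq.seq
    if not seq:
        raise ProfileError("empty sequence")
    idx = _encode_ungapped(seq, f"sequence {protein_id or '<anon>'!r}")
    Mx, Ix, Dx = _viterbi_fill(model, idx, masked=masked)
    flat = int(np.argmax(Mx))
    n, L = idx.size, model.consensus_length
    i, j = divmod(flat, L + 1)
    score = float(Mx[i, j])
    if score <= NEG / 2:  # nothing alignable (e.g. fully masked)
        return Hit(protein_id or "", model.name, float("-inf"), None, 1, 1, 0)
    path = _traceback(model, idx, Mx, Ix, Dx, i, j)
    m_positions = [pi for pi, state in path if state == M]
    env_start, env_end = m_positions[0], m_positions[-1]
    return Hit(
        protein_id=protein_id or "",
        model_name=model.name,
        bit_score=score,
        e_value=None,
        envelope_start=env_start,
        envelope_end=env_end,
        model_cols_matched=len(m_positions),
    )


def score_only(model: ProfileModel, idx: np.ndarray) -> float:
    """Bit score without traceback (used by calibration)."""
    Mx, _, _ = _viterbi_fill(model, idx)
    return float(Mx.max())


def _traceback(model, idx, Mx, Ix, Dx, i, j):
    """Reconstruct the optimal path ending at M[i, j].

    Returns a list of (sequence position 1-based or None, state) from first to
    last emitting/deleting state."""
    lod_m, lod_i, lod_t = _log_odds_tables(model)
    path = []
    state = M
    tol = 1e-9
    while True:
        if state == M:
            path.append((i, M))
            em = lod_m[j - 1, idx[i - 1]]
            rest = Mx[i, j] - em
            t = lod_t[j - 1]
            if abs(rest) <= tol:
                break  # entered here from begin
            if abs(Mx[i - 1, j - 1] + t[M, M] - rest) <= tol:
                i, j, state = i - 1, j - 1, M
            elif abs(Ix[i - 1, j - 1] + t[I, M] - rest) <= tol:
                i, j, state = i - 1, j - 1, I
            elif abs(Dx[i - 1, j - 1] + t[D, M] - rest) <= tol:
                i, j, state = i - 1, j - 1, D
            elif rest <= tol:  # free entry was optimal within tolerance
                break
            else:  # pragma: no cover - defensive
                raise AssertionError("traceback failed at match state")
        elif state == D:
            path.append((None, D))
            t = lod_t[j - 1]
            if abs(Mx[i, j - 1] + t[M, D] - Dx[i, j]) <= tol:
                j, state = j - 1, M
            else:
                j, state = j - 1, D
        else:  # insert
            path.append((i, I))
            t = lod_t[j]
            ei = lod_i[idx[i - 1]]
            rest = Ix[i, j] - ei
            if abs(Mx[i - 1, j] + t[M, I] - rest) <= tol:
                i, state = i - 1, M
            else:
                i, state = i - 1, I
    path.reverse()
    return path


def viterbi_alignment_row(model: ProfileModel, seq: str) -> str:
    """Model-anchored row: one character per match column (residue or '-').

    Inserted residues are dropped; columns outside the local path are gaps.
    """
    idx = _encode_ungapped(seq, "sequence")
    Mx, Ix, Dx = _viterbi_fill(model, idx)
    flat = int(np.argmax(Mx))
    i, j = divmod(flat, model.consensus_length + 1)
    path = _traceback(model, idx, Mx, Ix, Dx, i, j)
    row = ["-"] * model.consensus_length
    col = j - sum(1 for _, s in path if s in (M, D))
    for pos, state in path:
        if state in (M, D):
            col += 1
            if state == M:
                row[col - 1] = AMINO_ACIDS[idx[pos - 1]]
    return "".join(row)


# ---------------------------------------------------------------------------
# Calibration and E-values
# ---------------------------------------------------------------------------


def random_background_sequence(rng: np.random.Generator, length: int, background: np.ndarray) -> str:
    draws = rng.choice(N_AA, size=length, p=background)
    return "".join(AMINO_ACIDS[k] for k in draws)


def calibrate(
    model: ProfileModel,
    n_samples: int = 200,
    sample_length: int | None = None,
    rng_seed: int = 0,
) -> CalibrationParams:
    """Fit a Gumbel law to scores of random background sequences.

    Method of moments: lam = pi/(sd*sqrt(6)), mu = mean - euler_gamma/lam.
    """
    if n_samples < 100:
        raise CalibrationError("n_samples must be >= 100")
    if sample_length is None:
        sample_length = max(100, 2 * model.consensus_length)
    rng = np.random.default_rng(rng_seed)
    scores = np.empty(n_samples)
    for k in range(n_samples):
        draws = rng.choice(N_AA, size=sample_length, p=model.background)
        scores[k] = score_only(model, draws)
    sd = float(scores.std(ddof=1))
    if sd == 0:
        raise CalibrationError("degenerate score sample (sd = 0)")
    lam = math.pi / (sd * math.sqrt(6.0))
    mu = float(scores.mean()) - np.euler_gamma / lam
    params = CalibrationParams(mu=mu, lam=lam, n_samples=n_samples, sample_length=sample_length)
    model.calibration = params
    return params


def evalue(model: ProfileModel, bit_score: float, database_size: int) -> float:
    """E = database_size * exp(-lambda * (bit_score - mu)), clipped below at 0."""
    if model.calibration is None:
        raise CalibrationError(f"model {model.name!r} is not calibrated")
    c = model.calibration
    arg = -c.lam * (bit_score - c.mu)
    if arg < -745.0:  # exp underflow: astronomically significant
        return 0.0
    return max(0.0, database_size * math.exp(arg))


# ---------------------------------------------------------------------------
# Iterative inclusion search
# ---------------------------------------------------------------------------


def iterative_search(
    query: ProteinRecord,
    database: Sequence[ProteinRecord],
    max_iterations: int = 5,
    inclusion_evalue: float = 1e-20,
    pseudocount_weight: float = 2.0,
    calibration_samples: int = 100,
    rng_seed: int = 0,
) -> tuple[set[str], ProfileModel]:
    """Iterative profile search with a strict inclusion threshold (E < cutoff).

    Iteration 1 builds a single-sequence profile from the query; every
    iteration scans the database, includes hits with E strictly below the
    threshold, realigns the included sequences to the model and rebuilds.
    Stops when the included set is unchanged or after max_iterations.
    """
    if not database:
        raise ProfileError("empty database")
    if max_iterations < 1:
        raise ProfileError("max_iterations must be >= 1")
    db_size = len(database)
    aln = records_to_alignment([query])
    model = build_profile(aln, pseudocount_weight, name=f"iter:{query.id}")
    included: set[str] = {query.id}
    for it in range(max_iterations):
        calibrate(model, n_samples=calibration_samples, rng_seed=rng_seed + it)
        new_included = {query.id}
        for rec in database:
            s = score_sequence(model, rec)
            if evalue(model, s.bit_score, db_size) < inclusion_evalue:
                new_included.add(rec.id)
        if new_included == included and it > 0:
            included = new_included
            break
        included = new_included
        members = [query] + [r for r in database if r.id in included and r.id != query.id]
        rows = [viterbi_alignment_row(model, r.seq) for r in members]
        aln = Alignment([r.id for r in members], rows)
        model = build_profile(aln, pseudocount_weight, name=f"iter:{query.id}")
    if model.calibration is None:
        calibrate(model, n_samples=calibration_samples, rng_seed=rng_seed + max_iterations)
    return included, model


# ---------------------------------------------------------------------------
# Transmembrane seed extraction (Kyte-Doolittle)
# ---------------------------------------------------------------------------

KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}


@dataclasses.dataclass
class TmRegion:
    """1-based inclusive span around predicted transmembrane helices."""

    start: int
    end: int
    sequence: str
    helices: list[tuple[int, int]]


def predict_tm_helices(
    seq: str,
    window: int = 19,
    threshold: float = 1.6,
    min_windows: int = 6,
) -> list[tuple[int, int]]:
    """Kyte-Doolittle hydropathy helices, 1-based inclusive spans.

    A window qualifies when its mean hydropathy is >= threshold; a run of at
    least min_windows consecutive qualifying window starts becomes a helix
    spanning from the first window's start to the last window's end.
    """
    if len(seq) < window:
        return []
    vals = np.array([KYTE_DOOLITTLE.get(c, 0.0) for c in seq])
    kernel = np.ones(window) / window
    means = np.convolve(vals, kernel, mode="valid")  # means[i] = window at i
    ok = means >= threshold
    helices: list[tuple[int, int]] = []
    i = 0
    while i < ok.size:
        if ok[i]:
            k = i
            while k + 1 < ok.size and ok[k + 1]:
                k += 1
            if k - i + 1 >= min_windows:
                helices.append((i + 1, k + window))  # 1-based inclusive
            i = k + 1
        else:
            i += 1
    return helices


def extract_tm_region(seq: str | ProteinRecord, flank: int = 20, **kwargs) -> TmRegion | None:
    """Span from first helix start - flank to last helix end + flank, clipped.

    Returns None ("no TM region") when no helix is predicted.
    """
    if isinstance(seq, ProteinRecord):
        seq = seq.seq
    if flank < 0:
        raise ProfileError("flank must be >= 0")
    helices = predict_tm_helices(seq, **kwargs)
    if not helices:
        return None
    start = max(1, helices[0][0] - flank)
    end = min(len(seq), helices[-1][1] + flank)
    return TmRegion(start=start, end=end, sequence=seq[start - 1 : end], helices=helices)


# ---------------------------------------------------------------------------
# Serialization (versioned JSON lines, one model per line)
# ---------------------------------------------------------------------------

FORMAT_VERSION = 1


def save_models(models: Sequence[ProfileModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in models:
            obj = {
                "version": FORMAT_VERSION,
                "name": m.name,
                "match_emissions": m.match_emissions.tolist(),
                "insert_emissions": m.insert_emissions.tolist(),
                "transitions": m.transitions.tolist(),
                "background": m.background.tolist(),
                "calibration": dataclasses.asdict(m.calibration) if m.calibration else None,
            }
            fh.write(json.dumps(obj) + "\n")


def load_models(path: str | Path) -> list[ProfileModel]:
    models = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            if obj.get("version") != FORMAT_VERSION:
                raise ProfileError(f"unsupported model format version {obj.get('version')}")
            calib = obj["calibration"]
            models.append(
                ProfileModel(
                    name=obj["name"],
                    match_emissions=np.array(obj["match_emissions"]),
                    insert_emissions=np.array(obj["insert_emissions"]),
                    transitions=np.array(obj["transitions"]),
                    background=np.array(obj["background"]),
                    calibration=CalibrationParams(**calib) if calib else None,
                )
            )
    return models
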