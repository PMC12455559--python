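"""Profile hidden Markov models: build from alignments, score in bits, tune.

Architecture: match/insert/delete states per node with the full 3x3 transition
set, Laplace pseudocounts, and log-odds scoring against a configurable
background. Two scoring modes: "global" (closed-form testable) and "unilocal"
(uniform entry over match states, free exit, background-emitting flanks), the
default for homology-search-like scoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import _kernels
from .alphabet import AA_INDEX, GAP, UNIFORM_BACKGROUND, encode
from .seqio import Alignment, SequenceRecord

LN2 = np.log(2.0)
STATES = {"M": 0, "I": 1, "D": 2}


@dataclass
class ProfileHMM:
    """Profile HMM parameters.

    match_emissions: (L+1, 20) rows 1..L; insert_emissions: (20,) shared;
    transitions: (L+1, 3, 3) probabilities, node k from {M,I,D} to
    {M(k+1), I(k), D(k+1)}; node 0 M is Begin, node L M->M exits to End.
    """

    L: int
    match_emissions: np.ndarray
    insert_emissions: np.ndarray
    transitions: np.ndarray
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())
    mode: str = "unilocal"
    match_columns: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("profile must have at least one match state")
        if self.mode not in ("global", "unilocal"):
            raise ValueError(f"unknown mode {self.mode!r}")
        self._validate()

    def _validate(self) -> None:
        me = self.match_emissions[1:]
        if not np.allclose(me.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("match emissions must sum to 1")
        if not np.isclose(self.insert_emissions.sum(), 1.0, atol=1e-12):
            raise ValueError("insert emissions must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-12):
            raise ValueError("background must sum to 1")
        tr = self.transitions.sum(axis=2)
        # rows corresponding to unreachable states (I/D at begin/end edge) may be zero
        ok = np.isclose(tr, 1.0, atol=1e-12) | np.isclose(tr, 0.0, atol=1e-12)
        if not ok.all():
            raise ValueError("each outgoing transition set must sum to 1 (or be unused)")

    # -- log-odds parameterization -------------------------------------------------
    def _log_odds(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        with np.errstate(divide="ignore"):
            lb = np.log(self.background)
            lm = np.full((self.L + 1, 21), 0.0)
            lm[1:, :20] = np.log(self.match_emissions[1:]) - lb
            lm[1:, 20] = 0.0  # 'X' emits at background odds
            li = np.zeros((self.L + 1, 21))
            li[:, :20] = np.log(self.insert_emissions) - lb
            li[:, 20] = 0.0
            ltr = np.log(self.transitions)
        return lm, li, ltr

    def bit_score(self, seq: str | SequenceRecord) -> float:
        """Forward log2-odds score of a sequence against the background."""
        residues = seq.residues if isinstance(seq, SequenceRecord) else seq
        if not residues:
            raise ValueError("cannot score an empty sequence")
        x = encode(residues)
        lm, li, ltr = self._log_odds()
        nats = _kernels.hmm_forward(x, lm, li, ltr, self.mode == "unilocal")
        return float(nats / LN2)

    def viterbi(self, seq: str | SequenceRecord) -> tuple[float, np.ndarray]:
        """Viterbi bit score and per-residue assignment.

        assignment[t] > 0: match column; < 0: insert after column |k|; 0: flank.
        """
        residues = seq.residues if isinstance(seq, SequenceRecord) else seq
        x = encode(residues)
        lm, li, ltr = self._log_odds()
        nats, cols = _kernels.hmm_viterbi(x, lm, li, ltr, self.mode == "unilocal")
        return float(nats / LN2), cols

    def matched_span(self, seq: str | SequenceRecord) -> tuple[int, int] | None:
        """0-based [start, end) span of residues assigned to match states."""
        _, cols = self.viterbi(seq)
        hits = np.nonzero(cols > 0)[0]
        if hits.size == 0:
            return None
        return int(hits[0]), int(hits[-1]) + 1

    # -- serialization ---------------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "L": self.L,
            "mode": self.mode,
            "match_emissions": self.match_emissions.tolist(),
            "insert_emissions": self.insert_emissions.tolist(),
            "transitions": self.transitions.tolist(),
            "background": self.background.tolist(),
            "match_columns": self.match_columns,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "ProfileHMM":
        payload = json.loads(Path(path).read_text())
        return cls(
            L=payload["L"],
            match_emissions=np.array(payload["match_emissions"]),
            insert_emissions=np.array(payload["insert_emissions"]),
            transitions=np.array(payload["transitions"]),
            background=np.array(payload["background"]),
            mode=payload["mode"],
            match_columns=list(payload["match_columns"]),
        )


def build_profile(
    aln: Alignment,
    match_gap_threshold: float = 0.5,
    pseudocount: float = 1.0,
    transition_pseudocount: float = 1.0,
    background: np.ndarray | None = None,
    mode: str = "unilocal",
    weights: Sequence[float] | None = None,
) -> ProfileHMM:
    """Estimate a profile HMM from an alignment.

    Columns with gap fraction <= match_gap_threshold become match states.
    Emissions are (weighted) counts plus Laplace pseudocounts; transitions are
    counted from each row's implied Begin->...->End state path.
    """
    if len(aln) < 2:
        raise ValueError("profile construction needs at least 2 rows")
    bg = UNIFORM_BACKGROUND.copy() if background is None else np.asarray(background, float)
    gf = aln.gap_fractions()
    match_cols = [j for j in range(aln.n_columns) if gf[j] <= match_gap_threshold]
    if not match_cols:
        raise ValueError("no columns qualify as match states")
    L = len(match_cols)
    w = np.ones(len(aln)) if weights is None else np.asarray(weights, float)

    m_counts = np.zeros((L + 1, 20))
    i_counts = np.zeros(20)
    t_counts = np.zeros((L + 1, 3, 3))
    is_match = np.zeros(aln.n_columns, dtype=bool)
    node_of_col = np.zeros(aln.n_columns, dtype=int)
    for k, j in enumerate(match_cols, start=1):
        is_match[j] = True
        node_of_col[j] = k

    for row, wt in zip(aln.rows, w):
        prev_state, prev_node = "M", 0  # Begin
        for j, c in enumerate(row.residues):
            if is_match[j]:
                node = node_of_col[j]
                if c == GAP:
                    state = "D"
                else:
                    state = "M"
                    if c != "X":
                        m_counts[node, AA_INDEX[c]] += wt
                t_counts[prev_node, STATES[prev_state], STATES[state]] += wt
                prev_state, prev_node = state, node
            else:
                if c == GAP:
                    continue
                if c != "X":
                    i_counts[AA_INDEX[c]] += wt
                t_counts[prev_node, STATES[prev_state], STATES["I"]] += wt
                prev_state = "I"
        t_counts[prev_node, STATES[prev_state], STATES["M"]] += wt  # to End

    me = np.zeros((L + 1, 20))
    me[1:] = m_counts[1:] + pseudocount
    me[1:] /= me[1:].sum(axis=1, keepdims=True)
    # insert states emit at background (score-neutral), the usual search convention
    ie = bg.copy()

    tr = t_counts + transition_pseudocount
    # unusable rows: D at node 0 (no delete before first match), I at node 0 exists (N-terminal inserts)
    tr[0, STATES["D"], :] = 0.0
    # node L: M/I/D may only go to End (M) or I(L)
    tr[L, :, STATES["D"]] = 0.0
    sums = tr.sum(axis=2, keepdims=True)
    sums[sums == 0] = 1.0
    tr = tr / sums
    return ProfileHMM(
        L=L,
        match_emissions=me,
        insert_emissions=ie,
        transitions=tr,
        background=bg,
        mode=mode,
        match_columns=match_cols,
    )


def score_sequences(hmm: ProfileHMM, records: Iterable[SequenceRecord]) -> dict[str, float]:
    return {r.id: hmm.bit_score(r) for r in records}


@dataclass
class ScoreSet:
    """Bit scores plus scores normalized to a reference sequence's bit score."""

    bits: dict[str, float]
    reference_id: str

    @property
    def normalized(self) -> dict[str, float]:
        ref = self.bits[self.reference_id]
        return {k: v / ref for k, v in self.bits.items()}


def normalize_scores(bits: dict[str, float], reference_id: str) -> ScoreSet:
    """Divide every bit score by the reference sequence's bit score."""
    if reference_id not in bits:
        raise KeyError(f"reference {reference_id!r} absent from score set")
    if bits[reference_id] == 0:
        raise ValueError("reference bit score is zero; cannot normalize")
    return ScoreSet(bits=dict(bits), reference_id=reference_id)


def tune_hmm(
    base_actives: Sequence[SequenceRecord],
    new_actives: Sequence[SequenceRecord] = (),
    realign: bool = True,
    base_alignment: Alignment | None = None,
    **build_kwargs,
) -> ProfileHMM:
    """Rebuild a profile after augmenting the training set with condition-active
    sequences. With realign=True (default) the union is re-aligned from scratch;
    otherwise new sequences are aligned onto the base profile one at a time.
    """
    from .msa import progressive_align

    base = list(base_actives)
    new = [r for r in new_actives if r.id not in {b.id for b in base}]
    if realign or base_alignment is None:
        aln = progressive_align(base + new)
        return build_profile(aln, **build_kwargs)
    # align-to-profile route: insert each new sequence into the base alignment
    hmm = build_profile(base_alignment, **build_kwargs)
    rows = [list(r.residues) for r in base_alignment.rows]
    ids = base_alignment.ids()
    col_of_node = {k: j for k, j in enumerate(hmm.match_columns, start=1)}
    new_rows = []
    for rec in new:
        _, cols = hmm.viterbi(rec)
        row = [GAP] * base_alignment.n_columns
        for t, k in enumerate(cols):
            if k > 0:
                row[col_of_node[int(k)]] = rec.residues[t]
        new_rows.append(SequenceRecord(rec.id, "".join(row)))
    aln = Alignment(
        [SequenceRecord(i, "".join(r)) for i, r in zip(ids, rows)] + new_rows
    )
    return build_profile(aln, **build_kwargs)
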