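"""Collation of two model iterations by pairwise sequence alignment.

To show two snapshots of a model on one radial graphic, their chains
must be paired and their residue sequences aligned so each angular
segment corresponds to one alignment column.  Chains with identical ids
pair directly; leftovers pair greedily by best global alignment score.
Gap columns become "missing residue" markers downstream.

The aligner is a plain Needleman-Wunsch global alignment with a
declared, deterministic tie-break (prefer diagonal, then up), so the
report is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model_io import Chain, StructureModel

__all__ = [
    "AlignedPair",
    "AlignmentScheme",
    "THREE_TO_ONE",
    "one_letter_sequence",
    "align_sequences",
    "alignment_score",
    "pair_chains",
    "collate_positions",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass(frozen=True)
class AlignmentScheme:
    """Scoring for global alignment; 'X' (unknown) scores 0 vs anything."""

    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -2.0

    def score(self, a: str, b: str) -> float:
        if a == "X" or b == "X":
            return 0.0
        return self.match if a == b else self.mismatch


@dataclass
class AlignedPair:
    """One chain pairing: per-column residue indices (None = gap)."""

    chain_id_latest: str
    chain_id_previous: str | None
    alignment: list[tuple[int | None, int | None]] = field(default_factory=list)
    score: float = 0.0

    @property
    def n_positions(self) -> int:
        return len(self.alignment)


def one_letter_sequence(chain: Chain) -> str:
    """One-letter sequence of a chain's amino acids ('X' if non-standard)."""
    return "".join(
        THREE_TO_ONE.get(r.name, "X") for r in chain.amino_acids()
    )


def align_sequences(
    seq_a: str, seq_b: str, scheme: AlignmentScheme = AlignmentScheme()
) -> tuple[list[tuple[int | None, int | None]], float]:
    """Global alignment of two sequences.

    Returns (columns, score) where each column is a pair of indices into
    seq_a and seq_b, None marking a gap.  Ties in the dynamic program
    are broken deterministically: diagonal first, then up (gap in
    seq_b), then left.
    """
    if not seq_a or not seq_b:
        raise ValueError("both sequences must be non-empty")
    n, m = len(seq_a), len(seq_b)
    score = [[0.0] * (m + 1) for _ in range(n + 1)]
    move = [[0] * (m + 1) for _ in range(n + 1)]  # 0 diag, 1 up, 2 left
    for i in range(1, n + 1):
        score[i][0] = i * scheme.gap
        move[i][0] = 1
    for j in range(1, m + 1):
        score[0][j] = j * scheme.gap
        move[0][j] = 2
    for i in range(1, n + 1):
        row = score[i]
        prev = score[i - 1]
        a = seq_a[i - 1]
        for j in range(1, m + 1):
            diag = prev[j - 1] + scheme.score(a, seq_b[j - 1])
            up = prev[j] + scheme.gap
            left = row[j - 1] + scheme.gap
            best, which = diag, 0
            if up > best:
                best, which = up, 1
            if left > best:
                best, which = left, 2
            row[j] = best
            move[i][j] = which
    columns: list[tuple[int | None, int | None]] = []
    i, j = n, m
    while i > 0 or j > 0:
        which = move[i][j]
        if i > 0 and j > 0 and which == 0:
            columns.append((i - 1, j - 1))
            i -= 1
            j -= 1
        elif i > 0 and (which == 1 or j == 0):
            columns.append((i - 1, None))
            i -= 1
        else:
            columns.append((None, j - 1))
            j -= 1
    columns.reverse()
    return columns, score[n][m]


def alignment_score(
    seq_a: str, seq_b: str, scheme: AlignmentScheme = AlignmentScheme()
) -> float:
    return align_sequences(seq_a, seq_b, scheme)[1]


def pair_chains(
    latest: StructureModel,
    previous: StructureModel,
    scheme: AlignmentScheme = AlignmentScheme(),
) -> tuple[list[AlignedPair], list[str], list[str]]:
    """Pair chains between two model iterations.

    Identical chain ids pair first; remaining chains pair greedily by
    best alignment score.  Returns (pairs, unpaired_latest_ids,
    unpaired_previous_ids).  Pairing is independent of chain order in
    either input (greedy choices sort by score, then by chain id).
    """
    latest_chains = {c.chain_id: c for c in latest.chains if c.amino_acids()}
    prev_chains = {c.chain_id: c for c in previous.chains if c.amino_acids()}
    pairs: list[AlignedPair] = []
    used_prev: set[str] = set()
    leftover_latest = []
    for cid in sorted(latest_chains):
        if cid in prev_chains:
            cols, score = align_sequences(
                one_letter_sequence(latest_chains[cid]),
                one_letter_sequence(prev_chains[cid]),
                scheme,
            )
            pairs.append(AlignedPair(cid, cid, cols, score))
            used_prev.add(cid)
        else:
            leftover_latest.append(cid)
    leftover_prev = [cid for cid in sorted(prev_chains) if cid not in used_prev]
    # Greedy score-based pairing of the leftovers, deterministic order.
    candidates = []
    for lcid in leftover_latest:
        for pcid in leftover_prev:
            cols, score = align_sequences(
                one_letter_sequence(latest_chains[lcid]),
                one_letter_sequence(prev_chains[pcid]),
                scheme,
            )
            candidates.append((-score, lcid, pcid, cols))
    candidates.sort()
    matched_latest: set[str] = set()
    matched_prev: set[str] = set()
    for neg_score, lcid, pcid, cols in candidates:
        if lcid in matched_latest or pcid in matched_prev:
            continue
        pairs.append(AlignedPair(lcid, pcid, cols, -neg_score))
        matched_latest.add(lcid)
        matched_prev.add(pcid)
    unpaired_latest = [c for c in leftover_latest if c not in matched_latest]
    unpaired_prev = [c for c in leftover_prev if c not in matched_prev]
    pairs.sort(key=lambda p: p.chain_id_latest)
    return pairs, unpaired_latest, unpaired_prev


def collate_positions(pair: AlignedPair, metrics_latest, metrics_previous):
    """Zip two per-chain metric lists along an alignment.

    ``metrics_latest``/``metrics_previous`` are lists indexed like the
    chains' amino-acid sequences.  Returns one (latest, previous) tuple
    per alignment column, with None on the gap side — the downstream
    "missing residue" marker.
    """
    out = []
    for ia, ib in pair.alignment:
        rec_a = metrics_latest[ia] if ia is not None else None
        rec_b = (
            metrics_previous[ib]
            if (ib is not None and metrics_previous is not None)
            else None
        )
        out.append((rec_a, rec_b))
    return out
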