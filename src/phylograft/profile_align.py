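"""Extend an existing alignment with new sequences against its fixed column
profile.

The original alignment is a frozen template of homology: its rows and columns
are never re-aligned. Each new sequence is aligned independently against the
per-column base-frequency profile by global dynamic programming; characters
that cannot be placed in an original column become freshly inserted columns
that are gap in every original row. Deleting inserted columns and then new
rows reproduces the input alignment character-for-character, and that
round-trip is enforced as a type invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import Alignment
from .errors import FormatError, IntegrityError
from .seqs import IUPAC

_BASES = "ACGT"
_NEG = -1e30


@dataclass
class ProfileAlignConfig:
    # deletion (skipping an original column) is scaled by column occupancy,
    # so skipping columns that are mostly gaps in the template is near-free
    gap_open_del: float = 1.5
    gap_extend_del: float = 0.5
    gap_open_ins: float = 2.5
    gap_extend_ins: float = 1.0


@dataclass
class ExtendedAlignment:
    alignment: Alignment
    original_labels: set[str]
    new_labels: set[str]
    column_provenance: list[str]  # "original" | "inserted" per column

    def __post_init__(self):
        if self.original_labels & self.new_labels:
            raise FormatError("original and new labels overlap")
        if len(self.column_provenance) != self.alignment.width:
            raise IntegrityError("provenance length != alignment width")


def _profile(original: Alignment) -> tuple[np.ndarray, np.ndarray]:
    """Per-column base weights (A,C,G,T; ambiguity codes contribute
    fractionally) and occupancy (fraction of non-gap characters)."""
    W = original.width
    counts = np.zeros((W, 4))
    nongap = np.zeros(W)
    for seq in original.rows.values():
        for i, c in enumerate(seq):
            bases = IUPAC.get(c)
            if bases is None:
                continue  # gap or missing
            w = 1.0 / len(bases)
            for b in bases:
                counts[i, _BASES.index(b)] += w
            nongap[i] += 1.0
    freq = np.divide(counts, nongap[:, None], out=np.zeros_like(counts),
                     where=nongap[:, None] > 0)
    occupancy = nongap / len(original)
    return freq, occupancy


def _char_scores(freq: np.ndarray, seq: str) -> np.ndarray:
    """(W, L) match scores: 2*freq - 1 averaged over the candidate char's
    compatible bases (+1 for a column fixed on that base, -1 for absent)."""
    cols = []
    for c in seq:
        bases = IUPAC.get(c, "ACGT")
        idx = [_BASES.index(b) for b in bases]
        cols.append(2.0 * freq[:, idx].mean(axis=1) - 1.0)
    return np.stack(cols, axis=1)


def _align_to_profile(freq, occupancy, seq, cfg: ProfileAlignConfig):
    """Global three-state DP of ``seq`` against the profile.

    Returns (aligned_row over original columns, insertions) where insertions
    is a list of (after_column_index, inserted_chars)."""
    W = freq.shape[0]
    L = len(seq)
    s = _char_scores(freq, seq)
    od = cfg.gap_open_del * occupancy
    ed = cfg.gap_extend_del * occupancy
    oi, ei = cfg.gap_open_ins, cfg.gap_extend_ins

    M = np.full((W + 1, L + 1), _NEG)
    D = np.full((W + 1, L + 1), _NEG)
    I = np.full((W + 1, L + 1), _NEG)
    M[0, 0] = 0.0
    for j in range(1, L + 1):
        I[0, j] = -oi - ei * (j - 1)
    for i in range(1, W + 1):
        D[i, 0] = (D[i - 1, 0] - ed[i - 1]) if i > 1 else -od[0]
        prevM, prevD, prevI = M[i - 1], D[i - 1], I[i - 1]
        best_prev = np.maximum(np.maximum(prevM, prevD), prevI)
        M[i, 1:] = s[i - 1] + best_prev[:-1]
        D[i, 1:] = np.maximum(np.maximum(prevM[1:], prevI[1:]) - od[i - 1],
                              prevD[1:] - ed[i - 1])
        # I[i, j] = max(I[i, j-1] - ei, M[i, j-1] - oi): running-max recurrence
        Mi = M[i]
        row = np.maximum.accumulate(Mi[:-1] - oi + ei * np.arange(L))
        I[i, 1:] = np.maximum(I[i, 1:], row - ei * np.arange(L))

    # traceback (value-based; scores are exact enough for tolerant comparison)
    i, j = W, L
    state = max(("M", "D", "I"), key=lambda st: {"M": M, "D": D, "I": I}[st][W, L])
    aligned: list[str] = []  # per original column, reversed
    insertions: dict[int, list[str]] = {}
    tol = 1e-6
    while i > 0 or j > 0:
        if state == "M":
            aligned.append(seq[j - 1])
            prev = max(M[i - 1, j - 1], D[i - 1, j - 1], I[i - 1, j - 1])
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            for st, mat in (("M", M), ("D", D), ("I", I)):
                if abs(mat[i, j] - prev) < tol:
                    state = st
                    break
        elif state == "D":
            aligned.append("-")
            val = D[i, j]
            if abs(val - (M[i - 1, j] - od[i - 1])) < tol:
                state = "M"
            elif abs(val - (D[i - 1, j] - ed[i - 1])) < tol:
                state = "D"
            else:
                state = "I"
            i -= 1
        else:  # I: char inserted after original column i
            insertions.setdefault(i, []).insert(0, seq[j - 1])
            val = I[i, j]
            if abs(val - (M[i, j - 1] - oi)) < tol:
                state = "M"
            elif j > 1 and abs(val - (I[i, j - 1] - ei)) < tol:
                state = "I"
            else:
                state = "M"
            j -= 1
    row = "".join(reversed(aligned))
    ins = [(k, "".join(v)) for k, v in sorted(insertions.items())]
    return row, ins


def extend_alignment(
    original: Alignment,
    new_seqs: list[tuple[str, str]],
    config: ProfileAlignConfig | None = None,
) -> ExtendedAlignment:
    """Profile-align each (label, oriented gap-free sequence) in ``new_seqs``
    independently against ``original`` and merge the results.

    Insertions from different new sequences are kept in separate columns.
    """
    config = config or ProfileAlignConfig()
    labels = [l for l, _ in new_seqs]
    if len(set(labels)) != len(labels):
        raise FormatError("duplicate labels among new sequences")
    clash = set(labels) & set(original.rows)
    if clash:
        raise FormatError(f"new labels already in alignment: {sorted(clash)}")
    if not new_seqs:
        return ExtendedAlignment(
            alignment=Alignment(dict(original.rows), original.locus_name),
            original_labels=set(original.rows),
            new_labels=set(),
            column_provenance=["original"] * original.width,
        )

    freq, occupancy = _profile(original)
    placed = []  # (label, row over original columns, insertions)
    for label, seq in new_seqs:
        row, ins = _align_to_profile(freq, occupancy, seq.upper(), config)
        placed.append((label, row, ins))

    W = original.width
    # inserted column blocks keyed by insertion point, one block per
    # (candidate, insertion) - candidates do not share inserted columns
    blocks: dict[int, list[tuple[str, str]]] = {}  # after_col -> [(label, chars)]
    for label, _row, ins in placed:
        for after, chars in ins:
            blocks.setdefault(after, []).append((label, chars))

    def build_row(base_chars: str, owner: str | None) -> str:
        out = []
        for col in range(W + 1):
            for blk_label, chars in blocks.get(col, []):
                if owner is not None and blk_label == owner:
                    out.append(chars)
                else:
                    out.append("-" * len(chars))
            if col < W:
                out.append(base_chars[col])
        return "".join(out)

    rows: dict[str, str] = {}
    for label, seq in original.rows.items():
        rows[label] = build_row(seq, None)
    for label, row, _ins in placed:
        rows[label] = build_row(row, label)

    provenance = []
    for col in range(W + 1):
        for _lbl, chars in blocks.get(col, []):
            provenance.extend(["inserted"] * len(chars))
        if col < W:
            provenance.append("original")

    ext = ExtendedAlignment(
        alignment=Alignment(rows, original.locus_name),
        original_labels=set(original.rows),
        new_labels=set(labels),
        column_provenance=provenance,
    )
    if strip_to_original(ext) != original:
        raise IntegrityError("extension altered the original alignment template")
    return ext


def strip_to_original(ext: ExtendedAlignment) -> Alignment:
    """Remove inserted columns and new rows; must reproduce the original
    alignment exactly."""
    keep = [i for i, p in enumerate(ext.column_provenance) if p == "original"]
    if any(p not in ("original", "inserted") for p in ext.column_provenance):
        raise IntegrityError("unknown provenance flag")
    rows = {}
    for label in ext.alignment.labels:
        if label in ext.new_labels:
            continue
        seq = ext.alignment[label]
        rows[label] = "".join(seq[i] for i in keep)
    return Alignment(rows, ext.alignment.locus_name)
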