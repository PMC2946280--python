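"""Secondary-structure prediction for short RNA reads.

A deterministic scored maximum-pairing dynamic program (Nussinov-style, with
a stacking bonus and a minimum-helix post-filter) predicts one optimal
non-crossing structure per read. It is intentionally NOT a nearest-neighbor
free-energy model: end-structure classification downstream only needs a
reasonable, exactly-testable pairing engine, and a brute-force enumerator
(:func:`enumerate_structures`) serves as its oracle on short sequences.
Classifications may differ from thermodynamic folders on edge cases.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
from numba import njit

NEG_INF = float("-inf")

_PAIR_KEY: dict[tuple[str, str], str] = {
    ("G", "C"): "GC",
    ("C", "G"): "GC",
    ("A", "U"): "AU",
    ("U", "A"): "AU",
    ("G", "U"): "GU",
    ("U", "G"): "GU",
}


@dataclass(frozen=True)
class FoldParams:
    """Scoring parameters for the folding DP.

    ``gc >= au >= gu`` mirrors relative base-pair stability; ``stack_bonus``
    rewards each pair stacked directly on another, so helices out-score the
    same number of isolated pairs. Helices shorter than ``min_helix``
    consecutive pairs are dissolved in a post-pass, preventing isolated
    single pairs from spuriously creating "double-stranded" ends.
    """

    min_loop: int = 3
    gc: float = 3.0
    au: float = 2.0
    gu: float = 1.0
    stack_bonus: float = 1.0
    min_helix: int = 2

    def __post_init__(self) -> None:
        if self.min_loop < 3:
            raise ValueError("min_loop must be >= 3 nt")
        if not (self.gc >= self.au >= self.gu > 0):
            raise ValueError("pair scores must satisfy GC >= AU >= GU > 0")
        if self.stack_bonus < 0:
            raise ValueError("stack_bonus must be >= 0")
        if self.min_helix < 1:
            raise ValueError("min_helix must be >= 1")

    @property
    def pair_scores(self) -> Mapping[str, float]:
        return {"GC": self.gc, "AU": self.au, "GU": self.gu}

    @classmethod
    def with_scores(cls, pair_scores: Mapping[str, float], **kwargs) -> "FoldParams":
        return cls(
            gc=pair_scores["GC"], au=pair_scores["AU"], gu=pair_scores["GU"], **kwargs
        )

    def pair_score(self, a: str, b: str) -> float | None:
        """Score of pairing bases a-b, or None if not a legal pair (N never pairs)."""
        key = _PAIR_KEY.get((a, b))
        return None if key is None else self.pair_scores[key]


DEFAULT_PARAMS = FoldParams()


@dataclass(frozen=True)
class FoldResult:
    """A sequence with one predicted structure.

    ``score`` is the DP optimum over all non-crossing structures respecting
    the pairing rules and minimum loop; ``structure``/``pairs`` are that
    optimum after dissolving helices shorter than ``min_helix``, so the
    reported structure can score slightly below ``score``.
    """

    sequence: str
    structure: str
    score: float
    pairs: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.structure):
            raise ValueError("structure length must equal sequence length")


def _validate_sequence(sequence: str) -> str:
    seq = sequence.upper().replace("T", "U")
    bad = set(seq) - set("ACGUN")
    if bad:
        raise ValueError(f"invalid RNA characters: {sorted(bad)}")
    return seq


def structure_score(sequence: str, pairs: frozenset[tuple[int, int]], params: FoldParams) -> float:
    """Score of a given structure: pair scores plus stacking bonuses."""
    total = 0.0
    for i, j in pairs:
        s = params.pair_score(sequence[i], sequence[j])
        if s is None:
            raise ValueError(f"illegal pair {sequence[i]}-{sequence[j]} at ({i},{j})")
        total += s
        if (i + 1, j - 1) in pairs:
            total += params.stack_bonus
    return total


def _helices(pairs: frozenset[tuple[int, int]]) -> list[list[tuple[int, int]]]:
    """Group pairs into maximal stacked runs (helices)."""
    pairs_set = set(pairs)
    helices = []
    for i, j in sorted(pairs_set):
        if (i - 1, j + 1) in pairs_set:
            continue  # interior of a helix; handled from its outermost pair
        helix = [(i, j)]
        while (helix[-1][0] + 1, helix[-1][1] - 1) in pairs_set:
            helix.append((helix[-1][0] + 1, helix[-1][1] - 1))
        helices.append(helix)
    return helices


def _dissolve_short_helices(
    pairs: frozenset[tuple[int, int]], min_helix: int
) -> frozenset[tuple[int, int]]:
    kept: set[tuple[int, int]] = set()
    for helix in _helices(pairs):
        if len(helix) >= min_helix:
            kept.update(helix)
    return frozenset(kept)


@njit(cache=True)
def _fill_tables(S: np.ndarray, min_loop: int, stack_bonus: float):  # pragma: no cover
    """Fill V/W/Wnp interval tables; S[i,j] is the pair score or -inf."""
    n = S.shape[0]
    neg_inf = -np.inf
    V = np.full((n, n), neg_inf)
    W = np.zeros((n, n))
    Wnp = np.zeros((n, n))
    for span in range(1, n):
        for i in range(n - span):
            j = i + span
            if j - i > min_loop and S[i, j] > neg_inf:
                inner = Wnp[i + 1, j - 1] if i + 1 <= j - 1 else 0.0
                if V[i + 1, j - 1] > neg_inf:
                    stacked = V[i + 1, j - 1] + stack_bonus
                    if stacked > inner:
                        inner = stacked
                V[i, j] = S[i, j] + inner
            best = W[i + 1, j] if i + 1 <= j else 0.0
            best_np = best
            for k in range(i + min_loop + 1, j + 1):
                if V[i, k] > neg_inf:
                    tail = W[k + 1, j] if k + 1 <= j else 0.0
                    cand = V[i, k] + tail
                    if cand > best:
                        best = cand
                    if k < j and cand > best_np:
                        best_np = cand
            W[i, j] = best
            Wnp[i, j] = best_np
    return V, W, Wnp


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}


@functools.lru_cache(maxsize=64)
def _score_table(params: FoldParams) -> np.ndarray:
    """5x5 base-pair score lookup (A,C,G,U,N); -inf marks illegal pairs."""
    table = np.full((5, 5), NEG_INF)
    for (a, b), key in _PAIR_KEY.items():
        table[_BASE_INDEX[a], _BASE_INDEX[b]] = params.pair_scores[key]
    return table


def _score_matrix(seq: str, params: FoldParams) -> np.ndarray:
    idx = np.fromiter((_BASE_INDEX[c] for c in seq), dtype=np.intp, count=len(seq))
    S = _score_table(params)[idx[:, None], idx[None, :]]
    return np.where(np.triu(np.ones_like(S, dtype=bool), k=1), S, NEG_INF)


def fold(sequence: str, params: FoldParams = DEFAULT_PARAMS) -> FoldResult:
    """Predict the maximum-score non-crossing structure of ``sequence``.

    Dynamic program over (i, j) intervals; ``V`` scores intervals whose ends
    pair, ``W`` unrestricted intervals, ``Wnp`` intervals whose ends do not
    pair with each other (needed so the stacking bonus is awarded exactly
    when two pairs are adjacent). Traceback is deterministic: at score ties
    the 5'-most base is paired, to its 5'-most eligible partner.
    """
    seq = _validate_sequence(sequence)
    n = len(seq)
    if n == 0:
        raise ValueError("empty sequence")

    S = _score_matrix(seq, params)
    Vm, Wm, Wnpm = _fill_tables(S, params.min_loop, params.stack_bonus)
    V = Vm  # V[i, j]: best score of seq[i..j] with (i,j) paired; -inf if illegal
    W, Wnp = Wm, Wnpm

    def w(i: int, j: int) -> float:
        return W[i, j] if i <= j else 0.0

    pairs: set[tuple[int, int]] = set()

    def trace_v(i: int, j: int) -> None:
        pairs.add((i, j))
        s = params.pair_score(seq[i], seq[j])
        assert s is not None
        stacked = V[i + 1][j - 1] if i + 1 <= j - 1 else NEG_INF
        # replicate the DP's operation order so float equality is exact
        if stacked > NEG_INF and s + (stacked + params.stack_bonus) == V[i][j]:
            trace_v(i + 1, j - 1)
        else:
            trace_w(i + 1, j - 1, exclude_end_pair=True)

    def trace_w(i: int, j: int, exclude_end_pair: bool = False) -> None:
        if i >= j:
            return
        target = Wnp[i][j] if exclude_end_pair else W[i][j]
        kmax = j - 1 if exclude_end_pair else j
        for k in range(i + params.min_loop + 1, kmax + 1):
            if V[i][k] > NEG_INF and V[i][k] + w(k + 1, j) == target:
                trace_v(i, k)
                trace_w(k + 1, j)
                return
        trace_w(i + 1, j)

    trace_w(0, n - 1)
    score = float(W[0, n - 1]) if n > 1 else 0.0
    final_pairs = _dissolve_short_helices(frozenset(pairs), params.min_helix)
    return FoldResult(
        sequence=seq,
        structure=to_dotbracket(final_pairs, n),
        score=score,
        pairs=final_pairs,
    )


@functools.lru_cache(maxsize=200_000)
def fold_cached(sequence: str, params: FoldParams = DEFAULT_PARAMS) -> FoldResult:
    """Memoized :func:`fold`; read sets contain many duplicate sequences."""
    return fold(sequence, params)


MAX_ENUM_LENGTH = 16


def _enumerate_pairsets(
    seq: str, i: int, j: int, params: FoldParams
) -> Iterator[frozenset[tuple[int, int]]]:
    if i >= j:
        yield frozenset()
        return
    # base i unpaired
    for rest in _enumerate_pairsets(seq, i + 1, j, params):
        yield rest
    # base i paired with k
    for k in range(i + params.min_loop + 1, j + 1):
        if params.pair_score(seq[i], seq[k]) is None:
            continue
        for inner in _enumerate_pairsets(seq, i + 1, k - 1, params):
            for outer in _enumerate_pairsets(seq, k + 1, j, params):
                yield inner | outer | {(i, k)}


def enumerate_structures(
    sequence: str, params: FoldParams = DEFAULT_PARAMS
) -> list[FoldResult]:
    """Brute-force enumeration of every legal non-crossing structure.

    Legality covers the pairing rules, minimum loop and non-crossing; the
    ``min_helix`` presentation filter is not applied, so the maximum score in
    the list equals :func:`fold`'s reported DP score exactly. Testing oracle;
    guarded to short sequences.
    """
    seq = _validate_sequence(sequence)
    if len(seq) > MAX_ENUM_LENGTH:
        raise ValueError(
            f"enumeration guarded to length <= {MAX_ENUM_LENGTH} (got {len(seq)})"
        )
    results = []
    for pairs in _enumerate_pairsets(seq, 0, len(seq) - 1, params):
        results.append(
            FoldResult(
                sequence=seq,
                structure=to_dotbracket(pairs, len(seq)),
                score=structure_score(seq, pairs, params),
                pairs=frozenset(pairs),
            )
        )
    return results


def to_dotbracket(pairs: frozenset[tuple[int, int]] | set[tuple[int, int]], length: int) -> str:
    """Render a non-crossing pair set as a dot-bracket string."""
    chars = ["."] * length
    seen: set[int] = set()
    sorted_pairs = sorted(pairs)
    for a, (i, j) in enumerate(sorted_pairs):
        if not (0 <= i < j < length):
            raise ValueError(f"pair ({i},{j}) out of range for length {length}")
        if i in seen or j in seen:
            raise ValueError(f"position in multiple pairs: ({i},{j})")
        seen.update((i, j))
        for k, l in sorted_pairs[a + 1:]:
            if i < k <= j < l:
                raise ValueError(f"crossing pairs ({i},{j}) and ({k},{l})")
        chars[i] = "("
        chars[j] = ")"
    return "".join(chars)


def parse_dotbracket(structure: str) -> frozenset[tuple[int, int]]:
    """Inverse of :func:`to_dotbracket`."""
    stack: list[int] = []
    pairs: set[tuple[int, int]] = set()
    for idx, ch in enumerate(structure):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {idx}")
            pairs.add((stack.pop(), idx))
        elif ch != ".":
            raise ValueError(f"invalid structure character {ch!r} at {idx}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return frozenset(pairs)
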