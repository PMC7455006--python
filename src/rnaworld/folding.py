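"""Secondary-structure prediction and the folded-state fraction ``l``.

Only the *number* of paired nucleotides feeds the simulation — the
folded-state fraction ``l`` gates both enzymatic activity (a folded enzyme
is active) and template accessibility (an unfolded template is copyable).
The built-in predictor therefore maximises the base-pair count (Nussinov
dynamic programming) over nested structures, subject to a hairpin-loop
constraint and a configurable chemical pairing rule (Watson-Crick with or
without G·U wobble). An external predictor can be plugged in through a
simple callable contract; its output is validated against the structure
invariants but may contain crossing (pseudoknotted) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, FrozenSet, Tuple

import numpy as np

from . import _kernels
from .sequences import encode, validate_sequence

#: Chemical pairs by code (A=0, C=1, G=2, U=3).
_WC_PAIRS = {(0, 3), (3, 0), (1, 2), (2, 1)}
_WOBBLE_PAIRS = {(2, 3), (3, 2)}

ExternalBackend = Callable[[str], str]
"""An external folding backend maps an RNA string to a dot-bracket string."""


@lru_cache(maxsize=None)
def pair_matrix(allow_wobble: bool = True) -> np.ndarray:
    """4x4 boolean matrix of allowed pairs in code space."""
    mat = np.zeros((4, 4), dtype=np.bool_)
    pairs = _WC_PAIRS | (_WOBBLE_PAIRS if allow_wobble else set())
    for i, j in pairs:
        mat[i, j] = True
    mat.setflags(write=False)
    return mat


@dataclass(frozen=True)
class FoldingOptions:
    """Folding configuration.

    min_loop
        Minimum number of unpaired nucleotides enclosed by a pair (hairpin
        loop size); a pair (i, j) requires j - i - 1 >= min_loop.
    allow_wobble
        Whether G·U wobble pairs are chemically allowed in addition to
        Watson-Crick A·U and G·C.
    backend
        ``"builtin"`` for the max-pairing predictor, or a callable mapping
        an RNA string to a dot-bracket string (an external predictor).
    """

    min_loop: int = 3
    allow_wobble: bool = True
    backend: str | ExternalBackend = "builtin"

    def __post_init__(self) -> None:
        if self.min_loop < 0:
            raise ValueError("min_loop must be >= 0")
        if self.backend != "builtin" and not callable(self.backend):
            raise ValueError(
                "backend must be 'builtin' or a callable(seq) -> dot-bracket"
            )


@dataclass(frozen=True)
class SecondaryStructure:
    """A set of base pairs over a sequence of known length.

    Pairs are 0-based ``(i, j)`` tuples with ``i < j``; each position
    participates in at most one pair. Crossing pairs are permitted in the
    data model (external predictors may emit pseudoknots); the built-in
    predictor only ever produces nested structures.
    """

    pairs: FrozenSet[Tuple[int, int]]
    length: int

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for i, j in self.pairs:
            if not 0 <= i < j < self.length:
                raise ValueError(f"pair {(i, j)} out of bounds or unordered")
            if i in seen or j in seen:
                raise ValueError(f"position in more than one pair: {(i, j)}")
            seen.add(i)
            seen.add(j)

    @property
    def n_paired(self) -> int:
        return 2 * len(self.pairs)

    def partner_table(self) -> np.ndarray:
        pt = np.full(self.length, -1, dtype=np.int32)
        for i, j in self.pairs:
            pt[i] = j
            pt[j] = i
        return pt


def folded_fraction(structure: SecondaryStructure) -> float:
    """Fraction of nucleotides paired: ``l = 2 |pairs| / length``."""
    if structure.length == 0:
        return 0.0
    return structure.n_paired / structure.length


def predict_structure(
    seq: str, opts: FoldingOptions | None = None
) -> SecondaryStructure:
    """Predict a secondary structure for *seq* under *opts*.

    The built-in backend returns the nested structure with the maximum
    number of pairs (deterministic traceback: the 5'-most position of each
    interval pairs its leftmost admissible partner whenever pairing is
    optimal). An external backend's dot-bracket output is parsed and
    validated; failures propagate — there is no silent fallback.
    """
    opts = opts or FoldingOptions()
    validate_sequence(seq)
    if opts.backend == "builtin":
        pt = _kernels.nussinov_pair_table(
            encode(seq), opts.min_loop, pair_matrix(opts.allow_wobble)
        )
        pairs = frozenset(
            (i, int(j)) for i, j in enumerate(pt) if 0 <= i < j
        )
        return SecondaryStructure(pairs=pairs, length=len(seq))
    dot_bracket = opts.backend(seq)
    return dotbracket_to_structure(dot_bracket)


def structure_and_fraction(
    seq: str, opts: FoldingOptions | None = None
) -> tuple[SecondaryStructure, float]:
    """Convenience: predict and score in one call."""
    s = predict_structure(seq, opts)
    return s, folded_fraction(s)


# ---------------------------------------------------------------------------
# Exhaustive enumeration (test oracle for the DP)
# ---------------------------------------------------------------------------

_ENUM_MAX_LEN = 16


def enumerate_structures(
    seq: str, opts: FoldingOptions | None = None
) -> list[SecondaryStructure]:
    """Exhaustively enumerate every valid nested structure of a short seq.

    Combinatorial oracle used to verify the DP optimum; guarded to
    sequences of length <= 16.
    """
    opts = opts or FoldingOptions()
    if len(seq) > _ENUM_MAX_LEN:
        raise ValueError(
            f"enumeration limited to length <= {_ENUM_MAX_LEN}"
        )
    codes = encode(seq)
    mat = pair_matrix(opts.allow_wobble)
    min_loop = opts.min_loop

    memo: dict[tuple[int, int], list[tuple[tuple[int, int], ...]]] = {}

    def region(i: int, j: int) -> list[tuple[tuple[int, int], ...]]:
        if i >= j:
            return [()]
        key = (i, j)
        if key in memo:
            return memo[key]
        out: list[tuple[tuple[int, int], ...]] = list(region(i + 1, j))
        for k in range(i + min_loop + 1, j + 1):
            if mat[codes[i], codes[k]]:
                for left in region(i + 1, k - 1):
                    for right in region(k + 1, j):
                        out.append(((i, k),) + left + right)
        memo[key] = out
        return out

    return [
        SecondaryStructure(pairs=frozenset(s), length=len(seq))
        for s in region(0, len(seq) - 1)
    ]


# ---------------------------------------------------------------------------
# Dot-bracket exchange format
# ---------------------------------------------------------------------------

_OPENERS = "([{<"
_CLOSERS = ")]}>"


def structure_to_dotbracket(structure: SecondaryStructure) -> str:
    """Render a structure as dot-bracket; crossing pairs use extra layers."""
    chars = ["."] * structure.length
    layers: list[list[tuple[int, int]]] = []
    for pair in sorted(structure.pairs):
        for depth, layer in enumerate(layers):
            if not any(a < pair[0] < b < pair[1] for a, b in layer):
                layer.append(pair)
                break
        else:
            depth = len(layers)
            layers.append([pair])
        if depth >= len(_OPENERS):
            raise ValueError("structure too deeply pseudoknotted to render")
        chars[pair[0]] = _OPENERS[depth]
        chars[pair[1]] = _CLOSERS[depth]
    return "".join(chars)


def dotbracket_to_structure(dot_bracket: str) -> SecondaryStructure:
    """Parse dot-bracket (multi-layer brackets allowed) into a structure."""
    stacks: dict[int, list[int]] = {k: [] for k in range(len(_OPENERS))}
    pairs: set[tuple[int, int]] = set()
    for pos, ch in enumerate(dot_bracket):
        if ch == ".":
            continue
        if ch in _OPENERS:
            stacks[_OPENERS.index(ch)].append(pos)
        elif ch in _CLOSERS:
            layer = _CLOSERS.index(ch)
            if not stacks[layer]:
                raise ValueError(f"unbalanced bracket at position {pos}")
            pairs.add((stacks[layer].pop(), pos))
        else:
            raise ValueError(f"invalid dot-bracket symbol {ch!r}")
    for layer, stack in stacks.items():
        if stack:
            raise ValueError("unbalanced brackets: unclosed opener")
    return SecondaryStructure(pairs=frozenset(pairs), length=len(dot_bracket))
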