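"""RNA sequence primitives and the sequence-to-parameter mappings.

Every agent in the simulator carries an explicit RNA sequence (a string over
``A, C, G, U``) from which all of its behavioural parameters are derived:

* the replicase efficiency ``a`` comes from an ungapped position-wise
  comparison of the first 20 nucleotides against a catalytic motif,
* the decay rate ``b`` is the base decay rate plus the summed hydrolysis
  rates of the phosphodiester bonds along the strand,
* the folded-state fraction ``l`` comes from secondary-structure prediction
  (see :mod:`rnaworld.folding`).

This module owns the sequence-level operations: random pools, mutation,
reverse complement, motif scoring, decay-rate summation and the construction
of ideal replicases, plus FASTA round-tripping for custom populations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGU"
_CODE = {c: i for i, c in enumerate(ALPHABET)}
#: Complement in code space: A(0)<->U(3), C(1)<->G(2).
_COMP_CODE = np.array([3, 2, 1, 0], dtype=np.uint8)

#: 5'-terminal catalytic motif of the engineered polymerase ribozyme tC19Z,
#: used as the replicase signature.
REPLICASE_MOTIF = "UCAUUGAAAAAAAAAGACAA"

#: Non-enzymatic phosphodiester hydrolysis rates (per time unit) measured for
#: spontaneous RNA degradation; 5'->3' dinucleotide keyed. Bonds not listed
#: hydrolyse at rate 0.
MEASURED_HYDROLYSIS_RATES: Mapping[str, float] = {
    "UA": 0.000953,
    "CA": 0.000932,
    "UC": 0.000846,
    "CC": 0.000846,
    "UG": 0.000100,
    "CG": 0.000100,
    "UU": 0.000100,
    "CU": 0.000100,
}


def encode(seq: str) -> np.ndarray:
    """Encode an RNA string as a uint8 array (A=0, C=1, G=2, U=3)."""
    try:
        return np.array([_CODE[c] for c in seq], dtype=np.uint8)
    except KeyError as exc:  # pragma: no cover - message only
        raise ValueError(f"invalid RNA symbol {exc.args[0]!r}") from None


def decode(codes: Iterable[int]) -> str:
    """Decode a code array back to an RNA string."""
    return "".join(ALPHABET[int(c)] for c in codes)


def validate_sequence(seq: str) -> None:
    """Raise ``ValueError`` if *seq* contains a symbol outside {A,C,G,U}."""
    bad = set(seq) - set(ALPHABET)
    if bad:
        raise ValueError(f"invalid RNA symbols: {sorted(bad)}")


@dataclass(frozen=True)
class ReplicaseMotif:
    """Catalytic motif and the match-count -> replication-rate rule.

    An agent whose first ``len(bases)`` nucleotides match the motif in at
    least ``match_threshold`` positions is a replicase with replication rate
    ``k_R = rate_per_match * matches``; below the threshold ``k_R = 0`` and
    the agent is a parasite.
    """

    bases: str = REPLICASE_MOTIF
    match_threshold: int = 7
    rate_per_match: float = 10.0

    def __post_init__(self) -> None:
        validate_sequence(self.bases)
        if not 0 <= self.match_threshold <= len(self.bases):
            raise ValueError("match_threshold must lie in [0, motif length]")
        if self.rate_per_match < 0:
            raise ValueError("rate_per_match must be >= 0")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def codes(self) -> np.ndarray:
        return encode(self.bases)


@dataclass(frozen=True)
class HydrolysisTable:
    """Per-dinucleotide phosphodiester hydrolysis rates.

    Lookup is by the ordered 5'->3' neighbour pair (``UA`` is distinct from
    ``AU``); any dinucleotide absent from ``rates`` hydrolyses at rate 0.
    """

    rates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for dinuc, rate in self.rates.items():
            if len(dinuc) != 2:
                raise ValueError(f"not a dinucleotide: {dinuc!r}")
            validate_sequence(dinuc)
            if rate < 0:
                raise ValueError(f"negative hydrolysis rate for {dinuc}")
        # freeze the mapping so the dataclass is safely hashable-by-identity
        object.__setattr__(self, "rates", dict(self.rates))

    def rate(self, dinucleotide: str) -> float:
        return self.rates.get(dinucleotide, 0.0)

    def to_matrix(self) -> np.ndarray:
        """4x4 rate matrix indexed by (5' base code, 3' base code)."""
        mat = np.zeros((4, 4), dtype=np.float64)
        for dinuc, rate in self.rates.items():
            mat[_CODE[dinuc[0]], _CODE[dinuc[1]]] = rate
        return mat

    @classmethod
    def zero(cls) -> "HydrolysisTable":
        return cls({})

    @classmethod
    def measured(cls) -> "HydrolysisTable":
        """Table of measured non-enzymatic hydrolysis rates."""
        return cls(dict(MEASURED_HYDROLYSIS_RATES))

    @classmethod
    def from_file(cls, path: str | Path) -> "HydrolysisTable":
        """Load a two-column whitespace-separated file: dinucleotide, rate."""
        rates: dict[str, float] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                dinuc, value = line.split()
                rates[dinuc.upper().replace("T", "U")] = float(value)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: expected 'dinucleotide rate', got {line!r}"
                ) from None
        return cls(rates)

    def to_file(self, path: str | Path) -> None:
        lines = [f"{d}\t{r:g}" for d, r in sorted(self.rates.items())]
        Path(path).write_text("\n".join(lines) + "\n")


def random_sequence(length: int, rng: np.random.Generator) -> str:
    """Draw a uniform random RNA sequence of the given length."""
    if length <= 0:
        raise ValueError("sequence length must be positive")
    return decode(rng.integers(0, 4, size=length))


def reverse_complement(seq: str) -> str:
    """Watson-Crick complement (A<->U, C<->G) read in reverse order."""
    return decode(_COMP_CODE[encode(seq)][::-1])


def mutate(seq: str, seq_mut: float, rng: np.random.Generator) -> str:
    """Apply independent per-site substitutions.

    Each nucleotide is replaced with probability ``seq_mut``; the replacement
    is uniform over the three other symbols (a site never "mutates" to
    itself). Only substitutions occur, so the length is preserved.
    """
    if not 0.0 <= seq_mut <= 1.0:
        raise ValueError("seq_mut must be a probability")
    codes = encode(seq)
    hits = rng.random(codes.size) < seq_mut
    n_hits = int(hits.sum())
    if n_hits:
        shifts = rng.integers(1, 4, size=n_hits).astype(np.uint8)
        codes[hits] = (codes[hits] + shifts) % 4
    return decode(codes)


def motif_match_count(seq: str, motif: ReplicaseMotif | None = None) -> int:
    """Count position-wise identities between the 5' prefix and the motif.

    No alignment is performed: position i of the sequence is compared with
    position i of the motif, over the motif length only.
    """
    motif = motif or ReplicaseMotif()
    if len(seq) < len(motif):
        raise ValueError("sequence shorter than the motif")
    return sum(s == m for s, m in zip(seq, motif.bases))


def replication_rate(seq: str, motif: ReplicaseMotif | None = None) -> float:
    """Replication rate k_R: rate_per_match * matches, zeroed below threshold."""
    motif = motif or ReplicaseMotif()
    matches = motif_match_count(seq, motif)
    if matches < motif.match_threshold:
        return 0.0
    return motif.rate_per_match * matches


def replicase_efficiency(k_r: float, dt: float) -> float:
    """Per-step replication probability ``a = 1 - exp(-k_R * dt)``.

    Derived from constant-hazard (Poisson) kinetics: the probability that a
    reaction with rate k_R fires within one step of length dt. ``a = 0``
    exactly when ``k_R = 0``, which marks the agent as a parasite.
    """
    if k_r < 0:
        raise ValueError("k_R must be >= 0")
    if dt <= 0:
        raise ValueError("dt must be positive")
    return -math.expm1(-k_r * dt)


def decay_rate(
    seq: str, base_d: float, table: HydrolysisTable | None = None
) -> float:
    """Decay rate ``b``: base rate plus summed bond hydrolysis rates.

    Every pair of neighbouring nucleotides contributes the hydrolysis rate of
    its 5'->3' dinucleotide, e.g. UUUACG contributes d(UU) twice, d(UA),
    d(AC) and d(CG).
    """
    if base_d < 0:
        raise ValueError("base decay rate must be >= 0")
    table = table or HydrolysisTable.zero()
    return base_d + sum(
        table.rate(seq[i : i + 2]) for i in range(len(seq) - 1)
    )


def build_ideal_replicase(
    motif: ReplicaseMotif | None = None,
    seq_length: int = 50,
    rng: np.random.Generator | None = None,
) -> str:
    """Construct an ideal replicase sequence.

    Positions 1-20 carry the motif, positions 21-40 its reverse complement
    (the two fragments form a designed stem), and the 3'-terminal ten
    nucleotides are uniform random. Such an agent scores a full motif match
    and therefore the maximal replication rate.
    """
    motif = motif or ReplicaseMotif()
    tail = seq_length - 2 * len(motif)
    if tail < 0:
        raise ValueError(
            f"seq_length {seq_length} cannot hold motif plus complement "
            f"({2 * len(motif)} nt)"
        )
    if rng is None:
        rng = np.random.default_rng()
    stem = motif.bases + reverse_complement(motif.bases)
    if tail == 0:
        return stem
    return stem + random_sequence(tail, rng)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read (id, sequence) pairs from a FASTA file; T is read as U."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("T", "U")
        validate_sequence(seq)
        records.append((rec.id, seq))
    return records


def write_fasta(
    records: Sequence[tuple[str, str]] | Sequence[tuple[str, str, str]],
    path: str | Path,
) -> None:
    """Write (id, seq) or (id, seq, description) tuples as FASTA."""
    out = []
    for rec in records:
        rid, seq = rec[0], rec[1]
        desc = rec[2] if len(rec) > 2 else ""
        out.append(SeqRecord(Seq(seq), id=str(rid), description=desc))
    SeqIO.write(out, str(path), "fasta")
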