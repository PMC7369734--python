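"""Reading, validation and generation of DNA sequences.

Sequences are plain ACGT strings.  Real data enters through FASTA files
(via Biopython); benchmark data is generated here, either as i.i.d.
uniform sequences or as first-order Markov sequences constrained never to
contain a given set of dinucleotides ("forbidden-pair" / TR models).
Every generator takes an explicit integer seed; no global random state is
touched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ALPHABET",
    "NucleotideSequence",
    "ForbiddenPairSet",
    "TR_MODELS",
    "read_fasta",
    "write_fasta",
    "clean_bases",
    "generate_random_sequence",
    "generate_forbidden_pair_sequence",
]

logger = logging.getLogger(__name__)

#: The DNA alphabet, in the fixed order used to index vertices and transition rows.
ALPHABET = "ACGT"
_ALPHABET_SET = frozenset(ALPHABET)


@dataclass(frozen=True)
class NucleotideSequence:
    """A validated DNA sequence over the strict {A, C, G, T} alphabet.

    Parameters
    ----------
    id
        Free-text label (FASTA identifier or generator tag).
    bases
        Upper-case string containing only A, C, G, T; must be non-empty.
    """

    id: str
    bases: str

    def __post_init__(self) -> None:
        if len(self.bases) == 0:
            raise ValueError(f"sequence {self.id!r} has zero valid bases")
        invalid = set(self.bases) - _ALPHABET_SET
        if invalid:
            raise ValueError(
                f"sequence {self.id!r} contains non-ACGT symbols {sorted(invalid)}; "
                "use clean_bases() or read_fasta() first"
            )

    def __len__(self) -> int:
        return len(self.bases)

    def __iter__(self):
        return iter(self.bases)


def clean_bases(raw: str) -> tuple[str, int]:
    """Upper-case ``raw`` and drop every symbol outside {A, C, G, T}.

    Returns the cleaned string and the number of removed symbols
    (ambiguity codes such as N, gaps, whitespace).
    """
    upper = raw.upper()
    kept = "".join(c for c in upper if c in _ALPHABET_SET)
    return kept, len(upper) - len(kept)


def read_fasta(path: str | Path) -> list[NucleotideSequence]:
    """Read a (multi-record) FASTA file into validated sequences.

    Non-ACGT symbols (N, IUPAC ambiguity codes, gaps) are removed rather
    than rejected; the number of removals per record is logged so the
    cleaning can be audited.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        If the file contains no records, or a record has zero valid bases.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path} contains no FASTA records")
    out: list[NucleotideSequence] = []
    for rec in records:
        bases, n_removed = clean_bases(str(rec.seq))
        if n_removed:
            logger.info("record %s: removed %d non-ACGT symbols", rec.id, n_removed)
        if not bases:
            raise ValueError(f"record {rec.id!r} in {path} has zero valid bases")
        out.append(NucleotideSequence(id=rec.id, bases=bases))
    return out


def write_fasta(sequences: Iterable[NucleotideSequence], path: str | Path) -> None:
    """Write sequences to ``path`` in FASTA format (60-column wrapped)."""
    records = [SeqRecord(Seq(s.bases), id=s.id, description="") for s in sequences]
    SeqIO.write(records, str(path), "fasta")


@dataclass(frozen=True)
class ForbiddenPairSet:
    """A set of ordered dinucleotides that must never occur in a sequence.

    The constraint is checked at construction: every base must keep at
    least one allowed successor, otherwise generation would dead-end.
    """

    pairs: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        pairs = frozenset(tuple(p) for p in self.pairs)
        object.__setattr__(self, "pairs", pairs)
        for pred, succ in pairs:
            if pred not in _ALPHABET_SET or succ not in _ALPHABET_SET:
                raise ValueError(f"forbidden pair ({pred!r}, {succ!r}) is not over ACGT")
        for base in ALPHABET:
            if not self.allowed_successors(base):
                raise ValueError(f"base {base!r} has all four successors forbidden")

    def allowed_successors(self, base: str) -> str:
        return "".join(s for s in ALPHABET if (base, s) not in self.pairs)

    def __contains__(self, pair) -> bool:
        return tuple(pair) in self.pairs


#: Forbidden-dinucleotide benchmark models: TR12 bans A->T, TR13 bans A->G,
#: TR33 bans G->G.  Each yields a fractal chaos-game representation whose
#: empty regions follow a power-law size distribution.
TR_MODELS: dict[str, ForbiddenPairSet] = {
    "TR12": ForbiddenPairSet(frozenset({("A", "T")})),
    "TR13": ForbiddenPairSet(frozenset({("A", "G")})),
    "TR33": ForbiddenPairSet(frozenset({("G", "G")})),
}


def generate_random_sequence(
    length: int, seed: int, id: str | None = None
) -> NucleotideSequence:
    """Generate an i.i.d. uniform ACGT sequence of the given length."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, 4, size=length)
    bases = "".join(ALPHABET[i] for i in idx)
    return NucleotideSequence(id=id or f"random_n{length}_seed{seed}", bases=bases)


def generate_forbidden_pair_sequence(
    length: int,
    forbidden: ForbiddenPairSet,
    seed: int,
    id: str | None = None,
) -> NucleotideSequence:
    """Generate a random ACGT sequence avoiding every forbidden dinucleotide.

    The first base is uniform over the alphabet; each subsequent base is
    uniform over the successors of the previous base that are not
    forbidden (a first-order Markov chain).  By construction no forbidden
    pair occurs anywhere in the output.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    successors = {b: forbidden.allowed_successors(b) for b in ALPHABET}
    # Draw all uniform variates up front; index into per-state successor lists.
    u = rng.random(length)
    out = [ALPHABET[int(u[0] * 4)]]
    for k in range(1, length):
        allowed = successors[out[-1]]
        out.append(allowed[int(u[k] * len(allowed))])
    bases = "".join(out)
    return NucleotideSequence(id=id or f"forbidden_n{length}_seed{seed}", bases=bases)
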