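"""SMILES tokenization, vocabulary handling, and ``.smi`` corpus I/O.

A :class:`Vocabulary` maps between token strings and contiguous integer
indices. Three special markers are always present and always occupy the
lowest indices: padding, begin-of-sequence, and end-of-sequence. Chemical
tokens follow, sorted lexicographically, so a vocabulary built from the same
corpus is identical on every machine.

Tokenization is longest-match over a fixed table: two-character halogens
(``Cl``, ``Br``) and bracket atoms (``[nH]``, ``[O-]``, ...) are single
tokens; everything else (ring digits, bonds, branches, ``%nn`` ring labels)
is split per character except the two-digit ``%`` ring form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

PAD = "<pad>"
BOS = "<bos>"
EOS = "<eos>"
SPECIALS = (PAD, BOS, EOS)

_TWO_CHAR = ("Cl", "Br")


class TokenizationError(ValueError):
    """Raised when a SMILES string cannot be split into tokens."""


class VocabularyError(KeyError):
    """Raised on out-of-vocabulary tokens or invalid indices."""


def tokenize(smiles: str) -> list[str]:
    """Split a SMILES string into tokens.

    The concatenation of the returned tokens always equals the input.

    Raises
    ------
    TokenizationError
        If the string is empty or contains an unmatched ``[``.
    """
    if not smiles:
        raise TokenizationError("cannot tokenize an empty string")
    tokens: list[str] = []
    i = 0
    n = len(smiles)
    while i < n:
        ch = smiles[i]
        if ch == "[":
            j = smiles.find("]", i)
            if j < 0:
                raise TokenizationError(f"unmatched '[' at position {i} in {smiles!r}")
            tokens.append(smiles[i : j + 1])
            i = j + 1
        elif ch == "%" and i + 2 < n + 1 and smiles[i + 1 : i + 3].isdigit():
            tokens.append(smiles[i : i + 3])
            i += 3
        elif smiles[i : i + 2] in _TWO_CHAR:
            tokens.append(smiles[i : i + 2])
            i += 2
        else:
            tokens.append(ch)
            i += 1
    return tokens


@dataclass(frozen=True)
class Vocabulary:
    """Bijective token/index mapping with special markers first."""

    tokens: tuple[str, ...]
    _index: dict[str, int] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        index = {tok: i for i, tok in enumerate(self.tokens)}
        if len(index) != len(self.tokens):
            raise ValueError("duplicate tokens in vocabulary")
        for marker in SPECIALS:
            if marker not in index:
                raise ValueError(f"missing special marker {marker}")
        object.__setattr__(self, "_index", index)

    @classmethod
    def from_tokens(cls, chemical_tokens: Iterable[str]) -> "Vocabulary":
        chems = sorted(set(chemical_tokens) - set(SPECIALS))
        return cls(tokens=SPECIALS + tuple(chems))

    @classmethod
    def from_corpus(cls, corpus: Iterable[str]) -> "Vocabulary":
        seen: set[str] = set()
        for smi in corpus:
            seen.update(tokenize(smi))
        return cls.from_tokens(seen)

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self._index

    @property
    def pad(self) -> int:
        return self._index[PAD]

    @property
    def bos(self) -> int:
        return self._index[BOS]

    @property
    def eos(self) -> int:
        return self._index[EOS]

    def index(self, token: str) -> int:
        try:
            return self._index[token]
        except KeyError:
            raise VocabularyError(f"token {token!r} not in vocabulary") from None

    def encode(self, tokens: Sequence[str], add_markers: bool = True) -> list[int]:
        """Map token strings to indices, optionally wrapping in BOS/EOS."""
        if not tokens:
            raise VocabularyError("cannot encode an empty token list")
        body = [self.index(t) for t in tokens]
        if add_markers:
            return [self.bos] + body + [self.eos]
        return body

    def encode_smiles(self, smiles: str, add_markers: bool = True) -> list[int]:
        return self.encode(tokenize(smiles), add_markers=add_markers)

    def decode(self, indices: Sequence[int]) -> str:
        """Map indices back to a string, stripping special markers.

        Decoding stops at the first end marker; padding and begin markers are
        skipped wherever they occur, so incomplete (capped) sequences decode
        to their partial string.
        """
        out: list[str] = []
        for idx in indices:
            if not 0 <= int(idx) < len(self.tokens):
                raise VocabularyError(f"index {idx} outside vocabulary of size {len(self)}")
            tok = self.tokens[int(idx)]
            if tok == EOS:
                break
            if tok in (PAD, BOS):
                continue
            out.append(tok)
        return "".join(out)


def read_smi(path: str | Path) -> list[str]:
    """Read a ``.smi`` file: one SMILES per line, optional name column ignored.

    Blank lines are skipped; the skip count is logged.
    """
    path = Path(path)
    molecules: list[str] = []
    blanks = 0
    with path.open() as handle:
        for line in handle:
            stripped = line.strip()
            if not stripped:
                blanks += 1
                continue
            molecules.append(stripped.split()[0])
    if blanks:
        logger.info("read_smi(%s): skipped %d blank line(s)", path, blanks)
    return molecules


def write_smi(path: str | Path, molecules: Iterable[str]) -> None:
    """Write one SMILES per line."""
    path = Path(path)
    with path.open("w") as handle:
        for smi in molecules:
            handle.write(f"{smi}\n")
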