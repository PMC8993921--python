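"""Residue alphabets for aligned families.

The default alphabet is the 20 standard amino acids plus a single gap
symbol, giving C = 21 categories.  Ambiguity codes (B, J, X, Z) and the
rare residues U, O are mapped to the gap category by default so that C
stays fixed; the mapping is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field


AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: residues without a dedicated category in the default alphabet
AMBIGUOUS = "BJXZUO"


@dataclass(frozen=True)
class Alphabet:
    """Ordered residue alphabet with a single gap symbol.

    Parameters
    ----------
    symbols
        Residue characters in category order; must contain `gap` exactly once.
    gap
        The gap character.  Both ``'-'`` and ``'.'`` in input sequences are
        normalized to this symbol.
    unknown_to_gap
        If True, characters outside `symbols` (e.g. ambiguity codes) map to
        the gap category instead of raising.
    """

    symbols: str = AMINO_ACIDS + "-"
    gap: str = "-"
    unknown_to_gap: bool = True
    _index: dict = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self):
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be unique")
        if self.symbols.count(self.gap) != 1:
            raise ValueError("alphabet must contain the gap symbol exactly once")
        object.__setattr__(self, "_index", {s: i for i, s in enumerate(self.symbols)})

    @property
    def C(self) -> int:
        """Number of categories (21 for the default protein alphabet)."""
        return len(self.symbols)

    @property
    def gap_index(self) -> int:
        return self._index[self.gap]

    def encode_char(self, ch: str) -> int:
        ch = ch.upper()
        if ch in (".", "-"):
            return self.gap_index
        idx = self._index.get(ch)
        if idx is None:
            if self.unknown_to_gap:
                return self.gap_index
            raise ValueError(f"unknown residue {ch!r}")
        return idx

    def encode(self, seq: str):
        import numpy as np

        return np.array([self.encode_char(c) for c in seq], dtype=np.int64)

    def decode(self, codes) -> str:
        return "".join(self.symbols[int(c)] for c in codes)


#: the canonical 21-letter protein alphabet
PROTEIN = Alphabet()
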