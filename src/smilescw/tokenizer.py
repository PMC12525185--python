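"""SMILES-attribute extraction.

The molecular representation used throughout this package is not a molecular
graph but the SMILES string itself, cut into "SMILES atoms": indivisible
fragments such as ``C``, ``Cl``, ``[N+]`` or ``%11``.  Two classes of
attributes are derived from the token stream of one molecule:

* ``Sk`` — single SMILES atoms (one token each), and
* ``SSk`` — pairs of adjacent SMILES atoms, spelled in a canonical order so
  that the pair is independent of scan direction.

Stereochemistry markers are stripped before tokenization because the
correlation-weight model cannot use that information, and closing parentheses
are folded into ``(`` so that branch-neighbourhood attributes have a single
spelling (the attribute vocabulary of the method contains ``Cl(``, ``2(``,
``c(`` and the like, never a ``)``-containing attribute).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional

from .errors import MalformedSmilesError

__all__ = [
    "SmilesRecord",
    "AttributeProfile",
    "normalize_smiles",
    "tokenize",
    "pair_attribute",
    "extract_attributes",
    "profile_from_smiles",
]

#: Two-character element symbols recognized outside brackets.  The organic
#: subset of SMILES has exactly these; anything more exotic must be written
#: as a bracket atom, which is kept as one opaque token.
TWO_CHAR_ELEMENTS = ("Cl", "Br")

_STEREO_TABLE = str.maketrans("", "", "/\\@")


@dataclass(frozen=True)
class SmilesRecord:
    """One compound: identifier, raw SMILES, and optional endpoint.

    The endpoint is pLC50, the decimal logarithm of the LC50 concentration in
    mg/L; it is ``None`` for prediction-only inputs.
    """

    id: str
    smiles: str
    endpoint: Optional[float] = None


@dataclass(frozen=True)
class AttributeProfile:
    """Multiset of single-token (Sk) and neighbour-pair (SSk) attributes."""

    sk_counts: dict
    ssk_counts: dict

    def merged(self) -> dict:
        """Combined attribute → count map over both attribute classes.

        Sk and SSk keys live in one string namespace, mirroring how the
        method's weight tables list e.g. ``S`` and ``CC`` side by side.
        """
        out = dict(self.sk_counts)
        for key, cnt in self.ssk_counts.items():
            out[key] = out.get(key, 0) + cnt
        return out

    @property
    def n_tokens(self) -> int:
        return sum(self.sk_counts.values())


def normalize_smiles(smiles: str) -> str:
    """Strip stereochemistry and fold ``)`` into ``(``.

    Removes ``/``, ``\\`` and ``@`` (hence also ``@@``), strips surrounding
    whitespace, and replaces every closing parenthesis with ``(``.  All other
    characters are preserved in order.
    """
    out = smiles.strip().translate(_STEREO_TABLE).replace(")", "(")
    if not out:
        raise MalformedSmilesError("SMILES is empty after normalization")
    return out


def tokenize(normalized: str) -> list:
    """Cut a normalized SMILES into SMILES atoms by a left-to-right scan.

    ``Cl``/``Br`` are single tokens, ``[...]`` bracket atoms are single
    opaque tokens, ``%NN`` two-digit ring closures are single tokens, and
    every other character stands alone.
    """
    tokens = []
    i = 0
    n = len(normalized)
    while i < n:
        ch = normalized[i]
        if ch == "[":
            end = normalized.find("]", i + 1)
            if end < 0:
                raise MalformedSmilesError(
                    f"unterminated '[' at position {i}: {normalized!r}"
                )
            tokens.append(normalized[i : end + 1])
            i = end + 1
        elif ch == "%":
            digits = normalized[i + 1 : i + 3]
            if len(digits) != 2 or not digits.isdigit():
                raise MalformedSmilesError(
                    f"'%' not followed by two digits at position {i}: {normalized!r}"
                )
            tokens.append(normalized[i : i + 3])
            i += 3
        elif normalized[i : i + 2] in TWO_CHAR_ELEMENTS:
            tokens.append(normalized[i : i + 2])
            i += 2
        else:
            tokens.append(ch)
            i += 1
    return tokens


def pair_attribute(a: str, b: str) -> str:
    """Canonical spelling of a neighbour pair, independent of direction.

    The token whose leading character has the larger character code comes
    first (``('c','C') → 'cC'``, ``('(', 'Cl') → 'Cl('``); equal leading
    characters fall back to full-token comparison so the key is total.
    """
    if (ord(b[0]), b) > (ord(a[0]), a):
        a, b = b, a
    return a + b


def extract_attributes(tokens: list) -> AttributeProfile:
    """Count Sk and SSk attributes of one token sequence."""
    sk = Counter(tokens)
    ssk = Counter(pair_attribute(x, y) for x, y in zip(tokens, tokens[1:]))
    return AttributeProfile(sk_counts=dict(sk), ssk_counts=dict(ssk))


def profile_from_smiles(smiles: str) -> AttributeProfile:
    """Normalize, tokenize and count attributes in one call."""
    return extract_attributes(tokenize(normalize_smiles(smiles)))
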