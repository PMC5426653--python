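"""Atom-selection mini-language.

Tokens:

* residue tokens in one-letter + file-number form, e.g. ``L128`` (leucine 128,
  numbering verbatim from the input file);
* role tokens: ``protein``, ``water_oxygen``, ``water_hydrogen``,
  ``lipid_phosphorus``, ``wall``, ``other``;
* anything else is matched against atom names (e.g. ``CA``, ``OH``).

Tokens combine with ``and`` (intersection, binds tighter) and ``or`` (union);
parentheses group. Selection is deterministic and an empty result is legal
(logged, not an error).
"""

from __future__ import annotations

import logging
import re

import numpy as np

from .io import THREE_TO_ONE
from .model import AtomSelection, Role, Topology

logger = logging.getLogger(__name__)

__all__ = ["select", "SelectionError", "residue_token_mask"]

_ROLE_TOKENS = {r.value for r in Role}
_RESIDUE_RE = re.compile(r"^([A-Z])(\d+)$")


class SelectionError(ValueError):
    """Raised for an unparsable selection expression; carries the position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at token position {position})")
        self.position = position


def residue_token_mask(topology: Topology, token: str) -> np.ndarray:
    """Boolean atom mask for a one-letter residue token like ``Y306``."""
    m = _RESIDUE_RE.match(token)
    if m is None:
        raise ValueError(f"{token!r} is not a residue token")
    letter, num = m.group(1), int(m.group(2))
    ones = np.array(
        [THREE_TO_ONE.get(rn.upper(), "?") for rn in topology.residue_names],
        dtype=object,
    )
    return (ones == letter) & (topology.residue_numbers == num)


def _token_mask(topology: Topology, token: str) -> np.ndarray:
    if token in _ROLE_TOKENS:
        return topology.roles == token
    if _RESIDUE_RE.match(token):
        return residue_token_mask(topology, token)
    return topology.atom_names == token


class _Parser:
    def __init__(self, topology: Topology, tokens: list[str]):
        self.topology = topology
        self.tokens = tokens
        self.pos = 0

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of expression", self.pos)
        self.pos += 1
        return tok

    def parse_expr(self) -> np.ndarray:
        mask = self.parse_and()
        while self.peek() == "or":
            self.take()
            mask = mask | self.parse_and()
        return mask

    def parse_and(self) -> np.ndarray:
        mask = self.parse_term()
        while self.peek() == "and":
            self.take()
            mask = mask & self.parse_term()
        return mask

    def parse_term(self) -> np.ndarray:
        tok = self.take()
        if tok == "(":
            mask = self.parse_expr()
            if self.peek() != ")":
                raise SelectionError("missing closing parenthesis", self.pos)
            self.take()
            return mask
        if tok in (")", "or", "and"):
            raise SelectionError(f"unexpected token {tok!r}", self.pos - 1)
        return _token_mask(self.topology, tok)


def select(topology: Topology, expression: str) -> AtomSelection:
    """Evaluate a selection expression against a topology."""
    tokens = expression.replace("(", " ( ").replace(")", " ) ").split()
    if not tokens:
        raise SelectionError("empty expression", 0)
    parser = _Parser(topology, tokens)
    mask = parser.parse_expr()
    if parser.pos != len(tokens):
        raise SelectionError(
            f"trailing tokens starting with {tokens[parser.pos]!r}", parser.pos
        )
    sel = AtomSelection(np.flatnonzero(mask))
    if len(sel) == 0:
        logger.warning("selection %r matched no atoms", expression)
    return sel
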