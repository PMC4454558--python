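"""Minimal rooted ordered trees with Penn-style bracket serialisation.

Used for the reduced parse trees that summarise a sentence as the NP/VP
scaffold of its clauses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator


@dataclass(frozen=True)
class Tree:
    """A rooted ordered tree with string node labels.

    Equality is recursive on labels and child order, which is exactly the
    notion of "identical sub-tree" used by the reduced-parse-tree overlap.
    """

    label: str
    children: tuple["Tree", ...] = field(default_factory=tuple)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def subtrees(self) -> Iterator["Tree"]:
        """Yield every subtree rooted at a node, self first (pre-order)."""
        yield self
        for child in self.children:
            yield from child.subtrees()

    def __len__(self) -> int:
        return 1 + sum(len(c) for c in self.children)

    def to_bracket(self) -> str:
        """Serialise to Penn-style bracket notation, e.g. ``(S (NP) (VP))``."""
        if self.is_leaf:
            return f"({self.label})"
        inner = " ".join(c.to_bracket() for c in self.children)
        return f"({self.label} {inner})"

    @classmethod
    def from_bracket(cls, text: str) -> "Tree":
        """Parse Penn-style bracket notation produced by :meth:`to_bracket`.

        Raises ``ValueError`` on malformed input.
        """
        tokens = text.replace("(", " ( ").replace(")", " ) ").split()
        pos = 0

        def parse() -> Tree:
            nonlocal pos
            if pos >= len(tokens) or tokens[pos] != "(":
                raise ValueError(f"expected '(' at token {pos} of {text!r}")
            pos += 1
            if pos >= len(tokens) or tokens[pos] in "()":
                raise ValueError(f"missing node label at token {pos} of {text!r}")
            label = tokens[pos]
            pos += 1
            children = []
            while pos < len(tokens) and tokens[pos] == "(":
                children.append(parse())
            if pos >= len(tokens) or tokens[pos] != ")":
                raise ValueError(f"unbalanced brackets in {text!r}")
            pos += 1
            return cls(label, tuple(children))

        tree = parse()
        if pos != len(tokens):
            raise ValueError(f"trailing content after tree in {text!r}")
        return tree
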