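"""Restricted motif-pattern grammar.

Motif classes are expressed as regular expressions over the 20 amino-acid
letters, restricted to *finite, bounded* constructs so that each pattern can
be expanded into a small set of fixed-length residue-class strings.  That
expansion is what both the scanner and the background match-probability
model operate on, guaranteeing that the two agree by construction.

Grammar (one atom per pattern position)::

    atom     := '.' | LETTER | '[' '^'? LETTER+ ']'
    quant    := '?' | '{n}' | '{m,n}'        (bounded only)
    pattern  := (atom quant?)+

Unbounded repetition ('*', '+', '{n,}') is rejected: it would make the
begin-a-match probability ill-defined under the per-position product model.
The wildcard '.' means "any of the 20 amino acids"; the ambiguity letter X
matches nothing.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass

from .seqio import AMINO_ACIDS

_ALL = frozenset(AMINO_ACIDS)

MAX_VARIANTS = 256


class PatternError(ValueError):
    """Pattern outside the supported finite grammar."""


@dataclass(frozen=True)
class CompiledPattern:
    """A motif pattern expanded into fixed-length residue-class variants."""

    source: str
    #: each variant is a tuple of frozensets of allowed residues, one per position
    variants: tuple[tuple[frozenset[str], ...], ...]
    regex: "re.Pattern[str]"

    @property
    def min_length(self) -> int:
        return min(len(v) for v in self.variants)

    @property
    def max_length(self) -> int:
        return max(len(v) for v in self.variants)


def _parse_atoms(source: str) -> list[tuple[frozenset[str], int, int]]:
    """Parse into (residue set, min repeats, max repeats) triples."""
    atoms: list[tuple[frozenset[str], int, int]] = []
    i = 0
    n = len(source)
    while i < n:
        ch = source[i]
        if ch == ".":
            residues = _ALL
            i += 1
        elif ch == "[":
            j = source.find("]", i)
            if j == -1:
                raise PatternError(f"{source!r}: unterminated character class")
            body = source[i + 1 : j]
            negated = body.startswith("^")
            if negated:
                body = body[1:]
            letters = frozenset(body.upper())
            if not letters <= _ALL:
                raise PatternError(f"{source!r}: non-amino-acid letters in class [{body}]")
            residues = _ALL - letters if negated else letters
            i = j + 1
        elif ch.upper() in _ALL:
            residues = frozenset(ch.upper())
            i += 1
        elif ch in "*+":
            raise PatternError(f"{source!r}: unbounded repetition {ch!r} not supported")
        else:
            raise PatternError(f"{source!r}: unsupported token {ch!r} at offset {i}")
        lo, hi = 1, 1
        if i < n and source[i] == "?":
            lo, hi = 0, 1
            i += 1
        elif i < n and source[i] == "{":
            j = source.find("}", i)
            if j == -1:
                raise PatternError(f"{source!r}: unterminated quantifier")
            body = source[i + 1 : j]
            m = re.fullmatch(r"(\d+)(?:,(\d+)?)?", body)
            if not m or (m.group(0).count(",") and m.group(2) is None):
                raise PatternError(f"{source!r}: unbounded or malformed quantifier {{{body}}}")
            lo = int(m.group(1))
            hi = int(m.group(2)) if m.group(2) else lo
            if hi < lo:
                raise PatternError(f"{source!r}: quantifier {{{body}}} has max < min")
            i = j + 1
        if not residues:
            raise PatternError(f"{source!r}: empty residue class")
        atoms.append((residues, lo, hi))
    if not atoms:
        raise PatternError("empty pattern")
    return atoms


def compile_pattern(source: str) -> CompiledPattern:
    """Compile a pattern string, expanding it into fixed-length variants."""
    atoms = _parse_atoms(source)
    choices = [[k for k in range(lo, hi + 1)] for _, lo, hi in atoms]
    n_variants = 1
    for c in choices:
        n_variants *= len(c)
        if n_variants > MAX_VARIANTS:
            raise PatternError(f"{source!r}: more than {MAX_VARIANTS} length variants")
    variants = []
    for combo in itertools.product(*choices):
        positions: list[frozenset[str]] = []
        for (residues, _, _), k in zip(atoms, combo):
            positions.extend([residues] * k)
        if positions:
            variants.append(tuple(positions))
    if not variants:
        raise PatternError(f"{source!r}: pattern can match only the empty string")
    # shortest-first so same-start scan hits come out shortest-first
    variants.sort(key=lambda v: (len(v), [sorted(s) for s in v]))
    return CompiledPattern(source=source, variants=tuple(variants),
                           regex=re.compile(source))


def match_at(pattern: CompiledPattern, sequence: str, pos0: int) -> list[int]:
    """Lengths of all variants matching ``sequence`` at 0-based ``pos0``.

    Ascending, deduplicated.  X (or any letter outside the 20) matches no
    residue class.
    """
    lengths: list[int] = []
    for variant in pattern.variants:
        end = pos0 + len(variant)
        if end > len(sequence):
            continue
        if all(sequence[pos0 + k] in variant[k] for k in range(len(variant))):
            if not lengths or lengths[-1] != len(variant):
                lengths.append(len(variant))
    return lengths
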