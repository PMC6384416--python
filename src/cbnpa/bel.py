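"""Parser for a restricted BEL 1.0 statement dialect.

The supported grammar covers entity-level causal statements::

    statement := term relation term
    term      := FUNC "(" NS ":" ID ")"  |  "act" "(" term ")"
    FUNC      := p | r | a | bp | complex   (long synonyms accepted)
    relation  := increases | decreases | directlyIncreases | directlyDecreases

Identifiers containing spaces or other non-word characters must be
double-quoted (``bp(GO:"cilium assembly")``).  Any other relation token yields
a statement with ``relation="unsupported"`` (warning, never an edge); known
BEL functions outside the subset (``tloc``, ``deg``, ``pep``, ``pmod``, ...)
are rejected with an explicit message, as are unknown function names.

Scripts add an annotation state machine: ``SET Key = "value"`` /
``UNSET Key`` lines scope annotations onto subsequent statements, ``#``
starts a comment.
"""

from __future__ import annotations

import re
import warnings
from typing import Iterable, Optional

from .network import EntityRef, Statement, CAUSAL_RELATIONS

__all__ = ["BelParseError", "BelWarning", "parse_term", "parse_statement",
           "parse_script"]

_FUNC_KIND = {
    "p": "protein", "proteinAbundance": "protein",
    "r": "rna", "rnaAbundance": "rna",
    "a": "abundance", "abundance": "abundance",
    "bp": "bioprocess", "biologicalProcess": "bioprocess",
    "complex": "complex", "complexAbundance": "complex",
}

# recognized BEL 1.0 functions outside the supported subset
_REJECTED_FUNCS = {
    "tloc", "translocation", "deg", "degradation", "pep", "peptidaseActivity",
    "pmod", "proteinModification", "sub", "substitution", "trunc",
    "truncation", "fus", "fusion", "g", "geneAbundance", "m",
    "microRNAAbundance", "path", "pathology", "rxn", "reaction", "sec",
    "cellSecretion", "surf", "cellSurfaceExpression", "tscript",
    "transcriptionalActivity", "kin", "kinaseActivity", "cat",
    "catalyticActivity", "gtp", "gtpBoundActivity", "ribo",
    "ribosylationActivity", "phos", "phosphataseActivity", "chap",
    "chaperoneActivity", "tport", "transportActivity", "list", "composite",
}

_WORD = re.compile(r"[A-Za-z0-9_.\-]+")


class BelParseError(ValueError):
    """A malformed term or statement; carries 1-based line/column."""

    def __init__(self, message: str, line: int = 1, column: int = 1):
        super().__init__(f"line {line}, column {column}: {message}")
        self.line = line
        self.column = column


class BelWarning(UserWarning):
    """Recoverable oddity in a script (unsupported relation, stray UNSET)."""


class _Scanner:
    """Character scanner over one statement line."""

    def __init__(self, text: str, line: int = 1):
        self.text = text
        self.pos = 0
        self.line = line

    def error(self, message: str, pos: Optional[int] = None) -> BelParseError:
        return BelParseError(message, self.line,
                             (self.pos if pos is None else pos) + 1)

    def skip_ws(self) -> None:
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def expect(self, char: str) -> None:
        if self.peek() != char:
            found = self.peek() or "end of line"
            raise self.error(f"expected {char!r}, found {found!r}")
        self.pos += 1

    def word(self) -> str:
        m = _WORD.match(self.text, self.pos)
        if not m:
            found = self.peek() or "end of line"
            raise self.error(f"expected an identifier, found {found!r}")
        self.pos = m.end()
        return m.group()

    def quoted(self) -> str:
        start = self.pos
        self.expect('"')
        out = []
        while True:
            if self.pos >= len(self.text):
                raise self.error("unterminated quoted identifier", start)
            ch = self.text[self.pos]
            if ch == "\\" and self.pos + 1 < len(self.text):
                out.append(self.text[self.pos + 1])
                self.pos += 2
            elif ch == '"':
                self.pos += 1
                return "".join(out)
            else:
                out.append(ch)
                self.pos += 1

    def identifier(self) -> str:
        return self.quoted() if self.peek() == '"' else self.word()

    def term(self) -> EntityRef:
        start = self.pos
        func = self.word()
        if func == "act" or func == "activity":
            self.expect("(")
            self.skip_ws()
            inner = self.term()
            if inner.kind == "activity":
                raise self.error("nested activity terms are not allowed",
                                 start)
            self.skip_ws()
            self.expect(")")
            return EntityRef("activity", wrapped=inner)
        if func in _REJECTED_FUNCS:
            raise self.error(
                f"BEL function {func!r} is outside the supported subset "
                "(entity-level terms p/r/a/bp/complex and act only)", start)
        kind = _FUNC_KIND.get(func)
        if kind is None:
            raise self.error(f"unknown BEL function {func!r}", start)
        self.expect("(")
        self.skip_ws()
        namespace = self.word()
        self.skip_ws()
        self.expect(":")
        self.skip_ws()
        ident = self.identifier()
        if not ident:
            raise self.error("empty identifier")
        self.skip_ws()
        self.expect(")")
        return EntityRef(kind, namespace, ident)

    def relation(self) -> str:
        start = self.pos
        while self.pos < len(self.text) and not self.text[self.pos].isspace():
            self.pos += 1
        token = self.text[start:self.pos]
        if not token:
            raise self.error("expected a relation after the subject term",
                             start)
        if token in CAUSAL_RELATIONS:
            return token
        warnings.warn(f"line {self.line}: non-causal relation {token!r} "
                      "kept as unsupported", BelWarning, stacklevel=4)
        return "unsupported"


def parse_term(text: str, line: int = 1) -> EntityRef:
    """Parse a single BEL term such as ``p(HGNC:FOXJ1)``."""
    sc = _Scanner(text, line)
    sc.skip_ws()
    ref = sc.term()
    sc.skip_ws()
    if sc.pos != len(sc.text):
        raise sc.error(f"unexpected trailing text {sc.text[sc.pos:]!r}")
    return ref


def parse_statement(text: str, line: int = 1,
                    annotations: Optional[dict] = None) -> Statement:
    """Parse one statement line into subject, relation and object."""
    sc = _Scanner(text, line)
    sc.skip_ws()
    subject = sc.term()
    sc.skip_ws()
    relation = sc.relation()
    sc.skip_ws()
    obj = sc.term()
    sc.skip_ws()
    if sc.pos != len(sc.text):
        raise sc.error(f"unexpected trailing text {sc.text[sc.pos:]!r}")
    return Statement(subject, relation, obj,
                     annotations=dict(annotations or {}), source_line=line)


_SET_RE = re.compile(r"^SET\s+(\S+)\s*(=\s*(.*))?$")
_UNSET_RE = re.compile(r"^UNSET\s+(\S+)\s*$")


def parse_script(lines: Iterable[str]) -> list[Statement]:
    """Parse a BEL script: statements plus SET/UNSET annotation scoping.

    Each returned statement carries the annotation mapping in force at its
    line; source line numbers are 1-based.
    """
    statements: list[Statement] = []
    annotations: dict[str, str] = {}
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        m = _SET_RE.match(line)
        if m:
            if m.group(2) is None or not m.group(3).strip():
                raise BelParseError(
                    f"SET {m.group(1)} has no value", lineno, 1)
            value = m.group(3).strip()
            if value.startswith('"') and value.endswith('"') and len(value) > 1:
                value = value[1:-1]
            annotations[m.group(1)] = value
            continue
        m = _UNSET_RE.match(line)
        if m:
            if m.group(1) not in annotations:
                warnings.warn(f"line {lineno}: UNSET of never-set key "
                              f"{m.group(1)!r}", BelWarning, stacklevel=2)
            else:
                del annotations[m.group(1)]
            continue
        statements.append(parse_statement(line, lineno, annotations))
    return statements
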