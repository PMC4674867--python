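"""Bounded linear temporal logic (BLTL) over finite traces.

BLTL is LTL whose temporal operators carry integer step bounds, which makes
every formula decidable on a finite trace prefix (it is *monitorable*): the
prefix length needed is the formula's horizon.  Grammar::

    phi ::= a | phi & phi | phi "|" phi | !phi | phi U[d] phi
          | F[d] phi | G[d] phi | phi -> phi | (phi)

where ``a`` is an atomic proposition (a bare label name, or an inline numeric
comparison such as ``pro >= 2.5``) and ``d`` is a nonnegative integer bound.
``F[d] p == true U[d] p`` and ``G[d] p == !F[d] !p`` are derived operators;
``p -> q`` desugars to ``!p | q`` at parse time.  Precedence, tightest first:
``!``/``F``/``G``, ``U``, ``&``, ``|``, ``->``; ``U`` and ``->`` associate to
the right.

The bounded until ``p U[d] q`` holds on the suffix starting at position ``i``
iff there is an ``l <= d`` with ``q`` true at ``i+l`` and ``p`` true at every
``i+j`` for ``0 <= j < l``.  In particular ``F[0] q == q`` (``l = 0`` is
admitted).
"""

from __future__ import annotations

import enum
import operator
import re
from dataclasses import dataclass, field
from typing import Callable, Iterator, Mapping, Optional, Sequence, Tuple

__all__ = [
    "Kind",
    "Formula",
    "AtomicProposition",
    "State",
    "Trace",
    "ParseError",
    "TraceTooShortError",
    "parse_formula",
    "unparse",
    "required_horizon",
    "rewrite_derived",
    "evaluate",
    "read_formula_file",
]


class Kind(enum.Enum):
    ATOM = "atom"
    NOT = "not"
    AND = "and"
    OR = "or"
    UNTIL = "until"
    FINALLY = "finally"
    GLOBALLY = "globally"


_CMP_OPS: dict[str, Callable[[float, float], bool]] = {
    "<=": operator.le,
    ">=": operator.ge,
    "<": operator.lt,
    ">": operator.gt,
    "==": operator.eq,
    "!=": operator.ne,
}


@dataclass(frozen=True)
class Formula:
    """Immutable BLTL abstract-syntax-tree node.

    ``bound`` is present exactly on temporal nodes (UNTIL/FINALLY/GLOBALLY);
    ``atom`` names a registered proposition and ``comparison`` holds an
    inline ``(variable, op, constant)`` threshold atom — at most one of the
    two is set, on ATOM nodes only.
    """

    kind: Kind
    children: Tuple["Formula", ...] = ()
    bound: Optional[int] = None
    atom: Optional[str] = None
    comparison: Optional[Tuple[str, str, float]] = None

    def __post_init__(self) -> None:
        arity = {
            Kind.ATOM: 0,
            Kind.NOT: 1,
            Kind.AND: 2,
            Kind.OR: 2,
            Kind.UNTIL: 2,
            Kind.FINALLY: 1,
            Kind.GLOBALLY: 1,
        }[self.kind]
        if len(self.children) != arity:
            raise ValueError(f"{self.kind} expects {arity} children, got {len(self.children)}")
        needs_bound = self.kind in (Kind.UNTIL, Kind.FINALLY, Kind.GLOBALLY)
        if needs_bound and (self.bound is None or self.bound < 0):
            raise ValueError(f"{self.kind} requires a nonnegative integer bound")
        if not needs_bound and self.bound is not None:
            raise ValueError(f"{self.kind} does not take a bound")
        if self.kind is Kind.ATOM and (self.atom is None) == (self.comparison is None):
            raise ValueError("ATOM needs exactly one of atom name / comparison")

    # -- convenience constructors -------------------------------------
    @staticmethod
    def atom_(name: str) -> "Formula":
        return Formula(Kind.ATOM, atom=name)

    @staticmethod
    def cmp_(var: str, op: str, value: float) -> "Formula":
        if op not in _CMP_OPS:
            raise ValueError(f"unknown comparison operator {op!r}")
        return Formula(Kind.ATOM, comparison=(var, op, float(value)))

    @staticmethod
    def not_(child: "Formula") -> "Formula":
        return Formula(Kind.NOT, (child,))

    @staticmethod
    def and_(left: "Formula", right: "Formula") -> "Formula":
        return Formula(Kind.AND, (left, right))

    @staticmethod
    def or_(left: "Formula", right: "Formula") -> "Formula":
        return Formula(Kind.OR, (left, right))

    @staticmethod
    def until(bound: int, left: "Formula", right: "Formula") -> "Formula":
        return Formula(Kind.UNTIL, (left, right), bound=bound)

    @staticmethod
    def finally_(bound: int, child: "Formula") -> "Formula":
        return Formula(Kind.FINALLY, (child,), bound=bound)

    @staticmethod
    def globally(bound: int, child: "Formula") -> "Formula":
        return Formula(Kind.GLOBALLY, (child,), bound=bound)

    def __str__(self) -> str:
        return unparse(self)

    def subformulas(self) -> Iterator["Formula"]:
        """Postorder traversal (children before parents)."""
        for child in self.children:
            yield from child.subformulas()
        yield self


@dataclass(frozen=True)
class AtomicProposition:
    """A named boolean predicate over a state valuation."""

    name: str
    predicate: Callable[[Mapping[str, float]], bool]

    def holds(self, valuation: Mapping[str, float]) -> bool:
        return bool(self.predicate(valuation))


@dataclass(frozen=True)
class State:
    """One trace step: raw variable valuation plus the labels true in it."""

    valuation: Mapping[str, float]
    labels: frozenset[str]


@dataclass
class Trace:
    """Finite sequence of states with provenance metadata."""

    states: Sequence[State]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.states) < 1:
            raise ValueError("a trace must contain at least one state")

    def __len__(self) -> int:
        return len(self.states)

    def __getitem__(self, i: int) -> State:
        return self.states[i]


class ParseError(ValueError):
    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class TraceTooShortError(ValueError):
    """The trace prefix is too short to decide the formula (Lemma-style
    sufficiency fails); raised instead of silently guessing a truth value."""


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<num>\d+\.\d*|\.\d+|\d+)|(?P<ident>[A-Za-z_][A-Za-z0-9_]*)"
    r"|(?P<op>->|<=|>=|==|!=|[<>()!&|\[\]]))"
)


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens: list[tuple[str, str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            if text[pos:].strip() == "":
                break
            raise ParseError(f"unexpected character {text[pos]!r}", pos)
        if m.group("num") is not None:
            tokens.append(("num", m.group("num"), m.start()))
        elif m.group("ident") is not None:
            tokens.append(("ident", m.group("ident"), m.start()))
        else:
            tokens.append(("op", m.group("op"), m.start()))
        pos = m.end()
    return tokens


class _Parser:
    """Recursive descent for the grammar in the module docstring."""

    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def _peek(self) -> Optional[tuple[str, str, int]]:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def _next(self) -> tuple[str, str, int]:
        tok = self._peek()
        if tok is None:
            raise ParseError("unexpected end of input", len(self.text))
        self.i += 1
        return tok

    def _expect(self, value: str) -> None:
        tok = self._next()
        if tok[1] != value:
            raise ParseError(f"expected {value!r}, found {tok[1]!r}", tok[2])

    def parse(self) -> Formula:
        f = self._implication()
        tok = self._peek()
        if tok is not None:
            raise ParseError(f"trailing input {tok[1]!r}", tok[2])
        return f

    def _implication(self) -> Formula:
        left = self._disjunction()
        tok = self._peek()
        if tok is not None and tok[1] == "->":
            self._next()
            right = self._implication()  # right associative
            return Formula.or_(Formula.not_(left), right)
        return left

    def _disjunction(self) -> Formula:
        f = self._conjunction()
        while (tok := self._peek()) is not None and tok[1] == "|":
            self._next()
            f = Formula.or_(f, self._conjunction())
        return f

    def _conjunction(self) -> Formula:
        f = self._until()
        while (tok := self._peek()) is not None and tok[1] == "&":
            self._next()
            f = Formula.and_(f, self._until())
        return f

    def _until(self) -> Formula:
        left = self._unary()
        tok = self._peek()
        if tok is not None and tok[0] == "ident" and tok[1] == "U":
            self._next()
            bound = self._bound()
            right = self._until()  # right associative
            return Formula.until(bound, left, right)
        return left

    def _bound(self) -> int:
        self._expect("[")
        tok = self._next()
        if tok[0] != "num" or not tok[1].isdigit():
            raise ParseError(f"temporal bound must be a nonnegative integer, found {tok[1]!r}", tok[2])
        self._expect("]")
        return int(tok[1])

    def _unary(self) -> Formula:
        tok = self._peek()
        if tok is None:
            raise ParseError("unexpected end of input", len(self.text))
        if tok[1] == "!":
            self._next()
            return Formula.not_(self._unary())
        if tok[0] == "ident" and tok[1] in ("F", "G"):
            nxt = self.tokens[self.i + 1] if self.i + 1 < len(self.tokens) else None
            if nxt is not None and nxt[1] == "[":
                self._next()
                bound = self._bound()
                child = self._unary()
                if tok[1] == "F":
                    return Formula.finally_(bound, child)
                return Formula.globally(bound, child)
        return self._primary()

    def _primary(self) -> Formula:
        tok = self._next()
        if tok[1] == "(":
            f = self._implication()
            self._expect(")")
            return f
        if tok[0] == "ident":
            nxt = self._peek()
            if nxt is not None and nxt[1] in _CMP_OPS:
                op = self._next()[1]
                num = self._next()
                if num[0] != "num":
                    raise ParseError(f"comparison needs a numeric constant, found {num[1]!r}", num[2])
                return Formula.cmp_(tok[1], op, float(num[1]))
            return Formula.atom_(tok[1])
        raise ParseError(f"unexpected token {tok[1]!r}", tok[2])


def parse_formula(text: str) -> Formula:
    """Parse BLTL concrete syntax into its unique AST under the declared
    precedence; ``unparse(parse_formula(x))`` re-parses to an identical AST."""
    if not text or not text.strip():
        raise ParseError("empty formula", 0)
    return _Parser(text).parse()


def unparse(formula: Formula) -> str:
    """Fully parenthesised concrete syntax; round-trips through the parser."""
    if formula.kind is Kind.ATOM:
        if formula.atom is not None:
            return formula.atom
        var, op, value = formula.comparison  # type: ignore[misc]
        return f"({var} {op} {value:g})"
    if formula.kind is Kind.NOT:
        return f"!({unparse(formula.children[0])})"
    if formula.kind is Kind.AND:
        return f"({unparse(formula.children[0])} & {unparse(formula.children[1])})"
    if formula.kind is Kind.OR:
        return f"({unparse(formula.children[0])} | {unparse(formula.children[1])})"
    if formula.kind is Kind.UNTIL:
        return f"(({unparse(formula.children[0])}) U[{formula.bound}] ({unparse(formula.children[1])}))"
    if formula.kind is Kind.FINALLY:
        return f"F[{formula.bound}]({unparse(formula.children[0])})"
    return f"G[{formula.bound}]({unparse(formula.children[0])})"


# ---------------------------------------------------------------------------
# Horizon and derived-operator rewriting
# ---------------------------------------------------------------------------

def required_horizon(formula: Formula) -> int:
    """Number of transitions h such that a trace with >= h+1 states starting
    at the evaluation position always decides the formula."""
    if formula.kind is Kind.ATOM:
        return 0
    child_h = max(required_horizon(c) for c in formula.children)
    if formula.kind in (Kind.UNTIL, Kind.FINALLY, Kind.GLOBALLY):
        return formula.bound + child_h  # type: ignore[operator]
    return child_h


def _first_atom(formula: Formula) -> Formula:
    for sub in formula.subformulas():
        if sub.kind is Kind.ATOM:
            return sub
    raise ValueError("formula contains no atom")


def _true_formula(anchor: Formula) -> Formula:
    # "true" encoded as (a | !a) over an atom already present in the formula,
    # so rewriting never introduces foreign propositions.
    a = _first_atom(anchor)
    return Formula.or_(a, Formula.not_(a))


def rewrite_derived(formula: Formula) -> Formula:
    """Eliminate F/G via ``F[d] p = true U[d] p`` and ``G[d] p = !F[d] !p``;
    semantics-preserving on every trace, horizon-preserving."""
    children = tuple(rewrite_derived(c) for c in formula.children)
    if formula.kind is Kind.FINALLY:
        return Formula.until(formula.bound, _true_formula(children[0]), children[0])  # type: ignore[arg-type]
    if formula.kind is Kind.GLOBALLY:
        inner = Formula.not_(children[0])
        return Formula.not_(Formula.until(formula.bound, _true_formula(inner), inner))  # type: ignore[arg-type]
    if children == formula.children:
        return formula
    return Formula(formula.kind, children, bound=formula.bound,
                   atom=formula.atom, comparison=formula.comparison)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def _atom_holds(formula: Formula, state: State) -> bool:
    if formula.atom is not None:
        return formula.atom in state.labels
    var, op, value = formula.comparison  # type: ignore[misc]
    try:
        left = state.valuation[var]
    except KeyError:
        raise KeyError(f"variable {var!r} absent from state valuation") from None
    return _CMP_OPS[op](left, value)


def evaluate(trace: Trace, formula: Formula, position: int = 0) -> bool:
    """Decide ``trace, position |= formula``.

    Memoized bottom-up evaluation: one boolean table per distinct subformula
    over the positions where it is decidable, linear in |formula| * |trace|.
    Raises :class:`TraceTooShortError` when ``position + required_horizon``
    exceeds the last trace index.
    """
    k = len(trace) - 1
    if position < 0 or position > k:
        raise IndexError(f"position {position} outside trace of length {len(trace)}")
    if position + required_horizon(formula) > k:
        raise TraceTooShortError(
            f"trace has {len(trace)} states but deciding the formula at position "
            f"{position} needs {position + required_horizon(formula) + 1}"
        )

    # Deduplicate shared subtrees; Formula is hashable.
    order: list[Formula] = []
    seen: set[Formula] = set()
    for sub in formula.subformulas():
        if sub not in seen:
            seen.add(sub)
            order.append(sub)

    table: dict[Formula, list[Optional[bool]]] = {}
    horizon = {sub: required_horizon(sub) for sub in order}
    for sub in order:
        row: list[Optional[bool]] = [None] * (k + 1)
        last = k - horizon[sub]  # decidable positions are 0..last
        if sub.kind is Kind.ATOM:
            for i in range(last + 1):
                row[i] = _atom_holds(sub, trace[i])
        elif sub.kind is Kind.NOT:
            child = table[sub.children[0]]
            for i in range(last + 1):
                row[i] = not child[i]
        elif sub.kind is Kind.AND:
            a, b = (table[c] for c in sub.children)
            for i in range(last + 1):
                row[i] = a[i] and b[i]
        elif sub.kind is Kind.OR:
            a, b = (table[c] for c in sub.children)
            for i in range(last + 1):
                row[i] = a[i] or b[i]
        elif sub.kind is Kind.FINALLY:
            child = table[sub.children[0]]
            d = sub.bound or 0
            for i in range(last + 1):
                row[i] = any(child[i + l] for l in range(d + 1))
        elif sub.kind is Kind.GLOBALLY:
            child = table[sub.children[0]]
            d = sub.bound or 0
            for i in range(last + 1):
                row[i] = all(child[i + l] for l in range(d + 1))
        else:  # UNTIL
            a, b = (table[c] for c in sub.children)
            d = sub.bound or 0
            for i in range(last + 1):
                ok = False
                for l in range(d + 1):
                    if b[i + l]:
                        ok = True
                        break
                    if not a[i + l]:
                        break
                row[i] = ok
        table[sub] = row

    result = table[formula][position]
    assert result is not None
    return result


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_formula_file(path) -> list[Formula]:
    """One formula per line; blank lines and ``#`` comments ignored."""
    formulas = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            stripped = line.split("#", 1)[0].strip()
            if stripped:
                formulas.append(parse_formula(stripped))
    return formulas
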