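"""Tokenizer and recursive-descent parser for TQL programs.

A program is a sequence of ``var name = EXPRESSION`` definitions followed by
exactly one final query expression.  Variables are forward-only: a ``$ref``
must name a previously defined variable.  Command keywords are
case-insensitive; codes, quoted strings and variable names are
case-sensitive.  As printed in published queries, the ``var`` keyword may be
juxtaposed with the variable name (``varstroke=``); the lexer treats a
leading ``var`` prefix of an identifier at statement start as the keyword.

The grammar covers exactly the attested command set: the Boolean operators
AND, OR, NOT; the temporal operators UNION, INTERSECT, INVERT, SEQUENCE
(with ``+``/``-`` presence/absence windows), COUNT, FIRST MENTION,
NO HISTORY OF, NEVER HAD, DIFF; the ORIGINAL expansion bypass; EXPORT; and
the feature selectors ICD9/ICD10/CPT/RX/ATC/GENDER/RACE, AGE, LABS, TEXT and
YEAR.  Anything else is rejected with an "unknown command" error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, NamedTuple, Optional, Tuple, Union

from .algebra import ABSENCE, PRESENCE, STAR_FIRST, STAR_SECOND, WindowModifier, duration_days
from .errors import TQLSyntaxError

# ---------------------------------------------------------------------------
# AST
# ---------------------------------------------------------------------------

NARY_OPS = ("AND", "OR", "NOT", "UNION", "INTERSECT", "DIFF")
UNARY_OPS = ("INVERT", "FIRST_MENTION", "NO_HISTORY_OF", "NEVER_HAD", "ORIGINAL")
SELECTOR_NAMESPACES = ("ICD9", "ICD10", "CPT", "RX", "ATC", "GENDER", "RACE")
TEXT_FLAGS = ("NEGATED", "FAMILY_HISTORY")


@dataclass(frozen=True)
class Feature:
    """``NS="code"`` selector (diagnosis/procedure/drug codes, demographics)."""
    namespace: str
    code: str


@dataclass(frozen=True)
class VarRef:
    name: str


@dataclass(frozen=True)
class Nary:
    op: str
    operands: Tuple["Expression", ...]


@dataclass(frozen=True)
class Unary:
    op: str
    operand: "Expression"


@dataclass(frozen=True)
class Count:
    operand: "Expression"
    min_n: int
    max_n: Optional[int]  # None = MAX


@dataclass(frozen=True)
class SequenceOp:
    first: "Expression"
    second: "Expression"
    star: int  # STAR_FIRST / STAR_SECOND
    window: Optional[WindowModifier] = None


@dataclass(frozen=True)
class Age:
    """``AGE(lo, hi)`` — days since birth; ``hi=None`` is MAX."""
    lo: int
    hi: Optional[int]


@dataclass(frozen=True)
class Labs:
    """``LABS("code", lo, hi)`` — measurement events with value in range."""
    code: str
    lo: Optional[float]
    hi: Optional[float]


@dataclass(frozen=True)
class Text:
    phrase: str
    flags: frozenset


@dataclass(frozen=True)
class Year:
    lo: int
    hi: Optional[int]


@dataclass(frozen=True)
class Export:
    cohort: "Expression"
    time_expr: "Expression"
    columns: Tuple[Tuple[str, "Expression"], ...]


Expression = Union[Feature, VarRef, Nary, Unary, Count, SequenceOp, Age, Labs, Text, Year, Export]

SELECTOR_TYPES = (Feature, Labs, Text)


@dataclass
class QueryProgram:
    """Parsed variable definitions (in order) plus the final query."""
    var_defs: Dict[str, Expression]
    final_expr: Expression


# ---------------------------------------------------------------------------
# Tokenizer
# ---------------------------------------------------------------------------

class Token(NamedTuple):
    kind: str  # IDENT, STRING, NUMBER, REF, SYM, EOF
    value: str
    line: int
    col: int


_TRANSLATE = str.maketrans({
    "“": '"', "”": '"',   # curly double quotes
    "‘": "'", "’": "'",   # curly single quotes
    "−": "-",                    # minus sign
    " ": " ",
})

_SYMBOLS = set("()=,*+-")


def tokenize(text: str) -> List[Token]:
    """Lex TQL source into tokens.  ``#`` starts a comment to end of line."""
    text = text.translate(_TRANSLATE)
    tokens: List[Token] = []
    i, line, col = 0, 1, 1
    n = len(text)
    while i < n:
        ch = text[i]
        if ch == "\n":
            i += 1
            line += 1
            col = 1
            continue
        if ch in " \t\r":
            i += 1
            col += 1
            continue
        if ch == "#":
            while i < n and text[i] != "\n":
                i += 1
            continue
        if ch == '"':
            j = i + 1
            while j < n and text[j] not in '"\n':
                j += 1
            if j >= n or text[j] != '"':
                raise TQLSyntaxError("unterminated string literal", line, col)
            tokens.append(Token("STRING", text[i + 1:j], line, col))
            col += j + 1 - i
            i = j + 1
            continue
        if ch == "$":
            j = i + 1
            while j < n and (text[j].isalnum() or text[j] == "_"):
                j += 1
            if j == i + 1:
                raise TQLSyntaxError("expected variable name after '$'", line, col)
            tokens.append(Token("REF", text[i + 1:j], line, col))
            col += j - i
            i = j
            continue
        if ch.isdigit():
            j = i
            while j < n and (text[j].isdigit() or text[j] == "."):
                j += 1
            tokens.append(Token("NUMBER", text[i:j], line, col))
            col += j - i
            i = j
            continue
        if ch.isalpha() or ch == "_":
            j = i
            while j < n and (text[j].isalnum() or text[j] == "_"):
                j += 1
            tokens.append(Token("IDENT", text[i:j], line, col))
            col += j - i
            i = j
            continue
        if ch in _SYMBOLS:
            tokens.append(Token("SYM", ch, line, col))
            i += 1
            col += 1
            continue
        raise TQLSyntaxError(f"illegal character {ch!r}", line, col)
    tokens.append(Token("EOF", "", line, col))
    return tokens


# ---------------------------------------------------------------------------
# Parser
# ---------------------------------------------------------------------------

_MULTIWORD = {
    "FIRST": (("MENTION",), "FIRST_MENTION"),
    "NO": (("HISTORY", "OF"), "NO_HISTORY_OF"),
    "NEVER": (("HAD",), "NEVER_HAD"),
}


class _Parser:
    def __init__(self, tokens: List[Token]):
        self.tokens = tokens
        self.pos = 0
        self.defined: Dict[str, Expression] = {}

    # -- token helpers ------------------------------------------------------
    def peek(self, offset: int = 0) -> Token:
        return self.tokens[min(self.pos + offset, len(self.tokens) - 1)]

    def next(self) -> Token:
        tok = self.tokens[self.pos]
        if tok.kind != "EOF":
            self.pos += 1
        return tok

    def expect_sym(self, sym: str) -> Token:
        tok = self.next()
        if tok.kind != "SYM" or tok.value != sym:
            raise TQLSyntaxError(f"expected {sym!r}, found {tok.value!r}", tok.line, tok.col)
        return tok

    def eat_sym(self, sym: str) -> bool:
        tok = self.peek()
        if tok.kind == "SYM" and tok.value == sym:
            self.pos += 1
            return True
        return False

    # -- program ------------------------------------------------------------
    def parse_program(self) -> QueryProgram:
        final: Optional[Expression] = None
        while self.peek().kind != "EOF":
            tok = self.peek()
            name = self._var_def_name()
            if name is not None:
                self.expect_sym("=")
                if name in self.defined:
                    raise TQLSyntaxError(f"duplicate variable name {name!r}", tok.line, tok.col)
                if not name:
                    raise TQLSyntaxError("empty variable name", tok.line, tok.col)
                self.defined[name] = self.parse_expr()
            else:
                if final is not None:
                    raise TQLSyntaxError("multiple final query expressions", tok.line, tok.col)
                final = self.parse_expr()
        if final is None:
            tok = self.peek()
            raise TQLSyntaxError("program has no final query expression", tok.line, tok.col)
        return QueryProgram(var_defs=self.defined, final_expr=final)

    def _var_def_name(self) -> Optional[str]:
        """Recognise ``var name =`` or the juxtaposed ``varname=`` form."""
        tok = self.peek()
        if tok.kind != "IDENT":
            return None
        low = tok.value.lower()
        if low == "var":
            self.next()
            name_tok = self.next()
            if name_tok.kind != "IDENT":
                raise TQLSyntaxError("expected variable name after 'var'",
                                     name_tok.line, name_tok.col)
            return name_tok.value
        nxt = self.peek(1)
        if (low.startswith("var") and len(tok.value) > 3
                and nxt.kind == "SYM" and nxt.value == "="):
            self.next()
            return tok.value[3:]
        return None

    # -- expressions --------------------------------------------------------
    def parse_expr(self) -> Expression:
        tok = self.next()
        if tok.kind == "REF":
            if tok.value not in self.defined:
                raise TQLSyntaxError(f"undefined variable ${tok.value}", tok.line, tok.col)
            return VarRef(tok.value)
        if tok.kind != "IDENT":
            raise TQLSyntaxError(f"unexpected token {tok.value!r}", tok.line, tok.col)

        word = tok.value.upper()
        if word in _MULTIWORD:
            rest, combined = _MULTIWORD[word]
            if all(self.peek(k).kind == "IDENT" and self.peek(k).value.upper() == w
                   for k, w in enumerate(rest)):
                for _ in rest:
                    self.next()
                word = combined

        if word in ("AND", "OR", "NOT", "UNION", "INTERSECT", "DIFF"):
            return self._parse_nary(word, tok)
        if word in ("INVERT", "ORIGINAL", "FIRST_MENTION", "NO_HISTORY_OF", "NEVER_HAD"):
            self.expect_sym("(")
            operand = self.parse_expr()
            self.expect_sym(")")
            return Unary(word, operand)
        if word == "COUNT":
            return self._parse_count(tok)
        if word == "SEQUENCE":
            return self._parse_sequence(tok)
        if word == "AGE":
            return self._parse_age(tok)
        if word == "LABS":
            return self._parse_labs(tok)
        if word == "TEXT":
            return self._parse_text(tok)
        if word == "YEAR":
            return self._parse_year(tok)
        if word == "EXPORT":
            return self._parse_export(tok)
        if word in SELECTOR_NAMESPACES:
            self.expect_sym("=")
            return Feature(word, self._code_value())
        nxt = self.peek()
        if nxt.kind == "SYM" and nxt.value in "(=":
            raise TQLSyntaxError(f"unknown command {tok.value!r}", tok.line, tok.col)
        raise TQLSyntaxError(f"unexpected identifier {tok.value!r}", tok.line, tok.col)

    def _code_value(self) -> str:
        tok = self.next()
        if tok.kind not in ("STRING", "NUMBER"):
            raise TQLSyntaxError(f"expected code value, found {tok.value!r}", tok.line, tok.col)
        if tok.kind == "STRING" and not tok.value:
            raise TQLSyntaxError("empty code", tok.line, tok.col)
        return tok.value

    def _parse_nary(self, op: str, tok: Token) -> Nary:
        self.expect_sym("(")
        operands = [self.parse_expr()]
        while self.eat_sym(","):
            operands.append(self.parse_expr())
        self.expect_sym(")")
        if op == "DIFF" and len(operands) != 2:
            raise TQLSyntaxError("DIFF takes exactly 2 operands", tok.line, tok.col)
        return Nary(op, tuple(operands))

    def _parse_count(self, tok: Token) -> Count:
        self.expect_sym("(")
        operand = self.parse_expr()
        self.expect_sym(",")
        lo = self._int_or_max()
        self.expect_sym(",")
        hi = self._int_or_max()
        self.expect_sym(")")
        if lo is None:
            raise TQLSyntaxError("COUNT minimum may not be MAX", tok.line, tok.col)
        return Count(operand, lo, hi)

    def _parse_sequence(self, tok: Token) -> SequenceOp:
        self.expect_sym("(")
        first = self.parse_expr()
        star1 = self.eat_sym("*")
        self.expect_sym(",")
        second = self.parse_expr()
        star2 = self.eat_sym("*")
        self.expect_sym(")")
        if star1 == star2:
            raise TQLSyntaxError("SEQUENCE requires exactly one '*'-starred operand",
                                 tok.line, tok.col)
        window = self._maybe_window()
        return SequenceOp(first, second, STAR_FIRST if star1 else STAR_SECOND, window)

    def _maybe_window(self) -> Optional[WindowModifier]:
        tok = self.peek()
        nxt = self.peek(1)
        if (tok.kind == "SYM" and tok.value in "+-"
                and nxt.kind == "SYM" and nxt.value == "("):
            self.next()
            mode = PRESENCE if tok.value == "+" else ABSENCE
            self.expect_sym("(")
            lo = self._signed_duration()
            self.expect_sym(",")
            hi = self._signed_duration()
            self.expect_sym(")")
            if lo is not None and hi is not None and lo > hi:
                raise TQLSyntaxError(f"window bounds inverted ({lo}, {hi})", tok.line, tok.col)
            return WindowModifier(mode, lo, hi)
        return None

    def _signed_duration(self) -> Optional[int]:
        """``[+|-] NUMBER [unit]`` in days, or the MAX sentinel (None)."""
        sign = 1
        tok = self.peek()
        if tok.kind == "SYM" and tok.value in "+-":
            self.next()
            sign = -1 if tok.value == "-" else 1
            tok = self.peek()
        if tok.kind == "IDENT" and tok.value.upper() == "MAX":
            self.next()
            return None
        if tok.kind != "NUMBER":
            raise TQLSyntaxError(f"expected duration, found {tok.value!r}", tok.line, tok.col)
        self.next()
        try:
            amount = int(tok.value)
        except ValueError:
            raise TQLSyntaxError(f"durations must be whole numbers: {tok.value!r}",
                                 tok.line, tok.col) from None
        unit = None
        nxt = self.peek()
        if nxt.kind == "IDENT" and nxt.value.upper() in ("DAY", "DAYS", "MONTH", "MONTHS",
                                                         "YEAR", "YEARS"):
            self.next()
            unit = nxt.value
        return sign * duration_days(amount, unit)

    def _int_or_max(self) -> Optional[int]:
        tok = self.next()
        if tok.kind == "IDENT" and tok.value.upper() == "MAX":
            return None
        if tok.kind == "NUMBER":
            try:
                return int(tok.value)
            except ValueError:
                raise TQLSyntaxError(f"expected integer, found {tok.value!r}",
                                     tok.line, tok.col) from None
        raise TQLSyntaxError(f"expected number or MAX, found {tok.value!r}", tok.line, tok.col)

    def _float_or_max(self) -> Optional[float]:
        sign = 1.0
        tok = self.peek()
        if tok.kind == "SYM" and tok.value in "+-":
            self.next()
            sign = -1.0 if tok.value == "-" else 1.0
        tok = self.next()
        if tok.kind == "IDENT" and tok.value.upper() == "MAX":
            return None
        if tok.kind == "NUMBER":
            return sign * float(tok.value)
        raise TQLSyntaxError(f"expected number or MAX, found {tok.value!r}", tok.line, tok.col)

    def _parse_age(self, tok: Token) -> Age:
        self.expect_sym("(")
        lo = self._signed_duration()
        self.expect_sym(",")
        hi = self._signed_duration()
        self.expect_sym(")")
        if lo is None:
            raise TQLSyntaxError("AGE lower bound may not be MAX", tok.line, tok.col)
        return Age(lo, hi)

    def _parse_labs(self, tok: Token) -> Labs:
        self.expect_sym("(")
        code_tok = self.next()
        if code_tok.kind != "STRING":
            raise TQLSyntaxError("LABS code must be a quoted string",
                                 code_tok.line, code_tok.col)
        self.expect_sym(",")
        lo = self._float_or_max()
        self.expect_sym(",")
        hi = self._float_or_max()
        self.expect_sym(")")
        return Labs(code_tok.value, lo, hi)

    def _parse_text(self, tok: Token) -> Text:
        self.expect_sym("(")
        phrase_tok = self.next()
        if phrase_tok.kind != "STRING":
            raise TQLSyntaxError("TEXT phrase must be a quoted string",
                                 phrase_tok.line, phrase_tok.col)
        flags = set()
        while self.eat_sym(","):
            flag_tok = self.next()
            flag = flag_tok.value.upper() if flag_tok.kind == "IDENT" else ""
            if flag not in TEXT_FLAGS:
                raise TQLSyntaxError(f"unknown TEXT flag {flag_tok.value!r}",
                                     flag_tok.line, flag_tok.col)
            flags.add(flag)
        self.expect_sym(")")
        return Text(phrase_tok.value, frozenset(flags))

    def _parse_year(self, tok: Token) -> Year:
        self.expect_sym("(")
        lo = self._int_or_max()
        self.expect_sym(",")
        hi = self._int_or_max()
        self.expect_sym(")")
        if lo is None:
            raise TQLSyntaxError("YEAR lower bound may not be MAX", tok.line, tok.col)
        return Year(lo, hi)

    def _parse_export(self, tok: Token) -> Export:
        self.expect_sym("(")
        cohort = self.parse_expr()
        self.expect_sym(",")
        time_tok = self.next()
        if not (time_tok.kind == "IDENT" and time_tok.value.upper() == "TIME"):
            raise TQLSyntaxError("EXPORT requires TIME=<expr> as its second argument",
                                 time_tok.line, time_tok.col)
        self.expect_sym("=")
        time_expr = self.parse_expr()
        columns: List[Tuple[str, Expression]] = []
        while self.eat_sym(","):
            label_tok = self.next()
            if label_tok.kind != "STRING":
                raise TQLSyntaxError("EXPORT column labels must be quoted strings",
                                     label_tok.line, label_tok.col)
            self.expect_sym("=")
            columns.append((label_tok.value, self.parse_expr()))
        self.expect_sym(")")
        return Export(cohort, time_expr, tuple(columns))


def parse_program(text: str) -> QueryProgram:
    """Parse TQL source into a :class:`QueryProgram` with all refs resolved."""
    return _Parser(tokenize(text)).parse_program()


def parse_expression(text: str) -> Expression:
    """Parse a single TQL expression (no variable definitions)."""
    program = parse_program(text)
    if program.var_defs:
        raise TQLSyntaxError("expected a bare expression, found variable definitions")
    return program.final_expr


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def _walk(expr: Expression):
    yield expr
    if isinstance(expr, Nary):
        for op in expr.operands:
            yield from _walk(op)
    elif isinstance(expr, Unary):
        yield from _walk(expr.operand)
    elif isinstance(expr, Count):
        yield from _walk(expr.operand)
    elif isinstance(expr, SequenceOp):
        yield from _walk(expr.first)
        yield from _walk(expr.second)
    elif isinstance(expr, Export):
        yield from _walk(expr.cohort)
        yield from _walk(expr.time_expr)
        for _, col in expr.columns:
            yield from _walk(col)


def validate(program: QueryProgram) -> List[str]:
    """Semantic checks beyond the grammar; returns diagnostics (empty = clean)."""
    diags: List[str] = []

    def check(expr: Expression, context: str, top_level: bool) -> None:
        for node in _walk(expr):
            if isinstance(node, Export) and not (top_level and node is expr):
                diags.append(f"{context}: EXPORT must be the top-level final query")
            elif isinstance(node, Count):
                if node.max_n is not None and node.min_n > node.max_n:
                    diags.append(f"{context}: COUNT bounds inverted "
                                 f"({node.min_n}, {node.max_n})")
            elif isinstance(node, Age):
                if node.hi is not None and node.lo > node.hi:
                    diags.append(f"{context}: AGE bounds inverted ({node.lo}, {node.hi})")
            elif isinstance(node, Labs):
                if node.lo is not None and node.hi is not None and node.lo > node.hi:
                    diags.append(f"{context}: LABS bounds inverted ({node.lo}, {node.hi})")
            elif isinstance(node, Year):
                if node.hi is not None and node.lo > node.hi:
                    diags.append(f"{context}: YEAR bounds inverted ({node.lo}, {node.hi})")
            elif isinstance(node, Unary) and node.op == "ORIGINAL":
                if not isinstance(node.operand, SELECTOR_TYPES):
                    diags.append(f"{context}: ORIGINAL applies only to feature selectors")

    for name, expr in program.var_defs.items():
        check(expr, f"var {name}", top_level=False)
    check(program.final_expr, "final query", top_level=True)
    return diags


# ---------------------------------------------------------------------------
# Pretty-printer (round-trips through the parser)
# ---------------------------------------------------------------------------

_UNARY_PRINT = {
    "INVERT": "INVERT", "ORIGINAL": "ORIGINAL", "FIRST_MENTION": "FIRST MENTION",
    "NO_HISTORY_OF": "NO HISTORY OF", "NEVER_HAD": "NEVER HAD",
}


def _fmt_num(x: float) -> str:
    return f"{x:g}"


def _fmt_bound(x: Optional[float]) -> str:
    return "MAX" if x is None else _fmt_num(x)


def _fmt_days(d: Optional[int]) -> str:
    return "MAX" if d is None else f"{d} DAYS"


def format_expression(expr: Expression) -> str:
    """Canonical TQL text for an expression (durations printed in days)."""
    if isinstance(expr, Feature):
        return f'{expr.namespace}="{expr.code}"'
    if isinstance(expr, VarRef):
        return f"${expr.name}"
    if isinstance(expr, Nary):
        return f"{expr.op}({', '.join(format_expression(o) for o in expr.operands)})"
    if isinstance(expr, Unary):
        return f"{_UNARY_PRINT[expr.op]}({format_expression(expr.operand)})"
    if isinstance(expr, Count):
        return (f"COUNT({format_expression(expr.operand)}, {expr.min_n}, "
                f"{'MAX' if expr.max_n is None else expr.max_n})")
    if isinstance(expr, SequenceOp):
        a = format_expression(expr.first) + ("*" if expr.star == STAR_FIRST else "")
        b = format_expression(expr.second) + ("*" if expr.star == STAR_SECOND else "")
        out = f"SEQUENCE({a}, {b})"
        if expr.window is not None:
            sign = "+" if expr.window.mode == PRESENCE else "-"
            out += f"{sign}({_fmt_days(expr.window.lo)}, {_fmt_days(expr.window.hi)})"
        return out
    if isinstance(expr, Age):
        return f"AGE({_fmt_days(expr.lo)}, {_fmt_days(expr.hi)})"
    if isinstance(expr, Labs):
        return f'LABS("{expr.code}", {_fmt_bound(expr.lo)}, {_fmt_bound(expr.hi)})'
    if isinstance(expr, Text):
        flags = "".join(f", {f}" for f in sorted(expr.flags))
        return f'TEXT("{expr.phrase}"{flags})'
    if isinstance(expr, Year):
        return f"YEAR({expr.lo}, {'MAX' if expr.hi is None else expr.hi})"
    if isinstance(expr, Export):
        parts = [format_expression(expr.cohort), f"TIME={format_expression(expr.time_expr)}"]
        parts += [f'"{label}"={format_expression(col)}' for label, col in expr.columns]
        return f"EXPORT({', '.join(parts)})"
    raise TypeError(f"not an expression: {expr!r}")


def format_program(program: QueryProgram) -> str:
    lines = [f"var {name} = {format_expression(expr)}"
             for name, expr in program.var_defs.items()]
    lines.append(format_expression(program.final_expr))
    return "\n".join(lines) + "\n"
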