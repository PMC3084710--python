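"""Recursive-descent parser for Eugene source text.

One statement per ``;``-terminated clause; rule bodies become
:mod:`eugene.rules` expression trees with AND binding tighter than OR,
both left-associative, and parentheses honored.
"""

from __future__ import annotations

from .errors import EugeneSyntaxError, SourceLocation
from .lexer import Token, tokenize
from . import rules as R
from . import syntax as S


class _Parser:
    def __init__(self, tokens: list[Token], filename: str):
        self.tokens = tokens
        self.pos = 0
        self.filename = filename

    # -- cursor helpers -------------------------------------------------
    def peek(self, offset: int = 0) -> Token | None:
        i = self.pos + offset
        return self.tokens[i] if i < len(self.tokens) else None

    def loc(self) -> SourceLocation:
        tok = self.peek()
        if tok is not None:
            return tok.location
        if self.tokens:
            return self.tokens[-1].location
        return SourceLocation(self.filename, 1, 1)

    def advance(self) -> Token:
        tok = self.peek()
        if tok is None:
            raise EugeneSyntaxError("unexpected end of input", self.loc())
        self.pos += 1
        return tok

    def expect(self, category: str, lexeme: str | None = None) -> Token:
        tok = self.peek()
        want = lexeme if lexeme is not None else f"<{category}>"
        if tok is None:
            raise EugeneSyntaxError(f"unexpected end of input, expected {want!r}", self.loc())
        if tok.category != category or (lexeme is not None and tok.lexeme != lexeme):
            raise EugeneSyntaxError(
                f"unexpected {tok.lexeme!r}, expected {want!r}", tok.location
            )
        return self.advance()

    def expect_name(self) -> str:
        return self.expect("identifier").lexeme

    def at_punct(self, ch: str) -> bool:
        tok = self.peek()
        return tok is not None and tok.is_punct(ch)

    def eat_punct(self, ch: str) -> None:
        self.expect("punctuation", ch)

    # -- statements -----------------------------------------------------
    def parse_program(self) -> S.SyntaxTree:
        statements = []
        while self.peek() is not None:
            statements.append(self.parse_statement())
        return S.SyntaxTree(tuple(statements))

    def parse_statement(self) -> S.Statement:
        tok = self.peek()
        loc = tok.location
        if tok.category == "keyword":
            kw = tok.lexeme
            if kw == "include":
                return self.parse_include()
            if kw == "Property":
                return self.parse_property_def()
            if kw == "Part":
                return self.parse_part_def()
            if kw == "Device":
                return self.parse_device_decl()
            if kw == "Rule":
                return self.parse_rule_decl()
            if kw in ("Assert", "Note"):
                return self.parse_assert_note()
            if kw == "permute":
                self.advance()
                self.eat_punct("(")
                name = self.expect_name()
                self.eat_punct(")")
                self.eat_punct(";")
                return S.PermuteCall(device_name=name, location=loc)
            if kw == "print":
                self.advance()
                self.eat_punct("(")
                arg = self.parse_expr()
                self.eat_punct(")")
                self.eat_punct(";")
                return S.PrintCall(arg=arg, location=loc)
            if kw in ("txt", "num", "boolean"):
                return self.parse_var_decl()
            raise EugeneSyntaxError(f"unexpected keyword {kw!r}", loc)
        if tok.category == "identifier":
            nxt = self.peek(1)
            if nxt is not None and nxt.category == "identifier":
                return self.parse_part_decl()
            if nxt is not None and nxt.category == "operator" and nxt.lexeme == "=":
                name = self.expect_name()
                self.advance()  # '='
                expr = self.parse_expr()
                self.eat_punct(";")
                return S.Assignment(target=name, expr=expr, location=loc)
            expr = self.parse_expr()
            self.eat_punct(";")
            return S.ExprStmt(expr=expr, location=loc)
        raise EugeneSyntaxError(f"unexpected {tok.lexeme!r} at start of statement", loc)

    def parse_include(self) -> S.Include:
        loc = self.loc()
        self.expect("keyword", "include")
        paths = [self.parse_include_path()]
        while self.at_punct(","):
            self.advance()
            paths.append(self.parse_include_path())
        self.eat_punct(";")
        return S.Include(paths=tuple(paths), location=loc)

    def parse_include_path(self) -> str:
        tok = self.peek()
        if tok is not None and tok.category == "string":
            return self.advance().lexeme
        pieces = [self.expect_name()]
        while self.at_punct("."):
            self.advance()
            pieces.append(self.expect_name())
        return ".".join(pieces)

    def parse_property_def(self) -> S.PropertyDef:
        loc = self.loc()
        self.expect("keyword", "Property")
        name = self.expect_name()
        self.eat_punct("(")
        kind = self.parse_kind()
        self.eat_punct(")")
        self.eat_punct(";")
        return S.PropertyDef(name=name, kind=kind, location=loc)

    def parse_kind(self) -> str:
        tok = self.advance()
        if not (tok.category == "keyword" and tok.lexeme in ("txt", "num", "boolean")):
            raise EugeneSyntaxError(
                f"unexpected {tok.lexeme!r}, expected a primitive kind (txt/num/boolean)",
                tok.location,
            )
        kind = tok.lexeme
        if self.at_punct("["):
            self.advance()
            self.eat_punct("]")
            if kind == "boolean":
                raise EugeneSyntaxError("boolean arrays are not supported", tok.location)
            kind += "[]"
        return kind

    def parse_part_def(self) -> S.PartDef:
        loc = self.loc()
        self.expect("keyword", "Part")
        name = self.expect_name()
        self.eat_punct("(")
        props = [self.expect_name()]
        while self.at_punct(","):
            self.advance()
            props.append(self.expect_name())
        self.eat_punct(")")
        self.eat_punct(";")
        return S.PartDef(name=name, property_names=tuple(props), location=loc)

    def parse_part_decl(self) -> S.PartDecl:
        loc = self.loc()
        part_type = self.expect_name()
        name = self.expect_name()
        self.eat_punct("(")
        positional = None
        named = None
        if self.at_punct(")"):
            pass  # fully unset instance
        elif self.at_punct("."):
            pairs = []
            while True:
                self.eat_punct(".")
                prop = self.expect_name()
                self.eat_punct("(")
                pairs.append((prop, self.parse_expr()))
                self.eat_punct(")")
                if not self.at_punct(","):
                    break
                self.advance()
            named = tuple(pairs)
        else:
            values = [self.parse_expr()]
            while self.at_punct(","):
                self.advance()
                values.append(self.parse_expr())
            positional = tuple(values)
        self.eat_punct(")")
        self.eat_punct(";")
        return S.PartDecl(
            part_type=part_type, name=name, positional=positional, named=named, location=loc
        )

    def parse_device_decl(self) -> S.DeviceDecl:
        loc = self.loc()
        self.expect("keyword", "Device")
        name = self.expect_name()
        self.eat_punct("(")
        components = []
        if not self.at_punct(")"):
            components.append(self.parse_component())
            while self.at_punct(","):
                self.advance()
                components.append(self.parse_component())
        self.eat_punct(")")
        self.eat_punct(";")
        return S.DeviceDecl(name=name, components=tuple(components), location=loc)

    def parse_component(self) -> tuple[str | None, str]:
        tok = self.peek()
        if tok is not None and tok.is_kw("Device"):  # sub-device annotation
            self.advance()
            return ("Device", self.expect_name())
        first = self.expect_name()
        tok = self.peek()
        if tok is not None and tok.category == "identifier":
            return (first, self.advance().lexeme)  # annotated: "Promoter BBa_I0500"
        return (None, first)

    def parse_rule_decl(self) -> S.RuleDecl:
        loc = self.loc()
        self.expect("keyword", "Rule")
        name = self.expect_name()
        self.eat_punct("(")
        expr = self.parse_rule_or()
        self.eat_punct(")")
        self.eat_punct(";")
        return S.RuleDecl(name=name, expr=expr, location=loc)

    # AND binds tighter than OR; both left-associative.
    def parse_rule_or(self) -> R.RuleExpr:
        expr = self.parse_rule_and()
        while self.peek() is not None and self.peek().is_kw("OR"):
            self.advance()
            expr = R.Or(expr, self.parse_rule_and())
        return expr

    def parse_rule_and(self) -> R.RuleExpr:
        expr = self.parse_rule_primary()
        while self.peek() is not None and self.peek().is_kw("AND"):
            self.advance()
            expr = R.And(expr, self.parse_rule_primary())
        return expr

    def parse_rule_primary(self) -> R.RuleExpr:
        tok = self.peek()
        if tok is None:
            raise EugeneSyntaxError("unexpected end of input in rule expression", self.loc())
        if tok.is_punct("("):
            self.advance()
            expr = self.parse_rule_or()
            self.eat_punct(")")
            return expr
        if tok.is_kw("CONTAINS"):
            self.advance()
            return R.Contains(self.expect_name())
        if tok.is_kw("NOTCONTAINS"):
            self.advance()
            return R.NotContains(self.expect_name())
        first = self.expect_name()
        op = self.advance()
        if op.is_kw("CONTAINS"):
            return R.Contains(self.expect_name(), scope=first)
        if op.is_kw("NOTCONTAINS"):
            return R.NotContains(self.expect_name(), scope=first)
        if op.is_kw("BEFORE"):
            return R.Before(first, self.expect_name())
        if op.is_kw("WITH"):
            return R.With(first, self.expect_name())
        if op.is_kw("NOTWITH"):
            return R.NotWith(first, self.expect_name())
        if op.is_kw("NOTMORETHAN"):
            count_tok = self.advance()
            if count_tok.is_kw("once"):
                n = 1
            elif count_tok.category == "number" and "." not in count_tok.lexeme:
                n = int(count_tok.lexeme)
                if n < 1:
                    raise EugeneSyntaxError("NOTMORETHAN count must be >= 1", count_tok.location)
            else:
                raise EugeneSyntaxError(
                    f"unexpected {count_tok.lexeme!r}, expected a count or 'once'",
                    count_tok.location,
                )
            return R.NotMoreThan(first, n)
        raise EugeneSyntaxError(
            f"unexpected {op.lexeme!r}, expected a rule operator "
            "(BEFORE/CONTAINS/NOTCONTAINS/WITH/NOTWITH/NOTMORETHAN)",
            op.location,
        )

    def parse_assert_note(self) -> S.Statement:
        tok = self.advance()
        loc = tok.location
        self.eat_punct("(")
        names = [self.expect_name()]
        while self.peek() is not None and self.peek().is_kw("AND"):
            self.advance()
            names.append(self.expect_name())
        self.eat_punct(")")
        self.eat_punct(";")
        cls = S.AssertStmt if tok.lexeme == "Assert" else S.NoteStmt
        return cls(rule_names=tuple(names), location=loc)

    def parse_var_decl(self) -> S.VarDecl:
        loc = self.loc()
        kind = self.parse_kind()
        decls = [self.parse_one_declaration()]
        while self.at_punct(","):
            self.advance()
            decls.append(self.parse_one_declaration())
        self.eat_punct(";")
        return S.VarDecl(kind=kind, declarations=tuple(decls), location=loc)

    def parse_one_declaration(self) -> tuple[str, S.Expr | None]:
        name = self.expect_name()
        tok = self.peek()
        if tok is not None and tok.category == "operator" and tok.lexeme == "=":
            self.advance()
            return (name, self.parse_expr())
        return (name, None)

    # -- expressions ----------------------------------------------------
    def parse_expr(self) -> S.Expr:
        tok = self.peek()
        if tok is None:
            raise EugeneSyntaxError("unexpected end of input in expression", self.loc())
        if tok.category == "string":
            self.advance()
            return S.Literal("txt", tok.lexeme)
        if tok.category == "number":
            self.advance()
            return S.Literal("num", self._num(tok.lexeme))
        if tok.is_kw("true", "false"):
            self.advance()
            return S.Literal("boolean", tok.lexeme == "true")
        if tok.is_punct("["):
            self.advance()
            items = []
            if not self.at_punct("]"):
                items.append(self.parse_scalar_literal())
                while self.at_punct(","):
                    self.advance()
                    items.append(self.parse_scalar_literal())
            self.eat_punct("]")
            return S.ListLiteral(tuple(items))
        if tok.category == "identifier":
            name = self.advance().lexeme
            if self.at_punct("["):
                self.advance()
                idx_tok = self.peek()
                if idx_tok is not None and idx_tok.category == "number":
                    self.advance()
                    index: S.Literal | S.NameRef = S.Literal("num", self._num(idx_tok.lexeme))
                else:
                    index = S.NameRef(self.expect_name())
                self.eat_punct("]")
                return S.IndexRef(name, index)
            return S.NameRef(name)
        raise EugeneSyntaxError(f"unexpected {tok.lexeme!r} in expression", tok.location)

    def parse_scalar_literal(self) -> S.Literal:
        expr = self.parse_expr()
        if not isinstance(expr, S.Literal):
            raise EugeneSyntaxError("list literals may contain only scalar literals", self.loc())
        return expr

    @staticmethod
    def _num(lexeme: str) -> int | float:
        return float(lexeme) if "." in lexeme else int(lexeme)


def parse(source_or_tokens, filename: str = "<string>") -> S.SyntaxTree:
    """Parse source text (or a pre-lexed token list) into a syntax tree."""
    if isinstance(source_or_tokens, str):
        tokens = tokenize(source_or_tokens, filename)
    else:
        tokens = list(source_or_tokens)
    return _Parser(tokens, filename).parse_program()
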