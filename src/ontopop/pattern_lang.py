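"""Parser and expander for the OPPL-2 subset used in template patterns.

The supported scripts declare ``?var:CLASS`` input variables, optionally
define further variables as class-expression templates or as the
``createIntersection(?var.VALUES)`` macro, and carry one or more ``ADD``
actions between ``BEGIN`` and ``END``:

    ?cell:CLASS,
    ?anatomyPart:CLASS,
    ?partOfRestriction:CLASS = cell and ro:part_of some ?anatomyPart,
    ?anatomyIntersection:CLASS = createIntersection(?partOfRestriction.VALUES)
    BEGIN
    ADD ?cell equivalentTo ?anatomyIntersection
    END;

Expansion substitutes the term lists bound to the input variables.  A
defined variable whose body references a variable bound to k values is
instantiated k times (the ``.VALUES`` sequence); ``createIntersection``
conjoins those instances with flattening and syntactic de-duplication.
Only existential (``some``) restrictions are supported.  OPPL 2 constructs
outside this subset (REMOVE, SELECT, variable constraints, non-CLASS
variables) are rejected with an explicit unsupported-construct error.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence, Union

from .axioms import (
    GroundAxiom,
    GroundClass,
    GroundExpr,
    GroundIntersection,
    GroundSome,
    intersection_of,
)
from .errors import BindingError, PatternSyntaxError, UnsupportedConstructError
from .ontology_store import TermRef

__all__ = [
    "NamedClass",
    "VariableRef",
    "SomeRestriction",
    "Intersection",
    "VariableDecl",
    "DefinedVariable",
    "MacroCall",
    "Action",
    "PatternScript",
    "parse_pattern",
    "input_variables",
    "render_pattern",
    "expand",
]


# ---------------------------------------------------------------------------
# AST


@dataclass(frozen=True)
class NamedClass:
    """A class named in the script, as a CURIE or a bare label."""

    name: str


@dataclass(frozen=True)
class VariableRef:
    name: str


@dataclass(frozen=True)
class SomeRestriction:
    prop: str  # property CURIE or bare name
    filler: "ExprNode"


@dataclass(frozen=True)
class Intersection:
    children: tuple["ExprNode", ...]

    def __post_init__(self) -> None:
        if len(self.children) < 2:
            raise ValueError("intersection template needs >= 2 children")


ExprNode = Union[NamedClass, VariableRef, SomeRestriction, Intersection]


@dataclass(frozen=True)
class VariableDecl:
    name: str  # includes the leading '?'
    vartype: str = "CLASS"


@dataclass(frozen=True)
class MacroCall:
    macro: str  # createIntersection
    argument: str  # variable name whose .VALUES sequence is conjoined


@dataclass(frozen=True)
class DefinedVariable:
    name: str
    body: Union[ExprNode, MacroCall]


@dataclass(frozen=True)
class Action:
    verb: str  # ADD
    axiom_kind: str  # SubClassOf | EquivalentTo
    subject: str  # variable name
    object: ExprNode


@dataclass(frozen=True)
class PatternScript:
    declarations: tuple[VariableDecl, ...]
    definitions: tuple[DefinedVariable, ...]
    actions: tuple[Action, ...]
    identifier: str = "pattern"


def input_variables(script: PatternScript) -> list[str]:
    """Variables needing a column binding: declared but not defined."""
    defined = {d.name for d in script.definitions}
    return [d.name for d in script.declarations if d.name not in defined]


# ---------------------------------------------------------------------------
# Tokenizer

_TOKEN_RE = re.compile(
    r"""
    (?P<ws>\s+)
  | (?P<var>\?[A-Za-z_][A-Za-z0-9_]*)
  | (?P<ident>[A-Za-z_][A-Za-z0-9_]*(?::[A-Za-z0-9_.-]+)?)
  | (?P<punct>[,()=;.:])
    """,
    re.VERBOSE,
)

_UNSUPPORTED = {
    "remove", "select", "where", "match", "fail", "create", "createunion",
}

_KEYWORDS = {
    "begin", "end", "add", "class", "and", "some", "subclassof",
    "equivalentto", "createintersection", "values",
}


@dataclass(frozen=True)
class _Token:
    kind: str  # var | ident | punct | eof
    text: str
    line: int
    column: int

    @property
    def lowered(self) -> str:
        return self.text.lower()


def _tokenize(text: str) -> list[_Token]:
    tokens: list[_Token] = []
    line, col = 1, 1
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise PatternSyntaxError(
                f"unexpected character {text[pos]!r}", line, col
            )
        kind = m.lastgroup
        value = m.group()
        if kind != "ws":
            tokens.append(_Token(kind=kind, text=value, line=line, column=col))
        newlines = value.count("\n")
        if newlines:
            line += newlines
            col = len(value) - value.rfind("\n")
        else:
            col += len(value)
        pos = m.end()
    tokens.append(_Token(kind="eof", text="<end of script>", line=line, column=col))
    return tokens


# ---------------------------------------------------------------------------
# Parser (recursive descent)


class _Parser:
    def __init__(self, tokens: Sequence[_Token]):
        self.tokens = tokens
        self.pos = 0

    @property
    def cur(self) -> _Token:
        return self.tokens[self.pos]

    def advance(self) -> _Token:
        tok = self.cur
        self.pos += 1
        return tok

    def error(self, message: str) -> PatternSyntaxError:
        return PatternSyntaxError(message, self.cur.line, self.cur.column)

    def check_supported(self, tok: _Token) -> None:
        if tok.kind == "ident" and tok.lowered in _UNSUPPORTED:
            raise UnsupportedConstructError(tok.text, tok.line, tok.column)

    def expect_keyword(self, word: str) -> _Token:
        tok = self.cur
        if tok.kind == "ident" and tok.lowered == word:
            return self.advance()
        self.check_supported(tok)
        raise self.error(f"expected {word!r}, found {tok.text!r}")

    def at_keyword(self, *words: str) -> bool:
        return self.cur.kind == "ident" and self.cur.lowered in words

    def expect_punct(self, ch: str) -> _Token:
        tok = self.cur
        if tok.kind == "punct" and tok.text == ch:
            return self.advance()
        raise self.error(f"expected {ch!r}, found {tok.text!r}")

    # grammar ---------------------------------------------------------------

    def script(self, identifier: str) -> PatternScript:
        declarations: list[VariableDecl] = []
        definitions: list[DefinedVariable] = []
        known: set[str] = set()
        while not self.at_keyword("begin"):
            self.check_supported(self.cur)
            if self.cur.kind != "var":
                raise self.error(
                    f"expected a variable declaration or BEGIN, found {self.cur.text!r}"
                )
            name = self.advance().text
            if name in known:
                raise self.error(f"duplicate variable {name}")
            self.expect_punct(":")
            type_tok = self.cur
            self.check_supported(type_tok)
            if type_tok.kind != "ident":
                raise self.error(f"expected a variable type, found {type_tok.text!r}")
            if type_tok.lowered != "class":
                raise UnsupportedConstructError(
                    f"variable type {type_tok.text}", type_tok.line, type_tok.column
                )
            self.advance()
            declarations.append(VariableDecl(name=name))
            known.add(name)
            if self.cur.kind == "punct" and self.cur.text == "=":
                self.advance()
                body = self.definition_body(known - {name})
                definitions.append(DefinedVariable(name=name, body=body))
            if self.cur.kind == "punct" and self.cur.text == ",":
                self.advance()
                continue
            break
        self.expect_keyword("begin")
        actions: list[Action] = []
        while not self.at_keyword("end"):
            self.check_supported(self.cur)
            if self.cur.kind == "eof":
                raise self.error("unterminated script: missing END")
            actions.append(self.action(known))
        self.expect_keyword("end")
        if self.cur.kind == "punct" and self.cur.text == ";":
            self.advance()
        if self.cur.kind != "eof":
            raise self.error(f"trailing content after END: {self.cur.text!r}")
        if not actions:
            raise PatternSyntaxError(
                "script has no actions between BEGIN and END", 1, 1
            )
        return PatternScript(
            declarations=tuple(declarations),
            definitions=tuple(definitions),
            actions=tuple(actions),
            identifier=identifier,
        )

    def definition_body(self, prior: set[str]) -> Union[ExprNode, MacroCall]:
        if self.at_keyword("createintersection"):
            tok = self.advance()
            self.expect_punct("(")
            arg = self.cur
            if arg.kind != "var":
                raise self.error(
                    f"createIntersection expects ?var.VALUES, found {arg.text!r}"
                )
            self.advance()
            if arg.text not in prior:
                raise PatternSyntaxError(
                    f"createIntersection references undeclared variable {arg.text}",
                    arg.line, arg.column,
                )
            self.expect_punct(".")
            self.expect_keyword("values")
            self.expect_punct(")")
            return MacroCall(macro="createIntersection", argument=arg.text)
        expr = self.expression(prior)
        return expr

    def action(self, known: set[str]) -> Action:
        tok = self.cur
        self.check_supported(tok)
        if not self.at_keyword("add"):
            raise self.error(f"expected ADD, found {tok.text!r}")
        self.advance()
        subj = self.cur
        if subj.kind != "var":
            raise self.error(f"ADD subject must be a variable, found {subj.text!r}")
        if subj.text not in known:
            raise PatternSyntaxError(
                f"undeclared variable {subj.text}", subj.line, subj.column
            )
        self.advance()
        kind_tok = self.cur
        if self.at_keyword("subclassof"):
            kind = "SubClassOf"
        elif self.at_keyword("equivalentto"):
            kind = "EquivalentTo"
        else:
            self.check_supported(kind_tok)
            raise self.error(
                f"expected SubClassOf or equivalentTo, found {kind_tok.text!r}"
            )
        self.advance()
        obj = self.expression(known)
        return Action(verb="ADD", axiom_kind=kind, subject=subj.text, object=obj)

    def expression(self, known: set[str]) -> ExprNode:
        terms = [self.conjunct(known)]
        while self.at_keyword("and"):
            self.advance()
            terms.append(self.conjunct(known))
        if len(terms) == 1:
            return terms[0]
        # flatten nested syntactic intersections
        flat: list[ExprNode] = []
        for t in terms:
            if isinstance(t, Intersection):
                flat.extend(t.children)
            else:
                flat.append(t)
        return Intersection(children=tuple(flat))

    def conjunct(self, known: set[str]) -> ExprNode:
        left_tok = self.cur
        left = self.factor(known)
        if self.at_keyword("some"):
            self.advance()
            if not isinstance(left, NamedClass):
                raise PatternSyntaxError(
                    "left of 'some' must be a property name",
                    left_tok.line, left_tok.column,
                )
            filler = self.factor(known)
            return SomeRestriction(prop=left.name, filler=filler)
        return left

    def factor(self, known: set[str]) -> ExprNode:
        tok = self.cur
        if tok.kind == "punct" and tok.text == "(":
            self.advance()
            inner = self.expression(known)
            self.expect_punct(")")
            return inner
        if tok.kind == "var":
            if tok.text not in known:
                raise PatternSyntaxError(
                    f"undeclared variable {tok.text}", tok.line, tok.column
                )
            self.advance()
            return VariableRef(name=tok.text)
        if tok.kind == "ident":
            self.check_supported(tok)
            if tok.lowered in _KEYWORDS:
                raise self.error(f"unexpected keyword {tok.text!r}")
            self.advance()
            return NamedClass(name=tok.text)
        raise self.error(f"expected a class expression, found {tok.text!r}")


def parse_pattern(text: str, identifier: str = "pattern") -> PatternScript:
    """Parse pattern text into a :class:`PatternScript` AST.

    Keywords are recognized case-insensitively (both ``equivalentTo`` and
    ``EquivalentTo`` are accepted).  Syntax errors carry line/column;
    recognized-but-unsupported OPPL constructs raise
    :class:`~ontopop.errors.UnsupportedConstructError` naming the construct.
    """
    return _Parser(_tokenize(text)).script(identifier)


# ---------------------------------------------------------------------------
# Pretty-printer


def _render_expr_node(node: ExprNode) -> str:
    if isinstance(node, NamedClass):
        return node.name
    if isinstance(node, VariableRef):
        return node.name
    if isinstance(node, SomeRestriction):
        filler = _render_expr_node(node.filler)
        if isinstance(node.filler, Intersection):
            filler = f"({filler})"
        return f"{node.prop} some {filler}"
    parts = []
    for child in node.children:
        text = _render_expr_node(child)
        if isinstance(child, (SomeRestriction, Intersection)):
            text = f"({text})"
        parts.append(text)
    return " and ".join(parts)


def render_pattern(script: PatternScript) -> str:
    """Canonical text for a script; ``parse_pattern`` round-trips it."""
    defined = {d.name: d for d in script.definitions}
    decls = []
    for decl in script.declarations:
        line = f"{decl.name}:CLASS"
        if decl.name in defined:
            body = defined[decl.name].body
            if isinstance(body, MacroCall):
                line += f" = {body.macro}({body.argument}.VALUES)"
            else:
                line += f" = {_render_expr_node(body)}"
        decls.append(line)
    lines = [",\n".join(decls), "BEGIN"]
    for action in script.actions:
        lines.append(
            f"ADD {action.subject} {action.axiom_kind} "
            f"{_render_expr_node(action.object)}"
        )
    lines.append("END;")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Expansion

Resolver = Callable[[str, str], TermRef]
# (name, role) -> TermRef; role is "class" or "property"


def _default_resolver(name: str, role: str) -> TermRef:
    return TermRef(iri=f"urn:unresolved:{role}:{name}", curie=name if ":" in name else None)


def _referenced_vars(node: ExprNode, order: list[str] | None = None) -> list[str]:
    if order is None:
        order = []
    if isinstance(node, VariableRef):
        if node.name not in order:
            order.append(node.name)
    elif isinstance(node, SomeRestriction):
        _referenced_vars(node.filler, order)
    elif isinstance(node, Intersection):
        for c in node.children:
            _referenced_vars(c, order)
    return order


def _instantiate(node: ExprNode, env: Mapping[str, GroundExpr], resolver: Resolver) -> GroundExpr:
    if isinstance(node, NamedClass):
        return GroundClass(resolver(node.name, "class"))
    if isinstance(node, VariableRef):
        return env[node.name]
    if isinstance(node, SomeRestriction):
        return GroundSome(
            prop=resolver(node.prop, "property"),
            filler=_instantiate(node.filler, env, resolver),
        )
    return intersection_of(_instantiate(c, env, resolver) for c in node.children)


def _instances(
    node: ExprNode,
    values: Mapping[str, list[GroundExpr]],
    resolver: Resolver,
) -> list[GroundExpr]:
    """All instantiations of a template over its variables' value lists.

    A single referenced variable bound to k values yields k instances (the
    ``.VALUES`` sequence); several multi-valued variables combine as a
    cartesian product in first-reference order.  Any empty value list
    yields zero instances.
    """
    refs = _referenced_vars(node)
    for r in refs:
        if r not in values:
            raise BindingError(r)
    pools = [values[r] for r in refs]
    if any(not pool for pool in pools):
        return []
    out: list[GroundExpr] = []
    for combo in itertools.product(*pools):
        env = dict(zip(refs, combo))
        out.append(_instantiate(node, env, resolver))
    return out


def expand(
    script: PatternScript,
    binding: Mapping[str, Sequence[TermRef]],
    resolver: Resolver = _default_resolver,
) -> list[GroundAxiom]:
    """Instantiate a pattern over one row's variable bindings.

    *binding* maps every input variable to an ordered list (possibly
    empty) of resolved terms.  Defined variables are evaluated in order;
    ``createIntersection`` conjoins the instance sequence of its argument
    with flattening and syntactic de-duplication (one value → that value,
    no wrapper).  Each action emits one axiom per subject value; when the
    object of a **SubClassOf** action is an intersection it is split into
    one axiom per distinct conjunct (EquivalentTo objects stay whole).
    Actions touching a variable with zero values emit nothing for this row.
    """
    values: dict[str, list[GroundExpr]] = {}
    inputs = input_variables(script)
    for name in inputs:
        if name not in binding:
            raise BindingError(name)
        values[name] = [GroundClass(t) for t in binding[name]]
    for defn in script.definitions:
        if isinstance(defn.body, MacroCall):
            arg_values = values.get(defn.body.argument)
            if arg_values is None:
                raise BindingError(defn.body.argument)
            values[defn.name] = (
                [intersection_of(arg_values)] if arg_values else []
            )
        else:
            values[defn.name] = _instances(defn.body, values, resolver)

    axioms: list[GroundAxiom] = []
    for action in script.actions:
        subjects = values.get(action.subject)
        if subjects is None:
            raise BindingError(action.subject)
        objects = _instances(action.object, values, resolver)
        for subj in subjects:
            if not isinstance(subj, GroundClass):
                raise BindingError(action.subject)
            for obj in objects:
                if action.axiom_kind == "SubClassOf" and isinstance(
                    obj, GroundIntersection
                ):
                    for conjunct in obj.conjuncts:
                        axioms.append(
                            GroundAxiom(
                                kind="SubClassOf",
                                subject=subj.term,
                                object=conjunct,
                            )
                        )
                else:
                    axioms.append(
                        GroundAxiom(
                            kind=action.axiom_kind, subject=subj.term, object=obj
                        )
                    )
    return axioms
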