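"""The brick label pattern language.

Template-glyph labels carry small textual constructs delimited by ``$``,
``[``/``]``, ``{``/``}`` and ``!``:

* ``ERK``            — a literal, matching exactly itself (case-sensitive);
* ``$NAME$``         — a variable, matching any non-empty string; every
  occurrence of the same variable name in a brick must bind the same string;
* ``[CONTENT]``      — an optional group, matching CONTENT or the empty string;
* ``cell—CELL``      — a disjunction between two literals (``|`` is accepted
  as an equivalent of the typographic em dash and is the canonical spelling
  on output);
* ``{...}`` / ``!...!`` — whole-glyph modifiers (repetition / absence). They
  must span the entire label; their meaning lives in the matcher, the parser
  only records them.

``match_label`` returns *every* consistent way of binding the variables, not
just a greedy one, so that global variable consistency across a whole brick
can be checked without losing solutions.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterator, Mapping, Sequence, Union

from .errors import MissingBindingError, PatternSyntaxError

Bindings = dict[str, str]

_EM_DASH = "—"
_DELIMITERS = set("$[]{}!")


@dataclass(frozen=True)
class Literal:
    text: str


@dataclass(frozen=True)
class Variable:
    name: str


@dataclass(frozen=True)
class OptionalGroup:
    body: tuple["PatternToken", ...]


@dataclass(frozen=True)
class Disjunction:
    left: str
    right: str


PatternToken = Union[Literal, Variable, OptionalGroup, Disjunction]


class Modifier(str, Enum):
    NONE = "none"
    REPETITION = "repetition"
    ABSENCE = "absence"


@dataclass(frozen=True)
class LabelPattern:
    tokens: tuple[PatternToken, ...]
    modifier: Modifier = Modifier.NONE

    def source(self) -> str:
        """Re-emit the canonical textual form of the pattern."""
        inner = "".join(_token_source(t) for t in self.tokens)
        if self.modifier is Modifier.REPETITION:
            return "{" + inner + "}"
        if self.modifier is Modifier.ABSENCE:
            return "!" + inner + "!"
        return inner

    def variables(self, include_optionals: bool = True) -> frozenset[str]:
        out: set[str] = set()

        def walk(tokens: Sequence[PatternToken]) -> None:
            for t in tokens:
                if isinstance(t, Variable):
                    out.add(t.name)
                elif isinstance(t, OptionalGroup) and include_optionals:
                    walk(t.body)

        walk(self.tokens)
        return frozenset(out)


def _token_source(token: PatternToken) -> str:
    if isinstance(token, Literal):
        return token.text
    if isinstance(token, Variable):
        return f"${token.name}$"
    if isinstance(token, OptionalGroup):
        return "[" + "".join(_token_source(t) for t in token.body) + "]"
    return f"{token.left}|{token.right}"


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------


def parse_pattern(text: str) -> LabelPattern:
    """Parse a label pattern; raise PatternSyntaxError with character offset."""
    modifier = Modifier.NONE
    offset = 0
    if text.startswith("{") or text.endswith("}"):
        if not (len(text) >= 2 and text.startswith("{") and text.endswith("}")):
            bad = 0 if text.startswith("{") else len(text) - 1
            raise PatternSyntaxError("unbalanced '{'/'}' delimiter", offset=bad)
        modifier = Modifier.REPETITION
        text, offset = text[1:-1], 1
    elif text.startswith("!") or text.endswith("!"):
        if not (len(text) >= 2 and text.startswith("!") and text.endswith("!")):
            bad = 0 if text.startswith("!") else len(text) - 1
            raise PatternSyntaxError("unbalanced '!' delimiter", offset=bad)
        modifier = Modifier.ABSENCE
        text, offset = text[1:-1], 1
    for ch in "{}!":
        pos = text.find(ch)
        if pos >= 0:
            raise PatternSyntaxError(
                "repetition/absence delimiters may only enclose the whole label "
                f"and may not nest ({ch!r})",
                offset=offset + pos,
            )
    tokens = _parse_sequence(text, offset)
    return LabelPattern(tokens=tokens, modifier=modifier)


def _parse_sequence(text: str, offset: int) -> tuple[PatternToken, ...]:
    # A top-level dash splits the label into a two-armed literal disjunction.
    dash_positions = [
        i
        for i, ch in enumerate(text)
        if ch in (_EM_DASH, "|") and _at_top_level(text, i, offset)
    ]
    if dash_positions:
        if len(dash_positions) > 1:
            raise PatternSyntaxError(
                "a disjunction has exactly two arms", offset=offset + dash_positions[1]
            )
        pos = dash_positions[0]
        left, right = text[:pos], text[pos + 1 :]
        for arm, arm_off in ((left, 0), (right, pos + 1)):
            bad = next((ch for ch in arm if ch in _DELIMITERS), None)
            if bad is not None:
                raise PatternSyntaxError(
                    "disjunction arms must be plain literals",
                    offset=offset + arm_off + arm.index(bad),
                )
            if not arm:
                raise PatternSyntaxError(
                    "disjunction arm may not be empty", offset=offset + pos
                )
        return (Disjunction(left=left, right=right),)

    tokens: list[PatternToken] = []
    i = 0
    literal: list[str] = []

    def flush() -> None:
        if literal:
            tokens.append(Literal("".join(literal)))
            literal.clear()

    while i < len(text):
        ch = text[i]
        if ch == "$":
            end = text.find("$", i + 1)
            if end < 0:
                raise PatternSyntaxError("unbalanced '$' delimiter", offset=offset + i)
            name = text[i + 1 : end]
            if not name:
                raise PatternSyntaxError("empty variable name", offset=offset + i)
            bad = _DELIMITERS.intersection(name) | ({_EM_DASH, "|"} & set(name))
            if bad:
                raise PatternSyntaxError(
                    f"variable name may not contain {sorted(bad)}", offset=offset + i
                )
            flush()
            tokens.append(Variable(name))
            i = end + 1
        elif ch == "[":
            depth, j = 1, i + 1
            while j < len(text) and depth:
                if text[j] == "[":
                    depth += 1
                elif text[j] == "]":
                    depth -= 1
                j += 1
            if depth:
                raise PatternSyntaxError("unbalanced '[' delimiter", offset=offset + i)
            body = _parse_sequence(text[i + 1 : j - 1], offset + i + 1)
            if not body:
                raise PatternSyntaxError("empty optional group", offset=offset + i)
            flush()
            tokens.append(OptionalGroup(body=body))
            i = j
        elif ch == "]":
            raise PatternSyntaxError("unbalanced ']' delimiter", offset=offset + i)
        else:
            literal.append(ch)
            i += 1
    flush()
    return tuple(tokens)


def _at_top_level(text: str, pos: int, offset: int) -> bool:
    """True when text[pos] lies outside any $...$ or [...] span."""
    depth = 0
    in_var = False
    for i, ch in enumerate(text):
        if i == pos:
            return depth == 0 and not in_var
        if ch == "$":
            in_var = not in_var
        elif ch == "[" and not in_var:
            depth += 1
        elif ch == "]" and not in_var:
            depth = max(depth - 1, 0)
    return True


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------


def match_label(
    pattern: LabelPattern, text: str, given: Mapping[str, str] | None = None
) -> list[Bindings]:
    """All extensions of ``given`` under which the pattern matches ``text``.

    The whole-glyph modifier is ignored here — repetition and absence are
    interpreted by the matcher, which strips the modifier before calling in.
    A total function: no match is the empty list, a variable-free match is
    ``[{}]`` (extended with ``given``).
    """
    base: Bindings = dict(given or {})
    seen: set[tuple[tuple[str, str], ...]] = set()
    out: list[Bindings] = []
    for env in _match_seq(pattern.tokens, text, base):
        key = tuple(sorted(env.items()))
        if key not in seen:
            seen.add(key)
            out.append(dict(env))
    out.sort(key=lambda e: tuple(sorted(e.items())))
    return out


def _match_seq(
    tokens: Sequence[PatternToken], text: str, env: Bindings
) -> Iterator[Bindings]:
    if not tokens:
        if text == "":
            yield env
        return
    head, rest = tokens[0], tokens[1:]
    if isinstance(head, Literal):
        if text.startswith(head.text):
            yield from _match_seq(rest, text[len(head.text) :], env)
    elif isinstance(head, Variable):
        bound = env.get(head.name)
        if bound is not None:
            if bound and text.startswith(bound):
                yield from _match_seq(rest, text[len(bound) :], env)
        else:
            for i in range(1, len(text) + 1):  # non-empty prefixes only
                yield from _match_seq(rest, text[i:], {**env, head.name: text[:i]})
    elif isinstance(head, OptionalGroup):
        yield from _match_seq(rest, text, env)  # dropped
        yield from _match_seq(tuple(head.body) + tuple(rest), text, env)  # kept
    elif isinstance(head, Disjunction):
        for arm in (head.left, head.right):
            if text.startswith(arm):
                yield from _match_seq(rest, text[len(arm) :], env)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def render_label(
    pattern: LabelPattern, bindings: Mapping[str, str], keep_optionals: bool = True
) -> str:
    """Instantiate a pattern: variables from bindings, left disjunction arm.

    Optional groups are emitted only when ``keep_optionals`` is true; a
    variable outside any dropped optional with no binding raises
    MissingBindingError.
    """

    def render(tokens: Sequence[PatternToken]) -> str:
        parts: list[str] = []
        for t in tokens:
            if isinstance(t, Literal):
                parts.append(t.text)
            elif isinstance(t, Variable):
                value = bindings.get(t.name)
                if value is None:
                    raise MissingBindingError(t.name)
                parts.append(value)
            elif isinstance(t, OptionalGroup):
                if keep_optionals:
                    parts.append(render(t.body))
            else:
                parts.append(t.left)
        return "".join(parts)

    return render(pattern.tokens)
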