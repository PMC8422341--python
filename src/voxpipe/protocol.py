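"""The linear text-protocol language.

A protocol is a plain-text file holding a strictly linear list of module
invocations.  A module call starts with a ``process : <name>`` line; every
following ``key : value`` line attaches one string parameter to that call,
until the next ``process`` line.  ``//`` starts a whole-line comment, blank
lines are ignored.  Values are free text after the first ``:`` (they may
contain spaces, commas and further colons); no types exist at this level —
every parameter travels as a string and is interpreted by the consuming
module.

Parameter values may reference the batch item being processed through
``?token?`` keywords (``?image?``, ``?project?``, ``?dataset?``) and three
configured directories (``?ij?`` — the work folder, ``?home?``, ``?temp?``).
Substitution happens at execution time, once per batch item, which is what
lets a single protocol text serve a whole image set.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import KeywordError, ProtocolError

__all__ = [
    "ModuleCall",
    "Protocol",
    "KeywordContext",
    "Diagnostic",
    "parse_protocol",
    "serialize_protocol",
    "substitute_keywords",
    "validate_protocol",
]

PROCESS_KEYWORD = "process"
COMMENT_PREFIX = "//"


@dataclass
class ModuleCall:
    """One module invocation: a name plus an ordered map of raw string parameters."""

    name: str
    params: dict[str, str] = field(default_factory=dict)
    source_line: int = 1

    def __post_init__(self):
        if not self.name or self.name != self.name.strip():
            raise ProtocolError(
                f"module name must be a non-empty trimmed token, got {self.name!r}",
                self.source_line,
            )
        if ":" in self.name:
            raise ProtocolError(
                f"module name may not contain ':': {self.name!r}", self.source_line
            )


@dataclass
class Protocol:
    """An ordered list of module calls plus the text they were parsed from."""

    calls: list[ModuleCall] = field(default_factory=list)
    source_text: str = ""

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self):
        return iter(self.calls)


@dataclass
class KeywordContext:
    """Bindings for the ``?token?`` keywords of one batch item."""

    image: str
    project: str
    dataset: str
    ij_dir: str
    home_dir: str
    temp_dir: str

    def mapping(self) -> dict[str, str]:
        return {
            "image": self.image,
            "project": self.project,
            "dataset": self.dataset,
            "ij": self.ij_dir,
            "home": self.home_dir,
            "temp": self.temp_dir,
        }


@dataclass(frozen=True)
class Diagnostic:
    """One validation finding; ``severity`` is ``"error"`` or ``"warning"``."""

    severity: str
    line: int
    message: str

    def __str__(self) -> str:
        return f"{self.severity}: line {self.line}: {self.message}"


def parse_protocol(text: str) -> Protocol:
    """Parse protocol source text into an ordered list of module calls.

    Raises :class:`ProtocolError` (with the offending 1-based line number) on
    a parameter line appearing before any ``process`` line, a non-comment line
    without ``:``, an empty module name, or a duplicated parameter name within
    one call.
    """
    calls: list[ModuleCall] = []
    current: ModuleCall | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(COMMENT_PREFIX):
            continue
        if ":" not in line:
            raise ProtocolError(
                f"expected 'key : value', got {line!r}", lineno
            )
        key, _, value = line.partition(":")
        key = key.strip()
        value = value.strip()
        if key.casefold() == PROCESS_KEYWORD:
            if not value:
                raise ProtocolError("empty module name after 'process :'", lineno)
            current = ModuleCall(name=value, params={}, source_line=lineno)
            calls.append(current)
        else:
            if current is None:
                raise ProtocolError(
                    f"parameter {key!r} before any 'process :' line", lineno
                )
            if not key:
                raise ProtocolError("empty parameter name", lineno)
            if key in current.params:
                raise ProtocolError(
                    f"duplicate parameter {key!r} for module {current.name!r}", lineno
                )
            current.params[key] = value
    return Protocol(calls=calls, source_text=text)


def serialize_protocol(protocol: Protocol) -> str:
    """Render a protocol back to text such that re-parsing yields equal calls."""
    blocks = []
    for call in protocol.calls:
        lines = [f"{PROCESS_KEYWORD} : {call.name}"]
        lines.extend(f"{k} : {v}" for k, v in call.params.items())
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + ("\n" if blocks else "")


_TOKEN_RE = re.compile(r"\?([A-Za-z][A-Za-z0-9_]*)\?")


def substitute_keywords(raw: str, ctx: KeywordContext, line: int | None = None) -> str:
    """Replace every ``?token?`` in ``raw`` with its context binding.

    Substitution is simultaneous and non-recursive: the string is scanned
    once, and substituted values are never re-scanned, so a binding containing
    ``?image?`` survives literally.  An unrecognised token is a hard error —
    a typo like ``?imgae?`` passed through silently would corrupt database
    names downstream.
    """
    mapping = ctx.mapping()

    def _sub(match: re.Match) -> str:
        token = match.group(1)
        if token not in mapping:
            raise KeywordError(f"unknown keyword ?{token}?", line)
        return mapping[token]

    return _TOKEN_RE.sub(_sub, raw)


def _produced_files(call: ModuleCall) -> list[tuple[str, str]]:
    """(dir, file) pairs a call writes into the work folders, as raw keyword text."""
    name = call.name.casefold()
    if name in {
        "save",
        "measurement",
        "quantification",
        "coloc",
        "numbering",
        "distances",
        "mergetables",
        "appendtables",
        "savecalibration",
    }:
        d, f = call.params.get("dir"), call.params.get("file")
        if d is not None and f is not None:
            return [(d.strip(), f.strip())]
    return []


def _consumed_files(call: ModuleCall) -> list[tuple[str, str]]:
    """(dir, file) pairs a call expects to exist, as raw keyword text."""
    name = call.name.casefold()
    out: list[tuple[str, str]] = []
    if name in {"quantification", "coloc", "numbering", "distances"}:
        d, f = call.params.get("dirRaw"), call.params.get("fileRaw")
        if d is not None and f is not None:
            out.append((d.strip(), f.strip()))
    elif name == "attach":
        d, f = call.params.get("dir"), call.params.get("file")
        if d is not None and f is not None:
            out.append((d.strip(), f.strip()))
    elif name == "deletelist":
        d, items = call.params.get("dir"), call.params.get("list")
        if d is not None and items is not None:
            out.extend((d.strip(), item.strip()) for item in items.split(","))
    return out


def validate_protocol(protocol: Protocol, registry) -> list[Diagnostic]:
    """Static checks of a protocol against a module registry.

    Returns diagnostics rather than raising: errors for unknown module or
    parameter names, warnings for omitted parameters that have no default, and
    dataflow warnings for a work-folder file that is consumed (quantification
    raw input, attach, deleteList) without any earlier call producing it under
    the identical keyword text.
    """
    diagnostics: list[Diagnostic] = []
    produced: set[tuple[str, str]] = set()
    for call in protocol.calls:
        spec = registry.spec(call.name)
        if spec is None:
            diagnostics.append(
                Diagnostic("error", call.source_line, f"unknown module {call.name!r}")
            )
            continue
        known = {p.name for p in spec.params}
        for pname in call.params:
            if pname not in known:
                diagnostics.append(
                    Diagnostic(
                        "error",
                        call.source_line,
                        f"unknown parameter {pname!r} for module {spec.name!r}",
                    )
                )
        for p in spec.params:
            if p.default is None and p.name not in call.params:
                diagnostics.append(
                    Diagnostic(
                        "warning",
                        call.source_line,
                        f"module {spec.name!r} is missing required parameter {p.name!r}",
                    )
                )
        for pair in _consumed_files(call):
            if pair not in produced:
                diagnostics.append(
                    Diagnostic(
                        "warning",
                        call.source_line,
                        f"module {spec.name!r} references {pair[0]}/{pair[1]} "
                        "but no earlier call produces it",
                    )
                )
        produced.update(_produced_files(call))
    return diagnostics
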