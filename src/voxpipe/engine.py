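"""Module registry and sequential protocol execution.

The execution model is deliberately simple: there is exactly one *current
image* flowing through the protocol.  Each call receives it (pure-I/O calls
may run without one), plus the provenance record of the original database
image, and returns the image that becomes current for the next call.  Any
auxiliary image a module needs — raw intensities for quantification, a second
label map for co-localisation — must have been saved to a work folder earlier
in the protocol and is passed as a file parameter.

Keyword substitution (``?image?`` and friends) is applied to every resolved
parameter value at execution time, per batch item, so one protocol text
serves the whole image set.  A failing image never aborts the batch: its
report records the error and processing continues with the next image.
"""

from __future__ import annotations

import importlib
import logging
import tempfile
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable

import yaml

from .containers import ImageInfo, ImageRef, VoxelGrid
from .errors import ModuleError, RegistryError, VoxPipeError
from .protocol import (
    KeywordContext,
    ModuleCall,
    Protocol,
    substitute_keywords,
)
from .store import ImageDatabase

__all__ = [
    "Param",
    "ModuleSpec",
    "module",
    "ModuleRegistry",
    "load_registry",
    "default_registry",
    "resolve_params",
    "EngineConfig",
    "ExecutionState",
    "RunReport",
    "run_protocol",
    "run_batch",
]

logger = logging.getLogger("voxpipe.engine")

CATEGORIES = (
    "Input/Output",
    "Calibration",
    "Processing",
    "Filtering",
    "Thresholding",
    "Labelling",
    "Post-processing",
    "Analysis",
    "Measurements processing",
)


@dataclass(frozen=True)
class Param:
    """One module parameter: ``default is None`` marks it as required."""

    name: str
    default: str | None
    doc: str = ""

    @property
    def required(self) -> bool:
        return self.default is None


@dataclass(frozen=True)
class ModuleSpec:
    """Descriptor of one registered module."""

    name: str
    category: str
    doc: str
    params: tuple[Param, ...] = ()
    needs_image: bool = True

    def __post_init__(self):
        names = [p.name for p in self.params]
        if len(names) != len(set(names)):
            raise RegistryError(f"module {self.name!r} has duplicate parameter names")
        if self.category not in CATEGORIES:
            raise RegistryError(
                f"module {self.name!r} has unknown category {self.category!r}"
            )

    def param(self, name: str) -> Param | None:
        for p in self.params:
            if p.name == name:
                return p
        return None


def module(
    name: str,
    category: str,
    doc: str,
    params: tuple = (),
    needs_image: bool = True,
) -> Callable:
    """Decorator attaching a :class:`ModuleSpec` to an operation function."""

    def deco(fn: Callable) -> Callable:
        fn.module_spec = ModuleSpec(
            name=name,
            category=category,
            doc=doc,
            params=tuple(Param(*p) for p in params),
            needs_image=needs_image,
        )
        return fn

    return deco


class ModuleRegistry:
    """Case-insensitive name -> (spec, operation) map with duplicate rejection."""

    def __init__(self):
        self._entries: dict[str, tuple[ModuleSpec, Callable]] = {}
        self._targets: dict[str, str] = {}

    def add(self, fn: Callable, target: str = "") -> None:
        spec: ModuleSpec | None = getattr(fn, "module_spec", None)
        if spec is None:
            raise RegistryError(
                f"registry target {target or fn!r} is not a module operation "
                "(missing module spec)"
            )
        key = spec.name.casefold()
        if key in self._entries:
            raise RegistryError(
                f"duplicate module name {spec.name!r}: "
                f"{self._targets.get(key, '?')} and {target or fn!r} share it"
            )
        self._entries[key] = (spec, fn)
        self._targets[key] = target or getattr(fn, "__qualname__", str(fn))

    def lookup(self, name: str) -> tuple[ModuleSpec, Callable] | None:
        return self._entries.get(name.strip().casefold())

    def spec(self, name: str) -> ModuleSpec | None:
        entry = self.lookup(name)
        return entry[0] if entry else None

    def operation(self, name: str) -> Callable | None:
        entry = self.lookup(name)
        return entry[1] if entry else None

    def specs(self) -> list[ModuleSpec]:
        return sorted((s for s, _ in self._entries.values()), key=lambda s: s.name)

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, name: str) -> bool:
        return name.strip().casefold() in self._entries


def _import_target(target: str) -> Callable:
    modpath, _, attr = target.rpartition(".")
    if not modpath:
        raise RegistryError(f"registry target {target!r} is not a dotted path")
    try:
        mod = importlib.import_module(modpath)
    except ImportError as exc:
        raise RegistryError(f"cannot import registry target {target!r}: {exc}") from exc
    try:
        return getattr(mod, attr)
    except AttributeError as exc:
        raise RegistryError(f"registry target {target!r} not found") from exc


def load_registry(text: str) -> ModuleRegistry:
    """Build a registry from ``name:dotted.path.to.operation`` lines.

    Blank lines and ``#`` comments are skipped.  Two entries mapping to the
    same (case-folded) module name are rejected at load time.
    """
    registry = ModuleRegistry()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        name, sep, target = line.partition(":")
        name, target = name.strip(), target.strip()
        if not sep or not name or not target:
            raise RegistryError(f"registry line {lineno}: expected 'name:target', got {line!r}")
        fn = _import_target(target)
        spec = getattr(fn, "module_spec", None)
        if spec is not None and spec.name.casefold() != name.casefold():
            # the file may rename a module; re-register under the file's name
            fn = _renamed(fn, name)
        registry.add(fn, target=target)
    return registry


def _renamed(fn: Callable, name: str) -> Callable:
    import dataclasses

    spec = dataclasses.replace(fn.module_spec, name=name)

    def wrapper(state, params):
        return fn(state, params)

    wrapper.module_spec = spec
    wrapper.__qualname__ = getattr(fn, "__qualname__", name)
    return wrapper


def default_registry() -> ModuleRegistry:
    """The built-in catalog, loaded from the packaged registry file."""
    text = resources.files("voxpipe").joinpath("registry.txt").read_text("utf-8")
    return load_registry(text)


def resolve_params(call: ModuleCall, spec: ModuleSpec) -> dict[str, str]:
    """Merge a call's parameters with the module defaults.

    Unknown parameter names and omitted required parameters raise
    :class:`ModuleError` naming the module, the parameter and the source line.
    """
    known = {p.name for p in spec.params}
    for pname in call.params:
        if pname not in known:
            raise ModuleError(
                f"line {call.source_line}: unknown parameter {pname!r} "
                f"for module {spec.name!r}"
            )
    resolved: dict[str, str] = {}
    for p in spec.params:
        if p.name in call.params:
            resolved[p.name] = call.params[p.name]
        elif p.required:
            raise ModuleError(
                f"line {call.source_line}: module {spec.name!r} requires "
                f"parameter {p.name!r}"
            )
        else:
            resolved[p.name] = p.default
    return resolved


@dataclass
class EngineConfig:
    """Work-folder bindings and execution options.

    ``work_dir`` backs the ``?ij?`` keyword (the original notion of an
    ImageJ/Fiji folder has no meaning here, so it is simply a configured
    working directory); ``home_dir`` and ``temp_dir`` back ``?home?`` and
    ``?temp?``.
    """

    work_dir: Path = field(default_factory=Path.cwd)
    home_dir: Path = field(default_factory=Path.home)
    temp_dir: Path = field(default_factory=lambda: Path(tempfile.gettempdir()))

    def __post_init__(self):
        self.work_dir = Path(self.work_dir)
        self.home_dir = Path(self.home_dir)
        self.temp_dir = Path(self.temp_dir)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EngineConfig":
        data = yaml.safe_load(Path(path).read_text("utf-8")) or {}
        if not isinstance(data, dict):
            raise VoxPipeError(f"config {path} must be a mapping")
        kwargs = {}
        for key in ("work_dir", "home_dir", "temp_dir"):
            if key in data:
                kwargs[key] = Path(str(data[key]))
        return cls(**kwargs)

    def context_for(self, ref: ImageRef) -> KeywordContext:
        for d in (self.work_dir, self.home_dir, self.temp_dir):
            d.mkdir(parents=True, exist_ok=True)
        return KeywordContext(
            image=ref.image,
            project=ref.project,
            dataset=ref.dataset,
            ij_dir=str(self.work_dir),
            home_dir=str(self.home_dir),
            temp_dir=str(self.temp_dir),
        )


@dataclass
class ExecutionState:
    """Mutable state threaded through one protocol run."""

    info: ImageInfo
    ctx: KeywordContext
    db: ImageDatabase
    current: VoxelGrid | None = None
    log_lines: list[str] = field(default_factory=list)

    def log(self, message: str, level: int = logging.INFO) -> None:
        logger.log(level, message)
        self.log_lines.append(message)

    def warn(self, message: str) -> None:
        self.log("warning: " + message, logging.WARNING)


@dataclass
class RunReport:
    """Outcome of one protocol run over one image."""

    image: str
    success: bool
    elapsed: float
    calls_executed: int
    log_lines: list[str]
    error: str | None = None


def run_protocol(
    protocol: Protocol,
    ref: ImageRef,
    db: ImageDatabase,
    registry: ModuleRegistry,
    config: EngineConfig | None = None,
) -> RunReport:
    """Execute a protocol on one database image.

    Calls run strictly in textual order.  On the first error the remaining
    calls for this image are skipped and the report records the failure; the
    exception never propagates, so batches survive single bad images.
    """
    config = config or EngineConfig()
    ctx = config.context_for(ref)
    state = ExecutionState(info=ImageInfo(ref=ref), ctx=ctx, db=db)
    t_start = time.perf_counter()
    executed = 0
    error: str | None = None
    for call in protocol.calls:
        try:
            entry = registry.lookup(call.name)
            if entry is None:
                raise ModuleError(
                    f"line {call.source_line}: unknown module {call.name!r}"
                )
            spec, fn = entry
            params = resolve_params(call, spec)
            params = {
                k: substitute_keywords(v, ctx, line=call.source_line)
                for k, v in params.items()
            }
            if spec.needs_image and state.current is None:
                raise ModuleError(
                    f"line {call.source_line}: module {spec.name!r} has "
                    "no current image (nothing input yet)"
                )
            t0 = time.perf_counter()
            state.current = fn(state, params)
            dt = time.perf_counter() - t0
            shown = ", ".join(f"{k}={v}" for k, v in params.items())
            state.log(f"{spec.name}({shown}) [{dt:.3f} s]")
            executed += 1
        except VoxPipeError as exc:
            error = str(exc)
            state.log(f"FAILED {call.name}: {error}", logging.ERROR)
            break
    elapsed = time.perf_counter() - t_start
    state.log(f"processed {ref} in {elapsed:.3f} s")
    return RunReport(
        image=str(ref),
        success=error is None,
        elapsed=elapsed,
        calls_executed=executed,
        log_lines=state.log_lines,
        error=error,
    )


def run_batch(
    protocol: Protocol,
    refs: list[ImageRef],
    db: ImageDatabase,
    registry: ModuleRegistry,
    config: EngineConfig | None = None,
) -> list[RunReport]:
    """Run a protocol sequentially over a list of images, one report each."""
    if not refs:
        logger.warning("empty batch: no images to process")
        return []
    reports = []
    for ref in refs:
        reports.append(run_protocol(protocol, ref, db, registry, config))
    return reports


def read_batch_list(text: str) -> list[ImageRef]:
    """Parse a batch list file: one ``project/dataset/image`` per line."""
    refs = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.split("/")]
        if len(parts) != 3 or not all(parts):
            raise VoxPipeError(
                f"batch list line {lineno}: expected 'project/dataset/image', got {line!r}"
            )
        refs.append(ImageRef(*parts))
    return refs
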