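import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import voxpipe
from voxpipe import (
    Calibration,
    EngineConfig,
    SceneSpec,
    VoxelGrid,
    default_registry,
    init_db,
    parse_protocol,
    populate_db,
)
from voxpipe.engine import resolve_params
from voxpipe.protocol import ModuleCall

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def example_text():
    with open(voxpipe.example_protocol_path(), encoding="utf-8") as fh:
        return fh.read()


@pytest.fixture(scope="session")
def example_protocol(example_text):
    return parse_protocol(example_text)


@pytest.fixture
def db(tmp_path):
    return init_db(tmp_path / "db")


@pytest.fixture
def config(tmp_path):
    return EngineConfig(
        work_dir=tmp_path / "work",
        home_dir=tmp_path / "home",
        temp_dir=tmp_path / "tmp",
    )


def small_scene_spec(**overrides) -> SceneSpec:
    """A fast-to-generate scene for unit tests (the default spec is the
    full-size worked example)."""
    kwargs = dict(
        shape=(16, 64, 64),
        n_objects=3,
        radius_xy=(5, 7),
        radius_z=(3, 4),
        edge_touching=1,
    )
    kwargs.update(overrides)
    return SceneSpec(**kwargs)


@pytest.fixture
def small_db(db):
    """Database populated with two small synthetic stacks."""
    refs = populate_db(db, n_images=2, spec=small_scene_spec(), seed=7)
    return db, refs


class FakeState:
    """Minimal execution state for exercising operations directly."""

    def __init__(self, current=None, db=None, info=None, ctx=None):
        self.current = current
        self.db = db
        self.info = info
        self.ctx = ctx
        self.log_lines = []
        self.warnings = []

    def log(self, message, *a):
        self.log_lines.append(message)

    def warn(self, message):
        self.warnings.append(message)
        self.log_lines.append("warning: " + message)


def run_op(fn, current=None, db=None, info=None, state=None, **params):
    """Run one operation with defaults resolved from its module spec.

    Returns ``(new_current, state)``.
    """
    spec = fn.module_spec
    call = ModuleCall(
        name=spec.name, params={k: str(v) for k, v in params.items()}, source_line=1
    )
    resolved = resolve_params(call, spec)
    if state is None:
        state = FakeState(current=current, db=db, info=info)
    result = fn(state, resolved)
    return result, state


def grid_of(data, xy=1.0, z=1.0, unit="pixel", cls=VoxelGrid):
    return cls(np.asarray(data), Calibration(xy, z, unit))
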