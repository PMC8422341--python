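"""voxpipe: text-protocol batch processing and analysis of 3D microscopy stacks.

A protocol is a plain-text, strictly linear list of module calls; a single
*current image* flows from module to module while results tables and derived
images are pushed back into a local project/dataset/image folder database.
"""

__version__ = "0.1.0"

from .containers import (
    BinaryMask,
    Calibration,
    ImageInfo,
    ImageRef,
    LabelMap,
    MultiDimImage,
    VoxelGrid,
    extract_plane,
)
from .engine import (
    EngineConfig,
    ModuleRegistry,
    RunReport,
    default_registry,
    load_registry,
    resolve_params,
    run_batch,
    run_protocol,
)
from .errors import (
    FixtureError,
    KeywordError,
    ModuleError,
    ProtocolError,
    RegistryError,
    StoreError,
    VoxPipeError,
)
from .fixtures import SceneSpec, generate_scene, populate_db
from .protocol import (
    Diagnostic,
    KeywordContext,
    ModuleCall,
    Protocol,
    parse_protocol,
    serialize_protocol,
    substitute_keywords,
    validate_protocol,
)
from .store import (
    ImageDatabase,
    init_db,
    read_grid,
    read_table,
    write_grid,
    write_table,
)

__all__ = [
    "__version__",
    # containers
    "VoxelGrid", "BinaryMask", "LabelMap", "MultiDimImage",
    "Calibration", "ImageRef", "ImageInfo", "extract_plane",
    # protocol
    "Protocol", "ModuleCall", "KeywordContext", "Diagnostic",
    "parse_protocol", "serialize_protocol", "substitute_keywords",
    "validate_protocol",
    # store
    "ImageDatabase", "init_db", "read_grid", "write_grid",
    "read_table", "write_table",
    # engine
    "ModuleRegistry", "EngineConfig", "RunReport",
    "default_registry", "load_registry", "resolve_params",
    "run_protocol", "run_batch",
    # fixtures
    "SceneSpec", "generate_scene", "populate_db",
    # errors
    "VoxPipeError", "ProtocolError", "KeywordError", "RegistryError",
    "StoreError", "ModuleError", "FixtureError",
]


def example_protocol_path() -> str:
    """Path of the packaged nuclei-quantification example protocol."""
    from importlib import resources

    return str(resources.files("voxpipe") / "examples" / "nuclei_quantification.tapas")
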