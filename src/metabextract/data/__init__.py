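"""Bundled fixtures: compound registry and a demonstration pathway set."""
from importlib import resources
from pathlib import Path

from ..feature_io import CompoundRegistry, PathwayDef, load_pathways, read_registry

__all__ = [
    "registry_path",
    "pathways_path",
    "load_bundled_registry",
    "load_bundled_pathways",
]


def registry_path() -> Path:
    return Path(resources.files(__name__) / "registry.csv")


def pathways_path() -> Path:
    return Path(resources.files(__name__) / "pathways.json")


def load_bundled_registry() -> CompoundRegistry:
    return read_registry(registry_path())


def load_bundled_pathways() -> list[PathwayDef]:
    return load_pathways(pathways_path())
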