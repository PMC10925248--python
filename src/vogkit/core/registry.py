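"""Plugin registry: sources, pipelines and calibrations are registered by
name and interchangeable at run time."""

from __future__ import annotations

import enum
from typing import Callable, Dict, Tuple


class PluginKind(enum.Enum):
    SOURCE = "source"
    PIPELINE = "pipeline"
    CALIBRATION = "calibration"


class PluginError(KeyError):
    pass


class DuplicatePluginError(PluginError):
    pass


class UnknownPluginError(PluginError):
    pass


class PluginRegistry:
    """Maps (kind, name) to a factory callable."""

    def __init__(self) -> None:
        self._plugins: Dict[Tuple[PluginKind, str], Callable] = {}

    def register(self, kind: PluginKind, name: str, factory: Callable) -> None:
        kind = PluginKind(kind)
        key = (kind, name)
        if key in self._plugins:
            raise DuplicatePluginError(
                f"{kind.value} plugin '{name}' is already registered"
            )
        self._plugins[key] = factory

    def get(self, kind: PluginKind, name: str) -> Callable:
        kind = PluginKind(kind)
        try:
            return self._plugins[(kind, name)]
        except KeyError:
            available = ", ".join(sorted(self.names(kind))) or "<none>"
            raise UnknownPluginError(
                f"no {kind.value} plugin named '{name}'; available: {available}"
            ) from None

    def names(self, kind: PluginKind):
        kind = PluginKind(kind)
        return [n for (k, n) in self._plugins if k == kind]


default_registry = PluginRegistry()


def register_plugin(kind: PluginKind, name: str, factory: Callable) -> None:
    """Register into the process-wide default registry."""
    default_registry.register(kind, name, factory)
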