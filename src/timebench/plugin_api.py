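"""Plugin contract, registry, named settings sets and template generation.

A plugin is a self-describing processing stage with three mandatory entry
points:

``declare()``
    returns the :class:`PluginSpec` (id, category, scope, settings schema);
``configure(settings)``
    normalizes a validated settings mapping (a hook for derived defaults);
``process(study, subject_or_subjects, settings, ctx)``
    does the work.  Subject-scope plugins receive one :class:`~.model.Subject`
    per call; group-scope plugins receive the full selected subject list.

Settings are plain mappings validated against the declared schema; named
settings sets ("default", "noName", ...) can be stored per plugin and merged
with per-instance overrides at instantiation time.
"""

from __future__ import annotations

import inspect
import keyword
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import yaml

from .model import PluginInstance


class RegistrationError(ValueError):
    """Duplicate plugin id or malformed registration."""


class ContractError(TypeError):
    """A mandatory plugin entry point is missing or not callable."""


class SettingsError(ValueError):
    """A settings mapping does not validate against the plugin's schema."""


_TYPE_CHECKS: dict[str, Callable[[Any], bool]] = {
    "int": lambda v: isinstance(v, int) and not isinstance(v, bool),
    "float": lambda v: (isinstance(v, (int, float)) and not isinstance(v, bool)),
    "str": lambda v: isinstance(v, str),
    "bool": lambda v: isinstance(v, bool),
    "list": lambda v: isinstance(v, (list, tuple)),
    "pair": lambda v: isinstance(v, (list, tuple)) and len(v) == 2,
    "dict": lambda v: isinstance(v, dict),
}


@dataclass(frozen=True)
class SettingSpec:
    """Schema entry for one settings key."""

    type: str
    default: Any
    choices: tuple | None = None
    minimum: float | None = None
    maximum: float | None = None
    nullable: bool = False
    doc: str = ""

    def check(self, key: str, value: Any) -> None:
        if value is None:
            if self.nullable:
                return
            raise SettingsError(f"setting {key!r}: value may not be null")
        if self.type not in _TYPE_CHECKS:
            raise SettingsError(f"setting {key!r}: unknown schema type {self.type!r}")
        if not _TYPE_CHECKS[self.type](value):
            raise SettingsError(
                f"setting {key!r}: expected {self.type}, got {type(value).__name__} ({value!r})"
            )
        if self.choices is not None and value not in self.choices:
            raise SettingsError(
                f"setting {key!r}: {value!r} not one of {tuple(self.choices)}"
            )
        if self.minimum is not None and not isinstance(value, (list, tuple, dict)):
            if value < self.minimum:
                raise SettingsError(
                    f"setting {key!r}: {value!r} below minimum {self.minimum}"
                )
        if self.maximum is not None and not isinstance(value, (list, tuple, dict)):
            if value > self.maximum:
                raise SettingsError(
                    f"setting {key!r}: {value!r} above maximum {self.maximum}"
                )


@dataclass
class PluginSpec:
    """Self-description of a plugin: identity, scope and settings schema."""

    plugin_id: str
    category: str
    settings_schema: dict[str, SettingSpec] = field(default_factory=dict)
    doc: str = ""
    scope: str = "subject"  # "subject" or "group"

    def defaults(self) -> dict[str, Any]:
        return {k: s.default for k, s in self.settings_schema.items()}

    def validate(self, settings: dict[str, Any]) -> dict[str, Any]:
        """Return a complete validated settings mapping or raise SettingsError."""
        out = self.defaults()
        for key, value in settings.items():
            if key not in self.settings_schema:
                raise SettingsError(
                    f"unknown setting {key!r} for plugin {self.plugin_id!r}"
                )
            self.settings_schema[key].check(key, value)
            out[key] = list(value) if isinstance(value, tuple) else value
        return out


@dataclass
class RegistryEntry:
    spec: PluginSpec
    declare: Callable
    configure: Callable
    process: Callable
    source: str | None = None


class PluginRegistry:
    """Plugins discoverable by id and by category."""

    def __init__(self) -> None:
        self._entries: dict[str, RegistryEntry] = {}

    def register(
        self,
        declare: Callable | None,
        configure: Callable | None,
        process: Callable | None,
        source: str | None = None,
    ) -> RegistryEntry:
        for name, fn in (("declare", declare), ("configure", configure), ("process", process)):
            if fn is None or not callable(fn):
                raise ContractError(f"mandatory entry point {name!r} is missing")
        spec = declare()
        if not isinstance(spec, PluginSpec):
            raise ContractError("declare() must return a PluginSpec")
        if spec.plugin_id in self._entries:
            raise RegistrationError(f"plugin id {spec.plugin_id!r} already registered")
        if spec.scope not in ("subject", "group"):
            raise RegistrationError(f"plugin {spec.plugin_id!r}: invalid scope {spec.scope!r}")
        entry = RegistryEntry(spec, declare, configure, process, source)
        self._entries[spec.plugin_id] = entry
        return entry

    def register_namespace(self, ns: Any, source: str | None = None) -> RegistryEntry:
        """Register a plugin from a module-like object or mapping that
        defines the three mandatory entry points."""
        get = ns.get if isinstance(ns, dict) else lambda k, d=None: getattr(ns, k, d)
        return self.register(get("declare"), get("configure"), get("process"), source=source)

    def register_source(self, source: str) -> RegistryEntry:
        """Execute plugin source text and register the plugin it defines."""
        namespace: dict[str, Any] = {}
        exec(compile(source, "<plugin source>", "exec"), namespace)
        return self.register_namespace(namespace, source=source)

    def get(self, plugin_id: str) -> RegistryEntry:
        try:
            return self._entries[plugin_id]
        except KeyError:
            raise KeyError(f"plugin {plugin_id!r} is not registered") from None

    def __contains__(self, plugin_id: str) -> bool:
        return plugin_id in self._entries

    def ids(self, category: str | None = None) -> list[str]:
        return sorted(
            pid
            for pid, e in self._entries.items()
            if category is None or e.spec.category == category
        )

    def categories(self) -> list[str]:
        return sorted({e.spec.category for e in self._entries.values()})

    def source_for(self, plugin_id: str) -> str:
        """Source snapshot of a plugin (stored text, else the defining module)."""
        entry = self.get(plugin_id)
        if entry.source is None:
            module = sys.modules.get(entry.process.__module__)
            entry.source = inspect.getsource(module) if module else ""
        return entry.source


#: Process-wide default registry; the shipped plugins register here on import.
default_registry = PluginRegistry()


def register_plugin(
    declare: Callable | None,
    configure: Callable | None,
    process: Callable | None,
    registry: PluginRegistry | None = None,
    source: str | None = None,
) -> RegistryEntry:
    """Register a plugin by its three mandatory entry points."""
    return (registry or default_registry).register(declare, configure, process, source)


# ---------------------------------------------------------------------------
# named settings sets
# ---------------------------------------------------------------------------


class SettingsStore:
    """Named settings sets per plugin; 'default' always resolves to the
    declared schema defaults.  Optionally persisted as one YAML file per
    (plugin, name) so stored settings are diff-able and shareable."""

    def __init__(self, directory: str | Path | None = None) -> None:
        self._store: dict[tuple[str, str], dict[str, Any]] = {}
        self.directory = Path(directory) if directory is not None else None
        if self.directory is not None and self.directory.is_dir():
            for f in sorted(self.directory.glob("*.yaml")):
                plugin_id, _, name = f.stem.rpartition("__")
                self._store[(plugin_id.replace("~", "/"), name)] = yaml.safe_load(
                    f.read_text()
                )

    def save(self, plugin_id: str, name: str, settings: dict[str, Any]) -> None:
        self._store[(plugin_id, name)] = dict(settings)
        if self.directory is not None:
            self.directory.mkdir(parents=True, exist_ok=True)
            fname = f"{plugin_id.replace('/', '~')}__{name}.yaml"
            (self.directory / fname).write_text(
                yaml.safe_dump(dict(settings), sort_keys=True)
            )

    def names(self, plugin_id: str) -> list[str]:
        return sorted(n for (pid, n) in self._store if pid == plugin_id) or []

    def resolve(self, plugin_id: str, name: str, spec: PluginSpec) -> dict[str, Any]:
        if (plugin_id, name) in self._store:
            return dict(self._store[(plugin_id, name)])
        if name == "default":
            return spec.defaults()
        raise KeyError(f"no stored settings {name!r} for plugin {plugin_id!r}")


def instantiate(
    plugin_id: str,
    settings_name: str = "default",
    overrides: dict[str, Any] | None = None,
    registry: PluginRegistry | None = None,
    store: SettingsStore | None = None,
) -> PluginInstance:
    """Create a configured workflow stage: defaults <- named set <- overrides,
    validated against the plugin's declared schema."""
    registry = registry or default_registry
    entry = registry.get(plugin_id)
    base = (store or SettingsStore()).resolve(plugin_id, settings_name, entry.spec)
    merged = dict(base)
    merged.update(overrides or {})
    settings = entry.spec.validate(merged)
    settings = entry.configure(settings)
    return PluginInstance(
        plugin_id=plugin_id, settings_name=settings_name, settings=settings
    )


# ---------------------------------------------------------------------------
# template generation
# ---------------------------------------------------------------------------

_TEMPLATE_BASIC_GROUP = '''"""{plugin_id} -- custom group-level stage (generated from the
'{kind}' template).

The three mandatory entry points below (declare, configure, process) make
this file a complete, registrable stage.  Unmodified it is a no-op.
"""

from timebench.plugin_api import PluginSpec, SettingSpec


def declare():
    return PluginSpec(
        plugin_id="{plugin_id}",
        category="custom/{category}",
        scope="group",
        doc=__doc__,
        settings_schema={{
            # Example controls: two free-text values, a dropdown and a checkbox.
            "label": SettingSpec("str", default=""),
            "scale": SettingSpec("float", default=1.0),
            "mode": SettingSpec("str", default="plain", choices=("plain", "fancy")),
            "enabled": SettingSpec("bool", default=True),
        }},
    )


def configure(settings):
    return dict(settings)


def process(study, subjects, settings, ctx):
    outputs = {{}}
    # Your code for plugin processing should start here
    return outputs
'''

TEMPLATE_KINDS = {"basic-group": _TEMPLATE_BASIC_GROUP}


def generate_plugin_template(
    category: str, name: str, template_kind: str = "basic-group"
) -> str:
    """Emit source text for a new plugin named ``<category>/<name>``.

    The output is deterministic (same inputs, byte-identical text) and
    registrable as-is.
    """
    for part in (category, name):
        if not part.isidentifier() or keyword.iskeyword(part):
            raise ValueError(f"{part!r} is not a valid plugin identifier part")
    if template_kind not in TEMPLATE_KINDS:
        raise ValueError(
            f"unknown template kind {template_kind!r}; known: {sorted(TEMPLATE_KINDS)}"
        )
    return TEMPLATE_KINDS[template_kind].format(
        plugin_id=f"{category}/{name}", category=category, kind=template_kind
    )


def template_filename(category: str, name: str) -> str:
    return f"{category}_{name}.py"
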