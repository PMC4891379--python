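"""Self-contained study bundles: export/import, content-derived identifiers
and the lock lifecycle.

A bundle is a plain zip archive holding a JSON manifest (study metadata,
engine version, lock state, workflow with settings, channels/events/derived
data), every raw file byte-exact under ``data/<subject>/``, and a source
snapshot of every referenced plugin under ``plugins/``.  A bundle is
therefore sufficient to re-run the analysis elsewhere.

The unique workflow identifier (UWID) has the form ``ts-xxx-xxx`` (two
lowercase base-36 triplets) and is derived locally from a content hash of
the study's manifest, workflow and plugin sources: identical content yields
an identical identifier, and any settings change yields a different one.
"""

from __future__ import annotations

import json
import zipfile
from pathlib import Path

from . import __version__
from .model import (
    LockedStudyError,
    Modality,
    PluginInstance,
    ProvenanceRecord,
    Study,
    Subject,
    content_hash,
    validate_study,
)
from .plugin_api import PluginRegistry, default_registry

__all__ = [
    "export_bundle",
    "import_bundle",
    "assign_uwid",
    "lock_study",
    "BundleFormatError",
    "register_bundle_plugins",
]

FORMAT_VERSION = 1

_MANIFEST_SCHEMA: dict[str, type] = {
    "format_version": int,
    "engine_version": str,
    "name": str,
    "locked": bool,
    "subjects": list,
    "workflow": list,
    "plugin_ids": list,
    "provenance": list,
}


class BundleFormatError(ValueError):
    """Corrupt archive or manifest schema mismatch."""


def _plugin_file(plugin_id: str) -> str:
    return f"plugins/{plugin_id.replace('/', '~')}.py"


def _study_manifest(study: Study) -> dict:
    d = study.to_dict()
    d["format_version"] = FORMAT_VERSION
    return d


def _uwid_payload(study: Study) -> dict:
    """Content hashed into the UWID: everything reproducible (no provenance
    timestamps, no uwid itself)."""
    d = study.to_dict()
    d.pop("uwid", None)
    d.pop("provenance", None)
    d.pop("locked", None)
    d["plugin_sources"] = dict(study.plugin_sources)
    return d


def _base36(n: int, width: int) -> str:
    digits = "0123456789abcdefghijklmnopqrstuvwxyz"
    out = []
    for _ in range(width):
        n, r = divmod(n, 36)
        out.append(digits[r])
    return "".join(reversed(out))


def assign_uwid(study: Study, registry: PluginRegistry | None = None) -> str:
    """Derive (and set) the study's deterministic content identifier.

    Plugin sources are snapshotted into the study first: they are part of
    the identified content, and it leaves archived (locked) studies
    exportable without further mutation.
    """
    errors = validate_study(study)
    if errors:
        raise ValueError(f"study does not validate: {errors[0]}")
    _snapshot_sources(study, registry or default_registry)
    digest = int(content_hash(_uwid_payload(study)), 16)
    uwid = f"ts-{_base36(digest % 36**3, 3)}-{_base36((digest // 36**3) % 36**3, 3)}"
    if study.uwid != uwid:
        study.check_unlocked()
        study.uwid = uwid
    return uwid


def lock_study(study: Study) -> Study:
    """Archive the study: requires an assigned UWID; afterwards every
    mutating operation raises :class:`LockedStudyError`."""
    if study.locked:
        raise LockedStudyError(f"study {study.name!r} is already locked")
    errors = validate_study(study)
    if errors:
        raise ValueError(f"study does not validate: {errors[0]}")
    if study.uwid is None:
        raise ValueError("assign a UWID before locking")
    study.locked = True
    return study


def _snapshot_sources(study: Study, registry: PluginRegistry) -> None:
    for inst in study.workflow:
        ref = inst.source_ref or inst.plugin_id
        if ref not in study.plugin_sources:
            if study.locked:
                raise LockedStudyError(
                    "locked study is missing a plugin source snapshot"
                )
            study.plugin_sources[ref] = registry.source_for(inst.plugin_id)
            inst.source_ref = ref


def export_bundle(
    study: Study, path: str | Path, registry: PluginRegistry | None = None
) -> Path:
    """Write the study as a self-sufficient zip bundle."""
    registry = registry or default_registry
    errors = validate_study(study)
    if errors:
        raise ValueError(f"study does not validate: {errors[0]}")
    _snapshot_sources(study, registry)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    manifest = _study_manifest(study)
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("manifest.json", json.dumps(manifest, sort_keys=True, indent=1))
        for subject in study.subjects:
            for fname, blob in sorted(subject.raw_files.items()):
                zf.writestr(f"data/{subject.name}/{fname}", blob)
        for plugin_id, source in sorted(study.plugin_sources.items()):
            zf.writestr(_plugin_file(plugin_id), source)
    return path


def _check_manifest(manifest: dict) -> None:
    for key, typ in _MANIFEST_SCHEMA.items():
        if key not in manifest:
            raise BundleFormatError(f"manifest field {key!r} is missing")
        if not isinstance(manifest[key], typ):
            raise BundleFormatError(
                f"manifest field {key!r} has type {type(manifest[key]).__name__}, "
                f"expected {typ.__name__}"
            )
    if manifest["format_version"] > FORMAT_VERSION:
        raise BundleFormatError(
            f"bundle format version {manifest['format_version']} is newer than "
            f"supported version {FORMAT_VERSION}"
        )


def import_bundle(path: str | Path) -> Study:
    """Reconstruct a study (field-by-field equal to the exported one,
    raw bytes included) from a bundle archive."""
    path = Path(path)
    try:
        zf = zipfile.ZipFile(path)
    except (zipfile.BadZipFile, FileNotFoundError) as exc:
        raise BundleFormatError(f"not a readable bundle archive: {exc}") from None
    with zf:
        try:
            manifest = json.loads(zf.read("manifest.json"))
        except KeyError:
            raise BundleFormatError("manifest field 'manifest.json' is missing") from None
        except json.JSONDecodeError as exc:
            raise BundleFormatError(f"manifest is not valid JSON: {exc}") from None
        _check_manifest(manifest)
        study = Study(
            name=manifest["name"],
            uwid=manifest.get("uwid"),
            locked=False,  # set after reconstruction so mutators work here
            engine_version=manifest["engine_version"],
        )
        for sd in manifest["subjects"]:
            subject = Subject(name=sd["name"])
            for mod_name, mod_dict in sd["substructures"].items():
                subject.substructures[mod_name] = Modality.from_dict(mod_dict)
            for fname in sd["raw_files"]:
                subject.raw_files[fname] = zf.read(f"data/{subject.name}/{fname}")
            study.subjects.append(subject)
        study.workflow = [PluginInstance.from_dict(w) for w in manifest["workflow"]]
        study.provenance = [ProvenanceRecord.from_dict(p) for p in manifest["provenance"]]
        for plugin_id in manifest["plugin_ids"]:
            study.plugin_sources[plugin_id] = zf.read(_plugin_file(plugin_id)).decode()
        study.locked = manifest["locked"]
    return study


def register_bundle_plugins(
    study: Study, registry: PluginRegistry | None = None, namespace: str | None = None
) -> list[str]:
    """Register the study's plugin source snapshots under a bundle-specific
    namespace (``<namespace>/<plugin_id>``), shadowing nothing global.

    Returns the namespaced ids that were registered.  Sources whose declared
    id is already registered globally are still registered under the
    namespace, so two studies can safely ship different plugins of the same
    name.
    """
    registry = registry or default_registry
    namespace = namespace or f"bundle:{study.uwid or study.name}"
    registered = []
    for plugin_id, source in sorted(study.plugin_sources.items()):
        spaced = f"{namespace}/{plugin_id}"
        if spaced in registry:
            continue
        ns: dict = {}
        exec(compile(source, _plugin_file(plugin_id), "exec"), ns)
        declare = ns.get("declare")
        if declare is None:
            continue  # module-level snapshot of a built-in stage, not a single plugin

        def respaced_declare(_declare=declare, _spaced=spaced):
            spec = _declare()
            spec.plugin_id = _spaced
            return spec

        registry.register(
            respaced_declare, ns.get("configure"), ns.get("process"), source=source
        )
        registered.append(spaced)
    return registered
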