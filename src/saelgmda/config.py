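"""YAML run configuration, seed derivation and run manifests.

A single YAML file configures a whole run; unknown keys are rejected with a
closest-match suggestion so typos fail loudly instead of silently falling
back to defaults.  One global seed deterministically derives per-component
seeds by hashing the seed together with the component name, so components
never share RNG streams.
"""

from __future__ import annotations

import dataclasses
import difflib
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .autoencoder import SAEConfig
from .classifier import ClassifierConfig
from .evaluation import CvPlan
from .similarity import GipkConfig

__all__ = ["RunConfig", "validate_config", "derive_seed", "run_manifest",
           "validate_manifest", "ConfigError"]


class ConfigError(ValueError):
    """Aggregated configuration problems."""

    def __init__(self, problems: list):
        self.problems = list(problems)
        super().__init__("invalid configuration:\n" + "\n".join(
            f"  - {p}" for p in self.problems))


@dataclass(frozen=True)
class RunConfig:
    mda_path: str
    disease_genes_path: str | None = None
    gene_net_path: str | None = None
    microbe_sim_path: str | None = None
    gipk: GipkConfig = field(default_factory=GipkConfig)
    fusion_mode: str = "gipk_fallback"
    sae: SAEConfig = field(default_factory=SAEConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    cv: CvPlan = field(default_factory=CvPlan)
    similarity_scope: str = "masked"
    sae_scope: str = "train"
    out_dir: str = "."
    seed: int = 0


_SECTION_FIELDS = {
    "paths": {"mda", "disease_genes", "gene_net", "microbe_sim"},
    "gipk": {f.name for f in dataclasses.fields(GipkConfig)},
    "sae": {f.name for f in dataclasses.fields(SAEConfig)},
    "classifier": {f.name for f in dataclasses.fields(ClassifierConfig)},
    "cv": {f.name for f in dataclasses.fields(CvPlan)},
}
_TOP_KEYS = {"paths", "gipk", "fusion_mode", "sae", "classifier", "cv",
             "similarity_scope", "sae_scope", "out_dir", "seed"}


def _check_keys(given, allowed, context: str, problems: list) -> None:
    for key in given:
        if key not in allowed:
            near = difflib.get_close_matches(key, sorted(allowed), n=1)
            hint = f" (did you mean {near[0]!r}?)" if near else ""
            problems.append(f"{context}: unknown key {key!r}{hint}")


def validate_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Every problem found is reported at once in a single ``ConfigError``;
    omitted sections take the documented defaults.
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(["top level must be a mapping"])
    problems: list = []
    _check_keys(raw, _TOP_KEYS, "top level", problems)
    for section, allowed in _SECTION_FIELDS.items():
        sub = raw.get(section) or {}
        if not isinstance(sub, dict):
            problems.append(f"section {section!r} must be a mapping")
            continue
        _check_keys(sub, allowed, f"section {section!r}", problems)
    if problems:
        raise ConfigError(problems)

    paths = raw.get("paths") or {}
    if "mda" not in paths:
        problems.append("paths.mda is required")
    for key, value in paths.items():
        if value is not None and not Path(value).exists():
            problems.append(f"paths.{key}: file not found: {value}")

    def build(cls, section):
        sub = dict(raw.get(section) or {})
        if section == "sae" and "layer_sizes" in sub:
            sub["layer_sizes"] = tuple(sub["layer_sizes"])
        try:
            return cls(**sub)
        except (TypeError, ValueError) as exc:
            problems.append(f"section {section!r}: {exc}")
            return cls()

    gipk = build(GipkConfig, "gipk")
    sae = build(SAEConfig, "sae")
    clf = build(ClassifierConfig, "classifier")
    cv = build(CvPlan, "cv")
    for name, value, allowed in (
        ("fusion_mode", raw.get("fusion_mode", "gipk_fallback"),
         ("gipk_fallback", "paper_literal")),
        ("similarity_scope", raw.get("similarity_scope", "masked"),
         ("masked", "full")),
        ("sae_scope", raw.get("sae_scope", "train"), ("train", "full")),
    ):
        if value not in allowed:
            problems.append(f"{name}: must be one of {allowed}, got {value!r}")
    if problems:
        raise ConfigError(problems)
    return RunConfig(
        mda_path=paths["mda"],
        disease_genes_path=paths.get("disease_genes"),
        gene_net_path=paths.get("gene_net"),
        microbe_sim_path=paths.get("microbe_sim"),
        gipk=gipk,
        fusion_mode=raw.get("fusion_mode", "gipk_fallback"),
        sae=sae,
        classifier=clf,
        cv=cv,
        similarity_scope=raw.get("similarity_scope", "masked"),
        sae_scope=raw.get("sae_scope", "train"),
        out_dir=str(raw.get("out_dir", ".")),
        seed=int(raw.get("seed", 0)),
    )


def derive_seed(global_seed: int, component: str) -> int:
    """Deterministic per-component seed in [0, 2^31)."""
    digest = hashlib.sha256(f"{global_seed}:{component}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _config_hash(config) -> str:
    if dataclasses.is_dataclass(config):
        config = dataclasses.asdict(config)
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()


def _file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


MANIFEST_FIELDS = {
    "config_hash": str,
    "seed": int,
    "inputs": dict,
    "package_version": str,
}


def run_manifest(config, seed: int, input_paths: dict, out_path) -> dict:
    """Write a JSON manifest tying a run to its config, seed and inputs."""
    from . import __version__

    manifest = {
        "config_hash": _config_hash(config),
        "seed": int(seed),
        "inputs": {
            name: _file_sha256(p) for name, p in sorted(input_paths.items())
        },
        "package_version": __version__,
    }
    with open(out_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def validate_manifest(manifest: dict) -> None:
    """Check a manifest against the published field schema."""
    for name, typ in MANIFEST_FIELDS.items():
        if name not in manifest:
            raise ValueError(f"manifest missing field {name!r}")
        if not isinstance(manifest[name], typ):
            raise ValueError(
                f"manifest field {name!r} must be {typ.__name__}, "
                f"got {type(manifest[name]).__name__}"
            )
    for k, v in manifest["inputs"].items():
        if not (isinstance(k, str) and isinstance(v, str) and len(v) == 64):
            raise ValueError("manifest inputs must map names to sha256 hex digests")
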