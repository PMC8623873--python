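"""Shipped data files and configuration loading.

All parameter tables (pure-component PC-SAFT records, binary interactions,
mill/dryer designs) and every non-printed physical constant live in YAML
files under ``nanosusp/data``; user configs may override any block.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .pcsaft import BinaryInteractionSet, Mixture, PureComponentParams

__all__ = [
    "load_yaml",
    "data_path",
    "load_pure_components",
    "load_kij",
    "load_defaults",
    "load_mill_design",
    "load_dryer_runs",
    "build_mixture",
]


def data_path(name: str) -> Path:
    return Path(resources.files("nanosusp") / "data" / name)


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _deep_update(base: dict, extra: dict) -> dict:
    out = dict(base)
    for k, v in (extra or {}).items():
        out[k] = _deep_update(out[k], v) if isinstance(v, dict) and isinstance(out.get(k), dict) else v
    return out


def load_pure_components(path: str | Path | None = None,
                         apply_overrides: bool = True) -> dict:
    """Pure-component PC-SAFT records keyed by name.

    The shipped file keeps the published table verbatim under
    ``as_printed``; working values merge in the ``overrides`` (table-defect
    fixes) and ``supplements`` (fields the table does not print).
    """
    raw = load_yaml(path or data_path("pcsaft_pure.yaml"))
    merged = dict(raw["as_printed"])
    if apply_overrides:
        merged = _deep_update(merged, raw.get("overrides", {}))
    merged = _deep_update(merged, raw.get("supplements", {}))
    comps = {}
    for name, rec in merged.items():
        comps[name] = PureComponentParams(
            name=name, m=rec["m"], sigma=rec["sigma_A"], eps_k=rec["eps_k_K"],
            epsAB_k=rec.get("epsAB_k_K", 0.0), kappaAB=rec.get("kappaAB", 0.0),
            n_sites=rec.get("n_sites", 0), Mw=rec.get("Mw", 0.0))
    return comps


def load_assoc_pairs(path: str | Path | None = None) -> set:
    raw = load_yaml(path or data_path("pcsaft_pure.yaml"))
    return {tuple(p) for p in raw.get("assoc_pairs", [])}


def load_kij(path: str | Path | None = None) -> BinaryInteractionSet:
    raw = load_yaml(path or data_path("kij.yaml"))
    ks = BinaryInteractionSet()
    for entry in raw["kij"]:
        ks.set(entry["pair"][0], entry["pair"][1], entry["value"])
    return ks


def load_defaults(path: str | Path | None = None) -> dict:
    return load_yaml(path or data_path("defaults.yaml"))


def load_mill_design(path: str | Path | None = None) -> dict:
    return load_yaml(path or data_path("mill_design.yaml"))


def load_dryer_runs(path: str | Path | None = None) -> dict:
    return load_yaml(path or data_path("dryer_runs.yaml"))["runs"]


def build_mixture(names=("fenofibrate", "hpmc", "water"),
                  components: dict | None = None,
                  kij: BinaryInteractionSet | None = None,
                  assoc_pairs=None) -> Mixture:
    """Assemble the shipped ternary (or any sub-)mixture."""
    comps = components or load_pure_components()
    if assoc_pairs is None:
        pairs = load_assoc_pairs()
        assoc_pairs = {p for p in pairs if p[0] in names and p[1] in names}
    return Mixture([comps[n] for n in names], kij=kij or load_kij(),
                   assoc_pairs=assoc_pairs)
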