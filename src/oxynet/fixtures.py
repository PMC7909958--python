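"""Deterministic fixture generation: networks plus matching configs on disk."""

from __future__ import annotations

import json
from pathlib import Path

from . import __version__
from .network import (
    VesselNetwork,
    make_cobweb_2d,
    make_random_web,
    make_single_vessel_3d,
    write_network,
)
from .parameters import default_params, save_config

__all__ = ["FIXTURES", "build_fixture_network", "generate_fixture"]

#: name -> (builder, dim, domain length cm, physics overrides)
FIXTURES = {
    "single3d": ("single vessel in a 640 um cube", 3, 0.064, {"M0": 2.0e-3}),
    "cobweb2d": ("2D cobweb network", 2, 0.512, {}),
    "randomweb2d": ("random 2D capillary web", 2, 0.512, {}),
    "randomweb3d": ("random 3D capillary web", 3, 0.512, {}),
}


def build_fixture_network(name: str, seed: int = 0) -> VesselNetwork:
    if name == "single3d":
        return make_single_vessel_3d()
    if name == "cobweb2d":
        return make_cobweb_2d()
    if name == "randomweb2d":
        return make_random_web(dim=2, seed=seed)
    if name == "randomweb3d":
        return make_random_web(dim=3, seed=seed)
    raise ValueError(f"unknown fixture {name!r}; choose from {sorted(FIXTURES)}")


def generate_fixture(name: str, seed: int, outdir: str | Path) -> dict:
    """Write ``<name>.network.json`` and ``<name>.config.yaml`` under outdir.

    The single-vessel fixture raises the consumption ceiling to
    M0 = 2.0e-3 cm^3 O2/cm^3/s, the standard high-demand validation setting.
    Returns a manifest dict (also written alongside the files).
    """
    if name not in FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; choose from {sorted(FIXTURES)}")
    desc, dim, length, overrides = FIXTURES[name]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    net = build_fixture_network(name, seed)
    params = default_params().replace(**overrides)
    net_path = outdir / f"{name}.network.json"
    cfg_path = outdir / f"{name}.config.yaml"
    write_network(net, net_path)
    save_config(cfg_path, params, solver={"seed": seed})
    manifest = {
        "fixture": name,
        "description": desc,
        "dim": dim,
        "domain_cm": length,
        "seed": seed,
        "oxynet_version": __version__,
        "files": [net_path.name, cfg_path.name],
    }
    (outdir / f"{name}.manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
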