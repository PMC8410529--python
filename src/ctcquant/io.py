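"""Reading and writing the pipeline's on-disk formats.

Image fields travel as multichannel TIFF (one page per channel) with a
YAML sidecar naming the channel role of each page; tables are CSV;
gating configurations are YAML snapshots for audit.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
import yaml

from .core import CHANNEL_ROLES, ChannelStack
from .gating import GatingConfig

__all__ = [
    "write_stack",
    "read_stack",
    "write_gating_config",
    "read_gating_config",
]


def write_stack(stack: ChannelStack, tiff_path, roles_path=None) -> Path:
    """Write a ChannelStack as a multi-page TIFF plus a role sidecar.

    Pages follow the canonical role order (nuclear, caxii, ck,
    exclusion, biomarker) restricted to the roles present.  The sidecar
    (default: same stem with ``.roles.yaml``) lists the role of each
    page in order.
    """
    tiff_path = Path(tiff_path)
    roles = [r for r in CHANNEL_ROLES if r in stack] + [
        r for r in stack.roles if r not in CHANNEL_ROLES
    ]
    data = np.stack([stack[r] for r in roles]).astype(np.float32)
    tifffile.imwrite(tiff_path, data, photometric="minisblack")
    if roles_path is None:
        roles_path = tiff_path.with_suffix("").with_suffix(".roles.yaml")
    with open(roles_path, "w") as fh:
        yaml.safe_dump({"channels": roles}, fh)
    return tiff_path


def read_stack(tiff_path, roles_path=None) -> ChannelStack:
    """Read a multi-page TIFF and its channel-role sidecar."""
    tiff_path = Path(tiff_path)
    if roles_path is None:
        roles_path = tiff_path.with_suffix("").with_suffix(".roles.yaml")
    with open(roles_path) as fh:
        meta = yaml.safe_load(fh)
    roles = meta["channels"]
    data = tifffile.imread(tiff_path)
    if data.ndim == 2:
        data = data[None]
    if len(roles) != data.shape[0]:
        raise ValueError(
            f"sidecar lists {len(roles)} channels but TIFF has {data.shape[0]} pages"
        )
    return ChannelStack({role: data[i].astype(float) for i, role in enumerate(roles)})


def write_gating_config(config: GatingConfig, path) -> Path:
    path = Path(path)
    payload = {
        "cutoffs": {k: float(v) for k, v in config.cutoffs.items()},
        "method": config.method,
        "rules_version": config.rules_version,
        "scope": config.scope,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh)
    return path


def read_gating_config(path) -> GatingConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return GatingConfig(
        cutoffs={k: float(v) for k, v in payload["cutoffs"].items()},
        method=payload.get("method", "cluster"),
        rules_version=payload.get("rules_version", "exclusion-caxii-ck-v1"),
        scope=payload.get("scope", "per_sample"),
    )
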