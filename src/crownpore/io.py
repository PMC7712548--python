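"""Plain-text file formats: free-energy profiles, rate/report tables and
run manifests.

Profiles are 3-column delimited text (z_nm, F_kBT, SE_kBT) with '#'-prefixed
``key: value`` metadata header lines; everything else is CSV with '#'
comments or JSON.  All formats round-trip losslessly.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import numpy as np

from .landscape import FreeEnergyProfile


def write_profile(profile: FreeEnergyProfile, path: str | Path) -> None:
    path = Path(path)
    lines = []
    for k, v in profile.metadata.items():
        lines.append(f"# {k}: {v}")
    lines.append("# columns: z_nm F_kBT SE_kBT")
    se = profile.se if profile.se is not None else np.full_like(profile.z, np.nan)
    for z, f, s in zip(profile.z, profile.F, se):
        lines.append(f"{z:.17g} {f:.17g} {s:.17g}")
    path.write_text("\n".join(lines) + "\n")


def read_profile(path: str | Path) -> FreeEnergyProfile:
    meta: dict = {}
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if ":" in body:
                k, v = body.split(":", 1)
                k, v = k.strip(), v.strip()
                if k != "columns":
                    try:
                        meta[k] = float(v)
                    except ValueError:
                        meta[k] = v
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"malformed profile line: {line!r}")
        rows.append([float(p) for p in parts[:3]])
    arr = np.array(rows)
    se = arr[:, 2] if arr.shape[1] > 2 and not np.all(np.isnan(arr[:, 2])) else None
    return FreeEnergyProfile(z=arr[:, 0], F=arr[:, 1], se=se, metadata=meta)


@dataclass
class RunManifest:
    """Provenance record written next to every CLI output."""

    subcommand: str
    seed: Optional[int] = None
    config_path: Optional[str] = None
    inputs: list = field(default_factory=list)
    outputs: list = field(default_factory=list)
    package_version: str = ""
    timestamp: str = ""
    platform: str = ""

    def __post_init__(self):
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()
        if not self.platform:
            self.platform = platform.platform()
        if not self.package_version:
            from . import __version__
            self.package_version = __version__

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
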