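"""Report writing: delimited tables and JSON with reproducibility metadata.

Every output carries the config hash, seed and package version so a rerun
with the same configuration reproduces it byte for byte.  No timestamps.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import __version__


def metadata_lines(config, extra: dict | None = None) -> list[str]:
    meta = {"config_hash": config.digest(), "seed": config.seed,
            "scenario": config.scenario, "overlay_mode": config.overlay_mode,
            "rrr": config.rrr, "version": __version__}
    meta.update(extra or {})
    return [f"# {key} = {value}" for key, value in meta.items()]


def write_table(frame: pd.DataFrame, path: Path, config, extra: dict | None = None):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in metadata_lines(config, extra):
            fh.write(line + "\n")
        frame.to_csv(fh, index=False, float_format="%.10g")


def write_json(payload: dict, path: Path, config, extra: dict | None = None):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": config.digest(), "seed": config.seed,
            "scenario": config.scenario, "overlay_mode": config.overlay_mode,
            "rrr": config.rrr, "version": __version__}
    meta.update(extra or {})
    with open(path, "w") as fh:
        json.dump({"metadata": meta, **payload}, fh, indent=1, sort_keys=True)
        fh.write("\n")
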