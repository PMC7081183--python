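"""Plain-text I/O for force curves and fit results.

Force curves travel as tab-separated text with a header line and columns
``z_nm`` and ``d_nm``, one file per curve, with probe metadata in a
sidecar JSON (``k_N_per_m``, ``r_tip_nm``, ``label``, ``condition``).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .afm import ForceCurve, HertzFit, ModulusRatio

__all__ = ["write_force_curve", "read_force_curve", "write_fits",
           "read_fits", "write_ratio"]


def write_force_curve(curve: ForceCurve, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame({"z_nm": curve.z, "d_nm": curve.d}).to_csv(
        path, sep="\t", index=False)
    meta = {"k_N_per_m": curve.k, "r_tip_nm": curve.r_tip,
            "label": curve.label, "condition": curve.condition}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(meta, indent=1))


def read_force_curve(path: str | Path) -> ForceCurve:
    path = Path(path)
    tab = pd.read_csv(path, sep="\t")
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return ForceCurve(z=tab["z_nm"].to_numpy(), d=tab["d_nm"].to_numpy(),
                      k=float(meta["k_N_per_m"]),
                      r_tip=float(meta["r_tip_nm"]),
                      label=meta.get("label", ""),
                      condition=meta.get("condition", ""))


def write_fits(fits: list[HertzFit], path: str | Path) -> None:
    Path(path).write_text(json.dumps(
        [dataclasses.asdict(f) for f in fits], indent=1, default=float))


def read_fits(path: str | Path) -> list[HertzFit]:
    raw = json.loads(Path(path).read_text())
    return [HertzFit(E=r["E"], nu=r["nu"],
                     fit_window=tuple(r["fit_window"]), rss=r["rss"],
                     n_points=r["n_points"], valid=r["valid"],
                     label=r.get("label", "")) for r in raw]


def write_ratio(ratio: ModulusRatio, path: str | Path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(ratio), indent=1))
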