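"""Result aggregation and report assembly.

``summarize`` turns the per-run results table (method, noise_std, seed,
accuracy, aece) into the familiar methods-by-noise-level summary: each cell
shows "accuracy% +/- std, AECE +/- std", accuracy in percent with one
decimal and AECE with three (round-half-even).  ``RunManifest`` records
what a CLI run consumed and produced so it can be reproduced.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__

__all__ = ["RunManifest", "summarize", "format_cell"]


def format_cell(acc_mean, acc_std, aece_mean, aece_std) -> str:
    """'62.0 ± 0.0, 0.010 ± 0.000' — accuracy in percent (1 dp), AECE 3 dp."""
    return (
        f"{acc_mean * 100:.1f} ± {acc_std * 100:.1f}, "
        f"{aece_mean:.3f} ± {aece_std:.3f}"
    )


def summarize(results: pd.DataFrame | str | Path) -> tuple[str, pd.DataFrame]:
    """Aggregate per-run records into a methods x noise-levels table.

    Returns (plain-text table, cell DataFrame).  Cells are recomputed from
    the raw records; a missing (method, level) combination renders as an
    em dash with a warning.  Row order is sorted by method name and the
    result is independent of the input row order.
    """
    if not isinstance(results, pd.DataFrame):
        results = pd.read_csv(results)
    required = {"method", "noise_std", "accuracy", "aece"}
    missing = required - set(results.columns)
    if missing:
        raise ValueError(f"results table missing columns: {sorted(missing)}")
    methods = sorted(results["method"].unique())
    levels = sorted(results["noise_std"].unique())
    cells = pd.DataFrame(index=methods, columns=[f"noise={lv:g}" for lv in levels], dtype=object)
    for m in methods:
        for lv in levels:
            sub = results[(results["method"] == m) & (results["noise_std"] == lv)]
            if len(sub) == 0:
                warnings.warn(f"no runs for method={m}, noise={lv:g}", stacklevel=2)
                cells.loc[m, f"noise={lv:g}"] = "—"
                continue
            cells.loc[m, f"noise={lv:g}"] = format_cell(
                sub["accuracy"].mean(),
                sub["accuracy"].std(ddof=0),
                sub["aece"].mean(),
                sub["aece"].std(ddof=0),
            )
    widths = [max(len(str(m)) for m in methods + ["method"])] + [
        max(cells[c].map(len).max(), len(c)) for c in cells.columns
    ]
    header = "  ".join(
        s.ljust(w) for s, w in zip(["method"] + list(cells.columns), widths)
    )
    lines = [header, "-" * len(header)]
    for m in methods:
        lines.append(
            "  ".join(
                s.ljust(w)
                for s, w in zip([m] + [cells.loc[m, c] for c in cells.columns], widths)
            )
        )
    return "\n".join(lines), cells


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record for one CLI run."""

    command: str
    config: dict
    input_hashes: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    tool_version: str = __version__
    started: str = ""
    finished: str = ""

    def start(self):
        self.started = datetime.now(timezone.utc).isoformat()
        return self

    def hash_input(self, path: str | Path):
        path = Path(path)
        if path.is_file():
            self.input_hashes[str(path)] = _sha256(path)
        return self

    def add_output(self, path: str | Path):
        self.outputs.append(str(path))
        return self

    def finish(self, out_dir: str | Path) -> Path:
        self.finished = datetime.now(timezone.utc).isoformat()
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / "manifest.json"
        def _default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(type(o))
        path.write_text(json.dumps(vars(self), indent=2, default=_default))
        return path
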