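"""Human-readable traffic-light reports and run manifests."""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cbd_core import binarize, cbd, ranks_from_categories
from .partition import CategoryMatrix

__all__ = ["render_traffic_light", "write_manifest"]

_LETTER = {2: "G", 1: "Y", 0: "R", -1: ""}


def render_traffic_light(
    v_cat: CategoryMatrix,
    s_cat: CategoryMatrix,
    path: str | Path,
    html: bool = False,
) -> pd.DataFrame:
    """Side-by-side G/Y/R grid with a per-compound distance column.

    For each target two columns are written (``<target>_vitro``,
    ``<target>_silico``) followed by the compound's ternary CBD over the
    paired entries. CSV is the canonical output; ``html=True`` additionally
    writes a color-celled HTML file next to it.
    """
    if (
        v_cat.compound_ids != s_cat.compound_ids
        or v_cat.target_ids != s_cat.target_ids
    ):
        raise ValueError("traffic-light report requires aligned category matrices")
    res = cbd(ranks_from_categories(v_cat, 2), ranks_from_categories(s_cat, 2))
    data: dict[str, list] = {"compound_id": list(v_cat.compound_ids)}
    for j, t in enumerate(v_cat.target_ids):
        data[f"{t}_vitro"] = [_LETTER[int(c)] for c in v_cat.codes[:, j]]
        data[f"{t}_silico"] = [_LETTER[int(c)] for c in s_cat.codes[:, j]]
    data["distance"] = res.per_compound.tolist()
    df = pd.DataFrame(data)
    path = Path(path)
    df.to_csv(path, index=False)
    if html:
        _write_html(df, path.with_suffix(".html"))
    return df


_COLORS = {"G": "#2e9e4f", "Y": "#e0c030", "R": "#cc3b3b", "": "#ffffff"}


def _write_html(df: pd.DataFrame, path: Path) -> None:
    rows = []
    for _, row in df.iterrows():
        cells = []
        for col, val in row.items():
            if col.endswith("_vitro") or col.endswith("_silico"):
                cells.append(
                    f'<td style="background:{_COLORS.get(str(val), "#fff")}">{val}</td>'
                )
            else:
                cells.append(f"<td>{val}</td>")
        rows.append("<tr>" + "".join(cells) + "</tr>")
    header = "".join(f"<th>{c}</th>" for c in df.columns)
    path.write_text(
        "<table border='1'><thead><tr>"
        + header
        + "</tr></thead><tbody>"
        + "".join(rows)
        + "</tbody></table>",
        encoding="utf-8",
    )


def write_manifest(out_dir: str | Path, command: str, params: dict) -> Path:
    """Record inputs, effective parameters and tool version for a run."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "tool": "cbdeval",
        "version": __version__,
        "command": command,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "parameters": _jsonable(params),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    if hasattr(obj, "value") and not isinstance(obj, (int, float, str, bool)):
        return obj.value
    return obj
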