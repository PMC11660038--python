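"""Text-format readers and writers.

Three dialects, matching what the instruments/analysis tools emit:

* titration CSV — two columns ``conc,response``, header required, ``#``
  comments; technique and units come from flags/config, never sniffed;
* SAXS ``.dat`` — whitespace- or comma-separated ``q I sigma`` (3 columns)
  or ``q I`` (2 columns, sigma synthesized as 2% of I with a floor);
* xvg-style trace — two columns ``t value``, lines starting with ``@`` or
  ``#`` skipped (the de facto MD analysis output dialect).

Every writer emits exactly the dialect its reader consumes; generators'
truth sidecars are plain JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .md_postproc import TimeSeriesTrace
from .saxs_model import SAXSCurve
from .titration import TitrationSeries

__all__ = [
    "read_titration_csv",
    "write_titration_csv",
    "read_saxs_dat",
    "write_saxs_dat",
    "read_xvg",
    "write_xvg",
    "read_truth",
    "write_truth",
    "load_config",
]


def read_titration_csv(
    path, technique: str, conc_unit: str = "wt%", response_unit: str = ""
) -> TitrationSeries:
    """Read a 2-column ``conc,response`` CSV (header required, # comments)."""
    df = pd.read_csv(path, comment="#")
    cols = [c.strip().lower() for c in df.columns]
    if cols[:2] != ["conc", "response"]:
        raise ValueError(
            f"{path}: expected header 'conc,response', got {list(df.columns)!r}"
        )
    return TitrationSeries(
        technique=technique,
        conc=df.iloc[:, 0].to_numpy(float),
        response=df.iloc[:, 1].to_numpy(float),
        conc_unit=conc_unit,
        response_unit=response_unit,
    )


def write_titration_csv(path, series: TitrationSeries) -> None:
    with open(path, "w") as fh:
        fh.write(f"# technique: {series.technique}\n")
        fh.write(f"# conc_unit: {series.conc_unit}\n")
        fh.write("conc,response\n")
        for c, r in zip(series.conc, series.response):
            fh.write(f"{c:.10g},{r:.10g}\n")


def read_saxs_dat(path, sigma_frac: float = 0.02) -> SAXSCurve:
    """Read a 2- or 3-column (q, I[, sigma]) text file.

    Accepts whitespace or comma separation and ``#`` comments.  With only
    two columns, sigma is synthesized as ``sigma_frac * |I|`` floored at
    1e-4 of the maximum intensity (so near-zero-intensity points cannot
    dominate a weighted fit).
    """
    df = pd.read_csv(path, comment="#", sep=r"[,\s]+", engine="python", header=None)
    df = df.dropna(axis=1, how="all")
    arr = df.to_numpy(float)
    if arr.shape[1] == 2:
        q, I = arr[:, 0], arr[:, 1]
        sigma = np.maximum(sigma_frac * np.abs(I), 1e-4 * np.abs(I).max())
    elif arr.shape[1] >= 3:
        q, I, sigma = arr[:, 0], arr[:, 1], arr[:, 2]
    else:
        raise ValueError(f"{path}: expected 2 or 3 columns, got {arr.shape[1]}")
    return SAXSCurve(q=q, I=I, sigma=sigma)


def write_saxs_dat(path, curve: SAXSCurve) -> None:
    with open(path, "w") as fh:
        fh.write("# q[A^-1]  I[cm^-1]  sigma[cm^-1]\n")
        sig = curve.sigma
        if sig is None:
            sig = np.zeros_like(curve.q)
        for q, I, s in zip(curve.q, curve.I, sig):
            fh.write(f"{q:.8e}  {I:.8e}  {s:.8e}\n")


def read_xvg(path, observable: str = "sasa") -> TimeSeriesTrace:
    """Read an xvg-style 2-column trace, skipping ``@`` and ``#`` lines."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("@", "#")):
                continue
            parts = line.split()
            rows.append((float(parts[0]), float(parts[1])))
    if not rows:
        raise ValueError(f"{path}: no data rows")
    arr = np.array(rows)
    return TimeSeriesTrace(t=arr[:, 0], value=arr[:, 1], observable=observable)


def write_xvg(path, trace: TimeSeriesTrace) -> None:
    with open(path, "w") as fh:
        fh.write(f'@    title "{trace.observable}"\n')
        fh.write('@    xaxis label "t (ns)"\n')
        for t, v in zip(trace.t, trace.value):
            fh.write(f"{t:.8g}  {v:.8g}\n")


def write_truth(path, truth: dict) -> None:
    Path(path).write_text(json.dumps(truth, indent=1, sort_keys=True) + "\n")


def read_truth(path) -> dict:
    return json.loads(Path(path).read_text())


def load_config(path) -> dict:
    """Load a flat YAML or JSON analysis config."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    import yaml

    return yaml.safe_load(text)
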