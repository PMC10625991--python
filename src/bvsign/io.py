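"""Reading bivariate tables and serializing results."""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scores import BivariateSample

__all__ = ["read_bivariate_table", "write_bivariate_table", "ResultEnvelope"]


def read_bivariate_table(
    path,
    delimiter: str | None = None,
    header: bool = True,
    column_pair: tuple[int, int] = (0, 1),
) -> BivariateSample:
    """Read a CSV/TSV file of paired numeric observations.

    Parameters
    ----------
    path : str or Path
        File to read.
    delimiter : str, optional
        Field delimiter; inferred from the extension when omitted
        (``.tsv``/``.txt`` -> tab, otherwise comma).
    header : bool
        Whether the first row is a header line.
    column_pair : (int, int)
        Zero-based indices of the (x, y) columns.

    Rows with missing or non-numeric cells are rejected with their row
    numbers; zero-vector rows are rejected by the sample constructor.
    """
    if delimiter is None:
        delimiter = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(
        path, sep=delimiter, header=0 if header else None, float_precision="round_trip"
    )
    i, j = column_pair
    ncols = df.shape[1]
    if max(i, j) >= ncols:
        raise ValueError(f"column_pair {column_pair} out of range for a {ncols}-column file")
    sub = df.iloc[:, [i, j]].apply(pd.to_numeric, errors="coerce")
    bad = sub.isna().any(axis=1)
    if bad.any():
        rows = (np.flatnonzero(bad.to_numpy()) + 1 + int(header)).tolist()
        raise ValueError(f"missing or non-numeric cells in file row(s) {rows}")
    return BivariateSample(points=sub.to_numpy(dtype=float))


def write_bivariate_table(sample: BivariateSample, path, delimiter: str = ",") -> None:
    """Write a sample as a two-column table with an ``x,y`` header."""
    pd.DataFrame(sample.points, columns=["x", "y"]).to_csv(
        path, sep=delimiter, index=False, float_format="%.17g"
    )


@dataclass(frozen=True)
class ResultEnvelope:
    """JSON-serializable record of one mid-p computation."""

    test: str
    method: str
    tail_convention: str | None
    n: int
    statistic: tuple[float, float]
    mid_p: float
    se: float | None = None
    diagnostics: tuple[str, ...] = ()
    seed: int | None = None
    timestamp: str = field(
        default_factory=lambda: _dt.datetime.now(_dt.timezone.utc).isoformat()
    )

    def to_json(self, **kwargs) -> str:
        d = {
            "test": self.test,
            "method": self.method,
            "tail_convention": self.tail_convention,
            "n": self.n,
            "statistic": [repr_float(v) for v in self.statistic],
            "mid_p": repr_float(self.mid_p),
            "se": None if self.se is None else repr_float(self.se),
            "diagnostics": list(self.diagnostics),
            "seed": self.seed,
            "timestamp": self.timestamp,
        }
        return json.dumps(d, **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "ResultEnvelope":
        d = json.loads(text)
        return cls(
            test=d["test"],
            method=d["method"],
            tail_convention=d["tail_convention"],
            n=d["n"],
            statistic=tuple(float(v) for v in d["statistic"]),
            mid_p=float(d["mid_p"]),
            se=None if d["se"] is None else float(d["se"]),
            diagnostics=tuple(d["diagnostics"]),
            seed=d["seed"],
            timestamp=d["timestamp"],
        )


def repr_float(v: float) -> float:
    """Round-trip-safe float (17 significant digits survive JSON)."""
    return float(np.float64(v))
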