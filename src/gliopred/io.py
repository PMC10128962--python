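"""Reading and writing follow-up tables, and the packaged reference cohort.

Follow-ups travel as plain CSV with a mandatory header
``patient_id,time_years,radius_mm`` (comma-separated, dot decimal, UTF-8).
Times in months are accepted by passing ``time_unit="months"``; they are
converted on read (1 month = 1/12 year).

``table1_ensemble`` returns the packaged 20-patient reference cohort of
best-fit parameters (and tabulated regrowth times) used to build the
default prior.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, List, Union

import pandas as pd

from .model import EnsembleEntry, FollowUp, ModelParams, ParamEnsemble

__all__ = [
    "ParseError",
    "read_followups",
    "write_followups",
    "read_param_table",
    "table1_ensemble",
]

REQUIRED_COLUMNS = ("patient_id", "time_years", "radius_mm")


class ParseError(ValueError):
    """A malformed row or header in a follow-up file."""


def read_followups(
    path: Union[str, Path],
    time_unit: str = "years",
    sigma: float = 1.0,
) -> List[FollowUp]:
    """Read a follow-up CSV, grouped by patient and sorted by time.

    Raises :class:`ParseError` with the 1-based file line number on a
    malformed row, and ``ValueError`` naming the patient on duplicate
    measurement times.
    """
    if time_unit not in ("years", "months"):
        raise ValueError(f"time_unit must be 'years' or 'months', got {time_unit!r}")
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}; header row required")
    for col in ("time_years", "radius_mm"):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[values.isna() | df[col].isna()]
        if len(bad):
            line = int(bad[0]) + 2  # +1 header, +1 one-based
            raise ParseError(f"{path}:{line}: malformed value in column {col!r}")
        df[col] = values
    if df["patient_id"].isna().any():
        line = int(df.index[df["patient_id"].isna()][0]) + 2
        raise ParseError(f"{path}:{line}: missing patient_id")
    scale = 1.0 / 12.0 if time_unit == "months" else 1.0
    out: List[FollowUp] = []
    for pid, grp in df.groupby("patient_id", sort=True):
        grp = grp.sort_values("time_years", kind="stable")
        t = grp["time_years"].to_numpy() * scale
        r = grp["radius_mm"].to_numpy()
        if len(t) > 1 and (t[1:] <= t[:-1]).any():
            raise ValueError(f"patient {pid!r}: duplicate measurement times")
        out.append(FollowUp(str(pid), tuple(zip(t, r)), sigma=sigma))
    return out


def write_followups(followups: Iterable[FollowUp], path: Union[str, Path]) -> None:
    """Write follow-ups as CSV (inverse of :func:`read_followups`)."""
    rows = [
        {"patient_id": fu.patient_id, "time_years": t, "radius_mm": r}
        for fu in followups
        for t, r in fu.measurements
    ]
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)).to_csv(path, index=False)


def read_param_table(path: Union[str, Path]) -> ParamEnsemble:
    """Read a fitted-parameter table (CSV with columns patient_id, R0_mm,
    v_mm_per_yr, k_mm, tau_yr and optionally tmin_yr)."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    needed = ["patient_id", "R0_mm", "v_mm_per_yr", "k_mm", "tau_yr"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    entries = []
    for _, row in df.iterrows():
        params = ModelParams(
            float(row["R0_mm"]), float(row["v_mm_per_yr"]),
            float(row["k_mm"]), float(row["tau_yr"]),
        )
        t_min = float(row["tmin_yr"]) if "tmin_yr" in df.columns else None
        entries.append(EnsembleEntry(str(row["patient_id"]), params, t_min))
    return ParamEnsemble(tuple(entries))


@lru_cache(maxsize=1)
def table1_ensemble() -> ParamEnsemble:
    """The packaged 20-patient reference ensemble of best-fit parameters.

    Parameters are tabulated at 2 decimals; the tabulated regrowth time of
    each entry is carried alongside. Immutable and identical across calls.
    """
    with resources.as_file(
        resources.files("gliopred").joinpath("data/table1_bestfits.csv")
    ) as p:
        return read_param_table(p)
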