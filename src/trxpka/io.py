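"""File formats, report tables and display formatting.

Titration tables and replicate tables are delimited text read through
pandas; sequences are FASTA via Biopython.  Report writers emit full
repr-precision numbers plus separate display-rounded columns (rounding half
away from zero, matching the conventions "10.6 ± 0.2 (7)" for aggregated
pKas and "20,301 ± 2581 (7%)" for replicate summaries), so exact
reproduction never depends on rounding.
"""

from __future__ import annotations

import json
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .activity import RelativeActivity, ReplicateSummary
from .fitting import PkaEstimate, TitrationFit, TitrationSeries
from .motifs import Classification, ExtendedSiteRecord, SequenceRecord

__all__ = [
    "read_titration_table",
    "write_titration_table",
    "read_replicate_table",
    "read_fasta",
    "write_fasta",
    "read_config",
    "round_half_away",
    "format_pka_estimate",
    "format_replicate_summary",
    "format_relative_activity",
    "fit_report",
    "activity_report",
    "motif_report",
    "write_report",
]

TITRATION_COLUMNS = ["resonance_id", "nucleus", "ph", "shift_ppm"]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (display convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def read_titration_table(path: Union[str, Path]) -> list[TitrationSeries]:
    """Read a delimited titration table into per-resonance series.

    Expected header: resonance_id, nucleus, ph, shift_ppm, with an optional
    oxidation_state column.  Rows are grouped by (resonance_id, nucleus,
    oxidation_state) and sorted by pH; duplicate pH values within a series
    are retained as repeated measurements.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: empty titration table")
    missing = [c for c in TITRATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in ("ph", "shift_ppm"):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[values.isna() | ~np.isfinite(values)]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise ValueError(
                f"{path}: non-numeric {col} value at row {int(bad[0]) + 2}"
            )
        df[col] = values
    if "oxidation_state" not in df.columns:
        df["oxidation_state"] = ""
    df["oxidation_state"] = df["oxidation_state"].fillna("")
    series = []
    for (rid, nuc, ox), grp in df.groupby(
        ["resonance_id", "nucleus", "oxidation_state"], sort=True
    ):
        series.append(
            TitrationSeries(
                residue_label=str(rid),
                nucleus_label=str(nuc),
                ph=grp["ph"].to_numpy(),
                shift=grp["shift_ppm"].to_numpy(),
                oxidation_state_label=str(ox),
            )
        )
    return series


def write_titration_table(
    series: Sequence[TitrationSeries], path: Union[str, Path]
) -> None:
    """Write series to the delimited format :func:`read_titration_table` reads."""
    rows = []
    for s in series:
        for ph, shift in zip(s.ph, s.shift):
            rows.append(
                {
                    "resonance_id": s.residue_label,
                    "nucleus": s.nucleus_label,
                    "ph": repr(float(ph)),
                    "shift_ppm": repr(float(shift)),
                    "oxidation_state": s.oxidation_state_label,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_replicate_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a construct/dataset/reading replicate table."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ("construct", "dataset", "reading") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    values = pd.to_numeric(df["reading"], errors="coerce")
    bad = df.index[values.isna()]
    if len(bad):
        raise ValueError(f"{path}: non-numeric reading at row {int(bad[0]) + 2}")
    df["reading"] = values
    df["dataset"] = df["dataset"].astype(str)
    return df


def read_fasta(path: Union[str, Path]) -> list[SequenceRecord]:
    """Read protein sequences from FASTA (upper-cased)."""
    return [
        SequenceRecord(id=rec.id, residues=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Iterable[SequenceRecord], path: Union[str, Path]) -> None:
    SeqIO.write(
        [BioSeqRecord(Seq(r.residues), id=r.id, description="") for r in records],
        str(path),
        "fasta",
    )


def read_config(path: Union[str, Path]) -> dict[str, str]:
    """Parse a plain-text key = value config file ('#' starts a comment)."""
    out: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def format_pka_estimate(est: PkaEstimate) -> str:
    """Render an aggregate as "mean ± sd (n)", e.g. "10.6 ± 0.2 (7)"."""
    mean = f"{round_half_away(est.mean_pka, 1):.1f}"
    if est.sd_pka is None:
        return f"{mean} (n=1, sd undefined)"
    return f"{mean} ± {round_half_away(est.sd_pka, 1):.1f} ({est.n_resonances})"


def format_replicate_summary(s: ReplicateSummary) -> str:
    """Render as "20,301 ± 2581 (7%)" (mean comma-grouped, integers)."""
    mean = f"{int(round_half_away(s.mean)):,}"
    return f"{mean} ± {int(round_half_away(s.sd))} ({int(round_half_away(s.pct_se))}%)"


def format_relative_activity(r: RelativeActivity) -> str:
    """Render as "77 ± 11"."""
    return f"{int(round_half_away(r.percent))} ± {int(round_half_away(r.uncertainty))}"


def fit_report(
    fits: Sequence[TitrationFit],
    estimates: Sequence[tuple[str, PkaEstimate]] = (),
) -> pd.DataFrame:
    """Tabulate per-series fits (one row each) plus optional aggregates.

    Failed fits should be represented upstream; every row here is a
    converged fit.  Aggregates are (label, estimate) pairs appended as
    summary rows with the display string.
    """
    rows = []
    for f in fits:
        row = {
            "row_kind": "fit",
            "residue": f.series.residue_label if f.series else "",
            "nucleus": f.series.nucleus_label if f.series else "",
            "model": f.model_kind,
            "rss": f.rss,
            "dof": f.dof,
            "converged": f.converged,
            "extrapolated": f.extrapolated,
            "non_identifiable": f.non_identifiable,
        }
        pkas = f.pka_values
        row["pka1"] = pkas[0]
        row["pka2"] = pkas[1] if len(pkas) > 1 else np.nan
        row["stderr_pka1"] = f.stderr_pka[0] if f.stderr_pka[0] is not None else np.nan
        row["stderr_pka2"] = (
            f.stderr_pka[1]
            if len(f.stderr_pka) > 1 and f.stderr_pka[1] is not None
            else np.nan
        )
        row["display"] = ""
        rows.append(row)
    for label, est in estimates:
        rows.append(
            {
                "row_kind": "aggregate",
                "residue": label,
                "nucleus": "",
                "model": "",
                "rss": np.nan,
                "dof": est.n_resonances,
                "converged": True,
                "extrapolated": False,
                "non_identifiable": False,
                "pka1": est.mean_pka,
                "pka2": np.nan,
                "stderr_pka1": est.sd_pka if est.sd_pka is not None else np.nan,
                "stderr_pka2": np.nan,
                "display": format_pka_estimate(est),
            }
        )
    columns = [
        "row_kind", "residue", "nucleus", "model", "rss", "dof", "converged",
        "extrapolated", "non_identifiable", "pka1", "pka2", "stderr_pka1",
        "stderr_pka2", "display",
    ]
    return pd.DataFrame(rows, columns=columns)


def activity_report(
    summaries: Sequence[ReplicateSummary],
    activities: Sequence[RelativeActivity],
) -> pd.DataFrame:
    """Tabulate replicate summaries and relative activities with display columns."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "row_kind": "summary",
                "construct": s.construct_label,
                "dataset": s.dataset_label,
                "mean": s.mean,
                "sd": s.sd,
                "pct_se": s.pct_se,
                "n": s.n,
                "percent": np.nan,
                "uncertainty": np.nan,
                "display": format_replicate_summary(s),
            }
        )
    for a in activities:
        rows.append(
            {
                "row_kind": f"relative_{a.level}",
                "construct": a.construct_label,
                "dataset": a.dataset_label,
                "mean": np.nan,
                "sd": np.nan,
                "pct_se": np.nan,
                "n": 0,
                "percent": a.percent,
                "uncertainty": a.uncertainty,
                "display": format_relative_activity(a),
            }
        )
    columns = [
        "row_kind", "construct", "dataset", "mean", "sd", "pct_se", "n",
        "percent", "uncertainty", "display",
    ]
    return pd.DataFrame(rows, columns=columns)


def motif_report(
    records: Sequence[ExtendedSiteRecord],
    classifications: Sequence[Classification],
) -> pd.DataFrame:
    """Tabulate extracted extended-site records and their classes.

    Positions are reported 1-based; missing slots are empty strings.
    """
    if len(records) != len(classifications):
        raise ValueError("records and classifications must align")
    rows = []
    for rec, cls in zip(records, classifications):
        rows.append(
            {
                "sequence_id": rec.sequence_id,
                "cys_n_pos_1based": rec.cys_n_pos + 1,
                "xx_residues": rec.xx_residues,
                "beta1_minus6": rec.beta1_minus6 or "",
                "alpha1_acidic": rec.alpha1_acidic or "",
                "distal_partner": rec.distal_partner[0] if rec.distal_partner else "",
                "distal_partner_offset": (
                    rec.distal_partner[1] if rec.distal_partner else ""
                ),
                "rule": cls.rule,
                "class": cls.label,
                "trace": " | ".join(cls.trace),
            }
        )
    columns = [
        "sequence_id", "cys_n_pos_1based", "xx_residues", "beta1_minus6",
        "alpha1_acidic", "distal_partner", "distal_partner_offset", "rule",
        "class", "trace",
    ]
    return pd.DataFrame(rows, columns=columns)


def write_report(
    df: pd.DataFrame, path: Union[str, Path], format: str = "csv"
) -> None:
    """Write a report table as CSV or JSON (records orientation).

    Column order is preserved as built (deterministic); an empty table still
    produces a valid file with a header.
    """
    path = Path(path)
    if format == "csv":
        df.to_csv(path, index=False)
    elif format == "json":
        path.write_text(json.dumps(df.to_dict(orient="records"), indent=2, default=str))
    else:
        raise ValueError(f"unknown report format {format!r}")
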