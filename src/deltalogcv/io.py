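"""Data ingestion, fixture generation and report formatting.

Two CSV layouts are accepted:

* long format — columns ``group,value``; one row per observation, ``value``
  >= 0 and exactly 0 for a zero (e.g. a dry day).  Only literal zeros count
  as zeros; trace positives (0.1 mm) belong to the lognormal part.
* summary format — columns ``group,n,n1,mu_hat,sigma2_hat`` (``n1`` may be
  replaced by ``delta_hat``), one row per population, as printed in reports.
"""

from __future__ import annotations

import io as _io
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .distribution import DeltaLNParams, IntervalEstimate, SampleSummary, summarize

logger = logging.getLogger(__name__)

LONG_COLUMNS = {"group", "value"}
SUMMARY_COLUMNS = {"group", "n", "mu_hat", "sigma2_hat"}


@dataclass(frozen=True)
class AnalysisReport:
    """Everything one analysis run produced, plus provenance."""

    summaries: list[SampleSummary]
    point_estimate: float
    intervals: list[IntervalEstimate]
    level: float
    draws: int
    seed: int | None
    version: str = field(default=__version__)

    def anomalous_intervals(self) -> list[IntervalEstimate]:
        """Intervals that fail to bracket the point estimate (should be none)."""
        return [iv for iv in self.intervals if not iv.contains(self.point_estimate)]


def read_groups(path, format: str = "auto") -> list[SampleSummary]:
    """Read per-population summaries from a long or summary CSV.

    Rows with missing values are dropped (with a logged count); negative
    values are rejected with their row numbers.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    cols = set(df.columns)
    if format == "auto":
        format = "long" if LONG_COLUMNS <= cols else "summary"
    if format == "long":
        if not LONG_COLUMNS <= cols:
            raise ValueError(f"{path}: long format needs columns {sorted(LONG_COLUMNS)}")
        extra = cols - LONG_COLUMNS
        if extra:
            raise ValueError(f"{path}: unknown columns {sorted(extra)}")
        n_missing = int(df["value"].isna().sum())
        if n_missing:
            logger.info("%s: dropped %d rows with missing values", path, n_missing)
            df = df.dropna(subset=["value"])
        bad = df.index[df["value"] < 0]
        if len(bad):
            raise ValueError(
                f"{path}: negative values at rows {list((bad + 2)[:10])}"
                " (1-based, counting the header)"
            )
        return [
            summarize(g["value"].to_numpy(), label=str(name))
            for name, g in df.groupby("group", sort=False)
        ]
    if format == "summary":
        if not SUMMARY_COLUMNS <= cols:
            raise ValueError(
                f"{path}: summary format needs columns {sorted(SUMMARY_COLUMNS)}"
                " plus n1 or delta_hat"
            )
        out = []
        for _, row in df.iterrows():
            if "n1" in cols and not pd.isna(row.get("n1")):
                out.append(
                    SampleSummary(
                        n=int(row["n"]), n1=int(row["n1"]),
                        mu_hat=float(row["mu_hat"]),
                        sigma2_hat=float(row["sigma2_hat"]),
                        label=str(row["group"]),
                    )
                )
            elif "delta_hat" in cols:
                out.append(
                    SampleSummary.from_delta_hat(
                        n=int(row["n"]), delta_hat=float(row["delta_hat"]),
                        mu_hat=float(row["mu_hat"]),
                        sigma2_hat=float(row["sigma2_hat"]),
                        label=str(row["group"]),
                    )
                )
            else:
                raise ValueError(f"{path}: need an n1 or delta_hat column")
        return out
    raise ValueError(f"unknown format {format!r}")


def generate_fixture(
    groups: dict[str, DeltaLNParams], n: int, seed: int, path
) -> pd.DataFrame:
    """Write a deterministic long-format CSV of simulated observations."""
    rng = np.random.default_rng(seed)
    frames = []
    for name, params in groups.items():
        from .distribution import sample_delta_ln

        frames.append(
            pd.DataFrame({"group": name, "value": sample_delta_ln(params, n, rng)})
        )
    df = pd.concat(frames, ignore_index=True)
    df.to_csv(path, index=False)
    return df


def render_report(report: AnalysisReport, style: str = "text") -> str:
    """Serialise a report as aligned text, CSV, or JSON (4-decimal rounding)."""
    rows = [
        {
            "method": iv.method.value,
            "lower": round(iv.lower, 4),
            "upper": round(iv.upper, 4),
            "length": round(iv.length, 4),
        }
        for iv in report.intervals
    ]
    if style == "json":
        payload = {
            "version": report.version,
            "seed": report.seed,
            "draws": report.draws,
            "level": report.level,
            "point_estimate": round(report.point_estimate, 4),
            "groups": [
                {
                    "label": s.label,
                    "n": s.n,
                    "n1": s.n1,
                    "delta_hat": round(s.delta_hat, 4),
                    "mu_hat": round(s.mu_hat, 4),
                    "sigma2_hat": round(s.sigma2_hat, 4),
                }
                for s in report.summaries
            ],
            "intervals": rows,
        }
        return json.dumps(payload, indent=2)
    df = pd.DataFrame(rows, columns=["method", "lower", "upper", "length"])
    if style == "csv":
        buf = _io.StringIO()
        df.to_csv(buf, index=False)
        return buf.getvalue()
    if style == "text":
        lines = [
            f"deltalogcv {report.version}"
            + (f" | seed={report.seed}" if report.seed is not None else "")
            + f" | draws={report.draws} | level={report.level:g}",
            "",
            "group summaries:",
        ]
        for s in report.summaries:
            lines.append(
                f"  {s.label or '<unnamed>':12s} n={s.n:<4d} n1={s.n1:<4d} "
                f"delta_hat={s.delta_hat:.4f} mu_hat={s.mu_hat:.4f} "
                f"sigma2_hat={s.sigma2_hat:.4f}"
            )
        lines += [
            "",
            f"common CV point estimate: {report.point_estimate:.4f}",
            "",
            df.to_string(index=False),
        ]
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown style {style!r}")
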