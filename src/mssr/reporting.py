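"""Summary tables and the meta-analysis of MSSR against design factors.

Two table shapes flow through here.  The long "table 1" shape holds one
row per (condition, sample size) with the replication-summary columns
``lp``, ``up`` and ``above``; the wide "table 2" shape holds one row per
condition with its factor codes, Rt² and the two MSSR decisions, an
``X`` marking an unattainable requirement.  A transcription of the
published study's wide table ships with the package for decision replay
and for validating the meta-analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .conditions import condition_from_index
from .engine import MSSRResult, ReplicationSummary, UNATTAINABLE, decide_from_columns

#: factor columns analysed against MSSR, in reporting order
FACTORS = ("error", "n_iv", "linear", "complexity", "nonlinear", "rt2")

_CRITERION_COLUMNS = {
    "stability": "mssr_stability",
    "outperform": "mssr_outperform",
}


def _criterion_column(criterion: str) -> str:
    try:
        return _CRITERION_COLUMNS[criterion]
    except KeyError:
        raise ValueError(
            f"criterion must be one of {tuple(_CRITERION_COLUMNS)}, got {criterion!r}"
        ) from None


def _parse_mssr(col: pd.Series) -> pd.Series:
    def one(v):
        s = str(v).strip()
        return UNATTAINABLE if s.upper() == "X" else int(float(s))

    return col.map(one)


def read_condition_table(path_or_buf) -> pd.DataFrame:
    """Read a wide condition table, parsing 'X' as the unattainable marker."""
    df = pd.read_csv(path_or_buf, dtype={"mssr_stability": str, "mssr_outperform": str})
    for col in ("mssr_stability", "mssr_outperform"):
        df[col] = _parse_mssr(df[col])
    return df


def load_published_table2() -> pd.DataFrame:
    """The 108-row results table transcribed from the published study."""
    ref = resources.files("mssr.data") / "published_table2.csv"
    with resources.as_file(ref) as path:
        return read_condition_table(path)


def load_published_table1_selection() -> pd.DataFrame:
    """Published per-sample-size summary columns for five example
    conditions (ids 1, 19, 26, 38, 98)."""
    ref = resources.files("mssr.data") / "published_table1_selection.csv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


# ---------------------------------------------------------------------------
# decision replay
# ---------------------------------------------------------------------------

def replay_decisions(table1: pd.DataFrame, width: float = 0.1, threshold: float = 0.8) -> pd.DataFrame:
    """Apply both MSSR criteria to a long summary table.

    Expects columns ``condition_id, n, lp, up, above``; returns one row
    per condition with the replayed ``mssr_stability`` and
    ``mssr_outperform`` decisions.
    """
    rows = []
    for cid, grp in table1.groupby("condition_id", sort=True):
        mssr_s, mssr_o = decide_from_columns(
            grp["n"].to_numpy(), grp["lp"].to_numpy(), grp["up"].to_numpy(),
            grp["above"].to_numpy(), width=width, threshold=threshold,
        )
        rows.append({"condition_id": cid, "mssr_stability": mssr_s, "mssr_outperform": mssr_o})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# meta-analysis
# ---------------------------------------------------------------------------

def count_attainable(table: pd.DataFrame, criterion: str) -> int:
    """Number of conditions with a numeric MSSR for the given criterion."""
    col = table[_criterion_column(criterion)]
    return int((col != UNATTAINABLE).sum())


@dataclass(frozen=True)
class FactorCorrelation:
    """Spearman rank correlation of MSSR with one design factor."""

    factor: str
    rho: float
    p_value: float
    n_used: int

    @property
    def defined(self) -> bool:
        return np.isfinite(self.rho)


def spearman_factor_analysis(table: pd.DataFrame, criterion: str) -> list[FactorCorrelation]:
    """Spearman correlations (average ranks for ties) between the MSSR and
    each design factor, over conditions where the MSSR is numeric.

    Factor codes are taken as printed: error multiplier (1/4/10), number
    of IVs (3/5/10), linear and nonlinear coefficient levels (1/2),
    complexity (1/2/3) and Rt².  A constant factor leaves the
    correlation undefined (NaN) and is flagged via ``defined``.
    """
    col = _criterion_column(criterion)
    usable = table[table[col] != UNATTAINABLE]
    if len(usable) < 3:
        raise ValueError("need at least 3 conditions with a numeric MSSR")
    mssr = usable[col].astype(float).to_numpy()
    out: list[FactorCorrelation] = []
    for factor in FACTORS:
        x = usable[factor].astype(float).to_numpy()
        if np.all(x == x[0]):
            out.append(FactorCorrelation(factor, np.nan, np.nan, len(usable)))
            continue
        rho, p = stats.spearmanr(mssr, x)
        out.append(FactorCorrelation(factor, float(rho), float(p), len(usable)))
    return out


def pearson_factor_analysis(table: pd.DataFrame, criterion: str) -> list[FactorCorrelation]:
    """Pearson correlations of the raw MSSR values with the raw factor codes.

    Kept alongside :func:`spearman_factor_analysis` because it is the
    estimator that reproduces the published stability-criterion
    coefficients to the fourth decimal (all six factors): the published
    meta-analysis, although described as Spearman, was evidently computed
    on the raw values.  The rank-based analysis remains the statistically
    appropriate choice for these heavily tied ordinal codes.
    """
    col = _criterion_column(criterion)
    usable = table[table[col] != UNATTAINABLE]
    if len(usable) < 3:
        raise ValueError("need at least 3 conditions with a numeric MSSR")
    mssr = usable[col].astype(float).to_numpy()
    out: list[FactorCorrelation] = []
    for factor in FACTORS:
        x = usable[factor].astype(float).to_numpy()
        if np.all(x == x[0]):
            out.append(FactorCorrelation(factor, np.nan, np.nan, len(usable)))
            continue
        r, p = stats.pearsonr(mssr, x)
        out.append(FactorCorrelation(factor, float(r), float(p), len(usable)))
    return out


# ---------------------------------------------------------------------------
# table construction and round-trip I/O
# ---------------------------------------------------------------------------

def build_tables(
    results: Iterable[MSSRResult], summaries: Iterable[ReplicationSummary]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the long summary table and the wide condition table from a
    grid run."""
    table1 = pd.DataFrame(
        [
            {
                "condition_id": s.condition_id,
                "n": s.n,
                "lp": s.lp,
                "up": s.up,
                "above": s.above,
            }
            for s in summaries
        ]
    ).sort_values(["condition_id", "n"], ignore_index=True)

    rows = []
    for r in results:
        cond = condition_from_index(r.condition_id)
        rows.append(
            {
                "condition_id": r.condition_id,
                "complexity": int(cond.complexity),
                "linear": 1 if cond.linear_level == "small" else 2,
                "nonlinear": 1 if cond.nonlinear_level == "small" else 2,
                "error": int(cond.error_coef),
                "n_iv": cond.n_iv,
                "rt2": r.rt2,
                "mssr_stability": r.mssr_stability,
                "mssr_outperform": r.mssr_outperform,
            }
        )
    table2 = pd.DataFrame(rows).sort_values("condition_id", ignore_index=True)
    return table1, table2


def write_tables(table1: pd.DataFrame, table2: pd.DataFrame, out_dir) -> tuple[Path, Path]:
    """Write ``table1.csv`` / ``table2.csv``; unattainable cells serialize
    as the literal ``X``.  Reading back with the module readers round-trips
    losslessly."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p1 = out / "table1.csv"
    p2 = out / "table2.csv"
    table1.to_csv(p1, index=False)
    table2.to_csv(p2, index=False)
    return p1, p2


def read_table1(path) -> pd.DataFrame:
    return pd.read_csv(path)
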