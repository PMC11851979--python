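"""Bundled fixtures and coefficient-file interchange.

The published study saved its coefficient draws externally
(https://osf.io/ptzkj/); the package never requires that file — every
run can redraw coefficients from the stated uniform distributions — but
a saved coefficient CSV (columns ``condition_id, role, index, value``
with role one of cof/conf/coferr) can be ingested to reproduce a run
with fixed draws.  The one coefficient set printed in full in the study
(the medium-complexity 3-IV cell with small linear and large nonlinear
coefficients) ships here as ``eq10_coefficients``.
"""

from __future__ import annotations

from collections import defaultdict

import pandas as pd

from .conditions import Complexity, ConditionSpec
from .dgp import CoefficientSet

#: the design cell whose coefficients the published study prints in full
EQ10_CONDITION = ConditionSpec(
    complexity=Complexity.MEDIUM,
    n_iv=3,
    linear_level="small",
    nonlinear_level="large",
    error_coef=1.0,
)


def eq10_coefficients(coferr: float = 1.0) -> CoefficientSet:
    """The printed coefficient set of the medium-complexity 3-IV example:
    linear (0.29, 0.28, 0.13); nonlinear (0.61, 0.7, 0.81, 0.752)."""
    return CoefficientSet(cof=(0.29, 0.28, 0.13), conf=(0.61, 0.7, 0.81, 0.752), coferr=coferr)


def coefficients_to_frame(sets: dict[int, CoefficientSet]) -> pd.DataFrame:
    """Serialize per-condition coefficient sets to the interchange layout."""
    rows = []
    for cid, cs in sorted(sets.items()):
        for i, v in enumerate(cs.cof, start=1):
            rows.append({"condition_id": cid, "role": "cof", "index": i, "value": v})
        for i, v in enumerate(cs.conf, start=1):
            rows.append({"condition_id": cid, "role": "conf", "index": i, "value": v})
        rows.append({"condition_id": cid, "role": "coferr", "index": 1, "value": cs.coferr})
    return pd.DataFrame(rows)


def coefficients_from_frame(df: pd.DataFrame) -> dict[int, CoefficientSet]:
    """Parse the interchange layout back to per-condition coefficient sets.

    Accepts a user-supplied coefficient file (e.g. the study's deposited
    draws) as long as it follows the column convention.
    """
    out: dict[int, CoefficientSet] = {}
    for cid, grp in df.groupby("condition_id"):
        parts: dict[str, dict[int, float]] = defaultdict(dict)
        for _, row in grp.iterrows():
            parts[str(row["role"])][int(row["index"])] = float(row["value"])
        cof = tuple(parts["cof"][i] for i in sorted(parts["cof"]))
        conf = tuple(parts["conf"][i] for i in sorted(parts["conf"]))
        coferr = parts["coferr"][min(parts["coferr"])] if parts["coferr"] else 0.0
        out[int(cid)] = CoefficientSet(cof=cof, conf=conf, coferr=coferr)
    return out


def load_coefficients_csv(path) -> dict[int, CoefficientSet]:
    return coefficients_from_frame(pd.read_csv(path))


def save_coefficients_csv(sets: dict[int, CoefficientSet], path) -> None:
    coefficients_to_frame(sets).to_csv(path, index=False)
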