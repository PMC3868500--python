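"""Relative quantification by the 2**-ddCt method and concordance checks.

Per group (NC control, MN disease), the target miRNA's cycle threshold is
normalized against a reference RNA (dCt = Ct_target - Ct_ref); the
between-group difference ddCt = dCt_MN - dCt_NC gives the relative
expression ratio 2**-ddCt, whose log2 is simply -ddCt.  Direction
concordance with sequencing compares sign(-ddCt) against the sign of the
sequencing log2 fold change per miRNA.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Literal, Mapping, Sequence, Tuple

import math

import pandas as pd

from ._util import round_half_up

#: Ct values beyond this many cycles are considered implausible
MAX_PLAUSIBLE_CT = 50.0


@dataclass
class QPCRRecord:
    mirna: str
    ct_ref_nc: float
    ct_target_nc: float
    ct_ref_mn: float
    ct_target_mn: float
    dct_nc: float = 0.0
    dct_mn: float = 0.0
    ddct: float = 0.0
    ratio: float = 1.0  # 2**-ddCt
    log2_ratio: float = 0.0  # == -ddCt

    def compute(self) -> "QPCRRecord":
        self.dct_nc = delta_ct(self.ct_target_nc, self.ct_ref_nc)
        self.dct_mn = delta_ct(self.ct_target_mn, self.ct_ref_mn)
        self.ddct, self.ratio, self.log2_ratio = ddct_ratio(self.dct_mn, self.dct_nc)
        return self


def delta_ct(ct_target: float, ct_ref: float) -> float:
    """dCt = Ct_target - Ct_ref, full precision."""
    for name, value in (("ct_target", ct_target), ("ct_ref", ct_ref)):
        if not math.isfinite(value):
            raise ValueError(f"{name} is not finite: {value!r}")
        if value <= 0 or value >= MAX_PLAUSIBLE_CT:
            raise ValueError(f"{name}={value} outside plausible (0, {MAX_PLAUSIBLE_CT})")
    return ct_target - ct_ref


def ddct_ratio(dct_mn: float, dct_nc: float) -> Tuple[float, float, float]:
    """(ddCt, 2**-ddCt, log2 ratio) between the MN and NC groups."""
    ddct = dct_mn - dct_nc
    return ddct, 2.0 ** (-ddct), -ddct


def combine_replicates(
    cts: Sequence[float], how: Literal["mean", "median"] = "mean"
) -> float:
    """Collapse replicate Ct measurements before dCt (triplicates typically)."""
    if not cts:
        raise ValueError("no Ct replicates given")
    s = pd.Series(list(cts), dtype=float)
    return float(s.mean() if how == "mean" else s.median())


def read_ct_table(
    path: str | Path, how: Literal["mean", "median"] = "mean"
) -> List[QPCRRecord]:
    """Load a Ct TSV with columns mirna, group, ct_ref, ct_target.

    Replicate rows (same miRNA and group) are combined with ``how``.
    Groups must be labelled NC and MN.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"mirna", "group", "ct_ref", "ct_target"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: Ct table needs columns {sorted(required)}")
    records: List[QPCRRecord] = []
    for mirna, sub in df.groupby("mirna", sort=True):
        by_group: Dict[str, Tuple[float, float]] = {}
        for group, rows in sub.groupby("group"):
            by_group[str(group)] = (
                combine_replicates(rows["ct_ref"].tolist(), how),
                combine_replicates(rows["ct_target"].tolist(), how),
            )
        if not {"NC", "MN"}.issubset(by_group):
            raise ValueError(f"{mirna}: need one NC and one MN row in the Ct table")
        rec = QPCRRecord(
            mirna=str(mirna),
            ct_ref_nc=by_group["NC"][0],
            ct_target_nc=by_group["NC"][1],
            ct_ref_mn=by_group["MN"][0],
            ct_target_mn=by_group["MN"][1],
        )
        records.append(rec.compute())
    return records


def concordance(
    qpcr: Sequence[QPCRRecord], fold_changes: Mapping[str, float]
) -> Tuple[pd.DataFrame, float]:
    """Per-miRNA sign agreement between qPCR log2 ratio and sequencing FC.

    Raises on an empty intersection of miRNA names.
    """
    shared = [r for r in qpcr if r.mirna in fold_changes]
    if not shared:
        raise ValueError("no miRNA names shared between qPCR and sequencing tables")

    def sign(v: float) -> int:
        return (v > 0) - (v < 0)

    rows = []
    for r in shared:
        fc = fold_changes[r.mirna]
        rows.append(
            {
                "mirna": r.mirna,
                "qpcr_log2": r.log2_ratio,
                "seq_log2_fc": fc,
                "agree": sign(r.log2_ratio) == sign(fc),
            }
        )
    df = pd.DataFrame(rows).set_index("mirna")
    return df, float(df["agree"].mean())


def write_qpcr_table(records: Sequence[QPCRRecord], path: str | Path) -> None:
    """Derived-column TSV (dCt, ddCt, ratio, log2 ratio at 2 decimals)."""
    df = pd.DataFrame(
        {
            "mirna": [r.mirna for r in records],
            "dCt_NC": [f"{round_half_up(r.dct_nc, 2):.2f}" for r in records],
            "dCt_MN": [f"{round_half_up(r.dct_mn, 2):.2f}" for r in records],
            "ddCt": [f"{round_half_up(r.ddct, 2):.2f}" for r in records],
            "ratio_2^-ddCt": [f"{round_half_up(r.ratio, 2):.2f}" for r in records],
            "log2_ratio": [f"{round_half_up(r.log2_ratio, 2):.2f}" for r in records],
        }
    ).set_index("mirna")
    df.to_csv(path, sep="\t")
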