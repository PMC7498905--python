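"""JIP-test photosynthetic performance from fast chlorophyll fluorescence.

The OJIP transient of a dark-adapted leaf rises from the minimum
fluorescence F0 (all PSII reaction centers open) to the maximum FM (all
centers closed). From four points on the curve the performance index PiABS
is computed:

    VJ    = (FJ - F0) / (FM - F0)          relative variable fluorescence at 2 ms
    M0    = 4 * (F300us - F0) / (FM - F0)  initial slope of the kinetics
    PiABS = ((1 - F0/FM) / (M0/VJ)) * ((FM - F0)/F0) * ((1 - VJ)/VJ)

PiABS combines reaction-center density, trapping probability, and electron
transport efficiency of photosystem II; it is a pure ratio of fluorescence
values and therefore invariant to the instrument's absolute scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .distances import DistanceMatrix


@dataclass(frozen=True)
class OJIPRecord:
    sample_id: str
    leaf: str
    replicate: int
    f0: float
    f300: float
    fj: float
    fm: float

    def __post_init__(self) -> None:
        if min(self.f0, self.f300, self.fj, self.fm) <= 0:
            raise ValueError("fluorescence values must be positive")
        if self.fm <= self.f0:
            raise ValueError(
                f"invalid record {self.sample_id}/{self.leaf}/{self.replicate}: "
                "FM must exceed F0"
            )


def compute_piabs(rec: OJIPRecord) -> dict[str, float]:
    """VJ, M0, and PiABS for one measurement.

    Records with VJ outside (0, 1) or M0 <= 0 (saturated or inverted
    kinetics) get ``finite=False`` and a NaN PiABS; they are excluded from
    shoot means rather than propagated.
    """
    span = rec.fm - rec.f0
    vj = (rec.fj - rec.f0) / span
    m0 = 4.0 * (rec.f300 - rec.f0) / span
    if not (0.0 < vj < 1.0) or m0 <= 0.0:
        return {"VJ": vj, "M0": m0, "PiABS": math.nan, "finite": False}
    piabs = ((1.0 - rec.f0 / rec.fm) / (m0 / vj)) * (span / rec.f0) * ((1.0 - vj) / vj)
    return {"VJ": vj, "M0": m0, "PiABS": piabs, "finite": True}


def read_ojip_tsv(path) -> list[OJIPRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        OJIPRecord(
            sample_id=str(r.sample_id),
            leaf=str(r.leaf),
            replicate=int(r.replicate),
            f0=float(r.F0),
            f300=float(r.F300us),
            fj=float(r.F2ms),
            fm=float(r.FM),
        )
        for r in df.itertuples()
    ]


def piabs_table(records: list[OJIPRecord]) -> pd.DataFrame:
    """Per-record PiABS values with the finite flag."""
    rows = []
    for rec in records:
        res = compute_piabs(rec)
        rows.append(
            {
                "sample_id": rec.sample_id,
                "leaf": rec.leaf,
                "replicate": rec.replicate,
                **res,
            }
        )
    return pd.DataFrame(rows)


def shoot_means(records: list[OJIPRecord]) -> pd.DataFrame:
    """Mean finite PiABS per shoot (the <= 4 leaf x replicate measurements).

    Shoots whose every measurement is non-finite get a NaN mean; the number
    of excluded records per shoot is reported alongside.
    """
    per = piabs_table(records)
    out = []
    for sample, grp in per.groupby("sample_id", sort=False):
        finite = grp[grp["finite"]]
        out.append(
            {
                "sample_id": sample,
                "mean_piabs": finite["PiABS"].mean() if len(finite) else math.nan,
                "n_used": len(finite),
                "n_excluded": int((~grp["finite"]).sum()),
            }
        )
    return pd.DataFrame(out).set_index("sample_id")


def performance_difference_matrix(
    means: pd.Series | pd.DataFrame, label: str = "piabs"
) -> DistanceMatrix:
    """|PiABS_i - PiABS_j| between shoot means; NaN shoots are excluded."""
    if isinstance(means, pd.DataFrame):
        means = means["mean_piabs"]
    means = means.dropna()
    if len(means) < 3:
        raise ValueError(
            f"need >= 3 shoots with a PiABS value, got {len(means)}"
        )
    vals = means.to_numpy(dtype=float)
    return DistanceMatrix(
        [str(s) for s in means.index],
        np.abs(vals[:, None] - vals[None, :]),
        label,
    )


def pearson_test(x, y) -> dict[str, float]:
    """Two-sided Pearson product-moment correlation test.

    p comes from t = r * sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p)}
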