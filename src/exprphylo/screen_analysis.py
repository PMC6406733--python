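"""Drug-screen resistance scoring, re-sensitization calls and plate QC.

The resistance score of a drug is the fold change of mean viability signal
under TGF-beta over mean signal under vehicle; a fold change above 1 calls
the drug resistant (the treatment protected cells from it), below 1
sensitive.  Re-sensitization compares the control arm with the
ATG16L1-knockdown arm over the drugs called resistant in the control arm.
QC checks that control-well signal does not depend on plate position
(OLS R^2) and that per-drug means correlate across plating densities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ScreenDataset

__all__ = [
    "ResistanceTable",
    "QcReport",
    "fold_change_table",
    "resistance_calls",
    "resensitization",
    "plate_position_qc",
    "density_replicate_correlation",
]

ARMS = {
    "ctrl": ("siCtrl", "none"),
    "kd": ("siATG16L1",),
}


@dataclass
class ResistanceTable:
    """Per-(drug, density) fold changes plus the per-drug pooled score."""

    per_density: pd.DataFrame  # index (drug_id, density)
    per_drug: pd.DataFrame  # index drug_id, column fold_change
    arm: str

    @property
    def drugs(self) -> list[str]:
        return list(self.per_drug.index)


def fold_change_table(screen: ScreenDataset, arm: str = "ctrl") -> ResistanceTable:
    """Viability fold change tgfb/vehicle per drug.

    Computed per plating density, then averaged over densities to the
    per-drug score (densities act as replicates).
    """
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}; options: {', '.join(ARMS)}")
    df = screen.drug_wells
    df = df[df["knockdown"].isin(ARMS[arm])]
    if df.empty:
        raise ValueError(f"no drug wells in arm {arm!r}")
    rows = []
    for (drug, density), grp in df.groupby(["drug_id", "density"], sort=True):
        veh = grp.loc[grp["treatment"] == "vehicle", "signal"]
        tgf = grp.loc[grp["treatment"] == "tgfb", "signal"]
        if veh.empty or tgf.empty:
            missing = "vehicle" if veh.empty else "tgfb"
            raise ValueError(f"drug {drug!r} has no {missing} wells at density {density!r}")
        if veh.mean() <= 0:
            raise ValueError(f"drug {drug!r}: zero/invalid vehicle mean signal")
        rows.append(
            {
                "drug_id": drug,
                "density": density,
                "mean_vehicle": veh.mean(),
                "mean_tgfb": tgf.mean(),
                "fold_change": tgf.mean() / veh.mean(),
                "n_vehicle": len(veh),
                "n_tgfb": len(tgf),
            }
        )
    per_density = pd.DataFrame(rows).set_index(["drug_id", "density"])
    per_drug = (
        per_density.groupby(level="drug_id")["fold_change"].mean().to_frame()
    )
    return ResistanceTable(per_density=per_density, per_drug=per_drug, arm=arm)


def resistance_calls(table: ResistanceTable, threshold: float = 1.0) -> pd.DataFrame:
    """Call each drug resistant (> threshold), sensitive (<) or neutral (=).

    The returned frame carries the counts and fractions as attrs.
    """
    fc = table.per_drug["fold_change"]
    call = np.where(fc > threshold, "resistant", np.where(fc < threshold, "sensitive", "neutral"))
    out = pd.DataFrame({"fold_change": fc, "call": call})
    n = len(out)
    counts = {k: int((call == k).sum()) for k in ("resistant", "sensitive", "neutral")}
    out.attrs["counts"] = counts
    out.attrs["n_drugs"] = n
    out.attrs["fraction_resistant"] = counts["resistant"] / n if n else float("nan")
    return out


def resensitization(
    ctrl: ResistanceTable,
    kd: ResistanceTable,
    rule: str = "below_one",
    relative_drop: float = 0.2,
    threshold: float = 1.0,
) -> pd.DataFrame:
    """Re-sensitization calls over the drugs resistant in the control arm.

    ``below_one``: re-sensitized iff the knockdown-arm fold change drops to
    <= 1 (symmetric with the resistance definition).  ``relative_drop``:
    iff the knockdown fold change is <= ctrl * (1 - relative_drop).
    """
    cset, kset = set(ctrl.drugs), set(kd.drugs)
    if cset != kset:
        raise ValueError(
            f"drug panels differ between arms; symmetric difference: {sorted(cset ^ kset)}"
        )
    fc_c = ctrl.per_drug["fold_change"]
    fc_k = kd.per_drug["fold_change"].reindex(fc_c.index)
    resistant = fc_c > threshold
    if rule == "below_one":
        resens = fc_k <= 1.0
    elif rule == "relative_drop":
        resens = fc_k <= fc_c * (1.0 - relative_drop)
    else:
        raise ValueError(f"unknown rule {rule!r}; options: below_one, relative_drop")
    out = pd.DataFrame(
        {
            "fold_change_ctrl": fc_c,
            "fold_change_kd": fc_k,
            "resistant_in_ctrl": resistant,
            "resensitized": resistant & resens,
        }
    )
    n_res = int(resistant.sum())
    n_resens = int((resistant & resens).sum())
    out.attrs["n_resistant_ctrl"] = n_res
    out.attrs["n_resensitized"] = n_resens
    out.attrs["fraction_resensitized"] = n_resens / n_res if n_res else float("nan")
    out.attrs["rule"] = rule
    return out


@dataclass
class QcReport:
    """Plate-position regression and density-replicate correlations."""

    position_r2: float
    position_slope: float
    n_control_wells: int
    density_r: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)


def plate_position_qc(
    screen: ScreenDataset,
    wells=("empty", "DMSO"),
    n_cols: int | None = None,
) -> QcReport:
    """OLS of control-well signal on the row-major well index, pooled
    across plates sharing the layout; near-zero R^2 means no plate effect."""
    ctrl = screen.control_wells
    ctrl = ctrl[ctrl["control_kind"].isin(wells)]
    if len(ctrl) < 3:
        raise ValueError("need >= 3 control wells for position QC")
    if n_cols is None:
        n_cols = int(screen.wells["well_col"].max()) + 1
    idx = ctrl["well_row"].to_numpy() * n_cols + ctrl["well_col"].to_numpy()
    sig = ctrl["signal"].to_numpy(dtype=float)
    if np.allclose(sig, sig[0]) or np.allclose(idx, idx[0]):
        r2, slope = 0.0, 0.0
    else:
        res = stats.linregress(idx, sig)
        r2, slope = float(res.rvalue**2), float(res.slope)
    flags = ["position_effect"] if r2 > 0.1 else []
    return QcReport(
        position_r2=r2,
        position_slope=slope,
        n_control_wells=len(ctrl),
        flags=flags,
    )


def density_replicate_correlation(screen: ScreenDataset) -> dict:
    """Pearson r between per-drug mean signals at low vs high density,
    one value per treatment condition."""
    df = screen.drug_wells
    out: dict[str, float] = {}
    for cond, grp in df.groupby("treatment"):
        means = grp.groupby(["drug_id", "density"])["signal"].mean().unstack("density")
        if "low" not in means.columns or "high" not in means.columns:
            missing = {"low", "high"} - set(means.columns)
            raise ValueError(f"{cond}: missing density level(s) {sorted(missing)}")
        sub = means.dropna()
        r, _ = stats.pearsonr(sub["low"], sub["high"])
        out[cond] = float(r)
    return out
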