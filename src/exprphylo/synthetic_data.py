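"""Synthetic data generators with the statistical structure the method assumes.

Two generators: a longitudinal expression time course (ordered time points
with replicates, cumulative Brownian-like drift, i.i.d. measurement noise,
and an optional late-onset "signal" gene subset that shifts from a given
rank onward), and a 384-well viability screen (drug kill effects, a
planted TGF-beta-resistant drug subset, an optional knockdown arm that
re-sensitizes part of it, multiplicative noise, and an optional positional
gradient for QC testing).

Random-walk drift makes expected squared expression distance additive in
time separation — the regime where Neighbor Joining provably recovers the
chain — so the time course is a principled positive control for the
tree-building pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, ScreenDataset

__all__ = [
    "TimeCourseSpec",
    "ScreenSpec",
    "simulate_time_course",
    "simulate_screen",
]


@dataclass
class TimeCourseSpec:
    """Design of a simulated expression time course.

    Defaults emulate a TGF-beta-treatment microarray series: ~2000 genes,
    nine ordered time points with triplicates, log2-scale values around a
    baseline of 8, unit drift per step, small replicate noise, and (when
    ``signal_fraction`` > 0) a late-onset signal subset whose expression
    shifts by +-``signal_shift`` log2 units at every rank >= ``signal_onset``.
    """

    n_genes: int = 2000
    n_time_points: int = 9
    replicates: int = 3
    drift_sd: float = 1.0
    noise_sd: float = 0.05
    signal_fraction: float = 0.0
    signal_onset: int = 4
    signal_shift: float = 2.0
    baseline: float = 8.0
    seed: int | None = None

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_time_points < 2 or self.replicates < 1:
            raise ValueError("need >= 1 gene, >= 2 time points, >= 1 replicate")
        if self.drift_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if not 0.0 <= self.signal_fraction <= 1.0:
            raise ValueError("signal_fraction must lie in [0, 1]")
        if self.signal_fraction > 0 and not 0 <= self.signal_onset < self.n_time_points:
            raise ValueError("signal_onset must be a valid time rank")


def simulate_time_course(
    spec: TimeCourseSpec, seed: int | None = None
) -> tuple[ExpressionMatrix, dict]:
    """Simulate the time course; returns (ExpressionMatrix, truth record).

    Per gene, the latent trajectory is a Gaussian random walk over the
    ordered ranks (step sd ``drift_sd``); signal genes add a fixed-sign
    shift at ranks >= onset; every replicate observes trajectory +
    N(0, noise_sd^2).  Rank 0 is flagged as the outgroup.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    g, t, r = spec.n_genes, spec.n_time_points, spec.replicates
    steps = rng.normal(0.0, spec.drift_sd, size=(g, t - 1))
    latent = np.concatenate(
        [np.zeros((g, 1)), np.cumsum(steps, axis=1)], axis=1
    ) + spec.baseline

    n_signal = int(round(spec.signal_fraction * g))
    signal_idx = rng.choice(g, size=n_signal, replace=False) if n_signal else np.array([], dtype=int)
    signs = rng.choice([-1.0, 1.0], size=n_signal)
    if n_signal:
        shift = np.zeros((g, t))
        shift[signal_idx, spec.signal_onset:] = (signs * spec.signal_shift)[:, None]
        latent = latent + shift

    cols, data, meta_rows = [], [], []
    for rank in range(t):
        for rep in range(r):
            sid = f"t{rank}_r{rep + 1}"
            cols.append(sid)
            data.append(latent[:, rank] + rng.normal(0.0, spec.noise_sd, size=g))
            meta_rows.append(
                {"sample_id": sid, "time_rank": rank, "replicate": f"r{rep + 1}",
                 "is_outgroup": rank == 0}
            )
    gene_ids = [f"g{i:05d}" for i in range(g)]
    values = pd.DataFrame(np.column_stack(data), index=gene_ids, columns=cols)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    expr = ExpressionMatrix(values, meta, log_scale=True)
    truth = {
        "signal_genes": sorted(gene_ids[i] for i in signal_idx),
        "signal_signs": {gene_ids[i]: float(s) for i, s in zip(signal_idx, signs)},
        "signal_onset": spec.signal_onset,
        "time_rank": {row["sample_id"]: row["time_rank"] for row in meta_rows},
        "outgroup": [c for c, m in zip(cols, meta_rows) if m["is_outgroup"]],
    }
    return expr, truth


@dataclass
class ScreenSpec:
    """Design of a simulated 384-well viability screen.

    Defaults emulate the screening protocol: 119 drugs at a single dose,
    one well per drug per plate, plates for every treatment (vehicle /
    tgfb) x plating density (low = 250, high = 1000 cells per well)
    combination, plus DMSO and empty control wells.  Resistant drugs
    multiply the tgfb-well signal by ``resistant_multiplier``; in the
    knockdown arm, re-sensitized drugs fall back to
    ``resensitized_multiplier`` (< 1: knockdown removes the protection).
    Noise is multiplicative log-normal with the given CV; a positional
    gradient (signal units per well index) can be planted to exercise QC.
    """

    n_drugs: int = 119
    n_rows: int = 16
    n_cols: int = 24
    baseline: float = 1000.0
    density_factors: dict = field(default_factory=lambda: {"low": 0.3, "high": 1.0})
    survival_range: tuple = (0.2, 1.0)
    tgfb_effect: float = 1.0
    resistant_drugs: tuple = ()
    resistant_multiplier: float = 1.5
    resensitized_drugs: tuple = ()
    resensitized_multiplier: float = 0.9
    noise_cv: float = 0.03
    gradient_slope: float = 0.0
    n_dmso: int = 16
    n_empty: int = 16
    arm: str = "ctrl"
    seed: int | None = None

    def validate(self) -> None:
        if self.baseline <= 0:
            raise ValueError("baseline signal must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise CV must be >= 0")
        if self.n_drugs + self.n_dmso + self.n_empty > self.n_rows * self.n_cols:
            raise ValueError("wells do not fit on the plate")
        bad = set(self.resensitized_drugs) - set(self.resistant_drugs)
        if bad:
            raise ValueError(
                f"resensitized drugs must be a subset of resistant drugs: {sorted(bad)}"
            )
        if self.arm not in ("ctrl", "kd"):
            raise ValueError("arm must be 'ctrl' or 'kd'")


def _drug_id(i: int) -> str:
    return f"drug_{i + 1:03d}"


def simulate_screen(spec: ScreenSpec, seed: int | None = None) -> tuple[ScreenDataset, dict]:
    """Simulate one screen arm; returns (ScreenDataset, truth record).

    signal = baseline x density factor x drug survival x condition
    multiplier x LogNormal(cv) + gradient x well index.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    drugs = [_drug_id(i) for i in range(spec.n_drugs)]
    resistant = {_drug_id(i) if isinstance(i, (int, np.integer)) else i for i in spec.resistant_drugs}
    resens = {_drug_id(i) if isinstance(i, (int, np.integer)) else i for i in spec.resensitized_drugs}
    survival = dict(zip(drugs, rng.uniform(*spec.survival_range, size=spec.n_drugs)))
    knockdown = "siATG16L1" if spec.arm == "kd" else "siCtrl"
    sigma = np.sqrt(np.log(1.0 + spec.noise_cv**2)) if spec.noise_cv > 0 else 0.0

    # one fixed layout for every plate: controls interleaved across the
    # plate (alternating DMSO/empty) so position and well kind are not
    # confounded in the QC regression
    n_ctrl = spec.n_dmso + spec.n_empty
    n_used = spec.n_drugs + n_ctrl
    ctrl_items = []
    nd, ne = spec.n_dmso, spec.n_empty
    while nd or ne:  # alternate kinds so both span the plate
        if nd:
            ctrl_items.append(("DMSO", None))
            nd -= 1
        if ne:
            ctrl_items.append(("empty", None))
            ne -= 1
    ctrl_slots = set(np.round(np.linspace(0, n_used - 1, n_ctrl)).astype(int)) if n_ctrl else set()
    layout: list[tuple[str, str | None]] = []
    di, ci = 0, 0
    for slot in range(n_used):
        if slot in ctrl_slots and ci < n_ctrl:
            layout.append(ctrl_items[ci])
            ci += 1
        else:
            layout.append(("drug", drugs[di]))
            di += 1
    positions = np.round(
        np.linspace(0, spec.n_rows * spec.n_cols - 1, n_used)
    ).astype(int)

    rows = []
    for treatment in ("vehicle", "tgfb"):
        for density, dfac in spec.density_factors.items():
            plate = f"{spec.arm}_{treatment}_{density}"
            for (kind, drug), widx in zip(layout, positions):
                wr, wc = divmod(int(widx), spec.n_cols)
                mu = spec.baseline * dfac
                if kind == "drug":
                    mu *= survival[drug]
                    if treatment == "tgfb":
                        if drug in resistant:
                            if spec.arm == "kd" and drug in resens:
                                mu *= spec.resensitized_multiplier
                            else:
                                mu *= spec.resistant_multiplier
                        else:
                            mu *= spec.tgfb_effect
                elif kind == "empty":
                    mu *= 0.01  # residual background; no cells, no response
                elif treatment == "tgfb":
                    mu *= spec.tgfb_effect  # DMSO wells carry cells
                noise = np.exp(rng.normal(-0.5 * sigma**2, sigma)) if sigma else 1.0
                signal = mu * noise + spec.gradient_slope * widx
                rows.append(
                    {
                        "plate_id": plate,
                        "well_row": wr,
                        "well_col": wc,
                        "drug_id": drug if kind == "drug" else "",
                        "control_kind": None if kind == "drug" else ("DMSO" if kind == "DMSO" else "empty"),
                        "treatment": treatment,
                        "knockdown": knockdown,
                        "density": density,
                        "signal": max(signal, 0.0),
                    }
                )
    screen = ScreenDataset(pd.DataFrame(rows))
    truth = {
        "resistant_drugs": sorted(resistant),
        "resensitized_drugs": sorted(resens),
        "survival": survival,
        "arm": spec.arm,
    }
    return screen, truth
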