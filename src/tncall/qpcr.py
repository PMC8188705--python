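"""Junction-qPCR integration efficiencies.

Each sample is assayed with three primer pairs: a genomic reference pair
and one junction pair per integration orientation (T-RL and T-LR).  The
efficiency of an orientation is ``100 * 2 ** dCq`` percent, where
``dCq = Cq(reference) - Cq(orientation)``; total efficiency is the sum of
the two orientations.  Values above 100% are reported as-is with a flag
rather than clipped — the transform is faithful to the assay definition.
Replicates are transformed first and averaged after (the transform is
nonlinear, so averaging Cq values first would bias the mean).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import pandas as pd

ORIENTATION_PAIRS = ("T-RL", "T-LR")


@dataclass(frozen=True)
class QpcrMeasurement:
    sample_id: str
    cq_reference: float
    cq_t_rl: float | None = None
    cq_t_lr: float | None = None

    def __post_init__(self) -> None:
        for v in (self.cq_reference, self.cq_t_rl, self.cq_t_lr):
            if v is not None and (not math.isfinite(v) or v <= 0):
                raise ValueError(f"Cq values must be finite and > 0, got {v}")


class EfficiencyResult(NamedTuple):
    eff_rl: float | None  # percent
    eff_lr: float | None
    total: float
    exceeds_100: bool


def integration_efficiency(m: QpcrMeasurement) -> EfficiencyResult:
    """Per-orientation and total integration efficiency, in percent."""
    if m.cq_t_rl is None and m.cq_t_lr is None:
        raise ValueError(f"sample {m.sample_id}: no orientation Cq present")
    eff_rl = 100.0 * 2.0 ** (m.cq_reference - m.cq_t_rl) if m.cq_t_rl is not None else None
    eff_lr = 100.0 * 2.0 ** (m.cq_reference - m.cq_t_lr) if m.cq_t_lr is not None else None
    total = (eff_rl or 0.0) + (eff_lr or 0.0)
    return EfficiencyResult(eff_rl, eff_lr, total, total > 100.0)


def read_cq_table(path) -> list[QpcrMeasurement]:
    """Parse a long-format Cq TSV.

    Columns: sample_id, primer_pair in {reference, T-RL, T-LR}, cq, and an
    optional replicate column.  One measurement per (sample, replicate).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "primer_pair", "cq"}
    if not required.issubset(df.columns):
        raise ValueError(f"Cq table must have columns {sorted(required)}")
    if "replicate" not in df.columns:
        df = df.assign(replicate=1)
    out = []
    for (sample, rep), grp in df.groupby(["sample_id", "replicate"], sort=True):
        cqs = dict(zip(grp["primer_pair"], grp["cq"]))
        if "reference" not in cqs:
            raise ValueError(f"sample {sample} replicate {rep}: missing reference Cq")
        out.append(
            QpcrMeasurement(
                sample_id=f"{sample}",
                cq_reference=float(cqs["reference"]),
                cq_t_rl=float(cqs["T-RL"]) if "T-RL" in cqs else None,
                cq_t_lr=float(cqs["T-LR"]) if "T-LR" in cqs else None,
            )
        )
    return out


def summarize_efficiencies(measurements: list[QpcrMeasurement]) -> pd.DataFrame:
    """Mean +/- sd of efficiencies per sample over replicates."""
    rows = []
    for m in measurements:
        r = integration_efficiency(m)
        rows.append(
            {
                "sample_id": m.sample_id,
                "eff_rl": r.eff_rl,
                "eff_lr": r.eff_lr,
                "total": r.total,
                "exceeds_100": r.exceeds_100,
            }
        )
    df = pd.DataFrame(rows)
    agg = df.groupby("sample_id").agg(
        eff_rl_mean=("eff_rl", "mean"),
        eff_rl_sd=("eff_rl", "std"),
        eff_lr_mean=("eff_lr", "mean"),
        eff_lr_sd=("eff_lr", "std"),
        total_mean=("total", "mean"),
        total_sd=("total", "std"),
        n_replicates=("total", "size"),
        any_exceeds_100=("exceeds_100", "any"),
    )
    return agg.reset_index()
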