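"""In-silico biodistribution studies with the design of the mouse experiment.

The default design mirrors the animal study the model was built for: a
0.1 mg/kg IV bolus in 28 g tumor-bearing mice, destructive sampling at
5 min, 1, 6, 12, 24, and 168 h with three animals per time point, and
plasma, whole blood, eleven tissues, and tumor measured in each animal with
an assay LLOQ of 0.2 ng/mL. Residual error follows the combined
additive-proportional variance model V = (sigma1 + sigma2·Y)^2 used in the
maximum-likelihood fit; replicates are drawn from a normal truncated at zero
(a log-normal alternative is available by flag). BLQ values are retained but
flagged, as a destructive study would report them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .pbpk_model import DrugParams, ModelError, TumorParams
from .physiology import PhysiologyTable
from .simulator import (
    OBSERVED_MATRICES,
    DoseEvent,
    convert_units,
    simulate,
)

__all__ = [
    "DEFAULT_SAMPLE_TIMES",
    "StudyDesign",
    "StudyDataset",
    "generate_study",
    "censor",
]

DEFAULT_SAMPLE_TIMES: tuple[float, ...] = (5.0 / 60.0, 1.0, 6.0, 12.0, 24.0, 168.0)

DATASET_COLUMNS = ["matrix", "time_h", "replicate", "conc_nM", "conc_ng_mL", "blq"]


@dataclass(frozen=True)
class StudyDesign:
    """Design of a destructive-sampling biodistribution study."""

    dose_per_bw: float = 0.1  # mg/kg
    body_weight: float = 28.0  # g
    sample_times: tuple[float, ...] = DEFAULT_SAMPLE_TIMES  # h
    animals_per_time: int = 3
    matrices: tuple[str, ...] = OBSERVED_MATRICES
    LLOQ: float = 0.2  # ng/mL
    sigma1: float = 0.01  # nM, additive
    sigma2: float = 0.10  # proportional
    seed: int = 0
    noise: str = "truncated_normal"  # or "lognormal"

    def __post_init__(self) -> None:
        if self.dose_per_bw < 0:
            raise ModelError("dose must be nonnegative")
        if self.animals_per_time < 1:
            raise ModelError("animals_per_time must be >= 1")
        if self.LLOQ < 0:
            raise ModelError("LLOQ must be nonnegative")
        times = np.asarray(self.sample_times)
        if np.any(times <= 0) or np.any(np.diff(times) <= 0):
            raise ModelError("sample times must be positive and sorted")
        if self.sigma1 < 0 or self.sigma2 < 0:
            raise ModelError("variance parameters must be nonnegative")
        if self.noise not in ("truncated_normal", "lognormal"):
            raise ModelError(f"unknown noise model {self.noise!r}")


@dataclass
class StudyDataset:
    """Long-format concentration records plus the design that produced them."""

    records: pd.DataFrame
    design: StudyDesign | None = None
    MW: float = 717.98

    def __post_init__(self) -> None:
        missing = [c for c in DATASET_COLUMNS if c not in self.records.columns]
        if missing:
            raise ModelError(f"dataset missing columns: {missing}")

    @property
    def n_records(self) -> int:
        return len(self.records)

    def non_blq(self) -> pd.DataFrame:
        return self.records[~self.records["blq"]]

    def profile(self, matrix: str, drop_blq: bool = True) -> tuple[np.ndarray, np.ndarray]:
        """Mean concentration-time profile (nM) for one matrix.

        BLQ records are excluded; times where every replicate is BLQ are
        dropped (leading/trailing and embedded alike), matching the NCA
        handling of censored data.
        """
        sub = self.records[self.records["matrix"] == matrix]
        if sub.empty:
            raise ModelError(f"no records for matrix {matrix!r}")
        if drop_blq:
            sub = sub[~sub["blq"]]
        means = sub.groupby("time_h")["conc_nM"].mean().sort_index()
        return means.index.to_numpy(), means.to_numpy()


def _draw_noisy(
    rng: np.random.Generator, Y: np.ndarray, sd: np.ndarray, noise: str
) -> np.ndarray:
    out = Y.astype(float).copy()
    active = sd > 0
    if not np.any(active):
        return out
    if noise == "lognormal":
        pos = active & (Y > 0)
        cv = sd[pos] / Y[pos]
        s = np.sqrt(np.log1p(cv**2))
        out[pos] = Y[pos] * np.exp(rng.normal(-0.5 * s**2, s))
        out[active & (Y <= 0)] = 0.0
        return out
    a = (0.0 - Y[active]) / sd[active]  # truncate at zero
    out[active] = stats.truncnorm.rvs(
        a, np.inf, loc=Y[active], scale=sd[active], random_state=rng
    )
    return out


def generate_study(
    design: StudyDesign,
    phys: PhysiologyTable,
    drug: DrugParams,
    tum: TumorParams,
    seed: int | None = None,
) -> StudyDataset:
    """Simulate the model under a study design and add residual noise.

    Each animal (replicate index) contributes every matrix at its terminal
    time, as in destructive sampling. Reproducible from the seed; with
    sigma1 = sigma2 = 0 the records equal the model observables exactly.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    dose = DoseEvent(design.dose_per_bw, design.body_weight)
    times = np.asarray(design.sample_times, dtype=float)
    sim = simulate(dose, phys, drug, tum, times)

    obs = {m: sim.observable(m) for m in design.matrices}
    rows = []
    for it, t in enumerate(times):
        for rep in range(design.animals_per_time):
            for matrix in design.matrices:
                rows.append((matrix, t, rep, float(obs[matrix][it])))
    df = pd.DataFrame(rows, columns=["matrix", "time_h", "replicate", "conc_nM"])
    Y = df["conc_nM"].to_numpy()
    sd = design.sigma1 + design.sigma2 * Y
    df["conc_nM"] = _draw_noisy(rng, Y, sd, design.noise)
    df["conc_ng_mL"] = convert_units(df["conc_nM"].to_numpy(), "nM->ng_per_mL", drug.MW)
    df["blq"] = False
    ds = StudyDataset(records=df, design=design, MW=drug.MW)
    return censor(ds, design.LLOQ)


def censor(dataset: StudyDataset, LLOQ: float) -> StudyDataset:
    """Flag records whose ng/mL value falls below the LLOQ (idempotent)."""
    if LLOQ < 0:
        raise ModelError("LLOQ must be nonnegative")
    df = dataset.records.copy()
    df["blq"] = df["conc_ng_mL"] < LLOQ
    design = dataset.design
    if design is not None and design.LLOQ != LLOQ:
        design = replace(design, LLOQ=LLOQ)
    return StudyDataset(records=df, design=design, MW=dataset.MW)
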