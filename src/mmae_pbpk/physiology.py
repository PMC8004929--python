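"""Anatomical and physiological constants for the whole-body mouse model.

The model's flow topology follows the anatomy of a closed circulation: the
lung receives the whole cardiac output from the venous blood pool, every
other tissue receives arterial blood from the lung, and the splanchnic organs
(small/large intestine, spleen, pancreas) drain through the hepatic portal
vein into the liver before returning to the venous pool.

Physiological values are shipped as versioned fixtures (see
``data/mouse_28g.csv``); every downstream quantity that depends on them is
fixture-sensitive and documented as such in ``docs/methods.md``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "TISSUES",
    "NONBLOOD_TISSUES",
    "VENOUS_DIRECT",
    "PORTAL",
    "PhysiologyError",
    "TissueRow",
    "FlowSplit",
    "PhysiologyTable",
    "load_physiology",
    "split_flows",
    "tumor_volume",
]

#: Non-blood, non-tumor tissues in state-vector order.
NONBLOOD_TISSUES: tuple[str, ...] = (
    "lung",
    "heart",
    "kidney",
    "brain",
    "muscle",
    "bone",
    "skin",
    "adipose",
    "thymus",
    "small_intestine",
    "large_intestine",
    "spleen",
    "pancreas",
    "liver",
    "other",
)

TISSUES: tuple[str, ...] = ("blood",) + NONBLOOD_TISSUES

#: Tissues whose venous outflow returns directly to the blood pool.
VENOUS_DIRECT: tuple[str, ...] = (
    "heart",
    "kidney",
    "brain",
    "muscle",
    "bone",
    "skin",
    "adipose",
    "thymus",
    "other",
)

#: Tissues drained through the hepatic portal vein into the liver.
PORTAL: tuple[str, ...] = (
    "small_intestine",
    "large_intestine",
    "spleen",
    "pancreas",
)

#: Common aliases accepted in input files.
TISSUE_ALIASES = {"fat": "adipose", "carcass": "other", "si": "small_intestine", "li": "large_intestine"}

_FRACTION_TOL = 1e-9


class PhysiologyError(ValueError):
    """Structural or validation problem in a physiology table."""


@dataclass(frozen=True)
class FlowSplit:
    """Regional blood flow split into its plasma and blood-cell streams."""

    Q_plasma: float  # mL/h
    Q_BC: float  # mL/h


@dataclass(frozen=True)
class TissueRow:
    tissue: str
    V_total: float  # mL
    f_vascular: float
    f_endothelial: float
    f_interstitial: float
    f_cellular: float
    Q_blood: float  # mL/h, whole blood


@dataclass
class PhysiologyTable:
    """Per-tissue volumes, sub-compartment fractions, and blood flows.

    Volumes are mL, flows mL/h, body weight g. The vascular fraction is split
    into plasma and blood-cell volumes with the hematocrit; blood-flow splits
    use the same hematocrit (the circulation is assumed well mixed).
    """

    rows: dict[str, TissueRow]
    hematocrit: float
    body_weight: float
    source: str = "unknown"

    def __post_init__(self) -> None:
        self.validate()

    # -- derived volumes -------------------------------------------------
    def V_total(self, tissue: str) -> float:
        return self.rows[tissue].V_total

    def V_plasma(self, tissue: str) -> float:
        r = self.rows[tissue]
        return r.V_total * r.f_vascular * (1.0 - self.hematocrit)

    def V_BC(self, tissue: str) -> float:
        r = self.rows[tissue]
        return r.V_total * r.f_vascular * self.hematocrit

    def V_endothelial(self, tissue: str) -> float:
        r = self.rows[tissue]
        return r.V_total * r.f_endothelial

    def V_interstitial(self, tissue: str) -> float:
        r = self.rows[tissue]
        return r.V_total * r.f_interstitial

    def V_cellular(self, tissue: str) -> float:
        r = self.rows[tissue]
        return r.V_total * r.f_cellular

    def f_cellular(self, tissue: str) -> float:
        return self.rows[tissue].f_cellular

    # -- derived flows ---------------------------------------------------
    def Q_blood(self, tissue: str) -> float:
        return self.rows[tissue].Q_blood

    def flows(self, tissue: str) -> FlowSplit:
        return split_flows(self.rows[tissue].Q_blood, self.hematocrit)

    def Q_plasma(self, tissue: str) -> float:
        return self.flows(tissue).Q_plasma

    def Q_BC(self, tissue: str) -> float:
        return self.flows(tissue).Q_BC

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        missing = [t for t in TISSUES if t not in self.rows]
        if missing:
            raise PhysiologyError(f"missing tissue rows: {', '.join(missing)}")
        if not 0.0 < self.hematocrit < 1.0:
            raise PhysiologyError(f"hematocrit {self.hematocrit} outside (0, 1)")
        if self.body_weight <= 0:
            raise PhysiologyError("body weight must be positive")
        for t, r in self.rows.items():
            if r.V_total <= 0:
                raise PhysiologyError(f"{t}: nonpositive volume {r.V_total}")
            if r.Q_blood <= 0:
                raise PhysiologyError(f"{t}: nonpositive blood flow {r.Q_blood}")
            fracs = (r.f_vascular, r.f_endothelial, r.f_interstitial, r.f_cellular)
            if any(f < 0 for f in fracs):
                raise PhysiologyError(f"{t}: negative sub-compartment fraction")
            resid = sum(fracs) - 1.0
            if abs(resid) > _FRACTION_TOL:
                raise PhysiologyError(
                    f"{t}: sub-compartment fractions sum to {1.0 + resid:.12g}"
                    f" (residual {resid:.3e})"
                )
        # Cardiac-output conservation: lung flow = sum of arterial supplies.
        arterial = sum(
            self.rows[t].Q_blood for t in NONBLOOD_TISSUES if t != "lung"
        )
        resid = arterial - self.rows["lung"].Q_blood
        if abs(resid) > _FRACTION_TOL * max(1.0, arterial):
            raise PhysiologyError(
                f"regional flows sum to {arterial:.6g} mL/h but lung (cardiac"
                f" output) flow is {self.rows['lung'].Q_blood:.6g} mL/h"
            )


def split_flows(Q_blood: float, hematocrit: float) -> FlowSplit:
    """Split a whole-blood flow into plasma and blood-cell flows.

    Q_plasma = Q·(1−Hct), Q_BC = Q·Hct; the two always sum back to Q.
    """
    if Q_blood <= 0:
        raise PhysiologyError(f"blood flow must be positive, got {Q_blood}")
    if not 0.0 < hematocrit < 1.0:
        raise PhysiologyError(f"hematocrit {hematocrit} outside (0, 1)")
    return FlowSplit(Q_plasma=Q_blood * (1.0 - hematocrit), Q_BC=Q_blood * hematocrit)


def tumor_volume(R_tumor: float) -> float:
    """Volume (mL) of a spherical tumor of radius ``R_tumor`` (cm)."""
    if R_tumor <= 0:
        raise PhysiologyError(f"tumor radius must be positive, got {R_tumor}")
    return 4.0 / 3.0 * math.pi * R_tumor**3


def _bundled(name: str):
    return resources.files("mmae_pbpk.data").joinpath(f"{name}.csv")


def load_physiology(source: str | Path = "mouse_28g") -> PhysiologyTable:
    """Load and validate a physiology table.

    ``source`` is either the name of a bundled fixture (``"mouse_28g"``,
    ``"mouse_28g_literature"``) or a path to a CSV file in the same format:
    ``#``-prefixed metadata lines (``# hematocrit: 0.45``,
    ``# body_weight_g: 28.0``) followed by one labeled row per tissue.
    """
    path: Path | None = None
    if isinstance(source, (str, Path)):
        p = Path(source)
        if p.suffix == ".csv" or p.exists():
            path = p
    if path is None:
        res = _bundled(str(source))
        if not res.is_file():
            raise PhysiologyError(
                f"unknown physiology fixture {source!r}; bundled fixtures are"
                " 'mouse_28g' and 'mouse_28g_literature'"
            )
        text = res.read_text()
        label = str(res)
    else:
        if not path.exists():
            raise PhysiologyError(f"physiology file not found: {path}")
        text = path.read_text()
        label = str(path)

    meta: dict[str, float] = {}
    lines = []
    for line in text.splitlines():
        if line.startswith("#"):
            body = line.lstrip("# ").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                try:
                    meta[key.strip()] = float(val)
                except ValueError:
                    pass
            continue
        if line.strip():
            lines.append(line)
    if "hematocrit" not in meta or "body_weight_g" not in meta:
        raise PhysiologyError(
            f"{label}: missing '# hematocrit:' or '# body_weight_g:' metadata"
        )

    from io import StringIO

    df = pd.read_csv(StringIO("\n".join(lines)))
    required = {
        "tissue",
        "V_total_mL",
        "f_vascular",
        "f_endothelial",
        "f_interstitial",
        "f_cellular",
        "Q_blood_mL_per_h",
    }
    if not required.issubset(df.columns):
        raise PhysiologyError(
            f"{label}: missing columns {sorted(required - set(df.columns))}"
        )

    rows: dict[str, TissueRow] = {}
    for rec in df.itertuples(index=False):
        name = TISSUE_ALIASES.get(str(rec.tissue).strip().lower(), str(rec.tissue).strip().lower())
        if name not in TISSUES:
            raise PhysiologyError(f"{label}: unknown tissue {rec.tissue!r}")
        rows[name] = TissueRow(
            tissue=name,
            V_total=float(rec.V_total_mL),
            f_vascular=float(rec.f_vascular),
            f_endothelial=float(rec.f_endothelial),
            f_interstitial=float(rec.f_interstitial),
            f_cellular=float(rec.f_cellular),
            Q_blood=float(rec.Q_blood_mL_per_h),
        )
    return PhysiologyTable(
        rows=rows,
        hematocrit=meta["hematocrit"],
        body_weight=meta["body_weight_g"],
        source=label,
    )
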