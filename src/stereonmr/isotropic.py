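"""Isotropic NMR cross-validation: NOE distances, 3J couplings, 13C shifts.

NOE cross-peak intensities are converted to distances with the isolated
spin-pair approximation (ISPA), I ∝ r^-6, calibrated against a proton pair
of known separation (typically a geminal methylene pair at 1.78 Å). Multi-conformer model distances use r^-6 averaging,
r_eff = (sum_k w_k r_k^-6)^(-1/6), the slow-internal-motion limit; an r^-3
option exists for flexible pairs. Vicinal couplings are back-calculated
with a Karplus curve J = A cos^2(theta) + B cos(theta) + C. Computed 13C
shifts are linearly rescaled (slope + intercept, per configuration) onto
experiment before scoring, which removes the systematic offset and slope
error of any shift-calculation protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem import Conformer, ConformerEnsemble, internuclear_vector
from .rdc import aic as _aic

__all__ = [
    "NOERecord",
    "JCouplingRecord",
    "KarplusParams",
    "ShiftRecord",
    "NOEScore",
    "ShiftScore",
    "ispa_distance",
    "ensemble_noe_distance",
    "filter_noe_records",
    "score_noe",
    "karplus_j",
    "ensemble_j",
    "score_j",
    "score_shifts",
    "dihedral_angle",
]


@dataclass
class NOERecord:
    pair: tuple[str, str]
    intensity: float  # arbitrary units
    derived_distance: float | None = None  # Angstrom, via ISPA calibration
    include: bool = True

    def __post_init__(self) -> None:
        if self.include and not self.intensity > 0:
            raise ValueError("included NOE records need positive intensity")


@dataclass
class JCouplingRecord:
    pair: tuple[str, str]
    value: float  # Hz
    dihedral_path: tuple[str, str, str, str]
    include: bool = True


@dataclass(frozen=True)
class KarplusParams:
    """J = A cos^2(theta) + B cos(theta) + C, all in Hz.

    Defaults are the classic H-C-C-H parameterisation (A=9.5, B=-1.6,
    C=1.8); substitute calibrated coefficients for other fragments.
    """

    A: float = 9.5
    B: float = -1.6
    C: float = 1.8


@dataclass
class ShiftRecord:
    atom: str
    experimental: float  # ppm
    computed: dict[str, float]  # conformer label -> ppm
    nucleus: str = "13C"
    include: bool = True


def ispa_distance(
    intensity: float, ref_intensity: float, ref_distance: float = 1.78
) -> float:
    """ISPA distance r = r_ref * (I_ref / I)^(1/6)."""
    if intensity <= 0 or ref_intensity <= 0 or ref_distance <= 0:
        raise ValueError("ISPA inputs must all be positive")
    return float(ref_distance * (ref_intensity / intensity) ** (1.0 / 6.0))


def ensemble_noe_distance(
    ensemble: ConformerEnsemble,
    pair: tuple[str, str],
    averaging: str = "r6",
) -> float:
    """Effective NOE distance over the ensemble.

    ``r6``: (sum w r^-6)^(-1/6), slow internal motion (default);
    ``r3``: (sum w r^-3)^(-1/3), fast local reorientation.
    """
    power = {"r6": 6.0, "r3": 3.0}[averaging]
    acc = 0.0
    for w, conf in zip(ensemble.weights, ensemble.conformers):
        _, r = internuclear_vector(conf, pair[0], pair[1])
        acc += w * r ** (-power)
    return float(acc ** (-1.0 / power))


def filter_noe_records(
    records: list[NOERecord],
    graph,
    ensemble: ConformerEnsemble,
    min_bonds: int = 5,
    max_distance: float = 5.0,
) -> list[NOERecord]:
    """Keep NOEs between protons more than ``min_bonds`` bonds apart whose
    ensemble model distance is below ``max_distance`` (Angstrom).

    ``graph`` is a networkx bond graph over atom labels (e.g. from
    :func:`stereonmr.chem.bond_graph`); short-range NOEs carry constitution
    rather than configuration information, and long-distance ones fall
    outside the reliable ISPA regime.
    """
    import networkx as nx

    out = []
    for rec in records:
        if not rec.include:
            continue
        try:
            nbonds = nx.shortest_path_length(graph, rec.pair[0], rec.pair[1])
        except nx.NetworkXNoPath:
            nbonds = np.inf
        if nbonds <= min_bonds:
            continue
        if ensemble_noe_distance(ensemble, rec.pair) >= max_distance:
            continue
        out.append(rec)
    return out


@dataclass
class NOEScore:
    residuals: np.ndarray  # Angstrom
    model_distances: np.ndarray
    target_distances: np.ndarray
    rss: float
    aic: float
    n_obs: int
    n_params: int


def score_noe(
    ensemble: ConformerEnsemble,
    records: list[NOERecord],
    averaging: str = "r6",
    corrected_aic: bool = False,
) -> NOEScore:
    """Distance-residual score for one configuration.

    Residual = ISPA-derived distance minus ensemble model distance; the
    parameter count is the population degrees of freedom, k = m_active - 1.
    Records must be pre-filtered (see :func:`filter_noe_records`) and carry
    ``derived_distance``.
    """
    recs = [r for r in records if r.include]
    if not recs:
        raise ValueError("no NOE records to score")
    target = []
    model = []
    for rec in recs:
        if rec.derived_distance is None:
            raise ValueError(f"NOE record {rec.pair} lacks a derived distance")
        target.append(rec.derived_distance)
        model.append(ensemble_noe_distance(ensemble, rec.pair, averaging))
    target = np.array(target)
    model = np.array(model)
    resid = target - model
    rss = float(resid @ resid)
    k = int(np.count_nonzero(ensemble.weights > 0) - 1)
    return NOEScore(
        residuals=resid,
        model_distances=model,
        target_distances=target,
        rss=rss,
        aic=_aic(rss, len(recs), k, corrected_aic),
        n_obs=len(recs),
        n_params=k,
    )


def dihedral_angle(conformer: Conformer, path: tuple[str, str, str, str]) -> float:
    """Signed dihedral (degrees) along four bonded atoms."""
    p = [conformer.atom(a).position for a in path]
    b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.degrees(np.arctan2(m @ n2, n1 @ n2)))


def karplus_j(dihedral_deg: float, params: KarplusParams = KarplusParams()) -> float:
    c = np.cos(np.radians(dihedral_deg))
    return float(params.A * c * c + params.B * c + params.C)


def ensemble_j(
    ensemble: ConformerEnsemble,
    path: tuple[str, str, str, str],
    params: KarplusParams = KarplusParams(),
) -> float:
    """Population-weighted Karplus coupling over the ensemble."""
    return float(
        sum(
            w * karplus_j(dihedral_angle(c, path), params)
            for w, c in zip(ensemble.weights, ensemble.conformers)
        )
    )


def score_j(
    ensemble: ConformerEnsemble,
    records: list[JCouplingRecord],
    params: KarplusParams = KarplusParams(),
    corrected_aic: bool = False,
):
    """RSS/AIC over 3J_HH residuals (no fitted parameters)."""
    recs = [r for r in records if r.include]
    if not recs:
        raise ValueError("no J records to score")
    model = np.array([ensemble_j(ensemble, r.dihedral_path, params) for r in recs])
    exp = np.array([r.value for r in recs])
    resid = exp - model
    rss = float(resid @ resid)
    return NOEScore(
        residuals=resid,
        model_distances=model,
        target_distances=exp,
        rss=rss,
        aic=_aic(rss, len(recs), 0, corrected_aic),
        n_obs=len(recs),
        n_params=0,
    )


@dataclass
class ShiftScore:
    slope: float
    intercept: float
    residuals: np.ndarray  # ppm, after linear rescaling
    corrected_mae: float
    rss: float
    aic: float
    n_obs: int
    n_params: int
    scaled_computed: np.ndarray = field(default_factory=lambda: np.array([]))


def score_shifts(
    ensemble: ConformerEnsemble,
    records: list[ShiftRecord],
    nucleus: str = "13C",
    corrected_aic: bool = False,
) -> ShiftScore:
    """Linear-scaled chemical-shift score for one configuration.

    Ensemble-averaged computed shifts are regressed onto experiment
    (experimental ≈ slope*computed + intercept, least squares, per
    configuration); the score is the corrected MAE and an AIC over the
    scaled residuals with k = 2 regression parameters. Affine transforms of
    the computed shifts are absorbed by the regression and cannot change
    the score.
    """
    recs = [r for r in records if r.include and r.nucleus == nucleus]
    if len(recs) < 3:
        raise ValueError("need at least 3 included shift records")
    comp = []
    for rec in recs:
        vals = [
            rec.computed[c.label] for c in ensemble.conformers
        ]
        comp.append(float(np.dot(ensemble.weights, vals)))
    comp = np.array(comp)
    exp = np.array([r.experimental for r in recs])
    if np.ptp(comp) < 1e-12:
        raise ValueError("degenerate regression: computed shifts all equal")
    a = np.column_stack([comp, np.ones_like(comp)])
    (slope, intercept), _, _, _ = np.linalg.lstsq(a, exp, rcond=None)
    scaled = slope * comp + intercept
    resid = exp - scaled
    rss = float(resid @ resid)
    return ShiftScore(
        slope=float(slope),
        intercept=float(intercept),
        residuals=resid,
        corrected_mae=float(np.mean(np.abs(resid))),
        rss=rss,
        aic=_aic(rss, len(recs), 2, corrected_aic),
        n_obs=len(recs),
        n_params=2,
        scaled_computed=scaled,
    )


# --------------------------------------------------------------------------
# CSV I/O
# --------------------------------------------------------------------------

def read_noe_csv(path) -> list[NOERecord]:
    """Columns: h1,h2,intensity,include."""
    import pandas as pd

    tab = pd.read_csv(path)
    return [
        NOERecord(
            pair=(str(r["h1"]), str(r["h2"])),
            intensity=float(r["intensity"]),
            include=bool(r.get("include", True)),
        )
        for _, r in tab.iterrows()
    ]


def read_j_csv(path) -> list[JCouplingRecord]:
    """Columns: h1,h2,value_hz,a1,a2,a3,a4,include."""
    import pandas as pd

    tab = pd.read_csv(path)
    return [
        JCouplingRecord(
            pair=(str(r["h1"]), str(r["h2"])),
            value=float(r["value_hz"]),
            dihedral_path=(str(r["a1"]), str(r["a2"]), str(r["a3"]), str(r["a4"])),
            include=bool(r.get("include", True)),
        )
        for _, r in tab.iterrows()
    ]


def read_shift_csv(path, nucleus: str = "13C") -> list[ShiftRecord]:
    """Columns: atom,nucleus,experimental_ppm, then one column per
    conformer label."""
    import pandas as pd

    tab = pd.read_csv(path)
    fixed = {"atom", "nucleus", "experimental_ppm", "include"}
    conf_cols = [c for c in tab.columns if c not in fixed]
    out = []
    for _, r in tab.iterrows():
        out.append(
            ShiftRecord(
                atom=str(r["atom"]),
                experimental=float(r["experimental_ppm"]),
                computed={c: float(r[c]) for c in conf_cols},
                nucleus=str(r.get("nucleus", nucleus)),
                include=bool(r.get("include", True)),
            )
        )
    return out
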