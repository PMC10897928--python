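"""Residual chemical shift anisotropy (RCSA) back-calculation and scoring.

Under weak alignment the observed shift of a carbon moves away from its
isotropic value by the projection of the (traceless) shift tensor onto the
Saupe order matrix:

    RCSA = (2/3) sum_ab S_ab delta'_ab = -(2/3) sum_ab S_ab sigma'_ab

where sigma' is the traceless part of the *shielding* tensor (shift and
shielding carry opposite sign). In practice the alignment strength changes
over time in a self-assembling medium, and the quantity of interest is the
double difference DeltaDelta-RCSA: the day-4 minus day-1 shift change of a
carbon, minus the same change of a reference carbon (ideally one with the
smallest computed CSA) to cancel common-mode isotropic drift.

Values are handled internally in ppb; shielding tensors are supplied in ppm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem import ConformerEnsemble
from .rdc import SaupeTensor, aic as _aic

__all__ = [
    "ShieldingTensor",
    "RCSARecord",
    "RCSAScore",
    "predict_rcsa",
    "reference_ddrcsa",
    "score_rcsa",
    "read_shielding_csv",
    "read_rcsa_csv",
    "transfer_shieldings",
]

PPM_TO_PPB = 1000.0


@dataclass(frozen=True)
class ShieldingTensor:
    """Symmetric shielding tensor (ppm) of one carbon in the molecular frame
    of a named conformer; only the symmetric part contributes to RCSA."""

    carbon: str
    tensor: np.ndarray
    conformer_label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.tensor, float)
        if t.shape != (3, 3):
            raise ValueError("shielding tensor must be 3x3")
        object.__setattr__(self, "tensor", 0.5 * (t + t.T))

    @property
    def isotropic(self) -> float:
        return float(np.trace(self.tensor) / 3.0)

    @property
    def traceless(self) -> np.ndarray:
        return self.tensor - self.isotropic * np.eye(3)


@dataclass
class RCSARecord:
    carbon: str
    value: float  # ppb
    reference: str = "solvent"
    include: bool = True


def predict_rcsa(shielding: ShieldingTensor, tensor: SaupeTensor) -> float:
    """Alignment-induced shift change in ppb (shift convention: -shielding)."""
    return float(
        -(2.0 / 3.0)
        * np.sum(tensor.matrix * shielding.traceless)
        * PPM_TO_PPB
    )


def reference_ddrcsa(
    raw_day1: dict[str, float],
    raw_day4: dict[str, float],
    reference: str,
) -> list[RCSARecord]:
    """Doubly-referenced DeltaDelta-RCSA in ppb from two anisotropic 13C
    shift tables in ppm (weak day-1 vs strong day-4 alignment)."""
    missing = set(raw_day1) ^ set(raw_day4)
    if missing:
        raise ValueError(f"day tables cover different carbons: {sorted(missing)}")
    if reference not in raw_day1:
        raise ValueError(f"reference carbon {reference!r} missing from tables")
    ref_drift = raw_day4[reference] - raw_day1[reference]
    return [
        RCSARecord(
            carbon=c,
            value=((raw_day4[c] - raw_day1[c]) - ref_drift) * PPM_TO_PPB,
            reference=reference,
        )
        for c in raw_day1
    ]


@dataclass
class RCSAScore:
    tensor: SaupeTensor
    back_calculated: np.ndarray
    experimental: np.ndarray
    rss: float  # ppb^2
    aic: float
    n_obs: int
    n_params: int
    tensor_fitted: bool


def _ensemble_prediction_rows(
    ensemble: ConformerEnsemble,
    shieldings: dict[tuple[str, str], ShieldingTensor],
    records: list[RCSARecord],
) -> np.ndarray:
    """Design matrix (n_records x 5): referenced, ensemble-averaged RCSA is
    linear in the Saupe parameters."""

    def row_for(carbon: str, conformer_label: str) -> np.ndarray:
        st = shieldings.get((carbon, conformer_label))
        if st is None:
            raise KeyError(
                f"no shielding tensor for carbon {carbon!r} "
                f"in conformer {conformer_label!r}"
            )
        s = st.traceless
        # -(2/3)*sum_ab S_ab s_ab expressed in the 5-parameter basis
        return (
            -(2.0 / 3.0)
            * PPM_TO_PPB
            * np.array(
                [
                    s[2, 2] - 0.5 * (s[0, 0] + s[1, 1]),
                    0.5 * (s[0, 0] - s[1, 1]),
                    2.0 * s[0, 1],
                    2.0 * s[0, 2],
                    2.0 * s[1, 2],
                ]
            )
        )

    rows = []
    for rec in records:
        acc = np.zeros(5)
        for w, conf in zip(ensemble.weights, ensemble.conformers):
            r = row_for(rec.carbon, conf.label)
            if rec.reference != "solvent":
                r = r - row_for(rec.reference, conf.label)
            acc += w * r
        rows.append(acc)
    return np.array(rows)


def score_rcsa(
    ensemble: ConformerEnsemble,
    shieldings: dict[tuple[str, str], ShieldingTensor],
    records: list[RCSARecord],
    tensor: SaupeTensor | None = None,
    corrected_aic: bool = False,
) -> RCSAScore:
    """Score one candidate configuration against DeltaDelta-RCSA data.

    With ``tensor=None`` the 5-parameter alignment tensor is fitted from the
    RCSA data alone (needs >= 6 included records); otherwise a tensor from
    e.g. the RDC fit is reused and no parameters are counted.
    """
    recs = [r for r in records if r.include]
    fitted = tensor is None
    if fitted and len(recs) < 6:
        raise ValueError("need at least 6 included records to fit the tensor")
    if not recs:
        raise ValueError("no included RCSA records")
    a = _ensemble_prediction_rows(ensemble, shieldings, recs)
    y = np.array([r.value for r in recs])
    if fitted:
        p, _, _, _ = np.linalg.lstsq(a, y, rcond=None)
        tensor = SaupeTensor(p)
        k = 5
    else:
        k = 0
    back = a @ tensor.params
    rss = float(np.sum((back - y) ** 2))
    return RCSAScore(
        tensor=tensor,
        back_calculated=back,
        experimental=y,
        rss=rss,
        aic=_aic(rss, len(recs), k, corrected_aic),
        n_obs=len(recs),
        n_params=k,
        tensor_fitted=fitted,
    )


def transfer_shieldings(
    shieldings: dict[tuple[str, str], ShieldingTensor],
    ensemble: ConformerEnsemble,
    source_label: str,
) -> dict[tuple[str, str], ShieldingTensor]:
    """Rotate one conformer's shielding tensors onto every other conformer.

    Uses the optimal rigid (Kabsch) superposition of heavy atoms between the
    source conformer and each target; an approximation for when quantum
    shielding tensors exist for only one geometry.
    """
    source = next(
        c for c in ensemble.conformers if c.label == source_label
    )
    heavy_src = np.array(
        [a.position for a in source.atoms if a.element != "H"]
    )
    out = dict(shieldings)
    for conf in ensemble.conformers:
        if conf.label == source_label:
            continue
        heavy_tgt = np.array(
            [a.position for a in conf.atoms if a.element != "H"]
        )
        r = _kabsch(heavy_src, heavy_tgt)
        for (carbon, label), st in shieldings.items():
            if label != source_label:
                continue
            out[(carbon, conf.label)] = ShieldingTensor(
                carbon, r @ st.tensor @ r.T, conf.label
            )
    return out


def _kabsch(src: np.ndarray, tgt: np.ndarray) -> np.ndarray:
    """Proper rotation mapping centred ``src`` onto centred ``tgt``."""
    p = src - src.mean(axis=0)
    q = tgt - tgt.mean(axis=0)
    u, _, vt = np.linalg.svd(p.T @ q)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    return vt.T @ np.diag([1.0, 1.0, d]) @ u.T


def read_shielding_csv(path) -> dict[tuple[str, str], ShieldingTensor]:
    """Columns: carbon,conformer_label,xx,yy,zz,xy,xz,yz (ppm)."""
    import pandas as pd

    tab = pd.read_csv(path)
    out = {}
    for _, row in tab.iterrows():
        t = np.array(
            [
                [row["xx"], row["xy"], row["xz"]],
                [row["xy"], row["yy"], row["yz"]],
                [row["xz"], row["yz"], row["zz"]],
            ],
            float,
        )
        key = (str(row["carbon"]), str(row["conformer_label"]))
        out[key] = ShieldingTensor(key[0], t, key[1])
    return out


def read_rcsa_csv(path) -> list[RCSARecord]:
    """Columns: carbon,value,unit(ppb|ppm),reference,include."""
    import pandas as pd

    tab = pd.read_csv(path)
    recs = []
    for _, row in tab.iterrows():
        value = float(row["value"])
        unit = str(row.get("unit", "ppb")).strip().lower()
        if unit == "ppm":
            value *= PPM_TO_PPB
        elif unit != "ppb":
            raise ValueError(f"unknown RCSA unit {unit!r}")
        recs.append(
            RCSARecord(
                carbon=str(row["carbon"]),
                value=value,
                reference=str(row.get("reference", "solvent")),
                include=bool(row.get("include", True)),
            )
        )
    return recs
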