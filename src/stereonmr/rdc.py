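"""Alignment-tensor fitting of one-bond C-H residual dipolar couplings.

Every RDC is linear in the five independent components of the Saupe order
matrix S (symmetric, traceless):

    D_ij = D_max(r) * sum_ab S_ab n_a n_b,
    D_max(r) = -(mu0 h gamma_I gamma_S) / (16 pi^3 r^3)   [Hz]

with n the internuclear unit vector in the molecular frame. Under the
single-alignment-tensor approximation all conformers of a candidate
configuration share one S, and the observable is the population-weighted
average over conformers. For a fixed population vector the tensor is a
linear least-squares (SVD) solution; populations are fitted by variable
projection with a softmax parameterisation inside Levenberg-Marquardt, and
conformer subsets are compared with the Akaike Information Criterion
AIC = n ln(RSS/n) + 2k, k = 5 + (m_active - 1).

Agreement is summarised by the Q factor, rms(D_calc - D_exp) / rms(D_exp).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .chem import Conformer, ConformerEnsemble
from .constants import GAMMA, H_PLANCK, MU0

__all__ = [
    "SaupeTensor",
    "RDCRecord",
    "RDCFitResult",
    "SingleTensorRDCModel",
    "dipolar_constant",
    "predict_rdc",
    "fit_saupe_svd",
    "fit_ensemble_single_tensor",
    "q_factor",
    "aic",
    "read_rdc_csv",
]

RSS_FLOOR = 1e-12  # Hz^2, keeps AIC finite on exact fits
METHYL_AXIS_SCALE = -1.0 / 3.0  # fast C3 rotation projects D_CH onto the axis
# relative singular-value cutoff for the tensor solve: directions that move
# the predicted RDCs by less than 1e-4 of the leading response are treated
# as unmeasured (minimal-norm solution, flagged as rank-deficient); a
# well-posed 5-dof RDC design sits orders of magnitude above this
SVD_RCOND = 1e-4


@dataclass(frozen=True)
class SaupeTensor:
    """Symmetric traceless order matrix, stored as its 5 free parameters
    (Szz, Sxx-Syy, Sxy, Sxz, Syz)."""

    params: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.params, float)
        if p.shape != (5,):
            raise ValueError("SaupeTensor needs exactly 5 parameters")
        object.__setattr__(self, "params", p)

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "SaupeTensor":
        m = np.asarray(m, float)
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("order matrix must be symmetric")
        if abs(np.trace(m)) > 1e-9 * max(1.0, np.abs(m).max()):
            raise ValueError("order matrix must be traceless")
        return cls(
            np.array([m[2, 2], m[0, 0] - m[1, 1], m[0, 1], m[0, 2], m[1, 2]])
        )

    @property
    def matrix(self) -> np.ndarray:
        szz, sxx_yy, sxy, sxz, syz = self.params
        sxx = (sxx_yy - szz) / 2.0
        syy = (-sxx_yy - szz) / 2.0
        return np.array(
            [[sxx, sxy, sxz], [sxy, syy, syz], [sxz, syz, szz]]
        )

    @property
    def eigenvalues(self) -> np.ndarray:
        """Principal order parameters sorted by |value| ascending."""
        w = np.linalg.eigvalsh(self.matrix)
        return w[np.argsort(np.abs(w))]

    def principal_frame(self) -> tuple[np.ndarray, np.ndarray]:
        w, v = np.linalg.eigh(self.matrix)
        order = np.argsort(np.abs(w))
        return w[order], v[:, order]

    def rotated(self, rotation: np.ndarray) -> "SaupeTensor":
        r = np.asarray(rotation, float)
        return SaupeTensor.from_matrix(r @ self.matrix @ r.T)

    def validate(self) -> None:
        m = self.matrix
        assert abs(np.trace(m)) < 1e-12 * max(1.0, np.abs(m).max() + 1.0)
        w = np.linalg.eigvalsh(m)
        if w.min() < -0.5 - 1e-9 or w.max() > 1.0 + 1e-9:
            raise ValueError("order parameters outside physical [-0.5, 1]")


@dataclass
class RDCRecord:
    pair: tuple[str, str]  # (carbon label, hydrogen label)
    value: float  # Hz
    error: float = 0.0  # Hz
    include: bool = True
    is_methyl: bool = False

    def __post_init__(self) -> None:
        if self.error < 0:
            raise ValueError("RDC error must be non-negative")


def dipolar_constant(gamma_i: float, gamma_s: float, r: float) -> float:
    """Maximal static dipolar coupling D_max in Hz for distance r (Angstrom)."""
    if r <= 0:
        raise ValueError("internuclear distance must be positive")
    r_m = r * 1e-10
    return -(MU0 * H_PLANCK * gamma_i * gamma_s) / (16 * np.pi**3 * r_m**3)


def saupe_projection_row(unit: np.ndarray) -> np.ndarray:
    """Row r with sum_ab S_ab n_a n_b = r . params."""
    nx, ny, nz = unit
    return np.array(
        [
            nz * nz - 0.5 * (nx * nx + ny * ny),
            0.5 * (nx * nx - ny * ny),
            2.0 * nx * ny,
            2.0 * nx * nz,
            2.0 * ny * nz,
        ]
    )


def _methyl_geometry(conformer: Conformer, c_label: str, h_label: str):
    """C3-axis unit vector and mean C-H distance for a methyl group.

    The axis points from the attached heavy atom through the methyl carbon
    (the mean of the three C-H unit vectors); fast rotation about it scales
    the axis coupling by -1/3.
    """
    c = conformer.atom(c_label)
    hs = [
        a
        for a in conformer.atoms
        if a.element == "H"
        and np.linalg.norm(a.position - c.position) < 1.35
    ]
    if not hs:
        raise ValueError(f"no hydrogens bonded to methyl carbon {c_label}")
    units = []
    dists = []
    for h in hs:
        v = h.position - c.position
        r = np.linalg.norm(v)
        units.append(v / r)
        dists.append(r)
    axis = np.mean(units, axis=0)
    norm = np.linalg.norm(axis)
    if norm < 1e-8:
        raise ValueError(f"degenerate methyl geometry at {c_label}")
    return axis / norm, float(np.mean(dists))


def _record_row(conformer: Conformer, rec: RDCRecord) -> np.ndarray:
    """Design-matrix row: predicted RDC = row . tensor params."""
    if rec.is_methyl:
        axis, r = _methyl_geometry(conformer, rec.pair[0], rec.pair[1])
        dmax = dipolar_constant(GAMMA["13C"], GAMMA["1H"], r)
        return METHYL_AXIS_SCALE * dmax * saupe_projection_row(axis)
    c = conformer.atom(rec.pair[0])
    h = conformer.atom(rec.pair[1])
    v = h.position - c.position
    r = float(np.linalg.norm(v))
    dmax = dipolar_constant(GAMMA["13C"], GAMMA["1H"], r)
    return dmax * saupe_projection_row(v / r)


def design_blocks(
    ensemble: ConformerEnsemble, records: list[RDCRecord]
) -> np.ndarray:
    """Per-conformer design matrices, shape (m_conformers, n_records, 5).

    The ensemble design matrix for populations w is ``w @ blocks`` and the
    prediction for tensor p is ``(w @ blocks) @ p``; both fits below reuse
    these blocks so the geometry is computed once.
    """
    return np.array(
        [[_record_row(c, r) for r in records] for c in ensemble.conformers]
    )


def predict_rdc(
    ensemble: ConformerEnsemble,
    populations: np.ndarray,
    tensor: SaupeTensor,
    records: list[RDCRecord],
) -> np.ndarray:
    """Population-averaged RDCs (Hz) under a single shared alignment tensor."""
    blocks = design_blocks(ensemble, records)
    w = np.asarray(populations, float)
    if len(w) != len(ensemble):
        raise ValueError("populations length must equal conformer count")
    return np.einsum("k,knp,p->n", w, blocks, tensor.params)


@dataclass
class RDCFitResult:
    """Estimated tensor + populations for one candidate configuration."""

    tensor: SaupeTensor
    populations: np.ndarray
    back_calculated: np.ndarray
    experimental: np.ndarray
    rss: float
    q_factor: float
    aic: float
    n_obs: int
    n_params: int
    rank_deficient: bool = False
    converged: bool = True
    active_conformers: tuple[int, ...] = field(default_factory=tuple)

    def summary(self) -> str:
        w, _ = self.tensor.principal_frame()
        lines = [
            "Single-tensor RDC fit",
            "=" * 52,
            f"observations            {self.n_obs}",
            f"parameters              {self.n_params}",
            f"RSS [Hz^2]              {self.rss:.6g}",
            f"Q factor                {self.q_factor:.4f}",
            f"AIC                     {self.aic:.3f}",
            f"principal order params  "
            + "  ".join(f"{x: .4e}" for x in w),
            f"populations             "
            + "  ".join(f"{x:.3f}" for x in self.populations),
            f"active conformers       {list(self.active_conformers)}",
        ]
        if self.rank_deficient:
            lines.append("WARNING: rank-deficient design matrix "
                         "(minimal-norm tensor reported)")
        if not self.converged:
            lines.append("WARNING: population optimiser did not converge")
        return "\n".join(lines)

    def tensor_json(self) -> dict:
        w, v = self.tensor.principal_frame()
        from scipy.spatial.transform import Rotation

        if np.linalg.det(v) < 0:
            v = v * np.array([1.0, 1.0, -1.0])
        euler = Rotation.from_matrix(v).as_euler("zyz", degrees=True)
        return {
            "params": self.tensor.params.tolist(),
            "eigenvalues": w.tolist(),
            "euler_zyz_deg": euler.tolist(),
        }


def q_factor(back_calculated, experimental) -> float:
    """Q = rms(D_calc - D_exp) / rms(D_exp)."""
    calc = np.asarray(back_calculated, float)
    exp = np.asarray(experimental, float)
    if calc.shape != exp.shape or calc.size == 0:
        raise ValueError("need equal-length non-empty vectors")
    denom = np.sqrt(np.mean(exp**2))
    if denom == 0:
        raise ValueError("experimental vector is all zero")
    return float(np.sqrt(np.mean((calc - exp) ** 2)) / denom)


def aic(rss: float, n_obs: int, n_params: int, corrected: bool = False) -> float:
    """Least-squares AIC ``n ln(RSS/n) + 2k`` (optionally the small-sample
    AICc); RSS is floored at 1e-12 so exact fits stay finite."""
    if n_obs <= 0:
        raise ValueError("n_obs must be positive")
    if rss < 0:
        raise ValueError("RSS must be non-negative")
    rss = max(rss, RSS_FLOOR)
    value = n_obs * np.log(rss / n_obs) + 2 * n_params
    if corrected:
        denom = n_obs - n_params - 1
        if denom > 0:
            value += 2 * n_params * (n_params + 1) / denom
        else:
            value = np.inf
    return float(value)


def _included(records: list[RDCRecord]) -> list[RDCRecord]:
    return [r for r in records if r.include]


def fit_saupe_svd(
    conformer: Conformer, records: list[RDCRecord]
) -> SaupeTensor:
    """Linear least-squares (SVD) order-matrix fit to a single conformer."""
    recs = _included(records)
    if len(recs) < 5:
        raise ValueError("need at least 5 included RDC records")
    a = np.array([_record_row(conformer, r) for r in recs])
    if np.abs(a).max() == 0:
        raise ValueError("all-zero design matrix")
    d = np.array([r.value for r in recs])
    p, _, rank, _ = np.linalg.lstsq(a, d, rcond=SVD_RCOND)
    t = SaupeTensor(p)
    if rank < 5:
        # minimal-norm solution from the truncated SVD
        object.__setattr__(t, "rank_deficient", True)
    return t


def _solve_tensor(a: np.ndarray, d: np.ndarray) -> tuple[np.ndarray, float, int]:
    p, _, rank, _ = np.linalg.lstsq(a, d, rcond=SVD_RCOND)
    resid = a @ p - d
    return p, float(resid @ resid), rank


def _fit_subset(
    blocks: np.ndarray,
    d: np.ndarray,
    subset: tuple[int, ...],
    sigma: np.ndarray | None,
    rng: np.random.Generator,
    n_starts: int,
) -> tuple[np.ndarray, np.ndarray, float, int, bool]:
    """Optimal (weights, tensor, rss) for one conformer subset.

    Variable projection: tensor is solved linearly for each trial population
    vector; populations are softmax-parameterised (first logit pinned to 0)
    and refined with Levenberg-Marquardt from several random starts.
    """
    sub = blocks[list(subset)]
    m = len(subset)
    rhs = d if sigma is None else d / sigma

    def assemble(w):
        a = np.einsum("k,knp->np", w, sub)
        return a if sigma is None else a / sigma[:, None]

    if m == 1:
        p, rss, rank = _solve_tensor(assemble(np.ones(1)), rhs)
        return np.ones(1), p, rss, rank, True

    def residuals(z):
        w = np.exp(np.concatenate(([0.0], np.clip(z, -40.0, 40.0))))
        w = w / w.sum()
        a = assemble(w)
        p, _, _ = _solve_tensor(a, rhs)
        return a @ p - rhs

    best = None
    converged = False
    starts = [np.zeros(m - 1)] + [
        rng.normal(0.0, 1.5, m - 1) for _ in range(n_starts - 1)
    ]
    for z0 in starts:
        try:
            sol = least_squares(residuals, z0, method="lm", xtol=1e-12)
        except Exception:
            continue
        rss = float(sol.fun @ sol.fun)
        if best is None or rss < best[0] - 1e-14:
            best = (rss, sol.x)
            converged = converged or sol.success
        else:
            converged = converged or sol.success
    if best is None:
        raise RuntimeError("population optimiser failed on every start")
    w = np.exp(np.concatenate(([0.0], np.clip(best[1], -40.0, 40.0))))
    w = w / w.sum()
    p, rss, rank = _solve_tensor(assemble(w), rhs)
    return w, p, rss, rank, converged


def fit_ensemble_single_tensor(
    ensemble: ConformerEnsemble,
    records: list[RDCRecord],
    weighted: bool = False,
    corrected_aic: bool = False,
    seed: int = 0,
    n_starts: int = 8,
    max_exhaustive: int = 6,
) -> RDCFitResult:
    """Joint tensor + population fit with AIC model selection over
    conformer subsets.

    Subsets are enumerated exhaustively for ensembles of up to
    ``max_exhaustive`` conformers, otherwise reduced by greedy backward
    elimination; ties break toward fewer parameters, then lexicographic
    subset order. Deterministic for fixed ``seed``.
    """
    recs = _included(records)
    if len(recs) < 5:
        raise ValueError("need at least 5 included RDC records")
    blocks = design_blocks(ensemble, recs)
    d = np.array([r.value for r in recs])
    sigma = None
    if weighted:
        sigma = np.array([max(r.error, 1e-6) for r in recs])
    m = len(ensemble)

    def evaluate(subset):
        w, p, rss, rank, conv = _fit_subset(
            blocks, d, subset, sigma, np.random.default_rng(seed), n_starts
        )
        k = 5 + (len(subset) - 1)
        return {
            "subset": subset,
            "weights": w,
            "params": p,
            "rss": rss,
            "rank": rank,
            "converged": conv,
            "k": k,
            "aic": aic(rss, len(recs), k, corrected_aic),
        }

    if m <= max_exhaustive:
        candidates = [
            evaluate(s)
            for r in range(1, m + 1)
            for s in itertools.combinations(range(m), r)
        ]
        best = min(
            candidates, key=lambda c: (round(c["aic"], 10), c["k"], c["subset"])
        )
    else:
        current = evaluate(tuple(range(m)))
        while len(current["subset"]) > 1:
            trials = [
                evaluate(tuple(x for x in current["subset"] if x != drop))
                for drop in current["subset"]
            ]
            cand = min(
                trials, key=lambda c: (round(c["aic"], 10), c["k"], c["subset"])
            )
            if cand["aic"] < current["aic"]:
                current = cand
            else:
                break
        best = current

    populations = np.zeros(m)
    for idx, w in zip(best["subset"], best["weights"]):
        populations[idx] = w
    tensor = SaupeTensor(best["params"])
    back = np.einsum("k,knp,p->n", populations, blocks, tensor.params)
    rss_plain = float(np.sum((back - d) ** 2))
    return RDCFitResult(
        tensor=tensor,
        populations=populations,
        back_calculated=back,
        experimental=d,
        rss=rss_plain if sigma is None else best["rss"],
        q_factor=q_factor(back, d),
        aic=best["aic"],
        n_obs=len(recs),
        n_params=best["k"],
        rank_deficient=best["rank"] < 5,
        converged=best["converged"],
        active_conformers=best["subset"],
    )


class SingleTensorRDCModel:
    """Model object: one candidate ensemble against measured 1D_CH RDCs.

    Parameters
    ----------
    ensemble : ConformerEnsemble
        Conformers of one relative configuration.
    records : list of RDCRecord
        Experimental couplings; records with ``include=False`` are ignored.

    ``fit()`` returns an :class:`RDCFitResult` carrying the tensor, the
    selected conformer populations, back-calculated couplings, RSS, Q and
    AIC; ``result.summary()`` prints a compact report.
    """

    def __init__(self, ensemble: ConformerEnsemble, records: list[RDCRecord]):
        self.ensemble = ensemble
        self.records = records

    @classmethod
    def from_files(cls, ensemble_path, rdc_path, **kwargs):
        from .chem import read_ensemble

        return cls(read_ensemble(ensemble_path, **kwargs), read_rdc_csv(rdc_path))

    def fit(self, **kwargs) -> RDCFitResult:
        return fit_ensemble_single_tensor(self.ensemble, self.records, **kwargs)


def read_rdc_csv(path) -> list[RDCRecord]:
    """Read RDCs from CSV with columns
    c_atom,h_atom,value_hz,error_hz,include,is_methyl."""
    import pandas as pd

    tab = pd.read_csv(path)
    recs = []
    for _, row in tab.iterrows():
        recs.append(
            RDCRecord(
                pair=(str(row["c_atom"]), str(row["h_atom"])),
                value=float(row["value_hz"]),
                error=float(row.get("error_hz", 0.0) or 0.0),
                include=bool(row.get("include", True)),
                is_methyl=bool(row.get("is_methyl", False)),
            )
        )
    return recs


def write_rdc_csv(records: list[RDCRecord], path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "c_atom": [r.pair[0] for r in records],
            "h_atom": [r.pair[1] for r in records],
            "value_hz": [r.value for r in records],
            "error_hz": [r.error for r in records],
            "include": [r.include for r in records],
            "is_methyl": [r.is_methyl for r in records],
        }
    ).to_csv(path, index=False)
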