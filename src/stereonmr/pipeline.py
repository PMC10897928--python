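"""Configuration ranking across observables and the discrimination report.

The central object is :class:`StereoAssignmentModel`: candidate conformer
ensembles (one per relative configuration) plus an :class:`ObservableSet`
of experimental records. ``fit()`` scores every candidate with each enabled
observable (RDC tensor fit, RCSA, NOE distances, 3J, 13C shifts), ranks
them by AIC and returns a :class:`StereoAssignmentResults` carrying the
per-observable AIC table, the winning configuration, its fitted alignment
tensor and populations, and plotting/report helpers.

The observables are deliberately scored separately — each answers the same
question with different physics — and the RDC AIC is the default ranking
key, RDCs being by far the most discriminating observable in practice. An
opt-in combined score sums per-observable AIC offsets (each observable's
minimum across candidates subtracted) so that no single scale dominates;
this combination is a convenience of this package, not a standard of the
field.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chem import ConformerEnsemble
from .isotropic import (
    JCouplingRecord,
    KarplusParams,
    NOERecord,
    ShiftRecord,
    score_j,
    score_noe,
    score_shifts,
)
from .rcsa import RCSARecord, ShieldingTensor, score_rcsa
from .rdc import RDCFitResult, RDCRecord, fit_ensemble_single_tensor

__all__ = [
    "ObservableSet",
    "ObservableScore",
    "ConfigurationScore",
    "PipelineConfig",
    "StereoAssignmentModel",
    "StereoAssignmentResults",
    "score_configuration",
    "rank_configurations",
    "rank_by_rdc",
    "discrimination_report",
]


@dataclass
class ObservableSet:
    """Typed experimental records for one study.

    ``shifts`` and ``shieldings`` are keyed by configuration name because
    computed shifts / shielding tensors are configuration-specific inputs;
    all other observables are measured once.
    """

    rdc: list[RDCRecord] = field(default_factory=list)
    noe: list[NOERecord] = field(default_factory=list)
    j: list[JCouplingRecord] = field(default_factory=list)
    shifts: dict[str, list[ShiftRecord]] = field(default_factory=dict)
    rcsa: list[RCSARecord] = field(default_factory=list)
    shieldings: dict[str, dict[tuple[str, str], ShieldingTensor]] = field(
        default_factory=dict
    )

    def enabled(self) -> list[str]:
        names = []
        if self.rdc:
            names.append("rdc")
        if self.rcsa and self.shieldings:
            names.append("rcsa")
        if self.noe:
            names.append("noe")
        if self.j:
            names.append("j")
        if self.shifts:
            names.append("shifts")
        return names


@dataclass
class PipelineConfig:
    """Run-level knobs, mirrored into the run manifest."""

    observables: list[str] | None = None  # None = every observable present
    ranking_key: str = "rdc"  # "rdc" | "combined" | any single observable
    temperature: float = 300.0  # K, Boltzmann weighting
    population_threshold: float = 0.05  # discard conformers at/below this
    corrected_aic: bool = False
    weighted_rdc: bool = False
    karplus: KarplusParams = field(default_factory=KarplusParams)
    noe_averaging: str = "r6"
    seed: int = 0

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["karplus"] = [self.karplus.A, self.karplus.B, self.karplus.C]
        return d


@dataclass
class ObservableScore:
    rss: float
    aic: float
    n_obs: int


@dataclass
class ConfigurationScore:
    configuration_name: str
    per_observable: dict[str, ObservableScore]
    rdc_fit: RDCFitResult | None = None
    combined_aic: float = np.nan
    rank: int = 0
    margin: float = np.nan


def score_configuration(
    ensemble: ConformerEnsemble,
    observables: ObservableSet,
    cfg: PipelineConfig | None = None,
    name: str | None = None,
) -> ConfigurationScore:
    """Score one candidate with every enabled observable."""
    cfg = cfg or PipelineConfig()
    enabled = cfg.observables or observables.enabled()
    if not enabled:
        raise ValueError("no observable enabled")
    if name is None:
        name = ensemble.configuration.name if ensemble.configuration else ""
    per: dict[str, ObservableScore] = {}
    rdc_fit = None
    for obs in enabled:
        try:
            if obs == "rdc":
                rdc_fit = fit_ensemble_single_tensor(
                    ensemble,
                    observables.rdc,
                    weighted=cfg.weighted_rdc,
                    corrected_aic=cfg.corrected_aic,
                    seed=cfg.seed,
                )
                per[obs] = ObservableScore(rdc_fit.rss, rdc_fit.aic, rdc_fit.n_obs)
            elif obs == "rcsa":
                sc = score_rcsa(
                    ensemble,
                    observables.shieldings[name],
                    observables.rcsa,
                    corrected_aic=cfg.corrected_aic,
                )
                per[obs] = ObservableScore(sc.rss, sc.aic, sc.n_obs)
            elif obs == "noe":
                sc = score_noe(
                    ensemble,
                    observables.noe,
                    averaging=cfg.noe_averaging,
                    corrected_aic=cfg.corrected_aic,
                )
                per[obs] = ObservableScore(sc.rss, sc.aic, sc.n_obs)
            elif obs == "j":
                sc = score_j(
                    ensemble,
                    observables.j,
                    params=cfg.karplus,
                    corrected_aic=cfg.corrected_aic,
                )
                per[obs] = ObservableScore(sc.rss, sc.aic, sc.n_obs)
            elif obs == "shifts":
                sc = score_shifts(
                    ensemble,
                    observables.shifts[name],
                    corrected_aic=cfg.corrected_aic,
                )
                per[obs] = ObservableScore(sc.rss, sc.aic, sc.n_obs)
            else:
                raise ValueError(f"unknown observable {obs!r}")
        except (KeyError, ValueError) as exc:
            raise RuntimeError(f"scoring observable {obs!r} failed: {exc}") from exc
    return ConfigurationScore(name, per, rdc_fit=rdc_fit)


def rank_configurations(
    scores: list[ConfigurationScore], key: str = "rdc"
) -> list[ConfigurationScore]:
    """Order candidates by ascending AIC under ``key``.

    ``key`` is one observable name or ``"combined"`` (sum of per-observable
    AIC offsets). Ties break on configuration name; margins are AIC
    differences to the next-ranked candidate.
    """
    if len(scores) < 2:
        raise ValueError("ranking needs at least two candidates")
    if key == "combined":
        names = scores[0].per_observable.keys()
        minima = {
            obs: min(s.per_observable[obs].aic for s in scores) for obs in names
        }
        for s in scores:
            s.combined_aic = float(
                sum(s.per_observable[o].aic - minima[o] for o in names)
            )
        sort_value = {s.configuration_name: s.combined_aic for s in scores}
    else:
        for s in scores:
            if key not in s.per_observable:
                raise ValueError(f"observable {key!r} was not scored")
            s.combined_aic = s.per_observable[key].aic
        sort_value = {s.configuration_name: s.combined_aic for s in scores}
    ordered = sorted(
        scores, key=lambda s: (sort_value[s.configuration_name], s.configuration_name)
    )
    for i, s in enumerate(ordered):
        s.rank = i + 1
        s.margin = (
            sort_value[ordered[i + 1].configuration_name]
            - sort_value[s.configuration_name]
            if i + 1 < len(ordered)
            else np.nan
        )
    return ordered


def rank_by_rdc(
    ensembles: dict[str, ConformerEnsemble],
    records: list[RDCRecord],
    seed: int = 0,
    **fit_kwargs,
) -> list[tuple[str, RDCFitResult]]:
    """Fast RDC-only ranking: (name, fit) pairs sorted by ascending AIC."""
    fits = {
        name: fit_ensemble_single_tensor(ens, records, seed=seed, **fit_kwargs)
        for name, ens in ensembles.items()
    }
    return sorted(fits.items(), key=lambda kv: (kv[1].aic, kv[0]))


class StereoAssignmentModel:
    """Cross-validated relative-configuration assignment.

    Parameters
    ----------
    ensembles : dict
        Configuration name -> ConformerEnsemble for every candidate.
    observables : ObservableSet
        Experimental records (only populated observables are scored).
    config : PipelineConfig, optional
        Ranking key, AIC variant, Karplus parameters, seed.
    """

    def __init__(
        self,
        ensembles: dict[str, ConformerEnsemble],
        observables: ObservableSet,
        config: PipelineConfig | None = None,
    ):
        if not ensembles:
            raise ValueError("no candidate ensembles supplied")
        self.ensembles = ensembles
        self.observables = observables
        self.config = config or PipelineConfig()

    def fit(self) -> "StereoAssignmentResults":
        scores = [
            score_configuration(ens, self.observables, self.config, name=name)
            for name, ens in sorted(self.ensembles.items())
        ]
        ranked = rank_configurations(scores, key=self.config.ranking_key)
        return StereoAssignmentResults(self, ranked)


class StereoAssignmentResults:
    """Ranked candidates plus the winner's tensor fit and report writers."""

    def __init__(self, model: StereoAssignmentModel, ranked: list[ConfigurationScore]):
        self.model = model
        self.ranked = ranked

    @property
    def best(self) -> ConfigurationScore:
        return self.ranked[0]

    @property
    def best_configuration(self):
        return self.model.ensembles[self.best.configuration_name].configuration

    def to_frame(self):
        import pandas as pd

        rows = []
        for s in self.ranked:
            row = {
                "configuration": s.configuration_name,
                "rank": s.rank,
                "score_aic": s.combined_aic,
                "margin": s.margin,
            }
            for obs, sc in s.per_observable.items():
                row[f"aic_{obs}"] = sc.aic
                row[f"rss_{obs}"] = sc.rss
                row[f"n_{obs}"] = sc.n_obs
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        best = self.best
        lines = [
            "Stereochemical assignment (AIC ranking, key="
            + self.model.config.ranking_key + ")",
            "=" * 64,
        ]
        cfg = self.best_configuration
        if cfg is not None:
            lines.append(f"best candidate: {cfg.describe()}")
        else:
            lines.append(f"best candidate: {best.configuration_name}")
        lines.append(
            f"margin to runner-up: {best.margin:.3f} AIC units"
        )
        header = f"{'configuration':<16}{'rank':>5}" + "".join(
            f"{('aic_' + o):>14}" for o in best.per_observable
        )
        lines.append(header)
        for s in self.ranked:
            lines.append(
                f"{s.configuration_name:<16}{s.rank:>5}"
                + "".join(
                    f"{s.per_observable[o].aic:>14.3f}" for o in s.per_observable
                )
            )
        if best.rdc_fit is not None:
            lines.append("")
            lines.append(best.rdc_fit.summary())
        return "\n".join(lines)

    # ---- plots ----------------------------------------------------------

    def plot_aic(self, observable: str | None = None, ax=None):
        """Bar chart of per-candidate AIC values."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        key = observable or self.model.config.ranking_key
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        names = [s.configuration_name for s in self.ranked]
        vals = [
            s.combined_aic if key == "combined" else s.per_observable[key].aic
            for s in self.ranked
        ]
        colors = ["#2ca02c" if i == 0 else "#1f77b4" for i in range(len(names))]
        ax.bar(names, vals, color=colors)
        ax.set_ylabel(f"AIC ({key})")
        ax.set_xlabel("relative configuration")
        ax.tick_params(axis="x", rotation=75)
        return ax

    def plot_rdc_correlation(self, ax=None):
        """Back-calculated vs experimental RDCs for the top candidate."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fit = self.best.rdc_fit
        if fit is None:
            raise ValueError("no RDC fit available for the top candidate")
        if ax is None:
            _, ax = plt.subplots(figsize=(4.5, 4.5))
        ax.scatter(fit.experimental, fit.back_calculated, color="#1f77b4")
        lim = 1.1 * np.abs(
            np.concatenate([fit.experimental, fit.back_calculated])
        ).max()
        ax.plot([-lim, lim], [-lim, lim], "k--", lw=0.8)
        ax.set_xlabel("experimental RDC [Hz]")
        ax.set_ylabel("back-calculated RDC [Hz]")
        ax.set_title(
            f"{self.best.configuration_name}: Q = {fit.q_factor:.3f}"
        )
        return ax

    def save_report(self, out_dir, versions: dict | None = None) -> dict:
        """Write the discrimination report (CSV + plots + manifest)."""
        return discrimination_report(self, out_dir, versions=versions)


def discrimination_report(
    results: StereoAssignmentResults, out_dir, versions: dict | None = None
) -> dict:
    """CSV of all candidates, AIC bar plot, RDC correlation plot for the
    top candidate, and a JSON run manifest. Returns the file paths."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    frame = results.to_frame()
    paths["scores_csv"] = str(out / "configuration_scores.csv")
    frame.to_csv(paths["scores_csv"], index=False, float_format="%.10g")

    ax = results.plot_aic()
    ax.figure.tight_layout()
    paths["aic_plot"] = str(out / "aic_ranking.png")
    ax.figure.savefig(paths["aic_plot"], dpi=150)
    plt.close(ax.figure)

    if results.best.rdc_fit is not None:
        ax = results.plot_rdc_correlation()
        ax.figure.tight_layout()
        paths["rdc_correlation_plot"] = str(out / "rdc_correlation.png")
        ax.figure.savefig(paths["rdc_correlation_plot"], dpi=150)
        plt.close(ax.figure)
        paths["tensor_json"] = str(out / "alignment_tensor.json")
        Path(paths["tensor_json"]).write_text(
            json.dumps(results.best.rdc_fit.tensor_json(), indent=2)
        )

    import stereonmr

    manifest = {
        "package_version": getattr(stereonmr, "__version__", "unknown"),
        "config": results.model.config.to_dict(),
        "best_configuration": results.best.configuration_name,
        "n_candidates": len(results.ranked),
    }
    if versions:
        manifest["versions"] = versions
    paths["manifest"] = str(out / "manifest.json")
    Path(paths["manifest"]).write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return paths
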