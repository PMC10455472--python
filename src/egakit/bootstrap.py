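"""Parametric bootstrap of exploratory graph analysis (bootEGA).

Replicate b draws n observations from a multivariate normal with the
observed correlation matrix as covariance (stream seeded ``seed + b``),
computes the replicate's sample correlations, and re-runs the full EGA unit
(penalty path, EBIC selection, Walktrap).  The ensemble of replicate
solutions yields

* the *typical network*: edge-wise median of the replicate weight
  matrices, whose Walktrap solution is the typical (median) structure;
* the sampling distribution of the dimension count (frequency table,
  median, SD, normal-approximation and percentile confidence intervals);
* item stability and structural consistency against the empirical EGA
  solution (see :mod:`egakit.stability`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .communities import DEFAULT_STEPS, DimensionSolution, ega, walktrap_dimensions
from .corr import LabeledCorrelationMatrix, repair_psd
from .exceptions import EstimationError
from .glasso import EstimationSettings, GgmNetwork
from .stability import StabilityReport, stability_report


@dataclass(frozen=True)
class BootstrapSettings:
    """Replicate count, master seed, and CI level."""

    n_boot: int = 500
    seed: int = 0
    confidence: float = 0.95

    def __post_init__(self) -> None:
        if self.n_boot < 2:
            raise ValueError("n_boot must be >= 2")
        if not 0 < self.confidence < 1:
            raise ValueError("confidence must be in (0, 1)")


@dataclass(frozen=True)
class BootstrapEnsemble:
    """Per-replicate networks and dimension solutions."""

    labels: tuple[str, ...]
    solutions: tuple[DimensionSolution, ...]
    weights: np.ndarray = field(repr=False)  # (n_boot, p, p)
    n: int = 0
    seed: int = 0
    redraw_count: int = 0

    @property
    def n_boot(self) -> int:
        return len(self.solutions)

    def dimension_counts(self) -> np.ndarray:
        return np.array([s.n_dims for s in self.solutions])


def parametric_bootstrap(
    corr: LabeledCorrelationMatrix,
    settings: EstimationSettings | None = None,
    boot: BootstrapSettings | None = None,
    steps: int = DEFAULT_STEPS,
) -> BootstrapEnsemble:
    """Run the EGA unit on ``boot.n_boot`` parametric resamples.

    A replicate whose estimation fails outright is redrawn from a fresh
    stream (seeded past the replicate range); more than 10% failures abort
    the run with diagnostics.
    """
    settings = settings or EstimationSettings()
    boot = boot or BootstrapSettings()
    n = corr.require_n()
    sigma = repair_psd(corr.values)
    root = np.linalg.cholesky(sigma)
    max_failures = max(1, int(0.10 * boot.n_boot))
    failures: list[str] = []
    solutions: list[DimensionSolution] = []
    weights = np.empty((boot.n_boot, corr.p, corr.p))
    redraw_seed = boot.seed + boot.n_boot  # redraw streams past the replicate range

    def _draw_and_fit(stream: int):
        rng = np.random.default_rng(stream)
        z = rng.standard_normal((n, corr.p))
        rep = LabeledCorrelationMatrix.from_scores(z @ root.T, corr.labels)
        return ega(rep, settings, steps)

    for b in range(boot.n_boot):
        stream = boot.seed + b + 1  # replicate stream = seed + b
        while True:
            try:
                net, sol = _draw_and_fit(stream)
                break
            except EstimationError as exc:
                failures.append(f"replicate {b + 1} (stream {stream}): {exc}")
                if len(failures) > max_failures:
                    raise EstimationError(
                        f"{len(failures)} of {boot.n_boot} bootstrap replicates failed "
                        f"(> 10%); diagnostics: " + "; ".join(failures[:5])
                    ) from exc
                redraw_seed += 1
                stream = redraw_seed
        solutions.append(sol)
        weights[b] = net.weights
    weights.setflags(write=False)
    return BootstrapEnsemble(
        labels=corr.labels,
        solutions=tuple(solutions),
        weights=weights,
        n=n,
        seed=boot.seed,
        redraw_count=len(failures),
    )


def nonparametric_bootstrap(
    scores,
    labels=None,
    settings: EstimationSettings | None = None,
    boot: BootstrapSettings | None = None,
    steps: int = DEFAULT_STEPS,
) -> BootstrapEnsemble:
    """Row-resampling bootstrap of the EGA unit for raw score matrices.

    Replicate b resamples n rows with replacement (stream ``seed + b``)
    and re-runs EGA on the resampled correlations.  Only available when
    raw data are supplied; the default pipeline is parametric because its
    inputs are correlation matrices.
    """
    settings = settings or EstimationSettings()
    boot = boot or BootstrapSettings()
    base = LabeledCorrelationMatrix.from_scores(scores, labels)
    arr = np.asarray(scores if not hasattr(scores, "to_numpy") else scores.to_numpy(),
                     dtype=float)
    n = arr.shape[0]
    solutions: list[DimensionSolution] = []
    weights = np.empty((boot.n_boot, base.p, base.p))
    failures: list[str] = []
    max_failures = max(1, int(0.10 * boot.n_boot))
    redraw_seed = boot.seed + boot.n_boot
    for b in range(boot.n_boot):
        stream = boot.seed + b + 1
        while True:
            try:
                rng = np.random.default_rng(stream)
                idx = rng.integers(0, n, size=n)
                rep = LabeledCorrelationMatrix.from_scores(arr[idx], base.labels)
                net, sol = ega(rep, settings, steps)
                break
            except EstimationError as exc:
                failures.append(f"replicate {b + 1}: {exc}")
                if len(failures) > max_failures:
                    raise EstimationError(
                        f"{len(failures)} of {boot.n_boot} bootstrap replicates "
                        f"failed (> 10%): " + "; ".join(failures[:5])
                    ) from exc
                redraw_seed += 1
                stream = redraw_seed
        solutions.append(sol)
        weights[b] = net.weights
    weights.setflags(write=False)
    return BootstrapEnsemble(
        labels=base.labels,
        solutions=tuple(solutions),
        weights=weights,
        n=n,
        seed=boot.seed,
        redraw_count=len(failures),
    )


def typical_network(
    ensemble: BootstrapEnsemble, steps: int = DEFAULT_STEPS
) -> tuple[GgmNetwork, DimensionSolution]:
    """Edge-wise median network across replicates and its Walktrap
    solution (the 'typical/median structure')."""
    if ensemble.n_boot == 0:
        raise ValueError("empty ensemble")
    med = np.median(ensemble.weights, axis=0)
    net = GgmNetwork(ensemble.labels, med)
    return net, walktrap_dimensions(net, steps)


@dataclass(frozen=True)
class DimensionCountSummary:
    """Descriptives of the replicate dimension-count distribution."""

    frequencies: dict[int, float]
    median: float
    sd: float
    ci_normal: tuple[float, float]
    ci_percentile: tuple[float, float]
    confidence: float

    def to_dict(self) -> dict:
        return {
            "frequencies": {str(k): v for k, v in sorted(self.frequencies.items())},
            "median": self.median,
            "sd": self.sd,
            "ci_normal": list(self.ci_normal),
            "ci_percentile": list(self.ci_percentile),
            "confidence": self.confidence,
        }

    @property
    def modal_count(self) -> int:
        return max(self.frequencies, key=lambda k: (self.frequencies[k], -k))


def dimension_count_summary(
    ensemble: BootstrapEnsemble, confidence: float = 0.95
) -> DimensionCountSummary:
    """Frequency table (proportions summing to 1), median, SD, and two
    confidence intervals: normal approximation (median +/- z sd) and
    percentile (empirical quantiles, endpoints attained values)."""
    counts = ensemble.dimension_counts()
    uniq, freq = np.unique(counts, return_counts=True)
    props = {int(k): float(c) / len(counts) for k, c in zip(uniq, freq)}
    med = float(np.median(counts))
    sd = float(np.std(counts, ddof=1)) if len(counts) > 1 else 0.0
    z = float(stats.norm.ppf((1 + confidence) / 2))
    lo = (1 - confidence) / 2
    pci = np.quantile(counts, [lo, 1 - lo], method="inverted_cdf")
    return DimensionCountSummary(
        frequencies=props,
        median=med,
        sd=sd,
        ci_normal=(med - z * sd, med + z * sd),
        ci_percentile=(float(pci[0]), float(pci[1])),
        confidence=confidence,
    )


class BootEGA:
    """Bootstrap EGA model for one correlation matrix.

    Parameters
    ----------
    corr : LabeledCorrelationMatrix
        Observed correlations with a known sample size.
    settings : EstimationSettings, optional
        Penalty path and EBIC hyperparameters shared by the empirical fit
        and every replicate.
    steps : int
        Walktrap random-walk length.

    ``fit(n_boot=500, seed=0)`` returns a :class:`BootEGAResults`.
    """

    def __init__(
        self,
        corr: LabeledCorrelationMatrix,
        settings: EstimationSettings | None = None,
        steps: int = DEFAULT_STEPS,
    ):
        self.corr = corr
        self.settings = settings or EstimationSettings()
        self.steps = steps

    def fit(
        self,
        n_boot: int = 500,
        seed: int = 0,
        confidence: float = 0.95,
        reference: DimensionSolution | None = None,
    ) -> "BootEGAResults":
        network, solution = ega(self.corr, self.settings, self.steps)
        reference = reference or solution
        boot = BootstrapSettings(n_boot=n_boot, seed=seed, confidence=confidence)
        ensemble = parametric_bootstrap(self.corr, self.settings, boot, self.steps)
        typ_net, typ_sol = typical_network(ensemble, self.steps)
        return BootEGAResults(
            model=self,
            network=network,
            solution=solution,
            ensemble=ensemble,
            typical=(typ_net, typ_sol),
            counts=dimension_count_summary(ensemble, confidence),
            stability=stability_report(ensemble.solutions, reference),
        )


@dataclass(frozen=True)
class BootEGAResults:
    """Empirical EGA solution plus its bootstrap sampling distribution."""

    model: BootEGA
    network: GgmNetwork
    solution: DimensionSolution
    ensemble: BootstrapEnsemble
    typical: tuple[GgmNetwork, DimensionSolution]
    counts: DimensionCountSummary
    stability: StabilityReport

    @property
    def n_dims(self) -> int:
        return self.solution.n_dims

    @property
    def typical_n_dims(self) -> int:
        return self.typical[1].n_dims

    def summary(self) -> str:
        lines = []
        lines.append("Bootstrap Exploratory Graph Analysis")
        lines.append("=" * 52)
        lines.append(f"items: {self.network.p}   n: {self.ensemble.n}   "
                     f"replicates: {self.ensemble.n_boot}")
        lines.append(f"empirical dimensions: {self.n_dims}   "
                     f"typical (median network): {self.typical_n_dims}")
        lines.append(f"median count: {self.counts.median:.1f}  sd: {self.counts.sd:.3f}  "
                     f"{int(self.counts.confidence * 100)}% normal CI: "
                     f"({self.counts.ci_normal[0]:.2f}, {self.counts.ci_normal[1]:.2f})  "
                     f"percentile CI: ({self.counts.ci_percentile[0]:.0f}, "
                     f"{self.counts.ci_percentile[1]:.0f})")
        lines.append("dimension-count frequencies:")
        for k, v in sorted(self.counts.frequencies.items()):
            lines.append(f"  {k} dims: {100 * v:5.1f}%")
        lines.append("structural consistency:")
        for d, s in enumerate(self.solution.item_sets(), start=1):
            lines.append(f"  dim{d} ({', '.join(sorted(s))}): "
                         f"{100 * self.stability.consistency[f'dim{d}']:5.1f}%")
        unstable = self.stability.unstable_items
        lines.append(f"unstable items (< {self.stability.item_threshold:.2f}): "
                     f"{', '.join(unstable) if unstable else 'none'}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "n": self.ensemble.n,
            "n_boot": self.ensemble.n_boot,
            "seed": self.ensemble.seed,
            "redraws": self.ensemble.redraw_count,
            "empirical": {"n_dims": self.n_dims, "assignment": self.solution.assignment},
            "typical": {
                "n_dims": self.typical_n_dims,
                "assignment": self.typical[1].assignment,
            },
            "counts": self.counts.to_dict(),
            "stability": self.stability.to_dict(),
            "network": {
                "lambda": self.network.lam,
                "gamma": self.network.gamma,
                "ebic": self.network.ebic,
                "edge_count": self.network.edge_count,
            },
        }

    def counts_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"replicate": np.arange(1, self.ensemble.n_boot + 1),
             "n_dims": self.ensemble.dimension_counts()}
        )
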