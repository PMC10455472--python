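"""Correlated common-factor data generator.

Downstream stages (network estimation, community detection, bootstrap
stability) are exercised on data simulated from a correlated-factor model:
p standardized indicators, each loading on one primary factor (optionally a
declared cross-loading on a second), factors correlated by a matrix Phi.
The model-implied correlation matrix is

    Sigma = Lambda Phi Lambda' + Theta,

with Theta diagonal and theta_i = 1 - communality_i, so every indicator has
unit variance and Sigma is itself a correlation matrix.  Scores are drawn
multivariate normal.

The ``wisc_like_preset`` factory returns 15-indicator specifications whose
labels are the standard abbreviations of an intelligence battery's subtests
(SI, VO, ..., CA) and whose implied correlations form a strong positive
manifold in the range observed for such batteries (all pairwise r in
[0, 0.75]).  The ``five_dim_with_crossloaders`` variant splits the loading
of the six subtests known to behave multidimensionally (FW, PS, DS, AR,
LN, CA) near-equally over two factors, so their dimensional placement is
ambiguous by construction and churns across bootstrap replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .corr import LabeledCorrelationMatrix
from .exceptions import SpecificationError

WISC_LABELS = (
    "SI", "VO", "IN", "CO",          # verbal comprehension
    "BD", "VP",                       # visual-spatial
    "MR", "FW", "AR",                # fluid reasoning (+ AR)
    "DS", "PS", "LN",                # working memory
    "CD", "SS", "CA",                # processing speed
)


@dataclass(frozen=True)
class FactorModelSpec:
    """A correlated common-factor model for p standardized indicators.

    Parameters
    ----------
    loadings : ndarray, shape (p, k)
        Factor loading matrix Lambda.  Each row has one primary loading;
        additional nonzero entries must be declared via ``cross_loadings``.
    factor_corr : ndarray, shape (k, k)
        Factor correlation matrix Phi (symmetric, unit diagonal, PSD).
    labels : tuple of str
        Indicator names.
    cross_loadings : tuple of (label, factor_index, value)
        Declared secondary loadings (bookkeeping for which items are
        intentionally multidimensional; entries must match ``loadings``).
    """

    loadings: np.ndarray = field(repr=False)
    factor_corr: np.ndarray = field(repr=False)
    labels: tuple[str, ...]
    cross_loadings: tuple[tuple[str, int, float], ...] = ()

    def __post_init__(self) -> None:
        lam = np.atleast_2d(np.asarray(self.loadings, dtype=float))
        phi = np.atleast_2d(np.asarray(self.factor_corr, dtype=float))
        p, k = lam.shape
        if phi.shape != (k, k):
            raise SpecificationError(
                f"factor_corr shape {phi.shape} does not match {k} factors"
            )
        if len(self.labels) != p:
            raise SpecificationError(f"{len(self.labels)} labels for {p} indicators")
        if np.max(np.abs(phi - phi.T)) > 1e-10:
            raise SpecificationError("factor_corr must be symmetric")
        if np.max(np.abs(np.diag(phi) - 1.0)) > 1e-10:
            raise SpecificationError("factor_corr must have a unit diagonal")
        w = np.linalg.eigvalsh(phi)
        if w.min() < -1e-10:
            raise SpecificationError(
                f"factor_corr is not positive semi-definite (min eigenvalue {w.min():.3e})"
            )
        if np.max(np.abs(lam)) > 1.0:
            bad = np.unravel_index(np.argmax(np.abs(lam)), lam.shape)
            raise SpecificationError(
                f"loading for item {self.labels[bad[0]]!r} on factor {bad[1]} "
                f"exceeds 1 in magnitude"
            )
        comm = np.einsum("if,fg,ig->i", lam, phi, lam)
        high = np.where(comm > 1.0 + 1e-10)[0]
        if high.size:
            i = int(high[0])
            raise SpecificationError(
                f"item {self.labels[i]!r} has communality {comm[i]:.4f} > 1 "
                f"(negative uniqueness)"
            )
        lam.setflags(write=False)
        phi.setflags(write=False)
        object.__setattr__(self, "loadings", lam)
        object.__setattr__(self, "factor_corr", phi)
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))
        object.__setattr__(
            self,
            "cross_loadings",
            tuple((str(a), int(b), float(c)) for a, b, c in self.cross_loadings),
        )

    @property
    def p(self) -> int:
        return self.loadings.shape[0]

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]

    @property
    def uniqueness(self) -> np.ndarray:
        """Residual variances Theta = 1 - communality (always standardized)."""
        lam, phi = self.loadings, self.factor_corr
        return 1.0 - np.einsum("if,fg,ig->i", lam, phi, lam)

    def primary_factor(self) -> dict[str, int]:
        """Map each item to its primary factor (largest absolute loading,
        excluding declared cross-loading entries where the tie is exact)."""
        out = {}
        cross = {(lab, f) for lab, f, _ in self.cross_loadings}
        for i, lab in enumerate(self.labels):
            row = np.abs(self.loadings[i])
            order = np.argsort(-row, kind="stable")
            pick = next((int(f) for f in order if (lab, int(f)) not in cross), int(order[0]))
            out[lab] = pick
        return out

    @classmethod
    def simple(
        cls,
        n_factors: int,
        items_per_factor: int,
        loading: float = 0.70,
        factor_corr: float | np.ndarray = 0.0,
        labels: tuple[str, ...] | None = None,
    ) -> "FactorModelSpec":
        """Balanced design: ``items_per_factor`` pure indicators per factor,
        all primary loadings equal, exchangeable factor correlation."""
        p = n_factors * items_per_factor
        lam = np.zeros((p, n_factors))
        for f in range(n_factors):
            lam[f * items_per_factor:(f + 1) * items_per_factor, f] = loading
        if np.isscalar(factor_corr):
            phi = np.full((n_factors, n_factors), float(factor_corr))
            np.fill_diagonal(phi, 1.0)
        else:
            phi = np.asarray(factor_corr, dtype=float)
        if labels is None:
            labels = tuple(f"F{f + 1}I{i + 1}" for f in range(n_factors) for i in range(items_per_factor))
        return cls(lam, phi, labels)


@dataclass(frozen=True)
class SyntheticDataset:
    """n x p matrix of continuous indicator scores plus its provenance."""

    scores: np.ndarray = field(repr=False)
    labels: tuple[str, ...]
    spec: FactorModelSpec
    seed: int
    n: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, columns=list(self.labels))

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.15g")

    def correlation(self) -> LabeledCorrelationMatrix:
        return LabeledCorrelationMatrix.from_scores(self.to_dataframe())


def implied_correlation(spec: FactorModelSpec) -> LabeledCorrelationMatrix:
    """Population correlation matrix Sigma = Lambda Phi Lambda' + Theta.

    The returned matrix carries ``n=None``; attach a sample size with
    ``with_n`` before treating it as data.
    """
    lam, phi = spec.loadings, spec.factor_corr
    sigma = lam @ phi @ lam.T
    np.fill_diagonal(sigma, 1.0)
    return LabeledCorrelationMatrix(spec.labels, sigma, None)


def sample_scores(spec: FactorModelSpec, n: int, seed: int) -> SyntheticDataset:
    """Draw n iid multivariate-normal score vectors with the implied
    correlation structure; bit-for-bit reproducible given (spec, n, seed)."""
    if n < 2:
        raise ValueError(f"need n >= 2 observations, got {n}")
    sigma = implied_correlation(spec).values
    w, v = np.linalg.eigh(sigma)
    if w.min() < -1e-10:
        raise SpecificationError(
            f"implied correlation matrix is not PSD (min eigenvalue {w.min():.3e})"
        )
    root = v * np.sqrt(np.clip(w, 0.0, None))
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, spec.p))
    return SyntheticDataset(z @ root.T, spec.labels, spec, int(seed), int(n))


def _wisc_blocks_three() -> list[list[str]]:
    return [
        ["SI", "VO", "IN", "CO"],                                # VC
        ["BD", "VP", "MR", "FW", "AR", "DS", "PS", "LN"],        # PR (VS+FR+WM)
        ["CD", "SS", "CA"],                                      # PS (speed)
    ]


def _wisc_blocks_five() -> list[list[str]]:
    return [
        ["SI", "VO", "IN", "CO"],   # VC
        ["BD", "VP"],               # VS
        ["MR", "FW", "AR"],         # FR
        ["DS", "PS", "LN"],         # WM
        ["CD", "SS", "CA"],         # speed
    ]


# Loading patterns for the six multidimensional subtests in the
# crossloader preset: item -> [(factor, loading), ...]; the first entry is
# the primary factor, the rest are declared cross-loadings.  The near-equal
# split over two factors makes each item's community assignment genuinely
# ambiguous at realistic sample sizes.
_CROSSLOADERS: dict[str, list[tuple[int, float]]] = {
    "FW": [(2, 0.45), (0, 0.45)],   # figure weights: reasoning <-> verbal
    "AR": [(2, 0.42), (0, 0.42)],   # arithmetic: reasoning <-> verbal
    "DS": [(3, 0.45), (0, 0.40)],   # digit span: working memory <-> verbal
    "PS": [(3, 0.45), (4, 0.40)],   # picture span: working memory <-> speed
    "LN": [(3, 0.42), (0, 0.42)],   # letter-number: working memory <-> verbal
    "CA": [(4, 0.45), (2, 0.42)],   # cancellation: speed <-> reasoning
}


def wisc_like_preset(structure_kind: str) -> FactorModelSpec:
    """15-subtest factor model presets emulating an intelligence battery.

    ``three_dim``
        Three clearly separated clusters: verbal comprehension (SI, VO, IN,
        CO), perceptual reasoning (BD, VP, MR, FW, AR, DS, PS, LN), and
        processing speed (CD, SS, CA); pure indicators, loadings 0.70.
    ``five_dim``
        The publisher-style five factors VC/VS/FR/WM/speed with a strong
        positive manifold (factor correlations 0.40-0.65), pure indicators.
    ``five_dim_with_crossloaders``
        The five-factor layout with the six empirically multidimensional
        subtests (FW, AR, DS, PS, LN, CA) loading near-equally on two
        factors each (0.40-0.45), so their community placement churns
        across bootstrap replicates the way borderline subtests do in
        real batteries.
    """
    if structure_kind == "three_dim":
        blocks = _wisc_blocks_three()
        phi = np.array([
            [1.00, 0.55, 0.40],
            [0.55, 1.00, 0.45],
            [0.40, 0.45, 1.00],
        ])
        cross: dict[str, list[tuple[int, float]]] = {}
    elif structure_kind in ("five_dim", "five_dim_with_crossloaders"):
        blocks = _wisc_blocks_five()
        # strong positive manifold: cognitive factors intercorrelate
        # 0.55-0.65, processing speed 0.40-0.45, echoing published
        # intelligence batteries
        #            VC    VS    FR    WM    speed
        phi = np.array([
            [1.00, 0.55, 0.55, 0.55, 0.40],
            [0.55, 1.00, 0.65, 0.60, 0.40],
            [0.55, 0.65, 1.00, 0.60, 0.40],
            [0.55, 0.60, 0.60, 1.00, 0.45],
            [0.40, 0.40, 0.40, 0.45, 1.00],
        ])
        cross = dict(_CROSSLOADERS) if structure_kind == "five_dim_with_crossloaders" else {}
    else:
        raise ValueError(
            "structure_kind must be one of 'three_dim', 'five_dim', "
            f"'five_dim_with_crossloaders'; got {structure_kind!r}"
        )

    k = len(blocks)
    lam = np.zeros((len(WISC_LABELS), k))
    block_of = {lab: b for b, items in enumerate(blocks) for lab in items}
    for i, lab in enumerate(WISC_LABELS):
        lam[i, block_of[lab]] = 0.70
    declared = []
    for lab, pattern in cross.items():
        i = WISC_LABELS.index(lab)
        lam[i, :] = 0.0
        for j, (factor, value) in enumerate(pattern):
            lam[i, factor] = value
            if j > 0:
                declared.append((lab, factor, value))
    return FactorModelSpec(lam, phi, WISC_LABELS, tuple(declared))
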