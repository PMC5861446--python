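"""Stoichiometry inference from photobleaching step-count histograms.

The number of bleaching steps observed for a colocalized protein spot is an
imperfect readout of the number of bound protein molecules: only a fraction
``p_label`` of the protein pool carries a fluorescent tag, and a fraction of
binding events are contributed by protein dimers, so a complex with ``k``
bound molecules can bleach in anywhere from 0 to ``2k`` steps.  This module
implements the forward model (true count -> observed step distribution), its
inverse for the dimer fraction, histogram construction with binomial error
bars, the two-step/one-step ratio statistic, truncated-geometric fitting of
the nonspecific-binding tail, and a mixture model over true counts.

Model
-----
Each of the ``k`` binding events on an RNA is independently a monomer (with
probability ``1 - d``) or a dimer (``d``); every protomer is independently
labelled with probability ``p_label``.  The per-event distribution of
labelled molecules is therefore

    q0 = (1 - d)(1 - p) + d (1 - p)^2
    q1 = (1 - d) p + 2 d p (1 - p)
    q2 = d p^2

and the distribution of observed step counts for ``k`` events is the k-fold
convolution of ``(q0, q1, q2)``.  Spots with zero labelled molecules are
invisible, so observed distributions condition on at least one step.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

#: Histogram classes in display order: exact counts 1-5, then the
#: more-than-five class and the undetermined class.
STEP_CLASSES: tuple[str, ...] = ("1", "2", "3", "4", "5", ">5", "x")


def _normalize_class(label) -> str:
    """Map a classification (int or string) onto a canonical class label."""
    if isinstance(label, (int, np.integer)):
        if label < 1:
            raise ValueError(f"step count classes start at 1, got {label}")
        return str(int(label)) if label <= 5 else ">5"
    label = str(label)
    if label not in STEP_CLASSES:
        raise ValueError(f"unknown classification {label!r}")
    return label


# ---------------------------------------------------------------------------
# labeling / dimerization model
# ---------------------------------------------------------------------------

def per_event_label_pmf(p_label: float, d: float) -> np.ndarray:
    """Distribution (q0, q1, q2) of labelled molecules per binding event."""
    if not 0.0 <= p_label <= 1.0:
        raise ValueError("p_label must be in [0, 1]")
    if not 0.0 <= d <= 1.0:
        raise ValueError("dimer fraction must be in [0, 1]")
    p, q = p_label, 1.0 - p_label
    return np.array([
        (1.0 - d) * q + d * q * q,
        (1.0 - d) * p + 2.0 * d * p * q,
        d * p * p,
    ])


def infer_dimer_fraction(f2_observed: float, p_label: float) -> float:
    """Invert the labeling model for the true dimer fraction ``d``.

    Among protein-only spots (single binding event) that show at least one
    bleaching step, the fraction showing exactly two steps is

        f2 = d p^2 / [ (1-d) p + 2 d p (1-p) + d p^2 ] = d p / (1 + d (1-p))

    which is strictly increasing in ``d`` and solved in closed form.

    Parameters
    ----------
    f2_observed : fraction of visible protein-only spots bleaching in two
        steps (the control measurement; 0.12 in the reference dataset).
    p_label : fraction of the protein pool carrying a tag (0.58 there).

    Raises
    ------
    ValueError
        If ``f2_observed`` exceeds the largest value attainable at the given
        labelled fraction (reached at d = 1: ``p / (2 - p)``).
    """
    if not 0.0 <= f2_observed < 1.0:
        raise ValueError("f2_observed must be in [0, 1)")
    if not 0.0 < p_label <= 1.0:
        raise ValueError("p_label must be in (0, 1]")
    f2_max = p_label / (2.0 - p_label)
    if f2_observed > f2_max + 1e-12:
        raise ValueError(
            f"two-step fraction {f2_observed} unattainable at p_label={p_label}: "
            f"maximum (all-dimer) value is {f2_max:.4f}"
        )
    d = f2_observed / (p_label - f2_observed * (1.0 - p_label))
    return min(d, 1.0)


@dataclass(frozen=True)
class ExpectedStepDistribution:
    """Observed step-count distribution for ``k`` true binding events.

    ``probabilities[j]`` is P(j observed steps) for j = 0..2k;
    ``conditional[j]`` is P(j steps | at least one step) for j = 1..2k
    (index 0 is zero by construction).
    """

    k: int
    p_label: float
    d: float
    probabilities: np.ndarray
    conditional: np.ndarray

    def two_step_ratio(self) -> float:
        """Conditional P(2 steps)/P(1 step), in percent."""
        if self.k < 1 or self.conditional[1] == 0.0:
            raise ValueError("one-step probability is zero")
        return 100.0 * self.conditional[2] / self.conditional[1]


def expected_step_distribution(k: int, p_label: float, d: float) -> ExpectedStepDistribution:
    """Exact observed-step distribution for ``k`` bound molecules.

    Convolves the per-event labelled-count pmf ``k`` times; no sampling.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    q = per_event_label_pmf(p_label, d)
    probs = np.array([1.0])
    for _ in range(k):
        probs = np.convolve(probs, q)
    conditional = probs.copy()
    conditional[0] = 0.0
    visible = conditional.sum()
    if visible > 0.0:
        conditional /= visible
    return ExpectedStepDistribution(k=k, p_label=p_label, d=d,
                                    probabilities=probs, conditional=conditional)


@dataclass(frozen=True)
class LabelingModel:
    """Partial labeling plus dimerization, the map from true to observed counts.

    Built either directly from (p_label, d) or, as in practice, from the
    protein-only control: the observed fraction of visible protein spots
    bleaching in two steps (``f2_observed``) determines ``d`` through
    :func:`infer_dimer_fraction`.
    """

    p_label: float
    d: float
    f2_observed: float | None = None

    @classmethod
    def from_observed(cls, f2_observed: float, p_label: float) -> "LabelingModel":
        d = infer_dimer_fraction(f2_observed, p_label)
        return cls(p_label=p_label, d=d, f2_observed=f2_observed)

    def step_distribution(self, k: int) -> ExpectedStepDistribution:
        return expected_step_distribution(k, self.p_label, self.d)

    def forward_two_step_fraction(self) -> float:
        """Observed two-step fraction among visible protein-only spots."""
        return float(self.step_distribution(1).conditional[2])


# ---------------------------------------------------------------------------
# histograms
# ---------------------------------------------------------------------------

@dataclass
class StepHistogram:
    """Per-class bleach-step counts over the RNA spots of an experiment set.

    Frequencies and binomial error bars are expressed as percentages of the
    total number of RNA spots; the error bar for class c with count n_c out
    of N spots is 100 * sqrt(N p_c (1 - p_c)) / N with p_c = n_c / N.
    """

    counts: dict[str, int]
    total_rna_spots: int

    def __post_init__(self) -> None:
        self.counts = {c: int(self.counts.get(c, 0)) for c in STEP_CLASSES}
        if self.total_rna_spots <= 0:
            raise ValueError("total_rna_spots must be positive")
        if sum(self.counts.values()) > self.total_rna_spots:
            raise ValueError("classified spots exceed total RNA spots")

    @property
    def n_classified(self) -> int:
        return sum(self.counts.values())

    @property
    def frequencies(self) -> dict[str, float]:
        n = self.total_rna_spots
        return {c: 100.0 * k / n for c, k in self.counts.items()}

    @property
    def error_bars(self) -> dict[str, float]:
        n = self.total_rna_spots
        out = {}
        for c, k in self.counts.items():
            p = k / n
            out[c] = 100.0 * math.sqrt(n * p * (1.0 - p)) / n
        return out

    @property
    def colocalized_fraction(self) -> float:
        """Percent of RNA spots with a classified protein spot (incl. 'x')."""
        return 100.0 * self.n_classified / self.total_rna_spots

    def determined_counts(self) -> dict[str, int]:
        """Counts excluding the undetermined 'x' class."""
        return {c: k for c, k in self.counts.items() if c != "x"}

    def to_dict(self) -> dict:
        return {
            "counts": dict(self.counts),
            "total_rna_spots": self.total_rna_spots,
            "frequencies_percent": self.frequencies,
            "error_bars_percent": self.error_bars,
            "colocalized_fraction_percent": self.colocalized_fraction,
        }


def build_histogram(classifications: Iterable, n_rna_spots: int) -> StepHistogram:
    """Tally per-spot classifications (ints or '>5'/'x') into a histogram."""
    counts: dict[str, int] = {c: 0 for c in STEP_CLASSES}
    for label in classifications:
        counts[_normalize_class(label)] += 1
    return StepHistogram(counts=counts, total_rna_spots=n_rna_spots)


def two_step_ratio(hist_or_dist) -> float:
    """Two-step to one-step ratio, in percent.

    Accepts a :class:`StepHistogram` (ratio of class counts) or an
    :class:`ExpectedStepDistribution` (ratio of conditional probabilities).
    """
    if isinstance(hist_or_dist, ExpectedStepDistribution):
        return hist_or_dist.two_step_ratio()
    if isinstance(hist_or_dist, StepHistogram):
        n1 = hist_or_dist.counts["1"]
        if n1 == 0:
            raise ValueError("one-step class is empty")
        return 100.0 * hist_or_dist.counts["2"] / n1
    raise TypeError(f"unsupported input {type(hist_or_dist)!r}")


# ---------------------------------------------------------------------------
# geometric tail of nonspecific binding
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeometricFit:
    """Truncated-geometric fit to the higher-order tail of a step histogram."""

    support: tuple[int, ...]
    p_geo: float
    log_likelihood: float
    degenerate: bool = False

    def pmf(self) -> np.ndarray:
        return _truncated_geometric_pmf(self.p_geo, self.support)


def _truncated_geometric_pmf(p: float, support: Sequence[int]) -> np.ndarray:
    n = np.asarray(support, dtype=float)
    w = p * (1.0 - p) ** (n - n.min())
    return w / w.sum()


def fit_geometric_tail(hist: StepHistogram | Mapping[str, int],
                       support: Sequence[int] = (2, 3, 4, 5)) -> GeometricFit:
    """Maximum-likelihood truncated geometric over the stated step classes.

    The geometric parameter characterises the roll-off of nonspecific
    multi-molecule binding (classes n = 2..5 by default); the distribution
    is renormalized over the support.
    """
    counts_map = hist.counts if isinstance(hist, StepHistogram) else dict(hist)
    support = tuple(int(n) for n in support)
    if any(n > 5 or n < 1 for n in support):
        raise ValueError("support must lie within the exact-count classes 1..5")
    counts = np.array([counts_map.get(str(n), 0) for n in support], dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("no counts over the requested support")

    n = np.asarray(support, dtype=float) - min(support)
    if counts[1:].sum() == 0:
        # all mass at the lower edge: MLE is the boundary p -> 1
        return GeometricFit(support=support, p_geo=1.0,
                            log_likelihood=0.0, degenerate=True)

    def nll(p: float) -> float:
        pmf = _truncated_geometric_pmf(p, support)
        return -float(np.sum(counts * np.log(pmf)))

    res = optimize.minimize_scalar(nll, bounds=(1e-9, 1.0 - 1e-9), method="bounded",
                                   options={"xatol": 1e-10})
    return GeometricFit(support=support, p_geo=float(res.x),
                        log_likelihood=-float(res.fun))


# ---------------------------------------------------------------------------
# mixture of true stoichiometries
# ---------------------------------------------------------------------------

class StoichiometryMixtureModel:
    """Mixture of true bound-molecule counts fitted to a step histogram.

    Observed (conditional-on-visible) class probabilities are modelled as a
    simplex-weighted mixture of the expected step distributions for each
    candidate ``k``, optionally plus a truncated-geometric component for
    nonspecific binding.  ``fit`` maximises the multinomial likelihood over
    the weights (and the geometric parameter if enabled); 'x'-class spots
    are excluded.

    Parameters
    ----------
    hist : StepHistogram
        Observed histogram.
    model : LabelingModel
        Labeling/dimerization parameters, held fixed during the fit.
    components : candidate true counts k (e.g. (1, 2)).
    geometric_tail : include a truncated-geometric background component
        over classes 2..5.
    """

    def __init__(self, hist: StepHistogram, model: LabelingModel,
                 components: Sequence[int] = (1, 2),
                 geometric_tail: bool = False) -> None:
        if len(components) == 0:
            raise ValueError("components must be non-empty")
        self.hist = hist
        self.model = model
        self.components = tuple(int(k) for k in components)
        self.geometric_tail = geometric_tail
        self._class_labels = [c for c in STEP_CLASSES if c != "x"]
        self._counts = np.array([hist.counts[c] for c in self._class_labels], float)
        self._comp_probs = np.stack([
            self._binned_conditional(model.step_distribution(k)) for k in self.components
        ])
        self._visible = np.array([
            1.0 - model.step_distribution(k).probabilities[0] for k in self.components
        ])

    def _binned_conditional(self, dist: ExpectedStepDistribution) -> np.ndarray:
        """Bin a conditional step distribution into classes 1..5, '>5'."""
        probs = np.zeros(6)
        cond = dist.conditional
        for j in range(1, len(cond)):
            probs[min(j, 6) - 1] += cond[j]
        return probs

    def _geo_probs(self, p_geo: float) -> np.ndarray:
        probs = np.zeros(6)
        probs[1:5] = _truncated_geometric_pmf(p_geo, (2, 3, 4, 5))
        return probs

    def _mixture_probs(self, weights: np.ndarray, p_geo: float | None) -> np.ndarray:
        comps = self._comp_probs
        if self.geometric_tail:
            comps = np.vstack([comps, self._geo_probs(p_geo)])
        return weights @ comps

    def _nll(self, theta: np.ndarray) -> float:
        w = _softmax(theta[: self._n_comp])
        p_geo = _expit(theta[-1]) if self.geometric_tail else None
        probs = self._mixture_probs(w, p_geo)
        probs = np.clip(probs, 1e-300, None)
        return -float(self._counts @ np.log(probs))

    @property
    def _n_comp(self) -> int:
        return len(self.components) + (1 if self.geometric_tail else 0)

    def fit(self, n_restarts: int = 4) -> "MixtureResults":
        rng = np.random.default_rng(0)
        best = None
        n_par = self._n_comp + (1 if self.geometric_tail else 0)
        starts = [np.zeros(n_par)] + [rng.normal(scale=1.0, size=n_par)
                                      for _ in range(n_restarts - 1)]
        for x0 in starts:
            res = optimize.minimize(self._nll, x0, method="Nelder-Mead",
                                    options={"xatol": 1e-8, "fatol": 1e-10,
                                             "maxiter": 4000})
            if best is None or res.fun < best.fun:
                best = res
        w = _softmax(best.x[: self._n_comp])
        p_geo = float(_expit(best.x[-1])) if self.geometric_tail else None

        # non-identifiability: two components with numerically equal class
        # distributions, or a likelihood flat across the simplex
        identifiable = True
        comps = self._comp_probs
        if self.geometric_tail:
            comps = np.vstack([comps, self._geo_probs(p_geo)])
        for i, j in itertools.combinations(range(len(comps)), 2):
            if np.abs(comps[i] - comps[j]).sum() < 1e-9:
                identifiable = False
        return MixtureResults(model=self, observed_weights=w, p_geo=p_geo,
                              log_likelihood=-float(best.fun),
                              identifiable=identifiable)


@dataclass
class MixtureResults:
    """Fitted mixture weights over true bound-molecule counts.

    ``observed_weights`` are weights among *visible* complexes (at least one
    labelled molecule); ``population_weights`` rescales the stoichiometry
    components by 1/P(visible | k) to estimate weights over all complexes,
    including those invisible because no bound molecule was labelled.
    """

    model: StoichiometryMixtureModel
    observed_weights: np.ndarray
    p_geo: float | None
    log_likelihood: float
    identifiable: bool

    @property
    def component_labels(self) -> list[str]:
        labels = [f"k={k}" for k in self.model.components]
        if self.model.geometric_tail:
            labels.append("geometric")
        return labels

    @property
    def population_weights(self) -> np.ndarray:
        """Weights over all complexes, corrected for invisible zero-label ones.

        Only the stoichiometry components are rescaled; a geometric-tail
        component, which describes already-visible background spots, is
        dropped and the rest renormalized.
        """
        nk = len(self.model.components)
        w = self.observed_weights[:nk] / self.model._visible
        return w / w.sum()

    def summary(self) -> str:
        lines = ["Stoichiometry mixture fit",
                 "=" * 41,
                 f"{'component':<12}{'observed w':>14}{'population w':>15}"]
        pop = self.population_weights
        nk = len(self.model.components)
        for i, label in enumerate(self.component_labels):
            p = f"{pop[i]:>15.4f}" if i < nk else f"{'--':>15}"
            lines.append(f"{label:<12}{self.observed_weights[i]:>14.4f}{p}")
        if self.p_geo is not None:
            lines.append(f"geometric p = {self.p_geo:.4f}")
        lines.append(f"log-likelihood = {self.log_likelihood:.3f}")
        if not self.identifiable:
            lines.append("WARNING: components not identifiable (equal distributions)")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        out = {
            "components": self.component_labels,
            "observed_weights": [float(v) for v in self.observed_weights],
            "population_weights": [float(v) for v in self.population_weights],
            "log_likelihood": self.log_likelihood,
            "identifiable": self.identifiable,
        }
        if self.p_geo is not None:
            out["p_geo"] = self.p_geo
        return out


def _softmax(x: np.ndarray) -> np.ndarray:
    z = np.exp(x - np.max(x))
    return z / z.sum()


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


# ---------------------------------------------------------------------------
# colocalization vs activity regression
# ---------------------------------------------------------------------------

def linear_relation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Ordinary least squares y ~ x; returns (slope, intercept, R^2).

    Used to relate colocalization levels to functional readouts such as
    splicing efficiency across constructs.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    if np.ptp(y) == 0:
        return 0.0, float(y[0]), 0.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)
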