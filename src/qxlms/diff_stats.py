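"""Differential significance calling between two conditions.

The comparison follows the common label-free qXL-MS recipe: for each link
species, a homoscedastic (pooled-variance) two-sample t-test on normalized
MS1 intensities, with a one-tailed p-value taken in the direction of the
observed mean difference, and a call of *significant* only when p < alpha
AND the fold change (treated mean / control mean) exceeds 2 or falls below
0.5 — both thresholds strict.

Two distinct twofold rules coexist deliberately:

* the significance gate is strict (``fold_change > 2`` or ``< 0.5``);
* the census of links "changed at least twofold" is inclusive (``>= 2`` or
  ``<= 0.5``).

No multiple-testing correction is applied by default (raw p-values against
alpha); a Benjamini-Hochberg helper is provided for users who want it.

Also here: the negative-stain head-count comparison — a two-tailed unpaired
t-test on per-image interacting-heads-motif (IHM) percentages, after
excluding images with fewer than 250 detected particles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from qxlms.quant_norm import AggregatedQuant


class StatError(ValueError):
    """A test's preconditions are not met (e.g. too few replicates)."""


@dataclass
class DifferentialResult:
    """Fold change, one-tailed p and significance call for one link species."""

    key: tuple
    label: str
    link_kind: str
    fold_change: float
    p_value: float
    direction: str  # "increase" | "decrease" | "none"
    significant: bool
    n_control: int
    n_treated: int
    t_stat: float
    df: int
    flags: tuple[str, ...] = ()


def _condition_values(agg: AggregatedQuant, condition: str) -> list[float]:
    return [
        v
        for (c, _r), v in sorted(agg.normalized_intensity.items())
        if c == condition and v is not None
    ]


def differential_test(
    agg: AggregatedQuant,
    control: str,
    treated: str,
    alpha: float = 0.05,
    fc_threshold: float = 2.0,
    tail: str = "auto",
    log_scale: bool = False,
) -> DifferentialResult:
    """Pooled-variance t-test of one aggregated link between two conditions.

    Parameters
    ----------
    agg : AggregatedQuant
        Normalized residue-level intensities.
    control, treated : str
        Condition labels; fold change is mean(treated) / mean(control).
    alpha, fc_threshold : float
        Significance requires ``p < alpha`` and ``fold_change > fc_threshold``
        or ``< 1/fc_threshold`` (strict inequalities).
    tail : {"auto", "increase", "decrease"}
        ``auto`` (default) takes the one-tailed p in the direction of the
        observed mean difference — the only choice that can report both
        increasing and decreasing links from a single procedure.  A fixed
        tail gives the classically calibrated one-sided test.
    log_scale : bool
        Test log-transformed intensities instead of the relative signal
        itself.  Off by default.

    Degenerate inputs are reported, not hidden: zero pooled variance with
    unequal means gives p = 0 and the ``degenerate_variance`` flag; a zero
    control mean gives an infinite fold change and ``zero_control_mean``.
    """
    xs = _condition_values(agg, control)
    ys = _condition_values(agg, treated)
    if len(xs) < 2 or len(ys) < 2:
        raise StatError(
            f"link {agg.link.label}: need >=2 non-missing replicates per "
            f"condition (control {len(xs)}, treated {len(ys)})"
        )

    flags: list[str] = []
    mean_c, mean_t = float(np.mean(xs)), float(np.mean(ys))
    if mean_c == 0.0:
        fold_change = math.inf if mean_t > 0 else 1.0
        if mean_t > 0:
            flags.append("zero_control_mean")
    else:
        fold_change = mean_t / mean_c

    if log_scale:
        if min(xs) <= 0 or min(ys) <= 0:
            raise StatError("log-scale test requires strictly positive signal")
        data_c, data_t = np.log(xs), np.log(ys)
    else:
        data_c, data_t = np.asarray(xs, float), np.asarray(ys, float)

    df = len(xs) + len(ys) - 2
    pooled_var = (
        (len(xs) - 1) * np.var(data_c, ddof=1) + (len(ys) - 1) * np.var(data_t, ddof=1)
    ) / df
    diff = float(np.mean(data_t) - np.mean(data_c))

    if pooled_var == 0.0:
        flags.append("degenerate_variance")
        t_stat = math.inf if diff > 0 else (-math.inf if diff < 0 else 0.0)
        p_value = 0.0 if diff != 0 else 1.0
    else:
        if tail == "auto":
            alternative = "greater" if diff >= 0 else "less"
        elif tail == "increase":
            alternative = "greater"
        elif tail == "decrease":
            alternative = "less"
        else:
            raise ValueError(f"unknown tail {tail!r}")
        with warnings.catch_warnings():
            # scipy warns about precision on near-constant data; the huge-t,
            # tiny-p outcome it produces there is exactly what we report
            warnings.simplefilter("ignore", RuntimeWarning)
            t_stat, p_value = stats.ttest_ind(
                data_t, data_c, equal_var=True, alternative=alternative
            )
        t_stat, p_value = float(t_stat), float(p_value)

    if fold_change > 1.0:
        direction = "increase"
    elif fold_change < 1.0:
        direction = "decrease"
    else:
        direction = "none"
    significant = bool(
        p_value < alpha
        and (fold_change > fc_threshold or fold_change < 1.0 / fc_threshold)
    )
    return DifferentialResult(
        key=agg.link.key,
        label=agg.link.label,
        link_kind=agg.link.link_kind,
        fold_change=fold_change,
        p_value=p_value,
        direction=direction,
        significant=significant,
        n_control=len(xs),
        n_treated=len(ys),
        t_stat=t_stat,
        df=df,
        flags=tuple(flags),
    )


def count_changed_links(
    results: Iterable[DifferentialResult], min_fc: float = 2.0
) -> dict[str, int]:
    """Census of link species changed at least ``min_fc``-fold (inclusive).

    Returns counts keyed by link kind (interpeptide / intrapeptide /
    monolink).  Inclusive thresholds: ``fold_change >= min_fc`` or
    ``<= 1/min_fc`` counts as changed — distinct from the strict
    significance gate in :func:`differential_test`.
    """
    counts = {"interpeptide": 0, "intrapeptide": 0, "monolink": 0}
    for res in results:
        fc = res.fold_change
        if fc >= min_fc or fc <= 1.0 / min_fc:
            counts[res.link_kind] = counts.get(res.link_kind, 0) + 1
    return counts


def benjamini_hochberg(results: Sequence[DifferentialResult]) -> dict[tuple, float]:
    """Optional BH-adjusted p-values keyed by link key (off the main path)."""
    keys = [r.key for r in results]
    adjusted = stats.false_discovery_control(
        [r.p_value for r in results], method="bh"
    )
    return dict(zip(keys, (float(q) for q in adjusted)))


# ---------------------------------------------------------------------------
# negative-stain head counting


@dataclass
class HeadCountSample:
    """Per-image particle counts: open heads vs folded-back (IHM) molecules."""

    n_open: int
    n_ihm: int
    condition: str = ""

    @property
    def total(self) -> int:
        return self.n_open + self.n_ihm

    @property
    def ihm_fraction(self) -> float:
        return self.n_ihm / self.total

    def included(self, min_particles: int = 250) -> bool:
        return self.total >= min_particles


@dataclass
class HeadCountComparison:
    p_value: float
    t_stat: float
    fractions_a: tuple[float, ...]
    fractions_b: tuple[float, ...]
    excluded_a: int
    excluded_b: int


def headcount_compare(
    samples_a: Sequence[HeadCountSample],
    samples_b: Sequence[HeadCountSample],
    min_particles: int = 250,
) -> HeadCountComparison:
    """Two-tailed unpaired t-test on per-image IHM percentages.

    Images with fewer than ``min_particles`` detected particles are excluded
    before testing (so each retained image carries enough particles for a
    stable percentage); each condition needs at least two included images.
    """
    kept_a = [s for s in samples_a if s.included(min_particles)]
    kept_b = [s for s in samples_b if s.included(min_particles)]
    if len(kept_a) < 2 or len(kept_b) < 2:
        raise StatError(
            f"need >=2 images of >= {min_particles} particles per condition "
            f"(got {len(kept_a)} and {len(kept_b)})"
        )
    pct_a = [100.0 * s.ihm_fraction for s in kept_a]
    pct_b = [100.0 * s.ihm_fraction for s in kept_b]
    if np.var(pct_a, ddof=1) == 0 and np.var(pct_b, ddof=1) == 0:
        t_stat, p_value = 0.0, 1.0
        if np.mean(pct_a) != np.mean(pct_b):
            t_stat, p_value = math.inf, 0.0
    else:
        t_stat, p_value = stats.ttest_ind(pct_a, pct_b, equal_var=True)
        t_stat, p_value = float(t_stat), float(p_value)
    return HeadCountComparison(
        p_value=p_value,
        t_stat=t_stat,
        fractions_a=tuple(s.ihm_fraction for s in kept_a),
        fractions_b=tuple(s.ihm_fraction for s in kept_b),
        excluded_a=len(samples_a) - len(kept_a),
        excluded_b=len(samples_b) - len(kept_b),
    )
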