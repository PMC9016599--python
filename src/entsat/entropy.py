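"""Entropy-based test of substitution saturation.

Under full saturation every alignment column is an independent multinomial
draw from the overall base composition, and the alignment attains maximal
entropy. The test compares the mean per-site information content against the
exact entropy of a multinomial sample, with a one-sample t-statistic

    t = (mean(I) - H_full) / (sd(I) / sqrt(S)).

At full saturation the mean per-site information equals the full-saturation
entropy and t sits near zero; historical signal concentrates columns on
patterns that are improbable under the pooled multinomial, driving the mean
information above H_full and t to large positive values. *Small* t therefore
means the alignment is close to full saturation, and a locus is flagged
saturated when t falls below a simulation-calibrated critical value. All
entropies are reported in bits; t itself is invariant to the log base.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln
from scipy.stats import binom

from .align import (
    Alignment,
    BaseComposition,
    SiteCounts,
    informative_mask,
    site_count_matrix,
)
from .errors import (
    DegenerateVarianceError,
    InfiniteInformationError,
    InsufficientSitesError,
    UndefinedCompositionError,
)

__all__ = [
    "expected_full_entropy",
    "site_information",
    "entropy_t_statistic",
    "run_saturation_test",
    "SaturationTestResult",
]

_LN2 = np.log(2.0)

ALL_SITES = "all_sites"
INFORMATIVE_SITES = "informative_sites"


def _check_simplex(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or (p < 0).any() or abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("p must be a probability simplex")
    return p


def expected_full_entropy(n: int, p) -> float:
    """Exact entropy, in bits, of a multinomial sample of size ``n``.

    For counts X ~ Multinomial(n, p) over k categories,

        H(X) = -log2(n!) - n * sum_i p_i log2 p_i
               + sum_i sum_{x=0..n} Binom(x; n, p_i) * log2(x!).

    Categories with ``p_i = 0`` contribute nothing. Factorials are evaluated
    through log-gamma, and the binomial expectation is the exact finite sum
    over ``0..n`` (no approximation).
    """
    if n < 1 or int(n) != n:
        raise ValueError("n must be a positive integer")
    n = int(n)
    p = _check_simplex(p)
    nz = p > 0
    h = -gammaln(n + 1) / _LN2
    h += -n * np.sum(p[nz] * np.log2(p[nz]))
    x = np.arange(n + 1)
    logfact = gammaln(x + 1) / _LN2
    for pi in p[nz]:
        h += float(np.dot(binom.pmf(x, n, pi), logfact))
    return float(h)


def _information_profile(counts: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Vectorised -log2 multinomial pmf for a ``(S, 4)`` count matrix."""
    counts = np.asarray(counts, dtype=np.int64)
    if ((counts > 0) & (p == 0)).any():
        raise InfiniteInformationError(
            "a site contains a nucleotide with zero composition probability"
        )
    n = counts.sum(axis=1)
    logp = np.where(p > 0, np.log2(np.where(p > 0, p, 1.0)), 0.0)
    logpmf = (
        gammaln(n + 1) / _LN2
        - (gammaln(counts + 1) / _LN2).sum(axis=1)
        + counts @ logp
    )
    return -logpmf


def site_information(counts: SiteCounts | np.ndarray, p) -> float:
    """Information content, in bits, of one column's nucleotide counts.

    ``I(x) = -log2 P(X = x)`` where X ~ Multinomial(n_obs, p).
    """
    vec = counts.counts if isinstance(counts, SiteCounts) else np.asarray(counts)
    vec = vec.astype(np.int64)
    if vec.sum() < 1:
        raise ValueError("site has no observed states")
    p = _check_simplex(p)
    return float(_information_profile(vec[None, :], p)[0])


def entropy_t_statistic(informations, H_full: float) -> float:
    """One-sample t of per-site information against full-saturation entropy.

    Uses the sample standard deviation (S-1 denominator). Larger values mean
    the alignment is farther from full saturation.
    """
    info = np.asarray(informations, dtype=float)
    S = info.size
    if S < 2:
        raise InsufficientSitesError(f"need >= 2 sites, got {S}")
    mean = info.mean()
    sd = info.std(ddof=1)
    if sd == 0.0:
        if mean == H_full:
            return 0.0
        raise DegenerateVarianceError(
            "zero variance in site information with nonzero distance to full entropy"
        )
    return float((mean - H_full) / (sd / np.sqrt(S)))


@dataclass
class SaturationTestResult:
    """Outcome of the saturation test on one alignment.

    ``decision`` is ``None`` when no critical-value model was supplied,
    ``"saturated"``/``"unsaturated"`` otherwise; batch screening may override
    it with ``"not_testable"`` when its filters fail before the test runs.
    """

    t_obs: float
    mode: str
    H_full: float
    mean_I: float
    sd_I: float
    S: int
    n_used: int
    p_used: BaseComposition
    t_crit: float | None = None
    decision: str | None = None
    expected_fpr: float | None = None
    expected_tpr: float | None = None
    extrapolated: bool = False


def run_saturation_test(
    aln: Alignment,
    mode: str = INFORMATIVE_SITES,
    crit=None,
) -> SaturationTestResult:
    """Run the entropy saturation test on an alignment.

    Parameters
    ----------
    aln:
        Alignment with at least two taxa.
    mode:
        ``"informative_sites"`` restricts the test (and the base composition
        entering both entropy formulas) to parsimony-informative columns,
        removing the influence of slowly evolving sites on the composition;
        ``"all_sites"`` uses every column with at least one observed state.
    crit:
        Optional fitted critical-value model (see
        :class:`entsat.calibration.CritModel`). When given, the critical value
        is predicted from the taxon count and the number of sites entering the
        test, and the alignment is called ``saturated`` when
        ``t_obs < t_crit``.

    Columns differing in observation count from the modal one (missing data)
    are scored against the full-saturation entropy for their own ``n_obs``:
    their information is shifted by ``H(modal n) - H(column n)`` so every site
    is measured on a common scale.
    """
    if mode not in (ALL_SITES, INFORMATIVE_SITES):
        raise ValueError(f"unknown mode {mode!r}")
    if aln.n_taxa < 2:
        raise ValueError("need at least two taxa")

    counts = site_count_matrix(aln)
    if mode == INFORMATIVE_SITES:
        sel = informative_mask(aln)
    else:
        sel = np.ones(aln.n_sites, dtype=bool)
    sel &= counts.sum(axis=1) > 0
    selected = counts[sel]
    S = selected.shape[0]
    if S < 2:
        raise InsufficientSitesError(
            f"{S} usable site(s) in mode {mode!r}; need at least 2"
        )

    total = selected.sum()
    if total == 0:
        raise UndefinedCompositionError("no observed states in selected sites")
    p = selected.sum(axis=0) / total
    n_obs = selected.sum(axis=1)
    values, freq = np.unique(n_obs, return_counts=True)
    n_used = int(values[np.nonzero(freq == freq.max())[0][-1]])

    comp = BaseComposition(p, source=mode, n_effective=n_used)
    H_full = expected_full_entropy(n_used, p)
    info = _information_profile(selected, p)
    if values.size > 1:
        h_by_n = {int(v): expected_full_entropy(int(v), p) for v in values}
        info = info + (H_full - np.array([h_by_n[int(v)] for v in n_obs]))

    t_obs = entropy_t_statistic(info, H_full)
    result = SaturationTestResult(
        t_obs=t_obs,
        mode=mode,
        H_full=H_full,
        mean_I=float(info.mean()),
        sd_I=float(info.std(ddof=1)),
        S=S,
        n_used=n_used,
        p_used=comp,
    )
    if crit is not None:
        t_crit, tpr, fpr, extrapolated = crit.predict(aln.n_taxa, S)
        result.t_crit = float(t_crit)
        result.expected_tpr = tpr
        result.expected_fpr = fpr
        result.extrapolated = bool(extrapolated)
        result.decision = "saturated" if t_obs < t_crit else "unsaturated"
    return result
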