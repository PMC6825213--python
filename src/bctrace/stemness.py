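"""Leukemia-initiating-cell (L-IC) statistics.

Implements the xenograft readouts of barcoded-clone experiments: scoring a
recipient mouse positive for leukemia, estimating L-IC frequency from a
limiting-dilution design under the single-hit Poisson model (the ELDA-style
analysis), converting that population frequency into per-lineage expected
L-IC numbers and establishment probabilities, and calling lineages
established in more mice than the Poisson model expects (HiL-IC lineages).

Single-hit model: a mouse injected with ``d`` cells at L-IC frequency ``f``
is negative with probability exp(-f*d).  The frequency MLE maximizes the
binomial likelihood over dose groups; confidence bounds invert the
chi-square(1) profile-likelihood threshold on the log-frequency scale, with
a Wald interval on log f reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps


class StemnessError(ValueError):
    pass


POSITIVITY_THRESHOLD = 0.005  # fraction of mouse leukocytes, strict ">"


def score_mouse_positive(
    tibia_fraction: float | None,
    bone_marrow_fraction: float | None,
    threshold: float = POSITIVITY_THRESHOLD,
) -> bool:
    """Score a xenografted mouse positive for human AML engraftment.

    Positive iff the human AML fraction exceeds the threshold (default 0.5%
    of mouse leukocytes, strictly) in either the injected tibia or the
    pooled remaining bone marrow.  A missing measurement is ignored; both
    missing is an error.
    """
    if tibia_fraction is None and bone_marrow_fraction is None:
        raise StemnessError("both engraftment measurements missing")
    for frac in (tibia_fraction, bone_marrow_fraction):
        if frac is not None and not (0.0 <= frac <= 1.0):
            raise StemnessError(f"engraftment fraction {frac} outside [0, 1]")
    tibia = tibia_fraction if tibia_fraction is not None else 0.0
    marrow = bone_marrow_fraction if bone_marrow_fraction is not None else 0.0
    return tibia > threshold or marrow > threshold


# ---------------------------------------------------------------------------
# Limiting-dilution estimation
# ---------------------------------------------------------------------------


@dataclass
class LDAResult:
    """L-IC frequency estimate (per cell) with confidence bounds."""

    f_hat: float
    ci_lower: float
    ci_upper: float
    confidence: float
    all_negative: bool = False
    all_positive: bool = False
    wald_lower: float | None = None
    wald_upper: float | None = None
    log_likelihood: float | None = None

    @property
    def cells_per_lic(self) -> float:
        """1 L-IC per this many cells (inf when f_hat = 0)."""
        return math.inf if self.f_hat == 0 else 1.0 / self.f_hat


def _validate_design(design: pd.DataFrame) -> pd.DataFrame:
    req = {"dose", "tested", "positive"}
    missing = req - set(design.columns)
    if missing:
        raise StemnessError(f"design missing columns {sorted(missing)}")
    d = design[["dose", "tested", "positive"]].astype(float)
    if len(d) == 0:
        raise StemnessError("empty limiting-dilution design")
    if (d["dose"] <= 0).any():
        raise StemnessError("doses must be positive")
    if d["tested"].sum() == 0:
        raise StemnessError("no mice tested")
    if ((d["positive"] < 0) | (d["positive"] > d["tested"])).any():
        raise StemnessError("positive counts outside [0, tested]")
    return d


def _log_likelihood(f: float, dose, tested, positive) -> float:
    """Binomial log likelihood of the single-hit model (constants dropped)."""
    if f < 0:
        return -np.inf
    if f == 0:
        return 0.0 if positive.sum() == 0 else -np.inf
    lam = f * dose
    p_pos = -np.expm1(-lam)  # 1 - exp(-f d)
    with np.errstate(divide="ignore"):
        ll = positive * np.log(p_pos) - (tested - positive) * lam
    return float(np.sum(ll))


def fit_limiting_dilution(
    design: pd.DataFrame, confidence: float = 0.95
) -> LDAResult:
    """Estimate L-IC frequency from a (dose, tested, positive) design.

    Returns the MLE with profile-likelihood confidence bounds (and a Wald
    interval on log f alongside).  Boundary designs are flagged: all mice
    negative gives f_hat = 0 with a one-sided upper bound; all mice positive
    gives f_hat = inf with a one-sided lower bound.
    """
    d = _validate_design(design)
    dose = d["dose"].to_numpy()
    tested = d["tested"].to_numpy()
    positive = d["positive"].to_numpy()
    chi = sps.chi2.ppf(confidence, df=1)
    half_chi = chi / 2.0

    total_pos = positive.sum()
    total_neg = (tested - positive).sum()

    if total_pos == 0:
        # likelihood is exp(-f * sum(n_i d_i)); profile upper bound solves
        # -f * sum(n d) = -chi/2
        upper = half_chi / float(np.sum(tested * dose))
        return LDAResult(
            f_hat=0.0,
            ci_lower=0.0,
            ci_upper=upper,
            confidence=confidence,
            all_negative=True,
            log_likelihood=0.0,
        )

    def nll(log_f: float) -> float:
        return -_log_likelihood(math.exp(log_f), dose, tested, positive)

    if total_neg == 0:
        # MLE diverges; lower bound solves ll(f) = -chi/2 (sup ll = 0)
        def lower_eq(log_f: float) -> float:
            return _log_likelihood(math.exp(log_f), dose, tested, positive) + half_chi

        lo = math.log(1e-12 / dose.max())
        hi = math.log(1e3 / dose.min())
        lower = math.exp(optimize.brentq(lower_eq, lo, hi, xtol=1e-14))
        return LDAResult(
            f_hat=math.inf,
            ci_lower=lower,
            ci_upper=math.inf,
            confidence=confidence,
            all_positive=True,
            log_likelihood=0.0,
        )

    res = optimize.minimize_scalar(
        nll,
        bounds=(math.log(1e-12 / dose.max()), math.log(50.0 / dose.min())),
        method="bounded",
        options={"xatol": 1e-12},
    )
    f_hat = math.exp(res.x)
    ll_hat = -res.fun

    def profile_eq(log_f: float) -> float:
        return (
            _log_likelihood(math.exp(log_f), dose, tested, positive)
            - ll_hat
            + half_chi
        )

    log_lo_bracket = math.log(1e-14 / dose.max())
    log_hi_bracket = math.log(1e4 / dose.min())
    lower = math.exp(
        optimize.brentq(profile_eq, log_lo_bracket, res.x, xtol=1e-14)
    )
    upper = math.exp(
        optimize.brentq(profile_eq, res.x, log_hi_bracket, xtol=1e-14)
    )

    # Wald interval on log f from the numerical observed information
    eps = 1e-5
    ll = lambda t: _log_likelihood(math.exp(t), dose, tested, positive)
    second = (ll(res.x + eps) - 2.0 * ll_hat + ll(res.x - eps)) / eps**2
    wald_lower = wald_upper = None
    if second < 0:
        se = math.sqrt(-1.0 / second)
        z = sps.norm.ppf(0.5 + confidence / 2.0)
        wald_lower = math.exp(res.x - z * se)
        wald_upper = math.exp(res.x + z * se)

    return LDAResult(
        f_hat=f_hat,
        ci_lower=lower,
        ci_upper=upper,
        confidence=confidence,
        wald_lower=wald_lower,
        wald_upper=wald_upper,
        log_likelihood=ll_hat,
    )


# ---------------------------------------------------------------------------
# Per-lineage expectations and HiL-IC calling
# ---------------------------------------------------------------------------


def expected_engraftment_prob(
    f_hat: float,
    dose: float,
    frequencies: pd.Series,
    mode: str = "proportional",
) -> pd.DataFrame:
    """Expected L-ICs per lineage and per-mouse establishment probability.

    The total expected L-IC number per mouse is Lambda = f_hat * dose.  In
    ``proportional`` mode (default) each lineage's expectation is
    Lambda * freq_i -- L-ICs spread evenly among cells, so large lineages
    carry proportionally more.  In ``even`` mode Lambda is split equally
    across lineages.  Establishment probability p_i = 1 - exp(-lambda_i).
    """
    if f_hat < 0:
        raise StemnessError("f_hat must be >= 0")
    total = float(frequencies.sum())
    if abs(total - 1.0) > 1e-6:
        raise StemnessError(f"injection frequencies sum to {total:.6g}, not 1")
    lam_total = f_hat * dose
    if mode == "proportional":
        lam = lam_total * frequencies.astype(float)
    elif mode == "even":
        lam = pd.Series(
            lam_total / len(frequencies), index=frequencies.index, dtype=float
        )
    else:
        raise StemnessError(f"unknown allocation mode {mode!r}")
    p = 1.0 - np.exp(-lam)
    out = pd.DataFrame({"lambda": lam, "establishment_prob": p})
    out.index.name = "barcode_id"
    return out


def _poisson_binomial_tail(k: int, probs: np.ndarray) -> float:
    """Exact P(X >= k) for a sum of independent Bernoulli(p_j), by DP."""
    pmf = np.zeros(len(probs) + 1)
    pmf[0] = 1.0
    for p in probs:
        pmf[1:] = pmf[1:] * (1.0 - p) + pmf[:-1] * p
        pmf[0] *= 1.0 - p
    return float(pmf[k:].sum())


def call_hilic(
    engraftment: pd.DataFrame,
    establishment_prob: pd.Series | pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Call lineages established in more mice than the Poisson model expects.

    ``engraftment`` is a mouse x barcode 0/1 presence table over positive
    mice.  ``establishment_prob`` gives each lineage's per-mouse
    establishment probability p_i: a Series when all mice received the same
    dose, or a mouse x barcode DataFrame of per-mouse probabilities when
    doses differ (the tail is then an exact Poisson-binomial sum).

    Per lineage the one-sided tail P(X >= k_i) is computed for k_i observed
    established mice of M; HiL-IC iff k_i >= 1 and tail p < alpha.
    """
    if engraftment.shape[0] < 1:
        raise StemnessError("engraftment table has no mice")
    vals = engraftment.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise StemnessError("engraftment table must be 0/1")
    m = engraftment.shape[0]
    k = engraftment.sum(axis=0)

    rows = []
    for bc in engraftment.columns:
        ki = int(k[bc])
        if ki > m:
            raise StemnessError(f"barcode {bc!r}: {ki} established of {m} mice")
        if isinstance(establishment_prob, pd.DataFrame):
            probs = (
                establishment_prob.loc[engraftment.index, bc]
                .to_numpy(dtype=float)
            )
            p_rep = float(probs.mean())
            tail = _poisson_binomial_tail(ki, probs) if ki > 0 else 1.0
        else:
            p_i = float(establishment_prob[bc])
            p_rep = p_i
            tail = float(sps.binom.sf(ki - 1, m, p_i)) if ki > 0 else 1.0
        rows.append(
            {
                "barcode_id": bc,
                "established_mice": ki,
                "total_mice": m,
                "establishment_prob": p_rep,
                "tail_p": tail,
                "hilic": ki >= 1 and tail < alpha,
            }
        )
    return pd.DataFrame(rows).set_index("barcode_id")


def overlap_with_core(
    hilic_barcodes: Sequence[str] | frozenset[str],
    core_barcodes: Sequence[str] | frozenset[str],
    universe: Sequence[str] | None = None,
) -> dict:
    """Overlap between HiL-IC lineages and the chemoresistant core.

    When a shared barcode universe is given, both sets must be drawn from
    it.  Returns identities and counts of the intersection and each
    exclusive remainder.
    """
    hi = set(map(str, hilic_barcodes))
    core = set(map(str, core_barcodes))
    if universe is not None:
        uni = set(map(str, universe))
        stray = (hi | core) - uni
        if stray:
            raise StemnessError(
                f"sets contain barcodes outside the shared universe: "
                f"{sorted(stray)[:10]}"
            )
    both = hi & core
    return {
        "overlap": sorted(both),
        "hilic_only": sorted(hi - core),
        "core_only": sorted(core - hi),
        "n_overlap": len(both),
        "n_hilic_only": len(hi - core),
        "n_core_only": len(core - hi),
    }
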